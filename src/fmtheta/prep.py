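"""Trial selection, Go subsampling, and ERF correction.

The fixed preprocessing order is reject -> subsample -> ERF-correct:
incorrect and anticipatory trials are removed first, then a single-pass
variance screen; correct Go trials are randomly subsampled to the NoGo
count (equating trial numbers for the beamformer); finally the per-condition
trial-average waveform (the event-related field) is subtracted from every
trial so that only induced, non-phase-locked activity remains.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .epochs import EpochSet

KEPT = "kept"
INCORRECT = "incorrect"
ANTICIPATORY = "anticipatory"
HIGH_VARIANCE = "high_variance"


@dataclass
class RejectionLog:
    """Per-trial dispositions; the categories partition the input trials."""

    disposition: np.ndarray  # array of str, one per input trial
    variance_stat: np.ndarray  # per-trial channel-averaged variance
    variance_threshold: float

    @property
    def counts(self) -> dict:
        vals, cnts = np.unique(self.disposition, return_counts=True)
        out = {k: 0 for k in (KEPT, INCORRECT, ANTICIPATORY, HIGH_VARIANCE)}
        out.update(dict(zip(vals.tolist(), cnts.tolist())))
        return out

    @property
    def kept_indices(self) -> np.ndarray:
        return np.flatnonzero(self.disposition == KEPT)

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(
                {
                    "disposition": self.disposition.tolist(),
                    "counts": self.counts,
                    "variance_threshold": float(self.variance_threshold),
                },
                f,
                indent=2,
            )


def reject_epochs(epochs: EpochSet) -> tuple[EpochSet, RejectionLog]:
    """Remove incorrect, anticipatory, and high-variance trials.

    Rules, applied in order: (1) incorrect trials; (2) trials with an
    emitted response faster than or equal to 100 ms; (3) trials whose
    epoch-variance statistic exceeds mean + 2 SD of that statistic.  The
    variance statistic is the per-channel temporal variance averaged over
    channels, and the screen runs once on the trials surviving rules 1–2
    (single pass, no re-iteration).
    """
    if epochs.n_trials == 0:
        raise ValueError("cannot reject from an empty epoch set")
    meta = epochs.trial_meta
    disposition = np.full(epochs.n_trials, KEPT, dtype=object)

    correct = meta["correct"].to_numpy(bool)
    rt = meta["rt_ms"].to_numpy(float)
    disposition[~correct] = INCORRECT
    anticipatory = correct & np.isfinite(rt) & (rt <= 100.0)
    disposition[anticipatory] = ANTICIPATORY

    var_stat = epochs.data.var(axis=2).mean(axis=1)
    survivors = disposition == KEPT
    v = var_stat[survivors]
    threshold = float(v.mean() + 2.0 * v.std(ddof=1)) if survivors.sum() > 1 else np.inf
    outlier = survivors & (var_stat > threshold)
    disposition[outlier] = HIGH_VARIANCE

    log = RejectionLog(
        disposition=disposition.astype(str),
        variance_stat=var_stat,
        variance_threshold=threshold,
    )
    kept = log.kept_indices
    if len(kept) < 0.5 * epochs.n_trials:
        warnings.warn(
            f"rejected {epochs.n_trials - len(kept)}/{epochs.n_trials} trials",
            stacklevel=2,
        )
    return epochs.select(kept), log


def subsample_go(epochs: EpochSet, seed: int) -> EpochSet:
    """Random subsample of Go trials matched to the NoGo count.

    NoGo trials are untouched; the retained Go trials are a uniform random
    subset without replacement, and the relative temporal order of all
    retained trials is preserved.  Reproducible from ``seed``.
    """
    go = np.flatnonzero(epochs.condition_mask("Go"))
    nogo = np.flatnonzero(epochs.condition_mask("NoGo"))
    if len(go) < len(nogo):
        raise ValueError("fewer Go than NoGo trials; cannot subsample")
    rng = np.random.default_rng(seed)
    chosen_go = rng.choice(go, size=len(nogo), replace=False)
    keep = np.sort(np.concatenate([chosen_go, nogo]))
    return epochs.select(keep)


def erf_correct(epochs: EpochSet) -> EpochSet:
    """Subtract the per-condition trial-average waveform from every trial.

    Performed separately for Go and NoGo trials; after correction the
    across-trial mean within each condition is zero to float precision,
    isolating induced (non-phase-locked) activity.
    """
    data = epochs.data.copy()
    for cond in ("Go", "NoGo"):
        mask = epochs.condition_mask(cond)
        if mask.sum() == 0:
            continue
        if mask.sum() < 2:
            raise ValueError(f"condition {cond} has fewer than 2 trials")
        data[mask] -= data[mask].mean(axis=0, keepdims=True)
    out = epochs.select(np.arange(epochs.n_trials))
    out.data = data
    return out
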