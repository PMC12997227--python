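"""Shared epoch container for sensor- and source-space trial data.

An :class:`EpochSet` holds a trials x channels x samples array together with
per-trial behavioral metadata.  The same container is reused for virtual
(source) time series, where "channels" are grid points.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

META_COLUMNS = ("condition", "correct", "rt_ms", "onset_s")


@dataclass
class EpochSet:
    """Trials x channels x samples array (tesla) with trial metadata.

    The time axis is uniform with step 1/sfreq starting at ``tmin``;
    ``trial_meta`` must have one row per trial with columns
    condition ('Go'/'NoGo'), correct (bool), rt_ms (float, NaN when no
    response was emitted), onset_s (stimulus onset within the block).
    """

    data: np.ndarray
    sfreq: float
    tmin: float
    trial_meta: pd.DataFrame
    subject_id: str = "S00"
    group: str = "control"
    chan_pos: np.ndarray | None = None
    chan_ori: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if len(self.trial_meta) != self.data.shape[0]:
            raise ValueError("trial_meta length must equal trial count")
        missing = [c for c in META_COLUMNS if c not in self.trial_meta.columns]
        if missing:
            raise ValueError(f"trial_meta missing columns: {missing}")
        self.trial_meta = self.trial_meta.reset_index(drop=True)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.n_samples) / self.sfreq

    def select(self, indices) -> "EpochSet":
        """Subset of trials (indices keep their original relative order)."""
        idx = np.asarray(indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            data=self.data[idx],
            trial_meta=self.trial_meta.iloc[idx].reset_index(drop=True),
        )

    def condition_mask(self, condition: str) -> np.ndarray:
        return (self.trial_meta["condition"] == condition).to_numpy()

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data, compression="gzip")
            f.create_dataset("time", data=self.times)
            if self.chan_pos is not None:
                f.create_dataset("chan_pos", data=self.chan_pos)
            if self.chan_ori is not None:
                f.create_dataset("chan_ori", data=self.chan_ori)
            ev = f.create_group("events")
            meta = self.trial_meta
            ev.create_dataset(
                "condition", data=np.array(meta["condition"], dtype="S8")
            )
            ev.create_dataset("correct", data=meta["correct"].to_numpy(bool))
            ev.create_dataset("rt_ms", data=meta["rt_ms"].to_numpy(float))
            ev.create_dataset("onset_s", data=meta["onset_s"].to_numpy(float))
            f.attrs["subject_id"] = self.subject_id
            f.attrs["group"] = self.group
            f.attrs["sfreq"] = self.sfreq
            f.attrs["tmin"] = self.tmin
            if self.seed is not None:
                f.attrs["seed"] = int(self.seed)

    @classmethod
    def load(cls, path) -> "EpochSet":
        with h5py.File(path, "r") as f:
            data = f["data"][()]
            meta = pd.DataFrame(
                {
                    "condition": [c.decode() for c in f["events/condition"][()]],
                    "correct": f["events/correct"][()].astype(bool),
                    "rt_ms": f["events/rt_ms"][()],
                    "onset_s": f["events/onset_s"][()],
                }
            )
            return cls(
                data=data,
                sfreq=float(f.attrs["sfreq"]),
                tmin=float(f.attrs["tmin"]),
                trial_meta=meta,
                subject_id=str(f.attrs["subject_id"]),
                group=str(f.attrs["group"]),
                chan_pos=f["chan_pos"][()] if "chan_pos" in f else None,
                chan_ori=f["chan_ori"][()] if "chan_ori" in f else None,
                seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
            )
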