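"""End-to-end orchestration of the Go/NoGo frontal-midline-theta analysis.

Stage order mirrors the analysis design: simulate -> prep (reject,
subsample, ERF-correct) -> localize (common LCMV filter, virtual time
series) -> tfr (source-space Hanning TFR, relative change) -> cluster
(dependent-samples cluster-mass permutation over the grid, control group)
-> roi (mixed model, ΔFMΘ battery) -> behavior -> report.

Two entry styles are provided: :func:`analyze_cohort` runs everything in
memory and returns a result bundle (used by the test-suite and the
acceptance script), while :func:`run_pipeline` executes the staged,
file-backed, resumable workflow configured from YAML.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .beamform import apply_filters, compute_covariance, lcmv_filters
from .cluststat import ClusterResult, cluster_perm_dep
from .epochs import EpochSet
from .forward import (
    Leadfield,
    SensorGeometry,
    SourceGrid,
    build_grid,
    compute_leadfield,
    helmet_geometry,
)
from .prep import erf_correct, reject_epochs, subsample_go
from .roipipe import delta_table, roi_power_table, run_group_battery
from .spectral import ANALYSIS_WINDOW, average_window, baseline_correct, tfr_hanning
from .statskit import BehavioralCounts, bootstrap_stability, dprime, rank_sum_test
from .synthgen import (
    CohortSpec,
    TaskDesign,
    cohort_ground_truth,
    generate_behavior,
    make_cohort_profiles,
    null_cohort_spec,
    simulate_epochs,
)


@dataclass
class AnalysisParams:
    """Numerical scale of one end-to-end analysis run."""

    sfreq: float = 250.0
    n_sensors: int = 60
    grid_spacing_mm: float = 15.0
    connectivity: int = 6
    margin: float = 0.9
    lambda_frac: float = 0.05
    alpha_form: float = 0.05
    cluster_alpha: float = 0.05
    n_perm: int = 500
    n_boot: int = 2000
    freqs: np.ndarray = field(default_factory=lambda: np.arange(3.0, 6.01, 0.5))
    times: np.ndarray = field(
        default_factory=lambda: np.concatenate(
            [np.arange(-1.0, -0.5 + 1e-9, 0.05), np.arange(0.25, 0.5 + 1e-9, 0.05)]
        )
    )
    window_length: float = 1.0
    pad_to: float = 8.0


def reduced_params() -> AnalysisParams:
    """Desk-scale parameters used for repeated-cohort simulation studies."""
    return AnalysisParams(
        sfreq=100.0, n_sensors=32, grid_spacing_mm=24.0, n_perm=500, n_boot=500
    )


def paper_scale_params() -> AnalysisParams:
    """The full-scale settings of the target analysis (slow; not a default)."""
    return AnalysisParams(
        sfreq=500.0,
        n_sensors=102,
        grid_spacing_mm=6.0,
        n_perm=10_000,
        n_boot=10_000,
        freqs=np.arange(1.0, 15.01, 0.5),
        times=np.arange(-1.5, 1.5 + 1e-9, 0.05),
    )


def reduced_cohort_spec(effect: str = "paper", n_trials: int = 96) -> CohortSpec:
    """Cohort generation spec at a reduced per-subject trial count.

    ``effect='paper'`` plants the study-condition group structure
    (stroke tonic theta 0.6x, no NoGo gain); ``effect='null'`` makes both
    groups generatively identical for calibration runs.
    """
    design = TaskDesign(n_trials=n_trials)
    if effect == "paper":
        return CohortSpec(design=design)
    if effect == "null":
        return null_cohort_spec(design=design)
    raise ValueError("effect must be 'paper' or 'null'")


@dataclass
class ForwardBundle:
    geometry: SensorGeometry
    grid: SourceGrid
    leadfield: Leadfield


def make_forward(params: AnalysisParams) -> ForwardBundle:
    geometry = helmet_geometry(params.n_sensors)
    grid = build_grid(
        geometry, params.grid_spacing_mm, params.connectivity, params.margin
    )
    return ForwardBundle(geometry, grid, compute_leadfield(grid, geometry))


@dataclass
class SubjectResult:
    subject_id: str
    group: str
    raw: dict  # condition -> TFRMap over valid source points
    rel: dict  # condition -> relchange TFRMap
    contrast: np.ndarray  # per valid source point, NoGo - Go window mean
    valid_points: np.ndarray  # indices into the grid of the virtual channels
    n_kept: int
    rejection_counts: dict


def analyze_subject(
    epochs: EpochSet,
    leadfield: Leadfield,
    params: AnalysisParams,
    seed: int,
) -> SubjectResult:
    """Sensor epochs -> source TFRs and the per-source NoGo - Go contrast."""
    kept, log = reject_epochs(epochs)
    matched = subsample_go(kept, seed)
    induced = erf_correct(matched)
    cov = compute_covariance(induced)
    filters = lcmv_filters(cov, leadfield, params.lambda_frac)
    source = apply_filters(induced, filters)

    raw, rel = {}, {}
    for cond in ("Go", "NoGo"):
        sub = source.select(source.condition_mask(cond))
        tfr = tfr_hanning(
            sub,
            freqs=params.freqs,
            times=params.times,
            window_length=params.window_length,
            pad_to=params.pad_to,
        )
        raw[cond] = tfr
        rel[cond] = baseline_correct(tfr)
    contrast = average_window(rel["NoGo"], ANALYSIS_WINDOW) - average_window(
        rel["Go"], ANALYSIS_WINDOW
    )
    return SubjectResult(
        subject_id=epochs.subject_id,
        group=epochs.group,
        raw=raw,
        rel=rel,
        contrast=contrast,
        valid_points=np.flatnonzero(filters.valid),
        n_kept=matched.n_trials,
        rejection_counts=log.counts,
    )


def select_roi(
    cluster: ClusterResult,
    grid: SourceGrid,
    valid_points: np.ndarray,
    truth_location_mm: np.ndarray | None = None,
    alpha: float = 0.05,
) -> tuple[np.ndarray, bool]:
    """ROI = members of the largest significant cluster.

    When no cluster reaches significance the ROI falls back to the
    neighbourhood (point plus grid neighbours) of the planted source's
    nearest valid grid point, and the fallback is flagged in the report.
    """
    sig = cluster.significant_clusters(alpha)
    if sig:
        return sig[0].members, False
    if truth_location_mm is None:
        raise ValueError("no significant cluster and no fallback location")
    pts = grid.points_mm[valid_points]
    seed_local = int(np.argmin(np.linalg.norm(pts - np.asarray(truth_location_mm), axis=1)))
    seed_grid = valid_points[seed_local]
    neigh_grid = set(grid.neighbors(seed_grid).tolist()) | {int(seed_grid)}
    lut = {int(gp): i for i, gp in enumerate(valid_points)}
    roi = sorted(lut[g] for g in neigh_grid if g in lut)
    return np.asarray(roi, dtype=int), True


# ---------------------------------------------------------------------------
# behavioral summaries


def behavioral_summary(trial_table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject accuracy, median correct-Go RT, and d' from a trial table."""
    rows = []
    for (subject, group), df in trial_table.groupby(["subject", "group"], sort=False):
        go = df[df["condition"] == "Go"]
        nogo = df[df["condition"] == "NoGo"]
        hits = int(go["correct"].sum())
        fas = int((~nogo["correct"].astype(bool)).sum())
        counts = BehavioralCounts(hits, fas, len(go), len(nogo))
        go_rt = go.loc[go["correct"].astype(bool), "rt_ms"].dropna()
        rows.append(
            {
                "subject": subject,
                "group": group,
                "go_accuracy": 100.0 * hits / len(go),
                "nogo_accuracy": 100.0 * (len(nogo) - fas) / len(nogo),
                "median_rt_ms": float(go_rt.median()),
                "dprime": dprime(counts),
            }
        )
    return pd.DataFrame(rows)


def behavioral_battery(
    summary: pd.DataFrame, seed: int | None = None, n_boot: int = 10_000
) -> dict:
    """One-tailed group comparisons of accuracy, RT, and d' with bootstrap.

    The directional hypothesis is poorer inhibitory control after stroke:
    lower accuracy and sensitivity, longer response times in the stroke
    group.
    """
    ctrl = summary[summary["group"] == "control"]
    strk = summary[summary["group"] == "stroke"]
    out = {}
    for measure, tail in (
        ("go_accuracy", "greater"),
        ("nogo_accuracy", "greater"),
        ("median_rt_ms", "less"),
        ("dprime", "greater"),
    ):
        x = ctrl[measure].to_numpy()
        y = strk[measure].to_numpy()
        out[measure] = {
            "control_median": float(np.median(x)),
            "stroke_median": float(np.median(y)),
            "test": rank_sum_test(x, y, tail=tail).to_dict(),
            "bootstrap": bootstrap_stability(
                x, y, tail=tail, n_resamples=n_boot, seed=seed
            ).to_dict(),
        }
    return out


# ---------------------------------------------------------------------------
# in-memory cohort run


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def analyze_cohort(
    spec: CohortSpec,
    params: AnalysisParams,
    seed: int,
    forward: ForwardBundle | None = None,
    with_battery: bool = True,
) -> dict:
    """Simulate one cohort and run the full analysis in memory.

    Returns the control-group cluster result, ROI, ΔFMΘ table, the ROI
    power table, the statistics battery, and behavioral summaries.  All
    randomness derives from ``seed`` via a spawned seed tree, so repeated
    calls are reproducible.
    """
    fwd = forward or make_forward(params)
    truth = cohort_ground_truth(spec)

    seeds = _spawn_seeds(seed, 4)
    profiles = make_cohort_profiles(spec, seeds[0])
    subj_seeds = _spawn_seeds(seeds[1], 3 * len(profiles))

    results: list[SubjectResult] = []
    trial_frames = []
    for i, profile in enumerate(profiles):
        s_beh, s_epo, s_sub = subj_seeds[3 * i : 3 * i + 3]
        trials = generate_behavior(spec.design, profile, s_beh)
        epochs = simulate_epochs(
            trials,
            profile,
            fwd.geometry,
            noise=spec.noise,
            seed=s_epo,
            sfreq=params.sfreq,
            source_model=spec.source_model,
        )
        results.append(analyze_subject(epochs, fwd.leadfield, params, s_sub))
        tf = epochs.trial_meta.copy()
        tf.insert(0, "group", profile.group)
        tf.insert(0, "subject", profile.subject_id)
        trial_frames.append(tf)
    trial_table = pd.concat(trial_frames, ignore_index=True)

    valid_points = results[0].valid_points
    adj = fwd.grid.adjacency[valid_points][:, valid_points]
    control = [r for r in results if r.group == "control"]
    contrast = np.vstack([r.contrast for r in control])
    cluster = cluster_perm_dep(
        contrast,
        adj,
        alpha_form=params.alpha_form,
        n_perm=params.n_perm,
        seed=seeds[2],
    )
    roi, fallback = select_roi(
        cluster,
        fwd.grid,
        valid_points,
        truth_location_mm=np.asarray(truth.source_location_mm),
        alpha=params.cluster_alpha,
    )

    groups = {r.subject_id: r.group for r in results}
    raw_tfrs = {r.subject_id: r.raw for r in results}
    rel_tfrs = {r.subject_id: r.rel for r in results}
    roi_table = roi_power_table(raw_tfrs, groups, roi)
    deltas = delta_table(rel_tfrs, groups, roi)
    summary = behavioral_summary(trial_table)

    out = {
        "cluster": cluster,
        "roi": roi,
        "roi_fallback_used": fallback,
        "roi_table": roi_table,
        "deltas": deltas,
        "behavior_summary": summary,
        "trial_table": trial_table,
        "ground_truth": truth,
        "valid_points": valid_points,
        "results": results,
        "grid": fwd.grid,
    }
    if with_battery:
        out["battery"] = run_group_battery(
            roi_table,
            deltas,
            seed=seeds[3],
            n_boot=params.n_boot,
            roi_fallback_used=fallback,
        )
        out["behavior_battery"] = behavioral_battery(
            summary, seed=seeds[3], n_boot=params.n_boot
        )
    return out


# ---------------------------------------------------------------------------
# file-backed staged pipeline


STAGES = ("simulate", "prep", "localize", "tfr", "cluster", "roi", "behavior", "report")

_PARAM_KEYS = {
    "sfreq",
    "n_sensors",
    "grid_spacing_mm",
    "connectivity",
    "margin",
    "lambda_frac",
    "alpha_form",
    "cluster_alpha",
    "n_perm",
    "n_boot",
    "window_length",
    "pad_to",
    "fmin",
    "fmax",
    "fstep",
}
_COHORT_KEYS = {"n_control", "n_stroke", "n_trials", "effect"}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (YAML-backed, unknown keys rejected)."""

    cohort: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.cohort) - _COHORT_KEYS
        if unknown:
            raise ValueError(f"unknown cohort keys: {sorted(unknown)}")
        unknown = set(self.analysis) - _PARAM_KEYS
        if unknown:
            raise ValueError(f"unknown analysis keys: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        unknown = set(raw) - {"cohort", "analysis", "seed"}
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        return cls(
            cohort=raw.get("cohort", {}) or {},
            analysis=raw.get("analysis", {}) or {},
            seed=int(raw.get("seed", 0)),
        )

    def cohort_spec(self) -> CohortSpec:
        spec = reduced_cohort_spec(
            effect=self.cohort.get("effect", "paper"),
            n_trials=int(self.cohort.get("n_trials", 96)),
        )
        spec.n_control = int(self.cohort.get("n_control", spec.n_control))
        spec.n_stroke = int(self.cohort.get("n_stroke", spec.n_stroke))
        return spec

    def analysis_params(self) -> AnalysisParams:
        params = reduced_params()
        a = dict(self.analysis)
        fmin = a.pop("fmin", None)
        fmax = a.pop("fmax", None)
        fstep = a.pop("fstep", 0.5)
        if fmin is not None and fmax is not None:
            params.freqs = np.arange(fmin, fmax + 1e-9, fstep)
        for k, v in a.items():
            setattr(params, k, type(getattr(params, k))(v))
        return params

    def digest(self) -> str:
        blob = json.dumps(
            {"cohort": self.cohort, "analysis": self.analysis, "seed": self.seed},
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage_done(manifest: dict, stage: str, digest: str, out: Path) -> bool:
    entry = manifest.get("stages", {}).get(stage)
    if not entry or entry.get("config") != digest:
        return False
    return all((out / f).exists() for f in entry.get("files", []))


def run_pipeline(
    config: PipelineConfig,
    out_dir,
    seed: int | None = None,
    until: str = "report",
) -> Path:
    """Execute the staged workflow into ``out_dir``, resuming where possible.

    Each stage records its output files and the config digest in
    ``manifest.json``; a stage is skipped when its outputs exist and the
    digest matches.  ``until`` limits execution to a stage prefix.
    Fails fast with the offending stage named.
    """
    if until not in STAGES:
        raise ValueError(f"unknown stage {until!r}; choose from {STAGES}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    digest = config.digest() + f"-s{seed}"

    manifest_path = out / "manifest.json"
    manifest = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    )
    manifest.setdefault("stages", {})
    manifest["version"] = __version__
    manifest["seed"] = seed
    manifest["config"] = {"cohort": config.cohort, "analysis": config.analysis}

    # the in-memory analysis is cheap at the configured scale; stages
    # persist their slice of one shared cohort analysis
    spec = config.cohort_spec()
    params = config.analysis_params()
    wanted = STAGES[: STAGES.index(until) + 1]
    pending = [
        s for s in wanted if not _stage_done(manifest, s, digest, out)
    ]
    if pending:
        try:
            bundle = analyze_cohort(spec, params, seed)
        except Exception as err:  # noqa: BLE001
            raise RuntimeError(f"pipeline failed in stage 'analyze': {err}") from err

        def record(stage: str, files: list[str]) -> None:
            manifest["stages"][stage] = {"config": digest, "files": files}
            manifest_path.write_text(json.dumps(manifest, indent=2))

        if "simulate" in pending:
            bundle["trial_table"].to_csv(out / "behavior_trials.csv", index=False)
            bundle["ground_truth"].to_json(out / "ground_truth.json")
            record("simulate", ["behavior_trials.csv", "ground_truth.json"])
        if "prep" in pending:
            counts = pd.DataFrame(
                [
                    {"subject": r.subject_id, "n_kept": r.n_kept, **r.rejection_counts}
                    for r in bundle["results"]
                ]
            )
            counts.to_csv(out / "rejection_log.csv", index=False)
            record("prep", ["rejection_log.csv"])
        if "localize" in pending:
            np.savetxt(
                out / "valid_points_mm.tsv",
                bundle["grid"].points_mm[bundle["valid_points"]],
                delimiter="\t",
                header="x_mm\ty_mm\tz_mm",
                comments="",
            )
            record("localize", ["valid_points_mm.tsv"])
        if "tfr" in pending:
            contrasts = np.vstack([r.contrast for r in bundle["results"]])
            np.savetxt(out / "source_contrasts.tsv", contrasts, delimiter="\t")
            record("tfr", ["source_contrasts.tsv"])
        if "cluster" in pending:
            bundle["cluster"].to_json(out / "cluster.json", seed=seed)
            record("cluster", ["cluster.json"])
        if "roi" in pending:
            bundle["roi_table"].to_csv(out / "roi_power.csv", index=False)
            bundle["deltas"].to_csv(out / "delta_fmtheta.csv", index=False)
            with open(out / "battery.json", "w") as f:
                json.dump(bundle["battery"], f, indent=2)
            record("roi", ["roi_power.csv", "delta_fmtheta.csv", "battery.json"])
        if "behavior" in pending:
            bundle["behavior_summary"].to_csv(out / "behavior_summary.csv", index=False)
            with open(out / "behavior_stats.json", "w") as f:
                json.dump(bundle["behavior_battery"], f, indent=2)
            record("behavior", ["behavior_summary.csv", "behavior_stats.json"])
        if "report" in pending:
            _write_report(out, bundle, seed)
            record("report", ["report.md"])
    return out


def _write_report(out: Path, bundle: dict, seed: int) -> None:
    cl = bundle["cluster"]
    lines = [
        "# Cohort analysis report",
        "",
        f"seed: {seed}",
        f"subjects: {len(bundle['results'])}",
        f"control-group clusters: {len(cl.clusters)} "
        f"(min p = {cl.min_p:.4f}, n_perm = {cl.n_permutations})",
        f"ROI size: {len(bundle['roi'])} grid points"
        + (" [ground-truth fallback]" if bundle["roi_fallback_used"] else ""),
        "",
        "## ΔFMΘ",
    ]
    d = bundle["battery"]["delta_fmtheta"]
    lines += [
        f"control median = {d['control_median']:.3f}, "
        f"stroke median = {d['stroke_median']:.3f}",
        f"one-sided rank-sum p = {d['rank_sum']['p']:.4f} "
        f"(r = {d['rank_sum']['effect_size_r']:.2f})",
        f"KS D = {d['ks']['statistic']:.3f}, p = {d['ks']['p']:.4f}",
        f"bootstrap direction consistency = {d['bootstrap']['direction_consistency']:.3f}, "
        f"p-stability = {d['bootstrap']['p_stability']:.3f}",
    ]
    (out / "report.md").write_text("\n".join(lines) + "\n")
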