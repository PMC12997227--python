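"""Synthetic two-group Go/NoGo MEG cohorts with exported ground truth.

The generator produces, per subject, (a) a behavioral session — trial
conditions, correctness, and ex-Gaussian response times — and (b) sensor
epochs containing a midfrontal theta (3.5–5.5 Hz) dipole whose amplitude is
the sum of a tonic level and a condition-dependent post-stimulus burst, a
phase-locked evoked component, an off-midline alpha background source, and
white sensor noise.  The induced theta burst has a random phase per trial,
so it vanishes from the trial average but survives ERF subtraction; the
evoked component is identical across trials and is removed by ERF
subtraction.

Group structure mirrors the target study design: "control" subjects show a
NoGo > Go burst-gain ratio of 2, "stroke" subjects have tonic theta lowered
to 0.6x the control level and no NoGo-specific gain.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .epochs import EpochSet
from .forward import SensorGeometry, sarvas_field, tangential_basis


@dataclass
class TaskDesign:
    """Go/NoGo session layout: 504 trials, 25% NoGo, 200 ms stimuli."""

    n_trials: int = 504
    nogo_fraction: float = 0.25
    stim_duration_ms: float = 200.0
    response_window_ms: float = 1100.0
    isi_range_ms: tuple[float, float] = (2000.0, 2700.0)
    n_blocks: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.nogo_fraction < 1.0:
            raise ValueError("nogo_fraction must lie strictly in (0, 1)")
        if self.isi_range_ms[0] > self.isi_range_ms[1]:
            raise ValueError("isi_range must be ordered (low, high)")
        if self.n_trials < 1 or self.n_blocks < 1:
            raise ValueError("n_trials and n_blocks must be positive")

    @property
    def n_nogo(self) -> int:
        return int(round(self.n_trials * self.nogo_fraction))

    @property
    def n_go(self) -> int:
        return self.n_trials - self.n_nogo


@dataclass
class SubjectProfile:
    """Per-subject behavioral and neural generative parameters.

    Gains are dimensionless multipliers on the common dipole amplitude;
    RT parameters are the ex-Gaussian (mu, sigma, tau) in milliseconds.
    """

    subject_id: str
    group: str  # 'control' | 'stroke'
    hit_rate: float = 0.994
    false_alarm_rate: float = 0.042
    rt_mu: float = 450.0
    rt_sigma: float = 50.0
    rt_tau: float = 110.0
    tonic_theta_gain: float = 1.0
    burst_gain_go: float = 1.0
    burst_gain_nogo: float = 2.0
    evoked_gain: float = 1.0
    anticipatory_rate: float = 0.01

    def __post_init__(self) -> None:
        for name in ("hit_rate", "false_alarm_rate", "anticipatory_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in (
            "tonic_theta_gain",
            "burst_gain_go",
            "burst_gain_nogo",
            "evoked_gain",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.rt_sigma <= 0 or self.rt_tau <= 0:
            raise ValueError("RT scale parameters must be positive")
        if self.group not in ("control", "stroke"):
            raise ValueError("group must be 'control' or 'stroke'")

    def burst_gain(self, condition: str) -> float:
        return self.burst_gain_nogo if condition == "NoGo" else self.burst_gain_go


@dataclass
class TrialRecord:
    trial_index: int
    block: int
    condition: str  # 'Go' | 'NoGo'
    correct: bool
    rt_ms: float | None
    onset_s: float


@dataclass
class SourceModel:
    """Geometry and waveform parameters of the planted sources.

    Positions are metres in the sphere-centre frame.  The theta dipole sits
    on the frontal midline (anterior-superior); the alpha background dipole
    sits posteriorly.  Orientations default to the first tangential basis
    vector at each position.  The burst envelope is a raised cosine on
    [burst_t0, burst_t1] peaking at the midpoint (defaults 150–650 ms, peak
    400 ms, so the 250–500 ms analysis window sits inside it).
    """

    theta_pos: tuple[float, float, float] = (0.0, 0.035, 0.045)
    amplitude: float = 2e-8  # A·m
    burst_t0: float = 0.15
    burst_t1: float = 0.65
    freq_range: tuple[float, float] = (3.5, 5.5)
    evoked_freq: float = 4.0
    evoked_center: float = 0.30
    evoked_width: float = 0.12
    alpha_pos: tuple[float, float, float] = (0.0, -0.045, 0.035)
    alpha_freq: float = 10.0

    def burst_envelope(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        w = np.zeros_like(t)
        span = self.burst_t1 - self.burst_t0
        m = (t >= self.burst_t0) & (t <= self.burst_t1)
        w[m] = 0.5 * (1.0 - np.cos(2.0 * np.pi * (t[m] - self.burst_t0) / span))
        return w

    def evoked_waveform(self, t: np.ndarray) -> np.ndarray:
        env = np.exp(-0.5 * ((t - self.evoked_center) / self.evoked_width) ** 2)
        return env * np.sin(2.0 * np.pi * self.evoked_freq * t)


@dataclass
class NoiseParams:
    """Additive-noise configuration (tesla for sensor noise, A·m for alpha)."""

    sensor_noise_sd: float = 2e-13
    alpha_amplitude: float = 1e-8
    bad_epoch_rate: float = 0.01
    bad_epoch_scale: float = 8.0


@dataclass
class GroundTruth:
    """Planted-effect bookkeeping exported next to each synthetic cohort."""

    source_location_mm: tuple[float, float, float]
    source_orientation: tuple[float, float, float]
    expected_relchange: dict  # group -> condition -> expected relative change
    tonic_theta: dict  # group -> tonic gain

    def __post_init__(self) -> None:
        loc = np.asarray(self.source_location_mm)
        if np.linalg.norm(loc) >= 80.0:
            raise ValueError("planted source must lie strictly inside the sphere")
        ori = np.asarray(self.source_orientation)
        if not np.isclose(np.linalg.norm(ori), 1.0, atol=1e-6):
            raise ValueError("source orientation must be unit norm")

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(
                {
                    "source_location_mm": list(self.source_location_mm),
                    "source_orientation": list(self.source_orientation),
                    "expected_relchange": self.expected_relchange,
                    "tonic_theta": self.tonic_theta,
                },
                f,
                indent=2,
            )


# ---------------------------------------------------------------------------
# behavior


def _draw_rt(rng: np.random.Generator, profile: SubjectProfile, upper_ms: float) -> float:
    """Ex-Gaussian RT truncated to (0, upper_ms] by redrawing."""
    for _ in range(1000):
        rt = rng.normal(profile.rt_mu, profile.rt_sigma) + rng.exponential(profile.rt_tau)
        if 0.0 < rt <= upper_ms:
            return float(rt)
    raise RuntimeError("RT truncation failed; check ex-Gaussian parameters")


def generate_behavior(
    design: TaskDesign, profile: SubjectProfile, seed: int
) -> list[TrialRecord]:
    """One synthetic Go/NoGo session.

    Exactly ``round(n_trials * nogo_fraction)`` NoGo trials are placed at
    random positions; Go correctness is Bernoulli(hit_rate), NoGo commission
    errors Bernoulli(false_alarm_rate); RTs for emitted responses are
    ex-Gaussian truncated to the response window.  A small fraction of
    responses (``anticipatory_rate``) is replaced by anticipatory RTs below
    100 ms so that downstream rejection rules are exercised.  Fully
    reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    n = design.n_trials
    conditions = np.array(["Go"] * design.n_go + ["NoGo"] * design.n_nogo)
    rng.shuffle(conditions)

    blocks = np.concatenate(
        [np.full(len(chunk), b) for b, chunk in enumerate(np.array_split(np.arange(n), design.n_blocks))]
    )

    trials: list[TrialRecord] = []
    onset = 0.0
    prev_block = 0
    for i in range(n):
        if blocks[i] != prev_block:
            onset = 0.0
            prev_block = blocks[i]
        cond = conditions[i]
        responded = False
        if cond == "Go":
            correct = bool(rng.random() < profile.hit_rate)
            responded = correct  # a hit is an emitted response; a miss is not
        else:
            fa = bool(rng.random() < profile.false_alarm_rate)
            correct = not fa
            responded = fa
        rt = None
        if responded:
            rt = _draw_rt(rng, profile, design.response_window_ms)
            if rng.random() < profile.anticipatory_rate:
                rt = float(rng.uniform(30.0, 100.0))
        trials.append(
            TrialRecord(
                trial_index=i,
                block=int(blocks[i]),
                condition=str(cond),
                correct=correct,
                rt_ms=rt,
                onset_s=onset,
            )
        )
        onset += (design.stim_duration_ms + rng.uniform(*design.isi_range_ms)) / 1000.0
    return trials


def trials_to_frame(trials: list[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trial_index": [t.trial_index for t in trials],
            "block": [t.block for t in trials],
            "condition": [t.condition for t in trials],
            "correct": [t.correct for t in trials],
            "rt_ms": [np.nan if t.rt_ms is None else t.rt_ms for t in trials],
            "onset_s": [t.onset_s for t in trials],
        }
    )


# ---------------------------------------------------------------------------
# epochs


def simulate_epochs(
    trials: list[TrialRecord],
    profile: SubjectProfile,
    geometry: SensorGeometry,
    leadfield_fn=None,
    noise: NoiseParams | None = None,
    seed: int = 0,
    sfreq: float = 500.0,
    tmin: float = -1.5,
    tmax: float = 1.5,
    source_model: SourceModel | None = None,
) -> EpochSet:
    """Sensor epochs for one subject's session.

    Per trial the sensor data are
    ``L(theta) * s(t) + L(theta) * e(t) + L(alpha) * a(t) + noise`` where
    ``s(t) = amplitude * [tonic + burst_gain_cond * w(t)] * sin(2 pi f t + phi)``
    with a per-trial frequency in ``freq_range`` and a uniform random phase
    (induced, non-phase-locked), ``e(t)`` a fixed evoked waveform shared by
    all trials, and ``a(t)`` a random-phase alpha oscillation.  Epochs span
    ``tmin``..``tmax`` around stimulus onset.
    """
    if not trials:
        raise ValueError("need at least one trial")
    if any(t.onset_s is None or not np.isfinite(t.onset_s) for t in trials):
        raise ValueError("every trial must carry a stimulus onset")
    n_samp_f = (tmax - tmin) * sfreq
    if abs(n_samp_f - round(n_samp_f)) > 1e-9:
        raise ValueError("sampling rate must divide the epoch into integer samples")
    n_samp = int(round(n_samp_f)) + 1  # both endpoints included

    noise = noise or NoiseParams()
    sm = source_model or SourceModel()
    if leadfield_fn is None:
        leadfield_fn = lambda pos, mom: sarvas_field(pos, mom, geometry)

    theta_ori = tangential_basis(sm.theta_pos, geometry.sphere_center)[0]
    alpha_ori = tangential_basis(sm.alpha_pos, geometry.sphere_center)[0]
    L_theta = leadfield_fn(np.asarray(sm.theta_pos), theta_ori)
    L_alpha = leadfield_fn(np.asarray(sm.alpha_pos), alpha_ori)

    t = tmin + np.arange(n_samp) / sfreq
    w = sm.burst_envelope(t)
    evoked = profile.evoked_gain * sm.amplitude * sm.evoked_waveform(t)

    rng = np.random.default_rng(seed)
    n_trials = len(trials)
    n_ch = geometry.n_channels

    f = rng.uniform(*sm.freq_range, size=n_trials)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n_trials)
    a_phi = rng.uniform(0.0, 2.0 * np.pi, size=n_trials)
    a_f = sm.alpha_freq + rng.uniform(-0.5, 0.5, size=n_trials)
    sd = np.full(n_trials, noise.sensor_noise_sd)
    sd[rng.random(n_trials) < noise.bad_epoch_rate] *= noise.bad_epoch_scale

    gains = np.array([profile.burst_gain(tr.condition) for tr in trials])
    env = sm.amplitude * (profile.tonic_theta_gain + gains[:, None] * w[None, :])
    s = env * np.sin(2.0 * np.pi * f[:, None] * t[None, :] + phi[:, None])
    a = noise.alpha_amplitude * np.sin(
        2.0 * np.pi * a_f[:, None] * t[None, :] + a_phi[:, None]
    )
    data = (s + evoked[None, :])[:, None, :] * L_theta[None, :, None]
    data += a[:, None, :] * L_alpha[None, :, None]
    data += rng.standard_normal((n_trials, n_ch, n_samp)) * sd[:, None, None]

    return EpochSet(
        data=data,
        sfreq=sfreq,
        tmin=tmin,
        trial_meta=trials_to_frame(trials),
        subject_id=profile.subject_id,
        group=profile.group,
        chan_pos=geometry.positions.copy(),
        chan_ori=geometry.orientations.copy(),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# ground truth and cohorts


def expected_relchange(
    tonic: float,
    burst_gain: float,
    source_model: SourceModel | None = None,
    window: tuple[float, float] = (0.25, 0.50),
    window_length: float = 1.0,
    step: float = 0.05,
    sfreq: float = 500.0,
) -> float:
    """Expected 3–6 Hz relative power change in the analysis window.

    Computed directly from the generative amplitude envelope: a Hanning
    window of ``window_length`` centred at each analysis time point averages
    the envelope coherently, so the expected narrow-band power at that point
    is proportional to the squared taper-weighted mean amplitude.  Baseline
    amplitude is the tonic level, giving
    ``mean_t [(taper-weighted amp / tonic)^2] - 1``.
    """
    if tonic <= 0:
        raise ValueError("tonic level must be positive for a relative change")
    sm = source_model or SourceModel()
    nw = int(round(window_length * sfreq))
    taper = np.hanning(nw)
    offsets = (np.arange(nw) - (nw - 1) / 2.0) / sfreq
    centers = np.arange(window[0], window[1] + 1e-9, step)
    ratios = []
    for c in centers:
        amp = tonic + burst_gain * sm.burst_envelope(c + offsets)
        ratios.append((np.sum(taper * amp) / np.sum(taper) / tonic) ** 2)
    return float(np.mean(ratios) - 1.0)


@dataclass
class CohortSpec:
    """Study-condition defaults for a two-group synthetic cohort."""

    n_control: int = 17
    n_stroke: int = 10
    design: TaskDesign = field(default_factory=TaskDesign)
    control_template: SubjectProfile = field(
        default_factory=lambda: SubjectProfile(
            subject_id="template",
            group="control",
            hit_rate=0.994,
            false_alarm_rate=0.042,
            rt_mu=450.0,
            rt_sigma=50.0,
            rt_tau=110.0,
            tonic_theta_gain=1.0,
            burst_gain_go=1.0,
            burst_gain_nogo=2.0,
        )
    )
    stroke_template: SubjectProfile = field(
        default_factory=lambda: SubjectProfile(
            subject_id="template",
            group="stroke",
            hit_rate=0.992,
            false_alarm_rate=0.060,
            rt_mu=440.0,
            rt_sigma=40.0,
            rt_tau=95.0,
            tonic_theta_gain=0.6,
            burst_gain_go=1.0,
            burst_gain_nogo=1.0,
        )
    )
    gain_jitter_sd: float = 0.15  # lognormal sigma on the neural gains
    rate_jitter_sd: float = 0.25  # lognormal sigma on miss/false-alarm rates
    noise: NoiseParams = field(default_factory=NoiseParams)
    source_model: SourceModel = field(default_factory=SourceModel)


def null_cohort_spec(**kwargs) -> CohortSpec:
    """Cohort spec in which both groups share the control generative profile."""
    spec = CohortSpec(**kwargs)
    spec.stroke_template = replace(spec.control_template, group="stroke")
    return spec


def make_cohort_profiles(spec: CohortSpec, seed: int) -> list[SubjectProfile]:
    """Per-subject profiles with lognormal between-subject jitter on gains
    and on the miss / false-alarm probabilities."""
    rng = np.random.default_rng(seed)
    profiles = []
    for g, n, tmpl in (
        ("control", spec.n_control, spec.control_template),
        ("stroke", spec.n_stroke, spec.stroke_template),
    ):
        for k in range(n):
            jit = lambda: float(np.exp(rng.normal(0.0, spec.gain_jitter_sd)))
            miss = (1.0 - tmpl.hit_rate) * np.exp(rng.normal(0.0, spec.rate_jitter_sd))
            fa = tmpl.false_alarm_rate * np.exp(rng.normal(0.0, spec.rate_jitter_sd))
            profiles.append(
                replace(
                    tmpl,
                    subject_id=f"{g[:3]}{k + 1:02d}",
                    group=g,
                    hit_rate=float(np.clip(1.0 - miss, 0.0, 1.0)),
                    false_alarm_rate=float(np.clip(fa, 0.0, 1.0)),
                    tonic_theta_gain=tmpl.tonic_theta_gain * jit(),
                    burst_gain_go=tmpl.burst_gain_go * jit(),
                    burst_gain_nogo=tmpl.burst_gain_nogo * jit(),
                    evoked_gain=tmpl.evoked_gain * jit(),
                )
            )
    return profiles


def cohort_ground_truth(spec: CohortSpec) -> GroundTruth:
    sm = spec.source_model
    ori = tangential_basis(sm.theta_pos)[0]
    rel = {}
    tonic = {}
    for g, tmpl in (("control", spec.control_template), ("stroke", spec.stroke_template)):
        tonic[g] = tmpl.tonic_theta_gain
        rel[g] = {
            cond: expected_relchange(
                tmpl.tonic_theta_gain, tmpl.burst_gain(cond), source_model=sm
            )
            for cond in ("Go", "NoGo")
        }
    return GroundTruth(
        source_location_mm=tuple(1e3 * np.asarray(sm.theta_pos)),
        source_orientation=tuple(ori),
        expected_relchange=rel,
        tonic_theta=tonic,
    )


def behavior_table(
    spec: CohortSpec, profiles: list[SubjectProfile], seed: int
) -> pd.DataFrame:
    """Behavioral trial table (CSV layout) for a whole cohort."""
    ss = np.random.SeedSequence(seed)
    frames = []
    for profile, child in zip(profiles, ss.spawn(len(profiles))):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        df = trials_to_frame(generate_behavior(spec.design, profile, sub_seed))
        df.insert(0, "group", profile.group)
        df.insert(0, "subject", profile.subject_id)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
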