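"""ROI power extraction, the Group x State x Condition mixed model, and ΔFMΘ.

Two parallel bookkeepings follow the analysis design: the State comparison
(baseline −1500..−500 ms vs active 250..500 ms) uses *raw*, non-baseline-
corrected theta power, while ΔFMΘ — the per-subject NoGo minus Go
difference in the analysis window — uses baseline-corrected relative
change.  The factorial model is
``Power ~ Group * State * Condition + (1 | Subject)`` fitted by REML with
sum-to-zero factor coding; Type III F tests use the residual-degrees-of-
freedom convention ``df2 = n_obs - n_fixed_parameters`` (108 observations,
8 parameters -> df2 = 100 at the target cohort size), and partial eta
squared is recovered from (F, df1, df2).

The random-intercept REML fit is computed in profiled closed form: with
equal cluster sizes the marginal covariance is ``sigma_e^2 (I + rho Z Z')``
whose inverse and determinant are analytic, leaving a one-dimensional
REML criterion in ``rho = sigma_subject^2 / sigma_e^2`` that is optimised
deterministically.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .spectral import ANALYSIS_WINDOW, TFRMap, WindowSpec, average_window
from .statskit import (
    bootstrap_stability,
    ks_two_sample,
    leave_one_out,
    partial_eta_sq,
    rank_sum_test,
    signed_rank_test,
)

BASELINE_STATE_WINDOW = WindowSpec(3.0, 6.0, -1.5, -0.5)
ACTIVE_STATE_WINDOW = WindowSpec(3.0, 6.0, 0.250, 0.500)

FIXED_TERMS = (
    "Group",
    "State",
    "Condition",
    "Group:State",
    "Group:Condition",
    "State:Condition",
    "Group:State:Condition",
)


def extract_roi(tfr: TFRMap, roi: np.ndarray, window: WindowSpec) -> float:
    """Mean over the ROI members, then over the window's (freq, time) bins."""
    roi = np.asarray(roi, dtype=int)
    if roi.size == 0:
        raise ValueError("ROI must be nonempty")
    if roi.max() >= tfr.power.shape[0] or roi.min() < 0:
        raise ValueError("ROI indices out of range")
    per_channel = average_window(tfr, window)
    return float(np.mean(per_channel[roi]))


def roi_power_table(
    raw_tfrs: dict,
    groups: dict,
    roi: np.ndarray,
    baseline: WindowSpec = BASELINE_STATE_WINDOW,
    active: WindowSpec = ACTIVE_STATE_WINDOW,
) -> pd.DataFrame:
    """Subject x condition x state summary of raw ROI theta power.

    ``raw_tfrs`` maps subject -> {'Go': TFRMap, 'NoGo': TFRMap} (raw mode);
    ``groups`` maps subject -> group label.
    """
    rows = []
    for subject, tfrs in raw_tfrs.items():
        for condition in ("Go", "NoGo"):
            for state, window in (("baseline", baseline), ("active", active)):
                rows.append(
                    {
                        "subject": subject,
                        "group": groups[subject],
                        "condition": condition,
                        "state": state,
                        "power": extract_roi(tfrs[condition], roi, window),
                    }
                )
    return pd.DataFrame(rows)


def delta_fmtheta(
    tfr_go_rel: TFRMap,
    tfr_nogo_rel: TFRMap,
    roi: np.ndarray,
    window: WindowSpec = ANALYSIS_WINDOW,
) -> float:
    """ΔFMΘ: NoGo minus Go ROI-window mean of baseline-corrected power."""
    for tfr in (tfr_go_rel, tfr_nogo_rel):
        if tfr.mode != "relchange":
            raise ValueError("ΔFMΘ is defined on baseline-corrected TFRs")
    return extract_roi(tfr_nogo_rel, roi, window) - extract_roi(tfr_go_rel, roi, window)


def delta_table(rel_tfrs: dict, groups: dict, roi, window: WindowSpec = ANALYSIS_WINDOW) -> pd.DataFrame:
    rows = [
        {
            "subject": s,
            "group": groups[s],
            "delta_fmtheta": delta_fmtheta(t["Go"], t["NoGo"], roi, window),
        }
        for s, t in rel_tfrs.items()
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# linear mixed model


@dataclass
class LMEResult:
    """Type III fixed-effect tests and variance components."""

    anova: pd.DataFrame  # term, F, df1, df2, p, eta_p2
    coef: pd.Series
    var_subject: float
    var_residual: float
    n_obs: int

    def to_dict(self) -> dict:
        return {
            "anova": self.anova.to_dict(orient="records"),
            "var_subject": float(self.var_subject),
            "var_residual": float(self.var_residual),
            "n_obs": int(self.n_obs),
        }


def _design(table: pd.DataFrame):
    g = np.where(table["group"].to_numpy() == "control", 1.0, -1.0)
    s = np.where(table["state"].to_numpy() == "active", 1.0, -1.0)
    c = np.where(table["condition"].to_numpy() == "NoGo", 1.0, -1.0)
    X = np.column_stack([np.ones(len(table)), g, s, c, g * s, g * c, s * c, g * s * c])
    return X, ["Intercept", *FIXED_TERMS]


def _reml_profile(rho: float, Y, X, subj_index, m: int):
    """Profiled REML pieces for V = sigma_e^2 (I + rho Z Z') at given rho."""
    n_subj = subj_index.max() + 1
    c = rho / (1.0 + m * rho)

    def ainv(v):
        sums = np.zeros((n_subj,) + v.shape[1:])
        np.add.at(sums, subj_index, v)
        return v - c * sums[subj_index]

    XtAX = X.T @ ainv(X)
    XtAy = X.T @ ainv(Y)
    beta = np.linalg.solve(XtAX, XtAy)
    r = Y - X @ beta
    quad = float(r @ ainv(r))
    n, p = X.shape
    sigma_e2 = quad / (n - p)
    logdet_a = n_subj * np.log1p(m * rho)
    sign, logdet_xax = np.linalg.slogdet(XtAX)
    crit = (n - p) * np.log(sigma_e2) + logdet_a + logdet_xax
    return crit, beta, sigma_e2, XtAX


def fit_power_lme(table: pd.DataFrame) -> LMEResult:
    """REML random-intercept fit with Type III F tests and partial eta^2.

    Requires a complete balanced table: every subject contributes exactly
    one power value per (state, condition) cell.
    """
    req = {"subject", "group", "state", "condition", "power"}
    if not req.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(req)}")
    counts = table.groupby("subject").size()
    cells = table.groupby(["subject", "state", "condition"]).size()
    if not (counts == 4).all() or not (cells == 1).all():
        raise ValueError("design must be complete and balanced (4 cells per subject)")

    table = table.reset_index(drop=True)
    subjects, subj_index = np.unique(table["subject"].to_numpy(), return_inverse=True)
    Y = table["power"].to_numpy(float)
    X, names = _design(table)
    m = 4

    res = minimize_scalar(
        lambda u: _reml_profile(np.exp(u), Y, X, subj_index, m)[0],
        bounds=(-12.0, 12.0),
        method="bounded",
        options={"xatol": 1e-12},
    )
    rho = float(np.exp(res.x))
    crit0 = _reml_profile(0.0, Y, X, subj_index, m)[0]
    if crit0 <= res.fun:  # boundary solution: no subject variance
        rho = 0.0
    _, beta, sigma_e2, XtAX = _reml_profile(rho, Y, X, subj_index, m)

    cov_beta = sigma_e2 * np.linalg.inv(XtAX)
    se = np.sqrt(np.diag(cov_beta))
    n, p = X.shape
    df2 = n - p
    rows = []
    for j, term in enumerate(names):
        if term == "Intercept":
            continue
        F = float((beta[j] / se[j]) ** 2)
        pv = float(stats.f.sf(F, 1, df2))
        rows.append(
            {
                "term": term,
                "F": F,
                "df1": 1,
                "df2": df2,
                "p": pv,
                "eta_p2": partial_eta_sq(F, 1, df2),
            }
        )
    return LMEResult(
        anova=pd.DataFrame(rows),
        coef=pd.Series(beta, index=names),
        var_subject=float(rho * sigma_e2),
        var_residual=float(sigma_e2),
        n_obs=n,
    )


# ---------------------------------------------------------------------------
# group battery


def run_group_battery(
    roi_table: pd.DataFrame,
    deltas: pd.DataFrame,
    seed: int | None = None,
    n_boot: int = 10_000,
    loo_which: str = "groupB",
    roi_fallback_used: bool = False,
) -> dict:
    """The full ROI statistics battery as one JSON-serialisable report.

    Contents: the mixed model with Type III F and partial eta^2;
    within-group baseline-to-active signed-rank tests (per group x
    condition); between-group rank-sum tests (per state x condition); and
    the ΔFMΘ comparison — one-sided rank-sum (control > stroke), KS test,
    within-group bootstrap stability, and leave-one-out influence.
    """
    report: dict = {"seed": seed, "roi_fallback_used": bool(roi_fallback_used)}
    report["lme"] = fit_power_lme(roi_table).to_dict()

    within = {}
    for group in ("control", "stroke"):
        for condition in ("Go", "NoGo"):
            sub = roi_table[
                (roi_table["group"] == group) & (roi_table["condition"] == condition)
            ]
            piv = sub.pivot(index="subject", columns="state", values="power")
            rec = signed_rank_test(
                piv["active"].to_numpy(), piv["baseline"].to_numpy(), tail="two_sided"
            )
            within[f"{group}:{condition}:active_vs_baseline"] = rec.to_dict()
    report["within_group"] = within

    between = {}
    for state in ("baseline", "active"):
        for condition in ("Go", "NoGo"):
            sub = roi_table[
                (roi_table["state"] == state) & (roi_table["condition"] == condition)
            ]
            xc = sub.loc[sub["group"] == "control", "power"].to_numpy()
            xs = sub.loc[sub["group"] == "stroke", "power"].to_numpy()
            between[f"{state}:{condition}:control_vs_stroke"] = rank_sum_test(
                xc, xs, tail="two_sided"
            ).to_dict()
    report["between_group"] = between

    dc = deltas.loc[deltas["group"] == "control", "delta_fmtheta"].to_numpy()
    ds = deltas.loc[deltas["group"] == "stroke", "delta_fmtheta"].to_numpy()
    report["delta_fmtheta"] = {
        "rank_sum": rank_sum_test(dc, ds, tail="greater").to_dict(),
        "ks": ks_two_sample(dc, ds).to_dict(),
        "bootstrap": bootstrap_stability(
            dc, ds, tail="greater", n_resamples=n_boot, seed=seed, with_median_diff=True
        ).to_dict(),
        "leave_one_out": [
            r.to_dict()
            for r in leave_one_out(dc, ds, which=loo_which, tail="greater")
        ],
        "control_median": float(np.median(dc)),
        "stroke_median": float(np.median(ds)),
    }
    return report
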