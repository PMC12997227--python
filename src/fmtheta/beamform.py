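"""LCMV spatial filtering: covariance, filters, virtual time series.

A common (condition-pooled) covariance matrix is estimated across all Go
and NoGo epochs; filters are the classic linearly constrained minimum
variance solution ``w = C^-1 l / (l' C^-1 l)`` with diagonal loading
``C_r = C + lambda * (trace(C)/n) * I`` (lambda defaults to 5% of the mean
sensor variance).  A scalar (orientation-optimised) beamformer is used:
at each grid point the source orientation in the tangential plane is the
direction minimising ``u' (L' C_r^-1 L) u``, i.e. the eigenvector of the
2x2 matrix with the smallest eigenvalue, which maximises output power under
the unit-gain constraint.
"""
from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from .epochs import EpochSet
from .forward import Leadfield


@dataclass
class CovarianceEstimate:
    """Pooled sensor covariance (T^2), per-epoch mean removed."""

    matrix: np.ndarray
    n_samples_used: int
    conditions_pooled: tuple[str, ...]

    def __post_init__(self) -> None:
        if not np.allclose(self.matrix, self.matrix.T, atol=0):
            self.matrix = 0.5 * (self.matrix + self.matrix.T)
        w = np.linalg.eigvalsh(self.matrix)
        if w.min() < -1e-12 * max(self.matrix.trace(), 1e-300):
            raise ValueError("covariance estimate is not positive semidefinite")


def compute_covariance(epochs: EpochSet) -> CovarianceEstimate:
    """Sample covariance pooled over every time point of every trial.

    The per-epoch, per-channel temporal mean is removed before
    accumulation; the divisor is the total number of samples.
    """
    if epochs.n_trials == 0:
        raise ValueError("cannot estimate covariance from an empty epoch set")
    n_total = epochs.n_trials * epochs.n_samples
    if n_total < epochs.n_channels + 1:
        raise ValueError("need more samples than channels to estimate covariance")
    X = epochs.data - epochs.data.mean(axis=2, keepdims=True)
    X2 = np.ascontiguousarray(np.swapaxes(X, 0, 1)).reshape(epochs.n_channels, -1)
    C = (X2 @ X2.T) / n_total
    return CovarianceEstimate(
        matrix=C,
        n_samples_used=n_total,
        conditions_pooled=tuple(sorted(epochs.trial_meta["condition"].unique())),
    )


@dataclass
class SpatialFilterSet:
    """Unit-gain scalar LCMV filters per grid point.

    ``weights`` is (n_points, n_channels) with NaN rows at points where no
    filter could be built (vanishing leadfield, e.g. the exact sphere
    centre); ``orientations`` holds the chosen unit 2-vector in the
    tangential basis of the leadfield.
    """

    weights: np.ndarray
    orientations: np.ndarray
    lambda_frac: float
    valid: np.ndarray

    @property
    def n_points(self) -> int:
        return self.weights.shape[0]

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("weights", data=self.weights, compression="gzip")
            f.create_dataset("orientations", data=self.orientations)
            f.create_dataset("valid", data=self.valid)
            f.attrs["lambda"] = self.lambda_frac

    @classmethod
    def load(cls, path) -> "SpatialFilterSet":
        with h5py.File(path, "r") as f:
            return cls(
                weights=f["weights"][()],
                orientations=f["orientations"][()],
                lambda_frac=float(f.attrs["lambda"]),
                valid=f["valid"][()].astype(bool),
            )


def lcmv_filters(
    cov: CovarianceEstimate,
    leadfield: Leadfield,
    lambda_frac: float = 0.05,
) -> SpatialFilterSet:
    """Scalar LCMV filters with diagonal loading lambda * trace(C)/n.

    The filter sign is unidentifiable (source polarity is arbitrary); it is
    fixed by making the first non-negligible weight positive.
    """
    if not 0.0 <= lambda_frac < 1.0:
        raise ValueError("lambda_frac must lie in [0, 1)")
    C = cov.matrix
    n_ch = C.shape[0]
    if leadfield.n_channels != n_ch:
        raise ValueError("covariance and leadfield channel counts differ")
    Cr = C + lambda_frac * (np.trace(C) / n_ch) * np.eye(n_ch)
    try:
        Cinv = np.linalg.inv(Cr)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "regularized covariance is singular; increase lambda_frac"
        ) from err
    Cinv = 0.5 * (Cinv + Cinv.T)

    n_pts = leadfield.n_points
    weights = np.full((n_pts, n_ch), np.nan)
    orientations = np.full((n_pts, 2), np.nan)
    valid = np.zeros(n_pts, dtype=bool)
    gain_scale = np.linalg.norm(leadfield.gain)
    for i in range(n_pts):
        L = leadfield.gain[i]
        if np.linalg.norm(L) < 1e-12 * gain_scale:
            continue
        M = L.T @ Cinv @ L
        evals, evecs = np.linalg.eigh(M)
        u = evecs[:, 0]  # smallest eigenvalue -> maximal output power
        l = L @ u
        denom = l @ Cinv @ l
        w = (Cinv @ l) / denom
        nz = np.flatnonzero(np.abs(w) > 1e-12 * np.abs(w).max())
        if len(nz) and w[nz[0]] < 0:
            w = -w
            u = -u
        weights[i] = w
        orientations[i] = u
        valid[i] = True
    return SpatialFilterSet(
        weights=weights, orientations=orientations, lambda_frac=lambda_frac, valid=valid
    )


def neural_activity_index(filters: SpatialFilterSet, cov: CovarianceEstimate) -> np.ndarray:
    """Noise-normalised output power map ``(w'Cw) / (w'w)`` per grid point."""
    out = np.full(filters.n_points, np.nan)
    W = filters.weights[filters.valid]
    num = np.einsum("pc,cd,pd->p", W, cov.matrix, W)
    den = np.einsum("pc,pc->p", W, W)
    out[filters.valid] = num / den
    return out


def apply_filters(epochs: EpochSet, filters: SpatialFilterSet) -> EpochSet:
    """Virtual source time series per trial (channels become grid points).

    Only valid filter points are projected; metadata propagate unchanged.
    """
    if epochs.n_channels != filters.weights.shape[1]:
        raise ValueError("epoch channel count does not match filters")
    W = filters.weights[filters.valid]
    data = np.matmul(W, epochs.data)  # (p,c) @ (t,c,s) -> (t,p,s)
    return EpochSet(
        data=data,
        sfreq=epochs.sfreq,
        tmin=epochs.tmin,
        trial_meta=epochs.trial_meta.copy(),
        subject_id=epochs.subject_id,
        group=epochs.group,
        seed=epochs.seed,
    )
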