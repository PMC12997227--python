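"""Dependent-samples cluster-mass permutation tests.

Given per-subject paired contrasts (NoGo - Go) over graph-connected
elements (source grid points, or source x frequency x time voxels), an
element-wise one-sample t statistic is thresholded at the cluster-forming
quantile, supra-threshold elements are grouped into connected components,
and each cluster's mass (sum of t values) is compared against a null
distribution of per-permutation *maximal* cluster masses obtained by
randomly sign-flipping whole subject contrast maps — the exchangeability
unit for a paired two-condition design.  p-values use the standard
add-one Monte Carlo estimator, bounded below by 1/(n_perm + 1); an exact
mode enumerates all 2^n sign patterns.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy import stats


@dataclass
class Cluster:
    members: np.ndarray
    mass: float
    p_value: float


@dataclass
class ClusterResult:
    """Observed clusters (mass-sorted, descending) plus the permutation null."""

    t_map: np.ndarray
    clusters: list[Cluster]
    null_distribution: np.ndarray
    n_permutations: int
    alpha_form: float
    tail: str = "one_sided_pos"
    element_shape: tuple[int, ...] | None = None

    @property
    def min_p(self) -> float:
        return min((c.p_value for c in self.clusters), default=1.0)

    def significant_clusters(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value < alpha]

    def to_json(self, path, seed: int | None = None) -> None:
        with open(path, "w") as f:
            json.dump(
                {
                    "n_permutations": int(self.n_permutations),
                    "alpha_form": float(self.alpha_form),
                    "tail": self.tail,
                    "seed": seed,
                    "clusters": [
                        {
                            "n_members": int(len(c.members)),
                            "mass": float(c.mass),
                            "p_value": float(c.p_value),
                        }
                        for c in self.clusters
                    ],
                },
                f,
                indent=2,
            )

    def export_tsv(self, path, points_mm: np.ndarray, cluster_index: int = 0) -> None:
        """Cluster membership as a TSV of x_mm, y_mm, z_mm, t."""
        c = self.clusters[cluster_index]
        with open(path, "w") as f:
            f.write("x_mm\ty_mm\tz_mm\tt\n")
            for m in c.members:
                x, y, z = points_mm[m]
                f.write(f"{x:.3f}\t{y:.3f}\t{z:.3f}\t{self.t_map[m]:.6f}\n")


def _as_csr(adjacency) -> sp.csr_matrix:
    if sp.issparse(adjacency):
        adj = adjacency.tocsr()
    else:
        adj = sp.csr_matrix(np.asarray(adjacency))
    if (adj != adj.T).nnz:
        raise ValueError("adjacency must be symmetric")
    adj = adj.copy()
    adj.setdiag(False)
    adj.eliminate_zeros()
    return adj


def _t_one_sample(X: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    m = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
    return np.where(sd > 0, t, np.where(m > 0, np.inf, np.where(m < 0, -np.inf, 0.0)))


def _clusters_and_masses(
    t: np.ndarray, thr: float, indptr: np.ndarray, indices: np.ndarray
) -> list[tuple[np.ndarray, float]]:
    """Connected components of the supra-threshold element set (strict >)."""
    supra = t > thr
    labels = np.full(len(t), -1, dtype=np.int64)
    out = []
    for start in np.flatnonzero(supra):
        if labels[start] >= 0:
            continue
        comp = [start]
        labels[start] = start
        stack = [start]
        while stack:
            v = stack.pop()
            for u in indices[indptr[v] : indptr[v + 1]]:
                if supra[u] and labels[u] < 0:
                    labels[u] = start
                    comp.append(u)
                    stack.append(u)
        comp = np.array(comp)
        out.append((comp, float(t[comp].sum())))
    return out


def _max_masses(
    T: np.ndarray, thr: float, indptr: np.ndarray, indices: np.ndarray
) -> np.ndarray:
    """Maximal cluster mass per row of a (n_perm, n_elements) t array."""
    out = np.zeros(T.shape[0])
    for k in range(T.shape[0]):
        comps = _clusters_and_masses(T[k], thr, indptr, indices)
        if comps:
            out[k] = max(m for _, m in comps)
    return out


def _perm_t(X: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """One-sample t maps under per-subject sign flips, vectorised.

    Sign flips leave each element's sum of squares unchanged, so only the
    mean needs recomputing per permutation.
    """
    n = X.shape[0]
    sumsq = np.einsum("se,se->e", X, X)
    M = signs @ X / n
    var = (sumsq[None, :] / n - M**2) * (n / (n - 1))
    var = np.clip(var, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        T = M / np.sqrt(var / n)
    T[~np.isfinite(T)] = np.where(M[~np.isfinite(T)] > 0, np.inf, 0.0)
    return T


def cluster_perm_dep(
    per_subject_contrast: np.ndarray,
    adjacency,
    alpha_form: float = 0.05,
    n_perm: int = 10_000,
    seed: int | None = None,
    mode: str = "montecarlo",
) -> ClusterResult:
    """One-sided dependent-samples cluster-mass permutation test.

    ``per_subject_contrast`` is subjects x elements (e.g. NoGo - Go window
    power per grid point).  Cluster-forming threshold is the upper
    ``alpha_form`` quantile of t(df = n-1); the positive tail is tested.
    ``mode='exact'`` enumerates all 2^n sign patterns (n <= 20).
    """
    X = np.asarray(per_subject_contrast, dtype=float)
    if X.ndim != 2:
        raise ValueError("contrast must be subjects x elements")
    n, n_elem = X.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if not 0.0 < alpha_form <= 0.5:
        raise ValueError("alpha_form must lie in (0, 0.5]")
    adj = _as_csr(adjacency)
    if adj.shape[0] != n_elem:
        raise ValueError("adjacency size does not match element count")

    thr = float(stats.t.ppf(1.0 - alpha_form, df=n - 1))
    t_obs = _t_one_sample(X)
    comps = _clusters_and_masses(t_obs, thr, adj.indptr, adj.indices)
    comps.sort(key=lambda cm: cm[1], reverse=True)

    if mode == "exact":
        if n > 20:
            raise ValueError("exact enumeration limited to n <= 20 subjects")
        n_patterns = 2**n
        bits = ((np.arange(n_patterns)[:, None] >> np.arange(n)) & 1).astype(float)
        signs_all = 2.0 * bits - 1.0
        null = np.empty(n_patterns)
        for lo in range(0, n_patterns, 4096):
            T = _perm_t(X, signs_all[lo : lo + 4096])
            null[lo : lo + 4096] = _max_masses(T, thr, adj.indptr, adj.indices)
        n_eff = n_patterns
        # exact p: proportion of the full enumeration with mass >= observed
        pvals = [(np.sum(null >= m) / n_eff) for _, m in comps]
    elif mode == "montecarlo":
        rng = np.random.default_rng(seed)
        null = np.empty(n_perm)
        for lo in range(0, n_perm, 2048):
            hi = min(lo + 2048, n_perm)
            signs = rng.choice([-1.0, 1.0], size=(hi - lo, n))
            T = _perm_t(X, signs)
            null[lo:hi] = _max_masses(T, thr, adj.indptr, adj.indices)
        pvals = [(1.0 + np.sum(null >= m)) / (1.0 + n_perm) for _, m in comps]
    else:
        raise ValueError("mode must be 'montecarlo' or 'exact'")

    clusters = [
        Cluster(members=mem, mass=mass, p_value=float(p))
        for (mem, mass), p in zip(comps, pvals)
    ]
    return ClusterResult(
        t_map=t_obs,
        clusters=clusters,
        null_distribution=null,
        n_permutations=len(null) if mode == "exact" else n_perm,
        alpha_form=alpha_form,
    )


def product_adjacency(
    grid_adjacency, n_freqs: int, n_times: int
) -> sp.csr_matrix:
    """Cartesian product graph over (source, freq, time) voxels.

    Neighbours differ in exactly one axis: grid neighbours at the same
    (freq, time), or +-1 frequency bin, or +-1 time bin.
    """
    A_s = _as_csr(grid_adjacency).astype(np.int8)
    A_f = sp.diags([1, 1], [-1, 1], shape=(n_freqs, n_freqs), dtype=np.int8, format="csr")
    A_t = sp.diags([1, 1], [-1, 1], shape=(n_times, n_times), dtype=np.int8, format="csr")
    I_s = sp.eye(A_s.shape[0], dtype=np.int8, format="csr")
    I_f = sp.eye(n_freqs, dtype=np.int8, format="csr")
    I_t = sp.eye(n_times, dtype=np.int8, format="csr")
    A = (
        sp.kron(sp.kron(A_s, I_f), I_t)
        + sp.kron(sp.kron(I_s, A_f), I_t)
        + sp.kron(sp.kron(I_s, I_f), A_t)
    )
    return A.astype(bool).tocsr()


def cluster_perm_stf(
    per_subject_tfr_contrast: np.ndarray,
    grid_adjacency,
    freqs: np.ndarray,
    times: np.ndarray,
    freq_range: tuple[float, float] = (1.0, 10.0),
    time_range: tuple[float, float] = (0.0, 1.0),
    alpha_form: float = 0.05,
    n_perm: int = 5_000,
    seed: int | None = None,
) -> tuple[ClusterResult, np.ndarray, np.ndarray]:
    """Space x frequency x time cluster-mass permutation test.

    ``per_subject_tfr_contrast`` is subjects x sources x freqs x times; the
    test is restricted to ``freq_range`` and ``time_range`` (inclusive) and
    uses the Cartesian product adjacency of the grid graph with +-1
    frequency and time steps.  Returns (result, selected_freqs,
    selected_times); the result's ``element_shape`` encodes the restricted
    (sources, freqs, times) layout of flattened element indices.
    """
    X = np.asarray(per_subject_tfr_contrast, dtype=float)
    if X.ndim != 4:
        raise ValueError("contrast must be subjects x sources x freqs x times")
    freqs = np.asarray(freqs, dtype=float)
    times = np.asarray(times, dtype=float)
    fm = (freqs >= freq_range[0]) & (freqs <= freq_range[1])
    tm = (times >= time_range[0]) & (times <= time_range[1])
    if not fm.any() or not tm.any():
        raise ValueError("requested ranges select no bins")
    Xr = X[:, :, fm][:, :, :, tm]
    n_subj, n_src, n_f, n_t = Xr.shape
    adj = product_adjacency(grid_adjacency, n_f, n_t)
    result = cluster_perm_dep(
        Xr.reshape(n_subj, -1), adj, alpha_form=alpha_form, n_perm=n_perm, seed=seed
    )
    result.element_shape = (n_src, n_f, n_t)
    return result, freqs[fm], times[tm]


def cluster_centroid(
    result: ClusterResult,
    points_mm: np.ndarray,
    freqs: np.ndarray,
    times: np.ndarray,
    cluster_index: int = 0,
) -> tuple[np.ndarray, float, float]:
    """t-weighted centroid (xyz mm, Hz, s) of a space-time-frequency cluster."""
    if result.element_shape is None:
        raise ValueError("result does not carry a space-time-frequency layout")
    c = result.clusters[cluster_index]
    n_src, n_f, n_t = result.element_shape
    si, fi, ti = np.unravel_index(c.members, (n_src, n_f, n_t))
    w = result.t_map[c.members]
    w = w / w.sum()
    xyz = (points_mm[si] * w[:, None]).sum(axis=0)
    return xyz, float(freqs[fi] @ w), float(times[ti] @ w)
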