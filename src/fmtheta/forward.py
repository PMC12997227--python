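"""Spherical-conductor magnetometer forward model, source grids, and adjacency.

The head is modelled as a homogeneous conducting sphere.  The magnetic field
of a current dipole inside such a sphere has a closed form (Sarvas 1987) that
depends only on the dipole position/moment and the sensor position — not on
the conductivity profile.  Two structural properties of this model matter for
everything downstream:

* a radially oriented dipole produces **no** external magnetic field, so
* the leadfield at any source point has rank 2 (two tangential orientations).

A canonical "template-like" coordinate frame is used throughout: the sphere
is centred at the origin with radius 80 mm, and grid coordinates are reported
in millimetres in this frame.  All internal computation is in SI units
(metres, tesla, A·m).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import scipy.sparse as sp

MU0_OVER_4PI = 1e-7  # T·m/(A·m)

DEFAULT_SPHERE_RADIUS = 0.080  # m
DEFAULT_SENSOR_RADIUS = 0.102  # m, helmet shell outside the conductor


@dataclass
class SensorGeometry:
    """Magnetometer array on a helmet-like spherical cap.

    positions/orientations are (n, 3) arrays in metres / unit vectors;
    every sensor must sit strictly outside the conducting sphere.
    """

    channel_names: list[str]
    positions: np.ndarray
    orientations: np.ndarray
    sphere_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    sphere_radius: float = DEFAULT_SPHERE_RADIUS

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.orientations = np.atleast_2d(np.asarray(self.orientations, dtype=float))
        self.sphere_center = np.asarray(self.sphere_center, dtype=float)
        if self.positions.shape != self.orientations.shape:
            raise ValueError("positions and orientations must have matching shapes")
        if len(self.channel_names) != len(self.positions):
            raise ValueError("channel_names length must match positions")
        norms = np.linalg.norm(self.orientations, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("sensor orientations must be unit vectors")
        dist = np.linalg.norm(self.positions - self.sphere_center, axis=1)
        if np.any(dist <= self.sphere_radius):
            raise ValueError("every sensor must lie strictly outside the sphere")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def to_json_dict(self) -> dict:
        return {
            "channel_names": list(self.channel_names),
            "positions": self.positions.tolist(),
            "orientations": self.orientations.tolist(),
            "sphere_center": self.sphere_center.tolist(),
            "sphere_radius": float(self.sphere_radius),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "SensorGeometry":
        return cls(
            channel_names=list(d["channel_names"]),
            positions=np.asarray(d["positions"]),
            orientations=np.asarray(d["orientations"]),
            sphere_center=np.asarray(d["sphere_center"]),
            sphere_radius=float(d["sphere_radius"]),
        )


def helmet_geometry(
    n_channels: int = 102,
    sensor_radius: float = DEFAULT_SENSOR_RADIUS,
    sphere_radius: float = DEFAULT_SPHERE_RADIUS,
    cap_angle_deg: float = 115.0,
) -> SensorGeometry:
    """Deterministic helmet-like cap of radial magnetometers.

    Sensors are laid out on a Fibonacci lattice over a spherical cap of
    half-angle ``cap_angle_deg`` about +z (roughly the coverage of a
    whole-head MEG helmet), at ``sensor_radius`` from the sphere centre,
    with radially outward pointing sensitive axes.
    """
    if n_channels < 1:
        raise ValueError("need at least one channel")
    zmin = np.cos(np.deg2rad(cap_angle_deg))
    i = np.arange(n_channels)
    z = 1.0 - (1.0 - zmin) * (i + 0.5) / n_channels
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * i
    s = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    unit = np.column_stack([s * np.cos(phi), s * np.sin(phi), z])
    names = [f"MAG{k:03d}" for k in range(1, n_channels + 1)]
    return SensorGeometry(
        channel_names=names,
        positions=sensor_radius * unit,
        orientations=unit,
        sphere_radius=sphere_radius,
    )


def sarvas_field(
    dipole_pos: np.ndarray,
    dipole_moment: np.ndarray,
    geometry: SensorGeometry,
) -> np.ndarray:
    """Closed-form external field of a current dipole in a conducting sphere.

    Returns the projection of the magnetic field (tesla) onto each sensor's
    orientation, for a dipole at ``dipole_pos`` (m) with moment
    ``dipole_moment`` (A·m).  The dipole must be strictly inside the sphere
    and every sensor strictly outside (enforced by the geometry).
    """
    r0 = np.asarray(dipole_pos, dtype=float) - geometry.sphere_center
    q = np.asarray(dipole_moment, dtype=float)
    if np.linalg.norm(r0) >= geometry.sphere_radius:
        raise ValueError("dipole must lie strictly inside the conductor sphere")

    r = geometry.positions - geometry.sphere_center  # (n, 3)
    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=1)
    rn = np.linalg.norm(r, axis=1)
    if np.any(a < 1e-12):
        raise ValueError("sensor coincides with the dipole position")
    ar = np.einsum("ij,ij->i", a_vec, r)
    r0r = r @ r0

    F = a * (rn * a + rn**2 - r0r)
    grad_coef_r = a**2 / rn + ar / a + 2.0 * a + 2.0 * rn
    grad_coef_r0 = a + 2.0 * rn + ar / a
    gradF = grad_coef_r[:, None] * r - grad_coef_r0[:, None] * r0

    q_x_r0 = np.cross(q, r0)
    qr0_dot_r = r @ q_x_r0
    B = MU0_OVER_4PI / F[:, None] ** 2 * (F[:, None] * q_x_r0 - qr0_dot_r[:, None] * gradF)
    return np.einsum("ij,ij->i", B, geometry.orientations)


_OFFSETS_6 = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


def _neighbor_offsets(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return _OFFSETS_6
    grid = np.array(
        [[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
    )
    grid = grid[np.any(grid != 0, axis=1)]
    if connectivity == 26:
        return grid
    if connectivity == 18:
        return grid[np.abs(grid).sum(axis=1) <= 2]
    raise ValueError("connectivity must be one of {6, 18, 26}")


@dataclass
class SourceGrid:
    """Regular lattice of candidate source points inside the sphere.

    ``points`` holds only the inside points (m, sphere-centre frame);
    ``lattice_index`` holds their integer lattice coordinates;
    ``adjacency`` is a symmetric sparse boolean matrix over inside points.
    """

    points: np.ndarray
    lattice_index: np.ndarray
    spacing_mm: float
    connectivity: int
    adjacency: sp.csr_matrix
    margin: float

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def points_mm(self) -> np.ndarray:
        return self.points * 1e3

    def neighbors(self, i: int) -> np.ndarray:
        return self.adjacency.indices[
            self.adjacency.indptr[i] : self.adjacency.indptr[i + 1]
        ]


def build_grid(
    geometry: SensorGeometry,
    spacing_mm: float = 6.0,
    connectivity: int = 6,
    margin: float = 0.9,
) -> SourceGrid:
    """Regular 3D grid covering the sphere, masked to its interior.

    Points are kept where ``|p - center| < sphere_radius * margin``; the
    margin keeps sources away from the conductor surface, loosely mimicking
    a grey-matter source space.  Adjacency connects inside points exactly one
    lattice step apart under the chosen connectivity (6 = faces only).
    """
    if spacing_mm <= 0:
        raise ValueError("spacing must be positive")
    if spacing_mm * 1e-3 > geometry.sphere_radius:
        raise ValueError("grid spacing exceeds the sphere radius")
    h = spacing_mm * 1e-3
    r_in = geometry.sphere_radius * margin
    k_max = int(np.floor(r_in / h))
    axis = np.arange(-k_max, k_max + 1)
    idx = np.array(np.meshgrid(axis, axis, axis, indexing="ij")).reshape(3, -1).T
    pts = idx * h
    inside = np.linalg.norm(pts, axis=1) < r_in
    idx = idx[inside]
    pts = pts[inside] + geometry.sphere_center

    lut = {tuple(v): i for i, v in enumerate(idx)}
    offsets = _neighbor_offsets(connectivity)
    rows, cols = [], []
    for i, v in enumerate(idx):
        for off in offsets:
            j = lut.get((v[0] + off[0], v[1] + off[1], v[2] + off[2]))
            if j is not None:
                rows.append(i)
                cols.append(j)
    n = len(idx)
    adj = sp.csr_matrix(
        (np.ones(len(rows), dtype=bool), (rows, cols)), shape=(n, n)
    )
    return SourceGrid(
        points=pts,
        lattice_index=idx,
        spacing_mm=float(spacing_mm),
        connectivity=int(connectivity),
        adjacency=adj,
        margin=float(margin),
    )


def tangential_basis(point: np.ndarray, center: np.ndarray | None = None) -> np.ndarray:
    """Deterministic orthonormal tangential basis (2, 3) at ``point``.

    First vector: normalize(z_hat x r_hat), falling back to x_hat x r_hat
    when r_hat is (anti)parallel to z; second vector: r_hat x first.  At the
    exact sphere centre the radial direction is undefined; z_hat is used as
    the conventional radial direction there (any dipole at the centre is
    externally silent regardless).
    """
    p = np.asarray(point, dtype=float)
    if center is not None:
        p = p - np.asarray(center, dtype=float)
    nrm = np.linalg.norm(p)
    r_hat = p / nrm if nrm > 1e-12 else np.array([0.0, 0.0, 1.0])
    e1 = np.cross([0.0, 0.0, 1.0], r_hat)
    if np.linalg.norm(e1) < 1e-8:
        e1 = np.cross([1.0, 0.0, 0.0], r_hat)
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(r_hat, e1)
    return np.vstack([e1, e2])


@dataclass
class Leadfield:
    """Per grid point channels x 2 gain matrices in a tangential basis.

    gain has shape (n_points, n_channels, 2), units T per A·m; basis has
    shape (n_points, 2, 3) with the tangential unit moments used for the
    two columns.
    """

    gain: np.ndarray
    basis: np.ndarray
    grid: SourceGrid
    channel_names: list[str]

    @property
    def n_points(self) -> int:
        return self.gain.shape[0]

    @property
    def n_channels(self) -> int:
        return self.gain.shape[1]

    def column_norms(self) -> np.ndarray:
        return np.linalg.norm(self.gain, axis=1)


def compute_leadfield(grid: SourceGrid, geometry: SensorGeometry) -> Leadfield:
    """Forward gains for two orthonormal tangential moments at every grid point."""
    n = grid.n_points
    gain = np.empty((n, geometry.n_channels, 2))
    basis = np.empty((n, 2, 3))
    for i, p in enumerate(grid.points):
        b = tangential_basis(p, geometry.sphere_center)
        basis[i] = b
        gain[i, :, 0] = sarvas_field(p, b[0], geometry)
        gain[i, :, 1] = sarvas_field(p, b[1], geometry)
    if not np.all(np.isfinite(gain)):
        raise FloatingPointError("non-finite leadfield entries")
    return Leadfield(gain=gain, basis=basis, grid=grid, channel_names=list(geometry.channel_names))


def save_forward_h5(path, grid: SourceGrid, leadfield: Leadfield | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("points", data=grid.points)
        f.create_dataset("lattice_index", data=grid.lattice_index)
        coo = grid.adjacency.tocoo()
        f.create_dataset("adjacency_row", data=coo.row)
        f.create_dataset("adjacency_col", data=coo.col)
        f.attrs["spacing_mm"] = grid.spacing_mm
        f.attrs["connectivity"] = grid.connectivity
        f.attrs["margin"] = grid.margin
        if leadfield is not None:
            f.create_dataset("leadfield", data=leadfield.gain, compression="gzip")
            f.create_dataset("basis", data=leadfield.basis)
            f.attrs["channel_names"] = [str(c) for c in leadfield.channel_names]


def load_forward_h5(path) -> tuple[SourceGrid, Leadfield | None]:
    with h5py.File(path, "r") as f:
        pts = f["points"][()]
        idx = f["lattice_index"][()]
        row = f["adjacency_row"][()]
        col = f["adjacency_col"][()]
        n = len(pts)
        adj = sp.csr_matrix((np.ones(len(row), dtype=bool), (row, col)), shape=(n, n))
        grid = SourceGrid(
            points=pts,
            lattice_index=idx,
            spacing_mm=float(f.attrs["spacing_mm"]),
            connectivity=int(f.attrs["connectivity"]),
            adjacency=adj,
            margin=float(f.attrs["margin"]),
        )
        lf = None
        if "leadfield" in f:
            lf = Leadfield(
                gain=f["leadfield"][()],
                basis=f["basis"][()],
                grid=grid,
                channel_names=[str(c) for c in f.attrs["channel_names"]],
            )
    return grid, lf
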