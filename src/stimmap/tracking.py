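"""Deterministic streamline tractography on diffusion-tensor volumes.

Streamlines follow the principal eigenvector of the interpolated diffusion
tensor bidirectionally from a lattice of seeds around a CoG point.  The
stopping rules follow the clinical fiber-tracking convention used for the
language tracts: an absolute fractional-anisotropy floor of 0.1 *and* 50% of
the individual FA maximum (the larger of the two applies), a turning-angle
limit, and a 20 mm minimum fiber length below which streamlines are
discarded.  Tensors are interpolated component-wise (trilinear) before
eigen-decomposition, and eigenvector sign is kept coherent with the incoming
direction; tracking is fully deterministic for a given volume and parameter
set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from nibabel.affines import apply_affine

_TENSOR_ORDER = ("xx", "xy", "xz", "yy", "yz", "zz")  # row-major upper triangle


def _to_matrices(six: np.ndarray) -> np.ndarray:
    """(..., 6) upper-triangular components -> (..., 3, 3) symmetric matrices."""
    six = np.asarray(six, dtype=float)
    m = np.empty(six.shape[:-1] + (3, 3))
    m[..., 0, 0] = six[..., 0]
    m[..., 0, 1] = m[..., 1, 0] = six[..., 1]
    m[..., 0, 2] = m[..., 2, 0] = six[..., 2]
    m[..., 1, 1] = six[..., 3]
    m[..., 1, 2] = m[..., 2, 1] = six[..., 4]
    m[..., 2, 2] = six[..., 5]
    return m


def fa_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    """Fractional anisotropy from eigenvalue triples (clamped to >= 0).

    FA = sqrt(3/2) * ||lambda - mean|| / ||lambda||, in [0, 1]; an all-zero
    tensor has FA defined as 0.
    """
    lam = np.maximum(np.asarray(evals, dtype=float), 0.0)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.sqrt(((lam - mean) ** 2).sum(axis=-1))
    den = np.sqrt((lam**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.where(den > 0, num / den, 0.0)
    return np.clip(fa, 0.0, 1.0)


def compute_fa(tensor: np.ndarray) -> float:
    """FA of a single 3x3 symmetric tensor (or of a 6-component triple)."""
    t = np.asarray(tensor, dtype=float)
    if t.shape == (6,):
        t = _to_matrices(t)
    if t.shape == (3,):
        return float(fa_from_eigenvalues(t))
    evals = np.linalg.eigvalsh(t)
    return float(fa_from_eigenvalues(evals))


@dataclass
class TensorVolume:
    """Per-voxel symmetric diffusion tensors (mm^2/s) with world affine.

    ``data`` has shape (X, Y, Z, 6) in the order Dxx, Dxy, Dxz, Dyy, Dyz, Dzz.
    Eigenvalues are clamped at zero when deriving FA and principal directions.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4 or self.data.shape[-1] != 6:
            raise ValueError("tensor data must have shape (X, Y, Z, 6)")
        self._fa = None

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def fa_map(self) -> np.ndarray:
        if self._fa is None:
            evals = np.linalg.eigvalsh(_to_matrices(self.data))
            self._fa = fa_from_eigenvalues(evals)
        return self._fa

    # -- interpolation ---------------------------------------------------

    def _trilinear(self, arr: np.ndarray, vox: np.ndarray) -> np.ndarray:
        """Trilinear interpolation of (X, Y, Z, k) data at fractional voxel coords (n, 3)."""
        shape = np.asarray(arr.shape[:3])
        v = np.clip(vox, 0.0, shape - 1.000001)
        i0 = np.floor(v).astype(int)
        f = v - i0
        out = 0.0
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    w = (
                        (f[:, 0] if dx else 1 - f[:, 0])
                        * (f[:, 1] if dy else 1 - f[:, 1])
                        * (f[:, 2] if dz else 1 - f[:, 2])
                    )
                    out = out + w[:, None] * arr[i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz]
        return out

    def tensor_at(self, world_mm: np.ndarray) -> np.ndarray:
        """Interpolated 3x3 tensors at world points (n, 3) -> (n, 3, 3)."""
        vox = apply_affine(np.linalg.inv(self.affine), np.atleast_2d(world_mm))
        return _to_matrices(self._trilinear(self.data, vox))

    def fa_at(self, world_mm: np.ndarray) -> np.ndarray:
        """FA of the interpolated tensor at world points."""
        evals = np.linalg.eigvalsh(self.tensor_at(world_mm))
        return fa_from_eigenvalues(evals)

    def inside(self, world_mm: np.ndarray) -> np.ndarray:
        vox = apply_affine(np.linalg.inv(self.affine), np.atleast_2d(world_mm))
        shape = np.asarray(self.data.shape[:3])
        return np.all((vox >= 0) & (vox <= shape - 1), axis=1)


@dataclass
class TrackingParams:
    """Stopping rules and integration settings for deterministic tracking.

    fa_stop : absolute FA floor (0.1 by convention).
    fa_stop_relative : fraction of the individual FA maximum also applied
        (0.5); the effective threshold is max(fa_stop, fa_stop_relative * FAmax)
        with FAmax taken over the seed-region neighbourhood.
    min_length : minimum streamline length in mm (20 by convention).
    step : integration step, mm.
    max_angle : maximal turning angle per step, degrees.
    seed_radius : radius (mm) of the seed sphere around the CoG; seeds are
        all voxel centers inside it (a deterministic lattice).
    """

    fa_stop: float = 0.1
    fa_stop_relative: float = 0.5
    min_length: float = 20.0
    step: float = 1.0
    max_angle: float = 45.0
    seed_radius: float = 5.0

    def __post_init__(self):
        if not 0 < self.fa_stop < 1:
            raise ValueError("fa_stop must lie in (0, 1)")
        if self.min_length <= 0 or self.step <= 0:
            raise ValueError("min_length and step must be positive")
        if not 0 < self.max_angle <= 90:
            raise ValueError("max_angle must lie in (0, 90] degrees")


@dataclass
class TractStats:
    """Summary of one tracked bundle: count, mean length (mm), mean FA."""

    count: int
    mean_length: float
    mean_fa: float

    @property
    def defined(self) -> bool:
        return self.count > 0


def _principal_direction(tensor: np.ndarray, reference: np.ndarray | None) -> tuple[np.ndarray, float]:
    evals, evecs = np.linalg.eigh(tensor)
    fa = float(fa_from_eigenvalues(evals))
    v = evecs[:, -1]
    if reference is not None and np.dot(v, reference) < 0:
        v = -v
    return v, fa


def effective_fa_threshold(vol: TensorVolume, params: TrackingParams, seed_center) -> float:
    """max(fa_stop, fa_stop_relative * local FA maximum around the seed region).

    The individual FA maximum is taken over voxel centers within twice the
    seed radius of the CoG — the immediate neighbourhood the seeds sample.
    """
    idx = np.stack(np.meshgrid(*[np.arange(s) for s in vol.data.shape[:3]], indexing="ij"), axis=-1)
    world = apply_affine(vol.affine, idx.reshape(-1, 3))
    d = np.linalg.norm(world - np.asarray(seed_center, float), axis=1)
    near = d <= 2 * params.seed_radius
    if not np.any(near):
        return params.fa_stop
    fa_max = float(vol.fa_map.reshape(-1)[near].max())
    return max(params.fa_stop, params.fa_stop_relative * fa_max)


def _march(vol, start, direction, theta, cos_max, step, max_steps=2000):
    """One-sided streamline integration; returns the list of points beyond start."""
    pts = []
    p = np.asarray(start, float)
    d = np.asarray(direction, float)
    for _ in range(max_steps):
        q = p + step * d
        if not vol.inside(q[None])[0]:
            break
        v, fa = _principal_direction(vol.tensor_at(q[None])[0], d)
        if fa < theta:
            break
        if np.dot(v, d) < cos_max:
            break
        pts.append(q)
        p, d = q, v
    return pts


def track_streamlines(
    vol: TensorVolume,
    seed_center,
    params: TrackingParams | None = None,
) -> list[np.ndarray]:
    """Bidirectional deterministic tracking from a seed sphere around ``seed_center``.

    Returns world-mm polylines of length >= ``params.min_length``; an empty
    seed region (no voxel with FA above threshold) yields an empty list.
    """
    params = params or TrackingParams()
    theta = effective_fa_threshold(vol, params, seed_center)
    cos_max = float(np.cos(np.deg2rad(params.max_angle)))
    idx = np.stack(np.meshgrid(*[np.arange(s) for s in vol.data.shape[:3]], indexing="ij"), axis=-1)
    world = apply_affine(vol.affine, idx.reshape(-1, 3))
    near = np.linalg.norm(world - np.asarray(seed_center, float), axis=1) <= params.seed_radius
    seeds = world[near]
    streamlines = []
    for seed in seeds:
        v, fa = _principal_direction(vol.tensor_at(seed[None])[0], None)
        if fa < theta:
            continue
        fwd = _march(vol, seed, v, theta, cos_max, params.step)
        bwd = _march(vol, seed, -v, theta, cos_max, params.step)
        line = np.asarray(bwd[::-1] + [seed] + fwd)
        if len(line) < 2:
            continue
        if streamline_length(line) >= params.min_length:
            streamlines.append(line)
    return streamlines


def streamline_length(line: np.ndarray) -> float:
    """Polyline arc length in mm."""
    return float(np.linalg.norm(np.diff(line, axis=0), axis=1).sum())


def tract_stats(streamlines: list[np.ndarray], vol: TensorVolume) -> TractStats:
    """Mean length and mean FA (trilinear samples along each line, then over lines)."""
    if not streamlines:
        return TractStats(count=0, mean_length=float("nan"), mean_fa=float("nan"))
    lengths = [streamline_length(s) for s in streamlines]
    fas = [float(vol.fa_at(s).mean()) for s in streamlines]
    return TractStats(
        count=len(streamlines),
        mean_length=float(np.mean(lengths)),
        mean_fa=float(np.mean(fas)),
    )
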