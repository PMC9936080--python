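"""Direct electrical stimulation field: Laplace problem with electrode Dirichlet sets.

The exposed-cortex stimulation is modeled as a static conduction problem:
phi solves div(sigma grad phi) = 0 away from the electrodes, with the
potential prescribed on small ball electrodes at the grey-matter surface
(1 mm radius; bipolar pairs 4.4 mm apart center-to-center) and, for the
monopolar mode, on a remote large return electrode at the inferior end of
the model.  Zero normal current holds elsewhere on the outer boundary.  The
solve uses a unit potential contrast and is then rescaled so the net current
injected through the anode equals the configured stimulation current
(clinically 1-6 mA), which also absorbs the voxelization error of sub-voxel
electrode balls.  The 0.2 ms pulse is treated quasi-statically (DC solve).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from nibabel.affines import apply_affine

from .errors import GeometryError
from .volume_conductor import FieldSolution, GridSystem

_MM = 1e-3


@dataclass
class ElectrodeConfig:
    """Electrode geometry and drive for one DES solve.

    anode_mm : world-mm center of the anode ball (on/adjacent to the GM surface).
    cathode_mm : cathode center for bipolar mode (default: 4.4 mm from the
        anode along ``bipolar_axis``).
    mode : "bipolar" (default; the two balls of the electrode pen) or
        "monopolar" (anode + remote return region).
    ball_radius : mm, default 1.
    current_ma : stimulation current in mA, in (0, 6].
    return_region : for monopolar mode, "inferior" (a slab at the inferior
        end of the conductive domain), "boundary" (every voxel adjacent to
        background; useful for analytic benchmarks), or an explicit boolean
        voxel mask.
    return_thickness : slab thickness (mm) of the "inferior" return.
    """

    anode_mm: tuple
    cathode_mm: tuple | None = None
    mode: str = "bipolar"
    ball_radius: float = 1.0
    current_ma: float = 1.0
    bipolar_axis: tuple = (1.0, 0.0, 0.0)
    bipolar_separation: float = 4.4
    return_region: object = "inferior"
    return_thickness: float = 6.0

    def __post_init__(self):
        if self.mode not in ("bipolar", "monopolar"):
            raise GeometryError(f"unknown electrode mode {self.mode!r}")
        if self.ball_radius <= 0:
            raise GeometryError("ball radius must be positive")
        if not 0 < self.current_ma <= 6.0:
            raise GeometryError("stimulation current must lie in (0, 6] mA")
        if self.mode == "bipolar":
            if self.cathode_mm is None:
                a = np.asarray(self.bipolar_axis, dtype=float)
                a /= np.linalg.norm(a)
                self.cathode_mm = tuple(np.asarray(self.anode_mm, float) + self.bipolar_separation * a)
            sep = np.linalg.norm(np.asarray(self.cathode_mm, float) - np.asarray(self.anode_mm, float))
            if sep <= 2 * self.ball_radius:
                raise GeometryError("bipolar separation must exceed the ball diameter")


def _ball_voxels(center_mm, radius, affine, active) -> np.ndarray:
    """Boolean mask of active voxels forming one electrode ball.

    Voxel centers within ``radius`` mm; a sub-voxel ball is inflated to the
    single nearest active voxel (the current normalization absorbs the
    geometric error).
    """
    shape = active.shape
    idx = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1)
    world = apply_affine(affine, idx)
    d2 = np.sum((world - np.asarray(center_mm, float)) ** 2, axis=-1)
    mask = (d2 <= radius**2) & active
    if not np.any(mask):
        d2m = np.where(active, d2, np.inf)
        spacing = float(np.linalg.norm(np.asarray(affine)[:3, :3], axis=0).max())
        if d2m.min() > (2 * spacing) ** 2:
            raise GeometryError("electrode center lies outside the conductive domain")
        mask = d2m == d2m.min()
    return mask


def _return_mask(cfg: ElectrodeConfig, active: np.ndarray, affine) -> np.ndarray:
    if isinstance(cfg.return_region, np.ndarray):
        mask = cfg.return_region & active
    elif cfg.return_region == "boundary":
        pad = np.pad(active, 1, constant_values=False)
        interior = np.ones_like(active)
        for ax in range(3):
            for s in (-1, 1):
                interior &= np.roll(pad, s, axis=ax)[1:-1, 1:-1, 1:-1]
        mask = active & ~interior
    elif cfg.return_region == "inferior":
        idx = np.argwhere(active)
        z = apply_affine(affine, idx.astype(float))[:, 2]
        zmin = z.min()
        sel = z <= zmin + cfg.return_thickness
        mask = np.zeros_like(active)
        mask[tuple(idx[sel].T)] = True
    else:
        raise GeometryError(f"unknown return region {cfg.return_region!r}")
    if not np.any(mask):
        raise GeometryError("empty return electrode region")
    return mask


def solve_des(
    sigma: np.ndarray,
    affine: np.ndarray,
    electrodes: ElectrodeConfig,
    rtol: float = 1e-8,
    maxiter: int = 40000,
) -> FieldSolution:
    """DES field E = -grad(phi), current-normalized to the configured intensity."""
    affine = np.asarray(affine, dtype=float)
    system = GridSystem(sigma, tuple(np.linalg.norm(affine[:3, :3], axis=0)))
    anode = _ball_voxels(electrodes.anode_mm, electrodes.ball_radius, affine, system.active)
    fixed_masks = [(anode, 1.0)]
    if electrodes.mode == "bipolar":
        cathode = _ball_voxels(electrodes.cathode_mm, electrodes.ball_radius, affine, system.active)
        if np.any(anode & cathode):
            raise GeometryError("anode and cathode voxel sets overlap")
        fixed_masks.append((cathode, -1.0))
    else:
        ret = _return_mask(electrodes, system.active, affine)
        if np.any(ret & anode):
            raise GeometryError("anode overlaps the return electrode region")
        fixed_masks.append((ret, 0.0))
    ids, vals = [], []
    for mask, v in fixed_masks:
        mids = system.index[mask & system.active]
        ids.append(mids)
        vals.append(np.full(len(mids), v))
    phi, res = system.solve_dirichlet(np.concatenate(ids), np.concatenate(vals), rtol=rtol, maxiter=maxiter)
    i_anode = system.net_current(phi, anode)
    if i_anode <= 0:
        raise GeometryError("non-positive anode current; degenerate electrode configuration")
    scale = (electrodes.current_ma * 1e-3) / i_anode
    phi = phi * scale
    grad = system.gradient(phi)
    e_field = np.where(system.active[..., None], -grad, 0.0)
    return FieldSolution(
        e_field=e_field,
        affine=affine,
        modality="DES",
        residual=res,
        phi=system.embed(phi, fill=np.nan),
        meta={
            "mode": electrodes.mode,
            "current_ma": electrodes.current_ma,
            "anode_voxels": int(anode.sum()),
            "potential_scale": scale,
        },
    )


def current_density(sol: FieldSolution, sigma: np.ndarray) -> np.ndarray:
    """J = sigma E pointwise (A/m^2); zero wherever sigma is zero."""
    sigma = np.asarray(sigma, dtype=float)
    if sigma.shape != sol.e_field.shape[:3]:
        raise ValueError(
            f"sigma grid {sigma.shape} does not match field grid {sol.e_field.shape[:3]}"
        )
    return sigma[..., None] * sol.e_field
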