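"""Quasi-static TMS electric field: primary coil term plus induced-charge correction.

The coil is a set of magnetic dipole elements with time-varying moments; the
primary field is

    E_p(r) = -(mu0 / 4 pi) * rate * sum_j  m_j x (r - r_j) / |r - r_j|^3

(the -dA/dt of the superposed dipole vector potentials).  The secondary field
comes from charge accumulated at conductivity gradients: phi solves

    div(sigma grad phi) = div(sigma E_p)

in the head with zero normal total current on the outer boundary, and the
total field is E = E_p - grad phi.  Stimulation intensity is an arbitrary
linear scale (the ``rate`` factor); the downstream comparisons (CoG, overlap)
are scale-free, so no absolute coil-current calibration is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from nibabel.affines import apply_affine

from .errors import GeometryError
from .phantom import TissueLabelVolume
from .volume_conductor import FieldSolution, GridSystem

_MU0_4PI = 1e-7
_MM = 1e-3


@dataclass
class CoilModel:
    """Figure-8 (or arbitrary) coil as discrete magnetic dipole elements.

    positions : (n, 3) dipole positions, world mm.
    moments : (n, 3) magnetic moments, A m^2; the two wings of a figure-8
        carry antiparallel moments.
    rate : dI/dt surrogate (1/s); all moments scale linearly with it.
    """

    positions: np.ndarray
    moments: np.ndarray
    rate: float = 1.0e7

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.moments = np.atleast_2d(np.asarray(self.moments, dtype=float))
        if self.positions.shape != self.moments.shape or self.positions.shape[1] != 3:
            raise GeometryError("positions and moments must both be (n, 3)")
        if self.rate <= 0:
            raise GeometryError("rate factor must be positive")

    @classmethod
    def figure8(
        cls,
        center,
        normal=(0.0, 0.0, -1.0),
        junction_axis=(1.0, 0.0, 0.0),
        wing_radius: float = 35.0,
        wing_separation: float = 70.0,
        n_per_wing: int = 16,
        rate: float = 1.0e7,
    ) -> "CoilModel":
        """Standard figure-of-8 geometry: two coplanar wings, opposite winding.

        ``center`` is the junction point (world mm); ``normal`` the coil-plane
        normal (pointing from the coil toward the head); moments of the two
        wings are +/- normal.  Each wing is a uniform sheet of magnetic
        dipoles sampled on concentric rings over the wing disc — the exact
        magnetostatic equivalent of the rim current loop, which is what makes
        |E_p| peak beneath the wing junction.  ``n_per_wing`` sets the number
        of dipoles on the outermost ring; total elements per wing are >= 12.
        """
        if n_per_wing < 12:
            raise GeometryError("at least 12 dipole elements per wing")
        n_hat = np.asarray(normal, dtype=float)
        n_hat = n_hat / np.linalg.norm(n_hat)
        u = np.asarray(junction_axis, dtype=float)
        u = u - np.dot(u, n_hat) * n_hat
        if np.linalg.norm(u) < 1e-12:
            raise GeometryError("junction axis parallel to coil normal")
        u /= np.linalg.norm(u)
        v = np.cross(n_hat, u)
        center = np.asarray(center, dtype=float)
        n_rings = 3
        radii = (np.arange(n_rings) + 0.5) / n_rings * wing_radius
        counts = np.maximum(
            4, np.round(n_per_wing * (np.arange(n_rings) + 0.5) / (n_rings - 0.5)).astype(int)
        )
        offsets, weights = [], []
        for rad, cnt in zip(radii, counts):
            ang = 2 * np.pi * np.arange(cnt) / cnt
            offsets.append(rad * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v)))
            # equal-area annulus weight shared by the ring's dipoles
            weights.append(np.full(cnt, rad / cnt))
        offsets = np.vstack(offsets)
        weights = np.concatenate(weights)
        weights = weights / weights.sum()  # unit total moment per wing
        pos, mom = [], []
        for s in (+1.0, -1.0):
            wing_c = center + s * (wing_separation / 2.0) * u
            pos.append(wing_c + offsets)
            mom.append(s * np.outer(weights, n_hat))
        return cls(np.vstack(pos), np.vstack(mom), rate=rate)


def primary_field(coil: CoilModel, points_mm: np.ndarray) -> np.ndarray:
    """E_p (V/m) of the coil at world points (mm); linear in the rate factor."""
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float)) * _MM
    out = np.zeros_like(pts)
    for rj, mj in zip(coil.positions * _MM, coil.moments):
        d = pts - rj
        r3 = np.sum(d * d, axis=1) ** 1.5
        if np.any(r3 < 1e-18):
            raise GeometryError("field point coincides with a coil dipole element")
        out += np.cross(np.broadcast_to(mj, d.shape), d) / r3[:, None]
    return -_MU0_4PI * coil.rate * out


def solve_secondary(
    sigma: np.ndarray,
    affine: np.ndarray,
    coil: CoilModel,
    rtol: float = 1e-8,
    maxiter: int = 40000,
) -> FieldSolution:
    """Total TMS field E = E_p - grad(phi) on the labeled grid.

    The potential equation is assembled in conservative (finite-volume) form:
    the source term samples sigma_f * E_p . n at face centers, so discrete
    current conservation holds up to the solver residual.  The equation is
    invariant under uniform scaling of sigma and, for spherically symmetric
    conductors, under spherically symmetric relabeling.
    """
    system = GridSystem(sigma, tuple(np.linalg.norm(np.asarray(affine)[:3, :3], axis=0)))

    def ep_face(face_idx, axis):
        world = apply_affine(affine, face_idx)
        return primary_field(coil, world)[:, axis]

    b = system.divergence_of_primary(ep_face)
    phi, res = system.solve_neumann(b, rtol=rtol, maxiter=maxiter)
    grad = system.gradient(phi)
    idx = np.argwhere(system.active)
    ep = np.zeros(sigma.shape + (3,))
    ep[system.active] = primary_field(coil, apply_affine(affine, idx.astype(float)))
    e_total = np.where(system.active[..., None], ep - grad, 0.0)
    return FieldSolution(
        e_field=e_total,
        affine=np.asarray(affine, dtype=float),
        modality="nTMS",
        residual=res,
        phi=system.embed(phi, fill=np.nan),
        meta={"rate": coil.rate, "n_dipoles": len(coil.positions)},
    )


def simulate_tms(vol: TissueLabelVolume, sigma: np.ndarray, coil: CoilModel, **kw) -> FieldSolution:
    """Convenience wrapper taking a labeled volume (affine source) plus its sigma field."""
    return solve_secondary(sigma, vol.affine, coil, **kw)
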