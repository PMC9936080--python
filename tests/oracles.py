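"""Independent reference implementations used only to check the package.

Everything here is deliberately written from closed forms or brute force,
without reusing the package's solver/update code paths: a spherical-harmonic
series for the field induced in a spherically symmetric conductor by an
external magnetic dipole, Legendre-series solutions for point current
sources in grounded homogeneous and two-layer spheres, a brute-force
run-length rule, and a direct FA closed form.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import eval_legendre, lpmv

MM = 1e-3
MU0_4PI = 1e-7


# ---------------------------------------------------------------------------
# run-of-k rule by direct scan (independent of the package's streak logic)
# ---------------------------------------------------------------------------


def brute_force_positive(outcomes: list[bool], run: int = 3) -> bool:
    """True iff any window of ``run`` consecutive outcomes is all-interrupted."""
    return any(
        all(outcomes[i + j] for j in range(run)) for i in range(len(outcomes) - run + 1)
    )


def enumerate_positive_probability(n_trials: int, run: int = 3) -> float:
    """Exact probability that a fair outcome sequence contains a run of ``run``."""
    hits = 0
    for bits in range(2**n_trials):
        seq = [(bits >> k) & 1 == 1 for k in range(n_trials)]
        hits += brute_force_positive(seq, run)
    return hits / 2**n_trials


# ---------------------------------------------------------------------------
# TMS: tangential magnetic dipole over a spherically symmetric conductor
# ---------------------------------------------------------------------------


def sphere_tms_total_field(
    points_mm: np.ndarray,
    sphere_radius_mm: float,
    dipole_height_mm: float,
    rate: float,
    n_terms: int = 60,
) -> np.ndarray:
    """Closed-form total E (V/m) inside a spherically symmetric conductor.

    Source: a magnetic dipole m = x_hat at (0, 0, d) outside the sphere with
    moment rate ``rate``.  The primary term is the dipole -dA/dt; the
    secondary potential solves the interior Neumann problem whose boundary
    data E_p . r_hat reduce, for a tangential dipole on the z-axis, to the
    m = 1 azimuthal mode:

        phi(r, theta, az) = sin(az) * sum_l c_l r^l P_l^1(cos theta).

    The result is independent of the (spherically symmetric) conductivity
    profile.  Gradients are taken by central differences on the series.
    """
    R = sphere_radius_mm * MM
    d = dipole_height_mm * MM
    k = MU0_4PI * rate

    u, w = leggauss(200)
    sinth = np.sqrt(1 - u**2)
    dist3 = (R**2 + d**2 - 2 * R * d * u) ** 1.5
    ghat = -k * d * sinth / dist3  # boundary data g = ghat(theta) sin(az)
    ls = np.arange(1, n_terms + 1)
    P = np.array([lpmv(1, l, u) for l in ls])
    norms = 2 * ls * (ls + 1) / (2 * ls + 1)
    a = (P * ghat * w).sum(axis=1) / norms
    c = a / (ls * R ** (ls - 1))

    def phi_pot(p):
        r = np.linalg.norm(p, axis=1)
        uu = np.clip(p[:, 2] / np.maximum(r, 1e-30), -1, 1)
        az = np.arctan2(p[:, 1], p[:, 0])
        out = np.zeros(len(p))
        for l, cl in zip(ls, c):
            out += cl * r**l * lpmv(1, l, uu)
        return out * np.sin(az)

    pts = np.atleast_2d(points_mm) * MM
    h = 1e-6
    e_sec = np.zeros_like(pts)
    for ax in range(3):
        dp = np.zeros(3)
        dp[ax] = h
        e_sec[:, ax] = -(phi_pot(pts + dp) - phi_pot(pts - dp)) / (2 * h)

    # primary field of the dipole, written out directly
    r0 = np.array([0.0, 0.0, d])
    m = np.array([1.0, 0.0, 0.0])
    dvec = pts - r0
    r3 = np.sum(dvec**2, axis=1) ** 1.5
    e_p = -k * np.cross(np.broadcast_to(m, dvec.shape), dvec) / r3[:, None]
    return e_p + e_sec


# ---------------------------------------------------------------------------
# DES: point sources in grounded spheres
# ---------------------------------------------------------------------------


def grounded_sphere_point_phi(r_mm, current_a: float, sigma: float, radius_mm: float):
    """phi (V) at distance r from a central point source in a grounded sphere.

    phi(r) = I/(4 pi sigma) (1/r - 1/L); the grounded boundary at L fixes the
    potential reference; the radial field I/(4 pi sigma r^2) is unaffected.
    """
    r = np.asarray(r_mm, dtype=float) * MM
    L = radius_mm * MM
    return current_a / (4 * np.pi * sigma) * (1 / r - 1 / L)


def layered_sphere_point_phi(
    points_mm: np.ndarray,
    current_a: float,
    sigma_inner: float,
    sigma_outer: float,
    interface_mm: float,
    radius_mm: float,
    source_height_mm: float,
    n_terms: int = 400,
) -> np.ndarray:
    """Legendre-series phi for a point source at (0, 0, b) in the outer shell
    of a two-layer grounded sphere (sigma_inner for r < a, sigma_outer for
    a < r < R, phi(R) = 0).  Scaled radial functions keep every term O(1).
    """
    a = interface_mm * MM
    R = radius_mm * MM
    b = source_height_mm * MM
    s1, s2 = sigma_inner, sigma_outer
    k = current_a / (4 * np.pi * s2)
    pts = np.atleast_2d(points_mm) * MM
    r = np.linalg.norm(pts, axis=1)
    cz = np.clip(pts[:, 2] / np.maximum(r, 1e-30), -1, 1)
    inner = r < a
    out = np.where(inner, k / b - k / R, np.where(r < b, k / b, k / np.maximum(r, 1e-30)) - k / R)
    for l in range(1, n_terms + 1):
        aR = (a / R) ** l
        M = np.array(
            [
                [1.0, -aR, -1.0],
                [s1, -s2 * aR, s2 * (l + 1) / l],
                [0.0, 1.0, (a / R) ** (l + 1)],
            ]
        )
        rhs = np.array(
            [
                (k / b) * (a / b) ** l,
                s2 * (k / b) * (a / b) ** l,
                -(k / R) * (b / R) ** l,
            ]
        )
        ch, ah, bh = np.linalg.solve(M, rhs)
        with np.errstate(divide="ignore", invalid="ignore"):
            sing = np.where(
                r < b, (r / b) ** l / b, (b / np.maximum(r, 1e-30)) ** l / np.maximum(r, 1e-30)
            )
            term = np.where(
                inner,
                ch * (r / a) ** l,
                k * sing + ah * (r / R) ** l + bh * (a / np.maximum(r, 1e-30)) ** (l + 1),
            )
        out = out + term * eval_legendre(l, cz)
    return out


# ---------------------------------------------------------------------------
# FA closed form straight from the eigenvalue definition
# ---------------------------------------------------------------------------


def fa_closed_form(l1: float, l2: float, l3: float) -> float:
    lam = np.array([l1, l2, l3], dtype=float)
    lbar = lam.mean()
    den = np.sqrt((lam**2).sum())
    if den == 0:
        return 0.0
    return float(np.sqrt(1.5 * ((lam - lbar) ** 2).sum()) / den)


# ---------------------------------------------------------------------------
# grid helpers shared by solver tests
# ---------------------------------------------------------------------------


def sphere_sigma(radius_mm: float, spacing: float, shells=None, background=0.0):
    """(sigma, affine, r) for a voxelized ball; ``shells`` = [(outer_radius, sigma), ...]
    outermost first, defaulting to a homogeneous 0.2765 S/m ball."""
    n = int(round(2 * radius_mm / spacing)) + 1
    ax = -radius_mm + spacing * np.arange(n)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt(X**2 + Y**2 + Z**2)
    sigma = np.full(r.shape, background)
    for rad, s in shells or [(radius_mm, 0.2765)]:
        sigma[r <= rad] = s
    affine = np.diag([spacing, spacing, spacing, 1.0])
    affine[:3, 3] = -radius_mm
    return sigma, affine, r


def grid_interior(active: np.ndarray) -> np.ndarray:
    """Voxels whose six face neighbours are all active (staircase layer excluded)."""
    pad = np.pad(active, 1, constant_values=False)
    interior = active.copy()
    for ax in range(3):
        for sh in (-1, 1):
            interior &= np.roll(pad, sh, axis=ax)[1:-1, 1:-1, 1:-1]
    return interior
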