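"""Finite-volume machinery for quasi-static potential problems on labeled voxel grids.

Both stimulation modalities reduce, under the quasi-static approximation, to an
elliptic problem for the scalar potential phi on the conductive domain:

    div( sigma * (E_p - grad phi) ) = 0

with E_p the primary (source) field -- the coil term for TMS, zero for DES --
and boundary conditions of zero normal total current on the outer surface
(supplemented by Dirichlet sets for electrodes).  The domain is the set of
voxels with sigma > 0; fluxes are discretized on voxel faces with
harmonic-mean face conductivities, which makes the discrete operator
symmetric positive (semi-)definite and conservative: the net current through
any closed voxel surface is machine-zero up to the solver residual.

Distances enter in mm (NIfTI convention); conductances are converted to SI
internally so that potentials are in volts and currents in amperes when the
caller supplies sigma in S/m and currents in A.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import SolverError

_MM = 1e-3  # mm -> m


def face_conductance(sigma: np.ndarray, spacing, axis: int) -> np.ndarray:
    """Harmonic-mean conductance sigma_f * A_f / h (in siemens) for faces along ``axis``.

    Faces between an active (sigma > 0) and an inactive voxel get zero
    conductance, which is exactly the insulating outer boundary condition.
    """
    sl_lo = [slice(None)] * 3
    sl_hi = [slice(None)] * 3
    sl_lo[axis] = slice(None, -1)
    sl_hi[axis] = slice(1, None)
    s1 = sigma[tuple(sl_lo)]
    s2 = sigma[tuple(sl_hi)]
    with np.errstate(divide="ignore", invalid="ignore"):
        hm = np.where((s1 > 0) & (s2 > 0), 2.0 * s1 * s2 / (s1 + s2), 0.0)
    h = spacing[axis] * _MM
    area = _MM**2 * np.prod([spacing[a] for a in range(3) if a != axis])
    return hm * area / h


@dataclass
class GridSystem:
    """Assembled discrete operator for one conductivity field."""

    sigma: np.ndarray
    spacing: tuple[float, float, float]
    active: np.ndarray = field(init=False)
    index: np.ndarray = field(init=False)  # voxel -> unknown id, -1 inactive
    n: int = field(init=False)
    laplacian: sp.csr_matrix = field(init=False)
    _faces: list = field(init=False)

    def __post_init__(self):
        sigma = np.asarray(self.sigma, dtype=float)
        if sigma.ndim != 3:
            raise ValueError("sigma must be a 3-D array")
        self.sigma = sigma
        self.active = sigma > 0
        self.index = np.full(sigma.shape, -1, dtype=np.int64)
        self.n = int(self.active.sum())
        self.index[self.active] = np.arange(self.n)
        rows, cols, vals = [], [], []
        diag = np.zeros(self.n)
        self._faces = []
        for ax in range(3):
            w = face_conductance(sigma, self.spacing, ax)
            sl_lo = [slice(None)] * 3
            sl_hi = [slice(None)] * 3
            sl_lo[ax] = slice(None, -1)
            sl_hi[ax] = slice(1, None)
            i = self.index[tuple(sl_lo)]
            j = self.index[tuple(sl_hi)]
            m = w > 0
            iw, jw, ww = i[m], j[m], w[m]
            rows.append(iw)
            cols.append(jw)
            vals.append(-ww)
            rows.append(jw)
            cols.append(iw)
            vals.append(-ww)
            np.add.at(diag, iw, ww)
            np.add.at(diag, jw, ww)
            self._faces.append((ax, w, m, iw, jw))
        rows.append(np.arange(self.n))
        cols.append(np.arange(self.n))
        vals.append(diag)
        self.laplacian = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n, self.n),
        ).tocsr()

    # -- right-hand sides ------------------------------------------------

    def divergence_of_primary(self, ep_face) -> np.ndarray:
        """RHS vector for div(sigma E_p): per-voxel sum of sigma_f (E_p . n) A_f.

        ``ep_face`` is a callable mapping face-center *voxel-index* coordinates
        (float array (k,3)) and axis -> normal component of E_p (V/m) at those
        faces; sampling the primary field at face centers keeps the source
        term discretely conservative (the vector sums to exactly zero).
        """
        b = np.zeros(self.n)
        for ax, w, m, iw, jw in self._faces:
            lo = np.argwhere(m)  # index of lower voxel of each active face
            centers = lo.astype(float)
            centers[:, ax] += 0.5
            en = ep_face(centers, ax)  # V/m along +axis
            h = self.spacing[ax] * _MM
            flux = w[m] * en * h  # sigma_f * E_n * A_f  (amperes)
            # +flux leaves lower voxel i toward j
            np.add.at(b, iw, -flux)
            np.add.at(b, jw, +flux)
        return b

    # -- solves ----------------------------------------------------------

    def _cg(self, A, b, rtol, maxiter):
        d = A.diagonal()
        Minv = sp.diags(1.0 / d)
        x, info = spla.cg(A, b, rtol=rtol, atol=0.0, M=Minv, maxiter=maxiter)
        res = float(np.linalg.norm(A @ x - b) / max(np.linalg.norm(b), 1e-300))
        if info != 0:
            raise SolverError(f"conjugate gradients did not converge (info={info})", residual=res)
        return x, res

    def solve_neumann(self, b: np.ndarray, rtol: float = 1e-8, maxiter: int = 40000):
        """Solve L phi = b with pure zero-flux boundaries (singular up to a constant).

        The gauge is fixed by pinning one node, then removing the mean; the
        compatibility condition sum(b) = 0 holds exactly for fluxes assembled
        by :meth:`divergence_of_primary`.
        """
        if self.n == 0:
            raise SolverError("empty solve domain")
        pin = 0
        free = np.ones(self.n, dtype=bool)
        free[pin] = False
        A = self.laplacian[free][:, free]
        rhs = b[free]
        x, res = self._cg(A, rhs, rtol, maxiter)
        phi = np.zeros(self.n)
        phi[free] = x
        phi -= phi.mean()
        return phi, res

    def solve_dirichlet(
        self,
        fixed_ids: np.ndarray,
        fixed_vals: np.ndarray,
        b: np.ndarray | None = None,
        rtol: float = 1e-8,
        maxiter: int = 40000,
    ):
        """Solve L phi = b with phi prescribed on ``fixed_ids`` (unknown ids)."""
        free = np.ones(self.n, dtype=bool)
        free[fixed_ids] = False
        xd = np.zeros(self.n)
        xd[fixed_ids] = fixed_vals
        rhs = (b[free] if b is not None else 0.0) - (self.laplacian @ xd)[free]
        A = self.laplacian[free][:, free]
        x, res = self._cg(A, rhs, rtol, maxiter)
        phi = xd.copy()
        phi[free] = x
        return phi, res

    # -- post-processing -------------------------------------------------

    def gradient(self, phi: np.ndarray) -> np.ndarray:
        """Cell-centered grad(phi) in V/m from face differences.

        Each active voxel averages the face gradients of its conductive faces
        (consistent with the discrete operator); voxels with no conductive
        face along an axis get 0 for that component.
        """
        g = np.zeros(self.sigma.shape + (3,))
        cnt = np.zeros(self.sigma.shape + (3,))
        vol = np.full(self.sigma.shape, np.nan)
        vol[self.active] = phi
        for ax, w, m, iw, jw in self._faces:
            h = self.spacing[ax] * _MM
            sl_lo = [slice(None)] * 3
            sl_hi = [slice(None)] * 3
            sl_lo[ax] = slice(None, -1)
            sl_hi[ax] = slice(1, None)
            dif = np.zeros(w.shape)
            lo = vol[tuple(sl_lo)]
            hi = vol[tuple(sl_hi)]
            dif[m] = (hi[m] - lo[m]) / h
            gax = g[..., ax]
            cax = cnt[..., ax]
            gl = gax[tuple(sl_lo)]
            gh = gax[tuple(sl_hi)]
            cl = cax[tuple(sl_lo)]
            ch = cax[tuple(sl_hi)]
            gl[m] += dif[m]
            gh[m] += dif[m]
            cl[m] += 1
            ch[m] += 1
            gax[tuple(sl_lo)] = gl
            gax[tuple(sl_hi)] = gh
            cax[tuple(sl_lo)] = cl
            cax[tuple(sl_hi)] = ch
        with np.errstate(invalid="ignore", divide="ignore"):
            g = np.where(cnt > 0, g / np.maximum(cnt, 1), 0.0)
        g[~self.active] = 0.0
        return g

    def embed(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a per-unknown vector back onto the full grid."""
        out = np.full(self.sigma.shape, fill, dtype=float)
        out[self.active] = values
        return out

    def net_current(self, phi: np.ndarray, voxel_mask: np.ndarray) -> float:
        """Net conduction current (A) leaving the voxel set ``voxel_mask`` through grad(phi).

        Positive when current flows out of the set (J = -sigma grad phi).
        """
        inset = np.zeros(self.n, dtype=bool)
        inset[self.index[voxel_mask & self.active]] = True
        total = 0.0
        for ax, w, m, iw, jw in self._faces:
            ww = w[m]
            in_i = inset[iw]
            in_j = inset[jw]
            cross = in_i ^ in_j
            if not np.any(cross):
                continue
            dphi = phi[jw[cross]] - phi[iw[cross]]  # phi_hi - phi_lo
            wv = ww[cross]
            sign = np.where(in_i[cross], 1.0, -1.0)  # outward from the set
            # J . n_out * A = -w * dphi * sign(lo in set)
            total += float(np.sum(-wv * dphi * sign))
        return total


@dataclass
class FieldSolution:
    """A solved electric field on the model grid.

    Attributes
    ----------
    e_field : (X, Y, Z, 3) array, V/m, zero outside the conductive domain.
    affine : 4x4 voxel-index -> world-mm map of the grid.
    modality : "nTMS" or "DES".
    residual : relative solver residual of the potential solve.
    phi : scalar potential (V) on the grid (NaN outside), when available.
    meta : free-form provenance (electrode voxelization, coil pose, ...).
    """

    e_field: np.ndarray
    affine: np.ndarray
    modality: str
    residual: float
    phi: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.e_field, axis=-1)

    def sample_magnitude(self, voxel_indices: np.ndarray) -> np.ndarray:
        """|E| at integer voxel indices, shape (k, 3) -> (k,)."""
        idx = np.asarray(voxel_indices, dtype=int)
        return self.magnitude[idx[:, 0], idx[:, 1], idx[:, 2]]
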