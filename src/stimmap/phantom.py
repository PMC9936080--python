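"""Layered head phantoms: labeled tissue volumes, conductivities, tumors, surfaces.

The volume-conductor model is a regular voxel grid of tissue labels

    0 background, 1 skin, 2 skull, 3 CSF, 4 grey matter, 5 white matter, 6 tumor

with a NIfTI-style affine carrying voxel indices to world RAS coordinates in
mm.  The stock phantom is a 5-layer concentric sphere (skin, skull, CSF, GM,
WM) — the desk-scale stand-in for a subject-specific head mesh — with
conventional layer radii (92, 86, 80, 78, 70) mm.  Tumors are inserted as
spheres and, per the conductivity rule used for glioma tissue, conduct like
the surrounding grey matter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from nibabel.affines import apply_affine

from .errors import ConfigurationError, GeometryError

log = logging.getLogger(__name__)

BACKGROUND, SKIN, SKULL, CSF, GM, WM, TUMOR = range(7)

LABEL_NAMES = {
    BACKGROUND: "background",
    SKIN: "skin",
    SKULL: "skull",
    CSF: "csf",
    GM: "gm",
    WM: "wm",
    TUMOR: "tumor",
}

#: Isotropic tissue conductivities in S/m; glioma tissue conducts like the
#: surrounding grey matter.
DEFAULT_CONDUCTIVITY = {
    SKIN: 0.465,
    SKULL: 0.010,
    CSF: 1.654,
    GM: 0.2765,
    WM: 0.126,
    TUMOR: 0.2765,
}

#: Outer-to-inner ordering used to decide which neighbours count as "outside"
#: a tissue when extracting boundary surfaces; tumor sits at WM depth.
_DEPTH = {BACKGROUND: 0, SKIN: 1, SKULL: 2, CSF: 3, GM: 4, WM: 5, TUMOR: 5}

DEFAULT_RADII = (92.0, 86.0, 80.0, 78.0, 70.0)


@dataclass
class TissueLabelVolume:
    """Voxel grid of tissue labels with a world-coordinate affine (RAS, mm)."""

    labels: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.labels.ndim != 3 or self.labels.size == 0:
            raise GeometryError("label grid must be non-empty and 3-D")
        bad = set(np.unique(self.labels)) - set(LABEL_NAMES)
        if bad:
            raise GeometryError(f"unknown tissue labels {sorted(bad)}")
        if np.any(self.spacing <= 0):
            raise GeometryError("voxel spacing must be strictly positive")

    @property
    def spacing(self) -> np.ndarray:
        """mm per voxel along each axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def world_coords(self, indices: np.ndarray) -> np.ndarray:
        return apply_affine(self.affine, np.asarray(indices, dtype=float))

    def voxel_indices(self, world: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(self.affine)
        return apply_affine(inv, np.asarray(world, dtype=float))

    def grid_world(self) -> np.ndarray:
        """World coordinates (X, Y, Z, 3) of every voxel center."""
        idx = np.stack(
            np.meshgrid(*[np.arange(s) for s in self.labels.shape], indexing="ij"), axis=-1
        )
        return apply_affine(self.affine, idx)


@dataclass
class SurfacePatch:
    """Boundary faces of a named tissue against strictly outer tissue.

    ``centers`` are face-center world coordinates (mm), ``areas`` face areas
    (mm^2), ``inner_voxels`` the integer indices of the tissue-side voxel of
    every face (used to sample fields on the surface), ``normals`` outward
    unit normals.
    """

    tissue: int
    centers: np.ndarray
    areas: np.ndarray
    inner_voxels: np.ndarray
    normals: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __len__(self) -> int:
        return len(self.areas)

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    def subset(self, mask: np.ndarray) -> "SurfacePatch":
        """The sub-patch selected by a boolean face mask (e.g. a supra-threshold area)."""
        mask = np.asarray(mask, dtype=bool)
        return SurfacePatch(
            self.tissue,
            self.centers[mask],
            self.areas[mask],
            self.inner_voxels[mask],
            self.normals[mask],
            self.affine,
        )


def build_spherical_phantom(
    layer_radii=DEFAULT_RADII, spacing: float = 2.0, margin: float = 4.0
) -> TissueLabelVolume:
    """Build the 5-layer concentric-sphere head phantom.

    ``layer_radii`` are outer radii (mm), outermost first: skin, skull, CSF,
    GM, WM.  Each voxel is labeled by the innermost layer containing its
    center; the rule is pointwise, so construction is deterministic and
    independent of traversal order.
    """
    radii = np.asarray(layer_radii, dtype=float)
    if radii.shape != (5,):
        raise GeometryError("exactly 5 layer radii required (skin, skull, CSF, GM, WM)")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if np.any(np.diff(radii) >= 0):
        raise GeometryError("layer radii must be strictly decreasing outer->inner")
    if np.any(-np.diff(radii) < 2 * spacing):
        # layers thinner than two voxels cannot be resolved reliably
        thin = np.where(-np.diff(radii) < 2 * spacing)[0]
        log.warning("layers %s are thinner than 2 voxels at spacing %.3g mm", thin, spacing)
    half = radii[0] + margin
    n = int(np.ceil(2 * half / spacing)) | 1  # odd count -> a voxel center at the origin
    origin = -spacing * (n - 1) / 2.0
    affine = np.diag([spacing, spacing, spacing, 1.0])
    affine[:3, 3] = origin
    ax = origin + spacing * np.arange(n)
    r2 = ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2
    labels = np.zeros((n, n, n), dtype=np.int16)
    for lab, radius in zip((SKIN, SKULL, CSF, GM, WM), radii):
        labels[r2 <= radius**2] = lab
    return TissueLabelVolume(labels, affine)


def insert_tumor(vol: TissueLabelVolume, center, radius: float) -> TissueLabelVolume:
    """Relabel head voxels within ``radius`` mm of ``center`` (world mm) as tumor.

    Only voxels already inside the head are relabeled, so total head volume is
    conserved.  A tumor that misses the GM/WM compartment entirely is a no-op
    with a warning (the stimulation-relevant tissue is untouched).
    """
    if radius < 0:
        raise ValueError("tumor radius must be non-negative")
    coords = vol.grid_world()
    d2 = np.sum((coords - np.asarray(center, dtype=float)) ** 2, axis=-1)
    inside = d2 < radius**2  # half-open: a zero-radius sphere is empty
    if radius == 0:
        return TissueLabelVolume(vol.labels.copy(), vol.affine.copy())
    head = vol.labels > BACKGROUND
    target = inside & head
    if not np.any(target):
        log.warning("tumor sphere at %s r=%.3g mm lies outside the head; volume unchanged", center, radius)
        return TissueLabelVolume(vol.labels.copy(), vol.affine.copy())
    if not np.any(target & np.isin(vol.labels, (GM, WM))):
        log.warning("tumor sphere does not intersect GM/WM; inserting anyway in outer layers")
    labels = vol.labels.copy()
    labels[target] = TUMOR
    return TissueLabelVolume(labels, vol.affine.copy())


def assign_conductivity(vol: TissueLabelVolume, table: dict | None = None) -> np.ndarray:
    """Scalar sigma field (S/m) on the grid; background gets 0 (outside the solve domain)."""
    table = dict(DEFAULT_CONDUCTIVITY if table is None else table)
    present = set(np.unique(vol.labels)) - {BACKGROUND}
    missing = present - set(table)
    if missing:
        names = ", ".join(LABEL_NAMES.get(m, str(m)) for m in sorted(missing))
        raise ConfigurationError(f"no conductivity for tissue label(s): {names}")
    if any(v <= 0 for v in table.values()):
        raise ConfigurationError("all conductivities must be positive")
    sigma = np.zeros(vol.labels.shape, dtype=float)
    for lab, s in table.items():
        sigma[vol.labels == lab] = s
    return sigma


def extract_surface(vol: TissueLabelVolume, tissue: int = GM) -> SurfacePatch:
    """Boundary faces between ``tissue`` and any strictly outer tissue.

    Every returned face has exactly one tissue-side voxel.  For the grey
    matter this is the surface on which the nTMS/DES field comparison runs.
    """
    if tissue == BACKGROUND:
        raise ValueError("background has no surface")
    if not np.any(vol.labels == tissue):
        log.warning("tissue %s absent from volume; empty patch", LABEL_NAMES.get(tissue))
        z = np.zeros((0, 3))
        return SurfacePatch(tissue, z, np.zeros(0), z.astype(int), z, vol.affine.copy())
    depth = np.vectorize(_DEPTH.get, otypes=[np.int16])(vol.labels)
    want = vol.labels == tissue
    my_depth = _DEPTH[tissue]
    spacing = vol.spacing
    centers, areas, inner, normals = [], [], [], []
    for ax_i in range(3):
        for sign in (-1, +1):
            outer = np.zeros_like(want)
            sl_src = [slice(None)] * 3
            sl_dst = [slice(None)] * 3
            if sign > 0:
                sl_src[ax_i] = slice(1, None)
                sl_dst[ax_i] = slice(None, -1)
            else:
                sl_src[ax_i] = slice(None, -1)
                sl_dst[ax_i] = slice(1, None)
            outer[tuple(sl_dst)] = depth[tuple(sl_src)] < my_depth
            # voxels at the grid edge face the (background) exterior
            edge = [slice(None)] * 3
            edge[ax_i] = -1 if sign > 0 else 0
            outer[tuple(edge)] = True
            faces = want & outer
            if not np.any(faces):
                continue
            idx = np.argwhere(faces)
            fc = idx.astype(float)
            fc[:, ax_i] += 0.5 * sign
            centers.append(apply_affine(vol.affine, fc))
            area = float(np.prod([spacing[a] for a in range(3) if a != ax_i]))
            areas.append(np.full(len(idx), area))
            inner.append(idx)
            nrm = np.zeros((len(idx), 3))
            nrm[:, ax_i] = sign
            normals.append(nrm)
    return SurfacePatch(
        tissue,
        np.concatenate(centers),
        np.concatenate(areas),
        np.concatenate(inner),
        np.concatenate(normals),
        vol.affine.copy(),
    )
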