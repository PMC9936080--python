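"""Hotspot detection, centers of gravity, CoG distances and field-overlap analysis.

A stimulation site is *positive* (a hotspot) when the counting task was
interrupted in at least three consecutive trials at that site.  Positive-site
sets and field maps are reduced to a single center of gravity (CoG):

    CoG = sum_i w_i r_i / sum_i w_i

with uniform weights for plain site lists and |E|-weights for field maps on
the grey-matter surface.  The agreement metrics between the two modalities
are the Euclidean CoG distance and the percentage of the nTMS stimulation
area (half-max isocontour of |E_nTMS| on the GM surface) that falls within
the DES stimulation area.  By default the DES stimulation area is the
DES-determined region of interest — a disc on the GM surface around the DES
CoG — because the near-electrode DES field decays like 1/r^2 and its own
half-max isocontour collapses onto a few voxel faces; the literal per-field
half-max comparison restricted to the ROI is available as ``des_mode
="fraction"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    DegenerateWeightError,
    EmptyInputError,
    FrameMismatchError,
    UndefinedOverlapError,
)
from .phantom import SurfacePatch
from .volume_conductor import FieldSolution

log = logging.getLogger(__name__)

INTERRUPTED = "interrupted"
NORMAL = "normal"

TRIAL_COLUMNS = ["site_id", "x", "y", "z", "trial", "outcome", "modality"]


@dataclass
class HotspotSet:
    """Positive stimulation sites of one modality."""

    modality: str
    site_ids: np.ndarray
    coords: np.ndarray  # (n, 3) world mm
    weights: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        self.site_ids = np.asarray(self.site_ids)
        if len(self.coords) and not np.all(np.isfinite(self.coords)):
            raise ValueError("hotspot coordinates must be finite")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if np.any(self.weights <= 0):
                raise ValueError("hotspot weights must be positive")

    def __len__(self) -> int:
        return len(self.coords)


@dataclass
class CoGPoint:
    """Center-of-gravity reduction of a hotspot set or field map."""

    coords: np.ndarray
    modality: str
    frame: str | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("CoG coordinates must be finite")


def has_run_of_interruptions(outcomes, run: int = 3) -> bool:
    """True when the outcome sequence contains >= ``run`` consecutive interruptions."""
    streak = 0
    for o in outcomes:
        streak = streak + 1 if o == INTERRUPTED else 0
        if streak >= run:
            return True
    return False


def detect_hotspots(trials: pd.DataFrame, modality: str | None = None, run: int = 3) -> HotspotSet:
    """Apply the run-of-three positivity rule to a trial table.

    ``trials`` is a long table with columns site_id, x, y, z, trial, outcome,
    modality; trial indices must be consecutive from 1 within each site.
    Sites with fewer than ``run`` trials can never be positive and are logged.
    """
    df = trials
    if modality is not None:
        df = df[df["modality"] == modality]
    if modality is None:
        mods = df["modality"].unique()
        if len(mods) > 1:
            raise ValueError("trial table mixes modalities; pass modality explicitly")
        modality = mods[0] if len(mods) else "unknown"
    ids, coords = [], []
    for site_id, grp in df.groupby("site_id", sort=True):
        grp = grp.sort_values("trial")
        t = grp["trial"].to_numpy()
        if not np.array_equal(t, np.arange(1, len(t) + 1)):
            raise ValueError(f"site {site_id!r}: trial indices must be consecutive from 1")
        if len(grp) < run:
            log.info("site %r has %d < %d trials; cannot be positive", site_id, len(grp), run)
            continue
        if has_run_of_interruptions(grp["outcome"].tolist(), run=run):
            ids.append(site_id)
            coords.append(grp[["x", "y", "z"]].iloc[0].to_numpy(dtype=float))
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    return HotspotSet(modality=modality, site_ids=np.asarray(ids), coords=coords)


def center_of_gravity(
    obj,
    weighting: str = "uniform",
    patch: SurfacePatch | None = None,
    frame: str | None = None,
) -> CoGPoint:
    """CoG of a HotspotSet (uniform/site weights) or of a FieldSolution on a surface.

    For field maps pass ``weighting="magnitude"`` together with the surface
    ``patch``; the weights are |E| sampled at the GM-side voxel of each face.
    """
    if isinstance(obj, HotspotSet):
        if len(obj) == 0:
            raise EmptyInputError("cannot reduce an empty hotspot set")
        if weighting == "uniform" or obj.weights is None:
            w = np.ones(len(obj))
        else:
            w = obj.weights
        return CoGPoint((w[:, None] * obj.coords).sum(0) / w.sum(), obj.modality, frame)
    if isinstance(obj, FieldSolution):
        if patch is None or len(patch) == 0:
            raise EmptyInputError("field CoG needs a non-empty surface patch")
        if weighting == "magnitude":
            w = obj.sample_magnitude(patch.inner_voxels)
        else:
            w = np.ones(len(patch))
        if w.sum() <= 0:
            raise DegenerateWeightError("all field magnitudes vanish on the patch")
        return CoGPoint((w[:, None] * patch.centers).sum(0) / w.sum(), obj.modality, frame)
    raise TypeError(f"cannot compute a CoG of {type(obj).__name__}")


def cog_distance(a: CoGPoint, b: CoGPoint) -> float:
    """Euclidean distance (mm) between two CoG points in the same frame."""
    if a.frame is not None and b.frame is not None and a.frame != b.frame:
        raise FrameMismatchError(f"CoG frames differ: {a.frame!r} vs {b.frame!r}")
    return float(np.linalg.norm(a.coords - b.coords))


@dataclass
class OverlapRule:
    """Threshold construction for the nTMS/DES area comparison.

    ntms_fraction : |E_nTMS| threshold as a fraction of its maximum (half-max
        stimulation area by default); ``ntms_absolute`` (V/m) overrides it.
    des_mode : "roi" (default) — the DES stimulation area is the whole
        DES-determined ROI disc; "fraction" — per-field fractional threshold
        inside the ROI (the symmetric construction); "absolute" — fixed V/m.
    roi_radius : radius (mm) of the DES-determined ROI disc on the surface.
    """

    ntms_fraction: float = 0.5
    ntms_absolute: float | None = None
    des_mode: str = "roi"
    des_fraction: float = 0.5
    des_absolute: float | None = None
    roi_radius: float = 20.0


@dataclass
class OverlapResult:
    percent: float
    ntms_area: float
    overlap_area: float
    roi_area: float
    thresholds: dict


def field_overlap(
    e_ntms: FieldSolution,
    e_des: FieldSolution,
    patch: SurfacePatch,
    roi_center=None,
    rule: OverlapRule | None = None,
) -> OverlapResult:
    """Percentage of the nTMS stimulation area included in the DES stimulation area.

    ``roi_center`` is the DES-determined ROI center (typically the DES hotspot
    CoG or the electrode site); when omitted it is the magnitude-weighted CoG
    of |E_DES| on the patch.  Returns areas in mm^2 alongside the percentage.
    """
    rule = rule or OverlapRule()
    if len(patch) == 0:
        raise EmptyInputError("empty surface patch")
    vn = e_ntms.sample_magnitude(patch.inner_voxels)
    vd = e_des.sample_magnitude(patch.inner_voxels)
    if roi_center is None:
        roi_center = center_of_gravity(e_des, "magnitude", patch).coords
    roi = np.linalg.norm(patch.centers - np.asarray(roi_center, float), axis=1) <= rule.roi_radius
    areas = patch.areas
    if rule.des_mode == "roi":
        thr_n = rule.ntms_absolute if rule.ntms_absolute is not None else rule.ntms_fraction * vn.max()
        num_mask = (vn >= thr_n) & roi
        den_mask = vn >= thr_n
        thr_d = None
    elif rule.des_mode in ("fraction", "absolute"):
        if not np.any(roi):
            raise UndefinedOverlapError("ROI contains no surface faces")
        thr_n = (
            rule.ntms_absolute
            if rule.ntms_absolute is not None
            else rule.ntms_fraction * vn[roi].max()
        )
        thr_d = (
            rule.des_absolute
            if rule.des_mode == "absolute"
            else rule.des_fraction * vd[roi].max()
        )
        den_mask = (vn >= thr_n) & roi
        num_mask = den_mask & (vd >= thr_d)
    else:
        raise ValueError(f"unknown des_mode {rule.des_mode!r}")
    den = float(areas[den_mask].sum())
    if den <= 0:
        raise UndefinedOverlapError("no supra-threshold nTMS area; overlap undefined")
    num = float(areas[num_mask].sum())
    return OverlapResult(
        percent=100.0 * num / den,
        ntms_area=den,
        overlap_area=num,
        roi_area=float(areas[roi].sum()),
        thresholds={"ntms": float(thr_n), "des": None if thr_d is None else float(thr_d)},
    )
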