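"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of (spec, seed) and returns the ground
truth alongside the data, so every pipeline stage has a closed-loop recovery
test: paired nTMS/DES hotspot cohorts with controllable displacement
statistics (defaults match the clinically observed 6.32 +/- 2.6 mm CoG
separation over 9 subjects), per-site stimulation-trial outcome sequences
for the run-of-three positivity rule, diffusion-tensor volumes containing
straight or arc-shaped high-FA corridors standing in for the language
bundles (AF / SLF), and two-group WAB-score samples parameterized by the
reported group summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GeometryError
from .hotspots import INTERRUPTED, NORMAL, TRIAL_COLUMNS, HotspotSet, has_run_of_interruptions
from .tracking import TensorVolume

log = logging.getLogger(__name__)

#: WAB group summaries used as generator defaults: (label, mean, SD, n).
WAB_PREOP = (("ntms", 97.14, 2.56, 9), ("non_ntms", 97.7, 2.5, 7))
WAB_POSTOP = (("ntms", 78.4, 10.4, 9), ("non_ntms", 59.5, 8.8, 7))

#: Observed CoG displacement range (mm) used for a soft plausibility warning.
_DISPLACEMENT_RANGE = (2.2, 9.3)


# ---------------------------------------------------------------------------
# hotspot cohorts
# ---------------------------------------------------------------------------


@dataclass
class CohortSpec:
    """Paired nTMS/DES hotspot cohort parameters.

    Displacement norms are drawn from Normal(mean_mm, sd_mm) truncated at 0;
    one displacement vector per subject, tangent to the surface at the cap
    center, shifts every nTMS site relative to its DES partner, so the
    subject's CoG distance equals the drawn norm exactly.
    """

    n_subjects: int = 9
    sites_per_subject: int = 5
    mean_mm: float = 6.32
    sd_mm: float = 2.6
    surface_radius: float = 78.0
    cap_half_angle_deg: float = 25.0

    def __post_init__(self):
        if self.n_subjects < 1 or self.sites_per_subject < 1:
            raise ValueError("cohort needs at least one subject and one site")
        if self.mean_mm < 0 or self.sd_mm < 0:
            raise ValueError("displacement mean and SD must be non-negative")


@dataclass
class SubjectHotspots:
    """One synthetic subject: paired hotspot sets plus the true displacement."""

    subject_id: int
    des: HotspotSet
    ntms: HotspotSet
    displacement: np.ndarray  # (3,) true nTMS-minus-DES offset, mm


def _truncated_normal(rng, mean, sd, size=None):
    """Normal(mean, sd) truncated at zero, by resampling."""
    if sd == 0:
        return np.full(size if size is not None else (), float(mean))
    out = rng.normal(mean, sd, size=size)
    for _ in range(1000):
        neg = out < 0
        if not np.any(neg):
            break
        out = np.where(neg, rng.normal(mean, sd, size=np.shape(out)), out)
    return np.abs(out)


def gen_hotspot_cohort(spec: CohortSpec, seed: int = 0) -> list[SubjectHotspots]:
    """Generate per-subject paired hotspot sets on the phantom GM surface cap.

    DES sites are placed uniformly on the upper spherical cap (around +z) of
    radius ``surface_radius``; nTMS sites are the DES sites shifted by the
    subject's displacement vector, drawn in the tangent plane at the cap
    center with truncated-normal norm.  Ground-truth displacements are
    returned with the data.
    """
    rng = np.random.default_rng(seed)
    cap = np.deg2rad(spec.cap_half_angle_deg)
    subjects = []
    for sid in range(spec.n_subjects):
        # uniform on the cap: cos(theta) uniform in [cos(cap), 1]
        u = rng.uniform(np.cos(cap), 1.0, size=spec.sites_per_subject)
        theta = np.arccos(u)
        phi = rng.uniform(0, 2 * np.pi, size=spec.sites_per_subject)
        des_sites = spec.surface_radius * np.stack(
            [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)], axis=1
        )
        norm = float(_truncated_normal(rng, spec.mean_mm, spec.sd_mm))
        if norm > 0 and not _DISPLACEMENT_RANGE[0] <= norm <= _DISPLACEMENT_RANGE[1]:
            log.debug("subject %d displacement %.2f mm outside the observed range %s", sid, norm, _DISPLACEMENT_RANGE)
        ang = rng.uniform(0, 2 * np.pi)
        disp = norm * np.array([np.cos(ang), np.sin(ang), 0.0])  # tangent at the cap center (+z)
        ids = np.arange(1, spec.sites_per_subject + 1)
        subjects.append(
            SubjectHotspots(
                subject_id=sid,
                des=HotspotSet("DES", ids, des_sites),
                ntms=HotspotSet("nTMS", ids, des_sites + disp),
                displacement=disp,
            )
        )
    return subjects


# ---------------------------------------------------------------------------
# stimulation trial records
# ---------------------------------------------------------------------------


def gen_trial_records(
    sites: np.ndarray,
    p_interrupt,
    n_trials: int = 5,
    modality: str = "DES",
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Bernoulli trial-outcome sequences per site, plus run-of-3 ground truth.

    ``sites`` is an (n, 3) array of site coordinates; ``p_interrupt`` a scalar
    or per-site probability of an interrupted trial.  Returns the long trial
    table and the boolean ground-truth positivity of each site.
    """
    sites = np.atleast_2d(np.asarray(sites, dtype=float))
    p = np.broadcast_to(np.asarray(p_interrupt, dtype=float), (len(sites),))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("interruption probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    truth = np.zeros(len(sites), dtype=bool)
    for i, (xyz, pi) in enumerate(zip(sites, p)):
        outcomes = rng.random(n_trials) < pi
        truth[i] = has_run_of_interruptions(
            [INTERRUPTED if o else NORMAL for o in outcomes]
        )
        for t, o in enumerate(outcomes, start=1):
            rows.append((i + 1, *xyz, t, INTERRUPTED if o else NORMAL, modality))
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS), truth


# ---------------------------------------------------------------------------
# tensor bundles
# ---------------------------------------------------------------------------


@dataclass
class BundleSpec:
    """A synthetic white-matter bundle in an otherwise low-FA background.

    kind : "straight" (length ``length`` along +x) or "arc" (quarter circle
        of radius ``arc_radius`` in the xy plane).
    corridor_radius : tube radius (mm) of the high-FA corridor.
    fa_inside / fa_background : FA targets; inside must exceed the tracking
        threshold, background stay below it.  Background 0 means exactly
        isotropic tensors.
    mean_diffusivity : trace/3 of every tensor (mm^2/s).
    """

    kind: str = "straight"
    length: float = 60.0
    arc_radius: float = 40.0
    corridor_radius: float = 4.0
    fa_inside: float = 0.8
    fa_background: float = 0.05
    spacing: float = 2.0
    margin: float = 10.0
    mean_diffusivity: float = 0.7e-3

    def __post_init__(self):
        if self.kind not in ("straight", "arc"):
            raise GeometryError(f"unknown bundle kind {self.kind!r}")
        if not 0 <= self.fa_inside <= 1 or not 0 <= self.fa_background <= 1:
            raise GeometryError("FA targets must lie in [0, 1]")
        if self.fa_background >= self.fa_inside:
            raise GeometryError("background FA must stay below the corridor FA")
        if self.corridor_radius < self.spacing:
            raise GeometryError("corridor radius must be at least one voxel")


def eigenvalues_for_fa(fa: float, md: float) -> tuple[float, float]:
    """(axial, radial) eigenvalues of a cigar tensor with given FA and mean diffusivity.

    Inverts FA = sqrt(3) c / sqrt(1 + 2 c^2) for lambda_axial = md (1 + 2c),
    lambda_radial = md (1 - c); exact for fa in [0, 1].
    """
    if not 0 <= fa <= 1:
        raise GeometryError(f"FA target {fa} not reachable by a diffusion tensor")
    c = fa / np.sqrt(3.0 - 2.0 * fa**2)
    return md * (1 + 2 * c), md * (1 - c)


def _tensor_six(axial: float, radial: float, t: np.ndarray) -> np.ndarray:
    """Upper-triangular components of radial*I + (axial-radial) t t^T for unit tangents t (n,3)."""
    d = axial - radial
    return np.stack(
        [
            radial + d * t[..., 0] * t[..., 0],
            d * t[..., 0] * t[..., 1],
            d * t[..., 0] * t[..., 2],
            radial + d * t[..., 1] * t[..., 1],
            d * t[..., 1] * t[..., 2],
            radial + d * t[..., 2] * t[..., 2],
        ],
        axis=-1,
    )


def gen_tensor_bundle(spec: BundleSpec, seed: int = 0) -> tuple[TensorVolume, np.ndarray]:
    """Build the bundle volume and return it with the ground-truth centerline.

    Inside the corridor, cigar tensors align with the local centerline
    tangent at the requested FA; outside, tensors are isotropic (or weakly
    anisotropic with seeded random axes when ``fa_background`` > 0).  The
    centerline is returned as a polyline of world-mm points.
    """
    m = spec.margin
    if spec.kind == "straight":
        lo = np.array([-m, -m - spec.corridor_radius, -m - spec.corridor_radius])
        hi = np.array([spec.length + m, m + spec.corridor_radius, m + spec.corridor_radius])
        s_line = np.linspace(0, spec.length, 201)
        centerline = np.stack([s_line, np.zeros_like(s_line), np.zeros_like(s_line)], axis=1)
    else:
        R = spec.arc_radius
        lo = np.array([-m, -m, -m - spec.corridor_radius])
        hi = np.array([R + m, R + m, m + spec.corridor_radius])
        ang = np.linspace(0, np.pi / 2, 401)
        centerline = np.stack([R * np.cos(ang), R * np.sin(ang), np.zeros_like(ang)], axis=1)
    n = np.ceil((hi - lo) / spec.spacing).astype(int) + 1
    affine = np.diag([spec.spacing] * 3 + [1.0])
    affine[:3, 3] = lo
    ax = [lo[k] + spec.spacing * np.arange(n[k]) for k in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")

    # corridors are flat-ended tubes (no spherical end caps) with half-open
    # extent along the centerline, so the tracked length matches the nominal
    # centerline length up to the interpolation ramp at the ends
    if spec.kind == "straight":
        t_hat = np.zeros(tuple(n) + (3,))
        t_hat[..., 0] = 1.0
        dist = np.sqrt(Y**2 + Z**2)
        along = (X >= 0.0) & (X < spec.length)
    else:
        R = spec.arc_radius
        rho = np.sqrt(X**2 + Y**2)
        phi = np.arctan2(Y, X)
        dist = np.sqrt((rho - R) ** 2 + Z**2)
        along = (phi >= 0.0) & (phi < np.pi / 2)
        phi_c = np.clip(phi, 0.0, np.pi / 2)
        t_hat = np.stack([-np.sin(phi_c), np.cos(phi_c), np.zeros_like(X)], axis=-1)

    inside = along & (dist <= spec.corridor_radius)
    ax_in, rad_in = eigenvalues_for_fa(spec.fa_inside, spec.mean_diffusivity)
    data = np.empty(tuple(n) + (6,))
    if spec.fa_background == 0:
        iso = spec.mean_diffusivity
        data[...] = np.array([iso, 0, 0, iso, 0, iso])
    else:
        rng = np.random.default_rng(seed)
        v = rng.normal(size=tuple(n) + (3,))
        v /= np.linalg.norm(v, axis=-1, keepdims=True)
        ax_bg, rad_bg = eigenvalues_for_fa(spec.fa_background, spec.mean_diffusivity)
        data[...] = _tensor_six(ax_bg, rad_bg, v)
    data[inside] = _tensor_six(ax_in, rad_in, t_hat[inside])
    return TensorVolume(data, affine), centerline


# ---------------------------------------------------------------------------
# outcome scores
# ---------------------------------------------------------------------------


@dataclass
class OutcomeSpec:
    """Per-group (label, mean, SD, n) parameters for WAB-score generation."""

    groups: tuple = WAB_POSTOP
    clamp: bool = False  # clamp to the [0, 100] WAB scale when True

    def __post_init__(self):
        for label, mean, sd, n in self.groups:
            if sd < 0 or n < 2:
                raise ValueError(f"group {label!r}: need SD >= 0 and n >= 2")


def gen_outcome_scores(spec: OutcomeSpec, seed: int = 0) -> dict[str, np.ndarray]:
    """Seed-reproducible Normal draws per group; optional clamp to the WAB scale."""
    rng = np.random.default_rng(seed)
    out = {}
    for label, mean, sd, n in spec.groups:
        x = rng.normal(mean, sd, size=n)
        if spec.clamp:
            x = np.clip(x, 0.0, 100.0)
        out[label] = x
    return out
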