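"""Synthetic single-cell populations with planted morphological structure.

The generator emulates the study design of an image-based profiling
experiment on an airway epithelial line exposed to particulate-matter
(PM) mixtures: a panel of morphological subtypes spanning size and
elongation gradients, hierarchically organized into three cluster-groups
(CG1 large "healthy", CG2 intermediate/elongated, CG3 small/round,
high-damage), condition-dependent redistribution among subtypes, a
subtype-linked DNA-damage (γH2AX) level, and clone panels with planted
dose-response shift profiles that define a known susceptibility
ordering.

Cells are modeled as rasterized ellipses perturbed by a low-order radial
harmonic (which controls solidity), with concentric, centroid-jittered
elliptical nuclei.  Populations can be emitted either as per-cell
feature tables (closed-form geometry, fast) or as labeled mask images
(rasterized, for exercising the morphometry stage); both routes draw
from the same latent shape variables so their subtype means agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

from .features import FEATURE_NAMES, GH2AX_COL

N_CG = 3
#: Radial harmonic orders of the boundary perturbation.  Cells get a
#: three-lobed outline; nuclei a six-lobed gentle ruffle.  A low order
#: stays convex below amplitude 1/(m^2-1), so the same target solidity
#: needs a much smaller amplitude at order 6 — keeping nuclei compact so
#: their moment-based shape readouts stay unbiased and they fit inside
#: their cell.
M_CELL = 3
M_NUCLEUS = 6
DEFAULT_FIELD_SHAPE = (2048, 2048)
_BOUNDARY_POINTS = 256


class PlacementError(RuntimeError):
    """Requested cell density exceeds field capacity."""


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubtypeSpec:
    """One planted morphological subtype.

    Means are targets for the *final* shape (after the harmonic
    perturbation); CVs are coefficients of variation of the cell-level
    draws.
    """

    subtype_id: int
    cg_id: int
    cell_area_mean: float  # px^2
    cell_area_cv: float
    aspect_ratio_mean: float  # >= 1
    aspect_ratio_cv: float
    solidity_mean: float  # in (0, 1]
    nucleus_area_fraction: float  # in (0, 1)
    gh2ax_mean: float  # in [0, 1]
    gh2ax_sd: float
    # optional nucleus/placement shape axes (defaults mimic a typical
    # epithelial nucleus: mildly elongated with the cell, high solidity,
    # slightly off-center)
    nucleus_aspect_ratio_mean: float | None = None  # None: 1.1 + 0.35(AR-1)
    nucleus_solidity_mean: float = 0.97
    centroid_offset_scale: float = 0.05  # fraction of cell eq. diameter

    def __post_init__(self) -> None:
        if self.cell_area_mean <= 0:
            raise ValueError("cell_area_mean must be positive")
        if self.aspect_ratio_mean < 1:
            raise ValueError("aspect_ratio_mean must be >= 1")
        if not 0 < self.solidity_mean <= 1:
            raise ValueError("solidity_mean must be in (0, 1]")
        if not 0 < self.nucleus_area_fraction < 1:
            raise ValueError("nucleus_area_fraction must be in (0, 1)")
        if not 0 <= self.gh2ax_mean <= 1:
            raise ValueError("gh2ax_mean must be in [0, 1]")
        if self.cg_id not in range(1, N_CG + 1):
            raise ValueError(f"cg_id must be in 1..{N_CG}")


@dataclass(frozen=True)
class ConditionSpec:
    """One exposure condition: a mixture over subtypes."""

    condition_id: str
    dose_level: str  # {"control", "low", "high"}
    subtype_fractions: tuple[float, ...]

    def __post_init__(self) -> None:
        fr = np.asarray(self.subtype_fractions, dtype=float)
        if (fr < 0).any():
            raise ValueError("subtype fractions must be nonnegative")
        if abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError(f"subtype fractions sum to {fr.sum()}, not 1")
        if self.dose_level not in ("control", "low", "high"):
            raise ValueError("dose_level must be control/low/high")


@dataclass(frozen=True)
class ClonePanelSpec:
    """A clonal population with a planted dose-response shift profile.

    ``baseline_cg_bias`` is the clone's resting composition over the 3
    cluster-groups; ``shift_profile`` = (a, b) are the CG1-fraction
    drops at control→low and low→high dose.  The planted susceptibility
    score is (a − b)/(a + b).
    """

    clone_id: str
    baseline_cg_bias: tuple[float, float, float]
    shift_profile: tuple[float, float]

    def __post_init__(self) -> None:
        bias = np.asarray(self.baseline_cg_bias, dtype=float)
        if (bias < 0).any() or abs(bias.sum() - 1.0) > 1e-9:
            raise ValueError("baseline_cg_bias must be a 3-simplex point")
        a, b = self.shift_profile
        if a < 0 or b < 0:
            raise ValueError("shift_profile entries must be nonnegative")
        if a + b > bias[0] + 1e-12:
            raise ValueError("total CG1 shift a+b exceeds baseline CG1 fraction")

    @property
    def planted_score(self) -> float:
        a, b = self.shift_profile
        return (a - b) / (a + b)

    @property
    def cg1_truth(self) -> tuple[float, float, float]:
        c = self.baseline_cg_bias[0]
        a, b = self.shift_profile
        return (c, c - a, c - a - b)


# ---------------------------------------------------------------------------
# default study design
# ---------------------------------------------------------------------------


def default_subtypes() -> list[SubtypeSpec]:
    """Ten morphological archetypes in three cluster-groups.

    CG1 (subtypes 1, 2, 5): the largest cells, low damage.  CG2 (3, 4,
    6): intermediate, elongated; subtype 4 carries the lowest damage.
    CG3 (7-10): the smallest cells, rounder overall; subtypes 9 and 10
    carry the highest damage.  Cell area decreases strictly with the
    subtype id, so after size-ordered renumbering cluster i recovers
    subtype i.

    The archetypes differ along seven latent shape axes (size, cell
    elongation and solidity, nucleus size fraction, nucleus elongation
    and solidity, nucleus off-centering) so that, after log/z
    normalization, the ten subtype centroids are spread in many
    directions of feature space at comparable separations — each
    archetype is a genuinely distinct morphology rather than a step on
    a single size gradient — while subtypes within a cluster-group stay
    mutually closer than subtypes across groups.
    """
    rows = [
        # id cg  area  a_cv   AR  ar_cv    sol      nucf  gmean  gsd    nucAR     nsol      off
        (1, 1, 2900.0, 0.05, 1.4, 0.05, 0.985000, 0.306716, 0.1, 0.03, 1.550621, 0.977208, 0.042907),
        (2, 1, 2650.0, 0.05, 1.5, 0.05, 0.985000, 0.400000, 0.12, 0.03, 1.050000, 0.949929, 0.085466),
        (3, 2, 2430.0, 0.05, 1.75, 0.05, 0.889728, 0.400000, 0.22, 0.05, 2.200000, 0.958820, 0.031369),
        (4, 2, 2230.0, 0.05, 2.05, 0.05, 0.944728, 0.399349, 0.08, 0.02, 1.800000, 0.916297, 0.062884),
        (5, 1, 2040.0, 0.05, 1.32, 0.05, 0.933912, 0.346174, 0.11, 0.03, 1.114072, 0.973238, 0.102877),
        (6, 2, 1870.0, 0.05, 1.9, 0.05, 0.889728, 0.343010, 0.2, 0.05, 1.751201, 0.936728, 0.073960),
        (7, 3, 1715.0, 0.05, 1.25, 0.05, 0.921796, 0.400000, 0.35, 0.06, 1.571000, 0.983870, 0.056411),
        (8, 3, 1570.0, 0.05, 1.62, 0.05, 0.974000, 0.379420, 0.4, 0.06, 1.492388, 0.926556, 0.084291),
        (9, 3, 1440.0, 0.05, 1.18, 0.05, 0.911273, 0.400000, 0.62, 0.08, 1.921000, 0.949482, 0.082284),
        (10, 3, 1320.0, 0.05, 1.12, 0.05, 0.979000, 0.394492, 0.7, 0.08, 1.588156, 0.957648, 0.055809),
    ]
    return [
        SubtypeSpec(
            *r[:10],
            nucleus_aspect_ratio_mean=r[10],
            nucleus_solidity_mean=r[11],
            centroid_offset_scale=r[12],
        )
        for r in rows
    ]


_DEFAULT_CONTROL_FRACTIONS = (
    0.14, 0.12, 0.08, 0.07, 0.12, 0.09, 0.10, 0.08, 0.11, 0.09,
)


def default_conditions() -> list[ConditionSpec]:
    """Five exposure conditions with PM-composition-dependent shifts.

    High-dose urban/fine conditions redistribute toward the small round
    subtypes (9, 10); the high-dose diesel-like condition toward the
    larger elongated subtypes (4, 8).
    """
    return [
        ConditionSpec("control", "control", _DEFAULT_CONTROL_FRACTIONS),
        ConditionSpec(
            "urban_low", "low",
            (0.11, 0.10, 0.08, 0.06, 0.10, 0.08, 0.11, 0.09, 0.14, 0.13),
        ),
        ConditionSpec(
            "urban_high", "high",
            (0.05, 0.05, 0.06, 0.04, 0.05, 0.05, 0.11, 0.09, 0.26, 0.24),
        ),
        ConditionSpec(
            "fine_high", "high",
            (0.06, 0.06, 0.06, 0.05, 0.06, 0.06, 0.11, 0.10, 0.23, 0.21),
        ),
        ConditionSpec(
            "diesel_high", "high",
            (0.09, 0.08, 0.10, 0.18, 0.08, 0.12, 0.08, 0.17, 0.05, 0.05),
        ),
    ]


def default_cg_map() -> dict[int, int]:
    return {s.subtype_id: s.cg_id for s in default_subtypes()}


# ---------------------------------------------------------------------------
# harmonic-amplitude calibration
# ---------------------------------------------------------------------------


@lru_cache(maxsize=4)
def _harmonic_table(order: int) -> dict[str, np.ndarray]:
    """Geometry of the unit circle perturbed by r = 1 + a*cos(order*phi).

    Tabulates solidity (plus perimeter and caliper inflation, kept for
    diagnostics) over a dense amplitude grid.  Its inverse translates a
    target solidity into the harmonic amplitude used by both the feature
    and the mask generation routes.
    """
    phis = np.linspace(0, 2 * np.pi, 1024, endpoint=False)
    alphas = np.linspace(0.0, 0.35, 141)
    sol = np.empty_like(alphas)
    perim = np.empty_like(alphas)
    fmax = np.empty_like(alphas)
    fmin = np.empty_like(alphas)
    for i, a in enumerate(alphas):
        r = 1.0 + a * np.cos(order * phis)
        x, y = r * np.cos(phis), r * np.sin(phis)
        area = 0.5 * np.abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        seg = np.hypot(np.diff(np.append(x, x[0])), np.diff(np.append(y, y[0])))
        pts = np.stack([x, y], axis=1)
        hull = ConvexHull(pts)
        v = pts[hull.vertices]
        edges = np.roll(v, -1, axis=0) - v
        ln = np.hypot(edges[:, 0], edges[:, 1])
        normals = np.stack([-edges[:, 1], edges[:, 0]], axis=1) / ln[:, None]
        proj = v @ normals.T
        widths = proj.max(0) - proj.min(0)
        d2 = ((v[:, None] - v[None, :]) ** 2).sum(-1)
        sol[i] = area / hull.volume  # 2-D hull "volume" is its area
        perim[i] = seg.sum() / (2 * np.pi)
        fmax[i] = np.sqrt(d2.max()) / 2.0
        fmin[i] = widths.min() / 2.0
    return {"alpha": alphas, "solidity": sol, "perimeter": perim,
            "feret_max": fmax, "feret_min": fmin}


def alpha_for_solidity(s: np.ndarray | float, order: int = M_CELL) -> np.ndarray:
    """Harmonic amplitude producing target solidity ``s`` (clipped to the
    calibrated range)."""
    t = _harmonic_table(order)
    # solidity decreases monotonically with alpha
    return np.interp(np.clip(s, t["solidity"].min(), 1.0),
                     t["solidity"][::-1], t["alpha"][::-1])




# ---------------------------------------------------------------------------
# latent shape variables
# ---------------------------------------------------------------------------


def _lognormal(rng: np.random.Generator, mean: float, cv: float, n: int) -> np.ndarray:
    if cv <= 0:
        return np.full(n, mean)
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), n)


def _sample_latents(spec: SubtypeSpec, n: int, rng: np.random.Generator) -> dict:
    """Per-cell latent shape variables for one subtype."""
    area = _lognormal(rng, spec.cell_area_mean, spec.cell_area_cv, n)
    # aspect ratio >= 1 guaranteed: multiplicative noise on the excess
    if spec.aspect_ratio_mean > 1:
        ar = 1.0 + _lognormal(
            rng, spec.aspect_ratio_mean - 1.0, spec.aspect_ratio_cv, n
        )
    else:
        ar = 1.0 + rng.uniform(0.0, 0.02, n)  # nominally round cells
    solidity = np.clip(
        rng.normal(spec.solidity_mean, 0.010, n), 0.80, 0.995
    )
    nucfrac = np.clip(
        rng.normal(
            spec.nucleus_area_fraction, 0.07 * spec.nucleus_area_fraction, n
        ),
        0.03,
        0.85,
    )
    if spec.nucleus_aspect_ratio_mean is None:
        nuc_ar = 1.10 + 0.35 * (ar - 1.0)  # mildly elongated with the cell
    else:
        nuc_ar = 1.0 + _lognormal(
            rng, spec.nucleus_aspect_ratio_mean - 1.0, spec.aspect_ratio_cv, n
        )
    nuc_solidity = np.clip(
        rng.normal(spec.nucleus_solidity_mean, 0.008, n), 0.88, 0.995
    )
    theta = rng.uniform(0, np.pi, n)
    nuc_theta = theta + rng.normal(0, 0.2, n)
    offset_angle = rng.uniform(0, 2 * np.pi, n)
    # nucleus off-center by a subtype-specific fraction of the diameter
    offset_raw = rng.rayleigh(spec.centroid_offset_scale, n)
    phase = rng.uniform(0, 2 * np.pi, n)
    nuc_phase = rng.uniform(0, 2 * np.pi, n)
    gh2ax = np.clip(rng.normal(spec.gh2ax_mean, spec.gh2ax_sd, n), 0.0, 1.0)
    # width-fit: a nucleus wider than the cell's worst-case inner width
    # (inward harmonic lobes included) would be truncated when rendered,
    # distorting its shape readouts; shrink such nuclei so they fit.
    # Deterministic in the latents, hence identical in both routes.
    alpha_c = alpha_for_solidity(solidity)
    alpha_n = alpha_for_solidity(nuc_solidity, M_NUCLEUS)
    b_c = np.sqrt(area / (np.pi * ar)) * (1 - alpha_c)
    b_n = np.sqrt(area * nucfrac / (np.pi * nuc_ar)) * (1 + alpha_n)
    fit = np.minimum(1.0, 0.95 * b_c / b_n)
    nucfrac = nucfrac * fit**2
    return {
        "area": area, "ar": ar, "solidity": solidity, "nucfrac": nucfrac,
        "nuc_ar": nuc_ar, "nuc_solidity": nuc_solidity, "theta": theta,
        "nuc_theta": nuc_theta, "offset_angle": offset_angle,
        "offset_raw": offset_raw, "phase": phase, "nuc_phase": nuc_phase,
        "gh2ax": gh2ax,
    }


def _resolve_displacement(lat: dict) -> np.ndarray:
    """Nucleus centroid displacement in px, capped so the nucleus stays
    inside the cell; identical rule in both generation routes.

    The nucleus is displaced along the cell's major axis (where an
    elongated cell has room), capped at 80% of the free run between the
    nucleus and cell tips.
    """
    a_c = np.sqrt(lat["area"] * lat["ar"] / np.pi)
    alpha_c = alpha_for_solidity(lat["solidity"])
    nuc_area = lat["area"] * lat["nucfrac"]
    a_n = np.sqrt(nuc_area * lat["nuc_ar"] / np.pi)
    alpha_n = alpha_for_solidity(lat["nuc_solidity"], M_NUCLEUS)
    eqd = 2 * np.sqrt(lat["area"] / np.pi)
    cap = np.maximum(0.0, 0.8 * (a_c * (1 - alpha_c) - a_n * (1 + alpha_n)))
    return np.minimum(lat["offset_raw"] * eqd, cap)


_FERET_DIRECTIONS = np.stack(
    [
        np.cos(np.linspace(0, np.pi, 64, endpoint=False)),
        np.sin(np.linspace(0, np.pi, 64, endpoint=False)),
    ],
    axis=1,
)


def _polygon_geometry(
    a: np.ndarray,
    b: np.ndarray,
    alpha: np.ndarray,
    theta: np.ndarray,
    phase: np.ndarray,
    order: int = M_CELL,
    n_points: int = 128,
    chunk: int = 1024,
) -> dict[str, np.ndarray]:
    """Perimeter, bounding box, and Feret calipers of the
    harmonic-perturbed ellipse boundary, vectorized over cells.

    Evaluates exactly the boundary the mask route rasterizes, so
    polygon-derived features agree between the two generation routes.
    """
    n = len(a)
    out = {k: np.empty(n) for k in
           ("perimeter", "bbox_h", "bbox_w", "feret_max", "feret_min")}
    phis = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    for lo in range(0, n, chunk):
        sl = slice(lo, min(lo + chunk, n))
        a_, b_, al = a[sl, None], b[sl, None], alpha[sl, None]
        r_ell = a_ * b_ / np.sqrt(
            (b_ * np.cos(phis)) ** 2 + (a_ * np.sin(phis)) ** 2
        )
        scale = 1.0 / np.sqrt(1.0 + al**2 / 2.0)
        r = scale * r_ell * (1.0 + al * np.cos(order * phis + phase[sl, None]))
        x = r * np.cos(phis)
        y = r * np.sin(phis)
        th = theta[sl, None]
        rot_r = x * np.sin(th) + y * np.cos(th)
        rot_c = x * np.cos(th) - y * np.sin(th)
        dr = np.diff(rot_r, axis=1, append=rot_r[:, :1])
        dc = np.diff(rot_c, axis=1, append=rot_c[:, :1])
        out["perimeter"][sl] = np.hypot(dr, dc).sum(axis=1)
        out["bbox_h"][sl] = rot_r.max(axis=1) - rot_r.min(axis=1)
        out["bbox_w"][sl] = rot_c.max(axis=1) - rot_c.min(axis=1)
        # caliper widths over a half-circle of directions
        proj = (
            rot_r[:, :, None] * _FERET_DIRECTIONS[None, None, :, 0]
            + rot_c[:, :, None] * _FERET_DIRECTIONS[None, None, :, 1]
        )
        widths = proj.max(axis=1) - proj.min(axis=1)
        out["feret_max"][sl] = widths.max(axis=1)
        out["feret_min"][sl] = widths.min(axis=1)
    return out


def _polygon_centroid(poly_r: np.ndarray, poly_c: np.ndarray) -> np.ndarray:
    """Shoelace centroid of a closed polygon given as coordinate arrays."""
    x, y = poly_c, poly_r
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    area = cross.sum() / 2.0
    cx = ((x + x1) * cross).sum() / (6.0 * area)
    cy = ((y + y1) * cross).sum() / (6.0 * area)
    return np.array([cy, cx])


def _features_from_latents(lat: dict) -> pd.DataFrame:
    """Closed-form 33-feature table from latent shape variables."""
    A, AR, s = lat["area"], lat["ar"], lat["solidity"]
    a = np.sqrt(A * AR / np.pi)
    b = np.sqrt(A / (np.pi * AR))
    alpha = alpha_for_solidity(s)
    theta = lat["theta"]
    geom = _polygon_geometry(a, b, alpha, theta, lat["phase"])
    perim = geom["perimeter"]
    bw, bh = geom["bbox_w"], geom["bbox_h"]
    out = {}
    ff = 4 * np.pi * A / perim**2
    out["cell_area"] = A
    out["cell_perimeter"] = perim
    out["cell_form_factor"] = ff
    out["cell_eccentricity"] = np.sqrt(1 - 1 / AR**2)
    out["cell_solidity"] = s
    out["cell_extent"] = A / (bw * bh)
    out["cell_major_axis_length"] = 2 * a
    out["cell_minor_axis_length"] = 2 * b
    out["cell_aspect_ratio"] = AR
    out["cell_equivalent_diameter"] = 2 * np.sqrt(A / np.pi)
    out["cell_max_feret"] = geom["feret_max"]
    out["cell_min_feret"] = geom["feret_min"]
    out["cell_compactness"] = 1.0 / ff
    out["cell_convex_area"] = A / s

    An, ARn, sn = A * lat["nucfrac"], lat["nuc_ar"], lat["nuc_solidity"]
    an = np.sqrt(An * ARn / np.pi)
    bn = np.sqrt(An / (np.pi * ARn))
    alpn = alpha_for_solidity(sn, M_NUCLEUS)
    thn = lat["nuc_theta"]
    ngeom = _polygon_geometry(an, bn, alpn, thn, lat["nuc_phase"], order=M_NUCLEUS)
    perimn = ngeom["perimeter"]
    bwn, bhn = ngeom["bbox_w"], ngeom["bbox_h"]
    ffn = 4 * np.pi * An / perimn**2
    out["nucleus_area"] = An
    out["nucleus_perimeter"] = perimn
    out["nucleus_form_factor"] = ffn
    out["nucleus_eccentricity"] = np.sqrt(1 - 1 / ARn**2)
    out["nucleus_solidity"] = sn
    out["nucleus_extent"] = An / (bwn * bhn)
    out["nucleus_major_axis_length"] = 2 * an
    out["nucleus_minor_axis_length"] = 2 * bn
    out["nucleus_aspect_ratio"] = ARn
    out["nucleus_equivalent_diameter"] = 2 * np.sqrt(An / np.pi)
    out["nucleus_max_feret"] = ngeom["feret_max"]
    out["nucleus_min_feret"] = ngeom["feret_min"]
    out["nucleus_compactness"] = 1.0 / ffn
    out["nucleus_convex_area"] = An / sn

    disp = _resolve_displacement(lat)
    out["nucleus_cell_area_ratio"] = lat["nucfrac"]
    out["nucleus_cell_perimeter_ratio"] = perimn / perim
    out["centroid_displacement"] = disp
    out["normalized_centroid_displacement"] = disp / out["cell_equivalent_diameter"]
    out["cytoplasm_area"] = A - An
    df = pd.DataFrame(out)
    return df[list(FEATURE_NAMES)]


# ---------------------------------------------------------------------------
# mask rendering
# ---------------------------------------------------------------------------


def _boundary_polygon(
    center: np.ndarray, a: float, b: float, alpha: float, theta: float,
    phase: float, order: int = M_CELL,
) -> np.ndarray:
    """(row, col) boundary points of a harmonic-perturbed ellipse whose
    final area matches pi*a*b."""
    phis = np.linspace(0, 2 * np.pi, _BOUNDARY_POINTS, endpoint=False)
    r_ell = a * b / np.sqrt((b * np.cos(phis)) ** 2 + (a * np.sin(phis)) ** 2)
    scale = 1.0 / np.sqrt(1.0 + alpha**2 / 2.0)  # harmonic inflates area
    r = scale * r_ell * (1.0 + alpha * np.cos(order * phis + phase))
    x = r * np.cos(phis)
    y = r * np.sin(phis)
    rot_r = x * np.sin(theta) + y * np.cos(theta)
    rot_c = x * np.cos(theta) - y * np.sin(theta)
    # recenter on the shoelace centroid: the harmonic shifts the centroid
    # of elongated shapes, and downstream displacements assume `center`
    # is the shape centroid
    cen = _polygon_centroid(rot_r, rot_c)
    return np.stack(
        [center[0] + rot_r - cen[0], center[1] + rot_c - cen[1]], axis=1
    )


@dataclass
class MaskField:
    """One synthetic imaging field: paired label masks + ground truth."""

    field_id: int
    cell_labels: np.ndarray  # uint16, 0 = background
    nucleus_labels: np.ndarray
    damage: np.ndarray | None  # uint16 intensity, or None
    truth: pd.DataFrame = field(default_factory=pd.DataFrame)


def _render_fields(
    lat: dict,
    subtype_ids: np.ndarray,
    cg_ids: np.ndarray,
    field_shape: tuple[int, int],
    rng: np.random.Generator,
    with_damage: bool,
    bit_depth: int = 16,
) -> list[MaskField]:
    from skimage.draw import polygon as draw_polygon

    n = len(subtype_ids)
    a_c = np.sqrt(lat["area"] * lat["ar"] / np.pi)
    b_c = np.sqrt(lat["area"] / (np.pi * lat["ar"]))
    alpha_c = alpha_for_solidity(lat["solidity"])
    nuc_area = lat["area"] * lat["nucfrac"]
    a_n = np.sqrt(nuc_area * lat["nuc_ar"] / np.pi)
    b_n = np.sqrt(nuc_area / (np.pi * lat["nuc_ar"]))
    alpha_n = alpha_for_solidity(lat["nuc_solidity"], M_NUCLEUS)
    disp = _resolve_displacement(lat)
    r_out = a_c * (1 + alpha_c) + 2.0
    vmax = 2**bit_depth - 1

    H, W = field_shape
    field_area = H * W
    fields: list[MaskField] = []
    order = np.arange(n)  # keep caller order; packing is greedy

    i = 0
    fid = 0
    while i < n:
        cell_lab = np.zeros(field_shape, dtype=np.uint16)
        nuc_lab = np.zeros(field_shape, dtype=np.uint16)
        dmg = np.zeros(field_shape, dtype=np.uint16) if with_damage else None
        centers: list[np.ndarray] = []
        radii: list[float] = []
        rows = []
        label = 0
        used_area = 0.0
        while i < n and used_area < 0.28 * field_area:
            idx = order[i]
            r = r_out[idx]
            if 2 * r + 4 > min(H, W):
                raise PlacementError(
                    f"cell {idx} (radius {r:.0f}px) exceeds field size {field_shape}"
                )
            placed = False
            for _ in range(400):
                c = rng.uniform([r + 1, r + 1], [H - r - 1, W - r - 1])
                if all(
                    np.hypot(*(c - cj)) >= r + rj + 2
                    for cj, rj in zip(centers, radii)
                ):
                    placed = True
                    break
            if not placed:
                if not centers:
                    raise PlacementError("cannot place any cell in an empty field")
                break  # field full; continue on a fresh field
            label += 1
            poly = _boundary_polygon(
                c, a_c[idx], b_c[idx], alpha_c[idx], lat["theta"][idx],
                lat["phase"][idx],
            )
            rr, cc = draw_polygon(poly[:, 0], poly[:, 1], shape=field_shape)
            cell_lab[rr, cc] = label
            # displacement runs along the major axis; random sign
            sign = 1.0 if lat["offset_angle"][idx] < np.pi else -1.0
            th = lat["theta"][idx]
            nc = c + sign * disp[idx] * np.array([np.sin(th), np.cos(th)])
            npoly = _boundary_polygon(
                nc, a_n[idx], b_n[idx], alpha_n[idx], lat["nuc_theta"][idx],
                lat["nuc_phase"][idx], order=M_NUCLEUS,
            )
            nrr, ncc = draw_polygon(npoly[:, 0], npoly[:, 1], shape=field_shape)
            # containment guarantee: clip nucleus to its cell
            keep = cell_lab[nrr, ncc] == label
            nrr, ncc = nrr[keep], ncc[keep]
            nuc_lab[nrr, ncc] = label
            if dmg is not None:
                dmg[nrr, ncc] = int(round(lat["gh2ax"][idx] * vmax))
            centers.append(c)
            radii.append(r)
            used_area += np.pi * r**2
            rows.append(
                {
                    "field_id": fid,
                    "label": label,
                    "subtype_id": int(subtype_ids[idx]),
                    "cg_id": int(cg_ids[idx]),
                    "gh2ax_true": float(lat["gh2ax"][idx]),
                }
            )
            i += 1
        fields.append(
            MaskField(fid, cell_lab, nuc_lab, dmg, pd.DataFrame(rows))
        )
        fid += 1
    return fields


# ---------------------------------------------------------------------------
# population generation
# ---------------------------------------------------------------------------


def generate_population(
    subtypes: list[SubtypeSpec],
    condition: ConditionSpec,
    n_cells: int,
    seed: int,
    output: str = "features",
    field_shape: tuple[int, int] = DEFAULT_FIELD_SHAPE,
    with_damage: bool = True,
    population_id: str = "parental",
) -> pd.DataFrame | list[MaskField]:
    """Draw a population of cells from a subtype mixture.

    With ``output="features"`` returns a feature table (one row per
    cell: 33 morphology columns, γH2AX, metadata, and the ground-truth
    ``subtype_id``/``cg_id``).  With ``output="masks"`` returns a list
    of :class:`MaskField` label-mask images.  Identical arguments and
    seed give identical output.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if len(condition.subtype_fractions) != len(subtypes):
        raise ValueError("condition fractions do not match number of subtypes")
    if output not in ("features", "masks"):
        raise ValueError("output must be 'features' or 'masks'")
    rng = np.random.default_rng(seed)
    fractions = np.asarray(condition.subtype_fractions, dtype=float)
    counts = rng.multinomial(n_cells, fractions)

    lat_parts, sid_parts, cg_parts = [], [], []
    for spec, cnt in zip(subtypes, counts):
        if cnt == 0:
            continue
        lat_parts.append(_sample_latents(spec, cnt, rng))
        sid_parts.append(np.full(cnt, spec.subtype_id))
        cg_parts.append(np.full(cnt, spec.cg_id))
    lat = {k: np.concatenate([p[k] for p in lat_parts]) for k in lat_parts[0]}
    subtype_ids = np.concatenate(sid_parts)
    cg_ids = np.concatenate(cg_parts)
    # shuffle so field packing and row order are not subtype-blocked
    perm = rng.permutation(len(subtype_ids))
    lat = {k: v[perm] for k, v in lat.items()}
    subtype_ids, cg_ids = subtype_ids[perm], cg_ids[perm]

    if output == "masks":
        fields = _render_fields(
            lat, subtype_ids, cg_ids, field_shape, rng, with_damage
        )
        for f in fields:
            f.truth["population_id"] = population_id
            f.truth["condition_id"] = condition.condition_id
            f.truth["dose_level"] = condition.dose_level
        return fields

    df = _features_from_latents(lat)
    df[GH2AX_COL] = lat["gh2ax"]
    df.insert(0, "cell_id", np.arange(len(df)))
    df["subtype_id"] = subtype_ids
    df["cg_id"] = cg_ids
    df["population_id"] = population_id
    df["condition_id"] = condition.condition_id
    df["dose_level"] = condition.dose_level
    return df


def default_fixture(n_cells: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """The default study fixture: 10 subtypes in 3 CGs sampled across the
    five default exposure conditions (equal cells per condition)."""
    subtypes = default_subtypes()
    conditions = default_conditions()
    per = n_cells // len(conditions)
    rests = n_cells - per * len(conditions)
    parts = []
    for j, cond in enumerate(conditions):
        n = per + (1 if j < rests else 0)
        parts.append(
            generate_population(subtypes, cond, n, seed=seed + 1000 + j)
        )
    df = pd.concat(parts, ignore_index=True)
    df["cell_id"] = np.arange(len(df))
    return df


# ---------------------------------------------------------------------------
# clone panels and dose series
# ---------------------------------------------------------------------------


def _within_cg_weights(subtypes: list[SubtypeSpec]) -> dict[int, np.ndarray]:
    """Default control-condition mixture renormalized within each CG."""
    base = np.asarray(_DEFAULT_CONTROL_FRACTIONS[: len(subtypes)], dtype=float)
    base = base / base.sum()
    out = {}
    for cg in range(1, N_CG + 1):
        mask = np.array([s.cg_id == cg for s in subtypes])
        w = np.where(mask, base, 0.0)
        out[cg] = w / w.sum()
    return out


def clone_dose_fractions(
    panel: ClonePanelSpec, subtypes: list[SubtypeSpec] | None = None
) -> dict[str, np.ndarray]:
    """Planted subtype mixtures for a clone at control/low/high dose.

    CG1 loses ``a`` (control→low) then ``b`` (low→high) of the total
    population; the displaced mass redistributes to CG2 (30%) and CG3
    (70%), mimicking the stress shift toward small round morphologies.
    """
    subtypes = subtypes or default_subtypes()
    w = _within_cg_weights(subtypes)
    bias = np.asarray(panel.baseline_cg_bias, dtype=float)
    a, b = panel.shift_profile
    out = {}
    for dose, drop in (("control", 0.0), ("low", a), ("high", a + b)):
        cg_frac = np.array(
            [bias[0] - drop, bias[1] + 0.3 * drop, bias[2] + 0.7 * drop]
        )
        frac = sum(cg_frac[cg - 1] * w[cg] for cg in range(1, N_CG + 1))
        out[dose] = frac
    return out


@dataclass
class CloneSeries:
    """Feature tables of one clone at the three doses, with ground truth."""

    clone_id: str
    tables: dict[str, pd.DataFrame]  # dose -> feature table
    cg1_truth: tuple[float, float, float]
    planted_score: float

    @property
    def table(self) -> pd.DataFrame:
        return pd.concat(self.tables.values(), ignore_index=True)


def generate_condition_series(
    panel: ClonePanelSpec,
    n_cells: int = 2000,
    seed: int = 0,
    subtypes: list[SubtypeSpec] | None = None,
) -> CloneSeries:
    """Generate a clone's control/low/high-dose feature tables.

    The ground-truth CG1 fractions are (c, c−a, c−a−b) for baseline
    CG1 fraction c and shift profile (a, b); realized fractions converge
    to these as ``n_cells`` grows.
    """
    subtypes = subtypes or default_subtypes()
    fracs = clone_dose_fractions(panel, subtypes)
    tables = {}
    for j, (dose, frac) in enumerate(fracs.items()):
        cond = ConditionSpec(f"urban_{dose}", dose, tuple(frac))
        tables[dose] = generate_population(
            subtypes, cond, n_cells, seed=seed + 7919 * (j + 1),
            population_id=panel.clone_id,
        )
    return CloneSeries(
        panel.clone_id, tables, panel.cg1_truth, panel.planted_score
    )


def default_clone_panel() -> list[ClonePanelSpec]:
    """Four clones plus the parental, with strictly ordered planted
    susceptibility scores (a−b)/(a+b)."""
    return [
        ClonePanelSpec("parental", (0.40, 0.32, 0.28), (0.14, 0.14)),  # score 0
        ClonePanelSpec("clone_8", (0.30, 0.45, 0.25), (0.24, 0.04)),  # 0.714
        ClonePanelSpec("clone_1", (0.45, 0.40, 0.15), (0.24, 0.12)),  # 0.333
        ClonePanelSpec("clone_7", (0.60, 0.25, 0.15), (0.10, 0.40)),  # -0.6
        ClonePanelSpec("clone_5", (0.50, 0.30, 0.20), (0.04, 0.40)),  # -0.818
    ]
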