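"""Canonical per-cell feature schema.

The profiling pipeline describes every segmented cell by exactly 33
size/shape parameters: 14 per compartment (cell and nucleus) drawn from
the classic AreaShape family, plus 5 cross-compartment ratios and
displacements.  Orientation is deliberately excluded — every feature is
positive-valued or ratio-bounded so that an elementwise log transform is
well defined.
"""

from __future__ import annotations

#: AreaShape-style parameters computed per compartment.
COMPARTMENT_PARAMS: tuple[str, ...] = (
    "area",
    "perimeter",
    "form_factor",
    "eccentricity",
    "solidity",
    "extent",
    "major_axis_length",
    "minor_axis_length",
    "aspect_ratio",
    "equivalent_diameter",
    "max_feret",
    "min_feret",
    "compactness",
    "convex_area",
)

#: Cross-compartment parameters.
CROSS_PARAMS: tuple[str, ...] = (
    "nucleus_cell_area_ratio",
    "nucleus_cell_perimeter_ratio",
    "centroid_displacement",
    "normalized_centroid_displacement",
    "cytoplasm_area",
)

#: The 33 morphology feature names, in canonical column order.
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{comp}_{p}" for comp in ("cell", "nucleus") for p in COMPARTMENT_PARAMS
) + CROSS_PARAMS

assert len(FEATURE_NAMES) == 33

#: Column name for the damage readout (not one of the 33 shape features).
GH2AX_COL = "gh2ax_mean_nuclear_intensity"

#: Metadata columns carried alongside features where available.
META_COLS = ("field_id", "label", "population_id", "condition_id", "dose_level")

#: Features that may legitimately reach 0 and therefore receive a small
#: offset eps inside log10(x + eps); strictly positive features use eps=0.
_ZERO_REACHING = frozenset(
    {
        "cell_eccentricity",
        "nucleus_eccentricity",
        "centroid_displacement",
        "normalized_centroid_displacement",
        "cytoplasm_area",
    }
)

DEFAULT_EPS = 1e-6


def feature_eps(name: str, eps: float = DEFAULT_EPS) -> float:
    """Offset used for ``name`` in the log transform (0 for strictly
    positive features, ``eps`` for ratio features that may reach 0)."""
    return eps if name in _ZERO_REACHING else 0.0
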