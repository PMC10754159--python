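"""File I/O, pipeline configuration, and dose conversion.

Conventions: masks are 16-bit label TIFFs (0 = background) with matching
labels across the cell and nucleus compartments; all tabular I/O is CSV
with documented headers; configuration is YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .features import FEATURE_NAMES

#: Default exposure geometry, back-computed so that suspension
#: concentrations of 125 and 500 µg/mL correspond to areal depositions
#: of 35.2 and 140.8 µg/cm² over the cell growth area.
DEFAULT_VOLUME_PER_AREA = 0.2816  # mL/cm²


def convert_dose(concentration: float, volume_per_area: float = DEFAULT_VOLUME_PER_AREA) -> float:
    """Suspension concentration (µg/mL) → areal deposition (µg/cm²).

    The areal dose is concentration × medium volume per growth area.
    """
    if concentration < 0 or volume_per_area < 0:
        raise ValueError("concentration and volume_per_area must be nonnegative")
    return concentration * volume_per_area


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Resolved settings for a full pipeline run."""

    seed: int = 0
    n_cells: int = 10_000
    volume_per_area: float = DEFAULT_VOLUME_PER_AREA  # mL/cm²
    log_eps: float = 1e-6
    umap_n_neighbors: int = 30
    umap_min_dist: float = 0.1
    k_range: tuple[int, int] = (2, 20)
    kmeans_n_init: int = 50
    n_groups: int | str = "auto"
    entropy_base: float | None = None  # None = natural log
    bootstrap_reps: int = 0
    parental_id: str = "parental"

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.log_eps < 0:
            raise ValueError("log_eps must be nonnegative")
        lo, hi = self.k_range
        if lo < 2 or hi < lo:
            raise ValueError("k_range must satisfy 2 <= lo <= hi")
        if self.n_groups != "auto" and int(self.n_groups) < 1:
            raise ValueError("n_groups must be 'auto' or a positive integer")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["k_range"] = list(d["k_range"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------


@dataclass
class FieldPaths:
    """TIFF paths of one imaging field."""

    cell: Path
    nucleus: Path
    damage: Path | None = None


def write_mask_field(
    outdir: str | Path,
    field_id: int,
    cell_labels: np.ndarray,
    nucleus_labels: np.ndarray,
    damage: np.ndarray | None = None,
) -> FieldPaths:
    """Write one field's label masks (and damage channel) as 16-bit TIFFs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = FieldPaths(
        outdir / f"field{field_id:03d}_cell.tif",
        outdir / f"field{field_id:03d}_nucleus.tif",
        outdir / f"field{field_id:03d}_damage.tif" if damage is not None else None,
    )
    tifffile.imwrite(paths.cell, cell_labels.astype(np.uint16))
    tifffile.imwrite(paths.nucleus, nucleus_labels.astype(np.uint16))
    if damage is not None:
        tifffile.imwrite(paths.damage, damage.astype(np.uint16))
    return paths


def read_mask_field(paths: FieldPaths) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Read one field's masks; validates dtype and congruent shapes."""
    cell = tifffile.imread(paths.cell)
    nucleus = tifffile.imread(paths.nucleus)
    if not np.issubdtype(cell.dtype, np.integer) or not np.issubdtype(
        nucleus.dtype, np.integer
    ):
        raise ValueError("label masks must be integer-typed")
    if cell.shape != nucleus.shape:
        raise ValueError(
            f"compartment mask shapes differ: {cell.shape} vs {nucleus.shape}"
        )
    damage = None
    if paths.damage is not None:
        damage = tifffile.imread(paths.damage)
        if damage.shape != cell.shape:
            raise ValueError("damage channel shape differs from masks")
    return cell, nucleus, damage


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

REQUIRED_METADATA = ("population_id", "condition_id")


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def read_feature_table(path: str | Path, require_metadata: bool = False) -> pd.DataFrame:
    """Read a per-cell feature CSV and validate the 33-feature schema."""
    table = pd.read_csv(path)
    missing = [f for f in FEATURE_NAMES if f not in table.columns]
    if missing:
        raise ValueError(f"feature columns missing: {missing}")
    if require_metadata:
        meta_missing = [c for c in REQUIRED_METADATA if c not in table.columns]
        if meta_missing:
            raise ValueError(f"metadata columns missing: {meta_missing}")
    return table


def validate_metadata(table: pd.DataFrame, columns=REQUIRED_METADATA) -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise ValueError(f"metadata columns missing: {missing}")
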