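"""Surface-level representation of connectivity maps.

The cortical surface is modeled as a flat table of vertices ("surface
voxels"): each vertex belongs to one hemisphere, one lobar region and
one atlas area, and receives its value from exactly one source voxel of
the volume through a :class:`ProjectionMap` (a voxel may feed several
vertices).  No mesh geometry is involved.

Thresholded maps of the three seeds are combined into an 8-way
exclusive categorization per vertex:

    NONE, A, M, P, AM, MP, AP, AMP

where A/M/P denote connectivity to the anterior/middle/posterior seed,
pairs denote overlap, and AMP denotes overlap of all three.  Categories
carry the conventional additive RGB code (A blue, M green, P red, AM
cyan, MP yellow, AP magenta, AMP white, NONE black).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: category codes in fixed order; index into this tuple is the stored code
CATEGORIES = ("NONE", "A", "M", "P", "AM", "MP", "AP", "AMP")

#: bit pattern (a + 2*m + 4*p) -> category code
_BITS_TO_CODE = np.array([
    CATEGORIES.index("NONE"),   # 000
    CATEGORIES.index("A"),      # 100
    CATEGORIES.index("M"),      # 010
    CATEGORIES.index("AM"),     # 110
    CATEGORIES.index("P"),      # 001
    CATEGORIES.index("AP"),     # 101
    CATEGORIES.index("MP"),     # 011
    CATEGORIES.index("AMP"),    # 111
], dtype=np.int8)

#: additive RGB encoding per category
CATEGORY_RGB = {
    "NONE": (0, 0, 0),
    "A": (0, 0, 255),
    "M": (0, 255, 0),
    "P": (255, 0, 0),
    "AM": (0, 255, 255),
    "MP": (255, 255, 0),
    "AP": (255, 0, 255),
    "AMP": (255, 255, 255),
}

REGIONS = (
    "orbitofrontal", "prefrontal", "motor/premotor", "cingulate",
    "limbic", "temporal", "parietal", "occipital",
)

HEMISPHERES = ("left", "right")


@dataclass
class SurfaceModel:
    """Vertex table: hemisphere -> region -> area hierarchy.

    ``vertices`` is a DataFrame with columns
    ``vertex_id, hemisphere, region, area_id, area_name``; vertex_id is
    the row position (0..n-1).
    """

    vertices: pd.DataFrame

    def __post_init__(self):
        required = {"vertex_id", "hemisphere", "region", "area_id", "area_name"}
        missing = required - set(self.vertices.columns)
        if missing:
            raise ValueError(f"vertex table missing columns {sorted(missing)}")
        if self.vertices["vertex_id"].duplicated().any():
            raise ValueError("duplicate vertex ids")
        per_area = self.vertices.groupby("area_id")["region"].nunique()
        if (per_area > 1).any():
            raise ValueError("an area maps to more than one region")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def hemisphere_mask(self, hemisphere: str) -> np.ndarray:
        return (self.vertices["hemisphere"] == hemisphere).to_numpy()


@dataclass
class ProjectionMap:
    """Voxel-to-vertex assignment.

    ``vertex_source`` maps each vertex (by position) to the row index of
    its unique source voxel in the geometry's in-mask ordering.  The
    inverse direction (voxel -> one or multiple vertices) is implied.
    """

    vertex_source: np.ndarray

    def __post_init__(self):
        self.vertex_source = np.asarray(self.vertex_source, dtype=int)
        if self.vertex_source.ndim != 1:
            raise ValueError("vertex_source must be 1-D")

    @property
    def n_vertices(self) -> int:
        return self.vertex_source.size

    def vertices_of_voxel(self, voxel_row: int) -> np.ndarray:
        return np.flatnonzero(self.vertex_source == voxel_row)


@dataclass
class SurfaceScalarMap:
    """Per-vertex scalar values (NaN = missing), with map provenance."""

    values: np.ndarray
    seed: str | None = None
    hemisphere: str | None = None
    level: str | None = None
    subject_id: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class CategoryMap:
    """Per-vertex 8-way seed-overlap category (codes into CATEGORIES)."""

    category: np.ndarray
    threshold_used: float

    def __post_init__(self):
        self.category = np.asarray(self.category, dtype=np.int8)
        if self.category.min(initial=0) < 0 or self.category.max(initial=0) > 7:
            raise ValueError("category codes must be in 0..7")

    def names(self) -> np.ndarray:
        return np.asarray(CATEGORIES, dtype=object)[self.category]


def project_to_surface(
    volume_values: np.ndarray,
    projection: ProjectionMap,
    surface: SurfaceModel,
    **meta,
) -> SurfaceScalarMap:
    """Copy each voxel's value to all vertices it projects to.

    ``volume_values`` is per in-mask voxel; NaN (missing/contralateral)
    propagates to the vertices of that voxel.
    """
    volume_values = np.asarray(volume_values, dtype=float)
    if projection.n_vertices != surface.n_vertices:
        raise ValueError("projection and surface vertex counts differ")
    if projection.vertex_source.max(initial=-1) >= volume_values.size:
        raise ValueError("projection references voxels outside the volume map")
    values = volume_values[projection.vertex_source]
    n_missing = int(np.isnan(values).sum())
    if n_missing:
        logger.debug("projected map has %d missing vertices", n_missing)
    return SurfaceScalarMap(values=values, **meta)


def threshold_surface(smap: SurfaceScalarMap, z_thr: float = 0.05) -> np.ndarray:
    """Boolean supra-threshold mask: value present and strictly > z_thr."""
    if z_thr <= 0:
        raise ValueError("z_thr must be > 0")
    v = smap.values
    return np.isfinite(v) & (v > z_thr)


def categorize(
    a_bin: np.ndarray,
    m_bin: np.ndarray,
    p_bin: np.ndarray,
    threshold_used: float = 0.05,
) -> CategoryMap:
    """Combine three thresholded seed maps into the 8-way category map."""
    a_bin = np.asarray(a_bin, dtype=bool)
    m_bin = np.asarray(m_bin, dtype=bool)
    p_bin = np.asarray(p_bin, dtype=bool)
    if not (a_bin.shape == m_bin.shape == p_bin.shape):
        raise ValueError("thresholded maps are on different vertex sets")
    bits = a_bin.astype(np.int8) + 2 * m_bin.astype(np.int8) + 4 * p_bin.astype(np.int8)
    return CategoryMap(category=_BITS_TO_CODE[bits], threshold_used=threshold_used)


def rgb_encode(categories: CategoryMap) -> np.ndarray:
    """Per-vertex (r, g, b) uint8 colors for a category map."""
    palette = np.array([CATEGORY_RGB[c] for c in CATEGORIES], dtype=np.uint8)
    return palette[categories.category]


def rgb_hex(categories: CategoryMap) -> np.ndarray:
    """Per-vertex '#rrggbb' strings (for tabular/plotting output)."""
    rgb = rgb_encode(categories)
    return np.array([f"#{r:02x}{g:02x}{b:02x}" for r, g, b in rgb], dtype=object)


def composition(
    categories: CategoryMap,
    surface: SurfaceModel,
    scope: str = "hemisphere",
) -> pd.DataFrame:
    """Category composition (counts and percentages) per scope unit.

    scope: 'hemisphere' | 'region' | 'area'.  Percentages are relative
    to the scope unit's own vertex count (hemisphere-relative for pie
    charts over the whole hemisphere, region-relative when zooming into
    a lobar region).  Empty scope units yield zero counts and NaN
    percentages, flagged in the 'empty' column.
    """
    key_cols = {
        "hemisphere": ["hemisphere"],
        "region": ["hemisphere", "region"],
        "area": ["hemisphere", "region", "area_name"],
    }
    if scope not in key_cols:
        raise ValueError(f"unknown scope {scope!r}")
    cols = key_cols[scope]
    df = surface.vertices[cols].copy()
    df["category"] = categories.names()
    counts = (
        df.groupby(cols + ["category"], observed=False).size().unstack(
            "category", fill_value=0
        )
    )
    for cat in CATEGORIES:
        if cat not in counts.columns:
            counts[cat] = 0
    counts = counts[list(CATEGORIES)]
    total = counts.sum(axis=1)
    pct = counts.div(total.where(total > 0), axis=0) * 100.0
    out = pd.concat(
        {"count": counts, "percent": pct}, axis=1
    ).reset_index()
    out.columns = [
        c[1] if c[0] == "" else f"{c[0]}_{c[1]}" if c[0] in ("count", "percent")
        else c[0]
        for c in out.columns
    ]
    out["total"] = total.to_numpy()
    out["empty"] = out["total"] == 0
    return out


def map_similarity(
    map1: SurfaceScalarMap, map2: SurfaceScalarMap
) -> tuple[float, float, int]:
    """Spearman rank correlation between two surface maps.

    Computed over jointly non-missing vertices with average-rank tie
    handling; returns (rho, two-sided p, n).  Constant maps have an
    undefined rho, returned as NaN.
    """
    both = np.isfinite(map1.values) & np.isfinite(map2.values)
    n = int(both.sum())
    if n < 10:
        raise ValueError(f"only {n} jointly non-missing vertices (need >= 10)")
    x, y = map1.values[both], map2.values[both]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant map: Spearman rho undefined")
        return float("nan"), float("nan"), n
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p), n
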