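"""Atlas-area quantification and seed-comparison statistics.

For every subject, hemisphere, atlas area and seed, the fraction of the
area's vertices whose (significance-masked) connectivity exceeds the
z threshold — the "ratio of connected surface voxels" — and the mean z
over those supra-threshold vertices are tabulated.  Per area, the three
seeds' per-subject ratios are compared with a Kruskal-Wallis test
(tie-corrected, chi-square approximation with 2 df), per hemisphere and
pooled across hemispheres, with Benjamini-Hochberg correction across
areas within each scope.  Significant areas are classified by their
preferred seed (anterior vs posterior).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .connectivity import SEEDS
from .surface import SurfaceModel, SurfaceScalarMap

logger = logging.getLogger(__name__)

SCOPES = ("left", "right", "pooled")

BH_ALPHA = 0.05

#: relative tolerance under which aVIP and pVIP mean ratios count as tied
PREFERENCE_TIE_RTOL = 0.1


def areal_ratios(
    subject_maps: dict[tuple[str, str, str], SurfaceScalarMap],
    surface: SurfaceModel,
    z_thr: float = 0.05,
) -> pd.DataFrame:
    """Connected-vertex ratio and mean z per subject/hemisphere/area/seed.

    ``subject_maps`` maps (subject_id, seed, hemisphere) to the
    subject-level surface map (significance-masked mean z; missing =
    contralateral).  Ratio = fraction of the area's vertices with value
    strictly above ``z_thr``; mean_z is the mean over those vertices
    (NaN when the ratio is 0).  Areas with zero vertices are excluded
    with a log message.
    """
    v = surface.vertices
    rows = []
    for (subject_id, seed, hemisphere), smap in sorted(subject_maps.items()):
        if seed not in SEEDS:
            raise ValueError(f"unknown seed {seed!r}")
        hemi_sel = (v["hemisphere"] == hemisphere).to_numpy()
        values = smap.values
        supra = np.isfinite(values) & (values > z_thr)
        for (area, region), idx in v[hemi_sel].groupby(
            ["area_name", "region"], observed=False
        ).groups.items():
            idx = np.asarray(idx)
            if idx.size == 0:
                logger.info("area %s (%s): no vertices, excluded", area, hemisphere)
                continue
            hit = supra[idx]
            ratio = float(hit.mean())
            mean_z = float(values[idx][hit].mean()) if hit.any() else np.nan
            rows.append(
                {
                    "subject_id": subject_id,
                    "hemisphere": hemisphere,
                    "region": region,
                    "area": area,
                    "seed": seed,
                    "ratio": ratio,
                    "mean_z": mean_z,
                    "n_vertices": int(idx.size),
                }
            )
    return pd.DataFrame(rows)


def group_ratio_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Across-animal mean and SEM of ratios per hemisphere/area/seed."""

    def sem(x):
        x = np.asarray(x, dtype=float)
        return float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else np.nan

    grouped = table.groupby(["hemisphere", "region", "area", "seed"], observed=False)
    out = grouped.agg(
        mean_ratio=("ratio", "mean"),
        sem_ratio=("ratio", sem),
        mean_z=("mean_z", "mean"),
        n_subjects=("subject_id", "nunique"),
    ).reset_index()
    return out


def kruskal_wallis_per_area(
    table: pd.DataFrame, scope: str, alpha: float = BH_ALPHA
) -> pd.DataFrame:
    """Kruskal-Wallis comparison of the three seeds' ratios per area.

    scope 'left'/'right' restricts to one hemisphere (n = n_subjects
    per seed group); 'pooled' concatenates both hemispheres' rows,
    treating left and right observations of one animal as separate
    samples (doubling n).  All-identical values give H = 0, p = 1.
    Benjamini-Hochberg correction is applied across areas within the
    scope; ``significant`` means adjusted p < alpha.
    """
    if scope not in SCOPES:
        raise ValueError(f"scope must be one of {SCOPES}")
    sub = table if scope == "pooled" else table[table["hemisphere"] == scope]
    rows = []
    for area, df in sub.groupby("area", observed=False):
        groups = [
            df.loc[df["seed"] == seed, "ratio"].to_numpy(dtype=float)
            for seed in SEEDS
        ]
        if any(g.size < 3 for g in groups):
            raise ValueError(
                f"area {area}: Kruskal-Wallis needs >= 3 observations per seed"
            )
        pooled_vals = np.concatenate(groups)
        if np.ptp(pooled_vals) == 0:
            h, p = 0.0, 1.0
        else:
            h, p = stats.kruskal(*groups)
        rows.append(
            {"area": area, "scope": scope, "H": float(h), "p_raw": float(p)}
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_correct(out["p_raw"].to_numpy())
    out["significant"] = out["p_adj"] < alpha
    return out


def bh_correct(p_raw: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order)."""
    p_raw = np.asarray(p_raw, dtype=float)
    if p_raw.size == 0:
        return p_raw.copy()
    if np.any((p_raw < 0) | (p_raw > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p_raw, method="fdr_bh")[1]


def areal_tests(
    table: pd.DataFrame,
    scopes: tuple[str, ...] = SCOPES,
    alpha: float = BH_ALPHA,
) -> pd.DataFrame:
    """Kruskal-Wallis + BH for every requested scope, concatenated."""
    return pd.concat(
        [kruskal_wallis_per_area(table, scope, alpha) for scope in scopes],
        ignore_index=True,
    )


def classify_preference(
    tests: pd.DataFrame, ratios: pd.DataFrame
) -> pd.DataFrame:
    """Seed-preference classification per area (anterior vs posterior).

    An area significant in the pooled test or in both hemispheres is
    assigned the seed (aVIP or pVIP) with the higher pooled mean ratio,
    or 'both' when the two are within a small relative tolerance.  An
    area significant in exactly one hemisphere is judged by the average
    supra-threshold z score instead of the ratio.  Areas significant
    nowhere get 'none'.  The middle seed is never assigned a
    preference: it is the gradient's midpoint, not a pole.
    """
    for scope in SCOPES:
        if scope not in set(tests["scope"]):
            raise ValueError(f"tests table missing scope {scope!r}")
    sig = tests.pivot(index="area", columns="scope", values="significant")
    mean_ratio = ratios.groupby(["area", "seed"], observed=False)["ratio"].mean()
    mean_z = ratios.groupby(["area", "seed"], observed=False)["mean_z"].mean()
    rows = []
    for area in sig.index:
        s_left = bool(sig.loc[area, "left"])
        s_right = bool(sig.loc[area, "right"])
        s_pooled = bool(sig.loc[area, "pooled"])
        if s_pooled or (s_left and s_right):
            a, p = mean_ratio.get((area, "aVIP"), 0.0), mean_ratio.get(
                (area, "pVIP"), 0.0
            )
            preferred = _pick_pole(a, p)
            basis = "significant_test"
        elif s_left or s_right:
            a = mean_z.get((area, "aVIP"), np.nan)
            p = mean_z.get((area, "pVIP"), np.nan)
            a = 0.0 if pd.isna(a) else a
            p = 0.0 if pd.isna(p) else p
            preferred = _pick_pole(a, p)
            basis = "mean_z_tiebreak"
        else:
            preferred, basis = "none", "significant_test"
        rows.append({"area": area, "preferred": preferred, "basis": basis})
    return pd.DataFrame(rows)


def _pick_pole(a: float, p: float) -> str:
    """aVIP vs pVIP by the larger statistic, 'both' on a near-tie."""
    if a == 0.0 and p == 0.0:
        return "none"
    if abs(a - p) <= PREFERENCE_TIE_RTOL * max(abs(a), abs(p)):
        return "both"
    return "aVIP" if a > p else "pVIP"
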