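"""Seed-to-whole-brain correlation maps and their aggregation.

Workflow per seed (aVIP / mVIP / pVIP) and hemisphere:

1.  Average the seed ROI's voxel series into one seed signal per run.
2.  Correlate the seed signal with every ipsilateral in-mask voxel over
    the kept frames (Pearson r), then apply the variance-stabilizing
    Fisher transform z = arctanh(r).
3.  Across a subject's runs, one-sample t-test of the per-run z values
    against zero per voxel; the subject map is the across-run mean z
    with a significance mask at p < 0.001.
4.  Group map: unweighted across-subject mean, with non-significant
    subject voxels contributing zero.

Maps are restricted to the seed's hemisphere; contralateral voxels are
missing (NaN), not zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .preprocess import RunTimeSeries

logger = logging.getLogger(__name__)

SEEDS = ("aVIP", "mVIP", "pVIP")

#: seed construction scheme: seed -> (n_consecutive_coronal_slices, voxels_per_slice)
DEFAULT_SEED_SCHEME = {"aVIP": (4, 5), "mVIP": (4, 5), "pVIP": (5, 4)}

#: clip |r| below 1 so arctanh stays finite at self-correlated voxels
R_CLIP = 1.0 - 1e-7

MIN_KEPT_FRAMES = 32

SUBJECT_ALPHA = 1e-3


class SeedConstructionError(RuntimeError):
    """Raised when the requested ROI scheme cannot be built from the atlas."""


class SingleRunError(RuntimeError):
    """Raised when a subject has too few runs for a t-test."""


@dataclass
class SeedSignal:
    """Per-kept-frame seed time course for one run."""

    values: np.ndarray
    seed: str
    hemisphere: str
    subject_id: str
    run_id: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class ZMap:
    """Per-voxel Fisher-z connectivity values at run/subject/group level.

    ``values`` follows the geometry's in-mask voxel ordering; voxels
    outside the map's hemisphere are NaN.  Subject-level maps carry
    per-voxel p-values and the p < alpha significance mask; group maps
    carry the across-subject SEM.
    """

    values: np.ndarray
    level: str
    seed: str
    hemisphere: str
    subject_id: str | None = None
    pvals: np.ndarray | None = None
    sig_mask: np.ndarray | None = None
    sem: np.ndarray | None = None
    n_obs: int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.level not in ("run", "subject", "group"):
            raise ValueError(f"unknown level {self.level!r}")

    def masked_values(self) -> np.ndarray:
        """Subject map with non-significant voxels zero-filled.

        NaN (contralateral) entries are preserved.
        """
        if self.sig_mask is None:
            return self.values.copy()
        out = np.where(self.sig_mask, self.values, 0.0)
        out[np.isnan(self.values)] = np.nan
        return out


def build_seed_rois(
    geometry, scheme: dict | None = None
) -> dict[tuple[str, str], np.ndarray]:
    """Construct the three VIP seed ROIs per hemisphere from the atlas.

    For each hemisphere, voxels labeled as area VIP are grouped by
    coronal slice (anterior to posterior).  The anterior seed takes the
    first block of slices, the middle seed the next, the posterior seed
    the last; within each slice the requested number of voxels is taken
    in a fixed (dorso-ventral, medio-lateral) order.  The default
    scheme (aVIP and mVIP: 5 voxels from each of 4 slices; pVIP: 4
    voxels from each of 5 slices) gives all three ROIs 20 voxels.

    Returns a mapping (seed, hemisphere) -> ordered voxel-row indices.
    """
    scheme = dict(DEFAULT_SEED_SCHEME if scheme is None else scheme)
    rois: dict[tuple[str, str], np.ndarray] = {}
    for hemi in ("left", "right"):
        vip_rows = geometry.vip_voxel_rows(hemi)
        if vip_rows.size == 0:
            raise SeedConstructionError(f"no VIP-labeled voxels in {hemi} hemisphere")
        ys = geometry.coords[vip_rows, 1]
        slices = np.sort(np.unique(ys))
        needed = sum(n for n, _ in scheme.values())
        if slices.size < needed:
            raise SeedConstructionError(
                f"{hemi} VIP spans {slices.size} coronal slices; "
                f"scheme needs {needed} consecutive slices"
            )
        if not np.all(np.diff(slices) == 1):
            raise SeedConstructionError(f"{hemi} VIP slices are not consecutive")
        cursor = 0
        for seed in SEEDS:
            n_slices, per_slice = scheme[seed]
            picked = []
            for y in slices[cursor:cursor + n_slices]:
                rows = vip_rows[ys == y]
                if rows.size < per_slice:
                    raise SeedConstructionError(
                        f"coronal slice y={int(y)} ({hemi}) has {rows.size} VIP "
                        f"voxels; {seed} needs {per_slice}"
                    )
                # fixed dorso-ventral then medio-lateral order for determinism
                order = np.lexsort(
                    (geometry.coords[rows, 0], geometry.coords[rows, 2])
                )
                picked.append(rows[order][:per_slice])
            cursor += n_slices
            rois[(seed, hemi)] = np.concatenate(picked)
    return rois


def extract_seed_signal(
    run: RunTimeSeries, seed_voxels: np.ndarray, seed: str, hemisphere: str,
    agg: str = "mean",
) -> SeedSignal:
    """Seed time course over kept frames.

    agg='mean' (default) averages the ROI voxels; agg='first_pc' takes
    the first principal component (sign-aligned with the mean signal).
    """
    seed_voxels = np.asarray(seed_voxels, dtype=int)
    if seed_voxels.size == 0:
        raise ValueError("empty seed voxel set")
    block = run.kept_data()[:, seed_voxels]
    if agg == "mean":
        values = block.mean(axis=1)
    elif agg == "first_pc":
        centered = block - block.mean(axis=0, keepdims=True)
        u, s, _ = np.linalg.svd(centered, full_matrices=False)
        values = u[:, 0] * s[0]
        if np.corrcoef(values, block.mean(axis=1))[0, 1] < 0:
            values = -values
    else:
        raise ValueError(f"unknown seed aggregation {agg!r}")
    return SeedSignal(
        values=values, seed=seed, hemisphere=hemisphere,
        subject_id=run.subject_id, run_id=run.run_id,
    )


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Variance-stabilizing r-to-z transform with clipping near |r|=1."""
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


def run_correlation_maps(
    run: RunTimeSeries, seed_signals: list[SeedSignal], geometry
) -> list[ZMap]:
    """Fisher-z maps for several seeds of one hemisphere in one pass.

    Only the seeds' hemisphere is computed; contralateral voxels are
    NaN.  Zero-variance voxels get z = 0 (count logged).  The centered
    voxel matrix is shared across seeds, which matters at whole-brain
    scale.
    """
    if not seed_signals:
        raise ValueError("no seed signals")
    hemisphere = seed_signals[0].hemisphere
    if any(s.hemisphere != hemisphere for s in seed_signals):
        raise ValueError("seed signals mix hemispheres")
    y = run.kept_data()
    if y.shape[0] < MIN_KEPT_FRAMES:
        raise ValueError(
            f"need >= {MIN_KEPT_FRAMES} kept frames, got {y.shape[0]}"
        )
    hemi_mask = geometry.hemisphere_mask(hemisphere)
    yc = y[:, hemi_mask]
    yc = yc - yc.mean(axis=0, keepdims=True)
    v_ss = np.sqrt((yc ** 2).sum(axis=0))
    zero_var = v_ss == 0
    n_zero = int(zero_var.sum())
    if n_zero:
        logger.info(
            "run %s/%s: %d zero-variance voxels set to z=0",
            run.subject_id, run.run_id, n_zero,
        )
    denom = np.where(zero_var, 1.0, v_ss)
    out = []
    for sig in seed_signals:
        s = sig.values
        if s.shape[0] != y.shape[0]:
            raise ValueError("seed signal and run kept-frame counts differ")
        sc = s - s.mean()
        s_ss = float(np.sqrt((sc ** 2).sum()))
        if s_ss == 0:
            raise ValueError("zero-variance seed signal")
        r = (sc @ yc) / (s_ss * denom)
        r[zero_var] = 0.0
        values = np.full(geometry.n_voxels, np.nan)
        values[hemi_mask] = fisher_z(r)
        out.append(
            ZMap(
                values=values, level="run", seed=sig.seed,
                hemisphere=hemisphere, subject_id=run.subject_id,
            )
        )
    return out


def run_correlation_map(
    run: RunTimeSeries, seed_signal: SeedSignal, geometry
) -> ZMap:
    """Fisher-z map of seed-to-voxel Pearson correlations for one run."""
    return run_correlation_maps(run, [seed_signal], geometry)[0]


def subject_aggregate(run_maps: list[ZMap], alpha: float = SUBJECT_ALPHA) -> ZMap:
    """Across-run mean z with a per-voxel one-sample t-test against zero.

    Voxels with zero across-run variance get p = 0 when the mean is
    nonzero and p = 1 when it is zero.  The significance mask is
    p < alpha (two-sided, uncorrected).
    """
    if len(run_maps) < 2:
        raise SingleRunError("subject aggregation needs >= 2 run maps")
    first = run_maps[0]
    for m in run_maps[1:]:
        if (m.seed, m.hemisphere, m.subject_id) != (
            first.seed, first.hemisphere, first.subject_id
        ):
            raise ValueError("run maps mix seeds, hemispheres or subjects")
    stack = np.vstack([m.values for m in run_maps])
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    # vectorized one-sample t-test (contralateral NaN columns propagate;
    # scipy's axis-wise NaN handling degrades to a per-voxel loop here)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
        pvals = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    zero_var = sd == 0
    pvals[zero_var & (mean != 0)] = 0.0
    pvals[zero_var & (mean == 0)] = 1.0
    pvals[np.isnan(mean)] = np.nan
    sig = np.zeros(mean.shape, dtype=bool)
    finite = np.isfinite(pvals)
    sig[finite] = pvals[finite] < alpha
    return ZMap(
        values=mean, level="subject", seed=first.seed,
        hemisphere=first.hemisphere, subject_id=first.subject_id,
        pvals=pvals, sig_mask=sig, n_obs=len(run_maps),
    )


def group_average(subject_maps: list[ZMap]) -> ZMap:
    """Unweighted across-subject mean of masked subject maps.

    Each subject contributes its mean-z value where significant and
    zero elsewhere; the group map also carries the per-voxel SEM across
    subjects.
    """
    if not subject_maps:
        raise ValueError("no subject maps")
    first = subject_maps[0]
    for m in subject_maps[1:]:
        if (m.seed, m.hemisphere) != (first.seed, first.hemisphere):
            raise ValueError("subject maps mix seeds or hemispheres")
    stack = np.vstack([m.masked_values() for m in subject_maps])
    n = len(subject_maps)
    mean = stack.mean(axis=0)
    sem = stack.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.full_like(mean, np.nan)
    return ZMap(
        values=mean, level="group", seed=first.seed,
        hemisphere=first.hemisphere, sem=sem, n_obs=n,
    )
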