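"""Pipeline orchestration, acquisition bookkeeping and input validation.

``run_pipeline`` executes the five analysis stages in fixed order —

    simulate -> preprocess -> connectivity -> surface -> stats

— either from a :class:`~vipgradient.phantom.PhantomSpec` (in-memory
simulation) or from a dataset directory written by
:func:`vipgradient.io.write_dataset`.  Every stage records counts and a
checksum in a JSON run report; reruns with the same configuration
reproduce identical outputs because all randomness derives from the
phantom's seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import areal, connectivity as conn, io as vio, preprocess as prep
from .phantom import (
    GroundTruth,
    PhantomSpec,
    VolumeGeometry,
    make_geometry,
    plant_design,
    simulate_run,
    score_recovery,
    subject_label,
    run_label,
)
from .preprocess import FilterSettings, RunExcludedError
from .surface import (
    CATEGORIES,
    CategoryMap,
    ProjectionMap,
    SurfaceModel,
    SurfaceScalarMap,
    categorize,
    composition,
    map_similarity,
    project_to_surface,
    rgb_hex,
    threshold_surface,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "connectivity", "surface", "stats")

SEED_PAIRS = (("aVIP", "mVIP"), ("mVIP", "pVIP"), ("aVIP", "pVIP"))


@dataclass
class PipelineConfig:
    """All thresholds and switches of the analysis, fully serialized
    into the run report.

    Defaults follow standard practice for this analysis: band-pass
    0.01-0.1 Hz, per-subject alpha 0.001 (uncorrected, two-sided),
    surface z threshold 0.05 with a 0.03-0.07 robustness sweep, BH
    alpha 0.05, 1.5 mm FWHM smoothing applied at the map stage.
    """

    filter: FilterSettings = field(default_factory=FilterSettings)
    alpha: float = 1e-3
    z_thr: float = 0.05
    z_sweep: tuple[float, ...] = (0.03, 0.05, 0.07)
    bh_alpha: float = 0.05
    smooth_stage: str = "map"
    seed_agg: str = "mean"
    scopes: tuple[str, ...] = ("left", "right", "pooled")
    out_dir: str = "vipgradient_out"
    resume: bool = False

    def __post_init__(self):
        if not (0 < self.alpha < 1) or not (0 < self.bh_alpha < 1):
            raise ValueError("alpha levels must be in (0, 1)")
        if self.z_thr <= 0 or any(t <= 0 for t in self.z_sweep):
            raise ValueError("z thresholds must be > 0")
        if self.smooth_stage not in ("map", "timeseries"):
            raise ValueError("smooth_stage must be 'map' or 'timeseries'")
        if self.seed_agg not in ("mean", "first_pc"):
            raise ValueError("seed_agg must be 'mean' or 'first_pc'")
        if isinstance(self.filter, dict):
            self.filter = FilterSettings(**self.filter)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["filter"] = dict(self.filter.__dict__)
        d["filter"]["band_hz"] = list(self.filter.band_hz)
        d["z_sweep"] = list(self.z_sweep)
        d["scopes"] = list(self.scopes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "filter" in d and isinstance(d["filter"], dict):
            f = dict(d["filter"])
            if "band_hz" in f:
                f["band_hz"] = tuple(f["band_hz"])
            d["filter"] = FilterSettings(**f)
        for key in ("z_sweep", "scopes"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _checksum(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# acquisition bookkeeping


def reference_acquisition_table() -> pd.DataFrame:
    """Run manifest of the 10-monkey resting-state study.

    One row per run, with session membership, frames ("pulses") per run
    and TR; used for scan-duration bookkeeping and for emulating
    realistic per-subject heterogeneity.
    """
    study = {
        "CH": ([31, 16], 301, 2.0),
        "FE": ([8], 305, 2.0),
        "FI": ([24, 11], 301, 2.0),
        "IN": ([13], 300, 2.0),
        "JA": ([41, 20], 422, 1.4),
        "KA": ([23, 9], 301, 2.0),
        "LA": ([20, 12], 301, 2.0),
        "LE": ([21, 9], 300, 2.0),
        "NA": ([37, 5, 13], 422, 1.4),
        "TH": ([9], 905, 2.0),
    }
    rows = []
    for monkey, (sessions, frames, tr) in study.items():
        run_no = 0
        for sess_idx, n_runs in enumerate(sessions, start=1):
            for _ in range(n_runs):
                run_no += 1
                rows.append(
                    {
                        "subject_id": monkey,
                        "session_id": sess_idx,
                        "run_id": f"run-{run_no:02d}",
                        "n_frames": frames,
                        "tr_seconds": tr,
                    }
                )
    return pd.DataFrame(rows)


def summarize_acquisition(manifest: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-subject scan totals and study-wide minima.

    total_minutes = sum over runs of n_frames * tr_seconds / 60,
    reported at full precision.  The global summary gives the minimum
    cumulated duration, minimum run count and minimum single-run
    duration across subjects.
    """
    if manifest.empty:
        raise ValueError("empty run manifest")
    m = manifest.copy()
    m["run_minutes"] = m["n_frames"] * m["tr_seconds"] / 60.0
    per_subject = (
        m.groupby("subject_id", sort=True)
        .agg(
            n_sessions=("session_id", "nunique"),
            n_runs=("run_id", "size"),
            frames_per_run=("n_frames", lambda x: ";".join(
                str(v) for v in sorted(set(x)))),
            tr_seconds=("tr_seconds", "first"),
            total_minutes=("run_minutes", "sum"),
        )
        .reset_index()
    )
    summary = {
        "min_total_minutes": float(per_subject["total_minutes"].min()),
        "min_run_count": int(per_subject["n_runs"].min()),
        "min_single_run_minutes": float(m["run_minutes"].min()),
        "n_subjects": int(per_subject.shape[0]),
    }
    return per_subject, summary


def table1_phantom_spec(base: PhantomSpec) -> PhantomSpec:
    """Phantom spec with per-subject run counts drawn from the study table.

    Run counts (pooled over sessions) follow the reference acquisition
    table; frame counts and TR stay at the base spec's homogeneous
    values, which keeps a single common frequency grid.
    """
    per_subj, _ = summarize_acquisition(reference_acquisition_table())
    runs = per_subj["n_runs"].tolist()[: base.n_subjects]
    while len(runs) < base.n_subjects:
        runs.append(int(np.median(per_subj["n_runs"])))
    d = base.to_dict()
    d["runs_per_subject"] = runs
    return PhantomSpec.from_dict(d)


# ---------------------------------------------------------------------------
# input validation


@dataclass
class ValidationReport:
    findings: list = field(default_factory=list)

    def add(self, level: str, message: str) -> None:
        self.findings.append({"level": level, "message": message})

    @property
    def fatal(self) -> list:
        return [f for f in self.findings if f["level"] == "fatal"]

    @property
    def warnings(self) -> list:
        return [f for f in self.findings if f["level"] == "warning"]

    @property
    def ok(self) -> bool:
        return not self.fatal


def validate_inputs(indir: Path) -> ValidationReport:
    """Check a dataset directory for structural consistency.

    Fatal findings: missing required files, bold/mask shape mismatch,
    seed voxels outside the mask or the VIP label, vertices with
    multiple source voxels.  TR disagreement between a NIfTI header and
    the manifest is a warning naming the run.
    """
    indir = Path(indir)
    rep = ValidationReport()
    required = [
        "phantom_spec.json", "mask.nii.gz", "atlas.nii.gz", "areas.tsv",
        "seeds.tsv", "projection.tsv", "manifest.tsv",
    ]
    for name in required:
        if not (indir / name).exists():
            rep.add("fatal", f"missing required file {name}")
    if not rep.ok:
        return rep

    mask_img = nib.load(str(indir / "mask.nii.gz"))
    mask = np.asarray(mask_img.dataobj).astype(bool)
    atlas = np.asarray(nib.load(str(indir / "atlas.nii.gz")).dataobj, dtype=int)
    if atlas.shape != mask.shape:
        rep.add("fatal", "atlas and mask volume shapes differ")
        return rep

    areas = pd.read_csv(indir / "areas.tsv", sep="\t")
    for col in ("area_id", "area_name", "region_name", "hemisphere"):
        if col not in areas.columns:
            rep.add("fatal", f"areas.tsv missing column {col}")
    seeds = pd.read_csv(indir / "seeds.tsv", sep="\t")
    vip_ids = set(areas.loc[areas["area_name"] == "VIP", "area_id"])
    for _, row in seeds.iterrows():
        i, j, k = int(row["i"]), int(row["j"]), int(row["k"])
        if not (0 <= i < mask.shape[0] and 0 <= j < mask.shape[1]
                and 0 <= k < mask.shape[2]) or not mask[i, j, k]:
            rep.add(
                "fatal",
                f"seed {row['seed']} voxel ({i},{j},{k}) outside the brain mask",
            )
        elif int(atlas[i, j, k]) not in vip_ids:
            rep.add(
                "fatal",
                f"seed {row['seed']} voxel ({i},{j},{k}) not labeled VIP",
            )

    proj = pd.read_csv(indir / "projection.tsv", sep="\t")
    if proj["vertex_id"].duplicated().any():
        rep.add("fatal", "projection assigns a vertex to multiple voxels")
    off = ~mask[proj["i"], proj["j"], proj["k"]]
    if off.any():
        rep.add("fatal", f"projection references {int(off.sum())} out-of-mask voxels")

    manifest = pd.read_csv(indir / "manifest.tsv", sep="\t")
    for _, row in manifest.iterrows():
        bold = indir / row["bold_path"]
        if not bold.exists():
            rep.add("fatal", f"missing bold file {row['bold_path']}")
            continue
        img = nib.load(str(bold))
        if img.shape[:3] != mask.shape:
            rep.add(
                "fatal",
                f"{row['bold_path']}: spatial shape {img.shape[:3]} != mask "
                f"{mask.shape}",
            )
        if img.ndim == 4 and img.shape[3] != int(row["n_frames"]):
            rep.add(
                "warning",
                f"{row['bold_path']}: {img.shape[3]} frames, manifest says "
                f"{row['n_frames']}",
            )
        header_tr = float(img.header["pixdim"][4])
        if header_tr > 0 and abs(header_tr - float(row["tr_seconds"])) > 1e-6:
            rep.add(
                "warning",
                f"run {row['subject_id']}/{row['run_id']}: header TR "
                f"{header_tr} != manifest TR {row['tr_seconds']}",
            )
    return rep


# ---------------------------------------------------------------------------
# orchestration


def _smooth_map(values: np.ndarray, geom, settings: FilterSettings) -> np.ndarray:
    return prep.smooth(values, geom, settings)


def _smooth_timeseries(run, geom, settings: FilterSettings):
    data = run.data.copy()
    for t in np.flatnonzero(run.censor):
        data[t] = prep.smooth(data[t], geom, settings)
    from dataclasses import replace
    return replace(run, data=data)


def _full_surface_values(
    maps_by_hemi: dict[str, SurfaceScalarMap]
) -> np.ndarray:
    left = maps_by_hemi["left"].values
    right = maps_by_hemi["right"].values
    return np.where(np.isfinite(left), left, right)


def run_pipeline(
    config: PipelineConfig,
    spec: PhantomSpec | None = None,
    input_dir: Path | None = None,
) -> dict:
    """Execute the full analysis; returns the run report (also written
    to ``<out_dir>/report.json``).

    Exactly one of ``spec`` (simulate in memory) and ``input_dir``
    (load a written dataset) must be given.
    """
    if (spec is None) == (input_dir is None):
        raise ValueError("provide exactly one of spec or input_dir")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report_path = out / "report.json"
    if config.resume and report_path.exists():
        old = json.loads(report_path.read_text())
        if old.get("config_hash") == config.config_hash():
            logger.info("resume: existing report matches config, skipping")
            return old

    report: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stages": [],
        "thresholds": {
            "subject_alpha": config.alpha,
            "z_thr": config.z_thr,
            "z_sweep": list(config.z_sweep),
            "bh_alpha": config.bh_alpha,
            "fd_threshold_mm": config.filter.fd_threshold_mm,
        },
    }

    # -- stage 1: simulate / load ------------------------------------------
    truth: GroundTruth | None
    if spec is not None:
        geom, surface, projection = make_geometry(spec)
        truth = plant_design(spec, geom)
        subjects = [
            (subject_label(s), [
                (s, r) for r in range(spec.runs_for_subject(s))
            ])
            for s in range(spec.n_subjects)
        ]
        get_run = lambda s_idx, r_idx: simulate_run(spec, geom, truth, s_idx, r_idx)
        tr = spec.tr_seconds
        n_runs_total = sum(len(rr) for _, rr in subjects)
        sim_counts = {
            "n_subjects": spec.n_subjects,
            "n_runs": n_runs_total,
            "n_voxels": geom.n_voxels,
            "n_vertices": surface.n_vertices,
        }
        sim_checksum = _checksum(truth.loadings, geom.area_label)
    else:
        indir = Path(input_dir)
        vrep = validate_inputs(indir)
        if not vrep.ok:
            raise ValueError(
                "input validation failed: "
                + "; ".join(f["message"] for f in vrep.fatal)
            )
        geom, surface, projection = vio.load_geometry(indir)
        manifest = vio.load_manifest(indir)
        truth = (
            vio.load_ground_truth(indir, geom)
            if (indir / "ground_truth.tsv").exists() else None
        )
        by_subject = manifest.groupby("subject_id", sort=True)
        subjects = [
            (sid, [row for _, row in df.iterrows()]) for sid, df in by_subject
        ]
        get_run = lambda _sid, row: vio.load_run(indir, row, geom)
        tr = float(manifest["tr_seconds"].iloc[0])
        sim_counts = {
            "n_subjects": len(subjects),
            "n_runs": int(len(manifest)),
            "n_voxels": geom.n_voxels,
            "n_vertices": surface.n_vertices,
        }
        sim_checksum = _checksum(geom.area_label)
    config.filter.validate_for_tr(tr)
    report["stages"].append(
        {"name": "simulate", "status": "ok", "counts": sim_counts,
         "checksum": sim_checksum}
    )

    # -- stages 2+3: preprocess and per-run connectivity (streamed) --------
    hemis = ("left", "right")
    subject_zmaps: dict[tuple[str, str], list] = {}
    n_excluded = 0
    n_censored_frames = 0
    n_runs_done = 0
    dropped_subjects = []
    for sid, run_keys in subjects:
        run_maps: dict[tuple[str, str], list] = {
            (seed, hemi): [] for seed in conn.SEEDS for hemi in hemis
        }
        for key in run_keys:
            raw = get_run(*key) if isinstance(key, tuple) else get_run(sid, key)
            try:
                run = prep.preprocess_run(raw, config.filter)
            except RunExcludedError:
                n_excluded += 1
                continue
            if config.smooth_stage == "timeseries":
                run = _smooth_timeseries(run, geom, config.filter)
            n_censored_frames += int((~run.censor).sum())
            n_runs_done += 1
            for hemi in hemis:
                sigs = [
                    conn.extract_seed_signal(
                        run, geom.seed_voxels[(seed, hemi)], seed, hemi,
                        agg=config.seed_agg,
                    )
                    for seed in conn.SEEDS
                ]
                for zmap in conn.run_correlation_maps(run, sigs, geom):
                    if config.smooth_stage == "map":
                        zmap.values = _smooth_map(
                            zmap.values, geom, config.filter
                        )
                    run_maps[(zmap.seed, hemi)].append(zmap)
        try:
            for key_sh, maps in run_maps.items():
                subject_zmaps.setdefault(key_sh, []).append(
                    conn.subject_aggregate(maps, alpha=config.alpha)
                )
        except conn.SingleRunError:
            logger.warning("subject %s dropped: fewer than 2 usable runs", sid)
            dropped_subjects.append(sid)
            for key_sh in run_maps:
                if subject_zmaps.get(key_sh) and (
                    subject_zmaps[key_sh][-1].subject_id == sid
                ):
                    subject_zmaps[key_sh].pop()
    report["stages"].append(
        {"name": "preprocess", "status": "ok",
         "counts": {"n_runs_processed": n_runs_done,
                    "n_runs_excluded": n_excluded,
                    "n_frames_censored": n_censored_frames},
         "checksum": ""}
    )
    n_subject_maps = sum(len(v) for v in subject_zmaps.values())
    any_key = (conn.SEEDS[0], "left")
    report["stages"].append(
        {"name": "connectivity", "status": "ok",
         "counts": {"n_subject_maps": n_subject_maps,
                    "dropped_subjects": dropped_subjects},
         "checksum": _checksum(
             *[m.values for m in subject_zmaps.get(any_key, [])]
         )}
    )

    # -- stage 4: group maps, surface categorization, similarity -----------
    group_maps: dict[tuple[str, str], conn.ZMap] = {}
    for (seed, hemi), maps in subject_zmaps.items():
        group_maps[(seed, hemi)] = conn.group_average(maps)
        vio.save_volume(
            geom.scatter(group_maps[(seed, hemi)].values),
            out / f"group_{seed}_{hemi}.nii.gz",
        )
        sidecar = {
            "seed": seed, "hemisphere": hemi, "level": "group",
            "alpha": config.alpha,
            "n_subjects": group_maps[(seed, hemi)].n_obs,
        }
        (out / f"group_{seed}_{hemi}.json").write_text(json.dumps(sidecar))
    group_surface = {
        (seed, hemi): project_to_surface(
            zmap.values, projection, surface,
            seed=seed, hemisphere=hemi, level="group",
        )
        for (seed, hemi), zmap in group_maps.items()
    }
    similarity = {}
    for hemi in hemis:
        for s1, s2 in SEED_PAIRS:
            rho, p, n = map_similarity(
                group_surface[(s1, hemi)], group_surface[(s2, hemi)]
            )
            similarity[f"{s1}-{s2}-{hemi}"] = {"rho": rho, "p": p, "n": n}
    full_vals = {
        seed: _full_surface_values(
            {h: group_surface[(seed, h)] for h in hemis}
        )
        for seed in conn.SEEDS
    }
    sweep = {}
    for thr in sorted(config.z_sweep):
        sweep[str(thr)] = {
            seed: int((np.nan_to_num(full_vals[seed]) > thr).sum())
            for seed in conn.SEEDS
        }
    bins = {
        seed: threshold_surface(
            SurfaceScalarMap(values=full_vals[seed]), config.z_thr
        )
        for seed in conn.SEEDS
    }
    catmap = categorize(
        bins["aVIP"], bins["mVIP"], bins["pVIP"], threshold_used=config.z_thr
    )
    cat_df = pd.DataFrame(
        {
            "vertex_id": surface.vertices["vertex_id"],
            "category": catmap.names(),
            "color": rgb_hex(catmap),
        }
    )
    cat_df.to_csv(out / "category_map.tsv", sep="\t", index=False)
    comp_hemi = composition(catmap, surface, scope="hemisphere")
    comp_region = composition(catmap, surface, scope="region")
    comp_hemi.to_csv(out / "composition_hemisphere.csv", index=False)
    comp_region.to_csv(out / "composition_region.csv", index=False)
    report["similarity"] = similarity
    report["sweep_connected_vertices"] = sweep
    report["stages"].append(
        {"name": "surface", "status": "ok",
         "counts": {"n_vertices": surface.n_vertices,
                    "n_connected_at_z_thr": int(
                        (catmap.category != CATEGORIES.index("NONE")).sum()
                    )},
         "checksum": _checksum(catmap.category)}
    )
    if truth is not None:
        recovery = score_recovery(catmap, truth, projection)
        report["recovery"] = {
            "accuracy": recovery.accuracy,
            "n_vertices": recovery.n_vertices,
            "sensitivity": {
                k: (None if pd.isna(v) else float(v))
                for k, v in recovery.sensitivity.items()
            },
        }
        recovery.confusion.to_csv(out / "recovery_confusion.csv")

    # -- stage 5: areal statistics -----------------------------------------
    subject_surface: dict[tuple[str, str, str], SurfaceScalarMap] = {}
    for (seed, hemi), maps in subject_zmaps.items():
        for m in maps:
            subject_surface[(m.subject_id, seed, hemi)] = project_to_surface(
                m.masked_values(), projection, surface,
                seed=seed, hemisphere=hemi, level="subject",
                subject_id=m.subject_id,
            )
    ratio_table = areal.areal_ratios(subject_surface, surface, z_thr=config.z_thr)
    ratio_summary = areal.group_ratio_summary(ratio_table)
    ratio_table.to_csv(out / "areal_ratios.csv", index=False)
    ratio_summary.to_csv(out / "areal_ratio_summary.csv", index=False)
    n_subj_used = ratio_table["subject_id"].nunique() if len(ratio_table) else 0
    stats_counts: dict = {"n_ratio_rows": int(len(ratio_table))}
    if n_subj_used >= 3:
        tests = areal.areal_tests(ratio_table, scopes=config.scopes,
                                  alpha=config.bh_alpha)
        preference = areal.classify_preference(tests, ratio_table)
        tests.to_csv(out / "areal_tests.csv", index=False)
        preference.to_csv(out / "preference.csv", index=False)
        report["preference"] = dict(
            zip(preference["area"], preference["preferred"])
        )
        report["significant_areas"] = {
            scope: sorted(
                tests.loc[
                    (tests["scope"] == scope) & tests["significant"], "area"
                ]
            )
            for scope in config.scopes
        }
        stats_counts.update(
            n_areas_tested=int(tests["area"].nunique()),
            n_significant_pooled=int(
                tests.loc[tests["scope"] == "pooled", "significant"].sum()
            ),
        )
        stats_checksum = _checksum(tests["p_adj"].to_numpy())
    else:
        logger.warning(
            "area-wise tests skipped: %d subjects (< 3 per seed group)",
            n_subj_used,
        )
        stats_counts["tests"] = f"skipped ({n_subj_used} subjects < 3)"
        stats_checksum = _checksum(ratio_table["ratio"].to_numpy())
    report["stages"].append(
        {"name": "stats", "status": "ok", "counts": stats_counts,
         "checksum": stats_checksum}
    )

    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
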