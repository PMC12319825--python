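"""On-disk dataset layout (NIfTI-1 volumes, TSV tables, JSON sidecars).

Layout written by :func:`write_dataset` / the ``vipgradient simulate``
command::

    out/
      phantom_spec.json
      mask.nii.gz            brain mask (uint8)
      atlas.nii.gz           integer area labels (0 outside mask)
      areas.tsv              area_id, area_name, region_name, hemisphere
      seeds.tsv              seed, hemisphere, i, j, k
      projection.tsv         vertex_id, i, j, k  (vertex -> source voxel)
      ground_truth.tsv       i, j, k, w_a, w_m, w_p, category
      manifest.tsv           subject_id, session_id, run_id, n_frames,
                             tr_seconds, bold_path, nuisance_path
      sub-XX_run-YY_bold.nii.gz
      nuisance_sub-XX_run-YY.tsv   frame, wm, csf, fd
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import (
    GroundTruth,
    PhantomSpec,
    VolumeGeometry,
    plant_design,
    make_geometry,
    simulate_run,
    subject_label,
    run_label,
)
from .preprocess import RunTimeSeries
from .surface import CATEGORIES, ProjectionMap, SurfaceModel

VOXEL_MM = 1.25


def _affine(voxel_mm: float = VOXEL_MM) -> np.ndarray:
    return np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])


def save_volume(values_3d: np.ndarray, path: Path, dtype=np.float32,
                tr_seconds: float | None = None) -> None:
    img = nib.Nifti1Image(np.asarray(values_3d, dtype=dtype), _affine())
    if tr_seconds is not None:
        img.header["pixdim"][4] = tr_seconds
    nib.save(img, str(path))


def write_geometry(
    geom: VolumeGeometry,
    surface: SurfaceModel,
    projection: ProjectionMap,
    outdir: Path,
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_volume(geom.mask.astype(np.uint8), outdir / "mask.nii.gz", np.uint8)
    atlas = np.zeros(geom.shape, dtype=np.int16)
    atlas[geom.coords[:, 0], geom.coords[:, 1], geom.coords[:, 2]] = geom.area_label
    save_volume(atlas, outdir / "atlas.nii.gz", np.int16)
    areas = geom.areas.rename(columns={"region": "region_name"})
    areas.to_csv(outdir / "areas.tsv", sep="\t", index=False)
    seed_rows = [
        {"seed": seed, "hemisphere": hemi,
         "i": int(geom.coords[r, 0]), "j": int(geom.coords[r, 1]),
         "k": int(geom.coords[r, 2])}
        for (seed, hemi), rows in sorted(geom.seed_voxels.items())
        for r in rows
    ]
    pd.DataFrame(seed_rows).to_csv(outdir / "seeds.tsv", sep="\t", index=False)
    src = geom.coords[projection.vertex_source]
    pd.DataFrame(
        {
            "vertex_id": np.arange(projection.n_vertices),
            "i": src[:, 0], "j": src[:, 1], "k": src[:, 2],
        }
    ).to_csv(outdir / "projection.tsv", sep="\t", index=False)


def write_ground_truth(truth: GroundTruth, geom: VolumeGeometry, outdir: Path) -> None:
    pd.DataFrame(
        {
            "i": geom.coords[:, 0], "j": geom.coords[:, 1], "k": geom.coords[:, 2],
            "w_a": truth.loadings[:, 0],
            "w_m": truth.loadings[:, 1],
            "w_p": truth.loadings[:, 2],
            "category": truth.category_names(),
        }
    ).to_csv(Path(outdir) / "ground_truth.tsv", sep="\t", index=False)


def write_run(run: RunTimeSeries, geom: VolumeGeometry, outdir: Path) -> tuple[str, str]:
    outdir = Path(outdir)
    bold_name = f"{run.subject_id}_{run.run_id}_bold.nii.gz"
    vol4d = np.zeros(geom.shape + (run.n_frames,), dtype=np.float32)
    vol4d[geom.coords[:, 0], geom.coords[:, 1], geom.coords[:, 2], :] = (
        run.data.T.astype(np.float32)
    )
    save_volume(vol4d, outdir / bold_name, np.float32, tr_seconds=run.tr_seconds)
    nuis_name = f"nuisance_{run.subject_id}_{run.run_id}.tsv"
    pd.DataFrame(
        {
            "frame": np.arange(run.n_frames),
            "wm": run.nuisance["wm"],
            "csf": run.nuisance["csf"],
            "fd": run.fd,
        }
    ).to_csv(outdir / nuis_name, sep="\t", index=False)
    return bold_name, nuis_name


def write_dataset(spec: PhantomSpec, outdir: Path) -> Path:
    """Simulate and write a complete phantom dataset; returns outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geom, surface, projection = make_geometry(spec)
    truth = plant_design(spec, geom)
    write_geometry(geom, surface, projection, outdir)
    write_ground_truth(truth, geom, outdir)
    (outdir / "phantom_spec.json").write_text(spec.to_json())
    manifest_rows = []
    for s in range(spec.n_subjects):
        for r in range(spec.runs_for_subject(s)):
            run = simulate_run(spec, geom, truth, s, r)
            bold_name, nuis_name = write_run(run, geom, outdir)
            manifest_rows.append(
                {
                    "subject_id": subject_label(s),
                    "session_id": 1,
                    "run_id": run_label(r),
                    "n_frames": spec.frames_per_run,
                    "tr_seconds": spec.tr_seconds,
                    "bold_path": bold_name,
                    "nuisance_path": nuis_name,
                }
            )
    pd.DataFrame(manifest_rows).to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    return outdir


def load_spec(indir: Path) -> PhantomSpec:
    return PhantomSpec.from_dict(
        json.loads((Path(indir) / "phantom_spec.json").read_text())
    )


def load_manifest(indir: Path) -> pd.DataFrame:
    return pd.read_csv(Path(indir) / "manifest.tsv", sep="\t")


def load_geometry(indir: Path) -> tuple[VolumeGeometry, SurfaceModel, ProjectionMap]:
    """Rebuild geometry/surface/projection objects from the TSV layout."""
    indir = Path(indir)
    mask = np.asarray(
        nib.load(str(indir / "mask.nii.gz")).dataobj, dtype=np.uint8
    ).astype(bool)
    atlas = np.asarray(nib.load(str(indir / "atlas.nii.gz")).dataobj, dtype=int)
    areas = pd.read_csv(indir / "areas.tsv", sep="\t").rename(
        columns={"region_name": "region"}
    )
    coords = np.argwhere(mask)
    nx = mask.shape[0] // 2
    hemisphere = np.where(coords[:, 0] < nx, "left", "right").astype(object)
    area_label = atlas[coords[:, 0], coords[:, 1], coords[:, 2]]
    geom = VolumeGeometry(
        shape=mask.shape, mask=mask, coords=coords, hemisphere=hemisphere,
        area_label=area_label, areas=areas,
    )
    row_vol = geom.voxel_row_volume()
    seeds_df = pd.read_csv(indir / "seeds.tsv", sep="\t")
    seed_voxels = {}
    for (seed, hemi), df in seeds_df.groupby(["seed", "hemisphere"], sort=True):
        seed_voxels[(seed, hemi)] = row_vol[df["i"], df["j"], df["k"]]
    geom.seed_voxels = seed_voxels
    proj_df = pd.read_csv(indir / "projection.tsv", sep="\t").sort_values("vertex_id")
    vertex_source = row_vol[proj_df["i"], proj_df["j"], proj_df["k"]]
    projection = ProjectionMap(vertex_source=vertex_source)
    id_to_name = dict(zip(areas["area_id"], areas["area_name"]))
    id_to_region = dict(zip(areas["area_id"], areas["region"]))
    src_area = area_label[vertex_source]
    surface = SurfaceModel(
        vertices=pd.DataFrame(
            {
                "vertex_id": np.arange(vertex_source.size),
                "hemisphere": hemisphere[vertex_source],
                "region": [id_to_region[a] for a in src_area],
                "area_id": src_area,
                "area_name": [id_to_name[a] for a in src_area],
            }
        )
    )
    return geom, surface, projection


def load_ground_truth(indir: Path, geom: VolumeGeometry) -> GroundTruth:
    df = pd.read_csv(Path(indir) / "ground_truth.tsv", sep="\t")
    loadings = df[["w_a", "w_m", "w_p"]].to_numpy(dtype=float)
    codes = np.array([CATEGORIES.index(c) for c in df["category"]], dtype=np.int8)
    return GroundTruth(
        loadings=loadings,
        true_category=codes,
        wm_coupling=np.ones(geom.n_voxels),
        csf_coupling=np.ones(geom.n_voxels),
    )


def load_run(indir: Path, row: pd.Series, geom: VolumeGeometry) -> RunTimeSeries:
    indir = Path(indir)
    img = nib.load(str(indir / row["bold_path"]))
    vol4d = np.asarray(img.dataobj, dtype=np.float32)
    data = vol4d[geom.coords[:, 0], geom.coords[:, 1], geom.coords[:, 2], :].T
    nuis = pd.read_csv(indir / row["nuisance_path"], sep="\t")
    return RunTimeSeries(
        data=np.asarray(data, dtype=float),
        tr_seconds=float(row["tr_seconds"]),
        subject_id=str(row["subject_id"]),
        run_id=str(row["run_id"]),
        nuisance={"wm": nuis["wm"].to_numpy(), "csf": nuis["csf"].to_numpy()},
        fd=nuis["fd"].to_numpy(),
    )
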