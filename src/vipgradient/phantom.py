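"""Synthetic multi-subject resting-state phantom with planted connectivity.

The phantom stands in for a macaque resting-state dataset: a two-
hemisphere voxel grid carved into 8 lobar regions and a configurable
number of atlas areas per region, a ribbon of area VIP along the
intraparietal sulcus hosting the three seed ROIs, and multi-run 4D
time series in which every voxel loads on up to three band-limited
latent signals (one per seed sector).  The zero-pattern of each area's
loading triple (w_a, w_m, w_p) defines its true seed-overlap category
(NONE..AMP), which the full analysis pipeline must recover.

Signal model per voxel v and frame t::

    y_v(t) = w_a s_a(t) + w_m s_m(t) + w_p s_p(t)
             + g_amp * g(t) + wm_amp * c_v * n_wm(t) + csf_amp * d_v * n_csf(t)
             + spike(t) + eps_v(t)

with s_k and g independent band-limited Gaussian processes (white
noise -> hard DFT band mask -> unit-variance rescale), n_wm / n_csf
white nuisance traces with per-voxel couplings c_v, d_v, shared
motion-spike offsets at randomly chosen frames, and white Gaussian
noise eps.  The framewise-displacement trace is elevated exactly at
spike frames, so scrubbing at the default threshold removes them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import SEEDS, DEFAULT_SEED_SCHEME, build_seed_rois
from .preprocess import MIN_FRAMES, RunTimeSeries
from .surface import (
    CATEGORIES,
    _BITS_TO_CODE,
    HEMISPHERES,
    ProjectionMap,
    REGIONS,
    SurfaceModel,
)

_REGION_PREFIX = {
    "orbitofrontal": "OF",
    "prefrontal": "PF",
    "motor/premotor": "MOT",
    "cingulate": "CG",
    "limbic": "LB",
    "temporal": "TMP",
    "parietal": "PAR",
    "occipital": "OCC",
}

#: VIP ribbon extent: consecutive coronal slices needed by the seed scheme
_VIP_SLICES = sum(n for n, _ in DEFAULT_SEED_SCHEME.values())
_VIP_XW, _VIP_ZW = 3, 2  # in-slice cross-section (6 voxels/slice)

#: loading triples cycled over areas when no curated design applies
_PATTERN = [
    (0.0, 0.0, 0.0),   # NONE
    (0.8, 0.0, 0.0),   # A
    (0.6, 0.6, 0.0),   # AM
    (0.0, 0.8, 0.0),   # M
    (0.5, 0.0, 0.5),   # AP
    (0.0, 0.6, 0.6),   # MP
    (0.5, 0.5, 0.5),   # AMP
    (0.0, 0.0, 0.8),   # P
]

#: loading weight planted at each seed's own voxels (maximal in any design)
SEED_SELF_WEIGHT = 1.0


class SizingError(ValueError):
    """Grid too small to host the requested parcellation."""


def default_area_design(areas_per_region: int = 2) -> dict[str, tuple]:
    """Area-name -> (w_a, w_m, w_p) loading design.

    The default two-areas-per-region design plants the qualitative
    layout the analysis is meant to detect: anterior-seed territory in
    prefrontal/motor cortex, posterior-seed territory in occipito-
    temporal cortex, mixed AM / MP belts between them, a three-seed
    (AMP) core in parietal cortex, and unconnected (NONE) areas.  VIP
    itself is connected to all three seeds.
    """
    design: dict[str, tuple] = {}
    if areas_per_region == 2:
        curated = {
            "OF1": (0.0, 0.0, 0.0), "OF2": (0.8, 0.0, 0.0),
            "PF1": (0.8, 0.0, 0.0), "PF2": (0.6, 0.6, 0.0),
            "MOT1": (0.8, 0.0, 0.0), "MOT2": (0.6, 0.6, 0.0),
            "CG1": (0.0, 0.0, 0.0), "CG2": (0.0, 0.8, 0.0),
            "LB1": (0.0, 0.0, 0.0), "LB2": (0.5, 0.0, 0.5),
            "TMP1": (0.0, 0.0, 0.8), "TMP2": (0.0, 0.6, 0.6),
            "PAR1": (0.5, 0.5, 0.5), "PAR2": (0.6, 0.6, 0.0),
            "OCC1": (0.0, 0.0, 0.8), "OCC2": (0.0, 0.6, 0.6),
        }
        design.update(curated)
    else:
        for r, region in enumerate(REGIONS):
            prefix = _REGION_PREFIX[region]
            for j in range(areas_per_region):
                design[f"{prefix}{j + 1}"] = _PATTERN[
                    (r * areas_per_region + j) % len(_PATTERN)
                ]
    design["VIP"] = (0.8, 0.8, 0.8)
    return design


@dataclass
class PhantomSpec:
    """Study conditions for one phantom dataset.

    Defaults emulate the acquisition scale of a 10-monkey resting-state
    study (TR 2 s, 300-frame runs) on a 24x24x18-per-hemisphere grid
    (~20k voxels) with 2 areas per lobar region plus area VIP.
    """

    n_subjects: int = 10
    runs_per_subject: int | list = 8
    frames_per_run: int = 300
    tr_seconds: float = 2.0
    grid_dims: tuple[int, int, int] = (24, 24, 18)
    seed_size: int = 20
    areas_per_region: int = 2
    area_design: dict | None = None
    latent_band: tuple[float, float] = (0.01, 0.1)
    noise_sd: float = 1.0
    global_amp: float = 0.1
    wm_amp: float = 0.5
    csf_amp: float = 0.5
    spike_prob: float = 0.02
    loading_jitter: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.tr_seconds not in (1.4, 2.0):
            raise ValueError("tr_seconds must be 1.4 or 2.0")
        if self.frames_per_run < MIN_FRAMES:
            raise ValueError(f"frames_per_run must be >= {MIN_FRAMES}")
        for name in ("noise_sd", "global_amp", "wm_amp", "csf_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.spike_prob < 1):
            raise ValueError("spike_prob must be in [0, 1)")
        low, high = self.latent_band
        nyquist = 0.5 / self.tr_seconds
        if not (0 < low < high < nyquist):
            raise ValueError(
                f"latent_band must lie inside (0, {nyquist}) for TR "
                f"{self.tr_seconds} s"
            )
        if isinstance(self.runs_per_subject, (list, tuple)):
            self.runs_per_subject = list(self.runs_per_subject)
            if len(self.runs_per_subject) != self.n_subjects:
                raise ValueError("runs_per_subject list length != n_subjects")
        if self.area_design is None:
            self.area_design = default_area_design(self.areas_per_region)
        for name, triple in self.area_design.items():
            if len(triple) != 3 or any(w < 0 for w in triple):
                raise ValueError(f"invalid loading triple for area {name!r}")

    def runs_for_subject(self, subject_idx: int) -> int:
        if isinstance(self.runs_per_subject, list):
            return int(self.runs_per_subject[subject_idx])
        return int(self.runs_per_subject)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["grid_dims"] = list(self.grid_dims)
        d["latent_band"] = list(self.latent_band)
        d["area_design"] = {k: list(v) for k, v in self.area_design.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if "grid_dims" in d:
            d["grid_dims"] = tuple(d["grid_dims"])
        if "latent_band" in d:
            d["latent_band"] = tuple(d["latent_band"])
        if d.get("area_design"):
            d["area_design"] = {k: tuple(v) for k, v in d["area_design"].items()}
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


@dataclass
class VolumeGeometry:
    """Masked two-hemisphere voxel grid with atlas labels and seed ROIs.

    In-mask voxels are stored in a fixed row ordering (C-order over the
    full grid); all per-voxel arrays in the package follow it.
    """

    shape: tuple[int, int, int]
    mask: np.ndarray
    coords: np.ndarray            # (n_vox, 3) int
    hemisphere: np.ndarray        # (n_vox,) 'left'/'right'
    area_label: np.ndarray        # (n_vox,) int area_id
    areas: pd.DataFrame           # area_id, area_name, region, hemisphere
    seed_voxels: dict = field(default_factory=dict)

    @property
    def n_voxels(self) -> int:
        return self.coords.shape[0]

    def hemisphere_mask(self, hemisphere: str) -> np.ndarray:
        return self.hemisphere == hemisphere

    def area_id(self, area_name: str, hemisphere: str) -> int:
        rows = self.areas[
            (self.areas["area_name"] == area_name)
            & (self.areas["hemisphere"] == hemisphere)
        ]
        if rows.empty:
            raise KeyError(f"no area {area_name!r} in {hemisphere} hemisphere")
        return int(rows["area_id"].iloc[0])

    def vip_voxel_rows(self, hemisphere: str) -> np.ndarray:
        return np.flatnonzero(self.area_label == self.area_id("VIP", hemisphere))

    def voxel_row_volume(self) -> np.ndarray:
        """3-D int volume mapping grid position -> in-mask row (-1 outside)."""
        vol = np.full(self.shape, -1, dtype=int)
        vol[self.coords[:, 0], self.coords[:, 1], self.coords[:, 2]] = np.arange(
            self.n_voxels
        )
        return vol

    def scatter(self, values: np.ndarray, fill=np.nan) -> np.ndarray:
        """Per-voxel vector -> 3-D volume (fill outside the mask)."""
        vol = np.full(self.shape, fill, dtype=float)
        vol[self.coords[:, 0], self.coords[:, 1], self.coords[:, 2]] = values
        return vol


@dataclass
class GroundTruth:
    """Planted per-voxel loadings and the implied true category.

    ``latent_signals`` and ``spike_frames`` are filled per simulated
    run, keyed by (subject_id, run_id), so tests can compare recovered
    quantities against the exact planted traces.
    """

    loadings: np.ndarray          # (n_vox, 3) >= 0
    true_category: np.ndarray     # (n_vox,) int8 code into CATEGORIES
    wm_coupling: np.ndarray
    csf_coupling: np.ndarray
    latent_signals: dict = field(default_factory=dict)
    spike_frames: dict = field(default_factory=dict)

    def category_names(self) -> np.ndarray:
        return np.asarray(CATEGORIES, dtype=object)[self.true_category]


def category_codes_from_loadings(loadings: np.ndarray) -> np.ndarray:
    """Seed-overlap category code from the zero-pattern of loadings."""
    loadings = np.asarray(loadings, dtype=float)
    bits = (
        (loadings[:, 0] > 0).astype(np.int8)
        + 2 * (loadings[:, 1] > 0).astype(np.int8)
        + 4 * (loadings[:, 2] > 0).astype(np.int8)
    )
    return _BITS_TO_CODE[bits]


def make_geometry(
    spec: PhantomSpec,
) -> tuple[VolumeGeometry, SurfaceModel, ProjectionMap]:
    """Deterministic geometry, atlas, seed ROIs, surface and projection.

    Each hemisphere's grid is split into 8 coronal slabs (the lobar
    regions, anterior to posterior) subdivided dorso-ventrally into
    ``areas_per_region`` areas; a VIP ribbon spanning the consecutive
    coronal slices required by the seed scheme is carved out of the
    middle of the grid and assigned to the parietal region.  Each
    in-mask voxel feeds one or two surface vertices (alternating), and
    every vertex has exactly one source voxel.
    """
    nx, ny, nz = spec.grid_dims
    app = spec.areas_per_region
    if ny < max(8, _VIP_SLICES):
        raise SizingError(
            f"grid depth ny={ny} too small: needs >= {max(8, _VIP_SLICES)} "
            "coronal slices for the regions and area VIP"
        )
    if nx < 4 or nz < max(2, app):
        raise SizingError(f"grid cross-section {nx}x{nz} too small for area VIP")

    shape = (2 * nx, ny, nz)
    mask = np.ones(shape, dtype=bool)
    coords = np.argwhere(mask)
    hemisphere = np.where(coords[:, 0] < nx, "left", "right").astype(object)

    # area naming and ids
    slab_names = [
        f"{_REGION_PREFIX[r]}{j + 1}" for r in REGIONS for j in range(app)
    ]
    names = slab_names + ["VIP"]
    name_region = {
        f"{_REGION_PREFIX[r]}{j + 1}": r for r in REGIONS for j in range(app)
    }
    name_region["VIP"] = "parietal"
    area_rows = []
    ids: dict[tuple[str, str], int] = {}
    next_id = 1
    for hemi in HEMISPHERES:
        for name in names:
            ids[(name, hemi)] = next_id
            area_rows.append(
                {
                    "area_id": next_id,
                    "area_name": name,
                    "region": name_region[name],
                    "hemisphere": hemi,
                }
            )
            next_id += 1
    areas = pd.DataFrame(area_rows)

    # per-voxel labels
    lx = coords[:, 0] % nx
    y, z = coords[:, 1], coords[:, 2]
    vy0 = (ny - _VIP_SLICES) // 2
    x0 = nx // 2 - 1
    z0 = max(nz // 2 - 1, 0)
    in_vip = (
        (y >= vy0) & (y < vy0 + _VIP_SLICES)
        & (lx >= x0) & (lx < x0 + _VIP_XW)
        & (z >= z0) & (z < z0 + _VIP_ZW)
    )
    region_idx = (y * len(REGIONS)) // ny
    area_j = (z * app) // nz
    area_label = np.empty(coords.shape[0], dtype=int)
    for i in range(coords.shape[0]):
        hemi = hemisphere[i]
        if in_vip[i]:
            name = "VIP"
        else:
            name = f"{_REGION_PREFIX[REGIONS[region_idx[i]]]}{area_j[i] + 1}"
        area_label[i] = ids[(name, hemi)]

    # sizing validation: every area needs a workable voxel count
    counts = pd.Series(area_label).value_counts()
    for _, row in areas.iterrows():
        n = int(counts.get(row["area_id"], 0))
        minimum = _VIP_SLICES * 5 if row["area_name"] == "VIP" else 8
        if n < minimum:
            raise SizingError(
                f"area {row['area_name']} ({row['hemisphere']}) has {n} voxels; "
                f"needs >= {minimum} — enlarge the grid or reduce areas_per_region"
            )

    geom = VolumeGeometry(
        shape=shape,
        mask=mask,
        coords=coords,
        hemisphere=np.asarray(hemisphere, dtype=object),
        area_label=area_label,
        areas=areas,
    )
    geom.seed_voxels = build_seed_rois(geom)
    for (seed, hemi), rows in geom.seed_voxels.items():
        if rows.size != spec.seed_size:
            raise SizingError(
                f"seed {seed} ({hemi}) has {rows.size} voxels, expected "
                f"{spec.seed_size}"
            )

    # projection: voxel row i feeds 1 or 2 vertices (alternating)
    vertices_per_voxel = 1 + (np.arange(geom.n_voxels) % 2)
    vertex_source = np.repeat(np.arange(geom.n_voxels), vertices_per_voxel)
    projection = ProjectionMap(vertex_source=vertex_source)

    id_to_name = dict(zip(areas["area_id"], areas["area_name"]))
    id_to_region = dict(zip(areas["area_id"], areas["region"]))
    src_area = area_label[vertex_source]
    vertices = pd.DataFrame(
        {
            "vertex_id": np.arange(vertex_source.size),
            "hemisphere": geom.hemisphere[vertex_source],
            "region": [id_to_region[a] for a in src_area],
            "area_id": src_area,
            "area_name": [id_to_name[a] for a in src_area],
        }
    )
    surface = SurfaceModel(vertices=vertices)
    return geom, surface, projection


def plant_design(spec: PhantomSpec, geom: VolumeGeometry) -> GroundTruth:
    """Assign loading triples to voxels from the area design.

    Loadings are constant within an area (up to optional multiplicative
    jitter on nonzero weights, which preserves the zero-pattern and
    hence the true category).  Seed ROI voxels load exclusively on
    their own seed's latent signal with the maximal weight, so each
    seed signal is a clean readout of its latent.
    """
    design = spec.area_design
    missing = [
        row["area_name"]
        for _, row in geom.areas.iterrows()
        if row["area_name"] not in design
    ]
    if missing:
        raise ValueError(f"area_design missing areas: {sorted(set(missing))}")
    rng = np.random.default_rng(np.random.SeedSequence([spec.rng_seed, 7]))
    loadings = np.zeros((geom.n_voxels, 3), dtype=float)
    for _, row in geom.areas.iterrows():
        triple = np.asarray(design[row["area_name"]], dtype=float)
        if np.any(triple < 0):
            raise ValueError(f"negative weight in design for {row['area_name']}")
        sel = geom.area_label == row["area_id"]
        loadings[sel] = triple
    if spec.loading_jitter > 0:
        jitter = 1.0 + spec.loading_jitter * rng.standard_normal(loadings.shape)
        loadings = np.where(loadings > 0, np.maximum(loadings * jitter, 1e-3), 0.0)
    for (seed, _hemi), rows in geom.seed_voxels.items():
        triple = np.zeros(3)
        triple[SEEDS.index(seed)] = SEED_SELF_WEIGHT
        loadings[rows] = triple
    wm_coupling = rng.uniform(0.5, 1.5, geom.n_voxels)
    csf_coupling = rng.uniform(0.5, 1.5, geom.n_voxels)
    return GroundTruth(
        loadings=loadings,
        true_category=category_codes_from_loadings(loadings),
        wm_coupling=wm_coupling,
        csf_coupling=csf_coupling,
    )


def band_limited_noise(
    n_frames: int,
    tr_seconds: float,
    band: tuple[float, float],
    rng: np.random.Generator,
    size: int = 1,
) -> np.ndarray:
    """Unit-variance Gaussian processes band-limited by a hard DFT mask.

    Returns shape (size, n_frames).  All spectral power lies inside
    [band[0], band[1]] by construction.
    """
    freqs = np.fft.rfftfreq(n_frames, d=tr_seconds)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    if not keep.any():
        raise ValueError("latent_band contains no DFT bins at this run length")
    white = rng.standard_normal((size, n_frames))
    spectrum = np.fft.rfft(white, axis=1)
    spectrum[:, ~keep] = 0.0
    x = np.fft.irfft(spectrum, n=n_frames, axis=1)
    x -= x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    return x / np.where(sd == 0, 1.0, sd)


def subject_label(subject_idx: int) -> str:
    return f"sub-{subject_idx + 1:02d}"


def run_label(run_idx: int) -> str:
    return f"run-{run_idx + 1:02d}"


def simulate_run(
    spec: PhantomSpec,
    geom: VolumeGeometry,
    truth: GroundTruth,
    subject_idx: int,
    run_idx: int,
) -> RunTimeSeries:
    """Simulate one run; reproducible given (rng_seed, subject, run)."""
    frames = spec.frames_per_run
    if frames < MIN_FRAMES:
        raise ValueError(f"frames_per_run must be >= {MIN_FRAMES}")
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.rng_seed, subject_idx, run_idx])
    )
    latents = band_limited_noise(frames, spec.tr_seconds, spec.latent_band, rng, 3)
    g = band_limited_noise(frames, spec.tr_seconds, spec.latent_band, rng, 1)[0]
    n_wm = rng.standard_normal(frames)
    n_csf = rng.standard_normal(frames)

    # one combined (frames x 6) @ (6 x n_vox) product: latent loadings,
    # global signal, and the two coupled nuisance sources
    sources = np.vstack([latents, g, n_wm, n_csf])          # (6, frames)
    weights = np.column_stack([
        truth.loadings,
        np.full(truth.loadings.shape[0], spec.global_amp),
        spec.wm_amp * truth.wm_coupling,
        spec.csf_amp * truth.csf_coupling,
    ])                                                       # (n_vox, 6)
    data = sources.T @ weights.T                             # (frames, n_vox)
    if spec.noise_sd > 0:
        # float32 draws halve generation time; accumulation stays float64
        data += spec.noise_sd * rng.standard_normal(data.shape, dtype=np.float32)

    spikes = np.flatnonzero(rng.random(frames) < spec.spike_prob)
    fd = rng.uniform(0.02, 0.3, frames)
    if spikes.size:
        amp = 8.0 * max(spec.noise_sd, 0.5) * rng.standard_normal(spikes.size)
        data[spikes] += amp[:, None]
        fd[spikes] = 1.0 + rng.uniform(0.0, 0.5, spikes.size)

    sub, run = subject_label(subject_idx), run_label(run_idx)
    truth.latent_signals[(sub, run)] = latents
    truth.spike_frames[(sub, run)] = spikes
    return RunTimeSeries(
        data=data,
        tr_seconds=spec.tr_seconds,
        subject_id=sub,
        run_id=run,
        nuisance={"wm": n_wm, "csf": n_csf},
        fd=fd,
    )


@dataclass
class RecoveryReport:
    """Category-recovery summary of the pipeline on the phantom."""

    accuracy: float
    confusion: pd.DataFrame       # rows = truth, cols = estimated
    sensitivity: pd.Series        # per-category recall (NaN if absent)
    n_vertices: int


def score_recovery(
    estimated, truth: GroundTruth, projection: ProjectionMap
) -> RecoveryReport:
    """Compare an estimated vertex category map against the planted truth.

    The truth is carried to the surface through each vertex's unique
    source voxel.  Confusion rows sum to the per-category truth counts.
    """
    est = np.asarray(estimated.category, dtype=int)
    if est.size != projection.n_vertices:
        raise ValueError(
            f"estimated map has {est.size} vertices, projection has "
            f"{projection.n_vertices}"
        )
    true_v = truth.true_category[projection.vertex_source].astype(int)
    accuracy = float((est == true_v).mean())
    k = len(CATEGORIES)
    confusion = np.zeros((k, k), dtype=int)
    np.add.at(confusion, (true_v, est), 1)
    confusion_df = pd.DataFrame(
        confusion, index=list(CATEGORIES), columns=list(CATEGORIES)
    )
    totals = confusion.sum(axis=1)
    with np.errstate(invalid="ignore"):
        sens = np.where(totals > 0, np.diag(confusion) / np.maximum(totals, 1), np.nan)
    sensitivity = pd.Series(sens, index=list(CATEGORIES))
    return RecoveryReport(
        accuracy=accuracy,
        confusion=confusion_df,
        sensitivity=sensitivity,
        n_vertices=est.size,
    )
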