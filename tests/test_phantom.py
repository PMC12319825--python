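"""Phantom generator: geometry partitions, planted truth, signal model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vipgradient import connectivity as conn
from vipgradient.phantom import (
    GroundTruth,
    PhantomSpec,
    RecoveryReport,
    SizingError,
    band_limited_noise,
    category_codes_from_loadings,
    default_area_design,
    make_geometry,
    plant_design,
    score_recovery,
    simulate_run,
)
from vipgradient.preprocess import FilterSettings, scrub
from vipgradient.surface import CATEGORIES, CategoryMap, ProjectionMap


class TestGeometry:
    def test_every_seed_roi_has_twenty_voxels(self, small_geometry, small_spec):
        geom, _, _ = small_geometry
        assert len(geom.seed_voxels) == 6
        for (seed, hemi), rows in geom.seed_voxels.items():
            assert rows.size == small_spec.seed_size == 20

    def test_areas_partition_the_mask(self, small_geometry):
        geom, _, _ = small_geometry
        # every in-mask voxel carries exactly one valid area label
        valid_ids = set(geom.areas["area_id"])
        assert set(np.unique(geom.area_label)) <= valid_ids
        sizes = pd.Series(geom.area_label).value_counts()
        assert sizes.sum() == geom.n_voxels
        # disjointness is implied by a single label per voxel; check
        # that both hemispheres and all areas are populated
        assert set(geom.hemisphere) == {"left", "right"}
        assert sizes.min() >= 8

    def test_seed_voxels_carry_vip_label(self, small_geometry):
        geom, _, _ = small_geometry
        for (seed, hemi), rows in geom.seed_voxels.items():
            assert np.all(geom.area_label[rows] == geom.area_id("VIP", hemi))

    def test_projection_bijectivity(self, small_geometry):
        geom, surface, projection = small_geometry
        # every vertex has exactly one source voxel by construction;
        # every in-mask voxel feeds at least one vertex
        assert projection.n_vertices == surface.n_vertices
        covered = np.unique(projection.vertex_source)
        assert covered.size == geom.n_voxels

    def test_every_area_belongs_to_one_region(self, small_geometry):
        _, surface, _ = small_geometry
        per_area = surface.vertices.groupby("area_id")["region"].nunique()
        assert (per_area == 1).all()

    def test_deterministic_for_fixed_spec(self, small_spec, small_geometry):
        geom1, _, proj1 = small_geometry
        geom2, _, proj2 = make_geometry(small_spec)
        assert np.array_equal(geom1.area_label, geom2.area_label)
        assert np.array_equal(proj1.vertex_source, proj2.vertex_source)
        for key in geom1.seed_voxels:
            assert np.array_equal(geom1.seed_voxels[key], geom2.seed_voxels[key])

    def test_too_small_grid_names_offending_area(self):
        with pytest.raises(SizingError):
            make_geometry(PhantomSpec(grid_dims=(4, 13, 2), areas_per_region=2))
        with pytest.raises(SizingError, match="coronal slices"):
            make_geometry(PhantomSpec(grid_dims=(10, 10, 6)))


class TestPlantDesign:
    def test_category_follows_zero_pattern(self, small_truth):
        codes = category_codes_from_loadings(small_truth.loadings)
        assert np.array_equal(codes, small_truth.true_category)

    @pytest.mark.parametrize(
        "triple, expected",
        [((1.0, 0.0, 0.0), "A"), ((0.5, 0.5, 0.5), "AMP"), ((0.0, 0.0, 0.0), "NONE"),
         ((0.0, 0.3, 0.3), "MP")],
    )
    def test_planted_triples_map_to_categories(
        self, small_spec, small_geometry, triple, expected
    ):
        geom, _, _ = small_geometry
        design = {name: triple for name in small_spec.area_design}
        spec = PhantomSpec.from_dict(
            {**small_spec.to_dict(), "area_design": design}
        )
        truth = plant_design(spec, geom)
        seed_rows = np.concatenate(list(geom.seed_voxels.values()))
        non_seed = np.setdiff1d(np.arange(geom.n_voxels), seed_rows)
        names = truth.category_names()[non_seed]
        assert set(names) == {expected}

    def test_negative_weight_rejected(self, small_spec):
        with pytest.raises(ValueError):
            PhantomSpec.from_dict(
                {**small_spec.to_dict(),
                 "area_design": {
                     **small_spec.area_design, "PF1": (-0.1, 0.0, 0.0)}}
            )

    def test_seed_voxels_load_only_their_own_latent(self, small_geometry, small_truth):
        geom, _, _ = small_geometry
        max_w = small_truth.loadings.max()
        for (seed, hemi), rows in geom.seed_voxels.items():
            idx = conn.SEEDS.index(seed)
            w = small_truth.loadings[rows]
            assert np.all(w[:, idx] == max_w)
            other = [j for j in range(3) if j != idx]
            assert np.all(w[:, other] == 0)

    def test_jitter_preserves_category(self, small_spec, small_geometry):
        geom, _, _ = small_geometry
        spec = PhantomSpec.from_dict(
            {**small_spec.to_dict(), "loading_jitter": 0.2}
        )
        truth0 = plant_design(small_spec, geom)
        truth = plant_design(spec, geom)
        assert np.array_equal(truth.true_category, truth0.true_category)
        assert not np.allclose(truth.loadings, truth0.loadings)


class TestSimulateRun:
    def test_reproducible_per_subject_run(self, small_spec, small_geometry, small_truth):
        geom, _, _ = small_geometry
        r1 = simulate_run(small_spec, geom, small_truth, 1, 2)
        r2 = simulate_run(small_spec, geom, small_truth, 1, 2)
        r3 = simulate_run(small_spec, geom, small_truth, 1, 3)
        assert np.array_equal(r1.data, r2.data)
        assert not np.array_equal(r1.data, r3.data)

    def test_noiseless_voxel_equals_its_latent(self, noiseless_spec):
        geom, _, _ = make_geometry(noiseless_spec)
        truth = plant_design(noiseless_spec, geom)
        run = simulate_run(noiseless_spec, geom, truth, 0, 0)
        latents = truth.latent_signals[("sub-01", "run-01")]
        # an aVIP seed voxel has loadings (1, 0, 0): its series is s_a
        v = geom.seed_voxels[("aVIP", "left")][0]
        assert np.allclose(run.data[:, v], latents[0], atol=1e-10)
        r = np.corrcoef(run.data[:, v], latents[0])[0, 1]
        assert r == pytest.approx(1.0)

    def test_null_voxel_correlations_are_small(self, null_spec):
        """Monte-Carlo null: |r| with a latent < 3/sqrt(frames) in ~99%."""
        geom, _, _ = make_geometry(null_spec)
        truth = plant_design(null_spec, geom)
        run = simulate_run(null_spec, geom, truth, 0, 0)
        latents = truth.latent_signals[("sub-01", "run-01")]
        zero_rows = np.flatnonzero(truth.loadings.sum(axis=1) == 0)
        x = run.data[:, zero_rows]
        xc = x - x.mean(axis=0)
        s = latents[0] - latents[0].mean()
        r = (s @ xc) / (
            np.linalg.norm(s) * np.linalg.norm(xc, axis=0)
        )
        bound = 3.0 / np.sqrt(run.n_frames)
        assert (np.abs(r) < bound).mean() > 0.98

    def test_spike_count_within_binomial_interval(self, small_geometry, small_truth):
        geom, _, _ = small_geometry
        spec = PhantomSpec(
            n_subjects=1, runs_per_subject=20, grid_dims=(10, 16, 6),
            areas_per_region=1, spike_prob=0.05, rng_seed=31,
        )
        total = 0
        n_frames = 0
        for r in range(20):
            run = simulate_run(spec, geom, small_truth, 0, r)
            total += small_truth.spike_frames[("sub-01", f"run-{r + 1:02d}")].size
            n_frames += run.n_frames
        lo, hi = stats.binom.interval(0.99, n_frames, 0.05)
        assert lo <= total <= hi

    def test_fd_elevated_exactly_at_spike_frames(self, small_spec, small_geometry,
                                                 small_truth):
        geom, _, _ = small_geometry
        run = simulate_run(small_spec, geom, small_truth, 2, 0)
        spikes = small_truth.spike_frames[("sub-03", "run-01")]
        scrubbed = scrub(run, FilterSettings())
        assert np.array_equal(np.flatnonzero(~scrubbed.censor), spikes)

    def test_latent_power_confined_to_band(self, small_spec, rng):
        x = band_limited_noise(300, 2.0, (0.01, 0.1), rng, size=3)
        freqs = np.fft.rfftfreq(300, d=2.0)
        spec_power = np.abs(np.fft.rfft(x, axis=1)) ** 2
        in_band = (freqs >= 0.01) & (freqs <= 0.1)
        frac = spec_power[:, in_band].sum(axis=1) / spec_power.sum(axis=1)
        assert np.all(frac >= 0.95)
        assert np.allclose(x.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(x.std(axis=1), 1, atol=1e-12)

    def test_too_few_frames_refused(self):
        with pytest.raises(ValueError):
            PhantomSpec(frames_per_run=32)


class TestScoreRecovery:
    def _identity_setup(self, n=40):
        rng = np.random.default_rng(5)
        codes = rng.integers(0, 8, n).astype(np.int8)
        loadings = np.zeros((n, 3))
        # loadings consistent with codes (bit pattern of the code's name)
        for i, c in enumerate(codes):
            name = CATEGORIES[c]
            loadings[i] = [
                0.5 if "A" in name and name != "NONE" else 0.0,
                0.5 if "M" in name else 0.0,
                0.5 if "P" in name and name != "NONE" else 0.0,
            ]
        codes = category_codes_from_loadings(loadings)
        truth = GroundTruth(
            loadings=loadings, true_category=codes,
            wm_coupling=np.ones(n), csf_coupling=np.ones(n),
        )
        projection = ProjectionMap(vertex_source=np.arange(n))
        return truth, projection, codes

    def test_perfect_estimate_scores_one(self):
        truth, projection, codes = self._identity_setup()
        est = CategoryMap(category=codes, threshold_used=0.05)
        rep = score_recovery(est, truth, projection)
        assert isinstance(rep, RecoveryReport)
        assert rep.accuracy == 1.0
        off_diag = rep.confusion.to_numpy() - np.diag(np.diag(rep.confusion))
        assert off_diag.sum() == 0

    def test_confusion_rows_sum_to_truth_counts(self):
        truth, projection, codes = self._identity_setup()
        rng = np.random.default_rng(6)
        est = CategoryMap(
            category=rng.integers(0, 8, codes.size).astype(np.int8),
            threshold_used=0.05,
        )
        rep = score_recovery(est, truth, projection)
        row_sums = rep.confusion.sum(axis=1)
        for c, name in enumerate(CATEGORIES):
            assert row_sums[name] == int((codes == c).sum())

    def test_totally_wrong_estimate_scores_zero(self):
        n = 10
        loadings = np.tile([0.5, 0.0, 0.0], (n, 1))
        truth = GroundTruth(
            loadings=loadings,
            true_category=category_codes_from_loadings(loadings),
            wm_coupling=np.ones(n), csf_coupling=np.ones(n),
        )
        projection = ProjectionMap(vertex_source=np.arange(n))
        est = CategoryMap(category=np.zeros(n, dtype=np.int8), threshold_used=0.05)
        assert score_recovery(est, truth, projection).accuracy == 0.0

    def test_mismatched_vertex_sets_rejected(self):
        truth, projection, codes = self._identity_setup()
        est = CategoryMap(category=codes[:-1], threshold_used=0.05)
        with pytest.raises(ValueError):
            score_recovery(est, truth, projection)


def test_null_phantom_false_positive_calibration(null_spec):
    """With zero loadings, per-subject p < 0.001 flags at most ~0.5% of
    null voxels on average (5x the nominal two-sided alpha)."""
    geom, _, _ = make_geometry(null_spec)
    truth = plant_design(null_spec, geom)
    fs = FilterSettings()
    from vipgradient.preprocess import preprocess_run

    zero_rows = np.flatnonzero(truth.loadings.sum(axis=1) == 0)
    fractions = []
    for s in range(null_spec.n_subjects):
        maps = []
        for r in range(null_spec.runs_for_subject(s)):
            run = preprocess_run(
                simulate_run(null_spec, geom, truth, s, r), fs
            )
            sig = conn.extract_seed_signal(
                run, geom.seed_voxels[("aVIP", "left")], "aVIP", "left"
            )
            maps.append(conn.run_correlation_map(run, sig, geom))
        sub = conn.subject_aggregate(maps)
        left = geom.hemisphere_mask("left")
        null_left = np.intersect1d(zero_rows, np.flatnonzero(left))
        fractions.append(sub.sig_mask[null_left].mean())
    assert np.mean(fractions) <= 0.005
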