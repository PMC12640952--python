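"""Polar maps, AHA-16 segment model, territory statistics."""

import warnings

import numpy as np
import pytest

from ccperf import (ADJACENCY, DegenerateInputError, InputError, PhantomConfig,
                    SectorTruth, TERRITORIES, aha16_report, build_phantom,
                    build_polar_map, classify_ischemic, detect_landmarks,
                    generate_adjacency, relative_mbf, report_from_means,
                    territory_mbf)
from ccperf.mapping import PolarMap, segment_bin_map

#: canonical LAD adjacent-pair list for the right-dominant 16-segment model
LAD_PAIRS = [(1, 2), (1, 7), (1, 8), (2, 7), (2, 8), (7, 8),
             (13, 14), (7, 13), (8, 13), (8, 14)]


@pytest.fixture(scope="module")
def uniform_polar(clean_study):
    masks = clean_study.truth["masks"]
    lm = detect_landmarks(clean_study.frames[-1], masks, septal_angle_deg=300.0)
    return build_polar_map(clean_study.truth["mbf_map"], masks, lm)


class TestStructure:
    def test_lad_adjacency_matches_canonical_list(self):
        assert set(map(frozenset, ADJACENCY["LAD"])) == \
            set(map(frozenset, LAD_PAIRS))
        assert len(ADJACENCY["LAD"]) == 10

    def test_generator_reproduces_shipped_lists(self):
        for t in TERRITORIES:
            assert generate_adjacency(t) == ADJACENCY[t]

    def test_territories_partition_16_segments(self):
        segs = sorted(s for t in TERRITORIES.values() for s in t)
        assert segs == list(range(1, 17))

    def test_segment_bin_areas(self):
        """Basal/mid segments span 60 deg, apical 90 deg; rings cover 360."""
        segmap = segment_bin_map(24, 72)
        counts = {s: int((segmap == s).sum()) for s in range(1, 17)}
        for s in range(1, 13):
            assert counts[s] == 8 * 12     # 8 radius rows x 60 deg
        for s in range(13, 17):
            assert counts[s] == 8 * 18     # 8 radius rows x 90 deg
        assert (segmap > 0).all()

    def test_apical_cap_absent(self, uniform_polar):
        report = aha16_report(uniform_polar)
        assert list(report.segments.segment) == list(range(1, 17))
        assert 17 not in set(report.segments.segment)


class TestPolarMap:
    def test_uniform_phantom_uniform_map(self, uniform_polar):
        sampled = uniform_polar.raster[np.isfinite(uniform_polar.raster)]
        assert np.abs(sampled - 300.0).max() / 300.0 < 0.01

    def test_mean_preserved_within_5_percent(self, clean_study):
        masks = clean_study.truth["masks"]
        lm = detect_landmarks(clean_study.frames[-1], masks,
                              septal_angle_deg=300.0)
        mbf = clean_study.truth["mbf_map"]
        polar = build_polar_map(mbf, masks, lm)
        vox_mean = np.nanmean(mbf[masks.myocardium])
        polar_mean = np.nanmean(polar.raster)
        assert abs(polar_mean - vox_mean) / vox_mean < 0.05

    def test_deficit_localizes_to_matching_angles(self):
        """A 150-flow wedge at source angles [300, 360) lands in polar angle
        bins [0, 60) (origin = anterior insertion at 300 deg), +/-1 bin."""
        cfg = PhantomConfig(
            noise_sd_hu=0.0, motion_amplitude_vox=0,
            sectors=(SectorTruth(300, 360, 0, 10 ** 6, 150.0, 2.0, 0.15),
                     SectorTruth(0, 300, 0, 10 ** 6, 300.0, 2.0, 0.15)))
        study = build_phantom(cfg, seed=1)
        masks = study.truth["masks"]
        lm = detect_landmarks(study.frames[-1], masks, septal_angle_deg=300.0)
        polar = build_polar_map(study.truth["mbf_map"], masks, lm)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
            col = np.nanmean(polar.raster, axis=0)
        binw = 360.0 / polar.n_angle
        low_bins = np.nonzero(col < 225.0)[0]
        assert low_bins.size
        assert low_bins.min() * binw >= 0.0 - binw
        assert (low_bins.max() + 1) * binw <= 60.0 + binw

    def test_empty_map_rejected(self, clean_study):
        masks = clean_study.truth["masks"]
        lm = detect_landmarks(clean_study.frames[-1], masks,
                              septal_angle_deg=0.0)
        with pytest.raises(DegenerateInputError):
            build_polar_map(np.full(masks.labels.shape, np.nan), masks, lm)


class TestAHAReport:
    def test_fully_sampled_uniform_report(self, uniform_polar):
        report = aha16_report(uniform_polar)
        assert len(report.segments) == 16
        assert not report.segments.excluded.any()
        np.testing.assert_allclose(report.segments.mean_mbf, 300.0)
        assert report.global_mean_mbf == pytest.approx(300.0)

    def test_30_percent_exclusion_rule(self, uniform_polar):
        segmap = segment_bin_map(uniform_polar.n_radius, uniform_polar.n_angle)
        raster = uniform_polar.raster.copy()
        bins = np.argwhere(segmap == 13)
        keep = len(bins) - int(np.ceil(0.75 * len(bins)))
        for r, a in bins[keep:]:
            raster[r, a] = np.nan
        report = aha16_report(PolarMap(raster, uniform_polar.n_radius,
                                       uniform_polar.n_angle))
        assert report.excluded(13)
        assert not report.segments.loc[report.segments.segment != 13,
                                       "excluded"].any()

    def test_60_degree_rotation_permutes_ring_segments(self, uniform_polar):
        """Rotating the raster by one sextant cycles basal and mid means."""
        rng = np.random.default_rng(0)
        raster = uniform_polar.raster * rng.uniform(0.5, 1.5,
                                                    uniform_polar.raster.shape)
        polar = PolarMap(raster, uniform_polar.n_radius, uniform_polar.n_angle)
        base = aha16_report(polar)
        rot = aha16_report(polar.rotated(60.0))
        cycle_basal = {2: 3, 3: 4, 4: 5, 5: 6, 6: 1, 1: 2}
        cycle_mid = {8: 9, 9: 10, 10: 11, 11: 12, 12: 7, 7: 8}
        for a, b in list(cycle_basal.items()) + list(cycle_mid.items()):
            assert rot.mean(b) == pytest.approx(base.mean(a), rel=1e-12)

    def test_all_excluded_rejected(self, uniform_polar):
        empty = PolarMap(np.full_like(uniform_polar.raster, np.nan),
                         uniform_polar.n_radius, uniform_polar.n_angle)
        with pytest.raises(DegenerateInputError):
            aha16_report(empty)


class TestTerritoryMBF:
    def test_uniform_lad_value(self):
        report = report_from_means({s: 300.0 for s in range(1, 17)})
        t = territory_mbf(report, "LAD")
        assert t.value == pytest.approx(300.0)
        assert tuple(sorted(t.pair)) in set(ADJACENCY["LAD"])

    def test_matches_exhaustive_oracle_on_random_reports(self):
        rng = np.random.default_rng(12)
        for _ in range(1000):
            means = {s: float(rng.uniform(50, 400)) for s in range(1, 17)}
            # randomly exclude a few segments
            for s in rng.choice(np.arange(1, 17), size=rng.integers(0, 4),
                                replace=False):
                means[int(s)] = np.nan
            report = report_from_means(means)
            for terr, pairs in ADJACENCY.items():
                cand = [0.5 * (means[a] + means[b]) for a, b in pairs
                        if np.isfinite(means[a]) and np.isfinite(means[b])]
                got = territory_mbf(report, terr)
                if not cand:
                    assert not got.evaluable
                else:
                    assert got.value == pytest.approx(min(cand), rel=1e-12)

    def test_unevaluable_when_no_valid_pair(self):
        means = {s: 300.0 for s in range(1, 17)}
        for s in (3, 4, 9, 10, 15):     # knock out the whole RCA territory
            means[s] = np.nan
        t = territory_mbf(report_from_means(means), "RCA")
        assert not t.evaluable and np.isnan(t.value)


class TestRelativeMBF:
    def test_uniform_report_all_ones(self):
        report = relative_mbf(report_from_means({s: 300.0 for s in range(1, 17)}))
        np.testing.assert_allclose(report.segments.relative_mbf, 1.0)

    def test_scale_invariance(self):
        means = {s: float(50 + 20 * s) for s in range(1, 17)}
        r1 = relative_mbf(report_from_means(means))
        r2 = relative_mbf(report_from_means({s: 2 * v for s, v in means.items()}))
        np.testing.assert_allclose(r1.segments.relative_mbf,
                                   r2.segments.relative_mbf, rtol=1e-12)

    def test_two_territory_hand_case(self):
        """LAD segments at 200, everything else at 400: the reference is the
        400 territory, so LAD relative values are 0.5."""
        means = {s: 400.0 for s in range(1, 17)}
        for s in TERRITORIES["LAD"]:
            means[s] = 200.0
        report = relative_mbf(report_from_means(means))
        seg = report.segments.set_index("segment")
        for s in TERRITORIES["LAD"]:
            assert seg.loc[s, "relative_mbf"] == pytest.approx(0.5)
        for s in TERRITORIES["RCA"]:
            assert seg.loc[s, "relative_mbf"] == pytest.approx(1.0)


class TestIschemiaFlag:
    def test_strict_threshold_boundary(self):
        flags = classify_ischemic([199.9, 200.0, 200.1], 200.0)
        assert list(flags) == [True, False, False]

    def test_vectorized_order_preserved(self):
        vals = np.array([150.0, 250.0, 199.0, 201.0])
        np.testing.assert_array_equal(classify_ischemic(vals, 200.0),
                                      vals < 200.0)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(InputError):
            classify_ischemic([100.0], 0.0)
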