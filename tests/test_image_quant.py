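"""Segmentation, per-nucleus statistics, particle densities and group tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from conftest import match_truth_nuclei
from pchquant.image_quant import (
    IntensityGrid,
    LabelMask,
    crosslevel_summary,
    detect_particles,
    nucleus_statistics,
    region_particle_density,
    segment_nuclei,
    segment_pch_foci,
    students_t_test,
    wilcoxon_rank_test,
)
from pchquant.synthetic import simulate_cotransfection_population


def disk_image(centers, radius_px, inside=100.0, bg=20.0, shape=(120, 120)):
    img = np.full(shape, bg)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    for cy, cx in centers:
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px ** 2] = inside
    return img


class TestSegmentNuclei:
    def test_two_disks_two_labels(self):
        grid = IntensityGrid(disk_image([(30, 30), (80, 80)], 15), (0.2, 0.2), "dna")
        mask = segment_nuclei(grid)
        assert mask.n_objects == 2

    def test_blank_image_zero_labels(self):
        grid = IntensityGrid(np.full((50, 50), 7.0), (0.2, 0.2), "dna")
        assert segment_nuclei(grid).n_objects == 0

    def test_small_objects_removed(self):
        img = disk_image([(30, 30)], 15)
        img[5, 5] = 100.0  # 1 px = 0.04 um2, below the 10 um2 default
        mask = segment_nuclei(IntensityGrid(img, (0.2, 0.2), "dna"))
        assert mask.n_objects == 1

    def test_matches_simulator_truth(self, noise_free_image):
        cfg, res = noise_free_image
        seg = segment_nuclei(res.channels["dna"])
        assert seg.n_objects == res.nuclei.n_objects
        mapping = match_truth_nuclei(res.nuclei, seg)
        for tid, sid in mapping.items():
            a = res.nuclei.labels == tid
            b = seg.labels == sid
            jaccard = (a & b).sum() / (a | b).sum()
            assert jaccard >= 0.95


class TestSegmentFoci:
    def test_uniform_nucleus_no_foci(self):
        grid = IntensityGrid(disk_image([(30, 30)], 15), (0.2, 0.2), "dna")
        nuclei = segment_nuclei(grid)
        assert segment_pch_foci(grid, nuclei).n_objects == 0

    def test_three_planted_blobs_found(self):
        img = disk_image([(60, 60)], 40)
        for c in [(40, 60), (60, 40), (80, 80)]:
            img[
                (np.mgrid[:120, :120][0] - c[0]) ** 2
                + (np.mgrid[:120, :120][1] - c[1]) ** 2
                <= 9
            ] = 300.0
        grid = IntensityGrid(img, (0.2, 0.2), "dna")
        nuclei = segment_nuclei(grid)
        foci = segment_pch_foci(grid, nuclei)
        assert foci.n_objects == 3

    def test_single_voxel_speck_removed(self):
        img = disk_image([(30, 30)], 15)
        img[30, 30] = 300.0
        grid = IntensityGrid(img, (0.2, 0.2), "dna")
        nuclei = segment_nuclei(grid)
        assert segment_pch_foci(grid, nuclei, min_voxels=2).n_objects == 0

    def test_recovers_simulated_counts(self, noise_free_image):
        cfg, res = noise_free_image
        seg_nuc = segment_nuclei(res.channels["dna"])
        seg_foci = segment_pch_foci(res.channels["dna"], seg_nuc)
        assert seg_foci.n_objects == res.foci.n_objects
        mapping = match_truth_nuclei(res.nuclei, seg_nuc)
        truth_counts = res.params.set_index("nucleus_id")["n_foci"]
        for tid, sid in mapping.items():
            in_seg = np.unique(seg_foci.labels[(seg_nuc.labels == sid)])
            assert len(in_seg[in_seg != 0]) == truth_counts.loc[tid]


class TestNucleusStatistics:
    def _uniform_case(self):
        # 10x10 nucleus with a 2x2 focus, voxel 0.5 um -> sizes in um2
        labels = np.zeros((20, 20), dtype=np.int32)
        labels[5:15, 5:15] = 1
        foci = np.zeros((20, 20), dtype=np.int32)
        foci[8:10, 8:10] = 1
        grid = IntensityGrid(np.full((20, 20), 50.0), (0.5, 0.5), "ch")
        return (
            {"ch": grid},
            LabelMask(labels, "nucleus", (0.5, 0.5)),
            LabelMask(foci, "focus", (0.5, 0.5)),
        )

    def test_uniform_channel_formulas(self):
        channels, nuclei, foci = self._uniform_case()
        out = nucleus_statistics(channels, nuclei, foci).iloc[0]
        assert out["accumulation"] == pytest.approx(1.0)
        assert out["nucleus_size"] == pytest.approx(100 * 0.25)
        assert out["total_foci_volume"] == pytest.approx(4 * 0.25)
        # uniform channel: fraction in PCH = 100 * size ratio
        assert out["fraction_in_pch"] == pytest.approx(100 * 4 / 100)

    def test_foci_size_arithmetic(self):
        # two foci of 0.2 and 0.3 um^3 -> total 0.5, mean 0.25
        labels = np.zeros((4, 30, 30), dtype=np.int32)
        labels[:, 2:28, 2:28] = 1
        foci = np.zeros_like(labels)
        foci[1, 4:6, 4:6] = 1   # 4 voxels
        foci[2, 10:12, 10:13] = 2  # 6 voxels
        # voxel volume 0.05 um^3: 4 voxels = 0.2, 6 voxels = 0.3
        vox = (0.5, np.sqrt(0.1), np.sqrt(0.1))
        grid = IntensityGrid(np.full(labels.shape, 10.0), vox, "ch")
        out = nucleus_statistics(
            {"ch": grid},
            LabelMask(labels, "nucleus", vox),
            LabelMask(foci, "focus", vox),
        ).iloc[0]
        assert out["foci_count"] == 2
        assert out["total_foci_volume"] == pytest.approx(0.5)
        assert out["mean_pch_size"] == pytest.approx(0.25)
        assert out["total_foci_volume"] == pytest.approx(sum(out["foci_sizes"]))

    def test_planted_fold_recovered_exactly(self, noise_free_image):
        cfg, res = noise_free_image
        nuclei = segment_nuclei(res.channels["dna"])
        foci = segment_pch_foci(res.channels["dna"], nuclei)
        out = nucleus_statistics(res.channels, nuclei, foci)
        protein = out[out["channel"] == "protein"]
        assert np.allclose(protein["accumulation"], cfg.protein_fold_enrichment)
        dna = out[out["channel"] == "dna"]
        assert np.allclose(dna["accumulation"], cfg.focus_dna_contrast)

    def test_fraction_bounds(self, noise_free_image):
        cfg, res = noise_free_image
        out = nucleus_statistics(res.channels, res.nuclei, res.foci)
        assert ((out["fraction_in_pch"] >= 0) & (out["fraction_in_pch"] <= 100)).all()

    def test_nucleus_without_foci_reports_missing_accumulation(self):
        labels = np.zeros((10, 10), dtype=np.int32)
        labels[2:8, 2:8] = 1
        grid = IntensityGrid(np.full((10, 10), 5.0), (0.5, 0.5), "ch")
        out = nucleus_statistics(
            {"ch": grid},
            LabelMask(labels, "nucleus", (0.5, 0.5)),
            LabelMask(np.zeros_like(labels), "focus", (0.5, 0.5)),
        ).iloc[0]
        assert np.isnan(out["accumulation"])
        assert out["foci_count"] == 0


class TestParticles:
    def _spots(self, coords, shape=(60, 60), amp=200.0):
        img = np.full(shape, 10.0)
        for c in coords:
            img[c] = amp
        return img

    def test_isolated_spots_counted(self):
        coords = [(10, 10), (10, 40), (30, 20), (30, 50), (50, 10), (50, 40), (45, 28)]
        img = self._spots(coords)
        region = LabelMask(np.ones(img.shape, dtype=np.int32), "nucleus", (0.1, 0.1))
        det = detect_particles(IntensityGrid(img, (0.1, 0.1), "au"), region,
                               threshold_abs=20.0)
        assert len(det) == 7

    def test_blank_region_zero(self):
        img = np.full((40, 40), 10.0)
        region = LabelMask(np.ones(img.shape, dtype=np.int32), "nucleus", (0.1, 0.1))
        det = detect_particles(IntensityGrid(img, (0.1, 0.1), "au"), region,
                               threshold_abs=20.0)
        assert len(det) == 0

    def test_close_spots_merge(self):
        img = self._spots([(20, 20), (20, 21)])
        region = LabelMask(np.ones(img.shape, dtype=np.int32), "nucleus", (0.1, 0.1))
        det = detect_particles(IntensityGrid(img, (0.1, 0.1), "au"), region,
                               threshold_abs=20.0, min_distance=3)
        assert len(det) == 1

    def test_outside_region_dropped(self):
        img = self._spots([(5, 5), (30, 30)])
        labels = np.zeros(img.shape, dtype=np.int32)
        labels[20:40, 20:40] = 1
        det = detect_particles(
            IntensityGrid(img, (0.1, 0.1), "au"),
            LabelMask(labels, "nucleus", (0.1, 0.1)),
            threshold_abs=20.0,
        )
        assert len(det) == 1


class TestRegionDensity:
    def _masks(self):
        nuclei = np.zeros((20, 20), dtype=np.int32)
        nuclei[2:18, 2:18] = 1
        foci = np.zeros_like(nuclei)
        foci[5:10, 5:10] = 1
        vs = (0.5, 0.5)
        return LabelMask(nuclei, "nucleus", vs), LabelMask(foci, "focus", vs)

    def test_density_arithmetic(self):
        nuclei, foci = self._masks()
        # 10 particles inside the 25-voxel focus: 25 * 0.25 um2 = 6.25 um2
        coords = [(r, c) for r, c in itertools.product(range(5, 10), range(5, 7))]
        det = pd.DataFrame({"region_label": 1, "coords": coords})
        out = region_particle_density(det, nuclei, foci).set_index("kind")
        assert out.at["pch", "particle_count"] == 10
        assert out.at["pch", "density"] == pytest.approx(10 / 6.25)

    def test_zero_particles_zero_density(self):
        nuclei, foci = self._masks()
        det = pd.DataFrame(columns=["region_label", "coords"])
        out = region_particle_density(det, nuclei, foci)
        assert (out["density"] == 0).all()

    def test_nucleus_density_bounded_by_pch_density(self):
        nuclei, foci = self._masks()
        coords = [(6, 6), (7, 7), (8, 8)]  # all inside PCH
        det = pd.DataFrame({"region_label": 1, "coords": coords})
        out = region_particle_density(det, nuclei, foci).set_index("kind")
        assert out.at["whole_nucleus", "density"] <= out.at["pch", "density"]

    def test_zero_size_region_errors(self):
        nuclei, _ = self._masks()
        empty = LabelMask(np.zeros((20, 20), dtype=np.int32), "focus", (0.5, 0.5))
        det = pd.DataFrame(columns=["region_label", "coords"])
        with pytest.raises(ValueError, match="zero-size"):
            region_particle_density(det, nuclei, empty)


class TestRankSumTest:
    def test_complete_separation_example(self):
        u, p = wilcoxon_rank_test([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)  # 2 / C(6,3)

    def test_identical_groups_p_one(self):
        _, p = wilcoxon_rank_test([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_symmetric_in_groups(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=5), rng.normal(size=4)
        assert wilcoxon_rank_test(a, b)[1] == pytest.approx(
            wilcoxon_rank_test(b, a)[1]
        )

    def test_exact_matches_scipy_enumeration(self):
        # all no-tie instances at a fixed total size
        for n_a in range(1, 5):
            for n_b in range(1, 5):
                values = np.arange(1, n_a + n_b + 1, dtype=float)
                for labels in itertools.combinations(range(n_a + n_b), n_a):
                    a = values[list(labels)]
                    b = np.delete(values, list(labels))
                    _, p = wilcoxon_rank_test(a, b)
                    ref = sp_stats.mannwhitneyu(
                        a, b, alternative="two-sided", method="exact"
                    ).pvalue
                    assert p == pytest.approx(ref)

    def test_large_sample_uses_normal_approximation(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=30), rng.normal(0.5, 1, size=30)
        _, p = wilcoxon_rank_test(a, b)
        ref = sp_stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        assert p == pytest.approx(ref)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_test([], [1.0])


class TestStudentsT:
    def test_equal_groups(self):
        t, p = students_t_test([1, 2, 3], [1, 2, 3])
        assert t == 0.0
        assert p == 1.0

    def test_closed_form_example(self):
        t, p = students_t_test([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.6742, abs=1e-4)
        assert p == pytest.approx(0.0214, abs=1e-3)

    def test_scale_invariance(self):
        a, b = [1.0, 2.0, 4.0], [3.0, 5.0, 6.0]
        t1, _ = students_t_test(a, b)
        t2, _ = students_t_test([10 * x for x in a], [10 * x for x in b])
        assert t1 == pytest.approx(t2)

    def test_small_group_errors(self):
        with pytest.raises(ValueError):
            students_t_test([1.0], [1.0, 2.0])


class TestCrosslevelSummary:
    def test_identical_cells_same_means(self):
        records = pd.DataFrame(
            {
                "h1_total": 1.0,
                "mecp2_total": 1.0,
                "h1_accumulation": 2.0,
                "mecp2_accumulation": 3.0,
                "mean_pch_size": 1.5,
            },
            index=range(20),
        )
        out = crosslevel_summary(records)
        populated = out[out["n_cells"] > 0]
        assert (populated["h1_accumulation"] == 2.0).all()
        assert (populated["mean_pch_size"] == 1.5).all()

    def test_matches_groupby_oracle(self):
        records, _ = simulate_cotransfection_population(
            120, interaction_strength=0.7, seed=2, noise_sd_log2=0.1
        )
        out = crosslevel_summary(records, n_bins=3)
        h1_bin = pd.qcut(records["h1_total"], 3, labels=False)
        m_bin = pd.qcut(records["mecp2_total"], 3, labels=False)
        oracle = records.groupby([h1_bin, m_bin])["h1_accumulation"].mean()
        for (i, j), expected in oracle.items():
            assert out.at[(i, j), "h1_accumulation"] == pytest.approx(expected)

    def test_competition_monotone_across_bins(self):
        records, _ = simulate_cotransfection_population(
            300, interaction_strength=1.0, seed=4
        )
        out = crosslevel_summary(records, n_bins=3)
        mean_by_mecp2 = out.groupby("mecp2_bin")["h1_accumulation"].mean()
        assert mean_by_mecp2.is_monotonic_decreasing
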