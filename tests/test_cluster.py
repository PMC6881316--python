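"""Correlation distance, UPGMA agreement with a textbook reference,
silhouette cut, concordance, and the label audit's lenient/strict tallies."""
import itertools

import numpy as np
import pytest

from spectratype import (
    MSP,
    SynonymyPolicy,
    concordance,
    cut_by_silhouette,
    distance_matrix,
    linkage_average,
    misidentification_report,
    msp_distance,
)
from spectratype.fixtures import commercial_truffle_records


def msp_from(mzs, intensities, label="m"):
    mzs = np.asarray(mzs, float)
    inten = np.asarray(intensities, float)
    return MSP(label, mzs, inten, np.ones(mzs.size), n_sources=6)


def reference_upgma(dm):
    """Textbook UPGMA: merge the closest pair; inter-cluster distance is the
    unweighted mean of all cross pairs. Returns the sorted merge heights."""
    dm = dm.copy()
    clusters = [[i] for i in range(dm.shape[0])]
    heights = []
    while len(clusters) > 1:
        best, pair = np.inf, None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = np.mean([dm[i, j] for i in clusters[a] for j in clusters[b]])
            if d < best - 1e-15:
                best, pair = d, (a, b)
        a, b = pair
        heights.append(best)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return heights


def brute_force_corr_distance(a, b, tol_ppm=2000.0):
    """First-principles recomputation: greedy single-linkage walk over the
    pooled sorted masses, then 1 - Pearson r computed from raw sums."""
    peaks = sorted(
        [(mz, inten, 0) for mz, inten in zip(a.mz, a.mean_intensity)]
        + [(mz, inten, 1) for mz, inten in zip(b.mz, b.mean_intensity)]
    )
    groups = []
    for mz, inten, src in peaks:
        if groups:
            members = groups[-1]
            w = sum(m[1] for m in members)
            cen = (sum(m[0] * m[1] for m in members) / w if w
                   else np.mean([m[0] for m in members]))
            if mz - cen <= tol_ppm * cen / 1e6:
                members.append((mz, inten, src))
                continue
        groups.append([(mz, inten, src)])
    va, vb = [], []
    for g in groups:
        w = sum(m[1] for m in g)
        cen = (sum(m[0] * m[1] for m in g) / w if w
               else np.mean([m[0] for m in g]))
        row = [0.0, 0.0]
        for src in (0, 1):
            mine = [m for m in g if m[2] == src]
            if mine:
                # per source keep the member closest to the bin centroid
                row[src] = min(mine, key=lambda m: (abs(m[0] - cen), m[0], -m[1]))[1]
        va.append(row[0])
        vb.append(row[1])
    va, vb = np.array(va), np.array(vb)
    n = va.size
    sa, sb = va.sum(), vb.sum()
    num = n * np.dot(va, vb) - sa * sb
    den = np.sqrt(n * np.dot(va, va) - sa**2) * np.sqrt(n * np.dot(vb, vb) - sb**2)
    return 1.0 if den == 0 else 1.0 - num / den


class TestDistance:
    def test_identical_is_zero(self):
        m = msp_from([4000.0, 6000.0, 9000.0], [0.2, 0.5, 0.3])
        assert msp_distance(m, m) == pytest.approx(0.0, abs=1e-12)

    def test_anti_ordered_is_two(self):
        a = msp_from([4000.0, 6000.0], [1.0, 2.0])
        b = msp_from([4000.0, 6000.0], [2.0, 1.0])
        assert msp_distance(a, b) == pytest.approx(2.0, abs=1e-12)

    def test_constant_vector_guard(self):
        # a single shared bin leaves both vectors constant: r is undefined
        a = msp_from([4000.0], [1.0])
        b = msp_from([4000.5], [2.0])
        assert msp_distance(a, b) == 1.0

    def test_matches_first_principles_recomputation(self, rng):
        for _ in range(10):
            a = msp_from(np.sort(rng.uniform(3000, 15000, 20)),
                         rng.uniform(0.1, 1, 20), "a")
            b = msp_from(np.sort(rng.uniform(3000, 15000, 20)),
                         rng.uniform(0.1, 1, 20), "b")
            assert msp_distance(a, b) == pytest.approx(
                brute_force_corr_distance(a, b), abs=1e-9)

    def test_matrix_symmetric_zero_diagonal(self, rng):
        lib = [msp_from(np.sort(rng.uniform(3000, 15000, 15)),
                        rng.uniform(0.1, 1, 15), f"L{i}") for i in range(4)]
        dm, labels = distance_matrix(lib)
        np.testing.assert_array_equal(dm, dm.T)
        np.testing.assert_array_equal(np.diag(dm), 0.0)
        assert labels == ["L0", "L1", "L2", "L3"]


class TestLinkage:
    def test_three_leaf_hand_calculation(self):
        dm = np.array([[0.0, 0.1, 0.5], [0.1, 0.0, 0.5], [0.5, 0.5, 0.0]])
        dendro = linkage_average(dm, ["A", "B", "C"])
        np.testing.assert_allclose(dendro.linkage[:, 2], [0.1, 0.5])
        assert sorted(dendro.linkage[0, :2]) == [0.0, 1.0]  # A and B first

    def test_identical_leaves_merge_at_zero(self):
        dm = np.zeros((2, 2))
        dendro = linkage_average(dm)
        assert dendro.linkage[0, 2] == 0.0

    def test_matches_textbook_upgma_on_random_matrices(self, rng):
        for _ in range(8):
            n = 8
            x = rng.uniform(0.1, 1.0, size=(n, n))
            dm = (x + x.T) / 2
            np.fill_diagonal(dm, 0.0)
            dendro = linkage_average(dm)
            np.testing.assert_allclose(
                dendro.linkage[:, 2], reference_upgma(dm), rtol=1e-10)

    def test_nan_rejected(self):
        dm = np.zeros((3, 3))
        dm[0, 1] = dm[1, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            linkage_average(dm)

    def test_heights_monotone_on_study_matrix(self, fixture_peaklists):
        from spectratype import pipeline

        lib = pipeline.build_specimen_library(fixture_peaklists)
        dm, labels = distance_matrix(lib)
        dendro = linkage_average(dm, labels)
        assert np.all(np.diff(dendro.linkage[:, 2]) >= -1e-12)


class TestSilhouetteCut:
    def _blocky(self, sizes, within=0.05, between=1.0, jitter=0.0, seed=0):
        rng = np.random.default_rng(seed)
        n = sum(sizes)
        labels = np.repeat(np.arange(len(sizes)), sizes)
        dm = np.where(labels[:, None] == labels[None, :], within, between)
        dm = dm + rng.uniform(0, jitter, (n, n))
        dm = (dm + dm.T) / 2
        np.fill_diagonal(dm, 0.0)
        return dm

    def test_three_separated_groups(self):
        dm = self._blocky([3, 3, 3], jitter=0.02, seed=4)
        dendro = linkage_average(dm)
        k, flat = cut_by_silhouette(dendro, dm)
        assert k == 3
        # pure clusters: each group maps to a single flat label
        labels = np.repeat(np.arange(3), 3)
        for g in range(3):
            assert len(set(flat[labels == g])) == 1

    def test_degenerate_identical_leaves(self):
        dm = np.zeros((4, 4))
        dendro = linkage_average(dm)
        with pytest.warns(UserWarning, match="degenerate"):
            k, flat = cut_by_silhouette(dendro, dm)
        assert k == 2


class TestConcordance:
    def test_identical_partitions(self):
        labels = {"a": 1, "b": 1, "c": 2}
        truth = {"a": "x", "b": "x", "c": "y"}
        ari, purity = concordance(labels, truth)
        assert ari == 1.0
        assert all(v == 1.0 for v in purity.values())

    def test_one_cluster_vs_singletons_is_zero(self):
        labels = {k: 1 for k in "abcd"}
        truth = {k: k for k in "abcd"}
        ari, _ = concordance(labels, truth)
        assert ari == pytest.approx(0.0, abs=1e-12)

    def test_matches_contingency_formula(self, rng):
        from math import comb

        keys = [f"s{i}" for i in range(20)]
        labels = {k: int(rng.integers(0, 3)) for k in keys}
        truth = {k: str(rng.integers(0, 4)) for k in keys}
        ari, _ = concordance(labels, truth)

        pred_vals = sorted(set(labels.values()))
        true_vals = sorted(set(truth.values()))
        nij = np.array([[sum(1 for k in keys if labels[k] == p and truth[k] == t)
                         for t in true_vals] for p in pred_vals])
        a = nij.sum(axis=1)
        b = nij.sum(axis=0)
        n = len(keys)
        sum_ij = sum(comb(int(v), 2) for v in nij.ravel())
        sum_a = sum(comb(int(v), 2) for v in a)
        sum_b = sum(comb(int(v), 2) for v in b)
        expected = sum_a * sum_b / comb(n, 2)
        maximum = (sum_a + sum_b) / 2
        assert ari == pytest.approx((sum_ij - expected) / (maximum - expected), abs=1e-12)

    def test_mismatched_leaf_sets_rejected(self):
        with pytest.raises(ValueError, match="leaf"):
            concordance({"a": 1}, {"b": "x"})


class TestAudit:
    def test_lenient_tally_nine_of_34(self):
        report = misidentification_report(
            commercial_truffle_records(), SynonymyPolicy.default())
        assert report.attrs["n_misidentified"] == 9
        assert report.attrs["percent"] == 26

    def test_strict_indicum_subgroup_four_of_six(self):
        report = misidentification_report(
            commercial_truffle_records(), SynonymyPolicy.default(mode="strict"))
        by = report.attrs["by_marketed"].set_index("marketed_species")
        assert by.loc["T. indicum", "n_misidentified"] == 4
        assert by.loc["T. indicum", "n"] == 6
        assert by.loc["T. indicum", "percent"] == 67
        assert report.attrs["n_misidentified"] == 10  # the strict total

    def test_mesentericum_all_misidentified_either_policy(self):
        for mode in ("lenient", "strict"):
            report = misidentification_report(
                commercial_truffle_records(), SynonymyPolicy.default(mode=mode))
            by = report.attrs["by_marketed"].set_index("marketed_species")
            assert by.loc["T. mesentericum", "n_misidentified"] == 6
            assert by.loc["T. mesentericum", "percent"] == 100

    def test_uncinatum_synonym_not_a_mislabel(self):
        report = misidentification_report(
            commercial_truffle_records(), SynonymyPolicy.default())
        df = report[report["marketed_species"] == "T. uncinatum"]
        assert not df["misidentified"].any()

    def test_empty_records(self):
        report = misidentification_report([], SynonymyPolicy.default())
        assert report.attrs["n_misidentified"] == 0
        assert report.attrs["percent"] == 0

    def test_unknown_name_treated_as_itself(self):
        from spectratype import SpecimenRecord

        rec = SpecimenRecord("x1", "T. borchii", "", "", "T. borchii")
        report = misidentification_report([rec], SynonymyPolicy.default())
        assert not report.loc[0, "misidentified"]

    def test_synonym_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            SynonymyPolicy(synonyms={"A": "B", "B": "A"})

    def test_report_bytes_deterministic(self, tmp_path):
        records = commercial_truffle_records()
        outs = []
        for name in ("a.csv", "b.csv"):
            rep = misidentification_report(records, SynonymyPolicy.default())
            rep.to_csv(tmp_path / name, index=False)
            outs.append((tmp_path / name).read_bytes())
        assert outs[0] == outs[1]
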