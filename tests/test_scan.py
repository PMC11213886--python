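import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from capriscan import scan
from capriscan.popio import GeneRecord, PopulationMap
from capriscan.scan import ScanRegion, Thresholds

from conftest import make_hap_panel, make_panel


def one_pop_map(n, label="P"):
    return PopulationMap({f"s{i + 1}": label for i in range(n)})


def hp_formula(n_maj, n_min):
    tot = n_maj + n_min
    return 2 * n_maj * n_min / tot ** 2


class TestWindowedHp:
    def test_formula_value(self):
        # 10 SNPs: per-site counts 3/1 among 2 diploids -> sums 30/10
        G = np.array([[2, 1]]).repeat(10, axis=1).reshape(2, 10)
        G = np.tile(np.array([[2], [1]]), (1, 10))
        panel = make_panel(G, positions=np.arange(1, 11) * 1000)
        hp = scan.windowed_hp(panel, one_pop_map(2), "P", window=100_000,
                              step=100_000, min_snps=10, contigs={"1": 100_000})
        assert hp["hp"].iloc[0] == pytest.approx(0.375)

    def test_fixed_windows_are_zero(self):
        G = np.zeros((2, 12), dtype=np.int8)
        panel = make_panel(G, positions=np.arange(1, 13) * 1000)
        hp = scan.windowed_hp(panel, one_pop_map(2), "P", contigs={"1": 100_000})
        assert hp["hp"].iloc[0] == 0.0

    def test_balanced_counts_reach_half(self):
        G = np.tile(np.array([[2], [0]]), (1, 10))
        panel = make_panel(G, positions=np.arange(1, 11) * 1000)
        hp = scan.windowed_hp(panel, one_pop_map(2), "P", contigs={"1": 100_000})
        assert hp["hp"].iloc[0] == pytest.approx(0.5)

    def test_sparse_windows_discarded(self):
        G = np.tile(np.array([[1], [1]]), (1, 5))
        panel = make_panel(G, positions=np.arange(1, 6) * 1000)
        hp = scan.windowed_hp(panel, one_pop_map(2), "P", min_snps=10,
                              contigs={"1": 100_000})
        assert len(hp) == 0

    @given(st.integers(0, 200), st.integers(0, 200))
    @settings(max_examples=100, deadline=None)
    def test_bounds_and_symmetry(self, a, b):
        """Hp stays in [0, 0.5] and is symmetric in the two counts."""
        if a + b == 0:
            return
        assert 0 <= hp_formula(a, b) <= 0.5
        assert hp_formula(a, b) == hp_formula(b, a)


class TestZTransform:
    def test_sample_sd_arithmetic(self):
        df = pd.DataFrame({"hp": [0.2, 0.3, 0.4]})
        out = scan.z_transform(df, "hp")
        np.testing.assert_allclose(out["z"], [-1, 0, 1])

    def test_constant_values_raise(self):
        df = pd.DataFrame({"hp": [0.3, 0.3, 0.3]})
        with pytest.raises(ValueError, match="degenerate"):
            scan.z_transform(df, "hp")

    def test_normalisation_identity(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=50)})
        out = scan.z_transform(df, "x")
        assert out["z"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["z"].std(ddof=1) == pytest.approx(1.0)


class TestWindowedFst:
    def _panel(self, Ga, Gb):
        G = np.vstack([Ga, Gb])
        samples = [f"a{i}" for i in range(len(Ga))] + [f"b{i}" for i in range(len(Gb))]
        panel = make_panel(G, samples=samples,
                           positions=np.arange(1, G.shape[1] + 1) * 1000)
        pm = PopulationMap({s: ("A" if s[0] == "a" else "B") for s in samples})
        return panel, pm

    def test_fixed_difference_window(self):
        Ga = np.zeros((3, 20), dtype=np.int8)
        Gb = np.full((3, 20), 2, dtype=np.int8)
        # add a contrasting window so the Z-transform is non-degenerate
        Ga = np.hstack([Ga, np.tile([[0], [1], [2]], (1, 20))])
        Gb = np.hstack([Gb, np.tile([[0], [1], [2]], (1, 20))])
        panel, pm = self._panel(Ga, Gb)
        fst = scan.windowed_fst(panel, pm, "A", "B", window=20_000, step=20_000,
                                contigs={"1": 40_000})
        assert fst["fst"].iloc[0] == pytest.approx(1.0)

    def test_identical_pops_non_positive(self):
        G = np.tile([[0], [1], [2]], (1, 25))
        rng = np.random.default_rng(0)
        G = rng.binomial(2, 0.4, size=(3, 25)).astype(np.int8)
        panel, pm = self._panel(G, G)
        fst = scan.windowed_fst(panel, pm, "A", "B", window=25_000, step=25_000,
                                contigs={"1": 25_000}, per_site_z=True)
        # with identical pops every window is non-positive before the Z step
        n1, p1, h1 = scan.pop_site_stats(panel, pm, "A")
        n2, p2, h2 = scan.pop_site_stats(panel, pm, "B")
        a, b, c = scan.site_wc_components(n1, p1, h1, n2, p2, h2)
        ok = np.isfinite(a)
        assert a[ok].sum() / (a + b + c)[ok].sum() <= 0

    def test_min_snps_discard(self):
        Ga = np.tile([[0], [1]], (1, 5))
        Gb = np.tile([[2], [1]], (1, 5))
        panel, pm = self._panel(Ga, Gb)
        with pytest.raises(ValueError):
            # all windows discarded -> no retained windows to standardise
            scan.windowed_fst(panel, pm, "A", "B", window=5000, step=5000,
                              min_snps=10, contigs={"1": 5000})


class TestEhh:
    def test_carrier_groups_two_two(self):
        # 4 carriers of allele 1 split {2,2} one marker out
        H = np.array([
            [1, 0, 0],
            [1, 0, 0],
            [1, 1, 0],
            [1, 1, 0],
            [0, 0, 0],
        ])
        prof = scan.ehh(H, np.array([100, 200, 300]), core_idx=0,
                        core_allele=1, direction="right")["right"]
        assert prof["ehh"].iloc[0] == 1.0
        assert prof["ehh"].iloc[1] == pytest.approx(2 / 6)

    def test_identical_carriers_stay_one(self):
        H = np.tile(np.array([1, 0, 1, 1, 0]), (4, 1))
        prof = scan.ehh(H, np.arange(1, 6) * 10, 0, core_allele=1,
                        direction="right")["right"]
        assert (prof["ehh"] == 1.0).all()

    def test_all_distinct_reaches_zero(self):
        H = np.array([
            [1, 0, 0],
            [1, 0, 1],
            [1, 1, 0],
            [1, 1, 1],
        ])
        prof = scan.ehh(H, np.array([10, 20, 30]), 0, core_allele=1,
                        direction="right")["right"]
        assert prof["ehh"].iloc[-1] == 0.0

    def test_too_few_carriers_raise(self):
        H = np.array([[1, 0], [0, 0], [0, 1]])
        with pytest.raises(ValueError, match="carriers"):
            scan.ehh(H, np.array([10, 20]), 0, core_allele=1)

    def test_monotone_non_increasing(self, rng):
        for _ in range(20):
            H = rng.integers(0, 2, size=(10, 12))
            H[:, 5] = 1  # everyone carries the core allele
            prof = scan.ehh(H, np.arange(1, 13) * 7, 5, core_allele=1)
            for side in prof.values():
                assert (np.diff(side["ehh"]) <= 1e-12).all()


class TestXpehh:
    def _panel(self, Ha, Hb, positions=None):
        H = np.vstack([Ha, Hb])
        n = H.shape[0] // 2
        samples = [f"x{i}" for i in range(n)]
        panel = make_hap_panel(H, positions=positions, samples=samples)
        half = len(Ha) // 2
        pm = PopulationMap({s: ("A" if i < half else "B")
                            for i, s in enumerate(samples)})
        return panel, pm

    def test_identical_pops_zero_raw(self, rng):
        Ha = rng.integers(0, 2, size=(8, 30)).astype(np.int8)
        pos = np.sort(rng.choice(100_000, 30, replace=False) + 1)
        panel, pm = self._panel(Ha, Ha.copy(), positions=pos)
        xp = scan.xpehh(panel, pm, "A", "B")
        ok = xp["ok"]
        np.testing.assert_allclose(xp.loc[ok, "raw"], 0.0, atol=1e-12)

    def test_antisymmetry(self, rng):
        H = rng.integers(0, 2, size=(16, 40)).astype(np.int8)
        pos = np.sort(rng.choice(200_000, 40, replace=False) + 1)
        panel, pm = self._panel(H[:8], H[8:], positions=pos)
        ab = scan.xpehh(panel, pm, "A", "B")
        ba = scan.xpehh(panel, pm, "B", "A")
        ok = ab["ok"] & ba["ok"]
        np.testing.assert_allclose(ab.loc[ok, "raw"], -ba.loc[ok, "raw"],
                                   atol=1e-12)

    def test_standardised_scores_unit_scale(self, rng):
        H = rng.integers(0, 2, size=(12, 200)).astype(np.int8)
        pos = np.sort(rng.choice(500_000, 200, replace=False) + 1)
        panel, pm = self._panel(H[:6], H[6:], positions=pos)
        xp = scan.xpehh(panel, pm, "A", "B")
        good = xp["ok"]
        assert xp.loc[good, "std"].mean() == pytest.approx(0.0, abs=1e-9)
        assert xp.loc[good, "std"].std(ddof=1) == pytest.approx(1.0, rel=1e-9)
        # p-values are two-sided standard-normal tails
        from scipy.stats import norm
        np.testing.assert_allclose(
            xp.loc[good, "p"], 2 * norm.sf(np.abs(xp.loc[good, "std"])))


class TestCallCandidates:
    def test_zhp_tiers(self):
        out = scan.call_candidates([-8.1, -4.0, -2.0], "zhp")
        assert list(out["candidate"]) == [True, True, False]
        assert list(out["topmost"]) == [True, False, False]

    def test_no_hits(self):
        out = scan.call_candidates([0.5, -1.0], "zhp")
        assert not out.any().any()

    def test_xpehh_boundary_inclusive(self):
        out = scan.call_candidates([5.0, -5.0, 4.9, 6.0], "xpehh")
        assert list(out["candidate"]) == [True, True, False, True]
        assert list(out["topmost"]) == [False, False, False, True]

    def test_zfst_boundaries(self):
        out = scan.call_candidates([4.0, 4.01, 7.0], "zfst")
        assert list(out["candidate"]) == [False, True, True]
        assert list(out["topmost"]) == [False, False, True]

    def test_quantile_rule_unions_with_fixed_score(self):
        scores = np.concatenate([np.zeros(99_999), [4.8]])
        out = scan.call_candidates(scores, "xpehh")
        # 4.8 is below the fixed cut-off but inside the top 0.001%
        assert out["candidate"].iloc[-1]

    def test_invalid_threshold_signs(self):
        with pytest.raises(ValueError):
            Thresholds(zhp_candidate=3.9)
        with pytest.raises(ValueError):
            Thresholds(zfst_candidate=-4.0)


class TestMergeRegions:
    def test_overlapping_windows_merge(self):
        hits = pd.DataFrame({"chrom": ["1", "1"], "start": [100_000, 150_000],
                             "end": [200_000, 250_000], "z": [-5.0, -4.2]})
        (r,) = scan.merge_regions(hits, "ZHp")
        assert (r.start, r.end) == (100_000, 250_000)
        assert r.peak_score == -5.0
        assert r.n_constituents == 2

    def test_distant_snps_stay_separate(self):
        hits = pd.DataFrame({"chrom": ["1", "1"], "pos": [100_000, 400_000],
                             "std": [5.5, 6.1]})
        regions = scan.merge_regions(hits, "XP-EHH", score_column="std",
                                     max_gap=200_000)
        assert len(regions) == 2

    def test_constituent_count_conserved(self, rng):
        starts = np.sort(rng.choice(50, 20, replace=False)) * 50_000
        hits = pd.DataFrame({"chrom": "1", "start": starts,
                             "end": starts + 100_000,
                             "z": rng.normal(size=20)})
        regions = scan.merge_regions(hits, "ZHp")
        assert sum(r.n_constituents for r in regions) == 20

    def test_empty_input(self):
        assert scan.merge_regions(pd.DataFrame(), "ZHp") == []


class TestOverlapGenes:
    GENES = [GeneRecord("inG", "1", 120_001, 130_000),
             gene_abut := GeneRecord("abut", "1", 250_001, 260_000),
             GeneRecord("span", "1", 90_001, 260_000),
             GeneRecord("other", "2", 120_001, 130_000)]

    def test_overlap_rules(self):
        regions = [ScanRegion("1", 100_000, 250_000, "ZHp", -8.0, 3)]
        scan.overlap_genes(regions, self.GENES)
        assert regions[0].genes == ["inG", "span"]

    def test_gene_spanning_region_counted_once(self):
        regions = [ScanRegion("1", 100_000, 250_000, "ZHp", -8.0, 3)]
        scan.overlap_genes(regions, [self.GENES[2], self.GENES[2]])
        assert regions[0].genes == ["span"]


class TestVenn:
    def test_two_list_decomposition(self):
        counts, members = scan.intersect_gene_lists(
            {"m1": ["A", "B", "C"], "m2": ["B", "C", "D"]})
        assert members["m1&m2"] == ["B", "C"]
        assert members["m1"] == ["A"]
        assert members["m2"] == ["D"]

    def test_identical_lists(self):
        counts, members = scan.intersect_gene_lists(
            {"m1": ["A", "B"], "m2": ["A", "B"]})
        assert members["m1&m2"] == ["A", "B"]
        assert members["m1"] == [] and members["m2"] == []

    def test_disjoint_lists(self):
        counts, members = scan.intersect_gene_lists(
            {"m1": ["A"], "m2": ["B"], "m3": ["C"]})
        assert members["m1&m2&m3"] == []
        assert members["m1"] == ["A"]

    def test_single_list_raises(self):
        with pytest.raises(ValueError):
            scan.intersect_gene_lists({"m1": ["A"]})
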