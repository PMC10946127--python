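"""Selection-scan statistics against independent oracles and their invariants."""

import numpy as np
import pandas as pd
import pytest

from landgen.scan import (
    build_layer,
    ehh,
    empirical_p,
    ihh,
    layered_scan,
    make_windows,
    overlap_windows,
    wc_fst_per_site,
    wc_fst_sites,
    windowed_fst,
    xpehh,
    EhhCurve,
)
from landgen.sim import SimConfig, simulate_haplotypes, simulate_metadata

from conftest import toy_panel


def wc_oracle(c1, c2):
    """Spreadsheet-style transcription of the 1984 two-population formulas."""
    n1, n2 = sum(c1), sum(c2)
    p1 = (2 * c1[2] + c1[1]) / (2 * n1)
    p2 = (2 * c2[2] + c2[1]) / (2 * n2)
    h1, h2 = c1[1] / n1, c2[1] / n2
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
    )
    b = nbar / (nbar - 1) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


class TestWcFst:
    def test_fixed_difference_gives_one(self):
        assert wc_fst_per_site((10, 0, 0), (0, 0, 10)).theta == pytest.approx(1.0)

    def test_identical_half_half_pops_slightly_negative(self):
        fc = wc_fst_per_site((5, 0, 5), (5, 0, 5))
        assert fc.theta < 0
        assert fc.a < 0 and fc.b > 0 and fc.c == 0

    @pytest.mark.parametrize(
        "c1,c2",
        [
            ((8, 2, 0), (1, 4, 5)),
            ((3, 7, 10), (10, 5, 5)),
            ((1, 1, 1), (4, 0, 4)),
            ((20, 5, 1), (2, 9, 13)),
        ],
    )
    def test_matches_formula_oracle(self, c1, c2):
        fc = wc_fst_per_site(c1, c2)
        a, b, c = wc_oracle(c1, c2)
        assert fc.a == pytest.approx(a, abs=1e-12)
        assert fc.b == pytest.approx(b, abs=1e-12)
        assert fc.c == pytest.approx(c, abs=1e-12)

    def test_monomorphic_both_pops_undefined(self):
        assert np.isnan(wc_fst_per_site((10, 0, 0), (10, 0, 0)).theta)

    def test_theta_bounded_above_by_one(self):
        rng = np.random.default_rng(6)
        for _ in range(300):
            c1 = rng.multinomial(12, [1 / 3] * 3)
            c2 = rng.multinomial(15, [1 / 3] * 3)
            t = wc_fst_per_site(tuple(c1), tuple(c2)).theta
            if not np.isnan(t):
                assert t <= 1.0 + 1e-12


class TestMakeWindows:
    def test_expected_tiling(self):
        w = make_windows({"1": 100_000})
        assert w[["start", "end"]].values.tolist() == [
            [1, 50_000],
            [25_001, 75_000],
            [50_001, 100_000],
            [75_001, 100_000],
        ]

    def test_short_chromosome_single_truncated_window(self):
        w = make_windows({"1": 40_000})
        assert w[["start", "end"]].values.tolist() == [[1, 40_000]]

    def test_span_must_cover_step(self):
        with pytest.raises(ValueError):
            make_windows({"1": 100_000}, span=10_000, step=25_000)

    def test_site_window_membership(self):
        w = make_windows({"1": 100_000})
        hits = w[(w.start <= 60_000) & (w.end >= 60_000)]
        assert hits["start"].tolist() == [25_001, 50_001]


class TestWindowedFst:
    def test_single_snp_window_equals_site_theta(self):
        h = np.zeros((8, 1), dtype=np.uint8)
        h[0:4, 0] = 1  # pop1 samples 0-1 both het-ish
        panel = toy_panel(h, positions=[500])
        wins = make_windows({"1": 1000}, span=1000, step=1000)
        res = windowed_fst(panel, (np.array([0, 1]), np.array([2, 3])), wins, 1000, 1000)
        c1 = panel.genotype_counts([0, 1])[0]
        c2 = panel.genotype_counts([2, 3])[0]
        expect = wc_fst_per_site(tuple(c1), tuple(c2)).theta
        assert res["stat"].iloc[0] == pytest.approx(expect)
        assert res["n_snps"].iloc[0] == 1

    def test_identical_populations_mean_near_zero(self):
        """Null contrast: two halves of one population, mean theta ~ 0."""
        cfg = SimConfig(
            n_gradients=1, agroecologies=("lowland",), pops_per_cell=1,
            n_extra_pops=0, samples_per_pop=120, n_chromosomes=2,
            chrom_length=5_000_000, n_snps=10_000, fst_level=0.0, seed=8,
        )
        frame = simulate_metadata(cfg)
        panel = simulate_haplotypes(cfg, frame)
        idx = np.arange(panel.n_samples)
        wins = make_windows(panel.contig_lengths)
        res = windowed_fst(panel, (idx[::2], idx[1::2]), wins)
        assert abs(np.nanmean(res["stat"])) < 0.01


class TestEhh:
    def test_core_value_is_one_and_forced_identity_stays_one(self):
        h = np.tile(np.array([1, 0, 1, 0, 1], dtype=np.uint8), (6, 1))
        panel = toy_panel(h)
        curve = ehh(panel, [0, 1, 2], core_index=2, core_allele=1)
        assert curve.right_ehh[0] == 1.0
        assert np.all(curve.right_ehh == 1.0) and np.all(curve.left_ehh == 1.0)

    def test_two_of_three_carriers_identical_gives_one_third(self):
        # carriers of allele 1 at core (col 1): haplotypes 0,1,2
        # over the next column, haps 0,1 identical, hap 2 distinct
        h = np.array(
            [
                [1, 0],
                [1, 0],
                [1, 1],
                [0, 0],
                [0, 1],
                [0, 0],
            ],
            dtype=np.uint8,
        )
        panel = toy_panel(h)
        curve = ehh(panel, [0, 1, 2], core_index=0, core_allele=1)
        assert curve.right_ehh[1] == pytest.approx(1 / 3)

    def test_combinatorial_enumeration_oracle(self):
        """EHH equals sum over distinct extended haplotypes of C(n_k,2)/C(n,2)."""
        rng = np.random.default_rng(12)
        h = rng.integers(0, 2, (20, 15)).astype(np.uint8)
        panel = toy_panel(h)
        curve = ehh(panel, list(range(10)), core_index=5, core_allele=1, cutoff=0.0)
        carriers = h[h[:, 5] == 1]
        n = len(carriers)
        for off, j in enumerate(range(6, 15), start=1):
            segs = [tuple(row[5 : j + 1]) for row in carriers]
            counts = pd.Series(segs).value_counts().to_numpy()
            expect = (counts * (counts - 1)).sum() / (n * (n - 1))
            assert curve.right_ehh[off] == pytest.approx(expect, abs=1e-12)

    def test_curve_non_increasing_and_bounded(self):
        rng = np.random.default_rng(13)
        h = rng.integers(0, 2, (30, 40)).astype(np.uint8)
        panel = toy_panel(h)
        curve = ehh(panel, list(range(15)), core_index=20, core_allele=0, cutoff=0.0)
        for v in (curve.left_ehh, curve.right_ehh):
            assert np.all(np.diff(v) <= 1e-12)
            assert np.all((v >= 0) & (v <= 1))

    def test_fewer_than_two_carriers_rejected(self):
        h = np.zeros((4, 3), dtype=np.uint8)
        h[0, 1] = 1
        panel = toy_panel(h)
        with pytest.raises(ValueError, match="carriers"):
            ehh(panel, [0, 1], core_index=1, core_allele=1)


class TestIhh:
    def test_rectangle_integral(self):
        c = EhhCurve(
            core_index=0, core_pos=1000, core_allele=1,
            left_pos=np.array([1000, 900, 800]), left_ehh=np.array([1.0, 1.0, 1.0]),
            right_pos=np.array([1000, 1100, 1200]), right_ehh=np.array([1.0, 1.0, 1.0]),
        )
        assert ihh(c) == pytest.approx(400.0)

    def test_trapezoid_example_one_side(self):
        c = EhhCurve(
            core_index=0, core_pos=0, core_allele=1,
            left_pos=np.array([0]), left_ehh=np.array([1.0]),
            right_pos=np.array([0, 100]), right_ehh=np.array([1.0, 0.5]),
        )
        assert ihh(c) == pytest.approx(75.0)

    def test_single_point_curve_is_zero(self):
        c = EhhCurve(
            core_index=0, core_pos=0, core_allele=1,
            left_pos=np.array([0]), left_ehh=np.array([1.0]),
            right_pos=np.array([0]), right_ehh=np.array([1.0]),
        )
        assert ihh(c) == 0.0

    def test_faster_decay_means_smaller_ihh(self):
        pos = np.arange(0, 600, 100)
        slow = EhhCurve(0, 0, 1, np.array([0]), np.array([1.0]), pos, 0.9 ** np.arange(6))
        fast = EhhCurve(0, 0, 1, np.array([0]), np.array([1.0]), pos, 0.5 ** np.arange(6))
        assert ihh(fast) < ihh(slow)

    def test_sub_cutoff_tail_point_excluded(self):
        c = EhhCurve(
            core_index=0, core_pos=0, core_allele=1,
            left_pos=np.array([0]), left_ehh=np.array([1.0]),
            right_pos=np.array([0, 100, 200]), right_ehh=np.array([1.0, 0.5, 0.01]),
        )
        assert ihh(c) == pytest.approx(75.0)


@pytest.fixture(scope="module")
def two_pop_panel():
    cfg = SimConfig(
        n_gradients=1, agroecologies=("lowland",), pops_per_cell=2,
        n_extra_pops=0, samples_per_pop=25, n_chromosomes=1,
        chrom_length=2_000_000, n_snps=600, fst_level=0.03, seed=21,
    )
    frame = simulate_metadata(cfg)
    panel = simulate_haplotypes(cfg, frame)
    pops = frame["population_id"].unique()
    ia = panel.sample_indices(frame.loc[frame.population_id == pops[0], "sample_id"])
    ib = panel.sample_indices(frame.loc[frame.population_id == pops[1], "sample_id"])
    return panel, ia, ib


class TestXpehh:
    def test_identical_haplotype_sets_score_zero(self, two_pop_panel):
        panel, ia, _ = two_pop_panel
        sites, _ = xpehh(panel, ia, ia)
        raw = sites["xpehh_raw"].dropna()
        assert len(raw) > 100
        assert np.allclose(raw, 0.0)

    def test_population_swap_negates_raw_scores(self, two_pop_panel):
        panel, ia, ib = two_pop_panel
        s_ab, _ = xpehh(panel, ia, ib)
        s_ba, _ = xpehh(panel, ib, ia)
        a = s_ab["xpehh_raw"].to_numpy()
        b = s_ba["xpehh_raw"].to_numpy()
        assert np.array_equal(np.isnan(a), np.isnan(b))
        ok = ~np.isnan(a)
        assert np.allclose(a[ok], -b[ok], atol=1e-10)

    def test_scan_matches_ehh_ihh_composition(self, two_pop_panel):
        """The compiled genome scan agrees with the curve-based EHH/iHH path."""
        panel, ia, ib = two_pop_panel
        sites, _ = xpehh(panel, ia, ib, min_maf=0.05)

        def pop_ihh(idx, j):
            rows = panel.haplotype_rows(idx)
            parts = []
            for al in (0, 1):
                ncar = int((panel.haplotypes[rows, j] == al).sum())
                if ncar < 2:
                    continue
                parts.append((ncar, ihh(ehh(panel, idx, core_index=j, core_allele=al))))
            w = np.array([p[0] for p in parts], dtype=float)
            v = np.array([p[1] for p in parts], dtype=float)
            return float((w / w.sum() * v).sum())

        checked = 0
        for j in (50, 150, 300, 450, 550):
            raw = sites["xpehh_raw"].iloc[j]
            if np.isnan(raw):
                continue
            expect = np.log(pop_ihh(ia, j) / pop_ihh(ib, j))
            assert raw == pytest.approx(expect, rel=1e-9)
            checked += 1
        assert checked >= 2


class TestEmpiricalP:
    def test_one_sided_top_percent_contract(self):
        df = pd.DataFrame(
            {"chrom": "1", "start": np.arange(100), "end": np.arange(100) + 10,
             "stat": np.random.default_rng(0).permutation(100).astype(float)}
        )
        out = empirical_p(df)
        top = out.sort_values("stat", ascending=False)
        assert top["p"].iloc[0] == pytest.approx(0.01)
        assert bool(top["significant"].iloc[0])
        assert top["p"].iloc[1] == pytest.approx(0.02)
        assert not top["significant"].iloc[1]
        assert int(out["significant"].sum()) == 1

    def test_all_tied_nothing_significant(self):
        df = pd.DataFrame(
            {"chrom": "1", "start": range(50), "end": range(50), "stat": 1.0}
        )
        out = empirical_p(df)
        assert (out["p"] == 1.0).all()
        assert not out["significant"].any()

    def test_two_sided_signed_log10p_threshold(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {"chrom": "1", "start": range(150), "end": range(150),
             "stat": rng.standard_normal(150)}
        )
        out = empirical_p(df, two_sided=True)
        flagged = out["significant"]
        assert (np.abs(out.loc[flagged, "signed_log10p"]) > 2).all()
        assert (np.abs(out.loc[~flagged, "signed_log10p"]) < 2).all()
        # sign convention follows the statistic
        assert (np.sign(out.loc[out.stat != 0, "signed_log10p"])
                == np.sign(out.loc[out.stat != 0, "stat"])).all()

    def test_undefined_windows_excluded_from_n(self):
        df = pd.DataFrame(
            {"chrom": "1", "start": range(10), "end": range(10),
             "stat": [np.nan] * 5 + [5.0, 4.0, 3.0, 2.0, 1.0]}
        )
        out = empirical_p(df)
        assert out["p"].isna().sum() == 5
        assert out["p"].max() == 1.0
        assert out.loc[out.stat == 5.0, "p"].iloc[0] == pytest.approx(0.2)

    def test_all_missing_rejected(self):
        df = pd.DataFrame({"chrom": "1", "start": [0], "end": [1], "stat": [np.nan]})
        with pytest.raises(ValueError):
            empirical_p(df)


class TestOverlap:
    def _mk(self, sig):
        return pd.DataFrame(
            {"chrom": "1", "start": range(20), "end": range(20),
             "significant": [i in sig for i in range(20)]}
        )

    def test_identical_sets_100_percent(self):
        r = overlap_windows(self._mk(set(range(5))), self._mk(set(range(5))))
        assert r["pct_of_union"] == r["pct_of_a"] == r["pct_of_b"] == 100.0

    def test_disjoint_sets_zero(self):
        r = overlap_windows(self._mk({0, 1}), self._mk({5, 6}))
        assert r["n_overlap"] == 0
        assert r["pct_of_union"] == 0.0

    def test_partial_overlap_arithmetic(self):
        r = overlap_windows(self._mk(set(range(0, 10))), self._mk(set(range(5, 15))))
        assert r["n_overlap"] == 5
        assert r["pct_of_union"] == pytest.approx(100 * 5 / 15)
        assert r["pct_of_a"] == 50.0 and r["pct_of_b"] == 50.0

    def test_mismatched_tilings_rejected(self):
        a = self._mk({1})
        b = self._mk({1}).assign(start=lambda d: d.start + 1)
        with pytest.raises(ValueError, match="tilings"):
            overlap_windows(a, b)


class TestLayers:
    def test_layer_construction(self, small_frame):
        l1 = build_layer(small_frame, "I", gradients=("I", "II"))
        assert set(l1.contrasts) == {"I_vs_II"}
        l2 = build_layer(small_frame, "II", gradients=("I", "II"))
        assert set(l2.contrasts) == {"lowland_vs_highland"}
        l3 = build_layer(small_frame, "III", inner_gradient="II")
        ids_a, ids_b = next(iter(l3.contrasts.values()))
        sub = set(small_frame.loc[small_frame.gradient == "II", "sample_id"])
        assert set(ids_a) <= sub and set(ids_b) <= sub

    def test_four_gradients_give_six_pairs(self):
        cfg = SimConfig(n_snps=10, samples_per_pop=2)
        frame = simulate_metadata(cfg)
        spec = build_layer(frame, "I", gradients=("I", "II", "III", "IV"))
        assert len(spec.contrasts) == 6

    def test_scan_determinism_and_outputs(self, small_panel, small_frame):
        layer = build_layer(small_frame, "II", gradients=("I", "II"))
        r1 = layered_scan(small_panel, small_frame, layer, span=200_000, step=100_000)
        r2 = layered_scan(small_panel, small_frame, layer, span=200_000, step=100_000)
        for name in r1:
            pd.testing.assert_frame_equal(r1[name]["fst"], r2[name]["fst"])
            pd.testing.assert_frame_equal(r1[name]["xpehh"], r2[name]["xpehh"])
            assert r1[name]["mean_fst"] == r2[name]["mean_fst"]
            assert set(r1[name]["overlap"]) == {
                "n_significant_a", "n_significant_b", "n_overlap",
                "pct_of_union", "pct_of_a", "pct_of_b",
            }

    def test_empty_side_skipped_with_warning(self, small_panel, small_frame):
        from landgen.scan import LayerSpec

        layer = LayerSpec("I", "custom", {"bad": ([], small_frame["sample_id"].tolist())})
        with pytest.warns(UserWarning, match="empty side"):
            res = layered_scan(small_panel, small_frame, layer, run_xpehh=False)
        assert res == {}
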