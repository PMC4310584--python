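"""Diversity/differentiation estimators against formulas and oracles."""

import numpy as np

import pytest

from oracles import (
    nei_he_oracle,
    theta_h_oracle,
    wc84_fis_oracle,
    wc84_theta_oracle,
)

from domscan import popstats
from domscan.io import panel_from_dosage
from domscan.synth import SynthSpec, generate_pair


def _panel_from_counts(counts1, counts2):
    """Two-population panel realizing given (n0, n1, n2) genotype counts."""
    def expand(cts):
        return [0] * cts[0] + [1] * cts[1] + [2] * cts[2]

    rows = []
    labels = []
    for lab, cts_list in (("wild", counts1), ("dom", counts2)):
        cols = [expand(c) for c in cts_list]
        n_ind = len(cols[0])
        assert all(len(c) == n_ind for c in cols)
        rows.append(np.array(cols).T)
        labels += [lab] * n_ind
    # pad unequal sample sizes by stacking blocks
    dosage = np.vstack(rows)
    return panel_from_dosage(dosage, np.array(labels, dtype=object))


class TestHetStats:
    def test_fixed_locus(self):
        # locus 0 all hom-ref in wild (polymorphic in the pair): zeros across
        # the board; locus 1 gives the textbook unbiased-He value
        panel = _panel_from_counts([(10, 0, 0), (5, 0, 5)], [(3, 4, 3), (3, 4, 3)])
        hs = popstats.het_stats(panel)
        assert hs[("wild", "Ho")].iloc[0] == 0.0
        assert hs[("wild", "He")].iloc[0] == 0.0
        assert hs[("wild", "MAF")].iloc[0] == 0.0
        assert hs[("wild", "Ho")].iloc[1] == 0.0
        assert hs[("wild", "He")].iloc[1] == pytest.approx(20 / 19 * 0.5, abs=1e-12)
        assert hs[("wild", "MAF")].iloc[1] == 0.5

    def test_matches_direct_oracle(self):
        rng = np.random.default_rng(4)
        dosage = rng.integers(0, 3, size=(12, 5))
        labels = np.array(["wild"] * 6 + ["dom"] * 6, dtype=object)
        panel = panel_from_dosage(dosage, labels)
        hs = popstats.het_stats(panel)
        for j in range(5):
            if len(panel.allele_registry[j]) != 2:
                continue
            g = panel.genotypes[:6, j]
            assert hs[("wild", "He")].iloc[j] == pytest.approx(
                nei_he_oracle(list(g)), abs=1e-12
            )

    def test_mean_he_decreases_with_smaller_ne(self):
        def mean_he(ne):
            vals = []
            for s in range(6):
                spec = SynthSpec(
                    n_loci=500, n_linkage_groups=5, n_wild=40, n_dom=40,
                    ne_wild=ne, ne_dom=ne, t=12, missing_rate=0.0, seed=s,
                )
                panel, _, _ = generate_pair(spec)
                vals.append(np.nanmean(popstats.het_stats(panel)[("wild", "He")]))
            return np.mean(vals)

        assert mean_he(25) < mean_he(400)


class TestWcFst:
    def test_fixed_difference_gives_theta_one(self):
        panel = _panel_from_counts([(5, 0, 0), (5, 0, 0)], [(0, 0, 5), (0, 0, 5)])
        res = popstats.wc_fst(panel, n_boot=10, seed=0)
        assert np.allclose(res.per_locus["theta"], 1.0)

    def test_identical_count_vectors_give_small_nonpositive_theta(self):
        cts = [(12, 26, 12)] * 40
        panel = _panel_from_counts(cts, cts)
        res = popstats.wc_fst(panel, n_boot=10, seed=0)
        assert res.theta <= 0 and abs(res.theta) < 0.05

    def test_matches_wc84_oracle_on_random_counts(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            c1 = tuple(rng.integers(0, 12, size=3))
            c2 = tuple(rng.integers(0, 12, size=3))
            if sum(c1) < 2 or sum(c2) < 2:
                continue
            pooled_alt = 2 * (c1[2] + c2[2]) + c1[1] + c2[1]
            pooled_tot = 2 * (sum(c1) + sum(c2))
            if pooled_alt in (0, pooled_tot):
                continue  # pooled-monomorphic: dosage undefined by design
            panel = _panel_from_counts([c1], [c2])
            res = popstats.wc_fst(panel, n_boot=2, seed=0)
            a, b, c = wc84_theta_oracle(c1, c2)
            # polarity of the dosage recode may flip p -> 1-p; WC84 components
            # are invariant to that flip
            assert res.per_locus["a"].iloc[0] == pytest.approx(a, abs=1e-12)
            assert res.per_locus["b"].iloc[0] == pytest.approx(b, abs=1e-12)
            assert res.per_locus["c"].iloc[0] == pytest.approx(c, abs=1e-12)

    def test_multilocus_theta_within_per_locus_range(self):
        spec = SynthSpec(
            n_loci=300, n_linkage_groups=3, n_wild=30, n_dom=30,
            ne_wild=100, ne_dom=100, t=8, missing_rate=0.05, seed=3,
        )
        panel, _, _ = generate_pair(spec)
        res = popstats.wc_fst(panel, n_boot=50, seed=1)
        thetas = res.per_locus["theta"].dropna()
        assert thetas.min() <= res.theta <= thetas.max()
        assert res.ci[0] <= res.theta <= res.ci[1]

    def test_bootstrap_ci_narrows_with_more_loci(self):
        def width(n_loci, seed):
            spec = SynthSpec(
                n_loci=n_loci, n_linkage_groups=5, n_wild=40, n_dom=40,
                ne_wild=150, ne_dom=150, t=8, missing_rate=0.0, seed=seed,
            )
            panel, _, _ = generate_pair(spec)
            res = popstats.wc_fst(panel, n_boot=300, seed=0)
            return res.ci[1] - res.ci[0]

        small = np.mean([width(100, s) for s in range(3)])
        large = np.mean([width(2000, s) for s in range(3)])
        assert large < small


class TestWcFis:
    def test_hw_proportions_give_near_zero_f(self):
        rng = np.random.default_rng(11)
        dosage = rng.binomial(2, 0.5, size=(200, 1000))
        labels = np.array(["wild"] * 100 + ["dom"] * 100, dtype=object)
        panel = panel_from_dosage(dosage, labels)
        res = popstats.wc_fis(panel, n_boot=10, seed=0)
        assert abs(res["wild"].f) < 0.02

    def test_all_heterozygote_population_gives_minus_one(self):
        panel = _panel_from_counts([(0, 8, 0), (0, 8, 0)], [(2, 4, 2), (2, 4, 2)])
        res = popstats.wc_fis(panel, n_boot=10, seed=0)
        assert res["wild"].f == pytest.approx(-1.0, abs=1e-12)

    def test_matches_wc84_single_population_oracle(self):
        rng = np.random.default_rng(13)
        counts = []
        for _ in range(5):  # fixed sample size of 12, all classes present
            n0 = int(rng.integers(1, 6))
            n1 = int(rng.integers(1, 6))
            counts.append((n0, n1, 12 - n0 - n1))
        panel = _panel_from_counts(counts, counts)
        res = popstats.wc_fis(panel, n_boot=2, seed=0)
        assert res["wild"].f == pytest.approx(wc84_fis_oracle(counts), abs=1e-12)


class TestPopSpecificFst:
    def test_identical_frequencies_give_near_zero_betas(self):
        rng = np.random.default_rng(17)
        dosage = rng.binomial(2, 0.4, size=(400, 800))
        labels = np.array(["wild"] * 200 + ["dom"] * 200, dtype=object)
        panel = panel_from_dosage(dosage, labels)
        betas = popstats.pop_specific_fst(panel)
        assert abs(betas["wild"]) < 0.01 and abs(betas["dom"]) < 0.01

    def test_fixed_difference_gives_beta_one(self):
        panel = _panel_from_counts([(6, 0, 0), (6, 0, 0)], [(0, 0, 6), (0, 0, 6)])
        betas = popstats.pop_specific_fst(panel)
        assert betas["wild"] == pytest.approx(1.0)
        assert betas["dom"] == pytest.approx(1.0)

    def test_betas_average_to_overall_matching_differentiation(self):
        """Weighted by the shared denominator, mean(beta_i) equals the
        matching-based overall differentiation."""
        spec = SynthSpec(
            n_loci=400, n_linkage_groups=4, n_wild=30, n_dom=30,
            ne_wild=100, ne_dom=100, t=10, missing_rate=0.0, seed=21,
        )
        panel, _, _ = generate_pair(spec)
        betas = popstats.pop_specific_fst(panel)
        hs = popstats.het_stats(panel)
        pops = panel.populations
        p = {}
        for lab in pops:
            n0, n1, n2, n = panel.dosage_counts(lab)
            with np.errstate(invalid="ignore"):
                p[lab] = np.where(n > 0, (n1 + 2 * n2) / (2 * np.maximum(n, 1)), np.nan)
        p1, p2 = p[pops[0]], p[pops[1]]
        mb = p1 * p2 + (1 - p1) * (1 - p2)
        mw = 0.5 * ((1 - hs[(pops[0], "He")]) + (1 - hs[(pops[1], "He")]))
        ok = np.isfinite(mb) & np.isfinite(mw)
        overall = np.nansum((mw - mb)[ok]) / np.nansum((1 - mb)[ok])
        assert np.mean([betas[pops[0]], betas[pops[1]]]) == pytest.approx(
            overall, abs=1e-12
        )


class TestLnRH:
    def test_equal_he_gives_zero_raw(self):
        cts = [(3, 6, 3), (2, 6, 4), (4, 6, 2)]
        panel = _panel_from_counts(cts, cts)
        res = popstats.lnrh(panel, "wild", "dom")
        assert np.allclose(res.table["lnrh_raw"].dropna(), 0.0, atol=1e-12)

    def test_formula_value(self):
        # He_wild = 0.5, He_dom = 0.2 -> ln(1.5 / 0.28125) = 1.67398...
        assert np.log(
            theta_h_oracle(0.5) / theta_h_oracle(0.2)
        ) == pytest.approx(1.6739764335716716, abs=1e-12)

    def test_swapping_roles_negates_raw_values(self):
        spec = SynthSpec(
            n_loci=200, n_linkage_groups=2, n_wild=25, n_dom=30,
            ne_wild=80, ne_dom=80, t=6, missing_rate=0.05, seed=2,
        )
        panel, _, _ = generate_pair(spec)
        fwd = popstats.lnrh(panel, "wild", "dom").table["lnrh_raw"]
        rev = popstats.lnrh(panel, "dom", "wild").table["lnrh_raw"]
        assert np.allclose(fwd.dropna(), -rev.dropna(), atol=1e-12)

    def test_z_column_is_standardized(self):
        spec = SynthSpec(
            n_loci=1000, n_linkage_groups=5, n_wild=40, n_dom=40,
            ne_wild=150, ne_dom=150, t=8, missing_rate=0.02, seed=6,
        )
        panel, _, _ = generate_pair(spec)
        z = popstats.lnrh(panel, "wild", "dom").table["lnrh_z"].dropna()
        assert abs(z.mean()) < 1e-9
        assert abs(z.std(ddof=1) - 1.0) < 1e-9

    def test_monomorphic_in_one_population_uses_floor(self):
        # wild locus fixed (He=0) stays in the scan via the 1/(2n) floor
        panel = _panel_from_counts(
            [(8, 0, 0), (3, 4, 1)], [(3, 4, 1), (3, 4, 1)]
        )
        res = popstats.lnrh(panel, "wild", "dom")
        assert np.isfinite(res.table["lnrh_raw"].iloc[0])
        he_floor = 1.0 / 16.0
        he_dom = nei_he_oracle([0] * 3 + [1] * 4 + [2])
        expected = np.log(theta_h_oracle(he_floor) / theta_h_oracle(he_dom))
        assert res.table["lnrh_raw"].iloc[0] == pytest.approx(expected, abs=1e-12)


class TestScalarFormulas:
    @pytest.mark.parametrize(
        "alpha, expected",
        [(0.01, 2.58), (0.3173, 1.00), (0.05, 1.96)],
    )
    def test_lnrh_threshold(self, alpha, expected):
        assert round(popstats.lnrh_threshold(alpha), 2) == expected

    @pytest.mark.parametrize(
        "n, expected", [(4733, 47), (4039, 40), (2797, 28), (0, 0)]
    )
    def test_expected_false_positives(self, n, expected):
        assert popstats.expected_false_positives(n, 0.01) == expected

    def test_ne_moment(self):
        assert popstats.ne_moment(1, 0.5) == 1
        assert popstats.ne_moment(9, 0.015) == pytest.approx(300)
        assert popstats.ne_moment(5, 0.0069) == pytest.approx(362.3188, abs=1e-3)
        with pytest.raises(ValueError):
            popstats.ne_moment(5, 0.0)

    def test_diversity_loss(self):
        assert popstats.diversity_loss(0.5, 0.5) == 0
        assert popstats.diversity_loss(0.381, 0.370) == pytest.approx(
            0.0288714, abs=1e-6
        )
        with pytest.raises(ValueError):
            popstats.diversity_loss(0.0, 0.1)

    @pytest.mark.parametrize(
        "length, half, expected",
        [(2500, 0.2, 12500), (2500, 2.2, 1136), (2500, 2500, 1)],
    )
    def test_markers_needed(self, length, half, expected):
        assert popstats.markers_needed(length, half) == expected
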