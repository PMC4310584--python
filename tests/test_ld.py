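"""Two-locus EM haplotype frequencies and Hill-Weir decay fitting."""

import numpy as np
import pandas as pd
import pytest

from oracles import haplotype_counts_phase_known

from domscan import ld
from domscan.datamodel import LinkageMap
from domscan.io import panel_from_dosage


def _one_pop_panel(dosage):
    n = dosage.shape[0]
    return panel_from_dosage(
        np.asarray(dosage), np.array(["w"] * n, dtype=object)
    )


class TestEmHaplotypes:
    def test_perfect_coupling_gives_full_ld(self):
        g = np.array([0, 0, 1, 1, 2, 2, 0, 2])
        freqs, _ = ld.em_haplotype_freqs(g, g)
        r2, dprime = ld.ld_from_freqs(freqs)
        assert r2 == pytest.approx(1.0, abs=1e-9)
        assert dprime == pytest.approx(1.0, abs=1e-9)

    def test_phase_known_cases_equal_direct_counts(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            g1 = rng.integers(0, 3, size=30)
            g2 = rng.integers(0, 3, size=30)
            g2[(g1 == 1) & (g2 == 1)] = 2  # remove double heterozygotes
            freqs, _ = ld.em_haplotype_freqs(g1, g2)
            direct = haplotype_counts_phase_known(g1, g2)
            assert np.allclose(freqs, direct, atol=1e-12)

    def test_dprime_is_one_when_a_haplotype_class_is_absent(self):
        # AB, Ab, aB present; ab absent -> |D'| = 1 at the boundary
        g1 = np.array([2, 2, 1, 1, 2, 1])
        g2 = np.array([2, 0, 0, 2, 1, 0])
        g2[(g1 == 1) & (g2 == 1)] = 0
        freqs, _ = ld.em_haplotype_freqs(g1, g2)
        if np.min(freqs) < 1e-9:  # a class truly absent
            _, dprime = ld.ld_from_freqs(freqs)
            assert dprime == pytest.approx(1.0, abs=1e-6)


class TestPairwiseLd:
    def test_independent_loci_mean_r2_near_1_over_n(self):
        """With unlinked loci, E[r^2] ~ 1/n from sampling noise alone."""
        rng = np.random.default_rng(15)
        n = 100
        n_loci = 52  # ~1300 pairs; restrict to 500 below
        dosage = rng.binomial(2, rng.uniform(0.2, 0.8, n_loci), size=(n, n_loci))
        panel = _one_pop_panel(dosage)
        lmap = LinkageMap(
            panel.locus_ids, ["LG01"] * n_loci,
            np.linspace(0, 50, n_loci),
        )
        pairs = ld.pairwise_ld(panel, lmap, max_distance=50).head(500)
        se = pairs["r2"].std(ddof=1) / np.sqrt(len(pairs))
        assert abs(pairs["r2"].mean() - 1.0 / n) < 3 * se

    def test_pairs_respect_distance_cutoff_and_linkage_groups(self):
        rng = np.random.default_rng(2)
        dosage = rng.binomial(2, 0.5, size=(30, 6))
        panel = _one_pop_panel(dosage)
        lmap = LinkageMap(
            panel.locus_ids,
            ["LG01"] * 3 + ["LG02"] * 3,
            [0.0, 5.0, 30.0, 0.0, 2.0, 4.0],
        )
        pairs = ld.pairwise_ld(panel, lmap, max_distance=10)
        keys = set(zip(pairs["locus_a"], pairs["locus_b"]))
        ids = list(panel.locus_ids)
        assert (ids[0], ids[2]) not in keys  # 30 cM apart
        assert all(
            lmap[a][0] == lmap[b][0] for a, b in keys
        )

    def test_monomorphic_locus_pairs_are_skipped(self):
        dosage = np.column_stack([np.zeros(20, int), [0, 1] * 10, [1, 2] * 10])
        panel = _one_pop_panel(dosage)
        lmap = LinkageMap(panel.locus_ids, ["LG01"] * 3, [0.0, 1.0, 2.0])
        pairs = ld.pairwise_ld(panel, lmap, max_distance=10)
        assert set(pairs["locus_a"]) | set(pairs["locus_b"]) <= {
            panel.locus_ids[1], panel.locus_ids[2]
        }


class TestDecayFit:
    def test_recovers_rho_from_exact_curve(self):
        rho, n = 2.0, 100
        d = np.linspace(0.05, 12, 60)
        pairs = pd.DataFrame(
            {"distance_cm": d, "r2": ld.hill_weir_expected_r2(rho * d, n)}
        )
        fit = ld.fit_decay(pairs, n_chromosomes=n)
        assert fit.rho_per_cm == pytest.approx(rho, rel=0.01)
        # half-decay solves the fitted curve at half its zero-distance value
        f0 = ld.hill_weir_expected_r2(0.0, n)
        at_half = ld.hill_weir_expected_r2(fit.rho_per_cm * fit.half_decay, n)
        assert at_half == pytest.approx(f0 / 2, abs=1e-9)

    def test_distance_rescaling_inverts_rho_and_scales_half_decay(self):
        rho, n = 1.5, 80
        d = np.linspace(0.1, 8, 40)
        r2 = ld.hill_weir_expected_r2(rho * d, n)
        fit1 = ld.fit_decay(pd.DataFrame({"distance_cm": d, "r2": r2}), n)
        fit2 = ld.fit_decay(pd.DataFrame({"distance_cm": 2 * d, "r2": r2}), n)
        assert fit2.rho_per_cm == pytest.approx(fit1.rho_per_cm / 2, rel=1e-6)
        assert fit2.half_decay == pytest.approx(2 * fit1.half_decay, rel=1e-6)

    def test_half_decay_monotone_decreasing_in_rho(self):
        n = 100
        halves = []
        for rho in (0.5, 1.0, 2.0, 4.0):
            d = np.linspace(0.05, 20, 50)
            pairs = pd.DataFrame(
                {"distance_cm": d, "r2": ld.hill_weir_expected_r2(rho * d, n)}
            )
            halves.append(ld.fit_decay(pairs, n).half_decay)
        assert all(a > b for a, b in zip(halves, halves[1:]))

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError, match="one distance"):
            ld.fit_decay(
                pd.DataFrame({"distance_cm": [1.0] * 12, "r2": np.linspace(0, 1, 12)}),
                100,
            )
        with pytest.raises(ValueError, match="constant r2"):
            ld.fit_decay(
                pd.DataFrame(
                    {"distance_cm": np.linspace(0, 5, 12), "r2": [0.3] * 12}
                ),
                100,
            )
        with pytest.raises(ValueError, match=">= 10 pairs"):
            ld.fit_decay(
                pd.DataFrame({"distance_cm": [1, 2, 3], "r2": [0.5, 0.4, 0.3]}), 100
            )


def test_background_r2_in_drift_panel_approaches_1_over_n():
    """At large map distance in a drifted population, r^2 settles near the
    finite-sample floor 1/n_chromosomes... here dominated by sample size."""
    from domscan.synth import SynthSpec, generate_pair

    spec = SynthSpec(
        n_loci=40, n_linkage_groups=1, n_wild=60, n_dom=10, ne_wild=500,
        ne_dom=500, t=5, missing_rate=0.0, seed=31,
    )
    panel, lmap, _ = generate_pair(spec)
    wild = panel.population_panel("wild")
    pairs = ld.pairwise_ld(wild, lmap, max_distance=100)
    far = pairs[pairs["distance_cm"] > 40]
    assert len(far) > 30
    # drift panel loci are generated independently: background level only
    assert far["r2"].mean() < 3.0 / 60
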