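"""SSR diversity statistics, Shannon AMOVA and Evanno ΔK."""

import numpy as np
import pandas as pd
import pytest

from saltscreen import simulate
from saltscreen.diversity import (
    AssignmentError,
    GenotypeMatrix,
    band_matrix_to_calls,
    evanno_delta_k,
    locus_summaries,
    panel_summary,
    pic_from_frequencies,
    shannon_amova,
)


def _matrix(cols: dict) -> GenotypeMatrix:
    n = len(next(iter(cols.values())))
    return GenotypeMatrix(pd.DataFrame(cols, index=[f"i{k}" for k in range(n)]))


class TestLocusSummaries:
    def test_monomorphic(self):
        (s,) = locus_summaries(_matrix({"L1": ["a/a"] * 5}))
        assert (s.allele_count, s.He, s.PIC, s.Ho) == (1, 0.0, 0.0, 0.0)

    def test_biallelic_equifrequent(self):
        (s,) = locus_summaries(_matrix({"L1": ["a/a", "b/b", "a/b", "b/a"]}))
        assert s.He == pytest.approx(0.5)
        assert s.PIC == pytest.approx(0.375)
        assert s.Ho == pytest.approx(0.5)  # two of four heterozygous

    def test_four_allele_equifrequent(self):
        (s,) = locus_summaries(_matrix({"L1": ["a/b", "c/d", "a/c", "b/d"]}))
        assert s.He == pytest.approx(0.75)
        assert s.PIC == pytest.approx(0.703125)

    def test_missing_excluded_from_frequencies(self):
        (s,) = locus_summaries(_matrix({"L1": ["a/a", "NA", "b/b", "NA"]}))
        assert s.frequencies == {"a": 0.5, "b": 0.5}

    def test_pic_bounded_by_he(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            k = rng.integers(1, 6)
            p = rng.dirichlet(np.ones(k))
            pic = pic_from_frequencies(p)
            he = 1 - np.sum(p**2)
            assert pic <= he + 1e-12
            assert pic >= 0 or np.isclose(pic, 0)


class TestPanelSummary:
    def test_printed_panel_aggregates(self):
        """30 loci totalling 109 alleles average 3.63 alleles per locus."""
        counts = [4] * 19 + [3] * 11  # 19*4 + 11*3 = 109
        summaries = []
        for i, c in enumerate(counts):
            # c equifrequent alleles at a synthetic locus
            labels = [f"a{j}" for j in range(c)]
            calls = [f"{labels[j % c]}/{labels[(j + 1) % c]}" for j in range(12)]
            summaries += locus_summaries(_matrix({f"L{i}": calls}))
        agg = panel_summary(summaries)
        assert agg["total_alleles"] == 109
        assert agg["n_loci"] == 30
        assert round(agg["mean_alleles_per_locus"], 2) == 3.63

    def test_simple_means(self):
        s2 = locus_summaries(_matrix({"L1": ["a/b", "a/a"]}))
        assert panel_summary(s2)["mean_alleles_per_locus"] == 2.0
        s25 = locus_summaries(_matrix({"L1": ["a/b"] * 3, "L2": ["a/b", "c/d", "e/a"]}))
        assert panel_summary(s25)["mean_alleles_per_locus"] == 3.5


class TestShannonAmova:
    def test_null_partition(self, fixed_genotypes):
        g, pops = fixed_genotypes
        same = GenotypeMatrix(pd.DataFrame({"L1": ["a/b"] * 8}, index=g.individuals))
        res = shannon_amova(same, pops, permutations=99, seed=0)
        assert res.I_among == pytest.approx(0.0, abs=1e-12)
        assert res.G_among == pytest.approx(0.0, abs=1e-9)
        assert res.p_among > 0.9

    def test_fixed_difference_closed_form(self, fixed_genotypes):
        """Two equal pops fixed for different alleles: I_among = ln 2 per
        locus, all variation among populations."""
        g, pops = fixed_genotypes
        res = shannon_amova(g, pops, permutations=99, seed=0)
        assert res.I_among == pytest.approx(np.log(2))
        assert res.I_within == pytest.approx(0.0, abs=1e-12)
        assert res.pct_among == pytest.approx(100.0)
        # G = 2N I per locus summed: N = 16 copies, 3 loci
        assert res.G_among == pytest.approx(2 * 16 * np.log(2) * 3)

    def test_additivity_invariants(self):
        g, pops = simulate.simulate_genotypes(simulate.PopSimConfig(fst=0.2, seed=9))
        res = shannon_amova(g, pops, permutations=50, seed=1)
        assert res.G_total == pytest.approx(res.G_among + res.G_within, abs=1e-9)
        assert res.var_total == pytest.approx(res.var_among + res.var_within, abs=1e-9)
        assert res.pct_among + res.pct_within == pytest.approx(100.0, abs=1e-9)
        assert res.df_total == res.df_among + res.df_within
        assert res.I_among >= 0

    def test_seed_reproducibility(self):
        g, pops = simulate.simulate_genotypes(simulate.PopSimConfig(fst=0.1, seed=4))
        r1 = shannon_amova(g, pops, permutations=100, seed=42)
        r2 = shannon_amova(g, pops, permutations=100, seed=42)
        assert r1.p_among == r2.p_among
        assert r1.p_within == r2.p_within

    def test_pct_among_increases_with_fst(self):
        means = []
        for fst in (0.0, 0.1, 0.2, 0.4):
            vals = []
            for seed in range(10):
                g, pops = simulate.simulate_genotypes(
                    simulate.PopSimConfig(n_populations=3, n_individuals=10, fst=fst, seed=seed)
                )
                vals.append(shannon_amova(g, pops, permutations=0, seed=0).pct_among)
            means.append(np.mean(vals))
        assert means == sorted(means)

    def test_bad_assignment_raises(self, fixed_genotypes):
        g, pops = fixed_genotypes
        with pytest.raises(AssignmentError):
            shannon_amova(g, {k: "p1" for k in g.individuals}, permutations=10)
        with pytest.raises(AssignmentError):
            shannon_amova(g, {k: v for k, v in list(pops.items())[:-1]}, permutations=10)


class TestBandMatrix:
    def test_calls_from_bands(self):
        bands = pd.DataFrame(
            {"b1": [1, 1, 0, 0], "b2": [0, 1, 0, 1]},
            index=["i1", "i2", "i3", "i4"],
        )
        calls = band_matrix_to_calls(bands, "M1")
        assert calls["i1"] == "b1/b1"
        assert calls["i2"] == "b1/b2"  # top band first
        assert calls["i3"] == "NA"
        assert calls["i4"] == "b2/b2"

    def test_three_bands_raise(self):
        bands = pd.DataFrame({"b1": [1], "b2": [1], "b3": [1]}, index=["i1"])
        with pytest.raises(ValueError, match="more than 2"):
            band_matrix_to_calls(bands, "M1")


class TestEvannoDeltaK:
    def _runs(self, means, sd=10.0, reps=3, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for k, m in enumerate(means, start=1):
            for r in range(reps):
                rows.append({"K": k, "replicate": r, "lnP": m + rng.normal(0, sd)})
        return pd.DataFrame(rows)

    def test_linear_means_give_zero(self):
        rows = []
        for k, m in enumerate([-5000, -4000, -3000, -2000], start=1):
            # replicates symmetric around the mean so each mean is exact
            rows += [{"K": k, "replicate": r, "lnP": m + d} for r, d in enumerate((-5, 0, 5))]
        out = evanno_delta_k(pd.DataFrame(rows))
        assert np.allclose(out["deltaK"], 0.0)

    def test_hand_computed_value(self):
        rows = []
        for k, m in enumerate([-5000, -4000, -3900], start=1):
            rows += [{"K": k, "replicate": r, "lnP": m + d} for r, d in enumerate((-10, 0, 10))]
        out = evanno_delta_k(pd.DataFrame(rows))
        # |(-3900) - 2(-4000) + (-5000)| = 900; sd over (-10, 0, 10) = 10
        assert out.set_index("K").loc[2, "deltaK"] == pytest.approx(90.0)

    def test_replicate_permutation_invariance(self):
        runs = self._runs([-5000, -4500, -4400, -4350], seed=1)
        shuffled = runs.sample(frac=1.0, random_state=5).reset_index(drop=True)
        out1 = evanno_delta_k(runs)
        out2 = evanno_delta_k(shuffled)
        assert np.allclose(out1["deltaK"], out2["deltaK"])

    def test_peak_at_true_k(self):
        runs = simulate.simulate_structure_runs(true_k=2, seed=0)
        out = evanno_delta_k(runs).set_index("K")
        assert out["deltaK"].idxmax() == 2

    def test_too_few_k_raises(self):
        with pytest.raises(ValueError):
            evanno_delta_k(self._runs([-100, -90]))
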