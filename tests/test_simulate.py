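import numpy as np
import pandas as pd
import pytest

from binqtl.genome import ConfigurationError, build_genome_template
from binqtl.matrix import A, B, H, N
from binqtl.simulate import (
    TraitArchitecture,
    architecture_for_h2,
    corrupt_genotypes,
    genetic_values,
    simulate_phenotypes,
    simulate_ril_population,
)
from binqtl.phenostats import VarianceComponents, heritability


def _template(n_chrom=1, bp=100_000_000, cm=100.0, snps=200, seed=1):
    return build_genome_template(n_chrom, [bp] * n_chrom, [cm] * n_chrom, snps, seed=seed)


class TestRILSimulation:
    def test_f2_heterozygosity_near_half(self):
        truth, _ = simulate_ril_population(_template(), 300, 1, seed=2)
        assert truth.het_fraction() == pytest.approx(0.5, abs=0.05)

    def test_f6_heterozygosity_matches_selfing_recursion(self):
        truth, _ = simulate_ril_population(_template(), 300, 5, seed=3)
        assert truth.het_fraction() == pytest.approx(0.5**5, abs=0.015)

    def test_zero_genetic_length_gives_zero_breakpoints(self):
        tpl = _template(cm=0.0)
        truth, _ = simulate_ril_population(tpl, 50, 6, seed=4)
        assert truth.n_breakpoints().sum() == 0

    def test_calls_consistent_with_true_segments(self):
        """Re-deriving segments from error-free SNP calls recovers the truth."""
        tpl = _template(snps=2000)
        truth, matrix = simulate_ril_population(tpl, 30, 6, seed=5)
        pos = tpl.snp_positions["chr1"]
        for i in range(30):
            expected = truth.label_at("chr1", i, pos)
            assert np.array_equal(matrix.calls["chr1"][i], expected)

    def test_crossover_count_matches_map_expansion_and_oracle(self):
        """Mean crossovers per line ~ 2 x genetic length in Morgans,
        cross-checked against an independent discrete-locus gamete tracker."""
        cm = 150.0
        truth, _ = simulate_ril_population(_template(cm=cm), 1000, 6, seed=6)
        sim_mean = truth.n_crossovers().mean()
        oracle_mean = _oracle_crossovers(cm, generations=6, n_lines=1000, seed=7)
        assert sim_mean == pytest.approx(2 * cm / 100, rel=0.10)
        assert sim_mean == pytest.approx(oracle_mean, rel=0.08)

    def test_reproducible_from_seed(self):
        tpl = _template(snps=300)
        t1, m1 = simulate_ril_population(tpl, 20, 6, seed=11)
        t2, m2 = simulate_ril_population(tpl, 20, 6, seed=11)
        assert np.array_equal(m1.calls["chr1"], m2.calls["chr1"])
        assert all(
            np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
            for a, b in zip(t1.segments["chr1"], t2.segments["chr1"])
        )

    def test_selfing_requires_at_least_one_generation(self):
        with pytest.raises(ConfigurationError):
            simulate_ril_population(_template(), 10, 0, seed=1)


def _oracle_crossovers(cm, generations, n_lines, seed, n_loci=400):
    """Brute-force single-chromosome gamete tracker on a discrete locus grid.

    Haplotypes are boolean vectors; a meiosis draws a Poisson crossover count
    with uniform positions and splices the two parental vectors. Counts
    switches between successive homozygous diplotypes, skipping het loci.
    """
    rng = np.random.default_rng(seed)
    grid = np.linspace(0, cm, n_loci, endpoint=False)
    counts = []
    for _ in range(n_lines):
        h1 = np.zeros(n_loci, dtype=np.int8)
        h2 = np.ones(n_loci, dtype=np.int8)
        for _ in range(generations):
            gametes = []
            for _ in range(2):
                n_xo = rng.poisson(cm / 100)
                xo = np.sort(rng.uniform(0, cm, n_xo))
                use_second = (np.searchsorted(xo, grid) + rng.integers(0, 2)) % 2
                gametes.append(np.where(use_second == 1, h2, h1))
            h1, h2 = gametes
        hom = h1[h1 == h2]
        counts.append(int((hom[:-1] != hom[1:]).sum()) if hom.size > 1 else 0)
    return float(np.mean(counts))


class TestCorruption:
    def test_zero_rates_identity(self, small_population):
        _, clean = small_population
        out = corrupt_genotypes(clean, 0.0, 0.0, seed=1)
        for c in clean.chroms:
            assert np.array_equal(out.calls[c], clean.calls[c])

    def test_full_missingness(self, small_population):
        _, clean = small_population
        out = corrupt_genotypes(clean, 0.0, 1.0, seed=1)
        for c in clean.chroms:
            assert np.all(out.calls[c] == N)

    def test_flip_fraction_within_binomial_interval(self):
        tpl = _template(snps=5000)
        _, clean = simulate_ril_population(tpl, 200, 6, seed=8)  # 1e6 calls
        out = corrupt_genotypes(clean, 0.01, 0.0, seed=9)
        flipped = (out.calls["chr1"] != clean.calls["chr1"]).mean()
        n = clean.calls["chr1"].size
        half_width = 3 * np.sqrt(0.01 * 0.99 / n)
        assert abs(flipped - 0.01) < half_width

    def test_input_unmodified(self, small_population):
        _, clean = small_population
        before = clean.calls["chr1"].copy()
        corrupt_genotypes(clean, 0.5, 0.5, seed=1)
        assert np.array_equal(clean.calls["chr1"], before)

    @pytest.mark.parametrize("err,miss", [(-0.1, 0), (0, 1.5)])
    def test_rates_validated(self, small_population, err, miss):
        _, clean = small_population
        with pytest.raises(ConfigurationError):
            corrupt_genotypes(clean, err, miss, seed=1)


class TestPhenotypes:
    def test_all_zero_gives_intercept(self, small_population):
        truth, _ = small_population
        arch = TraitArchitecture(
            qtls=[], var_gy=0, var_gl=0, var_gly=0, var_e=0,
            var_env=0, var_rep=0, intercept=7.5,
        )
        ph = simulate_phenotypes(truth, arch, seed=1)
        assert np.allclose(ph["value"], 7.5)

    def test_substitution_effect_is_two(self, small_population):
        truth, _ = small_population
        qtl = [("chr1", 25_000_000, 1.0)]
        g = genetic_values(truth, qtl)
        labels = truth.label_at("chr1", 0, [25_000_000])  # sanity: labels exist
        assert labels[0] in (A, B, H)
        a_lines = g == 1.0
        b_lines = g == -1.0
        assert a_lines.any() and b_lines.any()
        assert g[a_lines][0] - g[b_lines][0] == pytest.approx(2.0)

    def test_off_chromosome_qtl_rejected(self, small_population):
        truth, _ = small_population
        with pytest.raises(ConfigurationError):
            genetic_values(truth, [("chr9", 1000, 1.0)])
        with pytest.raises(ConfigurationError):
            genetic_values(truth, [("chr1", 10**9, 1.0)])

    def test_record_layout(self, small_population):
        truth, _ = small_population
        arch = TraitArchitecture(qtls=[("chr1", 10_000_000, 0.5)])
        ph = simulate_phenotypes(truth, arch, seed=2)
        assert len(ph) == 60 * len(arch.env_cells) * arch.reps
        assert not ph.duplicated(["line", "env", "rep"]).any()

    def test_architecture_tuned_for_h2_closes_formula(self, small_population):
        truth, _ = small_population
        qtls = [("chr1", 20_000_000, 0.4), ("chr2", 30_000_000, 0.3)]
        arch = architecture_for_h2(truth, qtls, 0.81)
        vc = VarianceComponents(
            var_g=arch.var_g, var_gy=arch.var_gy, var_gl=arch.var_gl,
            var_gly=arch.var_gly, var_e=arch.var_e,
            n_years=2, n_locations=2, n_reps=3,
        )
        assert heritability(vc) == pytest.approx(0.81, abs=1e-12)

    def test_truth_bed_export(self, small_population, tmp_path):
        truth, _ = small_population
        path = tmp_path / "truth.bed"
        truth.to_bed(path)
        df = pd.read_csv(path, sep="\t")
        one = df[(df["line"] == truth.lines[0]) & (df["chrom"] == "chr1")]
        assert one["start"].iloc[0] == 0
        assert one["end"].iloc[-1] == 50_000_000
        assert np.array_equal(one["start"].to_numpy()[1:], one["end"].to_numpy()[:-1])
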