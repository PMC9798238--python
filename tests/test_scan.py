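import numpy as np
import pandas as pd
import pytest

from binqtl.binmap import BinMap
from binqtl.linkage import build_map
from binqtl.matrix import A, B, H, N
from binqtl.scan import (
    cim_scan,
    estimate_effects,
    fit_multi_qtl,
    genotype_probs,
    permutation_max_lods,
    permutation_threshold,
    scan_trait,
    select_cofactors,
    support_interval,
)


def _toy_binmap(genotypes, chrom="chr1", bin_size=1_000_000):
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n_lines, n_bins = genotypes.shape
    bins = pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n_bins) * bin_size,
            "end": (np.arange(n_bins) + 1) * bin_size,
            "bin_id": [f"mk{i + 1}" for i in range(n_bins)],
        }
    )
    return BinMap(lines=[f"L{i}" for i in range(n_lines)], bins=bins, genotypes=genotypes)


@pytest.fixture(scope="module")
def toy_grid(rng_module):
    """30 lines x 12 bins two-state mosaic with moderate recombination."""
    rng = rng_module
    n, m = 30, 12
    geno = np.empty((n, m), dtype=np.int8)
    geno[:, 0] = rng.integers(0, 2, n)
    for j in range(1, m):
        switch = rng.random(n) < 0.15
        geno[:, j] = np.where(switch, 1 - geno[:, j - 1], geno[:, j - 1])
    bm = _toy_binmap(geno)
    gmap = build_map(bm)
    return bm, gmap, genotype_probs(gmap, bm)


@pytest.fixture(scope="module")
def rng_module():
    return np.random.default_rng(1234)


class TestGenotypeProbs:
    def test_degenerate_at_observed_markers(self, toy_grid):
        bm, gmap, grid = toy_grid
        obs = bm.genotypes
        for j in range(grid.n_pos):
            col = grid.scores[:, j]
            assert np.all(col[obs[:, j] == A] == 1.0)
            assert np.all(col[obs[:, j] == B] == -1.0)

    def test_missing_call_conditioned_on_flanks(self):
        rows = [[A, N, A]] * 10 + [[B, N, B]] * 10 + [[A, N, B]] * 2 + [[A, B, B]]
        bm = _toy_binmap(np.array(rows, dtype=np.int8))
        grid = genotype_probs(build_map(bm), bm)
        s = grid.scores
        assert s[0, 1] > 0.9        # A?A -> almost surely A
        assert s[10, 1] < -0.9      # B?B -> almost surely B
        assert abs(s[20, 1]) < 0.7  # A?B -> intermediate

    def test_equidistant_opposite_flanks_symmetric(self):
        geno = np.array([[A, N, B]] * 6 + [[A, A, A], [B, B, B]] * 3, dtype=np.int8)
        bm = _toy_binmap(geno)
        grid = genotype_probs(build_map(bm), bm)
        assert grid.scores[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_pseudomarker_grid_contains_markers(self, toy_grid):
        bm, gmap, _ = toy_grid
        grid = genotype_probs(gmap, bm, grid_step=1.0)
        assert grid.is_marker.sum() == len(gmap.table)
        assert grid.n_pos > grid.is_marker.sum()


class TestCIMScan:
    def test_constant_phenotype_zero_lod(self, toy_grid):
        _, _, grid = toy_grid
        lod = cim_scan(grid, np.full(len(grid.lines), 3.3))
        assert np.allclose(lod, 0.0)

    def test_noise_free_qtl_peaks_exactly_at_marker(self, toy_grid):
        _, _, grid = toy_grid
        y = grid.scores[:, 7].copy()
        lod = cim_scan(grid, y)
        assert int(np.argmax(lod)) == 7

    def test_equivalence_to_simple_interval_mapping_oracle(self, toy_grid, rng_module):
        """With no cofactors the scan must equal direct Haley-Knott
        regression computed independently per position."""
        _, _, grid = toy_grid
        y = rng_module.normal(0, 1, len(grid.lines)) + 0.5 * grid.scores[:, 4]
        lod = cim_scan(grid, y, cofactors=[])
        n = y.size
        yc = y - y.mean()
        rss0 = yc @ yc
        for j in range(grid.n_pos):
            x = grid.scores[:, j]
            xc = x - x.mean()
            denom = xc @ xc
            rss1 = rss0 - (xc @ yc) ** 2 / denom if denom > 1e-12 else rss0
            expected = 0.5 * n * np.log10(rss0 / rss1)
            assert lod[j] == pytest.approx(expected, abs=1e-10)

    def test_affine_invariance(self, toy_grid, rng_module):
        _, _, grid = toy_grid
        y = rng_module.normal(0, 1, len(grid.lines))
        cof = [2]
        lod1 = cim_scan(grid, y, cof)
        lod2 = cim_scan(grid, -2.5 * y + 7.0, cof)
        assert np.allclose(lod1, lod2, atol=1e-8)

    def test_cofactor_excluded_near_test_position(self, toy_grid, rng_module):
        _, _, grid = toy_grid
        y = grid.scores[:, 5] + 0.1 * rng_module.normal(0, 1, len(grid.lines))
        lod_with = cim_scan(grid, y, cofactors=[5], window_cm=10.0)
        # at the cofactor position itself the cofactor is dropped, so the
        # signal must survive there
        assert lod_with[5] > 3.0


class TestPermutations:
    def test_constant_phenotype_zero_threshold(self, toy_grid):
        _, _, grid = toy_grid
        thr = permutation_threshold(grid, np.full(len(grid.lines), 1.0), n_perm=100, seed=1)
        assert thr == 0.0

    def test_alpha_one_gives_minimum(self, toy_grid, rng_module):
        _, _, grid = toy_grid
        y = rng_module.normal(0, 1, len(grid.lines))
        maxlods = permutation_max_lods(grid, y, n_perm=100, seed=2)
        thr = permutation_threshold(grid, y, n_perm=100, alpha=1.0, seed=2)
        assert thr == pytest.approx(maxlods.min())

    def test_reproducible_and_batch_independent(self, toy_grid, rng_module):
        _, _, grid = toy_grid
        y = rng_module.normal(0, 1, len(grid.lines))
        a = permutation_max_lods(grid, y, n_perm=50, seed=3)
        b = permutation_max_lods(grid, y, n_perm=50, seed=3)
        c = permutation_max_lods(grid, y, n_perm=60, seed=3)[:50]
        assert np.array_equal(a, b)
        assert np.array_equal(a, c)  # substream per permutation index

    def test_minimum_permutations_enforced(self, toy_grid):
        _, _, grid = toy_grid
        with pytest.raises(ValueError):
            permutation_threshold(grid, np.zeros(len(grid.lines)), n_perm=50)


class TestSupportInterval:
    def test_triangular_profile_peak_plus_minus_drop(self):
        pos = np.arange(0.0, 21.0)
        lod = 5.0 - np.abs(pos - 10.0)  # slope 1 LOD/cM
        lo, hi, *_ , clipped = support_interval(pos, pos * 1e6, lod, 10, drop=1.5)
        # region >= 3.5 is [8.5..11.5] -> grid points 9..11, expanded one out
        assert (lo, hi) == (8.0, 12.0)
        assert not clipped

    def test_zero_drop_degenerates_to_peak_plateau(self):
        pos = np.arange(0.0, 7.0)
        lod = np.array([0, 1, 4, 4, 4, 1, 0], dtype=float)
        lo, hi, *_ , _ = support_interval(pos, pos, lod, 3, drop=0.0)
        assert (lo, hi) == (1.0, 5.0)

    def test_clipped_at_chromosome_end(self):
        pos = np.arange(0.0, 5.0)
        lod = np.array([5, 4.8, 4, 3, 2.5], dtype=float)
        lo, hi, *_ , clipped = support_interval(pos, pos, lod, 0, drop=1.5)
        assert clipped and lo == 0.0


class TestEffects:
    def test_class_mean_difference(self):
        x = np.array([1.0] * 5 + [-1.0] * 5)
        y = np.array([10.0] * 5 + [9.0] * 5)
        add, _ = estimate_effects(x, y, lod=1.0)
        assert add == pytest.approx(0.5)

    def test_zero_lod_zero_pve(self):
        x = np.array([1.0, -1.0] * 5)
        _, pve = estimate_effects(x, x * 0 + np.arange(10), lod=0.0)
        assert pve == 0.0

    def test_perfect_signal_pve_saturates(self):
        x = np.tile([1.0, -1.0], 20)
        lod = 0.5 * x.size * np.log10(1e12)  # essentially zero residual
        _, pve = estimate_effects(x, x, lod=lod)
        assert pve == pytest.approx(100.0, abs=1e-6)

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError):
            estimate_effects(np.ones(10), np.arange(10.0), lod=1.0)


class TestMultiQTL:
    def test_two_unlinked_equal_qtls_split_variance(self, rng_module):
        n = 200
        g1 = rng_module.integers(0, 2, n) * 2.0 - 1
        g2 = rng_module.integers(0, 2, n) * 2.0 - 1
        geno = np.stack([g1, g2], axis=1)
        bm1 = _toy_binmap(np.where(geno == 1, A, B).astype(np.int8), chrom="chr1")
        # two separate chromosomes: build a combined grid manually
        bins = pd.concat(
            [
                bm1.bins.assign(chrom="chr1"),
                bm1.bins.assign(chrom="chr2", bin_id=["mk3", "mk4"]),
            ],
            ignore_index=True,
        )
        bm = BinMap(
            lines=bm1.lines,
            bins=bins,
            genotypes=np.hstack([bm1.genotypes, bm1.genotypes]),
        )
        grid = genotype_probs(build_map(bm), bm)
        y = g1 + g2
        report = fit_multi_qtl(grid, [0, 3], y)  # g1 on chr1, g2 on chr2
        assert np.allclose(report["pve"], 50.0, atol=6.0)

    def test_single_peak_matches_marginal(self, toy_grid, rng_module):
        _, _, grid = toy_grid
        y = grid.scores[:, 3] + 0.3 * rng_module.normal(0, 1, len(grid.lines))
        rep = fit_multi_qtl(grid, [3], y)
        x = grid.scores[:, 3]
        expected = 100.0 * np.corrcoef(x, y)[0, 1] ** 2
        assert rep["pve"].iloc[0] == pytest.approx(expected, abs=1e-6)

    def test_empty_peak_set(self, toy_grid):
        _, _, grid = toy_grid
        assert fit_multi_qtl(grid, [], np.zeros(len(grid.lines))).empty


class TestCofactorSelection:
    def test_zero_cofactors_requested(self, toy_grid, rng_module):
        _, _, grid = toy_grid
        y = rng_module.normal(0, 1, len(grid.lines))
        assert select_cofactors(grid, y, n_cofactors=0) == []

    def test_null_phenotype_usually_selects_none(self, toy_grid, rng_module):
        _, _, grid = toy_grid
        n_sel = [
            len(select_cofactors(grid, rng_module.normal(0, 1, len(grid.lines))))
            for _ in range(40)
        ]
        assert np.mean([s == 0 for s in n_sel]) >= 0.8

    def test_strong_qtl_selected_first(self, toy_grid, rng_module):
        _, _, grid = toy_grid
        hits = 0
        for _ in range(20):
            y = grid.scores[:, 6] + 0.8 * rng_module.normal(0, 1, len(grid.lines))
            cof = select_cofactors(grid, y, n_cofactors=3)
            if cof and abs(grid.pos_cm[cof[0]] - grid.pos_cm[6]) <= 10.0:
                hits += 1
        assert hits >= 16


def test_scan_trait_end_to_end(small_population):
    from binqtl.binmap import build_bin_map

    truth, clean = small_population
    cl = {"chr1": 50_000_000, "chr2": 50_000_000}
    bm, _ = build_bin_map(clean, chrom_lengths=cl)
    gmap = build_map(bm)
    rng = np.random.default_rng(9)
    from binqtl.simulate import genetic_values

    g = genetic_values(truth, [("chr2", 25_000_000, 1.0)])
    y = g + rng.normal(0, 1.0, g.size)
    blue = pd.DataFrame({"line": bm.lines, "blue": y})
    res = scan_trait(bm, gmap, blue, n_perm=120, seed=5)
    assert res.threshold > 0
    assert res.profile["lod"].min() >= 0.0
    chr2_qtls = [q for q in res.qtls if q.chrom == "chr2"]
    assert chr2_qtls, "planted QTL not detected"
    best = max(chr2_qtls, key=lambda q: q.lod)
    assert abs(best.peak_mb - 25.0) < 10.0
    assert best.ci_lo_mb <= best.peak_mb <= best.ci_hi_mb
    assert 0.0 <= best.pve <= 100.0
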