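from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cehkit.haplotypes import HaplotypeError
from cehkit.phasing import (
    assign_best_pair,
    canonical_pair,
    em_haplotype_frequencies,
    enumerate_compatible_pairs,
    posterior_coverage_summary,
    scan_snp_windows,
)
from cehkit.simulate import assign_phenotypes, build_pool, sample_diplotypes, unphase

from conftest import genotype_of, make_ceh


def brute_force_pairs(genotype):
    """Oracle: all 2^L ordered haplotype choices collapsed to unordered pairs."""
    options = [((x, y), (y, x)) if x != y else ((x, y),) for x, y in genotype]
    pairs = set()
    for choice in product(*[range(len(o)) for o in options]):
        h1 = tuple(options[i][c][0] for i, c in enumerate(choice))
        h2 = tuple(options[i][c][1] for i, c in enumerate(choice))
        pairs.add(canonical_pair(h1, h2))
    return pairs


class TestEnumerateCompatiblePairs:
    def test_fully_homozygous_genotype_has_one_pair(self):
        g = (("a", "a"), ("b", "b"), ("c", "c"))
        assert enumerate_compatible_pairs(g) == [(("a", "b", "c"), ("a", "b", "c"))]

    def test_three_heterozygous_loci_give_four_pairs(self):
        g = (("a", "A"), ("b", "B"), ("c", "C"), ("d", "d"), ("e", "e"), ("f", "f"))
        assert len(enumerate_compatible_pairs(g)) == 4

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.sampled_from(["aa", "ab", "bb", "ac"]), min_size=1, max_size=6))
    def test_matches_exhaustive_enumeration_oracle(self, loci):
        g = tuple(tuple(sorted(l)) for l in loci)
        assert set(enumerate_compatible_pairs(g)) == brute_force_pairs(g)

    def test_malformed_locus_rejected(self):
        with pytest.raises(HaplotypeError):
            enumerate_compatible_pairs((("a", "b", "c"),))


class TestEMFrequencies:
    def test_all_homozygous_counting_case(self):
        g1 = (("a", "a"), ("b", "b"))
        g2 = (("A", "A"), ("B", "B"))
        res = em_haplotype_frequencies([g1, g1, g1, g2])
        assert res.frequencies[("a", "b")] == pytest.approx(0.75)
        assert res.frequencies[("A", "B")] == pytest.approx(0.25)
        assert res.converged

    def test_single_heterozygous_locus_forces_symmetry(self):
        res = em_haplotype_frequencies([(("a", "A"), ("b", "b"))])
        assert res.frequencies[("a", "b")] == pytest.approx(0.5)
        assert res.frequencies[("A", "b")] == pytest.approx(0.5)

    def test_matches_grid_search_maximum_likelihood(self):
        """Two biallelic loci: 20 unambiguous AB/AB and ab/ab homozygotes plus
        10 double heterozygotes; EM must land on the grid-search maximum of
        the multinomial likelihood over the haplotype simplex."""
        ab = (("A", "A"), ("B", "B"))
        ab_low = (("a", "a"), ("b", "b"))
        dh = (("A", "a"), ("B", "b"))
        genotypes = [ab] * 20 + [ab_low] * 20 + [dh] * 10

        def loglik(fAB, fab, fAb):
            faB = 1.0 - fAB - fab - fAb
            if faB < 0:
                return -np.inf
            p_dh = 2 * fAB * fab + 2 * fAb * faB
            if fAB <= 0 or fab <= 0 or p_dh <= 0:
                return -np.inf
            return 20 * np.log(fAB**2) + 20 * np.log(fab**2) + 10 * np.log(p_dh)

        # grid search oracle at step 1e-4 along the symmetric ridge directions
        best, best_ll = None, -np.inf
        for fAB in np.arange(0.30, 0.55, 1e-4):
            for fAb in (0.0, 1e-4, 1e-3):
                fab = fAB
                if fAB + fab + 2 * fAb > 1:
                    continue
                ll = loglik(fAB, fab, fAb)
                if ll > best_ll:
                    best, best_ll = (fAB, fab, fAb), ll
        res = em_haplotype_frequencies(genotypes, tol=1e-10, prune_threshold=0.0)
        assert res.frequencies[("A", "B")] == pytest.approx(best[0], abs=1e-4)
        assert res.frequencies[("a", "b")] == pytest.approx(best[1], abs=1e-4)
        assert res.loglik == pytest.approx(best_ll, abs=1e-3)

    def test_loglik_monotone_and_simplex_preserved_without_pruning(self, skewed_pool):
        dips = sample_diplotypes(skewed_pool, 400, seed=8)
        recs = unphase(dips, seed=9)
        genotypes = [tuple(r.hla[l] for l in ("A", "C", "B", "DRB1", "DQB1"))
                     for r in recs]
        res = em_haplotype_frequencies(genotypes, prune_threshold=0.0)
        diffs = np.diff(res.loglik_trace)
        assert np.all(diffs >= -1e-9)
        assert sum(res.frequencies.values()) == pytest.approx(1.0, abs=1e-9)

    def test_pruning_keeps_simplex_and_near_monotone_trace(self, skewed_pool):
        dips = sample_diplotypes(skewed_pool, 400, seed=18)
        recs = unphase(dips, seed=19)
        genotypes = [tuple(r.hla[l] for l in ("A", "C", "B", "DRB1", "DQB1"))
                     for r in recs]
        res = em_haplotype_frequencies(genotypes)  # default pruning at 1/(4N)
        assert sum(res.frequencies.values()) == pytest.approx(1.0, abs=1e-9)
        diffs = np.diff(res.loglik_trace)
        # pruning may perturb the likelihood by at most the pruned mass
        assert np.all(diffs >= -1e-3 * np.abs(res.loglik))

    def test_unconverged_run_is_flagged_not_raised(self):
        hom = (("a", "a"), ("b", "b"))
        dh = (("a", "A"), ("b", "B"))
        res = em_haplotype_frequencies([hom, dh, dh], tol=1e-12, max_iter=2)
        assert not res.converged

    def test_empty_input_rejected(self):
        with pytest.raises(HaplotypeError):
            em_haplotype_frequencies([])


class TestAssignBestPair:
    def test_single_compatible_pair_posterior_one(self):
        g = (("a", "a"), ("b", "b"))
        a = assign_best_pair(g, {("a", "b"): 1.0})
        assert a.posterior == 1.0
        assert a.pair == (("a", "b"), ("a", "b"))

    def test_double_heterozygote_posterior(self):
        f = {("A", "B"): 0.4, ("a", "b"): 0.4, ("A", "b"): 0.1, ("a", "B"): 0.1}
        g = (("A", "a"), ("B", "b"))
        a = assign_best_pair(g, f)
        assert a.pair == canonical_pair(("A", "B"), ("a", "b"))
        assert a.posterior == pytest.approx(0.32 / 0.34)

    def test_uniform_frequencies_tie_breaks_lexicographically(self):
        f = {h: 0.25 for h in [("A", "B"), ("a", "b"), ("A", "b"), ("a", "B")]}
        g = (("A", "a"), ("B", "b"))
        a = assign_best_pair(g, f)
        assert a.posterior == pytest.approx(0.5)
        # lexicographically first canonical pair: A~B / a~b sorts before A~b / a~B
        assert a.pair == (("A", "B"), ("a", "b"))

    def test_zero_weight_everywhere_is_unassignable(self):
        g = (("a", "A"), ("b", "b"))
        a = assign_best_pair(g, {})
        assert not a.assignable


class TestPosteriorCoverage:
    def test_all_certain(self):
        cov = posterior_coverage_summary([1.0, 1.0, 1.0])
        assert cov == {0.5: 1.0, 0.6: 1.0, 0.7: 1.0}

    def test_direct_count(self):
        cov = posterior_coverage_summary([0.55, 0.65, 0.75, 0.45])
        assert cov[0.5] == pytest.approx(0.75)
        assert cov[0.6] == pytest.approx(0.50)
        assert cov[0.7] == pytest.approx(0.25)

    def test_fractions_weakly_decreasing_in_threshold(self, skewed_pool):
        from cehkit.phasing import phase_dataset

        dips = sample_diplotypes(skewed_pool, 300, seed=21)
        recs = unphase(dips, seed=22)
        res = phase_dataset(recs)
        cov = posterior_coverage_summary(res.posteriors())
        vals = [cov[t] for t in (0.5, 0.6, 0.7)]
        assert vals == sorted(vals, reverse=True)


class TestWindowScan:
    @staticmethod
    def _snp_genotypes(pool, n, seed, risk_target=None, baseline=0.25):
        dips = sample_diplotypes(pool, n, seed=seed)
        y = assign_phenotypes(dips, pool, baseline_odds=baseline, seed=seed + 1)
        gts = [
            tuple(tuple(sorted((d.hap1.snp[s], d.hap2.snp[s]))) for s in range(11))
            for d in dips
        ]
        return gts, y

    def test_width_eleven_yields_single_window(self, two_ceh_pool):
        gts, y = self._snp_genotypes(two_ceh_pool, 150, seed=3)
        res = scan_snp_windows(gts, y, widths=[11])
        assert len(res.windows) == 1
        assert res.selected == (0, 11)

    def test_causal_window_recovered(self):
        """A risk haplotype distinguishable only at SNPs 3..7 should be found
        by a window overlapping that span."""
        risk = make_ceh("01", "00011111000")
        null1 = make_ceh("01", "00000000000")
        null2 = make_ceh("01", "00011100000")
        pool = build_pool(haplotypes=[risk, null1, null2],
                          frequencies=[0.3, 0.4, 0.3], risk={risk: (3.0, 9.0)})
        hits = 0
        reps = 10
        for rep in range(reps):
            gts, y = self._snp_genotypes(pool, 800, seed=100 + rep)
            res = scan_snp_windows(gts, y, widths=range(2, 9), min_copies=10)
            start, width = res.selected
            if start < 8 and start + width > 3:  # overlaps the causal span
                hits += 1
        assert hits >= 9

    def test_null_scan_shows_no_positional_bias(self, skewed_pool):
        starts = []
        for rep in range(12):
            gts, y = self._snp_genotypes(skewed_pool, 120, seed=300 + rep)
            rng = np.random.default_rng(rep)
            y = rng.permutation(y)  # phenotype independent of genotype
            res = scan_snp_windows(gts, y, widths=[2, 3], min_copies=5)
            starts.append(res.selected[0])
        assert len(set(starts)) > 1  # not systematically stuck at one edge

    def test_too_few_snps_rejected(self):
        with pytest.raises(HaplotypeError):
            scan_snp_windows([((("0", "0"),) * 1)[0:1]], [0], widths=[2])
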