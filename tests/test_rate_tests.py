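import math

import numpy as np
import pytest

from cytorate.codon_ml import QUINTET_BRANCHES, BranchRate, BranchRates
from cytorate.experiments import simulated_concatenation
from cytorate.quintet_inference import Quintet
from cytorate.rate_tests import (
    OmegaRatioResult,
    codon_bootstrap,
    concatenate_by_category,
    concatenate_quintets,
    divergence_binning,
    gene_bootstrap_omega_ratio,
    gene_level_sign_test,
    median_branch_rates,
    normalize_ratio,
    polyploid_vs_diploid_ratio,
    two_tailed_p,
)
from cytorate.synthetic_data import simulate_quintet_genes

ROLES = ("polyploid_paternal", "diploid_paternal", "polyploid_maternal",
         "diploid_maternal", "outgroup")


def genes_to_inputs(genes):
    quintets, alignments = [], {}
    for gid, aln, _ in genes:
        quintets.append(Quintet(gene_id=gid, members=dict(zip(ROLES, aln.ids))))
        alignments[gid] = aln
    return quintets, alignments


class TestConcatenation:
    def test_lengths_and_boundaries(self):
        g300 = simulate_quintet_genes(1, 300, seed=1, prefix="a")
        g150 = simulate_quintet_genes(1, 150, seed=2, prefix="b")
        quintets, alignments = genes_to_inputs(g300 + g150)
        concat = concatenate_quintets(quintets, alignments)
        assert concat.n_codons == 450
        assert concat.boundaries() == [300]

    def test_single_gene_equals_itself(self):
        genes = simulate_quintet_genes(1, 90, seed=3)
        quintets, alignments = genes_to_inputs(genes)
        concat = concatenate_quintets(quintets, alignments)
        np.testing.assert_array_equal(
            concat.states, alignments[genes[0][0]].codon_states()
        )

    def test_input_order_irrelevant(self):
        genes = simulate_quintet_genes(4, 60, seed=4)
        quintets, alignments = genes_to_inputs(genes)
        a = concatenate_quintets(quintets, alignments)
        b = concatenate_quintets(list(reversed(quintets)), alignments)
        np.testing.assert_array_equal(a.states, b.states)
        assert a.gene_ids == b.gene_ids

    def test_missing_alignment_names_gene(self):
        genes = simulate_quintet_genes(2, 60, seed=5)
        quintets, alignments = genes_to_inputs(genes)
        del alignments[quintets[0].gene_id]
        with pytest.raises(KeyError, match=quintets[0].gene_id):
            concatenate_quintets(quintets, alignments)

    def test_category_split(self):
        import pandas as pd

        genes = simulate_quintet_genes(4, 60, seed=6)
        quintets, alignments = genes_to_inputs(genes)
        cls = pd.DataFrame(
            {
                "gene_id": [q.gene_id for q in quintets],
                "mito_targeted": [True, True, False, False],
                "plastid_targeted": False,
                "mito_interacting": False,
                "plastid_interacting": False,
                "mtec": False,
                "ptec": False,
            }
        )
        concats = concatenate_by_category(quintets, alignments, cls)
        assert concats["NOT"].n_genes == 2
        assert concats["mito_targeted"].n_genes == 2
        assert "ptec" not in concats


class TestTwoTailedP:
    def test_reference_at_median_gives_one(self):
        dist = np.linspace(0.5, 1.5, 101)
        assert two_tailed_p(dist, 1.0) == 1.0

    def test_reference_below_all_reports_resolution_floor(self):
        dist = np.linspace(2.0, 3.0, 200)
        assert two_tailed_p(dist, 1.0) == pytest.approx(2.0 / 200)

    def test_reference_at_percentile_2_5(self):
        dist = np.arange(1, 201) / 100.0  # uniform grid
        ref = np.percentile(dist, 2.5)
        assert two_tailed_p(dist, ref) == pytest.approx(0.05, abs=0.01)

    def test_empty_distribution_rejected(self):
        with pytest.raises(ValueError):
            two_tailed_p(np.array([]), 1.0)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            two_tailed_p(np.arange(10.0), 1.0)


class TestNormalizeRatio:
    def make_result(self, ratio, dist=None):
        dist = np.linspace(0.8, 1.2, 50) * ratio if dist is None else dist
        return OmegaRatioResult(
            category="x", omega_pat=ratio, omega_mat=1.0, ratio=ratio,
            bootstrap_ratios=dist, ci95=(dist.min(), dist.max()),
            p_two_tailed=1.0,
        )

    def test_equal_ratios_normalize_to_one(self):
        res = normalize_ratio(self.make_result(1.2), self.make_result(1.2))
        assert res.ratio == pytest.approx(1.0)

    def test_half_background(self):
        res = normalize_ratio(self.make_result(0.6), self.make_result(1.2))
        assert res.ratio == pytest.approx(0.5)

    def test_wheat_mtec_point_arithmetic(self):
        mtec = self.make_result(0.661 / 0.0771)
        background = self.make_result(0.444 / 0.201)
        res = normalize_ratio(mtec, background)
        assert res.ratio == pytest.approx(3.88, abs=0.01)

    def test_self_normalization_is_identity(self):
        for ratio in (0.3, 1.0, 2.5):
            x = self.make_result(ratio)
            assert normalize_ratio(x, x).ratio == pytest.approx(1.0)

    def test_undefined_reference_rejected(self):
        bad = self.make_result(float("nan"))
        with pytest.raises(ValueError):
            normalize_ratio(self.make_result(1.0), bad)


def make_rates(omega_pat, omega_mat, dn_pat=0.1, dn_mat=0.1):
    branches = {}
    for b in QUINTET_BRANCHES:
        branches[b] = BranchRate(t=0.2, dn=0.05, ds=0.2, omega=0.25)
    branches["polyploid_paternal"] = BranchRate(0.2, dn_pat, 0.2, omega_pat)
    branches["polyploid_maternal"] = BranchRate(0.2, dn_mat, 0.2, omega_mat)
    return BranchRates(branches=branches, kappa=2.0, lnl=-1.0)


class TestSignTest:
    def test_balanced_counts_give_p_one(self):
        rates = [make_rates(0.3, 0.2)] * 5 + [make_rates(0.2, 0.3)] * 5
        res = gene_level_sign_test(rates)
        assert res.n_pat_higher == 5 and res.n_mat_higher == 5
        assert res.p_binomial == pytest.approx(1.0)

    def test_60_40_matches_exact_enumeration(self):
        rates = [make_rates(0.3, 0.2)] * 60 + [make_rates(0.2, 0.3)] * 40
        res = gene_level_sign_test(rates)
        # independent oracle: sum the binomial pmf over the two-sided region
        n, k = 100, 60
        pmf = [math.comb(n, i) * 0.5**n for i in range(n + 1)]
        expected = sum(p for p in pmf if p <= pmf[k] * (1 + 1e-9))
        assert res.p_binomial == pytest.approx(expected, rel=1e-9)

    def test_all_ties_undefined(self):
        rates = [make_rates(0.25, 0.25)] * 4
        res = gene_level_sign_test(rates)
        assert math.isnan(res.p_binomial)
        assert res.n_ties == 4

    def test_undefined_omegas_count_as_ties(self):
        rates = [make_rates(float("nan"), 0.2), make_rates(0.3, 0.2)]
        res = gene_level_sign_test(rates)
        assert res.n_ties == 1 and res.n_pat_higher == 1

    def test_dn_comparison(self):
        rates = [make_rates(0.2, 0.2, dn_pat=0.2, dn_mat=0.1)] * 3
        res = gene_level_sign_test(rates, comparison="dN")
        assert res.n_pat_higher == 3

    def test_proportions_include_ties_in_denominator(self):
        rates = [make_rates(0.3, 0.2)] * 2 + [make_rates(0.25, 0.25)] * 2
        res = gene_level_sign_test(rates)
        assert res.p_pat == pytest.approx(0.5)
        assert res.p_pat + res.p_mat <= 1.0


class TestDivergenceBinning:
    def test_even_count_splits_in_half(self):
        dn = {f"g{i}": i / 10 for i in range(10)}
        bins = divergence_binning(dn)
        assert sum(b == "low" for b in bins.values()) == 5
        assert sum(b == "high" for b in bins.values()) == 5

    def test_odd_count_median_gene_goes_low(self):
        dn = {f"g{i}": float(i) for i in range(11)}
        bins = divergence_binning(dn)
        assert sum(b == "low" for b in bins.values()) == 6
        assert bins["g5"] == "low"

    def test_all_equal_all_low(self):
        bins = divergence_binning({"a": 0.1, "b": 0.1, "c": 0.1})
        assert set(bins.values()) == {"low"}

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            divergence_binning({"a": 0.1})


@pytest.fixture(scope="module")
def concat():
    return simulated_concatenation(6, 40, seed=51, omega_by_branch=0.3)


class TestBootstrap:

    def test_reproducible_bit_for_bit(self, concat):
        r1 = gene_bootstrap_omega_ratio(concat, b=24, optimizer_replicates=1, seed=9)
        r2 = gene_bootstrap_omega_ratio(concat, b=24, optimizer_replicates=1, seed=9)
        np.testing.assert_array_equal(r1.bootstrap_ratios, r2.bootstrap_ratios)
        assert r1.ratio == r2.ratio

    def test_identical_blocks_degenerate_distribution(self):
        one = simulate_quintet_genes(1, 60, seed=52)
        gid, aln, _ = one[0]
        quintets, alignments = [], {}
        for i in range(5):
            g = f"g{i}"
            quintets.append(Quintet(gene_id=g, members=dict(zip(ROLES, aln.ids))))
            alignments[g] = aln
        concat = concatenate_quintets(quintets, alignments)
        res = gene_bootstrap_omega_ratio(concat, b=24, optimizer_replicates=1, seed=1)
        # every resample is the same data: the distribution is a point mass
        assert np.ptp(res.bootstrap_ratios) < 1e-9
        # ... at the point estimate, up to optimizer refinement tolerance
        assert res.bootstrap_ratios[0] == pytest.approx(res.ratio, rel=1e-2)

    def test_ci_contains_bootstrap_median(self, concat):
        res = gene_bootstrap_omega_ratio(concat, b=30, optimizer_replicates=1, seed=3)
        med = np.median(res.bootstrap_ratios)
        assert res.ci95[0] <= med <= res.ci95[1]

    def test_single_gene_rejected_for_gene_bootstrap(self):
        concat = simulated_concatenation(1, 60, seed=53)
        with pytest.raises(ValueError):
            gene_bootstrap_omega_ratio(concat, b=24, optimizer_replicates=1, seed=1)

    def test_codon_bootstrap_valid_for_single_gene(self):
        concat = simulated_concatenation(1, 60, seed=54, omega_by_branch=0.3)
        r1 = codon_bootstrap(concat, b=24, optimizer_replicates=1, seed=2)
        r2 = codon_bootstrap(concat, b=24, optimizer_replicates=1, seed=2)
        np.testing.assert_array_equal(r1.bootstrap_ratios, r2.bootstrap_ratios)
        assert np.isfinite(r1.ratio)

    def test_codon_bootstrap_needs_30_codons(self):
        concat = simulated_concatenation(1, 20, seed=55)
        with pytest.raises(ValueError):
            codon_bootstrap(concat, b=24, optimizer_replicates=1, seed=1)


class TestMedianRates:
    def test_lower_median_used_for_even_counts(self):
        runs = [make_rates(o, 0.2) for o in (0.1, 0.2, 0.3, 0.4)]
        med = median_branch_rates(runs)
        assert med.branches["polyploid_paternal"].omega == 0.2

    def test_single_run_passthrough(self):
        r = make_rates(0.3, 0.2)
        assert median_branch_rates([r]) is r


class TestPolyploidVsDiploid:
    def test_equal_rates_ci_covers_one_end_to_end(self, concat):
        """Bootstrap replicate fits feed the polyploid-diploid contrast."""
        res = gene_bootstrap_omega_ratio(
            concat, b=40, optimizer_replicates=1, seed=11, method="profile"
        )
        out = polyploid_vs_diploid_ratio(res.point_fit, res.replicate_fits)
        for sub in ("paternal", "maternal"):
            lo, hi = out[sub].ci95
            assert lo <= 1.0 <= hi  # all branches simulated at equal omega

    def test_degenerate_diploid_flagged(self):
        point = make_rates(0.3, 0.2)
        point.branches["diploid_paternal"] = BranchRate(0.2, 0.0, 0.2, 0.0)
        reps = [make_rates(0.3, 0.2)] * 25
        out = polyploid_vs_diploid_ratio(point, reps)
        assert "undefined" in out["paternal"].flags
        assert math.isnan(out["paternal"].ratio)

    def test_equal_omegas_not_significant(self):
        point = make_rates(0.25, 0.25)
        rng = np.random.default_rng(5)
        reps = []
        for _ in range(40):
            r = make_rates(0.25 * rng.lognormal(0, 0.1), 0.25)
            r.branches["diploid_paternal"] = BranchRate(
                0.2, 0.05, 0.2, 0.25 * rng.lognormal(0, 0.1)
            )
            reps.append(r)
        out = polyploid_vs_diploid_ratio(point, reps)
        assert out["paternal"].significant is False
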