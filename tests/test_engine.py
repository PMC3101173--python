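"""Codon rate matrices, transition probabilities and tree likelihoods."""

import io

import numpy as np
import pytest

from codonsel.codes import STANDARD_CODE
from codonsel.engine import (
    CodonModelSpec,
    EngineError,
    alignment_log_likelihood,
    build_generator,
    expected_branch_substitutions,
    mean_rate,
    neutral_fluxes,
    transition_matrix,
    uniform_codon_freqs,
)
from codonsel.io import read_codon_alignment, read_tree


def _aln(pairs):
    return read_codon_alignment(io.StringIO(
        "".join(f">{n}\n{s}\n" for n, s in pairs)))


@pytest.fixture(scope="module")
def rate_matrix():
    return build_generator(uniform_codon_freqs(), kappa=2.0, omega=0.5)


class TestGenerator:
    def test_rows_sum_to_zero(self, rate_matrix):
        assert np.abs(rate_matrix.generator.sum(axis=1)).max() < 1e-12

    def test_multi_nucleotide_changes_have_zero_rate(self, rate_matrix):
        multi = STANDARD_CODE.n_diffs > 1
        assert np.all(rate_matrix.generator[multi] == 0)

    def test_neutrality_makes_rates_blind_to_effect(self):
        # at ω = 1 a single-nt rate depends only on ts/tv status and the
        # target frequency, not on whether the change is synonymous
        rm = build_generator(uniform_codon_freqs(), kappa=3.0, omega=1.0,
                             normalize=False)
        code = STANDARD_CODE
        single = code.n_diffs == 1
        expected = np.where(code.is_transition, 3.0, 1.0) / code.n_states
        assert np.allclose(rm.generator[single], expected[single])

    def test_detailed_balance(self):
        rng = np.random.default_rng(1)
        pi = rng.dirichlet(np.full(61, 3.0))
        rm = build_generator(pi, kappa=2.3, omega=0.4)
        flux = pi[:, None] * rm.generator
        assert np.allclose(flux, flux.T, atol=1e-14)

    def test_invalid_parameters(self):
        with pytest.raises(EngineError):
            build_generator(uniform_codon_freqs(), kappa=2.0, omega=-0.1)
        with pytest.raises(EngineError):
            build_generator(uniform_codon_freqs(), kappa=0.0, omega=1.0)

    def test_mean_rate_decomposes_into_fluxes(self):
        pi = uniform_codon_freqs()
        fn, fs = neutral_fluxes(pi, 2.0)
        assert mean_rate(pi, 2.0, 0.7) == pytest.approx(0.7 * fn + fs)


class TestTransitionMatrix:
    def test_zero_time_is_identity(self, rate_matrix):
        assert np.allclose(transition_matrix(rate_matrix, 0.0), np.eye(61),
                           atol=1e-12)

    def test_rows_are_distributions(self, rate_matrix):
        p = transition_matrix(rate_matrix, 0.7)
        assert np.all(p >= 0)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_short_time_series_expansion(self, rate_matrix):
        t = 1e-4
        p = transition_matrix(rate_matrix, t)
        first_order = np.eye(61) + rate_matrix.generator * t
        assert np.abs(p - first_order).max() < 10 * t ** 2

    def test_chapman_kolmogorov(self, rate_matrix):
        p1 = transition_matrix(rate_matrix, 0.3)
        p2 = transition_matrix(rate_matrix, 0.5)
        p12 = transition_matrix(rate_matrix, 0.8)
        assert np.abs(p1 @ p2 - p12).max() < 1e-10

    def test_stationary_distribution_reached(self):
        rm = build_generator(uniform_codon_freqs(), kappa=1.0, omega=1.0)
        p = transition_matrix(rm, 60.0)
        assert np.abs(p - 1.0 / 61).max() < 1e-8

    def test_negative_time_rejected(self, rate_matrix):
        with pytest.raises(EngineError):
            transition_matrix(rate_matrix, -0.1)


class TestLikelihood:
    def test_single_tip_is_log_frequency(self):
        aln = _aln([("A", "ATG")])
        tree = read_tree("(A:0.5);")
        pi = uniform_codon_freqs()
        spec = CodonModelSpec(kappa=2.0, codon_freqs=pi,
                              site_classes=[(1.0, 0.5)])
        total, per_site, _ = alignment_log_likelihood(aln, tree, spec)
        assert total == pytest.approx(np.log(pi[STANDARD_CODE.index["ATG"]]),
                                      abs=1e-10)

    def test_matches_enumeration_oracle(self, likelihood_oracle):
        aln = _aln([("A", "ATGAAATTTCCC"), ("B", "ATGAAGTTCCCA"),
                    ("C", "ATGAAAGGGCCC"), ("D", "ATAAAATTT---")])
        tree = read_tree("((A:0.2,B:0.3):0.1,(C:0.4,D:0.15):0.2);")
        rng = np.random.default_rng(3)
        pi = rng.dirichlet(np.full(61, 4.0))
        spec = CodonModelSpec(kappa=2.4, codon_freqs=pi,
                              site_classes=[(1.0, 0.6)])
        total, _, _ = alignment_log_likelihood(aln, tree, spec)
        expected = likelihood_oracle(aln, tree, 2.4, 0.6, pi)
        assert total == pytest.approx(expected, abs=1e-8)

    def test_random_instances_match_oracle(self, likelihood_oracle,
                                           oracle_instances):
        rng = np.random.default_rng(11)
        for _ in range(10):
            aln, tree, kappa, omega, pi = oracle_instances(rng, max_sites=8)
            spec = CodonModelSpec(kappa=kappa, codon_freqs=pi,
                                  site_classes=[(1.0, omega)])
            total, _, _ = alignment_log_likelihood(aln, tree, spec)
            expected = likelihood_oracle(aln, tree, kappa, omega, pi)
            assert total == pytest.approx(expected, abs=1e-8)

    def test_root_placement_is_irrelevant(self):
        aln = _aln([("A", "ATGAAATTT"), ("B", "ATGAAGTTC"),
                    ("C", "ATGAAAGGG"), ("D", "ATAAAATTT")])
        spec = CodonModelSpec(kappa=2.0, site_classes=[(1.0, 0.5)])
        rootings = [
            "((A:0.1,B:0.2):0.12,(C:0.3,D:0.4):0.0);",
            "((A:0.1,B:0.2):0.0,(C:0.3,D:0.4):0.12);",
            "(A:0.1,B:0.2,(C:0.3,D:0.4):0.12);",
            "((A:0.1,B:0.2):0.05,(C:0.3,D:0.4):0.07);",
        ]
        values = [alignment_log_likelihood(aln, read_tree(t), spec)[0]
                  for t in rootings]
        assert max(values) - min(values) < 1e-9

    def test_zero_length_resolution_of_polytomy_is_neutral(self):
        aln = _aln([("A", "ATGAAA"), ("B", "ATGAAG"),
                    ("C", "ATGAAA"), ("D", "ATGGAA")])
        spec = CodonModelSpec(kappa=2.0, site_classes=[(1.0, 0.5)])
        star = alignment_log_likelihood(
            aln, read_tree("(A:1,B:1,C:1,D:1);"), spec)[0]
        resolved = alignment_log_likelihood(
            aln, read_tree("((A:1,B:1):0.0,(C:1,D:1):0.0);"), spec)[0]
        assert star == pytest.approx(resolved, abs=1e-9)

    def test_degenerate_mixture_equals_single_class(self):
        aln = _aln([("A", "ATGAAATTT"), ("B", "ATGAAGTTC"),
                    ("C", "ATGAAAGGG")])
        tree = read_tree("((A:0.2,B:0.3):0.1,C:0.4);")
        one = CodonModelSpec(kappa=2.0, site_classes=[(1.0, 0.5)])
        two = CodonModelSpec(kappa=2.0,
                             site_classes=[(1.0, 0.5), (0.0, 3.0)])
        assert alignment_log_likelihood(aln, tree, one)[0] == pytest.approx(
            alignment_log_likelihood(aln, tree, two)[0], abs=1e-9)

    def test_taxon_mismatch_is_an_error(self):
        aln = _aln([("A", "ATGAAA"), ("B", "ATGAAG")])
        tree = read_tree("((A:1,B:1):1,Z:2);")
        spec = CodonModelSpec()
        with pytest.raises(EngineError):
            alignment_log_likelihood(aln, tree, spec)

    def test_per_site_values_sum_to_total(self):
        aln = _aln([("A", "ATGAAATTT"), ("B", "ATGAAGTTC"),
                    ("C", "ATGAAAGGG")])
        tree = read_tree("((A:0.2,B:0.3):0.1,C:0.4);")
        spec = CodonModelSpec(
            kappa=2.0, site_classes=[(0.6, 0.2), (0.4, 1.5)])
        total, per_site, per_class = alignment_log_likelihood(
            aln, tree, spec)
        assert per_site.shape == (3,)
        assert per_class.shape == (2, 3)
        assert total == pytest.approx(per_site.sum(), abs=1e-10)
        assert np.isfinite(total)


class TestExpectedSubstitutions:
    def test_zero_length_branch_gives_zero_counts(self):
        out = expected_branch_substitutions(
            uniform_codon_freqs(), 2.0, 1.5, 0.0)
        assert out["nonsyn_per_codon"] == 0 and out["syn_per_codon"] == 0

    def test_counts_scale_linearly_with_length(self):
        pi = uniform_codon_freqs()
        one = expected_branch_substitutions(pi, 2.0, 0.5, 0.1)
        two = expected_branch_substitutions(pi, 2.0, 0.5, 0.2)
        assert two["nonsyn_per_codon"] == pytest.approx(
            2 * one["nonsyn_per_codon"])
        assert two["syn_per_codon"] == pytest.approx(
            2 * one["syn_per_codon"])

    def test_dn_ds_ratio_recovers_branch_omega(self):
        pi = uniform_codon_freqs()
        for omega in (0.1, 1.0, 2.5):
            out = expected_branch_substitutions(pi, 2.0, omega, 0.3)
            assert out["dN"] / out["dS"] == pytest.approx(omega, rel=1e-10)

    def test_neutral_count_ratio_is_mutational_opportunity(self):
        pi = uniform_codon_freqs()
        fn, fs = neutral_fluxes(pi, 2.0)
        out = expected_branch_substitutions(pi, 2.0, 1.0, 0.5)
        assert out["nonsyn_per_codon"] / out["syn_per_codon"] == \
            pytest.approx(fn / fs, rel=1e-10)

    def test_site_counts_sum_to_three(self):
        out = expected_branch_substitutions(
            uniform_codon_freqs(), 2.0, 0.5, 0.1)
        assert out["N_sites"] + out["S_sites"] == pytest.approx(3.0)
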