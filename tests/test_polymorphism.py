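"""Heterozygote detection, change classification, parsimony counting
and the divergence/polymorphism contrast."""

from itertools import product
from math import comb

import numpy as np
import pytest
from Bio.Seq import Seq

from codonsel.codes import STANDARD_CODE
from codonsel.io import read_tree
from codonsel.polymorphism import (
    _fitch_changes,
    classify_change,
    detect_heterozygous_sites,
    divergence_polymorphism_contrast,
    optimize_intraspecific_changes,
    summarize_changes,
)
from codonsel.engine import CodonModelSpec
from codonsel.simulate import simulate_alignment


class TestDetection:
    def test_two_base_code_detected_with_resolution(self):
        assert detect_heterozygous_sites("ACRT") == [(3, ("A", "G"))]

    def test_plain_sequence_has_no_calls(self):
        assert detect_heterozygous_sites("ACGTACGT---") == []

    def test_many_base_codes_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="more than two"):
            calls = detect_heterozygous_sites("ACNT")
        assert calls == []

    def test_unknown_symbol_rejected(self):
        with pytest.raises(ValueError):
            detect_heterozygous_sites("AC?T")


class TestClassification:
    def test_fourfold_site_synonymous_transition(self):
        out = classify_change("CTT", 3, "T", "C")
        assert out == {"effect": "synonymous",
                       "mutation_class": "transition",
                       "position": 3, "to_stop": False}

    def test_first_position_nonsynonymous_transition(self):
        out = classify_change("ATG", 1, "A", "G")
        assert out["effect"] == "nonsynonymous"
        assert out["mutation_class"] == "transition"
        assert out["position"] == 1

    def test_change_to_stop_is_flagged(self):
        out = classify_change("TAC", 3, "C", "A")  # TAC -> TAA
        assert out["to_stop"] and out["effect"] == "nonsense"

    def test_mismatched_context_rejected(self):
        with pytest.raises(ValueError):
            classify_change("ATG", 1, "C", "G")

    def test_exhaustive_enumeration_matches_translation_oracle(self):
        purines = {"A", "G"}
        pyrimidines = {"C", "T"}
        for codon in STANDARD_CODE.codons:
            for offset, alt in product(range(3), "ACGT"):
                ref = codon[offset]
                if alt == ref:
                    continue
                derived = codon[:offset] + alt + codon[offset + 1:]
                out = classify_change(codon, offset + 1, ref, alt)
                expected_ts = ({ref, alt} <= purines
                               or {ref, alt} <= pyrimidines)
                assert (out["mutation_class"] == "transition") == expected_ts
                aa_ref = str(Seq(codon).translate())
                aa_alt = str(Seq(derived).translate())
                if aa_alt == "*":
                    assert out["effect"] == "nonsense"
                else:
                    assert (out["effect"] == "synonymous") == \
                        (aa_ref == aa_alt)


def _enumerate_min_changes(tree, present):
    """Oracle: minimize changes over all internal 0/1 assignments."""
    nodes = list(tree.tree.postorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    tip_state = {id(n): int(n.taxon.label in present)
                 for n in nodes if n.is_leaf()}
    best = np.inf
    for assign in product((0, 1), repeat=len(internal)):
        states = dict(tip_state)
        for n, s in zip(internal, assign):
            states[id(n)] = s
        changes = sum(
            1 for n in nodes if n.parent_node is not None
            and states[id(n)] != states[id(n.parent_node)])
        best = min(best, changes)
    return int(best)


@pytest.fixture(scope="module")
def gene_tree():
    return read_tree(
        "(((a:1,b:1):1,(c:1,d:1):1):1,((e:1,f:1):1,"
        "(g:1,(h:1,i:1):1):1):1,j:2);")


class TestParsimony:

    def test_private_variant_is_one_change(self, gene_tree):
        assert _fitch_changes(gene_tree, {"a"}) == 1

    def test_sister_sharing_counts_once(self, gene_tree):
        assert _fitch_changes(gene_tree, {"a", "b"}) == 1

    def test_disjoint_tips_count_separately(self, gene_tree):
        assert _fitch_changes(gene_tree, {"a", "e"}) == 2

    def test_matches_exhaustive_minimum(self, gene_tree):
        rng = np.random.default_rng(13)
        tips = gene_tree.tip_names()
        for _ in range(40):
            k = rng.integers(1, len(tips) + 1)
            present = set(rng.choice(tips, size=k, replace=False))
            assert _fitch_changes(gene_tree, present) == \
                _enumerate_min_changes(gene_tree, present)


@pytest.fixture(scope="module")
def het_setup(tree12):
    spec = CodonModelSpec(kappa=2.0, site_classes=[(1.0, 0.3)])
    aln, _ = simulate_alignment(tree12, spec, 80, seed=9)
    return aln, tree12


class TestOptimizeChanges:

    def test_private_heterozygote_yields_one_classified_change(self, het_setup):
        aln, tree = het_setup
        sp = aln.taxa[0]
        # plant an A/G het at the third position of the first codon
        # whose third position is A in that species
        for s in range(aln.n_sites):
            if aln.codons[0][s][2] == "A":
                break
        calls = {sp: [(3 * s + 3, ("A", "G"))]}
        changes = optimize_intraspecific_changes(calls, tree, aln)
        assert len(changes) == 1
        assert changes[0].n_events == 1
        assert changes[0].site == s + 1
        assert changes[0].nucleotide_offset == 3
        assert changes[0].effect in ("synonymous", "nonsynonymous")

    def test_shared_sister_heterozygote_counts_once(self, het_setup):
        aln, tree = het_setup
        sisters = [t for t in tree.tip_names()
                   if t.startswith("mysticete")][:2]
        for s in range(aln.n_sites):
            bases = {aln.codons[aln.taxon_index(t)][s][0] for t in sisters}
            if bases == {"A"}:
                break
        call = (3 * s + 1, ("A", "T"))
        changes = optimize_intraspecific_changes(
            {sisters[0]: [call], sisters[1]: [call]}, tree, aln)
        assert len(changes) == 1
        assert changes[0].n_events == 1
        total = summarize_changes(changes)["total"]
        assert total == 1

    def test_masked_site_excluded_with_warning(self, het_setup):
        aln, tree = het_setup
        masked = aln.subset(aln.taxa)
        masked.mask[0, 0] = True
        calls = {aln.taxa[0]: [(2, tuple(sorted(
            (masked.codons[0][0][1], "A" if masked.codons[0][0][1] != "A"
             else "C"))))]}
        with pytest.warns(UserWarning, match="masked"):
            changes = optimize_intraspecific_changes(calls, tree, masked)
        assert changes == []

    def test_unknown_species_rejected(self, het_setup):
        aln, tree = het_setup
        with pytest.raises(ValueError):
            optimize_intraspecific_changes(
                {"martian": [(1, ("A", "C"))]}, tree, aln)


class TestContrast:
    def test_published_style_percentages(self):
        out = divergence_polymorphism_contrast((326, 154), (22, 18))
        assert out["divergence_nonsyn_percent"] == 68
        assert out["polymorphism_nonsyn_percent"] == 55

    def test_identical_ratios_are_null(self):
        out = divergence_polymorphism_contrast((10, 10), (5, 5))
        assert out["divergence_nonsyn_percent"] == 50
        assert out["polymorphism_nonsyn_percent"] == 50
        assert out["fisher_exact_p"] == pytest.approx(1.0)

    def test_fisher_p_matches_hypergeometric_enumeration(self):
        a, b, c, d = 326, 154, 22, 18
        out = divergence_polymorphism_contrast((a, b), (c, d))
        # two-sided exact test by direct enumeration of the margin-fixed
        # tables, summing probabilities <= that of the observed table
        row1, col1, n = a + b, a + c, a + b + c + d

        def table_p(x):
            return (comb(col1, x) * comb(n - col1, row1 - x)
                    / comb(n, row1))

        observed = table_p(a)
        total = sum(table_p(x)
                    for x in range(max(0, row1 + col1 - n),
                                   min(row1, col1) + 1)
                    if table_p(x) <= observed * (1 + 1e-12))
        assert out["fisher_exact_p"] == pytest.approx(total, rel=1e-8)

    def test_zero_margin_flagged_undefined(self):
        out = divergence_polymorphism_contrast((0, 0), (5, 5))
        assert out["undefined"]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            divergence_polymorphism_contrast((-1, 2), (3, 4))
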