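"""Synthetic-data generators: determinism and statistical structure."""

import io

import numpy as np
import pytest

from codonsel.comparative import encephalization_quotient
from codonsel.engine import CodonModelSpec, EngineError, neutral_fluxes, \
    uniform_codon_freqs
from codonsel.io import read_tree, write_codon_alignment
from codonsel.polymorphism import detect_heterozygous_sites
from codonsel.simulate import (
    CLADES,
    FAMILIES,
    cetacean_time_tree,
    cetacean_tree,
    inject_heterozygosity,
    root_to_tip_true_omega,
    simulate_alignment,
    simulate_lineage_omegas,
    simulate_phenotypes,
)


class TestFixtureTree:
    def test_has_38_tips_in_seven_families(self, tree38):
        assert len(tree38.tip_names()) == 38
        assert len(FAMILIES) == 7
        assert sorted(CLADES["Cetacea"]) == sorted(tree38.tip_names())
        assert len(CLADES["Delphinidae"]) == 23
        assert len(CLADES["Odontoceti"]) == 34

    def test_clades_are_monophyletic(self, tree38):
        for name, tips in CLADES.items():
            mrca = tree38.mrca(tips)
            assert {l.taxon.label for l in mrca.leaf_iter()} == set(tips)

    def test_time_tree_is_ultrametric(self, time_tree38):
        depths = time_tree38.depths()
        assert max(depths.values()) == pytest.approx(35.0)
        assert max(depths.values()) - min(depths.values()) < 1e-9


class TestAlignmentSimulation:
    def test_fixed_seed_reproduces_fasta_bytes(self, tree12):
        spec = CodonModelSpec(kappa=2.0, site_classes=[(1.0, 0.5)])
        outputs = []
        for _ in range(2):
            aln, _ = simulate_alignment(tree12, spec, 50, seed=123)
            buf = io.StringIO()
            write_codon_alignment(aln, buf)
            outputs.append(buf.getvalue())
        assert outputs[0] == outputs[1]

    def test_event_log_ratio_tracks_omega(self, tree38):
        # realized nonsyn/syn event counts vs the ω-implied expectation
        pi = uniform_codon_freqs()
        fn, fs = neutral_fluxes(pi, 2.0)
        for omega in (0.3, 1.0):
            spec = CodonModelSpec(kappa=2.0, codon_freqs=pi,
                                  site_classes=[(1.0, omega)])
            aln, truth = simulate_alignment(tree38, spec, 600, seed=31)
            n_ev, s_ev = truth.event_totals()
            expected = omega * fn / fs
            assert n_ev / s_ev == pytest.approx(expected, rel=0.15)

    def test_event_totals_scale_with_tree_length(self):
        spec = CodonModelSpec(kappa=2.0, site_classes=[(1.0, 0.5)])
        short, _ = cetacean_tree(scale=1.0), None
        long = cetacean_tree(scale=2.0)
        _, t1 = simulate_alignment(short, spec, 500, seed=4)
        _, t2 = simulate_alignment(long, spec, 500, seed=4)
        ratio = sum(t2.event_totals()) / sum(t1.event_totals())
        assert 1.6 < ratio < 2.4

    def test_long_branch_reaches_stationarity(self):
        tree = read_tree("(A:25.0,B:25.0);")
        pi = uniform_codon_freqs()
        spec = CodonModelSpec(kappa=1.0, codon_freqs=pi,
                              site_classes=[(1.0, 1.0)])
        aln, _ = simulate_alignment(tree, spec, 2000, seed=8)
        from codonsel.codes import STANDARD_CODE
        counts = np.zeros(61)
        for codon in aln.codons[0]:
            counts[STANDARD_CODE.index[codon]] += 1
        tv = 0.5 * np.abs(counts / counts.sum() - pi).sum()
        assert tv < 0.1

    def test_site_classes_recorded_in_truth(self, tree12):
        spec = CodonModelSpec(
            kappa=2.0, site_classes=[(0.5, 0.1), (0.5, 1.0)])
        _, truth = simulate_alignment(tree12, spec, 300, seed=5)
        frac = (truth.per_site_class == 0).mean()
        assert frac == pytest.approx(0.5, abs=0.1)

    def test_invalid_sites_rejected(self, tree12):
        with pytest.raises(EngineError):
            simulate_alignment(tree12, CodonModelSpec(), 0, seed=1)


class TestLineageOmegas:
    def test_zero_dispersion_is_constant(self, time_tree38):
        _, omega_map = simulate_lineage_omegas(time_tree38, 0.4, 0.0,
                                               seed=1)
        assert all(v == pytest.approx(0.4) for v in omega_map.values())

    def test_dispersion_orders_tip_variance(self, time_tree38):
        spreads = {}
        for disp in (0.002, 0.05):
            variances = []
            for seed in range(25):
                marked, omega_map = simulate_lineage_omegas(
                    time_tree38, 0.4, disp, seed=seed)
                rtt = root_to_tip_true_omega(marked, omega_map)
                variances.append(np.var(np.log(list(rtt.values()))))
            spreads[disp] = np.mean(variances)
        assert spreads[0.05] > spreads[0.002]

    def test_sisters_more_correlated_than_distant_tips(self, time_tree38):
        sister_pair = FAMILIES["Monodontidae"]
        distant_pair = (FAMILIES["Monodontidae"][0],
                        FAMILIES["Mysticeti"][0])
        a = {"sister": [], "distant": []}
        for seed in range(40):
            marked, omega_map = simulate_lineage_omegas(
                time_tree38, 0.4, 0.03, seed=seed)
            rtt = root_to_tip_true_omega(marked, omega_map)
            a["sister"].append([np.log(rtt[t]) for t in sister_pair])
            a["distant"].append([np.log(rtt[t]) for t in distant_pair])
        corr_sister = np.corrcoef(np.array(a["sister"]).T)[0, 1]
        corr_distant = np.corrcoef(np.array(a["distant"]).T)[0, 1]
        assert corr_sister > corr_distant

    def test_invalid_parameters(self, time_tree38):
        with pytest.raises(EngineError):
            simulate_lineage_omegas(time_tree38, -1.0, 0.1, seed=0)
        with pytest.raises(EngineError):
            simulate_lineage_omegas(time_tree38, 1.0, -0.1, seed=0)


class TestPhenotypes:
    def test_no_slope_no_noise_is_constant(self, time_tree38):
        _, omega_map = simulate_lineage_omegas(time_tree38, 0.4, 0.05,
                                               seed=2)
        marked, omega_map = simulate_lineage_omegas(time_tree38, 0.4, 0.05,
                                                    seed=2)
        rtt = root_to_tip_true_omega(marked, omega_map)
        phen = simulate_phenotypes(time_tree38, rtt, slope=0.0,
                                   bm_sigma=0.0, seed=3, eq_sigma=0.0)
        assert phen["body_mass"].nunique() == 1

    def test_eq_column_matches_eq_operation_exactly(self, time_tree38):
        marked, omega_map = simulate_lineage_omegas(time_tree38, 0.4, 0.03,
                                                    seed=4)
        rtt = root_to_tip_true_omega(marked, omega_map)
        phen = simulate_phenotypes(time_tree38, rtt, slope=0.3,
                                   bm_sigma=0.15, seed=4)
        recomputed = encephalization_quotient(
            phen["brain_mass"].to_numpy(), phen["body_mass"].to_numpy())
        assert np.allclose(phen["EQ"].to_numpy(), recomputed, rtol=1e-12)

    def test_max_body_exceeds_body(self, time_tree38):
        marked, omega_map = simulate_lineage_omegas(time_tree38, 0.4, 0.03,
                                                    seed=5)
        rtt = root_to_tip_true_omega(marked, omega_map)
        phen = simulate_phenotypes(time_tree38, rtt, slope=0.3,
                                   bm_sigma=0.15, seed=5)
        assert (phen["max_body_mass"] > phen["body_mass"]).all()


@pytest.fixture(scope="module")
def base_alignment(tree38):
    spec = CodonModelSpec(kappa=2.0, site_classes=[(1.0, 0.3)])
    aln, _ = simulate_alignment(tree38, spec, 400, seed=19)
    return aln


class TestHeterozygoteInjection:

    def test_zero_rate_is_identity(self, base_alignment):
        out, truth = inject_heterozygosity(base_alignment, 0.0, seed=1)
        assert out.codons == base_alignment.codons
        assert truth == []

    def test_round_trip_recovers_planted_variants(self, base_alignment):
        out, truth = inject_heterozygosity(base_alignment, 0.005, seed=7)
        planted = {(t["species"], t["nt_position"], t["bases"])
                   for t in truth}
        detected = set()
        for name in out.taxa:
            for pos, pair in detect_heterozygous_sites(out.sequence(name)):
                detected.add((name, pos, pair))
        assert detected == planted
        assert len(planted) > 50

    def test_count_within_binomial_bounds(self, base_alignment):
        rate = 0.01
        out, truth = inject_heterozygosity(base_alignment, rate, seed=11)
        n_eligible = int((~base_alignment.mask).sum())
        p_hit = 1 - (1 - rate) ** 3
        expected = n_eligible * p_hit
        sd = np.sqrt(n_eligible * p_hit * (1 - p_hit))
        assert abs(len(truth) - expected) < 4 * sd

    def test_nonsyn_fraction_is_controllable(self, base_alignment):
        out, truth = inject_heterozygosity(base_alignment, 0.01, seed=13,
                                           nonsyn_fraction=0.55)
        effects = [t["effect"] for t in truth]
        frac = np.mean([e == "nonsynonymous" for e in effects])
        sd = np.sqrt(0.55 * 0.45 / len(effects))
        assert abs(frac - 0.55) < 4 * sd + 0.02

    def test_no_stop_only_resolutions(self, base_alignment):
        from codonsel.codes import STANDARD_CODE
        out, truth = inject_heterozygosity(base_alignment, 0.01, seed=17)
        for rec in truth:
            i = out.taxon_index(rec["species"])
            codon = out.codons[i][rec["site"] - 1]
            states = STANDARD_CODE.expand_ambiguous(codon)
            assert len(states) >= 1

    def test_invalid_rate_rejected(self, base_alignment):
        with pytest.raises(EngineError):
            inject_heterozygosity(base_alignment, 1.0, seed=0)
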