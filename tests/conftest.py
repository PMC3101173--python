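"""Shared fixtures and independent oracles.

The brute-force likelihood oracle here deliberately avoids the package's
pruning/eigendecomposition path: rate matrices are rebuilt from first
principles with Biopython's genetic code, matrix exponentials come from
scipy.linalg.expm, and the likelihood is an explicit sum over all
internal-node codon assignments.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pytest
from hypothesis import settings

from Bio.Data import CodonTable, IUPACData
from scipy.linalg import expm

from codonsel.engine import CodonModelSpec
from codonsel.io import CodonAlignment, Phylogeny
from codonsel.simulate import cetacean_tree, cetacean_time_tree, \
    simulate_alignment

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# Trees


@pytest.fixture(scope="session")
def tree38():
    return cetacean_tree()


@pytest.fixture(scope="session")
def time_tree38():
    return cetacean_time_tree()


@pytest.fixture(scope="session")
def tree12(tree38):
    return tree38.extract(tree38.tip_names()[::3][:12], name="t12")


@pytest.fixture(scope="session")
def m2a_data(tree12):
    """Alignment with a planted positive-selection class (session-wide)."""
    spec = CodonModelSpec(
        kappa=2.5,
        site_classes=[(0.65, 0.05), (0.20, 1.0), (0.15, 4.0)])
    aln, truth = simulate_alignment(tree12, spec, 200, seed=42)
    return aln, truth, spec


@pytest.fixture(scope="session")
def m2a_fits(m2a_data, tree12):
    """M1a and M2a fits of the planted-positive-selection alignment."""
    from codonsel.engine import LikelihoodEvaluator
    from codonsel.sitemodels import fit_site_model

    aln, truth, _ = m2a_data
    ev = LikelihoodEvaluator(aln, tree12)
    return {
        "M1a": fit_site_model(aln, tree12, "M1a", evaluator=ev),
        "M2a": fit_site_model(aln, tree12, "M2a", evaluator=ev),
    }


# ---------------------------------------------------------------------------
# Brute-force likelihood oracle


_TABLE = CodonTable.unambiguous_dna_by_id[1]
_SENSE = sorted(
    "".join(c) for c in product("ACGT", repeat=3)
    if "".join(c) not in _TABLE.stop_codons
)
_SENSE_INDEX = {c: i for i, c in enumerate(_SENSE)}


def _oracle_rate_matrix(freqs: np.ndarray, kappa: float,
                        omega: float) -> np.ndarray:
    """Goldman–Yang generator rebuilt from first principles, normalized
    to unit mean rate at stationarity."""
    n = len(_SENSE)
    q = np.zeros((n, n))
    purines = {"A", "G"}
    pyrimidines = {"C", "T"}
    for i, ci in enumerate(_SENSE):
        for j, cj in enumerate(_SENSE):
            if i == j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            rate = freqs[j]
            pair = {ci[k], cj[k]}
            if pair <= purines or pair <= pyrimidines:
                rate *= kappa
            if _TABLE.forward_table[ci] != _TABLE.forward_table[cj]:
                rate *= omega
            q[i, j] = rate
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -(freqs * np.diag(q)).sum()
    return q / mu


def _oracle_tip_vector(codon: str) -> np.ndarray:
    """Indicator over sense codons compatible with a (possibly
    IUPAC-ambiguous or gap) codon; all-ones for missing data."""
    vec = np.zeros(len(_SENSE))
    if codon == "---":
        return np.ones(len(_SENSE))
    choices = [sorted(IUPACData.ambiguous_dna_values.get(b, b))
               for b in codon]
    for combo in product(*choices):
        c = "".join(combo)
        if c in _SENSE_INDEX:
            vec[_SENSE_INDEX[c]] = 1.0
    return vec


def brute_force_loglik(aln: CodonAlignment, tree: Phylogeny, kappa: float,
                       omega: float, freqs: np.ndarray) -> float:
    """Exhaustive sum over all internal-node codon assignments.

    Only feasible for trees with at most 3 internal nodes; the grid has
    one 61-state axis per internal node.
    """
    q = _oracle_rate_matrix(freqs, kappa, omega)
    nodes = list(tree.tree.postorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    assert len(internal) <= 3, "oracle grid limited to 3 internal nodes"
    axis = {id(n): k for k, n in enumerate(internal)}
    n_axes = len(internal)
    shape = (len(_SENSE),) * n_axes

    def lift(arr: np.ndarray, ax: int) -> np.ndarray:
        idx = [None] * n_axes
        idx[ax] = slice(None)
        return arr[tuple(idx)]

    root = internal[-1]
    const = np.ones(shape) * lift(np.asarray(freqs), axis[id(root)])
    edge_p = {}
    for node in nodes:
        if node.parent_node is None:
            continue
        edge_p[id(node)] = expm(q * (node.edge.length or 0.0))
    for node in internal:
        if node.parent_node is None:
            continue
        p = edge_p[id(node)]
        pa, ca = axis[id(node.parent_node)], axis[id(node)]
        idx = [None] * n_axes
        idx[pa], idx[ca] = slice(None), slice(None)
        if pa < ca:
            const = const * p[tuple(idx)]
        else:
            const = const * p.T[tuple(idx)]

    taxon_row = {name: i for i, name in enumerate(aln.taxa)}
    total = 0.0
    for s in range(aln.n_sites):
        grid = const.copy()
        for node in nodes:
            if not node.is_leaf():
                continue
            i = taxon_row[node.taxon.label]
            codon = "---" if aln.mask[i, s] else aln.codons[i][s]
            vec = edge_p[id(node)] @ _oracle_tip_vector(codon)
            grid = grid * lift(vec, axis[id(node.parent_node)])
        total += np.log(grid.sum())
    return total


_ORACLE_TOPOLOGIES = (
    "((A:{0},B:{1}):{2},C:{3});",
    "((A:{0},B:{1}):{2},(C:{3},D:{4}):{5});",
    "(((A:{0},B:{1}):{2},C:{3}):{4},D:{5});",
    "((A:{0},B:{1},C:{2}):{3},(D:{4},E:{5}):{6});",
    "((A:{0},B:{1}):{2},(C:{3},D:{4}):{5},E:{6});",
    "(A:{0},B:{1},C:{2},D:{3},E:{4});",
)


def random_oracle_instance(rng: np.random.Generator,
                           max_sites: int = 25):
    """A random small (alignment, tree, κ, ω, freqs) likelihood instance
    with occasional gaps and ambiguous codons."""
    template = _ORACLE_TOPOLOGIES[rng.integers(len(_ORACLE_TOPOLOGIES))]
    n_lengths = template.count("{")
    lengths = rng.uniform(0.02, 0.7, n_lengths)
    tree = Phylogeny.from_newick(template.format(*lengths))
    taxa = sorted(tree.tip_names())
    n_sites = int(rng.integers(5, max_sites + 1))
    freqs = rng.dirichlet(np.full(len(_SENSE), 5.0))
    kappa = rng.uniform(1.0, 4.0)
    omega = float(np.exp(rng.uniform(np.log(0.05), np.log(3.0))))
    pair_code = {frozenset(b): c
                 for c, b in IUPACData.ambiguous_dna_values.items()
                 if len(b) == 2}
    codons, mask = [], np.zeros((len(taxa), n_sites), dtype=bool)
    for i in range(len(taxa)):
        row = []
        for s in range(n_sites):
            u = rng.random()
            if u < 0.05:
                row.append("---")
                mask[i, s] = True
            else:
                codon = _SENSE[rng.integers(len(_SENSE))]
                if u < 0.10:
                    # heterozygote-style ambiguity containing the
                    # original base, so a sense resolution always exists
                    pos = rng.integers(3)
                    orig = codon[pos]
                    alt = rng.choice([b for b in "ACGT" if b != orig])
                    code = pair_code[frozenset((orig, alt))]
                    codon = codon[:pos] + code + codon[pos + 1:]
                row.append(codon)
        codons.append(row)
    aln = CodonAlignment(taxa=taxa, codons=codons, mask=mask)
    return aln, tree, kappa, omega, freqs


@pytest.fixture(scope="session")
def likelihood_oracle():
    return brute_force_loglik


@pytest.fixture(scope="session")
def oracle_instances():
    return random_oracle_instance
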