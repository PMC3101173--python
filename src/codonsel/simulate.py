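"""Synthetic data with the statistical structure the analyses assume.

Alignments are simulated by exact continuous-time Markov sampling along
each branch (exponential waiting times between substitution events), so
every realized substitution is logged and classifiable — parameter-
recovery and calibration tests can compare fitted quantities against
counted truth rather than against another matrix-exponential code path.
Phenotypes evolve as Brownian motion on a time tree with a configurable
log-linear link to lineage ω, and heterozygous sites are injected as
two-base IUPAC codes with a controllable nonsynonymous fraction.

All generators are pure functions of their inputs and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codes import STANDARD_CODE, iupac_for_pair
from .comparative import EQ_COEFFICIENT, EQ_EXPONENT, bm_covariance
from .engine import CodonModelSpec, EngineError, TreeIndex, \
    _raw_generator, mean_rate
from .io import CodonAlignment, Phylogeny


# ---------------------------------------------------------------------------
# Fixture tree: 38 cetacean-like tips in seven family-level groups
# (4 baleen whales; toothed whales: 23 dolphins, 3 porpoises, 2 monodontids,
# sperm + dwarf sperm whale, 2 beaked whales, 2 river dolphins), mirroring
# a typical cetacean sampling design.  Branch lengths are fixed and
# arbitrary, in expected substitutions per codon.

FAMILIES = {
    "Mysticeti": [f"mysticete_{i:02d}" for i in range(1, 5)],
    "Physeteroidea": ["physeter", "kogia"],
    "Ziphiidae": ["ziphiid_01", "ziphiid_02"],
    "RiverDolphins": ["platanistid_01", "iniid_01"],
    "Monodontidae": ["monodontid_01", "monodontid_02"],
    "Phocoenidae": [f"phocoenid_{i:02d}" for i in range(1, 4)],
    "Delphinidae": [f"delphinid_{i:02d}" for i in range(1, 24)],
}

CLADES = {
    "Mysticeti": FAMILIES["Mysticeti"],
    "Delphinidae": FAMILIES["Delphinidae"],
    "Delphinoidea": (FAMILIES["Delphinidae"] + FAMILIES["Phocoenidae"]
                     + FAMILIES["Monodontidae"]),
    "Odontoceti": (FAMILIES["Physeteroidea"] + FAMILIES["Ziphiidae"]
                   + FAMILIES["RiverDolphins"] + FAMILIES["Monodontidae"]
                   + FAMILIES["Phocoenidae"] + FAMILIES["Delphinidae"]),
    "Cetacea": [t for tips in FAMILIES.values() for t in tips],
}


def _ladder(names: list[str], tip: float, step: float) -> str:
    """Pectinate subtree over ``names`` with fixed branch lengths."""
    if len(names) == 1:
        return f"{names[0]}:{tip}"
    inner = _ladder(names[1:], tip, step)
    return f"({names[0]}:{tip},{inner}):{step}"


def cetacean_tree(scale: float = 1.0, name: str = "cetacea") -> Phylogeny:
    """The 38-tip fixture tree; ``scale`` multiplies all branch lengths
    (substitutions per codon at scale 1, ~tens of Myr at scale 100)."""
    f = FAMILIES

    def lad(key, tip, step):
        return _ladder(f[key], tip * scale, step * scale)

    newick = (
        "("
        f"({lad('Mysticeti', 0.04, 0.015)}):{0.05 * scale},"
        "("
        f"({lad('Physeteroidea', 0.05, 0.02)}):{0.03 * scale},"
        "("
        f"({lad('Ziphiidae', 0.05, 0.02)}):{0.02 * scale},"
        "("
        f"({lad('RiverDolphins', 0.05, 0.02)}):{0.02 * scale},"
        "("
        f"(({lad('Monodontidae', 0.03, 0.012)}):{0.02 * scale},"
        f"({lad('Phocoenidae', 0.03, 0.012)}):{0.02 * scale}"
        f"):{0.015 * scale},"
        f"({lad('Delphinidae', 0.02, 0.008)}):{0.03 * scale}"
        f"):{0.02 * scale}"
        f"):{0.015 * scale}"
        f"):{0.015 * scale}"
        f"):{0.02 * scale}"
        ");"
    )
    phy = Phylogeny.from_newick(newick, name=name)
    # family wrappers above introduce unifurcations; merge them away
    phy.tree.suppress_unifurcations()
    return phy


def cetacean_time_tree(root_age: float = 35.0) -> Phylogeny:
    """Same topology ultrametricized to a time tree (root age in Myr)
    for Brownian-motion phenotype covariances."""
    phy = cetacean_tree(name="cetacea_time")
    tree = phy.tree
    # stretch terminal branches so all tips reach the same depth
    depths = {}
    for node in tree.preorder_node_iter():
        parent_depth = 0.0 if node.parent_node is None \
            else depths[id(node.parent_node)]
        depths[id(node)] = parent_depth + (node.edge.length or 0.0)
    max_depth = max(depths[id(l)] for l in tree.leaf_node_iter())
    for leaf in tree.leaf_node_iter():
        leaf.edge.length += max_depth - depths[id(leaf)]
    factor = root_age / max_depth
    for node in tree:
        if node.edge.length is not None:
            node.edge.length *= factor
    return phy


# ---------------------------------------------------------------------------
# Sequence simulation


@dataclass
class SimulationTruth:
    """Ground truth saved alongside every simulated dataset."""

    seed: int
    spec: CodonModelSpec
    per_site_class: np.ndarray | None = None
    per_branch_omega: dict[int, float] | None = None
    branch_events: list[dict] = field(default_factory=list)
    phenotype_slope: float | None = None

    def event_totals(self) -> tuple[int, int]:
        n = sum(e["nonsyn"] for e in self.branch_events)
        s = sum(e["syn"] for e in self.branch_events)
        return n, s


def _jump_tables(freqs, kappa, omega, code):
    q = _raw_generator(freqs, kappa, omega, code)
    rates = -np.diag(q).copy()
    jump = q / rates[:, None]
    np.fill_diagonal(jump, 0.0)
    return rates, np.cumsum(jump, axis=1)


def _evolve_branch(states: np.ndarray, duration: float, rates, jump_cum,
                   code, rng) -> tuple[np.ndarray, int, int]:
    """Exact CTMC sampling of all sites over one branch; returns end
    states and (nonsynonymous, synonymous) event counts."""
    states = states.copy()
    clock = np.zeros(len(states))
    n_events = s_events = 0
    active = np.arange(len(states))
    while len(active):
        waits = rng.exponential(1.0 / rates[states[active]])
        clock[active] += waits
        still = clock[active] <= duration
        active = active[still]
        if not len(active):
            break
        u = rng.random(len(active))
        rows = jump_cum[states[active]]
        new = (u[:, None] > rows).sum(axis=1)
        syn = code.is_synonymous[states[active], new]
        s_events += int(syn.sum())
        n_events += int((~syn).sum())
        states[active] = new
    return states, n_events, s_events


def simulate_alignment(tree: Phylogeny, spec: CodonModelSpec, n_sites: int,
                       seed: int) -> tuple[CodonAlignment, SimulationTruth]:
    """Evolve a codon alignment along ``tree`` under ``spec``.

    Sites draw a class from the mixture; root codons come from the
    stationary frequencies; branch lengths are expected substitutions
    per codon under the mixture (or per-branch ω map), matching the
    engine's normalization.  Every substitution event is logged per
    branch in the returned truth record.
    """
    if n_sites < 1:
        raise EngineError("n_sites must be at least 1")
    rng = np.random.default_rng(seed)
    code = STANDARD_CODE
    freqs = spec.codon_freqs if spec.codon_freqs is not None else \
        np.full(code.n_states, 1.0 / code.n_states)
    tidx = TreeIndex(tree, tree.tip_names())

    branch_mode = spec.branch_omega_map is not None
    if branch_mode:
        classes = [(1.0, 1.0)]
        site_class = np.zeros(n_sites, dtype=int)
        omegas = [1.0]
    else:
        classes = spec.resolved_classes()
        probs = np.array([p for p, _ in classes])
        omegas = [w for _, w in classes]
        site_class = rng.choice(len(classes), size=n_sites, p=probs)
        mus = np.array([mean_rate(freqs, spec.kappa, w, code)
                        for w in omegas])
        mixture_rate = float(probs @ mus)

    tables = {}

    def tables_for(omega):
        if omega not in tables:
            tables[omega] = _jump_tables(freqs, spec.kappa, omega, code)
        return tables[omega]

    states = {tidx.root: rng.choice(code.n_states, size=n_sites, p=freqs)}
    truth = SimulationTruth(seed=seed, spec=spec,
                            per_site_class=site_class,
                            per_branch_omega={} if branch_mode else None)
    for node in reversed(tidx.postorder):
        if node == tidx.root:
            continue
        parent_states = states[tidx.parent[node]]
        t = tidx.lengths[node]
        child = parent_states.copy()
        n_ev = s_ev = 0
        if branch_mode:
            omega_b = spec.branch_omega_map[int(tidx.labels[node])]
            truth.per_branch_omega[node] = omega_b
            mu = mean_rate(freqs, spec.kappa, omega_b, code)
            rates, jump = tables_for(omega_b)
            child, n_ev, s_ev = _evolve_branch(
                child, t / mu, rates, jump, code, rng)
        else:
            for k, omega_k in enumerate(omegas):
                idx = np.flatnonzero(site_class == k)
                if not len(idx):
                    continue
                rates, jump = tables_for(omega_k)
                sub, n_k, s_k = _evolve_branch(
                    child[idx], t / mixture_rate, rates, jump, code, rng)
                child[idx] = sub
                n_ev += n_k
                s_ev += s_k
        states[node] = child
        truth.branch_events.append(
            {"branch": node, "length": float(t),
             "nonsyn": n_ev, "syn": s_ev})

    order = {name: i for i, name in enumerate(tree.tip_names())}
    tip_rows = [None] * len(order)
    for node in tidx.postorder:
        if tidx.is_tip[node]:
            name = tree.tip_names()[tidx.tip_taxon[node]]
            tip_rows[order[name]] = [code.codons[s] for s in states[node]]
    taxa = list(tree.tip_names())
    aln = CodonAlignment(
        taxa=taxa, codons=tip_rows,
        mask=np.zeros((len(taxa), n_sites), dtype=bool))
    return aln, truth


def simulate_lineage_omegas(tree: Phylogeny, base_omega: float,
                            dispersion: float, seed: int
                            ) -> tuple[Phylogeny, dict[int, float]]:
    """Brownian motion of log ω along the tree.

    Node values evolve as BM with variance rate ``dispersion``; each
    branch's ω is the geometric mean of its endpoint values.  Returns a
    copy of the tree with every branch distinctly labeled and the
    label → ω map (suitable for ``CodonModelSpec.branch_omega_map``).
    """
    if base_omega <= 0:
        raise EngineError("base_omega must be positive")
    if dispersion < 0:
        raise EngineError("dispersion must be nonnegative")
    rng = np.random.default_rng(seed)
    marked = tree.clone()
    log_val = {}
    omega_map = {}
    label = 0
    for node in marked.tree.preorder_node_iter():
        if node.parent_node is None:
            log_val[id(node)] = float(np.log(base_omega))
            node.omega_label = 0
            continue
        t = node.edge.length or 0.0
        parent = log_val[id(node.parent_node)]
        log_val[id(node)] = parent + rng.normal(
            0.0, np.sqrt(dispersion * t)) if dispersion > 0 else parent
        node.omega_label = label
        omega_map[label] = float(
            np.exp(0.5 * (parent + log_val[id(node)])))
        label += 1
    return marked, omega_map


def root_to_tip_true_omega(tree_with_labels: Phylogeny,
                           omega_map: dict[int, float]) -> dict[str, float]:
    """Branch-length-weighted mean ω along each root-to-tip path (the
    generative counterpart of the fitted root-to-tip ω)."""
    out = {}
    for leaf in tree_with_labels.tree.leaf_node_iter():
        total_t = total_wt = 0.0
        node = leaf
        while node.parent_node is not None:
            t = node.edge.length or 0.0
            total_t += t
            total_wt += t * omega_map[node.omega_label]
            node = node.parent_node
        out[leaf.taxon.label] = total_wt / total_t if total_t else np.nan
    return out


def simulate_phenotypes(tree: Phylogeny, root_to_tip_omega: dict[str, float],
                        slope: float, bm_sigma: float, seed: int,
                        mean_log_body: float = 5.3,
                        eq_slope: float = 0.0,
                        eq_sigma: float = 0.1) -> pd.DataFrame:
    """Brownian log-phenotypes with a planted linear link to lineage ω.

    log10 body mass = intercept + slope·log10(ω) + BM noise (rate
    bm_sigma² on the time tree); brain mass follows the EQ allometry
    with a species EQ deviation log10 EQ = eq_slope·log10(ω) + iid
    noise.  The returned table's EQ column therefore reproduces the EQ
    operation applied to its brain and body columns exactly.
    """
    if not np.isfinite(slope):
        raise EngineError("slope must be finite")
    if bm_sigma < 0:
        raise EngineError("bm_sigma must be nonnegative")
    rng = np.random.default_rng(seed)
    species = [s for s in tree.tip_names() if s in root_to_tip_omega]
    log_omega = np.log10([root_to_tip_omega[s] for s in species])
    log_omega_c = log_omega - log_omega.mean()
    if bm_sigma > 0:
        cov = bm_covariance(tree, species) * bm_sigma ** 2
        noise = rng.multivariate_normal(np.zeros(len(species)), cov,
                                        method="cholesky")
    else:
        noise = np.zeros(len(species))
    log_body = mean_log_body + slope * log_omega_c + noise
    log_eq = (np.log10(1.2) + eq_slope * log_omega_c
              + rng.normal(0.0, eq_sigma, len(species)))
    body = 10.0 ** log_body
    eq = 10.0 ** log_eq
    brain = EQ_COEFFICIENT * body ** EQ_EXPONENT * eq
    max_body = body * rng.uniform(1.1, 1.6, len(species))
    return pd.DataFrame({
        "species": species,
        "brain_mass": brain,
        "body_mass": body,
        "max_body_mass": max_body,
        "EQ": eq,
    })


# ---------------------------------------------------------------------------
# Heterozygote injection


def inject_heterozygosity(aln: CodonAlignment, rate: float, seed: int,
                          nonsyn_fraction: float | None = None
                          ) -> tuple[CodonAlignment, list[dict]]:
    """Replace bases with two-base IUPAC codes at per-site rate ``rate``.

    The ambiguity always includes the original base, so no injected
    site resolves only to stop codons; candidate alternate bases that
    would create a stop codon are excluded outright.  When
    ``nonsyn_fraction`` is given, the synonymous/nonsynonymous mix of
    injected variants is biased accordingly (where the codon offers a
    choice).  Returns the modified alignment and a truth list.
    """
    if not (0 <= rate < 1):
        raise EngineError("rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    code = STANDARD_CODE
    codons = [list(row) for row in aln.codons]
    truth = []
    hit_prob = 1.0 - (1.0 - rate) ** 3  # any of the 3 codon positions
    for i, name in enumerate(aln.taxa):
        for s in range(aln.n_sites):
            if aln.mask[i, s] or aln.is_ambiguous(i, s):
                continue
            if rng.random() >= hit_prob:
                continue
            codon = codons[i][s]
            options = []  # (offset0, alt base, is_synonymous)
            for offset in range(3):
                orig = codon[offset]
                for alt in "ACGT":
                    if alt == orig:
                        continue
                    derived = codon[:offset] + alt + codon[offset + 1:]
                    if derived in code.stop_codons:
                        continue
                    syn = (code.translate(codon) == code.translate(derived))
                    options.append((offset, alt, syn))
            if not options:
                continue
            if nonsyn_fraction is not None:
                want_nonsyn = rng.random() < nonsyn_fraction
                filtered = [o for o in options if o[2] != want_nonsyn]
                if filtered:
                    options = filtered
            offset, alt, syn = options[rng.integers(len(options))]
            orig = codon[offset]
            het = iupac_for_pair(orig, alt)
            codons[i][s] = codon[:offset] + het + codon[offset + 1:]
            truth.append({
                "species": name,
                "nt_position": 3 * s + offset + 1,
                "site": s + 1,
                "offset": offset + 1,
                "bases": tuple(sorted((orig, alt))),
                "effect": "synonymous" if syn else "nonsynonymous",
            })
    out = CodonAlignment(taxa=list(aln.taxa), codons=codons,
                         mask=aln.mask.copy(),
                         genetic_code=aln.genetic_code)
    return out, truth
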