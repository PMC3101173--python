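"""Intraspecific variation: heterozygote detection, parsimony counting
of within-species changes, and the divergence-versus-polymorphism
contrast.

Heterozygous positions arrive as two-base IUPAC ambiguity codes (the
downstream representation of double peaks in chromatograms).  Each
distinct (site, allele pair) is optimized onto the gene tree by Fitch
parsimony on a presence/absence character, so an allele pair shared by
sister species counts as one change on their stem rather than two
independent ones.  Changes are classified by codon position, synonymous
versus nonsynonymous effect, and transition versus transversion, and the
within-species spectrum is contrasted with the expected between-species
substitution counts from an M0 fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from scipy import stats as _stats

from .codes import (
    AMBIGUOUS_DNA,
    NUCLEOTIDES,
    PURINES,
    PYRIMIDINES,
    STANDARD_CODE,
    TWO_BASE_IUPAC,
    CodonCode,
)
from .io import CodonAlignment, Phylogeny


@dataclass
class VariantChange:
    site: int                 # 1-based codon-alignment position
    nucleotide_offset: int    # 1 | 2 | 3 within the codon
    from_state: str
    to_state: str
    effect: str               # synonymous | nonsynonymous
    mutation_class: str       # transition | transversion
    species: str
    n_events: int = 1         # parsimony-inferred change count
    to_stop: bool = False


def detect_heterozygous_sites(seq: str) -> list[tuple[int, tuple[str, str]]]:
    """1-based positions bearing two-base IUPAC codes with their
    resolved base pairs; codes resolving to 3+ bases are excluded with
    a warning (unsupported as heterozygote calls)."""
    out = []
    for pos, base in enumerate(seq.upper(), start=1):
        if base in NUCLEOTIDES or base == "-":
            continue
        if base in TWO_BASE_IUPAC:
            a, b = sorted(TWO_BASE_IUPAC[base])
            out.append((pos, (a, b)))
        elif base in AMBIGUOUS_DNA:
            warnings.warn(
                f"position {pos}: {base} resolves to more than two bases; "
                "excluded from heterozygote calls")
        else:
            raise ValueError(f"unrecognized symbol {base!r} at {pos}")
    return out


def classify_change(codon_context: str, offset: int, from_base: str,
                    to_base: str, genetic_code: int = 1) -> dict:
    """Classify a single-nucleotide change within a sense codon.

    ``codon_context`` carries ``from_base`` at 1-based ``offset``; the
    derived codon substitutes ``to_base`` there.
    """
    code = STANDARD_CODE if genetic_code == 1 else CodonCode(genetic_code)
    codon_context = codon_context.upper()
    if codon_context not in code.index:
        raise ValueError(f"{codon_context} is not a sense codon")
    if offset not in (1, 2, 3):
        raise ValueError("offset must be 1, 2 or 3")
    if codon_context[offset - 1] != from_base.upper():
        raise ValueError(
            f"codon {codon_context} has {codon_context[offset - 1]} at "
            f"position {offset}, not {from_base}")
    derived = (codon_context[:offset - 1] + to_base.upper()
               + codon_context[offset:])
    pair = {from_base.upper(), to_base.upper()}
    transition = pair <= PURINES or pair <= PYRIMIDINES
    to_stop = derived in code.stop_codons
    if to_stop:
        effect = "nonsense"
    else:
        effect = ("synonymous"
                  if code.translate(codon_context) == code.translate(derived)
                  else "nonsynonymous")
    return {
        "effect": effect,
        "mutation_class": "transition" if transition else "transversion",
        "position": offset,
        "to_stop": to_stop,
    }


def _fitch_changes(tree: Phylogeny, present: set[str]) -> int:
    """Minimum state changes for a binary presence/absence character.

    Sankoff dynamic program (cost 1 per state change on an edge), exact
    on any tree including polytomies; tips absent from ``present`` carry
    state 0.
    """
    INF = float("inf")
    cost: dict[int, list[float]] = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            s = int(node.taxon.label in present)
            cost[id(node)] = [INF, INF]
            cost[id(node)][s] = 0.0
            continue
        here = [0.0, 0.0]
        for child in node.child_nodes():
            c = cost[id(child)]
            for s in (0, 1):
                here[s] += min(c[s], c[1 - s] + 1)
        cost[id(node)] = here
    return int(min(cost[id(tree.tree.seed_node)]))


def optimize_intraspecific_changes(
        het_calls: dict[str, list[tuple[int, tuple[str, str]]]],
        gene_tree: Phylogeny, alignment: CodonAlignment,
        genetic_code: int = 1) -> list[VariantChange]:
    """Parsimony-optimize heterozygote calls onto the gene tree.

    ``het_calls`` maps species to (1-based nucleotide position, base
    pair) records on the alignment coordinate system.  Each distinct
    (position, pair) is a presence/absence character whose Fitch change
    count gives the number of independent origins; shared alleles in
    related species are counted once.  Calls at masked sites are
    excluded with a warning.
    """
    tips = set(gene_tree.tip_names())
    unknown = set(het_calls) - tips
    if unknown:
        raise ValueError(f"species not in gene tree: {sorted(unknown)}")
    by_variant: dict[tuple[int, tuple[str, str]], set[str]] = {}
    for species, calls in het_calls.items():
        for pos, pair in calls:
            by_variant.setdefault((pos, tuple(sorted(pair))), set()
                                  ).add(species)
    changes: list[VariantChange] = []
    for (pos, pair), species_set in sorted(by_variant.items()):
        site = (pos - 1) // 3          # 0-based codon site
        offset = (pos - 1) % 3 + 1
        rep = sorted(species_set)[0]
        i = alignment.taxon_index(rep)
        if alignment.mask[i, site]:
            warnings.warn(
                f"heterozygote call at masked site {site + 1} "
                f"({rep}); excluded")
            continue
        # Ancestral base: the allele seen in homozygous form elsewhere
        # in the alignment at this position; falls back to the first of
        # the pair when both or neither occur.
        col = [alignment.codons[j][site][offset - 1]
               for j in range(alignment.n_taxa)
               if not alignment.mask[j, site]
               and alignment.taxa[j] not in species_set]
        counts = {b: col.count(b) for b in pair}
        from_base = max(pair, key=lambda b: counts.get(b, 0))
        to_base = pair[0] if from_base == pair[1] else pair[1]
        codon = alignment.codons[i][site]
        context = (codon[:offset - 1] + from_base + codon[offset:])
        info = classify_change(context, offset, from_base, to_base,
                               genetic_code=genetic_code)
        n_events = _fitch_changes(gene_tree, species_set)
        changes.append(VariantChange(
            site=site + 1, nucleotide_offset=offset,
            from_state=from_base, to_state=to_base,
            effect=info["effect"], mutation_class=info["mutation_class"],
            species=",".join(sorted(species_set)), n_events=n_events,
            to_stop=info["to_stop"],
        ))
    return changes


def summarize_changes(changes: list[VariantChange]) -> dict:
    """Counts by effect, mutation class and codon position, weighting
    each variant by its parsimony change count."""
    out = {"nonsynonymous": 0, "synonymous": 0, "nonsense": 0,
           "transitions": 0, "transversions": 0,
           "position_1": 0, "position_2": 0, "position_3": 0,
           "total": 0}
    for ch in changes:
        k = ch.n_events
        out[ch.effect] += k
        out["transitions" if ch.mutation_class == "transition"
            else "transversions"] += k
        out[f"position_{ch.nucleotide_offset}"] += k
        out["total"] += k
    return out


def divergence_polymorphism_contrast(divergence: tuple[float, float],
                                     polymorphism: tuple[float, float]
                                     ) -> dict:
    """Compare nonsynonymous proportions between species (divergence)
    and within species (polymorphism).

    Returns the two proportions (raw and rounded to whole percent) and,
    as an extension beyond the descriptive contrast, a two-sided Fisher
    exact test on the 2×2 table.
    """
    dn, ds = divergence
    pn, ps = polymorphism
    if min(dn, ds, pn, ps) < 0:
        raise ValueError("counts must be nonnegative")
    out = {"divergence_nonsyn": dn, "divergence_syn": ds,
           "polymorphism_nonsyn": pn, "polymorphism_syn": ps}
    if dn + ds == 0 or pn + ps == 0:
        out.update(undefined=True)
        return out
    div_prop = dn / (dn + ds)
    poly_prop = pn / (pn + ps)
    table = [[round(dn), round(ds)], [round(pn), round(ps)]]
    _, fisher_p = _stats.fisher_exact(table, alternative="two-sided")
    out.update(
        undefined=False,
        divergence_nonsyn_proportion=div_prop,
        polymorphism_nonsyn_proportion=poly_prop,
        divergence_nonsyn_percent=round(100 * div_prop),
        polymorphism_nonsyn_percent=round(100 * poly_prop),
        fisher_exact_p=float(fisher_p),
        fisher_note="two-sided exact test; extension beyond the "
                    "descriptive proportion contrast",
    )
    return out
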