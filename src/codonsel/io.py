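"""Readers/writers for alignments, trees and phenotype tables.

File formats
------------
* Codon alignments: FASTA of in-frame nucleotide sequences.  Gaps must
  occupy whole codons (in-frame indels); a gap that splits a codon is a
  frame error.  IUPAC-ambiguous codons are retained and flagged.
* Trees: Newick, polytomies allowed.  Branch ω-class labels use the
  ``#k`` dialect (as in codeml): an integer preceded by ``#`` appended to
  a tip name or an internal-node label marks the branch *subtending* that
  node with ω-class ``k``, e.g. ``((A#1:1,B:1)#1:1,C:2);``.  Unlabelled
  branches default to class 0.
* Phenotypes: CSV with columns species, brain_mass, body_mass,
  max_body_mass (grams).  EQ is computed when absent.
"""

from __future__ import annotations

import io as _io
import re
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codes import NUCLEOTIDES, AMBIGUOUS_DNA, STANDARD_CODE, CodonCode


class AlignmentError(ValueError):
    pass


class FrameError(AlignmentError):
    pass


class TreeError(ValueError):
    pass


GAP_CODON = "---"


@dataclass
class CodonAlignment:
    """In-frame codon matrix over taxa.

    ``codons[i][s]`` is the 3-mer of taxon ``i`` at alignment site ``s``
    (1-based site ``s+1`` in reports).  ``mask[i, s]`` is True where the
    codon is treated as missing data (gap, or masked downstream of a
    premature stop).
    """

    taxa: list[str]
    codons: list[list[str]]
    mask: np.ndarray
    genetic_code: int = 1

    def __post_init__(self):
        lengths = {len(row) for row in self.codons}
        if len(lengths) > 1:
            raise AlignmentError(f"taxa differ in codon length: {lengths}")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (len(self.taxa), self.n_sites):
            raise AlignmentError("mask shape does not match alignment")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return len(self.codons[0]) if self.codons else 0

    def taxon_index(self, name: str) -> int:
        return self.taxa.index(name)

    def is_ambiguous(self, i: int, s: int) -> bool:
        codon = self.codons[i][s]
        return any(b not in NUCLEOTIDES for b in codon) and codon != GAP_CODON

    def sequence(self, name: str) -> str:
        """Nucleotide sequence of one taxon (gaps included)."""
        return "".join(self.codons[self.taxon_index(name)])

    def subset(self, taxa: list[str]) -> "CodonAlignment":
        idx = [self.taxon_index(t) for t in taxa]
        return CodonAlignment(
            taxa=list(taxa),
            codons=[list(self.codons[i]) for i in idx],
            mask=self.mask[idx].copy(),
            genetic_code=self.genetic_code,
        )

    def drop_gapped_sites(self) -> "CodonAlignment":
        """Remove columns masked in any taxon (cleandata-style)."""
        keep = ~self.mask.any(axis=0)
        return CodonAlignment(
            taxa=list(self.taxa),
            codons=[[row[s] for s in np.flatnonzero(keep)]
                    for row in self.codons],
            mask=self.mask[:, keep].copy(),
            genetic_code=self.genetic_code,
        )


def _validate_codon(codon: str, code: CodonCode, taxon: str, site: int):
    if codon == GAP_CODON:
        return
    if "-" in codon:
        raise FrameError(
            f"{taxon}: gap splits codon {site + 1} ({codon}); "
            "indels must be whole codons"
        )
    for base in codon:
        if base not in NUCLEOTIDES and base not in AMBIGUOUS_DNA:
            raise AlignmentError(
                f"{taxon}: unrecognized symbol {base!r} at codon {site + 1}"
            )
    if all(b in NUCLEOTIDES for b in codon) and codon in code.stop_codons:
        # In-frame stop codons are tolerated at parse time; they are
        # handled by mask_after_premature_stop or rejected by the engine.
        return


def read_codon_alignment(path, frame_offset: int = 0,
                         genetic_code: int = 1) -> CodonAlignment:
    """Parse an in-frame nucleotide FASTA into a codon alignment.

    ``frame_offset`` nucleotides are trimmed from the start of every
    sequence before codon partitioning; trailing nucleotides that do not
    complete a codon raise a frame error.
    """
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise AlignmentError("no sequences in FASTA input")
    seqs = [str(r.seq).upper() for r in records]
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
    (length,) = lengths
    if (length - frame_offset) % 3 != 0:
        raise FrameError(
            f"alignment length {length} minus offset {frame_offset} "
            "is not a multiple of 3"
        )
    code = CodonCode(genetic_code) if genetic_code != 1 else STANDARD_CODE
    taxa = [r.id for r in records]
    if len(set(taxa)) != len(taxa):
        raise AlignmentError("duplicate taxon names in FASTA")
    n_sites = (length - frame_offset) // 3
    codons, mask = [], np.zeros((len(taxa), n_sites), dtype=bool)
    for i, seq in enumerate(seqs):
        row = []
        for s in range(n_sites):
            codon = seq[frame_offset + 3 * s: frame_offset + 3 * s + 3]
            _validate_codon(codon, code, taxa[i], s)
            if codon == GAP_CODON:
                mask[i, s] = True
            row.append(codon)
        codons.append(row)
    return CodonAlignment(taxa=taxa, codons=codons, mask=mask,
                          genetic_code=genetic_code)


def write_codon_alignment(aln: CodonAlignment, path) -> None:
    records = [
        SeqRecord(Seq("".join(row)), id=name, description="")
        for name, row in zip(aln.taxa, aln.codons)
    ]
    SeqIO.write(records, path, "fasta")


def mask_after_premature_stop(aln: CodonAlignment,
                              taxa) -> CodonAlignment:
    """Mask the first in-frame stop codon and everything downstream.

    Applied per named taxon (e.g. the monodontid premature stop near the
    3' end of MCPH1 exon 8); taxa without a stop are returned unchanged.
    Only unambiguous stop codons trigger masking.
    """
    taxa = list(taxa)
    missing = set(taxa) - set(aln.taxa)
    if missing:
        raise AlignmentError(f"taxa not in alignment: {sorted(missing)}")
    code = CodonCode(aln.genetic_code) if aln.genetic_code != 1 \
        else STANDARD_CODE
    mask = aln.mask.copy()
    for name in taxa:
        i = aln.taxon_index(name)
        for s, codon in enumerate(aln.codons[i]):
            if not mask[i, s] and codon in code.stop_codons:
                mask[i, s:] = True
                break
    return replace(aln, mask=mask)


# ---------------------------------------------------------------------------
# Trees

_LABEL_RE = re.compile(r"^(.*?)#(\d+)$")


@dataclass
class Phylogeny:
    """Rooted (possibly multifurcating) tree with branch lengths and
    optional integer ω-class labels on branches.

    A basal polytomy at the root stands in for an unrooted tree; the
    likelihood machinery is root-invariant for reversible models.
    """

    tree: dendropy.Tree
    name: str = "tree"

    @classmethod
    def from_newick(cls, newick_text: str, name: str = "tree") -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=newick_text, schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several parse errors
            raise TreeError(f"malformed Newick: {exc}") from exc
        tree.is_rooted = True  # basal polytomy stands in for unrootedness
        # Extract '#k' ω-class suffixes from tip / internal-node labels.
        for node in tree:
            node.omega_label = 0
            raw = node.taxon.label if node.taxon is not None else node.label
            if raw is None:
                continue
            m = _LABEL_RE.match(raw)
            if m:
                node.omega_label = int(m.group(2))
                stripped = m.group(1)
                if node.taxon is not None:
                    node.taxon.label = stripped
                else:
                    node.label = stripped or None
        phy = cls(tree=tree, name=name)
        phy.validate()
        return phy

    def validate(self):
        tips = self.tip_names()
        if len(set(tips)) != len(tips):
            raise TreeError("duplicate tip names")
        for node in self.tree:
            if node.parent_node is not None and node.edge.length is not None \
                    and node.edge.length < 0:
                raise TreeError(
                    f"negative branch length on edge above "
                    f"{node.taxon.label if node.taxon else node.label}"
                )

    def to_newick(self) -> str:
        clone = self.clone()
        for node in clone.tree:
            k = getattr(node, "omega_label", 0)
            if k:
                if node.taxon is not None:
                    node.taxon.label = f"{node.taxon.label}#{k}"
                else:
                    node.label = f"{node.label or ''}#{k}"
        return clone.tree.as_string(
            schema="newick", suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()

    def clone(self) -> "Phylogeny":
        tree = dendropy.Tree(self.tree)  # deep clone incl. taxon namespace
        for src, dst in zip(self.tree, tree):
            dst.omega_label = getattr(src, "omega_label", 0)
        return Phylogeny(tree=tree, name=self.name)

    def tip_names(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def extract(self, tips, name: str | None = None) -> "Phylogeny":
        """Subtree spanned by ``tips`` (ω labels are reset)."""
        missing = set(tips) - set(self.tip_names())
        if missing:
            raise TreeError(f"tips not in tree: {sorted(missing)}")
        sub = self.tree.extract_tree_with_taxa_labels(list(tips))
        # give the subtree its own namespace; purging the shared one
        # would corrupt the source tree
        sub.migrate_taxon_namespace(dendropy.TaxonNamespace())
        sub.is_rooted = True
        for node in sub:
            node.omega_label = 0
        return Phylogeny(tree=sub, name=name or f"{self.name}_subset")

    def n_branches(self) -> int:
        return sum(1 for n in self.tree if n.parent_node is not None)

    def mrca(self, tip_names) -> dendropy.Node:
        taxa = [t for t in self.tree.taxon_namespace
                if t.label in set(tip_names)]
        if len(taxa) != len(set(tip_names)):
            found = {t.label for t in taxa}
            raise TreeError(
                f"tips not in tree: {sorted(set(tip_names) - found)}")
        return self.tree.mrca(taxa=taxa)

    def branch_labels(self) -> dict[int, int]:
        """Map from node id (edge head) to ω-class label."""
        return {
            id(n): getattr(n, "omega_label", 0)
            for n in self.tree if n.parent_node is not None
        }

    def depths(self) -> dict[str, float]:
        """Root-to-tip path lengths (None branch lengths count as 0)."""
        out = {}
        for leaf in self.tree.leaf_node_iter():
            d, node = 0.0, leaf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            out[leaf.taxon.label] = d
        return out


def read_tree(newick_text: str, name: str = "tree") -> Phylogeny:
    return Phylogeny.from_newick(newick_text, name=name)


# ---------------------------------------------------------------------------
# Phenotypes

PHENOTYPE_COLUMNS = ("species", "brain_mass", "body_mass", "max_body_mass")


def read_phenotype_table(path, tree: Phylogeny | None = None
                         ) -> tuple[pd.DataFrame, list[str]]:
    """Load a phenotype CSV (grams), computing EQ when absent.

    Returns (table, warnings); a warning is emitted for each species
    absent from ``tree`` when a tree is supplied.
    """
    from .comparative import encephalization_quotient

    df = pd.read_csv(path)
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table lacks columns: {missing}")
    for col in PHENOTYPE_COLUMNS[1:]:
        bad = df[df[col] <= 0]
        if len(bad):
            raise ValueError(
                f"nonpositive {col} for species "
                f"{bad['species'].tolist()}"
            )
    if "EQ" not in df.columns:
        df = df.assign(
            EQ=encephalization_quotient(
                df["brain_mass"].to_numpy(), df["body_mass"].to_numpy())
        )
    warnings = []
    if tree is not None:
        tips = set(tree.tip_names())
        warnings = [
            f"species {s!r} not in tree" for s in df["species"]
            if s not in tips
        ]
    return df, warnings


def write_phenotype_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
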