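"""Genetic-code tables and codon state indexing.

The codon state space excludes stop codons: under the standard code there
are 61 sense codons, indexed alphabetically (AAA=0 ... TTT=60).  All
pairwise single-nucleotide change classifications (synonymous vs
nonsynonymous, transition vs transversion, which codon position changed)
are precomputed here once and shared by the rate-matrix, simulation and
polymorphism machinery.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from Bio.Data import CodonTable, IUPACData

NUCLEOTIDES = "ACGT"
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

# Two-base IUPAC ambiguity codes (heterozygote calls from chromatograms).
TWO_BASE_IUPAC = {
    code: frozenset(bases)
    for code, bases in IUPACData.ambiguous_dna_values.items()
    if len(bases) == 2
}
_BASES_TO_IUPAC = {bases: code for code, bases in TWO_BASE_IUPAC.items()}

# Any ambiguity code -> set of bases (includes N etc.).
AMBIGUOUS_DNA = {
    code: frozenset(bases)
    for code, bases in IUPACData.ambiguous_dna_values.items()
}


def iupac_for_pair(a: str, b: str) -> str:
    """Two-base IUPAC code for an unordered base pair, e.g. A/G -> R."""
    for bases, code in _BASES_TO_IUPAC.items():
        if bases == frozenset((a, b)):
            return code
    raise ValueError(f"no two-base IUPAC code for {a}/{b}")


def genetic_code(table_id: int = 1) -> CodonTable.CodonTable:
    return CodonTable.unambiguous_dna_by_id[table_id]


class CodonCode:
    """Indexed sense-codon state space for one genetic-code table."""

    def __init__(self, table_id: int = 1):
        table = genetic_code(table_id)
        self.table_id = table_id
        self.stop_codons = frozenset(table.stop_codons)
        self.codons = sorted(
            "".join(c) for c in product(NUCLEOTIDES, repeat=3)
            if "".join(c) not in self.stop_codons
        )
        self.n_states = len(self.codons)
        self.index = {c: i for i, c in enumerate(self.codons)}
        self.amino_acids = np.array(
            [table.forward_table["".join(c)] for c in self.codons]
        )

        n = self.n_states
        self.n_diffs = np.zeros((n, n), dtype=np.int8)
        self.is_transition = np.zeros((n, n), dtype=bool)
        self.is_synonymous = np.zeros((n, n), dtype=bool)
        self.diff_position = np.full((n, n), -1, dtype=np.int8)  # 0-based
        for i, ci in enumerate(self.codons):
            for j, cj in enumerate(self.codons):
                diffs = [k for k in range(3) if ci[k] != cj[k]]
                self.n_diffs[i, j] = len(diffs)
                if len(diffs) == 1:
                    k = diffs[0]
                    self.diff_position[i, j] = k
                    pair = {ci[k], cj[k]}
                    self.is_transition[i, j] = (
                        pair <= PURINES or pair <= PYRIMIDINES
                    )
                    self.is_synonymous[i, j] = (
                        self.amino_acids[i] == self.amino_acids[j]
                    )

    def expand_ambiguous(self, codon: str) -> list[int]:
        """Sense-codon state indices compatible with an IUPAC codon.

        Returns an empty list when every resolution is a stop codon.
        """
        choices = []
        for base in codon:
            if base in NUCLEOTIDES:
                choices.append([base])
            elif base in AMBIGUOUS_DNA:
                choices.append(sorted(AMBIGUOUS_DNA[base]))
            else:
                raise ValueError(f"unrecognized nucleotide symbol {base!r}")
        return [
            self.index[c]
            for c in ("".join(t) for t in product(*choices))
            if c in self.index
        ]

    def translate(self, codon: str) -> str:
        if codon in self.stop_codons:
            return "*"
        return str(self.amino_acids[self.index[codon]])


STANDARD_CODE = CodonCode(1)
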