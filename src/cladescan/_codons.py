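"""Genetic-code bookkeeping shared by the codon model, variation and
amino-acid-property modules.

The state space of every codon model here is the set of *sense* codons of the
chosen NCBI translation table (61 for the standard code). Plastid CDS
translate identically to the standard table over all sense codons, so table 1
is the package default; any NCBI table id can be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
GAP_CODON = "---"
PURINES = frozenset("AG")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def _is_transition(a: str, b: str) -> bool:
    return a != b and ((a in PURINES) == (b in PURINES))


@dataclass(frozen=True)
class GeneticCode:
    """Sense-codon state space of one NCBI translation table."""

    table_id: int
    codons: tuple[str, ...]
    stop_codons: frozenset[str]
    aa: tuple[str, ...]  # one-letter aa per sense codon, parallel to `codons`
    codon_index: dict[str, int] = field(repr=False)

    @property
    def n_states(self) -> int:
        return len(self.codons)

    def translate(self, codon: str) -> str:
        """Translate one codon; total over {A,C,G,T,-,N}.

        Returns ``-`` for an all-gap codon, ``*`` for a stop, ``X`` for a
        codon containing N or a partial gap, else the one-letter amino acid.
        """
        codon = codon.upper()
        if len(codon) != 3:
            raise ValueError(f"codon must have length 3, got {codon!r}")
        if codon == GAP_CODON:
            return "-"
        if any(c not in "ACGT" for c in codon):
            return "X"
        if codon in self.stop_codons:
            return "*"
        return self.aa[self.codon_index[codon]]

    def neighbors(self) -> "CodonNeighborhood":
        return _neighborhood(self.table_id)


@lru_cache(maxsize=None)
def get_genetic_code(table_id: int = 1) -> GeneticCode:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    stops = frozenset(table.stop_codons)
    codons = tuple(
        a + b + c
        for a in NUCLEOTIDES
        for b in NUCLEOTIDES
        for c in NUCLEOTIDES
        if a + b + c not in stops
    )
    aa = tuple(table.forward_table[c] for c in codons)
    index = {c: i for i, c in enumerate(codons)}
    return GeneticCode(table_id, codons, stops, aa, index)


@dataclass(frozen=True)
class CodonNeighborhood:
    """Single-nucleotide-change structure of the sense-codon graph.

    Arrays are parallel lists of ordered sense-codon pairs (i, j) differing at
    exactly one position: ``is_transition`` marks purine<->purine /
    pyrimidine<->pyrimidine changes, ``is_synonymous`` marks pairs translating
    to the same amino acid.
    """

    i: np.ndarray
    j: np.ndarray
    is_transition: np.ndarray
    is_synonymous: np.ndarray


@lru_cache(maxsize=None)
def _neighborhood(table_id: int) -> CodonNeighborhood:
    code = get_genetic_code(table_id)
    ii, jj, ts, syn = [], [], [], []
    for a, ca in enumerate(code.codons):
        for b, cb in enumerate(code.codons):
            if a == b:
                continue
            diff = [(x, y) for x, y in zip(ca, cb) if x != y]
            if len(diff) != 1:
                continue
            ii.append(a)
            jj.append(b)
            ts.append(_is_transition(*diff[0]))
            syn.append(code.aa[a] == code.aa[b])
    return CodonNeighborhood(
        np.asarray(ii), np.asarray(jj), np.asarray(ts), np.asarray(syn)
    )
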