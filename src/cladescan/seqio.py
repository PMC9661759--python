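"""Reading, writing and validation of codon alignments, trees and clade
definitions.

File formats are the field's plain-text standards: aligned FASTA (one file per
gene), Newick (single tree) and a TSV clades file with columns ``clade_name``
and ``taxa`` (comma-separated taxon labels). Parsing goes through Biopython
and dendropy; this module only adds the codon-alignment validation layer
(length divisible by 3, unique labels, internal-stop warnings) that a
selection scan needs.

Codon sites are reported 1-based in amino-acid coordinates of the gene
alignment throughout the package.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._codons import GAP_CODON, GeneticCode, get_genetic_code

logger = logging.getLogger(__name__)

ALLOWED_CHARS = frozenset("ACGTN-")

#: fallback length assigned to Newick edges lacking one (see read_tree)
DEFAULT_BRANCH_LENGTH = 0.01


def translate(codon: str, code: GeneticCode | int = 1) -> str:
    """Translate one codon over {A,C,G,T,-,N}; total function.

    ``---`` -> ``-`` (gap), stop -> ``*``, codon containing N or a partial
    gap -> ``X`` (ambiguous).
    """
    if isinstance(code, int):
        code = get_genetic_code(code)
    return code.translate(codon)


@dataclass
class CodonAlignment:
    """In-frame multiple alignment of one gene.

    The substrate of all downstream statistics: sequences are upper-case
    strings over {A,C,G,T,-,N}, all of equal length divisible by 3. Gap-only
    columns are retained (they feed indel detection).
    """

    gene_name: str
    taxa: list[str]
    sequences: dict[str, str]
    code: GeneticCode = field(default_factory=get_genetic_code, repr=False)

    def __post_init__(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise ValueError(f"duplicate taxon labels: {dupes}")
        if set(self.taxa) != set(self.sequences):
            raise ValueError("taxa and sequence keys differ")
        self.sequences = {t: s.upper() for t, s in self.sequences.items()}
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        (length,) = lengths or {0}
        if length % 3 != 0:
            raise ValueError(
                f"alignment length {length} not a multiple of 3 ({self.gene_name})"
            )
        for taxon, seq in self.sequences.items():
            bad = set(seq) - ALLOWED_CHARS
            if bad:
                raise ValueError(
                    f"illegal characters {sorted(bad)} in sequence {taxon!r}"
                )
        self._warn_internal_stops()

    def _warn_internal_stops(self) -> None:
        for taxon in self.taxa:
            aas = self.aa_sequence(taxon)
            if "*" in aas[:-1]:
                site = aas.index("*") + 1
                warnings.warn(
                    f"internal stop codon in {self.gene_name}/{taxon} "
                    f"at codon site {site}",
                    stacklevel=3,
                )

    # -- basic geometry -------------------------------------------------
    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    @property
    def n_codons(self) -> int:
        return self.length // 3

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    # -- accessors ------------------------------------------------------
    def sequence(self, taxon: str) -> str:
        return self.sequences[taxon]

    def codon(self, taxon: str, site: int) -> str:
        """Codon at 1-based amino-acid coordinate `site`."""
        if not 1 <= site <= self.n_codons:
            raise IndexError(f"codon site {site} out of range 1..{self.n_codons}")
        return self.sequences[taxon][3 * (site - 1) : 3 * site]

    def column(self, nt_site: int) -> dict[str, str]:
        """Nucleotide column at 1-based alignment coordinate."""
        if not 1 <= nt_site <= self.length:
            raise IndexError(f"column {nt_site} out of range 1..{self.length}")
        return {t: self.sequences[t][nt_site - 1] for t in self.taxa}

    def codon_column(self, site: int) -> dict[str, str]:
        return {t: self.codon(t, site) for t in self.taxa}

    def aa_sequence(self, taxon: str) -> str:
        seq = self.sequences[taxon]
        return "".join(
            self.code.translate(seq[i : i + 3]) for i in range(0, len(seq), 3)
        )

    def subset(self, taxa: list[str] | set[str]) -> "CodonAlignment":
        """Restriction to a taxon subset, preserving this alignment's order."""
        missing = set(taxa) - set(self.taxa)
        if missing:
            raise KeyError(f"unknown taxa: {sorted(missing)}")
        kept = [t for t in self.taxa if t in set(taxa)]
        return CodonAlignment(
            self.gene_name, kept, {t: self.sequences[t] for t in kept}, self.code
        )

    def codon_state_matrix(self) -> np.ndarray:
        """(n_taxa, n_codons) int matrix of sense-codon state indices.

        -1 marks missing data: gap codons, codons with N or partial gaps,
        and stop codons (excluded from the model state space).
        """
        mat = np.full((self.n_taxa, self.n_codons), -1, dtype=np.int64)
        index = self.code.codon_index
        for i, taxon in enumerate(self.taxa):
            seq = self.sequences[taxon]
            for s in range(self.n_codons):
                mat[i, s] = index.get(seq[3 * s : 3 * s + 3], -1)
        return mat

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CodonAlignment):
            return NotImplemented
        return (
            self.gene_name == other.gene_name
            and self.taxa == other.taxa
            and self.sequences == other.sequences
        )


def read_alignment(
    path, gene_name: str | None = None, code: GeneticCode | int = 1
) -> CodonAlignment:
    """Read one aligned FASTA file into a validated :class:`CodonAlignment`."""
    if isinstance(code, int):
        code = get_genetic_code(code)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    taxa = [r.id.strip() for r in records]
    seqs = {r.id.strip(): str(r.seq).upper() for r in records}
    if gene_name is None:
        gene_name = str(path).rsplit("/", 1)[-1].split(".")[0]
    return CodonAlignment(gene_name, taxa, seqs, code)


def write_alignment(aln: CodonAlignment, path) -> None:
    records = [
        SeqRecord(Seq(aln.sequences[t]), id=t, description="") for t in aln.taxa
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta-2line")


@dataclass
class PhyloTree:
    """Rooted phylogeny with branch lengths (polytomies allowed).

    Thin wrapper over a :class:`dendropy.Tree`; taxon matching against
    alignments and clade files is exact string match after whitespace
    trimming.
    """

    tree: dendropy.Tree

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def n_leaves(self) -> int:
        return len(self.tree.leaf_nodes())

    def newick(self) -> str:
        return (
            self.tree.as_string(schema="newick", suppress_rooting=True).strip()
        )

    def clone(self) -> "PhyloTree":
        return PhyloTree(self.tree.clone(depth=1))

    def mrca(self, taxa) -> dendropy.Node:
        labels = {t.strip() for t in taxa}
        missing = labels - set(self.leaf_labels)
        if missing:
            raise KeyError(f"taxa not in tree: {sorted(missing)}")
        return self.tree.mrca(taxon_labels=labels)

    def leaf_set(self, node: dendropy.Node) -> frozenset[str]:
        return frozenset(lf.taxon.label for lf in node.leaf_iter())


def _finalize_tree(tree: dendropy.Tree) -> None:
    tree.is_rooted = True  # MRCA queries need explicit rooting
    for taxon in tree.taxon_namespace:
        taxon.label = taxon.label.strip()


def _validate_lengths(tree: dendropy.Tree) -> None:
    n_defaulted = 0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            edge.length = DEFAULT_BRANCH_LENGTH
            n_defaulted += 1
        elif edge.length < 0:
            raise ValueError(f"negative branch length {edge.length}")
    if n_defaulted:
        logger.warning(
            "%d branch lengths missing; defaulted to %s",
            n_defaulted,
            DEFAULT_BRANCH_LENGTH,
        )


def read_tree(path) -> PhyloTree:
    """Read a single Newick tree; missing branch lengths default to 0.01."""
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    _finalize_tree(tree)
    _validate_lengths(tree)
    return PhyloTree(tree)


def tree_from_newick(newick: str) -> PhyloTree:
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    _finalize_tree(tree)
    _validate_lengths(tree)
    return PhyloTree(tree)


def write_tree(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.newick() + "\n")


@dataclass(frozen=True)
class CladeDefinition:
    """A named taxon set used for clade-private calls and foreground choice."""

    name: str
    taxa: frozenset[str]

    def __post_init__(self) -> None:
        if not self.taxa:
            raise ValueError(f"clade {self.name!r} has no taxa")
        object.__setattr__(
            self, "taxa", frozenset(t.strip() for t in self.taxa)
        )


def read_clades(path) -> list[CladeDefinition]:
    """Read a clades TSV with columns ``clade_name``, ``taxa`` (comma-sep)."""
    clades = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["clade_name", "taxa"]:
            raise ValueError(
                "clades file must have header columns 'clade_name'\\t'taxa'"
            )
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            name, taxa = line.split("\t")[:2]
            clades.append(
                CladeDefinition(
                    name.strip(),
                    frozenset(t.strip() for t in taxa.split(",") if t.strip()),
                )
            )
    return clades


def write_clades(clades: list[CladeDefinition], path) -> None:
    with open(path, "w") as fh:
        fh.write("clade_name\ttaxa\n")
        for clade in clades:
            fh.write(f"{clade.name}\t{','.join(sorted(clade.taxa))}\n")


def check_monophyly(
    tree: PhyloTree, clade: CladeDefinition
) -> tuple[bool, dendropy.Node]:
    """True iff the MRCA of the clade's taxa subtends exactly those taxa.

    Returns the MRCA node alongside, so callers can use it as the foreground
    root even when monophyly fails.
    """
    node = tree.mrca(clade.taxa)
    return tree.leaf_set(node) == clade.taxa, node
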