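"""Variation profiling of codon alignments: variable sites, synonymous /
nonsynonymous classification, nucleotide diversity, indels, clade-private
(diagnostic) mutation calling and the clade-specific-load gene ranking.

Conventions
-----------
* A gap-vs-base difference is an indel, never a substitution; variable-site
  and privacy calls only compare non-gap, non-ambiguous states.
* Clade privacy is unpolarized: a site is private to a clade iff every clade
  member carries a state X, no outside taxon carries X, and no clade member is
  gap/ambiguous there (strict diagnostic-character behaviour). Sites where any
  compared taxon is N are excluded from privacy calls.
* Codon sites are 1-based amino-acid coordinates of the gene alignment.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

from .seqio import CladeDefinition, CodonAlignment, PhyloTree, check_monophyly

BASES = frozenset("ACGT")


@dataclass(frozen=True)
class SubstitutionEvent:
    """One substitution at one alignment site, possibly clade-private."""

    gene: str
    codon_site: int  # 1-based aa coordinate
    nt_site: int  # 1-based alignment column
    from_state: str  # state(s) outside the carrier set ('' when mixed)
    to_state: str  # carrier state
    from_aa: str
    to_aa: str
    kind: str  # 'synonymous' | 'nonsynonymous'
    carriers: frozenset[str]
    private_to: str | None = None

    def __post_init__(self) -> None:
        if not self.carriers:
            raise ValueError("carriers must be non-empty")
        expected = "nonsynonymous" if self.from_aa != self.to_aa else "synonymous"
        if self.kind != expected:
            raise ValueError(
                f"kind {self.kind!r} inconsistent with {self.from_aa}->{self.to_aa}"
            )


@dataclass(frozen=True)
class IndelEvent:
    """A maximal run of gap columns shared by one carrier set."""

    gene: str
    start: int  # 1-based first gap column
    end: int  # 1-based last gap column (inclusive)
    length_nt: int
    carriers: frozenset[str]

    @property
    def frame_status(self) -> str:
        return "in-frame" if self.length_nt % 3 == 0 else "frameshift"


@dataclass
class GeneVariationSummary:
    """Per-gene counts mirroring a variation table row."""

    gene: str
    n_syn: int
    n_nonsyn: int
    n_clade_specific_nonsyn: int
    cds_length_nt: int
    pi: float
    indels: list[IndelEvent] = field(default_factory=list)

    @property
    def ratio(self) -> float:
        """Clade-specific nonsynonymous mutations per nt of CDS length."""
        if self.n_clade_specific_nonsyn == 0:
            return 0.0
        return self.n_clade_specific_nonsyn / self.cds_length_nt


def substitution_event_dict(ev: SubstitutionEvent) -> dict:
    """JSON-stable field mapping for one substitution event."""
    return {
        "gene": ev.gene,
        "codon_site": ev.codon_site,
        "nt_site": ev.nt_site,
        "from_state": ev.from_state,
        "to_state": ev.to_state,
        "from_aa": ev.from_aa,
        "to_aa": ev.to_aa,
        "kind": ev.kind,
        "carriers": sorted(ev.carriers),
        "private_to": ev.private_to,
    }


def indel_event_dict(ev: IndelEvent) -> dict:
    """JSON-stable field mapping for one indel event."""
    return {
        "gene": ev.gene,
        "start": ev.start,
        "end": ev.end,
        "length_nt": ev.length_nt,
        "frame_status": ev.frame_status,
        "carriers": sorted(ev.carriers),
    }


def find_variable_sites(aln: CodonAlignment) -> list[int]:
    """1-based nucleotide columns with >= 2 distinct non-gap, non-N states."""
    out = []
    for col in range(1, aln.length + 1):
        states = {b for b in aln.column(col).values() if b in BASES}
        if len(states) >= 2:
            out.append(col)
    return out


def classify_site(aln: CodonAlignment, codon_site: int) -> str:
    """Classify one codon column: invariant | synonymous | nonsynonymous | mixed.

    Taxa whose codon contains a gap or N at this site are excluded from the
    comparison. `nonsynonymous` iff >=2 distinct amino acids; `synonymous` iff
    codons differ but all translate identically; `mixed` when both synonymous
    and nonsynonymous variation co-occur (>=2 amino acids and some amino acid
    is realized by >=2 codons).
    """
    codons = [
        c
        for c in aln.codon_column(codon_site).values()
        if set(c) <= BASES
    ]
    distinct = set(codons)
    if len(distinct) <= 1:
        return "invariant"
    aas = {aln.code.translate(c) for c in distinct}
    if len(aas) == 1:
        return "synonymous"
    if len(distinct) > len(aas):
        return "mixed"
    return "nonsynonymous"


def nucleotide_diversity(aln: CodonAlignment) -> float:
    """Nei's pi: mean pairwise proportion of differing sites.

    Gapped/ambiguous positions are excluded pairwise; a pair with no
    comparable positions contributes 0.
    """
    if aln.n_taxa < 2:
        raise ValueError("nucleotide diversity needs >= 2 sequences")
    seqs = [aln.sequences[t] for t in aln.taxa]
    total = 0.0
    n_pairs = 0
    for s1, s2 in itertools.combinations(seqs, 2):
        diffs = comparable = 0
        for a, b in zip(s1, s2):
            if a in BASES and b in BASES:
                comparable += 1
                if a != b:
                    diffs += 1
        total += diffs / comparable if comparable else 0.0
        n_pairs += 1
    return total / n_pairs


def detect_indels(aln: CodonAlignment) -> list[IndelEvent]:
    """Maximal per-sequence gap runs, grouped into one event per coordinate
    span shared by its carrier set.

    Each sequence's maximal runs of ``-`` are found independently; runs with
    identical (start, end) across sequences are one event carried by all of
    them (the usual reading of a shared deletion/insertion).
    """
    runs: dict[tuple[int, int], set[str]] = {}
    for taxon in aln.taxa:
        seq = aln.sequences[taxon]
        start = None
        for col in range(1, aln.length + 2):
            gap = col <= aln.length and seq[col - 1] == "-"
            if gap and start is None:
                start = col
            elif not gap and start is not None:
                runs.setdefault((start, col - 1), set()).add(taxon)
                start = None
    return [
        IndelEvent(
            aln.gene_name, start, end, end - start + 1, frozenset(carriers)
        )
        for (start, end), carriers in sorted(runs.items())
    ]


def _column_private_state(
    column: dict[str, str], clade_taxa: frozenset[str]
) -> str | None:
    """The clade-private state of one column, or None.

    Strict diagnostic-character rule: all clade members share a non-gap,
    non-N state absent outside the clade, and no compared taxon is N.
    """
    inside = [column[t] for t in column if t in clade_taxa]
    outside = [column[t] for t in column if t not in clade_taxa]
    if any(b == "N" for b in column.values()):
        return None
    inside_states = {b for b in inside if b in BASES}
    if len(inside_states) != 1 or len(inside_states) != len(set(inside)):
        return None
    (state,) = inside_states
    if state in outside:
        return None
    return state


def clade_private_mutations(
    aln: CodonAlignment,
    tree: PhyloTree | None,
    clade: CladeDefinition,
    taxon_subset: set[str] | None = None,
) -> list[SubstitutionEvent]:
    """Clade-private (diagnostic) substitutions for one clade.

    Privacy is a character-pattern property evaluated per nucleotide column;
    a paired tree is only used to warn when the clade is not monophyletic.
    ``taxon_subset`` restricts the comparison to a sub-alignment (e.g. a
    single genus, to avoid reversions in distant outgroups).
    """
    if taxon_subset is not None:
        aln = aln.subset(taxon_subset)
    missing = clade.taxa - set(aln.taxa)
    if missing:
        raise KeyError(f"clade taxa not in alignment: {sorted(missing)}")
    if tree is not None:
        try:
            mono, _ = check_monophyly(tree, clade)
        except KeyError:
            mono = True  # clade not fully in tree; privacy is still defined
        if not mono:
            warnings.warn(
                f"clade {clade.name!r} is not monophyletic in the paired tree; "
                "privacy computed on the character pattern anyway",
                stacklevel=2,
            )
    events: list[SubstitutionEvent] = []
    for col in range(1, aln.length + 1):
        column = aln.column(col)
        state = _column_private_state(column, clade.taxa)
        if state is None:
            continue
        codon_site = (col - 1) // 3 + 1
        outside_states = {
            b for t, b in column.items() if t not in clade.taxa and b in BASES
        }
        # codon-level annotation: compare carrier codons with outside codons
        codon_col = aln.codon_column(codon_site)
        inside_codons = {codon_col[t] for t in clade.taxa}
        outside_codons = {
            codon_col[t]
            for t in aln.taxa
            if t not in clade.taxa and set(codon_col[t]) <= BASES
        }
        to_aa_set = {
            aln.code.translate(c) for c in inside_codons if set(c) <= BASES
        }
        from_aa_set = {aln.code.translate(c) for c in outside_codons}
        to_aa = to_aa_set.pop() if len(to_aa_set) == 1 else "X"
        # nonsynonymous iff the carrier amino acid is absent outside the clade
        nonsyn = to_aa not in from_aa_set if to_aa != "X" else bool(from_aa_set)
        if nonsyn:
            from_aa = from_aa_set.pop() if len(from_aa_set) == 1 else "X"
            if from_aa == to_aa:  # both ambiguous: fall back to synonymous
                nonsyn = False
        else:
            from_aa = to_aa
        events.append(
            SubstitutionEvent(
                gene=aln.gene_name,
                codon_site=codon_site,
                nt_site=col,
                from_state="/".join(sorted(outside_states)),
                to_state=state,
                from_aa=from_aa,
                to_aa=to_aa,
                kind="nonsynonymous" if nonsyn else "synonymous",
                carriers=frozenset(clade.taxa),
                private_to=clade.name,
            )
        )
    return events


def summarize_gene(
    aln: CodonAlignment,
    tree: PhyloTree | None,
    clades: list[CladeDefinition],
    taxon_subset: set[str] | None = None,
) -> GeneVariationSummary:
    """All variation-table columns for one gene.

    Synonymous / nonsynonymous counts are at amino-acid level per codon site
    (a mixed site contributes to both); the clade-specific count is the
    number of private nonsynonymous nucleotide substitutions over all clades.
    """
    n_syn = n_nonsyn = 0
    for site in range(1, aln.n_codons + 1):
        cls = classify_site(aln, site)
        if cls in ("synonymous", "mixed"):
            n_syn += 1
        if cls in ("nonsynonymous", "mixed"):
            n_nonsyn += 1
    n_private_ns = 0
    for clade in clades:
        if not clade.taxa <= set(taxon_subset or aln.taxa):
            continue
        for ev in clade_private_mutations(aln, tree, clade, taxon_subset):
            if ev.kind == "nonsynonymous":
                n_private_ns += 1
    return GeneVariationSummary(
        gene=aln.gene_name,
        n_syn=n_syn,
        n_nonsyn=n_nonsyn,
        n_clade_specific_nonsyn=n_private_ns,
        cds_length_nt=aln.length,
        pi=nucleotide_diversity(aln) if aln.n_taxa >= 2 else 0.0,
        indels=detect_indels(aln),
    )


def rank_genes(
    summaries: list[GeneVariationSummary],
    threshold: float = 0.002,
    override: list[str] | None = None,
) -> list[str]:
    """Candidate genes for selection testing, by clade-specific nonsynonymous
    load per nt, descending.

    Genes with ratio >= ``threshold`` are kept; an explicit ``override`` list
    bypasses the threshold entirely (order preserved from the ranking where
    present, appended alphabetically otherwise).
    """
    if not summaries:
        raise ValueError("no summaries to rank")
    ranked = sorted(summaries, key=lambda s: (-s.ratio, s.gene))
    if override is not None:
        chosen = set(override)
        out = [s.gene for s in ranked if s.gene in chosen]
        out.extend(sorted(chosen - set(out)))
        return out
    return [s.gene for s in ranked if s.ratio >= threshold and s.ratio > 0]
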