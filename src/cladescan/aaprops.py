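"""Detection of positive destabilizing selection at the protein level.

Amino-acid replacements are reconstructed on the tree by Fitch parsimony,
each replacement's effect on 31 structural and biochemical properties is
graded into 8 magnitude categories (1 = most conservative, 8 = most radical
possible change), and the frequency of radical changes (categories 6–8) is
compared to the neutral expectation with a one-tailed Z-test, both gene-wide
and in 15-codon sliding windows. Z > 2.33 flags 99% confidence, Z > 3.09
flags 99.9%.

Category bins are 8 equal-width intervals over the range of |Δproperty|
among amino-acid pairs reachable by a single nucleotide change, so category
8 is by construction the most radical change a point mutation can produce.
The neutral expectation is the category distribution induced by enumerating
every single-nucleotide nonsynonymous codon change, equally weighted
(a codon-frequency-weighted variant is available).

The packaged property table (``data/aa_properties_synthetic.tsv``) is a
synthetic reconstruction of the standard 31-property set: the property names
are the canonical list, the values are transcribed or approximated from the
published amino-acid-index literature. Users may substitute their own table
with the same layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np
from scipy import stats

from ._codons import AMINO_ACIDS, GeneticCode, get_genetic_code
from .seqio import CodonAlignment, PhyloTree
from .codonmodel import TreeIndex

#: one-tailed standard-normal critical values (99% and 99.9%)
Z_99 = float(stats.norm.isf(0.01))
Z_999 = float(stats.norm.isf(0.001))

RADICAL_CATEGORIES = frozenset({6, 7, 8})
N_CATEGORIES = 8
WINDOW = 15


def z_thresholds() -> tuple[float, float]:
    """One-tailed normal critical values at 0.01 and 0.001 (≈2.33, 3.09)."""
    return Z_99, Z_999


@dataclass
class PropertyTable:
    """31 named physicochemical scales over the 20 amino acids."""

    properties: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        if len(self.properties) != 31:
            raise ValueError(
                f"expected 31 properties, got {len(self.properties)}"
            )
        for name, values in self.properties.items():
            missing = set(AMINO_ACIDS) - set(values)
            if missing:
                raise ValueError(
                    f"property {name!r} missing amino acids {sorted(missing)}"
                )

    @property
    def names(self) -> list[str]:
        return list(self.properties)

    def delta(self, prop: str, a: str, b: str) -> float:
        values = self.properties[prop]
        return abs(values[a] - values[b])


def load_property_table(source=None) -> PropertyTable:
    """Load the packaged synthetic property table, or a user TSV.

    Layout: header ``property\\t<20 one-letter aa columns>``, one property
    per row.
    """
    if source is None:
        ref = resources.files("cladescan").joinpath(
            "data/aa_properties_synthetic.tsv"
        )
        text = ref.read_text()
    else:
        with open(source) as fh:
            text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    aas = header[1:]
    props: dict[str, dict[str, float]] = {}
    for line in lines[1:]:
        fields = line.split("\t")
        props[fields[0]] = {
            aa: float(v) for aa, v in zip(aas, fields[1:])
        }
    return PropertyTable(props)


# ---------------------------------------------------------------------------
# category grading
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _accessible_pairs(table_id: int = 1) -> tuple[tuple[str, str], ...]:
    """Unordered amino-acid pairs reachable by one nucleotide change."""
    nb = get_genetic_code(table_id).neighbors()
    code = get_genetic_code(table_id)
    pairs = set()
    for i, j, syn in zip(nb.i, nb.j, nb.is_synonymous):
        if not syn:
            pairs.add(tuple(sorted((code.aa[i], code.aa[j]))))
    return tuple(sorted(pairs))


def _bin_edges(table: PropertyTable, prop: str, table_id: int = 1):
    deltas = [table.delta(prop, a, b) for a, b in _accessible_pairs(table_id)]
    lo, hi = min(deltas), max(deltas)
    if hi <= lo:
        return lo, lo + 1.0  # degenerate scale: everything category 1
    return lo, hi


def categorize_change(
    from_aa: str,
    to_aa: str,
    prop: str,
    table: PropertyTable,
    table_id: int = 1,
) -> int:
    """Magnitude category 1–8 of one replacement's effect on one property."""
    if from_aa == to_aa:
        raise ValueError("not a replacement: identical amino acids")
    for aa in (from_aa, to_aa):
        if aa not in AMINO_ACIDS:
            raise KeyError(f"unknown amino acid {aa!r}")
    lo, hi = _bin_edges(table, prop, table_id)
    delta = table.delta(prop, from_aa, to_aa)
    width = (hi - lo) / N_CATEGORIES
    cat = int(np.floor((delta - lo) / width)) + 1
    return min(max(cat, 1), N_CATEGORIES)


def neutral_expectation(
    table: PropertyTable,
    code: GeneticCode | int = 1,
    codon_freqs: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Per-property category distribution under neutral point mutation.

    Enumerates every single-nucleotide nonsynonymous codon change, equally
    weighted by default; ``codon_freqs`` (over sense codons) weights each
    change by the frequency of its source codon.
    """
    if isinstance(code, int):
        code = get_genetic_code(code)
    nb = code.neighbors()
    sel = ~nb.is_synonymous
    src, dst = nb.i[sel], nb.j[sel]
    weights = (
        codon_freqs[src]
        if codon_freqs is not None
        else np.ones(len(src))
    )
    weights = weights / weights.sum()
    out: dict[str, np.ndarray] = {}
    for prop in table.names:
        dist = np.zeros(N_CATEGORIES)
        for i, j, w in zip(src, dst, weights):
            cat = categorize_change(
                code.aa[i], code.aa[j], prop, table, code.table_id
            )
            dist[cat - 1] += w
        out[prop] = dist
    return out


def count_nonsynonymous_neighbors(code: GeneticCode | int = 1) -> int:
    """Number of directed single-nt nonsynonymous codon changes."""
    if isinstance(code, int):
        code = get_genetic_code(code)
    return int((~code.neighbors().is_synonymous).sum())


# ---------------------------------------------------------------------------
# ancestral reconstruction (Fitch parsimony)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReplacementEvent:
    """One inferred amino-acid replacement on one tree edge."""

    gene: str
    codon_site: int  # 1-based
    branch: str  # smallest subtended leaf label (edge identifier)
    from_aa: str
    to_aa: str


@dataclass(frozen=True)
class PropertyChangeEvent:
    """A replacement graded against every property."""

    gene: str
    codon_site: int
    branch: str
    from_aa: str
    to_aa: str
    categories: dict[str, int] = field(hash=False)

    def category(self, prop: str) -> int:
        return self.categories[prop]

    def radical(self, prop: str) -> bool:
        return self.categories[prop] in RADICAL_CATEGORIES


@dataclass
class AncestralReconstruction:
    """Fitch states per node and the replacement events per edge."""

    node_states: np.ndarray  # (n_nodes, n_sites) int indices into AMINO_ACIDS
    state_sets: list[list[frozenset[str]]]  # ambiguity sets per node per site
    events: list[ReplacementEvent]
    parsimony_score: np.ndarray  # per site


def ancestral_aa(
    tree: PhyloTree,
    aln: CodonAlignment | dict[str, str],
    seed: int = 0,
    gene: str | None = None,
) -> AncestralReconstruction:
    """Fitch-parsimony amino-acid states and per-edge replacement events.

    Ambiguous node assignments are resolved uniformly at random under the
    given seed (top-down pass: keep the parent state when it is in the
    node's Fitch set, otherwise draw from the set). Tips with gap/ambiguous
    residues are unconstrained (full amino-acid set) and never emit events
    on their terminal edge.
    """
    if isinstance(aln, CodonAlignment):
        gene = gene or aln.gene_name
        aa_seqs = {t: aln.aa_sequence(t) for t in aln.taxa}
    else:
        gene = gene or ""
        aa_seqs = aln
    taxa = list(aa_seqs)
    n_sites = len(next(iter(aa_seqs.values())))
    ti = TreeIndex(tree, taxa)
    rng = np.random.default_rng(seed)
    full = frozenset(AMINO_ACIDS)
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}

    n = ti.n_nodes
    node_states = np.full((n, n_sites), -1, dtype=int)
    all_sets: list[list[frozenset[str]]] = [[] for _ in range(n)]
    score = np.zeros(n_sites, dtype=int)
    events: list[ReplacementEvent] = []
    unconstrained = [
        [False] * n_sites for _ in range(n)
    ]

    for site in range(n_sites):
        sets: list[frozenset[str] | None] = [None] * n
        # bottom-up
        for i in range(n):
            if ti.leaf_row[i] >= 0:
                aa = aa_seqs[taxa[ti.leaf_row[i]]][site]
                if aa in aa_index:
                    sets[i] = frozenset([aa])
                else:
                    sets[i] = full
                    unconstrained[i][site] = True
            elif ti.leaf_row[i] == -2:
                sets[i] = full
                unconstrained[i][site] = True
            else:
                child_sets = [sets[c] for c in ti.children[i]]
                inter = frozenset.intersection(*child_sets)
                if inter:
                    sets[i] = inter
                else:
                    sets[i] = frozenset.union(*child_sets)
                    score[site] += 1
        # top-down with seeded resolution
        for i in reversed(range(n)):
            s = sets[i]
            if i == ti.root:
                choice = (
                    sorted(s)[int(rng.integers(len(s)))] if len(s) > 1
                    else next(iter(s))
                )
            else:
                parent_aa = AMINO_ACIDS[node_states[ti.parent[i], site]]
                if parent_aa in s:
                    choice = parent_aa
                else:
                    choice = (
                        sorted(s)[int(rng.integers(len(s)))]
                        if len(s) > 1
                        else next(iter(s))
                    )
            node_states[i, site] = aa_index[choice]
        for i in range(n):
            all_sets[i].append(sets[i])
        for i in range(n):
            if i == ti.root or unconstrained[i][site]:
                continue
            parent_state = node_states[ti.parent[i], site]
            if node_states[i, site] != parent_state:
                branch = min(ti.leaf_sets[i]) if ti.leaf_sets[i] else str(i)
                events.append(
                    ReplacementEvent(
                        gene=gene,
                        codon_site=site + 1,
                        branch=branch,
                        from_aa=AMINO_ACIDS[parent_state],
                        to_aa=AMINO_ACIDS[node_states[i, site]],
                    )
                )
    return AncestralReconstruction(node_states, all_sets, events, score)


def grade_events(
    events: list[ReplacementEvent],
    table: PropertyTable,
    table_id: int = 1,
) -> list[PropertyChangeEvent]:
    """Attach per-property magnitude categories to replacement events."""
    out = []
    for ev in events:
        cats = {
            prop: categorize_change(ev.from_aa, ev.to_aa, prop, table, table_id)
            for prop in table.names
        }
        out.append(
            PropertyChangeEvent(
                ev.gene, ev.codon_site, ev.branch, ev.from_aa, ev.to_aa, cats
            )
        )
    return out


# ---------------------------------------------------------------------------
# Z-test
# ---------------------------------------------------------------------------

def z_test(
    events: list[PropertyChangeEvent],
    expectation: dict[str, np.ndarray],
    prop: str,
    category_group: frozenset[int] = RADICAL_CATEGORIES,
) -> float:
    """One-tailed Z for excess of radical changes on one property.

    z = (obs − n·p̂) / sqrt(n·p̂(1−p̂)) where p̂ is the neutral probability
    of the radical category group and obs counts events falling in it.
    """
    n = len(events)
    if n == 0:
        raise ValueError("z_test needs at least one event")
    p_hat = float(
        sum(expectation[prop][c - 1] for c in category_group)
    )
    if not 0.0 < p_hat < 1.0:
        return 0.0
    obs = sum(1 for ev in events if ev.categories[prop] in category_group)
    return float((obs - n * p_hat) / np.sqrt(n * p_hat * (1.0 - p_hat)))


@dataclass
class WindowZProfile:
    """Z-scores of one 15-codon window, per property."""

    gene: str
    window_start: int  # 1-based codon
    window_length: int
    z: dict[str, float]
    n_events: int

    def significant_99(self, prop: str) -> bool:
        return self.z[prop] > Z_99

    def significant_999(self, prop: str) -> bool:
        return self.z[prop] > Z_999


def sliding_window_scan(
    events: list[PropertyChangeEvent],
    gene_length: int,
    expectation: dict[str, np.ndarray],
    window: int = WINDOW,
    step: int = 1,
    properties: list[str] | None = None,
) -> list[WindowZProfile]:
    """Z profiles over full sliding windows (codon coordinates).

    Windows with no events score z = 0 on every property (no evidence).
    """
    if gene_length < window:
        raise ValueError(
            f"gene length {gene_length} shorter than window {window}"
        )
    properties = properties or list(expectation)
    gene = events[0].gene if events else ""
    profiles = []
    for start in range(1, gene_length - window + 2, step):
        inside = [
            ev for ev in events if start <= ev.codon_site < start + window
        ]
        if inside:
            zs = {
                prop: z_test(inside, expectation, prop) for prop in properties
            }
        else:
            zs = {prop: 0.0 for prop in properties}
        profiles.append(
            WindowZProfile(gene, start, window, zs, len(inside))
        )
    return profiles
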