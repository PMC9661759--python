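"""Seed-deterministic synthetic data: random trees, codon alignments evolved
under any supported ω-structure, and planted clade-diagnostic substitutions
and indels.

This is the generative twin of the likelihood in :mod:`cladescan.codonmodel`:
site classes are drawn from the mixture, the root codon from the equilibrium
frequencies, and each branch applies exp(Q_k t) with the same mixture-rate
scaling the likelihood uses, so parameters simulated here are recoverable by
``CodonModel.fit`` on the same scale. Stop codons are never emitted (the
state space is the sense codons). Indels are planted, not evolved.

One global RNG stream is keyed by the seed; per-operation substreams are
derived by stable hashing of operation names, so adding operations never
perturbs existing fixtures.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from ._codons import get_genetic_code
from .codonmodel import (
    CodonModelSpec,
    ReversibleMatrix,
    TreeIndex,
    _pack_natural,
    _unscaled_rate_matrix,
    edge_partitions,
    mean_rate,
    uniform_freqs,
    _FORMS,
)
from .seqio import (
    CladeDefinition,
    CodonAlignment,
    PhyloTree,
    check_monophyly,
    write_alignment,
    write_clades,
    write_tree,
)


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent RNG substream for one named operation under one seed."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


def random_tree(
    n_taxa: int,
    seed: int,
    mean_branch_length: float = 0.05,
    taxon_prefix: str = "s",
) -> PhyloTree:
    """Yule (pure-birth) topology with iid exponential branch lengths.

    Branch lengths are in expected substitutions per codon (default mean
    0.05); the tree is not ultrametric.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    rng = substream(seed, "random_tree")
    taxa = [f"{taxon_prefix}{i + 1}" for i in range(n_taxa)]
    ns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.is_rooted = True
    # Yule process: start with two lineages, split a uniformly chosen tip
    tips = []
    for label in taxa[:2]:
        child = dendropy.Node()
        child.taxon = ns.get_taxon(label)
        tree.seed_node.add_child(child)
        tips.append(child)
    for label in taxa[2:]:
        split = tips[int(rng.integers(len(tips)))]
        left = dendropy.Node()
        left.taxon = split.taxon
        right = dendropy.Node()
        right.taxon = ns.get_taxon(label)
        split.taxon = None
        split.add_child(left)
        split.add_child(right)
        tips.remove(split)
        tips.extend([left, right])
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        edge.length = float(rng.exponential(mean_branch_length))
    return PhyloTree(tree)


@dataclass(frozen=True)
class PlantedDiagnostic:
    """Request/record of one clade-diagnostic substitution."""

    codon_site: int  # 1-based; the realized site may differ if re-drawn
    clade: str
    from_aa: str = ""
    to_aa: str = ""
    nt_site: int = 0  # realized alignment column (record only)


@dataclass
class SimulationConfig:
    """Everything one simulation needs; the seed is mandatory."""

    seed: int
    n_codons: int
    tree: PhyloTree | None = None
    n_taxa: int = 8
    spec: CodonModelSpec | str = "M0"
    params: dict = field(default_factory=lambda: {"omega": 0.2, "kappa": 2.0})
    codon_freqs: np.ndarray | None = None  # default uniform over sense codons
    gene_name: str = "simulated"
    mean_branch_length: float = 0.05
    planted_events: list[PlantedDiagnostic] = field(default_factory=list)
    planted_indels: list[tuple[int, int, frozenset[str]]] = field(
        default_factory=list
    )
    clades: list[CladeDefinition] = field(default_factory=list)


@dataclass
class SimulationResult:
    alignment: CodonAlignment
    tree: PhyloTree
    site_classes: np.ndarray  # generating mixture class per codon site
    planted_events: list[PlantedDiagnostic]
    config: SimulationConfig


def _class_structure(spec: CodonModelSpec, params: dict, n_partitions: int):
    form = _FORMS[spec.model_id](spec, n_partitions)
    tail = np.asarray(_pack_natural(form, params))
    weights, omegas, _ = form.unpack(tail)
    return weights, omegas


def simulate_alignment(config: SimulationConfig) -> SimulationResult:
    """Evolve one codon alignment under the configured ω-structure."""
    code = get_genetic_code(
        config.spec.code_table
        if isinstance(config.spec, CodonModelSpec)
        else 1
    )
    spec = (
        config.spec
        if isinstance(config.spec, CodonModelSpec)
        else CodonModelSpec(config.spec)
    )
    tree = config.tree or random_tree(
        config.n_taxa, config.seed, config.mean_branch_length
    )
    pi = (
        np.asarray(config.codon_freqs, dtype=float)
        if config.codon_freqs is not None
        else uniform_freqs(code)
    )
    pi = pi / pi.sum()
    taxa = tree.leaf_labels
    tindex = TreeIndex(tree, taxa)
    part = (
        edge_partitions(tindex, spec.clades)
        if spec.clades
        else np.zeros(tindex.n_nodes, dtype=int)
    )
    n_partitions = int(part.max()) + 1
    weights, omegas = _class_structure(spec, config.params, n_partitions)
    if omegas.shape[1] != n_partitions:
        omegas = np.repeat(omegas[:, :1], n_partitions, axis=1)
    kappa = config.params.get("kappa", 2.0)

    # same mixture-rate scaling as the likelihood engine
    mats: dict[float, ReversibleMatrix] = {}
    rates: dict[float, float] = {}
    for w in np.unique(omegas):
        Q = _unscaled_rate_matrix(kappa, float(w), pi, code)
        mats[float(w)] = ReversibleMatrix(Q, pi)
        rates[float(w)] = mean_rate(Q, pi)
    scale = max(
        sum(w * rates[float(omegas[k, 0])] for k, w in enumerate(weights)),
        1e-12,
    )

    rng = substream(config.seed, "simulate_alignment")
    n_sites = config.n_codons
    site_class = rng.choice(len(weights), size=n_sites, p=weights)
    states = np.empty((tindex.n_nodes, n_sites), dtype=np.int64)
    states[tindex.root] = rng.choice(code.n_states, size=n_sites, p=pi)
    for i in reversed(range(tindex.n_nodes)):  # preorder = reverse postorder
        if i == tindex.root:
            continue
        parent = int(tindex.parent[i])
        t = tindex.edge_length[i] / scale
        for k in range(len(weights)):
            sel = site_class == k
            if not sel.any():
                continue
            P = mats[float(omegas[k, part[i]])].transition(t)
            probs = P[states[parent, sel]]
            probs /= probs.sum(axis=1, keepdims=True)
            u = rng.random(sel.sum())
            states[i, sel] = (u[:, None] > probs.cumsum(axis=1)).sum(axis=1)

    sequences = {}
    for i in range(tindex.n_nodes):
        if tindex.leaf_row[i] >= 0:
            label = taxa[tindex.leaf_row[i]]
            sequences[label] = "".join(code.codons[s] for s in states[i])
    aln = CodonAlignment(config.gene_name, list(taxa), sequences, code)

    planted: list[PlantedDiagnostic] = []
    if config.planted_events:
        clade_map = {c.name: c for c in config.clades}
        aln, planted = plant_clade_diagnostics(
            aln,
            tree,
            [
                (ev.codon_site, clade_map[ev.clade], ev.to_aa or None)
                for ev in config.planted_events
            ],
            config.seed,
        )
    if config.planted_indels:
        aln = plant_indels(aln, config.planted_indels)
    return SimulationResult(aln, tree, site_class, planted, config)


def plant_clade_diagnostics(
    aln: CodonAlignment,
    tree: PhyloTree,
    events: list[tuple[int, CladeDefinition, str | None]],
    seed: int,
) -> tuple[CodonAlignment, list[PlantedDiagnostic]]:
    """Plant clade-private substitutions; returns the new alignment and the
    realized ground truth.

    Each event sets every clade member to a derived codon differing from the
    clade's current codon at exactly one nucleotide whose derived state is
    absent outside the clade. If no such codon exists at the requested site,
    another site is drawn (and recorded in the returned truth). Planting into
    a non-monophyletic taxon set is an error.
    """
    rng = substream(seed, "plant_clade_diagnostics")
    code = aln.code
    seqs = {t: list(aln.sequences[t]) for t in aln.taxa}
    realized: list[PlantedDiagnostic] = []
    used_sites: set[int] = set()

    for codon_site, clade, to_aa in events:
        mono, _ = check_monophyly(tree, clade)
        if not mono:
            raise ValueError(f"clade {clade.name!r} is not monophyletic")
        outside = [t for t in aln.taxa if t not in clade.taxa]
        site = codon_site
        candidates_at: list[tuple[int, str, str, int]] = []
        tried = 0
        order = [site] + [
            s
            for s in rng.permutation(np.arange(1, aln.n_codons + 1)).tolist()
            if s != site
        ]
        for s in order:
            if s in used_sites:
                continue
            tried += 1
            base = "".join(seqs[next(iter(clade.taxa))][3 * (s - 1) : 3 * s])
            if set(base) - set("ACGT"):
                continue
            base_aa = code.translate(base)
            cands = []
            for pos in range(3):
                outside_states = {
                    seqs[t][3 * (s - 1) + pos] for t in outside
                }
                for nt in "ACGT":
                    if nt == base[pos] or nt in outside_states:
                        continue
                    derived = base[:pos] + nt + base[pos + 1 :]
                    if derived in code.stop_codons:
                        continue
                    d_aa = code.translate(derived)
                    if d_aa == base_aa:
                        continue
                    if to_aa is not None and d_aa != to_aa:
                        continue
                    cands.append((s, derived, d_aa, pos))
            if cands:
                candidates_at = cands
                break
        if not candidates_at:
            raise ValueError(
                f"no plantable site for clade {clade.name!r} "
                f"(requested site {codon_site})"
            )
        s, derived, d_aa, pos = candidates_at[
            int(rng.integers(len(candidates_at)))
        ]
        base = "".join(seqs[next(iter(clade.taxa))][3 * (s - 1) : 3 * s])
        for t in clade.taxa:
            seqs[t][3 * (s - 1) : 3 * s] = list(derived)
        used_sites.add(s)
        realized.append(
            PlantedDiagnostic(
                codon_site=s,
                clade=clade.name,
                from_aa=code.translate(base),
                to_aa=d_aa,
                nt_site=3 * (s - 1) + pos + 1,
            )
        )
    new_aln = CodonAlignment(
        aln.gene_name, list(aln.taxa), {t: "".join(s) for t, s in seqs.items()},
        code,
    )
    return new_aln, realized


def plant_indels(
    aln: CodonAlignment, indels: list[tuple[int, int, frozenset[str]]]
) -> CodonAlignment:
    """Gap out (start_nt_column, length_nt, carriers) stretches."""
    seqs = {t: list(aln.sequences[t]) for t in aln.taxa}
    for start, length, carriers in indels:
        if not 1 <= start <= aln.length - length + 1:
            raise ValueError(f"indel at {start} (+{length}) out of range")
        for t in carriers:
            if t not in seqs:
                raise KeyError(f"unknown carrier {t!r}")
            seqs[t][start - 1 : start - 1 + length] = ["-"] * length
    return CodonAlignment(
        aln.gene_name,
        list(aln.taxa),
        {t: "".join(s) for t, s in seqs.items()},
        aln.code,
    )


def emit_bundle(result: SimulationResult, outdir) -> dict[str, str]:
    """Write FASTA + Newick + clades TSV + ground-truth JSON for one run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gene = result.alignment.gene_name
    paths = {
        "fasta": str(outdir / f"{gene}.fasta"),
        "tree": str(outdir / "tree.nwk"),
        "clades": str(outdir / "clades.tsv"),
        "truth": str(outdir / f"{gene}.truth.json"),
    }
    write_alignment(result.alignment, paths["fasta"])
    write_tree(result.tree, paths["tree"])
    write_clades(result.config.clades, paths["clades"])
    truth = {
        "gene": gene,
        "seed": result.config.seed,
        "site_classes": result.site_classes.tolist(),
        "planted_events": [
            {
                "codon_site": ev.codon_site,
                "nt_site": ev.nt_site,
                "clade": ev.clade,
                "from_aa": ev.from_aa,
                "to_aa": ev.to_aa,
            }
            for ev in result.planted_events
        ],
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2)
    return paths
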