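"""End-to-end selection scan: variation profiling → gene ranking → selection
tests (site / branch-site / clade models) → amino-acid property Z-test →
per-site rate profiles, with TSV/JSON report export.

A gene is marked "verified" per method in the cross-method summary matrix
under these conventions:

* Site Model — any of M1a-vs-M2a / M7-vs-M8 significant at α with at least
  one BEB site at posterior ≥ 0.95;
* Branch-site Model — Model A LRT p < α on any tested foreground clade;
* Clade Model — CmC vs M2a_rel p < α;
* Z-test — any property's radical-change z > 2.33 (99% one-tailed).

Raw p-values are reported (no multiple-testing gate); a Benjamini–Hochberg
q-value column is emitted for reference only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import aaprops, rates, selection, variation
from .codonmodel import SITE_MODELS
from .seqio import (
    CladeDefinition,
    CodonAlignment,
    PhyloTree,
    read_alignment,
    read_clades,
    read_tree,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one full analysis needs."""

    gene_alignments: dict[str, str]  # gene -> FASTA path
    tree_path: str
    clades_path: str
    output_dir: str = "cladescan_out"
    taxon_subset: list[str] | None = None
    ranking_threshold: float = 0.002
    gene_override: list[str] | None = None
    site_models: tuple[str, ...] = SITE_MODELS
    run_branch_site: bool = True
    run_clade_model: bool = True
    run_z_test: bool = True
    run_rates: bool = True
    alpha: float = 0.05
    seed: int = 0
    n_rate_classes: int = 4

    def __post_init__(self) -> None:
        if self.ranking_threshold < 0:
            raise ValueError("ranking threshold must be >= 0")


@dataclass
class GeneResults:
    gene: str
    summary: variation.GeneVariationSummary
    alignment: CodonAlignment | None = None
    private_events: list[variation.SubstitutionEvent] = field(
        default_factory=list
    )
    site_scan: selection.SiteModelScan | None = None
    branch_site: list[selection.BranchSiteResult] = field(default_factory=list)
    clade_model: selection.CladeModelResult | None = None
    z_events: list[aaprops.PropertyChangeEvent] = field(default_factory=list)
    z_global: dict[str, float] = field(default_factory=dict)
    z_windows: list[aaprops.WindowZProfile] = field(default_factory=list)
    rate_profile: rates.RateProfile | None = None
    errors: dict[str, str] = field(default_factory=dict)


@dataclass
class ReportBundle:
    config: RunConfig
    variation_table: pd.DataFrame
    candidates: list[str]
    genes: dict[str, GeneResults]
    summary_matrix: pd.DataFrame
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.failures and not any(
            g.errors for g in self.genes.values()
        )


def _load_inputs(config: RunConfig):
    tree = read_tree(config.tree_path)
    clades = read_clades(config.clades_path)
    alignments = {
        gene: read_alignment(path, gene_name=gene)
        for gene, path in sorted(config.gene_alignments.items())
    }
    return tree, clades, alignments


def _indel_text(summary: variation.GeneVariationSummary) -> str:
    return ";".join(
        f"{ev.start}-{ev.end}({ev.frame_status})" for ev in summary.indels
    )


def variation_table(
    alignments: dict[str, CodonAlignment],
    tree: PhyloTree,
    clades: list[CladeDefinition],
    taxon_subset: list[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, variation.GeneVariationSummary]]:
    """Per-gene variation summary table (8 documented columns)."""
    subset = set(taxon_subset) if taxon_subset else None
    summaries = {}
    rows = []
    for gene, aln in alignments.items():
        s = variation.summarize_gene(aln, tree, clades, subset)
        summaries[gene] = s
        rows.append(
            {
                "gene": gene,
                "n_syn": s.n_syn,
                "n_nonsyn": s.n_nonsyn,
                "n_clade_specific_nonsyn": s.n_clade_specific_nonsyn,
                "indels": _indel_text(s),
                "cds_length_nt": s.cds_length_nt,
                "clade_specific_per_length": round(s.ratio, 5),
                "pi": round(s.pi, 6),
            }
        )
    return pd.DataFrame(rows), summaries


def _verified_site(scan: selection.SiteModelScan | None, alpha: float) -> bool:
    if scan is None:
        return False
    significant = any(
        r.p_value < alpha
        for r in scan.lrts
        if r.comparison in ("M1a vs M2a", "M7 vs M8")
    )
    return significant and bool(scan.significant_sites(0.95))


def run_full_analysis(config: RunConfig) -> ReportBundle:
    """Execute the whole scan; per-gene failures are isolated."""
    tree, clades, alignments = _load_inputs(config)
    var_df, summaries = variation_table(
        alignments, tree, clades, config.taxon_subset
    )
    candidates = variation.rank_genes(
        list(summaries.values()),
        threshold=config.ranking_threshold,
        override=config.gene_override,
    )
    if not candidates:
        logger.warning(
            "no candidate genes at threshold %s; selection stage skipped",
            config.ranking_threshold,
        )
    table = (
        aaprops.load_property_table() if config.run_z_test else None
    )
    expectation = (
        aaprops.neutral_expectation(table) if table is not None else None
    )

    genes: dict[str, GeneResults] = {}
    failures: dict[str, str] = {}
    for gene in candidates:
        aln = alignments[gene]
        res = GeneResults(gene=gene, summary=summaries[gene], alignment=aln)
        usable_clades = [
            c for c in clades if c.taxa <= set(aln.taxa)
        ]
        subset = set(config.taxon_subset) if config.taxon_subset else None
        for clade in usable_clades:
            if subset is not None and not clade.taxa <= subset:
                continue
            res.private_events.extend(
                variation.clade_private_mutations(aln, tree, clade, subset)
            )
        try:
            if config.site_models:
                res.site_scan = selection.site_model_scan(
                    aln, tree, models=config.site_models, alpha=config.alpha
                )
            if config.run_branch_site:
                for clade in usable_clades:
                    try:
                        res.branch_site.append(
                            selection.branch_site_test(aln, tree, clade)
                        )
                    except Exception as exc:
                        res.errors[f"branch_site:{clade.name}"] = str(exc)
            if config.run_clade_model and usable_clades:
                try:
                    res.clade_model = selection.clade_model_test(
                        aln, tree, usable_clades
                    )
                except Exception as exc:
                    res.errors["clade_model"] = str(exc)
            if config.run_z_test:
                rec = aaprops.ancestral_aa(tree, aln, seed=config.seed)
                res.z_events = aaprops.grade_events(rec.events, table)
                if res.z_events:
                    res.z_global = {
                        prop: aaprops.z_test(res.z_events, expectation, prop)
                        for prop in table.names
                    }
                if aln.n_codons >= aaprops.WINDOW:
                    res.z_windows = aaprops.sliding_window_scan(
                        res.z_events, aln.n_codons, expectation
                    )
            if config.run_rates:
                res.rate_profile = rates.assign_site_rates(
                    aln, tree, n_classes=config.n_rate_classes
                )
        except Exception as exc:
            failures[gene] = str(exc)
            logger.exception("gene %s failed", gene)
        genes[gene] = res

    matrix_rows = []
    for gene, res in genes.items():
        matrix_rows.append(
            {
                "gene": gene,
                "site_model": _verified_site(res.site_scan, config.alpha),
                "branch_site_model": any(
                    b.lrt.p_value < config.alpha for b in res.branch_site
                ),
                "clade_model": (
                    res.clade_model is not None
                    and res.clade_model.lrt.p_value < config.alpha
                ),
                "z_test": any(
                    z > aaprops.Z_99 for z in res.z_global.values()
                ),
            }
        )
    summary_matrix = pd.DataFrame(
        matrix_rows,
        columns=["gene", "site_model", "branch_site_model", "clade_model",
                 "z_test"],
    )
    return ReportBundle(
        config=config,
        variation_table=var_df,
        candidates=candidates,
        genes=genes,
        summary_matrix=summary_matrix,
        failures=failures,
    )


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def _lrt_rows(bundle: ReportBundle) -> pd.DataFrame:
    rows = []
    for gene, res in bundle.genes.items():
        if res.site_scan:
            for r in res.site_scan.lrts:
                rows.append(
                    dict(gene=gene, test="site", comparison=r.comparison,
                         foreground="", two_delta_lnl=round(r.two_delta_lnl, 5),
                         df=r.df, p_value=round(r.p_value, 6))
                )
        for b in res.branch_site:
            rows.append(
                dict(gene=gene, test="branch_site",
                     comparison=b.lrt.comparison, foreground=b.foreground,
                     two_delta_lnl=round(b.lrt.two_delta_lnl, 5),
                     df=b.lrt.df, p_value=round(b.lrt.p_value, 6))
            )
        if res.clade_model:
            c = res.clade_model
            rows.append(
                dict(gene=gene, test="clade_model",
                     comparison=c.lrt.comparison,
                     foreground=",".join(c.foreground),
                     two_delta_lnl=round(c.lrt.two_delta_lnl, 5),
                     df=c.lrt.df, p_value=round(c.lrt.p_value, 6))
            )
    df = pd.DataFrame(
        rows,
        columns=["gene", "test", "comparison", "foreground",
                 "two_delta_lnl", "df", "p_value"],
    )
    if len(df):
        df["q_value"] = [
            round(q, 6) for q in selection.bh_qvalues(df["p_value"].tolist())
        ]
    else:
        df["q_value"] = []
    return df


def _aa_states(aln: CodonAlignment | None, site: int):
    """Minority vs majority amino acid at one codon site, with carriers."""
    if aln is None:
        return "", "", ""
    counts: dict[str, list[str]] = {}
    for taxon in aln.taxa:
        aa = aln.code.translate(aln.codon(taxon, site))
        if aa in "-X*":
            continue
        counts.setdefault(aa, []).append(taxon)
    if len(counts) < 2:
        only = next(iter(counts), "")
        return only, only, ""
    ordered = sorted(counts.items(), key=lambda kv: (len(kv[1]), kv[0]))
    selected = "/".join(aa for aa, _ in ordered[:-1])
    alternative = ordered[-1][0]
    carriers = ",".join(
        sorted(t for aa, taxa in ordered[:-1] for t in taxa)
    )
    return selected, alternative, carriers


def _site_rows(bundle: ReportBundle, pp_min: float = 0.95) -> pd.DataFrame:
    rows = []
    for gene, res in bundle.genes.items():
        sources = []
        if res.site_scan:
            sources.append(("site", res.site_scan.site_posteriors))
        for b in res.branch_site:
            sources.append((f"branch_site:{b.foreground}", b.site_posteriors))
        if res.clade_model:
            sources.append(("clade_model", res.clade_model.site_posteriors))
        for label, sites in sources:
            for s in sites:
                if s.pp_positive >= pp_min:
                    selected, alternative, carriers = _aa_states(
                        res.alignment, s.codon_site
                    )
                    rows.append(
                        dict(gene=gene, test=label, codon_site=s.codon_site,
                             aa_selected=selected,
                             aa_alternative=alternative,
                             carrier_taxa=carriers,
                             pp_positive=round(s.pp_positive, 4),
                             flag=s.flag, method=s.method)
                    )
    return pd.DataFrame(
        rows,
        columns=["gene", "test", "codon_site", "aa_selected",
                 "aa_alternative", "carrier_taxa", "pp_positive", "flag",
                 "method"],
    )


def _z_rows(bundle: ReportBundle) -> pd.DataFrame:
    rows = []
    for gene, res in bundle.genes.items():
        for prop, z in sorted(res.z_global.items()):
            stars = (
                "***" if z > aaprops.Z_999 else "*" if z > aaprops.Z_99 else ""
            )
            rows.append(
                dict(gene=gene, property=prop, z=round(z, 4), flag=stars)
            )
    return pd.DataFrame(rows, columns=["gene", "property", "z", "flag"])


def export_reports(bundle: ReportBundle, fmt: str = "tsv") -> list[str]:
    """Write the report bundle under the configured output directory.

    TSV tables have stable column order; the JSON mirror carries the same
    content keyed by table name.
    """
    outdir = Path(bundle.config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = {
        "variation": bundle.variation_table,
        "lrt": _lrt_rows(bundle),
        "selected_sites": _site_rows(bundle),
        "z_test": _z_rows(bundle),
        "summary_matrix": bundle.summary_matrix,
    }
    written = []
    if fmt == "tsv":
        for name, df in tables.items():
            path = outdir / f"{name}.tsv"
            df.to_csv(path, sep="\t", index=False)
            written.append(str(path))
        for gene, res in bundle.genes.items():
            if res.rate_profile is not None:
                path = outdir / f"{gene}.rates.tsv"
                pd.DataFrame(
                    res.rate_profile.to_rows(),
                    columns=["column", "rate_class", "class_rate"],
                ).to_csv(path, sep="\t", index=False)
                written.append(str(path))
            if res.z_windows:
                path = outdir / f"{gene}.zwindows.tsv"
                rows = [
                    {"window_start": w.window_start, "n_events": w.n_events,
                     **{p: round(z, 4) for p, z in sorted(w.z.items())}}
                    for w in res.z_windows
                ]
                pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
                written.append(str(path))
    elif fmt == "json":
        payload = {
            name: df.to_dict(orient="records") for name, df in tables.items()
        }
        payload["candidates"] = bundle.candidates
        payload["clade_private_events"] = {
            gene: [
                variation.substitution_event_dict(ev)
                for ev in res.private_events
            ]
            for gene, res in bundle.genes.items()
        }
        payload["indel_events"] = {
            gene: [
                variation.indel_event_dict(ev) for ev in res.summary.indels
            ]
            for gene, res in bundle.genes.items()
        }
        path = outdir / "report.json"
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=str)
        written.append(str(path))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return written
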