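"""Likelihood-ratio tests for positive selection and empirical-Bayes site
identification.

Three test families, all nested-model chi-square LRTs on
:class:`~cladescan.codonmodel.CodonModel` fits:

* site models — M0 vs M3 (df 4), M1a vs M2a (df 2), M7 vs M8 (df 2),
  M8a vs M8 (df 1): ω varies among sites, not branches;
* branch-site — Model A vs Model A null (df 1): an extra ω2≥1 class on
  designated foreground branches (the null fixes ω2 = 1). The null
  distribution used is plain χ²₁, which is conservative at the ω2 = 1
  boundary; this is deliberate and configurable by the caller interpreting
  the p-value;
* clade model — CmC vs M2a_rel (df = number of branch partitions − 1): one
  site class whose ω diverges among clade partitions.

Positively selected sites are localized by empirical Bayes: NEB plugs the
MLEs into Bayes' rule; BEB integrates over a uniform grid prior on the
mixture parameters (10 points per dimension, the canonical grids: class
proportions on the (i+0.5)/10 lattice, ω0 on (0,1) bin midpoints, positive ω
on (1,11) bin midpoints) with κ, codon frequencies and branch lengths fixed
at their MLEs. Sites are flagged * / ** / *** at posterior probability
0.95 / 0.99 / 0.999.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .codonmodel import (
    CodonModel,
    CodonModelResults,
    CodonModelSpec,
    SITE_MODELS,
)
from .seqio import CladeDefinition, CodonAlignment, PhyloTree

_CLAMP = 1e-6
_LOG_FLOOR = 1e-300

SITE_MODEL_COMPARISONS = (
    ("M0", "M3", 4),
    ("M1a", "M2a", 2),
    ("M7", "M8", 2),
    ("M8a", "M8", 1),
)


@dataclass(frozen=True)
class LRTResult:
    """One nested-model likelihood-ratio test."""

    gene: str
    comparison: str
    two_delta_lnl: float
    df: int
    p_value: float


@dataclass(frozen=True)
class SitePosterior:
    """Per-site posterior over ω classes, with the positive-class summary."""

    gene: str
    codon_site: int  # 1-based aa coordinate
    class_posteriors: tuple[float, ...]
    pp_positive: float
    method: str  # 'BEB' | 'NEB'

    @property
    def flag(self) -> str:
        if self.pp_positive >= 0.999:
            return "***"
        if self.pp_positive >= 0.99:
            return "**"
        if self.pp_positive >= 0.95:
            return "*"
        return ""


def lrt(lnl_null: float, lnl_alt: float, df: int, gene: str = "",
        comparison: str = "") -> LRTResult:
    """Chi-square LRT; 2ΔlnL clamped at 0 for optimizer noise below 1e-6."""
    if df < 1:
        raise ValueError("df must be >= 1")
    two_delta = 2.0 * (lnl_alt - lnl_null)
    if two_delta < 0:
        if two_delta < -_CLAMP:
            raise ValueError(
                f"alternative log-likelihood below null by {-two_delta / 2:g}"
                " — fits are inconsistent"
            )
        two_delta = 0.0
    p = float(stats.chi2.sf(two_delta, df))
    return LRTResult(gene, comparison, two_delta, df, p)


# ---------------------------------------------------------------------------
# empirical Bayes site identification
# ---------------------------------------------------------------------------

_GRID10 = (np.arange(10) + 0.5) / 10.0  # proportions and ω0 ∈ (0,1)
_OMEGA_POS_GRID = 1.0 + 10.0 * _GRID10  # ω ∈ (1,11) bin midpoints


def _triangle_grid() -> list[tuple[float, float]]:
    return [
        (p0, p1)
        for p0, p1 in itertools.product(_GRID10, _GRID10)
        if p0 + p1 < 1.0 + 1e-12
    ]


def _grid_average(
    sl: np.ndarray,
    weight_rows: np.ndarray,
    positive_mask: np.ndarray,
    class_col_groups: list[np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior-averaged per-class and positive-class site probabilities.

    ``sl``: (n_cols, n_sites) log-likelihood of each grid ω-column;
    ``weight_rows``: (n_cells, n_cols) mixture weights of each grid cell;
    ``positive_mask``: (n_cols,) columns belonging to the ω>1 class;
    ``class_col_groups``: per model class, the columns realizing it.
    """
    shift = sl.max(axis=0, keepdims=True)
    lin = np.exp(sl - shift)  # (n_cols, n_sites)
    mix = weight_rows @ lin  # (n_cells, n_sites)
    np.maximum(mix, _LOG_FLOOR, out=mix)
    cell_ll = np.log(mix).sum(axis=1)
    cell_post = np.exp(cell_ll - cell_ll.max())
    cell_post /= cell_post.sum()

    pos = (weight_rows * positive_mask) @ lin
    pp_positive = cell_post @ (pos / mix)

    class_pp = []
    for cols in class_col_groups:
        mask = np.zeros(sl.shape[0])
        mask[cols] = 1.0
        num = (weight_rows * mask) @ lin
        class_pp.append(cell_post @ (num / mix))
    return np.array(class_pp).T, pp_positive


def _site_posteriors_from_arrays(
    gene: str, class_pp: np.ndarray, pp_pos: np.ndarray, method: str
) -> list[SitePosterior]:
    out = []
    for site in range(class_pp.shape[0]):
        row = class_pp[site]
        row = row / row.sum() if row.sum() > 0 else row
        out.append(
            SitePosterior(
                gene=gene,
                codon_site=site + 1,
                class_posteriors=tuple(float(v) for v in row),
                pp_positive=float(pp_pos[site]),
                method=method,
            )
        )
    return out


def _beb_m2a(fit: CodonModelResults) -> list[SitePosterior]:
    model = fit.model
    engine = model.engine
    lengths = model.base_lengths * fit.branch_multiplier
    scale = engine.mixture_scale(fit.kappa, fit.class_omegas, fit.class_weights)
    omegas = np.concatenate([_GRID10, [1.0], _OMEGA_POS_GRID])
    sl = engine.class_site_loglik(
        fit.kappa, omegas[:, None], lengths, scale=scale
    )
    cells = []
    for (p0, p1), i0, i2 in itertools.product(
        _triangle_grid(), range(10), range(10)
    ):
        w = np.zeros(21)
        w[i0] = p0
        w[10] = p1
        w[11 + i2] = 1.0 - p0 - p1
        cells.append(w)
    weight_rows = np.array(cells)
    positive = np.zeros(21)
    positive[11:] = 1.0
    groups = [np.arange(10), np.array([10]), np.arange(11, 21)]
    class_pp, pp = _grid_average(sl, weight_rows, positive, groups)
    return _site_posteriors_from_arrays(
        model.aln.gene_name, class_pp, pp, "BEB"
    )


def _beb_m8(fit: CodonModelResults) -> list[SitePosterior]:
    from .codonmodel import discretize_beta

    model = fit.model
    engine = model.engine
    lengths = model.base_lengths * fit.branch_multiplier
    scale = engine.mixture_scale(fit.kappa, fit.class_omegas, fit.class_weights)
    K = fit.spec.n_beta_categories
    betas = discretize_beta(fit.params["p"], fit.params["q"], K)
    omegas = np.concatenate([betas, _OMEGA_POS_GRID])
    sl = engine.class_site_loglik(
        fit.kappa, omegas[:, None], lengths, scale=scale
    )
    cells = []
    for p0, i_ws in itertools.product(_GRID10, range(10)):
        w = np.zeros(K + 10)
        w[:K] = p0 / K
        w[K + i_ws] = 1.0 - p0
        cells.append(w)
    weight_rows = np.array(cells)
    positive = np.zeros(K + 10)
    positive[K:] = 1.0
    groups = [np.arange(K), np.arange(K, K + 10)]
    class_pp, pp = _grid_average(sl, weight_rows, positive, groups)
    return _site_posteriors_from_arrays(
        model.aln.gene_name, class_pp, pp, "BEB"
    )


def _beb_model_a(fit: CodonModelResults) -> list[SitePosterior]:
    model = fit.model
    engine = model.engine
    lengths = model.base_lengths * fit.branch_multiplier
    scale = engine.mixture_scale(fit.kappa, fit.class_omegas, fit.class_weights)
    # ω-columns: shared ω0 (10) | shared 1 (1) | (ω0, ω2) (100) | (1, ω2) (10)
    cols = [[w0, w0] for w0 in _GRID10]
    cols.append([1.0, 1.0])
    for w0, w2 in itertools.product(_GRID10, _OMEGA_POS_GRID):
        cols.append([w0, w2])
    for w2 in _OMEGA_POS_GRID:
        cols.append([1.0, w2])
    sl = engine.class_site_loglik(
        fit.kappa, np.array(cols), lengths, scale=scale
    )
    n_cols = len(cols)
    cells = []
    for (p0, p1), i0, i2 in itertools.product(
        _triangle_grid(), range(10), range(10)
    ):
        p2 = 1.0 - p0 - p1
        rest = max(p0 + p1, 1e-12)
        w = np.zeros(n_cols)
        w[i0] = p0
        w[10] = p1
        w[11 + i0 * 10 + i2] = p2 * p0 / rest
        w[111 + i2] = p2 * p1 / rest
        cells.append(w)
    weight_rows = np.array(cells)
    positive = np.zeros(n_cols)
    positive[11:] = 1.0  # classes 2a and 2b (foreground ω2)
    groups = [
        np.arange(10),
        np.array([10]),
        np.arange(11, 111),
        np.arange(111, n_cols),
    ]
    class_pp, pp = _grid_average(sl, weight_rows, positive, groups)
    return _site_posteriors_from_arrays(
        model.aln.gene_name, class_pp, pp, "BEB"
    )


def _neb(fit: CodonModelResults, positive_classes: list[int]) -> list[SitePosterior]:
    post = fit.site_class_posteriors()
    any_positive = any(
        (fit.class_omegas[k] > 1.0 + 1e-9).any() for k in positive_classes
    )
    pp = post[:, positive_classes].sum(axis=1) if any_positive else np.zeros(
        post.shape[0]
    )
    return _site_posteriors_from_arrays(
        fit.model.aln.gene_name, post, pp, "NEB"
    )


def _positive_classes(fit: CodonModelResults) -> list[int]:
    return [
        k
        for k in range(len(fit.class_weights))
        if (fit.class_omegas[k] > 1.0 + 1e-9).any()
    ]


def empirical_bayes_sites(
    fit: CodonModelResults, method: str = "BEB"
) -> list[SitePosterior]:
    """Per-site posterior probabilities of the positive-selection class.

    BEB is available for M2a, M8 and ModelA (grid prior on the mixture
    parameters); NEB (plug-in) serves every mixture model with a positive
    class, including CmC where BEB is not canonically defined.
    """
    mid = fit.spec.model_id
    has_positive_structure = mid in ("M2a", "M8", "ModelA", "CmC", "M2a_rel")
    if not has_positive_structure:
        raise ValueError(f"model {mid} has no positive-selection class")
    if method == "BEB":
        if mid == "M2a":
            return _beb_m2a(fit)
        if mid == "M8":
            return _beb_m8(fit)
        if mid == "ModelA":
            return _beb_model_a(fit)
        method = "NEB"  # CmC and relatives: plug-in fallback
    if mid in ("M2a", "M8", "M2a_rel"):
        pos = _positive_classes(fit)
    elif mid == "ModelA":
        pos = [2, 3]
        pos = [k for k in pos if (fit.class_omegas[k] > 1.0 + 1e-9).any()]
    else:  # CmC: the divergent class, when any partition ω exceeds 1
        pos = [2] if (fit.class_omegas[2] > 1.0 + 1e-9).any() else []
    return _neb(fit, pos)


# ---------------------------------------------------------------------------
# test drivers
# ---------------------------------------------------------------------------

def _nested_init(
    null_fit: CodonModelResults, alt_model_id: str, n_partitions: int = 2
) -> dict:
    """Natural-scale parameters of the alternative at the null's optimum."""
    p = dict(null_fit.params)
    p["kappa"] = null_fit.kappa
    p["branch_multiplier"] = null_fit.branch_multiplier
    eps = 1e-7
    if alt_model_id == "M3":  # from M0
        w = p.pop("omega")
        p.update(p0=1 / 3, p1=1 / 3, omega0=w, omega1=w, omega2=w)
    elif alt_model_id == "M2a" and "p1" not in p:  # from M1a
        p0 = p["p0"]
        p.update(p0=p0 * (1 - eps), p1=(1 - p0) * (1 - eps), omega2=1 + eps)
    elif alt_model_id == "M8":
        p.setdefault("p0", 1 - eps)
        p["p0"] = min(p["p0"], 1 - eps)
        if p.get("omega_s", 1.0) <= 1.0:
            p["omega_s"] = 1 + eps
    elif alt_model_id == "ModelA":
        if p.get("omega2", 1.0) <= 1.0:
            p["omega2"] = 1 + eps
    elif alt_model_id == "CmC":
        w2 = p.pop("omega2")
        # one divergent ω per partition, all at the null's shared value
        for i in range(n_partitions):
            p[f"omega_div{i}"] = w2
    return p


def _guard_nested(
    null_fit: CodonModelResults, alt_fit: CodonModelResults
) -> CodonModelResults:
    """Enforce sup-over-alternative >= null for nested pairs.

    Every null here sits in the closure of its alternative's parameter space
    (the boundary embedding: zero weight or ω = 1 on the extra class), so
    when optimizer round-off leaves the alternative a hair below the null,
    the boundary point is the better alternative fit and its log-likelihood
    equals the null's. Gaps beyond 0.01 lnL are genuine failures and are
    left for the LRT to reject."""
    if null_fit.lnL - 0.01 < alt_fit.lnL < null_fit.lnL:
        return dataclasses.replace(alt_fit, lnL=null_fit.lnL)
    return alt_fit


def _fit_pair(
    aln: CodonAlignment,
    tree: PhyloTree,
    null_spec: CodonModelSpec,
    alt_spec: CodonModelSpec,
) -> tuple[CodonModelResults, CodonModelResults]:
    """Fit a nested pair; the alternative is additionally warm-started from
    the null and refitted if it lands below it."""
    null_fit = CodonModel(aln, tree, null_spec).fit()
    alt_model = CodonModel(aln, tree, alt_spec)
    init = _nested_init(
        null_fit, alt_spec.model_id, alt_model.engine.n_partitions
    )
    alt_fit = alt_model.fit(init=init)
    if alt_fit.lnL < null_fit.lnL - _CLAMP:
        retry = alt_model.fit(init=init, maxiter=2000)
        if retry.lnL > alt_fit.lnL:
            alt_fit = retry
    return null_fit, _guard_nested(null_fit, alt_fit)


@dataclass
class SiteModelScan:
    """All site-model fits, LRTs and (when warranted) BEB site posteriors."""

    gene: str
    fits: dict[str, CodonModelResults]
    lrts: list[LRTResult]
    site_posteriors: list[SitePosterior] = field(default_factory=list)
    failures: dict[str, str] = field(default_factory=dict)

    def lrt(self, comparison: str) -> LRTResult | None:
        for r in self.lrts:
            if r.comparison == comparison:
                return r
        return None

    def significant_sites(self, pp: float = 0.95) -> list[SitePosterior]:
        return [s for s in self.site_posteriors if s.pp_positive >= pp]


def site_model_scan(
    aln: CodonAlignment,
    tree: PhyloTree,
    models: tuple[str, ...] = SITE_MODELS,
    alpha: float = 0.05,
    spec_kwargs: dict | None = None,
) -> SiteModelScan:
    """Fit the site-model series and run the standard LRT ladder.

    BEB sites are reported from M8 when M7-vs-M8 is significant, else from
    M2a when M1a-vs-M2a is significant.
    """
    spec_kwargs = spec_kwargs or {}
    fits: dict[str, CodonModelResults] = {}
    failures: dict[str, str] = {}
    for mid in models:
        try:
            model = CodonModel(aln, tree, CodonModelSpec(mid, **spec_kwargs))
            fits[mid] = model.fit()
        except Exception as exc:  # isolate per-model failures, keep scanning
            failures[mid] = str(exc)
    lrts: list[LRTResult] = []
    for null_id, alt_id, df in SITE_MODEL_COMPARISONS:
        if null_id not in fits or alt_id not in fits:
            continue
        null_fit, alt_fit = fits[null_id], fits[alt_id]
        if alt_fit.lnL < null_fit.lnL:
            model = CodonModel(
                aln, tree, CodonModelSpec(alt_id, **spec_kwargs)
            )
            refit = model.fit(init=_nested_init(null_fit, alt_id))
            if refit.lnL > alt_fit.lnL:
                fits[alt_id] = alt_fit = refit
            fits[alt_id] = alt_fit = _guard_nested(null_fit, alt_fit)
        lrts.append(
            lrt(
                null_fit.lnL,
                alt_fit.lnL,
                df,
                gene=aln.gene_name,
                comparison=f"{null_id} vs {alt_id}",
            )
        )
    posteriors: list[SitePosterior] = []
    m7m8 = next((r for r in lrts if r.comparison == "M7 vs M8"), None)
    m1m2 = next((r for r in lrts if r.comparison == "M1a vs M2a"), None)
    if m7m8 is not None and m7m8.p_value < alpha and "M8" in fits:
        posteriors = empirical_bayes_sites(fits["M8"])
    elif m1m2 is not None and m1m2.p_value < alpha and "M2a" in fits:
        posteriors = empirical_bayes_sites(fits["M2a"])
    return SiteModelScan(aln.gene_name, fits, lrts, posteriors, failures)


@dataclass
class BranchSiteResult:
    gene: str
    foreground: str
    lrt: LRTResult
    null_fit: CodonModelResults
    alt_fit: CodonModelResults
    site_posteriors: list[SitePosterior]


def branch_site_test(
    aln: CodonAlignment,
    tree: PhyloTree,
    foreground: CladeDefinition,
    spec_kwargs: dict | None = None,
) -> BranchSiteResult:
    """Model A vs Model A null on the given foreground clade (df 1)."""
    spec_kwargs = spec_kwargs or {}
    null_spec = CodonModelSpec(
        "ModelA_null", foreground=foreground, **spec_kwargs
    )
    alt_spec = CodonModelSpec("ModelA", foreground=foreground, **spec_kwargs)
    null_fit, alt_fit = _fit_pair(aln, tree, null_spec, alt_spec)
    result = lrt(
        null_fit.lnL,
        alt_fit.lnL,
        1,
        gene=aln.gene_name,
        comparison="ModelA vs ModelA_null",
    )
    sites = empirical_bayes_sites(alt_fit)
    return BranchSiteResult(
        aln.gene_name, foreground.name, result, null_fit, alt_fit, sites
    )


@dataclass
class CladeModelResult:
    gene: str
    foreground: tuple[str, ...]
    lrt: LRTResult
    null_fit: CodonModelResults
    alt_fit: CodonModelResults
    site_posteriors: list[SitePosterior]


def clade_model_test(
    aln: CodonAlignment,
    tree: PhyloTree,
    clade_partition: list[CladeDefinition],
    spec_kwargs: dict | None = None,
) -> CladeModelResult:
    """CmC vs M2a_rel over background + the given clade partitions.

    df = number of branch partitions − 1 (the extra divergent-class ω's).
    """
    spec_kwargs = spec_kwargs or {}
    parts = tuple(clade_partition)
    null_spec = CodonModelSpec("M2a_rel", partitions=parts, **spec_kwargs)
    alt_spec = CodonModelSpec("CmC", partitions=parts, **spec_kwargs)
    null_fit, alt_fit = _fit_pair(aln, tree, null_spec, alt_spec)
    n_partitions = alt_fit.model.engine.n_partitions
    result = lrt(
        null_fit.lnL,
        alt_fit.lnL,
        max(n_partitions - 1, 1),
        gene=aln.gene_name,
        comparison="CmC vs M2a_rel",
    )
    sites = empirical_bayes_sites(alt_fit, method="NEB")
    return CladeModelResult(
        aln.gene_name,
        tuple(c.name for c in clade_partition),
        result,
        null_fit,
        alt_fit,
        sites,
    )


def bh_qvalues(pvalues: list[float]) -> list[float]:
    """Benjamini–Hochberg q-values (reporting aid; never gates output)."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p)
    q = np.empty(n)
    running = 1.0
    for rank in range(n - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * n / (rank + 1))
        q[i] = running
    return q.tolist()
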