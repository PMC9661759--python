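"""Per-site nucleotide substitution-rate classes under a GTR model.

``GTRModel.fit`` estimates the five relative exchangeabilities (G<->T fixed
at 1), empirical base frequencies and a branch-length multiplier by maximum
likelihood. ``assign_site_rates`` then fits a general discrete rate
distribution (default 4 free rates with free weights) on top of the fixed
GTR parameters and assigns each alignment column its empirical-Bayes most
probable rate class (MAP; ties broken toward the lower class). The result is
a plottable per-site rate-class track.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .codonmodel import ReversibleMatrix, TreeIndex, _sigmoid
from .seqio import CodonAlignment, PhyloTree

_BASES = "ACGT"
_PAIRS = (("A", "C"), ("A", "G"), ("A", "T"), ("C", "G"), ("C", "T"), ("G", "T"))
_LOG_FLOOR = 1e-300


def _nt_matrix(aln: CodonAlignment) -> np.ndarray:
    """(n_taxa, n_columns) nucleotide state indices; -1 = gap/ambiguous."""
    lookup = {b: i for i, b in enumerate(_BASES)}
    mat = np.full((aln.n_taxa, aln.length), -1, dtype=np.int64)
    for i, taxon in enumerate(aln.taxa):
        for j, base in enumerate(aln.sequences[taxon]):
            mat[i, j] = lookup.get(base, -1)
    return mat


def gtr_rate_matrix(
    exchangeabilities: np.ndarray, freqs: np.ndarray, scale: bool = True
) -> np.ndarray:
    """4×4 GTR generator from 6 exchangeabilities (order AC,AG,AT,CG,CT,GT)."""
    Q = np.zeros((4, 4))
    idx = {b: i for i, b in enumerate(_BASES)}
    for s, (a, b) in zip(exchangeabilities, _PAIRS):
        Q[idx[a], idx[b]] = s * freqs[idx[b]]
        Q[idx[b], idx[a]] = s * freqs[idx[a]]
    Q[np.diag_indices(4)] = -Q.sum(axis=1)
    if scale:
        Q /= max(-(freqs * np.diag(Q)).sum(), 1e-12)
    return Q


class _NucEngine:
    """Felsenstein pruning on the nucleotide view of an alignment."""

    def __init__(self, aln: CodonAlignment, tree: PhyloTree):
        self.tindex = TreeIndex(tree, aln.taxa)
        self.tips = _nt_matrix(aln)
        self.n_sites = aln.length
        counts = np.bincount(self.tips[self.tips >= 0].ravel(), minlength=4)
        total = counts.sum()
        self.freqs = (
            counts / total if total else np.full(4, 0.25)
        )
        self.freqs = np.maximum(self.freqs, 1e-6)
        self.freqs /= self.freqs.sum()

    def site_loglik(
        self, Q: np.ndarray, edge_lengths: np.ndarray
    ) -> np.ndarray:
        ti = self.tindex
        mat = ReversibleMatrix(Q, self.freqs)
        Pm = {
            i: mat.transition(edge_lengths[i])
            for i in range(ti.n_nodes)
            if i != ti.root
        }
        partials: dict[int, np.ndarray] = {}
        logscale = np.zeros(self.n_sites)
        for i in range(ti.n_nodes):
            if ti.leaf_row[i] != -1:
                continue
            part = np.ones((self.n_sites, 4))
            for c in ti.children[i]:
                P = Pm[c]
                if ti.leaf_row[c] == -1:
                    msg = partials.pop(c) @ P.T
                elif ti.leaf_row[c] == -2:
                    continue
                else:
                    states = self.tips[ti.leaf_row[c]]
                    msg = P.T[np.maximum(states, 0)]
                    msg[states < 0] = 1.0
                part *= msg
            m = np.maximum(part.max(axis=1), _LOG_FLOOR)
            part /= m[:, None]
            logscale += np.log(m)
            partials[i] = part
        lik = np.maximum(partials[ti.root] @ self.freqs, _LOG_FLOOR)
        return np.log(lik) + logscale


@dataclass
class GTRResults:
    """Fitted GTR parameters and diagnostics."""

    exchangeabilities: dict[str, float]  # AC..GT, GT == 1
    freqs: np.ndarray
    branch_multiplier: float
    lnL: float
    converged: bool
    degenerate: bool
    model: "GTRModel" = field(repr=False)

    @property
    def rates(self) -> np.ndarray:
        return np.array(
            [self.exchangeabilities[a + b] for a, b in _PAIRS]
        )

    def summary(self) -> str:
        lines = [
            "GTR model fit",
            "=" * 40,
            f"{'log-likelihood':<24}{self.lnL:>14.4f}",
            f"{'branch multiplier':<24}{self.branch_multiplier:>14.4f}",
            f"{'converged':<24}{str(self.converged):>14}",
            f"{'degenerate':<24}{str(self.degenerate):>14}",
            "-" * 40,
        ]
        for a, b in _PAIRS:
            lines.append(
                f"{'s(' + a + b + ')':<24}"
                f"{self.exchangeabilities[a + b]:>14.4f}"
            )
        for base, f in zip(_BASES, self.freqs):
            lines.append(f"{'pi(' + base + ')':<24}{f:>14.4f}")
        return "\n".join(lines)


class GTRModel:
    """GTR likelihood problem on the nucleotide view of one gene."""

    def __init__(self, aln: CodonAlignment, tree: PhyloTree):
        self.aln = aln
        self.tree = tree
        self.engine = _NucEngine(aln, tree)
        self.base_lengths = self.engine.tindex.edge_length.copy()

    def _negloglik(self, x: np.ndarray) -> float:
        rates = np.concatenate([np.exp(x[:5]), [1.0]])
        mult = math.exp(x[5])
        Q = gtr_rate_matrix(rates, self.engine.freqs)
        val = -self.engine.site_loglik(Q, self.base_lengths * mult).sum()
        return val if np.isfinite(val) else 1e12

    def fit(self) -> GTRResults:
        degenerate = not (
            np.array(
                [len(set(col[col >= 0])) for col in self.engine.tips.T]
            )
            > 1
        ).any()
        x0 = np.zeros(6)
        res = optimize.minimize(
            self._negloglik,
            x0,
            method="L-BFGS-B",
            bounds=[(-8.0, 8.0)] * 6,
            options={"ftol": 1e-10, "gtol": 1e-7, "maxiter": 500},
        )
        rates = np.concatenate([np.exp(res.x[:5]), [1.0]])
        return GTRResults(
            exchangeabilities={
                a + b: float(r) for (a, b), r in zip(_PAIRS, rates)
            },
            freqs=self.engine.freqs,
            branch_multiplier=float(math.exp(res.x[5])),
            lnL=float(-res.fun),
            converged=bool(res.success),
            degenerate=degenerate,
            model=self,
        )


def fit_gtr(aln: CodonAlignment, tree: PhyloTree) -> GTRResults:
    return GTRModel(aln, tree).fit()


@dataclass
class RateProfile:
    """Per-site rate classes of one gene."""

    gene: str
    n_classes: int
    class_rates: np.ndarray  # strictly increasing
    class_weights: np.ndarray
    per_site_class: np.ndarray  # 1-based class index per nucleotide column
    posteriors: np.ndarray  # (n_sites, n_classes)
    lnL: float
    shape: float | None = None  # gamma shape when gamma-derived (unused here)

    def to_rows(self) -> list[tuple[int, int, float]]:
        return [
            (i + 1, int(c), float(self.class_rates[c - 1]))
            for i, c in enumerate(self.per_site_class)
        ]


def assign_site_rates(
    aln: CodonAlignment,
    tree: PhyloTree,
    gtr: GTRResults | None = None,
    n_classes: int = 4,
) -> RateProfile:
    """Fit a general discrete rate distribution and MAP-assign each site.

    Rates and weights are free parameters fitted by ML with the GTR
    exchangeabilities, frequencies and branch multiplier held at their MLEs;
    classes are reported sorted by increasing rate and ties in the posterior
    break toward the lower class.
    """
    if gtr is None:
        gtr = fit_gtr(aln, tree)
    engine = gtr.model.engine
    lengths = gtr.model.base_lengths * gtr.branch_multiplier
    Q = gtr_rate_matrix(gtr.rates, engine.freqs)

    def site_logliks(log_rates: np.ndarray) -> np.ndarray:
        return np.stack(
            [
                engine.site_loglik(Q, lengths * math.exp(lr))
                for lr in log_rates
            ]
        )

    def unpack(x):
        log_rates = x[:n_classes]
        w = np.ones(n_classes)
        rest = 1.0
        for k in range(n_classes - 1):
            frac = float(_sigmoid(x[n_classes + k]))
            w[k] = rest * frac
            rest *= 1 - frac
        w[-1] = rest
        return log_rates, w

    def negloglik(x):
        log_rates, w = unpack(x)
        sl = site_logliks(log_rates)
        val = -float(
            special.logsumexp(
                sl + np.log(np.maximum(w, _LOG_FLOOR))[:, None], axis=0
            ).sum()
        )
        return val if np.isfinite(val) else 1e12

    x0 = np.concatenate(
        [
            np.linspace(math.log(0.05), math.log(3.0), n_classes),
            np.zeros(n_classes - 1),
        ]
    )
    res = optimize.minimize(
        negloglik,
        x0,
        method="L-BFGS-B",
        bounds=[(-10.0, 5.0)] * n_classes + [(-8.0, 8.0)] * (n_classes - 1),
        options={"ftol": 1e-10, "gtol": 1e-7, "maxiter": 500},
    )
    log_rates, w = unpack(res.x)
    order = np.argsort(log_rates, kind="stable")
    rates = np.exp(log_rates)[order]
    w = w[order]
    sl = site_logliks(np.log(rates))
    joint = sl + np.log(np.maximum(w, _LOG_FLOOR))[:, None]
    joint -= special.logsumexp(joint, axis=0, keepdims=True)
    post = np.exp(joint).T  # (n_sites, K)
    per_site = post.argmax(axis=1) + 1  # argmax takes the first (lower) tie
    return RateProfile(
        gene=aln.gene_name,
        n_classes=n_classes,
        class_rates=rates,
        class_weights=w,
        per_site_class=per_site,
        posteriors=post,
        lnL=float(-res.fun),
    )
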