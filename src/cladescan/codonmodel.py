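"""Codon substitution models (GY94 family) and maximum-likelihood fitting.

The model core of the package. A :class:`CodonModel` is built from a codon
alignment, a rooted tree with branch lengths and a :class:`CodonModelSpec`
naming one of the supported ω-structures:

========  =====================================================================
M0        one ω for all sites and branches
M1a       nearly neutral: (p0, ω0<1), (p1, ω=1)
M2a       M1a + a positive-selection class (p2, ω2>1)
M3        discrete, K=3 free ω classes
M7        beta-distributed ω on (0,1), 10 equal-probability categories
M8        M7 + a positive-selection class (p1, ωs>=1)
M8a       M8 with ωs fixed at 1
ModelA    branch-site: foreground branches get an extra ω2>=1 class
ModelA_null  ModelA with ω2 fixed at 1
CmC       clade model C: one site class with a separate ω per branch partition
M2a_rel   null for CmC: the divergent class shares a single free ω
========  =====================================================================

Substitution rates follow the Goldman–Yang parameterization: a change between
sense codons i and j differing at one nucleotide has rate π_j (synonymous
transversion), κπ_j (synonymous transition), ωπ_j (nonsynonymous transversion)
or ωκπ_j (nonsynonymous transition); multi-nucleotide changes have rate 0.
Likelihoods are computed by Felsenstein pruning with per-node scaling; site
classes mix at the site level. ``fit`` maximizes the likelihood by bounded
L-BFGS over transformed parameters from a deterministic multi-start grid, so
refits are reproducible to numerical precision.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, special, stats

from ._codons import GeneticCode, get_genetic_code
from .seqio import CladeDefinition, CodonAlignment, PhyloTree

SITE_MODELS = ("M0", "M1a", "M2a", "M3", "M7", "M8", "M8a")
ALL_MODELS = SITE_MODELS + ("ModelA", "ModelA_null", "CmC", "M2a_rel")

_FREQ_FLOOR = 1e-8
_LOG_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# codon frequencies
# ---------------------------------------------------------------------------

def _nt_counts(aln: CodonAlignment, by_position: bool) -> np.ndarray:
    shape = (3, 4) if by_position else (1, 4)
    counts = np.zeros(shape)
    lookup = {b: i for i, b in enumerate("ACGT")}
    for taxon in aln.taxa:
        seq = aln.sequences[taxon]
        for pos, base in enumerate(seq):
            if base in lookup:
                counts[pos % 3 if by_position else 0, lookup[base]] += 1
    return counts


def _freqs_from_nt(nt_freqs: np.ndarray, code: GeneticCode) -> np.ndarray:
    lookup = {b: i for i, b in enumerate("ACGT")}
    pi = np.array(
        [
            math.prod(
                nt_freqs[min(pos, nt_freqs.shape[0] - 1), lookup[base]]
                for pos, base in enumerate(codon)
            )
            for codon in code.codons
        ]
    )
    pi = np.maximum(pi, _FREQ_FLOOR)
    return pi / pi.sum()


def f3x4(aln: CodonAlignment) -> np.ndarray:
    """Position-specific nucleotide-product codon frequencies (F3×4).

    Stop codons are excluded and the result renormalized over sense codons.
    """
    counts = _nt_counts(aln, by_position=True)
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return _freqs_from_nt(counts / totals, aln.code)


def f1x4(aln: CodonAlignment) -> np.ndarray:
    counts = _nt_counts(aln, by_position=False)
    total = counts.sum()
    return _freqs_from_nt(counts / (total or 1.0), aln.code)


def f61(aln: CodonAlignment) -> np.ndarray:
    """Empirical sense-codon frequencies."""
    code = aln.code
    counts = np.zeros(code.n_states)
    mat = aln.codon_state_matrix()
    for s in mat.ravel():
        if s >= 0:
            counts[s] += 1
    counts = np.maximum(counts, _FREQ_FLOOR)
    return counts / counts.sum()


def uniform_freqs(code: GeneticCode) -> np.ndarray:
    return np.full(code.n_states, 1.0 / code.n_states)


def codon_frequencies(aln: CodonAlignment, mode: str = "F3x4") -> np.ndarray:
    mode = mode.lower()
    if mode == "f3x4":
        return f3x4(aln)
    if mode == "f1x4":
        return f1x4(aln)
    if mode == "f61":
        return f61(aln)
    if mode == "uniform":
        return uniform_freqs(aln.code)
    raise ValueError(f"unknown codon frequency mode {mode!r}")


# ---------------------------------------------------------------------------
# rate matrix
# ---------------------------------------------------------------------------

def _unscaled_rate_matrix(
    kappa: float, omega: float, pi: np.ndarray, code: GeneticCode
) -> np.ndarray:
    nb = code.neighbors()
    n = code.n_states
    Q = np.zeros((n, n))
    rate = np.where(nb.is_transition, kappa, 1.0) * np.where(
        nb.is_synonymous, 1.0, omega
    )
    Q[nb.i, nb.j] = rate * pi[nb.j]
    Q[np.diag_indices(n)] = -Q.sum(axis=1)
    return Q


def mean_rate(Q: np.ndarray, pi: np.ndarray) -> float:
    """Expected substitutions per codon per unit time, -Σ π_i q_ii."""
    return float(-(pi * np.diag(Q)).sum())


def build_rate_matrix(
    kappa: float,
    omega: float,
    codon_freqs: np.ndarray,
    code: GeneticCode | int = 1,
    scale: bool = True,
) -> np.ndarray:
    """GY94 instantaneous rate matrix over sense codons.

    By default scaled so the mean rate at equilibrium is one substitution per
    codon per unit time.
    """
    if isinstance(code, int):
        code = get_genetic_code(code)
    pi = np.asarray(codon_freqs, dtype=float)
    if pi.shape != (code.n_states,):
        raise ValueError(f"expected {code.n_states} codon frequencies")
    if abs(pi.sum() - 1.0) > 1e-8 or (pi < 0).any():
        raise ValueError("codon frequencies must be non-negative and sum to 1")
    Q = _unscaled_rate_matrix(kappa, omega, pi, code)
    if scale:
        Q = Q / mean_rate(Q, pi)
    return Q


class ReversibleMatrix:
    """Eigendecomposition of a reversible rate matrix for fast exp(Qt).

    With D = diag(π), B = D^{1/2} Q D^{-1/2} is symmetric; P(t) =
    D^{-1/2} V exp(Λt) Vᵀ D^{1/2} from B = V Λ Vᵀ.
    """

    def __init__(self, Q: np.ndarray | None, pi: np.ndarray):
        if Q is None:
            return  # filled by from_batch
        d = np.sqrt(np.maximum(pi, _FREQ_FLOOR))
        B = (Q * d[:, None]) / d[None, :]
        B = 0.5 * (B + B.T)  # symmetrize against round-off
        lam, V = np.linalg.eigh(B)
        self.lam = lam
        self.left = V / d[:, None]  # D^-1/2 V
        self.right = V.T * d[None, :]  # V^T D^1/2

    @classmethod
    def from_batch(
        cls, Qs: list[np.ndarray], pi: np.ndarray
    ) -> list["ReversibleMatrix"]:
        """Decompose several reversible generators in one LAPACK call."""
        d = np.sqrt(np.maximum(pi, _FREQ_FLOOR))
        stack = np.stack([(Q * d[:, None]) / d[None, :] for Q in Qs])
        stack = 0.5 * (stack + stack.transpose(0, 2, 1))
        lams, Vs = np.linalg.eigh(stack)
        out = []
        for lam, V in zip(lams, Vs):
            obj = cls(None, pi)
            obj.lam = lam
            obj.left = V / d[:, None]
            obj.right = V.T * d[None, :]
            out.append(obj)
        return out

    def transition(self, t: float) -> np.ndarray:
        P = (self.left * np.exp(self.lam * t)) @ self.right
        np.clip(P, 0.0, None, out=P)
        return P


# ---------------------------------------------------------------------------
# tree indexing
# ---------------------------------------------------------------------------

class TreeIndex:
    """Array view of a rooted tree paired with an alignment's taxon order."""

    def __init__(self, ptree: PhyloTree, taxa: list[str]):
        nodes = list(ptree.tree.postorder_node_iter())
        ids = {id(n): i for i, n in enumerate(nodes)}
        n = len(nodes)
        self.n_nodes = n
        self.root = ids[id(ptree.tree.seed_node)]
        self.children: list[list[int]] = [[] for _ in range(n)]
        self.edge_length = np.zeros(n)
        self.leaf_row = np.full(n, -1, dtype=int)  # -1: internal; -2: no data
        self.leaf_sets: list[frozenset[str]] = [frozenset()] * n
        row = {t: i for i, t in enumerate(taxa)}
        seen = set()
        self.parent = np.full(n, -1, dtype=int)
        for i, node in enumerate(nodes):
            for child in node.child_nodes():
                self.children[i].append(ids[id(child)])
                self.parent[ids[id(child)]] = i
            if i != self.root:
                self.edge_length[i] = (
                    node.edge.length if node.edge.length is not None else 0.0
                )
            if node.is_leaf():
                label = node.taxon.label
                seen.add(label)
                self.leaf_row[i] = row.get(label, -2)
                self.leaf_sets[i] = frozenset([label])
            else:
                self.leaf_sets[i] = frozenset().union(
                    *(self.leaf_sets[c] for c in self.children[i])
                )
        missing = set(taxa) - seen
        if missing:
            raise KeyError(f"alignment taxa absent from tree: {sorted(missing)}")
        self.n_edges = n - 1


def edge_partitions(
    tindex: TreeIndex, clades: list[CladeDefinition]
) -> np.ndarray:
    """Partition index per node's parent edge: 0 = background, i+1 = clade i.

    An edge belongs to a clade's partition iff the leaf set it subtends is a
    subset of the clade's taxa; the clade's stem edge is therefore included.
    """
    part = np.zeros(tindex.n_nodes, dtype=int)
    for ci, clade in enumerate(clades):
        for i in range(tindex.n_nodes):
            if i == tindex.root:
                continue
            if tindex.leaf_sets[i] and tindex.leaf_sets[i] <= clade.taxa:
                if part[i] not in (0, ci + 1):
                    raise ValueError(
                        f"edge assigned to two partitions ({clade.name})"
                    )
                part[i] = ci + 1
    return part


# ---------------------------------------------------------------------------
# likelihood engine
# ---------------------------------------------------------------------------

class LikelihoodEngine:
    """Pruning likelihood over ω site-class mixtures on a fixed data set.

    ``class_site_loglik`` evaluates per-class per-site log-likelihoods for a
    class structure given as an (K, n_partitions) ω matrix: each class may
    carry a different ω on each branch partition (branch-site / clade
    models); site models use a single partition.
    """

    def __init__(
        self,
        aln: CodonAlignment,
        tree: PhyloTree,
        pi: np.ndarray,
        partitions: list[CladeDefinition] | None = None,
    ):
        self.aln = aln
        self.code = aln.code
        self.pi = np.asarray(pi, dtype=float)
        self.tindex = TreeIndex(tree, aln.taxa)
        self.edge_part = (
            edge_partitions(self.tindex, partitions)
            if partitions
            else np.zeros(self.tindex.n_nodes, dtype=int)
        )
        self.n_partitions = int(self.edge_part.max()) + 1
        self.tipstates = aln.codon_state_matrix()
        self.n_sites = aln.n_codons
        # site-pattern compression: prune unique columns, expand afterwards
        patterns, inverse, counts = np.unique(
            self.tipstates, axis=1, return_inverse=True, return_counts=True
        )
        self.patterns = patterns
        self.pattern_inverse = inverse.ravel()
        self.pattern_counts = counts.astype(float)
        self.n_patterns = patterns.shape[1]

    def _unique_matrices(
        self, kappa: float, omegas: np.ndarray
    ) -> tuple[dict[float, ReversibleMatrix], dict[float, float]]:
        unique = [float(w) for w in np.unique(omegas)]
        Qs = [
            _unscaled_rate_matrix(kappa, w, self.pi, self.code)
            for w in unique
        ]
        decomposed = ReversibleMatrix.from_batch(Qs, self.pi)
        mats = dict(zip(unique, decomposed))
        rates = {w: mean_rate(Q, self.pi) for w, Q in zip(unique, Qs)}
        return mats, rates

    def mixture_scale(
        self,
        kappa: float,
        class_omegas: np.ndarray,
        class_weights: np.ndarray,
    ) -> float:
        """Mixture-average substitution rate (background-partition ω)."""
        class_omegas = np.atleast_2d(np.asarray(class_omegas, dtype=float))
        _, rates = self._unique_matrices(kappa, class_omegas[:, :1])
        return max(
            float(
                sum(
                    w * rates[float(class_omegas[k, 0])]
                    for k, w in enumerate(class_weights)
                )
            ),
            1e-12,
        )

    def class_site_loglik(
        self,
        kappa: float,
        class_omegas: np.ndarray,
        edge_lengths: np.ndarray,
        class_weights: np.ndarray | None = None,
        scale: float | None = None,
    ) -> np.ndarray:
        """(K, n_sites) log-likelihood per site class.

        ``class_omegas`` is (K, n_partitions); ``edge_lengths`` is the
        per-node branch length array (expected substitutions per codon under
        the mixture). The joint mixture scaling uses the background-partition
        ω of each class, weighted by ``class_weights`` (uniform if omitted);
        an explicit ``scale`` overrides it (used when single classes are
        evaluated under another model's fitted scaling).
        """
        class_omegas = np.atleast_2d(np.asarray(class_omegas, dtype=float))
        K = class_omegas.shape[0]
        if class_omegas.shape[1] != self.n_partitions:
            class_omegas = np.repeat(
                class_omegas[:, :1], self.n_partitions, axis=1
            )
        mats, rates = self._unique_matrices(kappa, class_omegas)
        if class_weights is None:
            class_weights = np.full(K, 1.0 / K)
        if scale is None:
            scale = float(
                sum(
                    w * rates[float(class_omegas[k, 0])]
                    for k, w in enumerate(class_weights)
                )
            )
        scale = max(scale, 1e-12)

        ti = self.tindex
        out = np.empty((K, self.n_patterns))
        for k in range(K):
            Pmats: dict[int, np.ndarray] = {}
            for i in range(ti.n_nodes):
                if i == ti.root:
                    continue
                w = float(class_omegas[k, self.edge_part[i]])
                Pmats[i] = mats[w].transition(edge_lengths[i] / scale)
            partials: dict[int, np.ndarray] = {}
            logscale = np.zeros(self.n_patterns)
            for i in range(ti.n_nodes):
                if ti.leaf_row[i] != -1:
                    continue  # leaves handled as messages from parent loop
                part = np.ones((self.n_patterns, self.code.n_states))
                for c in ti.children[i]:
                    P = Pmats[c]
                    if ti.leaf_row[c] == -1:
                        msg = partials.pop(c) @ P.T
                    elif ti.leaf_row[c] == -2:
                        continue  # tree leaf without data: missing
                    else:
                        states = self.patterns[ti.leaf_row[c]]
                        msg = P.T[np.maximum(states, 0)]
                        msg[states < 0] = 1.0
                    part *= msg
                m = np.maximum(part.max(axis=1), _LOG_FLOOR)
                part /= m[:, None]
                logscale += np.log(m)
                partials[i] = part
            sitelik = np.maximum(partials[ti.root] @ self.pi, _LOG_FLOOR)
            out[k] = np.log(sitelik) + logscale
        return out[:, self.pattern_inverse]

    def mixture_loglik(
        self,
        kappa: float,
        class_weights: np.ndarray,
        class_omegas: np.ndarray,
        edge_lengths: np.ndarray,
    ) -> float:
        csl = self.class_site_loglik(
            kappa, class_omegas, edge_lengths, class_weights
        )
        logw = np.log(np.maximum(class_weights, _LOG_FLOOR))
        return float(special.logsumexp(csl + logw[:, None], axis=0).sum())


# ---------------------------------------------------------------------------
# model specifications and parameterizations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodonModelSpec:
    """Which ω-structure to fit, and its fixed configuration."""

    model_id: str
    foreground: CladeDefinition | None = None  # ModelA / ModelA_null
    partitions: tuple[CladeDefinition, ...] | None = None  # CmC / M2a_rel
    codon_freqs: str = "F3x4"
    n_beta_categories: int = 10
    code_table: int = 1
    optimize_branches: str = "scale"  # 'scale' | 'full'

    def __post_init__(self) -> None:
        if self.model_id not in ALL_MODELS:
            raise ValueError(f"unknown model {self.model_id!r}")
        if self.model_id.startswith("ModelA") and self.foreground is None:
            raise ValueError(f"{self.model_id} requires a foreground clade")
        if self.model_id in ("CmC", "M2a_rel") and not self.partitions:
            raise ValueError(f"{self.model_id} requires branch partitions")

    @property
    def clades(self) -> list[CladeDefinition]:
        if self.foreground is not None:
            return [self.foreground]
        return list(self.partitions or [])


def discretize_beta(p: float, q: float, K: int) -> np.ndarray:
    """Means of K equal-probability quantile bins of Beta(p, q)."""
    edges = stats.beta.ppf(np.linspace(0.0, 1.0, K + 1), p, q)
    # mean over [a,b] of Beta(p,q) = (I_b(p+1,q) - I_a(p+1,q)) * (p/(p+q)) * K
    inc = special.betainc(p + 1.0, q, edges)
    means = (inc[1:] - inc[:-1]) * (p / (p + q)) * K
    return np.clip(means, 1e-8, 1.0 - 1e-8)


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return special.expit(x)


def _logit(p: float) -> float:
    p = min(max(p, 1e-8), 1 - 1e-8)
    return math.log(p / (1 - p))


def _stick(x0: float, x1: float) -> tuple[float, float, float]:
    """(p0, p1, p2) from two unconstrained stick-breaking coordinates."""
    p0 = _sigmoid(x0)
    p1 = (1 - p0) * _sigmoid(x1)
    return float(p0), float(p1), float(1 - p0 - p1)


def _stick_inv(p0: float, p1: float) -> tuple[float, float]:
    rest = max(1 - p0, 1e-8)
    return _logit(p0), _logit(min(p1 / rest, 1 - 1e-8))


class _Form:
    """Mapping between an unconstrained vector and one model's ω structure.

    The leading two coordinates are always log κ and log branch multiplier;
    subclass tails hold the model-specific parameters.
    """

    model_id: str = ""
    n_model_params: int = 0  # ω-structure parameters (for LRT df bookkeeping)

    def __init__(self, spec: CodonModelSpec, n_partitions: int):
        self.spec = spec
        self.n_partitions = n_partitions

    # tail -> (weights, omegas (K, n_partitions), params dict)
    def unpack(self, tail: np.ndarray):
        raise NotImplementedError

    def tails(self) -> list[list[float]]:
        """Deterministic start grid for the tail."""
        raise NotImplementedError

    def tail_from_params(self, params: dict) -> list[float] | None:
        return None

    def _tile(self, omegas: list[float]) -> np.ndarray:
        return np.repeat(
            np.asarray(omegas, dtype=float)[:, None], self.n_partitions, axis=1
        )


class _M0(_Form):
    model_id, n_model_params = "M0", 1

    def unpack(self, tail):
        w = math.exp(tail[0])
        return np.array([1.0]), self._tile([w]), {"omega": w}

    def tails(self):
        return [[math.log(w)] for w in (0.05, 0.5, 1.5, 3.0)]

    def tail_from_params(self, params):
        return [math.log(max(params["omega"], 1e-6))]


class _M1a(_Form):
    model_id, n_model_params = "M1a", 2

    def unpack(self, tail):
        p0 = float(_sigmoid(tail[0]))
        w0 = float(_sigmoid(tail[1]))
        return (
            np.array([p0, 1 - p0]),
            self._tile([w0, 1.0]),
            {"p0": p0, "omega0": w0},
        )

    def tails(self):
        return [[_logit(0.8), _logit(0.2)], [_logit(0.5), _logit(0.5)]]


class _M2a(_Form):
    model_id, n_model_params = "M2a", 4

    def unpack(self, tail):
        p0, p1, p2 = _stick(tail[0], tail[1])
        w0 = float(_sigmoid(tail[2]))
        w2 = 1.0 + math.exp(tail[3])
        return (
            np.array([p0, p1, p2]),
            self._tile([w0, 1.0, w2]),
            {"p0": p0, "p1": p1, "p2": p2, "omega0": w0, "omega2": w2},
        )

    def tails(self):
        s = _stick_inv(0.75, 0.15)
        return [
            [*s, _logit(0.2), math.log(1.5 - 1)],
            [*s, _logit(0.2), math.log(4.0 - 1)],
        ]


class _M3(_Form):
    model_id, n_model_params = "M3", 5

    def unpack(self, tail):
        p0, p1, p2 = _stick(tail[0], tail[1])
        ws = [math.exp(t) for t in tail[2:5]]
        return (
            np.array([p0, p1, p2]),
            self._tile(ws),
            {
                "p0": p0,
                "p1": p1,
                "p2": p2,
                "omega0": ws[0],
                "omega1": ws[1],
                "omega2": ws[2],
            },
        )

    def tails(self):
        s = _stick_inv(0.4, 0.35)
        return [
            [*s, math.log(0.05), math.log(0.5), math.log(1.5)],
            [*s, math.log(0.01), math.log(0.2), math.log(0.8)],
        ]


class _M7(_Form):
    model_id, n_model_params = "M7", 2

    def unpack(self, tail):
        p, q = math.exp(tail[0]), math.exp(tail[1])
        K = self.spec.n_beta_categories
        ws = discretize_beta(p, q, K)
        return np.full(K, 1.0 / K), self._tile(list(ws)), {"p": p, "q": q}

    def tails(self):
        return [[math.log(0.5), math.log(2.0)], [math.log(2.0), math.log(2.0)]]

    def tail_from_params(self, params):
        return [math.log(params["p"]), math.log(params["q"])]


class _M8(_Form):
    model_id, n_model_params = "M8", 4

    def unpack(self, tail):
        p0 = float(_sigmoid(tail[0]))
        p, q = math.exp(tail[1]), math.exp(tail[2])
        ws_pos = 1.0 + math.exp(tail[3])
        K = self.spec.n_beta_categories
        betas = discretize_beta(p, q, K)
        weights = np.concatenate([np.full(K, p0 / K), [1 - p0]])
        return (
            weights,
            self._tile(list(betas) + [ws_pos]),
            {"p0": p0, "p": p, "q": q, "omega_s": ws_pos},
        )

    def tails(self):
        return [
            [_logit(0.9), math.log(0.5), math.log(2.0), math.log(2.0 - 1)],
        ]

    def tail_from_params(self, params):
        return [
            _logit(params.get("p0", 0.9)),
            math.log(params["p"]),
            math.log(params["q"]),
            math.log(max(params.get("omega_s", 1.5) - 1, 1e-6)),
        ]


class _M8a(_Form):
    model_id, n_model_params = "M8a", 3

    def unpack(self, tail):
        p0 = float(_sigmoid(tail[0]))
        p, q = math.exp(tail[1]), math.exp(tail[2])
        K = self.spec.n_beta_categories
        betas = discretize_beta(p, q, K)
        weights = np.concatenate([np.full(K, p0 / K), [1 - p0]])
        return (
            weights,
            self._tile(list(betas) + [1.0]),
            {"p0": p0, "p": p, "q": q, "omega_s": 1.0},
        )

    def tails(self):
        return [[_logit(0.9), math.log(0.5), math.log(2.0)]]

    def tail_from_params(self, params):
        return [
            _logit(params.get("p0", 0.9)),
            math.log(params["p"]),
            math.log(params["q"]),
        ]


class _ModelA(_Form):
    model_id, n_model_params = "ModelA", 4
    fix_omega2 = False

    def unpack(self, tail):
        p0, p1, p2 = _stick(tail[0], tail[1])
        w0 = float(_sigmoid(tail[2]))
        w2 = 1.0 if self.fix_omega2 else 1.0 + math.exp(tail[3])
        rest = max(p0 + p1, 1e-12)
        weights = np.array(
            [p0, p1, p2 * p0 / rest, p2 * p1 / rest]
        )
        omegas = np.array(
            [[w0, w0], [1.0, 1.0], [w0, w2], [1.0, w2]], dtype=float
        )
        return (
            weights,
            omegas,
            {"p0": p0, "p1": p1, "p2": p2, "omega0": w0, "omega2": w2},
        )

    def tails(self):
        s = _stick_inv(0.7, 0.2)
        return [[*s, _logit(0.2), math.log(2.0 - 1)]]


class _ModelANull(_ModelA):
    model_id, n_model_params = "ModelA_null", 3
    fix_omega2 = True

    def tails(self):
        s = _stick_inv(0.7, 0.2)
        return [[*s, _logit(0.2)]]


class _CmC(_Form):
    model_id = "CmC"

    def __init__(self, spec, n_partitions):
        super().__init__(spec, n_partitions)
        self.n_model_params = 3 + n_partitions

    def unpack(self, tail):
        p0, p1, p2 = _stick(tail[0], tail[1])
        w0 = float(_sigmoid(tail[2]))
        divergent = [math.exp(t) for t in tail[3 : 3 + self.n_partitions]]
        omegas = np.array(
            [[w0] * self.n_partitions, [1.0] * self.n_partitions, divergent]
        )
        params = {"p0": p0, "p1": p1, "p2": p2, "omega0": w0}
        params.update(
            {f"omega_div{i}": w for i, w in enumerate(divergent)}
        )
        return np.array([p0, p1, p2]), omegas, params

    def tails(self):
        s = _stick_inv(0.6, 0.2)
        return [
            [*s, _logit(0.2)] + [math.log(w)] * self.n_partitions
            for w in (0.8, 2.0)
        ]


class _M2aRel(_Form):
    model_id, n_model_params = "M2a_rel", 4

    def unpack(self, tail):
        p0, p1, p2 = _stick(tail[0], tail[1])
        w0 = float(_sigmoid(tail[2]))
        w2 = math.exp(tail[3])
        return (
            np.array([p0, p1, p2]),
            self._tile([w0, 1.0, w2]),
            {"p0": p0, "p1": p1, "p2": p2, "omega0": w0, "omega2": w2},
        )

    def tails(self):
        s = _stick_inv(0.6, 0.2)
        return [[*s, _logit(0.2), math.log(w)] for w in (0.8, 2.0)]


_FORMS = {
    f.model_id: f
    for f in (
        _M0,
        _M1a,
        _M2a,
        _M3,
        _M7,
        _M8,
        _M8a,
        _ModelA,
        _ModelANull,
        _CmC,
        _M2aRel,
    )
}


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

@dataclass
class CodonModelResults:
    """MLEs, log-likelihood and diagnostics of one fitted codon model."""

    spec: CodonModelSpec
    lnL: float
    kappa: float
    branch_multiplier: float
    params: dict
    class_weights: np.ndarray
    class_omegas: np.ndarray
    n_params: int
    converged: bool
    n_restarts_used: int
    model: "CodonModel" = field(repr=False)

    @property
    def mle(self) -> dict:
        out = {"kappa": self.kappa, "branch_multiplier": self.branch_multiplier}
        out.update(self.params)
        return out

    def site_class_posteriors(self) -> np.ndarray:
        """(n_sites, K) plug-in (NEB) posterior over site classes."""
        csl = self.model.engine.class_site_loglik(
            self.kappa,
            self.class_omegas,
            self.model.base_lengths * self.branch_multiplier,
            self.class_weights,
        )
        logw = np.log(np.maximum(self.class_weights, _LOG_FLOOR))
        joint = csl + logw[:, None]
        joint -= special.logsumexp(joint, axis=0, keepdims=True)
        return np.exp(joint).T

    def summary(self) -> str:
        lines = [
            f"Codon model {self.spec.model_id} — gene "
            f"{self.model.aln.gene_name}",
            "=" * 58,
            f"{'log-likelihood':<28}{self.lnL:>14.4f}",
            f"{'free parameters':<28}{self.n_params:>14d}",
            f"{'kappa (ts/tv)':<28}{self.kappa:>14.4f}",
            f"{'branch multiplier':<28}{self.branch_multiplier:>14.4f}",
            f"{'converged':<28}{str(self.converged):>14}",
            f"{'restarts used':<28}{self.n_restarts_used:>14d}",
            "-" * 58,
        ]
        for name, value in self.params.items():
            lines.append(f"{name:<28}{value:>14.5f}")
        lines.append("-" * 58)
        lines.append("site classes (weight : background omega)")
        for w, om in zip(self.class_weights, self.class_omegas):
            lines.append(f"  {w:8.5f} : {om[0]:10.5f}")
        return "\n".join(lines)

    def to_json(self) -> str:
        payload = {
            "model": self.spec.model_id,
            "gene": self.model.aln.gene_name,
            "lnL": self.lnL,
            "n_params": self.n_params,
            "kappa": self.kappa,
            "branch_multiplier": self.branch_multiplier,
            "params": self.params,
            "class_weights": self.class_weights.tolist(),
            "class_omegas": self.class_omegas.tolist(),
            "converged": self.converged,
            "n_restarts_used": self.n_restarts_used,
        }
        return json.dumps(payload, indent=2)


class CodonModel:
    """One codon-model likelihood problem: alignment × tree × spec.

    ``fit`` returns a :class:`CodonModelResults`; ``loglike`` evaluates the
    likelihood at explicit parameter values.
    """

    def __init__(
        self,
        aln: CodonAlignment,
        tree: PhyloTree,
        spec: CodonModelSpec | str,
        freqs: np.ndarray | None = None,
    ):
        if isinstance(spec, str):
            spec = CodonModelSpec(spec)
        self.aln = aln
        self.tree = tree
        self.spec = spec
        self.pi = (
            np.asarray(freqs, dtype=float)
            if freqs is not None
            else codon_frequencies(aln, spec.codon_freqs)
        )
        self.engine = LikelihoodEngine(aln, tree, self.pi, spec.clades or None)
        self.base_lengths = self.engine.tindex.edge_length.copy()
        self.form: _Form = _FORMS[spec.model_id](
            spec, self.engine.n_partitions
        )

    # -- likelihood -----------------------------------------------------
    def loglike(
        self,
        kappa: float,
        class_weights,
        class_omegas,
        branch_multiplier: float = 1.0,
        edge_lengths: np.ndarray | None = None,
    ) -> float:
        lengths = (
            edge_lengths
            if edge_lengths is not None
            else self.base_lengths * branch_multiplier
        )
        return self.engine.mixture_loglik(
            kappa,
            np.asarray(class_weights, dtype=float),
            np.asarray(class_omegas, dtype=float),
            lengths,
        )

    def _negloglik(self, x: np.ndarray) -> float:
        kappa = math.exp(x[0])
        if self.spec.optimize_branches == "full":
            n_e = self.engine.tindex.n_nodes
            lengths = np.exp(x[1 : 1 + n_e])
            lengths[self.engine.tindex.root] = 0.0
            tail = x[1 + n_e :]
            mult = 1.0
        else:
            mult = math.exp(x[1])
            lengths = self.base_lengths * mult
            tail = x[2:]
        weights, omegas, _ = self.form.unpack(tail)
        try:
            val = -self.engine.mixture_loglik(kappa, weights, omegas, lengths)
        except np.linalg.LinAlgError:
            return 1e12
        return val if np.isfinite(val) else 1e12

    # -- fitting --------------------------------------------------------
    def fit(
        self,
        init: dict | None = None,
        maxiter: int = 500,
        warm_start_m0: bool = True,
    ) -> CodonModelResults:
        """Maximize the likelihood from a deterministic multi-start grid.

        κ and the branch multiplier of non-M0 models are warm-started from a
        quick M0 fit unless ``init`` supplies them (or ``warm_start_m0`` is
        off). ``init`` may carry natural-scale parameters of this model (as in
        ``CodonModelResults.params``) to seed a single extra start.
        """
        head0 = [math.log(2.0), 0.0]
        if self.spec.model_id != "M0" and warm_start_m0 and init is None:
            m0 = CodonModel(
                self.aln,
                self.tree,
                replace(self.spec, model_id="M0", foreground=None,
                        partitions=None),
                freqs=self.pi,
            ).fit(warm_start_m0=False)
            head0 = [math.log(m0.kappa), math.log(m0.branch_multiplier)]

        tails = list(self.form.tails())
        if init is not None:
            seeded = self.form.tail_from_params(init)
            if seeded is not None:
                tails = [seeded] + tails
            if "kappa" in init:
                head0[0] = math.log(init["kappa"])
            if "branch_multiplier" in init:
                head0[1] = math.log(init["branch_multiplier"])

        starts = []
        for tail in tails:
            if self.spec.optimize_branches == "full":
                n_e = self.engine.tindex.n_nodes
                lens = np.log(np.maximum(self.base_lengths, 1e-6))
                starts.append(np.concatenate([[head0[0]], lens, tail]))
            else:
                starts.append(np.array(head0 + list(tail)))

        bounds = [(-16.0, 16.0)] * len(starts[0])
        best = None
        n_used = 0
        for x0 in starts:
            n_used += 1
            res = optimize.minimize(
                self._negloglik,
                x0,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-7},
            )
            if best is None or res.fun < best.fun - 1e-9:
                best = res

        x = best.x
        kappa = math.exp(x[0])
        if self.spec.optimize_branches == "full":
            n_e = self.engine.tindex.n_nodes
            mult = 1.0
            tail = x[1 + n_e :]
        else:
            mult = math.exp(x[1])
            tail = x[2:]
        weights, omegas, params = self.form.unpack(tail)
        n_params = self.form.n_model_params + 1  # + kappa
        n_params += (
            self.engine.tindex.n_edges
            if self.spec.optimize_branches == "full"
            else 1
        )
        return CodonModelResults(
            spec=self.spec,
            lnL=-best.fun,
            kappa=kappa,
            branch_multiplier=mult,
            params=params,
            class_weights=weights,
            class_omegas=omegas,
            n_params=n_params,
            converged=bool(best.success),
            n_restarts_used=n_used,
            model=self,
        )


def log_likelihood(
    aln: CodonAlignment,
    tree: PhyloTree,
    spec: CodonModelSpec | str,
    params: dict,
) -> float:
    """Mixture log-likelihood at explicit parameter values.

    ``params`` uses the natural-scale names of the model's parameterization
    (as produced by ``CodonModelResults.params``) plus ``kappa`` and
    ``branch_multiplier``.
    """
    model = CodonModel(aln, tree, spec)
    tail = _pack_natural(model.form, params)
    weights, omegas, _ = model.form.unpack(np.asarray(tail))
    return model.loglike(
        params.get("kappa", 2.0),
        weights,
        omegas,
        params.get("branch_multiplier", 1.0),
    )


def _pack_natural(form: _Form, params: dict) -> list[float]:
    mid = form.model_id
    if mid == "M0":
        return [math.log(params["omega"])]
    if mid == "M1a":
        return [_logit(params["p0"]), _logit(params["omega0"])]
    if mid in ("M2a", "M2a_rel"):
        s = _stick_inv(params["p0"], params["p1"])
        w2 = params["omega2"]
        last = math.log(w2 - 1) if mid == "M2a" else math.log(w2)
        return [*s, _logit(params["omega0"]), last]
    if mid == "M3":
        s = _stick_inv(params["p0"], params["p1"])
        return [
            *s,
            math.log(params["omega0"]),
            math.log(params["omega1"]),
            math.log(params["omega2"]),
        ]
    if mid == "M7":
        return [math.log(params["p"]), math.log(params["q"])]
    if mid in ("M8", "M8a"):
        out = [
            _logit(params["p0"]),
            math.log(params["p"]),
            math.log(params["q"]),
        ]
        if mid == "M8":
            out.append(math.log(params["omega_s"] - 1))
        return out
    if mid in ("ModelA", "ModelA_null"):
        s = _stick_inv(params["p0"], params["p1"])
        out = [*s, _logit(params["omega0"])]
        if mid == "ModelA":
            out.append(math.log(params["omega2"] - 1))
        return out
    if mid == "CmC":
        s = _stick_inv(params["p0"], params["p1"])
        out = [*s, _logit(params["omega0"])]
        i = 0
        while f"omega_div{i}" in params:
            out.append(math.log(params[f"omega_div{i}"]))
            i += 1
        return out
    raise ValueError(mid)
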