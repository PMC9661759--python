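import itertools

import numpy as np
import pytest

from cladescan import (
    CodonAlignment,
    CodonModel,
    CodonModelSpec,
    build_rate_matrix,
    f3x4,
    log_likelihood,
    tree_from_newick,
)
from cladescan.codonmodel import (
    ReversibleMatrix,
    discretize_beta,
    mean_rate,
    uniform_freqs,
    _unscaled_rate_matrix,
)
from cladescan._codons import PURINES

from conftest import random_codon_alignment


def brute_force_rate_matrix(kappa, omega, pi, code):
    """Independent Q builder: explicit double loop over codon pairs."""
    n = code.n_states
    Q = np.zeros((n, n))
    for i, ci in enumerate(code.codons):
        for j, cj in enumerate(code.codons):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            a, b = diffs[0]
            rate = pi[j]
            if (a in PURINES) == (b in PURINES):
                rate *= kappa
            if code.aa[i] != code.aa[j]:
                rate *= omega
            Q[i, j] = rate
    Q[np.diag_indices(n)] = -Q.sum(axis=1)
    return Q


def exhaustive_loglik(aln, tree_spec, kappa, omegas, weights, pi, code):
    """Sum over all internal-node codon assignments; trees given as nested
    tuples (label, branch_length) / (children, branch_length)."""
    Qs = {
        w: _unscaled_rate_matrix(kappa, w, pi, code) for w in set(omegas)
    }
    scale = sum(
        wt * mean_rate(Qs[w], pi) for w, wt in zip(omegas, weights)
    )
    decomposed = {w: ReversibleMatrix(Q, pi) for w, Q in Qs.items()}
    cache = {}

    def transition(w, t):
        if (w, t) not in cache:
            cache[(w, t)] = decomposed[w].transition(t / scale)
        return cache[(w, t)]

    def site_lik(node, state, site, w):
        children, _ = node
        total = 1.0
        for child in children:
            sub, t = child
            P = transition(w, t)
            if isinstance(sub, str):
                obs = code.codon_index[
                    aln.sequences[sub][3 * site : 3 * site + 3]
                ]
                total *= P[state, obs]
            else:
                total *= sum(
                    P[state, x] * site_lik(child, x, site, w)
                    for x in range(code.n_states)
                )
        return total

    lnl = 0.0
    for site in range(aln.n_codons):
        lik = 0.0
        for w, wt in zip(omegas, weights):
            lik += wt * sum(
                pi[r] * site_lik((tree_spec, 0.0), r, site, w)
                for r in range(code.n_states)
            )
        lnl += np.log(lik)
    return lnl


# ---------------------------------------------------------------------------
# rate matrix
# ---------------------------------------------------------------------------

def test_rate_matrix_rows_sum_to_zero(code):
    pi = uniform_freqs(code)
    Q = build_rate_matrix(2.5, 0.4, pi)
    assert np.abs(Q.sum(axis=1)).max() < 1e-10
    assert mean_rate(Q, pi) == pytest.approx(1.0)


def test_rate_matrix_detailed_balance(rng, code):
    pi = rng.dirichlet(np.ones(code.n_states))
    Q = build_rate_matrix(3.0, 0.7, pi)
    flux = pi[:, None] * Q
    assert np.abs(flux - flux.T).max() < 1e-12


def test_rate_matrix_matches_brute_force(code):
    pi = uniform_freqs(code)
    Q = build_rate_matrix(1.0, 1.0, pi, scale=False)
    B = brute_force_rate_matrix(1.0, 1.0, pi, code)
    assert np.abs(Q - B).max() < 1e-14
    Q2 = build_rate_matrix(2.7, 0.3, pi, scale=False)
    B2 = brute_force_rate_matrix(2.7, 0.3, pi, code)
    assert np.abs(Q2 - B2).max() < 1e-14


def test_rate_matrix_rejects_bad_freqs(code):
    with pytest.raises(ValueError):
        build_rate_matrix(2.0, 0.5, np.ones(code.n_states))


@pytest.mark.parametrize("t", [0.01, 0.1, 1.0])
def test_transition_matrix_rows_sum_to_one(code, t):
    pi = uniform_freqs(code)
    Q = build_rate_matrix(2.0, 0.5, pi)
    P = ReversibleMatrix(Q, pi).transition(t)
    assert np.abs(P.sum(axis=1) - 1.0).max() < 1e-10
    assert (P >= 0).all()


# ---------------------------------------------------------------------------
# codon frequencies
# ---------------------------------------------------------------------------

def test_f3x4_uniform_composition(code):
    # all four bases equally frequent at every position -> 1/61 each
    seqs = {"t1": "AAACCCGGGTTT", "t2": "CCCGGGTTTAAA",
            "t3": "GGGTTTAAACCC", "t4": "TTTAAACCCGGG"}
    aln = CodonAlignment("g", list(seqs), seqs, code)
    freqs = f3x4(aln)
    assert freqs.sum() == pytest.approx(1.0)
    assert np.allclose(freqs, 1 / 61, atol=1e-9)


def test_f3x4_hand_computed_toy(code):
    # two sequences of one codon each: position freqs are exact products
    seqs = {"t1": "ATG", "t2": "ACG"}
    aln = CodonAlignment("g", list(seqs), seqs, code)
    freqs = f3x4(aln)
    # pos1: A=1; pos2: T=.5, C=.5; pos3: G=1 -> ATG and ACG each 0.5 pre-norm
    idx = {c: i for i, c in enumerate(code.codons)}
    assert freqs[idx["ATG"]] == pytest.approx(0.5, abs=1e-6)
    assert freqs[idx["ACG"]] == pytest.approx(0.5, abs=1e-6)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def test_identical_sequences_zero_branches(code):
    seqs = {"a": "ATGGAAGTT", "b": "ATGGAAGTT"}
    aln = CodonAlignment("g", list(seqs), seqs, code)
    tree = tree_from_newick("(a:0.0,b:0.0);")
    pi = uniform_freqs(code)
    model = CodonModel(aln, tree, "M0", freqs=pi)
    lnl = model.loglike(2.0, [1.0], [[0.5]], 1.0)
    expected = 3 * np.log(1 / 61)
    assert lnl == pytest.approx(expected, abs=1e-8)


def test_pruning_matches_exhaustive_three_taxon(rng, code):
    aln = random_codon_alignment(rng, code, n_taxa=3, n_codons=5)
    aln = CodonAlignment(
        "g", ["s1", "s2", "s3"],
        {t: aln.sequences[t] for t in ["s1", "s2", "s3"]}, code,
    )
    tree = tree_from_newick("(s1:0.1,s2:0.2,s3:0.15);")
    pi = uniform_freqs(code)
    model = CodonModel(aln, tree, "M0", freqs=pi)
    got = model.loglike(2.0, [1.0], [[0.5]], 1.0)
    spec = [("s1", 0.1), ("s2", 0.2), ("s3", 0.15)]
    expected = exhaustive_loglik(aln, spec, 2.0, [0.5], [1.0], pi, code)
    assert got == pytest.approx(expected, abs=1e-8)


def test_single_class_mixture_equals_m0(rng, code):
    aln = random_codon_alignment(rng, code, n_taxa=4, n_codons=10)
    tree = tree_from_newick(
        "((s1:0.1,s2:0.2):0.05,(s3:0.15,s4:0.1):0.07);"
    )
    pi = uniform_freqs(code)
    model = CodonModel(aln, tree, "M0", freqs=pi)
    one = model.loglike(2.0, [1.0], [[0.3]], 1.0)
    split = model.loglike(2.0, [0.5, 0.5], [[0.3], [0.3]], 1.0)
    assert one == pytest.approx(split, abs=1e-9)


def test_loglik_invariant_under_rerooting(rng, code):
    """Time-reversible model: lnL must not depend on root placement."""
    import dendropy

    aln = random_codon_alignment(rng, code, n_taxa=6, n_codons=20)
    newick = ("((s1:0.1,s2:0.2):0.05,((s3:0.15,s4:0.1):0.07,"
              "(s5:0.12,s6:0.08):0.04):0.06);")
    tree = tree_from_newick(newick)
    pi = uniform_freqs(code)
    base = CodonModel(aln, tree, "M0", freqs=pi).loglike(
        2.0, [1.0], [[0.5]], 1.0
    )
    for leaf in ["s3", "s5"]:
        t2 = tree_from_newick(newick)
        node = t2.tree.find_node_with_taxon_label(leaf)
        t2.tree.reroot_at_edge(
            node.edge, length1=node.edge.length / 2,
            length2=node.edge.length / 2, update_bipartitions=False,
        )
        rerooted = CodonModel(aln, t2, "M0", freqs=pi).loglike(
            2.0, [1.0], [[0.5]], 1.0
        )
        assert rerooted == pytest.approx(base, abs=1e-8)


def test_log_likelihood_function_matches_model(rng, code):
    aln = random_codon_alignment(rng, code, n_taxa=4, n_codons=12)
    tree = tree_from_newick(
        "((s1:0.1,s2:0.2):0.05,(s3:0.15,s4:0.1):0.07);"
    )
    params = {"omega": 0.4, "kappa": 2.0, "branch_multiplier": 1.1}
    got = log_likelihood(aln, tree, "M0", params)
    model = CodonModel(aln, tree, "M0")
    assert got == pytest.approx(
        model.loglike(2.0, [1.0], [[0.4]], 1.1), abs=1e-9
    )


# ---------------------------------------------------------------------------
# beta discretization
# ---------------------------------------------------------------------------

def test_discretize_beta_category_means():
    for p, q in [(0.5, 2.0), (2.0, 2.0), (0.2, 0.3)]:
        means = discretize_beta(p, q, 10)
        assert means.shape == (10,)
        assert ((means > 0) & (means < 1)).all()
        assert (np.diff(means) > 0).all()
        # equal-probability bins: category average == distribution mean
        assert means.mean() == pytest.approx(p / (p + q), abs=1e-6)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def test_fit_nesting_and_determinism(rng, code):
    from cladescan.simulate import SimulationConfig, simulate_alignment

    cfg = SimulationConfig(
        seed=42, n_codons=120, n_taxa=5, spec="M0",
        params={"kappa": 2.0, "omega": 0.3},
    )
    res = simulate_alignment(cfg)
    m0_a = CodonModel(res.alignment, res.tree, "M0").fit()
    m0_b = CodonModel(res.alignment, res.tree, "M0").fit()
    assert m0_a.lnL == pytest.approx(m0_b.lnL, abs=1e-8)
    assert m0_a.converged
    # M0 is M1a's boundary point (p0 -> 1); allow boundary optimizer noise
    m1a = CodonModel(res.alignment, res.tree, "M1a").fit()
    assert m1a.lnL >= m0_a.lnL - 1e-4

    summary = m0_a.summary()
    assert "log-likelihood" in summary and "kappa" in summary
    assert '"model": "M0"' in m0_a.to_json()


def test_local_optimality_of_mle(rng, code):
    """Perturbing ω away from its MLE must not increase the likelihood."""
    from cladescan.simulate import SimulationConfig, simulate_alignment

    cfg = SimulationConfig(
        seed=9, n_codons=150, n_taxa=6, spec="M0",
        params={"kappa": 2.0, "omega": 0.25},
    )
    res = simulate_alignment(cfg)
    fit = CodonModel(res.alignment, res.tree, "M0").fit()
    model = fit.model
    w = fit.params["omega"]
    at_mle = model.loglike(fit.kappa, [1.0], [[w]], fit.branch_multiplier)
    for factor in (0.7, 1.4):
        perturbed = model.loglike(
            fit.kappa, [1.0], [[w * factor]], fit.branch_multiplier
        )
        assert perturbed <= at_mle + 1e-9
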