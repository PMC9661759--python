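import numpy as np
import pytest

from cladescan import (
    CladeDefinition,
    CodonModel,
    branch_site_test,
    clade_model_test,
    empirical_bayes_sites,
    lrt,
    site_model_scan,
)
from cladescan.selection import SitePosterior, bh_qvalues, _guard_nested
from cladescan.simulate import SimulationConfig, simulate_alignment


# ---------------------------------------------------------------------------
# LRT arithmetic
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "two_delta,df,expected",
    [
        (24.285, 3, 0.00002),
        (11.864, 5, 0.03670),
        (17.065, 1, 0.00004),
    ],
)
def test_lrt_published_pvalues(two_delta, df, expected):
    result = lrt(0.0, two_delta / 2.0, df)
    assert round(result.p_value, 5) == expected


def test_lrt_zero_statistic():
    assert lrt(-100.0, -100.0, 3).p_value == 1.0


def test_lrt_clamps_tiny_negative():
    r = lrt(-100.0, -100.0 - 4e-7, 2)
    assert r.two_delta_lnl == 0.0
    assert r.p_value == 1.0


def test_lrt_rejects_large_negative():
    with pytest.raises(ValueError, match="inconsistent"):
        lrt(-100.0, -100.1, 2)


def test_lrt_rejects_bad_df():
    with pytest.raises(ValueError):
        lrt(-10.0, -9.0, 0)


def test_lrt_monotone_in_statistic():
    ps = [lrt(0.0, x / 2, 2).p_value for x in (0.5, 1.0, 5.0, 10.0)]
    assert ps == sorted(ps, reverse=True)


# ---------------------------------------------------------------------------
# site posteriors
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "pp,flag",
    [(0.3, ""), (0.95, "*"), (0.9899, "*"), (0.99, "**"), (0.9991, "***")],
)
def test_flag_is_pure_threshold_function(pp, flag):
    s = SitePosterior("g", 1, (1 - pp, pp), pp, "NEB")
    assert s.flag == flag


@pytest.fixture(scope="module")
def m2a_selected_fit():
    cfg = SimulationConfig(
        seed=77, n_codons=150, n_taxa=6, spec="M2a",
        params={"kappa": 2.0, "p0": 0.6, "p1": 0.25, "omega0": 0.1,
                "omega2": 5.0},
        mean_branch_length=0.08,
    )
    res = simulate_alignment(cfg)
    fit = CodonModel(res.alignment, res.tree, "M2a").fit()
    return res, fit


def test_neb_matches_hand_bayes_rule(m2a_selected_fit):
    """Plug-in posteriors equal Bayes' rule applied to the per-class site
    likelihoods (independent recomputation)."""
    _, fit = m2a_selected_fit
    sites = empirical_bayes_sites(fit, method="NEB")
    csl = fit.model.engine.class_site_loglik(
        fit.kappa, fit.class_omegas,
        fit.model.base_lengths * fit.branch_multiplier, fit.class_weights,
    )
    lik = np.exp(csl - csl.max(axis=0, keepdims=True))
    w = fit.class_weights[:, None]
    post = (w * lik) / (w * lik).sum(axis=0, keepdims=True)
    for s in sites:
        assert np.allclose(
            s.class_posteriors, post[:, s.codon_site - 1], atol=1e-9
        )
        assert sum(s.class_posteriors) == pytest.approx(1.0, abs=1e-9)


def test_beb_posteriors_are_probabilities(m2a_selected_fit):
    res, fit = m2a_selected_fit
    sites = empirical_bayes_sites(fit, method="BEB")
    assert len(sites) == res.alignment.n_codons
    for s in sites:
        assert 0.0 <= s.pp_positive <= 1.0 + 1e-12
        assert sum(s.class_posteriors) == pytest.approx(1.0, abs=1e-6)
        assert s.method == "BEB"


def test_beb_enriches_truly_selected_sites(m2a_selected_fit):
    """Sites generated in the ω>1 class should carry higher mean BEB pp
    than the purifying background."""
    res, fit = m2a_selected_fit
    sites = empirical_bayes_sites(fit, method="BEB")
    pp = np.array([s.pp_positive for s in sites])
    positive_class = res.site_classes == 2
    assert positive_class.any()
    assert pp[positive_class].mean() > pp[~positive_class].mean()


def test_empirical_bayes_requires_positive_class(m2a_selected_fit):
    res, _ = m2a_selected_fit
    m1a = CodonModel(res.alignment, res.tree, "M1a").fit()
    with pytest.raises(ValueError, match="positive"):
        empirical_bayes_sites(m1a)


def test_neb_zero_when_no_positive_omega():
    """CmC fit whose divergent ω stays below 1 yields pp_positive = 0."""
    cfg = SimulationConfig(
        seed=31, n_codons=80, n_taxa=5, spec="M0",
        params={"kappa": 2.0, "omega": 0.1},
    )
    res = simulate_alignment(cfg)
    clade = CladeDefinition("F", frozenset(res.tree.leaf_labels[:2]))
    from cladescan.codonmodel import CodonModelSpec

    fit = CodonModel(
        res.alignment, res.tree,
        CodonModelSpec("CmC", partitions=(clade,)),
    ).fit()
    if (fit.class_omegas[2] <= 1.0).all():
        sites = empirical_bayes_sites(fit, method="NEB")
        assert all(s.pp_positive == 0.0 for s in sites)


# ---------------------------------------------------------------------------
# scans (small, fast configurations)
# ---------------------------------------------------------------------------

def test_site_model_scan_m1a_m2a_detects_planted_selection():
    cfg = SimulationConfig(
        seed=101, n_codons=200, n_taxa=6, spec="M2a",
        params={"kappa": 2.0, "p0": 0.55, "p1": 0.25, "omega0": 0.05,
                "omega2": 6.0},
        mean_branch_length=0.1,
    )
    res = simulate_alignment(cfg)
    scan = site_model_scan(res.alignment, res.tree, models=("M1a", "M2a"))
    r = scan.lrt("M1a vs M2a")
    assert r is not None and r.df == 2
    assert r.p_value < 0.05
    assert scan.site_posteriors  # BEB ran on the significant comparison


def test_branch_site_whole_tree_foreground_nests():
    cfg = SimulationConfig(
        seed=55, n_codons=60, n_taxa=4, spec="M0",
        params={"kappa": 2.0, "omega": 0.3},
    )
    res = simulate_alignment(cfg)
    clade = CladeDefinition("all", frozenset(res.tree.leaf_labels))
    out = branch_site_test(res.alignment, res.tree, clade)
    assert out.lrt.df == 1
    assert out.alt_fit.lnL >= out.null_fit.lnL
    assert 0.0 <= out.lrt.p_value <= 1.0


def test_clade_model_constraint_identity():
    """CmC with its divergent ω's forced equal reproduces the M2a_rel
    likelihood (constraint identity), and the df matches the partitions."""
    cfg = SimulationConfig(
        seed=66, n_codons=80, n_taxa=6, spec="M0",
        params={"kappa": 2.0, "omega": 0.2},
    )
    res = simulate_alignment(cfg)
    labels = res.tree.leaf_labels
    from cladescan import check_monophyly
    from cladescan.codonmodel import CodonModelSpec

    clade = None
    for a in labels:
        for b in labels:
            if a < b:
                cand = CladeDefinition("F", frozenset({a, b}))
                if check_monophyly(res.tree, cand)[0]:
                    clade = cand
                    break
        if clade:
            break
    assert clade is not None
    rel = CodonModel(
        res.alignment, res.tree, CodonModelSpec("M2a_rel", partitions=(clade,))
    ).fit()
    cmc_model = CodonModel(
        res.alignment, res.tree, CodonModelSpec("CmC", partitions=(clade,))
    )
    p = dict(rel.params)
    constrained = cmc_model.loglike(
        rel.kappa,
        [p["p0"], p["p1"], 1 - p["p0"] - p["p1"]],
        [[p["omega0"]] * 2, [1.0] * 2, [p["omega2"]] * 2],
        rel.branch_multiplier,
    )
    assert constrained == pytest.approx(rel.lnL, abs=1e-6)

    out = clade_model_test(res.alignment, res.tree, [clade])
    assert out.lrt.df == 1
    assert out.lrt.p_value >= 0.0


def test_branch_site_detects_foreground_selection():
    """Strong foreground-only selection (ω2 = 8 on ~20% of sites) yields a
    significant Model A LRT, and BEB enriches the foreground-selected
    sites."""
    from cladescan.codonmodel import CodonModelSpec
    from cladescan import check_monophyly

    tree_seed = 404
    from cladescan.simulate import random_tree

    tree = random_tree(6, seed=tree_seed, mean_branch_length=0.15)
    clade = None
    for node in tree.tree.preorder_node_iter():
        leaves = tree.leaf_set(node)
        if len(leaves) == 3:
            clade = CladeDefinition("F", frozenset(leaves))
            break
    assert clade is not None and check_monophyly(tree, clade)[0]
    cfg = SimulationConfig(
        seed=405, n_codons=300, tree=tree,
        spec=CodonModelSpec("ModelA", foreground=clade),
        params={"kappa": 2.0, "p0": 0.55, "p1": 0.25, "omega0": 0.05,
                "omega2": 8.0},
        clades=[clade],
    )
    res = simulate_alignment(cfg)
    out = branch_site_test(res.alignment, tree, clade)
    assert out.lrt.p_value < 0.05
    pp = np.array([s.pp_positive for s in out.site_posteriors])
    fg_selected = np.isin(res.site_classes, (2, 3))
    assert pp[fg_selected].mean() > pp[~fg_selected].mean()


def test_clade_model_detects_divergent_constraint():
    """A site class with ω 0.1 in the background vs 3.5 in one clade is
    detected by CmC vs M2a_rel."""
    from cladescan.codonmodel import CodonModelSpec
    from cladescan.simulate import random_tree

    tree = random_tree(6, seed=500, mean_branch_length=0.15)
    clade = None
    for node in tree.tree.preorder_node_iter():
        leaves = tree.leaf_set(node)
        if len(leaves) in (2, 3):
            clade = CladeDefinition("D", frozenset(leaves))
            break
    assert clade is not None
    cfg = SimulationConfig(
        seed=501, n_codons=300, tree=tree,
        spec=CodonModelSpec("CmC", partitions=(clade,)),
        params={"kappa": 2.0, "p0": 0.4, "p1": 0.2, "omega0": 0.05,
                "omega_div0": 0.1, "omega_div1": 3.5},
        clades=[clade],
    )
    res = simulate_alignment(cfg)
    out = clade_model_test(res.alignment, tree, [clade])
    assert out.lrt.df == 1
    assert out.lrt.p_value < 0.05
    # the fitted divergent ω's should separate in the right direction
    div = out.alt_fit.class_omegas[2]
    assert div[1] > div[0]


def test_guard_nested_only_lifts_tiny_gaps(m2a_selected_fit):
    _, fit = m2a_selected_fit
    import dataclasses

    slightly_low = dataclasses.replace(fit, lnL=fit.lnL - 1e-5)
    assert _guard_nested(fit, slightly_low).lnL == fit.lnL
    much_low = dataclasses.replace(fit, lnL=fit.lnL - 5.0)
    assert _guard_nested(fit, much_low).lnL == fit.lnL - 5.0


def test_bh_qvalues_monotone():
    p = [0.001, 0.02, 0.04, 0.8]
    q = bh_qvalues(p)
    assert q == sorted(q)
    assert q[0] == pytest.approx(0.004)
    assert all(qq >= pp for qq, pp in zip(q, p))
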