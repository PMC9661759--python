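import itertools

import numpy as np
import pytest

from cladescan import (
    CodonAlignment,
    PropertyTable,
    ancestral_aa,
    categorize_change,
    load_property_table,
    neutral_expectation,
    sliding_window_scan,
    tree_from_newick,
    z_test,
    z_thresholds,
)
from cladescan.aaprops import (
    PropertyChangeEvent,
    RADICAL_CATEGORIES,
    _accessible_pairs,
    count_nonsynonymous_neighbors,
    grade_events,
)
from cladescan._codons import AMINO_ACIDS, get_genetic_code


@pytest.fixture(scope="module")
def table():
    return load_property_table()


@pytest.fixture(scope="module")
def expectation(table):
    return neutral_expectation(table)


# ---------------------------------------------------------------------------
# property table
# ---------------------------------------------------------------------------

def test_table_has_31_properties_of_20_values(table):
    assert len(table.properties) == 31
    for values in table.properties.values():
        assert len(values) == 20


def test_table_contains_cited_property_names(table):
    cited = {
        "Mean r.m.s. fluctuation displacement",
        "Alpha-helical tendencies",
        "Equilibrium constant (ionization of COOH)",
        "Turn tendencies",
        "Power to be at the C-terminal",
        "Isoelectric point",
        "Compressibility",
        "Hydropathy",
        "Polarity",
        "Thermodynamic transfer hydrophobicity",
    }
    assert cited <= set(table.names)


def test_delta_symmetry(table):
    for prop in table.names[:5]:
        for a, b in itertools.combinations("ACDEFG", 2):
            assert table.delta(prop, a, b) == table.delta(prop, b, a)


def test_wrong_property_count_rejected(table):
    subset = dict(list(table.properties.items())[:30])
    with pytest.raises(ValueError, match="31"):
        PropertyTable(subset)


# ---------------------------------------------------------------------------
# categories
# ---------------------------------------------------------------------------

def test_maximal_accessible_exchange_is_category_8(table):
    for prop in table.names:
        best = max(
            _accessible_pairs(1), key=lambda ab: table.delta(prop, *ab)
        )
        assert categorize_change(best[0], best[1], prop, table) == 8


def test_minimal_accessible_exchange_is_category_1(table):
    for prop in table.names[:8]:
        worst = min(
            _accessible_pairs(1), key=lambda ab: table.delta(prop, *ab)
        )
        assert categorize_change(worst[0], worst[1], prop, table) == 1


def test_ser_phe_fluctuation_is_most_radical(table):
    """The Ser→Phe replacement is the most radical possible change of mean
    r.m.s. fluctuation displacement (category 8) — the published calibration
    point for the bin boundaries."""
    cat = categorize_change(
        "S", "F", "Mean r.m.s. fluctuation displacement", table
    )
    assert cat == 8


def test_categorize_rejects_identity_and_unknown(table):
    with pytest.raises(ValueError):
        categorize_change("A", "A", "Hydropathy", table)
    with pytest.raises(KeyError):
        categorize_change("A", "B", "Hydropathy", table)


def test_categories_deterministic_and_in_range(table):
    for prop in table.names[:6]:
        for a, b in itertools.combinations("ARNDCQ", 2):
            c1 = categorize_change(a, b, prop, table)
            c2 = categorize_change(b, a, prop, table)
            assert c1 == c2
            assert 1 <= c1 <= 8


# ---------------------------------------------------------------------------
# neutral expectation
# ---------------------------------------------------------------------------

def test_neutral_expectation_sums_to_one(expectation):
    for dist in expectation.values():
        assert dist.sum() == pytest.approx(1.0, abs=1e-12)
        assert (dist >= 0).all()


def test_neighbor_count_matches_brute_force(code):
    brute = 0
    for ci in code.codons:
        for pos in range(3):
            for nt in "ACGT":
                if nt == ci[pos]:
                    continue
                cj = ci[:pos] + nt + ci[pos + 1 :]
                if cj in code.stop_codons:
                    continue
                if code.translate(cj) != code.translate(ci):
                    brute += 1
    assert count_nonsynonymous_neighbors(code) == brute


def test_uniform_dummy_property_all_category_one():
    flat = {
        f"scale {i}": {aa: 1.0 for aa in AMINO_ACIDS} for i in range(31)
    }
    table = PropertyTable(flat)
    exp = neutral_expectation(table)
    for dist in exp.values():
        assert dist[0] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Fitch parsimony
# ---------------------------------------------------------------------------

def _aa_aln(code, seqs):
    return {t: s for t, s in seqs.items()}


def test_invariant_column_no_events():
    tree = tree_from_newick("((t1:1,t2:1):1,(t3:1,t4:1):1);")
    rec = ancestral_aa(tree, {f"t{i}": "MM" for i in range(1, 5)})
    assert rec.events == []
    assert (rec.parsimony_score == 0).all()


def test_four_taxon_single_internal_event():
    tree = tree_from_newick("((t1:1,t2:1):1,(t3:1,t4:1):1);")
    rec = ancestral_aa(
        tree, {"t1": "A", "t2": "A", "t3": "V", "t4": "V"}, seed=0
    )
    assert len(rec.events) == 1
    ev = rec.events[0]
    assert {ev.from_aa, ev.to_aa} == {"A", "V"}
    assert rec.parsimony_score[0] == 1


def _exhaustive_parsimony(tree, tip_states):
    """Minimum change count over all internal-node labelings (oracle)."""
    from cladescan.codonmodel import TreeIndex

    taxa = list(tip_states)
    ti = TreeIndex(tree, taxa)
    internal = [i for i in range(ti.n_nodes) if ti.leaf_row[i] == -1]
    states = sorted(set(tip_states.values()))
    best = None
    for combo in itertools.product(states, repeat=len(internal)):
        assign = dict(zip(internal, combo))
        for i in range(ti.n_nodes):
            if ti.leaf_row[i] >= 0:
                assign[i] = tip_states[taxa[ti.leaf_row[i]]]
        changes = sum(
            1
            for i in range(ti.n_nodes)
            if i != ti.root and assign[i] != assign[ti.parent[i]]
        )
        best = changes if best is None else min(best, changes)
    return best


def test_fitch_score_matches_exhaustive_enumeration(rng):
    from cladescan.simulate import random_tree

    for seed in range(8):
        n = int(rng.integers(3, 7))
        tree = random_tree(n, seed=seed)
        tips = {
            t: rng.choice(list("AVLS"), size=1)[0] for t in tree.leaf_labels
        }
        rec = ancestral_aa(tree, {t: s for t, s in tips.items()}, seed=1)
        assert rec.parsimony_score[0] == _exhaustive_parsimony(tree, tips)
        assert len(rec.events) == rec.parsimony_score[0]


def test_fitch_event_count_equals_parsimony_score(rng):
    from cladescan.simulate import random_tree

    tree = random_tree(6, seed=3)
    seqs = {
        t: "".join(rng.choice(list("ACDE"), size=10)) for t in tree.leaf_labels
    }
    rec = ancestral_aa(tree, seqs, seed=5)
    per_site = np.zeros(10, dtype=int)
    for ev in rec.events:
        per_site[ev.codon_site - 1] += 1
    assert (per_site == rec.parsimony_score).all()


def test_gapped_tip_emits_no_terminal_event():
    tree = tree_from_newick("((t1:1,t2:1):1,(t3:1,t4:1):1);")
    rec = ancestral_aa(
        tree, {"t1": "A", "t2": "A", "t3": "A", "t4": "-"}, seed=0
    )
    assert rec.events == []


# ---------------------------------------------------------------------------
# Z-test
# ---------------------------------------------------------------------------

def _events(categories, prop="P1"):
    return [
        PropertyChangeEvent("g", i + 1, "b", "A", "V", {prop: c})
        for i, c in enumerate(categories)
    ]


def test_z_thresholds_match_normal_quantiles():
    z99, z999 = z_thresholds()
    assert round(z99, 2) == 2.33
    assert round(z999, 2) == 3.09


def test_z_zero_when_observed_equals_expected():
    exp = {"P1": np.array([0.0, 0.0, 0.0, 0.0, 0.0, 0.8, 0.1, 0.1])}
    # all radical with p_hat = 1.0 -> degenerate, z = 0 by convention
    assert z_test(_events([6] * 10), exp, "P1") == 0.0
    exp2 = {"P1": np.array([0.5, 0.0, 0.0, 0.0, 0.0, 0.5, 0.0, 0.0])}
    z = z_test(_events([6, 1] * 5), exp2, "P1")
    assert z == pytest.approx(0.0)


def test_z_hand_binomial_arithmetic():
    # n = 100, p_hat = 0.2, obs = 30 -> z = (30-20)/sqrt(16) = 2.5
    exp = {"P1": np.array([0.8, 0, 0, 0, 0, 0.2, 0, 0.0])}
    cats = [6] * 30 + [1] * 70
    assert z_test(_events(cats), exp, "P1") == pytest.approx(2.5)


def test_z_requires_events():
    with pytest.raises(ValueError):
        z_test([], {"P1": np.ones(8) / 8}, "P1")


def test_threshold_flags_are_strict(table):
    z99, z999 = z_thresholds()
    from cladescan.aaprops import WindowZProfile

    w1 = WindowZProfile("g", 1, 15, {"P1": 2.4}, 3)
    assert w1.significant_99("P1") and not w1.significant_999("P1")
    w2 = WindowZProfile("g", 1, 15, {"P1": 3.2}, 3)
    assert w2.significant_99("P1") and w2.significant_999("P1")


# ---------------------------------------------------------------------------
# sliding windows
# ---------------------------------------------------------------------------

def test_window_counts():
    exp = {"P1": np.array([0.8, 0, 0, 0, 0, 0.2, 0, 0.0])}
    assert len(sliding_window_scan([], 15, exp)) == 1
    assert len(sliding_window_scan([], 17, exp)) == 3
    with pytest.raises(ValueError):
        sliding_window_scan([], 10, exp)


def test_concentrated_events_peak_in_their_window():
    exp = {"P1": np.array([0.9, 0, 0, 0, 0, 0.1, 0, 0.0])}
    events = _events([6, 6, 6, 6])  # radical cluster at codons 1-4
    profiles = sliding_window_scan(events, 40, exp)
    zs = [w.z["P1"] for w in profiles]
    assert max(zs) == zs[0]  # the window containing all events
    assert zs[0] > max(z for w, z in zip(profiles[10:], zs[10:]))


def test_grade_events_covers_all_properties(table):
    from cladescan.aaprops import ReplacementEvent

    events = grade_events(
        [ReplacementEvent("g", 3, "b", "S", "F")], table
    )
    assert len(events) == 1
    assert set(events[0].categories) == set(table.names)
    assert events[0].radical("Mean r.m.s. fluctuation displacement")
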