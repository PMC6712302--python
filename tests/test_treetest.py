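"""Tree parsing, monophyly/sister diagnostics, pruning likelihood, AU test."""

import numpy as np
import pytest

from neogut.lineage import LineageMap
from neogut.treetest import (
    AUConfig,
    MonophylyError,
    SubstModel,
    TreeError,
    au_test,
    bipartitions,
    constrain_monophyly,
    infer_nj_tree,
    is_monophyletic,
    parse_newick,
    site_loglik,
    sister_lineage,
    write_newick,
)
from ._oracles import (
    all_bipartitions_by_enumeration,
    enumeration_site_loglik,
    naive_rell_winner_counts,
)

ALPHA = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# newick dialect
# ---------------------------------------------------------------------------


def test_support_as_internal_label():
    tree = parse_newick("((A,B)98:0.1,C);")
    mono, support = is_monophyletic(tree, {"A", "B"})
    assert mono and support == 98.0


def test_polytomy_preserved():
    tree = parse_newick("(A,B,C);")
    assert len(tree.seed_node.child_nodes()) == 3


def test_unbalanced_parentheses_rejected():
    with pytest.raises(TreeError):
        parse_newick("((A,B);")


@pytest.mark.parametrize(
    "newick",
    [
        "((A:1,B:1)90:1,(C:1,(D:1,E:1)80:1)70:1);",
        "(((a:1,b:1):1,c:1):1,(d:1,e:1):1,f:1);",
    ],
)
def test_write_parse_round_trip_keeps_topology(newick):
    tree = parse_newick(newick)
    again = parse_newick(write_newick(tree))
    assert bipartitions(tree) == bipartitions(again)


# ---------------------------------------------------------------------------
# monophyly
# ---------------------------------------------------------------------------


def test_monophyly_basic_cases():
    tree = parse_newick("((a1,a2),(b1,b2));")
    assert is_monophyletic(tree, {"a1", "a2"})[0]
    assert not is_monophyletic(tree, {"a1", "b1"})[0]
    with pytest.raises(TreeError):
        is_monophyletic(tree, {"zz"})


def _random_newick(taxa, rng):
    parts = list(taxa)
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        b = parts.pop(j)
        a = parts.pop(i)
        parts.append(f"({a}:{rng.uniform(0.05, 0.3):.3f},{b}:{rng.uniform(0.05, 0.3):.3f})")
    return parts[0] + ";"


def test_monophyly_agrees_with_bipartition_enumeration():
    rng = np.random.default_rng(4)
    for trial in range(10):
        taxa = [f"t{i:02d}" for i in range(12)]
        tree = parse_newick(_random_newick(taxa, rng))
        oracle_bips = all_bipartitions_by_enumeration(tree)
        mine = bipartitions(tree)
        assert mine == oracle_bips
        for _ in range(5):
            size = int(rng.integers(2, 11))
            subset = frozenset(rng.choice(taxa, size=size, replace=False))
            leaves = frozenset(taxa)
            ref = min(leaves)
            canon = subset if ref not in subset else leaves - subset
            expected = canon in oracle_bips or len(subset) in (1, len(taxa) - 1, len(taxa))
            assert is_monophyletic(tree, subset)[0] == expected


# ---------------------------------------------------------------------------
# sister lineage
# ---------------------------------------------------------------------------

SISTER_LM = LineageMap(
    {"AGF1": "recipient", "AGF2": "recipient", "BacX": "bacteria", "BacY": "bacteria"}
)


def test_sister_donor_with_support():
    tree = parse_newick("((AGF1:0.1,AGF2:0.1)98:0.4,(BacX:0.1,BacY:0.1):0.2);")
    res = sister_lineage(tree, ["AGF1", "AGF2"], SISTER_LM)
    assert res.donor_hypothesis == "bacteria"
    assert res.stem_support == 98.0
    assert res.sister_taxa == ["BacX", "BacY"]


def test_low_support_gives_unresolved():
    tree = parse_newick("((AGF1:0.1,AGF2:0.1)50:0.4,(BacX:0.1,BacY:0.1):0.2);")
    res = sister_lineage(tree, ["AGF1", "AGF2"], SISTER_LM, support_threshold=80.0)
    assert res.donor_hypothesis is None
    assert res.stem_support == 50.0


def test_non_monophyletic_clade_rejected():
    tree = parse_newick("((AGF1:0.1,BacX:0.1):0.2,(AGF2:0.1,BacY:0.1):0.2);")
    with pytest.raises(MonophylyError):
        sister_lineage(tree, ["AGF1", "AGF2"], SISTER_LM)


def test_planted_donor_recovered_across_seeds(small_cfg):
    """The sister lineage of the recipient clade names the planted donor
    group in at least 18 of 20 replicate simulations."""
    from neogut.lineage import taxon_of_protein
    from neogut.synthio import SimConfig, decode_seq, simulate_dataset

    hits = 0
    trials = 0
    for seed in range(10):
        cfg = SimConfig(
            n_recipient_taxa=5,
            n_outgroup_taxa=2,
            n_donor_taxa={"bacteria": 3, "animal": 3, "plant": 3},
            n_families=6,
            n_planted_hgt=2,
            n_planted_unique_domains=0,
            n_planted_lost_domains=0,
            loss_rate=0.0,
            redundancy_rate=0.0,
            seed=100 + seed,
        )
        ds = simulate_dataset(cfg)
        for fid in ds.ledger.families_with_label("hgt"):
            trials += 1
            fam = ds.ledger.families[fid]
            aln = {g: decode_seq(s) for g, s in ds.sequences[fid].items()}
            tree = infer_nj_tree(aln, n_bootstrap=30, seed=seed)
            recipients = sorted(
                g for g in aln if taxon_of_protein(g).startswith("agf")
            )
            if not is_monophyletic(tree, recipients)[0]:
                continue
            plm = LineageMap(
                {g: ds.lineage_map.group_of(taxon_of_protein(g)) for g in aln}
            )
            res = sister_lineage(tree, recipients, plm, support_threshold=0.0)
            if res.donor_hypothesis == fam.donor_group:
                hits += 1
    assert trials == 20
    assert hits >= 18


# ---------------------------------------------------------------------------
# pruning likelihood
# ---------------------------------------------------------------------------


def test_single_leaf_is_equilibrium_frequency():
    tree = parse_newick("(A:0.0);")
    ll = site_loglik({"A": "AC"}, tree, SubstModel())
    assert np.allclose(ll, np.log(1.0 / 20.0))


def test_two_leaf_closed_form():
    tree = parse_newick("(A:0.3,B:0.2);")
    ll = site_loglik({"A": "AC", "B": "AD"}, tree, SubstModel())
    t = 0.5
    p_same = 1 / 20 + (19 / 20) * np.exp(-20 * t / 19)
    p_diff = 1 / 20 - (1 / 20) * np.exp(-20 * t / 19)
    assert np.allclose(ll, [np.log(p_same / 20), np.log(p_diff / 20)])


@pytest.mark.parametrize(
    "newick, labels",
    [
        ("((A:0.1,B:0.25):0.15,(C:0.3,D:0.05):0.2);", "ABCD"),
        ("((A:0.2,(B:0.1,C:0.1):0.1):0.1,(D:0.3,E:0.15):0.05);", "ABCDE"),
        ("(A:0.1,B:0.2,C:0.3);", "ABC"),
    ],
)
def test_pruning_equals_exhaustive_enumeration(newick, labels):
    rng = np.random.default_rng(8)
    tree = parse_newick(newick)
    aln = {x: "".join(rng.choice(list(ALPHA), 6)) for x in labels}
    model = SubstModel()
    mine = site_loglik(aln, tree, model)
    oracle = enumeration_site_loglik(aln, tree, model)
    assert np.abs(mine - oracle).max() < 1e-8


def test_leaf_mismatch_lists_differences():
    tree = parse_newick("(A:0.1,B:0.1);")
    with pytest.raises(TreeError, match="C"):
        site_loglik({"A": "AA", "C": "AA"}, tree, SubstModel())


def test_gamma_rates_average_to_mean_one():
    model = SubstModel(n_rate_categories=4, gamma_alpha=0.5)
    rates = model.rate_categories()
    assert len(rates) == 4
    assert rates.mean() == pytest.approx(1.0)
    tree = parse_newick("(A:0.3,B:0.2);")
    ll = site_loglik({"A": "AC", "B": "AD"}, tree, model)
    assert np.all(np.isfinite(ll))


# ---------------------------------------------------------------------------
# constrained topologies
# ---------------------------------------------------------------------------


def test_already_monophyletic_returns_notice():
    tree = parse_newick("((g1:0.1,g2:0.1):0.2,(o1:0.1,o2:0.1):0.2);")
    out, notice = constrain_monophyly(tree, ["g1", "g2"])
    assert notice is not None
    assert bipartitions(out) == bipartitions(tree)


def test_intruder_regrafted_outside_group():
    tree = parse_newick(
        "(((g1:0.1,x1:0.1):0.1,(g2:0.1,g3:0.1):0.1):0.3,(o1:0.1,o2:0.1):0.2);"
    )
    out, notice = constrain_monophyly(tree, ["g1", "g2", "g3"])
    assert notice is None
    assert is_monophyletic(out, {"g1", "g2", "g3"})[0]
    assert sorted(l for l in (lf.taxon.label for lf in out.leaf_node_iter())) == [
        "g1", "g2", "g3", "o1", "o2", "x1",
    ]


def test_constrained_likelihood_not_better_than_truth():
    """Data simulated on a tree where the group is split: forcing the
    group monophyletic can only lower the total log-likelihood."""
    from neogut.synthio import SimConfig, decode_seq, simulate_dataset
    from neogut.lineage import taxon_of_protein

    cfg = SimConfig(
        n_recipient_taxa=4,
        n_outgroup_taxa=2,
        n_donor_taxa={"bacteria": 4, "animal": 2},
        n_families=3,
        n_planted_hgt=1,
        n_planted_unique_domains=0,
        n_planted_lost_domains=0,
        loss_rate=0.0,
        redundancy_rate=0.0,
        seed=21,
    )
    ds = simulate_dataset(cfg)
    fid = ds.ledger.families_with_label("hgt")[0]
    fam = ds.ledger.families[fid]
    aln = {g: decode_seq(s) for g, s in ds.sequences[fid].items()}
    tree = infer_nj_tree(aln)
    donors = sorted(
        g for g in aln if ds.lineage_map.group_of(taxon_of_protein(g)) == fam.donor_group
    )
    model = SubstModel()
    constrained, notice = constrain_monophyly(tree, donors, aln, model)
    if notice is not None:
        pytest.skip("NJ already placed the donor group monophyletic")
    unconstrained_ll = site_loglik(aln, tree, model).sum()
    constrained_ll = site_loglik(aln, constrained, model).sum()
    assert constrained_ll <= unconstrained_ll + 1e-6


# ---------------------------------------------------------------------------
# AU test
# ---------------------------------------------------------------------------


def test_identical_topologies_split_the_p_value():
    rng = np.random.default_rng(1)
    row = rng.normal(-8.0, 1.5, size=100)
    res = au_test(np.vstack([row, row]), AUConfig(seed=3, n_replicates=1000))
    assert abs(res.pvalues[0] - 0.5) < 0.05
    assert abs(res.pvalues[1] - 0.5) < 0.05


def test_dominated_topology_rejected_and_matches_naive_rell():
    rng = np.random.default_rng(2)
    good = rng.normal(-8.0, 1.0, size=100)
    ll = np.vstack([good, good - 10.0])  # worse by 10 units at every site
    res = au_test(ll, AUConfig(seed=5, n_replicates=1000))
    assert res.pvalues[1] < 0.05
    assert res.pvalues[0] > 0.95
    counts = naive_rell_winner_counts(ll, 500, seed=6)
    assert counts[1] == 0.0 and counts[0] == 1.0


def test_p_values_always_in_unit_interval():
    for seed in range(50):
        rng = np.random.default_rng(seed)
        ll = rng.normal(-6.0, 2.0, size=(3, 40))
        res = au_test(ll, AUConfig(seed=seed, n_replicates=100))
        assert np.all(res.pvalues >= 0.0) and np.all(res.pvalues <= 1.0)


def test_best_topology_p_dominates_sitewise_loser():
    rng = np.random.default_rng(9)
    good = rng.normal(-7.0, 1.0, size=60)
    ll = np.vstack([good, good - 0.4])
    res = au_test(ll, AUConfig(seed=11, n_replicates=500))
    assert res.pvalues[0] >= res.pvalues[1]


def test_too_few_sites_rejected():
    with pytest.raises(ValueError):
        au_test(np.zeros((2, 5)), AUConfig(seed=0))
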