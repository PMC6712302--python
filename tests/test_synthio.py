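"""Generator behaviour: planted structure, determinism, emitted dialects."""

import numpy as np
import pytest

from neogut.domainmat import architectures, parse_domtbl
from neogut.synthio import (
    SimConfig,
    SimConfigError,
    decode_seq,
    emit_domtbl,
    emit_hits,
    evolve_families,
    evolve_sequences,
    simulate_dataset,
    simulate_species_tree,
)


# ---------------------------------------------------------------------------
# configuration validation
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "kwargs, fragment",
    [
        ({"n_recipient_taxa": 1}, "n_recipient_taxa"),
        ({"n_outgroup_taxa": 0}, "n_outgroup_taxa"),
        ({"loss_rate": 1.5}, "loss_rate"),
        ({"redundancy_rate": -0.1}, "redundancy_rate"),
        ({"n_families": 5, "n_planted_hgt": 10}, "planted"),
        ({"n_planted_hgt": 1, "n_donor_taxa": {}}, "donor"),
    ],
)
def test_invalid_config_names_offending_field(kwargs, fragment):
    with pytest.raises(SimConfigError, match=fragment):
        SimConfig(**kwargs)


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------


def test_minimal_tree_recipients_monophyletic():
    cfg = SimConfig(
        n_recipient_taxa=2, n_outgroup_taxa=2, n_donor_taxa={},
        n_planted_hgt=0, n_families=4, n_planted_unique_domains=0,
        n_planted_lost_domains=0, seed=0,
    )
    sp = simulate_species_tree(cfg)
    assert len(sp.leaf_labels()) == 4
    mrca = sp.tree.mrca(taxon_labels=cfg.taxa_of_group("recipient"))
    assert {lf.taxon.label for lf in mrca.leaf_iter()} == set(
        cfg.taxa_of_group("recipient")
    )


def test_species_tree_deterministic():
    cfg = SimConfig(seed=1)
    assert simulate_species_tree(cfg).newick == simulate_species_tree(cfg).newick


def test_reference_scale_tree_long_recipient_stem():
    """31 taxa; the recipient stem dwarfs the median internal branch,
    checked by an independent traversal."""
    cfg = SimConfig(n_donor_taxa={}, n_planted_hgt=0, seed=3)
    sp = simulate_species_tree(cfg)
    assert len(sp.leaf_labels()) == 31
    recipients = set(cfg.taxa_of_group("recipient"))
    stem = None
    internal_lengths = []
    for node in sp.tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = {lf.taxon.label for lf in node.leaf_iter()}
        if below == recipients:
            stem = node.edge.length
        else:
            internal_lengths.append(node.edge.length)
    assert stem is not None
    assert stem / float(np.median(internal_lengths)) >= 5.0


# ---------------------------------------------------------------------------
# family evolution
# ---------------------------------------------------------------------------


def test_no_loss_families_cover_all_descendants(small_cfg, small_dataset):
    lm = small_dataset.lineage_map
    all_taxa = set(lm.taxa())
    recipients = set(lm.recipients)
    outgroups = set(lm.outgroups)
    for fam in small_dataset.ledger.families.values():
        present = set(fam.taxa_present())
        if fam.label == "shared":
            assert present == all_taxa
        elif fam.label == "unique":
            assert present == recipients
        elif fam.label == "lost":
            assert present == all_taxa - recipients
        else:  # hgt: donor clade + recipients + auxiliary homolog clade
            expected = recipients | set(lm.taxa(fam.donor_group))
            if fam.aux_group:
                expected |= set(lm.taxa(fam.aux_group))
            assert present == expected


def test_planted_counts_partition_families(small_cfg, small_dataset):
    counts = small_dataset.ledger.label_counts()
    assert counts["unique"] == small_cfg.n_planted_unique_domains
    assert counts["lost"] == small_cfg.n_planted_lost_domains
    assert counts["hgt"] == small_cfg.n_planted_hgt
    assert sum(counts.values()) == small_cfg.n_families


def test_loss_rate_matches_closed_form_survival():
    """Mean presence of root-origin families per taxon stays within 3
    binomial standard deviations of (1-p)^k, k = branches on the
    root-to-leaf path."""
    cfg = SimConfig(
        n_recipient_taxa=8,
        n_outgroup_taxa=4,
        n_donor_taxa={},
        n_families=1000,
        n_planted_hgt=0,
        n_planted_unique_domains=0,
        n_planted_lost_domains=0,
        loss_rate=0.1,
        seed=5,
    )
    sp = simulate_species_tree(cfg)
    families, ledger = evolve_families(sp, cfg)
    depth = {}
    for leaf in sp.tree.leaf_node_iter():
        k, node = 0, leaf
        while node.parent_node is not None:
            k += 1
            node = node.parent_node
        depth[leaf.taxon.label] = k
    for taxon, k in depth.items():
        p_survive = (1.0 - cfg.loss_rate) ** k
        observed = sum(1 for fam in families.values() if fam.get(taxon))
        sd = np.sqrt(cfg.n_families * p_survive * (1.0 - p_survive))
        assert abs(observed - cfg.n_families * p_survive) <= 3.0 * sd


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------


def test_zero_branch_lengths_give_identical_sequences(small_cfg, small_dataset):
    sp = simulate_species_tree(small_cfg)
    for edge in sp.tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = 0.0
    fam = next(
        f for f in small_dataset.ledger.families.values() if f.label == "shared"
    )
    seqs = evolve_sequences(sp, fam, small_cfg, seed=4)
    first_per_taxon = [seqs[genes[0]] for genes in fam.members.values()]
    for seq in first_per_taxon[1:]:
        assert np.array_equal(seq, first_per_taxon[0])


def test_redundant_variants_stay_above_90_percent_identity(small_dataset):
    for fid, seqs in small_dataset.sequences.items():
        fam = small_dataset.ledger.families[fid]
        for taxon, genes in fam.members.items():
            for variant in genes[1:]:
                same = int((seqs[genes[0]] == seqs[variant]).sum())
                assert same / fam.length >= 0.90


def test_transfer_families_most_similar_to_donor():
    """Across seeds, recipient copies of a transferred family are closer
    to the donor kingdom than to the auxiliary homolog kingdom, measured
    directly on the emitted sequences."""
    wins = 0
    for seed in range(20):
        cfg = SimConfig(
            n_recipient_taxa=4,
            n_outgroup_taxa=2,
            n_donor_taxa={"bacteria": 3, "animal": 3},
            n_families=6,
            n_planted_hgt=2,
            n_planted_unique_domains=0,
            n_planted_lost_domains=0,
            loss_rate=0.0,
            redundancy_rate=0.0,
            seed=seed,
        )
        ds = simulate_dataset(cfg)
        for fid in ds.ledger.families_with_label("hgt"):
            fam = ds.ledger.families[fid]
            seqs = ds.sequences[fid]
            donors = set(ds.lineage_map.taxa(fam.donor_group))
            aux = set(ds.lineage_map.taxa(fam.aux_group))
            by_group = {"recipient": [], "donor": [], "aux": []}
            for gene, seq in seqs.items():
                taxon = gene.split("|")[0]
                if taxon in donors:
                    by_group["donor"].append(seq)
                elif taxon in aux:
                    by_group["aux"].append(seq)
                elif taxon.startswith("agf"):
                    by_group["recipient"].append(seq)

            def mean_identity(a_list, b_list):
                vals = [
                    (a == b).mean() for a in a_list for b in b_list
                ]
                return float(np.mean(vals))

            ident_donor = mean_identity(by_group["recipient"], by_group["donor"])
            ident_aux = mean_identity(by_group["recipient"], by_group["aux"])
            if ident_donor > ident_aux:
                wins += 1
    assert wins == 40  # 2 transfer families x 20 seeds


# ---------------------------------------------------------------------------
# hit emission
# ---------------------------------------------------------------------------


def test_identical_pair_scores_maximum():
    seq = np.zeros(100, dtype=np.int8)
    rows = emit_hits({"F1": {"a|x_1": seq, "a|y_1": seq.copy()}}, score_floor=50.0)
    cross = [r.split("\t") for r in rows if r.split("\t")[0] != r.split("\t")[1]]
    assert cross and all(float(r[2]) == 100.0 and float(r[11]) == 200.0 for r in cross)


def test_unrelated_pair_below_floor_absent():
    rng = np.random.default_rng(0)
    a = rng.integers(0, 20, 120).astype(np.int8)
    b = rng.integers(0, 20, 120).astype(np.int8)
    rows = emit_hits({"F1": {"a|x_1": a, "b|y_1": b}}, score_floor=50.0)
    assert all(r.split("\t")[0] == r.split("\t")[1] for r in rows)


def test_bitscore_strictly_decreases_with_mutations():
    base = np.zeros(100, dtype=np.int8)
    scores = []
    for k in range(0, 51, 5):
        other = base.copy()
        other[:k] = 1
        rows = emit_hits({"F": {"a|p_1": base, "b|q_1": other}}, score_floor=-1e9)
        row = next(r for r in rows if r.startswith("a|p_1\tb|q_1"))
        scores.append(float(row.split("\t")[11]))
    assert all(s1 > s2 for s1, s2 in zip(scores, scores[1:]))


# ---------------------------------------------------------------------------
# domain-table emission
# ---------------------------------------------------------------------------


def test_domtbl_preserves_architecture_order(small_dataset, small_paths):
    hits = parse_domtbl(small_paths["domtbl"])
    archs = architectures(hits)
    for fid in small_dataset.ledger.families_with_label("hgt"):
        fam = small_dataset.ledger.families[fid]
        if len(fam.domains) < 2:
            continue
        for gene in fam.genes():
            names = [d[0] for d in archs[gene]]
            assert names == [d[0] for d in fam.domains]
            starts = [d[1] for d in archs[gene]]
            assert starts == sorted(starts)


def test_decoy_rows_all_above_cutoff(small_dataset):
    rows = emit_domtbl(small_dataset.ledger, n_decoys=25, seed=9)
    decoys = [r for r in rows if r.startswith("DECOY")]
    assert len(decoys) == 25
    assert all(float(r.split()[12]) > 1e-2 for r in decoys)


def test_domtbl_round_trip_recovers_ledger_architectures(small_dataset, tmp_path):
    rows = emit_domtbl(small_dataset.ledger, n_decoys=30, seed=9)
    path = tmp_path / "scan.domtbl"
    path.write_text("\n".join(rows) + "\n")
    hits = parse_domtbl(path)  # default 1e-2 cutoff filters every decoy
    assert not hits["domain_name"].str.startswith("DECOY").any()
    assert architectures(hits) == small_dataset.ledger.architectures()


# ---------------------------------------------------------------------------
# determinism
# ---------------------------------------------------------------------------


def test_same_seed_byte_identical_outputs(small_cfg):
    a = simulate_dataset(small_cfg)
    b = simulate_dataset(small_cfg)
    assert a.species_tree.newick == b.species_tree.newick
    assert a.fasta_records() == b.fasta_records()
    assert emit_hits(a.sequences) == emit_hits(b.sequences)
    assert emit_domtbl(a.ledger, seed=1) == emit_domtbl(b.ledger, seed=1)
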