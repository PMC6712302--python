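"""Synthetic comparative-genomics datasets with a known truth ledger.

This module emulates the data layout of a two-clade comparative study: a
recipient clade of gut-fungus taxa attached to the rest of the tree by a
long stem branch, a small fungal outgroup clade, and several non-fungal
reference clades (bacteria, animals, plants) that can act as donors of
horizontally transferred gene families.  Gene families evolve on the
species tree under a root-origin / per-branch-Bernoulli-loss model, with
planted recipient-unique families, recipient-lost families and inter-kingdom
transfers recorded in a :class:`TruthLedger`.  Protein sequences evolve
along the induced gene trees under a Poisson (equal-rates) substitution
model, and the results are emitted in the file dialects the analysis
pipeline consumes: protein FASTA, 12-column similarity-hit tables and
HMMER3-style per-domain tables.

Everything is deterministic given the :class:`SimConfig` seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .lineage import LineageMap

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA = np.frombuffer(AA_ALPHABET.encode(), dtype=np.uint8)

#: Synthetic bitscore: ``max(0, LAMBDA*matches - MU*mismatches)``.  Any
#: monotone surrogate of alignment quality suffices for the downstream
#: filters; this one decreases strictly with each added mismatch, crosses
#: zero at 1/3 identity (roughly where real protein hits disappear) and is
#: zero for unrelated sequences (~5% identity), which is what the score
#: floor relies on.  E-value = K * m * n * 2**(-bitscore) with K = 0.1.
LAMBDA_MATCH = 2.0
MU_MISMATCH = 1.0
EVALUE_K = 0.1
MIN_EVALUE = 1e-180

GROUP_PREFIX = {
    "recipient": "agf",
    "outgroup": "chy",
    "other_fungi": "fun",
    "animal": "ani",
    "plant": "pla",
    "bacteria": "bac",
    "archaea": "arc",
    "protist": "pro",
}

FAMILY_LABELS = ("shared", "unique", "lost", "hgt")


class SimConfigError(ValueError):
    """Raised when a simulation configuration field is invalid."""


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic generator.

    Defaults emulate the scale of the motivating study: 26 recipient taxa,
    5 fungal outgroup taxa, 500 gene families with 20 planted
    recipient-unique families, 20 recipient-lost families and 20 transfers
    split across bacterial, animal and plant donors.
    """

    n_recipient_taxa: int = 26
    n_outgroup_taxa: int = 5
    n_donor_taxa: dict[str, int] = field(
        default_factory=lambda: {"bacteria": 4, "animal": 4, "plant": 4}
    )
    n_families: int = 500
    family_birth_rate: float = 0.0
    loss_rate: float = 0.05
    n_planted_hgt: int = 20
    n_planted_unique_domains: int = 20
    n_planted_lost_domains: int = 20
    redundancy_rate: float = 0.2
    fusion_rate: float = 0.5
    seq_length_range: tuple[int, int] = (150, 400)
    transfer_branch: float = 0.05
    score_floor: float = 50.0
    n_decoys: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_recipient_taxa", "n_outgroup_taxa"):
            if getattr(self, name) < 2:
                raise SimConfigError(f"{name} must be >= 2, got {getattr(self, name)}")
        for name in (
            "n_families",
            "n_planted_hgt",
            "n_planted_unique_domains",
            "n_planted_lost_domains",
            "n_decoys",
        ):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("family_birth_rate", "loss_rate", "redundancy_rate", "fusion_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name} must be a probability in [0, 1], got {v}")
        for group, n in self.n_donor_taxa.items():
            if group not in GROUP_PREFIX:
                raise SimConfigError(f"n_donor_taxa: unknown group {group!r}")
            if n < 0:
                raise SimConfigError(f"n_donor_taxa[{group!r}] must be >= 0, got {n}")
        n_planted = (
            self.n_planted_hgt
            + self.n_planted_unique_domains
            + self.n_planted_lost_domains
        )
        if n_planted > self.n_families:
            raise SimConfigError(
                f"planted families ({n_planted}) exceed n_families ({self.n_families})"
            )
        if self.n_planted_hgt > 0 and not any(self.n_donor_taxa.values()):
            raise SimConfigError("n_planted_hgt > 0 requires at least one donor taxon")

    # -- derived taxon bookkeeping --------------------------------------

    def taxa_of_group(self, group: str) -> list[str]:
        prefix = GROUP_PREFIX[group]
        if group == "recipient":
            n = self.n_recipient_taxa
        elif group == "outgroup":
            n = self.n_outgroup_taxa
        else:
            n = self.n_donor_taxa.get(group, 0)
        return [f"{prefix}{i:02d}" for i in range(1, n + 1)]

    @property
    def donor_groups(self) -> list[str]:
        return sorted(g for g, n in self.n_donor_taxa.items() if n > 0)

    def lineage_map(self) -> LineageMap:
        assignments: dict[str, str] = {}
        for group in ("recipient", "outgroup", *self.donor_groups):
            for taxon in self.taxa_of_group(group):
                assignments[taxon] = group
        return LineageMap(assignments)


@dataclass
class SpeciesTree:
    """A rooted binary species tree with the recipient clade on a long stem."""

    tree: dendropy.Tree
    taxon_labels: list[str]

    @property
    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def stem_to_median_internal_ratio(self, clade_taxa: set[str]) -> float:
        """Length of the stem above the ``clade_taxa`` MRCA over the median
        internal branch length of the rest of the tree."""
        mrca = self.tree.mrca(taxon_labels=sorted(clade_taxa))
        stem = mrca.edge.length or 0.0
        internals = [
            nd.edge.length
            for nd in self.tree.preorder_node_iter()
            if nd.parent_node is not None
            and not nd.is_leaf()
            and nd is not mrca
            and nd.edge.length is not None
        ]
        med = float(np.median(internals)) if internals else 0.0
        return stem / med if med > 0 else float("inf")


@dataclass
class FamilyTruth:
    """Planted truth for one gene family."""

    family_id: str
    label: str  # shared | unique | lost | hgt
    donor_group: str | None
    length: int
    members: dict[str, list[str]]  # taxon -> gene ids (variants included)
    domains: list[tuple[str, int, int]]  # (name, env_start, env_end), 1-based
    #: For transfer families: a second, distant non-donor kingdom that also
    #: carries homologs (as real transferred domains do), making gene-tree
    #: constraints on the donor group non-trivial.
    aux_group: str | None = None

    def genes(self) -> list[str]:
        return [g for taxon in sorted(self.members) for g in self.members[taxon]]

    def taxa_present(self) -> list[str]:
        return sorted(t for t, genes in self.members.items() if genes)


@dataclass
class TruthLedger:
    """Ground truth for a synthetic dataset: one entry per family plus the
    per-protein domain architecture implied by family membership."""

    families: dict[str, FamilyTruth] = field(default_factory=dict)

    def architectures(self) -> dict[str, list[tuple[str, int, int]]]:
        archs: dict[str, list[tuple[str, int, int]]] = {}
        for fam in self.families.values():
            for gene in fam.genes():
                archs[gene] = list(fam.domains)
        return archs

    def label_counts(self) -> dict[str, int]:
        counts = {label: 0 for label in FAMILY_LABELS}
        for fam in self.families.values():
            counts[fam.label] += 1
        return counts

    def families_with_label(self, label: str) -> list[str]:
        return sorted(f for f, t in self.families.items() if t.label == label)

    def to_json(self, path: str | Path) -> None:
        payload = {
            fid: {
                "label": fam.label,
                "donor_group": fam.donor_group,
                "aux_group": fam.aux_group,
                "length": fam.length,
                "members": {t: fam.members[t] for t in sorted(fam.members)},
                "domains": [list(d) for d in fam.domains],
            }
            for fid, fam in sorted(self.families.items())
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthLedger":
        payload = json.loads(Path(path).read_text())
        families = {
            fid: FamilyTruth(
                family_id=fid,
                label=d["label"],
                donor_group=d["donor_group"],
                length=d["length"],
                members={t: list(g) for t, g in d["members"].items()},
                domains=[tuple(x) for x in d["domains"]],
                aux_group=d.get("aux_group"),
            )
            for fid, d in payload.items()
        }
        return cls(families)

    def to_tsv(self, path: str | Path) -> None:
        lines = ["family_id\tlabel\tdonor_group\ttaxon\tgene_id"]
        for fid, fam in sorted(self.families.items()):
            for taxon in sorted(fam.members):
                for gene in fam.members[taxon]:
                    lines.append(
                        f"{fid}\t{fam.label}\t{fam.donor_group or '-'}\t{taxon}\t{gene}"
                    )
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------


def _random_clade(
    labels: list[str],
    rng: np.random.Generator,
    ns: dendropy.TaxonNamespace,
    internal_range: tuple[float, float] = (0.015, 0.035),
    terminal_range: tuple[float, float] = (0.07, 0.11),
) -> dendropy.Node:
    """Random binary subtree over ``labels`` built by sequential joining."""
    nodes = []
    for label in labels:
        nd = dendropy.Node()
        nd.taxon = ns.require_taxon(label=label)
        nd.edge.length = float(rng.uniform(*terminal_range))
        nodes.append(nd)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = dendropy.Node()
        parent.add_child(left)
        parent.add_child(right)
        parent.edge.length = float(rng.uniform(*internal_range))
        nodes.append(parent)
    return nodes[0]


def simulate_species_tree(cfg: SimConfig) -> SpeciesTree:
    """Rooted binary species tree: recipient clade on a long stem, outgroup
    as its closest relatives, donor clades attached successively outside.

    The recipient stem is set to at least five times the median internal
    branch length so that the recipient radiation is recent relative to its
    separation from other lineages (a long naked stem followed by a rapid
    radiation).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    ns = dendropy.TaxonNamespace()

    recipient = _random_clade(cfg.taxa_of_group("recipient"), rng, ns)
    outgroup = _random_clade(cfg.taxa_of_group("outgroup"), rng, ns)
    core = dendropy.Node()
    core.add_child(recipient)
    core.add_child(outgroup)
    outgroup.edge.length = float(rng.uniform(0.03, 0.06))
    core.edge.length = float(rng.uniform(0.03, 0.06))

    # Donor lineages attach well outside the fungal core: inter-kingdom
    # distances must dominate the within-kingdom ones so that vertical
    # (fungal) homology always outscores chance donor-group similarity.
    root = core
    for group in cfg.donor_groups:
        clade = _random_clade(cfg.taxa_of_group(group), rng, ns)
        clade.edge.length = float(rng.uniform(0.10, 0.15))
        join = dendropy.Node()
        join.add_child(root)
        join.add_child(clade)
        join.edge.length = float(rng.uniform(0.08, 0.12))
        root = join
    root.edge.length = None

    tree = dendropy.Tree(taxon_namespace=ns, seed_node=root)
    tree.is_rooted = True

    # Fix the recipient stem length from the realized internal branches.
    internals = [
        nd.edge.length
        for nd in tree.preorder_node_iter()
        if nd.parent_node is not None and not nd.is_leaf() and nd is not recipient
    ]
    median_internal = float(np.median(internals))
    recipient.edge.length = max(0.15, 5.5 * median_internal)

    labels = sorted(t.label for t in ns)
    return SpeciesTree(tree=tree, taxon_labels=labels)


# ---------------------------------------------------------------------------
# family evolution
# ---------------------------------------------------------------------------


def _leaves_below(node: dendropy.Node) -> set[str]:
    return {lf.taxon.label for lf in node.leaf_iter()}


def _surviving_leaves(
    origin: dendropy.Node, loss_rate: float, rng: np.random.Generator
) -> set[str]:
    """Leaves that retain a family originating on the edge above ``origin``.

    Loss is a Bernoulli event per branch strictly below the origin; a loss
    removes the family from the whole subtree under that branch, so the
    survival probability of a leaf is ``(1 - loss_rate)**k`` with ``k`` the
    number of branches on the origin-to-leaf path.
    """
    alive: set[str] = set()

    def descend(node: dendropy.Node) -> None:
        if node.is_leaf():
            alive.add(node.taxon.label)
            return
        for child in node.child_nodes():
            if loss_rate > 0.0 and rng.random() < loss_rate:
                continue
            descend(child)

    descend(origin)
    return alive


def evolve_families(
    species_tree: SpeciesTree, cfg: SimConfig
) -> tuple[dict[str, dict[str, list[str]]], TruthLedger]:
    """Evolve gene-family presence/absence along the species tree.

    Returns ``(families, ledger)`` where ``families`` maps family id ->
    taxon -> gene ids.  Background families originate at the root (or, with
    probability ``family_birth_rate``, on a random internal branch);
    planted unique families originate on the recipient stem; planted lost
    families originate at the root and are forcibly lost on the recipient
    stem; planted transfer families originate at a donor-clade root with a
    copy established at the recipient-clade root.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 202]))
    tree = species_tree.tree
    lm = cfg.lineage_map()
    recipients = set(lm.recipients)
    recipient_mrca = tree.mrca(taxon_labels=sorted(recipients))
    donor_mrcas: dict[str, dendropy.Node] = {}
    for group in cfg.donor_groups:
        taxa = lm.taxa(group)
        donor_mrcas[group] = (
            tree.mrca(taxon_labels=taxa)
            if len(taxa) > 1
            else tree.find_node_with_taxon_label(taxa[0])
        )
    internal_nodes = [
        nd
        for nd in tree.preorder_node_iter()
        if nd.parent_node is not None and not nd.is_leaf()
    ]

    # Assign planted classes to randomly chosen family indices.
    n = cfg.n_families
    order = rng.permutation(n)
    labels = np.array(["shared"] * n, dtype=object)
    pos = 0
    for label, count in (
        ("unique", cfg.n_planted_unique_domains),
        ("lost", cfg.n_planted_lost_domains),
        ("hgt", cfg.n_planted_hgt),
    ):
        labels[order[pos : pos + count]] = label
        pos += count

    donor_cycle = cfg.donor_groups
    ledger = TruthLedger()
    families: dict[str, dict[str, list[str]]] = {}
    shared_fids: list[str] = []  # for fusion-partner domain sampling
    hgt_seen = 0

    lmin, lmax = cfg.seq_length_range
    for idx in range(n):
        fid = f"F{idx + 1:04d}"
        label = labels[idx]
        length = int(rng.integers(lmin, lmax + 1))
        donor_group: str | None = None
        aux_group: str | None = None

        if label == "shared":
            origin = tree.seed_node
            if cfg.family_birth_rate > 0.0 and rng.random() < cfg.family_birth_rate:
                origin = internal_nodes[int(rng.integers(len(internal_nodes)))]
            alive = _surviving_leaves(origin, cfg.loss_rate, rng)
        elif label == "unique":
            alive = _surviving_leaves(recipient_mrca, cfg.loss_rate, rng)
        elif label == "lost":
            alive = _surviving_leaves(tree.seed_node, cfg.loss_rate, rng)
            alive -= recipients  # forced loss on the recipient stem
        else:  # hgt
            donor_group = donor_cycle[hgt_seen % len(donor_cycle)]
            if len(donor_cycle) > 1:
                aux_group = donor_cycle[(hgt_seen + 1) % len(donor_cycle)]
            else:
                aux_group = None
            hgt_seen += 1
            alive = _surviving_leaves(donor_mrcas[donor_group], cfg.loss_rate, rng)
            alive |= _surviving_leaves(recipient_mrca, cfg.loss_rate, rng)
            if aux_group is not None:
                alive |= _surviving_leaves(donor_mrcas[aux_group], cfg.loss_rate, rng)

        members: dict[str, list[str]] = {}
        for taxon in sorted(alive):
            genes = [f"{taxon}|{fid}_1"]
            if cfg.redundancy_rate > 0.0 and rng.random() < cfg.redundancy_rate:
                genes.append(f"{taxon}|{fid}_1v2")
            members[taxon] = genes

        # Domain architecture shared by all members of the family.
        if label == "hgt":
            domains = [(f"PFX_{fid}", 10, max(11, int(0.55 * length)))]
            if rng.random() < cfg.fusion_rate and shared_fids:
                partner = shared_fids[int(rng.integers(len(shared_fids)))]
                domains.append((f"PF_{partner}", int(0.65 * length), length - 10))
        else:
            domains = [(f"PF_{fid}", 10, length - 10)]
            if label == "shared":
                shared_fids.append(fid)

        ledger.families[fid] = FamilyTruth(
            family_id=fid,
            label=str(label),
            donor_group=donor_group,
            length=length,
            members=members,
            domains=domains,
            aux_group=aux_group,
        )
        families[fid] = members

    return families, ledger


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------


def _p_different(t: float) -> float:
    """Probability a site differs across a branch of length ``t`` under the
    20-state Poisson model (equal exchangeabilities, uniform frequencies)."""
    return (19.0 / 20.0) * (1.0 - np.exp(-20.0 * t / 19.0))


def _mutate(seq: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    if t <= 0.0:
        return out
    mask = rng.random(seq.size) < _p_different(t)
    k = int(mask.sum())
    if k:
        out[mask] = (out[mask] + rng.integers(1, 20, size=k)) % 20
    return out


def _gene_tree_for_family(
    species_tree: SpeciesTree, fam: FamilyTruth, cfg: SimConfig
) -> dendropy.Tree:
    """Induced gene tree of a family.

    For transfer families the induced recipient subtree is grafted inside
    the donor clade (onto the terminal branch of the first donor taxon) with
    a short transfer branch, so donor sequences end up most similar to the
    recipient copies and the recipient clade is nested within the donor
    clade, as expected for a post-transfer gene tree.
    """
    present = fam.taxa_present()
    if not present:
        raise ValueError(f"family {fam.family_id} has no surviving members")
    lm = cfg.lineage_map()
    base = dendropy.Tree(species_tree.tree)  # deep clone, shared namespace

    if fam.label != "hgt" or fam.donor_group is None:
        sub = base.extract_tree_with_taxa_labels(labels=present)
        sub.is_rooted = True
        return sub

    donor_taxa = [t for t in present if lm.group_of(t) == fam.donor_group]
    recip_taxa = [t for t in present if lm.group_of(t) == "recipient"]
    other_taxa = [t for t in present if t not in donor_taxa and t not in recip_taxa]
    if not donor_taxa or not recip_taxa:
        sub = base.extract_tree_with_taxa_labels(labels=present)
        sub.is_rooted = True
        return sub

    # Donor clade plus any distant (auxiliary) homolog clades, related by
    # the species topology; recipients are grafted inside the donor clade.
    donor_tree = base.extract_tree_with_taxa_labels(labels=donor_taxa + other_taxa)
    recip_tree = dendropy.Tree(species_tree.tree).extract_tree_with_taxa_labels(
        labels=recip_taxa
    )
    # Graft the recipient subtree onto the midpoint of the first donor
    # taxon's terminal branch.
    host_leaf = donor_tree.find_node_with_taxon_label(donor_taxa[0])
    parent = host_leaf.parent_node
    half = (host_leaf.edge.length or 0.02) / 2.0
    attach = dendropy.Node()
    attach.edge.length = half
    if parent is None:  # single-donor-taxon clade: new root above the leaf
        attach.add_child(host_leaf)
        host_leaf.edge.length = half
        donor_tree.seed_node = attach
    else:
        parent.remove_child(host_leaf)
        parent.add_child(attach)
        host_leaf.edge.length = half
        attach.add_child(host_leaf)
    recip_root = recip_tree.seed_node
    recip_root.edge.length = cfg.transfer_branch
    attach.add_child(recip_root)
    donor_tree.is_rooted = True
    return donor_tree


def evolve_sequences(
    species_tree: SpeciesTree,
    fam: FamilyTruth,
    cfg: SimConfig,
    seed: int | np.random.SeedSequence,
) -> dict[str, np.ndarray]:
    """Simulate protein sequences for one family along its gene tree.

    Returns gene id -> integer-encoded sequence (indices into
    ``AA_ALPHABET``).  Redundant transcript variants are generated by
    mutating exactly 5% of sites of their parent gene, guaranteeing >90%
    identity.
    """
    rng = np.random.default_rng(seed)
    gtree = _gene_tree_for_family(species_tree, fam, cfg)
    root = gtree.seed_node
    root_seq = rng.integers(0, 20, size=fam.length).astype(np.int8)

    seqs: dict[str, np.ndarray] = {}
    stack: list[tuple[dendropy.Node, np.ndarray]] = [(root, root_seq)]
    while stack:
        node, seq = stack.pop()
        if node.is_leaf():
            taxon = node.taxon.label
            genes = fam.members.get(taxon, [])
            if genes:
                seqs[genes[0]] = seq
                for variant in genes[1:]:
                    n_mut = fam.length // 20  # 5% of sites, >90% identity kept
                    positions = rng.choice(fam.length, size=n_mut, replace=False)
                    vseq = seq.copy()
                    vseq[positions] = (
                        vseq[positions] + rng.integers(1, 20, size=n_mut)
                    ) % 20
                    seqs[variant] = vseq
            continue
        for child in node.child_nodes():
            stack.append((child, _mutate(seq, child.edge.length or 0.0, rng)))

    missing = set(fam.genes()) - set(seqs)
    if missing:
        raise RuntimeError(f"family {fam.family_id}: no sequence for {sorted(missing)}")
    return seqs


def decode_seq(seq: np.ndarray) -> str:
    return _AA[np.asarray(seq, dtype=np.intp)].tobytes().decode()


def encode_seq(seq: str) -> np.ndarray:
    lookup = {c: i for i, c in enumerate(AA_ALPHABET)}
    return np.array([lookup[c] for c in seq], dtype=np.int8)


# ---------------------------------------------------------------------------
# emission of standard file dialects
# ---------------------------------------------------------------------------


def emit_hits(
    sequences_by_family: dict[str, dict[str, np.ndarray]],
    score_floor: float = 50.0,
) -> list[str]:
    """Similarity rows (12-column tabular) for every ordered pair of
    sequences scoring at or above ``score_floor``.

    Bitscore and E-value follow the documented synthetic formulas (module
    constants).  Only pairs within a family are enumerated: unrelated
    sequences sit at background identity (~5%), for which the bitscore is
    clamped to zero and therefore always below any positive floor.
    Self-comparisons are emitted (downstream loaders flag them).
    """
    rows: list[str] = []
    for fid in sorted(sequences_by_family):
        genes = sorted(sequences_by_family[fid])
        if not genes:
            continue
        mat = np.stack([sequences_by_family[fid][g] for g in genes])
        m, L = mat.shape
        matches = (mat[:, None, :] == mat[None, :, :]).sum(axis=2)
        mismatches = L - matches
        bits = np.maximum(0.0, LAMBDA_MATCH * matches - MU_MISMATCH * mismatches)
        pident = 100.0 * matches / L
        evalue = np.maximum(EVALUE_K * L * L * np.exp2(-bits), MIN_EVALUE)
        for i in range(m):
            for j in range(m):
                if bits[i, j] < score_floor:
                    continue
                rows.append(
                    f"{genes[i]}\t{genes[j]}\t{pident[i, j]:.1f}\t{L}\t"
                    f"{int(mismatches[i, j])}\t0\t1\t{L}\t1\t{L}\t"
                    f"{evalue[i, j]:.2e}\t{bits[i, j]:.1f}"
                )
    return rows


def emit_domtbl(
    ledger: TruthLedger,
    n_decoys: int = 0,
    seed: int | np.random.SeedSequence = 0,
) -> list[str]:
    """HMMER3 ``--domtblout``-style rows for every (protein, domain
    instance) in the ledger, in architecture order.

    True domains receive independent E-values sampled below the standard
    analysis cutoff (1e-2); decoy rows, if requested, receive E-values
    above it and carry domain names prefixed ``DECOY`` on randomly chosen
    proteins.
    """
    rng = np.random.default_rng(seed)
    header = [
        "#                                                               --- full sequence ---"
        " -------------- this domain -------------   hmm coord   ali coord   env coord",
        "# target name        accession   tlen query name           accession   qlen"
        "   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to"
        "  from    to  from    to  acc description of target",
        "#------------------- ---------- ----- -------------------- ---------- -----"
        " --------- ------ ----- --- --- --------- --------- ------ ----- ----- -----"
        " ----- ----- ----- ----- ---- ---------------------",
    ]
    rows: list[str] = []
    genes_with_length: list[tuple[str, int]] = []
    for fid in sorted(ledger.families):
        fam = ledger.families[fid]
        for gene in fam.genes():
            genes_with_length.append((gene, fam.length))
            ndom = len(fam.domains)
            for k, (name, start, end) in enumerate(fam.domains, start=1):
                ievalue = 10.0 ** rng.uniform(-30.0, -3.0)
                score = 30.0 + 1.2 * (end - start)
                rows.append(
                    f"{name} - {end - start + 1} {gene} - {fam.length} "
                    f"{ievalue:.1e} {score:.1f} 0.0 {k} {ndom} {ievalue:.1e} "
                    f"{ievalue:.1e} {score:.1f} 0.0 1 {end - start + 1} "
                    f"{start} {end} {start} {end} 0.90 -"
                )
    for d in range(n_decoys):
        gene, length = genes_with_length[int(rng.integers(len(genes_with_length)))]
        start = int(rng.integers(1, max(2, length - 30)))
        end = min(length, start + int(rng.integers(20, 60)))
        ievalue = 10.0 ** rng.uniform(-1.9, 1.0)  # always above the 1e-2 cutoff
        rows.append(
            f"DECOY{d + 1:03d} - {end - start + 1} {gene} - {length} "
            f"{ievalue:.1e} 8.0 0.0 1 1 {ievalue:.1e} {ievalue:.1e} 8.0 0.0 "
            f"1 {end - start + 1} {start} {end} {start} {end} 0.50 -"
        )
    return header + rows


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    """In-memory synthetic dataset plus its truth ledger."""

    config: SimConfig
    species_tree: SpeciesTree
    lineage_map: LineageMap
    families: dict[str, dict[str, list[str]]]
    ledger: TruthLedger
    sequences: dict[str, dict[str, np.ndarray]] | None  # family -> gene -> seq

    def fasta_records(self) -> list[tuple[str, str]]:
        if self.sequences is None:
            raise ValueError("dataset was generated without sequences")
        records = []
        for fid in sorted(self.sequences):
            for gene in sorted(self.sequences[fid]):
                records.append((gene, decode_seq(self.sequences[fid][gene])))
        return sorted(records)


def simulate_dataset(cfg: SimConfig, with_sequences: bool = True) -> SyntheticDataset:
    """Run the full generator: species tree, families, sequences."""
    species_tree = simulate_species_tree(cfg)
    families, ledger = evolve_families(species_tree, cfg)
    sequences: dict[str, dict[str, np.ndarray]] | None = None
    if with_sequences:
        sequences = {}
        seq_ss = np.random.SeedSequence([cfg.seed, 303])
        children = seq_ss.spawn(cfg.n_families)
        for idx, fid in enumerate(sorted(ledger.families)):
            fam = ledger.families[fid]
            if not fam.taxa_present():
                continue
            sequences[fid] = evolve_sequences(species_tree, fam, cfg, children[idx])
    return SyntheticDataset(
        config=cfg,
        species_tree=species_tree,
        lineage_map=cfg.lineage_map(),
        families=families,
        ledger=ledger,
        sequences=sequences,
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset in the standard file dialects.

    Produces ``proteins.faa``, ``hits.tsv``, ``domains.domtbl``,
    ``lineage.tsv``, ``species_tree.nwk``, ``truth.json`` and ``truth.tsv``
    under ``outdir`` and returns the path of each.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = dataset.config
    paths = {
        "proteins": outdir / "proteins.faa",
        "hits": outdir / "hits.tsv",
        "domtbl": outdir / "domains.domtbl",
        "lineage": outdir / "lineage.tsv",
        "tree": outdir / "species_tree.nwk",
        "truth_json": outdir / "truth.json",
        "truth_tsv": outdir / "truth.tsv",
    }
    if dataset.sequences is not None:
        with paths["proteins"].open("w") as fh:
            for gene, seq in dataset.fasta_records():
                fh.write(f">{gene}\n{seq}\n")
        hits = emit_hits(dataset.sequences, score_floor=cfg.score_floor)
        paths["hits"].write_text("\n".join(hits) + ("\n" if hits else ""))
    domtbl = emit_domtbl(
        dataset.ledger,
        n_decoys=cfg.n_decoys,
        seed=np.random.SeedSequence([cfg.seed, 404]),
    )
    paths["domtbl"].write_text("\n".join(domtbl) + "\n")
    dataset.lineage_map.to_tsv(paths["lineage"])
    paths["tree"].write_text(dataset.species_tree.newick + "\n")
    dataset.ledger.to_json(paths["truth_json"])
    dataset.ledger.to_tsv(paths["truth_tsv"])
    return paths
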