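"""Gene-tree diagnostics for transfer candidates.

A candidate gene family is interrogated on its gene tree: do the recipient
copies form a single clade, which lineage is its sister (the donor
hypothesis) and with what support, and does an approximately-unbiased (AU)
topology test reject a constrained alternative?  Site log-likelihoods are
computed by Felsenstein pruning under a configurable amino-acid
substitution model (Poisson by default); the AU test resamples them with
the multiscale RELL bootstrap and extrapolates the support curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
from scipy.stats import norm

from .lineage import LineageMap
from .synthio import AA_ALPHABET

N_STATES = 20


class TreeError(ValueError):
    """Raised for malformed trees or taxon mismatches."""


class MonophylyError(TreeError):
    """Raised when an operation requires a monophyletic clade."""


# ---------------------------------------------------------------------------
# newick I/O
# ---------------------------------------------------------------------------


def parse_newick(source: str | Path) -> dendropy.Tree:
    """Parse a Newick tree (support-as-internal-label dialect allowed).

    ``source`` may be a path or a Newick string.  Branch supports, when
    present as internal node labels, stay available via
    :func:`support_of`.  Polytomies are preserved.
    """
    text = str(source)
    if "(" not in text:
        text = Path(source).read_text()
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            rooting="default-rooted",
        )
    except Exception as exc:
        raise TreeError(f"newick parse failure: {exc}") from exc
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    s = tree.as_string(schema="newick", suppress_rooting=True).strip()
    if path is not None:
        Path(path).write_text(s + "\n")
    return s


def support_of(node: dendropy.Node) -> float | None:
    """Bootstrap support attached to a node, parsed from its label."""
    label = node.label
    if label is None and node.taxon is not None and not node.is_leaf():
        label = node.taxon.label
    if label is None:
        return None
    try:
        return float(label)
    except (TypeError, ValueError):
        return None


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return sorted(lf.taxon.label for lf in tree.leaf_node_iter())


def _leafsets(tree: dendropy.Tree) -> dict[dendropy.Node, frozenset[str]]:
    sets: dict[dendropy.Node, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sets[node] = frozenset([node.taxon.label])
        else:
            acc: set[str] = set()
            for child in node.child_nodes():
                acc |= sets[child]
            sets[node] = frozenset(acc)
    return sets


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each canonicalized as the side not
    containing the alphabetically first leaf."""
    leaves = frozenset(leaf_labels(tree))
    ref = min(leaves)
    sets = _leafsets(tree)
    out: set[frozenset[str]] = set()
    for node, below in sets.items():
        if node.parent_node is None:
            continue
        side = below if ref not in below else leaves - below
        if 2 <= len(side) <= len(leaves) - 2:
            out.add(side)
    return out


# ---------------------------------------------------------------------------
# monophyly and sister-lineage diagnostics
# ---------------------------------------------------------------------------


def is_monophyletic(
    tree: dendropy.Tree, taxa_set: Iterable[str]
) -> tuple[bool, float | None]:
    """Does ``taxa_set`` form one side of some bipartition of the
    (unrooted) tree?  Returns the stem edge's support when it does."""
    target = frozenset(taxa_set)
    leaves = frozenset(leaf_labels(tree))
    unknown = target - leaves
    if unknown:
        raise TreeError(f"taxa not in tree: {sorted(unknown)}")
    if not target:
        raise TreeError("empty taxa set")
    sets = _leafsets(tree)
    for node, below in sets.items():
        if node.parent_node is None:
            continue
        if below == target or leaves - below == target:
            return True, support_of(node)
    return target == leaves, None


@dataclass
class SisterResult:
    """Sister lineage of a clade and the donor call derived from it."""

    sister_taxa: list[str]
    sister_groups: list[str]
    donor_hypothesis: str | None
    stem_support: float | None
    monophyletic: bool


def sister_lineage(
    tree: dendropy.Tree,
    clade_taxa: Iterable[str],
    lineage_map: LineageMap,
    support_threshold: float = 80.0,
) -> SisterResult:
    """Identify the sibling subtree of a clade and call its majority group
    as the putative donor.

    Unrooted trees are midpoint-rooted first.  The donor call requires the
    clade stem support, when supports are annotated, to reach
    ``support_threshold``; below it the call is ``None`` (unresolved).
    Ties in the majority vote give ``"ambiguous"``.
    """
    clade = frozenset(clade_taxa)
    work = parse_newick(write_newick(tree))  # private copy
    mono, bip_support = is_monophyletic(work, clade)
    if not mono:
        raise MonophylyError(
            "clade is not monophyletic; check with is_monophyletic first"
        )
    if len(work.seed_node.child_nodes()) != 2:
        work.reroot_at_midpoint(update_bipartitions=True)

    sets = _leafsets(work)
    mrca = None
    for node, below in sets.items():
        if below == clade:
            mrca = node
            break
    if mrca is None or mrca.parent_node is None:
        # Midpoint rooting landed inside the clade; root on the clade stem
        # instead so the clade is a subtree again.
        for node, below in _leafsets(work).items():
            if frozenset(leaf_labels(work)) - below == clade and node.parent_node:
                work.reroot_at_edge(node.edge, update_bipartitions=True)
                break
        sets = _leafsets(work)
        mrca = next((nd for nd, below in sets.items() if below == clade), None)
        if mrca is None or mrca.parent_node is None:
            raise MonophylyError("could not isolate the clade under any rooting")

    # Rerooting can displace internal-node labels; the clade's stem support
    # is its bipartition support, which rooting cannot change.
    support = bip_support if bip_support is not None else support_of(mrca)
    sister_taxa: list[str] = sorted(
        label
        for sib in mrca.parent_node.child_nodes()
        if sib is not mrca
        for label in sets[sib]
    )
    groups = [
        lineage_map.group_of(t) if t in lineage_map else "unknown" for t in sister_taxa
    ]
    donor: str | None = None
    if groups:
        tally: dict[str, int] = {}
        for g in groups:
            tally[g] = tally.get(g, 0) + 1
        best = max(tally.values())
        winners = sorted(g for g, c in tally.items() if c == best)
        donor = winners[0] if len(winners) == 1 else "ambiguous"
    if support is not None and support < support_threshold:
        donor = None
    return SisterResult(
        sister_taxa=sister_taxa,
        sister_groups=groups,
        donor_hypothesis=donor,
        stem_support=support,
        monophyletic=True,
    )


# ---------------------------------------------------------------------------
# substitution model and pruning likelihood
# ---------------------------------------------------------------------------


@dataclass
class SubstModel:
    """Time-reversible amino-acid substitution model.

    ``exchangeabilities`` is a symmetric 20x20 matrix of relative rates
    (diagonal ignored) and ``frequencies`` the equilibrium distribution;
    the defaults give the Poisson model (all exchangeabilities equal,
    uniform frequencies).  Optional discrete-Gamma rate variation uses
    ``n_rate_categories`` equal-probability categories with shape
    ``gamma_alpha``.  The generator is scaled to one expected substitution
    per site per unit branch length.
    """

    exchangeabilities: np.ndarray = field(
        default_factory=lambda: np.ones((N_STATES, N_STATES))
    )
    frequencies: np.ndarray = field(
        default_factory=lambda: np.full(N_STATES, 1.0 / N_STATES)
    )
    n_rate_categories: int = 1
    gamma_alpha: float | None = None

    def __post_init__(self) -> None:
        s = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.frequencies, dtype=float)
        if s.shape != (N_STATES, N_STATES) or pi.shape != (N_STATES,):
            raise ValueError("model matrices must be 20x20 and length-20")
        if not np.allclose(s, s.T):
            raise ValueError("exchangeability matrix must be symmetric")
        if not np.isclose(pi.sum(), 1.0):
            raise ValueError("frequencies must sum to 1")
        q = s * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        scale = -(pi * np.diag(q)).sum()
        q /= scale
        self._q = q
        sqrt_pi = np.sqrt(pi)
        b = (q * sqrt_pi[:, None]) / sqrt_pi[None, :]
        evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
        self._evals = evals
        self._left = evecs / sqrt_pi[:, None]
        self._right = evecs * sqrt_pi[:, None]
        self.frequencies = pi
        if self.n_rate_categories < 1:
            raise ValueError("n_rate_categories must be >= 1")

    def rate_categories(self) -> np.ndarray:
        """Equal-probability discrete-Gamma category rates (mean 1)."""
        k = self.n_rate_categories
        if k == 1 or self.gamma_alpha is None:
            return np.ones(1)
        from scipy.stats import gamma as gamma_dist

        quantiles = (2.0 * np.arange(k) + 1.0) / (2.0 * k)
        rates = gamma_dist.ppf(quantiles, a=self.gamma_alpha, scale=1.0 / self.gamma_alpha)
        return rates / rates.mean()

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(t): probability of state j after branch length t from state i."""
        expd = np.exp(self._evals * t * rate)
        p = (self._left * expd[None, :]) @ self._right.T
        return np.clip(p, 0.0, None)


def poisson_model(n_rate_categories: int = 1, gamma_alpha: float | None = None) -> SubstModel:
    return SubstModel(
        n_rate_categories=n_rate_categories, gamma_alpha=gamma_alpha
    )


def _encode_alignment(
    alignment: Mapping[str, str], labels: Sequence[str]
) -> np.ndarray:
    lookup = {c: i for i, c in enumerate(AA_ALPHABET)}
    lengths = {len(alignment[l]) for l in labels}
    if len(lengths) != 1:
        raise TreeError(f"alignment rows differ in length: {sorted(lengths)}")
    (n_sites,) = lengths
    coded = np.full((len(labels), n_sites), -1, dtype=np.int8)
    for row, label in enumerate(labels):
        for col, char in enumerate(alignment[label].upper()):
            coded[row, col] = lookup.get(char, -1)  # gaps/ambiguity = missing
    return coded


def site_loglik(
    alignment: Mapping[str, str],
    tree: dendropy.Tree,
    model: SubstModel | None = None,
) -> np.ndarray:
    """Per-site log-likelihood of an alignment on a fixed tree by
    Felsenstein pruning.

    The alignment is a mapping ``leaf label -> aligned sequence``; its
    labels must equal the tree's leaves.  Gaps and unknown characters are
    treated as missing data.  Branch lengths of ``None`` count as zero.
    """
    model = model or SubstModel()
    labels = leaf_labels(tree)
    aln_labels = sorted(alignment)
    if aln_labels != labels:
        only_tree = sorted(set(labels) - set(aln_labels))
        only_aln = sorted(set(aln_labels) - set(labels))
        raise TreeError(
            f"alignment/tree leaf mismatch; only in tree: {only_tree}, "
            f"only in alignment: {only_aln}"
        )
    coded = _encode_alignment(alignment, labels)
    row_of = {label: i for i, label in enumerate(labels)}
    n_sites = coded.shape[1]
    pi = model.frequencies
    rates = model.rate_categories()

    site_lik = np.zeros(n_sites)
    for rate in rates:
        partials: dict[dendropy.Node, np.ndarray] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                states = coded[row_of[node.taxon.label]]
                part = np.zeros((n_sites, N_STATES))
                known = states >= 0
                part[known, states[known]] = 1.0
                part[~known, :] = 1.0
                partials[node] = part
            else:
                part = np.ones((n_sites, N_STATES))
                for child in node.child_nodes():
                    p = model.transition_matrix(child.edge.length or 0.0, rate)
                    part *= partials.pop(child) @ p.T
                partials[node] = part
        site_lik += (partials[tree.seed_node] * pi[None, :]).sum(axis=1) / len(rates)
    with np.errstate(divide="ignore"):
        ll = np.log(site_lik)
    if not np.all(np.isfinite(ll)):
        raise TreeError("non-finite site log-likelihood (zero-probability site)")
    return ll


# ---------------------------------------------------------------------------
# constrained topologies
# ---------------------------------------------------------------------------


def _optimize_edge(
    edge: dendropy.Edge,
    alignment: Mapping[str, str],
    tree: dendropy.Tree,
    model: SubstModel,
    tol: float = 1e-4,
) -> None:
    from scipy.optimize import minimize_scalar

    def negll(x: float) -> float:
        edge.length = float(x)
        return -float(site_loglik(alignment, tree, model).sum())

    res = minimize_scalar(
        negll, bounds=(1e-6, 5.0), method="bounded", options={"xatol": tol}
    )
    edge.length = float(res.x)


def constrain_monophyly(
    tree: dendropy.Tree,
    group_taxa: Iterable[str],
    alignment: Mapping[str, str] | None = None,
    model: SubstModel | None = None,
) -> tuple[dendropy.Tree, str | None]:
    """Minimal rearrangement forcing ``group_taxa`` to be monophyletic.

    Maximal intruding subtrees inside the group's spanning clade are
    pruned and regrafted onto the group's stem.  Only the moved branches
    are re-optimized (bounded likelihood line search, tolerance 1e-4) and
    only when an alignment and model are supplied; all other branch
    lengths are preserved.  Returns ``(tree, notice)`` with a notice when
    the group was already monophyletic.
    """
    group = frozenset(group_taxa)
    work = parse_newick(write_newick(tree))
    leaves = frozenset(leaf_labels(work))
    unknown = group - leaves
    if unknown:
        raise TreeError(f"taxa not in tree: {sorted(unknown)}")
    mono, _ = is_monophyletic(work, group)
    if mono:
        return work, "group already monophyletic; tree returned unchanged"

    if len(work.seed_node.child_nodes()) != 2:
        work.reroot_at_midpoint(update_bipartitions=True)
    sets = _leafsets(work)
    mrca = min(
        (nd for nd, below in sets.items() if group <= below),
        key=lambda nd: len(sets[nd]),
    )

    # Maximal subtrees under the MRCA carrying no group taxon.
    intruders: list[dendropy.Node] = []

    def collect(node: dendropy.Node) -> None:
        for child in node.child_nodes():
            if not (sets[child] & group):
                intruders.append(child)
            elif not child.is_leaf():
                collect(child)

    collect(mrca)
    intruder_taxa = sorted(t for nd in intruders for t in sets[nd])

    kept = sorted(leaves - set(intruder_taxa))
    pruned = parse_newick(write_newick(work)).extract_tree_with_taxa_labels(labels=kept)
    pruned.is_rooted = True
    intruder_trees = [
        parse_newick(write_newick(work)).extract_tree_with_taxa_labels(
            labels=sorted(sets[nd])
        )
        for nd in intruders
    ]

    psets = _leafsets(pruned)
    new_mrca = min(
        (nd for nd, below in psets.items() if group <= below),
        key=lambda nd: len(psets[nd]),
    )
    stem_parent = new_mrca.parent_node
    moved_edges: list[dendropy.Edge] = []
    if stem_parent is None:
        # group spans one side of the root: attach intruders as sisters at
        # a fresh root above the old one
        for sub in intruder_trees:
            new_root = dendropy.Node()
            old = pruned.seed_node
            pruned.seed_node = new_root
            new_root.add_child(old)
            old.edge.length = 0.05
            graft = sub.seed_node
            graft.edge.length = graft.edge.length or 0.05
            new_root.add_child(graft)
            moved_edges.extend([old.edge, graft.edge])
    else:
        stem_len = new_mrca.edge.length or 0.05
        step = stem_len / (len(intruder_trees) + 1)
        anchor = stem_parent
        below = new_mrca
        for sub in intruder_trees:
            mid = dendropy.Node()
            anchor.remove_child(below)
            anchor.add_child(mid)
            mid.edge.length = step
            mid.add_child(below)
            below.edge.length = step
            graft = sub.seed_node
            graft.edge.length = graft.edge.length or 0.05
            mid.add_child(graft)
            moved_edges.extend([mid.edge, graft.edge, below.edge])
            anchor = mid

    pruned.is_rooted = True
    mono_after, _ = is_monophyletic(pruned, group)
    if not mono_after:
        raise TreeError("constraint rearrangement failed to isolate the group")
    if alignment is not None:
        model = model or SubstModel()
        for edge in moved_edges:
            _optimize_edge(edge, alignment, pruned, model)
    return pruned, None


# ---------------------------------------------------------------------------
# AU test (multiscale RELL bootstrap)
# ---------------------------------------------------------------------------


@dataclass
class AUConfig:
    seed: int = 0
    n_replicates: int = 1000
    scales: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.1, 1.2, 1.3, 1.4)


@dataclass
class AUResult:
    """AU p-values with the bootstrap support curves behind them."""

    pvalues: np.ndarray  # per topology, in [0, 1]
    support: np.ndarray  # topologies x scales selection frequencies
    scales: tuple[float, ...]
    n_replicates: int
    flags: list[str | None]


def au_test(site_ll: np.ndarray, config: AUConfig | None = None) -> AUResult:
    """Approximately-unbiased test over fixed topologies.

    ``site_ll`` is a (topologies x sites) matrix of per-site
    log-likelihoods.  For every scale factor r the site columns are
    resampled with replacement to ceil(r*n) columns, the per-topology
    totals compared (ties split evenly), and the selection frequency
    recorded; the normal-quantile support curve z(r) = d*sqrt(r) +
    c/sqrt(r) is then fit by weighted least squares and the AU p-value is
    1 - Phi(d - c).  Topologies never (or always) selected at any scale
    get p = 0 (or 1) and a degeneracy flag.
    """
    config = config or AUConfig()
    ll = np.asarray(site_ll, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise ValueError("site_ll must be a (>=2 topologies) x sites matrix")
    n_topo, n_sites = ll.shape
    if n_sites < 10:
        raise ValueError(f"need >= 10 sites, got {n_sites}")
    rng = np.random.default_rng(config.seed)
    B = config.n_replicates

    support = np.zeros((n_topo, len(config.scales)))
    for s_idx, r in enumerate(config.scales):
        m = int(np.ceil(r * n_sites))
        idx = rng.integers(0, n_sites, size=(B, m))
        totals = ll[:, idx].sum(axis=2)  # topologies x replicates
        best = totals.max(axis=0)
        winners = totals >= best[None, :] - 1e-9
        support[:, s_idx] = (winners / winners.sum(axis=0)[None, :]).sum(axis=1) / B

    sqrt_r = np.sqrt(np.asarray(config.scales))
    X = np.column_stack([sqrt_r, 1.0 / sqrt_r])
    pvals = np.zeros(n_topo)
    flags: list[str | None] = [None] * n_topo
    eps = 1.0 / (2.0 * B)
    for t in range(n_topo):
        bp = support[t]
        if np.all(bp <= 0.0):
            pvals[t] = 0.0
            flags[t] = "never-selected"
            continue
        if np.all(bp >= 1.0):
            pvals[t] = 1.0
            flags[t] = "always-selected"
            continue
        bp_c = np.clip(bp, eps, 1.0 - eps)
        z = norm.isf(bp_c)  # Phi^-1(1 - bp)
        w = B * norm.pdf(z) ** 2 / (bp_c * (1.0 - bp_c))
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        d, c = coef
        pvals[t] = float(np.clip(norm.sf(d - c), 0.0, 1.0))
    return AUResult(
        pvalues=pvals,
        support=support,
        scales=tuple(config.scales),
        n_replicates=B,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# distance-tree inference (used to build gene trees from sequences)
# ---------------------------------------------------------------------------


def p_distance_matrix(sequences: Mapping[str, str]) -> tuple[list[str], np.ndarray]:
    """Pairwise p-distances (fraction of differing aligned positions)."""
    ids = sorted(sequences)
    lengths = {len(sequences[i]) for i in ids}
    if len(lengths) != 1:
        raise TreeError("sequences must be aligned (equal length)")
    mat = np.array([np.frombuffer(sequences[i].encode(), dtype=np.uint8) for i in ids])
    eq = mat[:, None, :] == mat[None, :, :]
    return ids, 1.0 - eq.mean(axis=2)


def infer_nj_tree(
    sequences: Mapping[str, str],
    n_bootstrap: int = 0,
    seed: int = 0,
) -> dendropy.Tree:
    """Neighbor-joining tree from aligned sequences, with optional
    bootstrap supports (percent of column resamples containing each
    bipartition) written onto internal nodes."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    ids, dist = p_distance_matrix(sequences)
    if len(ids) < 3:
        raise TreeError("need >= 3 sequences for neighbor joining")
    tree = parse_newick(str(nj(DistanceMatrix(dist, ids))))
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0  # NJ can produce small negative estimates
    if n_bootstrap <= 0:
        return tree

    mat = np.array([np.frombuffer(sequences[i].encode(), dtype=np.uint8) for i in ids])
    eq = mat[:, None, :] == mat[None, :, :]
    n_sites = mat.shape[1]
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {}
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n_sites, size=n_sites)
        d = 1.0 - eq[:, :, idx].mean(axis=2)
        rep = parse_newick(str(nj(DistanceMatrix(d, ids))))
        for bip in bipartitions(rep):
            counts[bip] = counts.get(bip, 0) + 1

    leaves = frozenset(ids)
    ref = min(leaves)
    sets = _leafsets(tree)
    for node in tree.postorder_internal_node_iter():
        if node.parent_node is None:
            continue
        below = sets[node]
        side = below if ref not in below else leaves - below
        if 2 <= len(side) <= len(leaves) - 2:
            pct = 100.0 * counts.get(side, 0) / n_bootstrap
            node.label = f"{pct:.0f}"
    return tree
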