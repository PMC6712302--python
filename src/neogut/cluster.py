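"""Ortholog-graph construction, Markov clustering and dereplication.

Gene families are obtained the classic way: an all-vs-all protein
similarity table is filtered at an E-value cutoff (default 1e-5), turned
into an undirected bitscore-weighted graph, and partitioned with the Markov
clustering algorithm (MCL) at inflation 1.5.  Redundant near-identical
sequences (e.g. transcript variants from transcriptome assemblies) are
collapsed beforehand by greedy longest-first clustering at >90% global
identity, the CD-HIT convention.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from Bio import Align
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)

HIT_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


class HitFormatError(ValueError):
    """Raised when a similarity table does not follow the 12-column layout."""


@dataclass
class ClusterConfig:
    """Knobs for graph construction, MCL and dereplication."""

    evalue_cutoff: float = 1e-5
    inflation: float = 1.5
    expansion: int = 2
    max_iter: int = 200
    convergence_tol: float = 1e-6
    prune_threshold: float = 1e-8
    derep_identity: float = 0.90
    bbh_filter: bool = False  # keep only reciprocal pairs as edges

    def __post_init__(self) -> None:
        if self.inflation <= 1.0:
            raise ValueError(f"inflation must be > 1, got {self.inflation}")
        if self.expansion < 2:
            raise ValueError(f"expansion must be >= 2, got {self.expansion}")
        if not 0.0 < self.derep_identity < 1.0:
            raise ValueError(
                f"derep_identity must be a fraction in (0, 1), got {self.derep_identity}"
            )


@dataclass
class GeneFamily:
    """One disjoint cluster of proteins."""

    family_id: str
    members: list[str]


@dataclass
class ClusterReport:
    """Bookkeeping from a clustering run."""

    n_rows: int = 0
    n_kept: int = 0
    n_dropped_evalue: int = 0
    n_self_hits: int = 0
    n_malformed: int = 0
    mcl_iterations: int = 0
    mcl_converged: bool = True
    notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# hit loading
# ---------------------------------------------------------------------------


def load_hits(
    path: str | Path,
    cfg: ClusterConfig | None = None,
    report: ClusterReport | None = None,
) -> pd.DataFrame:
    """Load a 12-column similarity table, dropping rows above the E-value
    cutoff.  Self-hits are kept but flagged in the ``self_hit`` column.

    Malformed rows are counted; if more than 1% of rows are malformed the
    file is rejected as misformatted.
    """
    cfg = cfg or ClusterConfig()
    report = report or ClusterReport()
    path = Path(path)
    # Read with three spillover columns so rows with the wrong column count
    # can be detected and counted instead of aborting the parse.
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            dtype=str,
            names=HIT_COLUMNS + ["_x1", "_x2", "_x3"],
            skip_blank_lines=True,
        )
    except OSError as exc:
        raise OSError(f"cannot read hit table {path}: {exc}") from exc
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=HIT_COLUMNS + ["_x1", "_x2", "_x3"])
    malformed = df["_x1"].notna() | df["bitscore"].isna()
    numeric = {
        "pident": float,
        "evalue": float,
        "bitscore": float,
        "length": "Int64",
        "mismatch": "Int64",
        "gapopen": "Int64",
        "qstart": "Int64",
        "qend": "Int64",
        "sstart": "Int64",
        "send": "Int64",
    }
    for col, kind in numeric.items():
        converted = pd.to_numeric(df[col], errors="coerce")
        malformed |= converted.isna()
        df[col] = converted
    total = len(df)
    n_malformed = int(malformed.sum())
    report.n_rows = total
    report.n_malformed = n_malformed
    if total and n_malformed / total > 0.01:
        raise HitFormatError(
            f"{path}: {n_malformed}/{total} rows do not follow the 12-column layout"
        )
    df = df.loc[~malformed, HIT_COLUMNS].reset_index(drop=True)
    for col, kind in numeric.items():
        df[col] = df[col].astype(int if kind == "Int64" else float)
    if not len(df):
        logger.warning("%s: no similarity rows loaded", path)
        df["self_hit"] = pd.Series(dtype=bool)
        return df
    keep = df["evalue"] <= cfg.evalue_cutoff
    report.n_dropped_evalue = int((~keep).sum())
    df = df[keep].reset_index(drop=True)
    df["self_hit"] = df["qseqid"] == df["sseqid"]
    report.n_self_hits = int(df["self_hit"].sum())
    report.n_kept = len(df)
    return df


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------


def build_graph(
    hits: pd.DataFrame,
    proteins: list[str] | None = None,
    cfg: ClusterConfig | None = None,
) -> nx.Graph:
    """Undirected similarity graph.

    The weight of edge A--B is the mean of the best A->B and best B->A
    bitscores when both directions exist, otherwise the single direction's
    bitscore.  Self-loops are dropped.  ``proteins``, if given, seeds the
    node set so that proteins without any qualifying hit appear as
    singletons.
    """
    cfg = cfg or ClusterConfig()
    graph = nx.Graph()
    if proteins:
        graph.add_nodes_from(proteins)
    if len(hits):
        directed = (
            hits.loc[~hits["self_hit"], ["qseqid", "sseqid", "bitscore"]]
            .groupby(["qseqid", "sseqid"], sort=False)["bitscore"]
            .max()
        )
        pair_scores: dict[tuple[str, str], list[float]] = defaultdict(list)
        for (q, s), score in directed.items():
            key = (q, s) if q < s else (s, q)
            pair_scores[key].append(float(score))
        for (a, b), scores in pair_scores.items():
            if cfg.bbh_filter and len(scores) < 2:
                continue
            graph.add_edge(a, b, weight=float(np.mean(scores)))
        graph.add_nodes_from(hits["qseqid"])
        graph.add_nodes_from(hits["sseqid"])
    return graph


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------


def _normalize_columns(m: sp.csr_matrix) -> sp.csr_matrix:
    sums = np.asarray(m.sum(axis=0)).ravel()
    sums[sums == 0.0] = 1.0
    return (m @ sp.diags(1.0 / sums)).tocsr()


def mcl(
    graph: nx.Graph,
    cfg: ClusterConfig | None = None,
    report: ClusterReport | None = None,
) -> list[GeneFamily]:
    """Markov clustering of a weighted similarity graph.

    The column-stochastic transition matrix (with self-loops weighted by
    each node's maximum incident edge weight, a standard regularization) is
    alternately expanded (matrix power) and inflated (entrywise power,
    renormalized) until the maximum entry change drops below the
    convergence tolerance.  Clusters are the connected components of the
    converged attractor structure; each family is named after its
    lexicographically smallest member.
    """
    cfg = cfg or ClusterConfig()
    report = report or ClusterReport()
    nodes = sorted(graph.nodes)
    if not nodes:
        return []
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)

    rows, cols, vals = [], [], []
    loop_weight = np.zeros(n)
    for a, b, data in graph.edges(data=True):
        if a == b:
            continue
        w = float(data.get("weight", 1.0))
        i, j = index[a], index[b]
        rows += [i, j]
        cols += [j, i]
        vals += [w, w]
        loop_weight[i] = max(loop_weight[i], w)
        loop_weight[j] = max(loop_weight[j], w)
    loop_weight[loop_weight == 0.0] = 1.0  # isolated nodes
    rows += list(range(n))
    cols += list(range(n))
    vals += list(loop_weight)
    m = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    m = _normalize_columns(m)

    converged = False
    iterations = 0
    for iterations in range(1, cfg.max_iter + 1):
        prev = m.copy()
        expanded = m
        for _ in range(cfg.expansion - 1):
            expanded = expanded @ m
        expanded = expanded.tocsr()
        expanded.data = expanded.data**cfg.inflation
        expanded.data[expanded.data < cfg.prune_threshold] = 0.0
        expanded.eliminate_zeros()
        m = _normalize_columns(expanded)
        delta = abs(m - prev)
        if delta.nnz == 0 or delta.max() < cfg.convergence_tol:
            converged = True
            break
    report.mcl_iterations = iterations
    report.mcl_converged = converged
    if not converged:
        report.notes.append(f"MCL did not converge within {cfg.max_iter} iterations")

    structure = m.copy()
    structure.data = (structure.data > 1e-6).astype(float)
    structure.eliminate_zeros()
    n_comp, assignment = connected_components(structure, directed=False)
    clusters: dict[int, list[str]] = defaultdict(list)
    for node, comp in zip(nodes, assignment):
        clusters[comp].append(node)
    families = [
        GeneFamily(family_id=f"FAM_{min(members)}", members=sorted(members))
        for members in clusters.values()
    ]
    families.sort(key=lambda f: f.family_id)
    return families


# ---------------------------------------------------------------------------
# dereplication
# ---------------------------------------------------------------------------


def _global_identity(a: str, b: str, aligner: Align.PairwiseAligner) -> float:
    """Fraction of identical aligned positions over the shorter sequence
    (the CD-HIT convention) under global alignment with match=1,
    mismatch=0, gap=-1."""
    alignment = aligner.align(a, b)[0]
    identities = alignment.counts().identities
    return identities / min(len(a), len(b))


def _kmer_set(seq: str, k: int = 5) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def dereplicate(
    sequences: dict[str, str],
    cfg: ClusterConfig | None = None,
) -> tuple[list[str], dict[str, str]]:
    """Greedy longest-first clustering of near-identical sequences.

    Sequences are visited in order of decreasing length (ties broken by
    id); each joins the first existing representative with global identity
    strictly above ``derep_identity``, else becomes a representative
    itself.  Returns ``(representatives, member_map)`` with ``member_map``
    mapping every input id to its representative.  A cheap shared-k-mer
    screen limits full alignments to plausible near-duplicates; at the
    >90% identity regime near-duplicates always share a large fraction of
    their 5-mers, so the screen cannot split true variant clusters.
    """
    cfg = cfg or ClusterConfig()
    if not sequences:
        return [], {}
    order = sorted(sequences, key=lambda s: (-len(sequences[s]), s))
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=1.0,
        mismatch_score=0.0,
        open_gap_score=-1.0,
        extend_gap_score=-1.0,
    )
    representatives: list[str] = []
    kmer_index: dict[str, list[int]] = defaultdict(list)  # kmer -> rep indices
    member_map: dict[str, str] = {}
    for sid in order:
        seq = sequences[sid]
        kmers = _kmer_set(seq)
        hit_counts: dict[int, int] = defaultdict(int)
        for kmer in kmers:
            for rep_idx in kmer_index.get(kmer, ()):
                hit_counts[rep_idx] += 1
        min_shared = max(1, int(0.3 * len(kmers)))
        candidates = sorted(
            (idx for idx, c in hit_counts.items() if c >= min_shared),
            key=lambda idx: (-hit_counts[idx], idx),
        )
        assigned = False
        for rep_idx in candidates:
            rep = representatives[rep_idx]
            rep_seq = sequences[rep]
            if len(seq) < cfg.derep_identity * len(rep_seq):
                continue  # identity over the shorter sequence cannot reach cutoff
            if _global_identity(seq, rep_seq, aligner) > cfg.derep_identity:
                member_map[sid] = rep
                assigned = True
                break
        if not assigned:
            rep_idx = len(representatives)
            representatives.append(sid)
            for kmer in kmers:
                kmer_index[kmer].append(rep_idx)
            member_map[sid] = sid
    return representatives, member_map


# ---------------------------------------------------------------------------
# output helpers
# ---------------------------------------------------------------------------


def families_to_frame(
    families: list[GeneFamily], taxon_of: dict[str, str] | None = None
) -> pd.DataFrame:
    """Long-format table: family_id, protein_id, taxon."""
    from .lineage import taxon_of_protein

    records = []
    for fam in families:
        for member in fam.members:
            taxon = (
                taxon_of.get(member, "") if taxon_of is not None else taxon_of_protein(member)
            )
            records.append((fam.family_id, member, taxon))
    return pd.DataFrame(records, columns=["family_id", "protein_id", "taxon"])


def write_abc_graph(graph: nx.Graph, path: str | Path) -> None:
    """Dump the similarity graph in the simple ``a b weight`` format."""
    lines = [
        f"{a}\t{b}\t{data.get('weight', 1.0):.3f}"
        for a, b, data in sorted(graph.edges(data=True))
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
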