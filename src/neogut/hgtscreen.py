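"""Similarity-based screen for laterally acquired recipient genes.

For every recipient-lineage gene the screen collapses its similarity hits
into one best bitscore per lineage group (the recipient group itself is
excluded), applies the *alien filter* — flag the gene when its best
non-fungal hit outscores its best non-recipient fungal hit, with a missing
homolog counted as score 0 so that genes with no fungal homolog at all
produce the strongest possible signal — and ranks flagged candidates by
combining two strategies (bitscore margin and best non-fungal percent
identity) with a Borda mean rank.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .lineage import FUNGAL_GROUPS, NONFUNGAL_GROUPS, LineageMap, taxon_of_protein


@dataclass
class ScreenConfig:
    """Alien-filter settings.

    ``donor_groups`` are the non-fungal groups allowed to participate in
    the alien maximum (all of them by default; the reference screen named
    only animal/plant comparisons but its findings include a bacterial
    donor, so the filter is applied symmetrically).
    """

    donor_groups: tuple[str, ...] = NONFUNGAL_GROUPS
    margin_threshold: float = 0.0  # alien_margin must exceed this to flag
    use_evalue_index: bool = False  # ln(best alien E) - ln(best fungal E) mode

    def __post_init__(self) -> None:
        bad = set(self.donor_groups) - set(NONFUNGAL_GROUPS)
        if bad:
            raise ValueError(f"non-donor groups in donor_groups: {sorted(bad)}")


@dataclass
class GroupScores:
    """Per-group best similarity scores for one recipient gene."""

    gene_id: str
    best_bitscore: dict[str, float] = field(default_factory=dict)
    best_subject: dict[str, str] = field(default_factory=dict)
    best_pident: dict[str, float] = field(default_factory=dict)
    best_evalue: dict[str, float] = field(default_factory=dict)


def group_best_scores(
    hits: pd.DataFrame,
    lineage_map: LineageMap,
    genes: Sequence[str] | None = None,
) -> dict[str, GroupScores]:
    """Best bitscore (and subject, identity, E-value) per lineage group
    for each recipient gene.

    Hits whose subject belongs to the recipient group are ignored; hits to
    taxa absent from the lineage map are skipped.  ``genes`` optionally
    restricts and seeds the output (genes without hits get empty scores).
    """
    scores: dict[str, GroupScores] = {}
    if genes is not None:
        for g in genes:
            scores[g] = GroupScores(gene_id=g)
    if len(hits) == 0:
        return scores

    df = hits.copy()
    df["q_taxon"] = df["qseqid"].map(taxon_of_protein)
    df["s_taxon"] = df["sseqid"].map(taxon_of_protein)
    known = set(lineage_map.taxa())
    df = df[df["q_taxon"].isin(known) & df["s_taxon"].isin(known)]
    df["q_group"] = df["q_taxon"].map(lineage_map.group_of)
    df["s_group"] = df["s_taxon"].map(lineage_map.group_of)
    df = df[(df["q_group"] == "recipient") & (df["s_group"] != "recipient")]
    if genes is not None:
        df = df[df["qseqid"].isin(set(genes))]
    if len(df) == 0:
        return scores

    best = df.loc[
        df.groupby(["qseqid", "s_group"], sort=False)["bitscore"].idxmax()
    ]
    for row in best.itertuples():
        gs = scores.setdefault(row.qseqid, GroupScores(gene_id=row.qseqid))
        gs.best_bitscore[row.s_group] = float(row.bitscore)
        gs.best_subject[row.s_group] = row.sseqid
        gs.best_pident[row.s_group] = float(row.pident)
        gs.best_evalue[row.s_group] = float(row.evalue)
    return scores


def alien_filter(
    scores: GroupScores, cfg: ScreenConfig | None = None
) -> tuple[bool, float, str | None]:
    """Apply the alien rule to one gene's group scores.

    Returns ``(alien_flag, alien_margin, donor_hypothesis)``.  The margin
    is best non-fungal minus best fungal bitscore with absent scores
    counted as 0; the donor hypothesis is the arg-max non-fungal group
    (ties broken alphabetically), or None when the gene is not flagged.
    """
    cfg = cfg or ScreenConfig()
    fungal_best = max(
        (scores.best_bitscore.get(g, 0.0) for g in FUNGAL_GROUPS), default=0.0
    )
    alien_candidates = {
        g: scores.best_bitscore[g]
        for g in cfg.donor_groups
        if g in scores.best_bitscore
    }
    alien_best = max(alien_candidates.values(), default=0.0)
    margin = alien_best - fungal_best
    flag = margin > cfg.margin_threshold and alien_best > 0.0
    donor = None
    if flag:
        donor = min(g for g, v in alien_candidates.items() if v == alien_best)
    return flag, margin, donor


@dataclass
class HGTCandidate:
    """A flagged gene with its screening evidence."""

    gene_id: str
    alien_flag: bool
    alien_margin: float
    donor_hypothesis: str | None
    similarity_rank: int = 0
    screen_rank: int = 0
    combined_rank: float = 0.0


def screen_genes(
    hits: pd.DataFrame,
    lineage_map: LineageMap,
    cfg: ScreenConfig | None = None,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Run the alien filter over all recipient genes in a hit table.

    Returns one row per screened gene with flag, margin, donor hypothesis
    and the per-strategy scores used for ranking.
    """
    cfg = cfg or ScreenConfig()
    scores = group_best_scores(hits, lineage_map, genes=genes)
    records = []
    for gene in sorted(scores):
        gs = scores[gene]
        flag, margin, donor = alien_filter(gs, cfg)
        alien_pident = max(
            (gs.best_pident.get(g, 0.0) for g in cfg.donor_groups), default=0.0
        )
        records.append((gene, flag, margin, donor, alien_pident))
    return pd.DataFrame(
        records,
        columns=["gene_id", "alien_flag", "alien_margin", "donor_hypothesis", "alien_pident"],
    ).set_index("gene_id")


def rank_candidates(screened: pd.DataFrame) -> pd.DataFrame:
    """Rank flagged genes by the Borda mean of two within-strategy ranks.

    Strategy A ranks by alien bitscore margin (descending); strategy B by
    best non-fungal percent identity (descending) — the high-identity
    screen.  A candidate missing a strategy score receives that strategy's
    worst rank + 1.  The combined rank is the mean of the two; ties break
    by margin descending, then gene id ascending.  The result is a total
    order, invariant to input row order.
    """
    flagged = screened[screened["alien_flag"]].copy()
    if len(flagged) == 0:
        return flagged.assign(
            similarity_rank=pd.Series(dtype=int),
            screen_rank=pd.Series(dtype=int),
            combined_rank=pd.Series(dtype=float),
        )
    flagged = flagged.sort_index()

    def strategy_rank(values: pd.Series) -> pd.Series:
        present = values.dropna()
        order = present.sort_values(ascending=False, kind="mergesort")
        ranks = pd.Series(np.arange(1, len(order) + 1), index=order.index, dtype=float)
        worst = len(order) + 1
        return values.index.to_series().map(ranks).fillna(worst)

    flagged["similarity_rank"] = strategy_rank(flagged["alien_margin"]).astype(int)
    flagged["screen_rank"] = strategy_rank(flagged["alien_pident"]).astype(int)
    flagged["combined_rank"] = (
        flagged["similarity_rank"] + flagged["screen_rank"]
    ) / 2.0
    flagged = flagged.sort_values(
        by=["combined_rank", "alien_margin", "gene_id"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    return flagged


def summarize_candidates(
    ranked: pd.DataFrame,
    archs: dict[str, list[tuple[str, int, int]]] | None = None,
    domain_classification: pd.DataFrame | None = None,
    fusions: pd.DataFrame | None = None,
) -> list[dict]:
    """Per-candidate dossier joining screen evidence with domain-level
    classification and fusion evidence.

    Tiers: ``high-confidence`` when the candidate carries a
    recipient-unique domain fused with a native (non-unique) domain;
    ``domain-supported`` when it carries a recipient-unique domain without
    fusion evidence; ``similarity-only`` otherwise.
    """
    unique_domains: set[str] = set()
    if domain_classification is not None:
        unique_domains = set(
            domain_classification.index[
                domain_classification["label"] == "unique_recipient"
            ]
        )
    fused_proteins: dict[str, list[dict]] = {}
    if fusions is not None and len(fusions):
        for row in fusions.itertuples():
            fused_proteins.setdefault(row.protein_id, []).append(
                {
                    "foreign_domain": row.foreign_domain,
                    "native_domain": row.native_domain,
                    "native_position": row.native_position,
                }
            )
    dossiers = []
    for gene, row in ranked.iterrows():
        arch = archs.get(gene, []) if archs else []
        gene_unique = sorted({d for d, _, _ in arch} & unique_domains)
        gene_fusions = fused_proteins.get(gene, [])
        if gene_unique and gene_fusions:
            tier = "high-confidence"
        elif gene_unique:
            tier = "domain-supported"
        else:
            tier = "similarity-only"
        dossiers.append(
            {
                "gene_id": gene,
                "tier": tier,
                "alien_margin": float(row["alien_margin"]),
                "donor_hypothesis": row["donor_hypothesis"],
                "combined_rank": float(row["combined_rank"]),
                "similarity_rank": int(row["similarity_rank"]),
                "screen_rank": int(row["screen_rank"]),
                "unique_domains": gene_unique,
                "architecture": [list(d) for d in arch],
                "fusions": gene_fusions,
            }
        )
    return dossiers


def write_dossiers(dossiers: list[dict], path: str | Path) -> None:
    Path(path).write_text(json.dumps(dossiers, indent=1, sort_keys=True) + "\n")
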