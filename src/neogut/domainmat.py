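"""Presence/copy-number matrices, gain/loss classification and fusions.

The comparative step of the pipeline reduces gene families and protein
domains to per-taxon copy-number matrices and applies permissive
presence/absence rules to label each row:

* ``shared`` — missing in at most 5 of 26 recipient taxa and at most 1 of
  5 outgroup taxa (defaults scale proportionally for other group sizes);
* ``unique_recipient`` — absent from every outgroup (and, for domains,
  every other fungal) taxon while present in at least 21 of 26 recipients;
* ``lost_recipient`` — absent from all recipients but present in at least
  4 of the 5 outgroup taxa;
* ``enriched_recipient`` (domains only) — mean recipient copy number at
  least ``enrichment_fold`` times the outgroup mean, both positive.

Copy numbers come from per-domain HMMER3 table rows filtered at
independent E-value 1e-2; multiple hits of one domain on one protein count
as multiple copies.  The visualization matrix applies ln(count + 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .lineage import LineageMap, taxon_of_protein

LABELS = (
    "shared",
    "unique_recipient",
    "lost_recipient",
    "enriched_recipient",
    "absent_everywhere",
    "unclassified",
)


class DomtblFormatError(ValueError):
    """Raised for malformed per-domain table lines."""


@dataclass(frozen=True)
class Thresholds:
    """Classification thresholds, stored as absolute counts.

    Defaults reproduce the reference study exactly at 26 recipient and 5
    outgroup taxa; :meth:`for_groups` rescales them proportionally for
    other group sizes.
    """

    max_missing_recipient_shared: int = 5
    max_missing_outgroup_shared: int = 1
    min_present_recipient_unique: int = 21
    min_present_outgroup_lost: int = 4
    domain_evalue: float = 1e-2
    homolog_search_evalue: float = 1e-3
    cdd_evalue: float = 1e-5
    enrichment_fold: float = 4.0
    donor_support: float = 80.0

    def __post_init__(self) -> None:
        for name in ("domain_evalue", "homolog_search_evalue", "cdd_evalue"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def for_groups(self, n_recipient: int, n_outgroup: int) -> "Thresholds":
        """Rescale the 5/26, 1/5, 21/26 and 4/5 defaults to other group
        sizes (missing allowances round down, presence requirements round
        up).  Returns self unchanged at the reference sizes 26/5."""
        if n_recipient == 26 and n_outgroup == 5:
            return self
        return replace(
            self,
            max_missing_recipient_shared=math.floor(5 / 26 * n_recipient),
            max_missing_outgroup_shared=math.floor(1 / 5 * n_outgroup),
            min_present_recipient_unique=math.ceil(21 / 26 * n_recipient),
            min_present_outgroup_lost=math.ceil(4 / 5 * n_outgroup),
        )


# ---------------------------------------------------------------------------
# domtblout parsing
# ---------------------------------------------------------------------------

DOMHIT_COLUMNS = [
    "protein_id",
    "taxon_id",
    "domain_name",
    "domain_accession",
    "i_evalue",
    "score",
    "env_start",
    "env_end",
]


def parse_domtbl(
    path: str | Path,
    thresholds: Thresholds | None = None,
    taxon_of: Callable[[str], str] = taxon_of_protein,
) -> pd.DataFrame:
    """Parse a HMMER3 per-domain table (``--domtblout`` layout, hmmscan
    orientation: target = domain, query = protein).

    Rows with independent E-value above ``thresholds.domain_evalue`` are
    dropped; comment lines are ignored.  Returns a DataFrame with columns
    ``protein_id, taxon_id, domain_name, domain_accession, i_evalue,
    score, env_start, env_end`` (1-based inclusive envelope coordinates).
    """
    thresholds = thresholds or Thresholds()
    records = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 22)
            if len(parts) < 22:
                raise DomtblFormatError(
                    f"{path}:{lineno}: expected >= 23 whitespace-separated "
                    f"columns, got {len(parts)}"
                )
            try:
                i_evalue = float(parts[12])
                score = float(parts[13])
                env_start = int(parts[19])
                env_end = int(parts[20])
            except ValueError as exc:
                raise DomtblFormatError(f"{path}:{lineno}: {exc}") from None
            if i_evalue > thresholds.domain_evalue:
                continue
            if not 1 <= env_start <= env_end:
                raise DomtblFormatError(
                    f"{path}:{lineno}: invalid envelope {env_start}..{env_end}"
                )
            records.append(
                (
                    parts[3],
                    taxon_of(parts[3]),
                    parts[0],
                    parts[1],
                    i_evalue,
                    score,
                    env_start,
                    env_end,
                )
            )
    return pd.DataFrame(records, columns=DOMHIT_COLUMNS)


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------


def build_count_matrix(
    items: pd.DataFrame,
    lineage_map: LineageMap,
    row_field: str = "domain_name",
) -> pd.DataFrame:
    """Per-taxon copy-number matrix (rows = domains or families, columns =
    every taxon in the lineage map).

    ``items`` must carry ``taxon_id`` and the chosen ``row_field``
    (``domain_name`` for domain hits, ``family_id`` for family membership
    tables).  Rows with no hits anywhere do not appear; taxa with no hits
    appear as zero columns.  Unknown taxa are an error.
    """
    taxa = lineage_map.taxa()
    unknown = sorted(set(items["taxon_id"]) - set(taxa))
    if unknown:
        raise ValueError(f"taxa absent from the lineage map: {unknown}")
    counts = (
        items.groupby([row_field, "taxon_id"], sort=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=taxa, fill_value=0)
    )
    counts.index.name = row_field
    counts.columns.name = "taxon_id"
    return counts.astype(int)


def family_members_frame(
    families: dict[str, dict[str, list[str]]]
) -> pd.DataFrame:
    """Flatten ``family -> taxon -> genes`` into a long membership table."""
    records = [
        (fid, taxon, gene)
        for fid, by_taxon in families.items()
        for taxon, genes in by_taxon.items()
        for gene in genes
    ]
    return pd.DataFrame(records, columns=["family_id", "taxon_id", "protein_id"])


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def _group_slices(
    matrix: pd.DataFrame, lineage_map: LineageMap
) -> dict[str, pd.DataFrame]:
    return {
        group: matrix[[t for t in lineage_map.taxa(group) if t in matrix.columns]]
        for group in ("recipient", "outgroup", "other_fungi")
    }


def classify_families(
    matrix: pd.DataFrame,
    lineage_map: LineageMap,
    thresholds: Thresholds | None = None,
) -> pd.DataFrame:
    """Label each gene-family row as shared / unique_recipient /
    lost_recipient / unclassified from recipient and outgroup presence.

    Precedence: unique > lost > shared > unclassified; rows that are zero
    in every column of the matrix are ``absent_everywhere``.
    """
    thresholds = (thresholds or Thresholds()).for_groups(
        lineage_map.n_recipient, lineage_map.n_outgroup
    )
    missing_cols = set(lineage_map.recipients + lineage_map.outgroups) - set(
        matrix.columns
    )
    if missing_cols:
        raise ValueError(f"matrix lacks taxa columns: {sorted(missing_cols)}")
    g = _group_slices(matrix, lineage_map)
    n_r, n_o = lineage_map.n_recipient, lineage_map.n_outgroup
    pres_r = (g["recipient"] > 0).sum(axis=1)
    pres_o = (g["outgroup"] > 0).sum(axis=1)

    unique = (pres_r >= thresholds.min_present_recipient_unique) & (pres_o == 0)
    lost = (pres_r == 0) & (pres_o >= thresholds.min_present_outgroup_lost)
    shared = ((n_r - pres_r) <= thresholds.max_missing_recipient_shared) & (
        (n_o - pres_o) <= thresholds.max_missing_outgroup_shared
    )
    absent = (matrix > 0).sum(axis=1) == 0

    label = pd.Series("unclassified", index=matrix.index, dtype=object)
    label[shared] = "shared"
    label[lost] = "lost_recipient"
    label[unique] = "unique_recipient"
    label[absent] = "absent_everywhere"
    return pd.DataFrame(
        {
            "item_id": matrix.index,
            "label": label.values,
            "n_present_recipient": pres_r.values,
            "n_present_outgroup": pres_o.values,
            "copies_recipient": g["recipient"].sum(axis=1).values,
            "copies_outgroup": g["outgroup"].sum(axis=1).values,
        }
    ).set_index("item_id")


def classify_domains(
    matrix: pd.DataFrame,
    lineage_map: LineageMap,
    thresholds: Thresholds | None = None,
) -> pd.DataFrame:
    """Label each domain row, additionally requiring recipient-unique
    domains to be absent from every non-recipient fungal taxon supplied
    and flagging recipient-enriched domains by fold change of group mean
    copy numbers.

    Precedence: unique > lost > enriched > shared > unclassified.
    """
    thresholds = (thresholds or Thresholds()).for_groups(
        lineage_map.n_recipient, lineage_map.n_outgroup
    )
    g = _group_slices(matrix, lineage_map)
    n_r, n_o = lineage_map.n_recipient, lineage_map.n_outgroup
    pres_r = (g["recipient"] > 0).sum(axis=1)
    pres_o = (g["outgroup"] > 0).sum(axis=1)
    fungal_nonrecipient = pd.concat([g["outgroup"], g["other_fungi"]], axis=1)
    fungal_copies = fungal_nonrecipient.sum(axis=1)

    mean_r = g["recipient"].mean(axis=1) if n_r else pd.Series(0.0, index=matrix.index)
    mean_o = g["outgroup"].mean(axis=1) if n_o else pd.Series(0.0, index=matrix.index)

    unique = (pres_r >= thresholds.min_present_recipient_unique) & (fungal_copies == 0)
    lost = (pres_r == 0) & (pres_o >= thresholds.min_present_outgroup_lost)
    enriched = (
        (mean_r >= thresholds.enrichment_fold * mean_o) & (mean_r > 0) & (mean_o > 0)
    )
    shared = ((n_r - pres_r) <= thresholds.max_missing_recipient_shared) & (
        (n_o - pres_o) <= thresholds.max_missing_outgroup_shared
    )
    absent = (matrix > 0).sum(axis=1) == 0

    label = pd.Series("unclassified", index=matrix.index, dtype=object)
    label[shared] = "shared"
    label[enriched] = "enriched_recipient"
    label[lost] = "lost_recipient"
    label[unique] = "unique_recipient"
    label[absent] = "absent_everywhere"
    return pd.DataFrame(
        {
            "item_id": matrix.index,
            "label": label.values,
            "n_present_recipient": pres_r.values,
            "n_present_outgroup": pres_o.values,
            "copies_recipient": g["recipient"].sum(axis=1).values,
            "copies_outgroup": g["outgroup"].sum(axis=1).values,
            "mean_copies_recipient": mean_r.values,
            "mean_copies_outgroup": mean_o.values,
        }
    ).set_index("item_id")


def unique_fraction(n_unique: int, n_total: int, digits: int = 2) -> float:
    """Percentage of rows unique to the recipient lineage, e.g. 40 unique
    domains of a 5,980-domain pangenome -> 0.67 (%)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round(100.0 * n_unique / n_total, digits)


# ---------------------------------------------------------------------------
# heatmap matrix
# ---------------------------------------------------------------------------


def heatmap_matrix(
    matrix: pd.DataFrame, classification: pd.DataFrame | None = None
) -> pd.DataFrame:
    """ln(count + 1) transform of a copy-number matrix.

    The +1 offset maps absence to exactly 0 while keeping the transform
    strictly monotone in the count.  If a classification is supplied, rows
    are ordered by label then name.
    """
    if (matrix.values < 0).any():
        raise ValueError("copy counts must be non-negative")
    out = np.log(matrix.astype(float) + 1.0)
    if classification is not None:
        order = sorted(
            out.index,
            key=lambda i: (
                LABELS.index(classification.loc[i, "label"])
                if i in classification.index
                else len(LABELS),
                str(i),
            ),
        )
        out = out.loc[order]
    return out


def plot_heatmap(matrix: pd.DataFrame, path: str | Path) -> None:
    """Render the ln-scaled matrix to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(4, 0.22 * matrix.shape[1]), max(4, 0.12 * matrix.shape[0]))
    )
    im = ax.imshow(matrix.values, aspect="auto", cmap="viridis")
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=90, fontsize=5)
    ax.set_yticks(range(matrix.shape[0]), matrix.index, fontsize=4)
    fig.colorbar(im, ax=ax, label="ln(copies + 1)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# architectures and fusions
# ---------------------------------------------------------------------------


def architectures(hits: pd.DataFrame) -> dict[str, list[tuple[str, int, int]]]:
    """Ordered per-protein domain architecture.

    Hits are sorted by envelope start; overlapping envelopes of the *same*
    domain are merged into one instance, overlapping envelopes of
    different domains are both kept.
    """
    archs: dict[str, list[tuple[str, int, int]]] = {}
    for protein, sub in hits.groupby("protein_id", sort=True):
        rows = sorted(
            zip(sub["domain_name"], sub["env_start"], sub["env_end"]),
            key=lambda r: (r[1], r[2], r[0]),
        )
        merged: list[tuple[str, int, int]] = []
        for name, start, end in rows:
            if merged and merged[-1][0] == name and start <= merged[-1][2]:
                prev = merged[-1]
                merged[-1] = (name, prev[1], max(prev[2], end))
            else:
                merged.append((name, int(start), int(end)))
        archs[protein] = merged
    return archs


def detect_fusions(
    archs: dict[str, list[tuple[str, int, int]]],
    foreign_domains: Sequence[str],
    native_domains: Sequence[str],
) -> pd.DataFrame:
    """Proteins carrying a foreign-classified domain together with at
    least one native-classified domain.

    For each such protein the native partners are reported with their
    position relative to the (first) foreign domain: ``3prime`` if the
    partner starts after the foreign envelope ends, else ``5prime``.
    """
    foreign = set(foreign_domains)
    native = set(native_domains)
    records = []
    for protein in sorted(archs):
        arch = archs[protein]
        foreign_hits = [d for d in arch if d[0] in foreign]
        native_hits = [d for d in arch if d[0] in native]
        if not foreign_hits or not native_hits:
            continue
        fname, fstart, fend = foreign_hits[0]
        for name, start, end in native_hits:
            position = "3prime" if start > fend else "5prime"
            records.append((protein, fname, name, position, start, end))
    return pd.DataFrame(
        records,
        columns=[
            "protein_id",
            "foreign_domain",
            "native_domain",
            "native_position",
            "native_start",
            "native_end",
        ],
    )


def architectures_to_frame(
    archs: dict[str, list[tuple[str, int, int]]]
) -> pd.DataFrame:
    """Architecture table with one ``domain@start-end;...`` string per protein."""
    records = [
        (protein, ";".join(f"{d}@{s}-{e}" for d, s, e in arch))
        for protein, arch in sorted(archs.items())
    ]
    return pd.DataFrame(records, columns=["protein_id", "architecture"])
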