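"""Taxon-to-lineage assignments.

Every analysis in this package is phrased relative to a *recipient* lineage
(the anaerobic gut fungi, phylum Neocallimastigomycota), a fungal *outgroup*
(free-living chytrids), and a set of reference lineages that may act as
homolog sources or transfer donors (other fungi, animals, plants, bacteria,
archaea, protists).  The :class:`LineageMap` records which taxon belongs to
which group and provides the group partitions the classification and
screening rules operate on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

#: Closed vocabulary of lineage groups.
GROUPS: tuple[str, ...] = (
    "recipient",
    "outgroup",
    "other_fungi",
    "animal",
    "plant",
    "bacteria",
    "archaea",
    "protist",
)

#: Fungal groups other than the recipient lineage itself.  The alien filter
#: compares the best hit among these against the best non-fungal hit.
FUNGAL_GROUPS: frozenset[str] = frozenset({"outgroup", "other_fungi"})

#: Non-fungal groups that may act as transfer donors.
NONFUNGAL_GROUPS: tuple[str, ...] = ("animal", "plant", "bacteria", "archaea", "protist")


class LineageError(ValueError):
    """Raised for unknown taxa or malformed lineage assignments."""


@dataclass
class LineageMap:
    """Assignment of each taxon to exactly one lineage group."""

    assignments: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for taxon, group in self.assignments.items():
            if group not in GROUPS:
                raise LineageError(
                    f"taxon {taxon!r} assigned to unknown group {group!r}; "
                    f"expected one of {GROUPS}"
                )

    # -- queries ---------------------------------------------------------

    def group_of(self, taxon: str) -> str:
        try:
            return self.assignments[taxon]
        except KeyError:
            raise LineageError(f"taxon {taxon!r} is not in the lineage map") from None

    def taxa(self, group: str | None = None) -> list[str]:
        """All taxa, or the taxa of one group, in sorted order."""
        if group is None:
            return sorted(self.assignments)
        if group not in GROUPS:
            raise LineageError(f"unknown group {group!r}")
        return sorted(t for t, g in self.assignments.items() if g == group)

    @property
    def recipients(self) -> list[str]:
        return self.taxa("recipient")

    @property
    def outgroups(self) -> list[str]:
        return self.taxa("outgroup")

    @property
    def n_recipient(self) -> int:
        return len(self.recipients)

    @property
    def n_outgroup(self) -> int:
        return len(self.outgroups)

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.assignments

    def __len__(self) -> int:
        return len(self.assignments)

    # -- I/O -------------------------------------------------------------

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LineageMap":
        """Read a two-column ``taxon_id<TAB>group`` table (no header)."""
        assignments: dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise LineageError(f"{path}:{lineno}: expected 2 tab-separated fields")
            taxon, group = parts
            if taxon in assignments:
                raise LineageError(f"{path}:{lineno}: duplicate taxon {taxon!r}")
            assignments[taxon] = group
        return cls(assignments)

    def to_tsv(self, path: str | Path) -> None:
        lines = [f"{t}\t{g}" for t, g in sorted(self.assignments.items())]
        Path(path).write_text("\n".join(lines) + "\n")


def taxon_of_protein(protein_id: str) -> str:
    """Extract the taxon from a ``taxon|gene`` protein identifier.

    This is the identifier convention used throughout the package for
    per-taxon proteomes; identifiers without a ``|`` separator are rejected.
    """
    taxon, sep, _ = protein_id.partition("|")
    if not sep or not taxon:
        raise LineageError(
            f"protein id {protein_id!r} does not follow the 'taxon|gene' convention"
        )
    return taxon
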