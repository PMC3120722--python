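"""Three-way proteome overlap and evidence aggregation.

Compares a query fluid proteome (e.g. arachnoid cyst fluid) against two
reference fluid databases (e.g. CSF and plasma) at the accession level:
exact seven-region Venn partition, then per-protein evidence flags that
combine database membership with targeted-MS (MRM) detection outcomes for
the proteins absent from both databases, and flat annotation-category
summaries in the style of GO pie charts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .io_formats import AccessionSet, canonical_accession

__all__ = [
    "RegionCounts",
    "PartitionCounts",
    "three_way_partition",
    "build_evidence_table",
    "summarize_evidence",
    "AnnotationMap",
    "read_annotation_tsv",
    "annotation_summary",
    "annotation_comparison",
]

REGIONS = ("a_only", "b_only", "c_only", "ab_only", "ac_only", "bc_only", "abc")


@dataclass(frozen=True)
class RegionCounts:
    """Sizes of the seven disjoint regions of a three-set Venn diagram.

    ``ab_only`` counts elements in A and B but not C, etc.; ``abc`` the
    triple intersection.
    """

    a_only: int = 0
    b_only: int = 0
    c_only: int = 0
    ab_only: int = 0
    ac_only: int = 0
    bc_only: int = 0
    abc: int = 0

    def __post_init__(self) -> None:
        for name in REGIONS:
            if getattr(self, name) < 0:
                raise ValueError(f"region count {name} must be >= 0")

    @property
    def size_a(self) -> int:
        return self.a_only + self.ab_only + self.ac_only + self.abc

    @property
    def size_b(self) -> int:
        return self.b_only + self.ab_only + self.bc_only + self.abc

    @property
    def size_c(self) -> int:
        return self.c_only + self.ac_only + self.bc_only + self.abc

    @property
    def total(self) -> int:
        return sum(getattr(self, name) for name in REGIONS)

    def as_dict(self) -> dict[str, int]:
        return {name: getattr(self, name) for name in REGIONS}


@dataclass(frozen=True)
class PartitionCounts:
    """A computed partition: region counts plus the explicit member lists."""

    regions: RegionCounts
    members: dict[str, tuple[str, ...]]
    names: tuple[str, str, str]

    def as_dict(self) -> dict:
        return {
            "sets": {
                self.names[0]: self.regions.size_a,
                self.names[1]: self.regions.size_b,
                self.names[2]: self.regions.size_c,
            },
            "regions": self.regions.as_dict(),
        }


def three_way_partition(
    a: AccessionSet, b: AccessionSet, c: AccessionSet
) -> PartitionCounts:
    """Exact seven-region partition of three accession sets.

    The region member lists are pairwise disjoint and cover the union; empty
    sets are valid input.
    """
    A, B, C = a.accessions, b.accessions, c.accessions
    members = {
        "a_only": A - B - C,
        "b_only": B - A - C,
        "c_only": C - A - B,
        "ab_only": (A & B) - C,
        "ac_only": (A & C) - B,
        "bc_only": (B & C) - A,
        "abc": A & B & C,
    }
    regions = RegionCounts(**{k: len(v) for k, v in members.items()})
    return PartitionCounts(
        regions=regions,
        members={k: tuple(sorted(v)) for k, v in members.items()},
        names=(a.name, b.name, c.name),
    )


# ---------------------------------------------------------------------------
# Evidence aggregation
# ---------------------------------------------------------------------------

def build_evidence_table(
    ac: AccessionSet,
    csf_db: AccessionSet,
    plasma_db: AccessionSet,
    targeted: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-protein evidence flags for the query proteome.

    ``targeted`` maps accession -> targeted-MS peptide count for proteins
    absent from both databases (0 encodes tested-but-not-detected, "ND").
    Proteins present in either database are not targeted-tested; a targeted
    key that is also a database member is a consistency error.

    Returns a DataFrame indexed by accession with boolean columns
    ``in_csf_db``, ``in_plasma_db``, ``tested``, ``evidence_csf``,
    ``evidence_any`` and nullable-integer ``targeted_peptides`` (NA when the
    protein was not tested). ``evidence_csf`` is true when the protein is in
    the CSF database or was detected by targeted MS in CSF; ``evidence_any``
    additionally admits plasma-database membership.
    """
    targeted = {canonical_accession(k): int(v) for k, v in (targeted or {}).items()}
    bad_keys = set(targeted) - ac.accessions
    if bad_keys:
        raise ValueError(f"targeted accession(s) not in the query set: {sorted(bad_keys)}")
    in_db = [k for k in targeted if k in csf_db.accessions or k in plasma_db.accessions]
    if in_db:
        raise ValueError(
            f"targeted accession(s) already present in a reference database: {sorted(in_db)}"
        )
    for k, v in targeted.items():
        if v < 0:
            raise ValueError(f"negative targeted peptide count for {k}")

    rows = []
    for acc in sorted(ac.accessions):
        in_csf = acc in csf_db.accessions
        in_plasma = acc in plasma_db.accessions
        tested = acc in targeted
        peptides = targeted.get(acc)
        evidence_csf = in_csf or (tested and peptides >= 1)
        rows.append(
            {
                "accession": acc,
                "in_csf_db": in_csf,
                "in_plasma_db": in_plasma,
                "tested": tested,
                "targeted_peptides": peptides,
                "evidence_csf": evidence_csf,
                "evidence_any": evidence_csf or in_plasma,
            }
        )
    table = pd.DataFrame(rows).set_index("accession")
    table["targeted_peptides"] = table["targeted_peptides"].astype("Int64")
    return table


def summarize_evidence(table: pd.DataFrame) -> dict[str, int]:
    """Headline counts from an evidence table.

    ``n_unexplained`` is the number of query proteins with no evidence in
    either reference fluid (not in a database, not detected by targeted MS);
    ``n_any_evidence + n_unexplained == n_ac`` always.
    """
    n_ac = len(table)
    n_any = int(table["evidence_any"].sum())
    return {
        "n_ac": n_ac,
        "n_csf_evidence": int(table["evidence_csf"].sum()),
        "n_any_evidence": n_any,
        "n_absent_plasma_db": int((~table["in_plasma_db"]).sum()),
        "n_unexplained": n_ac - n_any,
    }


# ---------------------------------------------------------------------------
# Annotation summaries
# ---------------------------------------------------------------------------

#: facet -> accession -> set of category labels
AnnotationMap = dict[str, dict[str, set[str]]]


def read_annotation_tsv(path: str | Path) -> AnnotationMap:
    """Read a flat accession -> category mapping.

    Format: ``accession<TAB>facet<TAB>category`` per line, '#' comments
    allowed; a protein may carry several categories per facet.
    """
    amap: AnnotationMap = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3 or not all(f.strip() for f in fields):
                raise ValueError(f"{path}:{lineno}: expected accession<TAB>facet<TAB>category")
            acc, facet, category = (f.strip() for f in fields)
            amap.setdefault(facet, {}).setdefault(canonical_accession(acc), set()).add(category)
    return amap


def annotation_summary(
    accessions: AccessionSet, amap: AnnotationMap, facet: str
) -> tuple[pd.DataFrame, list[str]]:
    """Percentage of proteins per annotation category for one facet.

    A protein contributes to every category it carries, so percentages may
    sum past 100. Percentages are relative to the full accession-set size
    and reported to one decimal place; proteins without any annotation in
    the facet are returned separately.
    """
    if len(accessions) == 0:
        raise ValueError("cannot summarize an empty accession set")
    if facet not in amap:
        raise ValueError(f"facet {facet!r} not in annotation map; known: {sorted(amap)}")
    facet_map = amap[facet]
    counts: dict[str, int] = {}
    unmapped: list[str] = []
    for acc in sorted(accessions.accessions):
        cats = facet_map.get(acc)
        if not cats:
            unmapped.append(acc)
            continue
        for cat in cats:
            counts[cat] = counts.get(cat, 0) + 1
    n = len(accessions)
    table = pd.DataFrame(
        [
            {"category": cat, "n_proteins": c, "percent": round(100.0 * c / n, 1)}
            for cat, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        ]
    )
    return table, unmapped


def annotation_comparison(
    left: AccessionSet, right: AccessionSet, amap: AnnotationMap, facet: str
) -> pd.DataFrame:
    """Side-by-side category percentages for two accession sets on one facet."""
    t_left, _ = annotation_summary(left, amap, facet)
    t_right, _ = annotation_summary(right, amap, facet)
    merged = pd.merge(
        t_left[["category", "percent"]].rename(columns={"percent": f"percent_{left.name}"}),
        t_right[["category", "percent"]].rename(columns={"percent": f"percent_{right.name}"}),
        on="category",
        how="outer",
    ).fillna(0.0)
    return merged.sort_values("category", ignore_index=True)
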