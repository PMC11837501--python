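"""Marker-gene community composition and MAG QC summaries.

Community composition is the read-coverage share of a single-copy marker
(rps3): each taxon's abundance is the summed coverage of its marker genes
over the total marker coverage in the assembly. The binned flag records
whether any of a taxon's markers falls inside a recovered MAG, which is how
assembly-level diversity is compared with what binning captured.

QC summaries aggregate CheckM-style completeness/contamination, taxonomic
class counts and the "known species" tally (ANI to nearest neighbor above a
conventional species threshold, 95 % by default; MAGs placed by RED only can
never count as known).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .annotation_model import RANKS, MAGRecord, MarkerGeneRecord
from .errors import DegenerateDataError, DesignError

UNCLASSIFIED = "unclassified"


@dataclass
class CommunityProfile:
    """Relative marker coverage per taxon; abundances sum to 1."""

    entries: list[tuple[str, float, bool]]  # (taxon, abundance, binned)

    def abundance(self, taxon: str) -> float:
        for t, a, _ in self.entries:
            if t == taxon:
                return a
        return 0.0


@dataclass
class QCSummary:
    """Quality/novelty summary for one group of MAGs.

    Means are stored at full precision; :meth:`as_display` applies 2-decimal
    half-even rounding for reporting.
    """

    group: str
    n_mags: int
    mean_completeness: float
    mean_contamination: float
    class_counts: dict[str, int] = field(default_factory=dict)
    n_known_species: int = 0

    @property
    def fraction_known(self) -> float:
        return self.n_known_species / self.n_mags if self.n_mags else 0.0

    def as_display(self) -> dict:
        return {
            "group": self.group,
            "n_mags": self.n_mags,
            "mean_completeness": round(self.mean_completeness, 2),
            "mean_contamination": round(self.mean_contamination, 2),
            "n_classes": len(self.class_counts),
            "class_counts": dict(sorted(self.class_counts.items())),
            "n_known_species": self.n_known_species,
            "fraction_known": round(self.fraction_known, 4),
        }


def marker_profile(
    markers: Sequence[MarkerGeneRecord], rank: str = "order"
) -> CommunityProfile:
    """Coverage-share community profile at a taxonomic rank.

    Taxonomy strings are semicolon-separated lineages; the profile groups
    markers by the lineage truncated at ``rank`` (an entry with fewer ranks
    keeps its full string). Output is invariant to record order and to
    splitting one taxon's coverage across records.
    """
    if not markers:
        raise DegenerateDataError("no marker records")
    if rank not in RANKS:
        raise DesignError(f"unknown rank {rank!r}; expected one of {RANKS}")
    depth = RANKS.index(rank) + 1
    totals: dict[str, float] = {}
    binned: dict[str, bool] = {}
    for m in markers:
        parts = [p.strip() for p in m.taxonomy.split(";") if p.strip()]
        taxon = ";".join(parts[:depth]) if parts else UNCLASSIFIED
        totals[taxon] = totals.get(taxon, 0.0) + m.coverage
        binned[taxon] = binned.get(taxon, False) or m.mag_id is not None
    grand = sum(totals.values())
    if grand <= 0:
        raise DegenerateDataError("total marker coverage is zero")
    entries = sorted(
        ((t, cov / grand, binned[t]) for t, cov in totals.items()),
        key=lambda e: -e[1],
    )
    return CommunityProfile(entries=entries)


def qc_summary(
    mags: Sequence[MAGRecord],
    *,
    group: str = "all",
    ani_known_threshold: float = 95.0,
) -> QCSummary:
    """Summarize one group of MAGs.

    ``n_known_species`` counts MAGs with ani_nearest strictly above the
    threshold; RED-only placements never count. Class counts partition the
    group; MAGs with an empty class rank are grouped under "unclassified".
    """
    if not mags:
        raise DegenerateDataError("empty MAG list")
    n = len(mags)
    class_counts: dict[str, int] = {}
    for m in mags:
        cls = m.lineage.get("class", "") or UNCLASSIFIED
        class_counts[cls] = class_counts.get(cls, 0) + 1
    n_known = sum(
        1 for m in mags if m.ani_nearest is not None and m.ani_nearest > ani_known_threshold
    )
    return QCSummary(
        group=group,
        n_mags=n,
        mean_completeness=sum(m.completeness for m in mags) / n,
        mean_contamination=sum(m.contamination for m in mags) / n,
        class_counts=class_counts,
        n_known_species=n_known,
    )


def qc_summary_by_group(
    mags: Sequence[MAGRecord],
    labels: dict[str, str],
    *,
    ani_known_threshold: float = 95.0,
) -> list[QCSummary]:
    """One QCSummary per group, in first-appearance order of the labels."""
    order: dict[str, list[MAGRecord]] = {}
    for m in mags:
        if m.mag_id not in labels:
            raise DesignError(f"MAG {m.mag_id!r} has no group label")
        order.setdefault(labels[m.mag_id], []).append(m)
    return [
        qc_summary(group_mags, group=g, ani_known_threshold=ani_known_threshold)
        for g, group_mags in order.items()
    ]
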