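"""Completeness-normalized substrate-degradation gene-copy profiles.

Raw per-MAG copy totals under-count genes in incomplete genome bins, so each
substrate-class total is rescaled to copies per complete-genome equivalent:
``raw * 100 / completeness``. Contamination is a QC filter only and does not
enter the normalization. Beta oxidation is carried as a genome-level binary
(all four cycle enzymes encoded or not).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .annotation_model import AnnotationMatrix, GeneFamilyRef, MAGRecord, PathwayDef
from .errors import DegenerateDataError, DesignError, JoinError, ValidationError
from .pathway_engine import beta_oxidation_flag

SUBSTRATE_ORDER = ("cellulose", "hemicellulose", "starch", "chitin", "protein")


@dataclass
class SubstrateProfile:
    """Per-MAG normalized copy totals per substrate class + beta-oxidation bit."""

    mag_id: str
    normalized_copies: dict[str, float] = field(default_factory=dict)
    beta_oxidation: int = 0

    def __post_init__(self):
        if self.beta_oxidation not in (0, 1):
            raise ValidationError(f"{self.mag_id}: beta_oxidation must be 0 or 1")
        if any(v < 0 for v in self.normalized_copies.values()):
            raise ValidationError(f"{self.mag_id}: negative normalized copies")


@dataclass
class DietDesign:
    """MAG -> diet (group) labels; every profiled MAG labeled exactly once."""

    labels: dict[str, str]

    def group(self, mag_id: str) -> str:
        if mag_id not in self.labels:
            raise DesignError(f"MAG {mag_id!r} has no diet label")
        return self.labels[mag_id]

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.labels.values():
            seen.setdefault(g)
        return list(seen)

    def members(self, group: str) -> list[str]:
        return [m for m, g in self.labels.items() if g == group]


def normalize_copies(raw: int, completeness: float) -> float:
    """Copies per complete-genome equivalent: ``raw * 100 / completeness``."""
    if raw < 0:
        raise ValidationError(f"negative raw copy total {raw}")
    if completeness <= 0:
        raise DegenerateDataError(
            "completeness must be > 0 (zero-completeness MAGs should have been filtered)"
        )
    return raw * 100.0 / completeness


def build_profile_matrix(
    matrix: AnnotationMatrix,
    mags: Sequence[MAGRecord],
    substrate_families: Mapping[str, Sequence[GeneFamilyRef]],
    beta_def: PathwayDef,
) -> list[SubstrateProfile]:
    """One profile per MAG: per-class normalized copy totals + beta binary.

    Every matrix MAG must have a metadata record (with completeness > 0);
    MAGs with a record but no annotations get all-zero profiles.
    """
    by_id = {m.mag_id: m for m in mags}
    missing = [m for m in matrix.mags if m not in by_id]
    if missing:
        raise JoinError(f"annotation MAG(s) without metadata: {', '.join(sorted(missing))}")
    full = matrix.ensure_mags([m.mag_id for m in mags])
    profiles = []
    for rec in mags:
        row = full.row(rec.mag_id)
        copies = {
            cls: normalize_copies(
                int(sum(row.get(f, 0) for f in set(fams))), rec.completeness
            )
            for cls, fams in substrate_families.items()
        }
        profiles.append(
            SubstrateProfile(
                mag_id=rec.mag_id,
                normalized_copies=copies,
                beta_oxidation=beta_oxidation_flag(row, beta_def),
            )
        )
    return profiles


def profiles_to_frame(
    profiles: Sequence[SubstrateProfile], design: DietDesign | None = None
) -> pd.DataFrame:
    """Tabular form: mag_id [, diet], one column per substrate class,
    fatty_acid_binary last."""
    classes = sorted({c for p in profiles for c in p.normalized_copies})
    ordered = [c for c in SUBSTRATE_ORDER if c in classes] + [
        c for c in classes if c not in SUBSTRATE_ORDER
    ]
    rows = []
    for p in profiles:
        row = {"mag_id": p.mag_id}
        if design is not None:
            row["diet"] = design.group(p.mag_id)
        row.update({c: p.normalized_copies.get(c, 0.0) for c in ordered})
        row["fatty_acid_binary"] = p.beta_oxidation
        rows.append(row)
    return pd.DataFrame(rows)


def profiles_from_frame(
    frame: pd.DataFrame,
) -> tuple[list[SubstrateProfile], DietDesign | None]:
    """Inverse of :func:`profiles_to_frame` (for profile tables on disk)."""
    classes = [
        c for c in frame.columns if c not in ("mag_id", "diet", "fatty_acid_binary")
    ]
    profiles = []
    labels: dict[str, str] = {}
    for row in frame.itertuples(index=False):
        row = dict(zip(frame.columns, row))
        profiles.append(
            SubstrateProfile(
                mag_id=str(row["mag_id"]),
                normalized_copies={c: float(row[c]) for c in classes},
                beta_oxidation=int(row.get("fatty_acid_binary", 0)),
            )
        )
        if "diet" in row:
            labels[str(row["mag_id"])] = str(row["diet"])
    return profiles, (DietDesign(labels=labels) if labels else None)


def fold_change(
    profiles: Sequence[SubstrateProfile],
    design: DietDesign,
    substrate: str,
    numerator: str,
    denominator: str,
) -> float:
    """Ratio of per-diet arithmetic means of normalized copies."""
    groups = {numerator: [], denominator: []}
    for p in profiles:
        g = design.group(p.mag_id)
        if g in groups:
            if substrate not in p.normalized_copies:
                raise DesignError(f"{p.mag_id}: no {substrate!r} value in profile")
            groups[g].append(p.normalized_copies[substrate])
    for name, values in groups.items():
        if not values:
            raise DesignError(f"diet group {name!r} is empty")
    denom_mean = sum(groups[denominator]) / len(groups[denominator])
    if denom_mean == 0:
        raise DegenerateDataError(
            f"mean {substrate!r} copies in {denominator!r} is zero; fold change undefined"
        )
    num_mean = sum(groups[numerator]) / len(groups[numerator])
    return num_mean / denom_mean
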