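"""Domain types and readers/writers for MAG functional-annotation data.

The analysis starts from four flat tables rather than from sequence data:

* MAG metadata — one row per metagenome-assembled genome with its GTDB-style
  lineage, CheckM-style completeness/contamination percentages, mean read
  coverage and either an ANI value to its nearest database neighbor or, when
  ANI placement was impossible, a relative evolutionary distance (RED).
* gene-family annotations — long-format (mag_id, namespace, family_id[, count])
  rows produced by tools such as dbCAN (CAZy families), BlastKOALA/kofamscan
  (KEGG Orthology), MEROPS scans (peptidase families) and HydDB-style
  hydrogenase group assignment.
* pathway definitions — declarative YAML rules evaluated by
  :mod:`magdiet.pathway_engine`.
* marker-gene coverage — per-gene read depth of a single-copy marker (rps3)
  with its best-hit taxonomy, used for assembly-level community profiling.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .errors import (
    CycleError,
    PathwayDefinitionError,
    ReferenceResolutionError,
    SchemaError,
    TableParseError,
    UniquenessError,
    ValidationError,
)

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

NAMESPACES = ("CAZY", "KO", "MEROPS", "HYDDB", "CUSTOM")

#: Retention rule applied to MAG tables at read time (CheckM-style bins):
#: completeness at least 50 %, contamination at most 20 %.
QUALITY_MIN_COMPLETENESS = 50.0
QUALITY_MAX_CONTAMINATION = 20.0


@dataclass(frozen=True, order=True)
class GeneFamilyRef:
    """A namespaced gene-family identifier, e.g. ``CAZY:GH5`` or ``KO:K00925``.

    Identity is case-insensitive on ``family_id`` and whitespace-stripped;
    the canonical form stored here is upper-case.
    """

    namespace: str
    family_id: str

    def __post_init__(self):
        ns = self.namespace.strip().upper()
        fam = self.family_id.strip().upper()
        if ns not in NAMESPACES:
            raise SchemaError(f"unknown annotation namespace {self.namespace!r}")
        if not fam:
            raise ValidationError("empty family_id")
        object.__setattr__(self, "namespace", ns)
        object.__setattr__(self, "family_id", fam)

    def __str__(self) -> str:  # "CAZY:GH5"
        return f"{self.namespace}:{self.family_id}"

    @classmethod
    def parse(cls, token: str) -> "GeneFamilyRef":
        ns, _, fam = token.partition(":")
        if not _:
            raise SchemaError(f"family token {token!r} lacks a namespace prefix")
        return cls(ns, fam)


@dataclass
class MAGRecord:
    """Metadata for one metagenome-assembled genome."""

    mag_id: str
    lineage: Mapping[str, str] = field(default_factory=dict)
    completeness: float = 0.0
    contamination: float = 0.0
    coverage: float = 0.0
    ani_nearest: float | None = None
    red: float | None = None
    neighbor_accession: str | None = None

    def __post_init__(self):
        if not self.mag_id or not str(self.mag_id).strip():
            raise ValidationError("mag_id must be a non-empty token")
        self.mag_id = str(self.mag_id).strip()
        self.lineage = {r: str(self.lineage.get(r, "") or "") for r in RANKS}
        if not 0.0 <= self.completeness <= 100.0:
            raise ValidationError(
                f"{self.mag_id}: completeness {self.completeness} outside [0, 100]"
            )
        if self.contamination < 0:
            raise ValidationError(f"{self.mag_id}: negative contamination")
        if self.coverage < 0:
            raise ValidationError(f"{self.mag_id}: negative coverage")
        if self.ani_nearest is not None and not 0.0 <= self.ani_nearest <= 100.0:
            raise ValidationError(f"{self.mag_id}: ANI {self.ani_nearest} outside [0, 100]")
        if self.red is not None and not 0.0 <= self.red <= 1.0:
            raise ValidationError(f"{self.mag_id}: RED {self.red} outside [0, 1]")

    @property
    def rank(self) -> Mapping[str, str]:
        return self.lineage

    def passes_quality(
        self,
        min_completeness: float = QUALITY_MIN_COMPLETENESS,
        max_contamination: float = QUALITY_MAX_CONTAMINATION,
    ) -> bool:
        return (
            self.completeness >= min_completeness
            and self.contamination <= max_contamination
        )


@dataclass
class MarkerGeneRecord:
    """One single-copy marker gene (rps3) with coverage and best-hit taxonomy."""

    gene_id: str
    taxonomy: str
    coverage: float
    mag_id: str | None = None

    def __post_init__(self):
        if self.coverage < 0:
            raise ValidationError(f"{self.gene_id}: negative coverage")


class AnnotationMatrix:
    """MAG x gene-family copy-count matrix.

    Backed by an integer pandas DataFrame whose columns are
    :class:`GeneFamilyRef` objects; absent cells are zero.
    """

    def __init__(self, frame: pd.DataFrame):
        if (frame.to_numpy() < 0).any():
            raise ValidationError("annotation counts must be non-negative")
        self._frame = frame.astype(int)
        self._frame.index = self._frame.index.astype(str)

    # -- construction -----------------------------------------------------
    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, GeneFamilyRef, int]]
    ) -> "AnnotationMatrix":
        """Aggregate (mag_id, family, count) rows by summation."""
        rows: dict[str, dict[GeneFamilyRef, int]] = {}
        for mag_id, ref, count in records:
            if count < 0:
                raise ValidationError(f"{mag_id}/{ref}: negative count {count}")
            cell = rows.setdefault(str(mag_id), {})
            cell[ref] = cell.get(ref, 0) + int(count)
        frame = pd.DataFrame.from_dict(rows, orient="index").fillna(0)
        if frame.empty:
            frame = pd.DataFrame(index=pd.Index([], dtype=str))
        return cls(frame)

    @classmethod
    def empty(cls, mags: Sequence[str] = ()) -> "AnnotationMatrix":
        return cls(pd.DataFrame(index=pd.Index(list(mags), dtype=str)))

    # -- access ------------------------------------------------------------
    @property
    def mags(self) -> list[str]:
        return list(self._frame.index)

    @property
    def families(self) -> list[GeneFamilyRef]:
        return list(self._frame.columns)

    def copies(self, mag_id: str, ref: GeneFamilyRef) -> int:
        if mag_id not in self._frame.index or ref not in self._frame.columns:
            return 0
        return int(self._frame.at[mag_id, ref])

    def row(self, mag_id: str) -> pd.Series:
        """Copy counts for one MAG, keyed by GeneFamilyRef (0 if MAG unknown)."""
        if mag_id in self._frame.index:
            return self._frame.loc[mag_id]
        return pd.Series(0, index=self._frame.columns, dtype=int)

    def family_total(self, mag_id: str, refs: Iterable[GeneFamilyRef]) -> int:
        """Summed copies over a family list, each family counted once."""
        row = self.row(mag_id)
        return int(sum(row.get(ref, 0) for ref in set(refs)))

    def to_frame(self) -> pd.DataFrame:
        return self._frame.copy()

    def ensure_mags(self, mag_ids: Sequence[str]) -> "AnnotationMatrix":
        """Add all-zero rows for listed MAGs missing from the matrix."""
        missing = [m for m in mag_ids if m not in self._frame.index]
        if not missing:
            return self
        frame = self._frame.reindex(self._frame.index.union(missing, sort=False))
        return AnnotationMatrix(frame.fillna(0))

    def unmatched_mags(self, records: Sequence[MAGRecord]) -> list[str]:
        """Matrix MAG ids with no metadata record (reported, never dropped)."""
        known = {r.mag_id for r in records}
        return [m for m in self.mags if m not in known]

    def __eq__(self, other) -> bool:
        if not isinstance(other, AnnotationMatrix):
            return NotImplemented
        a = self._frame.sort_index().sort_index(axis=1)
        b = other._frame.sort_index().sort_index(axis=1)
        return a.shape == b.shape and a.index.equals(b.index) and list(a.columns) == list(b.columns) and (a.to_numpy() == b.to_numpy()).all()


# ---------------------------------------------------------------------------
# Pathway definitions
# ---------------------------------------------------------------------------

PATHWAY_CATEGORIES = (
    "degradation_chain",
    "enzyme_fraction",
    "gene_set_all",
    "marker",
    "any_of_pathways",
)

SUBSTRATE_CLASSES = (
    "cellulose",
    "hemicellulose",
    "starch",
    "chitin",
    "protein",
    "fatty_acid",
    "other",
)

DEFAULT_FRACTION_THRESHOLD = 0.8


@dataclass(frozen=True)
class PathwayStep:
    """One enzymatic step; satisfied when any alternative family has a copy."""

    step_id: str
    alternatives: frozenset[GeneFamilyRef]

    def __post_init__(self):
        if not self.alternatives:
            raise PathwayDefinitionError(f"step {self.step_id!r} has no alternatives")


@dataclass(frozen=True)
class PathwayDef:
    """A declarative pathway rule.

    Categories:

    * ``degradation_chain`` — ordered hydrolysis chain; complete only when
      every step is encoded (start-to-finish depolymerisation).
    * ``enzyme_fraction`` — complete when at least ``threshold`` of the steps
      are encoded (default 0.8, the "at least 80 % of the enzymes" rule).
    * ``gene_set_all`` — every listed gene required (e.g. the four-enzyme
      beta-oxidation cycle).
    * ``marker`` — a single diagnostic step.
    * ``any_of_pathways`` — complete when any member pathway is complete
      (e.g. hemicellulose over the xylan/mannan/xyloglucan chains).
    """

    pathway_id: str
    name: str
    category: str
    steps: tuple[PathwayStep, ...] = ()
    threshold: float | None = None
    members: tuple[str, ...] = ()
    substrate_class: str | None = None

    def __post_init__(self):
        if self.category not in PATHWAY_CATEGORIES:
            raise PathwayDefinitionError(
                f"{self.pathway_id}: unknown category {self.category!r}"
            )
        if self.substrate_class is not None and self.substrate_class not in SUBSTRATE_CLASSES:
            raise PathwayDefinitionError(
                f"{self.pathway_id}: unknown substrate_class {self.substrate_class!r}"
            )
        n = len(self.steps)
        if self.category in ("degradation_chain", "gene_set_all") and n < 1:
            raise PathwayDefinitionError(f"{self.pathway_id}: needs >=1 step")
        if self.category == "enzyme_fraction":
            if n < 2:
                raise PathwayDefinitionError(f"{self.pathway_id}: enzyme_fraction needs >=2 steps")
            thr = DEFAULT_FRACTION_THRESHOLD if self.threshold is None else self.threshold
            if not 0.0 < thr <= 1.0:
                raise PathwayDefinitionError(f"{self.pathway_id}: threshold {thr} outside (0, 1]")
            object.__setattr__(self, "threshold", float(thr))
        elif self.threshold is not None:
            raise PathwayDefinitionError(
                f"{self.pathway_id}: threshold only valid for enzyme_fraction"
            )
        if self.category == "marker" and n != 1:
            raise PathwayDefinitionError(f"{self.pathway_id}: marker needs exactly 1 step")
        if self.category == "any_of_pathways":
            if len(self.members) < 2:
                raise PathwayDefinitionError(f"{self.pathway_id}: any_of_pathways needs >=2 members")
            if n:
                raise PathwayDefinitionError(f"{self.pathway_id}: any_of_pathways takes no steps")
        elif self.members:
            raise PathwayDefinitionError(f"{self.pathway_id}: members only valid for any_of_pathways")

    @property
    def families(self) -> frozenset[GeneFamilyRef]:
        return frozenset(f for s in self.steps for f in s.alternatives)


def validate_pathway_set(defs: Sequence[PathwayDef]) -> dict[str, PathwayDef]:
    """Check id uniqueness, member resolution and absence of membership cycles."""
    registry: dict[str, PathwayDef] = {}
    for d in defs:
        if d.pathway_id in registry:
            raise UniquenessError(f"duplicate pathway_id {d.pathway_id!r}")
        registry[d.pathway_id] = d
    # resolve members transitively; detect cycles with a DFS colouring
    state: dict[str, int] = {}  # 0 = visiting, 1 = done

    def visit(pid: str, trail: tuple[str, ...]):
        if state.get(pid) == 1:
            return
        if state.get(pid) == 0:
            raise CycleError(f"cycle in any_of_pathways membership: {' -> '.join(trail + (pid,))}")
        state[pid] = 0
        for m in registry[pid].members:
            if m not in registry:
                raise ReferenceResolutionError(
                    f"{pid}: member pathway {m!r} is not defined"
                )
            visit(m, trail + (pid,))
        state[pid] = 1

    for pid in registry:
        visit(pid, ())
    return registry


# ---------------------------------------------------------------------------
# Table IO
# ---------------------------------------------------------------------------

_MAG_REQUIRED = ("mag_id", "completeness", "contamination", "coverage")


def _parse_ani_or_red(cell: str) -> tuple[float | None, float | None]:
    """Parse the combined ANI/RED column; "RED, 0.98" yields a RED value."""
    cell = (cell or "").strip()
    if not cell or cell.lower() in ("n/a", "na", "-", "nan"):
        return None, None
    if cell.upper().startswith("RED"):
        value = cell.split(",", 1)[1].strip() if "," in cell else cell[3:].strip(" ,")
        return None, float(value)
    return float(cell), None


def read_mag_table(
    path: str | Path | io.TextIOBase,
    *,
    quality_filter: bool = True,
    min_completeness: float = QUALITY_MIN_COMPLETENESS,
    max_contamination: float = QUALITY_MAX_CONTAMINATION,
) -> list[MAGRecord]:
    """Read a tab-separated MAG metadata table.

    Required columns: mag_id, completeness, contamination, coverage.
    Optional: the lineage ranks (domain..species), ani_or_red (accepting the
    "RED, <x>" dialect) and neighbor_accession.

    ``quality_filter`` applies the bin-retention rule (completeness >= 50 %,
    contamination <= 20 %) at read time; pass ``False`` to keep every row.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    frame.columns = [c.strip().lower() for c in frame.columns]
    missing = [c for c in _MAG_REQUIRED if c not in frame.columns]
    if missing:
        raise SchemaError(f"MAG table missing required column(s): {', '.join(missing)}")

    records: list[MAGRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(frame.itertuples(index=False), start=2):  # 1-based + header
        row = dict(zip(frame.columns, row))
        mag_id = row["mag_id"].strip()
        if mag_id in seen:
            raise UniquenessError(f"duplicate mag_id {mag_id!r}")
        seen.add(mag_id)
        try:
            completeness = float(row["completeness"])
            contamination = float(row["contamination"])
            coverage = float(row["coverage"])
        except ValueError as exc:
            raise TableParseError(f"non-numeric value ({exc})", row=i) from exc
        ani, red = None, None
        if "ani_or_red" in row:
            try:
                ani, red = _parse_ani_or_red(row["ani_or_red"])
            except ValueError as exc:
                raise TableParseError(f"bad ani_or_red cell {row['ani_or_red']!r}", row=i) from exc
        neighbor = (row.get("neighbor_accession") or "").strip() or None
        if neighbor and neighbor.lower() in ("n/a", "na", "-"):
            neighbor = None
        lineage = {r: row.get(r, "").strip() for r in RANKS}
        records.append(
            MAGRecord(
                mag_id=mag_id,
                lineage=lineage,
                completeness=completeness,
                contamination=contamination,
                coverage=coverage,
                ani_nearest=ani,
                red=red,
                neighbor_accession=neighbor,
            )
        )
    if quality_filter:
        records = [
            r for r in records if r.passes_quality(min_completeness, max_contamination)
        ]
    return records


def write_mag_table(records: Sequence[MAGRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        if r.red is not None:
            ani_or_red = f"RED, {r.red}"
        elif r.ani_nearest is not None:
            ani_or_red = repr(r.ani_nearest) if False else f"{r.ani_nearest}"
        else:
            ani_or_red = ""
        rows.append(
            {
                "mag_id": r.mag_id,
                **{rank: r.lineage.get(rank, "") for rank in RANKS},
                "completeness": f"{r.completeness}",
                "contamination": f"{r.contamination}",
                "coverage": f"{r.coverage}",
                "ani_or_red": ani_or_red,
                "neighbor_accession": r.neighbor_accession or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path | io.TextIOBase) -> AnnotationMatrix:
    """Read long-format annotations: mag_id, namespace, family_id[, count].

    Rows are aggregated by summation; a missing count column means one gene
    hit per row. Family identity is case-insensitive.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    frame.columns = [c.strip().lower() for c in frame.columns]
    for col in ("mag_id", "namespace", "family_id"):
        if col not in frame.columns:
            raise SchemaError(f"annotation table missing required column {col!r}")
    records = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        row = dict(zip(frame.columns, row))
        ref = GeneFamilyRef(row["namespace"], row["family_id"])
        if "count" in frame.columns and row["count"].strip():
            try:
                count = int(row["count"])
            except ValueError as exc:
                raise TableParseError(f"non-integer count {row['count']!r}", row=i) from exc
        else:
            count = 1
        if count < 0:
            raise ValidationError(f"row {i}: negative count {count}")
        records.append((row["mag_id"].strip(), ref, count))
    return AnnotationMatrix.from_records(records)


def write_annotations(matrix: AnnotationMatrix, path: str | Path) -> None:
    rows = []
    frame = matrix.to_frame()
    for mag_id in frame.index:
        for ref in frame.columns:
            count = int(frame.at[mag_id, ref])
            if count:
                rows.append(
                    {
                        "mag_id": mag_id,
                        "namespace": ref.namespace,
                        "family_id": ref.family_id,
                        "count": count,
                    }
                )
    pd.DataFrame(rows, columns=["mag_id", "namespace", "family_id", "count"]).to_csv(
        path, sep="\t", index=False
    )


def read_dbcan_overview(path: str | Path, mag_id: str) -> list[tuple[str, GeneFamilyRef, int]]:
    """Adapter for dbCAN overview-style tables (one gene per row).

    Expects a ``Gene ID`` column and an ``HMMER`` column with '+'-separated
    family hits like ``GH5(42-312)+CBM6(330-390)``; subfamily suffixes
    (``GH5_4``) are collapsed to the family. Each gene counts once per family
    even with multiple domains of that family.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = {c.strip().lower(): c for c in frame.columns}
    gene_col = cols.get("gene id") or cols.get("gene_id")
    hits_col = cols.get("hmmer") or cols.get("families")
    if gene_col is None or hits_col is None:
        raise SchemaError("dbCAN overview needs 'Gene ID' and 'HMMER' columns")
    out: list[tuple[str, GeneFamilyRef, int]] = []
    for _, row in frame.iterrows():
        fams = set()
        for token in str(row[hits_col]).split("+"):
            token = token.split("(")[0].split("_")[0].strip()
            if token and token != "-":
                fams.add(GeneFamilyRef("CAZY", token))
        for ref in fams:  # one gene, one count per distinct family
            out.append((mag_id, ref, 1))
    return out


def read_ko_table(path: str | Path, mag_id: str) -> list[tuple[str, GeneFamilyRef, int]]:
    """Adapter for two-column gene -> KO assignment tables (no header needed)."""
    frame = pd.read_csv(path, sep="\t", dtype=str, header=None, keep_default_na=False)
    if frame.shape[1] < 2:
        raise SchemaError("KO table needs two columns: gene_id, KO")
    out = []
    for _, row in frame.iterrows():
        ko = str(row[1]).strip()
        if ko:
            out.append((mag_id, GeneFamilyRef("KO", ko), 1))
    return out


def read_marker_table(path: str | Path | io.TextIOBase) -> list[MarkerGeneRecord]:
    """Read a marker (rps3) coverage table: gene_id, taxonomy, coverage[, mag_id]."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    frame.columns = [c.strip().lower() for c in frame.columns]
    for col in ("gene_id", "taxonomy", "coverage"):
        if col not in frame.columns:
            raise SchemaError(f"marker table missing required column {col!r}")
    records = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        row = dict(zip(frame.columns, row))
        try:
            coverage = float(row["coverage"])
        except ValueError as exc:
            raise TableParseError(f"non-numeric coverage {row['coverage']!r}", row=i) from exc
        records.append(
            MarkerGeneRecord(
                gene_id=row["gene_id"].strip(),
                taxonomy=row["taxonomy"].strip(),
                coverage=coverage,
                mag_id=(row.get("mag_id") or "").strip() or None,
            )
        )
    return records


def write_marker_table(records: Sequence[MarkerGeneRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "taxonomy": r.taxonomy,
                "coverage": r.coverage,
                "mag_id": r.mag_id or "",
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Pathway-definition IO (YAML)
# ---------------------------------------------------------------------------


def _def_from_mapping(entry: Mapping) -> PathwayDef:
    steps = tuple(
        PathwayStep(
            step_id=str(s["step_id"]),
            alternatives=frozenset(
                GeneFamilyRef.parse(tok) for tok in s["alternatives"]
            ),
        )
        for s in entry.get("steps", []) or []
    )
    return PathwayDef(
        pathway_id=str(entry["pathway_id"]),
        name=str(entry.get("name", entry["pathway_id"])),
        category=str(entry["category"]),
        steps=steps,
        threshold=entry.get("threshold"),
        members=tuple(entry.get("members", []) or []),
        substrate_class=entry.get("substrate_class"),
    )


def read_pathway_defs(path: str | Path | io.TextIOBase) -> list[PathwayDef]:
    """Read and validate a YAML pathway-definition file.

    Layout: a mapping with a ``pathways`` list; each item carries pathway_id,
    category, steps [{step_id, alternatives: ["CAZY:GH5", ...]}], optional
    threshold (enzyme_fraction; defaults to 0.8 when omitted), members
    (any_of_pathways) and substrate_class.
    """
    if isinstance(path, (str, Path)):
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = yaml.safe_load(path)
    if not isinstance(doc, Mapping) or "pathways" not in doc:
        raise PathwayDefinitionError("pathway file must be a mapping with a 'pathways' list")
    try:
        defs = [_def_from_mapping(entry) for entry in doc["pathways"]]
    except KeyError as exc:
        raise PathwayDefinitionError(f"pathway entry missing key {exc}") from exc
    validate_pathway_set(defs)
    return defs


def load_default_pathways() -> list[PathwayDef]:
    """The shipped default pathway set (carbohydrate chains, energy harvesting,
    fermentation, vitamins, hydrogenase group markers)."""
    from importlib import resources

    ref = resources.files("magdiet") / "data" / "pathways" / "default_pathways.yaml"
    with ref.open() as fh:
        return read_pathway_defs(fh)


def load_substrate_families() -> dict[str, list[GeneFamilyRef]]:
    """The shipped substrate-class -> family-list map used for copy totals."""
    from importlib import resources

    ref = resources.files("magdiet") / "data" / "pathways" / "substrate_families.yaml"
    with ref.open() as fh:
        doc = yaml.safe_load(fh)
    return {
        cls: [GeneFamilyRef.parse(tok) for tok in toks]
        for cls, toks in doc["substrate_families"].items()
    }
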