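"""Evaluate pathway rules against MAG annotations.

The engine turns a MAG's gene-family copy counts into per-pathway calls
(complete / partial / absent with a satisfied-step fraction), classifies
complete and partial polysaccharide degraders, computes the four-enzyme
beta-oxidation binary, and aggregates per-MAG function summaries (substrates,
energy pathways with partial flags, vitamins, host benefits).

All operations are deterministic; calls depend only on presence/absence of
step alternatives except where a rule counts copies (amylase and exopeptidase
totals).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_model import (
    AnnotationMatrix,
    GeneFamilyRef,
    MAGRecord,
    PathwayDef,
    validate_pathway_set,
)
from .errors import ConfigurationError, DesignError, PathwayDefinitionError

STATUS_COMPLETE = "complete"
STATUS_PARTIAL = "partial"
STATUS_ABSENT = "absent"

_FRACTION_EPS = 1e-9  # guards float representation of thresholds like 0.8


@dataclass(frozen=True)
class PathwayCall:
    """Evaluation of one pathway for one MAG."""

    mag_id: str
    pathway_id: str
    status: str
    fraction: float
    steps_present: frozenset[str] = frozenset()


@dataclass
class FunctionSummary:
    """Per-MAG biochemical function summary (one row of the report table)."""

    mag_id: str
    substrates: list[str] = field(default_factory=list)
    energy_pathways: list[tuple[str, bool]] = field(default_factory=list)  # (id, partial)
    vitamins: list[str] = field(default_factory=list)
    benefits: list[str] = field(default_factory=list)


def _step_satisfied(row: Mapping[GeneFamilyRef, int], alternatives) -> bool:
    return any(row.get(alt, 0) >= 1 for alt in alternatives)


def evaluate_pathway(
    row: Mapping[GeneFamilyRef, int],
    defn: PathwayDef,
    registry: Mapping[str, PathwayDef] | None = None,
    *,
    mag_id: str = "",
) -> PathwayCall:
    """Evaluate one pathway definition against one MAG's copy counts.

    ``row`` maps gene-family refs to copy counts (a pandas Series from
    :meth:`AnnotationMatrix.row` works); absent keys count as zero.
    ``registry`` (id -> def) is required for ``any_of_pathways``.

    Completeness per category: chains, gene sets and markers need every step;
    enzyme_fraction needs a satisfied-step fraction of at least its threshold
    (inclusive); any_of_pathways is complete when any member is complete,
    partial when any member is partial and none complete, and its fraction is
    the maximum member fraction.
    """
    if defn.category == "any_of_pathways":
        if registry is None:
            raise PathwayDefinitionError(
                f"{defn.pathway_id}: any_of_pathways needs a pathway registry"
            )
        member_calls = [
            evaluate_pathway(row, registry[m], registry, mag_id=mag_id)
            for m in defn.members
        ]
        fraction = max(c.fraction for c in member_calls)
        if any(c.status == STATUS_COMPLETE for c in member_calls):
            status = STATUS_COMPLETE
        elif any(c.status == STATUS_PARTIAL for c in member_calls):
            status = STATUS_PARTIAL
        else:
            status = STATUS_ABSENT
        steps = frozenset().union(*(c.steps_present for c in member_calls))
        return PathwayCall(mag_id, defn.pathway_id, status, fraction, steps)

    satisfied = [s.step_id for s in defn.steps if _step_satisfied(row, s.alternatives)]
    fraction = len(satisfied) / len(defn.steps)
    if not satisfied:
        status = STATUS_ABSENT
    elif defn.category == "enzyme_fraction":
        status = (
            STATUS_COMPLETE
            if fraction >= defn.threshold - _FRACTION_EPS
            else STATUS_PARTIAL
        )
    else:  # degradation_chain, gene_set_all, marker: all steps required
        status = STATUS_COMPLETE if len(satisfied) == len(defn.steps) else STATUS_PARTIAL
    return PathwayCall(mag_id, defn.pathway_id, status, fraction, frozenset(satisfied))


def evaluate_all(
    matrix: AnnotationMatrix,
    defs: Sequence[PathwayDef],
    *,
    pathway_ids: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Evaluate pathways for every MAG; returns a long-format call table
    (mag_id, pathway_id, status, fraction)."""
    registry = validate_pathway_set(defs)
    wanted = list(pathway_ids) if pathway_ids is not None else list(registry)
    frame = matrix.to_frame()
    # vectorized presence per (pathway, step): any alternative column >= 1
    presence_cache: dict[tuple[str, str], np.ndarray] = {}
    n = len(frame)

    def step_presence(pid: str) -> dict[str, np.ndarray]:
        out = {}
        for step in registry[pid].steps:
            key = (pid, step.step_id)
            if key not in presence_cache:
                cols = [c for c in step.alternatives if c in frame.columns]
                if cols:
                    presence_cache[key] = (frame[cols].to_numpy() >= 1).any(axis=1)
                else:
                    presence_cache[key] = np.zeros(n, dtype=bool)
            out[step.step_id] = presence_cache[key]
        return out

    def eval_vec(pid: str) -> tuple[np.ndarray, np.ndarray]:
        """fractions and statuses (int codes 0 absent / 1 partial / 2 complete)."""
        d = registry[pid]
        if d.category == "any_of_pathways":
            fracs, stats = zip(*(eval_vec(m) for m in d.members))
            fraction = np.max(np.vstack(fracs), axis=0)
            status = np.max(np.vstack(stats), axis=0)
            return fraction, status
        pres = np.vstack(list(step_presence(pid).values()))
        fraction = pres.mean(axis=0)
        n_sat = pres.sum(axis=0)
        status = np.where(n_sat == 0, 0, 1)
        if d.category == "enzyme_fraction":
            complete = fraction >= d.threshold - _FRACTION_EPS
        else:
            complete = n_sat == len(d.steps)
        status = np.where((n_sat > 0) & complete, 2, status)
        return fraction, status

    code = {0: STATUS_ABSENT, 1: STATUS_PARTIAL, 2: STATUS_COMPLETE}
    rows = []
    for pid in wanted:
        fraction, status = eval_vec(pid)
        for mag, f, s in zip(frame.index, fraction, status):
            rows.append((mag, pid, code[int(s)], float(f)))
    return pd.DataFrame(rows, columns=["mag_id", "pathway_id", "status", "fraction"])


def classify_degraders(
    matrix: AnnotationMatrix, defs: Sequence[PathwayDef]
) -> pd.DataFrame:
    """Call every substrate-tagged pathway for every MAG.

    Returns the long-format table (mag_id, pathway_id, substrate_class,
    status, fraction). Complete-degrader and partial-degrader sets are
    obtained by filtering on status.
    """
    registry = validate_pathway_set(defs)
    tagged = [pid for pid, d in registry.items() if d.substrate_class is not None]
    calls = evaluate_all(matrix, defs, pathway_ids=tagged)
    calls["substrate_class"] = calls["pathway_id"].map(
        {pid: registry[pid].substrate_class for pid in tagged}
    )
    return calls[["mag_id", "pathway_id", "substrate_class", "status", "fraction"]]


def beta_oxidation_flag(
    row: Mapping[GeneFamilyRef, int], beta_def: PathwayDef
) -> int:
    """1 iff the MAG encodes all four beta-oxidation enzymes, else 0."""
    if len(beta_def.steps) != 4 or beta_def.category != "gene_set_all":
        raise PathwayDefinitionError(
            f"{beta_def.pathway_id}: beta oxidation must be a 4-step gene_set_all"
        )
    call = evaluate_pathway(row, beta_def)
    return 1 if call.status == STATUS_COMPLETE else 0


@dataclass
class FunctionRuleConfig:
    """Thresholds and pathway wiring for the per-MAG function summary.

    * ``carbohydrate_pathways``: substrate label -> pathway_id whose complete
      call lists that carbohydrate (cellulose/hemicellulose/chitin chains).
    * ``amylase_families`` / ``amylase_cutoff``: starch is listed when the
      amylase copy total strictly exceeds the cutoff (default 5).
    * ``exopeptidase_families`` / ``exopeptidase_cutoff``: proteins listed on
      a strict > 10 total by default.
    * ``beta_glucosidase``: families whose presence (when nothing else
      qualifies) lists "simple saccharides".
    * ``energy_pathways`` / ``vitamin_pathways``: pathway_ids reported in the
      energy (with a partial flag) and vitamin columns.
    """

    carbohydrate_pathways: dict[str, str]
    amylase_families: list[GeneFamilyRef]
    exopeptidase_families: list[GeneFamilyRef]
    beta_glucosidase: list[GeneFamilyRef]
    energy_pathways: list[str]
    vitamin_pathways: dict[str, str]  # vitamin label (B1..B12) -> pathway_id
    amylase_cutoff: int = 5
    exopeptidase_cutoff: int = 10

    def __post_init__(self):
        if self.amylase_cutoff < 0 or self.exopeptidase_cutoff < 0:
            raise ConfigurationError("cutoffs must be non-negative")


def default_function_rules() -> FunctionRuleConfig:
    from .annotation_model import load_substrate_families

    fams = load_substrate_families()
    return FunctionRuleConfig(
        carbohydrate_pathways={
            "cellulose": "cellulose_chain",
            "hemicellulose": "hemicellulose_any",
            "chitin": "chitin_any",
        },
        amylase_families=fams["starch"],
        exopeptidase_families=fams["protein"],
        beta_glucosidase=[GeneFamilyRef("CAZY", "GH1"), GeneFamilyRef("CAZY", "GH3")],
        energy_pathways=[
            "glycolysis",
            "pyruvate_oxidation",
            "tca_cycle",
            "beta_oxidation",
            "nitrate_reduction",
            "lactate_fermentation",
            "h2_fermentation",
            "formate_fermentation",
            "acetogenesis",
        ],
        vitamin_pathways={
            "B1": "vitamin_b1",
            "B2": "vitamin_b2",
            "B7": "vitamin_b7",
            "B9": "vitamin_b9",
            "B12": "vitamin_b12",
        },
    )


def summarize_functions(
    mag: MAGRecord | str,
    calls: Sequence[PathwayCall] | pd.DataFrame,
    row: Mapping[GeneFamilyRef, int],
    rules: FunctionRuleConfig,
) -> FunctionSummary:
    """Aggregate pathway calls and copy totals into one function summary.

    Substrate listing rules: each carbohydrate whose configured pathway call
    is complete; starch when the amylase copy total strictly exceeds the
    cutoff; proteins when the exopeptidase total strictly exceeds its cutoff;
    "simple saccharides" only when nothing else qualifies but a
    beta-glucosidase is encoded. Energy pathways are listed when complete, or
    flagged partial when at least one step is encoded. Vitamins are listed
    iff the biosynthesis call is complete.
    """
    mag_id = mag.mag_id if isinstance(mag, MAGRecord) else str(mag)
    if isinstance(calls, pd.DataFrame):
        by_id = {
            r.pathway_id: PathwayCall(mag_id, r.pathway_id, r.status, r.fraction)
            for r in calls.itertuples(index=False)
        }
    else:
        by_id = {c.pathway_id: c for c in calls}

    def call_for(pid: str) -> PathwayCall:
        if pid not in by_id:
            raise ConfigurationError(f"no call for configured pathway {pid!r}")
        return by_id[pid]

    substrates: list[str] = []
    for label, pid in rules.carbohydrate_pathways.items():
        if call_for(pid).status == STATUS_COMPLETE:
            substrates.append(label)
    amylase_total = sum(row.get(f, 0) for f in set(rules.amylase_families))
    if amylase_total > rules.amylase_cutoff:
        substrates.append("starch")
    exo_total = sum(row.get(f, 0) for f in set(rules.exopeptidase_families))
    if exo_total > rules.exopeptidase_cutoff:
        substrates.append("proteins")
    if not substrates and any(row.get(f, 0) >= 1 for f in rules.beta_glucosidase):
        substrates.append("simple_saccharides")

    energy: list[tuple[str, bool]] = []
    for pid in rules.energy_pathways:
        c = call_for(pid)
        if c.status == STATUS_COMPLETE:
            energy.append((pid, False))
        elif c.status == STATUS_PARTIAL:
            energy.append((pid, True))

    vitamins = [
        label
        for label, pid in rules.vitamin_pathways.items()
        if call_for(pid).status == STATUS_COMPLETE
    ]

    benefits: list[str] = []
    if "proteins" in substrates:
        benefits.append("protein_degradation")
    if any(s in substrates for s in ("cellulose", "hemicellulose", "starch", "chitin")):
        benefits.append("plant_matter_degradation")
    if vitamins:
        benefits.append("vitamin_production")

    return FunctionSummary(mag_id, substrates, energy, vitamins, benefits)


def count_by_pathway(
    calls: pd.DataFrame, groups: Mapping[str, str]
) -> pd.DataFrame:
    """Per-group counts of complete/partial/absent MAGs per pathway.

    ``calls`` is a long table with mag_id, pathway_id, status; ``groups``
    maps every MAG to its diet label. Counts partition each group:
    complete + partial + absent = group size, for every pathway.
    """
    unlabeled = sorted(set(calls["mag_id"]) - set(groups))
    if unlabeled:
        raise DesignError(f"unlabeled MAG(s): {', '.join(unlabeled)}")
    t = calls.copy()
    t["group"] = t["mag_id"].map(groups)
    counts = (
        t.groupby(["pathway_id", "group", "status"], sort=True)
        .size()
        .unstack("status", fill_value=0)
        .reindex(columns=[STATUS_COMPLETE, STATUS_PARTIAL, STATUS_ABSENT], fill_value=0)
        .reset_index()
    )
    counts.columns.name = None
    return counts


def vitamin_producer_counts(
    summaries: Sequence[FunctionSummary], groups: Mapping[str, str]
) -> pd.DataFrame:
    """Per-group counts of MAGs listing each vitamin (group x vitamin table)."""
    unlabeled = sorted({s.mag_id for s in summaries} - set(groups))
    if unlabeled:
        raise DesignError(f"unlabeled MAG(s): {', '.join(unlabeled)}")
    vitamins = sorted({v for s in summaries for v in s.vitamins})
    out: dict[str, dict[str, int]] = {}
    for s in summaries:
        grp = groups[s.mag_id]
        row = out.setdefault(grp, {v: 0 for v in vitamins})
        for v in s.vitamins:
            row[v] = row.get(v, 0) + 1
    return pd.DataFrame.from_dict(out, orient="index").fillna(0).astype(int)


def summaries_to_frame(summaries: Sequence[FunctionSummary]) -> pd.DataFrame:
    """Serialize function summaries as the report table (semicolon lists)."""
    rows = []
    for s in summaries:
        energy = ";".join(f"{p}(p)" if partial else p for p, partial in s.energy_pathways)
        rows.append(
            {
                "mag_id": s.mag_id,
                "substrates": ";".join(s.substrates),
                "energy": energy,
                "vitamins": ";".join(s.vitamins),
                "benefits": ";".join(s.benefits),
            }
        )
    return pd.DataFrame(rows, columns=["mag_id", "substrates", "energy", "vitamins", "benefits"])


def read_function_table(path) -> tuple[list[FunctionSummary], dict[str, str]]:
    """Read a function-summary table (mag_id, [family], [diet], substrates,
    energy, vitamins, benefits; semicolon-separated lists, "(p)" marks partial
    energy pathways). Returns summaries plus a mag -> diet map (empty when no
    diet column)."""
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    summaries = []
    design: dict[str, str] = {}
    for r in frame.itertuples(index=False):
        row = dict(zip(frame.columns, r))
        energy = []
        for token in filter(None, row.get("energy", "").split(";")):
            partial = token.endswith("(p)")
            energy.append((token[:-3] if partial else token, partial))
        summaries.append(
            FunctionSummary(
                mag_id=row["mag_id"],
                substrates=[t for t in row.get("substrates", "").split(";") if t],
                energy_pathways=energy,
                vitamins=[t for t in row.get("vitamins", "").split(";") if t],
                benefits=[t for t in row.get("benefits", "").split(";") if t],
            )
        )
        if row.get("diet"):
            design[row["mag_id"]] = row["diet"]
    return summaries, design
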