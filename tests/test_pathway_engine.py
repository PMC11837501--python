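"""Pathway-call semantics: completeness rules, degrader classification,
function-summary thresholds, and agreement with brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from magdiet.annotation_model import GeneFamilyRef, PathwayDef, validate_pathway_set
from magdiet.errors import ConfigurationError, DesignError, PathwayDefinitionError
from magdiet.pathway_engine import (
    FunctionRuleConfig,
    beta_oxidation_flag,
    classify_degraders,
    count_by_pathway,
    default_function_rules,
    evaluate_all,
    evaluate_pathway,
    summarize_functions,
    vitamin_producer_counts,
)
from magdiet.datasets import load_reef_fish_functions

from tests.conftest import matrix_from, ref, step


def brute_force_call(row: dict, defn: PathwayDef, registry=None) -> tuple[str, float]:
    """Independent loop-based re-statement of the call rules."""
    if defn.category == "any_of_pathways":
        results = [brute_force_call(row, registry[m], registry) for m in defn.members]
        frac = max(r[1] for r in results)
        statuses = [r[0] for r in results]
        if "complete" in statuses:
            return "complete", frac
        if "partial" in statuses:
            return "partial", frac
        return "absent", frac
    sat = 0
    for s in defn.steps:
        hit = False
        for a in s.alternatives:
            if row.get(a, 0) >= 1:
                hit = True
        sat += hit
    frac = sat / len(defn.steps)
    if sat == 0:
        return "absent", frac
    if defn.category == "enzyme_fraction":
        return ("complete" if sat >= defn.threshold * len(defn.steps) - 1e-9 else "partial"), frac
    return ("complete" if sat == len(defn.steps) else "partial"), frac


class TestEvaluatePathway:
    def test_all_zero_row_is_absent(self, chain_def, fraction_def):
        for d in (chain_def, fraction_def):
            call = evaluate_pathway({}, d)
            assert call.status == "absent" and call.fraction == 0.0

    def test_80pct_threshold_is_inclusive(self, fraction_def):
        row8 = {ref(f"KO:K{i:05d}"): 1 for i in range(1, 9)}
        call = evaluate_pathway(row8, fraction_def)
        assert call.status == "complete" and call.fraction == pytest.approx(0.8)
        row7 = {ref(f"KO:K{i:05d}"): 1 for i in range(1, 8)}
        assert evaluate_pathway(row7, fraction_def).status == "partial"

    def test_chain_requires_every_step(self, chain_def):
        row = {ref("CAZY:GH5"): 3, ref("CAZY:GH6"): 1}
        call = evaluate_pathway(row, chain_def)
        assert call.status == "partial" and call.fraction == pytest.approx(2 / 3)
        row[ref("CAZY:GH3")] = 1
        assert evaluate_pathway(row, chain_def).status == "complete"

    def test_any_of_complete_when_one_member_complete(self, default_defs):
        registry = validate_pathway_set(default_defs)
        hemi = registry["hemicellulose_any"]
        # complete xylan chain only: one family per step
        row = {ref("CAZY:GH10"): 1, ref("CAZY:GH43"): 1}
        call = evaluate_pathway(row, hemi, registry)
        assert call.status == "complete" and call.fraction == 1.0
        # one mannan step only -> partial
        call = evaluate_pathway({ref("CAZY:GH26"): 1}, hemi, registry)
        assert call.status == "partial" and call.fraction == pytest.approx(0.5)

    def test_exhaustive_oracle_small(self, rng):
        """Full presence-pattern enumeration on random small definitions."""
        for trial in range(10):
            fams = [ref(f"KO:K{i:05d}") for i in range(1, int(rng.integers(2, 9)))]
            n_steps = int(rng.integers(1, min(5, len(fams)) + 1))
            assignment = [list() for _ in range(n_steps)]
            for i, f in enumerate(fams):
                assignment[i % n_steps].append(f)
            category = ["degradation_chain", "gene_set_all", "enzyme_fraction", "marker"][
                int(rng.integers(4))
            ]
            if category == "marker":
                n_steps, assignment = 1, [fams]
            if category == "enzyme_fraction" and n_steps < 2:
                category = "gene_set_all"
            d = PathwayDef(
                pathway_id=f"t{trial}",
                name="t",
                category=category,
                threshold=0.8 if category == "enzyme_fraction" else None,
                steps=tuple(
                    step(f"s{i}", *(str(f) for f in alts))
                    for i, alts in enumerate(assignment)
                    if alts
                ),
            )
            for bits in itertools.product([0, 1], repeat=len(fams)):
                row = {f: b for f, b in zip(fams, bits)}
                call = evaluate_pathway(row, d)
                status, frac = brute_force_call(row, d)
                assert (call.status, call.fraction) == (status, pytest.approx(frac))

    def test_monotone_in_copy_counts(self, chain_def, rng):
        """Adding copies never moves a call toward absent or lowers fraction."""
        order = {"absent": 0, "partial": 1, "complete": 2}
        fams = sorted(chain_def.families)
        for _ in range(200):
            row = {f: int(rng.integers(0, 2)) for f in fams}
            before = evaluate_pathway(row, chain_def)
            bumped = dict(row)
            for f in rng.choice(fams, size=2, replace=False):
                bumped[f] = bumped.get(f, 0) + int(rng.integers(1, 3))
            after = evaluate_pathway(bumped, chain_def)
            assert after.fraction >= before.fraction
            assert order[after.status] >= order[before.status]


class TestClassifyDegraders:
    def test_vectorized_calls_match_per_row_evaluation(self, default_defs, rng):
        registry = validate_pathway_set(default_defs)
        fams = sorted({f for d in default_defs for f in d.families})
        rows = {
            f"M{i}": {
                str(f): int(c)
                for f, c in zip(fams, rng.poisson(0.5, len(fams)))
                if c
            }
            for i in range(25)
        }
        matrix = matrix_from(rows)
        calls = classify_degraders(matrix, default_defs)
        for r in calls.sample(60, random_state=1).itertuples(index=False):
            expected = evaluate_pathway(matrix.row(r.mag_id), registry[r.pathway_id], registry)
            assert r.status == expected.status
            assert r.fraction == pytest.approx(expected.fraction)

    def test_no_initial_step_means_no_complete_chitin_degraders(self, default_defs):
        # community lacking chitinase and deacetylase families entirely
        matrix = matrix_from(
            {"M1": {"CAZY:GH20": 4, "CAZY:GH2": 2}, "M2": {"CAZY:GH20": 1}}
        )
        calls = classify_degraders(matrix, default_defs)
        chitin = calls[calls["substrate_class"] == "chitin"]
        assert not (chitin["status"] == "complete").any()

    def test_single_step_gives_partial_degrader(self, default_defs):
        matrix = matrix_from({"M1": {"CAZY:GH5": 2}})
        calls = classify_degraders(matrix, default_defs).set_index("pathway_id")
        assert calls.at["cellulose_chain", "status"] == "partial"


class TestBetaOxidation:
    def test_all_four_steps_required(self, beta_def):
        full = {ref("KO:K00249"): 1, ref("KO:K01692"): 1, ref("KO:K00022"): 1, ref("KO:K00632"): 1}
        assert beta_oxidation_flag(full, beta_def) == 1
        three = dict(full)
        del three[ref("KO:K00632")]
        assert beta_oxidation_flag(three, beta_def) == 0
        assert beta_oxidation_flag({}, beta_def) == 0

    def test_wrong_arity_rejected(self):
        bad = PathwayDef(
            pathway_id="b",
            name="b",
            category="gene_set_all",
            steps=(step("a", "KO:K00249"), step("b", "KO:K01692")),
        )
        with pytest.raises(PathwayDefinitionError):
            beta_oxidation_flag({}, bad)


class TestSummarizeFunctions:
    @pytest.fixture
    def rules(self):
        return FunctionRuleConfig(
            carbohydrate_pathways={"cellulose": "cellulose_chain"},
            amylase_families=[ref("CAZY:GH13"), ref("CAZY:GH57")],
            exopeptidase_families=[ref("MEROPS:M01"), ref("MEROPS:M17")],
            beta_glucosidase=[ref("CAZY:GH1"), ref("CAZY:GH3")],
            energy_pathways=["tca_cycle"],
            vitamin_pathways={"B12": "vitamin_b12"},
        )

    def make_calls(self, **status):
        from magdiet.pathway_engine import PathwayCall

        defaults = {"cellulose_chain": "absent", "tca_cycle": "absent", "vitamin_b12": "absent"}
        defaults.update(status)
        return [PathwayCall("M", pid, s, {"absent": 0.0, "partial": 0.5, "complete": 1.0}[s]) for pid, s in defaults.items()]

    def test_starch_needs_strictly_more_than_five_amylases(self, rules):
        six = summarize_functions("M", self.make_calls(), {ref("CAZY:GH13"): 6}, rules)
        assert six.substrates == ["starch"]
        five = summarize_functions("M", self.make_calls(), {ref("CAZY:GH13"): 5}, rules)
        assert "starch" not in five.substrates

    def test_protein_threshold_and_complete_energy_flag(self, rules):
        row = {ref("MEROPS:M01"): 7, ref("MEROPS:M17"): 4}
        s = summarize_functions("M", self.make_calls(tca_cycle="complete"), row, rules)
        assert "proteins" in s.substrates
        assert ("tca_cycle", False) in s.energy_pathways
        assert "protein_degradation" in s.benefits

    def test_partial_energy_pathway_flagged(self, rules):
        s = summarize_functions("M", self.make_calls(tca_cycle="partial"), {}, rules)
        assert ("tca_cycle", True) in s.energy_pathways

    def test_simple_saccharides_only_as_fallback(self, rules):
        s = summarize_functions("M", self.make_calls(), {ref("CAZY:GH1"): 1}, rules)
        assert s.substrates == ["simple_saccharides"]
        s2 = summarize_functions(
            "M", self.make_calls(cellulose_chain="complete"), {ref("CAZY:GH1"): 1}, rules
        )
        assert s2.substrates == ["cellulose"]

    def test_vitamins_require_complete_biosynthesis(self, rules):
        s = summarize_functions("M", self.make_calls(vitamin_b12="complete"), {}, rules)
        assert s.vitamins == ["B12"] and "vitamin_production" in s.benefits
        assert summarize_functions("M", self.make_calls(vitamin_b12="partial"), {}, rules).vitamins == []

    def test_missing_configured_call_is_config_error(self, rules):
        with pytest.raises(ConfigurationError):
            summarize_functions("M", [], {}, rules)


class TestCountByPathway:
    def random_calls(self, rng, groups):
        rows = []
        for mag, _ in groups.items():
            for pid in ("p1", "p2"):
                rows.append(
                    (mag, pid, ["complete", "partial", "absent"][int(rng.integers(3))], 0.0)
                )
        return pd.DataFrame(rows, columns=["mag_id", "pathway_id", "status", "fraction"])

    def test_counts_partition_group_sizes(self, rng):
        groups = {f"M{i}": ("a" if i < 18 else "b" if i < 36 else "c") for i in range(43)}
        counts = count_by_pathway(self.random_calls(rng, groups), groups)
        sizes = {"a": 18, "b": 18, "c": 7}
        for r in counts.itertuples(index=False):
            assert r.complete + r.partial + r.absent == sizes[r.group]

    def test_counts_equal_independent_tally(self, rng):
        groups = {f"M{i}": f"g{i % 3}" for i in range(20)}
        calls = self.random_calls(rng, groups)
        counts = count_by_pathway(calls, groups).set_index(["pathway_id", "group"])
        for r in calls.itertuples(index=False):
            expected = sum(
                1
                for q in calls.itertuples(index=False)
                if q.pathway_id == r.pathway_id
                and groups[q.mag_id] == groups[r.mag_id]
                and q.status == r.status
            )
            assert counts.at[(r.pathway_id, groups[r.mag_id]), r.status] == expected

    def test_unlabeled_mag_rejected(self, rng):
        groups = {f"M{i}": "a" for i in range(5)}
        calls = self.random_calls(rng, {**groups, "GHOST": "x"})
        with pytest.raises(DesignError, match="GHOST"):
            count_by_pathway(calls, groups)


class TestFunctionTableAggregation:
    def test_vitamin_counts_match_published_summary(self):
        summaries, design = load_reef_fish_functions()
        counts = vitamin_producer_counts(summaries, design.labels)
        assert counts.at["piscivorous", "B12"] == 7
        assert counts.at["herbivorous", "B12"] == 4
        assert counts.at["invertivorous", "B12"] == 2
        assert counts.at["herbivorous", "B1"] == 10

    def test_default_rules_reference_shipped_pathways(self, default_defs):
        rules = default_function_rules()
        ids = {d.pathway_id for d in default_defs}
        assert set(rules.carbohydrate_pathways.values()) <= ids
        assert set(rules.vitamin_pathways.values()) <= ids
        assert set(rules.energy_pathways) <= ids
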