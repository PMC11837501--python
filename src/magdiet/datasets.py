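"""Bundled example data: a published collection of 43 gut MAGs recovered
from three tropical reef fish held on controlled diets (piscivorous
hawkfish, herbivorous yellow tang, invertivorous triggerfish), as quality /
taxonomy metadata and per-MAG function-summary tables."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .annotation_model import MAGRecord, read_mag_table
from .pathway_engine import FunctionSummary, read_function_table
from .substrate_matrix import DietDesign


def _data_path(name: str):
    return resources.files("magdiet") / "data" / name


def load_reef_fish_mags() -> tuple[list[MAGRecord], DietDesign]:
    """MAG metadata for the three diet treatments plus the diet design."""
    path = _data_path("reef_fish_mags.tsv")
    with resources.as_file(path) as p:
        records = read_mag_table(p)
        table = pd.read_csv(p, sep="\t", dtype=str)
    design = DietDesign(labels=dict(zip(table["mag_id"], table["diet"])))
    return records, design


def load_reef_fish_functions() -> tuple[list[FunctionSummary], DietDesign]:
    """Per-MAG biochemical function summaries (substrates, energy pathways,
    vitamins, host benefits) for the same MAG collection."""
    with resources.as_file(_data_path("reef_fish_functions.tsv")) as p:
        summaries, labels = read_function_table(p)
    return summaries, DietDesign(labels=labels)
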