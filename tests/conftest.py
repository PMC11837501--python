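import numpy as np
import pytest

from magdiet.annotation_model import (
    AnnotationMatrix,
    GeneFamilyRef,
    MAGRecord,
    PathwayDef,
    PathwayStep,
    load_default_pathways,
    load_substrate_families,
)


def ref(token: str) -> GeneFamilyRef:
    return GeneFamilyRef.parse(token)


def step(step_id: str, *tokens: str) -> PathwayStep:
    return PathwayStep(step_id=step_id, alternatives=frozenset(ref(t) for t in tokens))


@pytest.fixture(scope="session")
def default_defs():
    return load_default_pathways()

@pytest.fixture(scope="session")
def substrate_families():
    return load_substrate_families()


@pytest.fixture(scope="session")
def beta_def(default_defs):
    return next(d for d in default_defs if d.pathway_id == "beta_oxidation")


@pytest.fixture
def chain_def():
    """A 3-step hydrolysis chain over 6 families."""
    return PathwayDef(
        pathway_id="chain3",
        name="test chain",
        category="degradation_chain",
        substrate_class="cellulose",
        steps=(
            step("endo", "CAZY:GH5", "CAZY:GH9"),
            step("exo", "CAZY:GH6", "CAZY:GH48"),
            step("gluco", "CAZY:GH1", "CAZY:GH3"),
        ),
    )


@pytest.fixture
def fraction_def():
    """10 single-family steps at the 80 % completeness threshold."""
    return PathwayDef(
        pathway_id="frac10",
        name="test fraction",
        category="enzyme_fraction",
        threshold=0.8,
        steps=tuple(step(f"s{i}", f"KO:K{i:05d}") for i in range(1, 11)),
    )


def matrix_from(rows: dict[str, dict[str, int]]) -> AnnotationMatrix:
    """Build a matrix from {mag: {"CAZY:GH5": 2, ...}}."""
    return AnnotationMatrix.from_records(
        (mag, ref(tok), n) for mag, cells in rows.items() for tok, n in cells.items()
    )


def mag(mag_id: str, completeness: float = 100.0, **kwargs) -> MAGRecord:
    kwargs.setdefault("contamination", 1.0)
    kwargs.setdefault("coverage", 10.0)
    return MAGRecord(mag_id=mag_id, completeness=completeness, **kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
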