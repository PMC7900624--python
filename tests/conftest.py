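import io

import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from toxsets import (
    ExpressionRecord,
    ExpressionTable,
    GeneSet,
    GeneSetCollection,
    PlantedSet,
    SpikeInDesign,
    generate_background,
    plant_signal,
)


def make_table(values: dict[str, float], p_values: dict[str, float] | None = None):
    """Small expression table straight from a dict of log FC values."""
    p_values = p_values or {}
    records = {
        g: ExpressionRecord(g, fc, p_values.get(g)) for g, fc in values.items()
    }
    return ExpressionTable(records=records, n_input_rows=len(records))


@pytest.fixture
def tiny_table():
    return make_table({"g1": 1.0, "g2": -0.5, "g3": 0.5, "g4": 2.0, "g5": -1.0})


@pytest.fixture
def tiny_collection():
    return GeneSetCollection(
        sets=(
            GeneSet("UP", "up set", ("g1", "g4")),
            GeneSet("MIXED", "mixed set", ("g2", "g3", "g5")),
            GeneSet("ABSENT", "not in table", ("x1", "x2", "x3")),
        ),
        source="fixture",
    )


@pytest.fixture
def spike_design():
    return SpikeInDesign(
        n_background_genes=1000,
        noise_sd=0.3,
        planted_sets=(PlantedSet("SPIKE25", 25, 1.0, "shift"),),
        seed=101,
    )


@pytest.fixture
def spiked(spike_design):
    """(table, planted collection) with one shift-mode planted set."""
    background = generate_background(spike_design)
    return plant_signal(background, spike_design)


def roundtrip_gmt(collection):
    from toxsets import parse_gmt, write_gmt

    buf = io.StringIO()
    write_gmt(collection, buf)
    buf.seek(0)
    return parse_gmt(buf, source=collection.source)
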