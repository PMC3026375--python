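from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from introview import (
    parse_config,
    parse_raw_data,
    parse_reference_map,
    parse_relationships,
)
from introview.caller import LineCalls, MarkerCallState
from introview.io import ReferenceMap, RefMarker

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

SAMPLE_DIR = Path(__file__).resolve().parent.parent / "examples" / "sample_data"


@pytest.fixture(scope="session")
def sample_dir():
    return SAMPLE_DIR


@pytest.fixture(scope="session")
def sample_refmap():
    return parse_reference_map(SAMPLE_DIR / "sample_ref_map.tab")


@pytest.fixture(scope="session")
def sample_records():
    return parse_relationships(SAMPLE_DIR / "sample_relationships.tab")


@pytest.fixture(scope="session")
def sample_matrix(sample_records):
    return parse_raw_data(
        SAMPLE_DIR / "sample_data.tab",
        {r.sample_id for r in sample_records},
    )


@pytest.fixture(scope="session")
def sample_config():
    return parse_config(SAMPLE_DIR / "sample.cfg")


def make_map(positions, chromosome="1", prefix="m"):
    """Reference map with one marker per position on one chromosome."""
    return ReferenceMap([
        RefMarker(f"{prefix}{i}", chromosome, p)
        for i, p in enumerate(positions)
    ])


def make_calls(line_id, refmap, state_names):
    """LineCalls from state names given in the map's marker order."""
    markers = list(refmap)
    assert len(markers) == len(state_names)
    return LineCalls(line_id=line_id, states={
        m.name: MarkerCallState[s] for m, s in zip(markers, state_names)
    })


#: Table-1-style map used by the segmentation examples: four markers on
#: chromosome "1" at 0, 9, 37 and 51 cM.
def four_marker_map():
    return ReferenceMap([
        RefMarker("PZA01271.1", "1", 0.0),
        RefMarker("PZA03613.1", "1", 9.0),
        RefMarker("PZA02129.1", "1", 37.0),
        RefMarker("PZA02032.1", "1", 51.0),
    ])
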