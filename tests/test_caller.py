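"""Marker ancestry classification and block segmentation."""

import itertools
import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from _oracles import oracle_classify, oracle_segment
from conftest import four_marker_map, make_calls, make_map
from introview import (
    Genotype,
    MISSING,
    MarkerCallState,
    ValidationError,
    call_library,
    classify_marker,
    segment_blocks,
)
from introview.caller import blocks_to_frame, call_line
from introview.consensus import ConsensusResult, replicate_groups
from introview.io import GenotypeMatrix, SampleRecord


def cr(token):
    return ConsensusResult(Genotype.from_token(token), 1, 1, False)


def g(token):
    return Genotype.from_token(token)


# ---------------------------------------------------------------------------
# classification


@pytest.mark.parametrize("nil,rec,don,state", [
    ("CC", "AA", "CC", "DONOR"),
    ("AA", "AA", "CC", "RECURRENT"),
    ("AC", "AA", "CC", "HET"),
    ("GG", "AA", "CC", "NON_PARENTAL"),
    ("--", "AA", "CC", "MISSING"),
    ("GG", "AA", "AA", "UNINFORMATIVE"),  # sample 7 at SNP1: parents equal
    ("AA", "AG", "CC", "UNINFORMATIVE"),  # het parent consensus
    ("AA", "--", "CC", "UNINFORMATIVE"),
])
def test_classify_marker_examples(nil, rec, don, state):
    assert classify_marker(g(nil), cr(rec), cr(don)) is MarkerCallState[state]


def _all_genotypes(alphabet):
    pairs = ["".join(sorted(p))
             for p in itertools.combinations_with_replacement(alphabet, 2)]
    return [None] + sorted(set(pairs))


def test_classification_exhaustive_two_allele_alphabet():
    """Every (NIL, recurrent, donor) triple matches the brute-force rule
    and the six states partition the space."""
    options = _all_genotypes("AG")
    n = 0
    for nil, rec, don in itertools.product(options, repeat=3):
        expected = oracle_classify(nil, rec, don)
        got = classify_marker(
            MISSING if nil is None else g(nil),
            cr("--" if rec is None else rec),
            cr("--" if don is None else don),
        )
        assert got.value == expected, (nil, rec, don)
        n += 1
    assert n == 4 ** 3


@given(st.permutations("ACGT"))
def test_classification_invariant_under_allele_relabeling(perm):
    relabel = dict(zip("ACGT", perm))

    def remap(token):
        if token is None:
            return "--"
        return "".join(sorted(relabel[c] for c in token))

    options = _all_genotypes("ACGT")
    for nil, rec, don in itertools.product(options, repeat=3):
        before = classify_marker(
            g("--" if nil is None else nil),
            cr("--" if rec is None else rec),
            cr("--" if don is None else don),
        )
        after = classify_marker(
            g(remap(nil)), cr(remap(rec)), cr(remap(don))
        )
        assert before is after


# ---------------------------------------------------------------------------
# segmentation examples on the four-marker map (0, 9, 37, 51 cM)


def test_segment_single_donor_block_with_flanks():
    refmap = four_marker_map()
    calls = make_calls("L", refmap, ["RECURRENT", "DONOR", "DONOR",
                                     "RECURRENT"])
    (block,) = segment_blocks(calls, refmap)
    assert block.state is MarkerCallState.DONOR
    assert (block.inner_start, block.inner_end) == (9.0, 37.0)
    assert (block.outer_start, block.outer_end) == (4.5, 44.0)
    assert block.support_markers == ("PZA03613.1", "PZA02129.1")
    assert block.n_support == 2
    assert block.left_flank == "PZA01271.1"
    assert block.right_flank == "PZA02032.1"


def test_segment_missing_does_not_break_run():
    refmap = four_marker_map()
    calls = make_calls("L", refmap, ["RECURRENT", "DONOR", "MISSING",
                                     "DONOR"])
    (block,) = segment_blocks(calls, refmap)
    assert (block.inner_start, block.inner_end) == (9.0, 51.0)
    assert block.support_markers == ("PZA03613.1", "PZA02032.1")
    assert block.outer_end == 51.0  # no recurrent flank: terminal marker
    assert block.right_flank is None


def test_segment_all_recurrent_yields_no_blocks():
    refmap = four_marker_map()
    calls = make_calls("L", refmap, ["RECURRENT"] * 4)
    assert segment_blocks(calls, refmap) == []


def test_segment_het_forms_its_own_block():
    refmap = four_marker_map()
    calls = make_calls("L", refmap, ["DONOR", "DONOR", "HET", "HET"])
    donor, hetb = segment_blocks(calls, refmap)
    assert donor.state is MarkerCallState.DONOR
    assert hetb.state is MarkerCallState.HET
    assert donor.inner_end < hetb.inner_start


def test_segment_het_as_donor_merges_runs():
    refmap = four_marker_map()
    calls = make_calls("L", refmap, ["DONOR", "HET", "DONOR", "RECURRENT"])
    blocks = segment_blocks(calls, refmap, het_as_donor=True)
    assert len(blocks) == 1
    assert blocks[0].n_support == 3


def test_segment_min_markers_filters_short_runs():
    refmap = four_marker_map()
    calls = make_calls("L", refmap, ["DONOR", "RECURRENT", "DONOR",
                                     "DONOR"])
    assert len(segment_blocks(calls, refmap, min_markers=1)) == 2
    blocks = segment_blocks(calls, refmap, min_markers=2)
    assert len(blocks) == 1 and blocks[0].inner_start == 37.0


# ---------------------------------------------------------------------------
# segmentation against the reference scan


STATE_NAMES = ["RECURRENT", "DONOR", "HET", "NON_PARENTAL", "MISSING",
               "UNINFORMATIVE"]


def random_state_sequence(rnd, max_len=200):
    n = rnd.randint(1, max_len)
    positions = []
    pos = 0.0
    for _ in range(n):
        pos += rnd.uniform(0.1, 5.0)
        positions.append(round(pos, 2))
    states = [rnd.choice(STATE_NAMES) for _ in range(n)]
    return states, positions


def assert_matches_oracle(states, positions, min_markers):
    refmap = make_map(positions)
    calls = make_calls("L", refmap, states)
    got = segment_blocks(calls, refmap, min_markers=min_markers)
    expected = oracle_segment(states, positions, min_markers=min_markers)
    assert len(got) == len(expected)
    for b, e in zip(got, expected):
        assert b.state.value == e["state"]
        assert (b.inner_start, b.inner_end) == \
            (e["inner_start"], e["inner_end"])
        assert (b.outer_start, b.outer_end) == \
            (e["outer_start"], e["outer_end"])
        assert b.support_markers == \
            tuple(f"m{i}" for i in e["support"])
        assert b.left_flank == (
            None if e["left_flank"] is None else f"m{e['left_flank']}"
        )
        assert b.right_flank == (
            None if e["right_flank"] is None else f"m{e['right_flank']}"
        )


def test_segmentation_matches_reference_scan_randomized():
    rnd = random.Random(20240901)
    for _ in range(200):
        states, positions = random_state_sequence(rnd, max_len=60)
        assert_matches_oracle(states, positions, rnd.choice([1, 1, 2, 3]))


def test_segmentation_structural_invariants():
    """Each donor marker lies in exactly one donor block; no recurrent
    marker position falls inside any inner span; min_markers is monotone."""
    rnd = random.Random(4)
    for _ in range(100):
        states, positions = random_state_sequence(rnd, max_len=80)
        refmap = make_map(positions)
        calls = make_calls("L", refmap, states)
        blocks = segment_blocks(calls, refmap)
        donor_blocks = [b for b in blocks
                        if b.state is MarkerCallState.DONOR]
        for i, (s, p) in enumerate(zip(states, positions)):
            if s == "DONOR":
                containing = [
                    b for b in donor_blocks
                    if f"m{i}" in b.support_markers
                ]
                assert len(containing) == 1
            if s == "RECURRENT":
                assert not any(
                    b.inner_start <= p <= b.inner_end for b in blocks
                )
        counts = [
            len(segment_blocks(calls, refmap, min_markers=k))
            for k in (1, 2, 3, 5)
        ]
        assert counts == sorted(counts, reverse=True)


# ---------------------------------------------------------------------------
# line and library calling


def _mini_library():
    """Two-marker-per-state toy library: parents plus three NILs."""
    refmap = make_map([0.0, 10.0, 20.0, 30.0], prefix="mk")
    records = [
        SampleRecord("R", "RecParent", "Control"),
        SampleRecord("D", "DonParent", "Control"),
        SampleRecord("LR", "LikeRecurrent", "NIL",
                     recurrent_parent_id="R", donor_parent_id="D"),
        SampleRecord("LD", "LikeDonor", "NIL",
                     recurrent_parent_id="R", donor_parent_id="D"),
        SampleRecord("LM", "MixedLine", "NIL",
                     recurrent_parent_id="R", donor_parent_id="D"),
    ]
    markers = [f"mk{i}" for i in range(4)]
    rows = {
        "R": ["AA", "CC", "GG", "TT"],
        "D": ["GG", "TT", "AA", "CC"],
        "LR": ["AA", "CC", "GG", "TT"],
        "LD": ["GG", "TT", "AA", "CC"],
        "LM": ["AA", "TT", "--", "CC"],
    }
    calls = {
        (m, s): Genotype.from_token(rows[s][i])
        for i, m in enumerate(markers) for s in rows
    }
    matrix = GenotypeMatrix.from_calls(markers, list(rows), calls)
    return refmap, records, matrix


def test_line_identical_to_a_parent_is_uniformly_classified():
    refmap, records, matrix = _mini_library()
    result = call_library(refmap, records, matrix)
    assert set(result.calls["LR"].states.values()) == \
        {MarkerCallState.RECURRENT}
    assert set(result.calls["LD"].states.values()) == {MarkerCallState.DONOR}
    assert result.blocks["LR"] == []
    assert [b.support_markers for b in result.blocks["LD"]] == \
        [("mk0", "mk1", "mk2", "mk3")]


def test_mixed_line_blocks():
    refmap, records, matrix = _mini_library()
    result = call_library(refmap, records, matrix)
    (block,) = result.blocks["LM"]
    assert block.support_markers == ("mk1", "mk3")
    assert (block.inner_start, block.inner_end) == (10.0, 30.0)


def test_fixture_line_has_no_mapped_calls(sample_refmap, sample_records,
                                          sample_matrix):
    """The sample raw data's SNPs are not on the sample map, so mapped
    markers of line 7 carry no information and no blocks are reported
    (parent consensi at unknown markers are missing, hence uninformative
    before the line's own missing call is even considered)."""
    result = call_library(sample_refmap, sample_records, sample_matrix)
    assert set(result.blocks) == {"7", "9"}
    assert set(result.calls["7"].states.values()) <= {
        MarkerCallState.MISSING, MarkerCallState.UNINFORMATIVE,
    }
    assert result.blocks["7"] == []
    assert len(result.unmapped_markers) == 8


def test_call_line_composes_classify_over_mapped_markers():
    refmap, records, matrix = _mini_library()
    groups = replicate_groups(records)
    from introview.consensus import group_consensus
    recurrent = {f"mk{i}": group_consensus(matrix, groups["R"], f"mk{i}")
                 for i in range(4)}
    donor = {f"mk{i}": group_consensus(matrix, groups["D"], f"mk{i}")
             for i in range(4)}
    calls = call_line("LM", matrix, refmap, ["LM"], recurrent, donor)
    assert [calls.states[f"mk{i}"].value for i in range(4)] == \
        ["RECURRENT", "DONOR", "MISSING", "DONOR"]


def test_library_without_callable_lines_errors(sample_refmap):
    records = [
        SampleRecord("R", "RecParent", "Control"),
        SampleRecord("D", "DonParent", "Control"),
    ]
    markers = ["PZA01271.1"]
    matrix = GenotypeMatrix.from_calls(markers, ["R", "D"], {
        ("PZA01271.1", "R"): g("AA"), ("PZA01271.1", "D"): g("CC"),
    })
    with pytest.raises(ValidationError, match="no callable lines"):
        call_library(sample_refmap, records, matrix)


def test_blocks_to_frame_layout():
    refmap = four_marker_map()
    calls = make_calls("L7", refmap, ["RECURRENT", "DONOR", "DONOR",
                                      "RECURRENT"])
    frame = blocks_to_frame(segment_blocks(calls, refmap))
    row = frame.iloc[0]
    assert row["line_id"] == "L7"
    assert row["support_markers"] == "PZA03613.1,PZA02129.1"
    assert row["left_flank"] == "PZA01271.1"
    assert list(frame.columns)[:4] == \
        ["line_id", "chromosome", "state", "inner_start"]
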