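"""Marker ancestry classification and introgression-block segmentation.

This is the core computation: given consensus genotypes for the recurrent
and donor parents and the genotype of a near-isogenic line (NIL), every
mapped marker is assigned an origin state, and runs of donor (or
heterozygous) states are segmented into introgression blocks on the
reference genetic map.

Classification cascade per marker (first matching rule wins):

1. either parent consensus missing or heterozygous, or the two parents
   identical -> UNINFORMATIVE (the marker cannot distinguish the parents);
2. NIL call missing -> MISSING;
3. NIL equals the recurrent parent -> RECURRENT;
4. NIL equals the donor -> DONOR;
5. NIL carries exactly one allele from each parent -> HET;
6. anything else -> NON_PARENTAL (reported, never silently merged).

Segmentation walks each chromosome in map order.  Maximal runs of DONOR
(or HET) markers become blocks; interior MISSING, UNINFORMATIVE and
NON_PARENTAL markers neither support nor break a run; a RECURRENT marker,
a marker of the other introgressed state, or the chromosome end closes it.
A block's *inner* span is the first-to-last supporting marker; its *outer*
span extends to the midpoint toward the nearest flanking RECURRENT marker
(or to the chromosome's terminal mapped position when there is none) —
the conventional point estimate for a breakpoint lying uniformly between
the last donor and first recurrent marker.  Both spans are closed
intervals in cM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from ._util import natural_key
from .consensus import (
    ConsensusResult,
    DonorInference,
    group_consensus,
    infer_donor_from_f1,
    replicate_groups,
)
from .errors import ValidationError
from .genotype import Genotype
from .io import GenotypeMatrix, ReferenceMap, SampleRecord

log = logging.getLogger(__name__)


class MarkerCallState(Enum):
    RECURRENT = "RECURRENT"
    DONOR = "DONOR"
    HET = "HET"
    NON_PARENTAL = "NON_PARENTAL"
    MISSING = "MISSING"
    UNINFORMATIVE = "UNINFORMATIVE"

    def __str__(self) -> str:
        return self.value


#: States that constitute introgression evidence.
BLOCK_STATES = (MarkerCallState.DONOR, MarkerCallState.HET)


def classify_marker(g: Genotype, r: ConsensusResult,
                    d: ConsensusResult) -> MarkerCallState:
    """Classify one NIL genotype against the two parental consensi."""
    rg, dg = r.genotype, d.genotype
    if rg.is_missing or dg.is_missing or rg.is_het or dg.is_het or rg == dg:
        return MarkerCallState.UNINFORMATIVE
    if g.is_missing:
        return MarkerCallState.MISSING
    if g == rg:
        return MarkerCallState.RECURRENT
    if g == dg:
        return MarkerCallState.DONOR
    if set(g.alleles) == {rg.hom_allele(), dg.hom_allele()}:
        return MarkerCallState.HET
    return MarkerCallState.NON_PARENTAL


@dataclass
class LineCalls:
    """Per-marker origin states of one line, in reference-map order."""

    line_id: str
    states: Dict[str, MarkerCallState]  # marker name -> state

    def state(self, marker: str) -> MarkerCallState:
        return self.states[marker]


@dataclass(frozen=True)
class IntrogressionBlock:
    """A contiguous donor or heterozygous segment of one line."""

    line_id: str
    chromosome: str
    state: MarkerCallState
    inner_start: float
    inner_end: float
    outer_start: float
    outer_end: float
    support_markers: Tuple[str, ...]
    left_flank: Optional[str] = None
    right_flank: Optional[str] = None

    @property
    def n_support(self) -> int:
        return len(self.support_markers)

    def overlaps(self, start: float, end: float, outer: bool = False) -> bool:
        """Closed-interval overlap with a query interval on the same chromosome."""
        lo = self.outer_start if outer else self.inner_start
        hi = self.outer_end if outer else self.inner_end
        return lo <= end and hi >= start


def call_line(line_id: str, matrix: GenotypeMatrix, refmap: ReferenceMap,
              line_samples: Sequence[str],
              recurrent: Dict[str, ConsensusResult],
              donor: Dict[str, ConsensusResult]) -> LineCalls:
    """Classify every mapped marker for one line.

    ``line_samples`` are the raw-data columns of the line (the line itself
    plus any replicates); their calls are collapsed by consensus before
    classification.  Mapped markers absent from the raw data are MISSING.
    """
    states: Dict[str, MarkerCallState] = {}
    for m in refmap:
        g = group_consensus(matrix, line_samples, m.name).genotype
        states[m.name] = classify_marker(g, recurrent[m.name], donor[m.name])
    return LineCalls(line_id=line_id, states=states)


def segment_blocks(calls: LineCalls, refmap: ReferenceMap,
                   min_markers: int = 1,
                   het_as_donor: bool = False) -> List[IntrogressionBlock]:
    """Segment one line's marker states into introgression blocks.

    With ``het_as_donor`` heterozygous markers count as donor evidence and
    are absorbed into DONOR blocks (no separate HET blocks are reported).
    """
    if min_markers < 1:
        raise ValueError("min_markers must be >= 1")
    blocks: List[IntrogressionBlock] = []
    for chrom in refmap.chromosomes:
        markers = refmap.markers_on(chrom)
        seq = []
        for m in markers:
            st = calls.states[m.name]
            if het_as_donor and st is MarkerCallState.HET:
                st = MarkerCallState.DONOR
            seq.append(st)
        blocks.extend(
            _segment_chromosome(calls.line_id, chrom, markers, seq, min_markers)
        )
    blocks.sort(key=lambda b: (natural_key(b.chromosome), b.inner_start))
    return blocks


def _segment_chromosome(line_id, chrom, markers, states, min_markers):
    runs: List[Tuple[MarkerCallState, List[int]]] = []
    cur_state: Optional[MarkerCallState] = None
    cur_idx: List[int] = []
    for i, st in enumerate(states):
        if st in BLOCK_STATES:
            if cur_state is st:
                cur_idx.append(i)
            else:
                if cur_state is not None:
                    runs.append((cur_state, cur_idx))
                cur_state, cur_idx = st, [i]
        elif st is MarkerCallState.RECURRENT:
            if cur_state is not None:
                runs.append((cur_state, cur_idx))
                cur_state, cur_idx = None, []
        # MISSING / UNINFORMATIVE / NON_PARENTAL: neither support nor break
    if cur_state is not None:
        runs.append((cur_state, cur_idx))

    out = []
    for state, idx in runs:
        if len(idx) < min_markers:
            log.info(
                "line %s chr %s: dropping %s run of %d marker(s) "
                "(min_markers=%d)", line_id, chrom, state, len(idx), min_markers,
            )
            continue
        first, last = idx[0], idx[-1]
        inner_start = markers[first].position
        inner_end = markers[last].position
        left = _nearest_recurrent(markers, states, first, step=-1)
        right = _nearest_recurrent(markers, states, last, step=+1)
        outer_start = (
            (left.position + inner_start) / 2.0
            if left is not None else markers[0].position
        )
        outer_end = (
            (right.position + inner_end) / 2.0
            if right is not None else markers[-1].position
        )
        out.append(IntrogressionBlock(
            line_id=line_id,
            chromosome=chrom,
            state=state,
            inner_start=inner_start,
            inner_end=inner_end,
            outer_start=outer_start,
            outer_end=outer_end,
            support_markers=tuple(markers[i].name for i in idx),
            left_flank=left.name if left is not None else None,
            right_flank=right.name if right is not None else None,
        ))
    return out


def _nearest_recurrent(markers, states, start, step):
    i = start + step
    while 0 <= i < len(states):
        if states[i] is MarkerCallState.RECURRENT:
            return markers[i]
        i += step
    return None


# ---------------------------------------------------------------------------
# whole-library calling


@dataclass
class LibraryResult:
    """Output of calling every line of a library."""

    blocks: Dict[str, List[IntrogressionBlock]]  # line root id -> blocks
    calls: Dict[str, LineCalls]
    line_names: Dict[str, str]  # line root id -> display name
    line_groups: Dict[str, str]  # line root id -> group label (display only)
    unmapped_markers: List[str] = field(default_factory=list)
    skipped: Dict[str, str] = field(default_factory=dict)  # id -> reason
    n_conflicts: int = 0


def _parent_consensi(matrix, refmap, groups, root_id):
    members = groups[root_id]
    return {
        m.name: group_consensus(matrix, members, m.name) for m in refmap
    }


def call_library(refmap: ReferenceMap, records: Sequence[SampleRecord],
                 matrix: GenotypeMatrix, min_markers: int = 1,
                 het_as_donor: bool = False) -> LibraryResult:
    """Call introgression blocks for every callable line of a library.

    A line is callable when it heads a replicate group (blank replicate-of),
    is not itself referenced as a parent or F1 of another sample, has a
    recurrent parent, and has either a directly genotyped donor parent or
    an F1 ancestor from which the donor is inferred by allele subtraction.
    """
    groups = replicate_groups(records)
    by_id = {r.sample_id: r for r in records}
    referenced = set()
    for r in records:
        for link in (r.recurrent_parent_id, r.donor_parent_id,
                     r.f1_ancestor_id):
            if link is not None:
                referenced.add(link)

    unmapped = [m for m in matrix.markers if m not in refmap]
    if unmapped:
        log.warning("%d raw-data marker(s) absent from the reference map "
                    "were excluded: %s", len(unmapped), ", ".join(unmapped[:10]))

    consensus_cache: Dict[str, Dict[str, ConsensusResult]] = {}

    def consensi_of(root: str) -> Dict[str, ConsensusResult]:
        if root not in consensus_cache:
            consensus_cache[root] = _parent_consensi(matrix, refmap, groups, root)
        return consensus_cache[root]

    result = LibraryResult(blocks={}, calls={}, line_names={}, line_groups={},
                           unmapped_markers=unmapped)

    for rec in records:
        sid = rec.sample_id
        if rec.replicate_of is not None:
            continue  # collapsed into its root's group
        if sid in referenced:
            result.skipped[sid] = "parent/F1 sample"
            continue
        if rec.recurrent_parent_id is None:
            result.skipped[sid] = "no recurrent parent"
            continue
        if rec.donor_parent_id is None and rec.f1_ancestor_id is None:
            result.skipped[sid] = "no donor parent or F1 ancestor"
            continue

        recurrent = consensi_of(rec.recurrent_parent_id)
        if rec.donor_parent_id is not None:
            donor = consensi_of(rec.donor_parent_id)
        else:
            f1 = consensi_of(rec.f1_ancestor_id)
            donor = {}
            for name, f1_res in f1.items():
                inf: DonorInference = infer_donor_from_f1(
                    f1_res.genotype, recurrent[name].genotype
                )
                if inf.flag is not None:
                    log.info("line %s marker %s: donor inference %s",
                             sid, name, inf.flag)
                donor[name] = ConsensusResult(
                    inf.genotype, f1_res.n_support, f1_res.n_total,
                    conflict=False,
                )

        line_calls = call_line(
            sid, matrix, refmap, groups[sid], recurrent, donor
        )
        result.calls[sid] = line_calls
        result.blocks[sid] = segment_blocks(
            line_calls, refmap, min_markers=min_markers,
            het_as_donor=het_as_donor,
        )
        result.line_names[sid] = rec.name
        result.line_groups[sid] = rec.group

    if not result.blocks:
        raise ValidationError(
            "no callable lines: every sample is a parent, a replicate, or "
            "lacks a recurrent/donor pedigree"
        )

    for root in consensus_cache.values():
        result.n_conflicts += sum(1 for c in root.values() if c.conflict)
    return result


def blocks_to_frame(blocks: Sequence[IntrogressionBlock]) -> pd.DataFrame:
    """Tabulate blocks with one row per block (the block-table TSV layout)."""
    rows = [{
        "line_id": b.line_id,
        "chromosome": b.chromosome,
        "state": b.state.value,
        "inner_start": b.inner_start,
        "inner_end": b.inner_end,
        "outer_start": b.outer_start,
        "outer_end": b.outer_end,
        "n_support": b.n_support,
        "support_markers": ",".join(b.support_markers),
        "left_flank": b.left_flank or "",
        "right_flank": b.right_flank or "",
    } for b in blocks]
    return pd.DataFrame(rows, columns=[
        "line_id", "chromosome", "state", "inner_start", "inner_end",
        "outer_start", "outer_end", "n_support", "support_markers",
        "left_flank", "right_flank",
    ])
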