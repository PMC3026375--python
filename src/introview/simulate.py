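"""Synthetic NIL libraries with known ground truth.

Emulates an introgression library: two fully homozygous parents that
differ at every marker, replicated parental genotyping, and NILs carrying
donor segments whose count per line is Poisson and whose lengths are
exponential with uniformly placed starts (a controllable stand-in for the
repeated-backcross process; overlapping draws are merged, so truth
segments are disjoint).  Marker-wise noise channels — genotyping error,
missing calls, residual heterozygosity — are applied after the clean
genotypes are laid down, so the consensus and conflict code paths are
exercised by the noise, not by construction.

All randomness flows from a single seed through one generator in a fixed
order (marker alleles, then per-line segments, then per-sample noise), so
a given seed reproduces the emitted files byte for byte.

``truth_blocks`` converts the true segments into the block list a perfect
caller must report: a segment's expected inner span runs from its first to
its last covered marker, segments covering fewer than ``min_markers``
markers are undetectable, and consecutive same-state segments with no
marker in the gap between them are indistinguishable from a single block
and are merged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np

from ._util import format_number
from .errors import ValidationError
from .genotype import MISSING, Genotype, het, hom
from .io import (
    Config,
    GenotypeMatrix,
    ReferenceMap,
    RefMarker,
    SampleRecord,
    write_config,
    write_raw_data,
    write_reference_map,
    write_relationships,
)

_BASES = "ACGT"


@dataclass
class SimParams:
    """Study conditions for a simulated library.

    Defaults describe a small maize-like library: 5 chromosomes of 150 cM
    with 100 equally spaced markers each, 20 NILs carrying on average two
    donor segments of mean length 20 cM, parents genotyped in triplicate,
    1% genotyping error, 5% missing calls, 1% residual heterozygosity.
    """

    seed: int
    n_chromosomes: int = 5
    chrom_length_cm: float = 150.0
    n_markers_per_chrom: int = 100
    n_lines: int = 20
    mean_segments_per_line: float = 2.0
    mean_segment_length_cm: float = 20.0
    het_segment_prob: float = 0.1
    n_parent_replicates: int = 3
    error_rate: float = 0.01
    missing_rate: float = 0.05
    het_residual_rate: float = 0.01
    db_name: str = "sim"

    def __post_init__(self):
        for name in ("error_rate", "missing_rate", "het_residual_rate",
                     "het_segment_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_chromosomes", "n_markers_per_chrom", "n_lines",
                     "n_parent_replicates"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        for name in ("chrom_length_cm", "mean_segment_length_cm"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.mean_segments_per_line < 0:
            raise ValidationError("mean_segments_per_line must be >= 0")


@dataclass(frozen=True)
class TruthSegment:
    chromosome: str
    start: float
    end: float
    zygosity: str  # "hom" | "het"


@dataclass
class SimTruth:
    """Ground truth: donor segments and per-marker origin per line."""

    segments: Dict[str, List[TruthSegment]]
    marker_states: Dict[str, Dict[str, str]]  # line -> marker -> state name


@dataclass
class SimResult:
    params: SimParams
    refmap: ReferenceMap
    records: List[SampleRecord]
    matrix: GenotypeMatrix
    config: Config
    truth: SimTruth
    paths: Dict[str, Path] = field(default_factory=dict)


def _marker_positions(params: SimParams) -> List[float]:
    n, length = params.n_markers_per_chrom, params.chrom_length_cm
    if n == 1:
        return [0.0]
    return [round(j * length / (n - 1), 3) for j in range(n)]


def _draw_segments(rng, params: SimParams) -> List[TruthSegment]:
    n_seg = rng.poisson(params.mean_segments_per_line)
    raw: Dict[str, List[Tuple[float, float]]] = {}
    for _ in range(n_seg):
        chrom = str(rng.integers(1, params.n_chromosomes + 1))
        start = float(rng.uniform(0.0, params.chrom_length_cm))
        length = float(rng.exponential(params.mean_segment_length_cm))
        end = min(start + length, params.chrom_length_cm)
        raw.setdefault(chrom, []).append((start, end))
    segments: List[TruthSegment] = []
    for chrom in sorted(raw, key=int):
        merged: List[List[float]] = []
        for start, end in sorted(raw[chrom]):
            if merged and start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], end)
            else:
                merged.append([start, end])
        for start, end in merged:
            zyg = "het" if rng.random() < params.het_segment_prob else "hom"
            segments.append(TruthSegment(chrom, start, end, zyg))
    return segments


def _apply_noise(rng, g: Genotype, r: str, d: str,
                 error_rate: float, missing_rate: float) -> Genotype:
    if error_rate > 0 and rng.random() < error_rate:
        options = [x for x in (hom(r), het(r, d), hom(d)) if x != g]
        g = options[rng.integers(len(options))]
    if missing_rate > 0 and rng.random() < missing_rate:
        return MISSING
    return g


def simulate_library(params: SimParams, out_dir=None) -> SimResult:
    """Generate a library; optionally write the four input files plus truth.

    With ``out_dir`` set, writes ``ref_map.tab``, ``relationships.tab``,
    ``raw_data.tab``, ``sim.cfg`` and ``truth.tsv`` there.
    """
    rng = np.random.default_rng(params.seed)
    positions = _marker_positions(params)

    # 1. reference map and per-marker parental alleles
    markers: List[RefMarker] = []
    alleles: Dict[str, Tuple[str, str]] = {}  # marker -> (recurrent, donor)
    for c in range(1, params.n_chromosomes + 1):
        for j, pos in enumerate(positions):
            name = f"M{c}_{j + 1:04d}"
            markers.append(RefMarker(name, str(c), pos))
            i, k = rng.choice(4, size=2, replace=False)
            alleles[name] = (_BASES[i], _BASES[k])
    refmap = ReferenceMap(markers)

    # 2. pedigree roster
    records: List[SampleRecord] = []
    next_id = 1

    def add(name, group, **links):
        nonlocal next_id
        rec = SampleRecord(sample_id=str(next_id), name=name, group=group,
                           **links)
        records.append(rec)
        next_id += 1
        return rec.sample_id

    rp_root = add("RP", "Control")
    for i in range(params.n_parent_replicates - 1):
        add("RP", "Control", replicate_of=rp_root)
    dp_root = add("DP", "Control")
    for i in range(params.n_parent_replicates - 1):
        add("DP", "Control", replicate_of=dp_root)
    line_ids: List[str] = []
    for i in range(params.n_lines):
        line_ids.append(add(f"NIL{i + 1:03d}", "NIL",
                            recurrent_parent_id=rp_root,
                            donor_parent_id=dp_root))

    # 3. true donor segments and marker states per line
    truth = SimTruth(segments={}, marker_states={})
    for line in line_ids:
        segs = _draw_segments(rng, params)
        truth.segments[line] = segs
        states: Dict[str, str] = {}
        for m in markers:
            state = "RECURRENT"
            for s in segs:
                if s.chromosome == m.chromosome and s.start <= m.position <= s.end:
                    state = "HET" if s.zygosity == "het" else "DONOR"
                    break
            states[m.name] = state
        truth.marker_states[line] = states

    # 4. genotype matrix with marker-wise noise, sample-major order
    calls: Dict[Tuple[str, str], Genotype] = {}
    sample_order = [r.sample_id for r in records]
    for rec in records:
        root = rec.replicate_of or rec.sample_id
        is_recurrent = root == rp_root
        is_donor = root == dp_root
        for m in markers:
            r, d = alleles[m.name]
            if is_recurrent:
                g = hom(r)
            elif is_donor:
                g = hom(d)
            else:
                state = truth.marker_states[rec.sample_id][m.name]
                if state == "DONOR":
                    g = hom(d)
                elif state == "HET":
                    g = het(r, d)
                else:
                    g = hom(r)
                    if (params.het_residual_rate > 0
                            and rng.random() < params.het_residual_rate):
                        g = het(r, d)
            calls[(m.name, rec.sample_id)] = _apply_noise(
                rng, g, r, d, params.error_rate, params.missing_rate
            )
    matrix = GenotypeMatrix.from_calls(
        [m.name for m in markers], sample_order, calls
    )

    config = Config(values={
        "DB_NAME": params.db_name,
        "RAW_DATA": "raw_data.tab",
        "REF_MAP": "ref_map.tab",
        "RELATIONSHIPS": "relationships.tab",
    })

    result = SimResult(params=params, refmap=refmap, records=records,
                       matrix=matrix, config=config, truth=truth)
    if out_dir is not None:
        result.paths = _write_all(result, Path(out_dir))
    return result


def _write_all(result: SimResult, out_dir: Path) -> Dict[str, Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ref_map": out_dir / "ref_map.tab",
        "relationships": out_dir / "relationships.tab",
        "raw_data": out_dir / "raw_data.tab",
        "config": out_dir / "sim.cfg",
        "truth": out_dir / "truth.tsv",
    }
    write_reference_map(result.refmap, paths["ref_map"])
    write_relationships(result.records, paths["relationships"])
    write_raw_data(result.matrix, paths["raw_data"])
    result.config.base_dir = out_dir
    write_config(result.config, paths["config"])
    lines = ["line_id\tchromosome\tstart\tend\tzygosity"]
    for line in result.truth.segments:
        for s in result.truth.segments[line]:
            lines.append(
                f"{line}\t{s.chromosome}\t{s.start:.4f}\t{s.end:.4f}\t"
                f"{s.zygosity}"
            )
    paths["truth"].write_text("\n".join(lines) + "\n", encoding="utf-8")
    return paths


@dataclass(frozen=True)
class TruthBlock:
    """A block a perfect caller must recover from one truth segment run."""

    line_id: str
    chromosome: str
    state: str  # "DONOR" | "HET"
    inner_start: float
    inner_end: float
    support_markers: Tuple[str, ...]


def truth_blocks(truth: SimTruth, refmap: ReferenceMap,
                 min_markers: int = 1) -> Dict[str, List[TruthBlock]]:
    """Expected detectable blocks per line, given marker resolution."""
    out: Dict[str, List[TruthBlock]] = {}
    for line, segs in truth.segments.items():
        per_chrom: Dict[str, List[TruthBlock]] = {}
        for s in sorted(segs, key=lambda s: (s.chromosome, s.start)):
            inside = [
                m for m in refmap.markers_on(s.chromosome)
                if s.start <= m.position <= s.end
            ]
            if not inside:
                continue  # undetectable at marker resolution
            state = "HET" if s.zygosity == "het" else "DONOR"
            per_chrom.setdefault(s.chromosome, []).append(TruthBlock(
                line_id=line, chromosome=s.chromosome, state=state,
                inner_start=inside[0].position, inner_end=inside[-1].position,
                support_markers=tuple(m.name for m in inside),
            ))
        blocks: List[TruthBlock] = []
        for chrom, chrom_blocks in per_chrom.items():
            merged = [chrom_blocks[0]]
            for b in chrom_blocks[1:]:
                prev = merged[-1]
                gap_markers = [
                    m for m in refmap.markers_on(chrom)
                    if prev.inner_end < m.position < b.inner_start
                ]
                if b.state == prev.state and not gap_markers:
                    merged[-1] = TruthBlock(
                        line_id=line, chromosome=chrom, state=prev.state,
                        inner_start=prev.inner_start, inner_end=b.inner_end,
                        support_markers=prev.support_markers + b.support_markers,
                    )
                else:
                    merged.append(b)
            blocks.extend(
                b for b in merged if len(b.support_markers) >= min_markers
            )
        out[line] = blocks
    return out


def expected_donor_marker_fraction(params: SimParams) -> float:
    """Analytic expected fraction of markers of donor origin (hom or het).

    Segment starts are uniform on a chromosome of length L and extend
    rightward with exponential length (mean mu), so a single segment covers
    position x with probability q(x) = (mu/L)(1 - exp(-x/mu)).  Segment
    counts per chromosome are Poisson with mean lambda/n_chromosomes, hence
    the number covering x is Poisson-thinned and
    P(covered) = 1 - exp(-lambda_c q(x)); average over marker positions.
    """
    lam_c = params.mean_segments_per_line / params.n_chromosomes
    mu = params.mean_segment_length_cm
    length = params.chrom_length_cm
    xs = np.array(_marker_positions(params))
    q = (mu / length) * (1.0 - np.exp(-xs / mu))
    return float(np.mean(1.0 - np.exp(-lam_c * q)))
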