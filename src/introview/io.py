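"""Readers and writers for the four tab-delimited input formats.

The formats are:

* **reference map** — three tab-separated columns (marker name, chromosome,
  cM position), no header line;
* **relationships** — one header line, then seven tab-separated columns
  (sample id, sample name, group, recurrent parent, donor parent,
  replicate-of, F1 ancestor), trailing fields may be blank;
* **raw data** — free-text preamble, a sentinel line containing ``[Data]``,
  a sample-ID line (leading tab, then tab-separated sample ids), then one
  row per marker with one genotype token per sample;
* **configuration** — ``KEY  VALUE`` pairs separated by whitespace.

Every writer is the exact inverse of its parser: ``parse(write(x)) == x``.
UTF-8 with Unix or Windows line endings is accepted on input; writers emit
Unix line endings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from ._util import format_number, natural_key
from .errors import ParseError, ValidationError
from .genotype import Genotype

log = logging.getLogger(__name__)

DATA_SENTINEL = "[data]"  # matched case-insensitively
REQUIRED_CONFIG_KEYS = ("DB_NAME", "RAW_DATA", "REF_MAP", "RELATIONSHIPS")
RELATIONSHIPS_HEADER = (
    "Sample ID\tSample name\tGroup\tRecurrent Parent\tDonor Parent\t"
    "Replicate of\tF1 ancestor"
)


# ---------------------------------------------------------------------------
# reference map


@dataclass(frozen=True)
class RefMarker:
    """One mapped marker: name, chromosome label, position in cM."""

    name: str
    chromosome: str
    position: float


class ReferenceMap:
    """Markers grouped by chromosome, sorted by cM position.

    Chromosome labels are free text ("1", "X", "1A"); chromosomes iterate
    in natural-sort order.  Ties in position keep input order (stable sort).
    """

    def __init__(self, markers: Sequence[RefMarker]):
        if not markers:
            raise ValidationError("no markers in reference map")
        by_name: Dict[str, RefMarker] = {}
        by_chrom: Dict[str, List[RefMarker]] = {}
        for m in markers:
            if not m.name:
                raise ValidationError("marker with empty name")
            if m.position < 0:
                raise ValidationError(f"marker {m.name}: negative position")
            if m.name in by_name:
                raise ValidationError(f"duplicate marker name {m.name!r}")
            by_name[m.name] = m
            by_chrom.setdefault(m.chromosome, []).append(m)
        for chrom in by_chrom:
            by_chrom[chrom].sort(key=lambda m: m.position)  # stable
        self._by_name = by_name
        self._by_chrom = {
            c: by_chrom[c] for c in sorted(by_chrom, key=natural_key)
        }

    @property
    def chromosomes(self) -> List[str]:
        return list(self._by_chrom)

    def markers_on(self, chromosome: str) -> List[RefMarker]:
        return list(self._by_chrom.get(chromosome, []))

    def __iter__(self):
        for chrom in self._by_chrom:
            yield from self._by_chrom[chrom]

    def __len__(self) -> int:
        return len(self._by_name)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def lookup(self, name: str) -> Tuple[str, float]:
        """Return (chromosome, position) for a marker name."""
        try:
            m = self._by_name[name]
        except KeyError:
            raise ValidationError(f"unknown marker {name!r}") from None
        return m.chromosome, m.position

    def span(self, chromosome: str) -> Tuple[float, float]:
        """First and last mapped position on a chromosome."""
        ms = self._by_chrom[chromosome]
        return ms[0].position, ms[-1].position

    def __eq__(self, other) -> bool:
        if not isinstance(other, ReferenceMap):
            return NotImplemented
        return self._by_chrom == other._by_chrom

    def __repr__(self) -> str:
        return (
            f"<ReferenceMap {len(self)} markers on "
            f"{len(self._by_chrom)} chromosomes>"
        )


def _read_lines(path) -> List[str]:
    text = Path(path).read_text(encoding="utf-8")
    return text.replace("\r\n", "\n").replace("\r", "\n").split("\n")


def parse_reference_map(path) -> ReferenceMap:
    """Parse a reference map file (3 tab-separated columns, no header)."""
    markers: List[RefMarker] = []
    for lineno, line in enumerate(_read_lines(path), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise ParseError(
                f"expected 3 tab-separated fields, got {len(fields)}",
                path, lineno,
            )
        name, chrom, pos_text = (f.strip() for f in fields)
        try:
            pos = float(pos_text)
        except ValueError:
            raise ParseError(
                f"non-numeric position {pos_text!r} for marker {name!r}",
                path, lineno,
            ) from None
        markers.append(RefMarker(name, chrom, pos))
    return ReferenceMap(markers)


def write_reference_map(refmap: ReferenceMap, path) -> None:
    lines = [
        f"{m.name}\t{m.chromosome}\t{format_number(m.position)}"
        for m in refmap
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# relationships


@dataclass(frozen=True)
class SampleRecord:
    """One row of the relationships file.

    Optional link fields are ``None`` when blank in the file.
    """

    sample_id: str
    name: str
    group: str
    recurrent_parent_id: Optional[str] = None
    donor_parent_id: Optional[str] = None
    replicate_of: Optional[str] = None
    f1_ancestor_id: Optional[str] = None


_LINK_FIELDS = (
    "recurrent_parent_id", "donor_parent_id", "replicate_of", "f1_ancestor_id"
)


def _validate_records(records: Sequence[SampleRecord]) -> None:
    ids = set()
    for rec in records:
        if rec.sample_id in ids:
            raise ValidationError(f"duplicate sample id {rec.sample_id!r}")
        ids.add(rec.sample_id)
    for rec in records:
        for fld in _LINK_FIELDS:
            target = getattr(rec, fld)
            if target is not None and target not in ids:
                raise ValidationError(
                    f"sample {rec.sample_id!r}: {fld} refers to unknown "
                    f"sample id {target!r}"
                )
    # replicate chains must terminate
    parent = {r.sample_id: r.replicate_of for r in records}
    for start in parent:
        seen = {start}
        cur = parent[start]
        while cur is not None:
            if cur in seen:
                raise ValidationError(
                    f"replicate cycle involving sample {cur!r}"
                )
            seen.add(cur)
            cur = parent[cur]


def parse_relationships(path) -> List[SampleRecord]:
    """Parse a relationships file (header line skipped, 7 columns)."""
    lines = _read_lines(path)
    records: List[SampleRecord] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) > 7:
            raise ParseError(
                f"expected at most 7 tab-separated fields, got {len(fields)}",
                path, lineno,
            )
        fields += [""] * (7 - len(fields))  # trailing blanks may be omitted
        fields = [f.strip() for f in fields]
        if not fields[0]:
            raise ParseError("blank sample id", path, lineno)
        records.append(SampleRecord(
            sample_id=fields[0],
            name=fields[1],
            group=fields[2],
            recurrent_parent_id=fields[3] or None,
            donor_parent_id=fields[4] or None,
            replicate_of=fields[5] or None,
            f1_ancestor_id=fields[6] or None,
        ))
    _validate_records(records)
    return records


def write_relationships(records: Sequence[SampleRecord], path) -> None:
    lines = [RELATIONSHIPS_HEADER]
    for r in records:
        lines.append("\t".join([
            r.sample_id, r.name, r.group,
            r.recurrent_parent_id or "",
            r.donor_parent_id or "",
            r.replicate_of or "",
            r.f1_ancestor_id or "",
        ]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# raw data


class GenotypeMatrix:
    """Marker x sample matrix of genotype calls.

    Stored as a pandas DataFrame of canonical genotype tokens with marker
    names as the index and sample ids as columns.
    """

    def __init__(self, markers: Sequence[str], samples: Sequence[str],
                 tokens: pd.DataFrame):
        self.markers = list(markers)
        self.samples = list(samples)
        self.tokens = tokens

    @classmethod
    def from_calls(cls, markers: Sequence[str], samples: Sequence[str],
                   calls: Dict[Tuple[str, str], Genotype]) -> "GenotypeMatrix":
        data = {
            s: [calls[(m, s)].token for m in markers] for s in samples
        }
        frame = pd.DataFrame(data, index=list(markers), columns=list(samples))
        return cls(markers, samples, frame)

    def genotype(self, marker: str, sample: str) -> Genotype:
        return Genotype.from_token(self.tokens.at[marker, sample])

    def calls_for(self, marker: str, samples: Sequence[str]) -> List[Genotype]:
        """Genotypes of several samples at one marker (present samples only)."""
        return [
            Genotype.from_token(self.tokens.at[marker, s])
            for s in samples
            if s in self.tokens.columns
        ]

    def __contains__(self, marker: str) -> bool:
        return marker in self.tokens.index

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.markers == other.markers
            and self.samples == other.samples
            and self.tokens.equals(other.tokens)
        )

    def __repr__(self) -> str:
        return (
            f"<GenotypeMatrix {len(self.markers)} markers x "
            f"{len(self.samples)} samples>"
        )


def parse_raw_data(path, known_samples) -> GenotypeMatrix:
    """Parse a raw-data file against the sample ids of the relationships file.

    Everything before the ``[Data]`` sentinel line is ignored.  Sentinel
    matching is case-insensitive and tolerates extra text on the line.
    """
    lines = _read_lines(path)
    known = set(known_samples)

    sentinel_idx = None
    for i, line in enumerate(lines):
        if DATA_SENTINEL in line.casefold():
            sentinel_idx = i
            break
    if sentinel_idx is None:
        raise ParseError('missing "[Data]" sentinel line', path)

    body = [
        (sentinel_idx + 1 + j + 1, line)  # (1-based lineno, text)
        for j, line in enumerate(lines[sentinel_idx + 1:])
        if line.strip()
    ]
    if not body:
        raise ParseError("no sample-ID line after sentinel", path)

    id_lineno, id_line = body[0]
    id_fields = id_line.split("\t")
    samples = [f.strip() for f in id_fields[1:]]  # first field is padding
    if not samples or any(not s for s in samples):
        raise ParseError("malformed sample-ID line", path, id_lineno)
    if len(set(samples)) != len(samples):
        raise ValidationError(f"{path}: duplicate sample ids in sample-ID line")
    unknown = [s for s in samples if s not in known]
    if unknown:
        raise ValidationError(
            f"{path}: sample IDs {unknown} not found; sample IDs in this "
            f"line must be represented in the relationships file"
        )

    markers: List[str] = []
    calls: Dict[Tuple[str, str], Genotype] = {}
    seen = set()
    for lineno, line in body[1:]:
        fields = line.split("\t")
        if len(fields) != len(samples) + 1:
            raise ParseError(
                f"expected {len(samples) + 1} fields, got {len(fields)}",
                path, lineno,
            )
        marker = fields[0].strip()
        if not marker:
            raise ParseError("blank marker name", path, lineno)
        if marker in seen:
            raise ValidationError(f"{path}: duplicate marker row {marker!r}")
        seen.add(marker)
        markers.append(marker)
        for sample, token in zip(samples, fields[1:]):
            try:
                calls[(marker, sample)] = Genotype.from_token(token)
            except ParseError as exc:
                raise ParseError(
                    f"marker {marker!r}, sample {sample!r}: {exc}",
                    path, lineno,
                ) from None
    return GenotypeMatrix.from_calls(markers, samples, calls)


def write_raw_data(matrix: GenotypeMatrix, path) -> None:
    if not matrix.markers or not matrix.samples:
        raise ValidationError("refusing to write an empty genotype matrix")
    lines = ["[Data]", "\t" + "\t".join(matrix.samples)]
    for marker in matrix.markers:
        row = matrix.tokens.loc[marker, matrix.samples]
        lines.append(marker + "\t" + "\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# configuration


@dataclass
class Config:
    """Parsed configuration: key/value pairs plus the config file's directory.

    File-path values (RAW_DATA, REF_MAP, RELATIONSHIPS) resolve relative to
    ``base_dir``.
    """

    values: Dict[str, str]
    base_dir: Path = field(default_factory=Path)

    @property
    def db_name(self) -> str:
        return self.values["DB_NAME"]

    def path(self, key: str) -> Path:
        return self.base_dir / self.values[key]

    @property
    def raw_data_path(self) -> Path:
        return self.path("RAW_DATA")

    @property
    def ref_map_path(self) -> Path:
        return self.path("REF_MAP")

    @property
    def relationships_path(self) -> Path:
        return self.path("RELATIONSHIPS")

    def __eq__(self, other) -> bool:
        if not isinstance(other, Config):
            return NotImplemented
        return self.values == other.values


def parse_config(path) -> Config:
    """Parse a configuration file of whitespace-separated key/value pairs."""
    values: Dict[str, str] = {}
    for lineno, line in enumerate(_read_lines(path), start=1):
        if not line.strip():
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise ParseError(
                f"expected KEY VALUE pair, got {line.strip()!r}", path, lineno
            )
        key, value = parts[0], parts[1].strip()
        if key in values:
            raise ValidationError(f"{path}: duplicate key {key!r}")
        values[key] = value
    for key in REQUIRED_CONFIG_KEYS:
        if key not in values:
            raise ValidationError(f"{path}: required key {key} absent")
    for key in values:
        if key not in REQUIRED_CONFIG_KEYS:
            log.warning("config %s: unknown key %r retained", path, key)
    return Config(values=values, base_dir=Path(path).resolve().parent)


def write_config(config: Config, path) -> None:
    lines = [f"{k}\t{v}" for k, v in config.values.items()]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
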