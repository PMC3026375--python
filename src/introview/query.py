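"""Include/exclude queries over a persistent introgression-block store.

A query term targets either a marker name (resolved to a point on the
reference map) or a chromosome interval in cM.  An *include* term matches
lines with a donor block whose marker-supported (inner) span overlaps the
closed query interval; an *exclude* term matches the complement.  Multiple
terms combine by conjunction.  Matching on the inner span is deliberate:
outer bounds are breakpoint estimates, and matching on them would claim
introgressions with no marker evidence inside the query region (an
``outer`` switch is available).

The store is a single SQLite file (the DB_NAME of the configuration file
plus the ``.iview`` suffix) holding the reference map, line roster and
block table; loading it reconstructs an index that answers queries
identically to the in-memory one.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from ._util import natural_key
from .caller import IntrogressionBlock, LibraryResult, MarkerCallState
from .errors import ValidationError
from .io import ReferenceMap, RefMarker

STORE_SUFFIX = ".iview"
_SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class QueryTerm:
    """One include/exclude search term.

    Either ``marker`` is set, or ``chromosome`` with ``start``/``end``
    (a point query has start == end).
    """

    mode: str  # "include" | "exclude"
    marker: Optional[str] = None
    chromosome: Optional[str] = None
    start: Optional[float] = None
    end: Optional[float] = None

    def __post_init__(self):
        if self.mode not in ("include", "exclude"):
            raise ValueError(f"bad query mode {self.mode!r}")
        if self.marker is None:
            if self.chromosome is None or self.start is None or self.end is None:
                raise ValueError("term needs a marker or chromosome+interval")
            if not (0 <= self.start <= self.end):
                raise ValueError(
                    f"bad interval [{self.start}, {self.end}]"
                )

    @classmethod
    def parse(cls, text: str, mode: str) -> "QueryTerm":
        """Parse CLI syntax: a marker name, ``CHR:POS`` or ``CHR:START-END``."""
        if ":" in text:
            chrom, _, span = text.partition(":")
            if "-" in span:
                lo, _, hi = span.partition("-")
                return cls(mode=mode, chromosome=chrom,
                           start=float(lo), end=float(hi))
            pos = float(span)
            return cls(mode=mode, chromosome=chrom, start=pos, end=pos)
        return cls(mode=mode, marker=text)


def marker_to_region(name: str, refmap: ReferenceMap) -> Tuple[str, float]:
    """Resolve a marker name to its (chromosome, position) point."""
    return refmap.lookup(name)  # raises ValidationError naming the marker


def resolve_term(term: QueryTerm,
                 refmap: ReferenceMap) -> Tuple[str, float, float]:
    if term.marker is not None:
        chrom, pos = marker_to_region(term.marker, refmap)
        return chrom, pos, pos
    return term.chromosome, term.start, term.end


def line_matches(blocks: Sequence[IntrogressionBlock], term: QueryTerm,
                 refmap: ReferenceMap, include_het: bool = False,
                 outer: bool = False) -> bool:
    """Does one line satisfy one term?"""
    chrom, start, end = resolve_term(term, refmap)
    states = {MarkerCallState.DONOR}
    if include_het:
        states.add(MarkerCallState.HET)
    hit = any(
        b.chromosome == chrom and b.state in states
        and b.overlaps(start, end, outer=outer)
        for b in blocks
    )
    return hit if term.mode == "include" else not hit


@dataclass
class QueryResult:
    """Lines matching every term, in natural order of their display names."""

    line_ids: List[str]
    names: Dict[str, str]
    matched_blocks: Dict[str, List[IntrogressionBlock]]


class BlockStore:
    """Queryable store of a called introgression library."""

    def __init__(self, refmap: ReferenceMap,
                 blocks: Dict[str, List[IntrogressionBlock]],
                 line_names: Dict[str, str],
                 line_groups: Optional[Dict[str, str]] = None,
                 db_name: str = "library"):
        self.refmap = refmap
        self.blocks = blocks
        self.line_names = line_names
        self.line_groups = line_groups or {}
        self.db_name = db_name

    @classmethod
    def from_library(cls, result: LibraryResult, refmap: ReferenceMap,
                     db_name: str = "library") -> "BlockStore":
        return cls(refmap=refmap, blocks=result.blocks,
                   line_names=result.line_names,
                   line_groups=result.line_groups, db_name=db_name)

    # -- querying ----------------------------------------------------------

    def run_query(self, terms: Sequence[QueryTerm],
                  include_het: bool = False,
                  outer: bool = False) -> QueryResult:
        if not terms:
            raise ValidationError("a query needs at least one term")
        hits = [
            line for line in self.blocks
            if all(
                line_matches(self.blocks[line], t, self.refmap,
                             include_het=include_het, outer=outer)
                for t in terms
            )
        ]
        hits.sort(key=lambda i: (natural_key(self.line_names.get(i, i)),
                                 natural_key(i)))
        include_regions = [
            resolve_term(t, self.refmap) for t in terms if t.mode == "include"
        ]
        states = {MarkerCallState.DONOR}
        if include_het:
            states.add(MarkerCallState.HET)
        matched = {
            line: [
                b for b in self.blocks[line]
                if b.state in states and any(
                    b.chromosome == c and b.overlaps(s, e, outer=outer)
                    for c, s, e in include_regions
                )
            ]
            for line in hits
        }
        return QueryResult(line_ids=hits,
                           names={i: self.line_names.get(i, i) for i in hits},
                           matched_blocks=matched)

    # -- persistence -------------------------------------------------------

    def save(self, path, overwrite: bool = False) -> Path:
        path = Path(path)
        if path.exists():
            if not overwrite:
                raise ValidationError(
                    f"store {path} already exists (use overwrite to replace)"
                )
            path.unlink()
        con = sqlite3.connect(path)
        try:
            cur = con.cursor()
            cur.execute("CREATE TABLE meta (key TEXT PRIMARY KEY, value TEXT)")
            cur.execute("CREATE TABLE map (name TEXT, chrom TEXT, pos REAL)")
            cur.execute(
                "CREATE TABLE lines (line_id TEXT PRIMARY KEY, name TEXT, "
                "grp TEXT)"
            )
            cur.execute(
                "CREATE TABLE blocks (line_id TEXT, chrom TEXT, state TEXT, "
                "inner_start REAL, inner_end REAL, outer_start REAL, "
                "outer_end REAL, support TEXT, left_flank TEXT, "
                "right_flank TEXT)"
            )
            cur.executemany("INSERT INTO meta VALUES (?, ?)", [
                ("schema_version", _SCHEMA_VERSION),
                ("db_name", self.db_name),
            ])
            cur.executemany(
                "INSERT INTO map VALUES (?, ?, ?)",
                [(m.name, m.chromosome, m.position) for m in self.refmap],
            )
            cur.executemany(
                "INSERT INTO lines VALUES (?, ?, ?)",
                [(i, self.line_names.get(i, i), self.line_groups.get(i, ""))
                 for i in sorted(self.blocks, key=natural_key)],
            )
            rows = []
            for line in sorted(self.blocks, key=natural_key):
                for b in self.blocks[line]:
                    rows.append((
                        b.line_id, b.chromosome, b.state.value,
                        b.inner_start, b.inner_end, b.outer_start, b.outer_end,
                        ",".join(b.support_markers),
                        b.left_flank or "", b.right_flank or "",
                    ))
            cur.executemany(
                "INSERT INTO blocks VALUES (?, ?, ?, ?, ?, ?, ?, ?, ?, ?)",
                rows,
            )
            con.commit()
        finally:
            con.close()
        return path

    @classmethod
    def load(cls, path) -> "BlockStore":
        path = Path(path)
        if not path.exists():
            raise ValidationError(f"store {path} does not exist")
        con = sqlite3.connect(path)
        try:
            meta = dict(con.execute("SELECT key, value FROM meta"))
            markers = [
                RefMarker(name, chrom, pos)
                for name, chrom, pos in con.execute(
                    "SELECT name, chrom, pos FROM map"
                )
            ]
            refmap = ReferenceMap(markers)
            names, groups = {}, {}
            blocks: Dict[str, List[IntrogressionBlock]] = {}
            for line_id, name, grp in con.execute(
                "SELECT line_id, name, grp FROM lines"
            ):
                names[line_id] = name
                groups[line_id] = grp
                blocks[line_id] = []
            for row in con.execute(
                "SELECT line_id, chrom, state, inner_start, inner_end, "
                "outer_start, outer_end, support, left_flank, right_flank "
                "FROM blocks"
            ):
                (line_id, chrom, state, i0, i1, o0, o1, support, lf, rf) = row
                blocks.setdefault(line_id, []).append(IntrogressionBlock(
                    line_id=line_id, chromosome=chrom,
                    state=MarkerCallState(state),
                    inner_start=i0, inner_end=i1,
                    outer_start=o0, outer_end=o1,
                    support_markers=tuple(support.split(",")) if support else (),
                    left_flank=lf or None, right_flank=rf or None,
                ))
        finally:
            con.close()
        return cls(refmap=refmap, blocks=blocks, line_names=names,
                   line_groups=groups, db_name=meta.get("db_name", "library"))


def store_path(directory, db_name: str) -> Path:
    """Conventional store filename for a DB_NAME."""
    return Path(directory) / f"{db_name}{STORE_SUFFIX}"
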