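"""Independent reference implementations used to cross-check the package.

These are deliberately written in a different style from the library code
(plain strings, explicit scans) so a shared bug is unlikely.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple


def oracle_classify(g: Optional[str], r: Optional[str],
                    d: Optional[str]) -> str:
    """Brute-force marker classification on plain allele-pair strings.

    ``None`` encodes a missing call; strings are unordered allele pairs.
    """
    def norm(x):
        return None if x is None else "".join(sorted(x))

    g, r, d = norm(g), norm(r), norm(d)
    informative = (
        r is not None and d is not None
        and r[0] == r[1] and d[0] == d[1] and r != d
    )
    if not informative:
        return "UNINFORMATIVE"
    if g is None:
        return "MISSING"
    if g == r:
        return "RECURRENT"
    if g == d:
        return "DONOR"
    if norm(r[0] + d[0]) == g:
        return "HET"
    return "NON_PARENTAL"


def oracle_segment(states: Sequence[str], positions: Sequence[float],
                   min_markers: int = 1) -> List[dict]:
    """Reference segmentation by explicit index scanning on one chromosome.

    For each introgressed state, consecutive supporting indices belong to
    the same block unless a breaker (RECURRENT or the other introgressed
    state) lies between them.  Bounds/flanks are recomputed by scanning
    outward from each block.
    """
    n = len(states)
    blocks = []
    for state in ("DONOR", "HET"):
        other = "HET" if state == "DONOR" else "DONOR"
        breakers = {"RECURRENT", other}
        idx = [i for i in range(n) if states[i] == state]
        groups: List[List[int]] = []
        for i in idx:
            if groups and not any(
                states[k] in breakers for k in range(groups[-1][-1] + 1, i)
            ):
                groups[-1].append(i)
            else:
                groups.append([i])
        for grp in groups:
            if len(grp) < min_markers:
                continue
            first, last = grp[0], grp[-1]
            left = next(
                (k for k in range(first - 1, -1, -1)
                 if states[k] == "RECURRENT"), None
            )
            right = next(
                (k for k in range(last + 1, n)
                 if states[k] == "RECURRENT"), None
            )
            inner_start, inner_end = positions[first], positions[last]
            outer_start = (
                (positions[left] + inner_start) / 2 if left is not None
                else positions[0]
            )
            outer_end = (
                (positions[right] + inner_end) / 2 if right is not None
                else positions[-1]
            )
            blocks.append({
                "state": state,
                "inner_start": inner_start,
                "inner_end": inner_end,
                "outer_start": outer_start,
                "outer_end": outer_end,
                "support": tuple(grp),
                "left_flank": left,
                "right_flank": right,
            })
    blocks.sort(key=lambda b: b["inner_start"])
    return blocks


def oracle_query(line_blocks: dict, terms: Sequence[Tuple[str, str, float, float]],
                 include_het: bool = False) -> List[str]:
    """Brute-force conjunctive query over {line: [(chrom, state, lo, hi)]}.

    Terms are (mode, chromosome, start, end) with resolved coordinates.
    """
    states = {"DONOR", "HET"} if include_het else {"DONOR"}
    hits = []
    for line, blocks in line_blocks.items():
        ok = True
        for mode, chrom, start, end in terms:
            found = False
            for (c, st, lo, hi) in blocks:
                if c == chrom and st in states and lo <= end and hi >= start:
                    found = True
            if (mode == "include") != found:
                ok = False
        if ok:
            hits.append(line)
    return sorted(hits)
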