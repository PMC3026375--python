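"""Graphical genotypes: chromosome ideograms, block tables, HTML reports.

Each line is drawn as one horizontal bar per chromosome, spanning the
first to last mapped marker (genetic maps carry no telomere information).
Donor and heterozygous blocks are overlaid in color: the *outer* span
(estimated extent toward flanking recurrent evidence) at reduced opacity,
the *inner* marker-supported span at full saturation.  Figures are SVG so
tests and users can assert on document structure; a raster (PNG) export
draws the same layout with Pillow.  All outputs are deterministic: no
timestamps, fixed float formatting.
"""

from __future__ import annotations

import html
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from ._util import natural_key
from .caller import IntrogressionBlock, MarkerCallState
from .errors import ValidationError
from .io import ReferenceMap
from .query import BlockStore, QueryResult

DEFAULT_COLORS = {
    "recurrent": "#d9d9d9",  # light gray background
    "donor": "#d7301f",      # red
    "het": "#fc8d59",        # orange
    "outline": "#000000",
}


@dataclass
class RenderSpec:
    """Geometry and palette for ideogram rendering."""

    width: int = 800
    bar_height: int = 18
    row_gap: int = 16
    margin_left: int = 70
    margin_right: int = 20
    margin_top: int = 36
    px_per_cm: Optional[float] = None  # derived from width when None
    colors: Dict[str, str] = field(default_factory=lambda: dict(DEFAULT_COLORS))

    def __post_init__(self):
        if self.px_per_cm is not None and self.px_per_cm <= 0:
            raise ValidationError("px_per_cm must be positive")
        for key in DEFAULT_COLORS:
            if key not in self.colors:
                raise ValidationError(f"missing color for {key!r}")
        fills = [self.colors[k] for k in ("recurrent", "donor", "het")]
        if len(set(fills)) != len(fills):
            raise ValidationError("state colors must be distinct")

    def color_for(self, state: MarkerCallState) -> str:
        return self.colors["donor" if state is MarkerCallState.DONOR
                           else "het"]


def chromosome_transforms(refmap: ReferenceMap,
                          spec: RenderSpec) -> Dict[str, Tuple[float, float]]:
    """Per-chromosome affine cM->px transform: ``px = offset + cm * scale``.

    All chromosomes share one scale so bar lengths are comparable; it is
    either the explicit ``px_per_cm`` or fitted so the longest chromosome
    fills the drawable width.
    """
    spans = {c: refmap.span(c) for c in refmap.chromosomes}
    if spec.px_per_cm is not None:
        scale = spec.px_per_cm
    else:
        widest = max((hi - lo) for lo, hi in spans.values())
        drawable = spec.width - spec.margin_left - spec.margin_right
        scale = drawable / widest if widest > 0 else 1.0
    return {
        c: (spec.margin_left - spans[c][0] * scale, scale)
        for c in refmap.chromosomes
    }


def _fmt(x: float) -> str:
    return f"{x:.2f}".rstrip("0").rstrip(".")


def render_line_figure(blocks: Sequence[IntrogressionBlock],
                       refmap: ReferenceMap, spec: RenderSpec,
                       title: str = "") -> str:
    """Render one line's graphical genotype as an SVG document string."""
    transforms = chromosome_transforms(refmap, spec)
    row_h = spec.bar_height + spec.row_gap
    n_rows = len(refmap.chromosomes)
    legend_y = spec.margin_top + n_rows * row_h + 10
    height = legend_y + 3 * 22 + 10

    parts: List[str] = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{spec.width}" '
        f'height="{height}" viewBox="0 0 {spec.width} {height}">',
        f'<text x="{spec.margin_left}" y="20" font-family="sans-serif" '
        f'font-size="14" font-weight="bold">{html.escape(title)}</text>',
    ]
    by_chrom: Dict[str, List[IntrogressionBlock]] = {}
    for b in blocks:
        by_chrom.setdefault(b.chromosome, []).append(b)

    for row, chrom in enumerate(refmap.chromosomes):
        offset, scale = transforms[chrom]
        lo, hi = refmap.span(chrom)
        y = spec.margin_top + row * row_h
        x0, x1 = offset + lo * scale, offset + hi * scale
        parts.append(
            f'<text x="{spec.margin_left - 8}" y="{y + spec.bar_height - 4}" '
            f'font-family="sans-serif" font-size="12" text-anchor="end">'
            f'{html.escape(chrom)}</text>'
        )
        parts.append(
            f'<rect class="chrom" x="{_fmt(x0)}" y="{y}" '
            f'width="{_fmt(max(x1 - x0, 1.0))}" height="{spec.bar_height}" '
            f'fill="{spec.colors["recurrent"]}" '
            f'stroke="{spec.colors["outline"]}" stroke-width="1"/>'
        )
        for b in sorted(by_chrom.get(chrom, []), key=lambda b: b.inner_start):
            color = spec.color_for(b.state)
            ox0 = offset + b.outer_start * scale
            ox1 = offset + b.outer_end * scale
            ix0 = offset + b.inner_start * scale
            ix1 = offset + b.inner_end * scale
            parts.append(
                f'<rect class="block-outer" x="{_fmt(ox0)}" y="{y}" '
                f'width="{_fmt(max(ox1 - ox0, 1.0))}" '
                f'height="{spec.bar_height}" fill="{color}" '
                f'fill-opacity="0.45"/>'
            )
            parts.append(
                f'<rect class="block-inner" x="{_fmt(ix0)}" y="{y}" '
                f'width="{_fmt(max(ix1 - ix0, 1.0))}" '
                f'height="{spec.bar_height}" fill="{color}"/>'
            )
    # legend
    entries = [
        ("recurrent parent", spec.colors["recurrent"]),
        ("donor introgression", spec.colors["donor"]),
        ("heterozygous region", spec.colors["het"]),
    ]
    for i, (label, color) in enumerate(entries):
        y = legend_y + i * 22
        parts.append(
            f'<rect class="legend" x="{spec.margin_left}" y="{y}" width="16" '
            f'height="16" fill="{color}" stroke="{spec.colors["outline"]}"/>'
        )
        parts.append(
            f'<text x="{spec.margin_left + 24}" y="{y + 13}" '
            f'font-family="sans-serif" font-size="12">{label}</text>'
        )
    parts.append("</svg>")
    return "\n".join(parts) + "\n"


TABLE_COLUMNS = [
    "chromosome", "state", "inner_start", "inner_end",
    "outer_start", "outer_end", "n_support", "support_markers",
    "left_flank", "right_flank",
]


def line_summary_table(blocks: Sequence[IntrogressionBlock]) -> pd.DataFrame:
    """One row per block, sorted by (chromosome, inner_start)."""
    rows = [{
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
    } for b in sorted(
        blocks, key=lambda b: (natural_key(b.chromosome), b.inner_start)
    )]
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def render_line_png(blocks: Sequence[IntrogressionBlock],
                    refmap: ReferenceMap, spec: RenderSpec, path) -> None:
    """Raster export of the same layout as the SVG figure."""
    from PIL import Image, ImageDraw

    transforms = chromosome_transforms(refmap, spec)
    row_h = spec.bar_height + spec.row_gap
    height = spec.margin_top + len(refmap.chromosomes) * row_h + 20
    img = Image.new("RGB", (spec.width, height), "#ffffff")
    draw = ImageDraw.Draw(img)
    by_chrom: Dict[str, List[IntrogressionBlock]] = {}
    for b in blocks:
        by_chrom.setdefault(b.chromosome, []).append(b)
    for row, chrom in enumerate(refmap.chromosomes):
        offset, scale = transforms[chrom]
        lo, hi = refmap.span(chrom)
        y = spec.margin_top + row * row_h
        draw.rectangle(
            [offset + lo * scale, y, offset + hi * scale, y + spec.bar_height],
            fill=spec.colors["recurrent"], outline=spec.colors["outline"],
        )
        for b in by_chrom.get(chrom, []):
            draw.rectangle(
                [offset + b.inner_start * scale, y,
                 max(offset + b.inner_end * scale,
                     offset + b.inner_start * scale + 1), y + spec.bar_height],
                fill=spec.color_for(b.state),
            )
    img.save(path, format="PNG")


# ---------------------------------------------------------------------------
# static HTML report


_PAGE = """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>{title}</title>
<style>
body {{ font-family: sans-serif; margin: 2em; }}
table {{ border-collapse: collapse; }}
th, td {{ border: 1px solid #999; padding: 4px 8px; font-size: 13px; }}
th {{ background: #eee; }}
</style>
</head>
<body>
{body}
</body>
</html>
"""


def _table_html(frame: pd.DataFrame) -> str:
    head = "".join(f"<th>{html.escape(c)}</th>" for c in frame.columns)
    rows = []
    for _, row in frame.iterrows():
        cells = "".join(
            f"<td>{html.escape(_fmt(v) if isinstance(v, float) else str(v))}"
            f"</td>"
            for v in row
        )
        rows.append(f"<tr>{cells}</tr>")
    return (
        f"<table><thead><tr>{head}</tr></thead>"
        f"<tbody>{''.join(rows)}</tbody></table>"
    )


def write_html_report(store: BlockStore, out_dir,
                      result: Optional[QueryResult] = None,
                      spec: Optional[RenderSpec] = None) -> List[Path]:
    """Write a self-contained static report: an index plus one page per line.

    With a ``result``, only matching lines are listed (a query-filtered
    report); otherwise the whole library is rendered.
    """
    spec = spec or RenderSpec()
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ValidationError(f"cannot create output directory: {exc}")

    if result is not None:
        line_ids = result.line_ids
    else:
        line_ids = sorted(
            store.blocks,
            key=lambda i: (natural_key(store.line_names.get(i, i)),
                           natural_key(i)),
        )

    written: List[Path] = []
    items = []
    for line_id in line_ids:
        name = store.line_names.get(line_id, line_id)
        page = f"line_{line_id}.html"
        items.append(
            f'<li><a href="{html.escape(page)}">{html.escape(name)}</a> '
            f'({len(store.blocks[line_id])} block(s))</li>'
        )
        svg = render_line_figure(
            store.blocks[line_id], store.refmap, spec,
            title=f"{name} introgression summary",
        )
        table = line_summary_table(store.blocks[line_id])
        body = (
            f"<h1>{html.escape(name)} — introgression summary</h1>\n"
            f'<p><a href="index.html">Back to index</a></p>\n'
            f"{svg}\n<h2>Blocks</h2>\n{_table_html(table)}"
        )
        path = out_dir / page
        path.write_text(_PAGE.format(title=html.escape(name), body=body),
                        encoding="utf-8")
        written.append(path)

    body = (
        f"<h1>Introgression library: {html.escape(store.db_name)}</h1>\n"
        f"<p>{len(line_ids)} line(s)</p>\n<ul>\n"
        + "\n".join(items) + "\n</ul>"
    )
    index = out_dir / "index.html"
    index.write_text(
        _PAGE.format(title=html.escape(store.db_name), body=body),
        encoding="utf-8",
    )
    written.insert(0, index)
    return written
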