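"""Motif-composition figure and color/frequency table.

Each allele is drawn as one horizontal band of colored cells, one cell per
non-gap alignment column, motif position increasing left to right; gaps are
empty space.  Every motif symbol receives a distinct, deterministic color
(evenly spaced HSV hues at fixed saturation/value, assigned by symbol
rank); the private symbol is grey.  SVG is the default, machine-checkable
output (band and cell counts are recoverable from element classes); PNG and
PDF are rasterized with matplotlib.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field
from pathlib import Path
from xml.sax.saxutils import escape

from .align import EncodedAlignment
from .encode import GAP_SYMBOL, MotifMapping
from .rearrange import RowOrder

__all__ = [
    "RenderSpec",
    "PRIVATE_COLOR",
    "assign_colors",
    "render_plot",
    "write_motif_table",
]

PRIVATE_COLOR = "#808080"

_CELL_W = 14
_CELL_H = 14
_ROW_GAP = 2
_LABEL_W = 110
_GROUP_W = 10
_MARGIN = 8

# distinct colors for the small, fixed set of group labels commonly used
_GROUP_PALETTE = [
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
    "#8c564b", "#e377c2", "#17becf", "#bcbd22", "#7f7f7f",
]


def _hsv_hex(h: float, s: float = 0.65, v: float = 0.90) -> str:
    r, g, b = colorsys.hsv_to_rgb(h % 1.0, s, v)
    return "#{:02x}{:02x}{:02x}".format(
        round(r * 255), round(g * 255), round(b * 255)
    )


def assign_colors(mapping: MotifMapping) -> dict[str, str]:
    """Deterministic symbol -> hex color map.

    Hues are spaced evenly over the color wheel in symbol-rank order, so
    the most frequent motifs get maximally separated colors; the private
    symbol is always grey.  Stable across runs for the same mapping.
    """
    symbols = mapping.symbols
    n = len(symbols)
    colors: dict[str, str] = {}
    used = {PRIVATE_COLOR}
    for i, sym in enumerate(symbols):
        c = _hsv_hex(i / max(n, 1))
        v = 0.90
        while c in used:  # nudge value on the rare rounding collision
            v -= 0.03
            c = _hsv_hex(i / max(n, 1), v=v)
        colors[sym] = c
        used.add(c)
    if mapping.has_private:
        colors[mapping.private_symbol] = PRIVATE_COLOR
    return colors


@dataclass
class RenderSpec:
    """Everything the plot needs besides the alignment itself."""

    colors: dict[str, str]
    order: RowOrder | None = None
    annotations: dict[str, str] = field(default_factory=dict)
    legend: list[tuple[str, str, int]] = field(default_factory=list)
    gap_style: str = "blank"  # gaps are empty space
    fmt: str = "svg"  # svg | png | pdf

    @classmethod
    def from_mapping(cls, mapping: MotifMapping, **kwargs) -> "RenderSpec":
        """Build a spec with colors and legend derived from a mapping."""
        legend = [(s, m, c) for m, s, c in mapping.entries]
        if mapping.has_private:
            legend.append(
                (
                    mapping.private_symbol,
                    "private",
                    sum(mapping.private_motifs.values()),
                )
            )
        return cls(colors=assign_colors(mapping), legend=legend, **kwargs)


def _group_colors(annotations: dict[str, str]) -> dict[str, str]:
    groups = sorted(set(annotations.values()))
    return {
        g: _GROUP_PALETTE[i % len(_GROUP_PALETTE)] for i, g in enumerate(groups)
    }


def _layout(alignment: EncodedAlignment, order, n_legend: int = 0):
    ids = list(order) if order is not None else alignment.ids
    width = alignment.width
    w = _MARGIN * 2 + _LABEL_W + _GROUP_W + 4 + width * _CELL_W
    h = _MARGIN * 2 + len(ids) * (_CELL_H + _ROW_GAP)
    if n_legend:
        h += 10 + n_legend * (_CELL_H + _ROW_GAP)
    return ids, w, h


def _render_svg(alignment, ids, spec, path):
    gcolors = _group_colors(spec.annotations) if spec.annotations else {}
    _, w, h = _layout(alignment, ids, len(spec.legend))
    x0 = _MARGIN + _LABEL_W + _GROUP_W + 4
    out = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{w}" height="{h}" '
        f'viewBox="0 0 {w} {h}">',
        f'<rect class="background" x="0" y="0" width="{w}" height="{h}" '
        'fill="white"/>',
    ]
    for r, rid in enumerate(ids):
        y = _MARGIN + r * (_CELL_H + _ROW_GAP)
        row = alignment.row(rid)
        out.append(f'<g class="allele-band" data-allele="{escape(rid)}">')
        out.append(
            f'<text class="allele-label" x="{_MARGIN + _LABEL_W - 4}" '
            f'y="{y + _CELL_H - 3}" text-anchor="end" '
            f'font-family="monospace" font-size="10">{escape(rid)}</text>'
        )
        if rid in spec.annotations:
            gc = gcolors[spec.annotations[rid]]
            out.append(
                f'<rect class="group-label" x="{_MARGIN + _LABEL_W}" '
                f'y="{y}" width="{_GROUP_W}" height="{_CELL_H}" '
                f'fill="{gc}"/>'
            )
        for k, sym in enumerate(row):
            if sym == GAP_SYMBOL:
                continue
            out.append(
                f'<rect class="motif-cell" x="{x0 + k * _CELL_W}" y="{y}" '
                f'width="{_CELL_W}" height="{_CELL_H}" '
                f'fill="{spec.colors[sym]}" stroke="white" '
                'stroke-width="0.5"/>'
            )
        out.append("</g>")
    if spec.legend:
        y0 = _MARGIN + len(ids) * (_CELL_H + _ROW_GAP) + 10
        out.append('<g class="legend">')
        for r, (sym, motif, count) in enumerate(spec.legend):
            y = y0 + r * (_CELL_H + _ROW_GAP)
            fill = spec.colors.get(sym, PRIVATE_COLOR)
            out.append(
                f'<rect class="legend-swatch" x="{_MARGIN}" y="{y}" '
                f'width="{_CELL_W}" height="{_CELL_H}" fill="{fill}"/>'
            )
            out.append(
                f'<text class="legend-label" x="{_MARGIN + _CELL_W + 6}" '
                f'y="{y + _CELL_H - 3}" font-family="monospace" '
                f'font-size="10">{escape(sym)} {escape(motif)} '
                f'(n={count})</text>'
            )
        out.append("</g>")
    out.append("</svg>")
    Path(path).write_text("\n".join(out) + "\n")


def _render_matplotlib(alignment, ids, spec, path, fmt):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    gcolors = _group_colors(spec.annotations) if spec.annotations else {}
    width = alignment.width
    nrow = len(ids)
    fig, ax = plt.subplots(
        figsize=(max(4.0, width * 0.18 + 1.8), max(2.0, nrow * 0.22))
    )
    for r, rid in enumerate(ids):
        y = nrow - 1 - r
        row = alignment.row(rid)
        if rid in spec.annotations:
            ax.add_patch(
                Rectangle(
                    (-0.9, y), 0.6, 0.9,
                    facecolor=gcolors[spec.annotations[rid]],
                    edgecolor="none",
                )
            )
        for k, sym in enumerate(row):
            if sym == GAP_SYMBOL:
                continue
            ax.add_patch(
                Rectangle(
                    (k, y), 1, 0.9,
                    facecolor=spec.colors[sym],
                    edgecolor="white", linewidth=0.3,
                )
            )
    ax.set_xlim(-1.2, width + 0.2)
    ax.set_ylim(-0.2, nrow + 0.2)
    ax.set_yticks([nrow - 1 - r + 0.45 for r in range(nrow)])
    ax.set_yticklabels(ids, fontsize=6, family="monospace")
    ax.set_xlabel("motif position")
    ax.set_xticks([])
    for spine in ax.spines.values():
        spine.set_visible(False)
    fig.tight_layout()
    fig.savefig(path, format=fmt, dpi=150)
    plt.close(fig)


def render_plot(
    alignment: EncodedAlignment,
    order: RowOrder | None,
    spec: RenderSpec,
    path,
) -> Path:
    """Write the motif-composition figure; returns the output path.

    One band per allele in the given order (alignment order when ``order``
    is None); every non-gap column becomes a colored cell; gaps are left
    blank.  The format is taken from ``spec.fmt`` (svg, png or pdf).
    """
    path = Path(path)
    ids, _, _ = _layout(alignment, order)
    missing = sorted(set(alignment.ids) - set(ids))
    if order is not None and missing:
        raise ValueError(f"order does not cover alleles {missing}")
    present = {
        s for _, row in alignment.rows for s in row if s != GAP_SYMBOL
    }
    uncolored = sorted(present - set(spec.colors))
    if uncolored:
        raise ValueError(f"no color assigned for symbols {uncolored}")
    fmt = spec.fmt.lower()
    if fmt == "svg":
        _render_svg(alignment, ids, spec, path)
    elif fmt in ("png", "pdf"):
        _render_matplotlib(alignment, ids, spec, path, fmt)
    else:
        raise ValueError(f"unknown output format {spec.fmt!r}")
    return path


def write_motif_table(
    mapping: MotifMapping, colors: dict[str, str], path
) -> None:
    """Legend table as TSV: symbol, motif, count, color hex."""
    with open(path, "w") as fh:
        fh.write("symbol\tmotif\tcount\tcolor\n")
        for m, s, c in mapping.entries:
            fh.write(f"{s}\t{m}\t{c}\t{colors[s]}\n")
        for m in sorted(mapping.private_motifs):
            fh.write(
                f"{mapping.private_symbol}\t{m}\t"
                f"{mapping.private_motifs[m]}\t"
                f"{colors.get(mapping.private_symbol, PRIVATE_COLOR)}\n"
            )
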