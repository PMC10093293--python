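"""Schematic splicing/backsplicing profile rendering (SVG).

The profile draws the gene as a row of exon boxes on a baseline, in
ordinal order (alternative-boundary exons unnumbered), with one arc per
junction: linear splice junctions in green above the baseline,
backsplice junctions in red below, and intronic-control signals as blue
ticks.  Arc apex heights map distinct-UMI counts through a square-root
scale by default, so a 4x difference in UMIs reads as a 2x height
difference.  Output is deterministic: fixed ordering, no timestamps.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd

from .junctions import LINEAR_CLASSES
from .panel import ProbePanel

EXON_W = 36.0
EXON_H = 22.0
GAP = 14.0
MARGIN = 30.0
MAX_ARC = 110.0
LINEAR_COLOR = "#2e8b57"
CIRC_COLOR = "#c0392b"
INTRONIC_COLOR = "#2a6fb0"


def _scale_height(umi: float, umi_max: float, scale: str) -> float:
    if umi_max <= 0:
        return 0.0
    if scale == "sqrt":
        return MAX_ARC * math.sqrt(umi / umi_max)
    if scale == "linear":
        return MAX_ARC * umi / umi_max
    if scale == "log":
        return MAX_ARC * math.log1p(umi) / math.log1p(umi_max)
    raise ValueError(f"unknown scale {scale!r}")


def render_profile(
    classified: pd.DataFrame,
    panel: ProbePanel,
    sample: str,
    gene: str,
    out: str | Path | None = None,
    scale: str = "sqrt",
    display_threshold: float = 0.001,
) -> tuple[str, pd.DataFrame]:
    """Render one sample-gene profile; returns (svg text, suppressed arcs).

    ``display_threshold`` suppresses junctions below that fraction of the
    mean canonical-junction UMI count (set 0 to draw everything);
    suppressed junctions are returned in the sidecar table, never
    dropped silently.  Writing ``out`` also writes ``<out>.suppressed.tsv``.
    """
    if gene not in panel.genes:
        raise ValueError(f"unknown gene {gene!r}")
    grp = classified[(classified["sample"] == sample) & (classified["gene"] == gene)]

    exons = sorted((e for e in panel.exons if e.gene == gene), key=lambda e: e.ordinal)
    x_of = {}
    for i, exon in enumerate(exons):
        x_of[exon.label] = MARGIN + i * (EXON_W + GAP)
    baseline = MAX_ARC + 40.0
    width = MARGIN * 2 + len(exons) * (EXON_W + GAP)
    height = baseline + EXON_H + MAX_ARC + 60.0

    junction_rows = grp[grp["class"].isin([*LINEAR_CLASSES, "backsplice"])]
    n_canonical = len(panel.canonical_junctions.get(gene, []))
    canonical_umi = junction_rows.loc[
        junction_rows["class"] == "linear_canonical", "umi_count"
    ].sum()
    mean_canonical = canonical_umi / n_canonical if n_canonical else 0.0
    floor = display_threshold * mean_canonical

    drawn = junction_rows[junction_rows["umi_count"] >= floor]
    suppressed = junction_rows[junction_rows["umi_count"] < floor][
        ["name", "class", "umi_count"]
    ].sort_values("name").reset_index(drop=True)
    umi_max = float(drawn["umi_count"].max()) if len(drawn) else 0.0

    parts: list[str] = []
    parts.append(
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width:.0f}" '
        f'height="{height:.0f}" viewBox="0 0 {width:.0f} {height:.0f}">'
    )
    parts.append(
        f'<text x="{MARGIN}" y="18" font-family="sans-serif" font-size="13">'
        f"{gene} — {sample}</text>"
    )
    # legend
    parts.append(
        f'<text x="{MARGIN}" y="34" font-family="sans-serif" font-size="10">'
        f'<tspan fill="{LINEAR_COLOR}">splicing</tspan> / '
        f'<tspan fill="{CIRC_COLOR}">backsplicing</tspan> / '
        f'<tspan fill="{INTRONIC_COLOR}">intronic</tspan></text>'
    )
    # intron line
    parts.append(
        f'<line x1="{MARGIN}" y1="{baseline + EXON_H / 2:.1f}" '
        f'x2="{width - MARGIN}" y2="{baseline + EXON_H / 2:.1f}" '
        'stroke="#555" stroke-width="1"/>'
    )
    # exon boxes (alternative exons drawn but unnumbered)
    for exon in exons:
        x = x_of[exon.label]
        parts.append(
            f'<rect x="{x:.1f}" y="{baseline:.1f}" width="{EXON_W}" height="{EXON_H}" '
            'fill="#dfe6ee" stroke="#333"/>'
        )
        if exon.in_canonical:
            parts.append(
                f'<text x="{x + EXON_W / 2:.1f}" y="{baseline + EXON_H - 6:.1f}" '
                'font-family="sans-serif" font-size="10" text-anchor="middle">'
                f"{exon.label}</text>"
            )

    def _arc(donor: str, acceptor: str, umi: int, cls: str, name: str) -> str:
        h = _scale_height(umi, umi_max, scale)
        if cls == "backsplice":
            x1 = x_of[donor] + EXON_W  # leaves the donor's 3' boundary
            x2 = x_of[acceptor]
            y0 = baseline + EXON_H
            apex = y0 + h
            color = CIRC_COLOR
        else:
            x1 = x_of[donor] + EXON_W
            x2 = x_of[acceptor]
            y0 = baseline
            apex = y0 - h
            color = LINEAR_COLOR
        mid = (x1 + x2) / 2
        return (
            f'<path d="M {x1:.1f} {y0:.1f} Q {mid:.1f} {apex:.1f} {x2:.1f} {y0:.1f}" '
            f'fill="none" stroke="{color}" stroke-width="1.5">'
            f"<title>{name}: {umi} UMIs</title></path>"
        )

    for _, r in drawn.sort_values(["class", "name"]).iterrows():
        parts.append(_arc(r["donor"], r["acceptor"], int(r["umi_count"]), r["class"], r["name"]))

    # intronic-control ticks at the right edge of the gene track
    intronic = grp[grp["class"] == "intronic_control"].sort_values("name")
    for i, (_, r) in enumerate(intronic.iterrows()):
        x = width - MARGIN + 4
        h = _scale_height(int(r["umi_count"]), umi_max or int(r["umi_count"]), scale)
        parts.append(
            f'<line x1="{x + i * 5:.1f}" y1="{baseline:.1f}" x2="{x + i * 5:.1f}" '
            f'y2="{baseline - h:.1f}" stroke="{INTRONIC_COLOR}" stroke-width="3">'
            f'<title>{r["name"]}: {int(r["umi_count"])} UMIs</title></line>'
        )

    parts.append("</svg>")
    svg = "\n".join(parts) + "\n"
    if out is not None:
        out = Path(out)
        out.write_text(svg)
        suppressed.to_csv(out.with_suffix(out.suffix + ".suppressed.tsv"), sep="\t", index=False)
    return svg, suppressed
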