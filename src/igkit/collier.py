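"""Collier de Perles layout and SVG rendering.

The Collier de Perles ("necklace of pearls") draws every IMGT position of
a numbered domain as a pearl on a serpentine path, one pearl per
canonical position -- occupied pearls carry the residue letter, gap
positions are hatched.  The one-layer form follows the sequence; the
two-layer form mirrors the 3D sandwich: for a V domain the
G-F-C-C'-C'' sheet in front and A-B-E-D behind, for a C domain G-F-C in
front and A-B-E-D behind joined by the transversal CD strand.

Anchors render as squares; CDR pearls take the loop palette (which
differs between V-D-J and V-J rearrangement products), hydrophobic
residues (and W) and prolines take their conventional highlight classes.
Layouts are pure functions of the numbered domain, and the SVG writer is
deterministic: identical layouts give byte-identical documents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .aa_properties import HYDROPHOBIC_SET
from .numbering import ImgtPosition, NumberedDomain

__all__ = [
    "PerleGlyph",
    "PerleLayout",
    "layout_domain",
    "render_svg",
]

# strand order along the serpentine, per layer
_V_FRONT = ("G", "F", "C", "C'", "C''")
_V_BACK = ("A", "B", "E", "D")
_C_FRONT = ("G", "F", "C")
_C_BACK = ("A", "B", "E", "D")

_CDR_SEGMENTS = {"BC": "cdr1", "C'C''": "cdr2", "FG": "cdr3"}


@dataclass(frozen=True)
class PerleGlyph:
    position: ImgtPosition
    aa: str | None              # None -> hatched gap pearl
    x: float
    y: float
    shape: str                  # "circle" | "square"
    fill_class: str             # cdr1|cdr2|cdr3|hydrophobic|proline|plain|gap


@dataclass(frozen=True)
class PerleLayout:
    domain_kind: str
    layers: int
    rearrangement: str          # "V-D-J" | "V-J" | "none"
    glyphs: tuple
    bonds: tuple = ()           # optional (position, position) overlays

    def glyph_at(self, position: ImgtPosition) -> PerleGlyph | None:
        for g in self.glyphs:
            if g.position == position:
                return g
        return None


def _fill_class(aa: str | None, segment: str, domain_kind: str) -> str:
    if aa is None:
        return "gap"
    if domain_kind == "V" and segment in _CDR_SEGMENTS:
        return _CDR_SEGMENTS[segment]
    if aa == "P":
        return "proline"
    if aa in HYDROPHOBIC_SET or aa == "W":
        return "hydrophobic"
    return "plain"


def layout_domain(domain: NumberedDomain, layers: int = 1,
                  rearrangement: str | None = None,
                  bonds=()) -> PerleLayout:
    """Compute pearl coordinates for a numbered domain.

    Coordinates are abstract grid units; the tested contract is strand
    membership and pearl order, not absolute geometry.  ``rearrangement``
    selects the CDR palette variant ("V-D-J" or "V-J"); it defaults to
    V-D-J for V domains.  Hydrogen-bond / disulfide overlays are accepted
    as data via ``bonds`` and never computed.
    """
    if domain.domain_kind not in ("V", "C"):
        raise ValueError(f"unknown domain kind {domain.domain_kind!r}")
    if layers not in (1, 2):
        raise ValueError("layers must be 1 or 2")
    if rearrangement is None:
        rearrangement = "V-D-J" if domain.domain_kind == "V" else "none"

    occupied = {r.position: r for r in domain.residues}
    all_positions = sorted(set(occupied) | set(domain.gaps))
    seg_of = {}
    for p in all_positions:
        if p in occupied:
            seg_of[p] = occupied[p].segment
        else:
            seg_of[p] = _segment_of_gap(domain, p)

    if layers == 1:
        coords = _serpentine(all_positions, seg_of, column=0.0)
    else:
        front, back = ((_V_FRONT, _V_BACK) if domain.domain_kind == "V"
                       else (_C_FRONT, _C_BACK))
        coords = {}
        front_pos = [p for p in all_positions
                     if _sheet_strand(seg_of[p]) in front]
        back_pos = [p for p in all_positions
                    if _sheet_strand(seg_of[p]) in back]
        other = [p for p in all_positions
                 if p not in set(front_pos) | set(back_pos)]
        coords.update(_serpentine(front_pos, seg_of, column=0.0))
        coords.update(_serpentine(back_pos, seg_of, column=12.0))
        coords.update(_serpentine(other, seg_of, column=24.0))

    anchors = {r.position for r in domain.residues if r.anchor}
    glyphs = []
    for p in all_positions:
        res = occupied.get(p)
        aa = res.aa if res else None
        x, y = coords[p]
        glyphs.append(PerleGlyph(
            position=p, aa=aa, x=x, y=y,
            shape="square" if p in anchors else "circle",
            fill_class=_fill_class(aa, seg_of[p], domain.domain_kind)))
    return PerleLayout(
        domain_kind=domain.domain_kind, layers=layers,
        rearrangement=rearrangement, glyphs=tuple(glyphs),
        bonds=tuple(tuple(b) for b in bonds))


def _sheet_strand(segment: str) -> str:
    # loops travel with their N-terminal strand for layer assignment
    return {"BC": "B", "C'C''": "C'", "FG": "F",
            "CD": "CD", "AB": "A", "DE": "D", "EF": "E"}.get(segment, segment)


def _segment_of_gap(domain: NumberedDomain, position: ImgtPosition) -> str:
    from .numbering import C_TOPOLOGY, V_TOPOLOGY
    topo = V_TOPOLOGY if domain.domain_kind == "V" else C_TOPOLOGY
    return topo.strand_of(position)


def _serpentine(positions, seg_of, column: float) -> dict:
    """One column per strand block; pearls run down then up alternately."""
    coords = {}
    block = -1
    last_seg = None
    row = 0
    for p in positions:
        seg = seg_of[p]
        if seg != last_seg:
            block += 1
            last_seg = seg
            row = 0
        direction = 1 if block % 2 == 0 else -1
        coords[p] = (column + block * 1.5,
                     float(row if direction == 1 else 30 - row))
        row += 1
    return coords


def render_svg(layout: PerleLayout, style: dict | None = None) -> str:
    """Serialize a layout to a deterministic standalone SVG document."""
    style = dict(style or {})
    unit = style.get("unit", 24)
    radius = style.get("radius", 10)
    palette = {
        "cdr1": "#d62728" if layout.rearrangement != "V-J" else "#1f77b4",
        "cdr2": "#ff7f0e" if layout.rearrangement != "V-J" else "#2ca02c",
        "cdr3": "#9467bd" if layout.rearrangement != "V-J" else "#17a2b8",
        "hydrophobic": "#aec7e8",
        "proline": "#ffdf00",
        "plain": "#ffffff",
        "gap": "url(#hatch)",
    }
    palette.update(style.get("palette", {}))

    xs = [g.x for g in layout.glyphs] or [0]
    ys = [g.y for g in layout.glyphs] or [0]
    width = int((max(xs) + 2) * unit)
    height = int((max(ys) + 2) * unit)
    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" '
        f'width="{width}" height="{height}">',
        '<defs><pattern id="hatch" width="4" height="4" '
        'patternUnits="userSpaceOnUse">'
        '<path d="M0,4 L4,0" stroke="#888888" stroke-width="1"/>'
        "</pattern></defs>",
    ]
    pos_xy = {}
    for g in layout.glyphs:
        cx = (g.x + 1) * unit
        cy = (g.y + 1) * unit
        pos_xy[g.position] = (cx, cy)
    for a, b in layout.bonds:
        pa = pos_xy.get(ImgtPosition.parse(str(a)))
        pb = pos_xy.get(ImgtPosition.parse(str(b)))
        if pa and pb:
            parts.append(
                f'<line x1="{pa[0]}" y1="{pa[1]}" x2="{pb[0]}" y2="{pb[1]}" '
                'stroke="#2ca02c" stroke-width="1"/>')
    # disulfide 23-104 when both occupied
    p23 = ImgtPosition(23)
    p104 = ImgtPosition(104)
    g23 = layout.glyph_at(p23)
    g104 = layout.glyph_at(p104)
    if g23 and g104 and g23.aa and g104.aa:
        (x1, y1), (x2, y2) = pos_xy[p23], pos_xy[p104]
        parts.append(
            f'<line x1="{x1}" y1="{y1}" x2="{x2}" y2="{y2}" '
            'stroke="#ff8c00" stroke-width="2" class="disulfide"/>')
    for g in layout.glyphs:
        cx, cy = pos_xy[g.position]
        fill = palette[g.fill_class]
        common = (f'fill="{fill}" stroke="#000000" stroke-width="1" '
                  f'class="perle {g.fill_class}" '
                  f'data-position="{g.position}"')
        if g.shape == "square":
            parts.append(
                f'<rect x="{cx - radius}" y="{cy - radius}" '
                f'width="{2 * radius}" height="{2 * radius}" {common}/>')
        else:
            parts.append(f'<circle cx="{cx}" cy="{cy}" r="{radius}" '
                         f'{common}/>')
        if g.aa:
            parts.append(
                f'<text x="{cx}" y="{cy + 4}" text-anchor="middle" '
                f'font-size="11" font-family="monospace">{g.aa}</text>')
    parts.append("</svg>")
    return "\n".join(parts) + "\n"
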