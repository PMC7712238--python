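"""To-scale SVG diagrams of factor domain architecture.

Each protein is a horizontal bar with shaded DNA-binding domains, the
degenerate upstream finger, poly-serine segments, inverted-triangle intron
marks at codon positions, and a total-length label. SVG is plain XML and
is emitted by direct templating; output is deterministic for a given
factor.
"""

from __future__ import annotations

from typing import Optional, Sequence

from .classify import GataFactor
from .gene_structure import IntronSite

__all__ = ["render_diagram"]

_SCALE = 1.0          # px per residue
_BAR_Y, _BAR_H = 40, 16
_MARGIN = 20
_COLORS = {"dbd": "#2b6cb0", "degenerate": "#b08f2b", "polyS": "#2ba05a"}


def _rect(x: float, w: float, color: str, title: str) -> str:
    return (f'  <rect x="{x:.1f}" y="{_BAR_Y}" width="{w:.1f}" height="{_BAR_H}" '
            f'fill="{color}"><title>{title}</title></rect>\n')


def render_diagram(factor: GataFactor,
                   introns: Optional[Sequence[IntronSite]] = None) -> str:
    """Render one factor as an SVG document string."""
    n = factor.length
    width = n * _SCALE + 2 * _MARGIN
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width:.0f}" height="100" '
        f'viewBox="0 0 {width:.0f} 100">\n',
        f'  <rect x="{_MARGIN}" y="{_BAR_Y}" width="{n * _SCALE:.1f}" '
        f'height="{_BAR_H}" fill="#d9d9d9"/>\n',
    ]
    for d in factor.dbds:
        start, end = d.finger.span[0], d.basic.span[1]
        parts.append(_rect(_MARGIN + start * _SCALE, (end - start) * _SCALE,
                           _COLORS["dbd"], f"DBD {start}-{end}"))
    for z in factor.degenerate_fingers:
        parts.append(_rect(_MARGIN + z.span[0] * _SCALE,
                           (z.span[1] - z.span[0]) * _SCALE,
                           _COLORS["degenerate"], f"degenerate {z.span[0]}-{z.span[1]}"))
    for s in factor.polyS:
        parts.append(_rect(_MARGIN + s.span[0] * _SCALE,
                           (s.span[1] - s.span[0]) * _SCALE,
                           _COLORS["polyS"], f"polyS {s.span[0]}-{s.span[1]}"))
    for site in introns or []:
        x = _MARGIN + site.codon_index * _SCALE
        top = _BAR_Y - 12
        parts.append(f'  <polygon points="{x - 5:.1f},{top} {x + 5:.1f},{top} '
                     f'{x:.1f},{_BAR_Y}" fill="#555">'
                     f'<title>intron codon {site.codon_index} phase {site.phase}</title>'
                     f'</polygon>\n')
    parts.append(f'  <text x="{_MARGIN + n * _SCALE + 4:.1f}" y="{_BAR_Y + _BAR_H - 3}" '
                 f'font-size="12" font-family="sans-serif">{n} aa</text>\n')
    parts.append(f'  <text x="{_MARGIN}" y="{_BAR_Y - 18}" font-size="12" '
                 f'font-family="sans-serif">{factor.protein_id}</text>\n')
    parts.append("</svg>\n")
    return "".join(parts)
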