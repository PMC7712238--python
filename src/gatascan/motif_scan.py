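"""Targeted motif scans of gene flanks.

Three interpreted motifs replace de novo discovery: single HGATAR core
sites (H = A/C/T, R = A/G) on either strand, the double-GATA arrangement
(two HGATAR sites in inverted, convergent orientation), and polypyrimidine
tracts. Minus-strand HGATAR hits are reported at forward coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence, Union

__all__ = [
    "MotifHit",
    "scan_hgatar",
    "find_double_gata",
    "find_polypyrimidine",
    "scan_flank",
]

HGATAR_PLUS = re.compile(r"(?=([ACT]GATA[AG]))")
HGATAR_MINUS = re.compile(r"(?=([CT]TATC[AGT]))")  # reverse complement of HGATAR
SITE_LEN = 6


@dataclass(frozen=True)
class MotifHit:
    kind: str  # hgatar / double_gata / polypyrimidine
    start: int
    end: int  # half-open, forward coordinates of the scanned sequence
    strand: str  # '+', '-' or 'both'
    detail: Optional[Union[int, float]] = None  # spacer length or pyrimidine fraction


def scan_hgatar(seq: str) -> list[MotifHit]:
    """All HGATAR core sites on both strands, at forward coordinates.

    Overlapping sites are all reported; hits are sorted by (start, strand).
    """
    s = seq.upper()
    hits = [MotifHit("hgatar", m.start(), m.start() + SITE_LEN, "+")
            for m in HGATAR_PLUS.finditer(s)]
    hits += [MotifHit("hgatar", m.start(), m.start() + SITE_LEN, "-")
             for m in HGATAR_MINUS.finditer(s)]
    return sorted(hits, key=lambda h: (h.start, h.strand))


def find_double_gata(seq: str, max_spacer: int = 20) -> list[MotifHit]:
    """Inverted convergent HGATAR pairs: a plus site 5' of a minus site.

    Emitted once per qualifying (plus, minus) pair spanning both sites,
    with the spacer length recorded; overlapping pairs are all reported.
    """
    hits = scan_hgatar(seq)
    plus = [h.start for h in hits if h.strand == "+"]
    minus = [h.start for h in hits if h.strand == "-"]
    out = []
    for i in plus:
        for j in minus:
            spacer = j - (i + SITE_LEN)
            if 0 <= spacer <= max_spacer:
                out.append(MotifHit("double_gata", i, j + SITE_LEN, "both", spacer))
    return sorted(out, key=lambda h: (h.start, h.end))


def find_polypyrimidine(seq: str, min_len: int = 12, min_frac: float = 0.9
                        ) -> list[MotifHit]:
    """Merged maximal C/T-rich tracts.

    Every length-``min_len`` window whose pyrimidine fraction reaches
    ``min_frac`` qualifies; overlapping or adjacent qualifying windows are
    merged, and the fraction is reported over the merged span.
    """
    s = seq.upper()
    n = len(s)
    is_pyr = [1 if ch in "CT" else 0 for ch in s]
    prefix = [0]
    for v in is_pyr:
        prefix.append(prefix[-1] + v)
    windows = [(i, i + min_len) for i in range(0, n - min_len + 1)
               if prefix[i + min_len] - prefix[i] >= min_frac * min_len]
    merged: list[list[int]] = []
    for a, b in windows:
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [MotifHit("polypyrimidine", a, b, "+", (prefix[b] - prefix[a]) / (b - a))
            for a, b in merged]


def scan_flank(seq: str, max_spacer: int = 20, min_len: int = 12,
               min_frac: float = 0.9) -> list[MotifHit]:
    """All three targeted scans of one flank, concatenated."""
    return (scan_hgatar(seq)
            + find_double_gata(seq, max_spacer)
            + find_polypyrimidine(seq, min_len, min_frac))
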