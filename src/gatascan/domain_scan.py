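"""Detection of GATA-type C4 zinc fingers and associated protein domains.

The canonical GATA DNA-binding domain is a C-X2-C-X17-C-X2-C zinc finger
followed by a ~30-residue lysine/arginine-rich basic domain. The scanner
also recognises variant fingers (first spacer 2-4 or non-17 loop within a
configured range), degenerate upstream CX2C-X(9-20)-CX2C fingers typical of
ELT-2-like factors, the diagnostic T-X-[LA]-W-R-R hexapeptide family
(TPLWRR/TTLWRR/TSLWRR/TTAWRR), and low-complexity poly-serine segments.

All residue comparisons are case-insensitive; 'X' never matches a specific
residue. Overlapping finger candidates are resolved deterministically:
leftmost match wins, then longest.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

__all__ = [
    "ScanConfig",
    "ZincFinger",
    "BasicDomain",
    "DBD",
    "PolySSegment",
    "find_gata_fingers",
    "find_basic_domain",
    "find_degenerate_fingers",
    "find_orphan_degenerate_fingers",
    "find_hexapeptide",
    "find_polyS",
    "build_dbds",
]

GATA_CANONICAL = "gata_canonical"
GATA_VARIANT = "gata_variant"
DEGENERATE = "degenerate"

CANONICAL_FIRST_SPACER = 2
CANONICAL_LOOP = 17
BASIC_DOMAIN_LEN = 30


@dataclass(frozen=True)
class ScanConfig:
    """Tunable parameters of the domain scanner.

    ``first_spacer_range``/``loop_range`` are inclusive bounds on the
    C1-C2 spacer and C2-C3 loop of GATA-type fingers; a finger is labelled
    canonical only at exactly (2, 17). ``degenerate_loop_range`` bounds the
    loop of the upstream degenerate finger and ``max_upstream_gap`` the
    residues allowed between its fourth cysteine and the first cysteine of
    a downstream GATA finger.
    """

    first_spacer_range: tuple[int, int] = (2, 4)
    loop_range: tuple[int, int] = (16, 19)
    degenerate_loop_range: tuple[int, int] = (9, 20)
    max_upstream_gap: int = 200
    hexapeptide_pattern: str = "T.[LA]WRR"
    polyS_window: int = 10
    polyS_min_ser: int = 6

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "ScanConfig":
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {}
        for key, value in mapping.items():
            if key not in known:
                raise ValueError(f"unknown scan-config key {key!r}")
            if isinstance(value, (list, tuple)):
                value = tuple(int(v) for v in value)
            kwargs[key] = value
        return cls(**kwargs)


DEFAULT_SCAN_CONFIG = ScanConfig()


@dataclass(frozen=True)
class ZincFinger:
    """A C4 zinc finger located by its four cysteine residue indices."""

    kind: str
    cys_positions: tuple[int, int, int, int]
    first_spacer_len: int
    loop_len: int
    span: tuple[int, int]  # half-open over C1..C4

    @property
    def c1(self) -> int:
        return self.cys_positions[0]

    @property
    def c3(self) -> int:
        return self.cys_positions[2]

    @property
    def c4(self) -> int:
        return self.cys_positions[3]


@dataclass(frozen=True)
class BasicDomain:
    """The up-to-30-residue window immediately after a finger's C4."""

    span: tuple[int, int]
    observed_len: int
    basic_fraction: float
    truncated: bool


@dataclass(frozen=True)
class DBD:
    """A GATA DNA-binding domain: finger + basic domain (+ hexapeptide)."""

    finger: ZincFinger
    basic: BasicDomain
    hexapeptide: Optional[str] = None
    hexapeptide_offset: Optional[int] = None

    @property
    def span(self) -> tuple[int, int]:
        return self.finger.span[0], self.basic.span[1]


@dataclass(frozen=True)
class PolySSegment:
    """Maximal union of length-10 windows containing >= 6 serines."""

    span: tuple[int, int]
    ser_count: int


def _finger_candidates(protein: str,
                       spacer_range: tuple[int, int],
                       loop_range: tuple[int, int],
                       second_spacer: int = 2) -> list[tuple[int, int, int, int]]:
    """All cysteine quadruples satisfying C-X(f)-C-X(L)-C-X(s2)-C."""
    seq = protein.upper()
    cys = [i for i, aa in enumerate(seq) if aa == "C"]
    cys_set = set(cys)
    out = []
    for i in cys:
        for f in range(spacer_range[0], spacer_range[1] + 1):
            j = i + 1 + f
            if j not in cys_set:
                continue
            for loop in range(loop_range[0], loop_range[1] + 1):
                k = j + 1 + loop
                if k not in cys_set:
                    continue
                m = k + 1 + second_spacer
                if m in cys_set:
                    out.append((i, j, k, m))
    return out


def _resolve_overlaps(candidates: Sequence[tuple[int, int, int, int]]
                      ) -> list[tuple[int, int, int, int]]:
    """Greedy leftmost-then-longest selection of non-overlapping quadruples."""
    chosen: list[tuple[int, int, int, int]] = []
    last_end = -1
    for quad in sorted(candidates, key=lambda q: (q[0], -q[3])):
        if quad[0] > last_end:
            chosen.append(quad)
            last_end = quad[3]
    return chosen


def _make_finger(quad: tuple[int, int, int, int], kind: Optional[str] = None) -> ZincFinger:
    i, j, k, m = quad
    f, loop = j - i - 1, k - j - 1
    if kind is None:
        kind = GATA_CANONICAL if (f, loop) == (CANONICAL_FIRST_SPACER, CANONICAL_LOOP) \
            else GATA_VARIANT
    return ZincFinger(kind=kind, cys_positions=quad, first_spacer_len=f,
                      loop_len=loop, span=(i, m + 1))


def find_gata_fingers(protein: str, cfg: ScanConfig = DEFAULT_SCAN_CONFIG) -> list[ZincFinger]:
    """Find all non-overlapping GATA-type C4 fingers, leftmost-then-longest.

    Fingers with first spacer exactly 2 and loop exactly 17 are labelled
    ``gata_canonical``; other accepted geometries are ``gata_variant``
    (e.g. the CSNSNC-type spacer of some divergent single-finger factors).
    """
    cands = _finger_candidates(protein, cfg.first_spacer_range, cfg.loop_range)
    return [_make_finger(q) for q in _resolve_overlaps(cands)]


def find_basic_domain(protein: str, finger: ZincFinger) -> BasicDomain:
    """The up-to-30-residue basic-domain window following the fourth cysteine.

    ``basic_fraction`` is the K/R fraction over the observed residues; the
    domain is flagged truncated when the protein ends within the window.
    """
    start = finger.c4 + 1
    end = min(start + BASIC_DOMAIN_LEN, len(protein))
    window = protein[start:end].upper()
    observed = len(window)
    basic = sum(1 for aa in window if aa in "KR")
    return BasicDomain(span=(start, end), observed_len=observed,
                       basic_fraction=(basic / observed) if observed else 0.0,
                       truncated=observed < BASIC_DOMAIN_LEN)


def _degenerate_candidates(protein: str, cfg: ScanConfig) -> list[tuple[int, int, int, int]]:
    return _finger_candidates(protein, (2, 2), cfg.degenerate_loop_range)


def _overlaps_any(quad: tuple[int, int, int, int], spans: Sequence[tuple[int, int]]) -> bool:
    start, end = quad[0], quad[3] + 1
    return any(start < e and s < end for s, e in spans)


def find_degenerate_fingers(protein: str,
                            gata_fingers: Sequence[ZincFinger],
                            cfg: ScanConfig = DEFAULT_SCAN_CONFIG) -> list[ZincFinger]:
    """Degenerate CX2C-X(9-20)-CX2C fingers upstream of a GATA finger.

    A candidate qualifies only if it does not overlap any GATA finger and
    its fourth cysteine lies at most ``cfg.max_upstream_gap`` residues
    upstream of some GATA finger's first cysteine.
    """
    spans = [f.span for f in gata_fingers]
    kept = []
    for quad in _degenerate_candidates(protein, cfg):
        if _overlaps_any(quad, spans):
            continue
        gaps = [g.c1 - quad[3] - 1 for g in gata_fingers if g.c1 > quad[3]]
        if any(0 <= gap <= cfg.max_upstream_gap for gap in gaps):
            kept.append(quad)
    return [_make_finger(q, DEGENERATE) for q in _resolve_overlaps(kept)]


def find_orphan_degenerate_fingers(protein: str,
                                   gata_fingers: Sequence[ZincFinger],
                                   cfg: ScanConfig = DEFAULT_SCAN_CONFIG) -> list[ZincFinger]:
    """Free-standing degenerate motifs with no qualifying downstream GATA finger."""
    spans = [f.span for f in gata_fingers]
    upstream = {f.cys_positions for f in find_degenerate_fingers(protein, gata_fingers, cfg)}
    kept = [q for q in _degenerate_candidates(protein, cfg)
            if not _overlaps_any(q, spans) and q not in upstream]
    return [_make_finger(q, DEGENERATE) for q in _resolve_overlaps(kept)]


def find_hexapeptide(protein: str,
                     window: tuple[int, int],
                     pattern: str = "T.[LA]WRR") -> Optional[tuple[str, int]]:
    """First diagnostic hexapeptide match inside ``window`` (half-open).

    Returns ``(matched_string, absolute_offset)`` or ``None``. The default
    pattern T-X-[LA]-W-R-R covers TPLWRR (ELT-1 amino finger), TTLWRR
    (ELT-1 carboxyl/ELT-2), TSLWRR and the ELT-5-diagnostic TTAWRR.
    """
    start, end = max(0, window[0]), min(len(protein), window[1])
    m = re.search(pattern, protein[start:end].upper())
    if m is None:
        return None
    return m.group(0), start + m.start()


def find_polyS(protein: str, window: int = 10, min_ser: int = 6) -> list[PolySSegment]:
    """Poly-serine segments: merged qualifying windows of length ``window``.

    Every length-``window`` window containing at least ``min_ser`` serines
    qualifies; overlapping or adjacent qualifying windows are merged into
    maximal segments and the serine count is reported over the merged span.
    """
    seq = protein.upper()
    n = len(seq)
    is_ser = [1 if aa == "S" else 0 for aa in seq]
    prefix = [0]
    for v in is_ser:
        prefix.append(prefix[-1] + v)
    intervals = []
    for i in range(0, n - window + 1):
        if prefix[i + window] - prefix[i] >= min_ser:
            intervals.append((i, i + window))
    merged: list[list[int]] = []
    for s, e in intervals:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [PolySSegment(span=(s, e), ser_count=prefix[e] - prefix[s]) for s, e in merged]


def build_dbds(protein: str, cfg: ScanConfig = DEFAULT_SCAN_CONFIG) -> list[DBD]:
    """Convenience: GATA fingers with basic domains and hexapeptides attached."""
    dbds = []
    for finger in find_gata_fingers(protein, cfg):
        basic = find_basic_domain(protein, finger)
        hexa = find_hexapeptide(protein, (finger.span[0], basic.span[1]),
                                cfg.hexapeptide_pattern)
        if hexa is None:
            dbds.append(DBD(finger=finger, basic=basic))
        else:
            dbds.append(DBD(finger=finger, basic=basic,
                            hexapeptide=hexa[0], hexapeptide_offset=hexa[1]))
    return dbds
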