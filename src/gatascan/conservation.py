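"""Landmark-anchored 55-column DBD alignments and conservation statistics.

Rather than a general-purpose MSA, DBD windows are aligned by their
structural landmarks into a fixed 55-column layout:

    col 0        C1
    cols 1-2     first spacer (canonical length 2)
    col 3        C2
    cols 4-20    loop (canonical length 17)
    col 21       C3
    cols 22-23   second spacer (always 2)
    col 24       C4
    cols 25-54   basic domain (30 columns, left-aligned)

Shorter-than-canonical spacer/loop regions are centre-padded with gaps
(the extra gap goes right of centre); longer regions are centre-trimmed
with the excised residues kept as an insertion side-record. Consensus
strings follow the family's case convention: uppercase = absolute
conservation (one residue, no gaps), lowercase = strict majority (>50%),
'.' = neither.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from Bio import SeqIO

from .domain_scan import DBD

__all__ = [
    "GAP",
    "N_COLUMNS",
    "CYS_COLUMNS",
    "AlignmentRow",
    "AnchoredAlignment",
    "anchor_row",
    "anchor_align",
    "consensus",
    "conservation_count",
    "identity_fraction",
    "contact_variability",
    "default_contact_positions",
    "export_alignment",
]

GAP = "-"
N_COLUMNS = 55
CYS_COLUMNS = (0, 3, 21, 24)
_SPACER1_W, _LOOP_W, _BASIC_W = 2, 17, 30


@dataclass(frozen=True)
class AlignmentRow:
    seq_id: str
    text: str  # exactly 55 characters
    insertions: tuple[tuple[str, str], ...] = ()  # (region, excised residues)


@dataclass
class AnchoredAlignment:
    rows: list[AlignmentRow] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def column(self, i: int) -> list[str]:
        return [r.text[i] for r in self.rows]


def _fit(segment: str, width: int, region: str) -> tuple[str, Optional[tuple[str, str]]]:
    """Centre-pad (extra gap right of centre) or centre-trim to ``width``."""
    n = len(segment)
    if n == width:
        return segment, None
    if n < width:
        left = (n + 1) // 2
        return segment[:left] + GAP * (width - n) + segment[left:], None
    left_keep = (width + 1) // 2
    right_keep = width - left_keep
    kept = segment[:left_keep] + (segment[n - right_keep:] if right_keep else "")
    excised = segment[left_keep:n - right_keep] if right_keep else segment[left_keep:]
    return kept, (region, excised)


def anchor_row(protein: str, dbd: DBD, seq_id: str = "") -> AlignmentRow:
    """Place one DBD into the fixed 55-column layout."""
    f = dbd.finger
    c1, c2, c3, c4 = f.cys_positions
    if c4 >= len(protein) or protein[c4].upper() != "C":
        raise ValueError(f"{seq_id or 'DBD'}: fourth cysteine missing at position {c4}")
    spacer1 = protein[c1 + 1:c2]
    loop = protein[c2 + 1:c3]
    spacer2 = protein[c3 + 1:c4]
    basic = protein[dbd.basic.span[0]:dbd.basic.span[1]]
    insertions = []
    s1, ins = _fit(spacer1, _SPACER1_W, "first_spacer")
    if ins:
        insertions.append(ins)
    lp, ins = _fit(loop, _LOOP_W, "loop")
    if ins:
        insertions.append(ins)
    text = ("C" + s1 + "C" + lp + "C" + spacer2 + "C"
            + basic + GAP * (_BASIC_W - len(basic)))
    assert len(text) == N_COLUMNS
    return AlignmentRow(seq_id=seq_id, text=text, insertions=tuple(insertions))


def anchor_align(entries: Iterable[tuple[str, DBD, str]]) -> AnchoredAlignment:
    """Anchored alignment from (seq_id, DBD, protein sequence) triples."""
    return AnchoredAlignment(rows=[anchor_row(protein, dbd, seq_id)
                                   for seq_id, dbd, protein in entries])


def _column_census(column: Sequence[str]) -> tuple[dict[str, int], int]:
    counts: dict[str, int] = {}
    gaps = 0
    for ch in column:
        if ch == GAP:
            gaps += 1
        else:
            counts[ch.upper()] = counts.get(ch.upper(), 0) + 1
    return counts, gaps


def consensus(aln: AnchoredAlignment) -> str:
    """Per-column consensus with the family's case convention.

    Uppercase marks absolute conservation (a single residue type, no
    gaps), lowercase a strict majority (>50% of rows), and '.' columns
    with neither (including ties).
    """
    if len(aln) < 2:
        raise ValueError("consensus requires at least 2 rows")
    n = len(aln)
    out = []
    for i in range(N_COLUMNS):
        counts, gaps = _column_census(aln.column(i))
        if len(counts) == 1 and gaps == 0:
            out.append(next(iter(counts)))
            continue
        best = max(counts.items(), key=lambda kv: (kv[1], kv[0])) if counts else None
        if best and best[1] * 2 > n and sum(1 for v in counts.values() if v == best[1]) == 1:
            out.append(best[0].lower())
        else:
            out.append(".")
    return "".join(out)


def conservation_count(aln: AnchoredAlignment, mode: str = "majority"
                       ) -> tuple[int, int, float]:
    """Count conserved columns of the 55: ``absolute`` or ``majority`` mode.

    Absolute: every row holds the same residue with no gaps. Majority: some
    residue is held by a strict majority (>50%) of rows. Returns
    ``(k, 55, k/55)``.
    """
    if mode not in ("absolute", "majority"):
        raise ValueError(f"mode must be 'absolute' or 'majority', got {mode!r}")
    if len(aln) < 2:
        raise ValueError("conservation_count requires at least 2 rows")
    n = len(aln)
    k = 0
    for i in range(N_COLUMNS):
        counts, gaps = _column_census(aln.column(i))
        if mode == "absolute":
            k += len(counts) == 1 and gaps == 0
        else:
            k += bool(counts) and max(counts.values()) * 2 > n
    return k, N_COLUMNS, k / N_COLUMNS


def identity_fraction(row_text: str, reference: str) -> float:
    """Case-insensitive identity of a 55-column row to a reference string.

    Gap and '.' positions never match; the denominator is always 55.
    """
    if len(row_text) != N_COLUMNS or len(reference) != N_COLUMNS:
        raise ValueError("identity_fraction expects two 55-column strings")
    matches = sum(1 for a, b in zip(row_text.upper(), reference.upper())
                  if a == b and a != GAP and a != ".")
    return matches / N_COLUMNS


def default_contact_positions() -> tuple[int, ...]:
    """The configured set of 18 DNA-base-contacting alignment columns.

    Shipped as data (``contact_positions.synthetic.json``): a constructed
    stand-in for the structurally annotated cGATA1 contact set, spanning
    the C2-C3 loop and the proximal basic domain where base contacts lie.
    """
    text = resources.files("gatascan.data").joinpath(
        "contact_positions.synthetic.json").read_text()
    positions = tuple(json.loads(text)["positions"])
    return positions


def contact_variability(consensus_by_class: Mapping[str, str],
                        positions: Optional[Sequence[int]] = None
                        ) -> tuple[int, int]:
    """Count contact positions whose consensus varies across classes.

    A position counts as varied unless every class consensus holds the
    same absolutely conserved (uppercase) residue there. Returns
    ``(varied, total)``.
    """
    if positions is None:
        positions = default_contact_positions()
    if not consensus_by_class:
        raise ValueError("no class consensus strings given")
    varied = 0
    for pos in positions:
        chars = {cons[pos] for cons in consensus_by_class.values()}
        if not (len(chars) == 1 and next(iter(chars)).isupper()):
            varied += 1
    return varied, len(positions)


def export_alignment(aln: AnchoredAlignment, path: Union[str, Path]) -> None:
    """Write the anchored alignment as aligned FASTA (row order preserved)."""
    with open(path, "w") as out:
        for row in aln.rows:
            out.write(f">{row.seq_id}\n{row.text}\n")
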