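"""Intron positions in protein codon coordinates and cysteine-landmark terms.

An intron is described by the number of complete codons 5' of it
(``codon_index``) and its phase (0, 1 or 2 nucleotides of the interrupted
codon lying 5' of the intron; phase 0 means the intron falls between
codons). Relative to a zinc-finger cysteine landmark (C3 or C4 of a named
finger), the intron gets a ``codon_offset``: for a phase-0 intron this is
the number of complete codons between the landmark codon and the intron,
and for phase 1/2 the interrupted codon itself counts as the offset-th
codon after the landmark. Under this convention the three conserved
landmark introns of the family are (C4 of the amino finger, +20, phase 0)
and (C4 of the carboxyl finger, +8, phase 0) in the two ELT-1 basic
domains, and (C3, +1, phase 1) in the ELT-2/ELT-3 zinc finger.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .domain_scan import ZincFinger
from .seq_io import GeneModel

__all__ = [
    "IntronSite",
    "LandmarkDescriptor",
    "IntronSignature",
    "N_BASIC_INTRON",
    "C_BASIC_INTRON",
    "ZF_INTRON",
    "map_introns_to_protein",
    "landmark_offset",
    "describe_introns",
    "intron_signature",
]

# (landmark, codon_offset, phase) of the conserved marker introns
N_BASIC_INTRON = ("C4", 20, 0)   # amino-finger basic domain (ELT-1 type)
C_BASIC_INTRON = ("C4", 8, 0)    # carboxyl-finger basic domain (ELT-1/ELT-5 type)
ZF_INTRON = ("C3", 1, 1)         # within the zinc finger (ELT-2/ELT-3 type)


@dataclass(frozen=True)
class IntronSite:
    """One coding intron in protein codon coordinates."""

    codon_index: int
    phase: int
    genomic: tuple[str, int, int]  # (scaffold, donor, acceptor), 0-based half-open

    def cds_offset(self) -> int:
        """Spliced-CDS nucleotides 5' of the intron."""
        return 3 * self.codon_index + self.phase


@dataclass(frozen=True)
class LandmarkDescriptor:
    """An intron position expressed relative to a finger cysteine landmark."""

    intron_index: int
    finger_index: int
    landmark: str  # "C3" or "C4"
    codon_offset: int
    phase: int
    non_canonical: bool = False  # intron not strictly 3' of the landmark codon

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.landmark, self.codon_offset, self.phase)


@dataclass(frozen=True)
class IntronSignature:
    """Presence flags for the conserved landmark introns of a factor."""

    has_N_basic_intron: bool
    has_C_basic_intron: bool
    has_zf_intron: bool
    intronless: bool
    extra_introns: int = 0


def map_introns_to_protein(gm: GeneModel) -> list[IntronSite]:
    """One IntronSite per inter-CDS gap, in transcription order.

    ``codon_index = cds_offset // 3`` and ``phase = cds_offset % 3`` where
    ``cds_offset`` counts spliced-CDS nucleotides 5' of the intron.
    """
    segments = gm.cds_segments if gm.strand == "+" else list(reversed(gm.cds_segments))
    sites = []
    offset = 0
    for (s0, e0), (s1, e1) in zip(segments, segments[1:]):
        offset += e0 - s0
        if gm.strand == "+":
            genomic = (gm.scaffold, e0, s1)
        else:
            genomic = (gm.scaffold, e1, s0)
        sites.append(IntronSite(codon_index=offset // 3, phase=offset % 3, genomic=genomic))
    return sites


def landmark_offset(site: IntronSite, finger: ZincFinger, landmark: str,
                    intron_index: int = 0, finger_index: int = 0) -> LandmarkDescriptor:
    """Express an intron position relative to C3 or C4 of a finger.

    For phase 0 the offset is the count of complete codons between the
    landmark cysteine's codon and the intron; for phase 1/2 the interrupted
    codon counts as the offset-th codon after the landmark. Introns 5' of
    (or within) the landmark codon get offsets <= 0 and are flagged
    non-canonical rather than discarded.
    """
    if landmark not in ("C3", "C4"):
        raise ValueError(f"landmark must be 'C3' or 'C4', got {landmark!r}")
    cys = finger.c3 if landmark == "C3" else finger.c4
    offset = site.codon_index - cys - 1 + (1 if site.phase else 0)
    non_canonical = site.codon_index <= cys
    return LandmarkDescriptor(intron_index=intron_index, finger_index=finger_index,
                              landmark=landmark, codon_offset=offset, phase=site.phase,
                              non_canonical=non_canonical)


def describe_introns(sites: Sequence[IntronSite],
                     fingers: Sequence[ZincFinger]) -> list[LandmarkDescriptor]:
    """All (intron, finger, landmark) descriptors, C3 and C4 per finger."""
    out = []
    for i, site in enumerate(sites):
        for fi, finger in enumerate(fingers):
            for landmark in ("C3", "C4"):
                out.append(landmark_offset(site, finger, landmark,
                                           intron_index=i, finger_index=fi))
    return out


def _matches(d: LandmarkDescriptor, target: tuple[str, int, int], slop: int) -> bool:
    landmark, offset, phase = target
    return (d.landmark == landmark and d.phase == phase
            and abs(d.codon_offset - offset) <= slop)


def intron_signature(descriptors: Sequence[LandmarkDescriptor],
                     n_introns: int,
                     n_fingers: int,
                     slop: int = 0) -> IntronSignature:
    """Set the conserved-intron flags from exact landmark-descriptor matches.

    The amino-basic-domain flag is matched against the first finger, the
    carboxyl-basic-domain flag against the last finger (for single-finger
    factors these coincide), and the zinc-finger intron against any finger.
    ``slop`` relaxes the codon-offset match for indel-shifted orthologues.
    """
    flagged: set[int] = set()
    has_n = has_c = has_zf = False
    for d in descriptors:
        if d.finger_index == 0 and _matches(d, N_BASIC_INTRON, slop):
            has_n = True
            flagged.add(d.intron_index)
        if d.finger_index == n_fingers - 1 and _matches(d, C_BASIC_INTRON, slop):
            has_c = True
            flagged.add(d.intron_index)
        if _matches(d, ZF_INTRON, slop):
            has_zf = True
            flagged.add(d.intron_index)
    return IntronSignature(has_N_basic_intron=has_n, has_C_basic_intron=has_c,
                           has_zf_intron=has_zf, intronless=n_introns == 0,
                           extra_introns=n_introns - len(flagged))
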