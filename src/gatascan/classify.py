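"""Five-class structural assignment of GATA factors.

The decision sequence formalises the family's structural taxonomy:

1. two or more GATA DBDs in tandem (C4-to-next-C1 gap <= ``tandem_gap``)
   -> ELT1;
2. a single GATA DBD plus at least one degenerate upstream finger -> ELT2;
3. a single GATA DBD: anchored 55-column identity to each single-finger
   class consensus (ELT3, ELT5); argmax wins if it reaches
   ``min_identity``, ties broken by the diagnostic hexapeptide
   (TTAWRR -> ELT5) then by intron flags (zinc-finger intron -> ELT3,
   carboxyl-basic intron -> ELT5); anything unresolved falls to the
   ELTX catch-all;
4. two or more widely spaced DBDs: each DBD classified by rule 3; a
   unanimous label wins, disagreement -> ELTX.

ELT1/ELT2 calls are purely structural and never depend on consensus
identity; the identity score attached to them is informational only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import conservation
from .domain_scan import DBD, PolySSegment, ZincFinger
from .gene_structure import IntronSignature

__all__ = [
    "CLASS_LABELS",
    "SINGLE_FINGER_CLASSES",
    "GataFactor",
    "ClassCall",
    "ClassifyConfig",
    "load_default_library",
    "assign_class",
    "tally_by_class",
]

CLASS_LABELS = ("ELT1", "ELT2", "ELT3", "ELT5", "ELTX")
SINGLE_FINGER_CLASSES = ("ELT3", "ELT5")

_HEX_TO_CLASS = {"TTAWRR": "ELT5"}


@dataclass
class GataFactor:
    """A protein with its detected domains and intron signature."""

    protein_id: str
    gene_id: str
    sequence: str
    dbds: list[DBD]
    degenerate_fingers: list[ZincFinger] = field(default_factory=list)
    polyS: list[PolySSegment] = field(default_factory=list)
    signature: IntronSignature = IntronSignature(False, False, False, True, 0)

    def __post_init__(self) -> None:
        if not self.dbds:
            raise ValueError(f"{self.protein_id}: GataFactor requires at least one DBD")
        self.dbds = sorted(self.dbds, key=lambda d: d.finger.c1)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ClassCall:
    label: str
    score: Optional[float]
    evidence: tuple[str, ...]


@dataclass(frozen=True)
class ClassifyConfig:
    """Thresholds of the structural classifier.

    ``tandem_gap`` (residues between C4 of one finger and C1 of the next)
    separates the ~29-residue tandem arrangement of two-finger factors from
    the 100-311-residue spacings seen in duplicated single-finger factors.
    ``min_identity`` is the anchored-55-column identity a single-finger DBD
    must reach to be called ELT3/ELT5 rather than ELTX.
    """

    tandem_gap: int = 50
    min_identity: float = 0.60


DEFAULT_CLASSIFY_CONFIG = ClassifyConfig()


def load_default_library() -> dict[str, str]:
    """Class consensus 55-column templates keyed by class name.

    Loaded from ``consensus_library.synthetic.fasta``: constructed synthetic
    stand-ins for the family's per-class consensus rows, satisfying the
    structural constraints of the classes (cysteine layout, hexapeptides,
    basic-domain composition).
    """
    text = resources.files("gatascan.data").joinpath(
        "consensus_library.synthetic.fasta").read_text()
    lib: dict[str, str] = {}
    name = None
    for line in text.splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            lib[name] = ""
        elif name:
            lib[name] += line.strip()
    for name, seq in lib.items():
        if len(seq) != conservation.N_COLUMNS:
            raise ValueError(f"library entry {name} is {len(seq)} columns, expected 55")
    return lib


def _dbd_identities(factor: GataFactor, dbd: DBD,
                    lib: Mapping[str, str]) -> dict[str, float]:
    row = conservation.anchor_row(factor.sequence, dbd, factor.protein_id)
    return {cls: conservation.identity_fraction(row.text, lib[cls])
            for cls in SINGLE_FINGER_CLASSES if cls in lib}


def _single_dbd_vote(factor: GataFactor, dbd: DBD, lib: Mapping[str, str],
                     cfg: ClassifyConfig) -> tuple[str, float, list[str]]:
    """Rule-3 decision for one DBD: (label, best identity, evidence)."""
    idents = _dbd_identities(factor, dbd, lib)
    evidence = ["consensus_identity:" +
                ",".join(f"{c}={idents[c]:.3f}" for c in sorted(idents))]
    best = max(idents.values())
    if best < cfg.min_identity:
        evidence.append(f"below_min_identity:best={best:.3f}<{cfg.min_identity}")
        return "ELTX", best, evidence
    winners = sorted(c for c, v in idents.items() if v == best)
    if len(winners) == 1:
        return winners[0], best, evidence
    # tie-breaks: hexapeptide, then intron flags
    if dbd.hexapeptide and _HEX_TO_CLASS.get(dbd.hexapeptide.upper()) in winners:
        label = _HEX_TO_CLASS[dbd.hexapeptide.upper()]
        evidence.append(f"tie_break:hexapeptide={dbd.hexapeptide}")
        return label, best, evidence
    if factor.signature.has_zf_intron and "ELT3" in winners:
        evidence.append("tie_break:zf_intron")
        return "ELT3", best, evidence
    if factor.signature.has_C_basic_intron and "ELT5" in winners:
        evidence.append("tie_break:C_basic_intron")
        return "ELT5", best, evidence
    evidence.append("tie_break:unresolved")
    return "ELTX", best, evidence


def assign_class(factor: GataFactor,
                 lib: Optional[Mapping[str, str]] = None,
                 cfg: ClassifyConfig = DEFAULT_CLASSIFY_CONFIG) -> ClassCall:
    """Assign one of ELT1/ELT2/ELT3/ELT5/ELTX with evidence of rule firings."""
    if lib is None:
        lib = load_default_library()
    dbds = factor.dbds

    if len(dbds) >= 2:
        gaps = [b.finger.c1 - a.finger.c4 - 1 for a, b in zip(dbds, dbds[1:])]
        if any(g <= cfg.tandem_gap for g in gaps):
            evidence = [f"tandem_dbds:n={len(dbds)},gaps={','.join(map(str, gaps))}"]
            score = None
            if "ELT1_C" in lib:
                row = conservation.anchor_row(factor.sequence, dbds[-1], factor.protein_id)
                score = conservation.identity_fraction(row.text, lib["ELT1_C"])
            return ClassCall("ELT1", score, tuple(evidence))

    if len(dbds) == 1 and factor.degenerate_fingers:
        evidence = [f"degenerate_upstream:n={len(factor.degenerate_fingers)}"]
        score = None
        if "ELT2" in lib:
            row = conservation.anchor_row(factor.sequence, dbds[0], factor.protein_id)
            score = conservation.identity_fraction(row.text, lib["ELT2"])
        return ClassCall("ELT2", score, tuple(evidence))

    if len(dbds) == 1:
        label, best, evidence = _single_dbd_vote(factor, dbds[0], lib, cfg)
        return ClassCall(label, best, tuple(evidence))

    # widely spaced multi-DBD factor: unanimous per-DBD vote or ELTX
    votes = [_single_dbd_vote(factor, d, lib, cfg) for d in dbds]
    labels = {v[0] for v in votes}
    evidence = [f"widely_spaced_dbds:n={len(dbds)}"]
    for i, v in enumerate(votes):
        evidence.extend(f"dbd{i}:{e}" for e in v[2])
    score = max(v[1] for v in votes)
    if len(labels) == 1:
        return ClassCall(labels.pop(), score, tuple(evidence))
    evidence.append("dbd_votes_disagree")
    return ClassCall("ELTX", score, tuple(evidence))


def tally_by_class(calls: Sequence[ClassCall],
                   species: Sequence[str]) -> pd.DataFrame:
    """Per-species count table: one row per species, five classes + total."""
    if len(calls) != len(species):
        raise ValueError("calls and species must have equal length")
    table = pd.DataFrame(0, index=sorted(set(species)), columns=list(CLASS_LABELS))
    for call, sp in zip(calls, species):
        table.loc[sp, call.label] += 1
    table["total"] = table.sum(axis=1)
    table.index.name = "species"
    return table
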