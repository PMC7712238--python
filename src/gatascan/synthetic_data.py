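"""Synthetic genomes with planted GATA genes and a truth manifest.

The generator emulates the corpus structure the analysis assumes: multi-
scaffold genomes carrying genes of each of the five structural classes,
built from the same 55-column class templates the classifier uses. Each
class gets its typical architecture — ELT1 two tandem DBDs 29 residues
apart with a poly-serine segment ~25 residues upstream of the amino DBD;
ELT2 a degenerate CX2C-X12-CX2C finger 60 residues upstream of its DBD;
ELT3 a short post-basic tail; ELT5 a long tail; ELTX a divergent DBD
(optionally with the CSNSNC-type variant spacer) — plus the class-typical
landmark introns, paralog pairs at stated separations and orientations,
and planted flank motifs. Proteins are mutated at a per-residue
substitution rate (landmark cysteines and hexapeptides optionally
protected), reverse-translated with uniform synonymous codons, and
embedded on scaffolds of i.i.d. background with configurable GC.

Flanks are scrubbed of chance motif matches so that motif recovery scoring
is unambiguous; everything planted is recorded in a JSON truth manifest.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from . import classify, motif_scan
from .classify import GataFactor, load_default_library
from .domain_scan import (DEFAULT_SCAN_CONFIG, ScanConfig, build_dbds,
                          find_degenerate_fingers, find_gata_fingers, find_polyS)
from .gene_structure import (C_BASIC_INTRON, N_BASIC_INTRON, ZF_INTRON,
                             IntronSignature)
from .motif_scan import MotifHit, scan_flank
from .seq_io import (GeneModel, SequenceRecord, _CODON_TABLE, reverse_complement,
                     write_fasta, write_gff3)

__all__ = [
    "SynthConfig",
    "TruthManifest",
    "SyntheticCorpus",
    "SynthesisError",
    "generate_corpus",
    "mutate_protein",
    "score_recovery",
    "classification_accuracy_study",
    "RecoveryReport",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# C/S/W-free filler so pads and tails can never create spurious fingers,
# poly-serine segments or hexapeptides in unmutated templates.
_PAD_POOL = "MDALNQHEVRGTKPIFYDAVHETKLNRQGIPMAFVDYHLKENRTQGVIPA" * 8

_SYNONYMS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(_CODON_TABLE.items()):
    if _aa != "*":
        _SYNONYMS.setdefault(_aa, ())
        _SYNONYMS[_aa] = _SYNONYMS[_aa] + (_codon,)

_CLASS_PAD = {"ELT1": 20, "ELT2": 40, "ELT3": 15, "ELT5": 25, "ELTX": 30}
_CLASS_TAIL = {"ELT1": 20, "ELT2": 30, "ELT3": 8, "ELT5": 80, "ELTX": 25}
_ELT1_TANDEM_GAP = 29       # C4 of amino finger to C1 of carboxyl finger
_ELT2_DEGEN_LOOP = 12       # within the observed 9-20 range
_ELT2_DEGEN_GAP = 60        # within the observed 34-152 upstream range
_POLYS_RUN = "S" * 10
_POLYS_OFFSET_FROM_DBD = 25

DEFAULT_CLASS_COUNTS: dict[str, int] = {c: 10 for c in classify.CLASS_LABELS}

# per-class planned landmark introns: (finger_index, landmark, codon_offset, phase)
DEFAULT_INTRON_PLAN: dict[str, tuple[tuple[int, str, int, int], ...]] = {
    "ELT1": ((0, "C4", 20, 0), (1, "C4", 8, 0)),
    "ELT2": ((0, "C3", 1, 1),),
    "ELT3": ((0, "C3", 1, 1),),
    "ELT5": ((0, "C4", 8, 0),),
    "ELTX": (),  # intronless, as in several of the divergent extra factors
}

# (class, separation_bp, orientation); mirrors the observed linked-paralog
# band: six pairs at 2.6-35 kbp plus one distant 893 kbp pair, five in the
# same direction and two convergent.
DEFAULT_PARALOG_PLAN: tuple[tuple[str, int, str], ...] = (
    ("ELT3", 2600, "same_direction"),
    ("ELT3", 35000, "same_direction"),
    ("ELT5", 5000, "convergent"),
    ("ELT2", 15000, "same_direction"),
    ("ELT1", 10000, "same_direction"),
    ("ELT5", 20000, "convergent"),
    ("ELT3", 893000, "same_direction"),
)

# per-class planted flank motifs: (flank, kind)
DEFAULT_FLANK_MOTIF_PLAN: dict[str, tuple[tuple[str, str], ...]] = {
    "ELT1": (("five", "polypyrimidine"),),
    "ELT2": (("five", "double_gata"),),
    "ELT3": (("five", "hgatar"),),
    "ELT5": (("five", "polypyrimidine"), ("three", "polypyrimidine")),
    "ELTX": (),
}


class SynthesisError(ValueError):
    """The synthesis plan is infeasible."""


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions of the synthetic corpus.

    Defaults are the conditions the analysis assumes: ten genes per class,
    class-typical architectures and landmark introns, linked paralog pairs
    at the observed separations/orientations, 1000-bp flanks with planted
    motifs, and 42% GC intergenic background.
    """

    seed: int = 0
    class_counts: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    mutation_rate: float = 0.0
    protect_landmarks: bool = True
    intron_plan: Mapping[str, tuple] = field(default_factory=lambda: dict(DEFAULT_INTRON_PLAN))
    intron_len_range: tuple[int, int] = (40, 80)
    paralog_plan: Sequence[tuple[str, int, str]] = DEFAULT_PARALOG_PLAN
    flank_motif_plan: Mapping[str, tuple] = field(default_factory=lambda: dict(DEFAULT_FLANK_MOTIF_PLAN))
    polyS_prob: float = 0.2  # non-ELT1 classes; ELT1 templates always carry one
    gc_background: float = 0.42
    flank_len: int = 1000
    pad_bp: int = 1100
    scaffold_bp: Optional[int] = None  # fixed scaffold size; None = fit contents
    eltx_variant_spacer: bool = True  # first ELTX gene gets the CSNSNC spacer
    species: str = "synthetica"

    def validate(self) -> None:
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise SynthesisError("mutation_rate must be in [0, 1]")
        if not 0.0 <= self.polyS_prob <= 1.0:
            raise SynthesisError("polyS_prob must be in [0, 1]")
        if not 0.0 < self.gc_background < 1.0:
            raise SynthesisError("gc_background must be in (0, 1)")
        if any(v < 0 for v in self.class_counts.values()):
            raise SynthesisError("class counts must be >= 0")
        if self.pad_bp < self.flank_len:
            raise SynthesisError("pad_bp must be >= flank_len so flanks stay on-scaffold")
        counts = dict(self.class_counts)
        for label, _, orientation in self.paralog_plan:
            if orientation not in ("same_direction", "convergent", "divergent"):
                raise SynthesisError(f"unknown pair orientation {orientation!r}")
            counts[label] = counts.get(label, 0) - 2
            if counts[label] < 0:
                raise SynthesisError(f"paralog plan needs more {label} genes than class_counts provides")


# ---------------------------------------------------------------------------
# protein templates

def _template(label: str, lib: Mapping[str, str], with_polyS: bool,
              variant_spacer: bool = False) -> tuple[str, dict]:
    """Class-typical protein template plus its planted-feature coordinates."""
    pad_len = _CLASS_PAD[label]
    parts: list[str] = []
    truth: dict = {"gata_fingers": [], "degenerate_fingers": [], "hexapeptides": []}

    def here() -> int:
        return sum(len(p) for p in parts)

    def add_finger_block(template_row: str, kind_override: Optional[str] = None,
                         spacer_override: Optional[str] = None) -> tuple[int, ...]:
        """Append the 25-residue finger of a 55-column template row."""
        finger = template_row[:25]
        if spacer_override is not None:
            finger = "C" + spacer_override + template_row[3:25]
        start = here()
        c1 = start
        c2 = start + finger.index("C", 1)
        rest = finger[finger.index("C", 1) + 1:]
        c3 = c2 + 1 + rest.index("C")
        c4 = c3 + 3
        parts.append(finger)
        f, loop = c2 - c1 - 1, c3 - c2 - 1
        kind = kind_override or ("gata_canonical" if (f, loop) == (2, 17) else "gata_variant")
        truth["gata_fingers"].append({"kind": kind, "cys_positions": [c1, c2, c3, c4],
                                      "span": [c1, c4 + 1]})
        m = re.search("T.[LA]WRR", finger)
        if m:
            truth["hexapeptides"].append([m.group(0), start + m.start()])
        return c1, c2, c3, c4

    if label == "ELT1":
        parts.append(_PAD_POOL[:pad_len])
        parts.append(_POLYS_RUN)
        parts.append(_PAD_POOL[pad_len:pad_len + _POLYS_OFFSET_FROM_DBD])
        add_finger_block(lib["ELT1_N"])
        parts.append(lib["ELT1_N"][25:25 + _ELT1_TANDEM_GAP])
        add_finger_block(lib["ELT1_C"])
        parts.append(lib["ELT1_C"][25:])
    elif label == "ELT2":
        pad = _PAD_POOL[:pad_len]
        if with_polyS:
            pad = pad[:5] + _POLYS_RUN + pad[5:]
        parts.append(pad)
        dstart = here()
        deg = "C" + "NT" + "C" + "KQEAGHLDNRVI" + "C" + "HK" + "C"
        assert len(deg) == 8 + _ELT2_DEGEN_LOOP
        parts.append(deg)
        truth["degenerate_fingers"].append(
            {"kind": "degenerate",
             "cys_positions": [dstart, dstart + 3, dstart + 4 + _ELT2_DEGEN_LOOP,
                               dstart + 7 + _ELT2_DEGEN_LOOP],
             "span": [dstart, dstart + 8 + _ELT2_DEGEN_LOOP]})
        parts.append(_PAD_POOL[100:100 + _ELT2_DEGEN_GAP])
        add_finger_block(lib["ELT2"])
        parts.append(lib["ELT2"][25:])
    elif label in ("ELT3", "ELT5"):
        pad = _PAD_POOL[:pad_len]
        if with_polyS:
            pad = pad[:5] + _POLYS_RUN + pad[5:]
        parts.append(pad)
        add_finger_block(lib[label])
        parts.append(lib[label][25:])
    elif label == "ELTX":
        pad = _PAD_POOL[:pad_len]
        if with_polyS:
            pad = pad[:5] + _POLYS_RUN + pad[5:]
        parts.append(pad)
        if variant_spacer:
            add_finger_block(lib["ELTX"], spacer_override="SNSN")
        else:
            add_finger_block(lib["ELTX"])
        parts.append(lib["ELTX"][25:])
    else:
        raise SynthesisError(f"unknown class label {label!r}")

    parts.append(_PAD_POOL[200:200 + _CLASS_TAIL[label]])
    protein = "".join(parts)
    truth["polyS"] = [[seg.span[0], seg.span[1], seg.ser_count]
                      for seg in find_polyS(protein)]
    return protein, truth


def _protected_positions(truth: dict) -> set[int]:
    """GATA-finger cysteines plus hexapeptide spans (landmark protection)."""
    protected: set[int] = set()
    for f in truth["gata_fingers"]:
        protected.update(f["cys_positions"])
    for hexa, offset in truth["hexapeptides"]:
        protected.update(range(offset, offset + len(hexa)))
    return protected


def mutate_protein(seq: str, rate: float, protected: set[int],
                   rng: Union[int, np.random.Generator]) -> str:
    """Substitute each unprotected residue with probability ``rate``.

    Substitutions are uniform over the 19 other standard residues.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out = list(seq)
    hits = rng.random(len(seq)) < rate
    for i in np.nonzero(hits)[0]:
        if int(i) in protected:
            continue
        choices = AMINO_ACIDS.replace(out[i].upper(), "")
        out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


# ---------------------------------------------------------------------------
# gene assembly

def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    codons = []
    for aa in protein:
        options = _SYNONYMS.get(aa.upper())
        if options is None:  # ambiguity codes have no codon: use NNN
            codons.append("NNN")
        else:
            codons.append(options[int(rng.integers(len(options)))])
    codons.append("TAA")
    return "".join(codons)


def _intron_cds_offset(cys: int, offset: int, phase: int) -> int:
    if phase == 0:
        return (cys + 1 + offset) * 3
    return (cys + offset) * 3 + phase


def _gene_region(cds: str, intron_offsets: Sequence[int], lens: Sequence[int],
                 rng: np.random.Generator) -> tuple[str, list[tuple[int, int]]]:
    """Interleave introns into the CDS; returns (region, local CDS segments)."""
    offsets = list(intron_offsets)
    if sorted(set(offsets)) != offsets:
        raise SynthesisError("planned intron offsets must be strictly increasing")
    if offsets and (offsets[0] <= 0 or offsets[-1] >= len(cds)):
        raise SynthesisError("planned intron falls outside the CDS")
    parts: list[str] = []
    segments: list[tuple[int, int]] = []
    pos = 0
    cursor = 0
    for off, ilen in zip(offsets, lens):
        exon = cds[pos:off]
        segments.append((cursor, cursor + len(exon)))
        parts.append(exon)
        cursor += len(exon)
        interior = "".join("ACGT"[int(b)] for b in rng.integers(4, size=ilen - 4))
        parts.append("GT" + interior + "AG")
        cursor += ilen
        pos = off
    exon = cds[pos:]
    segments.append((cursor, cursor + len(exon)))
    parts.append(exon)
    return "".join(parts), segments


def _background(n: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


# ---------------------------------------------------------------------------
# flank motif planting and scrubbing

def _flank_base_setter(scaffold: list[str], span: tuple[int, int], reverse: bool):
    """Write a base at flank-local position p (gene orientation) into the scaffold."""
    a, b = span

    def setter(p: int, base: str) -> None:
        if reverse:
            scaffold[b - 1 - p] = reverse_complement(base)
        else:
            scaffold[a + p] = base
    return setter


def _flank_text(scaffold: list[str], span: tuple[int, int], reverse: bool) -> str:
    seg = "".join(scaffold[span[0]:span[1]])
    return reverse_complement(seg) if reverse else seg


def _motif_instance(kind: str, rng: np.random.Generator) -> tuple[str, list[dict]]:
    """A planted motif sequence plus its expected hits at local offset 0."""
    def hgatar() -> str:
        return "ACT"[int(rng.integers(3))] + "GATA" + "AG"[int(rng.integers(2))]

    if kind == "hgatar":
        site = hgatar()
        return site, [{"kind": "hgatar", "start": 0, "end": 6, "strand": "+", "detail": None}]
    if kind == "double_gata":
        spacer = int(rng.integers(2, 13))
        # alternating C/G spacer cannot itself contain a GATA core or a
        # pyrimidine tract, so the planted span needs no interior scrubbing
        inner = ("CG" * 7)[:spacer]
        s1, s2 = hgatar(), hgatar()
        seq = s1 + inner + reverse_complement(s2)
        return seq, [
            {"kind": "hgatar", "start": 0, "end": 6, "strand": "+", "detail": None},
            {"kind": "hgatar", "start": 6 + spacer, "end": 12 + spacer, "strand": "-", "detail": None},
            {"kind": "double_gata", "start": 0, "end": 12 + spacer, "strand": "both", "detail": spacer},
        ]
    if kind == "polypyrimidine":
        seq = "".join("CT"[int(b)] for b in rng.integers(2, size=14))
        return seq, [{"kind": "polypyrimidine", "start": 0, "end": 14, "strand": "+", "detail": 1.0}]
    raise SynthesisError(f"unknown motif kind {kind!r}")


def _hits_as_dicts(hits: Sequence[MotifHit]) -> list[dict]:
    return [{"kind": h.kind, "start": h.start, "end": h.end, "strand": h.strand,
             "detail": h.detail} for h in hits]


def _hit_key(h: Mapping) -> tuple:
    return (h["kind"], h["start"], h["end"], h["strand"])


def _scrub_flank(scaffold: list[str], span: tuple[int, int], reverse: bool,
                 expected: list[dict], planted_span: Optional[tuple[int, int]],
                 planted_kind: Optional[str],
                 rng: np.random.Generator, max_rounds: int = 300) -> list[dict]:
    """Remove chance motif matches so only planted hits remain in the flank.

    Returns the final expected hit list. A planted pyrimidine tract merges
    with qualifying windows that lap onto its neighbours, so its expected
    hit is re-read from the scrubbed flank rather than pre-declared.
    """
    setter = _flank_base_setter(scaffold, span, reverse)
    expected_keys = {_hit_key(h) for h in expected}

    def overlaps_planted(h: Mapping) -> bool:
        return (planted_span is not None
                and h["start"] < planted_span[1] and planted_span[0] < h["end"])

    for _ in range(max_rounds):
        text = _flank_text(scaffold, span, reverse)
        hits = []
        for h in _hits_as_dicts(scan_flank(text)):
            if _hit_key(h) in expected_keys:
                continue
            if h["kind"] == "double_gata":
                continue  # vanishes once its component sites are scrubbed
            if (h["kind"] == "polypyrimidine" and planted_kind == "polypyrimidine"
                    and overlaps_planted(h)):
                continue  # the planted tract itself, merged with its context
            hits.append(h)
        if not hits:
            final = []
            hit_dicts = _hits_as_dicts(scan_flank(text))
            for h in expected:
                if h["kind"] == "polypyrimidine":
                    match = [x for x in hit_dicts
                             if x["kind"] == "polypyrimidine" and overlaps_planted(x)]
                    if len(match) != 1:
                        raise SynthesisError("planted pyrimidine tract not uniquely recoverable")
                    final.append(match[0])
                else:
                    final.append(h)
            return final
        h = hits[0]
        candidates = [p for p in range(h["start"], min(h["end"], span[1] - span[0]))
                      if planted_span is None
                      or not (planted_span[0] <= p < planted_span[1])]
        if not candidates:  # hit entirely inside the planted motif: impossible by design
            raise SynthesisError("cannot scrub a motif overlapping the planted span")
        if h["kind"] == "polypyrimidine":
            changed = False
            for p in candidates:
                if text[p] in "CT":
                    setter(p, "G")
                    changed = True
            if not changed:
                raise SynthesisError("pyrimidine-tract scrub made no progress")
        else:
            p = candidates[len(candidates) // 2]
            pool = [b for b in "ACGT" if b != text[p]]
            setter(p, pool[int(rng.integers(len(pool)))])
    raise SynthesisError("flank scrubbing did not converge")


# ---------------------------------------------------------------------------
# corpus

@dataclass
class TruthManifest:
    """Everything planted, locatable in the emitted FASTA/GFF3 exactly."""

    species: str
    seed: int
    mutation_rate: float
    flank_len: int
    genes: dict[str, dict]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        data = json.loads(text)
        return cls(**data)

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for g in self.genes.values():
            counts[g["label"]] = counts.get(g["label"], 0) + 1
        return counts


@dataclass
class SyntheticCorpus:
    genome: list[SequenceRecord]
    models: list[GeneModel]
    manifest: TruthManifest

    def write(self, outdir: Union[str, Path]) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, outdir / "genome.fasta")
        write_gff3(self.models, outdir / "annotation.gff3")
        (outdir / "truth.json").write_text(self.manifest.to_json() + "\n")


def _planned_signature(label: str, plan: Mapping[str, tuple], n_fingers: int) -> IntronSignature:
    entries = plan.get(label, ())
    keys = {(lm, off, ph) for (_fi, lm, off, ph) in entries}
    first = {(lm, off, ph) for (fi, lm, off, ph) in entries if fi == 0}
    last = {(lm, off, ph) for (fi, lm, off, ph) in entries if fi == n_fingers - 1}
    return IntronSignature(
        has_N_basic_intron=N_BASIC_INTRON in first,
        has_C_basic_intron=C_BASIC_INTRON in last,
        has_zf_intron=ZF_INTRON in keys,
        intronless=not entries,
        extra_introns=0,
    )


def generate_corpus(cfg: SynthConfig = SynthConfig()) -> SyntheticCorpus:
    """Generate (genome FASTA records, gene models, truth manifest).

    Deterministic under ``cfg.seed``: the same configuration and seed give
    byte-identical outputs.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    lib = load_default_library()

    # enumerate genes per class and reserve pair members
    per_class_ids: dict[str, list[str]] = {}
    for label in classify.CLASS_LABELS:
        count = int(cfg.class_counts.get(label, 0))
        per_class_ids[label] = [f"{label}_{i + 1}" for i in range(count)]
    consumed: dict[str, int] = {label: 0 for label in classify.CLASS_LABELS}

    pairs = []
    for pi, (label, sep, orientation) in enumerate(cfg.paralog_plan):
        ids = per_class_ids.get(label, [])
        if consumed.get(label, 0) + 2 > len(ids):
            raise SynthesisError(f"paralog plan needs more {label} genes than class_counts provides")
        a = ids[consumed[label]]
        b = ids[consumed[label] + 1]
        consumed[label] += 2
        pairs.append({"genes": (a, b), "label": label, "separation": int(sep),
                      "orientation": orientation})

    singles = []
    for label in classify.CLASS_LABELS:
        for gid in per_class_ids[label][consumed.get(label, 0):]:
            singles.append((label, gid))

    # build every gene's protein / region first
    built: dict[str, dict] = {}
    eltx_seen = 0
    order = [g for p in pairs for g in p["genes"]] + [gid for _, gid in singles]
    label_of = {}
    for p in pairs:
        for g in p["genes"]:
            label_of[g] = p["label"]
    for label, gid in singles:
        label_of[gid] = label

    for gid in order:
        label = label_of[gid]
        variant = False
        if label == "ELTX" and cfg.eltx_variant_spacer and eltx_seen == 0:
            variant = True
        if label == "ELTX":
            eltx_seen += 1
        with_polyS = label != "ELT1" and rng.random() < cfg.polyS_prob
        protein0, truth = _template(label, lib, with_polyS, variant)
        protected = _protected_positions(truth) if cfg.protect_landmarks else set()
        protein = mutate_protein(protein0, cfg.mutation_rate, protected, rng)
        truth["polyS"] = [[seg.span[0], seg.span[1], seg.ser_count]
                          for seg in find_polyS(protein)]
        cds = _reverse_translate(protein, rng)

        plan_entries = cfg.intron_plan.get(label, ())
        offsets, lens, intron_truth = [], [], []
        for fi, lm, off, ph in plan_entries:
            fingers = truth["gata_fingers"]
            if fi >= len(fingers):
                raise SynthesisError(f"{gid}: intron plan references finger {fi} "
                                     f"but template has {len(fingers)}")
            cys = fingers[fi]["cys_positions"][2 if lm == "C3" else 3]
            cds_off = _intron_cds_offset(cys, off, ph)
            offsets.append(cds_off)
            lens.append(int(rng.integers(cfg.intron_len_range[0], cfg.intron_len_range[1] + 1)))
            intron_truth.append({"codon_index": cds_off // 3, "phase": cds_off % 3,
                                 "finger_index": fi, "landmark": lm,
                                 "codon_offset": off})
        order_idx = np.argsort(offsets) if offsets else []
        offsets = [offsets[i] for i in order_idx]
        lens = [lens[i] for i in order_idx]
        region, segments = _gene_region(cds, offsets, lens, rng)
        sig = _planned_signature(label, cfg.intron_plan, len(truth["gata_fingers"]))
        built[gid] = {"label": label, "protein": protein, "region": region,
                      "segments": segments, "truth": truth,
                      "introns": intron_truth, "signature": sig}

    # scaffold layout
    scaffold_specs: list[dict] = []
    for p in pairs:
        a, b = p["genes"]
        strand_a, strand_b = {"same_direction": ("+", "+"),
                              "convergent": ("+", "-"),
                              "divergent": ("-", "+")}[p["orientation"]]
        scaffold_specs.append({"genes": [(a, strand_a), (b, strand_b)],
                               "separation": p["separation"], "pair": p})
    for i, (label, gid) in enumerate(singles):
        strand = "+" if i % 2 == 0 else "-"
        scaffold_specs.append({"genes": [(gid, strand)], "separation": 0, "pair": None})

    genome: list[SequenceRecord] = []
    models: list[GeneModel] = []
    gene_truth: dict[str, dict] = {}

    for si, spec in enumerate(scaffold_specs):
        name = f"scf_{si + 1:04d}"
        pieces: list[str] = [_background(cfg.pad_bp, cfg.gc_background, rng)]
        placements = []
        for gi, (gid, strand) in enumerate(spec["genes"]):
            if gi > 0:
                pieces.append(_background(spec["separation"], cfg.gc_background, rng))
            region = built[gid]["region"]
            start = sum(len(x) for x in pieces)
            embedded = region if strand == "+" else reverse_complement(region)
            pieces.append(embedded)
            placements.append((gid, strand, start, start + len(region)))
        pieces.append(_background(cfg.pad_bp, cfg.gc_background, rng))
        scaffold = list("".join(pieces))
        if cfg.scaffold_bp is not None:
            if len(scaffold) > cfg.scaffold_bp:
                raise SynthesisError(
                    f"scaffold {name}: contents ({len(scaffold)} bp) exceed "
                    f"scaffold_bp={cfg.scaffold_bp}")
            scaffold += list(_background(cfg.scaffold_bp - len(scaffold),
                                         cfg.gc_background, rng))

        # gene models in scaffold coordinates
        for gid, strand, gstart, gend in placements:
            entry = built[gid]
            region_len = gend - gstart
            if strand == "+":
                segs = [(gstart + s, gstart + e) for s, e in entry["segments"]]
            else:
                segs = [(gstart + region_len - e, gstart + region_len - s)
                        for s, e in entry["segments"]]
            models.append(GeneModel(gene_id=gid, scaffold=name, strand=strand,
                                    cds_segments=sorted(segs),
                                    transcript_id=f"{gid}.t1"))

        # plant and scrub flank motifs
        for gid, strand, gstart, gend in placements:
            entry = built[gid]
            label = entry["label"]
            flank_truth = {"five": [], "three": []}
            for which in ("five", "three"):
                if strand == "+":
                    span = (gstart - cfg.flank_len, gstart) if which == "five" \
                        else (gend, gend + cfg.flank_len)
                    reverse = False
                else:
                    span = (gend, gend + cfg.flank_len) if which == "five" \
                        else (gstart - cfg.flank_len, gstart)
                    reverse = True
                if span[0] < 0 or span[1] > len(scaffold):
                    raise SynthesisError(f"{gid}: flank outside scaffold bounds")
                planted = [k for (w, k) in cfg.flank_motif_plan.get(label, ()) if w == which]
                expected: list[dict] = []
                planted_span = None
                planted_kind = None
                if planted:
                    planted_kind = planted[0]
                    seq, hits = _motif_instance(planted_kind, rng)
                    pos = int(rng.integers(50, cfg.flank_len - len(seq) - 50))
                    setter = _flank_base_setter(scaffold, span, reverse)
                    for i, base in enumerate(seq):
                        setter(pos + i, base)
                    planted_span = (pos, pos + len(seq))
                    for h in hits:
                        expected.append({**h, "start": h["start"] + pos,
                                         "end": h["end"] + pos})
                flank_truth[which] = _scrub_flank(scaffold, span, reverse, expected,
                                                  planted_span, planted_kind, rng)
            entry["flank_motifs"] = flank_truth

        genome.append(SequenceRecord(name, "".join(scaffold),
                                     f"{name} synthetic scaffold"))

        for gid, strand, gstart, gend in placements:
            entry = built[gid]
            pair_info = None
            if spec["pair"] is not None:
                a, b = spec["pair"]["genes"]
                pair_info = {"partner": b if gid == a else a,
                             "separation_bp": spec["pair"]["separation"],
                             "orientation": spec["pair"]["orientation"]}
            sig = entry["signature"]
            gene_truth[gid] = {
                "label": entry["label"], "scaffold": name, "strand": strand,
                "span": [gstart, gend], "protein": entry["protein"],
                "gata_fingers": entry["truth"]["gata_fingers"],
                "degenerate_fingers": entry["truth"]["degenerate_fingers"],
                "hexapeptides": entry["truth"]["hexapeptides"],
                "polyS": entry["truth"]["polyS"],
                "introns": entry["introns"],
                "signature": {"has_N_basic_intron": sig.has_N_basic_intron,
                              "has_C_basic_intron": sig.has_C_basic_intron,
                              "has_zf_intron": sig.has_zf_intron,
                              "intronless": sig.intronless},
                "flank_motifs": entry["flank_motifs"],
                "pair": pair_info,
            }

    manifest = TruthManifest(species=cfg.species, seed=cfg.seed,
                             mutation_rate=cfg.mutation_rate,
                             flank_len=cfg.flank_len, genes=gene_truth)
    return SyntheticCorpus(genome=genome, models=sorted(models, key=lambda m: m.gene_id),
                           manifest=manifest)


# ---------------------------------------------------------------------------
# recovery scoring

@dataclass(frozen=True)
class PrecisionRecall:
    precision: float
    recall: float
    n_predicted: int
    n_true: int


@dataclass
class RecoveryReport:
    features: dict[str, PrecisionRecall]
    confusion: "object"  # pandas DataFrame truth x predicted
    class_accuracy: float


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    if inter == 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


def _match_spans(pred: list[tuple[int, int]], true: list[tuple[int, int]],
                 min_overlap: float = 0.8) -> int:
    """Greedy one-to-one span matching at reciprocal overlap >= 0.8."""
    used: set[int] = set()
    matched = 0
    for p in pred:
        best, best_ov = None, min_overlap
        for ti, t in enumerate(true):
            if ti in used:
                continue
            ov = _reciprocal_overlap(p, t)
            if ov >= best_ov:
                best, best_ov = ti, ov
        if best is not None:
            used.add(best)
            matched += 1
    return matched


def score_recovery(predicted: Mapping[str, Mapping],
                   truth: TruthManifest) -> RecoveryReport:
    """Per-feature precision/recall and a class confusion matrix.

    ``predicted`` maps gene id to a per-gene prediction mapping with keys
    ``label``, span lists ``gata_fingers``/``degenerate_fingers``/``polyS``,
    intron list ``introns`` of (codon_index, phase) and ``flank_motifs``
    (five/three lists of hit dicts) — the shape produced by
    :meth:`gatascan.pipeline.AnnotationResult.by_gene`. Domains match truth
    at >= 80% reciprocal span overlap, introns and motifs match exactly.
    """
    import pandas as pd

    unknown = set(predicted) - set(truth.genes)
    if unknown:
        raise KeyError(f"predicted gene ids not in truth manifest: {sorted(unknown)}")

    tallies = {k: [0, 0, 0] for k in  # matched, n_pred, n_true
               ("gata_fingers", "degenerate_fingers", "polyS", "introns", "motifs")}
    labels = list(classify.CLASS_LABELS) + ["none"]
    confusion = pd.DataFrame(0, index=list(classify.CLASS_LABELS), columns=labels)
    correct = 0

    for gid, true in sorted(truth.genes.items()):
        pred = predicted.get(gid)
        pred_label = pred["label"] if pred else "none"
        confusion.loc[true["label"], pred_label] += 1
        correct += pred_label == true["label"]

        for key in ("gata_fingers", "degenerate_fingers", "polyS"):
            tspans = [tuple(f["span"][:2]) if isinstance(f, dict) else (f[0], f[1])
                      for f in true[key]]
            pspans = [tuple(s) for s in (pred[key] if pred else [])]
            tallies[key][0] += _match_spans(pspans, tspans)
            tallies[key][1] += len(pspans)
            tallies[key][2] += len(tspans)

        t_introns = {(i["codon_index"], i["phase"]) for i in true["introns"]}
        p_introns = set(map(tuple, pred["introns"])) if pred else set()
        tallies["introns"][0] += len(t_introns & p_introns)
        tallies["introns"][1] += len(p_introns)
        tallies["introns"][2] += len(t_introns)

        for which in ("five", "three"):
            t_hits = {_hit_key(h) for h in true["flank_motifs"][which]}
            p_hits = {_hit_key(h) for h in (pred["flank_motifs"][which] if pred else [])}
            tallies["motifs"][0] += len(t_hits & p_hits)
            tallies["motifs"][1] += len(p_hits)
            tallies["motifs"][2] += len(t_hits)

    features = {}
    for key, (matched, n_pred, n_true) in tallies.items():
        features[key] = PrecisionRecall(
            precision=matched / n_pred if n_pred else 1.0,
            recall=matched / n_true if n_true else 1.0,
            n_predicted=n_pred, n_true=n_true)
    n_genes = len(truth.genes)
    return RecoveryReport(features=features, confusion=confusion,
                          class_accuracy=correct / n_genes if n_genes else 1.0)


# ---------------------------------------------------------------------------
# classification accuracy vs mutation rate (protein-level study)

def classification_accuracy_study(rates: Sequence[float] = (0.0, 0.05, 0.10, 0.20),
                                  n_replicates: int = 10,
                                  seed: int = 0,
                                  class_counts: Optional[Mapping[str, int]] = None,
                                  scan_cfg: ScanConfig = DEFAULT_SCAN_CONFIG,
                                  ) -> dict[float, list[float]]:
    """Classification accuracy of template-derived factors vs mutation rate.

    Runs at the protein level (mutated templates plus their planned intron
    signatures); the genome-embedding path is exercised separately by the
    recovery scoring. Returns per-rate lists of replicate accuracies.
    """
    if class_counts is None:
        class_counts = DEFAULT_CLASS_COUNTS
    lib = load_default_library()
    rng = np.random.default_rng(seed)
    out: dict[float, list[float]] = {}
    for rate in rates:
        accs = []
        for _ in range(n_replicates):
            correct = total = 0
            for label in classify.CLASS_LABELS:
                for i in range(int(class_counts.get(label, 0))):
                    variant = label == "ELTX" and i == 0
                    protein0, truth = _template(label, lib, with_polyS=False,
                                                variant_spacer=variant)
                    protein = mutate_protein(protein0, rate,
                                             _protected_positions(truth), rng)
                    dbds = build_dbds(protein, scan_cfg)
                    if not dbds:
                        total += 1
                        continue
                    degs = find_degenerate_fingers(
                        protein, [d.finger for d in dbds], scan_cfg)
                    sig = _planned_signature(label, DEFAULT_INTRON_PLAN,
                                             len(truth["gata_fingers"]))
                    factor = GataFactor(protein_id=label, gene_id=label,
                                        sequence=protein, dbds=dbds,
                                        degenerate_fingers=degs, signature=sig)
                    call = classify.assign_class(factor, lib)
                    correct += call.label == label
                    total += 1
            accs.append(correct / total if total else 1.0)
        out[rate] = accs
    return out
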