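"""End-to-end annotation: genome + gene models -> classified GATA factors.

For every gene model the pipeline assembles and translates the spliced
CDS, scans the protein for GATA-type fingers, basic domains, degenerate
upstream fingers, hexapeptides and poly-serine segments, maps introns to
codon coordinates and cysteine landmarks, assigns one of the five classes,
measures within-class paralog synteny, scans the 5'/3' flanks for the
targeted motifs, and builds per-class anchored DBD alignments with
consensus/conservation statistics. The output bundle is a set of TSV
tables, aligned FASTA exports and a JSON summary; reruns on identical
inputs produce byte-identical bundles.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from . import conservation, diagram
from .classify import (CLASS_LABELS, ClassCall, ClassifyConfig, GataFactor,
                       DEFAULT_CLASSIFY_CONFIG, assign_class, load_default_library,
                       tally_by_class)
from .domain_scan import (DEFAULT_SCAN_CONFIG, ScanConfig, build_dbds,
                          find_degenerate_fingers, find_orphan_degenerate_fingers,
                          find_polyS)
from .gene_structure import describe_introns, intron_signature, map_introns_to_protein
from .motif_scan import scan_flank
from .seq_io import (FlankPair, GeneModel, SequenceRecord, TranslationError,
                     as_genome, extract_flanks, read_fasta, read_gff3, spliced_cds,
                     translate)
from .synteny import find_paralog_pairs, nearby_fraction, pair_table

log = logging.getLogger("gatascan")

MISSING = "."


@dataclass
class RunConfig:
    """Inputs and knobs of one annotation run."""

    genome_path: Optional[Path] = None
    gff3_path: Optional[Path] = None
    proteins_path: Optional[Path] = None
    out_dir: Optional[Path] = None
    flank_len: int = 1000
    species: str = "unknown"
    transcript_policy: str = "longest"
    scan: ScanConfig = DEFAULT_SCAN_CONFIG
    classify: ClassifyConfig = DEFAULT_CLASSIFY_CONFIG
    write_diagrams: bool = False

    def validate(self) -> None:
        have_genome_pair = self.genome_path is not None and self.gff3_path is not None
        if not have_genome_pair and self.proteins_path is None:
            raise ValueError("need either genome+gff3 or a protein FASTA as input")


@dataclass
class AnnotatedFactor:
    """One classified factor with everything derived for it."""

    factor: GataFactor
    call: ClassCall
    model: Optional[GeneModel] = None
    introns: list = field(default_factory=list)
    descriptors: list = field(default_factory=list)
    flanks: Optional[FlankPair] = None
    flank_motifs: dict = field(default_factory=lambda: {"five": [], "three": []})
    orphan_degenerate: list = field(default_factory=list)


@dataclass
class AnnotationResult:
    factors: list[AnnotatedFactor]
    species: str = "unknown"
    qc: list[dict] = field(default_factory=list)

    def by_gene(self) -> dict[str, dict]:
        """Per-gene prediction mapping in the shape recovery scoring expects."""
        out: dict[str, dict] = {}
        for af in self.factors:
            f = af.factor
            out[f.gene_id] = {
                "label": af.call.label,
                "gata_fingers": [list(d.finger.span) for d in f.dbds],
                "degenerate_fingers": [list(z.span) for z in f.degenerate_fingers],
                "polyS": [list(p.span) for p in f.polyS],
                "introns": [[s.codon_index, s.phase] for s in af.introns],
                "flank_motifs": {
                    which: [{"kind": h.kind, "start": h.start, "end": h.end,
                             "strand": h.strand, "detail": h.detail}
                            for h in af.flank_motifs[which]]
                    for which in ("five", "three")},
            }
        return out

    def tally(self) -> pd.DataFrame:
        calls = [af.call for af in self.factors]
        return tally_by_class(calls, [self.species] * len(calls))


def _annotate_protein(protein_id: str, gene_id: str, sequence: str,
                      scan: ScanConfig) -> Optional[GataFactor]:
    dbds = build_dbds(sequence, scan)
    if not dbds:
        return None
    fingers = [d.finger for d in dbds]
    return GataFactor(
        protein_id=protein_id, gene_id=gene_id, sequence=sequence, dbds=dbds,
        degenerate_fingers=find_degenerate_fingers(sequence, fingers, scan),
        polyS=find_polyS(sequence, scan.polyS_window, scan.polyS_min_ser))


def annotate(genome: Optional[Sequence[SequenceRecord]] = None,
             models: Optional[Sequence[GeneModel]] = None,
             proteins: Optional[Sequence[SequenceRecord]] = None,
             cfg: Optional[RunConfig] = None) -> AnnotationResult:
    """Annotate GATA factors from genome+models and/or a proteome.

    When both a proteome and genome-derived translations are available the
    genome-derived translation wins (gene models are needed for introns);
    mismatches are recorded in the QC table.
    """
    cfg = cfg or RunConfig()
    lib = load_default_library()
    qc: list[dict] = []
    factors: list[AnnotatedFactor] = []
    protein_by_id = {p.id: p for p in proteins} if proteins else {}

    if genome is not None and models is not None:
        genome_map = as_genome(genome)
        for gm in models:
            try:
                cds, _ = spliced_cds(gm, genome_map)
                sequence = translate(cds)
            except TranslationError as exc:
                qc.append({"gene_id": gm.gene_id, "issue": f"translation_failed:{exc}"})
                continue
            supplied = protein_by_id.get(gm.gene_id) or protein_by_id.get(gm.transcript_id or "")
            if supplied and supplied.seq.upper() != sequence.upper():
                qc.append({"gene_id": gm.gene_id,
                           "issue": "supplied_protein_mismatch:genome_translation_used"})
            factor = _annotate_protein(gm.transcript_id or gm.gene_id, gm.gene_id,
                                       sequence, cfg.scan)
            if factor is None:
                continue
            sites = map_introns_to_protein(gm)
            fingers = [d.finger for d in factor.dbds]
            descriptors = describe_introns(sites, fingers)
            factor.signature = intron_signature(descriptors, len(sites), len(fingers))
            flanks = extract_flanks(gm, genome_map, cfg.flank_len)
            motifs = {"five": scan_flank(flanks.five_prime),
                      "three": scan_flank(flanks.three_prime)}
            call = assign_class(factor, lib, cfg.classify)
            factors.append(AnnotatedFactor(
                factor=factor, call=call, model=gm, introns=sites,
                descriptors=descriptors, flanks=flanks, flank_motifs=motifs,
                orphan_degenerate=find_orphan_degenerate_fingers(
                    factor.sequence, fingers, cfg.scan)))
    elif proteins is not None:
        for rec in proteins:
            factor = _annotate_protein(rec.id, rec.id, rec.seq, cfg.scan)
            if factor is None:
                continue
            call = assign_class(factor, lib, cfg.classify)
            factors.append(AnnotatedFactor(factor=factor, call=call))
    else:
        raise ValueError("annotate needs genome+models or proteins")

    factors.sort(key=lambda af: af.factor.gene_id)
    if not factors:
        log.info("no GATA factors found in input")
    return AnnotationResult(factors=factors, species=cfg.species, qc=qc)


# ---------------------------------------------------------------------------
# tables

def factor_table(result: AnnotationResult) -> pd.DataFrame:
    rows = []
    for af in result.factors:
        f, c = af.factor, af.call
        sig = f.signature
        rows.append({
            "protein_id": f.protein_id, "gene_id": f.gene_id, "class": c.label,
            "score": f"{c.score:.3f}" if c.score is not None else MISSING,
            "length": f.length, "n_DBDs": len(f.dbds),
            "n_degenerate": len(f.degenerate_fingers),
            "polyS": ";".join(f"{s.span[0]}-{s.span[1]}" for s in f.polyS) or MISSING,
            "hexapeptides": ";".join(d.hexapeptide for d in f.dbds if d.hexapeptide) or MISSING,
            "N_basic_intron": sig.has_N_basic_intron,
            "C_basic_intron": sig.has_C_basic_intron,
            "zf_intron": sig.has_zf_intron,
            "intronless": sig.intronless,
            "evidence": "|".join(c.evidence),
        })
    return pd.DataFrame(rows, columns=[
        "protein_id", "gene_id", "class", "score", "length", "n_DBDs",
        "n_degenerate", "polyS", "hexapeptides", "N_basic_intron",
        "C_basic_intron", "zf_intron", "intronless", "evidence"])


def domain_table(result: AnnotationResult) -> pd.DataFrame:
    rows = []
    for af in result.factors:
        f = af.factor
        for d in f.dbds:
            rows.append({"protein_id": f.protein_id, "domain_type": d.finger.kind,
                         "start": d.finger.span[0], "end": d.basic.span[1],
                         "cys_positions": ",".join(map(str, d.finger.cys_positions)),
                         "hexapeptide": d.hexapeptide or MISSING,
                         "truncated_basic": d.basic.truncated})
        for z in f.degenerate_fingers + af.orphan_degenerate:
            rows.append({"protein_id": f.protein_id, "domain_type": z.kind,
                         "start": z.span[0], "end": z.span[1],
                         "cys_positions": ",".join(map(str, z.cys_positions)),
                         "hexapeptide": MISSING, "truncated_basic": False})
        for s in f.polyS:
            rows.append({"protein_id": f.protein_id, "domain_type": "polyS",
                         "start": s.span[0], "end": s.span[1],
                         "cys_positions": MISSING, "hexapeptide": MISSING,
                         "truncated_basic": False})
    return pd.DataFrame(rows, columns=["protein_id", "domain_type", "start", "end",
                                       "cys_positions", "hexapeptide", "truncated_basic"])


def intron_table(result: AnnotationResult) -> pd.DataFrame:
    rows = []
    for af in result.factors:
        for i, site in enumerate(af.introns):
            descs = [d for d in af.descriptors if d.intron_index == i]
            rows.append({
                "gene_id": af.factor.gene_id, "intron": i,
                "scaffold": site.genomic[0], "donor": site.genomic[1],
                "acceptor": site.genomic[2], "codon_index": site.codon_index,
                "phase": site.phase,
                "landmarks": ";".join(
                    f"f{d.finger_index}:{d.landmark}{d.codon_offset:+d}/ph{d.phase}"
                    for d in descs) or MISSING})
    return pd.DataFrame(rows, columns=["gene_id", "intron", "scaffold", "donor",
                                       "acceptor", "codon_index", "phase", "landmarks"])


def motif_table(result: AnnotationResult) -> pd.DataFrame:
    rows = []
    for af in result.factors:
        for which in ("five", "three"):
            for h in af.flank_motifs[which]:
                rows.append({"gene_id": af.factor.gene_id,
                             "flank": "5'" if which == "five" else "3'",
                             "kind": h.kind, "start": h.start, "end": h.end,
                             "strand": h.strand,
                             "detail": MISSING if h.detail is None else h.detail})
    return pd.DataFrame(rows, columns=["gene_id", "flank", "kind", "start", "end",
                                       "strand", "detail"])


def class_alignments(result: AnnotationResult) -> dict[str, conservation.AnchoredAlignment]:
    """Per-class anchored alignment of every DBD (ELT1 split into N/C rows)."""
    groups: dict[str, list] = {}
    for af in result.factors:
        f = af.factor
        if af.call.label == "ELT1" and len(f.dbds) >= 2:
            groups.setdefault("ELT1_N", []).append((f.protein_id + "/N", f.dbds[0], f.sequence))
            groups.setdefault("ELT1_C", []).append((f.protein_id + "/C", f.dbds[-1], f.sequence))
        else:
            for i, d in enumerate(f.dbds):
                sid = f.protein_id if len(f.dbds) == 1 else f"{f.protein_id}/{i}"
                groups.setdefault(af.call.label, []).append((sid, d, f.sequence))
    return {name: conservation.anchor_align(entries)
            for name, entries in sorted(groups.items())}


def conservation_table(alignments: Mapping[str, conservation.AnchoredAlignment]
                       ) -> pd.DataFrame:
    rows = []
    for name, aln in sorted(alignments.items()):
        if len(aln) < 2:
            continue
        cons = conservation.consensus(aln)
        for mode in ("absolute", "majority"):
            k, n, frac = conservation.conservation_count(aln, mode)
            rows.append({"group": name, "n_rows": len(aln), "mode": mode,
                         "conserved": k, "columns": n, "fraction": round(frac, 4),
                         "consensus": cons})
    return pd.DataFrame(rows, columns=["group", "n_rows", "mode", "conserved",
                                       "columns", "fraction", "consensus"])


# ---------------------------------------------------------------------------
# bundle

def run_annotate(cfg: RunConfig) -> AnnotationResult:
    """Run the full pipeline from files and write the output bundle."""
    cfg.validate()
    genome = read_fasta(cfg.genome_path) if cfg.genome_path else None
    models = read_gff3(cfg.gff3_path, cfg.transcript_policy) if cfg.gff3_path else None
    proteins = read_fasta(cfg.proteins_path) if cfg.proteins_path else None
    result = annotate(genome, models, proteins, cfg)
    if cfg.out_dir is not None:
        write_bundle(result, cfg.out_dir, write_diagrams=cfg.write_diagrams)
    return result


def write_bundle(result: AnnotationResult, out_dir: Union[str, Path],
                 write_diagrams: bool = False) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    factor_table(result).to_csv(out / "factors.tsv", sep="\t", index=False)
    domain_table(result).to_csv(out / "domains.tsv", sep="\t", index=False)
    intron_table(result).to_csv(out / "introns.tsv", sep="\t", index=False)
    motif_table(result).to_csv(out / "motifs.tsv", sep="\t", index=False)

    entries = [(result.species, af.call.label, af.model)
               for af in result.factors if af.model is not None]
    pairs = find_paralog_pairs(entries)
    pair_table(pairs).to_csv(out / "synteny.tsv", sep="\t", index=False)

    alignments = class_alignments(result)
    (out / "alignments").mkdir(exist_ok=True)
    for name, aln in sorted(alignments.items()):
        conservation.export_alignment(aln, out / "alignments" / f"{name}.aln.fasta")
    conservation_table(alignments).to_csv(out / "conservation.tsv", sep="\t", index=False)

    pd.DataFrame(result.qc, columns=["gene_id", "issue"]).to_csv(
        out / "qc.tsv", sep="\t", index=False)

    tally = result.tally()
    summary = {
        "schema_version": 1,
        "species": result.species,
        "n_factors": len(result.factors),
        "class_tallies": {sp: {c: int(tally.loc[sp, c]) for c in tally.columns}
                          for sp in tally.index},
        "n_paralog_pairs": len(pairs),
        "paralog_nearby_fraction": round(nearby_fraction(pairs), 4),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")

    if write_diagrams:
        (out / "diagrams").mkdir(exist_ok=True)
        for af in result.factors:
            svg = diagram.render_diagram(af.factor, introns=af.introns)
            (out / "diagrams" / f"{af.factor.gene_id}.svg").write_text(svg)
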