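"""FASTA/GFF3 I/O, spliced-CDS assembly, translation and flank extraction.

All internal coordinates are 0-based half-open in scaffold space; GFF3's
1-based inclusive convention is converted at the parsing/writing boundary.
Minus-strand gene products are always reported in transcription (gene
reading) orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import gffutils
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

log = logging.getLogger("gatascan")

__all__ = [
    "SequenceRecord",
    "GeneModel",
    "FlankPair",
    "FastaError",
    "GffError",
    "TranslationError",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "spliced_cds",
    "translate",
    "extract_flanks",
    "reverse_complement",
]


class FastaError(ValueError):
    """Malformed or inconsistent FASTA input."""


class GffError(ValueError):
    """Malformed or inconsistent GFF3 input."""


class TranslationError(ValueError):
    """CDS cannot be translated cleanly (e.g. internal stop codon)."""


@dataclass
class SequenceRecord:
    """A single FASTA record (nucleotide or amino-acid)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaError("sequence record with empty id")
        if not self.seq:
            raise FastaError(f"sequence record {self.id!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GeneModel:
    """Scaffold-anchored CDS structure of one transcript.

    ``cds_segments`` are 0-based half-open intervals in scaffold coordinates,
    sorted ascending regardless of strand.
    """

    gene_id: str
    scaffold: str
    strand: str
    cds_segments: list[tuple[int, int]]
    transcript_id: Optional[str] = None
    source_line_numbers: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GffError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.cds_segments:
            raise GffError(f"{self.gene_id}: gene model with no CDS segments")
        segs = sorted(tuple(s) for s in self.cds_segments)
        for start, end in segs:
            if end <= start:
                raise GffError(f"{self.gene_id}: empty or inverted CDS segment ({start},{end})")
        for (s0, e0), (s1, e1) in zip(segs, segs[1:]):
            if s1 < e0:
                raise GffError(f"{self.gene_id}: overlapping CDS segments ({s0},{e0}) and ({s1},{e1})")
        if sum(e - s for s, e in segs) < 3:
            raise GffError(f"{self.gene_id}: total CDS length < 3")
        self.cds_segments = segs

    @property
    def span(self) -> tuple[int, int]:
        """(min start, max end) over all CDS segments."""
        return self.cds_segments[0][0], self.cds_segments[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_segments)


@dataclass
class FlankPair:
    """Up-to-n-bp flanks of a gene, both in gene-reading orientation."""

    gene_id: str
    five_prime: str
    three_prime: str
    five_prime_truncated: bool = False
    three_prime_truncated: bool = False


_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
                            "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: Union[str, Path]) -> list[SequenceRecord]:
    """Read a multi-record FASTA file.

    Raises :class:`FastaError` on duplicate ids or an empty file. Case is
    preserved; downstream comparisons are case-insensitive.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq), rec.description))
    if not records:
        raise FastaError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: Union[str, Path], width: int = 60) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id,
                      description=r.description[len(r.id):].strip() if r.description.startswith(r.id) else r.description)
        for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(bio)


def as_genome(records: Iterable[SequenceRecord]) -> dict[str, SequenceRecord]:
    """Index records by id for use as a genome mapping."""
    return {r.id: r for r in records}


# ---------------------------------------------------------------------------
# GFF3

def _prescan_gff3(path: Union[str, Path]) -> dict[tuple[str, int, int], list[int]]:
    """Validate coordinate fields line by line; return CDS line numbers.

    gffutils does not keep source line numbers, so this cheap pass both
    produces the line-numbered error messages required for malformed input
    and records provenance for CDS features keyed by (seqid, start, end).
    """
    cds_lines: dict[tuple[str, int, int], list[int]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise GffError(f"{path}: line {lineno}: expected >= 8 tab-separated fields")
            try:
                start = int(fields[3])
                end = int(fields[4])
            except ValueError:
                raise GffError(f"{path}: line {lineno}: non-integer coordinates "
                               f"{fields[3]!r}/{fields[4]!r}") from None
            if start < 1 or end < start:
                raise GffError(f"{path}: line {lineno}: invalid coordinate range {start}..{end}")
            if fields[2] == "CDS":
                cds_lines.setdefault((fields[0], start, end), []).append(lineno)
    return cds_lines


def _expected_phases(segments: Sequence[tuple[int, int]], strand: str) -> list[int]:
    """GFF3 phase per segment derived purely from CDS coordinates."""
    ordered = list(segments) if strand == "+" else list(reversed(segments))
    phases, cum = [], 0
    for s, e in ordered:
        phases.append((3 - cum % 3) % 3)
        cum += e - s
    if strand == "-":
        phases.reverse()
    return phases


def read_gff3(path: Union[str, Path], transcript_policy: str = "longest") -> list[GeneModel]:
    """Parse CDS features grouped by Parent transcript into GeneModels.

    ``transcript_policy`` selects among multiple transcripts of one gene:
    ``longest`` (largest total CDS, ties by transcript id), ``first-id``
    (lexicographically first transcript id) or ``all`` (keep every one).
    The GFF3 phase column is ignored for splicing but validated when
    present; mismatches are logged as model-quality warnings.
    """
    if transcript_policy not in ("longest", "first-id", "all"):
        raise ValueError(f"unknown transcript policy {transcript_policy!r}")
    cds_lines = _prescan_gff3(path)
    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)

    transcript_gene: dict[str, str] = {}
    for ftype in ("mRNA", "transcript"):
        try:
            feats = list(db.features_of_type(ftype))
        except Exception:
            feats = []
        for t in feats:
            parents = t.attributes.get("Parent", [])
            transcript_gene[t.id] = parents[0] if parents else t.id

    # group CDS segments by parent transcript
    by_parent: dict[str, list] = {}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent") or [cds.id]
        for p in parents:
            by_parent.setdefault(p, []).append(cds)

    models: list[GeneModel] = []
    for parent, feats in by_parent.items():
        scaffolds = {f.seqid for f in feats}
        strands = {f.strand for f in feats}
        if len(scaffolds) > 1:
            raise GffError(f"transcript {parent}: CDS segments on multiple scaffolds {sorted(scaffolds)}")
        if len(strands) > 1:
            raise GffError(f"transcript {parent}: CDS segments on mixed strands")
        strand = strands.pop()
        if strand not in ("+", "-"):
            raise GffError(f"transcript {parent}: CDS without strand")
        segments = sorted((f.start - 1, f.end) for f in feats)
        lines = sorted(n for f in feats for n in cds_lines.get((f.seqid, f.start, f.end), []))
        gene_id = transcript_gene.get(parent, parent)
        model = GeneModel(gene_id=gene_id, scaffold=scaffolds.pop() if scaffolds else feats[0].seqid,
                          strand=strand, cds_segments=segments,
                          transcript_id=parent, source_line_numbers=lines)
        # phase validation (coordinates win; mismatch is a model-quality flag)
        expected = _expected_phases(model.cds_segments, strand)
        stated = []
        for f in sorted(feats, key=lambda f: f.start):
            stated.append(f.frame)
        for (s, e), exp, got in zip(model.cds_segments, expected, stated):
            if got not in (".", "", None) and int(got) != exp:
                log.warning("gene model %s: CDS %d..%d states phase %s, derived %d",
                            parent, s, e, got, exp)
        models.append(model)

    if transcript_policy == "all":
        return sorted(models, key=lambda m: (m.gene_id, m.transcript_id or ""))

    by_gene: dict[str, list[GeneModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    chosen = []
    for gene, ms in by_gene.items():
        if transcript_policy == "longest":
            ms.sort(key=lambda m: (-m.cds_length, m.transcript_id or ""))
        else:  # first-id
            ms.sort(key=lambda m: m.transcript_id or "")
        chosen.append(ms[0])
    return sorted(chosen, key=lambda m: m.gene_id)


def write_gff3(models: Iterable[GeneModel], path: Union[str, Path]) -> None:
    """Emit gene/mRNA/CDS features (1-based inclusive) for the given models."""
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for m in sorted(models, key=lambda m: (m.scaffold, m.span[0], m.gene_id)):
            tid = m.transcript_id or f"{m.gene_id}.t1"
            start, end = m.span
            out.write(f"{m.scaffold}\tgatascan\tgene\t{start + 1}\t{end}\t.\t{m.strand}\t.\t"
                      f"ID={m.gene_id}\n")
            out.write(f"{m.scaffold}\tgatascan\tmRNA\t{start + 1}\t{end}\t.\t{m.strand}\t.\t"
                      f"ID={tid};Parent={m.gene_id}\n")
            phases = _expected_phases(m.cds_segments, m.strand)
            for (s, e), ph in zip(m.cds_segments, phases):
                out.write(f"{m.scaffold}\tgatascan\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t{ph}\t"
                          f"ID=cds:{tid};Parent={tid}\n")


# ---------------------------------------------------------------------------
# sequence assembly

def _scaffold_seq(genome: Mapping[str, Union[SequenceRecord, str]], name: str) -> str:
    try:
        entry = genome[name]
    except KeyError:
        raise GffError(f"scaffold {name!r} not present in genome") from None
    return entry.seq if isinstance(entry, SequenceRecord) else str(entry)


def spliced_cds(gm: GeneModel,
                genome: Mapping[str, Union[SequenceRecord, str]],
                ) -> tuple[str, list[tuple[int, int]]]:
    """Assemble the spliced CDS and list the introns between CDS segments.

    Returns ``(cds, introns)`` where the CDS is in transcription orientation
    (reverse-complemented for minus-strand genes) and introns are
    (donor, acceptor) scaffold intervals, 0-based half-open, listed in
    transcription order.
    """
    seq = _scaffold_seq(genome, gm.scaffold)
    for s, e in gm.cds_segments:
        if s < 0 or e > len(seq):
            raise GffError(f"{gm.gene_id}: CDS segment ({s},{e}) outside scaffold "
                           f"{gm.scaffold} (length {len(seq)})")
    cds = "".join(seq[s:e] for s, e in gm.cds_segments)
    introns = [(e0, s1) for (_, e0), (s1, _) in zip(gm.cds_segments, gm.cds_segments[1:])]
    if gm.strand == "-":
        cds = reverse_complement(cds)
        introns = introns[::-1]
    return cds, introns


_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"


def translate(cds: str, on_internal_stop: str = "error") -> str:
    """Translate a CDS with the standard genetic code.

    A trailing incomplete codon is dropped with a logged warning and a
    terminal stop codon is removed. Codons containing ambiguity codes
    translate to ``X``. An internal stop raises :class:`TranslationError`
    unless ``on_internal_stop='truncate'``, which truncates at the stop
    (mirroring manual gene-model repair) with a logged warning.
    """
    if len(cds) < 3:
        raise TranslationError(f"CDS of length {len(cds)} is shorter than one codon")
    if on_internal_stop not in ("error", "truncate"):
        raise ValueError(f"on_internal_stop must be 'error' or 'truncate', got {on_internal_stop!r}")
    if len(cds) % 3:
        log.warning("dropping trailing incomplete codon of %d nt", len(cds) % 3)
    upper = cds.upper().replace("U", "T")
    protein = []
    n_codons = len(cds) // 3
    for i in range(n_codons):
        codon = upper[3 * i:3 * i + 3]
        aa = _CODON_TABLE.get(codon, "X")
        if aa == "*":
            if i == n_codons - 1:
                break  # terminal stop removed
            if on_internal_stop == "truncate":
                log.warning("internal stop at codon %d: truncating translation", i)
                break
            raise TranslationError(f"internal stop codon at codon index {i}")
        protein.append(aa)
    return "".join(protein)


def extract_flanks(gm: GeneModel,
                   genome: Mapping[str, Union[SequenceRecord, str]],
                   n: int = 1000) -> FlankPair:
    """Extract up to ``n`` bp of 5' and 3' flanking sequence.

    Flanks are reported in gene-reading orientation (reverse-complemented
    for minus-strand genes) and truncated at scaffold ends with the
    corresponding flag set; truncation is not an error.
    """
    if n < 1:
        raise ValueError(f"flank length must be >= 1, got {n}")
    seq = _scaffold_seq(genome, gm.scaffold)
    start, end = gm.span
    left = seq[max(0, start - n):start]
    right = seq[end:end + n]
    left_trunc = start < n
    right_trunc = end + n > len(seq)
    if gm.strand == "+":
        return FlankPair(gm.gene_id, left, right, left_trunc, right_trunc)
    return FlankPair(gm.gene_id, reverse_complement(right), reverse_complement(left),
                     right_trunc, left_trunc)
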