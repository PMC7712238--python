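import random

import pytest
from Bio.Seq import Seq

from gatascan.seq_io import (FastaError, GeneModel, GffError, TranslationError,
                             extract_flanks, read_fasta, read_gff3,
                             reverse_complement, spliced_cds, translate,
                             write_fasta, write_gff3, SequenceRecord)


def test_read_fasta_single_record(tmp_path):
    p = tmp_path / "a.fasta"
    p.write_text(">s1\nACGT\n")
    records = read_fasta(p)
    assert [(r.id, r.seq) for r in records] == [("s1", "ACGT")]


def test_read_fasta_duplicate_id_error(tmp_path):
    p = tmp_path / "dup.fasta"
    p.write_text(">s1\nACGT\n>s1\nTTTT\n")
    with pytest.raises(FastaError, match="s1"):
        read_fasta(p)


def test_read_fasta_empty_file_error(tmp_path):
    p = tmp_path / "empty.fasta"
    p.write_text("")
    with pytest.raises(FastaError):
        read_fasta(p)


def test_fasta_round_trip_100_random_records(tmp_path):
    rng = random.Random(0)
    records = [SequenceRecord(f"r{i}", "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 200))))
               for i in range(100)]
    p = tmp_path / "rt.fasta"
    write_fasta(records, p)
    back = read_fasta(p)
    assert [(r.id, r.seq) for r in back] == [(r.id, r.seq) for r in records]


GFF_ONE_GENE = """##gff-version 3
scf1\tsrc\tgene\t101\t260\t.\t+\t.\tID=g1
scf1\tsrc\tmRNA\t101\t260\t.\t+\t.\tID=g1.t1;Parent=g1
scf1\tsrc\tCDS\t201\t260\t.\t+\t0\tID=c1;Parent=g1.t1
scf1\tsrc\tCDS\t101\t130\t.\t+\t0\tID=c1;Parent=g1.t1
"""


def test_gff3_coordinate_conversion_and_sorting(tmp_path):
    p = tmp_path / "one.gff3"
    p.write_text(GFF_ONE_GENE)
    models = read_gff3(p)
    assert len(models) == 1
    gm = models[0]
    # CDS lines given out of order are sorted; 1-based inclusive -> 0-based half-open
    assert gm.cds_segments == [(100, 130), (200, 260)]
    assert gm.gene_id == "g1" and gm.strand == "+"


def test_gff3_malformed_coordinates_reports_line_number(tmp_path):
    p = tmp_path / "bad.gff3"
    p.write_text("##gff-version 3\nscf1\tsrc\tCDS\tfoo\t130\t.\t+\t0\tParent=t1\n")
    with pytest.raises(GffError, match="line 2"):
        read_gff3(p)


def test_gff3_mixed_strands_error(tmp_path):
    p = tmp_path / "mixed.gff3"
    p.write_text("##gff-version 3\n"
                 "scf1\tsrc\tCDS\t1\t30\t.\t+\t0\tID=c;Parent=t1\n"
                 "scf1\tsrc\tCDS\t61\t90\t.\t-\t0\tID=c;Parent=t1\n")
    with pytest.raises(GffError, match="mixed strands"):
        read_gff3(p)


MULTI_TRANSCRIPT = """##gff-version 3
scf1\tsrc\tgene\t1\t300\t.\t+\t.\tID=g1
scf1\tsrc\tmRNA\t1\t300\t.\t+\t.\tID=g1.a;Parent=g1
scf1\tsrc\tmRNA\t1\t300\t.\t+\t.\tID=g1.b;Parent=g1
scf1\tsrc\tCDS\t1\t30\t.\t+\t0\tID=ca;Parent=g1.a
scf1\tsrc\tCDS\t1\t90\t.\t+\t0\tID=cb;Parent=g1.b
"""


def test_transcript_policy_selection(tmp_path):
    p = tmp_path / "multi.gff3"
    p.write_text(MULTI_TRANSCRIPT)
    longest = read_gff3(p, "longest")
    assert [m.transcript_id for m in longest] == ["g1.b"]
    first = read_gff3(p, "first-id")
    assert [m.transcript_id for m in first] == ["g1.a"]
    both = read_gff3(p, "all")
    assert sorted(m.transcript_id for m in both) == ["g1.a", "g1.b"]


def test_gff3_round_trip_identity(tmp_path):
    rng = random.Random(1)
    models = []
    for i in range(20):
        pos = rng.randint(0, 50)
        segs = []
        for _ in range(rng.randint(1, 5)):
            length = rng.randint(3, 60)
            segs.append((pos, pos + length))
            pos += length + rng.randint(10, 50)
        models.append(GeneModel(f"g{i}", f"scf{i % 3}", rng.choice("+-"), segs))
    p = tmp_path / "rt.gff3"
    write_gff3(models, p)
    back = read_gff3(p)
    orig = {m.gene_id: m for m in models}
    assert len(back) == len(models)
    for m in back:
        o = orig[m.gene_id]
        assert (m.scaffold, m.strand, m.cds_segments) == (o.scaffold, o.strand, o.cds_segments)


def test_spliced_cds_plus_strand():
    genome = {"s": SequenceRecord("s", "AAACCCGGGTTTAAACCC")}
    gm = GeneModel("g", "s", "+", [(0, 6), (12, 18)])
    cds, introns = spliced_cds(gm, genome)
    assert cds == "AAACCCAAACCC"
    assert introns == [(6, 12)]


def test_spliced_cds_minus_strand_is_reverse_complement():
    genome = {"s": SequenceRecord("s", "AAACCCGGGTTTAAACCC")}
    gm = GeneModel("g", "s", "-", [(0, 6), (12, 18)])
    cds, introns = spliced_cds(gm, genome)
    assert cds == reverse_complement("AAACCC" + "AAACCC")
    assert introns == [(6, 12)]


def test_spliced_cds_out_of_bounds_error():
    genome = {"s": SequenceRecord("s", "AAACCC")}
    gm = GeneModel("g", "s", "+", [(0, 12)])
    with pytest.raises(GffError, match="outside scaffold"):
        spliced_cds(gm, genome)


def test_spliced_cds_reinserting_introns_reconstructs_genomic_span():
    rng = random.Random(7)
    for _ in range(50):
        scaffold = "".join(rng.choice("ACGT") for _ in range(600))
        pos = rng.randint(0, 20)
        segs = []
        for _ in range(5):
            length = rng.randint(3, 40)
            segs.append((pos, pos + length))
            pos += length + rng.randint(5, 30)
        strand = rng.choice("+-")
        gm = GeneModel("g", "s", strand, segs)
        genome = {"s": SequenceRecord("s", scaffold)}
        cds, introns = spliced_cds(gm, genome)
        assert len(cds) == gm.cds_length
        # rebuild the genomic span from the CDS pieces plus intron sequence
        scaffold_order_cds = cds if strand == "+" else reverse_complement(cds)
        pieces, offset = [], 0
        for i, (s, e) in enumerate(gm.cds_segments):
            pieces.append(scaffold_order_cds[offset:offset + e - s])
            offset += e - s
            if i + 1 < len(gm.cds_segments):
                pieces.append(scaffold[e:gm.cds_segments[i + 1][0]])
        span = gm.span
        assert "".join(pieces) == scaffold[span[0]:span[1]]


def test_translate_basic_and_terminal_stop():
    assert translate("ATGGCCTAA") == "MA"


def test_translate_internal_stop_error_and_truncate():
    with pytest.raises(TranslationError, match="codon index 1"):
        translate("ATGTAAGCC")
    assert translate("ATGTAAGCC", on_internal_stop="truncate") == "M"


def test_translate_ambiguous_codons_are_X():
    assert translate("ATGANNGGG") == "MXG"


def test_translate_matches_biopython_on_random_orfs():
    rng = random.Random(11)
    stops = {"TAA", "TAG", "TGA"}
    codons = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
              if a + b + c not in stops]
    for _ in range(1000):
        cds = "".join(rng.choice(codons) for _ in range(rng.randint(1, 40)))
        assert translate(cds + "TAA") == str(Seq(cds).translate())


def test_extract_flanks_truncation_at_scaffold_start():
    genome = {"s": SequenceRecord("s", "A" * 2000)}
    gm = GeneModel("g", "s", "+", [(400, 700)])
    flanks = extract_flanks(gm, genome, 1000)
    assert len(flanks.five_prime) == 400
    assert flanks.five_prime_truncated
    assert len(flanks.three_prime) == 1000
    assert not flanks.three_prime_truncated


def test_extract_flanks_minus_strand_orientation():
    seq = "".join(random.Random(3).choice("ACGT") for _ in range(500))
    genome = {"s": SequenceRecord("s", seq)}
    gm = GeneModel("g", "s", "-", [(200, 260)])
    flanks = extract_flanks(gm, genome, 100)
    assert flanks.five_prime == reverse_complement(seq[260:360])
    assert flanks.three_prime == reverse_complement(seq[100:200])
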