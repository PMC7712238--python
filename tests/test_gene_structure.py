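import random

import pytest

from gatascan.domain_scan import find_gata_fingers
from gatascan.gene_structure import (C_BASIC_INTRON, N_BASIC_INTRON, ZF_INTRON,
                                     IntronSite, describe_introns, intron_signature,
                                     landmark_offset, map_introns_to_protein)
from gatascan.seq_io import GeneModel, SequenceRecord, reverse_complement, spliced_cds, translate

FINGER = "C" + "VN" + "C" + "GATATPLWRRDGTGNYL" + "C" + "NA" + "C"  # 25 aa canonical

# fixed reverse-translation so tests control every nucleotide
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


def encode(protein):
    return "".join(_CODON[aa] for aa in protein) + "TAA"


def make_gene(protein, intron_cds_offsets, strand="+", intron_len=50, pad=100):
    """Embed a CDS with introns at the given spliced-CDS nucleotide offsets."""
    cds = encode(protein)
    assert all(0 < o < len(cds) for o in intron_cds_offsets)
    pieces, segments, cursor, prev = [], [], pad, 0
    for off in sorted(intron_cds_offsets):
        exon = cds[prev:off]
        segments.append((cursor, cursor + len(exon)))
        pieces.append(exon)
        cursor += len(exon)
        pieces.append("GT" + "A" * (intron_len - 4) + "AG")
        cursor += intron_len
        prev = off
    exon = cds[prev:]
    segments.append((cursor, cursor + len(exon)))
    pieces.append(exon)
    region = "".join(pieces)
    scaffold = "T" * pad + region + "T" * pad
    if strand == "-":
        total = len(scaffold)
        scaffold = reverse_complement(scaffold)
        segments = sorted((total - e, total - s) for s, e in segments)
    gm = GeneModel("g", "s", strand, segments)
    return gm, {"s": SequenceRecord("s", scaffold)}


def test_codon_index_and_phase_basic_examples():
    protein = "M" * 30
    # intron after 30 nt -> between codons 10 and 11
    gm, _ = make_gene(protein, [30])
    sites = map_introns_to_protein(gm)
    assert [(s.codon_index, s.phase) for s in sites] == [(10, 0)]
    gm, _ = make_gene(protein, [31])
    assert [(s.codon_index, s.phase) for s in map_introns_to_protein(gm)] == [(10, 1)]


def landmark_nt_offset(cys, codon_offset, phase):
    """Independent arithmetic: spliced-CDS offset of a planted landmark intron."""
    if phase == 0:
        return (cys + 1 + codon_offset) * 3
    return (cys + codon_offset) * 3 + phase


@pytest.mark.parametrize("landmark,offset,phase", [
    ("C4", 20, 0),  # amino basic-domain intron
    ("C4", 8, 0),   # carboxyl basic-domain intron
    ("C3", 1, 1),   # zinc-finger intron, 1 bp after the C3 codon
])
def test_named_landmark_introns_recovered(landmark, offset, phase):
    protein = "G" * 10 + FINGER + "K" * 40
    finger = find_gata_fingers(protein)[0]
    cys = finger.c3 if landmark == "C3" else finger.c4
    gm, genome = make_gene(protein, [landmark_nt_offset(cys, offset, phase)])
    cds, _ = spliced_cds(gm, genome)
    assert translate(cds) == protein
    site = map_introns_to_protein(gm)[0]
    d = landmark_offset(site, finger, landmark)
    assert (d.landmark, d.codon_offset, d.phase) == (landmark, offset, phase)
    assert not d.non_canonical


def test_plant_and_recover_200_random_choices():
    rng = random.Random(23)
    protein = "G" * 12 + FINGER + "K" * 45
    finger = find_gata_fingers(protein)[0]
    for _ in range(200):
        landmark = rng.choice(["C3", "C4"])
        offset = rng.randint(0, 30)
        phase = rng.randint(0, 2)
        strand = rng.choice("+-")
        cys = finger.c3 if landmark == "C3" else finger.c4
        gm, genome = make_gene(protein, [landmark_nt_offset(cys, offset, phase)],
                               strand=strand, intron_len=rng.randint(20, 80))
        cds, _ = spliced_cds(gm, genome)
        assert translate(cds) == protein
        site = map_introns_to_protein(gm)[0]
        d = landmark_offset(site, finger, landmark)
        assert (d.codon_offset, d.phase) == (offset, phase)


def test_strand_invariance_of_descriptors():
    protein = "G" * 10 + FINGER + "K" * 40
    finger = find_gata_fingers(protein)[0]
    off = landmark_nt_offset(finger.c4, 8, 0)
    gm_p, genome_p = make_gene(protein, [off], strand="+")
    gm_m, genome_m = make_gene(protein, [off], strand="-")
    d_p = [(s.codon_index, s.phase) for s in map_introns_to_protein(gm_p)]
    d_m = [(s.codon_index, s.phase) for s in map_introns_to_protein(gm_m)]
    assert d_p == d_m
    assert translate(spliced_cds(gm_p, genome_p)[0]) == translate(spliced_cds(gm_m, genome_m)[0])


def test_intron_five_prime_of_landmark_is_non_canonical():
    protein = "G" * 10 + FINGER + "K" * 40
    finger = find_gata_fingers(protein)[0]
    gm, _ = make_gene(protein, [9])  # intron well before the finger
    site = map_introns_to_protein(gm)[0]
    d = landmark_offset(site, finger, "C4")
    assert d.non_canonical
    assert d.codon_offset < 0


def test_signature_flags_and_membership_oracle():
    protein = "G" * 10 + FINGER + "K" * 40
    finger = find_gata_fingers(protein)[0]
    offs = [landmark_nt_offset(finger.c4, 20, 0), landmark_nt_offset(finger.c4, 8, 0)]
    gm, _ = make_gene(protein, offs)
    sites = map_introns_to_protein(gm)
    descs = describe_introns(sites, [finger])
    sig = intron_signature(descs, len(sites), 1)
    assert sig.has_N_basic_intron and sig.has_C_basic_intron
    assert not sig.has_zf_intron and not sig.intronless
    assert sig.extra_introns == 0
    # membership oracle over the descriptor keys
    keys = {d.key for d in descs}
    assert sig.has_N_basic_intron == (N_BASIC_INTRON in keys)
    assert sig.has_C_basic_intron == (C_BASIC_INTRON in keys)
    assert sig.has_zf_intron == (ZF_INTRON in keys)


def test_intronless_signature():
    sig = intron_signature([], 0, 1)
    assert sig.intronless
    assert not (sig.has_N_basic_intron or sig.has_C_basic_intron or sig.has_zf_intron)


def test_extra_intron_counted():
    protein = "G" * 10 + FINGER + "K" * 40
    finger = find_gata_fingers(protein)[0]
    offs = [landmark_nt_offset(finger.c4, 8, 0), 9]
    gm, _ = make_gene(protein, offs)
    sites = map_introns_to_protein(gm)
    sig = intron_signature(describe_introns(sites, [finger]), len(sites), 1)
    assert sig.has_C_basic_intron
    assert sig.extra_introns == 1


def test_landmark_slop_option():
    site = IntronSite(codon_index=100, phase=0, genomic=("s", 0, 1))
    finger = find_gata_fingers("G" * 10 + FINGER + "K" * 90)[0]
    # plant an intron 9 codons after C4 (one codon off the C-basic landmark)
    protein = "G" * 10 + FINGER + "K" * 90
    gm, _ = make_gene(protein, [landmark_nt_offset(finger.c4, 9, 0)])
    sites = map_introns_to_protein(gm)
    descs = describe_introns(sites, [finger])
    assert not intron_signature(descs, 1, 1).has_C_basic_intron
    assert intron_signature(descs, 1, 1, slop=1).has_C_basic_intron
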