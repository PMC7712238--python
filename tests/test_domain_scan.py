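import random
import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gatascan.domain_scan import (DEFAULT_SCAN_CONFIG, ScanConfig, build_dbds,
                                  find_basic_domain, find_degenerate_fingers,
                                  find_gata_fingers, find_hexapeptide, find_polyS)

CANONICAL = "M" + "C" + "AA" + "C" + "A" * 17 + "C" + "AA" + "C" + "K" * 30


def brute_force_fingers(seq, spacer_range=(2, 4), loop_range=(16, 19)):
    """Independent oracle: exhaustive quadruple enumeration + same overlap rule."""
    seq = seq.upper()
    quads = []
    n = len(seq)
    for i in range(n):
        if seq[i] != "C":
            continue
        for j in range(i + 1, n):
            if seq[j] != "C" or not (spacer_range[0] <= j - i - 1 <= spacer_range[1]):
                continue
            for k in range(j + 1, n):
                if seq[k] != "C" or not (loop_range[0] <= k - j - 1 <= loop_range[1]):
                    continue
                m = k + 3
                if m < n and seq[m] == "C":
                    quads.append((i, j, k, m))
    chosen = []
    while quads:
        best = min(quads, key=lambda q: (q[0], -q[3]))
        chosen.append(best)
        quads = [q for q in quads if q[0] > best[3] or q[3] < best[0]]
    return sorted(chosen)


def test_constructed_canonical_finger():
    fingers = find_gata_fingers(CANONICAL)
    assert len(fingers) == 1
    f = fingers[0]
    assert f.cys_positions == (1, 4, 22, 25)
    assert f.kind == "gata_canonical"
    assert (f.first_spacer_len, f.loop_len) == (2, 17)


def test_csnsnc_variant_spacer_accepted():
    seq = "M" + "CSNSNC" + "A" * 17 + "C" + "AA" + "C" + "K" * 30
    fingers = find_gata_fingers(seq)
    assert len(fingers) == 1
    assert fingers[0].kind == "gata_variant"
    assert fingers[0].first_spacer_len == 4


def test_scanner_equals_bruteforce_on_random_sequences():
    rng = random.Random(5)
    alphabet = "ACDEFGHIKLMNPQRSTVWY" + "C" * 4  # boost cysteine frequency
    for _ in range(100):
        seq = "".join(rng.choice(alphabet) for _ in range(400))
        got = sorted(f.cys_positions for f in find_gata_fingers(seq))
        assert got == brute_force_fingers(seq)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.text(alphabet="ACDGKLSTX", min_size=0, max_size=120))
def test_reported_cysteines_are_literally_C(seq):
    for f in find_gata_fingers(seq):
        for pos in f.cys_positions:
            assert seq[pos].upper() == "C"


def test_basic_domain_full_and_fraction():
    basic = find_basic_domain(CANONICAL, find_gata_fingers(CANONICAL)[0])
    assert basic.observed_len == 30
    assert basic.basic_fraction == 1.0
    assert not basic.truncated


def test_basic_domain_truncated_at_protein_end():
    seq = "M" + "C" + "AA" + "C" + "A" * 17 + "C" + "AA" + "C" + "K" * 13
    basic = find_basic_domain(seq, find_gata_fingers(seq)[0])
    assert basic.observed_len == 13
    assert basic.truncated


def test_basic_fraction_matches_hand_count():
    rng = random.Random(9)
    for _ in range(50):
        tail = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(rng.randint(0, 40)))
        seq = "M" + "C" + "AA" + "C" + "A" * 17 + "C" + "AA" + "C" + tail
        basic = find_basic_domain(seq, find_gata_fingers(seq)[0])
        window = tail[:30]
        expected = sum(1 for aa in window if aa in "KR") / len(window) if window else 0.0
        assert basic.basic_fraction == pytest.approx(expected)


DEG = "C" + "AA" + "C" + "A" * 12 + "C" + "AA" + "C"


def test_degenerate_upstream_of_gata_finger():
    seq = "M" + DEG + "G" * 60 + CANONICAL[1:]
    gata = find_gata_fingers(seq)
    assert len(gata) == 1
    degs = find_degenerate_fingers(seq, gata)
    assert len(degs) == 1
    assert degs[0].kind == "degenerate"
    assert degs[0].loop_len == 12


def test_degenerate_downstream_is_rejected():
    seq = CANONICAL + "G" * 60 + DEG
    gata = find_gata_fingers(seq)
    assert find_degenerate_fingers(seq, gata) == []


@pytest.mark.parametrize("loop,accepted", [(9, True), (20, True), (8, False), (21, False)])
def test_degenerate_loop_bounds(loop, accepted):
    deg = "C" + "AA" + "C" + "A" * loop + "C" + "AA" + "C"
    seq = "M" + deg + "G" * 60 + CANONICAL[1:]
    gata = find_gata_fingers(seq)
    degs = find_degenerate_fingers(seq, gata)
    assert bool(degs) == accepted


def test_degenerate_beyond_max_upstream_gap_rejected():
    seq = "M" + DEG + "G" * 250 + CANONICAL[1:]
    gata = find_gata_fingers(seq)
    assert find_degenerate_fingers(seq, gata) == []


def test_hexapeptide_examples():
    window = "AAAATTAWRRAAA"
    assert find_hexapeptide(window, (0, len(window))) == ("TTAWRR", 4)
    assert find_hexapeptide("AAAATPLWRAAAA", (0, 13)) is None


def test_hexapeptide_matches_regex_oracle():
    rng = random.Random(13)
    for _ in range(200):
        window = "".join(rng.choice("TALWRPG") for _ in range(40))
        got = find_hexapeptide(window, (0, len(window)))
        m = re.search("T.[LA]WRR", window)
        assert got == ((m.group(0), m.start()) if m else None)


def brute_force_polyS(seq, window=10, min_ser=6):
    qualifying = [(i, i + window) for i in range(len(seq) - window + 1)
                  if seq[i:i + window].upper().count("S") >= min_ser]
    merged = []
    for s, e in qualifying:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def test_polyS_worked_example():
    segments = find_polyS("AAAAASSSSSSAAAAA")
    assert [(s.span, s.ser_count) for s in segments] == [((1, 15), 6)]


def test_polyS_five_serines_not_enough():
    assert find_polyS("SSSSS" + "A" * 20) == []


def test_polyS_matches_bruteforce():
    rng = random.Random(17)
    for _ in range(200):
        seq = "".join(rng.choice("SSSAAG") for _ in range(rng.randint(0, 80)))
        got = [s.span for s in find_polyS(seq)]
        assert got == brute_force_polyS(seq)
        for seg in find_polyS(seq):
            assert seq[seg.span[0]:seg.span[1]].count("S") == seg.ser_count


def test_polyS_segments_never_overlap():
    rng = random.Random(19)
    for _ in range(100):
        seq = "".join(rng.choice("SA") for _ in range(100))
        segs = find_polyS(seq)
        for a, b in zip(segs, segs[1:]):
            # adjacent qualifying windows merge, so gaps are strict
            assert b.span[0] > a.span[1]


def test_scan_is_deterministic():
    seq = CANONICAL * 3
    assert find_gata_fingers(seq) == find_gata_fingers(seq)
    assert build_dbds(seq) == build_dbds(seq)


def test_x_never_matches_c_or_s():
    assert find_gata_fingers("M" + "X" + "AA" + "X" + "A" * 17 + "X" + "AA" + "X") == []
    assert find_polyS("XXXXXXXXXX") == []
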