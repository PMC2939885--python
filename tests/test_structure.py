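"""Quadripartite detection, junction context, repeats, small inversions."""

import numpy as np
import pytest

from oracles import brute_force_repeats, suppress_contained_brute
from plastidkit._seq import random_dna, revcomp, rotate
from plastidkit.genome import ExonPart, GeneModel
from plastidkit.structure import (
    detect_quadripartite,
    find_repeats,
    find_small_inversions,
    hairpin_score,
    junction_report,
)
from plastidkit.synthetic_data import GenomeSpec, simulate_genome
from plastidkit.tables import PSAB_SMALL_INVERSION, PSAB_SMALL_INVERSION_ACORUS


# -- quadripartite ----------------------------------------------------------


def test_layout_round_trip(small_genome):
    lay = detect_quadripartite(small_genome.seq, min_ir_len=500)
    assert (lay.lsc_len, lay.ssc_len, lay.ir_len) == (2000, 600, 800)
    assert lay.total == len(small_genome.seq)


def test_random_sequence_has_no_structure():
    seq = random_dna(np.random.default_rng(5), 10000, 0.6)
    assert detect_quadripartite(seq, min_ir_len=1000) is None


def test_rotation_invariance(small_genome):
    rng = np.random.default_rng(6)
    base = detect_quadripartite(small_genome.seq, min_ir_len=500)
    for _ in range(4):
        k = int(rng.integers(1, len(small_genome.seq)))
        lay = detect_quadripartite(rotate(small_genome.seq, k), min_ir_len=500)
        assert (lay.lsc_len, lay.ssc_len, lay.ir_len) == (
            base.lsc_len, base.ssc_len, base.ir_len,
        )


def test_junction_positions_on_canonical_rotation(small_genome):
    lay = detect_quadripartite(small_genome.seq, min_ir_len=500)
    assert lay.junctions == {"JLB": 2000, "JSB": 2800, "JSA": 3400, "JLA": 4200}


# -- junction report --------------------------------------------------------


def _layout(small_genome):
    return detect_quadripartite(small_genome.seq, min_ir_len=500)


def test_gene_spanning_jsb_reports_55bp_overlap(small_genome):
    lay = _layout(small_genome)
    jsb = lay.junctions["JSB"]  # last base of IRb, 1-based
    gene = GeneModel("ndhF_like", [ExonPart(jsb - 55, jsb + 300, "-", 1)], "-")
    rows = junction_report(lay, [gene])
    jsb_rows = {r.side: r for r in rows if r.junction == "JSB"}
    assert jsb_rows["right"].overlap == 55
    assert jsb_rows["right"].distance is None


def test_gene_ending_exactly_at_jlb_distance_zero(small_genome):
    lay = _layout(small_genome)
    jlb = lay.junctions["JLB"]
    gene = GeneModel("g", [ExonPart(jlb - 200, jlb, "+", 1)], "+")
    rows = {r.side: r for r in junction_report(lay, [gene]) if r.junction == "JLB"}
    assert rows["left"].distance == 0
    assert rows["left"].overlap is None


def test_randomized_annotation_matches_interval_scan(small_genome):
    rng = np.random.default_rng(9)
    lay = _layout(small_genome)
    n = len(small_genome.seq)
    genes = []
    for i in range(12):
        a = int(rng.integers(0, n - 400))
        b = a + int(rng.integers(50, 400))
        genes.append(GeneModel(f"g{i}", [ExonPart(a, b, "+", 1)], "+"))
    rows = junction_report(lay, genes)
    for name, j1 in lay.junctions.items():
        c = j1 % n
        spanning = [g for g in genes if g.span[0] < c < g.span[1]]
        left = next(r for r in rows if r.junction == name and r.side == "left")
        if spanning:
            want = max(spanning, key=lambda g: g.span[1])
            assert left.gene == want.name and left.overlap == want.span[1] - c
        else:
            dist, want = min(((c - g.span[1]) % n, g) for g in genes)
            assert left.gene == want.name and left.distance == dist


def test_empty_annotation_warns(small_genome):
    with pytest.warns(UserWarning):
        assert junction_report(_layout(small_genome), []) == []


# -- repeats ----------------------------------------------------------------


def test_exact_planted_30mer_forward_pair():
    rng = np.random.default_rng(10)
    unit = random_dna(rng, 30, 0.5)
    s = random_dna(rng, 200, 0.6) + unit + random_dna(rng, 100, 0.6) + unit
    hits = find_repeats(s, min_len=30, max_mismatch=0)
    exact = [h for h in hits if h.unit_len == 30 and h.type == "F"]
    assert any(h.mismatches == 0 for h in exact)


def test_39mer_with_three_substitutions_reported_with_four_dropped():
    rng = np.random.default_rng(11)
    unit = random_dna(rng, 39, 0.5)
    for n_subs, expect_full in ((3, True), (4, False)):
        copy = list(unit)
        for k in range(n_subs):
            p = 5 + 8 * k
            copy[p] = "A" if copy[p] != "A" else "C"
        s = (random_dna(rng, 80, 0.6) + unit + random_dna(rng, 60, 0.6)
             + "".join(copy) + random_dna(rng, 80, 0.6))
        hits = find_repeats(s, min_len=30, max_mismatch=3)
        full = [h for h in hits if h.unit_len >= 39 and h.type == "F"]
        assert bool(full) == expect_full


def test_inverted_repeat_with_location_classes(small_genome):
    from plastidkit.structure import classify_location

    rng = np.random.default_rng(12)
    unit = random_dna(rng, 35, 0.4)
    g1, g2 = small_genome.genes[:2]
    seq = list(small_genome.seq)
    p1 = g1.span[0] + 6
    p2 = g2.span[0] + 6
    seq[p1 : p1 + 35] = list(unit)
    seq[p2 : p2 + 35] = list(revcomp(unit))
    hits = find_repeats("".join(seq), min_len=30, max_mismatch=3,
                        annotation=small_genome.genes)
    # the maximal hit may extend past the planted unit within the
    # mismatch budget; require a hit whose copies contain the plants
    inv = [
        h for h in hits if h.type == "I"
        and h.start1 - 1 <= p1 and p1 + 35 <= h.start1 - 1 + h.unit_len
        and h.start2 - 1 <= p2 and p2 + 35 <= h.start2 - 1 + h.unit_len
    ]
    assert inv
    # the planted intervals themselves classify to the two gene loci
    assert classify_location(p1, p1 + 35, small_genome.genes) == g1.name
    assert classify_location(p2, p2 + 35, small_genome.genes) == g2.name


def test_exclude_suppresses_pairs_inside_masked_intervals():
    rng = np.random.default_rng(13)
    unit = random_dna(rng, 32, 0.5)
    s = unit + random_dna(rng, 50, 0.6) + unit + random_dna(rng, 50, 0.6)
    masked = find_repeats(s, min_len=30, max_mismatch=0,
                          exclude=[(0, len(unit)), (82, 82 + len(unit))])
    assert not any(
        h.start1 == 1 and h.start2 == 83 for h in masked
    )


def test_repeats_equal_brute_force_oracle_random_and_planted():
    rng = np.random.default_rng(14)
    for trial in range(12):
        n = int(rng.integers(150, 450))
        s = random_dna(rng, n, 0.63)
        if trial % 3 == 0:
            unit = random_dna(rng, 25, 0.5)
            s = s[:20] + unit + s[45 : n - 60] + revcomp(unit) + s[n - 35 :]
        got = {(h.type, h.start1, h.start2, h.unit_len)
               for h in find_repeats(s, min_len=18, max_mismatch=3)}
        want = suppress_contained_brute(
            brute_force_repeats(s, min_len=18, max_mismatch=3)
        )
        assert got == want


# -- small inversions -------------------------------------------------------


def test_psab_hairpin_geometry():
    res = find_small_inversions(PSAB_SMALL_INVERSION, stem_range=(5, 24),
                                max_loop=50)
    sis = res.all()
    assert len(sis) == 1
    si = sis[0]
    assert (si.stem_len, si.loop_len) == (13, 37)
    assert si.end - si.start + 1 == 63


def test_no_inverted_repeat_no_si():
    # alternating purine-only sequence cannot pair with itself
    res = find_small_inversions("AG" * 60, stem_range=(11, 24))
    assert res.all() == []


def test_si_geometry_invariant_on_simulated_genome(small_genome):
    res = find_small_inversions(small_genome.seq, stem_range=(11, 24))
    for si in res.all():
        assert si.end - si.start + 1 == 2 * si.stem_len + si.loop_len
        stem5 = si.sequence[: si.stem_len]
        stem3 = si.sequence[-si.stem_len :]
        assert stem5 == revcomp(stem3)


def test_planted_si_recovered_at_planted_coordinates(small_genome):
    res = find_small_inversions(small_genome.seq, stem_range=(11, 24))
    truth = small_genome.truth["sis"][0]
    match = [si for si in res.all()
             if si.start == truth["start"] and si.stem_len == truth["stem"]]
    assert len(match) == 1
    assert match[0].loop_len == truth["loop"]


def test_homology_splits_confirmed_and_putative():
    # 29 planted hairpins in a purine-only background (A/G cannot base-pair
    # with itself, so the background contributes no stems); homologous
    # comparator spans exist for nine of them
    from plastidkit.synthetic_data import _make_hairpin

    rng = np.random.default_rng(51)
    geometries = [(13, 37)] * 9 + [(12, 20)] * 10 + [(15, 30)] * 10
    spans = [_make_hairpin(rng, stem, loop, 0.6) for stem, loop in geometries]

    def purine(n):
        return "".join("AG"[int(i)] for i in rng.integers(0, 2, n))

    pieces = []
    for span in spans:
        pieces.append(purine(120))
        pieces.append(span)
    pieces.append(purine(120))
    seq = "".join(pieces)

    comp = purine(100) + purine(100).join(spans[:9]) + purine(100)
    res = find_small_inversions(
        seq, stem_range=(11, 24), comparators=[("other", comp)]
    )
    assert len(res.confirmed) == 9
    assert len(res.putative) == 20


# -- hairpin score ----------------------------------------------------------


def test_all_gc_stem_loop4_scores_minus_39():
    stem = "G" * 13
    span = stem + "AAAA" + revcomp(stem)
    assert hairpin_score(span, stem_len=13) == -39.0


def test_score_is_deterministic():
    assert hairpin_score(PSAB_SMALL_INVERSION) == hairpin_score(
        PSAB_SMALL_INVERSION
    )


def test_phoenix_more_stable_than_acorus():
    phoenix = hairpin_score(PSAB_SMALL_INVERSION, stem_len=13)
    acorus = hairpin_score(PSAB_SMALL_INVERSION_ACORUS, stem_len=13,
                           max_mismatch=3)
    assert phoenix < acorus


def test_overbudget_stem_rejected():
    span = "AAAAAAAAAAAA" + "CCCC" + "AAAAAAAAAAAA"  # stem cannot pair
    assert hairpin_score(span, stem_len=12) == float("inf")
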