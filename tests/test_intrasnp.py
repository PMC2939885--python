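"""Pileup construction, heteroplasmy calling, classification, comparison."""

import numpy as np
import pandas as pd
import pytest

from plastidkit._seq import revcomp
from plastidkit.align import Alignment, map_reads
from plastidkit.assemble import HomopolymerRun, find_homopolymers
from plastidkit.codonstats import CdsRecord, extract_cds
from plastidkit.genome import ExonPart, GeneModel
from plastidkit.intrasnp import (
    IndelCall,
    Pileup,
    SnpCall,
    build_pileup,
    call_intra_indels,
    call_intrasnps,
    classify_snp,
    compare_genotypes,
    genotype_percentages,
    mutation_class,
)
from plastidkit.io import FastqRead
from plastidkit.synthetic_data import (
    GenomeSpec,
    HeteroplasmySpec,
    ReadSimConfig,
    simulate_genome,
    simulate_reads,
)
from plastidkit.tables import coding_intrasnps


def _aln(seq, start, quals=None, cigar=None, name="r"):
    return Alignment(
        query_name=name,
        ref_start=start,
        strand="+",
        cigar=cigar or [("=", len(seq))],
        seq=seq,
        quals=quals or [35] * len(seq),
        edit_distance=0,
    )


# -- pileup -----------------------------------------------------------------


def test_identical_reads_stack_on_reference():
    genome = "ACGTACGTACGT"
    alns = [_aln(genome[2:10], 2, name=f"r{i}") for i in range(10)]
    pile = build_pileup(alns, genome)
    col = pile.column(5)
    assert col.base_counts == {"A": 10}  # genome[4] on the plus strand
    assert col.gap_reads == 0


def test_low_quality_bases_excluded():
    genome = "ACGTACGT"
    quals = [35, 35, 10, 35]  # third base at Q10 <= 20 -> dropped
    pile = build_pileup([_aln(genome[0:4], 0, quals=quals)], genome)
    assert pile.column(3).base_counts == {}
    assert pile.column(2).base_counts == {"C": 1}


def test_deletion_counts_as_gap_only():
    genome = "ACGTACGTAC"
    # read matches 4, deletes 2 ref bases, matches 4
    aln = _aln("ACGTGTAC", 0, cigar=[("=", 4), ("D", 2), ("=", 4)])
    pile = build_pileup([aln], genome)
    assert pile.column(5).gap_reads == 1
    assert pile.column(5).base_counts == {}
    assert pile.column(4).base_counts == {"T": 1}


def test_alignment_past_linear_end_raises():
    with pytest.raises(ValueError):
        build_pileup([_aln("ACGT", 100)], "ACGTACGT")


def test_planted_minor_fraction_recovered_in_pileup():
    g = simulate_genome(GenomeSpec(lsc_len=1500, ssc_len=400, ir_len=300, seed=19))
    pos = 700
    major = g.seq[pos - 1]
    minor = "A" if major != "A" else "C"
    frac = 0.125
    het = HeteroplasmySpec(sites=[(pos, major, minor, frac)])
    cfg = ReadSimConfig(depth=330, mean_len=330, hp_error_rate=0.0,
                        sub_error_rate=0.0, seed=23)
    reads, _ = simulate_reads(g, cfg, het)
    pile = build_pileup(map_reads(reads, g.seq), g.seq)
    col = pile.column(pos)
    depth = col.depth_q
    got = col.base_counts.get(minor, 0)
    sd = np.sqrt(depth * frac * (1 - frac))
    assert abs(got - depth * frac) <= 3 * sd


# -- calling rules ----------------------------------------------------------


def _pile_with_column(counts, n=101, pos=51):
    pile = Pileup(n)
    for base, c in counts.items():
        pile.counts[pos - 1, "ACGT".index(base)] = c
    return pile


def test_table_style_counts_produce_published_percentages():
    pile = _pile_with_column({"C": 863, "T": 124})
    (call,) = call_intrasnps(pile)
    assert (call.major, call.minor) == ("C", "T")
    assert (call.major_pct, call.minor_pct) == (87.4, 12.6)
    assert call.mutation_class == "transition"


def test_depth_exactly_50_is_rejected():
    pile = _pile_with_column({"A": 40, "C": 10})  # depth exactly 50
    assert call_intrasnps(pile) == []


def test_minor_at_5_percent_rejected():
    pile = _pile_with_column({"A": 950, "C": 50})
    assert call_intrasnps(pile) == []


def test_minor_exactly_10_percent_rejected_strict():
    pile = _pile_with_column({"A": 900, "C": 100})
    assert call_intrasnps(pile) == []


def test_no_call_inside_homopolymer_mask():
    pile = _pile_with_column({"A": 800, "C": 200}, pos=51)
    mask = [HomopolymerRun("A", 45, 9)]  # covers 45..53 (+1 flank)
    assert call_intrasnps(pile, hp_mask=mask) == []
    # same column outside the mask is called
    assert len(call_intrasnps(pile, hp_mask=[HomopolymerRun("A", 5, 9)])) == 1


def test_simulation_recovers_all_planted_sites_none_in_masks():
    g = simulate_genome(
        GenomeSpec(lsc_len=2600, ssc_len=500, ir_len=300, seed=29,
                   homopolymer_plants=[("A", 9), ("T", 8)])
    )
    rng = np.random.default_rng(31)
    runs = find_homopolymers(g.seq, 5)
    forbidden = set()
    for r in runs:
        forbidden.update(range(r.start - 3, r.end + 4))
    sites = []
    want = {}
    fracs = [0.12, 0.2, 0.25, 0.3, 0.39] * 4
    while len(sites) < 20:
        pos = int(rng.integers(100, 2500))
        if pos in forbidden or pos in want:
            continue
        major = g.seq[pos - 1]
        minor = "ACGT"["ACGT".index(major) - 1]
        frac = fracs[len(sites)]
        sites.append((pos, major, minor, frac))
        want[pos] = (minor, frac)
    het = HeteroplasmySpec(sites=sites)
    cfg = ReadSimConfig(depth=800, mean_len=350, hp_error_rate=0.02,
                        sub_error_rate=0.002, seed=37)
    reads, _ = simulate_reads(g, cfg, het)
    pile = build_pileup(map_reads(reads, g.seq), g.seq)
    calls = call_intrasnps(pile, hp_mask=runs)
    by_pos = {c.position: c for c in calls}
    for pos, (minor, frac) in want.items():
        assert pos in by_pos, f"planted site {pos} not recovered"
        assert by_pos[pos].minor == minor
    mask = set()
    for r in runs:
        mask.update(range(r.start - 1, r.end + 2))
    assert not any(c.position in mask for c in calls)


def test_transition_transversion_partition():
    assert mutation_class("A", "G") == "transition"
    assert mutation_class("C", "T") == "transition"
    assert mutation_class("A", "C") == "transversion"
    assert mutation_class("G", "T") == "transversion"


# -- classification ---------------------------------------------------------


def _genome_with_plus_gene(cds, offset=9):
    seq = "GCGCGCGCG" + cds + "GCGCGCGCG"
    gene = GeneModel("g", [ExonPart(offset, offset + len(cds), "+", 1)], "+")
    return seq, gene


def test_synonymous_transition_like_psba_row():
    # codon ACC -> ACT at its third position: Thr(Thr), C<->T transition
    cds = "ATG" + "ACC" + "TAA"
    seq, gene = _genome_with_plus_gene(cds)
    call = SnpCall(position=9 + 6, major="C", minor="T", major_n=863,
                   minor_n=124, major_pct=87.4, minor_pct=12.6,
                   mutation_class=mutation_class("C", "T"))
    classify_snp(call, [gene], seq)
    (ctx,) = call.contexts
    assert ctx.major_codon == "acC" and ctx.minor_codon == "acT"
    assert ctx.effect == "synonymous"
    assert (ctx.major_aa, ctx.minor_aa) == ("Thr", "Thr")
    assert call.mutation_class == "transition"


def test_nonsense_like_rpoc2_row():
    # codon TTA -> TGA at its second position: Leu -> stop
    cds = "ATG" + "TTA" + "AAA" + "TAA"
    seq, gene = _genome_with_plus_gene(cds)
    call = SnpCall(position=9 + 5, major="T", minor="G", major_n=789,
                   minor_n=99, major_pct=88.9, minor_pct=11.1,
                   mutation_class=mutation_class("T", "G"))
    classify_snp(call, [gene], seq)
    (ctx,) = call.contexts
    assert ctx.major_codon == "tTa" and ctx.minor_codon == "tGa"
    assert ctx.effect == "nonsense"
    assert ctx.minor_aa == "-"
    assert call.mutation_class == "transversion"


def test_minus_strand_gene_classification():
    cds = "ATG" + "GAT" + "TAA"  # Asp at codon 2
    seq = "CCGCC" + revcomp(cds) + "CCGCC"
    gene = GeneModel("g", [ExonPart(5, 5 + 9, "-", 1)], "-")
    # genome position of cds position 6 (the T of GAT):
    # cds_pos0 5 -> p0 = end-1-5 = 5+9-1-5 = 8
    call = SnpCall(position=9, major="A", minor="G", major_n=700, minor_n=100,
                   major_pct=87.5, minor_pct=12.5)
    classify_snp(call, [gene], seq)
    (ctx,) = call.contexts
    assert ctx.cds_pos == 6
    assert ctx.major_codon == "gaT"  # complement of genome A
    assert ctx.minor_codon == "gaC"
    assert ctx.effect == "synonymous"


def test_intergenic_context():
    seq, gene = _genome_with_plus_gene("ATGAAATAA")
    call = SnpCall(position=2, major="A", minor="C", major_n=100, minor_n=20,
                   major_pct=83.3, minor_pct=16.7,
                   mutation_class=mutation_class("A", "C"))
    classify_snp(call, [gene], seq)
    assert call.context_kind == "intergenic"
    assert call.mutation_class == "transversion"


def test_overlapping_genes_both_contexts_emitted():
    cds = "ATGAAATAA"
    seq = "GG" + cds + "GG"
    g1 = GeneModel("g1", [ExonPart(2, 11, "+", 1)], "+")
    g2 = GeneModel("g2", [ExonPart(2, 11, "+", 1)], "+")
    call = SnpCall(position=6, major="A", minor="G", major_n=80, minor_n=20,
                   major_pct=80.0, minor_pct=20.0)
    classify_snp(call, [g1, g2], seq)
    assert {c.gene for c in call.contexts} == {"g1", "g2"}


# -- published-table arithmetic ---------------------------------------------


def test_published_rows_reproduce_major_pct():
    df = coding_intrasnps()
    rows = df.dropna(subset=["major_n"])
    assert len(rows) == 61  # one of 62 sites shares its codon, no counts
    for _, row in rows.iterrows():
        maj, mnr = genotype_percentages(int(row.major_n), int(row.minor_n))
        assert maj == float(row.major_pct)


def test_published_transition_transversion_split():
    df = coding_intrasnps().dropna(subset=["major_codon"])
    classes = [mutation_class(a, b) for a, b in zip(df.major, df.minor)]
    assert all(c in ("transition", "transversion") for c in classes)
    # coding-region calls: transversions outnumber transitions
    assert classes.count("transversion") > classes.count("transition")


# -- false positives --------------------------------------------------------


def test_zero_false_positives_on_homoplasmic_simulations():
    failures = 0
    for seed in range(20):
        g = simulate_genome(
            GenomeSpec(lsc_len=900, ssc_len=300, ir_len=200, seed=100 + seed)
        )
        cfg = ReadSimConfig(depth=120, mean_len=300, hp_error_rate=0.02,
                            sub_error_rate=0.005, seed=200 + seed)
        reads, _ = simulate_reads(g, cfg)
        pile = build_pileup(map_reads(reads, g.seq), g.seq)
        calls = call_intrasnps(pile, hp_mask=find_homopolymers(g.seq, 5))
        failures += len(calls)
    assert failures == 0


# -- indels -----------------------------------------------------------------


def _pile_with_insertion(with_n, without_n, ins="TAGA", anchor=30, n=101):
    pile = Pileup(n)
    pile.insertions[anchor] = {ins: with_n}
    pile.junction_cov[anchor] = with_n + without_n
    return pile


def test_minor_indel_fraction():
    pile = _pile_with_insertion(75, 180)
    (call,) = call_intra_indels(pile)
    assert call.inserted == "TAGA"
    assert (call.with_n, call.without_n) == (75, 180)
    assert call.minor
    assert call.fraction == pytest.approx(75 / 255)


def test_insertion_in_all_reads_is_consensus_difference():
    pile = _pile_with_insertion(60, 0)
    (call,) = call_intra_indels(pile)
    assert not call.minor


def test_singleton_insertions_ignored():
    pile = _pile_with_insertion(1, 100)
    assert call_intra_indels(pile) == []


def test_simulated_insertion_recovered_within_binomial_noise():
    g = simulate_genome(GenomeSpec(lsc_len=1200, ssc_len=300, ir_len=200, seed=61))
    # pick an anchor whose neighbourhood holds no G, and insert GGGG:
    # the alignment of the insertion is then unambiguous
    pos = next(
        p for p in range(400, 900) if "G" not in g.seq[p - 6 : p + 6]
    )
    frac = 0.3
    het = HeteroplasmySpec(indels=[(pos, "GGGG", frac)])
    cfg = ReadSimConfig(depth=500, mean_len=300, hp_error_rate=0.0,
                        sub_error_rate=0.0, seed=67)
    reads, _ = simulate_reads(g, cfg, het)
    pile = build_pileup(map_reads(reads, g.seq), g.seq)
    calls = [c for c in call_intra_indels(pile)
             if abs(c.position - pos) <= 4 and c.inserted == "GGGG"]
    assert calls
    call = max(calls, key=lambda c: c.with_n)
    total = call.with_n + call.without_n
    sd = np.sqrt(total * frac * (1 - frac))
    assert abs(call.with_n - total * frac) <= 3 * sd


# -- genotype comparison ----------------------------------------------------


def _call_with_context(gene, cds_pos, major, minor, codon):
    off = (cds_pos - 1) % 3
    call = SnpCall(position=cds_pos, major=major, minor=minor, major_n=80,
                   minor_n=20, major_pct=80.0, minor_pct=20.0)
    from plastidkit.intrasnp import CdsContext, _mark_codon

    major_codon = codon[:off] + major + codon[off + 1 :]
    minor_codon = codon[:off] + minor + codon[off + 1 :]
    call.contexts.append(
        CdsContext(gene=gene, strand="+", cds_pos=cds_pos,
                   major_codon=_mark_codon(major_codon, off),
                   minor_codon=_mark_codon(minor_codon, off),
                   major_aa="", minor_aa="", effect="synonymous")
    )
    return call


def test_identical_orthologs_yield_no_swaps():
    rng = np.random.default_rng(71)
    g = simulate_genome(GenomeSpec(lsc_len=3000, ssc_len=500, ir_len=300,
                                   n_genes=2, seed=73))
    recs = {r.gene: r for r in extract_cds(g.seq, g.genes)}
    gene = next(iter(recs))
    call = _call_with_context(gene, 4, recs[gene].spliced_sequence[3], "G"
                              if recs[gene].spliced_sequence[3] != "G" else "T",
                              recs[gene].spliced_sequence[3:6])
    out = compare_genotypes([call], recs,
                            {gene: recs[gene].spliced_sequence})
    assert all(r.status == "no_swap" for r in out)


def test_constructed_swaps_counted_exactly():
    rng = np.random.default_rng(79)
    g = simulate_genome(GenomeSpec(lsc_len=26000, ssc_len=2000, ir_len=1000,
                                   n_genes=12, seed=83, gene_len_range=(900, 1200)))
    recs = {r.gene: r for r in extract_cds(g.seq, g.genes)}
    calls, other = [], {}
    n_swapped = 0
    site_no = 0
    for gname, rec in sorted(recs.items()):
        cds = rec.spliced_sequence
        other_cds = list(cds)
        for k in range(5):  # five sites per gene -> 60 sites total
            cds_pos = 10 + 7 * k
            major = cds[cds_pos - 1]
            minor = "ACGT"["ACGT".index(major) - 2]
            codon_start = 3 * ((cds_pos - 1) // 3)
            calls.append(_call_with_context(
                gname, cds_pos, major, minor, cds[codon_start : codon_start + 3]
            ))
            if site_no % 3 == 0 and n_swapped < 19:  # flip 19 of the 60
                other_cds[cds_pos - 1] = minor
                n_swapped += 1
            site_no += 1
        other[gname] = "".join(other_cds)
        if len(calls) >= 60:
            break
    assert n_swapped == 19
    out = compare_genotypes(calls[:60], recs, other)
    assert sum(1 for r in out if r.status == "swap") == 19


def test_low_identity_ortholog_skipped_with_warning():
    g = simulate_genome(GenomeSpec(lsc_len=3000, ssc_len=500, ir_len=300,
                                   n_genes=1, seed=89))
    recs = {r.gene: r for r in extract_cds(g.seq, g.genes)}
    gene = next(iter(recs))
    junk = "".join(np.random.default_rng(97).choice(list("ACGT"),
                                                    len(recs[gene].spliced_sequence)))
    call = _call_with_context(gene, 4, recs[gene].spliced_sequence[3], "G",
                              recs[gene].spliced_sequence[3:6])
    with pytest.warns(UserWarning, match="identity"):
        out = compare_genotypes([call], recs, {gene: junk})
    assert out == []
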