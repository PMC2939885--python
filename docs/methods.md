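# Methods

This note documents the models, algorithms, parameter defaults, and
numerical conventions of plastidkit, and what the synthetic-data tests do
and do not establish about real data.

## Coordinates and conventions

Internally all intervals are 0-based half-open; every user-facing record
(repeats, hairpins, SNP calls, junctions, homopolymer runs) is 1-based
inclusive, matching the convention of plastome literature. Codons are
stored in the DNA alphabet (T) and rendered with U in reports. Printed
percentages and RSCU values use decimal round-half-up (1 and 2 decimals
respectively), matching how such tables are conventionally typeset.
Junction positions are the 1-based coordinate of the last base of the
upstream region at each boundary, in genome order LSC | IRb | SSC | IRa.

## Synthetic data

`simulate_genome` draws each region i.i.d. with a configurable A+T
fraction (default 0.63, the AT-richness typical of plastomes), plants the
requested features at random non-overlapping positions in the LSC with a
12-bp safety margin, and then constructs IRa as the exact reverse
complement of IRb, so the IR-mirror invariant holds by construction.
Three determinism-oriented interventions keep planted features exactly
recoverable:

* background homopolymer runs longer than 4 bp outside planted features
  are broken by a single interior substitution, so the only runs ≥ 5 bp
  in the genome are planted ones (gene interiors are generated
  run-free);
* the bases flanking planted runs, repeat copies, and hairpins are
  chosen so the planted feature is maximal exactly as specified;
* the bases adjacent to the region boundaries are adjusted so the
  maximal IR equals the planted IR.

Planted genes are ATG + random sense codons + TAA under translation
table 11; operons are contiguous gene blocks with configurable spacers,
laid right-to-left for minus-strand units. Planted hairpins resample
their stem composition until the default detector score threshold is
cleared with margin, i.e. the generator plants *detectable* hairpins by
construction.

`simulate_reads` emulates long pyrosequencing reads: length
N(380, 40) bp clipped at 50, uniform circular start, random strand,
Phred+33 qualities N(mean 30, sd 2) with a linear decay of 5 across the
read. The platform's characteristic error is modeled per homopolymer run
of length L ≥ 4 as a ±1 length miscall with probability
min(0.9, r·(L−3)); substitutions are uniform per base. Heteroplasmy is
applied per read (Bernoulli at the site's minor fraction) before errors.
Each stochastic operation takes a seed and uses one numpy Generator, so
outputs are byte-identical across runs.

`simulate_cdna` samples reads per gene (Poisson with the gene's
abundance as mean) from the operon transcript spanning the unit, so reads
cross intra-unit gene junctions; genes with a pure-A genomic track of
≥ 15 bp within 200 bp upstream on their strand are over-sampled by a
configurable enrichment factor (default 50×), reproducing the
polyT-priming artifact of oligo-dT libraries. A configurable fraction of
reads carries the adaptor on the 3' end.

What the simulations do **not** model: flowgram-level signal, paired-end
or short-read error profiles, chimeric reads, coverage biases other than
the polyA artifact, RNA secondary structure, or transcript processing.
Green tests therefore demonstrate algorithmic correctness under the
stated error model, not performance on any particular instrument's data.

## Assembly

Screening aligns each read (both strands, edlib infix alignment against
the circularised reference) and keeps it when identity over the read —
or over a prefix/suffix covering the coverage fraction — reaches the
threshold. Defaults are identity 0.90 over 0.80 of the read; both are
exposed because appropriate values depend on the divergence of the
available reference genomes.

Elongation is end-anchored consensus voting: reads containing the exact
terminal `min_overlap`-mer of a contig end (and agreeing with the contig
over their full overlap at ≥ `min_identity`) vote per position on the
extension, which is appended while ≥ `min_support` reads agree by
**qualified majority** (top base ≥ 70% of votes). A bare plurality is
deliberately insufficient: at the exit of a repeat longer than the read
length, anchored reads split into near-equal camps, and extending on
sampling noise would assemble a chimera. Such ends halt, and repeat-
spanning seed contigs (or independent evidence, e.g. junction PCR in a
real project) resolve them. Contigs whose ends overlap exactly by
≥ `min_overlap` merge; a contig overlapping itself closes into a circle
and is canonicalised to the least rotation of the lexicographically
smaller strand (Booth's algorithm). Defaults: min_overlap 40,
min_support 3, min_identity 0.98 — conservative values sized to ~400-bp
reads at ≥ 50× depth. Note that a quadripartite circle has an intrinsic
two-isomer degeneracy (SSC orientation); the round-trip tests avoid it
by seeding with junction-spanning fragments.

## Structure

The quadripartite detector indexes k-mers (k ≤ 24), anchors inverted
matches, and extends them maximally on the circle; the longest disjoint
pair ≥ `min_ir_len` (default 1,000 bp) defines the IRs, the larger gap is
the LSC, and IRb is the copy downstream of the LSC end. Detection is
rotation-invariant by construction. Absence of a qualifying IR returns
None ("no quadripartite structure"), not an exception.

The repeat finder enumerates maximal k-mismatch windows (Hamming
distance, default ≤ 3; unit length default ≥ 30 bp, i.e. ≥ 90% identity)
over all diagonals of the sequence against itself (forward) and against
its reverse complement (inverted), via vectorised mismatch arrays. A
window equal to its own reverse complement is one palindromic site, not
a pair, and is not reported. Hits whose two copies are contained in a
longer hit's copies are containment-redundant and suppressed; pairs with
both copies inside caller-supplied exclude intervals (normally the two
genome-scale IRs) are dropped. Each copy is classified against the
annotation as a gene name (inside an exon), intron(gene), or
IGS(left–right). The finder is validated against an independently coded
brute-force oracle on >100 random and adversarial sequences.

Small inversions: stems are maximal perfect inverted repeats (mismatch
budget 0 by default, configurable) with stem length in [11, 24] and loop
< 50 bp. The hairpin stability score is additive: −3 per G:C pair, −2
per A:T pair, +0.5·max(0, loop−4) as a loop penalty; more negative is
more stable. It is a deliberately simple surrogate for a thermodynamic
folding energy — it preserves stability *ordering* among same-geometry
candidates (more/stronger pairs ⇒ more negative) but its values are not
free energies and are not comparable to ΔG numbers. The default
threshold of −10 was calibrated on the package's own corpus of planted
hairpins so that 13-bp stems with long loops pass while short (≤ 6 bp)
AT-rich stems fail. Overlapping candidates resolve in favour of the
best-scoring one. Candidates aligning to a comparator genome at ≥ 90%
identity over the span are confirmed (with loop orientation per
comparator); the rest are reported separately as putative.

## Codon statistics

CDS extraction splices exons in annotated rank order with per-part
strands, so trans-spliced genes assembling from both strands are handled;
pseudogenes are excluded; records with length not divisible by 3 are
flagged, never silently dropped. Counting includes stop codons; codons
containing ambiguity characters are tallied separately. RSCU, amino-acid
composition (stops in the denominator), and positional A+T composition
follow the standard definitions given in the README; the package
cross-checks them against direct recomputation from the raw spliced
strings on simulated genomes. The start-codon audit reports each CDS's
first codon, flags non-ATG starts, scans the upstream sequence in frame
for nearby stop codons (window 30 bp), and notes long A/T runs around
the start whose miscall would shift the frame — the combination that
makes a start call ambiguous in AT-rich plastomes.

## Heteroplasmy calling

Pileups accumulate quality-passing bases (Phred strictly > 20) per locus,
tally gap-bearing reads separately, and record inserted strings between
positions. A SNP call requires, in order: depth after gap-read removal
strictly > 50; at least two observed bases; largest minor genotype
strictly > 10% of qualifying reads; locus outside the homopolymer mask
(runs ≥ 5 bp, ± 1 flanking base; both parameters exposed). Reported
percentages are computed over the two reported genotypes only, which is
what reproduces published-style figures such as 863/(863+124) = 87.4%.
Ties for the top count report the alphabetically smaller base as major
and set an ambiguity flag. Transition/transversion classification and
codon effects (synonymous / nonsynonymous / nonsense) are computed on the
coding strand at the CDS offset; a site hitting two overlapping genes
emits both contexts, and two sites in one codon are reported per site
with a shared-codon note. Insertion polymorphisms require the identical
string in ≥ 2 reads; the with/without fractions are over reads spanning
the insertion junction. Note that a multi-base insertion whose letters
partially match the flanking reference can be represented as split
smaller insertions by the aligner (standard indel-representation
ambiguity); counts at the affected anchors remain consistent.

The bundled published SNP table contains one internal inconsistency: one
row's printed minor percentage does not equal 100 − major nor
minor/(major+minor); the fixture transcribes the table as printed and
the invariant test checks major-percentage reconstruction only.

Genotype comparison across species maps each CDS call through a global
pairwise alignment of the orthologous coding sequences (Biopython
PairwiseAligner; match 1, mismatch −1, gap −2/−0.5) and labels the
comparator's base as swap (equals the minor genotype), no_swap (major),
or third; ortholog pairs under 60% identity are skipped with a warning.

## Transcripts

cDNA reads are adaptor-trimmed (edlib search for either orientation,
keeping the longer flank), mapped to the circular genome, and kept at
≥ 99% identity. A gene is detected when covered strictly above 80% of
its exonic length. Strand-resolved alignments overlapping by ≥ 20 bp
merge into transcript contigs; the genes on one strand that a contig
covers (> 80% of exonic span) form one transcription unit in genomic
order along the strand — polycistronic iff ≥ 2 genes. Every gene joins at
most one unit. The expression matrix renders count(coverage%) per gene ×
tissue with "-" for zero reads, and round-trips through its TSV
writer/parser bit-identically. PolyA-track detection reports maximal
A-rich windows (purity ≥ 0.8, length ≥ 10, both strands) with the
nearest downstream gene start within 200 bp; enrichment bias is flagged,
never corrected, since the artifact is a property of polyT-primed
library construction. Units are intended to be estimated from the
deepest (leaf-equivalent) tissue.

## Problem sizes in the test suite

The suite exercises the pipeline at reduced scale chosen to keep the
feedback loop fast while preserving the governing ratios (read length ≪
IR length < genome; depth ≫ the calling threshold): assembler round
trips use a 20.1-kb quadripartite genome at 50–60× depth; heteroplasmy
recovery uses ~800× pileups over a 2.9-kb genome with planted minor
fractions 0.11–0.39; the false-positive check runs twenty independent
homoplasmic simulations; operon recovery plants 18 polycistronic units
and 10 singletons over a ~54-kb genome; oracle equivalence for the
repeat finder covers 100 random plus 20 adversarial sequences up to
~1.5 kb. Published-value arithmetic (codon table, genotype percentages,
hairpin geometry, quadripartite lengths at full 158,462-bp scale) runs
at exactly the published numbers.

## Known limitations

* The read mapper is a best-strand infix aligner adequate for the
  simulated error model; it reports a single best location and does not
  model mapping quality, so reads wholly inside the two identical IR
  copies are placed at one of the two equivalent positions.
* The elongation consensus is quality-blind majority voting; it corrects
  homopolymer-length errors only where clean reads outnumber miscalled
  ones.
* The hairpin score is not a thermodynamic energy (no stacking
  interactions, no mismatch/bulge energetics beyond a budget, no
  temperature), and MFOLD/ViennaRNA-style values cannot be read off it.
* Transcription-unit assignment is a deterministic surrogate for what is
  partly manual curation in real projects; intron-containing genes are
  kept intact only when the contig gap coincides with an annotated
  intron, and processed/overlapping transcripts are out of scope.
* Circular-coordinate support in the repeat finder relies on a wrapped
  prefix of bounded length; repeats crossing the origin longer than that
  prefix are truncated.
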