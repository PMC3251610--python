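# Methods

## Variant mining model

Mining operates on per-genotype pileups over unigene alignments. The
substrate is a column: `{genotype → {allele → read count}}` with
alleles in {A, C, G, T, N, `-`, `+`}. A deletion contributes one `-`
at its leftmost deleted column (one event per anchor, so a multi-base
deletion is a single event); a read carrying an insertion immediately
right of column *p* contributes one `+` at *p* **in place of** its
matched base. This keeps the invariant that a column's total count
never exceeds the number of covering reads, at the cost of hiding the
anchor base of insertion-carrying reads — acceptable because the
pipeline treats any indel-involved column as a single INDEL event and
never genotypes it further.

A genotype **supports** a column iff its depth ≥ `min_reads_per_genotype`
(default 2) and its major-allele frequency ≥ `min_within_genotype_freq`
(default 0.9). A call is emitted iff ≥ `min_genotypes` (default 2)
genotypes support the column **and at least two supporting genotypes
disagree on their major allele**. The disagreement clause is an
interpretation: the depth/frequency criteria alone would fire on
monomorphic columns, so the only reading that yields polymorphisms is
adopted, and it is stated here rather than silently assumed. The
within-genotype frequency is the major-allele frequency of that
genotype's reads — the natural statistic for inbred lines, where a
genotype's reads should be effectively fixed and lower frequencies
indicate sequencing error or paralog collapse. The frequency filter is
evaluated only for genotypes that already meet the depth criterion.

The contig read-count bounds (6–5000) apply to the *total* reads
aligned to the unigene, not to column depth: too few reads means the
assembly consensus is unreliable, too many indicates collapsed
repeats. The alternate allele of a call is the non-reference major
allele backed by the most supporting genotypes (ties: more pooled
reads, then lexicographic). Columns where more than two major alleles
conflict are emitted with a `multiallelic` flag rather than suppressed.

Base qualities are ignored throughout: all aligned bases count.

**Reference ambiguity correction.** Positions whose reference base is
not A/C/G/T are replaced by the pooled strict-majority base when total
depth ≥ 6 and the majority frequency ≥ 0.5. These thresholds are not
externally fixed; they mirror the contig depth bound and are
configurable (`ref_correct_min_depth`, `ref_correct_min_freq`). Ties
never correct, non-ambiguous bases are never touched, and the
operation is idempotent.

**Expected recovery under the default study conditions.** At mean
per-genotype depth 6 and 0.5% base error, a genotype with *d* ≤ 9
reads at a column loses support whenever ≥ 1 of its reads errs there
(frequency drops below 0.9): probability ≈ 1 − 0.995^d ≈ 3% at d = 6.
With four genotypes split 2/2 per variant, a planted SNP is lost only
when both genotypes of one pool fail (≈ 2·0.03² ≈ 0.2% per SNP), so a
~100-SNP run typically recovers everything but occasionally misses one
or two; single-run sensitivity at covered positions therefore sits in
the 0.98–1.0 range with expectation ≈ 0.995. "Covered" means at least
two planted allele pools each retain a genotype at callable depth —
the standard coverage-conditioned benchmark definition. False
positives require two independent coincident errors in one genotype
plus a qualifying partner, and are effectively absent at these scales.

## ORF statistic and unigene classes

The longest ORF is computed over all six frames. Two definitions are
implemented because EST evidence is genuinely ambiguous here:

- `start_to_stop` (default): ATG … to the next in-frame stop (the
  stop codon is inside the reported span but excluded from
  `length_aa`) or to the sequence end — EST fragments are 5′/3′
  truncated, so running off the end is allowed.
- `stop_free`: any maximal stop-free codon run, no start required.

Codons containing N are neither start nor stop and count as one
residue. Ties break towards the lower frame index (+1,+2,+3,−1,−2,−3),
then the smaller start coordinate, making the result fully
deterministic. The output records which mode produced it.

Classification is a strict partition: with a homology hit (≥ 1 of the
screened genomes at the screening E-value), ORF > 50 aa ⇒ `gene`, else
`pseudogene_or_fragment`; without a hit, ORF > 75 aa ⇒
`possible_novel_gene`, else `not_gene`. Thresholds are strict
("longer than"), so 50/with-hit and 75/without-hit fall in the
excluded classes. The homology search itself is consumed as a table,
never run.

## Selection

The flanking-error score for a SNP is
(Σ over genotypes of read-vs-reference mismatches across the entire
unigene alignment, excluding the SNP column) / (reads covering the SNP
position). Each indel event counts one mismatch; positions where
either the read or the reference base is not a plain base are not
counted. The numerator spans the whole contig deliberately — the score
flags misassembled or error-rich contigs, not local context. Whether
the denominator should instead be the unigene's total read count is
ambiguous; column depth is the default and outputs state which was
used.

Gates are inclusive (≥ 0.70 Infinium, ≥ 0.55 GoldenGate, ≤ 10
flanking). [A/T] and [C/G] SNPs are discarded because their alleles
are reverse-complement symmetric and need two Illumina bead types.
Per-locus selection is made deterministic as a lexicographic sort:
supporting genotypes descending, Infinium score descending, position
ascending, then SNP id. Paired singletons (5′/3′ reads of one clone,
recognised by the `_p1`/`_p2` name pattern — the pattern is
configurable since the naming convention is not standardised) share a
locus key, so exactly one member of a pair can donate a SNP, decided
by the same sort key rather than by member identity. The final ranking
(Infinium desc, GoldenGate desc, SNP id) caps the panel at the target
size with reproducible boundary ties.

## Diversity statistics

Calls are biallelic AA/AB/BB with missing data; a sample's per-locus
A-allele frequency is 1, 0.5 or 0. Gene diversity is He = 1 − p² − q²
(= 2pq) from the non-missing calls at a locus; MAF is min(p, 1−p).
The 80% call-rate rule is applied jointly across the full sample set
by default, with a per-species option; for a 2-sample species it
degenerates to "called in both", which the transferability counts
document.

Nei's standard distance is computed *between individuals*, treating
each diploid sample as a two-allele population: over loci non-missing
in both samples, J_x = mean(p² + q²), J_xy = mean(p_x·p_y + q_x·q_y),
D = −ln(J_xy/√(J_x·J_y)). The small-sample "unbiased" variant
(substituting 2J − 1 for a single diploid's homozygosity) is offered
behind a flag; the classic 1972 form is the default and neither is
asserted to be what any particular historical analysis used. A pair
sharing no alleles anywhere has infinite D; it is replaced by
(max finite D + 1) with a warning so ordination stays computable.
By Cauchy–Schwarz the identity ratio cannot exceed 1, but it is
clamped against floating-point overshoot so D(x,x) = 0 holds exactly.

PCO is classical metric scaling: double-centre −D²/2, eigendecompose,
scale eigenvectors by √λ for eigenvalues above a relative tolerance of
1e−12·λ_max. Negative eigenvalues (non-Euclidean input) are dropped
from both the coordinates and the percent-variance denominator, and
their count is reported.

Evanno's ΔK(K) = |mean L(K+1) − 2·mean L(K) + mean L(K−1)| / sd(L(K))
uses the sample standard deviation (ddof = 1) over runs; endpoints are
undefined and zero-sd K values are omitted. The clustering itself is
consumed as a (K, run, log-likelihood) table, never run.

## Synthetic data generator

The generator emulates the study conditions end to end and is the
package's test substrate. Defaults, with rationale:

| parameter | default | why |
|---|---|---|
| unigene lengths | contigs ~N(828.5, 150), singletons ~N(444.2, 80), min 150 bp | EST-assembly length structure |
| singleton fraction | 0.61 | contig/singleton ratio of such assemblies |
| variant rate | 1/163.6 per bp | observed transcriptome SNP density |
| genotypes | 4 inbred lines | two breeding pools at desk scale |
| reads | 36 bp single-end, mean depth 6 per genotype, 0.5% error | short-read re-sequencing profile |
| ambiguity rate | 0.002 (N or a 2-base IUPAC code covering the true base) | assembler consensus artifacts |
| matrix | 32 samples in 6 breeding groups + 6 wild relatives, 300 loci, p ~ U(0.05, 0.95), 2% missing, 3 replicate pairs | diversity-panel structure |
| inbreeding | F = 0.65 for breeding lines, 0 for OPV/landrace and wild | reproduces the observed ~13% vs ~40% heterozygosity contrast |

Each planted variant splits the genotype panel into two balanced
allele pools (random assignment, n/2 vs the rest). This emulates fixed
differences between the two breeding pools that a genotyping array is
designed to separate, and is a deliberate simplification: real panels
also segregate private (1-vs-rest) alleles, which are harder to
recover at fixed total depth because a single genotype must then carry
the minor pool alone. Other simplifications: uniform read placement
(no expression-level variation), no quality-score simulation (the
pipeline ignores base qualities), fully homozygous inbred haplotypes
(no residual heterozygosity), no assembly errors, chimeras or paralog
collapse. Passing tests therefore demonstrate correctness of the
*pipeline logic* under a clean error model, not robustness to
misassembly or alignment artifacts.

Determinism: every stage draws from its own stream spawned from the
single config seed, so each generator is reproducible independently
(identical seeds give byte-identical FASTA/SAM/TSV outputs).

## Numerical choices

- Frequency thresholds are compared with a 1e−9 absolute slack so that
  exact fractions (9/10 vs 0.9) are not lost to binary rounding; the
  same guard applies to call-rate and MAF cutoffs at 1e−12.
- Major-allele ties within a genotype resolve lexicographically.
- Internal coordinates are 0-based half-open; every emitted table is
  1-based. Intron intervals are consumed as 0-based half-open BED, and
  a SNP exactly at an interval's (exclusive) end is retained.
- Reverse-strand reads are stored in reference orientation; alleles
  are always reported on the unigene strand.
- All mapped reads are treated uniformly regardless of how the
  upstream aligner resolved multi-mapping or orphaned mates.

## Problem sizes

The bundled test and acceptance runs use 20 unigenes × 4 genotypes
(~8,000 reads, ~70–100 planted variants), 250–300 random pileup
columns against the brute-force evaluator, a 1,000-candidate selection
fixture, and a 39-sample × 300-locus genotype matrix — sizes chosen so
the full suite exercises every code path in seconds while keeping
Monte-Carlo checks (binomial 3σ, 2·SE recovery bands) adequately
powered.

## Known limitations

- Insertion alleles are collapsed to a single `+` token: two different
  inserted sequences at one anchor are not distinguished.
- INDEL calls are not emitted in allele-resolved VCF form (symbolic
  `<INS>`/`<DEL>` only).
- The genotype matrix model is biallelic with locus-independent draws;
  no linkage disequilibrium is simulated, so ordination tests probe
  geometry, not realistic LD structure.
- Cross-species transferability on simulated data reflects the planted
  missingness model only.
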