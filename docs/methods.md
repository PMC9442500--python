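# Methods

## K-mer decomposition

A sequence of length *n* over an alphabet Σ (DNA: {A,C,G,T}; protein: the 20
canonical residues; optionally the Murphy 10-group reduced alphabet) yields
one window per position 0..n−k per spaced-seed mask. A mask is a binary
string of length k; only '1' positions contribute letters to the emitted
word, so the word space has size |Σ|^w with w the mask weight (w = k for
contiguous counting). Multiple masks of equal weight accumulate counts into
one shared word space. Windows containing an ambiguity symbol (N for DNA;
X/B/Z/J/U/O for protein) are skipped entirely; brittle rejection of records
containing occasional IUPAC codes is a known practical failure mode, so
ambiguity codes are tolerated on input and excluded only from counting.

Frequencies divide counts by the *realised* total of counted windows rather
than by n−k or n−k+1. The three denominators differ by O(1/n), but only the
realised total guarantees Σ_w f(w) = 1 when ambiguous windows were skipped,
which the histogram machinery downstream relies on. Counts are kept as
sparse word→count mappings (protein word spaces at k ≥ 3 are almost entirely
zero) with a dense conversion for the DNA-only Markov statistics. No
reverse-complement canonicalisation is applied: counting is forward-strand
only.

## Metrics

All metrics are symmetric; all except raw D2 return 0 for identical
sequences and are oriented lower = more similar.

- **d2raw**: Σ_w C_r(w)·C_q(w). Unbounded, grows with sequence length.
- **d2**: 0.5·(1 − cosine), cosine = D2/(‖C_r‖‖C_q‖). The affine map takes
  the cosine range [−1,1] onto [0,1]; with non-negative counts the realised
  range is [0, 0.5]. The declared histogram range is kept at [0,1].
- **euclid / manh / cheby**: L2/L1/L∞ distances on frequency vectors.
  On the frequency simplex manh ≤ 2, euclid ≤ √2, cheby ≤ 1.
- **ncanb**: mean of |x−y|/(x+y) over words with x+y > 0. Dividing by the
  number of contributing words (rather than the word-space size) bounds the
  score in [0,1] independently of k.
- **bc / ngd**: computed on raw counts, as their defining formulas are
  count-based (S_i are total counts). Both assume comparable totals; for
  very unequal totals NGD ≥ (S_long − S_short)/S_long, which is the
  analytic form of their failure in the unequal-length regime.
- **d2star / d2s**: centred counts X̃_w = C(w) − n·p_w with p_w the product
  of single-letter probabilities estimated separately per sequence (order-0
  background; higher orders are out of scope). d2star standardises by
  √(n·p_w) per sequence, d2s by √(X̃² + Ỹ²) per word; both correlation-like
  statistics are mapped onto [0,1] by 0.5·(1 − ρ). Words with zero
  background probability (d2star) or zero centred mass in both sequences
  (d2s) are skipped; a zero background probability together with a non-zero
  observed count raises. Both are restricted to DNA, where the single-letter
  background is well defined. The exact formulas follow the standard
  D2-statistics literature; no bit-compatibility with any particular
  implementation is claimed.

Degenerate inputs: distance metrics raise on zero-total vectors rather than
returning a sentinel; the search layer skips such pairs with a warning and
accounts for them as filtered.

## Search engine

All-vs-all scoring supports query-vs-reference, single-file all-vs-all, and
interleaved modes (consecutive record pairs, giving the caller full control
over which sequences are paired — used for positive-only distributions).
Per query, references are ranked by increasing distance (decreasing score
for d2raw); ties break by reference input order so top-hit evaluation is
reproducible. The optional length filter keeps a pair when
min(len)/max(len) ≥ fp; the cut-off filter retains score ≤ cutoff
(inclusive) before top-n truncation. Retained + filtered + truncated always
equals |Q|·|R|. Output is a BLAST-like TSV (query, reference, metric, score,
rank) or a PHYLIP-style square distance matrix for all-vs-all results. The
threads option is a contract knob only: per-query work is independent and
merged in input order, so results never depend on it.

## Calibration

Score histograms use 100 equal-width bins over the metric's declared range
(left-closed, last bin closed; out-of-range scores are clipped with a
warning). The overlapping index η(A,B) = Σ_bins min(f_A, f_B) is 1 for
identical and 0 for disjoint distributions.

The cut-off selector computes cumulative sums of the positive-only and
all-scores histograms and takes diff = cum_pos − cum_all. The sign is
chosen so that the curve has an informative maximum: positives concentrate
at low scores, so cum_pos rises ahead of cum_all and the peak marks the
score below which most true-positive mass but little background mass lies.
(The opposite order of subtraction would be ≤ 0 everywhere with no usable
maximum.) The cut-off is the upper edge of the *first* bin attaining the
maximum — a deterministic tie-break.

The calibration curve sweeps the grid of possible cut-offs s: among rank-1
hits with score ≤ s, frac_correct(s) is the fraction that are true (0 when
none are retained) and frac_excluded(s) is the fraction of all true top
hits removed. Mapping a score to a probability is a step lookup at the
first grid point covering the score; no interpolation or extrapolation.
Region labels: *high* where frac_correct ≥ 0.95, *low* above the score by
which 99 % of the true-hit mass has accumulated, *variable* elsewhere; both
thresholds are configurable.

## Objective functions and statistics

Truth is either a table of unordered id pairs or a taxonomy over the fixed
hierarchy strain < species < genus < family < order < class < phylum
(missing ranks never match; unknown ids are negative with a warning). Many-
to-many ortholog tables are reduced to one-to-one by keeping each left-side
id's first-listed partner. AUC is computed over all pairwise scores by the
Mann–Whitney rank statistic (ties count 0.5), with low scores as the
positive direction; a per-query variant is deliberately not the default.
Length–score correlation is Spearman's rho of mean pair length vs score.

## Synthetic data

The generators define the study conditions for every test; they are
deterministic under a fixed seed.

- **Fragment extraction**: a genome is split into 10 equal intervals
  (remainder dropped); queries take the first L bases of intervals
  {0,2,4,6,8}, references of {1,3,5,7,9}, five each, so the two sets never
  overlap and sample along the genome. Which parity goes to queries is an
  arbitrary fixed choice; any consistent assignment preserves non-overlap.
  L sweeps 100 bp doubling to 102,400 bp (figures conventionally restrict
  to 0.1/0.4/1.6/6.4/25.6/102.4 kb). If L exceeds the interval width only
  complete fragments are emitted, with a warning. The unequal-length design
  uses the genome's first 250 kb as a single long reference.
- **Signature genomes**: per-genome order-1 transition matrices are drawn
  by adding Gaussian noise (scale = `perturbation`, default 0.4) to shared
  logits and renormalising rows. Perturbation 0 makes all genomes
  statistically identical (AUC ≈ 0.5, the no-signal control); 0.4–0.5 gives
  compositional signatures recognisable from ≥ 1 kb fragments at k = 4.
  Default 12–20 genomes of 20 kb keep the full pipeline in seconds while
  leaving room for the 100 bp → 1.6 kb accuracy gradient. This emulates the
  *existence* of genome signatures, not their real fractal structure, CDS
  constraints or GC gradients — passing tests show the machinery recovers
  planted compositional signal, not field performance on real genomes.
- **Ortholog proteins**: ancestors are i.i.d.-uniform over the 20 residues
  with gamma-distributed lengths (shape 3, mean 450 aa, floor 50 — the
  scale of real proteomes); orthologs apply i.i.d. substitutions
  (default rate 0.3, a moderate divergence where k ≤ 3 signal survives) and
  geometric-length indels (rate 0.02); an equal number of unrelated decoys
  is added to the reference side. Real orthologs share composition biases
  and domain structure this model lacks, so it is used only for
  directional and parameter-recovery tests.

## Problem sizes

The test suite and the acceptance script run the full pipelines at desk
scale: 12 genomes × 20 kb for the taxonomic sweeps (3,600 fragment pairs
per length), 40 + 40 proteins per proteome for ortholog detection, 10,000
draws for the calibration-recovery experiment, and 1,000 random pairs for
brute-force metric agreement at 1e−9 relative tolerance. The large printed
comparison counts (tens of millions) are verified through the engine's
vectorised dry-run pair counter rather than by materialising score records.

## Known limitations

- Markov backgrounds are order 0 only, and d2star/d2s are DNA-only.
- No strand canonicalisation; reverse-complemented fragments of the same
  genome read as unrelated.
- The S2/dAI-style adjacency metric family is not implemented.
- FASTQ quality scores are ignored; only FASTA/FASTQ (± gzip) input.
- The probability map is a step function of the empirical curve; no
  smoothing or parametric fit of score distributions is attempted.
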