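# Methods

This note documents the models, numerical choices, and limitations
behind `synfrac`, in the order the pipeline runs them.

## Homology search

The unit of comparison is the primary protein per gene (longest CDS per
locus, ties broken by transcript ID — annotation formats rarely say
which model is "primary", so the package fixes a deterministic
convention).  Two hit sources are interchangeable:

* **BLAST tabular ingest** (`parse_hits`): standard 12-column rows;
  retention filters are E-value < 1e-5 and the five strongest subjects
  per query per target genome, with self hits removed in intra-genome
  mode.  "Top five" is interpreted per (query, target genome) rather
  than globally, so intra- and inter-genome searches do not compete.
* **Built-in search** (`naive_all_vs_all`): Smith–Waterman local
  alignment with BLOSUM62, gap open 11 / extend 1.  E-values use the
  Karlin–Altschul form `E = m·n·2^(-bit)` with the published gapped
  BLOSUM62 constants (λ = 0.267, K = 0.041); `m` is the query length and
  `n` the total subject proteome length.  Hits are produced for both
  query directions, as an all-against-all run would.

  A banded edit-distance prefilter (edlib) skips pairs whose normalised
  edit distance exceeds 0.65 or whose lengths differ more than twofold.
  Unrelated proteins sit near 0.75 normalised distance while homologous
  pairs even at the oldest event modelled here (protein identity
  ≳ 0.50) stay near 0.50, so the filter separates the populations by a
  wide margin; it exists purely to keep the all-vs-all cost manageable
  and can be disabled (`prefilter=False`).  Seed-based (k-mer)
  prefilters were rejected: at 50–60% identity over 100–200 aa their
  miss probability is non-negligible, and a single missed pair becomes
  a missing cell in the alignment table.

Rank classes (best / second-best / other, the dot-plot colours) are
assigned per query direction; ties break by E-value, then subject ID.

## Collinearity

Hits per chromosome pair become (rank_a, rank_b) points in gene-rank
space; base-pair coordinates are never used downstream, which makes the
analysis robust to assembly gaps.  A block is the longest chain of
points strictly increasing in rank_a and strictly monotone in rank_b,
with consecutive rank gaps in [1, max_gap] on both axes:

* `max_gap = 50` gene ranks, `min_len = 5` pairs by default.  min_len 5
  makes the smallest census class "more than 4 colinear genes"; the gap
  default follows common practice for collinearity scanners.
* Chain score is the pair count, not a bit-score sum, matching how
  block sizes are reported (numbers of colinear genes).
* The chain is found by an O(n²) DP; the best chain is extracted, every
  point sharing a gene with it removed, and the DP repeated until the
  best chain falls under `min_len`.  Ties prefer parallel orientation,
  then the smaller starting rank on each axis; within a DP, chain
  reconstruction always takes the smallest valid successor, so output
  is deterministic and independent of input order.  The DP optimum is
  property-tested against exhaustive enumeration of all monotone
  subsets for up to 12 points.
* Intra-genome mode folds mirrored hits onto a canonical triangle and
  collapses tandem arrays first: consecutive genes within 5 ranks on
  one axis hitting the same partner keep only the strongest hit,
  preventing spurious thick blocks at tandem clusters.
* An optional permutation test for block significance (shuffling
  rank_b) is provided but off by default; the census reports counts,
  not p-values.

## Ka/Ks (NG86)

Each colinear pair is aligned at the protein level (global,
BLOSUM62, affine 11/1), the alignment threaded back onto the CDS so
every column is a codon column, and gapped columns dropped (pairwise
deletion).  Counting follows Nei–Gojobori (1986):

* synonymous sites per codon = (synonymous changes among the 9 possible
  single-nucleotide changes) / 3, averaged between the two sequences;
  changes to stop codons count as nonsynonymous sites;
* codon pairs differing at k positions average their differences over
  the k! minimal pathways.  Pathways that pass through a stop codon are
  excluded and the average renormalised — a common implementation
  choice documented here because the original description averages all
  pathways; if every pathway is blocked, all are included with
  stop-crossing steps counted nonsynonymous;
* Jukes–Cantor correction `K = -(3/4) ln(1 - (4/3)p)` applied to both
  proportions; a pair with `1 - (4/3)pS ≤ 0` is flagged saturated and
  excluded from block medians (the median of an even count is the mean
  of the central two; a block with no unsaturated pair has no median).

The implementation is exact table lookup over the 61 sense codons and
is verified against an independent exhaustive-pathway oracle to 1e-9.
The standard genetic code is assumed throughout.

## Event classification

Block medians are dated into three windows: WGD 0.3 ± 0.1, speciation
0.9 ± 0.15, WGT 1.3 ± 0.3 (centre ± half-width, all configurable; with
real data the centres would be re-calibrated from `ks_peaks`, which
histograms the medians at 0.05 bin width with 3-bin moving-average
smoothing).  The speciation and WGT windows overlap on [1.0, 1.05];
there the nearer centre wins.  Intra-genome blocks become WGD or WGT
paralogy; inter-genome blocks become orthologs (speciation window) or
outparalogs (WGT window).  The expected region counts per reference
chromosome (2 orthologous, 4 out-paralogous, from the 1:2 ratio and the
triplication) serve as a rank-based consistency check on the
colinear-gene counts: when rank and Ks disagree, Ks decides and the
conflict is logged, because the Ks signal is per-block evidence while
rank is only an aggregate expectation.

## The nine-column table

Every reference gene anchors one row; the columns are the anchor, its
two derived ortholog copies, its two WGT homoeologs in the reference,
and each homoeolog's own two derived ortholog copies.  Missing
relations hold the literal `.`.  Consequences of the layout:

* ortholog blocks of each reference chromosome are bipartitioned into
  two copy columns greedily, strongest block first, with overlapping
  reference intervals forced into different copies; copy 1 is the side
  with more colinear genes, a per-chromosome labelling that makes no
  claim of genome-wide subgenome phasing (which is out of scope);
* within every non-anchor column a gene may appear only once.  For the
  homoeolog columns this requires coordination: the three anchors of a
  WGT triplet must place their partners cyclically (a→b, b→c, c→a),
  which the builder achieves by trying both column orders per anchor
  and preferring the assignment that fills more cells.  Competing
  claims anywhere resolve by block strength (more pairs, then lower
  median Ks, then lexicographic), the loser becoming `.` with a counted
  conflict;
* the table is intentionally redundant — each triplet member anchors
  its own row — and row order is invariant to block input order.

## Fractionation statistics

Per reference chromosome: the fraction of anchors missing the copy-1
cell, the copy-2 cell, or both, and the absolute copy-rate difference.
Rates computed by this module obey set semantics
(`both ≤ min(lost1, lost2)`; inclusion–exclusion bound), and these are
asserted — but an ingest mode accepts externally printed tables
verbatim and skips the checks, because published tables do not always
follow strict set semantics (two rows of the packaged 19-chromosome
table violate them).  The summary reports the mean difference, the
count of chromosomes at or below the 0.05 threshold, the maximum
difference and its chromosome, column extrema, and the genome-wide
both/one/none retention split.  A genome-wide near-uniform, small
copy-rate difference is the signature of balanced fractionation
between the two WGD subgenomes.

## The simulator

`synthetic_data` forward-simulates the scenario the pipeline is built
to reconstruct, and its defaults are the package's study conditions:

* 3 ancestral chromosomes × 200 genes, gene lengths uniform on
  100–200 codons, ancestral codons uniform over the 61 sense codons;
* event script: WGT (pairwise Ks target 1.3) → speciation (0.9) →
  derived-lineage WGD (0.3).  The WGT is one triplication (the possible
  two-step origin of the hexaploidy is out of scope);
* fractionation: each extra WGT copy (subgenomes B and C) is lost with
  probability 0.75 per gene before speciation (so WGT fractionation is
  shared by both lineages); after the WGD each derived copy is lost
  independently with probability 0.60 (copy 1) / 0.65 (copy 2).  Losses
  are whole-gene deletions.  The loss defaults sit in the 0.55–0.79
  range of the printed per-chromosome rates, with a deliberate
  copy-to-copy gap of 0.05 so that recovery of *unequal* rates is
  exercised;
* sequence divergence is a continuous-time Markov chain on the 61 sense
  codons: single-nucleotide exchanges at unit rate when synonymous and
  at `ka_ks_ratio = 0.2` times that when nonsynonymous; stop codons are
  excluded from the state space, which is the CTMC formulation of
  "stop-creating changes are redrawn".  The rate matrix is symmetric,
  so transition matrices come from one eigendecomposition.

**Branch-length calibration.**  Divergence is parameterised directly in
expected *estimated* Ks.  For a separation time T the exact joint
codon-pair distribution is `J = P(T/2)ᵀ diag(π₀) P(T/2)`, from which
the expected NG86 numerator and denominator — and hence the estimator's
large-sequence value — follow in closed form; T for each event is found
by bisection so that this value equals the event's target.  Calibrating
on the estimator scale matters: NG86 with the Jukes–Cantor correction
is not unbiased for a codon process with mixed site degeneracies, and
naive event counting would put the oldest peak ~30% above its target.
Targets whose expected uncorrected pS comes within 1% of the 3/4
Jukes–Cantor pole are rejected at configuration time (estimates there
are effectively saturated).  Epoch branch lengths follow from the three
calibrated times, each lineage receiving half of each epoch, so all
three pairwise targets hold simultaneously.

What the simulator does **not** emulate: intergenic DNA, transposons,
tandem duplication bursts, gene conversion between homoeologs
(multivalent-pairing homogenisation), indels within genes,
post-speciation continuation of WGT fractionation, codon-usage bias,
and rate variation among sites or lineages.  Passing tests therefore
show the pipeline recovers the layered homology structure under clean
divergence and clean whole-gene loss — not that it is robust to every
complication of real annotations (fragmented assemblies, tandem-array
misannotation, pervasive translocation).

## Pipeline, determinism, problem sizes

Every stage is deterministic given its inputs; the only randomness is
the simulation seed.  `run_pipeline` writes each artifact and a SHA-256
manifest; re-running with the same seed reproduces every byte, which
the suite asserts.  Dot plots are pure functions of their inputs
(rank-space axes, one SVG element per hit, one annotation per dated
block, binary Ks colouring split midway between the speciation and WGT
window centres).

Problem sizes used by the test suite and the acceptance script — the
default 3×200-gene scenario (~900 reference genes after WGT
fractionation), a loss-free 3×200 control (1800/3600 genes), three
replicate seeds for loss-rate recovery, and twenty 2×100 replicates
for the recovery mean-absolute-error bound — were chosen so the whole
validation cycle completes in minutes on a single CPU while leaving
every recovery bound (peaks ± 0.1, loss rates ± 0.03, ortholog
F1 ≥ 0.9) comfortably testable at binomial-noise level.

## Known limitations

* Orthology assignment works block-by-block with a per-chromosome rank
  check; it does not enforce a globally consistent two-colouring of
  derived regions across chromosomes (no subgenome phasing).
* The census reports colinear *pair* totals; published tables of this
  kind sometimes count genes (twice the pairs) — the writer keeps
  pairs and documents the convention.
* NG86 assumes equal base frequencies and no transition/transversion
  bias; it is the method this package is specified to implement, not
  the most accurate available (no ML codon models, no among-site rate
  variation).
* `naive_all_vs_all` is a testing-grade search: no HSP tiling, no
  composition-based statistics, no masking.  For real genomes, feed
  BLASTP tabular output instead.
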