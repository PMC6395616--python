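# Methods

This note records the models, parameter choices and numerical conventions
behind `paleofrac`, and what the synthetic benchmark does and does not show.

## Coordinates and formats

All genomic intervals are 0-based half-open internally; GFF3 (1-based
closed) and BED inputs are converted at the reader boundary, so `end − start`
always equals the GFF3 `end − start + 1` length.  Bismark CX reports keep
their native 1-based positions inside the methylation table and are converted
at query time.  Genes on unplaced scaffolds are retained by the readers but
never enter chromosome-windowed analyses.  TPM replicates are averaged to one
column per tissue before any analysis; the alternative (pooling counts before
quantification) is upstream of this package's inputs.

## Anchor chaining

The chainer is a documented dynamic programme over anchors sorted by gene
rank, run per chromosome pair and per orientation: extending a chain earns
`match_score` (50) and pays `gap_penalty` (−1) per unit of gene-rank gap on
either genome, an extension is forbidden when either gap exceeds `max_gaps`
(25), and chains shorter than `match_size` (5) pairs are dropped.  Chains are
extracted greedily (best score, ties to the longer chain, then the lower
starting rank); chains on one chromosome pair sharing more than
`overlap_window` (5) genes are merged when their union is still a valid
chain, otherwise the lower-scoring chain is trimmed.  This honours the
printed parameter semantics of the standard collinearity toolkit without
reproducing its internals bit-for-bit; real `.collinearity` files can be
supplied instead and bypass the chainer entirely.  A toy-instance exhaustive
chain enumerator in the test suite confirms the DP reaches the optimum.

The block E-value is defined as min(per-pair E-value)^(pair count), floored
at 1e−300 — a monotone surrogate adequate for the 1e−10 false-positive
threshold; files from the external toolkit carry that tool's own value.

## Ka/Ks (NG86)

Counting follows Nei–Gojobori (1986) under the universal code: per-codon
synonymous site fractions (mutations creating stops count as nonsynonymous)
averaged over both sequences; observed differences averaged over all
orderings of the differing codon positions, excluding orderings that pass
through a stop codon unless every ordering does; Jukes–Cantor correction on
both proportions.  Codon columns containing a gap, ambiguity or stop are
dropped pairwise.  Proportions within 1e−12 of 3/4 are reported as saturated
(infinite distance): at that point the corrected distance exceeds ~20
substitutions/site and is numerically meaningless, and the tolerance removes
floating-point ties at exactly 3/4.  Sequences must be equal-length codon
alignments; no aligner is included by design.

## Ks mixture and block dating

Block age is the median of its finite pair Ks values.  The mixture model is
a 1-D Gaussian mixture fitted by EM (quantile-chunk initialisation,
perturbed restarts on component collapse, log-likelihood gain < 1e−8 as
convergence); Ks values above 3.0 are excluded as saturated.  Within the
pipeline the mixture is fitted to the **per-pair** Ks distribution of the
filtered blocks rather than to the block medians: a duplicated genome yields
only a few dozen blocks, and a 2-component EM on ~30 points intermittently
collapses into a broad catch-all component that swallows recent blocks,
whereas the ~10⁴ pair values give a stable fit.  Blocks are then classified
ancient when the posterior of the highest-mean component at their median Ks
exceeds 0.5; a hard Ks interval is available as an option for users who
prefer the fixed-window reading.  k = 2 (speciation + ancient WGD) is the
default, with BIC over k ∈ 1..4 reported for model-order checks.

## Subgenome phasing

Within each outgroup chromosome, block footprints define breakpoints;
maximal segments with a constant covering-block set are the analysis units.
This replaces a reciprocal-overlap pairing rule: segmental translocations
nest a short footprint inside a chromosome-length one, where any fixed
reciprocal-coverage threshold fails, while breakpoint segmentation reduces
to the same pairing when regions match one-to-one.  Segments covered by more
than two blocks keep the top two by chain score (logged).

Per segment, each outgroup gene is classified: retained in one region only
(singleton of that region), in both (homeolog pair with mutual partner
links), or in neither.  Tandem-array genes — transitive closures of
intra-genome hits separated by at most one intervening gene — are excluded
before counting on both genomes.  The region with more singletons is
subgenome 1; ties go to more retained genes in total, then to the
lexicographically smaller duplicated-genome chromosome name.  Labels are
per region pair: the package deliberately does not claim subgenome 1 is one
contiguous ancestral haplotype genome-wide, and does not enforce label
consistency across region pairs sharing a duplicated chromosome.  A segment
covered by a single block inherits that block's label from the pair where it
was paired (largest shared segment wins); never-paired blocks stay
unassigned.

A direct consequence of the rule, visible in any loss-rate table built this
way: subgenome 1 always has the lower loss rate, and the per-chromosome
loss-rate difference equals Σ(n₁ − n₂)/N over its region pairs — a folded
(always-positive) noise statistic even when fractionation is perfectly
unbiased.  Its typical size scales as √(2p(1−p̃)/N_chrom), so the observable
"bias" floor depends strongly on chromosome gene counts: ~0.05 at 1,000
genes per chromosome versus ~0.02–0.03 at the ~3,350 genes per chromosome of
a peach-sized outgroup.  Comparisons of this statistic are therefore only
meaningful at matched genome scale, which is why the acceptance script
reports it at both the generator's default scale and the emulated outgroup's
annotation size.

## Fractionation statistics

Sliding windows are 100 genes wide with step 1 (configurable); tandem
outgroup genes are dropped before windowing.  Loss rates are reported
rounded half-up to two decimals, mirroring the conventional table layout;
differences are computed from unrounded rates and then rounded, which can
make a printed difference disagree by one unit in the last place with the
difference of the printed rates (deliberate, and why one published table row
with that property is not used as an exact check).

## Expression

The expression threshold is always recomputed from the supplied intergenic
TPM matrix (median per tissue, mean over tissues) — the published value
0.715 is treated as data-dependent, not a constant.  Breadth uses a strict
`>` comparison.  Dominance: both members at or below the threshold →
both-silent; otherwise a more-than-twofold ratio (strict, with an ε = 1e−9
division guard so silent-vs-expressed is dominant) picks the dominant
member; the boundary (exactly twofold) is conserved.  The subgenome-level
expression contrast uses per-gene mean TPM across tissues (one test), while
dominance is summarised per tissue, matching the respective result surfaces.

## Methylation

Levels are weighted (summed counts, one division), never means of
per-cytosine ratios; replicate pooling sums counts per site, so pooling is
invariant to how sites are split across files.  Metagene profiles use 30 ×
100-bp bins per 3-kb flank and 40 equal-width body slices (the region
definitions are fixed by the analysis; this binning is this package's
declared choice, configurable), pool counts across genes per bin, and flip
minus-strand genes onto the transcription axis.  Group comparisons use the
per-gene region level (upstream / body / downstream), not per-bin values, so
one significance call is made per region; genes without coverage are
dropped, and `min_total` (default 1, ≥4 recommended for shallow libraries)
sets the per-cytosine coverage floor.  CHH is parsed and supported but the
pipeline's comparisons focus on CG and CHG, the prevalent plant contexts.

## Statistics

Two-sided Mann–Whitney U with midranks; exact enumeration when
n₁ + n₂ ≤ 12 without ties, otherwise the normal approximation with
tie-corrected variance and continuity correction; two identical samples give
p = 1.  No multiple-testing correction is applied — each p-value is reported
raw next to its labelled comparison, matching the analysis style the package
reproduces.  Stars: `*` p < 0.05, `**` p < 0.01, strict.

## Synthetic data generator

The generator emulates the study design, not any particular genome sequence:

- **Genomes.** An outgroup of 8,000 genes on 8 chromosomes (default); a
  duplicated genome built as two copies (A, B) of the ancestral gene order
  with independent per-gene Bernoulli retention (p₁ = p₂ = 0.6 unbiased;
  0.675/0.525 biased, i.e. Δ = 0.15); 4 segmental translocations of 50–500
  genes (inverted with probability 0.5) creating the many-to-one dot-plot
  mosaic; 6 older duplicated segments (100–300 genes, retention 0.3)
  descending from an ancient shared WGD; ~60 tandem arrays; a second
  outgroup sharing the ancestral order with 0.85 retention.  Anchor hits get
  E-values 10^−U(10,100) plus 2% spurious hits at 10^−U(6,9).
- **Sequences.** A symmetric codon Markov process over the 61 sense codons
  (synonymous exchanges at rate 1, nonsynonymous at rate dN/dS = 0.2, stops
  unreachable), spectrally decomposed once; branch lengths are calibrated
  against the process's expected NG86 Ks so each planted segment realises
  its target Ks — recent segments N(0.40, 0.08), ancient N(1.37, 0.20), the
  second outgroup at Ks ≈ 0.9.
- **Expression.** log-normal TPM: per-family baseline (ln-mean 2.0, sd 1.2)
  and per-tissue effect (sd 0.3) shared by homeolog partners, member noise
  sd 0.15, singletons shifted +0.6 (ln scale), and a fourfold dominance
  boost planted on one random member of 20% of homeolog pairs across all
  seven tissues.  Intergenic TPM is Exponential(mean 0.7), whose per-tissue
  median 0.7·ln 2 ≈ 0.485 gives a closed-form check of the threshold.
- **Methylation.** Cytosines every ~50 bp across gene bodies and 3-kb
  flanks, context CG/CHG/CHH with probabilities 0.4/0.3/0.3; per-gene,
  per-region true levels on the logit scale around (CG: 0.35/0.55/0.35,
  CHG: 0.25/0.10/0.25, CHH: 0.05) with gene-level sd 0.5; two replicates
  with Poisson(20) coverage and binomial methylated counts, for a default
  subset of 3,000 genes (homeolog pairs kept whole, then singletons).

Ground truth records each gene's copy of origin, planted segment,
singleton/homeolog class, partner, planted expression effects and true
methylation levels.  The *true subgenome label* applies the package's own
singleton-majority rule to the planted segments (footprints spanning first
to last retained non-tandem gene): it is the label an ideal synteny detector
would assign, so label-recovery scores measure the reconstruction machinery
(chaining, filtering, dating, counting) rather than re-deriving the rule.

What passing tests do **not** show about real data: no transposon landscape
or methylation-expression coupling, fractionation is independent per gene
(no selection on dosage-sensitive genes), expression is log-normal without
count noise, CDS are equal-length and indel-free, and per-segment Ks targets
make evolutionary-rate contrasts between arbitrary gene groups
cluster-correlated (a real caveat the simulator shares with real blocks).

## Problem sizes and runtime

Unit tests run the generator at 800–3,000 outgroup genes; the study-scale
checks use the generator default (8,000 genes, seed 1), where the full
pipeline (files written and re-read) completes in well under a minute, and
one loss-rate computation is repeated at the emulated outgroup's annotation
size (26,873 genes) where the sliding statistic has its published-scale
noise floor.

## Known limitations

- No codon-aware alignment: Ka/Ks inputs must already be comparable.
- The block E-value surrogate is monotone but not MCScanX's formula.
- Subgenome labels are per region pair; genome-wide haplotype phasing
  (k-mer- or repeat-based) is out of scope.
- Mann–Whitney is the only test offered; effect sizes beyond group medians
  are not estimated.
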