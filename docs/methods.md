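# Methods

`loopshift` implements the statistics used to connect acute depletion of a
chromatin-binding transcription factor to changes in cohesin occupancy and 3D
genome organisation: contact-map normalisation, compartment and domain
summaries, loop pileups, a responsive-loop classifier, three permutation
nulls, 4C quantification and ChIP-MS candidate filtering.  Everything is
exercisable on synthetic data with planted, recorded truth.  This note
documents the models, the defaults and why, the numerical choices, and what
the synthetic tests do and do not demonstrate about real data.

## Coordinates and containers

All coordinates are 0-based half-open `[start, end)`; chromosome order is the
`GenomeModel` order, never lexicographic.  Contact matrices are
per-chromosome, intrachromosomal, stored as upper-triangle sparse pixels with
a `raw | balanced | oe` state flag and per-bin balancing weights (nan =
masked).  Interchromosomal input pixels are dropped at load with a logged
count.  Binned signal tracks are dense per-chromosome vectors; interval sets
are DataFrames sorted by (genome order, start).

## Contact-map normalisation

**Pair filter.** Pixels at genomic separation ≤ 20 kb are removed before
balancing (strictly-greater policy: a 25 kb separation survives a 20 kb
cutoff).  Short-separation pairs are below the effective map resolution and
are dominated by ligation artefacts.

**Balancing** is iterative correction (ICE) toward equal unmasked marginals:
repeat `w_i ← w_i / sqrt(rowsum_i / mean rowsum)` until the maximum relative
rowsum deviation is below `tol` (default 1e-5, `max_iter` 200), then rescale
weights so unmasked rowsums equal exactly 1.  Low-coverage bins are masked
first: bins whose log marginal falls more than `mad_max` (default 5) median
absolute deviations below the median.  The MAD cut is skipped when the MAD of
log marginals is below 1e-3 — i.e. when marginals are already essentially
uniform — because on a re-balanced matrix the MAD is numerical noise and the
cut would mask bins arbitrarily; this also makes balancing exactly idempotent.
Non-convergence is flagged on the result and warned, never silent.

**Expected profile and O/E.** The expected value at separation *d* is the
mean balanced contact over *all* pairs of unmasked bins at that separation,
structural zeros included, so long-range expectations are unbiased.  The O/E
transform divides each pixel by the expected value at its distance; on exact
inputs every populated O/E diagonal therefore averages 1 to ~1e-15.

**Depth matching** is multinomial thinning of the pixel count vector to an
exact target total; **`split_counts`** thins binomially with fraction 1/2,
which for Poisson counts yields two *independent* Poisson halves — the basis
of the cross-validated saddle below.

## Compartments and the saddle score

E1 is the leading eigenvector of the Pearson correlation matrix of the dense
O/E map (masked rows removed, re-inserted as nan; unit norm).  Undefined
cells (the filtered diagonal, masked pixels) are filled with the mean O/E
before the correlation: zero-filling would couple each pixel's noise
negatively into its own bins' correlation and systematically distort
downstream block averages.  E1 is sign-ambiguous and is oriented per
chromosome so it correlates positively with an active-chromatin reference
track; a zero-variance overlap leaves the sign unchanged and flags the
chromosome.

The saddle ranks bins by E1 into equal-count quantiles per chromosome (ties
broken by bin index), pools pixel means genome-wide into a Q×Q matrix
(symmetric by construction), and reports

    score = (AA + BB) / (2·AB)

where AA/BB are the mean O/E within the top/bottom 20% of quantiles and AB
the mean between them.

**Why the reported score is cross-validated.** If E1 is estimated from the
same map whose pixels the saddle averages, the ranking aligns with the map's
dominant noise mode and the score of a *compartment-free* map is pulled away
from 1 — at the desk-scale depth used here the bias reaches ~0.1, the scale
of a real biological effect.  `cross_validated_saddle` therefore splits the
raw counts into two independent halves, estimates E1 on one and averages the
saddle on the other.  Under the null this is unbiased (measured 1.00 ± 0.01
across seeds); with planted compartments the score remains monotone in the
planted amplitude.  The plain `saddle` function (ranking and averaging the
same map) is kept for use when E1 comes from an external source.

## Pileups and insulation

Pileups average O/E submatrices over targets with per-cell denominators, so
masked bins never zero-inflate the mean.  The pileup score is the mean of the
central 3×3 cells of the odd-sized (2F+1)² grid; the APA flank default is 10
bins at 25 kb (the window size is not critical and is exposed in every call).
Variants: `apa` centers on loop pixels, `local_pileup` on the diagonal at
anchor bins, `rescaled_domain_pileup` pads each domain by `pad_factor` × its
own length on both sides and block-averages (mass-preserving, deterministic —
not interpolation) the window to a fixed output size.  Rescaling with the
output size equal to the window size is the identity.

Insulation at bin *i* is the mean of the w×w diamond spanning bins
(i−w..i−1) × (i+1..i+w); the reported value is log2(diamond / chromosome mean
of diamonds), which cancels any global scale factor exactly.  Bins where the
diamond does not fit, or whose own bin is masked, are nan; an all-zero
diamond maps to −inf — a real structural-zero minimum, not missing data.

Note an identifiability limit: because the expected profile absorbs whatever
same-domain enrichment dominates each separation, O/E-based domain pileups
under-state the inside/outside contrast when compared across different
separations.  The domain-contrast test therefore compares inside vs
boundary-straddling cells *at matched rescaled distance*, where the planted
contrast is recovered.

## Loop statistics and permutation nulls

**Merging.** Loops called at 5/10/25 kb are mapped to the 25 kb bin holding
each anchor midpoint and deduplicated on the bin pair, keeping the finest
source resolution; merging is idempotent.

**Loop strength** is the mean O/E over the 3×3 block at the loop pixel;
condition changes are reported as log2(after/before).

**Length-rank GSEA.** Loops are sorted by decreasing length; the running sum
steps +1/|hits| at hits and −1/(N−|hits|) elsewhere (the classic, unweighted
running sum — rank-only input carries no weighting information); ES is the
signed maximum deviation.  The null permutes hit labels.

**Anchor-element enrichment.** Observed = element peaks (midpoint rule)
inside loop anchors; each of the (default 1000) permutations relocates every
loop uniformly on its own chromosome, preserving anchor widths and
separation.  Keeping each loop on its chromosome preserves per-chromosome
composition and avoids infeasible placements; loops longer than their
chromosome are skipped and counted.  Enrichment = observed / null mean.

**Gene-category enrichment.** A gene belongs to the loop set if its TSS lies
in ≥1 loop span; the per-category ratio is (in-loop category fraction) /
(genome-wide fraction); the null is length-preserving uniform relocation
(default 10 000 rounds), two-sided.

All permutation p-values use the +1 correction,
`p = (1 + #{null ≥ obs}) / (1 + n_perm)`, are never 0, and are bit-reproducible
under a fixed seed.  Under their own nulls both label/relocation tests reject
at α = 0.05 with empirical rate 0.047/0.053 (1000 replicates, n_perm = 200) —
computed by the acceptance suite, not quoted from anywhere.

**Responsive-loop classifier.** Candidates are loops longer than 500 kb
(midpoint separation, strict).  Each candidate scores the sum over ATAC peaks
inside its span (midpoint containment in [anchor1.start, anchor2.end]) of the
factor track signal at the peak plus |cohesin log2FC| at the peak; signal at
a peak is the length-weighted track mean over the peak interval.  Responsive
= top-N highest-scoring candidates containing ≥1 factor peak *and* ≥1
down-regulated cohesin peak; less-responsive = bottom-N candidates containing
neither.  Ties break by (score, genome chromosome order, anchor1 start), so
the partition is deterministic; short pools are returned whole with a
warning.  Down-regulated peaks are labelled *inputs* — the differential-
binding model that produces them is out of scope.

## ChIP quantification and small formulas

RPGC scaling multiplies a coverage track by genome_size / total coverage so
mean per-bp coverage is 1; spike-in scaling multiplies by reference spike
reads / sample spike reads.  Feature matrices gather exact length-weighted
window means around peak centers (summit when present) or TSSs, strand-
flipped for minus-strand genes; `scale-region` mode resamples the gene body
to a fixed column count.  Peak annotation applies the fixed priority
promoter > enhancer > CTCF site > gene body > other, with the element
builder enforcing the exclusion definitions (promoter = TSS ± 1 kb; enhancers
= active peaks minus promoter overlaps; CTCF sites minus both).  Bound genes
= top-N peak-bearing genes by mean promoter signal; unbound = bottom-N
peak-free genes; ties break by gene id.

Row z-scores use the sample SD (n−1); constant rows become zero and are
flagged.  Differential-signal clustering is agglomerative with Ward linkage
on Euclidean distance (the re-implementation of the quoted hierarchical
clustering); the dendrogram is cut at each k and the elbow is the k
maximising the second difference of within-cluster dispersion, with the
dispersion also evaluated one k beyond the requested range on each side
(k = 1 is the total dispersion) so the second difference is defined at every
requested k — without this, an elbow at the range boundary is invisible.
Co-occupancy regions are the maximal merged intervals of all factors' peaks,
labelled '1'…'4' or '4+' (more than four) by the number of distinct factors
overlapping.  Percent input is 100 · input_fraction · 2^(Ct_input −
Ct_sample) with input_fraction = 0.05.  Tissue-expression breadth counts
tissues strictly above 10 TPM; essentiality requires score < 0 and p < 0.05.

## ChIP-MS

Isoform rows are summed into protein rows (conserving per-sample totals).
Candidates satisfy total ChIP PSMs ≥ 2 × total input PSMs; "at least twice
more than" is read as ≥2× (a strict ≥3× reading is covered by the
configurable ratio), and a protein absent from *both* roles is never a
candidate.  The display value is log2((chip+1)/(input+1)); the pseudocount
keeps it finite and monotone in the chip count.  Venn partitions report all
2^k − 1 region counts, which sum to the union size.  The moderated-test /
imputation route used for other cell contexts in comparable studies is out
of scope; labels arrive as inputs.

## 4C

Display smoothing is a centered moving mean spanning span/bin bins (100 bins
at 50 bp/5 kb; left-biased by one bin when even), with shrinking windows at
chromosome ends — no zero padding, which would dilute termini.
Quantification always uses the *unsmoothed* normalised track: mean over the
target region divided by mean over a caller-supplied background region (the
two regions are taken verbatim as inputs; no downstream/width constraint is
imposed).  The ratio is invariant to global scaling; a zero background is
flagged nan.

## The synthetic-data generator

The generator defines the study conditions; its defaults are fixed, not
tuned.  Contact counts are Poisson with intensity

    λ_ij ∝ depth · (d+1)^(−α) · B_i B_j · exp(A·e_i e_j) · τ^[same TAD] · bump_ℓ(i,j)

with lognormal bin biases B (σ = 0.15), a ±1 block compartment vector e
(amplitude A = 0.3, 500 kb blocks), TAD contrast τ = 1.5 over 200–500 kb
domains, and decay α = 1.  The desk-scale fixture is 2 chromosomes × 10 Mb at
25 kb bins (400 bins each), depth 2×10⁶ pairs — sized so the whole acceptance
suite runs in well under its budget on one CPU.

**Planted loop strength is defined on the APA scale.** A loop multiplies
λ by 1 + c·exp(−(di²+dj²)/2) around its pixel with c = 9(ℓ−1)/Σ(3×3 Gaussian
weights), so the mean enhancement over the central 3×3 block is exactly ℓ —
the planted strength is the very quantity the APA central-3×3 score
estimates.  A unit-peak Gaussian bump would make the "strength" parameter an
abstraction no downstream statistic measures.

ChIP landscapes place factor peaks on a shared site pool (active-gene
promoters, enhancer and CTCF sites) with independent per-factor occupancy
probabilities (so co-occupancy counts are Binomial by construction); tracks
are Gaussian peak kernels (amplitude lognormal around 5, sd = half the peak
width) over |N(0, 0.1)| background noise.

The perturbation experiment emulates a paired acute-depletion design: the
treated cohesin track is the untreated one with amplitudes multiplied by 0.5
at factor-bound promoters (independent background noise per condition);
factor-bound promoters are those inside planted responsive loops plus a 5%
random sprinkle; down-regulated cohesin peak labels are emitted exactly
there.  Planted responsive loops (length > 500 kb) change strength
ℓ → 1 + (ℓ−1)·1.5 in the treated map; planted less-responsive loops are
rejection-sampled to avoid responsive spans and their genes are excluded from
factor binding, so their class membership is guaranteed by construction.
Gene DE categories are drawn with the 'up' rate doubled inside responsive
loops.  PSM tables give background proteins equal chip/input Poisson means
and enriched proteins a 4× chip mean; 4C profiles decay as 1/(distance+5 kb)
from a central bait with a 120 kb region 1 Mb away multiplied by the planted
fold.

**What passing these tests shows — and does not.** The generator matches the
multiplicative-bias, Poisson-noise assumptions the normalisation stack is
built on; recovery there demonstrates internal correctness (the estimators
recover what was planted, nulls are calibrated, classifications equal
brute-force oracles), not field performance.  Real maps have
distance-dependent artefacts, copy-number structure, unmappable regions and
correlated (non-Poisson) noise; real peak sets have width/score
distributions the planted ones only sketch.  Claims about real data require
real inputs through the same interfaces.

## Reproducibility

Every randomised routine takes an explicit seed (numpy `default_rng`;
identical seeds give byte-identical outputs, covered by tests).  The pipeline
driver writes a manifest with stage status, full parameter echo and a sha256
checksum of every artifact; a rerun with the same configuration is
bit-identical.  Failures are recorded in the manifest with the stage name and
earlier artifacts are preserved.

## Known limitations

- Single-chromosome (cis) analyses only; no trans expected model.
- One balancing algorithm (ICE); matrices balanced elsewhere can be supplied
  as `balanced` state but their masking conventions must match.
- The insulation normalisation (log2 against the chromosome mean of diamond
  means) is one of several conventions in circulation; absolute values are
  not comparable across conventions, minima positions are.
- The `.cool` container is not read directly; contact lists arrive as COO
  text (a converter upstream of this package is assumed).
- `anchor_element_enrichment` counts each element peak once even if it
  overlaps anchors of several loops; alternative multiplicity conventions
  would shift enrichment values, not the permutation calibration.
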