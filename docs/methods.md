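# Methods

This note documents the models and procedures each module implements, the
defaults and why they were chosen, what the synthetic generators do and do
not emulate, and the numerical choices that affect results.

## Time-lapse cycle quantification

A dark-field movie of a swimming plate shows bacterial territory as bright
signal; phage predation produces local collapses followed by regrowth. The
pipeline is: subtract the first frame from every later one and clamp
negatives to zero (removing plate background and dust); select the red
channel of multi-channel input (best dark-field signal-to-noise); average
over 10×10 px blocks; smooth each block trace with a 4-frame trailing
moving average, using shrinking windows at the start so the trace keeps its
length and frame indices stay aligned with acquisition times (frame
interval default 10 min).

A growth–lysis cycle is one intensity peak. Peaks are local maxima with
topographic prominence ≥ 4 intensity units — the height above the higher of
the two flanking minima separating the peak from higher terrain — thinned
greedily in order of descending height (ties to the earlier index) until
retained peaks are ≥ 20 frames apart. Two deliberate choices:

- A maximum at the trace boundary counts as a peak. A colony still growing
  when the movie ends has completed one colonisation cycle; plain
  `scipy.signal.find_peaks` would drop it, so detection runs on a trace
  padded with its own minimum, which leaves interior prominences unchanged.
- The plate-wide **median cycle count** is taken only over blocks whose
  maximal smoothed intensity exceeds an activity floor (default 4, equal to
  the prominence threshold). Agar the bacterial wave never colonised
  carries no cycle information and would bias the median toward zero. The
  floor and the px↔mm scale are configuration, not constants of nature.

## Plaque-image scoring

Each spot on a 96-spot omni-tray is scored inside its own L×L region
(L = 181 px, odd so a centre pixel exists). Regions are normalised by
rescale-then-clip: pixels are multiplied by 255/p90 and capped at 255, so
everything at or above the region's 90th percentile maps to 255. This
satisfies the "top decile equals 255" contract while fixing the behaviour
of darker pixels in a monotone, idempotent way, and it makes scores
invariant to per-spot illumination gain. The lysed area is the set of
pixels strictly below a threshold; by default the threshold is Otsu's
method on the pooled normalised plate histogram, overridable per plate or
region, because real plate thresholds are instrument-specific. With an
empty lysis mask the clearance mean is undefined; it is defined as 0 so a
spot without lysis scores 0 infectivity. Scores obey
`infectivity = phageFraction × clearance`, all in [0, 1], and turbidity
(normalised total intensity) acts inversely to infectivity.

Plates include deliberately phage-free spots (~25% of positions in the
original design); `carryover_qc` flags any of them whose infectivity
exceeds a tolerance, which is the designed detector for phage carryover
during colony isolation.

## Infection-network structure

The score matrix (phage rows × bacteria columns) is assembled from per-spot
tables; a pair may be scored once per plate, and repeat measurements across
plates are averaged. Wildtype control concordance is the squared Pearson
correlation between control profiles with pairwise deletion of missing
entries.

Phenotypic classes come from complete-linkage agglomeration of Euclidean
profile distances, cut at 40% of the maximum merge height. Tie-breaking on
equal merge heights follows SciPy's deterministic ordering. Missing cells
are imputed with the mean of present values in their 5×5 neighbourhood in
the class-sorted matrix (truncated at edges; an all-missing neighbourhood
is an error rather than a silent guess), then the matrix is binarised at
score > 0 (strict, configurable).

Nestedness is NODF on a 0–1 scale: over all row pairs and all column pairs,
a pair whose marginal totals strictly differ contributes the fraction of
the sparser line's 1s shared with the denser line; equal-marginal pairs
contribute 0; empty rows and columns are ignored. Modularity is Barber's
bipartite Q_b, maximised by BRIM-style alternating best-response updates of
row and column module labels from 24 initialisations (single module,
all-distinct, and seeded random label vectors), advanced in parallel; the
single-module partition has Q_b = 0 so the result is never negative. On an
exhaustive enumeration of all binary matrices up to 4×4 with ≥ 1 edge the
search attains the global optimum found by brute-force partition
enumeration; for much larger matrices it remains a heuristic with seeded,
reproducible behaviour.

Significance uses the EQUIPROBABLE null — i.i.d. Bernoulli matrices at the
observed fill — with the add-one estimator p = (1 + #{null ≥ obs})/(1 + n),
which can never return exactly zero; a reported p at the 1/(n+1) floor
means no null draw reached the observed value. Null draws whose non-empty
submatrix degenerates below 2×2 score 0 (no structure); at realistic fills
this is vanishingly rare.

## Genotype encoding

Coordinates are 1-based inclusive throughout (GenBank convention); interval
segmentation is computed half-open internally and rendered back inclusive,
so a 1000–3000 deletion in isolate A overlapping a 2000–4000 deletion in B
becomes the three unique events 1000–1999 (A), 2000–3000 (A, B) and
3001–4000 (B). Segmentation is per genome and per event type — a deletion
never cuts an amplification. Encoding gives binary columns for
SNP/insertion/deletion/IS and integer copy-number columns for
amplifications (ancestral state 1); synonymous SNPs are omitted. Predictors
with identical carrier patterns are merged into one compound predictor
(labels joined with "+" in genomic order) because no regression on these
isolates can distinguish them — except amplifications, whose integer values
are copy-number dependent. Observations are deduplicated: pairs with
identical joint genotypes are pooled into one observation carrying the mean
score and the pooled pair count as weight; weights sum to the number of
scored pairs.

Coverage-based CNV discovery divides each coverage track by its own median
and then by the median-normalised ancestral track, and reports contiguous
runs ≥ 100 bp (configurable) with normalised coverage ≥ 1.5 or ≤ 0.5 as
candidates — an automated, thresholded replacement for manual curation.
Zero-ancestral-coverage positions are masked with a warning.

## Lasso association

The model is infectivity ≈ b0 + Xb over joint genotype predictors, with the
standard Lasso objective (1/2n)·RSS + λ‖b‖₁. Predictors are standardised
internally and coefficients reported on the original scale; the intercept
is unpenalised. The penalty grid has 200 points, geometric, anchored at the
analytic critical penalty λ_max = max|X'(y − ȳ)|/n (the KKT point above
which all coefficients are exactly zero) and descending four decades — a
fixed raw penalty value would be meaningless after standardisation, so the
grid-length reading of the "200" convention is used. Selection is 5-fold CV
with the one-standard-error rule: the largest λ whose CV-MSE is within one
SE (computed across fold means) of the minimum. Folds are contiguous blocks
of a seeded shuffle, making fits bit-reproducible. Fitting is unweighted by
default; pooled-pair weights can be turned on (`weighted=True`), which
switches to a warm-started weighted coordinate-descent path.

## Adaptive-evolution tests

SNP effects are classified against the standard genetic code by translating
the containing codon before and after the change, reverse-complementing
minus-strand ORFs; stop gains and losses count as nonsynonymous, positions
outside every ORF as intergenic, and a position inside overlapping ORFs is
nonsynonymous if nonsynonymous in any (with a warning).

**P_dN/dS.** Each unique intragenic SNP is re-placed uniformly over the
concatenated ORF positions (longer ORFs proportionally more often — no
per-ORF weighting is assumed) and its alternative allele is drawn to
preserve its own substitution class: the transition partner is unique; a
transversion picks one of its two partners uniformly. The simulated
nonsynonymous count is compared with the observed one over 10,000
replicates; p uses the add-one estimator. Recurrent events (present in
several replicate plates) count once by default; a flag
(`weight_by_multiplicity`) weights each event's outcome by its replicate
count instead, since the informal "accounting for" phrasing of this rule
admits both readings. On a genome composed of codons whose per-site
nonsynonymous probability q is analytically enumerable, the null count is
exactly Binomial(s, q) for s same-class SNPs, which the test suite uses as
an exact oracle.

**Multi-hit genes.** Every mutation event is re-positioned uniformly over
the genome keeping its length (m independent draws for an event seen in m
replicates; interval events increment every overlapped gene). The null
statistic is the replicate-wise maximum per-gene count, which controls the
family-wise error of flagging any gene at all; a per-gene thresholding mode
is available behind a flag. The
threshold c* is the smallest count attained by at most α (default 0.05) of
replicates, and genes with observed count ≥ c* are flagged. Defaults follow
the original analysis scales: 10,000 dN/dS replicates, 500 (bacteria) and
5,000 (phage) multi-hit replicates.

## Synthetic data: what it emulates, and what it does not

`gen_timelapse` renders a radially expanding wave (raised-cosine ramp to a
plateau of 60 intensity units over 20 frames) with planted raised-cosine
lysis dips of configurable depth and 30-frame duration, so a block with k
events has exactly 1 + k intensity maxima; the spec validator rejects
geometries (events inside the ramp, too close together, or truncated by the
end of the recording) where that identity would not hold. Rendering is
8-bit with optional Gaussian pixel noise. It does not emulate chemotaxis
PDE dynamics, wave-front roughness, or illumination drift — so passing
recovery tests demonstrates correctness of the cycle-counting pipeline, not
robustness to every imaging artefact.

`gen_plate_image` paints plaques as centred discs with an exact pixel
count, so per-spot truth is closed-form on the post-normalisation scale and
scoring is exact up to the 1/L² area discretisation. Plaque morphology
(halos, bull's-eyes, ragged edges) is not modelled. Planting a plaque in a
designated phage-free spot is allowed deliberately: it simulates carryover,
the failure mode the QC stage detects.

`gen_genotype_phenotype` draws mutations carried by a fixed small fraction
(default 8%) of isolates — evolved mutations are minority variants — and
generates pair infectivity as clip(baseline + Σβx + ε, 0, 1), the additive
model the association stage assumes, with β ≠ 0 on a sparse support
(default 5 of 50). The default study condition measures 500 pairs sampled
from a 250 × 200 isolate library rather than a small full cross: in a full
cross of nb × np isolates the joint design has rank ≤ nb + np − 1, so 50
coefficients over a 25 × 20 library are provably non-identifiable and no
method could recover the planted support; sampling pairs from a larger
library keeps each predictor varying across many distinct isolates, making
the generator's "planted support is recoverable" contract true. Epistasis,
genotype-dependent noise and measurement batch effects are not modelled.

`gen_toy_genome` builds plus-strand ORFs from a stated codon composition
(e.g. all-TGG, where every substitution is nonsynonymous, or random sense
codons) separated by random spacers, and computes per-site nonsynonymous
probabilities per substitution class by exhaustive codon enumeration —
the analytic oracle for the permutation tests.

All generators are pure functions of their spec (including its seed):
repeated calls are bit-identical.

## Numerical choices and degenerate inputs

- Peak thinning is greedy by height with earlier-index tie-break:
  deterministic and matching common peak-picker semantics.
- Region normalisation computes v/p90·255 (not v·(255/p90)) so a pixel
  equal to p90 maps to exactly 255 in floating point.
- `normalize_region` on an all-zero region returns it unchanged; Otsu
  thresholding of a constant plate falls back to 127.5.
- Lasso: constant response is an error (no model); constant predictor
  columns are left standardised to zero and can never enter; coordinate
  descent runs at tol 1e-6, max 10,000 iterations.
- p-values from permutation/null tests are add-one estimates in (0, 1].
- `nodf` raises on matrices smaller than 2×2 after removing empty lines;
  inside null sampling such degenerate draws score 0.
- Problem sizes in the test suite and acceptance script (50×50 blocks ×
  300 frames; 10×10 null matrices × 1,000 draws × 200 replicates; 20
  regression seeds; 10,000/5,000 permutation replicates) were chosen to
  exercise each stage at the scale its guarantees are stated while keeping
  a full run in a few minutes on one CPU.

## Known limitations

- The modularity search is exact only where exhaustively verified (≤ 4×4);
  on large matrices it is a restart heuristic like all practical Q_b
  maximisers.
- The 1-SE rule on nearly noise-free, isolate-blocked designs can admit a
  few small spurious coefficients: when cross-validation cannot
  distinguish models near the flat optimum, sparsity rests on the SE
  margin, not on identifiability. The support-recovery guarantee is stated
  (and tested) as a ≥ 90%-of-seeds property, not per-dataset.
- Spot centres must come from a layout (regular grid fit); automatic spot
  detection is out of scope.
- dN/dS here is a permutation test of nonsynonymous excess, not a
  codon-model rate estimate; indels are not part of the selection tests.
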