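# Methods

This note documents the model behind `mragree`, the conventions it
fixes where the underlying method leaves choices open, what the
synthetic cohort generator does and does not emulate, and the package's
known limitations.

## Object-level agreement model

A *call* is one putative object delineated by one reader on one image,
represented as a pixel mask (set of `(row, col)` coordinates), an
inclusive bounding box `(xmin, ymin, xmax, ymax)` with `x = column`,
`y = row`, or both.  Boxes are inclusive at both ends (a single pixel
has area 1); this matches label-image indexing and makes pixel and box
IOU directly comparable.

Agreement between two calls is a pixel-level overlap score: mask IOU
(|A∩B|/|A∪B|), mask DSC (2|A∩B|/(|A|+|B|) = 2·IOU/(1+IOU)), or
bounding-box IOU for detector-style comparisons.  Two calls *agree*
when their score meets an IOU threshold **inclusively** (score ≥ t).
The threshold comparison had to be fixed by this package: descriptions
of the rule elsewhere alternate between "more than" and "≥"; the
inclusive form matches how thresholded results are conventionally
tabulated (e.g. "IOU ≥ 0.25") and is used everywhere here.

### Matching two readers

All calls of reader A are scored against all calls of reader B (an
M × N agreement matrix; disjoint bounding boxes short-circuit to 0 so
the matrix costs far less than M·N mask intersections on sparse
images).  Sub-threshold entries are zeroed and a version of non-maximum
suppression retains an entry only if it is the maximum of both its row
and its column among surviving entries.  This resolves *fragmenting* —
reader B drawing two calls inside one call of reader A — by accepting
only the best fragment; the other fragment remains an unmatched call.
Readers carry no confidence scores, so suppression is driven purely by
the overlap metric; every reader's call has equal weight.

**Tie-break.** Exact score ties for a row or column maximum have no
canonical resolution; `mragree` awards the tie to the smaller (row,
then column) index.  This is a repository decision made for
determinism; the test suite checks the implementation against an
independent brute-force scan of the same rule, including dense-tie
matrices.

The retained pairs are the object-level true positives; with reader A
as reference, FN = M − TP and FP = N − TP (swapping readers swaps
FP/FN and leaves both indices unchanged).  When neither reader called
anything, TP+FP+FN = 0 and the indices are *undefined* — reported as
missing, excluded from aggregation, never silently 0 or 1, because 0/0
has no natural value and silent defaults bias image-level means.

### Consensus across N_R readers

Matched pairs are computed for all N_R(N_R−1)/2 reader pairs.  Calls
are nodes, retained pairs are edges, and consensus *objects* are the
connected components of this graph; unmatched calls become singleton
objects, so the match matrix partitions every call.  Each object
carries k = number of readers with a call in it.

**Transitive conflicts.** Component linking can chain two calls of the
same reader into one object (A0–B0, B0–C0, C0–A1), which the
one-call-per-reader-per-object constraint forbids.  While any component
violates the constraint, the lowest-score edge in that component is
deleted and components are recomputed (ties broken by edge insertion
order).  This destroys the least agreement evidence; deletions are rare
under realistic geometry, are logged, and are recorded on the returned
match matrix (`dropped_edges`) because they mark genuinely ambiguous
annotations.

**Representative masks.** When a single mask must stand for an agreed
object (layered rendering, curated ground truth) `mragree` uses the
*medoid* member call — highest mean overlap with the other members,
ties to reader order — rather than a pixel-vote fusion.  This preserves
a real instance boundary and never fabricates pixels; it is a
deliberate contrast to binary-mask label fusion (STAPLE-style), which
discards object identity and cannot keep tightly packed nuclei
separate.  The layered consensus stack stores *labels*, not binary
masks, for the same reason.

### The multireader indices

With C = total calls and O = total objects at a threshold,

    J = (C − O) / ((N_R − 1) · O),
    S = N_R · J / (N_R − 1 + J) = N_R (C − O) / ((N_R − 1)² O + C − O).

Equivalently J is the object-average of (k−1)/(N_R−1): the fraction of
*other* readers agreeing with a call, averaged over objects.  The
closed form for S is derived from the Sørensen–Jaccard relation and is
verified symbolically (sympy) and by exact rational arithmetic against
the two-reader confusion forms in the tests.  S ≥ J always
(S − J = J(1−J)/(N_R−1+J)); both are undefined when O = 0.

Indices are computed **per image** and aggregated across images as a
mean with a two-sided 95% t-interval, excluding undefined images (and
reporting how many were excluded).  Pooling raw counts across images
before dividing is available (`pooled_counts`) but is not the default,
since image-level aggregation is the standard reporting convention for
reader studies and keeps images exchangeable units.

A property worth knowing: because every reader contributes some
unsupported calls, the group index *declines slightly as the panel
grows* even when all readers are statistically identical (each new
reader adds singleton objects).  Candidate-reader comparisons therefore
use noninferiority logic — "does adding the candidate decrease
agreement more than adding another typical reader would?" — rather than
naive equality tests.

## Evaluation protocols

* **Leave-one-reader-out** (N_R ≥ 3): per-image multireader Jaccard of
  the full panel vs. each N_R−1 subset; one-sided Mann–Whitney U toward
  the subset being higher ("the smaller group of readers has the higher
  mean"), Bonferroni-corrected over the N_R comparisons (the correction
  count is a parameter when more thresholds/metrics are tested jointly).
  Pairwise matchings are computed once per image and shared across
  subsets, which makes the N_R+1 evaluations nearly free beyond the
  first.
* **Candidate as extra reader**: per threshold, per-image group index
  without vs. with the candidate; two-sided Mann–Whitney U with
  Bonferroni over the thresholds tested, plus the noninferiority bound.
* **Noninferiority bound**: lower limit of the one-sided 90% CI of the
  mean paired per-image difference.  The construction is not canonical;
  the default is a seeded percentile bootstrap over images (10,000
  resamples), with a t-based construction available
  (`method="t"`).  The bootstrap is distribution-free and matches the
  otherwise nonparametric testing stance; on normal differences it
  agrees with the −z₀.₉·σ/√n closed form within Monte-Carlo error
  (tested).
* **Stringency curve**: ground-truth sets curated at min_calls k =
  1..N_R; the candidate is scored against each with the *pairwise*
  Jaccard (the curated set is a single reference, so the multireader
  form is not appropriate), and a Kruskal–Wallis test asks whether
  apparent performance depends on k.

Statistical tests are delegated to scipy — the contribution here is the
metrics and the protocol (alternatives, comparison counts, correction),
not the tests themselves.

## Synthetic reader cohorts

The generator emulates a reader panel annotating nucleus-like blobs:
per image a *scene* of disjoint random ellipses (rejection-sampled), and
per reader an error process with four independent mechanisms:

| parameter | meaning | default |
|---|---|---|
| `miss_rate` | probability a true object is not called | 0.06 |
| `fp_rate` | spurious calls per image (Poisson mean) | 2.5 |
| `jitter_px` | max dilate/erode radius applied to each call (px) | 2 |
| `fragment_rate` | probability a call is split along a random chord | 0.04 |

Cohort geometry defaults to the design size of a five-reader manual
annotation study: 50 patches of 512 × 512 px with ~25 nuclei of radius
5–15 px.  The moderate profile was calibrated once so that a 5-reader
cohort reproduces the agreement magnitudes reported for trained novice
readers on nucleus segmentation (multireader Jaccard ≈ 0.55 / 0.46 /
0.27 at IOU thresholds 0.25 / 0.50 / 0.75, mean pairwise above it); the
simulated cohort lands at ≈ 0.55 / 0.48 / 0.24.  Two notes on realism:

* `fp_rate` stands for *all* non-consensus calls — in real data mostly
  faint or ambiguous nuclei that only one reader outlines, not
  hallucinations.  Detection-level disagreement is what pushes the
  multireader index below the pairwise mean; pure independent misses
  push it the other way, so a generator with only misses would invert
  the qualitative ordering real panels show.
* Misses are independent across readers.  Real disagreement is
  object-difficulty-correlated (the same dim nucleus is skipped by
  several readers), which produces more middling-k objects than this
  generator does.  Passing tests therefore demonstrate the pipeline and
  the metric algebra, and qualitative orderings under an
  independence-noise model — not distributional claims about any real
  reader panel.

Randomness is counter-based (`SeedSequence` streams keyed by top seed,
image index, reader index, and a CRC of the image id), so adding a
reader or an image never perturbs the other annotations — required for
ceteris-paribus add-a-reader experiments.  Outlier readers for the
power analyses triple `miss_rate` and `fp_rate`.

Scale choices in the shipped checks: single-cohort analyses run at the
full 512 × 512 / 25-object design size; the replicate-cohort power
analyses (outlier detection across 20 cohorts) use 256 × 256 patches
with ~12 objects, which preserves the scale-free outlier effect while
keeping the suite quick on one CPU.

## Numerical and degenerate-input choices

* Overlap scores are exact ratios of integer pixel counts; the
  multireader indices optionally return `fractions.Fraction` so the
  two-reader reduction can be asserted bit-for-bit.
* Empty calls are rejected at load; images where a reader made no calls
  flow through as 0 × N agreement matrices (TP = 0, FP = N).
* Polygon rasterization: a pixel is foreground iff its center lies
  inside or on the polygon boundary (pixel `(r, c)` occupies
  `[c, c+1] × [r, r+1]`, center `(c+0.5, r+0.5)`).  Freehand annotation
  tools do not agree on a rule; this one is deterministic and verified
  against an independent point-in-polygon oracle.
* Label images cannot represent overlapping calls from one reader;
  instance JSON can, and both loaders agree on non-overlapping inputs
  (tested).  Whether real readers' outlines may self-overlap is
  unknowable from label images alone, so neither case is assumed.

## Limitations

* Single object class only.  A multiclass extension (summing calls and
  agreements across classes before forming the indices) is a documented
  future direction, deliberately not implemented here.
* The consensus conflict-resolution rule (weakest-edge deletion) and the
  NMS tie-break are repository conventions; alternative conventions
  could change object counts by small amounts on pathological
  geometries.
* The generator produces masks only — no intensity images — and cannot
  exercise appearance-driven reader behaviour (fatigue, contrast
  effects, difficulty correlation).
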