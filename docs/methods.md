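# Methods notes

This note documents the models, defaults and numerical choices behind
`sedadna`, what the synthetic-data generator does and does not emulate,
and the design decisions taken where the problem was genuinely open.

## Synthetic degraded-DNA model

**Fragments.** Lengths follow a log-normal truncated to
`[min_len, max_len]` (defaults 30–150 bp, mean 55 bp, spread 15 bp) —
the conventional shape for permafrost and lake-sediment DNA. `mean_len`
is defined as the mean of the *truncated* distribution: the log-normal
location parameter is solved numerically (Brent's method on the monotone
truncated-mean function), so truncation never shifts the realized mean
and "empirical mean ≈ mean_len" is an honest invariant rather than an
approximation.

**Deamination.** C→T substitution probability at 5′ position *i*
(1-based) is `p1_ct · exp(−λ(i−1))`; G→A is mirrored from the 3′ end —
the single-strand overhang approximation with a single exponential decay.
Defaults `p1_ct = 0.25–0.3`, `λ = 0.3` give the 20–30% terminal rates and
~10-position decay typical of Pleistocene permafrost material. A uniform
per-base error floor (default 0.001–0.002) is applied after damage.
Both are parameters, not constants; `DamageModel.none()` switches noise
off for exactness tests.

**Reference genomes.** Congeneric species are independent per-site
mutations (rate = `divergence_between_species`) of a shared genus
ancestor; genera and families are independent random sequences. This
gives the LCA machinery the ambiguity structure that matters (shared
sequence within genera, essentially no sharing across families) without
modelling real phylogenetic branch lengths.

**Mitochondrial panels.** A random bifurcating ingroup plus an outgroup
tip; every branch except the outgroup's carries a fixed number of
substitutions at globally distinct sites (infinite sites at generation
time), so the branch → site map is unambiguous and marker calling can be
scored for exact precision/recall. Mutations are not placed on the
outgroup terminal branch because outgroup polarization cannot distinguish
them from ingroup-stem mutations; with that convention the confound
disappears instead of being approximately rare. `inject_homoplasy` adds
sites whose derived tips span two clades, exercising the caller's
rejection path.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: PCR duplicates and index hopping, genome-size
and organelle-copy-number abundance skew, indels (matching is gap-free),
alignment-scale reference databases (hundreds of millions of entries),
contamination with close relatives of true taxa, and real phylogenetic
rate variation. Results on synthetic data validate the *algorithms*, not
field performance.

## Classification

"100% similarity" is interpreted as zero mismatches over the full read,
no clipping. Matching is an exhaustive gap-free scan of every reference on
both strands (numpy sliding-window comparison), so "every placement with
≤ k mismatches" is a guarantee; at 30–90 bp fragment lengths omitting
indels is the standard simplification and is a documented limitation.
N never matches anything, on either side (read-side and reference-side N
are encoded as distinct codes). Identical read sequences are collapsed
before matching and re-expanded afterwards, so duplicates cannot change a
call but are preserved in counts. Coordinates are 0-based half-open
internally; SAM export (pysam, NM tag = mismatches) converts to 1-based.

Defaults: minimum read length 30 bp, `max_mismatches` 2 for
classification (hard-capped at 3 — beyond that the perfect-hit LCA gains
nothing and cost grows), checklist thresholds `min_reads = 3`,
`min_samples = 1`. All are config keys.

Conservation is an invariant, not a hope: collation returns an
"above-rank" ledger and the unassigned list separately, and
`matrix.total() + above_rank + unassigned == n_reads` exactly.

## Damage estimation and the ancient/modern decision

The damage profile is computed from each read's *best* placement with
mismatches tolerated (default cap 8), not from the perfect-hit LCA
assignments — the deamination signal *is* a mismatch, so profiling only
perfectly aligned reads would be structurally blind to it. A read
contributes to a taxon's profile when all its fewest-mismatch placements
fall inside that taxon's rank-level subtree. Reverse-strand placements
are re-oriented into the read's own frame first, keeping damage at the
fragment's biological ends.

The decision rule is an explicit formalization: ancient iff
`ct5[1] ≥ min_terminal_rate` (default 0.05) and a one-sided exact
binomial test of the position-1 T count against the pooled baseline rate
(positions 11–25) rejects at α = 0.05. Fewer than 10 position-1
observations → *undetermined*, a third state distinct from "modern".
Only C→T (5′) and G→A (3′) enter the decision.

## Abundance correction

The estimator is ratio-then-renormalize:
`a_t = (r_t/e_t) / Σ_u (r_u/e_u)`. It is the minimal estimator satisfying
the three stated corrections — depth cancels within-sample, per-taxon
identification bias divides out, degradation enters through
condition-matched efficiencies — and is labelled as such; whether a joint
model would be preferable is an open question flagged here. Efficiency is
estimated by simulation from the taxon's own reference subtree
(`n_sim ≥ 500` enforced; the binomial error of *e* is recorded via
`n_sim`). Taxa with `e = 0` but nonzero counts are excluded from the
sample denominator and reported, never silently dropped. Sample
"condition" defaults to one shared fragment/damage model; per-sample
conditions can be fitted from the observed profile (mean fragment length
+ terminal rate) and matched by id.

## Community statistics

Sørensen incidence dissimilarity is the beta-diversity default, with
Jaccard and abundance Bray–Curtis selectable. Time bins are half-open
`[t, t + width)` anchored at age 0; presets: 2,000 yr (pan-Arctic) and
5,000 yr (regional). Empty bins are emitted as placeholders and their
turnover entries are NaN, keeping series aligned.

NMDS minimizes Kruskal stress-1 by alternating (i) isotonic regression of
configuration distances on dissimilarity ranks — primary approach to
ties, implemented by lexicographic sort on (dissimilarity, distance) +
PAVA — and (ii) a Guttman-transform configuration update. Defaults:
`n_starts = 50`, `max_iter = 500`, `tol = 1e−7` (the 100,000-restart
ceiling used in large published analyses is a config ceiling, not a
default; at the problem sizes here a few dozen starts find the same
minimum). If an iteration would increase stress the previous
configuration is kept and the start terminates, so the recorded stress
trace is non-increasing by construction. The reported solution is the
lowest-stress completed start, centred, rotated onto principal axes, with
a deterministic sign convention (largest-magnitude coordinate positive),
making fixed-seed runs bit-identical. All-equal dissimilarities are
flagged degenerate.

Axis correlations use the Pearson r with the exact t-test
(`t = r√((n−2)/(1−r²))`, two-sided); raw `p < 0.05` by default to match
standard practice in this literature, with an optional
Benjamini–Hochberg toggle (off by default). Constant variables are
flagged and can never be significant.

## Placement

Polarization is by a designated outgroup (the scheme had to be chosen;
outgroup rooting is the standard one). Majority rule per marker position
with exact ties discarded avoids double-counting damage-heterogeneous
tallies. The path score
`Σ_path(support − conflict) − Σ_offpath(support)` penalizes derived
observations the placement cannot explain, so chimeric mixtures surface
as low-margin placements rather than confident wrong ones; the margin
(best − runner-up) is always reported. Ties at the maximum collapse to
the tied nodes' common ancestor and are flagged ambiguous — two equally
supported sibling terminal branches resolve to their parent.
`min_markers = 10` informative observations gates "unplaced".
Transversions-only mode is the damage-safe default for real degraded
samples; all-sites mode is appropriate for undamaged tests. Read mapping
onto the alignment coordinates keeps only reads with a *unique*
fewest-mismatch placement (default cap 5–8 mismatches, to accommodate
private alleles plus damage).

The support-minus-conflict path score is this package's own definition,
validated by recovery properties (exact brute-force agreement on small
trees; ≥95% terminal-branch recovery at 5× coverage) rather than by
equivalence to any particular published placement tool.

## Chronology and orchestration

Ages are consumed as already-calibrated years BP; radiocarbon calibration
and Bayesian age–depth modelling are out of scope. The age–depth model is
strict piecewise-linear interpolation: stratigraphic inversions raise a
model-invalid error naming the offending pair, queries outside the dated
range raise rather than extrapolate, and per-segment sedimentation rates
are reported.

`run_pipeline` derives one sub-seed per stage from the global seed (a
fixed affine hash, all below 2³¹), logs every filter with counts, and
writes a manifest mapping each output file to its sha256 — two runs of
the same config are byte-identical. The demo configuration uses a small
world (12 species, 8 samples × 400 reads, 6-tip panel) chosen so a full
run completes in well under a minute on one CPU while still exercising
every stage; the acceptance checks use larger sizes (10,000-read
classification, 100 placement replicates) where the property demands it.

## Known limitations

Gap-free matching (no indels); no mapping-quality model; efficiency
simulation shares the read simulator with the data generator (a deliberate
closed loop when validating the *estimator*, but real-data efficiencies
would need an independent aligner); binomial damage test assumes
independent sites; NMDS is not guaranteed to find the global optimum for
adversarial inputs (more starts are the remedy); the k-mer coverage
definition (fraction of distinct canonical k-mers, N-containing skipped,
k = 31) is this package's concrete choice among the possible variants.
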