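# Methods

`microsig` implements a complete two-group 16S community analysis: a
synthetic-data generator with recorded ground truth, beta-diversity
statistics, a differential-taxon screen, a signature abundance index with
classification validation, and Bayesian source tracking of
post-transplant samples. This note records the models, conventions and
numerical choices, and what the synthetic benchmarks do and do not show.

## Synthetic communities

`simulate_two_group_tables` draws base taxon weights
`w_t ~ LogNormal(0, σ)` with σ = 1.5 by default; the heavy tail mimics
real 16S rank–abundance curves better than a Dirichlet draw. Group A's
population profile is `w / Σw`; group B multiplies the `n_signature`
planted taxa by the fold change and renormalises. Each sample is an
independent `Multinomial(depth, profile)` draw, so the only sample-level
noise is counting noise. Defaults are desk-scale: 60 taxa, 10 samples
per group, 5 planted taxa at fold change 4, depth 5,000 reads
(deeper sequencing, e.g. the ~67,000 reads/sample typical of MiSeq runs,
is supported but not the default).

**Where the signature is planted.** Because relative abundances are
compositional, scaling a slice of the community and renormalising shifts
*every* other taxon by the factor `1 / (1 + (f−1)·m)`, where `m` is the
planted slice's mass. If the signature were planted uniformly at random,
`m` ≈ 10% is common under a σ = 1.5 log-normal and the "null" taxa would
be genuinely differential (we measured ~48% of them passing the screen).
The generator therefore plants the signature within the bottom-third
abundance stratum: the planted mass is ~0.7% in expectation, the closure
shift on null taxa (~2%) stays below counting noise at the default
depth, and the planted taxa remain well within detection range. This
matches the biology being emulated — the differential genera in
knockdown-vs-wild-type mouse studies are subdominant organisms — and is
what makes "null-taxon pass rate" a meaningful quantity at all.
`GroundTruth.expected_fractions` stores the post-renormalisation
profiles so recovery tests compare against realised, not nominal,
effects.

**What the generator does not emulate:** biological overdispersion
(every sample of a group shares one profile; real mice vary), taxonomic
mis-assignment, chimeras and contaminants, longitudinal drift, and
sequence-level error. Benchmarks passed on this generator therefore
demonstrate correctness of the statistics under multinomial sampling,
not performance on real mouse data, where group separation would be
weaker at equal n.

`simulate_tree` builds a topology by sequential random leaf attachment
(each new leaf splits a uniformly chosen existing edge) with i.i.d.
Exponential(mean 1) branch lengths. `simulate_fmt_sinks` draws sinks
from `Multinomial(depth, Σ_k π_k · profile_k)` where `π` includes an
unknown-community component; the true `π` per sink is recorded.

## Beta diversity

*Rarefaction* subsamples each sample without replacement to a common
depth using exact multivariate hypergeometric draws
(`Generator.multivariate_hypergeometric`); samples below depth are
dropped with a warning. The pipeline rarefies before UniFrac, so
presence means "count > 0 after rarefaction".

*Unweighted UniFrac* is computed from an edge × taxon incidence matrix:
for samples i, j,
`d(i,j) = (Σ lengths of edges on exactly one sample's paths) /
(Σ lengths of edges on either's paths)`; a pair with empty union has
distance 0. Taxa absent from the tree are an error by default (silent
pruning distorts the denominator); lenient mode prunes with a warning.

*Bray–Curtis* on relative abundances is `1 − Σ_t min(x_it, x_jt)`,
delegated to `scipy.spatial.distance.pdist` (equivalent on the simplex).

*PCoA* Gower-centres `−½ D²` and eigendecomposes with `scipy.linalg.eigh`.
Axes with eigenvalue above `max|λ|·1e-10` are retained; coordinates are
`eigenvector · √λ`; `proportion_explained` is relative to the sum of
positive eigenvalues. Negative eigenvalues are reported unchanged — no
Cailliez/Lingoes correction — matching common QIIME-era practice.

*PERMANOVA* uses
`SS_total = (1/N) Σ_{i<j} d²_ij`, `SS_within = Σ_g (1/n_g) Σ_{i<j∈g} d²_ij`,
`F = ((SS_total − SS_within)/(k−1)) / (SS_within/(N−k))`, with free
(unstratified) label permutations, default `n_perm = 999`, and the
`p = (#{F_perm ≥ F_obs} + 1)/(n_perm + 1)` convention, so p is never 0
and ties count against rejection. When `SS_within = 0` the statistic is
+∞ and only permutations reproducing the exact split tie it — note that
for tiny designs (2+2) such permutations occur with probability 1/3, so
the attainable minimum p is ~0.34, not `1/(n_perm+1)`.

## Differential screen

The screen follows the two-class LEfSe recipe. Stage 1 is a per-taxon
Kruskal–Wallis test with tie-corrected ranks and a χ²(1) p-value; a
taxon constant across all samples is flagged degenerate with p = 1. The
χ² approximation is crude at small n (for an n = 4+4 dataset in the
middle of the distribution it can differ from the exact permutation p by
~0.1); at screening thresholds deep in the tail it is adequate, and the
test suite checks it against exhaustive enumeration there.

Stage 2 scales relative abundances to parts per million and, over
`n_boot = 30` bootstrap replicates (each group resampled with
replacement at 2/3 of its size), averages the absolute between-group
mean difference per taxon; `effect_log10` is the log10 of that average,
floored at 1 ppm. In the two-class per-taxon setting the
one-dimensional LDA projection LEfSe uses reduces to the between-group
mean difference, so with this scaling the conventional "LDA score > 2"
threshold means "≥ 100 ppm bootstrap-mean difference". A taxon passes
with KW p < α (default 0.05) and effect above threshold; no multiple
testing correction is applied by default (LEfSe behaviour), with an
optional Benjamini–Hochberg flag. Bootstrap resampling is performed in
a canonical (label- and id-sorted) sample order so results are invariant
to row order at a fixed seed.

## Signature index and validation

The index of a sample is the sum of its relative abundances over the
panel taxa — a number in [0, 1] by construction. Validation:

- **Mann–Whitney U**: U counts pairs (positive > negative) plus
  half-ties. The p-value is exact when `n₁·n₂ ≤ 400` and tie-free,
  otherwise a normal approximation with tie and continuity corrections;
  the two methods agree within ~0.011 at the switchover scale.
- **ROC/AUC**: cutoffs sweep the sorted unique index values (predict
  positive when index ≥ cutoff); tied values yield diagonal segments,
  making the trapezoid AUC identically `U/(n₁·n₂)` — an identity the
  suite verifies to 1e-12 including ties.
- **Leave-one-out cutoff CV**: each fold refits the cutoff that
  maximises training accuracy (Youden's J available via `objective=`);
  among tied optima the smallest cutoff is chosen and placed at the
  midpoint of the bracketing distinct training values; the held-out
  sample is classified against it. Midpoint placement makes fold
  predictions equivariant under affine maps of the index but not under
  arbitrary monotone maps (a held-out value can cross the midpoint of
  its bracket under a convex transform); comparisons against training
  values themselves would give full monotone invariance at the cost of a
  biased-looking cutoff. On label-permuted null data this LOO procedure
  is *pessimistically* biased (mean accuracy ≈ 0.34, not 0.5), the
  familiar below-chance artifact of cross-validating an overfit rule
  with a majority-class component; it cannot manufacture optimistic
  accuracy, which is the property that matters.
- Group medians and IQRs use linear-interpolation (type 7) quantiles.

The positive class defaults to the panel's enriched group, recorded in
the report.

## Source tracking

Sinks are modelled read-by-read: each read carries a latent source
among K known sources and one unknown source. Known-source likelihoods
are Dirichlet-smoothed pooled training profiles,
`P(t|v) = (n_t^v + α₁)/(N^v + α₁T)`, fixed during inference; the
unknown source's likelihood
`P(t|unk) = (m_t + α₂)/(M + α₂T)` uses the sink reads currently
assigned to it (excluding the read being updated); the assignment prior
is `P(v) ∝ c_v + β`. A collapsed Gibbs sampler sweeps the reads;
after a 100-sweep burn-in, 25 draws are retained at thinning 10, pooled
over 10 restarted chains. Defaults α₁ = 0.001, α₂ = 0.1, β = 10 follow
published practice for this class of sampler. Sinks deeper than 1,000
reads are rarefied before tracking (disable with `rarefy_depth=None`).

Numerical choices worth knowing:

- **Progressive warm start.** Chains are initialised by assigning reads
  sequentially from the same collapsed conditional, starting from empty
  counts. A cold uniform init parks ~1/(K+1) of reads in the unknown
  source, whose self-reinforcing empirical profile then drains very
  slowly — within a 100-sweep burn-in this depresses pure-source
  recovery and, for deep unrarefied sinks, lets the unknown component
  absorb the whole mixture (its empirical profile can fit the realised
  counts better than any fixed source profile once the α₂ smoothing is
  negligible). The warm start removes both artifacts; sink rarefaction
  additionally caps the regime where unknown-overfitting is possible.
- **Canonical source ordering.** Internally sources are ordered by the
  bytes of their count vectors, not by label, and results mapped back
  afterwards; swapping the two source labels therefore swaps the
  reported proportions *exactly* at the same seed.
- Accuracy saturates in sink depth once depth exceeds the rarefaction
  depth: error medians for a 0.7/0.2/0.1 mixture are ~0.028 / 0.014 /
  0.014 at depths 500 / 5,000 / 50,000.
- Attribution between two nearly identical source communities is
  intrinsically ambiguous: reads from flora shared by both sources are
  split between them, shrinking the donor–recipient contrast toward
  parity while the unknown fraction remains well estimated. The
  analysis scripts show this deliberately; the acceptance benchmarks use
  distinct communities where the 0.7/0.2/0.1 mixture is recovered within
  ~0.02.

The inner loop is JIT-compiled with numba; the chain is deterministic
given the seed, and per-sink seeds derive from one run seed.

## Pipeline

`run_pipeline` executes simulate/ingest → rarefy → distances/PCoA/
PERMANOVA → screen → index → sinks/source-tracking, aborting downstream
stages on the first failure with an error naming the stage. All
randomness derives from one global seed through fixed per-stage offsets,
so stages can be rerun in isolation; two runs of the same config produce
byte-identical outputs. The manifest (`manifest.json`) echoes the
config and records per-stage wall time, SHA-256 checksums of every
output, and machine-parsable warnings; it is written even on failure.
Because it contains timings, the manifest itself is a log — determinism
is asserted over the output files and the manifest's checksum map.

## Benchmark scales

The test suite and `scripts/acceptance.py` use: 200 random 8-leaf trees
for the UniFrac oracle, 500 instances for the AUC ≡ U identity, 100
draws for the Mann–Whitney enumeration check, 500 runs × 199
permutations for PERMANOVA calibration, 100 seeded cohorts for screen
recovery and end-to-end discrimination, 10 mixture sinks at depth 2×10⁴
for source-tracking recovery, and 100 instances for the LOO oracle.
These sizes keep a full run to a few minutes on one core while leaving
Monte-Carlo error well below the margins being asserted.

## Known limitations

- Two groups only in the screen and index (the multi-class, subclass-
  constrained LEfSe design is out of scope).
- UniFrac is unweighted only; no weighted/generalised variants, no
  alpha diversity.
- The source tracker assigns taxa at read granularity with fixed known
  profiles; it does not re-estimate source profiles from sink data
  (no "leave-one-out retraining" of sources) and is not a time-series
  model.
- The generator's multinomial noise model understates real biological
  variance; see above.
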