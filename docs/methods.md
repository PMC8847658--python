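# Methods

## The model

`netstab` quantifies how *persistent* the top-ranked features of a dynamic
functional network are, and at which observation timescale that persistence
is strongest.

Given one subject's multichannel recording — an `N × l` matrix of broadband
signals sampled at rate `f` — the signal is split into non-overlapping
windows of `w` samples (`⌊l/w⌋` windows; the remainder is discarded). Each
window yields a fully connected weighted network on the `N` channels whose
link weight is the absolute Pearson correlation of the two windowed signals,
a value in [0, 1]. No preprocessing (filtering, detrending, re-referencing)
is applied at any point: the method is defined on raw broadband signals, and
the windowed correlation is the only estimator of coupling.

From each window's network a *ranked feature identity* is extracted:

* **strongest link** — the channel pair with maximal weight;
* **top-m links** — the unordered set of the m largest-weight links;
* **max-strength node** — the node with the largest sum of incident weights;
* **max-clustering node** — the node with the largest weighted local
  clustering coefficient
  `C_i = (1/((N−1)(N−2))) Σ_{j≠h} (ŵ_ij ŵ_ih ŵ_jh)^{1/3}`,
  with weights normalised by the network maximum (geometric-mean triangle
  intensity; on a complete weighted graph this equals the standard
  degree-normalised form).

Across the `n = ⌊l/w⌋` windows the most frequent identity (the *modal*
identity, count `k`) is scored against the null hypothesis that consecutive
networks are independent. Under that null each window's feature identity is
a uniform draw — over the `L = N(N−1)/2` links for the strongest link, over
the `N` nodes for node features, over the `C(L, m)` unordered sets for top-m
sets — so the count of any fixed identity is Binomial(n, p) with `p = 1/L`,
`1/N` or `1/C(L, m)` respectively. The reported statistic is

    ln π = ln P(X ≥ k),   X ~ Binomial(n, p),

the log probability of a count at least as extreme arising by chance: a
p-value, with more negative values meaning more stable features. A
point-mass variant `ln P(X = k)` is available (`mode="pmf"`) but the tail is
the default, because a p-value is a tail area. The link-uniformity null is
exact for exchangeable channels (e.g. iid noise); the node-feature `1/N`
null extends the same uniformity argument to nodes.

Scanning a grid of window lengths gives a **stability profile** ln π(w); the
grid minimum locates the *optimal window length* — the timescale at which
the feature's persistence is most improbable under independence. Each
subject is finally summarised by six metrics: (min ln π, best window length)
for the strongest link, the max-strength node and the max-clustering node.

A companion **rank-gap profile** reports the mean per-window
`Δ = log2(s1/s2)` between the two largest link weights, which separates
"the leader is stable" from "the leader is far ahead"; windows with `s2 = 0`
are excluded and counted.

## Group-level procedures

* **Group mean profiles** average ln π pointwise across subjects and take
  the peak of the mean curve; per-subject peaks are retained separately
  (both are reported because peak-of-mean and mean-of-peaks genuinely
  differ). Sensitivity is quantified by a leave-one-subject-out envelope:
  the extrema of the recomputed summaries over all single-subject deletions.
* **Intra-group stability** pools every subject's per-window identities into
  one trial sequence (`n = Σ_s ⌊l_s/w⌋`), counts the globally modal identity
  and scores it with the same binomial tail — stability *across* subjects.
* **Upsampling** splits each recording into five contiguous equal parts
  treated as virtual subjects; distributions of optimal window lengths are
  compared between groups with the two-sample Kolmogorov–Smirnov test.

## Covariates and classification

Spearman rank correlations relate each of the six metrics to demographic or
cognitive covariates (pairwise deletion of missing values; raw p-values with
a significance flag at α = 0.01; no further multiple-testing correction).
Per covariate, an OLS fit of the covariate on the six metrics plus intercept
reports R² (complete cases; constant responses and rank-deficient designs
are flagged, not raised).

Group discrimination trains a random forest on the six metrics and scores it
by leave-one-out cross-validation, averaged over repeated realisations with
re-seeded forests. Defaults: 50 trees, unlimited depth, √-feature
subsampling — with six features and cohort-scale samples the LOO score is
seed-stable well below 50 trees, and the smaller forest keeps the
100-realisation protocols tractable on one CPU; the parameters are echoed in
every report. Three six-feature baselines calibrate the score: label
shuffling (chance), six random link weights, and two random link weights
plus strength and clustering of two random nodes, all read from the
mean-over-windows network at a configurable reference window length (the
mean-over-windows choice is ours; a single-window read would only add
noise). Feature relevance is the drop in mean accuracy when a model is
retrained without that feature.

## Synthetic data

The generator emulates the geometry of a resting-state EEG session —
defaults 32 channels, 500 Hz, 8 minutes (240 000 samples/channel) — as iid
standard Gaussian noise. It does **not** emulate 1/f spectra, volume
conduction, artifacts or electrode geometry; passing tests demonstrate
correct behaviour of the statistical machinery under its own null and under
planted structure, not performance on real EEG.

Planted structure has closed-form ground truth:

* a **planted pair** (j, k, ρ, q, epoch_ms): time is divided into epochs of
  `epoch_ms`; each epoch is independently active with probability q; inside
  active epochs both channels mix a shared latent with loading √ρ, so their
  within-epoch correlation is exactly ρ and zero elsewhere. The square-wave
  activation gives a well-defined target timescale for best-window recovery.
* a **planted hub** (hub, peripherals, ρ): per-peripheral latents with hub
  loading √(ρ/k) give hub–peripheral correlation ρ/√k and mutually
  uncorrelated peripherals, making the hub the unique strength apex.

Cohorts derive per-subject seeds from a master seed; planted identities can
be shared across subjects (for intra-group pooling) or redrawn per subject.

## Numerical choices

* **Binomial tail in log space.** `ln P(X ≥ k)` is a `logsumexp` over
  log-PMF terms when the tail is below ½, and `log1p(−exp(ln P(X < k)))`
  otherwise, so both deep tails (|ln π| ~ 10⁴ and beyond) and near-certain
  tails are computed at close to double-precision relative accuracy for n up
  to ~10⁶. `ln P(X ≥ n)` returns `n·ln p` exactly. Tests compare against an
  arbitrary-precision exact-summation oracle at 1e−8 relative tolerance.
* **Ties** (equal weights, equal counts) break deterministically toward the
  lexicographically smallest identity (pairs in row-major order, nodes by
  index, sets by sorted tuple). Ties are measure-zero for real-valued
  correlations; the rule only pins down degenerate inputs.
* **Zero-variance windows.** A channel that is exactly constant inside a
  window gets weight 0 on all its links in that window (with a warning)
  rather than NaN, keeping the ranking total and deterministic. Constancy is
  detected exactly (max = min), not via a variance threshold.
* **Window conversion** is `w = ⌊window_ms · f / 1000⌋`, windows are 0-based
  half-open `[i·w, (i+1)·w)`; grid points yielding fewer than 2 samples are
  skipped with a warning.
* **Profile minima** break ties toward the smallest window length.

## Problem sizes used in tests and the acceptance script

The full acquisition geometry (32 channels × 240 000 samples × a 30-point
grid × cohorts) is unnecessary for verifying the machinery; the shipped
checks use scaled study conditions chosen once:

* binomial oracle lattice: n ∈ {10, 1000, 48000}, p ∈ {1/496, 1/32}, k
  spanning the support;
* null calibration: 500 recordings of 8 channels × 5000 samples (200
  windows of 25 samples), compared to a 50 000-draw multinomial-maximum
  oracle at the 1% KS level;
* planted recovery: 50 subjects, 8 channels, 24 s at 500 Hz, ρ = 0.9,
  q = 0.8, 30 ms epochs, log grid 10–500 ms (16 points);
* classification: 20 planted vs 20 null subjects of 12 s each; stability
  mode over 20 realisations, shuffled baseline over 100.

At these sizes the modal identity is recovered for every subject, the best
window falls within a factor 2 of the planted epoch, and planted ln π sits
thousands of natural-log units below the null median — the contrasts are not
marginal, so the scaled sizes do not flatter the method.

## Known limitations

* Only absolute Pearson correlation ships as a weight estimator (a pluggable
  weight function is accepted but not validated for other estimators).
* The node-feature null (`p = 1/N`) and the set null (`1/C(L, m)`) assume
  uniformity by exchangeability; heavy-tailed or strongly inhomogeneous real
  data may deviate from uniformity even when windows are independent, making
  ln π conservative or anticonservative in ways the synthetic tests do not
  probe.
* ln π values from overlapping information (e.g. the same subject at nearby
  window lengths) are strongly dependent; profiles are descriptive scans,
  not families of independent tests.
* The rank-gap statistic averages per-window gaps; tracking the modal link's
  own gap is a reasonable alternative that was not adopted.
* LOO accuracy on small cohorts has high variance; class balance is reported
  next to every score and results on real cohorts should be read with the
  same caution as any small-sample classification.
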