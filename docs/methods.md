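# Methods

## Overlap probability and the association threshold

Two individuals identified T ordinal units apart were in the same observable
cluster at some intervening moment with probability
P(overlap) = (1 + μT)·e^{−μT}, derived from a first-departure integral under
three assumptions: each individual leaves the cluster independently at rate
μ; immigration and emigration rates are approximately equal (so the cluster
is in steady state); and re-immigration into the same cluster happens on
longer time scales than within-event lags, so a departed animal does not
return before the second identification. None of these assumptions is
enforced on data — they define the model, and the fit report records them as
metadata.

At T = 1/μ (the mean residence time) the overlap probability is 2/e ≈ 0.736
for every μ, which motivates using the fitted mean residence time as the
association threshold. Because frame-valued ordinals are integers, the
threshold is the fitted mean residence `b` rounded half-up, floored at 1 (a
zero threshold would forbid all associations). The unrounded `b` and the
overlap probability at the integer threshold are reported alongside, so the
rounding is always auditable.

## Lagged identification rate and model fitting

The empirical LIR at lag τ is m(τ)/n(τ): among all unordered pairs of
identifications τ apart within one collection event, the fraction naming the
same individual. Conceptually every identification is keyed as
`ordinal + event_index × offset` with the offset exceeding the largest
within-event lag (the classic choice of 10,000 is available; the default is
the smallest power of ten that suffices), which pushes every cross-event pair
beyond the maximum lag considered. The implementation enumerates pairs event
by event, which is algebraically identical for any valid offset and avoids
the O(N²) blow-up across events; an O(N²) composite-ordinal enumerator
nevertheless exists in the test suite as the independent oracle.

Choices worth stating:

* **Maximum lag** defaults to the largest within-event lag present in the
  data, so no cross-event artefact can enter the fit.
* **Lag-0 pairs** (two animals in one frame) are excluded from the LIR —
  they carry no decay information — but they still drive the same-frame
  association criterion.
* **Binning**: unit-lag resolution by default; log-spaced bins are available
  for sparse data. The choice is recorded on the curve object.
* **Likelihood**: per lag, m(τ) is treated as Binomial(n(τ), R(τ)) and the
  summed log-likelihood is maximized over (a, b, c). Pairs are not
  independent in reality, so this is a composite likelihood: adequate for
  point estimation of b, not for standard errors (none are reported).
* **Optimization**: Nelder–Mead on log(a), log(b), log(c) from a heuristic
  start (intercept → a, tail level → b/(b+c), half-decay lag → b) plus seven
  seeded log-normal jitters of it. The surface can be flat in c, hence the
  multi-start. The maximized log-likelihood is checked against every start in
  the tests.
* **Degenerate fits**: if the fitted R(τ) would reach 1 (tiny a), the
  likelihood is evaluated with R clipped to 1−10⁻⁹ and the fit flagged. A
  curve with no decay signal cannot identify b; the fit is flagged
  non-informative — detected as a log-likelihood improvement of less than 0.5
  over the best constant-rate model, or a fitted b beyond 100× the maximum
  lag — and no threshold is emitted.

## Association criteria and the half-weight index

Associations are scored once per sampling day. Three nested criteria are
supported: same frame (identical event and ordinal), probabilistic (some
pair of identifications in one event at most the threshold apart — the
comparison is inclusive, "within that number of frames"), and encounter
(any shared event). Nestedness (same_frame ⊆ probabilistic ⊆ encounter) and
monotonicity of HWI in the threshold are enforced by property tests.

The half-weight index for a dyad is x/(x + yAB + (yA+yB)/2) over sampling
days, the standard form correcting for individuals observed separately.
Dyads whose denominator is zero (neither animal ever seen) are structural
zeros and flagged. The individual-restriction filter retains animals seen on
at least `min_days` distinct dates and in every required calendar year —
typically the first and last year of a study, to exclude animals that died
during it or were born into it.

## Evaluation battery

* **CV of association indices** uses the population (n-denominator) standard
  deviation; computed over all off-diagonal dyads and over non-zero dyads
  only, since large numbers of never-associated dyads inflate the former.
* **Permutation null**: within-day, degree-preserving sequential
  checkerboard swaps. A trial picks a day and two associated dyads (i~j),
  (k~l) with four distinct members and (i~l), (k~j) absent, and rewires them
  — inverting a 2×2 block of that day's association matrix while preserving
  each individual's per-day association degree (asserted after every swap in
  test mode). Permutations are sequential (each continues from the last
  state); both CV statistics are recorded after each permutation, and
  P = (1 + #{null ≥ observed})/(1 + permutations), one-sided high because
  preferred/avoided companionship inflates the CV. Defaults are 1000
  permutations × 1000 trials. Calibration is verified by simulation: under a
  no-preference generator the rejection rate at α = 0.05 stays inside the
  exact binomial interval.
* **Mantel test**: Pearson correlation between the off-diagonal HWI and a
  binary same-unit indicator, with the null built by permuting unit labels
  across individuals (simultaneous row/column permutation); one-sided for
  positive correlation, add-one corrected. On very small matrices the P
  value has a combinatorial floor (e.g. 10% of relabelings of six animals in
  two triples reproduce the same partition).
* **Community structure**: Newman's leading-eigenvector method on the
  weighted modularity matrix B = W − s sᵀ/2W. Sub-networks are recursively
  bisected along the leading eigenvector of the generalized modularity
  matrix; a split is accepted only if it increases Q. No Kernighan–Lin
  fine-tuning by default (a flag enables a greedy sweep). Reported Q always
  equals direct recomputation from the returned partition.
* **Social differentiation** S: each dyad's latent association probability
  is modelled Beta(α, β), making the observed associated-day count x a
  Beta-Binomial draw out of the d days both animals were seen. (α, β) are
  fitted by maximum likelihood from a 4×4 log-grid of starts;
  S = √(β/(α(α+β+1))), the CV of the latent Beta. Boundary fits
  (α, β → ∞: homogeneous associations) are flagged and reported as S = 0.
  Note the balanced all-or-nothing society (half the dyads always together,
  half never) has latent CV exactly 1, the boundary of the "diverse
  relationships" regime.

## The synthetic generator

The generator emulates the data-collection process itself rather than its
summary statistics: social units (matriline analogues), per-event cluster
occupancy with geometric residence (per-frame leave hazard 1/b, mean b
frames — the discrete analogue of the exponential residence in the fitted
model, a deliberate, documented model mismatch that the ordinal frame clock
makes unavoidable), immigration biased toward unit-mates of current
occupants, and a photographer who identifies a Poisson-thinned subset of
occupants each frame. Events are anchored on a focal unit; if a cluster
empties mid-event it is re-seeded from the same unit (the boat re-approaching
the grouping). Initial cluster membership uses the same cohesion/mixing
multipliers as immigration, so setting `within_unit_cohesion` equal to
`between_unit_mixing` makes the process exchangeable across individuals —
the null condition used for permutation-test calibration.

Default condition (one "study"): 60 individuals in 12 units of 5, 25 days ×
8 events × ~50 frames, mean residence 10 frames, identification rate 0.5 per
frame (≈5,000 identifications), cohesion 0.9, mixing 0.05. The base
immigration rate of 0.05 per frame was chosen so the equilibrium cluster
occupancy (~4–5 animals) matches the social-unit size, which is what a
photographable cluster of unit-living animals should look like; much lower
rates let the cluster drain and make identification effectively episodic.
An optional per-individual detection probability (default 1: every selected
animal is identified) and an optional effort mode (frames scale with
occupancy) exist for sensitivity studies.

What the generator does **not** emulate: spatial structure, photo-quality
or identifiability differences between individuals, demographic turnover,
and behavioural-state-dependent grouping. Passing tests therefore show the
estimator chain is correct under the stated movement/sampling model, not
that field data satisfy that model.

## Problem sizes used in the test suite

Simulation-based checks use the default study condition (≈5,000
identifications) where parameter recovery is the question (20 replicate
seeds; median relative error of b within 15%), and smaller streams (15–30
individuals, 6–8 days) where only structural properties are asserted.
Permutation-test calibration uses 200 replicates of a 15-individual null
society with 200 permutations × 100 trials per test. The realized-residence
check uses 400-frame events so right-censoring of residence spells is
negligible.

## Known limitations

* The binomial loss ignores pair dependence; b is a point estimate with no
  uncertainty interval (bootstrap CIs are future work).
* The same-frame criterion equates "identical (event, ordinal)" with "same
  photograph"; distinct photographs sharing an ordinal within one event are
  indistinguishable.
* Only the emigration + re-immigration LIR family is implemented; no model
  selection across residence-model families.
* One partition level from modularity clustering; no multilevel analysis.
* Sequential permutations mean consecutive null samples are autocorrelated;
  with few trials per permutation the test is conservative. The calibration
  test pins the default behaviour at the sizes stated above.
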