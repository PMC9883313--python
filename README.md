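# probassoc

Data-driven association thresholds for animal social-network analysis from
sequential individual-identification data (photo-identification, PIT-tag or
acoustic detections).

## The problem

Social structure is usually inferred from *associations* — circumstances in
which two identified individuals could have interacted. When identifications
arrive as a sequential stream (frame numbers in a photographic encounter,
timestamps at a reader), the analyst must choose a lag threshold within which
two identifications count as an association. That choice is usually
arbitrary, yet it changes every downstream result. `probassoc` derives the
threshold from the data themselves.

## The model

Individuals move in and out of the *photographable cluster* — the latent set
of animals within identification range of the observer. If each individual
leaves the cluster independently at rate μ per ordinal time unit, two
individuals identified a lag T apart overlapped in the cluster with
probability

    P(overlap) = (1 + μT) · e^{−μT}

At a lag equal to the mean residence time, T = 1/μ, this is 2/e ≈ 0.736 for
every μ: taking the mean residence time as the association threshold
guarantees a ~74% probability that the two animals were genuinely together.

The mean residence time is estimated from the **lagged identification rate**
(LIR): the proportion, among all pairs of identifications τ units apart
*within the same collection event*, of pairs naming the same individual. An
emigration + re-immigration model

    R(T) = (1/a) · [ 1/c + (1/b) e^{−(1/b + 1/c) T} ] / (1/b + 1/c)

is fitted to the empirical LIR by maximum likelihood with binomial loss,
where `a` is the effective number of individuals in the focus area, `b` the
mean time inside the cluster and `c` the mean time outside. The fitted `b`,
rounded to the nearest integer ordinal unit, is the **probabilistic
association threshold**.

Around this core the package builds per-day dyadic associations under three
nested criteria (same frame ⊆ within-threshold ⊆ same encounter), collapses
them to half-weight index (HWI) matrices, and evaluates the social structure:
CV of association indices with within-day degree-preserving permutation
nulls, a Mantel test against known unit membership (e.g. matrilines),
Newman's leading-eigenvector modularity clustering, and likelihood-based
social differentiation S (a Beta-Binomial estimate of the CV of the latent
association probabilities).

## Worked example

The bundled generator simulates the whole data-collection process (cluster
occupancy with known mean residence, social units with known cohesion, a
photographer sampling occupants frame by frame), so the full pipeline runs
without any field data:

```python
from probassoc import (SimulationConfig, simulate_identifications,
                       ResidenceTimeModel, daily_associations, hwi_matrix,
                       permute_within_days, mantel_test, newman_clusters,
                       social_differentiation)

df, truth = simulate_identifications(SimulationConfig(seed=1),
                                     return_diagnostics=True)
res = ResidenceTimeModel.from_records(df).fit()
print(res.summary())

thr = res.threshold.threshold
assoc = daily_associations(df, "probabilistic", threshold=thr)
matrix = hwi_matrix(assoc)
cv = permute_within_days(assoc, n_permutations=1000, n_trials=1000, seed=1)
mt = mantel_test(matrix, truth["units"], seed=1)
part = newman_clusters(matrix)
sd = social_differentiation(assoc)
```

Output:

```
Residence-time model fit (emigration + re-immigration LIR)
============================================================
a (individuals in area): 4.722
b (mean time inside):    9.607
c (mean time outside):   43.65
log-likelihood:          -15905.5627
identification pairs:    59003
converged:               True
informative:             True
association threshold:   10 ordinal units (raw b = 9.607)
overlap probability at threshold: 0.721
```

The stream was generated with a true mean residence of 10 frames; the fit
recovers b = 9.61 and a threshold of 10 frames, at which two identifications
imply a 72% overlap probability. The evaluation battery on this stream
prints:

```
CV of HWI: 0.64 (P = 0.001); non-zero CV: 0.63 (P = 0.001)
matrix correlation with unit membership: 0.78 (Mantel P = 0.001)
modularity Q = 0.09 with 6 clusters
social differentiation S = 0.42
```

The permutation P of 0.001 (the add-one floor at 1000 permutations) says the
observed variability in association strengths cannot be produced by chance
given who was seen on each day; the matrix correlation of 0.78 recovers the
planted unit structure.

The same pipeline runs from the shell:

```
probassoc simulate --config sim.yaml --out ids.csv --seed 7
probassoc lir --input ids.csv --out fit.json
probassoc associate --input ids.csv --criterion probabilistic --threshold 10 --out hwi.csv
probassoc evaluate --input ids.csv --criterion probabilistic --threshold 10 --seed 1
probassoc run --input ids.csv --outdir results/
```

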