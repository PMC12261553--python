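# palliseq

Sequence analysis of palliative-care pathways in the last year of life,
built for health-services researchers working with claims-like data on
people with amyotrophic lateral sclerosis (ALS, ICD-10 G12.2).

In claims data, each deceased individual leaves a death-anchored record of
when each type of palliative care was first billed — primary palliative
care (PPC), specialized palliative home care (SPHC), inpatient palliative
care (IPC), and hospice care — alongside diagnoses, end-of-life utilization
and place of death. `palliseq` turns those records into timed pathway
sequences, compares all pairs with a **Temporal Needleman-Wunsch (TNW)**
alignment, clusters the resulting distances with **bootstrap-stability
selection** of the number of clusters, and reports **end-of-life quality
indicators** per cluster. Because real insurance claims cannot be shipped,
a seeded synthetic generator with planted pathway archetypes makes every
stage reproducible and testable.

## The model

A pathway is a sequence of up to four distinct service symbols
`s_1 … s_n` with transition times `g_1 = 0, g_2, …, g_n` (days between
consecutive initiations; 0 marks simultaneous initiation). Global
alignment of pathways A and B maximizes the classic Needleman-Wunsch
objective with an added timing term on matches:

```
M(i,j) = max( M(i-1,j-1) + s(a_i,b_j) + 1[a_i = b_j] · T_p · exp(-|gA_i - gB_j| / τ),
              M(i-1,j) - g,
              M(i,j-1) - g )
```

with match score `m = 1.0`, mismatch `x = -1.1`, gap penalty `g = 0.7`,
temporal weight `T_p = 0.25` and time scale `τ = 30` days. With `T_p = 0`
this is exactly Needleman-Wunsch on the symbol strings. Raw scores are
length-dependent, so pairwise comparison uses the normalized similarity
`sim(A,B) = exp(score(A,B) − max(score(A,A), score(B,B))) ∈ (0,1]`.
Distances `D = 1 − S` feed average-linkage agglomerative clustering; the
number of clusters k is chosen by bootstrap stability — the mean adjusted
Rand index between resample partitions and the full-data partition —
with ties broken toward smaller k.

## Worked example

```python
from palliseq import PathwaySequence, TNWParams, tnw_align, normalized_similarity

a = PathwaySequence("a", ("PPC", "SPHC"), (0, 95))
b = PathwaySequence("b", ("PPC", "SPHC"), (0, 35))
c = PathwaySequence("c", ("PPC", "IPC"), (0, 50))
for left, right in [(a, b), (a, c)]:
    res = tnw_align(left, right, TNWParams())
    print(left.individual_id, right.individual_id,
          round(res.score, 4), round(normalized_similarity(left, right), 4))
```

prints

```
a b 2.2838 0.8056
a c 0.15 0.0954
```

`a` and `b` share both services: two matches (2.0) plus a full timing bonus
on the first (0.25) and a discounted bonus on the second
(`0.25·e^{-60/30} ≈ 0.034`). `a` and `c` mismatch on the second element, so
their score barely beats gapping and the normalized similarity collapses.

A full run — simulate, filter the cohort, encode, align, cluster, report —
is one call (see `examples/` for narrated versions of each stage):

```python
from palliseq import archetype_config, run_pipeline

result = run_pipeline(archetype_config(n=120, seed=3), k_min=2, k_max=6, B=50)
print(result.solution.k)                 # 3  (the planted number of archetypes)
print(result.solution.stability[3])      # 1.0 (every resample reproduced it)
print(result.quality_table.loc["with_pc", "hospital_30d_pct"])
```

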