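# Methods

## Data model

All timing is death-anchored: `day_before_death` counts backward from the
day of death (0 = death, 365 = one year before), and only records inside
the final-year window exist. Three tables describe a claims extract:
diagnoses (ICD-10 code, outpatient/inpatient setting, day), billed service
events (service symbol, day), and persons (sex, age at death, place of
death). The four palliative-care services — PPC (primary palliative care,
mostly GP-delivered), SPHC (specialized palliative home care), IPC
(inpatient palliative care) and hospice — each enter an individual's
pathway at most once, at the day the service was *first* billed.

## Cohort construction

Inclusion requires at least one G12.2 (ALS) diagnosis in the window;
any diagnosis with a C00–C97 code (matched at the 3-character prefix
level, window boundary inclusive) excludes the individual, removing the
major competing source of palliative-care demand. Derived variables:

- **Weighted Charlson Comorbidity Index.** The ICD-10 literature offers
  several operationalizations; we ship the Quan 2005 coding algorithm with
  the original Charlson weights (1–6) as an editable CSV
  (`palliseq/data/charlson_quan.csv`). Hierarchy rules count each
  condition once and let the severe form supersede the mild one
  (complicated diabetes, severe liver disease, metastatic tumour).
- **Six condition flags** (cardiovascular, cerebrovascular, kidney, liver,
  respiratory, dementia). Published claims studies describe these sets
  without reprinting them; our default ICD-10 prefix ranges are in
  `palliseq/data/condition_flags.csv` and are deliberately editable.
- **End-of-life indicators.** Hospital stay, ICU stay, emergency
  deployment, PEG, mechanical ventilation, each true iff a matching event
  lies within the *closed* 30-day window (`day_before_death <= 30`).
- Percentages throughout are rounded half-up to one decimal; medians use
  the midpoint convention for even counts (hence `.5` values).

## Pathway encoding

Initiation days become a linear sequence ordered from earliest (largest
day value) to latest. Transition times are day differences between
consecutive initiations; the leading gap is fixed at 0, so absolute
anchoring (time from first service to death) is *not* part of the
sequence — only order and spacing are aligned. Simultaneous initiations
get gap 0 and are ordered canonically PPC < SPHC < IPC < HOSPICE; the tie
order is arbitrary but fixed, which makes encoding and alignment
deterministic (it is configurable in `palliseq.encode.CANONICAL_ORDER`).
The transition graph counts strictly sequential consecutive pairs as
directed edges; simultaneous pairs are tallied separately and never drawn
as edges.

## Temporal alignment

The alignment recurrence is in the README. Design choices:

- **The timing term applies only to symbol matches** and is a bounded
  reward, `T_p · exp(-Δ/τ)`, rather than an unbounded penalty. This keeps
  mismatch semantics purely categorical, guarantees the reduction to
  classic Needleman-Wunsch at `T_p = 0` (verified in the tests against an
  independent implementation), and bounds timing's influence by `T_p`.
- **Defaults** `m = 1, x = -1.1, g = 0.7, T_p = 0.25, τ = 30 days` were
  chosen so that one match outweighs one gap but not two
  (`m + T_p = 1.25 < 2g = 1.4` only when the timing bonus is partial;
  `m > g` always), a mismatch is always worse than a gap pair
  (`x < -2g + something small`), and timing differences are felt on the
  scale of a month. All are exposed via `TNWParams`.
- **Normalization.** Sequences range from one to four events, so raw
  scores are not comparable across pairs. We exponentiate the score
  deficit against the better self-alignment score:
  `sim = exp(score - max(self_A, self_B))`. This is 1 exactly for
  self-comparison, bounded in (0,1] even for negative raw scores, and
  monotone in the raw score.
- **Traceback ties** resolve diagonal > up > left; only `aligned_pairs`
  depends on this, never the score.
- An exhaustive enumeration oracle (`brute_force_score`, total length
  ≤ 8) ships in the package and is the correctness reference for the
  dynamic program.

## Clustering and model selection

`D = 1 - S` is clustered with SciPy's agglomerative hierarchical
clustering on the precomputed distances. **Average linkage** is the
default: Ward assumes Euclidean geometry, which `1 - similarity` does not
guarantee; single and complete linkage are available. Labels are
canonicalized (decreasing cluster size, then smallest member position) so
repeated runs write identical files.

The number of clusters is selected by **bootstrap stability**: for each
candidate k, B resamples are drawn with replacement, the induced distance
submatrix is reclustered at k, and the adjusted Rand index between the
resample partition and the full-data partition (restricted to the unique
resampled individuals) is averaged. The k maximizing mean stability wins;
ties break toward smaller k. Resamples with fewer than k unique
individuals are redrawn and logged. Stability-based selection is one of
several published ways to automate this choice; complementary
cluster-validity indices are a documented extension point, not
implemented. Defaults: B = 100, k range 2–12 (the pipeline and tests use
smaller B and ranges; sizes below).

The dendrogram is exported as Newick (leaf names = individual ids, branch
lengths = merge-height differences) via scikit-bio.

## Synthetic data

The generator emulates the analysis' assumed structure, not any real
claims distribution:

- **Nine default archetypes** mirror the reported pathway clusters of a
  German statutory-insurance ALS cohort: compositions (PPC only; SPHC
  only; PPC→SPHC; SPHC→PPC; hospice-final; IPC only; outpatient→IPC;
  PPC/hospice-final; SPHC-final), initiation-day medians (e.g. PPC-only at
  126.5 days, IPC-only at 5.5 days), mixture weights from the cluster
  shares, and cluster-conditional 30-day indicator rates and
  place-of-death distributions. Only medians and rates are published;
  **initiation-day dispersion is our assumption** (log-normal,
  σ = 0.25–0.5 by service). Published place-of-death rows can exceed 100%
  because hospital and palliative-unit deaths overlap there; our model is
  categorical, so those rows are renormalized.
- Cohort-level defaults: 53.7% of individuals receive palliative care,
  20.4% carry a cancer code (exercising the exclusion filter), sex ratio
  56.1% female, age ≈ N(72, 9²), condition prevalences at the published
  full-cohort rates with one representative ICD-10 code planted per
  condition.
- **Three-archetype test configuration** (`archetype_config`): the cyclic
  trio PPC→SPHC, SPHC→IPC, IPC→PPC. Each pair of archetypes shares exactly
  one service, so all three between-archetype distance distributions are
  identical by symmetry. The 3-way partition is sharply defined, while any
  2-way merge must break a three-way tie — the regime in which bootstrap
  stability cleanly discriminates the planted k. The stability-margin
  checks widen the timing dispersion (σ = 0.6, n = 30) so that k = 4
  solutions are also genuinely ambiguous while the 3-way partition stays
  perfectly stable.
- Ground-truth labels live in a `truth.csv` sidecar only; the
  pipeline-facing tables carry no label column (leak-tested).

What passing tests on synthetic data do **not** show: recovery of the
real nine-cluster structure (the real claims are inaccessible and real
pathways are far noisier), realistic comorbidity co-occurrence, insurance
churn, or multi-episode service use.

## Worked-example cohort

`palliseq.worked_example.synthetic_reference_cohort()` constructs a
synthetic 1,295-member cohort whose *marginal* counts are planted to match
published aggregates (695 with palliative care; 727 female, 416 of them
with palliative care; service users PPC 496 / SPHC 400 / IPC 138 /
hospice 94; per-condition diagnosis counts). It exists so the summary and
utilization arithmetic can be checked against printed reference
percentages (53.7, 56.1, 59.9, 71.4, 57.6, 19.9, 13.5); individual records
are otherwise schematic and carry no information.

## Problem sizes and determinism

The shipped experiments use n = 300 pathways (three archetypes, B = 50,
k ∈ 2–8) for recovery, n = 30 for the stability-margin check, and
n = 40–120 for pipeline tests; the full nine-archetype demo runs at
n = 300–600. Every random draw flows from a single integer seed
(simulation via one `numpy` generator; per-candidate-k bootstrap seeds
spawned from a `SeedSequence`), so identical configurations produce
byte-identical output files.

## Known limitations

- Alignment assumes at most one initiation per service type; recurring
  episodes are out of scope.
- The temporal term's exact functional form is a design choice; other
  published temporal-alignment variants weight timing differently, and no
  equivalence with any particular software implementation is claimed.
- Stability-only selection can prefer coarse partitions when a dataset
  contains a perfectly reproducible 2-way split; the full stability
  profile is always reported so such cases are visible.
- Quality indicators are claims proxies restricted to the last 30 days;
  they measure utilization, not symptom control or preference concordance.
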