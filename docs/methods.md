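# Methods

## Scope and model

`tcmpattern` treats TCM pattern differentiation as document scoring: a
knowledge base maps each pattern code to a bag of characteristic terms with
occurrence counts, and a case — a set of canonical terms pooled over the four
clinical categories — is assigned the code with the largest sum of
tf·idf weights over shared terms, with

- tf(t, d) = f_{t,d} / Σ_{t'∈d} f_{t',d}  (term counts normalized within a
  code document), and
- idf(t) = ln(1 + N/n_t)  (smoothed inverse document frequency; N codes,
  n_t of them containing t).

The natural logarithm is a free choice: changing the base multiplies every
score by the same constant, so rankings are invariant (asserted as a test).
Ties between equal scores break lexicographically by pattern id so runs are
deterministic. Case terms outside the knowledge base are skipped rather than
rejected — real records contain findings no pattern code mentions. A case
matching nothing is reported as `undetermined`, never silently assigned.
The engine exposes tf, idf and per-pattern matched terms so a learned
re-weighting could be layered on later; no such refinement is included,
because no published specification of one exists for this workflow.

## Cohort analysis

All clinical variables are binary (term present/absent in the record).
The per-variable selection statistic is KPI = √(n_yes/n_no), a
coefficient-of-variation form: it equals the standard deviation of the
complement indicator divided by its mean and grows with the yes-frequency,
so "more even" variables score higher. With the admissibility floor of
frequency > 5%, every admissible variable has KPI ≥ √(0.05/0.95) ≈ 0.2294.
The alternative reading — sd/mean of the yes-indicator, √(n_no/n_yes) — is
available as `variant="literal"`; it is the same statistic reflected around
1 and would reward rare variables, which contradicts the floor, so the
complement form is the default. The selection threshold is swept upward from
the minimum admissible KPI in steps of 0.01; each candidate subset is
re-clustered (k held fixed at the elbow choice made once on the full matrix)
and the threshold yielding the most primary features wins, ties going to the
smallest threshold. The sweep grid ends early if selection shrinks below
what the clusterer can split.

Clustering is Lloyd k-means (scikit-learn, k-means++ initialization, best of
25 restarts, fixed seed) on the raw 0/1 matrix with Euclidean distance — no
scaling, since all variables share the binary scale. Cluster labels are
1-based. The cluster count is chosen where the decline of the total
within-cluster sum of squares moderates, formalized as the smallest k whose
relative WSS drop to k+1 falls below 10% (configurable); if the decline
never moderates the largest tested k is returned with a warning.

Primary features (PF) are variables with similar weight everywhere: either
no significant frequency difference across clusters (chi-square test on the
clusters × yes/no table, no continuity correction, α = 0.05) with overall
frequency > 5%, or a significant difference but a stable within-category
frequency rank — max−min rank ≤ 10 (symptoms), ≤ 3 (tongue appearance,
pulse), ≤ 5 (tongue coating) — with > 5% frequency in every cluster. Ranks
are assigned within (cluster, category) by descending frequency with
lexicographic tie-break; a variable absent from a cluster ranks one past the
variables present there, so it fails rank criteria naturally. The "> 5%"
floors compare frequency rounded to 4 decimals against 0.05, making the
boundary (exactly 5.00%) inclusive. Two open choices were resolved here: the
non-significant PF arm uses the overall frequency (the per-cluster reading is
the stricter alternative), and no multiple-testing correction is applied
across variables, matching the single-test-per-variable workflow this
re-implements. Secondary features (SF) are the non-PF variables at ≥ 5%
within-cluster frequency, listed per cluster and category in descending
frequency order.

Combination expansion treats each (cluster, category) SF list independently:
its top-n prefixes for n = 1..len joined with the full PF set give the
P + Sx_n combinations, each weighted by the *anchor frequency* — the
frequency of the n-th (last) SF entry, not a mean. The total combination
count therefore equals the sum of SF list lengths. For the shipped reference
lists that sum is 87 as printed; one pulse entry is printed twice in cluster
5's list, and `enumerate_combinations(..., dedupe=True)` gives the
deduplicated alternative (86). Per cluster i, each pattern j aggregates
f_ij = mean anchor frequency of the combinations assigned to it, and
percentage_ij = f_ij / Σ_j f_ij. The overall table pools all clusters'
combinations and re-aggregates (pooling, rather than averaging the cluster
aggregates, is the package's choice; the alternative is one line of user
code over the audit output). Display rounding is to whole percent; exact
values are retained internally.

Herbal prescriptions carry total consumption in grams — person-days ×
average daily dose, or a precomputed total — and are ranked within kind
(single herb / formula) with alphabetical tie-break. Category summaries sum
totals per therapeutic effect; shares are exact before display rounding. In
the shipped reference table one row is labeled "Nourish the yin to
tranquilize" although the published category totals only balance when it is
pooled with "Nourish the heart to tranquilize"; the loader pools it by
default and preserves the printed label in `label_as_printed`.

## Synthetic cohort generator

The generator emulates a single-center breast-cancer TCM cohort as a
five-subgroup Bernoulli mixture over 41 binary features (21 symptoms, 6
tongue appearances, 5 coatings, 9 pulses):

- **Mixing weights** are proportional to the reference cluster sizes
  (975/290/634/501/338 of 2,738).
- **Twelve shared features** (the PF analogue: insomnia, dry mouth, lack of
  strength, …, slippery pulse, rapid pulse) keep one cohort-wide marginal in
  every subgroup, taken from the reference frequency table (e.g. insomnia
  0.387).
- **The remaining 29 features** are split into disjoint per-subgroup
  signature sets, present with probability 0.80 in their subgroup and 0.05
  elsewhere — a well-separated regime. Signature sets are sized inversely to
  subgroup weight so that every pair of subgroups is separated strongly
  enough for the planted k = 5 to register under the 10% relative-drop elbow
  rule; with fewer signatures on the small subgroups the WSS drop at five
  clusters falls below the rule's threshold and the structure, although
  still recoverable by ARI, would not be *selected*.
- **Surface noise**: with probability `synonym_rate` (default 0.15) a term is
  emitted as a hand-listed synonym or a decorated spelling (case, padding);
  with probability `missing_rate` (default 0.02) a record drops one whole
  category. True subgroup labels are returned on the record object and
  written to a side file, never into pipeline input.

At the defaults (2,000 cases), k-means recovers the planted labels with
ARI ≈ 0.99 and the elbow selects k = 5 across seeds. What passing these
checks shows is that the pipeline's machinery is correct and sensitive under
a favorable, well-separated regime; it does **not** show that real EMR
cohorts — with correlated symptoms, overlapping subgroups, class imbalance
in severity, and free-text noise far beyond synonym substitution — would
cluster this cleanly, nor that the demo knowledge base approximates a
clinical-grade one (the production analogue holds >20,000 terms; the demo
thesaurus has ~60 entries and the demo pattern documents are hand-authored
to standard pattern semantics over this vocabulary).

## Numerical and interface choices

- All randomness flows through `numpy.random.default_rng(seed)` or
  scikit-learn's `random_state`; fixed seeds give byte-identical outputs.
- The chi-square test errors on a degenerate margin (all-yes or all-no
  variable) rather than returning a fabricated p-value.
- k-means requires 2 ≤ k ≤ number of distinct rows; `choose_k` restricts the
  search range to [2, 12].
- Knowledge-base counts must be positive integers; tf of an empty document
  and idf of an unknown term are errors, not zeros, so silent vocabulary
  mismatches cannot masquerade as evidence.
- Thesaurus matching is exact after normalization (trim, casefold, collapse
  whitespace); no fuzzy matching. A variant may map to only one canonical
  term. Unmapped terms are counted and reported for curation instead of
  failing the run.
- Tabular I/O is UTF-8 CSV with headers; the knowledge base and PF/SF
  reports are JSON.

## Known limitations

- The cohort-level quantities of the original study (its best KPI threshold
  0.252045, its per-cluster pattern percentages computed from raw records)
  depend on a private hospital cohort and a proprietary thesaurus/knowledge
  base, and are not reproducible here; the package reproduces the published
  derived arithmetic exactly and the statistical behavior on its own
  synthetic conditions.
- Problem sizes used by the shipped checks: 2,000-case cohorts for recovery
  and elbow experiments, 200 simulated cohorts of 5 × 400 cases for the
  chi-square null-retention check.
- Only top-1 pattern assignment (plus the full ranking) is produced; no
  multi-label thresholds.
- The KPI sweep holds the cluster count fixed; re-selecting k per threshold
  is a one-line change but is not the default.
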