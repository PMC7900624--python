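# Methods

## Model and procedure

`toxsets` tests whether a predefined gene set is coherently perturbed in
a differential-expression experiment, using only per-gene log fold
changes. It is a *competitive* test: the reference is not "no change"
but "a random gene set of the same size drawn from this experiment".

Given the table of log fold changes `f_g` (all genes form the
*background*), a set with `n` matched genes is scored two ways:

- AFC: `S = Σ f_g` over the matched genes (signed; direction of
  regulation);
- AAFC: `S = Σ |f_g|` (direction-agnostic disruption).

The null distribution of each statistic is built by Monte Carlo: 10,000
draws, each selecting `n` values uniformly **without replacement** from
the background and applying the same statistic. Without-replacement
sampling matches the "random gene set of the same size" interpretation
exactly, and makes exhaustive subset enumeration an exact oracle for the
sampler (both are uniform over the `C(N, n)` subsets). The reported
quantities are

- `z = (S − μ_null) / σ_null` with `σ_null` the population-convention
  standard deviation of the draws;
- `p = (#{draws ≥ S} + 1) / (n_draws + 1)`, the add-one empirical
  upper-tail probability. The add-one estimator keeps p in (0, 1]: a
  finite resample can never certify p = 0.

Both methods use the upper tail: p is the probability that a random
same-size set scores *at least as high*. Consequently a strongly
down-regulated set has an AFC p near 1 by construction — its evidence is
carried by the large negative AFC z-score (and by AAFC). This is
deliberate: making the AFC p two-tailed or direction-conditional would
double the type-I rate at a nominal threshold (a direction-conditional
one-sided p has P(p ≤ α) = 2α under the null), and the package's
calibration test pins the type-I rate at the nominal level. Users who
want a direction-aware tail can call `empirical_p(..., tail="lower")`
directly.

For AAFC a negative z only means the set's genes move less than a random
set's — not a biological signal — so `aafc_significant` is false for
z ≤ 0 and the ranked report floors such sets below all activated ones.

If gene-level p-values are present, each set additionally gets Fisher's
combined probability over its matched genes that carry p-values:
`X = −2 Σ ln p_i ~ χ²(2k)` under the null of k independent uniform
p-values. Inputs are floored at 1e-300 before the log and the resulting
p is floored at the same value, keeping it in (0, 1] even when the χ²
survival function underflows.

### Degenerate cases

- Set size ≥ background size, or a constant background: the null has no
  spread. The result is flagged `degenerate` with z = 0 and p = 1 rather
  than raising, so one pathological set cannot abort a batch.
- Fewer than `min_matched` genes found in the table (default 3 — a
  z-score over one or two genes is statistically meaningless): the set is
  flagged `unscored` and kept in the output rather than dropped, so input
  problems (wrong identifier namespace, typos) stay visible.
- Ties in the ranked report break by set name ascending; the ordering is
  a total order and reproducible.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `n_draws` / `--permutations` | 10,000 | null draws per (set, method); Monte-Carlo SE of p ≈ √(p(1−p)/10⁴) |
| `seed` / `--seed` | 17 | seeds one NumPy generator per run |
| `min_matched` / `--min-matched` | 3 | minimum matched genes to score a set |
| `scale` | `log` | `linear` applies log2 to the value column (values must be > 0) |
| rank key | `aafc_z` | report ordering; `afc_z` and `fisher_p` also available |
| BH adjustment | off | Benjamini–Hochberg columns appended on request; never reorders |

One seeded generator is consumed set-by-set in sorted set-name order, so
every number is independent of the order of lines in the GMT file and
two runs with the same inputs and seed are byte-identical.

Duplicate gene IDs in the input are collapsed to the arithmetic mean of
their log FC (preserving the aggregate-sum semantics of AFC) and the
minimum of their p-values (conservative for drill-down display); the
collapse is counted and logged. Missing cells in the optional p-value
column are allowed. Gene identifiers are opaque case-sensitive text; no
translation between namespaces is attempted, only an advisory warning
when the bundled Entrez-keyed modules are paired with a table declared
as "other" identifiers.

## The injury-module manifest

The bundled manifest lists the 19 rat injury modules — 11 liver and 8
kidney gene sets, each associated with a graded histopathological
phenotype and grouped into inflammation, degeneration and proliferation —
with their published gene counts (e.g. liver Fibrogenesis 48, liver
Cellular infiltration 25, kidney Fibrogenesis 125, liver Oval cell
proliferation 126). The member gene lists are not bundled: they belong
to the prior work that derived the modules, and are supplied by the user
as a GMT file (`--injury-modules`). For pipeline testing,
`placeholder_injury_modules` fabricates clearly-labelled synthetic
memberships at exactly the declared sizes. Two module names occur in
both organs (Fibrogenesis, Cellular infiltration); in generated
collections only these are disambiguated with an organ suffix.

## The synthetic-data generator

`toxsets.fixtures` emulates the statistical structure the methods
assume: a background of independent null log2 fold changes
`f_g ~ Normal(0, σ)` with σ = 0.3 by default (a realistic
replicate-level noise magnitude for bulk expression data), plus planted
gene sets perturbed coherently:

- **shift** mode adds a constant effect (default experiments use +1.0,
  i.e. a two-fold change) to every planted gene — visible to both AFC
  and AAFC;
- **mixed-sign** mode adds the effect magnitude with a *sign-balanced*
  random assignment: ⌈n/2⌉ genes up, ⌊n/2⌋ down, allocation randomized.
  Balancing is essential to the mode's purpose of being AAFC-detectable
  but AFC-null: with independent random signs the net sign imbalance of
  a 25-gene set has a standard deviation of 5 genes, which alone drives
  |AFC z| beyond 3 in about a third of replicates.

Optional gene-level p-values are the exact two-sided normal tail
probability of `f_g/σ`, hence Uniform(0,1] under the null and small for
planted genes (they are recomputed after planting so they stay
consistent with the perturbed values).

What the generator does **not** emulate — and hence what passing tests
do not establish about real data: inter-gene correlation (co-expression
inflates the null spread of real gene sets, so real z-scores are
anti-conservative relative to this independent null), heavy-tailed or
asymmetric fold-change distributions, mean–variance coupling from count
noise, dose/time structure, and identifier mismatch rates. The scoring
engine itself is distribution-free — it never assumes normality — but
the calibration and power numbers reported by the acceptance experiments
are properties of this idealized background.

## Numerical and design choices

- Without-replacement subset draws use rejection sampling (draw with
  replacement, redraw rows containing a repeat) when `k(k−1) ≤ N`, which
  is exact and fast for small sets, and otherwise take the k smallest of
  N iid uniforms per draw (equivalently a uniform random k-subset),
  chunked to bound memory.
- The exhaustive oracle refuses instances with more than 10⁶ subsets.
- AFC and AAFC nulls for one set use separate draws from the shared
  stream; draws are not reused across methods.
- TSV output renders z with 4 decimals and p in scientific notation;
  JSON mirrors all fields at full precision and round-trips exactly.
- Problem sizes in the validation experiments (2,000-gene background
  with 1,000 random sets for calibration; 1,000-gene background, 25-gene
  planted set, 50 decoys, 100 replicates for power) were chosen as the
  smallest sizes at which the binomial acceptance bands are meaningful.

## Known limitations

- Competitive resampling of *values* ignores gene–gene correlation; see
  above. A sample-permutation null would address this but requires
  per-sample data, which the fold-change-only input contract rules out.
- The AFC upper-tail p is not a two-sided test; down-regulation must be
  read from the z sign or ranked via `afc_z`.
- Fisher's method assumes independent gene-level p-values, which real
  co-expressed genes violate; its combined p is best treated as a
  ranking heuristic.
- No identifier translation: a namespace mismatch between table and gene
  sets silently yields empty intersections (surfaced as `unscored` rows
  and a logged warning, not corrected).
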