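# Methods

## Model

The package scores the tissue-specific activity of gene sets in two
stages and then reuses those scores as multiple-testing weights.

**Stage 1 — gene weights.** For gene *i* and tissue *t*, the weight is
the product `w_g[i,t] = e[i,t] * a[i,t]` of an RNA fold-change and a
protein-detection gate:

- `e[i,t]` = expression of gene *i* in tissue *t* divided by the gene's
  mean expression over **all** tissues in the table. Missing cells count
  as 0 both in the numerator (the gene is assumed unexpressed where it
  was not measured) and in the denominator mean; a gene with zero mean
  gets `e = 0` in every tissue (0/0 is resolved to "no evidence" rather
  than an error, since an all-unmeasured gene carries no signal). The
  fold-change is dimensionless, so the expression units (FPKM, TPM, ...)
  only need to be consistent within the table.
- `a[i,t]` ∈ {0, 1} from the four-level IHC call: 1 for "Low" or
  stronger, 0 for "Not detected", and 1 when no record exists for the
  pair — an absent IHC measurement leaves the decision to the RNA
  evidence, whereas an explicit "Not detected" vetoes the gene in that
  tissue. Multiple records per pair (different antibody-stained cell
  types) collapse by maximum: detection in any cell type counts.
  Records can optionally be pre-filtered on their reliability label
  (e.g. dropping "Uncertain"); the filter is off by default because the
  detection calls are the primary evidence and reliability grading
  schemes differ between data releases.

**Stage 2 — set weights.** For set *j* with members **m** in a universe
of *p* genes, `w_s[j,t] = -log p` where *p* is the one-sided p-value of
a two-sample t-test of mean member weight > mean complement weight in
tissue *t* (a competitive test: the set is compared against the rest of
the universe, not against a null of zero effect). The universe defaults
to the collection's own universe; universe genes without measurements
enter with weight 0, consistent with the missing-data rules above
(`restrict_to_measured` switches to the intersection instead). Because
group sizes are wildly unbalanced (tens of members against thousands of
complement genes) the default is Welch's unequal-variance statistic with
Welch–Satterthwaite degrees of freedom; the pooled-variance form is
available for compatibility with classical two-sample testing. The test
treats gene weights as exchangeable between the groups under the null
and ignores inter-gene correlation; sets whose members are more
correlated than average will score high for that reason too, which is
acceptable for a specificity score but worth remembering when
interpreting weights as pure mean shifts.

**Multi-tissue weight.** `w_m[j] = min over the analyzed tissues of
w_s[j,t]`. The minimum is deliberately conservative: a set must show at
least basic specific activity in *every* tissue of the group to rank
highly, which is the right semantics for systemic-disease profiling.
Mean and median aggregators are exposed for sensitivity analyses.

**Weighted FDR.** Given external per-set p-values, weights are
standardized to mean 1, `p* = p / w*` is capped at 1, and BH runs on
`p*`. Mean-1 standardization plus independence of the weights from the
p-values under the null are exactly the conditions under which weighted
BH retains FDR control; the tissue weights are computed from reference
atlas data, not from the analyzed experiment, so null independence holds
by construction. A zero standardized weight maps to `p* = 1` (the set
can never be discovered) instead of an infinity, keeping the vector a
valid BH input.

## Numerical choices

- **Log-space tails.** `-log p` is computed from the t distribution's
  log survival function, never by exponentiating and re-logging. Where
  even `logsf` underflows (extreme t at large df), the tail switches to
  a term-by-term log-space evaluation of the regularized incomplete beta
  in hypergeometric form, `I_x(df/2, 1/2) = x^{df/2} (1-x)^{1/2} /
  ((df/2) B(df/2, 1/2)) · 2F1(1, (df+1)/2; df/2+1; x)` with
  `x = df/(df+t²)`, so weights stay finite for any finite t. The two
  branches agree to ~1e-10 relative at the switchover.
- **Log base.** Natural log by default — the magnitudes this produces
  over universes of thousands of genes (tens to hundreds) match how such
  weights are usually reported; base 10 is a flag, and rescales every
  weight by 1/ln 10, so rankings are unaffected.
- **Degenerate tests.** A set weight is *undefined* (NaN plus a flag),
  not 0, when a group has fewer than 2 values or both groups have zero
  variance. This keeps "no evidence of specificity" (w ≈ 0, p ≈ 1)
  distinct from "untestable". `min_set_size` defaults to 2, the minimum
  for a t-test. Sets with any undefined component are excluded from
  multi-tissue aggregates and reports, with the reason recorded.
- **Vectorization.** Collection-level testing computes member sums and
  sums of squares for all sets at once from the g × p indicator matrix,
  then derives complement moments from universe totals; sample variances
  are clamped at 0 against negative rounding. Results match the scalar
  per-set path to 1e-9 relative.
- **Ties and ordering.** Rankings sort by weight descending with
  lexicographic set-name tie-breaks, so reports are byte-reproducible.
- **Round-trips.** Weight tables are written at %.17g and read back with
  round-trip float parsing, making write-then-read bit-exact.

## Identifier matching

Identifiers are opaque strings compared by exact equality after
whitespace trimming; collections (typically gene symbols) and expression
tables (typically Ensembl genes) can be reconciled through a
user-supplied two-column mapping file, with an optional flag to
upper-case both sides. No built-in identifier translation is attempted:
symbol↔Ensembl mappings are version-dependent and belong to the user's
control. Unmapped genes drop out of the set and simply shrink `n_used`.

## Synthetic data

`simulate_hpa` emulates the statistical shape of an HPA-style input:
log-normal baseline expression per gene and tissue (default meanlog 1,
sdlog 1 — right-skewed, FPKM-like; the exact form matters for realism,
not correctness), planted sets whose members are multiplied by a fold
factor (> 1) in one target tissue and always IHC-detected there, and a
background detection probability (default 0.7) that by default rises
with within-tissue expression rank, mirroring RNA–protein concordance
without claiming to model it. Decoy sets of matched sizes are drawn
uniformly. Optional missingness rates blank RNA cells and IHC records to
exercise the missing-data rules. `simulate_pvalue_study` draws null
p-values from Uniform(0,1) and alternatives from Beta(0.1, 1), with
log-normal raw weights whose association with the truth labels is
favorable (alternatives' weights ×10), independent, or adverse (nulls'
weights ×10).

What the generators do **not** emulate: cell-type-resolved IHC,
reliability grading beyond a single label, inter-gene correlation,
between-tissue expression correlation, and realistic gene set overlap
structure. Tests passing on this data therefore demonstrate the
statistical machinery (weight arithmetic, test calibration, FDR
control, recovery of a genuine planted signal), not biological validity
on any particular atlas release.

## Problem sizes used in the checks

The simulation-based checks run at desk scale, chosen to make their
Monte-Carlo error small relative to the margins being tested: 2,000
sets × 200 replicates for null FDR control, 1,000 sets × 200 replicates
per association mode for power direction, and 100 seeds of a
2,000-gene × 10-tissue atlas with a 20-gene planted set among 100
decoys for recovery. Empirical FDR is compared against the target plus
three Monte-Carlo standard errors, since the false discovery proportion
of a single replicate is highly dispersed under a global null.

## Known limitations

- The competitive t-test inherits the usual caveat of ignoring
  inter-gene correlation (see above).
- Weights computed from one atlas release are not comparable in
  magnitude to weights from another release or another log base; only
  within-run rankings and standardized weights are.
- Very large weights on a few sets can make nominally insignificant
  p-values significant after weighting; filtering or discretizing
  weights before testing is a sensible guard in that regime, but is left
  to the user.
- The wFDR stage consumes p-values from any external gene set testing
  tool; it does not implement such a test itself.
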