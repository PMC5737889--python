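# Methods

## Setting

Two categorical factors with R and C nominal levels are cross-tabulated into
counts x_ij with row totals m_i, column totals n_j and grand total N. After a
significant Pearson chi-squared test of independence (statistic
Σ (x_ij − e_ij)²/e_ij with e_ij = m_i n_j / N, df = (R−1)(C−1), no continuity
correction), the post-hoc question is which cells depart from their
independence expectation.

## Cell statistics

Three residuals are computed per cell:

* raw: T_RawR = x_ij − e_ij;
* standardized: T_StdR = (x_ij − e_ij)/√e_ij, whose squares sum to the
  omnibus statistic;
* adjusted: T_AdjR = (x_ij − e_ij)/√(e_ij (1 − m_i/N)(1 − n_j/N)),
  the raw residual divided by its null standard error.

T_StdR and T_AdjR are asymptotically standard normal, giving two-sided
p-values 2(1 − Φ(|t|)) — identical to referring t² to χ²(1). Because the
variance deflation factors are below one, |T_AdjR| ≥ |T_StdR| always, so the
adjusted test is uniformly less conservative. Signed residuals are the
canonical internal representation; report tables print the squares, the
customary presentation.

## Exact conditional p-value

Testing cell (i, j) conditions on all margins. Merging the other rows and
the other columns reduces the problem to a 2 × 2 table with entries
(x, m − x, n − x, N − m − n + x), m = m_i, n = n_j, and the conditional null
law of x is central hypergeometric on max(0, m + n − N) ≤ x ≤ min(m, n).
The exact p-value is

    p = Σ_x P(x) · 1[ |T(x)| ≥ |T(x*)| ]

with the sum over the support and x* the observed count. Holding margins
fixed, all three residuals are positive multiples of x − mn/N, so they induce
the same rejection region and the same p-value; the implementation orders by
the raw deviation and `rejection_region()` re-derives the region under each
statistic in exact rational arithmetic (`fractions.Fraction`) so tests can
confirm the equivalence independently.

Numerical choices:

* **Integer boundary comparisons.** |x − mn/N| ≥ |x* − mn/N| is evaluated as
  |xN − mn| ≥ |x*N − mn| in integers. Deviation ties — including the
  mirror-image count on the far side of the expectation — are decided
  exactly, never by floating-point rounding, and ties are *included* in the
  region (the ≥ above).
* **Log-space probabilities.** Hypergeometric pmfs are computed through
  log-gamma, shifted by the support maximum, exponentiated once and
  normalized by the support sum; stable for N up to ~10⁶. Against a
  big-integer rational oracle the enumeration agrees to better than 1e-12.
* **Degenerate cells.** A margin that absorbs the whole sample pins the
  support to one point; the cell returns p = 1 rather than an error. Zero
  *margins* elsewhere in the table are rejected up front (dropping empty
  levels silently would change the number of comparisons W).
* The region is deviation-ordered, not probability-ordered: this differs
  from the pmf-ordered two-sided convention of some Fisher-test
  implementations, and the two are not interchangeable. No mid-p or
  one-sided variants are provided.

## Multiplicity

With W = R·C simultaneous cell tests, family-wise control uses (in
increasing power) Bonferroni (p ≤ α/W), Holm step-down (rank k vs
α/(W+1−k)) and the Simes step-up rule: find the largest k with
p_(k) ≤ αk/W and reject every hypothesis with p ≤ p_(k). Simes is the
default used for reporting and in the simulation harness. Conventions:
boundary comparisons use ≤ (equality rejects); tied p-values form one
decision unit evaluated at the largest adjusted p-value in the tie group —
relevant because in any 2-row table the two cells of a column share their
adjusted residual and exact p-value exactly. Rejection sets nest
(Bonferroni ⊆ Holm ⊆ Simes), a property the suite tests on random vectors.
The Simes rule is applied as a full step-up closure; adjusted p-values
(min_{j≥k} W p_(j)/j, capped at 1) are reported alongside.

## Null simulation design

The harness measures the family-wise error rate (FWER): the probability
that a method flags at least one cell of a table drawn from the
independence null.

1. **Margins.** For a given (R, C, N), row margins are a uniform multinomial
   allocation of N over R categories redrawn until strictly positive;
   column margins independently likewise. The allocation law is a pluggable
   strategy (`margin_sampler=`): the exact method's validity is conditional
   on margins, so its error control cannot depend on this choice, while the
   asymptotic method's inflation is expected (and observed) to persist
   across reasonable choices. N ≥ max(R, C) is required for feasibility.
2. **Tables.** Given margins, null tables are drawn by filling rows
   sequentially with multivariate-hypergeometric draws from the remaining
   column totals — exactly the multiple-hypergeometric law of independence
   conditioned on margins, distributionally identical to Patefield's
   sampler (verified by exhaustive-support goodness of fit at small N).
3. **Measurement.** Each table is tested cell-wise both ways (asymptotic
   adjusted residual; exact), Simes is applied at α = 0.05, and the FWER is
   the fraction of tables with ≥ 1 rejection. Γ_Asy and Γ_Exact, the
   per-table rejection counts, are also cross-classified into five
   categories (equal-positive, each-method-ahead with the other at zero or
   positive), excluding tables where both are zero.

Default scale is 200 margin sets × 200 tables per margin set (40,000
tables per configuration), which puts a nine-configuration sweep in the
low minutes on one CPU; `SimConfig.full_scale()` switches to
1,000 × 2,000 for study-scale runs. Within one margin set the exact
p-value lookup is computed once per (m_i, n_j) pair over the whole support
and reused across tables, which is what makes the sweep cheap. All
randomness flows through one `numpy.random.Generator` seeded from
`SimConfig.seed`; outputs are bit-reproducible under a fixed seed.

What the generator does *not* emulate: real survey margins are not uniform
multinomial — they are often highly unbalanced — and real tables under
association are not drawn from the null. FWER results here therefore
support the error-control comparison between methods, not power claims,
and specific category percentages in the Γ comparison depend on the margin
law; only directional statements (agreement grows with N; the exact method
rarely out-rejects the asymptotic one, never in the small-N runs observed)
are design-insensitive.

## Known limitations

* Tables with structural zeros, ordered categories (trend tests), or
  stratification are out of scope; zero rows/columns must be removed by
  the caller.
* The asymptotic p-values rely on scipy's normal survival function; below
  ~1e-15 the printed third significant figure of such tail values is at the
  mercy of the statistic's own rounding.
* The exact p-value is conditional on both margins; its guarantee is
  P(p ≤ α) ≤ α under the hypergeometric null (verified exhaustively on a
  margin grid), which makes it discrete and conservative for small
  supports — the familiar price of exactness.
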