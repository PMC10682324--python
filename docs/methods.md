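# Methods

## Problem and model

Commercial deep-learning CAD (DL-CAD) for lung-nodule detection on CT
is sold per case, as a one-off perpetual license, or as a yearly
subscription. Whether it saves a screening programme money depends on
how much radiologist reading time it frees and what that time costs.
The model monetises saved reading time and nothing else: accuracy
changes, downstream work-up costs and installation/hosting fees are
outside its scope (the latter can be added to the price via
configuration).

For an hourly radiologist cost *S* (EUR/h) and a mean saved time
*Δt* (seconds/scan):

- per-case break-even price: `C = S · Δt / 3600` (EUR/scan),
- minimum workload to recoup a fixed price *P*: `W = P / C` (scans;
  per year when *P* is an annual fee),

so `W · C = P` holds identically, and this is enforced as a run-time
consistency check. Confidence intervals propagate through these
monotone transforms by mapping the Δt interval endpoints; *W* is
decreasing in Δt, so its bounds swap.

Three reading paradigms enter the grid:

- **concurrent reader** — the radiologist reads with CAD marks visible;
  saves time (pooled 77 s/scan in the evidence table);
- **pre-screening reader** — CAD triages away scans it calls
  nodule-free; with nodule prevalence *p* and a fraction *r* of
  nodule-free scans ruled out, the workload (and reading-time) reduction
  is `r·(1−p)`, applied to the pooled unaided reading time;
- **second reader** — CAD review after an unaided read; *adds* 33–41 s
  per scan, so no break-even exists. The grid flags these cells rather
  than reporting negative workloads.

## Evidence corpus and pooling

The packaged corpus transcribes the published reader-timing evidence:
8 arm pairs from 6 studies (one study contributes two reader rows;
one reports median/IQR; two arms report no dispersion). Conventions:

- sign: difference = with CAD − without CAD, negative = time saved;
- median (IQR) is converted to mean/SD with the Wan quantile estimator
  (`mean = (q1+m+q3)/3`; SD denominator `(q3−q1)/1.35`, or the
  n-dependent `2·Φ⁻¹((0.75n−0.125)/(n+0.25))` when n is known);
- reported CIs are converted to SEs as `(hi−lo)/(2·1.959964)`;
- multi-reader rows are averaged within study before pooling (policy
  switchable to treat-as-independent).

Default pooling is the **unweighted mean with a t-based 95% CI** over
study estimates. This is a deliberate choice: two arms carry no
dispersion, so a complete inverse-variance pool over the real corpus is
impossible without imputation. The moment-based **DerSimonian–Laird**
random-effects estimator is implemented and used whenever every effect
carries an SE (all simulated corpora); requesting it with missing SEs
raises an error that names the studies and suggests the unweighted
route. DL uses z = 1.96 intervals (large-sample convention); the
unweighted route uses t with k−1 degrees of freedom. Tests cross-check
the DL implementation against `statsmodels.stats.meta_analysis
.combine_effects(method_re="dl")` to ~1e−10.

The published pooled values — 162 (111–212) s without CAD, 118 (82–154)
with, 77 (47–107) saved — **cannot be re-derived** from the printed
table: they are not the plain mean of the printed study values and the
original weighting is unstated. They are therefore treated as inputs
(shipped in the settings file), and the pooling machinery is validated
by properties and simulation instead: recomputed pools land inside
every printed CI (182.0, 129.6 and 50.3 s respectively).

## Scenario derivation

Prevalence 22–51% with an 80% rule-out gives reductions 0.624 and
0.392, quoted to the whole percent (62%/39%) and applied as quoted —
this reproduces the published derivation chain exactly
(0.62·162 = 100.44 → 100 s, CI 68.82–131.44 → 69–131;
0.39·162 = 63.18, CI 43.29–82.68 → 43–83). The exact-fraction mode is
available via `quote_to_percent=False`. No uncertainty on prevalence or
the rule-out fraction is propagated; that variation is what the
best/worst pair expresses. The worst-case point prints as 63 from this
chain while the published table carries 64; replication runs therefore
take the published scenario saved times (100/64 s with their CIs) as
inputs, like the pooled values.

## Replication grid and known discrepancies

The default (replication) grid uses the printed saved times (77/100/64
with printed CIs) and whole-euro salaries (196/127/45 EUR/h from
206 USD × 0.9518, 108 GBP × 1.1731, 211 PLN × 0.2135; rates frozen at
2022 averages, overridable in config). All arithmetic is exact;
rounding happens only at display: half-up, EUR costs to one decimal,
workloads to 0.1 thousand scans, saved times to whole seconds.

Under these inputs the concurrent-reader row and **every** pay-per-use
cost cell match the published table cell-for-cell. Twelve pre-screening
workload cells differ at the last displayed digit (worst case:
96.0 vs 94.9 thousand scans, ≈1.2%), consistent with the authors having
used unrounded pooled values (≈162.8–163.2 s) that the printed table
does not expose. Computing the grid from unrounded scenario times
(100.44/63.18 s) instead repairs none of these and additionally breaks
three best-case cost cells, so the printed-inputs mode is the better
replication default; the alternative remains available
(`replication=False` recomputes everything from the corpus). All
mismatches are emitted in a first-class discrepancy report
(`results/table2_discrepancies.csv`) with both values; none is forced.

## Synthetic data

`simulate_corpus` emulates the statistical structure behind the
evidence table: per study a true saving drawn from
Normal(μ_saving, τ²); per reader, per-scan times with within-reader SD
σ, summarised exactly as published tables report them (mean ± SD per
arm, difference with a normal-theory CI). Defaults mirror the evidence:
μ_no-CAD = 162 s, μ_saving = 77 s, τ = 25 s (the between-study spread of
the printed differences), σ = 40 s, 50–100 scans/reader, normal or
moment-matched lognormal noise. A single seeded `numpy` Generator per
run makes corpora bit-reproducible. Heterogeneity draws are truncated a
few sampling SEs above zero with-CAD time (reading takes positive
time); at the default parameters this affects <0.5% of draws and biases
the mean saving by <0.04 s. What the generator does **not** emulate:
reader-experience effects, paired within-reader designs, and
reading-time definitions that include reporting time — so passing
recovery tests show the pooling machinery is sound, not that the
published corpus is homogeneous.

Validation sizes, chosen to keep the default suite fast while leaving
Monte-Carlo error well below the tested margins: 1000 corpora
(6 studies × 100 scans) for bias (<2 MC SEs) and 95% CI coverage
(required within [0.92, 0.98]); 100,000-scan screening populations for
the triage check (within 3 binomial SEs of `r·(1−p)` = 0.624).

## Numerical choices and edge cases

- Display rounding is decimal half-up (0.9625 → 1.0), locale-independent,
  en-dash CI separator; every rendered cell parses back to its display
  values (round-trip tested).
- Degenerate inputs: zero-width CIs and zero IQRs warn and return 0;
  zero saved time yields cost 0 but an "unreachable" error for
  workloads; a single-study pool returns the study estimate with a
  z-interval when an SE exists, else a degenerate CI with a warning.
- τ̂² is clamped at zero; in that regime DL coincides with the
  fixed-effect pool (tested at 1e−10) and CI width scales linearly with
  a common SE factor. Without clamping the width is not monotone in the
  SEs, which is why the monotonicity test pins the clamped regime.
- The second reader is carried as negative saved time and short-circuits
  to a flagged no-break-even result.

## Limitations

Only radiologist time is monetised; a pre-screening reader that rules
out scans may miss non-nodule findings, and that risk is not priced.
Prices and salaries are point inputs from one country-year each;
sensitivity to them is linear and easy to rerun via the settings file.
The pooled inputs inherit whatever heterogeneity of reading-time
definitions the source studies had.
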