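# Methods

## The funding model

Norwegian hospitals receive activity-based funding: each episode of care
is assigned to a diagnosis-related group (DRG) carrying a per-case
tariff. In delivery care, seven DRGs apply — 370 and 371 (caesarean
section with / without complication) and 372, 373, 373O, 374, 375
(vaginal birth with complication, without complication, outpatient,
evacuation, other delivery-related surgery). DRGs 374 and 375 are
counted in the vaginal group because the national reporting lists them
under vaginal births; this grouping reproduces the 850 CS / 4,010
vaginal split of the 2016 Northern Norway data.

A delivery is modelled as a two-stage branching process: first CS
(probability `P1`) versus vaginal (`P2 = 1 − P1`), then, conditional on
the branch, one DRG leaf — `P3`/`P4` over 370/371 on the CS branch,
`P5`–`P9` over the five vaginal DRGs. All probabilities are estimated
as *pooled* empirical shares across the trusts, not as averages of
per-trust rates, since the registry counts are themselves pooled annual
volumes. The last vaginal share is computed as one minus the other
four, so each tree level sums to one to machine precision.

Funding is tariff-times-count. NOK amounts are converted to euro at the
fixed reference rate 9.3325 NOK/EUR (the 2017-05-16 Norges Bank rate
under which the input funding figures were produced); the rate is
configurable. Money is carried at full floating-point precision and
rounded to whole euro only on output; probabilities and ratios are
displayed at four decimals.

## The target-rate counterfactual ("15 % cap")

The policy funds each trust *as if* its CS rate were exactly the target
rate `r` (default 0.15, the WHO-recommended ceiling), holding the
trust's own total delivery volume `N` and per-case mean tariffs fixed:

    capped_cs      = actual_cs      · r · N / n_cs
    capped_vaginal = actual_vaginal · (1 − r) · N / n_vag

This is **target-rate normalisation**, not a one-sided cap: a trust
below the target gains (its hypothetical case mix contains more of the
better-paid CS cases) and a trust above loses. That symmetric reading
is the one consistent with the published counterfactual table, where
the trust with a 13.9 % actual rate gains. A one-sided variant
(`one_sided=True`), which only scales down trusts above the target, is
provided for sensitivity analysis.

The scaling is applied to each trust's *own* funding, preserving its
case mix and implied mean tariffs, rather than repricing at a
region-wide mean tariff; the latter alternative mispredicts the
published cells by tens of euro. The per-trust *difference* is actual
minus capped total (positive = budget reduction); its sum over trusts
is the *released resources* retained by the regional health authority.
The difference is zero exactly when the trust's actual rate equals the
target, and regional aggregates over any partition of the trusts sum to
the total — both properties are tested. The reproduction tolerance
against the published cells is ±5 EUR, absorbing per-cell rounding of
the published whole-euro figures.

Regional relative impact is reported as the signed percentage change of
the region's actual delivery budget (a gain prints as a positive
percentage). For the northern region this evaluates to −6.3 % of its
9,770,935 EUR delivery budget; published summaries round this figure to
6.4 %, presumably using a different denominator, and the report lists
the discrepancy rather than reconciling it.

## Statistics

Regional CS rates are compared with a Pearson chi-square test on the
2×2 table (region × CS/vaginal) built from pooled trust counts. The
statistic and its one-degree-of-freedom upper tail are written out
explicitly — the tail as `erfc(sqrt(X²/2))`, which is the exact χ²(1)
survival function — because the test is part of the analysis's
methodological surface; tests cross-check it against an independent
statistics library and against numerical integration of the density
(agreement to 1e-8 over statistics in [0, 50]). Yates' continuity
correction (|O−E| reduced by 0.5, floored at zero) is available behind
a flag; uncorrected Pearson is the default since the original analysis
does not state a variant. On the 2016 data the southern-vs-northern
comparison gives X² = 16.40, p ≈ 5.1×10⁻⁵, comfortably below the
published bound p < 0.002; the published point value 0.0002 cannot be
reproduced because the exact counts/variant behind it are unstated.

Registry concordance is the plain count ratio NPR/MBRN for vaginal and
CS deliveries (1.0017 and 1.0131 on the 2016 data), reported at four
decimals.

## Tariff inference

The national per-DRG unit prices are not part of the input data, so
implied tariffs are backed out from the linear relation
`funding(trust) = Σ_d count(trust, d) · tariff(d)` by least squares,
one funding group at a time. The CS system (4 trusts × 2 DRGs) is
over-determined and full rank; the vaginal system (4 trusts × 5 DRGs)
is under-determined, for which the minimum-norm solution is returned
and every DRG whose design column lies in the span of the others is
flagged non-identifiable. Estimates are unconstrained: a negative
estimate is a diagnostic (flagged as implausible by the caller), never
clipped. Residual orthogonality to the design and exact recovery on
noiseless synthetic full-rank systems (relative error ≤ 1e-9) are
property-tested; with ±0.5 EUR rounding noise per funding cell the
recovery error is bounded via the design's pseudo-inverse norm.

## Synthetic data and Monte-Carlo

The generator draws, for each trust, a single multinomial over the
seven DRG leaves with leaf probabilities `P1·P3, P1·P4, P2·P5, …,
P2·P9`. Per-trust totals are fixed (conditioned on the observed annual
volume) rather than Poisson-distributed, matching how the registry
reports one year of activity. Default study conditions mirror the 2016
data: trust volumes (633, 1402, 2115, 710), the tree estimated from the
shipped delivery table, group-mean tariffs (7,517 EUR per CS, 2,484 EUR
per vaginal birth), target rate 0.15. A seed is mandatory; there is no
hidden global randomness, and identical seeds give bit-identical
tables.

`monte_carlo_policy` propagates the sampling noise through the funding
and cap stages and summarises the released-resources distribution
(mean, SD, 2.5/97.5 percentiles). Replicates in which any trust draws
an empty CS or vaginal branch — where the cap scaling is undefined —
are rejected and redrawn, with the rejection count reported; a
rejection rate above 50 % aborts, since the model is not meaningful at
such small volumes. The acceptance script runs 500 replicates, which
pins the Monte-Carlo standard error of the mean well below the released
total while completing in seconds.

What the generator does *not* emulate: year-to-year drift in rates,
behavioural responses of clinicians to the incentive, correlation
between volume and case mix across trusts, and any within-trust
clustering (each delivery is independent given the tree). Passing
simulation tests therefore validate the pipeline's arithmetic and the
multinomial model, not the realism of those richer mechanisms.

## Numerical choices and degenerate inputs

- Money: full precision internally, whole-euro rounding on display; the
  ±5 EUR reproduction tolerance covers published rounding.
- Tree invariants enforced at 1e-12; the last vaginal share is the
  exact complement.
- Undefined quantities raise a validation error naming the offending
  branch, trust or DRG (zero deliveries → no rate; empty branch → no
  conditional probabilities or cap scaling; zero MBRN count → no ratio;
  zero margin → untestable 2×2 table; all-zero design → no tariff
  information).
- Cap rate must lie strictly in (0, 1).
- DRG code "373O" is the literal string with the letter O.

## Known limitations

- Funding is tariff × count only: no DRG cost-weight machinery, outlier
  payments, or the Norwegian block-grant/activity split.
- The counterfactual redistributes nothing; released resources are
  simply totalled.
- The vaginal tariff system is structurally under-identified from four
  trusts; only the CS tariffs are individually estimable from these
  data.
- Published regional rates (14.6 %/18.5 %) differ from the pooled
  patient-registry rates computed here (14.9 %/19.4 %), most likely
  because the former are birth-registry based; the package computes
  from its input table and reports the published values in a fixed
  discrepancy appendix.
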