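# Methods

## Model structure

The package implements a partitioned-survival cohort model with three
mutually exclusive states — progression-free (PFS), progressed disease (PD)
and death — evaluated on 3-week (21-day) cycles. State membership is read
directly off the overall-survival and progression-free-survival curves
rather than built from an explicit transition matrix: with only marginal
OS and PFS curves available (and no published split of PFS exits into
progression vs death), the partitioned-survival reading is the standard and
reproducible construction. At cycle c with start-of-cycle time t_c,

    pfs(c)  = min(PFS(t_c), OS*(t_c))
    dead(c) = 1 − OS*(t_c)
    pd(c)   = 1 − pfs(c) − dead(c)

The `min` clamps digitization or fitting artefacts where PFS would exceed
OS; occupancies are proportions and each row sums to one.

**Background mortality.** OS* applies a per-cycle mortality floor: the
cycle death probability is max(curve-implied, life-table-implied at the
cohort's current age), compounded cycle by cycle. The combination rule is
the package's choice (the source analysis includes natural death but does
not state how it is combined); the max rule guarantees modelled survival
never beats general-population survival. The bundled life table is a
Gompertz–Makeham fixture, q(age) = 1 − exp(−(a + b·c^age)) with
a = 0.001, b = 5·10⁻⁵, c = 1.09, terminal q = 1 at age 100 — a smooth
stand-in for a national life table with realistic magnitudes (q ≈ 0.012 at
age 63). Any age-indexed table (`age,q_annual` CSV) can replace it.

**Accrual.** Continuously accruing quantities (utilities, follow-up and
supportive care) use a trapezoid half-cycle correction,
corrected(c) = (v(c) + v(c+1))/2 with v/2 at the series end; drug
acquisition costs use uncorrected start-of-cycle occupancy, since drugs are
dispensed at visits. Everything is discounted at
(1 + r)^(−t_years) with r = 3 %/year (0–5 % in sensitivity analysis).

**Horizon.** Default 40 years with truncation once less than 10⁻⁶ of the
cohort is alive. A 30-year horizon leaves ~1 % of the treated cohort alive
under the heavy-tailed log-logistic OS (shape 1.5), which would violate the
intended "effectively lifetime" property; with the life-table terminal age
the cohort is fully extinct before 40 years. Year length is fixed at
365.25 days (one month = 30.4375 days) so cycle/month/year conversions are
unambiguous.

## Survival curves

Control-arm curves come from maximum-likelihood fits of five families —
exponential, Weibull, log-normal, log-logistic, Gompertz — to the
(reconstructed) pseudo-IPD, maximising Σ_events log h(t) + Σ_all log S(t),
with the working family chosen by minimum AIC; ties break toward fewer
parameters, then a fixed family order. Optimisation is Nelder–Mead on
log-transformed positive parameters (Gompertz shape unconstrained) with a
three-point multi-start around moment-based initial values and a 10⁻⁸
function tolerance. On data actually generated from a log-logistic the
log-logistic wins the AIC comparison decisively at n = 5000; on a single
censored arm of ~374 patients followed for 22.6 months, log-logistic and
log-normal are near-indistinguishable inside the observed window and either
may win by a small margin — the downstream model consumes whichever fit is
selected.

**Comparator arm.** The treated arm is by default not fitted independently
but derived from the control fit under proportional hazards,
S_trt(t) = S_ctrl(t)^HR (HR_OS 0.73, HR_PFS 0.65). This is what makes
one-way and subgroup analyses that vary the HR coherent: the effect
parameter and the comparator curve are the same object. Fitting the treated
arm directly remains available (`fit_parametric` on that arm's IPD, or
`reconstruct: false` plus explicit construction).

## Pseudo-IPD reconstruction

Digitized curve coordinates are treated as a step function
(last-value-carried-forward). Within each interval between consecutive
number-at-risk times, a censoring count is solved by fixed-point iteration
so that — after placing that many censorings at evenly spaced midpoints of
the interval and reading integer event counts off the survival drops at
each digitized point — the implied at-risk count at the next boundary
matches the published table. Beyond the last boundary, subjects still at
risk at the end of the curve are censored there. The procedure is fully
deterministic, conserves the initial sample size exactly, and on the
package's own fixtures reproduces the input curve to within 0.003 in
sup-norm (tolerance 0.02). Survival increases up to 0.005 (pixel noise)
are clamped to the running minimum; larger rises raise a validation error
naming the offending rows. An optional total-event-count input converts the
latest-time records to match a reported event total; it is off by default
since the source analysis does not state that it was used.

## Economics

Base-case inputs (2020 USD, $1 = ¥6.9 recorded as metadata only):

| parameter | base | range |
|---|---|---|
| HR OS / PFS | 0.73 / 0.65 | 0.58–0.88 / 0.52–0.78 (95 % CI) |
| pembrolizumab, $/cycle | 5625.75 | ±50 % of price |
| 5-FU / cisplatin, $/cycle | 256.67 / 17.52 | 95 % CI as printed |
| paclitaxel (2nd line), $/cycle | 351.81 | 281.44–422.17 |
| follow-up (PFS) / supportive (PD), $/cycle | 55.18 / 125.47 | as printed |
| AE unit costs, $/event | 71.00 / 73.68 / 466.00×3 | ±20 % |
| utilities PFS / PD | 0.74 / 0.58 | 0.59–0.89 / 0.46–0.70 |
| discount, %/yr | 3 | 0–5 |
| start age, yr | 63 | 55–70 (one-way) |

Regimen rules: pembrolizumab for up to 35 cycles and the 5-FU + cisplatin
backbone for up to 6 cycles, both applied to PFS occupancy in the
respective arms; after progression, 43 % (treated) / 47 % (control) of
patients receive second-line paclitaxel, modelled as an uncapped per-cycle
cost on PD occupancy weighted by the uptake fraction (duration is not
published; the cap is configurable). Follow-up cost attaches to PFS and
supportive care to PD — the most common convention where the source lists
both without state assignment; both assignments are config switches.
Grade ≥ 3 adverse events enter as a one-off expected lump cost
(Σ incidence × unit cost) at model start. AE incidences are not published;
the defaults in `pscea.params` are synthetic, trial-like magnitudes and are
config-overridable — they contribute < $300 per strategy and do not move
the ICER materially. Cohort start age (63, the trial's median age) and its
one-way range 55–70 are modelling assumptions, flagged in run manifests.

ICER = Δcost/ΔQALY with dominance labels (dominant / dominated /
non-comparable when ΔQALY ≈ 0); because the pembrolizumab price enters only
the treated arm's cost and linearly, the ICER is affine in that price —
which both yields the exact tornado-midpoint identity (base ICER equals the
mean of the ±50 % ICERs) and lets the threshold analysis solve the
ICER = WTP price in closed form from two model runs, confirmed by a third
to |ICER − WTP|/WTP ≤ 10⁻⁴. The pembrolizumab one-way bounds are computed
as exactly ±50 % of the base price rather than taken from rounded printed
values, so the midpoint identity holds to machine precision.

## Sensitivity analyses

One-way analysis reruns the deterministic model twice per parameter (bound
values with all else at base) and sorts by ICER spread. The PSA draws, per
run: beta utilities and gamma costs by method of moments with mean = base
and sd = (high − low)/3.92 (ranges treated as 95 % intervals; infeasible
beta variances are scaled down with a warning), and lognormal hazard ratios
with sd_log = (ln high − ln low)/3.92. Sampling HRs lognormally is the
package's choice — standard practice for ratio parameters — the source
names only beta and gamma; HRs can be frozen via a degenerate parameter
space. Discount rate and start age stay at base in the PSA. All draws flow
from one seeded generator, so the PSA is bit-reproducible. The CEAC
evaluates P(wtp·ΔQALY − Δcost ≥ 0) on a $0–340,000 grid in $2,500 steps,
covering the landmark WTP values of interest. Subgroup analysis replaces
both HRs (squamous histology 0.72/0.65; PD-L1 CPS ≥ 10 0.62/0.51) and
reruns the full pipeline.

## Synthetic study conditions

The generator emulates a two-arm first-line trial: 374 patients per arm;
control OS log-logistic (median 9.8 months, shape 1.5) and control PFS
log-logistic (median 5.8 months, shape 1.6); treated-arm event times drawn
by inverse transform from S_ctrl^HR; exponential dropout at 0.01/month and
administrative cutoff at 22.6 months (the trial's median follow-up).
Shapes are free parameters chosen for plausible tails and are
config-exposed. Per-patient OS and PFS are simulated independently — the
cohort model consumes only marginal curves, so no joint coupling is
needed — and the digitization artifacts sample the exact product-limit
estimate on a 0.5-month grid with a 3-month risk table.

What the generator does **not** emulate: digitization pixel error beyond
grid rounding, the plateau/delayed-separation shapes characteristic of real
immunotherapy KM curves, within-patient OS–PFS correlation, and
non-proportional hazards. Passing tests therefore demonstrate correctness
of the pipeline's machinery and its qualitative conclusions (ICER far above
the WTP threshold under every scenario examined), not numeric agreement
with results derived from the real digitized curves: with lighter synthetic
tails, absolute LY/QALY totals are smaller and the base-case ICER larger
than an analysis of the published curves would give.

## Problem sizes and runtimes

Default runs use 374 patients/arm, ~520 cycles of trace, 34 one-way
scenarios and 1000 PSA draws; parameter-recovery checks use n = 5000 per
family. The full pipeline (base case + all analyses) completes in a few
seconds on one CPU.

## Known limitations

- Partitioned-survival only; no explicit transition-matrix mode, tunnel
  states or time-varying HRs.
- Second-line treatment is a single agent with unpublished duration.
- AE disutilities and grade 1–2 AE costs are out of scope, matching the
  source analysis's costing rules.
- The utility invariant u_pfs ≥ u_pd is enforced for configured inputs but
  not per PSA draw (independent beta draws may occasionally cross).
- The reconstruction assumes non-informative censoring within risk
  intervals, as the underlying algorithm does.
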