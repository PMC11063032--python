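# Methods

## The model

`httime` implements the population-based threshold ("hydrothermal time")
description of seed germination under combined temperature and
water-potential stress. A seed lot is treated as a population in which each
seed carries its own base water potential ψb; germination of fraction *g*
requires accumulating a fixed amount of suprathreshold driving force:

- thermal time (sub-optimal T):   θT1 = (T − Tb)·tg
- thermal time (supra-optimal T): θT2 = (Tc − T)·tg
- hydrotime (fixed T):            θH = (ψ − ψb)·tg
- hydrothermal time:              θHTT = (ψ − ψb)·(T − Tb)·tg

with tg the time for fraction *g* to germinate, Tb/To/Tc the cardinal
(base/optimum/ceiling) temperatures, ψ the medium's osmotic potential and
ψb(g) the base water potential of the g-th population fraction. Assuming
ψb ~ Normal(ψb(50), σψb) across the population, the cumulative germinated
fraction at time t is

    g(t) = Φ( (ψ_eff − θHTT/((T − Tb)·t) − ψb(50)) / σψb )

where Φ is the standard normal CDF. Above the optimum temperature the
driving force declines; following the convention consistent with reporting
a single hydrotime constant plus a drift rate, we keep θHTT fixed and shift
the threshold distribution upward: ψ_eff = ψ − kT·max(0, T − To). The
hydrotime constant at the optimum is then θH = θHTT/(To − Tb).

A sign note: the hydrothermal accumulation is implemented with the
magnitude (ψ − ψb), which is positive whenever the seed can germinate; some
published statements of the relation write (ψb − ψ), which is negative
under the same sign conventions and cannot produce the positive constants
those same sources tabulate. Likewise the thermal-rate relation is
implemented in its dimensionally consistent form GR = (T − Tb)/θT1 = 1/tg.

## Parameter estimation

Probit-transforming g(t) linearises the model: probit(g) is linear in
x = ψ_eff − θHTT/((T − Tb)·t) with slope 1/σψb and x-intercept ψb(50).
Estimation is therefore *repeated probit regression*:

- **Hydrotime fit (one temperature).** For each candidate θH on a 500-point
  log grid spanning 0.1–10× a moment-based initial guess (the reciprocal
  slope of GR(50) vs ψ), regress probit(g) on ψ − θH/t over all (ψ, t)
  observations and keep the θH maximising R²; ties break toward the smaller
  θH. A bounded golden-section pass then refines the winner between its
  grid neighbours. ψb(50) and σψb come from the final probit line,
  diagnostics (R², F, SE, p) from the OLS.
- **Hydrothermal fit (full grid).** (θHTT, Tb, kT) are optimised by a
  coarse grid scan (25 log-spaced θHTT × 9 Tb × 7 kT values) followed by
  Nelder–Mead polish on (log θHTT, Tb, kT), minimising the probit
  regression's residual sum of squares. The optimum To is fixed beforehand
  as the temperature with the highest pooled GR(50) at the wettest ψ
  (configurable); with no data above To, kT is fixed at 0 with a warning.
- **Thermal fit (cardinal temperatures).** GR(50) at ψ = 0 is regressed on
  T separately below and at/above the observed optimum; Tb and Tc are the
  branch x-intercepts, θT1/θT2 the reciprocal slopes, To the branch
  intersection. A percentile that is never reached within the observation
  window contributes GR = 0 — in the threshold model that rate is genuinely
  zero, and it is what anchors the supra-optimal branch's ceiling when the
  median stops being reached at high T.

Boundary fractions (g = 0 or 1) carry no probit information and are
excluded by default; a 0.5/(2n) adjustment is available
(`boundary="adjust"`). The working percentile defaults to g = 0.5, matching
how ψb(50) is reported. tg(g) is extracted from discrete counts by linear
interpolation of the cumulative-fraction curve, with no sub-observation
smoothing.

## Germination indices

The metrics module computes the classical seed-lot indices (MGT, MGR = 1/MGT,
GE, GRI, GI, Timson, CVG = 100/MGT, T50, SVI-I/II) from daily counts. Two
conventions needed fixing where the literature is loose:

- GRI's day-independent variant ("ΣG_i/2") circulates in print; the default
  here is the standard day-weighted ΣG_i/i, with the literal form available
  as `variant="as_printed"`.
- GE is interpreted as the sum of daily increments of the cumulative
  germination percentage, each divided by its day number.
- GI uses fixed weights 10…1 over days 1…10; later germinations get weight
  0 with a warning.
- T50 targets half of the *final germinated count* (not seeds sown) and is
  reported only when at least half the seeds sown germinated; undefined
  indices are returned as missing values with a reason code, never 0.

Index formulas work in days (counts are daily); the model module works in
hours internally (thermal time in °C·h), converting at the boundary
(24 h/day).

## The synthetic study generator

`simulate` emulates a dish-level germination trial: each seed draws
ψb ~ Normal(ψb(50) + kT·max(0, T − To), σψb); seeds with ψb < ψ germinate at
tg = θHTT/((ψ − ψb)(T − Tb)), the rest never do (no dormancy release), and
the dish is scored at the observation times. Defaults reproduce the
reference sunflower design — 15/20/25/30 °C × 0/−0.3/−0.6/−0.9/−1.2 MPa,
3 replicate dishes of 10 seeds, daily counts for 10 days — with the
reported population truth (ψb(50) = −0.87 MPa, σψb = 0.20 MPa,
θH = 56.43 MPa·h at To, Tb = 6.8 °C, To = 20 °C, kT = 0.104 MPa/°C, hence
θHTT = 744.876 MPa·°C·h). Randomness follows one root seed with
deterministic per-dish substreams keyed by (seed, T, ψ, replicate), so any
grid subset regenerates identically. `noise_mode="none"` returns expected
(rounded) counts from the closed-form CDF.

What the generator does *not* emulate: dormancy and after-ripening, seed
mortality and fungal loss, temperature fluctuation within an incubator,
non-normal ψb distributions, and any correlation between a seed's threshold
and its post-threshold growth. Passing recovery tests therefore show that
the estimator inverts the model it assumes — not that real seed lots follow
that model.

## Verification scale and numerical choices

- Noiseless round-trip checks use 10,000 expected-count seeds per dish so
  that integer rounding (resolution 10⁻⁴ in fraction) is negligible against
  the 1% recovery tolerance; at that scale the joint fit returns all five
  parameters within 1% and R² > 0.999.
- Dish-scale stochastic recovery uses the real design (10 seeds × 3
  replicates) over 50 Monte-Carlo repeats; ψb(50) is recovered within
  ±0.15 MPa in ≥90% of repeats.
- The optimiser's θH choice is cross-checked against an exhaustive
  fine-grid scan using an independently coded R² (squared correlation);
  agreement is required within one scan step.
- Algebraic identities (θHTT = θH·(T − Tb) = θT1·(ψ − ψb); MGR·MGT = 1;
  CVG = 100·MGR) are property-tested at ~10⁻¹² relative tolerance —
  "machine precision" up to float re-association.

## The bundled reference grid

`datasets.SUNFLOWER_GRID` carries a published per-treatment constant table
for sunflower. Its columns are mutually consistent under Tb = 10 °C,
Tc = 45 °C, ψb = −1.5 MPa — constants that differ from the same study's
fitted population values (Tb = 6.8 °C etc.); the grid is therefore used
only as an internal-consistency oracle for the forward relations, never as
truth for the population fit. Its printed θH column is referenced to
distilled water ((0 − ψb)·tg in every cell), and four 15 °C cells (plus one
evident TTsub misprint, 97.65 for 97.6) do not satisfy the grid's own
arithmetic; the consistency tests pin those cells explicitly rather than
pretending they reproduce.

## Known limitations

- The supra-optimal treatment (fixed θHTT, ψb(50) drift) is one of several
  conventions in use; fits under an alternative (declining θHTT) are not
  implemented.
- Probit regression weights all retained observations equally; a
  generalised-linear (binomial) weighting would be more efficient at small
  dish sizes.
- The thermal fit's branch split at the observed optimum is discrete; with
  coarse temperature grids To is only resolved to the grid.
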