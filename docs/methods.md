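# Methods

## Capillary statics of the sealed transfer pipette

The instrument is treated as a quasi-static, isothermal system. The
capillary drive is the Young–Laplace pressure jump in the un-tapered
barrel, ΔP = 2γ cos β / R; dynamics of the meniscus, wetting kinetics,
evaporation and the temperature dependence of γ are out of scope. The
model's state variables are the rise height h₂ of the meniscus above the
reservoir, the fluid column length L₂ = h₂ / sin θ along the capillary
inclined at θ, and the pressure/volume (P₂, V₂) of the sealed gas
headspace.

Three relations close the system: Boyle's law P₁V₁ = P₂V₂ for the trapped
gas, the volume bookkeeping V₂ = V₁ − nπR²L₂, and the hydrostatic balance
P₂ + ρg h₂ − ΔP = P₁. The coefficient n ∈ (0, 1] (default 1/3) corrects
the displaced-gas volume for the taper: near the tip the bore is far
narrower than the nominal barrel cross-section. Eliminating P₂ and V₂
yields

    h₂² − [ΔP/(ρg) + V₁ sin θ/(nπR²) + P₁/(ρg)] · h₂
        + ΔP · V₁ sin θ/(ρg · nπR²) = 0.

Both roots are real for physical parameters; the larger (order
P₁/(ρg) ≈ 10 m) violates h₂ < ΔP/(ρg) and is rejected with validation,
not silently. The smaller root is computed in the co-root form
2c/(b + √(b²−4c)), which is numerically stable when c ≪ b² (the operating
regime: h₂ ≈ 9 mm against b ≈ 17 m); the naive (b − √disc)/2 loses about
three digits to cancellation here. Every solved state is checked against
Boyle's law at relative 1e−9 before being returned.

Two limits anchor the model. V₁ → 0 removes the compliant gas volume and
pins the meniscus at the reservoir (h₂ → 0); V₁ → ∞ makes the headspace an
open reservoir and h₂ → ΔP/(ρg), the Jurin height (relative gap < 1e−3 at
V₁ = 1 m³ with the default constants). A neutral contact angle (β = 90°)
zeroes the entire chain; this case is snapped exactly (cos 90° is not
exactly zero in floating point) so the trivial state is exact.

### Operating point and rounding policy

Default parameters are the documented operating point of the instrument:
γ = 0.0728 J/m², β = 32.3°, ρ = 997 kg/m³, g = 9.81 m/s², barrel radius
R = 0.56 mm (barrel I.D. 1.12 mm), tip I.D. 2.0 µm, θ = 45°, V₁ = 3.1 mL,
P₁ = 1.01 × 10⁵ Pa (as documented, deliberately not 101 325 Pa), n = 1/3.
The associated reference chain is rounded to printed precision: 220.5 Pa,
22.5 mm, 8.9 mm, 12.6 mm, 133.3 Pa. Exact evaluation of ΔP gives
219.77 Pa, i.e. the reference 220.5 carries some unstated rounding path;
both modes are exposed (`dp_override_pa` carries 220.5 downstream, the
default recomputes exactly).

The worked-example checker grades each stage with the *reference* upstream
value feeding it: h₂ is solved with ΔP = 220.5 Pa (8.844 mm vs 8.9), and
the on/off pressure is evaluated as 220.5 − ρg·(8.9 mm) = 133.45 Pa
(vs 133.3). This stage-wise convention isolates per-stage model agreement
from rounding accumulated along the chain; the fully self-consistent
chain (on/off 133.56 Pa recomputed, 134.00 Pa carried) is reported
alongside in the same JSON document.

The documented aspirated sample volume, 21.6 µL, is **not** reproduced by
ΔV = (L − L₁)πR² under either closed convention we can construct: taking
L from the theoretical Jurin rise with L₁ = L₂ gives ≈ 19.0 µL, and from
the experimentally measured 23.6 mm rise gives ≈ 20.6 µL. The reference
length L₁ is not defined in the source material; rather than guess, the
package computes both candidates, reports them side by side, and flags the
reference value as unreproduced. No downstream quantity depends on it.

## Membrane tension and the viability envelope

The cap tension of a cell aspirated at the tip is
τ = (ΔP/2)/(1/R_CH − 1/R_OUT), the law-of-Laplace balance on the aspirated
spherical cap. It is linear in ΔP, strictly increasing in tip radius and
decreasing in cell radius, with flat-cell limit ΔP·R_CH/2. Pairings with
R_CH ≥ R_OUT are rejected (scalar call) or masked (grid sweep): such a
cell would be swallowed whole and the cap model does not apply. Cortical
shells, projection-length dynamics and finite-element mechanics are out
of scope.

Dimensionally τ is Pa·µm (≡ µN/m); the rupture thresholds for clinical
tumor cells are carried at their literature printing, "800–5000 with
median 3700, label Pa/µm". The numbers are compared by magnitude and the
label discrepancy is recorded in report metadata rather than silently
relabelled. Classification is conservative: τ exactly at the minimum
threshold is "within-rupture-range", not "safe".

The design-space sweep defaults to tip I.D. 0.5–5.0 µm in 0.25 µm steps ×
cell diameter 8–20 µm in 2 µm steps — chosen to span the practical pulled
tip range and the size range of leukemia-line surrogates, since no axis
values are documented for the reference sweep; both axes are fully
configurable. At the 133.3 Pa operating suction the maximum tension on
this grid is ≈ 444, below the 800 minimum everywhere, which is the
quantitative content of the viability claim.

## Calibration statistics

Transfer efficiency is 100·released/target per trial. Summaries are per
target count: mean, sample SD (n−1 divisor; reported as absent, not zero,
for a single replicate), range, and replicate count — range-style and
SD-style error bars are both supported and labelled. Mean-of-ratios
deliberately differs from pooled-ratio when target counts are unequal;
a test pins the distinction.

The calibration fit is ordinary least squares via the closed-form normal
equations, with R² = 1 − SS_res/SS_tot ("correlation coefficient R²" is
read as the coefficient of determination). Two regression conventions are
exposed: `rows` (every trial a point) and `means` (default; one point per
nominal spike count, the convention of a calibration plot with mean ± SD
error bars). Degenerate abscissae raise rather than return NaN.

## Synthetic trial generator

The generator emulates the *statistical structure* of bench trials, not
the bench itself: per-cell Bernoulli retention during transfer and
binomial device capture. Retention is r(k) = max(0, 1 − c·max(0, k − k₀))
with k₀ = 10 and c = 0.0267 per cell beyond k₀ — the simplest shape that
is lossless for small transfers and gives an expected efficiency of
86.65% at k = 15, the documented large-transfer regime; an exponential
decay is available behind `retention_model="exponential"` for sensitivity
checks. Device capture probability p_dev = 0.90 is a convention (no
device efficiency is documented) chosen to place the spike-in series in a
high-R² calibration regime. Seeds are mandatory; a fixed seed reproduces
tables byte-for-byte.

What passing tests show — and do not. Parameter recovery (p_dev within
3 SE, c within 3 SE at 10⁴ replicates) and the efficiency regime (mean at
k = 15 within 1% of 86.7% at 10⁴ replicates) validate the generator and
the estimators against each other; they say nothing about bench values,
whose per-trial data are not available and which the package does not
claim to reproduce exactly. The generator also omits whole-blood
background cells, spatial microfluidics and dilution-series variance.

Under the default 3-replicate design the per-count-means calibration R²
is a random variable with median ≈ 0.996; the regime test therefore
asserts the *median* R² over 25 seeded replicate tables ≥ 0.99 rather
than a single draw, which would alias generator noise into a pass/fail
coin flip. Per-row R² is intrinsically lower (median ≈ 0.97) because
binomial capture noise is not averaged.

## Interfaces and reproducibility

SI units internally; the configuration layer accepts bench units through
suffixed keys (`v1_ml`/`v1_m3`, `tip_id_um`/`tip_id_m`, …), rejects
unknown keys and non-physical values naming the offending key, and
records per-key provenance (default/file/cli). Reports are plain-dict
JSON that round-trips losslessly; re-running from a report's serialized
parameters reproduces its numbers exactly. All randomness lives in the
generator; the physics chain is deterministic by contract.

Problem sizes used by the test suite — 10⁴ replicates for law-of-large-
numbers checks, 1000 random parameter sets for the solver-vs-bisection
oracle, 25 tables for the R² regime — keep every statistical assertion
comfortably powered while the whole suite runs in seconds.
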