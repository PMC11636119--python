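# Methods

## Scope and data model

The analysis unit is the *stratum*: one restoration age crossed with one
canopy position (`under_crown`, `crown_edge`, `outside_crown`). A community
table holds one species observation per row (quadrat id, age, position,
species, life form, height in cm, coverage as % of quadrat area, density
as individuals per quadrat, optional abundance count); a soil table holds
one depth-layer composite per row (pH, SOM in g/kg, AN in mg/kg, TP in
g/kg for the 0–20, 20–40 and 40–60 cm layers). Coverage is stored in
percent only; per-unit inputs are rejected rather than rescaled, so a 100×
unit error cannot pass silently. Validation is eager: field bounds at
construction, uniqueness of (quadrat, species) pairs, and referential
integrity of quadrat ids, with row errors carrying line numbers.

## Importance values and diversity indices

Species are aggregated across a stratum's quadrats — mean height, summed
coverage, summed density — before relativization; sums preserve relative
proportions, and the mean keeps height on a per-plant scale. Each relative
component is the species' aggregate over the stratum total, and
`Iv` is their mean, so `Σ Iv = 1` (enforced to 1e-9).

The index weights `Pᵢ` default to importance values, the convention in
vegetation-survey practice where the "number of individuals" in the index
formulas is interpreted as the species importance value; an `abundance`
mode uses raw counts instead. Margalef's `R = (S−1)/ln N` is the
exception: its `N` must be a genuine individual count (the importance
total is 1, whose logarithm is 0), so `N` is the stratum's total abundance
when counts were recorded, otherwise total density rounded to the nearest
integer and floored at 2. A monoculture has `R = D = H = 0` and *undefined*
evenness: `E = H/ln S` is 0/0 at `S = 1`, returned as NaN and printed as
NA — neither 0 nor 1 is a defensible convention. Natural logarithms
throughout.

## The improved Godron stability measurement

1. **Cumulative curve.** Species are ranked by total coverage descending
   (ties broken lexicographically for determinism); point *i* of *S* sits
   at `x = 100·i/S`, `y = 100·(cumulative coverage)/(total coverage)`.
   Descending order is what makes the curve concave and comparable across
   strata; the curve is invariant to rescaling all coverages by a common
   factor. Cumulating coverage rather than occurrence frequency is the
   "improved" variant, better suited to sparse vegetation where
   frequencies saturate.
2. **Smooth curve.** Unconstrained ordinary least squares of degree 2
   (degree 1 when the stratum has fewer than 3 species). The intercept is
   free: empirical cumulative curves start well above the origin, and
   forcing (0,0) would bias the crossing. Least squares, not
   interpolation: the published curves of this literature report R² < 1.
3. **Intersection.** The crossing with the anti-diagonal `y = 100 − x`
   solves `c₂x² + (c₁+1)x + (c₀−100) = 0` in closed form. The smallest
   real root in [0, 100] is returned; for every realistic concave curve
   the second root lies far beyond 100, and the ambiguous two-in-range
   case is logged. A bisection oracle cross-checks the closed form in the
   test suite.
4. **Distance and verdict.** Euclidean distance from the intersection to
   the stability point (20, 80) — on the anti-diagonal this equals
   `√2·|x* − 20|`, and both computations are asserted to agree. The
   community is *stable* iff distance ≤ `√(10²+10²) = 14.142`, inclusive.

`paper_compat=True` reproduces published-table precision: the intersection
coordinates are rounded to 2 decimals *before* the distance, and the
distance rounded to 2 decimals. The orders matter — a curve crossing at
x\* = 29.885 gives 13.98 at full precision but 13.97 after coordinate
rounding, and published tables carry the latter. Full precision is the
default for scientific use.

### Geometry of the distance, and a non-obvious monotonicity

The intersection x\* falls strictly as dominance concentrates (a higher
cumulative curve crosses the anti-diagonal earlier). The distance is
therefore **V-shaped in dominance**, not monotone: a community approaching
the 20/80 configuration from the even side (x\* > 20) gets *more* stable
as dominance grows, and only past the crossing does further dominance push
it away. For two-species strata the closed form is
`x*(s) = 200(1−s)/(3−2s)` for dominant share `s`, crossing 20 at
`s = 0.875`. The test suite asserts this correct form (x\* strictly
decreasing; distance weakly increasing past the crossing).

### Reproducing a published fit with a valid coverage profile

A published quadratic fitted to cumulative data generally *cannot* be hit
exactly by any legal cumulative profile: such curves exceed y = 100 and
turn over before x = 100, while a cumulative curve is non-decreasing and
ends at (100, 100) (a linear-programming feasibility check confirms the
impossibility for the 45-yr outside-crown curve). `shares_matching_curve`
therefore builds the closest feasible stand-in: starting from the target
curve capped at 100 and made monotone, it applies a closed-form
equality-constrained least-squares projection in increment space so that
the OLS fit of the resulting cumulative points passes *exactly* through
the target curve's anti-diagonal crossing. All downstream stability output
(intersection, distance, verdict) then reproduces the target's. The
construction is deterministic and synthetic by design.

## Soil summaries

Arithmetic means and sample (n−1) standard deviations per group, for any
subset of the three grouping dimensions (collapsed dimensions print
"all"); sd is 0 for singleton groups. Percent change vs control is
`100·(T − C)/C` — the only reading under which "250.08 % higher" means a
3.5008× ratio — and is scale-invariant.

## Synthetic chronosequence generator

The generator emulates the statistical structure of a shrub-restoration
chronosequence; it is the package's test bed, not a simulation of any real
site.

**Community.** Geometric (niche-preemption) rank abundance: shares
`k(1−k)^(i−1)`, renormalized. The single parameter `k` maps monotonically
to dominance, the simplest family with that property. Defaults, chosen
once from the study system's published structure:

| age (yr) | richness S (outside) | k | under-crown richness deficit |
|---|---|---|---|
| 0 | 3 | 0.38 | 0 % |
| 13 | 15 | 0.32 | 20 % |
| 25 | 17 | 0.31 | 10 % |
| 45 | 21 | 0.30 | 5 % |

Richness endpoints (3 → 21) are the published span; interior ages
interpolate monotonically. `k = 0.38` at `S = 3` puts the control's
dominant share at 0.50, the published control dominant importance value,
and k relaxes slightly with age so the dominant's share falls strictly.
The under-crown contrast is a *richness deficit* (fraction of the
stratum's species missing under the canopy) rather than a k-contrast: on
the even side of the 20/80 point, where the whole chronosequence sits,
only a richness deficit makes under-crown strata simultaneously less
diverse *and* less Godron-stable, which is the observed pattern; a
dominance boost would wrongly make them more stable. Both the falling
distance trend (≈31.6 → ≈5.8 at seed 1) and the shrinking under/outside
gap emerge from richness growth, the dominant driver on this side of the
stability point.

Heights and densities are proportional to the coverage shares (dominants
taller and denser) with multiplicative lognormal noise (σ = 0.15 default),
so at σ = 0 every relative component — hence every importance value —
equals the configured share exactly, and closed-form Shannon/Simpson
values of the shares are recovered to 1e-9. Abundance is the rounded
density (≥ 1). Three quadrats per stratum by default.

**Soil.** Deterministic trend surface times mean-preserving lognormal
noise (`value = mean·exp(σz − σ²/2)`, σ = 0.2) for nutrients, additive
normal noise (σ = 0.1) for pH, so expectations sit exactly on the trend at
any σ. Controls: pH 8.4, SOM 4 g/kg, AN 12 mg/kg, TP 0.30 g/kg — a
plausible alkaline, nutrient-poor mobile-sand profile. SOM and AN rise
geometrically to 3.5008× and 5.4243× the control by year 45 (the published
enrichment percentages 250.08 % and 442.43 % serve as calibration
targets); pH falls linearly by 0.8; TP is flat in time but enriched 1.4×
in the 0–20 cm layer; canopy positions scale nutrients 1.08/1.00/0.94
(under/edge/outside) with a small pH depression under the crown. Because
layer and position factors are age-independent they cancel in
45-yr/control ratios, which the tests verify in expectation (Monte-Carlo,
500 replicates, 5 %).

**Determinism.** Every stratum and soil cell draws from
`numpy.random.default_rng` seeded by (seed, stratum indices), so identical
configs regenerate byte-identical files and sub-streams are independent of
iteration order.

**What passing tests do not show.** The generator has no spatial
structure, no species turnover between ages (richer strata nest the
poorer), no interannual variance estimates from real data (noise levels
are implementer-chosen), and its evenness schedule is monotone by default
(the mid-chronosequence diversity hump seen in some field systems can be
configured via `k_by_year` but is not the default). Tests passing on this
generator demonstrate correctness of the computations and recoverability
of configured structure, not fidelity to any particular field site.

## Problem sizes

The default test suite runs in well under a minute on one CPU: property
suites use 1,000 random curves/strata, the Monte-Carlo soil check uses 500
single-replicate tables, and the acceptance script's soil computation uses
20 replicates per cell (n = 720 samples) to tighten the stochastic
enrichment estimates.

## Known limitations

* Degree > 2 smooth curves are not supported; the literature this package
  serves fits quadratics, and the closed-form intersection relies on it.
* The frequency-based classical Godron variant is exposed only through
  user-supplied per-species frequencies; the pipeline computes coverage.
* `stratified_summary` assumes balanced enough groups to make means
  meaningful; it performs no significance testing (ANOVA/LSD and
  ordination are out of scope).
* Pielou evenness is capped at 1 after floating-point division; values
  above `1 + 1e-9/ln S` raise an inconsistency error instead.
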