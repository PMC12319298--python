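# Methods

This note records the model equations, the synthetic data generator and its
defaults, the numerical choices, and known limitations of `xyloscale`.

## 1. Scaling models

### Conduit widening

Lumen diameter along the hydraulic path follows a power law in the distance
`L` (m) from the terminal leaf tip:

```
d = d0 · L^α        (shoots, fitted on log10 d vs log10 L)
d = d0 · D^β        (stems and roots, fitted on external diameter D, mm)
```

Generator truths: `α = 0.23`, root `β = 0.42` with normalization 2.19, and a
stem `β` that emerges from composing the widening law with the within-tree
length–diameter allometry `L ∝ D^1.391`, giving `β_stem = 0.23 · 1.391 ≈
0.32`.

### Standardized major axis (SMA) regression

Allometric exponents are estimated by Model II (SMA) regression on the
log–log scale:

- slope = `sign(r) · s_y / s_x`, intercept = `ȳ − slope·x̄`;
- 95% CI: with `B = F(0.95; 1, n−2)·(1−r²)/(n−2)`,
  `CI = slope·(√(B+1) ± √B)`;
- the test of a hypothesized slope `b0` uses the correlation between
  `y − b0·x` and `y + b0·x`.

All of these are closed-form moment expressions; no iterative optimizer is
involved, and the tests verify `|slope| = s_y/s_x` to 1e-12.

**The SMA estimand under measurement error.** For data generated as
`log y = a + b·log x + e` with `e ~ N(0, σ²)` independent of `x`, the SMA
slope converges to `√(b² + σ²/s_x²)`, *not* `b`: Model II regression
apportions the equation error to both axes and dilates the slope away from
zero. This identity drives two package choices:

1. The generator's diameter scatter default is `sigma_log_d = 0.05`. With the
   organ-placement defaults, `s_x(log10 L) ≈ 1.2` for shoots and
   `s_x(log10 D) ≈ 0.7` for stems/roots, so the dilation bias is below 0.01
   for every fitted exponent, keeping recovery within ±0.02 of truth. At a
   scatter of 0.15 the shoot bias alone would be ≈ +0.03 and recovery to
   ±0.02 would be analytically impossible. The value was fixed from this
   closed form, not tuned against test outcomes.
2. Confidence-interval coverage is assessed against the SMA estimand of the
   simulating distribution (`√(b² + σ_e²/σ_x²)`), for which the SMA interval
   is exact under bivariate normality; covering the structural `b` itself is
   impossible for any y-noise design, by the same identity.

### Curvature, breakpoints, and model comparison

- `quadratic_curvature` fits `y ~ 1 + x + x²` (OLS, statsmodels) on already
  log-transformed data; a coefficient indistinguishable from 0 supports a
  pure power law.
- `piecewise_fit` scans 200 candidate breakpoints on a 1–99% quantile grid,
  requiring ≥ 5 distinct x values on each side; the continuous hinge design
  is `[1, x−c, max(x−c, 0)]`. A break is `meaningful` only if it improves RSS
  over the single line by more than a relative tolerance.
- `model_compare` fits power, exponential, logarithmic, quadratic, and
  piecewise candidates **on a common response scale** (`log10 y`), so RSS
  values and `AIC = n·ln(RSS/n) + 2k` are comparable; `k` counts the
  breakpoint for the piecewise model (k = 4). The reported winner follows the
  parsimony convention: among candidates within ΔAIC ≤ 2 of the minimum,
  the one with fewest parameters. The raw AIC argmin is also reported. Raw
  argmin alone misidentifies a true power law ~15% of the time (a fitted
  extra parameter exceeds its 2-point penalty with χ²₁ exceedance
  probability ≈ 0.157), which is why the parsimony rule is the headline.

## 2. Bin-balanced resampling

Conduit tables are severely unbalanced: trunks contribute orders of magnitude
more conduits than leaves. `plan_bins` finds the largest number of equally
spaced log10 bins (≤ 30) of the predictor for which every occupied bin holds
at least `min_count` (default 100) records. Then either

- **subsample**: every bin drawn down to the smallest occupied-bin count
  `n_min`, without replacement; or
- **bootstrap**: every bin grown to the largest count `n_max`, retaining all
  raw records and adding `n_max − n_bin` draws with replacement.

`iterate_fit` repeats balance-then-fit over seeded iterations
(`numpy.random.SeedSequence` spawning, fully deterministic), reporting the
mean slope, the 2.5/97.5 percentiles of per-iteration slopes, and a
running-mean stability trace; convergence is declared when the trace moves
less than `stability_tol` over its last half.

**Percentile intervals are descriptive, not inferential.** Under bootstrap
balancing every iteration shares all raw records and differs only in the
augmentation draws, so the across-iteration slope spread is
`O(σ/√n_max)` — far smaller than the sampling error of the underlying data
(`O(σ/√n_min)`) plus the SMA dilation offset. The percentile band therefore
quantifies resampling noise, not estimation uncertainty, and must not be
read as a confidence interval for the true exponent: in a 20-seed recovery
study the point estimates land within ±0.02 of truth every time while the
percentile band (halfwidth ~1e-4) contains the truth essentially never. The
test suite documents this deliberately: the recovery test asserting
percentile-band coverage of the truth is expected to fail, with this section
as the explanation.

## 3. Collapse model

The hydraulic path of height `H` is discretized into `N = H/Δl` segments
(default `Δl` = 100 µm). Segment diameters use the midpoint rule,
`d_i = d0·((i−½)Δl)^α`, which avoids the `d(0) = 0` singularity at the tip.
Then, in MPa–m units with sap viscosity `η = 1.002e-9 MPa·s`:

```
r_i  = 128·η·Δl / (π·d_i⁴)          Hagen–Poiseuille, d in m
Q    = (ψ_soil − ψ_leaf) / Σr_i     Darcy
ψ_i  = ψ_leaf + Q·Σ_{j≤i} r_j       node potentials, ψ_0 = ψ_leaf
P_i  = |ψ_i| ;  (t/b)²_crit,i = P_i·β/σ
```

Defaults: `ψ_leaf = −4.7 MPa`, `ψ_soil = −1.5 MPa`, `β = 0.25`,
`σ = 41.6 MPa`. The endpoints are then analytic:
`4.7·0.25/41.6 = 0.0282` at the tip and `1.5·0.25/41.6 = 0.0090` at the
base, independent of `α`, `d0`, and `η` (both of the latter cancel between
`Q` and the cumulative resistance; the tests verify invariance to 1e-9 under
10³ rescalings). Safety factors compare each conduit's measured `(t/b)²` to
the critical value at the nearest node of its own tree's profile; a factor
of exactly 1 counts as safe.

The gravitational pressure head (≈ 0.01 MPa/m) is excluded; the
configuration exposes a `gravity_head` hook that accepts only the excluded
setting.

**Grid convergence.** For `α = 0.23` the segment resistances scale as
`L^−0.92`; the resistance integral is finite but its midpoint-rule error is
dominated by the first cell and decays only as `O(Δl^{1−4α})` = `O(Δl^0.08)`.
Halving `Δl` from 100 µm to 50 µm therefore still moves near-tip potentials
by ≈ 1.5% (measured max 1.53e-2 relative), concentrated in the first
millimetres of path; base-half potentials move by < 1e-7. The headline
endpoint values are unaffected (the tip node is pinned at `ψ_leaf` exactly
and the base recovers `ψ_soil` identically). A sub-0.1% everywhere-on-path
convergence claim is not achievable for any `α < 0.25` under this scheme;
the corresponding test is expected to fail and points here. For `α = 0` the
profile is analytically linear and the implementation matches it to 1e-9.

## 4. Synthetic data generator

One tree is one spawn of the master `SeedSequence`, so datasets are
reproducible record-for-record and insensitive to tree ordering. Per tree:

- height `H ~ U(15, 45) m`; 7 organ classes (leaf, twig, branch, trunk,
  coarse/fine/very-fine root) placed at physiologic path positions, trunk
  and roots at `L = H`;
- conduit counts per sampling point follow `clip(D², 20, 5000)` (D in mm),
  reproducing the natural imbalance (≥ 10× between log-bins of L);
- lumen diameters from the widening law with lognormal scatter
  (`sigma_log_d = 0.05`, see §1);
- thickness-to-span ratios decay exponentially from the tip,
  `(t/b)² = 0.8·e^(−1.5·L/H)`, with latewood (81% of conduits) 3× thicker
  in `(t/b)²` and Mork's index drawn consistently with the wood type
  (latewood iff `M > 1`);
- wall thicknesses back-computed so the stored four wall measurements and
  lumen spans reproduce the target `(t/b)²` and Mork's index exactly.

With zero noise every governing law is recovered to machine precision, which
the tests use as exact oracles.

Because the decay fit is also SMA, the reported decay rate on noisy data is
dilated above the structural 1.5 (to ≈ 2.0 with default scatter and the
latewood mixture), for the reason in §1; the zero-noise generator recovers
1.5 exactly.

## 5. Problem sizes

Default generator settings (5 species × 5 trees, conduit cap 5000) produce
≈ 114k records and are used for the safety-property checks. Recovery and
coverage studies use a reduced replicate chosen by this package for runtime
(3 species × 2 trees, cap 1500, ≈ 19k records), which preserves the
imbalance structure (max/min occupied-bin ratio > 10) and all generator
truths. The collapse grid default is `Δl = 100 µm` (300k segments at 30 m);
profile CSVs are decimated to ≤ ~2000 rows for output.

## 6. Limitations

- Percentile bands from bootstrap balancing are not confidence intervals
  (§2); treat `aggregate_ci` as a stability diagnostic.
- SMA exponents are estimands of the joint distribution, inflated by
  response scatter relative to the structural exponent (§1); comparisons
  across datasets with very different scatter or predictor ranges are not
  exponent comparisons alone.
- Near-tip water potentials depend on the grid resolution at the
  `O(Δl^0.08)` rate (§3); conclusions should rest on the analytic endpoint
  values or on grid-matched comparisons.
- The generator emulates sampling structure and governing laws, not
  species-level biology: species differ only by seed, not by parameters, and
  the within-tree length–diameter allometry is a single global power law.
- No image/section-level processing: inputs are measurement tables.
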