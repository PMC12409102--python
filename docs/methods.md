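# Methods

## Fluorescence model

All quantities derive from the lake (connected-antenna) model of photosystem
II under steady-state illumination. The package works from the three raw
signals a steady-state fluorometer reports — Fs (steady-state yield), Fm′
(maximal yield during a saturation pulse) and Fo′ (minimal yield after
far-red re-oxidation of QA) — and the convention that a healthy dark-adapted
leaf has Fm/Fo = 5.88 (equivalently Fv/Fm ≈ 0.83). That convention fixes the
constant 4.88 = Fm/Fo − 1 appearing in

- NPQt = 4.88/((Fm′/Fo′) − 1) − 1 — a rapid NPQ estimate needing no
  dark-adapted reference,
- ΦNO = 1/(1 + 4.88·qL + NPQt),
- ΦPSII = (Fm′ − Fs)/Fm′, and ΦNPQ = 1 − ΦPSII − ΦNO (an identity, not a
  check),

with qL = ((Fm′−Fs)/(Fm′−Fo′))·(Fo′/Fs) the open-center fraction. The
constant is exposed as a parameter (`k`, default 4.88) everywhere it enters.

The algebra inverts exactly. Normalising Fo = 1, Fm = 5.88:
Fm′ = 5.88/(1+NPQt); Fo′ = 5.88/(5.88+NPQt) (the Oxborough–Baker relation
1/Fo′ = 1/Fo − 1/Fm + 1/Fm′); and Fs = A·Fm′/(qL+A) with A = (1+NPQt)/4.88.
Substituting back gives the convenient closed forms used throughout the
generator and its analytic oracles:

    ΦNO   = 1/(1 + 4.88·qL + NPQt)
    ΦPSII = 4.88·qL · ΦNO

`forward_fluorescence` implements this inverse; the test suite verifies the
round trip to 1e-10 over a dense (qL, NPQt) grid, which pins down every sign
and parenthesis in the forward formulas.

**Quality control.** A record passes QC iff all three yields are strictly
positive and sum to 1 within tolerance (1e-6; the sum is exact when the
yields are computed internally). Raw signals slightly outside
Fo′ ≤ Fs ≤ Fm′ are never clamped — they produce a negative yield and the
record is rejected, mirroring how noisy field measurements are excluded in
practice. The rejection ledger counts violations per rule.

**VPD.** Leaf-level vapor pressure deficit is derived from air temperature
and relative humidity with the Tetens saturation pressure
e_s = 0.61078·exp(17.27·T/(T+237.3)) kPa; the function is isolated so an
alternative saturation formula can be swapped in.

## Synthetic campaign generator

The generator emulates the sampling design of a tall-evergreen-forest PAM
campaign: three height strata (S1 0–20 m, S2 20–40 m, S3 > 40 m), 45 trees
per stratum per season by default, three branches per tree at
bottom/middle/top crown positions, four leaves per branch, and two seasons
with distinct species pools (14 wet, 18 dry). Default totals: 3 240 records,
~3 080 after QC — the scale of a real multi-season campaign.

Mechanistic chain, per leaf at height h:

1. **Light**: PAR = par_top·exp(−k_ext·L(h))·ε, with L(h) the leaf area
   above h in a two-layer canopy (LAI 3.4 spread over 0–20 m understory,
   2.4 over the 25–45 m crown layer; k_ext = 0.62) and ε mean-one lognormal
   sunfleck noise (σ = 0.35).
2. **Atmosphere**: VPD and air temperature rise linearly with height
   (0.8→2.8 kPa, 26→32 °C) plus Gaussian noise; RH is back-computed so the
   Tetens derivation reproduces the VPD exactly.
3. **Physiology**: E[NPQt] = npq_max·PAR^n/(par50^n+PAR^n)·(1+β_V·VPD)·
   exp(species effect); E[qL] = ql_floor + (1−ql_floor)/(1+PAR/ql_par50)^m.
   Species effects are centered log-normal multipliers on NPQt; leaf-level
   noise is lognormal on NPQt and logit-Gaussian on qL.
4. **Signals**: (qL, NPQt) → (Fs, Fm′, Fo′) via the exact inverse model,
   then multiplicative Gaussian measurement noise (σ = 0.4%); a seeded 5% of
   rows is corrupted (Fs pushed above Fm′) to exercise QC.

**Season defaults.** The two seasons share the atmospheric profiles and the
canopy but differ in physiology:

| parameter | dry | wet | role |
|---|---|---|---|
| par_top (µmol m⁻² s⁻¹) | 2000 | 1400 | light ceiling |
| npq_max | 3.5 | 4.5 | NPQ capacity |
| par50 / hill n | 280 / 3.5 | 380 / 1.8 | NPQ induction |
| β_V (kPa⁻¹) | 0.02 | 0.06 | VPD sensitivity |
| ql_par50 / m / floor | 120 / 0.60 / 0.03 | 230 / 1.5 / 0.06 | qL decline |
| species sd | 0.20 | 0.15 | interspecific spread |

The dry season pairs a *weaker, sharply saturating* NPQ ceiling with a
*heavy-tailed* qL decline: once NPQt has saturated (PAR ≫ par50), qL keeps
falling, the denominator of ΦNO shrinks, and ΦNO rises again — the
high-stress phase emerges mechanistically, as it would from
photoinhibition-primed leaves. The wet season's gentler, later-saturating
NPQ and thin-tailed qL keep d(4.88·qL+NPQt)/dPAR positive beyond the first
crossing throughout its light range, so its ΦNO(PAR) curve has a single
maximum. Letting the response *shapes* differ by season (not only the
ceilings) was a deliberate design choice: with shared shapes, any
parameterisation that produces a detectable dry stress phase also drags a
spurious minimum into the wet season's range.

With these defaults the analytic curves give: dry ΦNO maximum at
PAR ≈ 141 (ΦPSII ≈ 0.705) and minimum at PAR ≈ 600 (ΦPSII ≈ 0.286); wet
maximum at PAR ≈ 160 (ΦPSII ≈ 0.561). Noise levels were set so that the
dry-season ΦNO–ΦPSII smoother explains ≈ 0.50 of deviance, the figure
reported for comparable field campaigns; the wet season comes out somewhat
cleaner (≈ 0.7) than real data. `analytic_breakpoints` exposes the exact
extrema (dense scan of the closed forms with interpolated zero crossings;
grid-edge flips are discarded) as the ground truth for end-to-end tests.

**What the generator does not emulate**: diurnal light cycles, leaf-age
dynamics, spatial autocorrelation within crowns, instrument drift, and any
radiative-transfer realism in the light field. Passing end-to-end tests
therefore demonstrate that the pipeline recovers the generating mechanism at
realistic noise — not that any particular field dataset follows it.

## Strata statistics

Profiles are simple 1-m bin means with Student-t confidence intervals (90%
default; undefined for singleton bins). Strata comparisons use
Kruskal–Wallis followed by pairwise two-sided Mann–Whitney U tests; pairwise
p-values are reported raw and Holm-adjusted, and the compact letter display
is built on the adjusted values at α = 0.05 by insert-and-absorb (split each
letter on every rejected pair, absorb subsets). Stratum boundaries are
half-open, assigned upward ([0,20), [20,40), [40,∞)); S1→S3 changes of the
yields are reported in percentage points (100·(mean_S3 − mean_S1)).

## Mixed and additive models

**Linear mixed models** (per yield × season, optionally per stratum):
response untransformed, predictors PAR/VPD/height z-scored so coefficients
are comparable across predictors; species random intercept via REML
(statsmodels MixedLM); singular fits fall back to OLS with a warning.
Significance is a 95% CI excluding zero. Variance partitioning follows
Nakagawa–Schielzeth: marginal R² = σ²_f/(σ²_f+σ²_α+σ²_ε) with σ²_f the
variance of the fixed-effect predictions; conditional R² adds σ²_α; their
difference is the interspecific share. Collinearity is screened with
VIF_j = 1/(1−R²_j).

**Additive mixed models**: beta likelihood on a logit link (yields live in
(0,1); boundary values are squeezed by y′ = (y(n−1)+0.5)/n with a warning),
one penalized smooth per predictor per season (basis dimension k = 5), a
season main effect, and a species random intercept. Seasonal contrasts are
pointwise differences of the two seasonal smooths on the link scale with
CI ±1.96·√(se²_dry+se²_wet); bands where the CI excludes zero are flagged
significant. Predictor contributions to explained deviance use all-subsets
hierarchical partitioning (the Shapley value over the 2^p subset fits, p ≤ 4),
so shares sum exactly to the full model's explained deviance; negative
averaged shares are floored at zero and the rest renormalized, with a
warning.

## The spline engine

No suitable penalized-GAM implementation with a beta likelihood exists in
the Python stack this package targets, so `leafquanta._gam` provides one:

- cubic B-spline bases, interior knots at covariate quantiles, sum-to-zero
  constraint absorbed by QR reparametrisation;
- exact curvature penalties ∫f″² (two-point Gauss quadrature per knot span,
  exact for cubics), rescaled to unit Frobenius norm so smoothing parameters
  are dimensionless;
- random intercepts as ridge-penalized dummy blocks — their smoothing
  parameter is the precision of the corresponding variance component;
- Gaussian (identity link, σ² profiled as RSS/(n−edf)) and beta (logit link,
  precision φ profiled by 1-D ML inside Fisher scoring with step halving)
  likelihoods;
- smoothness selected by the generalized Fellner–Schall update
  λ_j ← (rank_j − λ_j·tr(V S_j))/(β′S_jβ), iterated with the coefficient fit
  until the log smoothing parameters move < 3e-3 (λ clipped to [1e-9, 1e13]);
- per-term edf = tr(V X′WX) over the term's columns; AIC = −2ℓ + 2(edf+1);
  beta deviance explained computed against an intercept-only fit at the
  model's φ̂.

The engine reproduces mgcv's ML fits on shared data (cross-checked in the
test suite to 0.05 absolute on fitted curves) and shrinks genuinely linear
effects to edf ≈ 1.

## Phase analysis

The ΦNO-on-ΦPSII smoother is fitted per season under two knot policies —
restricted (k = 5) and unrestricted (k = 20) — and both AICs are reported;
the pipeline default follows the unrestricted policy, which wins the AIC
comparison on triphasic (dry-type) data. Breakpoints are sign changes of the
central-finite-difference derivative of the fitted curve on an even
1000-point grid spanning [P1, P99] of observed ΦPSII (edge percentiles
excluded to avoid boundary artifacts of penalized splines); derivative
magnitudes below 1e-6 count as zero; locations are linearly interpolated
zero crossings. Segments between breakpoints are labeled by slope: negative
at high ΦPSII → PQ-limited, positive → NPQ-limited, negative at low
ΦPSII → stress; with more than two breakpoints all are reported and labeled
by the same rule, with a warning. Near the low-ΦPSII edge the fitted
conditional mean can turn shallowly even when the generating curve does not
(asymmetric noise at extreme light); such extra breakpoints are reported,
not suppressed.

Each breakpoint's PAR value is obtained by inverting the same season's
fitted ΦPSII(PAR) smooth (k = 10; monotone decaying on canopy data) on a
2000-point grid — not by regressing PAR on ΦPSII — and its uncertainty is
the standard error over a seeded 200-draw bootstrap of the records,
refitting the smooth per draw. Breakpoints outside the fitted ΦPSII range
are flagged extrapolated and get no PAR value.

## Reproducibility and problem sizes

A single seed fans out to per-stage seeds by CRC-hashing stage names (all
below 2³¹). The default campaign (3 240 records) makes every stage run in
seconds; the end-to-end recovery checks use 20 seeded campaigns and the
mixed-model calibration 200 replicates on a reduced campaign (864 records
per season), sizes chosen to keep the full suite fast while leaving the
Monte-Carlo error well below the tolerances tested.

## Known limitations

- The beta GAMM treats φ as constant (no variance smooths) and random
  effects as intercepts only (no tree-level nesting or spatial structure).
- Fellner–Schall selection is ML-flavored; no REML option, no smoothing
  parameter uncertainty.
- The PAR mapping assumes the ΦPSII(PAR) smooth is effectively monotone
  over the observed range; it takes the first grid crossing otherwise.
- Hierarchical partitioning refits smooths per subset without the species
  random intercept, so its shares quantify the environmental smooths only.
- The stress phase in the generator is a stylized mechanism (NPQ saturation
  against continued center closure); real photoinhibition involves slow,
  history-dependent dynamics that steady-state measurements fold into a
  single snapshot.
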