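# Methods

This package analyses short-term prey-amendment microcosms in which a natural
community of heterotrophic nanoflagellates (HNFs) is fed a single bacterial
strain and followed for ~66 h. Four analysis stages are implemented —
biovolume calculus, growth kinetics, bacterivory budgets, and amplicon-vs-FISH
composition comparison — together with a synthetic-microcosm generator that
provides ground truth for validating every estimator.

## Biovolume calculus

Cells are approximated as prolate spheroids, V = (π/6)·L·W² (µm³), from
microscopy lengths and widths. Measurement tables do not guarantee axis
order, so pairs are re-oriented (larger dimension = length) before the volume
is computed. Community biovolume is abundance × mean cell volume.

Prey additions are *biovolume-equalised*: every strain is added at the same
biovolume, `factor` (default 10) times the ambient bacterial biovolume, so
per-strain cell concentrations scale inversely with strain cell volume. This
reconciles "ten-fold higher concentrations" with "equal initial biovolumes"
when strains span a ten-fold volume range: the factor applies to biovolume,
and cell counts follow.

The bundled strain table carries mean widths back-computed from published
mean volumes and lengths via W = √(6V/(πL)); the `width_source = derived`
column marks them as reconstructions, not measurements.

## Synthetic microcosm generator

The generator produces the data structures the estimators consume, with
known truth: replicated abundance time series, cell-measurement tables, FLB
(fluorescently labelled bacteria) tracer assays, amplicon read counts and
CARD-FISH hybridisation counts.

**Dynamics.** One prey pool B (cells ml⁻¹, mean cell volume V_B) and one
grazer pool H (V_H). Per-cell ingestion is the smaller of an encounter-
limited Holling type II term and a processing-limited (satiation) term:

    intake = min( i_max·B/(K+B),  µ_max·V_H/(gge·V_B) )

so prey consumption and predator biovolume production stay mutually
consistent with the gross growth efficiency at every instant — no prey is
killed without being used. The realised growth rate is
µ_eff = min(µ_max, gge·intake·V_B/V_H), zero before the lag. Prey change is
dB/dt = g·B − intake·H with bacterial growth g (default 0). The µ_max cap
together with prey depletion produces the observed plateau after the bloom
peak.

**Defaults** (one treatment): µ_max = 0.0806 h⁻¹ (doubling time 8.6 h, the
fastest observed response), lag 1 h, gge 0.33 (inside the observed
0.28–0.39 band), i_max = 25 bacteria HNF⁻¹ h⁻¹ and K = 10⁶ ml⁻¹ (cell-
specific rates near the measured 13.7 h⁻¹ at ambient abundances), H₀ =
5×10³ ml⁻¹, ambient bacteria 10⁶ ml⁻¹ at 0.1 µm³, prey strain 0.051 µm³,
HNF mean volume 5 µm³ (a ~3 µm cell), addition factor 10, observation CV
10 % (5 % in the recovery suite below). Sampling grid 0, 8, 16, 27, 40,
52, 66 h, mirroring the experimental 12–24 h intervals and the observed
peak near 27 h.

**Integration and noise.** Fixed step Δt = 0.05 h; bacteria advance by
explicit Euler (which keeps the cumulative-ingestion mass balance exact by
construction), HNFs by an exact exponential factor per step (which keeps a
log-linear fit of the latent trajectory unbiased). The system is smooth and
non-stiff at these rates. Observed counts are latent values times lognormal
noise with mean 1 and the stated CV — multiplicative counting error, the
dominant error of microscopy counts. Reads are multinomial with
probabilities ∝ cell fraction × rRNA copy factor; FISH counts are binomial
with p = cell fraction × probe efficiency. One master seed; each table uses
a crc32-derived child seed so tables regenerate independently.

**What the generator does not emulate:** predator mortality and the post-peak
HNF decline (trajectories plateau instead), cell-volume drift over the
bloom, aggregation/spatial structure, temperature effects, chimeras and
primer bias in reads (copy-number bias only), and probe cross-reactivity.
Passing recovery tests therefore demonstrate estimator correctness under
counting noise and depletion dynamics, not robustness to those unmodelled
features.

## Growth kinetics

`fit_exponential_window` implements the classical construction: the
steepest least-squares slope of ln(HNF) vs t over contiguous windows of at
least `min_points` (default 3) samples ending no later than the observed
maximum, gated at r² ≥ 0.95 (max-slope window flagged `degraded` if nothing
passes); ties prefer longer windows. Doubling time is ln 2/µ; the lag phase
is where the fitted line crosses the zero-time abundance, clamped at 0
(negative algebraic lags arise from noise only).

`summarize_growth` defaults to a pooled **segmented fit**: for the
replicates of one treatment jointly, ln N_r(t) = a_r + µ·clip(min(t, τ) −
λ, 0, ∞), i.e. flat during the lag λ, common slope µ, plateau after the
saturation time τ. Knots (λ, τ) are shared across replicates — they are
properties of the treatment's latent trajectory — profiled on a coarse grid
and refined by Nelder–Mead, with slopes and intercepts closed-form at each
knot pair. This uses the t₀ anchor and the plateau level that the windowed
rule discards, which matters on a 7-point grid: in simulation the windowed
estimator recovers µ within 5 % in only ~80 % of runs, the segmented fit in
~94 %. On noise-free data the two coincide. The windowed method remains
available (`method="window"`). Lag recovery is information-limited either
way: with a single pre-growth sample, the lag standard error is roughly
(counting CV)/µ divided by √replicates, ~0.6–0.7 h at µ = 0.05 h⁻¹ — close
to the 1 h tolerance used in validation.

Volumetric gross growth efficiency is the uncorrected quotient
GGE = ΔBV_HNF/(−ΔBV_bacteria) between t₀ and the HNF biovolume peak; no
correction is attempted for bacterial production inside the window, which
biases GGE when bacteria grow (documented, not corrected). In
`summarize_growth` the peak index is chosen on the replicate-mean biovolume
course: picking each replicate's own noisy maximum would select positive
noise excursions and bias GGE upward by several percent. Replicates are
estimated, then averaged (mean ± SD rows); DT·µ = ln 2 holds exactly on
replicate rows, while treatment rows average each parameter separately
(the mean of doubling times is reported, not ln 2 over the mean rate).

Relative growth rate anchors all treatments to the one with the largest
replicate-mean net HNF increase (its own peak minus t₀): each treatment
scores 100 × its net increase evaluated at the reference's peak time over
the reference's net increase; the reference scores exactly 100 and negative
scores clamp to 0. A net-increase ratio is used rather than a ratio of
fitted rates; both readings are defensible and the choice is recorded here.

## Bacterivory budgets

The community cell-specific uptake rate comes from short FLB incubations:
U = (tracer per cell / incubation) × (total prey / tracer prey). Group
rates are scaled from the community rate by food-vacuole content through a
single effective vacuole turnover k = U_community / vacuole_community
(h⁻¹) — the only rule consistent with all published budget cells
(13.7/2.9 ≈ 8.5/1.8). Total grazing rate is IGR × abundance × 24 (exactly
24 h per day); grazing impact is TGR / bacterial standing stock × 100.
Outputs carry full precision; a formatting layer rounds to the 1-decimal
reporting convention. The bundled T0 standing stock, 3.276×10⁶ ml⁻¹, is
back-solved from the community rate and the 54.2 % d⁻¹ removal — a
synthetic fixture value, since the ambient count at T0 is not published.
The published Cryptophyta IGR (14.8) differs from the vacuole-ratio value
(14.6) by ~1 %, consistent with rounded published inputs; tolerances in the
tests allow for this.

## Composition comparison and copy-number bias

Read fractions are counts restricted to the heterotrophic-flagellate groups
and renormalised; FISH fractions are hybridised over DAPI-inspected cells
with binomial standard errors (uncorrected for the general-probe detection
efficiency of 89.6 % unless requested — the published convention). The bias
table is log2(read fraction / FISH fraction) per shared group; zero entries
are floored at 0.5 pseudo-reads when a sequencing depth is supplied.
Copy-number factors are estimated as read/FISH ratios normalised to
geometric mean 1: factors are identifiable only up to a constant, and probe
efficiency differences between groups are confounded with copy number (as
in the underlying measurements — the estimate is a combined recovery
bias). Validation imprints a 40:1 copy ratio on two groups at 30/70 % of
cells and recovers the ratio within 15 % at depth 10⁵ and 10³ inspected
cells; with a 1.5 % rare group the binomial error of the FISH denominator
alone (~26 %) would swamp that tolerance, so the validation design uses
comfortably countable groups.

## Problem sizes

Validation suites use 200 simulated experiments (3 replicates, 7 time
points each) for growth recovery, depth 10⁵ reads and 10³ inspected cells
for composition recovery, and 10⁴–10⁵ cells for assay-level Monte-Carlo
checks — sizes at which Monte-Carlo error is small against every stated
tolerance.

## Known limitations

- The segmented growth model assumes a sharp growth-to-plateau transition;
  the latent transition is smooth over a few hours, a negligible misfit on
  a 12–24 h sampling grid.
- GGE is downward-biased by prey eaten during the lag (< 3 % at observed
  lags) and is undefined (flagged NaN) when bacteria do not decline.
- The generator's single-prey-pool bookkeeping counts ambient background
  bacteria at the strain's cell volume; drivers that mix strains of very
  different volume should pass a strain-equivalent background (see
  `analysis/01_simulate_microcosms.py`).
- Between-treatment significance testing (ANOVA/Tukey/t tests) is out of
  scope; standard statistical packages apply directly to the per-replicate
  output tables.
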