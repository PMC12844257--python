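# Methods

## Scope and model of the campaign

`clickscreen` models a combinatorial click-chemistry discovery campaign in
four computational stages:

1. **Virtual enumeration.** Products are built from three building-block
   sets — organic azides, terminal alkynes and carboxylic acids — by two
   sequential structural rewrites: a CuAAC cycloaddition that forms only
   the 1,4-disubstituted 1,2,3-triazole (the regiochemistry the copper
   catalyst enforces), then N-acylation of the primary sulfonamide carried
   by either the alkyne or the azide set, forming the acidic N-acyl
   sulfonamide `-S(=O)2-N(H)-C(=O)-` with loss of water. The theoretical
   space is the full factorial product of the set sizes.
2. **Synthesis tracking.** The synthesis success rate (SSR) is the
   percentage of planned wells that yielded an isolated product; the mean
   isolated yield averages over yield-reporting isolated members only.
3. **DSF screening.** Melting temperatures are extracted per well, shifts
   are computed against the per-plate control reference, and hits are
   called with a robust per-plate threshold.
4. **Dose–response confirmation.** Esterase kinetics are reduced to
   percent inhibition and fitted with a four-parameter logistic to give
   IC50 and Hill slope.

A synthetic-data module generates every input with planted ground truth,
so each stage is testable end to end without external data.

## Structural rewrites

Both transforms are RDKit reaction SMARTS applied to validated building
blocks. Validation enforces exactly one reactive group of the declared
role (azide on carbon, terminal alkyne, carboxylic acid), a single
connected fragment (salts and solvates are rejected), and at most one
primary sulfonamide. Polyfunctional blocks are rejected at validation
rather than enumerated over all sites: parallel synthesis presumes a
single reaction site, and rejecting up front avoids silently ambiguous
products. Equality is always judged on RDKit-canonical SMILES (the
toolkit default dialect), never raw strings; canonicalisation is
idempotent and tested as such.

Invariants checked on every emitted product: exactly one 1,2,3-triazole
ring, exactly one N-acyl sulfonamide, no residual azide / terminal alkyne
/ primary sulfonamide; CuAAC conserves heavy atoms; acylation loses
exactly one oxygen. Distinct index triples that collapse to the same
canonical product are emitted with a duplicate flag. Member labels follow
the `lib{i,j,k}` convention with 1-based, possibly non-contiguous labels;
planned lists reference labels, not positions.

## Robust hit calling

For each plate the compound shifts ΔTm (controls excluded) give

    MED = median(ΔTm),   RSD = c · median(|ΔTm − MED|),   c = 1.4826,

and a compound is a hit iff |ΔTm| ≥ MED + k·RSD **and** |ΔTm| ≥ floor,
with k = 3 and floor = 0.5 °C by default. The scaled MAD is the standard
robust standard-deviation estimator (c makes it consistent for the SD
under normality); because "robust standard deviation" admits other
estimators, c is a parameter. The floor is combined by AND — it is a
minimum meaningful shift, not an alternative threshold. The statistics
are computed on signed shifts by default; an `on_absolute` option
recomputes them on |ΔTm| for sensitivity analysis. When screening at
several concentrations, hits are called per run and a primary hit is any
compound flagged in at least one run. The reference Tm is the median of
usable control wells on the same plate; no cross-plate pooling.

## Tm extraction

Two methods:

- **boltzmann** (default): least-squares fit of the two-state sigmoid
  F(T) = base + amp / (1 + exp((Tm − T)/slope)), seeded from the
  derivative estimate, with Tm bounded to the ramp. Unusable when the
  amplitude-to-residual ratio falls below 3 or Tm pins to a boundary.
- **derivative**: maximum of dF/dT after Savitzky–Golay smoothing
  (window 7, order 3, configurable), refined by parabolic interpolation.
  Unusable when the peak sits on the grid boundary or its signal-to-noise
  (against a scaled-MAD baseline of the derivative) is below 6.

The sigmoid fit is the default because the derivative peak is limited by
the 0.5 °C ramp step and the smoothing window: at 2% amplitude noise its
worst-case error across 100 simulated wells is about 1 °C, versus about
0.1 °C for the fit. The derivative method remains useful as a fast,
model-free cross-check and as the fit initialiser.

## Dose–response

The titration is a geometric ladder `top/factor^(0..points−1)` (default
200 µM, 3-fold, 10 points — bottoming out at 0.010 µM). Initial rates are
least-squares slopes on the first 120 s window; percent inhibition is
100·(1 − (r − r_bg)/(r_ctrl − r_bg)), clamped to [−20, 120] with a flag.
The 4PL

    y = bottom + (top − bottom) / (1 + (IC50/x)^hill)

is fitted on pooled replicate points (mean-fit optional) with IC50 on the
log10 scale for conditioning, multi-start over Hill ∈ {0.5, 1, 2}, and
box bounds (top ∈ [0,150], bottom ∈ [−50,60], hill ∈ [0.1,10], log-IC50
within one decade of the tested range). A fit is reported converged only
when the response is dose-dependent (range ≥ 15 points **and** mean
inhibition at the top concentration ≥ 25%), the optimiser succeeded, and
the IC50 lies within the [min/10, max·10] guard band. The top-dose gate
matters: a flat titration read at realistic noise can otherwise be fitted
as a shallow curve with a nominally in-range IC50. Non-converged
compounds are reported qualitatively as "IC50 > top concentration". The
95% CI is the Wald interval on log-IC50; it is omitted when the
covariance is degenerate. Fits are exactly equivariant under
concentration-unit rescaling.

## Synthetic data

Generators are pure functions of an explicit seed (integer-indexed
`SeedSequence` streams per generator; no global RNG). Defaults encode the
campaign conditions the pipeline targets:

- **Building blocks** are drawn without replacement from pools built by
  decorating 15 ring scaffolds with 8 linkers (120 azides, 120 alkynes,
  120 acids, plus 14 sulfonamide-capped alkynes and 14 azido
  sulfonamides). The pools are constructed programmatically — nothing is
  shipped from a database — and every entry passes validation for its
  role.
- **Synthesis outcomes**: Bernoulli isolation at a true SSR of 75%,
  yields from a normal(56, 15) truncated to (0, 100].
- **Melt plates**: 8 controls plus 100 samples (5 planted at +3 °C, 10 at
  −2 °C, 85 nulls with N(0, 0.15²) jitter) on a 25–95 °C ramp in 0.5 °C
  steps; two-state sigmoids (amp 1, base 0.1, slope 1.2 °C) with 2%
  multiplicative Gaussian noise. An optional linear post-transition decay
  term emulates dye-aggregation droop (off by default), to stress-test
  extraction.
- **Dose kinetics**: linear 0–300 s traces (21 points) whose slopes follow
  the planted 4PL between a control rate of 2×10⁻³ AU/s and a background
  of 10⁻⁴ AU/s; per-point absorbance noise is scaled so a rate fitted on
  the 120 s window has an sd of 5% of the control window, i.e.
  percent-inhibition noise of ≈5 points at n = 4 replicates.

What the generators deliberately do not emulate: plate-position (edge)
effects, dye artefacts and multi-transition unfolding, substrate
depletion and product inhibition in the kinetics, and any structure–
activity relationship (hit identity is planted, not predicted). Passing
tests therefore demonstrate correctness of the analysis pipeline under
its stated noise model, not robustness to every pathology of real plates.

## Problem sizes used in checks

The recovery simulations use 100 seeds for Tm extraction (2% noise) and
50 seeds per planted potency {0.2, 1.1, 6.07, 8.74} µM for IC50 recovery
(5% noise, quadruplicate), one 100-sample planted plate for hit calling,
and ≥500 random building-block triples for the chemistry invariants.
These sizes give stable medians and run in seconds on one CPU.

## Known limitations

- The enumeration is structural only: no feasibility, yield or purity
  prediction, no stereochemistry beyond the input SMILES.
- Acylation targets the primary sulfonamide exclusively; building blocks
  containing other acylatable N–H are outside the validated input space.
- The derivative Tm method's precision is bounded by the ramp step.
- The Wald CI on log-IC50 undercovers slightly for potencies near the
  ladder edges; simulated coverage at mid-ladder potency is ≈93%.
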