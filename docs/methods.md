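# Methods

`spadspec` estimates relative chlorophyll content (SPAD, the unitless
reading of a transmittance-based leaf meter) from canopy hyperspectral
reflectance in 400–1000 nm. The analysis chain is: fractional-order
differentiation of the spectra, correlation screening of single
differentiated bands and of exhaustive two-band differential spectral
indices, and kernel regression with metaheuristic hyperparameter tuning.
This note records the model, the parameters that matter, and the design
choices made where the method left them open.

## Fractional-order differentiation

The Grünwald–Letnikov (GL) derivative of order α generalises the discrete
difference operator: at band t,

    D^α f[t] = Σ_{k=0}^{min(t, w)} c_k · f[t−k],
    c_0 = 1,  c_k = c_{k−1} · (k − 1 − α) / k  =  (−1)^k · C(α, k),

so α = 0 is the identity and α = 1 the backward first difference.
Intermediate orders trade the noise amplification of integer
differentiation against its baseline-removal power, which is why a sweep
of α ∈ {0.0, 0.1, …, 1.0} (the default) is screened rather than a single
order.

Numerical choices:

* **Weights by multiplicative recursion**, not direct Gamma ratios: the
  recursion is exact in floating point at any k while Γ(k−α) overflows
  near k ≈ 170. Equivalence with the Gamma form is unit-tested to 1e−10.
* **No h^−α step scaling by default.** The band index is the unit step, as
  is conventional when differentiated spectra are only ever compared at a
  common α. The optional `scale_by_step` flag multiplies by h^−α, which
  makes the operator converge to the analytic fractional derivative (the
  x² test verifies 2 % relative accuracy at h = 0.01).
* **Full-history window by default**; a finite window is available for
  speed. The left edge of a finite spectrum truncates the GL history, so
  the first `edge_trim` bands (default 30, ≈ 6.6 nm at 0.22 nm spacing;
  equal to the window when one is set) are retained in the arrays but
  excluded from every screening stage. Trimming instead of dropping keeps
  wavelength registration intact.
* Integer orders truncate the kernel to its exact short form, so α = 0 and
  α = 1 are bit-exact identity and first difference.

## Preprocessing: SNV and SPA

SNV maps each spectrum x to (x − mean(x)) / sd(x) with the n−1 denominator,
removing per-sample multiplicative scatter. Constant spectra are rejected
rather than silently zeroed.

The successive projections algorithm (SPA) picks minimally collinear
wavelengths: from each candidate starting band a chain grows by appending
the band whose column has the largest norm after projection onto the
orthogonal complement of the selected columns. Every chain prefix with
size in `[size_min, size_max]` (default 5–40) is scored by k-fold
cross-validated RMSE of an ordinary least-squares fit with intercept
(default 5 folds, seeded shuffle), and the subset size is the global RMSE
minimum, first minimum on ties. The method's sources state only an
"RMSE-minimum" sizing rule; OLS + k-fold CV is this package's concrete
choice, and the response is passed explicitly (the pipeline passes SPAD).
SPA runs on SNV-corrected reflectance by default (`spa_on_snv`).

## Two-band differential spectral indices

Three index families combine two differentiated bands R_i^α, R_j^α
(i ≠ j):

    FDI  = R_i^α − R_j^α          (difference)
    FRI  = R_i^α / R_j^α          (ratio)
    FNDI = (R_i^α − R_j^α) / (R_i^α + R_j^α)   (normalized difference)

Some literature lists a fourth label, "FSI", without defining it; by band
matching it is the ratio index, and this package treats it as FRI.

For each (kind, α) the exhaustive ordered-pair grid of Pearson
correlations with SPAD is computed. Differentiated spectra can be
negative, so FRI and FNDI denominators can vanish; affected samples are
**masked** (excluded pairwise) rather than epsilon-jittered — jitter would
corrupt r invisibly. A pair is invalid (NaN) when more than 20 % of
samples are masked, fewer than 3 survive, or the index is constant.

* **Grid resolution.** Maps run on a regular resampled grid (default 2 nm,
  nearest native band, ≈ 300 bands → 90 000 pairs per map) rather than the
  native 0.22 nm grid (≈ 7.3 M pairs per map). The native search is
  feasible but slow and adds nothing on smooth synthetic spectra; the step
  is configurable (`resample_step_nm`).
* **Orientation.** FDI and FNDI maps are antisymmetric under (i, j) swap,
  so only one orientation per unordered pair is reported: the one with
  r ≥ 0 (band_i < band_j when r = 0). FRI is not antisymmetric in r
  (swapped pairs hold reciprocal values), so both orientations remain
  candidates.
* Ranking is by |r| descending with deterministic ties (smaller band_i,
  then band_j).

## Screening and feature ranking

Per order, the band maximising |r| with SPAD over the edge-trimmed grid is
extracted (signed r preserved; significance stars from the two-sided
t-test: `**` p < 0.01, `*` p < 0.05). The single-band screen searches the
full grid per order, not only the SPA-selected set; the SPA table is
reported separately. Single-band and index features are merged into one
|r|-ranked list — the order in which they enter the models.

## Slime mold algorithm (SMA)

Bound-constrained continuous minimiser. Per iteration t of T: evaluate the
population, sort by fitness ("smell index"), then each individual moves by
one of

* uniform restart in the box, with probability z (default 0.03);
* x_b + v_b·(w·x_A − x_B) when rand < p = tanh|s(i) − DF|, with
  v_b ~ U(−a, a), a = arctanh(1 − t/T), A, B random individuals;
* contraction v_c·x otherwise, v_c ~ U(−b, b), b = 1 − t/T.

The rank weights are w = 1 ± r·log10((bF − s)/(bF − wF) + 1), plus branch
for the better-ranked half. DF is the elitist best-so-far, so its trace is
monotone non-increasing by construction. Positions are repaired by
clipping to the box. The arctanh argument is clamped to ±(1 − 1e−12) and
the log ratio to [0, 1] to guard the t = T and bF ≈ wF degeneracies. The
final population is evaluated once more so the last update is not wasted.
Some printed statements of SMA garble the weight equation (a duplicated
fraction) and describe v_c only as "decreasing from 1 to 0"; this
implementation follows the algorithm's standard published form
(symmetric-uniform v_c with a linearly decaying envelope).

## LSSVM regression and tuning

The least-squares SVM with RBF kernel K(x, x′) = exp(−‖x − x′‖²/σ²) trains
by solving one KKT system

    [0  1ᵀ; 1  K + I/γ] [b; a] = [0; y],

predicting ŷ(x) = Σ a_k K(x, x_k) + b. γ > 0 is the penalty (inverse ridge)
and σ² > 0 the squared kernel width. Features are standardized by
training-split statistics only (leakage prevention); the scaler travels
with the model, making predictions invariant to affine rescaling of raw
features. The solve is verified to a 1e−8 sup-norm residual; singular
systems raise instead of being jittered.

SMA tunes (log10 γ, log10 σ²) in the box [−2, 6] × [−3, 4] (scale-free for
the optimizer) against held-out RMSE, default population 20 and 40
iterations; the final model refits on the training split at the optimum.

Two R² variants are reported side by side: the standard mean-centred form
and an uncentred form 1 − Σe²/Σy², which some reports print; the uncentred
denominator is larger whenever mean(y) ≠ 0, so that variant is never
smaller. Model comparison in this package always uses held-out RMSE and
the standard R².

## Pipeline

Stages run in the order: load/generate → SNV + SPA table → fractional
differentiation → single-band screen → index maps → model grid → report.
The experiment grid fits, on one shared seeded 75/25 split (train fraction
0.75, floor on the training size), top-{3,4,5} single-band cells,
top-{7,8,9} index cells, and one fusion cell — the best single cell's
features plus the best index cell's features, "best" judged by the
SMA-LSSVM held-out RMSE (no selection rule is canonical; this one is
deterministic and matches how the cells are compared overall). Each cell
is fit by a fixed-hyperparameter LSSVM (γ = 100, σ² = 1) and an SMA-tuned
LSSVM.

Per-stage seeds derive from the master seed by hashing the stage name
(`sha256("{seed}:{stage}")`, truncated below 2³¹), so adding a stage never
perturbs earlier stages' streams. Reports (four CSV tables + JSON) are
byte-deterministic for a fixed config and master seed; every artifact
carries the config hash.

## Synthetic data

The generator is phenomenological, not radiative transfer: a smooth
visible baseline with a green bump at 550 nm, SPAD-scaled Gaussian
absorption troughs at 450 nm (depth 0.02 + 0.055·u) and 670 nm
(0.03 + 0.06·u) with u = SPAD/50, a logistic red edge inflecting at
712 + 10·u nm (width 9 nm), a NIR plateau 0.40 + 0.10·u, and additive
Gaussian noise (default sd 0.002). Defaults emulate the reference
conditions: 46 samples, 400–1000 nm at 0.22 nm (2728 bands), SPAD uniform
on [26.8, 46.9]. SPAD is drawn uniformly (only range statistics are
reported for the field data it emulates), and the seed splits into
independent SPAD and noise streams.

What it reproduces: the correlation sign structure (negative in the blue
and red troughs, positive on the NIR plateau and red edge) and a smooth,
injective SPAD→spectrum link. What it does not: instrument artifacts,
water-vapour features, canopy geometry/scatter variation, cultivar
effects, vertical-layer structure, or realistic band-to-band noise
correlation. Passing tests therefore demonstrate that the pipeline
recovers planted chlorophyll-like structure and that its statistics are
correct — not that its accuracy numbers transfer to field spectra, where
correlations are far weaker than on this generator.

## Problem sizes used by the test suite and acceptance script

Unit tests run on coarse grids (2–5 nm, 46–150 samples); the end-to-end
checks and the acceptance script use the reference synthetic dataset
(n = 200 samples at the native 0.22 nm grid) with 2 nm index maps — large
enough for stable correlation screening at the generator's noise level,
small enough to run on a laptop-class single core in about half a minute.

## Known limitations

* SPA's validation scheme (OLS + k-fold CV) and the fusion rule are this
  package's choices; other defensible variants exist.
* The exhaustive pair search reports raw Pearson r with no
  multiple-testing correction, by design — the screen feeds a model
  comparison, not an inference.
* On near-noiseless synthetic data many band pairs are nearly collinear,
  so the specific top-ranked pair is sensitive to the noise realization
  even though its |r| is stable.
* The uncentred R² can approach 1 for any predictor whose errors are small
  relative to Σy²; it is reported for comparability but never used for
  selection.
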