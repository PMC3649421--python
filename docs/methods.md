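# Methods

This note documents the models implemented in `leafspec`, the synthetic data
they are validated on, and the numerical and design choices made where the
underlying method description left the details open.

## Spectral preprocessing

Handheld Vis/NIR spectroradiometers are noisy at the extremes of their
sensitivity range, so the first and last 75 channels of the 325–1075 nm,
1-nm-step grid are discarded, leaving 601 channels over 400–1000 nm.
Smoothing uses the Savitzky–Golay filter — a sliding least-squares polynomial
fit — with window 7 (half-width 3) and polynomial order 2. The order is not
part of the original protocol; 2 is the customary choice for a 7-point window
and is exposed in `PreprocessConfig`. Edge points are produced by refitting
the polynomial on the truncated asymmetric window rather than by padding,
which keeps output length equal to input length without fabricating data.
Derivative filters (orders 1–2) are implemented and exposed, with output
scaled per nm (index-domain derivative divided by stepᵈ); they are not
applied before modelling by default, since the calibration models operate on
smoothed reflectance. A log₁₀(1/R) pseudo-absorbance transform is available
as an option (`absorbance=True`) but reflectance is the default input.

## PCA and PLS

PCA is the SVD of the column-mean-centred spectra matrix; loadings are
orthonormal, explained-variance fractions are relative to the total centred
variance. PLS1 uses classical NIPALS deflation for a single response, which
is the natural variant for per-element calibration. The latent-variable count
is selected by leave-one-out cross-validation (the deterministic reading of
"full cross-validation"), minimising PRESS with the smallest count winning
ties. Component sign indeterminacy in both decompositions is fixed by making
the largest-magnitude loading/weight element positive, so results do not
depend on BLAS build or sample order. Inputs are centred but not autoscaled
by default (reflectance channels share units and comparable variance);
autoscaling, where wanted, can be applied upstream.

## FastICA and sensitive wavelengths

The noise-free ICA model treats the N preprocessed spectra as mixtures
x = A·s of m independent wavelength-domain sources. Estimation: centre each
spectrum, whiten through the eigen-decomposition of the N×N sample
covariance retaining m directions, then run the symmetric fixed-point
iteration with the tanh contrast (cubic optional) from a seeded random
orthogonal start until the update aligns with the previous rotation to
within `tol` (default 1e-6, max 1000 iterations). Non-convergence is a
recorded warning, not an error, because a non-converged rotation of a
whitened basis is still a usable (if less independent) decomposition. ICA
has no inherent component order or sign; components are ordered by the data
variance they explain (squared mixing-column norm) and sign-fixed by the
largest-source-value-positive rule, which makes "the first m components"
well defined.

Sensitive wavelengths are selected from the source pseudo-spectra s(λ), not
the mixing matrix, because the sources are what exhibit the band peaks and
valleys of the spectra. The one-sentence selection rule ("the wavelengths
with the highest weights of each IC") is made algorithmic as follows: for
each of the first `n_ics_used` (default 4) components, locate the local
extrema of |s(λ)|; pool all extrema; keep candidates greedily by descending
magnitude subject to a pairwise separation of at least 10 nm; stop at
`n_sws` (default 6); finally, if some used component is unrepresented and a
feasible swap exists, exchange the weakest over-represented selection for
that component's best candidate. Because the source estimates inherit
per-channel noise, each pseudo-spectrum is lightly smoothed (7-point
quadratic local fit) before extremum location; without this, one noisy band
fragments into several micro-extrema and the cluster maximum can sit several
nm off the band centre. The 10-nm separation and the one-per-component
guarantee turn the selection into a deterministic algorithm while still
allowing near-neighbour selections from distinct bands.

By default ICA (like every feature extractor) is fitted on the calibration
split only, so no validation information leaks into wavelength selection;
`fit_on="all"` reproduces the older practice of fitting on the pooled data.

## LS-SVM regression

With kernel matrix Ω and regularisation γ, training solves the symmetric
(N+1)×(N+1) system [[0, 1ᵀ], [1, Ω + I/γ]]·[b; α] = [0; y]; the predictor is
y(x) = Σ αₖK(x, xₖ) + b. The RBF kernel uses the exp(−‖u−v‖²/σ²) convention
(no factor 2), consistent with the customary `sig2` parameterisation; a
linear kernel exists for closed-form cross-checks. Features are standardised
by calibration statistics before kerneling because a single σ² is shared
across feature columns of very different scales (PC scores next to raw
reflectances). The solver verifies its own residual (∞-norm ≤ 1e-6) and the
Σα = 0 KKT condition.

Hyperparameters are tuned by a two-stage grid search minimising RMSECV:
stage 1 on an integer-log₂ grid over γ ∈ [2⁻¹, 2¹⁰] and σ² ∈ [2, 2¹⁵];
stage 2 at log₂ step 0.25 within one crude step of the stage-1 optimum
(which the refined grid therefore contains, so refinement can never be
worse). The step sizes implement the "large step, then small step"
prescription; cross-validation is seeded 10-fold with fold assignment fixed
across all grid points so that grid values are comparable.

## Evaluation metrics

RMSEC/RMSEP = √(Σ(ŷᵢ−yᵢ)²/Iₚ) and bias = Σ(ŷᵢ−yᵢ)/Iₚ, in ppm. R² is the
squared Pearson correlation between predicted and measured values — the
predicted-vs-reference scatter convention — with the 1 − SSE/SST variant
available (`kind="explained"`). Model comparison tables sort by ascending
RMSE with ties broken alphabetically.

## Synthetic study conditions

The generator emulates the structure of leaf reflectance on the instrument's
grid: a 0.10 visible plateau, a green peak at 570 nm (+0.05, sd 10 nm), a
logistic red edge centred at 715 nm rising to a per-sample NIR plateau drawn
uniformly from 0.30–0.70 (the observed spread across leaves), and a water
dip at 960 nm proportional to the plateau. Concentrations are uniform over
the published ranges (Fe 39.951–134.254 ppm, Zn 9.085–49.927 ppm; 90 samples,
70/20 split).

The concentration signal is additive Gaussian absorption at 560, 680 and
960 nm. All three bands share one sensitivity (2×10⁻³ reflectance per ppm):
a single physiological driver (element status acting through pigment and
water content) moves all bands together, making the signal a rank-one
spectral pattern. The raw depth g·c passes through the saturating link
f(d) = (1 − e^{−νd})/ν with ν = 10, chosen so that the response bends
appreciably across the Fe range (ν·g·c from ≈0.8 to ≈2.7) without fully
saturating. This matters for the package's central comparison: with equal
gains the concentration→spectrum link is genuinely one-dimensional and
nonlinear, which is the regime that separates a nonlinear LS-SVM from linear
PLS. (With unequal gains the bands form several saturating curves of
different rates, and a linear model can combine them to linearize the link —
an artefact of the simulation, not a property of real leaves.) i.i.d.
Gaussian channel noise has sd 0.002 reflectance, reflecting the ~10-scan
instrument averaging typical of field protocols. The identical-baseline
degenerate case (no noise, zero gains, zero plateau spread) is exposed via
`plateau_spread=0`.

What the generator does **not** emulate: radiative-transfer physics
(PROSPECT-style), instrument dark current and white-reference drift,
wavelength-correlated noise, the nitrogen-treatment block structure of a
real field design, and replicate-scan averaging. Passing tests therefore
demonstrate the correctness and internal consistency of the algorithms and
the expected qualitative behaviour (e.g. the nonlinear SW model beating
full-spectrum PLS under a saturating link), not field performance on real
leaves.

## Problem sizes and determinism

Default test and acceptance runs use the study-scale conditions: 90 samples
× 751 channels, 70/20 split, 20-seed replications for cross-model ordering,
50-seed replications for wavelength localization. All randomness flows from
explicit integer seeds through `numpy.random.default_rng`; identical
configurations are bit-reproducible.

## Known limitations

* Symmetric FastICA on data whose true source count is below `n_components`
  leaves the surplus components fitting noise; they are last in the
  variance ordering but still contribute SW candidates (mitigated by the
  per-component swap rule, and flagged by near-zero explained variance).
* LOO-PRESS refits the full NIPALS path once per left-out sample (O(N)
  fits); fine at N ≤ a few hundred, not tuned for large N.
* The grid search re-solves the dual system per fold per grid point rather
  than caching kernel blocks; adequate at the method's N but quadratic in
  grid resolution.
* `predict_from_artifact` requires new spectra on the training wavelength
  grid; no resampling/interpolation is attempted.
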