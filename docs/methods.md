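# Methods

## Problem setting

The pipeline predicts the Trolox equivalent antioxidant capacity (TEAC,
µmol Trolox/g dry mass) of sprouted cruciferous seed extracts from six
composition variables — total phenolics (TP), inositol hexaphosphate (IP6),
glucosinolates (GLS), soluble proteins (PROT), ascorbic acid (AA) and total
tocopherols (TTOT). The reference laboratory database (172 samples) is not
publicly available, so the package pairs the modelling code with a
synthetic generator that reproduces the statistical features the analysis
depends on: the marginal feature–target correlations and the attainable
goodness of fit.

## Synthetic data generator

Let ρ ∈ (−1, 1)^d be the requested feature–target correlations and
R²max ∈ (0, 1] the requested population coefficient of determination of the
target on the features. With loadings λᵢ = ρᵢ/√R²max (validated to lie in
(−1, 1)), one latent antioxidant-activity factor z ~ N(0, 1), d−1 shared
noise factors u ~ N(0, I) and target noise η ~ N(0, 1):

    fᵢ = λᵢ z + √(1−λᵢ²) · gᵢᵀu          (standardized feature i)
    y  = √R²max · z + √(1−R²max) · η     (standardized target)

where gᵢ is the i-th coordinate unit vector for i < d and the flat unit
vector (1,…,1)/√(d−1) for the last feature. Every feature has unit variance
and corr(fᵢ, y) = λᵢ√R²max = ρᵢ exactly. Because the noise occupies only a
rank-(d−1) subspace, a linear combination of the features cancels it and
recovers z exactly, so for generic loadings the population OLS R² of y on
the features equals R²max exactly. A full-rank independent-noise factor
model cannot do this: with independent per-feature noises the explainable
variance is pinned at R²max·λᵀΣ⁻¹λ (≈ 0.76 for the defaults), well below
the fit quality the study conditions require, which is why the noise is
shared. Features and target are affinely rescaled to the configured means
and spreads at the end, which leaves correlations and R² untouched.

Defaults. n = 172 samples. ρ(GLS) = −0.85 and ρ(TTOT) = +0.26 are the two
published relevancy factors; the remaining four inputs are only known to be
negative and are set to TP −0.45, IP6 −0.35, PROT −0.40, AA −0.25 —
package choices, documented as such. R²max = 0.980 leaves headroom above
the headline total R² of 0.973 so a well-tuned model can reach it while an
under-parameterized one cannot. The target scale (mean 50, sd 21.8 µmol
Trolox/g d.m.) is chosen so that at R² ≈ 0.973 the residual spread
21.8·√(1−0.973) ≈ 3.6 matches the reported RMSE magnitude; feature scales
are arbitrary plausible concentrations. Gaussian tails are accepted (no
truncation at zero) to keep the correlation algebra exact — a documented
fidelity trade-off against real, strictly positive concentrations.

What the generator does **not** emulate: the real measurements' units,
skewness, detection limits, replicate structure, or any nonlinear
feature–target relationships. Passing tests therefore demonstrate that the
pipeline recovers the structure this generator encodes, not that the model
generalizes to laboratory data.

## Preprocessing

Every column (features and target) is min–max normalized to [−1, +1],
x′ = 2(x − min)/(max − min) − 1. Extrema are fitted on the full dataset by
default — matching a workflow that normalizes before splitting — with a
train-only scope available to avoid leakage in non-replication use. The
target is normalized for training and predictions are denormalized before
any metric, so all reported errors are on the physical TEAC scale. Values
outside the fitted range map outside [−1, 1] (affine, not clipped);
constant columns raise an error rather than being silently imputed. The
split draws round(0.75·n) training rows uniformly at random with a recorded
seed — 129/43 at n = 172.

## ELM core

Hidden weights and biases are i.i.d. uniform on [−1, 1]; activations
registered: logistic sigmoid (default — the activation is otherwise a free
choice, and the sigmoid is the classic one), tanh, linear. Output weights
solve A α ≈ y: with ridge λ = 0 the minimum-norm least-squares
(Moore–Penrose) solution via `numpy.linalg.lstsq`; by default a tiny ridge
λ = 1e−8 solves the regularized normal equations instead, which keeps
near-singular hidden matrices stable inside the swarm loop without
measurably biasing well-conditioned fits. The implicit ELM kernel
k(xᵢ, xⱼ) = h(xᵢ)·h(xⱼ) is provided as a verified utility; a full
kernel-ELM training path is out of scope.

## PSO and the hybrid trainer

Global-best PSO with inertia w = 0.729 and c₁ = c₂ = 1.49445
(constriction-equivalent values), 30 particles, 200 iterations. One
independent uniform(0, 1) draw per dimension per attraction term (the
standard choice where the update rule is ambiguous). Initial positions are
uniform in the search box, initial velocities zero (avoids an extra
distribution choice). Positions are clipped to the box and the clipped
velocity component zeroed. Non-finite fitness values become +∞ with a
logged warning. The incumbent global best is monotone by construction. An
optional early stop (improvement < 1e−10 over 30 iterations) exists but is
off by default so a run is exactly its iteration budget.

The trainer searches the ELM's input weights and hidden biases — flattened
row-major, weights before biases, D = H(d+1) = 84 dimensions for H = 12,
d = 6 — inside the [−1, 1] box matching the random-initialization support.
H = 12 is the package default: twice the input width, large enough to track
the mildly nonlinear normalized response, small enough to keep the swarm
dimension modest; H is deliberately not searched. Output weights stay
analytic inside every fitness evaluation; the fitness is the
training-partition RMSE on the normalized scale (an optional k-fold
cross-validated fitness is available, off by default for the simplest
reading of the procedure). Test rows never enter the fitness — verified
bitwise in the tests.

## Diagnostics

* Five statistics per phase (train/test/total), all on the TEAC scale:
  R² = 1 − SSres/SStot (the coefficient of determination, not squared
  Pearson — they differ for biased predictors), MRE % = (100/n)Σ|y−ŷ|/|y|,
  MSE, RMSE = √MSE, and STD = sample standard deviation of the *absolute*
  errors. The absolute-error convention is the one consistent with STD
  falling below RMSE (std(|e|)² = rmse² − mae²); STD of signed residuals
  would essentially equal the RMSE. MRE and the per-sample relative
  deviations are undefined at an actual value of exactly zero and raise.
* Williams plot: design = normalized features + intercept fitted on the
  training rows; leverage of any row x is x(XᵀX)⁻¹xᵀ; warning leverage
  h\* = 3(p+1)/n_train (the standard QSAR formula — the source analysis
  names but never defines it); standardized residual = residual / phase
  RMSE (the common Williams-plot convention; leverage-adjusted
  studentization is noted but not used). Flags: high leverage, residual
  outlier (|r| > 3), both, or in-domain.
* Relevancy factor: Pearson correlation of each raw feature with the raw
  target; matching the signed-bar semantics of the published sensitivity
  analysis.

## Pipeline and seeding

`run_pipeline` fans one master seed into stage seeds (generation, split,
swarm) through numpy's `SeedSequence`, so a single integer reproduces the
run bit for bit; stage failures abort with the stage name and remove
partial outputs. Artifacts are flat text files (CSV tables ready for
plotting, JSON model and report with sorted keys); figure rendering is out
of scope.

## Problem sizes and numerical choices

The study-size runs use n = 172 throughout; generator-calibration checks
use 50,000-row draws, where a Pearson estimate of r = −0.85 has a sampling
sd ≈ 0.0012 and the ±0.02 test band is wide. At n = 172 a single
correlation estimate has sd ≈ (1−r²)/√172 ≈ 0.07 for the weaker factor, so
the study-size calibration check bounds the across-seed mean of five draws
rather than each draw. Reduced swarm budgets (10–15 particles, 25–60
iterations) are used in unit tests where only structural properties are
asserted; the headline fit checks always run the full 30 × 200 budget.
Tolerances: exact algebraic identities at 1e−10…1e−12; Moore–Penrose
interpolation at 1e−6 (sigmoid saturation limits attainable residuals);
Monte-Carlo checks at 2–3 sampling standard deviations.

## Known limitations

* The generator is linear-Gaussian; the tuned ELM's advantage over plain
  OLS on such data is modest, and the pipeline's fit quality on it says
  nothing about nonlinear composition–TEAC chemistry.
* Concentrations can be negative in extreme tails (no truncation).
* The 75/25 split is random; whether the original partition was random or
  ordered is unknown, so replication of its exact membership is impossible.
* With full-dataset normalization scope, test-row extrema influence the
  scaling (fidelity choice); use the train scope for leakage-free practice.
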