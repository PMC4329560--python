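# Methods

## The biokinetic model

`asmcal` implements an extended Activated Sludge Model No. 3 (ASM3) with
two-step nitrification and denitrification, in the Kaelin-type
"hydrolysis – storage – growth – respiration" frame. The state has 14
components: dissolved oxygen S_O2, inert and readily biodegradable soluble
COD (S_I, S_S), the nitrogen species S_NH4, S_NO2, S_NO3, S_N2, alkalinity
S_ALK (mol HCO₃⁻ m⁻³), and the particulate pools X_I, X_S, X_H (heterotrophs),
X_STO (internal storage), X_AOB and X_NOB (the two nitrifier guilds).
Seventeen processes cover hydrolysis; aerobic/anoxic (NO₃ and NO₂ routes)
storage of S_S; aerobic/anoxic heterotrophic growth on X_STO; endogenous
respiration of X_H and X_STO under O₂ and NO₃; AOB and NOB growth; and
aerobic/anoxic decay of both nitrifier guilds. Forty parameters (composition
fractions, six storage/growth yields, two autotroph yields, rate constants,
decay rates, anoxic reduction factors, and half-saturation/inhibition
constants) carry defaults and box bounds in the model-definition file
`src/asmcal/data/asm3_2step.yaml`.

The model is data, not code: components declare their conservation weights
(COD as ThOD with the NH₄ reference — NO₂-N counts −48/14, NO₃-N −64/14,
N₂-N −24/14 g COD per g N; charge +1/14 eq per g NH₄-N, −1/14 for NO₂/NO₃,
−1 per mol alkalinity), and every stoichiometric entry is written out
explicitly. Loading the file checks each process row against all three
balances, so any transcription error in a yield or composition coefficient
is caught mechanically (residuals are ~1e-14 for valid parameters, and the
error message names the process and the balance). Rate laws are declared
as products of named switching functions (Monod `S/(K+S)`, inhibition
`K/(K+S)`, ratio-Monod on X_STO/X_H and X_S/X_H, first-order biomass terms)
and compiled at load time into a single jitted function; the declarative
form doubles as the ground truth against which tests recompose every rate.

Two composition choices are forced by the 40-parameter budget: X_S carries
the same nitrogen content as S_S (hydrolysis releases no NH₄) and S_I
carries none. Both are conventional simplifications; the first makes the
hydrolysis row close its N balance exactly.

Negative-state protection follows standard ASM practice: rates are
evaluated on max(state, 0), which keeps the right-hand side smooth when
the stiff integrator undershoots zero; stored trajectories are floored at
zero. Dissolved oxygen is a forcing input (zero-order hold between
samples): its state is substituted algebraically in the rate evaluation
and its derivative set to zero. The measured COD observable is filtered
COD (S_S + S_I), configurable to include particulate pools.

## Scenario engines

The SBR engine integrates each phase of a cycle separately (LSODA,
rtol 1e-6, atol 1e-8) and stitches them: feeding is continuous inflow over
the stated duration (dC/dt gains Q/V(t)·(C_in − C) with V(t) linear);
aerobic phases force DO at the setpoint; anoxic, settle and idle phases run
at DO = 0. Reactions continue through settling (an unmixed-blanket
approximation — denitrification on storage demonstrably proceeds there;
switch off per phase with `react: false`). Decanting removes particle-free
supernatant at the end of the phase: soluble concentrations are unchanged,
particulate mass is conserved, so particulate concentrations scale by
V_pre/V_post on the reduced volume. Volume bookkeeping is exact over any
number of cycles and checked every cycle.

The CSTR engine lumps the clarifier into the reactor: solubles wash out at
the dilution rate Q/V, particulates at 1/SRT. This captures SRT control by
sludge wasting without a settling-velocity model, which the data being
emulated cannot identify anyway.

## Sensitivity analysis (DGSM)

The relative time-varying sensitivity of observable i to parameter j is

    s_ij(t) = (∂y_i(t)/∂θ_j) · θ_j / sc_i,

computed by central finite differences with relative step h (default 1e-3;
on simulation failure the step is halved up to three times before the
sample is discarded). The per-observable scale sc_i is the maximum of
|y_i| over the output grid at the unperturbed point — a trajectory scale,
chosen because nitrite and nitrate cross zero within SBR cycles and a
pointwise relative normalisation diverges there.

The global measure averages the squared sensitivities over a Sobol
low-discrepancy sample of the parameter box (mean over time, weighted sum
over observables, mean over samples), and the reported index takes the
square root and normalises:

    ν_j = E_box[ Σ_i w_i · mean_t s_ij(t)² ],    I_j = √ν_j / Σ_k √ν_k.

The squared-mean (ν-measure) form follows the DGSM literature and is
numerically stable; a config switch selects mean-absolute averaging
instead. Indices are non-negative and sum to one. The convergence
diagnostic is the largest index discrepancy between the two half-samples;
it is reported, not enforced. Because the Sobol dimensions are not
exchange-symmetric, permuting the parameter list reproduces indices only
to quasi-Monte-Carlo accuracy, not bit-exactly.

## Correlation analysis

At each Sobol point the local Fisher information matrix is assembled from
the scaled sensitivities, FIM = Σ_t SᵀQS with Q diagonal; the weights are
(sc_i/σ_i)² so that the information is measured against the per-observable
noise scale σ_i (default 5% of the observable's range). Local FIMs of
overparameterised biokinetic models are routinely singular, so the
covariance is the Moore–Penrose pseudo-inverse with singular values below
1e-10·σ_max truncated; condition numbers are recorded per sample.

The pseudo-global covariance is the weighted average of the local
covariances with the objective value at each point as the weight — the
literal reading of the averaging rule; a likelihood-style alternative
w_k = exp(−J_k/2) and uniform weighting are exposed but not default. The
correlation matrix R_jk = C_jk/√(C_jj·C_kk) (unit diagonal forced,
zero-variance rows flagged) feeds pair detection: all unordered pairs with
|r| above the threshold (default 0.95), with parameters appearing in two
or more pairs labelled "crossing".

One property worth knowing: a pair entering the model only as a *product*
has identical sensitivity columns at every point, so its averaged
correlation is exactly ±1 for any box. A pair entering as a *sum* has
rank-one local covariances whose principal direction rotates across the
box, so the averaged |r| decays with box width (measured on the test
construction: 0.9992 at ±5% bounds, 0.9967 at ±10%, 0.987 at ±20%, 0.971
at ±30%). Sum-type redundancy detection is therefore a statement about
realistically tight bounds; with very wide boxes the pseudo-global average
deliberately discounts a correlation that does not persist globally.

## Parameter estimation

The objective is σ-normalised weighted least squares over all observables
and sampling times; simulation failures earn a fixed penalty (1e12) and
are counted (more than half the initial population failing aborts with a
bounds diagnostic). Per-observable fitting goodness is Nash–Sutcliffe
R² = 1 − SSE/SStot, which is 1 for a perfect fit, 0 for predicting the
observation mean, and negative for worse-than-mean predictions; a
constant observable has no defined R² and is returned as NaN (and can
never certify a fit).

The optimiser is a real-coded genetic algorithm on decision variables
scaled to [0,1]: tournament selection (size 2), simulated-binary crossover
(rate 0.8, η = 15), polynomial mutation (per-gene rate 1/p, η = 20),
elitism 2, population 50 and 200 generations by default, early stop after
40 stall generations. A deterministic local polish (L-BFGS-B inside the
bounds, started from the GA incumbent) is applied afterwards and accepted
only if it improves the objective; it sharpens noise-free recoveries from
percent-level to ~1e-4 relative error. All randomness flows from one seed;
two runs with the same seed are bit-identical, including the
non-increasing best-so-far trace. Estimating the four initial observables
alongside the parameters is supported by treating them as additional
decision variables in a custom problem; it is off by default.

## The iterative protocol

Step I reduces to schema and range validation of the dataset. Step II
computes DGSM indices, seeds the estimation subset with the smallest
top-ranked set whose cumulative index reaches 0.8, and iterates: if the
fitted minimum per-observable R² meets criterion A (default 0.85), the
lowest-sensitivity member is removed on trial (one per trial, ascending
index order — the ranking is the only ordering information available);
otherwise the next-ranked parameter is added. The loop stops at a fixed
point, a trial cap, or — if even the full parameter set fails — with an
"improper bounds or model structure" verdict. A dataset already matched by
the nominal parameters short-circuits to an empty subset. Step III
computes the pseudo-global correlation on the reduced subset only and
prunes: crossing parameters first, then the lower-sensitivity member of
each remaining flagged pair, with parameter-list order as the tie-break;
every removal is logged with its rule. Pruning never empties the subset.
Step IV runs the final estimation and judges criterion B (default 0.95)
on the minimum per-observable R² — the minimum, not the mean, because
calibration failures in practice are single-observable failures (typically
ammonium). If pruning broke the fit, the pruned members are restored for
one re-calibration pass before the verdict.

Criteria are judged on the calibration data; validation R² on a held-out
range (the CSTR fixture's day 75–113 split) is reported separately rather
than folded into the pass/fail decision.

## Synthetic data

The fixture module emulates the two experiments the package targets. The
SBR scenario runs a 14 L working-volume reactor at 50% exchange through a
3 min feed / 4 h aeration (DO 2 g m⁻³) / 2 h anoxic / 1 h settle / 6 min
decant / 1 min idle cycle, with municipal-strength influent (430 g COD m⁻³,
45 g NH₄-N m⁻³) chosen so ammonium is largely nitrified within the aerobic
phase and nitrate is denitrified under anoxia; samples are taken every
15 min through the reacting phases. The partial-nitrification variant
shortens aeration to 2.5 h at DO 0.8. The CSTR scenario (4 L, 8 L d⁻¹,
SRT 12 d, DO 0.5 g m⁻³) runs 113 days with daily effluent samples; the
chosen oxygen affinities (K_AOB_O2 = 0.4, K_NOB_O2 = 2.0 g m⁻³) make low
DO suppress the nitrite oxidisers, so the fixture reproduces nitrite
accumulation, and the record splits at day 75 into calibration and
validation ranges. Truth parameters override the defaults with literature
point estimates (k_STO = 4.37 d⁻¹, μ_AOB = 1.02 d⁻¹, μ_NOB = 0.76 d⁻¹ for
the SBR; K_H_NO3 = 5.69 g N m⁻³ for the CSTR). Noise is additive Gaussian
truncated at zero — concentrations cannot be negative — with σ per
observable defaulting to a stated fraction of that observable's range; the
seed and σ travel in a truth sidecar that the calibrator never reads.

What the fixtures do *not* emulate: sensor drift, outliers, influent
variability, temperature effects, or real settling behaviour. Passing
tests therefore certify the numerical machinery (conservation,
sensitivity, identifiability detection, estimation, protocol logic) on
data whose generating process is exactly the model — they do not certify
that this ASM3 variant describes any particular plant.

## Numerical choices and problem sizes

Integration uses LSODA at rtol 1e-6 / atol 1e-8 (halving the tolerances
moves observables by < 1e-4 relative). Calibration simulations use a 5 min
output grid for interpolation at sampling times; interpolation error is
far below measurement scales. The shipped protocol and acceptance runs use
compact sampling and GA settings — 8 Sobol points for the 40-parameter
screening, 16 for subset correlation, populations of 20–24 over 25–40
generations with the polish reserved for final estimates — sizes at which
the screening ranking is already stable (convergence diagnostic ~0.1) and
noise-free recoveries land within a fraction of a percent. Trial fits
inside Step II skip the polish: they only need to clear criterion A, and
the polish there would dominate the protocol's cost.

## Known limitations

* Parameter identities in the yield and half-saturation blocks follow the
  Kaelin-type convention; other extended-ASM3 variants order or name them
  differently.
* The pseudo-global correlation's sum-redundancy sensitivity decays with
  box width (see above); very wide priors can mask sum-type degeneracies.
* The GA is a global heuristic: with strongly multimodal objectives the
  recovered optimum depends on the seed and budget, which is why seeds are
  recorded everywhere and the polish is deterministic.
* Temperature correction, pH dynamics beyond the alkalinity switch,
  phosphorus removal and greenhouse-gas extensions are out of scope.
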