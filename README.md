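# asmcal — calibration toolkit for extended ASM3 activated sludge models

Activated sludge models (ASMs) describe the biokinetics of wastewater
treatment — heterotrophic storage and growth, two-step nitrification
(NH₄ → NO₂ by ammonia oxidisers, NO₂ → NO₃ by nitrite oxidisers) and
denitrification — as stiff ODE systems with dozens of stoichiometric and
kinetic parameters. Only a handful of those parameters can be identified
from any one dataset; calibrating the wrong subset produces fits that
validate poorly. `asmcal` is for modellers of lab- and pilot-scale reactors
who want that subset chosen numerically rather than by convention.

The package provides:

* **An extended ASM3 for two-step nitrification/denitrification** (Kaelin-type
  structure, 14 state components, 17 processes, 40 parameters with box
  bounds), declared as a Gujer matrix in a versioned YAML file and verified
  mechanically: every process row closes its COD (ThOD), nitrogen and charge
  balances to below 1e-9.
* **Scenario engines** for a sequencing batch reactor (feed / aerobic /
  anoxic / settle / decant / idle cycles with volume bookkeeping) and a
  CSTR with idealised clarifier (solubles leave at the hydraulic rate Q/V,
  particulates at 1/SRT), with dissolved oxygen as a zero-order-hold
  forcing.
* **DGSM global sensitivity analysis**: the relative sensitivity
  s<sub>ij</sub>(t) = (∂y<sub>i</sub>/∂θ<sub>j</sub>) · θ<sub>j</sub>/sc<sub>i</sub>
  is square-averaged over time and a Sobol sample of the parameter box;
  the normalised index I<sub>j</sub> = √ν<sub>j</sub> / Σ<sub>k</sub>√ν<sub>k</sub>
  ranks parameters for factor fixing.
* **Pseudo-global correlation analysis**: local Fisher information
  FIM = Σ<sub>t</sub> SᵀQS and its pseudo-inverse covariance are computed at
  each Sobol point, averaged with the objective value as weight, and turned
  into a correlation matrix; pairs with |r| > 0.95 are flagged as
  practically non-identifiable ("crossing" parameters correlate with two or
  more partners).
* **Genetic-algorithm estimation** of the weighted least-squares objective
  J(θ) = Σ<sub>i,t</sub> w<sub>i</sub> ((y<sup>obs</sup> − y<sup>sim</sup>)/σ<sub>i</sub>)²
  over box bounds, judged per observable by Nash–Sutcliffe goodness
  R² = 1 − SSE/SStot.
* **The NOAP protocol** chaining the above: factor fixing with estimation
  trials against criterion A (min per-observable R² ≥ 0.85), correlation
  pruning at the 0.95 cutoff, final estimation against criterion B (≥ 0.95).

Because the reactor measurements behind the original calibration studies
are not publicly deposited, the package ships a synthetic-fixture module
that emulates both experiments (SBR cycles sampled every 15 min, a 113-day
CSTR with daily effluent samples split into calibration and validation at
day 75) at known "truth" parameters with controlled noise.

## Worked example

Generate a noisy synthetic SBR dataset at planted truths and re-estimate
the planted subset (`examples/04_ga_calibration.py`):

```sh
$ python examples/04_ga_calibration.py
objective J = 79.75  (1112 simulations)
 parameter  estimate   truth  error %
     k_STO     4.707    4.37     7.72
    mu_AOB     1.017    1.02     0.33
    mu_NOB     0.761    0.76     0.16

per-observable Nash-Sutcliffe goodness:
     COD: R2 = 0.9735
   S_NH4: R2 = 0.9729
   S_NO2: R2 = 0.9687
   S_NO3: R2 = 0.9807
```

The storage rate constant, AOB and NOB growth rates planted in the data are
recovered to within 8% under 5% measurement noise; the R² ≈ 0.97 per
observable is the noise floor, not estimator bias. The other examples
simulate a full SBR cycle, rank all 40 parameters by DGSM index, flag the
classic growth-rate/yield degeneracies (|r| > 0.999 for μ_AOB–Y_AOB), and
run the complete protocol (`examples/05_noap_protocol.py`).

A thin CLI wraps the same library calls:

```sh
asmcal fixture --scenario sbr_complete_nitrification --noise 0.05 --out sbr.csv
asmcal noap --config run.yaml --seed 1 --out results/   # exit 0 = criterion B met
```

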