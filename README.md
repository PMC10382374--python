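# patchtwin

A physics-based digital twin of transdermal fentanyl therapy for chronic
cancer pain, simulated over a correlated virtual patient population.

Transdermal fentanyl has a narrow therapeutic window and strongly
patient-dependent kinetics: the same 72-h patch that leaves one patient in
pain pushes another toward toxic plasma levels and hypoventilation.
`patchtwin` builds an individualized simulation — a digital twin — for every
member of a virtual cancer-patient population and uses it to compare the
conventional fixed 72-h replacement schedule with a feedback schedule that
replaces the patch whenever the predicted pain score exceeds a target.

It is aimed at pharmacometricians and modelling researchers who want a
fully reproducible, end-to-end implementation of this kind of closed-loop
PBPK/PD study: every stage (cohort synthesis, population generation,
parameterization, simulation, outcome statistics) is a library function
with an explicit seed.

## Model

The twin couples three stages, integrated monolithically as one stiff ODE
system between patch events:

1. **Skin uptake.** Fickian diffusion ∂c/∂t = ∇·(D ∇c) through patch,
   stratum corneum, viable epidermis and an equivalent dermis (the reduced
   thickness that mimics capillary uptake), written in the drug-potential
   form ψ = c/K so the partition-coefficient jumps K_i/j = K_i/K_j at layer
   interfaces become continuous. Conservative finite volumes with harmonic
   face conductances; no-flux at the top, potential continuity with plasma
   (ψ = c_p/K_dermis) at the dermis base. The bottom flux × area feeds the
   central PK compartment.
2. **Pharmacokinetics.** Five compartments — central (blood + lungs),
   rapidly equilibrating (brain, heart, skin, kidneys), slowly
   equilibrating (muscle, fat, carcass), gastrointestinal and hepatic —
   with first-order inter-compartment clearances, the unbound fraction
   f_u = 0.20 gating every flux leaving the central compartment, renal
   elimination from plasma and hepatic metabolism in the liver.
3. **Pharmacodynamics.** Each endpoint lags plasma through an effect
   compartment, dc_e/dt = k_e (c_p − c_e), and responds through a
   decreasing sigmoid E = E0 − Emax · c_e^γ / (EC50^γ + c_e^γ): VAS pain
   (E0 = Emax = 8, γ = 2.71, EC50 age-dependent) and minute ventilation
   (E0 = 20 L/min, Emax = 0.91·E0, EC50 = 1.14 ng/ml, γ = 2.69).

Per-patient parameters come from covariate formulas (skin-layer
thicknesses from age, gender and BMI; compartment volumes and clearances
scaled by weight/70 per gender; pain EC50 falling linearly with age), each
multiplied by an independent lognormal inter-individual factor exp(θ),
θ ~ N(0, 0.1). The population itself is produced by a Gibbs sampler —
gender ~ Bernoulli(p) with a uniform prior, covariates per gender
multivariate normal with a conjugate normal–inverse-Wishart prior centred
on a 20-patient sample cohort — keeping one posterior-predictive draw per
iteration after burn-in, which preserves the cohort's covariate
correlations (e.g. the 0.87 gender–height correlation).

## Worked example

```python
import patchtwin as pt
from patchtwin.config import default_config

config = default_config()

cohort = pt.generate_sample_cohort(seed=1)                    # 20 patients
pop = pt.gibbs_sample_population(
    cohort, pt.GibbsConfig(n_burn=20_000, n_keep=3_000, seed=2)
)
print(pt.population_diagnostics(pop).mean)

patient = pop.members[0]
twin = pt.assemble_twin(patient, config, seed=7)
for kind in ("conventional", "twin_assisted"):
    policy = pt.TherapyPolicy.from_config(config["policy"], kind=kind)
    result = pt.run_simulation(twin, policy, config["numerics"])
    out = pt.patient_outcomes(result, config["thresholds"])
    print(kind, out.n_patches, out.mean_vas, out.time_without_pain_total)
```

prints (seeds as above):

```
sample: n=20, mean age 56.75 y, corr(gender, height) = 0.87
population: n=3000, mean age 56.84 y, mean weight 73.85 kg, mean height 1.70 m, 50.9% male
patient 1: age 52 y, female, 68.1 kg, 1.58 m -> EC50 1.19 ng/ml
conventional: 1 patch(es), max c_p 2.21 ng/ml, mean VAS 3.46, pain-free 32.0 h, min ventilation 4.4 L/min
twin_assisted: 2 patch(es), max c_p 2.85 ng/ml, mean VAS 2.10, pain-free 62.0 h, min ventilation 3.2 L/min
```

The twin-assisted schedule replaced this patient's patch once mid-course,
nearly doubling her pain-free time (32 → 62 h of VAS < 3) at the cost of a
higher plasma peak — exactly the trade-off the population comparison
quantifies. `pt.population_compare` aggregates both arms over any number
of patients (median and IQR of time without pain, pain mean/SD changes,
the fraction of patients pain-free more than half the horizon, heavy-user
subgroup statistics).

A CLI mirrors the pipeline:

```bash
patchtwin generate-sample --seed 1 --out sample.csv
patchtwin generate-population --sample sample.csv --n-burn 20000 --n-keep 3000 --seed 2 --out population.csv
patchtwin simulate --population population.csv --policy twin_assisted --out runs/
patchtwin study --out study/ --seed 1 --n-simulate 200
```

## Layout

- `src/patchtwin/cohort.py` — moment-matched synthetic sample cohort
- `src/patchtwin/population.py` — Gibbs-sampled virtual population
- `src/patchtwin/parameters.py` — covariate → twin-parameter mapping
- `src/patchtwin/skin.py` — finite-volume skin diffusion solver
- `src/patchtwin/pkpd.py` — compartmental PK and sigmoid-Emax PD
- `src/patchtwin/system.py` — coupled monolithic integrator
- `src/patchtwin/therapy.py` — replacement policies and simulation loop
- `src/patchtwin/outcomes.py` — outcome metrics and arm comparison
- `src/patchtwin/runner.py`, `cli.py`, `config.py` — pipeline, CLI, config

See `docs/methods.md` for modelling assumptions, numerical choices and
known limitations.
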