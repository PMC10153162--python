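# placentig

Mechanistic modeling of transplacental IgG transfer and prenatal
immunization design.

Maternal IgG is the newborn's first line of immune defense, delivered
across the placenta by Fc-receptor-mediated transcytosis through two
cellular barriers: syncytiotrophoblasts (STB, expressing FcRn) and fetal
capillary endothelial cells (EC, co-expressing FcRn and FcγRIIb).  Because
the receptors are expressed in limited, gestation-dependent quantities, the
four IgG subclasses compete for transport, producing the characteristic
transfer hierarchy IgG1 > IgG3 > IgG4 > IgG2.  `placentig` implements a
compartmental ODE model of this process together with the analysis stack a
quantitative study of it needs:

- **`placentig.transfer`** — five-compartment, four-subclass placental ODE
  model with parabolic receptor-expression schedules; fetal:maternal ratio
  and subclass-entropy outcome metrics; EC receptor-variant experiments.
- **`placentig.calibration`** — iterative Latin-hypercube pass/fail
  calibration (CaliPro-style) of the 11 free parameters against
  gestational-age-binned cordocentesis-style data.
- **`placentig.sensitivity`** — global sensitivity analysis: LHS
  perturbation plus a scikit-learn-compatible single-response
  orthogonalized PLS regressor (`OPLS`) with signed VIP scores, 5-fold
  cross-validated Q², and permutation testing.
- **`placentig.huvec`** — the in vitro Transwell transcytosis model
  (HUVEC/FcRn), its closed-form receptor-competition solution
  `C4 = FcRn0 (IgG4/K_D4) / (1 + IgG4/K_D4 + IgG1/K_D1)`, saturation and
  competition analyses, and monolayer-permeability QC.
- **`placentig.immunization`** — maternal booster-response ODE model
  (antigen → short/long-lived plasma cells → IgG) coupled into the
  placental model as competing antigen-specific species; vaccination-timing
  optimization, receptor-deficiency, dose-compensation, and
  affinity-modulation experiments for a Tdap (anti-pertussis-toxin) case
  study.
- **`placentig.synthetic`** — generators for every dataset the pipeline
  consumes, from known ground truth with truncated-Gaussian noise.
- **`placentig.config` / `placentig.cli`** — YAML configs, packaged
  printed-table parameter presets, and a `placentig` command-line tool.

The model, its assumptions, and all numerical choices are documented in
[docs/methods.md](docs/methods.md).

## Worked example

```python
from placentig import table1_midpoint, simulate_transfer, \
    fetal_maternal_ratio, subclass_entropy
from placentig.immunization import optimize_tvax

params = table1_midpoint()               # packaged printed-table defaults
res = simulate_transfer(params)          # conception -> 40 weeks
for sub, r in zip(res.labels, fetal_maternal_ratio(res, 40.0)):
    print(f"{sub}: F:M = {r:.3f}")
print(f"entropy = {subclass_entropy(res.fetal_at(40.0)):.3f}")
print(f"optimal Tdap week (term) = {optimize_tvax(40.0):.0f}")
```

prints

```
IgG1: F:M = 0.479
IgG2: F:M = 0.126
IgG3: F:M = 0.299
IgG4: F:M = 0.205
entropy = 0.579
optimal Tdap week (term) = 26
```

The fetal:maternal (F:M) ratios show the subclass selectivity the model
exists to explain: IgG1 transfers most efficiently, IgG2 least, despite
IgG2 being the second-most-abundant subclass in maternal blood — the
signature of competition for limited FcγRIIb on the endothelium.  The
entropy value summarizes how far the fetal subclass mix departs from the
maternal one, and the last line is the vaccination week that maximizes
fetal anti-pertussis-toxin IgG for a term delivery.

The same stages are available from the shell:

```sh
placentig simulate --preset table1 --out trajectory.csv
placentig calibrate --n 200 --seed 7 --out calibration.json
placentig sens --outcome total_igg --n 1000 --seed 7 --out vip.csv
placentig huvec saturation
placentig vaccinate optimize --gl 40
placentig synth --kind cordocentesis --cv 0.1 --seed 7 --out bins.csv
```

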