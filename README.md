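# glimtwin

A whole-body physiologically based pharmacokinetic (PBPK) "digital twin"
of the sulfonylurea **glimepiride** and its metabolites **M1**
(hydroxy-glimepiride, pharmacologically active) and **M2**
(carboxy-glimepiride), for pharmacologists and modelers who want to
explore how clinically relevant patient factors shift drug exposure:

* **CYP2C9 genotype** — allele activities *1 = 1.0, *2 = 0.68,
  *3 = 0.23; diplotype activity is the allele mean, and `f_cyp2c9`
  scales the hepatic Vmax of GLI→M1 conversion,
* **renal function** — GFR classes scale metabolite renal clearances
  (`f_renal_function`: 1.0 / 0.69 / 0.32 / 0.19); glimepiride itself is
  not renally excreted,
* **cirrhosis** — Child-Turcotte-Pugh classes map to `f_cirrhosis`,
  which removes functional parenchyma and shunts liver-directed blood
  flow past the hepatocytes,
* **bodyweight** — allometric scaling of volumes and capacities,
* **food state** — a scalar bioavailable fraction.

The core is a compartmental ODE system (gut lumen, venous/arterial
plasma, liver plasma + hepatocyte, kidney plasma, rest tissue, cumulative
urine/feces) with Michaelis–Menten hepatic metabolism
v = f_cyp2c9·(1−f_cirrhosis)·Vmax·C/(Km+C) behind a partially
uptake-limited hepatocyte membrane — the structural feature that keeps
the *3/*3 exposure increase near the clinically observed ≈2-fold instead
of 1/0.23. On top of the simulator sit a non-compartmental analysis
module (Cmax, Tmax, AUC, λz, t½, CL/F), a weighted multi-start
least-squares calibration engine, a virtual-population simulator with
lognormal within-genotype CYP2C9 activity sampling across
biogeographical genotype-frequency tables, and a synthetic-study
generator. See `docs/methods.md` for the full model description.

## Worked example

```python
from glimtwin import (Patient, build_parameters, reference_parameters,
                      simulate, DoseEvent, pk_summary)
from glimtwin import nca

patient = Patient(bodyweight=75.0, genotype="*1/*3", renal="normal",
                  hepatic="none", fed_state="fasted")
params = build_parameters(patient, reference_parameters())
res = simulate(params, [DoseEvent(time=0.0, amount=4.0)], t_end=49.0)
pk = nca.pk_from_result(res, "gli", dose_mg=4.0)
print(f"Cmax  {pk.cmax:6.1f} ng/mL at Tmax {pk.tmax:.1f} h")
print(f"AUCinf {pk.auc_0_inf:6.0f} ng*h/mL   t1/2 {pk.t_half:.2f} h")
print(f"CL/F  {pk.cl_over_f:6.1f} mL/min")
```

prints

```
Cmax   369.7 ng/mL at Tmax 2.4 h
AUCinf   2418 ng*h/mL   t1/2 4.47 h
CL/F    27.6 mL/min
```

i.e. an intermediate metabolizer (*1/*3, activity 0.615) shows ~21 %
higher exposure than the wild-type reference (AUC ≈ 1990 ng·h/mL at
4 mg), with the absorption-determined Tmax and the ≈4-h half-life only
mildly changed — genotype mostly shifts *how much* drug is present, not
*when*.

The same runs from the shell:

```bash
glimtwin simulate scenario.json --out results/
glimtwin population --group "European" --n 1000 --seed 1 --out results/
glimtwin fixtures --out fixtures/
```

where `scenario.json` holds
`{"dose_mg": 4, "genotype": "*1/*3", "renal": "normal", "hepatic": "none",
"bodyweight": 75, "fed_state": "fasted"}`.

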