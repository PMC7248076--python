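# ferropoiesis

A coupled ordinary-differential-equation model of human erythropoiesis and
iron metabolism, for simulating how red blood cell production, haemoglobin
and the plasma/tissue iron pools respond to interventions: oral and
intravenous iron, erythropoietin (EPO) dosing schedules, blood donation,
dietary iron deficiency, chronic inflammation, haemochromatosis and
cytotoxic chemotherapy (CHOP-14). It is aimed at modellers and clinical
pharmacologists studying anaemia management — when iron helps, when EPO
helps, and how the two interact.

## The model in brief

Erythropoiesis is a chain of normalised cell compartments

    S → BE → CE → PEB → MEB → RET → ERY (15 ageing stages + random ageing)

whose proliferation and maturation are driven by EPO (4-compartment
pharmacokinetics with saturable receptor binding; endogenous production a
decreasing sigmoid of haemoglobin). Iron flows through a parallel network
of hepcidin HEP, plasma NTBI, stores F_S, loaded/free transferrin
TRFl/TRFu, enterocytes behind an intestinal delay, a recycling
(macrophage) pool F_HB, and an erythroid iron chain that mirrors the cell
chain. Hepcidin blocks the iron exporter ferroportin, whose efficacy

    Zferro(HEP) = Zferro_max − (Zferro_max − Zferro_min)
                  · exp(−log r · HEP^b),   b < 0

gates all three cellular iron effluxes (absorption, store release,
recycling). Haemoglobin is computed from the erythrocyte iron content, so
iron restriction produces anaemia even at normal cell counts. All
compartments equal 1 at the healthy steady state; most rate constants are
fixed in closed form by that steady state, and the remaining free
parameters can be calibrated to time-series data by minimising the
integrated log-deviation ∫|log f_model − log f_data| dt with a
(1+3)-evolution strategy. See `docs/methods.md` for the full account.

## Worked example

Simulate a single 100 mg intravenous iron infusion into a healthy adult:

```python
from ferropoiesis import default_parameters, simulate, presets

params = default_parameters()
traj = simulate(presets()["iv_iron_100mg"], params, grid=0.25)
obs = traj.observables()
for d in (0.0, 0.25, 2.0, 7.0, 30.0, 60.0):
    r = obs.loc[d]
    print(f"day {d:5.2f}  HB {r.HB:5.2f} g/dl  serum iron {r.serum_iron:6.1f} ug/dl  "
          f"ferritin {r.ferritin:5.1f} ug/l  TSAT {r.TSAT:.2f}  hepcidin {r.HEP:.2f}")
```

prints

```
day  0.00  HB 14.00 g/dl  serum iron  100.0 ug/dl  ferritin 100.0 ug/l  TSAT 0.50  hepcidin 1.00
day  0.25  HB 14.00 g/dl  serum iron  768.7 ug/dl  ferritin 104.9 ug/l  TSAT 0.72  hepcidin 2.18
day  2.00  HB 14.01 g/dl  serum iron  412.0 ug/dl  ferritin 131.4 ug/l  TSAT 0.69  hepcidin 3.94
day  7.00  HB 14.12 g/dl  serum iron  113.2 ug/dl  ferritin 145.2 ug/l  TSAT 0.53  hepcidin 1.58
day 30.00  HB 14.09 g/dl  serum iron  102.1 ug/dl  ferritin 143.3 ug/l  TSAT 0.52  hepcidin 1.29
day 60.00  HB 13.83 g/dl  serum iron   99.4 ug/dl  ferritin 134.1 ug/l  TSAT 0.50  hepcidin 1.17
```

Serum iron and transferrin saturation spike during the 15-minute infusion
and return to normal within about a week as hepcidin rises and the dose is
cleared into stores (ferritin up ~45%) and the erythron (haemoglobin up
~0.1 g/dl); reticulocytes and EPO dip slightly while haemoglobin is
elevated.

The same engine is scriptable from the shell:

```
ferropoiesis presets                                    # list shipped scenarios
ferropoiesis simulate --scenario phlebotomy_10pct --out traj.csv
ferropoiesis suite                                       # direction report
ferropoiesis check-steady-state
ferropoiesis synth --scenario iv_iron_100mg --noise-cv 0.1 --seed 1 --out data.csv
ferropoiesis fit --spec fitspec.yaml --data data.csv --scenario iv_iron_100mg \
    --out fitted.yaml --seed 1
```

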