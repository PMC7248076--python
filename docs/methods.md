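# Model and methods

`ferropoiesis` couples a cell-kinetic model of human erythropoiesis with a
compartmental model of iron homoeostasis regulated by hepcidin and
ferroportin, and adds an intervention engine (iron and EPO dosing,
phlebotomy, malnutrition, inflammation, haemochromatosis, cytotoxic
chemotherapy) and an evolution-strategy calibrator. This note records the
model structure, the meaning and provenance of the tunable parameters, the
numerical choices, and what the synthetic tests do and do not demonstrate.

## Normalisation

Every compartment is expressed relative to its healthy homeostatic value,
so the reference state of the healthy adult is the all-ones vector (the
subcutaneous EPO depot rests at 0 and the intestinal delay compartment at
its diet-driven fixed point `FeDiet_nor / Delay_intest`, in mg). Clinical
units enter only through *unit bridges* at the observable layer
(haemoglobin 14 g/dl, serum iron 100 µg/dl, ferritin 100 µg/l, EPO
10 mIU/ml, red cells 4.8·10⁶/µl, reticulocytes 60·10³/µl, haematocrit
0.42) and through dose conversions (mg of iron, IU of EPO).

A consequence of per-compartment normalisation is that the *relative* flux
scales between compartments are encoded in the rate constants, not in the
state: the plasma-iron balance weighs enterocyte export, storage exchange
and macrophage recycling on comparable O(1) scales even though their
physical magnitudes differ. A single configurable bridge
(`iv_iron_mg_per_unit`, default 10 mg per plasma-flux unit) converts
intravenously infused milligrams into normalised plasma-iron flux; it is a
model constant of the same standing as the rate constants, not a measured
quantity.

## Regulators

All regulation is phenomenological, through one saturating-response family

    response(x) = v_max − (v_max − v_min) · exp(−log r · x^b),
    r = (v_max − v_min)/(v_max − v_nor),

anchored so that `response(1) = v_nor` exactly. A positive exponent gives
an increasing response (`v_min` at 0, `v_max` at ∞); a negative exponent
swaps the plateaus and yields a decreasing response. Decreasing regulators
(ferroportin efficacy in hepcidin; transferrin production in its combined
drive; endogenous EPO in haemoglobin) therefore carry `b < 0`; this
preserves the anchor identity while matching the biology, and the
zero-drive case is resolved by the analytic limit rather than an error.

Three regulators act on the iron side:

* **Hepcidin production** is an increasing sigmoid of the weighted drive
  `A = (k_HEPFS·F_S + k_HEPFP·F_P + k_HEPHB·HB/HB_nor) / Σk`, minus linear
  elimination `d_HEP·HEP`, plus an optional constant inflammatory influx.
  The plasma-iron argument enters normalised (`F_P/F_P0`) so that `A = 1`
  at rest — without this the hepcidin balance cannot be closed by the
  elimination-rate identity.
* **Ferroportin efficacy** `Zferro(HEP)` gates every cellular iron efflux:
  enterocyte export, release from stores, and macrophage recycling.
* **Transferrin production** `Z_TRF` is a decreasing sigmoid of the
  weighted mean of plasma iron, haemoglobin, storage iron and hepcidin.

## Iron compartments

State variables: hepcidin `HEP`, non-transferrin-bound plasma iron `NTBI`,
stores `F_S`, loaded/free transferrin `TRFl`/`TRFu`, enterocyte iron
`F_entero` behind a first-order intestinal delay `C_Fe`, the recycling
system `F_HB`, and an erythroid iron chain `Fe_MEB → Fe_RET → Fe_ERY(15
ageing stages) → random ageing` that uses the identical transition and
maturation rates as the corresponding cell compartments.

Ingested iron (diet plus oral medication pulses scaled by `1/Zferro_min`)
enters the delay compartment; its efflux feeds the enterocytes through a
Michaelis–Menten absorption term, and ferroportin-gated export delivers
enterocyte iron to plasma while enterocyte decay (`d_entero`) discards the
rest. NTBI exchanges with stores (rate `k_S`, release gated by
ferroportin) and loads free transferrin (`k_ul·TRFu·NTBI/(k_MM+NTBI)`).
Marrow iron uptake is `(k_PEB + d_TRFl)·PEB_out·TRFl^α`, where `PEB_out`
is the normalised efflux of proliferating erythroid blasts; the `k_PEB`
share of the transferrin shuttle is recycled and `d_TRFl` degraded. Dying
erythrocytes return `(1 − d_Fe)` of their iron to the recycling
macrophages, which release it back to plasma under ferroportin control.

Haemoglobin is computed from the erythrocyte iron chain (reticulocyte iron
neglected), so cell counts and haemoglobin can dissociate: iron-restricted
states produce many under-haemoglobinised cells, which is the mechanism
behind the anaemia of malnutrition and inflammation in this model.

### Steady-state-derived constants

Requiring the reference state to be stationary fixes, in closed form:
`d_HEP = HEP_nor/HEP_0`; `k_HB = (1−d_Fe)/(F_HB0·Zferro_0)`;
`k_lu` from the loaded-transferrin balance;
`d_TRFu` from the free-transferrin balance (with `Z_TRF` at its resting
value); `k_FeTRF` from the NTBI balance; `k_intest` from the enterocyte
balance under the normal diet; and the endogenous EPO production scale
from the EPO pharmacokinetics. The storage balance contains no free
constant of its own — it forces `Zferro(HEP_0)·F_S0 = NTBI_0`, i.e. a unit
ferroportin anchor, which the validator enforces. Inadmissible free
parameters (any derived constant ≤ 0) are rejected with the violated
identity named.

## Erythropoiesis

Cell chain `S → BE → CE → PEB → MEB → RET → ERY`. Stem cells self-renew
logistically (`beta_S`, carrying capacity 1). EPO increases the effective
amplification of CE and PEB and shortens MEB maturation, each through an
anchored sigmoid of the pharmacodynamically active (internalised) EPO
pool. Erythrocytes age through 15 sub-compartments (transit 110 days)
with a small random loss (0.001/day) and a terminal random-ageing
compartment (death rate 0.1/day), giving a mean lifespan of ≈120 days; in
normalised coordinates the ageing chain is uniform, and the absolute
steady-state profile re-enters only through the death-flux and
cell-count observation weights.

EPO pharmacokinetics: subcutaneous depot (absorption 1/day,
bioavailability 0.7), central and peripheral compartments (exchange
1/day), capacity-limited receptor binding (capacity twice the resting
bound pool), internalisation (2/day) and linear elimination (3/day).
Doses are state jumps (50 IU of EPO ≈ one normalised unit of the central
pool for a 70 kg adult). Endogenous production is a decreasing sigmoid of
haemoglobin.

Chemotherapy is a delayed, transient first-order kill on the proliferating
compartments only (S, BE, CE, PEB; maturing cells spared), with
per-compartment sensitivities (stem cells 0.15 of the nominal rate). The
shipped CHOP-14 preset applies six pulses 14 days apart (kill rate
0.29/day, 4-day window, 1-day delay).

### Provenance of the erythropoiesis coefficients

The compartment structure above is fixed, but the numerical coefficients
of the cell chain, the EPO sigmoids and the chemotherapy toxicity are
*reconstructions*: they were chosen, once, so that (a) the reference
steady state holds exactly, (b) all qualitative intervention scenarios
change every observable in the physiologically expected direction, (c)
haemoglobin recovery after a 10% blood donation takes on the order of five
months, and (d) CHOP-14 without support first crosses 10.5 g/dl
haemoglobin in the fourth cycle. They are not literature measurements, and
the shipped parameter file should be read accordingly. Quantitative
amplitudes (e.g. the depth of the CHOP-14 nadir, the height of the
reticulocyte overshoot) are not calibration targets and should not be
over-interpreted.

## Interventions

* iv iron: rectangular infusion pulses of 15 min (integral equals the
  dose exactly); the dose is the bioavailable amount.
* Oral iron: rectangular 30-min pulses at the scheduled clock times,
  divided by `Zferro_min` (the normalisation that keeps absorbed iron
  below the administered dose once ferroportin-gated export is applied);
  the intestinal delay low-passes the input, so results are insensitive to
  the pulse width.
* Phlebotomy: instantaneous proportional reduction of reticulocytes, all
  erythrocyte ageing compartments and the random-ageing compartment, in
  both cell count and iron content; plasma volume is assumed restored
  immediately, so haemoglobin concentration right after a fraction-f bleed
  is (1−f) times its previous value. A 500 ml donation maps to f = 0.1 of
  the default 5 l blood volume.
* Chronic modifiers (diet factor, inflammatory hepcidin influx, hepcidin
  production factor for haemochromatosis) act from t = 0 on a subject
  that starts at the healthy steady state.

## Numerics

Stiff-capable variable-step integration (LSODA), default relative
tolerance 1e−8 and absolute 1e−10, restarted at every input discontinuity
(dose pulse edges, chemotherapy window edges); instantaneous transforms
(phlebotomy, EPO boluses) are applied exactly at their event times, and a
dose falling on an output grid point is applied before that point is
sampled. The output grid defaults to 0.1 days. Halving the tolerances
changes haemoglobin trajectories by well under 0.1% in sup-norm. States
are clamped at zero within an absolute tolerance of 1e−6 (beyond which the
run aborts with a diagnostic); regulator inputs are clamped non-negative
inside the right-hand side to tolerate solver probing.

The qualitative scenario suite and the calibrator use a relaxed tolerance
(1e−6/1e−9) and coarser grids; the direction-of-change conclusions are
insensitive to this (they hold identically at the tight tolerances).

## Calibration

Fitness is the integrated absolute log-deviation between the model
trajectory and the piecewise-linear interpolant of the data, trapezoidal
on the union of the model and data grids, summed over datasets. It is
invariant under common rescaling of model and data, and undefined
(an error) for non-positive values.

The optimiser is an elitist (1+3)-evolution strategy: three children per
generation by per-coordinate log-normal mutation (log-scale respects the
positivity bounds naturally), parent replaced only by a strictly fitter
child, and self-adaptive step size (×1.3 on success, ×1.3^(−1/4) on
failure — a 1/5-success-style rule; the generation budget, step constants
and mutation scale are package choices, documented defaults rather than
prescribed values). Children whose parameters are inadmissible or whose
simulation fails count as unviable; runs are bit-reproducible under a
fixed seed.

The shipped parameter-recovery exercise fits (`k_S`, `k_ul`, `d_entero`)
to noiseless synthetic haemoglobin, transferrin saturation and ferritin
from an iv-EPO + oral-iron course sampled every 0.25 days over 28 days.
The triple was chosen for identifiability: `d_Fe`, a natural-looking
alternative, is absorbed almost entirely by the steady-state derivations
(it mainly sets the recycling-pool time constant) and cannot be recovered
from these observables on this horizon. Dense sampling matters because
the fitness integrates against the data interpolant: with sparse samples
the generating parameters themselves score a nonzero interpolation floor.

## What the synthetic tests show — and what they do not

The synthetic-data generator samples the model's own trajectories with
multiplicative, mean-preserving log-normal noise of configurable CV. It
emulates the sampling structure of intervention studies (scheduled draws
of haemoglobin, TSAT, ferritin, …) but none of the things that make
clinical data hard: between-subject variability, assay floors, missed
visits, model misspecification. Passing the recovery test therefore shows
that the fitting machinery is correct and that the chosen parameters are
identifiable *given the model*; it does not validate the model against
real patients. Likewise the direction suite checks signs, not magnitudes.

## Known limitations

* Fe²⁺/Fe³⁺ speciation and mono- vs di-ferric transferrin are not
  distinguished; there is a single storage pool.
* Serum ferritin is reported as proportional to the storage compartment.
  Under chronic inflammation this makes "ferritin" rise with the stores,
  whereas clinically ferritin is also an acute-phase reactant — the model
  exposes both the raw `F_S` and the scaled ferritin observable and leaves
  the interpretation to the user.
* Hepcidin regulation is phenomenological; no BMP/SMAD or IL-6 signalling.
* The normalised flux scales (see above) mean absolute mg bookkeeping is
  only as good as the bridge constants.
* Erythrocyte transfusion is not modelled; granulopoiesis and G-CSF are
  out of scope.
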