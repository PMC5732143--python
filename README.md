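# spherohca

High-content monitoring of drug effects in 3D tumor-spheroid cultures.

One spheroid grows in each U-bottom well of a cell-repellent 96-well plate.
Bright-field and fluorescence images taken once a day, plus an ATP
luminescence endpoint, yield a panel of phenotype parameters per well:

* **Area** — projected spheroid area (growth);
* **Shape P2A** = P²/(4πA) — roundness, 1 for a perfect circle, larger for
  disrupted or irregular spheroids (integrity);
* **CellEvent (CE)** — caspase-3/7 reporter fluorescence (apoptosis);
* **LysoTracker (LysoT)** — lysosomal vital-dye uptake in the metabolically
  active outer layers (viability);
* **ATP** — luciferase luminescence of the lysed spheroid (viability
  endpoint).

Each parameter's concentration–response is normalized to the vehicle
control and fitted with a four-parameter logistic or, where the data
support it, a biphasic double-Hill mixture with ordered EC50s
(EC50‑1 < EC50‑2).  Comparing every EC50 with a **static ATP threshold**
(the highest tested concentration at which spheroid ATP content shows no
change from vehicle) dissects cytostatic (growth-arresting, below the
threshold) from cytotoxic (cell-killing, above it) drug action.

The package covers the whole workflow: plate-design bookkeeping and
dilution arithmetic, bright-field segmentation and morphometry,
fluorescence quantification, assembly/uptake kinetics, dose–response
modelling, ATP-endpoint processing, and profile assembly — plus a
ground-truthed synthetic image generator (896.6 µm field of view rendered
to 552×552 px, one centered spheroid occupying ~12 pL per seeded cell)
so that every stage is testable without instrument data.

## Worked example

Fit a biphasic growth-arrest curve (simulated with lower/upper EC50s of
18 and 600 nM, six replicates, 10% noise) and read the results off the
Results object:

```python
from spherohca.doseresponse import DoseResponseModel, simulate_curve

curve = simulate_curve([18.0, 600.0], hills=2.0, fraction=0.55,
                       left=1.0, right=0.25, noise_sd=0.10, seed=11,
                       parameter="Area")
res = DoseResponseModel(curve).fit("auto", seed=0)
print(res.summary())
```

```
Dose-response fit: Area
  model        biphasic_double_hill
  n_obs        54
  ...
  EC50 Area-1: 14.8205  CI [4.56, 48.17]
  EC50 Area-2: >1000
```

The lower EC50 (the "-1" increment, here 14.8 nM for a 18 nM truth under
this noise draw) is the growth-arrest phase; the upper one fell outside
the tested range on this draw and is reported censored (`>1000`), the same
convention used for saturating curves in the tabulated profiles.  Plate
bookkeeping is equally direct:

```python
from spherohca import benchmarks
print(benchmarks.worked_examples())
# {'circle_p2a': 1.0, 'usable_wells': 60,
#  'drug_concentrations_per_plate': 9,
#  'working_volume_per_condition_ul': 600.0, 'dye_final_um': 1.0}
```

i.e. excluding the evaporation-prone edge wells leaves 60 usable wells;
with six replicate spheroids per condition and one vehicle control that is
nine drug concentrations per plate, 600 µL of 2× working solution per
condition, and a 2 µM dye working solution becomes 1 µM in the well after
half-volume medium replacement.

A full synthetic plate can be run end-to-end from the shell:

```bash
spherohca run --out out/ --seed 1      # simulate → segment → fit → profile
spherohca layout --design design.csv   # validate an experimental design
```

`out/` then contains tidy CSVs (`morphometrics.csv`, `responses.csv`,
`fits.csv`, `profile.csv`) plus the generator's `ground_truth.csv`.

## Documentation

`docs/methods.md` describes the models, the synthetic-data generator, the
numerical choices and the known limitations.
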