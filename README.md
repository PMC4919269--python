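# renalpet

Quantitative analysis of dynamic small-animal PET for renally excreted
tracers — built around the study design of ¹¹C-labelled metformin imaging
in a mouse model of chronic kidney disease (CKD), where renal uptake of an
organic cation reports on the basolateral transporter OCT2.

The package covers the full analysis chain of such a study, plus a
synthetic-data layer so that every stage is testable without any scanner
data:

- **Synthetic cohorts** (`renalpet.cohort`) — bolus plasma input
  functions, one-tissue-compartment renal-cortex kinetics, frame-averaged
  sampling on a 33-frame / 90-min schedule, duration-scaled measurement
  noise, and per-subject dosimetry. Group presets (`control`/`wt`, `tg`
  CKD transgenic, `oct12_ko`, `cimetidine`, `pyrimethamine`) carry known
  ground-truth kinetics and plasma exposure.
- **4D phantoms and image analysis** (`renalpet.phantom`) — a labelled
  mouse-like digital phantom (heart, liver, crescent renal cortices,
  accumulating bladder), VOI-mean TAC extraction, the heart image-derived
  input function (IDIF: first-20-s average image, 15-pixel circles on the
  six most intense axial slices), and SUV conversion, with NIfTI-1 I/O.
- **Kinetic modelling** (`renalpet.kinetics`) — one-tissue compartment
  model fits and Logan graphical analysis.
- **Clearance** (`renalpet.clearance`) — input-function AUC, total body
  clearance, group fold-changes.
- **Statistics** (`renalpet.stats`) — Lilliefors-screened Student's
  *t* / Mann-Whitney comparison and Pearson correlation.
- **Pipeline + CLI** (`renalpet.pipeline`, `renalpet` console script) —
  one-seed reproducible end-to-end runs with CSV reports.

## The model

Tracer exchange between blood plasma and the renal cortex follows a
one-tissue compartment model with influx and backflux rate constants
K₁ and k₂ (min⁻¹):

    C_T(t) = K₁ ∫₀ᵗ C_p(τ) e^(−k₂ (t−τ)) dτ

where C_p is the plasma input function, approximated by the heart IDIF.
Parameters are estimated per kidney by bounded nonlinear least squares on
the frame-averaged model prediction; non-physiological fits are flagged
and excluded from group statistics. The Logan plot of the same data gives
the total distribution volume V_T (= K₁/k₂ for this model) as the
late-time slope. Total body clearance for a non-metabolised,
renally excreted tracer is

    TBC = ID / AUC(0–90 min)    [mL/min/kg]

with ID the injected dose per kg body weight and AUC the area under the
IDIF. Standard uptake values are
SUV = concentration [kBq/mL] × body weight [g] / injected dose [kBq].

The group presets encode the biology of interest: the CKD transgenic
preset has a 2.2-fold lower K₁ (reduced OCT2-mediated uptake) and
1.8-fold higher plasma exposure (hence 1.8-fold lower TBC); the OCT1/2
knock-out and cimetidine presets reduce clearance 3.0- and 2.5-fold; the
MATE1-inhibition preset leaves renal uptake intact and raises TBC
1.1-fold. k₂ is shared by all groups.

## Worked example

```python
import renalpet as rp

# one noisy wild-type subject with its own image-derived input function
subj = rp.simulate_cohort(rp.DEFAULT_PRESETS["wt"], 1, seed=1)[0]

fit = rp.fit_1tcm(subj.cortex_left, subj.idif)
lg = rp.logan_vt(subj.cortex_left, subj.idif, t_star=20.0)
clr = rp.tbc(subj.record, subj.idif)
```

This prints (via f-strings on the returned objects):

```
K1 = 0.798 /min, k2 = 0.150 /min (truth 0.800, 0.150)
Logan V_T = 5.32 mL/mL (K1/k2 = 5.33), R^2 = 1.0000
TBC = 81.6 mL/min/kg (AUC = 3828 kBq*min/mL)
```

The fitted rate constants recover the generating values within a fraction
of a percent at the default noise level; the Logan slope agrees with the
compartmental V_T; the clearance is in the physiological range for a
renally excreted organic cation in the mouse.

A full study — all six group presets, per-subject fits, clearance, and
the normality-gated group statistics — runs from one seed:

```python
report = rp.run_study(rp.StudyConfig(seed=1))
print(report.table1.to_string(index=False))
```

```
        group  n  fold_change_tbc direction      p_value
      control  5         1.000000                    NaN
           tg  8         1.799079      down 4.310358e-03
     oct12_ko  4         2.998038      down 1.207002e-19
   cimetidine  5         2.497247      down 3.893231e-22
pyrimethamine  4         1.098694        up 2.290279e-11
```

The fold-change column recovers each preset's designed plasma-exposure
ratio (1.8, 3.0, 2.5, 1.1) from the noisy simulated data; `direction`
says whether the group's clearance is below or above control. The same
run is available from the shell:

```sh
renalpet run --seed 1 --outdir out/       # writes subjects.csv, table1.csv, ...
renalpet simulate --seed 1 --outdir sim/  # cohort TAC files + manifests
renalpet fit --tacs sim/wt --outdir kin/  # kinetics.csv from TAC files
```

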