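# mbrtwin

A desk-scale digital twin of an autonomous microbioreactor screening
platform, for bioprocess-development and laboratory-automation
informatics work: everything such a platform computes — trigger logic,
liquid-handling mass balance, clean-in-place (CIP) carry-over, batch-time
detection, enzymatic activity quantification and batch-effect statistics
— reimplemented as a tested Python library, so control strategies and
analysis procedures can be exercised and validated without hardware.

The simulated platform is a 48-well FlowerPlate microbioreactor coupled
to a liquid handler: 12 preculture wells in the outer columns are
inoculated from a cryopreserved working cell bank (20 µL of an OD 4
suspension into 780 µL medium → OD 0.1); when a preculture's backscatter
crosses 5.5 a.u. it triggers inoculation of its three adjacent
main-culture wells; main cultures are induced (IPTG to 250 or 500 µM at
3.7 a.u.) and harvested, and between consecutive runs all 48 wells are
cleaned in place. The secreted product of the case-study organism
(*Corynebacterium glutamicum* exporting a fungal cutinase via *Bacillus
subtilis* Sec signal peptides) is quantified photometrically.

## What it computes

- **Mass balance** (`mbrtwin.mass_balance`) — exact volume-weighted
  mixing, inoculation OD arithmetic, and the wash-chain carry-over model
  `c_n = c_0 · (V_res / (V_res + V_wash))^n`. With the platform's 10 µL
  residual and 700 µL washes, two washes reduce pure disinfectant below
  0.02 % (v/v).
- **Synthetic data** (`mbrtwin.synthetic_data`) — batch growth as
  lag → exponential (µ_max) → hard substrate stop, read out as
  backscatter = gain·OD + offset + noise on a fixed 4- or 13-min cycle
  grid; secreted activities with run-level random effects; 4-nitrophenol
  absorbance kinetics. All generators expose their ground truth.
- **Orchestration** (`mbrtwin.orchestration`) — a discrete-event
  controller: per-well threshold triggers (upward crossing, no
  interpolation), triplicate inoculation, induction boluses, harvests,
  plate-level CIP (medium-wash ≈ 2 h, methanol + evaporation ≈ 11 h),
  sterility checks, consecutive runs, and an exactly balanced volume
  audit over an append-only event log.
- **Batch-time detection** (`mbrtwin.batch_time`) — cubic smoothing
  splines with a k-fold cross-validated penalty; the batch time is the
  maximum of the first spline derivative, t̂ = argmax_t f̂′(t); replicate
  summaries floor the SD at one measurement cycle.
- **Assay analysis** (`mbrtwin.assay_analysis`) — standard-curve OLS,
  initial-linear kinetic slopes, and EA = ΔA₄₁₀ · (1/m_standard) · DF
  in U/mL (1 U = 1 µmol/min).
- **Batch effects** (`mbrtwin.batch_effects`) — balanced one-way
  random-effects decomposition (method of moments), same-plate vs
  spread replicate-placement comparison, and weekly stability reports.

## Worked example

```bash
python examples/autonomous_campaign.py
```

```
event counts over 3 runs:
  inoculate_preculture: 36
  inoculate_main: 108
  harvest: 108
  cip_done: 2
CIP phase 1: medium_wash, 1.93 h, worst residual disinfectant 0.000244% (v/v)
CIP phase 2: medium_wash, 1.93 h, worst residual disinfectant 0.000244% (v/v)
supernatant samples collected: 108
volume audit discrepancy: 0.00e+00 µL
```

Per run, 12 precultures each fire one triplicate inoculation (36 main
cultures), every main culture is harvested once, and the two CIP phases
between the three runs each take ~2 h and leave far less disinfectant
than the 0.02 % (v/v) carry-over target. The volume audit confirms every
microlitre moved is accounted for across wells, waste, samples and
evaporation. The other scripts in `examples/` walk the cell-bank
dilution arithmetic, the CIP carry-over chain, spline batch-time
detection, the cutinase assay calculation and the replicate-placement
comparison, one capability each.

## Layout

```
src/mbrtwin/        the library (one module per concern, see above)
examples/           one narrative script per capability
tests/              pytest suite incl. end-to-end acceptance checks
scripts/acceptance.py
docs/methods.md     models, parameters, design choices, limitations
```
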