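# helifret

Simulation and kinetic analysis of repetitive RNA unwinding by RNA
helicase A (RHA/DHX9), as observed in single-molecule FRET (smFRET)
experiments.

RHA unwinds a surface-tethered RNA duplex in discrete substeps —
binding (B), activation (A), gradual unwinding (U), a high-FRET stall
(S) and reactivation (R) — and a single enzyme repeats the U–S–R cycle
many times without dissociating, until the strands fully separate.
Binding and dissociation are visible as abrupt steps in total
fluorescence intensity (protein-induced fluorescence enhancement);
unwinding and rewinding are visible as a gradual rise and a rapid drop
of the FRET efficiency `E = I_A/(I_D + I_A)`. This package is for
single-molecule biophysicists who want to prototype, validate and run
the full analysis chain for that class of experiment:

- `helifret.synthetic_data` — a continuous-time Markov (Gillespie)
  simulator of the five-substep cycle that renders realistic
  two-channel camera traces with ground truth: exponential dwells,
  Michaelis–Menten ATP dependence of unwinding
  (`k_U = k_unw·[ATP]/(Km+[ATP])`), PIFE intensity steps,
  photobleaching, terminal strand separation, per-frame Gaussian
  noise; plus annealing-field time-courses;
- `helifret.trace_processing` — FRET/total-intensity computation,
  change-point detection of binding/dissociation steps, bleach
  detection, population FRET histograms (first 10 frames per
  molecule);
- `helifret.substep_segmentation` — idealization of each bound
  interval into A/U/S/R segments with censoring flags, cycle counting,
  dwell tables;
- `helifret.rate_inference` — substep rates (exponential MLE with
  SEM), the association constant `k_on` (zero-intercept fit of binding
  rate vs [RHA]), the ATP Michaelis constant `Km`, off rates from
  total bound times, temperature fold-changes, and the
  fluorescence-polarization binding isotherm (`Kd`);
- `helifret.annealing_analysis` — annealing rates from molecule-count
  time-courses and the enhancement factor (unwinding-induced vs
  binding-induced annealing);
- a `helifret` command-line interface (`simulate`, `analyze`, `rates`,
  `assoc-fit`, `mm-fit`, `isotherm-fit`, `anneal`, `report`) tying the
  stages together.

Two preset parameter sets are shipped (`wild_type` and the
dsRBD-truncation mutant `delta_dsRBD`); the anchored constants are
`k_on = 2.61×10⁶ M⁻¹s⁻¹` and `Km = 26 µM`, everything else is a
documented model assumption (see `docs/methods.md` and
`src/helifret/presets.yaml`).

## Worked example

Simulate 160 wild-type molecules at 40 nM RHA / 1 mM ATP for 250 s,
run the analysis chain, and estimate all substep rates:

```python
import helifret as hf

params = hf.preset_params("wild_type")
cond = hf.Condition()  # 40 nM RHA, 1 mM ATP, room temperature

ds = hf.simulate_dataset(params, [cond], n_molecules=160,
                         duration_s=250.0, seed=2024)
table = hf.analyze_traces(ds.traces[cond.key()], condition_key=cond.key())
rates = hf.rates_from_dwell_table(table)
print(rates.drop(columns="condition").to_string(index=False))
print("binding events:", len(table.events),
      " median cycles per event:", table.events["n_cycles"].median())
```

prints

```
substep     rate      sem   n  n_censored
      A 0.057267 0.004304 177          20
      B 0.109353 0.007791 197           2
      R 0.294241 0.010140 842          14
      S 0.939317 0.032105 856         133
      U 0.476512 0.015152 989          30
    off 0.022046 0.003530  39         158
binding events: 197  median cycles per event: 4.0
```

Reading the output: `B` is the binding rate at 40 nM
(0.109 ≈ k_on·[RHA] = 2.61×10⁶ × 40×10⁻⁹ = 0.104 s⁻¹); activation `A`
is the slowest substep (rate-limiting, generating value 0.05 s⁻¹);
`U`, `S`, `R` recover their generating values (0.49, 1.0, 0.3 s⁻¹)
within errors — completed dwells are slightly fast because they must
outrun dissociation and bleaching. The off rate conditions on
observing dissociation and therefore reads higher than the generating
`k_off`; it is used for comparisons (mutant vs wild type,
concentration invariance), not absolute recovery. A median of 4
unwinding cycles per binding event reflects repetitive unwinding by a
single enzyme.

The same run from the shell:

```sh
helifret simulate --variant wild_type --rha-nM 40 --atp-uM 1000 \
    --n 160 --duration-s 250 --seed 2024 --out out/
helifret analyze --traces out/traces_wild_type_rha40nM_atp1000uM_RT_gc50.csv \
    --out out/wt
helifret rates --dwells out/wt_dwells.tsv --events out/wt_events.tsv \
    --out out/rates.tsv
```

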