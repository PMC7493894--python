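# apoptimer

Modelling of apoptosis execution at the apoptosome: cooperative caspase-9
recruitment, the molecular timer, and XIAP.

After mitochondrial outer membrane permeabilisation (MOMP), cytochrome c
and SMAC enter the cytosol; cytochrome c and ATP oligomerise APAF1 into the
apoptosome, which recruits and activates pro-caspase 9 (PC9).  PC9
autocleavage to caspase 9 (C9-35/12) both exposes the site XIAP needs to
inhibit C9 and sharply lowers C9's affinity for the platform — a
*molecular timer* that shuts apoptosome activity down on a set schedule.
`apoptimer` implements a mass-action ODE model of this network with
*cooperative* PC9 recruitment (weak primary binding of one PC9, strong
secondary binding of a second directly into a homodimer), switchable
regulatory layers (timer on/off, XIAP present/absent, cleavable /
non-cleavable PC9), and the analysis pipeline built on it:

* extraction of binding kinetics from dissociation (SPR-style) traces via
  one-phase-decay fits: k_off = ln 2 / t½, k_on = k_off / K_D;
* global least-squares calibration of the recruitment kinetics under
  SPR-derived bounds against substrate-cleavage and timer-decay training
  curves (`ExecutionModelCalibration(...).fit()` returns a results object
  with estimates, bound diagnostics and a `summary()` table);
* IETDase activity screens over the APAF1 × PC9 concentration plane
  (maximum, time-to-maximum, decay half-life, integrated activity) after
  full or 5% (minority) MOMP;
* virtual-cell cohorts sampled from physiological ranges: Kaplan–Meier
  survival under four model variants, logrank tests, apoptosis /
  timer-dependence classification, ROC analysis of single proteins and the
  XIAP–SMAC balance, and Webb's fractional-product synergy score
  (score < 0.9 ⇒ synergistic);
* apoptosis-competency classification of patient tumour protein profiles
  (300-min simulation, 25% substrate-cleavage threshold) with
  Kaplan–Meier / Cox proportional-hazards survival analysis, plus a
  synthetic patient-cohort generator targeting reported tumour protein
  dispersion.

The model and all default constants are documented in
[docs/methods.md](docs/methods.md).

## Worked example

```python
import apoptimer as ap

params = ap.default_parameters()                  # calibrated defaults
state = ap.apply_momp(ap.default_initial_state(), 1.0)   # full MOMP
net = ap.build_network(params, ap.VARIANTS["normal"])
traj = ap.simulate(net, state, t_end=240.0, death_threshold=0.25)

ev = ap.detect_death_event(traj)
print(f"died={ev.died} at t={ev.event_time:.1f} min")
print(f"substrate cleavage at 60 min: {traj.c3_substrate_cleavage(60.0):.3f}")

mini = ap.apply_momp(ap.default_initial_state(), 0.05)   # minority MOMP
t_mini = ap.simulate(net, mini, 240.0)
t_nt = ap.simulate(ap.build_network(params, ap.VARIANTS["no_timer"]), mini, 240.0)
print(f"minMOMP cleavage at 240 min: {t_mini.c3_substrate_cleavage(240.0):.3f}")
print(f"         without the timer: {t_nt.c3_substrate_cleavage(240.0):.3f}")
```

prints

```
died=True at t=9.2 min
substrate cleavage at 60 min: 0.999
minMOMP cleavage at 240 min: 0.168
         without the timer: 0.304
```

A HeLa-like cell dies ~9 min after full MOMP (>25% of the effector
substrate cleaved).  After minority MOMP the same cell survives the 4-h
horizon: cleavage stalls at 17% — and removing the molecular timer nearly
doubles it, showing the timer actively suppressing execution after partial
release.

A thin CLI mirrors the library:

```bash
apoptimer simulate --momp-fraction 0.05 --t-end 240 --variant normal --out run1
apoptimer fit-spr --traces src/apoptimer/data/spr_traces_synthetic.csv --out fits.json
apoptimer cohort --n 1000 --seed 1 --momp-fraction 1.0 --out results/cohort
apoptimer roc --outcomes results/cohort --score balance
apoptimer synth patients --n 200 --seed 1 --out patients.csv
apoptimer patients --table patients.csv --out results/patients
```

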