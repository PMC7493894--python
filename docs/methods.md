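# Methods

## The model

The package simulates the execution phase of apoptosis downstream of
mitochondrial outer membrane permeabilisation (MOMP) as a deterministic
mass-action ODE system in units of µM and minutes.  MOMP itself is an
instantaneous operator transferring a fraction of the mitochondrial
cytochrome c (CytC) and SMAC pools to the cytosol; minority MOMP (minMOMP)
is the same operator with fraction 0.05.  Upstream Bcl-2 family signalling,
spatial effects, caspase-3 feedback cleavage of caspase-9 (D330), and
protein synthesis/degradation are out of scope (synthesis/degradation is
rejected at network build time rather than silently ignored).

Species and reactions:

1. **Apoptosome assembly.**  Cytosolic CytC activates APAF1 in a lumped
   bimolecular step (k_assembly, with a saturating ATP factor
   ATP/(ATP+100 µM) that is ≈1 at cellular ATP); seven activated APAF1 with
   seven CytC form one platform, tracked in platform units.  k_assembly =
   0.1 µM⁻¹min⁻¹ so that platform formation is complete within ~2 min of
   full CytC release (10 µM) and is ~20-fold slower after minMOMP — this
   single mass-action step reproduces the delayed, less efficient
   apoptosome formation that drives the slower IETDase onset after minMOMP.
2. **Cooperative PC9 recruitment.**  A first pro-caspase 9 (PC9) binds an
   empty platform reversibly and weakly (primary binding); a second PC9
   then binds the singly occupied platform much more strongly, directly
   forming a homodimer (secondary binding).  The platform:PC9 heterodimer
   and the homodimer are both catalytically active against the IETD site of
   pro-caspase 3 (PC3), with rate k_PC9 per PC9 moiety.
3. **The molecular timer.**  Only the homodimer autocleaves (k_auto, first
   order); both protomers convert to C9-35/12, one remaining bound and one
   released.  C9 re-binds the platform only weakly (kon_C9/koff_C9), and
   the C9-apoptosome is also catalytically poorer (k_C9 < k_PC9).  The
   apoptosome therefore shuts itself down on the timescale of PC9
   conversion plus C9 dissociation — the molecular timer.
4. **Effector step.**  Active caspase 3 (C3) cleaves a DEVD-site effector
   substrate (k_devd); the cleaved fraction is the apoptosis readout and
   a death event is the first crossing of 25% cleavage (root-refined by
   the integrator's event machinery; censoring at 240 min).
5. **XIAP.**  XIAP binds C3 (BIR2 site) and C9-35/12 (BIR3 site) — never
   uncleaved PC9 — and is neutralised by SMAC one-to-one.  XIAP capture of
   *platform-bound* C9 ejects the C9 (the platform is freed).  The
   alternative, an inhibited platform-bound complex, sequesters platforms
   and makes timer removal *decrease* substrate cleavage in XIAP-rich
   cells, inverting the ordering the variants are defined to probe.

### Variants

* `normal` — full model.
* `no_xiap` — XIAP total forced to zero.
* `no_timer` — autocleavage becomes a no-op at the platform: C9 inherits
  the secondary PC9 binding kinetics *and* the homodimer catalytic rate,
  so apoptosome activity persists; XIAP inhibition of C9 is retained, which
  keeps the XIAP and timer switches independent.
* `no_xiap_no_timer` — both removals.
* `noncleavable` — k_auto = 0: the experimental non-cleavable PC9 mutant,
  which escapes both the timer and XIAP inhibition of C9.

With these definitions, removing the timer or XIAP can only increase
substrate cleavage per cell.  The non-cleavable mutant is more lethal than
timer removal at the population level; single cells can deviate by ~10⁻³
in cleavage fraction because the C9 flux in the timer-off variant titrates
XIAP away from C3.

## Parameterisation

Fixed rates are literature-scale: XIAP–C3 (150 µM⁻¹min⁻¹ / 0.07 min⁻¹),
XIAP–C9 (100 / 1.2), SMAC–XIAP (240 / 0.1), all sub-nM to low-nM
affinities.  k_devd = 2 µM⁻¹min⁻¹ is an effective rate chosen once so the
25% cleavage threshold discriminates within the 240-min horizon: at the
~10-fold larger literature kcat/Km of purified C3 on DEVD substrates, any
cell producing trace C3 crosses the threshold within 4 h, which collapses
the resistant subpopulation the screens are built to study.  The cost is a
HeLa cleavage curve slightly shallower than its training target.

The binding and catalytic constants of the cooperative-recruitment step
are estimated by bounded multi-start least squares in log10 space
(`apoptimer.calibration`), against two equally weighted synthetic training
sets that emulate the published experiments:

* a Boltzmann substrate-cleavage curve (bottom 0, top 100%, half-time 15
  min post-MOMP, slope 2.5 min) for the HeLa-like baseline — APAF1 0.4,
  PC9 0.04, PC3 0.2, XIAP 0.3, SMAC 1.0, CytC 10, ATP 920 µM;
* relative maximal substrate-cleavage rates after 5–30 min apoptosome
  preincubation (APAF1 0.3, PC9 0.0125, CytC 10 µM, ATP 1 mM, then PC3
  0.5 and substrate 15 µM), decaying to a floor of 0.15 with a 15-min
  half-life;

plus the non-cleavable control of that protocol (no decline with delay) as
an additional residual, and two soft constraints: K_D(C9) > K_D(secondary)
(the timer precondition) and k_C9 ≤ 0.5·k_PC9 (non-cleavable apoptosomes
are the more active species).  Bounds are anchored to dissociation
kinetics extracted from synthetic SPR traces by the one-phase-decay fitter
(primary binding no stronger than the SPR estimate, secondary binding no
weaker), and a deterministic start at the SPR kinetics themselves is run
ahead of the Latin-hypercube starts.  The shipped defaults
(`data/defaults.yaml`) are the best of 11 starts (SSE 0.19; cleavage RMS
≈ 7%, timer-decline RMS ≈ 3%): primary 4.0 µM⁻¹min⁻¹ / 0.71 min⁻¹ (K_D
0.18 µM), secondary 592 / 0.040 (K_D 6.7·10⁻⁵ µM), k_auto 0.073 min⁻¹,
C9 binding 0.44 / 2.8 (K_D 6.4 µM), k_PC9 1.28, k_C9 0.074 µM⁻¹min⁻¹.

## Numerics

LSODA (stiff-capable) with absolute tolerance 10⁻¹⁹ µM and relative
tolerance 10⁻⁸; an exactly bilinear rate law lets a compiled one-sided
finite-difference Jacobian serve as an analytic one.  Dense output defaults
to one point per 10 s (1441 points / 240 min) to stabilise trapezoidal AUC
metrics; screens that only need checkpoints use coarser grids (the solution
itself is step-size controlled, not grid controlled).  Conserved moieties
(CytC, APAF1, PC9+C9, PC3+C3, XIAP, SMAC, substrate) stay constant to
better than 10⁻⁶ relative.  Death events are root-refined on the solver's
interpolant; trajectories without an attached event function fall back to
bisection on the dense output (10⁻⁶ min).  IETDase decay half-lives come
from a one-phase-decay fit of the post-maximum segment with y0 fixed at the
maximum and the plateau constrained nonnegative; non-decaying traces are
flagged with an infinite half-life rather than fitted.

## Study conditions for the screens

The physiological concentration ranges (µM, sampled independently and
uniformly; log-uniform available) are APAF1 0.05–1, PC9 0.0005–0.04,
PC3 0.02–2, XIAP 0.02–1, SMAC 0.02–1, with CytC and ATP fixed at the HeLa
values 10 and 920 µM.  PC9 is kept sub-stoichiometric to APAF1 (the ~1:10
cellular ratio): if PC9 exceeds the platform count, stable C9 binding in
the timer-off variant blocks platform recycling and timer removal can
*reduce* activity, which contradicts the behaviour the variants are defined
to expose.  The ~two-order-of-magnitude spans are consistent with the >100%
coefficients of variation reported for these proteins in tumours.

Screen protocols: classification screens simulate 1 h post-MOMP with and
without the timer and call a cell resistant at ≤25% cleavage (an 80%
cut-off is available); resistant cells are timer-dependent if timer removal
pushes them past the threshold.  ROC analysis scores raw input
concentrations (and the XIAP−SMAC balance, log10(XIAP/SMAC), zero at
equimolarity) with AUC oriented ≥0.5.  Survival screens run all four
variants to 240 min; Webb's fractional product is computed from surviving
fractions at 15/30/60/240 min and flagged synergistic strictly below 0.9.
After full MOMP no sampled cell survives 240 min without XIAP, so the
240-min (sometimes 60-min) Webb score has a zero denominator and is
reported undefined; medians are taken over the defined checkpoints.

The synthetic patient generator draws log-normal concentrations with
medians (PC9 0.02, PC3 0.30, XIAP 0.15, SMAC 0.20 µM) and CVs targeting
the dispersion reported for stage III colorectal tumours (XIAP 100%, PC9
154%, PC3 144%, SMAC 135%), fixes APAF1 at the 0.123 µM colorectal median,
classifies each profile by a 300-min full-MOMP simulation, and draws
exponential survival times whose hazard depends on the simulated class
(default hazard ratio 2, median DFS 60 months for capable patients,
independent censoring plus a 120-month administrative cut-off).  It
emulates the statistical structure of a clinical cohort, not RPPA
measurement error; passing tests demonstrate the pipeline's statistical
machinery, not clinical validity of the classifier.

## Problem sizes

Grid screens default to 25×25 (the acceptance script uses 15×15);
classification/ROC screens use 5,000 virtual cells and survival screens
1,000 cells per MOMP condition; the synthetic patient cohort is 150
patients.  These sizes give AUC standard errors of ~0.01 and keep a full
reanalysis to roughly ten minutes on one core.

## Known limitations

* The HeLa substrate-cleavage sigmoid is shallower than its Boltzmann
  training curve (no cooperativity or feedback in the effector step).
* Apoptosome assembly is a lumped step; CytC/APAF1 sub-complex dynamics
  and nucleotide exchange are not resolved.
* Absent degradation, C3 activity is irreversible, so survival without
  XIAP requires essentially zero caspase output; the no-XIAP arm
  consequently has no long-horizon survivors (see Webb note above).
* Timer-off is an idealised counterfactual (cleavage a no-op at the
  platform), one of several definitions compatible with published
  descriptions; sensitivity of conclusions to this choice can be probed
  through `ModelVariant` and parameter overrides.
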