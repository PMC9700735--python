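# nucleoforce

Analysis pipeline for single-molecule optical-tweezers experiments on
nucleosome arrays under constant tension, in the presence or absence of an
ATP-dependent chromatin remodeler (PICH).  The package covers the full
chain from raw-style data to published-scale quantities:

- **Step detection** in force-clamp distance–time traces: change-point
  fitting of horizontal plateaus, classification of ~26 nm inner-turn
  unwrapping steps (≥40 nm = double events, counted twice), and a
  net-increase filter that excludes transient loop-extrusion excursions.
- **Censored lifetime kinetics**: cumulative probability distributions of
  wrapped lifetimes (censored at the 10-minute window) and bi-exponential
  fits separating a slow canonical-nucleosome population from a fast
  minor (tetrasome) population.
- **Unwrapped-fraction statistics**: α = N_unwrapped/N_total with exact
  Clopper–Pearson intervals, the tetrasome correction
  α_corr = (α − 0.26)/(1 − 0.26), and a two-state Arrhenius-type model

      P(F) = 1 / (1 + exp(−(Δx/k_BT)(F − F_1/2)))

  fitted by binomial maximum likelihood, where F_1/2 is the half force of
  inner-turn unwrapping and Δx the distance to the transition state; the
  rate-limiting barrier is ΔG‡ = F_1/2·Δx.
- **Polymer mechanics**: extensible worm-like-chain extension, predicting
  the ~26 nm step from the ~80 bp inner turn released at 10 pN.
- **Fluorescence quantification**: kymograph intensity profiles, monomer
  PSF calibration, quantized multi-Gaussian decomposition into apparent
  oligomers, protein coverage counting, and pause/translocation
  segmentation of histone-sliding trajectories (pause < 3 nm/s).
- **Synthetic-data generators** for every input, with ground truth, so
  each stage is validated by recovery without instrument data.

## Worked example

```python
from nucleoforce.fractions import (
    ArrheniusFit, arrhenius_probability, delta_g, difference_curve)
from nucleoforce.mechanics import predicted_step_size

without = ArrheniusFit(f_half=10.6, delta_x=5.7)   # no remodeler
with_atp = ArrheniusFit(f_half=5.5, delta_x=4.4)   # remodeler + ATP

print(round(100 * arrhenius_probability(8.2, without), 1))  # 3.5
print(round(100 * arrhenius_probability(8.2, with_atp), 1)) # 94.7
print(round(delta_g(without), 1), round(delta_g(with_atp), 1))  # 14.7 5.9
dc = difference_curve(without, with_atp)
print(round(dc["peak_force"], 2),
      round(dc["fwhm_low"], 2), round(dc["fwhm_high"], 2))  # 8.26 5.34 10.72
print(round(predicted_step_size(10.0, 80), 1))  # 26.2
```

At 8.2 pN the within-window unwrapping probability rises from ~3.5% to
~95% when the remodeler and ATP are present; the free-energy barrier drops
from ~15 k_BT to ~6 k_BT; the remodeler is most effective between ~5.3 and
~10.7 pN, peaking near 8.3 pN; and the released 80 bp inner turn extends
to ~26 nm at the 10 pN clamp.

## Analysis scripts

The numbered drivers under `analysis/` run the study end to end on
synthetic data (the generated dataset lands in `scratch/`, summary tables
in `results/`):

```sh
python analysis/01_simulate_dataset.py    # traces, stretch curves, kymograph, tracks
python analysis/02_detect_steps.py        # plateau fits, event accounting, step sizes
python analysis/03_lifetime_kinetics.py   # censored CPDs, bi-exponential fits
python analysis/04_unwrap_fractions.py    # fractions, two-state fits, difference curve
python analysis/05_kymograph_oligomers.py # PSF calibration, oligomer counting
python analysis/06_sliding_trajectories.py# pause/translocation segmentation
```

A typical run reports a mean detected single-step size of 25.6 ± 0.4 nm,
two-state fits near (F_1/2, Δx) = (10.6 pN, 5.1 nm) and (5.0 pN, 3.3 nm)
for the two conditions, a difference-curve peak at 8.2 pN, a bound-protein
coverage of 7 on the low-coverage construct, and a mean sliding velocity
of 10.6 ± 0.3 nm/s.

The same pipeline is available as a CLI
(`nucleoforce simulate|stepfit|kinetics|fractions|report ...`).

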