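# axodiff

Axon diameter mapping with diffusion MRI hinges on hardware: the maximal
gradient strength *G*max of a scanner sets the smallest axon diameters a
pulsed-gradient spin-echo (PGSE) protocol can distinguish, while the tissue's
T2 caps the diffusion times and hence the largest diameters that leave a
signature. `axodiff` is a simulation and estimation toolkit for studying
exactly this: it synthesizes diffusion-weighted signals from known cylinder
substrates, fits the four-compartment minimal model of white matter diffusion
(MMWMD) to recover the axon diameter index *a*′, and quantifies how the
contrast and stability of *a*′ depend on *G*max, SNR and T2. It is written
for diffusion-MRI methods researchers who want a self-contained, seedable
pipeline rather than scanner data.

## The model in brief

A voxel's normalized PGSE signal is modelled as

    S = S0 · (f1·S_ic + f2·S_ec + f3·S_csf + f4)

* **intra-axonal** `S_ic`: parallel impermeable cylinders of a single
  diameter *a*′ — free Gaussian diffusion along the axis, Gaussian-phase-
  distribution (GPD) restricted signal perpendicular to it (series over roots
  of J₁′);
* **extra-axonal** `S_ec`: axially symmetric hindered tensor with the
  tortuosity link d⊥ = d∥·(1 − f1/(f1+f2));
* **CSF** `S_csf = exp(−b·d_iso)` and a **stationary** ("dot") compartment
  with no attenuation (fixed tissue).

Ground truth substrates are periodic packings of non-abutting cylinders with
gamma-distributed diameters; their idealized index is the volume-weighted
mean diameter **α = Σa³/Σa²**. Signals come either from a Monte-Carlo random
walk with specular reflection at cylinder walls or from the analytic
cylinder-mixture forward model. Fitting is three-stage (coarse grid →
quasi-Newton MAP → adaptive Metropolis MCMC); the reported *a*′ is the
posterior mean. A greedy optimizer reassigns a 360-measurement budget among
HARDI shells by the Cramér–Rao lower bound on *a*′. The optimized ex-vivo
protocol tables for *G*max = 60, 140, 200 and 300 mT/m ship as fixtures.

## Worked example

```bash
python examples/fit_single_voxel.py
```

```
true diameter:        4.00 um, f1 = 0.70
MAP estimate:         a' = 4.26 um, f1 = 0.75
posterior mean a':    4.29 um (90% interval 3.83-4.71, acceptance 25%)
the posterior mean is the value a voxel map of the diameter index reports
```

A 4 μm cylinder population at SNR 20 under the 300 mT/m protocol is
recovered to within a few tenths of a micrometre, with the posterior interval
quantifying the noise-limited precision. The other scripts in `examples/`
walk through the protocol tables (`protocol_tables.py`), substrate packing
and the α indices (`substrate_and_indices.py`), Monte-Carlo versus analytic
signals (`mc_vs_model.py`), the shell optimizer (`optimize_shells.py`), the
*G*max stability comparison (`gmax_comparison.py`) and the posterior window
of sensitivity (`sensitivity_window.py`).

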