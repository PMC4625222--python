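# emwedge

Strongly coupled electromechanics of a human left-ventricular wedge, in
normal and failing-heart conditions.

Transmural heterogeneity of repolarization — endocardial, midmyocardial
(M) and epicardial myocytes with different action-potential durations —
is a substrate for arrhythmia, and it is modulated by contraction: as the
wall thickens, cells move apart, electrotonic coupling weakens, and the
transmural dispersion of repolarization (TDR) grows. `emwedge` is a
simulation package for studying that feedback loop on an in-silico wedge
preparation: a 9×9×9 mm (normal) or 13×9×9 mm (failing, hypertrophic)
block of ventricular wall with transmural cell-type layering
(12 % endo / 60 % M / 28 % epi), fibers along y and the transmural axis
along x. It is aimed at computational cardiac electrophysiologists who
want a desk-scale, fully scriptable wedge model.

## Model

* **Myocyte**: ten Tusscher–Noble–Noble–Panfilov (2004) human ventricular
  ionic model (endo/M/epi variants) coupled one-way to the Rice et al.
  (2008) myofilament model; the normalized active force `T_a` drives
  contraction. Heart failure adds a late sodium current
  `I_NaL = g_NaL m_L³ h_L (v − E_Na)` and remodels conductances,
  exchanger and SERCA fluxes homogeneously and per cell type.
* **Tissue electrophysiology**: deformation-modified bidomain model,

  `χC_m ∂(Jv)/∂t + χJI_ion − Div(JF⁻¹D_iF⁻ᵀ Grad(v + u_e)) = 0`,
  `Div(JF⁻¹(D_i+D_e)F⁻ᵀ Grad u_e) = −Div(JF⁻¹D_iF⁻ᵀ Grad v)`,

  discretized with trilinear hexahedra and Crank–Nicolson/Rush–Larsen
  splitting (Δx = 0.5 mm, Δt = 0.05 ms). A 1-D transmural cable mode
  exploits the planar symmetry of the full-face stimulus protocol.
* **Mechanics**: quasistatic finite elasticity `div(FS) = 0` with the
  reduced transversely isotropic Holzapfel–Ogden energy
  `Ψ = a/2b (e^{b(I₁−3)}−1) + a_f/2b_f (e^{b_f(I₄f−1)²}−1)·[I₄f≥1]`
  plus fiber-aligned active stress
  `S_a = T_a^max T_a (f₀⊗f₀)/‖Ff₀‖²` (`T_a^max` = 50 kPa), solved with a
  three-field (mean-dilatation) Q1 formulation and incremental Newton.
* **Coupling**: explicit staggering — mechanics re-solved every 1 ms from
  the nodal active force, the resulting deformation gradient pulled back
  into the bidomain conductivities and mass.

Failing-heart tissue additionally reduces conductivities by 30 % and
(case 1) stiffens the passive law 5-fold; "case 2" keeps control
stiffness to isolate the myocyte-level contribution.

See `docs/methods.md` for equations, parameters, numerical choices and
known limitations.

## Worked example

Pace a normal and a failing epicardial myocyte to steady state:

```sh
$ emwedge cell --cell-type epi --out epi_nf.csv
epi: APD90 268.1 ms, Ca peak 0.964 uM, Ta peak 0.580 (43 beats) -> epi_nf.csv
$ emwedge cell --cell-type epi --hf --out epi_hf.csv
epi HF: APD90 355.8 ms, Ca peak 0.618 uM, Ta peak 0.225 (20 beats) -> epi_hf.csv
```

Heart failure prolongs the action potential (268 → 356 ms), depresses the
calcium transient (0.96 → 0.62 µM) and weakens the twitch (normalized
force 0.58 → 0.23) — the cellular signature the tissue model builds on.
The CSV holds the last beat (`time_ms,v_mV,Ca_i_mM,Ta_norm`).

Run the normal transmural cable (the planar-wave surrogate of the wedge)
and report dispersions:

```sh
$ emwedge cable --condition nf --t-total 600
disp ACT 32.9 ms, disp REP 25.9 ms, disp APD 32.4 ms -> cable.csv
```

Activation takes ≈33 ms to cross the 9 mm wall; electrotonic coupling
compresses the intrinsic 50 ms APD gap between cell types to ≈32 ms of
transmural APD dispersion. A quasistatic contraction solve at peak active
tension:

```sh
$ emwedge mechanics --static-peak --condition nf --out nf.vtk
nf: wall thickening 42.3% -> nf.vtk
```

Coupled electromechanics (thin-section wedge, deformation on/off) is
available through `emwedge wedge --condition nf --deformation on`;
experiment presets are serialized with `emwedge setup`.

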