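# stackmap

Integrated small- and wide-angle neutron-scattering (SANS/WANS) analysis of
self-assembling β-hairpin peptides, built around the model peptide CLN025 —
a 10-residue hairpin that stacks into charged elliptical-cylinder
assemblies in concentrated solution.

The package is for scattering and simulation practitioners who want a
tested, scriptable version of the full analysis chain:

* **Curve reduction** — reading 2–3 column I(Q) files, least-squares
  stitching of a wide-angle curve onto an absolutely scaled small-angle
  curve, and buffer subtraction with quadrature error propagation.
* **Total-scattering theory** — Q = 4π sin θ/λ, the Bragg map d = 2π/Q,
  partial structure factors S_αβ(Q) = ρ∫4πr²[g_αβ(r)−1] sinc(Qr) dr and
  their inverse, and the weighted total intensity
  I(Q) = Σ_{α≤β}(2−δ_αβ) c_α c_β b_α b_β S_αβ(Q) with exchangeable-hydrogen
  H/D contrast handled through effective scattering lengths.
* **The composite SANS model** — a repulsive elliptical cylinder with two
  Gaussian stacking peaks, a low-Q power law and a constant background:

  I(Q) = φ Δρ² V P_EC(Q) S_ER(Q) + α e^{−(Q−Q_ip)²/2σ_ip²}
        + β e^{−(Q−Q_is)²/2σ_is²} + γ Q^(−n) + bkg

  with P_EC the orientationally averaged elliptical-cylinder form factor
  and S_ER a rescaled-MSA screened-Coulomb structure factor (numerical
  Ornstein–Zernike solution with Hansen–Hayter rescaling).  A staged fit
  (power law → Gaussians → cylinder, optional joint polish) follows the
  term-by-term protocol that keeps the composite fit stable, and
  `stack_metrics` converts fitted parameters into stack geometry
  (d_ip = 2π/Q_ip, monomers per stack, aspect ratio, total charge).
* **Structure building** — Metropolis Monte Carlo rigid-body docking of
  hairpin monomers into stacks, and packing of a periodic solvated box
  (SPC/E-geometry waters, Na⁺ counterions).
* **Hydration analysis** — site–water RDFs under periodic boundaries, and
  the per-site hydrogen-bonding index Δ built from the first-peak shift
  D = r_XOw − r_XHw, normalised to R_donor = 0.96 Å (acceptors) or
  R_acceptor = r_OH cos(θ_HOH/2) ≈ 0.577 Å (donors): Δ = +1 is a perfect
  acceptor, −1 a perfect donor, 0 an orientationally indifferent site.
* **Synthetic data** — noisy model curves, orientation-biased hydration
  shells, and a reference solvated two-stack box, so the whole pipeline
  runs and is tested without beamline data.

## Worked example

Fit a synthetic noisy curve drawn at the reference cylinder parameters and
read off the stack geometry:

```python
import numpy as np
from stackmap import (REFERENCE_SANS_PARAMS, synth_sans_curve, staged_fit,
                      stack_metrics)

q = np.geomspace(0.003, 3.0, 400)            # 1/Å, the combined instrument range
curve = synth_sans_curve(REFERENCE_SANS_PARAMS, q, noise_fraction=0.01, seed=1)
result = staged_fit(curve, REFERENCE_SANS_PARAMS)
p = result.params
print(f"L = {p.length:.1f} Å, R = {p.r_minor:.2f} x {p.r_major:.2f} Å")
m = stack_metrics(p, per_monomer_charge=-2.0)
print(f"d_ip = {m.d_ip:.2f} Å, d_is = {m.d_is:.2f} Å, "
      f"{m.n_units} hairpins, {m.total_charge:+.0f} e")
```

prints

```
L = 59.7 Å, R = 6.38 x 12.78 Å
d_ip = 8.52 Å, d_is = 4.49 Å, 7 hairpins, -14 e
```

i.e. a ~60 Å cylinder of elliptical cross-section 6.5 × 12.6 Å holding
seven −2 e hairpins stacked 8.5 Å apart (two β-strands 4.5 Å apart within
each hairpin), total charge −14 e.

The hydration side runs the same way from synthetic shells:

```python
from stackmap import ShellSpec, synth_hydration_shell, delta_surface_map

shell = synth_hydration_shell(ShellSpec(bias=+1.0, seed=1))   # acceptor-like site
rec = delta_surface_map(shell, ["X"], r_max=10.0)[0]
print(f"Delta = {rec.delta:+.2f} ({rec.klass})")              # Delta = +1.00 (acceptor)
```

A `stackmap` command-line tool exposes the same operations
(`stackmap stitch`, `stackmap subtract`, `stackmap fit-sans`,
`stackmap build-stack`, `stackmap solvate`, `stackmap delta-map`,
`stackmap synth …`); see `stackmap --help`.

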