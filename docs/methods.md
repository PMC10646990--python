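# Methods

This note documents the models, conventions and numerical choices behind
the package, in the order the pipeline uses them.

## Scattering geometry and total-scattering conventions

Momentum transfer is Q = 4π sin(θ)/λ with θ half the scattering angle 2θ
(the angle quoted by diffractometers); repeat distances map to peak
positions through d = 2π/Q, an involution.  Partial structure factors use
the *interference* convention

S_αβ(Q) = ρ ∫ 4πr² [g_αβ(r) − 1] sin(Qr)/(Qr) dr,

i.e. the self (unity) term is excluded, so S_αβ → 0 at high Q and the
weighted sum I(Q) = Σ_{α≤β} (2−δ_αβ) c_α c_β b_α b_β S_αβ(Q) is a pure
interference intensity.  This choice makes the weight identity
Σ(2−δ)c c b b = (Σ c b)² hold exactly and leaves any self-scattering in
the experimental background term.  Transforms use trapezoidal quadrature
on the uniform r (or Q) grid; a Lorch-style taper is available (off by
default) for truncated data.  The forward/inverse pair is reciprocal to
better than 10⁻³ (max abs) on smooth functions for r ≤ 25 Å, Q ≤ 40 Å⁻¹,
excluding the first few bins below r ≈ 0.1 Å where the 1/r kernel
amplifies quadrature error.

Bound coherent scattering lengths (fm): H −3.739, D 6.671, C 6.646,
N 9.36, O 5.803, Na 3.63 (standard neutron data tables, Sears 1992).
Exchangeable hydrogens scatter as the solvent mixture
(1−x_D)·b_H + x_D·b_D; this is what makes a single set of partials
predict distinct H₂O/HDO/D₂O curves.

## Curve reduction

Stitching multiplies the wide-angle curve by the scalar minimising
Σ(s·I_wide − I_small)² over a user-chosen overlap window; the small-angle
curve is taken as the absolute (cm⁻¹) scale and its points win inside the
overlap.  No physical barns→cm⁻¹ conversion constant is applied — the
fitted scalar absorbs it, and the curve's unit tag records provenance.
Buffer subtraction defaults to fraction 1 (subtraction of a pure-solvent
scan) with σ combined in quadrature.  Duplicate Q points are averaged
(σ in quadrature of the mean) to keep grids strictly increasing.

## The composite small-angle model

I(Q) = φ Δρ² V_block P_EC(Q) S_ER(Q) + α G(Q; Q_ip, σ_ip)
      + β G(Q; Q_is, σ_is) + γ Q^(−n) + bkg

* **P_EC** — orientationally averaged elliptical-cylinder form factor,
  normalised to P_EC(0) = 1, evaluated by Gauss–Legendre quadrature over
  the axis polar angle and cross-section azimuth (default order 48 × 24;
  configurable).  At equal radii it agrees with the circular-cylinder
  closed form to better than 10⁻⁶ at high quadrature order.
* **S_ER** — structure factor of charged spheres with the DLVO
  screened-Coulomb tail βu(r) = γ₀σ e^{−κ(r−σ)}/r,
  γ₀ = Z²λ_B/(σ(1+κσ/2)²), κ from the ionic strength (mol/L),
  temperature and dielectric constant.  It is computed by a numerical
  Ornstein–Zernike solution under the MSA closure (Picard iteration with
  FFT sine transforms on a 4096-point grid, Δr = 0.005σ).  When the plain
  MSA produces a negative contact value g(σ⁺) — the weak-coupling/low-φ
  regime — the Hansen–Hayter rescaling maps to a larger effective core at
  fixed number density such that g vanishes at contact.  At Z = 0 the MSA
  closure coincides with Percus–Yevick for hard spheres, and the solver
  agrees with the analytic PY structure factor to ~3×10⁻⁵.  The effective
  diameter is that of the equal-volume sphere, σ = 2(3V_block/4π)^{1/3}
  (the mapping from cylinder to sphere is not uniquely defined; equal
  volume keeps φ consistent between the prefactor and the liquid-state
  model).  P·S coupling is a plain product — no β(Q) decoupling
  correction for anisotropy, a known limitation for strongly anisometric
  particles.
* φ and Δρ² are degenerate with one amplitude; the fitter therefore works
  with a single combined scale (φΔρ²V_block, cm⁻¹) and keeps the
  user-supplied φ fixed for the structure factor (φ is known from sample
  concentration in practice).  The Gaussian widths are free parameters.

### Staged fitting

Each term is fit on the window where it dominates, which keeps the
composite fit stable: (1) γ, n plus a local baseline on Q ≤ 10⁻² Å⁻¹;
(2) both Gaussians plus a local baseline on 0.5–3 Å⁻¹; (3) the cylinder
scale, L, R_minor, R_major (parameterised as R_minor × ratio ≥ R_minor),
|Z| and the background on 0.02–0.5 Å⁻¹ with stages 1–2 frozen; (4) an
optional joint polish of everything with bounds around the stage
estimates.  All windows are configurable.  Weighting is 1/σ² when σ is
present, else uniform on log I.  1-σ uncertainties come from the stage
Jacobians (linearised covariance); parameters that finish at a bound are
flagged in the result's warnings rather than silently accepted.  With the
polish enabled, a noiseless model curve is recovered to ≲0.1%; without
it, the per-stage windows introduce sub-percent biases (the other terms
are not exactly constant inside a stage window), which is far below the
uncertainties of interest here.

The geometric reading of a fit: d_ip = 2π/Q_ip (inter-hairpin stacking),
d_is = 2π/Q_is (inter-strand), monomers per stack = round(L/d_ip), total
charge = n_units × per-monomer charge.  If a fit returns Q_is < Q_ip the
labels are swapped with a warning so d_ip > d_is always holds.

## Stack building and solvation

The docking score used by `build_stack_mc` is a *reconstruction* — the
original protocol's scoring function is not public — combining a capped
soft-core repulsion Σ min((r₀/r)¹², cap), Debye-screened Coulomb
λ_B q_i q_j e^{−κr}/r between partial charges, and harmonic restraints
holding consecutive monomer centres at the target spacing along +z plus a
weak lateral term that keeps centres on the axis (this is what maintains
the ordered-stack invariant).  Moves are small rigid rotations (σ = 4°)
and translations (σ = 0.25 Å) of one monomer under a linear temperature
ramp; the best-scoring pose set is returned along with its non-increasing
best-score trace.  Runs are bit-reproducible for a fixed seed.  The stack
axis is +z by construction; the monomer is expected to lie flat in x–y
(hairpin plane perpendicular to the cylinder axis).

Solvation places stacks with centres at box fractions (2k+1)/2n on the x
axis — two stacks sit half a box width apart — then inserts rigid 3-site
waters (SPC/E geometry: OH 1.0 Å, HOH 109.47°, charges −0.8476/+0.4238 e)
and Na⁺ at random positions subject to a 2.0 Å minimum heavy-atom
distance (1.2 Å for pairs involving H), via a periodic cell list.  The
packing is rejection sampling, not equilibration: emitted boxes satisfy
contact and charge bookkeeping but are a starting point for refinement,
not a thermalised liquid.

## Hydration shells and the Δ index

Site–water RDFs are minimum-image histograms normalised per frame by
N_α ρ_β 4πr²Δr, with ρ_β = (N_β − δ_same)/V so an ideal gas sits at
g = 1 without 1/N bias; equivalent sites across monomers are pooled.
First-shell peaks are the first local maximum inside 1.0–3.5 Å with
g ≥ max(1.2, 0.2·max g in window), refined by quadratic interpolation;
the relative term suppresses counting-noise bumps on the rising edge when
g ≫ 1 (shell fragments normalised to a large box), while for
bulk-normalised RDFs the absolute threshold governs.  Sites whose
first-shell water-oxygen coordination number is below 0.5 are classified
buried.

Δ = D/R_donor for D = r_XOw − r_XHw ≥ 0 (acceptor) and D/R_acceptor for
D < 0 (donor), clamped to [−1, 1].  R_donor = 0.96 Å is the water OH bond
length; R_acceptor is computed from the water geometry as
r_OH cos(θ_HOH/2) = 0.577 Å — the peak shift that results when both
hydrogens point as far from the site as possible.  Clamping is needed
because finite-temperature peak positions can overshoot the geometric
endpoints (e.g. a strongly donating hydroxyl hydrogen can shift the
water-hydrogen peak by more than R_acceptor).  Classification is by the
sign of D; |Δ| < 0.1 is reported neutral.  Records store both D and the
normalisation used, so alternative conventions can be recovered.

## Synthetic data: what it emulates and what it does not

* **Curves** are exact model evaluations with i.i.d. multiplicative
  Gaussian noise and σ = noise·I.  They emulate counting statistics on a
  reduced curve, not instrument resolution smearing, incoherent
  inelasticity, or correlated reduction artefacts — so fit-recovery tests
  demonstrate estimator correctness under the stated noise model, not
  robustness to real-world systematics.  The reference parameter set
  (L = 60 Å, R = 6.5 × 12.6 Å, Z = −14 e, Q_ip = 2π/8.5, Q_is = 2π/4.5,
  n = 3, φ = 0.11 at 150 mg/mL, 250 mM 1:1 ionic strength, Δρ = 3.1×10⁻⁶ Å⁻²,
  γ = 3×10⁻⁷, bkg = 0.01 cm⁻¹) describes the assembled hairpin cylinder;
  amplitudes/widths of the Gaussians and the power law are chosen so each
  term dominates its observation window as in the measured curve.
* **Shells** place one ghost water per draw at Gaussian radial distance
  (2.8 ± 0.1 Å) with an orientation interpolated between three exactly
  realisable references: one OH pointing at the site (ω = +1), the
  distance-preserving neutral orientation with both OH direction cosines
  at −1/(2d), which puts both hydrogens at exactly the oxygen's distance
  (ω = 0), and the dipole-away orientation (ω = −1).  The HOH angle is
  preserved at every ω by solving for the azimuthal separation on the two
  cones.  The neutral reference was chosen over an isotropic orientation
  deliberately: an isotropically oriented rigid water at radius d has an
  X–H distance density ∝ r on [d−1, d+1], which after the 1/(4πr²) RDF
  normalisation decays like 1/r from the *near* edge — its first peak
  sits at ≈ d−1, and a "random orientation" baseline would therefore
  register as a strong acceptor (Δ ≈ +1), not as neutral.  The
  distance-preserving orientation is the correct zero of the first-peak
  statistic, and with it recovered Δ is strictly monotone in ω with exact
  endpoints.  Shells carry no water–water structure; they emulate an
  ensemble-averaged hydration shell, not a liquid configuration.
* **The reference box** (two 7-mer stacks of a 172-atom toy hairpin,
  6944 waters, 28 Na⁺, cube side 61.506 Å) reproduces the bookkeeping of
  the refined simulation — 23268 atoms, 0.100 atoms/Å³, net charge 0 —
  with a *geometric stand-in* monomer (two strands + turn, labelled
  Tyr-hydroxyl-like and Glu-carboxylate-like sites, net −2 e), not a
  crystal structure.  Real monomers are ingested as PDB plus a charge
  side table.

## Problem sizes used by the tests and the reproduction script

Recovery studies use 400 log-spaced points on 0.003–3 Å⁻¹, 1% noise and
20 seeds (medians reported); the power-law study uses 100 points on
0.003–0.03 Å⁻¹.  The RDF oracle comparisons run on ≤500-atom boxes where
the O(N²) reference is exact; Monte Carlo form-factor checks use
4×10⁵–10⁶ orientations.  These sizes were chosen so the whole suite runs
in minutes on one core while keeping every statistical bound several
standard errors wide.

## Known limitations

* No instrument resolution smearing or Placzek/inelasticity corrections;
  reduced curves are assumed fully corrected upstream.
* The P·S product neglects orientation–position coupling (no decoupling
  correction); adequate for the moderate aspect ratios here.
* The rescaled-MSA solver assumes a repulsive (Z², non-sign-resolved)
  Yukawa tail; attraction and polydispersity are out of scope.
* The docking score is a documented stand-in, not the original protocol;
  emitted stacks are geometrically sensible starting structures, not
  refined ensembles.
* Δ classification is purely geometric (sign of the peak shift); site
  chemistry is not consulted.
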