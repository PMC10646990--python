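"""Synthetic inputs for the whole pipeline, at desk scale.

Three generators stand in for the beamline data and the refined atomistic
ensemble:

* :func:`synth_sans_curve` draws noisy composite-model curves around a
  reference parameter set describing the self-assembled CLN025 hairpin
  cylinder at 150 mg/mL (length 60 Å, elliptical cross-section 6.5 × 12.6 Å,
  charge −14 e, stacking peaks at 2π/8.5 and 2π/4.5 Å⁻¹, a Q⁻³ low-Q power
  law) — these are the study conditions for all fit-recovery work.
* :func:`synth_hydration_shell` builds first hydration shells with a
  controllable orientation bias ω ∈ [−1, 1] around a labelled site, the
  test harness for the hydrogen-bonding index: ω = +1 places one OH bond
  pointing at the site (perfect acceptor geometry), ω = −1 points the
  dipole directly away (perfect donor geometry), ω = 0 is the
  distance-neutral orientation that leaves the site–hydrogen first peak at
  the site–oxygen distance.  Intermediate ω interpolates the OH direction
  cosines continuously, so the recovered Δ is strictly monotone in ω.
* :func:`synth_reference_config` builds the reference solvated two-stack
  box: 14 toy hairpin monomers (172 atoms each) in two 7-mer stacks,
  6944 SPC/E waters and 28 Na⁺ in a 61.506 Å cube — 23268 atoms at
  0.1 atoms/Å³ and zero net charge.

Shell waters are statistical samples (one ghost water per draw, no
water–water excluded volume): the shells emulate an ensemble-averaged
hydration structure, not a packed liquid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io_formats import AtomicConfiguration, Fragment, ScatteringCurve
from .sans_model import SANSModelParams, composite_intensity
from .structure_builder import (
    SPCE_CHARGES,
    WATER_ANGLE_DEG,
    WATER_OH,
    StackAssembly,
    build_stack_mc,
    solvate_box,
)

__all__ = [
    "REFERENCE_SANS_PARAMS",
    "ShellSpec",
    "synth_sans_curve",
    "synth_hydration_shell",
    "toy_hairpin_monomer",
    "synth_reference_config",
    "REFERENCE_BOX_SIDE",
    "REFERENCE_N_WATERS",
    "REFERENCE_N_IONS",
    "REFERENCE_N_MONOMERS",
]

#: Composition of the reference solvated box.
REFERENCE_BOX_SIDE = 61.506
REFERENCE_N_WATERS = 6944
REFERENCE_N_IONS = 28
REFERENCE_N_MONOMERS = 14

#: The fitted description of the hairpin cylinder at 150 mg/mL in D₂O with
#: 250 mM NaOH; all recovery studies generate data from this set.
REFERENCE_SANS_PARAMS = SANSModelParams()


def synth_sans_curve(
    params: SANSModelParams,
    q: np.ndarray,
    noise_fraction: float,
    seed: int,
    order: tuple[int, int] = (48, 24),
) -> ScatteringCurve:
    """Composite-model curve with multiplicative Gaussian noise.

    intensity = I_model(Q)·(1 + ε), ε ~ N(0, noise_fraction) i.i.d.; the σ
    column is noise_fraction · intensity (zero noise yields the model
    exactly, with σ = 0).
    """
    if noise_fraction < 0:
        raise ValueError("noise_fraction must be >= 0")
    model = composite_intensity(q, params, order)
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, 1.0, size=model.q.size) if noise_fraction > 0 else 0.0
    intensity = model.intensity * (1.0 + noise_fraction * eps)
    sigma = noise_fraction * np.abs(model.intensity)
    return ScatteringCurve(q=model.q, intensity=intensity, sigma=sigma, unit_tag="cm^-1")


# ----------------------------------------------------------------------------
# orientation-biased hydration shells


@dataclass
class ShellSpec:
    """Specification of one synthetic first hydration shell.

    ``bias`` is the orientation bias ω ∈ [−1, 1]; ``r_mean``/``r_spread``
    give the Gaussian radial distribution of the site–oxygen distance
    (default 2.8 ± 0.1 Å, a typical X–Ow hydrogen-bond distance).
    """

    site_label: str = "X"
    n_waters: int = 2000
    r_mean: float = 2.8
    r_spread: float = 0.1
    bias: float = 0.0
    seed: int = 0
    site_element: str = "O"

    def __post_init__(self) -> None:
        if self.n_waters < 1:
            raise ValueError("need at least one water")
        if self.r_mean <= 1.0:
            raise ValueError("mean radial distance must exceed 1 Å")
        if not -1.0 <= self.bias <= 1.0:
            raise ValueError("bias must lie in [-1, 1]")


def _orthonormal_frame(n_hat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors completing a right-handed frame with n_hat (vectorised)."""
    ref = np.where(np.abs(n_hat[:, 2:3]) < 0.9, [[0.0, 0.0, 1.0]], [[1.0, 0.0, 0.0]])
    e1 = np.cross(n_hat, ref)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(n_hat, e1)
    return e1, e2


def synth_hydration_shell(spec: ShellSpec) -> AtomicConfiguration:
    """Place oriented rigid waters around a site at the box centre.

    The OH direction cosines (measured against the outward site→oxygen
    axis) interpolate between three exactly realisable reference
    orientations:

    * ω = +1: one OH at cosine −1 (hydrogen directly at the site, first
      X–Hw peak at r_XOw − 1 Å), the other on the tetrahedral cone;
    * ω = 0: both OH at cosine −1/(2d) — elementary geometry puts both
      hydrogens then at exactly the oxygen's distance d from the site, so
      the X–Hw and X–Ow first peaks coincide and Δ = 0;
    * ω = −1: both OH at cosine +cos(θ_HOH/2), the dipole pointing away,
      which shifts the X–Hw peak outwards by ≈ r_OH·cos(θ_HOH/2).

    The HOH angle is preserved exactly at every ω by solving for the
    azimuthal separation of the two OH bonds on their cones.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_waters
    cos_hoh = np.cos(np.deg2rad(WATER_ANGLE_DEG))

    d = rng.normal(spec.r_mean, spec.r_spread, size=n)
    d = np.clip(d, 1.05, None)
    # random outward directions
    v = rng.normal(size=(n, 3))
    n_hat = v / np.linalg.norm(v, axis=1, keepdims=True)
    e1, e2 = _orthonormal_frame(n_hat)

    c0 = -1.0 / (2.0 * d)  # distance-preserving cosine
    w = spec.bias
    if w >= 0:
        c1 = (1.0 - w) * c0 + w * (-1.0)
        c2 = (1.0 - w) * c0 + w * (-cos_hoh - 0.0)  # -cos(109.47°) = +1/3
    else:
        c_away = np.cos(np.deg2rad(WATER_ANGLE_DEG) / 2.0)
        c1 = (1.0 + w) * c0 + (-w) * c_away
        c2 = c1.copy()
    s1 = np.sqrt(np.clip(1.0 - c1**2, 0.0, None))
    s2 = np.sqrt(np.clip(1.0 - c2**2, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        cos_dphi = np.where(
            s1 * s2 > 1e-12, (cos_hoh - c1 * c2) / np.where(s1 * s2 > 1e-12, s1 * s2, 1.0), 1.0
        )
    dphi = np.arccos(np.clip(cos_dphi, -1.0, 1.0))
    phi1 = rng.uniform(0.0, 2.0 * np.pi, size=n)
    sign = rng.choice((-1.0, 1.0), size=n)
    phi2 = phi1 + sign * dphi

    def oh_dir(c, s, phi):
        return (
            c[:, None] * n_hat
            + s[:, None] * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2)
        )

    o_pos = d[:, None] * n_hat
    h1 = o_pos + WATER_OH * oh_dir(c1, s1, phi1)
    h2 = o_pos + WATER_OH * oh_dir(c2, s2, phi2)

    box = max(8.0 * spec.r_mean, 40.0)
    centre = box / 2.0
    labels = [spec.site_label] + ["OW", "HW1", "HW2"] * n
    elements = [spec.site_element] + ["O", "H", "H"] * n
    positions = np.vstack(
        [np.zeros(3)] + [np.stack([o, a, b]) for o, a, b in zip(o_pos, h1, h2)]
    ) + centre
    charges = [0.0] + list(SPCE_CHARGES) * n
    exch = [False] + [False, True, True] * n
    mols = [0] + [1 + i for i in range(n) for _ in range(3)]
    return AtomicConfiguration(
        box_side=box,
        site_labels=np.array(labels, dtype=object),
        elements=np.array(elements, dtype=object),
        positions=positions,
        charges=np.array(charges, dtype=float),
        exchangeable=np.array(exch, dtype=bool),
        molecule_ids=np.array(mols, dtype=int),
    )


# ----------------------------------------------------------------------------
# toy hairpin monomer and the reference box


def _residue_atoms(kind: str) -> list[tuple[str, str, float, bool, tuple[float, float, float]]]:
    """(label, element, charge, exchangeable, offset) for one residue.

    Offsets are in a local frame: x outward (side-chain direction), y along
    the strand, z normal to the hairpin plane.  Every residue carries a
    6-atom backbone and an 11-atom side chain with charges summing to the
    residue's formal charge (0, or −1 for the carboxylate-bearing kind).
    """
    backbone = [
        ("N", "N", -0.42, False, (0.4, -1.8, 0.3)),
        ("HN", "H", 0.27, True, (0.5, -2.1, 1.25)),
        ("CA", "C", 0.02, False, (0.0, 0.0, 0.0)),
        ("HA1", "H", 0.06, False, (-0.45, 0.1, 1.0)),
        ("C", "C", 0.60, False, (0.4, 1.8, -0.3)),
        ("O", "O", -0.53, False, (1.35, 2.2, -0.95)),
    ]
    stem = [
        ("CB", "C", -0.12, False, (1.5, 0.2, -0.6)),
        ("HB1", "H", 0.06, False, (1.7, 1.05, -1.3)),
        ("HB2", "H", 0.06, False, (1.6, -0.75, -1.15)),
        ("CG", "C", -0.12, False, (2.8, 0.3, 0.2)),
        ("HG1", "H", 0.06, False, (2.9, 1.25, 0.8)),
        ("HG2", "H", 0.06, False, (2.9, -0.55, 0.95)),
    ]
    if kind == "generic":
        tip = [
            ("CD", "C", -0.12, False, (4.0, 0.2, -0.7)),
            ("HD1", "H", 0.06, False, (4.15, 1.05, -1.4)),
            ("HD2", "H", 0.06, False, (4.1, -0.7, -1.3)),
            ("CE", "C", -0.22, False, (5.3, 0.2, 0.1)),
            ("HE1", "H", 0.22, False, (6.2, 0.2, -0.5)),
        ]
    elif kind == "tyr":
        tip = [
            ("CZ", "C", -0.06, False, (4.0, 0.2, -0.7)),
            ("HZ1", "H", 0.06, False, (4.15, 1.1, -1.35)),
            ("YCZ", "C", 0.15, False, (5.3, 0.2, 0.1)),
            ("YOH", "O", -0.55, False, (6.45, 0.3, -0.65)),
            ("YHH", "H", 0.40, True, (7.3, 0.4, -0.1)),
        ]
    elif kind == "glu":
        tip = [
            ("HD1", "H", 0.06, False, (3.6, -0.9, 1.6)),
            ("HD2", "H", 0.06, False, (2.2, 1.5, 1.9)),
            ("ECD", "C", 0.70, False, (4.1, 0.2, -0.6)),
            ("EOE1", "O", -0.91, False, (5.2, 0.75, -0.3)),
            ("EOE2", "O", -0.91, False, (4.0, -0.5, -1.65)),
        ]
    else:
        raise ValueError(f"unknown residue kind {kind!r}")
    return backbone + stem + tip


def toy_hairpin_monomer() -> Fragment:
    """A 172-atom geometric stand-in for a capped 10-residue β-hairpin.

    Two antiparallel 4-residue strands joined by a 2-residue turn, flat in
    the x–y plane (stacking direction z), with labelled Tyr-hydroxyl-like
    (YOH/YHH) and Glu-carboxylate-like (ECD/EOE1/EOE2) sites.  Net charge
    exactly −2 e (two carboxylates).  This is a synthetic fixture — real
    monomer structures are ingested as PDB through the structure reader.
    """
    kinds = ["generic", "tyr", "glu", "generic", "generic",
             "generic", "generic", "glu", "generic", "generic"]
    labels, elements, charges, exch, positions = [], [], [], [], []
    for i, kind in enumerate(kinds):
        if i < 4:  # strand A, running +y
            origin = np.array([-2.6, -9.0 + 6.0 * i, 0.0])
            ex, ey = np.array([-1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])
        elif i < 6:  # turn, across the top (chain runs left to right)
            origin = np.array([-2.5 + 5.0 * (i - 4), 13.8, 0.0])
            ex = np.array([0.0, 1.0, 0.0])
            ey = np.array([1.0, 0.0, 0.0])
        else:  # strand B, running -y
            origin = np.array([2.6, 9.0 - 6.0 * (i - 6), 0.0])
            ex, ey = np.array([1.0, 0.0, 0.0]), np.array([0.0, -1.0, 0.0])
        ez = np.cross(ex, ey)
        flip = 1.0 if i % 2 == 0 else -1.0  # alternate side chains above/below
        for label, element, charge, x_flag, (ox, oy, oz) in _residue_atoms(kind):
            positions.append(origin + ox * ex + oy * ey + flip * oz * ez)
            labels.append(label)
            elements.append(element)
            charges.append(charge)
            exch.append(x_flag)
    # caps: acetyl-like on the strand-A N terminus, amide-like on strand B
    positions.append(np.array([-2.6, -11.6, 0.6]))
    labels.append("CAC"); elements.append("C"); charges.append(0.0); exch.append(False)
    positions.append(np.array([2.6, -11.6, -0.6]))
    labels.append("NTC"); elements.append("N"); charges.append(0.0); exch.append(False)
    frag = Fragment(
        site_labels=np.array(labels, dtype=object),
        elements=np.array(elements, dtype=object),
        positions=np.array(positions, dtype=float),
        charges=np.array(charges, dtype=float),
        exchangeable=np.array(exch, dtype=bool),
    )
    assert len(frag) == 172, len(frag)
    return frag.centered()


def synth_reference_config(
    seed: int,
    *,
    n_units: int = 7,
    n_stacks: int = 2,
    spacing: float = 8.5,
    n_waters: int = REFERENCE_N_WATERS,
    n_ions: int = REFERENCE_N_IONS,
    box_side: float = REFERENCE_BOX_SIDE,
    mc_steps: int = 600,
) -> AtomicConfiguration:
    """The reference solvated two-stack box (23268 atoms, 0.1 atoms/Å³, net 0 e).

    Two 7-mer stacks of the toy monomer are built by Monte Carlo docking at
    the inter-hairpin spacing, placed half a box width apart, and hydrated
    with 6944 waters and 28 Na⁺.
    """
    seeds = np.random.SeedSequence(seed).generate_state(n_stacks + 1)
    monomer = toy_hairpin_monomer()
    stacks = [
        build_stack_mc(monomer, n_units, spacing, int(seeds[k]) % 2**31, n_steps=mc_steps)
        for k in range(n_stacks)
    ]
    return solvate_box(
        stacks, n_waters, n_ions, box_side, int(seeds[-1]) % 2**31
    )
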