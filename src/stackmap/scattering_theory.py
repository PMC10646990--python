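"""Total-scattering theory: momentum transfer, Bragg distances, partial
structure factors and their concentration/scattering-length weighting.

The conventions used throughout:

* ``Q = 4π sin(θ)/λ`` with θ half the scattering angle 2θ.
* A repeat distance maps to a peak position through ``d = 2π/Q``.
* Partial structure factors exclude the self (unity) term,

  .. math:: S_{αβ}(Q) = ρ ∫ 4πr² \\,[g_{αβ}(r) − 1]\\, \\frac{\\sin Qr}{Qr}\\,dr,

  so ``S_αβ → 0`` at high Q and the weighted total intensity

  .. math:: I(Q) = \\sum_{α≤β} (2 − δ_{αβ})\\, c_α c_β b_α b_β S_{αβ}(Q)

  is a pure interference term.  Weights use *effective* scattering lengths:
  exchangeable hydrogens scatter as the H/D mixture of the solvent.

Bound coherent scattering lengths are from the standard neutron data
tables (Sears, Neutron News 3 (1992) 26), in fm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io_formats import DiffractionSetup, ScatteringCurve

__all__ = [
    "COHERENT_B_FM",
    "CompositionTable",
    "PartialStructureFactorSet",
    "RDF",
    "RDFSet",
    "q_from_geometry",
    "d_from_q",
    "q_from_d",
    "effective_scattering_length",
    "partial_sq_from_rdf",
    "gr_from_sq",
    "total_iq_from_partials",
]

#: Bound coherent neutron scattering lengths, fm (Sears 1992).
COHERENT_B_FM: dict[str, float] = {
    "H": -3.7390,
    "D": 6.671,
    "C": 6.6460,
    "N": 9.36,
    "O": 5.803,
    "Na": 3.63,
}


def q_from_geometry(setup: DiffractionSetup) -> float:
    """Momentum transfer Q = 4π sin(θ)/λ in Å⁻¹ (θ = half of 2θ)."""
    theta = np.deg2rad(setup.scattering_angle) / 2.0
    return float(4 * np.pi * np.sin(theta) / setup.wavelength)


def d_from_q(q):
    """Bragg repeat distance d = 2π/Q (Å); the inverse map is identical."""
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("Q must be positive")
    out = 2 * np.pi / q
    return float(out) if out.ndim == 0 else out


#: d = 2π/Q is an involution, so the inverse conversion is the same function.
q_from_d = d_from_q


def effective_scattering_length(element: str, exchangeable: bool, x_d: float) -> float:
    """Coherent b (fm) of a site, accounting for solvent H/D exchange.

    A non-exchangeable site scatters with its tabulated value; an
    exchangeable hydrogen scatters as (1−x_D)·b_H + x_D·b_D where x_D is the
    deuterium fraction of the solvent.
    """
    if element not in COHERENT_B_FM:
        raise ValueError(f"unsupported element {element!r}")
    if not 0 <= x_d <= 1:
        raise ValueError("x_d must lie in [0, 1]")
    if exchangeable and element in ("H", "D"):
        return (1 - x_d) * COHERENT_B_FM["H"] + x_d * COHERENT_B_FM["D"]
    return COHERENT_B_FM[element]


def _pair_key(alpha: str, beta: str) -> tuple[str, str]:
    return (alpha, beta) if alpha <= beta else (beta, alpha)


@dataclass
class CompositionTable:
    """Number fractions, elements and exchange flags of the atom types in a box.

    ``types`` maps a type label to ``(concentration, element, exchangeable)``.
    ``x_d`` is the solvent deuterium fraction, ``rho`` the total number
    density in atoms·Å⁻³.
    """

    types: dict[str, tuple[float, str, bool]]
    x_d: float
    rho: float

    def __post_init__(self) -> None:
        total = sum(c for c, _, _ in self.types.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"concentrations must sum to 1 (got {total!r})")
        if not 0 <= self.x_d <= 1:
            raise ValueError("x_d must lie in [0, 1]")
        if self.rho <= 0:
            raise ValueError("number density must be positive")

    def concentration(self, label: str) -> float:
        return self.types[label][0]

    def effective_b(self, label: str) -> float:
        c, element, exch = self.types[label]
        return effective_scattering_length(element, exch, self.x_d)


@dataclass
class RDF:
    """A single site-pair radial distribution function on a uniform r grid."""

    r: np.ndarray
    g: np.ndarray
    pair: tuple[str, str]

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.r.shape != self.g.shape:
            raise ValueError("r and g must have equal length")
        dr = np.diff(self.r)
        if dr.size and not np.allclose(dr, dr[0], rtol=1e-8):
            raise ValueError("r grid must be uniform")
        if np.any(self.g < 0):
            raise ValueError("g(r) must be non-negative")


@dataclass
class RDFSet:
    """Site-pair RDFs sharing one r grid, with the box number density."""

    r: np.ndarray
    pairs: dict[tuple[str, str], np.ndarray]
    rho: float
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.rho <= 0:
            raise ValueError("number density must be positive")
        self.pairs = {_pair_key(*k): np.asarray(v, dtype=float) for k, v in self.pairs.items()}
        for v in self.pairs.values():
            if v.shape != self.r.shape:
                raise ValueError("every g(r) must share the r grid")

    def to_frame(self) -> pd.DataFrame:
        cols = {"r": self.r}
        cols.update({f"{a}-{b}": g for (a, b), g in self.pairs.items()})
        return pd.DataFrame(cols)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class PartialStructureFactorSet:
    """Interference partial structure factors S_αβ(Q) on one Q grid."""

    q: np.ndarray
    pairs: dict[tuple[str, str], np.ndarray]

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.pairs = {_pair_key(*k): np.asarray(v, dtype=float) for k, v in self.pairs.items()}
        for v in self.pairs.values():
            if v.shape != self.q.shape:
                raise ValueError("every S(Q) must share the Q grid")

    def to_frame(self) -> pd.DataFrame:
        cols = {"q": self.q}
        cols.update({f"{a}-{b}": s for (a, b), s in self.pairs.items()})
        return pd.DataFrame(cols)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _sinc(x: np.ndarray) -> np.ndarray:
    # sin(x)/x with the x→0 limit; np.sinc is normalised to π
    return np.sinc(x / np.pi)


def lorch_window(r: np.ndarray, r_max: float) -> np.ndarray:
    """Lorch taper sin(πr/r_max)/(πr/r_max), suppressing truncation ripple."""
    return _sinc(np.pi * r / r_max)


def partial_sq_from_rdf(
    rdf: RDFSet, q: np.ndarray, taper: bool = False
) -> PartialStructureFactorSet:
    """Sine-transform g_αβ(r) − 1 into interference partials S_αβ(Q).

    Trapezoidal quadrature on the (uniform) r grid; ``taper`` applies a
    Lorch window to [g − 1] before transforming.  The Q = 0 point is
    evaluated through the sin(Qr)/(Qr) → 1 limit.
    """
    q = np.asarray(q, dtype=float)
    r = rdf.r
    window = lorch_window(r, r[-1]) if taper else 1.0
    kernel = _sinc(np.outer(q, r))  # (nq, nr)
    out: dict[tuple[str, str], np.ndarray] = {}
    for pair, g in rdf.pairs.items():
        integrand = 4 * np.pi * r**2 * (g - 1.0) * window
        out[pair] = rdf.rho * np.trapezoid(kernel * integrand, r, axis=1)
    return PartialStructureFactorSet(q=q, pairs=out)


def gr_from_sq(psf: PartialStructureFactorSet, rho: float, r: np.ndarray) -> RDFSet:
    """Inverse sine transform: g(r) = 1 + (2π²ρ)⁻¹ ∫ Q² S(Q) sinc(Qr) dQ.

    Requires a uniform Q grid extending far enough that S has decayed;
    this is the reciprocal normalisation of :func:`partial_sq_from_rdf`.
    """
    q = psf.q
    dq = np.diff(q)
    if dq.size == 0 or not np.allclose(dq, dq[0], rtol=1e-8):
        raise ValueError("inverse transform requires a uniform Q grid")
    if rho <= 0:
        raise ValueError("number density must be positive")
    r = np.asarray(r, dtype=float)
    kernel = _sinc(np.outer(r, q))  # (nr, nq)
    out: dict[tuple[str, str], np.ndarray] = {}
    for pair, s in psf.pairs.items():
        integrand = q**2 * s
        out[pair] = np.clip(
            1.0 + np.trapezoid(kernel * integrand, q, axis=1) / (2 * np.pi**2 * rho),
            0.0,
            None,
        )
    return RDFSet(r=r, pairs=out, rho=rho)


def pair_weight(comp: CompositionTable, alpha: str, beta: str) -> float:
    """(2 − δ_αβ) c_α c_β b_α b_β, in fm² (effective b, exchange-aware)."""
    w = (
        comp.concentration(alpha)
        * comp.concentration(beta)
        * comp.effective_b(alpha)
        * comp.effective_b(beta)
    )
    return w if alpha == beta else 2.0 * w


def total_iq_from_partials(
    psf: PartialStructureFactorSet, comp: CompositionTable
) -> ScatteringCurve:
    """Weighted sum of partials: I(Q) = Σ_{α≤β} (2−δ)c_αc_βb_αb_β S_αβ(Q).

    With b in fm, the result is in barns·sr⁻¹·atom⁻¹ (1 barn = 100 fm²);
    the same partial set yields distinct H₂O/HDO/D₂O predictions through the
    composition's solvent deuteration x_D.
    """
    missing = sorted({t for pair in psf.pairs for t in pair} - set(comp.types))
    if missing:
        raise ValueError(f"composition is missing atom types: {missing}")
    total = np.zeros_like(psf.q)
    for (alpha, beta), s in psf.pairs.items():
        total = total + pair_weight(comp, alpha, beta) * s / 100.0  # fm² → barn
    sort = np.argsort(psf.q)
    return ScatteringCurve(
        q=psf.q[sort], intensity=total[sort], sigma=None, unit_tag="barns/sr/atom"
    )
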