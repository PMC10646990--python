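"""Composite small-angle model for stacked-hairpin cylinders and its staged fit.

The model is a repulsive elliptical cylinder plus two Gaussian peaks, a
low-Q power law and a constant background:

.. math::

    I(Q) = φ Δρ² V_\\text{block} P_\\text{EC}(Q) S_\\text{ER}(Q)
         + α e^{-(Q-Q_{ip})²/2σ_{ip}²} + β e^{-(Q-Q_{is})²/2σ_{is}²}
         + γ Q^{-n} + \\text{bkg}

* ``P_EC`` is the orientationally averaged elliptical-cylinder form factor,
  normalised to 1 at Q = 0 and evaluated by fixed-order Gauss–Legendre
  quadrature over the cylinder-axis polar angle and cross-section azimuth.
* ``S_ER`` is a rescaled mean-spherical-approximation structure factor for
  charged spheres with screened-Coulomb (Yukawa) repulsion, computed by a
  numerical Ornstein–Zernike solver with the Hansen–Hayter contact-value
  rescaling.  The effective diameter is that of the sphere with the same
  volume as the cylinder.
* The two Gaussians model the mid-Q inter-hairpin and inter-strand stacking
  peaks; their centres convert to distances through d = 2π/Q.
* The power law captures the upturn from large, dilute aggregates at the
  lowest Q.

Fitting follows the term-by-term protocol: the power law is fit on the
lowest-Q window, the Gaussians on the mid-Q window, the cylinder prefactor,
geometry and charge on the intermediate window with the other terms frozen,
and an optional final polish refines everything jointly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.fft import dst
from scipy.optimize import brentq, least_squares
from scipy.special import j1, roots_legendre

from .io_formats import ScatteringCurve
from .units import INV_ANGSTROM_TO_INV_CM, bjerrum_length, debye_kappa

__all__ = [
    "SANSModelParams",
    "StackGeometry",
    "StagedFitConfig",
    "SANSFitResult",
    "StageFitError",
    "MSAConvergenceError",
    "elliptical_cylinder_form_factor",
    "charged_structure_factor",
    "composite_intensity",
    "model_terms",
    "staged_fit",
    "stack_metrics",
]


class StageFitError(RuntimeError):
    """A fit stage failed (insufficient window coverage or non-convergence)."""


class MSAConvergenceError(RuntimeError):
    """The MSA solver found no physical solution for the given parameters."""


# ----------------------------------------------------------------------------
# parameters


@dataclass
class SANSModelParams:
    """All parameters of the composite model plus cylinder geometry and charge.

    Lengths in Å, Q in Å⁻¹, Δρ in Å⁻², charge in e, ionic strength in mol/L,
    amplitudes and background on the intensity scale of the data (cm⁻¹).
    """

    phi: float = 0.11                  # volume fraction of cylinders
    drho: float = 3.1e-6               # neutron contrast, Å⁻²
    length: float = 60.0               # cylinder length L, Å
    r_minor: float = 6.5               # minor cross-section radius, Å
    r_major: float = 12.6              # major cross-section radius, Å
    charge: float = -14.0              # total charge per cylinder, e
    ionic_strength: float = 0.25       # mol/L
    temperature: float = 298.0         # K
    dielectric: float = 78.3
    gauss_ip_amp: float = 0.05         # α, inter-hairpin peak amplitude
    gauss_is_amp: float = 0.035        # β, inter-strand peak amplitude
    q_ip: float = 2 * np.pi / 8.5      # inter-hairpin peak centre, Å⁻¹
    q_is: float = 2 * np.pi / 4.5      # inter-strand peak centre, Å⁻¹
    sigma_ip: float = 0.12             # Å⁻¹
    sigma_is: float = 0.25             # Å⁻¹
    powerlaw_amp: float = 3.0e-7       # γ (intensity at Q = 1 Å⁻¹)
    powerlaw_exp: float = 3.0          # n
    background: float = 0.01           # bkg, cm⁻¹
    scale: float | None = None         # overrides φ·Δρ²·V_block when set, cm⁻¹

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0 < self.phi < 0.74:
            raise ValueError("volume fraction must lie in (0, 0.74)")
        for name in ("length", "r_minor", "r_major", "sigma_ip", "sigma_is"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.r_major < self.r_minor:
            raise ValueError("r_major must be >= r_minor")
        if self.powerlaw_exp <= 0:
            raise ValueError("power-law exponent must be positive")

    @property
    def v_block(self) -> float:
        """Cylinder volume π·R_minor·R_major·L, Å³."""
        return np.pi * self.r_minor * self.r_major * self.length

    @property
    def effective_diameter(self) -> float:
        """Diameter of the equal-volume sphere used by the structure factor."""
        return 2.0 * (3.0 * self.v_block / (4.0 * np.pi)) ** (1.0 / 3.0)

    @property
    def effective_scale(self) -> float:
        """Cylinder-term prefactor φ·Δρ²·V_block on the cm⁻¹ scale."""
        if self.scale is not None:
            return self.scale
        return self.phi * self.drho**2 * self.v_block * INV_ANGSTROM_TO_INV_CM

    def to_dict(self) -> dict[str, float]:
        keys = [
            "phi", "drho", "length", "r_minor", "r_major", "charge",
            "ionic_strength", "temperature", "dielectric",
            "gauss_ip_amp", "gauss_is_amp", "q_ip", "q_is",
            "sigma_ip", "sigma_is", "powerlaw_amp", "powerlaw_exp",
            "background",
        ]
        out = {k: float(getattr(self, k)) for k in keys}
        out["scale"] = float(self.effective_scale)
        return out


@dataclass
class StackGeometry:
    """Geometric reading of a fitted parameter set."""

    n_units: int
    d_ip: float
    d_is: float
    aspect_ratio: float
    total_charge: float

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("a stack holds at least one monomer")
        if not self.d_ip > self.d_is > 0:
            raise ValueError("expected d_ip > d_is > 0")
        if self.aspect_ratio < 1:
            raise ValueError("aspect ratio is R_major/R_minor >= 1")


# ----------------------------------------------------------------------------
# elliptical-cylinder form factor


def elliptical_cylinder_form_factor(
    q,
    length: float,
    r_minor: float,
    r_major: float,
    order: tuple[int, int] = (48, 24),
):
    """Orientationally averaged form factor of an elliptical cylinder.

    .. math::

        P(Q) = ∫_0^{π/2} dα \\sinα \\; \\frac{2}{π} ∫_0^{π/2} dψ
               \\left[ \\frac{2 J_1(Q r(ψ) \\sinα)}{Q r(ψ) \\sinα}
                       \\frac{\\sin(Q L \\cosα / 2)}{Q L \\cosα / 2} \\right]^2

    with r(ψ)² = R_minor² sin²ψ + R_major² cos²ψ.  Normalised so P(0) = 1.
    ``order`` sets the Gauss–Legendre orders for (α, ψ).
    """
    if length <= 0 or r_minor <= 0 or r_major < r_minor:
        raise ValueError("need length > 0 and r_major >= r_minor > 0")
    q = np.asarray(q, dtype=float)
    scalar = q.ndim == 0
    qv = np.atleast_1d(q)
    if np.any(qv < 0):
        raise ValueError("Q must be non-negative")

    n_alpha, n_psi = order
    xa, wa = roots_legendre(n_alpha)
    xp, wp = roots_legendre(n_psi)
    alpha = 0.25 * np.pi * (xa + 1.0)        # (0, π/2)
    w_alpha = 0.25 * np.pi * wa * np.sin(alpha)
    psi = 0.25 * np.pi * (xp + 1.0)
    w_psi = 0.25 * np.pi * wp * (2.0 / np.pi)

    r_psi = np.sqrt((r_minor * np.sin(psi)) ** 2 + (r_major * np.cos(psi)) ** 2)
    # shapes: q (nq,1,1), alpha (na,1), psi (np,)
    a = qv[:, None, None] * np.sin(alpha)[None, :, None] * r_psi[None, None, :]
    b = qv[:, None, None] * np.cos(alpha)[None, :, None] * (length / 2.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        radial = np.where(a > 1e-10, 2.0 * j1(a) / np.where(a > 1e-10, a, 1.0), 1.0)
        axial = np.where(np.abs(b) > 1e-10, np.sin(b) / np.where(np.abs(b) > 1e-10, b, 1.0), 1.0)
    amp2 = (radial * axial) ** 2
    p = np.einsum("qap,a,p->q", amp2, w_alpha, w_psi)
    return float(p[0]) if scalar else p


# ----------------------------------------------------------------------------
# charged-sphere structure factor (OZ + MSA + Hansen–Hayter rescaling)

_OZ_N = 4096
_OZ_DR = 0.005  # in units of the (rescaled) hard-core diameter
_OZ_R = (np.arange(_OZ_N) + 0.5) * _OZ_DR
_OZ_K = np.pi * (np.arange(_OZ_N) + 1) / (_OZ_N * _OZ_DR)
_OZ_CORE = _OZ_R < 1.0


class _MSASolver:
    """Picard/FFT Ornstein–Zernike solver with the MSA closure.

    Works in reduced units (hard-core diameter = 1); keeps the last
    converged indirect correlation function as a warm start, which makes
    repeated calls with nearby parameters (as in a fit loop) cheap.
    """

    def __init__(self) -> None:
        self._warm: np.ndarray | None = None
        self.last_rescale: float | None = None

    def solve(
        self, phi: float, kappa_sigma: float, contact_potential: float,
        tol: float = 1e-9, max_iter: int = 8000, mix: float = 0.45,
    ) -> tuple[np.ndarray, np.ndarray, float]:
        """Return (γ_indirect(r), βu(r), ρ) at convergence."""
        rho = 6.0 * phi / np.pi
        u = np.where(
            _OZ_CORE, 0.0,
            contact_potential * np.exp(-kappa_sigma * (_OZ_R - 1.0)) / _OZ_R,
        )
        g = self._warm.copy() if self._warm is not None else np.zeros(_OZ_N)
        fw = 2.0 * np.pi * _OZ_DR
        dk = np.pi / (_OZ_N * _OZ_DR)
        iw = dk / (4.0 * np.pi**2)
        for _ in range(max_iter):
            c = np.where(_OZ_CORE, -1.0 - g, -u)
            ch = fw / _OZ_K * dst(_OZ_R * c, type=2)
            denom = 1.0 - rho * ch
            if np.any(denom <= 0):
                raise MSAConvergenceError(
                    f"MSA has no physical solution at phi={phi:.4g}, "
                    f"kappa*sigma={kappa_sigma:.4g}, contact={contact_potential:.4g}"
                )
            gh = rho * ch * ch / denom
            g_new = iw / _OZ_R * dst(_OZ_K * gh, type=3)
            err = np.max(np.abs(g_new - g))
            g = (1.0 - mix) * g + mix * g_new
            if err < tol:
                self._warm = g.copy()
                return g, u, rho
        raise MSAConvergenceError(
            f"OZ iteration did not converge at phi={phi:.4g}, "
            f"kappa*sigma={kappa_sigma:.4g}, contact={contact_potential:.4g}"
        )

    @staticmethod
    def contact_value(g_ind: np.ndarray, u: np.ndarray) -> float:
        """g(r) extrapolated to the outside of the hard core, r → 1⁺."""
        sel = (_OZ_R > 1.0) & (_OZ_R < 1.0 + 10 * _OZ_DR)
        coeffs = np.polyfit(_OZ_R[sel], 1.0 + g_ind[sel] - u[sel], 2)
        return float(np.polyval(coeffs, 1.0))

    @staticmethod
    def sq(q_sigma: np.ndarray, g_ind: np.ndarray, u: np.ndarray, rho: float) -> np.ndarray:
        """S(qσ) = 1/(1 − ρ ĉ) from the converged direct correlation."""
        c = np.where(_OZ_CORE, -1.0 - g_ind, -u)
        q_sigma = np.atleast_1d(np.asarray(q_sigma, dtype=float))
        out = np.empty_like(q_sigma)
        rc = _OZ_R * c
        for i, qq in enumerate(q_sigma):
            if qq < 1e-12:
                ch = 4.0 * np.pi * _OZ_DR * np.sum(_OZ_R**2 * c)
            else:
                ch = 4.0 * np.pi * _OZ_DR / qq * np.sum(rc * np.sin(qq * _OZ_R))
            out[i] = 1.0 / (1.0 - rho * ch)
        return out


_solver = _MSASolver()


def charged_structure_factor(
    q,
    phi: float,
    charge: float,
    effective_diameter: float,
    ionic_strength: float = 0.25,
    temperature: float = 298.0,
    dielectric: float = 78.3,
):
    """Rescaled-MSA structure factor for screened-Coulomb repulsive spheres.

    The pair potential outside the hard core of diameter σ is the DLVO
    screened Coulomb form βu(r) = γ₀ σ e^{−κ(r−σ)}/r with contact strength
    γ₀ = Z² λ_B / (σ (1 + κσ/2)²).  If the plain MSA yields a negative
    contact value g(σ⁺), the Hansen–Hayter rescaling maps the system onto a
    larger effective core (same number density, same potential tail) chosen
    so that g vanishes at contact.
    """
    if not 0 < phi <= 0.5:
        raise ValueError("volume fraction must lie in (0, 0.5] for the MSA solver")
    if effective_diameter <= 0:
        raise ValueError("effective diameter must be positive")
    sigma = effective_diameter
    kappa = debye_kappa(ionic_strength, temperature, dielectric)
    lam_b = bjerrum_length(temperature, dielectric)
    k_sig = kappa * sigma
    gamma0 = charge**2 * lam_b / (sigma * (1.0 + 0.5 * k_sig) ** 2)

    def state_at(s: float):
        return _solver.solve(
            phi * s**3, k_sig * s, gamma0 * np.exp(-k_sig * (s - 1.0)) / s
        )

    g_ind, u, rho = state_at(1.0)
    s_star = 1.0
    if _MSASolver.contact_value(g_ind, u) < -1e-10 and gamma0 > 0:
        # Hansen–Hayter: grow the core until g(contact) = 0
        s_max = min((0.5 / phi) ** (1.0 / 3.0), 10.0)

        def contact_of(s: float) -> float:
            gi, uu, _ = state_at(s)
            return _MSASolver.contact_value(gi, uu)

        lo, hi = 1.0, s_max
        guess = _solver.last_rescale
        if guess is not None and 1.0 < guess < s_max:
            # bracket around the previous solution (fit loops move slowly)
            a = max(1.0, guess - 0.03)
            b = min(s_max, guess + 0.03)
            fa, fb = contact_of(a), contact_of(b)
            if fa < 0 <= fb:
                lo, hi = a, b
            elif fa >= 0:
                hi = a
            else:
                lo = b
        if hi == s_max and contact_of(s_max) < 0:
            raise MSAConvergenceError(
                f"no rescaled-MSA solution: g(contact) < 0 up to s={s_max:.3g} "
                f"(phi={phi:.4g}, Z={charge:.4g}, sigma={sigma:.4g})"
            )
        s_star = brentq(contact_of, lo, hi, xtol=1e-5)
        _solver.last_rescale = s_star
        g_ind, u, rho = state_at(s_star)

    q = np.asarray(q, dtype=float)
    scalar = q.ndim == 0
    q_sig = np.atleast_1d(q) * sigma * s_star
    s_out = _MSASolver.sq(q_sig, g_ind, u, rho)
    return float(s_out[0]) if scalar else s_out


# ----------------------------------------------------------------------------
# composite model


def _gaussian(q: np.ndarray, amp: float, centre: float, width: float) -> np.ndarray:
    return amp * np.exp(-((q - centre) ** 2) / (2.0 * width**2))


def model_terms(
    q,
    params: SANSModelParams,
    order: tuple[int, int] = (48, 24),
) -> dict[str, np.ndarray]:
    """Evaluate each term of the composite model separately (cm⁻¹)."""
    q = np.atleast_1d(np.asarray(q, dtype=float))
    p_ec = elliptical_cylinder_form_factor(q, params.length, params.r_minor, params.r_major, order)
    s_er = charged_structure_factor(
        q, params.phi, params.charge, params.effective_diameter,
        params.ionic_strength, params.temperature, params.dielectric,
    )
    return {
        "cylinder": params.effective_scale * p_ec * s_er,
        "gauss_ip": _gaussian(q, params.gauss_ip_amp, params.q_ip, params.sigma_ip),
        "gauss_is": _gaussian(q, params.gauss_is_amp, params.q_is, params.sigma_is),
        "powerlaw": params.powerlaw_amp * q ** (-params.powerlaw_exp),
        "background": np.full_like(q, params.background),
    }


def composite_intensity(
    q, params: SANSModelParams, order: tuple[int, int] = (48, 24)
) -> ScatteringCurve:
    """Evaluate the full composite model on a Q grid, as a cm⁻¹ curve."""
    q = np.atleast_1d(np.asarray(q, dtype=float))
    terms = model_terms(q, params, order)
    total = sum(terms.values())
    return ScatteringCurve(q=q, intensity=total, sigma=None, unit_tag="cm^-1")


# ----------------------------------------------------------------------------
# staged fit


@dataclass
class StagedFitConfig:
    """Windows and switches for the term-by-term fit.

    Defaults follow the observation windows of the measurement: the power law
    lives below ~10⁻² Å⁻¹, the stacking peaks in the mid-Q band, the cylinder
    between.  ``polish`` adds a final joint refinement of all parameters.
    """

    powerlaw_qmax: float = 0.01
    gauss_window: tuple[float, float] = (0.5, 3.0)
    cylinder_window: tuple[float, float] = (0.02, 0.5)
    stages: tuple[str, ...] = ("powerlaw", "gaussians", "cylinder")
    polish: bool = False
    form_factor_order: tuple[int, int] = (48, 24)
    max_nfev: int = 400


@dataclass
class SANSFitResult:
    params: SANSModelParams
    uncertainties: dict[str, float]
    stage_chi2: dict[str, float]
    warnings: list[str] = field(default_factory=list)


def _weights(curve: ScatteringCurve, mask: np.ndarray) -> tuple[np.ndarray, bool]:
    """Return (weight array, log_space flag): 1/σ weights when σ is present,
    otherwise uniform weighting of log I."""
    if curve.sigma is not None and np.all(curve.sigma[mask] > 0):
        return 1.0 / curve.sigma[mask], False
    return np.ones(int(mask.sum())), True


def _run_ls(stage, residual, x0, bounds, max_nfev):
    res = least_squares(residual, x0, bounds=bounds, max_nfev=max_nfev, x_scale="jac")
    if res.status <= 0:
        raise StageFitError(f"stage '{stage}' did not converge: {res.message}")
    return res


def _param_sigmas(res) -> np.ndarray:
    """1-σ uncertainties from the Jacobian at the optimum."""
    m, p = res.jac.shape
    dof = max(m - p, 1)
    try:
        cov = np.linalg.inv(res.jac.T @ res.jac) * 2.0 * res.cost / dof
        return np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        return np.full(p, np.nan)


def _flag_bounds(stage, names, x, lo, hi, warn_list):
    for nm, xv, lov, hiv in zip(names, x, lo, hi):
        span = hiv - lov
        if np.isfinite(lov) and xv - lov < 1e-8 * max(abs(lov), 1.0):
            warn_list.append(f"stage '{stage}': parameter {nm} at lower bound")
        if np.isfinite(hiv) and hiv - xv < 1e-8 * max(abs(hiv), 1.0):
            warn_list.append(f"stage '{stage}': parameter {nm} at upper bound")
        del span


def staged_fit(
    curve: ScatteringCurve,
    init: SANSModelParams,
    config: StagedFitConfig | None = None,
) -> SANSFitResult:
    """Fit the composite model term by term for stability.

    Stage 1 fits (γ, n) plus a local baseline below ``powerlaw_qmax``;
    stage 2 fits the two Gaussians plus a local baseline on the mid-Q window;
    stage 3 fits (scale, L, R_minor, R_major, |Z|, bkg) on the cylinder
    window with the stage-1/2 terms frozen; the optional polish refines all
    parameters jointly with bounds around the stage estimates.

    Returns fitted parameters, 1-σ uncertainties from the stage covariances
    and per-stage χ² (weighted residual sum of squares).
    """
    cfg = config or StagedFitConfig()
    params = replace(init)
    sigmas: dict[str, float] = {}
    chi2: dict[str, float] = {}
    warn_list: list[str] = []
    q = curve.q
    intensity = curve.intensity

    def stage_residual(mask, model_of):
        w, log_space = _weights(curve, mask)
        qm, im = q[mask], intensity[mask]

        def residual(x):
            model = model_of(x, qm)
            if log_space:
                return np.log(np.clip(model, 1e-300, None)) - np.log(np.clip(im, 1e-300, None))
            return w * (model - im)

        return residual

    if "powerlaw" in cfg.stages:
        mask = q <= cfg.powerlaw_qmax
        if mask.sum() < 5:
            raise StageFitError(
                f"stage 'powerlaw': only {int(mask.sum())} points at Q <= {cfg.powerlaw_qmax}"
            )

        def pl_model(x, qm):
            log_gamma, n, c = x
            return 10.0**log_gamma * qm**(-n) + c

        x0 = [np.log10(max(init.powerlaw_amp, 1e-30)), init.powerlaw_exp,
              0.5 * float(np.min(intensity[mask]))]
        lo = [-30.0, 0.1, 0.0]
        hi = [10.0, 8.0, np.inf]
        res = _run_ls("powerlaw", stage_residual(mask, pl_model), x0, (lo, hi), cfg.max_nfev)
        sg = _param_sigmas(res)
        params = replace(params, powerlaw_amp=10.0 ** res.x[0], powerlaw_exp=res.x[1])
        sigmas["powerlaw_amp"] = params.powerlaw_amp * np.log(10.0) * sg[0]
        sigmas["powerlaw_exp"] = sg[1]
        chi2["powerlaw"] = 2.0 * res.cost
        _flag_bounds("powerlaw", ["log_gamma", "n", "baseline"], res.x, lo, hi, warn_list)

    if "gaussians" in cfg.stages:
        glo, ghi = cfg.gauss_window
        mask = (q >= glo) & (q <= ghi)
        if mask.sum() < 8:
            raise StageFitError(f"stage 'gaussians': too few points in [{glo}, {ghi}]")

        def g_model(x, qm):
            a1, c1, w1, a2, c2, w2, base = x
            return _gaussian(qm, a1, c1, w1) + _gaussian(qm, a2, c2, w2) + base

        x0 = [init.gauss_ip_amp, init.q_ip, init.sigma_ip,
              init.gauss_is_amp, init.q_is, init.sigma_is,
              float(np.median(intensity[mask])) * 0.1]
        lo = [0.0, glo * 0.5, 0.01, 0.0, glo * 0.5, 0.01, 0.0]
        hi = [np.inf, ghi, 1.0, np.inf, ghi, 1.0, np.inf]
        res = _run_ls("gaussians", stage_residual(mask, g_model), x0, (lo, hi), cfg.max_nfev)
        sg = _param_sigmas(res)
        a1, c1, w1, a2, c2, w2, _ = res.x
        s1, s2 = sg[:3], sg[3:6]
        if c1 > c2:  # keep the inter-hairpin (lower-Q) peak labelled q_ip
            (a1, c1, w1, s1), (a2, c2, w2, s2) = (a2, c2, w2, s2), (a1, c1, w1, s1)
            warn_list.append("stage 'gaussians': peak labels swapped to keep q_ip < q_is")
        params = replace(params, gauss_ip_amp=a1, q_ip=c1, sigma_ip=w1,
                         gauss_is_amp=a2, q_is=c2, sigma_is=w2)
        for nm, v in zip(("gauss_ip_amp", "q_ip", "sigma_ip"), s1):
            sigmas[nm] = v
        for nm, v in zip(("gauss_is_amp", "q_is", "sigma_is"), s2):
            sigmas[nm] = v
        chi2["gaussians"] = 2.0 * res.cost
        _flag_bounds("gaussians", ["amp_ip", "q_ip", "sigma_ip", "amp_is", "q_is", "sigma_is", "baseline"],
                     res.x, lo, hi, warn_list)

    if "cylinder" in cfg.stages:
        clo, chi_ = cfg.cylinder_window
        mask = (q >= clo) & (q <= chi_)
        if mask.sum() < 8:
            raise StageFitError(f"stage 'cylinder': too few points in [{clo}, {chi_}]")
        frozen = (
            params.powerlaw_amp * q[mask] ** (-params.powerlaw_exp)
            + _gaussian(q[mask], params.gauss_ip_amp, params.q_ip, params.sigma_ip)
            + _gaussian(q[mask], params.gauss_is_amp, params.q_is, params.sigma_is)
        )
        sign_z = -1.0 if init.charge < 0 else 1.0

        def cyl_model(x, qm):
            log_scale, length, r_min, ratio, z_abs, bkg = x
            trial = replace(
                params, length=length, r_minor=r_min, r_major=r_min * ratio,
                charge=sign_z * z_abs, scale=10.0**log_scale, background=bkg,
            )
            p_ec = elliptical_cylinder_form_factor(
                qm, trial.length, trial.r_minor, trial.r_major, cfg.form_factor_order
            )
            s_er = charged_structure_factor(
                qm, trial.phi, trial.charge, trial.effective_diameter,
                trial.ionic_strength, trial.temperature, trial.dielectric,
            )
            return trial.effective_scale * p_ec * s_er + frozen + bkg

        x0 = [np.log10(init.effective_scale), init.length, init.r_minor,
              init.r_major / init.r_minor, abs(init.charge), init.background]
        lo = [-10.0, 5.0, 1.0, 1.0, 0.0, 0.0]
        hi = [6.0, 400.0, 60.0, 12.0, 120.0, np.inf]
        res = _run_ls("cylinder", stage_residual(mask, cyl_model), x0, (lo, hi), cfg.max_nfev)
        sg = _param_sigmas(res)
        log_scale, length, r_min, ratio, z_abs, bkg = res.x
        params = replace(
            params, length=length, r_minor=r_min, r_major=r_min * ratio,
            charge=sign_z * z_abs, scale=10.0**log_scale, background=bkg,
        )
        sigmas["scale"] = params.effective_scale * np.log(10.0) * sg[0]
        sigmas["length"] = sg[1]
        sigmas["r_minor"] = sg[2]
        # R_major = R_minor * ratio: first-order propagation
        sigmas["r_major"] = np.hypot(ratio * sg[2], r_min * sg[3])
        sigmas["charge"] = sg[4]
        sigmas["background"] = sg[5]
        chi2["cylinder"] = 2.0 * res.cost
        _flag_bounds("cylinder", ["log_scale", "L", "R_minor", "ratio", "|Z|", "bkg"],
                     res.x, lo, hi, warn_list)

    if cfg.polish:
        mask = np.ones_like(q, dtype=bool)
        sign_z = -1.0 if params.charge < 0 else 1.0

        def full_model(x, qm):
            (log_scale, length, r_min, ratio, z_abs, bkg,
             a1, c1, w1, a2, c2, w2, log_gamma, n_exp) = x
            trial = replace(
                params, length=length, r_minor=r_min, r_major=r_min * ratio,
                charge=sign_z * z_abs, scale=10.0**log_scale, background=bkg,
                gauss_ip_amp=a1, q_ip=c1, sigma_ip=w1,
                gauss_is_amp=a2, q_is=c2, sigma_is=w2,
                powerlaw_amp=10.0**log_gamma, powerlaw_exp=n_exp,
            )
            terms = model_terms(qm, trial, cfg.form_factor_order)
            return sum(terms.values())

        x0 = [np.log10(params.effective_scale), params.length, params.r_minor,
              params.r_major / params.r_minor, abs(params.charge), params.background,
              params.gauss_ip_amp, params.q_ip, params.sigma_ip,
              params.gauss_is_amp, params.q_is, params.sigma_is,
              np.log10(max(params.powerlaw_amp, 1e-30)), params.powerlaw_exp]
        lo = [x - d for x, d in zip(x0, (2, 0.5 * params.length, 0.5 * params.r_minor,
                                         1.0, 10.0, max(params.background, 0.01),
                                         params.gauss_ip_amp, 0.2, 0.1,
                                         params.gauss_is_amp, 0.2, 0.1, 2.0, 1.0))]
        hi = [x + d for x, d in zip(x0, (2, 0.5 * params.length, 0.5 * params.r_minor,
                                         1.0, 10.0, 10 * max(params.background, 0.01),
                                         params.gauss_ip_amp, 0.2, 0.1,
                                         params.gauss_is_amp, 0.2, 0.1, 2.0, 1.0))]
        lo = [max(l, b) for l, b in zip(
            lo, (-10, 5.0, 1.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.01, 0.0, 0.0, 0.01, -30, 0.1))]
        res = _run_ls("polish", stage_residual(mask, full_model), x0, (lo, hi), cfg.max_nfev)
        (log_scale, length, r_min, ratio, z_abs, bkg,
         a1, c1, w1, a2, c2, w2, log_gamma, n_exp) = res.x
        params = replace(
            params, length=length, r_minor=r_min, r_major=r_min * ratio,
            charge=sign_z * z_abs, scale=10.0**log_scale, background=bkg,
            gauss_ip_amp=a1, q_ip=c1, sigma_ip=w1,
            gauss_is_amp=a2, q_is=c2, sigma_is=w2,
            powerlaw_amp=10.0**log_gamma, powerlaw_exp=n_exp,
        )
        chi2["polish"] = 2.0 * res.cost

    return SANSFitResult(params=params, uncertainties=sigmas, stage_chi2=chi2,
                         warnings=warn_list)


def stack_metrics(params: SANSModelParams, per_monomer_charge: float) -> StackGeometry:
    """Geometric interpretation of a fitted parameter set.

    The Gaussian centres convert to the inter-hairpin and inter-strand
    distances through d = 2π/Q; the monomer count is the nearest integer of
    L/d_ip and the assembly charge is n_units × per-monomer charge.
    """
    if params.q_ip <= 0 or params.q_is <= 0:
        raise ValueError("both Gaussian centres must be positive")
    q_ip, q_is = params.q_ip, params.q_is
    if q_is < q_ip:
        warnings.warn(
            "q_is < q_ip: swapping peak labels so that d_ip > d_is", stacklevel=2
        )
        q_ip, q_is = q_is, q_ip
    d_ip = 2 * np.pi / q_ip
    d_is = 2 * np.pi / q_is
    n_units = int(round(params.length / d_ip))
    return StackGeometry(
        n_units=n_units,
        d_ip=d_ip,
        d_is=d_is,
        aspect_ratio=params.r_major / params.r_minor,
        total_charge=n_units * per_monomer_charge,
    )
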