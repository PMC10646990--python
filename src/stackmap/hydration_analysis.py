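"""Hydration-shell analysis: site–water RDFs and the hydrogen-bonding index Δ.

The per-site statistic is built from the first peaks of the site–water
RDFs.  Writing ``D = r_XOw − r_XHw`` for the difference between the first
peak of the site–water-oxygen RDF and that of the site–water-hydrogen RDF:

* a hydrogen-bond *acceptor* pulls a water hydrogen inwards, so D ≥ 0 and
  Δ = D / R_donor with R_donor = 0.96 Å (the OH bond length);
* a hydrogen-bond *donor* pushes both hydrogens outwards, so D < 0 and
  Δ = D / R_acceptor, where R_acceptor = r_OH·cos(θ_HOH/2) ≈ 0.577 Å is
  the oxygen–hydrogen distance split that results when the water orients
  both hydrogens as far from the site as possible;
* Δ is clamped to [−1, 1]: finite-temperature peak positions can overshoot
  the geometric endpoints.

Sites whose first hydration shell holds essentially no water (coordination
number below a cutoff) are classified *buried* rather than assigned a Δ.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import AtomicConfiguration
from .scattering_theory import RDF

__all__ = [
    "R_DONOR",
    "R_ACCEPTOR",
    "DeltaRecord",
    "HydrophobicityScale",
    "compute_rdf",
    "first_shell_peak",
    "hbond_delta",
    "delta_surface_map",
    "normalize_hydrophobicity",
    "write_delta_csv",
]

#: OH bond-length normalisation for acceptors, Å.
R_DONOR = 0.96
#: Geometric normalisation for donors: r_OH·cos(θ_HOH/2) for 3-site water
#: (OH 1.0 Å, HOH 109.47°), Å.
R_ACCEPTOR = 1.0 * np.cos(np.deg2rad(109.47) / 2.0)


@dataclass
class DeltaRecord:
    """Per-site hydrogen-bonding record.

    ``delta`` is None for buried sites (no first hydration shell), in which
    case ``klass`` is ``"buried"``.
    """

    site_label: str
    r_xow: float | None
    r_xhw: float | None
    r_donor: float
    r_acceptor: float
    delta: float | None
    klass: str
    coordination: float | None = None

    def __post_init__(self) -> None:
        if self.klass not in ("acceptor", "donor", "neutral", "buried"):
            raise ValueError(f"unknown class {self.klass!r}")
        if self.klass == "buried":
            if self.delta is not None:
                raise ValueError("buried sites carry no Δ value")
        else:
            if self.delta is None or not -1 <= self.delta <= 1:
                raise ValueError("Δ must lie in [-1, 1]")
            if self.klass == "acceptor" and self.delta < 0:
                raise ValueError("acceptor Δ must be >= 0")
            if self.klass == "donor" and self.delta > 0:
                raise ValueError("donor Δ must be <= 0")


@dataclass
class HydrophobicityScale:
    """A per-amino-acid hydrophobicity index.

    ``hydrophilic_positive`` records the polarity of the source scale: True
    when larger raw values mean more hydrophilic.
    """

    values: dict[str, float]
    name: str = ""
    hydrophilic_positive: bool = True

    def __post_init__(self) -> None:
        if len(set(self.values.values())) < 2:
            raise ValueError("a hydrophobicity scale needs >= 2 distinct values")


def compute_rdf(
    ensemble: Sequence[AtomicConfiguration] | AtomicConfiguration,
    site_pair: tuple[str | Sequence[str], str | Sequence[str]],
    bin_width: float = 0.05,
    r_max: float | None = None,
) -> RDF:
    """Site–site RDF averaged over an ensemble of periodic configurations.

    Minimum-image distances between the α and β selections are histogrammed
    and normalised per frame by N_α · ρ_β · 4π r² Δr; the per-frame
    estimates are averaged.  ρ_β is N_β/V for distinct selections and
    (N_β − 1)/V when α and β are the same selection (self pairs are
    excluded, and this keeps an ideal gas at g = 1 without 1/N bias).
    Either selection may be a single site label or a sequence of labels
    (pooled).
    """
    frames = [ensemble] if isinstance(ensemble, AtomicConfiguration) else list(ensemble)
    if not frames:
        raise ValueError("ensemble must contain at least one configuration")
    box = frames[0].box_side
    if r_max is None:
        r_max = box / 2.0
    if r_max > box / 2.0 + 1e-9:
        raise ValueError(f"r_max {r_max} exceeds half the box side {box / 2.0}")
    alpha, beta = site_pair
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    edges = edges[edges <= r_max + 1e-12]
    r_mid = 0.5 * (edges[:-1] + edges[1:])
    shell = 4.0 * np.pi * r_mid**2 * bin_width
    g_acc = np.zeros_like(r_mid)
    same = (alpha == beta) or (
        not isinstance(alpha, str) and not isinstance(beta, str) and tuple(alpha) == tuple(beta)
    )
    for frame in frames:
        if abs(frame.box_side - box) > 1e-9:
            raise ValueError("all frames must share the box size")
        pos_a = frame.select(alpha)
        pos_b = frame.select(beta)
        if len(pos_a) == 0 or len(pos_b) == 0:
            raise ValueError(f"empty site selection for pair {site_pair!r}")
        d = pos_a[:, None, :] - pos_b[None, :, :]
        d -= box * np.round(d / box)
        r = np.sqrt((d**2).sum(axis=-1))
        if same:
            np.fill_diagonal(r, np.inf)
        counts, _ = np.histogram(r.ravel(), bins=edges)
        rho_b = (len(pos_b) - (1 if same else 0)) / frame.volume
        g_acc += counts / (len(pos_a) * rho_b * shell)
    key = (
        alpha if isinstance(alpha, str) else "+".join(alpha),
        beta if isinstance(beta, str) else "+".join(beta),
    )
    return RDF(r=r_mid, g=g_acc / len(frames), pair=key)


def first_shell_peak(
    rdf: RDF,
    search_window: tuple[float, float] = (1.0, 3.5),
    threshold: float = 1.2,
    rel_threshold: float = 0.2,
) -> float | None:
    """Position of the first qualifying local maximum of g(r), or None.

    The first bin inside the window that is a local maximum with
    g ≥ max(threshold, rel_threshold · max g in window) is refined by
    quadratic interpolation through the three surrounding bins.  The
    relative part guards against counting-noise bumps on the rising edge
    when g is far above 1 (shell fragments are normalised to a huge box, so
    an absolute threshold alone cannot separate shell from noise there);
    for bulk-normalised RDFs the absolute threshold dominates.  ``None`` is
    the no-shell signal that drives the buried classification.
    """
    lo, hi = search_window
    if lo < rdf.r[0] or hi > rdf.r[-1]:
        raise ValueError("search window must lie within the r grid")
    g = rdf.g
    idx = np.flatnonzero((rdf.r >= lo) & (rdf.r <= hi))
    threshold = max(threshold, rel_threshold * float(g[idx].max(initial=0.0)))
    for i in idx:
        if i == 0 or i == len(g) - 1:
            continue
        if g[i] >= threshold and g[i] >= g[i - 1] and g[i] > g[i + 1]:
            denom = g[i - 1] - 2.0 * g[i] + g[i + 1]
            if abs(denom) < 1e-300:
                return float(rdf.r[i])
            shift = 0.5 * (g[i - 1] - g[i + 1]) / denom
            shift = float(np.clip(shift, -0.5, 0.5))
            dr = rdf.r[1] - rdf.r[0]
            return float(rdf.r[i] + shift * dr)
    return None


def hbond_delta(
    r_xow: float | None,
    r_xhw: float | None,
    r_donor: float = R_DONOR,
    r_acceptor: float = R_ACCEPTOR,
    neutral_threshold: float = 0.1,
) -> tuple[float | None, str]:
    """Hydrogen-bonding index Δ and class from the two first-peak positions.

    D = r_XOw − r_XHw is normalised to R_donor when the site accepts
    (D ≥ 0) and to R_acceptor when it donates (D < 0); Δ is clamped to
    [−1, 1] and |Δ| below ``neutral_threshold`` is classed neutral.
    A missing peak yields (None, "buried").
    """
    if r_xow is None or r_xhw is None:
        return None, "buried"
    d = r_xow - r_xhw
    if d >= 0:
        delta = d / r_donor
        klass = "acceptor"
    else:
        delta = d / r_acceptor
        klass = "donor"
    delta = float(np.clip(delta, -1.0, 1.0))
    if abs(delta) < neutral_threshold:
        klass = "neutral"
    return delta, klass


def coordination_number(rdf: RDF, rho_b: float, r_cut: float = 3.5) -> float:
    """First-shell coordination number ρ_β ∫₀^{r_cut} g(r) 4πr² dr."""
    mask = rdf.r <= r_cut
    return float(
        rho_b * np.trapezoid(rdf.g[mask] * 4.0 * np.pi * rdf.r[mask] ** 2, rdf.r[mask])
    )


def delta_surface_map(
    ensemble: Sequence[AtomicConfiguration] | AtomicConfiguration,
    site_labels: Sequence[str],
    *,
    water_oxygen: str = "OW",
    water_hydrogens: Sequence[str] = ("HW1", "HW2"),
    bin_width: float = 0.02,
    r_max: float | None = None,
    search_window: tuple[float, float] = (1.0, 3.5),
    threshold: float = 1.2,
    buried_coordination: float = 0.5,
    r_donor: float = R_DONOR,
    r_acceptor: float = R_ACCEPTOR,
    neutral_threshold: float = 0.1,
) -> list[DeltaRecord]:
    """Δ map of an assembly surface, one record per site label.

    Equivalent atoms (same label on every monomer) are pooled into one RDF,
    so the statistic is the ensemble- and copy-averaged hydration structure.
    Sites with a first-shell water-oxygen coordination number below
    ``buried_coordination`` are flagged buried.
    """
    frames = [ensemble] if isinstance(ensemble, AtomicConfiguration) else list(ensemble)
    records: list[DeltaRecord] = []
    rho_ow = len(frames[0].select(water_oxygen)) / frames[0].volume
    for label in site_labels:
        g_xo = compute_rdf(frames, (label, water_oxygen), bin_width, r_max)
        g_xh = compute_rdf(frames, (label, tuple(water_hydrogens)), bin_width, r_max)
        coord = coordination_number(g_xo, rho_ow, r_cut=search_window[1])
        if coord < buried_coordination:
            records.append(
                DeltaRecord(label, None, None, r_donor, r_acceptor, None, "buried", coord)
            )
            continue
        r_xow = first_shell_peak(g_xo, search_window, threshold)
        r_xhw = first_shell_peak(g_xh, search_window, threshold)
        delta, klass = hbond_delta(r_xow, r_xhw, r_donor, r_acceptor, neutral_threshold)
        records.append(
            DeltaRecord(label, r_xow, r_xhw, r_donor, r_acceptor, delta, klass, coord)
        )
    return records


def normalize_hydrophobicity(scale: HydrophobicityScale) -> HydrophobicityScale:
    """Min–max normalise a hydrophobicity scale so 1 = hydrophilic.

    Source scales whose polarity is opposite (``hydrophilic_positive``
    False) come out exactly reversed; an already-[0,1] hydrophilic-positive
    scale is unchanged.
    """
    raw = np.array(list(scale.values.values()), dtype=float)
    lo, hi = raw.min(), raw.max()
    if hi - lo <= 0:
        raise ValueError("constant scale: normalisation undefined")
    norm = (raw - lo) / (hi - lo)
    if not scale.hydrophilic_positive:
        norm = 1.0 - norm
    return HydrophobicityScale(
        values=dict(zip(scale.values.keys(), norm.tolist())),
        name=f"{scale.name} (normalised)" if scale.name else "normalised",
        hydrophilic_positive=True,
    )


def write_delta_csv(records: Sequence[DeltaRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        d = None if rec.r_xow is None or rec.r_xhw is None else rec.r_xow - rec.r_xhw
        rows.append(
            {
                "site_label": rec.site_label,
                "r_XOw": rec.r_xow,
                "r_XHw": rec.r_xhw,
                "D": d,
                "R_used": rec.r_donor if (d is not None and d >= 0) else rec.r_acceptor,
                "Delta": rec.delta,
                "class": rec.klass,
                "coordination": rec.coordination,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def delta_bfactor_structure(
    config: AtomicConfiguration, records: Sequence[DeltaRecord], path: str | Path
) -> None:
    """Write a PDB with Δ in the B-factor column (buried sites get 0)."""
    import gemmi

    delta_of = {r.site_label: (0.0 if r.delta is None else r.delta) for r in records}
    st = gemmi.Structure()
    st.cell = gemmi.UnitCell(config.box_side, config.box_side, config.box_side, 90, 90, 90)
    st.spacegroup_hm = "P 1"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for mol in np.unique(config.molecule_ids):
        idx = np.flatnonzero(config.molecule_ids == mol)
        res = gemmi.Residue()
        res.name = "PEP"
        res.seqid = gemmi.SeqId(int(mol) % 10000, " ")
        for i in idx:
            atom = gemmi.Atom()
            atom.name = str(config.site_labels[i])
            el = str(config.elements[i])
            atom.element = gemmi.Element("H" if el == "D" else el)
            x, y, z = config.positions[i]
            atom.pos = gemmi.Position(x, y, z)
            atom.occ = 1.0
            atom.b_iso = float(delta_of.get(str(config.site_labels[i]), 0.0))
            res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.write_pdb(str(Path(path)))
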