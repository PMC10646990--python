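"""Readers, writers and reduction steps for the formats the pipeline touches.

Scattering curves are plain 2–3 column delimited text (Q [Å⁻¹], I, [σ]);
atomistic configurations are single-frame PDB files with a CRYST1 record
defining a cubic box, plus a CSV side table carrying per-site partial
charges and exchangeable-hydrogen flags.

Two reduction operations from the small-angle workflow live here as well:
stitching a wide-angle curve onto an absolutely scaled small-angle curve
through a least-squares overlap scalar, and buffer subtraction with
quadrature error propagation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "CurveParseError",
    "StructureError",
    "ScatteringCurve",
    "DiffractionSetup",
    "Fragment",
    "AtomicConfiguration",
    "read_curve",
    "write_curve",
    "stitch_curves",
    "subtract_buffer",
    "read_charge_table",
    "write_charge_table",
    "read_structure",
    "write_structure",
]

SUPPORTED_ELEMENTS = ("H", "D", "C", "N", "O", "Na")


class CurveParseError(ValueError):
    """Raised when a curve file cannot be parsed."""


class StructureError(ValueError):
    """Raised for malformed or inconsistent structure input."""


@dataclass
class ScatteringCurve:
    """A measured or modelled I(Q) curve on a strictly increasing Q grid.

    ``unit_tag`` records the intensity scale: ``"cm^-1"`` (absolute) or
    ``"barns/sr/atom"`` (per-atom differential cross section).
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    unit_tag: str = "cm^-1"

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
        if self.q.ndim != 1 or self.q.shape != self.intensity.shape:
            raise ValueError("q and intensity must be 1-d arrays of equal length")
        if self.sigma is not None and self.sigma.shape != self.q.shape:
            raise ValueError("sigma must match q in length")
        if self.q.size and (np.any(self.q <= 0) or np.any(np.diff(self.q) <= 0)):
            raise ValueError("q must be positive and strictly increasing")
        if self.sigma is not None and np.any(self.sigma < 0):
            raise ValueError("sigma must be non-negative")
        if self.unit_tag not in ("cm^-1", "barns/sr/atom"):
            raise ValueError(f"unknown unit tag {self.unit_tag!r}")

    def __len__(self) -> int:
        return self.q.size


@dataclass
class DiffractionSetup:
    """Instrument geometry: neutron wavelength λ (Å) and scattering angle 2θ (deg)."""

    wavelength: float
    scattering_angle: float

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if not 0 < self.scattering_angle <= 180:
            raise ValueError("scattering angle 2θ must lie in (0, 180] degrees")


@dataclass
class Fragment:
    """An unboxed group of typed, charged atoms (e.g. one hairpin monomer).

    Unlike :class:`AtomicConfiguration`, coordinates are unconstrained, so a
    fragment can be centred at the origin and posed rigidly.
    """

    site_labels: np.ndarray
    elements: np.ndarray
    positions: np.ndarray
    charges: np.ndarray
    exchangeable: np.ndarray

    def __post_init__(self) -> None:
        self.site_labels = np.asarray(self.site_labels, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.charges = np.asarray(self.charges, dtype=float)
        self.exchangeable = np.asarray(self.exchangeable, dtype=bool)
        n = len(self.site_labels)
        if not (len(self.elements) == len(self.positions) == len(self.charges) == len(self.exchangeable) == n):
            raise ValueError("fragment arrays must have equal length")
        for el in set(self.elements.tolist()):
            if el not in SUPPORTED_ELEMENTS:
                raise ValueError(f"unsupported element {el!r}")

    def __len__(self) -> int:
        return len(self.site_labels)

    @property
    def center(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    def centered(self) -> "Fragment":
        return replace(self, positions=self.positions - self.center)

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())


@dataclass
class AtomicConfiguration:
    """A periodic cubic box of typed, charged atoms grouped into molecules."""

    box_side: float
    site_labels: np.ndarray
    elements: np.ndarray
    positions: np.ndarray
    charges: np.ndarray
    exchangeable: np.ndarray
    molecule_ids: np.ndarray

    def __post_init__(self) -> None:
        if self.box_side <= 0:
            raise ValueError("box_side must be positive")
        self.site_labels = np.asarray(self.site_labels, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.charges = np.asarray(self.charges, dtype=float)
        self.exchangeable = np.asarray(self.exchangeable, dtype=bool)
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=int)
        n = len(self.site_labels)
        arrays = (self.elements, self.positions, self.charges, self.exchangeable, self.molecule_ids)
        if any(len(a) != n for a in arrays):
            raise ValueError("configuration arrays must have equal length")
        if n and any(lbl == "" for lbl in self.site_labels):
            raise ValueError("site labels must be nonempty")
        for el in set(self.elements.tolist()):
            if el not in SUPPORTED_ELEMENTS:
                raise ValueError(f"unsupported element {el!r}")
        # wrap rather than reject: periodic images are equivalent
        self.positions = np.mod(self.positions, self.box_side)

    def __len__(self) -> int:
        return len(self.site_labels)

    @property
    def n_atoms(self) -> int:
        return len(self.site_labels)

    @property
    def volume(self) -> float:
        return self.box_side**3

    @property
    def number_density(self) -> float:
        """Atoms per Å³."""
        return self.n_atoms / self.volume

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())

    def select(self, labels: str | Sequence[str]) -> np.ndarray:
        """Positions of all atoms whose site label is in ``labels``."""
        if isinstance(labels, str):
            labels = (labels,)
        mask = np.isin(self.site_labels, np.asarray(labels, dtype=object))
        return self.positions[mask]


# ----------------------------------------------------------------------------
# curve I/O


def read_curve(path: str | Path, unit_tag: str = "cm^-1") -> ScatteringCurve:
    """Read a 2–3 column delimited curve file ('#' starts a comment line).

    Rows are sorted by Q; rows with identical Q are averaged (intensities
    by mean, uncertainties combined in quadrature of the mean).
    """
    path = Path(path)
    rows: list[list[float]] = []
    ncols: int | None = None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        try:
            values = [float(p) for p in parts]
        except ValueError as exc:
            raise CurveParseError(f"{path.name}: non-numeric value on line {lineno}: {raw!r}") from exc
        if len(values) not in (2, 3):
            raise CurveParseError(f"{path.name}: expected 2 or 3 columns on line {lineno}, got {len(values)}")
        if ncols is None:
            ncols = len(values)
        elif len(values) != ncols:
            raise CurveParseError(f"{path.name}: inconsistent column count on line {lineno}")
        rows.append(values)
    if not rows:
        raise CurveParseError(f"{path.name}: file contains no data rows")

    data = np.asarray(rows, dtype=float)
    order = np.argsort(data[:, 0], kind="stable")
    data = data[order]
    q, inv = np.unique(data[:, 0], return_inverse=True)
    counts = np.bincount(inv).astype(float)
    intensity = np.bincount(inv, weights=data[:, 1]) / counts
    sigma = None
    if ncols == 3:
        var = np.bincount(inv, weights=data[:, 2] ** 2)
        sigma = np.sqrt(var) / counts
    return ScatteringCurve(q=q, intensity=intensity, sigma=sigma, unit_tag=unit_tag)


def write_curve(curve: ScatteringCurve, path: str | Path) -> None:
    """Write a curve as 3 (or 2) column text with a unit-tag header comment."""
    cols = [curve.q, curve.intensity]
    if curve.sigma is not None:
        cols.append(curve.sigma)
    np.savetxt(
        Path(path),
        np.column_stack(cols),
        header=f"Q(1/A) I({curve.unit_tag})" + (" sigma" if curve.sigma is not None else ""),
        fmt="%.17g",
    )


def stitch_curves(
    wide: ScatteringCurve,
    small: ScatteringCurve,
    overlap: tuple[float, float],
) -> ScatteringCurve:
    """Rescale ``wide`` onto ``small``'s absolute scale and merge the grids.

    The scalar minimising Σ (s·I_wide − I_small)² over the overlap window is
    applied to ``wide`` (intensity and σ); the output grid is the union, with
    the small-angle points preferred inside the overlap.  The output inherits
    ``small``'s unit tag, which is taken to be the absolute scale.
    """
    qlo, qhi = overlap
    if qhi <= qlo:
        raise ValueError("overlap interval must have qmin < qmax")
    in_wide = (wide.q >= qlo) & (wide.q <= qhi)
    in_small = (small.q >= qlo) & (small.q <= qhi)
    if in_wide.sum() < 3 or in_small.sum() < 3:
        raise ValueError(
            f"overlap [{qlo}, {qhi}] must contain >= 3 points of each curve "
            f"(got {int(in_wide.sum())} wide, {int(in_small.sum())} small)"
        )
    # compare on the small curve's overlap grid
    q_ov = small.q[in_small]
    iw = np.interp(q_ov, wide.q, wide.intensity)
    is_ = small.intensity[in_small]
    denom = float(np.dot(iw, iw))
    scale = float(np.dot(iw, is_)) / denom
    if scale <= 0:
        raise ValueError(f"fitted stitch scale {scale:.3g} is not positive; curves look incompatible")

    keep_wide = ~((wide.q >= qlo) & (wide.q <= qhi)) & ~np.isin(wide.q, small.q)
    q_out = np.concatenate([small.q, wide.q[keep_wide]])
    i_out = np.concatenate([small.intensity, scale * wide.intensity[keep_wide]])
    if small.sigma is not None and wide.sigma is not None:
        s_out = np.concatenate([small.sigma, scale * wide.sigma[keep_wide]])
    else:
        s_out = None
    order = np.argsort(q_out)
    return ScatteringCurve(
        q=q_out[order],
        intensity=i_out[order],
        sigma=None if s_out is None else s_out[order],
        unit_tag=small.unit_tag,
    )


def subtract_buffer(
    sample: ScatteringCurve, buffer: ScatteringCurve, fraction: float = 1.0
) -> ScatteringCurve:
    """Subtract ``fraction`` × buffer from sample, σ combined in quadrature.

    The buffer is linearly interpolated onto the sample grid; sample points
    outside the buffer's Q range are dropped.  ``fraction`` defaults to 1
    (subtraction of a pure solvent scan).
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    mask = (sample.q >= buffer.q[0]) & (sample.q <= buffer.q[-1])
    if not mask.any():
        raise ValueError("sample and buffer Q grids do not overlap")
    q = sample.q[mask]
    ib = np.interp(q, buffer.q, buffer.intensity)
    intensity = sample.intensity[mask] - fraction * ib
    sigma = None
    if sample.sigma is not None and buffer.sigma is not None:
        sb = np.interp(q, buffer.q, buffer.sigma)
        sigma = np.sqrt(sample.sigma[mask] ** 2 + (fraction * sb) ** 2)
    elif sample.sigma is not None:
        sigma = sample.sigma[mask].copy()
    return ScatteringCurve(q=q, intensity=intensity, sigma=sigma, unit_tag=sample.unit_tag)


# ----------------------------------------------------------------------------
# structure I/O


def read_charge_table(path: str | Path) -> dict[str, tuple[float, bool]]:
    """Read the (site_label, charge_e, exchangeable) CSV side table."""
    df = pd.read_csv(path)
    required = {"site_label", "charge_e", "exchangeable"}
    if not required.issubset(df.columns):
        raise StructureError(f"charge table must have columns {sorted(required)}")
    return {
        str(row.site_label): (float(row.charge_e), bool(int(row.exchangeable)))
        for row in df.itertuples()
    }


def write_charge_table(table: Mapping[str, tuple[float, bool]], path: str | Path) -> None:
    pd.DataFrame(
        [(k, q, int(x)) for k, (q, x) in table.items()],
        columns=["site_label", "charge_e", "exchangeable"],
    ).to_csv(path, index=False)


def charge_table_from_config(
    config: AtomicConfiguration | Fragment,
) -> dict[str, tuple[float, bool]]:
    """Collect the label → (charge, exchangeable) map a configuration implies."""
    table: dict[str, tuple[float, bool]] = {}
    for lbl, q, x in zip(config.site_labels, config.charges, config.exchangeable):
        entry = (float(q), bool(x))
        if lbl in table and not math.isclose(table[lbl][0], entry[0], abs_tol=1e-9):
            raise StructureError(f"site label {lbl!r} carries inconsistent charges")
        table[lbl] = entry
    return table


def _element_of(atom_name: str, gemmi_element: str) -> str:
    if gemmi_element in SUPPORTED_ELEMENTS:
        return gemmi_element
    head = atom_name.strip()[:2].capitalize()
    if head == "Na":
        return "Na"
    first = atom_name.strip()[0].upper()
    if first in ("H", "D", "C", "N", "O"):
        return first
    raise StructureError(f"cannot infer a supported element for atom {atom_name!r}")


def read_structure(
    path: str | Path, charge_table: Mapping[str, tuple[float, bool]]
) -> AtomicConfiguration:
    """Read a single-frame PDB with CRYST1 into an :class:`AtomicConfiguration`.

    Atom names are the site labels and must all resolve in ``charge_table``;
    coordinates are wrapped into [0, box).  Molecules are PDB residues.
    """
    st = gemmi.read_pdb(str(Path(path)))
    cell = st.cell
    if cell.a <= 1.0:  # gemmi leaves a dummy 1 Å cell when CRYST1 is absent
        raise StructureError(f"{Path(path).name}: missing or degenerate CRYST1 record")
    if abs(cell.a - cell.b) > 1e-3 or abs(cell.a - cell.c) > 1e-3:
        raise StructureError("only cubic boxes are supported (CRYST1 a=b=c)")
    labels, elements, pos, charges, exch, mols = [], [], [], [], [], []
    mol_id = -1
    unknown: set[str] = set()
    for model in st:
        for chain in model:
            for residue in chain:
                mol_id += 1
                for atom in residue:
                    name = atom.name.strip()
                    labels.append(name)
                    elements.append(_element_of(name, atom.element.name))
                    pos.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    if name not in charge_table:
                        unknown.add(name)
                        charges.append(0.0)
                        exch.append(False)
                    else:
                        qv, xv = charge_table[name]
                        charges.append(qv)
                        exch.append(xv)
                    mols.append(mol_id)
        break  # single-frame dialect
    if unknown:
        raise StructureError(f"atom names missing from charge table: {sorted(unknown)}")
    return AtomicConfiguration(
        box_side=cell.a,
        site_labels=np.array(labels, dtype=object),
        elements=np.array(elements, dtype=object),
        positions=np.array(pos, dtype=float),
        charges=np.array(charges, dtype=float),
        exchangeable=np.array(exch, dtype=bool),
        molecule_ids=np.array(mols, dtype=int),
    )


def _residue_name(elements: Sequence[str]) -> str:
    counts = sorted(elements)
    if counts == ["H", "H", "O"]:
        return "HOH"
    if counts == ["Na"]:
        return "NA"
    return "PEP"


def write_structure(config: AtomicConfiguration, path: str | Path) -> None:
    """Write a configuration as a PDB file with a CRYST1 cubic cell."""
    st = gemmi.Structure()
    st.cell = gemmi.UnitCell(config.box_side, config.box_side, config.box_side, 90, 90, 90)
    st.spacegroup_hm = "P 1"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for mol in np.unique(config.molecule_ids):
        idx = np.flatnonzero(config.molecule_ids == mol)
        res = gemmi.Residue()
        res.name = _residue_name([config.elements[i] for i in idx])
        res.seqid = gemmi.SeqId(int(mol) % 10000, " ")
        for i in idx:
            atom = gemmi.Atom()
            atom.name = str(config.site_labels[i])
            el = str(config.elements[i])
            atom.element = gemmi.Element("H" if el == "D" else el)
            x, y, z = config.positions[i]
            atom.pos = gemmi.Position(x, y, z)
            atom.occ = 1.0
            atom.b_iso = 0.0
            res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.write_pdb(str(Path(path)))
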