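"""Rigid-body assembly of hairpin stacks and solvated-box packing.

``build_stack_mc`` docks ``n_units`` copies of a rigid monomer into a stack
along +z by Metropolis Monte Carlo over rigid poses.  The score combines

* a capped soft-core steric repulsion Σ (r₀/r)¹² between atoms of
  different monomers,
* Debye-screened Coulomb interactions λ_B q_i q_j e^{−κr}/r between the
  partial charges, and
* a harmonic restraint holding consecutive monomer centres at the target
  spacing along the axis (with a weak lateral term that keeps the centres
  on the axis, so the stack stays ordered).

This scoring function is a documented stand-in for the original docking
protocol, whose exact form is not public; all weights are adjustable.

``solvate_box`` places the stacks in a cubic periodic box (two stacks are
separated by half the box width) and inserts rigid 3-site waters (SPC/E
geometry: OH 1.0 Å, HOH 109.47°) and Na⁺ counterions at random
non-overlapping positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .io_formats import AtomicConfiguration, Fragment
from .units import bjerrum_length, debye_kappa

__all__ = [
    "RigidPose",
    "StackAssembly",
    "BuildError",
    "PackingError",
    "build_stack_mc",
    "solvate_box",
    "WATER_OH",
    "WATER_ANGLE_DEG",
    "SPCE_CHARGES",
]

#: SPC/E rigid water geometry.
WATER_OH = 1.0
WATER_ANGLE_DEG = 109.47
#: SPC/E partial charges (O, H, H), e.
SPCE_CHARGES = (-0.8476, 0.4238, 0.4238)


class BuildError(RuntimeError):
    """Stack building failed to reach an overlap-free configuration."""


class PackingError(RuntimeError):
    """Solvent insertion failed before reaching the requested count."""


@dataclass
class RigidPose:
    """A rigid-body pose: rotation matrix plus translation (Å)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if not np.all(np.isfinite(self.translation)):
            raise ValueError("translation must be finite")

    @classmethod
    def identity(cls, translation=(0.0, 0.0, 0.0)) -> "RigidPose":
        return cls(np.eye(3), np.asarray(translation, dtype=float))

    def apply(self, positions: np.ndarray) -> np.ndarray:
        return positions @ self.rotation.T + self.translation


@dataclass
class StackAssembly:
    """A stack: one monomer template plus one rigid pose per monomer.

    ``score_trace`` records the best score so far at every accepted Monte
    Carlo move (non-increasing by construction); it is None for assemblies
    not produced by the docking run.
    """

    template: Fragment
    poses: list[RigidPose]
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    score_trace: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.axis = self.axis / np.linalg.norm(self.axis)

    @property
    def n_units(self) -> int:
        return len(self.poses)

    def centers(self) -> np.ndarray:
        base = self.template.centered().positions
        return np.array([pose.apply(base).mean(axis=0) for pose in self.poses])

    def monomer_positions(self) -> list[np.ndarray]:
        base = self.template.centered().positions
        return [pose.apply(base) for pose in self.poses]

    def to_fragment(self) -> Fragment:
        """Materialise all monomers as one fragment (atom order: unit by unit)."""
        n = len(self.template)
        tile = lambda a: np.tile(np.asarray(a, dtype=object), self.n_units)
        return Fragment(
            site_labels=tile(self.template.site_labels),
            elements=tile(self.template.elements),
            positions=np.vstack(self.monomer_positions()),
            charges=np.tile(self.template.charges, self.n_units),
            exchangeable=np.tile(self.template.exchangeable, self.n_units),
        )

    def min_intermonomer_distance(self) -> float:
        coords = self.monomer_positions()
        best = np.inf
        for i in range(len(coords)):
            for j in range(i + 1, len(coords)):
                d = coords[i][:, None, :] - coords[j][None, :, :]
                best = min(best, float(np.sqrt((d**2).sum(axis=-1)).min()))
        return best


# ----------------------------------------------------------------------------
# Monte Carlo docking


def _pair_energy(
    pos_i: np.ndarray, q_i: np.ndarray, pos_j: np.ndarray, q_j: np.ndarray,
    r0: float, cap: float, lam_b: float, kappa: float, w_rep: float, w_el: float,
) -> float:
    r = np.maximum(cdist(pos_i, pos_j), 1e-6)
    rep = np.minimum((r0 / r) ** 12, cap)
    el = lam_b * np.outer(q_i, q_j) * np.exp(-kappa * r) / r
    return float(w_rep * rep.sum() + w_el * el.sum())


def _spring_energy(
    centers: np.ndarray, spacing: float, w_spring: float, w_lateral: float
) -> float:
    dz = np.diff(centers[:, 2])
    lateral = np.diff(centers[:, :2], axis=0)
    return float(
        w_spring * np.sum((dz - spacing) ** 2)
        + w_lateral * np.sum(lateral**2)
    )


def build_stack_mc(
    monomer: Fragment,
    n_units: int,
    target_spacing: float,
    seed: int,
    *,
    n_steps: int = 1500,
    rot_step_deg: float = 4.0,
    trans_step: float = 0.25,
    softcore_r0: float = 2.5,
    softcore_cap: float = 50.0,
    w_repulsion: float = 1.0,
    w_electrostatic: float = 1.0,
    w_spring: float = 5.0,
    w_lateral: float = 1.0,
    ionic_strength: float = 0.25,
    temperature_schedule: tuple[float, float] = (2.0, 0.05),
    hard_core: float = 1.2,
) -> StackAssembly:
    """Dock ``n_units`` rigid monomers into a +z stack by Metropolis MC.

    Deterministic for a fixed seed.  Monomers start at the ideal spacing
    along +z and are relaxed under the score; the best-scoring pose set is
    returned.  Raises :class:`BuildError` if the best configuration still
    has an inter-monomer contact below ``hard_core`` Å.
    """
    if len(monomer) < 1:
        raise ValueError("monomer must contain at least one atom")
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    template = monomer.centered()
    poses = [RigidPose.identity((0.0, 0.0, k * target_spacing)) for k in range(n_units)]
    assembly = StackAssembly(template=template, poses=poses)
    if n_units == 1:
        return assembly

    rng = np.random.default_rng(seed)
    lam_b = bjerrum_length()
    kappa = debye_kappa(ionic_strength)
    base = template.positions
    charges = template.charges
    coords = [pose.apply(base) for pose in poses]

    def unit_energy(i: int, coords_i: np.ndarray) -> float:
        total = 0.0
        for j in range(n_units):
            if j == i:
                continue
            total += _pair_energy(
                coords_i, charges, coords[j], charges,
                softcore_r0, softcore_cap, lam_b, kappa,
                w_repulsion, w_electrostatic,
            )
        return total

    def springs() -> float:
        centers = np.array([c.mean(axis=0) for c in coords])
        return _spring_energy(centers, target_spacing, w_spring, w_lateral)

    energy = 0.5 * sum(unit_energy(i, coords[i]) for i in range(n_units)) + springs()
    best_energy = energy
    best_poses = [RigidPose(p.rotation.copy(), p.translation.copy()) for p in poses]
    trace = [best_energy]
    t_start, t_end = temperature_schedule

    for step in range(n_steps):
        temp = t_start + (t_end - t_start) * step / max(n_steps - 1, 1)
        i = int(rng.integers(n_units))
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = np.deg2rad(rng.normal(0.0, rot_step_deg))
        d_rot = Rotation.from_rotvec(angle * axis).as_matrix()
        d_trans = rng.normal(0.0, trans_step, size=3)
        old_pose = poses[i]
        new_pose = RigidPose(d_rot @ old_pose.rotation, old_pose.translation + d_trans)
        old_coords_i = coords[i]
        new_coords_i = new_pose.apply(base)

        delta = unit_energy(i, new_coords_i) - unit_energy(i, old_coords_i)
        spring_old = springs()
        coords[i] = new_coords_i
        spring_new = springs()
        delta += spring_new - spring_old

        if delta <= 0 or rng.random() < np.exp(-delta / max(temp, 1e-9)):
            poses[i] = new_pose
            energy += delta
            if energy < best_energy:
                best_energy = energy
                best_poses = [RigidPose(p.rotation.copy(), p.translation.copy()) for p in poses]
            trace.append(best_energy)
        else:
            coords[i] = old_coords_i

    order = np.argsort([p.translation[2] for p in best_poses])
    best = StackAssembly(
        template=template,
        poses=[best_poses[k] for k in order],
        score_trace=np.asarray(trace),
    )
    if best.min_intermonomer_distance() < hard_core:
        raise BuildError(
            f"no overlap-free stack after {n_steps} steps "
            f"(best score {best_energy:.4g}, min distance "
            f"{best.min_intermonomer_distance():.3f} Å)"
        )
    return best


# ----------------------------------------------------------------------------
# solvation packing


class _CellList:
    """Periodic cell list over a cubic box for minimum-image contact checks."""

    def __init__(self, box: float, cell: float = 2.6) -> None:
        self.box = box
        self.n = max(int(np.floor(box / cell)), 1)
        self.size = box / self.n
        self.cells: dict[tuple[int, int, int], list[tuple[np.ndarray, bool]]] = {}

    def _index(self, pos: np.ndarray) -> tuple[int, int, int]:
        idx = np.floor(pos / self.size).astype(int) % self.n
        return (int(idx[0]), int(idx[1]), int(idx[2]))

    def add(self, pos: np.ndarray, heavy: bool) -> None:
        self.cells.setdefault(self._index(pos), []).append((pos, heavy))

    def neighbours(self, pos: np.ndarray):
        ci, cj, ck = self._index(pos)
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for dk in (-1, 0, 1):
                    key = ((ci + di) % self.n, (cj + dj) % self.n, (ck + dk) % self.n)
                    yield from self.cells.get(key, ())

    def clash(self, pos: np.ndarray, heavy: bool, min_heavy: float, min_any: float) -> bool:
        for other, other_heavy in self.neighbours(pos):
            d = pos - other
            d -= self.box * np.round(d / self.box)
            r2 = float(d @ d)
            cut = min_heavy if (heavy and other_heavy) else min_any
            if r2 < cut * cut:
                return True
        return False


def _water_template() -> np.ndarray:
    """O at origin, two H at SPC/E geometry, bisector along +z."""
    half = np.deg2rad(WATER_ANGLE_DEG) / 2.0
    h1 = WATER_OH * np.array([np.sin(half), 0.0, np.cos(half)])
    h2 = WATER_OH * np.array([-np.sin(half), 0.0, np.cos(half)])
    return np.array([[0.0, 0.0, 0.0], h1, h2])


def solvate_box(
    stacks: Sequence[StackAssembly],
    n_waters: int,
    n_counterions: int,
    box_side: float,
    seed: int,
    *,
    min_heavy: float = 2.0,
    min_any: float = 1.2,
    max_attempts_per_molecule: int = 500,
) -> AtomicConfiguration:
    """Pack stacks, waters and Na⁺ into a cubic periodic box.

    Stacks are placed with centres on the x axis at box fractions
    (2k+1)/(2·n_stacks) — two stacks end up separated by half the box
    width — with the stack axis along z.  Waters and ions are inserted at
    random positions subject to a minimum heavy-atom distance of
    ``min_heavy`` Å (``min_any`` for pairs involving hydrogen).
    """
    if box_side <= 0:
        raise ValueError("box_side must be positive")
    n_stack_atoms = sum(len(s.template) * s.n_units for s in stacks)
    n_total = n_stack_atoms + 3 * n_waters + n_counterions
    if n_total / box_side**3 > 0.12:
        raise ValueError(
            f"requested contents ({n_total} atoms) exceed 0.12 atoms/Å³ "
            f"in a {box_side} Å box"
        )

    rng = np.random.default_rng(seed)
    half_box = box_side / 2.0
    labels: list[str] = []
    elements: list[str] = []
    positions: list[np.ndarray] = []
    charges: list[float] = []
    exchangeable: list[bool] = []
    mol_ids: list[int] = []
    mol = 0
    cells = _CellList(box_side)

    for k, stack in enumerate(stacks):
        frag = stack.to_fragment()
        centre = np.array(
            [box_side * (2 * k + 1) / (2 * max(len(stacks), 1)), half_box, half_box]
        )
        pos = frag.positions - frag.positions.mean(axis=0) + centre
        n_per = len(stack.template)
        for u in range(stack.n_units):
            sl = slice(u * n_per, (u + 1) * n_per)
            for lbl, el, p, q, x in zip(
                frag.site_labels[sl], frag.elements[sl], pos[sl],
                frag.charges[sl], frag.exchangeable[sl],
            ):
                wrapped = np.mod(p, box_side)
                labels.append(str(lbl))
                elements.append(str(el))
                positions.append(wrapped)
                charges.append(float(q))
                exchangeable.append(bool(x))
                mol_ids.append(mol)
                cells.add(wrapped, el != "H")
            mol += 1

    water = _water_template()
    attempts_left = max_attempts_per_molecule * max(n_waters, 1)
    inserted = 0
    while inserted < n_waters:
        if attempts_left <= 0:
            raise PackingError(
                f"water insertion stalled: placed {inserted} of {n_waters}"
            )
        attempts_left -= 1
        o_pos = rng.uniform(0.0, box_side, size=3)
        if cells.clash(o_pos, True, min_heavy, min_any):
            continue
        rot = Rotation.random(random_state=rng).as_matrix()
        sites = water @ rot.T + o_pos
        sites = np.mod(sites, box_side)
        if cells.clash(sites[1], False, min_heavy, min_any) or cells.clash(
            sites[2], False, min_heavy, min_any
        ):
            continue
        for name, el, p, q in zip(
            ("OW", "HW1", "HW2"), ("O", "H", "H"), sites, SPCE_CHARGES
        ):
            labels.append(name)
            elements.append(el)
            positions.append(p)
            charges.append(q)
            exchangeable.append(el == "H")
            mol_ids.append(mol)
            cells.add(p, el != "H")
        mol += 1
        inserted += 1

    attempts_left = max_attempts_per_molecule * max(n_counterions, 1)
    inserted = 0
    while inserted < n_counterions:
        if attempts_left <= 0:
            raise PackingError(
                f"ion insertion stalled: placed {inserted} of {n_counterions}"
            )
        attempts_left -= 1
        pos = rng.uniform(0.0, box_side, size=3)
        if cells.clash(pos, True, min_heavy, min_any):
            continue
        labels.append("NA")
        elements.append("Na")
        positions.append(pos)
        charges.append(1.0)
        exchangeable.append(False)
        mol_ids.append(mol)
        cells.add(pos, True)
        mol += 1
        inserted += 1

    return AtomicConfiguration(
        box_side=box_side,
        site_labels=np.array(labels, dtype=object),
        elements=np.array(elements, dtype=object),
        positions=np.array(positions, dtype=float),
        charges=np.array(charges, dtype=float),
        exchangeable=np.array(exchangeable, dtype=bool),
        molecule_ids=np.array(mol_ids, dtype=int),
    )
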