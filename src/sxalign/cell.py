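"""Unit cell, crystal orientation and the per-crystal free-parameter map.

The canonical real-space frame places the *a* axis along lab x and *b* in the
x-y plane; a crystal's orientation is a proper rotation applied to that frame.
Reciprocal vectors carry no factor of 2*pi, so a reflection's scattering vector
is q = R B h with |q| = 1/d.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .geometry import rotation_matrix

__all__ = [
    "UnitCell",
    "CrystalState",
    "LocalParamMap",
    "reciprocal_basis",
    "real_basis",
    "free_parameter_map",
    "apply_local_shifts",
    "random_orientation",
]

LATTICE_TYPES = (
    "triclinic", "monoclinic", "orthorhombic", "tetragonal",
    "rhombohedral", "hexagonal", "cubic",
)

#: independent cell parameters per lattice system
FREE_CELL_PARAMS = {
    "triclinic": ("a", "b", "c", "alpha", "beta", "gamma"),
    "monoclinic": ("a", "b", "c", "beta"),
    "orthorhombic": ("a", "b", "c"),
    "tetragonal": ("a", "c"),
    "rhombohedral": ("a", "alpha"),
    "hexagonal": ("a", "c"),
    "cubic": ("a",),
}


@dataclass(frozen=True)
class UnitCell:
    lattice_type: str
    a: float
    b: float
    c: float
    alpha: float = 90.0  # degrees
    beta: float = 90.0
    gamma: float = 90.0
    centering: str = "P"

    def __post_init__(self):
        if self.lattice_type not in LATTICE_TYPES:
            raise ValueError(f"unknown lattice type {self.lattice_type!r}")
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0 < ang < 180:
                raise ValueError("cell angles must lie in (0, 180) degrees")
        self._check_restrictions()

    def _check_restrictions(self):
        lt = self.lattice_type
        eq = lambda x, y: abs(x - y) < 1e-9
        ok = True
        if lt == "monoclinic":
            ok = eq(self.alpha, 90) and eq(self.gamma, 90)
        elif lt == "orthorhombic":
            ok = eq(self.alpha, 90) and eq(self.beta, 90) and eq(self.gamma, 90)
        elif lt == "tetragonal":
            ok = eq(self.a, self.b) and all(eq(x, 90) for x in (self.alpha, self.beta, self.gamma))
        elif lt == "rhombohedral":
            ok = eq(self.a, self.b) and eq(self.b, self.c) and eq(self.alpha, self.beta) and eq(self.beta, self.gamma)
        elif lt == "hexagonal":
            ok = eq(self.a, self.b) and eq(self.alpha, 90) and eq(self.beta, 90) and eq(self.gamma, 120)
        elif lt == "cubic":
            ok = eq(self.a, self.b) and eq(self.b, self.c) and all(
                eq(x, 90) for x in (self.alpha, self.beta, self.gamma))
        if not ok:
            raise ValueError(f"cell parameters violate {lt} restrictions")


def real_basis(cell: UnitCell) -> np.ndarray:
    """Real-space basis matrix, columns a, b, c (Angstrom), canonical frame."""
    al, be, ga = (math.radians(x) for x in (cell.alpha, cell.beta, cell.gamma))
    ca, cb, cg = math.cos(al), math.cos(be), math.cos(ga)
    sg = math.sin(ga)
    a_vec = np.array([cell.a, 0.0, 0.0])
    b_vec = np.array([cell.b * cg, cell.b * sg, 0.0])
    cz_sq = 1.0 - cb ** 2 - ((ca - cb * cg) / sg) ** 2
    if cz_sq <= 0:
        raise ValueError("degenerate cell: non-positive volume")
    c_vec = cell.c * np.array([cb, (ca - cb * cg) / sg, math.sqrt(cz_sq)])
    return np.column_stack([a_vec, b_vec, c_vec])


def reciprocal_basis(cell: UnitCell, orientation: np.ndarray | None = None) -> np.ndarray:
    """Reciprocal basis, columns a*, b*, c* in 1/Angstrom (no 2*pi factor).

    With B the returned matrix and A the real basis, B = inv(A).T so that
    B.T @ A = I; ``orientation`` (a proper rotation) is applied on the left.
    """
    B = np.linalg.inv(real_basis(cell)).T
    if orientation is not None:
        B = np.asarray(orientation) @ B
    return B


@dataclass(frozen=True)
class CrystalState:
    """A unit cell plus lab-frame orientation; caches the reciprocal basis."""

    cell: UnitCell
    orientation: np.ndarray  # (3,3) proper rotation

    def __post_init__(self):
        O = np.asarray(self.orientation, dtype=float)
        object.__setattr__(self, "orientation", O)
        if abs(np.linalg.det(O) - 1.0) > 1e-10:
            raise ValueError("orientation must be a proper rotation (det = 1)")
        object.__setattr__(self, "_rb", reciprocal_basis(self.cell, O))

    @property
    def reciprocal(self) -> np.ndarray:
        return self._rb


@dataclass(frozen=True)
class LocalParamMap:
    """Ordered per-crystal parameter names: free cell parameters, then the
    orientation adjustments (rx, ry, rz) in radians about the lab axes."""

    lattice_type: str
    names: tuple

    def __len__(self):
        return len(self.names)


def free_parameter_map(lattice_type: str) -> LocalParamMap:
    if lattice_type not in FREE_CELL_PARAMS:
        raise ValueError(f"unknown lattice type {lattice_type!r}")
    return LocalParamMap(
        lattice_type=lattice_type,
        names=FREE_CELL_PARAMS[lattice_type] + ("rx", "ry", "rz"),
    )


def _updated_cell(cell: UnitCell, name: str, delta: float) -> dict:
    """Parameter update respecting lattice-type ties (e.g. tetragonal b = a)."""
    lt = cell.lattice_type
    updates = {name: getattr(cell, name) + delta}
    if name == "a" and lt in ("tetragonal", "hexagonal"):
        updates["b"] = updates["a"]
    elif name == "a" and lt in ("rhombohedral", "cubic"):
        updates["b"] = updates["c"] = updates["a"]
    elif name == "alpha" and lt == "rhombohedral":
        updates["beta"] = updates["gamma"] = updates["alpha"]
    return updates


def apply_local_shifts(crystal: CrystalState, shifts, param_map: LocalParamMap | None = None) -> CrystalState:
    """Apply a shift vector over the free-parameter map.

    Cell lengths shift in Angstrom, cell angles in degrees; the final three
    entries are small lab-frame rotations in radians, composed Rz.Ry.Rx and
    applied on the left of the current orientation.
    """
    if param_map is None:
        param_map = free_parameter_map(crystal.cell.lattice_type)
    shifts = np.asarray(shifts, dtype=float)
    if shifts.shape != (len(param_map),):
        raise ValueError(f"expected {len(param_map)} shifts, got {shifts.shape}")
    updates: dict = {}
    for name, delta in zip(param_map.names[:-3], shifts[:-3]):
        updates.update(_updated_cell(crystal.cell, name, float(delta)))
    cell = replace(crystal.cell, **updates) if updates else crystal.cell
    rx, ry, rz = shifts[-3:]
    if rx or ry or rz:
        orientation = rotation_matrix(rx, ry, rz) @ crystal.orientation
    else:
        orientation = crystal.orientation
    return CrystalState(cell=cell, orientation=orientation)


def random_orientation(rng: np.random.Generator) -> np.ndarray:
    """Rotation drawn uniformly from SO(3) via a random unit quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
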