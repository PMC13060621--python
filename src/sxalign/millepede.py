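"""Schur-complement global alignment: registry, constraints, accumulation, solve.

The joint least-squares problem couples every crystal's local parameters to
the shared detector parameters through a bordered block-diagonal normal
matrix.  Eliminating each crystal's local block with a Schur complement leaves
a system over the global parameters alone,

    (C - sum_k G_k Gamma_k^-1 G_k^T) dg = -(g - sum_k G_k Gamma_k^-1 b_k),

whose size is independent of the number of crystals.  Hierarchy degeneracies
(a parent translation versus equal child translations) are removed by
constraining sibling parameters to sum to zero at every level, and the
undetermined overall rotation about the beam is gauged to zero; constraints
enter as Lagrange multipliers on the KKT system.

Units: translations in mm, rotations in degrees (matching the correction
interface of the geometry module); the solved shifts are corrections, i.e.
applying them to the model geometry cancels the geometry error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import null_space

from .geometry import PARAM_KINDS, CorrectionSet, DetectorGeometry, PanelGroup
from .localfit import MilleRecord

__all__ = [
    "GlobalParamRegistry",
    "ConstraintSet",
    "NormalSystem",
    "GlobalSolution",
    "WeakModeError",
    "accumulate",
    "hierarchy_constraints",
    "solve",
    "full_matrix_solve",
    "local_updates",
    "reject_outliers",
    "weak_mode_report",
]

IN_PLANE_KINDS = ("tx", "ty", "rz")


class WeakModeError(np.linalg.LinAlgError):
    """Raised when the constrained normal matrix is (near-)singular.

    Carries the offending near-null parameter combinations in ``modes``:
    a list of (eigenvalue, {param: coefficient}) entries.
    """

    def __init__(self, message: str, modes):
        super().__init__(message)
        self.modes = modes


@dataclass
class GlobalParamRegistry:
    """Ordered active global parameters: (group-or-panel name, kind) -> label."""

    params: list  # of (name, kind)

    def __post_init__(self):
        if len(set(self.params)) != len(self.params):
            raise ValueError("duplicate global parameters in registry")
        self.labels = {p: i for i, p in enumerate(self.params)}

    def __len__(self):
        return len(self.params)

    @classmethod
    def from_hierarchy(cls, geometry: DetectorGeometry, level: int = 1,
                       kinds=PARAM_KINDS, top_kinds=None) -> "GlobalParamRegistry":
        """Activate parameters for all groups down to hierarchy depth ``level``.

        Depth 0 is the root; panels are leaves.  ``kinds`` applies below the
        top level, ``top_kinds`` (default: same as ``kinds``) to the root.
        """
        if geometry.root is None:
            raise ValueError("geometry has no hierarchy")
        if not kinds:
            raise ValueError("at least one parameter kind must be active")
        top_kinds = kinds if top_kinds is None else top_kinds
        params = []

        def visit(node, depth):
            name = node.name if isinstance(node, PanelGroup) else node
            for kind in (top_kinds if depth == 0 else kinds):
                params.append((name, kind))
            if isinstance(node, PanelGroup) and depth < level:
                for child in node.children:
                    visit(child, depth + 1)

        visit(geometry.root, 0)
        return cls(params)


@dataclass
class ConstraintSet:
    """Homogeneous linear constraints A dg = 0 over registry labels."""

    matrix: np.ndarray  # (n_c, n_g)
    descriptions: list = field(default_factory=list)

    def __post_init__(self):
        A = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        self.matrix = A
        if A.size and np.linalg.matrix_rank(A) < A.shape[0]:
            raise ValueError("constraint rows are linearly dependent")

    @property
    def n_constraints(self) -> int:
        return 0 if self.matrix.size == 0 else self.matrix.shape[0]


def hierarchy_constraints(registry: GlobalParamRegistry,
                          geometry: DetectorGeometry) -> ConstraintSet:
    """Sibling sum-to-zero rows per level and kind, plus the beam-rotation gauge.

    For every internal group, for every kind active on its children, the
    children's parameters must sum to zero — the level above then owns the
    common motion.  One extra row pins the top-level rotation about the beam
    (rz) to zero, removing the overall gauge freedom.
    """
    rows, descs = [], []
    n_g = len(registry)

    def visit(node):
        if not isinstance(node, PanelGroup):
            return
        child_names = [c.name if isinstance(c, PanelGroup) else c for c in node.children]
        for kind in PARAM_KINDS:
            labels = [registry.labels[(c, kind)] for c in child_names
                      if (c, kind) in registry.labels]
            if labels:
                row = np.zeros(n_g)
                row[labels] = 1.0
                rows.append(row)
                descs.append(f"sum({node.name}.children.{kind}) = 0")
        for child in node.children:
            visit(child)

    visit(geometry.root)
    root_rz = (geometry.root.name, "rz")
    if root_rz in registry.labels:
        row = np.zeros(n_g)
        row[registry.labels[root_rz]] = 1.0
        rows.append(row)
        descs.append(f"{geometry.root.name}.rz = 0 (beam-rotation gauge)")
    matrix = np.array(rows) if rows else np.zeros((0, n_g))
    return ConstraintSet(matrix=matrix, descriptions=descs)


@dataclass
class NormalSystem:
    """Accumulated Schur-reduced normal equations over the global parameters."""

    matrix: np.ndarray  # C'
    rhs: np.ndarray  # b'  (solve C' dg = b')
    n_crystals: int = 0
    n_skipped: int = 0

    @classmethod
    def empty(cls, registry: GlobalParamRegistry) -> "NormalSystem":
        n = len(registry)
        return cls(matrix=np.zeros((n, n)), rhs=np.zeros(n))


def _record_blocks(record: MilleRecord, n_global: int, use_excitation: bool = True):
    """Weighted normal-equation blocks of one record, scattered to full width."""
    rows = slice(None)
    values, sigmas = record.values, record.sigmas
    A, labels, Gd = record.local_derivs, record.global_labels, record.global_derivs
    if not use_excitation:
        keep = np.ones(len(values), dtype=bool)
        keep[2::3] = False
        values, sigmas, A, Gd = values[keep], sigmas[keep], A[keep], Gd[keep]
    w = 1.0 / sigmas ** 2
    B = np.zeros((len(values), n_global))
    B[:, labels] = Gd
    C = (B * w[:, None]).T @ B
    G = (B * w[:, None]).T @ A
    gamma = (A * w[:, None]).T @ A
    g_glob = B.T @ (w * values)
    g_loc = A.T @ (w * values)
    return C, G, gamma, g_glob, g_loc


def accumulate(record: MilleRecord, system: NormalSystem,
               registry: GlobalParamRegistry, use_excitation: bool = True) -> NormalSystem:
    """Add one crystal's Schur-complement contribution to the global system.

    The correction term involving the local gradient is computed even though
    it vanishes for converged local fits.  Crystals with a singular local
    normal matrix are skipped (counted in ``n_skipped``) with a warning.
    """
    C, G, gamma, g_glob, g_loc = _record_blocks(record, len(registry), use_excitation)
    try:
        gamma_inv_Gt = np.linalg.solve(gamma, G.T)
        gamma_inv_b = np.linalg.solve(gamma, g_loc)
    except np.linalg.LinAlgError:
        warnings.warn(f"crystal {record.crystal_id}: singular local normal matrix; skipped",
                      stacklevel=2)
        system.n_skipped += 1
        return system
    system.matrix += C - G @ gamma_inv_Gt
    system.rhs += -g_glob + G @ gamma_inv_b
    system.n_crystals += 1
    return system


@dataclass
class GlobalSolution:
    """Solved corrections with covariance and eigen-spectrum diagnostics."""

    registry: GlobalParamRegistry
    shifts: np.ndarray  # (n_g,) mm / degrees
    covariance: np.ndarray
    spectrum: np.ndarray  # eigenvalues of C' on the constraint null space
    constraint_residual: float
    n_crystals: int
    rejected: list = field(default_factory=list)

    def to_correction_set(self) -> CorrectionSet:
        return CorrectionSet.from_entries(
            (name, kind, float(v))
            for (name, kind), v in zip(self.registry.params, self.shifts)
        )

    def frame(self) -> pd.DataFrame:
        sig = np.sqrt(np.maximum(np.diag(self.covariance), 0.0))
        return pd.DataFrame({
            "group": [p[0] for p in self.registry.params],
            "kind": [p[1] for p in self.registry.params],
            "value": self.shifts,
            "sigma": sig,
            "unit": ["mm" if k.startswith("t") else "deg"
                     for _, k in self.registry.params],
        })


def _null_space_spectrum(matrix: np.ndarray, constraints: ConstraintSet):
    """Eigen-decomposition of the system projected on the constraint null space."""
    if constraints.n_constraints:
        N = null_space(constraints.matrix)
    else:
        N = np.eye(matrix.shape[0])
    vals, vecs = np.linalg.eigh(N.T @ matrix @ N)
    return vals, N @ vecs


def solve(system: NormalSystem, constraints: ConstraintSet,
          registry: GlobalParamRegistry, sing_rtol: float = 1e-12) -> GlobalSolution:
    """Solve the constrained global system via the Lagrange (KKT) form.

    Raises :class:`WeakModeError`, carrying the near-null parameter
    combinations, if the constrained system is numerically singular.
    """
    if system.n_crystals < 1:
        raise ValueError("no crystals accumulated")
    n = len(registry)
    n_c = constraints.n_constraints
    kkt = np.zeros((n + n_c, n + n_c))
    kkt[:n, :n] = system.matrix
    if n_c:
        kkt[:n, n:] = constraints.matrix.T
        kkt[n:, :n] = constraints.matrix
    rhs = np.concatenate([system.rhs, np.zeros(n_c)])
    vals, vecs = _null_space_spectrum(system.matrix, constraints)
    scale = np.max(np.abs(vals)) if len(vals) else 0.0
    if scale == 0 or np.min(np.abs(vals)) < sing_rtol * scale:
        modes = _describe_modes(vals, vecs, registry, scale, rtol=max(sing_rtol, 1e-10))
        raise WeakModeError("constrained normal matrix is singular or near-singular", modes)
    sol = np.linalg.solve(kkt, rhs)
    shifts = sol[:n]
    cov = np.linalg.inv(kkt)[:n, :n]
    resid = float(np.max(np.abs(constraints.matrix @ shifts))) if n_c else 0.0
    return GlobalSolution(
        registry=registry, shifts=shifts, covariance=cov, spectrum=np.sort(vals),
        constraint_residual=resid, n_crystals=system.n_crystals,
    )


def _describe_modes(vals, vecs, registry, scale, rtol):
    modes = []
    for i in np.nonzero(np.abs(vals) < rtol * max(scale, 1e-300))[0]:
        v = vecs[:, i]
        top = np.argsort(-np.abs(v))[:6]
        combo = {f"{registry.params[j][0]}.{registry.params[j][1]}": float(v[j])
                 for j in top if abs(v[j]) > 1e-3}
        modes.append((float(vals[i]), combo))
    return modes


def weak_mode_report(system: NormalSystem, constraints: ConstraintSet,
                     registry: GlobalParamRegistry, rtol: float = 1e-10):
    """Eigen-spectrum of the constrained system with near-null modes flagged.

    Returns (eigenvalues ascending, flagged modes) where each flagged mode is
    (eigenvalue, {parameter: coefficient}) for eigenvalues below ``rtol``
    times the largest.
    """
    vals, vecs = _null_space_spectrum(system.matrix, constraints)
    scale = np.max(np.abs(vals)) if len(vals) else 0.0
    modes = _describe_modes(vals, vecs, registry, scale, rtol)
    order = np.argsort(vals)
    return vals[order], modes


def full_matrix_solve(records, registry: GlobalParamRegistry,
                      constraints: ConstraintSet, use_excitation: bool = True):
    """Joint dense solve of the bordered block-diagonal system (test oracle).

    Builds the full normal matrix over the global parameters and every
    crystal's local parameters, augments it with the constraint rows, and
    solves in one shot.  Returns (dg, [da_k]).  Intended for small problems;
    the Schur path must agree with this within tight tolerance.
    """
    n_g = len(registry)
    blocks = [_record_blocks(r, n_g, use_excitation) for r in records]
    n_loc = [b[2].shape[0] for b in blocks]
    n_c = constraints.n_constraints
    size = n_g + sum(n_loc) + n_c
    M = np.zeros((size, size))
    rhs = np.zeros(size)
    off = n_g
    for (C, G, gamma, g_glob, g_loc), nl in zip(blocks, n_loc):
        M[:n_g, :n_g] += C
        M[:n_g, off:off + nl] = G
        M[off:off + nl, :n_g] = G.T
        M[off:off + nl, off:off + nl] = gamma
        rhs[:n_g] += -g_glob
        rhs[off:off + nl] = -g_loc
        off += nl
    if n_c:
        M[:n_g, off:off + n_c] = constraints.matrix.T
        M[off:off + n_c, :n_g] = constraints.matrix
    try:
        sol = np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError as err:
        u, s, vt = np.linalg.svd(M[:size - n_c, :size - n_c])
        null = vt[s < 1e-12 * s.max()]
        raise WeakModeError(f"rank-deficient joint system: {err}", null.tolist())
    dg = sol[:n_g]
    das = []
    off = n_g
    for nl in n_loc:
        das.append(sol[off:off + nl])
        off += nl
    return dg, das


def local_updates(records, dg: np.ndarray, registry: GlobalParamRegistry,
                  use_excitation: bool = True):
    """Back-substituted local shifts da_k = Gamma_k^-1 (-b_k - G_k^T dg).

    Optional output: in practice one re-runs indexing with the corrected
    geometry instead of applying these.
    """
    out = []
    for record in records:
        _, G, gamma, _, g_loc = _record_blocks(record, len(registry), use_excitation)
        try:
            out.append(np.linalg.solve(gamma, -g_loc - G.T @ dg))
        except np.linalg.LinAlgError:
            out.append(None)
    return out


def reject_outliers(records, cutoff: float = 4.0):
    """Drop records whose chi2/ndf exceeds ``cutoff`` times the typical value.

    The reference scale is the median chi2/ndf floored at 1: on clean data the
    cut acts at ``cutoff`` itself, while a systematically misaligned geometry
    (which inflates every crystal's chi2 alike) does not reject the whole
    dataset.  Returns (kept, report).
    """
    if not np.isfinite(cutoff):
        return list(records), pd.DataFrame(columns=["crystal_id", "chi2_per_ndf"])
    scale = max(1.0, float(np.median([r.chi2 / r.ndf for r in records])))
    kept, rejected = [], []
    for record in records:
        if record.chi2 / record.ndf > cutoff * scale:
            rejected.append((record.crystal_id, record.chi2 / record.ndf))
        else:
            kept.append(record)
    if not kept:
        raise ValueError("all records rejected as outliers")
    report = pd.DataFrame(rejected, columns=["crystal_id", "chi2_per_ndf"])
    return kept, report
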