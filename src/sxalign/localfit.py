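"""Per-crystal machinery: peak pairing, residuals, gradients and the local fit.

Every peak-reflection pair contributes a measurement triple

    (r_fs, r_ss, r_e)

where r_fs and r_ss are the calculated-minus-observed spot coordinates in
pixels on the panel containing the observation, and r_e is the modeled
excitation error in 1/m scaled by 1e-7 so that all three components are of
comparable size.  Measurement standard errors are constants: 0.3 px for the
coordinates and 0.2 for the scaled excitation error; weights are 1/sigma^2.

The calculated spot position is obtained by intersecting the diffracted ray
with the plane of the observation's panel (out-of-bounds intersections are
permitted), which keeps residuals smooth under small geometry changes.

The "local fit" is a weighted Gauss-Newton update of one crystal's free cell
parameters and orientation with the detector geometry held fixed — the
prediction-refinement step of serial-crystallography processing.  Its normal
matrix and gradient are retained: they are exactly the per-crystal blocks that
the Schur-complement global solver consumes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .cell import CrystalState, LocalParamMap, apply_local_shifts, free_parameter_map
from .config import E_SCALE, SIGMA_E, SIGMA_FS, SIGMA_SS
from .geometry import (
    BeamModel,
    CorrectionSet,
    DetectorGeometry,
    apply_corrections,
    project_on_panel,
)
from .predict import excitation_error

__all__ = [
    "PeakPairing",
    "PairedMeasurements",
    "MeasurementTriple",
    "LocalFitResult",
    "MilleRecord",
    "pair_peaks",
    "paired_measurements",
    "residual_vector",
    "residuals",
    "local_gradients",
    "global_gradients",
    "local_fit",
    "build_mille_record",
    "sigma_vector",
]

# finite-difference steps, in each parameter's native unit
FD_STEP_LENGTH = 1e-4          # Angstrom, cell lengths
FD_STEP_ANGLE = math.degrees(1e-6)  # degrees, cell angles (1e-6 rad)
FD_STEP_ROT = 1e-6             # radians, orientation adjustments
FD_STEP_TRANS = 1e-3           # mm, detector translations
FD_STEP_GROT = math.degrees(1e-6)   # degrees, detector rotations (1e-6 rad)


@dataclass(frozen=True)
class PeakPairing:
    """One-to-one assignment of peak indices to Miller indices."""

    peak_index: np.ndarray  # (n,)
    hkl: np.ndarray  # (n, 3)

    def __len__(self):
        return len(self.peak_index)


@dataclass(frozen=True)
class MeasurementTriple:
    r_fs: float
    r_ss: float
    r_e: float
    sigma_fs: float = SIGMA_FS
    sigma_ss: float = SIGMA_SS
    sigma_e: float = SIGMA_E


@dataclass
class PairedMeasurements:
    """Observation arrays for the paired peaks of one pattern."""

    panel_idx: np.ndarray  # (n,) index into geometry panel order
    fs_obs: np.ndarray
    ss_obs: np.ndarray
    hkl: np.ndarray  # (n, 3)

    def __len__(self):
        return len(self.fs_obs)


@dataclass
class LocalFitResult:
    crystal: CrystalState
    measurements: PairedMeasurements
    param_map: LocalParamMap
    gamma: np.ndarray  # (n_loc, n_loc) weighted normal matrix A^T W A
    b: np.ndarray  # (n_loc,) weighted gradient A^T W r  (normal eq: gamma d = -b)
    local_derivs: np.ndarray  # (3n, n_loc) Jacobian at the fitted state
    residuals: np.ndarray  # (3n,) final residual vector
    chi2: float
    n_iter: int
    converged: bool


@dataclass
class MilleRecord:
    """One crystal's measurements with local and global derivatives."""

    values: np.ndarray  # (m,) residuals
    sigmas: np.ndarray  # (m,)
    local_derivs: np.ndarray  # (m, n_loc)
    global_labels: np.ndarray  # (g,) registry labels with any support here
    global_derivs: np.ndarray  # (m, g) dense over global_labels
    crystal_id: int = -1

    @property
    def n_measurements(self) -> int:
        return len(self.values)

    @property
    def chi2(self) -> float:
        return float(np.sum((self.values / self.sigmas) ** 2))

    @property
    def ndf(self) -> int:
        return max(1, self.n_measurements - self.local_derivs.shape[1])


def sigma_vector(n_pairs: int) -> np.ndarray:
    """Interleaved (fs, ss, e) standard errors for ``n_pairs`` pairs."""
    return np.tile([SIGMA_FS, SIGMA_SS, SIGMA_E], n_pairs)


def pair_peaks(peaks, predictions, max_dist: float = 10.0) -> PeakPairing:
    """Greedy nearest-neighbour peak-reflection assignment.

    ``peaks`` is (panel_idx, fs, ss) arrays; ``predictions`` is
    (hkl, panel_idx, fs, ss) arrays from the current model.  Candidate pairs on
    the same panel within ``max_dist`` pixels are taken in ascending distance,
    one-to-one; ties break deterministically by peak index then hkl.
    """
    pk_panel, pk_fs, pk_ss = (np.asarray(a) for a in peaks)
    hkl, pr_panel, pr_fs, pr_ss = predictions
    candidates = []
    for ipk in range(len(pk_fs)):
        same = np.nonzero(pr_panel == pk_panel[ipk])[0]
        if len(same) == 0:
            continue
        d = np.hypot(pr_fs[same] - pk_fs[ipk], pr_ss[same] - pk_ss[ipk])
        for j, dist in zip(same[d <= max_dist], d[d <= max_dist]):
            candidates.append((dist, ipk, tuple(hkl[j]), j))
    candidates.sort()
    used_peaks: set = set()
    used_refl: set = set()
    out_idx, out_hkl = [], []
    for _, ipk, _, j in candidates:
        if ipk in used_peaks or j in used_refl:
            continue
        used_peaks.add(ipk)
        used_refl.add(j)
        out_idx.append(ipk)
        out_hkl.append(hkl[j])
    order = np.argsort(out_idx) if out_idx else []
    return PeakPairing(
        peak_index=np.asarray(out_idx, dtype=int)[order] if out_idx else np.empty(0, dtype=int),
        hkl=np.asarray(out_hkl, dtype=int)[order] if out_hkl else np.empty((0, 3), dtype=int),
    )


def truth_pairing(pattern) -> PeakPairing:
    """Ground-truth pairing of a simulated sketch pattern."""
    return PeakPairing(peak_index=np.arange(len(pattern)), hkl=np.asarray(pattern.hkl))


def paired_measurements(peaks, pairing: PeakPairing) -> PairedMeasurements:
    """Gather the observation arrays selected by a pairing."""
    panel_idx, fs, ss = (np.asarray(a) for a in peaks)
    sel = pairing.peak_index
    return PairedMeasurements(
        panel_idx=panel_idx[sel],
        fs_obs=np.asarray(fs, dtype=float)[sel],
        ss_obs=np.asarray(ss, dtype=float)[sel],
        hkl=np.asarray(pairing.hkl, dtype=int),
    )


def residual_vector(crystal: CrystalState, geometry: DetectorGeometry, beam: BeamModel,
                    meas: PairedMeasurements, components: str = "fse") -> np.ndarray:
    """Interleaved residual vector for one pattern.

    Returns shape (3n,) ordered (r_fs, r_ss, r_e) per pair ("fse"), or (2n,)
    without the excitation rows ("fs").  Pairs whose diffracted ray does not
    reach the observation panel's plane yield nan entries.
    """
    q = meas.hkl @ crystal.reciprocal.T
    kq = q + np.array([0.0, 0.0, 1.0 / beam.wavelength])
    directions = kq / np.linalg.norm(kq, axis=1)[:, None]
    n = len(meas)
    fs_calc = np.full(n, np.nan)
    ss_calc = np.full(n, np.nan)
    panels = list(geometry.panels.values())
    for i in np.unique(meas.panel_idx):
        rows = meas.panel_idx == i
        fs_calc[rows], ss_calc[rows] = project_on_panel(panels[i], directions[rows])
    r_fs = fs_calc - meas.fs_obs
    r_ss = ss_calc - meas.ss_obs
    if components == "fs":
        out = np.empty(2 * n)
        out[0::2], out[1::2] = r_fs, r_ss
        return out
    r_e = excitation_error(q, beam.wavelength) * E_SCALE
    out = np.empty(3 * n)
    out[0::3], out[1::3], out[2::3] = r_fs, r_ss, r_e
    return out


def residuals(crystal, peaks, pairing: PeakPairing, geometry, beam) -> list:
    """Measurement triples for one pattern (pairs missing the detector dropped)."""
    meas = paired_measurements(peaks, pairing)
    r = residual_vector(crystal, geometry, beam, meas)
    out = []
    for i in range(len(meas)):
        tri = r[3 * i:3 * i + 3]
        if np.isnan(tri).any():
            warnings.warn(f"pair {i}: modeled reflection misses the detector; dropped",
                          stacklevel=2)
            continue
        out.append(MeasurementTriple(r_fs=tri[0], r_ss=tri[1], r_e=tri[2]))
    return out


def local_gradients(crystal: CrystalState, meas: PairedMeasurements,
                    geometry: DetectorGeometry, beam: BeamModel,
                    param_map: LocalParamMap | None = None) -> np.ndarray:
    """Jacobian d(residual)/d(local parameter) by central finite differences.

    Shape (3n, n_loc); columns follow the free-parameter map.  Steps are
    halved and retried if a step leaves the cell-validity domain.
    """
    if param_map is None:
        param_map = free_parameter_map(crystal.cell.lattice_type)
    n_loc = len(param_map)
    J = np.empty((3 * len(meas), n_loc))
    for j, name in enumerate(param_map.names):
        if name in ("rx", "ry", "rz"):
            step = FD_STEP_ROT
        elif name in ("alpha", "beta", "gamma"):
            step = FD_STEP_ANGLE
        else:
            step = FD_STEP_LENGTH
        for _ in range(8):
            shifts = np.zeros(n_loc)
            shifts[j] = step
            try:
                hi = apply_local_shifts(crystal, shifts, param_map)
                lo = apply_local_shifts(crystal, -shifts, param_map)
                break
            except ValueError:
                step *= 0.5
        else:
            raise ValueError(f"cannot find a valid step for parameter {name}")
        J[:, j] = (
            residual_vector(hi, geometry, beam, meas)
            - residual_vector(lo, geometry, beam, meas)
        ) / (2 * step)
    return J


def global_gradients(crystal: CrystalState, meas: PairedMeasurements,
                     geometry: DetectorGeometry, beam: BeamModel,
                     params: list) -> np.ndarray:
    """Jacobian d(residual)/d(global parameter), shape (3n, len(params)).

    ``params`` is an ordered list of (group name, kind) with kind in tx..rz.
    Spot rows are central finite differences through geometry corrections;
    excitation rows are exactly zero (the excitation error is a property of
    crystal and beam only), and pairs on panels outside a group feel nothing.
    """
    n = len(meas)
    J = np.zeros((3 * n, len(params)))
    panel_names = list(geometry.panels)
    for col, (group, kind) in enumerate(params):
        step = FD_STEP_TRANS if kind.startswith("t") else FD_STEP_GROT
        affected = set(geometry.panels_under(group))
        rows = np.isin(meas.panel_idx, [panel_names.index(p) for p in affected])
        if not rows.any():
            continue
        sub = PairedMeasurements(
            panel_idx=meas.panel_idx[rows], fs_obs=meas.fs_obs[rows],
            ss_obs=meas.ss_obs[rows], hkl=meas.hkl[rows])
        hi = apply_corrections(geometry, CorrectionSet.from_entries([(group, kind, step)]))
        lo = apply_corrections(geometry, CorrectionSet.from_entries([(group, kind, -step)]))
        dr = (
            residual_vector(crystal, hi, beam, sub, components="fs")
            - residual_vector(crystal, lo, beam, sub, components="fs")
        ) / (2 * step)
        idx = np.nonzero(rows)[0]
        J[3 * idx, col] = dr[0::2]
        J[3 * idx + 1, col] = dr[1::2]
        # excitation rows (3*idx + 2) remain exactly zero
    return J


def local_fit(crystal: CrystalState, peaks, pairing: PeakPairing,
              geometry: DetectorGeometry, beam: BeamModel,
              max_iter: int = 10, tol: float = 1e-8) -> LocalFitResult:
    """Iterated weighted Gauss-Newton refinement of one crystal's parameters.

    The pairing is held fixed throughout.  Solves Gamma da = -b with
    Gamma = A^T W A, b = A^T W r and weights 1/sigma^2, until the largest
    parameter shift falls below ``tol`` (native units) or ``max_iter``.
    """
    param_map = free_parameter_map(crystal.cell.lattice_type)
    meas = paired_measurements(peaks, pairing)
    if 3 * len(meas) < len(param_map):
        return _failed_fit(crystal, meas, param_map)
    r = residual_vector(crystal, geometry, beam, meas)
    keep = ~np.isnan(r).reshape(-1, 3).any(axis=1)
    if not keep.all():
        meas = PairedMeasurements(meas.panel_idx[keep], meas.fs_obs[keep],
                                  meas.ss_obs[keep], meas.hkl[keep])
        r = residual_vector(crystal, geometry, beam, meas)
    w = 1.0 / sigma_vector(len(meas)) ** 2
    converged = False
    n_iter = 0
    A = local_gradients(crystal, meas, geometry, beam, param_map)
    while n_iter < max_iter:
        gamma = (A * w[:, None]).T @ A
        b = A.T @ (w * r)
        try:
            delta = np.linalg.solve(gamma, -b)
        except np.linalg.LinAlgError:
            return _failed_fit(crystal, meas, param_map)
        crystal = apply_local_shifts(crystal, delta, param_map)
        r = residual_vector(crystal, geometry, beam, meas)
        bad = np.isnan(r)
        if bad.any():
            # reflections that left the detector plane this iteration: ignore
            r = np.where(bad, 0.0, r)
        n_iter += 1
        if np.max(np.abs(delta)) < tol:
            converged = True
            break
        A = local_gradients(crystal, meas, geometry, beam, param_map)
    A = local_gradients(crystal, meas, geometry, beam, param_map)
    gamma = (A * w[:, None]).T @ A
    b = A.T @ (w * r)
    return LocalFitResult(
        crystal=crystal, measurements=meas, param_map=param_map,
        gamma=gamma, b=b, local_derivs=A, residuals=r,
        chi2=float(r @ (w * r)), n_iter=n_iter, converged=converged,
    )


def _failed_fit(crystal, meas, param_map) -> LocalFitResult:
    n_loc = len(param_map)
    return LocalFitResult(
        crystal=crystal, measurements=meas, param_map=param_map,
        gamma=np.zeros((n_loc, n_loc)), b=np.zeros(n_loc),
        local_derivs=np.zeros((3 * len(meas), n_loc)),
        residuals=np.full(3 * len(meas), np.nan),
        chi2=float("inf"), n_iter=0, converged=False,
    )


def build_mille_record(result: LocalFitResult, geometry: DetectorGeometry,
                       beam: BeamModel, registry, crystal_id: int = -1) -> MilleRecord:
    """Package a converged local fit for the global solver.

    ``registry`` supplies the ordered active (group, kind) global parameters
    and their integer labels.  Derivatives are evaluated at the fitted state.
    """
    if not result.converged:
        raise ValueError("refusing to build a record from a non-converged local fit")
    G = global_gradients(result.crystal, result.measurements, geometry, beam,
                         registry.params)
    support = np.nonzero(np.any(G != 0, axis=0))[0]
    return MilleRecord(
        values=result.residuals.copy(),
        sigmas=sigma_vector(len(result.measurements)),
        local_derivs=result.local_derivs.copy(),
        global_labels=support.astype(int),
        global_derivs=G[:, support],
        crystal_id=crystal_id,
    )
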