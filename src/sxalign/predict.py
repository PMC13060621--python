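"""Thin-Ewald-sphere reflection prediction and spot projection.

A reflection h = (h, k, l) scatters at q = R B h (1/Angstrom, lab frame).  Its
excitation error is the signed distance of the reciprocal point from the Ewald
sphere, e = |k + q| - |k| with k = (0, 0, 1/lambda); e > 0 outside the sphere.
Reflections with |e| below a cutoff are considered excited and are projected
onto the detector along the diffracted direction (k + q) / |k + q|.

Excitation errors are reported in 1/m (1/Angstrom times 1e10).  They depend
only on the crystal and the beam, never on the detector geometry — the
property that anchors the detector-tilt/cell-squeeze degeneracy analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cell import CrystalState, UnitCell, reciprocal_basis
from .geometry import BeamModel, DetectorGeometry, intersect_rays

__all__ = [
    "ReflectionPrediction",
    "PeakObservation",
    "excitation_error",
    "predict_reflections",
    "predict_arrays",
    "project",
    "hkl_candidates",
    "detector_q_max",
]

A_PER_M = 1e10  # 1/Angstrom -> 1/m


@dataclass(frozen=True)
class ReflectionPrediction:
    hkl: tuple
    q: np.ndarray  # (3,) 1/A, lab frame
    excitation_error: float  # 1/m
    hit: tuple | None  # (panel name, fs, ss)


@dataclass(frozen=True)
class PeakObservation:
    panel: str
    fs: float
    ss: float


def excitation_error(q, wavelength: float):
    """Signed Ewald-sphere distance in 1/m; positive outside the sphere.

    Vectorised: q may be (3,) or (n, 3).
    """
    q = np.asarray(q, dtype=float)
    k = 1.0 / wavelength
    kq = q + np.array([0.0, 0.0, k])
    e_A = np.linalg.norm(kq, axis=-1) - k
    return e_A * A_PER_M


def detector_q_max(geometry: DetectorGeometry, beam: BeamModel) -> float:
    """Largest |q| (1/A) reaching any panel corner, from the max scattering angle."""
    best = 0.0
    for panel in geometry.panels.values():
        for i in (0, panel.n_fs):
            for j in (0, panel.n_ss):
                p = panel.corner_pos + panel.pixel_size * (i * panel.fs_dir + j * panel.ss_dir)
                norm = np.linalg.norm(p)
                if norm == 0:
                    continue
                cos2t = p[2] / norm
                cos2t = min(1.0, max(-1.0, cos2t))
                theta = 0.5 * np.arccos(cos2t)
                best = max(best, 2.0 * np.sin(theta) / beam.wavelength)
    return best


_GRID_CACHE: dict = {}


def hkl_candidates(cell: UnitCell, q_max: float) -> np.ndarray:
    """Integer hkl (excluding 000) with |B h| <= q_max, cached per (cell, q_max).

    q_max is quantised upward to 0.01 1/A so that small geometry perturbations
    reuse the cached grid; the exact culling happens downstream on the
    excitation error and the detector bounds.
    """
    q_max = np.ceil(q_max * 100.0) / 100.0
    key = (cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma, q_max)
    hit = _GRID_CACHE.get(key)
    if hit is not None:
        return hit
    B = reciprocal_basis(cell)
    # |h| = |a_vec . q| <= |a| q_max, and cyclic: real axis lengths bound the indices
    bounds = [int(np.floor(ax * q_max)) for ax in (cell.a, cell.b, cell.c)]
    h = np.arange(-bounds[0], bounds[0] + 1)
    k = np.arange(-bounds[1], bounds[1] + 1)
    l = np.arange(-bounds[2], bounds[2] + 1)
    hkl = np.stack(np.meshgrid(h, k, l, indexing="ij"), axis=-1).reshape(-1, 3)
    q = hkl @ B.T
    keep = (np.einsum("ij,ij->i", q, q) <= q_max ** 2) & hkl.any(axis=1)
    out = np.ascontiguousarray(hkl[keep], dtype=np.int32)
    if len(_GRID_CACHE) > 8:
        _GRID_CACHE.clear()
    _GRID_CACHE[key] = out
    return out


def predict_arrays(crystal: CrystalState, beam: BeamModel, geometry: DetectorGeometry,
                   e_max: float, q_max_margin: float = 5.0):
    """Vectorised prediction core.

    Returns (hkl (n,3) int, q (n,3), e (n,) 1/m, panel_idx (n,), fs (n,), ss (n,))
    for reflections with |e| <= e_max and an in-bounds detector hit.
    """
    if e_max <= 0:
        raise ValueError("e_max must be positive")
    q_bound = detector_q_max(geometry, beam) + q_max_margin * e_max / A_PER_M
    hkl = hkl_candidates(crystal.cell, q_bound)
    q = hkl @ crystal.reciprocal.T
    e = excitation_error(q, beam.wavelength)
    sel = np.abs(e) <= e_max
    hkl, q, e = hkl[sel], q[sel], e[sel]
    kq = q + np.array([0.0, 0.0, 1.0 / beam.wavelength])
    norms = np.linalg.norm(kq, axis=1)
    directions = kq / norms[:, None]
    panel_idx, fs, ss = intersect_rays(geometry, directions)
    hit = panel_idx >= 0
    return hkl[hit], q[hit], e[hit], panel_idx[hit], fs[hit], ss[hit]


def predict_reflections(crystal: CrystalState, beam: BeamModel,
                        geometry: DetectorGeometry, e_max: float) -> list:
    """Excited reflections landing on the detector, as ReflectionPrediction list."""
    hkl, q, e, panel_idx, fs, ss = predict_arrays(crystal, beam, geometry, e_max)
    panel_names = list(geometry.panels)
    return [
        ReflectionPrediction(
            hkl=tuple(int(x) for x in hkl[i]),
            q=q[i],
            excitation_error=float(e[i]),
            hit=(panel_names[panel_idx[i]], float(fs[i]), float(ss[i])),
        )
        for i in range(len(hkl))
    ]


def project(q, beam: BeamModel, geometry: DetectorGeometry):
    """Detector hit (panel, fs, ss) of the diffracted ray for one q, or None."""
    kq = np.asarray(q, dtype=float) + np.array([0.0, 0.0, 1.0 / beam.wavelength])
    norm = np.linalg.norm(kq)
    if norm == 0:
        raise ValueError("q is antiparallel to the beam with |q| = 2/lambda exactly")
    from .geometry import intersect_ray
    return intersect_ray(geometry, kq / norm)
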