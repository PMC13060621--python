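"""Sketch-pattern simulator: idealised diffraction snapshots with known truth.

A "sketch" is a peak list produced by predicting reflections for a random
crystal orientation on the true detector geometry, keeping each prediction
independently with probability ``keep_prob`` (emulating an imperfect peak
search), and rounding the surviving positions to the nearest pixel (emulating
peak-search localisation error).  The generating crystal state and the hkl of
every retained peak are recorded so that downstream fits can be validated
against ground truth.

Peaks are raw detector data: they are always expressed on the panels of the
true geometry, regardless of any model geometry used later for refinement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cell import CrystalState, random_orientation
from .config import SimConfig
from .geometry import CorrectionSet, DetectorGeometry, apply_corrections
from .predict import predict_arrays

__all__ = [
    "SketchPattern",
    "SketchDataset",
    "PerturbationSpec",
    "make_sketch",
    "perturb_geometry",
    "simulate_dataset",
]


@dataclass
class SketchPattern:
    pattern_id: int
    crystal: CrystalState  # generating ("true") crystal state
    panels: np.ndarray  # (n,) int, index into geometry panel order
    fs: np.ndarray  # (n,) observed fast-scan pixel coordinate
    ss: np.ndarray  # (n,)
    hkl: np.ndarray  # (n, 3) truth pairing

    def __len__(self):
        return len(self.fs)


@dataclass
class SketchDataset:
    patterns: list
    geometry: DetectorGeometry  # true geometry the peaks were generated on
    config: SimConfig
    seed: int | None = None

    def __len__(self):
        return len(self.patterns)

    @property
    def panel_names(self) -> list[str]:
        return list(self.geometry.panels)

    def peaks_frame(self) -> pd.DataFrame:
        """All peaks as a table: pattern_id, panel, fs, ss."""
        names = self.panel_names
        rows = [
            pd.DataFrame({
                "pattern_id": p.pattern_id,
                "panel": [names[i] for i in p.panels],
                "fs": p.fs,
                "ss": p.ss,
            })
            for p in self.patterns
        ]
        return pd.concat(rows, ignore_index=True)

    def truth_frame(self) -> pd.DataFrame:
        """Truth pairing table: pattern_id, peak index, h, k, l."""
        rows = [
            pd.DataFrame({
                "pattern_id": p.pattern_id,
                "peak": np.arange(len(p)),
                "h": p.hkl[:, 0],
                "k": p.hkl[:, 1],
                "l": p.hkl[:, 2],
            })
            for p in self.patterns
        ]
        return pd.concat(rows, ignore_index=True)


@dataclass
class PerturbationSpec:
    """Injected geometry errors: (group name, parameter kind, amount) entries.

    Translations in mm, rotations in degrees (about the group center).
    """

    entries: list = field(default_factory=list)

    def to_corrections(self) -> CorrectionSet:
        return CorrectionSet.from_entries(self.entries)


def make_sketch(true_geometry: DetectorGeometry, crystal: CrystalState, beam,
                rng: np.random.Generator, keep_prob: float = 0.5,
                e_max: float | None = None, round_pixels: bool = True):
    """One sketch: (panels, fs, ss, hkl) arrays for the retained peaks."""
    if not 0 < keep_prob <= 1:
        raise ValueError("keep_prob must lie in (0, 1]")
    if e_max is None:
        e_max = SimConfig().e_max
    hkl, _, _, panel_idx, fs, ss = predict_arrays(crystal, beam, true_geometry, e_max)
    if keep_prob < 1:
        keep = rng.random(len(hkl)) < keep_prob
        hkl, panel_idx, fs, ss = hkl[keep], panel_idx[keep], fs[keep], ss[keep]
    if round_pixels:
        fs = np.rint(fs)
        ss = np.rint(ss)
        # a coordinate in [n-0.5, n) rounds up to the panel edge; such a peak
        # would not be localised by a real peak search, so drop it
        panels = list(true_geometry.panels.values())
        n_fs = np.array([panels[i].n_fs for i in panel_idx])
        n_ss = np.array([panels[i].n_ss for i in panel_idx])
        ok = (fs < n_fs) & (ss < n_ss)
        hkl, panel_idx, fs, ss = hkl[ok], panel_idx[ok], fs[ok], ss[ok]
    return panel_idx, fs, ss, hkl


def perturb_geometry(geometry: DetectorGeometry, spec: PerturbationSpec) -> DetectorGeometry:
    """Apply an injected-error specification; returns the perturbed geometry."""
    return apply_corrections(geometry, spec.to_corrections())


def simulate_dataset(n_patterns: int, seed: int, config: SimConfig | None = None) -> SketchDataset:
    """Simulate ``n_patterns`` independent sketches, deterministically in ``seed``.

    Each pattern uses an independent substream derived from (seed, pattern_id),
    so datasets are reproducible and patterns are order-independent.
    """
    if n_patterns < 1:
        raise ValueError("n_patterns must be >= 1")
    if config is None:
        config = SimConfig()
    patterns = []
    for pid in range(n_patterns):
        rng = np.random.default_rng([seed, pid])
        crystal = CrystalState(cell=config.cell, orientation=random_orientation(rng))
        panels, fs, ss, hkl = make_sketch(
            config.geometry, crystal, config.beam, rng,
            keep_prob=config.keep_prob, e_max=config.e_max,
            round_pixels=config.round_pixels,
        )
        patterns.append(SketchPattern(pid, crystal, panels, fs, ss, hkl))
    return SketchDataset(patterns, config.geometry, config, seed=seed)


def write_dataset(dataset: SketchDataset, out_dir: str | Path):
    """Write peaks.csv and truth.csv under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.peaks_frame().to_csv(out / "peaks.csv", index=False)
    dataset.truth_frame().to_csv(out / "truth.csv", index=False)
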