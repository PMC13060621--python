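"""High-level alignment drivers: the estimator, bias demo and reporting.

:class:`MillepedeAligner` bundles the full pipeline — per-pattern local fits,
record building, outlier rejection, Schur accumulation, hierarchical
constraints and the constrained solve — behind a scikit-learn estimator
interface: construct with hyper-parameters, call ``fit(dataset, geometry)``
with the observed peaks and the current model geometry, and read the fitted
``corrections_`` / ``geometry_`` / ``solution_`` attributes.

Indexing is emulated, not implemented: each local fit starts from the
pattern's generating crystal state, which stands in for an indexing solution
obtained with the current geometry.  This isolates the solver (the object
under study) from any particular indexing algorithm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .config import SimConfig
from .geometry import (
    PARAM_KINDS,
    CorrectionSet,
    DetectorGeometry,
    apply_corrections,
    corner_motion,
)
from .localfit import build_mille_record, local_fit, pair_peaks, truth_pairing
from .millepede import (
    GlobalParamRegistry,
    NormalSystem,
    accumulate,
    hierarchy_constraints,
    reject_outliers,
    solve,
)
from .predict import predict_arrays
from .sketch import PerturbationSpec, SketchDataset, perturb_geometry, simulate_dataset

__all__ = [
    "MillepedeAligner",
    "AlignmentExperiment",
    "bias_demo",
    "report_corner_motions",
    "section4_perturbation",
    "run_two_iteration_experiment",
]


def section4_perturbation() -> PerturbationSpec:
    """The stock three-part injected error: q0 +0.2 mm x, q2 +0.5 deg about y
    through its center, whole detector +1 mm z."""
    return PerturbationSpec([
        ("q0", "tx", 0.2),
        ("q2", "ry", 0.5),
        ("all", "tz", 1.0),
    ])


class MillepedeAligner(BaseEstimator):
    """Detector-geometry refinement by Schur-complement least squares.

    Parameters
    ----------
    level : int
        Hierarchy depth at which groups receive alignment parameters
        (0 = whole detector only, 1 = detector plus its immediate children).
    kinds : tuple of str
        Active parameter kinds below the top level (subset of tx..rz).
    top_kinds : tuple of str or None
        Active kinds for the top-level group (defaults to ``kinds``).
    use_excitation : bool
        Include the excitation-error rows in the refinement target.
    pairing : {"truth", "distance"}
        Use the simulator's ground-truth peak-reflection pairing, or greedy
        nearest-neighbour pairing against predictions from the model geometry.
    max_dist : float
        Pairing cutoff in pixels (distance mode).
    outlier_cutoff : float
        Records with chi2/ndf above this are dropped before accumulation.
    e_max : float or None
        Prediction cutoff for distance pairing; defaults to the dataset's.

    Attributes (after ``fit``)
    --------------------------
    registry_, records_, solution_, corrections_, geometry_, spectrum_,
    n_rejected_, n_failed_
    """

    def __init__(self, level: int = 1, kinds=PARAM_KINDS, top_kinds=None,
                 use_excitation: bool = True, pairing: str = "truth",
                 max_dist: float = 10.0, outlier_cutoff: float = 4.0,
                 e_max: float | None = None):
        self.level = level
        self.kinds = kinds
        self.top_kinds = top_kinds
        self.use_excitation = use_excitation
        self.pairing = pairing
        self.max_dist = max_dist
        self.outlier_cutoff = outlier_cutoff
        self.e_max = e_max

    def fit(self, dataset: SketchDataset, geometry: DetectorGeometry | None = None):
        """Run local fits on every pattern and solve for geometry corrections.

        ``dataset`` supplies the observed peaks (and the emulated indexing
        solutions); ``geometry`` is the current model geometry to refine
        (default: the dataset's true geometry, e.g. for null tests).
        """
        if self.pairing not in ("truth", "distance"):
            raise ValueError("pairing must be 'truth' or 'distance'")
        if not self.kinds:
            raise ValueError("at least one parameter kind must be active")
        if geometry is None:
            geometry = dataset.geometry
        beam = dataset.config.beam
        e_max = self.e_max if self.e_max is not None else dataset.config.e_max
        registry = GlobalParamRegistry.from_hierarchy(
            geometry, level=self.level, kinds=tuple(self.kinds),
            top_kinds=None if self.top_kinds is None else tuple(self.top_kinds))
        records = []
        n_failed = 0
        for pattern in dataset.patterns:
            peaks = (pattern.panels, pattern.fs, pattern.ss)
            if self.pairing == "truth":
                pairing = truth_pairing(pattern)
            else:
                pred = predict_arrays(pattern.crystal, beam, geometry, e_max)
                pairing = pair_peaks(peaks, (pred[0], pred[3], pred[4], pred[5]),
                                     max_dist=self.max_dist)
            result = local_fit(pattern.crystal, peaks, pairing, geometry, beam)
            if not result.converged:
                n_failed += 1
                continue
            records.append(build_mille_record(result, geometry, beam, registry,
                                              crystal_id=pattern.pattern_id))
        if not records:
            raise ValueError("no refinable crystals")
        kept, rejection_report = reject_outliers(records, cutoff=self.outlier_cutoff)
        system = NormalSystem.empty(registry)
        for record in kept:
            accumulate(record, system, registry, use_excitation=self.use_excitation)
        constraints = hierarchy_constraints(registry, geometry)
        solution = solve(system, constraints, registry)
        solution.rejected = list(rejection_report["crystal_id"])

        self.registry_ = registry
        self.records_ = kept
        self.rejection_report_ = rejection_report
        self.n_rejected_ = len(rejection_report)
        self.n_failed_ = n_failed
        self.solution_ = solution
        self.spectrum_ = solution.spectrum
        self.corrections_ = solution.to_correction_set()
        self.geometry_ = apply_corrections(geometry, self.corrections_)
        return self

    def corrections_frame(self) -> pd.DataFrame:
        return self.solution_.frame()


def report_corner_motions(corrections: CorrectionSet, geometry: DetectorGeometry,
                          signed: bool = True) -> pd.DataFrame:
    """Per-panel corner translations (mm) and cumulative rotations (degrees).

    Translations are the lab displacement of each panel's (0, 0) corner under
    the corrections — directly comparable no matter at which hierarchy level a
    motion was applied.  Rotations are the summed small-angle contributions of
    the panel and all its ancestor groups.
    """
    rows = {}
    ancestors = _ancestry(geometry)
    for name in geometry.panels:
        t = corner_motion(geometry, corrections, name)
        rot = np.zeros(3)
        for node in ancestors[name]:
            rot += corrections.rotation_deg(node)
        rows[name] = np.concatenate([t, rot])
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["x", "y", "z", "rx", "ry", "rz"])


def _ancestry(geometry: DetectorGeometry) -> dict:
    """panel name -> [panel, parent group, ..., root]."""
    out = {p: [p] for p in geometry.panels}
    if geometry.root is None:
        return out
    def visit(node, path):
        from .geometry import PanelGroup
        if isinstance(node, PanelGroup):
            for child in node.children:
                visit(child, path + [node.name])
        else:
            out[node] = [node] + path[::-1]
    visit(geometry.root, [])
    return out


def bias_demo(seed: int, n_patterns: int = 100, config: SimConfig | None = None,
              perturbation: PerturbationSpec | None = None,
              pairing: str = "distance", bin_width_um: float = 20.0,
              hist_range_um: float = 300.0):
    """The spot-deviation bias demonstration.

    Simulates sketches on the true geometry, perturbs the model geometry
    (default: q0 moved +200 um along x), refines each crystal's local
    parameters only, and tabulates the per-panel mean calculated-minus-observed
    spot offsets in micrometres.  The local fits partially absorb the panel
    shift, so the q0 mean under-reports the injected error and the opposite
    panel acquires a spurious offset — the failure mode of spot-deviation
    geometry refinement.

    Returns (means DataFrame indexed by panel with mean_x_um/mean_y_um/n_peaks,
    histograms dict panel -> (H, edges_um)).
    """
    if config is None:
        config = SimConfig()
    if perturbation is None:
        perturbation = PerturbationSpec([("q0", "tx", 0.2)])
    dataset = simulate_dataset(n_patterns, seed, config)
    model_geometry = perturb_geometry(config.geometry, perturbation)
    beam = config.beam
    panel_names = dataset.panel_names
    px_um = {p.name: p.pixel_size * 1000.0 for p in config.geometry.panels.values()}
    offsets = {name: [] for name in panel_names}
    for pattern in dataset.patterns:
        peaks = (pattern.panels, pattern.fs, pattern.ss)
        if pairing == "truth":
            pair = truth_pairing(pattern)
        else:
            pred = predict_arrays(pattern.crystal, beam, model_geometry, config.e_max)
            pair = pair_peaks(peaks, (pred[0], pred[3], pred[4], pred[5]))
        result = local_fit(pattern.crystal, peaks, pair, model_geometry, beam)
        if not result.converged:
            warnings.warn(f"pattern {pattern.pattern_id}: local fit did not converge")
            continue
        r = result.residuals
        meas = result.measurements
        for i, name in enumerate(panel_names):
            rows = meas.panel_idx == i
            if rows.any():
                # fs/ss coincide with lab x/y for the stock axis-aligned panels
                offsets[name].append(np.column_stack(
                    [r[0::3][rows], r[1::3][rows]]) * px_um[name])
    means = {}
    hists = {}
    edges = np.arange(-hist_range_um, hist_range_um + bin_width_um, bin_width_um)
    for name in panel_names:
        if offsets[name]:
            xy = np.vstack(offsets[name])
            means[name] = [xy[:, 0].mean(), xy[:, 1].mean(), len(xy)]
            H, _, _ = np.histogram2d(xy[:, 0], xy[:, 1], bins=[edges, edges])
            hists[name] = (H, edges)
        else:
            means[name] = [np.nan, np.nan, 0]
    frame = pd.DataFrame.from_dict(
        means, orient="index", columns=["mean_x_um", "mean_y_um", "n_peaks"])
    return frame, hists


@dataclass
class AlignmentExperiment:
    """Bookkeeping for a multi-iteration simulate-fit-align experiment."""

    injected: PerturbationSpec
    injected_report: pd.DataFrame
    iteration_reports: list = field(default_factory=list)
    aligners: list = field(default_factory=list)

    @property
    def total_report(self) -> pd.DataFrame:
        """Summed corrections over iterations (corner mm / degrees)."""
        total = self.iteration_reports[0].copy()
        for rep in self.iteration_reports[1:]:
            total = total + rep
        return total

    @property
    def residual_report(self) -> pd.DataFrame:
        """Total corrections plus injected motions: zero means full recovery."""
        return self.total_report + self.injected_report


def run_two_iteration_experiment(seed: int, n_patterns: int = 100,
                                 config: SimConfig | None = None,
                                 perturbation: PerturbationSpec | None = None,
                                 iterations: int = 2,
                                 use_excitation: bool = True,
                                 pairing: str = "truth",
                                 resimulate: bool = True) -> AlignmentExperiment:
    """The simulated recovery experiment: inject, align, re-simulate, align again.

    Observed peaks always come from the true geometry; the model geometry
    starts at the perturbed state and is corrected after each alignment round.
    With ``resimulate`` the per-round sketches are regenerated with the same
    seed (emulating a fresh indexing run); otherwise the same sketches are
    re-fit.  Reports are corner translations / cumulative rotations per panel,
    which add across rounds.
    """
    if config is None:
        config = SimConfig()
    if perturbation is None:
        perturbation = section4_perturbation()
    true_geometry = config.geometry
    injected_report = report_corner_motions(perturbation.to_corrections(), true_geometry)
    model_geometry = perturb_geometry(true_geometry, perturbation)
    experiment = AlignmentExperiment(injected=perturbation,
                                     injected_report=injected_report)
    dataset = simulate_dataset(n_patterns, seed, config)
    for it in range(iterations):
        if it > 0 and resimulate:
            dataset = simulate_dataset(n_patterns, seed, config)
        aligner = MillepedeAligner(level=1, use_excitation=use_excitation,
                                   pairing=pairing)
        aligner.fit(dataset, model_geometry)
        experiment.aligners.append(aligner)
        experiment.iteration_reports.append(
            report_corner_motions(aligner.corrections_, model_geometry))
        model_geometry = aligner.geometry_
    return experiment
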