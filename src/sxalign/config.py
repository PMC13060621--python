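"""Default simulation world: a four-quadrant detector and a monoclinic cell.

The stock configuration is four 1024 x 1024-pixel panels with 100 um pixels
arranged quadrant-wise around the beam axis at a camera length of 100 mm, a
9 keV beam (1.3776 A), and a primitive monoclinic cell with a = 123, b = 45,
c = 80 A, beta = 97 deg.  Panel q0 occupies the +x/+y quadrant and q2 the
opposite (-x/-y) quadrant.

``DEFAULT_E_MAX`` is the excitation-error cutoff for prediction.  It was
calibrated once (scripts/calibrate_emax.py, bisection on this configuration)
so that an average pattern yields about 324 excited in-bounds reflections,
i.e. about 162 simulated peaks after random half-selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cell import UnitCell
from .geometry import BeamModel, DetectorGeometry, DetectorPanel, PanelGroup

__all__ = [
    "DEFAULT_E_MAX",
    "SIGMA_FS",
    "SIGMA_SS",
    "SIGMA_E",
    "E_SCALE",
    "four_panel_geometry",
    "default_cell",
    "default_beam",
    "SimConfig",
]

#: prediction cutoff on |excitation error|, 1/m (calibrated; see module docstring)
DEFAULT_E_MAX = 3.259e6

#: measurement standard errors: spot coordinates in pixels, excitation error
#: dimensionless after the 1e-7 scaling
SIGMA_FS = 0.3
SIGMA_SS = 0.3
SIGMA_E = 0.2

#: scale factor applied to excitation errors (1/m) in the residual vector
E_SCALE = 1e-7


def four_panel_geometry(camera_length: float = 100.0, n_px: int = 1024,
                        pixel_size: float = 0.1) -> DetectorGeometry:
    """Four square panels tiling the quadrants around the beam axis."""
    size = n_px * pixel_size
    corners = {
        "q0": (0.0, 0.0),
        "q1": (-size, 0.0),
        "q2": (-size, -size),
        "q3": (0.0, -size),
    }
    panels = {
        name: DetectorPanel(
            name=name,
            corner_pos=np.array([cx, cy, camera_length]),
            fs_dir=np.array([1.0, 0.0, 0.0]),
            ss_dir=np.array([0.0, 1.0, 0.0]),
            n_fs=n_px,
            n_ss=n_px,
            pixel_size=pixel_size,
        )
        for name, (cx, cy) in corners.items()
    }
    root = PanelGroup("all", ["q0", "q1", "q2", "q3"])
    return DetectorGeometry(panels, root)


def default_cell() -> UnitCell:
    return UnitCell(lattice_type="monoclinic", a=123.0, b=45.0, c=80.0,
                    alpha=90.0, beta=97.0, gamma=90.0, centering="P")


def default_beam() -> BeamModel:
    return BeamModel(wavelength=1.3776)


@dataclass
class SimConfig:
    """Knobs of the sketch simulator; defaults reproduce the stock world."""

    cell: UnitCell = field(default_factory=default_cell)
    beam: BeamModel = field(default_factory=default_beam)
    geometry: DetectorGeometry = field(default_factory=four_panel_geometry)
    e_max: float = DEFAULT_E_MAX
    keep_prob: float = 0.5
    round_pixels: bool = True
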