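"""Lab-frame detector model: panels, hierarchy, ray projection and corrections.

The detector is a set of planar panels in the lab frame.  Each panel carries a
corner position (the lab position of the (fs, ss) = (0, 0) pixel corner, in mm)
and two orthonormal in-plane scan directions, ``fs_dir`` (fast scan) and
``ss_dir`` (slow scan).  Panels are organised into a hierarchy of rigid groups;
alignment corrections (translations in mm, rotations in degrees about axes
through the group center) may be attached to any group and are applied
root-to-leaf.

Coordinate conventions: the lab frame is right-handed with the X-ray beam along
+z; pixel coordinates are 0-based and continuous, with (0, 0) at the panel
corner.
"""

from __future__ import annotations

import io
import math
import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DetectorPanel",
    "PanelGroup",
    "DetectorGeometry",
    "BeamModel",
    "CorrectionSet",
    "GeometryParseError",
    "HierarchyError",
    "load_geometry",
    "write_geometry",
    "lab_position",
    "intersect_ray",
    "group_center",
    "apply_corrections",
    "corner_motion",
    "rotation_matrix",
]

#: conversion factor, photon energy (eV) * wavelength (A)
HC_EV_A = 12398.42

PARAM_KINDS = ("tx", "ty", "tz", "rx", "ry", "rz")


class GeometryParseError(ValueError):
    """Raised when a geometry document is malformed."""


class HierarchyError(ValueError):
    """Raised when the panel-group hierarchy is not a tree."""


@dataclass(frozen=True)
class DetectorPanel:
    """One planar detector panel.

    Parameters are validated on construction: scan directions must be unit
    vectors (1e-12) and mutually orthogonal (1e-9 by default; relaxed to a
    warning for user-supplied files via ``strict_orthogonality=False`` in
    :func:`load_geometry`).
    """

    name: str
    corner_pos: np.ndarray  # (3,) mm
    fs_dir: np.ndarray  # (3,) unit
    ss_dir: np.ndarray  # (3,) unit
    n_fs: int
    n_ss: int
    pixel_size: float  # mm

    def __post_init__(self):
        object.__setattr__(self, "corner_pos", np.asarray(self.corner_pos, dtype=float))
        object.__setattr__(self, "fs_dir", np.asarray(self.fs_dir, dtype=float))
        object.__setattr__(self, "ss_dir", np.asarray(self.ss_dir, dtype=float))
        if self.pixel_size <= 0:
            raise ValueError(f"panel {self.name}: pixel_size must be positive")
        if self.n_fs < 1 or self.n_ss < 1:
            raise ValueError(f"panel {self.name}: pixel counts must be >= 1")
        for v, label in ((self.fs_dir, "fs"), (self.ss_dir, "ss")):
            if abs(np.linalg.norm(v) - 1.0) > 1e-12:
                raise ValueError(f"panel {self.name}: {label} direction is not a unit vector")
        dot = abs(float(self.fs_dir @ self.ss_dir))
        if dot > 1e-9:
            warnings.warn(
                f"panel {self.name}: scan axes not orthogonal (fs.ss = {dot:.3g})",
                stacklevel=2,
            )

    @property
    def normal(self) -> np.ndarray:
        return np.cross(self.fs_dir, self.ss_dir)

    @property
    def center(self) -> np.ndarray:
        """Mean of the four corner positions."""
        return self.corner_pos + self.pixel_size * (
            0.5 * self.n_fs * self.fs_dir + 0.5 * self.n_ss * self.ss_dir
        )


@dataclass
class PanelGroup:
    """A node of the rigid-group hierarchy; leaves are panel names (str)."""

    name: str
    children: list  # of PanelGroup or str (panel leaf names)

    def walk(self):
        """Yield this group and all descendant groups, depth-first."""
        yield self
        for child in self.children:
            if isinstance(child, PanelGroup):
                yield from child.walk()

    def leaf_panels(self) -> list[str]:
        out = []
        for child in self.children:
            if isinstance(child, PanelGroup):
                out.extend(child.leaf_panels())
            else:
                out.append(child)
        return out


@dataclass(frozen=True)
class BeamModel:
    """Incident beam: wavelength in Angstrom, direction fixed along +z."""

    wavelength: float

    def __post_init__(self):
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")

    @property
    def direction(self) -> np.ndarray:
        return np.array([0.0, 0.0, 1.0])

    @property
    def k_vector(self) -> np.ndarray:
        """Wavevector (0, 0, 1/lambda) in inverse Angstrom (no 2*pi)."""
        return np.array([0.0, 0.0, 1.0 / self.wavelength])


@dataclass
class DetectorGeometry:
    """Panels plus the rigid-group hierarchy."""

    panels: dict  # name -> DetectorPanel
    root: PanelGroup | None = None

    def __post_init__(self):
        if self.root is not None:
            self._validate_tree()

    def _validate_tree(self):
        seen_groups: set[str] = set()
        seen_leaves: list[str] = []
        for g in self.root.walk():
            if g.name in seen_groups:
                raise HierarchyError(f"group {g.name!r} appears more than once")
            seen_groups.add(g.name)
        for leaf in self.root.leaf_panels():
            if leaf not in self.panels:
                raise HierarchyError(f"hierarchy leaf {leaf!r} names no panel")
            seen_leaves.append(leaf)
        if len(seen_leaves) != len(set(seen_leaves)):
            raise HierarchyError("a panel is reachable through more than one path")

    def group(self, name: str) -> PanelGroup:
        for g in self.root.walk():
            if g.name == name:
                return g
        raise KeyError(f"no group named {name!r}")

    def group_names(self) -> list[str]:
        """All group names, root first, plus panel leaves (panels are groups of one)."""
        names = [g.name for g in self.root.walk()]
        names.extend(self.root.leaf_panels())
        return names

    def panels_under(self, name: str) -> list[str]:
        """Panel names governed by group or panel ``name``."""
        if name in self.panels:
            return [name]
        return self.group(name).leaf_panels()

    def copy(self) -> "DetectorGeometry":
        return DetectorGeometry(dict(self.panels), self.root)


class CorrectionSet(dict):
    """Mapping group/panel name -> (tx, ty, tz, rx, ry, rz).

    Translations in mm; rotations in degrees about axes through the group
    center along lab x, y, z.  Missing kinds default to zero.
    """

    @classmethod
    def from_entries(cls, entries):
        """Build from an iterable of (group, kind, amount) triples."""
        out = cls()
        for group, kind, amount in entries:
            vec = out.setdefault(group, np.zeros(6))
            vec[PARAM_KINDS.index(kind)] += amount
        return out

    def translation(self, group: str) -> np.ndarray:
        return np.asarray(self.get(group, np.zeros(6)))[:3]

    def rotation_deg(self, group: str) -> np.ndarray:
        return np.asarray(self.get(group, np.zeros(6)))[3:]


def rotation_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    """Exact rotation Rz(rz) @ Ry(ry) @ Rx(rx); angles in radians."""
    cx, sx = math.cos(rx), math.sin(rx)
    cy, sy = math.cos(ry), math.sin(ry)
    cz, sz = math.cos(rz), math.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def lab_position(panel: DetectorPanel, fs, ss) -> np.ndarray:
    """Lab position (mm) of continuous pixel coordinates (fs, ss) on ``panel``.

    Vectorised over fs/ss arrays: returns shape (..., 3).
    """
    fs = np.asarray(fs, dtype=float)
    ss = np.asarray(ss, dtype=float)
    return (
        panel.corner_pos
        + panel.pixel_size * (fs[..., None] * panel.fs_dir + ss[..., None] * panel.ss_dir)
    )


def _panel_ray_coords(panel: DetectorPanel, directions: np.ndarray):
    """Intersect rays from the origin with the panel plane.

    Returns (t, fs, ss) arrays; t is the ray parameter in mm (nan where the
    ray is parallel to the plane or hits it behind the origin).
    """
    d = np.atleast_2d(directions)
    n = panel.normal
    denom = d @ n
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(np.abs(denom) > 1e-12, (panel.corner_pos @ n) / denom, np.nan)
    t = np.where(t > 0, t, np.nan)
    p = t[:, None] * d - panel.corner_pos
    fs = (p @ panel.fs_dir) / panel.pixel_size
    ss = (p @ panel.ss_dir) / panel.pixel_size
    return t, fs, ss


def intersect_ray(geometry: DetectorGeometry, direction: np.ndarray):
    """Intersect a single ray from the sample (origin) with the detector.

    Returns (panel_name, fs, ss) for the in-bounds hit with the smallest ray
    parameter, or None if no panel is hit.
    """
    best = None
    best_t = np.inf
    for panel in geometry.panels.values():
        t, fs, ss = _panel_ray_coords(panel, direction)
        t, fs, ss = float(t[0]), float(fs[0]), float(ss[0])
        if not np.isfinite(t):
            continue
        if 0 <= fs < panel.n_fs and 0 <= ss < panel.n_ss and t < best_t:
            best = (panel.name, fs, ss)
            best_t = t
    return best


def intersect_rays(geometry: DetectorGeometry, directions: np.ndarray):
    """Vectorised ray intersection.

    Returns (panel_index, fs, ss) arrays where panel_index indexes the
    geometry's panel order and is -1 for misses.  Panel order follows
    ``geometry.panels`` insertion order.
    """
    d = np.atleast_2d(directions)
    n_ray = d.shape[0]
    best_t = np.full(n_ray, np.inf)
    panel_idx = np.full(n_ray, -1, dtype=int)
    fs_out = np.full(n_ray, np.nan)
    ss_out = np.full(n_ray, np.nan)
    for i, panel in enumerate(geometry.panels.values()):
        t, fs, ss = _panel_ray_coords(panel, d)
        ok = (
            np.isfinite(t)
            & (fs >= 0)
            & (fs < panel.n_fs)
            & (ss >= 0)
            & (ss < panel.n_ss)
            & (t < best_t)
        )
        best_t[ok] = t[ok]
        panel_idx[ok] = i
        fs_out[ok] = fs[ok]
        ss_out[ok] = ss[ok]
    return panel_idx, fs_out, ss_out


def project_on_panel(panel: DetectorPanel, directions: np.ndarray):
    """Panel-frame (fs, ss) of ray intersections with one panel's plane.

    Out-of-bounds coordinates are returned as-is (the caller decides); rays
    parallel to the plane give nan.
    """
    _, fs, ss = _panel_ray_coords(panel, np.atleast_2d(directions))
    return fs, ss


def group_center(group, geometry: DetectorGeometry) -> np.ndarray:
    """Rotation center of a group: recursive unweighted mean of child centers.

    A leaf panel's center is the mean of its four corners.  ``group`` may be a
    PanelGroup, a group name, or a panel name (a panel is its own group).
    """
    if isinstance(group, str):
        if group in geometry.panels:
            return geometry.panels[group].center
        group = geometry.group(group)
    if not group.children:
        raise ValueError(f"group {group.name!r} is empty")
    centers = []
    for child in group.children:
        if isinstance(child, PanelGroup):
            centers.append(group_center(child, geometry))
        else:
            centers.append(geometry.panels[child].center)
    return np.mean(centers, axis=0)


def _transform_panel(panel: DetectorPanel, R: np.ndarray, center: np.ndarray,
                     translation: np.ndarray) -> DetectorPanel:
    corner = R @ (panel.corner_pos - center) + center + translation
    return replace(
        panel,
        corner_pos=corner,
        fs_dir=R @ panel.fs_dir,
        ss_dir=R @ panel.ss_dir,
    )


def apply_corrections(geometry: DetectorGeometry, corrections: CorrectionSet) -> DetectorGeometry:
    """Apply group corrections root-to-leaf; returns a new geometry.

    Each group's rotation is taken about the group's center as positioned by
    its ancestors' (already applied) corrections; the translation is added
    afterwards.  Corrections may also address individual panels by name.
    """
    known = set(geometry.group_names()) if geometry.root is not None else set(geometry.panels)
    for name in corrections:
        if name not in known:
            raise KeyError(f"correction references unknown group {name!r}")

    panels = dict(geometry.panels)
    out = DetectorGeometry(panels, geometry.root)

    def apply_one(name: str, affected: list[str]):
        vec = np.asarray(corrections.get(name, np.zeros(6)), dtype=float)
        if not vec.any():
            return
        R = rotation_matrix(*np.radians(vec[3:]))
        center = group_center(name, out)
        for pname in affected:
            panels[pname] = _transform_panel(panels[pname], R, center, vec[:3])

    if geometry.root is not None:
        def recurse(node):
            if isinstance(node, PanelGroup):
                apply_one(node.name, [p for p in node.leaf_panels()])
                for child in node.children:
                    recurse(child)
            else:
                apply_one(node, [node])
        recurse(geometry.root)
    else:
        for pname in panels:
            apply_one(pname, [pname])
    return out


def corner_motion(geometry: DetectorGeometry, corrections: CorrectionSet, panel: str) -> np.ndarray:
    """Lab displacement (mm) of a panel's (0, 0) corner under ``corrections``."""
    moved = apply_corrections(geometry, corrections)
    return moved.panels[panel].corner_pos - geometry.panels[panel].corner_pos


# ---------------------------------------------------------------------------
# Geometry text dialect


_VEC_RE = re.compile(r"([+-]?\d*\.?\d+(?:[eE][+-]?\d+)?)\s*([xyz])")

_MANDATORY_PANEL_KEYS = (
    "corner_x", "corner_y", "corner_z", "fs", "ss", "pixel_size", "n_fs", "n_ss",
)


def _parse_axis_vector(text: str, where: str) -> np.ndarray:
    v = np.zeros(3)
    matches = _VEC_RE.findall(text)
    if not matches:
        raise GeometryParseError(f"{where}: cannot parse direction {text!r}")
    for value, axis in matches:
        v["xyz".index(axis)] += float(value)
    return v


def load_geometry(text: str, strict_orthogonality: bool = True):
    """Parse a geometry document; returns (DetectorGeometry, BeamModel).

    The dialect is line-oriented ``key = value``.  Beam: ``wavelength = 1.3776 A``
    or ``photon_energy = 9000 eV``.  Panels: ``<name>/corner_x`` (mm), ``fs``/``ss``
    direction strings like ``+1.0x +0.0y``, ``pixel_size`` (mm), ``n_fs``/``n_ss``
    (alternatively ``min_fs``/``max_fs`` inclusive ranges).  Hierarchy:
    ``group_<name> = child1,child2`` where children are group or panel names;
    exactly one group must be unreferenced (the root).  Unknown keys warn.
    """
    wavelength = None
    panel_fields: dict[str, dict] = {}
    groups: dict[str, list[str]] = {}

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split(";")[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise GeometryParseError(f"line {lineno}: expected 'key = value': {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        if key == "wavelength":
            wavelength = float(value.split()[0])
        elif key == "photon_energy":
            wavelength = HC_EV_A / float(value.split()[0])
        elif key.startswith("group_"):
            groups[key[len("group_"):]] = [c.strip() for c in value.split(",") if c.strip()]
        elif "/" in key:
            pname, field_ = key.split("/", 1)
            panel_fields.setdefault(pname, {})[field_] = (value, lineno)
        else:
            warnings.warn(f"line {lineno}: unknown key {key!r} ignored", stacklevel=2)

    if wavelength is None:
        raise GeometryParseError("missing mandatory key: wavelength or photon_energy")
    beam = BeamModel(wavelength=wavelength)

    panels = {}
    for pname, fields in panel_fields.items():
        def get(fkey, pname=pname, fields=fields):
            if fkey not in fields:
                raise GeometryParseError(f"missing mandatory key {pname}/{fkey}")
            return fields[fkey][0]

        if "n_fs" in fields:
            n_fs, n_ss = int(get("n_fs")), int(get("n_ss"))
        elif "min_fs" in fields:
            n_fs = int(get("max_fs")) - int(get("min_fs")) + 1
            n_ss = int(get("max_ss")) - int(get("min_ss")) + 1
        else:
            raise GeometryParseError(f"missing mandatory key {pname}/n_fs")
        for fkey in ("corner_x", "corner_y", "corner_z", "fs", "ss", "pixel_size"):
            get(fkey)
        known = {"corner_x", "corner_y", "corner_z", "fs", "ss", "pixel_size",
                 "n_fs", "n_ss", "min_fs", "max_fs", "min_ss", "max_ss"}
        for fkey, (_, lineno) in fields.items():
            if fkey not in known:
                warnings.warn(f"line {lineno}: unknown panel key {pname}/{fkey} ignored",
                              stacklevel=2)
        fs_dir = _parse_axis_vector(get("fs"), f"{pname}/fs")
        ss_dir = _parse_axis_vector(get("ss"), f"{pname}/ss")
        for v, label in ((fs_dir, "fs"), (ss_dir, "ss")):
            norm = np.linalg.norm(v)
            if norm == 0:
                raise GeometryParseError(f"{pname}/{label}: zero direction")
            v /= norm
        if strict_orthogonality and abs(fs_dir @ ss_dir) > 1e-9:
            raise GeometryParseError(f"{pname}: fs and ss directions not orthogonal")
        panels[pname] = DetectorPanel(
            name=pname,
            corner_pos=np.array([float(get("corner_x")), float(get("corner_y")),
                                 float(get("corner_z"))]),
            fs_dir=fs_dir,
            ss_dir=ss_dir,
            n_fs=n_fs,
            n_ss=n_ss,
            pixel_size=float(get("pixel_size")),
        )

    root = _build_tree(groups, panels) if groups else None
    return DetectorGeometry(panels, root), beam


def _build_tree(groups: dict, panels: dict) -> PanelGroup:
    referenced = {c for children in groups.values() for c in children}
    roots = [g for g in groups if g not in referenced]
    if len(roots) != 1:
        raise HierarchyError(f"expected exactly one root group, found {roots!r}")

    building: set[str] = set()

    def build(name: str) -> PanelGroup:
        if name in building:
            raise HierarchyError(f"cyclic group definition involving {name!r}")
        building.add(name)
        children = []
        for c in groups[name]:
            if c in groups:
                children.append(build(c))
            elif c in panels:
                children.append(c)
            else:
                raise HierarchyError(f"group {name!r} child {c!r} is neither group nor panel")
        building.discard(name)
        return PanelGroup(name, children)

    return build(roots[0])


def write_geometry(geometry: DetectorGeometry, beam: BeamModel) -> str:
    """Serialise to the documented dialect; inverse of :func:`load_geometry`."""
    buf = io.StringIO()
    buf.write(f"wavelength = {float(beam.wavelength)!r} A\n\n")
    for panel in geometry.panels.values():
        p = panel.name
        cx, cy, cz = (float(x) for x in panel.corner_pos)
        buf.write(f"{p}/corner_x = {cx!r}\n")
        buf.write(f"{p}/corner_y = {cy!r}\n")
        buf.write(f"{p}/corner_z = {cz!r}\n")
        for label, v in (("fs", panel.fs_dir), ("ss", panel.ss_dir)):
            buf.write(f"{p}/{label} = {float(v[0])!r}x {float(v[1])!r}y {float(v[2])!r}z\n")
        buf.write(f"{p}/pixel_size = {float(panel.pixel_size)!r}\n")
        buf.write(f"{p}/n_fs = {panel.n_fs}\n")
        buf.write(f"{p}/n_ss = {panel.n_ss}\n\n")
    if geometry.root is not None:
        for g in geometry.root.walk():
            names = [c.name if isinstance(c, PanelGroup) else c for c in g.children]
            buf.write(f"group_{g.name} = {','.join(names)}\n")
    return buf.getvalue()
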