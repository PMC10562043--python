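"""Parametric active-volume geometries for small-field dosimetry detectors.

Three shape families cover the detectors in common use on Gamma Knife
Perfexion:

* ``chamber`` — ionization chamber: cylindrical gas cavity, optionally a
  hemispherical cap on top, minus a coaxial central electrode entering
  from the stem (bottom) end;
* ``disk`` — thin cylindrical sensitive element (diodes, diamond,
  scintillator fibers), axis along z;
* ``box`` — rectangular sensitive element.

Detector-local coordinates place the centroid of the active volume at the
origin with the long axis parallel to the device z axis, matching how the
detector is positioned in the field (reference point at the field center,
long axis along z).  Exact chamber cavity dimensions are generally not
published; the shipped library encodes dimensions consistent with the
manufacturers' nominal active volumes and published length/diameter
ratios, and flags each entry ``approximate`` where the drawing is not
fully determined by its designation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "DetectorGeometry",
    "volume",
    "contains",
    "load_detector_library",
    "monte_carlo_volume",
]


@dataclass(frozen=True)
class DetectorGeometry:
    """One detector's active volume, in mm.

    ``chamber``: ``cavity_radius``/``cavity_length`` describe the
    cylindrical part, ``cap`` adds a hemispherical top of the same radius,
    and ``electrode_radius``/``electrode_length`` a coaxial cylinder
    subtracted from the stem end.  ``disk`` uses ``radius``/``thickness``;
    ``box`` uses ``dx, dy, dz``.
    """

    name: str
    shape: str
    detector_type: str = "unspecified"
    # chamber
    cavity_radius: float = 0.0
    cavity_length: float = 0.0
    cap: bool = False
    electrode_radius: float = 0.0
    electrode_length: float = 0.0
    # disk
    radius: float = 0.0
    thickness: float = 0.0
    # box
    dx: float = 0.0
    dy: float = 0.0
    dz: float = 0.0
    nominal_volume_mm3: float | None = None
    approximate: bool = True

    def __post_init__(self):
        if self.shape not in ("chamber", "disk", "box"):
            raise ValueError(f"{self.name}: unknown shape {self.shape!r}")
        if self.shape == "chamber":
            if self.cavity_radius <= 0 or self.cavity_length <= 0:
                raise ValueError(f"{self.name}: chamber needs positive cavity dimensions")
            if self.electrode_radius >= self.cavity_radius:
                raise ValueError(f"{self.name}: electrode must be narrower than the cavity")
            max_len = self.cavity_length + (self.cavity_radius if self.cap else 0.0)
            if self.electrode_length > max_len:
                raise ValueError(f"{self.name}: electrode longer than the cavity")
        elif self.shape == "disk":
            if self.radius <= 0 or self.thickness <= 0:
                raise ValueError(f"{self.name}: disk needs positive radius and thickness")
        else:
            if min(self.dx, self.dy, self.dz) <= 0:
                raise ValueError(f"{self.name}: box needs positive edge lengths")

    # -- derived geometry -------------------------------------------------

    @property
    def volume_mm3(self) -> float:
        return volume(self)

    @property
    def z_centroid_body(self) -> float:
        """Centroid of the active volume along z in the *body* frame.

        Body frame: cylinder/disk/box centered at 0, cap (if any) on top of
        the cylinder, electrode entering from the bottom.  The detector is
        placed with this centroid at the field center.
        """
        if self.shape != "chamber":
            return 0.0
        r, L = self.cavity_radius, self.cavity_length
        v_cyl = math.pi * r * r * L
        num = 0.0
        den = v_cyl
        if self.cap:
            v_cap = (2.0 / 3.0) * math.pi * r ** 3
            num += v_cap * (L / 2.0 + 3.0 * r / 8.0)
            den += v_cap
        if self.electrode_radius > 0 and self.electrode_length > 0:
            v_e = math.pi * self.electrode_radius ** 2 * self.electrode_length
            num -= v_e * (-L / 2.0 + self.electrode_length / 2.0)
            den -= v_e
        return num / den

    def bounding_box(self):
        """(lo, hi) corners of an axis-aligned box enclosing the active
        volume in detector-local (centroid-at-origin) coordinates."""
        zc = self.z_centroid_body
        if self.shape == "chamber":
            r, L = self.cavity_radius, self.cavity_length
            z_top = L / 2.0 + (r if self.cap else 0.0)
            lo = np.array([-r, -r, -L / 2.0 - zc])
            hi = np.array([r, r, z_top - zc])
        elif self.shape == "disk":
            r, t = self.radius, self.thickness
            lo = np.array([-r, -r, -t / 2.0])
            hi = np.array([r, r, t / 2.0])
        else:
            half = np.array([self.dx, self.dy, self.dz]) / 2.0
            lo, hi = -half, half
        return lo, hi


def volume(geometry: DetectorGeometry) -> float:
    """Closed-form active volume in mm^3."""
    g = geometry
    if g.shape == "disk":
        return math.pi * g.radius ** 2 * g.thickness
    if g.shape == "box":
        return g.dx * g.dy * g.dz
    v = math.pi * g.cavity_radius ** 2 * g.cavity_length
    if g.cap:
        v += (2.0 / 3.0) * math.pi * g.cavity_radius ** 3
    v -= math.pi * g.electrode_radius ** 2 * g.electrode_length
    return v


def contains(geometry: DetectorGeometry, points) -> np.ndarray:
    """Point-in-active-volume test in detector-local coordinates.

    Boundaries of the body count as inside; the electrode is removed as an
    open set so its boundary also counts as inside (a measure-zero
    convention, fixed for determinism).
    """
    g = geometry
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    x, y, z = pts[..., 0], pts[..., 1], pts[..., 2]
    r2 = x * x + y * y
    if g.shape == "box":
        half = np.array([g.dx, g.dy, g.dz]) / 2.0
        inside = np.all(np.abs(pts) <= half, axis=-1)
    elif g.shape == "disk":
        inside = (r2 <= g.radius ** 2) & (np.abs(z) <= g.thickness / 2.0)
    else:
        zb = z + g.z_centroid_body  # back to body frame
        L, R = g.cavity_length, g.cavity_radius
        inside = (np.abs(zb) <= L / 2.0) & (r2 <= R * R)
        if g.cap:
            in_cap = (zb >= L / 2.0) & (r2 + (zb - L / 2.0) ** 2 <= R * R)
            inside |= in_cap
        if g.electrode_radius > 0 and g.electrode_length > 0:
            in_elec = ((r2 < g.electrode_radius ** 2)
                       & (zb > -L / 2.0) & (zb < -L / 2.0 + g.electrode_length))
            inside &= ~in_elec
    if np.asarray(points).ndim == 1:
        return bool(inside[0])
    return inside


def monte_carlo_volume(geometry: DetectorGeometry, n: int = 10 ** 6,
                       seed: int = 0) -> tuple[float, float]:
    """Monte Carlo volume estimate: (estimate, standard error) in mm^3.

    Uniform points in the bounding box times the inclusion fraction;
    serves as an independent check of the closed-form volume.
    """
    rng = np.random.default_rng(seed)
    lo, hi = geometry.bounding_box()
    pts = rng.uniform(lo, hi, size=(n, 3))
    frac = contains(geometry, pts).mean()
    box = float(np.prod(hi - lo))
    se = box * math.sqrt(max(frac * (1 - frac), 1e-30) / n)
    return box * frac, se


_REQUIRED = {"shape"}


def load_detector_library(path=None) -> list[DetectorGeometry]:
    """Load a detector-geometry library from YAML.

    With no ``path`` the shipped 14-detector library is returned.  Raises
    ``ValueError`` with the offending entry's name on schema violations.
    """
    if path is None:
        text = resources.files("gkvol.data").joinpath("detectors.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    if not raw or "detectors" not in raw or not raw["detectors"]:
        raise ValueError("detector library is empty or missing a 'detectors' list")
    out = []
    for entry in raw["detectors"]:
        name = entry.get("name", "<unnamed>")
        missing = _REQUIRED - entry.keys()
        if missing:
            raise ValueError(f"detector {name!r}: missing fields {sorted(missing)}")
        try:
            out.append(DetectorGeometry(**entry))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"detector {name!r}: {exc}") from exc
    return out
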