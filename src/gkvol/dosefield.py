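"""The 3D elliptical dose model for a single Gamma Knife shot.

The three fitted principal-axis profiles are combined with
squared-direction-cosine weights: at displacement dr = r - r1 with radial
distance rho = |dr|,

    D(r) = sum_k D_k(s_k * rho) * (dr_k / rho)^2 ,   k in {x, y, z}

where each 1D profile D_k is center-normalized (D_k(0) = 1).  The weights
sum to one, so the model reduces exactly to the corresponding 1D profile
on each principal axis, a uniform set of profiles yields a uniform field,
and equal x/y profiles make every XY cross-section circular while the
distinct z profile makes XZ sections elliptical.  The z profile is
evaluated at the signed distance sign(dr_z) * rho so its hemispheric
asymmetry carries over to the 3D model; x/y models are symmetric, for
which the sign is irrelevant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .profiles import ErfSumModel

__all__ = ["DoseField", "isodose_points", "isodose_radius"]


@dataclass
class DoseField:
    """Three center-normalized principal-axis profiles for one collimator.

    ``model_x/y/z`` may be :class:`ErfSumModel` instances or any callables
    mapping off-axis distance (mm) to relative dose; each is normalized
    internally by its value at 0, so evaluation returns dimensionless dose
    with 1.0 at the field center.
    """

    field_size_mm: int
    model_x: object
    model_y: object
    model_z: object
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        if self.center.shape != (3,):
            raise ValueError("center must be a 3-vector")
        self._d0 = np.array([float(m(0.0)) for m in self.models])
        if np.any(self._d0 <= 0):
            raise ValueError("each profile must be positive at the field center")

    @property
    def models(self):
        return (self.model_x, self.model_y, self.model_z)

    def evaluate(self, points) -> np.ndarray:
        """Normalized dose at one or more 3D points (mm); center = 1 exactly."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        if pts.shape[-1] != 3:
            raise ValueError("points must have shape (..., 3)")
        dr = pts - self.center
        rho2 = np.einsum("...i,...i->...", dr, dr)
        rho = np.sqrt(rho2)
        safe = np.where(rho2 > 0, rho2, 1.0)
        w = dr ** 2 / safe[..., None]
        # signed argument on z propagates the profile asymmetry to z<0 / z>0
        sz = np.where(dr[..., 2] < 0, -1.0, 1.0)
        dose = (w[..., 0] * self.model_x(rho) / self._d0[0]
                + w[..., 1] * self.model_y(rho) / self._d0[1]
                + w[..., 2] * self.model_z(sz * rho) / self._d0[2])
        dose = np.where(rho2 > 0, dose, 1.0)
        return float(dose[0]) if single else dose

    def __call__(self, points):
        return self.evaluate(points)

    # -- serialization (erf-sum models only) ------------------------------

    def to_dict(self) -> dict:
        models = {}
        for name, m in zip(("x", "y", "z"), self.models):
            if not isinstance(m, ErfSumModel):
                raise TypeError("only ErfSumModel-based fields are serializable")
            models[name] = m.to_dict()
        return {"field_size_mm": int(self.field_size_mm),
                "center": self.center.tolist(), "models": models}

    @classmethod
    def from_dict(cls, d: dict) -> "DoseField":
        return cls(field_size_mm=int(d["field_size_mm"]),
                   model_x=ErfSumModel.from_dict(d["models"]["x"]),
                   model_y=ErfSumModel.from_dict(d["models"]["y"]),
                   model_z=ErfSumModel.from_dict(d["models"]["z"]),
                   center=np.asarray(d.get("center", [0, 0, 0]), float))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "DoseField":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def isodose_radius(field: DoseField, direction, level: float,
                   max_radius: float = 100.0, tol: float = 1e-9) -> float:
    """Distance from the center to the ``level`` isodose along ``direction``.

    Scans outward for a bracket, then bisects.  Raises ``ValueError`` if the
    dose never falls to ``level`` within ``max_radius`` mm.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("isodose level must lie strictly between 0 and 1")
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)

    def f(r):
        return field.evaluate(field.center + r * u) - level

    lo, hi = 0.0, 1.0
    while f(hi) > 0:
        lo, hi = hi, 2.0 * hi
        if hi > max_radius:
            raise ValueError(f"dose does not reach level {level} within {max_radius} mm")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def isodose_points(field: DoseField, level: float, n_samples: int,
                   seed: int = 0) -> np.ndarray:
    """Points on the ``level`` isodose surface, found by bisection along
    random directions.  Each returned point satisfies
    |evaluate - level| < 1e-6."""
    rng = np.random.default_rng(seed)
    dirs = rng.normal(size=(n_samples, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    pts = np.empty((n_samples, 3))
    for i, u in enumerate(dirs):
        r = isodose_radius(field, u, level)
        pts[i] = field.center + r * u
    return pts
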