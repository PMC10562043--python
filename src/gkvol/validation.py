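"""Model-accuracy check against a reference (TPS-style) dose point set.

The elliptical model's absorbed-dose prediction is validated over
isodose-bounded volumes: the integral of dose from the center out to a
given isodose is approximated by summing point doses inside that volume,
for both the reference point set and the model, and compared as a signed
relative error

    R_v = (D_ref - D_model) / D_ref * 100 %.

Membership in the volume is decided by the *reference* dose value (the
isodose envelope is drawn on the reference distribution), and the same
point subset feeds both sums, so R_v is invariant under a common rescaling
of the two dose sets and is identically zero when the reference doses were
generated by the model itself.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

__all__ = ["ReferencePointSet", "dose_sum", "model_error"]


@dataclass(frozen=True)
class ReferencePointSet:
    """Reference dose points: positions in mm, relative doses in percent."""

    points: np.ndarray     # (n, 3), mm
    doses: np.ndarray      # (n,), %
    field_size_mm: int

    def __post_init__(self):
        object.__setattr__(self, "points", np.asarray(self.points, dtype=float))
        object.__setattr__(self, "doses", np.asarray(self.doses, dtype=float))
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must have shape (n, 3)")
        if self.doses.shape != (self.points.shape[0],):
            raise ValueError("doses must be one value per point")
        if self.points.shape[0] == 0:
            raise ValueError("reference set must contain at least one point")

    def __len__(self) -> int:
        return self.points.shape[0]

    def to_csv(self, path) -> None:
        arr = np.column_stack([self.points, self.doses])
        np.savetxt(path, arr, delimiter=",",
                   header="x_mm,y_mm,z_mm,dose_percent", comments="")

    @classmethod
    def from_csv(cls, path, field_size_mm: int) -> "ReferencePointSet":
        with open(path) as fh:
            lines = [ln for ln in fh if ln.strip() and not ln.lstrip().startswith("#")]
        data = np.loadtxt(io.StringIO("".join(lines[1:])), delimiter=",", ndmin=2)
        return cls(points=data[:, :3], doses=data[:, 3],
                   field_size_mm=field_size_mm)


def _select(ref: ReferencePointSet, level_low: float) -> np.ndarray:
    if not 0.0 < level_low < 1.0:
        raise ValueError("level_low must lie strictly between 0 and 1")
    mask = ref.doses >= level_low * 100.0
    if not mask.any():
        raise ValueError(f"no reference point has dose >= {level_low:.0%}: empty volume")
    return mask


def dose_sum(doses, level_low: float, membership_doses=None) -> float:
    """Sum of point doses inside the ``level_low`` isodose volume.

    ``membership_doses`` (default: ``doses`` itself) decides which points
    lie inside the volume; pass the reference doses here when summing
    model doses over the reference-defined envelope so that both sums use
    the same point subset.
    """
    if not 0.0 < level_low < 1.0:
        raise ValueError("level_low must lie strictly between 0 and 1")
    doses = np.asarray(doses, dtype=float)
    member = doses if membership_doses is None else np.asarray(membership_doses, float)
    mask = member >= level_low * 100.0
    if not mask.any():
        raise ValueError(f"no point has dose >= {level_low:.0%}: empty volume")
    return float(doses[mask].sum())


def model_error(ref: ReferencePointSet, field, level_low: float) -> float:
    """Signed relative dose error R_v (%) of the model over the reference
    ``level_low`` isodose volume."""
    mask = _select(ref, level_low)
    d_ref = float(ref.doses[mask].sum())
    if d_ref == 0:
        raise ValueError("reference dose sum is zero")
    d_model = float(np.sum(field.evaluate(ref.points[mask]) * 100.0))
    return (d_ref - d_model) / d_ref * 100.0
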