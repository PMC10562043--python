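"""Volume-averaging correction factors by quadrature over detector volumes.

A finite detector centered at the field's dose maximum reads the mean dose
over its active volume, underestimating the point dose.  The correction

    k_vol = D / D_mean = V / integral_V D_norm(r) d^3r

is computed by composite Simpson quadrature of the center-normalized
elliptical dose model over the detector's active volume, with the default
100 steps per spatial direction resolving k_vol to the third decimal.

Bodies of revolution (chambers, disks) are integrated in cylindrical
coordinates (z, rho, phi) piecewise over the smooth sub-domains
(cylindrical cavity, hemispherical cap, electrode), with the radial
coordinate mapped to a fixed unit grid so the domain boundary is exact and
Simpson's convergence order is preserved; the electrode enters as a signed
(negative) contribution.  Boxes are integrated on a Cartesian grid.  A
uniform-random Monte Carlo mean over the same volume serves as an
independent cross-check (:func:`monte_carlo_mean_dose`).

The clin/msr ratio divides the clinical-field k_vol by the 16 mm
machine-specific-reference-field k_vol, and the volume contribution to the
field output correction factor divides that ratio by the published TRS-483
field output correction factor k_Q.  Reported values are rounded half away
from zero to 3 decimals; all chaining uses full precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import simpson

from .detectors import DetectorGeometry, contains, volume

__all__ = [
    "KvolResult",
    "kvol",
    "mean_dose",
    "monte_carlo_mean_dose",
    "kvol_ratio",
    "volume_contribution",
    "flag_unsuitable",
    "round_half_away",
    "TRS483_LOWER",
    "TRS483_UPPER",
]

#: TRS-483 suitability band for the volume-averaging correction factor
TRS483_LOWER = 0.95
TRS483_UPPER = 1.05


def round_half_away(x: float, ndigits: int = 3) -> float:
    """Round half away from zero (0.0005 -> 0.001), the convention used
    for reported 3-decimal correction factors."""
    scale = 10 ** ndigits
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class KvolResult:
    """k_vol for one detector in one field.

    ``mean_dose`` is the volume average of the center-normalized dose, so
    ``kvol == 1 / mean_dose``; when the field center is the dose maximum
    over the detector volume, ``kvol >= 1``.
    """

    detector: str
    field_size_mm: int
    kvol: float
    mean_dose: float
    steps_per_axis: int


def _simpson_cyl_segment(field, z0, z1, rho_max, steps, z_shift):
    """Integral of D over one body of revolution segment, cylindrical
    coordinates, radial coordinate mapped to u = rho/rho_max(z) in [0,1].

    ``rho_max`` is a callable of z (body frame); ``z_shift`` converts body
    frame z to detector-local/field z.
    """
    nz = nu = nphi = steps
    z = np.linspace(z0, z1, nz + 1)
    u = np.linspace(0.0, 1.0, nu + 1)
    phi = np.linspace(0.0, 2.0 * np.pi, nphi + 1)
    rmax = np.asarray(rho_max(z), dtype=float)

    rho = u[None, :] * rmax[:, None]                      # (nz+1, nu+1)
    pts = np.empty((nz + 1, nu + 1, nphi + 1, 3))
    pts[..., 0] = rho[..., None] * np.cos(phi)
    pts[..., 1] = rho[..., None] * np.sin(phi)
    pts[..., 2] = (z - z_shift)[:, None, None]
    dose = field.evaluate(pts.reshape(-1, 3)).reshape(nz + 1, nu + 1, nphi + 1)

    integrand = dose * (u[None, :, None] * (rmax ** 2)[:, None, None])
    inner = simpson(integrand, x=phi, axis=-1)
    inner = simpson(inner, x=u, axis=-1)
    return float(simpson(inner, x=z, axis=-1))


def mean_dose(field, detector: DetectorGeometry, steps_per_axis: int = 100) -> float:
    """Volume average of the normalized dose over the detector's active
    volume, detector centroid at the field center, long axis along z."""
    if steps_per_axis < 2 or steps_per_axis % 2:
        raise ValueError("steps_per_axis must be even and >= 2")
    g = detector
    n = steps_per_axis
    if g.shape == "box":
        xs = np.linspace(-g.dx / 2, g.dx / 2, n + 1)
        ys = np.linspace(-g.dy / 2, g.dy / 2, n + 1)
        zs = np.linspace(-g.dz / 2, g.dz / 2, n + 1)
        pts = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1)
        dose = field.evaluate(pts.reshape(-1, 3)).reshape(n + 1, n + 1, n + 1)
        integral = simpson(simpson(simpson(dose, x=zs), x=ys), x=xs)
        return float(integral) / volume(g)

    if g.shape == "disk":
        integral = _simpson_cyl_segment(
            field, -g.thickness / 2, g.thickness / 2,
            lambda z: np.full_like(z, g.radius), n, z_shift=0.0)
        return integral / volume(g)

    # chamber: signed sum over cylinder + cap - electrode, body frame
    zc = g.z_centroid_body
    L, R = g.cavity_length, g.cavity_radius
    integral = _simpson_cyl_segment(
        field, -L / 2, L / 2, lambda z: np.full_like(z, R), n, z_shift=zc)
    if g.cap:
        integral += _simpson_cyl_segment(
            field, L / 2, L / 2 + R,
            lambda z: np.sqrt(np.maximum(R * R - (z - L / 2) ** 2, 0.0)),
            n, z_shift=zc)
    if g.electrode_radius > 0 and g.electrode_length > 0:
        integral -= _simpson_cyl_segment(
            field, -L / 2, -L / 2 + g.electrode_length,
            lambda z: np.full_like(z, g.electrode_radius), n, z_shift=zc)
    return integral / volume(g)


def kvol(field, detector: DetectorGeometry, steps_per_axis: int = 100) -> KvolResult:
    """Volume-averaging correction factor for one detector in one field."""
    md = mean_dose(field, detector, steps_per_axis)
    if md <= 0:
        raise RuntimeError(
            f"{detector.name}: non-positive mean dose {md}; invalid field")
    return KvolResult(
        detector=detector.name,
        field_size_mm=int(getattr(field, "field_size_mm", 0)),
        kvol=1.0 / md,
        mean_dose=md,
        steps_per_axis=steps_per_axis,
    )


def monte_carlo_mean_dose(field, detector: DetectorGeometry,
                          n: int = 10 ** 6, seed: int = 0) -> float:
    """Independent stochastic oracle: mean normalized dose over uniform
    random points inside the active volume (rejection from the bounding
    box).  Standard error scales as std(D)/sqrt(n_inside)."""
    rng = np.random.default_rng(seed)
    lo, hi = detector.bounding_box()
    pts = rng.uniform(lo, hi, size=(n, 3))
    mask = contains(detector, pts)
    if not mask.any():
        raise RuntimeError(f"{detector.name}: no sample fell inside the volume")
    return float(np.mean(field.evaluate(pts[mask])))


def kvol_ratio(kvol_clin: float, kvol_msr: float) -> float:
    """Clin/msr volume-averaging ratio (full precision; round only when
    reporting)."""
    if kvol_clin <= 0 or kvol_msr <= 0:
        raise ValueError("k_vol values must be positive")
    return kvol_clin / kvol_msr


def volume_contribution(ratio: float, kq: float) -> float:
    """Volume-averaging contribution to the field output correction
    factor: clin/msr k_vol ratio divided by the TRS-483 k_Q."""
    if kq <= 0:
        raise ValueError("field output correction factor kQ must be positive")
    return ratio / kq


def flag_unsuitable(table: pd.DataFrame, lower: float = TRS483_LOWER,
                    upper: float = TRS483_UPPER) -> pd.DataFrame:
    """Flag detector/field cells whose k_vol falls outside the TRS-483
    suitability band [lower, upper] (bounds inclusive = not flagged).

    Operates on the ``kvol_*`` columns of a correction table; returns a
    boolean frame with matching index and one column per field.
    """
    cols = [c for c in table.columns if c.startswith("kvol_")]
    if not cols:
        raise ValueError("table has no kvol_* columns")
    flags = pd.DataFrame(index=table.index)
    for c in cols:
        vals = pd.to_numeric(table[c], errors="coerce")
        flags[c.replace("kvol", "flagged")] = (vals < lower) | (vals > upper)
    return flags
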