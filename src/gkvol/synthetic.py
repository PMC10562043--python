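"""Synthetic vendor-style profiles and TPS-style reference point sets.

The vendor's Monte Carlo dose profiles and the treatment planning system's
exported point doses are not redistributable, so this module generates
stand-ins with the statistical structure the method assumes: flat-topped
two-erf profiles with field-size-dependent FWHM and penumbra, an optional
positive/negative penumbra-width skew for the asymmetric z axis, seeded
Gaussian noise at the sub-percent level typical of Monte Carlo profile
statistics, and rejection-sampled reference points whose doses come from
the model itself (optionally biased to emulate model-TPS disagreement).

Default FWHMs equal the nominal 16/8/4 mm collimator designations for the
x/y axes (the designation is the 50 % isodose diameter), with a slightly
smaller z FWHM reflecting the shorter device-axis profile; penumbra widths
narrow with field size.  These defaults are documented approximations of a
generic Perfexion field, not vendor data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .dosefield import DoseField
from .profiles import ProfileCurve
from .validation import ReferencePointSet

__all__ = [
    "ProfileSpec",
    "generate_profile",
    "default_profile_specs",
    "default_field",
    "generate_reference_points",
    "DEFAULT_POINT_COUNTS",
]

#: reference point-set sizes per field, matching a typical TPS export
DEFAULT_POINT_COUNTS = {16: 1700, 8: 783, 4: 378}

#: default 80-20 penumbra widths (mm) per field size for x/y profiles
_DEFAULT_PENUMBRA = {16: 2.0, 8: 1.4, 4: 1.0}
#: z profile is slightly shorter than x/y for the same collimator
_Z_FWHM_FACTOR = 0.85
#: z-axis penumbra skew (positive side wider), strongest at 16 mm
_DEFAULT_SKEW = {16: 0.15, 8: 0.08, 4: 0.02}

# 80-20 distance of an erf edge of width b is 2*erfinv(0.6)*b
_EDGE_8020 = 2.0 * special.erfinv(0.6)


@dataclass(frozen=True)
class ProfileSpec:
    """Parameters of one synthetic principal-axis profile."""

    field_size_mm: int
    axis: str
    fwhm: float                 # mm, 50 % isodose width
    penumbra_80_20: float       # mm, mean 80-20 penumbra distance
    asymmetry: float = 0.0      # fractional +/- penumbra-width skew (z only)
    noise_sd: float = 0.0       # %, Gaussian noise on sampled doses
    n_points: int = 201
    span: float | None = None   # mm, total sampled extent (default 3*fwhm)
    seed: int = 0

    def __post_init__(self):
        if self.fwhm <= 0 or self.penumbra_80_20 <= 0:
            raise ValueError("fwhm and penumbra must be positive")
        if self.n_points < 20:
            raise ValueError("need at least 20 sample points")
        if not -0.9 < self.asymmetry < 0.9:
            raise ValueError("asymmetry must lie in (-0.9, 0.9)")


def _flat_top(k, h, b_neg, b_pos):
    """Two-erf flat-top: rises at -h with width b_neg, falls at +h with
    width b_pos; plateau 100 for b << h."""
    return 50.0 * (special.erf((k + h) / b_neg) - special.erf((k - h) / b_pos))


def generate_profile(spec: ProfileSpec) -> ProfileCurve:
    """Sample a synthetic profile; deterministic per seed, max scaled to 100."""
    span = spec.span if spec.span is not None else 3.0 * spec.fwhm
    k = np.linspace(-span / 2.0, span / 2.0, spec.n_points)
    h = spec.fwhm / 2.0
    b = spec.penumbra_80_20 / _EDGE_8020
    b_pos = b * (1.0 + spec.asymmetry)
    b_neg = b * (1.0 - spec.asymmetry)
    doses = _flat_top(k, h, b_neg, b_pos)
    doses *= 100.0 / doses.max()
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        doses = doses + rng.normal(0.0, spec.noise_sd, size=doses.shape)
        doses = np.clip(doses, 0.0, 110.0)
    return ProfileCurve(axis=spec.axis, field_size_mm=spec.field_size_mm,
                        positions=k, doses=doses)


def default_profile_specs(field_size_mm: int, noise_sd: float = 0.0,
                          seed: int = 0) -> dict[str, ProfileSpec]:
    """The stated generic-Perfexion conditions for one collimator: one
    spec per principal axis (x = y symmetric; z shorter and skewed)."""
    if field_size_mm not in _DEFAULT_PENUMBRA:
        raise ValueError("field size must be one of 16, 8, 4 mm")
    pen = _DEFAULT_PENUMBRA[field_size_mm]
    specs = {}
    for i, axis in enumerate(("x", "y", "z")):
        if axis == "z":
            fwhm = _Z_FWHM_FACTOR * field_size_mm
            pen_axis = _Z_FWHM_FACTOR * pen
            skew = _DEFAULT_SKEW[field_size_mm]
        else:
            fwhm, pen_axis, skew = float(field_size_mm), pen, 0.0
        specs[axis] = ProfileSpec(
            field_size_mm=field_size_mm, axis=axis, fwhm=fwhm,
            penumbra_80_20=pen_axis, asymmetry=skew, noise_sd=noise_sd,
            seed=seed + 97 * field_size_mm + i)
    return specs


def default_field(field_size_mm: int, scale_profiles: float = 1.0) -> DoseField:
    """Analytic fixture field for one collimator built directly from the
    generator's underlying flat-top functions (no fitting, no noise).

    ``scale_profiles`` proportionally rescales FWHM and penumbra together,
    giving the family of geometrically similar fields used for field-size
    trend checks.
    """
    specs = default_profile_specs(field_size_mm)

    def make(spec: ProfileSpec):
        h = scale_profiles * spec.fwhm / 2.0
        b = scale_profiles * spec.penumbra_80_20 / _EDGE_8020
        bp, bn = b * (1 + spec.asymmetry), b * (1 - spec.asymmetry)
        return lambda k: _flat_top(np.asarray(k, float), h, bn, bp)

    return DoseField(field_size_mm=field_size_mm,
                     model_x=make(specs["x"]), model_y=make(specs["y"]),
                     model_z=make(specs["z"]))


def generate_reference_points(field: DoseField, n: int | None = None,
                              dose_range: tuple[float, float] = (19.0, 99.0),
                              seed: int = 0, bias: float = 0.0,
                              z_resolution: float = 1.0) -> ReferencePointSet:
    """Rejection-sample a TPS-style reference point set from a dose field.

    Points are uniform over a bounding cube, z snapped to the
    ``z_resolution`` grid *before* dose lookup, and kept when the model
    dose (in %) falls inside ``dose_range``.  Stored doses are the model
    doses times ``(1 + bias)``, so ``bias = 0`` makes the model-error
    identity exact and a uniform bias of +1 % yields R_v of about 0.99 %.
    """
    if n is None:
        n = DEFAULT_POINT_COUNTS.get(field.field_size_mm, 500)
    if n <= 0:
        raise ValueError("n must be positive")
    lo, hi = dose_range
    if not 0.0 < lo < hi <= 100.0:
        raise ValueError("dose_range must satisfy 0 < low < high <= 100")
    rng = np.random.default_rng(seed)
    span = 2.0 * field.field_size_mm  # generously covers the 19 % isodose
    pts_out = np.empty((0, 3))
    doses_out = np.empty(0)
    for _ in range(200):
        m = max(4 * n, 1000)
        cand = rng.uniform(-span, span, size=(m, 3))
        cand[:, 2] = np.round(cand[:, 2] / z_resolution) * z_resolution
        dose = field.evaluate(cand) * 100.0
        keep = (dose >= lo) & (dose <= hi)
        pts_out = np.vstack([pts_out, cand[keep]])
        doses_out = np.concatenate([doses_out, dose[keep]])
        if len(doses_out) >= n:
            break
    else:
        raise ValueError("dose_range appears infeasible for this field")
    return ReferencePointSet(points=pts_out[:n],
                             doses=doses_out[:n] * (1.0 + bias),
                             field_size_mm=field.field_size_mm)
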