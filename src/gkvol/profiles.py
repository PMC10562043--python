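"""Principal-axis relative dose profiles and their erf-sum representation.

A Gamma Knife Perfexion shot produces, along each principal frame axis
(x, y, z), a flat-topped relative dose profile with steep penumbrae.  Each
profile is modelled analytically as a sum of error functions

    D(k) = sum_i A_i * erf((k + a_i) / b_i) + C0

where ``k`` is the off-axis distance in mm.  The x and y profiles are
treated as perfectly symmetric about the beam axis (only non-negative
off-axis values enter the fit and the model is evaluated at ``|k|``); the
z profile is asymmetric because the 192 Co-60 sources are distributed
symmetrically around the device z axis only, so it is fitted over the full
range with a single global erf-sum.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import optimize, special

__all__ = [
    "erf",
    "ProfileCurve",
    "ErfSumModel",
    "FitReport",
    "evaluate_profile",
    "fit_profile",
]

#: axes of the Leksell stereotactic frame; z is the device axis
AXES = ("x", "y", "z")
FIELD_SIZES_MM = (16, 8, 4)

#: erf-sum term counts that describe the vendor-style profiles well:
#: 4 terms for every x/y profile, 5 for the asymmetric z profiles of the
#: 16 and 8 mm collimators, 2 for the nearly symmetric 4 mm z profile.
DEFAULT_TERM_COUNTS = {
    ("x", 16): 4, ("x", 8): 4, ("x", 4): 4,
    ("y", 16): 4, ("y", 8): 4, ("y", 4): 4,
    ("z", 16): 5, ("z", 8): 5, ("z", 4): 2,
}


def erf(z):
    """Gauss error function, (2/sqrt(pi)) * integral_0^z exp(-t^2) dt."""
    return special.erf(z)


@dataclass(frozen=True)
class ProfileCurve:
    """Sampled relative dose versus off-axis distance on one principal axis.

    Doses are in percent with the profile maximum near 100; positions are
    strictly increasing, in mm.
    """

    axis: str
    field_size_mm: int
    positions: np.ndarray
    doses: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=float))
        object.__setattr__(self, "doses", np.asarray(self.doses, dtype=float))
        if self.axis not in AXES:
            raise ValueError(f"axis must be one of {AXES}, got {self.axis!r}")
        if self.positions.ndim != 1 or self.positions.shape != self.doses.shape:
            raise ValueError("positions and doses must be 1-d arrays of equal length")
        if not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.doses < 0) or np.any(self.doses > 110):
            raise ValueError("doses must lie in [0, 110] percent")

    @property
    def symmetric(self) -> bool:
        """x/y profiles are symmetric about the axis; z is not."""
        return self.axis in ("x", "y")

    def to_csv(self, path) -> None:
        arr = np.column_stack([self.positions, self.doses])
        header = "position_mm,dose_percent"
        np.savetxt(path, arr, delimiter=",", header=header, comments="")

    @classmethod
    def from_csv(cls, path, axis: str, field_size_mm: int) -> "ProfileCurve":
        """Read a two-column ``position_mm, dose_percent`` CSV (header row
        required, ``#`` comment lines allowed)."""
        with open(path) as fh:
            lines = [ln for ln in fh if ln.strip() and not ln.lstrip().startswith("#")]
        data = np.loadtxt(io.StringIO("".join(lines[1:])), delimiter=",", ndmin=2)
        order = np.argsort(data[:, 0])
        return cls(axis=axis, field_size_mm=field_size_mm,
                   positions=data[order, 0], doses=data[order, 1])


@dataclass(frozen=True)
class ErfSumModel:
    """Fitted analytical profile: n erf terms plus a constant offset.

    When ``symmetric`` is set the model is evaluated at ``|k|`` so that
    f(k) == f(-k) holds exactly.
    """

    A: np.ndarray          # amplitudes, %
    a: np.ndarray          # shifts, mm (term transition sits at k = -a_i)
    b: np.ndarray          # widths, mm, strictly positive
    c0: float              # offset, %
    symmetric: bool = False

    def __post_init__(self):
        for name in ("A", "a", "b"):
            object.__setattr__(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        if not (self.A.shape == self.a.shape == self.b.shape) or self.A.ndim != 1:
            raise ValueError("A, a, b must be 1-d arrays of equal length")
        if self.n < 1:
            raise ValueError("at least one erf term is required")
        if np.any(self.b <= 0):
            raise ValueError("all widths b must be strictly positive")

    @property
    def n(self) -> int:
        return self.A.size

    def __call__(self, k):
        return evaluate_profile(self, k)

    def to_dict(self) -> dict:
        return {
            "n": int(self.n),
            "A": self.A.tolist(),
            "a": self.a.tolist(),
            "b": self.b.tolist(),
            "c0": float(self.c0),
            "symmetric": bool(self.symmetric),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ErfSumModel":
        return cls(A=np.asarray(d["A"], float), a=np.asarray(d["a"], float),
                   b=np.asarray(d["b"], float), c0=float(d["c0"]),
                   symmetric=bool(d["symmetric"]))


@dataclass(frozen=True)
class FitReport:
    """Outcome of a profile fit: model plus goodness-of-fit diagnostics."""

    model: ErfSumModel
    r_squared: float
    residual_max: float      # %
    residual_rms: float      # %
    success: bool = True

    def to_yaml(self, path) -> None:
        payload = dict(self.model.to_dict(), r_squared=float(self.r_squared))
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def evaluate_profile(model: ErfSumModel, k):
    """Evaluate the erf-sum profile at off-axis distance(s) ``k`` (mm).

    Symmetric models are evaluated at ``|k|``.  Returns relative dose in
    the same units the model was fitted in (percent for shipped fits).
    """
    k = np.asarray(k, dtype=float)
    if model.symmetric:
        k = np.abs(k)
    z = (k[..., None] + model.a) / model.b
    return np.sum(model.A * special.erf(z), axis=-1) + model.c0


def _initial_guess(k, d, n, symmetric, rng=None):
    """Physics-informed starting point: transitions at the 50 % crossings,
    widths from the 80-20 penumbra distance, amplitudes from the plateau."""
    plateau = float(np.max(d))
    tail = float(np.min(d))
    height = plateau - tail
    half = tail + 0.5 * height

    def crossing(side):
        # outermost 50 % crossing on the requested side of the origin
        mask = k >= 0 if side > 0 else k <= 0
        kk, dd = k[mask], d[mask]
        below = dd < half
        if not below.any() or below.all():
            return 0.6 * np.max(np.abs(kk)) if kk.size else 1.0
        if side > 0:
            i = int(np.argmax(below))  # first point past the edge
            i = max(i, 1)
            k0, k1, d0, d1 = kk[i - 1], kk[i], dd[i - 1], dd[i]
        else:
            i = int(len(below) - 1 - np.argmax(below[::-1]))  # last below point
            i = min(i, len(kk) - 2)
            k0, k1, d0, d1 = kk[i], kk[i + 1], dd[i], dd[i + 1]
        if d1 == d0:
            return abs(k0)
        return abs(k0 + (half - d0) * (k1 - k0) / (d1 - d0))

    edge_pos = max(crossing(+1), 1e-2)
    edge_neg = max(crossing(-1), 1e-2) if not symmetric else edge_pos

    # 80-20 distance on the positive side -> erf width scale
    lo, hi = tail + 0.2 * height, tail + 0.8 * height
    pos = k >= 0 if symmetric else k > edge_pos / 2
    kk, dd = k[pos], d[pos]
    in_pen = (dd > lo) & (dd < hi)
    span = np.ptp(kk[in_pen]) if in_pen.sum() >= 2 else 0.15 * edge_pos
    b0 = max(span, 0.05 * edge_pos) / (2.0 * special.erfinv(0.6))

    spreads = np.linspace(0.85, 1.15, max(n, 1))
    scales = np.geomspace(0.6, 1.8, max(n, 1))

    if symmetric:
        # only a falling edge is needed: negative amplitudes, a ~ -edge
        A0 = np.full(n, -0.5 * height / n)
        a0 = -edge_pos * spreads
        b_init = b0 * scales
        c0 = tail + 0.5 * height
    else:
        n_rise = n // 2
        n_fall = n - n_rise
        A0 = np.concatenate([
            np.full(n_rise, +0.5 * height / max(n_rise, 1)),
            np.full(n_fall, -0.5 * height / n_fall),
        ])
        a0 = np.concatenate([
            +edge_neg * spreads[:n_rise],
            -edge_pos * spreads[:n_fall],
        ])
        b_init = b0 * scales
        c0 = tail
    theta = np.concatenate([A0, a0, b_init, [c0]])
    if rng is not None:
        jitter = np.ones_like(theta)
        jitter[: 3 * n] = rng.lognormal(0.0, 0.25, size=3 * n)
        theta = theta * jitter
        theta[2 * n: 3 * n] = np.abs(theta[2 * n: 3 * n])
    return theta


def _unpack(theta, n, symmetric):
    return ErfSumModel(A=theta[:n], a=theta[n:2 * n],
                       b=np.maximum(theta[2 * n:3 * n], 1e-6),
                       c0=theta[-1], symmetric=symmetric)


def fit_profile(curve: ProfileCurve, n: int | None = None,
                symmetric: bool | None = None, *,
                n_starts: int = 5, seed: int = 0) -> FitReport:
    """Least-squares fit of an erf-sum to a sampled profile.

    Uses trust-region least squares (``scipy.optimize.least_squares``)
    with a deterministic physics-informed start plus ``n_starts - 1``
    seeded jittered restarts; the lowest-cost solution wins.  The erf-sum
    parameterization is degenerate (term permutations, compensating
    sign structures), so quality is judged on the predicted curve: the
    report carries R^2 and residual statistics on the fitted points.

    For symmetric curves only the non-negative positions are fitted and
    the model is evaluated at ``|k|``.

    Raises ``ValueError`` for a constant curve (R^2 undefined) or too few
    points; non-convergence of every restart is reported via
    ``FitReport.success = False`` with the best-so-far model.
    """
    if symmetric is None:
        symmetric = curve.symmetric
    if n is None:
        n = DEFAULT_TERM_COUNTS[(curve.axis, curve.field_size_mm)]
    k, d = curve.positions, curve.doses
    if symmetric:
        mask = k >= 0
        k, d = k[mask], d[mask]
    if k.size < 3 * n + 1:
        raise ValueError(f"need at least {3 * n + 1} points to fit n={n} terms, have {k.size}")
    if np.ptp(d) == 0:
        raise ValueError("constant profile: zero variance, R^2 undefined")

    lower = np.concatenate([np.full(n, -np.inf), np.full(n, -np.inf),
                            np.full(n, 1e-3), [-np.inf]])
    upper = np.full(3 * n + 1, np.inf)

    def residuals(theta):
        return evaluate_profile(_unpack(theta, n, symmetric), k) - d

    rng = np.random.default_rng(seed)
    best = None
    any_converged = False
    for start in range(n_starts):
        theta0 = _initial_guess(k, d, n, symmetric, rng=None if start == 0 else rng)
        theta0 = np.clip(theta0, lower + 1e-9, None)
        try:
            res = optimize.least_squares(residuals, theta0, bounds=(lower, upper),
                                         method="trf", max_nfev=4000)
        except Exception:
            continue
        any_converged = any_converged or res.status > 0
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("profile fit failed to evaluate from any start")

    model = _unpack(best.x, n, symmetric)
    pred = evaluate_profile(model, k)
    resid = pred - d
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((d - d.mean()) ** 2))
    return FitReport(
        model=model,
        r_squared=1.0 - ss_res / ss_tot,
        residual_max=float(np.max(np.abs(resid))),
        residual_rms=float(np.sqrt(np.mean(resid ** 2))),
        success=bool(any_converged),
    )
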