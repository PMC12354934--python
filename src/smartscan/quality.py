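"""Quality curves and their inversion to a minimal rescan fraction.

A quality curve maps a rescan fraction ``x`` in [0, 1] to an image-quality
value ``q(x)`` in [0, 1] and is assumed continuous and non-decreasing.  The
packaged default is a shifted logistic that is exactly 1 at ``x = 1``;
empirical curves can be fitted from (fraction, accuracy) samples by isotonic
regression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import UnreachableQualityError, ValidationError
from .runtime_model import RescanPlan

ArrayLike = Union[float, np.ndarray]

DEFAULT_STEEPNESS = 4.0


@dataclass(frozen=True)
class QualityCurve:
    """A monotone map from rescan fraction to quality.

    Attributes
    ----------
    evaluator : callable
        Maps ``x`` in [0, 1] (scalar or ndarray) to quality values.
    q0, q1 : float
        The curve's endpoint values ``q(0)`` and ``q(1)``.
    name : str
        Human-readable label used in reports.
    """

    evaluator: Callable[[ArrayLike], ArrayLike]
    q0: float
    q1: float
    name: str = "quality curve"

    def __call__(self, x: ArrayLike) -> ArrayLike:
        arr = np.asarray(x, dtype=float)
        if np.any(arr < 0.0) or np.any(arr > 1.0):
            raise ValidationError(
                f"rescan fraction must lie in [0, 1], got {x!r}"
            )
        out = self.evaluator(arr)
        return float(out) if np.isscalar(x) or arr.ndim == 0 else np.asarray(out)


def logistic_quality(x: ArrayLike, k: float = DEFAULT_STEEPNESS) -> ArrayLike:
    """Shifted logistic quality function with steepness ``k``.

    ``q(x) = 1/(1 + e^(-k x)) + e^(-k)/(1 + e^(-k))``, rewritten as
    ``1 + (t/(1+t) - s/(1+s))`` with ``s = e^(-k x)``, ``t = e^(-k)`` so that
    ``q(1) == 1.0`` holds exactly in floating point for every ``k > 0``.
    """
    if not (isinstance(k, (int, float)) and k > 0):
        raise ValidationError(f"steepness k must be positive, got {k!r}")
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValidationError(f"rescan fraction must lie in [0, 1], got {x!r}")
    s = np.exp(-k * arr)
    t = np.exp(-float(k))
    out = 1.0 + (t / (1.0 + t) - s / (1.0 + s))
    return float(out) if arr.ndim == 0 else out


def logistic_curve(k: float = DEFAULT_STEEPNESS) -> QualityCurve:
    """The packaged logistic :class:`QualityCurve` (default steepness 4)."""
    return QualityCurve(
        evaluator=lambda x: logistic_quality(x, k),
        q0=float(logistic_quality(0.0, k)),
        q1=float(logistic_quality(1.0, k)),
        name=f"logistic(k={k:g})",
    )


def invert_for_alpha(
    curve: QualityCurve,
    quality_standard: float,
    tol: float = 1e-9,
    max_iter: int = 200,
) -> RescanPlan:
    """Smallest rescan fraction whose quality meets ``quality_standard``.

    Located by bisection on [0, 1] to within ``tol``.  Returns exactly 0 when
    the standard is already met with no rescanning.  For curves with
    plateaus the left edge of the qualifying plateau is returned (within
    ``tol``).

    Raises
    ------
    UnreachableQualityError
        If ``quality_standard`` is negative or exceeds ``q(1)``.
    """
    if not (isinstance(tol, (int, float)) and tol > 0):
        raise ValidationError(f"tol must be positive, got {tol!r}")
    q = quality_standard
    if q < 0.0 or q > curve.q1:
        raise UnreachableQualityError(q, curve.q0, curve.q1)
    if q <= curve.q0:
        return RescanPlan(0.0)
    lo, hi = 0.0, 1.0  # invariant: q(lo) < standard <= q(hi)
    for _ in range(max_iter):
        if hi - lo <= tol:
            break
        mid = 0.5 * (lo + hi)
        if curve(mid) >= q:
            hi = mid
        else:
            lo = mid
    return RescanPlan(hi)


@dataclass(frozen=True)
class CurveValidation:
    """Outcome of a monotonicity/range check on a grid."""

    ok: bool
    first_violation_x: Optional[float] = None
    reason: Optional[str] = None


def validate_quality_curve(
    curve: QualityCurve, grid_size: int = 101, tol: float = 1e-9
) -> CurveValidation:
    """Check a curve on a uniform grid: values stay in [0, 1] and never
    decrease by more than ``tol``.  Reports the first violating grid point."""
    if not (isinstance(grid_size, int) and grid_size >= 2):
        raise ValidationError(f"grid_size must be an integer >= 2, got {grid_size!r}")
    xs = np.linspace(0.0, 1.0, grid_size)
    qs = np.asarray(curve(xs), dtype=float)
    for i, (x, v) in enumerate(zip(xs, qs)):
        if not (-tol <= v <= 1.0 + tol):
            return CurveValidation(False, float(x), f"value {v!r} outside [0, 1]")
        if i > 0 and v < qs[i - 1] - tol:
            return CurveValidation(
                False, float(x), f"decrease from {qs[i - 1]!r} to {v!r}"
            )
    return CurveValidation(True)


@dataclass(frozen=True)
class QualitySample:
    """One measured (rescan fraction, accuracy) point, with replicate info."""

    rescan_fraction: float
    accuracy: float
    n_replicates: int = 1
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None


def fit_monotone_curve(samples: Sequence[QualitySample]) -> QualityCurve:
    """Fit a monotone piecewise-linear curve through quality samples.

    Accuracies are regressed on rescan fraction with isotonic
    (pool-adjacent-violators) regression, clamped to [0, 1], and connected
    by linear interpolation; the fit extends constantly outside the sampled
    fraction range.
    """
    from sklearn.isotonic import IsotonicRegression

    if len(samples) < 2:
        raise ValidationError(f"need at least 2 samples, got {len(samples)}")
    xs = np.asarray([s.rescan_fraction for s in samples], dtype=float)
    ys = np.asarray([s.accuracy for s in samples], dtype=float)
    if np.any(xs < 0.0) or np.any(xs > 1.0):
        raise ValidationError("rescan fractions must lie in [0, 1]")
    if np.all(xs == xs[0]):
        raise ValidationError("degenerate design: all samples at one rescan fraction")
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
    iso.fit(xs, ys)

    def evaluator(x: ArrayLike) -> ArrayLike:
        arr = np.atleast_1d(np.asarray(x, dtype=float))
        out = iso.predict(arr)
        return out[0] if np.ndim(x) == 0 else out

    return QualityCurve(
        evaluator=evaluator,
        q0=float(iso.predict([0.0])[0]),
        q1=float(iso.predict([1.0])[0]),
        name=f"isotonic fit ({len(samples)} samples)",
    )


def write_quality_samples(samples: Sequence[QualitySample], path) -> None:
    """Write samples as the two-column exchange CSV (rescan_fraction, quality)."""
    df = pd.DataFrame(
        {
            "rescan_fraction": [s.rescan_fraction for s in samples],
            "quality": [s.accuracy for s in samples],
        }
    )
    df.to_csv(path, index=False)


def read_quality_samples(path) -> list[QualitySample]:
    """Read the two-column exchange CSV produced by :func:`write_quality_samples`."""
    df = pd.read_csv(path)
    required = {"rescan_fraction", "quality"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"quality sample CSV must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    return [
        QualitySample(rescan_fraction=float(r.rescan_fraction), accuracy=float(r.quality))
        for r in df.itertuples()
    ]
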