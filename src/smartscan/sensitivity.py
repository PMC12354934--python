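"""One-parameter-at-a-time sensitivity sweeps of the runtime model."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import UnreachableQualityError, ValidationError
from .quality import QualityCurve, invert_for_alpha, logistic_curve
from .runtime_model import (
    AcquisitionParams,
    RescanPlan,
    parallel_smart_runtime,
    serial_smart_runtime,
    traditional_runtime,
)

#: Parameters that may be swept.  Traditional imaging time is deliberately
#: excluded: it is the fixed yardstick the smart modes are compared against.
SWEEPABLE_PARAMETERS = (
    "quality_standard",
    "n_tiles",
    "n_sections",
    "t_fast_s",
    "t_slow_s",
    "t_compute_s",
    "t_tile_s",
    "t_section_s",
)

_COUNT_PARAMS = ("n_tiles", "n_sections")


@dataclass(frozen=True)
class SweepSpec:
    """One sweep: vary ``parameter`` over ``values``, all else held at ``base``."""

    parameter: str
    values: Sequence
    base: AcquisitionParams = field(default_factory=AcquisitionParams)
    curve: QualityCurve = field(default_factory=logistic_curve)

    def __post_init__(self) -> None:
        if self.parameter == "t_trad_s":
            raise ValidationError(
                "t_trad_s is not swept in the model's sensitivity analysis"
            )
        if self.parameter not in SWEEPABLE_PARAMETERS:
            raise ValidationError(
                f"unknown sweep parameter {self.parameter!r}; "
                f"expected one of {SWEEPABLE_PARAMETERS}"
            )
        if len(self.values) == 0:
            raise ValidationError("sweep values must be non-empty")
        # Domain checks mirror AcquisitionParams invariants.
        for v in self.values:
            if self.parameter in _COUNT_PARAMS:
                if not (isinstance(v, (int, np.integer)) and v >= 1):
                    raise ValidationError(
                        f"{self.parameter} values must be integers >= 1, got {v!r}"
                    )
            elif self.parameter == "quality_standard":
                if not 0.0 <= v <= 1.0:
                    raise ValidationError(
                        f"quality_standard values must lie in [0, 1], got {v!r}"
                    )
            elif v < 0:
                raise ValidationError(
                    f"{self.parameter} values must be non-negative, got {v!r}"
                )


@dataclass(frozen=True)
class SweepResult:
    """Sweep output; ``table`` has one row per swept value with columns
    (value, alpha, reachable, t_traditional_s, t_smart_serial_s,
    t_smart_parallel_s)."""

    spec: SweepSpec
    table: pd.DataFrame


def sweep_parameter(spec: SweepSpec) -> SweepResult:
    """Evaluate all three analytic runtimes at each swept value.

    At every row the rescan fraction is re-derived by inverting the quality
    curve at that row's quality standard (it only changes when
    ``quality_standard`` itself is swept).  A standard outside the curve's
    range marks the row unreachable — smart runtimes are NaN — and the sweep
    continues.
    """
    rows = []
    for v in spec.values:
        value = int(v) if spec.parameter in _COUNT_PARAMS else float(v)
        p = spec.base.replace(**{spec.parameter: value})
        try:
            alpha = invert_for_alpha(spec.curve, p.quality_standard).alpha
            reachable = True
        except UnreachableQualityError:
            alpha, reachable = float("nan"), False
        if reachable:
            plan = RescanPlan(alpha)
            serial = serial_smart_runtime(p, plan)
            parallel = parallel_smart_runtime(p, plan)
        else:
            serial = parallel = float("nan")
        rows.append(
            {
                "value": value,
                "alpha": alpha,
                "reachable": reachable,
                "t_traditional_s": traditional_runtime(p),
                "t_smart_serial_s": serial,
                "t_smart_parallel_s": parallel,
            }
        )
    return SweepResult(spec=spec, table=pd.DataFrame(rows))


def savings_table(result: SweepResult) -> pd.DataFrame:
    """Per-row time saved by each smart mode relative to traditional
    (may be negative)."""
    t = result.table
    return pd.DataFrame(
        {
            "value": t["value"],
            "savings_serial_s": t["t_traditional_s"] - t["t_smart_serial_s"],
            "savings_parallel_s": t["t_traditional_s"] - t["t_smart_parallel_s"],
        }
    )


def default_grid(parameter: str, base: AcquisitionParams, n_points: int = 25):
    """Default sweep grid: ``n_points`` evenly spaced values spanning 0.1x to
    10x the base value, clipped to the parameter's validity domain.  Count
    parameters are rounded to unique integers >= 1; a zero base time falls
    back to [0, 1]."""
    if parameter == "t_trad_s":
        raise ValidationError(
            "t_trad_s is not swept in the model's sensitivity analysis"
        )
    if parameter not in SWEEPABLE_PARAMETERS:
        raise ValidationError(
            f"unknown sweep parameter {parameter!r}; expected one of {SWEEPABLE_PARAMETERS}"
        )
    d = getattr(base, parameter)
    if parameter in _COUNT_PARAMS:
        raw = np.linspace(max(1.0, 0.1 * d), 10 * d, n_points)
        return [int(v) for v in np.unique(np.rint(raw).astype(int))]
    if parameter == "quality_standard":
        return list(np.linspace(max(0.0, 0.1 * d), min(1.0, 10 * d), n_points))
    if d == 0:
        return list(np.linspace(0.0, 1.0, n_points))
    return list(np.linspace(0.1 * d, 10 * d, n_points))


def sweep_all(
    base: AcquisitionParams = None,
    curve: QualityCurve = None,
    n_points: int = 25,
) -> dict[str, SweepResult]:
    """Run the default sweep for every sweepable parameter."""
    base = base if base is not None else AcquisitionParams()
    curve = curve if curve is not None else logistic_curve()
    out = {}
    for name in SWEEPABLE_PARAMETERS:
        spec = SweepSpec(name, default_grid(name, base, n_points), base, curve)
        out[name] = sweep_parameter(spec)
    return out


def plot_sweep(result: SweepResult, path=None, ax=None):
    """Plot the three runtimes against the swept value."""
    import matplotlib

    if path is not None and ax is None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.2))
    t = result.table
    ax.plot(t["value"], t["t_traditional_s"], label="traditional")
    ax.plot(t["value"], t["t_smart_serial_s"], label="smart serial")
    ax.plot(t["value"], t["t_smart_parallel_s"], label="smart parallel")
    ax.set_xlabel(result.spec.parameter)
    ax.set_ylabel("runtime (s)")
    ax.legend(fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
        return None
    return ax
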