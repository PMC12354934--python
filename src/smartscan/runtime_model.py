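"""Closed-form runtime models for traditional and smart acquisition workflows.

A *smart* workflow images every tile quickly, predicts which sub-regions need
better signal-to-noise, and selectively re-images a fraction ``alpha`` of each
tile at a slow dwell time.  This module provides the analytic end-to-end
runtimes of the three planning modes:

``traditional``
    Fixed-rate imaging of every tile, no rescanning.
``smart_serial``
    Per tile: fast scan, mask computation, rescan, strictly in sequence.
``smart_parallel_global``
    Fast scans for the whole volume are pipelined against mask computation on
    a second thread; a single rescan pass over all sections follows.

A fourth mode label, ``smart_parallel_per_section``, is realized by the
discrete-event simulator (:mod:`smartscan.des_simulator`); it has no closed
form and is included here only for breakdown/reporting purposes.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Mapping, Optional

from .errors import ValidationError

#: Canonical mode labels, in tie-break order (earlier wins a tie).
TRADITIONAL = "traditional"
SMART_SERIAL = "smart_serial"
SMART_PARALLEL_GLOBAL = "smart_parallel_global"
SMART_PARALLEL_PER_SECTION = "smart_parallel_per_section"

ANALYTIC_MODES = (TRADITIONAL, SMART_SERIAL, SMART_PARALLEL_GLOBAL)
ALL_MODES = ANALYTIC_MODES + (SMART_PARALLEL_PER_SECTION,)

#: Component keys of a runtime breakdown.
BREAKDOWN_COMPONENTS = (
    "section_transitions",
    "tile_transitions",
    "initial_scan",
    "compute",
    "rescan",
)

_NS_PER_S = 1e9


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass(frozen=True)
class TileSpec:
    """Pixel geometry of one tile plus the beam dwell time.

    Parameters
    ----------
    width_px, height_px : int
        Tile dimensions in pixels; must be positive.
    dwell_ns : float
        Beam dwell time per pixel in nanoseconds; must be positive and finite.
    """

    width_px: int
    height_px: int
    dwell_ns: float

    def __post_init__(self) -> None:
        _require(
            isinstance(self.width_px, int) and self.width_px > 0,
            f"width_px must be a positive integer, got {self.width_px!r}",
        )
        _require(
            isinstance(self.height_px, int) and self.height_px > 0,
            f"height_px must be a positive integer, got {self.height_px!r}",
        )
        _require(
            math.isfinite(self.dwell_ns) and self.dwell_ns > 0,
            f"dwell_ns must be positive and finite, got {self.dwell_ns!r}",
        )


def derive_tile_time(spec: TileSpec) -> float:
    """Per-tile imaging time in seconds: ``width * height * dwell_ns / 1e9``.

    Dividing by ``1e9`` (an exactly-representable power of ten) keeps the
    conversion correctly rounded, so e.g. a 12000 x 12000 px tile at 100 ns/px
    yields exactly the double nearest 14.4 s.
    """
    return spec.width_px * spec.height_px * spec.dwell_ns / _NS_PER_S


@dataclass(frozen=True)
class AcquisitionParams:
    """The nine workflow parameters of the acquisition model.

    Defaults are the model's reference operating point: 12000 x 12000 px
    tiles at 100 / 1000 ns per pixel fast / slow dwell times, 24 tiles per
    section and 30 sections.

    Attributes
    ----------
    quality_standard : float
        Minimum acceptable quality ``Q`` in [0, 1].
    n_tiles : int
        Tiles (fields of view) per section, >= 1.
    n_sections : int
        Number of serial sections, >= 1.
    t_trad_s : float
        Traditional imaging time per tile, seconds.
    t_fast_s : float
        Fast (overview) imaging time per tile, seconds.
    t_slow_s : float
        Slow imaging time for a *full* tile, seconds; a rescan of fraction
        ``alpha`` costs ``alpha * t_slow_s``.
    t_compute_s : float
        Rescan-mask computation time per tile, seconds.
    t_tile_s : float
        Stage transition time between tiles, seconds.
    t_section_s : float
        Stage transition time between sections, seconds.
    """

    quality_standard: float = 0.8
    n_tiles: int = 24
    n_sections: int = 30
    t_trad_s: float = 144.0
    t_fast_s: float = 14.4
    t_slow_s: float = 144.0
    t_compute_s: float = 28.8
    t_tile_s: float = 4.0
    t_section_s: float = 20.0

    def __post_init__(self) -> None:
        _require(
            0.0 <= self.quality_standard <= 1.0,
            f"quality_standard must lie in [0, 1], got {self.quality_standard!r}",
        )
        for name in ("n_tiles", "n_sections"):
            v = getattr(self, name)
            _require(
                isinstance(v, int) and v >= 1,
                f"{name} must be an integer >= 1, got {v!r}",
            )
        for name in (
            "t_trad_s",
            "t_fast_s",
            "t_slow_s",
            "t_compute_s",
            "t_tile_s",
            "t_section_s",
        ):
            v = getattr(self, name)
            _require(
                isinstance(v, (int, float)) and math.isfinite(v) and v >= 0,
                f"{name} must be a finite non-negative number, got {v!r}",
            )

    def replace(self, **changes) -> "AcquisitionParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    @classmethod
    def reference_defaults(cls) -> "AcquisitionParams":
        """The default operating point (all nine reference values)."""
        return cls()


def params_from_tile_geometry(
    tile_width_px: int,
    tile_height_px: int,
    fast_dwell_ns: float,
    slow_dwell_ns: float,
    trad_dwell_ns: float,
    **other,
) -> AcquisitionParams:
    """Build :class:`AcquisitionParams` with per-tile times derived from pixel
    geometry and dwell times; remaining fields are passed through ``other``."""
    return AcquisitionParams(
        t_fast_s=derive_tile_time(TileSpec(tile_width_px, tile_height_px, fast_dwell_ns)),
        t_slow_s=derive_tile_time(TileSpec(tile_width_px, tile_height_px, slow_dwell_ns)),
        t_trad_s=derive_tile_time(TileSpec(tile_width_px, tile_height_px, trad_dwell_ns)),
        **other,
    )


@dataclass(frozen=True)
class RescanPlan:
    """The rescanned fraction ``alpha`` of each tile, in [0, 1]."""

    alpha: float

    def __post_init__(self) -> None:
        _require(
            isinstance(self.alpha, (int, float)) and 0.0 <= self.alpha <= 1.0,
            f"alpha must lie in [0, 1], got {self.alpha!r}",
        )


def traditional_runtime(p: AcquisitionParams) -> float:
    """Total runtime of the traditional workflow:
    ``N_s * (T_sec + N_t * (T_tile + T_trad))``."""
    return p.n_sections * (p.t_section_s + p.n_tiles * (p.t_tile_s + p.t_trad_s))


def serial_smart_runtime(p: AcquisitionParams, plan: RescanPlan) -> float:
    """Total runtime of the serial smart workflow:
    ``N_s * (T_sec + N_t * (T_tile + T_fast + T_compute + alpha*T_slow))``."""
    per_tile = p.t_tile_s + p.t_fast_s + p.t_compute_s + plan.alpha * p.t_slow_s
    return p.n_sections * (p.t_section_s + p.n_tiles * per_tile)


def parallel_smart_runtime(p: AcquisitionParams, plan: RescanPlan) -> float:
    """Total runtime of the globally-pipelined smart workflow.

    The first pass overlaps fast imaging with mask computation on a second
    thread; its span is the pipeline start-up (one transition + fast scan)
    plus the longer of the remaining imaging or the remaining computation,
    plus the final compute.  A full rescan pass over every section and tile
    (charging a tile transition even for empty rescans) follows::

        (T_sec + T_tile + T_fast
         + max{(N_s-1)*T_sec + (n-1)*(T_tile + T_fast), (n-1)*T_compute}
         + T_compute)
        + N_s * (T_sec + N_t * (T_tile + alpha*T_slow))

    with ``n = N_s * N_t``.  This is a lower bound on the achievable
    schedule: it ignores compute idling at section boundaries (see
    :func:`smartscan.des_simulator.validate_against_analytic`).
    """
    n = p.n_sections * p.n_tiles
    first_pass = (
        p.t_section_s
        + p.t_tile_s
        + p.t_fast_s
        + max(
            (p.n_sections - 1) * p.t_section_s + (n - 1) * (p.t_tile_s + p.t_fast_s),
            (n - 1) * p.t_compute_s,
        )
        + p.t_compute_s
    )
    rescan_pass = p.n_sections * (
        p.t_section_s + p.n_tiles * (p.t_tile_s + plan.alpha * p.t_slow_s)
    )
    return first_pass + rescan_pass


@dataclass(frozen=True)
class RuntimeBreakdown:
    """Per-component decomposition of one mode's runtime.

    For serial modes the components sum to ``total_s``; for parallel modes
    the sum can exceed ``total_s`` because computation overlaps imaging.
    """

    mode: str
    total_s: float
    components: Mapping[str, float]


def breakdown(p: AcquisitionParams, plan: RescanPlan, mode: str) -> RuntimeBreakdown:
    """Decompose a mode's runtime into transition / scan / compute / rescan time.

    ``smart_parallel_per_section`` has no closed form; its total is taken
    from the discrete-event simulator.
    """
    n = p.n_sections * p.n_tiles
    if mode == TRADITIONAL:
        comps = {
            "section_transitions": p.n_sections * p.t_section_s,
            "tile_transitions": n * p.t_tile_s,
            "initial_scan": n * p.t_trad_s,
            "compute": 0.0,
            "rescan": 0.0,
        }
        total = traditional_runtime(p)
    elif mode == SMART_SERIAL:
        comps = {
            "section_transitions": p.n_sections * p.t_section_s,
            "tile_transitions": n * p.t_tile_s,
            "initial_scan": n * p.t_fast_s,
            "compute": n * p.t_compute_s,
            "rescan": n * plan.alpha * p.t_slow_s,
        }
        total = serial_smart_runtime(p, plan)
    elif mode in (SMART_PARALLEL_GLOBAL, SMART_PARALLEL_PER_SECTION):
        # Both parallel modes visit every tile twice (fast pass + rescan pass).
        comps = {
            "section_transitions": 2 * p.n_sections * p.t_section_s,
            "tile_transitions": 2 * n * p.t_tile_s,
            "initial_scan": n * p.t_fast_s,
            "compute": n * p.t_compute_s,
            "rescan": n * plan.alpha * p.t_slow_s,
        }
        if mode == SMART_PARALLEL_GLOBAL:
            total = parallel_smart_runtime(p, plan)
        else:
            from . import des_simulator  # local import avoids a cycle

            log = des_simulator.simulate_acquisition(
                p, plan, des_simulator.PARALLEL_PER_SECTION
            )
            total = des_simulator.makespan(log)
    else:
        raise ValidationError(f"unknown mode {mode!r}; expected one of {ALL_MODES}")
    return RuntimeBreakdown(mode=mode, total_s=total, components=comps)


@dataclass(frozen=True)
class ModeVerdict:
    """Which analytic mode is fastest, and by how much.

    ``margin_s`` is the seconds saved relative to the second-fastest mode.
    Ties are broken by the fixed order traditional < serial < parallel.
    """

    fastest_mode: str
    margin_s: float
    per_mode_totals: Mapping[str, float]


def compare_modes(p: AcquisitionParams, plan: RescanPlan) -> ModeVerdict:
    """Evaluate all three analytic modes and return the winner and margin."""
    totals = {
        TRADITIONAL: traditional_runtime(p),
        SMART_SERIAL: serial_smart_runtime(p, plan),
        SMART_PARALLEL_GLOBAL: parallel_smart_runtime(p, plan),
    }
    ordered = sorted(totals, key=lambda m: (totals[m], ANALYTIC_MODES.index(m)))
    fastest, runner_up = ordered[0], ordered[1]
    return ModeVerdict(
        fastest_mode=fastest,
        margin_s=totals[runner_up] - totals[fastest],
        per_mode_totals=totals,
    )


def breakeven_alpha(p: AcquisitionParams, mode: str) -> Optional[float]:
    """Rescan fraction at which a smart mode's runtime equals traditional.

    Both smart runtimes are affine in ``alpha``, so the crossing is solved in
    closed form.  Returns ``None`` when no crossing exists in [0, 1] —
    including the degenerate ``t_slow_s == 0`` case with unequal endpoints.
    """
    if mode == SMART_SERIAL:
        f = serial_smart_runtime
    elif mode == SMART_PARALLEL_GLOBAL:
        f = parallel_smart_runtime
    else:
        raise ValidationError(
            f"mode must be {SMART_SERIAL!r} or {SMART_PARALLEL_GLOBAL!r}, got {mode!r}"
        )
    target = traditional_runtime(p)
    at0 = f(p, RescanPlan(0.0)) - target
    at1 = f(p, RescanPlan(1.0)) - target
    slope = at1 - at0  # == n_sections * n_tiles * t_slow_s
    if slope == 0.0:
        return 0.0 if at0 == 0.0 else None
    alpha = -at0 / slope
    if 0.0 <= alpha <= 1.0:
        return alpha
    return None
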