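"""qHTS curve-class assignment, cytotoxicity flagging and hit triage.

Every titration receives exactly one curve class describing how much of a
classical sigmoidal dose-response it exhibits:

* ``1.1`` / ``1.2`` — complete sigmoid with both asymptotes inside the
  tested range, at full (>= ``eff_high``) or partial efficacy;
* ``2.1`` / ``2.2`` — sigmoid lacking one asymptote, full or partial
  efficacy;
* ``3``   — activity at the extreme concentration only, with no acceptable
  curve fit;
* ``4``   — inactive.

High-quality hits are the non-cytotoxic complete/partial curves; partial
curves additionally need decent efficacy and support from a structural
series (several similar compounds active) to rank as high quality.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from .hill import HillFit, f_test_vs_flat, hill_response
from .screen_model import TitrationSeries

__all__ = [
    "CurveClass",
    "Direction",
    "Quality",
    "ClassThresholds",
    "CurveClassResult",
    "ScreenSummary",
    "efficacy",
    "assign_curve_class",
    "flag_cytotoxicity",
    "triage_quality",
    "summarize_screen",
]


class CurveClass(str, Enum):
    CC1_1 = "1.1"
    CC1_2 = "1.2"
    CC2_1 = "2.1"
    CC2_2 = "2.2"
    CC3 = "3"
    CC4 = "4"


class Direction(str, Enum):
    INHIBITOR = "inhibitor"
    ACTIVATOR = "activator"
    INACTIVE = "inactive"


class Quality(str, Enum):
    HIGH = "high"
    LOW = "low"
    NONE = "none"


@dataclass(frozen=True)
class ClassThresholds:
    """Numeric cutoffs for classification and triage.

    These are declared defaults of this pipeline (the qHTS scheme defines
    the taxonomy, not the numbers) and are echoed into every report header.

    r2_min : minimum r^2 for an accepted curve fit.
    eff_high / eff_low : percent efficacy separating full / partial /
        inactive responses.
    plateau_tol : maximum percent gap between the fitted curve at a range
        end and the corresponding asymptote for that asymptote to count as
        reached.
    hq_partial_eff : efficacy a partial curve needs (besides structural
        series support) to be triaged high quality.
    tox_cutoff : percent cell-signal change below which a well counts as
        cytotoxic.
    min_point_activity : percent response above which a concentration
        counts as responding; a compound responding at fewer than two
        concentrations cannot be classed as concentration-dependent.
    """

    r2_min: float = 0.9
    eff_high: float = 80.0
    eff_low: float = 30.0
    plateau_tol: float = 10.0
    hq_partial_eff: float = 50.0
    tox_cutoff: float = -50.0
    p_flat_max: float = 0.05
    min_point_activity: float = 5.0

    def __post_init__(self):
        if not (0 < self.eff_low < self.hq_partial_eff <= self.eff_high):
            raise ValueError("require 0 < eff_low < hq_partial_eff <= eff_high")
        if not (0 < self.r2_min <= 1):
            raise ValueError("r2_min must lie in (0, 1]")


@dataclass
class CurveClassResult:
    compound_id: str
    curve_class: CurveClass
    direction: Direction
    efficacy: float  # percent span realized within the tested range
    quality: Quality = Quality.NONE
    cytotoxic: bool = False
    fit: HillFit | None = None
    p_flat: float = 1.0


def efficacy(fit: HillFit, series: TitrationSeries) -> float:
    """Percent response span the curve realizes inside the tested range.

    This is |fitted response at c_min - fitted response at c_max|, which is
    smaller than the asymptotic span whenever the midpoint sits near or
    beyond the range ends.
    """
    c, _ = series.unmasked()
    lo, hi = hill_response(np.array([c.min(), c.max()]), fit)
    return float(abs(hi - lo))


def assign_curve_class(
    fit: HillFit,
    series: TitrationSeries,
    thresholds: ClassThresholds = ClassThresholds(),
    p_flat: float | None = None,
) -> CurveClassResult:
    """Assign the qHTS curve class for one fitted titration.

    Decision order: an *accepted* fit (converged, r^2 and flat-test gates
    passed, and activity beyond ``plateau_tol`` at two or more
    concentrations) is classed 1.x when both asymptotes are reached within
    ``plateau_tol`` and 2.x otherwise, with the .1/.2 split at
    ``eff_high``; activity at the extreme concentration without an
    accepted fit is class 3; everything else is class 4 (inactive).

    The two-active-point requirement encodes the taxonomy's intent that a
    response seen at a single concentration carries no concentration
    dependence: a step at the top concentration is always representable by
    a steep 4PL, so fit statistics alone cannot demote it to class 3.
    """
    t = thresholds
    c, y = series.unmasked()
    if p_flat is None:
        p_flat = f_test_vs_flat(series, fit)
    resp = hill_response(c, fit)
    resp_lo, resp_hi = float(resp[np.argmin(c)]), float(resp[np.argmax(c)])
    eff = float(abs(resp_hi - resp_lo))
    n_active_points = int(np.sum(np.abs(y) >= t.min_point_activity))
    accepted = (
        fit.converged
        and fit.r2 >= t.r2_min
        and p_flat < t.p_flat_max
        and n_active_points >= 2
    )
    # an asymptote counts as reached only when >= 2 tested concentrations
    # sit on that fitted plateau: a noisy rising tail can always be bent
    # flat by a steeper fit, but it cannot fake two supporting points
    # (this refines, and implies, the |curve-end - asymptote| <= tol check)
    n_top = int(np.sum(np.abs(resp - fit.top) <= t.plateau_tol))
    n_bot = int(np.sum(np.abs(resp - fit.bottom) <= t.plateau_tol))
    both_asymptotes = n_top >= 2 and n_bot >= 2
    act_cmax = float(y[np.argmax(c)])

    if accepted and eff >= t.eff_low:
        if both_asymptotes:
            cls = CurveClass.CC1_1 if eff >= t.eff_high else CurveClass.CC1_2
        else:
            cls = CurveClass.CC2_1 if eff >= t.eff_high else CurveClass.CC2_2
        direction = Direction.INHIBITOR if resp_hi < resp_lo else Direction.ACTIVATOR
    elif not accepted and abs(act_cmax) >= t.eff_low:
        cls = CurveClass.CC3
        eff = abs(act_cmax)
        direction = Direction.INHIBITOR if act_cmax < 0 else Direction.ACTIVATOR
    else:
        cls = CurveClass.CC4
        direction = Direction.INACTIVE
        eff = min(eff, abs(act_cmax))

    return CurveClassResult(
        compound_id=series.compound_id,
        curve_class=cls,
        direction=direction,
        efficacy=eff,
        fit=fit,
        p_flat=float(p_flat),
    )


def flag_cytotoxicity(
    series: TitrationSeries,
    thresholds: ClassThresholds = ClassThresholds(),
    fit: HillFit | None = None,
) -> bool:
    """True when the cell signal collapses inside the compound's active window.

    The active window is every tested concentration up to 25x the fitted
    EC50 (the whole range when no converged fit is available): a cell-count
    drop below ``tox_cutoff`` there means the apparent LD phenotype may be
    secondary to cell loss.
    """
    window = np.ones(len(series.concentrations), dtype=bool)
    if fit is not None and fit.converged:
        window = series.concentrations <= 25.0 * fit.ec50
        if not window.any():
            window[:] = True
    return bool(np.any(series.cell_activity[window & ~series.mask] < thresholds.tox_cutoff))


def triage_quality(
    result: CurveClassResult,
    cytotoxic: bool,
    series_support: bool,
    thresholds: ClassThresholds = ClassThresholds(),
) -> CurveClassResult:
    """Attach the high/low/none quality tier to a classified compound.

    Full curves (1.1, 2.1) are high quality unless cytotoxic; partial
    curves (1.2, 2.2) additionally need efficacy >= ``hq_partial_eff`` and
    membership in a structural series with >= 2 members.  Class 3 actives
    are always low quality, class 4 has no tier.
    """
    t = thresholds
    cls = result.curve_class
    if cls is CurveClass.CC4:
        quality = Quality.NONE
    else:
        full = cls in (CurveClass.CC1_1, CurveClass.CC2_1)
        partial_hq = (
            cls in (CurveClass.CC1_2, CurveClass.CC2_2)
            and result.efficacy >= t.hq_partial_eff
            and series_support
        )
        quality = Quality.HIGH if (not cytotoxic and (full or partial_hq)) else Quality.LOW
    return replace(result, quality=quality, cytotoxic=cytotoxic)


@dataclass
class ScreenSummary:
    """Count tree over (curve class x quality x direction) plus the totals
    a screen report prints."""

    n_compounds: int
    counts: dict  # (CurveClass, Quality, Direction) -> int
    hq_inhibitors: int
    hq_activators: int
    lq_inhibitors: int
    lq_activators: int
    inactive: int

    def to_dict(self) -> dict:
        return {
            "n_compounds": self.n_compounds,
            "counts": {
                f"cc{cc.value}|{q.value}|{d.value}": n
                for (cc, q, d), n in sorted(
                    self.counts.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value, kv[0][2].value)
                )
            },
            "hq_inhibitors": self.hq_inhibitors,
            "hq_activators": self.hq_activators,
            "lq_inhibitors": self.lq_inhibitors,
            "lq_activators": self.lq_activators,
            "inactive": self.inactive,
        }


def summarize_screen(results) -> ScreenSummary:
    """Aggregate per-compound calls into the class/quality/direction count
    tree; totals are sums of their parts by construction."""
    seen = set()
    counts: Counter = Counter()
    for r in results:
        if r.compound_id in seen:
            raise ValueError(f"duplicate compound_id {r.compound_id!r}")
        seen.add(r.compound_id)
        counts[(r.curve_class, r.quality, r.direction)] += 1

    def total(quality, direction):
        return sum(
            n for (cc, q, d), n in counts.items() if q is quality and d is direction
        )

    return ScreenSummary(
        n_compounds=len(seen),
        counts=dict(counts),
        hq_inhibitors=total(Quality.HIGH, Direction.INHIBITOR),
        hq_activators=total(Quality.HIGH, Direction.ACTIVATOR),
        lq_inhibitors=total(Quality.LOW, Direction.INHIBITOR),
        lq_activators=total(Quality.LOW, Direction.ACTIVATOR),
        inactive=sum(n for (cc, q, d), n in counts.items() if d is Direction.INACTIVE),
    )
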