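"""Water-quality indices: weighted arithmetic WQI and CCME-style CWQI.

Two complementary single-number summaries of multi-parameter water
chemistry:

* The **weighted arithmetic WQI** (WAWQI) rates each parameter on a scale
  where the ideal value maps to 0 and the permissible limit to 100
  (``q_i = 100 (V_i - V_0) / (S_i - V_0)``) and averages the ratings with
  importance weights, ``WAWQI = sum(W_i q_i) / sum(W_i)``.  Higher means
  more polluted; scores above 100 mean at least one heavily weighted
  parameter is beyond its limit.  Classes: excellent (0-25], good
  (25-50], poor (50-75], very poor (75-100], unsuitable (>100); the
  scheme's printed class edges leave (25, 26) undefined, so contiguous
  half-open bins with upper-inclusive edges are used.

* The **CWQI** follows the Canadian Council of Ministers of the
  Environment (2001) formulation.  Over a pool of tests it combines
  scope ``F1`` (percent of parameters with any failed test), frequency
  ``F2`` (percent of failed tests) and amplitude ``F3`` (from the
  normalized sum of excursions, ``F3 = nse / (0.01 nse + 0.01)``) into
  ``CWQI = 100 - sqrt(F1^2 + F2^2 + F3^2) / 1.732``.  Higher means
  cleaner.  The literal divisor 1.732 (rather than sqrt(3)) makes the
  worst case marginally negative, so the score is clamped to [0, 100].
  Classes: excellent [95-100], good [80-95), fair [65-80), marginal
  [45-65), poor [0-45).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .core import ParameterDef, SampleRecord, StandardsRegistry

log = logging.getLogger(__name__)

WAWQI_CATEGORIES = ("excellent", "good", "poor", "very_poor", "unsuitable")
CWQI_CATEGORIES = ("excellent", "good", "fair", "marginal", "poor")

#: Divisor of the CWQI vector norm, kept literally as printed (not sqrt(3)).
CWQI_DIVISOR = 1.732


@dataclass
class QualityRating:
    """Quality rating q_i of one measurement against its standard.

    Dimensionless; 0 at the ideal value, exactly 100 at the standard
    limit, above 100 when worse than the limit.  Measurements on the
    safe side of the ideal clamp to 0 (``clamped`` records this).
    """

    parameter: str
    qi: float
    value_used: float
    clamped: bool = False


@dataclass
class WawqiResult:
    group_key: tuple
    score: float
    category: str
    ratings: list[QualityRating]
    weights_used: dict[str, float]


@dataclass
class CwqiFactors:
    """Scope/frequency/amplitude bookkeeping behind the CWQI."""

    F1: float
    F2: float
    F3: float
    nse: float
    n_parameters: int
    n_tests: int
    n_failed_parameters: int
    n_failed_tests: int
    excursions: list[tuple[str, int, float]] = field(default_factory=list)


@dataclass
class CwqiResult:
    group_key: tuple
    score: float
    category: str
    factors: CwqiFactors


def _rating_limit(pdef: ParameterDef, value: float) -> float:
    """Scalar standard limit used in the quality-rating denominator.

    For range objectives (pH) the bound on the side of the measurement
    relative to the ideal is used, so the rating is 100 at either bound.
    """
    if pdef.objective == "range":
        low, high = pdef.standard_limit  # type: ignore[misc]
        return high if value >= pdef.ideal else low
    return float(pdef.standard_limit)  # type: ignore[arg-type]


def quality_rating(value: float, pdef: ParameterDef) -> QualityRating:
    """Quality rating ``q_i = 100 (V_i - V_0) / (S_i - V_0)``.

    Works unchanged for floor objectives (dissolved oxygen): there the
    denominator is negative, which flips the sense so that values below
    the limit rate above 100.  Negative ratings (measurement on the safe
    side of the ideal) clamp to 0.
    """
    si = _rating_limit(pdef, value)
    if si == pdef.ideal:
        raise ValueError(f"parameter {pdef.name!r}: degenerate standard (Si == V0)")
    qi = 100.0 * (value - pdef.ideal) / (si - pdef.ideal)
    clamped = qi < 0.0
    return QualityRating(
        parameter=pdef.name, qi=max(qi, 0.0), value_used=value, clamped=clamped
    )


def wawqi_score(
    ratings: Sequence[QualityRating], weights: Mapping[str, float]
) -> float:
    """Weighted arithmetic index ``sum(W_i q_i) / sum(W_i)``."""
    if not ratings:
        raise ValueError("wawqi_score needs at least one quality rating")
    num = 0.0
    den = 0.0
    for r in ratings:
        try:
            w = weights[r.parameter]
        except KeyError:
            raise ValueError(f"no weight for parameter {r.parameter!r}") from None
        if not w > 0:
            raise ValueError(f"weight for {r.parameter!r} must be positive")
        num += w * r.qi
        den += w
    return num / den


def classify_wawqi(score: float) -> str:
    """Map a WAWQI score to its five-class category."""
    if score < 0:
        raise ValueError("WAWQI score cannot be negative")
    if score <= 25:
        return "excellent"
    if score <= 50:
        return "good"
    if score <= 75:
        return "poor"
    if score <= 100:
        return "very_poor"
    return "unsuitable"


def _excursion(pdef: ParameterDef, value: float, cap: float) -> float | None:
    """Excursion of a failed test; None when the test passes.

    ceiling: value/guideline - 1; floor: guideline/value - 1; range:
    nearest-bound analog.  A zero measurement under a floor objective has
    an undefined excursion and is capped at ``cap`` with a warning.
    """
    g = pdef.guideline
    if pdef.objective == "ceiling":
        gl = float(g)  # type: ignore[arg-type]
        if value <= gl:
            return None
        exc = value / gl - 1.0
    elif pdef.objective == "floor":
        gl = float(g)  # type: ignore[arg-type]
        if value >= gl:
            return None
        if value <= 0:
            log.warning(
                "WARN zero/negative %s under floor objective: excursion capped at %g",
                pdef.name,
                cap,
            )
            return cap
        exc = gl / value - 1.0
    else:  # range
        low, high = g  # type: ignore[misc]
        if low <= value <= high:
            return None
        if value > high:
            exc = value / high - 1.0
        elif value <= 0:
            log.warning(
                "WARN zero/negative %s below range guideline: excursion capped at %g",
                pdef.name,
                cap,
            )
            return cap
        else:
            exc = low / value - 1.0
    if exc > cap:
        log.warning("WARN excursion for %s capped at %g (was %g)", pdef.name, cap, exc)
        exc = cap
    return exc


def cwqi_factors(
    records: Iterable[SampleRecord],
    registry: StandardsRegistry,
    excursion_cap: float = 100.0,
) -> CwqiFactors:
    """Scope, frequency and amplitude factors over a pool of tests.

    Every record is one test of its parameter against the registry
    guideline.  F1 = 100 * failed parameters / parameters tested,
    F2 = 100 * failed tests / tests, nse = sum(excursions) / tests,
    F3 = nse / (0.01 nse + 0.01).
    """
    records = list(records)
    if not records:
        raise ValueError("cwqi_factors needs at least one record")
    params: set[str] = set()
    failed_params: set[str] = set()
    excursions: list[tuple[str, int, float]] = []
    n_tests = 0
    for i, rec in enumerate(records):
        pdef = registry[rec.parameter]
        params.add(rec.parameter)
        n_tests += 1
        exc = _excursion(pdef, rec.value, excursion_cap)
        if exc is not None:
            failed_params.add(rec.parameter)
            excursions.append((rec.parameter, i, exc))
    n_failed_tests = len(excursions)
    nse = sum(e for _, _, e in excursions) / n_tests
    f1 = 100.0 * len(failed_params) / len(params)
    f2 = 100.0 * n_failed_tests / n_tests
    f3 = nse / (0.01 * nse + 0.01)
    return CwqiFactors(
        F1=f1,
        F2=f2,
        F3=f3,
        nse=nse,
        n_parameters=len(params),
        n_tests=n_tests,
        n_failed_parameters=len(failed_params),
        n_failed_tests=n_failed_tests,
        excursions=excursions,
    )


def cwqi_score(factors: CwqiFactors, group_key: tuple = ()) -> CwqiResult:
    """``CWQI = 100 - sqrt(F1^2 + F2^2 + F3^2) / 1.732``, clamped to [0, 100]."""
    raw = 100.0 - math.sqrt(
        factors.F1**2 + factors.F2**2 + factors.F3**2
    ) / CWQI_DIVISOR
    score = min(max(raw, 0.0), 100.0)
    return CwqiResult(
        group_key=group_key,
        score=score,
        category=classify_cwqi(score),
        factors=factors,
    )


def classify_cwqi(score: float) -> str:
    """Map a CWQI score to its five-class CCME category."""
    if not 0.0 <= score <= 100.0:
        raise ValueError("CWQI score must lie in [0, 100]")
    if score >= 95:
        return "excellent"
    if score >= 80:
        return "good"
    if score >= 65:
        return "fair"
    if score >= 45:
        return "marginal"
    return "poor"


# ---------------------------------------------------------------------------
# Dataset-level driver


def compute_indices(
    dataset,
    registry: StandardsRegistry,
    pool_seasons: bool = False,
    include_nonstatutory: bool = False,
    excursion_cap: float = 100.0,
):
    """Both indices per group, as a pandas DataFrame.

    Groups are (site_id, sector, season) by default, or (site_id,
    sector) with seasons pooled (multi-visit CCME usage).  The WAWQI
    rates the mean value of each parameter within the group; the CWQI
    treats every record in the group as one test.  By default only
    parameters with a statutory limit enter the indices.
    """
    import pandas as pd

    allowed = {
        p.name for p in registry if (p.statutory or include_nonstatutory)
    }
    weights = {name: registry[name].weight for name in allowed}
    by_group: dict[tuple, list[SampleRecord]] = {}
    for rec in dataset.records:
        if rec.parameter not in allowed:
            continue
        key = (
            (rec.site_id, rec.sector)
            if pool_seasons
            else (rec.site_id, rec.sector, rec.season)
        )
        by_group.setdefault(key, []).append(rec)

    rows = []
    for key in sorted(by_group):
        recs = by_group[key]
        means: dict[str, float] = {}
        counts: dict[str, int] = {}
        for r in recs:
            means[r.parameter] = means.get(r.parameter, 0.0) + r.value
            counts[r.parameter] = counts.get(r.parameter, 0) + 1
        ratings = [
            quality_rating(means[p] / counts[p], registry[p]) for p in sorted(means)
        ]
        wscore = wawqi_score(ratings, weights)
        factors = cwqi_factors(recs, registry, excursion_cap=excursion_cap)
        cres = cwqi_score(factors, group_key=key)
        row = {
            "site_id": key[0],
            "sector": key[1],
            "season": "pooled" if pool_seasons else key[2],
            "wawqi": wscore,
            "wawqi_category": classify_wawqi(wscore),
            "cwqi": cres.score,
            "cwqi_category": cres.category,
            "F1": factors.F1,
            "F2": factors.F2,
            "F3": factors.F3,
            "n_parameters": factors.n_parameters,
            "n_tests": factors.n_tests,
        }
        for r in ratings:
            row[f"qi_{r.parameter}"] = r.qi
        rows.append(row)
    return pd.DataFrame(rows)
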