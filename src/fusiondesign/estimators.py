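"""Diverter-effectiveness estimators: BA, BACI and the two fusion models.

All four estimators express diverter effectiveness as a collision-reduction
percentage ``100 * (1 - exp(beta))`` where ``beta`` is the relevant
log-scale coefficient:

* **BA** — before/after contrast of carcass counts at the marked (impact)
  line only; ``beta`` is the period coefficient. Confounded by any change
  in flight intensity between the periods.
* **BACI** — carcass counts at both sites, ``period + site + period:site``;
  ``beta`` is the interaction. Unbiased only under the synchronicity
  assumption (equal relative flight-intensity change at both sites).
* **NB fusion** — carcass counts at the marked line with the observed
  flight exposure ``A = days * individuals / hours`` entering as an offset
  ``log(1 + A)``; ``beta`` is the period coefficient of a collision *rate*
  per observed crossing, immune to flight-intensity fluctuations.
* **B fusion** — the same contrast as a binomial model of carcasses-per-day
  events against observed-crossings-per-hour non-events.

`SynchronicityModel` quantifies how strongly a BACI estimate would be
biased, from flight counts alone: the period:site interaction of an
exposure-offset NB model of bird numbers gives the expected multiplicative
bias ``100 * (exp(beta_int) - 1)`` percent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .glm_core import (
    BinomialModel,
    GLMResults,
    NegativeBinomialModel,
    cyclic_spline_basis,
    wald_inference,
)
from .survey_data import (
    ValidationError,
    flights_to_frame,
    observations_to_frame,
    searches_to_frame,
)

__all__ = [
    "ReductionEstimate",
    "SynchronicityResult",
    "BAModel",
    "BACIModel",
    "NBFusionModel",
    "BFusionModel",
    "SynchronicityModel",
    "fit_ba",
    "fit_baci",
    "fit_nb_fusion",
    "fit_b_fusion",
    "test_synchronicity",
    "reduction_from_coefficient",
]


def reduction_from_coefficient(beta: float) -> float:
    """Collision-reduction percentage implied by a log-scale coefficient."""
    return 100.0 * (1.0 - math.exp(beta))


@dataclass
class ReductionEstimate:
    """A method's diverter-effectiveness estimate with CI and p-value.

    ``reduction_pct`` is positive when the diverter reduces collisions; the
    CI is obtained by transforming the link-scale Wald interval through the
    monotone map ``beta -> 100 * (1 - exp(beta))``.
    """

    method: str
    coefficient: float
    reduction_pct: float
    ci_low_pct: float
    ci_high_pct: float
    p_value: float
    level: float
    fit: GLMResults = field(repr=False)

    def summary(self) -> str:
        pct = f"{100 * self.level:.0f}%"
        return (
            f"{self.method}: estimated collision reduction "
            f"{self.reduction_pct:.1f}% ({pct} CI [{self.ci_low_pct:.1f}%, "
            f"{self.ci_high_pct:.1f}%], p = {self.p_value:.3g})\n"
            + self.fit.summary()
        )

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "coefficient": float(self.coefficient),
            "reduction_pct": float(self.reduction_pct),
            "ci_low_pct": float(self.ci_low_pct),
            "ci_high_pct": float(self.ci_high_pct),
            "p_value": float(self.p_value),
            "level": float(self.level),
            "fit": self.fit.to_dict(),
        }


@dataclass
class SynchronicityResult:
    """Estimated violation of the BACI synchronicity assumption."""

    interaction_coefficient: float
    expected_baci_bias_pct: float
    p_value: float
    fit: GLMResults = field(repr=False)

    def summary(self) -> str:
        return (
            f"synchronicity test: expected BACI bias "
            f"{self.expected_baci_bias_pct:+.1f}% (interaction = "
            f"{self.interaction_coefficient:.4f}, p = {self.p_value:.3g})\n"
            + self.fit.summary()
        )


# ---------------------------------------------------------------------------
# frame coercion and design building
# ---------------------------------------------------------------------------

def _coerce(data, to_frame, required: Sequence[str]) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        frame = data.copy()
    else:
        frame = to_frame(data)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(f"missing column(s) {missing}")
    return frame.reset_index(drop=True)


def _jday(frame: pd.DataFrame) -> np.ndarray:
    if "jday" in frame.columns:
        return np.asarray(frame["jday"], dtype=float)
    return pd.to_datetime(frame["date"]).dt.dayofyear.to_numpy(dtype=float)


def _with_spline(X: pd.DataFrame, frame: pd.DataFrame, seasonal: bool,
                 n_basis: int = 8) -> pd.DataFrame:
    if not seasonal:
        return X
    basis = cyclic_spline_basis(_jday(frame), n_basis=n_basis)
    for j in range(basis.shape[1]):
        X[f"s(jday).{j + 1}"] = basis[:, j]
    return X


def _check_cells(frame: pd.DataFrame, need_site: bool) -> None:
    periods = ("before", "after")
    sites = ("impact", "control") if need_site else (None,)
    for period in periods:
        for site in sites:
            mask = frame["period"] == period
            label = f"period={period}"
            if site is not None:
                mask &= frame["site"] == site
                label += f", site={site}"
            if not mask.any():
                raise ValidationError(f"no observations in cell ({label})")


def _estimate(fit: GLMResults, name: str, method: str, level: float) -> ReductionEstimate:
    w = wald_inference(fit, name, level)
    return ReductionEstimate(
        method=method,
        coefficient=w.estimate,
        reduction_pct=reduction_from_coefficient(w.estimate),
        ci_low_pct=reduction_from_coefficient(w.ci_high),
        ci_high_pct=reduction_from_coefficient(w.ci_low),
        p_value=w.p_value,
        level=level,
        fit=fit,
    )


# ---------------------------------------------------------------------------
# model classes
# ---------------------------------------------------------------------------

class BACIModel:
    """Before-after control-impact NB model of carcass counts."""

    method = "BACI"

    def __init__(self, searches, seasonal: bool = False, n_basis: int = 8):
        frame = _coerce(searches, searches_to_frame,
                        ["site", "period", "n_carcass"])
        _check_cells(frame, need_site=True)
        self.frame = frame
        after = (frame["period"] == "after").astype(float)
        impact = (frame["site"] == "impact").astype(float)
        X = pd.DataFrame({
            "intercept": 1.0,
            "period[after]": after,
            "site[impact]": impact,
            "period[after]:site[impact]": after * impact,
        })
        self.exog = _with_spline(X, frame, seasonal, n_basis)
        self._glm = NegativeBinomialModel(frame["n_carcass"], self.exog)

    def fit(self, level: float = 0.95) -> ReductionEstimate:
        return _estimate(self._glm.fit(), "period[after]:site[impact]",
                         self.method, level)


class BAModel:
    """Before-after NB model of carcass counts at the marked line only."""

    method = "BA"

    def __init__(self, searches, seasonal: bool = False, n_basis: int = 8,
                 site: str = "impact"):
        frame = _coerce(searches, searches_to_frame, ["period", "n_carcass"])
        if "site" in frame.columns:
            frame = frame[frame["site"] == site].reset_index(drop=True)
        if frame.empty or set(frame["period"]) != {"before", "after"}:
            raise ValidationError(
                f"BA needs searches at site {site!r} in both periods")
        self.frame = frame
        X = pd.DataFrame({
            "intercept": 1.0,
            "period[after]": (frame["period"] == "after").astype(float),
        })
        self.exog = _with_spline(X, frame, seasonal, n_basis)
        self._glm = NegativeBinomialModel(frame["n_carcass"], self.exog)

    def fit(self, level: float = 0.95) -> ReductionEstimate:
        return _estimate(self._glm.fit(), "period[after]", self.method, level)


class NBFusionModel:
    """NB model of carcass counts with flight exposure offset log(1 + A)."""

    method = "NB_fusion"

    def __init__(self, observations, seasonal: bool = False, n_basis: int = 8):
        frame = _coerce(observations, observations_to_frame,
                        ["period", "n_carcass", "exposure_A"])
        if set(frame["period"]) != {"before", "after"}:
            raise ValidationError("fusion model needs observations in both periods")
        A = np.asarray(frame["exposure_A"], dtype=float)
        if not np.all(np.isfinite(A)) or np.any(A < 0):
            raise ValidationError("exposure_A must be finite and non-negative")
        if np.all(A == 0):
            raise ValidationError("all exposures are zero: no flight information")
        self.frame = frame
        X = pd.DataFrame({
            "intercept": 1.0,
            "period[after]": (frame["period"] == "after").astype(float),
        })
        self.exog = _with_spline(X, frame, seasonal, n_basis)
        self._glm = NegativeBinomialModel(frame["n_carcass"], self.exog,
                                          offset=np.log1p(A))

    def fit(self, level: float = 0.95) -> ReductionEstimate:
        return _estimate(self._glm.fit(), "period[after]", self.method, level)


class BFusionModel:
    """Binomial model of carcasses/day events vs crossings/hour non-events.

    Rates are multiplied by ``c`` before rounding so that non-integer
    corrected counts lose little information to rounding. Note that ``c``
    also scales the nominal binomial sample size: choose the smallest ``c``
    that makes the rates near-integer (``c=1`` when counts are integers and
    intervals are single days), since inflating already-integer counts
    overstates the information in the data.
    """

    method = "B_fusion"

    def __init__(self, observations, c: int = 10_000, seasonal: bool = False,
                 n_basis: int = 8):
        if c < 1:
            raise ValidationError("c must be a positive integer")
        frame = _coerce(observations, observations_to_frame,
                        ["period", "n_carcass", "interval_days",
                         "pooled_individuals", "pooled_hours"])
        events = np.rint(c * frame["n_carcass"] / frame["interval_days"]).astype(int)
        hours = np.asarray(frame["pooled_hours"], dtype=float)
        rate = np.divide(frame["pooled_individuals"], hours,
                         out=np.zeros(len(frame)), where=hours > 0)
        nonevents = np.rint(c * rate).astype(int)
        keep = (events + nonevents) > 0
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} observation(s) whose rounded "
                f"event/non-event pair is (0, 0); consider a larger c",
                stacklevel=2)
        frame = frame[keep].reset_index(drop=True)
        if frame.empty or set(frame["period"]) != {"before", "after"}:
            raise ValidationError("fusion model needs observations in both periods")
        self.frame = frame
        X = pd.DataFrame({
            "intercept": 1.0,
            "period[after]": (frame["period"] == "after").astype(float),
        })
        self.exog = _with_spline(X, frame, seasonal, n_basis)
        self._glm = BinomialModel(events[keep.values if hasattr(keep, "values") else keep],
                                  nonevents[keep.values if hasattr(keep, "values") else keep],
                                  self.exog)

    def fit(self, level: float = 0.95) -> ReductionEstimate:
        return _estimate(self._glm.fit(), "period[after]", self.method, level)


class SynchronicityModel:
    """NB model of flight counts testing the BACI synchronicity assumption."""

    def __init__(self, flights):
        frame = _coerce(flights, flights_to_frame,
                        ["site", "period", "individuals", "hours"])
        _check_cells(frame, need_site=True)
        self.frame = frame
        after = (frame["period"] == "after").astype(float)
        impact = (frame["site"] == "impact").astype(float)
        self.exog = pd.DataFrame({
            "intercept": 1.0,
            "period[after]": after,
            "site[impact]": impact,
            "period[after]:site[impact]": after * impact,
        })
        self._glm = NegativeBinomialModel(
            frame["individuals"], self.exog,
            offset=np.log(np.asarray(frame["hours"], dtype=float)))

    def fit(self, level: float = 0.95) -> SynchronicityResult:
        res = self._glm.fit()
        w = wald_inference(res, "period[after]:site[impact]", level)
        return SynchronicityResult(
            interaction_coefficient=w.estimate,
            expected_baci_bias_pct=100.0 * (math.exp(w.estimate) - 1.0),
            p_value=w.p_value,
            fit=res,
        )


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def fit_baci(searches, seasonal: bool = False, level: float = 0.95) -> ReductionEstimate:
    return BACIModel(searches, seasonal=seasonal).fit(level=level)


def fit_ba(searches, seasonal: bool = False, level: float = 0.95) -> ReductionEstimate:
    return BAModel(searches, seasonal=seasonal).fit(level=level)


def fit_nb_fusion(observations, seasonal: bool = False, level: float = 0.95) -> ReductionEstimate:
    return NBFusionModel(observations, seasonal=seasonal).fit(level=level)


def fit_b_fusion(observations, c: int = 10_000, seasonal: bool = False,
                 level: float = 0.95) -> ReductionEstimate:
    return BFusionModel(observations, c=c, seasonal=seasonal).fit(level=level)


def test_synchronicity(flights, level: float = 0.95) -> SynchronicityResult:
    return SynchronicityModel(flights).fit(level=level)
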