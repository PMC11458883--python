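"""Parametric survival curves: evaluation, hazard-ratio adjustment, and fitting.

Five parametric families are supported, in the parameterizations below
(time in years throughout):

=============  ==================  ==========================================
family         params (ordered)    survival function S(t)
=============  ==================  ==========================================
exponential    rate                exp(-rate * t)
weibull        shape, scale        exp(-(t / scale) ** shape)
lognormal      meanlog, sdlog      1 - Phi((log t - meanlog) / sdlog)
loglogistic    shape, scale        1 / (1 + (t / scale) ** shape)
gompertz       shape, rate         exp(-(rate / shape) * (exp(shape * t) - 1))
=============  ==================  ==========================================

Curves are fitted to Kaplan-Meier summary points by weighted least squares
on the complementary log-log scale, log(-log S); the weights are the
numbers at risk when available.  This works directly on published summary
data without reconstructing pseudo individual-patient data.  Generalized
gamma is deliberately not offered: with summary points only, its three
parameters are too weakly identified to fit stably.

Hazard-ratio adjustment follows proportional hazards, S_target = S_ref**hr.
The exponential, Weibull and Gompertz families are closed under this
operation and return an exact family member; log-normal and log-logistic
are not, and return a :class:`PowerSurvival` wrapper instead.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

#: survival probabilities below this are treated as zero in ratios, to
#: avoid division blow-up deep in the extrapolated tail
SURVIVAL_FLOOR = 1e-12


class Family(str, enum.Enum):
    """Parametric survival families, in tie-break precedence order."""

    EXPONENTIAL = "exponential"
    WEIBULL = "weibull"
    LOGNORMAL = "lognormal"
    LOGLOGISTIC = "loglogistic"
    GOMPERTZ = "gompertz"


class LineSetting(str, enum.Enum):
    """Licensing setting a regimen's evidence applies to."""

    FIRST = "first"
    RELAPSED_REFRACTORY = "relapsed_refractory"
    DOUBLE_REFRACTORY = "double_refractory"


_PARAM_NAMES: dict[Family, tuple[str, ...]] = {
    Family.EXPONENTIAL: ("rate",),
    Family.WEIBULL: ("shape", "scale"),
    Family.LOGNORMAL: ("meanlog", "sdlog"),
    Family.LOGLOGISTIC: ("shape", "scale"),
    Family.GOMPERTZ: ("shape", "rate"),
}


@dataclass(frozen=True)
class SurvivalCurve:
    """A parametric survival function S(t), t in years.

    Parameters are validated at construction: every parameter must be
    strictly positive and finite, except the log-normal ``meanlog`` which
    may be any finite real.
    """

    family: Family
    params: tuple[float, ...]

    def __init__(self, family: Family | str, params: Sequence[float]):
        family = Family(family)
        params = tuple(float(p) for p in params)
        names = _PARAM_NAMES[family]
        if len(params) != len(names):
            raise ValueError(
                f"{family.value} takes {len(names)} parameters "
                f"{names}, got {len(params)}"
            )
        for name, value in zip(names, params):
            if not math.isfinite(value):
                raise ValueError(f"{family.value} {name} must be finite, got {value}")
            positive_required = not (family is Family.LOGNORMAL and name == "meanlog")
            if positive_required and value <= 0:
                raise ValueError(f"{family.value} {name} must be > 0, got {value}")
        object.__setattr__(self, "family", family)
        object.__setattr__(self, "params", params)

    @property
    def param_names(self) -> tuple[str, ...]:
        return _PARAM_NAMES[self.family]

    def survival(self, t):
        """S(t); vectorized over ``t``. Negative times raise."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("survival is only defined for t >= 0")
        fam, p = self.family, self.params
        with np.errstate(over="ignore", divide="ignore"):
            if fam is Family.EXPONENTIAL:
                out = np.exp(-p[0] * t)
            elif fam is Family.WEIBULL:
                out = np.exp(-((t / p[1]) ** p[0]))
            elif fam is Family.LOGNORMAL:
                out = np.where(
                    t > 0,
                    stats.norm.sf((np.log(np.where(t > 0, t, 1.0)) - p[0]) / p[1]),
                    1.0,
                )
            elif fam is Family.LOGLOGISTIC:
                out = 1.0 / (1.0 + (t / p[1]) ** p[0])
            else:  # gompertz
                out = np.exp(-(p[1] / p[0]) * np.expm1(p[0] * t))
        out = np.clip(out, 0.0, 1.0)
        return float(out) if out.ndim == 0 else out

    def quantile(self, s):
        """Inverse survival: the time t with S(t) = s, for s in (0, 1]."""
        s = np.asarray(s, dtype=float)
        if np.any((s <= 0) | (s > 1)):
            raise ValueError("quantile requires survival probabilities in (0, 1]")
        fam, p = self.family, self.params
        neg_log_s = -np.log(s)
        if fam is Family.EXPONENTIAL:
            out = neg_log_s / p[0]
        elif fam is Family.WEIBULL:
            out = p[1] * neg_log_s ** (1.0 / p[0])
        elif fam is Family.LOGNORMAL:
            out = np.exp(p[0] + p[1] * stats.norm.isf(s))
        elif fam is Family.LOGLOGISTIC:
            out = p[1] * ((1.0 - s) / s) ** (1.0 / p[0])
        else:  # gompertz
            out = np.log1p(p[0] * neg_log_s / p[1]) / p[0]
        return float(out) if out.ndim == 0 else out

    def sample_times(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` event times by inverse-transform sampling."""
        return self.quantile(rng.uniform(size=n))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        args = ", ".join(
            f"{k}={v:g}" for k, v in zip(self.param_names, self.params)
        )
        return f"SurvivalCurve({self.family.value}, {args})"


@dataclass(frozen=True)
class PowerSurvival:
    """Survival function S_base(t)**power (proportional-hazards adjustment).

    Used when the base family is not closed under powering (log-normal,
    log-logistic); behaves like a curve for evaluation purposes.
    """

    base: "SurvivalCurve | PowerSurvival"
    power: float

    def __post_init__(self):
        if not (math.isfinite(self.power) and self.power > 0):
            raise ValueError(f"power must be a positive real, got {self.power}")

    def survival(self, t):
        return self.base.survival(t) ** self.power

    def quantile(self, s):
        s = np.asarray(s, dtype=float)
        return self.base.quantile(s ** (1.0 / self.power))

    def sample_times(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.quantile(rng.uniform(size=n))


@dataclass(frozen=True)
class KMPoints:
    """Kaplan-Meier summary points: (time, survival[, n at risk]) triples."""

    times: np.ndarray
    surv: np.ndarray
    n_at_risk: np.ndarray | None = None

    def __init__(self, times, surv, n_at_risk=None):
        times = np.asarray(times, dtype=float)
        surv = np.asarray(surv, dtype=float)
        if times.ndim != 1 or surv.shape != times.shape:
            raise ValueError("times and surv must be equal-length 1-D arrays")
        if times.size == 0:
            raise ValueError("KMPoints requires at least one point")
        if np.any(times < 0):
            raise ValueError("times must be non-negative")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly ascending")
        if np.any((surv < 0) | (surv > 1)):
            raise ValueError("survival probabilities must lie in [0, 1]")
        if np.any(np.diff(surv) > 1e-12):
            raise ValueError("survival probabilities must be non-increasing")
        if n_at_risk is not None:
            n_at_risk = np.asarray(n_at_risk)
            if n_at_risk.shape != times.shape:
                raise ValueError("n_at_risk must match times in length")
            if np.any(n_at_risk <= 0):
                raise ValueError("n_at_risk entries must be positive")
            n_at_risk = n_at_risk.astype(float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "surv", surv)
        object.__setattr__(self, "n_at_risk", n_at_risk)

    def __len__(self) -> int:
        return self.times.size

    @classmethod
    def from_csv(cls, path) -> "KMPoints":
        """Read a ``time_years,survival[,n_at_risk]`` CSV (header required)."""
        df = pd.read_csv(path)
        required = {"time_years", "survival"}
        if not required.issubset(df.columns):
            raise ValueError(
                f"KM CSV must have columns {sorted(required)}; got {list(df.columns)}"
            )
        nar = df["n_at_risk"].to_numpy() if "n_at_risk" in df.columns else None
        return cls(df["time_years"].to_numpy(), df["survival"].to_numpy(), nar)

    def to_csv(self, path) -> None:
        data = {"time_years": self.times, "survival": self.surv}
        if self.n_at_risk is not None:
            data["n_at_risk"] = self.n_at_risk.astype(int)
        pd.DataFrame(data).to_csv(path, index=False)


@dataclass(frozen=True)
class HazardRatioEntry:
    """A proportional-hazards link from a reference regimen's curve."""

    reference_regimen: str
    target_regimen: str
    line_setting: LineSetting
    hr: float

    def __post_init__(self):
        object.__setattr__(self, "line_setting", LineSetting(self.line_setting))
        if not (math.isfinite(self.hr) and self.hr > 0):
            raise ValueError(f"hazard ratio must be > 0, got {self.hr}")


@dataclass(frozen=True)
class FitResult:
    """A fitted curve plus its weighted least-squares fit statistics.

    ``criterion`` is the sample-size-penalized score
    ``n * log(RSS / n) + 2k`` (k = number of family parameters) used to
    rank families; smaller is better.
    """

    curve: SurvivalCurve
    rss: float
    n_points: int
    criterion: float = field(init=False)

    def __post_init__(self):
        k = len(self.curve.params)
        rss = max(self.rss, 1e-300)
        object.__setattr__(
            self, "criterion", self.n_points * math.log(rss / self.n_points) + 2 * k
        )


def survival_at(curve, t) -> float:
    """Evaluate S(t) for a curve or any object exposing ``survival``."""
    return curve.survival(t)


def apply_hazard_ratio(curve, hr: float):
    """Proportional-hazards adjustment: returns a function with S**hr.

    Families closed under powering (exponential, Weibull, Gompertz) return
    an exact :class:`SurvivalCurve`; otherwise a :class:`PowerSurvival`.
    """
    if not (math.isfinite(hr) and hr > 0):
        raise ValueError(f"hazard ratio must be > 0, got {hr}")
    if hr == 1.0:
        return curve
    if isinstance(curve, SurvivalCurve):
        p = curve.params
        if curve.family is Family.EXPONENTIAL:
            return SurvivalCurve(Family.EXPONENTIAL, (hr * p[0],))
        if curve.family is Family.WEIBULL:
            # exp(-hr (t/scale)^shape) = exp(-(t/scale')^shape)
            return SurvivalCurve(
                Family.WEIBULL, (p[0], p[1] * hr ** (-1.0 / p[0]))
            )
        if curve.family is Family.GOMPERTZ:
            return SurvivalCurve(Family.GOMPERTZ, (p[0], hr * p[1]))
    return PowerSurvival(curve, hr)


def cycle_event_prob(curve, u: int, cycle_len: float) -> float:
    """Conditional event probability in cycle ``u`` of time-in-state.

    q(u) = 1 - S((u+1)*cycle_len) / S(u*cycle_len).  When the cohort is
    already (numerically) extinct, S(u*cycle_len) <= floor, the event
    probability is 1 by convention.
    """
    if u < 0:
        raise ValueError("cycle index must be >= 0")
    if cycle_len <= 0:
        raise ValueError("cycle length must be > 0")
    s0 = curve.survival(u * cycle_len)
    if s0 <= SURVIVAL_FLOOR:
        return 1.0
    s1 = curve.survival((u + 1) * cycle_len)
    return float(np.clip(1.0 - s1 / s0, 0.0, 1.0))


def restricted_mean(curve, horizon: float, step: float = 1.0 / 365.25) -> float:
    """Area under S over [0, horizon], composite trapezoid at ``step``."""
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    if step <= 0:
        raise ValueError("step must be > 0")
    if horizon == 0:
        return 0.0
    n = max(1, math.ceil(horizon / step))
    ts = np.linspace(0.0, horizon, n + 1)
    return float(np.trapezoid(curve.survival(ts), ts))


def _cloglog_data(km: KMPoints) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Usable (t, log(-log S), weight) triples for fitting."""
    mask = (km.surv < 1.0) & (km.surv > SURVIVAL_FLOOR) & (km.times > 0)
    t = km.times[mask]
    y = np.log(-np.log(km.surv[mask]))
    w = km.n_at_risk[mask] if km.n_at_risk is not None else np.ones_like(t)
    return t, y, w


def _initial_params(family: Family, t, y, w) -> np.ndarray:
    """Starting values from transform-scale linear regressions."""
    logt = np.log(t)
    sw = np.sqrt(w)
    if family is Family.EXPONENTIAL:
        rate = math.exp(float(np.average(y - logt, weights=w)))
        return np.array([rate])
    # weighted simple linear regression of y on log t
    X = np.column_stack([logt, np.ones_like(logt)])
    slope, intercept = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)[0]
    slope = max(slope, 1e-6)
    if family is Family.WEIBULL:
        return np.array([slope, math.exp(-intercept / slope)])
    if family is Family.LOGLOGISTIC:
        return np.array([slope, math.exp(-intercept / slope)])
    if family is Family.LOGNORMAL:
        # probit regression: Phi^-1(1 - S) = (log t - meanlog) / sdlog
        z = stats.norm.isf(np.exp(-np.exp(y)))  # isf(S)
        zX = np.column_stack([logt, np.ones_like(logt)])
        b, a = np.linalg.lstsq(zX * sw[:, None], z * sw, rcond=None)[0]
        b = max(b, 1e-6)
        return np.array([-a / b, 1.0 / b])
    # gompertz: start near the exponential fit with mild curvature
    rate = math.exp(float(np.average(y - logt, weights=w)))
    return np.array([0.1, rate])


def fit_parametric(km: KMPoints, family: Family | str) -> FitResult:
    """Fit one family to KM summary points.

    Weighted least squares on the complementary log-log scale,
    log(-log S); weights are ``n_at_risk`` when provided, else 1.
    Points with S = 1 (no events yet) or S at the numerical floor carry no
    cloglog information and are excluded.
    """
    family = Family(family)
    t, y, w = _cloglog_data(km)
    k = len(_PARAM_NAMES[family])
    if t.size < k + 1:
        raise ValueError(
            f"need at least {k + 1} usable points (0 < S < 1) to fit "
            f"{family.value}, have {t.size}"
        )
    x0 = _initial_params(family, t, y, w)
    sw = np.sqrt(w)
    lognormal = family is Family.LOGNORMAL

    def residuals(theta):
        # positive params optimized in log-space; lognormal meanlog raw
        if lognormal:
            params = (theta[0], math.exp(theta[1]))
        else:
            params = tuple(np.exp(theta))
        curve = SurvivalCurve(family, params)
        s = np.clip(curve.survival(t), SURVIVAL_FLOOR, 1.0 - 1e-15)
        return sw * (np.log(-np.log(s)) - y)

    if lognormal:
        theta0 = np.array([x0[0], math.log(x0[1])])
    else:
        theta0 = np.log(x0)
    sol = optimize.least_squares(residuals, theta0, method="lm", max_nfev=2000)
    if not sol.success and not np.all(np.isfinite(sol.x)):
        raise RuntimeError(f"{family.value} fit failed: {sol.message}")
    if lognormal:
        params = (sol.x[0], math.exp(sol.x[1]))
    else:
        params = tuple(np.exp(sol.x))
    curve = SurvivalCurve(family, params)
    rss = float(np.sum(sol.fun**2))
    return FitResult(curve=curve, rss=rss, n_points=int(t.size))


def select_family(
    km: KMPoints, families: Sequence[Family | str] | None = None
) -> list[FitResult]:
    """Fit each candidate family and rank by the penalized criterion.

    Families whose fit fails are skipped with a logged warning.  Ties are
    broken by the fixed precedence order of :class:`Family` (simpler
    families first).  The ranking is statistical only; callers retain a
    clinical-plausibility override by picking any entry of the list.
    """
    if families is None:
        families = list(Family)
    families = [Family(f) for f in families]
    if not families:
        raise ValueError("families must be non-empty")
    precedence = {fam: i for i, fam in enumerate(Family)}
    results: list[FitResult] = []
    for fam in families:
        try:
            results.append(fit_parametric(km, fam))
        except (ValueError, RuntimeError) as exc:
            logger.warning("skipping family %s: %s", fam.value, exc)
    if not results:
        raise RuntimeError("every candidate family failed to fit")
    results.sort(key=lambda r: (r.criterion, precedence[r.curve.family]))
    return results
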