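"""Fire return intervals from burn-date series.

A burn-date series for one location inside a fixed observation window yields
``k - 1`` complete inter-fire intervals plus two open-tailed durations (from
the window start to the first fire and from the last fire to the window
end).  The open tails are right-censored observations of the interval
distribution; a Weibull is fitted to the pooled per-species intervals by
maximizing the censored log-likelihood

    l(b, c) = sum_complete log f(t; b, c) + sum_censored log S(t; b, c)

with density f(t) = (c/b) (t/b)^(c-1) exp(-(t/b)^c) and survival
S(t) = exp(-(t/b)^c).  The median fire return interval follows as
FRI = b (ln 2)^(1/c).

Species are kept in frequency analyses only when fire is a recurrent part of
their environment: the proportion of a species' records falling in burnt
pixels must exceed a threshold estimated by break-point (two-segment)
regression on the species-count curve, and the fitted median FRI must lie
inside a plausibility band (1-100 yr by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special
from sklearn.base import BaseEstimator

__all__ = [
    "FireHistory",
    "IntervalSet",
    "extract_intervals",
    "pool_species_intervals",
    "CensoredWeibull",
    "fit_weibull_censored",
    "median_fri",
    "proportion_burned",
    "BreakpointRegression",
    "fit_breakpoint",
    "species_count_curve",
    "classify_fire_prone",
    "filter_fri_bounds",
    "date_to_year_fraction",
]

LN2 = float(np.log(2.0))


def date_to_year_fraction(dates) -> np.ndarray:
    """Convert datelike values to fractional years (day-of-year / 365.25)."""
    dt = pd.to_datetime(pd.Series(dates), format="mixed")
    return (dt.dt.year + (dt.dt.dayofyear - 1) / 365.25).to_numpy(float)


@dataclass
class FireHistory:
    """Burn dates (fractional years) for one location in an observation window."""

    location_id: str
    window_start: float
    window_end: float
    burn_dates: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        self.burn_dates = np.unique(np.asarray(self.burn_dates, dtype=float))
        if self.window_start >= self.window_end:
            raise ValueError("window_start must precede window_end")
        if self.burn_dates.size and (
            self.burn_dates[0] < self.window_start or self.burn_dates[-1] > self.window_end
        ):
            raise ValueError(
                f"burn dates outside window for location {self.location_id!r}"
            )

    @property
    def n_fires(self) -> int:
        return int(self.burn_dates.size)


@dataclass
class IntervalSet:
    """Complete and open-tailed (censored) inter-fire durations in years.

    Open tails are kept in two groups because they are statistically
    different objects: ``censored`` holds trailing tails (time from the last
    fire to the window end — an ordinary right-censored draw from the
    interval distribution) and ``recurrence`` holds leading tails (time from
    the window start to the first fire — a forward recurrence time of the
    stationary renewal process, whose density is S(t)/mu).  ``window_length``
    carries the observation-window length so the fit can condition on the
    pixel having burnt at least once.
    """

    complete: np.ndarray = field(default_factory=lambda: np.empty(0))
    censored: np.ndarray = field(default_factory=lambda: np.empty(0))
    recurrence: np.ndarray = field(default_factory=lambda: np.empty(0))
    window_length: float | None = None

    def __post_init__(self):
        self.complete = np.asarray(self.complete, dtype=float)
        self.censored = np.asarray(self.censored, dtype=float)
        self.recurrence = np.asarray(self.recurrence, dtype=float)

    @property
    def open_tailed(self) -> np.ndarray:
        return np.concatenate([self.recurrence, self.censored])

    @property
    def n_complete(self) -> int:
        return int(self.complete.size)

    @property
    def n_censored(self) -> int:
        return int(self.censored.size + self.recurrence.size)

    def merged_with(self, other: "IntervalSet") -> "IntervalSet":
        wl = self.window_length if self.window_length is not None else other.window_length
        return IntervalSet(
            np.concatenate([self.complete, other.complete]),
            np.concatenate([self.censored, other.censored]),
            np.concatenate([self.recurrence, other.recurrence]),
            window_length=wl,
        )


def extract_intervals(history: FireHistory) -> IntervalSet:
    """Split one fire history into complete and open-tailed durations.

    With zero fires the whole window is a single censored duration.  Total
    duration is conserved: complete + open-tailed durations sum to the
    window length.
    """
    dates = history.burn_dates
    length = history.window_end - history.window_start
    if dates.size == 0:
        return IntervalSet(censored=[length], window_length=length)
    return IntervalSet(
        complete=np.diff(dates),
        censored=[history.window_end - dates[-1]],
        recurrence=[dates[0] - history.window_start],
        window_length=length,
    )


def pool_species_intervals(
    histories: dict[str, FireHistory], locations: list[str]
) -> IntervalSet:
    """Pool intervals over a species' locations, skipping never-burnt locations.

    Only pixels that burnt at least once inside the window contribute; a
    species with no burnt locations yields an empty set (flagged by its
    zero counts).
    """
    pooled = IntervalSet()
    for loc in locations:
        hist = histories.get(loc)
        if hist is None or hist.n_fires == 0:
            continue
        pooled = pooled.merged_with(extract_intervals(hist))
    return pooled


def _log_burn_probability(log_b, log_c, window_length):
    """log P(at least one fire in a window of given length) for a stationary
    Weibull(b, c) renewal process: gammainc(1/c, (L/b)^c) regularized."""
    b, c = np.exp(log_b), np.exp(log_c)
    p = special.gammainc(1.0 / c, np.exp(np.clip(c * (np.log(window_length) - log_b), -745.0, 200.0)))
    return np.log(max(float(p), 1e-300))


def _censored_weibull_negloglik(theta, t_obs, t_cens, t_rec, window_length):
    """Negative log-likelihood and gradient in (log b, log c).

    Complete intervals contribute log f, trailing tails log S.  Leading
    tails (``t_rec``) are forward recurrence times with density S(t)/mu,
    mu = b Gamma(1 + 1/c); when ``window_length`` is given the likelihood
    further conditions on the pixel having burnt at least once inside the
    window.  With ``t_rec`` empty this is the ordinary right-censored
    Weibull log-likelihood.
    """
    log_b, log_c = theta
    c = np.exp(log_c)
    nll = 0.0
    g_logb = 0.0
    g_logc = 0.0
    if t_obs.size:
        lr = np.log(t_obs) - log_b  # log(t/b)
        z = np.exp(np.clip(c * lr, -745.0, 200.0))
        nll -= np.sum(log_c - c * log_b + (c - 1.0) * np.log(t_obs) - z)
        g_logb += t_obs.size * c - c * np.sum(z)
        g_logc += -t_obs.size - c * np.sum(lr) + c * np.sum(z * lr)
    for tails in (t_cens, t_rec):
        if tails.size:
            pos = tails[tails > 0]
            lr = np.log(pos) - log_b
            z = np.exp(np.clip(c * lr, -745.0, 200.0))
            nll += np.sum(z)
            g_logb += -c * np.sum(z)
            g_logc += c * np.sum(z * lr)
    n_rec = t_rec.size
    if n_rec:
        # -log mu per leading tail, mu = b * Gamma(1 + 1/c)
        nll += n_rec * (log_b + special.gammaln(1.0 + 1.0 / c))
        g_logb += n_rec
        g_logc += n_rec * (-special.digamma(1.0 + 1.0 / c) / c)
        if window_length is not None:
            # condition on >= 1 fire; gradient by central differences
            h = 1e-6
            lp = _log_burn_probability(log_b, log_c, window_length)
            nll += n_rec * lp
            g_logb += (
                n_rec
                * (
                    _log_burn_probability(log_b + h, log_c, window_length)
                    - _log_burn_probability(log_b - h, log_c, window_length)
                )
                / (2 * h)
            )
            g_logc += (
                n_rec
                * (
                    _log_burn_probability(log_b, log_c + h, window_length)
                    - _log_burn_probability(log_b, log_c - h, window_length)
                )
                / (2 * h)
            )
    if not np.isfinite(nll):
        return 1e300, np.array([0.0, 0.0])
    return nll, np.array([g_logb, g_logc])


class CensoredWeibull(BaseEstimator):
    """Maximum-likelihood Weibull fit to window-censored interval data.

    Parameters
    ----------
    n_starts : int
        Number of optimizer starts (moment-based start plus perturbations).
    tol : float
        Gradient-norm convergence tolerance.
    min_complete : int
        Minimum number of complete intervals required to attempt a fit; with
        fewer, the fit is flagged non-converged rather than extrapolated.
    stationary_tails : bool
        When True (default) leading open tails flagged in an
        :class:`IntervalSet` are treated as forward recurrence times of the
        stationary renewal process (density S(t)/mu) and, when the window
        length is known, the likelihood conditions on the pixel having burnt
        at least once.  When False every open tail is treated as an ordinary
        right-censored observation (the simpler survival-analysis treatment,
        which overestimates long fire return intervals under heavy window
        censoring).

    Attributes
    ----------
    scale_ : float
        Weibull scale ``b`` (years).
    shape_ : float
        Weibull shape ``c``.
    median_fri_ : float
        ``b * (ln 2)**(1/c)``; NaN when not converged.
    loglik_ : float
    n_complete_, n_censored_ : int
    converged_ : bool
    """

    _LOG_BOUNDS = ((np.log(1e-3), np.log(1e5)), (np.log(1e-2), np.log(1e3)))

    def __init__(
        self,
        n_starts: int = 3,
        tol: float = 1e-8,
        min_complete: int = 1,
        stationary_tails: bool = True,
    ):
        self.n_starts = n_starts
        self.tol = tol
        self.min_complete = min_complete
        self.stationary_tails = stationary_tails

    def fit(self, durations, event_observed=None):
        """Fit to durations; ``event_observed`` marks complete (non-censored) ones.

        ``durations`` may also be an :class:`IntervalSet`, in which case
        ``event_observed`` is ignored and leading/trailing open tails are
        distinguished.
        """
        window_length = None
        if isinstance(durations, IntervalSet):
            t_obs = durations.complete
            if self.stationary_tails:
                t_cens, t_rec = durations.censored, durations.recurrence
                window_length = durations.window_length
            else:
                t_cens, t_rec = durations.open_tailed, np.empty(0)
        else:
            t = np.asarray(durations, dtype=float)
            e = (
                np.ones(t.shape, dtype=bool)
                if event_observed is None
                else np.asarray(event_observed, dtype=bool)
            )
            t_obs, t_cens, t_rec = t[e], t[~e], np.empty(0)
        if np.any(t_obs <= 0) or np.any(t_cens < 0) or np.any(t_rec < 0):
            raise ValueError("durations must be positive")

        self.n_complete_ = int(t_obs.size)
        self.n_censored_ = int(t_cens.size + t_rec.size)
        self.converged_ = False
        self.scale_ = self.shape_ = self.median_fri_ = np.nan
        self.loglik_ = np.nan
        if self.n_complete_ < self.min_complete:
            return self

        # moment-based start: exponential scale guess, shape 1
        mean_t = float(np.mean(np.concatenate([t_obs, t_cens, t_rec])))
        starts = [(np.log(mean_t), 0.0)]
        rng = np.random.default_rng(0)
        for _ in range(self.n_starts - 1):
            starts.append(
                (np.log(mean_t) + rng.normal(0, 0.7), rng.normal(0, 0.5))
            )

        best = None
        for x0 in starts:
            res = optimize.minimize(
                _censored_weibull_negloglik,
                x0=np.asarray(x0),
                args=(t_obs, t_cens, t_rec, window_length),
                jac=True,
                method="L-BFGS-B",
                bounds=self._LOG_BOUNDS,
                options={"gtol": self.tol, "ftol": 1e-15, "maxiter": 500},
            )
            if best is None or res.fun < best.fun:
                best = res
        (b_lo, b_hi), (c_lo, c_hi) = self._LOG_BOUNDS
        at_bad_bound = (
            np.isclose(best.x[0], b_lo, atol=1e-6)
            or np.isclose(best.x[0], b_hi, atol=1e-6)
            or np.isclose(best.x[1], c_lo, atol=1e-6)
        )
        # shape at its *upper* bound means effectively regular fires
        # (zero-variance intervals, c -> inf); the bounded maximum is kept
        self.shape_at_bound_ = bool(np.isclose(best.x[1], c_hi, atol=1e-6))
        self.loglik_ = -float(best.fun)
        # judge convergence by the score at the solution, not the
        # optimizer's status word (its final line search may be abandoned
        # within rounding of the optimum)
        _, grad = _censored_weibull_negloglik(best.x, t_obs, t_cens, t_rec, window_length)
        stationary = bool(np.max(np.abs(grad)) < 1e-2) or self.shape_at_bound_
        if stationary and not at_bad_bound:
            self.scale_ = float(np.exp(best.x[0]))
            self.shape_ = float(np.exp(best.x[1]))
            self.median_fri_ = self.scale_ * LN2 ** (1.0 / self.shape_)
            self.converged_ = True
        return self

    def survival_function(self, t):
        t = np.asarray(t, dtype=float)
        return np.exp(-((t / self.scale_) ** self.shape_))


@dataclass
class WeibullFRIFit:
    """Plain-record view of a censored Weibull fit."""

    b: float
    c: float
    median_fri: float
    n_complete: int
    n_censored: int
    loglik: float
    converged: bool


def fit_weibull_censored(intervals: IntervalSet, **kwargs) -> WeibullFRIFit:
    """Functional wrapper around :class:`CensoredWeibull`."""
    est = CensoredWeibull(**kwargs).fit(intervals)
    return WeibullFRIFit(
        b=est.scale_,
        c=est.shape_,
        median_fri=est.median_fri_,
        n_complete=est.n_complete_,
        n_censored=est.n_censored_,
        loglik=est.loglik_,
        converged=est.converged_,
    )


def median_fri(fit) -> float:
    """Median fire return interval ``b * (ln 2)**(1/c)`` of a converged fit."""
    b, c, ok = (
        (fit.b, fit.c, fit.converged)
        if isinstance(fit, WeibullFRIFit)
        else (fit.scale_, fit.shape_, fit.converged_)
    )
    if not ok:
        warnings.warn("median_fri of a non-converged fit is undefined", stacklevel=2)
        return float("nan")
    return float(b * LN2 ** (1.0 / c))


def proportion_burned(species_records: pd.DataFrame, burn_lookup: dict) -> float:
    """Fraction of a species' records lying in pixels that burned at least once."""
    if len(species_records) == 0:
        raise ValueError("no records for species")
    locs = species_records["location_id"]
    missing = set(locs) - set(burn_lookup)
    if missing:
        raise KeyError(f"records at locations with no burn flag: {sorted(missing)[:5]}")
    burnt = locs.map(lambda k: bool(burn_lookup[k]))
    return float(burnt.mean())


class BreakpointRegression(BaseEstimator):
    """Continuous two-segment linear regression with an estimated hinge.

    The break point is found by an exhaustive search over interior x values
    followed by bounded local refinement of the residual sum of squares.

    Attributes
    ----------
    breakpoint_ : float
    left_slope_, right_slope_ : float
    intercept_ : float
        Intercept of the left segment.
    rss_ : float
    degenerate_ : bool
        True when the data are collinear and the hinge is not identified.
    """

    def __init__(self, n_grid: int = 200):
        self.n_grid = n_grid

    @staticmethod
    def _rss_at(psi, x, y):
        design = np.column_stack([np.ones_like(x), x, np.clip(x - psi, 0.0, None)])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        return float(resid @ resid), coef

    def fit(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size < 6:
            raise ValueError("need at least 6 points for a break-point fit")
        if np.any(np.diff(x) < 0):
            order = np.argsort(x)
            x, y = x[order], y[order]

        lo, hi = x[1], x[-2]
        # candidate hinges: interior data points plus a uniform grid
        cand = np.unique(
            np.concatenate([x[(x > lo) & (x < hi)], np.linspace(lo, hi, self.n_grid)])
        )
        cand = cand[(cand > x[0]) & (cand < x[-1])]
        rss = np.array([self._rss_at(p, x, y)[0] for p in cand])
        i = int(np.argmin(rss))
        span = max(hi - lo, 1e-12)
        left = cand[max(i - 1, 0)] if i > 0 else max(cand[i] - 0.02 * span, lo)
        right = cand[min(i + 1, len(cand) - 1)] if i < len(cand) - 1 else min(
            cand[i] + 0.02 * span, hi
        )
        res = optimize.minimize_scalar(
            lambda p: self._rss_at(p, x, y)[0],
            bounds=(left, right),
            method="bounded",
            options={"xatol": 1e-10},
        )
        psi = float(res.x) if res.fun <= rss[i] else float(cand[i])
        self.rss_, coef = self._rss_at(psi, x, y)
        self.breakpoint_ = psi
        self.intercept_ = float(coef[0])
        self.left_slope_ = float(coef[1])
        self.right_slope_ = float(coef[1] + coef[2])
        # collinear data: the hinge adds nothing over a single line
        line = np.column_stack([np.ones_like(x), x])
        line_coef, *_ = np.linalg.lstsq(line, y, rcond=None)
        line_rss = float(np.sum((y - line @ line_coef) ** 2))
        self.degenerate_ = line_rss - self.rss_ <= 1e-12 * max(line_rss, 1.0)
        return self

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        return (
            self.intercept_
            + self.left_slope_ * x
            + (self.right_slope_ - self.left_slope_) * np.clip(x - self.breakpoint_, 0.0, None)
        )


@dataclass
class BreakpointFit:
    breakpoint: float
    left_slope: float
    right_slope: float
    intercept: float
    rss: float
    degenerate: bool


def fit_breakpoint(x, y, **kwargs) -> BreakpointFit:
    """Functional wrapper around :class:`BreakpointRegression`."""
    est = BreakpointRegression(**kwargs).fit(x, y)
    return BreakpointFit(
        est.breakpoint_,
        est.left_slope_,
        est.right_slope_,
        est.intercept_,
        est.rss_,
        est.degenerate_,
    )


def species_count_curve(proportions, bin_width: float = 0.02):
    """Histogram species counts per proportion-burned bin (x = bin centers)."""
    props = np.asarray(proportions, dtype=float)
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    counts, _ = np.histogram(props, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts.astype(float)


def classify_fire_prone(profiles: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Flag species whose proportion burned reaches the break-point threshold."""
    if not 0 <= threshold < 1:
        raise ValueError("threshold must be in [0, 1)")
    out = profiles.copy()
    out["fire_prone"] = out["proportion_burned"] >= threshold
    return out


def filter_fri_bounds(profiles: pd.DataFrame, lo: float = 1.0, hi: float = 100.0) -> pd.DataFrame:
    """Blank out median FRI values outside [lo, hi]; such regimes are unresolved."""
    out = profiles.copy()
    bad = (out["median_fri"] < lo) | (out["median_fri"] > hi)
    out.loc[bad, "median_fri"] = np.nan
    return out
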