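"""Joint logistic dose-response ("supercurve") fitting for one RPPA slide.

All dilution series on a slide share one antibody and hence one response
curve.  The model for spot intensity is

    y_ij = alpha + beta / (1 + exp(-gamma * (x_i + d_j))) + noise,

where ``x_i`` is the relative log2 concentration of series i at its first
(undiluted) step and ``d_j = -(j-1) * log2(f)`` is the known log2 offset of
dilution step j at dilution factor f.  The curve's midpoint is pinned at
x = 0, which makes the per-series positions x_i identifiable: a common shift
of all x_i moves every spot along a fixed, non-translatable curve and
strictly increases the residual sum of squares.

Fitting alternates two low-dimensional sub-problems: nonlinear least squares
for (alpha, beta, gamma) with the x_i held fixed, then a bounded scalar
minimisation for each x_i with the curve held fixed, iterated until the RSS
stops decreasing.  Series excluded from the fit (user-specified outliers,
buffer/negative-control spots) are positioned afterwards against the frozen
curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .slide_io import SlideError

__all__ = [
    "DilutionSeries",
    "CurveFit",
    "ConcentrationEstimate",
    "FitOptions",
    "FitDiagnostics",
    "response",
    "fit_supercurve",
    "estimate_excluded",
    "fit_diagnostics",
    "series_from_slide",
]

#: Spot types whose series participate in curve fitting by default.  Technical
#: replicates are genuine dilution series of a common sample and inform the
#: curve; negative controls, buffer and blank spots carry no dose-response.
DEFAULT_FIT_SPOT_TYPES = frozenset({"Sample", "PosCtrl", "NoiseRep"})


@dataclass
class DilutionSeries:
    """One dilution series: known log2 offsets d_j and observed intensities."""

    series_id: str
    d: np.ndarray  #: per-step log2 offsets, d_1 = 0, strictly decreasing
    y: np.ndarray  #: per-step net intensities
    spot_type: str = "Sample"
    excluded_from_fit: bool = False

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.d.shape != self.y.shape:
            raise ValueError("d and y must have equal length")


@dataclass(frozen=True)
class CurveFit:
    """Fitted slide-level response curve and fit diagnostics."""

    alpha: float  #: lower asymptote (baseline intensity)
    beta: float  #: dynamic range, upper asymptote = alpha + beta
    gamma: float  #: slope per log2 concentration unit
    rss: float
    r2: float
    n_series_used: int
    n_spots_used: int
    converged: bool
    n_iterations: int


@dataclass
class ConcentrationEstimate:
    """Relative log2 concentration of one series at its undiluted step."""

    series_id: str
    x: float
    se_x: float
    in_fit: bool
    residuals: np.ndarray  #: per-step fitted minus observed intensity
    flags: set = field(default_factory=set)


@dataclass(frozen=True)
class FitOptions:
    """Tunable fitting parameters (all exposed through the run config)."""

    max_iterations: int = 100
    rss_tolerance: float = 1e-8
    x_bounds: tuple[float, float] = (-15.0, 15.0)
    clamp_low: float = 0.01  #: fraction of beta marking "below detection"
    clamp_high: float = 0.99  #: fraction of beta marking "saturated"
    min_series: int = 8
    min_intensity_range: float = 1e-6  #: absolute floor on the spot intensity range
    joint_refinement: bool = True  #: polish with one joint Gauss-Newton solve
    #: Upper bound on beta as a multiple of the robust intensity spread
    #: (95th - 5th percentile).  An upper asymptote far beyond the observed
    #: intensities is not identifiable, and leaving beta free lets a few
    #: strong outlier series stretch the curve until everything sits on its
    #: scale-free exponential bottom.  Set to 0 to disable.
    beta_max_factor: float = 4.0
    poor_fit_residual_frac: float = 0.5  #: |residual|/beta beyond which a series is PoorFit
    fit_spot_types: frozenset = DEFAULT_FIT_SPOT_TYPES


@dataclass
class FitDiagnostics:
    """Slide QC summary derived from a fit and its estimates."""

    r2: float
    max_residual_frac: dict  #: series_id -> max |residual| / beta
    ranked_series: list  #: series ids, largest residual first
    exclusion_candidates: list  #: ranked ids above the candidate threshold
    n_flagged: dict  #: flag name -> count


def response(x, fit) -> np.ndarray | float:
    """Predicted intensity at log2 concentration ``x`` under a fitted curve.

    Strictly increasing in x, bounded in (alpha, alpha + beta), with
    ``response(0) = alpha + beta/2`` (midpoint pinned at x = 0).
    """
    alpha, beta, gamma = fit.alpha, fit.beta, fit.gamma
    return alpha + beta / (1.0 + np.exp(-gamma * np.asarray(x, dtype=float)))


def _predict(alpha: float, beta: float, gamma: float, u: np.ndarray) -> np.ndarray:
    return alpha + beta / (1.0 + np.exp(-gamma * u))


def series_from_slide(slide, design, excluded_series=(), fit_spot_types=DEFAULT_FIT_SPOT_TYPES):
    """Build :class:`DilutionSeries` objects from a parsed slide.

    The per-step log2 offset is the log2 of the declared relative
    concentration (step 1 at concentration 1 has offset 0).  Steps with
    non-finite intensity are dropped with no effect on other steps.
    """
    excluded = set(excluded_series)
    by_series: dict[str, list] = {}
    order: list[str] = []
    for rec in slide.records:
        if rec.spot_type == "Blank":
            continue
        if rec.series_id not in by_series:
            by_series[rec.series_id] = []
            order.append(rec.series_id)
        by_series[rec.series_id].append(rec)

    out = []
    for sid in order:
        recs = sorted(by_series[sid], key=lambda r: r.dilution_step)
        d = np.array([math.log2(r.dilution) if r.dilution > 0 else np.nan for r in recs])
        y = np.array([r.net_intensity for r in recs])
        keep = np.isfinite(d) & np.isfinite(y)
        if keep.sum() == 0:
            continue
        spot_type = recs[0].spot_type
        out.append(
            DilutionSeries(
                series_id=sid,
                d=d[keep],
                y=y[keep],
                spot_type=spot_type,
                excluded_from_fit=(sid in excluded) or (spot_type not in fit_spot_types),
            )
        )
    return out


def _initial_values(fit_series, options):
    all_y = np.concatenate([s.y for s in fit_series])
    alpha0 = float(np.percentile(all_y, 5))
    top = float(np.percentile(all_y, 95))
    beta0 = max(top - alpha0, options.min_intensity_range)
    gamma0 = 1.0
    x0 = np.empty(len(fit_series))
    for i, s in enumerate(fit_series):
        p = (float(np.mean(s.y)) - alpha0) / beta0
        p = min(max(p, 1e-3), 1 - 1e-3)
        x0[i] = math.log(p / (1 - p)) / gamma0
    lo, hi = options.x_bounds
    return alpha0, beta0, gamma0, np.clip(x0, lo, hi)


def _curve_step(fit_series, x, alpha, beta, gamma, beta_max=np.inf):
    """Nonlinear least squares over (alpha, beta, gamma) at fixed x."""
    u = np.concatenate([x[i] + s.d for i, s in enumerate(fit_series)])
    y = np.concatenate([s.y for s in fit_series])

    def resid(theta):
        return _predict(theta[0], theta[1], theta[2], u) - y

    def jac(theta):
        _a, b, g = theta
        z = np.exp(-g * u)
        denom = 1.0 + z
        J = np.empty((u.size, 3))
        J[:, 0] = 1.0
        J[:, 1] = 1.0 / denom
        J[:, 2] = b * u * z / denom**2
        return J

    sol = optimize.least_squares(
        resid,
        x0=np.array([alpha, min(beta, beta_max * 0.999), gamma]),
        jac=jac,
        bounds=([-np.inf, 1e-12, 1e-12], [np.inf, beta_max, np.inf]),
        method="trf",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
        max_nfev=200,
    )
    a, b, g = sol.x
    return float(a), float(b), float(g)


def _series_rss(series, alpha, beta, gamma, x):
    r = _predict(alpha, beta, gamma, x + series.d) - series.y
    return float(r @ r)


def _x_step(series, alpha, beta, gamma, bounds):
    """Bounded 1-D minimisation of a single series' RSS over its position."""
    res = optimize.minimize_scalar(
        lambda x: _series_rss(series, alpha, beta, gamma, x),
        bounds=bounds,
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


_INV_PHI = (math.sqrt(5.0) - 1.0) / 2.0


def _x_step_batch(d_pad, y_pad, mask, alpha, beta, gamma, bounds, xatol=1e-10):
    """Golden-section search over every series position simultaneously.

    ``d_pad``/``y_pad`` are (n_series, max_steps) arrays padded with zeros
    where ``mask`` is False.  All series are searched on the same bracket,
    so the whole sweep is a fixed number of vectorised RSS evaluations.
    """
    lo = np.full(d_pad.shape[0], float(bounds[0]))
    hi = np.full(d_pad.shape[0], float(bounds[1]))

    def rss_at(x):
        u = x[:, None] + d_pad
        r = (alpha + beta / (1.0 + np.exp(-gamma * u)) - y_pad) * mask
        return np.einsum("ij,ij->i", r, r)

    a, b = lo, hi
    n_iter = int(math.ceil(math.log(xatol / (bounds[1] - bounds[0])) / math.log(_INV_PHI)))
    for _ in range(max(n_iter, 1)):
        c = b - _INV_PHI * (b - a)
        d_pt = a + _INV_PHI * (b - a)
        left = rss_at(c) < rss_at(d_pt)
        b = np.where(left, d_pt, b)
        a = np.where(left, a, c)
    return 0.5 * (a + b)


def _joint_refine(fit_series, alpha, beta, gamma, x, options, beta_max=np.inf):
    """One joint least-squares solve over (alpha, beta, gamma, all x_i).

    Alternating optimisation converges linearly and can stall on its zigzag
    path; seeded with its solution, a joint Gauss-Newton polish restores the
    quadratic local rate.  The Jacobian is assembled analytically (each spot
    depends on the curve parameters and exactly one x_i).
    """
    n_series = len(fit_series)
    lengths = np.array([s.y.size for s in fit_series])
    series_idx = np.repeat(np.arange(n_series), lengths)
    d_all = np.concatenate([s.d for s in fit_series])
    y_all = np.concatenate([s.y for s in fit_series])
    n_spots = y_all.size

    def unpack(theta):
        return theta[0], theta[1], theta[2], theta[3:]

    def resid(theta):
        a, b, g, xv = unpack(theta)
        return _predict(a, b, g, xv[series_idx] + d_all) - y_all

    def jac(theta):
        a, b, g, xv = unpack(theta)
        u = xv[series_idx] + d_all
        z = np.exp(-g * u)
        denom = (1.0 + z) ** 2
        J = np.zeros((n_spots, 3 + n_series))
        J[:, 0] = 1.0
        J[:, 1] = 1.0 / (1.0 + z)
        J[:, 2] = b * u * z / denom
        dydx = b * g * z / denom
        J[np.arange(n_spots), 3 + series_idx] = dydx
        return J

    lo, hi = options.x_bounds
    lower = np.concatenate([[-np.inf, 1e-12, 1e-12], np.full(n_series, lo)])
    upper = np.concatenate([[np.inf, beta_max, np.inf], np.full(n_series, hi)])
    theta0 = np.concatenate(
        [[alpha, min(beta, beta_max * 0.999), gamma], np.clip(x, lo, hi)]
    )
    sol = optimize.least_squares(
        resid, theta0, jac=jac, bounds=(lower, upper), method="trf",
        xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=100,
    )
    a, b, g, xv = unpack(sol.x)
    return float(a), float(b), float(g), np.asarray(xv)


def fit_supercurve(series, options: FitOptions | None = None):
    """Fit the shared response curve and all series positions jointly.

    Minimises ``sum_ij (y_ij - response(x_i + d_j))^2`` over the curve
    parameters and all non-excluded series positions by alternating
    optimisation.  Excluded series (and series of non-fitting spot types)
    are positioned post hoc against the frozen curve.

    Returns ``(CurveFit, [ConcentrationEstimate, ...])`` with one estimate
    per input series, in input order.

    Raises
    ------
    SlideError
        Fewer non-excluded series than ``options.min_series``, or intensity
        range below ``options.min_intensity_range`` ("no signal").
    """
    options = options or FitOptions()
    series = list(series)
    fit_series = [s for s in series if not s.excluded_from_fit and len(s.y) >= 2]

    if len(fit_series) < options.min_series:
        raise SlideError(
            f"only {len(fit_series)} series available for curve fitting; "
            f"at least {options.min_series} required"
        )
    all_y = np.concatenate([s.y for s in fit_series])
    if not np.all(np.isfinite(all_y)):
        raise SlideError("non-finite intensities in fitting series")
    if float(np.ptp(all_y)) <= options.min_intensity_range:
        raise SlideError(
            "no signal: spot intensity range "
            f"{float(np.ptp(all_y)):g} is below {options.min_intensity_range:g}"
        )

    alpha, beta, gamma, x = _initial_values(fit_series, options)
    n_spots = int(all_y.size)

    # Padded per-series arrays for the vectorised x sweep.
    max_steps = max(s.y.size for s in fit_series)
    d_pad = np.zeros((len(fit_series), max_steps))
    y_pad = np.zeros_like(d_pad)
    mask = np.zeros_like(d_pad, dtype=bool)
    for i, s in enumerate(fit_series):
        d_pad[i, : s.d.size] = s.d
        y_pad[i, : s.y.size] = s.y
        mask[i, : s.y.size] = True

    def total_rss(a, b, g, xv):
        u = xv[:, None] + d_pad
        r = (a + b / (1.0 + np.exp(-g * u)) - y_pad) * mask
        return float(np.sum(r * r))

    scale = float(np.percentile(np.abs(all_y), 95)) or 1.0
    rss_floor = n_spots * (1e-8 * scale) ** 2
    if options.beta_max_factor > 0:
        spread = float(np.percentile(all_y, 95) - np.percentile(all_y, 5))
        beta_max = max(options.beta_max_factor * spread, options.min_intensity_range)
    else:
        beta_max = np.inf
    beta = min(beta, beta_max * 0.999)
    rss = total_rss(alpha, beta, gamma, x)
    converged = False
    iteration = 0
    for iteration in range(1, options.max_iterations + 1):
        alpha, beta, gamma = _curve_step(fit_series, x, alpha, beta, gamma, beta_max)
        x = _x_step_batch(d_pad, y_pad, mask, alpha, beta, gamma, options.x_bounds)
        new_rss = total_rss(alpha, beta, gamma, x)
        if new_rss <= rss_floor or (rss - new_rss) <= options.rss_tolerance * max(rss, rss_floor):
            rss = new_rss
            converged = True
            break
        rss = new_rss

    if options.joint_refinement:
        a2, b2, g2, x2 = _joint_refine(
            fit_series, alpha, beta, gamma, x, options, beta_max
        )
        new_rss = total_rss(a2, b2, g2, x2)
        if new_rss <= rss:  # keep the polish only if it did not regress
            alpha, beta, gamma, x = a2, b2, g2, x2
            # a near-zero change means the alternating path had converged to
            # the joint optimum already; either way we are at a stationary
            # point of the full objective now
            converged = True
            rss = new_rss

    tss = float(np.sum((all_y - all_y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    r2 = min(max(r2, 0.0), 1.0)

    fit = CurveFit(
        alpha=alpha,
        beta=beta,
        gamma=gamma,
        rss=rss,
        r2=r2,
        n_series_used=len(fit_series),
        n_spots_used=n_spots,
        converged=converged,
        n_iterations=iteration,
    )

    # Residual variance for curvature-based standard errors.
    dof = max(n_spots - (3 + len(fit_series)), 1)
    sigma2 = rss / dof

    estimates = []
    x_of = {s.series_id: x[i] for i, s in enumerate(fit_series)}
    for s in series:
        if s.series_id in x_of:
            est = _finalize_estimate(s, fit, x_of[s.series_id], sigma2, options, in_fit=True)
            if not converged:
                est.flags.add("PoorFit")
            estimates.append(est)
        else:
            estimates.append(estimate_excluded(s, fit, options, sigma2=sigma2))
    return fit, estimates


def _finalize_estimate(series, fit, x_hat, sigma2, options, in_fit):
    pred = response(x_hat + series.d, fit)
    residuals = pred - series.y
    flags = set()
    lo_level = fit.alpha + fit.beta * options.clamp_low
    hi_level = fit.alpha + fit.beta * options.clamp_high
    if np.all(series.y >= hi_level):
        flags.add("Saturated")
    elif np.all(series.y <= lo_level):
        flags.add("BelowDetection")
    if fit.beta > 0 and float(np.max(np.abs(residuals))) > options.poor_fit_residual_frac * fit.beta:
        flags.add("PoorFit")
    se = _curvature_se(series, fit, x_hat, sigma2)
    return ConcentrationEstimate(
        series_id=series.series_id,
        x=float(x_hat),
        se_x=se,
        in_fit=in_fit,
        residuals=residuals,
        flags=flags,
    )


def _curvature_se(series, fit, x_hat, sigma2):
    """SE of x from the curvature of the per-series RSS at its minimum.

    Near the minimum RSS_i(x) ~ RSS_i(x_hat) + h/2 (x - x_hat)^2, so
    Var(x_hat) ~ 2 sigma^2 / h.
    """
    eps = 1e-4
    g0 = _series_rss(series, fit.alpha, fit.beta, fit.gamma, x_hat)
    gp = _series_rss(series, fit.alpha, fit.beta, fit.gamma, x_hat + eps)
    gm = _series_rss(series, fit.alpha, fit.beta, fit.gamma, x_hat - eps)
    h = (gp - 2 * g0 + gm) / eps**2
    if h <= 0 or not math.isfinite(h):
        return float("nan")
    return math.sqrt(max(2.0 * sigma2 / h, 0.0))


def estimate_excluded(series, fit: CurveFit, options: FitOptions | None = None, sigma2=None):
    """Position one series against a frozen fitted curve.

    Series whose intensities all sit at the curve's asymptotes are not
    identifiable: they are clamped to the position bounds and flagged
    ``Saturated`` or ``BelowDetection``.
    """
    options = options or FitOptions()
    lo_level = fit.alpha + fit.beta * options.clamp_low
    hi_level = fit.alpha + fit.beta * options.clamp_high
    lo, hi = options.x_bounds

    if np.all(series.y >= hi_level):
        x_hat, flag = hi, "Saturated"
    elif np.all(series.y <= lo_level):
        x_hat, flag = lo, "BelowDetection"
    else:
        x_hat = _x_step(series, fit.alpha, fit.beta, fit.gamma, options.x_bounds)
        flag = None

    if sigma2 is None:
        dof = max(fit.n_spots_used - (3 + fit.n_series_used), 1)
        sigma2 = fit.rss / dof
    est = _finalize_estimate(series, fit, x_hat, sigma2, options, in_fit=False)
    if flag:
        est.flags.add(flag)
        est.se_x = float("nan")
    return est


def fit_diagnostics(fit: CurveFit, estimates, candidate_threshold: float = 0.1) -> FitDiagnostics:
    """Rank series by residual magnitude to surface exclusion candidates.

    ``candidate_threshold`` is the max |residual| as a fraction of the
    dynamic range beta above which a series is listed as a candidate for
    exclusion on a re-run.
    """
    frac = {}
    for est in estimates:
        if est.residuals.size and fit.beta > 0:
            frac[est.series_id] = float(np.max(np.abs(est.residuals))) / fit.beta
        else:
            frac[est.series_id] = float("nan")
    ranked = sorted(
        (sid for sid in frac if math.isfinite(frac[sid])),
        key=lambda sid: frac[sid],
        reverse=True,
    )
    candidates = [sid for sid in ranked if frac[sid] > candidate_threshold]
    n_flagged: dict[str, int] = {}
    for est in estimates:
        for flag in est.flags:
            n_flagged[flag] = n_flagged.get(flag, 0) + 1
    return FitDiagnostics(
        r2=fit.r2,
        max_residual_frac=frac,
        ranked_series=ranked,
        exclusion_candidates=candidates,
        n_flagged=n_flagged,
    )
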