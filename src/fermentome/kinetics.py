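"""Sigmoidal kinetics of fermentation temperature and pH.

Cocoa-bean fermentation temperature rises sigmoidally as microbial
metabolism heats the bean mass, testa/pulp pH rises as pulp acids are
consumed, and cotyledon pH falls as acids diffuse inward.  All three are
summarized here by a single 5-parameter generalized logistic (Richards)
curve

    y(t) = y0 + (yf - y0) / (1 + exp(-k (t - ti)))**(1/nu)

with lower/upper asymptotes ``y0``/``yf`` (native units), rate ``k``
(1/h), inflection-locating time ``ti`` (h) and asymmetry ``nu`` (> 0,
dimensionless; nu = 1 gives the symmetric logistic).  From a fitted
curve thirteen kinetic features are derived (maximum rate, time/value at
maximum kinetic energy, tangent-construction phase durations, per-phase
deltas and rates, and the inflection point), which downstream modules
correlate with chocolate sensory attributes.

Falling curves (e.g. cotyledon pH) are handled by reflecting about the
series maximum before fitting (:func:`invert_series`), which preserves
the sigmoid shape.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "KineticSeries",
    "FiveParamFit",
    "AbioticFeatures",
    "FitConfig",
    "ABIOTIC_FEATURE_NAMES",
    "five_param_model",
    "five_param_rate",
    "invert_series",
    "fit_five_param",
    "extract_abiotic_features",
    "colour_metrics",
]

MIN_POINTS_FIT = 15  # minimum observations required before a curve is fitted
MIN_POINTS_STORE = 3

ABIOTIC_FEATURE_NAMES = (
    "max_growth_rate",
    "time_to_max_ke",
    "value_at_max_ke",
    "exp_phase_duration",
    "linear_phase_duration",
    "decay_phase_duration",
    "delta_exp",
    "delta_linear",
    "delta_decay",
    "rate_exp",
    "rate_linear",
    "time_to_inflection",
    "inflection_value",
)


@dataclass(frozen=True)
class KineticSeries:
    """One measured fermentation curve (temperature or pH vs time)."""

    times: np.ndarray
    values: np.ndarray
    variable: str = "temperature"
    compartment: str = "mid-box"
    replicate: str = "r1"
    orientation: str = "as-is"  # or "inverted"
    invert_offset: float = 0.0  # recorded max used by invert_series

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or v.shape != t.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if t.size < MIN_POINTS_STORE:
            raise ValueError(f"need at least {MIN_POINTS_STORE} points, got {t.size}")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise ValueError("missing or non-finite values are not allowed")
        if self.orientation not in ("as-is", "inverted"):
            raise ValueError(f"unknown orientation {self.orientation!r}")

    @property
    def span(self) -> float:
        return float(self.values.max() - self.values.min())


@dataclass(frozen=True)
class FiveParamFit:
    """Least-squares estimate of the 5-parameter generalized logistic."""

    y0: float
    yf: float
    k: float
    ti: float
    nu: float
    rmse: float
    r_squared: float
    converged: bool
    n_starts_used: int

    def __post_init__(self) -> None:
        if self.converged:
            if not (self.k > 0 and self.nu > 0):
                raise ValueError("converged fit requires k > 0 and nu > 0")
            if not np.isfinite(self.rmse) or self.rmse < 0:
                raise ValueError("converged fit requires finite rmse >= 0")

    @property
    def params(self) -> tuple[float, float, float, float, float]:
        return (self.y0, self.yf, self.k, self.ti, self.nu)

    def predict(self, t: np.ndarray) -> np.ndarray:
        return five_param_model(t, *self.params)


@dataclass(frozen=True)
class AbioticFeatures:
    """The 13 kinetic features derived from a fitted curve."""

    max_growth_rate: float
    time_to_max_ke: float
    value_at_max_ke: float
    exp_phase_duration: float
    linear_phase_duration: float
    decay_phase_duration: float
    delta_exp: float
    delta_linear: float
    delta_decay: float
    rate_exp: float
    rate_linear: float
    time_to_inflection: float
    inflection_value: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in ABIOTIC_FEATURE_NAMES}


@dataclass(frozen=True)
class FitConfig:
    """Controls for the multi-start least-squares fit."""

    min_span: float = 0.5          # native units; below it the series is non-kinetic
    nu_starts: tuple[float, ...] = (0.3, 1.0, 3.0)
    n_jitter: int = 2              # extra jittered starts per nu
    seed: int = 0                  # seeds the start jitter only
    max_nfev: int = 2000
    decay_cutoff: float = 0.95     # fraction of span ending the decay phase


def five_param_model(t, y0, yf, k, ti, nu):
    """Evaluate y(t) = y0 + (yf-y0)/(1+exp(-k(t-ti)))**(1/nu), overflow-safe."""
    t = np.asarray(t, dtype=float)
    z = -k * (t - ti)
    # (1+e^z)^(-1/nu) = exp(-log(1+e^z)/nu); logaddexp keeps large z finite
    return y0 + (yf - y0) * np.exp(-np.logaddexp(0.0, z) / nu)


def five_param_rate(t, y0, yf, k, ti, nu):
    """Analytic dy/dt of the 5-parameter model.

    dy/dt = (yf-y0) * (k/nu) * u * (1+u)^(-1/nu - 1) with u = exp(-k(t-ti)).
    """
    t = np.asarray(t, dtype=float)
    z = -k * (t - ti)
    log1pu = np.logaddexp(0.0, z)
    return (yf - y0) * (k / nu) * np.exp(z - (1.0 / nu + 1.0) * log1pu)


def inflection_time(k: float, ti: float, nu: float) -> float:
    """Root of d2y/dt2 = 0: t = ti - ln(nu)/k (closed form for this model)."""
    return ti - np.log(nu) / k


def invert_series(series: KineticSeries) -> KineticSeries:
    """Reflect a falling series about its maximum so it rises sigmoidally.

    Records the offset so that a second inversion restores the original
    values (involution).  Used for cotyledon pH, which decreases with
    fermentation time.
    """
    if series.orientation == "as-is":
        offset = float(series.values.max())
        return replace(
            series,
            values=offset - series.values,
            orientation="inverted",
            invert_offset=offset,
        )
    # undo a previous inversion using the recorded offset
    return replace(
        series,
        values=series.invert_offset - series.values,
        orientation="as-is",
        invert_offset=0.0,
    )


def _initial_guesses(t: np.ndarray, y: np.ndarray, cfg: FitConfig):
    """Data-driven starts: asymptotes from min/max, ti from steepest slope."""
    y0g, yfg = float(y.min()), float(y.max())
    slopes = np.diff(y) / np.diff(t)
    i = int(np.argmax(np.abs(slopes)))
    tig = float(0.5 * (t[i] + t[i + 1]))
    span = max(yfg - y0g, 1e-9)
    kg = max(4.0 * abs(slopes[i]) / span, 1e-3)
    rng = np.random.default_rng(cfg.seed)
    starts = []
    for nu in cfg.nu_starts:
        starts.append((y0g, yfg, kg, tig, nu))
        for _ in range(cfg.n_jitter):
            jk = kg * float(np.exp(rng.normal(0, 0.5)))
            jti = tig + float(rng.normal(0, 0.1 * (t[-1] - t[0])))
            starts.append((y0g, yfg, jk, jti, nu))
    return starts


def fit_five_param(series: KineticSeries, config: FitConfig | None = None) -> FiveParamFit:
    """Fit the 5-parameter generalized logistic by multi-start least squares.

    Requires at least 15 observations and a value span above
    ``config.min_span``.  Starts are deterministic given ``config.seed``;
    the best-residual solution is returned.  A failure to converge is
    reported via ``converged=False`` with diagnostics, not raised.
    """
    cfg = config or FitConfig()
    t, y = series.times, series.values
    if t.size < MIN_POINTS_FIT:
        raise ValueError(
            f"fitting requires >= {MIN_POINTS_FIT} points, got {t.size}"
        )
    if series.span <= cfg.min_span:
        raise ValueError(
            f"value span {series.span:.4g} below minimum {cfg.min_span}; "
            "series is non-kinetic"
        )

    t_range = t[-1] - t[0]
    lower = [-np.inf, -np.inf, 1e-6, t[0] - 2 * t_range, 1e-3]
    upper = [np.inf, np.inf, 1e3, t[-1] + 2 * t_range, 1e3]

    def resid(p):
        return five_param_model(t, *p) - y

    best = None
    n_used = 0
    for p0 in _initial_guesses(t, y, cfg):
        p0 = np.clip(p0, lower, upper)
        n_used += 1
        try:
            sol = least_squares(
                resid, p0, bounds=(lower, upper), max_nfev=cfg.max_nfev
            )
        except Exception:  # pragma: no cover - optimizer pathologies
            continue
        if best is None or sol.cost < best.cost:
            best = sol

    if best is None:
        return FiveParamFit(
            np.nan, np.nan, np.nan, np.nan, np.nan,
            rmse=np.inf, r_squared=np.nan, converged=False, n_starts_used=n_used,
        )

    y0, yf, k, ti, nu = (float(v) for v in best.x)
    pred = five_param_model(t, y0, yf, k, ti, nu)
    rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum((pred - y) ** 2)) / ss_tot if ss_tot > 0 else np.nan
    return FiveParamFit(
        y0, yf, k, ti, nu,
        rmse=rmse, r_squared=r2, converged=bool(best.success), n_starts_used=n_used,
    )


def _argmax_rate(fit: FiveParamFit, t0: float, t1: float) -> float:
    """Locate argmax |dy/dt| on [t0, t1]: fine grid then golden-section polish."""
    grid = np.linspace(t0, t1, 4001)
    r = np.abs(five_param_rate(grid, *fit.params))
    i = int(np.argmax(r))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda t: -abs(float(five_param_rate(t, *fit.params))),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def extract_abiotic_features(
    fit: FiveParamFit, series: KineticSeries, config: FitConfig | None = None
) -> AbioticFeatures:
    """Derive the 13 kinetic features from a converged fit.

    Kinetic energy is taken proportional to (dy/dt)^2, so its maximum
    coincides with the maximum rate.  Phase boundaries come from the
    tangent at the inflection point: the exponential phase runs from the
    curve start to where the tangent meets the lower asymptote, the
    linear phase to where it meets the upper asymptote, and the decay
    phase to where the curve reaches y0 + decay_cutoff * span.
    """
    cfg = config or FitConfig()
    if not fit.converged:
        raise ValueError("features require a converged fit")
    y0, yf, k, ti, nu = fit.params
    if abs(yf - y0) <= cfg.min_span:
        raise ValueError("fitted span below minimum; degenerate kinetics")

    t_start = float(series.times[0])
    t_infl = inflection_time(k, ti, nu)
    y_infl = float(five_param_model(t_infl, *fit.params))

    # argmax of the rate; for this model it equals the inflection time,
    # but it is located numerically (grid + polish) as its own quantity.
    t_pad = series.times[-1] - t_start
    t_maxke = _argmax_rate(fit, t_start - t_pad, float(series.times[-1]) + t_pad)
    max_rate = float(five_param_rate(t_maxke, *fit.params))
    y_maxke = float(five_param_model(t_maxke, *fit.params))

    # tangent construction at the inflection
    m = float(five_param_rate(t_infl, *fit.params))
    t_lower = t_infl + (y0 - y_infl) / m
    t_upper = t_infl + (yf - y_infl) / m
    # time at which the curve reaches y0 + cutoff * (yf - y0):
    # (1+u)^(-1/nu) = cutoff  =>  u = cutoff^(-nu) - 1
    u95 = cfg.decay_cutoff ** (-nu) - 1.0
    t_decay_end = ti - np.log(u95) / k

    # phases are contiguous; durations clipped at 0 for curves truncated
    # so far into saturation that a boundary precedes the series start
    b0 = t_start
    b1 = max(t_lower, b0)
    b2 = max(t_upper, b1)
    b3 = max(t_decay_end, b2)

    yv = lambda t: float(five_param_model(t, *fit.params))
    d_exp, d_lin, d_dec = b1 - b0, b2 - b1, b3 - b2
    delta_exp = yv(b1) - yv(b0)
    delta_lin = yv(b2) - yv(b1)
    delta_dec = yv(b3) - yv(b2)

    def rate(delta: float, dur: float) -> float:
        return delta / dur if dur > 0 else 0.0

    return AbioticFeatures(
        max_growth_rate=max_rate,
        time_to_max_ke=t_maxke,
        value_at_max_ke=y_maxke,
        exp_phase_duration=d_exp,
        linear_phase_duration=d_lin,
        decay_phase_duration=d_dec,
        delta_exp=delta_exp,
        delta_linear=delta_lin,
        delta_decay=delta_dec,
        rate_exp=rate(delta_exp, d_exp),
        rate_linear=rate(delta_lin, d_lin),
        time_to_inflection=t_infl,
        inflection_value=y_infl,
    )


def colour_metrics(R: float, G: float, B: float) -> tuple[float, float]:
    """Greyscale and luminance of a bean-image RGB triple.

    greyscale = (R+G+B)/3;  luminance = 0.299 R + 0.587 G + 0.114 B.
    Channels must lie in [0, 255].
    """
    for name, c in (("R", R), ("G", G), ("B", B)):
        if not (0 <= c <= 255):
            raise ValueError(f"channel {name}={c} outside [0, 255]")
    grey = (R + G + B) / 3.0
    lum = 0.299 * R + 0.587 * G + 0.114 * B
    return grey, lum
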