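"""Per-pixel signal features for thermal excitation/relaxation curves.

Each pixel's curve is summarised by three families the classifier draws on:

* **Fourier-series coefficients** of the curve over its own duration taken
  as one fundamental period (linearly detrended by default, since
  relaxation curves are aperiodic), on both the relaxation window and the
  full recording;
* a **fitted exponential-decay coefficient**: least squares of
  ``T(t) = T_eq + A exp(-lambda t)`` on the relaxation segment;
* **lumped bioheat coefficients**: least squares of the piecewise
  heating+relaxation solution for (lambda_p, g, T_eq);

plus four summary statistics (baseline, peak, rise, time to half
relaxation).  Default configuration yields 2*(2H+1) + 3 + 3 + 4 = 44
features at H = 8 harmonics.

Control integration subtracts, per feature, the mean over the mass's
control grid from every site pixel — cancelling additive patient- and
location-specific effects — after which control rows are dropped.
Normalization is a per-feature z-score with sample (n-1) standard
deviation; the statistics are returned so held-out data can be transformed
with training statistics only.

Everything in this module is deterministic: no RNG anywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from .simulate import MassRecord, Protocol, ThermalSignal

__all__ = [
    "DecayFit",
    "FourierFeatures",
    "PennesFit",
    "FeatureConfig",
    "FeatureTable",
    "NormalizationStats",
    "relaxation_segment",
    "fourier_coefficients",
    "fit_exponential_decay",
    "fit_lumped_pennes",
    "pixel_feature_vector",
    "feature_names",
    "extract_features",
    "integrate_control",
    "normalize_features",
    "apply_normalization",
]

META_COLUMNS = ["dog_id", "mass_id", "pixel_row", "pixel_col", "label"]

LAMBDA_BOUNDS = (1e-4, 10.0)  # s^-1, admissible decay-rate range for fits


@dataclass(frozen=True)
class DecayFit:
    """Exponential relaxation fit T(t) = T_eq + A exp(-lambda t)."""

    t_eq_hat: float
    amplitude_hat: float
    lambda_hat: float
    rss: float
    converged: bool


@dataclass(frozen=True)
class FourierFeatures:
    """Fourier-series coefficients over one window of the signal."""

    a0: float
    a: np.ndarray  # cosine coefficients, harmonics 1..H
    b: np.ndarray  # sine coefficients, harmonics 1..H
    window: str    # "heating" | "relaxation" | "full"


@dataclass(frozen=True)
class PennesFit:
    """Lumped bioheat fit of the full heating+relaxation trajectory."""

    lambda_p_hat: float
    g_hat: float
    t_eq_hat: float
    rss: float
    converged: bool = True


@dataclass(frozen=True)
class FeatureConfig:
    """Configuration of the per-pixel feature family."""

    harmonics: int = 8
    detrend: bool = True
    integration_mode: str = "subtract"  # or "ratio"

    def __post_init__(self) -> None:
        if self.harmonics < 1:
            raise ValueError("harmonics must be >= 1")
        if self.integration_mode not in ("subtract", "ratio"):
            raise ValueError("integration_mode must be 'subtract' or 'ratio'")

    @property
    def n_features(self) -> int:
        return 2 * (2 * self.harmonics + 1) + 3 + 3 + 4


@dataclass
class FeatureTable:
    """Per-pixel feature matrix with mass/dog metadata and a processing state.

    ``data`` carries the metadata columns first (dog_id, mass_id, pixel_row,
    pixel_col, label), features after.  ``state`` is one of ``raw``,
    ``control-integrated``, ``normalized``.
    """

    data: pd.DataFrame
    state: str = "raw"

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing metadata columns: {missing}")
        if self.state not in ("raw", "control-integrated", "normalized"):
            raise ValueError(f"unknown state {self.state!r}")
        if self.data[self.feature_columns].isna().any().any():
            raise ValueError("feature table contains missing values")

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in META_COLUMNS]

    @property
    def features(self) -> pd.DataFrame:
        return self.data[self.feature_columns]

    def mass_labels(self) -> pd.Series:
        """One label per mass_id."""
        return self.data.groupby("mass_id", sort=True)["label"].first()


@dataclass(frozen=True)
class NormalizationStats:
    """Per-feature training means/s.d.s; applied to held-out rows as-is."""

    means: pd.Series
    sds: pd.Series
    zero_variance: tuple = ()

    def to_dict(self) -> dict:
        return {
            "means": self.means.to_dict(),
            "sds": self.sds.to_dict(),
            "zero_variance": list(self.zero_variance),
        }


def relaxation_segment(signal: ThermalSignal) -> ThermalSignal:
    """Post-heating samples with the time axis re-zeroed at segment start."""
    start = signal.heat_end_index
    if start >= len(signal):
        raise ValueError("relaxation segment is empty")
    times = signal.times[start:] - signal.times[start]
    return ThermalSignal(
        times=times, temperatures=signal.temperatures[start:], heat_end_index=0
    )


def _window_slice(signal: ThermalSignal, window: str) -> np.ndarray:
    if window == "full":
        return signal.temperatures
    if window == "relaxation":
        return relaxation_segment(signal).temperatures
    if window == "heating":
        return signal.temperatures[: signal.heat_end_index]
    raise ValueError(f"unknown window {window!r}")


def fourier_coefficients(
    signal: ThermalSignal, harmonics: int, window: str = "full", detrend: bool = True
) -> FourierFeatures:
    """Fourier-series coefficients of the windowed signal.

    The window's duration is the fundamental period; ``a0`` is the mean and
    (a_h, b_h) the cosine/sine coefficients of harmonic h, computed via the
    DFT of the (optionally linearly detrended) samples:

        a_h = (2/N) sum_n x_n cos(2 pi h n / N),  b_h likewise with sin.
    """
    x = np.asarray(_window_slice(signal, window), dtype=float)
    n = len(x)
    if n < 2 * harmonics + 1:
        raise ValueError(
            f"need at least {2 * harmonics + 1} samples for {harmonics} harmonics, got {n}"
        )
    if detrend:
        # remove the least-squares linear drift but keep the mean level,
        # so a0 still reports the window's average temperature
        idx = np.arange(n, dtype=float)
        slope = np.polyfit(idx, x, 1)[0]
        x = x - slope * (idx - idx.mean())
    spectrum = np.fft.rfft(x)
    a0 = spectrum[0].real / n
    a = 2.0 * spectrum[1 : harmonics + 1].real / n
    b = -2.0 * spectrum[1 : harmonics + 1].imag / n
    return FourierFeatures(a0=float(a0), a=a, b=b, window=window)


def _log_linear_lambda(times: np.ndarray, excess: np.ndarray) -> float:
    """Initial decay-rate guess via log-linear regression of the excess."""
    mask = excess > 1e-9
    if mask.sum() < 2:
        return 0.05
    slope = np.polyfit(times[mask], np.log(excess[mask]), 1)[0]
    return float(np.clip(-slope, LAMBDA_BOUNDS[0], LAMBDA_BOUNDS[1]))


_LAMBDA_GRID = np.geomspace(LAMBDA_BOUNDS[0], LAMBDA_BOUNDS[1], 40)

# per-time-axis basis matrices for the grid scan; pixels of a cohort all
# share one clock, so this is computed once, not per pixel
_GRID_CACHE: dict = {}
_GRID_CACHE_MAX = 16


def _grid_tables(key, basis_of_lambda):
    hit = _GRID_CACHE.get(key)
    if hit is None:
        e = np.vstack([basis_of_lambda(lam) for lam in _LAMBDA_GRID])
        hit = (e, e.sum(axis=1), np.einsum("ij,ij->i", e, e))
        if len(_GRID_CACHE) >= _GRID_CACHE_MAX:
            _GRID_CACHE.pop(next(iter(_GRID_CACHE)))
        _GRID_CACHE[key] = hit
    return hit


def _profiled_fit(basis_of_lambda, y: np.ndarray, cache_key, lam0: float | None):
    """Separable least squares: profile the rate, solve the rest exactly.

    Both fit models here are linear in two parameters once the rate is
    fixed, so for each candidate lambda the 2-parameter subproblem is
    solved in closed form and only the profiled residual sum of squares
    RSS(lambda) is minimized: a coarse log-spaced scan over the bounds
    brackets the optimum (the regression-based seed ``lam0`` is scanned
    too), then bounded scalar minimization refines it.
    """
    n = float(len(y))
    b0 = float(y.sum())
    yy = float(y @ y)

    def coeffs(g01, g11, b1):
        # model: y ~ c0 * 1 + c1 * phi(lam); 2x2 normal equations with a
        # tiny ridge guarding near-collinearity at the low-rate bound
        det = n * g11 - g01 * g01
        if det <= 1e-14 * n * max(g11, 1e-300):
            ridge = 1e-12 * max(n, g11)
            det = (n + ridge) * (g11 + ridge) - g01 * g01
            c0 = ((g11 + ridge) * b0 - g01 * b1) / det
            c1 = ((n + ridge) * b1 - g01 * b0) / det
        else:
            c0 = (g11 * b0 - g01 * b1) / det
            c1 = (n * b1 - g01 * b0) / det
        return c0, c1

    def solve(lam: float):
        phi = basis_of_lambda(lam)
        c0, c1 = coeffs(float(phi.sum()), float(phi @ phi), float(phi @ y))
        resid = c0 + c1 * phi - y
        return float(resid @ resid), c0, c1

    e, g01s, g11s = _grid_tables(cache_key, basis_of_lambda)
    b1s = e @ y
    rss_grid = np.empty(len(_LAMBDA_GRID))
    for i in range(len(_LAMBDA_GRID)):
        c0, c1 = coeffs(g01s[i], g11s[i], float(b1s[i]))
        # RSS via the expanded quadratic; exact given the solved coefficients
        rss_grid[i] = (
            yy + c0 * c0 * n + c1 * c1 * g11s[i]
            + 2 * (c0 * c1 * g01s[i] - c0 * b0 - c1 * b1s[i])
        )
    i = int(np.argmin(rss_grid))
    lo = _LAMBDA_GRID[max(i - 1, 0)]
    hi = _LAMBDA_GRID[min(i + 1, len(_LAMBDA_GRID) - 1)]
    if lam0 is not None and LAMBDA_BOUNDS[0] < lam0 < LAMBDA_BOUNDS[1]:
        if solve(lam0)[0] < rss_grid[i]:
            j = int(np.searchsorted(_LAMBDA_GRID, lam0))
            lo = min(lo, _LAMBDA_GRID[max(j - 1, 0)])
            hi = max(hi, _LAMBDA_GRID[min(j, len(_LAMBDA_GRID) - 1)])
    if hi > lo:
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(
            lambda l: solve(l)[0], bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-12},
        )
        lam = float(res.x)
    else:
        lam = float(_LAMBDA_GRID[i])
    rss, c0, c1 = solve(lam)
    return lam, c0, c1, max(rss, 0.0)


def fit_exponential_decay(segment: ThermalSignal) -> DecayFit:
    """Least-squares exponential relaxation fit on a post-heating segment.

    Separable least squares: for fixed lambda the optimal (T_eq, A) follow
    in closed form, and the profiled objective is minimized over
    lambda in [1e-4, 10] s^-1 (coarse log grid seeded with a log-linear
    regression estimate, then bounded refinement to 1e-12).  A flat segment
    (negligible amplitude) leaves lambda unidentifiable; the fit then
    reports ``converged=False`` with the best iterate rather than raising.
    """
    t = segment.times
    y = segment.temperatures
    if len(t) < 4:
        raise ValueError("need at least 4 samples to fit a decay")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite temperatures in segment")

    teq0 = float(y[-1])
    a0 = float(y[0] - y[-1])
    if abs(a0) < 1e-12 and float(np.ptp(y)) < 1e-12:
        # constant signal: amplitude zero, rate unidentifiable
        return DecayFit(teq0, 0.0, LAMBDA_BOUNDS[0], 0.0, converged=False)
    lam0 = _log_linear_lambda(t, np.sign(a0) * (y - teq0)) if a0 != 0 else None

    def basis(lam: float) -> np.ndarray:
        return np.exp(-lam * t)

    lam, teq, amp, rss = _profiled_fit(basis, y, ("decay", t.tobytes()), lam0)
    identifiable = abs(amp) > 1e-8 * max(1.0, abs(teq))
    return DecayFit(float(teq), float(amp), float(lam), rss, converged=identifiable)


def _piecewise_model(t: np.ndarray, lam: float, g: float, teq: float, heat_duration: float) -> np.ndarray:
    heating = t < heat_duration
    out = np.empty_like(t)
    out[heating] = teq + (g / lam) * -np.expm1(-lam * t[heating])
    rise_end = (g / lam) * -np.expm1(-lam * heat_duration)
    out[~heating] = teq + rise_end * np.exp(-lam * (t[~heating] - heat_duration))
    return out


def fit_lumped_pennes(
    signal: ThermalSignal,
    protocol: Protocol,
    decay_init: DecayFit | None = None,
) -> PennesFit:
    """Fit the lumped bioheat trajectory (lambda_p, g, T_eq) to a full scan.

    The model is the piecewise heating+relaxation solution of
    dT/dt = -lambda_p (T - T_eq) + g u(t) with T(0) = T_eq, which is linear
    in (g, T_eq) once lambda_p is fixed; the same profiled separable least
    squares as :func:`fit_exponential_decay` is used, seeded with the
    relaxation-segment decay estimate (pass ``decay_init`` to reuse one
    already computed).
    """
    t = signal.times
    y = signal.temperatures
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite temperatures in signal")
    hd = protocol.heat_duration

    if decay_init is None:
        try:
            decay_init = fit_exponential_decay(relaxation_segment(signal))
        except ValueError:
            decay_init = None
    lam0 = decay_init.lambda_hat if decay_init is not None and decay_init.converged else None

    heating = t < hd
    t_heat = t[heating]
    s_relax = t[~heating] - hd
    n = len(t)

    def basis(lam: float) -> np.ndarray:
        # response to a unit drive during the heating window
        phi = np.empty(n)
        phi[heating] = -np.expm1(-lam * t_heat) / lam
        phi[~heating] = (-np.expm1(-lam * hd) / lam) * np.exp(-lam * s_relax)
        return phi

    lam, teq, g, rss = _profiled_fit(basis, y, ("pennes", hd, t.tobytes()), lam0)
    return PennesFit(float(lam), float(g), float(teq), rss, converged=True)


def _summary_stats(signal: ThermalSignal) -> dict:
    """Baseline (t=0 sample), peak, rise, and time to half relaxation."""
    y = signal.temperatures
    baseline = float(y[0])
    peak = float(y.max())
    rise = peak - baseline
    seg = relaxation_segment(signal)
    start, final = seg.temperatures[0], seg.temperatures[-1]
    half = final + 0.5 * (start - final)
    below = np.nonzero(seg.temperatures <= half)[0] if start >= final else np.nonzero(
        seg.temperatures >= half
    )[0]
    t_half = float(seg.times[below[0]]) if len(below) else float(seg.times[-1])
    return {
        "baseline_c": baseline,
        "peak_c": peak,
        "rise_c": rise,
        "t_half_relax_s": t_half,
    }


def feature_names(config: FeatureConfig = FeatureConfig()) -> list[str]:
    """Stable, unique names of the full feature vector, in order."""
    names: list[str] = []
    for window in ("relax", "full"):
        names.append(f"fourier_{window}_a0")
        for h in range(1, config.harmonics + 1):
            names.append(f"fourier_{window}_a{h}")
            names.append(f"fourier_{window}_b{h}")
    names += ["decay_t_eq", "decay_amplitude", "decay_lambda"]
    names += ["pennes_lambda_p", "pennes_g", "pennes_t_eq"]
    names += ["baseline_c", "peak_c", "rise_c", "t_half_relax_s"]
    return names


def pixel_feature_vector(
    signal: ThermalSignal,
    protocol: Protocol,
    config: FeatureConfig = FeatureConfig(),
) -> dict:
    """Full named feature vector for one pixel's signal."""
    values: dict[str, float] = {}
    for window, tag in (("relaxation", "relax"), ("full", "full")):
        ff = fourier_coefficients(signal, config.harmonics, window, config.detrend)
        values[f"fourier_{tag}_a0"] = ff.a0
        for h in range(1, config.harmonics + 1):
            values[f"fourier_{tag}_a{h}"] = float(ff.a[h - 1])
            values[f"fourier_{tag}_b{h}"] = float(ff.b[h - 1])
    d = fit_exponential_decay(relaxation_segment(signal))
    values["decay_t_eq"] = d.t_eq_hat
    values["decay_amplitude"] = d.amplitude_hat
    values["decay_lambda"] = d.lambda_hat
    p = fit_lumped_pennes(signal, protocol, decay_init=d)
    values["pennes_lambda_p"] = p.lambda_p_hat
    values["pennes_g"] = p.g_hat
    values["pennes_t_eq"] = p.t_eq_hat
    values.update(_summary_stats(signal))
    return values


def extract_features(
    records: list[MassRecord],
    protocol: Protocol,
    config: FeatureConfig = FeatureConfig(),
) -> tuple[FeatureTable, FeatureTable]:
    """Raw per-pixel feature tables for the site and control grids."""
    site_rows, control_rows = [], []
    for record in records:
        side = record.grid_side
        for region, grid, rows in (
            ("site", record.site_grid, site_rows),
            ("control", record.control_grid, control_rows),
        ):
            for idx, signal in enumerate(grid):
                r, c = divmod(idx, side)
                row = {
                    "dog_id": record.dog_id,
                    "mass_id": record.mass_id,
                    "pixel_row": r,
                    "pixel_col": c,
                    "label": record.label,
                }
                row.update(pixel_feature_vector(signal, protocol, config))
                rows.append(row)
    cols = META_COLUMNS + feature_names(config)
    site = pd.DataFrame(site_rows, columns=cols)
    control = pd.DataFrame(control_rows, columns=cols)
    return FeatureTable(site, "raw"), FeatureTable(control, "raw")


def integrate_control(
    site: FeatureTable,
    control: FeatureTable,
    mode: str = "subtract",
) -> FeatureTable:
    """Fold each mass's control-grid features into its site pixels.

    ``subtract`` (default) replaces every site value by
    (site value - mean of that feature over the mass's control pixels),
    which cancels additive patient/ambient effects exactly; ``ratio``
    divides instead.  Control rows are dropped from the result.
    """
    if site.state != "raw" or control.state != "raw":
        raise ValueError("integrate_control expects raw tables")
    if site.feature_columns != control.feature_columns:
        raise ValueError("site and control tables have different feature sets")
    site_masses = set(site.data["mass_id"])
    control_masses = set(control.data["mass_id"])
    missing = sorted(site_masses - control_masses)
    if missing:
        raise ValueError(f"masses missing a control grid: {missing}")

    feats = site.feature_columns
    control_means = control.data.groupby("mass_id")[feats].mean()
    out = site.data.copy()
    aligned = control_means.loc[out["mass_id"]].to_numpy()
    if mode == "subtract":
        out[feats] = out[feats].to_numpy() - aligned
    elif mode == "ratio":
        out[feats] = out[feats].to_numpy() / aligned
    else:
        raise ValueError(f"unknown integration mode {mode!r}")
    return FeatureTable(out, "control-integrated")


def normalize_features(
    table: FeatureTable,
) -> tuple[FeatureTable, NormalizationStats]:
    """Z-score every feature across the table's rows (sample s.d., ddof=1).

    Returns the statistics so held-out rows can be transformed with the
    training partition's means and s.d.s only.  Zero-variance features are
    set to 0 and flagged with a warning.
    """
    if table.state != "control-integrated":
        raise ValueError("normalize_features expects a control-integrated table")
    if len(table.data) < 2:
        raise ValueError("need at least 2 rows to normalize")
    feats = table.feature_columns
    values = table.data[feats]
    if not np.all(np.isfinite(values.to_numpy())):
        raise ValueError("non-finite feature values")
    means = values.mean()
    sds = values.std(ddof=1)
    zero_var = tuple(sds.index[sds == 0.0])
    if zero_var:
        warnings.warn(
            f"zero-variance features set to 0: {list(zero_var)}", stacklevel=2
        )
    stats = NormalizationStats(means=means, sds=sds, zero_variance=zero_var)
    return apply_normalization(table, stats), stats


def apply_normalization(table: FeatureTable, stats: NormalizationStats) -> FeatureTable:
    """Transform a table with previously computed (training) statistics."""
    feats = table.feature_columns
    out = table.data.copy()
    sds = stats.sds.replace(0.0, 1.0)
    out[feats] = (out[feats] - stats.means[feats]) / sds[feats]
    for name in stats.zero_variance:
        out[name] = 0.0
    return FeatureTable(out, "normalized")
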