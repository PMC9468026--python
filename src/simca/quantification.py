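"""Langmuir calibration, limit of detection, and bootstrap quantification error.

The calibration curve is the Langmuir binding isotherm

    signal(c) = B_max * c / (K_d + c)

fitted to per-FOV signals (absolute colocalized counts, capture-normalized
colocalized counts, or single-color counts) across a titration by nonlinear
least squares. Its inverse,

    c(y) = K_d * y / (B_max - y),

converts a measured signal into a concentration. The limit of detection is
the concentration at the blank mean plus three blank standard deviations,
with its uncertainty propagated in quadrature through the inverse function
(cross-covariance terms omitted):

    sigma_LOD^2 = (K_d*y/(B_max-y)^2 * s_Bmax)^2
                + (y/(B_max-y)     * s_Kd)^2
                + (K_d*B_max/(B_max-y)^2 * s_y)^2

Quantification error is summarized by the mean absolute percentage log error
(MAPLE) under an out-of-bag bootstrap: resample FOVs with replacement, refit,
predict the concentrations of the unsampled FOVs, and average
``|log True - log Pred| / |log True|`` (base-invariant; concentrations in pM
so the log of every nonzero ladder point is positive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "langmuir",
    "LangmuirModel",
    "CalibrationResult",
    "LodResult",
    "MapleResult",
    "invert_langmuir",
    "compute_lod",
    "bootstrap_maple",
    "maple",
]

# predictions are clipped into this window (pM) before logging so that one
# pathological out-of-bag draw cannot make MAPLE infinite
_PRED_FLOOR_PM = 1e-3
_PRED_CEIL_PM = 1e9


def langmuir(c, kd: float, bmax: float):
    """Langmuir isotherm ``bmax * c / (kd + c)``."""
    c = np.asarray(c, dtype=float)
    return bmax * c / (kd + c)


class LangmuirModel:
    """Langmuir calibration model for a titration of per-FOV signals.

    Parameters
    ----------
    concentrations : array-like, pM
        Analyte concentration of each FOV.
    signals : array-like
        Per-FOV signal (same length), one of the assay's count statistics.
    signal_kind : str
        Which statistic the signals are; carried through to results.
    """

    def __init__(
        self,
        concentrations: Sequence[float],
        signals: Sequence[float],
        signal_kind: str = "normalized_coloc",
    ) -> None:
        c = np.asarray(concentrations, dtype=float)
        y = np.asarray(signals, dtype=float)
        if c.shape != y.shape or c.ndim != 1:
            raise ValueError("concentrations and signals must be equal-length 1-D")
        if not np.isfinite(y).all():
            raise ValueError("signals must be finite")
        if (c < 0).any():
            raise ValueError("concentrations must be non-negative")
        if len(np.unique(c[c > 0])) < 3:
            raise ValueError("need at least 3 distinct non-zero concentrations")
        self.concentrations = c
        self.signals = y
        self.signal_kind = signal_kind

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        signal_kind: str = "normalized_coloc",
        concentration_col: str = "concentration_pm",
    ) -> "LangmuirModel":
        """Build from a per-FOV counts table; the signal column is
        ``signal_kind`` itself if present, else a column named ``signal``."""
        col = signal_kind if signal_kind in df.columns else "signal"
        return cls(df[concentration_col].to_numpy(), df[col].to_numpy(), signal_kind)

    def fit(self) -> "CalibrationResult":
        """Nonlinear least squares, both parameters bounded positive.

        Initialization: K_d at the median non-zero concentration, B_max at the
        maximum observed signal. Standard errors come from the Jacobian-based
        covariance of the fit.
        """
        c, y = self.concentrations, self.signals
        p0 = [float(np.median(c[c > 0])), float(y.max()) if y.max() > 0 else 1.0]
        try:
            popt, pcov = curve_fit(
                langmuir, c, y, p0=p0,
                bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                maxfev=20000,
            )
        except RuntimeError as exc:  # pragma: no cover - pathological data
            raise RuntimeError(
                f"Langmuir fit failed to converge (n={len(y)}, p0={p0}): {exc}"
            ) from exc
        kd, bmax = popt
        sd = np.sqrt(np.diag(pcov))
        return CalibrationResult(
            kd=float(kd),
            bmax=float(bmax),
            sigma_kd=float(sd[0]),
            sigma_bmax=float(sd[1]),
            covariance=pcov,
            signal_kind=self.signal_kind,
            nobs=len(y),
            model=self,
        )


@dataclass
class CalibrationResult:
    """Fitted Langmuir calibration: estimates, uncertainties, inversion."""

    kd: float
    bmax: float
    sigma_kd: float
    sigma_bmax: float
    covariance: np.ndarray
    signal_kind: str = "normalized_coloc"
    nobs: int = 0
    model: LangmuirModel | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.kd <= 0 or self.bmax <= 0:
            raise ValueError("kd and bmax must be positive")
        cov = np.asarray(self.covariance, dtype=float)
        if cov.shape != (2, 2) or not np.allclose(cov, cov.T):
            raise ValueError("covariance must be a symmetric 2x2 matrix")
        self.covariance = cov

    def predict(self, concentrations) -> np.ndarray:
        """Forward curve: expected signal at the given concentrations (pM)."""
        return langmuir(concentrations, self.kd, self.bmax)

    def invert(self, signal) -> np.ndarray | float:
        """Concentration at a signal; see :func:`invert_langmuir`."""
        return invert_langmuir(self, signal)

    def lod(self, blank_signals: Sequence[float]) -> "LodResult":
        """Limit of detection from blank FOVs; see :func:`compute_lod`."""
        return compute_lod(self, blank_signals)

    def summary(self) -> str:
        lines = [
            "Langmuir calibration",
            "====================",
            f"signal kind : {self.signal_kind}",
            f"n FOVs      : {self.nobs}",
            f"K_d   [pM]  : {self.kd:10.4g}  +/- {self.sigma_kd:.4g}",
            f"B_max       : {self.bmax:10.4g}  +/- {self.sigma_bmax:.4g}",
            f"half-saturation signal (B_max/2): {self.bmax / 2:.4g}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Calibration curve with the fitted FOV signals overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.model is not None:
            ax.semilogx(
                np.clip(self.model.concentrations, 1e-2, None),
                self.model.signals, ".", alpha=0.4, label="FOVs",
            )
            cmax = self.model.concentrations.max()
        else:  # pragma: no cover - plotting without data
            cmax = 100 * self.kd
        grid = np.logspace(-1, np.log10(cmax * 1.5), 200)
        ax.semilogx(grid, self.predict(grid), "-",
                    label=f"fit: Kd={self.kd:.3g} pM, Bmax={self.bmax:.3g}")
        ax.set_xlabel("concentration [pM]")
        ax.set_ylabel(self.signal_kind)
        ax.legend()
        return ax


def invert_langmuir(fit: CalibrationResult, signal) -> np.ndarray | float:
    """Invert the calibration: ``c = K_d * y / (B_max - y)``.

    Signals at or above ``B_max`` map to ``+inf`` (with a warning), negative
    signals are clamped to concentration 0 (with a warning).
    """
    y = np.asarray(signal, dtype=float)
    scalar = y.ndim == 0
    y = np.atleast_1d(y)
    out = np.empty_like(y)
    over = y >= fit.bmax
    under = y < 0
    ok = ~(over | under)
    out[ok] = fit.kd * y[ok] / (fit.bmax - y[ok])
    if over.any():
        warnings.warn("signal >= B_max: concentration is unbounded (+inf)")
        out[over] = np.inf
    if under.any():
        warnings.warn("negative signal clamped to concentration 0")
        out[under] = 0.0
    return float(out[0]) if scalar else out


@dataclass(frozen=True)
class LodResult:
    """Limit of detection: signal-space definition and concentration-space value."""

    lod_signal: float
    lod_concentration: float  # pM
    sigma_lod: float  # pM
    blank_mean: float
    blank_sd: float


def compute_lod(fit: CalibrationResult, blank_signals: Sequence[float]) -> LodResult:
    """LOD = blank mean + 3 blank SD, converted to concentration with error.

    Uses the quadrature propagation through the inverse function with the
    fit's parameter standard errors and the blank SD. If the LOD signal
    reaches ``B_max`` the assay cannot resolve it: the concentration and its
    error are ``+inf`` (with a warning).
    """
    blanks = np.asarray(blank_signals, dtype=float)
    if blanks.size < 2:
        raise ValueError("need at least 2 blank FOVs")
    y_bar = float(blanks.mean())
    s_y = float(blanks.std(ddof=1))
    lod_signal = y_bar + 3.0 * s_y

    if lod_signal >= fit.bmax:
        warnings.warn("LOD signal exceeds B_max; LOD is unresolvable (+inf)")
        return LodResult(lod_signal, np.inf, np.inf, y_bar, s_y)

    y = lod_signal
    denom = fit.bmax - y
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # y==0 is a legitimate all-zero blank
        lod_conc = invert_langmuir(fit, y)
    d_bmax = fit.kd * y / denom**2
    d_kd = y / denom
    d_y = fit.kd * fit.bmax / denom**2
    sigma_lod = float(
        np.sqrt(
            (d_bmax * fit.sigma_bmax) ** 2
            + (d_kd * fit.sigma_kd) ** 2
            + (d_y * s_y) ** 2
        )
    )
    return LodResult(float(lod_signal), float(lod_conc), sigma_lod, y_bar, s_y)


def maple(true_pm: Sequence[float], predicted_pm: Sequence[float]) -> float:
    """Mean absolute percentage log error, in percent.

    ``100/n * sum |log(True) - log(Pred)| / |log(True)|`` — invariant to the
    log base but not to concentration units (fixed to pM). Entries with
    non-positive truth are excluded (log undefined).
    """
    t = np.asarray(true_pm, dtype=float)
    p = np.asarray(predicted_pm, dtype=float)
    keep = t > 0
    if not keep.any():
        raise ValueError("MAPLE needs at least one FOV with non-zero truth")
    t, p = t[keep], np.clip(p[keep], _PRED_FLOOR_PM, _PRED_CEIL_PM)
    log_t = np.log(t)
    if np.any(log_t == 0):
        raise ValueError("truth of exactly 1 pM makes the denominator vanish")
    return float(100.0 * np.mean(np.abs(log_t - np.log(p)) / np.abs(log_t)))


@dataclass(frozen=True)
class MapleResult:
    """Bootstrap quantification error: MAPLE mean and spread over iterations."""

    mean_percent: float
    sd_percent: float
    samples: np.ndarray
    n_redrawn: int = 0

    def summary(self) -> str:
        return (
            f"MAPLE over {len(self.samples)} out-of-bag bootstraps: "
            f"{self.mean_percent:.2f}% +/- {self.sd_percent:.2f}%"
            + (f" ({self.n_redrawn} degenerate iterations redrawn)"
               if self.n_redrawn else "")
        )


def bootstrap_maple(
    concentrations: Sequence[float],
    signals: Sequence[float],
    signal_kind: str = "normalized_coloc",
    n_boot: int = 1000,
    rng_seed: int | np.random.Generator | None = 0,
) -> MapleResult:
    """Out-of-bag bootstrap of the quantification error.

    Per iteration: resample the FOVs with replacement as a training set, fit
    the Langmuir curve, predict the concentration of every unsampled FOV
    through the inverse curve, and score MAPLE on those with non-zero truth.
    Iterations whose out-of-bag set is empty of usable FOVs, or whose
    training set cannot support a fit, are redrawn (counted in the result).
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(signals, dtype=float)
    if len(np.unique(c[c > 0])) < 2:
        raise ValueError("need at least 2 distinct non-zero concentrations")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(rng_seed)
    n = len(c)
    samples = np.empty(n_boot)
    redrawn = 0
    i = 0
    guard = 0
    while i < n_boot:
        guard += 1
        if guard > 50 * n_boot:
            raise RuntimeError("bootstrap cannot produce usable out-of-bag sets")
        idx = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), idx)
        oob = oob[c[oob] > 0]
        if oob.size == 0 or len(np.unique(c[idx][c[idx] > 0])) < 3:
            redrawn += 1
            continue
        try:
            fit = LangmuirModel(c[idx], y[idx], signal_kind).fit()
        except (ValueError, RuntimeError):
            redrawn += 1
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pred = np.atleast_1d(fit.invert(y[oob]))
        samples[i] = maple(c[oob], pred)
        i += 1
    return MapleResult(
        mean_percent=float(samples.mean()),
        sd_percent=float(samples.std(ddof=1)) if n_boot > 1 else 0.0,
        samples=samples,
        n_redrawn=redrawn,
    )
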