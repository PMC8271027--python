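"""Thermal-shift (differential scanning fluorimetry) melting-point fits.

A dye-based melt curve is fitted with the Boltzmann sigmoid

    F(T) = F_min + (F_max - F_min) / (1 + exp((Tm - T) / slope))

whose midpoint ``Tm`` is the melting temperature.  Real dye curves quench
after the transition, so the data are truncated after the global fluorescence
maximum and the rising limb alone is fitted.  ``delta_tm`` compares two
conditions with a propagated standard error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = ["MeltCurve", "TmFit", "BoltzmannMelt", "fit_boltzmann", "delta_tm"]


@dataclass
class MeltCurve:
    """Fluorescence vs temperature for one well."""

    temperature: np.ndarray      # degC, strictly increasing
    fluorescence: np.ndarray     # arbitrary units
    condition: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperature.shape != self.fluorescence.shape:
            raise ValueError("temperature and fluorescence length mismatch")
        if self.temperature.size < 10:
            raise ValueError("a melt curve needs at least 10 points")
        if np.any(np.diff(self.temperature) <= 0):
            raise ValueError("temperatures must be strictly increasing")


@dataclass
class TmFit:
    tm: float
    slope: float
    f_min: float
    f_max: float
    tm_stderr: float
    slope_stderr: float
    converged: bool
    truncation_index: int
    condition: str = ""


class BoltzmannMelt(RegressorMixin, BaseEstimator):
    """Boltzmann-sigmoid estimator for DSF melt curves.

    Parameters
    ----------
    truncate_after_max : bool
        Drop points after the global fluorescence maximum (post-transition
        dye quench) before fitting.
    noise_factor : float
        Minimum transition height in units of the estimated noise SD.

    Attributes
    ----------
    tm_ : float
        Melting temperature (degC), initialized at the temperature of the
        steepest rise (max dF/dT).
    slope_ : float
        Transition width (degC).
    f_min_, f_max_ : float
    """

    def __init__(self, truncate_after_max: bool = True,
                 noise_factor: float = 3.0):
        self.truncate_after_max = truncate_after_max
        self.noise_factor = noise_factor

    @staticmethod
    def _model(t, f_min, f_max, tm, slope):
        return f_min + (f_max - f_min) / (1.0 + np.exp((tm - t) / slope))

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).reshape(-1)
        f = np.asarray(y, dtype=float).reshape(-1)
        if t.size != f.size:
            raise ValueError("X and y must have the same length")

        if self.truncate_after_max:
            cut = int(np.argmax(f)) + 1
        else:
            cut = t.size
        if cut < 5:
            raise ValueError("no melting transition detected before the "
                             "fluorescence maximum")
        tt, ff = t[:cut], f[:cut]
        self.truncation_index_ = cut

        d = np.diff(ff)
        noise = 1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0)
        height = float(np.max(ff) - np.min(ff))
        if height < self.noise_factor * noise or height == 0:
            raise ValueError("no melting transition detected")

        # initialize Tm at the steepest rise
        slopes = d / np.diff(tt)
        tm0 = float(0.5 * (tt[np.argmax(slopes)] + tt[np.argmax(slopes) + 1]))
        p0 = [float(np.min(ff)), float(np.max(ff)), tm0,
              max((tt[-1] - tt[0]) / 20.0, 0.5)]
        try:
            popt, pcov = optimize.curve_fit(self._model, tt, ff, p0=p0,
                                            maxfev=20000)
            self.converged_ = True
        except RuntimeError:
            popt = p0
            pcov = np.full((4, 4), np.nan)
            self.converged_ = False
        self.f_min_, self.f_max_, self.tm_, self.slope_ = map(float, popt)
        se = np.sqrt(np.clip(np.diag(pcov), 0, None))
        self.f_min_stderr_, self.f_max_stderr_, self.tm_stderr_, \
            self.slope_stderr_ = map(float, se)
        if not (tt[0] - 5.0 <= self.tm_ <= tt[-1] + 5.0):
            self.converged_ = False
        return self

    def predict(self, X):
        t = np.asarray(X, dtype=float).reshape(-1)
        return self._model(t, self.f_min_, self.f_max_, self.tm_, self.slope_)


def fit_boltzmann(curve: MeltCurve, **params) -> TmFit:
    """Fit one melt curve; thin wrapper over :class:`BoltzmannMelt`."""
    est = BoltzmannMelt(**params).fit(curve.temperature, curve.fluorescence)
    return TmFit(tm=est.tm_, slope=est.slope_, f_min=est.f_min_,
                 f_max=est.f_max_, tm_stderr=est.tm_stderr_,
                 slope_stderr=est.slope_stderr_, converged=est.converged_,
                 truncation_index=est.truncation_index_,
                 condition=curve.condition)


def delta_tm(fit_a: TmFit, fit_b: TmFit) -> tuple[float, float]:
    """Tm difference (a minus b) with propagated standard error."""
    if not (fit_a.converged and fit_b.converged):
        raise ValueError("delta_tm requires two converged fits")
    d = fit_a.tm - fit_b.tm
    se = float(np.sqrt(fit_a.tm_stderr**2 + fit_b.tm_stderr**2))
    return float(d), se
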