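"""Methyl-CPMG relaxation-dispersion analysis.

A constant-time CPMG experiment reports, for each methyl group, peak
intensities ``I(nu)`` at a set of refocusing frequencies ``nu_CPMG`` plus a
reference intensity ``I0`` recorded without the relaxation block.  These
convert to effective transverse relaxation rates

    R2_eff(nu) = (1 / T_CPMG) * ln(I0 / I(nu))

whose dependence on ``nu`` (a "dispersion") reports micro- to millisecond
conformational exchange.  Exchange between two states in the fast limit
follows the Luz-Meiboom closed form

    R2(nu) = R2_0 + (phi / k_ex) * (1 - (4 nu / k_ex) * tanh(k_ex / (4 nu)))

with intrinsic rate ``R2_0`` (1/s), exchange rate ``k_ex`` (1/s) and
amplitude ``phi = p_a * p_b * delta_omega**2`` (1/s^2).  Individual
populations and chemical-shift differences are not identifiable in this form
and are not reported.

The module computes R2_eff tables, pools duplicate-based errors, flags
dispersing methyls (amplitude > 2 1/s), and fits both the two-state model
and a flat no-exchange model with AICc model selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "DispersionProfile",
    "DispersionFit",
    "dispersion_curve",
    "compute_r2eff",
    "estimate_errors",
    "detect_dispersion",
    "TwoStateDispersion",
    "fit_two_state",
    "select_model",
    "DISPERSION_THRESHOLD",
]

#: Dispersion-amplitude threshold (1/s) above which a methyl counts as exchanging.
DISPERSION_THRESHOLD = 2.0


def dispersion_curve(nu, r2_0: float, kex: float, phi: float) -> np.ndarray:
    """Fast-exchange (Luz-Meiboom) two-state dispersion curve.

    Defined by continuity at ``nu = 0`` as the limit ``r2_0 + phi / kex``.
    """
    nu = np.asarray(nu, dtype=float)
    if kex <= 0:
        raise ValueError("kex must be positive")
    out = np.empty_like(nu, dtype=float)
    zero = nu == 0
    out[zero] = r2_0 + phi / kex
    nz = nu[~zero]
    x = kex / (4.0 * nz)
    out[~zero] = r2_0 + (phi / kex) * (1.0 - np.tanh(x) / x)
    return out


@dataclass
class DispersionProfile:
    """Per-methyl CPMG intensities over the pulse-frequency schedule.

    ``nu`` may contain duplicates (used for error estimation) and one or more
    ``nu = 0`` entries marking the reference scan.  ``i_ref`` defaults to the
    mean intensity of the ``nu = 0`` rows.
    """

    methyl_id: str
    nu: np.ndarray
    intensity: np.ndarray
    t_cpmg: float = 0.040
    i_ref: float | None = None

    def __post_init__(self) -> None:
        self.nu = np.asarray(self.nu, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.nu.shape != self.intensity.shape or self.nu.ndim != 1:
            raise ValueError("nu and intensity must be 1-D arrays of equal length")
        if np.any(self.nu < 0):
            raise ValueError("nu_CPMG values must be non-negative")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")
        if self.t_cpmg <= 0:
            raise ValueError("t_cpmg must be positive")
        if self.i_ref is None:
            ref = self.intensity[self.nu == 0]
            self.i_ref = float(ref.mean()) if ref.size else None
        if self.i_ref is not None and self.i_ref <= 0:
            raise ValueError("reference intensity must be positive")


@dataclass
class DispersionFit:
    """Two-state vs no-exchange fit result for one methyl."""

    methyl_id: str
    model: str                       # "two-state-fast" or "no-exchange"
    r2_0: float
    kex: float
    phi: float
    r2_0_stderr: float
    kex_stderr: float
    phi_stderr: float
    rss: float                       # weighted (chi-square) for chosen model
    aicc_two_state: float
    aicc_flat: float
    r2_0_flat: float
    dispersion_amplitude: float
    dispersing: bool
    sigma: float


def compute_r2eff(profile: DispersionProfile) -> pd.DataFrame:
    """Convert peak intensities to effective relaxation rates.

    Returns a frame with columns ``nu``, ``r2eff`` and ``negative`` for all
    ``nu > 0`` rows (duplicates kept as separate rows).  Non-positive
    intensities are dropped with a warning; intensities above the reference
    yield negative rates, which are emitted but flagged.
    """
    if profile.i_ref is None:
        raise ValueError(f"{profile.methyl_id}: no nu = 0 reference intensity")
    mask = profile.nu > 0
    nu = profile.nu[mask]
    inten = profile.intensity[mask]
    ok = inten > 0
    if not np.all(ok):
        warnings.warn(f"{profile.methyl_id}: dropped {np.sum(~ok)} "
                      "non-positive intensities", stacklevel=2)
        nu, inten = nu[ok], inten[ok]
    r2 = np.log(profile.i_ref / inten) / profile.t_cpmg
    neg = r2 < 0
    if np.any(neg):
        warnings.warn(f"{profile.methyl_id}: {np.sum(neg)} intensities exceed "
                      "the reference (negative R2_eff)", stacklevel=2)
    return pd.DataFrame({"nu": nu, "r2eff": r2, "negative": neg})


def estimate_errors(profile: DispersionProfile,
                    fallback_sigma: float | None = None) -> float:
    """Pooled R2_eff uncertainty from duplicated nu_CPMG points.

    For ``m`` duplicate pairs with differences ``dR2``, the pooled SD is
    ``sqrt(sum(dR2**2) / (2 m))``, applied to every point of the profile.
    Without duplicates, ``fallback_sigma`` is returned with a warning.
    """
    table = compute_r2eff(profile)
    diffs = []
    for _, grp in table.groupby("nu"):
        vals = grp["r2eff"].to_numpy()
        # consecutive pairing within a nu value; the default schedule has
        # exactly two measurements at 50 and at 300 Hz
        for i in range(0, vals.size - 1, 2):
            diffs.append(vals[i + 1] - vals[i])
    if not diffs:
        if fallback_sigma is None:
            raise ValueError(f"{profile.methyl_id}: no duplicated nu points "
                             "and no fallback sigma given")
        warnings.warn(f"{profile.methyl_id}: no duplicates; using fallback "
                      f"sigma = {fallback_sigma}", stacklevel=2)
        return float(fallback_sigma)
    d = np.asarray(diffs)
    return float(np.sqrt(np.sum(d**2) / (2.0 * d.size)))


def detect_dispersion(r2eff: pd.DataFrame,
                      threshold: float = DISPERSION_THRESHOLD
                      ) -> tuple[bool, float]:
    """Flag a dispersing methyl from its low- minus high-frequency rates.

    The dispersion amplitude is the mean R2_eff over the two lowest distinct
    frequencies minus the mean over the two highest; a methyl is flagged when
    the amplitude strictly exceeds ``threshold`` (default 2 1/s).
    """
    per_nu = r2eff.groupby("nu")["r2eff"].mean()   # duplicates averaged first
    if len(per_nu) < 5:
        raise ValueError("need at least 5 distinct nu values")
    per_nu = per_nu.sort_index()
    amplitude = float(per_nu.iloc[:2].mean() - per_nu.iloc[-2:].mean())
    return amplitude > threshold, amplitude


def _aicc(chi2: float, n: int, p: int) -> float:
    pen = 2.0 * p
    if n - p - 1 > 0:
        pen += 2.0 * p * (p + 1) / (n - p - 1)
    else:
        pen = np.inf
    return chi2 + pen


class TwoStateDispersion(RegressorMixin, BaseEstimator):
    """Weighted least-squares fit of the fast-exchange dispersion model.

    Fits ``R2_eff(nu) = r2_0 + (phi/kex) * (1 - tanh(kex/4nu)/(kex/4nu))``
    by multi-start optimization in ``(r2_0, ln kex, ln phi)`` space, together
    with the flat no-exchange model ``R2_eff = r2_0``; AICc is reported for
    both and the lower one (ties to the flat model) selects ``model_``.

    Attributes
    ----------
    r2_0_, kex_, phi_ : float
        Two-state parameter estimates.
    r2_0_flat_ : float
        Weighted mean of the flat model.
    aicc_two_state_, aicc_flat_ : float
    model_ : str
        ``"two-state-fast"`` or ``"no-exchange"``.
    rss_ : float
        Weighted residual sum of squares (chi-square) of the selected model.
    """

    def __init__(self, kex_starts: tuple[float, ...] = (200.0, 1000.0, 5000.0)):
        self.kex_starts = kex_starts

    def fit(self, X, y, sigma: float = 1.0):
        nu = np.asarray(X, dtype=float).reshape(-1)
        r2 = np.asarray(y, dtype=float).reshape(-1)
        if nu.size != r2.size:
            raise ValueError("X and y must have the same length")
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        n = nu.size
        if n < 4:
            raise ValueError("need more data points than the 3 parameters")
        if np.all(r2 < 0):
            raise ValueError("all R2_eff values negative; cannot fit")
        w = 1.0 / sigma

        # flat model: weighted mean (uniform weights here, one sigma/profile)
        r2_0_flat = float(np.mean(r2))
        chi2_flat = float(np.sum(((r2 - r2_0_flat) * w) ** 2))

        amp = max(float(np.max(r2) - np.min(r2)), 1e-3)
        r2_0_init = max(float(np.min(r2)), 1e-3)

        best = None
        for kex0 in self.kex_starts:
            theta0 = np.array([r2_0_init, np.log(kex0), np.log(amp * kex0)])

            def resid(th):
                return (dispersion_curve(nu, th[0], np.exp(th[1]),
                                         np.exp(th[2])) - r2) * w

            try:
                sol = optimize.least_squares(resid, theta0, method="lm",
                                             max_nfev=5000)
            except Exception:
                continue
            chi2 = float(2.0 * sol.cost)
            if best is None or chi2 < best[0]:
                best = (chi2, sol)

        if best is None:
            raise RuntimeError("two-state optimization failed from all starts")
        chi2_two, sol = best
        r2_0, kex, phi = float(sol.x[0]), float(np.exp(sol.x[1])), float(np.exp(sol.x[2]))

        self.r2_0_, self.kex_, self.phi_ = r2_0, kex, phi
        self.r2_0_flat_ = r2_0_flat
        self.chi2_two_state_ = chi2_two
        self.chi2_flat_ = chi2_flat
        self.aicc_two_state_ = _aicc(chi2_two, n, 3)
        self.aicc_flat_ = _aicc(chi2_flat, n, 1)
        self.model_ = ("no-exchange" if self.aicc_flat_ <= self.aicc_two_state_
                       else "two-state-fast")
        self.rss_ = chi2_flat if self.model_ == "no-exchange" else chi2_two
        self.sigma_ = float(sigma)

        # delta-method standard errors back on the (r2_0, kex, phi) scale
        try:
            cov_log = np.linalg.pinv(sol.jac.T @ sol.jac)
            scale = np.array([1.0, kex, phi])   # d(param)/d(theta)
            se = np.sqrt(np.clip(np.diag(cov_log), 0, None)) * scale
            self.r2_0_stderr_, self.kex_stderr_, self.phi_stderr_ = map(float, se)
        except np.linalg.LinAlgError:
            self.r2_0_stderr_ = self.kex_stderr_ = self.phi_stderr_ = np.nan
        return self

    def predict(self, X):
        nu = np.asarray(X, dtype=float).reshape(-1)
        if self.model_ == "no-exchange":
            return np.full_like(nu, self.r2_0_flat_)
        return dispersion_curve(nu, self.r2_0_, self.kex_, self.phi_)


def fit_two_state(profile: DispersionProfile, sigma: float | None = None,
                  **params) -> DispersionFit:
    """Fit one methyl's dispersion profile; wrapper over the estimator.

    ``sigma`` defaults to the duplicate-based pooled error (floored at a
    small positive value so noiseless synthetic profiles stay fittable).
    """
    table = compute_r2eff(profile)
    if sigma is None:
        sigma = max(estimate_errors(profile), 1e-6)
    dispersing, amplitude = detect_dispersion(table)
    est = TwoStateDispersion(**params).fit(table["nu"], table["r2eff"], sigma=sigma)
    return DispersionFit(
        methyl_id=profile.methyl_id, model=est.model_,
        r2_0=est.r2_0_, kex=est.kex_, phi=est.phi_,
        r2_0_stderr=est.r2_0_stderr_, kex_stderr=est.kex_stderr_,
        phi_stderr=est.phi_stderr_, rss=est.rss_,
        aicc_two_state=est.aicc_two_state_, aicc_flat=est.aicc_flat_,
        r2_0_flat=est.r2_0_flat_, dispersion_amplitude=amplitude,
        dispersing=dispersing, sigma=sigma)


def select_model(fit: DispersionFit | "TwoStateDispersion") -> str:
    """Minimum-AICc model label; ties resolve to the flat model."""
    flat = fit.aicc_flat if isinstance(fit, DispersionFit) else fit.aicc_flat_
    two = (fit.aicc_two_state if isinstance(fit, DispersionFit)
           else fit.aicc_two_state_)
    return "no-exchange" if flat <= two else "two-state-fast"
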