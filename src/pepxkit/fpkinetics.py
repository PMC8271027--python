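"""Fluorescence-polarization peptide-exchange kinetics.

Peptide association onto a peptide-receptive MHC-I molecule is monitored as a
rising fluorescence-polarization (FP) signal and modelled as a single
exponential::

    Y(t) = Y0 - A * exp(-K * t)

where ``Y0`` is the plateau (maximum) polarization, ``A`` the increased FP
range and ``K`` the observed association rate (reported as ``K_on``).  On top
of the per-trace fit this module provides the derived statistics used to
compare chaperone conditions:

* fold change        -- catalyzed ``K_on`` over uncatalyzed ``K_on``,
* relative activity  -- ``(K_mut - K_none) / (K_WT - K_none)`` for tapasin
  scoop-loop mutants, normalized so that the wild-type conjugate scores 1 and
  an inactive catalyst scores 0,
* Welch's unequal-variance t test for mutant-vs-WT comparisons,

together with replicate-level summaries (mean, SD, error-propagated SDs for
the ratio statistics).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "FPTrace",
    "KineticsFit",
    "FlatTraceError",
    "AssociationKinetics",
    "subtract_baseline",
    "fit_association",
    "fold_change",
    "relative_activity",
    "welch_t_test",
    "summarize_conditions",
]


class FlatTraceError(ValueError):
    """Raised when a trace shows no association signal above the noise."""


@dataclass
class FPTrace:
    """One well's polarization-vs-time series with condition metadata.

    Parameters
    ----------
    time : array of float
        Time in seconds, strictly increasing, at least 8 points.
    fp : array of float
        Polarization in arbitrary FP units.
    allotype, catalyst : str
        Condition labels, e.g. ``"A*03:01"`` and ``"Tsn-WT"`` (``"none"`` for
        the uncatalyzed reaction).
    replicate : int
        Replicate index within the condition.
    role : str
        ``"sample"`` or ``"baseline"`` (free-FITC-peptide well).
    baseline_subtracted : bool
        Whether a baseline has already been removed (dFP signal).
    """

    time: np.ndarray
    fp: np.ndarray
    allotype: str = ""
    catalyst: str = "none"
    replicate: int = 0
    role: str = "sample"
    baseline_subtracted: bool = False

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.fp = np.asarray(self.fp, dtype=float)
        if self.time.shape != self.fp.shape or self.time.ndim != 1:
            raise ValueError("time and fp must be 1-D arrays of equal length")
        if self.time.size < 8:
            raise ValueError("an FP trace needs at least 8 time points")
        if not (np.all(np.isfinite(self.time)) and np.all(np.isfinite(self.fp))):
            raise ValueError("FP trace contains non-finite values")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def condition(self) -> tuple[str, str, int]:
        return (self.allotype, self.catalyst, self.replicate)


@dataclass
class KineticsFit:
    """Result of fitting ``Y = Y0 - A exp(-K t)`` to one trace."""

    y0: float
    a: float
    k_on: float
    y0_stderr: float
    a_stderr: float
    k_on_stderr: float
    rss: float
    converged: bool
    n_points: int
    condition: tuple[str, str, int] = ("", "none", 0)
    message: str = ""


def _estimate_noise_sd(y: np.ndarray) -> float:
    """Robust noise estimate from successive differences (trend-insensitive)."""
    d = np.diff(y)
    if d.size == 0:
        return 0.0
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))


class AssociationKinetics(RegressorMixin, BaseEstimator):
    """Least-squares estimator for the exponential FP association model.

    Fits ``y = y0 - a * exp(-k * t)`` by multi-start Levenberg-Marquardt.
    The starting rate is ``k0 = ln 2 / t_half`` (first crossing of the
    half-range) refined from ``k0 * multi_start``; the start with the lowest
    residual sum of squares wins.

    Parameters
    ----------
    multi_start : tuple of float
        Multipliers applied to the data-driven initial rate.
    noise_factor : float
        A trace whose range is below ``noise_factor`` times the estimated
        noise SD is rejected as "no association detected".

    Attributes
    ----------
    y0_, a_, k_on_ : float
        Fitted plateau, amplitude and observed association rate (1/s).
    y0_stderr_, a_stderr_, k_on_stderr_ : float
        Asymptotic standard errors from the Jacobian at the optimum.
    rss_ : float
        Residual sum of squares.
    converged_ : bool
    """

    def __init__(self, multi_start: tuple[float, ...] = (0.1, 1.0, 10.0),
                 noise_factor: float = 3.0):
        self.multi_start = multi_start
        self.noise_factor = noise_factor

    @staticmethod
    def _model(t: np.ndarray, y0: float, a: float, k: float) -> np.ndarray:
        return y0 - a * np.exp(-k * t)

    def fit(self, X, y):
        """Fit the association model.

        Parameters
        ----------
        X : array-like of shape (n,) or (n, 1)
            Time in seconds.
        y : array-like of shape (n,)
            Baseline-subtracted polarization.
        """
        t = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if t.size != y.size:
            raise ValueError("X and y must have the same length")
        if t.size < 8:
            raise ValueError("need at least 8 points to fit three parameters")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite values in input")

        ymax, ymin = float(np.max(y)), float(np.min(y))
        noise = _estimate_noise_sd(y)
        if ymax - ymin < self.noise_factor * noise or ymax == ymin:
            raise FlatTraceError("no association detected")

        half = 0.5 * (ymax + ymin)
        above = np.nonzero(y >= half)[0]
        t_half = t[above[0]] if above.size and t[above[0]] > 0 else (
            t[-1] / 2 if t[-1] > 0 else 1.0)
        k0 = np.log(2.0) / t_half

        best = None
        for mult in self.multi_start:
            p0 = np.array([ymax, ymax - ymin, k0 * mult])

            def resid(p):
                return self._model(t, *p) - y

            try:
                sol = optimize.least_squares(
                    resid, p0,
                    bounds=([-np.inf, 0.0, 0.0], [np.inf, np.inf, np.inf]),
                    method="trf")
            except Exception:
                continue
            rss = float(2.0 * sol.cost)
            if best is None or rss < best[0]:
                best = (rss, sol)

        if best is None:
            self.converged_ = False
            self.y0_ = self.a_ = self.k_on_ = np.nan
            self.y0_stderr_ = self.a_stderr_ = self.k_on_stderr_ = np.nan
            self.rss_ = np.nan
            self.message_ = "all optimizer starts failed"
            return self

        rss, sol = best
        self.y0_, self.a_, self.k_on_ = map(float, sol.x)
        self.rss_ = rss
        self.converged_ = bool(sol.success and self.k_on_ > 0 and self.a_ > 0)
        self.message_ = sol.message
        self.n_points_ = t.size

        # asymptotic covariance: s^2 * (J^T J)^-1 with s^2 = rss / (n - p)
        dof = t.size - 3
        try:
            jtj_inv = np.linalg.pinv(sol.jac.T @ sol.jac)
            se = np.sqrt(np.clip(np.diag(jtj_inv), 0, None) * rss / max(dof, 1))
            self.y0_stderr_, self.a_stderr_, self.k_on_stderr_ = map(float, se)
        except np.linalg.LinAlgError:
            self.y0_stderr_ = self.a_stderr_ = self.k_on_stderr_ = np.nan
        return self

    def predict(self, X):
        t = np.asarray(X, dtype=float).reshape(-1)
        return self._model(t, self.y0_, self.a_, self.k_on_)


def subtract_baseline(trace: FPTrace, baseline: FPTrace,
                      mode: str = "constant") -> FPTrace:
    """Subtract the free-FITC-peptide background from a sample trace.

    ``mode="constant"`` (default) removes the mean of the baseline well, the
    convention for wells containing only the labelled peptide.
    ``mode="pointwise"`` subtracts point by point and requires a matching
    time grid.  ``mode="auto"`` subtracts pointwise when the grids match and
    falls back to the constant mode otherwise.
    """
    if mode not in ("constant", "pointwise", "auto"):
        raise ValueError(f"unknown baseline mode {mode!r}")
    grids_match = (trace.time.size == baseline.time.size
                   and np.allclose(trace.time, baseline.time))
    if mode == "pointwise" and not grids_match:
        raise ValueError("baseline time grid does not match the trace; "
                         "use mode='constant' to subtract its mean")
    if mode == "pointwise" or (mode == "auto" and grids_match):
        new_fp = trace.fp - baseline.fp
    else:
        new_fp = trace.fp - float(np.mean(baseline.fp))
    return replace(trace, fp=new_fp, baseline_subtracted=True)


def fit_association(trace: FPTrace, **params) -> KineticsFit:
    """Fit one FP trace; thin wrapper over :class:`AssociationKinetics`."""
    if not trace.baseline_subtracted:
        warnings.warn("fitting a trace that is not marked baseline-subtracted",
                      stacklevel=2)
    est = AssociationKinetics(**params).fit(trace.time, trace.fp)
    return KineticsFit(
        y0=est.y0_, a=est.a_, k_on=est.k_on_,
        y0_stderr=est.y0_stderr_, a_stderr=est.a_stderr_,
        k_on_stderr=est.k_on_stderr_, rss=est.rss_,
        converged=est.converged_, n_points=trace.time.size,
        condition=trace.condition, message=est.message_)


def fold_change(k_cat: float, k_uncat: float) -> float:
    """Catalyzed over uncatalyzed observed association rate."""
    if k_uncat <= 0:
        raise ValueError("uncatalyzed rate must be positive")
    if k_cat <= 0:
        raise ValueError("catalyzed rate must be positive")
    return k_cat / k_uncat


def relative_activity(k_mut: float, k_wt: float, k_none: float) -> float:
    """Mutant catalytic activity normalized to wild type.

    ``(K_mut - K_none) / (K_WT - K_none)``; 1 for WT-like, 0 for inactive.
    The value is reported unclamped and may fall outside [0, 1].
    """
    denom = k_wt - k_none
    if denom == 0:
        raise ValueError("k_wt equals k_none: relative activity undefined")
    return (k_mut - k_none) / denom


def welch_t_test(group_a: Sequence[float],
                 group_b: Sequence[float]) -> tuple[float, float, float]:
    """Two-sample unequal-variance (Welch) t test, two-sided.

    Returns ``(t, dof, p)`` with the Welch-Satterthwaite degrees of freedom.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("both groups have zero variance")
    sa, sb = va / a.size, vb / b.size
    t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
    dof = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    p = 2.0 * stats.t.sf(abs(t), dof)
    return float(t), float(dof), float(p)


def summarize_conditions(fits: Sequence[KineticsFit],
                         wt_catalyst: str = "Tsn-WT") -> pd.DataFrame:
    """Aggregate per-trace fits into per-condition exchange statistics.

    For every (allotype, catalyst) group: mean and SD of ``k_on`` over
    replicates; fold change versus the matching uncatalyzed ("none")
    condition with a first-order error-propagated SD; where the allotype has
    a ``wt_catalyst`` condition, the relative activity of every other
    catalyst versus WT plus a Welch t test of the replicate rates against the
    WT replicates.

    Raises if any catalyzed condition lacks a matching "none" condition.
    """
    rows = [{"allotype": f.condition[0], "catalyst": f.condition[1],
             "replicate": f.condition[2], "k_on": f.k_on}
            for f in fits if f.converged]
    if not rows:
        raise ValueError("no converged fits to summarize")
    df = pd.DataFrame(rows)

    out = []
    for (allo, cat), grp in df.groupby(["allotype", "catalyst"], sort=True):
        k = grp["k_on"].to_numpy()
        rec = {"allotype": allo, "catalyst": cat, "n": k.size,
               "k_on_mean": k.mean(),
               "k_on_sd": k.std(ddof=1) if k.size >= 2 else np.nan}
        out.append(rec)
    summary = pd.DataFrame(out)

    def _group(allo, cat):
        sel = df[(df["allotype"] == allo) & (df["catalyst"] == cat)]
        return sel["k_on"].to_numpy()

    fc, fc_sd, ra, ra_sd, tstat, tdof, tp = [], [], [], [], [], [], []
    for _, rec in summary.iterrows():
        allo, cat = rec["allotype"], rec["catalyst"]
        k_none = _group(allo, "none")
        if k_none.size == 0:
            raise ValueError(f"no uncatalyzed ('none') condition for {allo}")
        m_none, s_none = k_none.mean(), (k_none.std(ddof=1)
                                         if k_none.size >= 2 else np.nan)
        m_cat = rec["k_on_mean"]
        s_cat = rec["k_on_sd"]
        f = fold_change(m_cat, m_none)
        fc.append(f)
        # first-order propagation from the two replicate SDs
        with np.errstate(invalid="ignore"):
            fc_sd.append(abs(f) * np.sqrt((s_cat / m_cat) ** 2
                                          + (s_none / m_none) ** 2))

        k_wt = _group(allo, wt_catalyst)
        if k_wt.size and cat not in ("none",):
            m_wt = k_wt.mean()
            s_wt = k_wt.std(ddof=1) if k_wt.size >= 2 else np.nan
            r = relative_activity(m_cat, m_wt, m_none)
            ra.append(r)
            denom = m_wt - m_none
            with np.errstate(invalid="ignore"):
                var = ((s_cat**2 + s_none**2) / denom**2
                       + r**2 * (s_wt**2 + s_none**2) / denom**2)
            ra_sd.append(np.sqrt(var))
            if cat != wt_catalyst and k_wt.size >= 2 and _group(allo, cat).size >= 2:
                t, d, p = welch_t_test(_group(allo, cat), k_wt)
                tstat.append(t); tdof.append(d); tp.append(p)
            else:
                tstat.append(np.nan); tdof.append(np.nan); tp.append(np.nan)
        else:
            ra.append(np.nan); ra_sd.append(np.nan)
            tstat.append(np.nan); tdof.append(np.nan); tp.append(np.nan)

    summary["fold_change"] = fc
    summary["fold_change_sd"] = fc_sd
    summary["relative_activity"] = ra
    summary["relative_activity_sd"] = ra_sd
    summary["t_statistic"] = tstat
    summary["dof"] = tdof
    summary["p_value"] = tp
    return summary
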