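"""IRF-free exponential tail fitting of MCR-resolved pure decay traces.

The pure traces delivered by curve resolution still carry the instrument
rise; the classical follow-up is to drop the channels up to (and just
past) the maximum and fit the remaining tail with the minimum number of
exponential terms, ignoring the IRF entirely.  Model order is chosen as
the smallest term count with R^2 > 0.999 whose every lifetime passes a
t-test (|tau| / SE(tau) above the two-sided critical value).

Ignoring the IRF biases components comparable to the IRF width
(sub-100 ps) toward longer apparent lifetimes; the bias is inherent to
the procedure and documented, not corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .axes import TimeAxis

__all__ = ["trim_trace", "TailFit", "TailFitResults", "tail_fit"]

R2_THRESHOLD = 0.999


def trim_trace(
    values: np.ndarray, axis: TimeAxis, offset: int = 2
) -> tuple[np.ndarray, np.ndarray, int]:
    """Drop channels up to and including the maximum, plus ``offset`` more.

    Returns ``(trimmed_values, times, trim_count)`` with the time axis
    re-origined at the first kept bin.

    Raises
    ------
    ValueError
        If the vector never decays (monotone increasing).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("need a 1-D vector of length >= 2")
    if np.all(np.diff(v) >= 0):
        raise ValueError("monotone-increasing vector: no decay to fit")
    peak = int(np.argmax(v))
    first = peak + 1 + offset
    if first >= v.size - 2:
        raise ValueError("trim leaves fewer than 3 channels")
    trimmed = v[first:]
    t = (np.arange(trimmed.size)) * axis.bin_width
    return trimmed, t, first


@dataclass
class TailFitResults:
    """Selected tail-fit model with per-term significance."""

    lifetimes: np.ndarray
    lifetime_se: np.ndarray
    amplitudes: np.ndarray
    fractional_amplitudes: np.ndarray   # %, sums to 100
    r2_fit: float
    n_terms: int
    trim: int
    term_tstats: np.ndarray
    term_accepted: np.ndarray
    satisfied: bool
    r2_by_order: dict[int, float]

    def summary(self) -> str:
        table = pd.DataFrame(
            {
                "tau_ns": self.lifetimes,
                "se_ns": self.lifetime_se,
                "%amplitude": self.fractional_amplitudes,
                "t_stat": self.term_tstats,
                "significant": self.term_accepted,
            }
        ).to_string(index=False, float_format="%.4g")
        head = (
            f"tail fit: {self.n_terms} terms, R2 = {self.r2_fit:.6f}, "
            f"trimmed {self.trim} channels"
            + ("" if self.satisfied else "  (selection criteria NOT satisfied)")
        )
        return head + "\n" + table


class TailFit:
    """Minimal sum-of-exponentials model of a trimmed pure decay trace."""

    def __init__(
        self,
        trace: np.ndarray,
        axis: TimeAxis,
        max_terms: int = 4,
        alpha: float = 0.05,
        trim_offset: int = 2,
    ) -> None:
        if max_terms > 4:
            raise ValueError("max_terms is capped at 4")
        self.values, self.t, self.trim = trim_trace(trace, axis, trim_offset)
        self.max_terms = max_terms
        self.alpha = alpha
        self.axis = axis

    def _fit_order(self, m: int):
        y = self.values
        t = self.t
        span = t[-1] if t[-1] > 0 else 1.0
        tau0 = np.geomspace(max(2 * self.axis.bin_width, span / 200), span / 2, m)
        p0 = np.concatenate([np.log(tau0), np.full(m, max(y.max(), 1e-12) / m)])

        def resid(p):
            tau = np.exp(p[:m])
            a = p[m:]
            return (a[None, :] * np.exp(-t[:, None] / tau[None, :])).sum(axis=1) - y

        sol = least_squares(resid, p0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
        tau = np.exp(sol.x[:m])
        a = sol.x[m:]
        ss_res = float(np.sum(sol.fun**2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot

        # Gauss-Newton covariance; SE(tau) via the log-parameter delta rule
        dof = max(y.size - sol.x.size, 1)
        jtj = sol.jac.T @ sol.jac
        sigma2 = ss_res / dof
        cov = np.linalg.pinv(jtj) * sigma2
        se_log_tau = np.sqrt(np.maximum(np.diag(cov)[:m], 0.0))
        se_tau = tau * se_log_tau
        with np.errstate(divide="ignore"):
            tstat = np.where(se_tau > 0, tau / se_tau, np.inf)
        tcrit = stats.t.ppf(1.0 - self.alpha / 2.0, dof)
        accepted = tstat > tcrit
        order = np.argsort(-tau)
        return (tau[order], se_tau[order], np.maximum(a[order], 0.0), r2,
                tstat[order], accepted[order])

    @staticmethod
    def _well_formed(tau: np.ndarray, a: np.ndarray) -> bool:
        """Reject over-parameterised fits: near-duplicate lifetimes
        (neighbour ratio < 1.2) or terms carrying < 0.1% of the amplitude."""
        srt = np.sort(tau)
        if np.any(srt[1:] / srt[:-1] < 1.2):
            return False
        total = a.sum()
        return total > 0 and bool(np.all(a / total >= 1e-3))

    def fit(self) -> TailFitResults:
        r2_by_order: dict[int, float] = {}
        best = None
        best_formed = None
        for m in range(1, self.max_terms + 1):
            tau, se, a, r2, tstat, accepted = self._fit_order(m)
            r2_by_order[m] = r2
            candidate = (tau, se, a, r2, tstat, accepted, m)
            if best is None or r2 > best[3]:
                best = candidate
            formed = self._well_formed(tau, a)
            if formed and (best_formed is None or r2 > best_formed[3]):
                best_formed = candidate
            if r2 > R2_THRESHOLD and bool(np.all(accepted)) and formed:
                return self._package(candidate, satisfied=True, r2_by_order=r2_by_order)
        return self._package(best_formed or best, satisfied=False,
                             r2_by_order=r2_by_order)

    def _package(self, cand, satisfied: bool, r2_by_order) -> TailFitResults:
        tau, se, a, r2, tstat, accepted, m = cand
        total = a.sum()
        frac = 100.0 * a / total if total > 0 else np.full(m, np.nan)
        return TailFitResults(
            lifetimes=tau,
            lifetime_se=se,
            amplitudes=a,
            fractional_amplitudes=frac,
            r2_fit=r2,
            n_terms=m,
            trim=self.trim,
            term_tstats=tstat,
            term_accepted=accepted,
            satisfied=satisfied,
            r2_by_order=r2_by_order,
        )


def tail_fit(
    pure_trace: np.ndarray,
    axis: TimeAxis,
    max_terms: int = 4,
    alpha: float = 0.05,
    trim_offset: int = 2,
) -> TailFitResults:
    """Functional wrapper: ``TailFit(trace, axis, ...).fit()``."""
    return TailFit(pure_trace, axis, max_terms, alpha, trim_offset).fit()
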