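"""EXP and BAR free-energy estimators for bidirectional work samples.

Both estimators operate in kcal/mol and use log-sum-exp formulations
throughout, so no intermediate exponential can overflow.  Backward-direction
estimates are sign-corrected to the forward (lambda_a -> lambda_b) convention
so that forward, backward, and BAR values are directly comparable.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from lipidflux.constants import rt_kcal
from lipidflux.errors import DataError, ParameterError
from lipidflux.fep.diagnostics import decorrelate_series
from lipidflux.fep.models import DeltaGEstimate, FepSeries, FepWindow

#: Fermi-weight effective sample size below which overlap is considered poor.
MIN_OVERLAP_ESS = 10.0


def _exp_core(work: np.ndarray, rt: float) -> tuple[float, float, float]:
    """Zwanzig estimate -RT*log<exp(-W/RT)>, its error, and the weight ESS."""
    n = len(work)
    logw = -work / rt
    lse = logsumexp(logw)
    dg = -rt * (lse - np.log(n))
    # normalized importance weights for ESS and a delta-method error estimate
    w = np.exp(logw - lse)
    ess = 1.0 / np.sum(w**2)
    if n > 1:
        # var of the log-mean via the delta method on the weight sum:
        # Var(W)/mean(W)^2 expressed through the normalized weights
        rel_var = n**2 * np.sum((w - 1.0 / n) ** 2) / (n - 1)
        err = rt * np.sqrt(rel_var / n)
    else:
        err = 0.0
    return float(dg), float(err), float(ess)


def exp_estimate(
    window: FepWindow, direction: str = "forward", decorrelate: bool = False
) -> DeltaGEstimate:
    """Exponential-averaging estimate for one direction of a window."""
    if direction not in ("forward", "backward"):
        raise ParameterError(f"direction must be 'forward' or 'backward', got {direction!r}")
    work = window.forward_work if direction == "forward" else window.backward_work
    if len(work) == 0:
        raise DataError(f"no {direction} samples in window ({window.lambda_a}, {window.lambda_b})")
    if decorrelate:
        work = decorrelate_series(work)
    rt = rt_kcal(window.temperature)
    dg, err, ess = _exp_core(np.asarray(work, dtype=float), rt)
    if direction == "backward":
        dg = -dg  # sign-correct the b->a estimate to the forward convention
    return DeltaGEstimate(
        value=dg,
        stat_error=err,
        method=f"EXP_{direction}",
        n_effective=ess,
        overlap_warning=ess < MIN_OVERLAP_ESS,
    )


def _bar_zero(x_reduced: float, uf: np.ndarray, ub: np.ndarray, m: float) -> float:
    # log sum_F sigmoid(-(M + uF - x)) - log sum_R sigmoid(-(-M + uR + x))
    lf = logsumexp(-np.logaddexp(0.0, m + uf - x_reduced))
    lr = logsumexp(-np.logaddexp(0.0, -m + ub + x_reduced))
    return lf - lr


def bar_estimate(window: FepWindow, decorrelate: bool = False) -> DeltaGEstimate:
    """Bennett acceptance ratio estimate for one window.

    Solves the BAR self-consistency condition (logistic-weighted sums over
    both directions with the log(n_F/n_R) offset) by Brent bracketing on
    [min work - 50, max work + 50] to 1e-8 kcal/mol.  The statistical error
    comes from the asymptotic variance expression; when the Fermi-weight
    effective sample size falls below 10 in either direction the estimate is
    still returned but flagged with an overlap warning.
    """
    fwd = np.asarray(window.forward_work, dtype=float)
    bwd = np.asarray(window.backward_work, dtype=float)
    if len(fwd) == 0 or len(bwd) == 0:
        raise DataError(
            f"BAR needs samples in both directions for window "
            f"({window.lambda_a}, {window.lambda_b})"
        )
    if decorrelate:
        fwd = decorrelate_series(fwd)
        bwd = decorrelate_series(bwd)
    rt = rt_kcal(window.temperature)
    uf = fwd / rt
    ub = bwd / rt
    m = np.log(len(uf) / len(ub))

    lo = min(fwd.min(), (-bwd).max(), (-bwd).min()) - 50.0
    hi = max(fwd.max(), (-bwd).max(), (-bwd).min()) + 50.0
    dg = brentq(lambda x: _bar_zero(x / rt, uf, ub, m), lo, hi, xtol=1e-8)

    x = dg / rt
    f_f = 1.0 / (1.0 + np.exp(np.clip(m + uf - x, -700, 700)))
    f_r = 1.0 / (1.0 + np.exp(np.clip(-m + ub + x, -700, 700)))
    ess_f = float(np.sum(f_f) ** 2 / np.sum(f_f**2)) if np.any(f_f) else 0.0
    ess_r = float(np.sum(f_r) ** 2 / np.sum(f_r**2)) if np.any(f_r) else 0.0
    var = 0.0
    if len(uf) > 1 and np.mean(f_f) > 0:
        var += (np.mean(f_f**2) / np.mean(f_f) ** 2 - 1.0) / len(uf)
    if len(ub) > 1 and np.mean(f_r) > 0:
        var += (np.mean(f_r**2) / np.mean(f_r) ** 2 - 1.0) / len(ub)
    err = rt * np.sqrt(max(var, 0.0))

    overlap = min(ess_f, ess_r) < MIN_OVERLAP_ESS
    if overlap and err < rt:
        err = max(err, rt)  # inflate: asymptotic variance is unreliable here
    return DeltaGEstimate(
        value=float(dg),
        stat_error=float(err),
        method="BAR",
        n_effective=min(ess_f, ess_r),
        overlap_warning=overlap,
    )


def accumulate(
    series: FepSeries, decorrelate: bool = True
) -> tuple[DeltaGEstimate, np.ndarray, np.ndarray]:
    """Accumulated BAR over a contiguous series.

    Returns the total estimate (errors combined in quadrature), the lambda
    boundaries, and the cumulative free-energy profile at those boundaries
    (starting at 0).
    """
    series.validate_coverage()
    values, variances = [], []
    warn = False
    for w in series.windows:
        est = bar_estimate(w, decorrelate=decorrelate)
        values.append(est.value)
        variances.append(est.stat_error**2)
        warn = warn or est.overlap_warning
    values = np.asarray(values)
    lambdas = np.array([series.windows[0].lambda_a] + [w.lambda_b for w in series.windows])
    profile = np.concatenate([[0.0], np.cumsum(values)])
    total = DeltaGEstimate(
        value=float(values.sum()),
        stat_error=float(np.sqrt(np.sum(variances))),
        method="BAR",
        n_effective=float(sum(len(w.forward_work) for w in series.windows)),
        overlap_warning=warn,
    )
    return total, lambdas, profile


def aggregate_replicas(estimates: list[DeltaGEstimate]) -> DeltaGEstimate:
    """Aggregate replica totals: mean value, SEM error (n >= 2).

    With a single replica the value and its carried-through estimator error
    pass straight through, with the mode recorded in ``method``.
    """
    if not estimates:
        raise ParameterError("no replica estimates supplied")
    values = np.array([e.value for e in estimates])
    if len(estimates) == 1:
        e = estimates[0]
        return DeltaGEstimate(
            value=e.value,
            stat_error=e.stat_error,
            method=f"single_replica({e.method})",
            n_effective=e.n_effective,
            overlap_warning=e.overlap_warning,
        )
    sem = float(np.std(values, ddof=1) / np.sqrt(len(values)))
    return DeltaGEstimate(
        value=float(values.mean()),
        stat_error=sem,
        method="replica_mean",
        n_effective=float(len(values)),
        overlap_warning=any(e.overlap_warning for e in estimates),
    )
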