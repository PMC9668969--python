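"""Fitting operations for stopped-flow flux kinetics.

The chain is: quench trace -> stretched-exponential fit over an early window
-> instantaneous flux rate at a fixed evaluation time (default 2 ms) ->
per-delay time course -> biexponential desensitization fit with a weighted
time constant -> Hill dose-response of peak rates.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

import numpy as np
from scipy.optimize import least_squares

from lipidflux.errors import FitError, ParameterError
from lipidflux.kinetics.models import (
    DecayFit,
    FluxRate,
    HillFit,
    QuenchTrace,
    StretchedExpFit,
    TimeCourse,
    stretched_exp,
)

BETA_BOUNDS = (0.05, 1.5)
TAU_BOUNDS = (1e-5, 1e3)


def fit_stretched_exp(
    trace: QuenchTrace, window: tuple[float, float] = (0.0, 0.1)
) -> StretchedExpFit:
    """Nonlinear least-squares stretched-exponential fit over ``window``.

    Initialization: F0 = first sample, Finf = mean of last 5% of the window,
    tau = time to reach 1/e of the amplitude, beta = 0.9.
    """
    lo, hi = window
    mask = (trace.time >= lo) & (trace.time <= hi)
    t = trace.time[mask]
    f = trace.fluorescence[mask]
    if len(t) < 10:
        raise FitError(
            f"need at least 10 points inside window {window}, got {len(t)}"
        )

    f0_init = float(f[0])
    n_tail = max(1, int(0.05 * len(f)))
    finf_init = float(f[-n_tail:].mean())
    amp = f0_init - finf_init
    if amp > 0:
        target = finf_init + amp / np.e
        below = np.nonzero(f <= target)[0]
        tau_init = float(t[below[0]]) if len(below) and t[below[0]] > 0 else (hi - lo) / 3
    else:
        tau_init = (hi - lo) / 3
    tau_init = float(np.clip(tau_init, *TAU_BOUNDS))
    beta_init = 0.9

    def residuals(p: np.ndarray) -> np.ndarray:
        return stretched_exp(t, p[0], p[1], p[2], p[3]) - f

    lower = [-np.inf, -np.inf, TAU_BOUNDS[0], BETA_BOUNDS[0]]
    upper = [np.inf, np.inf, TAU_BOUNDS[1], BETA_BOUNDS[1]]
    x0 = np.clip([f0_init, finf_init, tau_init, beta_init], lower, upper)
    res = least_squares(residuals, x0, bounds=(lower, upper), method="trf")
    F0, Finf, tau, beta = res.x
    return StretchedExpFit(
        F0=float(F0),
        Finf=float(Finf),
        tau=float(tau),
        beta=float(beta),
        rss=float(np.sum(res.fun**2)),
        window=(lo, hi),
        converged=bool(res.status > 0),
        n_points=len(t),
    )


def flux_rate(fit: StretchedExpFit, t_eval: float = 0.002) -> FluxRate:
    """Instantaneous quench rate k = (beta/tau) * (t_eval/tau)^(beta-1).

    This is the time derivative of (t/tau)^beta evaluated at ``t_eval`` and is
    invariant to rescaling of the fluorescence axis.
    """
    if fit.tau <= 0:
        raise ParameterError(f"tau must be positive, got {fit.tau}")
    if t_eval <= 0:
        raise ParameterError(f"t_eval must be positive, got {t_eval}")
    k = (fit.beta / fit.tau) * (t_eval / fit.tau) ** (fit.beta - 1.0)
    return FluxRate(k=float(k), t_eval=t_eval)


def weighted_tau(A1: float, tau1: float, A2: float, tau2: float) -> float:
    """Amplitude-weighted time constant (A1*tau1 + A2*tau2) / (A1 + A2)."""
    if A1 + A2 <= 0:
        raise ParameterError("at least one amplitude must be positive")
    if tau1 <= 0 or tau2 <= 0:
        raise ParameterError("time constants must be positive")
    return (A1 * tau1 + A2 * tau2) / (A1 + A2)


def _exp_model(d: np.ndarray, params: np.ndarray, n_comp: int) -> np.ndarray:
    out = np.zeros_like(d)
    for i in range(n_comp):
        out += params[2 * i] * np.exp(-d / params[2 * i + 1])
    return out


def fit_decay(
    delays: np.ndarray,
    rates: np.ndarray,
    model: str = "double",
    sem: np.ndarray | None = None,
) -> DecayFit:
    """Least-squares single or double exponential decay fit of rate vs delay.

    Components are ordered by tau ascending (ties broken by amplitude
    descending); for the double model the weighted time constant is the
    amplitude-weighted mean of the two taus.  When per-point SEMs are
    supplied (all positive) the fit is inverse-variance weighted.  Component
    taus are bounded above by 10x the delay span: slower components are not
    identifiable from the data and would otherwise absorb the noise floor.
    """
    if model not in ("single", "double"):
        raise ParameterError(f"model must be 'single' or 'double', got {model!r}")
    d = np.asarray(delays, dtype=float)
    r = np.asarray(rates, dtype=float)
    n_comp = 1 if model == "single" else 2
    n_free = 2 * n_comp
    if len(d) < n_free:
        raise FitError(
            f"{model} decay fit needs at least {n_free} points, got {len(d)}"
        )
    scale = max(abs(r.max()), abs(r.min()), 1e-300)
    if np.ptp(r) < 1e-10 * scale:
        raise FitError("constant data: zero-amplitude decay cannot be fit")

    w = np.ones_like(r)
    if sem is not None:
        sem = np.asarray(sem, dtype=float)
        if sem.shape == r.shape and np.all(sem > 0):
            w = 1.0 / sem

    span = d.max() - d.min()
    tau_max = 10.0 * span
    amp0 = float(r.max())
    if n_comp == 1:
        x0 = [amp0, span / 3]
    else:
        x0 = [0.6 * amp0, span / 10, 0.4 * amp0, span]
    lower = [0.0, 1e-9] * n_comp
    upper = [np.inf, tau_max] * n_comp

    def residuals(p: np.ndarray) -> np.ndarray:
        return w * (_exp_model(d, p, n_comp) - r)

    res = least_squares(residuals, np.clip(x0, lower, upper), bounds=(lower, upper))
    comps = [(float(res.x[2 * i]), float(res.x[2 * i + 1])) for i in range(n_comp)]
    comps.sort(key=lambda c: (c[1], -c[0]))
    if n_comp == 1:
        wt = comps[0][1]
    else:
        (A1, t1), (A2, t2) = comps
        wt = weighted_tau(A1, t1, A2, t2)
    return DecayFit(
        components=comps,
        weighted_tau=float(wt),
        model=model,
        rss=float(np.sum(res.fun**2)),
        converged=bool(res.status > 0),
    )


def _flatten(traces) -> list[QuenchTrace]:
    if isinstance(traces, Mapping):
        return [t for group in traces.values() for t in group]
    return list(traces)


def build_time_course(
    traces: Iterable[QuenchTrace] | Mapping[float, list[QuenchTrace]],
    window: tuple[float, float] = (0.0, 0.1),
    t_eval: float = 0.002,
    control: QuenchTrace | None = None,
    fit_desensitization: bool = True,
    decay_model: str = "double",
) -> TimeCourse:
    """Assemble per-delay mean +/- SEM flux rates from replicate traces.

    A no-agonist ``control`` trace, when supplied, has its rate subtracted
    from every point (and the subtraction is recorded).  Desensitization is
    fit on the delays at and after the peak.
    """
    flat = _flatten(traces)
    if not flat:
        raise ParameterError("no traces supplied")
    if any(t.delay_time is None for t in flat):
        raise ParameterError("every trace must carry a delay time")
    concs = {t.agonist_conc for t in flat}
    if len(concs) > 1:
        raise ParameterError(
            f"mixed agonist concentrations {sorted(map(str, concs))}; "
            "group traces by concentration before building a time course"
        )

    background = None
    if control is not None:
        background = flux_rate(fit_stretched_exp(control, window), t_eval).k

    groups: dict[float, list[float]] = {}
    for tr in flat:
        k = flux_rate(fit_stretched_exp(tr, window), t_eval).k
        if background is not None:
            k -= background
        groups.setdefault(float(tr.delay_time), []).append(k)

    delays = np.array(sorted(groups))
    means = np.array([np.mean(groups[d]) for d in delays])
    sems = np.array(
        [
            np.std(groups[d], ddof=1) / np.sqrt(len(groups[d]))
            if len(groups[d]) > 1
            else 0.0
            for d in delays
        ]
    )
    ns = np.array([len(groups[d]) for d in delays])

    peak_idx = int(np.argmax(means))
    desens = None
    if fit_desensitization:
        post = slice(peak_idx, None)
        n_free = 2 if decay_model == "single" else 4
        if len(delays[post]) < 2 * n_free:
            raise FitError(
                f"desensitization fit needs at least {2 * n_free} delays at/after "
                f"the peak, got {len(delays[post])}; pass fit_desensitization=False "
                "to skip"
            )
        sems_post = sems[post] if np.all(sems[post] > 0) else None
        desens = fit_decay(delays[post], means[post], model=decay_model, sem=sems_post)

    return TimeCourse(
        delays=delays,
        mean_rate=means,
        sem=sems,
        n=ns,
        peak_rate=float(means.max()),
        desensitization=desens,
        background_rate=background,
    )


def normalize_time_course(tc: TimeCourse) -> TimeCourse:
    """Scale rates so the peak equals exactly 1; SEMs scale identically."""
    if tc.peak_rate <= 0:
        raise ParameterError(f"peak rate must be positive, got {tc.peak_rate}")
    s = 1.0 / tc.peak_rate
    return TimeCourse(
        delays=tc.delays.copy(),
        mean_rate=tc.mean_rate * s,
        sem=tc.sem * s,
        n=tc.n.copy(),
        peak_rate=1.0,
        desensitization=tc.desensitization,
        background_rate=tc.background_rate,
    )


def fit_hill(
    concentrations: np.ndarray,
    responses: np.ndarray,
    fix_bottom: bool = True,
) -> HillFit:
    """Hill fit (logistic in log-concentration), bottom pinned to 0 by default."""
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(responses, dtype=float)
    if len(c) != len(r):
        raise ParameterError("concentrations and responses must have equal length")
    if len(c) < 4:
        raise FitError(f"need at least 4 concentrations, got {len(c)}")
    scale = max(abs(r).max(), 1e-300)
    flat = np.ptp(r) < 1e-3 * scale

    top0 = float(r.max())
    half = top0 / 2.0
    above = np.nonzero(r >= half)[0]
    ec50_0 = float(c[above[0]]) if len(above) and c[above[0]] > 0 else float(np.median(c[c > 0]))

    def model(p: np.ndarray) -> np.ndarray:
        log_ec50, n, top = p[0], p[1], p[2]
        bottom = 0.0 if fix_bottom else p[3]
        ec50 = np.exp(log_ec50)
        with np.errstate(divide="ignore", invalid="ignore"):
            cn = np.where(c > 0, c**n, 0.0)
        return bottom + (top - bottom) * cn / (cn + ec50**n)

    x0 = [np.log(ec50_0), 1.0, top0] + ([float(r.min())] if not fix_bottom else [])
    res = least_squares(lambda p: model(p) - r, x0)
    ec50 = float(np.exp(res.x[0]))
    return HillFit(
        ec50=ec50,
        hill_n=float(res.x[1]),
        top=float(res.x[2]),
        bottom=0.0 if fix_bottom else float(res.x[3]),
        rss=float(np.sum(res.fun**2)),
        converged=bool(res.status > 0) and not flat,
    )
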