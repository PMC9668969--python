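"""Synthetic fluorescence quenching traces and agonist-delay series.

The generating model for a single trace is the stretched exponential

    F(t) = Finf + (F0 - Finf) * exp(-(t/tau)^beta)

with optional additive i.i.d. Gaussian noise.  A delay series emulates the
sequential-mixing protocol: proteoliposomes are mixed with agonist, then with
quencher after a variable delay, so the true flux rate as a function of delay
follows an activation rise multiplied by a biexponential desensitization
decay, normalized so its maximum over the delay grid equals ``peak_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from lipidflux.errors import ParameterError
from lipidflux.kinetics.models import QuenchTrace, stretched_exp

# Per-generator stream tags: adding traces from one generator never perturbs
# the stream of another generator run with the same user seed.
_STREAM_TRACE = 101
_STREAM_DELAY = 102


@dataclass
class TraceParams:
    """Ground-truth parameters for one synthetic quenching trace."""

    F0: float = 1.0
    Finf: float = 0.1
    tau: float = 0.05
    beta: float = 0.85
    noise_sd: float = 0.0
    n_points: int = 500
    duration: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.tau <= 0:
            raise ParameterError(f"tau must be positive, got {self.tau}")
        if not (0 < self.beta <= 1.5):
            raise ParameterError(f"beta must be in (0, 1.5], got {self.beta}")
        if self.noise_sd < 0:
            raise ParameterError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.n_points < 2:
            raise ParameterError(f"n_points must be >= 2, got {self.n_points}")
        if self.duration <= 0:
            raise ParameterError(f"duration must be positive, got {self.duration}")
        if self.F0 < self.Finf:
            raise ParameterError(
                f"F0 must be >= Finf for a quenching trace, got F0={self.F0} < Finf={self.Finf}"
            )


def gen_quench_trace(
    params: TraceParams,
    *,
    delay_time: float | None = None,
    agonist_conc: float | None = None,
    label: str = "",
    _spawn_key: tuple[int, ...] = (),
) -> QuenchTrace:
    """Generate a quenching trace from ``params``.

    At ``noise_sd = 0`` every sample equals the stretched exponential exactly;
    with noise, additive i.i.d. Gaussian deviates are drawn from a stream
    fully determined by ``params.seed``.
    """
    params.validate()
    t = np.linspace(0.0, params.duration, params.n_points)
    f = stretched_exp(t, params.F0, params.Finf, params.tau, params.beta)
    if params.noise_sd > 0:
        rng = np.random.default_rng((_STREAM_TRACE, params.seed, *_spawn_key))
        f = f + rng.normal(0.0, params.noise_sd, size=f.shape)
    return QuenchTrace(
        time=t,
        fluorescence=f,
        delay_time=delay_time,
        agonist_conc=agonist_conc,
        label=label,
    )


def _default_delays() -> list[float]:
    # protocol span: 10 ms to 25 s, log-spaced
    return list(np.geomspace(0.010, 25.0, 12))


@dataclass
class GatingScenario:
    """Ground truth for an activation/desensitization delay series.

    The true flux rate at delay d is::

        rate(d) = peak_rate * act(d) * (A1*exp(-d/tau1) + A2*exp(-d/tau2)) / max

    where act(d) = 1 - exp(-d/activation_tau) and ``max`` normalizes the
    product over the delay grid so the grid maximum equals ``peak_rate``.
    """

    peak_rate: float = 20.0
    activation_tau: float = 0.003
    A1: float = 0.7
    A2: float = 0.3
    tau1: float = 2.0
    tau2: float = 20.0
    delay_times: list[float] = field(default_factory=_default_delays)
    replicates: int = 5
    seed: int = 0
    # trace-shape configuration (not part of the kinetic ground truth)
    beta: float = 0.85
    F0: float = 1.0
    Finf: float = 0.1
    noise_sd: float = 0.0
    n_points: int = 500
    duration: float = 1.0
    agonist_conc: float = 10.0

    def validate(self) -> None:
        if not self.delay_times:
            raise ParameterError("delay_times must be non-empty")
        if any(d <= 0 for d in self.delay_times):
            raise ParameterError("delay times must be positive")
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ParameterError("desensitization taus must be positive")
        if abs(self.A1 + self.A2 - 1.0) > 1e-9:
            raise ParameterError(
                f"amplitude fractions must sum to 1, got A1+A2={self.A1 + self.A2}"
            )
        if self.A1 < 0 or self.A2 < 0:
            raise ParameterError("amplitude fractions must be non-negative")
        if self.peak_rate <= 0:
            raise ParameterError(f"peak_rate must be positive, got {self.peak_rate}")
        if self.replicates < 1:
            raise ParameterError(f"replicates must be >= 1, got {self.replicates}")


def true_delay_rates(scenario: GatingScenario) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth flux rate at each delay of the scenario grid."""
    scenario.validate()
    d = np.asarray(sorted(scenario.delay_times), dtype=float)
    if scenario.activation_tau > 0:
        act = 1.0 - np.exp(-d / scenario.activation_tau)
    else:
        act = np.ones_like(d)
    des = scenario.A1 * np.exp(-d / scenario.tau1) + scenario.A2 * np.exp(-d / scenario.tau2)
    raw = act * des
    rates = scenario.peak_rate * raw / raw.max()
    return d, rates


def tau_for_rate(k: float, beta: float, t_ref: float = 0.002) -> float:
    """Invert k = (beta/tau) * (t_ref/tau)^(beta-1) for tau."""
    if k <= 0:
        raise ParameterError(f"rate must be positive, got {k}")
    return (beta * t_ref ** (beta - 1.0) / k) ** (1.0 / beta)


def gen_delay_series(
    scenario: GatingScenario, t_ref: float = 0.002
) -> dict[float, list[QuenchTrace]]:
    """Generate replicate quench traces for each delay, grouped by delay.

    Each trace's (tau, beta) is chosen so the instantaneous quench rate
    evaluated at ``t_ref`` reproduces the scenario's true rate at that delay
    (beta is fixed at the configured value and tau is solved analytically).
    """
    delays, rates = true_delay_rates(scenario)
    out: dict[float, list[QuenchTrace]] = {}
    for i, (d, k) in enumerate(zip(delays, rates)):
        traces = []
        for rep in range(scenario.replicates):
            params = TraceParams(
                F0=scenario.F0,
                Finf=scenario.Finf,
                tau=tau_for_rate(k, scenario.beta, t_ref),
                beta=scenario.beta,
                noise_sd=scenario.noise_sd,
                n_points=scenario.n_points,
                duration=scenario.duration,
                seed=scenario.seed,
            )
            traces.append(
                gen_quench_trace(
                    params,
                    delay_time=float(d),
                    agonist_conc=scenario.agonist_conc,
                    label=f"delay={d:.4g}s rep={rep}",
                    _spawn_key=(_STREAM_DELAY, i, rep),
                )
            )
        out[float(d)] = traces
    return out
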