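"""Domain types for stopped-flow flux kinetics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from lipidflux.errors import ParameterError


@dataclass
class QuenchTrace:
    """One sequential-mixing fluorescence quenching trace.

    Attributes
    ----------
    time : ndarray
        Sample times in seconds, strictly increasing, starting >= 0.
        t = 0 is the quencher mixing event.
    fluorescence : ndarray
        Fluorescence in arbitrary units, same length as ``time``.
    delay_time : float or None
        Agonist-to-quencher delay in seconds, if part of a delay series.
    agonist_conc : float or None
        Agonist concentration in mM (None for a no-agonist control).
    label : str
        Free-text identifier.
    """

    time: np.ndarray
    fluorescence: np.ndarray
    delay_time: float | None = None
    agonist_conc: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.time.ndim != 1 or self.fluorescence.ndim != 1:
            raise ParameterError("time and fluorescence must be 1-D arrays")
        if len(self.time) != len(self.fluorescence):
            raise ParameterError(
                f"length mismatch: {len(self.time)} times vs "
                f"{len(self.fluorescence)} fluorescence samples"
            )
        if len(self.time) and self.time[0] < 0:
            raise ParameterError("time must start at or after 0")
        if np.any(np.diff(self.time) <= 0):
            raise ParameterError("time must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class StretchedExpFit:
    """Result of fitting F(t) = Finf + (F0 - Finf) * exp(-(t/tau)^beta)."""

    F0: float
    Finf: float
    tau: float
    beta: float
    rss: float
    window: tuple[float, float]
    converged: bool
    n_points: int = 0

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return stretched_exp(t, self.F0, self.Finf, self.tau, self.beta)


def stretched_exp(
    t: np.ndarray, F0: float, Finf: float, tau: float, beta: float
) -> np.ndarray:
    """Evaluate Finf + (F0 - Finf) * exp(-(t/tau)^beta)."""
    t = np.asarray(t, dtype=float)
    return Finf + (F0 - Finf) * np.exp(-((t / tau) ** beta))


@dataclass
class FluxRate:
    """Instantaneous quench rate k = (beta/tau) * (t_eval/tau)^(beta-1)."""

    k: float
    t_eval: float = 0.002

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ParameterError(f"rate k must be non-negative, got {self.k}")


@dataclass
class DecayFit:
    """Single or double exponential decay fit of rate vs delay.

    ``components`` is a list of (amplitude, tau) sorted by tau ascending.
    ``weighted_tau`` is the amplitude-weighted mean of the component taus.
    """

    components: list[tuple[float, float]]
    weighted_tau: float
    model: str  # "single" | "double"
    baseline: float = 0.0
    rss: float = float("nan")
    converged: bool = True


@dataclass
class TimeCourse:
    """Per-delay mean flux rate with SEM, plus optional desensitization fit."""

    delays: np.ndarray
    mean_rate: np.ndarray
    sem: np.ndarray
    n: np.ndarray
    peak_rate: float = field(default=0.0)
    desensitization: DecayFit | None = None
    background_rate: float | None = None

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.mean_rate = np.asarray(self.mean_rate, dtype=float)
        self.sem = np.asarray(self.sem, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        if np.any(np.diff(self.delays) <= 0):
            raise ParameterError("delays must be sorted strictly ascending")


@dataclass
class HillFit:
    """Hill (logistic in log-concentration) dose-response fit."""

    ec50: float
    hill_n: float
    top: float
    bottom: float = 0.0
    rss: float = float("nan")
    converged: bool = True

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ParameterError(f"ec50 must be positive, got {self.ec50}")

    def predict(self, conc: np.ndarray) -> np.ndarray:
        c = np.asarray(conc, dtype=float)
        with np.errstate(divide="ignore"):
            cn = c**self.hill_n
        return self.bottom + (self.top - self.bottom) * cn / (cn + self.ec50**self.hill_n)
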