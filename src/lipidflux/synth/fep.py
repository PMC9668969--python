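"""Crooks-consistent Gaussian work-sample generator.

For a window with true free-energy difference dG and work standard deviation
sigma, forward work is drawn from N(dG + sigma^2/(2RT), sigma^2) and reverse
work from N(-dG + sigma^2/(2RT), sigma^2).  These two Gaussians satisfy the
Crooks fluctuation relation

    P_F(W) / P_R(-W) = exp((W - dG)/RT)

exactly, so estimator consistency can be tested against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from lipidflux.constants import DEFAULT_TEMPERATURE, rt_kcal
from lipidflux.errors import ParameterError
from lipidflux.fep.models import FepSeries, FepWindow

_STREAM_FEP = 201


@dataclass
class FepScenario:
    """Ground truth for a synthetic bidirectional FEP series."""

    true_dg_per_window: list[float] = field(default_factory=lambda: [0.5] * 10)
    work_sd: float = 1.0
    samples_per_window: int = 1000
    temperature: float = DEFAULT_TEMPERATURE
    seed: int = 0

    def validate(self) -> None:
        if not self.true_dg_per_window:
            raise ParameterError("true_dg_per_window must be non-empty")
        if self.work_sd <= 0:
            raise ParameterError(f"work_sd must be positive, got {self.work_sd}")
        if self.samples_per_window < 1:
            raise ParameterError(
                f"samples_per_window must be >= 1, got {self.samples_per_window}"
            )
        if self.temperature <= 0:
            raise ParameterError(f"temperature must be positive, got {self.temperature}")


def gen_fep_dataset(scenario: FepScenario, replica_id: str = "synthetic") -> FepSeries:
    """Generate a contiguous FepSeries on [0, 1] with known per-window dG."""
    scenario.validate()
    rt = rt_kcal(scenario.temperature)
    n_win = len(scenario.true_dg_per_window)
    bounds = np.linspace(0.0, 1.0, n_win + 1)
    shift = scenario.work_sd**2 / (2.0 * rt)
    windows = []
    for i, dg in enumerate(scenario.true_dg_per_window):
        rng = np.random.default_rng((_STREAM_FEP, scenario.seed, i))
        fwd = rng.normal(dg + shift, scenario.work_sd, scenario.samples_per_window)
        bwd = rng.normal(-dg + shift, scenario.work_sd, scenario.samples_per_window)
        windows.append(
            FepWindow(
                lambda_a=float(bounds[i]),
                lambda_b=float(bounds[i + 1]),
                forward_work=fwd,
                backward_work=bwd,
                temperature=scenario.temperature,
            )
        )
    return FepSeries(
        windows=windows,
        replica_id=replica_id,
        true_dg_per_window=np.asarray(scenario.true_dg_per_window, dtype=float),
    )
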