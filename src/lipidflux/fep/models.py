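"""Domain types for alchemical free-energy estimation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from lipidflux.constants import DEFAULT_TEMPERATURE
from lipidflux.errors import DataError, ParameterError


@dataclass
class FepWindow:
    """One alchemical window with bidirectional (IDWS) work samples.

    ``forward_work`` holds work values for the lambda_a -> lambda_b direction,
    ``backward_work`` for lambda_b -> lambda_a, both in kcal/mol and in
    temporal (step) order.
    """

    lambda_a: float
    lambda_b: float
    forward_work: np.ndarray
    backward_work: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        self.forward_work = np.asarray(self.forward_work, dtype=float)
        self.backward_work = np.asarray(self.backward_work, dtype=float)
        if not (0.0 <= self.lambda_a < self.lambda_b <= 1.0):
            raise ParameterError(
                f"require 0 <= lambda_a < lambda_b <= 1, got "
                f"({self.lambda_a}, {self.lambda_b})"
            )
        if self.temperature <= 0:
            raise ParameterError(f"temperature must be positive, got {self.temperature}")

    def reversed(self) -> "FepWindow":
        """The reverse transformation: directions swap roles.

        Backward work is already the work of the b -> a perturbation, so the
        swap alone yields the reverse window and negates the BAR estimate.
        """
        return FepWindow(
            lambda_a=self.lambda_a,
            lambda_b=self.lambda_b,
            forward_work=self.backward_work,
            backward_work=self.forward_work,
            temperature=self.temperature,
        )


@dataclass
class FepSeries:
    """Ordered, contiguous windows jointly covering [0, 1]."""

    windows: list[FepWindow]
    replica_id: str = ""
    true_dg_per_window: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.windows:
            raise DataError("FepSeries requires at least one window")
        self.windows = sorted(self.windows, key=lambda w: w.lambda_a)

    def validate_coverage(self) -> None:
        if self.windows[0].lambda_a != 0.0:
            raise DataError(
                f"lambda coverage does not start at 0 (first window starts at "
                f"{self.windows[0].lambda_a})"
            )
        for prev, nxt in zip(self.windows, self.windows[1:]):
            if not np.isclose(prev.lambda_b, nxt.lambda_a, atol=1e-9):
                raise DataError(
                    f"gap in lambda coverage between {prev.lambda_b} and {nxt.lambda_a}"
                )
        if not np.isclose(self.windows[-1].lambda_b, 1.0, atol=1e-9):
            raise DataError(
                f"lambda coverage does not end at 1 (last window ends at "
                f"{self.windows[-1].lambda_b})"
            )

    def __len__(self) -> int:
        return len(self.windows)


@dataclass
class DeltaGEstimate:
    """A free-energy difference estimate in kcal/mol."""

    value: float
    stat_error: float
    method: str  # "BAR" | "EXP_forward" | "EXP_backward" | "replica_mean"
    n_effective: float = 0.0
    overlap_warning: bool = False

    def __post_init__(self) -> None:
        if self.stat_error < 0:
            raise ParameterError(f"stat_error must be >= 0, got {self.stat_error}")


@dataclass
class ConvergenceReport:
    """Convergence diagnostics for one FEP series."""

    per_window_delta: np.ndarray | None = None
    delta_mean: float = float("nan")
    delta_max_abs: float = float("nan")
    runs_z: float = float("nan")
    runs_random: bool | None = None
    half_split: tuple[float, float, float] | None = None  # (first, second, |diff|)
    passes_1kcal: bool | None = None
    inefficiency_g: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class LambdaSchedule:
    """Window boundaries on [0, 1] plus electrostatic-scaling onset metadata."""

    values: np.ndarray
    elec_start: float = 0.5

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.values) <= 0):
            raise ParameterError("lambda values must be strictly increasing")
        if self.values[0] != 0.0 or self.values[-1] != 1.0:
            raise ParameterError("lambda schedule must span [0, 1] inclusive")
        if not (0.0 <= self.elec_start <= 1.0):
            raise ParameterError(f"elec_start must be in [0,1], got {self.elec_start}")

    @property
    def n_windows(self) -> int:
        return len(self.values) - 1


@dataclass
class DbcReference:
    """Reference geometry for the distance-to-bound-configuration coordinate."""

    frame_atom_coords: np.ndarray
    glycerol_ref_coords: np.ndarray
    wall: float = 6.0

    def __post_init__(self) -> None:
        self.frame_atom_coords = np.asarray(self.frame_atom_coords, dtype=float)
        self.glycerol_ref_coords = np.asarray(self.glycerol_ref_coords, dtype=float)
        if self.frame_atom_coords.ndim != 2 or self.frame_atom_coords.shape[1] != 3:
            raise ParameterError("frame_atom_coords must be (n, 3)")
        if self.glycerol_ref_coords.ndim != 2 or self.glycerol_ref_coords.shape[1] != 3:
            raise ParameterError("glycerol_ref_coords must be (m, 3)")
        if len(self.frame_atom_coords) < 3:
            raise ParameterError("need at least 3 frame atoms")
        if self.wall <= 0:
            raise ParameterError(f"wall must be positive, got {self.wall}")
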