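"""Lambda schedule construction."""

from __future__ import annotations

import numpy as np

from lipidflux.errors import ParameterError
from lipidflux.fep.models import LambdaSchedule


def make_lambda_schedule(n_windows: int, elec_start: float = 0.5) -> LambdaSchedule:
    """n_windows + 1 linearly spaced boundaries on [0, 1].

    ``elec_start`` records where electrostatic scaling begins (metadata only;
    it does not alter the spacing).
    """
    if n_windows < 1:
        raise ParameterError(f"n_windows must be >= 1, got {n_windows}")
    values = np.linspace(0.0, 1.0, n_windows + 1)
    values[0], values[-1] = 0.0, 1.0
    return LambdaSchedule(values=values, elec_start=elec_start)
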