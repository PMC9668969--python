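"""Hill-type dose-response record generator."""

from __future__ import annotations

import numpy as np
import pandas as pd

from lipidflux.errors import ParameterError

_STREAM_DOSE = 301


def gen_dose_series(
    ec50: float,
    hill_n: float,
    concentrations: list[float] | np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    top: float = 1.0,
) -> pd.DataFrame:
    """Generate dose-response records with bottom fixed at 0.

    Noiseless response at concentration c is ``top * c^n / (c^n + ec50^n)``.
    Returns a DataFrame with columns ``conc_mM`` and ``response``.
    """
    if ec50 <= 0:
        raise ParameterError(f"ec50 must be positive, got {ec50}")
    conc = np.asarray(concentrations, dtype=float)
    if conc.size == 0:
        raise ParameterError("concentrations must be non-empty")
    if np.any(conc < 0):
        raise ParameterError("concentrations must be >= 0")
    if noise_sd < 0:
        raise ParameterError(f"noise_sd must be >= 0, got {noise_sd}")
    cn = conc**hill_n
    response = np.where(conc > 0, top * cn / (cn + ec50**hill_n), 0.0)
    if noise_sd > 0:
        rng = np.random.default_rng((_STREAM_DOSE, seed))
        response = response + rng.normal(0.0, noise_sd, size=response.shape)
    return pd.DataFrame({"conc_mM": conc, "response": response})
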