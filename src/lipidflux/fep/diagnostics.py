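"""Convergence diagnostics: statistical inefficiency, hysteresis, half-split."""

from __future__ import annotations

import math

import numpy as np

from lipidflux.errors import DataError
from lipidflux.fep.models import ConvergenceReport, FepSeries, FepWindow


def statistical_inefficiency(samples: np.ndarray) -> tuple[float, np.ndarray]:
    """Statistical inefficiency g and subsampled (decorrelated) indices.

    g = 1 + 2 * sum of normalized autocorrelations, summed until the first
    non-positive term, clamped to >= 1.  Indices are strided by ceil(g).
    A constant series has g = 1 by convention.
    """
    x = np.asarray(samples, dtype=float)
    n = len(x)
    if n < 4:
        raise DataError(f"statistical inefficiency needs at least 4 samples, got {n}")
    g = _inefficiency(x)
    stride = max(1, math.ceil(g))
    return g, np.arange(0, n, stride)


def _inefficiency(x: np.ndarray) -> float:
    n = len(x)
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var <= 0:
        return 1.0  # zero-variance convention
    acc = 0.0
    for t in range(1, n):
        c = np.dot(x[:-t], x[t:]) / ((n - t) * var)
        if c <= 0:
            break
        acc += c
    return max(1.0, 1.0 + 2.0 * acc)


def decorrelate_series(samples: np.ndarray) -> np.ndarray:
    """Subsample a work series by its statistical inefficiency.

    Series too short to estimate autocorrelation (< 4 samples) are returned
    unchanged.
    """
    x = np.asarray(samples, dtype=float)
    if len(x) < 4:
        return x
    _, idx = statistical_inefficiency(x)
    return x[idx]


def _runs_test(signs: np.ndarray) -> tuple[float, bool]:
    """Wald-Wolfowitz runs test on a sign sequence (zeros excluded)."""
    s = signs[signs != 0]
    n = len(s)
    n_pos = int(np.sum(s > 0))
    n_neg = n - n_pos
    if n == 0:
        return 0.0, True
    if n_pos == 0 or n_neg == 0:
        # one-sided sequence: no evidence against randomness only if very short
        return (0.0, True) if n < 5 else (np.inf, False)
    runs = 1 + int(np.sum(s[1:] != s[:-1]))
    mu = 2.0 * n_pos * n_neg / n + 1.0
    var = 2.0 * n_pos * n_neg * (2.0 * n_pos * n_neg - n) / (n**2 * (n - 1))
    if var <= 0:
        return 0.0, True
    z = (runs - mu) / np.sqrt(var)
    return float(z), bool(abs(z) <= 1.96)


def hysteresis(series: FepSeries, decorrelate: bool = True) -> ConvergenceReport:
    """Per-window difference between forward and backward EXP estimates.

    delta_lambda = EXP_forward - EXP_backward (both in the forward sign
    convention).  The summary includes the mean, the maximum absolute value,
    and a Wald-Wolfowitz sign-runs statistic testing whether the deltas are
    randomly distributed with respect to lambda.
    """
    from lipidflux.fep.estimators import exp_estimate

    missing = [
        i
        for i, w in enumerate(series.windows)
        if len(w.forward_work) == 0 or len(w.backward_work) == 0
    ]
    if missing:
        raise DataError(f"windows missing a direction: indices {missing}")
    deltas = np.array(
        [
            exp_estimate(w, "forward", decorrelate=decorrelate).value
            - exp_estimate(w, "backward", decorrelate=decorrelate).value
            for w in series.windows
        ]
    )
    z, random = _runs_test(np.sign(deltas))
    return ConvergenceReport(
        per_window_delta=deltas,
        delta_mean=float(deltas.mean()),
        delta_max_abs=float(np.abs(deltas).max()),
        runs_z=z,
        runs_random=random,
    )


def _split_window(w: FepWindow) -> tuple[FepWindow, FepWindow]:
    nf, nb = len(w.forward_work), len(w.backward_work)
    if nf < 2 or nb < 2:
        raise DataError(
            f"half-split needs >= 2 samples per direction in window "
            f"({w.lambda_a}, {w.lambda_b}), got {nf} forward / {nb} backward"
        )
    first = FepWindow(
        w.lambda_a, w.lambda_b, w.forward_work[: nf // 2], w.backward_work[: nb // 2],
        temperature=w.temperature,
    )
    second = FepWindow(
        w.lambda_a, w.lambda_b, w.forward_work[nf // 2 :], w.backward_work[nb // 2 :],
        temperature=w.temperature,
    )
    return first, second


def half_split(
    series: FepSeries, threshold: float = 1.0, decorrelate: bool = True
) -> ConvergenceReport:
    """Compare accumulated dG from the first vs second half of the raw data.

    The temporal split is applied per window per direction on the raw sample
    order (before any decorrelation); each half is then accumulated like a
    full series.  ``passes_1kcal`` is True when |dG_first - dG_second| is
    within ``threshold`` kcal/mol.
    """
    from lipidflux.fep.estimators import accumulate

    halves = [_split_window(w) for w in series.windows]
    first = FepSeries([h[0] for h in halves], replica_id=f"{series.replica_id}/first")
    second = FepSeries([h[1] for h in halves], replica_id=f"{series.replica_id}/second")
    dg1, _, _ = accumulate(first, decorrelate=decorrelate)
    dg2, _, _ = accumulate(second, decorrelate=decorrelate)
    diff = abs(dg1.value - dg2.value)
    gs = []
    for w in series.windows:
        gf = _inefficiency(np.asarray(w.forward_work, dtype=float))
        gb = _inefficiency(np.asarray(w.backward_work, dtype=float))
        gs.append((gf, gb))
    return ConvergenceReport(
        half_split=(dg1.value, dg2.value, diff),
        passes_1kcal=bool(diff <= threshold),
        inefficiency_g=gs,
    )


def diagnose(series: FepSeries, threshold: float = 1.0, decorrelate: bool = True) -> ConvergenceReport:
    """Full convergence report: hysteresis plus half-split."""
    hyst = hysteresis(series, decorrelate=decorrelate)
    hs = half_split(series, threshold=threshold, decorrelate=decorrelate)
    hyst.half_split = hs.half_split
    hyst.passes_1kcal = hs.passes_1kcal
    hyst.inefficiency_g = hs.inefficiency_g
    return hyst
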