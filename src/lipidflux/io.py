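"""File I/O: trace CSV, work-table TSV, NAMD fepout subset, free-energy tables.

Canonical tabular output is TSV (headers, UTF-8, '.' decimal); nested fit
results are JSON.  Every writer emits a provenance header (package version,
seed, config hash) as '#'-prefixed comment lines, which all readers skip.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from lipidflux import __version__
from lipidflux.constants import DEFAULT_TEMPERATURE
from lipidflux.errors import DataError
from lipidflux.fep.models import FepSeries, FepWindow
from lipidflux.kinetics.models import QuenchTrace
from lipidflux.thermo.models import TransformFreeEnergies


def provenance_lines(seed: int | None = None, config: dict | None = None) -> list[str]:
    """Provenance header lines for output artifacts."""
    lines = [f"# lipidflux {__version__}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    if config:
        blob = json.dumps(config, sort_keys=True, default=str)
        lines.append(f"# config_hash={hashlib.sha256(blob.encode()).hexdigest()[:12]}")
    return lines


# ---------------------------------------------------------------------------
# quench traces
# ---------------------------------------------------------------------------

def read_trace_csv(path: str | Path, **trace_kwargs) -> QuenchTrace:
    """Read a two-column (time_s, fluorescence_au) CSV trace.

    A header row is optional; '#' comment lines are skipped; ragged rows are
    reported with their line number.
    """
    path = Path(path)
    times: list[float] = []
    fluor: list[float] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or (row[0].lstrip().startswith("#")):
                continue
            if len(row) != 2:
                raise DataError(
                    f"{path}:{lineno}: expected 2 columns, got {len(row)}"
                )
            try:
                times.append(float(row[0]))
                fluor.append(float(row[1]))
            except ValueError:
                if lineno == 1 or (not times and not fluor):
                    continue  # header row
                raise DataError(f"{path}:{lineno}: non-numeric value in {row!r}")
    if not times:
        raise DataError(f"{path}: no data rows")
    return QuenchTrace(time=np.array(times), fluorescence=np.array(fluor), **trace_kwargs)


def write_trace_csv(
    path: str | Path,
    trace: QuenchTrace,
    seed: int | None = None,
    sidecar: dict | None = None,
) -> None:
    """Write a trace as CSV; optional ground-truth sidecar JSON at <path>.json."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        for line in provenance_lines(seed):
            fh.write(line + "\n")
        fh.write("time_s,fluorescence_au\n")
        for t, f in zip(trace.time, trace.fluorescence):
            fh.write(f"{float(t)!r},{float(f)!r}\n")
    if sidecar is not None:
        with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
            json.dump(sidecar, fh, indent=2, default=str)


def write_fit(path: str | Path, fit, seed: int | None = None, config: dict | None = None) -> None:
    """Write any fit dataclass as JSON with provenance fields."""
    payload = {
        "provenance": {
            "package": f"lipidflux {__version__}",
            "seed": seed,
            "config": config,
        },
        "fit": _to_jsonable(fit),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


# ---------------------------------------------------------------------------
# work tables
# ---------------------------------------------------------------------------

WORK_TABLE_COLUMNS = [
    "window_index",
    "lambda_a",
    "lambda_b",
    "direction",
    "work_kcal_mol",
    "step",
]


def write_work_table(
    path: str | Path, series: FepSeries, seed: int | None = None
) -> None:
    """Write a FepSeries in the canonical work-table TSV dialect."""
    rows = []
    for i, w in enumerate(series.windows):
        for direction, work in (("fwd", w.forward_work), ("bwd", w.backward_work)):
            for step, value in enumerate(work):
                rows.append((i, w.lambda_a, w.lambda_b, direction, value, step))
    df = pd.DataFrame(rows, columns=WORK_TABLE_COLUMNS)
    with open(path, "w") as fh:
        for line in provenance_lines(seed):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_work_table(
    path: str | Path, temperature: float = DEFAULT_TEMPERATURE
) -> FepSeries:
    """Read the work-table TSV dialect into a contiguous FepSeries.

    Rows may arrive in any order (they are ordered by step within each window
    and direction); overlapping windows or a gap in lambda coverage are
    errors.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(WORK_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    bad = set(df["direction"]) - {"fwd", "bwd"}
    if bad:
        raise DataError(f"{path}: unknown direction token(s) {sorted(bad)}")
    windows = []
    for idx, grp in df.groupby("window_index"):
        la = grp["lambda_a"].unique()
        lb = grp["lambda_b"].unique()
        if len(la) != 1 or len(lb) != 1:
            raise DataError(
                f"{path}: window {idx} has inconsistent lambda bounds"
            )
        fwd = grp[grp["direction"] == "fwd"].sort_values("step")["work_kcal_mol"]
        bwd = grp[grp["direction"] == "bwd"].sort_values("step")["work_kcal_mol"]
        windows.append(
            FepWindow(
                lambda_a=float(la[0]),
                lambda_b=float(lb[0]),
                forward_work=fwd.to_numpy(),
                backward_work=bwd.to_numpy(),
                temperature=temperature,
            )
        )
    _check_no_overlap(windows, str(path))
    series = FepSeries(windows=windows, replica_id=str(path))
    series.validate_coverage()
    return series


def _check_no_overlap(windows: list[FepWindow], origin: str) -> None:
    ordered = sorted(windows, key=lambda w: w.lambda_a)
    for prev, nxt in zip(ordered, ordered[1:]):
        if nxt.lambda_a < prev.lambda_b - 1e-9:
            raise DataError(
                f"{origin}: overlapping windows "
                f"({prev.lambda_a}, {prev.lambda_b}) and ({nxt.lambda_a}, {nxt.lambda_b})"
            )


# ---------------------------------------------------------------------------
# NAMD fepout subset
# ---------------------------------------------------------------------------

def read_fepout(
    path: str | Path, temperature: float = DEFAULT_TEMPERATURE
) -> FepSeries:
    """Parse the 'FepEnergy:' record subset of a NAMD fepout file.

    Dialect assumptions (documented, not configurable):

    * ``#NEW FEP WINDOW: LAMBDA SET TO <l> LAMBDA2 <l2>`` starts a section;
      every following ``FepEnergy:`` line contributes its dE field (column 7)
      as one work sample for the l -> l2 perturbation at that window.
    * l2 > l is a forward sample for window (l, l2); l2 < l is a backward
      sample for window (l2, l).  Interleaved (IDWS) output must already be
      demultiplexed into such sections.
    * Fields used per record: step (column 2), dE (column 7); the accumulated
      dG column is ignored for estimation.
    """
    path = Path(path)
    sections: dict[tuple[float, float], dict[str, list[tuple[int, float]]]] = {}
    current: tuple[float, float] | None = None
    direction = "fwd"
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if "NEW FEP WINDOW" in line:
                tokens = line.split()
                try:
                    l1 = float(tokens[tokens.index("TO") + 1])
                    l2 = float(tokens[tokens.index("LAMBDA2") + 1])
                except (ValueError, IndexError):
                    raise DataError(f"{path}:{lineno}: malformed window header")
                if l2 > l1:
                    current, direction = (l1, l2), "fwd"
                elif l2 < l1:
                    current, direction = (l2, l1), "bwd"
                else:
                    raise DataError(f"{path}:{lineno}: zero-width window")
                sections.setdefault(current, {"fwd": [], "bwd": []})
            elif line.startswith("FepEnergy:"):
                if current is None:
                    raise DataError(f"{path}:{lineno}: FepEnergy before any window header")
                tokens = line.split()
                try:
                    step = int(tokens[1])
                    de = float(tokens[6])
                except (ValueError, IndexError):
                    raise DataError(f"{path}:{lineno}: malformed FepEnergy record")
                sections[current][direction].append((step, de))
    if not sections:
        raise DataError(f"{path}: no FEP windows found")
    windows = []
    for (la, lb), works in sorted(sections.items()):
        fwd = [w for _, w in sorted(works["fwd"])]
        bwd = [w for _, w in sorted(works["bwd"])]
        windows.append(
            FepWindow(
                lambda_a=la,
                lambda_b=lb,
                forward_work=np.array(fwd),
                backward_work=np.array(bwd),
                temperature=temperature,
            )
        )
    _check_no_overlap(windows, str(path))
    return FepSeries(windows=windows, replica_id=str(path))


# ---------------------------------------------------------------------------
# free-energy tables
# ---------------------------------------------------------------------------

def read_free_energy_table(path) -> TransformFreeEnergies:
    """Read a transformation free-energy table (TSV or JSON records).

    Schema: environment, species_from, species_to, dg_kcal_mol, err_kcal_mol.
    Antisymmetric closure is applied on load; duplicate conflicting entries
    and thermodynamic-cycle violations are errors.
    """
    path_str = str(path)
    if path_str.endswith(".json"):
        with open(path) as fh:
            records = json.load(fh)
        df = pd.DataFrame(records)
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    required = {"environment", "species_from", "species_to", "dg_kcal_mol", "err_kcal_mol"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    table = TransformFreeEnergies()
    for row in df.itertuples(index=False):
        table.add(
            str(row.environment),
            str(row.species_from),
            str(row.species_to),
            float(row.dg_kcal_mol),
            float(row.err_kcal_mol),
        )
    for env in table.environments():
        table.check_cycle_closure(env)
    return table


def write_free_energy_table(path: str | Path, table: TransformFreeEnergies) -> None:
    rows = [
        {
            "environment": env,
            "species_from": a,
            "species_to": b,
            "dg_kcal_mol": dg,
            "err_kcal_mol": err,
        }
        for (env, a, b), (dg, err) in sorted(table.entries.items())
    ]
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        for line in provenance_lines():
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)
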