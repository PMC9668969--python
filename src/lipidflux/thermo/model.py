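"""Allosteric lipid-site model operations.

From state-dependent lipid transformation free energies to relative binding
constants, site occupancies, 50%-occupancy mole fractions, and the relative
conformational-stability landscape over ternary compositions.

The chain is:

1. ddG(a->b) = dG_bound(a->b) - dG_bulk(a->b)     (thermodynamic cycle)
2. K(a,b)    = exp(-ddG / RT)                      (relative binding constant)
3. p_occ^a   = (1 + K(a,b) x_b/x_a + K(a,c) x_c/x_a)^-1
4. x50       = POPG mole fraction with p_occ^POPG = 1/2 on the 2:1:x path
5. dlog      = log[(x_C + K5(C,E) x_E + K5(C,G) x_G) /
                   (x_C + Kwt(C,E) x_E + Kwt(C,G) x_G)]

Positive dlog means the open (ELIC5) conformation is stabilized relative to
pure POPC, where dlog is 0 by definition.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq

from lipidflux.constants import DEFAULT_TEMPERATURE, rt_kcal
from lipidflux.errors import DataError, ParameterError
from lipidflux.thermo.models import (
    REFERENCE_SPECIES,
    SPECIES,
    Composition,
    OccupancyResult,
    RelativeAffinityMatrix,
    StabilityMap,
    TransformFreeEnergies,
    X50Result,
    check_conformation,
    check_species,
)

#: Default bulk composition whose transformation free energies anchor ddG.
DEFAULT_BULK = "2:1:1"


def ddg_replacement(
    table: TransformFreeEnergies,
    conformation: str,
    bulk_label: str,
    a: str,
    b: str,
) -> tuple[float, float]:
    """Relative free energy of replacing bound lipid a with bulk lipid b.

    ddG = dG_bound(a->b) - dG_bulk(a->b); errors combine in quadrature.
    """
    check_conformation(conformation)
    bound_dg, bound_err = table.get(conformation, a, b)
    bulk_dg, bulk_err = table.get(bulk_label, a, b)
    return bound_dg - bulk_dg, math.hypot(bound_err, bulk_err)


def relative_K(ddg: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Convert a replacement free energy to a relative binding constant."""
    return math.exp(-ddg / rt_kcal(temperature))


def build_affinity_matrix(
    table: TransformFreeEnergies,
    conformation: str,
    bulk_label: str = DEFAULT_BULK,
    temperature: float = DEFAULT_TEMPERATURE,
) -> RelativeAffinityMatrix:
    """Relative binding constants for one conformation, anchored at POPE."""
    k = {REFERENCE_SPECIES: 1.0}
    for species in SPECIES:
        if species == REFERENCE_SPECIES:
            continue
        ddg, _ = ddg_replacement(table, conformation, bulk_label, REFERENCE_SPECIES, species)
        k[species] = relative_K(ddg, temperature)
    return RelativeAffinityMatrix(
        conformation=conformation,
        k_by_species=k,
        temperature=temperature,
        bulk_reference=bulk_label,
    )


def occupancy(K: RelativeAffinityMatrix, comp: Composition) -> OccupancyResult:
    """Site occupancy probability for each species at a composition.

    For species a with x_a > 0, p^a = (1 + sum_b K(a,b) x_b / x_a)^-1; the
    x_a = 0 limit gives p^a = 0.  Probabilities sum to 1.
    """
    p: dict[str, float] = {}
    for a in SPECIES:
        xa = comp.x(a)
        if xa == 0.0:
            p[a] = 0.0
            continue
        denom = 1.0
        for b in SPECIES:
            if b == a:
                continue
            denom += K.K(a, b) * comp.x(b) / xa
        p[a] = 1.0 / denom
    return OccupancyResult(p_occ=p)


def occupancy_curve(
    K: RelativeAffinityMatrix, x_grid: np.ndarray
) -> list[tuple[float, OccupancyResult]]:
    """Occupancies along the 2 POPC : 1 POPE : x POPG composition path.

    Each grid point x is normalized to mole fractions (2, 1, x)/(3 + x)
    before evaluation.  Returns (x_POPG mole fraction, occupancy) pairs.
    """
    x_grid = np.asarray(x_grid, dtype=float)
    if np.any(x_grid < 0):
        raise ParameterError("path coordinates must be >= 0")
    out = []
    for x in x_grid:
        comp = Composition.on_pg_path(float(x))
        out.append((comp.x_popg, occupancy(K, comp)))
    return out


def _p_popg_on_path(K: RelativeAffinityMatrix, x: float) -> float:
    return occupancy(K, Composition.on_pg_path(x))["POPG"]


def x50(
    K: RelativeAffinityMatrix,
    log_x_bracket: tuple[float, float] = (-30.0, 30.0),
    rtol: float = 1e-6,
) -> X50Result:
    """POPG mole fraction giving 50% POPG occupancy on the 2:1:x path.

    Solved by root bracketing on log x to relative tolerance ``rtol``;
    reported as the normalized mole fraction x/(3+x) alongside the raw path
    coordinate x.
    """
    lo, hi = log_x_bracket
    f = lambda u: _p_popg_on_path(K, math.exp(u)) - 0.5
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise DataError(
            "POPG occupancy does not cross 50% on the 2:1:x path within the "
            f"bracket e^{lo}..e^{hi}"
        )
    u = brentq(f, lo, hi, rtol=rtol / 10)
    x = math.exp(u)
    return X50Result(
        mole_fraction=x / (3.0 + x), path_x=x, conformation=K.conformation
    )


def stability_ratio(
    K_elic5: RelativeAffinityMatrix,
    K_wt: RelativeAffinityMatrix,
    comp: Composition,
) -> float:
    """log of the ELIC5:WT population ratio relative to its pure-POPC value.

    Natural log.  Exactly 0 at pure POPC for any pair of valid matrices.
    """
    num = (
        comp.x_popc
        + K_elic5.K("POPC", "POPE") * comp.x_pope
        + K_elic5.K("POPC", "POPG") * comp.x_popg
    )
    den = (
        comp.x_popc
        + K_wt.K("POPC", "POPE") * comp.x_pope
        + K_wt.K("POPC", "POPG") * comp.x_popg
    )
    if den <= 0 or num <= 0:
        raise DataError("non-positive population factor; invalid K matrix or composition")
    return math.log(num / den)


def stability_map(
    K_elic5: RelativeAffinityMatrix,
    K_wt: RelativeAffinityMatrix,
    grid_resolution: int = 51,
) -> StabilityMap:
    """Evaluate the stability log-ratio on a barycentric simplex grid.

    The grid has resolution*(resolution+1)/2 points with POPE and POPG
    fractions stepping by 1/(resolution-1); POPC takes the remainder.
    """
    if grid_resolution < 2:
        raise ParameterError(f"grid_resolution must be >= 2, got {grid_resolution}")
    m = grid_resolution
    xs_c, xs_e, xs_g, vals = [], [], [], []
    for i in range(m):  # POPG steps
        for j in range(m - i):  # POPE steps
            x_g = i / (m - 1)
            x_e = j / (m - 1)
            x_c = max(0.0, 1.0 - x_g - x_e)
            comp = Composition(x_popc=x_c, x_pope=x_e, x_popg=x_g)
            xs_c.append(x_c)
            xs_e.append(x_e)
            xs_g.append(x_g)
            vals.append(stability_ratio(K_elic5, K_wt, comp))
    return StabilityMap(
        x_popc=np.array(xs_c),
        x_pope=np.array(xs_e),
        x_popg=np.array(xs_g),
        delta_log=np.array(vals),
    )


def propagate_table_errors(
    table: TransformFreeEnergies,
    n_draws: int = 1000,
    seed: int = 0,
    bulk_label: str = DEFAULT_BULK,
    temperature: float = DEFAULT_TEMPERATURE,
    comp: Composition | None = None,
    percentiles: tuple[float, float, float] = (2.5, 50.0, 97.5),
) -> dict:
    """Monte-Carlo propagation of the table's +/- errors.

    Each draw perturbs every stored dG by Normal(dg, err) and recomputes the
    binding constants, x50 per conformation, and the stability log-ratio at
    ``comp`` (default 2:1:1).  Returns percentile intervals per quantity;
    draws where x50 has no crossing contribute NaN.
    """
    if n_draws < 2:
        raise ParameterError(f"n_draws must be >= 2, got {n_draws}")
    if comp is None:
        comp = Composition(x_popc=0.5, x_pope=0.25, x_popg=0.25)
    rng = np.random.default_rng((501, seed))
    keys = sorted(table.entries)
    results: dict[str, list[float]] = {
        "x50_WT_CA": [],
        "x50_ELIC5_CA": [],
        "delta_log": [],
        "K_CG_WT_CA": [],
        "K_CG_ELIC5_CA": [],
    }
    for _ in range(n_draws):
        drawn = TransformFreeEnergies()
        for env, a, b in keys:
            dg, err = table.entries[(env, a, b)]
            drawn.add(env, a, b, rng.normal(dg, err) if err > 0 else dg, err)
        k_wt = build_affinity_matrix(drawn, "WT_CA", bulk_label, temperature)
        k_e5 = build_affinity_matrix(drawn, "ELIC5_CA", bulk_label, temperature)
        for name, k in (("WT_CA", k_wt), ("ELIC5_CA", k_e5)):
            try:
                results[f"x50_{name}"].append(x50(k).mole_fraction)
            except DataError:
                results[f"x50_{name}"].append(float("nan"))
            results[f"K_CG_{name}"].append(k.K("POPC", "POPG"))
        results["delta_log"].append(stability_ratio(k_e5, k_wt, comp))
    out = {}
    for name, vals in results.items():
        arr = np.asarray(vals)
        out[name] = {
            "percentiles": dict(
                zip((str(p) for p in percentiles), np.nanpercentile(arr, percentiles))
            ),
            "n_valid": int(np.sum(np.isfinite(arr))),
        }
    return out
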