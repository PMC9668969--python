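"""Lipid-site allosteric model: binding constants, occupancy, x50, stability maps."""

from importlib import resources

from lipidflux.thermo.models import (
    CONFORMATIONS,
    REFERENCE_SPECIES,
    SPECIES,
    Composition,
    OccupancyResult,
    RelativeAffinityMatrix,
    StabilityMap,
    TransformFreeEnergies,
    X50Result,
)
from lipidflux.thermo.model import (
    DEFAULT_BULK,
    build_affinity_matrix,
    ddg_replacement,
    occupancy,
    occupancy_curve,
    propagate_table_errors,
    relative_K,
    stability_map,
    stability_ratio,
    x50,
)


def packaged_table_path():
    """Path to the packaged lipid-transformation free-energy table (TSV)."""
    return resources.files("lipidflux.thermo") / "data" / "free_energy_table.tsv"


def load_packaged_table() -> TransformFreeEnergies:
    """Load the packaged transformation free-energy table."""
    from lipidflux.io import read_free_energy_table

    return read_free_energy_table(packaged_table_path())


__all__ = [
    "SPECIES",
    "CONFORMATIONS",
    "REFERENCE_SPECIES",
    "DEFAULT_BULK",
    "TransformFreeEnergies",
    "RelativeAffinityMatrix",
    "Composition",
    "OccupancyResult",
    "X50Result",
    "StabilityMap",
    "ddg_replacement",
    "relative_K",
    "build_affinity_matrix",
    "occupancy",
    "occupancy_curve",
    "x50",
    "stability_ratio",
    "stability_map",
    "propagate_table_errors",
    "packaged_table_path",
    "load_packaged_table",
]
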