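"""Thin PDB coordinate reader for the DBC coordinate (MDAnalysis-backed)."""

from __future__ import annotations

import numpy as np

from lipidflux.errors import DataError


def load_selection(pdb_path: str, selection: str) -> np.ndarray:
    """Coordinates (angstrom) of an MDAnalysis selection from a PDB file."""
    import warnings

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(pdb_path))
    atoms = u.select_atoms(selection)
    if len(atoms) == 0:
        raise DataError(f"{pdb_path}: selection {selection!r} matched no atoms")
    return atoms.positions.astype(float)
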