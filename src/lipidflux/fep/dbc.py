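"""Distance-to-bound-configuration (DBC) coordinate.

The DBC of a snapshot is the RMSD of the ligand anchor (glycerol) atoms
relative to their reference positions, measured after an optimal rigid
(Kabsch) superposition of the protein frame atoms onto the reference frame.
It is therefore invariant under rigid motions of the whole snapshot.
"""

from __future__ import annotations

import numpy as np

from lipidflux.errors import DataError, ParameterError
from lipidflux.fep.models import DbcReference


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t with mobile @ R.T + t ~= target."""
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape:
        raise ParameterError(
            f"shape mismatch: mobile {mobile.shape} vs target {target.shape}"
        )
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    h = (mobile - cm).T @ (target - ct)
    u, s, vt = np.linalg.svd(h)
    if s[1] <= 1e-10 * max(s[0], 1e-300):
        raise DataError("degenerate (collinear) frame geometry: superposition underdetermined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    r = vt.T @ corr @ u.T
    t = ct - r @ cm
    return r, t


def dbc(
    frame_coords: np.ndarray, glycerol_coords: np.ndarray, ref: DbcReference
) -> float:
    """DBC (angstrom) of one snapshot relative to ``ref``."""
    frame_coords = np.asarray(frame_coords, dtype=float)
    glycerol_coords = np.asarray(glycerol_coords, dtype=float)
    if frame_coords.shape != ref.frame_atom_coords.shape:
        raise ParameterError(
            f"frame atom count mismatch: snapshot {frame_coords.shape} vs "
            f"reference {ref.frame_atom_coords.shape}"
        )
    if glycerol_coords.shape != ref.glycerol_ref_coords.shape:
        raise ParameterError(
            f"glycerol atom count mismatch: snapshot {glycerol_coords.shape} vs "
            f"reference {ref.glycerol_ref_coords.shape}"
        )
    r, t = kabsch(frame_coords, ref.frame_atom_coords)
    aligned = glycerol_coords @ r.T + t
    diff = aligned - ref.glycerol_ref_coords
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def dbc_profile(snapshots_frame, snapshots_glycerol, ref: DbcReference) -> np.ndarray:
    """DBC for each snapshot in a stack of (frame, glycerol) coordinates."""
    return np.array(
        [dbc(f, g, ref) for f, g in zip(snapshots_frame, snapshots_glycerol)]
    )


def dbc_wall(dbc_values: np.ndarray, q: float = 95.0) -> float:
    """Empirical q-th percentile of DBC values (linear interpolation).

    Used to place the upper wall of the flat-bottom restraint defining the
    bound state.
    """
    values = np.asarray(dbc_values, dtype=float)
    if len(values) == 0:
        raise DataError("no DBC values supplied")
    if len(values) < 20:
        raise DataError(f"need at least 20 DBC values for a stable percentile, got {len(values)}")
    if not (0 <= q <= 100):
        raise ParameterError(f"percentile must be in [0, 100], got {q}")
    return float(np.percentile(values, q, method="linear"))
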