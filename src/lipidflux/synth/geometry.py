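"""Rigid-body coordinate snapshot generator for the DBC coordinate.

Each snapshot is a rigid transform (rotation + translation) of the reference
frame atoms together with the glycerol atoms, optionally with glycerol-only
Gaussian jitter applied in the reference frame before the transform.  Because
rotations preserve norms, the ground-truth DBC of a snapshot is the RMSD of
the jitter displacements themselves, which is recorded per snapshot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from lipidflux.errors import ParameterError

_STREAM_GEOM = 401


def _check_rotation(R: np.ndarray) -> None:
    if R.shape != (3, 3):
        raise ParameterError("rigid_rotation must be a 3x3 matrix")
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
        raise ParameterError("rigid_rotation must be orthonormal")
    if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
        raise ParameterError("rigid_rotation must have determinant +1")


def _check_noncollinear(coords: np.ndarray) -> None:
    centered = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ParameterError(
            "frame atoms are collinear; rigid superposition is underdetermined"
        )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (via QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


@dataclass
class SiteGeometryScenario:
    """Ground truth for DBC coordinate snapshots."""

    frame_coords: np.ndarray
    glycerol_coords: np.ndarray
    rigid_rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    jitter_sd: float = 0.0
    n_snapshots: int = 1
    seed: int = 0
    random_rigid: bool = False
    glycerol_offset: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def validate(self) -> None:
        self.frame_coords = np.asarray(self.frame_coords, dtype=float)
        self.glycerol_coords = np.asarray(self.glycerol_coords, dtype=float)
        self.rigid_rotation = np.asarray(self.rigid_rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        self.glycerol_offset = np.asarray(self.glycerol_offset, dtype=float)
        if self.frame_coords.ndim != 2 or self.frame_coords.shape[1] != 3:
            raise ParameterError("frame_coords must be (n, 3)")
        if len(self.frame_coords) < 3:
            raise ParameterError("need at least 3 frame atoms")
        _check_noncollinear(self.frame_coords)
        if self.glycerol_coords.ndim != 2 or self.glycerol_coords.shape[1] != 3:
            raise ParameterError("glycerol_coords must be (m, 3)")
        _check_rotation(self.rigid_rotation)
        if self.jitter_sd < 0:
            raise ParameterError(f"jitter_sd must be >= 0, got {self.jitter_sd}")
        if self.n_snapshots < 1:
            raise ParameterError(f"n_snapshots must be >= 1, got {self.n_snapshots}")


@dataclass
class SiteSnapshots:
    """Generated snapshots plus recorded ground-truth DBC values."""

    frame: np.ndarray  # (n_snapshots, n_frame, 3)
    glycerol: np.ndarray  # (n_snapshots, n_glycerol, 3)
    true_dbc: np.ndarray  # (n_snapshots,)


def gen_site_coords(scenario: SiteGeometryScenario) -> SiteSnapshots:
    """Generate rigid-transformed snapshots with known DBC ground truth."""
    scenario.validate()
    rng = np.random.default_rng((_STREAM_GEOM, scenario.seed))
    nf = len(scenario.frame_coords)
    ng = len(scenario.glycerol_coords)
    frame_out = np.empty((scenario.n_snapshots, nf, 3))
    gly_out = np.empty((scenario.n_snapshots, ng, 3))
    true_dbc = np.empty(scenario.n_snapshots)
    for s in range(scenario.n_snapshots):
        if scenario.random_rigid:
            R = random_rotation(rng)
            t = rng.normal(0.0, 10.0, size=3)
        else:
            R = scenario.rigid_rotation
            t = scenario.translation
        disp = np.broadcast_to(scenario.glycerol_offset, (ng, 3)).copy()
        if scenario.jitter_sd > 0:
            disp += rng.normal(0.0, scenario.jitter_sd, size=(ng, 3))
        gly = scenario.glycerol_coords + disp
        frame_out[s] = scenario.frame_coords @ R.T + t
        gly_out[s] = gly @ R.T + t
        true_dbc[s] = np.sqrt(np.mean(np.sum(disp**2, axis=1)))
    return SiteSnapshots(frame=frame_out, glycerol=gly_out, true_dbc=true_dbc)
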