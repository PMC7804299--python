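"""Small shared helpers: seed derivation and rigid-transform sampling."""

from __future__ import annotations

import hashlib

import numpy as np

MAX_SEED = 2**31 - 1


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed from a master seed and a stage name.

    Hashing the stage name together with the master seed means adding a new
    stage never perturbs the random streams of existing stages.
    """
    digest = hashlib.sha256(f"{stage}:{int(master_seed)}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % MAX_SEED


def random_rotation(rng: np.random.Generator, max_angle_deg: float) -> np.ndarray:
    """Proper rotation matrix (det = +1) about a uniform random axis.

    The rotation angle is uniform on [0, max_angle_deg] degrees.
    """
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(0.0, max_angle_deg))
    k = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(angle) * k + (1.0 - np.cos(angle)) * (k @ k)
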