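"""Rigid transforms as 4x4 homogeneous matrices, degree-based rotation helpers."""

from __future__ import annotations

import numpy as np

__all__ = [
    "identity",
    "rot_x",
    "rot_y",
    "rot_z",
    "translation",
    "rotation_about",
    "apply_transform",
    "compose",
    "invert",
    "joint_rotation",
    "mirror_z",
    "random_rotation",
]


def identity() -> np.ndarray:
    return np.eye(4)


def _embed(R: np.ndarray) -> np.ndarray:
    T = np.eye(4)
    T[:3, :3] = R
    return T


def rot_x(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return _embed(np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float))


def rot_y(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return _embed(np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float))


def rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return _embed(np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float))


def translation(t) -> np.ndarray:
    T = np.eye(4)
    T[:3, 3] = np.asarray(t, dtype=float)
    return T


def rotation_about(R4: np.ndarray, center) -> np.ndarray:
    """Rotation (4x4, origin-centred) re-centred about ``center``."""
    return compose(translation(center), R4, translation(-np.asarray(center, dtype=float)))


def compose(*Ts: np.ndarray) -> np.ndarray:
    out = np.eye(4)
    for T in Ts:
        out = out @ T
    return out


def invert(T: np.ndarray) -> np.ndarray:
    R = T[:3, :3]
    out = np.eye(4)
    out[:3, :3] = R.T
    out[:3, 3] = -R.T @ T[:3, 3]
    return out


def apply_transform(T: np.ndarray, points: np.ndarray) -> np.ndarray:
    points = np.asarray(points, dtype=float)
    return points @ T[:3, :3].T + T[:3, 3]


def joint_rotation(roll: float, yaw: float, pitch: float) -> np.ndarray:
    """Intrinsic roll->yaw->pitch rotation in the joint frame.

    Roll is applied first about the joint x-axis, then yaw about the rotated
    y-axis, then pitch about the rotated z-axis; as a single matrix in the
    original frame this is Rx(roll) @ Ry(yaw) @ Rz(pitch).
    """
    return compose(rot_x(roll), rot_y(yaw), rot_z(pitch))


def mirror_z() -> np.ndarray:
    T = np.eye(4)
    T[2, 2] = -1.0
    return T


def random_rotation(rng: np.random.Generator, max_deg: float) -> np.ndarray:
    """Uniform random axis, rotation angle uniform in [0, max_deg]."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = np.radians(rng.uniform(0.0, max_deg))
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
    return _embed(R)
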