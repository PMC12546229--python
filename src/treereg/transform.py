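"""Homogeneous rigid transforms (4x4) with the source-to-target convention.

A transform T maps homogeneous source coordinates into the target frame:
[q 1]^T = T [p 1]^T. The rotation block must be orthonormal with det +1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class RigidTransform:
    """A 4x4 homogeneous rigid-body transform."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (4, 4):
            raise ValueError(f"transform must be 4x4, got {m.shape}")
        if not np.allclose(m[3], (0.0, 0.0, 0.0, 1.0), atol=1e-9):
            raise ValueError("bottom row must be (0, 0, 0, 1)")
        R = m[:3, :3]
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation block is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation block has negative determinant (reflection)")
        object.__setattr__(self, "matrix", m)

    # -- constructors ------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_rt(cls, R: np.ndarray, t: np.ndarray) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = R
        m[:3, 3] = np.asarray(t, dtype=np.float64).reshape(3)
        return cls(m)

    @classmethod
    def translation_only(cls, t: np.ndarray) -> "RigidTransform":
        return cls.from_rt(np.eye(3), t)

    @classmethod
    def rot_z(cls, alpha: float, center: np.ndarray | None = None) -> "RigidTransform":
        """Rotation by ``alpha`` about the vertical line through ``center``.

        With center O = (x_o, y_o), the translation part is
        (x_o (1 - cos a) + y_o sin a, y_o (1 - cos a) - x_o sin a, 0),
        i.e. Trans(O) . Rz(a) . Trans(-O).
        """
        c, s = np.cos(alpha), np.sin(alpha)
        R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        if center is None:
            t = np.zeros(3)
        else:
            xo, yo = float(center[0]), float(center[1])
            t = np.array([xo * (1.0 - c) + yo * s,
                          yo * (1.0 - c) - xo * s,
                          0.0])
        return cls.from_rt(R, t)

    # -- accessors ---------------------------------------------------
    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    # -- algebra -----------------------------------------------------
    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return RigidTransform(self.matrix @ other.matrix)

    def inverse(self) -> "RigidTransform":
        R = self.rotation.T
        return RigidTransform.from_rt(R, -R @ self.translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (N, 3) array of points into the target frame."""
        pts = np.asarray(points, dtype=np.float64)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        out = pts @ self.rotation.T + self.translation
        return out[0] if single else out

    # -- serialization -----------------------------------------------
    def to_json_dict(self) -> dict:
        return {"matrix": [float(v) for v in self.matrix.reshape(-1)]}

    @classmethod
    def from_json_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.array(d["matrix"], dtype=np.float64).reshape(4, 4))

    def save_text(self, path: str) -> None:
        """Plain-text 4x4 matrix, one row per line."""
        np.savetxt(path, self.matrix, fmt="%.17g")

    @classmethod
    def load_text(cls, path: str) -> "RigidTransform":
        return cls(np.loadtxt(path).reshape(4, 4))

    def save_json(self, path: str, extra: dict | None = None) -> None:
        d = self.to_json_dict()
        if extra:
            d.update(extra)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)
            fh.write("\n")

    @classmethod
    def load_json(cls, path: str) -> "RigidTransform":
        with open(path) as fh:
            return cls.from_json_dict(json.load(fh))
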