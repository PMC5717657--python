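"""Geometric morphometrics: Procrustes alignment and shape variables.

Raw 2-D landmark configurations are superimposed by generalized
Procrustes analysis (GPA: translation removed, centroid size scaled to
one, rotation fitted — reflection disallowed), then summarised by a
principal-component decomposition of the flattened aligned coordinates.
The number of PC axes carrying interpretable shape variation is chosen
with the broken-stick rule, with an explicit override for analyses that
fix the axis count a priori.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .trees import InputError

__all__ = [
    "LandmarkConfiguration",
    "AlignedShape",
    "ShapeSpace",
    "generalized_procrustes",
    "principal_components",
    "broken_stick_select",
    "optimal_rotation",
    "read_tps",
    "write_tps",
    "read_scores_csv",
    "write_scores_csv",
]


@dataclass
class LandmarkConfiguration:
    """One specimen's raw 2-D landmarks, in arbitrary image units."""

    specimen_id: str
    coords: np.ndarray  # (k, 2)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise InputError(
                f"{self.specimen_id}: coords must be (k, 2), got {self.coords.shape}")
        if self.coords.shape[0] < 3:
            raise InputError(f"{self.specimen_id}: need at least 3 landmarks")
        if not np.all(np.isfinite(self.coords)):
            raise InputError(f"{self.specimen_id}: non-finite coordinates")

    @property
    def k(self) -> int:
        return self.coords.shape[0]


@dataclass
class AlignedShape:
    """Procrustes-aligned configuration: centroid at origin, size one."""

    specimen_id: str
    coords: np.ndarray  # (k, 2)


@dataclass
class ShapeSpace:
    """PC decomposition of aligned shapes.

    ``scores`` are the centered data projected on the orthonormal
    ``loadings``; ``eigenvalues`` are per-axis sample variances (n-1
    denominator) in descending order; ``mean_shape`` is the (k, 2) mean
    of the aligned coordinates.
    """

    scores: np.ndarray       # (n, p)
    eigenvalues: np.ndarray  # (p,)
    mean_shape: np.ndarray   # (k, 2)
    loadings: np.ndarray     # (2k, p), orthonormal columns
    n_retained: int
    specimen_ids: list = field(default_factory=list)

    @property
    def retained_scores(self) -> np.ndarray:
        return self.scores[:, : self.n_retained]


def _center_and_scale(coords: np.ndarray, specimen_id: str) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    size = np.sqrt((centered ** 2).sum())
    if size < 1e-300:
        raise InputError(
            f"degenerate configuration {specimen_id!r}: zero centroid size")
    return centered / size


def optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation matrix R (no reflection) minimising |source @ R - target|.

    Standard orthogonal-Procrustes solution via SVD of the 2x2
    cross-product matrix, with the determinant sign corrected so the
    result is a proper rotation.
    """
    h = source.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    corr = np.diag([1.0, d])
    return u @ corr @ vt


def generalized_procrustes(
    configs: Sequence[LandmarkConfiguration],
    tol: float = 1e-10,
    max_iter: int = 100,
) -> tuple[list[AlignedShape], np.ndarray]:
    """Generalized Procrustes superimposition of 2-D configurations.

    Each configuration is centered, scaled to unit centroid size and
    rotated to the current consensus; the consensus is re-estimated until
    it moves by less than ``tol`` or ``max_iter`` is reached (with a
    warning).  Returns the aligned shapes and the consensus mean shape.
    """
    if len(configs) < 2:
        raise InputError("need at least 2 configurations")
    ks = {c.k for c in configs}
    if len(ks) != 1:
        raise InputError(f"landmark-count mismatch across configurations: {sorted(ks)}")

    shapes = [_center_and_scale(c.coords, c.specimen_id) for c in configs]

    # initial consensus: the plain average of the pre-scaled shapes, so
    # re-aligning an already-aligned sample is a no-op (idempotence);
    # if random orientations nearly cancel the average, fall back to the
    # first shape as reference
    mean = np.mean(shapes, axis=0)
    norm = np.sqrt((mean ** 2).sum())
    if norm > 1e-6:
        mean = (mean - mean.mean(axis=0)) / norm
    else:
        mean = shapes[0].copy()
    for _ in range(max_iter):
        rotated = []
        for s, cfg in zip(shapes, configs):
            r = optimal_rotation(s, mean)
            if np.linalg.det(s.T @ mean) < 0:
                warnings.warn(
                    f"configuration {cfg.specimen_id!r} fits the consensus "
                    "better with a reflection, which is disallowed; fitted "
                    "rotation-only", stacklevel=2)
            rotated.append(s @ r)
        new_mean = np.mean(rotated, axis=0)
        new_mean = new_mean - new_mean.mean(axis=0)
        new_mean = new_mean / np.sqrt((new_mean ** 2).sum())
        shapes = rotated
        if np.abs(new_mean - mean).max() < tol:
            mean = new_mean
            break
        mean = new_mean
    else:
        warnings.warn(f"GPA did not converge in {max_iter} iterations",
                      stacklevel=2)

    aligned = [AlignedShape(cfg.specimen_id, s)
               for cfg, s in zip(configs, shapes)]
    return aligned, mean


def principal_components(shapes: Sequence[AlignedShape]) -> ShapeSpace:
    """PCA of flattened aligned coordinates (sample covariance, n-1).

    Performed by SVD of the centered (x1, y1, ..., xk, yk) data matrix;
    the eigenvalue sum equals the total sample variance of the aligned
    data, and at most 2k-4 eigenvalues are non-zero after GPA (two
    translations, one rotation and one scale removed).
    """
    if len(shapes) < 3:
        raise InputError("need at least 3 shapes for PCA")
    ids = [s.specimen_id for s in shapes]
    flat = np.array([s.coords.ravel() for s in shapes])
    n = flat.shape[0]
    mean_flat = flat.mean(axis=0)
    centered = flat - mean_flat
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = s ** 2 / (n - 1)
    loadings = vt.T
    scores = centered @ loadings
    k = shapes[0].coords.shape[0]
    return ShapeSpace(
        scores=scores,
        eigenvalues=eigenvalues,
        mean_shape=mean_flat.reshape(k, 2),
        loadings=loadings,
        n_retained=max(int(np.sum(eigenvalues > 0)), 1),
        specimen_ids=ids,
    )


def broken_stick_expected(p: int) -> np.ndarray:
    """Expected eigenvalue proportions b_j = (1/p) * sum_{i=j..p} 1/i."""
    inv = 1.0 / np.arange(1, p + 1)
    return np.cumsum(inv[::-1])[::-1] / p


def broken_stick_select(eigenvalues: Sequence[float]) -> int:
    """Number of leading axes whose proportion of variance exceeds the
    broken-stick expectation (strict inequality; ties do not count).

    Returns the length of the leading contiguous run of such axes, with
    a floor of 1 so at least one axis is always retained.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size == 0 or np.any(lam < -1e-12):
        raise InputError("eigenvalues must be non-negative")
    total = lam.sum()
    if total <= 0:
        raise InputError("all eigenvalues are zero")
    props = lam / total
    expected = broken_stick_expected(lam.size)
    n = 0
    for obs, exp in zip(props, expected):
        if obs > exp:
            n += 1
        else:
            break
    return max(n, 1)


# ----------------------------------------------------------------------
# TPS and CSV I/O
# ----------------------------------------------------------------------

def read_tps(path) -> list[LandmarkConfiguration]:
    """Read a TPS landmark file.

    Supports ``LM=k`` blocks of ``x y`` coordinate lines, ``ID=`` (or
    ``IMAGE=``) specimen identifiers and ``SCALE=`` factors applied
    multiplicatively to the block's coordinates.
    """
    configs: list[LandmarkConfiguration] = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    i = 0
    block_no = 0
    while i < len(lines):
        line = lines[i]
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise InputError(f"{path}: line {i + 1}: expected LM=, got {line!r}")
        try:
            k = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise InputError(f"{path}: line {i + 1}: bad LM count") from exc
        i += 1
        coords = []
        for j in range(k):
            if i >= len(lines):
                raise InputError(f"{path}: unexpected EOF in landmark block")
            parts = lines[i].split()
            if len(parts) != 2:
                raise InputError(
                    f"{path}: line {i + 1}: expected 'x y', got {lines[i]!r}")
            coords.append([float(parts[0]), float(parts[1])])
            i += 1
        spec_id = None
        scale = 1.0
        while i < len(lines) and lines[i] and not lines[i].upper().startswith("LM="):
            key, _, value = lines[i].partition("=")
            key = key.strip().upper()
            if key in ("ID", "IMAGE") and spec_id is None:
                spec_id = value.strip()
            elif key == "SCALE":
                scale = float(value)
            i += 1
        if spec_id is None:
            spec_id = f"specimen_{block_no}"
        configs.append(
            LandmarkConfiguration(spec_id, np.asarray(coords) * scale))
        block_no += 1
    return configs


def write_tps(path, configs: Sequence[LandmarkConfiguration]) -> None:
    with open(path, "w") as fh:
        for cfg in configs:
            fh.write(f"LM={cfg.k}\n")
            for x, y in cfg.coords:
                fh.write(f"{float(x)!r} {float(y)!r}\n")
            fh.write(f"ID={cfg.specimen_id}\n")


def write_scores_csv(path, space: ShapeSpace, n_axes: Optional[int] = None) -> None:
    n_axes = n_axes or space.scores.shape[1]
    cols = [f"PC{i + 1}" for i in range(n_axes)]
    df = pd.DataFrame(space.scores[:, :n_axes], columns=cols)
    df.insert(0, "specimen_id", space.specimen_ids)
    df.to_csv(path, index=False)


def read_scores_csv(path) -> pd.DataFrame:
    """Read precomputed PC scores: specimen_id column + PC1..PCp."""
    df = pd.read_csv(path)
    if "specimen_id" not in df.columns:
        raise InputError(f"{path}: missing 'specimen_id' column")
    return df.set_index("specimen_id")
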