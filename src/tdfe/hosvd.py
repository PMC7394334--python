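"""Higher-order singular value decomposition (Tucker form) of the expression tensor.

The factor matrix of each mode holds the left singular vectors of that mode's
unfolding; the core tensor is the data tensor contracted with every factor
transposed.  With all components retained the decomposition is exact, and the
squared core entries partition the tensor's total energy — which is what the
cumulative-contribution truncation rule exploits.

Modes and components are 1-based in the public API, matching the field's
notation (the "second dose-dependence singular value vector" is component 2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import DegenerateInputError
from .io import ExpressionTensor


def _as_array(tensor) -> np.ndarray:
    if isinstance(tensor, ExpressionTensor):
        return tensor.values
    return np.asarray(tensor, dtype=float)


def unfold(tensor, mode: int) -> np.ndarray:
    """Mode-n unfolding: mode ``mode`` (1-based) as rows, remaining indices as
    columns in C order of the other modes."""
    x = _as_array(tensor)
    if not 1 <= mode <= x.ndim:
        raise ValueError(f"mode must be in 1..{x.ndim}, got {mode}")
    return np.moveaxis(x, mode - 1, 0).reshape(x.shape[mode - 1], -1)


def fold(matrix: np.ndarray, mode: int, shape: Sequence[int]) -> np.ndarray:
    """Inverse of :func:`unfold` for a tensor of the given shape."""
    shape = tuple(shape)
    if not 1 <= mode <= len(shape):
        raise ValueError(f"mode must be in 1..{len(shape)}, got {mode}")
    rest = shape[: mode - 1] + shape[mode:]
    return np.moveaxis(np.reshape(matrix, (shape[mode - 1],) + rest), 0, mode - 1)


def mode_dot(tensor: np.ndarray, matrix: np.ndarray, mode: int) -> np.ndarray:
    """Multiply ``tensor`` along 1-based ``mode`` by ``matrix`` (rows index output)."""
    x = _as_array(tensor)
    return np.moveaxis(np.tensordot(matrix, x, axes=(1, mode - 1)), 0, mode - 1)


@dataclass
class HOSVDResult:
    """Core tensor, per-mode factor matrices and unfolding singular values.

    ``factors[m]`` has shape (components, items) with orthonormal rows, ordered
    by decreasing singular value of mode ``m+1``'s unfolding.
    """

    core: np.ndarray
    factors: list[np.ndarray]
    singular_values: list[np.ndarray]

    @property
    def factor_dose(self) -> np.ndarray:
        return self.factors[0]

    @property
    def factor_compound(self) -> np.ndarray:
        return self.factors[1]

    @property
    def factor_gene(self) -> np.ndarray:
        return self.factors[2]

    def reconstruct(self) -> np.ndarray:
        x = self.core
        for m, f in enumerate(self.factors, start=1):
            x = mode_dot(x, f.T, m)
        return x

    def save(self, out_dir: str | Path) -> None:
        """Serialize to a directory of TSV matrices plus JSON metadata."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        np.savetxt(out_dir / "core_mode1_unfolding.tsv", unfold(self.core, 1), delimiter="\t")
        for m, f in enumerate(self.factors, start=1):
            np.savetxt(out_dir / f"factor_mode{m}.tsv", f, delimiter="\t")
        meta = {
            "core_shape": list(self.core.shape),
            "singular_values": [sv.tolist() for sv in self.singular_values],
        }
        (out_dir / "hosvd_meta.json").write_text(json.dumps(meta, indent=2))


def _orient_signs(core: np.ndarray, factors: list[np.ndarray]) -> None:
    # deterministic orientation: largest-|loading| entry of each component positive
    for m, f in enumerate(factors):
        for k in range(f.shape[0]):
            idx = int(np.argmax(np.abs(f[k])))
            if f[k, idx] < 0:
                f[k] *= -1.0
                sl = [slice(None)] * core.ndim
                sl[m] = k
                core[tuple(sl)] *= -1.0


def hosvd(tensor) -> HOSVDResult:
    """Economy-size HOSVD of a complete tensor (any number of modes >= 2)."""
    x = _as_array(tensor)
    if not np.all(np.isfinite(x)):
        raise DegenerateInputError("tensor contains non-finite values")
    if x.ndim < 2:
        raise ValueError("need at least two modes")

    factors: list[np.ndarray] = []
    singular_values: list[np.ndarray] = []
    for mode in range(1, x.ndim + 1):
        u, s, _ = np.linalg.svd(unfold(x, mode), full_matrices=False)
        factors.append(u.T.copy())
        singular_values.append(s)

    core = x
    for mode, f in enumerate(factors, start=1):
        core = mode_dot(core, f, mode)
    _orient_signs(core, factors)
    return HOSVDResult(core=core, factors=factors, singular_values=singular_values)


def cumulative_contribution(result: HOSVDResult, K1: int, K2: int, K3: int) -> float:
    """Energy fraction of the leading (K1, K2, K3) core block.

    Returns sum_{k1<=K1,k2<=K2,k3<=K3} G^2 / sum_all G^2.
    """
    dims = result.core.shape
    for K, d, name in zip((K1, K2, K3), dims, ("K1", "K2", "K3")):
        if not 1 <= K <= d:
            raise ValueError(f"{name}={K} outside 1..{d}")
    total = float(np.sum(result.core**2))
    if total == 0.0:
        raise DegenerateInputError("all-zero core tensor")
    return float(np.sum(result.core[:K1, :K2, :K3] ** 2) / total)
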