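"""GGE biplots: genotype main effect + genotype-by-environment interaction.

A genotype x environment table of trait means (or BLUPs) is centred by
environment (column) means — removing the environment main effect so that
what remains is G + GxE — and decomposed by SVD.  The first two components
give 2-D genotype scores and environment loadings; with the symmetric
singular-value partition (f = 0.5) the angle between two environment
vectors reflects their correlation and a vector's length how much G + GxE
the environment discriminates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ScalingError

__all__ = ["GGEModel", "build_gge", "env_vector_angle", "env_vector_length"]


@dataclass
class GGEModel:
    genotypes: list[str]
    environments: list[str]
    centred: np.ndarray              # genotypes x environments
    singular_values: np.ndarray      # descending, >= 0
    scores: np.ndarray               # genotypes x k,   U S^f
    loadings: np.ndarray             # environments x k, V S^(1-f)
    proportion: np.ndarray           # variance share per component
    partition: float

    def reconstruct(self, rank: int | None = None) -> np.ndarray:
        """Recombine scores and loadings (undoing the f-partition)."""
        k = len(self.singular_values) if rank is None else rank
        s = self.singular_values[:k]
        safe = np.where(s > 0, s, 1.0)
        u = self.scores[:, :k] / safe ** self.partition
        v = self.loadings[:, :k] / safe ** (1.0 - self.partition)
        return (u * s) @ v.T


def build_gge(
    table: pd.DataFrame,
    scaling: str = "none",
    partition: float = 0.5,
) -> GGEModel:
    """Environment-centred SVD of a genotype x environment table.

    ``scaling='sd'`` additionally divides each centred column by its
    standard deviation (raises :class:`ScalingError` on a constant
    column).  Missing cells are imputed with the environment mean.  The
    sign of each component is fixed so the first environment's loading is
    non-negative, making repeated runs identical.
    """
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need >= 2 genotypes and >= 2 environments")
    M = table.to_numpy(dtype=float).copy()
    col_means = np.nanmean(M, axis=0)
    nan_r, nan_c = np.where(np.isnan(M))
    if len(nan_r):
        M[nan_r, nan_c] = col_means[nan_c]
    C = M - M.mean(axis=0)
    if scaling == "sd":
        sd = C.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = [str(table.columns[i]) for i in np.flatnonzero(sd == 0)]
            raise ScalingError(f"constant environment column(s): {bad}")
        C = C / sd
    elif scaling != "none":
        raise ValueError(f"unknown scaling {scaling!r}")
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    V = Vt.T
    # deterministic sign: first environment's loading non-negative per component
    flip = np.where(V[0, :] < 0, -1.0, 1.0)
    U, V = U * flip, V * flip
    total = float(np.sum(s**2))
    prop = s**2 / total if total > 0 else np.zeros_like(s)
    return GGEModel(
        genotypes=[str(g) for g in table.index],
        environments=[str(e) for e in table.columns],
        centred=C,
        singular_values=s,
        scores=U * s**partition,
        loadings=V * s ** (1.0 - partition),
        proportion=prop,
        partition=partition,
    )


def _loading2d(model: GGEModel, env: str) -> np.ndarray:
    i = model.environments.index(str(env))
    return model.loadings[i, :2]


def env_vector_angle(model: GGEModel, env_a: str, env_b: str) -> float:
    """Angle (degrees, [0, 180]) between two 2-D environment vectors."""
    va, vb = _loading2d(model, env_a), _loading2d(model, env_b)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("zero-length environment vector; angle undefined")
    cos = np.clip(float(va @ vb) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def env_vector_length(model: GGEModel, env: str) -> float:
    """Euclidean norm of the 2-D environment loading."""
    return float(np.linalg.norm(_loading2d(model, env)))
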