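"""K-select analysis: marginality vectors and their weighted eigenanalysis.

For each animal the marginality vector m is the difference between the mean
standardized habitat conditions at its used resource units and the mean over
the units available to it; its squared norm ||m||^2 measures the strength of
selection.  The K-select step performs a non-centred weighted eigenanalysis
of the animals' marginality vectors,

    C = sum_k w_k m_k m_k^T,

whose eigenvalues partition the weighted mean squared marginality
(sum lambda = sum_k w_k ||m_k||^2) and whose leading axes describe the
directions of selection shared across animals.

Significance is assessed by randomization: used sets of the observed size are
redrawn without replacement from the animal's available units, marginality is
recomputed, and the add-one p-value (1 + #{||m*||^2 >= ||m||^2}) / (N + 1)
is reported.  The first-eigenvalue test redraws every animal simultaneously.
EGVs are standardized globally (mean 0, sd 1 over all study-area RUs) before
any marginality computation so that components are comparable across
variables with different units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


def standardize(
    rut: pd.DataFrame, columns: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardize EGV columns to mean 0, sd 1 over all study-area RUs.

    Constant columns are dropped with a warning.  Returns the standardized
    table (indexed by ru_id when present) and a (mean, sd) table per EGV.
    """
    if columns is None:
        columns = [c for c in rut.columns if c not in ("ru_id", "x", "y", "zone")]
    data = rut[columns].to_numpy(dtype=float)
    mean = data.mean(axis=0)
    sd = data.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all EGV columns are constant")
    if not keep.all():
        dropped = [c for c, k in zip(columns, keep) if not k]
        warnings.warn(f"constant EGV columns dropped: {dropped}")
    cols = [c for c, k in zip(columns, keep) if k]
    z = (data[:, keep] - mean[keep]) / sd[keep]
    ztab = pd.DataFrame(z, columns=cols)
    if "ru_id" in rut.columns:
        ztab.index = pd.Index(rut["ru_id"], name="ru_id")
    stats_tab = pd.DataFrame({"mean": mean[keep], "sd": sd[keep]}, index=cols)
    return ztab, stats_tab


@dataclass
class MarginalityVector:
    animal_id: str
    period: str
    m: pd.Series            # per standardized EGV
    n_used: int
    n_available: int
    p_value: float | None = None

    @property
    def squared_norm(self) -> float:
        return float((self.m**2).sum())


def marginality(
    used_ids: np.ndarray,
    available_ids: np.ndarray,
    ztab: pd.DataFrame,
    animal_id: str = "",
    period: str = "",
) -> MarginalityVector:
    """Marginality vector: mean used minus mean available, per EGV.

    ``ztab`` is the globally standardized RU table indexed by ru_id; used RUs
    must be a subset of the available RUs.
    """
    available_ids = np.asarray(available_ids)
    used_ids = np.asarray(used_ids)
    if available_ids.size == 0:
        raise ValueError(f"animal {animal_id!r}: empty availability")
    if used_ids.size == 0:
        raise ValueError(f"animal {animal_id!r}: no used RUs")
    if not np.isin(np.unique(used_ids), available_ids).all():
        raise ValueError(f"animal {animal_id!r}: used RUs outside availability")
    m = ztab.loc[used_ids].mean(axis=0) - ztab.loc[available_ids].mean(axis=0)
    return MarginalityVector(
        animal_id, period, m, int(used_ids.size), int(available_ids.size)
    )


@dataclass
class KSelectResult:
    eigenvalues: np.ndarray
    loadings: pd.DataFrame       # EGV x axis, orthonormal columns
    scores: pd.DataFrame         # animal x axis
    percent_marginality: np.ndarray
    weights: np.ndarray
    first_eigenvalue_p: float | None = None


def kselect_eigen(
    vectors: list[MarginalityVector],
    weights: np.ndarray | None = None,
) -> KSelectResult:
    """Weighted non-centred eigenanalysis of the marginality table.

    ``weights`` default to uniform (1/K); weighting by relocation count is
    obtained by passing each animal's n_used (weights are renormalized).
    """
    if not vectors:
        raise ValueError("no marginality vectors supplied")
    p = len(vectors[0].m)
    if any(len(v.m) != p for v in vectors):
        raise ValueError("marginality vectors have mismatched dimensions")
    K = len(vectors)
    if weights is None:
        w = np.full(K, 1.0 / K)
    else:
        w = np.asarray(weights, dtype=float)
        if w.size != K or (w < 0).any():
            raise ValueError("weights must be K non-negative numbers")
        w = w / w.sum()
    M = np.vstack([v.m.to_numpy() for v in vectors])  # K x p
    C = (M * w[:, None]).T @ M
    eigval, eigvec = np.linalg.eigh(C)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    axes = [f"axis{i + 1}" for i in range(p)]
    egvs = list(vectors[0].m.index)
    loadings = pd.DataFrame(eigvec, index=egvs, columns=axes)
    scores = pd.DataFrame(
        M @ eigvec, index=[v.animal_id for v in vectors], columns=axes
    )
    total = eigval.sum()
    pct = 100.0 * eigval / total if total > 0 else np.zeros(p)
    return KSelectResult(eigval, loadings, scores, pct, w)


def bonferroni_alpha(alpha: float, n_tests: int) -> float:
    """Per-test significance level alpha / K for K simultaneous tests."""
    if n_tests < 1:
        raise ValueError("need at least one test")
    return alpha / n_tests


def marginality_randomization(
    used_ids: np.ndarray,
    available_ids: np.ndarray,
    ztab: pd.DataFrame,
    n_randomizations: int = 10_000,
    rng: np.random.Generator | int | None = None,
    animal_id: str = "",
) -> tuple[float, np.ndarray]:
    """Randomization test of one animal's marginality.

    Draws ``n_randomizations`` used sets of the observed size without
    replacement from the available RUs, recomputes ||m*||^2, and returns the
    add-one p-value (1 + #{||m*||^2 >= obs}) / (N + 1) with the null sample.
    Ties count as exceedances (conservative).
    """
    rng = np.random.default_rng(rng)
    used_ids = np.asarray(used_ids)
    available_ids = np.asarray(available_ids)
    n_used, n_avail = used_ids.size, available_ids.size
    if n_used >= n_avail:
        raise ValueError(
            f"animal {animal_id!r}: used count ({n_used}) must be smaller "
            f"than available count ({n_avail})"
        )
    Z = ztab.loc[available_ids].to_numpy()
    avail_mean = Z.mean(axis=0)
    obs = marginality(used_ids, available_ids, ztab, animal_id).squared_norm
    null = np.empty(n_randomizations)
    for r in range(n_randomizations):
        idx = rng.choice(n_avail, size=n_used, replace=False)
        m = Z[idx].mean(axis=0) - avail_mean
        null[r] = float(m @ m)
    p = (1.0 + np.count_nonzero(null >= obs)) / (n_randomizations + 1.0)
    return p, null


def first_eigenvalue_test(
    animals: list[tuple[np.ndarray, np.ndarray]],
    ztab: pd.DataFrame,
    n_randomizations: int = 1_000,
    rng: np.random.Generator | int | None = None,
    weights: np.ndarray | None = None,
) -> tuple[float, float, np.ndarray]:
    """Randomization test of the first K-select eigenvalue.

    ``animals`` is a list of (used_ids, available_ids) pairs.  Each
    randomization redraws every animal's used set simultaneously and
    recomputes lambda_1.  Returns (p, observed lambda_1, null sample).
    """
    rng = np.random.default_rng(rng)
    K = len(animals)
    if K == 0:
        raise ValueError("no animals supplied")
    if weights is None:
        w = np.full(K, 1.0 / K)
    else:
        w = np.asarray(weights, dtype=float) / np.sum(weights)

    Zs, means, n_useds, obs_vecs = [], [], [], []
    for used_ids, avail_ids in animals:
        used_ids, avail_ids = np.asarray(used_ids), np.asarray(avail_ids)
        if used_ids.size >= avail_ids.size:
            raise ValueError("used count must be smaller than available count")
        Z = ztab.loc[avail_ids].to_numpy()
        Zs.append(Z)
        means.append(Z.mean(axis=0))
        n_useds.append(used_ids.size)
        obs_vecs.append(ztab.loc[used_ids].to_numpy().mean(axis=0) - means[-1])

    def lam1(M: np.ndarray) -> float:
        C = (M * w[:, None]).T @ M
        return float(np.linalg.eigvalsh(C)[-1])

    obs = lam1(np.vstack(obs_vecs))
    null = np.empty(n_randomizations)
    for r in range(n_randomizations):
        rows = []
        for Z, mu, n_used in zip(Zs, means, n_useds):
            idx = rng.choice(Z.shape[0], size=n_used, replace=False)
            rows.append(Z[idx].mean(axis=0) - mu)
        null[r] = lam1(np.vstack(rows))
    p = (1.0 + np.count_nonzero(null >= obs)) / (n_randomizations + 1.0)
    return p, obs, null
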