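"""Three-method applicability-domain (AD) ensemble with a union rule.

A prediction is only trusted where the model has seen comparable
chemistry.  Three complementary definitions of "comparable" are used:

* similarity — max Tanimoto similarity of the query's 166-key MACCS
  fingerprint to any training compound, inside iff >= ``tanimoto_min``
  (default 0.3; the threshold is on similarity = 1 − Tanimoto distance);
* euclidean — distance to the nearest training point in modified-
  descriptor space, inside iff <= mean + k·SD of the training set's own
  nearest-neighbor distances (k default 3);
* leverage — h = xᵀ(XᵀX)⁻¹x against the warning limit h* = 3(k+1)/n,
  with k the number of model columns and n the training rows.

A compound is inside the AD if at least one method accepts it (union
rule), which makes the verdict monotone under relaxing any threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ADReference", "ADVerdict", "build_ad_reference", "ad_verdict", "leverage_hstar", "training_leverages"]


def leverage_hstar(k: int, n: int) -> float:
    """Leverage warning limit h* = 3(k+1)/n."""
    return 3.0 * (k + 1) / n


@dataclass(frozen=True)
class ADVerdict:
    """Per-method inside/outside booleans; overall = OR of the three."""

    similarity: bool
    euclidean: bool
    leverage: bool

    @property
    def inside(self) -> bool:
        return self.similarity or self.euclidean or self.leverage


@dataclass
class ADReference:
    """Training-set reference data for all three AD methods."""

    fingerprints: np.ndarray  # (n, 166) 0/1
    X: np.ndarray  # (n, k) training modified descriptors
    columns: tuple
    xtx_pinv: np.ndarray
    n: int
    k: int
    leverage_enabled: bool
    nn_mean: float
    nn_sd: float
    thresholds: dict  # tanimoto_min, euclidean_k, leverage_hstar


def build_ad_reference(
    train_fingerprints,
    train_matrix: pd.DataFrame,
    tanimoto_min: float = 0.3,
    euclidean_k: float = 3.0,
) -> ADReference:
    """Build the AD reference from the training set.

    Leverage is disabled (with a warning) when n <= k + 1, where the
    pseudo-inverse projection is degenerate and h* exceeds 1.
    """
    if isinstance(train_fingerprints, pd.DataFrame):
        fps = train_fingerprints.to_numpy(dtype=float)
    else:
        fps = np.asarray(train_fingerprints, dtype=float)
    X = train_matrix.to_numpy(dtype=float)
    n, k = X.shape
    if n == 0:
        raise ValueError("empty training set")
    if fps.shape[0] != n:
        raise ValueError("fingerprints and matrix row counts differ")

    leverage_enabled = n > k + 1
    if not leverage_enabled:
        warnings.warn(f"leverage AD disabled: n={n} <= k+1={k + 1}")
    xtx_pinv = np.linalg.pinv(X.T @ X)

    if n > 1:
        d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
        np.fill_diagonal(d2, np.inf)
        nn = np.sqrt(d2.min(axis=1))
        nn_mean, nn_sd = float(nn.mean()), float(nn.std(ddof=0))
    else:
        nn_mean, nn_sd = 0.0, 0.0

    return ADReference(
        fingerprints=fps,
        X=X,
        columns=tuple(train_matrix.columns),
        xtx_pinv=xtx_pinv,
        n=n,
        k=k,
        leverage_enabled=leverage_enabled,
        nn_mean=nn_mean,
        nn_sd=nn_sd,
        thresholds={
            "tanimoto_min": float(tanimoto_min),
            "euclidean_k": float(euclidean_k),
            "leverage_hstar": leverage_hstar(k, n),
        },
    )


def _tanimoto_max(fp: np.ndarray, fps: np.ndarray) -> float:
    """Max Tanimoto similarity of one binary fingerprint to a set."""
    fp = fp.astype(bool)
    fps = fps.astype(bool)
    inter = (fps & fp).sum(axis=1)
    union = (fps | fp).sum(axis=1)
    sims = np.where(union > 0, inter / np.maximum(union, 1), 1.0)  # empty vs empty: identical
    return float(sims.max())


def leverage(x: np.ndarray, ref: ADReference) -> float:
    x = np.asarray(x, dtype=float)
    return float(x @ ref.xtx_pinv @ x)


def training_leverages(ref: ADReference) -> np.ndarray:
    """Leverages of the training rows; sums to rank(X) (= k if full rank)."""
    return np.einsum("ij,jk,ik->i", ref.X, ref.xtx_pinv, ref.X)


def ad_verdict(query_fingerprint, query_row, ref: ADReference, thresholds: dict | None = None) -> ADVerdict:
    """AD verdict of one query compound under one model.

    ``query_row`` must carry exactly the reference columns (as a Series
    or aligned array).  ``thresholds`` optionally overrides the stored
    cut-offs (used e.g. for sensitivity analyses).
    """
    th = dict(ref.thresholds)
    if thresholds:
        th.update(thresholds)
    if isinstance(query_row, pd.Series):
        if tuple(query_row.index) != tuple(ref.columns):
            raise ValueError("query columns do not match AD reference columns")
        x = query_row.to_numpy(dtype=float)
    else:
        x = np.asarray(query_row, dtype=float)
        if x.shape[0] != ref.k:
            raise ValueError("query row length does not match AD reference columns")
    fp = np.asarray(query_fingerprint, dtype=float)

    sim_inside = _tanimoto_max(fp, ref.fingerprints) >= th["tanimoto_min"]

    dists = np.linalg.norm(ref.X - x, axis=1)
    eu_inside = float(dists.min()) <= ref.nn_mean + th["euclidean_k"] * ref.nn_sd

    if ref.leverage_enabled:
        lev_inside = leverage(x, ref) <= th["leverage_hstar"]
    else:
        lev_inside = False

    return ADVerdict(bool(sim_inside), bool(eu_inside), bool(lev_inside))
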