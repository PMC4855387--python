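"""Redundancy analysis of the species x driver correlation profile on trait
matrices, and Moran's I spatial autocorrelation screening.

RDA projects a centred multivariate response Y onto the column space of a
standardized predictor matrix X; the constrained proportion is
trace(Yhat' Yhat) / trace(Y' Y) and the constrained axes are the principal
axes of Yhat. Inference is by unrestricted row permutation of X with an
add-one p-value. The partial variant residualizes both Y and X on covariates
Z first and reports the proportion of the Z-residual variance.

Moran's I for island values x with spatial weights w_ij (zero diagonal):

    I = (n / sum_ij w_ij) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2

with null expectation -1/(n-1); inference again by permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# RDA
# ---------------------------------------------------------------------------

@dataclass
class RDAResults:
    """Constrained-ordination summary.

    ``constrained_proportion`` is the fraction of (covariate-residual)
    response variance the predictor matrix explains; eigenvalues are of the
    fitted-value covariance, non-increasing.
    """

    constrained_proportion: float
    eigenvalues: np.ndarray
    species_scores: pd.DataFrame
    trait_scores: pd.DataFrame
    p_perm: float | None
    n_perm: int
    partial: bool = False

    def summary(self) -> str:
        lines = [
            ("Partial redundancy analysis" if self.partial else "Redundancy analysis"),
            f"constrained proportion: {self.constrained_proportion:.3f}"
            + (f"   permutation p = {self.p_perm:.4f} ({self.n_perm} perms)"
               if self.p_perm is not None else ""),
            "axis eigenvalues: "
            + ", ".join(f"{e:.4f}" for e in self.eigenvalues[:5]),
        ]
        return "\n".join(lines)


def _as_matrix(M) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(M, pd.DataFrame):
        return M.to_numpy(dtype=float), list(M.index.astype(str)), list(M.columns.astype(str))
    arr = np.asarray(M, dtype=float)
    return arr, [str(i) for i in range(arr.shape[0])], [str(j) for j in range(arr.shape[1])]


def _standardize(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return Xc / sd


def _project(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return X @ beta


class RDA:
    """Redundancy analysis model: response matrix Y constrained by traits X.

    Rows are species (complete cases); Y columns are centred, X columns
    standardized, so the analysis is invariant to predictor scaling. With
    covariates Z the fit becomes a partial RDA on Z-residuals.
    """

    def __init__(self, Y, X, Z=None):
        self.Y, self.row_names, self.y_names = _as_matrix(Y)
        self.X, _, self.x_names = _as_matrix(X)
        if self.Y.shape[0] != self.X.shape[0]:
            raise ValueError("Y and X must have the same number of rows")
        if Z is not None:
            self.Z, _, _ = _as_matrix(Z)
            if self.Z.shape[1] == 0:
                self.Z = None
        else:
            self.Z = None
        if self.X.shape[0] <= self.X.shape[1]:
            import logging
            logging.getLogger(__name__).warning(
                "n_species <= n_traits: projection is least-norm, proportion -> 1")

    def _prepared(self) -> tuple[np.ndarray, np.ndarray]:
        Yc = self.Y - self.Y.mean(axis=0)
        Xs = _standardize(self.X)
        if self.Z is not None:
            Zs = np.column_stack([np.ones(len(Yc)), _standardize(self.Z)])
            Yc = Yc - _project(Yc, Zs)
            Xs = Xs - _project(Xs, Zs)
        return Yc, Xs

    @staticmethod
    def _proportion(Yc: np.ndarray, Xs: np.ndarray) -> tuple[float, np.ndarray]:
        total = float((Yc ** 2).sum())
        if total <= 0:
            raise ValueError("response matrix is constant; RDA undefined")
        Yhat = _project(Yc, np.column_stack([np.ones(len(Yc)), Xs]))
        return float((Yhat ** 2).sum()) / total, Yhat

    def fit(self, n_perm: int = 999, seed: int | None = None) -> RDAResults:
        Yc, Xs = self._prepared()
        prop, Yhat = self._proportion(Yc, Xs)
        n = Yc.shape[0]
        # constrained axes: SVD of fitted values
        U, s, Vt = np.linalg.svd(Yhat, full_matrices=False)
        eig = (s ** 2) / (n - 1)
        keep = s > 1e-12 * (s[0] if len(s) else 1.0)
        axes = [f"RDA{i + 1}" for i in range(int(keep.sum()))]
        site_scores = U[:, keep] * s[keep]
        species_scores = pd.DataFrame(site_scores, index=self.row_names, columns=axes)
        with np.errstate(invalid="ignore", divide="ignore"):
            trait_corr = np.array([
                [_safe_corr(self.X[:, j], site_scores[:, a]) for a in range(len(axes))]
                for j in range(self.X.shape[1])
            ])
        trait_scores = pd.DataFrame(trait_corr, index=self.x_names, columns=axes)
        p = None
        if n_perm and n_perm > 0:
            if seed is None:
                raise ValueError("seed is required for the permutation test")
            rng = np.random.default_rng(seed)
            hits = 0
            for _ in range(n_perm):
                perm = rng.permutation(n)
                p_stat, _ = self._proportion(Yc, Xs[perm])
                if p_stat >= prop - 1e-12:
                    hits += 1
            p = (1 + hits) / (1 + n_perm)
        return RDAResults(constrained_proportion=prop, eigenvalues=eig[keep],
                          species_scores=species_scores, trait_scores=trait_scores,
                          p_perm=p, n_perm=n_perm or 0, partial=self.Z is not None)


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def rda(Y, X, n_perm: int = 999, seed: int | None = None) -> RDAResults:
    """Functional wrapper: RDA of response matrix Y on predictors X."""
    return RDA(Y, X).fit(n_perm=n_perm, seed=seed)


def partial_rda(Y, X, Z, n_perm: int = 999, seed: int | None = None) -> RDAResults:
    """Partial RDA: residualize Y and X on covariates Z, then RDA."""
    if Z is None or (hasattr(Z, "shape") and np.asarray(Z).size == 0):
        return rda(Y, X, n_perm=n_perm, seed=seed)
    return RDA(Y, X, Z=Z).fit(n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# Moran's I
# ---------------------------------------------------------------------------

@dataclass
class SpatialStat:
    """Moran's I with its permutation p-value and the weight specification."""

    morans_i: float
    expected: float
    p_perm: float | None
    n_perm: int
    weight_spec: dict = field(default_factory=dict)


EARTH_RADIUS_KM = 6371.0088


def great_circle_km(coords: np.ndarray) -> np.ndarray:
    """Pairwise haversine distances (km) for (lat, lon) rows in degrees."""
    lat = np.radians(coords[:, 0])[:, None]
    lon = np.radians(coords[:, 1])[:, None]
    dlat = lat - lat.T
    dlon = lon - lon.T
    a = np.sin(dlat / 2) ** 2 + np.cos(lat) * np.cos(lat.T) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def inverse_distance_weights(coords) -> np.ndarray:
    d = great_circle_km(np.asarray(coords, dtype=float))
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    np.fill_diagonal(w, 0.0)
    if not np.isfinite(w).all():
        raise ValueError("coincident coordinates give non-finite inverse-distance weights")
    return w


def chain_adjacency_weights(order: np.ndarray | list) -> np.ndarray:
    """Binary adjacency along the island chain (neighbours in chain_order)."""
    order = np.asarray(order)
    rank = np.argsort(np.argsort(order))
    n = len(order)
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j and abs(rank[i] - rank[j]) == 1:
                w[i, j] = 1.0
    return w


def _moran_stat(x: np.ndarray, w: np.ndarray) -> float:
    n = len(x)
    z = x - x.mean()
    denom = float(z @ z)
    return float(n / w.sum() * (z @ w @ z) / denom)


def morans_i(values, coords=None, weights=None, n_perm: int = 999,
             seed: int | None = None, tail: str = "greater",
             row_standardize: bool = False) -> SpatialStat:
    """Moran's I with inverse-distance (default) or user-supplied weights.

    ``tail='greater'`` tests for positive spatial autocorrelation (clustered
    diversity); ``'less'`` and ``'two-sided'`` are available. Null
    expectation is -1/(n-1).
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need n >= 4 islands")
    if np.ptp(x) == 0:
        raise ValueError("constant values; Moran's I undefined")
    if weights is None:
        if coords is None:
            raise ValueError("supply coords (lat, lon) or a weight matrix")
        w = inverse_distance_weights(coords)
        spec = {"type": "inverse_great_circle_distance"}
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n, n):
            raise ValueError("weight matrix shape mismatch")
        if np.diagonal(w).any():
            raise ValueError("weight matrix must have zero diagonal")
        if not np.isfinite(w).all():
            raise ValueError("non-finite weight")
        spec = {"type": "user"}
    if row_standardize:
        rs = w.sum(axis=1, keepdims=True)
        rs[rs == 0] = 1.0
        w = w / rs
    spec["row_standardized"] = row_standardize
    spec["tail"] = tail
    obs = _moran_stat(x, w)
    p = None
    if n_perm and n_perm > 0:
        if seed is None:
            raise ValueError("seed is required for the permutation test")
        rng = np.random.default_rng(seed)
        perm_stats = np.empty(n_perm)
        for b in range(n_perm):
            perm_stats[b] = _moran_stat(x[rng.permutation(n)], w)
        if tail == "greater":
            hits = int((perm_stats >= obs - 1e-12).sum())
        elif tail == "less":
            hits = int((perm_stats <= obs + 1e-12).sum())
        elif tail == "two-sided":
            centre = -1.0 / (n - 1)
            hits = int((np.abs(perm_stats - centre) >= abs(obs - centre) - 1e-12).sum())
        else:
            raise ValueError(f"unknown tail {tail!r}")
        p = (1 + hits) / (1 + n_perm)
    return SpatialStat(morans_i=obs, expected=-1.0 / (n - 1), p_perm=p,
                       n_perm=n_perm or 0, weight_spec=spec)
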