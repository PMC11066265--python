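"""Diversity-environment-EMF association statistics.

Mantel and partial Mantel tests (Spearman, permutation p), an environmental
Euclidean distance on Z-scored variables, ordinary least-squares regression
and per-variable Spearman screens. Permutation tests shuffle one matrix's
sample order jointly in rows and columns; all tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from .io_core import ValidationError


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_perm: int
    method: str = "spearman"


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int


def _check_aligned(*dists: DistanceMatrix) -> int:
    ids = list(dists[0].ids)
    for d in dists[1:]:
        if list(d.ids) != ids:
            raise ValidationError("distance matrices have mismatched sample ids")
    if len(ids) < 4:
        raise ValidationError("Mantel tests need at least 4 samples")
    return len(ids)


def _condensed(d: DistanceMatrix) -> np.ndarray:
    return squareform(np.asarray(d.data, dtype=float), checks=False)


def _permuted_condensed(data: np.ndarray, perm: np.ndarray) -> np.ndarray:
    return squareform(data[np.ix_(perm, perm)], checks=False)


def mantel(d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 999,
           seed: int = 0) -> MantelResult:
    """Spearman Mantel test between two distance matrices.

    r is the Spearman correlation of the lower-triangle entries; the
    p-value permutes d2's samples (rows and columns jointly) and is
    two-sided on |r|.
    """
    n = _check_aligned(d1, d2)
    v1 = stats.rankdata(_condensed(d1))
    data2 = np.asarray(d2.data, dtype=float)
    r_obs = _pearson(v1, stats.rankdata(squareform(data2, checks=False)))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_perm = _pearson(v1, stats.rankdata(_permuted_condensed(data2, perm)))
        if abs(r_perm) >= abs(r_obs) - 1e-12:
            hits += 1
    return MantelResult(r=float(r_obs), p_value=(1 + hits) / (1 + n_perm),
                        n_perm=n_perm)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def _residual(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    x = x - x.mean()
    y = y - y.mean()
    xx = (x * x).sum()
    if xx == 0:
        return y
    return y - (x * y).sum() / xx * x


def partial_mantel(d1: DistanceMatrix, d2: DistanceMatrix, d3: DistanceMatrix,
                   n_perm: int = 999, seed: int = 0) -> MantelResult:
    """Partial Spearman Mantel correlation of d1 and d2 controlling d3.

    Ranks of each matrix's lower triangle are residualized on the ranks of
    d3 before correlating; significance permutes d2 as in ``mantel``.
    """
    n = _check_aligned(d1, d2, d3)
    r3 = stats.rankdata(_condensed(d3))
    res1 = _residual(stats.rankdata(_condensed(d1)), r3)
    data2 = np.asarray(d2.data, dtype=float)
    r_obs = _pearson(
        res1, _residual(stats.rankdata(squareform(data2, checks=False)), r3)
    )
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r2v = stats.rankdata(_permuted_condensed(data2, perm))
        if abs(_pearson(res1, _residual(r2v, r3))) >= abs(r_obs) - 1e-12:
            hits += 1
    return MantelResult(r=float(r_obs), p_value=(1 + hits) / (1 + n_perm),
                        n_perm=n_perm)


def env_distance(frame: pd.DataFrame, variables: list[str]) -> DistanceMatrix:
    """Euclidean distance between samples on Z-scored variables."""
    missing = [v for v in variables if v not in frame.columns]
    if missing:
        raise ValidationError(f"missing variables: {', '.join(missing)}")
    x = frame[variables].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValidationError("environmental variables contain missing values")
    sd = x.std(axis=0, ddof=0)
    if (sd == 0).any():
        bad = [v for v, s in zip(variables, sd) if s == 0]
        raise ValidationError(f"constant variable(s): {', '.join(bad)}")
    z = (x - x.mean(axis=0)) / sd
    return DistanceMatrix(squareform(pdist(z)), ids=list(frame.index))


def linear_fit(x, y) -> RegressionResult:
    """Ordinary least squares y ~ x with a two-sided t-test on the slope."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValidationError("x and y must be 1-D and the same length")
    if len(xv) < 3:
        raise ValidationError("need at least 3 paired observations")
    if not (np.isfinite(xv).all() and np.isfinite(yv).all()):
        raise ValidationError("non-finite values in regression inputs")
    if xv.std(ddof=0) == 0:
        raise ValidationError("x has zero variance")
    res = stats.linregress(xv, yv)
    return RegressionResult(
        slope=float(res.slope), intercept=float(res.intercept),
        r2=float(res.rvalue ** 2), p_value=float(res.pvalue), n=len(xv),
    )


def spearman_screen(frame: pd.DataFrame, response, variables: list[str],
                    fdr: bool = False) -> pd.DataFrame:
    """Spearman rho and two-sided p of a response against each variable.

    Midranks handle ties. No multiplicity correction by default; ``fdr=True``
    adds Benjamini-Hochberg adjusted q-values.
    """
    y = pd.Series(response)
    if len(y) < 4:
        raise ValidationError("Spearman screen needs at least 4 samples")
    rows = []
    for v in variables:
        if v not in frame.columns:
            raise ValidationError(f"variable {v!r} not in metadata")
        rho, p = stats.spearmanr(frame[v].to_numpy(dtype=float), y.to_numpy())
        rows.append({"variable": v, "rho": float(rho), "p_value": float(p)})
    out = pd.DataFrame(rows).set_index("variable")
    if fdr:
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out
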