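"""Partial least squares path modeling (PLS-PM) with reflective blocks.

Latent variables (water properties, nutrients, alpha diversity, beta
diversity, species pool, EMF) are estimated by the Lohmoeller alternating
algorithm: indicators are standardized, outer weights start equal, and the
loop alternates an inner approximation (path scheme by default) with a
mode-A outer weight update until the weights stabilize. Inner path
coefficients are then OLS regressions of each endogenous latent score on
its predecessors, and direct/indirect/total effects come from exhaustive
enumeration of directed paths in the (acyclic) inner model. Significance is
by bootstrap resampling of samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import ValidationError

SCHEMES = ("centroid", "factorial", "path")


@dataclass
class PathModel:
    """Measurement blocks plus the inner (structural) DAG.

    ``blocks`` maps each latent name to its indicator columns; ``inner``
    maps each endogenous latent to the list of latents pointing at it.
    All blocks are reflective (mode A).
    """

    blocks: dict[str, list[str]]
    inner: dict[str, list[str]]
    scheme: str = "path"

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValidationError(f"unknown scheme {self.scheme!r}")
        for name, cols in self.blocks.items():
            if not cols:
                raise ValidationError(f"block {name!r} is empty")
        unknown = [l for l in self.inner if l not in self.blocks]
        unknown += [s for ss in self.inner.values() for s in ss
                    if s not in self.blocks]
        if unknown:
            raise ValidationError(f"inner model names unknown latents: {unknown}")
        self.order()  # raises on cycles

    @property
    def latents(self) -> list[str]:
        return list(self.blocks)

    def edges(self) -> list[tuple[str, str]]:
        return [(s, t) for t, ss in self.inner.items() for s in ss]

    def order(self) -> list[str]:
        """Topological order of the inner DAG (cycle check)."""
        preds = {l: set(self.inner.get(l, [])) for l in self.latents}
        done: list[str] = []
        while preds:
            free = [l for l, p in preds.items() if not p]
            if not free:
                raise ValidationError("inner model contains a cycle")
            for l in sorted(free):
                done.append(l)
                del preds[l]
            for p in preds.values():
                p.difference_update(free)
        return done

    def neighbors(self, latent: str) -> dict[str, str]:
        """Adjacent latents tagged 'pred' or 'succ'."""
        out: dict[str, str] = {}
        for s in self.inner.get(latent, []):
            out[s] = "pred"
        for t, ss in self.inner.items():
            if latent in ss:
                out[t] = "succ"
        return out


def fig6_path_model(beta_indicator: str = "beta_score") -> PathModel:
    """The default structural model of the analysis: exogenous water
    properties and nutrients; alpha diversity, beta diversity and species
    pool endogenous on both; EMF endogenous on all."""
    blocks = {
        "WP": ["temperature", "salinity", "pH", "Chl-a"],
        "nutrients": ["TOC", "COD", "NO3-N", "NO2-N", "NH4-N", "DIN", "TN",
                      "DIP", "TP"],
        "alpha": ["shannon"],
        "beta": [beta_indicator],
        "species_pool": ["richness"],
        "EMF": ["MNI"],
    }
    inner = {
        "alpha": ["WP", "nutrients"],
        "beta": ["WP", "nutrients"],
        "species_pool": ["WP", "nutrients"],
        "EMF": ["WP", "nutrients", "alpha", "beta", "species_pool"],
    }
    return PathModel(blocks=blocks, inner=inner)


@dataclass
class PlsPmResult:
    weights: dict[str, pd.Series]     # outer weights per block
    loadings: dict[str, pd.Series]    # indicator-score correlations
    scores: pd.DataFrame              # latent scores, unit variance
    paths: dict[str, pd.Series]       # target -> coefficients on predecessors
    r2: dict[str, float]
    effects: pd.DataFrame             # source, target, direct, indirect, total
    n_iter: int = 0
    delta: float = np.nan


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=0)
    if (sd == 0).any():
        raise ValidationError("constant indicator column")
    return (x - x.mean(axis=0)) / sd


def fit_plspm(data: pd.DataFrame, model: PathModel, tol: float = 1e-7,
              max_iter: int = 300) -> PlsPmResult:
    """Estimate the path model on complete numeric data.

    Raises on non-convergence (carrying the last weight delta). A collinear
    block (condition number above 1e8) draws a warning. Latent scores are
    standardized to unit variance; each score's sign is fixed to correlate
    positively with its block's first indicator.
    """
    cols = [c for b in model.blocks.values() for c in b]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValidationError(f"data lacks indicator columns: {missing}")
    sub = data[cols].apply(pd.to_numeric, errors="coerce")
    if sub.isna().any().any():
        raise ValidationError("indicator data contains missing values; "
                              "listwise-delete beforehand")
    n = len(sub)
    if n < len(cols) + 1:
        raise ValidationError("need more samples than indicators")
    X = {b: _standardize(sub[ix].to_numpy(dtype=float))
         for b, ix in model.blocks.items()}
    for b, xb in X.items():
        if xb.shape[1] > 1 and np.linalg.cond(xb) > 1e8:
            warnings.warn(f"block {b!r} indicators are nearly collinear",
                          stacklevel=2)

    w = {b: np.ones(xb.shape[1]) for b, xb in X.items()}

    def score(b: str) -> np.ndarray:
        y = X[b] @ w[b]
        y = y / y.std(ddof=0)
        if np.corrcoef(y, X[b][:, 0])[0, 1] < 0:
            y = -y
        return y

    def norm_w(b: str, wv: np.ndarray) -> np.ndarray:
        y = X[b] @ wv
        sd = y.std(ddof=0)
        if sd == 0:
            raise ValidationError(f"degenerate outer weights in block {b!r}")
        wv = wv / sd
        if np.corrcoef(X[b] @ wv, X[b][:, 0])[0, 1] < 0:
            wv = -wv
        return wv

    w = {b: norm_w(b, wv) for b, wv in w.items()}
    Y = {b: score(b) for b in X}
    delta = np.inf
    for it in range(1, max_iter + 1):
        # inner approximation: weighted sum of neighbor scores
        Z: dict[str, np.ndarray] = {}
        for b in X:
            nbrs = model.neighbors(b)
            if not nbrs:
                # an isolated latent keeps its own score as the inner proxy
                Z[b] = Y[b].copy()
                continue
            z = np.zeros(n)
            if model.scheme == "path":
                preds = model.inner.get(b, [])
                if preds:  # predecessors weighted by regression coefficients
                    P = np.column_stack([Y[p] for p in preds])
                    coef, *_ = np.linalg.lstsq(P, Y[b], rcond=None)
                    z += P @ coef
                for nb, role in nbrs.items():
                    if role == "succ":  # successors by correlation
                        z += np.corrcoef(Y[b], Y[nb])[0, 1] * Y[nb]
            else:
                for nb in nbrs:
                    r = np.corrcoef(Y[b], Y[nb])[0, 1]
                    e = (np.sign(r) if r != 0 else 1.0) \
                        if model.scheme == "centroid" else r
                    z += e * Y[nb]
            Z[b] = z
        # outer mode-A update
        new_w = {b: norm_w(b, X[b].T @ Z[b] / n) for b in X}
        delta = max(np.abs(new_w[b] - w[b]).max() for b in X)
        w = new_w
        Y = {b: score(b) for b in X}
        if delta < tol:
            break
    else:
        raise ValidationError(
            f"PLS-PM did not converge in {max_iter} iterations "
            f"(last delta {delta:.3e})"
        )

    scores = pd.DataFrame(Y, index=sub.index)[model.latents]
    weights = {
        b: pd.Series(w[b], index=model.blocks[b], name=b) for b in model.blocks
    }
    loadings = {
        b: pd.Series(
            [np.corrcoef(X[b][:, j], Y[b])[0, 1] for j in range(X[b].shape[1])],
            index=model.blocks[b], name=b,
        )
        for b in model.blocks
    }
    paths: dict[str, pd.Series] = {}
    r2: dict[str, float] = {}
    for target, preds in model.inner.items():
        P = np.column_stack([Y[p] for p in preds])
        coef, *_ = np.linalg.lstsq(P, Y[target], rcond=None)
        fitted = P @ coef
        paths[target] = pd.Series(coef, index=preds, name=target)
        r2[target] = float(1 - ((Y[target] - fitted) ** 2).sum()
                           / (Y[target] ** 2).sum())
    effects = effects_table(model, paths)
    return PlsPmResult(weights=weights, loadings=loadings, scores=scores,
                       paths=paths, r2=r2, effects=effects,
                       n_iter=it, delta=float(delta))


def enumerate_paths(model: PathModel, source: str, target: str) -> list[list[str]]:
    """All directed latent paths from source to target in the inner DAG."""
    succ: dict[str, list[str]] = {l: [] for l in model.latents}
    for s, t in model.edges():
        succ[s].append(t)
    out: list[list[str]] = []

    def walk(node: str, trail: list[str]) -> None:
        if node == target:
            out.append(trail)
            return
        for nxt in succ[node]:
            walk(nxt, trail + [nxt])

    walk(source, [source])
    return out


def effects_table(model: PathModel, paths: dict[str, pd.Series]) -> pd.DataFrame:
    """Direct, indirect and total effects for every connected latent pair.

    The indirect effect sums, over every directed path of length >= 2, the
    product of the path coefficients along it; total = direct + indirect.
    """
    coef = {(s, t): float(paths[t][s]) for t in paths for s in paths[t].index}
    rows = []
    order = model.order()
    for i, s in enumerate(order):
        for t in order[i + 1:]:
            chains = enumerate_paths(model, s, t)
            if not chains:
                continue
            direct = coef.get((s, t), 0.0)
            indirect = 0.0
            for chain in chains:
                if len(chain) == 2:
                    continue
                prod = 1.0
                for a, b in zip(chain[:-1], chain[1:]):
                    prod *= coef[(a, b)]
                indirect += prod
            rows.append({"source": s, "target": t, "direct": direct,
                         "indirect": indirect, "total": direct + indirect})
    return pd.DataFrame(rows)


@dataclass
class BootstrapResult:
    paths: pd.DataFrame   # source, target, estimate, ci_low, ci_high, p_value
    n_boot: int
    n_failed: int


def bootstrap_plspm(data: pd.DataFrame, model: PathModel, n_boot: int = 999,
                    seed: int = 0, tol: float = 1e-7,
                    max_iter: int = 300) -> BootstrapResult:
    """Percentile bootstrap CIs and two-sided sign-based p-values per path.

    Samples are resampled with replacement and the model refit; replicates
    that fail to converge (or hit a degenerate resample) are dropped, and
    more than 5% failures is an error. The per-fit sign convention (score
    positively correlated with the block's first indicator) keeps replicate
    path signs aligned with the full-data solution.
    """
    full = fit_plspm(data, model, tol=tol, max_iter=max_iter)
    edges = model.edges()
    rng = np.random.default_rng(seed)
    draws = {e: [] for e in edges}
    n_failed = 0
    n = len(data)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boot = data.iloc[idx]
        boot.index = pd.RangeIndex(n)
        try:
            res = fit_plspm(boot, model, tol=tol, max_iter=max_iter)
        except ValidationError:
            n_failed += 1
            continue
        for s, t in edges:
            draws[(s, t)].append(float(res.paths[t][s]))
    if n_failed > 0.05 * n_boot:
        raise ValidationError(
            f"{n_failed}/{n_boot} bootstrap refits failed (> 5%)"
        )
    rows = []
    for (s, t) in edges:
        d = np.asarray(draws[(s, t)])
        est = float(full.paths[t][s])
        lo, hi = np.percentile(d, [2.5, 97.5])
        neg = (d <= 0).sum()
        pos = (d >= 0).sum()
        p = 2 * min(neg + 1, pos + 1) / (len(d) + 1)
        rows.append({"source": s, "target": t, "estimate": est,
                     "ci_low": float(lo), "ci_high": float(hi),
                     "p_value": float(min(p, 1.0)), "n_draws": len(d)})
    return BootstrapResult(paths=pd.DataFrame(rows), n_boot=n_boot,
                           n_failed=n_failed)
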