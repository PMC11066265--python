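"""Alpha diversity, Bray-Curtis beta diversity, PERMANOVA and PCoA scores.

Shannon entropy (natural log) is the alpha-diversity index; richness — the
count of taxa observed in a sample — stands for the species pool. Beta
diversity is the Bray-Curtis dissimilarity; group structure on it is tested
with PERMANOVA (Anderson's pseudo-F, permutation p, r-squared), and the
per-sample "beta diversity score" used by the regressions and the path
model is, by default, the first principal-coordinate axis of the
Bray-Curtis matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .io_core import CountTable, ValidationError


def shannon(counts, base: float | None = None) -> float:
    """Shannon entropy H = -sum p_i log p_i over nonzero proportions.

    Natural log (nats) by default; pass ``base`` to change units.
    """
    x = np.asarray(counts, dtype=float)
    if x.size == 0 or (x < 0).any():
        raise ValidationError("counts must be non-negative and nonempty")
    total = x.sum()
    if total <= 0:
        raise ValidationError("cannot compute Shannon of an all-zero sample")
    p = x[x > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def richness(counts) -> int:
    """Number of taxa with strictly positive abundance."""
    x = np.asarray(counts)
    if (x < 0).any():
        raise ValidationError("counts must be non-negative")
    return int((x > 0).sum())


def alpha_diversity(table: CountTable) -> pd.DataFrame:
    """Per-sample Shannon (nats) and richness."""
    rows = [
        {"sample_id": s, "shannon": shannon(row), "richness": richness(row)}
        for s, row in zip(table.sample_ids, table.counts)
    ]
    return pd.DataFrame(rows).set_index("sample_id")


def bray_curtis(table: CountTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity: sum|x-y| / sum(x+y)."""
    x = table.counts.astype(float)
    totals = x.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if len(zero) >= 2:
        a, b = table.sample_ids[zero[0]], table.sample_ids[zero[1]]
        raise ValidationError(
            f"Bray-Curtis undefined for all-zero sample pair ({a!r}, {b!r})"
        )
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    den = totals[:, None] + totals[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        d = num / den
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=table.sample_ids)


@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p_value: float
    n_permutations: int


def _permanova_stats(d2: np.ndarray, labels: np.ndarray, uniq: np.ndarray):
    """Pseudo-F and r2 from squared distances (Anderson's formulation)."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in uniq:
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    a = len(uniq)
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    return f, ss_between / ss_total


def permanova(dist: DistanceMatrix, groups, n_perm: int = 999,
              seed: int = 0) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    Whole samples are permuted freely across groups; the p-value is
    (1 + #{perm F >= obs F}) / (1 + n_perm).
    """
    labels = np.asarray(pd.Series(groups).to_numpy())
    if len(labels) != dist.shape[0]:
        raise ValidationError("group labels do not match distance matrix size")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("PERMANOVA needs at least 2 groups")
    if (counts < 2).any():
        bad = uniq[counts < 2]
        raise ValidationError(f"singleton group(s): {list(bad)}")
    d2 = np.asarray(dist.data, dtype=float) ** 2
    f_obs, r2 = _permanova_stats(d2, labels, uniq)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        f_perm, _ = _permanova_stats(d2, perm, uniq)
        if f_perm >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermanovaResult(pseudo_f=float(f_obs), r2=float(r2),
                           p_value=float(p), n_permutations=n_perm)


def pcoa_axis(dist: DistanceMatrix, axis: int = 1,
              salinity=None) -> pd.Series:
    """Principal-coordinate scores of one axis (1-based).

    Classical scaling on double-centered squared distances; negative
    eigenvalues are left uncorrected. The axis sign is fixed so that scores
    correlate positively with ``salinity`` when given, else so the first
    sample's score is non-negative.
    """
    if axis < 1:
        raise ValidationError("axis is 1-based and must be >= 1")
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        ord_res = _skbio_pcoa(dist, method="eigh")
    eigvals = ord_res.eigvals.to_numpy()
    n_pos = int((eigvals > 1e-10).sum())
    if axis > n_pos:
        raise ValidationError(
            f"axis {axis} exceeds the {n_pos} positive-eigenvalue axes"
        )
    scores = ord_res.samples.iloc[:, axis - 1].copy()
    scores.index = list(dist.ids)
    if salinity is not None:
        sal = pd.Series(salinity)
        sal.index = scores.index if len(sal) == len(scores) else sal.index
        r = np.corrcoef(scores.to_numpy(), sal.loc[scores.index].to_numpy())[0, 1]
        if np.isfinite(r) and r < 0:
            scores = -scores
    elif scores.iloc[0] < 0:
        scores = -scores
    scores.name = f"PCo{axis}"
    return scores


def mean_dissimilarity(dist: DistanceMatrix, groups=None) -> pd.Series:
    """Each sample's mean dissimilarity to the other members of its group
    (to all other samples when ``groups`` is None) — the alternative
    per-sample beta-diversity reduction."""
    d = np.asarray(dist.data, dtype=float)
    ids = list(dist.ids)
    n = len(ids)
    if groups is None:
        labels = np.zeros(n)
    else:
        labels = np.asarray(pd.Series(groups).to_numpy())
    out = np.empty(n)
    for i in range(n):
        mask = (labels == labels[i])
        mask[i] = False
        if not mask.any():
            raise ValidationError(f"sample {ids[i]!r} has no group partner")
        out[i] = d[i, mask].mean()
    return pd.Series(out, index=ids, name="mean_dissimilarity")


def beta_scores(dist: DistanceMatrix, method: str = "pcoa",
                salinity=None, groups=None) -> pd.Series:
    """Per-sample beta-diversity score: PCoA axis 1 (default) or mean
    within-group dissimilarity."""
    if method == "pcoa":
        return pcoa_axis(dist, 1, salinity=salinity)
    if method == "mean_dissim":
        return mean_dissimilarity(dist, groups=groups)
    raise ValueError(f"unknown beta-score method {method!r}")


def distance_to_frame(dist: DistanceMatrix) -> pd.DataFrame:
    """Square TSV-ready DataFrame view of a distance matrix."""
    return pd.DataFrame(dist.data, index=dist.ids, columns=dist.ids)


def lower_triangle(dist: DistanceMatrix) -> np.ndarray:
    """Condensed vector of the strictly-lower-triangle entries."""
    return squareform(np.asarray(dist.data, dtype=float), checks=False)
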