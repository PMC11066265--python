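"""Null-model inference of community assembly processes.

Implements the two-stage phylogenetic/taxonomic null-model framework used
to partition pairwise community turnover into ecological processes:

1. beta-mean-nearest-taxon distance (betaMNTD) between every sample pair,
   abundance-weighted by default, standardized against a taxa-shuffle null
   to give the beta nearest taxon index (betaNTI). |betaNTI| > 2 indicates
   selection (deterministic assembly): betaNTI > +2 heterogeneous selection,
   betaNTI < -2 homogeneous selection.
2. for pairs without a selection signal, the Bray-Curtis-based Raup-Crick
   metric (RC_bray) against a probabilistic assembly null that preserves
   each sample's richness and read total while drawing taxa by regional
   occupancy and reads by regional relative abundance. RC > +0.95 indicates
   dispersal limitation, RC < -0.95 homogenizing dispersal, |RC| <= 0.95
   drift.

All thresholds are strict inequalities; exact ties fall through to the next
rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .io_core import CountTable, ValidationError, patristic_matrix

PROCESSES = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
    "undetermined",
)


@dataclass
class NullConfig:
    """Knobs of the null-model stage.

    n_null draws per statistic (>= 99), a seed for reproducibility, whether
    betaMNTD is abundance-weighted, and the classification thresholds
    (|betaNTI| > 2 for selection, |RC| > 0.95 for dispersal processes).
    """

    n_null: int = 999
    seed: int = 0
    abundance_weighted: bool = True
    bnti_threshold: float = 2.0
    rc_threshold: float = 0.95

    def __post_init__(self) -> None:
        if self.n_null < 99:
            raise ValidationError("n_null must be at least 99")
        if self.bnti_threshold <= 0 or self.rc_threshold <= 0:
            raise ValidationError("classification thresholds must be positive")


# ---------------------------------------------------------------------------
# betaMNTD / betaNTI
# ---------------------------------------------------------------------------


def _taxon_distance_matrix(table: CountTable, tree: TreeNode) -> np.ndarray:
    dm = patristic_matrix(tree)
    missing = [t for t in table.taxon_ids if t not in set(dm.ids)]
    if missing:
        raise ValidationError(f"taxa absent from tree: {missing[:5]}")
    return np.asarray(dm.filter(table.taxon_ids).data, dtype=float)


def _weights(counts: np.ndarray, weighted: bool) -> np.ndarray:
    """Per-sample taxon weight vectors (relative abundance or uniform over
    present taxa)."""
    x = counts.astype(float)
    if not weighted:
        x = (x > 0).astype(float)
    totals = x.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise ValidationError("betaMNTD needs every sample to be non-empty")
    return x / totals


def _beta_mntd_all_pairs(weights: np.ndarray, presence: np.ndarray,
                         dist: np.ndarray) -> np.ndarray:
    """betaMNTD for all sample pairs given taxon distances.

    For each sample t, M[t, i] = distance from taxon i to its nearest taxon
    present in t; then betaMNTD(s, t) = 0.5 * (w_s . M_t + w_t . M_s).
    """
    n_samples = weights.shape[0]
    m = np.empty_like(weights)
    for t in range(n_samples):
        idx = np.flatnonzero(presence[t])
        m[t] = dist[:, idx].min(axis=1)
    b = weights @ m.T
    return 0.5 * (b + b.T)


def beta_mntd(x, y, tree: TreeNode, taxon_ids: list[str] | None = None,
              weighted: bool = True) -> float:
    """betaMNTD between two communities on a shared taxon set.

    ``x`` and ``y`` are abundance vectors over ``taxon_ids`` (defaults to the
    tree's tip order). Each present taxon contributes its patristic distance
    to the nearest taxon present in the other community, weighted by its
    within-community relative abundance (or equally when unweighted), and
    the two directions are averaged.
    """
    dm = patristic_matrix(tree)
    ids = list(taxon_ids) if taxon_ids is not None else list(dm.ids)
    missing = [t for t in ids if t not in set(dm.ids)]
    if missing:
        raise ValidationError(f"taxa absent from tree: {missing[:5]}")
    dist = np.asarray(dm.filter(ids).data, dtype=float)
    counts = np.vstack([np.asarray(x, dtype=float), np.asarray(y, dtype=float)])
    if counts.shape[1] != len(ids):
        raise ValidationError("abundance vectors do not match the taxon set")
    w = _weights(counts, weighted)
    return float(_beta_mntd_all_pairs(w, counts > 0, dist)[0, 1])


@dataclass
class BntiResult:
    """Observed betaMNTD with its null mean/sd and the resulting betaNTI."""

    bnti: pd.DataFrame
    beta_mntd_obs: pd.DataFrame
    null_mean: pd.DataFrame
    null_sd: pd.DataFrame


def bnti_matrix(table: CountTable, tree: TreeNode,
                config: NullConfig | None = None) -> BntiResult:
    """Pairwise betaNTI via a taxa-label shuffle null.

    Each null iteration draws one permutation of taxon labels across the
    (pruned) tree's tips, shared across all sample pairs, and recomputes
    betaMNTD; betaNTI = (obs - null mean) / null sd. Pairs whose null sd is
    below 1e-12 are returned as NaN with a warning.
    """
    config = config or NullConfig()
    dist = _taxon_distance_matrix(table, tree)
    w = _weights(table.counts, config.abundance_weighted)
    presence = table.counts > 0
    obs = _beta_mntd_all_pairs(w, presence, dist)

    rng = np.random.default_rng(config.seed)
    n = table.n_taxa
    total = np.zeros_like(obs)
    total_sq = np.zeros_like(obs)
    for _ in range(config.n_null):
        perm = rng.permutation(n)
        null = _beta_mntd_all_pairs(w, presence, dist[np.ix_(perm, perm)])
        total += null
        total_sq += null * null
    mean = total / config.n_null
    var = total_sq / config.n_null - mean ** 2
    sd = np.sqrt(np.clip(var, 0.0, None))

    with np.errstate(invalid="ignore", divide="ignore"):
        bnti = (obs - mean) / sd
    degenerate = sd < 1e-12
    np.fill_diagonal(degenerate, False)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum() // 2)} sample pairs have a degenerate "
            "(zero-variance) betaMNTD null; betaNTI flagged missing",
            stacklevel=2,
        )
        bnti[degenerate] = np.nan
    np.fill_diagonal(bnti, 0.0)

    ids = table.sample_ids
    wrap = lambda a: pd.DataFrame(a, index=ids, columns=ids)
    return BntiResult(bnti=wrap(bnti), beta_mntd_obs=wrap(obs),
                      null_mean=wrap(mean), null_sd=wrap(sd))


# ---------------------------------------------------------------------------
# RC_bray
# ---------------------------------------------------------------------------


def _null_community(rng: np.random.Generator, occupancy_w: np.ndarray,
                    abundance_p: np.ndarray, richness: int,
                    depth: int) -> np.ndarray:
    """One null assembly of a sample: draw ``richness`` taxa without
    replacement with probability proportional to regional occupancy, seed
    each with one read, then allocate the remaining reads multinomially by
    regional relative abundance (so observed richness and depth are
    preserved exactly)."""
    # Gumbel top-k == successive weighted sampling without replacement
    keys = np.log(occupancy_w) + rng.gumbel(size=occupancy_w.size)
    chosen = np.argpartition(-keys, richness - 1)[:richness]
    counts = np.zeros(occupancy_w.size, dtype=np.int64)
    counts[chosen] = 1
    extra = depth - richness
    if extra > 0:
        p = abundance_p[chosen]
        counts[chosen] += rng.multinomial(extra, p / p.sum())
    return counts


def _bray_curtis_pairs(x: np.ndarray) -> np.ndarray:
    totals = x.sum(axis=1, dtype=float)
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2, dtype=float)
    den = totals[:, None] + totals[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        d = num / den
    np.fill_diagonal(d, 0.0)
    return d


def rc_bray_matrix(table: CountTable,
                   config: NullConfig | None = None) -> pd.DataFrame:
    """Pairwise Raup-Crick metric on Bray-Curtis, scaled to [-1, 1].

    The regional pool (taxon occupancy and relative abundance) comes from
    the full table. Each null iteration assembles every sample independently
    and the pairwise null Bray-Curtis values are compared with the observed:
    RC = 2 * [(#{null < obs} + 0.5 * #{null = obs}) / n_null] - 1.
    """
    config = config or NullConfig()
    counts = table.counts
    occupancy = (counts > 0).sum(axis=0).astype(float)
    regional = counts.sum(axis=0).astype(float)
    pool = np.flatnonzero(occupancy > 0)
    richness = (counts > 0).sum(axis=1)
    depth = counts.sum(axis=1)
    if (richness > pool.size).any():
        bad = int(np.argmax(richness > pool.size))
        raise ValidationError(
            f"regional pool ({pool.size} taxa) smaller than richness of "
            f"sample {table.sample_ids[bad]!r} ({richness[bad]})"
        )
    occ_w = occupancy[pool]
    ab_p = regional[pool] / regional[pool].sum()

    obs = _bray_curtis_pairs(counts)
    rng = np.random.default_rng(config.seed)
    n_samples = table.n_samples
    below = np.zeros((n_samples, n_samples))
    equal = np.zeros((n_samples, n_samples))
    null_counts = np.empty((n_samples, pool.size), dtype=np.int64)
    for _ in range(config.n_null):
        for s in range(n_samples):
            null_counts[s] = _null_community(
                rng, occ_w, ab_p, int(richness[s]), int(depth[s])
            )
        null_bc = _bray_curtis_pairs(null_counts)
        below += null_bc < obs - 1e-9
        equal += np.abs(null_bc - obs) <= 1e-9
    rc = 2.0 * (below + 0.5 * equal) / config.n_null - 1.0
    np.fill_diagonal(rc, 0.0)
    return pd.DataFrame(rc, index=table.sample_ids, columns=table.sample_ids)


# ---------------------------------------------------------------------------
# Process classification
# ---------------------------------------------------------------------------


def classify_pair(bnti: float, rc: float,
                  config: NullConfig | None = None) -> str:
    """Process label for one (betaNTI, RC_bray) pair."""
    config = config or NullConfig()
    if not np.isfinite(bnti):
        return "undetermined"
    if bnti > config.bnti_threshold:
        return "heterogeneous_selection"
    if bnti < -config.bnti_threshold:
        return "homogeneous_selection"
    if not np.isfinite(rc):
        return "undetermined"
    if rc > config.rc_threshold:
        return "dispersal_limitation"
    if rc < -config.rc_threshold:
        return "homogenizing_dispersal"
    return "drift"


def classify_processes(bnti: pd.DataFrame, rc: pd.DataFrame,
                       config: NullConfig | None = None) -> pd.DataFrame:
    """Elementwise five-way process classification of sample pairs."""
    config = config or NullConfig()
    if bnti.shape != rc.shape or list(bnti.index) != list(rc.index):
        raise ValidationError("betaNTI and RC matrices are not aligned")
    b = bnti.to_numpy(dtype=float)
    r = rc.to_numpy(dtype=float)
    out = np.full(b.shape, "drift", dtype=object)
    out[~np.isfinite(b)] = "undetermined"
    sel_pos = np.isfinite(b) & (b > config.bnti_threshold)
    sel_neg = np.isfinite(b) & (b < -config.bnti_threshold)
    out[sel_pos] = "heterogeneous_selection"
    out[sel_neg] = "homogeneous_selection"
    rest = np.isfinite(b) & ~sel_pos & ~sel_neg
    out[rest & ~np.isfinite(r)] = "undetermined"
    out[rest & np.isfinite(r) & (r > config.rc_threshold)] = "dispersal_limitation"
    out[rest & np.isfinite(r) & (r < -config.rc_threshold)] = "homogenizing_dispersal"
    np.fill_diagonal(out, "")
    return pd.DataFrame(out, index=bnti.index, columns=bnti.columns)


def process_fractions(calls: pd.DataFrame, groups=None,
                      bnti: pd.DataFrame | None = None) -> pd.DataFrame:
    """Percentage of sample pairs per process, overall and per group.

    A group's pairs are those with both members in the group. Percentages
    are over classified (non-undetermined) pairs and sum to 100;
    undetermined pairs are reported separately as a percentage of all pairs.
    When betaNTI is supplied, the deterministic share (% of pairs with
    |betaNTI| > 2) is included.
    """
    ids = list(calls.index)
    n = len(ids)
    iu = np.triu_indices(n, 1)
    labels = calls.to_numpy()[iu]
    if len(labels) == 0:
        raise ValidationError("no sample pairs to tally")
    b = bnti.to_numpy(dtype=float)[iu] if bnti is not None else None

    def tally(mask: np.ndarray, name) -> dict:
        sub = labels[mask]
        det = np.array([lab != "undetermined" for lab in sub])
        row: dict = {"group": name, "n_pairs": int(mask.sum())}
        n_class = int(det.sum())
        for proc in PROCESSES[:-1]:
            pct = 100.0 * (sub == proc).sum() / n_class if n_class else np.nan
            row[proc] = pct
        row["undetermined"] = 100.0 * (~det).sum() / len(sub)
        if b is not None:
            fin = np.isfinite(b[mask])
            row["deterministic_share"] = (
                100.0 * (np.abs(b[mask][fin]) > 2.0).sum() / fin.sum()
                if fin.any() else np.nan
            )
        return row

    rows = [tally(np.ones(len(labels), dtype=bool), "overall")]
    if groups is not None:
        g = np.asarray(pd.Series(groups).to_numpy())
        if len(g) != n:
            raise ValidationError("group labels do not match call matrix")
        pair_groups_i = g[iu[0]]
        pair_groups_j = g[iu[1]]
        for name in pd.unique(g):
            if (g == name).sum() < 2:
                warnings.warn(f"group {name!r} has <2 members; skipped",
                              stacklevel=2)
                continue
            mask = (pair_groups_i == name) & (pair_groups_j == name)
            rows.append(tally(mask, name))
    return pd.DataFrame(rows).set_index("group")
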