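"""Multi-nutrient cycling index (MNI) — the ecosystem-multifunctionality measure.

Each nutrient variable V is Z-score transformed and then min-max
standardized, STD = (V - Vmin) / (Vmax - Vmin), so every factor spans
[0, 1]; a sample's MNI is the mean of its standardized factors. Because
min-max standardization is invariant to positive affine transforms, the
Z-score stage cannot change the result; it is kept for fidelity to the
published procedure and its inertness is asserted in tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import MNI_FACTORS, ValidationError


def zscore(values) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValidationError("cannot Z-score a constant vector")
    return (x - x.mean()) / sd


def std_minmax(values, name: str | None = None) -> np.ndarray:
    """Min-max standardization (V - Vmin) / (Vmax - Vmin) onto [0, 1]."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValidationError("need at least 2 values to standardize")
    vmin, vmax = x.min(), x.max()
    if vmax == vmin:
        raise ValidationError(
            f"factor {name or '<unnamed>'} is constant; STD undefined"
        )
    return (x - vmin) / (vmax - vmin)


@dataclass
class MniResult:
    mni: pd.Series                 # per-sample index in [0, 1]
    std: pd.DataFrame              # per-sample, per-factor standardized values
    factors: list[str] = field(default_factory=list)
    dropped_samples: list[str] = field(default_factory=list)


def mni(frame: pd.DataFrame, factors: list[str] | None = None) -> MniResult:
    """Per-sample MNI: mean over factors of std_minmax(zscore(factor)).

    Samples with any missing factor value are dropped (with a warning)
    rather than per-factor deleted, so every retained sample is scored on
    the identical factor set.
    """
    factors = list(factors) if factors is not None else list(MNI_FACTORS)
    missing = [f for f in factors if f not in frame.columns]
    if missing:
        raise ValidationError(f"missing MNI factor columns: {', '.join(missing)}")
    sub = frame[factors].apply(pd.to_numeric, errors="coerce")
    incomplete = sub.isna().any(axis=1)
    dropped = list(sub.index[incomplete])
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} samples with missing factor values: "
            f"{dropped[:5]}",
            stacklevel=2,
        )
        sub = sub.loc[~incomplete]
    if len(sub) < 2:
        raise ValidationError("MNI needs at least 2 complete samples")
    std = pd.DataFrame(
        {f: std_minmax(zscore(sub[f].to_numpy()), name=f) for f in factors},
        index=sub.index,
    )
    return MniResult(
        mni=std.mean(axis=1).rename("MNI"),
        std=std,
        factors=factors,
        dropped_samples=dropped,
    )
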