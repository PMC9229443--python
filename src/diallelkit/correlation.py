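"""Correlation of parental marker distance with F1 heterosis.

For each trait and heterosis basis (mid-parent, better-parent) the Pearson
product-moment correlation is computed between the genetic distance of each
cross's two parents and the cross's heterosis percentage, with a two-sided
p-value from t = r * sqrt((n-2)/(1-r^2)) on n-2 df.  Distances are looked up
from the distance matrix, never recomputed here.  By default DISTANCE is
correlated with heterosis; a flag switches to similarity (1 - GD), which only
flips signs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .distance import DistanceMatrix

__all__ = ["CorrelationRecord", "pearson", "correlate_gd_heterosis",
           "write_correlation_table"]


@dataclass(frozen=True)
class CorrelationRecord:
    """One trait x basis correlation between parental GD and heterosis."""

    trait: str
    basis: str  # "MP" or "BP"
    r: float
    p_value: float
    n: int
    n_dropped: int = 0

    @property
    def sig(self) -> str:
        if self.p_value <= 0.01:
            return "**"
        if self.p_value <= 0.05:
            return "*"
        return "ns"


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r and two-sided p-value (t on n-2 df).

    Requires equal lengths n >= 3 and non-zero variance in both vectors
    (zero variance is an explicit error, not a silent NaN).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if xa.size < 3:
        raise ValueError("need n >= 3 for a correlation p-value")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("zero variance in input vector")
    res = stats.pearsonr(xa, ya)
    return float(res.statistic), float(res.pvalue)


def correlate_gd_heterosis(
    dm: DistanceMatrix,
    entries: pd.DataFrame,
    use_similarity: bool = False,
) -> list[CorrelationRecord]:
    """GD-vs-heterosis Pearson records, one per trait x {MP, BP}.

    ``entries`` is the long heterosis frame (columns cross, trait, hmp_pct,
    hbp_pct) from :func:`diallelkit.heterosis.heterosis_table`; cross ids are
    "P1xP2" with both parents required in ``dm``.  Crosses with undefined
    (NaN) heterosis are dropped and counted in ``n_dropped``.
    """
    records = []
    for trait in entries["trait"].unique():
        sub = entries[entries["trait"] == trait]
        gd = []
        for cid in sub["cross"]:
            p1, _, p2 = cid.partition("x")
            if p1 not in dm.labels or p2 not in dm.labels:
                raise KeyError(
                    f"parent of cross {cid!r} missing from distance matrix"
                )
            d = dm.get(p1, p2)
            gd.append(1.0 - d if use_similarity else d)
        gd_arr = np.asarray(gd)
        for basis, col in (("MP", "hmp_pct"), ("BP", "hbp_pct")):
            h = sub[col].to_numpy(dtype=float)
            keep = np.isfinite(h)
            if keep.sum() < 3:
                raise ValueError(
                    f"fewer than 3 crosses with defined {basis} heterosis "
                    f"for trait {trait!r}"
                )
            r, p = pearson(gd_arr[keep], h[keep])
            records.append(CorrelationRecord(
                trait=trait, basis=basis, r=r, p_value=p,
                n=int(keep.sum()), n_dropped=int((~keep).sum()),
            ))
    return records


def write_correlation_table(records: Sequence[CorrelationRecord],
                            path: str | Path, sep: str = "\t") -> None:
    pd.DataFrame([
        {"trait": rec.trait, "basis": rec.basis, "r": round(rec.r, 3),
         "p_value": rec.p_value, "n": rec.n, "sig": rec.sig}
        for rec in records
    ]).to_csv(path, sep=sep, index=False)
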