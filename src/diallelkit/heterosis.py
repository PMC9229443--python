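"""Half-diallel heterosis estimation from replicated RCBD trials.

A half diallel (Griffing method 2, no reciprocals, no selfs) crosses n
parents in all n(n-1)/2 unordered pairs; parents and F1s are evaluated
together in a randomized complete block design.  For each cross x trait:

    HMP% = 100 * (F1 - MP) / MP      MP = (P1 + P2) / 2
    HBP% = 100 * (F1 - BP) / BP      BP = parent with the larger mean

Significance uses least significant differences built from the RCBD error
mean square (Wynne):

    LSD_MP = t_(alpha/2, df_e) * sqrt(3 * MSE / (2 r))
    LSD_BP = t_(alpha/2, df_e) * sqrt(2 * MSE / r)

so LSD_BP / LSD_MP = 2/sqrt(3) whenever MSE, r and df agree.  Stars are
assigned on the trait-unit difference scale (|F1 - MP| vs LSD_MP, |F1 - BP|
vs LSD_BP); an optional flag rescales the LSDs by MP (resp. BP) to compare on
the percent scale instead.  The better parent is always the larger-mean
parent; a per-trait desirability direction (higher/lower) is carried as
presentation metadata only and never alters the formulas.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DiallelDesign",
    "AnovaResult",
    "LsdThresholds",
    "enumerate_crosses",
    "cross_id",
    "read_phenotypes",
    "write_phenotypes",
    "entry_means",
    "rcbd_anova",
    "lsd_thresholds",
    "heterosis_table",
    "render_heterosis_report",
    "write_anova_table",
]

SIG_CODES = ("ns", "*", "**")


def cross_id(p1: str, p2: str) -> str:
    """Canonical id "P1xP2" for an unordered parent pair."""
    return f"{p1}x{p2}"


def enumerate_crosses(parents: Sequence[str]) -> list[tuple[str, str]]:
    """All n(n-1)/2 unordered crosses, in canonical parent order."""
    if len(parents) < 2:
        raise ValueError("need at least 2 parents")
    if len(set(parents)) != len(parents):
        raise ValueError("duplicate parent id")
    return list(itertools.combinations(parents, 2))


@dataclass(frozen=True)
class DiallelDesign:
    """Parents, their half-diallel crosses and the replication count."""

    parents: tuple[str, ...]
    r: int

    def __post_init__(self) -> None:
        if self.r < 2:
            raise ValueError("RCBD needs r >= 2 replications")
        enumerate_crosses(self.parents)  # validates

    @property
    def crosses(self) -> list[tuple[str, str]]:
        return enumerate_crosses(self.parents)

    @property
    def cross_ids(self) -> list[str]:
        return [cross_id(a, b) for a, b in self.crosses]

    @property
    def entries(self) -> list[str]:
        return list(self.parents) + self.cross_ids


@dataclass(frozen=True)
class AnovaResult:
    """Two-way additive RCBD decomposition for one trait."""

    trait: str
    ss_genotype: float
    ss_block: float
    ss_error: float
    df_genotype: int
    df_block: int
    df_error: int

    @property
    def ss_total(self) -> float:
        return self.ss_genotype + self.ss_block + self.ss_error

    @property
    def mse(self) -> float:
        return self.ss_error / self.df_error

    @property
    def ms_genotype(self) -> float:
        return self.ss_genotype / self.df_genotype

    @property
    def ms_block(self) -> float:
        return self.ss_block / self.df_block


@dataclass(frozen=True)
class LsdThresholds:
    """LSDs for mid-parent and better-parent contrasts at one alpha."""

    trait: str
    alpha: float
    lsd_mp: float
    lsd_bp: float


# ---------------------------------------------------------------------------
# phenotype IO
# ---------------------------------------------------------------------------

PHENO_COLUMNS = ("entry", "block", "trait", "value")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read long-format phenotype observations (entry, block, trait, value)."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"empty phenotype file: {path}")
    sep = "\t" if "\t" in lines[0] else ","
    header = [h.strip() for h in lines[0].split(sep)]
    if [h.lower() for h in header] != list(PHENO_COLUMNS):
        raise ValueError(
            f"phenotype header must be {PHENO_COLUMNS}, got {header}"
        )
    records = []
    for lineno, raw in enumerate(lines[1:], start=2):
        fields = [f.strip() for f in raw.split(sep)]
        if len(fields) != 4:
            raise ValueError(
                f"ragged row at line {lineno} of {path.name}: "
                f"{len(fields)} fields, expected 4"
            )
        try:
            value = float(fields[3])
        except ValueError as exc:
            raise ValueError(
                f"non-numeric value at line {lineno} of {path.name}: "
                f"{fields[3]!r}"
            ) from exc
        if not np.isfinite(value):
            raise ValueError(f"non-finite value at line {lineno} of {path.name}")
        records.append((fields[0], int(fields[1]), fields[2], value))
    obs = pd.DataFrame(records, columns=list(PHENO_COLUMNS))
    dup = obs.duplicated(subset=["entry", "block", "trait"])
    if dup.any():
        first = obs.loc[dup.idxmax()]
        raise ValueError(
            f"duplicate observation for entry={first['entry']!r} "
            f"block={first['block']} trait={first['trait']!r}"
        )
    return obs


def write_phenotypes(obs: pd.DataFrame, path: str | Path,
                     sep: str = "\t") -> None:
    obs[list(PHENO_COLUMNS)].to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# means and ANOVA
# ---------------------------------------------------------------------------

def entry_means(obs: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic entry x trait means over blocks (entries as index).

    Missing (entry, block) cells are tolerated with a warning — the mean is
    over the available blocks; an entry absent for a whole trait stays NaN in
    the pivot and is the caller's error to handle.
    """
    _require_columns(obs)
    n_blocks = obs["block"].nunique()
    counts = obs.groupby(["entry", "trait"])["value"].count()
    short = counts[counts < n_blocks]
    if not short.empty:
        entry, trait = short.index[0]
        warnings.warn(
            f"unbalanced data: e.g. entry {entry!r} trait {trait!r} observed "
            f"in {short.iloc[0]} of {n_blocks} blocks; means use available "
            f"blocks",
            stacklevel=2,
        )
    return obs.pivot_table(index="entry", columns="trait", values="value",
                           aggfunc="mean")


def rcbd_anova(obs: pd.DataFrame, trait: str) -> AnovaResult:
    """RCBD ANOVA (genotype + block + error) for one trait.

    Requires a complete genotype x block table of plot values; incomplete
    data is an error (no imputation — the LSD formulas assume balance).
    """
    _require_columns(obs)
    sub = obs[obs["trait"] == trait]
    if sub.empty:
        raise ValueError(f"no observations for trait {trait!r}")
    wide = sub.pivot(index="entry", columns="block", values="value")
    if wide.isna().any().any():
        mask = wide.isna().to_numpy()
        i, j = np.argwhere(mask)[0]
        raise ValueError(
            f"incomplete RCBD for trait {trait!r}: entry {wide.index[i]!r} "
            f"missing in block {wide.columns[j]}"
        )
    y = wide.to_numpy(dtype=float)
    g, b = y.shape
    if g < 2 or b < 2:
        raise ValueError("RCBD ANOVA needs >= 2 genotypes and >= 2 blocks")
    grand = y.mean()
    geno_means = y.mean(axis=1)
    block_means = y.mean(axis=0)
    ss_geno = b * float(((geno_means - grand) ** 2).sum())
    ss_block = g * float(((block_means - grand) ** 2).sum())
    ss_total = float(((y - grand) ** 2).sum())
    ss_error = ss_total - ss_geno - ss_block
    return AnovaResult(
        trait=trait,
        ss_genotype=ss_geno,
        ss_block=ss_block,
        ss_error=max(ss_error, 0.0),
        df_genotype=g - 1,
        df_block=b - 1,
        df_error=(g - 1) * (b - 1),
    )


def _require_columns(obs: pd.DataFrame) -> None:
    missing = [c for c in PHENO_COLUMNS if c not in obs.columns]
    if missing:
        raise ValueError(f"phenotype frame missing columns {missing}")


# ---------------------------------------------------------------------------
# LSD and heterosis
# ---------------------------------------------------------------------------

def lsd_thresholds(mse: float, r: int, df_error: int, alpha: float = 0.05,
                   trait: str = "") -> LsdThresholds:
    """Wynne LSDs for mid-parent and better-parent contrasts.

    LSD_MP = t * sqrt(3 MSE / (2 r)); LSD_BP = t * sqrt(2 MSE / r), with t
    the two-sided (alpha/2 upper-tail) Student quantile at df_error.
    """
    if mse < 0:
        raise ValueError("MSE must be non-negative")
    if r < 2:
        raise ValueError("r must be >= 2")
    if df_error < 1:
        raise ValueError("df_error must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    t = stats.t.ppf(1 - alpha / 2, df_error)
    return LsdThresholds(
        trait=trait,
        alpha=alpha,
        lsd_mp=float(t * np.sqrt(3.0 * mse / (2.0 * r))),
        lsd_bp=float(t * np.sqrt(2.0 * mse / r)),
    )


def _sig_code(diff: float, lsd05: float, lsd01: float) -> str:
    if abs(diff) > lsd01:
        return "**"
    if abs(diff) > lsd05:
        return "*"
    return "ns"


def heterosis_table(
    means: pd.DataFrame,
    design: DiallelDesign,
    anova: Mapping[str, AnovaResult],
    alphas: tuple[float, float] = (0.05, 0.01),
    trait_directions: Mapping[str, str] | None = None,
    percent_scale_lsd: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per cross x trait heterosis with significance codes.

    ``means`` is the entry x trait frame from :func:`entry_means`.  Returns
    ``(entries, thresholds)``: one row per cross x trait with f1_mean, mp, bp,
    hmp_pct, hbp_pct and sig codes; and the LSD table (trait x alpha).
    Crosses whose MP or BP mean is zero get NaN heterosis with a warning.
    """
    a05, a01 = sorted(alphas)
    directions = dict(trait_directions or {})
    rows = []
    lsd_rows = []
    for trait, result in anova.items():
        if trait not in means.columns:
            raise ValueError(f"trait {trait!r} absent from entry means")
        lsd05 = lsd_thresholds(result.mse, design.r, result.df_error, a05, trait)
        lsd01 = lsd_thresholds(result.mse, design.r, result.df_error, a01, trait)
        lsd_rows += [lsd05, lsd01]
        col = means[trait]
        for p1, p2 in design.crosses:
            cid = cross_id(p1, p2)
            for entry in (p1, p2, cid):
                if entry not in col.index or pd.isna(col.loc[entry]):
                    raise ValueError(
                        f"no mean for entry {entry!r}, trait {trait!r}"
                    )
            m1, m2, f1 = col.loc[p1], col.loc[p2], col.loc[cid]
            mp = (m1 + m2) / 2.0
            bp = max(m1, m2)
            row = {
                "cross": cid, "trait": trait, "f1_mean": f1,
                "p1_mean": m1, "p2_mean": m2, "mp": mp, "bp": bp,
                "direction": directions.get(trait, "higher"),
            }
            if mp == 0 or bp == 0:
                warnings.warn(
                    f"zero parent mean for cross {cid}, trait {trait!r}; "
                    f"heterosis undefined",
                    stacklevel=2,
                )
                row.update(hmp_pct=np.nan, hbp_pct=np.nan,
                           sig_mp=None, sig_bp=None)
            else:
                hmp = 100.0 * (f1 - mp) / mp
                hbp = 100.0 * (f1 - bp) / bp
                if percent_scale_lsd:
                    sig_mp = _sig_code(hmp, 100 * lsd05.lsd_mp / abs(mp),
                                       100 * lsd01.lsd_mp / abs(mp))
                    sig_bp = _sig_code(hbp, 100 * lsd05.lsd_bp / abs(bp),
                                       100 * lsd01.lsd_bp / abs(bp))
                else:
                    sig_mp = _sig_code(f1 - mp, lsd05.lsd_mp, lsd01.lsd_mp)
                    sig_bp = _sig_code(f1 - bp, lsd05.lsd_bp, lsd01.lsd_bp)
                row.update(hmp_pct=hmp, hbp_pct=hbp,
                           sig_mp=sig_mp, sig_bp=sig_bp)
            rows.append(row)
    entries = pd.DataFrame(rows)
    thresholds = pd.DataFrame(
        [{"trait": t.trait, "alpha": t.alpha,
          "lsd_mp": t.lsd_mp, "lsd_bp": t.lsd_bp} for t in lsd_rows]
    )
    return entries, thresholds


def render_heterosis_report(entries: pd.DataFrame, thresholds: pd.DataFrame,
                            sep: str = "\t") -> str:
    """Wide report: one row per cross, MP/BP columns per trait with stars,
    LSD rows at both alphas appended."""
    traits = list(thresholds["trait"].unique())
    header = ["cross"]
    for trait in traits:
        header += [f"{trait}_MP", f"{trait}_BP"]
    lines = [sep.join(header)]

    def cell(h: float, sig: object) -> str:
        if pd.isna(h):
            return "NA"
        return f"{h:.2f} {sig}" if sig else f"{h:.2f}"

    if not entries.empty:
        for cid in entries["cross"].unique():
            sub = entries[entries["cross"] == cid].set_index("trait")
            row = [cid]
            for trait in traits:
                rec = sub.loc[trait]
                row += [cell(rec["hmp_pct"], rec["sig_mp"]),
                        cell(rec["hbp_pct"], rec["sig_bp"])]
            lines.append(sep.join(row))
    for alpha in sorted(thresholds["alpha"].unique(), reverse=True):
        row = [f"L.S.D. at {alpha:g}"]
        for trait in traits:
            rec = thresholds[(thresholds["trait"] == trait)
                             & (thresholds["alpha"] == alpha)].iloc[0]
            row += [f"{rec['lsd_mp']:.2f}", f"{rec['lsd_bp']:.2f}"]
        lines.append(sep.join(row))
    return "\n".join(lines) + "\n"


def write_anova_table(anova: Mapping[str, AnovaResult], path: str | Path,
                      sep: str = "\t") -> None:
    rows = []
    for trait, a in anova.items():
        rows.append({
            "trait": trait,
            "ss_genotype": a.ss_genotype, "df_genotype": a.df_genotype,
            "ms_genotype": a.ms_genotype,
            "ss_block": a.ss_block, "df_block": a.df_block,
            "ms_block": a.ms_block,
            "ss_error": a.ss_error, "df_error": a.df_error, "mse": a.mse,
        })
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
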