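"""Synthetic half-diallel datasets with known genetic architecture.

Emulates the study design the package analyses: a handful of fully
homozygous (inbred) parents genotyped at multi-allelic SSR loci, crossed in a
half diallel, with a quantitative trait generated by an additive + dominance
model and measured in a randomized complete block design:

    parent value   v_P  = mu + sum_l a_l(allele_P at l)
    F1 value       v_F1 = (v_P1 + v_P2) / 2 + sum_{l heterozygous} d_l
    observation    y    = v + block_b + Normal(0, sigma)

Per-locus additive allele values a_l(.) are drawn Normal(0, additive_effects_l)
once per allele; dominance deviations d_l are fixed per locus.  When marker
loci coincide with trait loci (``markers_are_trait_loci``) the F1
heterozygosity fraction at trait loci equals the Nei DA distance between the
parents, so mid-parent heterosis has a closed form against which every
downstream estimate can be checked:

    true HMP% = 100 * sum_{het l} d_l / MP.

Defaults mirror the scale of a small rice drought trial: 8 parents (hence 28
crosses), 11 SSR loci with up to 4 alleles each, 3 blocks.  An optional
``stress_multiplier`` shrinks the baseline mean to mimic a water-deficit
environment; it is a label-level device only, no genotype-by-environment
interaction is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .heterosis import DiallelDesign, cross_id
from .markers import GenotypeTable

__all__ = ["SimulationConfig", "GroundTruth", "simulate_parents",
           "simulate_phenotypes", "simulate_dataset", "write_ground_truth"]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator; defaults match a small rice diallel trial."""

    n_parents: int = 8
    n_marker_loci: int = 11
    alleles_per_locus: int = 4
    markers_are_trait_loci: bool = True
    n_trait_loci: int = 11          # ignored when markers_are_trait_loci
    additive_effects: float | Sequence[float] = 0.0   # per-locus SD of allele values
    dominance_effects: float | Sequence[float] = 1.0  # per-locus d_l, trait units
    baseline_mu: float = 30.0       # trait units (grain-yield-per-plant scale)
    stress_multiplier: float = 1.0  # shrink mu to mimic a stress environment
    block_effects: tuple[float, ...] | None = None    # per-block shifts
    residual_sigma: float = 1.0     # plot-level noise SD, trait units
    r_blocks: int = 3
    allele_freq_skew: float = 0.0   # 0 = uniform sampling; >0 Dirichlet(1/(1+skew))
    trait: str = "grain_yield"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_parents < 2 or self.n_marker_loci < 1:
            raise ValueError("need >= 2 parents and >= 1 marker locus")
        if self.alleles_per_locus < 1:
            raise ValueError("alleles_per_locus must be >= 1")
        if self.residual_sigma < 0:
            raise ValueError("residual_sigma must be >= 0")
        if self.r_blocks < 2:
            raise ValueError("r_blocks must be >= 2")
        if self.block_effects is not None and len(self.block_effects) != self.r_blocks:
            raise ValueError("block_effects length must equal r_blocks")

    def per_locus(self, value: float | Sequence[float], n: int) -> np.ndarray:
        arr = np.asarray(value, dtype=float)
        if arr.ndim == 0:
            return np.full(n, float(arr))
        if arr.shape != (n,):
            raise ValueError(f"per-locus vector has length {arr.shape}, "
                             f"expected {n}")
        return arr


@dataclass(frozen=True)
class GroundTruth:
    """Exact per-cross genetic quantities implied by the generator."""

    table: pd.DataFrame = field(repr=False)
    # columns: cross, mp, dominance_dev, hmp_pct, het_fraction


def _parent_ids(n: int) -> list[str]:
    return [f"P{i+1}" for i in range(n)]


def simulate_parents(config: SimulationConfig) -> GenotypeTable:
    """Homozygous parental genotypes; deterministic under config.seed.

    Allele labels are fragment-size-like integers (distinct per locus).
    Sampling is uniform over the locus allele set by default; a positive
    ``allele_freq_skew`` draws locus allele probabilities from a Dirichlet to
    stress-test the diversity statistics.
    """
    rng = np.random.default_rng(config.seed)
    loci = [f"L{j+1}" for j in range(config.n_marker_loci)]
    labels = {
        locus: [str(100 + 10 * j + 2 * k)
                for k in range(config.alleles_per_locus)]
        for j, locus in enumerate(loci)
    }
    rows = {}
    for locus in loci:
        k = config.alleles_per_locus
        if config.allele_freq_skew > 0:
            probs = rng.dirichlet(np.full(k, 1.0 / (1.0 + config.allele_freq_skew)))
        else:
            probs = np.full(k, 1.0 / k)
        draws = rng.choice(k, size=config.n_parents, p=probs)
        rows[locus] = [labels[locus][d] for d in draws]
    calls = pd.DataFrame(rows, index=pd.Index(_parent_ids(config.n_parents),
                                              name="line"), dtype=object)
    return GenotypeTable(calls)


def simulate_phenotypes(
    config: SimulationConfig,
    table: GenotypeTable,
    design: DiallelDesign | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Replicated RCBD observations for parents + crosses, with ground truth.

    With ``residual_sigma = 0`` and zero block effects the observed plot
    values equal the genotypic values exactly.
    """
    if design is None:
        design = DiallelDesign(tuple(table.line_ids), r=config.r_blocks)
    if list(design.parents) != table.line_ids:
        raise ValueError("design parents do not match genotype table lines")
    if design.r != config.r_blocks:
        raise ValueError("design replication does not match config.r_blocks")

    if config.markers_are_trait_loci:
        trait_loci = list(table.loci)
    else:
        trait_loci = [f"T{j+1}" for j in range(config.n_trait_loci)]
    n_tl = len(trait_loci)
    a_sd = config.per_locus(config.additive_effects, n_tl)
    d_eff = config.per_locus(config.dominance_effects, n_tl)

    # a separate stream so phenotype noise does not disturb genotype draws
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    # trait-locus genotypes: reuse marker calls, or draw fresh ones
    if config.markers_are_trait_loci:
        geno = {}
        for p in design.parents:
            calls = []
            for l in trait_loci:
                w = table.allele_weights(p, l)
                if w is None or len(w) != 1:
                    raise ValueError(
                        f"trait-locus call for {p!r} at {l!r} must be a "
                        f"single homozygous allele"
                    )
                calls.append(next(iter(w)))
            geno[p] = calls
        allele_sets = [sorted({geno[p][j] for p in design.parents} |
                              set(_locus_alleles(table, l)))
                       for j, l in enumerate(trait_loci)]
    else:
        k = config.alleles_per_locus
        allele_sets = [[f"t{j}a{i}" for i in range(k)] for j in range(n_tl)]
        geno = {p: [allele_sets[j][rng.integers(k)] for j in range(n_tl)]
                for p in design.parents}

    # additive value per (locus, allele)
    additive = [
        {a: (rng.normal(0.0, a_sd[j]) if a_sd[j] > 0 else 0.0)
         for a in allele_sets[j]}
        for j in range(n_tl)
    ]

    mu = config.baseline_mu * config.stress_multiplier
    parent_value = {
        p: mu + sum(additive[j][geno[p][j]] for j in range(n_tl))
        for p in design.parents
    }

    truth_rows = []
    entry_value = dict(parent_value)
    for p1, p2 in design.crosses:
        het = [j for j in range(n_tl) if geno[p1][j] != geno[p2][j]]
        dom = float(sum(d_eff[j] for j in het))
        mp = (parent_value[p1] + parent_value[p2]) / 2.0
        entry_value[cross_id(p1, p2)] = mp + dom
        truth_rows.append({
            "cross": cross_id(p1, p2),
            "mp": mp,
            "dominance_dev": dom,
            "hmp_pct": 100.0 * dom / mp if mp != 0 else np.nan,
            "het_fraction": len(het) / n_tl,
        })

    blocks = (np.asarray(config.block_effects, dtype=float)
              if config.block_effects is not None
              else np.zeros(config.r_blocks))
    records = []
    for entry in design.entries:
        for b in range(config.r_blocks):
            noise = (rng.normal(0.0, config.residual_sigma)
                     if config.residual_sigma > 0 else 0.0)
            records.append((entry, b + 1, config.trait,
                            entry_value[entry] + blocks[b] + noise))
    obs = pd.DataFrame(records, columns=["entry", "block", "trait", "value"])
    return obs, GroundTruth(pd.DataFrame(truth_rows))


def _locus_alleles(table: GenotypeTable, locus: str) -> set[str]:
    out: set[str] = set()
    for line in table.line_ids:
        w = table.allele_weights(line, locus)
        if w:
            out.update(w)
    return out


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[GenotypeTable, pd.DataFrame, GroundTruth, DiallelDesign]:
    """Genotypes, phenotype observations, ground truth and design in one call."""
    table = simulate_parents(config)
    design = DiallelDesign(tuple(table.line_ids), r=config.r_blocks)
    obs, truth = simulate_phenotypes(config, table, design)
    return table, obs, truth, design


def write_ground_truth(truth: GroundTruth, path: str | Path,
                       sep: str = "\t") -> None:
    truth.table.to_csv(path, sep=sep, index=False)


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)
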