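"""Microsatellite (SSR) marker diversity statistics for panels of inbred lines.

Reads a wide genotype table (lines x loci, cells are allele labels, usually
PCR-fragment sizes in base pairs), computes per-locus allele frequencies,
Nei gene diversity H = 1 - sum(p_i^2) (expected heterozygosity) and Botstein
polymorphic information content

    PIC = 1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2,

and aggregates them into a panel summary (total alleles, mean alleles per
locus, mean diversity, polymorphism rate).

Lines are treated as fully homozygous (one allele per locus); a heterozygote
cell written "a/b" is accepted and contributes half a count to each allele.
Allele labels are opaque, pre-binned strings — no fragment-size tolerance
matching is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "MarkerPanel",
    "GenotypeTable",
    "AlleleFrequencySet",
    "LocusSummary",
    "PanelSummary",
    "read_genotypes",
    "read_marker_panel",
    "allele_frequencies",
    "gene_diversity",
    "pic",
    "summarize_panel",
    "summarize_locus",
    "aggregate_panel",
    "write_locus_summaries",
]

MISSING_TOKENS = frozenset({"", "NA", "na", "N/A", ".", "nan"})


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerPanel:
    """Metadata for one microsatellite marker.

    ``chromosome`` is the rice chromosome number (1-12); ``motif`` the repeat
    motif, e.g. ``(GA)14``; ``annealing_temp`` in degrees C; ``expected_size``
    in base pairs.
    """

    marker_name: str
    chromosome: int
    motif: str
    annealing_temp: float
    expected_size: int

    def __post_init__(self) -> None:
        if not 1 <= self.chromosome <= 12:
            raise ValueError(
                f"chromosome must be in [1, 12], got {self.chromosome} "
                f"for marker {self.marker_name!r}"
            )


@dataclass
class GenotypeTable:
    """Allele calls for a set of (assumed homozygous) lines at SSR loci.

    ``calls`` is indexed by line id with one column per locus; cells hold the
    allele label as a string, ``None`` for missing, or ``"x/y"`` for a
    heterozygote.  Every line has a cell for every locus.
    """

    calls: pd.DataFrame

    @property
    def line_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def loci(self) -> list[str]:
        return list(self.calls.columns)

    def allele_weights(self, line: str, locus: str) -> dict[str, float] | None:
        """Within-line allele dosage at ``locus`` (None if the call is missing).

        A homozygous call maps to weight 1.0; an "a/b" heterozygote to 0.5 each.
        """
        cell = self.calls.at[line, locus]
        return parse_call(cell)

    def locus_weights(self, locus: str) -> list[dict[str, float]]:
        """Non-missing allele-weight dicts for every line at ``locus``."""
        out = []
        for line in self.line_ids:
            w = self.allele_weights(line, locus)
            if w is not None:
                out.append(w)
        return out


@dataclass(frozen=True)
class AlleleFrequencySet:
    """Allele frequencies at one locus; proportions sum to 1."""

    locus: str
    frequencies: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.frequencies:
            raise ValueError(f"no alleles for locus {self.locus!r}")
        total = sum(self.frequencies.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(
                f"frequencies at {self.locus!r} sum to {total}, expected 1"
            )
        if any(p < 0 or p > 1 for p in self.frequencies.values()):
            raise ValueError(f"frequencies at {self.locus!r} outside [0, 1]")


@dataclass(frozen=True)
class LocusSummary:
    """Per-locus diversity summary (one output row of the panel table)."""

    locus: str
    n_alleles: int
    min_allele: int | None
    max_allele: int | None
    gene_diversity: float
    pic: float


@dataclass(frozen=True)
class PanelSummary:
    """Panel-level aggregates over loci."""

    n_loci: int
    total_alleles: int
    mean_alleles_per_locus: float
    mean_gene_diversity: float
    min_gene_diversity: float
    max_gene_diversity: float
    mean_pic: float | None
    polymorphism_rate: float  # percent of loci with >= 2 alleles
    loci: tuple[LocusSummary, ...] = field(default=())


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def parse_call(cell: object) -> dict[str, float] | None:
    """Parse one genotype cell into allele weights, or None if missing."""
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    text = str(cell).strip()
    if text in MISSING_TOKENS:
        return None
    if "/" in text:
        a, b = (part.strip() for part in text.split("/", 1))
        if not a or not b:
            raise ValueError(f"malformed heterozygote call {text!r}")
        if a == b:
            return {a: 1.0}
        return {a: 0.5, b: 0.5}
    return {text: 1.0}


def _detect_delimiter(header: str) -> str:
    return "\t" if "\t" in header else ","


def read_genotypes(path: str | Path) -> GenotypeTable:
    """Read a delimited genotype file (header = loci, first column = line ids).

    Comma or tab delimiter is autodetected from the header.  Cells equal to
    "NA" (or empty, ".") are missing; "x/y" cells are heterozygotes.  Duplicate
    line ids and ragged rows are errors.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise ValueError(f"empty genotype file: {path}")
    sep = _detect_delimiter(lines[0])
    header = [h.strip() for h in lines[0].split(sep)]
    loci = header[1:]
    if not loci:
        raise ValueError(f"no locus columns in {path}")
    if len(set(loci)) != len(loci):
        raise ValueError(f"duplicate locus names in {path}")

    ids: list[str] = []
    rows: list[list[str | None]] = []
    for lineno, raw in enumerate(lines[1:], start=2):
        fields = [f.strip() for f in raw.split(sep)]
        if len(fields) != len(header):
            raise ValueError(
                f"ragged row at line {lineno} of {path.name} "
                f"(line id {fields[0]!r}): {len(fields)} fields, "
                f"expected {len(header)}"
            )
        line_id = fields[0]
        if line_id in ids:
            raise ValueError(f"duplicate line id {line_id!r} in {path.name}")
        ids.append(line_id)
        rows.append([None if f in MISSING_TOKENS else f for f in fields[1:]])

    if not ids:
        raise ValueError(f"no data rows in {path}")
    calls = pd.DataFrame(rows, index=pd.Index(ids, name="line"), columns=loci,
                         dtype=object)
    # validate cells eagerly so malformed files fail at read time
    for line in ids:
        for locus in loci:
            parse_call(calls.at[line, locus])
    return GenotypeTable(calls)


def read_marker_panel(path: str | Path) -> list[MarkerPanel]:
    """Read marker metadata (name, chromosome, motif, Tm, expected size)."""
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower().strip(): c for c in df.columns}
    required = ["marker_name", "chromosome", "motif", "annealing_temp",
                "expected_size"]
    missing = [c for c in required if c not in cols]
    if missing:
        raise ValueError(f"marker metadata missing columns: {missing}")
    panel = [
        MarkerPanel(
            marker_name=str(row[cols["marker_name"]]),
            chromosome=int(row[cols["chromosome"]]),
            motif=str(row[cols["motif"]]),
            annealing_temp=float(row[cols["annealing_temp"]]),
            expected_size=int(row[cols["expected_size"]]),
        )
        for _, row in df.iterrows()
    ]
    names = [m.marker_name for m in panel]
    if len(set(names)) != len(names):
        raise ValueError("duplicate marker names in metadata")
    return panel


# ---------------------------------------------------------------------------
# diversity statistics
# ---------------------------------------------------------------------------

def allele_frequencies(table: GenotypeTable, locus: str) -> AlleleFrequencySet:
    """Allele frequencies at ``locus`` among non-missing calls.

    Homozygous calls count 1 toward their allele, "a/b" heterozygotes 0.5
    toward each; the denominator is the number of non-missing calls.
    """
    if locus not in table.calls.columns:
        raise KeyError(f"locus {locus!r} not in table")
    weights = table.locus_weights(locus)
    if not weights:
        raise ValueError(f"all calls missing at locus {locus!r}")
    counts: dict[str, float] = {}
    for w in weights:
        for allele, dose in w.items():
            counts[allele] = counts.get(allele, 0.0) + dose
    n = len(weights)
    return AlleleFrequencySet(locus, {a: c / n for a, c in counts.items()})


def gene_diversity(freqs: AlleleFrequencySet) -> float:
    """Nei gene diversity H = 1 - sum(p_i^2), in [0, 1 - 1/k]."""
    return 1.0 - sum(p * p for p in freqs.frequencies.values())


def pic(freqs: AlleleFrequencySet) -> float:
    """Botstein polymorphic information content.

    PIC = 1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2.  The cross term equals
    (sum p^2)^2 - sum p^4, so PIC <= H always, with equality only for a
    monomorphic locus.
    """
    ps = list(freqs.frequencies.values())
    s2 = sum(p * p for p in ps)
    s4 = sum(p ** 4 for p in ps)
    return 1.0 - s2 - (s2 * s2 - s4)


def _allele_size_range(alleles: Iterable[str]) -> tuple[int | None, int | None]:
    sizes = []
    for a in alleles:
        try:
            sizes.append(int(a))
        except ValueError:
            return None, None
    return (min(sizes), max(sizes)) if sizes else (None, None)


def summarize_locus(table: GenotypeTable, locus: str) -> LocusSummary:
    freqs = allele_frequencies(table, locus)
    lo, hi = _allele_size_range(freqs.frequencies)
    return LocusSummary(
        locus=locus,
        n_alleles=len(freqs.frequencies),
        min_allele=lo,
        max_allele=hi,
        gene_diversity=gene_diversity(freqs),
        pic=pic(freqs),
    )


def summarize_panel(table: GenotypeTable) -> PanelSummary:
    """Per-locus summaries plus panel aggregates for a genotype table."""
    if not table.loci:
        raise ValueError("empty genotype table")
    summaries = tuple(summarize_locus(table, locus) for locus in table.loci)
    return aggregate_panel(
        n_alleles=[s.n_alleles for s in summaries],
        gene_diversity=[s.gene_diversity for s in summaries],
        pic_values=[s.pic for s in summaries],
        loci=summaries,
    )


def aggregate_panel(
    n_alleles: Sequence[int],
    gene_diversity: Sequence[float],
    pic_values: Sequence[float] | None = None,
    loci: tuple[LocusSummary, ...] = (),
) -> PanelSummary:
    """Panel aggregates from per-locus allele counts and diversity values.

    Accepts externally supplied per-locus values (e.g. a published marker
    description table) as well as values computed by :func:`summarize_panel`.
    """
    if len(n_alleles) != len(gene_diversity) or not n_alleles:
        raise ValueError("need equal, non-empty per-locus vectors")
    n_loci = len(n_alleles)
    return PanelSummary(
        n_loci=n_loci,
        total_alleles=int(sum(n_alleles)),
        mean_alleles_per_locus=sum(n_alleles) / n_loci,
        mean_gene_diversity=sum(gene_diversity) / n_loci,
        min_gene_diversity=min(gene_diversity),
        max_gene_diversity=max(gene_diversity),
        mean_pic=(sum(pic_values) / n_loci) if pic_values is not None else None,
        polymorphism_rate=100.0 * sum(k >= 2 for k in n_alleles) / n_loci,
        loci=loci,
    )


def write_locus_summaries(summary: PanelSummary, path: str | Path,
                          sep: str = "\t") -> None:
    """Write the per-locus table plus Total/Mean footer rows."""
    rows = [
        {
            "locus": s.locus,
            "min_allele": s.min_allele,
            "max_allele": s.max_allele,
            "n_alleles": s.n_alleles,
            "gene_diversity": round(s.gene_diversity, 4),
            "pic": round(s.pic, 4),
        }
        for s in summary.loci
    ]
    rows.append({"locus": "Total", "min_allele": "", "max_allele": "",
                 "n_alleles": summary.total_alleles, "gene_diversity": "",
                 "pic": ""})
    rows.append({"locus": "Mean", "min_allele": "", "max_allele": "",
                 "n_alleles": round(summary.mean_alleles_per_locus, 2),
                 "gene_diversity": round(summary.mean_gene_diversity, 3),
                 "pic": (round(summary.mean_pic, 3)
                         if summary.mean_pic is not None else "")})
    pd.DataFrame(rows, dtype=object).to_csv(path, sep=sep, index=False)
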