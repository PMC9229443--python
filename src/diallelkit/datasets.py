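"""Bundled worked-example data.

``RICE_SSR_PANEL`` is the published per-locus description of an 11-marker
rice microsatellite panel scored on 8 inbred rice varieties evaluated in a
half diallel under drought: marker name, scored allele-size range (bp),
number of alleles detected, and the reported gene-diversity value.  It is
used as input for panel-level aggregation (total alleles, mean alleles per
locus, mean diversity) — per-locus diversity values are taken as given, not
recomputed, since the underlying genotype calls were not published.
"""

from __future__ import annotations

from .markers import aggregate_panel, PanelSummary

__all__ = ["RICE_SSR_PANEL", "rice_panel_summary"]

# marker, min allele (bp), max allele (bp), n alleles, reported gene diversity
RICE_SSR_PANEL: tuple[tuple[str, int, int, int, float], ...] = (
    ("RM 1",   67, 119, 4, 0.534),
    ("RM 452", 192, 213, 4, 0.654),
    ("RM 338", 178, 184, 4, 0.456),
    ("RM 124", 257, 289, 3, 0.789),
    ("RM 162", 191, 244, 2, 0.549),
    ("RM 118", 149, 165, 3, 0.687),
    ("RM 433", 216, 248, 3, 0.827),
    ("RM 316", 194, 216, 4, 0.597),
    ("RM 271", 80, 120, 4, 0.751),
    ("RM 144", 216, 295, 4, 0.652),
    ("RM 19",  192, 250, 4, 0.745),
)


def rice_panel_summary() -> PanelSummary:
    """Panel aggregates of the bundled 11-marker rice SSR description."""
    return aggregate_panel(
        n_alleles=[row[3] for row in RICE_SSR_PANEL],
        gene_diversity=[row[4] for row in RICE_SSR_PANEL],
    )
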