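"""Published species-count bookkeeping for the global tetrapod study design.

The study compiled IUCN range polygons for four tetrapod groups and retained
the subset with complete body-size and diet information.  These printed
per-group counts are inputs to sanity checks on the data-preparation
arithmetic (totals and the retained fraction), not something the pipeline
recomputes from raw data.
"""

from __future__ import annotations

#: Species with an IUCN range polygon compiled per group.
IUCN_COMPILED_COUNTS: dict[str, int] = {
    "amphibian": 220,
    "squamate": 2512,
    "bird": 7949,
    "mammal": 5107,
}

#: Species retained after requiring body mass and diet information.
RETAINED_COUNTS: dict[str, int] = {
    "amphibian": 178,
    "squamate": 1501,
    "bird": 6607,
    "mammal": 3748,
}

#: Grid cells entering the statistical analyses after the richness filter.
ANALYSIS_CELLS: int = 2722


def total_compiled() -> int:
    """Total number of species with compiled range polygons."""
    return sum(IUCN_COMPILED_COUNTS.values())


def total_retained() -> int:
    """Total number of species retained with full trait information."""
    return sum(RETAINED_COUNTS.values())


def retained_fraction_percent(ndigits: int = 1) -> float:
    """Retained species as a percentage of the compiled pool.

    Rounded to ``ndigits`` decimals (one decimal place by default, the
    precision the totals are usually reported at).
    """
    return round(100.0 * total_retained() / total_compiled(), ndigits)
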