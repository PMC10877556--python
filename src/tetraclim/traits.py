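"""Trophic classification and community-wide trait aggregation.

Species are binned into three trophic levels from diet composition: primary
consumers (> 90% plant material), secondary consumers (> 90% animal
material), and omnivores (everything else).  The levels carry isotope-based
weights 2 / 2.5 / 3, and the community trophic-structure index is the mean
weight over the species present in a cell: values near 2 indicate a
bottom-heavy pyramid dominated by herbivores, values near 3 a top-heavy
pyramid dominated by predators and omnivores.

Community size structure is summarized by the log10 of the median body mass
(grams) and the variance of log10 body mass; body mass distributions are
strongly right-skewed, which is why aggregation happens on the log scale.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TROPHIC_WEIGHTS",
    "GROUPS",
    "SpeciesTraitRecord",
    "TrophicLevel",
    "classify_trophic_level",
    "trophic_structure_index",
    "community_size_structure",
    "aggregate_assemblage_traits",
]

#: Trophic-level weights (nitrogen-isotope positioning of omnivores midway).
TROPHIC_WEIGHTS: dict[str, float] = {"primary": 2.0, "omnivore": 2.5, "secondary": 3.0}

#: Tetrapod groups analyzed separately throughout the pipeline.
GROUPS: tuple[str, ...] = ("amphibian", "bird", "mammal", "squamate")

#: Diet-fraction threshold for primary/secondary classification (strict >).
DIET_THRESHOLD: float = 0.9

_FRACTION_TOL = 1e-6


@dataclasses.dataclass(frozen=True)
class TrophicLevel:
    category: str  # "primary" | "omnivore" | "secondary"
    weight: float

    def __post_init__(self) -> None:
        if TROPHIC_WEIGHTS.get(self.category) != self.weight:
            raise ValueError(f"weight {self.weight} does not match category {self.category!r}")


@dataclasses.dataclass(frozen=True)
class SpeciesTraitRecord:
    """Per-species trait record: group, body mass (g), diet fractions.

    ``diet_plant`` and ``diet_animal`` are proportions in [0, 1] summing to
    at most 1; the remainder is unclassified diet ("other").
    """

    species: str
    group: str
    body_mass_g: float
    diet_plant: float
    diet_animal: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if not self.body_mass_g > 0:
            raise ValueError("body mass must be positive")
        for frac in (self.diet_plant, self.diet_animal):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("diet fractions must lie in [0, 1]")
        if self.diet_plant + self.diet_animal > 1.0 + _FRACTION_TOL:
            raise ValueError("diet fractions sum to more than 1")

    @property
    def trophic_level(self) -> TrophicLevel:
        return classify_trophic_level(self.diet_plant, self.diet_animal)


def classify_trophic_level(diet_plant: float, diet_animal: float) -> TrophicLevel:
    """Classify a species' trophic level from its diet composition.

    Strictly more than 90% plant-derived diet makes a primary consumer,
    strictly more than 90% animal-derived diet a secondary consumer, and any
    mixed diet without such a predominance an omnivore.
    """
    if not (0.0 <= diet_plant <= 1.0 and 0.0 <= diet_animal <= 1.0):
        raise ValueError("diet fractions must lie in [0, 1]")
    if diet_plant + diet_animal > 1.0 + _FRACTION_TOL:
        raise ValueError("diet fractions sum to more than 1")
    if diet_plant > DIET_THRESHOLD:
        category = "primary"
    elif diet_animal > DIET_THRESHOLD:
        category = "secondary"
    else:
        category = "omnivore"
    return TrophicLevel(category=category, weight=TROPHIC_WEIGHTS[category])


def trophic_structure_index(levels: Iterable[TrophicLevel]) -> float:
    """Mean trophic-level weight of the species in a community.

    Bounded in [2, 3]; 2 means all primary consumers (bottom-heavy), 3 all
    secondary consumers (top-heavy).  Undefined (raises) for an empty
    community.
    """
    weights = [lvl.weight for lvl in levels]
    if not weights:
        raise ValueError("trophic structure index undefined for an empty community")
    return float(np.mean(weights))


def community_size_structure(
    masses_g: Sequence[float], log_scale_variance: bool = True
) -> tuple[float, float]:
    """Community body-size summary: (log10 median mass, variance).

    ``body_size`` is log10 of the median body mass in grams.  The variance is
    the sample (n-1) variance of log10 mass by default; set
    ``log_scale_variance=False`` for raw-gram variance.  A single-species
    community gets variance 0.
    """
    masses = np.asarray(masses_g, dtype=float)
    if masses.size == 0:
        raise ValueError("community size structure undefined for an empty community")
    if np.any(masses <= 0):
        raise ValueError("body masses must be positive")
    body_size = float(np.log10(np.median(masses)))
    values = np.log10(masses) if log_scale_variance else masses
    variance = float(np.var(values, ddof=1)) if masses.size > 1 else 0.0
    return body_size, variance


def aggregate_assemblage_traits(
    presence: pd.DataFrame,
    traits: pd.DataFrame,
    cells: Sequence | None = None,
    log_scale_variance: bool = True,
) -> pd.DataFrame:
    """Aggregate species traits to community-wide traits per cell and group.

    Parameters
    ----------
    presence : DataFrame
        Binary cell x species matrix (index: cell ids, columns: species ids).
    traits : DataFrame
        One row per species with columns ``species``, ``group``,
        ``body_mass_g``, ``diet_plant``, ``diet_animal``.  Every species
        present in ``presence`` must have a record (species without traits
        are removed upstream).
    cells : optional
        Restrict output to these cell ids (e.g., the richness-filtered set).

    Returns
    -------
    DataFrame with columns ``cell``, ``group``, ``richness``, ``body_size``,
    ``size_variance``, ``trophic_structure`` — one row per (cell, group) with
    at least one species present.
    """
    traits = traits.set_index("species") if "species" in traits.columns else traits
    missing = presence.columns.difference(traits.index)
    if len(missing) > 0:
        raise ValueError(
            f"{len(missing)} present species lack trait records (e.g. {list(missing[:3])}); "
            "species without traits must be removed upstream"
        )
    if cells is not None:
        presence = presence.loc[presence.index.intersection(cells)]
    log_mass = np.log10(traits["body_mass_g"].astype(float))
    weight = traits.apply(
        lambda r: classify_trophic_level(r["diet_plant"], r["diet_animal"]).weight, axis=1
    )
    rows = []
    for group, sp in traits.groupby("group").groups.items():
        sp = presence.columns.intersection(sp)
        if len(sp) == 0:
            continue
        sub = presence[sp].to_numpy(dtype=bool)
        masses = traits.loc[sp, "body_mass_g"].to_numpy(dtype=float)
        lmass = log_mass.loc[sp].to_numpy()
        wts = weight.loc[sp].to_numpy(dtype=float)
        for i, cell in enumerate(presence.index):
            present = sub[i]
            k = int(present.sum())
            if k == 0:
                continue
            body_size = float(np.log10(np.median(masses[present])))
            vals = lmass[present] if log_scale_variance else masses[present]
            variance = float(np.var(vals, ddof=1)) if k > 1 else 0.0
            rows.append(
                {
                    "cell": cell,
                    "group": group,
                    "richness": k,
                    "body_size": body_size,
                    "size_variance": variance,
                    "trophic_structure": float(wts[present].mean()),
                }
            )
    return pd.DataFrame(rows, columns=["cell", "group", "richness", "body_size", "size_variance", "trophic_structure"])
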