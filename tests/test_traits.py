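"""Trophic classification and community-wide trait aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tetraclim.traits import (
    TROPHIC_WEIGHTS,
    SpeciesTraitRecord,
    TrophicLevel,
    aggregate_assemblage_traits,
    classify_trophic_level,
    community_size_structure,
    trophic_structure_index,
)


@pytest.mark.parametrize(
    "plant,animal,category,weight",
    [
        (0.95, 0.02, "primary", 2.0),
        (0.05, 0.92, "secondary", 3.0),
        (0.60, 0.40, "omnivore", 2.5),
        (0.90, 0.10, "omnivore", 2.5),  # threshold is strict: exactly 90% is mixed
        (0.10, 0.90, "omnivore", 2.5),
    ],
)
def test_trophic_classification(plant, animal, category, weight):
    level = classify_trophic_level(plant, animal)
    assert level.category == category
    assert level.weight == weight


def test_diet_fractions_must_be_proportions():
    with pytest.raises(ValueError):
        classify_trophic_level(0.7, 0.7)
    with pytest.raises(ValueError):
        classify_trophic_level(-0.1, 0.5)
    with pytest.raises(ValueError):
        TrophicLevel(category="primary", weight=3.0)


@pytest.mark.parametrize(
    "categories,expected",
    [
        (["primary", "primary"], 2.0),
        (["secondary"] * 3, 3.0),
        (["primary", "secondary"], 2.5),
        (["primary", "omnivore", "secondary"], 2.5),
    ],
)
def test_trophic_structure_index(categories, expected):
    levels = [TrophicLevel(c, TROPHIC_WEIGHTS[c]) for c in categories]
    assert trophic_structure_index(levels) == pytest.approx(expected)


def test_trophic_index_empty_community_is_undefined():
    with pytest.raises(ValueError):
        trophic_structure_index([])


@given(st.lists(st.sampled_from(["primary", "omnivore", "secondary"]), min_size=1, max_size=20))
def test_trophic_index_bounded_and_monotone(categories):
    levels = [TrophicLevel(c, TROPHIC_WEIGHTS[c]) for c in categories]
    idx = trophic_structure_index(levels)
    assert 2.0 <= idx <= 3.0
    if "primary" in categories:
        promoted = list(categories)
        promoted[promoted.index("primary")] = "secondary"
        levels2 = [TrophicLevel(c, TROPHIC_WEIGHTS[c]) for c in promoted]
        assert trophic_structure_index(levels2) >= idx


def test_community_size_structure_examples():
    body, var = community_size_structure([10.0, 100.0, 1000.0])
    assert body == pytest.approx(2.0)  # median 100 g
    assert var == pytest.approx(1.0)  # log10 masses {1,2,3}, sample variance 1
    body, var = community_size_structure([50.0, 50.0, 50.0])
    assert var == 0.0
    _, var_single = community_size_structure([123.0])
    assert var_single == 0.0
    with pytest.raises(ValueError):
        community_size_structure([10.0, -1.0])
    with pytest.raises(ValueError):
        community_size_structure([])


@given(st.floats(min_value=0.1, max_value=1e4), st.lists(st.floats(min_value=0.5, max_value=1e5), min_size=2, max_size=12))
def test_size_variance_invariant_to_mass_rescaling(factor, masses):
    """Multiplying masses by a constant shifts log-mass, leaving variance unchanged."""
    _, v1 = community_size_structure(masses)
    _, v2 = community_size_structure([m * factor for m in masses])
    assert v2 == pytest.approx(v1, abs=1e-8)


def _random_fixture(rng, n_cells=6, n_species=15):
    species = [f"sp{i}" for i in range(n_species)]
    presence = pd.DataFrame(
        rng.integers(0, 2, size=(n_cells, n_species)),
        index=[f"c{i}" for i in range(n_cells)],
        columns=species,
    )
    traits = pd.DataFrame(
        {
            "species": species,
            "group": rng.choice(["bird", "mammal"], size=n_species),
            "body_mass_g": 10.0 ** rng.uniform(0, 4, size=n_species),
            "diet_plant": rng.uniform(0, 1, size=n_species),
        }
    )
    traits["diet_animal"] = (1.0 - traits["diet_plant"]) * rng.uniform(0, 1, size=n_species)
    return presence, traits


def test_aggregation_matches_brute_force(rng):
    """Aggregated cell traits equal an explicit per-cell, per-species loop."""
    presence, traits = _random_fixture(rng)
    out = aggregate_assemblage_traits(presence, traits).set_index(["cell", "group"])
    by_sp = traits.set_index("species")
    checked = 0
    for cell in presence.index:
        for group in ("bird", "mammal"):
            members = [
                s for s in presence.columns
                if presence.loc[cell, s] == 1 and by_sp.loc[s, "group"] == group
            ]
            if not members:
                assert (cell, group) not in out.index
                continue
            masses = [by_sp.loc[s, "body_mass_g"] for s in members]
            weights = [
                classify_trophic_level(by_sp.loc[s, "diet_plant"], by_sp.loc[s, "diet_animal"]).weight
                for s in members
            ]
            row = out.loc[(cell, group)]
            assert row["richness"] == len(members)
            assert row["body_size"] == pytest.approx(np.log10(np.median(masses)))
            expected_var = np.var(np.log10(masses), ddof=1) if len(members) > 1 else 0.0
            assert row["size_variance"] == pytest.approx(expected_var)
            assert row["trophic_structure"] == pytest.approx(np.mean(weights))
            checked += 1
    assert checked >= 4


def test_aggregation_invariant_to_species_order(rng):
    presence, traits = _random_fixture(rng)
    out1 = aggregate_assemblage_traits(presence, traits)
    perm = rng.permutation(presence.columns)
    out2 = aggregate_assemblage_traits(presence[perm], traits.sample(frac=1, random_state=3))
    key = ["cell", "group"]
    pd.testing.assert_frame_equal(
        out1.sort_values(key).reset_index(drop=True),
        out2.sort_values(key).reset_index(drop=True),
    )


def test_aggregation_rejects_missing_trait_records(rng):
    presence, traits = _random_fixture(rng)
    with pytest.raises(ValueError, match="lack trait records"):
        aggregate_assemblage_traits(presence, traits.iloc[:-2])


def test_species_trait_record_validation():
    rec = SpeciesTraitRecord("sp1", "bird", 25.0, 0.95, 0.01)
    assert rec.trophic_level.category == "primary"
    with pytest.raises(ValueError):
        SpeciesTraitRecord("sp2", "bird", -5.0, 0.5, 0.2)
    with pytest.raises(ValueError):
        SpeciesTraitRecord("sp3", "dinosaur", 5.0, 0.5, 0.2)
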