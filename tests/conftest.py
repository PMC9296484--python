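import numpy as np
import pytest

from traitspace.trait_data import (
    FuzzyTraitTable,
    Trait,
    TraitDictionary,
    TraitGroup,
)


def make_dictionary(layout: list[tuple[str, int, list[str]]]) -> TraitDictionary:
    """Build a dictionary from (group_name, max_code, [abbr, ...]) triples."""
    groups = []
    for name, max_code, abbrs in layout:
        traits = tuple(Trait(f"{name} state {a}", a) for a in abbrs)
        groups.append(TraitGroup(name, max_code, traits))
    return TraitDictionary(tuple(groups))


@pytest.fixture
def tiny_dictionary() -> TraitDictionary:
    """Two trait groups: one 0-3 coded (2 states), one 0-5 coded (3 states)."""
    return make_dictionary(
        [("Feeding", 3, ["F1", "F2"]), ("Size", 5, ["S1", "S2", "S3"])]
    )


def make_table(
    dictionary: TraitDictionary,
    matrix,
    mask=None,
    groups=None,
    full_groups=None,
) -> FuzzyTraitTable:
    matrix = np.asarray(matrix, dtype=int)
    n = matrix.shape[0]
    return FuzzyTraitTable(
        taxon_ids=[f"t{i}" for i in range(n)],
        groups=list(groups) if groups is not None else ["G"] * n,
        matrix=matrix,
        mask=np.ones_like(matrix, dtype=bool) if mask is None else np.asarray(mask, bool),
        dictionary=dictionary,
        full_groups=list(full_groups) if full_groups is not None else None,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)
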