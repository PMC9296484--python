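"""Synthetic fuzzy-coded trait tables with planted taxonomic syndromes.

The generator emulates the structure of a continental macroinvertebrate trait
database: ~600 taxa in a dozen major taxonomic groups, 63 fuzzy-coded traits
in 11 groups with 0–3 / 0–5 integer affinity coding, about 1% of cells
unknown, and group-level trait *syndromes* — each taxonomic group follows a
characteristic affinity profile, so groups separate in ordination the way
real taxonomic groups do.

Each group gets an archetype: a [0, 1] affinity profile over all traits.
Taxa are noisy copies of their group's archetype, rescaled to the integer
coding of each trait group.  ``syndrome_strength`` interpolates between one
shared profile (0: no group structure at all) and fully group-specific
profiles (1).  Archetype entries are drawn from a Beta(0.4, 1.1) law, which
pushes mass toward 0 with a thinner tail near 1 — fuzzy trait profiles are
sparse in practice: most taxa have no affinity for most states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trait_data import FuzzyTraitTable, TraitDictionary, default_dictionary

__all__ = [
    "SyntheticConfig",
    "DEFAULT_GROUP_SIZES",
    "OTHERS_COMPOSITION",
    "generate_archetypes",
    "simulate_fuzzy_table",
    "inject_missingness",
    "simulate_dataset",
]

#: Default taxon counts per major taxonomic group (total 596).  The mix
#: follows the composition typical of European macroinvertebrate trait
#: databases, where Coleoptera and Trichoptera dominate the taxon list and
#: Bivalvia is the smallest named group.
DEFAULT_GROUP_SIZES: dict[str, int] = {
    "Annelida": 42,
    "Gastropoda": 41,
    "Bivalvia": 10,
    "Crustacea": 28,
    "Ephemeroptera": 37,
    "Plecoptera": 31,
    "Odonata": 39,
    "Heteroptera": 29,
    "Coleoptera": 173,
    "Trichoptera": 96,
    "Diptera": 38,
    "Others": 32,
}

#: How the pooled "Others" group decomposes into real (rare) taxonomic
#: groups, used to populate the full-resolution label vector.
OTHERS_COMPOSITION: dict[str, int] = {
    "Porifera": 4,
    "Cnidaria": 4,
    "Bryozoa": 4,
    "Platyhelminthes": 3,
    "Nemertea": 3,
    "Nematomorpha": 3,
    "Hymenoptera": 3,
    "Lepidoptera": 3,
    "Megaloptera": 3,
    "Neuroptera": 2,
}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic trait-table generator.

    noise_sd is the standard deviation of the Gaussian taxon-level scatter
    around the group archetype, on the [0, 1] affinity scale; 0.15 keeps
    groups distinct but overlapping, as in real ordinations.
    """

    n_taxa_per_group: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    dictionary: TraitDictionary = field(default_factory=default_dictionary)
    syndrome_strength: float = 0.8
    noise_sd: float = 0.15
    missing_rate: float = 0.0103
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_taxa_per_group.values()):
            raise ValueError("every group needs at least one taxon")
        if not 0.0 <= self.syndrome_strength <= 1.0:
            raise ValueError("syndrome_strength must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")

    @property
    def n_taxa(self) -> int:
        return sum(self.n_taxa_per_group.values())


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round halves away from zero (0.5 -> 1), unlike numpy's banker's
    rounding; inputs here are non-negative."""
    return np.floor(x + 0.5).astype(int)


def generate_archetypes(config: SyntheticConfig) -> dict[str, np.ndarray]:
    """One [0, 1] affinity profile per taxonomic group, fixed by the seed.

    Profiles are convex mixtures ``(1 - s) * shared + s * group_specific``
    with s = ``syndrome_strength``, so s = 0 collapses every group onto the
    same shared profile and s > 0 makes them pairwise distinct.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    p = config.dictionary.n_traits
    shared = rng.beta(0.4, 1.1, size=p)
    s = config.syndrome_strength
    archetypes: dict[str, np.ndarray] = {}
    for group in config.n_taxa_per_group:
        specific = rng.beta(0.4, 1.1, size=p)
        archetypes[group] = np.clip((1.0 - s) * shared + s * specific, 0.0, 1.0)
    return archetypes


def simulate_fuzzy_table(config: SyntheticConfig) -> FuzzyTraitTable:
    """Simulate a fully observed integer affinity table.

    Per taxon: continuous affinity = archetype + N(0, noise_sd), clipped to
    [0, 1], scaled by the trait group's max code and rounded half-away-from-
    zero to an integer code.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    archetypes = generate_archetypes(config)
    max_codes = config.dictionary.column_max_codes().astype(float)
    p = config.dictionary.n_traits

    rows, taxa, groups, full_groups = [], [], [], []
    others_pool = [
        label for label, k in OTHERS_COMPOSITION.items() for _ in range(k)
    ]
    counter = 0
    for group, n in config.n_taxa_per_group.items():
        base = archetypes[group]
        noise = (
            rng.normal(0.0, config.noise_sd, size=(n, p))
            if config.noise_sd > 0
            else np.zeros((n, p))
        )
        affin = np.clip(base[None, :] + noise, 0.0, 1.0)
        rows.append(_round_half_away(affin * max_codes[None, :]))
        for i in range(n):
            taxa.append(f"taxon_{counter:04d}")
            groups.append(group)
            if group == "Others":
                full_groups.append(others_pool[i % len(others_pool)])
            else:
                full_groups.append(group)
            counter += 1

    matrix = np.vstack(rows)
    return FuzzyTraitTable(
        taxon_ids=taxa,
        groups=groups,
        matrix=matrix,
        mask=np.ones_like(matrix, dtype=bool),
        dictionary=config.dictionary,
        full_groups=full_groups,
    )


def inject_missingness(
    table: FuzzyTraitTable, rate: float, seed: int
) -> FuzzyTraitTable:
    """Mask each observed cell independently with probability ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("missingness rate must lie in [0, 1)")
    if rate == 0.0:
        return table
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    drop = rng.random(table.mask.shape) < rate
    return FuzzyTraitTable(
        taxon_ids=list(table.taxon_ids),
        groups=list(table.groups),
        matrix=table.matrix.copy(),
        mask=table.mask & ~drop,
        dictionary=table.dictionary,
        full_groups=list(table.full_groups) if table.full_groups else None,
    )


def simulate_dataset(config: SyntheticConfig) -> FuzzyTraitTable:
    """Simulate a table and apply the configured missingness in one call."""
    table = simulate_fuzzy_table(config)
    return inject_missingness(table, config.missing_rate, config.seed)
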