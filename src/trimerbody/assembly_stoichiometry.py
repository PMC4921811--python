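"""Stoichiometry of random trimer assembly from co-expressed chains.

When several monospecific chains are co-expressed and trimerize at random,
what fraction of trimers carries three distinct specificities? Two weighting
models are provided:

* ``multiset_uniform`` — every distinct unordered composition of 3 chains is
  counted once with equal weight. With 3 chain types this gives C(5,3) = 10
  species of which exactly one is trispecific: a 10% trispecific fraction.
* ``sequence_random`` — trimers assemble from 3 independent draws at given
  chain abundances (multinomial). At equal abundances of 3 types the
  trispecific fraction is 3!/27 = 6/27 ≈ 22.2%.

The 10% figure corresponds to counting distinct species; physically random
assembly at equal synthesis rates gives 22.2%. Both numbers are surfaced so
the distinction stays visible; ``multiset_uniform`` is the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement, product
from math import comb

import numpy as np

MODES = ("multiset_uniform", "sequence_random")


@dataclass
class SpeciesTable:
    """Trimer compositions with their fractions (summing to 1)."""

    compositions: list[tuple[tuple[int, ...], float]]  # (sorted chain types, fraction)
    mode: str

    def validate(self) -> None:
        fractions = [f for _, f in self.compositions]
        if abs(sum(fractions) - 1.0) > 1e-12:
            raise ValueError("species fractions must sum to 1")
        comps = [c for c, _ in self.compositions]
        if len(set(comps)) != len(comps):
            raise ValueError("species compositions must be distinct")

    def as_records(self) -> list[dict]:
        return [
            {
                "composition": "+".join(str(c) for c in comp),
                "n_distinct": len(set(comp)),
                "fraction": frac,
            }
            for comp, frac in self.compositions
        ]


def enumerate_trimer_species(
    n_chain_types: int,
    mode: str = "multiset_uniform",
    abundances: list[float] | None = None,
) -> SpeciesTable:
    """Enumerate all trimer compositions of `n_chain_types` chain types.

    ``multiset_uniform`` weights each of the C(n+2, 3) distinct unordered
    compositions equally (abundances are not meaningful and rejected).
    ``sequence_random`` draws 3 chains independently at the given abundances
    (default equal) and aggregates ordered outcomes by composition.
    """
    if n_chain_types < 1:
        raise ValueError("n_chain_types must be at least 1")
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")

    if mode == "multiset_uniform":
        if abundances is not None:
            raise ValueError("abundances only apply to sequence_random mode")
        comps = list(combinations_with_replacement(range(n_chain_types), 3))
        weight = 1.0 / len(comps)
        table = SpeciesTable(
            compositions=[(c, weight) for c in comps], mode=mode
        )
    else:
        if abundances is None:
            p = np.full(n_chain_types, 1.0 / n_chain_types)
        else:
            p = np.asarray(abundances, dtype=float)
            if p.shape != (n_chain_types,):
                raise ValueError("abundances must list one value per chain type")
            if np.any(p <= 0) or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError("abundances must be positive and sum to 1")
        probs: dict[tuple[int, ...], float] = {}
        for ordered in product(range(n_chain_types), repeat=3):
            comp = tuple(sorted(ordered))
            probs[comp] = probs.get(comp, 0.0) + float(np.prod(p[list(ordered)]))
        table = SpeciesTable(
            compositions=sorted(probs.items()), mode=mode
        )
    table.validate()
    return table


def trispecific_fraction(table: SpeciesTable) -> float:
    """Summed fraction of species with at least 3 distinct chain types."""
    return sum(frac for comp, frac in table.compositions if len(set(comp)) >= 3)


def n_species(n_chain_types: int) -> int:
    """Stars-and-bars count of distinct trimer compositions: C(n+2, 3)."""
    return comb(n_chain_types + 2, 3)
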