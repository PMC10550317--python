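"""Discrete-generation diploid pedigrees.

A pedigree is a DAG of diploid individuals organised into non-overlapping
generations.  Founders (generation 0) have no parents; every later individual
has an *ordered* pair of parents drawn from the previous generation.  Parent
order is meaningful throughout the package: gene copy 1 of an individual
descends from ``parent1`` and gene copy 2 from ``parent2``.

The population is monoecious (no sexes) and a parent may appear in any number
of matings.  Selfing (``parent1 == parent2``) is permitted only when the
pedigree's ``selfing_allowed`` flag is set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["Individual", "Pedigree", "PedigreeError", "make_random_pedigree",
           "read_pedigree", "write_pedigree"]


class PedigreeError(ValueError):
    """Raised when a pedigree violates a structural invariant."""


@dataclass(frozen=True)
class Individual:
    """One diploid individual.

    ``parent1``/``parent2`` are ids of the individuals contributing gene copy
    1 and 2 respectively, or ``None`` for a founder (both must be ``None``
    together).
    """

    id: str
    generation: int
    parent1: Optional[str] = None
    parent2: Optional[str] = None

    @property
    def is_founder(self) -> bool:
        return self.parent1 is None and self.parent2 is None


@dataclass
class Pedigree:
    """An ordered collection of individuals, topologically sorted by generation."""

    individuals: list[Individual]
    selfing_allowed: bool = True
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {ind.id: k for k, ind in enumerate(self.individuals)}
        if len(self._index) != len(self.individuals):
            seen: set[str] = set()
            for ind in self.individuals:
                if ind.id in seen:
                    raise PedigreeError(f"duplicate individual id {ind.id!r}")
                seen.add(ind.id)
        self.validate()

    # -- accessors ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.individuals)

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self._index

    def __getitem__(self, ind_id: str) -> Individual:
        try:
            return self.individuals[self._index[ind_id]]
        except KeyError:
            raise KeyError(f"unknown individual id {ind_id!r}") from None

    def index(self, ind_id: str) -> int:
        if ind_id not in self._index:
            raise KeyError(f"unknown individual id {ind_id!r}")
        return self._index[ind_id]

    @property
    def n_generations(self) -> int:
        """Largest generation label present (0 for a founders-only pedigree)."""
        return max(ind.generation for ind in self.individuals)

    def founders(self) -> list[Individual]:
        return [ind for ind in self.individuals if ind.generation == 0]

    def parents(self, ind_id: str) -> Optional[tuple[str, str]]:
        """Ordered parent pair of ``ind_id``, or ``None`` for a founder."""
        ind = self[ind_id]
        if ind.is_founder:
            return None
        return (ind.parent1, ind.parent2)

    def generation_members(self, t: int) -> list[Individual]:
        return [ind for ind in self.individuals if ind.generation == t]

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        """Raise :class:`PedigreeError` on any invariant breach."""
        for ind in self.individuals:
            has1, has2 = ind.parent1 is not None, ind.parent2 is not None
            if has1 != has2:
                raise PedigreeError(
                    f"individual {ind.id!r}: parents must both be set or both NA")
            if ind.generation < 0:
                raise PedigreeError(f"individual {ind.id!r}: negative generation")
            if ind.is_founder:
                if ind.generation != 0:
                    raise PedigreeError(
                        f"individual {ind.id!r}: founder must be generation 0")
                continue
            if ind.generation == 0:
                raise PedigreeError(
                    f"individual {ind.id!r}: generation-0 individual has parents")
            for p in (ind.parent1, ind.parent2):
                if p not in self._index:
                    raise PedigreeError(
                        f"individual {ind.id!r}: unknown parent id {p!r}")
                if self[p].generation >= ind.generation:
                    raise PedigreeError(
                        f"individual {ind.id!r}: parent {p!r} generation "
                        f"{self[p].generation} is not earlier than {ind.generation}")
            if not self.selfing_allowed and ind.parent1 == ind.parent2:
                raise PedigreeError(
                    f"individual {ind.id!r}: selfing not allowed in this pedigree")

    # -- array views used by the simulators --------------------------------

    def parent_indices(self) -> np.ndarray:
        """(n, 2) integer array of parent row indices; -1 marks founders."""
        out = np.full((len(self), 2), -1, dtype=np.int64)
        for k, ind in enumerate(self.individuals):
            if not ind.is_founder:
                out[k, 0] = self._index[ind.parent1]
                out[k, 1] = self._index[ind.parent2]
        return out

    def generations(self) -> np.ndarray:
        return np.array([ind.generation for ind in self.individuals], dtype=np.int64)


def make_random_pedigree(n_per_generation: int, n_generations: int,
                         selfing_allowed: bool = False, seed: int = 0) -> Pedigree:
    """Random-mating pedigree of constant size with discrete generations.

    Each non-founder's two parents are drawn uniformly at random from the
    previous generation, independently across individuals; when selfing is
    disallowed the two parents are distinct.  Deterministic given ``seed``.
    """
    if n_per_generation < 1:
        raise ValueError("n_per_generation must be >= 1")
    if n_generations < 0:
        raise ValueError("n_generations must be >= 0")
    if not selfing_allowed and n_per_generation < 2 and n_generations > 0:
        raise ValueError("no valid mate: n_per_generation=1 with selfing disallowed")
    rng = np.random.default_rng(seed)
    inds: list[Individual] = [
        Individual(id=f"G0-{i}", generation=0) for i in range(n_per_generation)]
    for t in range(1, n_generations + 1):
        prev = [f"G{t-1}-{i}" for i in range(n_per_generation)]
        for i in range(n_per_generation):
            if selfing_allowed:
                p1, p2 = rng.integers(0, n_per_generation, size=2)
            else:
                p1 = int(rng.integers(0, n_per_generation))
                p2 = int(rng.integers(0, n_per_generation - 1))
                if p2 >= p1:
                    p2 += 1
            inds.append(Individual(id=f"G{t}-{i}", generation=t,
                                   parent1=prev[int(p1)], parent2=prev[int(p2)]))
    return Pedigree(inds, selfing_allowed=selfing_allowed)


_NA = "NA"


def write_pedigree(ped: Pedigree, path) -> None:
    """Serialize to a UTF-8 TSV with header ``id parent1 parent2 generation``."""
    df = pd.DataFrame(
        {"id": [i.id for i in ped.individuals],
         "parent1": [i.parent1 if i.parent1 is not None else _NA
                     for i in ped.individuals],
         "parent2": [i.parent2 if i.parent2 is not None else _NA
                     for i in ped.individuals],
         "generation": [i.generation for i in ped.individuals]})
    df.to_csv(path, sep="\t", index=False)


def read_pedigree(path, selfing_allowed: bool = True) -> Pedigree:
    """Read a pedigree TSV written by :func:`write_pedigree`.

    Validation errors name the offending row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"id", "parent1", "parent2", "generation"}
    if not required.issubset(df.columns):
        raise PedigreeError(f"pedigree TSV must have columns {sorted(required)}")
    inds = []
    for rownum, row in enumerate(df.itertuples(index=False), start=2):
        p1 = None if row.parent1 == _NA else row.parent1
        p2 = None if row.parent2 == _NA else row.parent2
        try:
            gen = int(row.generation)
        except ValueError:
            raise PedigreeError(f"row {rownum}: non-integer generation "
                                f"{row.generation!r}") from None
        inds.append(Individual(id=row.id, generation=gen, parent1=p1, parent2=p2))
    try:
        return Pedigree(inds, selfing_allowed=selfing_allowed)
    except PedigreeError as err:
        raise PedigreeError(f"invalid pedigree in {path}: {err}") from None
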