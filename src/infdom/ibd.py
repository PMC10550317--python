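"""Exact identity-by-descent coefficients on a pedigree.

Two-way (kinship, inbreeding), three- and four-way identity coefficients are
computed exactly by a recursion over *generalized IBD functionals*: the
probability that, within each of a collection of disjoint blocks of gene
draws, all genes are identical by descent.  The latest-generation individual
appearing in the state is expanded — each random draw from it resolves to its
gene copy 1 or 2 with probability 1/2, draws landing on the same physical
gene merge (IBD is an equivalence relation), and each physical gene copy is
itself a uniform random gene of the corresponding parent.  States are
memoized in canonical form; founder genes are the atoms (genes of distinct
founders, or the two genes of one founder, are never IBD).

The nine condensed identity states Delta1..Delta9 of an ordered pair are
obtained by Moebius inversion over the 15 detailed partitions of the four
genes.  A Monte Carlo gene-dropping oracle provides an independent check.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .pedigree import Pedigree

__all__ = ["CondensedIdentity", "PairIdentitySet", "ParentalIdentitySet",
           "kinship", "inbreeding", "condensed_identity", "pair_identities",
           "parental_identity_set", "gene_drop_oracle",
           "mean_pairwise_identity_by_generation"]


# ---------------------------------------------------------------------------
# result containers

@dataclass(frozen=True)
class CondensedIdentity:
    """The nine condensed four-way IBD state probabilities for an ordered pair.

    delta[0] is Delta1 (all four genes IBD), ..., delta[8] is Delta9 (no IBD).
    """

    delta: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.delta) != 9:
            raise ValueError("need nine state probabilities")
        s = sum(self.delta)
        if abs(s - 1.0) > 1e-12 or min(self.delta) < -1e-12:
            raise ValueError(f"invalid condensed identity distribution (sum {s})")


@dataclass(frozen=True)
class PairIdentitySet:
    """Two-, three- and four-way identities for an ordered pair (a, b).

    ``Fab``: one random gene from each IBD.  ``Faa``/``Fbb``: the two genes
    within a/b IBD.  ``Faab``/``Fabb``: within-pair IBD and IBD with a random
    gene of the other individual.  ``Faabb``: all four IBD.  ``Ft_abab``: two
    disjoint cross pairs IBD but not all four.  ``Ft_aabb``: both within
    pairs IBD but not all four.
    """

    Fab: float
    Faa: float
    Fbb: float
    Faab: float
    Fabb: float
    Faabb: float
    Ft_abab: float
    Ft_aabb: float


@dataclass(frozen=True)
class ParentalIdentitySet:
    """The identity set of an individual's parent pair (i[1], i[2]).

    This is the :class:`PairIdentitySet` of the parents relabeled with 1/2
    subscripts; ``F12`` equals the offspring's own inbreeding coefficient.
    """

    F11: float
    F22: float
    F12: float
    F112: float
    F122: float
    F1122: float
    Ft_1212: float
    Ft_1122: float

    @property
    def FW(self) -> float:
        """Within-individual identity averaged over the two parents."""
        return 0.5 * (self.F11 + self.F22)

    @property
    def F3(self) -> float:
        """Symmetrized three-way identity (F112 + F122)/2."""
        return 0.5 * (self.F112 + self.F122)


# ---------------------------------------------------------------------------
# generalized IBD functional

class _IdentityCalculator:
    """Memoized exact IBD computations for one pedigree."""

    def __init__(self, ped: Pedigree):
        self.ped = ped
        self.parents = ped.parent_indices()
        self.gens = ped.generations()
        self._kin: dict[tuple[int, int], float] = {}
        self._state: dict[tuple, float] = {}

    # -- classic kinship recursion -----------------------------------------

    def kinship(self, a: int, b: int) -> float:
        """P(random gene of a ~ random gene of b); a == b gives (1+F_aa)/2."""
        if a > b:
            a, b = b, a
        key = (a, b)
        hit = self._kin.get(key)
        if hit is not None:
            return hit
        if a == b:
            p1, p2 = self.parents[a]
            val = 0.5 if p1 < 0 else 0.5 * (1.0 + self.kinship(p1, p2))
        else:
            # recurse on the later-generation member (ties: the larger index,
            # which cannot be an ancestor of the other in topological order)
            x, y = (a, b) if (self.gens[a], a) > (self.gens[b], b) else (b, a)
            px1, px2 = self.parents[x]
            if px1 < 0:
                val = 0.0  # founder unrelated to anyone earlier or concurrent
            else:
                val = 0.5 * (self.kinship(px1, y) + self.kinship(px2, y))
        self._kin[key] = val
        return val

    def inbreeding(self, a: int) -> float:
        p1, p2 = self.parents[a]
        return 0.0 if p1 < 0 else self.kinship(p1, p2)

    # -- generalized functional --------------------------------------------
    # items: ('g', i)   an independent uniform draw of one of i's two genes
    #        ('s', i, c) the specific gene copy c (1 or 2) of individual i;
    #                    terminal (an atom) when i is a founder

    def functional(self, blocks: Sequence[Sequence[tuple]]) -> float:
        state = self._canon(blocks)
        if state is None:
            return 0.0
        return self._eval(state)

    def _is_founder(self, i: int) -> bool:
        return self.parents[i, 0] < 0

    def _canon(self, blocks) -> tuple | None:
        """Canonical state, or None if some block is impossible."""
        out = []
        for blk in blocks:
            items = []
            atoms = set()
            for it in blk:
                if it[0] == "s":
                    if self._is_founder(it[1]):
                        atoms.add(it)
                    elif it not in items:
                        items.append(it)  # specific genes dedupe within block
                else:
                    items.append(it)      # independent draws keep multiplicity
            if len(atoms) > 1:
                return None               # distinct founder genes never IBD
            items.extend(atoms)
            if len(items) >= 2:
                out.append(tuple(sorted(items)))
        return tuple(sorted(out))

    def _eval(self, state: tuple) -> float:
        if not state:
            return 1.0
        hit = self._state.get(state)
        if hit is not None:
            return hit

        # pick the latest-generation individual with unresolved items
        target = -1
        key = (-1, -1)
        for blk in state:
            for it in blk:
                i = it[1]
                if it[0] == "s" and self._is_founder(i):
                    continue
                if (self.gens[i], i) > key:
                    key = (self.gens[i], i)
                    target = i
        if target < 0:
            # only founder atoms remain; blocks of >=2 were already pruned to
            # single-atom impossibilities in _canon, so any surviving block
            # with >=2 items holds a non-IBD combination
            val = 0.0 if state else 1.0
            self._state[state] = val
            return val

        founder = self._is_founder(target)
        p1, p2 = self.parents[target]
        new_item = {1: ("s", target, 1) if founder else ("g", p1),
                    2: ("s", target, 2) if founder else ("g", p2)}

        g_counts, has_s = [], []
        rest_items = []
        for blk in state:
            g = sum(1 for it in blk if it == ("g", target))
            s1 = ("s", target, 1) in blk
            s2 = ("s", target, 2) in blk
            g_counts.append(g)
            has_s.append((s1, s2))
            rest_items.append([it for it in blk
                               if it != ("g", target)
                               and it != ("s", target, 1)
                               and it != ("s", target, 2)])

        nb = len(state)
        total = 0.0
        # branch over how many of each block's random draws land on copy 1
        for us in itertools.product(*(range(g + 1) for g in g_counts)):
            w = 1.0
            for g, u in zip(g_counts, us):
                if g:
                    w *= comb(g, u) / (1 << g)
            # union-find over blocks + two virtual nodes for the gene copies
            parent = list(range(nb + 2))

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            def union(x, y):
                rx, ry = find(x), find(y)
                if rx != ry:
                    parent[rx] = ry

            c1, c2 = nb, nb + 1
            touched1 = touched2 = False
            for b in range(nb):
                in1 = us[b] > 0 or has_s[b][0]
                in2 = (g_counts[b] - us[b]) > 0 or has_s[b][1]
                if in1:
                    union(b, c1)
                    touched1 = True
                if in2:
                    union(b, c2)
                    touched2 = True
            comp_items: dict[int, list] = {}
            for b in range(nb):
                comp_items.setdefault(find(b), []).extend(rest_items[b])
            if touched1:
                comp_items.setdefault(find(c1), []).append(new_item[1])
            if touched2:
                comp_items.setdefault(find(c2), []).append(new_item[2])
            sub = self._canon(list(comp_items.values()))
            if sub is not None:
                total += w * self._eval(sub)
        self._state[state] = total
        return total

    # -- gene items for specific individuals --------------------------------

    def specific_genes(self, i: int) -> tuple[tuple, tuple]:
        return ("s", i, 1), ("s", i, 2)


_PARTITIONS: list[tuple[frozenset, ...]] = []


def _partitions_of_four() -> list[tuple[frozenset, ...]]:
    if _PARTITIONS:
        return _PARTITIONS
    elems = (0, 1, 2, 3)

    def rec(rest):
        if not rest:
            yield []
            return
        first, tail = rest[0], rest[1:]
        for k in range(len(tail) + 1):
            for subset in itertools.combinations(tail, k):
                block = frozenset((first,) + subset)
                remaining = tuple(x for x in tail if x not in subset)
                for more in rec(remaining):
                    yield [block] + more

    for p in rec(elems):
        _PARTITIONS.append(tuple(sorted(p, key=lambda b: sorted(b))))
    return _PARTITIONS


def _refines(p, q) -> bool:
    return all(any(bp <= bq for bq in q) for bp in p)


def _classify(partition) -> int:
    """Condensed state index 0..8 of a detailed partition of (a1,a2,b1,b2)."""
    def same(x, y):
        return any(x in blk and y in blk for blk in partition)

    aa, bb = same(0, 1), same(2, 3)
    if aa and bb and same(0, 2):
        return 0  # Delta1
    if aa and bb:
        return 1  # Delta2
    if aa:
        return 2 if (same(0, 2) or same(0, 3)) else 3   # Delta3 / Delta4
    if bb:
        return 4 if (same(2, 0) or same(2, 1)) else 5   # Delta5 / Delta6
    links = sum(same(x, y) for x in (0, 1) for y in (2, 3))
    return {2: 6, 1: 7, 0: 8}[links]                    # Delta7/8/9


def _calculator(ped: Pedigree) -> _IdentityCalculator:
    calc = getattr(ped, "_ibd_calc", None)
    if calc is None or calc.ped is not ped:
        calc = _IdentityCalculator(ped)
        ped._ibd_calc = calc
    return calc


# ---------------------------------------------------------------------------
# public API

def kinship(ped: Pedigree, a: str, b: str) -> float:
    """Exact kinship: P(one random gene of ``a`` ~ one random gene of ``b``).

    ``a == b`` returns the with-replacement self-kinship (1 + F_aa)/2.
    """
    calc = _calculator(ped)
    return calc.kinship(ped.index(a), ped.index(b))


def inbreeding(ped: Pedigree, a: str) -> float:
    """Probability the two distinct genes of ``a`` are IBD (founders: 0)."""
    return _calculator(ped).inbreeding(ped.index(a))


def condensed_identity(ped: Pedigree, a: str, b: str) -> CondensedIdentity:
    """Exact condensed identity coefficients Delta1..Delta9 for ordered (a, b)."""
    if a == b:
        raise ValueError("condensed identity requires two distinct individuals")
    calc = _calculator(ped)
    ia, ib = ped.index(a), ped.index(b)
    genes = calc.specific_genes(ia) + calc.specific_genes(ib)
    parts = _partitions_of_four()
    m = np.array([calc.functional([[genes[x] for x in blk] for blk in p
                                   if len(blk) >= 2]) for p in parts])
    zeta = np.array([[1.0 if _refines(p, q) else 0.0 for q in parts]
                     for p in parts])
    probs = np.linalg.solve(zeta, m)
    delta = [0.0] * 9
    for p, pr in zip(parts, probs):
        delta[_classify(p)] += pr
    delta = [0.0 if abs(d) < 1e-14 else float(d) for d in delta]
    return CondensedIdentity(tuple(delta))


def pair_identities(ped: Pedigree, a: str, b: str) -> PairIdentitySet:
    """All pair identities of ordered (a, b), assembled from Delta1..Delta9."""
    d = condensed_identity(ped, a, b).delta
    return PairIdentitySet(
        Fab=d[0] + 0.5 * (d[2] + d[4] + d[6]) + 0.25 * d[7],
        Faa=d[0] + d[1] + d[2] + d[3],
        Fbb=d[0] + d[1] + d[4] + d[5],
        Faab=d[0] + 0.5 * d[2],
        Fabb=d[0] + 0.5 * d[4],
        Faabb=d[0],
        Ft_abab=d[6],
        Ft_aabb=d[1])


def parental_identity_set(ped: Pedigree, i: str) -> ParentalIdentitySet:
    """Identity set of ``i``'s parent pair, as used by the trait predictions.

    For a selfed individual (i[1] == i[2]) the degenerate with-replacement
    set is returned: with F the single parent's inbreeding coefficient,
    F12 = (1+F)/2, the three- and four-way entries equal F, and the
    not-all-four cross terms are (1-F)/2 and (1-F)/4.
    """
    parents = ped.parents(i)
    if parents is None:
        raise ValueError(f"{i!r} is a founder: no parental identity set")
    p1, p2 = parents
    if p1 == p2:
        F = inbreeding(ped, p1)
        return ParentalIdentitySet(
            F11=F, F22=F, F12=0.5 * (1.0 + F),
            F112=F, F122=F, F1122=F,
            Ft_1212=0.5 * (1.0 - F), Ft_1122=0.25 * (1.0 - F))
    s = pair_identities(ped, p1, p2)
    return ParentalIdentitySet(F11=s.Faa, F22=s.Fbb, F12=s.Fab,
                               F112=s.Faab, F122=s.Fabb, F1122=s.Faabb,
                               Ft_1212=s.Ft_abab, Ft_1122=s.Ft_aabb)


def mean_pairwise_identity_by_generation(ped: Pedigree) -> pd.Series:
    """Mean kinship over unordered distinct pairs, per generation."""
    calc = _calculator(ped)
    gens = ped.generations()
    out = {}
    for t in range(int(gens.max()) + 1):
        members = np.flatnonzero(gens == t)
        vals = [calc.kinship(int(x), int(y))
                for x, y in itertools.combinations(members, 2)]
        out[t] = float(np.mean(vals)) if vals else np.nan
    return pd.Series(out, name="mean_pairwise_identity")


# ---------------------------------------------------------------------------
# Monte Carlo gene dropping

def gene_drop_oracle(ped: Pedigree, pairs: Sequence[tuple[str, str]],
                     n_reps: int, seed: int = 0) -> pd.DataFrame:
    """Monte Carlo estimates of all pair identities by gene dropping.

    Founders carry unique gene labels; labels are dropped down the pedigree
    with fair coin flips, ``n_reps`` independent replicates.  Returns one row
    per pair with estimates and standard errors for every
    :class:`PairIdentitySet` field and every condensed state.
    """
    if not pairs:
        raise ValueError("empty pair list")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(ped)
    parents = ped.parent_indices()
    labels = np.empty((n_reps, n, 2), dtype=np.int32)
    order = np.argsort(ped.generations(), kind="stable")
    next_label = 0
    for k in order:
        p1, p2 = parents[k]
        if p1 < 0:
            labels[:, k, 0] = next_label
            labels[:, k, 1] = next_label + 1
            next_label += 2
        else:
            pick1 = rng.integers(0, 2, size=n_reps)
            pick2 = rng.integers(0, 2, size=n_reps)
            labels[:, k, 0] = labels[np.arange(n_reps), p1, pick1]
            labels[:, k, 1] = labels[np.arange(n_reps), p2, pick2]

    rows = []
    for a, b in pairs:
        ia, ib = ped.index(a), ped.index(b)
        a1, a2 = labels[:, ia, 0], labels[:, ia, 1]
        b1, b2 = labels[:, ib, 0], labels[:, ib, 1]
        aa = a1 == a2
        bb = b1 == b2
        cross = ((a1 == b1).astype(float) + (a1 == b2) + (a2 == b1)
                 + (a2 == b2))
        all4 = aa & bb & (a1 == b1)
        stats = {
            "Fab": cross / 4.0,
            "Faa": aa.astype(float),
            "Fbb": bb.astype(float),
            "Faab": aa * ((a1 == b1).astype(float) + (a1 == b2)) / 2.0,
            "Fabb": bb * ((b1 == a1).astype(float) + (b1 == a2)) / 2.0,
            "Faabb": all4.astype(float),
            "Ft_abab": (~aa & ~bb
                        & (((a1 == b1) & (a2 == b2))
                           | ((a1 == b2) & (a2 == b1)))).astype(float),
            "Ft_aabb": (aa & bb & ~all4).astype(float),
        }
        nlinks = ((a1 == b1).astype(int) + (a1 == b2) + (a2 == b1)
                  + (a2 == b2))
        stats["Delta1"] = all4.astype(float)
        stats["Delta2"] = stats["Ft_aabb"]
        stats["Delta3"] = (aa & ~bb & (nlinks > 0)).astype(float)
        stats["Delta4"] = (aa & ~bb & (nlinks == 0)).astype(float)
        stats["Delta5"] = (bb & ~aa & (nlinks > 0)).astype(float)
        stats["Delta6"] = (bb & ~aa & (nlinks == 0)).astype(float)
        stats["Delta7"] = stats["Ft_abab"]
        stats["Delta8"] = (~aa & ~bb & (nlinks == 1)).astype(float)
        stats["Delta9"] = (~aa & ~bb & (nlinks == 0)).astype(float)
        row = {"a": a, "b": b}
        for name, x in stats.items():
            row[name] = float(np.mean(x))
            row[name + "_se"] = float(np.std(x, ddof=1) / np.sqrt(n_reps))
        rows.append(row)
    return pd.DataFrame(rows)
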