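"""Discrete factor tables and variable elimination over pedigree genotype variables.

The pedigree likelihood is a product of small nonnegative tables (founder
priors, transmission probabilities, penetrance/observation weights) over
per-individual genotype variables.  Peeling a pedigree is variable
elimination on that product in a leaves-first order; on loop-free pedigrees
this reproduces the classical anterior/posterior recursion.  Tables are kept
in linear space and rescaled after every elimination so that likelihoods far
below double-precision range (deep pedigrees, rare alleles) stay exact in
log10.
"""

from __future__ import annotations

from typing import Dict, Hashable, Iterable, List, Sequence, Tuple

import numpy as np

Var = Hashable


class Factor:
    """A nonnegative table over an ordered tuple of discrete variables."""

    __slots__ = ("vars", "table")

    def __init__(self, vars: Sequence[Var], table: np.ndarray):
        self.vars: Tuple[Var, ...] = tuple(vars)
        self.table = np.asarray(table, dtype=float)
        if self.table.ndim != len(self.vars):
            raise ValueError("factor table rank does not match variable count")

    def _aligned(self, uvars: Tuple[Var, ...]) -> np.ndarray:
        order = [self.vars.index(v) for v in uvars if v in self.vars]
        t = np.transpose(self.table, order)
        shape = []
        it = iter(t.shape)
        for v in uvars:
            shape.append(next(it) if v in self.vars else 1)
        return t.reshape(shape)

    def multiply(self, other: "Factor") -> "Factor":
        uvars = self.vars + tuple(v for v in other.vars if v not in self.vars)
        return Factor(uvars, self._aligned(uvars) * other._aligned(uvars))

    def marginalize(self, var: Var) -> "Factor":
        axis = self.vars.index(var)
        return Factor(self.vars[:axis] + self.vars[axis + 1 :], self.table.sum(axis=axis))

    def conditioned(self, assignment: Dict[Var, int]) -> "Factor":
        idx = tuple(assignment[v] if v in assignment else slice(None) for v in self.vars)
        rem = tuple(v for v in self.vars if v not in assignment)
        return Factor(rem, self.table[idx])


def greedy_elimination_order(factors: Iterable[Factor]) -> List[Var]:
    """Min-degree elimination order over the factors' interaction graph.

    Greedy with fill-in updates; keeps intermediate factor ranks near the
    pedigree's treewidth (leaves peel before founders, married-in spouses
    before the central couple), where a naive generation order can join every
    spouse factor at once.
    """
    adj: Dict[Var, set] = {}
    for f in factors:
        for v in f.vars:
            adj.setdefault(v, set()).update(u for u in f.vars if u != v)
    remaining = set(adj)
    order: List[Var] = []
    while remaining:
        v = min(remaining, key=lambda x: (len(adj[x] & remaining), str(x)))
        nbrs = adj[v] & remaining
        for a in nbrs:
            adj[a].update(nbrs - {a})
        order.append(v)
        remaining.discard(v)
    return order


def _product(factors: List[Factor]) -> Factor:
    prod = factors[0]
    for f in factors[1:]:
        prod = prod.multiply(f)
    return prod


def eliminate_all(factors: Iterable[Factor], order: Sequence[Var]) -> float:
    """Sum the factor product over every variable in ``order``.

    Returns log10 of the total, or -inf when the product is identically zero
    (data inconsistent with the model, e.g. an obligate recombinant at
    recombination fraction zero).
    """
    log10_total, facs = _eliminate(list(factors), order, None)
    return log10_total


def eliminate_and_sample(
    factors: Iterable[Factor], order: Sequence[Var], rng: np.random.Generator, n: int
) -> List[Dict[Var, int]]:
    """Draw ``n`` joint assignments proportional to the factor product.

    Runs one forward elimination sweep recording, for each variable, the
    product factor present at its elimination; then backward-samples each
    variable conditioned on the variables eliminated after it.
    """
    records: List[Tuple[Var, Factor]] = []
    log10_total, _ = _eliminate(list(factors), order, records)
    if log10_total == -np.inf:
        raise ValueError("factor product is identically zero; nothing to sample")
    out = []
    for _ in range(n):
        assignment: Dict[Var, int] = {}
        for var, prod in reversed(records):
            f = prod.conditioned(assignment)
            if f.vars != (var,):
                raise AssertionError("sampling order inconsistent with elimination order")
            p = f.table / f.table.sum()
            assignment[var] = int(rng.choice(len(p), p=p))
        out.append(assignment)
    return out


def _eliminate(facs, order, records):
    log10_acc = 0.0
    for var in order:
        group = [f for f in facs if var in f.vars]
        if not group:
            continue
        facs = [f for f in facs if var not in f.vars]
        prod = _product(group)
        if records is not None:
            records.append((var, prod))
        marg = prod.marginalize(var)
        m = marg.table.max() if marg.table.size else 0.0
        if m <= 0.0:
            return -np.inf, facs
        facs.append(Factor(marg.vars, marg.table / m))
        log10_acc += np.log10(m)
    total = 1.0
    for f in facs:
        if f.vars:
            raise ValueError(f"variables {f.vars} were never eliminated")
        total *= float(f.table)
    if total <= 0.0:
        return -np.inf, facs
    return log10_acc + np.log10(total), facs
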