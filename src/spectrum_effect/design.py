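"""Uniform experimental design by the good-lattice-point (GLP) construction.

A uniform design spreads ``n`` runs of ``s`` factors as evenly as possible
over the unit cube, so that a small number of formulation variants covers
the dose space representatively.  The classical number-theoretic
construction takes a generator integer ``g`` coprime with ``n`` and places
run ``i`` of the corresponding column at level ``((i*g - 1) mod n) + 1``;
every column is then a permutation of ``1..n`` (a U-type / Latin layout).

Design quality is scored by the Hickernell centered L2 discrepancy (CD2):
lower is more uniform.  :func:`search_design` enumerates all coprime
generator tuples and returns the CD2-minimal table, which is how the
two-factor nine-level layout behind a nine-sample formulation series is
chosen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "DesignTable",
    "glp_design",
    "centered_l2_discrepancy",
    "search_design",
]


@dataclass(frozen=True)
class DesignTable:
    """An ``n_runs x n_factors`` table of integer levels in ``1..n_runs``.

    Every column must be a permutation of ``1..n_runs`` (Latin property).
    ``generators`` records the GLP generator tuple when the table was
    constructed number-theoretically; ``discrepancy`` caches CD2.
    """

    levels: np.ndarray
    generators: tuple[int, ...] | None = None
    discrepancy: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        levels = np.asarray(self.levels, dtype=int)
        if levels.ndim != 2 or levels.size == 0:
            raise ValueError("design table must be a non-empty 2-D integer matrix")
        object.__setattr__(self, "levels", levels)
        n = levels.shape[0]
        expected = np.arange(1, n + 1)
        for j in range(levels.shape[1]):
            if not np.array_equal(np.sort(levels[:, j]), expected):
                raise ValueError(
                    f"column {j} is not a permutation of 1..{n}: Latin property violated"
                )
        if self.generators is not None:
            gens = tuple(int(g) for g in self.generators)
            for g in gens:
                if math.gcd(g, n) != 1:
                    raise ValueError(f"generator {g} is not coprime with n_runs={n}")
            object.__setattr__(self, "generators", gens)

    @property
    def n_runs(self) -> int:
        return self.levels.shape[0]

    @property
    def n_factors(self) -> int:
        return self.levels.shape[1]

    def unit_points(self) -> np.ndarray:
        """Map levels to centered points of the unit cube: u = (level - 0.5)/n."""
        return (self.levels - 0.5) / self.n_runs

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.levels,
            columns=[f"factor_{j + 1}" for j in range(self.n_factors)],
        )
        df.insert(0, "run_id", np.arange(1, self.n_runs + 1))
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DesignTable":
        df = pd.read_csv(path)
        cols = [c for c in df.columns if c != "run_id"]
        return cls(levels=df[cols].to_numpy(dtype=int))


def glp_design(n_runs: int, generators) -> DesignTable:
    """Construct a good-lattice-point design.

    Column ``j`` holds ``((i * g_j - 1) mod n_runs) + 1`` for run
    ``i = 1..n_runs``.  Each generator must be coprime with ``n_runs``,
    otherwise the column would visit only a subgroup of the levels and the
    Latin property would fail.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be at least 2")
    gens = tuple(int(g) for g in np.atleast_1d(generators))
    if not gens:
        raise ValueError("at least one generator is required")
    for g in gens:
        if math.gcd(g, n_runs) != 1:
            raise ValueError(
                f"generator {g} rejected: gcd({g}, {n_runs}) = "
                f"{math.gcd(g, n_runs)} != 1, so the column would not be a "
                f"permutation of 1..{n_runs}"
            )
    i = np.arange(1, n_runs + 1)[:, None]
    g = np.asarray(gens)[None, :]
    levels = (i * g - 1) % n_runs + 1
    return DesignTable(levels=levels, generators=gens)


def centered_l2_discrepancy(table: DesignTable) -> float:
    """Hickernell centered L2 discrepancy CD2 of a design table.

    Levels are mapped to the cell centers ``u = (level - 0.5)/n``.  With
    ``s`` factors and ``n`` runs,

        CD2^2 = (13/12)^s
                - (2/n)   sum_i prod_j [1 + |u_ij - 1/2|/2 - |u_ij - 1/2|^2/2]
                + (1/n^2) sum_ik prod_j [1 + |u_ij - 1/2|/2 + |u_kj - 1/2|/2
                                           - |u_ij - u_kj|/2]

    CD2 is invariant to row reordering and to the reflection u -> 1 - u.
    """
    u = table.unit_points()
    n, s = u.shape
    a = np.abs(u - 0.5)
    term1 = (13.0 / 12.0) ** s
    term2 = (2.0 / n) * np.prod(1.0 + 0.5 * a - 0.5 * a**2, axis=1).sum()
    # pairwise product over factors, n x n
    diff = np.abs(u[:, None, :] - u[None, :, :])
    cross = np.prod(1.0 + 0.5 * a[:, None, :] + 0.5 * a[None, :, :] - 0.5 * diff, axis=2)
    term3 = cross.sum() / n**2
    sq = term1 - term2 + term3
    # numerical round-off can leave a tiny negative residue
    return math.sqrt(max(sq, 0.0))


def _coprime_residues(n: int) -> list[int]:
    return [g for g in range(1, n) if math.gcd(g, n) == 1]


def search_design(n_runs: int, n_factors: int) -> DesignTable:
    """Exhaustive CD2-minimal GLP design with the first generator fixed to 1.

    All strictly increasing coprime generator tuples ``(1, g_2, ..., g_s)``
    are scored and the table with the smallest CD2 is returned; ties break
    to the lexicographically smallest tuple.  Deterministic by construction.
    """
    if n_factors >= n_runs:
        raise ValueError("n_factors must be smaller than n_runs")
    if n_factors < 1:
        raise ValueError("n_factors must be at least 1")
    residues = _coprime_residues(n_runs)
    others = [g for g in residues if g != 1]
    if n_factors - 1 > len(others):
        raise ValueError(
            f"only {len(residues)} coprime generators available for n_runs={n_runs}; "
            f"cannot build {n_factors} distinct columns"
        )
    best: DesignTable | None = None
    best_key: tuple[float, tuple[int, ...]] | None = None
    for tail in combinations(others, n_factors - 1):
        gens = (1,) + tail
        table = glp_design(n_runs, gens)
        cd2 = centered_l2_discrepancy(table)
        key = (cd2, gens)
        if best_key is None or key < best_key:
            best_key = key
            best = DesignTable(levels=table.levels, generators=gens, discrepancy=cd2)
    assert best is not None
    return best
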