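"""Management-unit (MU) scenario evaluation by variation partitioning.

A candidate MU delineation is a set of polygons assigning every individual
to exactly one unit.  Its merit is measured by how much of the spatial
genetic pattern (the first axis of the spatial genetic regression, or all
axes) is explained by dummy-coded unit membership uniquely ([a]), by the
selected MEM spatial variables uniquely ([b]), by both confounded ([c]),
and by neither ([d]); [a]+[b]+[c]+[d] = 1.

Because there is no penalty for the number of dummy variables, scenarios
are only comparable when they have the same number of units —
``compare_scenarios`` enforces this rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point

from .mem import MemGeneResult
from .varpart import variation_partition

__all__ = [
    "MUScenario",
    "MUPartitionResult",
    "dummy_code",
    "assign_membership",
    "mu_varpart",
    "compare_scenarios",
]


@dataclass
class MUScenario:
    """A named MU delineation: polygons or a precomputed membership vector."""

    name: str
    polygons: list | None = None       # shapely polygons, unit i = index i
    membership: np.ndarray | None = None
    n_units: int | None = None

    def __post_init__(self):
        if self.polygons is None and self.membership is None:
            raise ValueError("scenario needs polygons or a membership vector")
        if self.n_units is None:
            if self.polygons is not None:
                self.n_units = len(self.polygons)
            else:
                self.n_units = len(np.unique(np.asarray(self.membership)))
        if self.n_units < 2:
            raise ValueError("a scenario needs at least 2 units")


@dataclass
class MUPartitionResult:
    """Table-5-style fractions for one scenario.

    a: unique to MU membership; b: unique to spatial variables;
    c: confounded; d: residual.  a + b + c + d = 1.
    """

    scenario: str
    n_units: int
    a: float
    b: float
    c: float
    d: float
    p_a: float = np.nan
    p_b: float = np.nan
    p_abc: float = np.nan


def dummy_code(membership) -> np.ndarray:
    """Full-rank treatment coding of unit labels (n x (k-1) indicators).

    The lexicographically first unit is the reference; units with zero
    members are dropped with a warning.
    """
    m = pd.Series(np.asarray(membership, dtype=object))
    counts = m.value_counts()
    empty = [u for u in counts.index if counts[u] == 0]
    if empty:
        warnings.warn(f"units with 0 members dropped: {empty}", stacklevel=2)
    levels = sorted(counts.index)
    if len(levels) < 2:
        raise ValueError("need at least 2 distinct unit labels")
    cols = [(m == u).to_numpy(float) for u in levels[1:]]
    return np.column_stack(cols)


def assign_membership(
    xy: np.ndarray,
    scenario: MUScenario,
    fallback: bool = True,
) -> np.ndarray:
    """Point-in-polygon assignment of individuals to MU indices.

    Boundary points go to the containing polygon with the lowest index;
    with ``fallback``, points covered by no polygon are assigned to the
    polygon with the nearest boundary (count reported via a warning).
    """
    if scenario.membership is not None:
        return np.asarray(scenario.membership)
    xy = np.asarray(xy, float)
    n = xy.shape[0]
    out = np.full(n, -1, dtype=int)
    for idx, poly in enumerate(scenario.polygons):
        mask = shapely.intersects_xy(poly, xy[:, 0], xy[:, 1])
        unassigned = (out == -1) & mask
        out[unassigned] = idx
    uncovered = out == -1
    if uncovered.any():
        if not fallback:
            raise ValueError(
                f"{uncovered.sum()} points outside all polygons "
                "(fallback disabled)"
            )
        warnings.warn(
            f"{int(uncovered.sum())} points assigned to nearest polygon",
            stacklevel=2,
        )
        for i in np.flatnonzero(uncovered):
            p = Point(xy[i])
            out[i] = int(np.argmin([poly.distance(p) for poly in scenario.polygons]))
    return out


def mu_varpart(
    memgene: MemGeneResult | np.ndarray,
    xy: np.ndarray,
    scenario: MUScenario,
    n_perm: int = 999,
    random_state=None,
    response: str = "first",
    spatial_vars: np.ndarray | None = None,
) -> MUPartitionResult:
    """Partition a spatial genetic axis between MU membership and space.

    ``memgene`` is a fitted :class:`~landgen.mem.MemGeneResult` (or a plain
    axis array) — the response is its first axis (``response='first'``, the
    default) or all axes (``'all'``).  The spatial block defaults to the
    individuals' coordinates (a linear trend surface capturing spatial
    proximity); note it must *not* be the selected MEM eigenvectors
    themselves, since the spatial genetic axes lie exactly in their span
    and every unique MU fraction would degenerate to zero.  Pass
    ``spatial_vars`` to substitute any other spatial block.  X1 =
    dummy-coded membership; fractions and partial permutation tests via
    two-block variation partitioning.
    """
    xy = np.asarray(xy, float)
    if isinstance(memgene, MemGeneResult):
        if memgene.n_axes == 0:
            raise ValueError("spatial regression found no axes to partition")
        Y = memgene.axes[:, :1] if response == "first" else memgene.axes
    else:
        Y = np.asarray(memgene, float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if response == "first":
            Y = Y[:, :1]
    X2 = xy if spatial_vars is None else np.asarray(spatial_vars, float)
    membership = assign_membership(xy, scenario)
    X1 = dummy_code(membership)
    # collinearity of the MU block with the spatial block folds into [c]
    part = variation_partition(
        Y, X1, X2, n_perm=n_perm, random_state=random_state,
        label_1=scenario.name, label_2="MEM",
    )
    # relabel: partition's (a=X1-unique, c=X2-unique, b=confounded) maps to
    # the MU table's (a=MU-unique, b=space-unique, c=confounded)
    return MUPartitionResult(
        scenario=scenario.name,
        n_units=scenario.n_units,
        a=part.a,
        b=part.c,
        c=part.b,
        d=part.d,
        p_a=part.p_a,
        p_b=part.p_c,
        p_abc=part.p_abc,
    )


def compare_scenarios(
    results: list[MUPartitionResult], force: bool = False
) -> pd.DataFrame:
    """Rank MU scenarios by boundary-specific signal.

    Scenarios with different unit counts are not comparable (dummy
    variables inflate explained variance with no available penalty); mixed
    counts raise unless ``force``.  Ranking: fraction [a] descending, ties
    broken by larger [a] + [c].
    """
    if len(results) < 2:
        raise ValueError("need at least 2 scenarios to compare")
    counts = {r.n_units for r in results}
    if len(counts) > 1:
        msg = (
            f"scenarios have unequal unit counts {sorted(counts)}: only "
            "scenarios with the same number of units are directly comparable"
        )
        if not force:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    df = pd.DataFrame(
        [
            {
                "scenario": r.scenario,
                "n_units": r.n_units,
                "a": r.a,
                "b": r.b,
                "c": r.c,
                "d": r.d,
                "p_a": r.p_a,
            }
            for r in results
        ]
    )
    df["a_plus_c"] = df["a"] + df["c"]
    df = df.sort_values(["a", "a_plus_c"], ascending=False, kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)
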