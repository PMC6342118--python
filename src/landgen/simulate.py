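"""Spatially explicit forward-time microsatellite simulator.

Generates the three canonical processes that shape spatial genetic
structure in continuously distributed populations — isolation by distance
(distance-limited mating), isolation by resistance (a linear barrier that
inflates effective distance), and panmixia — with known truth, so the
analysis chain can be validated against planted signal.

Model: n individuals at fixed uniform-random sites on a plane; discrete
non-overlapping generations; each site's offspring draws two parents with
probability proportional to exp(-d_eff²/2σ²), where d_eff is the
straight-line distance multiplied by the barrier factor when the segment
between the two sites crosses the barrier (panmixia: uniform parent
choice).  One allele per parent per locus; stepwise mutation (±1 repeat,
probability μ) with reflecting bounds on repeat size.  Founders are drawn
at Hardy–Weinberg from 10 equifrequent alleles per locus.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from shapely.geometry import LineString

from .genotypes import GenotypeTable

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_population",
    "make_landscape_fixture",
]

REPEAT_MIN, REPEAT_MAX = 5, 50     # reflecting bounds of the stepwise model
N_FOUNDER_ALLELES = 10


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Defaults mirror the structure of the empirical system the analyses were
    designed for: 9 unlinked microsatellite loci, a square study area, and
    dispersal limited to a few percent of the extent under IBD.
    """

    n_individuals: int = 200
    n_loci: int = 9
    extent: float = 100_000.0            # side of the square study area, m
    sigma: float = 5_000.0               # dispersal scale, m (IBD default 5%)
    mu: float = 5e-4                     # stepwise mutation rate
    n_generations: int = 100
    scenario: str = "ibd"                # 'panmixia' | 'ibd' | 'ibr'
    barrier: object | None = None        # shapely line; default mid vertical
    barrier_multiplier: float = 10.0
    duplicate_rate: float = 0.0          # planted re-sampled individuals
    seed: int | None = None

    def __post_init__(self):
        if self.scenario not in ("panmixia", "ibd", "ibr"):
            raise ValueError("scenario must be panmixia, ibd or ibr")
        if self.scenario != "panmixia" and self.sigma <= 0:
            raise ValueError("sigma must be positive unless panmictic")
        if not 0 <= self.mu <= 0.01:
            raise ValueError("mu must lie in [0, 0.01]")
        if self.barrier_multiplier < 1:
            raise ValueError("barrier multiplier must be >= 1")


@dataclass
class SimulationTruth:
    """What the generator actually planted (for recovery tests)."""

    scenario: str
    sigma: float
    barrier: object | None = None
    barrier_multiplier: float = 1.0
    deme: np.ndarray | None = None       # side of the barrier, if it splits
    n_planted_duplicates: int = 0
    notes: str = ""


def _segment_crosses(xy: np.ndarray, barrier) -> np.ndarray:
    """Boolean (n, n): does the straight segment i-j cross the barrier?"""
    import shapely

    n = xy.shape[0]
    iu = np.triu_indices(n, 1)
    coords = np.stack([xy[iu[0]], xy[iu[1]]], axis=1)      # (m, 2, 2)
    segs = shapely.linestrings(coords)
    hit = shapely.intersects(segs, barrier)
    out = np.zeros((n, n), dtype=bool)
    out[iu] = hit
    return out | out.T


def simulate_population(config: SimulationConfig):
    """Run the forward simulation; returns (GenotypeTable, SimulationTruth)."""
    rng = np.random.default_rng(config.seed)
    n, L = config.n_individuals, config.n_loci
    xy = rng.uniform(0, config.extent, size=(n, 2))

    barrier = None
    deme = None
    if config.scenario == "ibr":
        barrier = config.barrier
        if barrier is None:
            mid = config.extent / 2
            barrier = LineString([(mid, -config.extent), (mid, 2 * config.extent)])
        crosses = _segment_crosses(xy, barrier)
        # deme labels only meaningful for a dividing barrier
        deme = (xy[:, 0] > config.extent / 2).astype(int)

    if config.scenario == "panmixia":
        W = np.ones((n, n))
    else:
        diff = xy[:, None, :] - xy[None, :, :]
        d = np.sqrt((diff**2).sum(axis=2))
        if config.scenario == "ibr":
            d = d * np.where(crosses, config.barrier_multiplier, 1.0)
        W = np.exp(-0.5 * (d / config.sigma) ** 2)
    np.fill_diagonal(W, 0.0)             # a site cannot be its own parent
    row_sums = W.sum(axis=1)
    if np.any(row_sums <= 0):
        raise ValueError(
            "sigma too small: some individual has no reachable parent mass; "
            "increase sigma or shrink the extent"
        )
    cum = np.cumsum(W, axis=1)
    cum /= cum[:, -1][:, None]

    founders = rng.integers(0, N_FOUNDER_ALLELES, size=(n, L, 2))
    alleles = (founders + 15).astype(np.int32)       # repeat sizes 15..24

    def pick_parents():
        # per-row inverse-CDF lookup, vectorized over individuals; the two
        # parents must be distinct (no selfing)
        u = rng.random((n, 2))
        idx = np.clip((cum[:, :, None] < u[:, None, :]).sum(axis=1), 0, n - 1)
        same = idx[:, 0] == idx[:, 1]
        for _ in range(8):
            if not same.any():
                break
            redraw = rng.random(int(same.sum()))
            idx[same, 1] = np.clip(
                (cum[same, :] < redraw[:, None]).sum(axis=1), 0, n - 1
            )
            same = idx[:, 0] == idx[:, 1]
        # exact draw excluding the first parent for any stuck rows
        for i in np.flatnonzero(same):
            w = W[i].copy()
            w[idx[i, 0]] = 0.0
            tot = w.sum()
            if tot <= 0:
                raise ValueError(
                    "sigma too small: no second parent reachable; "
                    "increase sigma or the number of individuals"
                )
            idx[i, 1] = np.searchsorted(np.cumsum(w) / tot, rng.random())
        return idx

    for _ in range(config.n_generations):
        parents = pick_parents()
        # one gamete per parent per locus
        pick = rng.integers(0, 2, size=(n, L, 2))
        mother = alleles[parents[:, 0]]
        father = alleles[parents[:, 1]]
        child = np.empty_like(alleles)
        child[:, :, 0] = np.take_along_axis(mother, pick[:, :, :1], axis=2)[:, :, 0]
        child[:, :, 1] = np.take_along_axis(father, pick[:, :, 1:], axis=2)[:, :, 0]
        if config.mu > 0:
            mut = rng.random(child.shape) < config.mu
            step = rng.choice([-1, 1], size=child.shape)
            child = child + mut * step
            child = np.where(child < REPEAT_MIN, REPEAT_MIN + 1, child)
            child = np.where(child > REPEAT_MAX, REPEAT_MAX - 1, child)
        alleles = child.astype(np.int32)

    ids = np.array([f"ind{i:04d}" for i in range(n)], dtype=object)
    sex = rng.choice(["F", "M"], size=n)

    n_dup = int(round(config.duplicate_rate * n))
    if n_dup > 0:
        pick_idx = rng.choice(n, size=n_dup, replace=False)
        dup_alleles = alleles[pick_idx].copy()
        for k, src in enumerate(pick_idx):
            locus = rng.integers(0, L)
            slot = rng.integers(0, 2)
            dup_alleles[k, locus, slot] += rng.choice([-1, 1])
        jitter = rng.normal(0, config.extent / 100, size=(n_dup, 2))
        alleles = np.concatenate([alleles, dup_alleles])
        xy_all = np.concatenate([xy, xy[pick_idx] + jitter])
        ids = np.concatenate(
            [ids, np.array([f"dup{k:04d}" for k in range(n_dup)], dtype=object)]
        )
        sex = np.concatenate([sex, sex[pick_idx]])
    else:
        xy_all = xy

    table = GenotypeTable(
        individual_id=ids,
        alleles=alleles,
        locus_names=[f"L{j + 1}" for j in range(config.n_loci)],
        xy=xy_all,
        sex=sex,
        group=None,
    )
    truth = SimulationTruth(
        scenario=config.scenario,
        sigma=config.sigma,
        barrier=barrier,
        barrier_multiplier=(
            config.barrier_multiplier if config.scenario == "ibr" else 1.0
        ),
        deme=deme,
        n_planted_duplicates=n_dup,
    )
    return table, truth


# ---------------------------------------------------------------------------
# Landscape and MU fixtures
# ---------------------------------------------------------------------------


def make_landscape_fixture(
    extent: float = 100_000.0, seed: int | None = 0, n_units: int = 5
) -> dict:
    """Deterministic GeoJSON fixtures: features plus candidate MU sets.

    Produces a roads line, a water polygon, two fire polygons (years 1950
    and 1990, straddling the recency filter), and two candidate MU polygon
    sets with equal unit counts (vertical strips, and strips offset by half
    a strip width).  Same seed -> byte-identical output.
    """
    rng = np.random.default_rng(seed)
    e = extent
    jitter = rng.uniform(-0.02, 0.02) * e
    road_x = 0.5 * e + jitter

    def poly(coords):
        return {
            "type": "Polygon",
            "coordinates": [[list(map(float, c)) for c in coords]],
        }

    features = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"class": "roads"},
                "geometry": {
                    "type": "LineString",
                    "coordinates": [[float(road_x), -0.1 * e], [float(road_x), 1.1 * e]],
                },
            },
            {
                "type": "Feature",
                "properties": {"class": "water"},
                "geometry": poly(
                    [(0.1 * e, 0.6 * e), (0.35 * e, 0.6 * e), (0.35 * e, 0.85 * e),
                     (0.1 * e, 0.85 * e), (0.1 * e, 0.6 * e)]
                ),
            },
            {
                "type": "Feature",
                "properties": {"class": "fire", "year": 1950},
                "geometry": poly(
                    [(0.6 * e, 0.1 * e), (0.8 * e, 0.1 * e), (0.8 * e, 0.3 * e),
                     (0.6 * e, 0.3 * e), (0.6 * e, 0.1 * e)]
                ),
            },
            {
                "type": "Feature",
                "properties": {"class": "fire", "year": 1990},
                "geometry": poly(
                    [(0.55 * e, 0.55 * e), (0.75 * e, 0.55 * e), (0.75 * e, 0.8 * e),
                     (0.55 * e, 0.8 * e), (0.55 * e, 0.55 * e)]
                ),
            },
        ],
    }

    def strip_set(offset: float) -> dict:
        width = e / n_units
        feats = []
        for u in range(n_units):
            x0 = u * width + offset
            # pad the outermost strips so the set covers the whole extent
            lo = x0 if u > 0 else min(x0, -0.2 * e)
            hi = x0 + width if u < n_units - 1 else max(x0 + width, 1.2 * e)
            feats.append(
                {
                    "type": "Feature",
                    "properties": {"unit_id": u},
                    "geometry": poly(
                        [(lo, -0.2 * e), (hi, -0.2 * e), (hi, 1.2 * e),
                         (lo, 1.2 * e), (lo, -0.2 * e)]
                    ),
                }
            )
        return {"type": "FeatureCollection", "features": feats}

    return {
        "features": features,
        "mu_scenarios": {
            "strips": strip_set(0.0),
            "strips_offset": strip_set(e / (2 * n_units)),
        },
        "config": {"extent": extent, "seed": seed, "n_units": n_units},
    }


def write_fixture(fixture: dict, outdir) -> None:
    """Write the fixture dict as GeoJSON files plus a JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "features.geojson").write_text(
        json.dumps(fixture["features"], sort_keys=True), encoding="utf-8"
    )
    for name, fc in fixture["mu_scenarios"].items():
        (outdir / f"mu_{name}.geojson").write_text(
            json.dumps(fc, sort_keys=True), encoding="utf-8"
        )
    (outdir / "fixture_config.json").write_text(
        json.dumps(fixture["config"], sort_keys=True), encoding="utf-8"
    )
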