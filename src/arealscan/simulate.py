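"""Synthetic areal datasets with known embedded clusters.

Generates study areas that mimic the statistical structure of county-level
chronic-disease prevalence data: a few dozen regions, populations spanning
four orders of magnitude, a baseline prevalence of a few percent, high-risk
zones of controlled shape (compact disks or irregular L/line shapes) with
relative risks in the 1.2-2.5 range, and region-level covariates that may
partially or wholly drive the excess risk.  Every generator is a pure
function of (scenario, seed).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .regions import Region, StudyArea
from .scan.flexible import Adjacency

__all__ = [
    "EmbeddedZone",
    "CovariateSpec",
    "SimulationScenario",
    "generate",
    "scenario_suite",
    "grid_adjacency",
]


@dataclass(frozen=True)
class EmbeddedZone:
    """A true high-risk zone.

    shape: "disk" (centre cell plus rook neighbours within ``radius``
    steps), "L" (two arms meeting at ``anchor``), "line" (horizontal run),
    or "set" (explicit cell list).  ``rr`` multiplies the baseline rate for
    member regions.
    """

    shape: Literal["disk", "L", "line", "set"]
    rr: float
    anchor: tuple[int, int] = (0, 0)
    size: int = 2
    cells: tuple[tuple[int, int], ...] = ()

    def member_cells(self, rows: int, cols: int) -> list[tuple[int, int]]:
        r0, c0 = self.anchor
        if self.shape == "set":
            cells = list(self.cells)
        elif self.shape == "disk":
            cells = [
                (r, c)
                for r in range(rows)
                for c in range(cols)
                if abs(r - r0) + abs(c - c0) <= self.size
            ]
        elif self.shape == "L":
            cells = [(r0 + i, c0) for i in range(self.size)]
            cells += [(r0 + self.size - 1, c0 + j) for j in range(1, self.size)]
        elif self.shape == "line":
            cells = [(r0, c0 + j) for j in range(self.size)]
        else:  # pragma: no cover - guarded by Literal
            raise ValueError(self.shape)
        out = [(r, c) for r, c in cells if 0 <= r < rows and 0 <= c < cols]
        if not out:
            raise ValueError("embedded zone lies entirely outside the lattice")
        return out


@dataclass(frozen=True)
class CovariateSpec:
    """A region-level covariate: Normal(mean, sd) percentages, an effect
    ``beta`` on the log rate per unit, and an optional in-zone mean shift
    that lets a covariate drive a hotspot."""

    name: str
    mean: float
    sd: float
    beta: float = 0.0
    zone_shift: float = 0.0


@dataclass(frozen=True)
class SimulationScenario:
    """Full specification of one synthetic dataset family.

    A lattice of rows x cols cells (or ``n_points`` random planar points),
    log-uniform populations between ``pop_range`` bounds, baseline
    prevalence ``baseline_prevalence``, embedded zones and covariates as
    above.  ``seed`` is part of the scenario; :func:`generate` may override
    it to draw independent datasets from the same scenario.
    """

    name: str = "scenario"
    rows: int = 10
    cols: int = 10
    n_points: int | None = None  # random planar layout instead of a grid
    pop_range: tuple[float, float] = (1e4, 2.5e6)
    uniform_population: float | None = None
    baseline_prevalence: float = 0.037
    zones: tuple[EmbeddedZone, ...] = ()
    covariates: tuple[CovariateSpec, ...] = ()
    largest_pop_fraction: float | None = None
    seed: int = 0

    @property
    def n_regions(self) -> int:
        return self.n_points if self.n_points is not None else self.rows * self.cols

    def with_seed(self, seed: int) -> "SimulationScenario":
        return replace(self, seed=seed)


def grid_adjacency(rows: int, cols: int) -> Adjacency:
    """Rook adjacency of a rows x cols lattice (indices in row-major order)."""
    adj: Adjacency = {i: set() for i in range(rows * cols)}
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            if c + 1 < cols:
                adj[i].add(i + 1)
                adj[i + 1].add(i)
            if r + 1 < rows:
                adj[i].add(i + cols)
                adj[i + cols].add(i)
    return adj


def _populations(scenario: SimulationScenario, rng: np.random.Generator) -> np.ndarray:
    if scenario.uniform_population is not None:
        pops = np.full(scenario.n_regions, float(scenario.uniform_population))
    else:
        lo, hi = scenario.pop_range
        pops = np.exp(rng.uniform(math.log(lo), math.log(hi), scenario.n_regions))
    if scenario.largest_pop_fraction is not None:
        # rescale the largest region so it holds the stated share of the total
        f = scenario.largest_pop_fraction
        i = int(np.argmax(pops))
        others = pops.sum() - pops[i]
        pops[i] = f / (1.0 - f) * others
    return np.maximum(1, np.round(pops)).astype(int)


def generate(
    scenario: SimulationScenario, seed: int | None = None
) -> tuple[StudyArea, np.ndarray]:
    """Draw one dataset: a StudyArea plus per-region truth labels.

    Region rates are lambda_i = pi0 * RR_i * exp(sum beta_k (x_ik -
    mean_k)), with covariates centred on their specified means so pi0
    stays the marginal prevalence; counts are Poisson(lambda_i * N_i)
    truncated at N_i (with a warning).  Truth labels mark embedded-zone
    members, including zones with RR = 1.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    n = scenario.n_regions
    if scenario.n_points is not None:
        coords = rng.uniform(0.0, 100.0, size=(n, 2))
        cell_of = None
    else:
        coords = np.array(
            [(c, r) for r in range(scenario.rows) for c in range(scenario.cols)],
            dtype=float,
        )
        cell_of = {(r, c): r * scenario.cols + c
                   for r in range(scenario.rows) for c in range(scenario.cols)}

    pops = _populations(scenario, rng)

    truth = np.zeros(n, dtype=bool)
    rr = np.ones(n)
    for zone in scenario.zones:
        if cell_of is None:
            raise ValueError("embedded zones require a grid lattice")
        idx = [cell_of[cell] for cell in zone.member_cells(scenario.rows, scenario.cols)]
        truth[idx] = True
        rr[idx] = np.maximum(rr[idx], zone.rr)

    log_shift = np.zeros(n)
    cov_values: dict[str, np.ndarray] = {}
    for spec in scenario.covariates:
        x = rng.normal(spec.mean, spec.sd, size=n)
        if spec.zone_shift:
            x[truth] += spec.zone_shift
        cov_values[spec.name] = x
        log_shift += spec.beta * (x - spec.mean)

    lam = scenario.baseline_prevalence * rr * np.exp(log_shift)
    if np.any(lam >= 1.0):
        raise ValueError("infeasible region rates (lambda >= 1)")
    counts = rng.poisson(lam * pops)
    if np.any(counts > pops):
        warnings.warn("case counts truncated at population", stacklevel=2)
        counts = np.minimum(counts, pops)

    width = len(str(n))
    regions = [
        Region(
            id=f"R{i:0{width}d}",
            name=f"{scenario.name}-{i}",
            x=float(coords[i, 0]),
            y=float(coords[i, 1]),
            population=int(pops[i]),
            cases=int(counts[i]),
            covariates={k: float(v[i]) for k, v in cov_values.items()},
        )
        for i in range(n)
    ]
    return StudyArea(regions, coordinate_mode="planar"), truth


def scenario_suite() -> dict[str, SimulationScenario]:
    """The named scenarios used throughout the test suite.

    - "null-10x10": 100 equal-population cells, no embedded zones.
    - "disk-hotspot": compact 5-cell disk at relative risk 2.0.
    - "l-hotspot": irregular 7-cell L-shape at relative risk 2.0.
    - "covariate-driven": a disk whose excess risk (about 1.6-fold) comes
      entirely from an elevated hypertension-like covariate.
    - "florida-like": 67 irregularly placed regions with log-uniform
      populations, the largest holding 13% of the total.
    """
    base = dict(rows=10, cols=10, uniform_population=5_000.0,
                baseline_prevalence=0.037)
    disk = EmbeddedZone(shape="disk", rr=2.0, anchor=(4, 4), size=1)  # 5 cells
    ell = EmbeddedZone(shape="L", rr=2.0, anchor=(2, 2), size=4)  # 7 cells
    # beta chosen so a +6-point covariate shift multiplies risk by ~1.6:
    # exp(beta * 6) = 1.6  =>  beta = ln(1.6)/6
    beta = math.log(1.6) / 6.0
    return {
        "null-10x10": SimulationScenario(name="null-10x10", **base),
        "disk-hotspot": SimulationScenario(name="disk-hotspot", zones=(disk,), **base),
        "l-hotspot": SimulationScenario(name="l-hotspot", zones=(ell,), **base),
        "covariate-driven": SimulationScenario(
            name="covariate-driven",
            zones=(EmbeddedZone(shape="disk", rr=1.0, anchor=(4, 4), size=1),),
            covariates=(
                CovariateSpec(
                    name="hypertension", mean=34.0, sd=2.0, beta=beta, zone_shift=6.0
                ),
            ),
            **base,
        ),
        "florida-like": SimulationScenario(
            name="florida-like",
            n_points=67,
            rows=0,
            cols=0,
            pop_range=(1e4, 2.5e6),
            largest_pop_fraction=0.13,
            baseline_prevalence=0.037,
        ),
    }
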