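"""Monte Carlo corrosion engine.

Corrosion advances in time steps of length ``dt`` (hours).  Each step:

1. measures the saline-exposed surface ``S`` (the current surface by
   default; optionally frozen at the initial ``S_O`` for the linear
   reference limit),
2. converts the experimental mass-loss rate into a step mass budget
   ``ML = ml_rate * S * dt`` and an element count
   ``n_remove = floor((ML + carry) / Me)`` — the fractional-mass carry
   keeps the cumulative removed mass equal to the cumulative budget to
   within one element mass over arbitrarily long runs,
3. weights every element by its corrosion attribute ``CA = EA * OA``
   (exposure times oxide factor) and normalises to corrosion
   probabilities ``CP_i = n_remove * CA_i / sum(CA)``,
4. stochastically removes elements — either exactly ``n_remove`` by
   weighted sampling without replacement (default) or one independent
   Bernoulli trial per element at probability ``CP_i``,
5. voids the selected elements and records a history row.

Elements uncovered by a removal join the corrodible population only from
the following step (voids appear "at the next time step"), which falls out
naturally from selecting before removing within a step.

Units: the default mass-loss rate is 3.0e-5 mg/mm^2/h (0.003 mg/cm^2/h),
the linear rate measured for AZ61 in 0.9% saline over the first 500 h.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .grid import (
    VOID,
    SpecimenGrid,
    apply_removals,
    build_specimen,
    exposed_surface_area,
    total_mass,
)
from .oxide import OxideConfig, PorousSeedMap, apply_seed_map, assign_oxide_layer, generate_seed_map

logger = logging.getLogger("mgpit")

ML_RATE_UNITS = {"mg_per_mm2_h": 1.0, "mg_per_cm2_h": 0.01}

SURFACE_MODES = ("current", "initial")
REMOVAL_MODES = ("exact_count", "bernoulli")


@dataclass(frozen=True)
class CorrosionConfig:
    """All run parameters.

    Defaults reproduce the reference study conditions: a 15 x 15 x 2 mm
    AZ61 specimen discretised at 0.125 mm (230,400 elements), density
    1.7 mg/mm^3, mass-loss rate 3.0e-5 mg/mm^2/h, 20 steps of 25 h
    (500 h total; use ``n_steps=120`` for the 3,000 h extension).
    """

    length: float = 15.0
    width: float = 15.0
    thickness: float = 2.0
    element_size: float = 0.125
    density: float = 1.7
    ml_rate: float = 3.0e-5
    ml_rate_units: str = "mg_per_mm2_h"
    dt: float = 25.0
    n_steps: int = 20
    surface_mode: str = "current"
    removal_mode: str = "exact_count"
    rng_seed: int = 0
    oxide: OxideConfig = field(default_factory=OxideConfig)

    def __post_init__(self) -> None:
        if self.ml_rate < 0:
            raise ValueError("ml_rate must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.ml_rate_units not in ML_RATE_UNITS:
            raise ValueError(
                f"ml_rate_units must be one of {sorted(ML_RATE_UNITS)}"
            )
        if self.surface_mode not in SURFACE_MODES:
            raise ValueError(f"surface_mode must be one of {SURFACE_MODES}")
        if self.removal_mode not in REMOVAL_MODES:
            raise ValueError(f"removal_mode must be one of {REMOVAL_MODES}")

    @property
    def ml_rate_per_mm2(self) -> float:
        """Mass-loss rate converted to mg/mm^2/h."""
        return self.ml_rate * ML_RATE_UNITS[self.ml_rate_units]

    @property
    def total_time(self) -> float:
        return self.n_steps * self.dt


@dataclass(frozen=True)
class StepRecord:
    """One history row.

    ``mlpa`` is the cumulative mass loss divided by the *initial* surface
    area ``S_O`` (mg/mm^2), the quantity the gravimetric experiment reports.
    """

    step: int
    time: float
    surface: float       # S used in this step's budget, mm^2
    mass_budget: float   # ML = ml_rate * S * dt, mg
    n_remove: int
    removed: int
    mass_remaining: float  # M_N, mg
    mlpa: float


@dataclass
class CorrosionHistory:
    """Ordered step records plus the metadata needed to re-run bit-identically."""

    records: list[StepRecord]
    config: CorrosionConfig
    rng_seed: int
    grid_checksum: str = ""
    truncated: bool = False
    seed_map: Optional[PorousSeedMap] = None

    def times(self) -> np.ndarray:
        return np.array([r.time for r in self.records])

    def mlpa(self) -> np.ndarray:
        return np.array([r.mlpa for r in self.records])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": [r.step for r in self.records],
                "time_h": [r.time for r in self.records],
                "surface_mm2": [r.surface for r in self.records],
                "mass_budget_mg": [r.mass_budget for r in self.records],
                "n_remove": [r.n_remove for r in self.records],
                "removed": [r.removed for r in self.records],
                "mass_remaining_mg": [r.mass_remaining for r in self.records],
                "mlpa_mg_mm2": [r.mlpa for r in self.records],
            }
        )


def step_mass_budget(config: CorrosionConfig, surface: float,
                     carry: float, element_mass: float) -> tuple[float, int, float]:
    """Convert the exposed surface into this step's removal count.

    Returns ``(ML, n_remove, new_carry)`` with ``ML = ml_rate * S * dt``,
    ``n_remove = floor((ML + carry) / Me)`` and the sub-element remainder
    carried into the next step.
    """
    if surface < 0:
        raise ValueError("surface must be >= 0")
    ml = config.ml_rate_per_mm2 * surface * config.dt
    total = ml + carry
    n_remove = int(math.floor(total / element_mass))
    new_carry = total - n_remove * element_mass
    return ml, n_remove, new_carry


def corrosion_attributes(grid: SpecimenGrid) -> np.ndarray:
    """Per-element corrosion attribute ``CA = EA * OA`` (0 for void)."""
    ca = grid.ea.astype(np.float64) * grid.oa
    ca[grid.state == VOID] = 0.0
    return ca


def corrosion_probabilities(grid: SpecimenGrid, n_remove: int,
                            ca: np.ndarray | None = None) -> np.ndarray:
    """Per-element removal probability ``CP_i = n_remove * CA_i / sum(CA)``.

    The pre-clip probabilities sum exactly to ``n_remove``; values above 1
    (possible only when the corrodible population is tiny) are clipped to
    1 with a logged warning.
    """
    if ca is None:
        ca = corrosion_attributes(grid)
    total = ca.sum()
    if total <= 0.0:
        if n_remove > 0:
            raise ValueError("no corrodible surface (sum of CA is zero) "
                             f"but n_remove = {n_remove}")
        return np.zeros_like(ca)
    cp = (n_remove / total) * ca
    if (cp > 1.0).any():
        logger.warning(
            "clipping %d corrosion probabilities > 1 (corrodible population "
            "is small relative to the mass budget)", int((cp > 1.0).sum()),
        )
        cp = np.minimum(cp, 1.0)
    return cp


def select_elements(grid: SpecimenGrid, n_remove: int,
                    mode: str = "exact_count",
                    rng: np.random.Generator | None = None,
                    ca: np.ndarray | None = None) -> np.ndarray:
    """Monte Carlo selection of elements to corrode this step.

    ``exact_count`` draws exactly ``n_remove`` elements by weighted
    sampling without replacement with weights proportional to CA
    (exponential-race keys: the k smallest of ``E_i / w_i`` with
    ``E_i ~ Exp(1)`` reproduce sequential weighted draws).  ``bernoulli``
    removes each element independently with probability ``CP_i``, so the
    removal count is random with mean ``n_remove`` (pre-clip).

    Returns an ``(m, 3)`` integer array of ``(i, j, k)`` coordinates.
    """
    rng = rng if rng is not None else np.random.default_rng()
    if n_remove < 0:
        raise ValueError("n_remove must be >= 0")
    if n_remove == 0 and mode == "exact_count":
        return np.empty((0, 3), dtype=np.intp)
    if ca is None:
        ca = corrosion_attributes(grid)
    if mode == "exact_count":
        coords = np.argwhere(ca > 0)
        weights = ca[ca > 0]
        if n_remove > coords.shape[0]:
            logger.warning(
                "n_remove = %d exceeds the corrodible population (%d); "
                "removing all corrodible elements", n_remove, coords.shape[0],
            )
            return coords.astype(np.intp)
        keys = rng.exponential(size=weights.shape[0]) / weights
        pick = np.argpartition(keys, n_remove - 1)[:n_remove]
        return coords[pick].astype(np.intp)
    if mode == "bernoulli":
        cp = corrosion_probabilities(grid, n_remove, ca=ca)
        u = rng.random(size=cp.shape)
        return np.argwhere(u < cp).astype(np.intp)
    raise ValueError(f"unknown removal mode {mode!r}")


def advance_step(grid: SpecimenGrid, config: CorrosionConfig,
                 rng: np.random.Generator, carry: float,
                 step_index: int = 1) -> tuple[StepRecord, float]:
    """Advance corrosion by one ``dt`` and return the history row.

    Order within a step: surface measurement -> mass budget -> CA -> CP ->
    Monte Carlo selection -> removal -> bookkeeping, so elements uncovered
    this step only become candidates next step.
    """
    me = grid.element_mass
    if config.surface_mode == "current":
        surface = exposed_surface_area(grid)
    else:
        surface = grid.initial_surface_area
    ml, n_remove, new_carry = step_mass_budget(config, surface, carry, me)
    removed = 0
    if n_remove > 0:
        ca = corrosion_attributes(grid)
        coords = select_elements(grid, n_remove, mode=config.removal_mode,
                                 rng=rng, ca=ca)
        if coords.shape[0] > 0:
            apply_removals(grid, coords)
        removed = int(coords.shape[0])
    m_n = total_mass(grid)
    mlpa = (grid.initial_mass - m_n) / grid.initial_surface_area
    record = StepRecord(
        step=step_index,
        time=step_index * config.dt,
        surface=surface,
        mass_budget=ml,
        n_remove=n_remove,
        removed=removed,
        mass_remaining=m_n,
        mlpa=mlpa,
    )
    logger.info(
        "step %d: T=%.0f h, S=%.2f mm^2, ML=%.4f mg, n_remove=%d, "
        "removed=%d, M_N=%.3f mg", step_index, record.time, surface, ml,
        n_remove, removed, m_n,
    )
    return record, new_carry


def run_simulation(
    config: CorrosionConfig,
    seed_map: PorousSeedMap | None = None,
    on_step: Callable[[SpecimenGrid, StepRecord], None] | None = None,
) -> tuple[SpecimenGrid, CorrosionHistory]:
    """Build, oxidise, seed and corrode a specimen for ``n_steps`` steps.

    All randomness (seed-map generation and removal sampling) flows from
    ``config.rng_seed`` through two deterministically derived sub-streams,
    so supplying an explicit ``seed_map`` does not change the removal
    trajectory's stream.  Returns the final grid and the full history; if
    the specimen is consumed early the history is truncated and flagged.
    """
    grid = build_specimen(config.length, config.width, config.thickness,
                          config.element_size, config.density)
    assign_oxide_layer(grid, config.oxide)
    ss_map, ss_run = np.random.SeedSequence(config.rng_seed).spawn(2)
    if seed_map is None and config.oxide.n_seeds > 0:
        seed_map = generate_seed_map(grid, config.oxide,
                                     np.random.default_rng(ss_map))
    if seed_map is not None and len(seed_map) > 0:
        apply_seed_map(grid, seed_map)
    rng = np.random.default_rng(ss_run)
    carry = 0.0
    records: list[StepRecord] = []
    truncated = False
    for step in range(1, config.n_steps + 1):
        if not grid.solid_mask.any():
            logger.warning("specimen fully consumed after %d steps; "
                           "terminating early", step - 1)
            truncated = True
            break
        record, carry = advance_step(grid, config, rng, carry, step_index=step)
        records.append(record)
        if on_step is not None:
            on_step(grid, record)
    history = CorrosionHistory(
        records=records,
        config=config,
        rng_seed=config.rng_seed,
        grid_checksum=grid.checksum(),
        truncated=truncated,
        seed_map=seed_map,
    )
    return grid, history


# ---------------------------------------------------------------------------
# Config (de)serialisation — YAML/JSON dicts mirroring CorrosionConfig.

def config_from_dict(data: dict) -> CorrosionConfig:
    """Build a config from a plain dict (YAML/JSON run file).

    Oxide parameters live under an ``oxide`` sub-dict; the mass-loss rate
    may be given as ``ml_rate_value`` + ``ml_rate_units`` (explicit units)
    or plain ``ml_rate`` (mg/mm^2/h).
    """
    data = dict(data)
    oxide_data = data.pop("oxide", {}) or {}
    if "ml_rate_value" in data:
        data["ml_rate"] = data.pop("ml_rate_value")
    known = {f for f in CorrosionConfig.__dataclass_fields__ if f != "oxide"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    unknown_ox = set(oxide_data) - set(OxideConfig.__dataclass_fields__)
    if unknown_ox:
        raise ValueError(f"unknown oxide config keys: {sorted(unknown_ox)}")
    if "seed_faces" in oxide_data:
        oxide_data["seed_faces"] = tuple(oxide_data["seed_faces"])
    return CorrosionConfig(oxide=OxideConfig(**oxide_data), **data)


def config_to_dict(config: CorrosionConfig) -> dict:
    d = {f: getattr(config, f) for f in CorrosionConfig.__dataclass_fields__
         if f != "oxide"}
    d["oxide"] = {f: getattr(config.oxide, f)
                  for f in OxideConfig.__dataclass_fields__}
    d["oxide"]["seed_faces"] = list(config.oxide.seed_faces)
    return d


def load_config(path: str) -> CorrosionConfig:
    """Read a YAML (or JSON — YAML superset) run configuration."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return config_from_dict(data)
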