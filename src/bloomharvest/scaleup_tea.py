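"""Modular flotation-pontoon scale-up and techno-economic model.

A full-size flotation module treats a fixed batch volume (24,000 L default)
on a fill / treat / drain cycle. Air demand scales linearly from the
laboratory basis of 1 mL·min⁻¹ of air per litre treated; a compressor's free
air delivery derates to roughly 25% of the nameplate rating when run against
3 bar(g), so design feasibility checks the derated flow against demand.

Operating cost per batch is metered energy (power × duty time × tariff) or a
given per-batch figure; flocculant cost scales with the whole treated volume
and its dose. Whole-lake treatment cost multiplies per-batch items by a
real-valued batch count (a lake volume is not an integer number of batches —
the scheduling view rounds up, the costing view does not).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "ScaleUpDesign",
    "CostItem",
    "CostLedger",
    "air_demand",
    "derated_flow",
    "batch_cycle",
    "energy_cost",
    "flocculant_cost",
    "capex_total",
    "treatment_cost",
    "solar_sizing",
]


@dataclass(frozen=True)
class ScaleUpDesign:
    """Design point of one pontoon module (defaults: the 24 m³ reference)."""

    batch_volume_l: float = 24_000.0
    specific_air_rate_ml_per_min_per_l: float = 1.0
    operating_pressure_bar_g: float = 3.0
    compressor_rated_flow_l_per_min: float = 201.0
    derating_fraction: float = 0.25
    treat_time_min: float = 30.0
    fill_time_min: float = 48.0
    drain_time_min: float = 48.0
    pump_power_kw: float = 0.32
    skimmer_power_kw: float = 16.0
    compressor_power_kw: float = 1.1

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")

    @property
    def air_demand_l_per_min(self) -> float:
        return air_demand(self.batch_volume_l, self.specific_air_rate_ml_per_min_per_l)

    @property
    def derated_flow_l_per_min(self) -> float:
        return self.compressor_rated_flow_l_per_min * self.derating_fraction

    @property
    def feasible(self) -> bool:
        return self.derated_flow_l_per_min >= self.air_demand_l_per_min

    @property
    def cycle_min(self) -> float:
        return batch_cycle(self.treat_time_min, self.fill_time_min, self.drain_time_min)


@dataclass(frozen=True)
class CostItem:
    """One equipment or consumable line of the cost model.

    Per-batch OPEX is either given directly, derived from (power_kw,
    duty_min_per_batch) via the tariff, or — for dose-priced consumables —
    computed from price_per_kg and the flocculant dose over the whole volume.
    """

    name: str
    capex: float = 0.0
    opex_per_batch: float | None = None
    duty_min_per_batch: float | None = None
    power_kw: float | None = None
    price_per_kg: float | None = None
    capex_components: tuple[tuple[int, float], ...] = ()

    def __post_init__(self) -> None:
        if self.capex < 0:
            raise ValueError(f"{self.name}: negative CAPEX")
        if self.opex_per_batch is not None and self.opex_per_batch < 0:
            raise ValueError(f"{self.name}: negative OPEX")

    @property
    def total_capex(self) -> float:
        if self.capex_components:
            return float(sum(q * p for q, p in self.capex_components))
        return self.capex


@dataclass
class CostLedger:
    """Per-item and total costs for treating a whole water body."""

    n_batches: float
    electricity_tariff_per_kwh: float
    rows: list[dict] = field(default_factory=list)

    @property
    def total_opex(self) -> float:
        return sum(r["full_cost"] for r in self.rows)

    @property
    def total_capex(self) -> float:
        return sum(r["capex"] for r in self.rows)


def air_demand(
    treatment_volume_l: float, specific_rate_ml_per_min_per_l: float = 1.0
) -> float:
    """Airflow (L/min) needed for a treatment volume at the specific air rate."""
    if treatment_volume_l <= 0:
        raise ValueError(f"treatment volume must be positive, got {treatment_volume_l}")
    return treatment_volume_l * specific_rate_ml_per_min_per_l / 1000.0


def derated_flow(
    rated_flow_l_per_min: float,
    fraction: float = 0.25,
    demand_l_per_min: float | None = None,
) -> tuple[float, bool | None]:
    """Compressor free-air delivery at pressure, and feasibility vs demand.

    Returns (derated L/min, feasible); feasible is None when no demand is
    given.
    """
    if rated_flow_l_per_min <= 0:
        raise ValueError(f"rated flow must be positive, got {rated_flow_l_per_min}")
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"derating fraction {fraction} outside (0, 1]")
    flow = rated_flow_l_per_min * fraction
    feasible = None if demand_l_per_min is None else flow >= demand_l_per_min
    return flow, feasible


def batch_cycle(treat_min: float, fill_min: float, drain_min: float) -> float:
    """Total batch cycle time (min): fill + treat + drain."""
    for v in (treat_min, fill_min, drain_min):
        if v < 0:
            raise ValueError(f"negative duration: {v}")
    return treat_min + fill_min + drain_min


def energy_cost(power_kw: float, duration_min: float, tariff_per_kwh: float) -> float:
    """Electricity cost of running a load for a duration."""
    for name, v in (("power", power_kw), ("duration", duration_min),
                    ("tariff", tariff_per_kwh)):
        if v < 0:
            raise ValueError(f"negative {name}: {v}")
    return power_kw * (duration_min / 60.0) * tariff_per_kwh


def flocculant_cost(
    dose_mg_per_l: float, volume_l: float, unit_price_per_kg: float
) -> tuple[float, float]:
    """Flocculant mass (kg) and cost for dosing a volume.

    Returns (kg used, cost).
    """
    for name, v in (("dose", dose_mg_per_l), ("volume", volume_l),
                    ("price", unit_price_per_kg)):
        if v < 0:
            raise ValueError(f"negative {name}: {v}")
    kg = dose_mg_per_l * volume_l * 1e-6
    return kg, kg * unit_price_per_kg


def capex_total(items: list[CostItem]) -> float:
    """Total capital cost; composite items expand their component lists."""
    return float(sum(item.total_capex for item in items))


def treatment_cost(
    items: list[CostItem],
    total_volume_l: float,
    batch_volume_l: float,
    flocculant_dose_mg_per_l: float = 0.0,
    electricity_tariff_per_kwh: float = 0.15,
) -> CostLedger:
    """Cost ledger for treating a whole water body batch-by-batch.

    Metered items cost opex_per_batch × n_batches with n_batches real-valued;
    items carrying (power, duty) but no explicit per-batch OPEX have it
    derived from the tariff; price_per_kg items are dosed over the whole
    volume. Full costs are kept at full precision — round only for display.
    """
    if batch_volume_l <= 0:
        raise ValueError(f"batch volume must be positive, got {batch_volume_l}")
    if total_volume_l < 0:
        raise ValueError(f"negative total volume: {total_volume_l}")
    n_batches = total_volume_l / batch_volume_l
    ledger = CostLedger(
        n_batches=n_batches, electricity_tariff_per_kwh=electricity_tariff_per_kwh
    )
    for item in items:
        if item.price_per_kg is not None:
            kg, cost = flocculant_cost(
                flocculant_dose_mg_per_l, total_volume_l, item.price_per_kg
            )
            ledger.rows.append(
                {"name": item.name, "capex": item.total_capex,
                 "opex_per_batch": (cost / n_batches) if n_batches else 0.0,
                 "duty_min": item.duty_min_per_batch, "full_cost": cost,
                 "flocculant_kg": kg}
            )
            continue
        if item.opex_per_batch is not None:
            per_batch = item.opex_per_batch
        elif item.power_kw is not None and item.duty_min_per_batch is not None:
            per_batch = energy_cost(
                item.power_kw, item.duty_min_per_batch, electricity_tariff_per_kwh
            )
        else:
            raise ValueError(
                f"{item.name}: no per-batch OPEX and no (power, duty) to derive it"
            )
        ledger.rows.append(
            {"name": item.name, "capex": item.total_capex,
             "opex_per_batch": per_batch, "duty_min": item.duty_min_per_batch,
             "full_cost": per_batch * n_batches}
        )
    return ledger


def solar_sizing(
    continuous_load_kw: float,
    panel_rating_w: float = 250.0,
    area_per_panel_m2: float = 1.5,
    derate: float = 1.0,
) -> dict[str, float]:
    """Panel count and array area to carry a continuous electrical load.

    n = ceil(load / (panel rating × derate)); derate folds in inverter and
    soiling losses (1 = nameplate).
    """
    if continuous_load_kw <= 0 or panel_rating_w <= 0 or area_per_panel_m2 <= 0:
        raise ValueError("solar sizing inputs must be positive")
    if not 0.0 < derate <= 1.0:
        raise ValueError(f"derate {derate} outside (0, 1]")
    n = math.ceil(continuous_load_kw * 1000.0 / (panel_rating_w * derate))
    return {"n_panels": n, "array_area_m2": n * area_per_panel_m2}
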