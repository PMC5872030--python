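"""End-to-end case-study orchestration.

Runs the whole chain on a parameter file of published inputs (water
physicochemistry, biomass contents, harvesting efficiencies, scale-up design
and the cost table) and emits the resource-recovery table, the
techno-economic ledger, and a checklist comparing each computed quantity to
its published counterpart at the published rounding precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import resource_recovery, scaleup_tea
from .units_io import read_config

__all__ = ["RunConfig", "CaseStudyReport", "load_default_parameters", "run_case_study"]

logger = logging.getLogger("bloomharvest")

_ALLOWED_CONFIG_KEYS = {
    "scenario", "parameters_file", "overrides", "output_dir", "log_level",
}


@dataclass
class RunConfig:
    """Run settings: which parameter file, overrides, and where output goes."""

    scenario: str = "wrp"
    parameters_file: str | None = None
    overrides: dict[str, Any] = field(default_factory=dict)
    output_dir: str | None = None
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        unknown = set(raw) - _ALLOWED_CONFIG_KEYS
        if unknown:
            raise ValueError(
                f"unknown config key(s): {sorted(unknown)}; "
                f"allowed: {sorted(_ALLOWED_CONFIG_KEYS)}"
            )
        return cls(**raw)


def load_default_parameters() -> dict:
    """The bundled water-retention-pond case-study parameter set."""
    text = (
        resources.files("bloomharvest").joinpath("data/wrp_case_study.yaml")
        .read_text(encoding="utf-8")
    )
    return yaml.safe_load(text)


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


@dataclass
class CaseStudyReport:
    resource_table: pd.DataFrame
    ledger: scaleup_tea.CostLedger
    design: scaleup_tea.ScaleUpDesign
    solar: dict[str, float]
    checks: list[dict]

    @property
    def n_passed(self) -> int:
        return sum(c["passed"] for c in self.checks)

    def render(self) -> str:
        """Deterministic plain-text report (same config -> identical bytes)."""
        lines = ["# Resource recovery (kg)", ""]
        cols = ["mode", "resource", "efficiency_pct",
                "low_kg_display", "high_kg_display"]
        lines.append(self.resource_table[cols].to_string(index=False))
        lines += ["", "# Scale-up design", ""]
        lines.append(f"air demand: {self.design.air_demand_l_per_min:.1f} L/min")
        lines.append(
            f"derated compressor flow: {self.design.derated_flow_l_per_min:.2f} "
            f"L/min (feasible: {self.design.feasible})"
        )
        lines.append(f"batch cycle: {self.design.cycle_min:.0f} min")
        lines.append(
            f"solar: {self.solar['n_panels']} panels, "
            f"{self.solar['array_area_m2']:.1f} m2"
        )
        lines += ["", "# Cost ledger", ""]
        lines.append(f"n_batches = {self.ledger.n_batches:g}")
        for r in self.ledger.rows:
            lines.append(
                f"{r['name']:<20s} capex {r['capex']:8.0f}   "
                f"per-batch {r['opex_per_batch']:8.4f}   "
                f"full {r['full_cost']:10.2f}"
            )
        lines.append(f"{'TOTAL':<20s} capex {self.ledger.total_capex:8.0f}   "
                     f"{'':20s} full {self.ledger.total_opex:10.2f}")
        lines += ["", "# Checklist (computed vs published)", ""]
        for c in self.checks:
            status = "pass" if c["passed"] else "FAIL"
            lines.append(
                f"[{status}] {c['name']}: computed {c['computed']} "
                f"vs published {c['published']}"
            )
        lines.append("")
        lines.append(f"{self.n_passed}/{len(self.checks)} checks passed")
        return "\n".join(lines) + "\n"

    def to_dict(self) -> dict:
        return {
            "resources": self.resource_table.to_dict(orient="records"),
            "ledger": {
                "n_batches": self.ledger.n_batches,
                "rows": self.ledger.rows,
                "total_opex": self.ledger.total_opex,
                "total_capex": self.ledger.total_capex,
            },
            "design": {
                "air_demand_l_per_min": self.design.air_demand_l_per_min,
                "derated_flow_l_per_min": self.design.derated_flow_l_per_min,
                "feasible": self.design.feasible,
                "cycle_min": self.design.cycle_min,
            },
            "solar": self.solar,
            "checks": self.checks,
        }


def _check(name: str, computed, published, ndigits: int | None) -> dict:
    """Compare a computed value to its published counterpart after rounding
    the computed value to the published precision."""
    def _round(v):
        return round(v, ndigits) if ndigits is not None else int(round(v))

    if isinstance(published, (list, tuple)):
        rounded = [_round(v) for v in computed]
        passed = all(r == p for r, p in zip(rounded, published))
    else:
        rounded = _round(computed)
        passed = rounded == published
    return {"name": name, "computed": rounded, "published": published,
            "passed": passed}


def run_case_study(config: RunConfig | dict | None = None) -> CaseStudyReport:
    """Run the full chain on the bundled (or overridden) parameter set."""
    if config is None:
        config = RunConfig()
    elif isinstance(config, dict):
        config = RunConfig.from_dict(config)
    logger.setLevel(config.log_level.upper())

    if config.parameters_file is not None:
        path = Path(config.parameters_file)
        if not path.exists():
            raise FileNotFoundError(f"parameter file not found: {path}")
        params = read_config(path)
    else:
        params = load_default_parameters()
    if config.overrides:
        params = _deep_merge(params, config.overrides)

    logger.info("scenario %s: computing resource recovery", config.scenario)
    comp = resource_recovery.BiomassComposition.from_micrograms_per_mg(
        lipid=params["composition_ug_per_mg"]["lipid"],
        phosphate=params["composition_ug_per_mg"]["phosphate"],
        protein=params["composition_ug_per_mg"]["protein"],
    )
    vol_lo, vol_hi = params["photic_zone_volume_m3"]
    stock = resource_recovery.biomass_stock(
        params["water"]["dry_weight_g_per_l"], (vol_lo, vol_hi)
    )
    effs = {str(k): float(v)
            for k, v in params["harvesting_efficiency_pct"].items()}
    table = resource_recovery.recovery_report(stock, comp, effs)

    logger.info("scale-up design and cost ledger")
    design = scaleup_tea.ScaleUpDesign(**params["scaleup"])
    tea = params["tea"]
    items = []
    for spec in tea["items"]:
        spec = dict(spec)
        if "capex_components" in spec:
            spec["capex_components"] = tuple(
                (int(q), float(p)) for q, p in spec["capex_components"]
            )
        items.append(scaleup_tea.CostItem(**spec))
    dose_max = float(params["flocculant_dose_mg_per_l"]["max"])
    ledger = scaleup_tea.treatment_cost(
        items,
        total_volume_l=float(tea["total_volume_l"]),
        batch_volume_l=design.batch_volume_l,
        flocculant_dose_mg_per_l=dose_max,
        electricity_tariff_per_kwh=float(tea["electricity_tariff_per_kwh"]),
    )
    solar = scaleup_tea.solar_sizing(**params["solar"])

    pub = params["published"]
    t = table.set_index(["mode", "resource"])

    def rec(mode, resource):
        row = t.loc[(mode, resource)]
        return float(row["low_kg"]), float(row["high_kg"])

    chitosan_cost = next(
        r["full_cost"] for r in ledger.rows if r["name"].lower() == "chitosan"
    )
    checks = [
        _check("biomass_stock_kg", (stock.stock_low_kg, stock.stock_high_kg),
               pub["biomass_stock_kg"], None),
        _check("lipid_recovery_max_kg", rec("max", "lipid"),
               pub["lipid_recovery_max_kg"], None),
        _check("lipid_recovery_submax_kg", rec("sub-max", "lipid"),
               pub["lipid_recovery_submax_kg"], None),
        _check("phosphate_recovery_max_kg", rec("max", "phosphate"),
               pub["phosphate_recovery_max_kg"], 2),
        _check("phosphate_recovery_submax_kg", rec("sub-max", "phosphate"),
               pub["phosphate_recovery_submax_kg"], 2),
        _check("protein_recovery_max_low_kg", rec("max", "protein")[0],
               pub["protein_recovery_max_low_kg"], 2),
        _check("protein_recovery_submax_low_kg", rec("sub-max", "protein")[0],
               pub["protein_recovery_submax_low_kg"], 2),
        _check("air_demand_l_per_min", design.air_demand_l_per_min,
               pub["air_demand_l_per_min"], None),
        _check("derated_flow_l_per_min", design.derated_flow_l_per_min,
               pub["derated_flow_l_per_min"], None),
        _check("batch_cycle_min", design.cycle_min, pub["batch_cycle_min"], None),
        _check("chitosan_full_cost", chitosan_cost, pub["chitosan_full_cost"],
               None),
        {
            "name": "total_opex_bound",
            "computed": round(ledger.total_opex, 2),
            "published": f"< {pub['total_opex_bound']}",
            "passed": ledger.total_opex < pub["total_opex_bound"],
        },
    ]

    report = CaseStudyReport(
        resource_table=table, ledger=ledger, design=design, solar=solar,
        checks=checks,
    )
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "case_study_report.txt").write_text(report.render(),
                                                   encoding="utf-8")
        (out / "case_study_results.yaml").write_text(
            yaml.safe_dump(_plain(report.to_dict()), sort_keys=True),
            encoding="utf-8",
        )
        table.to_csv(out / "resource_recovery.csv", index=False)
    return report


def _plain(obj):
    """Recursively coerce numpy scalars for clean YAML serialisation."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj
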