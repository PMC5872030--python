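"""Biomass stock estimation and the recoverable-resource mass balance.

A bloom's standing biomass is dry-weight concentration times the photic-zone
volume. Multiplying the stock by a per-mass content (lipid, phosphate or
protein, as mass fractions) and by the flotation harvesting efficiency gives
the recoverable mass of each resource. The harvesting efficiency measured on
the Chlorophyll a proxy is applied to bulk biomass — the model assumes the
two are removed alike.

Protein content is routinely estimated from total nitrogen with a
nitrogen-to-protein conversion factor (4.78 for algal biomass here).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .separation import removal_efficiency

__all__ = [
    "BiomassComposition",
    "BloomStock",
    "N_TO_PROTEIN_FACTOR",
    "biomass_stock",
    "recoverable_mass",
    "protein_from_nitrogen",
    "dissolved_removal",
    "recovery_report",
]

N_TO_PROTEIN_FACTOR = 4.78


@dataclass(frozen=True)
class BiomassComposition:
    """Per-mass contents of harvested biomass, as g per g dry weight."""

    lipid_g_per_g: float
    phosphate_g_per_g: float
    protein_g_per_g: float
    total_n_g_per_g: float | None = None
    total_c_g_per_g: float | None = None

    def __post_init__(self) -> None:
        for name in ("lipid_g_per_g", "phosphate_g_per_g", "protein_g_per_g"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} is not a mass fraction in [0, 1]")

    @classmethod
    def from_micrograms_per_mg(
        cls, lipid: float, phosphate: float, protein: float, **kw
    ) -> "BiomassComposition":
        """Construct from contents quoted in µg per mg biomass (x 1e-3 to g/g)."""
        return cls(
            lipid_g_per_g=lipid * 1e-3,
            phosphate_g_per_g=phosphate * 1e-3,
            protein_g_per_g=protein * 1e-3,
            **kw,
        )


@dataclass(frozen=True)
class BloomStock:
    """Dry-biomass standing stock over a photic-zone volume range."""

    dry_weight_g_per_l: float
    volume_low_m3: float
    volume_high_m3: float
    stock_low_kg: float
    stock_high_kg: float


def biomass_stock(
    dry_weight_g_per_l: float, volume_range_m3: tuple[float, float]
) -> BloomStock:
    """Standing dry biomass (kg) for a concentration and volume range.

    1 g/L over 1 m^3 (1000 L) is exactly 1 kg, so kg = (g/L) x (m^3).
    """
    lo, hi = volume_range_m3
    if dry_weight_g_per_l < 0:
        raise ValueError(f"negative dry weight: {dry_weight_g_per_l}")
    if lo <= 0 or hi <= 0 or lo > hi:
        raise ValueError(f"invalid volume range: {volume_range_m3}")
    return BloomStock(
        dry_weight_g_per_l=dry_weight_g_per_l,
        volume_low_m3=lo,
        volume_high_m3=hi,
        stock_low_kg=dry_weight_g_per_l * lo,
        stock_high_kg=dry_weight_g_per_l * hi,
    )


def recoverable_mass(
    stock_kg: float, content_g_per_g: float, harvesting_efficiency_pct: float
) -> float:
    """Mass of a resource recoverable at a given harvesting efficiency (kg).

    Full-precision product; any rounding for presentation happens at report
    time, never here.
    """
    if stock_kg < 0:
        raise ValueError(f"negative stock: {stock_kg}")
    if not 0.0 <= content_g_per_g <= 1.0:
        raise ValueError(f"content {content_g_per_g} outside [0, 1]")
    if not 0.0 <= harvesting_efficiency_pct <= 100.0:
        raise ValueError(
            f"efficiency {harvesting_efficiency_pct} outside [0, 100]"
        )
    return stock_kg * content_g_per_g * harvesting_efficiency_pct / 100.0


def protein_from_nitrogen(
    total_n_g_per_g: float, factor: float = N_TO_PROTEIN_FACTOR
) -> float:
    """Protein mass fraction estimated from total nitrogen."""
    if not 0.0 <= total_n_g_per_g <= 1.0:
        raise ValueError(f"total N {total_n_g_per_g} outside [0, 1]")
    protein = factor * total_n_g_per_g
    if protein > 1.0:
        raise ValueError(
            f"derived protein fraction {protein:.4f} exceeds 1: impossible "
            "composition"
        )
    return protein


def dissolved_removal(c0_mg_per_l: float, ct_mg_per_l: float, **kw) -> float:
    """Removal efficiency (%) of a dissolved nutrient, e.g. PO4.

    Same contract as the Chlorophyll a removal computation; shared
    implementation.
    """
    return removal_efficiency(c0_mg_per_l, ct_mg_per_l, **kw)


def recovery_report(
    stock: BloomStock,
    composition: BiomassComposition,
    efficiencies_pct: dict[str, float],
) -> pd.DataFrame:
    """Recoverable kg of each resource per harvesting mode and volume bound.

    `efficiencies_pct` maps mode name (e.g. "max", "sub-max") to harvesting
    efficiency. Lipids are reported to the nearest kg, phosphate and protein
    to 2 decimal places, in separate presentation columns; the *_kg columns
    stay full precision.
    """
    contents = {
        "lipid": composition.lipid_g_per_g,
        "phosphate": composition.phosphate_g_per_g,
        "protein": composition.protein_g_per_g,
    }
    rows = []
    for mode, eff in efficiencies_pct.items():
        for resource, content in contents.items():
            low = recoverable_mass(stock.stock_low_kg, content, eff)
            high = recoverable_mass(stock.stock_high_kg, content, eff)
            ndp = 0 if resource == "lipid" else 2
            rows.append(
                {
                    "mode": mode,
                    "resource": resource,
                    "efficiency_pct": eff,
                    "low_kg": low,
                    "high_kg": high,
                    "low_kg_display": round(low, ndp) if ndp else int(round(low)),
                    "high_kg_display": round(high, ndp) if ndp else int(round(high)),
                }
            )
    return pd.DataFrame(rows)
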