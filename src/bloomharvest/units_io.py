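"""Units, conversions and table/config I/O shared by the whole pipeline.

The package operates on a small closed set of units that appear in bloom
harvesting work: concentrations (mg/L and friends), per-mass contents
(µg per mg of biomass), volumes, airflow (including imperial cfm for
compressor ratings), power, time, mass, currency and percentages.

Canonical internal units are: volume L, concentration mg/L, content g/g
(mass fraction), mass kg, time min, power kW, airflow L/min.
Percentages are carried on the 0–100 scale throughout.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

__all__ = [
    "Quantity",
    "WaterSample",
    "UnitError",
    "TableError",
    "convert",
    "conversion_factor",
    "read_table",
    "write_table",
    "read_config",
    "read_water_sample",
    "CFM_TO_L_PER_MIN",
]

# 1 cubic foot = 28.3168 L; fixed here — a 7.1 cfm compressor rating
# converts to 201.05 L/min and is quoted as "201" after rounding.
CFM_TO_L_PER_MIN = 28.3168

# unit -> (dimension, factor to the canonical unit of that dimension)
_REGISTRY: dict[str, tuple[str, float]] = {
    # volume (canonical: L)
    "L": ("volume", 1.0),
    "mL": ("volume", 1e-3),
    "m3": ("volume", 1000.0),
    # concentration (canonical: mg/L)
    "mg/L": ("concentration", 1.0),
    "g/L": ("concentration", 1000.0),
    "ug/L": ("concentration", 1e-3),
    # per-mass content (canonical: g/g mass fraction)
    "g/g": ("content", 1.0),
    "ug/mg": ("content", 1e-3),
    "mg/g": ("content", 1e-3),
    "mg/mg": ("content", 1.0),
    # mass (canonical: kg)
    "kg": ("mass", 1.0),
    "g": ("mass", 1e-3),
    "mg": ("mass", 1e-6),
    # time (canonical: min)
    "min": ("time", 1.0),
    "h": ("time", 60.0),
    # power (canonical: kW)
    "kW": ("power", 1.0),
    "W": ("power", 1e-3),
    # airflow (canonical: L/min)
    "L/min": ("airflow", 1.0),
    "mL/min": ("airflow", 1e-3),
    "cfm": ("airflow", CFM_TO_L_PER_MIN),
    # scalars
    "kWh": ("energy", 1.0),
    "currency": ("currency", 1.0),
    "%": ("fraction_pct", 1.0),
}

# Unicode variants accepted on input (µ vs u, · vs /, superscripts).
_ALIASES = {
    "µg/mg": "ug/mg",
    "μg/mg": "ug/mg",
    "µg/L": "ug/L",
    "μg/L": "ug/L",
    "m³": "m3",
    "£": "currency",
    "GBP": "currency",
}


class UnitError(ValueError):
    """Raised for unknown units or dimensionally incompatible conversions."""


class TableError(ValueError):
    """Raised for malformed delimiter-separated input tables."""


def _canon_unit(unit: str) -> str:
    unit = _ALIASES.get(unit, unit)
    if unit not in _REGISTRY:
        raise UnitError(f"unknown unit {unit!r}; registry has {sorted(_REGISTRY)}")
    return unit


@dataclass(frozen=True)
class Quantity:
    """A number tagged with one of the registry units."""

    value: float
    unit: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "unit", _canon_unit(self.unit))

    def to(self, target_unit: str) -> "Quantity":
        return convert(self, target_unit)


def conversion_factor(unit: str, target_unit: str) -> float:
    """Multiplicative factor taking a value in `unit` to `target_unit`.

    Raises UnitError when the two units measure different dimensions.
    """
    u, t = _canon_unit(unit), _canon_unit(target_unit)
    dim_u, f_u = _REGISTRY[u]
    dim_t, f_t = _REGISTRY[t]
    if dim_u != dim_t:
        raise UnitError(
            f"cannot convert {unit!r} ({dim_u}) to {target_unit!r} ({dim_t}): "
            "incompatible dimensions"
        )
    return f_u / f_t


def convert(q: Quantity, target_unit: str) -> Quantity:
    """Convert a Quantity to a dimensionally compatible unit.

    >>> convert(Quantity(7.1, "cfm"), "L/min").value
    201.04928
    """
    return Quantity(q.value * conversion_factor(q.unit, target_unit), target_unit)


# ---------------------------------------------------------------------------
# Delimiter-separated tables
# ---------------------------------------------------------------------------


def _sniff_delimiter(path: Path) -> str:
    # Fixtures are hand-written CSV or TSV; decide from the header line.
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_table(
    path: str | Path,
    required: Iterable[str] = (),
    numeric: Iterable[str] = (),
) -> pd.DataFrame:
    """Read a CSV/TSV file with a header row into a typed DataFrame.

    `required` columns must be present; `numeric` columns are coerced to
    float and a non-numeric cell is reported with its (1-based, data) row
    number. Unknown columns are preserved untouched. An empty file is an
    error, not an empty table.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    if path.stat().st_size == 0:
        raise TableError(f"{path}: file is empty")
    df = pd.read_csv(path, sep=_sniff_delimiter(path), dtype=str, skipinitialspace=True)
    if df.empty and len(df.columns) == 0:
        raise TableError(f"{path}: no data rows")
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableError(f"{path}: missing mandatory column(s) {missing}")
    for col in numeric:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise TableError(
                f"{path}: non-numeric value {df[col][bad.idxmax()]!r} in column "
                f"{col!r} at data row {row}"
            )
        df[col] = coerced
    return df


def write_table(df: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    """Write a DataFrame as a headered delimiter-separated file (UTF-8)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False)


def read_config(path: str | Path) -> dict:
    """Load a nested key/value configuration file (YAML)."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise TableError(f"{path}: config must be a mapping at the top level")
    return cfg


# ---------------------------------------------------------------------------
# Water sample physicochemistry
# ---------------------------------------------------------------------------

ION_NAMES = (
    "F", "Cl", "NO2", "SO4", "Br", "NO3", "PO4", "Na", "NH4", "K", "Mg", "Ca",
)


@dataclass
class WaterSample:
    """Physicochemistry of a bloom-affected water sample.

    Chlorophyll a (µg/L) proxies photosynthetic biomass; dry weight (g/L)
    feeds the biomass-stock estimate; the ion block (mg/L) carries the
    dissolved-nutrient bookkeeping, PO4 in particular.
    """

    temperature_c: float | None = None
    ph: float | None = None
    dissolved_oxygen_mg_per_l: float | None = None
    conductivity_us_per_cm: float | None = None
    salinity_psu: float | None = None
    dry_weight_g_per_l: float | None = None
    chlorophyll_a_ug_per_l: float | None = None
    ions_mg_per_l: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ph is not None and not 0.0 <= self.ph <= 14.0:
            raise ValueError(f"pH {self.ph} outside [0, 14]")
        for name, conc in self.ions_mg_per_l.items():
            if conc < 0:
                raise ValueError(f"negative ion concentration: {name} = {conc}")
        for attr in ("dry_weight_g_per_l", "chlorophyll_a_ug_per_l",
                     "dissolved_oxygen_mg_per_l"):
            v = getattr(self, attr)
            if v is not None and v < 0:
                raise ValueError(f"negative {attr}: {v}")


_PARAMETER_MAP = {
    "temperature": "temperature_c",
    "ph": "ph",
    "do": "dissolved_oxygen_mg_per_l",
    "dissolved oxygen": "dissolved_oxygen_mg_per_l",
    "conductivity": "conductivity_us_per_cm",
    "salinity": "salinity_psu",
    "dry weight": "dry_weight_g_per_l",
    "chlorophyll a": "chlorophyll_a_ug_per_l",
}


def read_water_sample(path: str | Path) -> WaterSample:
    """Build a WaterSample from a two-column parameter/value table.

    Rows whose parameter matches a known physicochemical field populate it;
    anything else is treated as an ion (mg/L).
    """
    df = read_table(path, required=("parameter", "value"), numeric=("value",))
    fields: dict = {}
    ions: dict[str, float] = {}
    for _, row in df.iterrows():
        key = str(row["parameter"]).strip()
        attr = _PARAMETER_MAP.get(key.lower())
        if attr is not None:
            fields[attr] = float(row["value"])
        else:
            ions[key] = float(row["value"])
    return WaterSample(ions_mg_per_l=ions, **fields)
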