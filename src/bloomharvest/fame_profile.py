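"""FAME shorthand parsing, saturation classification and yield aggregation.

Fatty acid methyl esters are named with the lipid shorthand Cx:y[n-z], where
x is the carbon chain length, y the number of double bonds and n-z the omega
position of the first double bond; an optional cis/trans token gives the
geometry (e.g. "C18:1 cis" is oleic acid, "C18:3n3" alpha-linolenic acid).
Zero double bonds is a saturated fatty acid (SFA), one is monounsaturated
(MUFA), two or more polyunsaturated (PUFA) — the three resource classes a
harvested biomass is usually summarised by.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "FameRecord",
    "parse_fame",
    "format_fame",
    "classify_saturation",
    "group_yields",
    "filter_true_hits",
]

# Cx:y with optional omega (n3 or n-3) and optional geometry token.
_FAME_RE = re.compile(
    r"^C(?P<carbons>\d+):(?P<bonds>\d+)"
    r"(?:\s*n-?(?P<omega>\d+))?"
    r"(?:\s+(?P<geometry>cis|trans))?$"
)


@dataclass(frozen=True)
class FameRecord:
    name: str
    carbons: int
    double_bonds: int
    omega: int | None = None
    geometry: str = "unspecified"
    yield_mg_per_g: float = 0.0

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise ValueError(f"{self.name}: chain length {self.carbons} < 2")
        if self.double_bonds < 0:
            raise ValueError(f"{self.name}: negative double-bond count")
        if self.omega is not None and self.double_bonds < 1:
            raise ValueError(
                f"{self.name}: omega position given for a saturated species"
            )
        if self.yield_mg_per_g < 0:
            raise ValueError(f"{self.name}: negative yield")


def parse_fame(name: str, yield_mg_per_g: float = 0.0) -> FameRecord:
    """Parse a FAME shorthand name into its structural components.

    >>> parse_fame("C18:3n3").omega
    3
    """
    m = _FAME_RE.match(name.strip())
    if m is None:
        raise ValueError(f"malformed FAME name: {name!r}")
    omega = m.group("omega")
    return FameRecord(
        name=name.strip(),
        carbons=int(m.group("carbons")),
        double_bonds=int(m.group("bonds")),
        omega=int(omega) if omega is not None else None,
        geometry=m.group("geometry") or "unspecified",
        yield_mg_per_g=yield_mg_per_g,
    )


def format_fame(record: FameRecord) -> str:
    """Canonical shorthand for a record; parse(format(r)) round-trips."""
    s = f"C{record.carbons}:{record.double_bonds}"
    if record.omega is not None:
        s += f"n{record.omega}"
    if record.geometry != "unspecified":
        s += f" {record.geometry}"
    return s


def classify_saturation(record: FameRecord) -> str:
    """SFA (0 double bonds), MUFA (1) or PUFA (>= 2)."""
    if record.double_bonds == 0:
        return "SFA"
    if record.double_bonds == 1:
        return "MUFA"
    return "PUFA"


def group_yields(records: list[FameRecord]) -> pd.DataFrame:
    """Aggregate per-species yields into SFA/MUFA/PUFA group totals.

    Returns a frame indexed by group with `yield_mg_per_g` subtotals and a
    `relative_pct` profile over total FAME mass (sums to 100). Duplicate
    species names are ambiguous input and rejected.
    """
    if not records:
        raise ValueError("no FAME records: relative profile undefined")
    names = [r.name for r in records]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate FAME name(s): {dupes}")
    totals = {"SFA": 0.0, "MUFA": 0.0, "PUFA": 0.0}
    for r in records:
        totals[classify_saturation(r)] += r.yield_mg_per_g
    total = sum(totals.values())
    if total == 0.0:
        raise ValueError("total FAME yield is zero: relative profile undefined")
    df = pd.DataFrame(
        {
            "yield_mg_per_g": totals,
            "relative_pct": {g: 100.0 * v / total for g, v in totals.items()},
        }
    )
    df.index.name = "group"
    return df


def filter_true_hits(
    long_table: pd.DataFrame, min_replicates: int = 3
) -> pd.DataFrame:
    """Keep species detected in at least `min_replicates` replicates.

    Input is long format with columns fame_name, yield_mg_per_g,
    replicate_id; output is one row per retained species with the mean yield
    over the replicates it was detected in.
    """
    required = {"fame_name", "yield_mg_per_g", "replicate_id"}
    missing = required - set(long_table.columns)
    if missing:
        raise ValueError(f"missing column(s) for replicate filtering: {sorted(missing)}")
    n_reps = long_table.groupby("fame_name")["replicate_id"].nunique()
    keep = n_reps[n_reps >= min_replicates].index
    out = (
        long_table[long_table["fame_name"].isin(keep)]
        .groupby("fame_name", as_index=False)["yield_mg_per_g"]
        .mean()
    )
    return out
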