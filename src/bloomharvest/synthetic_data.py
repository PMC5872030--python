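"""Seeded generators emulating the measurements the pipeline ingests.

Each generator produces data with the statistical structure its analysis
stage assumes, so the whole chain is testable end-to-end without any lab
measurements:

* dose-response: a saturating Hill curve E(d) = e_max d^h / (ec50^h + d^h)
  with additive Gaussian noise on the percentage scale, clipped to [0, 100];
* flotation: the first-order rise E(t) = e_inf (1 - exp(-k t));
* community: Dirichlet-multinomial counts with a configurable dominant taxon
  (a bloom is one cyanobacterial genus holding most of the reads);
* biomass composition: truncated-normal contents around configured means.

Same seed, same parameters: byte-identical output.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .separation import FlotationSeries

__all__ = [
    "DEFAULT_COMPOSITION_MEANS",
    "hill_curve",
    "simulate_dose_response",
    "simulate_flotation",
    "simulate_community",
    "simulate_composition",
]

#: default per-mass contents (g/g): lipid, phosphate, protein of bloom biomass
DEFAULT_COMPOSITION_MEANS = {
    "lipid_g_per_g": 0.1037,
    "phosphate_g_per_g": 0.00902,
    "protein_g_per_g": 0.32545,
}


def hill_curve(dose, e_max: float, ec50: float, hill_coef: float):
    """Saturating Hill dose-response E(d) = e_max d^h / (ec50^h + d^h)."""
    d = np.asarray(dose, dtype=float)
    return e_max * d**hill_coef / (ec50**hill_coef + d**hill_coef)


def simulate_dose_response(
    e_max: float,
    ec50: float,
    hill_coef: float,
    doses,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Jar-test dose-response table from a Hill curve plus seeded noise.

    Returns columns dose_mg_per_L, efficiency_pct; noiseless output equals
    the Hill curve exactly, noisy output is clipped to [0, 100].
    """
    doses = np.asarray(doses, dtype=float)
    if doses.size == 0:
        raise ValueError("empty dose list")
    if not 0.0 <= e_max <= 100.0:
        raise ValueError(f"e_max {e_max} outside [0, 100]")
    if ec50 <= 0:
        raise ValueError(f"ec50 must be positive, got {ec50}")
    eff = hill_curve(doses, e_max, ec50, hill_coef)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        eff = np.clip(eff + rng.normal(0.0, noise_sd, doses.size), 0.0, 100.0)
    return pd.DataFrame({"dose_mg_per_L": doses, "efficiency_pct": eff})


def simulate_flotation(
    e_inf: float,
    k: float,
    times,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> FlotationSeries:
    """Flotation time series from the first-order model plus seeded noise."""
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("empty time list")
    if e_inf > 0 and k <= 0:
        raise ValueError("non-positive rate with nonzero plateau: series never rises")
    eff = e_inf * (1.0 - np.exp(-k * t)) if e_inf > 0 else np.zeros_like(t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        eff = np.clip(eff + rng.normal(0.0, noise_sd, t.size), 0.0, 100.0)
    return FlotationSeries(time_min=tuple(t), efficiency_pct=tuple(eff))


def simulate_community(
    n_taxa: int,
    dominance: float,
    depth: int,
    n_samples: int = 1,
    seed: int = 0,
    concentration: float = 200.0,
) -> pd.DataFrame:
    """Dirichlet-multinomial OTU table with one dominant taxon.

    `dominance` is the expected read share of the top taxon; the remainder is
    spread evenly over the others. `concentration` scales the Dirichlet
    precision (larger = samples closer to the expected profile). Output is an
    OTU table: one row per taxon, integer sample columns and a trailing
    genus-level taxonomy string.
    """
    if n_taxa < 2:
        raise ValueError(f"need >= 2 taxa, got {n_taxa}")
    if not 1.0 / n_taxa <= dominance < 1.0:
        raise ValueError(
            f"dominance {dominance} outside [1/{n_taxa}, 1) for {n_taxa} taxa"
        )
    if depth < n_taxa:
        raise ValueError(f"depth {depth} < n_taxa {n_taxa}")
    p = np.full(n_taxa, (1.0 - dominance) / (n_taxa - 1))
    p[0] = dominance
    rng = np.random.default_rng(seed)
    counts = np.empty((n_taxa, n_samples), dtype=int)
    for j in range(n_samples):
        theta = rng.dirichlet(concentration * p)
        counts[:, j] = rng.multinomial(depth, theta)
    table = pd.DataFrame(
        counts, columns=[f"sample_{j + 1}" for j in range(n_samples)]
    )
    table.insert(0, "otu_id", [f"OTU_{i + 1:04d}" for i in range(n_taxa)])
    table["taxonomy"] = [
        f"k__Bacteria;p__SimPhylum;c__SimClass;o__SimOrder;"
        f"f__SimFamily;g__Taxon{i + 1:03d}"
        for i in range(n_taxa)
    ]
    return table


def simulate_composition(
    means: dict[str, float] | None = None,
    cv: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate biomass-composition measurements (g/g mass fractions).

    Truncated-normal draws (resampled into [0, 1]) around `means` with
    coefficient of variation `cv`; cv = 0 returns the exact means.
    """
    if means is None:
        means = DEFAULT_COMPOSITION_MEANS
    if cv < 0:
        raise ValueError(f"negative cv: {cv}")
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_replicates):
        row = {}
        for name, mu in means.items():
            if not 0.0 <= mu <= 1.0:
                raise ValueError(f"{name}: mean {mu} is not a mass fraction")
            if cv == 0.0:
                row[name] = mu
            else:
                x = rng.normal(mu, cv * mu)
                while not 0.0 <= x <= 1.0:  # truncate by resampling
                    x = rng.normal(mu, cv * mu)
                row[name] = x
        rows.append(row)
    return pd.DataFrame(rows)
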