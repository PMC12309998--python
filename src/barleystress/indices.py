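"""Drought tolerance / susceptibility indices and tolerance typing.

For a chosen trait (grain yield GY by default) each genotype contributes a
control mean ``Yp`` and a stress mean ``Ys``; the stress mean is the equal-
weight average of the single (Ds) and double (Dd) drought treatment means.
With grand means over genotypes ``Ȳp`` and ``Ȳs``:

    SI  = 1 - Ȳs/Ȳp                 (panel stress intensity)
    DSI = (1 - Ys/Yp) / SI          (1 = panel-average susceptibility)
    STI = (Ys * Yp) / Ȳp**2         (rewards jointly high Yp and Ys)
    YSI = Ys / Yp                   (stress-to-control ratio)
    TOL = Yp - Ys                   (absolute yield gap, trait units)

Classification follows the published thresholds: per-index classes
(DSI < 1 tolerant, DSI > 1 sensitive; STI >= 1 high / 0.5 <= STI < 1
moderate / < 0.5 low) and joint labels — *most_tolerant* when DSI < 0.4,
YSI >= 0.75, STI >= 1 and TOL in the bottom quartile, *most_susceptible*
when DSI > 1.5, YSI < 0.3, STI < 0.2 and TOL in the top quartile.
Boundary values sit with the susceptible side for DSI (strict <) and with
the tolerant side for STI/YSI (>=); the quartile rule for "lowest/highest
TOL" is configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import ConfigError, PhenomicsWarning
from .tables import PhenotypeTable

STRESS_MODES = ("both", "Ds-only", "Dd-only")


def stress_mean(table: PhenotypeTable, trait: str, mode: str = "both") -> pd.Series:
    """Per-genotype stress mean ``Ys``.

    ``mode="both"`` averages the Ds and Dd cell means with equal weight
    regardless of replicate counts (the published convention, justified by
    the lack of a significant difference between the two stress levels);
    single-treatment modes use that treatment's cell mean alone.
    """
    if mode not in STRESS_MODES:
        raise ConfigError(f"stress mode must be one of {STRESS_MODES}")
    means = table.cell_means(trait)
    need = ("Ds", "Dd") if mode == "both" else (mode.split("-")[0],)
    absent = [t for t in need if t not in means.columns or means[t].isna().all()]
    if absent:
        raise ConfigError(
            f"treatment(s) {absent} absent; use a single-treatment stress mode"
        )
    return means[list(need)].mean(axis=1)


def stress_intensity(grand_ys: float, grand_yp: float) -> float:
    """Panel-level fractional loss SI = 1 - Ȳs/Ȳp."""
    if grand_yp <= 0:
        raise ValueError("grand control mean must be > 0")
    return 1.0 - grand_ys / grand_yp


def dsi(yp, ys, si: float):
    """Drought Susceptibility Index (1 = panel-average relative loss)."""
    if si == 0:
        warnings.warn("SI = 0 (no stress detected); DSI undefined",
                      PhenomicsWarning, stacklevel=2)
        return np.full_like(np.asarray(yp, dtype=float), np.nan)
    return (1.0 - np.asarray(ys, dtype=float) / np.asarray(yp, dtype=float)) / si


def sti(yp, ys, grand_yp: float):
    """Stress Tolerance Index (Ys*Yp)/Ȳp²."""
    if grand_yp <= 0:
        raise ValueError("grand control mean must be > 0")
    return np.asarray(ys, dtype=float) * np.asarray(yp, dtype=float) / grand_yp**2


def ysi(yp, ys):
    """Yield Stability Index Ys/Yp."""
    return np.asarray(ys, dtype=float) / np.asarray(yp, dtype=float)


def tol(yp, ys):
    """Tolerance Index Yp - Ys (trait units)."""
    return np.asarray(yp, dtype=float) - np.asarray(ys, dtype=float)


def compute_indices(
    table: PhenotypeTable, trait: str = "GY", mode: str = "both"
) -> pd.DataFrame:
    """One row per genotype: Yp, Ys, SI (panel constant), DSI, STI, YSI, TOL.

    Grand means are unweighted means of the per-genotype means (equal
    genotype weight; identical to pooled means under balance).
    """
    means = table.cell_means(trait)
    if "C" not in means.columns or means["C"].isna().all():
        raise ConfigError("control treatment absent")
    yp = means["C"]
    if (yp <= 0).any():
        bad = list(yp[yp <= 0].index)
        raise ValueError(f"control mean must be > 0 for ratio indices: {bad}")
    ys = stress_mean(table, trait, mode=mode)
    grand_yp = float(yp.mean())
    grand_ys = float(ys.mean())
    si = stress_intensity(grand_ys, grand_yp)
    out = pd.DataFrame(
        {
            "genotype": yp.index,
            "Yp": yp.to_numpy(),
            "Ys": ys.to_numpy(),
            "SI": si,
            "DSI": dsi(yp.to_numpy(), ys.to_numpy(), si),
            "STI": sti(yp.to_numpy(), ys.to_numpy(), grand_yp),
            "YSI": ysi(yp.to_numpy(), ys.to_numpy()),
            "TOL": tol(yp.to_numpy(), ys.to_numpy()),
        }
    ).set_index("genotype")
    out.attrs["trait"] = trait
    out.attrs["mode"] = mode
    out.attrs["grand_Yp"] = grand_yp
    out.attrs["grand_Ys"] = grand_ys
    return out


@dataclass(frozen=True)
class ToleranceThresholds:
    """Published classification cut-offs; the TOL quantile rule is ours
    (the source states only "lowest/highest TOL")."""

    dsi_tolerant: float = 1.0          # DSI < 1 -> tolerant (strict)
    sti_high: float = 1.0              # STI >= 1 -> high
    sti_moderate: float = 0.5          # 0.5 <= STI < 1 -> moderate
    most_tolerant_dsi: float = 0.4     # joint rule: DSI < 0.4
    most_tolerant_ysi: float = 0.75    # YSI >= 0.75
    most_tolerant_sti: float = 1.0     # STI >= 1
    most_susceptible_dsi: float = 1.5  # DSI > 1.5
    most_susceptible_ysi: float = 0.3  # YSI < 0.3
    most_susceptible_sti: float = 0.2  # STI < 0.2
    tol_quantile: float = 0.25         # bottom/top TOL quartile


def classify_tolerance(
    results: pd.DataFrame, thresholds: ToleranceThresholds | None = None
) -> pd.DataFrame:
    """Add per-index class columns and the joint tolerance label.

    Genotypes with any missing index are labeled ``unclassified``.
    """
    th = thresholds or ToleranceThresholds()
    out = results.copy()
    out["dsi_class"] = np.where(out["DSI"] < th.dsi_tolerant, "tolerant", "sensitive")
    out["sti_class"] = np.select(
        [out["STI"] >= th.sti_high, out["STI"] >= th.sti_moderate],
        ["high", "moderate"],
        default="low",
    )
    tol_lo = out["TOL"].quantile(th.tol_quantile)
    tol_hi = out["TOL"].quantile(1 - th.tol_quantile)
    most_tol = (
        (out["DSI"] < th.most_tolerant_dsi)
        & (out["YSI"] >= th.most_tolerant_ysi)
        & (out["STI"] >= th.most_tolerant_sti)
        & (out["TOL"] <= tol_lo)
    )
    most_sus = (
        (out["DSI"] > th.most_susceptible_dsi)
        & (out["YSI"] < th.most_susceptible_ysi)
        & (out["STI"] < th.most_susceptible_sti)
        & (out["TOL"] >= tol_hi)
    )
    out["label"] = np.select(
        [most_tol, most_sus], ["most_tolerant", "most_susceptible"],
        default="intermediate",
    )
    incomplete = out[["DSI", "STI", "YSI", "TOL"]].isna().any(axis=1)
    out.loc[incomplete, "label"] = "unclassified"
    return out


def consensus_rank(results: pd.DataFrame) -> pd.DataFrame:
    """Average of per-index ranks (DSI, TOL ascending; STI, YSI descending).

    Deterministic: the final ordering breaks average-rank ties by genotype
    name.  Rank 1 is the most drought-tolerant across all four indices.
    """
    if len(results) < 2:
        raise ValueError("consensus ranking needs >= 2 genotypes")
    ranks = pd.DataFrame(index=results.index)
    ranks["DSI"] = rankdata(results["DSI"], method="average")
    ranks["TOL"] = rankdata(results["TOL"], method="average")
    ranks["STI"] = rankdata(-results["STI"], method="average")
    ranks["YSI"] = rankdata(-results["YSI"], method="average")
    avg = ranks.mean(axis=1)
    order = sorted(results.index, key=lambda g: (avg[g], g))
    out = results.copy()
    out["mean_rank"] = avg
    out["consensus_rank"] = pd.Series(
        {g: i + 1 for i, g in enumerate(order)}, name="consensus_rank"
    )
    return out.sort_values("consensus_rank")
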