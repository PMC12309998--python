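"""Balanced genotype x treatment random-effects model: variance components,
heritabilities and shrinkage BLUPs of genotype means.

Model
-----
For replicate ``k`` of genotype ``i`` under treatment ``j``::

    y_ijk = mu + tau_j + g_i + (g tau)_ij + e_ijk

with treatment fixed and genotype and interaction random:
``g_i ~ N(0, Vg)``, ``(g tau)_ij ~ N(0, Vge)``, ``e_ijk ~ N(0, Vr)``.
On a balanced design the ANOVA / expected-mean-squares estimators coincide
with REML whenever the estimates are interior::

    Vr  = MS_error
    Vge = (MS_gxt - MS_error) / r
    Vg  = (MS_g - MS_gxt) / (r * t)

Negative solutions are truncated to zero and flagged.  Derived genetic
parameters (``Vph = Vg + Vge + Vr``)::

    h2   = Vg / Vph                       broad-sense, individual plot
    h2mg = Vg / (Vg + Vge/t + Vr/(t*r))   heritability of the genotype mean
    accuracy = sqrt(h2mg)
    CVg = 100*sqrt(Vg)/mu,  CVr = 100*sqrt(Vr)/mu

The BLUP of a genotype's mean is the shrinkage predictor
``mu + h2mg * (ybar_i - mu)`` — for the balanced design this equals the
solution of Henderson's mixed-model equations at the same variance
components.  Its 95% interval uses the prediction-error variance of the
genotype effect, ``PEV = (1 - h2mg) * Vg``, with the error degrees of
freedom of the ANOVA: ``blup_i +/- t(0.975, df_error) * sqrt(PEV)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import BalanceError, PhenomicsWarning
from .profiling import _balanced_array, balanced_two_way_ss
from .tables import PhenotypeTable


@dataclass
class VarianceComponents:
    """Variance components and genetic coefficients for one trait."""

    trait: str
    mu: float
    Vg: float
    Vge: float
    Vr: float
    design: tuple  # (n genotypes, t treatments, r replicates)
    df_error: int
    truncated: list = field(default_factory=list)

    @property
    def Vph(self) -> float:
        return self.Vg + self.Vge + self.Vr

    @property
    def gen_pct(self) -> float:
        return 100.0 * self.Vg / self.Vph if self.Vph > 0 else np.nan

    @property
    def res_pct(self) -> float:
        return 100.0 * self.Vr / self.Vph if self.Vph > 0 else np.nan

    @property
    def h2(self) -> float:
        return self.Vg / self.Vph if self.Vph > 0 else 0.0

    @property
    def h2mg(self) -> float:
        n, t, r = self.design
        denom = self.Vg + self.Vge / t + self.Vr / (t * r)
        return self.Vg / denom if denom > 0 else 0.0

    @property
    def accuracy(self) -> float:
        return float(np.sqrt(self.h2mg))

    @property
    def CVg(self) -> float:
        if self.mu == 0:
            warnings.warn("zero grand mean; CVg undefined", PhenomicsWarning,
                          stacklevel=2)
            return np.nan
        return 100.0 * np.sqrt(self.Vg) / self.mu

    @property
    def CVr(self) -> float:
        if self.mu == 0:
            warnings.warn("zero grand mean; CVr undefined", PhenomicsWarning,
                          stacklevel=2)
            return np.nan
        return 100.0 * np.sqrt(self.Vr) / self.mu

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trait": [self.trait],
                "mu": [self.mu],
                "Vg": [self.Vg],
                "Vge": [self.Vge],
                "Vr": [self.Vr],
                "Vph": [self.Vph],
                "gen_pct": [self.gen_pct],
                "res_pct": [self.res_pct],
                "h2": [self.h2],
                "h2mg": [self.h2mg],
                "accuracy": [self.accuracy],
                "CVg": [self.CVg],
                "CVr": [self.CVr],
            }
        )


class GenotypeBlupModel:
    """Random-effects model of one trait on a balanced phenotype table.

    Statsmodels-style usage::

        model = GenotypeBlupModel(table, trait="GY")
        res = model.fit()
        res.variance_components.h2mg
        res.predictions          # genotype means, BLUPs, 95% intervals
        print(res.summary())
    """

    def __init__(self, table: PhenotypeTable, trait: str = "GY") -> None:
        self.trait = trait
        self.values, self.genotypes, self.treatments, self.n_reps = (
            _balanced_array(table, trait)
        )
        n, t, r = self.values.shape
        if n < 2 or t < 2 or r < 2:
            raise BalanceError(
                "variance-component estimation needs >= 2 genotypes, "
                ">= 2 treatments and >= 2 replicates"
            )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, trait: str = "GY") -> "GenotypeBlupModel":
        """Build from a long-format frame (same columns as PhenotypeTable)."""
        return cls(PhenotypeTable(df), trait=trait)

    def fit(self) -> "BlupResults":
        y = self.values
        n, t, r = y.shape
        res = balanced_two_way_ss(y)
        ss, df = res["ss"], res["df"]
        ms_g = ss["genotype"] / df["genotype"]
        ms_gt = ss["interaction"] / df["interaction"]
        ms_e = ss["residual"] / df["residual"]

        truncated = []
        vr = ms_e
        vge = (ms_gt - ms_e) / r
        if vge < 0:
            truncated.append("Vge")
            vge = 0.0
        vg = (ms_g - ms_gt) / (r * t)
        if vg < 0:
            truncated.append("Vg")
            vg = 0.0
        if truncated:
            warnings.warn(
                f"negative variance estimate(s) truncated to 0: {truncated}",
                PhenomicsWarning, stacklevel=2,
            )
        vc = VarianceComponents(
            trait=self.trait,
            mu=float(y.mean()),
            Vg=float(vg),
            Vge=float(vge),
            Vr=float(vr),
            design=(n, t, r),
            df_error=df["residual"],
            truncated=truncated,
        )
        return BlupResults(self, vc, mean_squares={"genotype": ms_g,
                                                   "interaction": ms_gt,
                                                   "error": ms_e})


class BlupResults:
    """Fit results: variance components, genotype-mean BLUPs, diagnostics."""

    def __init__(self, model: GenotypeBlupModel, vc: VarianceComponents,
                 mean_squares: dict) -> None:
        self.model = model
        self.variance_components = vc
        self.mean_squares = mean_squares
        self.genotype_means = pd.Series(
            model.values.mean(axis=(1, 2)), index=model.genotypes, name="mean"
        )
        self.predictions = self._predict()

    def _predict(self, level: float = 0.95) -> pd.DataFrame:
        vc = self.variance_components
        mu, h2mg = vc.mu, vc.h2mg
        blup = mu + h2mg * (self.genotype_means - mu)
        # prediction-error variance of the genotype effect: (1 - h2mg) * Vg
        pev = max((1.0 - h2mg) * vc.Vg, 0.0)
        tcrit = stats.t.ppf(0.5 + level / 2.0, vc.df_error)
        half = tcrit * np.sqrt(pev)
        out = pd.DataFrame(
            {
                "mean": self.genotype_means,
                "blup": blup,
                "ci_low": blup - half,
                "ci_high": blup + half,
            }
        )
        out["above_mean"] = out["blup"] > mu
        return out.sort_values("blup", ascending=False)

    def random_effects(self) -> pd.DataFrame:
        """Shrunken genotype effects (BLUP - mu) and raw interaction
        deviations, for external Q-Q inspection."""
        vc = self.variance_components
        g_hat = self.predictions["blup"] - vc.mu
        cell = self.model.values.mean(axis=2)
        n, t, _ = self.model.values.shape
        inter = (cell - cell.mean(axis=1, keepdims=True)
                 - cell.mean(axis=0, keepdims=True) + cell.mean())
        ge = pd.DataFrame(inter, index=self.model.genotypes,
                          columns=self.model.treatments)
        return pd.DataFrame({"g_blup": g_hat}).join(
            ge.add_prefix("ge_dev_"), how="left"
        )

    def residuals(self) -> np.ndarray:
        cell = self.model.values.mean(axis=2, keepdims=True)
        return (self.model.values - cell).ravel()

    def summary(self) -> str:
        vc = self.variance_components
        n, t, r = vc.design
        lines = [
            f"Genotype x treatment random-effects model — trait {vc.trait}",
            f"design: {n} genotypes x {t} treatments x {r} replicates "
            f"(df_error={vc.df_error})",
            "-" * 62,
            f"{'grand mean':<22}{vc.mu:>12.4f}",
            f"{'Vg (genotypic)':<22}{vc.Vg:>12.5f}   Gen%  {vc.gen_pct:8.2f}",
            f"{'Vge (interaction)':<22}{vc.Vge:>12.5f}",
            f"{'Vr (residual)':<22}{vc.Vr:>12.5f}   Res%  {vc.res_pct:8.2f}",
            f"{'Vph (phenotypic)':<22}{vc.Vph:>12.5f}",
            f"{'h2 (plot)':<22}{vc.h2:>12.4f}",
            f"{'h2mg (genotype mean)':<22}{vc.h2mg:>12.4f}",
            f"{'accuracy':<22}{vc.accuracy:>12.4f}",
            f"{'CVg %':<22}{vc.CVg:>12.2f}",
            f"{'CVr %':<22}{vc.CVr:>12.2f}",
        ]
        if vc.truncated:
            lines.append(f"note: truncated at zero: {', '.join(vc.truncated)}")
        return "\n".join(lines)


def fit_random_model(table: PhenotypeTable, trait: str = "GY") -> BlupResults:
    """Convenience wrapper: ``GenotypeBlupModel(table, trait).fit()``."""
    return GenotypeBlupModel(table, trait).fit()


def rank_stability(
    results: BlupResults, indices: pd.DataFrame, top_frac: float = 1 / 3
) -> pd.DataFrame:
    """Join BLUP above/below-mean flags with the index consensus ranking.

    Labels: ``high_yield_tolerant`` (above the BLUP mean and consensus rank
    in the best ``top_frac``), ``low_yield_susceptible`` (below the mean and
    rank in the worst ``top_frac``), else ``mixed``.
    """
    if "consensus_rank" not in indices.columns:
        raise ValueError("indices frame lacks consensus ranks; run consensus_rank()")
    preds = results.predictions
    common = preds.index.intersection(indices.index)
    if common.empty:
        raise ValueError("genotype sets of BLUPs and indices are disjoint")
    n = len(indices)
    cut_top = int(np.ceil(top_frac * n))
    cut_bottom = n - cut_top
    out = preds.loc[common, ["mean", "blup", "above_mean"]].join(
        indices.loc[common, ["consensus_rank", "label"]]
    )
    conds = [
        out["above_mean"] & (out["consensus_rank"] <= cut_top),
        ~out["above_mean"] & (out["consensus_rank"] > cut_bottom),
    ]
    out["stability_label"] = np.select(
        conds, ["high_yield_tolerant", "low_yield_susceptible"], default="mixed"
    )
    return out.sort_values("consensus_rank")
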