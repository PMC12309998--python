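"""Synthetic winter-barley drought cohorts with known ground truth.

The generator emulates the statistical structure of the controlled
phytotron study the rest of the package analyses: 28 genotypes (half
two-rowed, half six-rowed) x 3 treatments (control C, single drought Ds at
booting, double drought Dd at first node appearance + booting) x 4
replicates x 14 measured traits, with the 4 computed traits derived from
the simulated components.

Generative model (log-scale variance declaration, the default)::

    y_ijkt = det_ij(t) * exp(g_i + u_ij - (Vg + Vge)/2) + eps,
    eps ~ N(0, Vr * mean^2)            (Vr is a squared CV)

where the deterministic part is

    det_ij(t) = baseline(trait, row_i) * vigor(archetype_i, trait)
                * m(trait, treatment_j, row_i)
                * a(archetype_i, trait)          [stress treatments only]
                * p_i                            [Dd only, priming factor]

``g_i ~ N(0, Vg)`` is a genotype effect shared across traits,
``u_ij ~ N(0, Vge)`` a genotype x treatment interaction, and the lognormal
factor is mean-corrected so that every replicate's expectation equals its
deterministic part exactly.  Values are truncated at zero.  With the
``additive`` declaration the effects enter as ``det + g_i + u_ij + eps``
with ``eps ~ N(0, Vr)`` — the exact model assumed by the balanced
variance-component estimators, used for parameter-recovery experiments.

Archetypes plant three stylised tolerance types: *main_ear_preserver*
(keeps grain number/weight in the main ear and its reproductive tillers —
the tolerant type), *side_ear_compensator* (compensates through the side
ears — moderately tolerant) and *susceptible* (main-ear parameters collapse
towards zero while vegetative biomass increases).  The per-archetype
"vigor" factor multiplies yield traits under every treatment (it cancels
from all change%-of-control statistics) and averages exactly 1 over the
default 6/14/8 mix.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .exceptions import SpecError
from .tables import PhenotypeTable, derive_traits
from .traits import ROW_TYPES, TREATMENTS, GenotypeMeta

ARCHETYPES = ("main_ear_preserver", "side_ear_compensator", "susceptible")
STRESS_TREATMENTS = ("Ds", "Dd")


@dataclass
class VarianceSpec:
    """Variance components with their scale declaration.

    scale="log": Vg/Vge are variances of log-normal genotype and interaction
    effects, Vr the squared coefficient of variation of residual noise.
    scale="additive": all three are plain additive variances.
    """

    scale: str = "log"
    Vg: float = 0.0064   # sd 0.08 on the log scale (~8% genotypic CV)
    Vge: float = 0.0025  # sd 0.05
    Vr: float = 0.0144   # residual CV 12% per replicate (pot mean of 4 plants)

    def __post_init__(self) -> None:
        if self.scale not in ("log", "additive"):
            raise SpecError(f"variance scale must be 'log' or 'additive': {self.scale}")
        if min(self.Vg, self.Vge, self.Vr) < 0:
            raise SpecError("variance components must be >= 0")


@dataclass
class CohortSpec:
    """Full parameterization of a synthetic drought study."""

    n_genotypes: int = 28
    row_type_counts: dict = field(default_factory=lambda: {"2R": 14, "6R": 14})
    n_reps: int = 4
    genotype_names: Optional[list] = None
    archetype_assignment: Optional[list] = None
    #: trait -> {row_type -> control expectation}
    baseline_means: dict = field(default_factory=dict)
    #: trait -> {treatment -> {row_type -> multiplicative effect}}
    treatment_effects: dict = field(default_factory=dict)
    #: archetype -> {trait -> multiplier applied under stress treatments}
    archetype_modifiers: dict = field(default_factory=dict)
    #: archetype -> {trait -> multiplier applied under all treatments}
    archetype_vigor: dict = field(default_factory=dict)
    #: SD of the genotype-specific Dd priming factor (mean 1, clipped at 0.2)
    priming_sd: float = 0.0
    variance: VarianceSpec = field(default_factory=VarianceSpec)
    seed: int = 202507

    def __post_init__(self) -> None:
        if isinstance(self.variance, dict):
            self.variance = VarianceSpec(**self.variance)
        if sum(self.row_type_counts.values()) != self.n_genotypes:
            raise SpecError("row_type_counts must sum to n_genotypes")
        if any(rt not in ROW_TYPES for rt in self.row_type_counts):
            raise SpecError(f"row types must be among {ROW_TYPES}")
        if self.genotype_names is None:
            self.genotype_names = [f"G{i + 1:02d}" for i in range(self.n_genotypes)]
        if len(self.genotype_names) != self.n_genotypes:
            raise SpecError("genotype_names length != n_genotypes")
        if self.archetype_assignment is None:
            self.archetype_assignment = ["side_ear_compensator"] * self.n_genotypes
        if len(self.archetype_assignment) != self.n_genotypes:
            raise SpecError("archetype_assignment length != n_genotypes")
        if any(a not in ARCHETYPES for a in self.archetype_assignment):
            raise SpecError(f"archetypes must be among {ARCHETYPES}")
        if not self.baseline_means:
            raise SpecError("baseline_means must define at least one trait")
        for trait, eff in self.treatment_effects.items():
            for tr, per_row in eff.items():
                if tr not in STRESS_TREATMENTS:
                    raise SpecError(f"treatment effect for non-stress level {tr}")
                if any(m <= 0 for m in per_row.values()):
                    raise SpecError(f"multiplier <= 0 for {trait}/{tr}")

    # -- bookkeeping -------------------------------------------------------

    @property
    def traits(self) -> tuple:
        return tuple(self.baseline_means)

    def row_types(self) -> list:
        """Row type per genotype, interleaved deterministically."""
        seq = []
        counts = dict(self.row_type_counts)
        order = [rt for rt in ROW_TYPES if counts.get(rt, 0) > 0]
        i = 0
        while len(seq) < self.n_genotypes:
            rt = order[i % len(order)]
            if counts.get(rt, 0) > 0:
                seq.append(rt)
                counts[rt] -= 1
            else:
                order = [r for r in order if counts.get(r, 0) > 0]
            i += 1
        return seq

    def _factor(self, table: dict, archetype: str, trait: str, default=1.0) -> float:
        return float(table.get(archetype, {}).get(trait, default))

    def expected_mean(self, idx: int, trait: str, treatment: str) -> float:
        """Deterministic expectation of one cell (priming factor at its mean 1)."""
        rt = self.row_types()[idx]
        arch = self.archetype_assignment[idx]
        det = self.baseline_means[trait][rt]
        det *= self._factor(self.archetype_vigor, arch, trait)
        if treatment in STRESS_TREATMENTS:
            eff = self.treatment_effects.get(trait, {}).get(treatment, {})
            det *= float(eff.get(rt, eff.get("all", 1.0)))
            det *= self._factor(self.archetype_modifiers, arch, trait)
        return det

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class GroundTruth:
    """Realized latent quantities of one simulated cohort."""

    genotypes: list
    archetypes: list
    row_types: list
    g: np.ndarray            # genotype effects, shape (n,)
    u: pd.DataFrame          # interaction effects, index genotypes x columns treatments
    priming: np.ndarray      # Dd priming factors, shape (n,)
    spec_digest: str = ""

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "genotype": self.genotypes,
                "row_type": self.row_types,
                "archetype": self.archetypes,
                "g": self.g,
                "priming": self.priming,
            }
        )
        for t in self.u.columns:
            df[f"u_{t}"] = self.u[t].to_numpy()
        return df


def simulate_cohort(
    spec: CohortSpec, seed: Optional[int] = None
) -> tuple[PhenotypeTable, GroundTruth]:
    """Draw one balanced cohort from ``spec``.

    Identical (spec, seed) pairs give identical tables.  The returned table
    contains every measured trait in ``spec.baseline_means`` plus whichever
    of the computed traits (MTKW, ATKW, ASN, ASW) have all their components
    simulated.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n, r = spec.n_genotypes, spec.n_reps
    vs = spec.variance
    row_types = spec.row_types()

    g = rng.normal(0.0, np.sqrt(vs.Vg), size=n)
    u = rng.normal(0.0, np.sqrt(vs.Vge), size=(n, len(TREATMENTS)))
    priming = (
        np.clip(rng.normal(1.0, spec.priming_sd, size=n), 0.2, None)
        if spec.priming_sd > 0
        else np.ones(n)
    )

    records = []
    for i, geno in enumerate(spec.genotype_names):
        arch = spec.archetype_assignment[i]
        for j, treat in enumerate(TREATMENTS):
            for trait in spec.traits:
                det = spec.expected_mean(i, trait, treat)
                if treat == "Dd":
                    det *= priming[i]
                if vs.scale == "log":
                    mu = det * np.exp(g[i] + u[i, j] - (vs.Vg + vs.Vge) / 2.0)
                    sd = np.sqrt(vs.Vr) * mu
                else:
                    mu = det + g[i] + u[i, j]
                    sd = np.sqrt(vs.Vr)
                vals = mu + (rng.normal(0.0, sd, size=r) if sd > 0 else np.zeros(r))
                vals = np.clip(vals, 0.0, None)
                for k in range(r):
                    records.append((geno, row_types[i], treat, k + 1, trait, vals[k]))

    df = pd.DataFrame(
        records,
        columns=["genotype", "row_type", "treatment", "replicate", "trait", "value"],
    )
    meta = {
        geno: GenotypeMeta(name=geno, row_type=row_types[i])
        for i, geno in enumerate(spec.genotype_names)
    }
    table = PhenotypeTable(df, meta=meta, provenance=f"simulated:{spec.digest()}")

    have = set(spec.traits)
    from .tables import DEFAULT_FORMULAS

    derivable = {
        code: spec_fn
        for code, spec_fn in DEFAULT_FORMULAS.items()
        if code not in have and set(spec_fn[0]) <= have
    }
    if derivable:
        table = derive_traits(table, formulas=derivable)

    truth = GroundTruth(
        genotypes=list(spec.genotype_names),
        archetypes=list(spec.archetype_assignment),
        row_types=row_types,
        g=g,
        u=pd.DataFrame(u, index=spec.genotype_names, columns=list(TREATMENTS)),
        priming=priming,
        spec_digest=spec.digest(),
    )
    return table, truth


# ---------------------------------------------------------------------------
# default study conditions
#
# Anchored group-level quantities (two-rowed control GY 4.7 g dropping to
# 2.45 g under single and 2.2 g under double drought; six-rowed GY reductions
# 47.52% / 44.24%; MSW reductions 53.12% / 54.42%; MSN medians 24 -> 14.13 /
# 14.25 for two-rowed and 40.63 -> 25.13 / 20.5 for six-rowed) enter as
# row-type mean targets.  Because archetype modifiers multiply on top, the
# baked-in treatment multiplier is the target divided by the vigor-weighted
# mixture mean of the archetype modifiers, so the row-type expectation equals
# the target exactly.

_BASELINES = {  # trait -> (2R, 6R) control expectations
    "LIN": (30.0, 26.0),
    "EaL": (9.5, 7.0),
    "SPS": (26.0, 20.0),
    "DENS": (2.74, 2.86),
    "BIOM": (17.0, 19.0),
    "RT": (9.0, 6.0),
    "MSSN": (0.92, 2.03),
    "MEaW": (1.62, 2.12),
    "MSW": (1.25, 1.70),
    "MSN": (24.0, 40.63),
    "SEaW": (4.30, 4.60),
    "SSW": (3.45, 3.70),
    "SSN": (69.0, 92.0),
    "GY": (4.70, 5.40),
}

_TARGET_MULTIPLIERS = {  # trait -> {"Ds": (2R, 6R), "Dd": (2R, 6R)}
    "GY": {"Ds": (2.45 / 4.70, 1 - 0.4752), "Dd": (2.20 / 4.70, 1 - 0.4424)},
    "MSW": {"Ds": (1 - 0.5312, 1 - 0.5312), "Dd": (1 - 0.5442, 1 - 0.5442)},
    "MSN": {"Ds": (14.13 / 24.0, 25.13 / 40.63), "Dd": (14.25 / 24.0, 20.5 / 40.63)},
    "MSSN": {"Ds": (0.67, 0.68), "Dd": (0.66, 0.62)},
    "MEaW": {"Ds": (0.52, 0.52), "Dd": (0.51, 0.50)},
    "SEaW": {"Ds": (0.60, 0.60), "Dd": (0.60, 0.60)},
    "SSW": {"Ds": (0.55, 0.55), "Dd": (0.54, 0.56)},
    "SSN": {"Ds": (0.60, 0.60), "Dd": (0.60, 0.61)},
    "RT": {"Ds": (1.02, 1.02), "Dd": (1.08, 1.08)},
    "BIOM": {"Ds": (0.80, 0.80), "Dd": (0.78, 0.78)},
    "LIN": {"Ds": (0.74, 0.74), "Dd": (0.72, 0.72)},
    "EaL": {"Ds": (0.86, 0.86), "Dd": (0.84, 0.84)},
    "SPS": {"Ds": (0.88, 0.88), "Dd": (0.87, 0.87)},
    "DENS": {"Ds": (1.00, 1.00), "Dd": (1.02, 1.02)},
}

_ARCHETYPE_MODIFIERS = {  # trait -> (preserver, compensator, susceptible)
    "GY": (2.00, 1.00, 0.35),
    "MSW": (1.60, 1.00, 0.10),
    "MSN": (1.45, 1.00, 0.12),
    "MSSN": (1.25, 1.00, 0.35),
    "MEaW": (1.50, 1.00, 0.25),
    "SSW": (1.25, 1.30, 0.45),
    "SSN": (1.20, 1.30, 0.50),
    "SEaW": (1.20, 1.25, 0.55),
    "RT": (1.10, 1.00, 0.85),
    "BIOM": (0.95, 0.82, 1.35),
    "LIN": (1.05, 1.00, 0.92),
    "EaL": (1.04, 1.00, 0.95),
    "SPS": (1.03, 1.00, 0.96),
    "DENS": (1.00, 1.00, 1.00),
}

#: Productivity factor applied under all treatments to yield traits.  Chosen
#: so the 6/14/8 mixture mean is exactly 1: 6*1.18 + 14*1.00 + 8*0.865 = 28.
_VIGOR = {"main_ear_preserver": 1.18, "side_ear_compensator": 1.00,
          "susceptible": 0.865}
#: Vigor is a reproductive-productivity factor; vegetative biomass (BIOM)
#: and the morphological traits are deliberately excluded.
_VIGOR_TRAITS = ("GY", "MSW", "MSN", "MEaW", "SSW", "SSN", "SEaW")

#: Archetype counts of the default panel (per row type: 3 / 7 / 4).
_ARCHETYPE_MIX = {"main_ear_preserver": 6, "side_ear_compensator": 14,
                  "susceptible": 8}


def _default_assignment(row_types: list) -> list:
    """Spread archetypes proportionally within each row type."""
    per_row = {rt: ["main_ear_preserver"] * 3 + ["side_ear_compensator"] * 7
               + ["susceptible"] * 4 for rt in ROW_TYPES}
    out = []
    for rt in row_types:
        out.append(per_row[rt].pop(0))
    return out


def default_study_spec(seed: int = 202507) -> CohortSpec:
    """The study conditions: 28 genotypes, 3 treatments, 4 replicates,
    14 measured traits, archetype mix 6/14/8, row-type means anchored to the
    reported group-level reductions."""
    counts = {"2R": 14, "6R": 14}
    # need row types before assignment; replicate CohortSpec interleaving
    tmp = CohortSpec(baseline_means={"GY": {"2R": 1, "6R": 1}},
                     row_type_counts=counts)
    row_types = tmp.row_types()
    assignment = _default_assignment(row_types)

    vigor = {
        arch: {t: (_VIGOR[arch] if t in _VIGOR_TRAITS else 1.0)
               for t in _BASELINES}
        for arch in ARCHETYPES
    }
    modifiers = {
        arch: {t: _ARCHETYPE_MODIFIERS[t][k] for t in _ARCHETYPE_MODIFIERS}
        for k, arch in enumerate(ARCHETYPES)
    }

    # vigor-weighted mixture mean of archetype modifiers, per trait (the two
    # row types share the same 3/7/4 mix, so one normalizer serves both)
    def mixture_mean(trait: str) -> float:
        num = den = 0.0
        for arch, cnt in _ARCHETYPE_MIX.items():
            w = cnt * vigor[arch][trait]
            num += w * modifiers[arch][trait]
            den += w
        return num / den

    baselines = {t: {"2R": v2, "6R": v6} for t, (v2, v6) in _BASELINES.items()}
    effects = {}
    for trait, per_treat in _TARGET_MULTIPLIERS.items():
        norm = mixture_mean(trait)
        effects[trait] = {
            tr: {"2R": m2 / norm, "6R": m6 / norm}
            for tr, (m2, m6) in per_treat.items()
        }

    return CohortSpec(
        n_genotypes=28,
        row_type_counts=counts,
        n_reps=4,
        archetype_assignment=assignment,
        baseline_means=baselines,
        treatment_effects=effects,
        archetype_modifiers=modifiers,
        archetype_vigor=vigor,
        priming_sd=0.15,
        variance=VarianceSpec(scale="log", Vg=0.0064, Vge=0.0025, Vr=0.0144),
        seed=seed,
    )


def expected_row_type_multiplier(spec: CohortSpec, trait: str, treatment: str,
                                 row_type: str) -> float:
    """Expected (mean stress)/(mean control) over the genotypes of one row
    type — the quantity the published group-level reductions report."""
    idxs = [i for i, rt in enumerate(spec.row_types()) if rt == row_type]
    num = sum(spec.expected_mean(i, trait, treatment) for i in idxs)
    den = sum(spec.expected_mean(i, trait, "C") for i in idxs)
    return num / den
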