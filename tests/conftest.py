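import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import barleystress as bs

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded draw of the 28-genotype study design with ground truth."""
    spec = bs.default_study_spec()
    table, truth = bs.simulate_cohort(spec, seed=1)
    return spec, table, truth


@pytest.fixture(scope="session")
def archetype_series(default_cohort):
    _, _, truth = default_cohort
    return pd.Series(truth.archetypes, index=truth.genotypes)


def make_long_frame(genotypes, treatments, n_reps, traits, value_fn,
                    row_type="2R"):
    """Deterministic long-format frame; value_fn(genotype, treatment,
    replicate, trait) -> value."""
    rows = []
    for g in genotypes:
        for t in treatments:
            for r in range(1, n_reps + 1):
                for tr in traits:
                    rows.append((g, row_type, t, r, tr, value_fn(g, t, r, tr)))
    return pd.DataFrame(
        rows,
        columns=["genotype", "row_type", "treatment", "replicate", "trait", "value"],
    )


@pytest.fixture
def tiny_table():
    """2 genotypes x 3 treatments x 4 reps x 1 trait (24 records)."""
    base = {"C": 4.0, "Ds": 2.0, "Dd": 2.4}
    df = make_long_frame(
        ["A", "B"], ["C", "Ds", "Dd"], 4, ["GY"],
        lambda g, t, r, tr: base[t] + (0.5 if g == "B" else 0.0) + 0.1 * r,
    )
    return bs.PhenotypeTable(df)


@pytest.fixture
def additive_spec():
    """Single-trait additive-scale spec used for variance recovery work."""

    def build(vg=1.0, vge=0.5, vr=0.25, n=28, reps=4, seed=7):
        half = n // 2
        return bs.CohortSpec(
            n_genotypes=n,
            row_type_counts={"2R": half, "6R": n - half},
            n_reps=reps,
            baseline_means={"GY": {"2R": 100.0, "6R": 100.0}},
            treatment_effects={"GY": {"Ds": {"2R": 0.6, "6R": 0.6},
                                      "Dd": {"2R": 0.55, "6R": 0.55}}},
            variance=bs.VarianceSpec(scale="additive", Vg=vg, Vge=vge, Vr=vr),
            seed=seed,
        )

    return build
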