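"""End-to-end analysis driver and report bundle assembly.

``run_full_analysis`` runs the stages in order — ingest or simulate, derive
traits, change% matrices (Ds, Dd), clustering + group profiles, indices +
classification, BLUP, multivariate — and writes a bundle of CSV / Newick /
JSON artifacts.  Deterministic given (input, config, seed); any stage error
propagates with the stage name attached.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .blup import fit_random_model, rank_stability
from .exceptions import ConfigError
from .indices import ToleranceThresholds, classify_tolerance, compute_indices, consensus_rank
from .multivariate import correlation_matrix, correlation_network, genotype_trait_means, pca
from .profiling import (
    change_percent_matrix,
    cluster_axis,
    group_profile,
    group_separation_letters,
)
from .simulate import CohortSpec, default_study_spec, simulate_cohort
from .tables import derive_traits, read_phenotype_table


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``input_path`` / ``simulate`` must be set; a seed is
    mandatory when simulating.
    """

    input_path: Optional[str] = None
    layout: str = "long"
    simulate: bool = False
    spec_path: Optional[str] = None     # YAML CohortSpec; default study spec if None
    trait: str = "GY"
    stress_mode: str = "both"
    k: int = 3
    distance: str = "euclidean"
    linkage: str = "complete"
    alpha: float = 0.05
    network_threshold: float = 0.6
    tol_quantile: float = 0.25
    out_dir: str = "barleystress_report"
    seed: Optional[int] = None

    def validate(self) -> None:
        if bool(self.input_path) == bool(self.simulate):
            raise ConfigError("exactly one of input_path / simulate must be set")
        if self.simulate and self.seed is None:
            raise ConfigError("seed is mandatory when simulating")

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            text = fh.read()
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError:
            data = json.loads(text)
        return cls(**data)


@dataclass
class ReportBundle:
    out_dir: Path
    files: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)

    def path(self, key: str) -> Path:
        return Path(self.files[key])


def _stage(name):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"stage '{name}' failed: {exc}") from exc
            return False

    return _Ctx()


class _StageError(RuntimeError):
    pass


def run_full_analysis(config: RunConfig) -> ReportBundle:
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(out_dir=out_dir)
    collected_warnings: list[str] = []

    def save(key: str, name: str, writer) -> None:
        path = out_dir / name
        writer(path)
        bundle.files[key] = str(path)

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")

        with _stage("ingest"):
            if config.simulate:
                spec = (CohortSpec.from_yaml(config.spec_path)
                        if config.spec_path else default_study_spec())
                table, truth = simulate_cohort(spec, seed=config.seed)
                save("ground_truth", "ground_truth.csv",
                     lambda p: truth.to_frame().to_csv(p, index=False))
                save("cohort_spec", "cohort_spec.yaml", spec.to_yaml)
            else:
                table = read_phenotype_table(config.input_path, layout=config.layout)
                table = derive_traits(table)
            if len(table) == 0:
                raise ConfigError("empty input table")
            save("phenotypes", "phenotypes.csv", table.write)

        with _stage("change_matrices"):
            matrices = {}
            stress_levels = [t for t in ("Ds", "Dd") if t in table.treatments]
            if not stress_levels:
                raise ConfigError("no stress treatment present")
            for tr in stress_levels:
                cm = change_percent_matrix(table, tr)
                matrices[tr] = cm
                save(f"change_{tr}", f"change_percent_{tr}.csv",
                     lambda p, cm=cm: cm.to_csv(p))

        with _stage("clustering"):
            for tr, cm in matrices.items():
                res = cluster_axis(cm, axis="genotypes", k=config.k,
                                   distance=config.distance,
                                   linkage=config.linkage)
                save(f"clusters_{tr}", f"clusters_{tr}.csv",
                     lambda p, r=res: r.labels.rename("group").to_csv(p))
                save(f"dendrogram_{tr}", f"dendrogram_{tr}.nwk",
                     lambda p, r=res: Path(p).write_text(r.to_newick() + "\n"))
                prof = group_profile(cm, res.labels)
                letters = {}
                for trait_code in cm.index:
                    try:
                        letters[trait_code] = group_separation_letters(
                            cm.loc[trait_code], res.labels, alpha=config.alpha
                        )
                    except ValueError:
                        letters[trait_code] = {}
                prof_out = prof.copy()
                prof_out.columns = [f"group_{g}" for g in prof_out.columns]
                for g in prof.columns:
                    prof_out[f"letters_group_{g}"] = [
                        letters[t].get(g, "") for t in prof.index
                    ]
                save(f"profiles_{tr}", f"group_profiles_{tr}.csv",
                     lambda p, d=prof_out: d.to_csv(p))

        with _stage("indices"):
            mode = config.stress_mode
            idx = compute_indices(table, trait=config.trait, mode=mode)
            idx = classify_tolerance(
                idx, ToleranceThresholds(tol_quantile=config.tol_quantile)
            )
            idx = consensus_rank(idx)
            save("indices", "indices.csv", lambda p: idx.to_csv(p))

        with _stage("blup"):
            blup_res = fit_random_model(table, trait=config.trait)
            save("variance_components", "variance_components.csv",
                 lambda p: blup_res.variance_components.to_frame().to_csv(p, index=False))
            save("blups", "blups.csv", lambda p: blup_res.predictions.to_csv(p))
            stab = rank_stability(blup_res, idx)
            save("stability", "stability.csv", lambda p: stab.to_csv(p))

        with _stage("multivariate"):
            for tr in table.treatments:
                means = genotype_trait_means(table, tr)
                corr = correlation_matrix(means)
                save(f"correlations_{tr}", f"correlations_{tr}.csv",
                     lambda p, c=corr: c.r.to_csv(p))
                save(f"correlation_p_{tr}", f"correlation_p_{tr}.csv",
                     lambda p, c=corr: c.p.to_csv(p))
                edges = correlation_network(corr, threshold=config.network_threshold)
                save(f"network_{tr}", f"network_{tr}.csv",
                     lambda p, e=edges: e.to_csv(p, index=False))
                complete = means.dropna(axis=1)
                nz = complete.loc[:, complete.std(ddof=1) > 0]
                if nz.shape[1] < 2:
                    warnings.warn(
                        f"PCA skipped for {tr}: fewer than 2 informative traits",
                        stacklevel=1,
                    )
                    continue
                pc = pca(nz)
                eig = pd.DataFrame({
                    "component": [f"PC{i+1}" for i in range(len(pc.eigenvalues))],
                    "eigenvalue": pc.eigenvalues,
                    "variance_pct": pc.variance_pct,
                    "cumulative_pct": pc.cumulative_pct,
                })
                save(f"pca_{tr}", f"pca_{tr}.csv",
                     lambda p, e=eig: e.to_csv(p, index=False))
                save(f"pca_scores_{tr}", f"pca_scores_{tr}.csv",
                     lambda p, s=pc.scores: s.to_csv(p))

        collected_warnings = [str(w.message) for w in wlist]

    bundle.summary = {
        "package_version": __version__,
        "config": asdict(config),
        "config_hash": config.digest(),
        "n_genotypes": len(table.genotypes),
        "treatments": table.treatments,
        "traits": table.traits,
        "warnings": collected_warnings,
        "files": {k: str(Path(v).name) for k, v in bundle.files.items()},
    }
    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(bundle.summary, indent=2, default=str))
    bundle.files["summary"] = str(summary_path)
    return bundle
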