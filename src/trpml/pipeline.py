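"""Reproducible pipeline runs: one validated config, one manifest.

A run executes (optionally) target scoring, then phenotyping, model
fitting and recommendation, writing every artifact with a content hash so
reruns with the same config are verifiably identical for deterministic
stages. All randomness flows from one root seed through named substreams.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

import trpml
from trpml.encoding import GenotypeOneHotEncoder
from trpml.ensemble import BayesianEnsembleRegressor, cross_validate
from trpml.gsm import DEFAULT_FRACTIONS, DEFAULT_PSEUDO_FLUX, StoichiometricModel, score_targets
from trpml.library import default_catalog
from trpml.phenotyping import outlier_filter_percentile, phenotype_study
from trpml.recommend import recommend
from trpml.synthetic import generate_mock_study


class McmcSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_chains: int = 4
    n_draws: int = 5000
    n_burn: int = 1000


class RunConfig(BaseModel):
    """Validated, hermetic run configuration. Unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    out_dir: str
    seed: int = 7
    synthetic: bool = True
    n_strains: int = 250
    n_reps: int = 3
    cv_noise: float = 0.043
    # paths (required when synthetic=False)
    model_path: str | None = None
    reads_path: str | None = None
    well_map_path: str | None = None
    metadata_path: str | None = None
    # stage parameters
    fractions: list[float] = Field(default_factory=lambda: list(DEFAULT_FRACTIONS))
    pseudo_flux: float = DEFAULT_PSEUDO_FLUX
    od_window: tuple[float, float] = (0.075, 0.150)
    estimator: str = "endpoint"
    outlier_fraction: float = 0.01
    folds: int = 10
    mcmc: McmcSettings = Field(default_factory=McmcSettings)
    n_recommendations: int = 30
    mode: str = "exploit"
    pick: str = "uniform"


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception, manifest: dict):
        self.stage = stage
        self.manifest = manifest
        super().__init__(f"stage {stage!r} failed: {cause}")


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _substream(root: int, name: str) -> int:
    h = hashlib.sha256(f"{root}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; return the run manifest.

    The manifest records per stage the artifacts written (with sha256
    prefixes), wall time, and the documented defaults in effect (estimator,
    pseudo-flux, fold count, fraction grid). A stage failure raises
    :class:`StageError` carrying the partial manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": trpml.__version__,
        "config": json.loads(config.model_dump_json()),
        "config_hash": hashlib.sha256(config.model_dump_json().encode()).hexdigest()[:16],
        "stages": {},
        "warnings": [],
        "decisions": {
            "rate_estimator": config.estimator,
            "pseudo_flux": config.pseudo_flux,
            "cv_folds": config.folds,
            "fraction_grid": config.fractions,
            "outlier_fraction": config.outlier_fraction,
        },
    }

    def record(stage: str, t0: float, artifacts: dict[str, Path], extra: dict | None = None):
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 3),
            "artifacts": {k: {"path": str(p), "sha256": _hash_file(p)} for k, p in artifacts.items()},
            **(extra or {}),
        }

    catalog = default_catalog(pick=config.pick)

    # stage: score-targets (optional, needs a stoichiometric model)
    if config.model_path:
        t0 = time.time()
        try:
            model = StoichiometricModel.from_json(config.model_path)
            scores = score_targets(model, config.fractions, config.pseudo_flux)
            p = out / "gene_scores.csv"
            scores.to_csv(p)
            record("score_targets", t0, {"gene_scores": p}, {"n_genes": len(scores)})
        except Exception as e:  # noqa: BLE001
            raise StageError("score_targets", e, manifest) from e

    # stage: generate / load inputs
    t0 = time.time()
    try:
        if config.synthetic:
            study = generate_mock_study(
                n_strains=config.n_strains,
                n_reps=config.n_reps,
                cv=config.cv_noise,
                seed=_substream(config.seed, "generate"),
                catalog=catalog,
                render=True,
            )
            reads, well_map = study["reads"], study["well_map"]
            metadata = study["training"].genotypes
            p1, p2, p3 = out / "reads.csv", out / "well_map.csv", out / "metadata.csv"
            # plate tables are large; keep the manifest hash on metadata only
            metadata.to_csv(p3, index=False)
            record("generate", t0, {"metadata": p3}, {"n_strains": config.n_strains})
        else:
            for name in ("reads_path", "well_map_path", "metadata_path"):
                if getattr(config, name) is None:
                    raise FileNotFoundError(f"{name} is required when synthetic=False")
            reads = pd.read_csv(config.reads_path)
            well_map = pd.read_csv(config.well_map_path)
            metadata = pd.read_csv(config.metadata_path)
            record("load_inputs", t0, {})
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("generate", e, manifest) from e

    # stage: phenotype
    t0 = time.time()
    try:
        phen = phenotype_study(
            reads, well_map, metadata, od_window=config.od_window, estimator=config.estimator
        )
        p = out / "phenotypes.csv"
        phen.to_csv(p, index=False)
        record("phenotype", t0, {"phenotypes": p}, {"n_strains": len(phen)})
    except Exception as e:  # noqa: BLE001
        raise StageError("phenotype", e, manifest) from e

    # stage: fit
    t0 = time.time()
    try:
        usable = phen[phen["qc_pass"] & (phen["n"] >= 2)]
        joined = usable.merge(metadata, on="strain")
        enc = GenotypeOneHotEncoder(catalog).fit()
        X = enc.transform(joined[list(catalog.genes)])
        y = joined["rate_mean"].to_numpy()
        est = BayesianEnsembleRegressor(
            n_chains=config.mcmc.n_chains,
            n_draws=config.mcmc.n_draws,
            n_burn=config.mcmc.n_burn,
            random_state=_substream(config.seed, "fit"),
        )
        model_fit = est.fit(X, y)
        cvres = cross_validate(est, X, y, k=min(config.folds, len(y)), seed=_substream(config.seed, "cv"))
        p = out / "model_posterior.csv"
        pd.DataFrame(
            model_fit.weight_samples_[:: max(1, len(model_fit.weight_samples_) // 1000)],
            columns=model_fit.learner_names_,
        ).to_csv(p, index=False)
        record(
            "fit",
            t0,
            {"posterior": p},
            {
                "n_training": int(len(y)),
                "test_mae": cvres.mae,
                "acceptance_rate": model_fit.acceptance_rate_,
            },
        )
    except Exception as e:  # noqa: BLE001
        raise StageError("fit", e, manifest) from e

    # stage: recommend
    t0 = time.time()
    try:
        seen = set(joined["key"]) if "key" in joined else set()
        recs = recommend(
            model_fit,
            catalog,
            mode=config.mode,
            n=config.n_recommendations,
            exclude=seen,
            f_best=float(y.max()),
            encoder=enc,
        )
        p = out / "recommendations.csv"
        recs.table.to_csv(p, index=False)
        record("recommend", t0, {"recommendations": p}, {"mode": config.mode})
    except Exception as e:  # noqa: BLE001
        raise StageError("recommend", e, manifest) from e

    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
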