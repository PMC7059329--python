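"""End-to-end pipeline orchestration: curate -> featurize -> filter ->
split -> select -> train -> evaluate -> interpret -> applicability domain
-> fragments.

A :class:`PipelineConfig` carries every stage's parameters (unknown keys
are rejected before any computation); :func:`run_pipeline` executes the
stages in order, writing each stage's artifact plus a manifest of
parameters into the run directory. All randomness flows from the single
config seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation as ev
from .applicability import coverage, fit_ad
from .curation import curate
from .featurization import (FeatureMatrix, binary_fingerprints, compute_features,
                            correlation_filter, near_zero_variance_filter)
from .fragments import fragment_table, misclassification_enrichment, rank_fragments
from .interpretation import permutation_importance
from .io import read_activity_csv, read_smiles_csv, write_json
from .modeling import BCRPInhibitionModel
from .plots import plot_importance, plot_residual_profiles, plot_sa_trace
from .sa_selection import SAConfig, sa_search, select_best_iteration
from .synthetic import SyntheticSpec, gen_compound_library

logger = logging.getLogger("bcrpqsar")

__all__ = ["PipelineConfig", "run_pipeline"]

_DEFAULT_FRAGMENTS = (
    ("c1ccc2ncncc2c1", 0.30, 0.03),   # quinazoline-like inhibitor enrichment
    ("C1COCCN1", 0.03, 0.25),         # morpholine-like non-inhibitor enrichment
    ("c1ccsc1", 0.05, 0.20),          # thiophene-like non-inhibitor enrichment
)


@dataclass
class PipelineConfig:
    """All pipeline parameters; unknown keys are rejected at load time."""

    outdir: str = "run"
    seed: int = 0
    input: str | None = None            # labeled SMILES CSV (id, smiles, label)
    activity_input: str | None = None   # raw activity-record CSV to curate
    n_inhibitors: int = 150             # synthetic library size when no input
    n_noninhibitors: int = 200
    test_fraction: float = 0.2
    nzv_freq_cut: float = 95 / 5
    nzv_unique_cut: float = 10.0
    corr_threshold: float = 0.90
    run_selection: bool = True
    sa_iterations: int = 60
    sa_t0: float = 0.10
    sa_alpha: float = 0.99
    sa_rf_trees: int = 30
    sa_cv_folds: int = 3
    sa_cv_repeats: int = 1
    methods: tuple = ("NB", "kNN_weighted", "RLR", "SVM_RBF", "SGB", "XGBoost", "DNN")
    consensus_members: tuple = ("SVM_RBF", "DNN", "XGBoost")
    hyperparameters: dict = field(default_factory=dict)
    cluster_cv: bool = True
    cluster_threshold: float = 0.7
    ad_variance: float = 0.95
    interpret_models: tuple = ("SVM_RBF", "XGBoost")
    interpret_repeats: int = 10
    fragments_top_n: int = 12

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("methods", "consensus_members", "interpret_models"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage(out: Path, name: str, params: dict):
    write_json({"stage": name, "params": params}, out / f"manifest_{name}.json")
    logger.info("stage %s done", name)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every enabled stage; returns the artifact directory."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    # --- inputs: curate, load, or simulate -------------------------------
    if config.activity_input:
        records = read_activity_csv(config.activity_input)
        dataset, rejects = curate(records)
        dataset = dataset.rename(columns={"compound_id": "id",
                                          "canonical_smiles": "smiles"})
        rejects.to_csv(out / "curation_rejects.csv", index=False)
        dataset.to_csv(out / "curated.csv", index=False)
        library = dataset
        _stage(out, "curate", {"n_kept": len(dataset), "n_rejected": len(rejects)})
    elif config.input:
        library, skipped = read_smiles_csv(config.input)
        if skipped:
            logger.warning("skipped %d malformed records", skipped)
        _stage(out, "load", {"n": len(library), "skipped": skipped})
    else:
        spec = SyntheticSpec(n_inhibitors=config.n_inhibitors,
                             n_noninhibitors=config.n_noninhibitors,
                             planted_fragments=_DEFAULT_FRAGMENTS, seed=seed)
        library, _membership = gen_compound_library(spec)
        library.to_csv(out / "library.csv", index=False)
        _stage(out, "simulate", {"n": len(library)})

    smiles = list(library["smiles"])
    labels = library["label"].to_numpy(dtype=int)
    ids = list(library["id"])

    # --- featurization and pre-filters -----------------------------------
    fm, dropped = compute_features(smiles, ids=ids, labels=labels)
    provenance = {"dropped_compounds": dropped, "removed": {}}
    nzv_kept = near_zero_variance_filter(fm, config.nzv_freq_cut,
                                         config.nzv_unique_cut)
    provenance["removed"]["near_zero_variance"] = sorted(
        set(fm.feature_names) - set(nzv_kept))
    fm = fm.subset_features(nzv_kept)
    corr_kept = correlation_filter(fm, config.corr_threshold)
    provenance["removed"]["correlation"] = sorted(
        set(fm.feature_names) - set(corr_kept))
    fm = fm.subset_features(corr_kept)
    fm.values.to_csv(out / "features.csv")
    write_json(provenance, out / "filter_provenance.json")
    _stage(out, "featurize", {"n_features": len(fm.feature_names)})

    # --- model build: split, normalize, select, train, evaluate ----------
    fingerprints = binary_fingerprints(smiles)
    model = BCRPInhibitionModel(fm, fingerprints=fingerprints)
    results = model.fit(methods=config.methods,
                        hyperparameters=config.hyperparameters,
                        consensus_members=config.consensus_members,
                        test_fraction=config.test_fraction,
                        cluster_cv=config.cluster_cv,
                        cluster_threshold=config.cluster_threshold,
                        seed=seed)

    if config.run_selection:
        from .featurization import fit_normalizer, normalize
        stats = fit_normalizer(fm, results.train_idx)
        train_vals = normalize(fm, stats).values.iloc[results.train_idx]
        sa_cfg = SAConfig(max_iterations=config.sa_iterations, t0=config.sa_t0,
                          alpha=config.sa_alpha, rf_trees=config.sa_rf_trees,
                          cv_folds=config.sa_cv_folds,
                          cv_repeats=config.sa_cv_repeats, seed=seed)
        trace = sa_search(train_vals, results.y_train, sa_cfg)
        best_iter, subset = select_best_iteration(trace, train_vals,
                                                  results.y_train)
        trace.records.to_csv(out / "sa_trace.csv", index=False)
        (out / "selected_features.txt").write_text("\n".join(sorted(subset)) + "\n")
        plot_sa_trace(trace, out / "sa_trace.png")
        _stage(out, "select", {"best_iteration": best_iter,
                               "n_selected": len(subset)})
        # refit on the selected subset
        model = BCRPInhibitionModel(fm.subset_features(subset),
                                    fingerprints=fingerprints)
        results = model.fit(methods=config.methods,
                            hyperparameters=config.hyperparameters,
                            consensus_members=config.consensus_members,
                            test_fraction=config.test_fraction,
                            cluster_cv=config.cluster_cv,
                            cluster_threshold=config.cluster_threshold,
                            seed=seed)

    metrics = pd.concat({"cv": results.metrics_cv(),
                         "test": results.metrics_test(),
                         **({"cluster_cv": results.metrics_cluster_cv()}
                            if config.cluster_cv else {})}, axis=0)
    metrics.to_csv(out / "metrics.csv")
    (out / "summary.txt").write_text(results.summary() + "\n")
    profiles = {m: results.residual_profile(m)
                for m in config.methods if m in results.test_predictions}
    plot_residual_profiles(profiles, out / "residuals.png")
    _stage(out, "evaluate", {"methods": list(config.methods)})

    # --- interpretation ---------------------------------------------------
    test_vals = results.model.features.values.iloc[results.test_idx]
    from .featurization import fit_normalizer as _fit_norm, normalize as _norm
    stats = _fit_norm(results.model.features, results.train_idx)
    test_vals = _norm(results.model.features, stats).values.iloc[results.test_idx]
    for m in config.interpret_models:
        if m not in results.fitted:
            continue
        imp = permutation_importance(results.fitted[m], test_vals,
                                     results.y_test,
                                     n_repeats=config.interpret_repeats,
                                     seed=seed)
        imp.to_csv(out / f"importance_{m}.csv", index=False)
        plot_importance(imp, out / f"importance_{m}.png")
    _stage(out, "interpret", {"models": list(config.interpret_models)})

    # --- applicability domain --------------------------------------------
    train_vals = _norm(results.model.features, stats).values.iloc[results.train_idx]
    ad = fit_ad(train_vals, variance=config.ad_variance)
    rows = []
    for name, vals, y in (("train", train_vals, results.y_train),
                          ("test", test_vals, results.y_test)):
        cov = coverage(ad, vals, y)
        rows.append({"set": name, **cov})
    pd.DataFrame(rows).to_csv(out / "ad_summary.csv", index=False)
    _stage(out, "ad", {"n_components": ad.n_components})

    # --- fragments --------------------------------------------------------
    table = fragment_table(smiles, labels)
    pos, neg = rank_fragments(table, config.fragments_top_n)
    table.to_csv(out / "fragments_all.csv", index=False)
    pos.to_csv(out / "fragments_positive.csv", index=False)
    neg.to_csv(out / "fragments_negative.csv", index=False)
    best_model = config.consensus_members[0] if config.consensus_members else config.methods[0]
    mis_ids = set(results.misclassified(best_model))
    id_to_smiles = dict(zip(ids, smiles))
    train_smiles = [smiles[i] for i in results.train_idx]
    test_ids = [ids[i] for i in results.test_idx]
    test_smiles = [smiles[i] for i in results.test_idx]
    mis_smiles = [id_to_smiles[c] for c in test_ids if c in mis_ids]
    enrich = misclassification_enrichment(train_smiles, test_smiles, mis_smiles)
    enrich.to_csv(out / "misclassified_fragments.csv", index=False)
    _stage(out, "fragments", {"n_fragments": len(table),
                              "n_misclassified": len(mis_smiles)})

    write_json({"config": dataclasses.asdict(config), "digest": config.digest()},
               out / "manifest.json")
    return out
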