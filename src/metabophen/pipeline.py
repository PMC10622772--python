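"""End-to-end orchestration of the discovery pipeline.

Stages (simulate → discover → cluster → panel → associate) communicate
through plain-text artifacts in a run directory with fixed names, each
stamped with a hash of the run configuration so downstream stages refuse
mismatched upstream artifacts unless forced. The whole chain is driven by
a single :class:`RunConfig` (YAML-loadable) and one seed.
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

from . import cluster as clustermod
from . import cohort as cohortmod
from . import panel as panelmod
from . import screen as screenmod
from . import simulate as simmod
from . import stats as statsmod
from .features import compute_features, enumerate_features
from . import defaults

logger = logging.getLogger(__name__)

ARTIFACTS = {
    "participants": "participants.tsv",
    "concentrations": "concentrations.tsv",
    "assay": "assay.yaml",
    "truth": "truth.json",
    "filtered_participants": "filtered_participants.tsv",
    "clipped_concentrations": "clipped_concentrations.tsv",
    "ledger": "exclusion_ledger.tsv",
    "ledger_summary": "exclusion_ledger.json",
    "biomarkers": "biomarkers.tsv",
    "biomarkers_json": "biomarkers.json",
    "profiles": "profiles.tsv",
    "clusters": "clusters.json",
    "cluster_summaries": "cluster_summaries.tsv",
    "fold_changes": "fold_changes.tsv",
    "cluster_groups": "cluster_groups.tsv",
    "primary_clusters": "primary_clusters.tsv",
    "panel": "panel.json",
    "panel_trace": "panel_trace.tsv",
    "associations": "associations.tsv",
}


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "run"
    # input files; ignored when synthetic is not None
    participants: str | None = None
    concentrations: str | None = None
    assay: str | None = None
    # overrides for the synthetic cohort generator (CohortConfig fields)
    synthetic: dict | None = field(default_factory=dict)
    min_sens: float = 0.045
    min_pmp: float = 0.90
    alpha_fdr: float = 0.1
    folds: int = 4
    repeats: int = 50
    n_perm: int = 1000
    k_range: tuple[int, int] = (5, 50)
    n_groups: int = 7
    fold_change_scope: str = "asd_only"
    min_specificity: float = 0.90

    def __post_init__(self) -> None:
        for r in (self.min_sens, self.min_pmp, self.alpha_fdr, self.min_specificity):
            if not 0 <= r <= 1:
                raise ValueError(f"rate {r} outside [0, 1]")
        lo, hi = self.k_range
        if not (2 <= lo <= hi):
            raise ValueError(f"invalid k_range {self.k_range}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        d = yaml.safe_load(Path(path).read_text()) or {}
        if "k_range" in d:
            d["k_range"] = tuple(d["k_range"])
        return cls(**d)

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def screen_params(self) -> screenmod.ScreenParams:
        return screenmod.ScreenParams(
            min_sens=self.min_sens, min_pmp=self.min_pmp, alpha_fdr=self.alpha_fdr,
            folds=self.folds, repeats=self.repeats, n_perm=self.n_perm, seed=self.seed,
        )


def _write_manifest(cfg: RunConfig, stage: str, counts: dict) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {"stage": stage, "seed": cfg.seed, "config_hash": cfg.config_hash(),
               "counts": counts}
    (out / f"manifest_{stage}.json").write_text(json.dumps(payload, indent=1))


def _check_upstream(cfg: RunConfig, stage: str, force: bool) -> None:
    path = Path(cfg.out_dir) / f"manifest_{stage}.json"
    if not path.exists():
        raise FileNotFoundError(
            f"missing upstream artifact manifest {path}; run the {stage!r} stage first"
        )
    manifest = json.loads(path.read_text())
    if manifest["config_hash"] != cfg.config_hash() and not force:
        raise RuntimeError(
            f"upstream stage {stage!r} was produced with a different configuration "
            f"({manifest['config_hash']} != {cfg.config_hash()}); rerun it or use force"
        )


def run_simulate(cfg: RunConfig) -> simmod.SyntheticCohort:
    overrides = dict(cfg.synthetic or {})
    overrides.setdefault("seed", cfg.seed)
    sim_cfg = simmod.CohortConfig.from_dict(overrides)
    cohort = simmod.generate_cohort(sim_cfg)
    simmod.write_cohort(cohort, cfg.out_dir)
    _write_manifest(cfg, "simulate", {
        "n_participants": len(cohort.records),
        "n_asd": int((cohort.records["diagnosis"] == "ASD").sum()),
        "n_typ": int((cohort.records["diagnosis"] == "TYP").sum()),
        "n_metabolites": len(cohort.quant.metabolites),
    })
    return cohort


def _load_cohort(cfg: RunConfig):
    out = Path(cfg.out_dir)
    if cfg.synthetic is not None:
        paths = (out / ARTIFACTS["participants"], out / ARTIFACTS["concentrations"],
                 out / ARTIFACTS["assay"])
    else:
        paths = (cfg.participants, cfg.concentrations, cfg.assay)
    return cohortmod.read_cohort(*paths)


def run_discover(cfg: RunConfig, force: bool = False) -> screenmod.ScreenResult:
    if cfg.synthetic is not None:
        _check_upstream(cfg, "simulate", force)
    records, quant, assay = _load_cohort(cfg)
    n_in = len(records)
    records, quant, ledger = cohortmod.preprocess_cohort(records, quant, assay)

    defs = enumerate_features(quant.metabolites,
                              excluded_ids=tuple(m for m in defaults.LOW_QUANT_METABOLITES
                                                 if m in quant.metabolites))
    fm = compute_features(quant, defs)
    labels = records["diagnosis"].to_numpy()
    strata = screenmod.make_strata(records)
    result = screenmod.screen_all(fm, labels, strata, cfg.screen_params())
    profile = screenmod.build_profiles(result.definitions, fm)

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records.to_csv(out / ARTIFACTS["filtered_participants"], sep="\t")
    quant.to_tsv(out / ARTIFACTS["clipped_concentrations"])
    ledger.to_tsv(out / ARTIFACTS["ledger"])
    ledger.to_json(out / ARTIFACTS["ledger_summary"])
    result.to_tsv(out / ARTIFACTS["biomarkers"])
    result.to_json(out / ARTIFACTS["biomarkers_json"])
    profile.to_tsv(out / ARTIFACTS["profiles"])
    _write_manifest(cfg, "discover", {
        "n_in": n_in, "n_after_filters": len(records),
        "n_excluded": len(ledger.excluded_ids),
        "n_features": len(fm.feature_ids),
        "n_screened": result.metadata["n_features_screened"],
        "n_accepted": result.metadata["n_accepted"],
        "reduced_precision": cfg.repeats < 50 or cfg.n_perm < 1000,
    })
    return result


def _load_discover(cfg: RunConfig):
    out = Path(cfg.out_dir)
    records = pd.read_csv(out / ARTIFACTS["filtered_participants"], sep="\t",
                          index_col="participant_id")
    quant = cohortmod.QuantMatrix(pd.read_csv(
        out / ARTIFACTS["clipped_concentrations"], sep="\t", index_col="participant_id"))
    prof = pd.read_csv(out / ARTIFACTS["profiles"], sep="\t", index_col="participant_id")
    profile = screenmod.BiomarkerProfile(matrix=prof.astype(np.int8))
    return records, quant, profile


def run_cluster(cfg: RunConfig, force: bool = False) -> clustermod.ClusterModel | None:
    _check_upstream(cfg, "discover", force)
    records, quant, profile = _load_discover(cfg)
    out = Path(cfg.out_dir)
    if profile.matrix.shape[1] < 2:
        logger.warning("fewer than 2 accepted biomarkers; skipping clustering")
        _write_manifest(cfg, "cluster", {"n_biomarkers": profile.matrix.shape[1],
                                         "k": 0})
        return None
    labels = records["diagnosis"].to_numpy()
    D = clustermod.jaccard_distance_matrix(profile)
    model = clustermod.cluster_biomarkers(D, k_range=cfg.k_range)
    summaries = clustermod.cluster_summaries(model, profile, labels)
    fct = clustermod.fold_changes(model, quant, labels, profile,
                                  scope=cfg.fold_change_scope)
    n_groups = min(cfg.n_groups, model.k)
    groups = clustermod.group_clusters(fct, n_groups=n_groups)
    primary = clustermod.assign_primary_cluster(profile, model, labels)

    model.to_json(out / ARTIFACTS["clusters"])
    summaries.to_csv(out / ARTIFACTS["cluster_summaries"], sep="\t")
    fct.to_csv(out / ARTIFACTS["fold_changes"], sep="\t")
    groups.to_frame().to_csv(out / ARTIFACTS["cluster_groups"], sep="\t")
    primary.to_csv(out / ARTIFACTS["primary_clusters"], sep="\t",
                   index_label="participant_id")
    _write_manifest(cfg, "cluster", {
        "n_biomarkers": profile.matrix.shape[1], "k": model.k,
        "n_groups": int(groups.nunique()),
        "n_identified": int(profile.identified.sum()),
    })
    return model


def run_panel(cfg: RunConfig, force: bool = False) -> panelmod.PanelModel:
    _check_upstream(cfg, "discover", force)
    records, _, profile = _load_discover(cfg)
    labels = records["diagnosis"].to_numpy()
    model = panelmod.optimize_panel(profile, labels, min_specificity=cfg.min_specificity)
    out = Path(cfg.out_dir)
    model.to_json(out / ARTIFACTS["panel"])
    model.trace.to_csv(out / ARTIFACTS["panel_trace"], sep="\t", index=False)
    _write_manifest(cfg, "panel", {
        "n_members": len(model.biomarkers),
        "sensitivity": model.sensitivity, "specificity": model.specificity,
    })
    return model


def run_associate(cfg: RunConfig, force: bool = False) -> pd.DataFrame:
    _check_upstream(cfg, "discover", force)
    records, _, profile = _load_discover(cfg)
    out = Path(cfg.out_dir)
    primary_path = out / ARTIFACTS["primary_clusters"]
    cluster_count = pd.Series(0, index=records.index, dtype=float)
    if primary_path.exists():
        primary = pd.read_csv(primary_path, sep="\t", index_col="participant_id")
        cluster_count.loc[primary.index] = primary["cluster_count"].astype(float)
    else:
        logger.warning("no clustering artifacts; cluster_count is all zeros")
    data = records.copy()
    data["cluster_count"] = cluster_count
    asd = data[data["diagnosis"] == "ASD"]
    plan = statsmod.default_association_plan(asd)
    results = statsmod.run_association_suite(asd, plan, alpha=cfg.alpha_fdr)
    results.to_csv(out / ARTIFACTS["associations"], sep="\t", index=False)
    _write_manifest(cfg, "associate", {
        "n_tests": len(results),
        "n_significant": int(results["significant"].sum()) if len(results) else 0,
    })
    return results


def run_all(cfg: RunConfig, force: bool = False) -> dict:
    if cfg.synthetic is not None:
        run_simulate(cfg)
    discover = run_discover(cfg, force=force)
    cluster_model = run_cluster(cfg, force=force)
    panel_model = run_panel(cfg, force=force)
    associations = run_associate(cfg, force=force)
    return {"discover": discover, "cluster": cluster_model,
            "panel": panel_model, "associations": associations}
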