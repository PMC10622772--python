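"""Seeded synthetic case-control metabolomics cohorts.

The generator emulates the statistical structure the downstream analysis
assumes: a two-group cohort (cases ≈ 499, controls ≈ 209) with log-normal,
block-correlated plasma metabolite concentrations; a set of planted
low-prevalence, case-enriched *metabolic phenotypes*, each shifting a few
metabolites on the log2 scale in its carriers; hemolysis contamination and
the resulting preanalytical exclusions; random missingness; and behavioral
scores (developmental quotient, autism severity) whose means shift with
the number of phenotypes a participant carries.

Everything is reproducible from a single integer seed, and the generator
returns a ``Truth`` record (carrier membership, pre-censoring values) so
recovery tests can compare discovered biomarkers against the planted
signal.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml

from . import defaults
from .cohort import AssaySpec, QuantMatrix, default_assay_spec


@dataclass(frozen=True)
class PhenotypeSpec:
    """A planted metabolic subpopulation.

    ``affected_metabolites`` maps metabolite id to its log2-scale shift δ in
    carriers. Prevalence is diagnosis-specific; the control-group prevalence
    models contamination and must be below the case prevalence.
    ``overlap_group`` ties membership of several phenotypes to a shared
    latent carrier state, producing positively associated memberships.
    """

    name: str
    affected_metabolites: dict[str, float]
    prevalence_asd: float
    prevalence_typ: float = 0.0
    overlap_group: str | None = None

    def __post_init__(self) -> None:
        if not self.affected_metabolites:
            raise ValueError("phenotype must affect at least one metabolite")
        if not (0 < self.prevalence_asd < 1):
            raise ValueError("prevalence_asd must lie in (0, 1)")
        if not (0 <= self.prevalence_typ < self.prevalence_asd):
            raise ValueError("require 0 <= prevalence_typ < prevalence_asd")


def default_phenotypes() -> list[PhenotypeSpec]:
    """Six planted phenotypes spanning the compound classes of the panel.

    Effect sizes (1.0–1.5 log2 units, i.e. 2–2.8-fold shifts against
    baseline log2 SDs of 0.4–0.6) and prevalences (6–12% of cases, ≤1% of
    controls) are set so each phenotype is detectable as a rare,
    case-enriched threshold biomarker rather than a whole-group mean shift.
    """
    return [
        PhenotypeSpec("lacpyr_up", {"lactate": 1.5, "pyruvate": 1.5},
                      prevalence_asd=0.08, prevalence_typ=0.005,
                      overlap_group="bioenergetics"),
        PhenotypeSpec("carnitine_down", {"carnitine": -1.2},
                      prevalence_asd=0.10, prevalence_typ=0.01),
        PhenotypeSpec("bcaa_down",
                      {"leucine": -1.0, "isoleucine": -1.0, "valine": -1.0},
                      prevalence_asd=0.12, prevalence_typ=0.01),
        PhenotypeSpec("glycine_up", {"glycine": 1.2},
                      prevalence_asd=0.10, prevalence_typ=0.01),
        PhenotypeSpec("purine_up", {"xanthine": 1.3, "hypoxanthine": 1.3},
                      prevalence_asd=0.06, prevalence_typ=0.005),
        PhenotypeSpec("mc_acylcarnitine_up",
                      {"octanoylcarnitine": 1.2, "decanoylcarnitine": 1.2,
                       "hexanoylcarnitine": 1.0},
                      prevalence_asd=0.10, prevalence_typ=0.01,
                      overlap_group="bioenergetics"),
    ]


@dataclass
class ScoreModel:
    """Behavioral-score model.

    Scores are drawn from the diagnosis-specific marginal distributions of
    the study population and, when ``enabled``, shifted linearly by the
    number of planted phenotypes carried: the developmental quotient drops
    ``beta_dq`` points per carried phenotype and the autism severity scores
    rise ``gamma_ados`` points per carried phenotype.

    The default slopes are calibrated so that the *measured* rank
    correlation between the discovered-cluster count and DQ lands near
    −0.13 at the default cohort size: the slope on the true carried count
    must overshoot that magnitude because the discovered cluster count is
    an attenuated proxy for the true count (attenuation ≈ 0.5 under the
    default phenotypes).
    """

    enabled: bool = True
    beta_dq: float = 7.0
    beta_subscale: float = 4.0
    gamma_ados: float = 0.7


@dataclass
class CohortConfig:
    n_asd: int = 499
    n_typ: int = 209
    seed: int = 0
    metabolites: list[str] = field(default_factory=lambda: list(defaults.METABOLITES))
    baseline: dict[str, tuple[float, float]] | None = None  # µM mean, log2 SD
    correlation_blocks: list[tuple[tuple[str, ...], float]] | None = None
    phenotypes: list[PhenotypeSpec] = field(default_factory=default_phenotypes)
    overlap_agreement: float = 0.7
    hemolysis_rates: tuple[float, float] = (0.01, 0.04)  # P(>600), P(300..600)
    hemolysis_purine_shift: float = 1.5  # log2 contamination added to purines
    missing_rate: float = 0.01
    score_model: ScoreModel = field(default_factory=ScoreModel)

    def __post_init__(self) -> None:
        if self.n_asd <= 0 or self.n_typ <= 0:
            raise ValueError("n_asd and n_typ must be positive")
        for r in (*self.hemolysis_rates, self.missing_rate, self.overlap_agreement):
            if not 0 <= r <= 1:
                raise ValueError(f"rate {r} outside [0, 1]")
        if self.baseline is None:
            self.baseline = {m: defaults.BASELINE[m] for m in self.metabolites}
        if self.correlation_blocks is None:
            self.correlation_blocks = [
                (tuple(m for m in block if m in self.metabolites), r)
                for block, r in defaults.CORRELATION_BLOCKS
            ]
        unknown = {m for p in self.phenotypes for m in p.affected_metabolites} - set(self.metabolites)
        if unknown:
            raise ValueError(f"phenotype metabolites not in panel: {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phenotypes"] = [dataclasses.asdict(p) for p in self.phenotypes]
        d["score_model"] = dataclasses.asdict(self.score_model)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "phenotypes" in d:
            d["phenotypes"] = [
                p if isinstance(p, PhenotypeSpec) else PhenotypeSpec(**p)
                for p in d["phenotypes"]
            ]
        if "score_model" in d and not isinstance(d["score_model"], ScoreModel):
            d["score_model"] = ScoreModel(**d["score_model"])
        if "baseline" in d and d["baseline"] is not None:
            d["baseline"] = {k: tuple(v) for k, v in d["baseline"].items()}
        if "correlation_blocks" in d and d["correlation_blocks"] is not None:
            d["correlation_blocks"] = [(tuple(b), float(r)) for b, r in d["correlation_blocks"]]
        if "hemolysis_rates" in d:
            d["hemolysis_rates"] = tuple(d["hemolysis_rates"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def null_config(seed: int = 0, **overrides) -> CohortConfig:
    """Default cohort with no planted phenotypes (the null configuration)."""
    return CohortConfig(seed=seed, phenotypes=[], **overrides)


@dataclass
class Truth:
    """Ground truth of a generated cohort."""

    membership: pd.DataFrame  # participants × phenotypes (bool)
    pre_censor: pd.DataFrame  # concentrations before missingness (µM)
    phenotypes: list[PhenotypeSpec]

    @property
    def carried_count(self) -> pd.Series:
        if self.membership.shape[1] == 0:
            return pd.Series(0, index=self.membership.index)
        return self.membership.sum(axis=1)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "phenotypes": [dataclasses.asdict(p) for p in self.phenotypes],
            "membership": {
                pid: [ph for ph in self.membership.columns if self.membership.loc[pid, ph]]
                for pid in self.membership.index
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


class SyntheticCohort(NamedTuple):
    records: pd.DataFrame
    quant: QuantMatrix
    assay: AssaySpec
    truth: Truth


def _covariance(config: CohortConfig) -> np.ndarray:
    mets = config.metabolites
    sd = np.array([config.baseline[m][1] for m in mets])
    cov = np.diag(sd ** 2)
    idx = {m: i for i, m in enumerate(mets)}
    for block, r in config.correlation_blocks:
        for a in block:
            for b in block:
                if a != b:
                    cov[idx[a], idx[b]] = r * sd[idx[a]] * sd[idx[b]]
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlation blocks yield a non-positive-definite covariance") from exc
    return cov


def _sample_membership(config: CohortConfig, diagnosis: np.ndarray,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Bernoulli membership per phenotype; phenotypes sharing an
    ``overlap_group`` mix a shared latent carrier state (probability
    ``overlap_agreement``) with an independent draw."""
    n = diagnosis.size
    is_case = diagnosis == "ASD"
    groups = {p.overlap_group for p in config.phenotypes if p.overlap_group}
    latent: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for g in sorted(groups):
        members = [p for p in config.phenotypes if p.overlap_group == g]
        p_asd = max(p.prevalence_asd for p in members)
        p_typ = max(p.prevalence_typ for p in members)
        u = rng.random(n)
        latent_carrier = np.where(is_case, u < p_asd, u < p_typ)
        latent[g] = (latent_carrier, np.where(is_case, p_asd, np.maximum(p_typ, 1e-12)))
    member = {}
    for p in config.phenotypes:
        prev = np.where(is_case, p.prevalence_asd, p.prevalence_typ)
        indep = rng.random(n) < prev
        if p.overlap_group:
            carrier, p_group = latent[p.overlap_group]
            nested = carrier & (rng.random(n) < np.minimum(1.0, prev / p_group))
            use_latent = rng.random(n) < config.overlap_agreement
            member[p.name] = np.where(use_latent, nested, indep)
        else:
            member[p.name] = indep
    cols = [p.name for p in config.phenotypes]
    return pd.DataFrame(member, columns=cols) if cols else pd.DataFrame(index=range(n))


_RACES = ["native_american", "asian", "black", "pacific_islander", "not_specified", "white"]
_RACE_P_ASD = np.array([0.010, 0.060, 0.068, 0.002, 0.146, 0.713])
_RACE_P_TYP = np.array([0.000, 0.014, 0.191, 0.000, 0.077, 0.718])

# diagnosis-specific marginal score distributions (mean, SD)
_SCORES = {
    "msel_dq": ((62.7, 17.3), (101.7, 16.3)),
    "msel_el": ((28.1, 10.5), (49.7, 9.5)),
    "msel_rl": ((27.0, 11.4), (50.5, 10.0)),
    "msel_fm": ((28.4, 10.7), (48.8, 10.9)),
    "msel_vr": ((31.4, 13.6), (54.1, 12.9)),
}
_ADOS = {"ados_css": (7.1, 1.8), "ados_sa_css": (6.9, 1.7), "ados_rrb_css": (7.8, 1.7)}

# metadata response rates (ASD, TYP); vision_abnormal is deliberately
# near-constant to exercise the >98%-identical filter downstream
_METADATA = {
    "medication": (0.66, 0.36),
    "preferred_diet": (0.62, 0.19),
    "special_diet": (0.16, 0.09),
    "walk_delayed": (0.12, 0.03),
    "vision_abnormal": (0.01, 0.01),
}


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a complete synthetic cohort; byte-reproducible given the seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_asd + config.n_typ
    ids = [f"ASD-{i + 1:04d}" for i in range(config.n_asd)] + [
        f"TYP-{i + 1:04d}" for i in range(config.n_typ)
    ]
    diagnosis = np.array(["ASD"] * config.n_asd + ["TYP"] * config.n_typ)
    is_case = diagnosis == "ASD"

    membership = _sample_membership(config, diagnosis, rng)
    membership.index = ids
    count = membership.sum(axis=1).to_numpy() if membership.shape[1] else np.zeros(n)

    # concentrations: block-correlated MVN on the log2 scale
    mets = config.metabolites
    mean = np.array([np.log2(config.baseline[m][0]) for m in mets])
    cov = _covariance(config)
    log2c = rng.multivariate_normal(mean, cov, size=n, method="cholesky")
    midx = {m: i for i, m in enumerate(mets)}
    for p in config.phenotypes:
        carriers = membership[p.name].to_numpy()
        for m, delta in p.affected_metabolites.items():
            log2c[carriers, midx[m]] += delta

    # hemolysis: hemoglobin mixture, plus purine contamination above 300 mg/dL
    p600, p300 = config.hemolysis_rates
    u = rng.random(n)
    hgb = rng.uniform(0, 100, size=n)
    mid_band = (u >= p600) & (u < p600 + p300)
    hgb[mid_band] = rng.uniform(300, 600, size=int(mid_band.sum()))
    hgb[u < p600] = rng.uniform(600, 1200, size=int((u < p600).sum()))
    contaminated = hgb > 300
    for m in sorted(defaults.HEMOLYSIS_SENSITIVE & set(mets)):
        log2c[contaminated, midx[m]] += config.hemolysis_purine_shift

    conc = 2.0 ** log2c
    pre_censor = pd.DataFrame(conc.copy(), index=ids, columns=mets)

    # random missingness
    miss = rng.random(conc.shape) < config.missing_rate
    conc[miss] = np.nan

    # demographics and scores
    age = np.where(is_case, rng.normal(35.1, 7.8, n), rng.normal(32.6, 8.7, n))
    age = np.clip(age, 18.0, 48.0)
    sex = np.where(rng.random(n) < np.where(is_case, 0.79, 0.593), "M", "F")
    race_asd = rng.choice(_RACES, size=n, p=_RACE_P_ASD / _RACE_P_ASD.sum())
    race_typ = rng.choice(_RACES, size=n, p=_RACE_P_TYP / _RACE_P_TYP.sum())
    race = np.where(is_case, race_asd, race_typ)
    bmi = np.where(is_case, rng.normal(16.7, 2.1, n), rng.normal(17.0, 2.5, n))
    bmi = np.clip(bmi, 10.0, 30.0)

    sm = config.score_model
    beta = {"msel_dq": sm.beta_dq} if sm.enabled else {}
    records = pd.DataFrame(index=pd.Index(ids, name="participant_id"))
    records["diagnosis"] = diagnosis
    records["age_months"] = np.round(age, 1)
    records["sex"] = sex
    records["race"] = race
    records["bmi"] = np.round(bmi, 1)
    records["hemoglobin_mgdl"] = np.round(hgb, 1)
    for col, ((m_a, s_a), (m_t, s_t)) in _SCORES.items():
        base = np.where(is_case, rng.normal(m_a, s_a, n), rng.normal(m_t, s_t, n))
        if sm.enabled:
            slope = sm.beta_dq if col == "msel_dq" else sm.beta_subscale
            base = base - slope * count
        records[col] = np.round(np.maximum(base, 1.0), 1)
    for col, (m_a, s_a) in _ADOS.items():
        score = rng.normal(m_a, s_a, n)
        if sm.enabled and col != "ados_rrb_css":
            score = score + sm.gamma_ados * count
        score = np.clip(np.round(score), 1, 10)
        records[col] = np.where(is_case, score, np.nan)
    for col, (r_a, r_t) in _METADATA.items():
        yes = rng.random(n) < np.where(is_case, r_a, r_t)
        records[col] = np.where(yes, "yes", "no")

    quant = QuantMatrix(pd.DataFrame(conc, index=ids, columns=mets))
    assay = default_assay_spec(mets)
    truth = Truth(membership=membership, pre_censor=pre_censor,
                  phenotypes=list(config.phenotypes))
    return SyntheticCohort(records=records, quant=quant, assay=assay, truth=truth)


def truth_report(truth: Truth) -> pd.DataFrame:
    """Per-phenotype realized prevalence and realized log2 effect size.

    The realized effect is the carrier-vs-noncarrier difference of mean
    log2 pre-censoring values among cases, averaged over the phenotype's
    affected metabolites.
    """
    rows = []
    is_case = pd.Series(
        [pid.startswith("ASD") for pid in truth.membership.index],
        index=truth.membership.index,
    )
    log2v = np.log2(truth.pre_censor)
    for p in truth.phenotypes:
        carriers = truth.membership[p.name]
        effects = []
        for m in p.affected_metabolites:
            car = log2v.loc[carriers & is_case, m]
            non = log2v.loc[(~carriers) & is_case, m]
            if len(car) and len(non):
                effects.append(car.mean() - non.mean())
        rows.append({
            "phenotype": p.name,
            "n_carriers_asd": int((carriers & is_case).sum()),
            "n_carriers_typ": int((carriers & ~is_case).sum()),
            "realized_prevalence_asd": float((carriers & is_case).mean() / max(is_case.mean(), 1e-12))
            if is_case.any() else 0.0,
            "realized_prevalence_typ": float((carriers & ~is_case).sum() / max((~is_case).sum(), 1)),
            "realized_log2_effect": float(np.mean(effects)) if effects else np.nan,
        })
    if not rows:
        return pd.DataFrame(columns=["phenotype", "n_carriers_asd", "n_carriers_typ",
                                     "realized_prevalence_asd", "realized_prevalence_typ",
                                     "realized_log2_effect"])
    return pd.DataFrame(rows)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write the cohort in the exact formats the reader expects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "participants": outdir / "participants.tsv",
        "concentrations": outdir / "concentrations.tsv",
        "assay": outdir / "assay.yaml",
        "truth": outdir / "truth.json",
    }
    cohort.records.to_csv(paths["participants"], sep="\t")
    cohort.quant.to_tsv(paths["concentrations"])
    cohort.assay.to_file(paths["assay"])
    cohort.truth.to_json(paths["truth"])
    return paths
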