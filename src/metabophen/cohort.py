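"""Cohort input, preanalytical filtering, and quantification-limit handling.

The analysis starts from two delimited-text tables — a participant table
(diagnosis, demographics, plasma free hemoglobin, behavioral scores) and a
participants × metabolites concentration matrix in µM — plus an assay
specification giving each metabolite's lower/upper limit of quantification
(LLOQ/ULOQ). Before any feature is computed the cohort passes through
preanalytical filters:

* samples with plasma free hemoglobin > 600 mg/dL are excluded outright;
* for hemoglobin in (300, 600] mg/dL the purine catabolites released by
  red-cell lysis (xanthine, urate, hypoxanthine) are unreliable and those
  cells are omitted;
* samples whose entire concentration row is missing (failed acquisitions)
  are excluded;
* values below the LLOQ are replaced by 0.9·LLOQ and values above the ULOQ
  by 1.1·ULOQ.

Every exclusion is recorded in an :class:`ExclusionLedger` so the final
cohort size reconciles exactly with the input.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import defaults

logger = logging.getLogger(__name__)

DIAGNOSES = ("ASD", "TYP")

# clip_flags codes
FLAG_NONE = 0
FLAG_LOW_CLIPPED = 1
FLAG_HIGH_CLIPPED = 2
FLAG_OMITTED_HEMOLYSIS = 3

FLAG_NAMES = {
    FLAG_NONE: "none",
    FLAG_LOW_CLIPPED: "low_clipped",
    FLAG_HIGH_CLIPPED: "high_clipped",
    FLAG_OMITTED_HEMOLYSIS: "omitted_hemolysis",
}

RULE_HEMOLYSIS_EXCLUDE = "hemolysis>600"
RULE_HEMOLYSIS_OMIT = "hemolysis_300_600_omit"
RULE_ACQUISITION = "acquisition_failure"


@dataclass(frozen=True)
class ParticipantRecord:
    """One enrolled child.

    ADOS-2 calibrated severity scores are only defined for the ASD group;
    MSEL scores and BMI are optional. ``metadata`` carries categorical
    questionnaire responses (diet, medication, milestones, co-occurring
    conditions).
    """

    participant_id: str
    diagnosis: str
    age_months: float
    sex: str
    race: str = "unknown"
    bmi: float | None = None
    hemoglobin_mgdl: float = 0.0
    ados_css: float | None = None
    ados_sa_css: float | None = None
    ados_rrb_css: float | None = None
    msel_dq: float | None = None
    msel_rl: float | None = None
    msel_el: float | None = None
    msel_fm: float | None = None
    msel_vr: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.diagnosis not in DIAGNOSES:
            raise ValueError(f"diagnosis must be one of {DIAGNOSES}, got {self.diagnosis!r}")
        if not 18 <= self.age_months <= 48:
            raise ValueError(f"age_months must lie in [18, 48], got {self.age_months}")
        if self.diagnosis == "TYP" and any(
            v is not None and not (isinstance(v, float) and np.isnan(v))
            for v in (self.ados_css, self.ados_sa_css, self.ados_rrb_css)
        ):
            raise ValueError("ADOS-2 scores must be absent for TYP participants")


#: columns of the participant table that are not questionnaire metadata
CORE_PARTICIPANT_COLUMNS = [
    "diagnosis", "age_months", "sex", "race", "bmi", "hemoglobin_mgdl",
    "ados_css", "ados_sa_css", "ados_rrb_css",
    "msel_dq", "msel_rl", "msel_el", "msel_fm", "msel_vr",
]


def validate_participants(records: pd.DataFrame) -> None:
    """Check the participant-table invariants; raise ``ValueError`` on breach."""
    required = {"diagnosis", "age_months", "sex"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"participant table missing columns: {sorted(missing)}")
    bad_dx = records.loc[~records["diagnosis"].isin(DIAGNOSES)]
    if len(bad_dx):
        raise ValueError(f"unknown diagnosis values for {list(bad_dx.index[:5])}")
    ages = records["age_months"].astype(float)
    out = records.index[(ages < 18) | (ages > 48)]
    if len(out):
        raise ValueError(f"age_months outside [18, 48] for {list(out[:5])}")
    typ = records["diagnosis"] == "TYP"
    for col in ("ados_css", "ados_sa_css", "ados_rrb_css"):
        if col in records.columns and records.loc[typ, col].notna().any():
            offenders = records.index[typ & records[col].notna()]
            raise ValueError(f"ADOS scores present for TYP participants: {list(offenders[:5])}")


@dataclass
class AssaySpec:
    """Per-metabolite quantification limits (µM) and hemolysis sensitivity."""

    limits: dict[str, tuple[float, float]]
    hemolysis_sensitive: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for mid, (lloq, uloq) in self.limits.items():
            if not (0 < lloq < uloq):
                raise ValueError(f"{mid}: require 0 < lloq < uloq, got ({lloq}, {uloq})")
        unknown = set(self.hemolysis_sensitive) - set(self.limits)
        if unknown:
            raise ValueError(f"hemolysis_sensitive ids not in panel: {sorted(unknown)}")

    @property
    def metabolites(self) -> list[str]:
        return list(self.limits)

    def lloq(self, mid: str) -> float:
        return self.limits[mid][0]

    def uloq(self, mid: str) -> float:
        return self.limits[mid][1]

    @classmethod
    def from_dict(cls, d: dict) -> "AssaySpec":
        limits = {}
        sensitive = set()
        for mid, entry in d.items():
            limits[mid] = (float(entry["lloq"]), float(entry["uloq"]))
            if entry.get("hemolysis_sensitive", False):
                sensitive.add(mid)
        return cls(limits=limits, hemolysis_sensitive=frozenset(sensitive))

    @classmethod
    def from_file(cls, path: str | Path) -> "AssaySpec":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML superset also parses JSON
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return {
            mid: {
                "lloq": float(lloq),
                "uloq": float(uloq),
                "hemolysis_sensitive": mid in self.hemolysis_sensitive,
            }
            for mid, (lloq, uloq) in self.limits.items()
        }

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def default_assay_spec(
    metabolites: list[str] | None = None,
    lloq_quantile: float = 1e-5,
    uloq_quantile: float = 1 - 1e-5,
    low_quant_quantile: float = 0.92,
) -> AssaySpec:
    """Assay limits for the default 54-metabolite panel.

    A validated assay's measurable range covers pathological excursions,
    not just the typical population, so the default limits sit far out in
    each metabolite's baseline log-normal distribution (≈ ±4.3 SD): typical
    samples are essentially never censored and even strongly shifted
    subpopulations are censored only in their extreme tail. The three
    chronically low-abundance metabolites instead get an LLOQ at a high
    quantile, emulating analytes measured below the LLOQ in >90% of
    samples.
    """
    metabolites = list(defaults.METABOLITES) if metabolites is None else metabolites
    limits = {}
    for mid in metabolites:
        mean_um, sd_log2 = defaults.BASELINE[mid]
        mu = np.log2(mean_um)
        if mid in defaults.LOW_QUANT_METABOLITES:
            lo_q = low_quant_quantile
        else:
            lo_q = lloq_quantile
        lloq = 2.0 ** (mu + sps.norm.ppf(lo_q) * sd_log2)
        uloq = 2.0 ** (mu + sps.norm.ppf(uloq_quantile) * sd_log2)
        if uloq <= lloq:  # degenerate when the LLOQ quantile is very high
            uloq = lloq * 4.0
        limits[mid] = (lloq, uloq)
    sensitive = frozenset(defaults.HEMOLYSIS_SENSITIVE) & set(metabolites)
    return AssaySpec(limits=limits, hemolysis_sensitive=sensitive)


@dataclass
class QuantMatrix:
    """Participants × metabolites concentrations (µM) with per-cell flags.

    Missing cells are ``NaN`` in ``values``; ``clip_flags`` uses the integer
    codes ``FLAG_*`` above.
    """

    values: pd.DataFrame
    clip_flags: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.clip_flags is None:
            self.clip_flags = pd.DataFrame(
                np.zeros(self.values.shape, dtype=np.int8),
                index=self.values.index, columns=self.values.columns,
            )
        if not self.clip_flags.index.equals(self.values.index) or not (
            self.clip_flags.columns.equals(self.values.columns)
        ):
            raise ValueError("clip_flags must align with values")

    @property
    def participants(self) -> list[str]:
        return list(self.values.index)

    @property
    def metabolites(self) -> list[str]:
        return list(self.values.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def copy(self) -> "QuantMatrix":
        return QuantMatrix(self.values.copy(), self.clip_flags.copy())

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="participant_id")


@dataclass
class ExclusionLedger:
    """Auditable record of every exclusion decision.

    ``entries`` is an ordered list of ``(participant_id, rule, detail,
    excluded)``; ``excluded`` distinguishes participant-level removal from
    cell-level omissions (hemolysis 300–600 mg/dL), which do not change the
    cohort size.
    """

    entries: list[tuple[str, str, str, bool]] = field(default_factory=list)

    def add(self, participant_id: str, rule: str, detail: str = "", excluded: bool = True) -> None:
        self.entries.append((participant_id, rule, detail, excluded))

    def extend(self, other: "ExclusionLedger") -> None:
        self.entries.extend(other.entries)

    @property
    def excluded_ids(self) -> list[str]:
        seen, out = set(), []
        for pid, _, _, excl in self.entries:
            if excl and pid not in seen:
                seen.add(pid)
                out.append(pid)
        return out

    def summary(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, rule, _, _ in self.entries:
            counts[rule] = counts.get(rule, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries, columns=["participant_id", "rule", "detail", "excluded"]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"summary": self.summary(),
                                          "n_excluded": len(self.excluded_ids)}, indent=2))

    def reconcile(self, n_in: int, n_out: int) -> None:
        """Assert n_in = n_out + n_excluded; raise on mismatch."""
        n_excl = len(self.excluded_ids)
        if n_in != n_out + n_excl:
            raise AssertionError(
                f"ledger does not reconcile: {n_in} in != {n_out} out + {n_excl} excluded"
            )


LONG_COLUMNS = {"participant_id", "metabolite_id", "value"}


def _read_concentrations(path: str | Path) -> pd.DataFrame:
    """Read a concentration table; wide (participants × metabolites) is
    canonical, a long (participant_id, metabolite_id, value) triplet table
    is accepted and pivoted."""
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if set(raw.columns) == LONG_COLUMNS:
        raw = raw.pivot(index="participant_id", columns="metabolite_id", values="value")
        raw.columns.name = None
        wide = raw
    else:
        wide = raw.set_index(raw.columns[0])
        wide.index.name = "participant_id"
    values = pd.DataFrame(index=wide.index)
    for col in wide.columns:
        converted = pd.to_numeric(wide[col], errors="coerce")
        bad = wide[col].notna() & converted.isna()
        if bad.any():
            pid = wide.index[bad][0]
            raise ValueError(
                f"non-numeric concentration at participant {pid!r}, metabolite {col!r}: "
                f"{wide.loc[pid, col]!r}"
            )
        values[col] = converted
    return values


def read_cohort(
    participants_path: str | Path,
    concentrations_path: str | Path,
    assay_spec_path: str | Path | AssaySpec,
) -> tuple[pd.DataFrame, QuantMatrix, AssaySpec]:
    """Read and align the participant table and the concentration matrix.

    Participant ids must match one-to-one across the two files; unknown
    metabolites (absent from the assay spec) are an error. Missing cells are
    preserved as missing.
    """
    records = pd.read_csv(participants_path, sep="\t", index_col="participant_id")
    if records.index.duplicated().any():
        dups = records.index[records.index.duplicated()].unique()
        raise ValueError(f"duplicate participant ids: {list(dups[:5])}")
    validate_participants(records)

    values = _read_concentrations(concentrations_path)
    assay = assay_spec_path if isinstance(assay_spec_path, AssaySpec) else AssaySpec.from_file(assay_spec_path)

    unknown = [m for m in values.columns if m not in assay.limits]
    if unknown:
        raise ValueError(f"metabolites not in assay spec: {unknown}")

    only_conc = values.index.difference(records.index)
    only_meta = records.index.difference(values.index)
    if len(only_conc) or len(only_meta):
        raise ValueError(
            "participant id mismatch between files; "
            f"in concentrations only: {list(only_conc[:10])}, "
            f"in participants only: {list(only_meta[:10])}"
        )
    values = values.loc[records.index]
    return records, QuantMatrix(values), assay


def drop_failed_acquisitions(
    records: pd.DataFrame, quant: QuantMatrix, ledger: ExclusionLedger | None = None
) -> tuple[pd.DataFrame, QuantMatrix, ExclusionLedger]:
    """Exclude participants whose entire concentration row is missing."""
    ledger = ledger if ledger is not None else ExclusionLedger()
    all_missing = quant.values.isna().all(axis=1)
    failed = list(quant.values.index[all_missing])
    for pid in failed:
        ledger.add(pid, RULE_ACQUISITION, "all metabolite measurements missing")
    keep = ~all_missing
    return (
        records.loc[keep[keep].index],
        QuantMatrix(quant.values.loc[keep], quant.clip_flags.loc[keep]),
        ledger,
    )


def apply_hemolysis_filter(
    records: pd.DataFrame,
    quant: QuantMatrix,
    assay: AssaySpec,
    ledger: ExclusionLedger | None = None,
    exclude_above: float = 600.0,
    omit_above: float = 300.0,
) -> tuple[pd.DataFrame, QuantMatrix, ExclusionLedger]:
    """Apply the two-tier hemolysis rule.

    Hemoglobin > ``exclude_above`` mg/dL removes the participant entirely;
    hemoglobin in (``omit_above``, ``exclude_above``] blanks the
    hemolysis-sensitive metabolites only. A missing hemoglobin value is
    treated as non-hemolyzed (0) and logged.
    """
    ledger = ledger if ledger is not None else ExclusionLedger()
    if "hemoglobin_mgdl" not in records.columns:
        raise ValueError("participant table lacks hemoglobin_mgdl")
    hgb = records["hemoglobin_mgdl"].astype(float)
    n_missing = int(hgb.isna().sum())
    if n_missing:
        logger.warning("hemoglobin missing for %d participants; treated as 0", n_missing)
        hgb = hgb.fillna(0.0)

    values = quant.values.copy()
    flags = quant.clip_flags.copy()

    excluded = hgb.index[hgb > exclude_above]
    for pid in excluded:
        ledger.add(pid, RULE_HEMOLYSIS_EXCLUDE, f"hemoglobin={hgb[pid]:g} mg/dL")

    partial = hgb.index[(hgb > omit_above) & (hgb <= exclude_above)]
    sensitive = [m for m in values.columns if m in assay.hemolysis_sensitive]
    for pid in partial:
        ledger.add(
            pid, RULE_HEMOLYSIS_OMIT,
            f"hemoglobin={hgb[pid]:g} mg/dL; omitted {sensitive}", excluded=False,
        )
    if len(partial) and sensitive:
        values.loc[partial, sensitive] = np.nan
        flags.loc[partial, sensitive] = FLAG_OMITTED_HEMOLYSIS

    keep = values.index.difference(excluded)
    keep = values.index[values.index.isin(keep)]  # preserve order
    return records.loc[keep], QuantMatrix(values.loc[keep], flags.loc[keep]), ledger


def clip_to_quant_limits(quant: QuantMatrix, assay: AssaySpec) -> QuantMatrix:
    """Replace out-of-range values by 0.9·LLOQ / 1.1·ULOQ.

    Strict inequalities: a value exactly equal to a limit is kept. The
    operation is idempotent (0.9·LLOQ and 1.1·ULOQ are inside the open
    interval's replacement range and are never re-clipped).
    """
    values = quant.values.copy()
    flags = quant.clip_flags.copy()
    for mid in values.columns:
        if mid not in assay.limits:
            raise ValueError(f"no assay limits for metabolite {mid!r}")
        col = values[mid]
        if (col < 0).any():
            pid = col.index[col < 0][0]
            raise ValueError(f"negative concentration for participant {pid!r}, metabolite {mid!r}")
        lloq, uloq = assay.limits[mid]
        low = col.notna() & (col < lloq)
        high = col.notna() & (col > uloq)
        values.loc[low, mid] = 0.9 * lloq
        values.loc[high, mid] = 1.1 * uloq
        flags.loc[low, mid] = FLAG_LOW_CLIPPED
        flags.loc[high, mid] = FLAG_HIGH_CLIPPED
    return QuantMatrix(values, flags)


def preprocess_cohort(
    records: pd.DataFrame, quant: QuantMatrix, assay: AssaySpec
) -> tuple[pd.DataFrame, QuantMatrix, ExclusionLedger]:
    """Full preanalytical chain: acquisition filter, hemolysis rules,
    quantification-limit clipping, with a reconciled ledger."""
    n_in = len(records)
    ledger = ExclusionLedger()
    records, quant, ledger = drop_failed_acquisitions(records, quant, ledger)
    records, quant, ledger = apply_hemolysis_filter(records, quant, assay, ledger)
    quant = clip_to_quant_limits(quant, assay)
    ledger.reconcile(n_in, len(records))
    return records, quant, ledger
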