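"""Threshold-biomarker screening.

For each feature the engine looks for a decision threshold that carves out
a small, strongly case-enriched subpopulation: among candidate thresholds
(midpoints between consecutive distinct sorted values, plus a −∞ sentinel)
it maximizes the proportion of cases among threshold-exceeders (PMP, the
positive predictive value at study prevalence) subject to a minimum
sensitivity floor (default 4.5% of cases above the threshold). A feature
becomes an accepted biomarker when

* its mean test-set sensitivity over repeated stratified cross-validation
  (4 folds × 50 repeats, stratified by diagnosis × sex × age tercile) is at
  least the floor,
* its mean test-set PMP is at least 0.90, and
* a label-permutation test of the constrained-PMP objective survives
  Benjamini–Hochberg FDR control at 0.1 across all screened features.

Final thresholds are then refit on the full cohort. All statistics are
rank-based, so they are invariant to the monotone log2/standardization
transforms applied upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .features import FeatureDefinition, FeatureMatrix

logger = logging.getLogger(__name__)

CASE_LABEL = "ASD"


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of constrained threshold selection on one oriented feature."""

    threshold: float
    sensitivity: float
    pmp: float
    n_positive: int
    feasible: bool = True


def _scan(v: np.ndarray, y: np.ndarray, min_sens: float) -> ThresholdResult:
    """Exact constrained scan over all candidate cuts of an oriented,
    NaN-free feature. ``y`` is the boolean case indicator.

    Candidates are cuts after each run of tied values in descending order;
    the cut after the last position is the −∞ sentinel (everyone positive).
    Objective: maximize PMP subject to sensitivity ≥ ``min_sens``; ties
    break to higher sensitivity, then larger threshold.
    """
    n = v.size
    n_case = int(y.sum())
    if n_case == 0 or n_case == n:
        raise ValueError("need at least one case and one control")
    order = np.argsort(-v, kind="stable")
    vs = v[order]
    cum = np.cumsum(y[order].astype(np.int64))
    j = np.arange(1, n + 1)
    valid = np.empty(n, dtype=bool)
    valid[:-1] = vs[:-1] > vs[1:]
    valid[-1] = True
    sens = cum / n_case
    pmp = cum / j
    feasible_mask = valid & (sens >= min_sens - 1e-12)
    feasible = bool(feasible_mask.any())
    cand = np.flatnonzero(feasible_mask) if feasible else np.flatnonzero(valid)
    if feasible:
        best = cand[pmp[cand] == pmp[cand].max()]
        best = best[sens[best] == sens[best].max()]
    else:  # no cut meets the floor: report the max-sensitivity candidate
        best = cand[sens[cand] == sens[cand].max()]
        best = best[pmp[best] == pmp[best].max()]
    i = int(best.min())  # smallest positive count → largest threshold
    thr = -np.inf if i == n - 1 else 0.5 * (vs[i] + vs[i + 1])
    return ThresholdResult(
        threshold=float(thr), sensitivity=float(sens[i]), pmp=float(pmp[i]),
        n_positive=int(i + 1), feasible=feasible,
    )


def select_threshold(values, labels, min_sens: float = 0.045) -> ThresholdResult:
    """Constrained-PMP threshold for one feature, oriented so that
    positive = above. Missing values are dropped pairwise."""
    v = np.asarray(values, dtype=float)
    y = _case_indicator(labels)
    ok = ~np.isnan(v)
    if not ok.any():
        raise ValueError("all values missing")
    return _scan(v[ok], y[ok], min_sens)


def _case_indicator(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype == bool:
        return arr
    return arr == CASE_LABEL


def make_strata(records: pd.DataFrame, n_age_bins: int = 3) -> pd.Series:
    """Diagnosis × sex × (diagnosis-specific age tercile) stratum labels."""
    strata = pd.Series("", index=records.index, dtype=object)
    for dx, grp in records.groupby("diagnosis"):
        bins = pd.qcut(grp["age_months"].astype(float).rank(method="first"),
                       n_age_bins, labels=False, duplicates="drop")
        strata.loc[grp.index] = [
            f"{dx}|{s}|a{b}" for s, b in zip(grp["sex"], bins)
        ]
    return strata


def _merge_small_strata(strata: np.ndarray, min_size: int) -> np.ndarray:
    """Iteratively coarsen '|'-separated stratum labels until every
    stratum holds at least ``min_size`` members."""
    strata = strata.astype(object).copy()
    while True:
        labels, counts = np.unique(strata, return_counts=True)
        small = [l for l, c in zip(labels, counts) if c < min_size]
        if not small:
            return strata
        progressed = False
        for l in small:
            parts = str(l).split("|")
            if len(parts) > 1:
                merged = "|".join(parts[:-1])
                logger.info("merging small stratum %r into %r", l, merged)
                strata[strata == l] = merged
                progressed = True
        if not progressed:
            # cannot coarsen further: collapse everything
            strata[:] = "all"
            return strata


def repeated_stratified_folds(
    strata, n_folds: int, repeats: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """(train_idx, test_idx) pairs for ``repeats`` independent stratified
    n-fold partitions; deterministic given the seed."""
    from sklearn.model_selection import StratifiedKFold

    strata = _merge_small_strata(np.asarray(strata, dtype=object), n_folds)
    codes = pd.factorize(strata)[0]
    dummy = np.zeros(len(codes))
    out = []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=(seed + r) % (2**32))
        for train_idx, test_idx in skf.split(dummy.reshape(-1, 1), codes):
            out.append((train_idx, test_idx))
    return out


def _cv_feature(v: np.ndarray, y: np.ndarray,
                folds: list[tuple[np.ndarray, np.ndarray]],
                min_sens: float) -> tuple[float, float]:
    """Mean held-out sensitivity and PMP over precomputed folds.

    Test folds with zero threshold-exceeders contribute sensitivity 0 but
    are dropped from the PMP mean (a 0/0 is not fabricated).
    """
    sens_acc: list[float] = []
    pmp_acc: list[float] = []
    for tr, te in folds:
        vt, yt = v[tr], y[tr]
        ok = ~np.isnan(vt)
        vt, yt = vt[ok], yt[ok]
        if yt.sum() == 0 or yt.sum() == yt.size:
            continue
        res = _scan(vt, yt, min_sens)
        ve, ye = v[te], y[te]
        ok = ~np.isnan(ve)
        ve, ye = ve[ok], ye[ok]
        n_case = ye.sum()
        if n_case == 0:
            continue
        pos = ve > res.threshold
        sens_acc.append(float((pos & ye).sum() / n_case))
        if pos.any():
            pmp_acc.append(float(ye[pos].mean()))
    cv_sens = float(np.mean(sens_acc)) if sens_acc else 0.0
    cv_pmp = float(np.mean(pmp_acc)) if pmp_acc else 0.0
    return cv_sens, cv_pmp


def crossvalidate_feature(
    values, labels, strata, folds: int = 4, repeats: int = 50,
    min_sens: float = 0.045, seed: int = 0,
) -> tuple[float, float]:
    """Repeated stratified n-fold CV of the constrained-threshold rule for
    one oriented feature; returns (mean test sensitivity, mean test PMP)."""
    v = np.asarray(values, dtype=float)
    y = _case_indicator(labels)
    fold_pairs = repeated_stratified_folds(strata, folds, repeats, seed)
    return _cv_feature(v, y, fold_pairs, min_sens)


def _perm_stats(v: np.ndarray, perms: np.ndarray, n_case: int, min_sens: float) -> np.ndarray:
    """Constrained-PMP objective for every permuted label row (vectorized)."""
    n = v.size
    order = np.argsort(-v, kind="stable")
    vs = v[order]
    valid = np.empty(n, dtype=bool)
    valid[:-1] = vs[:-1] > vs[1:]
    valid[-1] = True
    P = perms[:, order]
    cum = np.cumsum(P, axis=1, dtype=np.float64)
    j = np.arange(1, n + 1, dtype=np.float64)
    feas = valid[None, :] & (cum >= min_sens * n_case - 1e-9)
    ratio = np.where(feas, cum / j, 0.0)
    return ratio.max(axis=1)


def permutation_test(values, labels, min_sens: float = 0.045,
                     n_perm: int = 1000, seed: int = 0) -> float:
    """Permutation p-value of the constrained-PMP objective for one
    oriented feature: p = (1 + #{perm ≥ obs}) / (n_perm + 1)."""
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    v = np.asarray(values, dtype=float)
    y = _case_indicator(labels)
    ok = ~np.isnan(v)
    v, y = v[ok], y[ok]
    res = _scan(v, y, min_sens)
    obs = res.pmp if res.feasible else 0.0
    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm, v.size), dtype=np.int8)
    for b in range(n_perm):
        perms[b] = rng.permutation(y.astype(np.int8))
    stats = _perm_stats(v, perms, int(y.sum()), min_sens)
    return float((1 + int((stats >= obs - 1e-12).sum())) / (n_perm + 1))


def adjust_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ScreenParams:
    min_sens: float = 0.045
    min_pmp: float = 0.90
    alpha_fdr: float = 0.1
    folds: int = 4
    repeats: int = 50
    n_perm: int = 1000
    seed: int = 0
    include_flagged_singles: bool = False


@dataclass
class BiomarkerDefinition:
    """A screened feature with its CV performance and final threshold.

    ``threshold`` is on the standardized oriented feature scale;
    ``threshold_raw`` is the corresponding cutoff on the raw
    concentration(-ratio) scale (positives lie above it for ``up``
    orientation, below it for ``down``).
    """

    feature: FeatureDefinition
    threshold: float
    threshold_raw: float
    sensitivity: float
    pmp: float
    cv_sensitivity: float
    cv_pmp: float
    perm_p: float
    adj_p: float = np.nan
    accepted: bool = False

    @property
    def feature_id(self) -> str:
        return self.feature.feature_id

    @property
    def display_name(self) -> str:
        return self.feature.display_name


@dataclass
class ScreenResult:
    definitions: list[BiomarkerDefinition]
    params: ScreenParams
    metadata: dict = field(default_factory=dict)

    @property
    def accepted(self) -> list[BiomarkerDefinition]:
        return [d for d in self.definitions if d.accepted]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for d in self.definitions:
            rows.append({
                "feature_id": d.feature_id,
                "display_name": d.display_name,
                "kind": d.feature.kind,
                "numerator": d.feature.numerator,
                "denominator": d.feature.denominator or "",
                "orientation": d.feature.orientation,
                "threshold": d.threshold,
                "threshold_raw": d.threshold_raw,
                "sensitivity": d.sensitivity,
                "pmp": d.pmp,
                "cv_sensitivity": d.cv_sensitivity,
                "cv_pmp": d.cv_pmp,
                "perm_p": d.perm_p,
                "adj_p": d.adj_p,
                "accepted": d.accepted,
            })
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json(self, path) -> None:
        import json

        payload = {
            "params": {k: getattr(self.params, k) for k in vars(self.params)},
            "metadata": self.metadata,
            "biomarkers": self.to_frame().to_dict(orient="records"),
        }
        from pathlib import Path

        Path(path).write_text(json.dumps(payload, indent=1))


def screen_all(
    fm: FeatureMatrix,
    labels,
    strata,
    params: ScreenParams | None = None,
) -> ScreenResult:
    """Screen every feature in both orientations and apply the full
    acceptance rule (CV sensitivity and PMP floors, permutation FDR).

    The better-objective orientation on the full cohort is each feature's
    candidate; permutation p-values are computed over all candidates and
    BH-adjusted across the full candidate set; final thresholds are refit
    on the entire cohort. Missing values are median-imputed internally for
    the rank scans (the imputation is shared by observed and permuted
    labels and so cannot create enrichment).
    """
    params = params or ScreenParams()
    defs = [d for d in fm.definitions if params.include_flagged_singles or not d.flagged]
    X = fm.values[[d.feature_id for d in defs]].to_numpy(dtype=float)
    y = _case_indicator(labels)
    n, n_feat = X.shape
    n_case = int(y.sum())
    if n_case == 0 or n_case == n:
        raise ValueError("need both cases and controls")

    n_nan = int(np.isnan(X).sum())
    if n_nan:
        logger.info("median-imputing %d missing feature cells for screening", n_nan)
        med = np.nanmedian(X, axis=0)
        idx = np.where(np.isnan(X))
        X[idx] = med[idx[1]]

    fold_pairs = repeated_stratified_folds(strata, params.folds, params.repeats, params.seed)
    rng = np.random.default_rng((params.seed + 1) % (2**31))
    perms = np.empty((params.n_perm, n), dtype=np.int8)
    y8 = y.astype(np.int8)
    for b in range(params.n_perm):
        perms[b] = rng.permutation(y8)

    definitions: list[BiomarkerDefinition] = []
    perm_ps = np.empty(n_feat)
    for k, d in enumerate(defs):
        v = X[:, k]
        up = _scan(v, y, params.min_sens)
        down = _scan(-v, y, params.min_sens)
        if (down.feasible, down.pmp, down.sensitivity) > (up.feasible, up.pmp, up.sensitivity):
            orientation, scan_res, vv = "down", down, -v
        else:
            orientation, scan_res, vv = "up", up, v
        cv_sens, cv_pmp = _cv_feature(vv, y, fold_pairs, params.min_sens)
        obs = scan_res.pmp if scan_res.feasible else 0.0
        stats = _perm_stats(vv, perms, n_case, params.min_sens)
        perm_p = float((1 + int((stats >= obs - 1e-12).sum())) / (params.n_perm + 1))
        perm_ps[k] = perm_p
        feature = d.with_orientation(orientation)
        definitions.append(BiomarkerDefinition(
            feature=feature,
            threshold=scan_res.threshold,
            threshold_raw=fm.threshold_to_raw(d.feature_id, scan_res.threshold, orientation),
            sensitivity=scan_res.sensitivity,
            pmp=scan_res.pmp,
            cv_sensitivity=cv_sens,
            cv_pmp=cv_pmp,
            perm_p=perm_p,
        ))

    adj = adjust_fdr(perm_ps)
    for d, a in zip(definitions, adj):
        d.adj_p = float(a)
        d.accepted = (
            d.cv_sensitivity >= params.min_sens
            and d.cv_pmp >= params.min_pmp
            and d.adj_p < params.alpha_fdr
        )
    meta = {
        "n_features_screened": n_feat,
        "n_accepted": sum(d.accepted for d in definitions),
        "permutation_statistic": "full-data constrained-PMP objective",
        "n_perm": params.n_perm,
        "repeats": params.repeats,
    }
    return ScreenResult(definitions=definitions, params=params, metadata=meta)


@dataclass
class BiomarkerProfile:
    """Participants × accepted-biomarkers binary outcome matrix."""

    matrix: pd.DataFrame  # int8 0/1
    definitions: list[BiomarkerDefinition] = field(default_factory=list)

    @property
    def positive_counts(self) -> pd.Series:
        return self.matrix.sum(axis=1)

    @property
    def identified(self) -> pd.Series:
        """Participants positive for at least one biomarker."""
        return self.positive_counts > 0

    def to_tsv(self, path) -> None:
        self.matrix.to_csv(path, sep="\t", index_label="participant_id")


def build_profiles(definitions: list[BiomarkerDefinition], fm: FeatureMatrix) -> BiomarkerProfile:
    """Binary outcome profile over accepted biomarkers.

    A participant whose constituent metabolite is missing is scored
    negative for that biomarker (logged). Positivity is strict exceedance
    of the final threshold on the oriented standardized scale.
    """
    accepted = [d for d in definitions if d.accepted]
    cols = {}
    n_missing = 0
    for d in accepted:
        v = fm.values[d.feature_id].to_numpy(dtype=float)
        if d.feature.orientation == "down":
            v = -v
        missing = np.isnan(v)
        n_missing += int(missing.sum())
        pos = np.zeros(v.size, dtype=np.int8)
        pos[~missing] = (v[~missing] > d.threshold).astype(np.int8)
        cols[d.feature_id] = pos
    out = pd.DataFrame(cols, index=fm.values.index, dtype=np.int8)
    if n_missing:
        logger.info("%d missing biomarker cells scored negative", n_missing)
    return BiomarkerProfile(matrix=out, definitions=accepted)


def identified_fraction(profile: BiomarkerProfile, labels) -> float:
    """Fraction of case participants identified by at least one biomarker."""
    y = _case_indicator(labels)
    if profile.matrix.shape[1] == 0:
        return 0.0
    ident = profile.identified.to_numpy()
    return float(ident[y].sum() / y.sum())
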