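"""Oriented log2 feature space: single metabolites and all unique ratios.

A feature is either a single metabolite concentration or the ratio of two
metabolites. Ratios are formed over all C(m, 2) unordered pairs of the m
ratio-eligible metabolites (chronically below-LLOQ analytes are excluded
from ratio generation). All features are log2 transformed — so a ratio is
simply log2(numerator) − log2(denominator) — and standardized to mean 0,
SD 1 (sample SD, n−1) over the full cohort. Because every screening
statistic downstream is a function of ranks only, the transform and
standardization are cosmetic for discovery but give thresholds a common
scale for reporting.

Each feature carries an orientation: ``up`` means large values are
biomarker-positive, ``down`` means small values are (equivalently, the
reciprocal ratio is large). Orientation is provisional at enumeration time
and fixed during screening.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureDefinition:
    feature_id: str
    kind: str  # "single" | "ratio"
    numerator: str
    denominator: str | None = None
    orientation: str = "up"  # "up" | "down"
    flagged: bool = False  # single over a chronically-censored metabolite

    def __post_init__(self) -> None:
        if self.kind not in ("single", "ratio"):
            raise ValueError(f"bad kind {self.kind!r}")
        if self.kind == "ratio" and (self.denominator is None or self.denominator == self.numerator):
            raise ValueError("ratio requires distinct numerator and denominator")
        if self.orientation not in ("up", "down"):
            raise ValueError(f"bad orientation {self.orientation!r}")

    @property
    def display_name(self) -> str:
        """Human-readable name with the orientation folded into the ratio
        (the displayed ratio always increases in biomarker-positives)."""
        if self.kind == "single":
            arrow = "↑" if self.orientation == "up" else "↓"
            return f"{arrow}{self.numerator}"
        if self.orientation == "up":
            return f"{self.numerator}/{self.denominator}"
        return f"{self.denominator}/{self.numerator}"

    def with_orientation(self, orientation: str) -> "FeatureDefinition":
        return replace(self, orientation=orientation)


def enumerate_features(
    metabolite_ids: list[str],
    excluded_ids: tuple[str, ...] | list[str] = (),
) -> list[FeatureDefinition]:
    """All single-metabolite features plus all unique ratio features.

    ``excluded_ids`` are excluded from ratio generation only; their single
    features are kept but flagged so callers can drop them from screening.
    """
    if len(set(metabolite_ids)) != len(metabolite_ids):
        raise ValueError("duplicate metabolite ids")
    unknown = set(excluded_ids) - set(metabolite_ids)
    if unknown:
        raise ValueError(f"excluded_ids not in panel: {sorted(unknown)}")
    defs = [
        FeatureDefinition(mid, "single", mid, flagged=mid in excluded_ids)
        for mid in metabolite_ids
    ]
    eligible = [m for m in metabolite_ids if m not in excluded_ids]
    # canonical pair ordering: lexicographic by metabolite id
    for a, b in combinations(sorted(eligible), 2):
        defs.append(FeatureDefinition(f"{a}/{b}", "ratio", a, b))
    return defs


def ratio_definitions(defs: list[FeatureDefinition]) -> list[FeatureDefinition]:
    return [d for d in defs if d.kind == "ratio"]


@dataclass
class FeatureMatrix:
    """Participants × features on the standardized log2 scale.

    ``mu`` and ``sigma`` are the per-feature log2-scale mean and sample SD
    used for standardization, kept so thresholds can be mapped back to the
    raw concentration(-ratio) scale. Missing cells are NaN.
    """

    values: pd.DataFrame
    mu: pd.Series
    sigma: pd.Series
    definitions: list[FeatureDefinition] = field(default_factory=list)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    def definition(self, feature_id: str) -> FeatureDefinition:
        for d in self.definitions:
            if d.feature_id == feature_id:
                return d
        raise KeyError(feature_id)

    def threshold_to_raw(self, feature_id: str, t: float, orientation: str = "up") -> float:
        """Map a threshold on the standardized oriented scale back to the
        raw concentration/ratio scale. For ``down`` orientation the returned
        value is the raw cutoff *below* which a participant is positive."""
        mu = self.mu[feature_id]
        sigma = self.sigma[feature_id]
        log2_cut = mu + sigma * t if orientation == "up" else mu - sigma * t
        return float(2.0 ** log2_cut)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="participant_id")

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(self.values.copy(), self.mu.copy(), self.sigma.copy(),
                             list(self.definitions))


def compute_features(quant, defs: list[FeatureDefinition]) -> FeatureMatrix:
    """Compute log2 features and standardize each to mean 0, SD 1.

    A feature is missing wherever any constituent metabolite is missing.
    Constant features (zero sample SD) are dropped with a warning.
    Concentrations must be strictly positive (guaranteed upstream by LLOQ
    clipping).
    """
    conc = quant.values if hasattr(quant, "values") else quant
    if ((conc <= 0) & conc.notna()).any().any():
        raise ValueError("non-positive concentrations; clip to quantification limits first")
    log2c = np.log2(conc.to_numpy(dtype=float))
    col_index = {m: i for i, m in enumerate(conc.columns)}

    n = conc.shape[0]
    cols = np.empty((n, len(defs)), dtype=float)
    for k, d in enumerate(defs):
        num = log2c[:, col_index[d.numerator]]
        if d.kind == "single":
            cols[:, k] = num
        else:
            cols[:, k] = num - log2c[:, col_index[d.denominator]]

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(cols, axis=0)
        sigma = np.nanstd(cols, axis=0, ddof=1)
    sigma = np.where(np.isnan(sigma), 0.0, sigma)
    keep = sigma > 0
    dropped = [d.feature_id for d, k in zip(defs, keep) if not k]
    if dropped:
        logger.warning("dropping %d constant feature(s): %s%s", len(dropped),
                       dropped[:5], "..." if len(dropped) > 5 else "")
    std = (cols[:, keep] - mu[keep]) / sigma[keep]
    kept_defs = [d for d, k in zip(defs, keep) if k]
    ids = [d.feature_id for d in kept_defs]
    return FeatureMatrix(
        values=pd.DataFrame(std, index=conc.index, columns=ids),
        mu=pd.Series(mu[keep], index=ids),
        sigma=pd.Series(sigma[keep], index=ids),
        definitions=kept_defs,
    )


def handle_missing(fm: FeatureMatrix, policy: str = "omit") -> FeatureMatrix:
    """Apply the missing-value policy.

    ``omit`` leaves the matrix unchanged (consumers drop incomplete rows
    pairwise); ``median_impute`` fills each feature's missing entries with
    its median over non-missing standardized values. A feature that is
    entirely missing is an error.
    """
    if policy not in ("omit", "median_impute"):
        raise ValueError(f"unknown policy {policy!r}")
    if policy == "omit":
        return fm
    all_missing = fm.values.isna().all(axis=0)
    if all_missing.any():
        raise ValueError(
            f"feature(s) entirely missing: {list(fm.values.columns[all_missing][:5])}"
        )
    filled = fm.values.fillna(fm.values.median(axis=0))
    return FeatureMatrix(filled, fm.mu.copy(), fm.sigma.copy(), list(fm.definitions))
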