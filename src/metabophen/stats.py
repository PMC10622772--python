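"""Association statistics with the effect sizes reported alongside them.

The suite links biomarker values, biomarker-positive status, and
per-participant cluster counts to phenotypic and demographic variables:

* continuous vs continuous → partial Spearman correlation with age as a
  covariate (first-order partial correlation of mid-rank vectors, p from a
  t-approximation with n−3 df);
* continuous vs categorical → Kruskal–Wallis with rank eta squared
  η² = (H − k + 1)/(n − k), with Wilcoxon rank-sum post hocs (effect size
  r = |Z|/√n);
* binary status vs categorical → Fisher exact (odds ratio with Haldane 0.5
  correction for 2×2; Monte-Carlo exact p and bias-corrected Cramér's V
  for 2×K);
* binary status vs continuous → Welch t-test with Cohen's d using the
  root-mean of the two variances.

Benjamini–Hochberg adjustment is applied within each analysis suite and
results are reported at adj. p < 0.1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .screen import adjust_fdr

logger = logging.getLogger(__name__)


def partial_spearman(x, y, covariate) -> tuple[float, float]:
    """First-order partial Spearman correlation of x and y given a covariate.

    Mid-ranks handle ties; ρ_xy·z = (r_xy − r_xz·r_yz) /
    √((1−r_xz²)(1−r_yz²)); two-sided p from t = ρ√((n−3)/(1−ρ²)) with
    n−3 degrees of freedom. Requires ≥ 10 complete triples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(covariate, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y) | np.isnan(z))
    x, y, z = x[ok], y[ok], z[ok]
    n = x.size
    if n < 10:
        raise ValueError(f"need at least 10 complete triples, got {n}")
    rx, ry, rz = sps.rankdata(x), sps.rankdata(y), sps.rankdata(z)
    for name, r in (("x", rx), ("y", ry), ("covariate", rz)):
        if np.std(r) == 0:
            raise ValueError(f"zero-variance rank vector for {name}")
    r_xy = np.corrcoef(rx, ry)[0, 1]
    r_xz = np.corrcoef(rx, rz)[0, 1]
    r_yz = np.corrcoef(ry, rz)[0, 1]
    denom = np.sqrt((1 - r_xz ** 2) * (1 - r_yz ** 2))
    if denom == 0:
        raise ValueError("covariate is perfectly rank-correlated with x or y")
    rho = float((r_xy - r_xz * r_yz) / denom)
    rho = float(np.clip(rho, -1.0, 1.0))
    df = n - 3
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt(df / (1 - rho ** 2))
    p = float(2 * sps.t.sf(abs(t), df))
    return rho, p


def kruskal_wallis_eta(values, groups) -> tuple[float, float, float]:
    """Kruskal–Wallis H (tie-corrected), rank eta squared, and χ² p-value.

    η² = (H − k + 1)/(n − k); small negative values can occur under the
    null and are reported as computed."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ok = ~np.isnan(values)
    if groups.dtype.kind == "f":
        ok &= ~np.isnan(groups.astype(float))
    values, groups = values[ok], groups[ok]
    samples = [values[groups == g] for g in pd.unique(groups)]
    samples = [s for s in samples if s.size >= 2]
    k = len(samples)
    if k < 2:
        raise ValueError("need at least 2 groups with n >= 2")
    if np.unique(values).size < 2:
        raise ValueError("values are constant across all groups")
    H, p = sps.kruskal(*samples)
    n = sum(s.size for s in samples)
    eta2 = float((H - k + 1) / (n - k))
    return float(H), eta2, float(p)


def welch_cohen(x1, x2) -> tuple[float, float, float]:
    """Welch t-test with Cohen's d = (m1−m2)/√((s1²+s2²)/2).

    The root-mean-variance standardizer (rather than the df-pooled SD) is
    consistent with Welch's refusal to assume equal variances."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    x1, x2 = x1[~np.isnan(x1)], x2[~np.isnan(x2)]
    if x1.size < 2 or x2.size < 2:
        raise ValueError("both samples need n >= 2")
    s1, s2 = x1.var(ddof=1), x2.var(ddof=1)
    if s1 == 0 and s2 == 0:
        if x1.mean() == x2.mean():
            return 0.0, 0.0, 1.0
        raise ValueError("zero variance in both samples")
    t, p = sps.ttest_ind(x1, x2, equal_var=False)
    d = float((x1.mean() - x2.mean()) / np.sqrt((s1 + s2) / 2))
    return float(t), d, float(p)


def wilcoxon_r(x1, x2) -> tuple[float, float]:
    """Wilcoxon rank-sum effect size r = |Z|/√n with tie-corrected normal
    approximation, plus the two-sided p-value."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    x1, x2 = x1[~np.isnan(x1)], x2[~np.isnan(x2)]
    n1, n2 = x1.size, x2.size
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    n = n1 + n2
    pooled = np.concatenate([x1, x2])
    ranks = sps.rankdata(pooled)
    U = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mean_u = n1 * n2 / 2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1)))
    var_u = n1 * n2 / 12 * ((n + 1) - tie_term)
    if var_u <= 0:
        return 0.0, 1.0
    z = (U - mean_u) / np.sqrt(var_u)
    p = float(2 * sps.norm.sf(abs(z)))
    return float(abs(z) / np.sqrt(n)), p


def _cramers_v_corrected(table: np.ndarray) -> float:
    """Bias-corrected Cramér's V (Bergsma 2013):
    φ̃² = max(0, φ² − (r−1)(c−1)/(n−1)) with shrunken row/col counts."""
    chi2 = sps.chi2_contingency(table, correction=False)[0]
    n = table.sum()
    r, c = table.shape
    phi2 = chi2 / n
    phi2c = max(0.0, phi2 - (r - 1) * (c - 1) / (n - 1))
    r_t = r - (r - 1) ** 2 / (n - 1)
    c_t = c - (c - 1) ** 2 / (n - 1)
    denom = min(r_t - 1, c_t - 1)
    if denom <= 0:
        return 0.0
    return float(np.sqrt(phi2c / denom))


def fisher_effect(
    table, n_mc: int = 9999, seed: int = 0
) -> tuple[float, float, str]:
    """Exact association test for a 2×K contingency table.

    2×2: hypergeometric two-sided p (Fisher) and the odds ratio ad/bc, with
    a Haldane 0.5 correction to every cell when any cell is zero. 2×K with
    K>2: Monte-Carlo exact p (tables sampled with fixed margins; the test
    statistic is the table's hypergeometric probability, small = extreme)
    and bias-corrected Cramér's V. Returns (p, effect, effect_name)."""
    T = np.asarray(table, dtype=np.int64)
    if T.ndim != 2 or T.shape[0] != 2 or (T < 0).any():
        raise ValueError("need a 2xK table of nonnegative counts")
    if T.sum(axis=0).min() == 0 or T.sum(axis=1).min() == 0:
        raise ValueError("table has an all-zero margin")
    if T.shape[1] == 2:
        _, p = sps.fisher_exact(T, alternative="two-sided")
        a, b = T[0]
        c, d = T[1]
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        return float(p), float((a * d) / (b * c)), "odds_ratio"
    # 2×K Monte-Carlo exact test on the hypergeometric table probability
    logger.info("2x%d table: Monte-Carlo exact p with %d samples", T.shape[1], n_mc)
    rng = np.random.default_rng(seed)
    obs_lp = _log_table_prob(T)
    sampler = sps.random_table(T.sum(axis=1), T.sum(axis=0), seed=rng)
    draws = sampler.rvs(n_mc, method="patefield").astype(np.int64)
    lps = np.array([_log_table_prob(t) for t in draws])
    p = float((1 + int((lps <= obs_lp + 1e-9).sum())) / (n_mc + 1))
    return p, _cramers_v_corrected(T), "cramers_v_corrected"


def _log_table_prob(T: np.ndarray) -> float:
    """Log multivariate-hypergeometric probability of a table given its margins."""
    from scipy.special import gammaln

    def lf(x):
        return gammaln(np.asarray(x, dtype=float) + 1)

    n = T.sum()
    return float(lf(T.sum(axis=1)).sum() + lf(T.sum(axis=0)).sum()
                 - lf(n) - lf(T).sum())


@dataclass
class AssociationResult:
    outcome: str
    predictor: str
    test: str
    statistic: float
    effect: float
    effect_name: str
    p: float
    n: int
    adj_p: float = np.nan


def filter_metadata(
    data: pd.DataFrame, columns: list[str], within: pd.Series | None = None,
    max_missing: float = 0.10, max_identical: float = 0.98,
) -> tuple[list[str], list[tuple[str, str]]]:
    """Drop metadata variables with too many missing responses (>10% of the
    case group by default) or a near-constant response (>98% identical).
    Returns (kept, dropped-with-reason)."""
    ref = data if within is None else data.loc[within]
    kept, dropped = [], []
    for col in columns:
        s = ref[col]
        if s.isna().mean() > max_missing:
            dropped.append((col, f"missing in >{max_missing:.0%} of cases"))
            continue
        vc = s.dropna().value_counts(normalize=True)
        if len(vc) and vc.iloc[0] > max_identical:
            dropped.append((col, f"identical response in >{max_identical:.0%}"))
            continue
        kept.append(col)
    for col, reason in dropped:
        logger.info("metadata variable %r dropped: %s", col, reason)
    return kept, dropped


def run_association_suite(
    data: pd.DataFrame, plan: list[dict], alpha: float = 0.1,
    covariate: str = "age_months",
) -> pd.DataFrame:
    """Run a declared list of association tests and BH-adjust within the suite.

    Each plan entry is ``{"outcome": col, "predictor": col, "test": name}``
    with test one of ``partial_spearman`` (uses ``covariate``), ``kruskal``,
    ``welch``, ``wilcoxon``, ``fisher``. For ``welch``/``fisher`` the
    predictor must be binary (0/1 or yes/no positivity). Results are sorted
    by adjusted p."""
    results: list[AssociationResult] = []
    for entry in plan:
        out_col, pred_col, test = entry["outcome"], entry["predictor"], entry["test"]
        cov = entry.get("covariate", covariate)
        sub = data[[c for c in {out_col, pred_col, cov} if c in data.columns]].copy()
        try:
            if test == "partial_spearman":
                s = sub.dropna()
                rho, p = partial_spearman(s[pred_col], s[out_col], s[cov])
                res = AssociationResult(out_col, pred_col, test, rho, rho,
                                        "rho", p, len(s))
            elif test == "kruskal":
                s = sub[[out_col, pred_col]].dropna()
                H, eta2, p = kruskal_wallis_eta(s[pred_col], s[out_col])
                res = AssociationResult(out_col, pred_col, test, H, eta2,
                                        "eta_squared", p, len(s))
            elif test == "welch":
                s = sub[[out_col, pred_col]].dropna()
                g = _binary(s[pred_col])
                t, d, p = welch_cohen(s.loc[g, out_col], s.loc[~g, out_col])
                res = AssociationResult(out_col, pred_col, test, t, d,
                                        "cohens_d", p, len(s))
            elif test == "wilcoxon":
                s = sub[[out_col, pred_col]].dropna()
                g = _binary(s[pred_col])
                r, p = wilcoxon_r(s.loc[g, out_col], s.loc[~g, out_col])
                res = AssociationResult(out_col, pred_col, test, r, r,
                                        "r", p, len(s))
            elif test == "fisher":
                s = sub[[out_col, pred_col]].dropna()
                g = _binary(s[pred_col])
                tab = pd.crosstab(g, s[out_col]).to_numpy()
                p, eff, eff_name = fisher_effect(tab)
                res = AssociationResult(out_col, pred_col, test, np.nan, eff,
                                        eff_name, p, len(s))
            else:
                raise ValueError(f"unknown test {test!r}")
        except ValueError as exc:
            logger.warning("skipping %s ~ %s (%s): %s", out_col, pred_col, test, exc)
            continue
        results.append(res)
    frame = pd.DataFrame([vars(r) for r in results])
    if frame.empty:
        return frame
    bad = frame["p"].isna()
    if bad.any():
        logger.warning("dropping %d test(s) with undefined p-values", int(bad.sum()))
        frame = frame.loc[~bad].reset_index(drop=True)
        if frame.empty:
            return frame
    frame["adj_p"] = adjust_fdr(frame["p"].to_numpy())
    frame["significant"] = frame["adj_p"] < alpha
    return frame.sort_values("adj_p").reset_index(drop=True)


def _binary(s: pd.Series) -> pd.Series:
    vals = set(s.dropna().unique())
    if vals <= {0, 1} or vals <= {False, True}:
        return s.astype(bool)
    if vals <= {"yes", "no"}:
        return s == "yes"
    raise ValueError(f"predictor is not binary: {sorted(map(str, vals))[:5]}")


def default_association_plan(
    records: pd.DataFrame, metadata_columns: list[str] | None = None,
    predictor: str = "cluster_count",
) -> list[dict]:
    """The study-style plan for a continuous biomarker-burden predictor:
    partial Spearman (age covariate) against continuous behavioral scores,
    Kruskal–Wallis against surviving categorical metadata."""
    continuous = [c for c in (
        "msel_dq", "msel_rl", "msel_el", "msel_fm", "msel_vr",
        "ados_css", "ados_sa_css", "ados_rrb_css", "bmi",
    ) if c in records.columns]
    plan = [{"outcome": c, "predictor": predictor, "test": "partial_spearman"}
            for c in continuous]
    if metadata_columns is None:
        metadata_columns = [c for c in ("medication", "preferred_diet", "special_diet",
                                        "walk_delayed", "vision_abnormal", "sex", "race")
                            if c in records.columns]
    is_case = records["diagnosis"] == "ASD" if "diagnosis" in records.columns else None
    kept, _ = filter_metadata(records, metadata_columns, within=is_case)
    plan += [{"outcome": c, "predictor": predictor, "test": "kruskal"} for c in kept]
    return plan
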