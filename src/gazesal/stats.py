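"""Statistical plan: group comparison, correlation, regression, power.

Group comparisons of participant-level mean fixation saliency values use
the Mann-Whitney U test, exact by full enumeration of group labelings for
small samples and normal-approximated (tie-corrected, with continuity
correction) otherwise. Feature-score correlations with functional-vision
item scores use Spearman's rank correlation. Covariate adjustment is an
ordinary least-squares fit. The two-means sample-size formula and a
Monte-Carlo power simulator complete the plan.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparisonResult",
    "CorrelationResult",
    "PowerResult",
    "mann_whitney_u",
    "spearman_rho",
    "covariate_regression",
    "sample_size_two_means",
    "simulate_power",
    "compare_groups",
    "subgroup_compare",
    "correlate_features",
    "DEFAULT_CR_MAPPING",
    "EXACT_CUTOFF",
]

# exact enumeration when the pooled sample is at most this large
EXACT_CUTOFF = 12

# Which functional-vision assessment item each feature's saliency score is
# correlated with. The adult-attention (deep-saliency) map correlates with
# the instrument's two overall scores.
DEFAULT_CR_MAPPING: dict[str, list[str]] = {
    "color_red": ["color preference"],
    "color_yellow": ["color preference"],
    "color_green": ["color preference"],
    "color_blue": ["color preference"],
    "field_central_peripheral": ["visual field preference"],
    "field_upper_lower": ["visual field preference"],
    "field_right_left": ["visual field preference"],
    "complexity": ["difficulties with visual complexity"],
    "luminance": ["need for light"],
    "adult_attention": ["Score1", "Score2"],
}


@dataclass(frozen=True)
class GroupComparisonResult:
    feature_label: str
    n_cvi: int
    n_control: int
    median_cvi: float
    median_control: float
    U: float
    p_value: float
    method: str  # "exact" | "normal-approximation"


@dataclass(frozen=True)
class CorrelationResult:
    feature_label: str
    item_label: str
    n: int
    rho: float
    p_value: float


@dataclass(frozen=True)
class PowerResult:
    """Two-means sample-size result.

    ``n_per_group`` uses nearest-integer rounding of the closed-form value;
    ``n_per_group_ceiling`` the conservative ceiling convention; both are
    reported. ``n_per_group_rank`` inflates by the Pitman efficiency of the
    rank test relative to the t test (3/pi), for planning a Mann-Whitney
    analysis from a means-based formula.
    """

    mean_a: float
    mean_b: float
    sd: float
    alpha: float
    power: float
    n_per_group_unrounded: float
    n_per_group: int
    n_total: int
    n_per_group_ceiling: int
    n_per_group_rank: int


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group a, from midrank sums over the pooled sample."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r_a = ranks[: len(a)].sum()
    return float(r_a - len(a) * (len(a) + 1) / 2.0)


def mann_whitney_u(
    a,
    b,
    feature_label: str = "",
    exact_cutoff: int = EXACT_CUTOFF,
) -> GroupComparisonResult:
    """Two-sided Mann-Whitney U test of two independent samples.

    For pooled sample size up to ``exact_cutoff`` the two-sided p-value is
    exact, by full enumeration of all group labelings of the pooled
    midranks (p = min(1, 2 * min(P(U <= u), P(U >= u)))). Larger samples
    use the normal approximation with tie-corrected variance and a 0.5
    continuity correction. U is reported for the first group.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = len(a), len(b)
    u_obs = _u_statistic(a, b)

    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        p = 1.0
        method = "exact" if n_a + n_b <= exact_cutoff else "normal-approximation"
    elif n_a + n_b <= exact_cutoff:
        ranks = sps.rankdata(pooled)
        offset = n_a * (n_a + 1) / 2.0
        n_le = n_ge = n_tot = 0
        for combo in itertools.combinations(range(n_a + n_b), n_a):
            u = ranks[list(combo)].sum() - offset
            n_tot += 1
            if u <= u_obs + 1e-12:
                n_le += 1
            if u >= u_obs - 1e-12:
                n_ge += 1
        p = min(1.0, 2.0 * min(n_le, n_ge) / n_tot)
        method = "exact"
    else:
        mu = n_a * n_b / 2.0
        n = n_a + n_b
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
        var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            p = 1.0
        else:
            z = (abs(u_obs - mu) - 0.5) / math.sqrt(var)
            p = min(1.0, 2.0 * sps.norm.sf(max(z, 0.0)))
        method = "normal-approximation"
    return GroupComparisonResult(
        feature_label=feature_label,
        n_cvi=n_a,
        n_control=n_b,
        median_cvi=float(np.median(a)),
        median_control=float(np.median(b)),
        U=u_obs,
        p_value=p,
        method=method,
    )


def spearman_rho(
    x,
    y,
    feature_label: str = "",
    item_label: str = "",
    exact_cutoff: int = 8,
) -> CorrelationResult:
    """Spearman rank correlation with exact-permutation p for small n.

    Midrank transform followed by product-moment correlation of the
    ranks; two-sided p by full permutation enumeration when n <=
    ``exact_cutoff``, otherwise the t approximation with n - 2 degrees of
    freedom. Zero variance in either vector yields rho = NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must be paired")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return CorrelationResult(feature_label, item_label, n, float("nan"), float("nan"))
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = math.sqrt((rx_c**2).sum() * (ry_c**2).sum())
    rho = float((rx_c * ry_c).sum() / denom)

    if n <= exact_cutoff:
        # rho is monotone in the rank dot product for fixed marginals
        count = total = 0
        for perm in itertools.permutations(range(n)):
            r = float((rx_c * ry_c[list(perm)]).sum() / denom)
            total += 1
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        p = count / total
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return CorrelationResult(feature_label, item_label, n, rho, p)


def covariate_regression(data: pd.DataFrame, response: str, covariates: list[str]):
    """OLS fit of a response on covariates (age, comorbidity indicators).

    Returns a statsmodels results object (coefficients, standard errors,
    two-sided p-values via ``.summary()``). Rank-deficient designs raise an
    error naming the collinear columns.
    """
    import statsmodels.api as sm

    X = data[list(covariates)].astype(float)
    X = sm.add_constant(X, has_constant="add")
    Xm = X.to_numpy()
    if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        bad = []
        kept = np.empty((Xm.shape[0], 0))
        for j, name in enumerate(X.columns):
            cand = np.column_stack([kept, Xm[:, j]])
            if np.linalg.matrix_rank(cand) > kept.shape[1]:
                kept = cand
            else:
                bad.append(str(name))
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    return sm.OLS(data[response].astype(float), X).fit()


def sample_size_two_means(
    mean_a: float,
    mean_b: float,
    sd: float,
    alpha: float = 0.05,
    power: float = 0.80,
) -> PowerResult:
    """Closed-form per-group sample size for a two-sided two-means test.

    n per group = 2 (z_{1-alpha/2} + z_{power})^2 sd^2 / (mean_a - mean_b)^2,
    reported unrounded, rounded to the nearest integer (the headline
    convention), and by ceiling. A zero effect admits no finite sample
    size and raises.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must be in (0, 1)")
    delta = mean_a - mean_b
    if delta == 0:
        raise ValueError("zero effect size: required sample size is infinite")
    z_alpha = sps.norm.ppf(1 - alpha / 2)
    z_power = sps.norm.ppf(power)
    n_raw = 2.0 * (z_alpha + z_power) ** 2 * sd**2 / delta**2
    n_near = int(round(n_raw))
    return PowerResult(
        mean_a=mean_a,
        mean_b=mean_b,
        sd=sd,
        alpha=alpha,
        power=power,
        n_per_group_unrounded=n_raw,
        n_per_group=n_near,
        n_total=2 * n_near,
        n_per_group_ceiling=math.ceil(n_raw),
        n_per_group_rank=math.ceil(n_raw * math.pi / 3.0),
    )


def simulate_power(
    mean_a: float,
    mean_b: float,
    sd: float,
    n_per_group: int,
    alpha: float = 0.05,
    n_reps: int = 10_000,
    seed: int | np.random.Generator = 0,
    test: str = "t",
) -> float:
    """Monte-Carlo power of a two-sided two-sample comparison.

    Draws ``n_reps`` replicate cohorts from Normal(mean_a, sd) and
    Normal(mean_b, sd), ``n_per_group`` each, and returns the fraction
    rejected at level ``alpha``. ``test`` selects the two-sample t test
    (vectorized) or the Mann-Whitney U test.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = rng.normal(mean_a, sd, size=(n_reps, n_per_group))
    b = rng.normal(mean_b, sd, size=(n_reps, n_per_group))
    if test == "t":
        res = sps.ttest_ind(a, b, axis=1)
        pvals = np.asarray(res.pvalue)
    elif test == "mannwhitney":
        res = sps.mannwhitneyu(a, b, axis=1, alternative="two-sided")
        pvals = np.asarray(res.pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(np.mean(pvals < alpha))


def _bh_adjust(pvals: list[float]) -> list[float]:
    from statsmodels.stats.multitest import multipletests

    return list(multipletests(pvals, method="fdr_bh")[1])


def compare_groups(
    summaries: pd.DataFrame,
    group_a: str = "cvi",
    group_b: str = "control",
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Mann-Whitney group comparison per feature on participant means.

    ``summaries`` needs columns ``participant_id, group, feature,
    overall_mean``. Raw p-values are reported; an optional
    Benjamini-Hochberg column can be added (off by default).
    """
    rows = []
    for feat, sub in summaries.groupby("feature", sort=True):
        a = sub.loc[sub["group"] == group_a, "overall_mean"].to_numpy()
        b = sub.loc[sub["group"] == group_b, "overall_mean"].to_numpy()
        if len(a) == 0 or len(b) == 0:
            continue
        r = mann_whitney_u(a, b, feature_label=str(feat))
        rows.append(
            {
                "feature": feat,
                "n_cvi": r.n_cvi,
                "n_control": r.n_control,
                "median_cvi": r.median_cvi,
                "median_control": r.median_control,
                "U": r.U,
                "p_value": r.p_value,
                "method": r.method,
            }
        )
    out = pd.DataFrame(rows)
    if bh_adjust and len(out):
        out["p_bh"] = _bh_adjust(list(out["p_value"]))
    return out


def subgroup_compare(
    summaries: pd.DataFrame,
    subgroups: pd.Series | dict,
    group_a: str = "cvi",
    group_b: str = "control",
    min_n: int = 3,
) -> pd.DataFrame:
    """Per-subgroup Mann-Whitney comparisons.

    ``subgroups`` maps participant_id to a subgroup label (e.g. an age
    band, or an ophthalmologic-comorbidity stratum). Subgroups with fewer
    than ``min_n`` participants in either group are reported with
    ``insufficient = True`` and no test.
    """
    mapping = dict(subgroups) if not isinstance(subgroups, dict) else subgroups
    unknown = set(summaries["participant_id"]) - set(mapping)
    if unknown:
        raise ValueError(f"participants missing a subgroup label: {sorted(unknown)[:5]}")
    df = summaries.copy()
    df["subgroup"] = df["participant_id"].map(mapping)
    rows = []
    for (label, feat), sub in df.groupby(["subgroup", "feature"], sort=True):
        a = sub.loc[sub["group"] == group_a, "overall_mean"].to_numpy()
        b = sub.loc[sub["group"] == group_b, "overall_mean"].to_numpy()
        if len(a) < min_n or len(b) < min_n:
            rows.append(
                {
                    "subgroup": label,
                    "feature": feat,
                    "n_cvi": len(a),
                    "n_control": len(b),
                    "U": np.nan,
                    "p_value": np.nan,
                    "insufficient": True,
                }
            )
            continue
        r = mann_whitney_u(a, b, feature_label=str(feat))
        rows.append(
            {
                "subgroup": label,
                "feature": feat,
                "n_cvi": r.n_cvi,
                "n_control": r.n_control,
                "U": r.U,
                "p_value": r.p_value,
                "insufficient": False,
            }
        )
    return pd.DataFrame(rows)


def correlate_features(
    summaries: pd.DataFrame,
    scores: pd.DataFrame,
    mapping: dict[str, list[str]] | None = None,
    group: str | None = "cvi",
) -> pd.DataFrame:
    """Spearman correlation of feature saliency means with item scores.

    ``scores`` has columns ``participant_id, item_label, score``;
    ``mapping`` pairs each feature with the instrument items it is
    correlated against (default :data:`DEFAULT_CR_MAPPING`). Correlations
    are computed within ``group`` (the clinical group) unless ``group`` is
    None.
    """
    mapping = mapping if mapping is not None else DEFAULT_CR_MAPPING
    df = summaries if group is None else summaries[summaries["group"] == group]
    rows = []
    for feat, items in mapping.items():
        feat_df = df[df["feature"] == feat][["participant_id", "overall_mean"]]
        if feat_df.empty:
            continue
        for item in items:
            item_df = scores[scores["item_label"] == item][["participant_id", "score"]]
            merged = feat_df.merge(item_df, on="participant_id")
            if len(merged) < 3:
                continue
            r = spearman_rho(
                merged["overall_mean"], merged["score"], feature_label=feat, item_label=item
            )
            rows.append(
                {
                    "feature": feat,
                    "item": item,
                    "n": r.n,
                    "rho": r.rho,
                    "p_value": r.p_value,
                }
            )
    return pd.DataFrame(rows, columns=["feature", "item", "n", "rho", "p_value"])
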