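"""Cohort-level statistics.

Normality-gated two-group comparison (Shapiro-Wilk at alpha = 0.05 per group,
then Welch t-test if both groups look normal, Mann-Whitney U otherwise),
Spearman rank correlation with interpretation bins, and simple/multiple
ordinary-least-squares regression of TKE on Helicity and Velocity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

ALPHA = 0.05

METRICS = ("tortuosity", "diameter", "helicity", "tke", "velocity", "reynolds")

#: parameter pairs in the order the cohort correlation table reports them
CORRELATION_PAIRS = (
    ("tortuosity", "helicity"),
    ("tortuosity", "tke"),
    ("tortuosity", "velocity"),
    ("tortuosity", "reynolds"),
    ("tortuosity", "diameter"),
    ("helicity", "tke"),
    ("helicity", "velocity"),
    ("helicity", "reynolds"),
    ("helicity", "diameter"),
    ("tke", "velocity"),
    ("tke", "reynolds"),
    ("velocity", "diameter"),
    ("reynolds", "diameter"),
)

_INTERPRETATION_BINS = (
    (0.2, "very weak"),
    (0.4, "weak"),
    (0.6, "moderate"),
    (0.8, "strong"),
    (1.0 + 1e-12, "very strong"),
)


def interpret_rho(rho: float) -> str:
    """Label |rho| by the conventional strength bins (left-closed)."""
    a = abs(rho)
    if not np.isfinite(a) or a > 1 + 1e-9:
        raise ValueError(f"rho out of range: {rho}")
    for upper, label in _INTERPRETATION_BINS:
        if a < upper:
            return label
    return "very strong"


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    interpretation: str = ""

    def __post_init__(self) -> None:
        if not self.interpretation:
            self.interpretation = interpret_rho(self.rho)


@dataclass
class GroupComparisonResult:
    test_used: str                 # "t" or "mann_whitney"
    statistic: float
    p_value: float
    summary_young: str
    summary_old: str
    notes: list[str] = field(default_factory=list)


@dataclass
class RegressionResult:
    model: str                     # simple_helicity | simple_velocity | multiple
    coefficients: dict[str, float]
    p_values: dict[str, float]
    r_squared: float
    n: int


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

def _normalish(x: np.ndarray) -> tuple[bool, str | None]:
    if np.ptp(x) == 0:
        return False, "constant data: normality undefined, using Mann-Whitney"
    return bool(sps.shapiro(x).pvalue > ALPHA), None


def _summary(x: np.ndarray, normal: bool) -> str:
    if normal:
        return f"{np.mean(x):.3g} ± {np.std(x, ddof=1):.3g}"
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.3g} [{q1:.3g}, {q3:.3g}]"


def compare_groups(
    table: pd.DataFrame, parameter: str, region: str
) -> GroupComparisonResult:
    """Young-vs-Old comparison of one parameter in one region.

    Shapiro-Wilk gates the test choice: both groups normal at alpha = 0.05 ->
    Welch two-sample t; otherwise Mann-Whitney U (exact for group sizes <= 20
    without ties, normal approximation with tie correction above that).
    """
    sub = table[table["region"] == region]
    young = sub.loc[sub["group"] == "Young", parameter].dropna().to_numpy(float)
    old = sub.loc[sub["group"] == "Old", parameter].dropna().to_numpy(float)
    if len(young) < 3 or len(old) < 3:
        raise ValueError("each group needs n >= 3 for a comparison")
    notes = []
    ny, my = _normalish(young)
    no, mo = _normalish(old)
    notes += [m for m in (my, mo) if m]
    if ny and no:
        res = sps.ttest_ind(young, old, equal_var=False)
        test, normal = "t", True
    else:
        method = "exact" if (len(young) <= 20 and len(old) <= 20) else "asymptotic"
        try:
            res = sps.mannwhitneyu(young, old, alternative="two-sided", method=method)
        except ValueError:
            res = sps.mannwhitneyu(young, old, alternative="two-sided", method="asymptotic")
            notes.append("exact Mann-Whitney unavailable (ties); used approximation")
        test, normal = "mann_whitney", False
    return GroupComparisonResult(
        test_used=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        summary_young=_summary(young, normal),
        summary_old=_summary(old, normal),
        notes=notes,
    )


def group_summary_table(table: pd.DataFrame, regions=None, parameters=METRICS) -> pd.DataFrame:
    """Per-region Young/Old summaries and p-values for each parameter."""
    regions = regions or sorted(table["region"].unique())
    rows = []
    for parameter in parameters:
        if parameter not in table.columns:
            continue
        for region in regions:
            try:
                r = compare_groups(table, parameter, region)
            except ValueError as exc:
                rows.append(
                    {
                        "parameter": parameter,
                        "region": region,
                        "young": "",
                        "old": "",
                        "test": "none",
                        "p_value": np.nan,
                        "note": str(exc),
                    }
                )
                continue
            rows.append(
                {
                    "parameter": parameter,
                    "region": region,
                    "young": r.summary_young,
                    "old": r.summary_old,
                    "test": r.test_used,
                    "p_value": r.p_value,
                    "note": "; ".join(r.notes),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

_NULL_CACHE: dict[tuple, np.ndarray] = {}


def _spearman_null(rx: np.ndarray, ry: np.ndarray) -> np.ndarray:
    """Sorted |rho| over all n! pairings of the two rank vectors.

    The null distribution depends only on the two rank multisets, so it is
    cached; with untied data every call for the same n reuses one enumeration.
    """
    key = (tuple(np.sort(rx)), tuple(np.sort(ry)))
    cached = _NULL_CACHE.get(key)
    if cached is not None:
        return cached
    rx_c = rx - rx.mean()
    denom_x = np.sqrt((rx_c**2).sum())
    ry_mean = ry.mean()
    out = []
    chunk: list[tuple] = []

    def flush(block) -> np.ndarray:
        perms = np.asarray(block)
        ry_c = perms - ry_mean
        denom_y = np.sqrt((ry_c**2).sum(axis=1))
        return np.abs(ry_c @ rx_c) / (denom_x * denom_y)

    for perm in itertools.permutations(ry):
        chunk.append(perm)
        if len(chunk) >= 200_000:
            out.append(flush(chunk))
            chunk = []
    if chunk:
        out.append(flush(chunk))
    null = np.sort(np.concatenate(out))
    if len(_NULL_CACHE) > 4:  # bound memory: n=10 costs ~30 MB per entry
        _NULL_CACHE.clear()
    _NULL_CACHE[key] = null
    return null


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman rho (small n).

    Enumerates all n! assignments of the y mid-ranks against the x mid-ranks
    and counts |rho_perm| >= |rho_obs|.
    """
    null = _spearman_null(sps.rankdata(x), sps.rankdata(y))
    target = abs(rho_obs) - 1e-12
    count = len(null) - int(np.searchsorted(null, target, side="left"))
    return count / len(null)


def spearman_correlation(x, y, exact_max_n: int = 10) -> CorrelationResult:
    """Spearman rho with an interpretation label.

    rho is the Pearson correlation of mid-ranks (ties averaged). The p-value
    uses the t-distribution approximation for n > ``exact_max_n`` and exact
    permutation enumeration for smaller samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D and of equal length")
    n = len(x)
    if n < 4:
        raise ValueError("need n >= 4 for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: Spearman rho undefined")
    res = sps.spearmanr(x, y)
    rho = float(res.statistic)
    if n <= exact_max_n:
        p = _exact_spearman_p(x, y, rho)
    else:
        p = float(res.pvalue)
    return CorrelationResult(rho=rho, p_value=p, n=n)


def correlation_matrix(table: pd.DataFrame, region: str) -> pd.DataFrame:
    """The cohort's pairwise Spearman correlations for one region.

    Computes the parameter pairings of the cohort correlation table, in its
    reporting order, pooled over both groups.
    """
    sub = table[table["region"] == region]
    rows = []
    for a, b in CORRELATION_PAIRS:
        if a not in sub.columns or b not in sub.columns:
            continue
        valid = sub[[a, b]].dropna()
        r = spearman_correlation(valid[a].to_numpy(), valid[b].to_numpy())
        rows.append(
            {
                "pair": f"{a}-{b}",
                "region": region,
                "rho": r.rho,
                "interpretation": r.interpretation,
                "p_value": r.p_value,
                "n": r.n,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Regression
# ---------------------------------------------------------------------------

def _ols(y: np.ndarray, X: pd.DataFrame, model: str) -> RegressionResult:
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    return RegressionResult(
        model=model,
        coefficients={k: float(v) for k, v in fit.params.items()},
        p_values={k: float(v) for k, v in fit.pvalues.items()},
        r_squared=float(fit.rsquared),
        n=int(fit.nobs),
    )


def fit_tke_regressions(
    table: pd.DataFrame, region: str, subset: str = "Young+Old"
) -> dict[str, RegressionResult]:
    """OLS models predicting TKE: ~Helicity, ~Velocity, and the combined model.

    ``subset`` is "Young", "Old", or "Young+Old" (pooled).
    """
    sub = table[table["region"] == region]
    if subset != "Young+Old":
        sub = sub[sub["group"] == subset]
    sub = sub[["tke", "helicity", "velocity"]].dropna()
    if len(sub) < 4:
        raise ValueError(f"subset {subset!r} has fewer than 4 rows in {region}")
    y = sub["tke"].to_numpy(float)
    h = sub[["helicity"]]
    v = sub[["velocity"]]
    out = {
        "simple_helicity": _ols(y, h, "simple_helicity"),
        "simple_velocity": _ols(y, v, "simple_velocity"),
    }
    corr = np.corrcoef(sub["helicity"], sub["velocity"])[0, 1]
    if abs(corr) >= 1.0 - 1e-12:
        raise ValueError("helicity and velocity are perfectly collinear")
    out["multiple"] = _ols(y, sub[["helicity", "velocity"]], "multiple")
    return out


def regression_table(table: pd.DataFrame, regions=None) -> pd.DataFrame:
    """TKE regression coefficients and p-values per region and subset."""
    regions = regions or sorted(table["region"].unique())
    rows = []
    for region in regions:
        for subset in ("Young", "Old", "Young+Old"):
            try:
                fits = fit_tke_regressions(table, region, subset)
            except ValueError:
                continue
            for name, fit in fits.items():
                for pred in ("helicity", "velocity"):
                    if pred in fit.coefficients:
                        rows.append(
                            {
                                "region": region,
                                "subset": subset,
                                "model": name,
                                "predictor": pred,
                                "coefficient": fit.coefficients[pred],
                                "p_value": fit.p_values[pred],
                                "r_squared": fit.r_squared,
                                "n": fit.n,
                            }
                        )
    return pd.DataFrame(rows)
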