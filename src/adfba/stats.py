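"""Statistical mining of simulated trajectories.

Operates on *time-series tables*: plain DataFrames with the time grid as
index and one column per variable (metabolite concentration or reaction
flux).  The pipeline mirrors how simulation output is typically mined:

1. normality screening (Shapiro-Wilk + Anderson-Darling) to choose between
   parametric and rank-based tests;
2. all-pairs correlation sweeps (Pearson, Spearman, quadratic/cubic
   curvilinear R^2);
3. feature selection of the variables that best explain an outcome flux
   (forward/backward stepwise regression scored by AICc, and a grouped
   Boruta built on shadow-feature random-forest importances, batching
   variables in groups of 20 and re-grouping the survivors until one final
   pass remains);
4. two-sample comparison of whole or windowed timelines between two
   simulations (ANOVA, Kruskal-Wallis, Welch t, Mann-Whitney U — the
   Mann-Whitney p-value matrix is the primary, heatmap-ready artifact since
   trajectory variables are essentially never normally distributed);
5. polynomial time-trend fits (linear/quadratic/cubic) compared across
   non-nested specifications with the Cox test and the Davidson-MacKinnon
   J test.

All stochastic operations are reproducible bit-for-bit under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.ensemble import RandomForestRegressor
from statsmodels.stats.diagnostic import compare_cox, compare_j, normal_ad
from statsmodels.stats.multitest import multipletests

from .exceptions import ContractError

logger = logging.getLogger("adfba.stats")

DEFAULT_ALPHA = 0.05

#: Variables per Boruta batch.
BORUTA_GROUP_SIZE = 20
#: Random-forest size for Boruta importances.
BORUTA_N_TREES = 500
#: Shadow-comparison iterations per Boruta pass.
BORUTA_N_ITER = 25


# ---------------------------------------------------------------------------
# Normality screening
# ---------------------------------------------------------------------------

def normality_screen(table: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Shapiro-Wilk and Anderson-Darling per variable.

    Returns a frame indexed by variable with test statistics and p-values,
    a ``recommendation`` column ("parametric" unless both tests reject at
    ``alpha``, then "rank-based"), and a ``skipped`` flag for constant
    variables (the tests are undefined there).
    """
    if len(table) < 8:
        raise ContractError("normality screening needs at least 8 time points")
    rows = []
    for var in table.columns:
        x = table[var].to_numpy(dtype=float)
        if np.ptp(x) == 0.0:
            rows.append(
                dict(variable=var, shapiro_stat=np.nan, shapiro_p=np.nan,
                     ad_stat=np.nan, ad_p=np.nan, recommendation="skipped",
                     skipped=True)
            )
            logger.info("normality screen: %s is constant, skipped", var)
            continue
        sw_stat, sw_p = sps.shapiro(x)
        ad_stat, ad_p = normal_ad(x)
        both_reject = (sw_p < alpha) and (ad_p < alpha)
        rows.append(
            dict(variable=var, shapiro_stat=float(sw_stat), shapiro_p=float(sw_p),
                 ad_stat=float(ad_stat), ad_p=float(ad_p),
                 recommendation="rank-based" if both_reject else "parametric",
                 skipped=False)
        )
    return pd.DataFrame(rows).set_index("variable")


# ---------------------------------------------------------------------------
# Correlation sweeps
# ---------------------------------------------------------------------------

_POLY_ORDER = {"quad": 2, "cubic": 3}


def _poly_r2(y: np.ndarray, x: np.ndarray, order: int) -> float:
    """Coefficient of determination of the polynomial fit y ~ poly(x)."""
    coef = np.polyfit(x, y, order)
    resid = y - np.polyval(coef, x)
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        return np.nan
    return 1.0 - float(np.sum(resid**2)) / tss


def correlation_sweep(
    table: pd.DataFrame,
    methods: tuple[str, ...] = ("pearson", "spearman"),
) -> dict[str, pd.DataFrame]:
    """All-pairs association matrices, one per requested method.

    ``pearson``/``spearman`` give the usual symmetric correlation matrices
    with unit diagonal.  ``quad``/``cubic`` give curvilinear-regression R^2:
    entry (i, j) is the R^2 of regressing variable i on a polynomial in
    variable j — inherently directional, so those matrices need not be
    symmetric.  Zero-variance variables yield NaN entries.
    """
    allowed = {"pearson", "spearman", "quad", "cubic"}
    bad = set(methods) - allowed
    if bad:
        raise ContractError(f"unknown correlation methods: {sorted(bad)}")
    out: dict[str, pd.DataFrame] = {}
    cols = list(table.columns)
    n = len(table)
    for method in methods:
        if method in ("pearson", "spearman"):
            if n < 4:
                raise ContractError("correlation sweep needs >= 4 points")
            mat = table.corr(method=method)
            np.fill_diagonal(mat.values, 1.0)
        else:
            order = _POLY_ORDER[method]
            if n < order + 2:
                raise ContractError(
                    f"{method} sweep needs >= {order + 2} points, got {n}"
                )
            mat = pd.DataFrame(np.nan, index=cols, columns=cols)
            arrays = {c: table[c].to_numpy(dtype=float) for c in cols}
            for yi in cols:
                for xj in cols:
                    y, x = arrays[yi], arrays[xj]
                    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
                        continue  # undefined for constant variables
                    mat.loc[yi, xj] = _poly_r2(y, x, order)
            np.fill_diagonal(mat.values, 1.0)
        mat.attrs["method"] = method
        out[method] = mat
    return out


def strong_pairs(matrix: pd.DataFrame, threshold: float = 0.9) -> pd.DataFrame:
    """Variable pairs whose |statistic| exceeds the screening threshold."""
    rows = []
    cols = list(matrix.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            r = matrix.loc[a, b]
            if np.isfinite(r) and abs(r) > threshold:
                rows.append(dict(var_a=a, var_b=b, statistic=float(r)))
    return pd.DataFrame(rows, columns=["var_a", "var_b", "statistic"])


# ---------------------------------------------------------------------------
# Feature selection
# ---------------------------------------------------------------------------

@dataclass
class FeatureImportanceResult:
    outcome: str
    method: str                       # forward | backward | boruta-grouped
    seed: int | None
    #: (variable, importance score) in decreasing importance
    ranking: list[tuple[str, float]]
    selected: list[str]
    #: per Boruta round, the sizes of the variable groups
    group_history: list[list[int]] = field(default_factory=list)


def _aicc(y: np.ndarray, X: np.ndarray) -> float:
    """Small-sample corrected AIC of an OLS fit with intercept included in X."""
    n, k = X.shape
    if n - k - 1 <= 0:
        return np.inf
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    rss = max(rss, 1e-300)
    aic = n * np.log(rss / n) + 2 * k
    return aic + 2 * k * (k + 1) / (n - k - 1)


def _stepwise(table: pd.DataFrame, outcome: str, direction: str) -> tuple[list[tuple[str, float]], list[str]]:
    y = table[outcome].to_numpy(dtype=float)
    candidates = [c for c in table.columns if c != outcome]
    Xall = {c: table[c].to_numpy(dtype=float) for c in candidates}
    ones = np.ones((len(y), 1))

    def design(sel: list[str]) -> np.ndarray:
        if not sel:
            return ones
        return np.column_stack([ones] + [Xall[c] for c in sel])

    if direction == "forward":
        selected: list[str] = []
        scores: dict[str, float] = {}
        current = _aicc(y, design(selected))
        while True:
            best, best_aicc = None, current
            for c in candidates:
                if c in selected:
                    continue
                a = _aicc(y, design(selected + [c]))
                if a < best_aicc - 1e-12:
                    best, best_aicc = c, a
            if best is None:
                break
            scores[best] = current - best_aicc  # AICc improvement on entry
            selected.append(best)
            current = best_aicc
        ranking = sorted(scores.items(), key=lambda kv: -kv[1])
        ranking += [(c, 0.0) for c in candidates if c not in scores]
        return ranking, selected

    # backward: drop while AICc improves; importance = AICc cost of removal
    selected = list(candidates)
    current = _aicc(y, design(selected))
    while len(selected) > 0:
        best, best_aicc = None, current
        for c in selected:
            rest = [s for s in selected if s != c]
            a = _aicc(y, design(rest))
            if a < best_aicc - 1e-12:
                best, best_aicc = c, a
        if best is None:
            break
        selected.remove(best)
        current = best_aicc
    scores = {}
    for c in selected:
        rest = [s for s in selected if s != c]
        scores[c] = _aicc(y, design(rest)) - current
    ranking = sorted(scores.items(), key=lambda kv: -kv[1])
    ranking += [(c, 0.0) for c in candidates if c not in scores]
    return ranking, selected


def partition_into_groups(names: list[str], size: int = BORUTA_GROUP_SIZE) -> list[list[str]]:
    """Split variables, in order, into batches of ``size`` (last may be short)."""
    return [names[i: i + size] for i in range(0, len(names), size)]


def _boruta_pass(
    X: pd.DataFrame,
    y: np.ndarray,
    rng: np.random.Generator,
    n_trees: int,
    n_iter: int,
    alpha: float,
) -> tuple[list[str], list[str], dict[str, float]]:
    """One Boruta pass: confirmed, tentative, mean importances.

    Each iteration appends a shadow copy of every feature (independently
    permuted rows), fits a random forest, and counts a *hit* whenever a real
    feature out-ranks the best shadow importance.  Features whose hit counts
    are binomially significantly above / below chance (p0 = 0.5) at ``alpha``
    are confirmed / rejected; the rest stay tentative.
    """
    cols = list(X.columns)
    hits = {c: 0 for c in cols}
    mean_imp = {c: 0.0 for c in cols}
    Xv = X.to_numpy(dtype=float)
    n, p = Xv.shape
    for _ in range(n_iter):
        shadow = Xv.copy()
        for j in range(p):
            shadow[:, j] = shadow[rng.permutation(n), j]
        Z = np.hstack([Xv, shadow])
        rf = RandomForestRegressor(
            n_estimators=n_trees,
            random_state=int(rng.integers(0, 2**31 - 1)),
            n_jobs=1,
        )
        rf.fit(Z, y)
        imp = rf.feature_importances_
        shadow_max = imp[p:].max() if p else 0.0
        for j, c in enumerate(cols):
            mean_imp[c] += imp[j] / n_iter
            if imp[j] > shadow_max:
                hits[c] += 1
    confirmed, tentative = [], []
    for c in cols:
        p_hi = sps.binomtest(hits[c], n_iter, 0.5, alternative="greater").pvalue
        p_lo = sps.binomtest(hits[c], n_iter, 0.5, alternative="less").pvalue
        if p_hi < alpha:
            confirmed.append(c)
        elif p_lo < alpha:
            pass  # rejected
        else:
            tentative.append(c)
    return confirmed, tentative, mean_imp


def select_features(
    table: pd.DataFrame,
    outcome: str,
    method: str,
    seed: int | None = None,
    *,
    n_trees: int = BORUTA_N_TREES,
    n_iter: int = BORUTA_N_ITER,
    group_size: int = BORUTA_GROUP_SIZE,
    alpha: float = DEFAULT_ALPHA,
) -> FeatureImportanceResult:
    """Rank the variables that explain ``outcome``.

    ``forward`` and ``backward`` are stepwise OLS searches scored by AICc.
    ``boruta-grouped`` batches the candidates into groups of ``group_size``,
    runs a shadow-feature Boruta pass per group, pools the survivors
    (confirmed + tentative), and re-groups until at most one group remains,
    which receives a final pass; the selected set is that pass's confirmed
    features.  Deterministic given ``seed``.
    """
    if outcome not in table.columns:
        raise ContractError(f"outcome {outcome!r} not in table")
    candidates = [c for c in table.columns if c != outcome]
    if len(candidates) < 2:
        raise ContractError("feature selection needs >= 2 candidate variables")

    if method in ("forward", "backward"):
        ranking, selected = _stepwise(table, outcome, method)
        return FeatureImportanceResult(outcome, method, seed, ranking, selected)
    if method != "boruta-grouped":
        raise ContractError(
            f"method must be forward, backward or boruta-grouped, got {method!r}"
        )

    rng = np.random.default_rng(seed)
    y = table[outcome].to_numpy(dtype=float)
    survivors = list(candidates)
    group_history: list[list[int]] = []
    importances: dict[str, float] = {}
    while len(survivors) > group_size:
        groups = partition_into_groups(survivors, group_size)
        group_history.append([len(g) for g in groups])
        pooled: list[str] = []
        for g in groups:
            confirmed, tentative, imp = _boruta_pass(
                table[g], y, rng, n_trees, n_iter, alpha
            )
            importances.update(imp)
            pooled.extend(confirmed + tentative)
        if len(pooled) == len(survivors):
            # no attrition: fall through to a single final pass on the pool
            survivors = pooled
            break
        survivors = pooled
        if not survivors:
            break
    if survivors:
        group_history.append([len(survivors)])
        confirmed, tentative, imp = _boruta_pass(
            table[survivors], y, rng, n_trees, n_iter, alpha
        )
        importances.update(imp)
        selected = confirmed
    else:
        selected = []
    ranking = sorted(importances.items(), key=lambda kv: -kv[1])
    ranking += [(c, 0.0) for c in candidates if c not in importances]
    return FeatureImportanceResult(
        outcome, "boruta-grouped", seed, ranking, selected, group_history
    )


# ---------------------------------------------------------------------------
# Timeline comparison
# ---------------------------------------------------------------------------

def compare_timelines(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    window: tuple[float, float] | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Two-sample tests per shared variable over a (windowed) timeline.

    Computes ANOVA, Kruskal-Wallis, Welch t and Mann-Whitney U p-values per
    variable; ``mannwhitney_p`` is the primary column (simulation variables
    are essentially never normal, so the rank test is the one retained), and
    a Benjamini-Hochberg adjusted column is added as a clearly-labelled
    extra.  Variables present in only one table are skipped with a log
    entry.  The result is a heatmap-ready table.
    """
    shared = [c for c in table_a.columns if c in set(table_b.columns)]
    skipped = (set(table_a.columns) | set(table_b.columns)) - set(shared)
    for var in sorted(skipped):
        logger.info("compare_timelines: variable %s absent from one table, skipped", var)
    if not shared:
        raise ContractError("tables share no variables")

    def slice_(tbl: pd.DataFrame) -> pd.DataFrame:
        if window is None:
            return tbl
        lo, hi = window
        idx = np.asarray(tbl.index, dtype=float)
        return tbl.loc[(idx >= lo - 1e-9) & (idx <= hi + 1e-9)]

    A, B = slice_(table_a), slice_(table_b)
    if len(A) == 0 or len(B) == 0:
        raise ContractError("comparison window excludes all time points")
    rows = []
    for var in shared:
        a = A[var].to_numpy(dtype=float)
        b = B[var].to_numpy(dtype=float)
        if np.ptp(np.concatenate([a, b])) == 0.0:
            rows.append(dict(variable=var, anova_p=np.nan, kruskal_p=np.nan,
                             welch_p=np.nan, mannwhitney_p=1.0))
            continue
        anova_p = float(sps.f_oneway(a, b).pvalue)
        try:
            kruskal_p = float(sps.kruskal(a, b).pvalue)
        except ValueError:  # all-identical values
            kruskal_p = 1.0
        welch_p = float(sps.ttest_ind(a, b, equal_var=False).pvalue)
        mw_p = float(
            sps.mannwhitneyu(a, b, use_continuity=False, method="asymptotic").pvalue
        )
        rows.append(dict(variable=var, anova_p=anova_p, kruskal_p=kruskal_p,
                         welch_p=welch_p, mannwhitney_p=mw_p))
    out = pd.DataFrame(rows).set_index("variable")
    out["mannwhitney_p_bh"] = multipletests(
        out["mannwhitney_p"].fillna(1.0), method="fdr_bh"
    )[1]
    out["different"] = out["mannwhitney_p"] < alpha
    return out


# ---------------------------------------------------------------------------
# Time-trend models and non-nested comparison
# ---------------------------------------------------------------------------

@dataclass
class TimeModelFit:
    variable: str
    order: int
    coefficients: np.ndarray        # intercept first
    r_squared: float
    residuals: np.ndarray
    results: object                 # statsmodels OLSResults
    time_transform: str = "t"


def fit_time_models(
    table: pd.DataFrame,
    variable: str,
    orders: tuple[int, ...] = (1, 2, 3),
    time_transform=None,
) -> dict[int, TimeModelFit]:
    """Polynomial-in-time least-squares fits of one variable.

    ``time_transform`` optionally maps the time axis before building the
    polynomial (e.g. ``np.sqrt``), which is how genuinely non-nested
    specifications of the same response are obtained.
    """
    if variable not in table.columns:
        raise ContractError(f"variable {variable!r} not in table")
    t = np.asarray(table.index, dtype=float)
    label = "t"
    if time_transform is not None:
        t = time_transform(t)
        label = getattr(time_transform, "__name__", "g(t)")
    y = table[variable].to_numpy(dtype=float)
    fits: dict[int, TimeModelFit] = {}
    for order in orders:
        if order not in (1, 2, 3):
            raise ContractError(f"model order must be 1, 2 or 3, got {order}")
        if len(y) < order + 2:
            raise ContractError(
                f"order-{order} fit needs >= {order + 2} points, got {len(y)}"
            )
        X = np.column_stack([t**k for k in range(order + 1)])
        res = sm.OLS(y, X).fit()
        fits[order] = TimeModelFit(
            variable=variable,
            order=order,
            coefficients=np.asarray(res.params),
            r_squared=float(res.rsquared),
            residuals=np.asarray(res.resid),
            results=res,
            time_transform=label,
        )
    return fits


@dataclass
class NonNestedComparison:
    cox_statistic: float
    cox_p: float
    j_statistic: float
    j_p: float
    degenerate: bool = False


def compare_nonnested(fit_a: TimeModelFit, fit_b: TimeModelFit) -> NonNestedComparison:
    """Cox test and Davidson-MacKinnon J test between two non-nested fits.

    Direction: a small ``j_p`` (or ``cox_p``) is evidence *against*
    ``fit_b`` — the J statistic tests whether ``fit_a``'s fitted values add
    explanatory power to ``fit_b``'s specification; run the comparison in
    both orders, as is standard for non-nested tests.

    Both fits must model the same response.  If one regressor set spans the
    other the models are nested and an F-test is the right tool instead — a
    contract error says so.  Zero-residual (exact) fits make both tests
    degenerate; the result is flagged rather than fabricated.
    """
    if fit_a.variable != fit_b.variable:
        raise ContractError(
            f"fits model different responses ({fit_a.variable!r} vs "
            f"{fit_b.variable!r}); non-nested comparison is undefined"
        )
    ya = np.asarray(fit_a.results.model.endog)
    yb = np.asarray(fit_b.results.model.endog)
    if ya.shape != yb.shape or not np.allclose(ya, yb):
        raise ContractError("fits are not over the same observations")
    Xa = np.asarray(fit_a.results.model.exog)
    Xb = np.asarray(fit_b.results.model.exog)
    rank_a = np.linalg.matrix_rank(Xa)
    rank_b = np.linalg.matrix_rank(Xb)
    rank_ab = np.linalg.matrix_rank(np.hstack([Xa, Xb]))
    if rank_ab == max(rank_a, rank_b):
        raise ContractError(
            "one regressor set is contained in the other: the models are "
            "nested — use an F-test, not a non-nested comparison"
        )
    ssr = min(float(fit_a.results.ssr), float(fit_b.results.ssr))
    if ssr <= 1e-12:
        return NonNestedComparison(np.nan, np.nan, np.nan, np.nan, degenerate=True)
    cox_t, cox_p = compare_cox(fit_a.results, fit_b.results)
    j_t, j_p = compare_j(fit_a.results, fit_b.results)
    return NonNestedComparison(
        float(cox_t), float(cox_p), float(j_t), float(j_p)
    )
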