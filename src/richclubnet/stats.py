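"""Covariate-adjusted group/sex inference with permutation-adjusted p-values.

The inferential engine is an ordinary-least-squares general linear model of
a per-subject outcome (e.g. feeder connectivity strength) on diagnostic
group, sex and nuisance covariates (age, years of education), with

* Type-III sums of squares under sum-to-zero factor coding, so each term's
  F compares the full model against the model with that term removed;
* partial eta squared η_p² = SS_term / (SS_term + SS_error) as effect size;
* permutation-adjusted p-values: for main effects the term's factor labels
  are permuted across subjects while covariates stay attached to their
  subjects; for interaction terms simple label permutation is invalid under
  non-null main effects, so residuals of the reduced (no-interaction) model
  are permuted instead (Freedman–Lane).  p = (b + 1) / (n_perm + 1).
* family-wise control across an outcome family via the max-statistic over
  a shared set of permutations.

Pearson correlations between connectivity and cognitive scores trim
subjects outside the 5th–95th percentile range of the cognitive variable
before computing r.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatResult",
    "CorrelationResult",
    "glm_term_test",
    "permutation_adjusted_p",
    "interaction_test",
    "trimmed_pearson",
    "family_maxstat_pvalues",
]

DEFAULT_COVARIATES = ("age", "education")


@dataclasses.dataclass
class StatResult:
    outcome: str
    term: str
    F_statistic: float
    df_num: int
    df_den: int
    partial_eta_sq: float
    p_parametric: float
    p_permutation: float | None = None
    n_perm: int | None = None
    seed: int | None = None
    adjusted_means: pd.DataFrame | None = None


@dataclasses.dataclass
class CorrelationResult:
    pair: tuple[str, str]
    r: float
    n_used: int
    n_excluded: int
    p_parametric: float
    p_permutation: float | None = None


# --------------------------------------------------------------------------
# design matrices (sum-to-zero factor coding)

def _sum_code(labels: np.ndarray, levels: list) -> np.ndarray:
    """n × (L−1) sum-to-zero (deviation) coding; last level is the baseline."""
    n = labels.shape[0]
    cols = np.zeros((n, len(levels) - 1))
    for j, lev in enumerate(levels[:-1]):
        cols[:, j] = (labels == lev).astype(float)
    cols[labels == levels[-1], :] = -1.0
    return cols


def _term_parts(term: str) -> tuple[str, ...]:
    return tuple(term.split(":"))


def _build_design(
    data: pd.DataFrame,
    factors: tuple[str, ...],
    covariates: tuple[str, ...],
    interaction: bool,
    factor_columns: dict[str, np.ndarray] | None = None,
):
    """Design matrix blocks: dict term -> column block, plus intercept.

    ``factor_columns`` overrides the coded block of a factor (used by the
    permutation engine to substitute permuted labels without re-deriving
    levels).
    """
    n = len(data)
    blocks: dict[str, np.ndarray] = {"Intercept": np.ones((n, 1))}
    coded: dict[str, np.ndarray] = {}
    for f in factors:
        if factor_columns and f in factor_columns:
            coded[f] = factor_columns[f]
        else:
            labels = data[f].to_numpy()
            levels = sorted(pd.unique(labels).tolist())
            if len(levels) < 2:
                raise ValueError(f"factor {f!r} has fewer than 2 levels present")
            coded[f] = _sum_code(labels, levels)
        blocks[f] = coded[f]
    if interaction and len(factors) >= 2:
        for a, b in itertools.combinations(factors, 2):
            ca, cb = coded[a], coded[b]
            prod = np.einsum("ni,nj->nij", ca, cb).reshape(n, -1)
            blocks[f"{a}:{b}"] = prod
    for cov in covariates:
        blocks[cov] = data[cov].to_numpy(dtype=float).reshape(n, -1)
    return blocks


def _stack(blocks: dict[str, np.ndarray], drop: str | None = None) -> np.ndarray:
    return np.hstack([b for t, b in blocks.items() if t != drop])


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    # small k: normal equations via lstsq for rank safety
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if res.size:
        return float(res[0])
    r = y - X @ beta
    return float(r @ r)


def _check_full_rank(X: np.ndarray, what: str) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(f"{what} design matrix is rank deficient "
                         f"(rank {rank} < {X.shape[1]} columns)")


def _term_f(
    blocks: dict[str, np.ndarray], y: np.ndarray, term: str
) -> tuple[float, int, int, float, float, float]:
    """Type-III F, dfs, η_p², parametric p and (rss_full, rss_reduced)."""
    if term not in blocks:
        raise ValueError(f"term {term!r} not in model ({list(blocks)})")
    X_full = _stack(blocks)
    X_red = _stack(blocks, drop=term)
    n = y.shape[0]
    _check_full_rank(X_full, "full")
    rss_full = _rss(X_full, y)
    rss_red = _rss(X_red, y)
    df_num = blocks[term].shape[1]
    df_den = n - X_full.shape[1]
    if df_den <= 0:
        raise ValueError("no residual degrees of freedom")
    ss_term = max(rss_red - rss_full, 0.0)
    if rss_full <= 1e-12 * max(1.0, float(y @ y)):
        warnings.warn("degenerate design: residual sum of squares ~ 0")
    F = (ss_term / df_num) / (rss_full / df_den) if rss_full > 0 else np.inf
    eta = ss_term / (ss_term + rss_full) if (ss_term + rss_full) > 0 else 0.0
    p = float(sps.f.sf(F, df_num, df_den)) if np.isfinite(F) else 0.0
    return F, df_num, df_den, eta, p, rss_full


def _model_spec(term: str, factors: tuple[str, ...] | None):
    parts = _term_parts(term)
    interaction = len(parts) > 1
    if factors is None:
        factors = parts
    else:
        factors = tuple(factors)
        missing = set(parts) - set(factors)
        if missing:
            factors = factors + tuple(sorted(missing))
    return factors, interaction


def _adjusted_means(
    blocks: dict[str, np.ndarray],
    data: pd.DataFrame,
    y: np.ndarray,
    factors: tuple[str, ...],
    covariates: tuple[str, ...],
    interaction: bool,
) -> pd.DataFrame:
    """Least-squares (covariate-adjusted) cell means ± SE at covariate means."""
    X = _stack(blocks)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    n, k = X.shape
    sigma2 = _rss(X, y) / (n - k)
    cov_beta = sigma2 * np.linalg.pinv(X.T @ X)
    level_lists = [sorted(pd.unique(data[f]).tolist()) for f in factors]
    cov_means = {c: float(np.mean(data[c])) for c in covariates}
    rows = []
    for cell in itertools.product(*level_lists):
        cell_df = pd.DataFrame({f: [lev] for f, lev in zip(factors, cell)})
        for c in covariates:
            cell_df[c] = cov_means[c]
        coded = {
            f: _sum_code(cell_df[f].to_numpy(),
                         sorted(pd.unique(data[f]).tolist()))
            for f in factors
        }
        cell_blocks = _build_design(cell_df, factors, covariates, interaction,
                                    factor_columns=coded)
        x = _stack(cell_blocks)[0]
        mean = float(x @ beta)
        se = float(np.sqrt(x @ cov_beta @ x))
        rows.append({**dict(zip(factors, cell)), "mean": mean, "se": se})
    return pd.DataFrame(rows)


def glm_term_test(
    outcome: pd.Series | np.ndarray,
    data: pd.DataFrame,
    term: str,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    factors: tuple[str, ...] | None = None,
    outcome_name: str = "outcome",
    with_adjusted_means: bool = True,
) -> StatResult:
    """Type-III GLM F test of one model term with covariate adjustment.

    ``term`` is a factor name (e.g. ``"sex"``) or an interaction
    (``"group:sex"``, which implies both main effects in the model).
    ``factors`` can widen the model beyond the tested term's factors.
    """
    y = np.asarray(outcome, dtype=float)
    factors, interaction = _model_spec(term, factors)
    blocks = _build_design(data, factors, tuple(covariates), interaction)
    F, df1, df2, eta, p, _ = _term_f(blocks, y, term)
    adj = (
        _adjusted_means(blocks, data, y, factors, tuple(covariates), interaction)
        if with_adjusted_means else None
    )
    return StatResult(
        outcome=outcome_name, term=term, F_statistic=F, df_num=df1,
        df_den=df2, partial_eta_sq=eta, p_parametric=p, adjusted_means=adj,
    )


# --------------------------------------------------------------------------
# permutation engine

def _perm_f_label(
    blocks: dict[str, np.ndarray],
    data: pd.DataFrame,
    y: np.ndarray,
    term: str,
    factors: tuple[str, ...],
    perm: np.ndarray,
) -> float:
    """F of ``term`` after permuting that term's factor labels.

    Only the label-derived columns move; covariates (and other factors)
    stay attached to their subjects.  Interaction columns involving the
    permuted factor are rebuilt as products with the permuted block.
    """
    parts = _term_parts(term)
    new_blocks = dict(blocks)
    permuted = {f: blocks[f][perm] for f in parts}
    for f in parts:
        new_blocks[f] = permuted[f]
    for key in blocks:
        if ":" in key:
            a, b = key.split(":")
            ca = permuted.get(a, blocks[a])
            cb = permuted.get(b, blocks[b])
            n = ca.shape[0]
            new_blocks[key] = np.einsum("ni,nj->nij", ca, cb).reshape(n, -1)
    X_full = _stack(new_blocks)
    X_red = _stack(new_blocks, drop=term)
    rss_full = _rss(X_full, y)
    rss_red = _rss(X_red, y)
    df_num = blocks[term].shape[1]
    df_den = y.shape[0] - X_full.shape[1]
    if rss_full <= 0:
        return np.inf
    return (max(rss_red - rss_full, 0.0) / df_num) / (rss_full / df_den)


def _distinct_label_permutations(labels: np.ndarray, limit: int = 50000):
    """All distinct arrangements of a label vector (exact enumeration)."""
    seen = set()
    out = []
    for p in itertools.permutations(range(labels.shape[0])):
        key = tuple(labels[list(p)])
        if key not in seen:
            seen.add(key)
            out.append(np.array(p))
            if len(out) > limit:
                raise ValueError("too many distinct permutations to enumerate")
    return out


def permutation_adjusted_p(
    outcome: pd.Series | np.ndarray,
    data: pd.DataFrame,
    term: str,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    n_perm: int = 10000,
    seed: int = 0,
    factors: tuple[str, ...] | None = None,
    scheme: str = "auto",
    exhaustive: bool = False,
    outcome_name: str = "outcome",
) -> StatResult:
    """Permutation-adjusted p-value for one GLM term.

    ``scheme``: ``"label"`` permutes the term's factor labels (covariates
    stay attached to subjects); ``"freedman_lane"`` permutes residuals of
    the reduced model; ``"auto"`` uses label permutation for main effects
    and Freedman–Lane for interaction terms.  ``exhaustive=True`` replaces
    Monte-Carlo sampling by exact enumeration of all distinct label
    arrangements (p = b / n_total, the observed arrangement included).
    """
    y = np.asarray(outcome, dtype=float)
    factors, interaction = _model_spec(term, factors)
    blocks = _build_design(data, factors, tuple(covariates), interaction)
    F_obs, df1, df2, eta, p_param, rss_full = _term_f(blocks, y, term)
    result = StatResult(
        outcome=outcome_name, term=term, F_statistic=F_obs, df_num=df1,
        df_den=df2, partial_eta_sq=eta, p_parametric=p_param,
        n_perm=n_perm, seed=seed,
    )
    if np.ptp(y) == 0:
        warnings.warn("constant outcome: permutation p set to 1")
        result.p_permutation = 1.0
        return result
    if scheme == "auto":
        scheme = "freedman_lane" if ":" in term else "label"
    rng = np.random.default_rng(seed)
    n = y.shape[0]

    if scheme == "freedman_lane":
        X_red = _stack(blocks, drop=term)
        beta_r, *_ = np.linalg.lstsq(X_red, y, rcond=None)
        fitted = X_red @ beta_r
        resid = y - fitted
        def stat(perm):
            y_star = fitted + resid[perm]
            rss_f = _rss(_stack(blocks), y_star)
            rss_r = _rss(X_red, y_star)
            if rss_f <= 0:
                return np.inf
            return (max(rss_r - rss_f, 0.0) / df1) / (rss_f / df2)
    elif scheme == "label":
        def stat(perm):
            return _perm_f_label(blocks, data, y, term, factors, perm)
    else:
        raise ValueError(f"unknown permutation scheme {scheme!r}")

    if exhaustive:
        labels = data[_term_parts(term)[0]].to_numpy()
        perms = _distinct_label_permutations(labels)
        stats_null = np.array([stat(p) for p in perms])
        p_perm = float(np.sum(stats_null >= F_obs - 1e-12) / len(perms))
        result.n_perm = len(perms)
    else:
        hits = 0
        for _ in range(n_perm):
            if stat(rng.permutation(n)) >= F_obs - 1e-12:
                hits += 1
        p_perm = (hits + 1) / (n_perm + 1)
    result.p_permutation = float(p_perm)
    return result


def interaction_test(
    outcome: pd.Series | np.ndarray,
    data: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    n_perm: int = 10000,
    seed: int = 0,
    factors: tuple[str, ...] = ("group", "sex"),
    outcome_name: str = "outcome",
) -> StatResult:
    """Group-by-sex interaction F, η_p² and Freedman–Lane permutation p."""
    term = f"{factors[0]}:{factors[1]}"
    cells = data.groupby(list(factors), observed=True).size()
    expect = 1
    for f in factors:
        expect *= data[f].nunique()
    if len(cells) < expect:
        raise ValueError("empty group×sex cell(s): interaction not estimable")
    return permutation_adjusted_p(
        outcome, data, term, covariates=covariates, n_perm=n_perm, seed=seed,
        scheme="freedman_lane", outcome_name=outcome_name,
    )


def family_maxstat_pvalues(
    outcomes: dict[str, pd.Series | np.ndarray],
    data: pd.DataFrame,
    term: str,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    n_perm: int = 10000,
    seed: int = 0,
    scheme: str = "auto",
) -> dict[str, StatResult]:
    """Family-wise permutation adjustment via the max statistic.

    One shared stream of permutations is applied to every outcome in the
    family; each permutation contributes its maximum F across outcomes, and
    each outcome's adjusted p compares its observed F to that max-F null.
    """
    factors, interaction = _model_spec(term, None)
    blocks = _build_design(data, factors, tuple(covariates), interaction)
    if scheme == "auto":
        scheme = "freedman_lane" if ":" in term else "label"
    ys = {k: np.asarray(v, dtype=float) for k, v in outcomes.items()}
    results: dict[str, StatResult] = {}
    for name, y in ys.items():
        F, df1, df2, eta, p_param, _ = _term_f(blocks, y, term)
        results[name] = StatResult(
            outcome=name, term=term, F_statistic=F, df_num=df1, df_den=df2,
            partial_eta_sq=eta, p_parametric=p_param, n_perm=n_perm, seed=seed,
        )
    rng = np.random.default_rng(seed)
    n = len(data)
    fl_cache = {}
    if scheme == "freedman_lane":
        X_red = _stack(blocks, drop=term)
        X_full = _stack(blocks)
        for name, y in ys.items():
            beta_r, *_ = np.linalg.lstsq(X_red, y, rcond=None)
            fitted = X_red @ beta_r
            fl_cache[name] = (fitted, y - fitted, X_full, X_red)
    hits = {name: 0 for name in ys}
    df1 = next(iter(results.values())).df_num
    df2 = next(iter(results.values())).df_den
    for _ in range(n_perm):
        perm = rng.permutation(n)
        fmax = -np.inf
        for name, y in ys.items():
            if scheme == "label":
                f = _perm_f_label(blocks, data, y, term, factors, perm)
            else:
                fitted, resid, X_full, X_red = fl_cache[name]
                y_star = fitted + resid[perm]
                rss_f = _rss(X_full, y_star)
                rss_r = _rss(X_red, y_star)
                f = np.inf if rss_f <= 0 else (
                    max(rss_r - rss_f, 0.0) / df1) / (rss_f / df2)
            fmax = max(fmax, f)
        for name in ys:
            if fmax >= results[name].F_statistic - 1e-12:
                hits[name] += 1
    for name in ys:
        results[name].p_permutation = (hits[name] + 1) / (n_perm + 1)
    return results


def groupwise_sex_family(
    outcomes: dict[str, pd.Series | np.ndarray],
    data: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    group_col: str = "group",
    term: str = "sex",
    n_perm: int = 10000,
    seed: int = 0,
) -> dict[tuple[str, str], StatResult]:
    """Per-group sex tests, family-adjusted across every (group, outcome).

    One GLM of ``outcome ~ sex + covariates`` is fitted per diagnostic-group
    subset (the figure-panel convention of separate per-group comparisons);
    all group × outcome tests form one family.  Each permutation shuffles
    the sex labels *within* every group subset (stratified permutation) and
    contributes the maximum F across all tests, giving family-wise adjusted
    p-values via the max statistic.
    """
    ys = {k: np.asarray(v, dtype=float) for k, v in outcomes.items()}
    groups = sorted(pd.unique(data[group_col]).tolist())
    per_group: dict[str, dict] = {}
    results: dict[tuple[str, str], StatResult] = {}
    for g in groups:
        idx = np.flatnonzero((data[group_col] == g).to_numpy())
        sub = data.iloc[idx].reset_index(drop=True)
        blocks = _build_design(sub, (term,), tuple(covariates), False)
        per_group[g] = {"idx": idx, "blocks": blocks, "data": sub}
        for name, y in ys.items():
            F, df1, df2, eta, p_param, _ = _term_f(blocks, y[idx], term)
            results[(g, name)] = StatResult(
                outcome=name, term=term, F_statistic=F, df_num=df1,
                df_den=df2, partial_eta_sq=eta, p_parametric=p_param,
                n_perm=n_perm, seed=seed,
            )
    rng = np.random.default_rng(seed)
    hits = {key: 0 for key in results}
    for _ in range(n_perm):
        fmax = -np.inf
        for g in groups:
            info = per_group[g]
            perm = rng.permutation(info["idx"].size)
            for name, y in ys.items():
                f = _perm_f_label(info["blocks"], info["data"],
                                  y[info["idx"]], term, (term,), perm)
                fmax = max(fmax, f)
        for key, res in results.items():
            if fmax >= res.F_statistic - 1e-12:
                hits[key] += 1
    for key in results:
        results[key].p_permutation = (hits[key] + 1) / (n_perm + 1)
    return results


# --------------------------------------------------------------------------
# correlations

def trimmed_pearson(
    x: pd.Series | np.ndarray,
    y: pd.Series | np.ndarray,
    trim_values: pd.Series | np.ndarray | None = None,
    lower_pct: float = 5.0,
    upper_pct: float = 95.0,
    n_perm: int = 10000,
    seed: int = 0,
    pair: tuple[str, str] = ("x", "y"),
) -> CorrelationResult:
    """Pearson r after trimming on a variable's 5th–95th percentile range.

    Subjects whose ``trim_values`` (default: ``y``) fall outside the
    inclusive [P5, P95] interval (percentiles by linear interpolation) are
    excluded; r is computed on the remainder and its permutation p shuffles
    ``y`` (two-tailed on |r|).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t = y if trim_values is None else np.asarray(trim_values, dtype=float)
    lo, hi = np.percentile(t, [lower_pct, upper_pct])
    keep = (t >= lo) & (t <= hi)
    n_used, n_excluded = int(keep.sum()), int((~keep).sum())
    if n_used < 4:
        raise ValueError("fewer than 4 subjects remain after trimming")
    xk, yk = x[keep], y[keep]
    if np.ptp(xk) == 0 or np.ptp(yk) == 0:
        raise ValueError("zero variance after trimming")
    r, p_param = sps.pearsonr(xk, yk)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        rp = sps.pearsonr(xk, rng.permutation(yk))[0]
        if abs(rp) >= abs(r) - 1e-12:
            hits += 1
    return CorrelationResult(
        pair=pair, r=float(r), n_used=n_used, n_excluded=n_excluded,
        p_parametric=float(p_param), p_permutation=(hits + 1) / (n_perm + 1),
    )
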