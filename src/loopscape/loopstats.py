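"""Interaction-matrix normalization and cross-cell-type variability testing.

The normalization pipeline is: per-row z-scoring, column quantile
normalization (all columns end up sharing one multiset of values), then a
per-column affine rescale to [0, 1000].

Variability testing models the log normalized interaction frequency of each
loop as a function of cell type.  The primary test fits a random-intercept
model (cell type as random effect) by maximum likelihood with
per-observation precision weights and compares it to the intercept-only
model with a likelihood-ratio test; a weighted fixed-effect ANOVA and a
Kruskal-Wallis test are provided as alternates.  Precision weights come
from a voom-style mean-variance trend fitted to log counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .io import SampleSheet

NORM_SCALE = 1000.0


# ---------------------------------------------------------------------------
# filtering and normalization
# ---------------------------------------------------------------------------

def filter_testable(M: pd.DataFrame, min_pets: int = 4) -> pd.DataFrame:
    """Keep loops with at least ``min_pets`` PETs in at least one sample."""
    if min_pets <= 0:
        return M
    return M.loc[M.max(axis=1) >= min_pets]


def zero_variance_rows(M: pd.DataFrame) -> pd.Series:
    """Boolean mask of rows that are constant across samples."""
    arr = M.to_numpy(dtype=float)
    return pd.Series(arr.std(axis=1) == 0.0, index=M.index)


def _quantile_normalize_columns(X: np.ndarray) -> np.ndarray:
    """Replace each column's values by cross-column mean reference values.

    The rank-r entry of every column becomes the mean of the rank-r values
    across columns; tied entries within a column receive the mean of the
    reference values at their tied ranks.
    """
    n, m = X.shape
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X, dtype=float)
    for j in range(m):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        sorted_col = col[order]
        assigned = ref.copy()
        # average reference values over runs of tied observations
        i = 0
        while i < n:
            k = i + 1
            while k < n and sorted_col[k] == sorted_col[i]:
                k += 1
            if k - i > 1:
                assigned[i:k] = ref[i:k].mean()
            i = k
        out[order, j] = assigned
    return out


def normalize_matrix(M: pd.DataFrame) -> pd.DataFrame:
    """Row-standardize, quantile-normalize columns, rescale columns to [0, 1000]."""
    if M.shape[1] < 2:
        raise ValueError("normalization needs at least 2 samples")
    X = M.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    if (sd == 0).any():
        raise ValueError("zero-variance rows must be removed before normalization")
    Z = (X - mu) / sd
    Q = _quantile_normalize_columns(Z)
    lo = Q.min(axis=0, keepdims=True)
    hi = Q.max(axis=0, keepdims=True)
    if np.any(hi == lo):
        raise ValueError("degenerate column after quantile normalization")
    R = (Q - lo) / (hi - lo) * NORM_SCALE
    return pd.DataFrame(R, index=M.index, columns=M.columns)


# ---------------------------------------------------------------------------
# voom-style precision weights
# ---------------------------------------------------------------------------

def voom_weights(
    M_raw: pd.DataFrame,
    samples: SampleSheet,
    lowess_frac: float = 0.5,
    min_rows: int = 50,
) -> pd.DataFrame:
    """Per-observation inverse-variance weights from a mean-variance trend.

    Counts are transformed to log2(count + 0.5); per-loop residual standard
    deviations about the cell-type means are computed, a lowess trend of
    sqrt(sd) against mean log-count is fitted, and each observation gets
    weight 1 / predicted_sqrt_sd**4 evaluated at its fitted log-count.
    Falls back to unit weights (with a warning) below ``min_rows`` loops.
    """
    if len(M_raw) < min_rows:
        warnings.warn(f"too few loops ({len(M_raw)}) to fit a mean-variance trend; using unit weights")
        return pd.DataFrame(1.0, index=M_raw.index, columns=M_raw.columns)
    cell_of = samples.cell_type_of()
    groups = np.array([cell_of[s] for s in M_raw.columns])
    Y = np.log2(M_raw.to_numpy(dtype=float) + 0.5)
    n, m = Y.shape
    fitted = np.empty_like(Y)
    uniq = np.unique(groups)
    k = len(uniq)
    for g in uniq:
        cols = groups == g
        fitted[:, cols] = Y[:, cols].mean(axis=1, keepdims=True)
    dof = max(m - k, 1)
    resid_sd = np.sqrt(((Y - fitted) ** 2).sum(axis=1) / dof)
    mean_log = Y.mean(axis=1)
    trend = lowess(np.sqrt(resid_sd), mean_log, frac=lowess_frac, return_sorted=True)
    tx, ty = trend[:, 0], trend[:, 1]
    pred = np.interp(fitted, tx, ty)
    pred = np.clip(pred, 1e-4, None)
    W = pred ** -4
    return pd.DataFrame(W, index=M_raw.index, columns=M_raw.columns)


# ---------------------------------------------------------------------------
# variability testing
# ---------------------------------------------------------------------------

def _lmm_loglik_parts(y, w, group_codes, n_groups, theta):
    """Profile ML log-likelihood of the weighted random-intercept model.

    theta is the ratio of random-intercept variance to residual variance.
    Returns the maximized log-likelihood (over the intercept and residual
    variance) at the given theta.
    """
    n = len(y)
    sw = np.bincount(group_codes, weights=w, minlength=n_groups)
    swy = np.bincount(group_codes, weights=w * y, minlength=n_groups)
    denom = 1.0 + theta * sw
    mu = (swy / denom).sum() / (sw / denom).sum()
    r = y - mu
    swr = np.bincount(group_codes, weights=w * r, minlength=n_groups)
    swr2 = np.bincount(group_codes, weights=w * r * r, minlength=n_groups)
    quad = (swr2 - theta * swr**2 / denom).sum()
    sigma2 = quad / n
    # constant term sum(log 1/w) cancels in the LRT but is kept for honesty
    logdet = np.log(denom).sum() - np.log(w).sum()
    return -0.5 * (n * np.log(2 * np.pi * sigma2) + n + logdet)


def _lmm_lrt_single(y, w, group_codes, n_groups, theta_grid):
    ll0 = _lmm_loglik_parts(y, w, group_codes, n_groups, 0.0)
    best_ll, best_theta = ll0, 0.0
    for th in theta_grid:
        ll = _lmm_loglik_parts(y, w, group_codes, n_groups, th)
        if ll > best_ll:
            best_ll, best_theta = ll, th
    if best_theta > 0.0:
        lo = best_theta / 4.0
        hi = best_theta * 4.0
        res = optimize.minimize_scalar(
            lambda th: -_lmm_loglik_parts(y, w, group_codes, n_groups, th),
            bounds=(lo, hi), method="bounded",
        )
        if -res.fun > best_ll:
            best_ll = -res.fun
    return max(0.0, 2.0 * (best_ll - ll0))


_THETA_GRID = np.concatenate([[0.01], np.geomspace(0.05, 200.0, 24)])


def _weighted_anova(Y, W, group_codes, n_groups):
    """Vectorized weighted one-way ANOVA F-test per row."""
    n = Y.shape[1]
    sw = np.zeros((Y.shape[0], n_groups))
    swy = np.zeros_like(sw)
    swy2 = np.zeros_like(sw)
    for g in range(n_groups):
        cols = group_codes == g
        sw[:, g] = W[:, cols].sum(axis=1)
        swy[:, g] = (W[:, cols] * Y[:, cols]).sum(axis=1)
        swy2[:, g] = (W[:, cols] * Y[:, cols] ** 2).sum(axis=1)
    tot_w = sw.sum(axis=1)
    tot_wy = swy.sum(axis=1)
    tot_wy2 = swy2.sum(axis=1)
    rss0 = tot_wy2 - tot_wy**2 / tot_w
    rss1 = (swy2 - swy**2 / np.where(sw > 0, sw, np.nan)).sum(axis=1)
    df1 = n_groups - 1
    df2 = n - n_groups
    with np.errstate(invalid="ignore", divide="ignore"):
        F = ((rss0 - rss1) / df1) / (rss1 / df2)
    p = stats.f.sf(F, df1, df2)
    return F, p


@dataclass
class VariabilityResult:
    table: pd.DataFrame  # columns: p, q, method
    variable_ids: pd.Index
    n_failed: int = 0


def test_variability(
    normM: pd.DataFrame,
    samples: SampleSheet,
    weights: pd.DataFrame | None = None,
    method: str = "lmm_lrt",
    fdr: float = 0.10,
    boundary_mixture: bool = False,
) -> VariabilityResult:
    """Test each loop for interaction-frequency differences across cell types.

    ``normM`` holds normalized interaction frequencies; the response is
    log(value + 1).  Methods:

    * ``lmm_lrt`` - weighted random-intercept (cell type) model vs
      intercept-only model, likelihood-ratio test against chi2(1) (or the
      50:50 chi2(0)/chi2(1) boundary mixture when ``boundary_mixture``).
    * ``lm_anova`` - weighted fixed-effect one-way ANOVA F-test.
    * ``kruskal``  - Kruskal-Wallis rank test (unweighted).
    """
    if method not in ("lmm_lrt", "lm_anova", "kruskal"):
        raise ValueError(f"unknown method {method!r}")
    cell_of = samples.cell_type_of()
    groups = np.array([cell_of[s] for s in normM.columns])
    uniq, group_codes = np.unique(groups, return_inverse=True)
    n_groups = len(uniq)
    counts = np.bincount(group_codes)
    if (counts < 2).any():
        raise ValueError("every cell type needs at least 2 samples")
    Y = np.log(normM.to_numpy(dtype=float) + 1.0)
    if weights is None:
        W = np.ones_like(Y)
    else:
        W = weights.reindex(index=normM.index, columns=normM.columns).to_numpy(dtype=float)

    constant = Y.std(axis=1) == 0.0  # no variation: no evidence of difference
    n_failed = 0
    if method == "lmm_lrt":
        p = np.empty(len(Y))
        for i in range(len(Y)):
            if constant[i]:
                p[i] = 1.0
                continue
            try:
                lrt = _lmm_lrt_single(Y[i], W[i], group_codes, n_groups, _THETA_GRID)
            except (FloatingPointError, ZeroDivisionError, ValueError):
                p[i] = np.nan
                n_failed += 1
                continue
            if boundary_mixture:
                p[i] = 0.5 * stats.chi2.sf(lrt, 1) if lrt > 0 else 1.0
            else:
                p[i] = stats.chi2.sf(lrt, 1)
    elif method == "lm_anova":
        _, p = _weighted_anova(Y, W, group_codes, n_groups)
        p = np.where(constant, 1.0, p)
    else:
        p = np.empty(len(Y))
        for i in range(len(Y)):
            if constant[i]:
                p[i] = 1.0
                continue
            groups_vals = [Y[i, group_codes == g] for g in range(n_groups)]
            try:
                p[i] = stats.kruskal(*groups_vals).pvalue
            except ValueError:  # all values identical
                p[i] = 1.0
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    n_failed += int((~ok).sum()) if method != "lmm_lrt" else 0
    if ok.any():
        _, q_ok, _, _ = multipletests(p[ok], method="fdr_bh")
        q[ok] = q_ok
    table = pd.DataFrame({"p": p, "q": q, "method": method}, index=normM.index)
    variable_ids = table.index[np.nan_to_num(q, nan=1.0) < fdr]
    return VariabilityResult(table=table, variable_ids=variable_ids, n_failed=n_failed)


# ---------------------------------------------------------------------------
# relative entropy and static (non-variable) loop sets
# ---------------------------------------------------------------------------

def relative_entropy(values, reference=None) -> float:
    """Relative entropy (bits) of a non-negative vector vs a reference.

    The vector is converted to fractions f_j; the default reference is the
    uniform distribution.  0 * log 0 is taken as 0.  Bounded by log2(J).
    """
    v = np.asarray(values, dtype=float)
    if (v < 0).any():
        raise ValueError("values must be non-negative")
    total = v.sum()
    if total <= 0:
        raise ValueError("all-zero input has no entropy")
    f = v / total
    if reference is None:
        q = np.full(len(v), 1.0 / len(v))
    else:
        q = np.asarray(reference, dtype=float)
        q = q / q.sum()
    nz = f > 0
    return float(np.sum(f[nz] * np.log2(f[nz] / q[nz])))


def relative_entropy_rows(M: pd.DataFrame) -> pd.Series:
    """Row-wise relative entropy against the uniform reference (bits)."""
    X = M.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("values must be non-negative")
    tot = X.sum(axis=1, keepdims=True)
    if (tot <= 0).any():
        raise ValueError("all-zero row has no entropy")
    F = X / tot
    J = X.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(F > 0, F * np.log2(F * J), 0.0)
    return pd.Series(terms.sum(axis=1), index=M.index)


def static_score(M_raw: pd.DataFrame) -> pd.DataFrame:
    """Static score = mean PET frequency / relative entropy per loop.

    Loops with zero relative entropy (perfectly uniform) rank above all
    others, ordered among themselves by mean frequency descending.
    """
    re = relative_entropy_rows(M_raw)
    mean_freq = M_raw.mean(axis=1)
    with np.errstate(divide="ignore"):
        score = mean_freq / re
    return pd.DataFrame({"relative_entropy": re, "mean_frequency": mean_freq, "static_score": score})


def static_sets(
    M_raw: pd.DataFrame,
    variable_ids,
    spans: pd.Series | None = None,
    loop_p: pd.Series | None = None,
    variability_q: pd.Series | None = None,
    mode: str = "score_ranked",
    seed: int = 0,
    n_deciles: int = 10,
) -> pd.Index:
    """Select a non-variable (static) control loop set of |variable_ids| loops.

    ``score_ranked`` ranks all loops by the static score (uniform loops
    first, then descending mean/entropy ratio) and takes the top set.
    ``matched`` samples from loops with variability FDR > 0.5, matching the
    variable set's joint (span decile x loop-score-p decile) distribution.
    """
    variable_ids = pd.Index(variable_ids)
    n_target = len(variable_ids)
    if mode == "score_ranked":
        tab = static_score(M_raw)
        zero_re = tab["relative_entropy"] == 0
        order_key = pd.DataFrame({
            "zero": (~zero_re).astype(int),  # uniform loops first
            "score": -tab["static_score"].where(~zero_re, -np.inf),
            "mean": -tab["mean_frequency"],
        }, index=tab.index)
        ranked = order_key.sort_values(["zero", "score", "mean"]).index
        return ranked[:n_target]
    if mode != "matched":
        raise ValueError(f"unknown mode {mode!r}")
    if spans is None or loop_p is None or variability_q is None:
        raise ValueError("matched mode needs spans, loop_p and variability_q")
    idx = M_raw.index
    span_dec = pd.qcut(spans.loc[idx], n_deciles, labels=False, duplicates="drop")
    p_dec = pd.qcut(loop_p.loc[idx].rank(method="first"), n_deciles, labels=False, duplicates="drop")
    cells = pd.DataFrame({"span_dec": span_dec, "p_dec": p_dec}, index=idx)
    candidates = idx[(variability_q.loc[idx] > 0.5).to_numpy()]
    rng = np.random.default_rng(seed)
    chosen = []
    deficits = []
    var_cells = cells.loc[cells.index.isin(variable_ids)]
    for (sd, pdec), grp in var_cells.groupby(["span_dec", "p_dec"]):
        need = len(grp)
        pool = cells.index[
            (cells["span_dec"] == sd) & (cells["p_dec"] == pdec) & cells.index.isin(candidates)
        ]
        if len(pool) < need:
            deficits.append(((sd, pdec), need, len(pool)))
            continue
        pick = rng.choice(len(pool), size=need, replace=False)
        chosen.extend(pool[np.sort(pick)])
    if deficits:
        raise ValueError(f"matched sampling infeasible in strata: {deficits}")
    return pd.Index(chosen)


def classify_genes_entropy(
    expression: pd.DataFrame,
    min_expr_tpm: float = 1.0,
    tail: float = 0.10,
) -> dict:
    """Split genes into housekeeping and cell-type-specific sets by entropy.

    Relative entropy across cell types is computed for every gene; the top
    ``tail`` fraction is cell-type-specific and the bottom tail, restricted
    to genes whose minimum expression exceeds ``min_expr_tpm``, is
    housekeeping.  Each set holds floor(tail * n_genes) genes.
    """
    expr = expression.loc[expression.sum(axis=1) > 0]
    if len(expr) < 10:
        raise ValueError("fewer than 10 genes available for entropy ranking")
    re = relative_entropy_rows(expr)
    n_take = int(np.floor(tail * len(re)))
    order = re.sort_values(ascending=False, kind="mergesort")
    specific = order.index[:n_take]
    passes = expr.min(axis=1) > min_expr_tpm
    bottom_up = order.index[::-1]
    hk = [g for g in bottom_up if passes.loc[g]][:n_take]
    return {
        "cell_type_specific": pd.Index(specific),
        "housekeeping": pd.Index(hk),
        "relative_entropy": re,
    }


# ---------------------------------------------------------------------------
# sample similarity and PCA
# ---------------------------------------------------------------------------

def sample_similarity(
    M_raw: pd.DataFrame,
    samples: SampleSheet,
    extra_groupings: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman correlations between all sample pairs, compared by grouping.

    Built-in groupings: ``all`` (pairs of different cell types), ``same_group``
    (same sample group, replicates included) and ``replicates`` (same cell
    type).  ``extra_groupings`` maps a name to a set of frozenset sample-id
    pairs.  Each non-'all' grouping is compared to 'all' with a two-sided
    rank-sum test, Bonferroni-adjusted.
    """
    ids = [s for s in samples.sample_ids if s in M_raw.columns]
    X = M_raw[ids].to_numpy(dtype=float)
    rho = stats.spearmanr(X).statistic
    if np.isscalar(rho):  # two samples
        rho = np.array([[1.0, rho], [rho, 1.0]])
    cell_of = samples.cell_type_of()
    group_of = samples.group_of()
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            rows.append((ids[i], ids[j], rho[i, j]))
    pairs = pd.DataFrame(rows, columns=["sample_1", "sample_2", "spearman_rho"])
    same_cell = pairs.apply(lambda r: cell_of[r.sample_1] == cell_of[r.sample_2], axis=1)
    same_group = pairs.apply(lambda r: group_of[r.sample_1] == group_of[r.sample_2], axis=1)
    groupings = {
        "all": ~same_cell,
        "same_group": same_group,
        "replicates": same_cell,
    }
    for name, pairset in (extra_groupings or {}).items():
        groupings[name] = pairs.apply(
            lambda r: frozenset((r.sample_1, r.sample_2)) in pairset, axis=1
        )
    base = pairs.loc[groupings["all"], "spearman_rho"]
    comps = []
    names = [n for n in groupings if n != "all"]
    for name in names:
        vals = pairs.loc[groupings[name], "spearman_rho"]
        if len(vals) < 2 or len(base) < 2:
            warnings.warn(f"grouping {name!r} has too few pairs; skipped")
            continue
        stat = stats.mannwhitneyu(vals, base, alternative="two-sided")
        comps.append((name, len(vals), float(vals.median()), stat.pvalue))
    comp_df = pd.DataFrame(comps, columns=["grouping", "n_pairs", "median_rho", "p"])
    if len(comp_df):
        comp_df["p_bonferroni"] = np.minimum(comp_df["p"] * len(comp_df), 1.0)
    pairs["same_cell_type"] = same_cell
    pairs["same_group"] = same_group
    return pairs, comp_df


def pca_and_confounders(
    normM: pd.DataFrame,
    samples: SampleSheet,
    covariates: pd.DataFrame | None = None,
    n_pcs: int = 10,
) -> dict:
    """PCA of samples in loop space plus covariate-association testing.

    Samples are observations.  For each (PC, covariate) pair a one-way linear
    model F-test is computed (categorical covariates become factors), with BH
    adjustment across all pairs.  Constant covariates are skipped.
    """
    from sklearn.decomposition import PCA

    ids = [s for s in samples.sample_ids if s in normM.columns]
    X = normM[ids].to_numpy(dtype=float).T  # samples x loops
    n_pcs = int(min(n_pcs, len(ids) - 1, X.shape[1]))
    pca = PCA(n_components=n_pcs, svd_solver="full")
    scores = pca.fit_transform(X - X.mean(axis=0, keepdims=True))
    emb = pd.DataFrame(scores, index=ids, columns=[f"PC{i+1}" for i in range(n_pcs)])
    varfrac = pd.Series(pca.explained_variance_ratio_, index=emb.columns)
    assoc = []
    if covariates is not None:
        import statsmodels.api as sm

        cov = covariates.loc[ids]
        for cname in cov.columns:
            col = cov[cname]
            if col.nunique() < 2:
                warnings.warn(f"covariate {cname!r} is constant; skipped")
                continue
            if col.dtype == object or str(col.dtype) == "category":
                design = pd.get_dummies(col, drop_first=True).astype(float)
            else:
                design = col.to_frame().astype(float)
            Xd = sm.add_constant(design.to_numpy())
            for pc in emb.columns:
                fit = sm.OLS(emb[pc].to_numpy(), Xd).fit()
                assoc.append((pc, cname, float(fit.f_pvalue)))
    assoc_df = pd.DataFrame(assoc, columns=["pc", "covariate", "p"])
    if len(assoc_df):
        _, q, _, _ = multipletests(assoc_df["p"], method="fdr_bh")
        assoc_df["q"] = q
    return {"embedding": emb, "variance_fraction": varfrac, "associations": assoc_df}
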