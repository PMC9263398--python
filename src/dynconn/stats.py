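"""Group inference: covariate-adjusted contrasts, dual-family FDR, the
network-based statistic (NBS), and clinical partial correlations.

The group contrast is a Gaussian-identity GLM (ordinary least squares) of the
metric on group plus covariates (age, sex, education, mean frame
displacement), with a two-sided Wald t test on the group coefficient.  With
exactly two groups the Tukey post-hoc comparison coincides with this test; a
Tukey HSD branch exists for more than two labels.

Multiple comparisons are handled by Benjamini-Hochberg FDR in two families:
whole-brain (all analysis ROIs at once) and network-wise (ROIs sharing a
network label corrected separately).

NBS controls family-wise error over connected components of suprathreshold
edges: per-edge GLM t statistics are thresholded at the two-sided critical
value for the primary p, components are formed through shared ROI endpoints,
and observed component sizes (edge counts) are referred to the permutation
distribution of the maximal null component size obtained by permuting group
labels while keeping covariates attached to subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy import sparse, stats as sps
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.multitest import multipletests

DEFAULT_COVARIATES = ("age", "sex", "education", "mean_fd")
ALPHA_PRIMARY = 0.005
ALPHA_MARGINAL = 0.01

#: Dummy coding of the phenotype factors used in design matrices.
SEX_CODES = {"female": 1.0, "male": 0.0}
GROUP_CODES = {"SCD": 1.0, "NC": 0.0}


def encode_sex(values: pd.Series) -> np.ndarray:
    if values.dtype.kind in "ifu":
        return values.to_numpy(dtype=float)
    return values.map(SEX_CODES).to_numpy(dtype=float)


def build_design(phenotypes: pd.DataFrame,
                 covariates: tuple[str, ...] = DEFAULT_COVARIATES) -> tuple[np.ndarray, list[str]]:
    """Design matrix [intercept, group(SCD=1), covariates...] and column names."""
    n = len(phenotypes)
    cols = [np.ones(n), phenotypes["group"].map(GROUP_CODES).to_numpy(float)]
    names = ["intercept", "group"]
    for cov in covariates:
        col = encode_sex(phenotypes[cov]) if cov == "sex" else phenotypes[cov].to_numpy(float)
        cols.append(col)
        names.append(cov)
    return np.column_stack(cols), names


def _check_design(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        collinear = [names[j] for j in range(X.shape[1])
                     if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {collinear}")


def _ols_group_t(X: np.ndarray, Y: np.ndarray, group_col: int = 1
                 ) -> tuple[np.ndarray, np.ndarray, int]:
    """Vectorized OLS of every column of Y on X; returns (beta_g, t_g, dof)."""
    n, p = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)
    resid = Y - X @ beta
    dof = n - p
    sigma2 = (resid * resid).sum(axis=0) / dof
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[group_col, group_col], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[group_col] / se, 0.0)
    return beta[group_col], t, dof


def significance_tier(p: np.ndarray,
                      alpha_primary: float = ALPHA_PRIMARY,
                      alpha_marginal: float = ALPHA_MARGINAL) -> np.ndarray:
    """Partition raw p-values into {significant, marginal, none}."""
    p = np.asarray(p, dtype=float)
    tier = np.where(p < alpha_primary, "significant",
                    np.where(p < alpha_marginal, "marginal", "none"))
    return tier


def fit_group_glm(values: np.ndarray | pd.DataFrame, phenotypes: pd.DataFrame,
                  covariates: tuple[str, ...] = DEFAULT_COVARIATES) -> pd.DataFrame:
    """Covariate-adjusted group contrast for one or many metrics.

    ``values`` is (n_subjects,) or (n_subjects, n_metrics), subject order
    matching ``phenotypes`` rows.  Returns a DataFrame with one row per metric
    column: ``beta_group`` (SCD minus NC in metric units), ``t_stat``,
    ``p_raw`` and ``tier``.
    """
    counts = phenotypes["group"].value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"group(s) with fewer than 2 subjects: {list(small.index)}")
    if phenotypes["group"].nunique() > 2:
        raise ValueError("more than two group labels; use tukey_posthoc for pairwise tests")
    X, names = build_design(phenotypes, covariates)
    _check_design(X, names)
    Y = np.asarray(values, dtype=float)
    squeeze = Y.ndim == 1
    Y = Y[:, None] if squeeze else Y
    if Y.shape[0] != len(phenotypes):
        raise ValueError("values rows must match phenotype rows")
    beta, t, dof = _ols_group_t(X, Y)
    p = 2 * sps.t.sf(np.abs(t), dof)
    return pd.DataFrame({
        "beta_group": beta, "t_stat": t, "p_raw": p, "dof": dof,
        "tier": significance_tier(p),
    })


def tukey_posthoc(values: np.ndarray, groups: pd.Series):
    """Tukey HSD over >2 group labels (unadjusted for covariates)."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    return pairwise_tukeyhsd(np.asarray(values, float), np.asarray(groups))


def fdr_correct(p_values: np.ndarray, families: np.ndarray | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, independently per family.

    ``families`` labels each p-value; ``None`` treats all values as one
    family.  Empty families are skipped with a warning (NaN p-values are
    propagated as NaN q-values).
    """
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    fam = np.zeros(p.shape, dtype=object) if families is None else np.asarray(families, object)
    for label in pd.unique(fam):
        sel = (fam == label) & ~np.isnan(p)
        if not sel.any():
            warnings.warn(f"FDR family {label!r} is empty; skipped")
            continue
        q[sel] = multipletests(p[sel], method="fdr_bh")[1]
    return q


def contrast_table(metric_table: pd.DataFrame, phenotypes: pd.DataFrame,
                   atlas, value_col: str,
                   covariates: tuple[str, ...] = DEFAULT_COVARIATES) -> pd.DataFrame:
    """Per-ROI group contrast of one mdALFF column with dual-family FDR.

    ``metric_table`` is tidy (subject_id, roi_id, <value_col>).  Output has a
    row per ROI with beta/t/p, ``q_wholebrain`` (BH over all ROIs) and
    ``q_network`` (BH within each network label).
    """
    wide = metric_table.pivot(index="subject_id", columns="roi_id", values=value_col)
    wide = wide.loc[phenotypes["subject_id"]]
    res = fit_group_glm(wide.to_numpy(), phenotypes, covariates)
    res.insert(0, "roi_id", wide.columns.to_numpy(int))
    res.insert(1, "metric", value_col)
    net = atlas.network_of()
    res["network"] = res["roi_id"].map(net)
    res["q_wholebrain"] = fdr_correct(res["p_raw"].to_numpy())
    res["q_network"] = fdr_correct(res["p_raw"].to_numpy(), res["network"].to_numpy())
    return res


@dataclass
class NbsResult:
    """Connected components of the suprathreshold contrast graph.

    ``p_fwe`` follows the permutation formula
    (1 + #{null max size >= observed size}) / (1 + n_permutations).
    """

    components: list[list[tuple[int, int]]]
    component_sizes: list[int]
    p_fwe: list[float]
    n_permutations: int
    primary_threshold: float
    edge_t: np.ndarray = field(repr=False, default=None)
    all_suprathreshold: bool = False

    def significant(self, alpha: float = 0.05) -> list[list[tuple[int, int]]]:
        return [c for c, p in zip(self.components, self.p_fwe) if p < alpha]


def _components_from_edges(edges: np.ndarray, mask: np.ndarray
                           ) -> tuple[list[list[int]], list[int]]:
    """Component membership (edge indices) of the suprathreshold subgraph."""
    sup = np.flatnonzero(mask)
    if sup.size == 0:
        return [], []
    sub = edges[sup]
    nodes, inv = np.unique(sub, return_inverse=True)
    inv = inv.reshape(sub.shape)
    adj = sparse.coo_matrix(
        (np.ones(len(sub)), (inv[:, 0], inv[:, 1])), shape=(len(nodes), len(nodes)))
    n_comp, labels = connected_components(adj, directed=False)
    comp_edges: list[list[int]] = [[] for _ in range(n_comp)]
    for e_idx, (u, _v) in zip(sup, inv):
        comp_edges[labels[u]].append(int(e_idx))
    sizes = [len(c) for c in comp_edges]
    return comp_edges, sizes


def _max_component_size(edges: np.ndarray, mask: np.ndarray) -> int:
    _, sizes = _components_from_edges(edges, mask)
    return max(sizes) if sizes else 0


def nbs_test(edge_values: np.ndarray, edges: list[tuple[int, int]],
             phenotypes: pd.DataFrame, n_perm: int = 1000,
             primary_p: float = 0.005,
             covariates: tuple[str, ...] = DEFAULT_COVARIATES,
             rng: np.random.Generator | int | None = None) -> NbsResult:
    """Network-based statistic permutation test on a subject x edge matrix.

    ``edges`` gives the (roi_u, roi_v) endpoints of each column.  Group labels
    are permuted across subjects while covariate rows stay attached to their
    subjects; the null statistic is the maximal component size (edge count).
    """
    rng = np.random.default_rng(rng)
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very low; family-wise p-values will be coarse")
    Y = np.asarray(edge_values, dtype=float)
    edge_arr = np.asarray(edges, dtype=int)
    if Y.shape[1] != len(edge_arr):
        raise ValueError("edge_values columns must match the edge list")

    X, names = build_design(phenotypes, covariates)
    _check_design(X, names)
    _, t_obs, dof = _ols_group_t(X, Y)
    t_crit = sps.t.isf(primary_p / 2, dof)

    obs_mask = np.abs(t_obs) >= t_crit
    all_sup = bool(obs_mask.all())
    comps_idx, sizes = _components_from_edges(edge_arr, obs_mask)

    group = X[:, 1].copy()
    null_max = np.empty(n_perm)
    Xp = X.copy()
    for b in range(n_perm):
        Xp[:, 1] = rng.permutation(group)
        _, t_b, _ = _ols_group_t(Xp, Y)
        null_max[b] = _max_component_size(edge_arr, np.abs(t_b) >= t_crit)

    p_fwe = [(1 + int((null_max >= s).sum())) / (1 + n_perm) for s in sizes]
    components = [[tuple(edge_arr[e]) for e in comp] for comp in comps_idx]
    return NbsResult(components=components, component_sizes=sizes, p_fwe=p_fwe,
                     n_permutations=n_perm, primary_threshold=float(t_crit),
                     edge_t=t_obs, all_suprathreshold=all_sup)


def _residualize(v: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    n = len(v)
    X = np.ones((n, 1)) if covariates is None or np.size(covariates) == 0 \
        else np.column_stack([np.ones(n), covariates])
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


def partial_correlation(x: np.ndarray, y: np.ndarray,
                        covariates: np.ndarray | None = None) -> tuple[float, float]:
    """Partial Pearson correlation of x and y given covariate columns.

    Both variables are residualized on [intercept, covariates]; the p-value
    uses t = r*sqrt((n-2-k)/(1-r^2)) with n-2-k degrees of freedom.  With no
    covariates this is the ordinary Pearson correlation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if covariates is None or np.size(covariates) == 0:
        covariates, k = None, 0
    else:
        covariates = np.asarray(covariates, float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        k = covariates.shape[1]
    if n <= k + 3:
        raise ValueError(f"need n > k + 3 subjects (n={n}, k={k})")
    rx = _residualize(x, covariates)
    ry = _residualize(y, covariates)
    sx, sy = rx.std(), ry.std()
    tol_x = 1e-10 * max(x.std(), 1e-300)
    tol_y = 1e-10 * max(y.std(), 1e-300)
    if sx <= tol_x or sy <= tol_y:
        raise ValueError("zero residual variance; partial correlation undefined")
    r = float(np.clip((rx * ry).mean() / (sx * sy), -1.0, 1.0))
    dof = n - 2 - k
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(dof / (1 - r * r))
    p = 2 * sps.t.sf(abs(t), dof)
    return r, float(p)


def compare_correlations_fisher(r1: float, n1: int, r2: float, n2: int,
                                k: int = 0, alternative: str = "two-sided"
                                ) -> tuple[float, float]:
    """Compare two (partial) correlations via Fisher's Z.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3-k) + 1/(n2-3-k)); the default
    is a two-sided normal p-value, with ``alternative`` in
    {"two-sided", "greater", "less"} for one-sided use.
    """
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise ValueError("|r| must be < 1 for Fisher's Z")
    d1, d2 = n1 - 3 - k, n2 - 3 - k
    if d1 <= 0 or d2 <= 0:
        raise ValueError(f"insufficient sample size for k={k} covariates (n1={n1}, n2={n2})")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / d1 + 1.0 / d2)
    if alternative == "two-sided":
        p = 2 * sps.norm.sf(abs(z))
    elif alternative == "greater":
        p = sps.norm.sf(z)
    elif alternative == "less":
        p = sps.norm.cdf(z)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(z), float(p)


def correlation_grid(metric_table: pd.DataFrame, phenotypes: pd.DataFrame,
                     rois: list[int], scores: list[str],
                     metrics: tuple[str, ...] = ("mdalff_mean", "mdalff_var"),
                     covariates: tuple[str, ...] = DEFAULT_COVARIATES,
                     alternative: str = "two-sided") -> pd.DataFrame:
    """Clinical partial-correlation grid with group split and Fisher comparison.

    For every (ROI, metric, score) cell: the all-subject partial correlation
    (FDR over the full grid, one family), the per-group correlations, and the
    Fisher-Z group comparison (its own FDR family).
    """
    C = np.column_stack([
        encode_sex(phenotypes[c]) if c == "sex" else phenotypes[c].to_numpy(float)
        for c in covariates]) if covariates else None
    k = 0 if C is None else C.shape[1]
    is_scd = (phenotypes["group"] == "SCD").to_numpy()

    rows = []
    for metric in metrics:
        wide = metric_table.pivot(index="subject_id", columns="roi_id", values=metric)
        wide = wide.loc[phenotypes["subject_id"]]
        for roi in rois:
            x = wide[roi].to_numpy(float)
            for score in scores:
                y = phenotypes[score].to_numpy(float)
                r_all, p_all = partial_correlation(x, y, C)
                r_s, _ = partial_correlation(x[is_scd], y[is_scd],
                                             None if C is None else C[is_scd])
                r_n, _ = partial_correlation(x[~is_scd], y[~is_scd],
                                             None if C is None else C[~is_scd])
                z, p_z = compare_correlations_fisher(
                    r_s, int(is_scd.sum()), r_n, int((~is_scd).sum()), k=k,
                    alternative=alternative)
                rows.append((roi, metric, score, r_all, p_all, r_s, r_n, z, p_z))
    out = pd.DataFrame(rows, columns=[
        "roi_id", "metric", "score", "r_all", "p_all", "r_scd", "r_nc",
        "group_diff_z", "group_diff_p"])
    out["q_fdr"] = fdr_correct(out["p_all"].to_numpy())
    out["group_diff_q"] = fdr_correct(out["group_diff_p"].to_numpy())
    out["dof"] = len(phenotypes) - 2 - k
    return out
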