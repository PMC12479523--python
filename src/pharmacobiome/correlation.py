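"""Microbe-gene and metabolite-gene association tables and gene signatures.

Associations between a feature matrix (taxa relative abundances or
metabolite intensities) and a host expression matrix are measured with
Spearman rank correlation; when covariates are supplied (the
Lactobacillus-dominance indicator for metabolite-gene associations), the
partial Spearman correlation is used instead: all variables are midrank
transformed, the covariates' least-squares contribution is removed from both
ranked variables, and the residuals are Pearson-correlated.

P-values come from the asymptotic t approximation
``t = rho * sqrt(df / (1 - rho^2))`` on ``df = n - 2 - k`` degrees of
freedom (``k`` = number of covariates, 0 for plain Spearman), two-sided.
Within each feature, p-values are Benjamini-Hochberg adjusted across genes,
and genes with adjusted p <= alpha form the feature's up (rho > 0) and down
(rho < 0) signature.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    CORRELATION_COLUMNS,
    CovariateTable,
    GeneSignature,
    OmicsMatrix,
    PharmacobiomeError,
    normalize_gene_id,
)

logger = logging.getLogger("pharmacobiome")


class UndefinedCorrelationError(PharmacobiomeError):
    """A vector is constant after missing-value filtering."""


class CollinearityError(PharmacobiomeError):
    """The covariate matrix is rank-deficient after rank transformation."""


@dataclass
class CorrelationConfig:
    """Settings for the association stage.

    alpha
        Significance threshold on the BH-adjusted p-value (default 0.05).
    adjust_scope
        BH family definition: ``"per_feature"`` adjusts each feature's gene
        p-values as one family (one family per microbe/metabolite, matching
        the per-feature gene-list framing); ``"global"`` adjusts all
        (feature, gene) pairs together.
    min_pairs
        Minimum number of complete observation pairs for a record (>= 3).
    covariate_names
        Covariate columns for partial correlation; empty means plain
        Spearman.
    exact_small_n
        Use exact permutation p-values for plain Spearman when n <= 9.
    """

    alpha: float = 0.05
    adjust_scope: str = "per_feature"
    min_pairs: int = 5
    covariate_names: tuple[str, ...] = ()
    exact_small_n: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_pairs < 3:
            raise ValueError("min_pairs must be >= 3")
        if self.adjust_scope not in ("per_feature", "global"):
            raise ValueError("adjust_scope must be 'per_feature' or 'global'")


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------

def _midrank(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, method="average")

def _pearson_from_vectors(u: np.ndarray, v: np.ndarray) -> float:
    u = u - u.mean()
    v = v - v.mean()
    denom = math.sqrt(float(u @ u) * float(v @ v))
    if denom == 0.0:
        raise UndefinedCorrelationError("constant vector after filtering")
    return float(np.clip((u @ v) / denom, -1.0, 1.0))

def _t_pvalue(rho: float, df: int) -> float:
    """Two-sided p from the t statistic of a correlation on df dof."""
    if df <= 0:
        return float("nan")
    denom = 1.0 - rho * rho
    if denom <= 0.0:
        return 0.0
    t = abs(rho) * math.sqrt(df / denom)
    return float(2.0 * stats.t.sf(t, df))


def spearman_rho(
    x: np.ndarray, y: np.ndarray, *, exact_small_n: bool = False,
) -> tuple[float, float, int]:
    """Spearman correlation with midranks and a two-sided asymptotic p.

    Incomplete pairs (NaN in either vector) are dropped pairwise; ``n_used``
    reports how many pairs remained. Requires ``n_used >= 3``. With
    ``exact_small_n`` and ``n_used <= 9`` the p-value is computed by exact
    enumeration of all rank permutations instead of the t approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise UndefinedCorrelationError(f"only {n} complete pairs (need >= 3)")
    rx, ry = _midrank(x), _midrank(y)
    rho = _pearson_from_vectors(rx, ry)
    if exact_small_n and n <= 9:
        p = _exact_spearman_p(rx, ry, rho)
    else:
        p = _t_pvalue(rho, n - 2)
    return rho, p, n


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Exact two-sided p by enumerating all n! pairings of the given ranks."""
    n = rx.size
    hits = 0
    total = 0
    tol = 1e-12
    for perm in itertools.permutations(range(n)):
        rho = _pearson_from_vectors(rx, ry[list(perm)])
        total += 1
        if abs(rho) >= abs(rho_obs) - tol:
            hits += 1
    return hits / total


def partial_spearman_rho(
    x: np.ndarray, y: np.ndarray, Z: np.ndarray | None,
) -> tuple[float, float, int]:
    """Partial Spearman correlation of x and y given covariates Z.

    Rows with a missing value in x, y, or any covariate are dropped
    listwise. All variables are midrank transformed; the least-squares
    projection onto ``[1, Z_ranked]`` is removed from ranked x and ranked y,
    and the residuals are Pearson-correlated. The p-value uses
    ``df = n - 2 - k``. With no covariates the result equals
    :func:`spearman_rho` exactly.
    """
    if Z is None or (Z := np.asarray(Z, dtype=float)).size == 0:
        return spearman_rho(x, y)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    keep = ~(np.isnan(x) | np.isnan(y) | np.isnan(Z).any(axis=1))
    x, y, Z = x[keep], y[keep], Z[keep]
    n, k = x.size, Z.shape[1]
    if n < k + 3:
        raise UndefinedCorrelationError(
            f"only {n} complete rows (need >= {k + 3} for {k} covariate(s))"
        )
    rx, ry = _midrank(x), _midrank(y)
    rz = np.column_stack([_midrank(Z[:, j]) for j in range(k)])
    design = np.column_stack([np.ones(n), rz])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CollinearityError("rank-deficient covariate matrix after ranking")
    coef, *_ = np.linalg.lstsq(design, np.column_stack([rx, ry]), rcond=None)
    resid = np.column_stack([rx, ry]) - design @ coef
    rho = _pearson_from_vectors(resid[:, 0], resid[:, 1])
    return rho, _t_pvalue(rho, n - 2 - k), n


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (Q-values).

    ``q_(i) = min_{j >= i} p_(j) * m / j`` over the ascending order
    statistics, clipped at 1 and mapped back to the input order; ties keep
    their input order (stable sort).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# Bulk correlation
# ---------------------------------------------------------------------------

def correlate_all(
    features: OmicsMatrix,
    expression: OmicsMatrix,
    covariates: CovariateTable | None = None,
    config: CorrelationConfig | None = None,
) -> pd.DataFrame:
    """Correlate every feature against every gene.

    Inputs must already be sample-aligned (same samples, same order). The
    result is a tidy table with one row per (feature, gene) pair that had at
    least ``config.min_pairs`` complete observations, with columns
    ``feature_id, gene_id, rho, n_used, p_raw, q_adj, method``. Constant
    features or genes yield no records (counted and logged). The method is
    ``partial_spearman`` iff covariate names are configured.
    """
    config = config or CorrelationConfig()
    if features.sample_ids != expression.sample_ids:
        raise ValueError("features and expression are not sample-aligned")
    Z = None
    method = "spearman"
    if config.covariate_names:
        if covariates is None:
            raise ValueError("covariate_names configured but no covariates supplied")
        if covariates.sample_ids != features.sample_ids:
            raise ValueError("covariates are not sample-aligned with the matrices")
        Z = covariates.require(config.covariate_names).to_numpy(dtype=float)
        method = "partial_spearman"

    F = features.values
    E = expression.values
    no_missing = not (np.isnan(F).any() or np.isnan(E).any()
                      or (Z is not None and np.isnan(Z).any()))
    if no_missing:
        table = _correlate_dense(F, E, Z, features.feature_ids,
                                 expression.feature_ids, method)
    else:
        table = _correlate_pairwise(F, E, Z, features.feature_ids,
                                    expression.feature_ids, method, config)
    if table.empty:
        table = pd.DataFrame(columns=list(CORRELATION_COLUMNS))
        return table

    if config.adjust_scope == "global":
        table["q_adj"] = bh_adjust(table["p_raw"].to_numpy())
    else:
        table["q_adj"] = (
            table.groupby("feature_id", sort=False)["p_raw"]
            .transform(lambda s: bh_adjust(s.to_numpy()))
        )
    return table.loc[:, list(CORRELATION_COLUMNS)].reset_index(drop=True)


def _correlate_dense(
    F: np.ndarray, E: np.ndarray, Z: np.ndarray | None,
    feature_ids: list[str], gene_ids: list[str], method: str,
) -> pd.DataFrame:
    """Vectorized path when no value is missing anywhere."""
    n = F.shape[0]
    RF = np.apply_along_axis(_midrank, 0, F)
    RE = np.apply_along_axis(_midrank, 0, E)
    k = 0
    if Z is not None:
        k = Z.shape[1]
        RZ = np.column_stack([_midrank(Z[:, j]) for j in range(k)])
        design = np.column_stack([np.ones(n), RZ])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise CollinearityError("rank-deficient covariate matrix after ranking")
        Q, _ = np.linalg.qr(design)
        RF = RF - Q @ (Q.T @ RF)
        RE = RE - Q @ (Q.T @ RE)
    else:
        RF = RF - RF.mean(axis=0)
        RE = RE - RE.mean(axis=0)
    sf = np.sqrt((RF ** 2).sum(axis=0))
    se = np.sqrt((RE ** 2).sum(axis=0))
    const_f = sf == 0.0
    const_e = se == 0.0
    if const_f.any():
        logger.warning("skipping %d constant feature(s)", int(const_f.sum()))
    if const_e.any():
        logger.warning("skipping %d constant gene(s)", int(const_e.sum()))
    sf_safe = np.where(const_f, 1.0, sf)
    se_safe = np.where(const_e, 1.0, se)
    rho = np.clip((RF / sf_safe).T @ (RE / se_safe), -1.0, 1.0)
    df = n - 2 - k
    denom = 1.0 - rho ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(rho) * np.sqrt(df / np.where(denom <= 0, np.inf, denom))
    p = 2.0 * stats.t.sf(t, df)
    p[denom <= 0.0] = 0.0
    fi, gi = np.meshgrid(np.arange(len(feature_ids)), np.arange(len(gene_ids)),
                         indexing="ij")
    valid = ~(const_f[fi] | const_e[gi])
    return pd.DataFrame(
        {
            "feature_id": np.asarray(feature_ids, dtype=object)[fi[valid]],
            "gene_id": np.asarray(gene_ids, dtype=object)[gi[valid]],
            "rho": rho[valid],
            "n_used": n,
            "p_raw": p[valid],
            "q_adj": np.nan,
            "method": method,
        }
    )


def _correlate_pairwise(
    F: np.ndarray, E: np.ndarray, Z: np.ndarray | None,
    feature_ids: list[str], gene_ids: list[str], method: str,
    config: CorrelationConfig,
) -> pd.DataFrame:
    """Per-pair path with pairwise-complete (listwise with covariates) rows."""
    rows = []
    n_skipped = 0
    for i, fid in enumerate(feature_ids):
        for j, gid in enumerate(gene_ids):
            try:
                if method == "partial_spearman":
                    rho, p, n_used = partial_spearman_rho(F[:, i], E[:, j], Z)
                else:
                    rho, p, n_used = spearman_rho(
                        F[:, i], E[:, j], exact_small_n=config.exact_small_n
                    )
            except UndefinedCorrelationError:
                n_skipped += 1
                continue
            if n_used < config.min_pairs:
                n_skipped += 1
                continue
            rows.append((fid, gid, rho, n_used, p, np.nan, method))
    if n_skipped:
        logger.warning("skipped %d (feature, gene) pair(s)", n_skipped)
    return pd.DataFrame(rows, columns=list(CORRELATION_COLUMNS))


# ---------------------------------------------------------------------------
# Signature extraction
# ---------------------------------------------------------------------------

def extract_signature(
    records: pd.DataFrame, universe: set[str] | frozenset[str], alpha: float = 0.05,
) -> GeneSignature:
    """Threshold one feature's correlation records into a gene signature.

    ``up_genes``: adjusted p <= alpha and rho > 0; ``down_genes``: adjusted
    p <= alpha and rho < 0. A record with rho exactly 0 has no direction and
    enters neither set.
    """
    feats = records["feature_id"].unique()
    if len(feats) != 1:
        raise ValueError(f"records must cover exactly one feature, got {list(feats)}")
    sig = records[records["q_adj"] <= alpha]
    up = frozenset(sig.loc[sig["rho"] > 0, "gene_id"].map(normalize_gene_id))
    down = frozenset(sig.loc[sig["rho"] < 0, "gene_id"].map(normalize_gene_id))
    uni = frozenset(normalize_gene_id(g) for g in universe)
    return GeneSignature(str(feats[0]), up, down, uni | up | down, alpha=alpha)


def extract_signatures(
    records: pd.DataFrame, universe: set[str] | frozenset[str], alpha: float = 0.05,
) -> list[GeneSignature]:
    """Per-feature signatures for every feature in a correlation table."""
    return [
        extract_signature(sub, universe, alpha)
        for _, sub in records.groupby("feature_id", sort=False)
    ]
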