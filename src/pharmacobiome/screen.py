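"""Directional signature-similarity screen (the mimicry comparison).

Every microbiome feature signature is compared against every drug signature
with Fisher's exact test, up-sets against up-sets and down-sets against
down-sets, over a shared gene universe. The two directions are tested
separately: upregulated signature similarity is the concordance between
genes positively correlated with a feature and genes a drug up-regulates;
downregulated similarity pairs the negative correlates with the drug's
suppressed genes.

P-values are Benjamini-Hochberg adjusted (by default one family per
direction across the whole feature x drug grid), and results carry
``-log10(Q)`` capped for finite serialization — the quantity plotted in the
similarity heatmaps.

The choice of gene universe materially changes every p-value and the
original analysis does not pin it down; the default here is the
intersection of the feature-signature universe (genes tested for
correlation) and the drug-catalog universe (genes measurable in the
perturbation assay), since overlap can only be observed among genes present
on both platforms. The policy in force is recorded in the result table's
``attrs`` and report headers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    OVERLAP_COLUMNS,
    DrugSignature,
    GeneSignature,
    PharmacobiomeError,
    neg_log10_capped,
)
from .correlation import bh_adjust
from .drugs import catalog_universe

logger = logging.getLogger("pharmacobiome")


class UniverseError(PharmacobiomeError):
    """Empty or invalid gene universe."""


class IntegrityError(PharmacobiomeError):
    """Duplicate (feature, drug, direction) rows in a result table."""


@dataclass
class ScreenConfig:
    """Settings for the similarity screen.

    universe_policy
        ``"intersection"`` (default): feature universe ∩ drug-catalog
        universe; ``"union"``: their union; ``"explicit"``: the caller's
        ``universe`` set.
    alternative
        ``"two_sided"`` (default, the exact-test convention of R's
        ``fisher.test``) or ``"greater"`` (enrichment only).
    bh_scope
        BH family: ``"per_direction"`` (default, all feature x drug pairs
        within one direction), ``"global"``, ``"per_feature"`` or
        ``"per_drug"`` (the latter two within direction).
    neglog_cap
        Cap for -log10(Q); Q = 0 maps to the cap.
    include_cross_direction
        Also test feature-up vs drug-down and vice versa (reversal /
        anti-mimicry); off by default — only concordant comparisons are part
        of the canonical screen.
    """

    universe_policy: str = "intersection"
    alternative: str = "two_sided"
    bh_scope: str = "per_direction"
    neglog_cap: float = 16.0
    universe: frozenset[str] | None = None
    include_cross_direction: bool = False

    def __post_init__(self) -> None:
        if self.universe_policy not in ("intersection", "union", "explicit"):
            raise ValueError(f"unknown universe_policy {self.universe_policy!r}")
        if self.alternative not in ("two_sided", "greater"):
            raise ValueError(f"unknown alternative {self.alternative!r}")
        if self.bh_scope not in ("per_direction", "global", "per_feature", "per_drug"):
            raise ValueError(f"unknown bh_scope {self.bh_scope!r}")
        if self.neglog_cap <= 0:
            raise ValueError("neglog_cap must be positive")
        if self.universe_policy == "explicit" and not self.universe:
            raise ValueError("explicit universe_policy requires a universe set")


def fisher_overlap(
    set_a: Iterable[str],
    set_b: Iterable[str],
    universe: Iterable[str],
    alternative: str = "two_sided",
) -> tuple[tuple[int, int, int, int], float, float]:
    """Fisher's exact test of the overlap between two gene sets.

    Returns the 2x2 contingency counts ``(k, a_only, b_only, neither)``,
    the sample odds ratio ``(k * neither) / (a_only * b_only)`` (NaN for
    0/0, inf for x/0), and the exact hypergeometric p-value. Genes outside
    the universe are trimmed (with a logged count) before testing.

    ``alternative="greater"`` gives ``P(X >= k)``; ``"two_sided"`` sums the
    probabilities of all tables with the same margins whose point
    probability does not exceed the observed one (with a ``1 + 1e-7``
    relative tolerance, the convention of R's ``fisher.test``).
    """
    U = frozenset(universe)
    if len(U) < 2:
        raise UniverseError(f"universe has {len(U)} gene(s); need >= 2")
    A = frozenset(set_a)
    B = frozenset(set_b)
    stray = len(A - U) + len(B - U)
    if stray:
        logger.debug("fisher_overlap: trimmed %d gene(s) outside the universe", stray)
        A &= U
        B &= U
    k = len(A & B)
    a_only = len(A) - k
    b_only = len(B) - k
    neither = len(U) - k - a_only - b_only
    counts = (k, a_only, b_only, neither)

    num = k * neither
    den = a_only * b_only
    if den == 0:
        odds = float("nan") if num == 0 else float("inf")
    else:
        odds = num / den

    # canonical margin order makes the test exactly symmetric in A and B
    M = len(U)
    nK, nD = sorted((len(A), len(B)))
    if alternative == "greater":
        p = float(stats.hypergeom.sf(k - 1, M, nK, nD))
    else:
        k_min = max(0, nK + nD - M)
        k_max = nK
        support = np.arange(k_min, k_max + 1)
        pmf = stats.hypergeom.pmf(support, M, nK, nD)
        qualifies = pmf <= pmf[k - k_min] * (1.0 + 1e-7)
        # every table qualifying means p = 1 by definition, not a float sum
        p = 1.0 if qualifies.all() else float(pmf[qualifies].sum())
    return counts, odds, min(p, 1.0)


def resolve_universe(
    feature_sigs: Sequence[GeneSignature],
    drug_sigs: Sequence[DrugSignature],
    config: ScreenConfig,
) -> frozenset[str]:
    """The gene universe over which every contingency table is formed."""
    if config.universe_policy == "explicit":
        assert config.universe is not None
        return frozenset(config.universe)
    feat_uni: set[str] = set()
    for s in feature_sigs:
        feat_uni |= s.universe
    drug_uni = set(catalog_universe(drug_sigs))
    if config.universe_policy == "union":
        out = feat_uni | drug_uni
    else:
        out = feat_uni & drug_uni
    if len(out) < 2:
        raise UniverseError(
            f"{config.universe_policy} universe has {len(out)} gene(s); "
            "check that feature and drug universes share a gene namespace"
        )
    return frozenset(out)


def run_screen(
    feature_sigs: Sequence[GeneSignature],
    drug_sigs: Sequence[DrugSignature],
    config: ScreenConfig | None = None,
) -> pd.DataFrame:
    """Fisher-compare every feature signature with every drug signature.

    Produces one row per (feature, drug, direction) with contingency
    counts, odds ratio, exact p, BH-adjusted q within ``config.bh_scope``,
    and capped ``-log10(Q)``. Features (or drugs) whose up and down sets are
    both empty are skipped with a log message. Deterministic given inputs
    and invariant to input ordering up to row order.
    """
    config = config or ScreenConfig()
    if not feature_sigs or not drug_sigs:
        raise ValueError("both signature collections must be non-empty")
    universe = resolve_universe(feature_sigs, drug_sigs, config)

    usable_feats = []
    for s in feature_sigs:
        if (s.up_genes | s.down_genes) & universe:
            usable_feats.append(s)
        else:
            logger.info("run_screen: feature %s has no signature genes in the "
                        "universe; skipped", s.feature_id)
    usable_drugs = []
    for d in drug_sigs:
        if (d.up_genes | d.down_genes) & universe:
            usable_drugs.append(d)
        else:
            logger.info("run_screen: drug %s has no signature genes in the "
                        "universe; skipped", d.drug_id)

    comparisons = [("up", "up_genes", "up_genes"), ("down", "down_genes", "down_genes")]
    if config.include_cross_direction:
        comparisons += [("up_vs_down", "up_genes", "down_genes"),
                        ("down_vs_up", "down_genes", "up_genes")]

    rows = []
    for feat in usable_feats:
        for drug in usable_drugs:
            for direction, f_attr, d_attr in comparisons:
                counts, odds, p = fisher_overlap(
                    getattr(feat, f_attr), getattr(drug, d_attr), universe,
                    alternative=config.alternative,
                )
                rows.append((feat.feature_id, drug.drug_id, direction,
                             *counts, odds, p, np.nan, np.nan))
    table = pd.DataFrame(rows, columns=list(OVERLAP_COLUMNS))
    if table.empty:
        table.attrs["universe_policy"] = config.universe_policy
        table.attrs["universe_size"] = len(universe)
        return table

    if config.bh_scope == "global":
        table["q_adj"] = bh_adjust(table["p_raw"].to_numpy())
    else:
        group_cols = {"per_direction": ["direction"],
                      "per_feature": ["direction", "feature_id"],
                      "per_drug": ["direction", "drug_id"]}[config.bh_scope]
        table["q_adj"] = (
            table.groupby(group_cols, sort=False)["p_raw"]
            .transform(lambda s: bh_adjust(s.to_numpy()))
        )
    table["neg_log10_q"] = neg_log10_capped(
        table["q_adj"].to_numpy(), cap=config.neglog_cap
    )
    table.attrs["universe_policy"] = config.universe_policy
    table.attrs["universe_size"] = len(universe)
    return table


def build_similarity_matrix(
    results: pd.DataFrame, direction: str, *, cap: float | None = None,
) -> pd.DataFrame:
    """Pivot one direction's results into a features x drugs -log10(Q) matrix.

    Missing (feature, drug) pairs — skipped during the screen — are filled
    with 0, the matrix's semantic "no evidence of similarity". Row and
    column order follow first appearance in the result table. Duplicate
    (feature, drug) rows for the direction raise :class:`IntegrityError`.
    """
    sub = results[results["direction"] == direction]
    if sub.duplicated(["feature_id", "drug_id"]).any():
        dup = sub[sub.duplicated(["feature_id", "drug_id"])].iloc[0]
        raise IntegrityError(
            f"duplicate result for ({dup['feature_id']}, {dup['drug_id']}, {direction})"
        )
    feats = list(dict.fromkeys(results["feature_id"]))
    drugs = list(dict.fromkeys(results["drug_id"]))
    mat = (
        sub.pivot(index="feature_id", columns="drug_id", values="neg_log10_q")
        .reindex(index=feats, columns=drugs)
        .fillna(0.0)
    )
    if cap is not None:
        mat = mat.clip(upper=cap)
    mat.index.name = "feature_id"
    mat.columns.name = "drug_id"
    return mat
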