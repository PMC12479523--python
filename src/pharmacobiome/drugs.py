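"""Drug perturbation catalog: metadata filtering and ranked-profile cutting.

Drug signatures arrive either as pre-cut up/down gene sets (GMT pairs, the
canonical exchange format) or as ranked differential-expression profiles
from which the top/bottom N genes are cut. A catalog filter narrows the
ingested signatures to a candidate compound list and one experimental
condition — by default the MCF7 cell line at a 10 micromolar dose over 24
hours, the most consistent condition across L1000-style screens.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import DrugSignature, PharmacobiomeError, normalize_gene_id

logger = logging.getLogger("pharmacobiome")


class EmptyCatalogError(PharmacobiomeError):
    """Filtering removed every candidate signature."""


class DegenerateProfileError(PharmacobiomeError):
    """A ranked profile with all-equal scores cannot be cut."""


@dataclass
class CatalogFilter:
    """Criteria a drug signature must meet to stay in the screen.

    Fields set to ``None`` are inactive. Dose and timepoint match on value
    and unit string (case-insensitive unit comparison).
    """

    drug_whitelist: frozenset[str] | None = None
    cell_line: str | None = "MCF7"
    dose: float | None = 10.0
    dose_unit: str = "uM"
    timepoint: float | None = 24.0
    time_unit: str = "h"
    signature_size: int | None = None

    def __post_init__(self) -> None:
        if self.signature_size is not None and self.signature_size < 1:
            raise ValueError("signature_size must be >= 1")
        if self.drug_whitelist is not None:
            self.drug_whitelist = frozenset(self.drug_whitelist)

    def _criteria(self):
        if self.drug_whitelist is not None:
            yield ("drug_whitelist", lambda d: d.drug_id in self.drug_whitelist)
        if self.cell_line is not None:
            yield ("cell_line", lambda d: d.cell_line == self.cell_line)
        if self.dose is not None:
            yield ("dose", lambda d: math.isclose(d.dose, self.dose)
                   and d.dose_unit.lower() == self.dose_unit.lower())
        if self.timepoint is not None:
            yield ("timepoint", lambda d: math.isclose(d.time, self.timepoint)
                   and d.time_unit.lower() == self.time_unit.lower())


def filter_catalog(
    signatures: Sequence[DrugSignature], catalog_filter: CatalogFilter,
) -> list[DrugSignature]:
    """Retain exactly the signatures matching every active criterion.

    A pure filter (output is a subset of input, idempotent). Raises
    :class:`EmptyCatalogError` naming the criterion that eliminated the last
    candidate if nothing survives.
    """
    remaining = list(signatures)
    for name, pred in catalog_filter._criteria():
        kept = [d for d in remaining if pred(d)]
        if not kept:
            raise EmptyCatalogError(
                f"criterion {name!r} eliminated all {len(remaining)} remaining candidate(s)"
            )
        remaining = kept
    logger.info("filter_catalog: retained %d of %d signatures",
                len(remaining), len(signatures))
    return remaining


def cut_ranked_profile(
    profile: Mapping[str, float], signature_size: int,
) -> tuple[frozenset[str], frozenset[str]]:
    """Cut a ranked differential-expression profile into up/down sets.

    ``up`` = the ``signature_size`` genes with the highest scores, ``down``
    = the ``signature_size`` genes with the lowest. Score ties at the cut
    boundary are broken lexicographically by gene identifier, so the result
    is identical across runs and input orderings.
    """
    items = [(normalize_gene_id(g), float(s)) for g, s in profile.items()]
    scores = np.array([s for _, s in items])
    if not np.all(np.isfinite(scores)):
        raise ValueError("profile scores must be finite")
    if signature_size > len(items) // 2:
        raise ValueError(
            f"signature_size {signature_size} exceeds half the profile size {len(items)}"
        )
    if np.ptp(scores) == 0.0:
        raise DegenerateProfileError("all scores equal; profile has no direction")
    up_order = sorted(items, key=lambda kv: (-kv[1], kv[0]))
    down_order = sorted(items, key=lambda kv: (kv[1], kv[0]))
    up = frozenset(g for g, _ in up_order[:signature_size])
    down = frozenset(g for g, _ in down_order[:signature_size])
    return up, down


def catalog_universe(signatures: Sequence[DrugSignature]) -> frozenset[str]:
    """Default drug-catalog universe: all genes appearing in any signature.

    A drug signature's own ``universe`` field takes precedence when set;
    this union is the fallback and the default for the screen's
    intersection universe policy.
    """
    uni: set[str] = set()
    for d in signatures:
        uni |= d.universe if d.universe else (d.up_genes | d.down_genes)
    return frozenset(uni)
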