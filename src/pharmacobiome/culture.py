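"""Producer/consumer classification from culture supernatant metabolomics.

Cultured strains are profiled against uninoculated medium controls; a
metabolite is called *produced* when its mean supernatant intensity exceeds
the control by a log2 fold-change threshold, *consumed* when it falls below
by the same margin, and *unchanged* otherwise. The rule is a deliberate,
transparent simplification: mean log2 fold-change against the medium
control with a symmetric threshold and no inferential test at
triplicate-scale n.

A small pseudocount (half the smallest nonzero intensity in the profile)
keeps zero means finite, the standard convention for intensity data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import PharmacobiomeError

logger = logging.getLogger("pharmacobiome")

LABELS = ("produced", "consumed", "unchanged")


class CultureIntegrityError(PharmacobiomeError):
    """Duplicate (strain, metabolite) profiles."""


@dataclass
class CultureProfile:
    """Replicate intensities of one metabolite for one cultured strain."""

    strain_id: str
    metabolite_id: str
    supernatant_intensities: np.ndarray
    control_intensities: np.ndarray

    def __post_init__(self) -> None:
        self.supernatant_intensities = np.asarray(
            self.supernatant_intensities, dtype=float
        )
        self.control_intensities = np.asarray(self.control_intensities, dtype=float)
        for name, arr in (("supernatant", self.supernatant_intensities),
                          ("control", self.control_intensities)):
            if arr.size < 1:
                raise ValueError(f"{name} arm needs >= 1 replicate")
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"{name} intensities must be finite and >= 0")


def classify_production(
    profile: CultureProfile, log2fc_threshold: float = 1.0,
) -> tuple[str, float]:
    """Label a profile produced / consumed / unchanged with its effect size.

    effect = log2((mean_sup + eps) / (mean_ctl + eps)). The pseudocount eps
    is zero when both arm means are positive (so a clean 4x change reads
    exactly 2.0) and otherwise half the smallest nonzero intensity across
    both arms, keeping zero-mean arms finite. ``produced`` iff
    effect >= threshold, ``consumed`` iff effect <= -threshold. A profile
    with all-zero intensities in both arms is ``unchanged`` with zero
    effect (flagged in the log).
    """
    sup = float(profile.supernatant_intensities.mean())
    ctl = float(profile.control_intensities.mean())
    all_int = np.concatenate(
        [profile.supernatant_intensities, profile.control_intensities]
    )
    nonzero = all_int[all_int > 0]
    if nonzero.size == 0:
        logger.warning("classify_production: %s/%s has all-zero intensities",
                       profile.strain_id, profile.metabolite_id)
        return "unchanged", 0.0
    eps = 0.0 if (sup > 0 and ctl > 0) else float(nonzero.min()) / 2.0
    effect = math.log2((sup + eps) / (ctl + eps))
    if effect >= log2fc_threshold:
        return "produced", effect
    if effect <= -log2fc_threshold:
        return "consumed", effect
    return "unchanged", effect


def read_culture_profiles(path: str) -> list[CultureProfile]:
    """Read long-form TSV (strain_id, metabolite_id, arm, replicate, intensity)."""
    df = pd.read_csv(path, sep="\t")
    required = {"strain_id", "metabolite_id", "arm", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"culture table missing columns: {sorted(missing)}")
    out = []
    for (strain, metab), grp in df.groupby(["strain_id", "metabolite_id"], sort=False):
        out.append(
            CultureProfile(
                str(strain), str(metab),
                grp.loc[grp["arm"] == "supernatant", "intensity"].to_numpy(),
                grp.loc[grp["arm"] == "control", "intensity"].to_numpy(),
            )
        )
    return out


def producer_consumer_table(
    profiles: Sequence[CultureProfile],
    metabolite_whitelist: Iterable[str] | None = None,
    log2fc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Strain x metabolite label matrix for the whitelisted metabolites.

    One label per (strain, metabolite) profile; whitelist entries with no
    profile are reported in the log and absent from the table. Duplicate
    profiles for one cell raise :class:`CultureIntegrityError`.
    """
    seen = set()
    for p in profiles:
        key = (p.strain_id, p.metabolite_id)
        if key in seen:
            raise CultureIntegrityError(f"duplicate profile for {key}")
        seen.add(key)
    whitelist = None if metabolite_whitelist is None else {
        str(m) for m in metabolite_whitelist
    }
    if whitelist is not None:
        profiled = {p.metabolite_id for p in profiles}
        unprofiled = whitelist - profiled
        if unprofiled:
            logger.warning("whitelisted metabolites without profiles: %s",
                           sorted(unprofiled))
    rows = []
    for p in profiles:
        if whitelist is not None and p.metabolite_id not in whitelist:
            continue
        label, effect = classify_production(p, log2fc_threshold)
        rows.append((p.strain_id, p.metabolite_id, label, effect))
    long = pd.DataFrame(
        rows, columns=["strain_id", "metabolite_id", "label", "log2fc"]
    )
    if long.empty:
        return pd.DataFrame()
    strains = list(dict.fromkeys(long["strain_id"]))
    metabs = list(dict.fromkeys(long["metabolite_id"]))
    return (
        long.pivot(index="strain_id", columns="metabolite_id", values="label")
        .reindex(index=strains, columns=metabs)
    )
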