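"""Synthetic multi-omics cohorts and drug catalogs with planted structure.

The generator emulates the shape of a paired vaginal multi-omics study —
tens of samples, ~51 taxa, ~99 metabolites, thousands of host genes, a
35-compound perturbation catalog — with known ground truth so every
pipeline stage is verifiable offline:

* a binary Lactobacillus-dominance covariate, with one taxon (the
  "Lactobacillus" column) tied to it;
* monotone planted taxon->gene and metabolite->gene effects: each planted
  gene is ``effect * link(feature)`` plus Gaussian noise, where ``link`` is
  a strictly increasing transform drawn per gene (identity or a cubic) of
  the feature's normal scores — Spearman's premise is monotonicity, so the
  generator must not secretly favor linear relationships;
* confounded metabolite-gene pairs driven solely by the dominance
  covariate on both sides with no direct link (detected by plain Spearman,
  correctly rejected by the dominance-adjusted partial Spearman);
* drugs organized in mechanism classes sharing a class core gene set (a
  fraction of one anchor feature's planted genes plus class filler) with
  drug-private noise genes, so mechanism classes are recoverable from the
  similarity matrix;
* planted mimicry pairs whose drug sets overlap a feature's planted up and
  down sets at a configured fraction — the screen's positive controls.

One mandatory seed drives a single root generator; every matrix gets its
own deterministically spawned substream, so outputs are bit-identical
across runs with the same configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core import CovariateTable, DrugSignature, OmicsMatrix, write_drug_catalog

DOMINANT_TAXON = "LACTOBACILLUS"


class ConfigError(ValueError):
    """Inconsistent generator configuration."""


@dataclass
class PlantedEffect:
    """One planted feature->gene-set effect (one direction)."""

    feature_id: str
    n_genes: int
    effect_size: float
    sign: int  # +1: genes rise with the feature; -1: genes fall
    confounded: bool = False

    def __post_init__(self) -> None:
        if self.sign not in (-1, 1):
            raise ConfigError("sign must be +1 or -1")
        if self.n_genes < 1 or self.effect_size < 0:
            raise ConfigError("n_genes >= 1 and effect_size >= 0 required")


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the structure of the motivating study at a reduced gene
    count: 90 samples, 2000 genes, 51 taxa, 99 metabolites, 35 drugs in 5
    mechanism classes. Planted effects default to 6 taxa and 10 metabolites
    (3 of them confounded — 30% of metabolite effects carry no direct link,
    only the dominance covariate on both sides), each with 30 up- and 30
    down-regulated genes at effect size 1.5 against unit noise. Mimicry
    features carry larger signatures (80 + 80 genes) so the planted mimics
    are unambiguous positive controls; three mimicry pairs at overlap 0.5
    are planted by default. The seed is mandatory: there is no silent
    nondeterminism.
    """

    seed: int
    n_samples: int = 90
    n_genes: int = 2000
    n_taxa: int = 51
    n_metabolites: int = 99
    n_drugs: int = 35
    n_drug_classes: int = 5
    planted_taxon_effects: list[PlantedEffect] | None = None
    planted_metabolite_effects: list[PlantedEffect] | None = None
    confounded_fraction: float = 0.3
    mimicry_pairs: list[tuple[str, str, float]] | None = None
    drug_classes: dict[str, int] | None = None
    noise_sd: float = 1.0
    effect_size: float = 1.5
    dominance_effect: float = 2.5
    confounder_strength: float = 1.5
    planted_set_size: int = 30
    mimicry_set_size: int = 80
    class_core_fraction: float = 0.65
    class_filler_size: int = 45
    drug_private_size: int = 40

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_genes", "n_taxa", "n_metabolites",
                     "n_drugs", "n_drug_classes"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if not 0.0 <= self.confounded_fraction <= 1.0:
            raise ConfigError("confounded_fraction must be in [0, 1]")
        if self.planted_taxon_effects is None:
            self.planted_taxon_effects = self._default_taxon_effects()
        if self.planted_metabolite_effects is None:
            self.planted_metabolite_effects = self._default_metabolite_effects()
        if self.drug_classes is None:
            self.drug_classes = {
                self.drug_id(i): i % self.n_drug_classes for i in range(self.n_drugs)
            }
        if self.mimicry_pairs is None:
            self.mimicry_pairs = self._default_mimicry_pairs()
        for _, _, frac in self.mimicry_pairs:
            if not 0.0 < frac <= 1.0:
                raise ConfigError("mimicry overlap fraction must be in (0, 1]")
        planted_features = {e.feature_id for e in self.all_planted_effects()}
        for feat, drug, _ in self.mimicry_pairs:
            if feat not in planted_features:
                raise ConfigError(
                    f"mimicry pair references effect-free feature {feat!r}"
                )
            if drug not in self.drug_classes:
                raise ConfigError(f"mimicry pair references unknown drug {drug!r}")
        need = sum(e.n_genes for e in self.all_planted_effects())
        if need > self.n_genes:
            raise ConfigError(
                f"planted effects need {need} genes but n_genes = {self.n_genes}"
            )

    # -- identifier schemes -------------------------------------------------
    def sample_id(self, i: int) -> str:
        return f"S{i:03d}"

    def gene_id(self, i: int) -> str:
        return f"G{i:04d}"

    def taxon_id(self, i: int) -> str:
        return DOMINANT_TAXON if i == 0 else f"TAXON_{i:03d}"

    def metabolite_id(self, i: int) -> str:
        return f"METAB_{i:03d}"

    def drug_id(self, i: int) -> str:
        return f"DRUG_{i:02d}"

    # -- default planted structure -----------------------------------------
    def _mimicry_feature_ids(self) -> tuple[str, str]:
        # one mimicking taxon and one mimicking metabolite, chosen outside
        # the class-anchor range (anchors are the first planted features)
        return self.taxon_id(6), self.metabolite_id(9)

    def _default_taxon_effects(self) -> list[PlantedEffect]:
        mim_taxon, _ = self._mimicry_feature_ids()
        effects = []
        for i in range(1, 7):  # taxa 1..6 planted; taxon 0 is the dominant one
            tid = self.taxon_id(i)
            size = self.mimicry_set_size if tid == mim_taxon else self.planted_set_size
            effects.append(PlantedEffect(tid, size, self.effect_size, +1))
            effects.append(PlantedEffect(tid, size, self.effect_size, -1))
        return effects

    def _default_metabolite_effects(self) -> list[PlantedEffect]:
        _, mim_metab = self._mimicry_feature_ids()
        n_planted = 10
        n_conf = round(self.confounded_fraction * n_planted)
        effects = []
        for i in range(n_planted):
            mid = self.metabolite_id(i)
            confounded = i < n_conf
            size = self.mimicry_set_size if mid == mim_metab else self.planted_set_size
            eff = self.confounder_strength if confounded else self.effect_size
            effects.append(PlantedEffect(mid, size, eff, +1, confounded))
            effects.append(PlantedEffect(mid, size, eff, -1, confounded))
        return effects

    def _default_mimicry_pairs(self) -> list[tuple[str, str, float]]:
        mim_taxon, mim_metab = self._mimicry_feature_ids()
        return [
            (mim_taxon, self.drug_id(3), 0.5),
            (mim_metab, self.drug_id(11), 0.5),
            (mim_metab, self.drug_id(24), 0.5),
        ]

    def all_planted_effects(self) -> list[PlantedEffect]:
        return list(self.planted_taxon_effects or []) + list(
            self.planted_metabolite_effects or []
        )


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a generated cohort.

    ``records`` has one row per planted (feature, gene) pair with columns
    ``feature_id, gene_id, sign, effect_size, feature_kind, confounded``;
    confounded rows carry no direct feature->gene link, only the shared
    dominance driver.
    """

    records: pd.DataFrame
    dominance: pd.Series
    mimicry_pairs: list[tuple[str, str, float]]
    drug_classes: dict[str, int]
    class_anchors: dict[int, str]

    def planted_gene_sets(self, feature_id: str) -> tuple[set[str], set[str]]:
        sub = self.records[self.records["feature_id"] == feature_id]
        return (
            set(sub.loc[sub["sign"] > 0, "gene_id"]),
            set(sub.loc[sub["sign"] < 0, "gene_id"]),
        )

    def write(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def _normal_scores(x: np.ndarray) -> np.ndarray:
    """Blom-type inverse-normal transform of the ranks of x."""
    r = stats.rankdata(x)
    return stats.norm.ppf((r - 0.375) / (len(x) + 0.25))


def _apply_link(v: np.ndarray, kind: int) -> np.ndarray:
    """Strictly increasing, variance-standardized link functions."""
    if kind == 0:
        return v
    return v ** 3 / np.sqrt(15.0)  # E[(Z^3)^2] = 15 for standard normal


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[OmicsMatrix, OmicsMatrix, OmicsMatrix, CovariateTable, SyntheticTruth]:
    """Generate (expression, taxa, metabolites, covariates, truth).

    Construction: per-sample dominance D ~ Bernoulli(0.5); taxa from a
    logistic-normal model with the dominant taxon's latent shifted by
    ``dominance_effect * D``; metabolites log-normal, confounded ones
    shifted by ``confounder_strength * D`` on the latent scale; planted
    genes respond to a monotone link of their feature's normal scores at
    the configured effect size against ``noise_sd`` Gaussian noise;
    confounded genes respond to D only; everything else is pure noise.
    """
    root = np.random.SeedSequence(config.seed)
    rng_dom, rng_taxa, rng_metab, rng_expr, rng_links = (
        np.random.default_rng(s) for s in root.spawn(5)
    )
    samples = [config.sample_id(i) for i in range(config.n_samples)]
    genes = [config.gene_id(i) for i in range(config.n_genes)]
    taxa_ids = [config.taxon_id(i) for i in range(config.n_taxa)]
    metab_ids = [config.metabolite_id(i) for i in range(config.n_metabolites)]

    D = rng_dom.integers(0, 2, size=config.n_samples).astype(float)

    # taxa: logistic-normal relative abundances
    latent = rng_taxa.normal(0.0, 1.0, size=(config.n_samples, config.n_taxa))
    latent[:, 0] += config.dominance_effect * D
    expl = np.exp(latent)
    taxa_values = expl / expl.sum(axis=1, keepdims=True)

    # metabolites: log-normal intensities; confounded ones shifted by D
    w = rng_metab.normal(0.0, 1.0, size=(config.n_samples, config.n_metabolites))
    confounded_metabs = {
        e.feature_id for e in (config.planted_metabolite_effects or []) if e.confounded
    }
    for j, mid in enumerate(metab_ids):
        if mid in confounded_metabs:
            w[:, j] += config.confounder_strength * D
    metab_values = np.exp(0.5 * w)

    expr = rng_expr.normal(0.0, config.noise_sd,
                           size=(config.n_samples, config.n_genes))

    # assign disjoint gene blocks to planted effects, in config order
    cursor = 0
    records = []
    taxa_cols = {tid: i for i, tid in enumerate(taxa_ids)}
    metab_cols = {mid: i for i, mid in enumerate(metab_ids)}
    for effect in config.all_planted_effects():
        block = list(range(cursor, cursor + effect.n_genes))
        cursor += effect.n_genes
        if effect.feature_id in taxa_cols:
            kind = "taxon"
            driver = _normal_scores(taxa_values[:, taxa_cols[effect.feature_id]])
        else:
            kind = "metabolite"
            driver = _normal_scores(metab_values[:, metab_cols[effect.feature_id]])
        for g in block:
            if effect.confounded:
                expr[:, g] += effect.sign * effect.effect_size * D
            else:
                link_kind = int(rng_links.integers(0, 2))
                expr[:, g] += (
                    effect.sign * effect.effect_size * _apply_link(driver, link_kind)
                )
            records.append(
                (effect.feature_id, config.gene_id(g), effect.sign,
                 effect.effect_size, kind, effect.confounded)
            )

    idx = pd.Index(samples, name="sample_id")
    expression = OmicsMatrix(pd.DataFrame(expr, index=idx, columns=genes),
                             "expression")
    taxa = OmicsMatrix(pd.DataFrame(taxa_values, index=idx, columns=taxa_ids),
                       "taxa")
    metabolites = OmicsMatrix(
        pd.DataFrame(metab_values, index=idx, columns=metab_ids), "metabolite"
    )
    covariates = CovariateTable(
        pd.DataFrame({"lactobacillus_dominance": D}, index=idx)
    )
    truth = SyntheticTruth(
        records=pd.DataFrame(
            records,
            columns=["feature_id", "gene_id", "sign", "effect_size",
                     "feature_kind", "confounded"],
        ),
        dominance=pd.Series(D, index=idx, name="lactobacillus_dominance"),
        mimicry_pairs=list(config.mimicry_pairs or []),
        drug_classes=dict(config.drug_classes or {}),
        class_anchors=_class_anchors(config),
    )
    return expression, taxa, metabolites, covariates, truth


def _class_anchors(config: GeneratorConfig) -> dict[int, str]:
    """Assign each mechanism class an anchor planted feature.

    Anchors cycle through the non-confounded, non-mimicry planted features
    in config order; each class core borrows a fraction of its anchor's
    planted genes, which is what makes classes separable in the screen.
    """
    mim_feats = {f for f, _, _ in (config.mimicry_pairs or [])}
    candidates = []
    for e in config.all_planted_effects():
        if e.confounded or e.feature_id in mim_feats:
            continue
        if e.feature_id not in candidates:
            candidates.append(e.feature_id)
    if not candidates:
        return {}
    return {c: candidates[c % len(candidates)]
            for c in range(config.n_drug_classes)}


def generate_drug_catalog(
    config: GeneratorConfig, truth: SyntheticTruth,
) -> tuple[list[DrugSignature], pd.DataFrame]:
    """Generate the drug catalog implied by a cohort's truth.

    Each mechanism class shares a core per direction — a
    ``class_core_fraction`` sample of its anchor feature's planted genes
    plus ``class_filler_size`` random non-planted genes — and every drug
    adds ``drug_private_size`` private random genes. Mimicry drugs
    additionally absorb the configured fraction of their target feature's
    planted up/down genes. Metadata is stamped with the default screen
    condition (MCF7, 10 uM, 24 h) so catalog filters pass. The declared
    universe is the full generated gene set (the assay's measured genes).
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(6)[5])
    all_genes = [config.gene_id(i) for i in range(config.n_genes)]
    planted_genes = set(truth.records["gene_id"])
    free_genes = np.array([g for g in all_genes if g not in planted_genes])
    universe = frozenset(all_genes)

    mimicry_by_drug: dict[str, tuple[str, float]] = {
        drug: (feat, frac) for feat, drug, frac in truth.mimicry_pairs
    }

    class_cores: dict[int, tuple[set[str], set[str]]] = {}
    for cls in sorted(set(truth.drug_classes.values())):
        anchor = truth.class_anchors.get(cls)
        core_up: set[str] = set()
        core_down: set[str] = set()
        if anchor is not None:
            a_up, a_down = truth.planted_gene_sets(anchor)
            n_up = round(config.class_core_fraction * len(a_up))
            n_down = round(config.class_core_fraction * len(a_down))
            core_up |= set(rng.choice(sorted(a_up), size=n_up, replace=False))
            core_down |= set(rng.choice(sorted(a_down), size=n_down, replace=False))
        filler = rng.choice(free_genes, size=2 * config.class_filler_size,
                            replace=False)
        core_up |= set(filler[: config.class_filler_size])
        core_down |= set(filler[config.class_filler_size:])
        class_cores[cls] = (core_up, core_down)

    drugs = []
    meta_rows = []
    for i in range(config.n_drugs):
        drug_id = config.drug_id(i)
        cls = truth.drug_classes[drug_id]
        up, down = (set(s) for s in class_cores[cls])
        private = rng.choice(free_genes, size=2 * config.drug_private_size,
                             replace=False)
        up |= set(private[: config.drug_private_size]) - down
        down |= set(private[config.drug_private_size:]) - up
        if drug_id in mimicry_by_drug:
            feat, frac = mimicry_by_drug[drug_id]
            f_up, f_down = truth.planted_gene_sets(feat)
            take_up = round(frac * len(f_up))
            take_down = round(frac * len(f_down))
            up |= set(rng.choice(sorted(f_up), size=take_up, replace=False))
            down |= set(rng.choice(sorted(f_down), size=take_down, replace=False))
        # disjointness: any gene landing in both directions is removed from both
        both = up & down
        up -= both
        down -= both
        drugs.append(
            DrugSignature(
                drug_id=drug_id, up_genes=frozenset(up), down_genes=frozenset(down),
                universe=universe, cell_line="MCF7", dose=10.0, dose_unit="uM",
                time=24.0, time_unit="h",
            )
        )
        meta_rows.append(dict(drug_id=drug_id, cell_line="MCF7", dose=10.0,
                              dose_unit="uM", time=24.0, time_unit="h",
                              mechanism_class=cls))
    return drugs, pd.DataFrame(meta_rows)


def write_cohort(
    out_dir: str | Path,
    expression: OmicsMatrix,
    taxa: OmicsMatrix,
    metabolites: OmicsMatrix,
    covariates: CovariateTable,
    truth: SyntheticTruth,
    drugs: list[DrugSignature] | None = None,
) -> None:
    """Serialize a generated cohort in the formats the pipeline reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expression.write(out / "expression.tsv")
    taxa.write(out / "taxa.tsv")
    metabolites.write(out / "metabolites.tsv")
    covariates.write(out / "covariates.tsv")
    truth.write(out / "truth.tsv")
    if drugs is not None:
        write_drug_catalog(out / "drugs.gmt", out / "drugs_meta.tsv", drugs)


def simulate_confounded_pairs(
    n_samples: int = 100,
    n_replicates: int = 2000,
    strength: float = 1.5,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Replicated confounded (metabolite, gene) pairs with no direct link.

    Each replicate draws a binary dominance covariate D and two variables
    ``x = strength * D + noise`` and ``y = strength * D + noise`` that are
    conditionally independent given D. Returns arrays of shape
    (n_replicates, n_samples) for x and y and the shared D per replicate —
    the design under which plain Spearman's false-positive rate inflates
    while dominance-adjusted partial Spearman stays calibrated.
    """
    rng = np.random.default_rng(seed)
    D = rng.integers(0, 2, size=(n_replicates, n_samples)).astype(float)
    x = strength * D + rng.normal(0.0, noise_sd, size=D.shape)
    y = strength * D + rng.normal(0.0, noise_sd, size=D.shape)
    return x, y, D
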