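"""Core data model and IO for the mimicry-screening pipeline.

The pipeline works on three sample-by-feature matrices (host expression,
microbial relative abundance, metabolite intensity), a covariate table
carrying at least a Lactobacillus-dominance indicator, and directional gene
sets (up/down) for both microbiome features and drug perturbations.

Everything downstream consumes the types defined here:

* :class:`OmicsMatrix` — validated samples x features numeric matrix.
* :class:`CovariateTable` — per-sample covariates used for partial
  correlation adjustment.
* :class:`GeneSignature` / :class:`DrugSignature` — directional gene sets
  over a declared universe.
* Tidy result tables (correlation records, overlap results) are plain
  :class:`pandas.DataFrame` objects with fixed column schemas
  (:data:`CORRELATION_COLUMNS`, :data:`OVERLAP_COLUMNS`).

On-disk formats are delimited text (TSV/CSV) for matrices and tidy tables,
and GMT for gene sets, with a ``NAME_UP`` / ``NAME_DOWN`` suffix convention
pairing the two directions of one signature.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("pharmacobiome")

ASSAY_KINDS = ("expression", "taxa", "metabolite")

#: Column schema of the tidy correlation table.
CORRELATION_COLUMNS = (
    "feature_id", "gene_id", "rho", "n_used", "p_raw", "q_adj", "method",
)

#: Column schema of the tidy overlap (screen) table.
OVERLAP_COLUMNS = (
    "feature_id", "drug_id", "direction", "k_overlap", "n_feature_only",
    "n_drug_only", "n_neither", "odds_ratio", "p_raw", "q_adj", "neg_log10_q",
)


class PharmacobiomeError(Exception):
    """Base class for all pipeline errors."""


class IdentifierError(PharmacobiomeError):
    """Duplicate or unresolvable sample/feature identifiers."""


class MatrixParseError(PharmacobiomeError):
    """Malformed matrix file (non-numeric cell, empty matrix...)."""


class AlignmentError(PharmacobiomeError):
    """Sample alignment produced an empty intersection."""


class GmtFormatError(PharmacobiomeError):
    """Malformed GMT line."""


def normalize_gene_id(gene: str) -> str:
    """Canonical gene identifier: uppercased, stripped of whitespace.

    Microarray symbol tables and L1000 metadata differ in case convention;
    every gene identifier entering the pipeline passes through here so that
    set operations compare like with like.
    """
    return str(gene).strip().upper()


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------

@dataclass
class OmicsMatrix:
    """A validated samples x features numeric matrix.

    Parameters
    ----------
    data
        DataFrame indexed by sample identifier with feature identifiers as
        columns. Missing cells are NaN and are excluded pairwise at
        correlation time; non-finite values other than NaN are rejected.
    assay_kind
        One of ``expression``, ``taxa``, ``metabolite``. Taxa values must be
        non-negative (relative abundances).
    """

    data: pd.DataFrame
    assay_kind: str

    def __post_init__(self) -> None:
        if self.assay_kind not in ASSAY_KINDS:
            raise ValueError(
                f"assay_kind must be one of {ASSAY_KINDS}, got {self.assay_kind!r}"
            )
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise MatrixParseError("empty matrix")
        dup_s = self.data.index[self.data.index.duplicated()].unique().tolist()
        if dup_s:
            raise IdentifierError(f"duplicate sample identifiers: {dup_s}")
        dup_f = self.data.columns[self.data.columns.duplicated()].unique().tolist()
        if dup_f:
            raise IdentifierError(f"duplicate feature identifiers: {dup_f}")
        values = self.data.to_numpy(dtype=float)
        bad = np.isinf(values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise MatrixParseError(
                f"non-finite value at sample {self.data.index[i]!r}, "
                f"feature {self.data.columns[j]!r}"
            )
        if self.assay_kind == "taxa" and np.nanmin(values) < 0:
            raise MatrixParseError("taxa abundances must be non-negative")
        self.data = self.data.astype(float)
        self.data.index = self.data.index.rename("sample_id")
        self.data.columns = self.data.columns.rename(None)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def restrict_samples(self, sample_ids: Sequence[str]) -> "OmicsMatrix":
        return OmicsMatrix(self.data.loc[list(sample_ids)], self.assay_kind)

    def write(self, path: str | Path, sep: str | None = None) -> None:
        sep = sep if sep is not None else _sep_for(path)
        self.data.to_csv(path, sep=sep, index_label="sample_id")


@dataclass
class CovariateTable:
    """Per-sample covariates; indexed by sample identifier.

    Covariates used for partial-correlation adjustment must be complete
    (no missing values) — validated by :meth:`require`.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        dup = self.data.index[self.data.index.duplicated()].unique().tolist()
        if dup:
            raise IdentifierError(f"duplicate sample identifiers: {dup}")
        self.data = self.data.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def require(self, names: Sequence[str]) -> pd.DataFrame:
        """Return the named covariate columns, validating completeness."""
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise IdentifierError(f"unknown covariates: {missing}")
        sub = self.data[list(names)]
        if sub.isna().any().any():
            bad = sub.columns[sub.isna().any()].tolist()
            raise MatrixParseError(f"missing values in adjustment covariates: {bad}")
        return sub

    def restrict_samples(self, sample_ids: Sequence[str]) -> "CovariateTable":
        return CovariateTable(self.data.loc[list(sample_ids)])

    def write(self, path: str | Path, sep: str | None = None) -> None:
        sep = sep if sep is not None else _sep_for(path)
        self.data.to_csv(path, sep=sep, index_label="sample_id")


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_matrix(
    path: str | Path,
    assay_kind: str,
    *,
    orientation_hint: str = "samples_by_features",
    known_sample_ids: Iterable[str] | None = None,
    sep: str | None = None,
) -> OmicsMatrix:
    """Read a delimited-text matrix into samples x features orientation.

    The on-disk file may be in either orientation (GEO expression matrices
    are genes x samples; abundance tables are samples x taxa).
    ``orientation_hint`` declares the expected on-disk layout
    (``"samples_by_features"`` or ``"features_by_samples"``); if
    ``known_sample_ids`` is given, the orientation is instead resolved by
    matching identifiers against it, overriding the hint when the evidence
    is unambiguous.
    """
    sep = sep if sep is not None else _sep_for(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise MatrixParseError(f"empty matrix file: {path}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise MatrixParseError(f"empty matrix file: {path}")
    non_numeric = df.map(lambda v: not _is_number(v))
    if non_numeric.any().any():
        i, j = np.argwhere(non_numeric.to_numpy())[0]
        raise MatrixParseError(
            f"non-numeric cell at row {df.index[i]!r}, column {df.columns[j]!r} in {path}"
        )
    df = df.astype(float)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)

    if known_sample_ids is not None:
        known = {str(s) for s in known_sample_ids}
        rows_hit = len(known.intersection(df.index))
        cols_hit = len(known.intersection(df.columns))
        if cols_hit > rows_hit:
            df = df.T
        elif rows_hit == cols_hit == 0:
            raise IdentifierError(
                f"no supplied sample identifiers found on either axis of {path}"
            )
    elif orientation_hint == "features_by_samples":
        df = df.T
    elif orientation_hint != "samples_by_features":
        raise ValueError(f"unknown orientation_hint {orientation_hint!r}")
    return OmicsMatrix(df, assay_kind)


def _is_number(v: object) -> bool:
    if isinstance(v, (int, float, np.integer, np.floating)):
        return True
    try:
        float(v)  # type: ignore[arg-type]
        return True
    except (TypeError, ValueError):
        return False


def read_covariates(path: str | Path, sep: str | None = None) -> CovariateTable:
    sep = sep if sep is not None else _sep_for(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    return CovariateTable(df)


def align_samples(
    *matrices: OmicsMatrix,
    covariates: CovariateTable | None = None,
) -> tuple[list, dict[int, int]]:
    """Restrict all inputs to the shared samples, in one canonical order.

    The canonical order is the sample order of the first matrix restricted
    to the intersection, which makes alignment idempotent and independent of
    the sample order of the other inputs.

    Returns
    -------
    aligned : list
        The input matrices (and covariate table, if given) restricted to the
        common samples, in input order.
    dropped : dict
        Number of samples dropped per input position.
    """
    if len(matrices) + (covariates is not None) < 2:
        raise ValueError("align_samples needs at least two inputs")
    id_sets = [set(m.sample_ids) for m in matrices]
    if covariates is not None:
        id_sets.append(set(covariates.sample_ids))
    common = set.intersection(*id_sets)
    if not common:
        counts = ", ".join(str(len(s)) for s in id_sets)
        raise AlignmentError(
            f"no samples shared by all inputs (per-input sample counts: {counts})"
        )
    order = [s for s in matrices[0].sample_ids if s in common]
    aligned: list = [m.restrict_samples(order) for m in matrices]
    dropped = {i: len(s) - len(common) for i, s in enumerate(id_sets[: len(matrices)])}
    if covariates is not None:
        aligned.append(covariates.restrict_samples(order))
        dropped[len(matrices)] = len(set(covariates.sample_ids)) - len(common)
    for i, n in dropped.items():
        if n:
            logger.info("align_samples: dropped %d sample(s) from input %d", n, i)
    return aligned, dropped


# ---------------------------------------------------------------------------
# Gene signatures
# ---------------------------------------------------------------------------

@dataclass
class GeneSignature:
    """Directional gene signature of one microbiome feature.

    ``up_genes`` are genes positively associated with the feature at the
    significance threshold ``alpha`` (on BH-adjusted p), ``down_genes`` the
    negatively associated ones; ``universe`` is the set of genes tested.
    """

    feature_id: str
    up_genes: frozenset[str]
    down_genes: frozenset[str]
    universe: frozenset[str]
    alpha: float = 0.05

    def __post_init__(self) -> None:
        self.up_genes = frozenset(map(normalize_gene_id, self.up_genes))
        self.down_genes = frozenset(map(normalize_gene_id, self.down_genes))
        self.universe = frozenset(map(normalize_gene_id, self.universe))
        overlap = self.up_genes & self.down_genes
        if overlap:
            raise ValueError(
                f"{self.feature_id}: genes in both up and down sets: {sorted(overlap)[:5]}"
            )
        stray = (self.up_genes | self.down_genes) - self.universe
        if stray:
            raise ValueError(
                f"{self.feature_id}: signature genes outside universe: {sorted(stray)[:5]}"
            )

    @property
    def is_empty(self) -> bool:
        return not (self.up_genes or self.down_genes)


@dataclass
class DrugSignature:
    """Up/down gene sets of one compound perturbation with its metadata."""

    drug_id: str
    up_genes: frozenset[str]
    down_genes: frozenset[str]
    universe: frozenset[str] = field(default_factory=frozenset)
    cell_line: str = ""
    dose: float = float("nan")
    dose_unit: str = ""
    time: float = float("nan")
    time_unit: str = ""

    def __post_init__(self) -> None:
        self.up_genes = frozenset(map(normalize_gene_id, self.up_genes))
        self.down_genes = frozenset(map(normalize_gene_id, self.down_genes))
        self.universe = frozenset(map(normalize_gene_id, self.universe))
        if not self.universe:
            self.universe = self.up_genes | self.down_genes
        overlap = self.up_genes & self.down_genes
        if overlap:
            raise ValueError(
                f"{self.drug_id}: genes in both up and down sets: {sorted(overlap)[:5]}"
            )


# ---------------------------------------------------------------------------
# GMT IO
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a GMT file into ``{set name: gene set}``.

    Each line is ``name<TAB>description<TAB>gene...`` with at least one gene.
    Gene identifiers are case-normalized. Malformed lines raise
    :class:`GmtFormatError` with the offending line number.
    """
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtFormatError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            name = fields[0].strip()
            genes = frozenset(
                normalize_gene_id(g) for g in fields[2:] if g.strip()
            )
            if not genes:
                raise GmtFormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            if name in sets:
                raise GmtFormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = genes
    return sets


def write_gmt(path: str | Path, sets: Mapping[str, Iterable[str]],
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "na")
            genes_sorted = sorted(normalize_gene_id(g) for g in genes)
            fh.write("\t".join([name, desc, *genes_sorted]) + "\n")


def pair_directional_sets(
    sets: Mapping[str, frozenset[str]],
) -> dict[str, tuple[frozenset[str], frozenset[str]]]:
    """Combine ``NAME_UP`` / ``NAME_DOWN`` sets into ``{NAME: (up, down)}``.

    An ``_UP`` set without a matching ``_DOWN`` (or vice versa) is retained
    with an empty complement and a warning. A gene appearing in both
    directions of one name is dropped from both (disjointness is an
    invariant of every signature) and logged.
    """
    names: dict[str, dict[str, frozenset[str]]] = {}
    for name, genes in sets.items():
        if name.endswith("_UP"):
            names.setdefault(name[:-3], {})["up"] = genes
        elif name.endswith("_DOWN"):
            names.setdefault(name[:-5], {})["down"] = genes
        else:
            names.setdefault(name, {})["up"] = genes
            logger.warning("gene set %r has no _UP/_DOWN suffix; treated as up", name)
    paired: dict[str, tuple[frozenset[str], frozenset[str]]] = {}
    for name, parts in names.items():
        up = parts.get("up", frozenset())
        down = parts.get("down", frozenset())
        if "up" not in parts or "down" not in parts:
            logger.warning("signature %r has only one direction", name)
        both = up & down
        if both:
            logger.warning(
                "signature %r: %d gene(s) in both directions dropped from both",
                name, len(both),
            )
            up, down = up - both, down - both
        paired[name] = (up, down)
    return paired


def read_signature_gmt_pair(
    up_path: str | Path, down_path: str | Path, *, alpha: float = 0.05,
    universe: Iterable[str] | None = None,
) -> list[GeneSignature]:
    """Read feature signatures serialized as paired up/down GMT files."""
    ups = read_gmt(up_path)
    downs = read_gmt(down_path)
    all_names = list(dict.fromkeys([*ups, *downs]))
    out = []
    for name in all_names:
        up = ups.get(name, frozenset())
        down = downs.get(name, frozenset())
        uni = frozenset(map(normalize_gene_id, universe)) if universe else (up | down)
        out.append(GeneSignature(name, up, down, uni | up | down, alpha=alpha))
    return out


def read_drug_gmt(
    gmt_path: str | Path, meta_path: str | Path | None = None,
    *, universe: Iterable[str] | None = None,
) -> list[DrugSignature]:
    """Read a drug catalog from one GMT of ``DRUG_UP``/``DRUG_DOWN`` lines.

    The optional metadata sidecar is a TSV with columns
    ``drug_id, cell_line, dose, dose_unit, time, time_unit``.
    """
    paired = pair_directional_sets(read_gmt(gmt_path))
    meta = {}
    if meta_path is not None:
        mdf = pd.read_csv(meta_path, sep="\t", dtype={"drug_id": str})
        meta = {row["drug_id"]: row for _, row in mdf.iterrows()}
    uni = frozenset(map(normalize_gene_id, universe)) if universe else None
    out = []
    for drug_id, (up, down) in paired.items():
        row = meta.get(drug_id)
        out.append(
            DrugSignature(
                drug_id=drug_id,
                up_genes=up,
                down_genes=down,
                universe=uni if uni is not None else frozenset(),
                cell_line=str(row["cell_line"]) if row is not None else "",
                dose=float(row["dose"]) if row is not None else float("nan"),
                dose_unit=str(row["dose_unit"]) if row is not None else "",
                time=float(row["time"]) if row is not None else float("nan"),
                time_unit=str(row["time_unit"]) if row is not None else "",
            )
        )
    return out


def write_drug_catalog(
    gmt_path: str | Path, meta_path: str | Path, drugs: Sequence[DrugSignature],
) -> None:
    sets: dict[str, Iterable[str]] = {}
    rows = []
    for d in drugs:
        sets[f"{d.drug_id}_UP"] = d.up_genes
        sets[f"{d.drug_id}_DOWN"] = d.down_genes
        rows.append(
            dict(drug_id=d.drug_id, cell_line=d.cell_line, dose=d.dose,
                 dose_unit=d.dose_unit, time=d.time, time_unit=d.time_unit)
        )
    write_gmt(gmt_path, {k: v for k, v in sets.items() if v})
    pd.DataFrame(rows).to_csv(meta_path, sep="\t", index=False)


def neg_log10_capped(q: float | np.ndarray, cap: float = 16.0):
    """``min(cap, -log10(q))`` with ``q == 0`` mapped to the cap.

    The cap keeps zero adjusted p-values finite for plotting and
    serialization of the -log10(Q) similarity matrices.
    """
    q_arr = np.asarray(q, dtype=float)
    with np.errstate(divide="ignore"):
        out = np.where(q_arr > 0.0, -np.log10(np.maximum(q_arr, 1e-300)), math.inf)
    out = np.minimum(out, cap)
    return float(out) if np.isscalar(q) or q_arr.ndim == 0 else out
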