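"""Reading, writing and preprocessing of expression studies.

The central container is :class:`ExpressionStudy`: a log-scale expression
matrix (genes x samples) together with per-gene genomic annotation
(chromosome, position), a binary sample phenotype (e.g. metastasis within
5 years vs. none) and optional per-sample covariates (receptor status,
age, batch, ...).

Preprocessing follows common microarray practice: probes mapping to the
same gene are collapsed by averaging their profiles, and clinical
covariates are regressed out per gene (robust Huber M-estimation by
default, plain least squares optionally), carrying the residuals forward
as the expression traits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionStudy",
    "ParseError",
    "read_expression_matrix",
    "collapse_probes",
    "adjust_covariates",
    "write_expression_matrix",
]


class ParseError(ValueError):
    """Raised for malformed input tables (names the offending line/cell)."""


@dataclass
class ExpressionStudy:
    """An expression matrix cross-referenced with gene and sample annotation.

    Parameters
    ----------
    matrix
        Genes x samples table of (log-scale) expression values. Row index
        holds gene/probe IDs, columns hold sample IDs.
    annotation
        Per-gene table with columns ``chrom`` and ``position_bp``, indexed
        by gene ID. Genes absent from the annotation are kept in the matrix
        but treated as *unplaced* (NaN chromosome/position); they are
        excluded from chromosome tracks downstream but still usable for
        network stages.
    phenotype
        Binary group label (0/1) per sample, aligned with the matrix columns.
    covariates
        Optional per-sample covariate table (numeric or categorical).
    """

    matrix: pd.DataFrame
    annotation: pd.DataFrame
    phenotype: pd.Series
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)
    study_id: str = "study"

    def __post_init__(self) -> None:
        samples = list(self.matrix.columns)
        if list(self.phenotype.index) != samples:
            self.phenotype = self.phenotype.reindex(samples)
        if self.phenotype.isna().any():
            missing = self.phenotype.index[self.phenotype.isna()].tolist()
            raise ValueError(f"samples missing from phenotype table: {missing}")
        values = set(pd.unique(self.phenotype))
        if not values <= {0, 1}:
            raise ValueError(f"phenotype labels must be 0/1, got {sorted(values)}")
        self.phenotype = self.phenotype.astype(int)
        # Align annotation to matrix rows; unknown genes become unplaced rows.
        ann = self.annotation.reindex(self.matrix.index)
        for col in ("chrom", "position_bp"):
            if col not in ann.columns:
                ann[col] = np.nan
        pos = ann["position_bp"].dropna()
        if (pos < 0).any():
            raise ValueError("gene positions must be non-negative")
        self.annotation = ann
        if len(self.covariates) and list(self.covariates.index) != samples:
            self.covariates = self.covariates.reindex(samples)

    # -- convenience views -------------------------------------------------
    @property
    def genes(self) -> list:
        return list(self.matrix.index)

    @property
    def samples(self) -> list:
        return list(self.matrix.columns)

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def placed_genes(self) -> pd.Index:
        """Genes with both a chromosome label and a bp position."""
        ann = self.annotation
        ok = ann["chrom"].notna() & ann["position_bp"].notna()
        return self.matrix.index[ok.to_numpy()]

    def group_masks(self) -> tuple[np.ndarray, np.ndarray]:
        """Boolean masks (group1, group0) over the sample axis."""
        lab = self.phenotype.to_numpy()
        return lab == 1, lab == 0


def _parse_matrix_tsv(path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ParseError(f"{path}: header must contain at least one sample column")
        samples = header[1:]
        n_fields = len(header)
        ids, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n_fields:
                raise ParseError(
                    f"{path}: line {lineno} has {len(parts)} fields, expected {n_fields}"
                )
            ids.append(parts[0])
            try:
                rows.append([float(v) for v in parts[1:]])
            except ValueError:
                bad = next(v for v in parts[1:] if not _is_number(v))
                raise ParseError(
                    f"{path}: non-numeric expression value {bad!r} on line {lineno}"
                ) from None
    return pd.DataFrame(np.asarray(rows, dtype=float), index=ids, columns=samples)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def read_expression_matrix(path, annotation_path, phenotype_path) -> ExpressionStudy:
    """Load a TSV expression matrix plus gene annotation and phenotype tables.

    The matrix TSV has a header row of sample IDs and gene/probe IDs in the
    first column. The annotation TSV needs columns ``gene_id``, ``chrom``,
    ``position_bp``; the phenotype TSV needs ``sample_id`` and ``group``
    (0/1), with any further columns taken as covariates.

    Duplicate probe IDs are accepted here (collapsing is a separate step);
    genes missing from the annotation are retained as unplaced. A sample
    present in the matrix but absent from the phenotype table is an error.
    """
    matrix = _parse_matrix_tsv(path)
    ann = pd.read_csv(annotation_path, sep="\t", dtype={"gene_id": str, "chrom": str})
    if "gene_id" not in ann.columns:
        raise ParseError(f"{annotation_path}: missing required column 'gene_id'")
    ann = ann.set_index("gene_id")
    pheno = pd.read_csv(phenotype_path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "group"):
        if col not in pheno.columns:
            raise ParseError(f"{phenotype_path}: missing required column {col!r}")
    pheno = pheno.set_index("sample_id")
    missing = [s for s in matrix.columns if s not in pheno.index]
    if missing:
        raise ValueError(f"samples missing from phenotype table: {missing}")
    pheno = pheno.loc[list(matrix.columns)]
    covariates = pheno.drop(columns=["group"])
    n_unplaced = int((~matrix.index.isin(ann.index)).sum())
    if n_unplaced:
        logger.info("%d matrix rows have no annotation (kept as unplaced)", n_unplaced)
    return ExpressionStudy(
        matrix=matrix,
        annotation=ann,
        phenotype=pheno["group"],
        covariates=covariates,
    )


def write_expression_matrix(study: ExpressionStudy, path) -> None:
    """Serialize the matrix back to the TSV dialect consumed by the reader."""
    out = study.matrix.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def collapse_probes(study: ExpressionStudy, probe_map) -> ExpressionStudy:
    """Average probe profiles mapping to the same gene.

    ``probe_map`` maps probe ID -> gene ID (a mapping, Series, or two-column
    DataFrame ``probe_id``/``gene_id``). Probes without a mapping are dropped
    (the count is logged). Raises if no matrix row is covered by the map.
    """
    if isinstance(probe_map, pd.DataFrame):
        probe_map = probe_map.set_index("probe_id")["gene_id"]
    probe_map = pd.Series(dict(probe_map)) if not isinstance(probe_map, pd.Series) else probe_map

    mapped = study.matrix.index[study.matrix.index.isin(probe_map.index)]
    if len(mapped) == 0:
        raise ValueError("probe map shares no probe IDs with the expression matrix")
    n_dropped = study.n_genes - len(mapped)
    if n_dropped:
        logger.info("collapse_probes: dropped %d unmapped probes", n_dropped)
    sub = study.matrix.loc[mapped]
    genes = probe_map.loc[mapped]
    collapsed = sub.groupby(genes.to_numpy()).mean()
    collapsed = collapsed.loc[pd.unique(genes)]  # first-seen gene order
    return replace(study, matrix=collapsed, annotation=study.annotation)


def _design_matrix(covariates: pd.DataFrame, names: list) -> pd.DataFrame:
    missing = [c for c in names if c not in covariates.columns]
    if missing:
        raise KeyError(f"covariates not found: {missing}")
    sub = covariates[names]
    if sub.isna().any().any():
        raise ValueError("covariates contain missing values")
    X = pd.get_dummies(sub, drop_first=True, dtype=float)
    X.insert(0, "const", 1.0)
    return X


def adjust_covariates(
    study: ExpressionStudy,
    covariate_names: list,
    method: str = "robust",
    max_iter: int = 50,
    tol: float = 1e-8,
) -> ExpressionStudy:
    """Regress covariates out of every gene and carry the residuals forward.

    ``method="robust"`` fits a Huber M-estimator per gene by iteratively
    reweighted least squares (tuning constant 1.345, the conventional 95%%
    efficiency default); ``method="ols"`` uses ordinary least squares, for
    which re-adjusting residuals on the same design is a no-op. Categorical
    covariates are one-hot encoded with the first level dropped.

    Constant expression rows yield all-zero residuals and a warning;
    a rank-deficient design raises, naming the collinear columns.
    """
    if method not in ("robust", "ols"):
        raise ValueError(f"unknown method {method!r}")
    X = _design_matrix(study.covariates, list(covariate_names))
    p = X.shape[1]
    if study.n_samples < p + 1:
        raise ValueError(f"need at least {p + 1} samples for {p} design columns")
    Xv = X.to_numpy()
    rank = np.linalg.matrix_rank(Xv)
    if rank < p:
        # identify columns involved in the deficiency
        keep, bad = [], []
        for j in range(p):
            trial = Xv[:, keep + [j]]
            if np.linalg.matrix_rank(trial) > len(keep):
                keep.append(j)
            else:
                bad.append(X.columns[j])
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")

    Y = study.matrix.to_numpy()
    const_rows = Y.std(axis=1) == 0.0
    resid = np.zeros_like(Y)
    if method == "ols":
        beta, *_ = np.linalg.lstsq(Xv, Y.T, rcond=None)
        resid = Y - (Xv @ beta).T
    else:
        huber = sm.robust.norms.HuberT(t=1.345)
        for i in range(Y.shape[0]):
            if const_rows[i]:
                continue
            fit = sm.RLM(Y[i], Xv, M=huber).fit(maxiter=max_iter, tol=tol)
            resid[i] = fit.resid
    resid[const_rows] = 0.0
    if const_rows.any():
        logger.warning(
            "adjust_covariates: %d constant expression rows set to zero residuals",
            int(const_rows.sum()),
        )
    adjusted = pd.DataFrame(resid, index=study.matrix.index, columns=study.matrix.columns)
    return replace(study, matrix=adjusted)
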