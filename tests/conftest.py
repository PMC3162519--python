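import numpy as np
import pandas as pd
import pytest

from wacekit.io import ExpressionStudy


def make_study(
    n_genes=12,
    n_per_group=5,
    seed=0,
    chrom="chr1",
    spacing=100_000,
    covariates=None,
) -> ExpressionStudy:
    """Small single-chromosome noise study used across unit tests."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i:03d}" for i in range(n_genes)]
    samples = [f"s{i:02d}" for i in range(2 * n_per_group)]
    matrix = pd.DataFrame(rng.standard_normal((n_genes, 2 * n_per_group)),
                          index=genes, columns=samples)
    annotation = pd.DataFrame(
        {"chrom": [chrom] * n_genes,
         "position_bp": [(i + 1) * spacing for i in range(n_genes)]},
        index=genes,
    )
    phenotype = pd.Series([1] * n_per_group + [0] * n_per_group, index=samples)
    cov = pd.DataFrame(covariates, index=samples) if covariates is not None else pd.DataFrame(index=samples)
    return ExpressionStudy(matrix=matrix, annotation=annotation,
                           phenotype=phenotype, covariates=cov)


@pytest.fixture
def tiny_study():
    return make_study()


@pytest.fixture
def study_files(tmp_path):
    """A 3-gene x 4-sample study written out as the three TSV inputs."""
    matrix = tmp_path / "matrix.tsv"
    matrix.write_text(
        "gene_id\ts1\ts2\ts3\ts4\n"
        "gA\t1.0\t2.0\t3.0\t4.0\n"
        "gB\t0.5\t0.5\t0.5\t0.5\n"
        "gC\t-1.0\t0.0\t1.0\t2.0\n"
    )
    annotation = tmp_path / "annotation.tsv"
    annotation.write_text(
        "gene_id\tchrom\tposition_bp\n"
        "gA\tchr1\t1000\n"
        "gB\tchr1\t2000\n"
        "gC\tchr2\t1500\n"
    )
    phenotype = tmp_path / "phenotype.tsv"
    phenotype.write_text(
        "sample_id\tgroup\tage\n"
        "s1\t1\t50\n"
        "s2\t1\t61\n"
        "s3\t0\t47\n"
        "s4\t0\t55\n"
    )
    return matrix, annotation, phenotype
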