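"""siRNA viability signatures and gene-set fold enrichment.

A viability screen reports, per gene and cell line, cell growth as a
percentage of a negative-control (luciferase siRNA) median. Genes whose
knockdown drops viability more than ``k`` standard deviations below the
screen median form a hit signature: V1 thresholds a combined
across-cell-line score, per-line signatures threshold each line's own
distribution, and V2 is the union of V1 with all per-line signatures
(so V1 is always a subset of V2).

Enrichment of a hit set in a target gene set is the ratio of in-target
hit rate to background hit rate, with a one-sided Fisher exact
(hypergeometric upper-tail) p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ViabilityScreen",
    "EnrichmentResult",
    "viability_cutoff",
    "derive_signatures",
    "fold_enrichment",
    "read_screen_tsv",
    "write_gmt",
]


@dataclass
class ViabilityScreen:
    """Per-gene, per-cell-line viability (% of control), plus an optional
    precomputed combined across-cell-line score per gene."""

    viability: pd.DataFrame  # genes x cell lines, percent
    combined: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.viability.to_numpy() < 0).any():
            raise ValueError("viability percentages must be >= 0")
        if self.viability.notna().sum(axis=1).min() < 1:
            raise ValueError("every gene needs at least one cell-line measurement")
        if self.combined is not None:
            self.combined = self.combined.reindex(self.viability.index)

    def combined_scores(self, combiner="median") -> pd.Series:
        """Across-cell-line score per gene: the stored column if present,
        else a pluggable row summary (``"median"``, ``"mean"``, ``"min"`` or
        a callable Series -> float applied per row)."""
        if self.combined is not None:
            return self.combined
        if callable(combiner):
            return self.viability.apply(combiner, axis=1)
        if combiner in ("median", "mean", "min"):
            return getattr(self.viability, combiner)(axis=1)
        raise ValueError(f"unknown combiner {combiner!r}")


@dataclass
class EnrichmentResult:
    fold: float
    p_value: float
    hits_in_set: int
    set_size: int
    hits_in_background: int
    background_size: int

    counts: tuple = field(init=False)

    def __post_init__(self) -> None:
        self.counts = (self.hits_in_set, self.set_size,
                       self.hits_in_background, self.background_size)


def viability_cutoff(scores, k: float = 1.5) -> float:
    """Hit threshold: median(scores) - k * sample standard deviation (n-1)."""
    scores = np.asarray(list(scores), dtype=float)
    if len(scores) < 2:
        raise ValueError("need at least 2 scores")
    return float(np.median(scores) - k * np.std(scores, ddof=1))


def derive_signatures(
    screen: ViabilityScreen, k: float = 1.5, combiner="median"
) -> tuple[set, set]:
    """Derive the across-line signature V1 and the union signature V2.

    V1: genes whose combined across-cell-line score falls strictly below
    the cutoff computed on the combined-score distribution. Per-line
    signatures apply the same rule within each cell line; V2 is V1 united
    with all of them.
    """
    combined = screen.combined_scores(combiner).dropna()
    if len(combined) == 0:
        raise ValueError("no combined across-cell-line scores available")
    cut = viability_cutoff(combined, k)
    v1 = set(combined.index[combined < cut])
    v2 = set(v1)
    for line in screen.viability.columns:
        col = screen.viability[line].dropna()
        if len(col) < 2:
            continue
        line_cut = viability_cutoff(col, k)
        v2 |= set(col.index[col < line_cut])
    return v1, v2


def fold_enrichment(hits, target, background) -> EnrichmentResult:
    """Fold enrichment of ``hits`` in ``target`` relative to ``background``.

    fold = (|hits ∩ target| / |target|) / (|hits| / |background|); the
    p-value is the exact hypergeometric upper tail (one-sided Fisher) for
    drawing at least the observed overlap when |target| genes are sampled
    from the background.
    """
    hits, target, background = set(hits), set(target), set(background)
    if not target or not background:
        raise ValueError("target and background must be non-empty")
    if not target <= background:
        raise ValueError("target must be a subset of background")
    if not hits <= background:
        raise ValueError("hits must be a subset of background")
    a = len(hits & target)
    if len(hits) == 0:
        fold = 0.0
    else:
        fold = (a / len(target)) / (len(hits) / len(background))
    # P(X >= a), X ~ Hypergeom(M=|bg|, n=|hits|, N=|target|)
    p = float(stats.hypergeom.sf(a - 1, len(background), len(hits), len(target)))
    return EnrichmentResult(
        fold=fold,
        p_value=min(p, 1.0),
        hits_in_set=a,
        set_size=len(target),
        hits_in_background=len(hits),
        background_size=len(background),
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_screen_tsv(path) -> ViabilityScreen:
    """Read a long-format screen TSV (gene_id, cell_line, viability_pct) or a
    wide table (gene_id plus one column per line, optional ``combined``)."""
    df = pd.read_csv(path, sep="\t")
    if {"gene_id", "cell_line", "viability_pct"} <= set(df.columns):
        wide = df.pivot_table(index="gene_id", columns="cell_line",
                              values="viability_pct", aggfunc="mean")
        return ViabilityScreen(viability=wide)
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: expected 'gene_id' column")
    df = df.set_index("gene_id")
    combined = df.pop("combined") if "combined" in df.columns else None
    return ViabilityScreen(viability=df, combined=combined)


def write_gmt(signatures: dict, path, description: str = "wacekit") -> None:
    """Write gene sets as GMT (name, description, tab-separated members)."""
    with open(path, "w") as fh:
        for name, genes in signatures.items():
            fh.write("\t".join([name, description] + sorted(map(str, genes))) + "\n")
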