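"""Cross-study alignment of inferred CNV regions into recurrent regions.

A locus is *recurrent* when same-sign regions from at least ``k`` distinct
studies cover it. Each maximal >=k-coverage core interval is expanded to
the union of the study regions that intersect it, so a recurrent region
keeps the full extent of its supporting evidence; gains and losses are
aligned independently and may overlap each other.

Intervals use inclusive bp coordinates in memory (region endpoints anchor
at member-gene positions); BED serialization converts to the 0-based
half-open convention, with the strand column repurposed to carry the sign
('+' gain, '-' loss).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .wace import GAIN, LOSS, ICNVRegion

__all__ = [
    "RecurrentRegion",
    "RecurrentRegionSet",
    "align_regions",
    "genes_in_regions",
    "overlap_summary",
    "write_regions_bed",
    "read_regions_bed",
]


@dataclass
class RecurrentRegion:
    chromosome: str
    start_bp: int
    end_bp: int
    sign: str
    supporting_studies: frozenset
    source_regions: list = field(default_factory=list)

    @property
    def k_support(self) -> int:
        return len(self.supporting_studies)


@dataclass
class RecurrentRegionSet:
    regions: list
    k: int
    m: int  # total studies supplied

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "chromosome": r.chromosome,
                "start_bp": r.start_bp,
                "end_bp": r.end_bp,
                "sign": r.sign,
                "k_support": r.k_support,
                "studies": ",".join(sorted(r.supporting_studies)),
            }
            for r in self.regions
        ]
        return pd.DataFrame(rows)


def _coverage_cores(intervals: list[tuple[int, int]], k: int) -> list[tuple[int, int]]:
    """Maximal inclusive intervals covered by >= k of the given intervals."""
    events: dict[int, int] = defaultdict(int)
    for s, e in intervals:
        events[s] += 1
        events[e + 1] -= 1
    cores = []
    depth = 0
    start = None
    for x in sorted(events):
        depth += events[x]
        if depth >= k and start is None:
            start = x
        elif depth < k and start is not None:
            cores.append((start, x - 1))
            start = None
    return cores


def align_regions(region_sets, k: int = 2) -> RecurrentRegionSet:
    """Align per-study region lists into recurrent regions supported by >= k studies.

    ``region_sets`` is either a mapping study_id -> list of
    :class:`~wacekit.wace.ICNVRegion` or a flat iterable of regions carrying
    ``study_id``. Coverage is counted per study (multiple overlapping
    regions from one study count once), per chromosome and sign; each
    maximal >=k core is expanded to the union of intersecting same-sign
    study regions, and overlapping expanded regions are merged so the final
    same-sign regions are disjoint.
    """
    if isinstance(region_sets, dict):
        regions = [r for rs in region_sets.values() for r in rs]
        studies = set(region_sets.keys())
    else:
        regions = list(region_sets)
        studies = {r.study_id for r in regions}
    m = len(studies)
    if k > m:
        raise ValueError(f"k={k} exceeds the number of studies supplied ({m})")
    if k < 1:
        raise ValueError("k must be >= 1")

    grouped: dict[tuple[str, str], list[ICNVRegion]] = defaultdict(list)
    for r in regions:
        grouped[(r.chromosome, r.sign)].append(r)

    out: list[RecurrentRegion] = []
    for (chrom, sign), regs in grouped.items():
        # per-study flattened coverage so one study never counts twice
        per_study: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for r in regs:
            per_study[r.study_id].append((r.start_bp, r.end_bp))
        study_cover = []
        for sid, ivs in per_study.items():
            study_cover.extend(_coverage_cores(ivs, 1))  # merge within study
        cores = _coverage_cores(study_cover, k)
        expanded = []
        for cs, ce in cores:
            hit = [r for r in regs if r.start_bp <= ce and r.end_bp >= cs]
            expanded.append(
                (
                    min(r.start_bp for r in hit),
                    max(r.end_bp for r in hit),
                    frozenset(r.study_id for r in hit),
                    hit,
                )
            )
        # merge overlapping expanded intervals -> disjoint same-sign regions
        expanded.sort(key=lambda t: t[0])
        merged: list[list] = []
        for s, e, sup, hit in expanded:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
                merged[-1][2] |= sup
                merged[-1][3].extend(hit)
            else:
                merged.append([s, e, set(sup), list(hit)])
        for s, e, sup, hit in merged:
            out.append(
                RecurrentRegion(
                    chromosome=chrom,
                    start_bp=s,
                    end_bp=e,
                    sign=sign,
                    supporting_studies=frozenset(sup),
                    source_regions=hit,
                )
            )
    out.sort(key=lambda r: (str(r.chromosome), r.start_bp, r.sign))
    return RecurrentRegionSet(regions=out, k=k, m=m)


def genes_in_regions(regions, annotation) -> dict[str, set]:
    """Genes whose position falls inside a region (closed interval), per sign.

    ``regions`` is a :class:`RecurrentRegionSet` or iterable of regions with
    chromosome/start_bp/end_bp/sign; ``annotation`` is the per-gene table
    (columns ``chrom`` and ``position_bp``).
    """
    placed = annotation[annotation["chrom"].notna() & annotation["position_bp"].notna()]
    result: dict[str, set] = {GAIN: set(), LOSS: set()}
    by_chrom: dict[str, pd.DataFrame] = dict(tuple(placed.groupby("chrom")))
    for r in regions:
        sub = by_chrom.get(r.chromosome)
        if sub is None:
            continue
        pos = sub["position_bp"]
        inside = sub.index[(pos >= r.start_bp) & (pos <= r.end_bp)]
        result[r.sign].update(inside)
    return result


def overlap_summary(queries, references) -> tuple[int, int, float]:
    """How many query intervals intersect (>=1 bp) any reference interval.

    Returns ``(n_overlapping, n_total, percent)``. Signs are ignored: this
    serves cross-platform comparisons (e.g. aCGH segment calls against
    expression-inferred recurrent regions) where the two sides need not
    agree on direction to count as concordant loci.
    """
    refs = defaultdict(list)
    for r in references:
        refs[r.chromosome].append((r.start_bp, r.end_bp))
    n_total = 0
    n_hit = 0
    for q in queries:
        n_total += 1
        if any(q.start_bp <= e and q.end_bp >= s for s, e in refs.get(q.chromosome, ())):
            n_hit += 1
    pct = 100.0 * n_hit / n_total if n_total else float("nan")
    return n_hit, n_total, pct


# ---------------------------------------------------------------------------
# BED serialization
# ---------------------------------------------------------------------------


def write_regions_bed(regions, path, name_prefix: str | None = None) -> None:
    """Write regions as BED6 (0-based half-open; strand column carries sign)."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            label = getattr(r, "study_id", None) or name_prefix or "region"
            score = getattr(r, "mean_abs_ns", float("nan"))
            score_txt = f"{score:.4f}" if score == score else "0"
            fh.write(
                "\t".join(
                    [
                        str(r.chromosome),
                        str(r.start_bp),            # inclusive -> 0-based start
                        str(r.end_bp + 1),          # inclusive -> half-open end
                        f"{label}:{i}",
                        score_txt,
                        "+" if r.sign == GAIN else "-",
                    ]
                )
                + "\n"
            )


def read_regions_bed(path, study_id: str = "study") -> list[ICNVRegion]:
    """Read BED6 regions written by :func:`write_regions_bed` (or equivalent)."""
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}: BED6 requires 6 columns, got {len(parts)}")
            chrom, start, end, name, score, strand = parts[:6]
            regions.append(
                ICNVRegion(
                    chromosome=chrom,
                    start_bp=int(start),
                    end_bp=int(end) - 1,
                    sign=GAIN if strand == "+" else LOSS,
                    gene_ids=[],
                    n_significant=1,
                    study_id=study_id,
                    mean_abs_ns=float(score) if score not in (".", "") else float("nan"),
                )
            )
    return regions
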