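"""Align inferred CNV regions across four simulated studies.

Two segments are shared by every study while a third is private to one;
with k=2 the alignment keeps only loci supported by at least two studies,
so the private segment drops out.
"""

from wacekit.recurrent import align_regions, genes_in_regions
from wacekit.simdata import SimConfig, simulate_study
from wacekit.wace import infer_icnv_regions

shared = [("chr1", (40, 69), "gain", 1.0), ("chr3", (100, 129), "loss", 1.0)]
per_study = {}
for s in range(4):
    segments = list(shared)
    if s == 0:
        segments.append(("chr6", (10, 39), "gain", 1.0))  # one study only
    cfg = SimConfig(n_genes=2000, n_samples_per_group=50, n_chromosomes=8,
                    segments=segments, seed=100 + s)
    study, _ = simulate_study(cfg)
    study.study_id = f"study{s}"
    regions, _ = infer_icnv_regions(study, B=200, seed=s, fdr_method="excess")
    per_study[study.study_id] = regions
    print(f"study{s}: {len(regions)} regions")

rrs = align_regions(per_study, k=2)
print(f"\nrecurrent regions (k={rrs.k} of m={rrs.m} studies):")
print(rrs.to_dataframe().to_string(index=False))

study, _ = simulate_study(cfg)
members = genes_in_regions(rrs, study.annotation)
print(f"\n{len(members['gain'])} genes in recurrent gains, "
      f"{len(members['loss'])} in recurrent losses")
# The chr6 segment seen in a single study is absent: recurrence across
# independent cohorts is the guard against study-specific artifacts.
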