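"""Map DMRs onto genes and classify differentially methylated genes (DMGs).

A gene is differentially methylated when at least one DMR overlaps (by at
least 1 bp) its body, its 2 kb upstream flank, or its 2 kb downstream
flank.  Flanks are strand-aware (upstream is 5' of the gene body) and
clipped at chromosome ends.  Each DMG carries exactly one direction: the
shared direction of its member DMRs, or — when they disagree — the
direction of the member with the smallest adjusted p (ties broken by
larger span, then hyper).  Summaries include cross-comparison overlaps by
direction combination and the 7-way body/upstream/downstream partition.
"""

from __future__ import annotations

import dataclasses
from itertools import product
from typing import Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

FLANK = 2000  # bp, either side of the gene body

DMG_COLUMNS = [
    "gene_id",
    "chrom",
    "direction",
    "best_p_adj",
    "in_body",
    "in_upstream",
    "in_downstream",
    "n_dmrs",
    "dmrs",
]

PARTITION_BUCKETS = [
    "body",
    "upstream",
    "downstream",
    "body+upstream",
    "body+downstream",
    "upstream+downstream",
    "body+upstream+downstream",
]


@dataclasses.dataclass(frozen=True)
class GeneRegions:
    """Body and flanking intervals of one gene (1-based inclusive).

    Empty flanks (a gene starting at position 1, say) are ``None``.
    """

    gene_id: str
    chrom: str
    strand: str
    body: tuple[int, int]
    upstream: tuple[int, int] | None
    downstream: tuple[int, int] | None


def gene_regions(
    gene, chrom_length: int | None = None, flank: int = FLANK
) -> GeneRegions:
    """Compute strand-aware body/upstream/downstream intervals of a gene.

    ``gene`` is any object with gene_id, chrom, strand, start, end
    attributes (e.g. a row from :func:`methylite.io.read_gff3_genes` via
    ``itertuples``).  Intervals are clipped to [1, chrom_length].
    """
    start, end = int(gene.start), int(gene.end)
    if start > end:
        raise ValueError(f"gene {gene.gene_id}: start > end")
    length = chrom_length if chrom_length is not None else end + flank

    def clip(lo: int, hi: int) -> tuple[int, int] | None:
        lo, hi = max(1, lo), min(length, hi)
        return (lo, hi) if lo <= hi else None

    left = clip(start - flank, start - 1)
    right = clip(end + 1, end + flank)
    if gene.strand == "-":
        upstream, downstream = right, left
    else:
        upstream, downstream = left, right
    return GeneRegions(
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        strand=gene.strand,
        body=(start, end),
        upstream=upstream,
        downstream=downstream,
    )


def direction_assign(members: pd.DataFrame) -> str:
    """Assign one exclusive direction to a DMG from its member DMRs.

    A shared direction wins outright; otherwise the member with the
    smallest adjusted p decides, with ties broken by larger span and then
    by hyper.
    """
    dirs = members["direction"].unique()
    if len(dirs) == 1:
        return str(dirs[0])
    ranked = members.assign(
        _span=members["end"] - members["start"] + 1,
        _hyper=(members["direction"] == "hyper"),
    ).sort_values(
        ["best_p_adj", "_span", "_hyper"], ascending=[True, False, False],
        kind="mergesort",
    )
    return str(ranked.iloc[0]["direction"])


def annotate_dmgs(
    dmrs: pd.DataFrame,
    genes: pd.DataFrame,
    chrom_lengths: Mapping[str, int] | None = None,
    flank: int = FLANK,
) -> pd.DataFrame:
    """Intersect DMRs with gene bodies and flanks and classify DMGs.

    Only features of class ``gene`` are considered (transposable elements
    participate in feature-level summaries, not DMG calling).  A DMR may
    hit several genes and a gene several DMRs; a 1 bp intersection
    suffices.  Returns one row per DMG with region flags and the member
    DMR coordinates.
    """
    feats = genes
    if "feature_class" in genes.columns:
        feats = genes[genes["feature_class"] == "gene"]

    # canonical DMR order makes the annotation input-order invariant
    dmr_tab = dmrs.sort_values(
        ["chrom", "start", "end", "direction"], kind="mergesort"
    ).reset_index(drop=True)
    trees: dict[str, IntervalTree] = {}
    for idx, row in dmr_tab.iterrows():
        trees.setdefault(row["chrom"], IntervalTree()).addi(
            int(row["start"]), int(row["end"]) + 1, idx
        )

    rows = []
    for gene in feats.itertuples(index=False):
        length = chrom_lengths.get(gene.chrom) if chrom_lengths else None
        regions = gene_regions(gene, length, flank)
        tree = trees.get(gene.chrom)
        if tree is None:
            continue
        hits: dict[str, set[int]] = {"body": set(), "upstream": set(), "downstream": set()}
        for name in hits:
            interval = getattr(regions, name)
            if interval is None:
                continue
            lo, hi = interval
            hits[name] = {iv.data for iv in tree.overlap(lo, hi + 1)}
        member_idx = sorted(hits["body"] | hits["upstream"] | hits["downstream"])
        if not member_idx:
            continue
        members = dmr_tab.loc[member_idx]
        rows.append(
            {
                "gene_id": gene.gene_id,
                "chrom": gene.chrom,
                "direction": direction_assign(members),
                "best_p_adj": float(members["best_p_adj"].min()),
                "in_body": bool(hits["body"]),
                "in_upstream": bool(hits["upstream"]),
                "in_downstream": bool(hits["downstream"]),
                "n_dmrs": len(member_idx),
                "dmrs": ";".join(
                    f"{m.chrom}:{m.start}-{m.end}:{m.direction}"
                    for m in members.itertuples(index=False)
                ),
            }
        )
    frame = pd.DataFrame(rows, columns=DMG_COLUMNS)
    return frame.sort_values("gene_id", kind="mergesort").reset_index(drop=True)


def overlap_analysis(
    dmgs_1: pd.DataFrame,
    dmgs_2: pd.DataFrame,
    name_1: str = "set1",
    name_2: str = "set2",
) -> pd.DataFrame:
    """Cross-tabulate shared DMGs between two comparisons by direction.

    For every (direction in set 1, direction in set 2) combination the
    intersection of gene ids is counted, and the percentage is reported
    against the named reference set (the direction subset of set 1).
    """
    by_dir_1 = {d: set(dmgs_1.loc[dmgs_1["direction"] == d, "gene_id"]) for d in ("hyper", "hypo")}
    by_dir_2 = {d: set(dmgs_2.loc[dmgs_2["direction"] == d, "gene_id"]) for d in ("hyper", "hypo")}
    rows = []
    for d1, d2 in product(("hyper", "hypo"), repeat=2):
        inter = by_dir_1[d1] & by_dir_2[d2]
        denom = len(by_dir_1[d1])
        rows.append(
            {
                "direction_1": d1,
                "direction_2": d2,
                "count": len(inter),
                "percent_of_reference": 100.0 * len(inter) / denom if denom else np.nan,
                "reference_set": f"{name_1}:{d1} (n={denom})",
                "comparison": f"{name_1} vs {name_2}",
            }
        )
    return pd.DataFrame(rows)


def region_partition(dmgs: pd.DataFrame) -> pd.Series:
    """7-way partition of DMGs over {body, upstream, downstream} hits.

    Buckets are disjoint and exhaustive; counts sum to the number of DMGs.
    """
    counts = {bucket: 0 for bucket in PARTITION_BUCKETS}
    for row in dmgs.itertuples(index=False):
        parts = [
            name
            for name, flag in (
                ("body", row.in_body),
                ("upstream", row.in_upstream),
                ("downstream", row.in_downstream),
            )
            if flag
        ]
        counts["+".join(parts)] += 1
    return pd.Series(counts, name="n_dmgs")
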