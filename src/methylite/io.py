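"""Readers and writers for the on-disk formats the pipeline touches.

Formats: a 7-column tab-separated per-cytosine report (the CX dialect
emitted by bisulfite aligners; both covered and uncovered cytosines are
allowed), GFF3 gene models, BED6 for DMRs, and headered TSV tables whose
header line starts with ``#``.  Cytosine reports and GFF3 are 1-based
inclusive; BED output is 0-based half-open.  Strands are reported
separately and never pooled at I/O level.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import os

import gffutils
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CX_COLUMNS = [
    "chrom",
    "pos",
    "strand",
    "n_meth",
    "n_unmeth",
    "context",
    "trinucleotide",
]
VALID_CONTEXTS = {"CG", "CHG", "CHH"}
GENE_COLUMNS = ["gene_id", "chrom", "strand", "start", "end", "feature_class"]
MARKER_COLUMNS = [
    "chrom",
    "pos",
    "allele_high_mut",
    "allele_high_wt",
    "allele_norm_mut",
    "allele_norm_wt",
]


class CxFormatError(ValueError):
    """A cytosine report violates the 7-column dialect."""


@dataclasses.dataclass
class MethylomeSample:
    """One bisulfite sample: labels plus its per-cytosine count table.

    Records are kept sorted by (chrom, pos, strand).
    """

    sample_id: str = "sample"
    tissue: str | None = None
    genotype: str | None = None
    data: pd.DataFrame = dataclasses.field(
        default_factory=lambda: pd.DataFrame(columns=CX_COLUMNS)
    )

    def __post_init__(self) -> None:
        if list(self.data.columns) != CX_COLUMNS:
            raise ValueError(f"sample data must have columns {CX_COLUMNS}")
        if len(self.data):
            self.data = self.data.sort_values(
                ["chrom", "pos", "strand"], kind="mergesort"
            ).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)


def read_cx_report(
    path: str | os.PathLike,
    sample_id: str | None = None,
    tissue: str | None = None,
    genotype: str | None = None,
) -> MethylomeSample:
    """Parse a 7-column cytosine report into a sorted sample.

    Malformed rows are reported with their line numbers; duplicate
    (chrom, pos, strand) triples and unknown context tokens raise
    :class:`CxFormatError`.  An empty file yields an empty sample and a
    logged warning.
    """
    chroms: list[str] = []
    poss: list[int] = []
    strands: list[str] = []
    meths: list[int] = []
    unmeths: list[int] = []
    ctxs: list[str] = []
    tris: list[str] = []
    bad: list[tuple[int, str]] = []

    with open(path, "r", encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                bad.append((lineno, f"expected 7 fields, got {len(fields)}"))
                continue
            chrom, pos_s, strand, m_s, u_s, ctx, tri = fields
            try:
                pos = int(pos_s)
                n_meth = int(m_s)
                n_unmeth = int(u_s)
            except ValueError:
                bad.append((lineno, "non-integer pos or count"))
                continue
            if pos < 1 or n_meth < 0 or n_unmeth < 0:
                bad.append((lineno, "pos must be >= 1 and counts >= 0"))
                continue
            if strand not in ("+", "-"):
                bad.append((lineno, f"bad strand {strand!r}"))
                continue
            if ctx not in VALID_CONTEXTS:
                bad.append((lineno, f"unknown context token {ctx!r}"))
                continue
            chroms.append(chrom)
            poss.append(pos)
            strands.append(strand)
            meths.append(n_meth)
            unmeths.append(n_unmeth)
            ctxs.append(ctx)
            tris.append(tri)

    if bad:
        detail = "; ".join(f"line {n}: {msg}" for n, msg in bad[:5])
        more = f" (+{len(bad) - 5} more)" if len(bad) > 5 else ""
        raise CxFormatError(f"{path}: {len(bad)} malformed rows: {detail}{more}")

    data = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": np.array(poss, dtype=np.int64),
            "strand": strands,
            "n_meth": np.array(meths, dtype=np.int64),
            "n_unmeth": np.array(unmeths, dtype=np.int64),
            "context": ctxs,
            "trinucleotide": tris,
        },
        columns=CX_COLUMNS,
    )
    if data.empty:
        logger.warning("%s: empty cytosine report", path)
    dup = data.duplicated(["chrom", "pos", "strand"])
    if dup.any():
        first = data.loc[dup.idxmax(), ["chrom", "pos", "strand"]].tolist()
        raise CxFormatError(
            f"{path}: {int(dup.sum())} duplicate (chrom, pos, strand) rows, "
            f"first at {tuple(first)}"
        )
    return MethylomeSample(
        sample_id=sample_id or os.path.splitext(os.path.basename(path))[0],
        tissue=tissue,
        genotype=genotype,
        data=data,
    )


def write_cx_report(sample: MethylomeSample | pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a sample to the 7-column cytosine-report dialect."""
    data = sample.data if isinstance(sample, MethylomeSample) else sample
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("#" + "\t".join(CX_COLUMNS) + "\n")
        data.to_csv(handle, sep="\t", header=False, index=False)


def read_gff3_genes(path: str | os.PathLike) -> pd.DataFrame:
    """Load gene and transposable_element features from a GFF3 file.

    Returns a frame with columns gene_id, chrom, strand, start, end,
    feature_class (1-based inclusive coordinates).  Other feature types
    are ignored; features with start > end are rejected with a logged
    message and counted, never silently dropped.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    rejected = 0
    for ftype in ("gene", "transposable_element"):
        for feat in db.features_of_type(ftype):
            if feat.start > feat.end:
                rejected += 1
                logger.warning(
                    "%s: rejecting %s %s: start %d > end %d",
                    path, ftype, feat.id, feat.start, feat.end,
                )
                continue
            rows.append(
                (feat.id, feat.seqid, feat.strand, feat.start, feat.end, ftype)
            )
    if rejected:
        logger.warning("%s: rejected %d malformed features", path, rejected)
    if not rows:
        logger.warning("%s: no gene or transposable_element features", path)
        return pd.DataFrame(columns=GENE_COLUMNS)
    frame = pd.DataFrame(rows, columns=GENE_COLUMNS)
    return frame.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def write_gff3_genes(genes: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write gene models as minimal GFF3."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            handle.write(
                f"{row.chrom}\tmethylite\t{row.feature_class}\t{row.start}\t"
                f"{row.end}\t.\t{row.strand}\t.\tID={row.gene_id}\n"
            )


def bed_score(p_adj: float) -> int:
    """BED score: min(1000, round(-10 log10 p_adj)), 0 for p_adj = 1."""
    if p_adj <= 0:
        return 1000
    return min(1000, int(round(-10.0 * math.log10(p_adj))))


def write_dmr_bed(dmrs: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write DMRs as BED6 (0-based half-open).

    The name field is ``context:direction`` and the score encodes the best
    adjusted p-value as a capped Phred-like quality.
    """
    with open(path, "w", encoding="utf-8") as handle:
        for row in dmrs.itertuples(index=False):
            handle.write(
                f"{row.chrom}\t{row.start - 1}\t{row.end}\t"
                f"{row.context}:{row.direction}\t{bed_score(row.best_p_adj)}\t.\n"
            )


def write_table(frame: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a TSV table with a single ``#``-prefixed header line."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("#" + "\t".join(map(str, frame.columns)) + "\n")
        frame.to_csv(handle, sep="\t", header=False, index=False, float_format="%.10g")


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a TSV table written by :func:`write_table`."""
    with open(path, "r", encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n")
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing '#'-prefixed header line")
        names = header[1:].split("\t")
        return pd.read_csv(handle, sep="\t", header=None, names=names)


def write_window_table(tests: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write the per-window test table (raw/adjusted p, levels, fold change,
    coverage fraction, pass flag) as headered TSV."""
    write_table(tests, path)


def write_marker_table(markers: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a BSA marker table (per-pool mutant/wild-type allele counts)."""
    write_table(markers[MARKER_COLUMNS], path)


def read_marker_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a BSA marker table; validates column names and count signs."""
    frame = read_table(path)
    missing = [c for c in MARKER_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing marker columns {missing}")
    counts = frame[MARKER_COLUMNS[2:]]
    if (counts.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative allele counts")
    return frame[MARKER_COLUMNS]
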