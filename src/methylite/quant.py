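"""Site-level methylation, genome/feature summaries, density profiles, QC.

The site-level methylation of a cytosine is the fraction of reads covering
it that are methylated, and is only defined at sites with at least
fourfold coverage.  Context summaries are *weighted* levels: pooled
methylated reads over pooled total reads across qualifying sites, reported
as percentages per CG/CHG/CHH context and in total.  Chromosome-scale
profiles sum site-level methylation in fixed genomic bins (100 kb by
default) and normalise each context so its densest bin reads 100%.

The bisulfite conversion rate is estimated from an organellar chromosome
(the chloroplast genome is unmethylated in vivo): 100 * (1 - pooled
methylated fraction) over all covered organellar cytosines, with no
coverage floor — the fourfold rule applies to methylation levels only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from methylite.io import MethylomeSample

MIN_COVERAGE = 4  # reads; sites below this have undefined methylation level


def _as_frame(sample: MethylomeSample | pd.DataFrame) -> pd.DataFrame:
    return sample.data if isinstance(sample, MethylomeSample) else sample


def _check_counts(data: pd.DataFrame) -> None:
    if (data["n_meth"].to_numpy() < 0).any() or (data["n_unmeth"].to_numpy() < 0).any():
        raise ValueError("negative read counts")


def site_levels(
    sample: MethylomeSample | pd.DataFrame, min_coverage: int = MIN_COVERAGE
) -> pd.DataFrame:
    """Annotate records with coverage, a qualifying flag, and level.

    ``level`` is n_meth / (n_meth + n_unmeth) where coverage >=
    ``min_coverage`` and NaN (undefined) elsewhere.
    """
    data = _as_frame(sample)
    _check_counts(data)
    out = data.copy()
    coverage = out["n_meth"] + out["n_unmeth"]
    out["coverage"] = coverage
    out["qualifies"] = coverage >= min_coverage
    with np.errstate(invalid="ignore", divide="ignore"):
        level = out["n_meth"] / coverage
    out["level"] = level.where(out["qualifies"])
    return out


def _feature_mask(
    data: pd.DataFrame, features: pd.DataFrame, feature_class: str | None
) -> np.ndarray:
    """True for records inside any feature body (of the given class)."""
    feats = features
    if feature_class is not None:
        feats = feats[feats["feature_class"] == feature_class]
    mask = np.zeros(len(data), dtype=bool)
    for chrom, grp in feats.groupby("chrom"):
        sel = data["chrom"] == chrom
        if not sel.any():
            continue
        # merge feature intervals, then locate each site by searchsorted
        ivals = sorted(zip(grp["start"], grp["end"]))
        starts: list[int] = []
        ends: list[int] = []
        for s, e in ivals:
            if starts and s <= ends[-1] + 1:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        pos = data.loc[sel, "pos"].to_numpy()
        idx = np.searchsorted(np.array(starts), pos, "right") - 1
        inside = (idx >= 0) & (pos <= np.array(ends)[np.clip(idx, 0, None)])
        mask[np.flatnonzero(sel.to_numpy())] = inside
    return mask


def context_summary(
    sample: MethylomeSample | pd.DataFrame,
    features: pd.DataFrame | None = None,
    feature_class: str | None = None,
    min_coverage: int = MIN_COVERAGE,
) -> pd.DataFrame:
    """Weighted methylation percentages per context and in total.

    Optionally restricted to sites inside features (gene or
    transposable_element bodies).  Rows where no site qualifies carry
    ``defined = False`` and a NaN percentage.
    """
    data = _as_frame(sample)
    _check_counts(data)
    if features is not None:
        data = data[_feature_mask(data, features, feature_class)]
    coverage = (data["n_meth"] + data["n_unmeth"]).to_numpy()
    qual = coverage >= min_coverage
    rows = []
    for ctx in ("CG", "CHG", "CHH", "Total"):
        sel = qual if ctx == "Total" else qual & (data["context"] == ctx).to_numpy()
        n_sites = int(sel.sum())
        total = int(coverage[sel].sum())
        if total == 0:
            rows.append((ctx, np.nan, n_sites, False))
        else:
            meth = int(data["n_meth"].to_numpy()[sel].sum())
            rows.append((ctx, 100.0 * meth / total, n_sites, True))
    return pd.DataFrame(
        rows, columns=["context", "percent", "n_sites", "defined"]
    ).set_index("context")


def density_profile(
    sample: MethylomeSample | pd.DataFrame,
    bin_size: int = 100_000,
    chrom_lengths: dict[str, int] | None = None,
    min_coverage: int = MIN_COVERAGE,
) -> pd.DataFrame:
    """Binned methylated-cytosine density per context, self-normalised.

    The raw density of a bin is the summed site-level methylation of its
    qualifying sites (methylated-read mass per site).  Normalised values
    scale each context so its maximum bin is 100%; an all-zero context
    stays at 0 throughout.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    levels = site_levels(sample, min_coverage)
    rows = []
    chroms = (
        list(chrom_lengths)
        if chrom_lengths is not None
        else sorted(levels["chrom"].unique())
    )
    for chrom in chroms:
        sub = levels[levels["chrom"] == chrom]
        if chrom_lengths is not None:
            n_bins = max(1, -(-chrom_lengths[chrom] // bin_size))
        elif len(sub):
            n_bins = -(-int(sub["pos"].max()) // bin_size)
        else:
            continue
        bin_of = (sub["pos"].to_numpy() - 1) // bin_size
        qual = sub["qualifies"].to_numpy()
        lev = np.nan_to_num(sub["level"].to_numpy())
        for ctx in ("CG", "CHG", "CHH"):
            in_ctx = (sub["context"] == ctx).to_numpy() & qual
            raw = np.bincount(
                bin_of[in_ctx], weights=lev[in_ctx], minlength=n_bins
            )[:n_bins]
            for b in range(n_bins):
                rows.append(
                    (chrom, b * bin_size + 1, (b + 1) * bin_size, ctx, raw[b])
                )
    profile = pd.DataFrame(
        rows, columns=["chrom", "bin_start", "bin_end", "context", "raw"]
    )
    profile["normalized"] = 0.0
    for ctx in ("CG", "CHG", "CHH"):
        sel = profile["context"] == ctx
        peak = profile.loc[sel, "raw"].max()
        if sel.any() and peak > 0:
            profile.loc[sel, "normalized"] = 100.0 * profile.loc[sel, "raw"] / peak
    return profile


def conversion_rate(
    sample: MethylomeSample | pd.DataFrame, organellar_chrom: str = "ChrC"
) -> float:
    """Bisulfite conversion rate (%) from an unmethylated organellar genome.

    rate = 100 * (1 - pooled methylated reads / pooled total reads) over
    every covered cytosine of ``organellar_chrom``.

    Raises
    ------
    ValueError
        If the chromosome is absent or has zero covered cytosines.
    """
    data = _as_frame(sample)
    _check_counts(data)
    sub = data[data["chrom"] == organellar_chrom]
    if sub.empty:
        raise ValueError(
            f"organellar chromosome {organellar_chrom!r} absent from sample"
        )
    total = int((sub["n_meth"] + sub["n_unmeth"]).sum())
    if total == 0:
        raise ValueError(
            f"organellar chromosome {organellar_chrom!r} has no covered cytosines"
        )
    return 100.0 * (1.0 - sub["n_meth"].sum() / total)
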