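"""Bulk-segregant allele-frequency-difference mapping of F2 pools.

Two phenotypically selected pools of F2 individuals are genotyped at a
panel of markers polymorphic between the parents.  Per marker, the
mutant-parent allele frequency is computed in each pool and their
difference Delta = f_high - f_normal profiled along the genome.  Near a
recessive causal locus the high (mutant-phenotype) pool is fixed for the
mutant allele while the normal pool holds it at 1/3, so Delta peaks at
2/3; unlinked markers fluctuate around 0.  A centered moving average
smooths the profile and maximal runs of markers above a Delta threshold
are reported as candidate intervals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

AFD_COLUMNS = [
    "chrom",
    "pos",
    "f_high",
    "f_norm",
    "delta",
    "n_high",
    "n_norm",
    "defined",
]


def allele_freq_diff(markers: pd.DataFrame) -> pd.DataFrame:
    """Per-marker mutant-allele frequencies and their pool difference.

    ``markers`` carries per-pool mutant/wild-type allele counts.  Markers
    where either pool has zero counted chromosomes are flagged undefined
    (NaN frequencies).  Negative counts raise ``ValueError``.
    """
    count_cols = [
        "allele_high_mut", "allele_high_wt", "allele_norm_mut", "allele_norm_wt"
    ]
    counts = markers[count_cols].to_numpy()
    if (counts < 0).any():
        raise ValueError("negative allele counts")
    n_high = counts[:, 0] + counts[:, 1]
    n_norm = counts[:, 2] + counts[:, 3]
    with np.errstate(invalid="ignore", divide="ignore"):
        f_high = np.where(n_high > 0, counts[:, 0] / n_high, np.nan)
        f_norm = np.where(n_norm > 0, counts[:, 2] / n_norm, np.nan)
    return pd.DataFrame(
        {
            "chrom": markers["chrom"].to_numpy(),
            "pos": markers["pos"].to_numpy(),
            "f_high": f_high,
            "f_norm": f_norm,
            "delta": f_high - f_norm,
            "n_high": n_high.astype(int),
            "n_norm": n_norm.astype(int),
            "defined": (n_high > 0) & (n_norm > 0),
        },
        columns=AFD_COLUMNS,
    )


def smooth_profile(afd: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Centered moving average of Delta over ``k`` markers per chromosome.

    The window shrinks at chromosome ends; ``k = 1`` is the identity.
    ``k`` must be odd.
    """
    if k < 1 or k % 2 == 0:
        raise ValueError("k must be an odd integer >= 1")
    out = afd.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    out["delta_smooth"] = (
        out.groupby("chrom", sort=False)["delta"]
        .transform(lambda s: s.rolling(k, center=True, min_periods=1).mean())
    )
    return out


def candidate_intervals(
    smoothed: pd.DataFrame, threshold: float = 0.4
) -> pd.DataFrame:
    """Maximal runs of consecutive markers with smoothed Delta >= threshold.

    Interval bounds are the outermost member marker positions; the peak is
    the member with the largest smoothed Delta.  Undefined markers break
    runs.  An empty result is returned when no marker reaches the
    threshold.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    rows = []
    for chrom, grp in smoothed.groupby("chrom", sort=False):
        grp = grp.sort_values("pos", kind="mergesort")
        vals = grp["delta_smooth"].to_numpy()
        pos = grp["pos"].to_numpy()
        above = np.where(np.isnan(vals), False, vals >= threshold)
        i = 0
        while i < len(above):
            if not above[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(above) and above[j + 1]:
                j += 1
            seg = slice(i, j + 1)
            peak = i + int(np.argmax(vals[seg]))
            rows.append(
                {
                    "chrom": chrom,
                    "start": pos[i],
                    "end": pos[j],
                    "peak_pos": pos[peak],
                    "peak_delta": vals[peak],
                    "n_markers": j - i + 1,
                }
            )
            i = j + 1
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "peak_pos", "peak_delta", "n_markers"],
    )
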