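"""Sliding-window differential-methylation test and DMR construction.

The caller compares two bisulfite samples per sequence context (CG, CHG,
CHH treated separately).  Windows of five consecutive context cytosines
slide along each chromosome at one-cytosine steps over the *union*
reference inventory of the two samples, so window coordinates are
sample-independent.  A member site qualifies when it has at least fourfold
coverage in both samples; read counts are pooled over qualifying members
into a 2x2 table (methylated/unmethylated x sample) and tested with a
two-sided Fisher's exact test.  P-values are Benjamini-Hochberg adjusted
within one (comparison x context) family over all windows whose
covered-site fraction exceeds the coverage cut-off.  A window passes when
adjusted p <= 0.05, the fold change of pooled methylation levels exceeds
2, and more than 0.6 of its sites qualify (i.e. at least 4 of 5).
Overlapping passing windows of the same direction are merged transitively
into DMRs; merged regions spanning less than 200 bp are discarded.

Fold change uses the pooled window levels with no pseudocounts: if one
level is 0 and the other positive the fold change is +inf (which satisfies
the > 2 criterion); a window with both levels 0, or with zero pooled
coverage in either sample, fails.  Direction is defined relative to sample
A: "hyper" when sample B is more methylated.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from methylite.io import MethylomeSample
from methylite.quant import _as_frame

logger = logging.getLogger(__name__)

WINDOW_SITES = 5

WINDOW_COLUMNS = [
    "chrom",
    "start",
    "end",
    "context",
    "first_site",
    "n_qual",
    "covered_fraction",
    "m_a",
    "u_a",
    "m_b",
    "u_b",
]

DMR_COLUMNS = [
    "chrom",
    "start",
    "end",
    "context",
    "direction",
    "length",
    "n_windows",
    "level_a",
    "level_b",
    "best_p_adj",
]

# Relative tolerance when comparing hypergeometric probabilities for the
# two-sided rule, as in R's fisher.test.
_REL_TOL = 1e-7


def _log_comb(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_p_batch(
    m_a: np.ndarray, u_a: np.ndarray, m_b: np.ndarray, u_b: np.ndarray,
    chunk: int = 16384,
) -> np.ndarray:
    """Two-sided Fisher's exact p for many 2x2 tables, vectorised.

    For each table the full hypergeometric support is enumerated and the
    probabilities of tables no more likely than the observed one (within a
    relative tolerance of 1e-7) are summed.  Degenerate margins give p = 1.
    """
    m_a = np.asarray(m_a, dtype=np.int64)
    u_a = np.asarray(u_a, dtype=np.int64)
    m_b = np.asarray(m_b, dtype=np.int64)
    u_b = np.asarray(u_b, dtype=np.int64)
    if min(m_a.min(initial=0), u_a.min(initial=0), m_b.min(initial=0), u_b.min(initial=0)) < 0:
        raise ValueError("negative counts in 2x2 table")
    out = np.ones(m_a.shape, dtype=float)
    for lo_idx in range(0, m_a.size, chunk):
        sl = slice(lo_idx, lo_idx + chunk)
        out[sl] = _fisher_chunk(m_a[sl], u_a[sl], m_b[sl], u_b[sl])
    return out


def _fisher_chunk(m_a, u_a, m_b, u_b) -> np.ndarray:
    n_a = m_a + u_a
    n_b = m_b + u_b
    k_meth = m_a + m_b
    n_tot = n_a + n_b
    lo = np.maximum(0, k_meth - n_b)
    hi = np.minimum(k_meth, n_a)
    width = int((hi - lo).max(initial=0)) + 1

    grid = lo[:, None] + np.arange(width)[None, :]
    valid = grid <= hi[:, None]
    k = np.where(valid, grid, 0)

    log_pmf = (
        _log_comb(n_a[:, None], k)
        + _log_comb(n_b[:, None], k_meth[:, None] - k)
        - _log_comb(n_tot, k_meth)[:, None]
    )
    log_obs = (
        _log_comb(n_a, m_a) + _log_comb(n_b, m_b) - _log_comb(n_tot, k_meth)
    )
    include = valid & (log_pmf <= log_obs[:, None] + np.log1p(_REL_TOL))
    p = np.where(include, np.exp(log_pmf), 0.0).sum(axis=1)
    return np.minimum(p, 1.0)


def fisher_p(m_a: int, u_a: int, m_b: int, u_b: int) -> float:
    """Two-sided Fisher's exact p-value for one 2x2 table.

    Rows are samples, columns are methylated/unmethylated counts.  A table
    with a zero row or column margin has p = 1 by convention.
    """
    return float(
        fisher_p_batch(
            np.array([m_a]), np.array([u_a]), np.array([m_b]), np.array([u_b])
        )[0]
    )


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order kept)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def build_windows(
    sample_a: MethylomeSample | pd.DataFrame,
    sample_b: MethylomeSample | pd.DataFrame,
    context: str,
    min_coverage: int = 4,
    window_sites: int = WINDOW_SITES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Slide windows of ``window_sites`` context cytosines over both samples.

    Returns ``(windows, sites)``: the per-window table and the aligned
    union site table it indexes into (``first_site`` points at the first
    member row; members are ``window_sites`` consecutive rows).  A
    chromosome with fewer than ``window_sites`` context cytosines yields
    no windows.
    """
    a = _as_frame(sample_a)
    b = _as_frame(sample_b)
    a = a[a["context"] == context]
    b = b[b["context"] == context]
    merged = pd.merge(
        a[["chrom", "pos", "strand", "n_meth", "n_unmeth"]],
        b[["chrom", "pos", "strand", "n_meth", "n_unmeth"]],
        on=["chrom", "pos", "strand"],
        how="outer",
        suffixes=("_a", "_b"),
    ).fillna(0)
    merged = merged.sort_values(["chrom", "pos", "strand"], kind="mergesort")
    merged = merged.reset_index(drop=True)
    for col in ("n_meth_a", "n_unmeth_a", "n_meth_b", "n_unmeth_b"):
        merged[col] = merged[col].astype(np.int64)
    cov_a = merged["n_meth_a"] + merged["n_unmeth_a"]
    cov_b = merged["n_meth_b"] + merged["n_unmeth_b"]
    merged["qual"] = ((cov_a >= min_coverage) & (cov_b >= min_coverage)).to_numpy()

    win_rows = []
    for chrom, grp in merged.groupby("chrom", sort=False):
        n = len(grp)
        if n < window_sites:
            continue
        pos = grp["pos"].to_numpy()
        qual = grp["qual"].to_numpy()
        qmask = qual.astype(np.int64)

        def wsum(x: np.ndarray) -> np.ndarray:
            c = np.concatenate([[0], np.cumsum(x)])
            return c[window_sites:] - c[:-window_sites]

        n_qual = wsum(qmask)
        m_a = wsum(grp["n_meth_a"].to_numpy() * qmask)
        u_a = wsum(grp["n_unmeth_a"].to_numpy() * qmask)
        m_b = wsum(grp["n_meth_b"].to_numpy() * qmask)
        u_b = wsum(grp["n_unmeth_b"].to_numpy() * qmask)
        first = grp.index.to_numpy()[: n - window_sites + 1]
        win_rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": pos[: n - window_sites + 1],
                    "end": pos[window_sites - 1 :],
                    "context": context,
                    "first_site": first,
                    "n_qual": n_qual,
                    "covered_fraction": n_qual / window_sites,
                    "m_a": m_a,
                    "u_a": u_a,
                    "m_b": m_b,
                    "u_b": u_b,
                }
            )
        )
    windows = (
        pd.concat(win_rows, ignore_index=True)
        if win_rows
        else pd.DataFrame(columns=WINDOW_COLUMNS)
    )
    return windows, merged


def evaluate_windows(
    windows: pd.DataFrame,
    max_fdr: float = 0.05,
    min_fold: float = 2.0,
    min_fraction: float = 0.6,
) -> pd.DataFrame:
    """Test windows and apply the three DMR criteria.

    Adds pooled levels, fold change, raw and BH-adjusted p (the family is
    the set of windows with covered fraction strictly above
    ``min_fraction``), direction, and the pass flag.
    """
    out = windows.copy()
    n = len(out)
    if n == 0:
        for col in ("level_a", "level_b", "fold_change", "p", "p_adj"):
            out[col] = pd.Series(dtype=float)
        out["direction"] = pd.Series(dtype=object)
        out["passed"] = pd.Series(dtype=bool)
        return out

    tot_a = (out["m_a"] + out["u_a"]).to_numpy(dtype=float)
    tot_b = (out["m_b"] + out["u_b"]).to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        level_a = np.where(tot_a > 0, out["m_a"] / tot_a, np.nan)
        level_b = np.where(tot_b > 0, out["m_b"] / tot_b, np.nan)
        lo = np.minimum(level_a, level_b)
        hi = np.maximum(level_a, level_b)
        fold = np.where(
            np.isnan(lo),
            np.nan,
            np.where(hi == 0, np.nan, np.where(lo == 0, np.inf, hi / lo)),
        )
    out["level_a"] = level_a
    out["level_b"] = level_b
    out["fold_change"] = fold

    eligible = (out["covered_fraction"] > min_fraction).to_numpy()
    p = np.full(n, np.nan)
    if eligible.any():
        sub = out[eligible]
        p[eligible] = fisher_p_batch(
            sub["m_a"].to_numpy(),
            sub["u_a"].to_numpy(),
            sub["m_b"].to_numpy(),
            sub["u_b"].to_numpy(),
        )
    p_adj = np.full(n, np.nan)
    if eligible.any():
        p_adj[eligible] = bh_adjust(p[eligible])
    out["p"] = p
    out["p_adj"] = p_adj

    direction = np.where(
        np.isnan(level_a) | np.isnan(level_b) | (level_a == level_b),
        None,
        np.where(level_b > level_a, "hyper", "hypo"),
    )
    out["direction"] = direction
    out["passed"] = (
        eligible
        & np.where(np.isnan(p_adj), False, p_adj <= max_fdr)
        & np.where(np.isnan(fold), False, fold > min_fold)
        & (tot_a > 0)
        & (tot_b > 0)
        & pd.notna(out["direction"]).to_numpy()
    )
    return out


def _merge_direction(
    tests: pd.DataFrame, sites: pd.DataFrame, direction: str, window_sites: int
) -> list[dict]:
    sub = tests[(tests["passed"]) & (tests["direction"] == direction)]
    sub = sub.sort_values(["chrom", "start"], kind="mergesort")
    qual = sites["qual"].to_numpy()
    qm_a = sites["n_meth_a"].to_numpy() * qual
    qu_a = sites["n_unmeth_a"].to_numpy() * qual
    qm_b = sites["n_meth_b"].to_numpy() * qual
    qu_b = sites["n_unmeth_b"].to_numpy() * qual

    regions: list[dict] = []
    current: dict | None = None
    for row in sub.itertuples(index=False):
        if (
            current is not None
            and row.chrom == current["chrom"]
            and row.start <= current["end"]
        ):
            current["end"] = max(current["end"], row.end)
            current["last_site"] = max(
                current["last_site"], row.first_site + window_sites - 1
            )
            current["n_windows"] += 1
            current["best_p_adj"] = min(current["best_p_adj"], row.p_adj)
        else:
            if current is not None:
                regions.append(current)
            current = {
                "chrom": row.chrom,
                "start": int(row.start),
                "end": int(row.end),
                "context": row.context,
                "direction": direction,
                "first_site": int(row.first_site),
                "last_site": int(row.first_site + window_sites - 1),
                "n_windows": 1,
                "best_p_adj": float(row.p_adj),
            }
    if current is not None:
        regions.append(current)

    for region in regions:
        sl = slice(region["first_site"], region["last_site"] + 1)
        ma, ua = int(qm_a[sl].sum()), int(qu_a[sl].sum())
        mb, ub = int(qm_b[sl].sum()), int(qu_b[sl].sum())
        region["level_a"] = ma / (ma + ua) if ma + ua else np.nan
        region["level_b"] = mb / (mb + ub) if mb + ub else np.nan
        region["length"] = region["end"] - region["start"] + 1
    return regions


def merge_to_dmrs(
    tests: pd.DataFrame,
    sites: pd.DataFrame,
    min_length: int = 200,
    window_sites: int = WINDOW_SITES,
) -> pd.DataFrame:
    """Merge overlapping same-direction passing windows into DMRs.

    Merged spans shorter than ``min_length`` bp are dropped (counts are
    logged).  In the rare event that opposite-direction candidates
    overlap, the one with the smaller best adjusted p survives (ties:
    larger span, then hyper), preserving non-overlap of emitted DMRs
    within a context.
    """
    regions = _merge_direction(tests, sites, "hyper", window_sites)
    regions += _merge_direction(tests, sites, "hypo", window_sites)
    kept = [r for r in regions if r["length"] >= min_length]
    logger.info(
        "merged %d passing windows into %d candidate regions; kept %d "
        "(dropped %d shorter than %d bp)",
        int(tests["passed"].sum()) if len(tests) else 0,
        len(regions),
        len(kept),
        len(regions) - len(kept),
        min_length,
    )

    kept.sort(key=lambda r: (r["chrom"], r["start"]))
    resolved: list[dict] = []
    for region in kept:
        if (
            resolved
            and region["chrom"] == resolved[-1]["chrom"]
            and region["start"] <= resolved[-1]["end"]
        ):
            prev = resolved[-1]
            keys = (
                lambda r: (r["best_p_adj"], -r["length"], r["direction"] != "hyper")
            )
            winner = min(prev, region, key=keys)
            logger.warning(
                "overlapping opposite-direction candidates at %s:%d-%d; "
                "keeping %s", region["chrom"], region["start"], region["end"],
                winner["direction"],
            )
            resolved[-1] = winner
        else:
            resolved.append(region)

    frame = pd.DataFrame(resolved, columns=DMR_COLUMNS + ["first_site", "last_site"])
    return frame[DMR_COLUMNS].reset_index(drop=True)


@dataclasses.dataclass
class DmrResult:
    """DMRs and the full per-window test tables of one comparison."""

    dmrs: pd.DataFrame
    windows: dict[str, pd.DataFrame]
    params: dict


def call_dmrs(
    sample_a: MethylomeSample | pd.DataFrame,
    sample_b: MethylomeSample | pd.DataFrame,
    contexts: Sequence[str] = ("CG", "CHG", "CHH"),
    min_coverage: int = 4,
    window_sites: int = WINDOW_SITES,
    max_fdr: float = 0.05,
    min_fold: float = 2.0,
    min_fraction: float = 0.6,
    min_length: int = 200,
) -> DmrResult:
    """Run the full build -> test -> adjust -> merge pipeline per context.

    Contexts are processed independently; BH adjustment is applied within
    one (comparison x context) family.  Direction is reported for sample B
    relative to sample A (hyper = B more methylated).
    """
    params = dict(
        contexts=list(contexts), min_coverage=min_coverage,
        window_sites=window_sites, max_fdr=max_fdr, min_fold=min_fold,
        min_fraction=min_fraction, min_length=min_length,
    )
    all_dmrs = []
    window_tables: dict[str, pd.DataFrame] = {}
    for context in contexts:
        windows, sites = build_windows(
            sample_a, sample_b, context, min_coverage, window_sites
        )
        tests = evaluate_windows(windows, max_fdr, min_fold, min_fraction)
        window_tables[context] = tests
        all_dmrs.append(merge_to_dmrs(tests, sites, min_length, window_sites))
    nonempty = [d for d in all_dmrs if len(d)]
    dmrs = (
        pd.concat(nonempty, ignore_index=True)
        if nonempty
        else pd.DataFrame(columns=DMR_COLUMNS)
    )
    return DmrResult(dmrs=dmrs, windows=window_tables, params=params)
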