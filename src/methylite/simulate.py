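"""Synthetic bisulfite-sequencing and F2-pool data with known ground truth.

The generator produces every input the analysis stages consume: random
reference chromosomes with a full strand-aware cytosine inventory, truth
methylomes with planted differentially methylated regions (DMRs), binomial
bisulfite read counts with Poisson depth and conversion failure, an
unmethylated organellar (chloroplast) chromosome for conversion-rate QC,
non-overlapping gene models, and allele counts for phenotypically selected
F2 pools segregating a recessive causal locus.

Model summary
-------------
* Read depth at each cytosine is Poisson(``depth``), independent across
  sites and samples.
* A read at a cytosine with true methylation probability ``m`` is called
  methylated with probability ``m + (1 - m) * f`` where ``f`` is the
  bisulfite conversion-failure rate; over-conversion of methylated
  cytosines is not modelled.
* The two strands are simulated independently; no CG symmetry is imposed.
* Baseline methylation per context defaults to an Arabidopsis wild-type
  shoot-like profile: CG 28%, CHG 10%, CHH 3%.
* F2 gametes recombine along the genetic map under the Haldane (no
  interference) model.  The "high" pool contains individuals homozygous for
  the mutant allele at the causal locus; the "normal" pool is drawn from
  the phenotypically normal classes (homozygous wild type : heterozygous
  = 1 : 2), so the expected mutant-allele frequency difference at the
  causal locus is 1 - 1/3 = 2/3.

All coordinates are 1-based inclusive.  Identical seeds give byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from methylite.io import CX_COLUMNS, MethylomeSample

logger = logging.getLogger(__name__)

CONTEXTS = ("CG", "CHG", "CHH")

#: Default per-context baseline methylation rates (fractions of reads).
DEFAULT_BASELINES: Mapping[str, float] = {"CG": 0.28, "CHG": 0.10, "CHH": 0.03}

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Global parameters of a bisulfite simulation.

    Parameters
    ----------
    seed:
        Master seed; fixing it makes all derived outputs byte-identical.
    depth:
        Mean sequencing depth per cytosine (reads/site, Poisson).
    conversion_failure:
        Probability ``f`` in [0, 1) that an unmethylated cytosine escapes
        bisulfite conversion and is read as methylated.
    chrom_lengths:
        Mapping of nuclear chromosome name to length in bp (each >= 10).
    gc_content:
        Fraction of G+C in the generated reference sequence.
    """

    seed: int = 0
    depth: float = 30.0
    conversion_failure: float = 0.005
    chrom_lengths: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: {"Chr1": 200_000}
    )
    gc_content: float = 0.36

    def __post_init__(self) -> None:
        if not 0.0 <= self.conversion_failure < 1.0:
            raise ValueError(
                f"conversion_failure must be in [0, 1), got {self.conversion_failure}"
            )
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")
        for chrom, length in self.chrom_lengths.items():
            if length < 10:
                raise ValueError(f"chromosome {chrom} shorter than 10 bp")


@dataclasses.dataclass(frozen=True)
class PlantedDMR:
    """Ground-truth record of one planted differentially methylated region."""

    chrom: str
    start: int  # 1-based inclusive
    end: int
    context: str
    m_a: float
    m_b: float
    n_sites: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("end < start")
        if self.m_a == self.m_b:
            raise ValueError("m_a and m_b must differ")


@dataclasses.dataclass
class TruthMethylome:
    """True per-cytosine methylation probabilities for one sample.

    ``m`` is aligned row-by-row with ``inventory``.
    """

    inventory: pd.DataFrame
    m: np.ndarray
    baselines: Mapping[str, float]
    planted: list[PlantedDMR] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float)
        if len(self.m) != len(self.inventory):
            raise ValueError("m must align with the inventory")
        if np.any((self.m < 0) | (self.m > 1)):
            raise ValueError("true methylation probabilities must lie in [0, 1]")


@dataclasses.dataclass(frozen=True)
class Reference:
    """Generated reference sequences plus their cytosine inventory."""

    sequences: Mapping[str, str]
    inventory: pd.DataFrame

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}


def _revcomp(s: bytes) -> bytes:
    return s.translate(_COMPLEMENT)[::-1]


def cytosine_inventory(sequence: str, chrom: str) -> pd.DataFrame:
    """Classify every cytosine of both strands of ``sequence``.

    Every C on the plus strand and every G on the minus strand (a C when
    read 5'->3' on that strand) is reported once with its CG/CHG/CHH
    context and trinucleotide.  Within two bases of a chromosome end the
    missing downstream bases are treated as H and the trinucleotide is
    padded with ``N``.

    Raises
    ------
    ValueError
        If the sequence contains characters outside A/C/G/T.
    """
    raw = sequence.upper().encode()
    arr = np.frombuffer(raw, dtype="S1")
    if arr.size and not np.isin(arr, np.array([b"A", b"C", b"G", b"T"])).all():
        bad = sorted(set(raw) - set(b"ACGT"))
        raise ValueError(f"non-ACGT characters in {chrom}: {[chr(b) for b in bad]}")

    padded = np.concatenate([np.full(2, b"N"), arr, np.full(2, b"N")])

    plus_idx = np.flatnonzero(arr == b"C")
    nxt1 = padded[plus_idx + 3]
    nxt2 = padded[plus_idx + 4]
    plus_ctx = np.where(nxt1 == b"G", "CG", np.where(nxt2 == b"G", "CHG", "CHH"))
    plus_tri = [
        raw[i : i + 3].decode().ljust(3, "N") for i in plus_idx
    ]

    minus_idx = np.flatnonzero(arr == b"G")
    prv1 = padded[minus_idx + 1]
    prv2 = padded[minus_idx]
    minus_ctx = np.where(prv1 == b"C", "CG", np.where(prv2 == b"C", "CHG", "CHH"))
    minus_tri = [
        _revcomp(raw[max(i - 2, 0) : i + 1]).decode().ljust(3, "N")
        for i in minus_idx
    ]

    frame = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.concatenate([plus_idx, minus_idx]) + 1,
            "strand": ["+"] * len(plus_idx) + ["-"] * len(minus_idx),
            "context": np.concatenate([plus_ctx, minus_ctx]),
            "trinucleotide": plus_tri + minus_tri,
        }
    )
    return frame.sort_values(["pos", "strand"], kind="mergesort").reset_index(drop=True)


def generate_reference(config: SimConfig) -> Reference:
    """Generate random chromosomes and their full cytosine inventory."""
    rng = np.random.default_rng(config.seed)
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    sequences: dict[str, str] = {}
    frames = []
    for chrom, length in config.chrom_lengths.items():
        seq = "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=probs)])
        sequences[chrom] = seq
        frames.append(cytosine_inventory(seq, chrom))
    inventory = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "pos", "strand", "context", "trinucleotide"]
    )
    return Reference(sequences=sequences, inventory=inventory)


def plant_dmrs(
    reference: Reference,
    n_dmrs: int,
    context: str = "CG",
    m_a: float = 0.1,
    m_b: float = 0.8,
    min_sites: int = 10,
    region_len: int = 1000,
    seed: int = 0,
    baselines: Mapping[str, float] | None = None,
) -> tuple[TruthMethylome, TruthMethylome]:
    """Create a pair of truth methylomes differing only inside planted DMRs.

    Outside the planted regions both samples carry the per-context baseline
    rate; inside, context cytosines take ``m_a`` in sample A and ``m_b`` in
    sample B.  Regions are disjoint, each ``region_len`` bp long, and each
    contains at least ``min_sites`` cytosines of ``context``.

    Raises
    ------
    RuntimeError
        If ``n_dmrs`` disjoint regions satisfying the site-count constraint
        cannot be placed.
    """
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    if n_dmrs and m_a == m_b:
        raise ValueError("m_a and m_b must differ for planted DMRs")
    baselines = dict(DEFAULT_BASELINES if baselines is None else baselines)

    inv = reference.inventory
    m_base = inv["context"].map(baselines).to_numpy(dtype=float)
    m_a_arr = m_base.copy()
    m_b_arr = m_base.copy()

    rng = np.random.default_rng(seed)
    lengths = reference.chrom_lengths
    chroms = [c for c, L in lengths.items() if L >= region_len]
    if n_dmrs > 0 and not chroms:
        raise RuntimeError(
            f"cannot place DMRs: no chromosome is at least {region_len} bp long"
        )
    weights = np.array([lengths[c] for c in chroms], dtype=float)
    weights = weights / weights.sum() if len(chroms) else weights

    # per-chromosome sorted positions of the target context (both strands)
    ctx_pos = {
        c: grp["pos"].to_numpy()
        for c, grp in inv[inv["context"] == context].groupby("chrom")
    }

    planted: list[PlantedDMR] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in lengths}
    max_attempts = max(2000, 500 * n_dmrs)
    attempts = 0
    while len(planted) < n_dmrs:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {n_dmrs} disjoint {region_len} bp regions with "
                f">= {min_sites} {context} sites after {max_attempts} attempts"
            )
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        start = int(rng.integers(1, lengths[chrom] - region_len + 2))
        end = start + region_len - 1
        if any(start <= e and s <= end for s, e in occupied[chrom]):
            continue
        pos = ctx_pos.get(chrom, np.empty(0, dtype=int))
        n_in = int(np.searchsorted(pos, end, "right") - np.searchsorted(pos, start))
        if n_in < min_sites:
            continue
        occupied[chrom].append((start, end))
        planted.append(
            PlantedDMR(chrom, start, end, context, m_a, m_b, n_in)
        )
        mask = (
            (inv["chrom"] == chrom)
            & (inv["context"] == context)
            & inv["pos"].between(start, end)
        ).to_numpy()
        m_a_arr[mask] = m_a
        m_b_arr[mask] = m_b

    planted.sort(key=lambda d: (d.chrom, d.start))
    truth_a = TruthMethylome(inv, m_a_arr, baselines, planted)
    truth_b = TruthMethylome(inv, m_b_arr, baselines, planted)
    return truth_a, truth_b


def simulate_counts(
    truth: TruthMethylome,
    config: SimConfig,
    seed: int | None = None,
    sample_id: str = "sample",
    tissue: str | None = None,
    genotype: str | None = None,
) -> MethylomeSample:
    """Draw a cytosine count table from a truth methylome.

    Per site the total read count is Poisson(``depth``) and the methylated
    count is Binomial(n, m + (1 - m) * f) with ``f`` the conversion-failure
    rate.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = rng.poisson(config.depth, size=len(truth.m))
    f = config.conversion_failure
    p_meth = truth.m + (1.0 - truth.m) * f
    n_meth = rng.binomial(n, p_meth)
    data = pd.DataFrame(
        {
            "chrom": truth.inventory["chrom"].to_numpy(),
            "pos": truth.inventory["pos"].to_numpy(),
            "strand": truth.inventory["strand"].to_numpy(),
            "n_meth": n_meth,
            "n_unmeth": n - n_meth,
            "context": truth.inventory["context"].to_numpy(),
            "trinucleotide": truth.inventory["trinucleotide"].to_numpy(),
        },
        columns=CX_COLUMNS,
    )
    return MethylomeSample(
        sample_id=sample_id, tissue=tissue, genotype=genotype, data=data
    )


def simulate_chloroplast(
    length: int,
    config: SimConfig,
    seed: int | None = None,
    chrom: str = "ChrC",
    sample_id: str = "chloroplast",
) -> MethylomeSample:
    """Simulate a fully unmethylated organellar chromosome.

    All sites have true methylation 0, so any methylated call is a
    conversion failure; the downstream conversion-rate estimate converges
    to ``100 * (1 - f)`` percent.
    """
    if length == 0:
        data = pd.DataFrame(columns=CX_COLUMNS)
        return MethylomeSample(sample_id=sample_id, data=data)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=probs)])
    inv = cytosine_inventory(seq, chrom)
    truth = TruthMethylome(inv, np.zeros(len(inv)), {c: 0.0 for c in CONTEXTS})
    return simulate_counts(
        truth, config, seed=int(rng.integers(2**31)), sample_id=sample_id
    )


def simulate_genes(
    reference: Reference,
    n_genes: int = 20,
    te_fraction: float = 0.2,
    mean_length: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Place non-overlapping gene and transposable-element models.

    Returns a frame with columns gene_id, chrom, strand, start, end,
    feature_class suitable for GFF3 export.
    """
    rng = np.random.default_rng(seed)
    lengths = reference.chrom_lengths
    chroms = list(lengths)
    weights = np.array([lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    rows = []
    attempts = 0
    n_te = int(round(n_genes * te_fraction))
    classes = ["transposable_element"] * n_te + ["gene"] * (n_genes - n_te)
    for cls in classes:
        placed = False
        while not placed:
            attempts += 1
            if attempts > 200 * n_genes + 2000:
                raise RuntimeError(
                    f"could not place {n_genes} non-overlapping gene models"
                )
            glen = max(200, int(rng.exponential(mean_length)))
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            if lengths[chrom] <= glen + 2:
                continue
            start = int(rng.integers(1, lengths[chrom] - glen + 1))
            end = start + glen - 1
            if any(start <= e and s <= end for s, e in occupied[chrom]):
                continue
            occupied[chrom].append((start, end))
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((chrom, strand, start, end, cls))
            placed = True
    frame = pd.DataFrame(
        rows, columns=["chrom", "strand", "start", "end", "feature_class"]
    ).sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    n_g = n_t = 0
    ids = []
    for cls in frame["feature_class"]:
        if cls == "gene":
            n_g += 1
            ids.append(f"gene{n_g:04d}")
        else:
            n_t += 1
            ids.append(f"te{n_t:04d}")
    frame.insert(0, "gene_id", ids)
    return frame


@dataclasses.dataclass(frozen=True)
class PoolSimConfig:
    """Parameters of a bulk-segregant F2 pool simulation.

    The genetic map is a single chromosome of ``map_length`` centimorgans
    carrying ``n_markers`` evenly spaced markers (or explicit
    ``marker_positions``).  ``causal_cm`` locates the recessive causal
    locus.  Pool sizes are numbers of F2 individuals (two chromosomes
    each).
    """

    map_length: float = 100.0
    n_markers: int = 100
    causal_cm: float = 40.0
    n_high: int = 40
    n_normal: int = 40
    seed: int = 0
    chrom: str = "Chr1"
    marker_positions: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if self.n_high <= 0 or self.n_normal <= 0:
            raise ValueError("pool sizes must be positive")
        if not 0.0 <= self.causal_cm <= self.map_length:
            raise ValueError("causal locus must lie on the genetic map")

    @property
    def positions(self) -> np.ndarray:
        if self.marker_positions is not None:
            return np.asarray(self.marker_positions, dtype=float)
        return np.linspace(0.0, self.map_length, self.n_markers)


def _draw_gametes(rng: np.random.Generator, positions: np.ndarray, n: int) -> np.ndarray:
    """Mutant-allele indicators (n x loci) under Haldane recombination."""
    d_morgan = np.diff(positions) / 100.0
    rec = 0.5 * (1.0 - np.exp(-2.0 * d_morgan))
    alleles = np.empty((n, positions.size), dtype=bool)
    alleles[:, 0] = rng.random(n) < 0.5
    if rec.size:
        switches = rng.random((n, rec.size)) < rec
        alleles[:, 1:] = alleles[:, [0]] ^ (np.cumsum(switches, axis=1) % 2).astype(bool)
    return alleles


def simulate_f2_pools(config: PoolSimConfig) -> pd.DataFrame:
    """Simulate per-marker allele counts for selected F2 pools.

    The high pool holds individuals homozygous mutant at the causal locus;
    the normal pool is drawn from the phenotypically normal classes
    (WT/WT : WT/mut = 1 : 2).  Returns one row per marker with columns
    chrom, pos, allele_high_mut, allele_high_wt, allele_norm_mut,
    allele_norm_wt; counts tally ``2 * pool size`` chromosomes.
    """
    rng = np.random.default_rng(config.seed)
    markers = np.sort(config.positions)
    loci = np.union1d(markers, [config.causal_cm])
    causal_idx = int(np.searchsorted(loci, config.causal_cm))
    marker_idx = np.searchsorted(loci, markers)

    def collect(target: int, accept) -> np.ndarray:
        """Chromosomes (2 * target x loci) of accepted F2 individuals."""
        got: list[np.ndarray] = []
        n_got = 0
        while n_got < target:
            batch = max(64, 4 * (target - n_got))
            g1 = _draw_gametes(rng, loci, batch)
            g2 = _draw_gametes(rng, loci, batch)
            geno_causal = g1[:, causal_idx].astype(int) + g2[:, causal_idx].astype(int)
            keep = accept(geno_causal)
            got.append(np.stack([g1[keep], g2[keep]], axis=1))
            n_got += int(keep.sum())
        pool = np.concatenate(got, axis=0)[:target]
        return pool.reshape(2 * target, loci.size)

    high = collect(config.n_high, lambda g: g == 2)
    normal = collect(config.n_normal, lambda g: g <= 1)

    high_mut = high[:, marker_idx].sum(axis=0)
    norm_mut = normal[:, marker_idx].sum(axis=0)
    return pd.DataFrame(
        {
            "chrom": config.chrom,
            "pos": markers,
            "allele_high_mut": high_mut.astype(int),
            "allele_high_wt": (2 * config.n_high - high_mut).astype(int),
            "allele_norm_mut": norm_mut.astype(int),
            "allele_norm_wt": (2 * config.n_normal - norm_mut).astype(int),
        }
    )
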