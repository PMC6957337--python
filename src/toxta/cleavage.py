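"""Global mRNA-cleavage signatures from paired-end insert sizes.

A sequence-nonspecific ribonuclease shortens transcripts genome-wide, so
cleaved libraries have systematically smaller sequencing inserts.  Because
independent library preparations differ in their size selection, insert
sizes are only comparable between libraries *prepared in the same batch* —
the batch-match is enforced as a hard precondition.

The shift test compares two libraries' |TLEN| distributions with a
rank-sum statistic whose null distribution is generated by permuting
library labels over the pooled inserts (one-sided: shorter in the first
library).  A quantile-wise difference distribution (percentiles 1-99)
summarizes the shape of the shift.  A simplified k-mer depletion scan
(canonical k-mer counts per million, flagging strong dropouts) stands in
for assembly-based differential k-mer analysis; with a sequence-nonspecific
toxin it is expected to find nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import fragments_from_sam, read_sam, revcomp

MAX_INSERT = 2000  # |TLEN| above this is treated as a structural artifact


@dataclass
class InsertSizeDistribution:
    """Histogram of absolute template lengths for one library."""

    library_id: str
    batch_id: str
    histogram: dict[int, int]
    n: int
    n_discarded: int = 0  # pairs beyond MAX_INSERT

    @property
    def values(self) -> np.ndarray:
        """Expanded insert lengths (sorted)."""
        out = np.repeat(
            np.fromiter(self.histogram.keys(), dtype=int),
            np.fromiter(self.histogram.values(), dtype=int),
        )
        return np.sort(out)

    @property
    def median(self) -> float:
        return float(np.median(self.values))

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def iqr(self) -> float:
        v = self.values
        return float(np.percentile(v, 75) - np.percentile(v, 25))


def insert_size_distribution(
    inserts: Iterable[int],
    library_id: str,
    batch_id: str,
    max_insert: int = MAX_INSERT,
) -> InsertSizeDistribution:
    """Histogram |TLEN| values (leftmost mates of proper pairs)."""
    hist: dict[int, int] = {}
    n = 0
    discarded = 0
    for ins in inserts:
        ins = abs(int(ins))
        if ins == 0:
            continue
        if ins > max_insert:
            discarded += 1
            continue
        hist[ins] = hist.get(ins, 0) + 1
        n += 1
    if n == 0:
        raise ValueError(f"{library_id}: no proper pairs with usable insert sizes")
    return InsertSizeDistribution(library_id, batch_id, hist, n, discarded)


def insert_sizes_from_sam(
    path: str | Path, library_id: str, batch_id: str, max_insert: int = MAX_INSERT
) -> InsertSizeDistribution:
    inserts = (tlen for _, _, tlen in fragments_from_sam(read_sam(path)))
    return insert_size_distribution(inserts, library_id, batch_id, max_insert)


@dataclass
class ShiftTestResult:
    library_a: str
    library_b: str
    batch_id: str
    median_difference: float  # median_a − median_b (negative: a shorter)
    quantile_differences: np.ndarray  # ECDF⁻¹_a − ECDF⁻¹_b at percentiles 1..99
    statistic_z: float  # rank-sum Z of library a
    p_value: float  # permutation, one-sided for shorter-in-a
    n_perm: int
    batch_matched: bool = True


def _rank_sum_z(ranks_a: np.ndarray, n_a: int, n_b: int) -> float:
    """Normal-approximation Z of the rank sum of sample a (ties pooled)."""
    w = ranks_a.sum()
    mu = n_a * (n_a + n_b + 1) / 2.0
    sigma = np.sqrt(n_a * n_b * (n_a + n_b + 1) / 12.0)
    return float((w - mu) / sigma)


def batch_matched_shift_test(
    dist_a: InsertSizeDistribution,
    dist_b: InsertSizeDistribution,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
    max_n: int = 20_000,
) -> ShiftTestResult:
    """Rank-sum shift test between two batch-matched insert distributions.

    The permutation null shuffles library labels over the pooled inserts;
    the one-sided p-value is for library a having *shorter* inserts.  To
    bound permutation cost, each library is subsampled to ``max_n``
    inserts (deterministically, from the seeded generator).
    """
    if dist_a.batch_id != dist_b.batch_id:
        raise ValueError(
            "batch mismatch: comparisons are limited to samples prepared at the same "
            f"time (got {dist_a.batch_id!r} vs {dist_b.batch_id!r})"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a, b = dist_a.values, dist_b.values
    if a.size > max_n:
        a = rng.choice(a, size=max_n, replace=False)
    if b.size > max_n:
        b = rng.choice(b, size=max_n, replace=False)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a, n_b = a.size, b.size
    z_obs = _rank_sum_z(ranks[:n_a], n_a, n_b)

    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled.size)
        z = _rank_sum_z(ranks[perm[:n_a]], n_a, n_b)
        if z <= z_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)

    q = np.arange(1, 100)
    qdiff = np.percentile(a, q) - np.percentile(b, q)
    return ShiftTestResult(
        library_a=dist_a.library_id,
        library_b=dist_b.library_id,
        batch_id=dist_a.batch_id,
        median_difference=float(np.median(a) - np.median(b)),
        quantile_differences=qdiff,
        statistic_z=z_obs,
        p_value=p,
        n_perm=n_perm,
    )


def shift_time_course(
    manifest: pd.DataFrame,
    distributions: dict[str, InsertSizeDistribution],
    strain_pair: tuple[str, str],
    n_perm: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-timepoint shift tests for a strain pair within each batch.

    Returns one row per (batch, timepoint) with the pooled-replicate median
    difference and permutation p, plus a Spearman trend of median
    difference against time (NA with < 2 timepoints).
    """
    test_strain, ref_strain = strain_pair
    rng = np.random.default_rng(seed)
    rows = []
    for batch, grp in manifest.groupby("batch"):
        timepoints = sorted(grp["timepoint"].unique())
        for t in timepoints:
            libs_a = grp[(grp["genotype"] == test_strain) & (grp["timepoint"] == t)]["library_id"]
            libs_b = grp[(grp["genotype"] == ref_strain) & (grp["timepoint"] == t)]["library_id"]
            if libs_a.empty or libs_b.empty:
                continue
            da = _pool_distributions([distributions[l] for l in libs_a], batch)
            db = _pool_distributions([distributions[l] for l in libs_b], batch)
            res = batch_matched_shift_test(da, db, n_perm=n_perm, seed=rng)
            rows.append(
                {
                    "batch": batch,
                    "timepoint": t,
                    "median_difference": res.median_difference,
                    "statistic_z": res.statistic_z,
                    "p_value": res.p_value,
                }
            )
    out = pd.DataFrame(rows)
    if not out.empty:
        trends = {}
        for batch, grp in out.groupby("batch"):
            if grp["timepoint"].nunique() >= 2:
                rho = stats.spearmanr(grp["timepoint"], grp["median_difference"]).statistic
            else:
                rho = np.nan
            trends[batch] = rho
        out["trend_spearman"] = out["batch"].map(trends)
    return out


def _pool_distributions(
    dists: Sequence[InsertSizeDistribution], batch_id: str
) -> InsertSizeDistribution:
    hist: dict[int, int] = {}
    for d in dists:
        for k, v in d.histogram.items():
            hist[k] = hist.get(k, 0) + v
    return InsertSizeDistribution(
        "+".join(d.library_id for d in dists), batch_id, hist, sum(d.n for d in dists)
    )


# ---------------------------------------------------------------------------
# k-mer depletion scan
# ---------------------------------------------------------------------------


@dataclass
class KmerDiffResult:
    k: int
    table: pd.DataFrame  # kmer, count_a, count_b, cpm_a, cpm_b, log2_ratio, depleted
    depleted: list[str] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return len(self.depleted) > 0


def _canonical_kmers(reads: Iterable[str], k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for read in reads:
        read = read.upper()
        for i in range(len(read) - k + 1):
            kmer = read[i : i + k]
            if "N" in kmer:
                continue
            rc = revcomp(kmer)
            if rc < kmer:
                kmer = rc
            counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def kmer_depletion_scan(
    reads_a: Iterable[str],
    reads_b: Iterable[str],
    k: int = 10,
    min_count: int = 20,
    log2_threshold: float = -1.0,
) -> KmerDiffResult:
    """Flag canonical k-mers strongly depleted in set a relative to set b.

    Counts are normalized per million k-mers.  A k-mer is flagged when its
    normalized log2 ratio is ≤ ``log2_threshold`` and its count in the
    reference set b is ≥ ``min_count``.  An empty flag list is the
    "no significant differences" outcome.
    """
    if not 8 <= k <= 16:
        raise ValueError("k must be in [8, 16]")
    ca = _canonical_kmers(reads_a, k)
    cb = _canonical_kmers(reads_b, k)
    if not ca or not cb:
        raise ValueError("both read sets must be non-empty")
    tot_a = sum(ca.values())
    tot_b = sum(cb.values())
    rows = []
    depleted = []
    for kmer, nb in cb.items():
        if nb < min_count:
            continue
        na = ca.get(kmer, 0)
        cpm_a = na / tot_a * 1e6
        cpm_b = nb / tot_b * 1e6
        log2_ratio = np.log2(cpm_a / cpm_b) if na > 0 else -np.inf
        flag = log2_ratio <= log2_threshold
        if flag:
            depleted.append(kmer)
            rows.append(
                {
                    "kmer": kmer,
                    "count_a": na,
                    "count_b": nb,
                    "cpm_a": cpm_a,
                    "cpm_b": cpm_b,
                    "log2_ratio": log2_ratio,
                    "depleted": True,
                }
            )
    table = pd.DataFrame(rows, columns=["kmer", "count_a", "count_b", "cpm_a", "cpm_b", "log2_ratio", "depleted"])
    return KmerDiffResult(k=k, table=table, depleted=sorted(depleted))


def read_fastq_sequences(path: str | Path) -> list[str]:
    """Sequences of a FASTQ file (plain text, 4-line records)."""
    seqs = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if i % 4 == 1:
                seqs.append(line.strip())
    return seqs
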