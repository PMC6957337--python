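"""Position-level coverage, internal-promoter detection, and translatability.

Coverage is *fragment-level* (physical): every position spanned by a
sequenced fragment (|TLEN| of its proper pair) gets one count, so the
track describes molecule abundance rather than read pileup.  Fragment
5'-start counts are tracked separately: a promoter creates a step in where
fragments *begin*, which is the signal the internal-TSS detector uses.

The detector fits a two-segment piecewise-constant Poisson model to the
start profile over a window around the toxin start codon, takes the
maximum-likelihood change point, and assesses it with a parametric
bootstrap of the single-rate null.  Position contrasts follow the
figure convention of the study: position 0 is the *toxT* start codon
(34 nt downstream of the CRP-S promoter) and position 100 lies 70 nt
downstream of the internal P2 promoter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .io import SequenceRecord, fragments_from_sam, read_sam
from .reference import Liftover, OperonModel


def build_strain_reference(model: OperonModel, genotype: str) -> tuple[SequenceRecord, Liftover]:
    """Strain-specific locus sequence and its wildtype-coordinate liftover."""
    seq = model.strain_locus(genotype)
    return SequenceRecord(f"locus_{genotype}", seq), model.liftover(genotype)


@dataclass
class CoverageTrack:
    """Per-position fragment coverage and fragment 5'-start counts."""

    reference_id: str
    coverage: np.ndarray  # raw integer fragment coverage
    starts: np.ndarray  # raw fragment 5'-start counts
    size_factor: float = 1.0
    n_pairs: int = 0
    n_clipped: int = 0  # fragments extending past the reference end

    @property
    def normalized_coverage(self) -> np.ndarray:
        return self.coverage / self.size_factor

    @property
    def normalized_starts(self) -> np.ndarray:
        return self.starts / self.size_factor


def coverage_track(
    fragments: Iterable[tuple[str, int, int]],
    reference_id: str,
    reference_length: int,
    size_factor: float = 1.0,
) -> CoverageTrack:
    """Accumulate fragment coverage/starts from (ref, start, insert) triples."""
    delta = np.zeros(reference_length + 1, dtype=np.int64)
    starts = np.zeros(reference_length, dtype=np.int64)
    n_pairs = 0
    n_clipped = 0
    for ref, start, tlen in fragments:
        if ref != reference_id:
            continue
        end = start + tlen
        if end > reference_length:
            end = reference_length
            n_clipped += 1
        if start < 0 or start >= reference_length:
            n_clipped += 1
            continue
        delta[start] += 1
        delta[end] -= 1
        starts[start] += 1
        n_pairs += 1
    coverage = np.cumsum(delta[:-1])
    return CoverageTrack(reference_id, coverage, starts, size_factor, n_pairs, n_clipped)


def coverage_from_sam(
    path: str | Path, reference_id: str, reference_length: int, size_factor: float = 1.0
) -> CoverageTrack:
    return coverage_track(
        fragments_from_sam(read_sam(path)), reference_id, reference_length, size_factor
    )


def replicate_mean_se(tracks: Sequence[CoverageTrack]) -> tuple[np.ndarray, np.ndarray]:
    """Mean and standard error of normalized coverage across replicates."""
    if not tracks:
        raise ValueError("no tracks")
    stack = np.vstack([t.normalized_coverage for t in tracks])
    mean = stack.mean(axis=0)
    if stack.shape[0] < 2:
        return mean, np.full_like(mean, np.nan)
    se = stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
    return mean, se


# ---------------------------------------------------------------------------
# Internal-TSS change-point detection
# ---------------------------------------------------------------------------


@dataclass
class PromoterCall:
    tss_position: Optional[int]  # track coordinates; None = no internal promoter
    offset_from_toxT_start: Optional[int]
    upstream_rate: float
    downstream_rate: float
    llr: float
    p_value: float

    @property
    def called(self) -> bool:
        return self.tss_position is not None


def _segment_loglik(counts: np.ndarray) -> tuple[np.ndarray, float]:
    """Profile log-likelihoods of all two-segment splits and the single-rate
    model (constant terms dropped)."""
    n = counts.size
    cum = np.cumsum(counts)
    total = cum[-1]
    c = np.arange(1, n)
    s1 = cum[:-1].astype(float)
    s2 = total - s1
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = (
            np.where(s1 > 0, s1 * np.log(s1 / c), 0.0)
            - s1
            + np.where(s2 > 0, s2 * np.log(s2 / (n - c)), 0.0)
            - s2
        )
        ll0 = (total * np.log(total / n) if total > 0 else 0.0) - total
    return ll, ll0


def change_point_scan(counts: np.ndarray) -> tuple[int, float]:
    """Best two-segment split of a count profile: (change point, LLR)."""
    ll, ll0 = _segment_loglik(counts)
    best = int(np.argmax(ll))
    return best + 1, float(ll[best] - ll0)


def detect_internal_tss(
    starts: np.ndarray,
    window: tuple[int, int],
    toxT_start: int,
    n_bootstrap: int = 200,
    alpha: float = 0.01,
    rng: Optional[np.random.Generator] = None,
    min_total: int = 100,
) -> PromoterCall:
    """Change-point detection of an internal promoter on a start profile.

    ``starts`` is a full-track raw start-count array; the scan runs on
    ``window`` (track coordinates, half-open).  A promoter is called when
    the ML change point has a higher downstream than upstream rate and the
    likelihood-ratio beats a parametric bootstrap of the single-rate
    Poisson null at level ``alpha``.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    lo, hi = window
    profile = np.asarray(starts[lo:hi], dtype=float)
    total = profile.sum()
    if total < min_total:
        raise ValueError(f"only {int(total)} fragment starts in window; need ≥ {min_total}")
    cp, llr = change_point_scan(profile)
    n = profile.size
    up_rate = profile[:cp].mean()
    down_rate = profile[cp:].mean()

    lam = total / n
    null_llr = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        sim = rng.poisson(lam, size=n)
        _, null_llr[b] = change_point_scan(sim)
    p_value = (1 + int((null_llr >= llr).sum())) / (n_bootstrap + 1)

    if down_rate <= up_rate or p_value >= alpha:
        return PromoterCall(None, None, up_rate, down_rate, llr, p_value)
    tss = lo + cp
    return PromoterCall(tss, tss - toxT_start, up_rate, down_rate, llr, p_value)


# ---------------------------------------------------------------------------
# Position contrasts (figure convention: offsets from the toxT start codon)
# ---------------------------------------------------------------------------


def position_contrast(
    tracks: dict[tuple[str, int], Sequence[CoverageTrack]],
    model: OperonModel,
    positions: Sequence[int] = (0, 100),
    reference_genotype: str = "wildtype",
) -> pd.DataFrame:
    """Normalized coverage (mean ± SE) at named operon positions.

    ``tracks`` maps (genotype, timepoint) to replicate tracks on the
    strain's own locus.  Positions are offsets from the *toxT* start codon
    in wildtype coordinates and are lifted to each strain; positions
    deleted in a strain yield NA.  Ratios are taken against the reference
    genotype at the matched timepoint, with propagated SE.
    """
    rows = []
    values: dict[tuple[str, int, int], tuple[float, float]] = {}
    for (genotype, timepoint), reps in tracks.items():
        lift = model.liftover(genotype)
        stack = np.vstack([t.normalized_coverage for t in reps])
        for offset in positions:
            pos = lift.wt_to_strain(model.toxT_start + offset)
            if pos is None or pos >= stack.shape[1]:
                values[(genotype, timepoint, offset)] = (np.nan, np.nan)
                continue
            col = stack[:, pos]
            mean = float(col.mean())
            se = float(col.std(ddof=1) / np.sqrt(len(col))) if len(col) > 1 else np.nan
            values[(genotype, timepoint, offset)] = (mean, se)

    for (genotype, timepoint), _ in tracks.items():
        for offset in positions:
            mean, se = values[(genotype, timepoint, offset)]
            ref = values.get((reference_genotype, timepoint, offset), (np.nan, np.nan))
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = mean / ref[0]
                ratio_se = (
                    abs(ratio) * np.sqrt((se / mean) ** 2 + (ref[1] / ref[0]) ** 2)
                    if mean and np.isfinite(ratio)
                    else np.nan
                )
            rows.append(
                {
                    "genotype": genotype,
                    "timepoint": timepoint,
                    "position": offset,
                    "mean": mean,
                    "se": se,
                    "ratio_vs_reference": ratio,
                    "ratio_se": ratio_se,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Translatability of truncated transcripts
# ---------------------------------------------------------------------------

_SD_MOTIF = "AGGAGG"
SD_SCORE_THRESHOLD = 5  # ≤ 1 mismatch against AGGAGG
_SD_SPACING = (5, 13)  # nt between SD end and start codon


@dataclass
class StartCandidate:
    codon: str
    position: int
    in_frame: bool
    sd_score: int
    sd_spacing: Optional[int]


@dataclass
class TranslatabilityReport:
    transcript_5prime: int
    candidates: list[StartCandidate] = field(default_factory=list)
    verdict: str = "nonfunctional"  # "functional" | "nonfunctional"


def _best_sd(seq: str, start_pos: int) -> tuple[int, Optional[int]]:
    best_score, best_spacing = 0, None
    for spacing in range(_SD_SPACING[0], _SD_SPACING[1] + 1):
        end = start_pos - spacing
        s = end - len(_SD_MOTIF)
        if s < 0:
            continue
        mism = sum(a != b for a, b in zip(seq[s:end], _SD_MOTIF))
        score = len(_SD_MOTIF) - mism
        if score > best_score:
            best_score, best_spacing = score, spacing
    return best_score, best_spacing


def translatability_scan(
    transcript_5prime: int,
    cds: tuple[int, int],
    sequence: str,
    sd_threshold: int = SD_SCORE_THRESHOLD,
) -> TranslatabilityReport:
    """Scan a transcript for usable start codons.

    Candidates are ATG/GTG triplets from the transcript 5' end to the CDS
    end, annotated with frame (relative to the CDS) and the best
    Shine-Dalgarno match (AGGAGG, ≥ ``sd_threshold`` of 6 within 5-13 nt
    spacing).  The verdict is ``functional`` iff an in-frame, SD-equipped
    start exists upstream of 90% of the CDS.
    """
    cds_start, cds_end = cds
    if transcript_5prime >= cds_end:
        raise ValueError("transcript 5' end lies beyond the CDS")
    candidates = []
    functional = False
    latest_start = cds_start + (cds_end - cds_start) // 10  # keeps ≥ 90% of the CDS
    for p in range(transcript_5prime, cds_end - 2):
        codon = sequence[p : p + 3]
        if codon not in ("ATG", "GTG"):
            continue
        in_frame = (p - cds_start) % 3 == 0
        sd_score, sd_spacing = _best_sd(sequence, p)
        candidates.append(StartCandidate(codon, p, in_frame, sd_score, sd_spacing))
        if in_frame and sd_score >= sd_threshold and p <= latest_start:
            functional = True
    return TranslatabilityReport(
        transcript_5prime=transcript_5prime,
        candidates=candidates,
        verdict="functional" if functional else "nonfunctional",
    )
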