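"""Codon-aware alignment and Nei–Gojobori (1986) selection statistics.

The antitoxin selection analysis needs three pieces: a codon-aware multiple
alignment of CDS variants, pairwise nucleotide distances, and pairwise
dN/dS under the unweighted-pathway NG86 model:

* synonymous/nonsynonymous **site** counts per codon are the fractions of
  one-step changes that preserve/change the amino acid (changes to stop
  codons count as nonsynonymous), normalized so each codon contributes
  exactly 3 sites, and averaged over the two sequences;
* **difference** counts for codons differing at k positions average the
  synonymous/nonsynonymous steps over all k! substitution pathways;
* proportions are Jukes–Cantor corrected, d = −3/4 ln(1 − 4p/3).

The cohort summary reports the mean over all unordered pairs, with ω
computed as (mean dN)/(mean dS) — a ratio of means, which is stable when
individual pairs have few synonymous differences.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .io import SequenceRecord
from .reference import STOP_CODONS, codon_table

GAP_CODON = "---"

_START_CODONS = ("ATG", "GTG", "TTG")


@dataclass
class CodonAlignment:
    """Gap-aligned CDS set; gaps occur in whole-codon units."""

    gene_id: str
    ids: list[str]
    sequences: list[str]  # aligned DNA, equal lengths divisible by 3

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError("aligned sequences differ in length")
        (length,) = lengths
        if length % 3:
            raise ValueError("aligned length not divisible by 3")
        for sid, seq in zip(self.ids, self.sequences):
            for i in range(0, length, 3):
                codon = seq[i : i + 3]
                if "-" in codon and codon != GAP_CODON:
                    raise ValueError(f"{sid}: gap interrupts codon {i // 3}")

    @property
    def n_codons(self) -> int:
        return len(self.sequences[0]) // 3

    def codons(self, index: int) -> list[str]:
        seq = self.sequences[index]
        return [seq[i : i + 3] for i in range(0, len(seq), 3)]


@dataclass
class SelectionSummary:
    gene_id: str
    n_sequences: int
    mean_pairwise_distance: float
    dN: float
    dS: float
    omega: Optional[float]  # None when dS == 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": self.gene_id,
                    "n_sequences": self.n_sequences,
                    "mean_pairwise_distance": self.mean_pairwise_distance,
                    "dN": self.dN,
                    "dS": self.dS,
                    "omega": np.nan if self.omega is None else self.omega,
                }
            ]
        )


def _validate_cds(rec: SequenceRecord, check_start: bool) -> str:
    seq = rec.sequence.upper()
    if len(seq) % 3:
        raise ValueError(f"{rec.id}: length {len(seq)} not divisible by 3")
    for ci in range(len(seq) // 3 - 1):
        if seq[3 * ci : 3 * ci + 3] in STOP_CODONS:
            raise ValueError(f"{rec.id}: internal stop codon at codon {ci}")
    if check_start and seq[:3] not in _START_CODONS:
        raise ValueError(f"{rec.id}: does not begin with a start codon")
    return seq


def _translate(seq: str) -> str:
    aa = str(Seq(seq).translate())
    return aa[:-1] if aa.endswith("*") else aa


def _aa_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def _pairwise_aa_gaps(center: str, other: str) -> tuple[list[int], list[int]]:
    """Align two AA strings; return per-position gap patterns.

    Returns (ins_after_center, other_cols): ``ins_after_center[i]`` is the
    number of inserted columns after center position i (index 0 =
    insertions before the first position); ``other_cols`` maps each
    alignment column to the other sequence's AA index or -1 for a gap.
    """
    aln = _aa_aligner().align(center, other)[0]
    t_blocks, q_blocks = aln.aligned
    ins = [0] * (len(center) + 1)
    cols: list[int] = []  # per center position: other index or -1
    prev_t = prev_q = 0
    ins_pos: dict[int, int] = {}
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        ins_pos[prev_t] = ins_pos.get(prev_t, 0) + (qs - prev_q)
        cols.extend([-1] * (ts - prev_t))
        cols.extend(range(qs, qe))
        prev_t, prev_q = te, qe
    ins_pos[prev_t] = ins_pos.get(prev_t, 0) + (len(other) - prev_q)
    cols.extend([-1] * (len(center) - prev_t))
    for pos, count in ins_pos.items():
        ins[pos] = count
    return ins, cols


def codon_align(
    records: Sequence[SequenceRecord],
    gene_id: str = "gene",
    check_start: bool = True,
) -> CodonAlignment:
    """Codon-aware multiple alignment (star alignment on the first sequence).

    Sequences are translated, aligned at the amino-acid level (BLOSUM62,
    affine gaps) against the first sequence, and the amino-acid gaps are
    back-threaded onto whole codons.
    """
    if not records:
        raise ValueError("no sequences to align")
    seqs = [_validate_cds(r, check_start) for r in records]
    aas = [_translate(s) for s in seqs]
    center = aas[0]

    results = [_pairwise_aa_gaps(center, aa) for aa in aas[1:]]
    master_ins = [0] * (len(center) + 1)
    for ins, _ in results:
        for i, c in enumerate(ins):
            master_ins[i] = max(master_ins[i], c)

    def thread(seq: str, ins: list[int], cols: Optional[list[int]]) -> str:
        """Rebuild one sequence on the master column set, in codon units.

        Own insertions relative to the center are placed left-aligned
        within the master insertion block; ``cols=None`` denotes the center
        itself (every center position is a real codon).
        """
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        out: list[str] = []
        qi = 0
        for pos in range(len(center) + 1):
            own = ins[pos]
            out.extend(codons[qi : qi + own])
            qi += own
            out.extend([GAP_CODON] * (master_ins[pos] - own))
            if pos < len(center):
                if cols is not None and cols[pos] == -1:
                    out.append(GAP_CODON)
                else:
                    out.append(codons[qi])
                    qi += 1
        return "".join(out)

    aligned = [thread(seqs[0], [0] * (len(center) + 1), None)]
    for seq, (ins, cols) in zip(seqs[1:], results):
        aligned.append(thread(seq, ins, cols))
    return CodonAlignment(gene_id, [r.id for r in records], aligned)


# ---------------------------------------------------------------------------
# NG86
# ---------------------------------------------------------------------------


def _site_counts(codon: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous site fractions of one codon (sum = 3)."""
    table = codon_table()
    aa = table[codon]
    syn = nonsyn = 0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant in STOP_CODONS or table[mutant] != aa:
                nonsyn += 1
            else:
                syn += 1
    total = syn + nonsyn  # 9 one-step neighbours
    return 3 * syn / total, 3 * nonsyn / total


def _diff_counts(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous differences of a codon pair."""
    table = codon_table()
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    syn = nonsyn = 0.0
    paths = list(itertools.permutations(diff))
    w = 1.0 / len(paths)
    for path in paths:
        cur = c1
        for pos in path:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if table[cur] == table[nxt]:
                syn += w
            else:
                nonsyn += w
            cur = nxt
    return syn, nonsyn


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        warnings.warn(f"proportion {p:.3f} ≥ 3/4: distance saturates to infinity")
        return float("inf")
    return -0.75 * np.log(1 - 4 * p / 3)


def ng86_pair(a: str, b: str) -> tuple[float, float, Optional[float]]:
    """NG86 (dN, dS, ω) for two aligned codon sequences.

    Codons gapped in either sequence are excluded pairwise.  ω is None when
    there are no synonymous substitutions (dS = 0).
    """
    if len(a) != len(b) or len(a) % 3:
        raise ValueError("sequences must be aligned and of equal codon length")
    syn_sites = nonsyn_sites = 0.0
    syn_diff = nonsyn_diff = 0.0
    for i in range(0, len(a), 3):
        c1, c2 = a[i : i + 3], b[i : i + 3]
        if "-" in c1 or "-" in c2:
            continue
        s1, n1 = _site_counts(c1)
        s2, n2 = _site_counts(c2)
        syn_sites += (s1 + s2) / 2
        nonsyn_sites += (n1 + n2) / 2
        sd, nd = _diff_counts(c1, c2)
        syn_diff += sd
        nonsyn_diff += nd
    if syn_sites == 0 or nonsyn_sites == 0:
        raise ValueError("no ungapped codons shared by the pair")
    dS = _jukes_cantor(syn_diff / syn_sites)
    dN = _jukes_cantor(nonsyn_diff / nonsyn_sites)
    omega = None if dS == 0 else dN / dS
    return dN, dS, omega


def p_distance(a: str, b: str) -> float:
    """Raw nucleotide p-distance with pairwise deletion of gap columns."""
    pairs = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
    if not pairs:
        return float("nan")
    return sum(x != y for x, y in pairs) / len(pairs)


def pairwise_matrix(aln: CodonAlignment) -> pd.DataFrame:
    """Long-format table of pairwise distance/dN/dS/ω for all pairs."""
    rows = []
    for i, j in itertools.combinations(range(len(aln.sequences)), 2):
        a, b = aln.sequences[i], aln.sequences[j]
        dN, dS, omega = ng86_pair(a, b)
        rows.append(
            {
                "id_a": aln.ids[i],
                "id_b": aln.ids[j],
                "p_distance": p_distance(a, b),
                "dN": dN,
                "dS": dS,
                "omega": np.nan if omega is None else omega,
            }
        )
    return pd.DataFrame(rows)


def cohort_selection_summary(aln: CodonAlignment) -> SelectionSummary:
    """Mean pairwise distance and NG86 dN/dS over all unordered pairs."""
    if len(aln.sequences) < 2:
        raise ValueError("need at least 2 sequences")
    pairs = pairwise_matrix(aln)
    mean_dN = float(pairs["dN"].mean())
    mean_dS = float(pairs["dS"].mean())
    omega = None if mean_dS == 0 else mean_dN / mean_dS
    return SelectionSummary(
        gene_id=aln.gene_id,
        n_sequences=len(aln.sequences),
        mean_pairwise_distance=float(pairs["p_distance"].mean()),
        dN=mean_dN,
        dS=mean_dS,
        omega=omega,
    )
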