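"""Reference model of the toxTA locus and its engineered variants.

The packaged reference is a synthetic but structurally faithful model of the
*H. influenzae* Rd KW20 toxTA region: a toxin CDS (*toxT*, 119 codons + stop,
360 nt) followed by an antitoxin CDS (*toxA*, 98 codons + stop, 297 nt),
sharing a CRP-S promoter 34 nt upstream of the *toxT* start codon, with an
internal antitoxin-repressed promoter (P2) whose transcripts begin 30 nt
downstream of the *toxT* start.  Flanking anchor genes delimit the locus for
cohort scanning; the analysis window is 2300 nt centered on *toxA*.

The locus sequence is generated deterministically (fixed seed) under explicit
sequence constraints so that the biology the pipeline tests for is actually
encoded:

* the only in-frame ATG downstream of P2 sits 30 bp from the 3' end of
  *toxT*, and the first GTG downstream of P2 is at position +35 — neither has
  a Shine-Dalgarno sequence, so P2 transcripts cannot yield active toxin;
* the *toxT* start itself carries a canonical AGGAGG Shine-Dalgarno;
* the three natural deletion alleles (178 nt toxT-internal, 306 nt
  promoter-spanning, 1015 nt whole-operon with an 87 nt novel replacement)
  are defined at fixed coordinates with unambiguous breakpoints.

Coordinates are 0-based half-open on the forward strand of the locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .io import dump_yaml, load_yaml

# Standard genetic code, DNA alphabet.
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_CODON_TABLE: dict[str, str] = {}


def _build_codon_table() -> dict[str, str]:
    from Bio.Data.CodonTable import standard_dna_table

    table = dict(standard_dna_table.forward_table)
    for stop in STOP_CODONS:
        table[stop] = "*"
    return table


def codon_table() -> dict[str, str]:
    if not _CODON_TABLE:
        _CODON_TABLE.update(_build_codon_table())
    return _CODON_TABLE


SENSE_CODONS = None  # filled lazily


def sense_codons() -> list[str]:
    global SENSE_CODONS
    if SENSE_CODONS is None:
        SENSE_CODONS = sorted(set(codon_table()) - STOP_CODONS)
    return SENSE_CODONS


@dataclass(frozen=True)
class AlleleDefinition:
    """One of the naturally occurring toxTA allele structures."""

    allele_id: str
    deleted_interval: tuple[int, int]  # locus coordinates; (0, 0) for intact
    replacement: str = ""  # novel sequence inserted in place of the deletion
    features_lost: frozenset[str] = field(default_factory=frozenset)

    @property
    def deletion_length(self) -> int:
        return self.deleted_interval[1] - self.deleted_interval[0]


class Liftover:
    """Coordinate map between wildtype locus and a deletion construct."""

    def __init__(self, deleted: Optional[tuple[int, int]]):
        self.deleted = deleted

    def wt_to_strain(self, pos: int) -> Optional[int]:
        if self.deleted is None:
            return pos
        s, e = self.deleted
        if s <= pos < e:
            return None  # position deleted in this strain
        return pos if pos < s else pos - (e - s)

    def strain_to_wt(self, pos: int) -> int:
        if self.deleted is None:
            return pos
        s, e = self.deleted
        return pos if pos < s else pos + (e - s)


@dataclass
class OperonModel:
    """Coordinates, features, and sequence of the reference toxTA locus."""

    locus: str
    toxT_cds: tuple[int, int]
    toxA_cds: tuple[int, int]
    crp_s_promoter: int  # promoter point; transcription of the full isoform starts here
    p2_tss: int  # internal promoter TSS, +30 from the toxT start codon
    transcript_end: int  # 3' end of both operon isoforms
    upstream_anchor: tuple[int, int]
    downstream_anchor: tuple[int, int]
    window_halfwidth: int = 1150
    alleles: dict[str, AlleleDefinition] = field(default_factory=dict)
    genotype_deletions: dict[str, Optional[tuple[int, int]]] = field(default_factory=dict)

    # -- derived geometry ---------------------------------------------------
    @property
    def toxT_start(self) -> int:
        return self.toxT_cds[0]

    @property
    def window(self) -> tuple[int, int]:
        center = (self.toxA_cds[0] + self.toxA_cds[1]) // 2
        return (center - self.window_halfwidth, center + self.window_halfwidth)

    @property
    def window_seq(self) -> str:
        s, e = self.window
        return self.locus[s:e]

    @property
    def features(self) -> dict[str, tuple[int, int]]:
        """Feature intervals in locus coordinates (points as length-1/3)."""
        return {
            "crp_s_promoter": (self.crp_s_promoter, self.crp_s_promoter + 1),
            "toxT_start": (self.toxT_start, self.toxT_start + 3),
            "p2_tss": (self.p2_tss, self.p2_tss + 1),
            "toxT_cds": self.toxT_cds,
            "toxA_cds": self.toxA_cds,
        }

    def anchor_seq(self, which: str) -> str:
        s, e = self.upstream_anchor if which == "upstream" else self.downstream_anchor
        return self.locus[s:e]

    def cds_seq(self, which: str) -> str:
        s, e = self.toxT_cds if which == "toxT" else self.toxA_cds
        return self.locus[s:e]

    def liftover(self, genotype: str) -> Liftover:
        if genotype not in self.genotype_deletions:
            raise ValueError(f"unknown genotype {genotype!r}")
        return Liftover(self.genotype_deletions[genotype])

    def strain_locus(self, genotype: str) -> str:
        """Locus sequence of an engineered deletion construct."""
        deleted = self.genotype_deletions.get(genotype)
        if genotype not in self.genotype_deletions:
            raise ValueError(f"unknown genotype {genotype!r}")
        if deleted is None:
            return self.locus
        s, e = deleted
        return self.locus[:s] + self.locus[e:]

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "locus": self.locus,
            "toxT_cds": list(self.toxT_cds),
            "toxA_cds": list(self.toxA_cds),
            "crp_s_promoter": self.crp_s_promoter,
            "p2_tss": self.p2_tss,
            "transcript_end": self.transcript_end,
            "upstream_anchor": list(self.upstream_anchor),
            "downstream_anchor": list(self.downstream_anchor),
            "window_halfwidth": self.window_halfwidth,
            "alleles": {
                aid: {
                    "deleted_interval": list(a.deleted_interval),
                    "replacement": a.replacement,
                    "features_lost": sorted(a.features_lost),
                }
                for aid, a in self.alleles.items()
            },
            "genotype_deletions": {
                g: (list(d) if d is not None else None)
                for g, d in self.genotype_deletions.items()
            },
        }

    def save(self, path: str | Path) -> None:
        dump_yaml(self.to_dict(), path)

    @classmethod
    def from_dict(cls, data: dict) -> "OperonModel":
        alleles = {
            aid: AlleleDefinition(
                allele_id=aid,
                deleted_interval=tuple(a["deleted_interval"]),
                replacement=a.get("replacement", ""),
                features_lost=frozenset(a.get("features_lost", [])),
            )
            for aid, a in data.get("alleles", {}).items()
        }
        return cls(
            locus=data["locus"],
            toxT_cds=tuple(data["toxT_cds"]),
            toxA_cds=tuple(data["toxA_cds"]),
            crp_s_promoter=data["crp_s_promoter"],
            p2_tss=data["p2_tss"],
            transcript_end=data["transcript_end"],
            upstream_anchor=tuple(data["upstream_anchor"]),
            downstream_anchor=tuple(data["downstream_anchor"]),
            window_halfwidth=data.get("window_halfwidth", 1150),
            alleles=alleles,
            genotype_deletions={
                g: (tuple(d) if d is not None else None)
                for g, d in data.get("genotype_deletions", {}).items()
            },
        )


GENOTYPES = ("wildtype", "dtoxA", "dtoxT", "dtoxTA", "dcrp", "dsxy")

# Locus layout constants used by the deterministic constructor.
_LOCUS_LEN = 2600
_TOXT = (800, 1160)  # 119 codons + stop = 360 nt
_TOXA = (1166, 1463)  # 98 codons + stop = 297 nt
_CRP_S = 766  # 34 nt upstream of the toxT start codon
_P2 = 830  # +30 from the toxT start codon
_TRANSCRIPT_END = 1470
_UP_ANCHOR = (240, 540)
_DOWN_ANCHOR = (1700, 2000)
_SD = "AGGAGG"
_SD_POS = 789  # ends 5 nt upstream of the toxT start codon

_ALLELE_INTERVALS = {
    "intact": (0, 0),
    "del_toxT_internal": (900, 1078),  # 178 nt, inside toxT, downstream of P2
    "del_promoters": (560, 866),  # 306 nt, removes CRP-S, toxT start, and P2
    "del_complete": (650, 1665),  # 1015 nt, removes both CDSs, anchors intact
}

_GENOTYPE_DELETIONS: dict[str, Optional[tuple[int, int]]] = {
    "wildtype": None,
    "dcrp": None,  # regulatory gene deleted elsewhere on the chromosome
    "dsxy": None,
    "dtoxA": (1166, 1463),  # toxA CDS excised; both promoters intact
    "dtoxT": (810, 1155),  # retains the toxT start codon; removes P2 and position +100
    "dtoxTA": (950, 1463),  # retains the first 150 nt of the operon, including P2
}

_BASE_P = {"A": 0.31, "C": 0.19, "G": 0.19, "T": 0.31}  # ~38% GC
_DEFAULT_SEED = 660_659


def _random_bases(rng: np.random.Generator, n: int) -> str:
    bases = np.array(list("ACGT"))
    p = np.array([_BASE_P[b] for b in bases])
    return "".join(rng.choice(bases, size=n, p=p))


def _has_sd_like(seq: str, start_pos: int, max_mismatch: int = 1) -> bool:
    """Is there an AGGAGG-like hexamer 5-13 nt upstream of ``start_pos``?"""
    for end in range(start_pos - 13, start_pos - 4):
        s = end - len(_SD)
        if s < 0 or end > len(seq):
            continue
        mism = sum(a != b for a, b in zip(seq[s:end], _SD))
        if mism <= max_mismatch:
            return True
    return False


def _build_toxT(rng: np.random.Generator) -> str:
    """119 codons + TAA satisfying the start-codon layout constraints."""
    pool = [c for c in sense_codons() if c not in ("ATG", "GTG")]
    for _ in range(1000):
        codons = ["ATG"] + [pool[i] for i in rng.integers(0, len(pool), size=118)]
        # GTG at +35..+37 spans codon 11 (third base G) and codon 12 (TG_).
        c11 = [c for c in pool if c[2] == "G"]
        codons[11] = c11[rng.integers(0, len(c11))]
        codons[12] = "TGC"
        # The only internal in-frame ATG: codon 109, i.e. 30 bp from the gene end.
        codons[109] = "ATG"
        seq = "".join(codons) + "TAA"
        assert len(seq) == 360
        # first GTG at or after +30 must be exactly at +35
        hits = [i for i in range(30, len(seq) - 2) if seq[i : i + 3] == "GTG"]
        if not hits or hits[0] != 35:
            continue
        # neither alternative start may have an upstream SD
        if _has_sd_like(seq, 35) or _has_sd_like(seq, 327):
            continue
        return seq
    raise RuntimeError("could not satisfy toxT sequence constraints")


def _build_cds(rng: np.random.Generator, n_codons: int) -> str:
    pool = sense_codons()
    codons = ["ATG"] + [pool[i] for i in rng.integers(0, len(pool), size=n_codons - 1)]
    return "".join(codons) + "TAA"


def build_default_model(seed: int = _DEFAULT_SEED) -> OperonModel:
    """Deterministically construct the packaged reference locus."""
    rng = np.random.default_rng(seed)
    locus = list(_random_bases(rng, _LOCUS_LEN))

    toxT = _build_toxT(rng)
    toxA = _build_cds(rng, 98)
    locus[_TOXT[0] : _TOXT[1]] = toxT
    locus[_TOXA[0] : _TOXA[1]] = toxA
    locus[_SD_POS : _SD_POS + len(_SD)] = _SD
    seq = "".join(locus)

    # 87 nt of novel sequence replacing the whole-operon deletion.  Its first
    # and last bases are forced to differ from the reference bases they abut,
    # so the deletion/insert breakpoints are unambiguous.
    dc_s, dc_e = _ALLELE_INTERVALS["del_complete"]
    while True:
        novel = _random_bases(rng, 87)
        if novel[0] != seq[dc_s] and novel[-1] != seq[dc_e - 1]:
            break

    features = {
        "crp_s_promoter": (_CRP_S, _CRP_S + 1),
        "toxT_start": (_TOXT[0], _TOXT[0] + 3),
        "p2_tss": (_P2, _P2 + 1),
        "toxT_cds": _TOXT,
        "toxA_cds": _TOXA,
    }

    def lost(interval: tuple[int, int]) -> frozenset[str]:
        s, e = interval
        out = set()
        for name, (fs, fe) in features.items():
            if fs >= s and fe <= e:
                out.add(name)
        return frozenset(out)

    alleles = {
        aid: AlleleDefinition(
            allele_id=aid,
            deleted_interval=iv,
            replacement=novel if aid == "del_complete" else "",
            features_lost=lost(iv) if iv != (0, 0) else frozenset(),
        )
        for aid, iv in _ALLELE_INTERVALS.items()
    }

    return OperonModel(
        locus=seq,
        toxT_cds=_TOXT,
        toxA_cds=_TOXA,
        crp_s_promoter=_CRP_S,
        p2_tss=_P2,
        transcript_end=_TRANSCRIPT_END,
        upstream_anchor=_UP_ANCHOR,
        downstream_anchor=_DOWN_ANCHOR,
        alleles=alleles,
        genotype_deletions=dict(_GENOTYPE_DELETIONS),
    )


_CACHED_MODEL: Optional[OperonModel] = None


def load_reference(path: Optional[str | Path] = None) -> OperonModel:
    """Load an operon model from YAML, or the packaged default."""
    global _CACHED_MODEL
    if path is not None:
        return OperonModel.from_dict(load_yaml(path))
    if _CACHED_MODEL is None:
        _CACHED_MODEL = build_default_model()
    return _CACHED_MODEL


def apply_allele(model: OperonModel, allele_id: str) -> str:
    """Window sequence of a genome carrying the given allele (no divergence)."""
    if allele_id not in model.alleles:
        raise ValueError(f"unknown allele {allele_id!r}")
    allele = model.alleles[allele_id]
    ws, we = model.window
    window = model.locus[ws:we]
    if allele.deletion_length == 0:
        return window
    s, e = allele.deleted_interval
    return window[: s - ws] + allele.replacement + window[e - ws :]
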