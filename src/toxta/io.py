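"""I/O primitives shared by every pipeline stage.

Sequence records travel as plain FASTA (read through Biopython's SeqIO),
alignments as headered SAM text (read through pysam), tabular outputs as
TSV with a header line, and configuration as YAML.  All genomic coordinates
inside the package are 0-based, half-open, on the forward strand; SAM's
1-based positions are converted on read and write.

Randomness is controlled by one global integer seed.  Each stage derives an
independent substream by hashing its stage name into the seed sequence, so
stages are reproducible in isolation and insensitive to execution order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence over the alphabet {A,C,G,T,N}."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")


@dataclass(frozen=True)
class AlignmentRecord:
    """One SAM alignment line, coordinates 0-based.

    ``flags`` is a subset of {"paired", "proper_pair", "reverse",
    "first_in_pair", "unmapped"}.  For a proper pair the two mates carry
    template lengths of equal magnitude and opposite sign, mirroring SAM
    TLEN semantics.
    """

    query_name: str
    reference_name: str
    pos: int
    mate_pos: int
    template_length: int
    flags: frozenset[str] = field(default_factory=frozenset)
    cigar: tuple[tuple[str, int], ...] = ()

    @property
    def is_proper_pair(self) -> bool:
        return "proper_pair" in self.flags and "unmapped" not in self.flags

    @property
    def is_leftmost_mate(self) -> bool:
        """True for the mate that represents the fragment (positive TLEN)."""
        return self.is_proper_pair and self.template_length > 0


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (wrapped or unwrapped) FASTA file.

    Sequences are upper-cased and RNA U is mapped to T.  Duplicate ids and
    empty files are rejected.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        records.append(SequenceRecord(rec.id, seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    bio = [_BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(bio)


_FLAG_BITS = (
    (0x1, "paired"),
    (0x2, "proper_pair"),
    (0x4, "unmapped"),
    (0x10, "reverse"),
    (0x40, "first_in_pair"),
)


def _flags_from_int(flag: int) -> frozenset[str]:
    return frozenset(name for bit, name in _FLAG_BITS if flag & bit)


def read_sam(path: str | Path) -> Iterator[AlignmentRecord]:
    """Stream alignment records from a SAM file (header required).

    Unmapped reads are retained with the ``unmapped`` flag so downstream
    operations can filter them explicitly.  Malformed lines raise an error
    naming the offending line.
    """
    # pysam tolerates some truncation silently, so validate field counts first.
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.startswith("@") or not line.strip():
                continue
            nfields = line.rstrip("\n").count("\t") + 1
            if nfields < 11:
                raise ValueError(f"line {lineno}: expected ≥11 fields, got {nfields}")
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            cigar = tuple(
                ("MIDNSHP=X"[op], ln) for op, ln in (aln.cigartuples or ())
            )
            yield AlignmentRecord(
                query_name=aln.query_name,
                reference_name=aln.reference_name or "*",
                pos=max(aln.reference_start, -1) if aln.reference_start is not None else -1,
                mate_pos=aln.next_reference_start if aln.next_reference_start is not None else -1,
                template_length=aln.template_length,
                flags=_flags_from_int(aln.flag),
                cigar=cigar,
            )


def fragments_from_sam(
    records: Iterable[AlignmentRecord],
) -> Iterator[tuple[str, int, int]]:
    """Yield (reference_name, start, insert_length) per proper pair.

    Each pair contributes exactly once, through its leftmost mate
    (positive TLEN); unmapped and non-proper alignments are skipped.
    """
    for rec in records:
        if rec.is_leftmost_mate:
            yield rec.reference_name, rec.pos, rec.template_length


def rng_for_stage(seed: int, stage: str) -> np.random.Generator:
    """Derive a stage-specific random generator from the global seed.

    The stage name is hashed (CRC32, stable across runs and platforms) and
    spawned into the seed sequence, so every stage sees an independent,
    reproducible stream.
    """
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(stage.encode())]))


def load_yaml(path: str | Path) -> dict:
    with open(path) as handle:
        data = yaml.safe_load(handle)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a YAML mapping at top level")
    return data


def dump_yaml(data: dict, path: str | Path) -> None:
    with open(path, "w") as handle:
        yaml.safe_dump(data, handle, sort_keys=False)


@dataclass
class RunConfig:
    """Global run configuration: one seed plus per-stage paths/overrides."""

    seed: int
    paths: dict[str, str] = field(default_factory=dict)
    overrides: dict = field(default_factory=dict)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        data = load_yaml(path)
        if "seed" not in data:
            raise ValueError(f"{path}: config must define a seed")
        return cls(
            seed=int(data["seed"]),
            paths=dict(data.get("paths", {})),
            overrides=dict(data.get("overrides", {})),
        )

    def save(self, path: str | Path) -> None:
        dump_yaml({"seed": self.seed, "paths": self.paths, "overrides": self.overrides}, path)
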