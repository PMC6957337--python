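"""Synthetic genome cohorts and stranded paired-end RNA-seq libraries.

Two generators back the whole pipeline:

* **Cohort generator** — genomes carrying one of the four natural toxTA
  allele structures (intact, 178 nt toxT-internal deletion, 306 nt
  promoter-spanning deletion, 1015 nt whole-operon deletion replaced by
  87 nt of novel sequence), diverged from the reference by neutral point
  substitutions.  Substitutions inside the *toxA* CDS follow a purifying
  scheme: nonsynonymous proposals are accepted with probability ω
  (packaged default ω = 0.037, the antitoxin's estimated dN/dS).

* **Read simulator** — a two-promoter operon model (CRP-S promoter induced
  ~10-fold by competence, internal P2 promoter repressed by antitoxin)
  plus a background gene set spanning the competence (CRP-S), CRP-N, purR,
  tryptophan, tRNA and ribosomal regulons.  Transcript molecule counts are
  Poisson; fragments are sampled mass-proportionally with lognormal insert
  sizes (batch-specific parameters) and emitted as FASTQ pairs plus a truth
  SAM with exact POS/TLEN on the strain-specific reference.  An optional
  Poisson cleavage process cuts transcripts before fragmentation, the
  simulated analogue of nonspecific toxin ribonuclease activity.

The packaged promoter rates are calibrated (see ``calibrate_promoters``)
so the full simulate→count→normalize stack reproduces the study's printed
anchors: ~10-fold wildtype induction of *toxT* at t = 30, 9-fold elevated
baseline in the antitoxin deletion, and ~3-fold attenuated interior
coverage in the double deletion.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .io import SequenceRecord, dump_yaml, load_yaml, revcomp, rng_for_stage
from .reference import GENOTYPES, OperonModel, codon_table, load_reference

REGULONS = ("CRP-N", "CRP-S", "purR", "trp", "tRNA", "ribosomal", "other")

#: Per-allele composition of the published 181-genome cohort, reconciled so
#: that the whole-cohort totals match the printed 181 genomes and 162
#: recognizable antitoxin genes alongside the printed per-deletion counts.
PUBLISHED_COMPOSITION = {
    "intact": 20,
    "del_toxT_internal": 97,
    "del_promoters": 45,
    "del_complete": 19,
}

#: Antitoxin dN/dS used by the purifying-selection scheme.
DEFAULT_OMEGA = 0.037


def _data_path(name: str) -> Path:
    return Path(str(importlib.resources.files("toxta") / "data" / name))


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass
class PromoterParams:
    """Promoter activities of the two-promoter operon model.

    Rates are expected transcript molecules per library (arbitrary units).
    The CRP-S promoter output is ``basal × induction[t] × modifier[genotype]``
    with induction pinned to 1 for genotypes listed in ``induction_blocked``
    (Δcrp, Δsxy).  P2 output is genotype-dependent and time-invariant.
    """

    crp_s_basal: float
    crp_s_induction: dict[int, float]
    crp_s_genotype_modifier: dict[str, float]
    p2_rate: dict[str, float]
    induction_blocked: tuple[str, ...] = ("dcrp", "dsxy")

    def crp_s_output(self, genotype: str, timepoint: int) -> float:
        if genotype not in self.crp_s_genotype_modifier:
            raise ValueError(f"no packaged promoter parameters for genotype {genotype!r}")
        induction = 1.0 if genotype in self.induction_blocked else self.crp_s_induction[timepoint]
        return self.crp_s_basal * induction * self.crp_s_genotype_modifier[genotype]

    def p2_output(self, genotype: str) -> float:
        if genotype not in self.p2_rate:
            raise ValueError(f"no packaged P2 rate for genotype {genotype!r}")
        return self.p2_rate[genotype]


@dataclass
class LibraryParams:
    """Sequencing-library parameters (one batch shares insert parameters)."""

    batch_id: str
    insert_mean_log: float
    insert_sd_log: float
    read_length: int = 100
    pairs_per_library: int = 50_000
    cleavage_rate: float = 0.0  # expected cuts per kb of transcript
    min_fragment: int = 130  # size selection: shorter cleavage fragments are lost


@dataclass(frozen=True)
class BackgroundGene:
    gene_id: str
    length: int
    regulon: str
    operon_id: str
    baseline: float
    fold_change: dict[int, float]

    def expected_count(self, genotype: str, timepoint: int) -> float:
        fold = self.fold_change[timepoint]
        if genotype == "dcrp" and self.regulon in ("CRP-S", "CRP-N"):
            fold = 1.0
        elif genotype == "dsxy" and self.regulon == "CRP-S":
            fold = 1.0
        return self.baseline * fold


@dataclass(frozen=True)
class TranscriptMolecule:
    isoform: str  # "full" (CRP-S TSS) | "truncated" (P2 TSS) | gene_id
    start: int  # strain-reference coordinates
    end: int


def load_promoters(path: Optional[str | Path] = None) -> PromoterParams:
    data = load_yaml(path if path is not None else _data_path("promoters.yaml"))
    return PromoterParams(
        crp_s_basal=float(data["crp_s_basal"]),
        crp_s_induction={int(k): float(v) for k, v in data["crp_s_induction"].items()},
        crp_s_genotype_modifier={k: float(v) for k, v in data["crp_s_genotype_modifier"].items()},
        p2_rate={k: float(v) for k, v in data["p2_rate"].items()},
        induction_blocked=tuple(data.get("induction_blocked", ("dcrp", "dsxy"))),
    )


def load_library_defaults(path: Optional[str | Path] = None) -> dict:
    return load_yaml(path if path is not None else _data_path("libraries.yaml"))


def make_library_params(
    genotype: str,
    timepoint: int,
    batch_id: str = "batch1",
    pairs_per_library: int = 50_000,
    defaults: Optional[dict] = None,
    cleavage_rate: Optional[float] = None,
) -> LibraryParams:
    """Assemble LibraryParams from the packaged batch/cleavage defaults."""
    d = defaults if defaults is not None else load_library_defaults()
    batch = d["batches"][batch_id]
    if cleavage_rate is None:
        cleavage_rate = float(d.get("cleavage_rate", {}).get(genotype, {}).get(str(timepoint), 0.0))
    return LibraryParams(
        batch_id=batch_id,
        insert_mean_log=float(batch["insert_mean_log"]),
        insert_sd_log=float(batch["insert_sd_log"]),
        read_length=int(d.get("read_length", 100)),
        pairs_per_library=pairs_per_library,
        cleavage_rate=cleavage_rate,
        min_fragment=int(d.get("min_fragment", 130)),
    )


def load_background(path: Optional[str | Path] = None) -> list[BackgroundGene]:
    data = load_yaml(path if path is not None else _data_path("background_genes.yaml"))
    genes = []
    for g in data["genes"]:
        genes.append(
            BackgroundGene(
                gene_id=g["gene_id"],
                length=int(g["length"]),
                regulon=g["regulon"],
                operon_id=g.get("operon_id", g["gene_id"]),
                baseline=float(g["baseline"]),
                fold_change={int(k): float(v) for k, v in g["fold_change"].items()},
            )
        )
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate background gene ids")
    return genes


# ---------------------------------------------------------------------------
# Cohort generator
# ---------------------------------------------------------------------------


def mutate_sequence(
    seq: str,
    rate: float,
    rng: np.random.Generator,
    omega: float = 1.0,
    coding: Sequence[tuple[int, int]] = (),
) -> str:
    """Apply point substitutions at a per-site rate.

    Within ``coding`` intervals (in-frame, length divisible by 3) a proposed
    substitution that changes the encoded amino acid is accepted with
    probability ``omega``; proposals creating stop codons are rejected.
    Outside coding intervals all proposals are accepted (neutral).
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("substitution rate must be in [0, 1]")
    table = codon_table()
    bases = "ACGT"
    out = list(seq)
    sites = np.flatnonzero(rng.random(len(seq)) < rate)
    # draw all proposals up front for determinism-friendly vectorization
    proposals = rng.integers(0, 3, size=len(sites))
    accepts = rng.random(len(sites))
    for site, prop, acc in zip(sites, proposals, accepts):
        old = out[site]
        if old not in bases:
            continue
        new = [b for b in bases if b != old][prop]
        region = next((c for c in coding if c[0] <= site < c[1]), None)
        if region is not None:
            cs = region[0] + (site - region[0]) // 3 * 3
            old_codon = "".join(out[cs : cs + 3])
            new_codon = old_codon[: site - cs] + new + old_codon[site - cs + 1 :]
            if table.get(new_codon, "X") == "*":
                continue  # nonsense substitutions are never accepted
            if table.get(new_codon) != table.get(old_codon) and acc > omega:
                continue  # purifying selection on nonsynonymous changes
        out[site] = new
    return "".join(out)


def _toxa_interval_in_allele(model: OperonModel, allele_id: str) -> Optional[tuple[int, int]]:
    """toxA CDS coordinates within an allele's window sequence, if present."""
    allele = model.alleles[allele_id]
    ws, _ = model.window
    a_s, a_e = model.toxA_cds
    d_s, d_e = allele.deleted_interval
    if allele.deletion_length and not (d_e <= a_s or d_s >= a_e):
        return None  # toxA hit by the deletion (whole-operon allele)
    shift = 0
    if allele.deletion_length and d_e <= a_s:
        shift = allele.deletion_length - len(allele.replacement)
    return (a_s - ws - shift, a_e - ws - shift)


def generate_cohort(
    model: OperonModel,
    composition: dict[str, int],
    divergence: float,
    seed: int,
    omega: float = DEFAULT_OMEGA,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Generate one genome window per requested allele slot plus a truth table."""
    from .reference import apply_allele

    if not composition or sum(composition.values()) == 0:
        raise ValueError("cohort composition is empty")
    if not 0.0 <= divergence <= 0.2:
        raise ValueError("divergence must be in [0, 0.2]")
    rng = rng_for_stage(seed, "generate_cohort")
    records: list[SequenceRecord] = []
    truth_rows = []
    idx = 0
    for allele_id in sorted(composition):
        count = composition[allele_id]
        if count < 0:
            raise ValueError(f"negative count for allele {allele_id!r}")
        base_seq = apply_allele(model, allele_id)
        coding = _toxa_interval_in_allele(model, allele_id)
        for _ in range(count):
            gid = f"g{idx:04d}"
            idx += 1
            seq = mutate_sequence(
                base_seq, divergence, rng, omega=omega, coding=[coding] if coding else []
            )
            records.append(SequenceRecord(gid, seq))
            truth_rows.append({"genome_id": gid, "allele_id": allele_id})
    truth = pd.DataFrame(truth_rows)
    return records, truth


def simulate_cds_cohort(
    model: OperonModel,
    n: int,
    divergence: float,
    seed: int,
    omega: float = DEFAULT_OMEGA,
) -> list[SequenceRecord]:
    """Simulate antitoxin CDS variants under the purifying scheme.

    Each variant descends independently from the reference *toxA* CDS, so at
    substitution attempt rate *d* per site the mean pairwise distance is
    roughly ``2 d (f_syn + ω f_nonsyn)`` before multiple-hit correction.
    """
    rng = rng_for_stage(seed, "simulate_cds_cohort")
    cds = model.cds_seq("toxA")
    out = []
    for i in range(n):
        seq = mutate_sequence(cds, divergence, rng, omega=omega, coding=[(0, len(cds))])
        out.append(SequenceRecord(f"toxA_{i:03d}", seq))
    return out


# ---------------------------------------------------------------------------
# Strain-specific composite reference (operon locus + background genes)
# ---------------------------------------------------------------------------

_SPACER = 50


def gene_sequence(gene_id: str, length: int) -> str:
    """Deterministic background-gene sequence (independent of library seed)."""
    import zlib

    rng = np.random.default_rng(np.random.SeedSequence([0xB6, zlib.crc32(gene_id.encode())]))
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


@dataclass
class StrainReference:
    """Composite per-strain reference: operon locus followed by background genes."""

    record: SequenceRecord
    annotation: pd.DataFrame  # gene_id, start, end, strand, operon_id, regulon
    genotype: str
    locus_length: int

    @property
    def length(self) -> int:
        return len(self.record.sequence)


def build_strain_transcriptome(
    model: OperonModel,
    genotype: str,
    background: Sequence[BackgroundGene],
) -> StrainReference:
    """Strain-specific reference sequence plus its gene annotation table."""
    locus = model.strain_locus(genotype)
    lift = model.liftover(genotype)
    parts = [locus]
    rows = []

    def lifted_interval(iv: tuple[int, int]) -> Optional[tuple[int, int]]:
        """Intersect a wildtype interval with the retained coordinate set."""
        s, e = iv
        dele = model.genotype_deletions[genotype]
        if dele is None:
            return iv
        ds, de = dele
        spans = [(a, b) for a, b in ((min(s, ds), min(e, ds)), (max(s, de), max(e, de))) if b > a]
        if not spans:
            return None
        ls = lift.wt_to_strain(spans[0][0])
        return (ls, ls + sum(b - a for a, b in spans))

    for gene, iv in (("toxT", model.toxT_cds), ("toxA", model.toxA_cds)):
        lifted = lifted_interval(iv)
        if lifted is None or lifted[1] - lifted[0] <= 0:
            continue
        rows.append(
            {
                "gene_id": gene,
                "start": lifted[0],
                "end": lifted[1],
                "strand": "+",
                "operon_id": "toxTA",
                "regulon": "CRP-S",
                "length": iv[1] - iv[0],
            }
        )

    offset = len(locus)
    for g in background:
        offset += _SPACER
        parts.append(gene_sequence(f"spacer_{g.gene_id}", _SPACER))
        parts.append(gene_sequence(g.gene_id, g.length))
        rows.append(
            {
                "gene_id": g.gene_id,
                "start": offset,
                "end": offset + g.length,
                "strand": "+",
                "operon_id": g.operon_id,
                "regulon": g.regulon,
                "length": g.length,
            }
        )
        offset += g.length

    record = SequenceRecord(f"ref_{genotype}", "".join(parts))
    annot = pd.DataFrame(rows)
    return StrainReference(record=record, annotation=annot, genotype=genotype, locus_length=len(locus))


# ---------------------------------------------------------------------------
# Transcription, cleavage, fragment sampling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IsoformSpec:
    name: str
    start: int  # strain coordinates
    end: int
    rate: float  # expected molecules


def operon_isoform_rates(
    model: OperonModel,
    promoters: PromoterParams,
    genotype: str,
    timepoint: int,
    n_cells: float = 1.0,
) -> list[IsoformSpec]:
    """Expected molecule counts and strain-coordinate spans of both isoforms."""
    if genotype not in model.genotype_deletions:
        raise ValueError(f"unknown genotype {genotype!r}")
    lift = model.liftover(genotype)
    end = lift.wt_to_strain(model.transcript_end)
    if end is None:  # transcript end inside the deletion: fall back to junction
        end = lift.wt_to_strain(model.genotype_deletions[genotype][1])
    specs = []
    full_start = lift.wt_to_strain(model.crp_s_promoter)
    if full_start is not None:
        specs.append(
            IsoformSpec("full", full_start, end, promoters.crp_s_output(genotype, timepoint) * n_cells)
        )
    p2_start = lift.wt_to_strain(model.p2_tss)
    if p2_start is not None:
        specs.append(IsoformSpec("truncated", p2_start, end, promoters.p2_output(genotype) * n_cells))
    return specs


def simulate_transcripts(
    model: OperonModel,
    promoters: PromoterParams,
    genotype: str,
    timepoint: int,
    n_cells: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> list[TranscriptMolecule]:
    """Draw operon transcript molecules (Poisson counts per isoform)."""
    rng = seed if isinstance(seed, np.random.Generator) else rng_for_stage(seed, "transcripts")
    molecules = []
    for spec in operon_isoform_rates(model, promoters, genotype, timepoint, n_cells):
        for _ in range(rng.poisson(spec.rate)):
            molecules.append(TranscriptMolecule(spec.name, spec.start, spec.end))
    return molecules


def apply_cleavage(
    molecules: Sequence[TranscriptMolecule],
    cleavage_rate: float,
    rng: np.random.Generator,
    min_fragment: int = 130,
) -> list[TranscriptMolecule]:
    """Cut each molecule at Poisson(rate × length/1000) uniform positions.

    Sub-fragments shorter than ``min_fragment`` are discarded (size
    selection removes them from the library).
    """
    if cleavage_rate < 0:
        raise ValueError("cleavage rate must be ≥ 0")
    if cleavage_rate == 0:
        return list(molecules)
    out = []
    for mol in molecules:
        length = mol.end - mol.start
        ncuts = rng.poisson(cleavage_rate * length / 1000.0)
        if ncuts == 0:
            out.append(mol)
            continue
        cuts = np.sort(rng.integers(1, length, size=ncuts))
        bounds = np.concatenate([[0], cuts, [length]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            if b - a >= min_fragment:
                out.append(TranscriptMolecule(mol.isoform, mol.start + int(a), mol.start + int(b)))
    return out


def background_molecules(
    ref: StrainReference,
    background: Sequence[BackgroundGene],
    genotype: str,
    timepoint: int,
    rng: np.random.Generator,
    n_cells: float = 1.0,
) -> list[TranscriptMolecule]:
    annot = ref.annotation.set_index("gene_id")
    out = []
    for g in background:
        row = annot.loc[g.gene_id]
        count = rng.poisson(g.expected_count(genotype, timepoint) * n_cells)
        for _ in range(count):
            out.append(TranscriptMolecule(g.gene_id, int(row["start"]), int(row["end"])))
    return out


def draw_fragments(
    starts: np.ndarray,
    ends: np.ndarray,
    n_pairs: int,
    lib: LibraryParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Sample fragments mass-proportionally from molecules.

    Returns (molecule_index, fragment_start, insert_length, n_resampled).
    Inserts are lognormal, truncated to the molecule length; draws shorter
    than the read length are resampled (the count is returned).
    """
    if n_pairs <= 0:
        raise ValueError("pairs_per_library must be > 0")
    lengths = ends - starts
    eligible = np.flatnonzero(lengths >= lib.read_length)
    if eligible.size == 0:
        raise ValueError("no molecule long enough to sequence")
    w = lengths[eligible].astype(float)
    idx = eligible[rng.choice(eligible.size, size=n_pairs, p=w / w.sum())]
    mol_len = lengths[idx]
    insert = np.rint(rng.lognormal(lib.insert_mean_log, lib.insert_sd_log, n_pairs)).astype(int)
    n_resampled = 0
    for _ in range(100):
        bad = insert < lib.read_length
        if not bad.any():
            break
        n_resampled += int(bad.sum())
        insert[bad] = np.rint(
            rng.lognormal(lib.insert_mean_log, lib.insert_sd_log, int(bad.sum()))
        ).astype(int)
    insert = np.maximum(insert, lib.read_length)  # safety clamp after resampling
    insert = np.minimum(insert, mol_len)
    offset = rng.integers(0, mol_len - insert + 1)
    return idx, starts[idx] + offset, insert, n_resampled


@dataclass
class LibraryResult:
    library_id: str
    reference: StrainReference
    fragment_start: np.ndarray
    insert: np.ndarray
    n_resampled: int
    r1_path: Optional[Path] = None
    r2_path: Optional[Path] = None
    sam_path: Optional[Path] = None


def simulate_library(
    model: OperonModel,
    promoters: PromoterParams,
    background: Sequence[BackgroundGene],
    genotype: str,
    timepoint: int,
    lib: LibraryParams,
    seed: int | np.random.Generator,
    library_id: str = "lib",
    out_prefix: Optional[str | Path] = None,
    n_cells: float = 1.0,
) -> LibraryResult:
    """Simulate one stranded paired-end library (FASTQ pair + truth SAM)."""
    rng = seed if isinstance(seed, np.random.Generator) else rng_for_stage(seed, f"library:{library_id}")
    ref = build_strain_transcriptome(model, genotype, background)
    molecules = simulate_transcripts(model, promoters, genotype, timepoint, n_cells, rng)
    molecules += background_molecules(ref, background, genotype, timepoint, rng, n_cells)
    molecules = apply_cleavage(molecules, lib.cleavage_rate, rng, lib.min_fragment)
    starts = np.array([m.start for m in molecules])
    ends = np.array([m.end for m in molecules])
    _, frag_start, insert, n_resampled = draw_fragments(
        starts, ends, lib.pairs_per_library, lib, rng
    )
    result = LibraryResult(library_id, ref, frag_start, insert, n_resampled)
    if out_prefix is not None:
        out_prefix = Path(out_prefix)
        out_prefix.parent.mkdir(parents=True, exist_ok=True)
        result.r1_path = out_prefix.with_suffix(".R1.fastq")
        result.r2_path = out_prefix.with_suffix(".R2.fastq")
        result.sam_path = out_prefix.with_suffix(".sam")
        _write_library(result, lib)
    return result


def _write_library(res: LibraryResult, lib: LibraryParams) -> None:
    seq = res.reference.record.sequence
    rl = lib.read_length
    qual = "I" * rl
    order = np.argsort(res.fragment_start, kind="stable")
    with open(res.r1_path, "w") as r1, open(res.r2_path, "w") as r2:
        for rank in range(len(order)):
            i = order[rank]
            fs, ins = int(res.fragment_start[i]), int(res.insert[i])
            name = f"{res.library_id}:{rank}"
            fwd = seq[fs : fs + rl]
            rev = revcomp(seq[fs + ins - rl : fs + ins])
            r1.write(f"@{name}/1\n{fwd}\n+\n{qual}\n")
            r2.write(f"@{name}/2\n{rev}\n+\n{qual}\n")
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": res.reference.record.id, "LN": res.reference.length}],
        "PG": [{"ID": "toxta-sim", "PN": "toxta-sim"}],
    }
    records = []
    for rank in range(len(order)):
        i = order[rank]
        fs, ins = int(res.fragment_start[i]), int(res.insert[i])
        name = f"{res.library_id}:{rank}"
        records.append((fs, 99, name, fs + ins - rl, ins))
        records.append((fs + ins - rl, 147, name, fs, -ins))
    records.sort(key=lambda r: (r[0], r[2]))
    with pysam.AlignmentFile(str(res.sam_path), "w", header=header) as sam:
        for pos, flag, name, mate_pos, tlen in records:
            a = pysam.AlignedSegment(sam.header)
            a.query_name = name
            a.flag = flag
            a.reference_id = 0
            a.reference_start = pos
            a.mapping_quality = 60
            a.cigarstring = f"{rl}M"
            a.next_reference_id = 0
            a.next_reference_start = mate_pos
            a.template_length = tlen
            a.query_sequence = seq[pos : pos + rl]
            a.query_qualities = pysam.qualitystring_to_array(qual)
            sam.write(a)


def simulate_experiment(
    outdir: str | Path,
    conditions: Iterable[dict],
    seed: int,
    model: Optional[OperonModel] = None,
    promoters: Optional[PromoterParams] = None,
    background: Optional[Sequence[BackgroundGene]] = None,
    pairs_per_library: int = 50_000,
    library_defaults: Optional[dict] = None,
    n_cells: float = 50.0,
) -> pd.DataFrame:
    """Simulate a set of libraries and write a manifest.

    ``conditions`` rows are dicts with keys genotype, timepoint, replicate,
    and optionally batch and cleavage_rate.  ``n_cells`` scales every
    transcript rate: a library samples a pool of transcripts from many
    cells, so replicate-to-replicate variation is dominated by fragment
    sampling rather than per-molecule Poisson noise.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = model if model is not None else load_reference()
    promoters = promoters if promoters is not None else load_promoters()
    background = background if background is not None else load_background()
    defaults = library_defaults if library_defaults is not None else load_library_defaults()
    rows = []
    for cond in conditions:
        genotype, timepoint = cond["genotype"], int(cond["timepoint"])
        replicate = int(cond.get("replicate", 1))
        batch = cond.get("batch", "batch1")
        lib_id = f"{genotype}_t{timepoint}_r{replicate}"
        lib = make_library_params(
            genotype,
            timepoint,
            batch_id=batch,
            pairs_per_library=int(cond.get("pairs", pairs_per_library)),
            defaults=defaults,
            cleavage_rate=cond.get("cleavage_rate"),
        )
        res = simulate_library(
            model,
            promoters,
            background,
            genotype,
            timepoint,
            lib,
            seed=rng_for_stage(seed, f"library:{lib_id}"),
            library_id=lib_id,
            out_prefix=outdir / lib_id,
            n_cells=float(cond.get("n_cells", n_cells)),
        )
        rows.append(
            {
                "library_id": lib_id,
                "genotype": genotype,
                "timepoint": timepoint,
                "replicate": replicate,
                "batch": batch,
                "r1": str(res.r1_path),
                "r2": str(res.r2_path),
                "sam": str(res.sam_path),
                "reference_id": res.reference.record.id,
                "seed": seed,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    return manifest


# ---------------------------------------------------------------------------
# Calibration: expected fragment statistics under the sampling model
# ---------------------------------------------------------------------------


def insert_pmf(lib: LibraryParams, smax: int = 3000) -> tuple[np.ndarray, np.ndarray]:
    """Discretized lognormal insert distribution, conditioned on ≥ read length."""
    from scipy.stats import lognorm

    sizes = np.arange(lib.read_length, smax + 1)
    dist = lognorm(s=lib.insert_sd_log, scale=np.exp(lib.insert_mean_log))
    cdf = dist.cdf(sizes + 0.5)
    pmf = np.diff(np.concatenate([[dist.cdf(lib.read_length - 0.5)], cdf]))
    return sizes, pmf / pmf.sum()


def _p_midpoint_in(L: int, a: float, b: float, sizes: np.ndarray, pmf: np.ndarray) -> float:
    """P(fragment midpoint lies in molecule-relative interval [a, b))."""
    s = np.minimum(sizes, L)
    lo = np.maximum(np.ceil(a - s // 2), 0)
    hi = np.minimum(np.floor(b - 1 - s // 2), L - s)
    frac = np.clip(hi - lo + 1, 0, None) / (L - s + 1)
    return float(np.sum(pmf * frac))


def _p_covers(L: int, x: float, sizes: np.ndarray, pmf: np.ndarray) -> float:
    """P(fragment covers molecule-relative position x)."""
    s = np.minimum(sizes, L)
    lo = np.maximum(x - s + 1, 0)
    hi = np.minimum(x, L - s)
    frac = np.clip(hi - lo + 1, 0, None) / (L - s + 1)
    return float(np.sum(pmf * frac))


def expected_gene_weight(
    isoforms: Sequence[IsoformSpec],
    gene: tuple[int, int],
    lib: LibraryParams,
) -> float:
    """Σ rate × length × P(midpoint in gene): the expected, depth- and
    normalization-invariant contribution of the isoform set to a gene's
    fragment count."""
    sizes, pmf = insert_pmf(lib)
    total = 0.0
    for iso in isoforms:
        L = iso.end - iso.start
        if L < lib.read_length:
            continue
        a, b = gene[0] - iso.start, gene[1] - iso.start
        total += iso.rate * L * _p_midpoint_in(L, a, b, sizes, pmf)
    return total


def expected_position_weight(
    isoforms: Sequence[IsoformSpec], pos: int, lib: LibraryParams
) -> float:
    """Σ rate × length × P(fragment covers pos): expected normalized coverage."""
    sizes, pmf = insert_pmf(lib)
    total = 0.0
    for iso in isoforms:
        L = iso.end - iso.start
        if L < lib.read_length:
            continue
        total += iso.rate * L * _p_covers(L, pos - iso.start, sizes, pmf)
    return total


def calibrate_promoters(
    model: OperonModel,
    lib: LibraryParams,
    crp_s_basal: float = 50.0,
    induction_30: float = 10.0,
    p2_repressed: float = 2.0,
    fold_dtoxA: float = 9.0,
    attenuation_dtoxTA: float = 3.0,
) -> dict:
    """Solve for the packaged derepressed-P2 rate and ΔtoxTA attenuation.

    The derepressed P2 rate makes the expected normalized *toxT* fragment
    count of the antitoxin deletion at t = 0 exactly ``fold_dtoxA`` times
    wildtype.  The ΔtoxTA multiplier makes expected normalized coverage at
    operon position +100 at t = 30 exactly 1/``attenuation_dtoxTA`` of
    wildtype.  Expectations integrate over the library's insert-size
    distribution, so they account for transcript-geometry differences
    between strain constructs.
    """
    base = PromoterParams(
        crp_s_basal=crp_s_basal,
        crp_s_induction={0: 1.0, 10: 1.5, 30: induction_30, 100: induction_30},
        crp_s_genotype_modifier={g: 1.0 for g in GENOTYPES},
        p2_rate={g: p2_repressed for g in GENOTYPES},
    )
    toxT = model.toxT_cds

    def gene_weight(genotype: str, timepoint: int, params: PromoterParams) -> float:
        # toxT is intact in wildtype and dtoxA, the only genotypes used here
        lift = model.liftover(genotype)
        gene = (lift.wt_to_strain(toxT[0]), lift.wt_to_strain(toxT[1] - 1) + 1)
        isoforms = operon_isoform_rates(model, params, genotype, timepoint)
        return expected_gene_weight(isoforms, gene, lib)

    w_wt = gene_weight("wildtype", 0, base)
    iso_full = [s for s in operon_isoform_rates(model, base, "dtoxA", 0) if s.name == "full"]
    iso_trunc = [s for s in operon_isoform_rates(model, base, "dtoxA", 0) if s.name == "truncated"]
    lift = model.liftover("dtoxA")
    gene_dtoxA = (lift.wt_to_strain(toxT[0]), lift.wt_to_strain(toxT[1] - 1) + 1)
    w_full = expected_gene_weight(
        [IsoformSpec("full", iso_full[0].start, iso_full[0].end, 1.0)], gene_dtoxA, lib
    )
    w_trunc = expected_gene_weight(
        [IsoformSpec("truncated", iso_trunc[0].start, iso_trunc[0].end, 1.0)], gene_dtoxA, lib
    )
    p2_derepressed = (fold_dtoxA * w_wt - crp_s_basal * w_full) / w_trunc

    # ΔtoxTA attenuation at position +100, t = 30
    pos_wt = model.toxT_start + 100
    w_pos_wt = expected_position_weight(
        operon_isoform_rates(model, base, "wildtype", 30), pos_wt, lib
    )
    lift_ta = model.liftover("dtoxTA")
    pos_ta = lift_ta.wt_to_strain(pos_wt)
    w_pos_ta_unit = expected_position_weight(
        operon_isoform_rates(model, base, "dtoxTA", 30), pos_ta, lib
    )
    attenuation_modifier = w_pos_wt / attenuation_dtoxTA / w_pos_ta_unit

    return {
        "p2_derepressed": float(p2_derepressed),
        "dtoxTA_modifier": float(attenuation_modifier),
        "p2_dtoxTA": float(p2_repressed * attenuation_modifier),
    }
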