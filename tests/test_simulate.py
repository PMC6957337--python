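"""Generators: cohort divergence model, transcription, cleavage, libraries."""

import numpy as np
import pytest

from toxta.io import read_fasta, read_sam, revcomp, rng_for_stage
from toxta.reference import apply_allele
from toxta.simulate import (
    TranscriptMolecule,
    apply_cleavage,
    build_strain_transcriptome,
    draw_fragments,
    generate_cohort,
    insert_pmf,
    make_library_params,
    mutate_sequence,
    operon_isoform_rates,
    simulate_library,
    simulate_transcripts,
)

# ---------------------------------------------------------------- cohort


def test_zero_divergence_identity(model):
    records, truth = generate_cohort(model, {"intact": 1}, 0.0, seed=3)
    assert records[0].sequence == model.window_seq
    assert truth.iloc[0]["allele_id"] == "intact"


def test_figure_composition_lengths(model):
    """The literal figure composition: per-class genome lengths differ from
    the reference window by -178, -306, -1015+87, and 0 nt."""
    comp = {"del_toxT_internal": 97, "del_promoters": 45, "del_complete": 19, "intact": 24}
    records, truth = generate_cohort(model, comp, 0.0, seed=4)
    assert len(records) == 185
    ref_len = len(model.window_seq)
    expected = {
        "intact": ref_len,
        "del_toxT_internal": ref_len - 178,
        "del_promoters": ref_len - 306,
        "del_complete": ref_len - 1015 + 87,
    }
    for rec, allele in zip(records, truth["allele_id"]):
        assert len(rec.sequence) == expected[allele]


def test_cohort_divergence_matches_expectation(model):
    """Mean pairwise difference of intact genomes at neutral sites matches
    the closed-form expectation of the substitution scheme within 3 SE."""
    d = 0.05
    records, _ = generate_cohort(model, {"intact": 30}, d, seed=5)
    ws = model.window[0]
    # neutral flank: downstream of the operon, upstream of nothing coding
    lo, hi = model.toxA_cds[1] - ws, len(model.window_seq)
    seqs = [np.frombuffer(r.sequence[lo:hi].encode(), dtype=np.uint8) for r in records]
    diffs = []
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            diffs.append((seqs[i] != seqs[j]).mean())
    # two independent lineages: differ if exactly one site mutated, or both
    # mutated to different bases
    p_site = 2 * d * (1 - d) + d * d * (2 / 3)
    n_sites = hi - lo
    se = np.sqrt(p_site * (1 - p_site) / n_sites) / np.sqrt(len(diffs) / 30)
    assert abs(np.mean(diffs) - p_site) < 3 * se


def test_empty_composition_error(model):
    with pytest.raises(ValueError, match="empty"):
        generate_cohort(model, {}, 0.0, seed=1)


def test_purifying_scheme_suppresses_nonsynonymous(model):
    """At ω=0 every accepted toxA change is synonymous."""
    from Bio.Seq import Seq

    cds = model.cds_seq("toxA")
    rng = np.random.default_rng(0)
    mutated = mutate_sequence(cds, 0.1, rng, omega=0.0, coding=[(0, len(cds))])
    assert mutated != cds  # substitutions did happen
    assert str(Seq(mutated).translate()) == str(Seq(cds).translate())


# ----------------------------------------------------------- transcription


def test_transcript_rate_passthrough(model, promoters):
    """Wildtype t=0 full-isoform count is Poisson around the basal rate."""
    counts = []
    for seed in range(40):
        mols = simulate_transcripts(model, promoters, "wildtype", 0, 1.0, seed=seed)
        counts.append(sum(m.isoform == "full" for m in mols))
    mean = np.mean(counts)
    assert abs(mean - promoters.crp_s_basal) < 3 * np.sqrt(promoters.crp_s_basal / 40)


def test_regulatory_knockouts_block_induction(model, promoters):
    """Δcrp/Δsxy hold CRP-S output at basal regardless of timepoint."""
    for genotype in ("dcrp", "dsxy"):
        r0 = operon_isoform_rates(model, promoters, genotype, 0)
        r30 = operon_isoform_rates(model, promoters, genotype, 30)
        assert {s.name: s.rate for s in r0} == {s.name: s.rate for s in r30}
        assert [s.rate for s in r0 if s.name == "full"] == [promoters.crp_s_basal]


def test_dtoxA_baseline_elevation_expectation(model, promoters):
    """Packaged P2 derepression puts the expected normalized toxT fragment
    count of ΔtoxA at 9x wildtype at t=0 (insert-geometry aware)."""
    from toxta.simulate import expected_gene_weight

    lib = make_library_params("wildtype", 0)
    weights = {}
    for genotype in ("wildtype", "dtoxA"):
        lift = model.liftover(genotype)
        gene = (lift.wt_to_strain(model.toxT_cds[0]), lift.wt_to_strain(model.toxT_cds[1] - 1) + 1)
        isoforms = operon_isoform_rates(model, promoters, genotype, 0)
        weights[genotype] = expected_gene_weight(isoforms, gene, lib)
    assert weights["dtoxA"] / weights["wildtype"] == pytest.approx(9, rel=0.01)


def test_dtoxT_lacks_truncated_isoform(model, promoters):
    names = [s.name for s in operon_isoform_rates(model, promoters, "dtoxT", 0)]
    assert names == ["full"]  # P2 is deleted in this construct


def test_unknown_genotype_errors(model, promoters):
    with pytest.raises(ValueError):
        simulate_transcripts(model, promoters, "dmystery", 0, seed=1)


# --------------------------------------------------------------- cleavage


def test_cleavage_rate_zero_identity():
    mols = [TranscriptMolecule("full", 0, 1000)]
    rng = np.random.default_rng(0)
    assert apply_cleavage(mols, 0.0, rng) == mols


def test_cleavage_mean_fragment_length_analytic():
    """Mean surviving fragment length tracks L/(1+rL/1000) and decreases
    with the cleavage rate."""
    L = 2000
    rng = np.random.default_rng(1)
    means = []
    for rate in (0.5, 2.0, 8.0):
        frags = apply_cleavage(
            [TranscriptMolecule("m", 0, L)] * 3000, rate, rng, min_fragment=1
        )
        lengths = np.array([f.end - f.start for f in frags])
        means.append(lengths.mean())
        analytic = L / (1 + rate * L / 1000)
        assert lengths.mean() == pytest.approx(analytic, rel=0.05)
    assert means[0] > means[1] > means[2]


def test_cleavage_single_cut_splits_molecule():
    rng = np.random.default_rng(2)
    frags = apply_cleavage([TranscriptMolecule("m", 100, 400)], 1e3, rng, min_fragment=1)
    assert sum(f.end - f.start for f in frags) == 300
    assert all(f.start >= 100 and f.end <= 400 for f in frags)


def test_cleavage_discards_short_fragments():
    rng = np.random.default_rng(3)
    frags = apply_cleavage([TranscriptMolecule("m", 0, 300)] * 500, 10.0, rng, min_fragment=140)
    assert all(f.end - f.start >= 140 for f in frags)


# ---------------------------------------------------------------- library


def test_insert_distribution_matches_lognormal(model, promoters):
    """With no cleavage and a long template, |TLEN| follows the generating
    lognormal (KS distance at n=50k)."""
    from scipy.stats import kstest, lognorm

    lib = make_library_params("wildtype", 0, pairs_per_library=50_000)
    L = 50_000
    starts, ends = np.array([0]), np.array([L])
    rng = np.random.default_rng(7)
    _, _, insert, _ = draw_fragments(starts, ends, lib.pairs_per_library, lib, rng)
    dist = lognorm(s=lib.insert_sd_log, scale=np.exp(lib.insert_mean_log))
    # condition the reference CDF on insert >= read length (short draws resampled)
    p0 = dist.cdf(lib.read_length)
    stat = kstest(insert, lambda x: (dist.cdf(x) - p0) / (1 - p0)).statistic
    assert stat < 0.02
    assert abs(np.median(insert) - dist.median()) / dist.median() < 0.02


def test_cleaved_library_has_smaller_median_insert(model, promoters, background):
    lib0 = make_library_params("dtoxA", 0, pairs_per_library=15_000, cleavage_rate=0.0)
    lib1 = make_library_params("dtoxA", 0, pairs_per_library=15_000, cleavage_rate=4.0)
    r0 = simulate_library(model, promoters, background, "dtoxA", 0, lib0, seed=1, n_cells=3)
    r1 = simulate_library(model, promoters, background, "dtoxA", 0, lib1, seed=2, n_cells=3)
    assert np.median(r1.insert) < np.median(r0.insert)


def test_library_outputs_deterministic(tmp_path, model, promoters, background):
    lib = make_library_params("wildtype", 0, pairs_per_library=2000)
    paths = []
    for run in ("a", "b"):
        res = simulate_library(
            model, promoters, background, "wildtype", 0, lib,
            seed=99, library_id="det", out_prefix=tmp_path / run / "lib",
        )
        paths.append(res)
    for attr in ("r1_path", "r2_path", "sam_path"):
        b0 = getattr(paths[0], attr).read_bytes()
        b1 = getattr(paths[1], attr).read_bytes()
        assert b0 == b1


def test_truth_sam_matches_reference_exactly(tmp_path, model, promoters, background):
    """Every truth alignment maps back to an exact substring of the
    strain-specific reference (no sequencing error by default)."""
    lib = make_library_params("dtoxA", 0, pairs_per_library=1000)
    res = simulate_library(
        model, promoters, background, "dtoxA", 0, lib,
        seed=5, library_id="truth", out_prefix=tmp_path / "lib",
    )
    n = 0
    tlens = []
    for rec in read_sam(res.sam_path):
        assert rec.reference_name == res.reference.record.id
        assert rec.is_proper_pair
        tlens.append(rec.template_length)
        n += 1
    assert n == 2000  # two mates per pair
    # mates carry TLEN of equal magnitude and opposite sign
    tlens = np.array(tlens)
    assert (np.sort(tlens[tlens > 0]) == np.sort(-tlens[tlens < 0])).all()
    assert np.array_equal(np.sort(tlens[tlens > 0]), np.sort(res.insert))


def read_fastq(path):
    with open(path) as fh:
        lines = fh.read().splitlines()
    return [(lines[i][1:], lines[i + 1]) for i in range(0, len(lines), 4)]


def test_fastq_reads_are_reference_substrings(tmp_path, model, promoters, background):
    lib = make_library_params("wildtype", 0, pairs_per_library=500)
    res = simulate_library(
        model, promoters, background, "wildtype", 0, lib,
        seed=6, library_id="sub", out_prefix=tmp_path / "lib",
    )
    ref = res.reference.record.sequence
    order = np.argsort(res.fragment_start, kind="stable")
    r1 = read_fastq(res.r1_path)
    r2 = read_fastq(res.r2_path)
    for rank in range(0, 500, 25):
        i = order[rank]
        fs, ins = int(res.fragment_start[i]), int(res.insert[i])
        assert r1[rank][1] == ref[fs : fs + lib.read_length]
        assert r2[rank][1] == revcomp(ref[fs + ins - lib.read_length : fs + ins])


def test_background_counts_scale_with_depth(model, promoters, background):
    """Aggregate per-gene fragment counts scale linearly with library size."""
    ref = build_strain_transcriptome(model, "wildtype", background)
    ann = ref.annotation.set_index("gene_id")
    gene = "rpoB"
    counts = {}
    for pairs in (5000, 20000):
        lib = make_library_params("wildtype", 0, pairs_per_library=pairs)
        res = simulate_library(model, promoters, background, "wildtype", 0, lib, seed=8, n_cells=5)
        mid = res.fragment_start + res.insert // 2
        s, e = ann.loc[gene, "start"], ann.loc[gene, "end"]
        counts[pairs] = ((mid >= s) & (mid < e)).sum()
    ratio = counts[20000] / counts[5000]
    assert ratio == pytest.approx(4.0, rel=0.15)


def test_dsxy_blocks_crp_s_but_not_crp_n(background):
    """Regulon rules: Δsxy silences CRP-S induction; CRP-N still induces."""
    crp_s = next(g for g in background if g.regulon == "CRP-S")
    crp_n = next(g for g in background if g.regulon == "CRP-N")
    assert crp_s.expected_count("dsxy", 30) == crp_s.expected_count("dsxy", 0)
    assert crp_n.expected_count("dsxy", 30) > crp_n.expected_count("dsxy", 0)
    assert crp_n.expected_count("dcrp", 30) == crp_n.expected_count("dcrp", 0)
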