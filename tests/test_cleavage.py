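"""Insert-size distributions, batch-matched shift tests, k-mer scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from toxta.cleavage import (
    InsertSizeDistribution,
    batch_matched_shift_test,
    insert_size_distribution,
    kmer_depletion_scan,
    shift_time_course,
)
from toxta.simulate import make_library_params, simulate_library


def _dist(values, lib_id="a", batch="batch1"):
    return insert_size_distribution(values, lib_id, batch)


# ------------------------------------------------------------- histograms


def test_histogram_and_median():
    d = _dist([200, 200, 300])
    assert d.histogram == {200: 2, 300: 1}
    assert d.n == 3
    assert d.median == 200


def test_negative_tlen_uses_magnitude():
    d = _dist([-250, 250])
    assert d.histogram == {250: 2}


def test_oversize_inserts_discarded_and_counted():
    d = _dist([300, 5000])
    assert d.n == 1 and d.n_discarded == 1


def test_empty_library_errors():
    with pytest.raises(ValueError, match="no proper pairs"):
        _dist([])


def test_simulated_median_tracks_lognormal(model, promoters, background):
    """A full library's median insert sits at or slightly below the
    generating lognormal median: truncation to transcript length (short
    tRNAs) can only shorten inserts.  (The unconstrained sampler is held to
    a 2% median / KS check on a long template in the simulator tests.)"""
    lib = make_library_params("wildtype", 0, pairs_per_library=50_000)
    res = simulate_library(model, promoters, background, "wildtype", 0, lib, seed=21, n_cells=10)
    d = insert_size_distribution(res.insert, "wt", "batch1")
    analytic = np.exp(lib.insert_mean_log)
    assert d.median <= analytic * 1.01
    assert d.median >= analytic * 0.9


# -------------------------------------------------------------- shift test


def test_identical_distributions_null():
    rng = np.random.default_rng(0)
    vals = np.rint(rng.lognormal(5.5, 0.25, 800)).astype(int)
    a, b = _dist(vals[:400], "a"), _dist(vals[400:], "b")
    res = batch_matched_shift_test(a, b, n_perm=500, seed=1)
    assert abs(res.median_difference) < 20
    assert res.p_value > 0.01


def test_batch_mismatch_refused():
    a = _dist([200, 300], "a", "batch1")
    b = _dist([200, 300], "b", "batch2")
    with pytest.raises(ValueError, match="prepared at the same"):
        batch_matched_shift_test(a, b)


def test_cleaved_library_detected(model, promoters, background):
    """Cleaved vs uncleaved library in the same batch: negative median
    difference, p < 0.01."""
    lib0 = make_library_params("dtoxA", 0, pairs_per_library=15_000, cleavage_rate=0.0)
    lib2 = make_library_params("dtoxA", 0, pairs_per_library=15_000, cleavage_rate=2.0)
    r0 = simulate_library(model, promoters, background, "dtoxA", 0, lib0, seed=30, n_cells=5)
    r2 = simulate_library(model, promoters, background, "dtoxA", 0, lib2, seed=31, n_cells=5)
    d0 = insert_size_distribution(r0.insert, "uncleaved", "batch1")
    d2 = insert_size_distribution(r2.insert, "cleaved", "batch1")
    res = batch_matched_shift_test(d2, d0, n_perm=2000, seed=32)
    assert res.median_difference < 0
    assert res.p_value < 0.01


def test_shift_grows_with_cleavage_rate(model, promoters, background):
    meds = []
    for rate in (0.0, 1.0, 3.0):
        lib = make_library_params("dtoxA", 0, pairs_per_library=10_000, cleavage_rate=rate)
        res = simulate_library(model, promoters, background, "dtoxA", 0, lib, seed=40, n_cells=5)
        meds.append(np.median(res.insert))
    assert meds[0] > meds[1] > meds[2]


def test_shift_test_antisymmetric():
    rng = np.random.default_rng(5)
    a = _dist(np.rint(rng.lognormal(5.4, 0.25, 500)).astype(int), "a")
    b = _dist(np.rint(rng.lognormal(5.6, 0.25, 500)).astype(int), "b")
    ab = batch_matched_shift_test(a, b, n_perm=999, seed=6)
    ba = batch_matched_shift_test(b, a, n_perm=999, seed=6)
    assert ab.median_difference == -ba.median_difference
    assert ab.statistic_z == pytest.approx(-ba.statistic_z, abs=1e-9)
    assert ab.p_value < 0.05 < ba.p_value


def test_quantile_differences_consistent():
    """Quantile-difference distribution sums to ≈ 99x the mean quantile gap."""
    rng = np.random.default_rng(7)
    a = _dist(np.rint(rng.lognormal(5.4, 0.2, 2000)).astype(int), "a")
    b = _dist(np.rint(rng.lognormal(5.5, 0.2, 2000)).astype(int), "b")
    res = batch_matched_shift_test(a, b, n_perm=10, seed=8)
    assert res.quantile_differences.size == 99
    assert res.quantile_differences.sum() == pytest.approx(
        99 * res.quantile_differences.mean()
    )
    assert (res.quantile_differences < 0).mean() > 0.9


def test_null_p_values_uniform():
    """Permutation p-values are uniform under the null (KS at α=0.01)."""
    rng = np.random.default_rng(9)
    pvals = []
    for i in range(200):
        vals = np.rint(rng.lognormal(5.5, 0.25, 300)).astype(int)
        a, b = _dist(vals[:150], "a"), _dist(vals[150:], "b")
        pvals.append(batch_matched_shift_test(a, b, n_perm=199, seed=rng).p_value)
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_permutation_p_matches_exact_rank_sum():
    """Permutation p agrees with the exact Mann-Whitney p on small samples."""
    rng = np.random.default_rng(10)
    a_vals = np.rint(rng.lognormal(5.35, 0.2, 30)).astype(int)
    b_vals = np.rint(rng.lognormal(5.55, 0.2, 30)).astype(int)
    a, b = _dist(a_vals, "a"), _dist(b_vals, "b")
    res = batch_matched_shift_test(a, b, n_perm=20_000, seed=11)
    exact = stats.mannwhitneyu(a_vals, b_vals, alternative="less", method="exact").pvalue
    mc_se = np.sqrt(exact * (1 - exact) / 20_000)
    assert abs(res.p_value - exact) < 4 * mc_se + 1e-4


# ------------------------------------------------------------ time course


@pytest.fixture(scope="module")
def time_course_data(model, promoters, background):
    """ΔtoxA vs wildtype across the MIV time course with packaged
    (time-increasing) cleavage rates."""
    manifest_rows = []
    dists = {}
    for genotype in ("wildtype", "dtoxA"):
        for t in (0, 10, 30, 100):
            lib = make_library_params(genotype, t, pairs_per_library=8000)
            res = simulate_library(
                model, promoters, background, genotype, t, lib,
                seed=50 + t, library_id=f"{genotype}_t{t}", n_cells=5,
            )
            lid = f"{genotype}_t{t}"
            dists[lid] = insert_size_distribution(res.insert, lid, "batch1")
            manifest_rows.append(
                {"library_id": lid, "genotype": genotype, "timepoint": t, "batch": "batch1"}
            )
    return pd.DataFrame(manifest_rows), dists


def test_time_course_trend(model, time_course_data):
    manifest, dists = time_course_data
    course = shift_time_course(manifest, dists, ("dtoxA", "wildtype"), n_perm=500, seed=60)
    assert len(course) == 4
    by_t = course.set_index("timepoint")["median_difference"]
    # cleavage grows with time after induction: monotonically more negative
    assert by_t[100] < by_t[30] < by_t[0] + 1e-9
    assert course["trend_spearman"].iloc[0] < -0.7
    # late timepoints clearly significant
    assert course.set_index("timepoint")["p_value"][100] < 0.01


def test_single_timepoint_trend_na():
    rng = np.random.default_rng(12)
    vals = np.rint(rng.lognormal(5.5, 0.25, 400)).astype(int)
    manifest = pd.DataFrame(
        [
            {"library_id": "a", "genotype": "dtoxA", "timepoint": 0, "batch": "b1"},
            {"library_id": "b", "genotype": "wildtype", "timepoint": 0, "batch": "b1"},
        ]
    )
    dists = {"a": _dist(vals[:200], "a", "b1"), "b": _dist(vals[200:], "b", "b1")}
    course = shift_time_course(manifest, dists, ("dtoxA", "wildtype"), n_perm=99, seed=13)
    assert len(course) == 1
    assert np.isnan(course["trend_spearman"].iloc[0])


# -------------------------------------------------------------- k-mer scan


def test_identical_read_sets_no_depletion():
    rng = np.random.default_rng(14)
    reads = ["".join(np.array(list("ACGT"))[rng.integers(0, 4, 100)]) for _ in range(200)]
    res = kmer_depletion_scan(reads, list(reads), k=10, min_count=5)
    assert not res.significant


def test_planted_kmer_depletion_detected():
    """Removing every read containing a planted 10-mer flags that 10-mer."""
    rng = np.random.default_rng(15)
    planted = "ACGTACGTAC"
    reads = []
    for i in range(400):
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 100)])
        if i % 4 == 0:
            pos = int(rng.integers(0, 90))
            seq = seq[:pos] + planted + seq[pos + 10 :]
        reads.append(seq)
    depleted_set = [r for r in reads if planted not in r]
    res = kmer_depletion_scan(depleted_set, reads, k=10, min_count=20)
    assert planted in res.depleted or any(
        k in (planted,) for k in res.depleted
    )


def test_nonspecific_cleavage_leaves_no_kmer_signal(model):
    """Sequence-nonspecific cleavage does not deplete specific k-mers.

    Tested on a long template so molecule-end edge effects (which shift
    where fragments *start* but carry no sequence preference) do not
    masquerade as k-mer signal.
    """
    from toxta.simulate import TranscriptMolecule, apply_cleavage, draw_fragments

    rng = np.random.default_rng(70)
    template = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 10_000)])
    # deep coverage (~300x): a 2-fold dip cannot arise from sampling noise
    lib = make_library_params("dtoxA", 0, pairs_per_library=30_000)

    def reads(rate, seed):
        mols = apply_cleavage(
            [TranscriptMolecule("m", 0, len(template))] * 300, rate, np.random.default_rng(seed)
        )
        starts = np.array([m.start for m in mols])
        ends = np.array([m.end for m in mols])
        _, fs, _, _ = draw_fragments(starts, ends, 30_000, lib, np.random.default_rng(seed + 1))
        return [template[int(s) : int(s) + 100] for s in fs]

    res = kmer_depletion_scan(reads(2.0, 80), reads(0.0, 90), k=10, min_count=150)
    assert not res.significant


def test_k_out_of_range_rejected():
    with pytest.raises(ValueError, match="k must be"):
        kmer_depletion_scan(["ACGTACGTACGT"], ["ACGTACGTACGT"], k=5)
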