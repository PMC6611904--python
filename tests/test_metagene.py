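"""Binning, RPKM calibration, aggregation and the KS group comparison."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

import cismark as cm
from cismark.core_io import CoverageTrack, GeneModel
from cismark.metagene import body_bin_edges
from cismark.simulate import SimulationTruth


def _uniform_track(size, value=1.0, read_length=50):
    return CoverageTrack({"chr1": [(0, size, value)]}, {"chr1": size}, read_length=read_length)


def test_rpkm_unit_case_and_zero():
    assert cm.rpkm(1000, 1000, 1_000_000) == 1000.0
    assert cm.rpkm(0, 500, 1_000_000) == 0.0


def test_rpkm_scale_invariance():
    assert cm.rpkm(200, 700, 5e6) == pytest.approx(cm.rpkm(400, 700, 1e7))


def test_rpkm_invalid_inputs():
    with pytest.raises(ValueError):
        cm.rpkm(10, 0, 1e6)
    with pytest.raises(ValueError):
        cm.rpkm(10, 100, 0)


def test_body_bin_edges_match_cumulative_rounding_oracle():
    start, end, n = 100, 100 + 1234, 300
    edges = body_bin_edges(start, end, n)
    # brute-force oracle: bin of each base via floor(i * n / len), then edges
    base_bin = (np.arange(1234) * n) // 1234
    expect = [start] + [start + int(np.searchsorted(base_bin, b)) for b in range(1, n)] + [end]
    assert edges.tolist() == pytest.approx(expect, abs=1)  # same partition family
    assert edges[0] == start and edges[-1] == end
    assert np.all(np.diff(edges) >= 0)
    assert np.diff(edges).sum() == 1234


def test_body_shorter_than_bins_has_empty_bins():
    edges = body_bin_edges(0, 100, 300)
    widths = np.diff(edges)
    assert widths.sum() == 100 and np.all(widths >= 0) and (widths == 0).any()


def test_identical_tracks_give_flat_unit_profile():
    track = _uniform_track(20_000)
    gene = GeneModel("g", "chr1", 8000, 10_000, "+")
    vals = cm.gene_profile(track, track, gene)
    assert np.allclose(vals, 1.0)


def test_truncated_flanks_are_missing():
    track = _uniform_track(9000)
    gene = GeneModel("g", "chr1", 1000, 3000, "+")  # only 1 kb upstream exists
    vals = cm.gene_profile(track, track, gene)
    assert np.isnan(vals[:200]).all()  # first 2 kb of the 3-kb flank truncated
    assert np.isfinite(vals[200:]).all()


def test_planted_five_prime_enrichment_peaks_in_first_half_of_body():
    cfg = cm.SimConfig(n_genes=0, chrom_len=40_000, enrichment_fold=8.0, seed=5)
    gene = GeneModel("g", "chr1", 20_000, 22_000, "+")
    ann = cm.Annotation([gene], {"chr1": 40_000})
    truth = SimulationTruth(enriched_genes={"g"}, seed=5)
    chip, inp = cm.simulate_coverage(ann, truth, cfg)
    vals = cm.gene_profile(chip, inp, gene)
    body = np.asarray(vals[300:600])
    assert 300 <= 300 + int(np.nanargmax(body)) <= 450


def test_minus_strand_profile_is_orientation_flipped():
    """Mirroring the genome maps a profile onto its reverse."""
    size = 30_000
    ivs = [(i * 200, (i + 1) * 200, float(1 + (i % 7))) for i in range(size // 200)]
    fwd = CoverageTrack({"chr1": ivs}, {"chr1": size})
    mirrored = CoverageTrack(
        {"chr1": sorted((size - e, size - s, v) for s, e, v in ivs)}, {"chr1": size}
    )
    flat = _uniform_track(size, 2.0)
    gene_f = GeneModel("g", "chr1", 12_000, 14_500, "+")
    gene_r = GeneModel("g", "chr1", size - 14_500, size - 12_000, "-")
    prof_f = cm.gene_profile(fwd, flat, gene_f)
    prof_r = cm.gene_profile(mirrored, flat, gene_r)
    np.testing.assert_allclose(prof_f, prof_r, rtol=1e-12)


def test_aggregate_single_and_pair():
    a = np.full(900, 2.0)
    b = np.full(900, 4.0)
    single = cm.aggregate_and_matrix([a], ["g1"])
    assert np.allclose(single.aggregate, a)
    pair = cm.aggregate_and_matrix([a, b], ["g1", "g2"])
    assert np.allclose(pair.aggregate, 3.0)
    assert pair.gene_ids == ["g1", "g2"]


def test_aggregate_empty_errors():
    with pytest.raises(ValueError):
        cm.aggregate_and_matrix([], [])


def test_aggregate_matches_brute_force_mean(rng):
    rows = [rng.uniform(0, 5, size=900) for _ in range(50)]
    for row in rows[:5]:
        row[rng.integers(0, 900, size=20)] = np.nan
    prof = cm.aggregate_and_matrix(rows, [f"g{i}" for i in range(50)])
    stack = np.vstack(rows)
    for b in range(0, 900, 37):
        col = stack[:, b]
        expect = col[~np.isnan(col)].mean()
        assert prof.aggregate[b] == pytest.approx(expect)


def test_tss_downstream_signal_cases(rng):
    assert cm.tss_downstream_signal(np.ones(900)) == 1.0
    v = np.zeros(900)
    v[300:600] = 2.0
    assert cm.tss_downstream_signal(v) == 2.0
    for _ in range(20):
        row = rng.uniform(0, 3, 900)
        assert cm.tss_downstream_signal(row) == pytest.approx(row[300:600].mean())
    allnan = np.full(900, np.nan)
    assert np.isnan(cm.tss_downstream_signal(allnan))


def test_ks_identical_and_disjoint_samples():
    d, p = cm.ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert d == 0.0 and p == 1.0
    d, p = cm.ks_two_sample([1, 2, 3], [4, 5, 6])
    assert d == 1.0


def test_ks_rejects_tiny_or_nonfinite_groups():
    with pytest.raises(ValueError):
        cm.ks_two_sample([1.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        cm.ks_two_sample([1.0, np.nan], [1.0, 2.0])


def test_ks_statistic_matches_scipy_and_brute_ecdf(rng):
    for _ in range(25):
        a = rng.normal(0, 1, size=int(rng.integers(5, 40)))
        b = rng.normal(0.4, 1.3, size=int(rng.integers(5, 40)))
        d, _p = cm.ks_two_sample(a, b)
        ref = ks_2samp(a, b)
        assert d == pytest.approx(ref.statistic, abs=1e-12)
        # brute ECDF scan over a dense grid
        grid = np.concatenate([a, b])
        brute = max(
            abs((a <= x).mean() - (b <= x).mean()) for x in grid
        )
        assert d == pytest.approx(brute, abs=1e-12)


def test_ks_p_close_to_permutation_oracle():
    rng = np.random.default_rng(42)
    a = rng.normal(0, 1, 15)
    b = rng.normal(0.6, 1, 15)
    d, p = cm.ks_two_sample(a, b)
    pool = np.concatenate([a, b])
    hits = 0
    reps = 10_000
    for _ in range(reps):
        perm = rng.permutation(pool)
        dd, _ = cm.ks_two_sample(perm[:15], perm[15:])
        hits += dd >= d - 1e-12
    assert abs(p - hits / reps) <= 0.02


def test_enriched_vs_background_groups_separate_by_ks(small_dataset):
    """Gene-body signal of truly enriched genes beats the background genes."""
    ds = small_dataset
    ann, truth = ds["annotation"], ds["truth"]
    enr = sorted(truth.enriched_genes)[:50]
    non = sorted(set(ann.gene_ids()) - truth.enriched_genes)[:50]
    prof = cm.profile_genes(ds["chip"], ds["input"], [ann[g] for g in enr + non])
    vals = [cm.tss_downstream_signal(r) for r in prof.matrix]
    d, p = cm.ks_two_sample(vals[: len(enr)], vals[len(enr) :])
    assert p < 0.01
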