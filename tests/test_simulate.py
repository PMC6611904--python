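"""Generator contracts: determinism, truth exactness, planted statistics."""

import numpy as np
import pytest

import cismark as cm
from cismark.simulate import SIM_WINDOW, SimulationTruth, _enriched_region, choose_enriched


def test_empty_annotation():
    cfg = cm.SimConfig(n_genes=0, chrom_len=10_000)
    assert len(cm.simulate_annotation(cfg)) == 0


def test_annotation_deterministic_under_seed():
    cfg = cm.SimConfig(n_genes=50, chrom_len=300_000, seed=4)
    a1, a2 = cm.simulate_annotation(cfg), cm.simulate_annotation(cfg)
    assert a1 == a2
    a3 = cm.simulate_annotation(cm.SimConfig(n_genes=50, chrom_len=300_000, seed=5))
    assert a1 != a3


def test_annotation_genes_pairwise_disjoint_brute_force():
    cfg = cm.SimConfig(n_genes=500, chrom_len=2_200_000, seed=2)
    genes = list(cm.simulate_annotation(cfg))
    assert len(genes) == 500
    for i, a in enumerate(genes):  # O(n^2) interval-overlap oracle
        for b in genes[i + 1 :]:
            assert a.end <= b.start or b.end <= a.start


def test_annotation_overflow_raises():
    with pytest.raises(ValueError, match="chrom_len"):
        cm.simulate_annotation(cm.SimConfig(n_genes=100, chrom_len=20_000))


def test_sequences_zero_rate_means_no_hits_anywhere():
    cfg = cm.SimConfig(n_genes=40, chrom_len=250_000, element_rate=0.0, seed=7)
    ann = cm.simulate_annotation(cfg)
    genome, planted = cm.simulate_sequences(ann, cfg)
    assert planted == set()
    gene_set, _ = cm.genes_with_element(ann, genome)
    assert gene_set == set()


def test_sequences_full_rate_plants_everywhere():
    cfg = cm.SimConfig(n_genes=40, chrom_len=250_000, element_rate=1.0, seed=8)
    ann = cm.simulate_annotation(cfg)
    genome, planted = cm.simulate_sequences(ann, cfg)
    gene_set, _ = cm.genes_with_element(ann, genome)
    assert gene_set == planted
    # nearly every gene should be plantable at this geometry
    assert len(planted) >= 0.9 * len(ann)


def test_planted_offsets_round_trip():
    """Scanned hit coordinates land inside the allowed planting window and
    every planted gene is recovered with its exact 7-bp span."""
    cfg = cm.SimConfig(n_genes=100, chrom_len=600_000, element_rate=0.5, seed=9)
    ann = cm.simulate_annotation(cfg)
    genome, planted = cm.simulate_sequences(ann, cfg)
    gene_set, hits = cm.genes_with_element(ann, genome)
    assert gene_set == planted
    for h in hits:
        assert -2000 <= h.tss_start <= -8
        assert h.tss_end == h.tss_start + 6
        assert h.matched_seq in (cm.CORE_ELEMENT, cm.revcomp(cm.CORE_ELEMENT))


def test_sequences_deterministic():
    cfg = cm.SimConfig(n_genes=30, chrom_len=200_000, seed=3)
    ann = cm.simulate_annotation(cfg)
    g1, p1 = cm.simulate_sequences(ann, cfg)
    g2, p2 = cm.simulate_sequences(ann, cfg)
    assert g1 == g2 and p1 == p2


def test_coverage_poisson_mean_inside_enriched_regions():
    """Fully interior windows of enriched regions average fold x depth reads."""
    cfg = cm.SimConfig(n_genes=200, chrom_len=1_000_000, enrichment_fold=8.0,
                       background_depth=20.0, seed=13)
    ann = cm.simulate_annotation(cfg)
    truth = SimulationTruth(element_genes=set(), seed=cfg.seed)
    truth.enriched_genes = set(ann.gene_ids()[:60])
    chip, _inp = cm.simulate_coverage(ann, truth, cfg)
    counts = []
    for gid in sorted(truth.enriched_genes):
        lo, hi = _enriched_region(ann[gid], cfg)
        w0 = -(-lo // SIM_WINDOW)  # first window fully inside
        while (w0 + 1) * SIM_WINDOW <= hi:
            counts.append(chip.mass("chr1", w0 * SIM_WINDOW, (w0 + 1) * SIM_WINDOW) / 50)
            w0 += 1
    counts = np.array(counts)
    assert len(counts) >= 100
    se = np.sqrt(160.0 / len(counts))
    assert abs(counts.mean() - 160.0) <= 3 * se


def test_coverage_deterministic_and_null_exchangeable():
    cfg = cm.SimConfig(n_genes=50, chrom_len=300_000, enrichment_fold=1.0, seed=21)
    ann = cm.simulate_annotation(cfg)
    truth = SimulationTruth(enriched_genes=set(ann.gene_ids()[:10]), seed=cfg.seed)
    c1, i1 = cm.simulate_coverage(ann, truth, cfg)
    c2, i2 = cm.simulate_coverage(ann, truth, cfg)
    assert c1.library_size == c2.library_size and i1.library_size == i2.library_size
    assert np.array_equal(c1.intervals("chr1")[2], c2.intervals("chr1")[2])
    # fold 1: ChIP and input are drawn from the same law; their genome-wide
    # means agree within a few standard errors
    n_win = 300_000 / SIM_WINDOW
    se = np.sqrt(2 * 20.0 / n_win)
    assert abs(c1.library_size - i1.library_size) / n_win <= 4 * se


def test_deg_association_binomial_check():
    cfg = cm.SimConfig(n_genes=1000, chrom_len=4_500_000, p_down_given_element=0.9,
                       p_down_given_no_element=0.1, seed=17)
    ann = cm.simulate_annotation(cfg)
    rng = np.random.default_rng(1)
    element = {gid for gid in ann.gene_ids() if rng.random() < 0.2}
    truth = SimulationTruth(element_genes=element, seed=cfg.seed)
    records, down = cm.simulate_deg(ann, truth, cfg)
    frac = len(down & element) / len(element)
    se = np.sqrt(0.9 * 0.1 / len(element))
    assert abs(frac - 0.9) <= 3 * se
    # filter recovers the truth set exactly (non-DEGs get q >= 0.05)
    assert cm.filter_downregulated(records) == down


def test_deg_no_association_zero_rate():
    cfg = cm.SimConfig(n_genes=100, chrom_len=500_000, p_down_given_element=0.0,
                       p_down_given_no_element=0.0, seed=5)
    ann = cm.simulate_annotation(cfg)
    records, down = cm.simulate_deg(ann, SimulationTruth(seed=5), cfg)
    assert down == set()
    assert cm.filter_downregulated(records) == set()


def test_deg_deterministic():
    cfg = cm.SimConfig(n_genes=60, chrom_len=350_000, seed=2)
    ann = cm.simulate_annotation(cfg)
    truth = SimulationTruth(element_genes=set(ann.gene_ids()[:10]), seed=2)
    r1, d1 = cm.simulate_deg(ann, truth, cfg)
    r2, d2 = cm.simulate_deg(ann, truth, cfg)
    assert r1 == r2 and d1 == d2


def test_choose_enriched_respects_probabilities():
    cfg = cm.SimConfig(n_genes=400, chrom_len=1_800_000,
                       p_enriched_given_element=1.0, p_enriched_background=0.0, seed=6)
    ann = cm.simulate_annotation(cfg)
    element = set(ann.gene_ids()[:40])
    assert choose_enriched(ann, element, cfg) == element


def test_full_dataset_changing_seed_changes_outputs():
    cfg_a = cm.SimConfig(n_genes=30, chrom_len=200_000, seed=1)
    cfg_b = cm.SimConfig(n_genes=30, chrom_len=200_000, seed=2)
    ga, _ = cm.simulate_sequences(cm.simulate_annotation(cfg_a), cfg_a)
    gb, _ = cm.simulate_sequences(cm.simulate_annotation(cfg_b), cfg_b)
    assert ga != gb
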