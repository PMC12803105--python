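"""Peak caller: conventions, permutation-FDR oracle, clustering, regions."""
import numpy as np
import pandas as pd
import pytest

from clipfunnel.models import GeneModel
from clipfunnel.peaks import (annotate_cluster_regions, assign_region, call_peaks,
                              call_peaks_and_clusters, cluster_peaks,
                              derive_crosslink_sites, region_distribution)

from conftest import make_sites


class FakeRead:
    """Duck-typed stand-in for a mapped alignment record."""

    def __init__(self, chrom, start, end, reverse=False, unmapped=False):
        self.reference_name = chrom
        self.reference_start = start
        self.reference_end = end
        self.is_reverse = reverse
        self.is_unmapped = unmapped


# --- derive_crosslink_sites ---------------------------------------------


def test_derive_empty_input():
    sites, rejected = derive_crosslink_sites([])
    assert len(sites) == 0 and rejected == 0


def test_derive_plus_strand_truncation_convention():
    reads = [FakeRead("chr1", 100, 130) for _ in range(3)]
    sites, _ = derive_crosslink_sites(reads, offset=-1)
    assert len(sites) == 1
    assert sites.loc[0, "pos"] == 99 and sites.loc[0, "score"] == 3
    assert sites.loc[0, "strand"] == "+"


def test_derive_minus_strand_mirror():
    # 5'-terminal aligned base of a minus read is reference_end - 1 = 200
    reads = [FakeRead("chr1", 171, 201, reverse=True)]
    sites, _ = derive_crosslink_sites(reads, offset=-1)
    assert sites.loc[0, "pos"] == 201 and sites.loc[0, "strand"] == "-"


def test_derive_offset_zero_places_event_at_terminus():
    sites, _ = derive_crosslink_sites([FakeRead("chr1", 100, 130)], offset=0)
    assert sites.loc[0, "pos"] == 100


def test_derive_rejects_unmapped_with_count():
    reads = [FakeRead("chr1", 100, 130), FakeRead("chr1", 0, 0, unmapped=True)]
    sites, rejected = derive_crosslink_sites(reads)
    assert len(sites) == 1 and rejected == 1


# --- call_peaks ----------------------------------------------------------


def test_single_event_site_never_significant():
    sites = make_sites([500], [1])
    out = call_peaks(sites, (0, 1000), n_perm=50, seed=0, return_all_sites=True)
    assert out.loc[0, "fdr"] == 1.0
    assert len(call_peaks(sites, (0, 1000), n_perm=50, seed=0)) == 0


def test_alpha_one_returns_every_site():
    sites = make_sites([10, 20, 30], [1, 2, 1])
    out = call_peaks(sites, (0, 100), n_perm=20, alpha=1.0, seed=0)
    assert len(out) == 3


def test_errors_on_empty_span_and_bad_nperm():
    sites = make_sites([5], [1])
    with pytest.raises(ValueError):
        call_peaks(sites, (10, 10), n_perm=10)
    with pytest.raises(ValueError):
        call_peaks(sites, (0, 10), n_perm=0)


def brute_force_fdr(sites, span, n_perm, window, seed):
    """Independent re-implementation of the randomization with the same
    seed stream: one uniform draw of the gene's events per permutation,
    heights by explicit double loops."""
    rng = np.random.default_rng(seed)
    pos = sites["pos"].to_numpy()
    score = sites["score"].to_numpy()
    n_events = int(score.sum())
    obs_height = np.array([
        sum(int(s) for q, s in zip(pos, score) if abs(int(q) - int(p)) <= window)
        for p in pos
    ])
    thresholds = sorted(set(obs_height))
    rand_ge = {h: 0 for h in thresholds}
    for _ in range(n_perm):
        draw = rng.integers(span[0], span[1], size=n_events)
        occupied = sorted(set(draw.tolist()))
        heights = [int(np.sum((draw >= p - window) & (draw <= p + window)))
                   for p in occupied]
        for h in thresholds:
            rand_ge[h] += sum(1 for x in heights if x >= h)
    fdr_at = {}
    for h in thresholds:
        obs_ge = int(np.sum(obs_height >= h))
        fdr_at[h] = min(1.0, (rand_ge[h] / n_perm) / obs_ge)
    # monotonize: running minimum over increasing height
    out = {}
    best = np.inf
    for h in sorted(thresholds):
        best = min(best, fdr_at[h])
        out[h] = best
    return np.array([out[h] for h in obs_height])


def test_permutation_fdr_matches_brute_force_oracle():
    """Span 50, one score-10 site among ten score-1 sites; the implementation
    must reproduce an independent brute-force randomization that consumes the
    identical seed stream."""
    positions = [25] + [2, 6, 11, 16, 21, 31, 36, 40, 44, 48]
    scores = [10] + [1] * 10
    sites = make_sites(positions, scores)
    seed, n_perm = 123, 2000
    got = call_peaks(sites, (0, 50), n_perm=n_perm, seed=seed, return_all_sites=True)
    expected = brute_force_fdr(got[["pos", "score"]], (0, 50), n_perm, 3, seed)
    np.testing.assert_allclose(got["fdr"].to_numpy(), expected, atol=1e-12)
    # the hot site is far more significant than the background sites
    hot = got.loc[got["pos"] == 25, "fdr"].iloc[0]
    assert hot < got.loc[got["pos"] != 25, "fdr"].min()


def test_fdr_monotone_in_window_height(small_sim):
    _, tr, truth, sites1, _ = small_sim
    gid = sorted(truth.ligand_gene_ids)[1]
    out = call_peaks(sites1[sites1["gene_id"] == gid], tr.genes[gid].span,
                     n_perm=200, seed=5, return_all_sites=True)
    df = out.sort_values("window_height")
    assert (np.diff(df["fdr"].to_numpy()) <= 1e-12).all()


def test_seed_contract_identical_and_stable():
    sites = make_sites([25, 2, 6, 11, 16, 21, 31, 36, 40, 44, 48],
                       [10, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1])
    a = call_peaks(sites, (0, 50), n_perm=1000, seed=7, return_all_sites=True)
    b = call_peaks(sites, (0, 50), n_perm=1000, seed=7, return_all_sites=True)
    pd.testing.assert_frame_equal(a, b)
    c = call_peaks(sites, (0, 50), n_perm=1000, seed=8, return_all_sites=True)
    assert np.max(np.abs(a["fdr"].to_numpy() - c["fdr"].to_numpy())) < 0.02


def test_strand_symmetry_of_fdr():
    """Reflecting the coordinates leaves the FDR of each (reflected) site
    unchanged when the same seed is used: the null depends only on the drawn
    event configuration, not on the observed orientation."""
    span = (100, 400)
    positions = [120, 150, 151, 155, 290, 300]
    scores = [4, 1, 2, 1, 3, 1]
    fwd = call_peaks(make_sites(positions, scores), span, n_perm=300, seed=3,
                     return_all_sites=True)
    refl_pos = [span[0] + span[1] - 1 - p for p in positions]
    rev = call_peaks(make_sites(refl_pos, scores, strand="-"), span, n_perm=300,
                     seed=3, return_all_sites=True)
    fwd_map = dict(zip(fwd["pos"], fwd["fdr"]))
    rev_map = dict(zip(rev["pos"], rev["fdr"]))
    for p in positions:
        assert fwd_map[p] == pytest.approx(rev_map[span[0] + span[1] - 1 - p], abs=1e-12)


# --- clustering ----------------------------------------------------------


def test_single_peak_cluster_interval_and_score():
    peaks = make_sites([100], [5])
    cl = cluster_peaks(peaks, peaks)
    assert len(cl) == 1
    row = cl.iloc[0]
    assert (row.start, row.end) == (97, 104) and row.cluster_score == 5


def test_merge_rule_boundary_at_gap_20():
    sites_a = make_sites([100, 119], [1, 1])
    assert len(cluster_peaks(sites_a, sites_a)) == 1
    sites_b = make_sites([100, 120], [1, 1])
    assert len(cluster_peaks(sites_b, sites_b)) == 2


def test_cluster_score_adds_adjacent_non_peak_signal_only():
    peaks = make_sites([100, 110], [4, 2])
    all_sites = make_sites([100, 105, 110, 130], [4, 1, 2, 7])
    cl = cluster_peaks(peaks, all_sites)
    assert len(cl) == 1
    assert cl.iloc[0].cluster_score == 7  # 4 + 2 + 1; site at 130 excluded
    assert (cl.iloc[0].start, cl.iloc[0].end) == (97, 114)


def test_empty_peaks_give_empty_clusters():
    assert len(cluster_peaks(make_sites([], []), make_sites([], []))) == 0


# --- region assignment ---------------------------------------------------


def _gene():
    return GeneModel("g1", "chrS", "+", 0, 1000,
                     five_prime_utr=[(0, 100)], cds=[(100, 400), (600, 700)],
                     introns=[(400, 600)], three_prime_utr=[(700, 1000)])


def test_region_of_cluster_inside_utr3():
    assert assign_region(800, 850, _gene()) == "3UTR"


def test_region_midpoint_rule_at_junction():
    # cluster spans the CDS/3'UTR junction, midpoint in the 3'UTR
    assert assign_region(690, 720, _gene()) == "3UTR"


def test_region_outside_all_features_is_other():
    gene = GeneModel("g2", "chrS", "+", 0, 1000, three_prime_utr=[(700, 1000)])
    assert assign_region(100, 120, gene) == "other"


def test_region_fractions_sum_to_one(small_sim):
    _, tr, _, sites1, _ = small_sim
    _, clusters = call_peaks_and_clusters(sites1, tr.genes, n_perm=50, seed=1)
    fractions, counts = region_distribution(clusters)
    assert counts["total"] == len(clusters) > 0
    assert sum(fractions.values()) == pytest.approx(1.0)


def test_region_distribution_trivial_cases():
    df = pd.DataFrame({"region": ["3UTR", "3UTR"]})
    fractions, counts = region_distribution(df)
    assert fractions == {"3UTR": 1.0} and counts["total"] == 2
    fractions, counts = region_distribution(pd.DataFrame())
    assert fractions == {} and counts == {"total": 0}


def test_planted_signal_concentrates_clusters_in_utr3():
    from clipfunnel.simulate import SimulationConfig, simulate_clip_events, \
        simulate_transcriptome
    cfg = SimulationConfig(n_genes=40, n_ligands=40, signal_fraction=0.9, seed=21)
    tr, truth = simulate_transcriptome(cfg)
    s1, _ = simulate_clip_events(cfg, tr, truth)
    _, clusters = call_peaks_and_clusters(s1, tr.genes, n_perm=50, seed=2)
    fractions, _ = region_distribution(clusters)
    assert fractions.get("3UTR", 0.0) > 0.5
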