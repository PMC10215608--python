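"""Windowed selection statistics and candidate-region selection."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ovisweep.panel import HIGH, LOW, GenotypePanel
from ovisweep.scan import (ScanConfig, Window, assign_sites,
                           compute_window_stats, make_windows,
                           select_candidates, site_fst_components, site_pi,
                           window_fst, window_hp, window_log2_ratio,
                           window_pi, zhp)
from ovisweep.simulate import SimulationConfig, simulate_two_pop_genotypes
from tests.conftest import random_panel


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

def test_window_count_one_megabase():
    ws = make_windows({"chr1": 1_000_000}, 100_000, 10_000)
    assert len(ws) == 100
    assert ws[0].start == 0 and ws[-1].start == 990_000
    assert ws[-1].end == 1_000_000


def test_window_equals_step_tiles_without_overlap():
    ws = make_windows({"chr1": 300_000}, 100_000, 100_000)
    spans = [(w.start, w.end) for w in ws]
    assert spans == [(0, 100_000), (100_000, 200_000), (200_000, 300_000)]


def test_short_contig_single_window():
    ws = make_windows({"chr1": 50_000}, 100_000, 10_000)
    assert len(ws) == 5  # starts 0..40k, all truncated at 50 kb
    assert all(w.end == 50_000 for w in ws)
    ws = make_windows({"chr1": 5_000}, 100_000, 10_000)
    assert len(ws) == 1 and ws[0].end == 5_000


def test_assign_sites_boundary_convention(make_panel):
    """1-based position p lies in 0-based window [s, e) iff s < p <= e."""
    sites = pd.DataFrame({"contig": "chr1", "pos": [100, 101, 200, 201],
                          "ref": "A", "alt": "G"})
    g = np.zeros((4, 4), dtype=np.int8)
    samples = [f"s{i}" for i in range(4)]
    panel = GenotypePanel(sites=sites, genotypes=g, samples=samples,
                          groups={s: HIGH for s in samples})
    ws = [Window("chr1", 100, 200)]
    assign_sites(ws, panel)
    assert list(panel.sites.loc[ws[0].site_idx, "pos"]) == [101, 200]


# ---------------------------------------------------------------------------
# per-site F_ST
# ---------------------------------------------------------------------------

def wc_fst_oracle(c1, n1, c2, n2):
    """Weir–Cockerham 1984 components written from the general r-pop
    formulas, independently of the vectorised implementation."""
    r = 2
    samples = [(c1, n1), (c2, n2)]
    nbar = sum(n for _, n in samples) / r
    nc = (sum(n for _, n in samples)
          - sum(n * n for _, n in samples) / sum(n for _, n in samples)) \
        / (r - 1)
    pbar = sum(c for c, _ in samples) / sum(n for _, n in samples)
    s2 = sum(n * (c / n - pbar) ** 2 for c, n in samples) / ((r - 1) * nbar)
    a = (nbar / nc) * (s2 - (1.0 / (nbar - 1))
                       * (pbar * (1 - pbar) - s2 * (r - 1) / r))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r)
    return a, a + b


def test_site_fst_fixed_difference_is_one():
    a, total = site_fst_components((20, 20), (0, 20))
    assert a / total == pytest.approx(1.0)


def test_site_fst_negative_bias_at_equal_frequencies():
    a, _ = site_fst_components((10, 40), (10, 40))
    assert a <= 0.0


def test_site_fst_matches_independent_formula_oracle():
    rng = np.random.default_rng(31)
    for _ in range(200):
        n1 = int(rng.integers(4, 100))
        n2 = int(rng.integers(4, 100))
        c1 = int(rng.integers(0, n1 + 1))
        c2 = int(rng.integers(0, n2 + 1))
        if c1 + c2 == 0 or c1 + c2 == n1 + n2:
            continue  # monomorphic convention checked separately
        a, total = site_fst_components((c1, n1), (c2, n2))
        ea, etotal = wc_fst_oracle(c1, n1, c2, n2)
        assert a == pytest.approx(ea, abs=1e-12)
        assert total == pytest.approx(etotal, abs=1e-12)


def test_site_fst_monomorphic_returns_zeros():
    assert site_fst_components((0, 20), (0, 30)) == (0.0, 0.0)
    assert site_fst_components((20, 20), (30, 30)) == (0.0, 0.0)


def test_site_fst_group_without_calls_is_nan():
    a, total = site_fst_components((0, 0), (5, 20))
    assert np.isnan(a) and np.isnan(total)


# ---------------------------------------------------------------------------
# window F_ST
# ---------------------------------------------------------------------------

def test_window_fst_all_fixed_differences():
    a, total = site_fst_components(
        (np.array([20, 20]), np.array([20, 20])),
        (np.array([0, 0]), np.array([20, 20])))
    w = Window("chr1", 0, 1000, site_idx=np.array([0, 1]))
    assert window_fst(a, total, w) == pytest.approx(1.0)


def test_window_fst_ratio_of_sums_not_mean_of_ratios():
    counts_h = (np.array([18, 10]), np.array([20, 20]))
    counts_l = (np.array([2, 10]), np.array([20, 20]))
    a, total = site_fst_components(counts_h, counts_l)
    w = Window("chr1", 0, 1000, site_idx=np.array([0, 1]))
    got = window_fst(a, total, w)
    assert got == pytest.approx(a.sum() / total.sum(), abs=1e-12)
    mean_of_ratios = np.mean(a / total)
    assert got != pytest.approx(mean_of_ratios, abs=1e-6)


def test_window_fst_near_zero_without_differentiation():
    cfg = SimulationConfig(n_contigs=2, n_sites=2_000, background_fst=0.0,
                           seed=41)
    panel, _ = simulate_two_pop_genotypes(cfg)
    stats = compute_window_stats(panel, ScanConfig(),
                                 contig_lengths=cfg.contig_lengths)
    fst = stats["fst"].dropna()
    assert (fst.abs() < 0.05).mean() >= 0.95


# ---------------------------------------------------------------------------
# θπ
# ---------------------------------------------------------------------------

def test_window_pi_monomorphic_zero():
    pi_sites = site_pi(np.array([0, 0]), np.array([20, 20]))
    w = Window("chr1", 0, 100, site_idx=np.array([0, 1]))
    assert window_pi(pi_sites, w) == 0.0


def test_single_site_half_frequency_formula():
    # c = n/2 -> per-site pi = n/(2(n-1)); window length L scales it
    n = 20
    pi_sites = site_pi(np.array([n // 2]), np.array([n]))
    w = Window("chr1", 0, 50, site_idx=np.array([0]))
    assert window_pi(pi_sites, w) == pytest.approx(
        (n / (2 * (n - 1))) / 50.0)


def pi_pairwise_oracle(dosages):
    """Mean pairwise allele difference at one site, brute force over all
    pairs of called allele copies."""
    alleles = []
    for d in dosages:
        if d >= 0:
            alleles += [1] * d + [0] * (2 - d)
    pairs = list(itertools.combinations(range(len(alleles)), 2))
    if not pairs:
        return 0.0
    diff = sum(alleles[i] != alleles[j] for i, j in pairs)
    return diff / len(pairs)


def test_window_pi_matches_pairwise_oracle(make_panel):
    panel = make_panel(n_sites=50, n_samples=20, missing_rate=0.1, seed=43)
    alt, tot = panel.allele_counts(panel.group_indices(HIGH))
    pi_sites = site_pi(alt, tot)
    hi = panel.group_indices(HIGH)
    for i in range(panel.n_sites):
        assert pi_sites[i] == pytest.approx(
            pi_pairwise_oracle(panel.genotypes[i, hi]), abs=1e-9)
    w = Window("chr1", 0, 1_000_000, site_idx=np.arange(panel.n_sites))
    expected = sum(pi_pairwise_oracle(panel.genotypes[i, hi])
                   for i in range(panel.n_sites)) / 1_000_000
    assert window_pi(pi_sites, w) == pytest.approx(expected, abs=1e-12)


def test_log2_ratio_conventions():
    assert window_log2_ratio(0.01, 0.01) == 0.0
    assert window_log2_ratio(0.02, 0.01) == pytest.approx(1.0)
    assert np.isnan(window_log2_ratio(0.0, 0.01))
    assert np.isnan(window_log2_ratio(0.01, 0.0))


# ---------------------------------------------------------------------------
# Hp / ZHp
# ---------------------------------------------------------------------------

def test_hp_fixed_sites_zero():
    w = Window("chr1", 0, 100, site_idx=np.array([0, 1]))
    assert window_hp(np.array([0, 20]), np.array([20, 20]), w) == 0.0


def test_hp_balanced_sites_maximal():
    w = Window("chr1", 0, 100, site_idx=np.array([0, 1]))
    assert window_hp(np.array([10, 10]), np.array([20, 20]), w) == \
        pytest.approx(0.5)


def test_hp_three_site_hand_sum():
    # alt counts 2, 15, 10 of totals 20 -> minors 2, 5, 10; majors 18, 15, 10
    alt = np.array([2, 15, 10])
    tot = np.array([20, 20, 20])
    w = Window("chr1", 0, 100, site_idx=np.arange(3))
    s_min, s_maj = 2 + 5 + 10, 18 + 15 + 10
    assert window_hp(alt, tot, w) == pytest.approx(
        2 * s_maj * s_min / (s_maj + s_min) ** 2, abs=1e-12)


def test_zhp_standardization_identities():
    rng = np.random.default_rng(47)
    hp = rng.uniform(0.0, 0.5, size=200)
    z = zhp(hp)
    assert z.mean() == pytest.approx(0.0, abs=1e-9)
    assert z.std() == pytest.approx(1.0, abs=1e-9)


def test_zhp_window_at_mean_is_zero():
    hp = np.array([0.1, 0.2, 0.3])
    assert zhp(hp)[1] == pytest.approx(0.0, abs=1e-12)


def test_zhp_hand_values():
    hp = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    expected = (hp - 3.0) / np.sqrt(2.0)
    assert zhp(hp) == pytest.approx(expected, abs=1e-12)


def test_zhp_degenerate_errors():
    with pytest.raises(ValueError):
        zhp(np.array([0.2, 0.2, 0.2]))
    with pytest.raises(ValueError):
        zhp(np.array([0.2, np.nan]))


# ---------------------------------------------------------------------------
# candidate selection
# ---------------------------------------------------------------------------

def synthetic_stats(n=100, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "contig": "chr1",
        "start": np.arange(n) * 10_000,
        "end": np.arange(n) * 10_000 + 100_000,
        "n_sites": 50,
        "fst": rng.normal(0.05, 0.02, n),
        "pi_high": rng.uniform(1e-4, 1e-3, n),
        "pi_low": rng.uniform(1e-4, 1e-3, n),
        "hp_high": rng.uniform(0.1, 0.5, n),
        "hp_low": rng.uniform(0.1, 0.5, n),
    })
    df["log2_ratio"] = np.log2(df.pi_high / df.pi_low)
    df["zhp_high"] = zhp(df["hp_high"].to_numpy())
    df["zhp_low"] = zhp(df["hp_low"].to_numpy())
    return df


def test_top5_pass_counts_match_quantile_oracle():
    df = synthetic_stats(100, seed=3)
    cfg = ScanConfig()
    _, report = select_candidates(df, cfg)
    # distinct values: type-7 0.95 quantile leaves exactly 5 above it
    assert report["n_pass_fst"] == 5
    assert report["n_pass_ratio"] == 5
    assert report["n_pass_zhp"] == 5
    thr = np.quantile(df["fst"], 0.95)
    assert report["threshold_fst"] == pytest.approx(thr)
    assert (df["fst"] >= thr).sum() == 5


def test_identical_statistics_give_empty_candidates():
    df = synthetic_stats(50, seed=4)
    df["fst"] = 0.25  # degenerate: constant across windows
    regions, report = select_candidates(df, ScanConfig())
    assert regions == []
    assert report["n_pass_fst"] == 0


def test_candidate_regions_merge_overlapping_windows():
    df = synthetic_stats(100, seed=5)
    # plant an unambiguous three-window signal
    for col, val in (("fst", 0.9), ("log2_ratio", -5.0), ("zhp_high", -9.0)):
        df.loc[40:42, col] = val
    regions, report = select_candidates(df, ScanConfig())
    # windows 40-42 span [400k, 520k) once merged
    assert any(r.start <= 400_000 and r.end >= 520_000 and r.n_windows >= 3
               for r in regions)
    spans = sorted((r.contig, r.start, r.end) for r in regions)
    for (c1, s1, e1), (c2, s2, e2) in zip(spans, spans[1:]):
        assert c1 != c2 or e1 < s2  # non-overlapping, sorted


def planted_sweep_config(intensity=0.9, seed=101):
    return SimulationConfig(
        n_high=50, n_low=50, n_contigs=5, contig_length=1_000_000,
        n_sites=2_000, background_fst=0.05, sweep_intensity=intensity,
        seed=seed,
        sweep_windows=[("chr1", 200_000, 300_000, HIGH),
                       ("chr3", 500_000, 600_000, HIGH),
                       ("chr5", 700_000, 800_000, HIGH)])


def sweep_recovery(intensity, seed=101):
    cfg = planted_sweep_config(intensity, seed)
    panel, truth = simulate_two_pop_genotypes(cfg)
    scfg = ScanConfig()
    stats = compute_window_stats(panel, scfg,
                                 contig_lengths=cfg.contig_lengths)
    regions, _ = select_candidates(stats, scfg)
    hits = 0
    for (c, s, e, _g) in truth.sweep_regions:
        if any(r.contig == c and r.start < e and s < r.end
               for r in regions):
            hits += 1
    overlapping = sum(
        1 for r in regions
        if any(r.contig == c and r.start < e and s < r.end
               for (c, s, e, _g) in truth.sweep_regions))
    precision = overlapping / len(regions) if regions else 0.0
    return hits, precision, regions


def test_planted_sweeps_recovered():
    hits, precision, regions = sweep_recovery(0.9)
    assert hits >= 2
    assert precision >= 0.5


def test_recovery_monotone_in_sweep_intensity():
    recovered = [sweep_recovery(i)[0] for i in (0.5, 0.7, 0.9)]
    assert recovered == sorted(recovered)


def test_candidates_reproducible_bit_for_bit():
    cfg = planted_sweep_config()
    scfg = ScanConfig()
    runs = []
    for _ in range(2):
        panel, _ = simulate_two_pop_genotypes(cfg)
        stats = compute_window_stats(panel, scfg,
                                     contig_lengths=cfg.contig_lengths)
        regions, _ = select_candidates(stats, scfg)
        runs.append([(r.contig, r.start, r.end, r.n_windows) for r in regions])
    assert runs[0] == runs[1]
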