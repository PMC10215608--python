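"""Windowed selection-signature scan.

Three complementary statistics are computed in sliding windows (default
100 kb, 10-kb step) over a two-group genotype panel:

* **F_ST** — Weir–Cockerham (1984) variance-component estimator of
  population differentiation, combined per window as a ratio of sums
  (Σa / Σ(a+b)).  Because the panel interface carries allele counts per
  group, the random-union-of-gametes (allele-count) form of the
  estimator is used.
* **θπ ratio** — nucleotide diversity per bp per group, reported as
  log2(π_high / π_low); a sweep in one group drives the ratio toward
  that group's tail.
* **Hp / ZHp** — pooled heterozygosity over the window's summed major-
  and minor-allele counts (Rubin-style), Z-standardised across all
  windows of the group.

Windows in the extreme ``top_quantile`` tail of all three statistics are
intersected and merged into candidate selection regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import HIGH, LOW, GenotypePanel

UPPER, LOWER = "upper", "lower"


@dataclass
class Window:
    contig: str
    start: int  # 0-based inclusive
    end: int    # exclusive
    site_idx: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def n_sites(self) -> int:
        return len(self.site_idx)


@dataclass
class ScanConfig:
    window_bp: int = 100_000
    step_bp: int = 10_000
    top_quantile: float = 0.05
    min_sites_per_window: int = 10
    zhp_group: str = HIGH
    zhp_tail: str = LOWER
    ratio_tail: str = LOWER
    pi_per_site: bool = False  # normalise θπ by n variant sites, not bp

    def __post_init__(self) -> None:
        if not (1 <= self.step_bp <= self.window_bp):
            raise ValueError("need window_bp >= step_bp >= 1")
        if not (0.0 < self.top_quantile <= 0.5):
            raise ValueError("top_quantile must be in (0, 0.5]")
        for tail in (self.zhp_tail, self.ratio_tail):
            if tail not in (UPPER, LOWER):
                raise ValueError(f"unknown tail {tail!r}")

    @classmethod
    def literal_tails(cls, **kw) -> "ScanConfig":
        """Literal 'highest 5% of all three statistics' reading: upper
        tails everywhere."""
        return cls(zhp_tail=UPPER, ratio_tail=UPPER, **kw)


@dataclass
class CandidateRegion:
    contig: str
    start: int
    end: int
    n_windows: int
    peak_fst: float
    min_log2_ratio: float
    min_zhp: float


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

def make_windows(contig_lengths: dict[str, int], window_bp: int,
                 step_bp: int) -> list[Window]:
    """Sliding windows starting at 0, step, 2·step, … per contig.

    The trailing windows are truncated at the contig end; a contig
    shorter than the step yields a single window.
    """
    if not (1 <= step_bp <= window_bp):
        raise ValueError("need window_bp >= step_bp >= 1")
    out: list[Window] = []
    for contig, length in contig_lengths.items():
        start = 0
        while start < length:
            out.append(Window(contig=contig, start=start,
                              end=min(start + window_bp, length)))
            start += step_bp
    return out


def assign_sites(windows: list[Window], panel: GenotypePanel) -> None:
    """Fill each window's ``site_idx`` with the panel sites it contains.

    A 1-based position p belongs to the 0-based half-open window
    [start, end) iff start < p <= end.
    """
    by_contig: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for contig, sub in panel.sites.groupby("contig", sort=False):
        by_contig[contig] = (sub["pos"].to_numpy(), sub.index.to_numpy())
    for w in windows:
        if w.contig not in by_contig:
            w.site_idx = np.empty(0, dtype=int)
            continue
        pos, idx = by_contig[w.contig]
        lo = np.searchsorted(pos, w.start + 1, side="left")
        hi = np.searchsorted(pos, w.end, side="right")
        w.site_idx = idx[lo:hi]


# ---------------------------------------------------------------------------
# per-site statistics
# ---------------------------------------------------------------------------

def site_fst_components(counts_high, counts_low):
    """Weir–Cockerham 1984 variance components from allele counts.

    Each argument is ``(alt allele count, called allele total)`` for one
    group — scalars or equal-length arrays.  Returns ``(a, a + b)``: the
    among-population component and the total, whose ratio-of-sums over a
    window is the multi-locus F_ST estimator.  Sites monomorphic across
    both groups return (0, 0); sites where a group has fewer than two
    called alleles return NaN and should be skipped.
    """
    c1, n1 = (np.asarray(v, dtype=float) for v in counts_high)
    c2, n2 = (np.asarray(v, dtype=float) for v in counts_low)
    bad = (n1 < 2) | (n2 < 2)

    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = c1 / n1
        p2 = c2 / n2
        nbar = (n1 + n2) / 2.0
        nc = (n1 + n2) - (n1 ** 2 + n2 ** 2) / (n1 + n2)  # r - 1 = 1
        pbar = (c1 + c2) / (n1 + n2)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
        het = pbar * (1.0 - pbar)
        a = (nbar / nc) * (s2 - (het - s2 / 2.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (het - s2 / 2.0)

    total = a + b
    mono = (pbar == 0.0) | (pbar == 1.0)
    a = np.where(mono, 0.0, a)
    total = np.where(mono, 0.0, total)
    a = np.where(bad, np.nan, a)
    total = np.where(bad, np.nan, total)
    if a.ndim == 0:
        return float(a), float(total)
    return a, total


def site_pi(alt, tot):
    """Unbiased per-site heterozygosity 2c(n−c)/(n(n−1)).

    Equals the mean pairwise difference over all pairs of called
    alleles; 0 where fewer than two alleles are called.
    """
    c = np.asarray(alt, dtype=float)
    n = np.asarray(tot, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * c * (n - c) / (n * (n - 1.0))
    return np.where(n >= 2, pi, 0.0)


# ---------------------------------------------------------------------------
# window statistics
# ---------------------------------------------------------------------------

def window_fst(a: np.ndarray, total: np.ndarray, window: Window,
               min_sites: int = 1) -> float:
    """Ratio-of-sums Weir–Cockerham estimate over the window's sites."""
    idx = window.site_idx
    aa, tt = a[idx], total[idx]
    ok = np.isfinite(aa) & np.isfinite(tt)
    if ok.sum() < min_sites:
        return np.nan
    denom = tt[ok].sum()
    if denom == 0.0:
        return np.nan
    return float(aa[ok].sum() / denom)


def window_pi(pi_sites: np.ndarray, window: Window,
              per_site: bool = False) -> float:
    """Window nucleotide diversity: Σ per-site π over window length (bp),
    or over the number of contained variant sites when ``per_site``."""
    idx = window.site_idx
    total = float(pi_sites[idx].sum())
    if per_site:
        return total / idx.size if idx.size else 0.0
    return total / window.length


def window_log2_ratio(pi_high: float, pi_low: float) -> float:
    """log2(π_high / π_low); NaN (excluded from ranking) when either is 0."""
    if pi_high <= 0.0 or pi_low <= 0.0:
        return np.nan
    return float(np.log2(pi_high / pi_low))


def window_hp(alt: np.ndarray, tot: np.ndarray, window: Window) -> float:
    """Pooled heterozygosity 2·ΣnMAJ·ΣnMIN / (ΣnMAJ + ΣnMIN)².

    Major/minor allele is decided per site within the group; a 50/50
    site contributes equally to both sums.  NaN when the window has no
    called sites.
    """
    idx = window.site_idx
    c, n = alt[idx].astype(float), tot[idx].astype(float)
    called = n > 0
    if not called.any():
        return np.nan
    c, n = c[called], n[called]
    n_min = np.minimum(c, n - c)
    n_maj = np.maximum(c, n - c)
    s_min, s_maj = n_min.sum(), n_maj.sum()
    return float(2.0 * s_maj * s_min / (s_maj + s_min) ** 2)


def zhp(hp_values: np.ndarray) -> np.ndarray:
    """Z-standardise window Hp values: (Hp − μ)/σ over non-missing
    windows (population SD).  NaN entries stay NaN."""
    hp = np.asarray(hp_values, dtype=float)
    ok = np.isfinite(hp)
    if ok.sum() < 2:
        raise ValueError("need at least 2 non-missing windows")
    if hp[ok].min() == hp[ok].max():
        raise ValueError("degenerate panel: all window Hp identical")
    mu = hp[ok].mean()
    sd = hp[ok].std()  # population SD
    out = np.full_like(hp, np.nan)
    out[ok] = (hp[ok] - mu) / sd
    return out


def compute_window_stats(panel: GenotypePanel, cfg: ScanConfig,
                         contig_lengths: dict[str, int] | None = None
                         ) -> pd.DataFrame:
    """Per-window F_ST, θπ per group, log2 ratio, Hp and ZHp per group.

    Returns one row per window with columns contig, start, end, n_sites,
    fst, pi_high, pi_low, log2_ratio, hp_high, hp_low, zhp_high, zhp_low.
    Contig lengths default to the last SNP position per contig.
    """
    if contig_lengths is None:
        contig_lengths = {
            c: int(sub["pos"].max())
            for c, sub in panel.sites.groupby("contig", sort=False)
        }
    windows = make_windows(contig_lengths, cfg.window_bp, cfg.step_bp)
    assign_sites(windows, panel)

    hi_cols = panel.group_indices(HIGH)
    lo_cols = panel.group_indices(LOW)
    alt_h, tot_h = panel.allele_counts(hi_cols)
    alt_l, tot_l = panel.allele_counts(lo_cols)
    a, total = site_fst_components((alt_h, tot_h), (alt_l, tot_l))
    pi_h_sites = site_pi(alt_h, tot_h)
    pi_l_sites = site_pi(alt_l, tot_l)

    rows = []
    for w in windows:
        enough = w.n_sites >= cfg.min_sites_per_window
        fst = window_fst(a, total, w) if enough else np.nan
        pi_h = window_pi(pi_h_sites, w, cfg.pi_per_site) if enough else np.nan
        pi_l = window_pi(pi_l_sites, w, cfg.pi_per_site) if enough else np.nan
        ratio = window_log2_ratio(pi_h, pi_l) if enough else np.nan
        hp_h = window_hp(alt_h, tot_h, w) if enough else np.nan
        hp_l = window_hp(alt_l, tot_l, w) if enough else np.nan
        rows.append((w.contig, w.start, w.end, w.n_sites, fst,
                     pi_h, pi_l, ratio, hp_h, hp_l))
    df = pd.DataFrame(rows, columns=[
        "contig", "start", "end", "n_sites", "fst",
        "pi_high", "pi_low", "log2_ratio", "hp_high", "hp_low"])
    df["zhp_high"] = zhp(df["hp_high"].to_numpy())
    df["zhp_low"] = zhp(df["hp_low"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# candidate selection
# ---------------------------------------------------------------------------

def _tail_pass(values: np.ndarray, q: float, tail: str):
    """Mask of windows in the extreme q-tail; empirical type-7 quantile.

    Ties at the threshold are retained; a statistic constant across all
    defined windows selects nothing (no window strictly exceeds any
    threshold of a degenerate distribution).
    """
    ok = np.isfinite(values)
    passed = np.zeros(values.shape, dtype=bool)
    if ok.sum() == 0:
        return passed, np.nan
    vals = values[ok]
    if vals.min() == vals.max():
        return passed, float(vals.min())
    if tail == UPPER:
        thr = float(np.quantile(vals, 1.0 - q))
        passed[ok] = values[ok] >= thr
    else:
        thr = float(np.quantile(vals, q))
        passed[ok] = values[ok] <= thr
    return passed, thr


def select_candidates(stats: pd.DataFrame, cfg: ScanConfig):
    """Three-way top-quantile intersection → merged candidate regions.

    A window is a candidate iff its F_ST is in the upper tail and its
    log2 θπ ratio and chosen group's ZHp are in their configured tails;
    overlapping or bookended candidate windows are merged.  Returns
    ``(regions, report)`` where the report records the thresholds and the
    pre-/post-merge counts.
    """
    fst = stats["fst"].to_numpy(dtype=float)
    ratio = stats["log2_ratio"].to_numpy(dtype=float)
    zcol = "zhp_high" if cfg.zhp_group == HIGH else "zhp_low"
    zh = stats[zcol].to_numpy(dtype=float)

    defined = np.isfinite(fst) & np.isfinite(ratio) & np.isfinite(zh)
    if defined.sum() < 20:
        raise ValueError("need >= 20 windows with all three statistics")

    pass_fst, thr_fst = _tail_pass(np.where(defined, fst, np.nan),
                                   cfg.top_quantile, UPPER)
    pass_ratio, thr_ratio = _tail_pass(np.where(defined, ratio, np.nan),
                                       cfg.top_quantile, cfg.ratio_tail)
    pass_zhp, thr_zhp = _tail_pass(np.where(defined, zh, np.nan),
                                   cfg.top_quantile, cfg.zhp_tail)
    cand = pass_fst & pass_ratio & pass_zhp

    regions: list[CandidateRegion] = []
    sub = stats.loc[cand].sort_values(["contig", "start"])
    for contig, block in sub.groupby("contig", sort=False):
        cur = None
        for row in block.itertuples(index=False):
            if cur is not None and row.start <= cur["end"]:
                cur["end"] = max(cur["end"], row.end)
                cur["n"] += 1
                cur["fst"] = max(cur["fst"], row.fst)
                cur["ratio"] = min(cur["ratio"], row.log2_ratio)
                cur["zhp"] = min(cur["zhp"], getattr(row, zcol))
            else:
                if cur is not None:
                    regions.append(CandidateRegion(
                        contig, cur["start"], cur["end"], cur["n"],
                        cur["fst"], cur["ratio"], cur["zhp"]))
                cur = {"start": row.start, "end": row.end, "n": 1,
                       "fst": row.fst, "ratio": row.log2_ratio,
                       "zhp": getattr(row, zcol)}
        if cur is not None:
            regions.append(CandidateRegion(
                contig, cur["start"], cur["end"], cur["n"],
                cur["fst"], cur["ratio"], cur["zhp"]))

    report = {
        "threshold_fst": thr_fst,
        "threshold_log2_ratio": thr_ratio,
        "threshold_zhp": thr_zhp,
        "n_windows_defined": int(defined.sum()),
        "n_pass_fst": int(pass_fst.sum()),
        "n_pass_ratio": int(pass_ratio.sum()),
        "n_pass_zhp": int(pass_zhp.sum()),
        "n_candidate_windows": int(cand.sum()),
        "n_candidate_regions": len(regions),
        "n_ratio_excluded_zero_pi": int(
            (~np.isfinite(ratio) & np.isfinite(fst)).sum()),
    }
    return regions, report


def regions_to_bed(regions: list[CandidateRegion], path) -> None:
    """Write candidate regions as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for k, r in enumerate(regions, 1):
            fh.write(f"{r.contig}\t{r.start}\t{r.end}\tregion{k}\t"
                     f"{r.peak_fst:.6g}\t.\n")
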