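"""Site-level quality control: call-rate/MAF/missingness/HWE filters and
LD pruning of a genotype panel.

Two default profiles mirror the two stages of the study design:
``structure`` (call rate >= 0.9, MAF >= 0.05, missing <= 0.05) feeds the
population-structure analyses, ``scan`` (call rate >= 0.996, MAF >= 0.01,
missing <= 0.1) feeds the selection scan.  Both drop sites whose exact
Hardy–Weinberg p falls below 1e-6.  The LD rule follows the PLINK
``--indep 50 5 2`` convention: VIF 2, i.e. pairwise r² > 0.5 within
sliding 50-SNP windows advancing 5 SNPs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .panel import MISSING, GenotypePanel


@dataclass
class QCConfig:
    min_call_rate: float = 0.9
    min_maf: float = 0.05
    max_missing: float = 0.05
    hwe_p_floor: float = 1e-6
    ld_window_snps: int = 50
    ld_step_snps: int = 5
    ld_r2_max: float = 0.5  # 1 - 1/VIF at VIF = 2

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "min_maf", "max_missing",
                     "hwe_p_floor", "ld_r2_max"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not self.ld_window_snps >= self.ld_step_snps >= 1:
            raise ValueError("need ld_window_snps >= ld_step_snps >= 1")


PROFILES: dict[str, QCConfig] = {
    "structure": QCConfig(min_call_rate=0.9, min_maf=0.05, max_missing=0.05),
    "scan": QCConfig(min_call_rate=0.996, min_maf=0.01, max_missing=0.1),
}


@dataclass
class QCReport:
    """First-failure counts per filter, in application order."""

    n_input: int
    fail_call_rate: int
    fail_maf: int
    fail_missing: int
    fail_hwe: int
    retained: int

    def __post_init__(self) -> None:
        total = (self.fail_call_rate + self.fail_maf + self.fail_missing
                 + self.fail_hwe + self.retained)
        if total != self.n_input:
            raise ValueError("QC report counts do not sum to input sites")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy–Weinberg test p-value.

    Enumerates every heterozygote count consistent with the observed
    allele counts and sums the probabilities of configurations no more
    likely than the observed one under the exact HWE distribution
    (the Wigginton/Cutler/Abecasis construction).  Monomorphic sites
    return 1.0 by convention.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotype")
    n_a = 2 * n_aa + n_Aa  # minor-ish allele count, symmetric below
    n_A = 2 * n_AA + n_Aa
    rare = min(n_a, n_A)
    if rare == 0:
        return 1.0

    # P(het = h | n, rare) up to a common constant, via the recurrence
    #   P(h+2)/P(h) = 4 * hom_rare(h) * hom_common(h) / ((h+2)(h+1))
    # over all feasible h of the right parity, then normalise.
    h_values = list(range(rare % 2, rare + 1, 2))
    probs = np.empty(len(h_values))
    probs[0] = 1.0
    for k in range(1, len(h_values)):
        h = h_values[k - 1]
        hom_rare = (rare - h) // 2
        hom_common = n - hom_rare - h
        probs[k] = probs[k - 1] * 4.0 * hom_rare * hom_common \
            / ((h + 2.0) * (h + 1.0))
    probs /= probs.sum()

    obs = n_Aa
    p_obs = probs[h_values.index(obs)]
    p = probs[probs <= p_obs * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def hwe_pvalues(panel: GenotypePanel) -> np.ndarray:
    """Exact HWE p-value per site (missing genotypes excluded)."""
    out = np.empty(panel.n_sites)
    g = panel.genotypes
    for i in range(panel.n_sites):
        row = g[i]
        called = row[row != MISSING]
        n_aa = int(np.sum(called == 2))
        n_Aa = int(np.sum(called == 1))
        n_AA = int(np.sum(called == 0))
        out[i] = hwe_exact_test(n_AA, n_Aa, n_aa) if called.size else 1.0
    return out


# ---------------------------------------------------------------------------
# site filters
# ---------------------------------------------------------------------------

def apply_site_filters(panel: GenotypePanel, cfg: QCConfig):
    """Filter sites in order call-rate → MAF → missingness → HWE.

    Returns ``(filtered_panel, QCReport)``.  Each failing site is
    attributed to the first filter it fails; the retained set itself is
    order-independent for the threshold filters.
    """
    if panel.n_sites == 0:
        raise ValueError("empty panel")
    cr = panel.call_rate()
    maf = panel.maf()
    miss = 1.0 - cr
    hwe = hwe_pvalues(panel)

    ok_cr = cr >= cfg.min_call_rate
    ok_maf = np.nan_to_num(maf, nan=-1.0) >= cfg.min_maf
    ok_miss = miss <= cfg.max_missing
    ok_hwe = hwe >= cfg.hwe_p_floor

    fail_cr = ~ok_cr
    fail_maf = ok_cr & ~ok_maf
    fail_miss = ok_cr & ok_maf & ~ok_miss
    fail_hwe = ok_cr & ok_maf & ok_miss & ~ok_hwe
    keep = ok_cr & ok_maf & ok_miss & ok_hwe

    report = QCReport(
        n_input=panel.n_sites,
        fail_call_rate=int(fail_cr.sum()),
        fail_maf=int(fail_maf.sum()),
        fail_missing=int(fail_miss.sum()),
        fail_hwe=int(fail_hwe.sum()),
        retained=int(keep.sum()),
    )
    return panel.subset_sites(np.flatnonzero(keep)), report


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def ld_r2(dosages_i: np.ndarray, dosages_j: np.ndarray) -> float | None:
    """Squared Pearson correlation of two dosage vectors.

    Computed over pairwise-complete samples; 0.0 when either site has no
    variance; ``None`` (pair unusable) with fewer than 2 complete pairs.
    """
    x = np.asarray(dosages_i, dtype=float)
    y = np.asarray(dosages_j, dtype=float)
    if x.shape != y.shape:
        raise ValueError("dosage vectors differ in length")
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return None
    x, y = x[ok], y[ok]
    vx = x.var()
    vy = y.var()
    if vx == 0.0 or vy == 0.0:
        return 0.0
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov * cov / (vx * vy))


def _prune_pass(geno: np.ndarray, maf: np.ndarray, kept: list[int],
                cfg: QCConfig) -> list[int]:
    """One sliding-window pass over the currently kept sites."""
    alive = set(kept)
    order = list(kept)
    start = 0
    while start < len(order):
        window = [s for s in order[start:start + cfg.ld_window_snps]
                  if s in alive]
        for a in range(len(window)):
            i = window[a]
            if i not in alive:
                continue
            for b in range(a + 1, len(window)):
                j = window[b]
                if j not in alive or i not in alive:
                    continue
                r2 = ld_r2(geno[i], geno[j])
                if r2 is None or r2 <= cfg.ld_r2_max:
                    continue
                # drop the lower-MAF site; ties drop the higher index
                if maf[i] < maf[j]:
                    drop = i
                elif maf[j] < maf[i]:
                    drop = j
                else:
                    drop = max(i, j)
                alive.discard(drop)
                if drop == i:
                    break
        start += cfg.ld_step_snps
    return [s for s in order if s in alive]


def ld_prune(panel: GenotypePanel, cfg: QCConfig) -> np.ndarray:
    """Greedy windowed LD pruning; returns kept site indices.

    Windows of ``ld_window_snps`` sites advance by ``ld_step_snps``
    within each contig; in every window the lower-MAF member of any pair
    with r² above ``ld_r2_max`` is dropped (ties drop the higher index).
    Passes repeat — with windows laid over the surviving sites — until no
    site is removed, so the result is idempotent and free of
    within-window pairs above the threshold.
    """
    geno = panel.genotypes
    maf = panel.maf()
    kept_all: list[int] = []
    for contig in panel.sites["contig"].unique():
        idx = np.flatnonzero((panel.sites["contig"] == contig).to_numpy())
        kept = list(idx)
        while True:
            new = _prune_pass(geno, maf, kept, cfg)
            if len(new) == len(kept):
                break
            kept = new
        kept_all.extend(kept)
    return np.asarray(sorted(kept_all), dtype=int)
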