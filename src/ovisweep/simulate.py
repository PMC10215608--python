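"""Synthetic study generator with planted ground truth.

Emulates the data a divergent milk-yield contrast produces: two sheep
groups genotyped genome-wide with neutral background differentiation and
planted selective sweeps; a shallow pedigree with additive breeding
values under the milk-yield animal model; and qPCR CT tables with a known
linear ΔCT–yield relationship.  Every generator is deterministic given
its seed, so downstream stages can be tested against the planted truth
without any external download.

Frequency model
---------------
Background differentiation follows the Balding–Nichols model: each site
draws an ancestral frequency p ~ Uniform(0.05, 0.95) and each group an
own frequency from Beta(p(1-F)/F, (1-p)(1-F)/F), so that F is the
expected fixation index between the groups.  Inside a sweep window a
``sweep_intensity`` fraction of sites is driven near fixation
(alt frequency <= 0.02) in the swept group only, depressing that group's
diversity and heterozygosity while inflating differentiation — the
classic hard-sweep footprint the windowed scan is built to find.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import HIGH, LOW, GenotypePanel

_BASES = np.array(list("ACGT"))

# Default fixed-effect structure of the milk-yield animal model:
# lactation-day class, lactation number, birth year, daily milking times.
DEFAULT_FIXED_EFFECT_LEVELS = {
    "lactation_days_class": 4,
    "lactation_number": 3,
    "birth_year": 3,
    "milking_times": 2,
}

QPCR_GENES = ["FCGR3A", "CTSK", "CTSS", "ARNT"]
QPCR_REFERENCE_GENE = "GAPDH"


@dataclass
class SimulationConfig:
    """Parameters of the two-population genotype simulation.

    Defaults reflect the study design being emulated: two groups of 50
    diploids, five 1-Mb contigs, background F_ST 0.05 and hard sweeps of
    intensity 0.9 planted in the high-yield group.
    """

    n_high: int = 50
    n_low: int = 50
    n_contigs: int = 5
    contig_length: int = 1_000_000
    n_sites: int = 2_000  # per contig
    background_fst: float = 0.05
    sweep_windows: list[tuple] = field(default_factory=list)
    # (contig, start 0-based, end exclusive, swept group "high"/"low")
    sweep_intensity: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_high < 2 or self.n_low < 2:
            raise ValueError("need at least 2 diploids per group")
        if not (0 <= self.background_fst < 1):
            raise ValueError("background_fst must be in [0, 1)")
        if not (0 < self.sweep_intensity <= 1):
            raise ValueError("sweep_intensity must be in (0, 1]")
        by_contig: dict[str, list[tuple[int, int]]] = {}
        for contig, start, end, group in self.sweep_windows:
            if not (0 <= start < end <= self.contig_length):
                raise ValueError(
                    f"sweep window ({start}, {end}) outside contig bounds"
                )
            if group not in (HIGH, LOW):
                raise ValueError(f"unknown swept group {group!r}")
            by_contig.setdefault(contig, []).append((start, end))
        for contig, spans in by_contig.items():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"overlapping sweep windows on contig {contig}"
                    )

    @property
    def contig_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_contigs)]

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {c: self.contig_length for c in self.contig_names}


@dataclass
class TruthSet:
    """Planted ground truth for recovery tests."""

    sweep_regions: list[tuple] = field(default_factory=list)
    causal_genes: list[str] = field(default_factory=list)
    true_breeding_values: dict[str, float] = field(default_factory=dict)
    true_dct_slope: float = 0.0


# ---------------------------------------------------------------------------
# two-population genotypes
# ---------------------------------------------------------------------------

def simulate_two_pop_genotypes(config: SimulationConfig):
    """Draw a two-group genotype panel with planted sweeps.

    Returns ``(panel, truth)``.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    F = config.background_fst
    n_h, n_l = config.n_high, config.n_low
    samples = [f"HY{i + 1:03d}" for i in range(n_h)] + \
              [f"LY{i + 1:03d}" for i in range(n_l)]
    groups = {s: (HIGH if s.startswith("HY") else LOW) for s in samples}

    site_rows = []
    geno_blocks = []
    for contig in config.contig_names:
        pos = np.sort(rng.choice(
            np.arange(1, config.contig_length + 1),
            size=config.n_sites, replace=False))
        p_anc = rng.uniform(0.05, 0.95, size=config.n_sites)
        if F > 0:
            a = p_anc * (1 - F) / F
            b = (1 - p_anc) * (1 - F) / F
            p_high = rng.beta(a, b)
            p_low = rng.beta(a, b)
        else:
            p_high = p_anc.copy()
            p_low = p_anc.copy()

        for (c, start, end, swept) in config.sweep_windows:
            if c != contig:
                continue
            in_win = (pos > start) & (pos <= end)
            idx = np.flatnonzero(in_win)
            n_swept = int(round(config.sweep_intensity * idx.size))
            chosen = rng.choice(idx, size=n_swept, replace=False)
            near_fixed = rng.uniform(0.0, 0.02, size=n_swept)
            if swept == HIGH:
                p_high[chosen] = near_fixed
            else:
                p_low[chosen] = near_fixed

        g_high = rng.binomial(2, p_high[:, None], size=(config.n_sites, n_h))
        g_low = rng.binomial(2, p_low[:, None], size=(config.n_sites, n_l))
        geno_blocks.append(np.hstack([g_high, g_low]).astype(np.int8))

        ref_idx = rng.integers(0, 4, size=config.n_sites)
        alt_idx = (ref_idx + rng.integers(1, 4, size=config.n_sites)) % 4
        site_rows.append(pd.DataFrame({
            "contig": contig, "pos": pos,
            "ref": _BASES[ref_idx], "alt": _BASES[alt_idx],
        }))

    panel = GenotypePanel(
        sites=pd.concat(site_rows, ignore_index=True),
        genotypes=np.vstack(geno_blocks),
        samples=samples,
        groups=groups,
    )
    truth = TruthSet(sweep_regions=list(config.sweep_windows))
    return panel, truth


# ---------------------------------------------------------------------------
# pedigree + phenotypes under the animal model
# ---------------------------------------------------------------------------

def simulate_pedigree_phenotypes(
    n_founders: int = 100,
    n_generations: int = 3,
    h2: float = 0.3,
    fixed_effect_levels: dict[str, int] | None = None,
    seed: int = 0,
    beta: float = 0.5,
):
    """Random-mating pedigree with phenotypes y = fixed + beta*x + BV + e.

    Breeding values are additive with variance ``sigma_a^2 = h2`` (total
    genetic + residual variance 1): founders draw N(0, h2); a non-founder
    gets the parental mean plus Mendelian-sampling noise of variance
    ``h2 / 2`` (parental inbreeding ignored — adequate for shallow
    pedigrees).  Each generation has ``n_founders`` animals.

    Returns ``(pedigree_df, phenotype_df, truth)`` where the pedigree has
    columns ``animal, sire, dam`` ("0" = unknown) and the phenotype table
    one row per animal with the fixed-effect factor levels, the covariate
    and the milk-yield record.
    """
    if n_founders < 2:
        raise ValueError("need at least 2 founders")
    if not (0 < h2 < 1):
        raise ValueError("h2 must be in (0, 1)")
    levels = fixed_effect_levels or DEFAULT_FIXED_EFFECT_LEVELS
    rng = np.random.default_rng(seed)
    sigma_a2, sigma_e2 = h2, 1.0 - h2

    animals: list[str] = []
    sires: list[str] = []
    dams: list[str] = []
    bv: dict[str, float] = {}

    def new_id() -> str:
        return f"A{len(animals) + 1:05d}"

    prev_gen: list[str] = []
    for gen in range(n_generations):
        cur: list[str] = []
        for _ in range(n_founders):
            aid = new_id()
            if gen == 0:
                s = d = "0"
                bv[aid] = rng.normal(0.0, np.sqrt(sigma_a2))
            else:
                s, d = rng.choice(prev_gen, size=2, replace=False)
                bv[aid] = 0.5 * (bv[s] + bv[d]) + \
                    rng.normal(0.0, np.sqrt(sigma_a2 / 2.0))
            animals.append(aid)
            sires.append(s)
            dams.append(d)
            cur.append(aid)
        prev_gen = cur

    ped = pd.DataFrame({"animal": animals, "sire": sires, "dam": dams})

    effect_values = {
        factor: rng.normal(0.0, 0.5, size=n) for factor, n in levels.items()
    }
    n = len(animals)
    pheno = pd.DataFrame({"animal": animals})
    fixed_part = np.zeros(n)
    for factor, nlev in levels.items():
        lev = rng.integers(0, nlev, size=n)
        pheno[factor] = lev + 1  # 1-based level codes, as recorded on-farm
        fixed_part += effect_values[factor][lev]
    x = rng.normal(0.0, 1.0, size=n)
    pheno["covariate"] = x
    resid = rng.normal(0.0, np.sqrt(sigma_e2), size=n)
    u = np.array([bv[a] for a in animals])
    pheno["milk_yield"] = fixed_part + beta * x + u + resid
    pheno["fixed_part"] = fixed_part + beta * x

    truth = TruthSet(true_breeding_values=dict(bv))
    return ped, pheno, truth


# ---------------------------------------------------------------------------
# qPCR CT tables
# ---------------------------------------------------------------------------

def simulate_qpcr_table(
    n_ewes: int = 11,
    genes: list[str] | None = None,
    true_dct_slope: float = 1.2,
    noise_sd: float = 0.5,
    seed: int = 0,
    causal_gene: str | None = None,
    reference_gene: str = QPCR_REFERENCE_GENE,
    yield_range: tuple[float, float] = (1.0, 4.0),
):
    """CT table for target genes + reference with a planted ΔCT–yield slope.

    Daily milk yields are uniform over ``yield_range`` (litres/day, a
    realistic span for dairy ewes).  Reference-gene CT ~ N(20, 0.2).  The
    causal gene's ΔCT is ``a + true_dct_slope * yield + N(0, noise_sd²)``
    (higher ΔCT = lower expression, so a positive slope encodes expression
    falling with yield); null genes have slope 0.  Two technical
    replicates per well, with replicate scatter ``noise_sd / 2``.

    Returns ``(ct_df, yield_df, truth)``; ``ct_df`` has columns
    ``ewe, gene, replicate, ct``.
    """
    if n_ewes < 3:
        raise ValueError("need at least 3 ewes")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    genes = list(genes) if genes is not None else list(QPCR_GENES)
    causal = causal_gene if causal_gene is not None else genes[0]
    if causal not in genes:
        raise ValueError(f"causal gene {causal!r} not among targets")
    rng = np.random.default_rng(seed)

    ewes = [f"ewe{i + 1:02d}" for i in range(n_ewes)]
    yields = rng.uniform(*yield_range, size=n_ewes)
    ct_ref = rng.normal(20.0, 0.2, size=n_ewes)
    intercept = 0.5
    rep_sd = noise_sd / 2.0

    records = []
    for i, ewe in enumerate(ewes):
        for rep in (1, 2):
            records.append((ewe, reference_gene, rep,
                            ct_ref[i] + rng.normal(0.0, rep_sd)
                            if rep_sd > 0 else ct_ref[i]))
    for gene in genes:
        slope = true_dct_slope if gene == causal else 0.0
        dct = intercept + slope * yields + \
            (rng.normal(0.0, noise_sd, size=n_ewes) if noise_sd > 0
             else np.zeros(n_ewes))
        for i, ewe in enumerate(ewes):
            ct_t = ct_ref[i] + dct[i]
            for rep in (1, 2):
                records.append((ewe, gene, rep,
                                ct_t + rng.normal(0.0, rep_sd)
                                if rep_sd > 0 else ct_t))

    ct_df = pd.DataFrame(records, columns=["ewe", "gene", "replicate", "ct"])
    yield_df = pd.DataFrame({"ewe": ewes, "milk_yield": yields})
    truth = TruthSet(true_dct_slope=true_dct_slope,
                     causal_genes=[causal])
    return ct_df, yield_df, truth


# ---------------------------------------------------------------------------
# synthetic gene annotation
# ---------------------------------------------------------------------------

def write_gene_annotation(
    config: SimulationConfig,
    truth: TruthSet,
    gff_path=None,
    bed_path=None,
    gene_length: int = 10_000,
    gene_spacing: int = 20_000,
):
    """Tile contigs with non-overlapping synthetic genes; mark causal ones.

    Genes start every ``gene_spacing`` bp and span ``gene_length`` bp
    (0-based half-open internally).  A gene overlapping any sweep window
    is recorded in ``truth.causal_genes``.  Writes GFF3 (1-based closed)
    and/or BED6 (0-based half-open) when paths are given; returns the
    gene table as a DataFrame with 0-based half-open coordinates.
    """
    rows = []
    causal: list[str] = []
    k = 0
    for contig in config.contig_names:
        for start in range(0, config.contig_length - gene_length + 1,
                           gene_spacing):
            k += 1
            gid = f"SYNG{k:05d}"
            end = start + gene_length
            is_causal = any(
                c == contig and start < we and wstart < end
                for (c, wstart, we, _grp) in truth.sweep_regions
            )
            if is_causal:
                causal.append(gid)
            rows.append((gid, contig, start, end, "+" if k % 2 else "-"))
    genes = pd.DataFrame(rows, columns=["gene_id", "contig", "start", "end",
                                        "strand"])
    truth.causal_genes = causal

    if gff_path is not None:
        with open(gff_path, "w") as fh:
            fh.write("##gff-version 3\n")
            for c, length in config.contig_lengths.items():
                fh.write(f"##sequence-region {c} 1 {length}\n")
            for r in genes.itertuples(index=False):
                fh.write(f"{r.contig}\tovisweep\tgene\t{r.start + 1}\t{r.end}"
                         f"\t.\t{r.strand}\t.\tID={r.gene_id};"
                         f"Name={r.gene_id}\n")
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for r in genes.itertuples(index=False):
                fh.write(f"{r.contig}\t{r.start}\t{r.end}\t{r.gene_id}\t0\t"
                         f"{r.strand}\n")
    return genes
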