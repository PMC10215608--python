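"""Genotype panel container and VCF / sample-group I/O.

The panel holds diploid biallelic SNP genotypes as an alt-allele dosage
matrix (sites x samples, values 0/1/2, -1 = missing) together with
per-site metadata and a sample-to-group assignment.  All downstream
statistics (QC, structure, selection scan) operate on this container.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = -1

#: group labels for the divergent-phenotype contrast
HIGH, LOW = "high", "low"


@dataclass
class GenotypePanel:
    """Sites x samples diploid genotype matrix with metadata.

    Parameters
    ----------
    sites : pandas.DataFrame
        Columns ``contig`` (str), ``pos`` (int, 1-based), ``ref``, ``alt``.
        Positions are strictly increasing within a contig.
    genotypes : numpy.ndarray
        ``(n_sites, n_samples)`` int8 array of alt-allele dosages
        {0, 1, 2}, with ``-1`` marking a missing call.
    samples : list of str
        Sample identifiers, in genotype-column order.
    groups : dict
        ``sample -> group`` map; groups are free-form labels but the
        selection scan expects exactly ``{"high", "low"}``.
    """

    sites: pd.DataFrame
    genotypes: np.ndarray
    samples: list[str] = field(default_factory=list)
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D sites x samples matrix")
        n_sites, n_samples = self.genotypes.shape
        if len(self.sites) != n_sites:
            raise ValueError(
                f"site table has {len(self.sites)} rows but genotype matrix "
                f"has {n_sites}"
            )
        if len(self.samples) != n_samples:
            raise ValueError(
                f"{len(self.samples)} sample ids for {n_samples} genotype columns"
            )
        for s in self.samples:
            if s not in self.groups:
                raise ValueError(f"sample {s!r} missing from group map")
        for contig, sub in self.sites.groupby("contig", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"positions not strictly increasing on contig {contig}"
                )

    # -- basic shape ----------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[1]

    def group_indices(self, group: str) -> np.ndarray:
        """Column indices of samples belonging to ``group``."""
        idx = [i for i, s in enumerate(self.samples) if self.groups[s] == group]
        if not idx:
            raise ValueError(f"no samples in group {group!r}")
        return np.asarray(idx, dtype=int)

    def subset_sites(self, index: np.ndarray) -> "GenotypePanel":
        """New panel restricted to the given site indices (order kept)."""
        index = np.asarray(index, dtype=int)
        return GenotypePanel(
            sites=self.sites.iloc[index].reset_index(drop=True),
            genotypes=self.genotypes[index],
            samples=list(self.samples),
            groups=dict(self.groups),
        )

    # -- per-site summaries ---------------------------------------------
    def allele_counts(self, columns: np.ndarray | None = None):
        """Per-site (alt allele count, called allele total).

        Restricted to the given sample columns when provided.  Returns two
        int arrays of length ``n_sites``.
        """
        g = self.genotypes if columns is None else self.genotypes[:, columns]
        called = g != MISSING
        alt = np.where(called, g, 0).sum(axis=1)
        tot = 2 * called.sum(axis=1)
        return alt.astype(np.int64), tot.astype(np.int64)

    def call_rate(self) -> np.ndarray:
        """Fraction of non-missing genotype calls per site."""
        return (self.genotypes != MISSING).mean(axis=1)

    def maf(self) -> np.ndarray:
        """Minor-allele frequency from non-missing alleles; NaN when no calls."""
        alt, tot = self.allele_counts()
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
        return np.minimum(p, 1.0 - p)


# ---------------------------------------------------------------------------
# sample-group table
# ---------------------------------------------------------------------------

def read_groups_tsv(path) -> dict[str, str]:
    """Read a two-column ``sample<TAB>group`` table (no header)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"],
                     dtype=str, comment="#")
    return dict(zip(df["sample"], df["group"]))


def write_groups_tsv(groups: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for sample, group in groups.items():
            fh.write(f"{sample}\t{group}\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, groups: dict[str, str]) -> GenotypePanel:
    """Parse a VCF into a :class:`GenotypePanel`.

    Multiallelic and non-SNP records are skipped (a count is logged);
    half-calls are treated as missing.  Every VCF sample must appear in
    ``groups``.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError on parse trouble
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in groups]
    if unknown:
        raise ValueError(f"VCF samples missing from group table: {unknown}")

    rows, dosages = [], []
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or not v.is_snp:
            n_skipped += 1
            continue
        gt = np.asarray(v.genotype.array())  # (n_samples, 3): a0, a1, phased
        a0, a1 = gt[:, 0], gt[:, 1]
        dose = np.where((a0 < 0) | (a1 < 0), MISSING, a0 + a1).astype(np.int8)
        rows.append((v.CHROM, v.POS, v.REF, v.ALT[0]))
        dosages.append(dose)
    if n_skipped:
        log.info("read_vcf: skipped %d multiallelic/non-SNP records", n_skipped)

    sites = pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt"])
    geno = (np.vstack(dosages) if dosages
            else np.empty((0, len(samples)), dtype=np.int8))
    return GenotypePanel(sites=sites, genotypes=geno, samples=samples,
                         groups={s: groups[s] for s in samples})


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=ovisweep
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""

_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(panel: GenotypePanel, path,
              contig_lengths: dict[str, int] | None = None) -> None:
    """Write the panel as an unphased biallelic-SNP VCF v4.2.

    Contig header lines use ``contig_lengths`` when given, else the last
    SNP position per contig.
    """
    if contig_lengths is None:
        contig_lengths = {
            c: int(sub["pos"].max())
            for c, sub in panel.sites.groupby("contig", sort=False)
        }
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for contig, length in contig_lengths.items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.samples) + "\n")
        sites = panel.sites
        for i in range(panel.n_sites):
            row = sites.iloc[i]
            gts = "\t".join(_GT_STR[int(g)] for g in panel.genotypes[i])
            fh.write(f"{row.contig}\t{row.pos}\t.\t{row.ref}\t{row.alt}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")
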