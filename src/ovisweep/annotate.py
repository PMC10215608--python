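"""Candidate-region gene annotation and generic term enrichment.

Gene models are stored 0-based half-open internally; the GFF3 (1-based
closed) and BED (already half-open) conventions are converted at the
I/O boundary only.  Enrichment is a plain one-sided hypergeometric test
over a user-supplied term→gene map with Benjamini–Hochberg correction —
a self-contained stand-in for web-service GO/KEGG enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .scan import CandidateRegion

STRANDS = {"+", "-", "."}


@dataclass
class GeneModel:
    gene_id: str
    name: str
    contig: str
    start: int  # 0-based half-open
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} >= end {self.end}")
        if self.strand not in STRANDS:
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass
class EnrichmentResult:
    term: str
    term_size: int
    overlap: int
    p_value: float
    q_value: float


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_annotation(path) -> list[GeneModel]:
    """Read gene models from GFF3 or BED (by extension).

    GFF3: only ``gene``-type features are retained and their 1-based
    closed intervals become 0-based half-open.  BED intervals are taken
    as-is.
    """
    p = str(path)
    if p.endswith((".bed", ".bed6")):
        return _read_bed(p)
    return _read_gff3(p)


def _read_bed(path: str) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            if end < start:
                raise ValueError(f"{path}:{lineno}: end {end} < start {start}")
            name = parts[3] if len(parts) > 3 else f"bed{lineno}"
            strand = parts[5] if len(parts) > 5 and parts[5] in STRANDS else "."
            genes.append(GeneModel(name, name, contig, start, end, strand))
    return genes


def _read_gff3(path: str) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(path, ":memory:", force=True,
                            merge_strategy="create_unique")
    genes: list[GeneModel] = []
    for f in db.features_of_type("gene"):
        if f.end < f.start:
            raise ValueError(
                f"{path}: gene {f.id}: end {f.end} < start {f.start}")
        name = f.attributes.get("Name", [f.id])[0]
        strand = f.strand if f.strand in STRANDS else "."
        genes.append(GeneModel(f.id, name, f.seqid, f.start - 1, f.end,
                               strand))
    return genes


def write_bed(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.contig}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t"
                     f"{g.strand}\n")


# ---------------------------------------------------------------------------
# overlap
# ---------------------------------------------------------------------------

def overlap_genes(regions: list[CandidateRegion],
                  genes: list[GeneModel]) -> dict:
    """Map each region to the genes it intersects (half-open, >= 1 bp).

    Endpoint-sorted sweep per contig; strand is ignored.  Returns
    ``{(contig, start, end): [GeneModel, ...]}`` with genes in genomic
    order.
    """
    by_contig: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_contig.setdefault(g.contig, []).append(g)
    for lst in by_contig.values():
        lst.sort(key=lambda g: g.start)

    out: dict[tuple, list[GeneModel]] = {}
    for r in regions:
        hits: list[GeneModel] = []
        glist = by_contig.get(r.contig, [])
        starts = np.array([g.start for g in glist])
        ends = np.array([g.end for g in glist])
        if glist:
            # candidates: gene.start < r.end and gene.end > r.start
            hi = int(np.searchsorted(starts, r.end, side="left"))
            sel = np.flatnonzero(ends[:hi] > r.start)
            hits = [glist[i] for i in sel]
        out[(r.contig, r.start, r.end)] = hits
    return out


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def read_term_map(path) -> dict[str, set]:
    """Two-column ``term<TAB>gene`` TSV → term → gene-set map."""
    df = pd.read_csv(path, sep="\t", header=None, names=["term", "gene"],
                     dtype=str, comment="#")
    out: dict[str, set] = {}
    for term, gene in zip(df["term"], df["gene"]):
        out.setdefault(term, set()).add(gene)
    return out


def hypergeometric_enrichment(query_genes, background_genes,
                              term_map: dict) -> list[EnrichmentResult]:
    """One-sided hypergeometric enrichment with BH correction.

    ``query_genes`` must be a subset of ``background_genes``.  Terms are
    intersected with the background; zero-overlap terms report p = 1.
    Results are sorted by p-value.
    """
    background = set(background_genes)
    if not background:
        raise ValueError("empty background")
    query = set(query_genes)
    if not query <= background:
        raise ValueError("query genes must be a subset of the background")

    M, N = len(background), len(query)
    rows = []
    for term, genes in term_map.items():
        members = set(genes) & background
        K = len(members)
        k = len(members & query)
        # upper tail: P(X >= k)
        p = 1.0 if k == 0 else float(hypergeom.sf(k - 1, M, K, N))
        rows.append((term, K, k, min(p, 1.0)))
    if not rows:
        return []
    pvals = [r[3] for r in rows]
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    results = [EnrichmentResult(t, K, k, p, float(q))
               for (t, K, k, p), q in zip(rows, qvals)]
    results.sort(key=lambda r: (r.p_value, r.term))
    return results
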