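"""Basal-plus-extension regulatory domains and region-to-gene assignment.

Every gene gets a basal domain around its TSS (default 5 kb upstream, 1 kb
downstream, strand-aware, regardless of neighbours).  The domain is then
extended in both directions, up to a cap measured from the TSS (default
1 Mb), until it meets a neighbouring gene's basal domain or the chromosome
edge.  A genomic region — or a SNP, treated as a width-1 region — is
associated with every gene whose (extended, by default) regulatory domain it
overlaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

from intervaltree import IntervalTree

from .genomic_io import ChromSizes, GeneModel, GenomicInterval, SnpSet


@dataclass(frozen=True)
class DomainParams:
    """Basal window sizes and the maximum extension, all in bases from the TSS."""

    up_bp: int = 5_000
    down_bp: int = 1_000
    max_ext_bp: int = 1_000_000

    def __post_init__(self) -> None:
        if min(self.up_bp, self.down_bp, self.max_ext_bp) < 0:
            raise ValueError("domain distances must be >= 0")
        if self.max_ext_bp < max(self.up_bp, self.down_bp):
            raise ValueError("max_ext_bp must be >= max(up_bp, down_bp)")


@dataclass(frozen=True)
class RegulatoryDomain:
    gene_id: str
    chrom: str
    basal: GenomicInterval
    extended: GenomicInterval

    def __post_init__(self) -> None:
        if not (self.extended.start <= self.basal.start and self.basal.end <= self.extended.end):
            raise ValueError(f"basal domain of {self.gene_id} not contained in extended domain")


@dataclass(frozen=True)
class RegionGeneAssignment:
    region_id: str
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError(f"duplicate gene ids for region {self.region_id}")


def _basal_bounds(gene: GeneModel, params: DomainParams, chrom_len: int) -> tuple[int, int]:
    if gene.strand == "+":
        lo, hi = gene.tss - params.up_bp, gene.tss + params.down_bp
    else:
        lo, hi = gene.tss - params.down_bp, gene.tss + params.up_bp
    # the basal domain always contains the TSS base, even with a zero width
    lo = min(lo, gene.tss)
    hi = max(hi, gene.tss + 1)
    return max(lo, 0), min(hi, chrom_len)


def build_basal_domains(
    genes: Sequence[GeneModel],
    params: DomainParams = DomainParams(),
    sizes: ChromSizes | None = None,
) -> list[RegulatoryDomain]:
    """Strand-aware basal windows, clipped to the chromosome; the TSS is
    always inside its own basal domain."""
    if sizes is not None:
        sizes.check_covers(g.chrom for g in genes)
    out = []
    for g in genes:
        chrom_len = sizes[g.chrom] if sizes is not None else None
        if chrom_len is not None and g.tss >= chrom_len:
            raise ValueError(f"gene {g.gene_id}: tss {g.tss} outside chromosome {g.chrom}")
        lo, hi = _basal_bounds(g, params, chrom_len if chrom_len is not None else g.tss + params.max_ext_bp + 1)
        iv = GenomicInterval(g.chrom, lo, hi)
        out.append(RegulatoryDomain(gene_id=g.gene_id, chrom=g.chrom, basal=iv, extended=iv))
    return out


def extend_domains(
    basal_domains: Sequence[RegulatoryDomain],
    genes: Sequence[GeneModel],
    params: DomainParams = DomainParams(),
    sizes: ChromSizes | None = None,
) -> list[RegulatoryDomain]:
    """Extend each basal domain toward neighbouring basal domains.

    The extension on each side stops at the nearest other gene's basal-domain
    edge on that side (neighbours are all genes on the chromosome, strand
    ignored; genes with an identical TSS bound each other on both sides), at
    ``max_ext_bp`` from the TSS, or at the chromosome boundary — whichever is
    closest.  The gene's own basal domain is never truncated: the extended
    domain is the union of the basal window and the extension interval.
    """
    by_id = {d.gene_id: d for d in basal_domains}
    gene_by_id = {g.gene_id: g for g in genes}
    if set(by_id) != set(gene_by_id):
        raise ValueError("basal_domains and genes must cover the same gene ids")
    by_chrom: dict[str, list[str]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g.gene_id)

    out = []
    for chrom, ids in by_chrom.items():
        chrom_len = sizes[chrom] if sizes is not None else None
        ids_sorted = sorted(ids, key=lambda i: (gene_by_id[i].tss, i))
        for gid in ids_sorted:
            g = gene_by_id[gid]
            basal = by_id[gid].basal
            left_edges = [
                by_id[o].basal.end
                for o in ids_sorted
                if o != gid and gene_by_id[o].tss <= g.tss
            ]
            right_edges = [
                by_id[o].basal.start
                for o in ids_sorted
                if o != gid and gene_by_id[o].tss >= g.tss
            ]
            ext_lo = max(g.tss - params.max_ext_bp, 0, *left_edges) if left_edges else max(
                g.tss - params.max_ext_bp, 0
            )
            hi_cap = g.tss + params.max_ext_bp
            if chrom_len is not None:
                hi_cap = min(hi_cap, chrom_len)
            ext_hi = min([hi_cap, *right_edges]) if right_edges else hi_cap
            lo = min(basal.start, ext_lo)
            hi = max(basal.end, ext_hi)
            out.append(
                RegulatoryDomain(
                    gene_id=gid,
                    chrom=chrom,
                    basal=basal,
                    extended=GenomicInterval(chrom, lo, hi),
                )
            )
    # deterministic output order regardless of input order
    out.sort(key=lambda d: (d.chrom, d.extended.start, d.gene_id))
    return out


def build_regulatory_domains(
    genes: Sequence[GeneModel],
    params: DomainParams = DomainParams(),
    sizes: ChromSizes | None = None,
) -> list[RegulatoryDomain]:
    """Convenience composition of basal construction and extension."""
    return extend_domains(build_basal_domains(genes, params, sizes), genes, params, sizes)


Regions = Union[Sequence[GenomicInterval], SnpSet]


def _iter_regions(regions: Regions) -> Iterable[tuple[str, GenomicInterval]]:
    if isinstance(regions, SnpSet):
        for rec in regions:
            yield f"{rec.chrom}:{rec.pos}:{rec.ref}>{rec.alt}", GenomicInterval(
                rec.chrom, rec.pos0, rec.pos0 + 1
            )
    else:
        for iv in regions:
            yield f"{iv.chrom}:{iv.start}-{iv.end}", iv


def assign_regions_to_genes(
    regions: Regions,
    domains: Sequence[RegulatoryDomain],
    use_basal_only: bool = False,
) -> tuple[list[RegionGeneAssignment], list[str]]:
    """Associate every region with all genes whose regulatory domain it
    overlaps (half-open semantics).

    Returns the per-region assignments (gene list possibly empty) and the
    deduplicated, sorted list of genes hit by at least one region — the
    "pDHS gene" list when the regions are pDHS SNPs.
    """
    trees: dict[str, IntervalTree] = {}
    for d in domains:
        iv = d.basal if use_basal_only else d.extended
        trees.setdefault(d.chrom, IntervalTree()).addi(iv.start, iv.end, d.gene_id)
    assignments = []
    hit_genes: set[str] = set()
    for region_id, iv in _iter_regions(regions):
        tree = trees.get(iv.chrom)
        gene_ids: tuple[str, ...] = ()
        if tree is not None:
            gene_ids = tuple(sorted({hit.data for hit in tree.overlap(iv.start, iv.end)}))
        hit_genes.update(gene_ids)
        assignments.append(RegionGeneAssignment(region_id=region_id, gene_ids=gene_ids))
    return assignments, sorted(hit_genes)
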