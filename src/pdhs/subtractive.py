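"""Subtractive screen: restrict target-strain SNPs to DNase-hypersensitive
sites and remove variants shared with a comparator strain.

The product is the polymorphic-DHS (pDHS) SNP set: strain-specific variants
that fall in open chromatin and are therefore candidates for cis-regulatory
differences between the strains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Literal, Sequence

from intervaltree import IntervalTree

from .genomic_io import GenomicInterval, SnpSet

logger = logging.getLogger(__name__)

MatchMode = Literal["position", "position_allele"]


@dataclass(frozen=True)
class SubtractionSummary:
    """Stage-by-stage SNP counts of the subtractive screen."""

    n_input_snps: int
    n_in_dhs: int
    n_shared_removed: int
    n_retained: int

    def __post_init__(self) -> None:
        if self.n_retained != self.n_in_dhs - self.n_shared_removed:
            raise ValueError("n_retained must equal n_in_dhs - n_shared_removed")
        if not (0 <= self.n_retained <= self.n_in_dhs <= self.n_input_snps):
            raise ValueError("counts must be nested: retained <= in_dhs <= input")

    def to_dict(self) -> dict[str, int]:
        return asdict(self)


def _build_trees(regions: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in regions:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def filter_snps_to_regions(snps: SnpSet, regions: Sequence[GenomicInterval]) -> SnpSet:
    """Retain SNPs whose 0-based position lies inside any region.

    Half-open semantics: a SNP at 1-based position ``p`` is retained iff some
    region on the same chromosome satisfies ``start <= p - 1 < end``.
    Overlapping regions are used as-is; no record is ever duplicated.
    """
    trees = _build_trees(regions)
    kept = []
    for rec in snps:
        tree = trees.get(rec.chrom)
        if tree is not None and tree.overlaps_point(rec.pos0):
            kept.append(rec)
    return SnpSet(strain=snps.strain, records=kept)


def subtract_snps(
    target: SnpSet,
    comparator: SnpSet,
    match_mode: MatchMode = "position_allele",
) -> SnpSet:
    """Remove target SNPs present in the comparator strain.

    ``match_mode`` chooses the identity key: ``position_allele`` (default)
    matches on (chrom, pos, alt); ``position`` matches on (chrom, pos) alone,
    so any comparator variant at the same site removes the target SNP.
    """
    if match_mode == "position_allele":
        shared = comparator.keys()
        kept = [r for r in target if r.key not in shared]
    elif match_mode == "position":
        shared_pos = comparator.position_keys()
        kept = [r for r in target if (r.chrom, r.pos) not in shared_pos]
    else:
        raise ValueError(f"unknown match_mode {match_mode!r}")
    logger.info(
        "subtract_snps(%s - %s, %s): %d -> %d",
        target.strain, comparator.strain, match_mode, len(target), len(kept),
    )
    return SnpSet(strain=target.strain, records=kept)


def run_subtractive_screen(
    target: SnpSet,
    comparator: SnpSet,
    dhs: Sequence[GenomicInterval],
    match_mode: MatchMode = "position_allele",
    high_stringency_dhs: Sequence[GenomicInterval] | None = None,
) -> tuple[SnpSet, SubtractionSummary]:
    """Restrict to DHS, then subtract shared variants; return the pDHS SNP set
    with a count summary of every stage.

    ``high_stringency_dhs`` optionally intersects with a second open-chromatin
    track before subtraction (a SNP must fall in both tracks to survive).
    """
    in_dhs = filter_snps_to_regions(target, dhs)
    if high_stringency_dhs is not None:
        in_dhs = filter_snps_to_regions(in_dhs, high_stringency_dhs)
    retained = subtract_snps(in_dhs, comparator, match_mode=match_mode)
    summary = SubtractionSummary(
        n_input_snps=len(target),
        n_in_dhs=len(in_dhs),
        n_shared_removed=len(in_dhs) - len(retained),
        n_retained=len(retained),
    )
    return retained, summary
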