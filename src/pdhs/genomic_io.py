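"""Readers, writers and core coordinate types.

Coordinate conventions follow the underlying file formats: BED intervals and
gene TSS are 0-based half-open, VCF positions are 1-based.  A SNP at VCF
position ``p`` therefore occupies 0-based position ``p - 1``.  Chromosome
names are matched by exact string equality; no "chr" normalisation is
attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, TypeVar

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


class ParseError(ValueError):
    """A malformed input file; the message names the offending line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval [start, end)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains_point(self, chrom: str, pos0: int) -> bool:
        return chrom == self.chrom and self.start <= pos0 < self.end


@dataclass(frozen=True, order=True)
class SnpRecord:
    """A biallelic single-nucleotide variant at a 1-based position."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"VCF position must be >= 1, got {self.pos}")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"ref/alt must be single bases ACGT, got {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    @property
    def pos0(self) -> int:
        """0-based position of the variant base."""
        return self.pos - 1

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.alt)


class SnpSet:
    """A strain-labelled collection of SNPs, unique by (chrom, pos, alt)."""

    def __init__(self, strain: str, records: Iterable[SnpRecord] = ()):
        self.strain = strain
        self._records: dict[tuple[str, int, str], SnpRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: SnpRecord) -> None:
        if rec.key in self._records:
            raise ValueError(f"duplicate SNP {rec.chrom}:{rec.pos} {rec.ref}>{rec.alt}")
        self._records[rec.key] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[SnpRecord]:
        """Iterate in (chrom, pos, alt) order."""
        return iter(sorted(self._records.values()))

    def __contains__(self, rec: SnpRecord) -> bool:
        return rec.key in self._records

    def keys(self) -> set[tuple[str, int, str]]:
        return set(self._records)

    def position_keys(self) -> set[tuple[str, int]]:
        return {(c, p) for (c, p, _a) in self._records}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SnpSet):
            return NotImplemented
        return self.strain == other.strain and self._records == other._records


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to what the regulatory-domain rule needs: a stranded TSS."""

    gene_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 0:
            raise ValueError(f"tss must be >= 0, got {self.tss}")


class ChromSizes(dict):
    """Mapping chromosome name -> length in bases."""

    def __init__(self, sizes: Mapping[str, int] = ()):
        super().__init__(sizes)
        for name, length in self.items():
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length {length}")

    def check_covers(self, chroms: Iterable[str]) -> None:
        missing = sorted({c for c in chroms if c not in self})
        if missing:
            raise ValueError(f"chromosomes missing from sizes table: {missing}")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf_snps(
    path: str | Path,
    strain: str | None = None,
    keep_filter: set[str] | None = None,
) -> SnpSet:
    """Read single-nucleotide variants from a VCF 4.x text file.

    Multi-allelic records are split into one record per ALT allele; indels
    (REF or ALT longer than one base, or symbolic alleles) are dropped and
    counted; records whose FILTER is not in ``keep_filter`` (default
    ``{"PASS", "."}``) are excluded.

    Parameters
    ----------
    path
        VCF file path (uncompressed text).
    strain
        Label for the returned :class:`SnpSet`; defaults to the file stem.
    keep_filter
        FILTER column values to retain.
    """
    path = Path(path)
    if keep_filter is None:
        keep_filter = {"PASS", "."}
    strain = strain if strain is not None else path.stem
    records: list[SnpRecord] = []
    n_indels = 0
    saw_header = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                saw_header = True
                continue
            if line.startswith("#CHROM"):
                saw_header = True
                continue
            if line.startswith("#"):
                raise ParseError(f"{path}:{lineno}: unexpected header line {line[:40]!r}")
            if not saw_header:
                raise ParseError(f"{path}:{lineno}: data before any VCF header line")
            fields = line.split("\t")
            if len(fields) < 8:
                raise ParseError(
                    f"{path}:{lineno}: expected >= 8 tab-separated VCF columns, got {len(fields)}"
                )
            chrom, pos_s, _id, ref, alt_s, _qual, filt = fields[:7]
            try:
                pos = int(pos_s)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric POS {pos_s!r}") from None
            if pos < 1:
                raise ParseError(f"{path}:{lineno}: POS must be >= 1, got {pos}")
            if filt not in keep_filter:
                continue
            ref = ref.upper()
            for alt in alt_s.upper().split(","):
                if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
                    n_indels += 1
                    continue
                records.append(SnpRecord(chrom=chrom, pos=pos, ref=ref, alt=alt))
    if n_indels:
        logger.info("read_vcf_snps(%s): dropped %d non-SNP alleles", path.name, n_indels)
    return SnpSet(strain=strain, records=records)


def write_vcf_snps(snps: SnpSet, path: str | Path, sizes: ChromSizes | None = None) -> None:
    """Write a SnpSet as a minimal sites-only VCF 4.2 file."""
    with open(Path(path), "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=pdhs strain={snps.strain}\n")
        if sizes:
            for chrom in sorted(sizes):
                fh.write(f"##contig=<ID={chrom},length={sizes[chrom]}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for rec in snps:
            fh.write(f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\tPASS\t.\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+ intervals (0-based half-open); extra columns are ignored."""
    path = Path(path)
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: BED line needs >= 3 columns")
            chrom, start_s, end_s = fields[:3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric BED coordinates") from None
            if start < 0 or start >= end:
                raise ParseError(
                    f"{path}:{lineno}: invalid interval [{start},{end}): require 0 <= start < end"
                )
            out.append(GenomicInterval(chrom=chrom, start=start, end=end))
    return out


def write_bed_intervals(
    intervals: Iterable[GenomicInterval],
    path: str | Path,
    names: Iterable[str] | None = None,
) -> None:
    """Write intervals as BED3, or BED4 when per-interval names are given."""
    intervals = list(intervals)
    name_list = list(names) if names is not None else None
    if name_list is not None and len(name_list) != len(intervals):
        raise ValueError("names must match intervals one-to-one")
    with open(Path(path), "w") as fh:
        for i, iv in enumerate(intervals):
            if name_list is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name_list[i]}\n")


# ---------------------------------------------------------------------------
# Gene table / chromosome sizes
# ---------------------------------------------------------------------------

_GENE_COLUMNS = ("gene_id", "chrom", "strand", "tss")


def read_gene_table(path: str | Path, sizes: ChromSizes | None = None) -> list[GeneModel]:
    """Read a TSV gene annotation table with columns gene_id, chrom, strand, tss.

    ``tss`` is a 0-based position.  Duplicate gene ids are an error.  When a
    :class:`ChromSizes` is given, every gene chromosome must be present and
    every TSS must lie inside its chromosome.
    """
    path = Path(path)
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {}
        for col in _GENE_COLUMNS:
            if col not in header:
                raise ParseError(f"{path}:1: missing required column {col!r}")
            idx[col] = header.index(col)
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            try:
                tss = int(fields[idx["tss"]])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric tss") from None
            gene_id = fields[idx["gene_id"]]
            if gene_id in seen:
                raise ParseError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            try:
                gene = GeneModel(
                    gene_id=gene_id,
                    chrom=fields[idx["chrom"]],
                    strand=fields[idx["strand"]],
                    tss=tss,
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            genes.append(gene)
    if sizes is not None:
        sizes.check_covers(g.chrom for g in genes)
        for g in genes:
            if g.tss >= sizes[g.chrom]:
                raise ParseError(f"gene {g.gene_id}: tss {g.tss} beyond chromosome {g.chrom}")
    return genes


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        fh.write("\t".join(_GENE_COLUMNS) + "\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\n")


def read_chrom_sizes(path: str | Path) -> ChromSizes:
    """Read a two-column name<TAB>length table."""
    path = Path(path)
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected name<TAB>length")
            try:
                sizes[fields[0]] = int(fields[1])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric length") from None
    return ChromSizes(sizes)


def write_chrom_sizes(sizes: ChromSizes, path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


_T = TypeVar("_T", SnpSet, list)


def rename_chroms(obj: _T, alias_map: Mapping[str, str]) -> _T:
    """Apply a chromosome-name alias map (e.g. {"1": "chr1"}) to a SnpSet or
    a list of intervals/genes.  Names absent from the map pass through;
    matching elsewhere in the package is always exact string equality."""
    def ren(c: str) -> str:
        return alias_map.get(c, c)

    if isinstance(obj, SnpSet):
        return SnpSet(
            obj.strain,
            (SnpRecord(ren(r.chrom), r.pos, r.ref, r.alt) for r in obj),
        )
    out = []
    for item in obj:
        if isinstance(item, GenomicInterval):
            out.append(GenomicInterval(ren(item.chrom), item.start, item.end))
        elif isinstance(item, GeneModel):
            out.append(GeneModel(item.gene_id, ren(item.chrom), item.strand, item.tss))
        else:
            raise TypeError(f"cannot rename chromosomes on {type(item).__name__}")
    return out


def write_snp_tsv(snps: SnpSet, path: str | Path) -> None:
    """Write a SnpSet as a four-column TSV (chrom, pos, ref, alt; pos 1-based)."""
    with open(Path(path), "w") as fh:
        fh.write("chrom\tpos\tref\talt\n")
        for rec in snps:
            fh.write(f"{rec.chrom}\t{rec.pos}\t{rec.ref}\t{rec.alt}\n")


def read_snp_tsv(path: str | Path, strain: str | None = None) -> SnpSet:
    path = Path(path)
    strain = strain if strain is not None else path.stem
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["chrom", "pos", "ref", "alt"]:
            raise ParseError(f"{path}:1: expected header chrom/pos/ref/alt")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            try:
                records.append(SnpRecord(chrom=f[0], pos=int(f[1]), ref=f[2], alt=f[3]))
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return SnpSet(strain=strain, records=records)
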