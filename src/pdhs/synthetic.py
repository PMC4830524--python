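"""Synthetic study generator with planted ground truth.

Emulates the statistical structure of the real screen — strain-specific SNPs
enriched in open chromatin near causal genes, tumour-cohort expression with
variance heterogeneity, metastasis counts and censored survival driven by a
linear predictor over the causal genes — so that every pipeline stage, and
the screen end to end, is testable without any external download.

Key generative choices (see docs/methods.md for rationale):

* Causal genes form a sign-aligned co-expression module: each causal gene
  shares a latent per-sample factor with loading ``sqrt(causal_corr)``,
  oriented by the sign of its effect.  Metastasis-susceptibility programs
  are coordinated, not twenty independent coin flips; marginal per-gene
  screens only have realistic power against such a module.
* Causal genes (like half of the non-causal genes) carry inflated
  expression variance, reflecting the screen's premise that functional
  polymorphisms drive expression variability — otherwise the variance
  filter would remove the very genes the screen is meant to find.
* Survival is exponential proportional hazards (Weibull shape optional)
  with independent uniform censoring tuned to a target censoring fraction.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .domains import DomainParams, build_basal_domains
from .genomic_io import (
    ChromSizes,
    GeneModel,
    GenomicInterval,
    SnpRecord,
    SnpSet,
    write_bed_intervals,
    write_chrom_sizes,
    write_gene_table,
    write_vcf_snps,
)
from .screen import ExpressionMatrix, PhenotypeTable

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic screen.

    Defaults describe the reference synthetic study: a 50 Mb genome with
    2,000 genes, 20 causal genes with per-gene hazard coefficients of
    magnitude 0.3-0.6, a mouse tumour cohort of 150 and a validation cohort
    of 500 samples.
    """

    n_chroms: int = 5
    chrom_length_bp: int = 10_000_000
    n_genes: int = 2_000
    n_dhs: int = 3_000  # background DHS, on top of one guaranteed per gene
    dhs_length_bp: int = 150
    background_snp_rate: float = 0.002  # per bp, per strain
    shared_fraction: float = 0.5
    n_causal: int = 20
    beta_range: tuple[float, float] = (0.3, 0.6)
    causal_corr: float = 0.1  # shared-factor variance fraction in causal genes
    n_mouse_samples: int = 150
    n_human_samples: int = 500
    censor_fraction: float = 0.3
    nb_dispersion: float = 2.0
    variable_fraction: float = 0.45  # fraction of non-causal genes with inflated variance
    baseline_count_mean: float = 5.0
    baseline_hazard: float = 0.1
    weibull_shape: float = 1.0  # 1.0 = exponential
    variance_inflation: float = 4.0
    domain_params: DomainParams = field(default_factory=DomainParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_chroms, self.n_genes, self.n_dhs, self.dhs_length_bp) <= 0:
            raise ValueError("counts must be positive")
        for f in (self.shared_fraction, self.causal_corr):
            if not (0 <= f <= 1):
                raise ValueError("fractions must lie in [0, 1]")
        if not (0 <= self.censor_fraction < 1):
            raise ValueError("censor_fraction must lie in [0, 1)")
        lo, hi = self.beta_range
        if not (0 <= lo <= hi):
            raise ValueError("beta_range must satisfy 0 <= lo <= hi")
        if self.n_causal > self.n_genes:
            raise ValueError("n_causal cannot exceed n_genes")


@dataclass
class SyntheticTruth:
    """Planted ground truth: which genes are causal and how."""

    causal_gene_ids: list[str]
    betas: dict[str, float]  # signed per-gene hazard coefficients
    planted_snps: dict[str, list[str]]  # causal gene -> SNP ids in its basal DHS
    config: GeneratorConfig

    def __post_init__(self) -> None:
        if set(self.causal_gene_ids) != set(self.betas):
            raise ValueError("betas must cover exactly the causal genes")

    def to_json(self, path: str | Path) -> None:
        cfg = dataclasses.asdict(self.config)
        cfg["domain_params"] = dataclasses.asdict(self.config.domain_params)
        payload = {
            "causal_gene_ids": self.causal_gene_ids,
            "betas": self.betas,
            "planted_snps": self.planted_snps,
            "config": cfg,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        cfg = dict(payload["config"])
        cfg["domain_params"] = DomainParams(**cfg["domain_params"])
        cfg["beta_range"] = tuple(cfg["beta_range"])
        return cls(
            causal_gene_ids=payload["causal_gene_ids"],
            betas={g: float(b) for g, b in payload["betas"].items()},
            planted_snps=payload["planted_snps"],
            config=GeneratorConfig(**cfg),
        )


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([stage, seed])


# ---------------------------------------------------------------------------
# Genome, DHS, variants
# ---------------------------------------------------------------------------


def generate_genome(cfg: GeneratorConfig, seed: int | None = None) -> tuple[list[GeneModel], ChromSizes]:
    """Random gene annotation: TSS uniform per chromosome with minimum
    spacing 2*(up+down); strands Bernoulli(1/2)."""
    seed = cfg.seed if seed is None else seed
    rng = _rng(seed, 1)
    p = cfg.domain_params
    spacing = 2 * (p.up_bp + p.down_bp)
    sizes = ChromSizes({f"chr{i + 1}": cfg.chrom_length_bp for i in range(cfg.n_chroms)})
    per_chrom = [cfg.n_genes // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_genes % cfg.n_chroms):
        per_chrom[i] += 1
    margin = p.up_bp + 1
    genes: list[GeneModel] = []
    gid = 0
    for ci, m in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        usable = cfg.chrom_length_bp - 2 * margin - (m - 1) * spacing
        if usable <= 0:
            raise ValueError(
                f"cannot place {m} genes with spacing {spacing} on a "
                f"{cfg.chrom_length_bp} bp chromosome"
            )
        u = np.sort(rng.uniform(0, usable, size=m))
        tss = (margin + u + np.arange(m) * spacing).astype(int)
        strands = rng.choice(["+", "-"], size=m)
        for k in range(m):
            gid += 1
            genes.append(GeneModel(f"g{gid:04d}", chrom, str(strands[k]), int(tss[k])))
    return genes, sizes


def generate_dhs(
    genes: list[GeneModel],
    sizes: ChromSizes,
    cfg: GeneratorConfig,
    seed: int | None = None,
) -> list[GenomicInterval]:
    """One guaranteed DHS inside every gene's basal domain plus uniform
    background DHS; total footprint kept below 2% of the genome."""
    seed = cfg.seed if seed is None else seed
    rng = _rng(seed, 2)
    genome = sum(sizes.values())
    footprint = (len(genes) + cfg.n_dhs) * cfg.dhs_length_bp
    if footprint > 0.02 * genome:
        raise ValueError(
            f"requested DHS footprint {footprint} bp exceeds 2% of the {genome} bp genome"
        )
    out: list[GenomicInterval] = []
    basal = build_basal_domains(genes, cfg.domain_params, sizes)
    for d in basal:
        width = d.basal.end - d.basal.start
        if width <= cfg.dhs_length_bp:
            start = d.basal.start
        else:
            start = d.basal.start + int(rng.integers(0, width - cfg.dhs_length_bp))
        end = min(start + cfg.dhs_length_bp, sizes[d.chrom])
        out.append(GenomicInterval(d.chrom, start, end))
    chroms = sorted(sizes)
    for _ in range(cfg.n_dhs):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, sizes[chrom] - cfg.dhs_length_bp))
        out.append(GenomicInterval(chrom, start, start + cfg.dhs_length_bp))
    return out


def _basal_dhs_of(genes, dhs, cfg, sizes) -> dict[str, GenomicInterval]:
    """The guaranteed basal DHS per gene (the first len(genes) intervals)."""
    return {g.gene_id: dhs[i] for i, g in enumerate(genes)}


def generate_strain_variants(
    genes: list[GeneModel],
    dhs: list[GenomicInterval],
    sizes: ChromSizes,
    cfg: GeneratorConfig,
    seed: int | None = None,
) -> tuple[SnpSet, SnpSet, SyntheticTruth]:
    """Two strain SNP sets plus the planted truth.

    Background SNPs are Poisson-uniform per chromosome; a ``shared_fraction``
    of them is copied to the comparator strain.  Each causal gene gets one to
    three target-only SNPs inside the DHS guaranteed to sit in its basal
    regulatory domain, so the subtractive screen recovers every causal gene
    by construction.
    """
    seed = cfg.seed if seed is None else seed
    rng = _rng(seed, 3)
    target: dict[tuple[str, int, str], SnpRecord] = {}
    comparator: dict[tuple[str, int, str], SnpRecord] = {}

    def _draw_alleles(k: int) -> tuple[np.ndarray, np.ndarray]:
        ref_i = rng.integers(0, 4, size=k)
        alt_i = (ref_i + rng.integers(1, 4, size=k)) % 4
        return _BASES[ref_i], _BASES[alt_i]

    for chrom in sorted(sizes):
        n_bg = rng.poisson(cfg.background_snp_rate * sizes[chrom])
        pos = rng.integers(1, sizes[chrom] + 1, size=n_bg)
        refs, alts = _draw_alleles(n_bg)
        shared = rng.random(n_bg) < cfg.shared_fraction
        for i in range(n_bg):
            rec = SnpRecord(chrom, int(pos[i]), str(refs[i]), str(alts[i]))
            if rec.key in target:
                continue
            target[rec.key] = rec
            if shared[i]:
                comparator[rec.key] = rec

    # plant causal genes
    causal_ids = sorted(
        str(g) for g in rng.choice([g.gene_id for g in genes], size=cfg.n_causal, replace=False)
    )
    lo, hi = cfg.beta_range
    mags = rng.uniform(lo, hi, size=cfg.n_causal)
    signs = rng.choice([-1.0, 1.0], size=cfg.n_causal)
    betas = {g: float(m * s) for g, m, s in zip(causal_ids, mags, signs)}

    basal_dhs = _basal_dhs_of(genes, dhs, cfg, sizes)
    comparator_positions = {(c, p) for (c, p, _a) in comparator}
    planted: dict[str, list[str]] = {}
    for g in causal_ids:
        iv = basal_dhs[g]
        n_snp = int(rng.integers(1, 4))
        ids = []
        for _ in range(n_snp):
            for _try in range(20):
                p1 = int(rng.integers(iv.start + 1, iv.end + 1))  # 1-based within DHS
                ref, alt = _draw_alleles(1)
                rec = SnpRecord(iv.chrom, p1, str(ref[0]), str(alt[0]))
                if rec.key in target or (iv.chrom, p1) in comparator_positions:
                    continue
                target[rec.key] = rec
                ids.append(f"{rec.chrom}:{rec.pos}:{rec.ref}>{rec.alt}")
                break
        if not ids:  # extremely unlikely; force one by evicting the comparator copy
            p1 = int(rng.integers(iv.start + 1, iv.end + 1))
            ref, alt = _draw_alleles(1)
            rec = SnpRecord(iv.chrom, p1, str(ref[0]), str(alt[0]))
            target[rec.key] = rec
            comparator.pop(rec.key, None)
            ids.append(f"{rec.chrom}:{rec.pos}:{rec.ref}>{rec.alt}")
        planted[g] = ids

    truth = SyntheticTruth(
        causal_gene_ids=causal_ids, betas=betas, planted_snps=planted, config=cfg
    )
    return (
        SnpSet("target", target.values()),
        SnpSet("comparator", comparator.values()),
        truth,
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


def _tuned_uniform_censor_bound(hazards: np.ndarray, censor_fraction: float) -> float:
    """Upper bound c of the U(0, c) censoring law such that the expected
    event fraction matches 1 - censor_fraction for exponential event times."""
    if censor_fraction == 0:
        return float("inf")

    def event_prob(c: float) -> float:
        hc = hazards * c
        return float(np.mean(1.0 - (1.0 - np.exp(-hc)) / hc))

    return brentq(lambda c: event_prob(c) - (1.0 - censor_fraction), 1e-12, 1e12)


def _simulate_cohort(
    genes: list[GeneModel],
    truth: SyntheticTruth,
    n_samples: int,
    prefix: str,
    rng: np.random.Generator,
    with_counts: bool,
) -> tuple[ExpressionMatrix, PhenotypeTable]:
    cfg = truth.config
    gene_ids = [g.gene_id for g in genes]
    n_genes = len(gene_ids)
    causal = truth.causal_gene_ids
    causal_idx = {g: i for i, g in enumerate(gene_ids) if g in set(causal)}

    # latent standard-normal expression; causal genes share a sign-aligned factor
    u = rng.standard_normal((n_genes, n_samples))
    eps = u.copy()
    r = cfg.causal_corr
    if causal and r > 0:
        factor = rng.standard_normal(n_samples)
        for g in causal:
            i = causal_idx[g]
            s = np.sign(truth.betas[g]) or 1.0
            eps[i] = s * np.sqrt(r) * factor + np.sqrt(1.0 - r) * u[i]

    # variance heterogeneity: causal genes plus a slice of the non-causal
    # genes; keeping the variable share below one half anchors the median
    # gene variance (the filter's reference) in the non-variable majority
    sd = np.ones(n_genes)
    non_causal = [i for i, g in enumerate(gene_ids) if g not in causal_idx]
    inflate = rng.permutation(non_causal)[: int(cfg.variable_fraction * len(non_causal))]
    sd[inflate] = np.sqrt(cfg.variance_inflation)
    sd[[causal_idx[g] for g in causal]] = np.sqrt(cfg.variance_inflation)

    gene_means = rng.normal(8.0, 1.0, size=n_genes)
    sample_shifts = rng.normal(0.0, 0.2, size=n_samples)
    values = gene_means[:, None] + sample_shifts[None, :] + sd[:, None] * eps

    # linear predictor over the causal latent variables
    L = np.zeros(n_samples)
    for g in causal:
        L += truth.betas[g] * eps[causal_idx[g]]

    hazards = cfg.baseline_hazard * np.exp(L)
    if cfg.weibull_shape == 1.0:
        t_event = rng.exponential(1.0 / hazards)
    else:
        # Weibull PH: S(t) = exp(-h * t^shape)
        t_event = (rng.exponential(1.0, n_samples) / hazards) ** (1.0 / cfg.weibull_shape)
    c_bound = _tuned_uniform_censor_bound(hazards, cfg.censor_fraction)
    t_censor = (
        rng.uniform(0.0, c_bound, size=n_samples)
        if np.isfinite(c_bound)
        else np.full(n_samples, np.inf)
    )
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    time = np.maximum(time, 1e-9)

    sample_ids = [f"{prefix}{i + 1:04d}" for i in range(n_samples)]
    expr = ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids))
    pheno = {"dmfs_time": time, "dmfs_event": event}
    if with_counts:
        mu = cfg.baseline_count_mean * np.exp(L)
        k = cfg.nb_dispersion
        pheno["metastasis_count"] = rng.negative_binomial(k, k / (k + mu))
    table = PhenotypeTable(pd.DataFrame(pheno, index=pd.Index(sample_ids, name="sample_id")))
    return expr, table


def generate_mouse_cohort(
    genes: list[GeneModel],
    truth: SyntheticTruth,
    seed: int | None = None,
) -> tuple[ExpressionMatrix, PhenotypeTable]:
    """Tumour cohort with expression, metastasis counts (negative binomial)
    and censored DMFS times, all driven by the planted linear predictor."""
    seed = truth.config.seed if seed is None else seed
    return _simulate_cohort(
        genes, truth, truth.config.n_mouse_samples, "M", _rng(seed, 4), with_counts=True
    )


def generate_validation_cohort(
    genes: list[GeneModel],
    truth: SyntheticTruth,
    seed: int | None = None,
) -> tuple[ExpressionMatrix, PhenotypeTable]:
    """Independent validation cohort: same generative law as the mouse
    cohort's survival component (same causal genes, same directions), no
    metastasis counts."""
    seed = truth.config.seed if seed is None else seed
    return _simulate_cohort(
        genes, truth, truth.config.n_human_samples, "H", _rng(seed, 5), with_counts=False
    )


# ---------------------------------------------------------------------------
# Full study
# ---------------------------------------------------------------------------


@dataclass
class SyntheticStudy:
    genes: list[GeneModel]
    sizes: ChromSizes
    dhs: list[GenomicInterval]
    target: SnpSet
    comparator: SnpSet
    truth: SyntheticTruth
    mouse_expr: ExpressionMatrix
    mouse_pheno: PhenotypeTable
    human_expr: ExpressionMatrix
    human_pheno: PhenotypeTable


def generate_study(cfg: GeneratorConfig | None = None, seed: int | None = None) -> SyntheticStudy:
    """Generate the complete synthetic study from a single seed."""
    cfg = cfg if cfg is not None else GeneratorConfig()
    seed = cfg.seed if seed is None else seed
    genes, sizes = generate_genome(cfg, seed)
    dhs = generate_dhs(genes, sizes, cfg, seed)
    target, comparator, truth = generate_strain_variants(genes, dhs, sizes, cfg, seed)
    mouse_expr, mouse_pheno = generate_mouse_cohort(genes, truth, seed)
    human_expr, human_pheno = generate_validation_cohort(genes, truth, seed)
    return SyntheticStudy(
        genes=genes,
        sizes=sizes,
        dhs=dhs,
        target=target,
        comparator=comparator,
        truth=truth,
        mouse_expr=mouse_expr,
        mouse_pheno=mouse_pheno,
        human_expr=human_expr,
        human_pheno=human_pheno,
    )


def write_fixture_bundle(
    outdir: str | Path, cfg: GeneratorConfig | None = None, seed: int | None = None
) -> SyntheticStudy:
    """Write the full study to ``outdir`` as plain-text files that round-trip
    through the package readers: target.vcf, comparator.vcf, dhs.bed,
    genes.tsv, chrom_sizes.tsv, mouse_expr.tsv, mouse_pheno.tsv,
    human_expr.tsv, human_surv.tsv, truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study = generate_study(cfg, seed)
    write_vcf_snps(study.target, outdir / "target.vcf", study.sizes)
    write_vcf_snps(study.comparator, outdir / "comparator.vcf", study.sizes)
    write_bed_intervals(study.dhs, outdir / "dhs.bed")
    write_gene_table(study.genes, outdir / "genes.tsv")
    write_chrom_sizes(study.sizes, outdir / "chrom_sizes.tsv")
    study.mouse_expr.to_tsv(outdir / "mouse_expr.tsv")
    study.mouse_pheno.to_tsv(outdir / "mouse_pheno.tsv")
    study.human_expr.to_tsv(outdir / "human_expr.tsv")
    study.human_pheno.to_tsv(outdir / "human_surv.tsv")
    study.truth.to_json(outdir / "truth.json")
    return study
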