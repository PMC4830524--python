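"""End-to-end orchestration of the subtractive screen.

``run_full_screen`` drives the whole workflow from a single configuration:
subtract -> regulatory domains/assignment -> normalisation -> variance
filter -> both association screens -> weighted signatures -> validation
cohort evaluation -> permutation nulls.  Every stage writes its output to
the run directory (TSV/JSON), logs its counts and wall time, and the final
report is deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import domains as _domains
from . import permutation as _perm
from . import signature as _sig
from .genomic_io import (
    read_bed_intervals,
    read_chrom_sizes,
    read_gene_table,
    read_vcf_snps,
    write_snp_tsv,
)
from .screen import (
    ExpressionMatrix,
    PhenotypeTable,
    ScreenConfig,
    log_intensity_variation_filter,
    normalize_to_median_array,
    screen_genes,
)
from .subtractive import SubtractionSummary, run_subtractive_screen

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    target_vcf: str
    comparator_vcf: str
    dhs_bed: str
    genes_tsv: str
    chrom_sizes_tsv: str
    mouse_expr_tsv: str
    mouse_pheno_tsv: str
    human_expr_tsv: str
    human_pheno_tsv: str
    outdir: str = "pdhs_run"
    match_mode: str = "position_allele"
    domain_params: _domains.DomainParams = field(default_factory=_domains.DomainParams)
    assign_basal_only: bool = False
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    n_groups: int = 3
    n_perm: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "domain_params" in raw:
            raw["domain_params"] = _domains.DomainParams(**raw["domain_params"])
        if "screen" in raw:
            raw["screen"] = ScreenConfig(**raw["screen"])
        return cls(**raw)


@dataclass
class ScreenReport:
    subtraction: SubtractionSummary
    n_pdhs_genes: int
    n_variable_genes: int
    n_candidates: int
    n_dmfs_genes: int
    n_metcorr_genes: int
    signatures: dict  # mode -> {statistic, df, p, coverage, n_genes, group_sizes}
    permutations: dict  # mode -> scheme -> {observed_stat, empirical_p}
    seed: int

    def __post_init__(self) -> None:
        if not (
            self.n_pdhs_genes >= self.n_candidates >= max(self.n_dmfs_genes, self.n_metcorr_genes)
        ):
            raise ValueError("screen counts must be non-increasing along the filter chain")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["subtraction"] = self.subtraction.to_dict()
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # annotate with the stage name
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


def run_full_screen(config: PipelineConfig) -> ScreenReport:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- inputs -----------------------------------------------------------
    load = _stage("load_inputs")(
        lambda: (
            read_vcf_snps(config.target_vcf, strain="target"),
            read_vcf_snps(config.comparator_vcf, strain="comparator"),
            read_bed_intervals(config.dhs_bed),
            read_chrom_sizes(config.chrom_sizes_tsv),
        )
    )
    target, comparator, dhs, sizes = load()
    genes = _stage("load_genes")(lambda: read_gene_table(config.genes_tsv, sizes))()

    # --- subtractive screen ----------------------------------------------
    def _subtract():
        pdhs, summary = run_subtractive_screen(target, comparator, dhs, config.match_mode)
        write_snp_tsv(pdhs, outdir / "pdhs_snps.tsv")
        (outdir / "subtraction_summary.json").write_text(
            json.dumps(summary.to_dict(), indent=1, sort_keys=True)
        )
        return pdhs, summary

    pdhs, summary = _stage("subtract")(_subtract)()

    # --- regulatory domains and gene assignment --------------------------
    def _assign():
        doms = _domains.build_regulatory_domains(genes, config.domain_params, sizes)
        assignments, pdhs_genes = _domains.assign_regions_to_genes(
            pdhs, doms, use_basal_only=config.assign_basal_only
        )
        with open(outdir / "pdhs_gene_assignment.tsv", "w") as fh:
            fh.write("region_id\tgene_ids\n")
            for a in assignments:
                fh.write(f"{a.region_id}\t{','.join(a.gene_ids)}\n")
        (outdir / "pdhs_genes.txt").write_text("\n".join(pdhs_genes) + "\n")
        return pdhs_genes

    pdhs_genes = _stage("assign")(_assign)()

    # --- expression screens ----------------------------------------------
    def _screens():
        expr = normalize_to_median_array(ExpressionMatrix.from_tsv(config.mouse_expr_tsv))
        pheno = PhenotypeTable.from_tsv(config.mouse_pheno_tsv).align_to(expr)
        variable, var_p = log_intensity_variation_filter(expr, config.screen.variance_alpha)
        var_p.to_csv(outdir / "variance_filter_p.tsv", sep="\t", header=["p"])
        candidates = sorted(set(pdhs_genes) & set(variable))
        if not candidates:
            raise ValueError("no candidate genes survive pDHS + variance filtering")
        dmfs = screen_genes(expr, pheno, candidates, "dmfs", config.screen)
        met = screen_genes(expr, pheno, candidates, "met_count", config.screen)
        dmfs.all_p.to_csv(outdir / "screen_dmfs_p.tsv", sep="\t", index=False)
        met.all_p.to_csv(outdir / "screen_metcount_p.tsv", sep="\t", index=False)
        return variable, candidates, dmfs, met

    variable, candidates, dmfs_res, met_res = _stage("screen")(_screens)()

    # --- signatures, validation, permutations ----------------------------
    def _signatures():
        human_expr = ExpressionMatrix.from_tsv(config.human_expr_tsv)
        human_pheno = PhenotypeTable.from_tsv(config.human_pheno_tsv).align_to(human_expr)
        sig_results: dict = {}
        perm_results: dict = {}
        for mode, res in (("dmfs", dmfs_res), ("correlation", met_res)):
            if len(res) == 0:
                sig_results[mode] = None
                perm_results[mode] = None
                continue
            sig = _sig.build_weighted_signature(res.passing, mode)
            sig.to_tsv(outdir / f"signature_{mode}.tsv")
            ev = _sig.evaluate_signature(sig, human_expr, human_pheno, config.n_groups)
            (outdir / f"evaluation_{mode}.json").write_text(
                json.dumps(ev.to_dict(), indent=1, sort_keys=True)
            )
            sig_results[mode] = {
                "statistic": ev.logrank_stat,
                "df": ev.df,
                "p": ev.p,
                "coverage": ev.coverage,
                "n_genes": len(sig),
                "group_sizes": ev.group_sizes,
            }
            per_scheme = {}
            for scheme in _perm.SCHEMES:
                cfg = _perm.PermutationConfig(
                    scheme=scheme, n_perm=config.n_perm, seed=config.seed
                )
                pr = _perm.permutation_test(sig, human_expr, human_pheno, cfg)
                (outdir / f"permutation_{mode}_{scheme}.json").write_text(
                    json.dumps(pr.to_dict(), indent=1, sort_keys=True)
                )
                per_scheme[scheme] = {
                    "observed_stat": pr.observed_stat,
                    "empirical_p": pr.empirical_p,
                }
            perm_results[mode] = per_scheme
        return sig_results, perm_results

    sig_results, perm_results = _stage("signatures")(_signatures)()

    report = ScreenReport(
        subtraction=summary,
        n_pdhs_genes=len(pdhs_genes),
        n_variable_genes=len(variable),
        n_candidates=len(candidates),
        n_dmfs_genes=len(dmfs_res),
        n_metcorr_genes=len(met_res),
        signatures=sig_results,
        permutations=perm_results,
        seed=config.seed,
    )
    report.to_json(outdir / "report.json")
    return report
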