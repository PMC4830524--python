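"""Permutation nulls for signature significance, Fisher's combined
probability test, and a 2x2 chi-square utility.

Three null schemes probe what makes an experimentally derived signature
prognostic: ``random_genes`` keeps the observed weights but assigns them to
random gene sets of the same size; ``random_weights`` keeps the genes but
draws fresh Gaussian weights; ``random_both`` does both.  Performance is
compared on the k-group log-rank chi-square of the stratified cohort (a
monotone transform of the displayed p-values that avoids floating-point
underflow ties), and significance is the +1-corrected empirical p
(1 + #{null >= observed}) / (1 + n_perm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .screen import ExpressionMatrix, PhenotypeTable
from .signature import (
    StratifiedSurvivalResult,
    WeightedSignature,
    evaluate_signature,
    logrank_test,
    stratify_samples,
    zscore_rows,
)

Scheme = Literal["random_genes", "random_weights", "random_both"]
SCHEMES: tuple[Scheme, ...] = ("random_genes", "random_weights", "random_both")


@dataclass(frozen=True)
class PermutationConfig:
    scheme: Scheme = "random_genes"
    n_perm: int = 1000
    seed: int = 0
    weight_sd_source: Literal["observed", "unit"] = "observed"

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")


@dataclass(frozen=True)
class PermutationResult:
    observed_stat: float
    null_stats: np.ndarray
    empirical_p: float
    scheme: Scheme
    n_perm: int

    def __post_init__(self) -> None:
        expected = (1 + int(np.sum(self.null_stats >= self.observed_stat))) / (
            1 + len(self.null_stats)
        )
        if not math.isclose(self.empirical_p, expected, rel_tol=1e-12):
            raise ValueError("empirical_p inconsistent with null_stats")

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "n_perm": self.n_perm,
            "observed_stat": self.observed_stat,
            "empirical_p": self.empirical_p,
            "null_stats": self.null_stats.tolist(),
        }


class _FastEvaluator:
    """Pre-z-scored cohort for tight permutation loops.

    Scoring, stratification and the log-rank statistic are identical to
    :func:`pdhs.signature.evaluate_signature`; the per-gene z-scores are
    just computed once instead of per permutation.
    """

    def __init__(self, expr: ExpressionMatrix, pheno: PhenotypeTable, n_groups: int = 3):
        pheno = pheno.align_to(expr)
        self.z = zscore_rows(expr)
        self.gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
        self.times = pheno.times
        self.events = pheno.events
        self.n_groups = n_groups

    def stat(self, gene_ids: Sequence[str], weights: np.ndarray) -> float:
        rows = [self.gene_index[g] for g in gene_ids if g in self.gene_index]
        if not rows:
            raise ValueError("no signature gene present in cohort")
        w = np.asarray(
            [weights[i] for i, g in enumerate(gene_ids) if g in self.gene_index]
        )
        scores = w @ self.z[rows] / len(rows)
        labels = stratify_samples(scores, n_groups=self.n_groups)
        stat, _df, _p = logrank_test(self.times, self.events, labels)
        return stat


def permutation_test(
    sig: WeightedSignature,
    expr: ExpressionMatrix,
    pheno: PhenotypeTable,
    config: PermutationConfig = PermutationConfig(),
    gene_universe: Sequence[str] | None = None,
    n_groups: int = 3,
) -> PermutationResult:
    """Empirical significance of a signature against a permutation null.

    ``gene_universe`` defaults to all genes in the cohort expression matrix;
    it must contain at least as many genes as the signature.  Fully
    reproducible given ``config.seed``.
    """
    if gene_universe is None:
        gene_universe = expr.gene_ids
    universe = list(gene_universe)
    missing = set(universe) - set(expr.gene_ids)
    if missing:
        raise ValueError(f"gene_universe members absent from cohort: {sorted(missing)[:5]}")
    if len(universe) < len(sig):
        raise ValueError("gene_universe smaller than the signature")

    ev = _FastEvaluator(expr, pheno, n_groups=n_groups)
    sig_genes = sig.gene_ids
    sig_weights = sig.weights_array()
    observed = ev.stat(sig_genes, sig_weights)

    sd = float(np.std(sig_weights, ddof=0)) if config.weight_sd_source == "observed" else 1.0
    if sd == 0:
        sd = 1.0
    rng = np.random.default_rng(config.seed)
    null_stats = np.empty(config.n_perm)
    m = len(sig)
    universe_arr = np.array(universe)
    for b in range(config.n_perm):
        if config.scheme in ("random_genes", "random_both"):
            genes_b = list(rng.choice(universe_arr, size=m, replace=False))
        else:
            genes_b = sig_genes
        if config.scheme in ("random_weights", "random_both"):
            weights_b = rng.normal(loc=0.0, scale=sd, size=m)
        else:
            weights_b = sig_weights
        null_stats[b] = ev.stat(genes_b, weights_b)
    empirical_p = (1 + int(np.sum(null_stats >= observed))) / (1 + config.n_perm)
    return PermutationResult(
        observed_stat=float(observed),
        null_stats=null_stats,
        empirical_p=float(empirical_p),
        scheme=config.scheme,
        n_perm=config.n_perm,
    )


def fisher_combined_p(pvals: Sequence[float]) -> tuple[float, float]:
    """Fisher's combined probability test.

    X = -2 * sum(ln p_i) is compared to chi-square with 2k degrees of
    freedom; returns (X, combined p).
    """
    p = np.asarray(pvals, dtype=float)
    if len(p) == 0:
        raise ValueError("need >= 1 p-value")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("all p-values must lie in (0, 1]")
    x = float(-2.0 * np.sum(np.log(p)))
    combined = float(stats.chi2.sf(x, df=2 * len(p)))
    return x, combined


def chi2_test_2x2(
    table: Sequence[Sequence[float]] | np.ndarray, yates: bool = False
) -> tuple[float, float]:
    """Pearson chi-square test on a 2x2 contingency table (df = 1), with
    optional Yates continuity correction.  Returns (statistic, p)."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0):
        raise ValueError("counts must be >= 0")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("both margins must be positive")
    stat, p, _df, _exp = stats.chi2_contingency(t, correction=yates)
    return float(stat), float(p)
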