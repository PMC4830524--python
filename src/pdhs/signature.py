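"""Weighted prognostic gene signatures: construction from screen results,
cohort scoring, quantile stratification, and Kaplan–Meier / log-rank
evaluation of outcome separation.

A signature maps genes to signed weights — log2 hazard ratios from a DMFS
screen, Spearman correlation coefficients from a metastasis-count screen, or
expression fold changes from a treatment contrast.  A cohort sample's score
is the weighted mean of its (by default z-scored) expression over the
signature genes present in the cohort; samples are cut into score tertiles
(or halves) and survival separation is tested by the k-group log-rank test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .screen import (
    ExpressionMatrix,
    GeneAssociation,
    PhenotypeTable,
    cox_univariate,
    InsufficientEventsError,
)

logger = logging.getLogger(__name__)

SignatureMode = str  # "dmfs" | "correlation" | "foldchange"
_MODES = ("dmfs", "correlation", "foldchange")


@dataclass(frozen=True)
class WeightedSignature:
    mode: SignatureMode
    entries: dict[str, float]

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        if not self.entries:
            raise ValueError("signature must have >= 1 entry")
        if not all(math.isfinite(w) for w in self.entries.values()):
            raise ValueError("weights must be finite")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.entries)

    def weights_array(self) -> np.ndarray:
        return np.array(list(self.entries.values()), dtype=float)

    def to_tsv(self, path: str | Path) -> None:
        with open(Path(path), "w") as fh:
            fh.write(f"# mode={self.mode}\n")
            fh.write("gene_id\tweight\n")
            for g, w in self.entries.items():
                fh.write(f"{g}\t{w:.10g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "WeightedSignature":
        mode = None
        entries: dict[str, float] = {}
        with open(Path(path)) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    if "mode=" in line:
                        mode = line.split("mode=")[1].strip()
                    continue
                if not line or line.startswith("gene_id"):
                    continue
                g, w = line.split("\t")[:2]
                entries[g] = float(w)
        if mode is None:
            raise ValueError(f"{path}: missing '# mode=' header comment")
        return cls(mode=mode, entries=entries)


def build_weighted_signature(
    assocs: Sequence[GeneAssociation], mode: SignatureMode
) -> WeightedSignature:
    """Turn screen associations into a weighted signature.

    mode="dmfs" uses weight = log2(hazard ratio); mode="correlation" uses the
    Spearman coefficient.  Genes with hazard ratio exactly 1 (weight 0) are
    retained — direction-free but still part of the signature.
    """
    if not assocs:
        raise ValueError("no associations given")
    entries: dict[str, float] = {}
    for a in assocs:
        if mode == "dmfs":
            if a.endpoint != "dmfs" or a.hr is None:
                raise ValueError(f"association for {a.gene_id} is not a DMFS result")
            if a.hr <= 0:
                raise ValueError(f"hazard ratio must be positive, got {a.hr}")
            entries[a.gene_id] = math.log2(a.hr)
        elif mode == "correlation":
            if a.endpoint != "met_count" or a.rho is None:
                raise ValueError(f"association for {a.gene_id} is not a metastasis-count result")
            entries[a.gene_id] = a.rho
        else:
            raise ValueError("build_weighted_signature supports modes dmfs/correlation")
    return WeightedSignature(mode=mode, entries=entries)


def build_foldchange_signature(
    de_table: Mapping[str, float], min_fold: float = 10.0
) -> WeightedSignature:
    """Signature from a differential-expression contrast: keep genes with
    |fold change| > min_fold and weight each gene by its signed fold change."""
    entries = {g: fc for g, fc in de_table.items() if abs(fc) > min_fold}
    if not entries:
        raise ValueError(f"no genes exceed |fold change| > {min_fold}")
    return WeightedSignature(mode="foldchange", entries=entries)


# ---------------------------------------------------------------------------
# Scoring and stratification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SignatureScore:
    scores: dict[str, float]
    coverage: float

    def __post_init__(self) -> None:
        if not (0 < self.coverage <= 1):
            raise ValueError("coverage must lie in (0, 1]")
        if not all(math.isfinite(s) for s in self.scores.values()):
            raise ValueError("scores must be finite")

    def values_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.scores[s] for s in sample_ids], dtype=float)


def zscore_rows(expr: ExpressionMatrix) -> np.ndarray:
    """Row-wise z-scores (ddof=1); constant rows map to zero."""
    v = expr.data.to_numpy(dtype=float)
    mean = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (v - mean) / sd


def score_samples(
    sig: WeightedSignature,
    expr: ExpressionMatrix,
    standardize: bool = True,
) -> SignatureScore:
    """Score every sample as the weighted mean of signature-gene expression.

    With ``standardize`` (default), each gene row is z-scored across samples
    first, making the score invariant to per-gene affine rescaling.
    Signature genes absent from the matrix are dropped (coverage reported);
    zero overlap is an error.
    """
    present = [g for g in sig.entries if g in expr.data.index]
    if not present:
        raise ValueError("no signature gene present in the expression matrix")
    missing = len(sig) - len(present)
    if missing:
        logger.info("score_samples: %d signature genes missing from matrix", missing)
    sub = ExpressionMatrix(expr.data.loc[present])
    mat = zscore_rows(sub) if standardize else sub.data.to_numpy(dtype=float)
    w = np.array([sig.entries[g] for g in present], dtype=float)
    raw = w @ mat / len(present)
    return SignatureScore(
        scores=dict(zip(expr.sample_ids, map(float, raw))),
        coverage=len(present) / len(sig),
    )


def stratify_samples(
    scores: SignatureScore | Sequence[float] | np.ndarray,
    n_groups: int = 3,
    sample_ids: Sequence[str] | None = None,
) -> np.ndarray:
    """Cut samples into score-quantile groups (tertiles by default).

    Cut points are the empirical ``i/n_groups`` quantiles taken as actual
    data values (lower interpolation); a sample whose score equals a cut
    point goes to the lower group.  Returns integer labels 0..n_groups-1
    (0 = lowest scores).
    """
    if n_groups not in (2, 3):
        raise ValueError("n_groups must be 2 or 3")
    if isinstance(scores, SignatureScore):
        if sample_ids is None:
            sample_ids = list(scores.scores)
        vals = scores.values_for(sample_ids)
    else:
        vals = np.asarray(scores, dtype=float)
    n = len(vals)
    if n < 2 * n_groups:
        raise ValueError(f"need >= {2 * n_groups} samples for {n_groups} groups")
    if np.ptp(vals) == 0:
        raise ValueError("all scores identical; cannot stratify")
    cuts = [
        float(np.quantile(vals, i / n_groups, method="lower"))
        for i in range(1, n_groups)
    ]
    labels = np.zeros(n, dtype=int)
    for c in cuts:
        labels += vals > c
    return labels


# ---------------------------------------------------------------------------
# Kaplan–Meier and log-rank
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve: step coordinates at distinct event times."""

    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # risk-set size just before each event time
    n: int

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(
    times: Sequence[float] | np.ndarray, events: Sequence[int] | np.ndarray
) -> KMCurve:
    """Kaplan–Meier product-limit estimator.

    With no events the curve is flat at 1; without censoring it equals one
    minus the empirical CDF of the event times.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    ev_times = []
    surv = []
    at_risk = []
    s = 1.0
    n = len(t)
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        d = int(e[i:j].sum())
        if d > 0:
            risk = n - i
            s *= 1.0 - d / risk
            ev_times.append(t[i])
            surv.append(s)
            at_risk.append(risk)
        i = j
    return KMCurve(
        times=np.array(ev_times),
        survival=np.array(surv),
        at_risk=np.array(at_risk, dtype=int),
        n=n,
    )


def logrank_test(
    times: Sequence[float] | np.ndarray,
    events: Sequence[int] | np.ndarray,
    groups: Sequence[int] | np.ndarray,
) -> tuple[float, int, float]:
    """k-group log-rank test.

    At each distinct event time the observed minus expected event count per
    group is accumulated with the hypergeometric covariance; the statistic is
    the quadratic form over the first k-1 groups, chi-square with k-1
    degrees of freedom under the null of identical hazards.
    Returns (statistic, df, p).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    labels, g_idx = np.unique(g, return_inverse=True)
    k = len(labels)
    if k < 2:
        raise ValueError("need >= 2 groups")
    if e.sum() < 1:
        raise ValueError("need >= 1 event")

    order = np.argsort(t, kind="stable")
    t, e, g_idx = t[order], e[order], g_idx[order]
    n = len(t)

    oe = np.zeros(k)
    cov = np.zeros((k, k))
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        d = int(e[i:j].sum())
        if d > 0:
            n_risk = n - i
            n_j = np.bincount(g_idx[i:], minlength=k).astype(float)
            d_j = np.bincount(g_idx[i:j], weights=e[i:j].astype(float), minlength=k)
            frac = n_j / n_risk
            oe += d_j - d * frac
            if n_risk > 1:
                mult = d * (n_risk - d) / (n_risk - 1)
                cov += mult * (np.diag(frac) - np.outer(frac, frac))
        i = j
    v = cov[: k - 1, : k - 1]
    u = oe[: k - 1]
    try:
        stat = float(u @ np.linalg.solve(v, u))
    except np.linalg.LinAlgError:
        stat = float(u @ np.linalg.pinv(v) @ u)
    stat = max(stat, 0.0)
    df = k - 1
    p = float(stats.chi2.sf(stat, df=df))
    return stat, df, p


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


@dataclass
class StratifiedSurvivalResult:
    group_labels: np.ndarray
    sample_ids: list[str]
    curves: list[KMCurve]
    logrank_stat: float
    df: int
    p: float
    coverage: float

    @property
    def group_sizes(self) -> list[int]:
        return np.bincount(self.group_labels, minlength=self.df + 1).tolist()

    def to_dict(self) -> dict:
        return {
            "logrank_stat": self.logrank_stat,
            "df": self.df,
            "p": self.p,
            "coverage": self.coverage,
            "group_sizes": self.group_sizes,
            "curves": [
                {
                    "times": c.times.tolist(),
                    "survival": c.survival.tolist(),
                    "at_risk": c.at_risk.tolist(),
                    "n": c.n,
                }
                for c in self.curves
            ],
        }


def evaluate_signature(
    sig: WeightedSignature,
    expr: ExpressionMatrix,
    pheno: PhenotypeTable,
    n_groups: int = 3,
    standardize: bool = True,
) -> StratifiedSurvivalResult:
    """Score a cohort, stratify by score quantiles, and test survival
    separation with the k-group log-rank test."""
    pheno = pheno.align_to(expr)
    score = score_samples(sig, expr, standardize=standardize)
    sample_ids = expr.sample_ids
    labels = stratify_samples(score, n_groups=n_groups, sample_ids=sample_ids)
    times, events = pheno.times, pheno.events
    stat, df, p = logrank_test(times, events, labels)
    curves = [
        km_estimate(times[labels == gidx], events[labels == gidx])
        for gidx in range(n_groups)
    ]
    return StratifiedSurvivalResult(
        group_labels=labels,
        sample_ids=sample_ids,
        curves=curves,
        logrank_stat=stat,
        df=df,
        p=p,
        coverage=score.coverage,
    )


def split_and_reweight(
    sig_genes: Sequence[str],
    expr: ExpressionMatrix,
    pheno: PhenotypeTable,
    fraction: float = 0.5,
    seed: int = 0,
) -> tuple[WeightedSignature, list[str], list[str]]:
    """Discovery/test reweighting of a gene signature on an independent cohort.

    The cohort is split (stratified by event flag, deterministic in the
    seed) into a discovery fraction and a test remainder; per-gene univariate
    Cox on the discovery half yields fresh weights log2(HR).  Evaluating the
    reweighted signature on the test half is the caller's job.
    Returns (signature, discovery sample ids, test sample ids).
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must lie in (0, 1)")
    pheno = pheno.align_to(expr)
    genes = [g for g in sig_genes if g in expr.data.index]
    if not genes:
        raise ValueError("no signature gene present in the cohort")
    rng = np.random.default_rng(seed)
    sample_ids = np.array(expr.sample_ids)
    events = pheno.events
    disc_mask = np.zeros(len(sample_ids), dtype=bool)
    for flag in (0, 1):
        idx = np.flatnonzero(events == flag)
        n_pick = int(round(fraction * len(idx)))
        disc_mask[rng.choice(idx, size=n_pick, replace=False)] = True
    disc_ids = list(sample_ids[disc_mask])
    test_ids = list(sample_ids[~disc_mask])
    for name, ids in (("discovery", disc_ids), ("test", test_ids)):
        if pheno.data.loc[ids, "dmfs_event"].sum() < 2:
            raise InsufficientEventsError(f"{name} half has < 2 events")
    disc_expr = ExpressionMatrix(expr.data[disc_ids])
    disc_pheno = PhenotypeTable(pheno.data.loc[disc_ids])
    entries: dict[str, float] = {}
    for g in genes:
        try:
            a = cox_univariate(
                disc_expr.gene_values(g), disc_pheno.times, disc_pheno.events, gene_id=g
            )
        except Exception:
            continue
        entries[g] = math.log2(a.hr)
    if not entries:
        raise ValueError("no gene could be reweighted on the discovery half")
    return WeightedSignature(mode="dmfs", entries=entries), disc_ids, test_ids
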