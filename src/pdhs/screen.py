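"""Expression normalisation, variance filtering, and per-gene association
screens against censored survival (univariate Cox) and metastasis counts
(Spearman rank correlation).

The screens deliberately apply no multiple-testing correction: genes are
called at a raw two-sided p < 0.05, matching the low-stringency character of
the subtractive strategy.  A Benjamini–Hochberg adjusted column is attached
for information only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import permutations
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

Endpoint = Literal["dmfs", "met_count"]
TieMethod = Literal["breslow", "efron"]


class DegenerateCovariateError(ValueError):
    """Covariate (or response) is constant; no association is estimable."""


class InsufficientEventsError(ValueError):
    """Fewer than two observed events; the Cox fit is not identified."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


class ExpressionMatrix:
    """Gene x sample matrix of log2-scale expression values.

    Thin wrapper around a pandas DataFrame (index = gene ids, columns =
    sample ids) enforcing finiteness and id uniqueness.
    """

    def __init__(self, data: pd.DataFrame):
        if data.shape[0] < 1 or data.shape[1] < 2:
            raise ValueError("expression matrix needs >= 1 gene and >= 2 samples")
        if data.index.has_duplicates or data.columns.has_duplicates:
            raise ValueError("gene ids and sample ids must be unique")
        values = data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("expression values must be finite")
        self.data = data.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def gene_values(self, gene_id: str) -> np.ndarray:
        return self.data.loc[gene_id].to_numpy(dtype=float)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.data.equals(other.data)


class PhenotypeTable:
    """Per-sample metastasis phenotypes: censored DMFS time, event flag and,
    for the mouse cohorts, a metastasis count."""

    REQUIRED = ("dmfs_time", "dmfs_event")

    def __init__(self, data: pd.DataFrame):
        for col in self.REQUIRED:
            if col not in data.columns:
                raise ValueError(f"phenotype table missing column {col!r}")
        if data.index.has_duplicates:
            raise ValueError("sample ids must be unique")
        if (data["dmfs_time"] <= 0).any():
            raise ValueError("dmfs_time must be positive")
        if not data["dmfs_event"].isin([0, 1]).all():
            raise ValueError("dmfs_event must be 0/1")
        if "metastasis_count" in data.columns:
            mc = data["metastasis_count"]
            if (mc < 0).any() or (mc != mc.round()).any():
                raise ValueError("metastasis_count must be non-negative integers")
        self.data = data

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def times(self) -> np.ndarray:
        return self.data["dmfs_time"].to_numpy(dtype=float)

    @property
    def events(self) -> np.ndarray:
        return self.data["dmfs_event"].to_numpy(dtype=int)

    @property
    def metastasis_counts(self) -> np.ndarray:
        if "metastasis_count" not in self.data.columns:
            raise ValueError("phenotype table has no metastasis_count column")
        return self.data["metastasis_count"].to_numpy(dtype=float)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PhenotypeTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id")

    def align_to(self, expr: ExpressionMatrix) -> "PhenotypeTable":
        missing = set(expr.sample_ids) - set(self.sample_ids)
        if missing:
            raise ValueError(f"phenotypes missing for samples: {sorted(missing)[:5]} ...")
        return PhenotypeTable(self.data.loc[expr.sample_ids])


@dataclass(frozen=True)
class ScreenConfig:
    variance_alpha: float = 0.05
    association_alpha: float = 0.05
    tie_method: TieMethod = "efron"
    p_kind: Literal["wald", "lr"] = "wald"

    def __post_init__(self) -> None:
        for a in (self.variance_alpha, self.association_alpha):
            if not (0 < a < 1):
                raise ValueError("alphas must lie in (0, 1)")


@dataclass(frozen=True)
class GeneAssociation:
    """One gene's association with an endpoint.

    Exactly one of ``hr`` (with ``beta``, DMFS endpoint) or ``rho``
    (metastasis-count endpoint) is populated.
    """

    gene_id: str
    endpoint: Endpoint
    p: float
    n: int
    beta: float | None = None
    hr: float | None = None
    rho: float | None = None
    se: float | None = None
    monotone_likelihood: bool = False

    def __post_init__(self) -> None:
        if self.endpoint == "dmfs":
            if self.hr is None or self.beta is None or self.rho is not None:
                raise ValueError("dmfs association must carry beta/hr and no rho")
            if not math.isclose(self.hr, math.exp(self.beta), rel_tol=1e-9):
                raise ValueError("hr must equal exp(beta)")
        else:
            if self.rho is None or self.hr is not None:
                raise ValueError("met_count association must carry rho and no hr")
        if not (0 <= self.p <= 1):
            raise ValueError("p must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Normalisation and variance filter
# ---------------------------------------------------------------------------


def normalize_to_median_array(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Median-array normalisation on the log scale.

    The reference is the sample whose median expression is the median of the
    per-sample medians (the lower of the two middle samples when the count is
    even); every sample is shifted additively so its median equals the
    reference median.  Idempotent.
    """
    if expr.n_samples < 3:
        raise ValueError("median-array normalisation needs >= 3 samples")
    medians = expr.data.median(axis=0)
    ref_median = float(np.sort(medians.to_numpy())[(expr.n_samples - 1) // 2])
    shifted = expr.data.sub(medians, axis=1).add(ref_median)
    return ExpressionMatrix(shifted)


def log_intensity_variation_filter(
    expr: ExpressionMatrix, alpha: float = 0.05
) -> tuple[list[str], pd.Series]:
    """Keep genes whose expression varies more than the array-wide typical gene.

    Per gene the statistic is T = (n-1) * s_i^2 / s_med^2, where s_i^2 is the
    gene's sample variance and s_med^2 the median of all gene variances; the
    p-value is the upper tail of chi-square with n-1 degrees of freedom at T.
    Genes with p < alpha are retained.
    """
    n = expr.n_samples
    if n < 3:
        raise ValueError("variance filter needs >= 3 samples")
    variances = expr.data.var(axis=1, ddof=1)
    s_med = float(variances.median())
    if s_med == 0:
        raise ValueError("median gene variance is zero; all genes constant?")
    t_stat = (n - 1) * variances / s_med
    pvals = pd.Series(stats.chi2.sf(t_stat.to_numpy(), df=n - 1), index=expr.data.index)
    kept = list(pvals.index[pvals < alpha])
    return kept, pvals


# ---------------------------------------------------------------------------
# Univariate Cox proportional hazards
# ---------------------------------------------------------------------------

_BETA_CAP = 15.0
_MAX_ITER = 50
_TOL = 1e-9


def _cox_loglik_grad_hess(
    beta: float,
    x: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    tie_method: TieMethod,
) -> tuple[float, float, float]:
    """Partial log-likelihood, gradient and negative Hessian (information)
    for a single covariate, with Breslow or Efron handling of tied events."""
    order = np.argsort(times, kind="stable")
    x = x[order]
    t = times[order]
    e = events[order].astype(bool)
    n = len(t)
    theta = np.exp(beta * x)
    xtheta = x * theta
    x2theta = x * xtheta
    # suffix sums over the risk set {j : t_j >= t_i}
    s0 = np.cumsum(theta[::-1])[::-1]
    s1 = np.cumsum(xtheta[::-1])[::-1]
    s2 = np.cumsum(x2theta[::-1])[::-1]

    ll = 0.0
    grad = 0.0
    info = 0.0
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        ev = np.arange(i, j)[e[i:j]]
        d = len(ev)
        if d > 0:
            sum_x = float(x[ev].sum())
            ll += beta * sum_x
            r0, r1, r2 = float(s0[i]), float(s1[i]), float(s2[i])
            if tie_method == "breslow" or d == 1:
                ll -= d * math.log(r0)
                grad += sum_x - d * r1 / r0
                info += d * (r2 / r0 - (r1 / r0) ** 2)
            else:  # efron
                d0 = float(theta[ev].sum())
                d1 = float(xtheta[ev].sum())
                d2 = float(x2theta[ev].sum())
                for k in range(d):
                    f = k / d
                    e0 = r0 - f * d0
                    e1 = r1 - f * d1
                    e2 = r2 - f * d2
                    ll -= math.log(e0)
                    grad += sum_x / d - e1 / e0
                    info += e2 / e0 - (e1 / e0) ** 2
        i = j
    return ll, grad, info


def cox_univariate(
    values: Sequence[float] | np.ndarray,
    times: Sequence[float] | np.ndarray,
    events: Sequence[int] | np.ndarray,
    tie_method: TieMethod = "efron",
    gene_id: str = "",
    p_kind: Literal["wald", "lr"] = "wald",
) -> GeneAssociation:
    """Fit a single-covariate Cox proportional-hazards model.

    Newton iteration on the partial likelihood with step-halving safeguards,
    at most 50 iterations, convergence when the update falls below 1e-9.
    |beta| is capped at 15; hitting the cap sets the monotone-likelihood
    flag (complete separation of the risk sets).  The default p-value is the
    two-sided Wald test; a likelihood-ratio p is available.

    Sign convention: larger covariate values with earlier events give
    beta > 0 (hazard ratio above 1).
    """
    x = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if not (len(x) == len(t) == len(e)):
        raise ValueError("values, times and events must have equal length")
    if e.sum() < 2:
        raise InsufficientEventsError("need >= 2 observed events")
    if np.ptp(x) == 0:
        raise DegenerateCovariateError("constant covariate")
    # centre and scale for numerical stability; beta rescaled back at the end
    scale = x.std()
    xs = (x - x.mean()) / scale

    beta = 0.0
    ll0, _, _ = _cox_loglik_grad_hess(0.0, xs, t, e, tie_method)
    ll = ll0
    monotone = False
    for _ in range(_MAX_ITER):
        _, grad, info = _cox_loglik_grad_hess(beta, xs, t, e, tie_method)
        if info <= 0:
            monotone = True
            break
        step = grad / info
        # safeguard: halve the step until the likelihood does not decrease
        new_beta = beta + step
        for _h in range(30):
            if abs(new_beta) > _BETA_CAP:
                new_beta = math.copysign(_BETA_CAP, new_beta)
            new_ll, _, _ = _cox_loglik_grad_hess(new_beta, xs, t, e, tie_method)
            if new_ll >= ll - 1e-12:
                break
            step /= 2.0
            new_beta = beta + step
        delta = new_beta - beta
        beta, ll = new_beta, new_ll
        if abs(beta) >= _BETA_CAP:
            monotone = True
            break
        if abs(delta) < _TOL:
            break

    _, _, info = _cox_loglik_grad_hess(beta, xs, t, e, tie_method)
    se_s = 1.0 / math.sqrt(info) if info > 0 else math.inf
    if p_kind == "wald":
        z = beta / se_s if math.isfinite(se_s) and se_s > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
    else:
        lr = 2.0 * (ll - ll0)
        p = float(stats.chi2.sf(max(lr, 0.0), df=1))
    beta_raw = beta / scale
    se_raw = se_s / scale
    return GeneAssociation(
        gene_id=gene_id,
        endpoint="dmfs",
        beta=beta_raw,
        hr=math.exp(beta_raw),
        se=se_raw,
        p=float(p),
        n=len(x),
        monotone_likelihood=monotone,
    )


# ---------------------------------------------------------------------------
# Spearman rank correlation against a quantitative trait
# ---------------------------------------------------------------------------


def _midranks(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v, method="average")


def spearman_test(
    values: Sequence[float] | np.ndarray,
    counts: Sequence[float] | np.ndarray,
    gene_id: str = "",
) -> GeneAssociation:
    """Spearman rank correlation between expression and a quantitative trait.

    rho is the Pearson correlation of mid-ranks (average ranks at ties).  The
    p-value is exact by full permutation when n <= 9 and neither vector has
    ties, otherwise by the t approximation t = rho * sqrt((n-2)/(1-rho^2))
    with n-2 degrees of freedom.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(counts, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need n >= 4 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateCovariateError("constant input")
    rx, ry = _midranks(x), _midranks(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    no_ties = len(np.unique(x)) == n and len(np.unique(y)) == n
    if n <= 9 and no_ties:
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = math.sqrt(float((rx_c**2).sum() * (ry_c**2).sum()))
        count = 0
        total = 0
        for perm in permutations(range(n)):
            r = float((rx_c * ry_c[list(perm)]).sum()) / denom
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t_stat = rho * math.sqrt((n - 2) / (1.0 - rho**2))
            p = 2.0 * float(stats.t.sf(abs(t_stat), df=n - 2))
    return GeneAssociation(
        gene_id=gene_id, endpoint="met_count", rho=rho, p=float(min(p, 1.0)), n=n
    )


# ---------------------------------------------------------------------------
# The screen
# ---------------------------------------------------------------------------


@dataclass
class ScreenResult:
    """Genes passing the association screen, plus bookkeeping."""

    endpoint: Endpoint
    alpha: float
    n_tested: int
    passing: list[GeneAssociation]
    all_p: pd.DataFrame = field(repr=False, default=None)  # gene_id, p, p_bh

    def __iter__(self):
        return iter(self.passing)

    def __len__(self) -> int:
        return len(self.passing)

    def gene_ids(self) -> list[str]:
        return [a.gene_id for a in self.passing]


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def screen_genes(
    expr: ExpressionMatrix,
    pheno: PhenotypeTable,
    candidate_genes: Sequence[str],
    endpoint: Endpoint,
    config: ScreenConfig = ScreenConfig(),
) -> ScreenResult:
    """Screen candidate genes for association with metastatic disease.

    Each candidate gene is tested marginally — univariate Cox against DMFS,
    or Spearman correlation against metastasis count — and genes with
    two-sided p < ``association_alpha`` are returned sorted by p ascending.
    No multiple-testing correction is applied to the call; a BH-adjusted
    column is reported alongside for information.  Degenerate genes
    (constant expression) are skipped with a log message.
    """
    candidates = list(candidate_genes)
    if not candidates:
        raise ValueError("empty candidate gene set")
    unknown = set(candidates) - set(expr.gene_ids)
    if unknown:
        raise ValueError(f"candidate genes absent from matrix: {sorted(unknown)[:5]} ...")
    pheno = pheno.align_to(expr)
    times, events = pheno.times, pheno.events
    counts = pheno.metastasis_counts if endpoint == "met_count" else None

    assocs: list[GeneAssociation] = []
    n_skipped = 0
    for gid in candidates:
        vals = expr.gene_values(gid)
        try:
            if endpoint == "dmfs":
                a = cox_univariate(
                    vals, times, events,
                    tie_method=config.tie_method, gene_id=gid, p_kind=config.p_kind,
                )
            else:
                a = spearman_test(vals, counts, gene_id=gid)
        except DegenerateCovariateError:
            n_skipped += 1
            continue
        assocs.append(a)
    if n_skipped:
        logger.info("screen_genes(%s): skipped %d degenerate genes", endpoint, n_skipped)
    if not assocs:
        raise ValueError("no testable candidate genes")
    pvals = np.array([a.p for a in assocs])
    table = pd.DataFrame(
        {"gene_id": [a.gene_id for a in assocs], "p": pvals, "p_bh": _bh_adjust(pvals)}
    )
    passing = sorted(
        (a for a in assocs if a.p < config.association_alpha),
        key=lambda a: (a.p, a.gene_id),
    )
    return ScreenResult(
        endpoint=endpoint,
        alpha=config.association_alpha,
        n_tested=len(assocs),
        passing=passing,
        all_p=table,
    )


def collapse_probes_max_variance(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Collapse duplicate gene-id rows to the row with maximal variance.

    Utility for probe-level matrices; gene-level matrices pass through
    unchanged.  Accepts a raw DataFrame-backed matrix whose index may repeat.
    """
    df = expr if isinstance(expr, pd.DataFrame) else expr.data
    if not df.index.has_duplicates:
        return ExpressionMatrix(df)
    variances = df.var(axis=1, ddof=1)
    keep_pos = (
        pd.Series(np.arange(len(df)), index=df.index)
        .groupby(level=0, sort=False)
        .apply(lambda s: s.iloc[int(np.argmax(variances.iloc[s.to_numpy()]))])
    )
    return ExpressionMatrix(df.iloc[sorted(keep_pos.to_numpy())])
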