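"""Random variance model (RVM) differential expression for small samples.

The RVM moderated t-test assumes gene-wise precisions 1/sigma^2 are drawn
from a Gamma(a, scale=b) prior (equivalently sigma^2 is inverse-gamma).
Under that prior the observed residual variance s^2 (with m degrees of
freedom) satisfies

    s^2 * a * b  ~  F(m, 2a)

across genes, which gives a marginal likelihood for (a, b). The posterior
variance estimate shrinks each gene's s^2 toward the prior,

    s~^2 = (m * s^2 + 2/b) / (m + 2a),

and the moderated statistic t = (xbar_case - xbar_control) /
sqrt(s~^2 * (1/n1 + 1/n2)) is referred to a Student t distribution with
m + 2a degrees of freedom — strictly more than the m available to the
ordinary pooled t-test, which is the point of the method for 5-vs-5 designs.

Statistics are computed on log2 intensities; fold changes are ratios of
group geometric means on the linear scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError, InsufficientDataError, InvalidInputError
from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

MIN_GENES_FOR_FIT = 50

DE_COLUMNS = [
    "gene_id", "mean_case", "mean_control", "fold_change",
    "s2", "t_rvm", "p", "q", "direction",
]


@dataclass(frozen=True)
class RVMPrior:
    """Fitted inverse-gamma variance prior.

    ``a`` and ``b`` are the shape and scale of the Gamma prior on gene
    precisions; ``m`` is the per-gene residual degrees of freedom
    (n_case + n_control - 2). The moderated test uses m + 2a degrees of
    freedom.
    """

    a: float
    b: float
    m: int

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise InvalidInputError(f"prior parameters must be positive, got a={self.a}, b={self.b}")
        if self.m < 1:
            raise InvalidInputError(f"residual degrees of freedom must be >= 1, got m={self.m}")

    @property
    def df(self) -> float:
        """Degrees of freedom of the moderated t statistic (m + 2a)."""
        return self.m + 2.0 * self.a


@dataclass
class DEGeneList:
    """Genes selected at a p-value threshold, partitioned by direction."""

    selected: pd.DataFrame
    alpha: float

    @property
    def n_up(self) -> int:
        return int((self.selected["direction"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.selected["direction"] == "down").sum())

    def genes(self, direction: str | None = None) -> set[str]:
        df = self.selected
        if direction is not None:
            df = df[df["direction"] == direction]
        return set(df["gene_id"])


def _rvm_negloglik(log_ab: np.ndarray, variances: np.ndarray, m: float) -> float:
    a, b = np.exp(log_ab)
    # density of s^2 when a*b*s^2 ~ F(m, 2a); the Jacobian contributes log(a*b)
    ll = stats.f.logpdf(a * b * variances, m, 2.0 * a) + np.log(a * b)
    if not np.all(np.isfinite(ll)):
        return np.inf
    return -float(np.sum(ll))


def fit_rvm_prior(variances, m: int) -> RVMPrior:
    """Fit the (a, b) variance prior by maximum likelihood.

    Parameters
    ----------
    variances
        Per-gene residual variances of log2 intensities (>= 50 values, all >= 0).
    m
        Residual degrees of freedom each variance was computed with.

    Returns
    -------
    RVMPrior
        Maximizer of the F(m, 2a) marginal likelihood of ``a*b*s^2``.

    Raises
    ------
    InsufficientDataError
        Fewer than 50 variances.
    DegenerateInputError
        Variances (almost) all identical — the prior-dispersion MLE diverges.
    """
    v = np.asarray(variances, dtype=float)
    if v.ndim != 1 or len(v) < MIN_GENES_FOR_FIT:
        raise InsufficientDataError(f"need >= {MIN_GENES_FOR_FIT} variances, got {v.size}")
    if np.any(v < 0) or not np.all(np.isfinite(v)):
        raise InvalidInputError("variances must be finite and non-negative")
    if m < 1:
        raise InvalidInputError(f"m must be >= 1, got {m}")
    n_zero = int((v == 0).sum())
    if n_zero:
        logger.warning("dropping %d exactly-zero variances before prior fit", n_zero)
        v = v[v > 0]
        if len(v) < MIN_GENES_FOR_FIT:
            raise InsufficientDataError("too few positive variances after dropping zeros")
    mean_v = float(np.mean(v))
    if float(np.std(v)) / mean_v < 1e-8:
        raise DegenerateInputError("variances have (near-)zero dispersion; (a, b) MLE is degenerate")

    best = None
    for a0 in (1.2, 2.0, 4.0, 8.0):
        # moment-matched start: E[s^2] = 1/(b*(a-1)) for a > 1
        b0 = 1.0 / (max(a0 - 1.0, 0.25) * mean_v)
        res = optimize.minimize(
            _rvm_negloglik, x0=np.log([a0, b0]), args=(v, float(m)),
            method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    a_hat, b_hat = np.exp(best.x)
    if not (np.isfinite(a_hat) and np.isfinite(b_hat) and a_hat > 0 and b_hat > 0):
        raise DegenerateInputError("RVM prior fit did not converge to finite positive (a, b)")
    return RVMPrior(a=float(a_hat), b=float(b_hat), m=int(m))


def pooled_variances(matrix: ExpressionMatrix) -> pd.Series:
    """Pooled within-group variance of log2 intensities per gene."""
    log = matrix.log2()
    case, ctrl = matrix.samples("case"), matrix.samples("control")
    n1, n2 = len(case), len(ctrl)
    v1 = log[case].var(axis=1, ddof=1)
    v2 = log[ctrl].var(axis=1, ddof=1)
    return ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)


def fold_change(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Group geometric means and their ratio, on the linear intensity scale.

    Returns a DataFrame indexed by gene id with columns ``mean_case``,
    ``mean_control`` (geometric means, i.e. 2**(mean of log2)) and
    ``fold_change`` = mean_case / mean_control.
    """
    log = matrix.log2()
    gm_case = 2.0 ** log[matrix.samples("case")].mean(axis=1)
    gm_ctrl = 2.0 ** log[matrix.samples("control")].mean(axis=1)
    return pd.DataFrame({
        "mean_case": gm_case,
        "mean_control": gm_ctrl,
        "fold_change": gm_case / gm_ctrl,
    })


def rvm_t_test(matrix: ExpressionMatrix, prior: RVMPrior) -> pd.DataFrame:
    """Moderated t-test of case vs control for every gene.

    Returns one row per gene (input order preserved) with the columns of
    ``DE_COLUMNS``: geometric group means and fold change (linear scale),
    pooled log2 variance ``s2``, moderated statistic ``t_rvm``, two-sided
    ``p`` from Student t with m + 2a df, BH-adjusted ``q`` and ``direction``.

    A gene with zero within-group variance and zero mean difference gets
    t = 0, p = 1 (not an error).
    """
    log = matrix.log2()
    case, ctrl = matrix.samples("case"), matrix.samples("control")
    n1, n2 = len(case), len(ctrl)
    m = n1 + n2 - 2
    if prior.m != m:
        raise InvalidInputError(
            f"prior was fitted with m={prior.m} but matrix has m={m} residual df"
        )
    diff = log[case].mean(axis=1) - log[ctrl].mean(axis=1)
    s2 = pooled_variances(matrix)
    s2_mod = (m * s2 + 2.0 / prior.b) / (m + 2.0 * prior.a)
    denom = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, diff / denom, 0.0)
    t = np.where((denom == 0) & (diff == 0), 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), prior.df)
    p = np.clip(p, 0.0, 1.0)

    fc = fold_change(matrix)
    direction = np.where(
        fc["fold_change"] > 1, "up",
        np.where(fc["fold_change"] < 1, "down", np.where(diff > 0, "up", "down")),
    )
    return pd.DataFrame({
        "gene_id": matrix.gene_ids,
        "mean_case": fc["mean_case"].to_numpy(),
        "mean_control": fc["mean_control"].to_numpy(),
        "fold_change": fc["fold_change"].to_numpy(),
        "s2": s2.to_numpy(),
        "t_rvm": t,
        "p": p,
        "q": bh_fdr(p),
        "direction": direction,
    })


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise InvalidInputError("empty p-value sequence")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise InvalidInputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_de_genes(records: pd.DataFrame, alpha: float = 0.05) -> DEGeneList:
    """Keep genes with p < alpha, classified up/down by fold change.

    Fold change exactly 1 falls back to the sign of the mean log2 difference
    (already encoded in ``direction`` by :func:`rvm_t_test`); a record with
    fold change 1 *and* zero statistic is excluded with a warning. Output is
    sorted by p ascending, ties broken by |t| descending then gene id.
    """
    if not (0 < alpha <= 1):
        raise InvalidInputError(f"alpha must be in (0, 1], got {alpha}")
    sel = records[records["p"] < alpha].copy()
    ambiguous = (sel["fold_change"] == 1) & (sel["t_rvm"] == 0)
    if ambiguous.any():
        logger.warning(
            "excluding %d genes with fold change 1 and zero statistic", int(ambiguous.sum())
        )
        sel = sel[~ambiguous]
    sel = sel.assign(_abs_t=sel["t_rvm"].abs())
    sel = sel.sort_values(
        ["p", "_abs_t", "gene_id"], ascending=[True, False, True], kind="mergesort"
    ).drop(columns="_abs_t").reset_index(drop=True)
    return DEGeneList(selected=sel, alpha=alpha)


def run_de(matrix: ExpressionMatrix, alpha: float = 0.05) -> tuple[pd.DataFrame, DEGeneList, RVMPrior]:
    """Fit the variance prior on *matrix*, test every gene, select at *alpha*."""
    m = matrix.n_case + matrix.n_control - 2
    prior = fit_rvm_prior(pooled_variances(matrix).to_numpy(), m)
    records = rvm_t_test(matrix, prior)
    return records, select_de_genes(records, alpha), prior
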