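"""Reference-anchored compositional abundance testing.

Cell-type (or niche) counts per sample are modelled with a
Dirichlet-multinomial regression: y_s ~ DM(n_s, alpha_s) with
log alpha_{s,c} = a_c + b_c * x_s, where x_s is the binary condition and the
declared reference category's condition coefficient is pinned to zero
(b_ref = 0) so relative shifts are identifiable. Each non-reference
category's b_c = 0 is tested with a likelihood-ratio test; p-values are
Benjamini-Hochberg corrected and categories with q below the FDR level
(default 20%) are flagged as credible changes.

This is a maximum-likelihood stand-in for the Bayesian spike-and-slab
Dirichlet-multinomial formulation commonly used for this task: the decision
rule (FDR-thresholded credible changes against a stable reference) is the
same, without MCMC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import digamma, gammaln
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, ConvergenceError

PSEUDOCOUNT = 0.001
DEFAULT_FDR = 0.20


@dataclass
class CountTable:
    """Samples x categories counts with a binary condition and a reference."""

    counts: pd.DataFrame  # samples x categories, non-negative
    condition: pd.Series  # per sample, exactly 2 levels
    reference: str

    def __post_init__(self) -> None:
        if self.reference not in self.counts.columns:
            raise ConfigError(f"reference category {self.reference!r} not in counts")
        levels = pd.unique(self.condition)
        if len(levels) != 2:
            raise ConfigError(f"condition must be binary, got levels {list(levels)}")
        per_level = self.condition.value_counts()
        if (per_level < 2).any():
            raise ConfigError("need at least 2 samples per condition")
        if (self.counts.to_numpy() < 0).any():
            raise ConfigError("counts must be non-negative")

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, condition_col: str, reference: str
    ) -> "CountTable":
        cond = df[condition_col]
        counts = df.drop(columns=[condition_col])
        return cls(counts=counts, condition=cond, reference=reference)


def _dm_nll_grad(params, y, x, free_b):
    """Negative log-likelihood and gradient of the DM regression.

    params = [a_1..a_C, b for categories in free_b]; b is 0 elsewhere.
    """
    S, C = y.shape
    a = params[:C]
    b = np.zeros(C)
    b[free_b] = params[C:]
    log_alpha = a[None, :] + np.outer(x, b)
    alpha = np.exp(log_alpha)
    A = alpha.sum(axis=1)
    N = y.sum(axis=1)

    ll = (
        gammaln(A) - gammaln(N + A)
        + (gammaln(y + alpha) - gammaln(alpha)).sum(axis=1)
    ).sum()
    g_alpha = (
        digamma(A)[:, None]
        - digamma(N + A)[:, None]
        + digamma(y + alpha)
        - digamma(alpha)
    )
    ga = -(g_alpha * alpha).sum(axis=0)
    gb = -((g_alpha * alpha) * x[:, None]).sum(axis=0)[free_b]
    return -ll, np.concatenate([ga, gb])


def _fit_dm(y, x, free_b, a0=None, b0=None):
    C = y.shape[1]
    if a0 is None:
        p = y.sum(axis=0) / y.sum()
        a0 = np.log(np.maximum(p, 1e-8) * 10.0)
    if b0 is None:
        b0 = np.zeros(int(np.sum(free_b)))
    x0 = np.concatenate([a0, b0])
    # The concentration ridge is unbounded when the data are exactly
    # multinomial; cap the intercepts so the optimizer terminates there.
    bounds = [(-25.0, 15.0)] * C + [(-20.0, 20.0)] * len(b0)
    res = minimize(
        _dm_nll_grad,
        x0,
        args=(y, x, free_b),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    flat_ridge = res.status == 2 and np.max(np.abs(res.jac)) < 1e-3 * (1 + abs(res.fun))
    if not res.success and res.status != 1 and not flat_ridge:
        raise ConvergenceError(
            f"Dirichlet-multinomial fit failed: {res.message}", res
        )
    a = res.x[:C]
    b = np.zeros(C)
    b[free_b] = res.x[C:]
    return a, b, -res.fun


@dataclass
class AbundanceResult:
    """Per-category condition effects with BH-corrected credibility flags."""

    table: pd.DataFrame  # category, beta, log2_fc_proportion, p_value, q_value,
    #                      credible_flag
    reference: str
    fdr: float
    loglik: float

    def credible(self) -> list[str]:
        return list(self.table.loc[self.table["credible_flag"], "category"])


def test_abundance(
    tab: CountTable, fdr: float = DEFAULT_FDR, pseudocount: float = PSEUDOCOUNT
) -> AbundanceResult:
    """Fit the DM regression and LRT-test each non-reference category.

    A pseudocount (default 0.001) is added to every count before fitting.
    Categories absent in every sample are dropped with a warning. The
    reference category's effect is exactly 0 and is never flagged. Log2 fold
    changes are of fitted relative abundances (proportions) between
    conditions.
    """
    counts = tab.counts
    empty = counts.columns[counts.sum(axis=0) == 0]
    if len(empty):
        warnings.warn(
            f"dropping categor{'y' if len(empty)==1 else 'ies'} absent in all "
            f"samples: {', '.join(empty)}",
            stacklevel=2,
        )
        counts = counts.drop(columns=empty)
    cats = list(counts.columns)
    ref_i = cats.index(tab.reference)

    levels = sorted(pd.unique(tab.condition))
    # control level = first sorted unless an obvious baseline name is present
    baseline_names = [l for l in levels if str(l).lower() in
                      ("control", "ctrl", "healthy", "non-ibd", "baseline", "0")]
    base = baseline_names[0] if baseline_names else levels[0]
    x = (tab.condition != base).to_numpy(float)

    y = counts.to_numpy(float) + pseudocount
    free_b = np.ones(len(cats), dtype=bool)
    free_b[ref_i] = False

    a_full, b_full, ll_full = _fit_dm(y, x, free_b)

    pvals = np.ones(len(cats))
    for ci, cat in enumerate(cats):
        if ci == ref_i:
            continue
        restricted = free_b.copy()
        restricted[ci] = False
        _, _, ll_r = _fit_dm(y, x, restricted, a0=a_full)
        lr = max(0.0, 2.0 * (ll_full - ll_r))
        pvals[ci] = chi2.sf(lr, df=1)

    mask = np.arange(len(cats)) != ref_i
    qvals = np.ones(len(cats))
    if mask.any():
        _, q, _, _ = multipletests(pvals[mask], method="fdr_bh")
        qvals[mask] = q
    flags = (qvals < fdr) & mask

    alpha0 = np.exp(a_full)
    alpha1 = np.exp(a_full + b_full)
    p0 = alpha0 / alpha0.sum()
    p1 = alpha1 / alpha1.sum()
    lfc = np.log2(p1 / p0)

    table = pd.DataFrame(
        {
            "category": cats,
            "beta": b_full,
            "log2_fc_proportion": lfc,
            "p_value": pvals,
            "q_value": qvals,
            "credible_flag": flags,
        }
    )
    return AbundanceResult(table, reference=tab.reference, fdr=fdr, loglik=ll_full)
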