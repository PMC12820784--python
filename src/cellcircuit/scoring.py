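"""Dual-cytokine synergy statistics, signature derivation, single-sample
enrichment scoring and ordered-probit severity association.

The synergy statistic compares a measured dual-stimulus response with two
expectations built from the single-stimulus increments over baseline X:

    E_add = X + dA + dB
    E_syn = X * (1 + dA/X) * (1 + dB/X) = E_add + dA*dB/X

so the multiplicative (synergistic) expectation exceeds the additive one by
exactly dA*dB/X.

Single-sample enrichment uses the rank-weighted running-sum statistic: genes
are ranked descending, in-set positions contribute a weighted ECDF step
(weight rank^alpha, alpha = 0.25 by default), out-of-set positions a uniform
step, and the score is the sum of the ECDF difference over all ranks.

Severity association is an ordered probit: P(y = j) = Phi(tau_j - b*z) -
Phi(tau_{j-1} - b*z) with strictly increasing cutpoints, fitted by maximum
likelihood with a log-gap cutpoint reparameterization, reporting a one-sided
Wald p for b > 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

from .errors import ConfigError, ConvergenceError, SchemaError, SeparationError
from .io import DETable

DEFAULT_SSGSEA_ALPHA = 0.25
DEFAULT_SYNERGY_TOL = 0.10


# ---------------------------------------------------------------------------
# Synergy
# ---------------------------------------------------------------------------

@dataclass
class SynergyInput:
    """Baseline response plus single-stimulus increments and the measured
    dual response (same units throughout)."""

    x_baseline: float
    delta_a: float
    delta_b: float
    observed_dual: float

    def __post_init__(self) -> None:
        if self.x_baseline <= 0:
            raise ConfigError("x_baseline must be > 0")
        if self.delta_a < -self.x_baseline or self.delta_b < -self.x_baseline:
            raise ConfigError("increments cannot drive the response below 0")


@dataclass
class SynergyResult:
    e_additive: float
    e_synergistic: float
    observed_dual: float
    classification: str  # sub-additive | additive | super-additive/synergistic


def synergy_statistic(
    inp: SynergyInput, tol: float = DEFAULT_SYNERGY_TOL
) -> SynergyResult:
    """Compute both expectations and classify the observed dual response.

    Observed within ``tol`` (relative) of E_add is additive; below that band
    sub-additive; at or above E_syn's direction past the band and past the
    midpoint toward E_syn, super-additive/synergistic.
    """
    x, da, db = inp.x_baseline, inp.delta_a, inp.delta_b
    e_add = x + da + db
    e_syn = x * (1 + da / x) * (1 + db / x)
    obs = inp.observed_dual
    band = abs(e_add) * tol
    if obs > e_add + band:
        cls = "super-additive/synergistic"
    elif obs < e_add - band:
        cls = "sub-additive"
    else:
        cls = "additive"
    return SynergyResult(e_add, e_syn, obs, cls)


# ---------------------------------------------------------------------------
# Signature derivation
# ---------------------------------------------------------------------------

@dataclass
class SignatureSet:
    effector_genes: set[str]
    core_signature: set[str]
    refined_signature: set[str] | None = None


def derive_signature(
    de_ko: DETable,
    de_act: DETable,
    bound_genes: set[str],
    specific_genes: set[str],
    alpha: float = 0.05,
    ko_group: str | None = None,
    act_group: str | None = None,
) -> SignatureSet:
    """Intersect multi-assay evidence into effector and core gene sets.

    effector = {down on regulator knockout at adjusted p < alpha} intersected
    with {up on activation at adjusted p < alpha}; core additionally requires
    membership in the regulator-bound and cell-type-specific sets.
    """
    for de, name in ((de_ko, "knockout"), (de_act, "activation")):
        if "adjusted_p" not in de.df.columns:
            raise SchemaError(f"{name} DE table lacks an adjusted_p column")
    dko = de_ko.df if ko_group is None else de_ko.df[de_ko.df["group"] == ko_group]
    dact = (
        de_act.df if act_group is None else de_act.df[de_act.df["group"] == act_group]
    )
    down_ko = set(
        dko.loc[(dko["adjusted_p"] < alpha) & (dko["log_fold_change"] < 0), "gene"]
    )
    up_act = set(
        dact.loc[(dact["adjusted_p"] < alpha) & (dact["log_fold_change"] > 0), "gene"]
    )
    effector = down_ko & up_act
    core = effector & set(bound_genes) & set(specific_genes)
    return SignatureSet(effector_genes=effector, core_signature=core)


# ---------------------------------------------------------------------------
# Single-sample enrichment (ssGSEA)
# ---------------------------------------------------------------------------

def ssgsea_score(
    profile: pd.Series | dict[str, float],
    gene_set: set[str] | list[str],
    alpha: float = DEFAULT_SSGSEA_ALPHA,
) -> float:
    """Rank-weighted running-sum enrichment of one profile against one set.

    Genes are ranked descending by expression (rank N at the top); at each
    position the weighted in-set ECDF (weight rank^alpha) minus the uniform
    out-of-set ECDF is accumulated. Rank-based, so invariant to strictly
    monotone transforms of the expression values.
    """
    if not isinstance(profile, pd.Series):
        profile = pd.Series(profile)
    genes = set(profile.index)
    gs = set(gene_set) & genes
    if not gs:
        raise ConfigError("gene set is empty or disjoint from the profile")
    if gs == genes:
        raise ConfigError("gene set must be a proper subset of the profile")

    order = profile.sort_values(ascending=False, kind="stable")
    n = len(order)
    in_set = np.array([g in gs for g in order.index])
    ranks = np.arange(n, 0, -1, dtype=float)  # N at the top position
    w = np.where(in_set, ranks**alpha, 0.0)
    w_total = w.sum()
    ecdf_in = np.cumsum(w) / w_total
    ecdf_out = np.cumsum(~in_set) / (n - len(gs))
    return float(np.sum(ecdf_in - ecdf_out))


def score_cohort(
    profiles: pd.DataFrame, gene_set, alpha: float = DEFAULT_SSGSEA_ALPHA,
    normalize: bool = False,
) -> pd.Series:
    """ssGSEA score per subject (profiles are genes x subjects).

    With ``normalize`` the scores are min-max scaled across the cohort (the
    returned series is then named to flag it).
    """
    scores = pd.Series(
        {c: ssgsea_score(profiles[c], gene_set, alpha) for c in profiles.columns},
        name="ssgsea",
    )
    if normalize:
        span = scores.max() - scores.min()
        scores = (scores - scores.min()) / (span if span else 1.0)
        scores.name = "ssgsea_minmax"
    return scores


# ---------------------------------------------------------------------------
# Ordered probit
# ---------------------------------------------------------------------------

@dataclass
class ProbitFit:
    beta: float
    cutpoints: np.ndarray  # strictly increasing, length J-1
    se_beta: float
    p_one_sided: float  # Wald test of beta > 0
    loglik: float
    n: int
    J: int


def _probit_nll(params, z, yi, J):
    beta = params[0]
    tau = np.empty(J - 1)
    tau[0] = params[1]
    if J > 2:
        tau[1:] = params[1] + np.cumsum(np.exp(params[2:]))
    eta = beta * z
    upper = np.where(yi < J - 1, norm.cdf(tau[np.minimum(yi, J - 2)] - eta), 1.0)
    lower = np.where(yi > 0, norm.cdf(tau[np.maximum(yi - 1, 0)] - eta), 0.0)
    p = np.clip(upper - lower, 1e-300, 1.0)
    return -np.log(p).sum()


def ordered_probit(
    scores: np.ndarray | pd.Series, severity: np.ndarray | pd.Series
) -> ProbitFit:
    """Maximum-likelihood ordered probit of an ordinal response on one
    predictor.

    Cutpoints are kept strictly increasing through a log-gap
    reparameterization. Reports a one-sided Wald p for beta > 0 (standard
    error from the inverse numerical Hessian). Perfect separation raises
    :class:`SeparationError`.
    """
    z = np.asarray(scores, float)
    y = pd.Categorical(np.asarray(severity)).codes.astype(int)
    J = int(y.max()) + 1
    if J < 2:
        raise ConfigError("need at least 2 ordinal categories present")
    if len(z) != len(y):
        raise ConfigError("predictor and response lengths differ")
    # standardize internally for optimizer conditioning; rescale afterwards
    mu, sd = z.mean(), z.std()
    sd = sd if sd > 0 else 1.0
    zs = (z - mu) / sd

    # initialize cutpoints from marginal category frequencies
    freqs = np.bincount(y, minlength=J) / len(y)
    cum = np.cumsum(freqs)[:-1]
    tau0 = norm.ppf(np.clip(cum, 1e-3, 1 - 1e-3))
    x0 = np.concatenate([[0.0], [tau0[0]], np.log(np.maximum(np.diff(tau0), 1e-2))])

    res = minimize(
        _probit_nll, x0, args=(zs, y, J), method="BFGS",
        options={"gtol": 1e-8, "maxiter": 1000},
    )
    if not res.success and res.status not in (1, 2):
        # status 2: precision loss near the optimum is acceptable if the
        # gradient is small
        if np.max(np.abs(res.jac)) > 1e-3:
            raise ConvergenceError(f"ordered probit failed: {res.message}", res)
    if abs(res.x[0]) > 50:
        raise SeparationError(
            "coefficient diverged; the predictor perfectly separates the "
            "ordinal categories"
        )
    beta_s = res.x[0]
    # delta-method SE from the inverse Hessian (BFGS approximation is
    # refined with a finite-difference Hessian on the beta axis)
    h = 1e-5
    f0 = _probit_nll(res.x, zs, y, J)
    xp = res.x.copy(); xp[0] += h
    xm = res.x.copy(); xm[0] -= h
    d2 = (_probit_nll(xp, zs, y, J) - 2 * f0 + _probit_nll(xm, zs, y, J)) / h**2
    se_s = float(np.sqrt(max(1.0 / d2, 1e-12))) if d2 > 0 else float(
        np.sqrt(res.hess_inv[0, 0])
    )

    beta = beta_s / sd
    se = se_s / sd
    zstat = beta_s / se_s if se_s > 0 else np.inf
    p_one = float(norm.sf(zstat))
    tau = np.empty(J - 1)
    tau[0] = res.x[1]
    if J > 2:
        tau[1:] = res.x[1] + np.cumsum(np.exp(res.x[2:]))
    # cutpoints back on the original predictor scale
    tau_orig = tau + beta * mu  # since tau_s - beta_s*z_s = (tau_s + beta*mu) - beta*z
    return ProbitFit(
        beta=float(beta),
        cutpoints=tau_orig,
        se_beta=float(se),
        p_one_sided=min(max(p_one, np.nextafter(0, 1)), 1.0),
        loglik=-float(res.fun),
        n=len(y),
        J=J,
    )


def refine_signature(
    core: set[str],
    profiles: pd.DataFrame,
    severity: pd.Series,
    alpha: float = 0.05,
    beta_min: float = 0.0,
) -> set[str]:
    """Per-gene ordered probit refinement of a core signature.

    A gene is retained when its expression is independently predictive of
    severity: one-sided p, Bonferroni corrected over the core set, below
    ``alpha`` with beta > beta_min. ``beta_min <= 0`` with ``alpha >= 1``
    returns the core unchanged.
    """
    genes = sorted(core & set(profiles.index))
    m = len(genes)
    refined = set()
    for g in genes:
        fit = ordered_probit(profiles.loc[g], severity)
        if min(1.0, fit.p_one_sided * m) < alpha and fit.beta > beta_min:
            refined.add(g)
    return refined


# ---------------------------------------------------------------------------
# Deconvolution marker selection
# ---------------------------------------------------------------------------

@dataclass
class DeconvMarkerConfig:
    """Published bulk-deconvolution marker filter: p < 1e-8, average
    log fold change >= 0.75, expressed in < 20% of background cells."""

    p_max: float = 1e-8
    min_lfc: float = 0.75
    max_frac_bg: float = 0.20


def select_deconv_markers(
    de: DETable, cfg: DeconvMarkerConfig | None = None
) -> dict[str, list[str]]:
    """Apply the three-threshold marker filter per cell type."""
    cfg = cfg or DeconvMarkerConfig()
    d = de.df
    keep = (
        (d["p_value"] < cfg.p_max)
        & (d["log_fold_change"] >= cfg.min_lfc)
        & (d["frac_bg"] < cfg.max_frac_bg)
    )
    out: dict[str, list[str]] = {}
    for t, sub in d[keep].groupby("group"):
        out[str(t)] = sorted(sub["gene"])
    return out
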