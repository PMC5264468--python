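"""Two-component beta-binomial mixture model of Xi expression.

For gene *i* in one sample, let :math:`n_i` be the total allele-specific
reads and :math:`k_i` the reads supporting the Xi allele.  Allelic counts
from RNA-seq are overdispersed relative to a binomial, so each mixture
component is a beta-binomial parameterised by mean :math:`\\mu` and
overdispersion :math:`\\rho` (``alpha = mu*(1-rho)/rho``,
``beta = (1-mu)*(1-rho)/rho``; the limit ``rho -> 0`` is the binomial):

* component 0 — genes subject to inactivation: the only Xi-allele reads are
  sequencing errors, so :math:`\\mu_0` is anchored near the phred-derived
  error rate of the Xi-supporting reads;
* component 1 — genes expressed from the Xi (escape/reactivated), with an
  appreciable Xi fraction :math:`\\mu_1`.

EM yields the mixture weight :math:`\\pi_0` and, per gene, the posterior
probability of inactivation

.. math::

    \\tau_{i0} = \\frac{\\pi_0 f_0(k_i)}{\\pi_0 f_0(k_i) + (1-\\pi_0) f_1(k_i)}.

A gene with :math:`\\tau_{i0} \\le \\alpha` (default 0.05) is significantly
expressed from the Xi with :math:`1-\\alpha` confidence.  Classification of
the reprogramming time course (active / reactivated / inactive) is layered
on these per-sample calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import betabinom, binom

from .errors import InputError

ALPHA = 0.05
MIN_READS = 20
DEFAULT_EPSILON = 0.001

# escape-component mean is kept away from the error regime: an "escaping"
# gene means appreciable Xi transcription, not residual miscalls
MU1_BOUNDS = (0.05, 0.995)
RHO_BOUNDS = (1e-6, 0.99)


def betabin_logpmf(k, n, mu, rho):
    """Log pmf of the beta-binomial in mean/overdispersion form.

    ``rho = 0`` gives exactly the binomial.  Computed in log space and valid
    for n up to 1e5.
    """
    k = np.asarray(k)
    n = np.asarray(n)
    if np.any((k < 0) | (k > n)):
        raise InputError("require 0 <= k <= n")
    if not (0 < mu < 1) or not (0 <= rho < 1):
        raise InputError("require mu in (0,1) and rho in [0,1)")
    if rho == 0:
        return binom.logpmf(k, n, mu)
    a = mu * (1 - rho) / rho
    b = (1 - mu) * (1 - rho) / rho
    return betabinom.logpmf(k, n, a, b)


def betabin_pmf(k, n, mu, rho):
    return np.exp(betabin_logpmf(k, n, mu, rho))


def error_rate_from_quals(xi_qualsum, xi_reads, default_eps: float = DEFAULT_EPSILON):
    """Per-gene base-call error rate from the summed phred of Xi reads.

    eps = 10^(-Qbar/10) with Qbar the mean phred; genes with no Xi reads
    fall back to ``default_eps``.
    """
    q = np.asarray(xi_qualsum, dtype=float)
    r = np.asarray(xi_reads, dtype=float)
    if (q < 0).any() or (r < 0).any():
        raise InputError("negative quality sum or read count")
    with np.errstate(invalid="ignore", divide="ignore"):
        qbar = np.where(r > 0, q / np.where(r > 0, r, 1.0), np.nan)
    eps = np.where(r > 0, 10.0 ** (-qbar / 10.0), default_eps)
    return eps if eps.ndim else float(eps)


@dataclass
class MixtureParams:
    """Parameters of the two-component beta-binomial mixture."""
    pi0: float = 0.8
    mu0: float = DEFAULT_EPSILON
    rho0: float = 0.01
    mu1: float = 0.3
    rho1: float = 0.1

    def validate(self):
        if not (0 < self.pi0 < 1):
            raise InputError("pi0 must lie in (0,1)")
        if not (0 < self.mu0 < self.mu1 < 1):
            raise InputError("require 0 < mu0 < mu1 < 1")
        for r in (self.rho0, self.rho1):
            if not (0 <= r < 1):
                raise InputError("rho must lie in [0,1)")
        return self


@dataclass
class MixtureFit:
    """EM result: fitted parameters, per-gene tau_i0, diagnostics."""
    params: MixtureParams
    tau: np.ndarray
    loglik: float
    loglik_trace: list = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False
    degenerate: bool = False
    eps_bar: float = DEFAULT_EPSILON

    def to_dict(self):
        d = asdict(self.params)
        d.update(loglik=self.loglik, n_iter=self.n_iter,
                 converged=self.converged, degenerate=self.degenerate,
                 eps_bar=self.eps_bar)
        return d


def _mixture_loglik(k, n, p: MixtureParams):
    lf0 = betabin_logpmf(k, n, p.mu0, p.rho0) + np.log(p.pi0)
    lf1 = betabin_logpmf(k, n, p.mu1, p.rho1) + np.log1p(-p.pi0)
    return lf0, lf1


def _responsibilities(k, n, p: MixtureParams):
    lf0, lf1 = _mixture_loglik(k, n, p)
    denom = np.logaddexp(lf0, lf1)
    tau = np.exp(lf0 - denom)
    return tau, float(denom.sum())


def _weighted_mle(k, n, w, mu_start, rho_start, mu_bounds):
    """Bounded maximisation of the w-weighted beta-binomial log-likelihood."""
    mu_start = float(np.clip(mu_start, mu_bounds[0], mu_bounds[1]))
    rho_start = float(np.clip(rho_start, *RHO_BOUNDS))

    def nll(theta):
        mu, rho = theta
        return -float(np.sum(w * betabin_logpmf(k, n, mu, rho)))

    res = minimize(nll, x0=[mu_start, rho_start], method="L-BFGS-B",
                   bounds=[mu_bounds, RHO_BOUNDS])
    # never accept a step that worsens the weighted objective: EM monotonicity
    if res.fun <= nll([mu_start, rho_start]):
        return float(res.x[0]), float(res.x[1])
    return mu_start, rho_start


def fit_mixture(k, n, xi_qualsum, init: MixtureParams | None = None,
                tol: float = 1e-6, max_iter: int = 1000,
                default_eps: float = DEFAULT_EPSILON) -> MixtureFit:
    """Fit the mixture by EM on one sample's gene-level (k, n, qualsum).

    E-step: responsibilities tau_i0.  M-step: pi0 in closed form; (mu, rho)
    of each component by bounded numerical maximisation of the weighted
    log-likelihood.  mu0 is anchored to the interval
    [eps_bar/3, 3*eps_bar + 1e-6] around the quality-derived mean error rate
    eps_bar of inactivated-weighted genes, keeping the inactivated component
    tied to the sequencing-error regime.  The log-likelihood is
    non-decreasing across iterations.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    keep = n > 0
    if keep.sum() < 10:
        raise InputError("fit_mixture requires at least 10 genes with reads")
    kf, nf = k[keep], n[keep]
    eps = np.asarray(error_rate_from_quals(xi_qualsum, k, default_eps))[keep]

    p = (init or MixtureParams()).validate()
    if not np.any(kf > 0):  # nothing expressed from the Xi at all
        tau_full = np.full(len(k), np.nan)
        tau_full[keep] = 1.0
        return MixtureFit(params=p, tau=tau_full, loglik=float("-inf"),
                          degenerate=True, eps_bar=float(np.mean(eps)))

    tau, ll = _responsibilities(kf, nf, p)
    trace = [ll]
    converged = False
    it = 0
    eps_bar = float(np.mean(eps))
    for it in range(1, max_iter + 1):
        # M-step
        w0 = tau
        w1 = 1.0 - tau
        eps_bar = float(np.sum(w0 * eps) / max(np.sum(w0), 1e-12))
        mu0_bounds = (eps_bar / 3.0, min(3.0 * eps_bar + 1e-6, MU1_BOUNDS[0] * 0.98))
        pi0 = float(np.clip(np.mean(tau), 1e-6, 1 - 1e-6))
        mu0, rho0 = _weighted_mle(kf, nf, w0, p.mu0, p.rho0, mu0_bounds)
        mu1, rho1 = _weighted_mle(kf, nf, w1, p.mu1, p.rho1, MU1_BOUNDS)
        p = MixtureParams(pi0=pi0, mu0=mu0, rho0=rho0, mu1=mu1, rho1=rho1)
        # E-step
        tau, ll_new = _responsibilities(kf, nf, p)
        trace.append(ll_new)
        if ll_new - ll < tol and ll_new >= ll - 1e-8:
            converged = True
            ll = ll_new
            break
        ll = ll_new
    tau_full = np.full(len(k), np.nan)
    tau_full[keep] = tau
    return MixtureFit(params=p, tau=tau_full, loglik=ll, loglik_trace=trace,
                      n_iter=it, converged=converged, eps_bar=eps_bar)


def tau_inactivation(k, n, xi_qualsum, fit: MixtureFit):
    """Posterior probability of inactivation for arbitrary (k, n) under a
    fitted mixture; NaN where n = 0 (gene not evaluable)."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    scalar = k.ndim == 0
    k, n = np.atleast_1d(k), np.atleast_1d(n)
    out = np.full(len(k), np.nan)
    m = n > 0
    if m.any():
        if fit.degenerate:
            out[m] = 1.0
        else:
            tau, _ = _responsibilities(k[m], n[m], fit.params)
            out[m] = tau
    return float(out[0]) if scalar else out


def escape_census(summary_by_clone: pd.DataFrame, min_reads: int = MIN_READS,
                  alpha: float = ALPHA) -> tuple[int, int]:
    """Count genes significantly expressed from the Xi in >=1 clone.

    ``summary_by_clone`` is a long table with columns gene_id, clone,
    total_reads (n), tau_i0.  Restricted to genes with n >= min_reads in
    both clones.  Returns (n_escape, n_total).
    """
    wide_n = summary_by_clone.pivot(index="gene_id", columns="clone", values="total_reads")
    wide_tau = summary_by_clone.pivot(index="gene_id", columns="clone", values="tau_i0")
    ok = (wide_n >= min_reads).all(axis=1) & wide_n.notna().all(axis=1)
    sig = (wide_tau[ok] <= alpha).any(axis=1)
    return int(sig.sum()), int(ok.sum())


def per_snp_concordance(snp_counts: pd.DataFrame, gene_tau: pd.Series,
                        fit: MixtureFit, alpha: float = ALPHA) -> float:
    """Fraction of SNPs whose individual significance call matches their
    gene's call, over genes with >=2 SNPs.

    ``snp_counts`` carries gene_id, xi_count (k), xa_count and xi_qualsum
    per SNP for one sample; ``gene_tau`` maps gene_id -> gene-level tau_i0.
    """
    df = snp_counts.copy()
    df["n"] = df["xa_count"] + df["xi_count"]
    df = df[df["n"] > 0]
    multi = df.groupby("gene_id")["n"].transform("size") >= 2
    df = df[multi & df["gene_id"].isin(gene_tau.index)]
    if df.empty:
        return float("nan")
    tau_snp = tau_inactivation(df["xi_count"].to_numpy(), df["n"].to_numpy(),
                               df["xi_qualsum"].to_numpy(), fit)
    gene_sig = (gene_tau.loc[df["gene_id"]].to_numpy() <= alpha)
    snp_sig = tau_snp <= alpha
    return float(np.mean(snp_sig == gene_sig))


PRE_TIMEPOINTS = ("hF", "day0")
POST_TIMEPOINTS = ("day4", "day6")

ACTIVE = "active"
REACTIVATED = "reactivated"
INACTIVE = "inactive"
NOT_EVALUATED = "not_evaluated"


def classify_gene(tau: dict, n: dict, alpha: float = ALPHA,
                  min_reads: int = MIN_READS, strict: bool = False) -> str:
    """Classify one gene's reprogramming time course.

    ``tau`` and ``n`` map (clone, timepoint) -> value on replicate-merged
    data; missing or zero-coverage points are treated as absent.

    Evaluability requires >= ``min_reads`` reads in at least one pre-fusion
    point (hF or day0, either clone) and at least one post-fusion point
    (day4 or day6); ``strict=True`` instead requires day4 and day6 each to
    reach the threshold.  Then, with "significant" meaning tau <= alpha:

    * active       — significant at >=1 pre point and >=1 post point;
    * reactivated  — not significant at any observed pre point (both
                     clones) but significant at >=1 post point;
    * inactive     — not significant anywhere.

    Precedence: active > reactivated > inactive.
    """
    def points(tps):
        return [(c, t) for (c, t) in tau.keys() if t in tps
                and tau[(c, t)] is not None and not np.isnan(tau[(c, t)])]

    def covered(tps):
        return [(c, t) for (c, t) in n.keys() if t in tps
                and n[(c, t)] is not None and n[(c, t)] >= min_reads]

    if strict:
        post_ok = all(any(t == tp for _, t in covered(POST_TIMEPOINTS))
                      for tp in POST_TIMEPOINTS)
    else:
        post_ok = bool(covered(POST_TIMEPOINTS))
    if not covered(PRE_TIMEPOINTS) or not post_ok:
        return NOT_EVALUATED

    pre_sig = any(tau[p] <= alpha for p in points(PRE_TIMEPOINTS))
    post_sig = any(tau[p] <= alpha for p in points(POST_TIMEPOINTS))
    if pre_sig and post_sig:
        return ACTIVE
    if post_sig:
        return REACTIVATED
    return INACTIVE


def classify_genes(results: pd.DataFrame, alpha: float = ALPHA,
                   min_reads: int = MIN_READS, strict: bool = False) -> pd.DataFrame:
    """Classify every gene from a long results table with columns gene_id,
    clone, timepoint, total_reads, tau_i0 (replicate-merged)."""
    rows = []
    clones = sorted(results["clone"].unique())
    tps = list(PRE_TIMEPOINTS + POST_TIMEPOINTS)
    for gene_id, grp in results.groupby("gene_id"):
        tau = {(r.clone, r.timepoint): r.tau_i0 for r in grp.itertuples()}
        n = {(r.clone, r.timepoint): r.total_reads for r in grp.itertuples()}
        row = {"gene_id": gene_id,
               "class": classify_gene(tau, n, alpha=alpha, min_reads=min_reads,
                                      strict=strict)}
        for c in clones:
            for t in tps:
                row[f"tau_{c}_{t}"] = tau.get((c, t), np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def classification_census(calls: pd.DataFrame) -> dict:
    """Tabulate classes; reports the evaluable-gene denominator."""
    counts = calls["class"].value_counts().to_dict()
    out = {cls: int(counts.get(cls, 0))
           for cls in (ACTIVE, REACTIVATED, INACTIVE, NOT_EVALUATED)}
    out["n_evaluable"] = out[ACTIVE] + out[REACTIVATED] + out[INACTIVE]
    return out
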