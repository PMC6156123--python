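"""Empirical-Bayes Beta-negative-binomial differential-expression engine.

Model: counts for gene g in sample i follow NB(r_gi, q_g) with
P(X = x) = C(x + r - 1, x) q^r (1 - q)^x, so that E[X] = r(1 - q)/q.
Library depth enters through the size parameter, r_gi = r0_g * s_i with s_i
the sample's size factor, so expected counts scale with depth at a shared
success probability q_g.  The success probability carries a conjugate
Beta(alpha, beta) prior, which integrates out to a closed-form marginal
("predictive") likelihood for any group of samples:

    f(x_1..x_n) = [prod_i C(x_i + r_i - 1, x_i)]
                  * B(alpha + sum r_i, beta + sum x_i) / B(alpha, beta)

A two-component mixture compares, per gene, equal expression (EE: one q
shared by both conditions) against differential expression (DE: independent
q per condition).  The mixing proportion p and the prior shapes (alpha,
beta) are fitted by expectation-maximization on the incomplete-data
log-likelihood; the per-gene posterior weight of the DE component is the
PPDE and its complement the PPEE.  Genes are called DE at a hard posterior
threshold PPDE >= 1 - FDR combined with a fold-change gate, and EE at
PPEE >= 1 - FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import betaln, gammaln, logsumexp

logger = logging.getLogger(__name__)

_LOG_SHAPE_BOUND = np.log(1e4)


@dataclass
class EBHyperparams:
    """Fitted prior shapes, mixing proportion and per-gene NB sizes."""

    alpha: float
    beta: float
    p_de: float
    r0: np.ndarray  # per-gene NB size (before size-factor scaling)

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("Beta shapes must be positive")
        if not 0.0 <= self.p_de <= 1.0:
            raise ValueError("p_de must lie in [0, 1]")


@dataclass
class EBFit:
    """Result of an EM fit: posteriors, marginals and the likelihood trace."""

    genes: pd.Index
    hyperparams: EBHyperparams
    log_f_ee: np.ndarray
    log_f_de: np.ndarray
    ppde: pd.Series
    ppee: pd.Series
    mean_a: pd.Series  # normalized condition means
    mean_b: pd.Series
    loglik_trace: list = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0


def _validate_counts(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x)
    if np.any(x < 0):
        raise ValueError(f"{name}: counts must be non-negative")
    if not np.allclose(x, np.rint(x)):
        raise ValueError(f"{name}: counts must be integers (round upstream)")
    return np.rint(x).astype(np.int64)


def marginal_loglik(
    x: Sequence[float], r: Sequence[float], alpha: float, beta: float
) -> float:
    """Log marginal likelihood of one group of counts under the Beta-NB model.

    ``x`` are the counts and ``r`` the matching per-sample NB size
    parameters; the Beta(alpha, beta) prior on the shared success
    probability is integrated out analytically.
    """
    x = _validate_counts(np.atleast_1d(np.asarray(x, dtype=float)), "x")
    r = np.atleast_1d(np.asarray(r, dtype=float))
    if r.shape != x.shape:
        raise ValueError("x and r must have matching shapes")
    if np.any(r <= 0) or alpha <= 0 or beta <= 0:
        raise ValueError("r, alpha, beta must be positive")
    comb = np.sum(gammaln(x + r) - gammaln(r) - gammaln(x + 1))
    return float(comb + betaln(alpha + r.sum(), beta + x.sum()) - betaln(alpha, beta))


def _row_marginal(
    X: np.ndarray, R: np.ndarray, alpha: float, beta: float, comb: np.ndarray
) -> np.ndarray:
    """Vectorized marginal log-likelihood per gene; ``comb`` precomputed."""
    return comb + betaln(alpha + R.sum(axis=1), beta + X.sum(axis=1)) - betaln(alpha, beta)


def _estimate_r0(
    xa: np.ndarray, xb: np.ndarray, s: np.ndarray, prior_df: float = 10.0
) -> np.ndarray:
    """Moderated method-of-moments NB size per gene on normalized counts.

    The gene-wise estimate uses the pooled within-condition variance when
    both conditions have at least two samples (so genuine DE does not
    inflate the dispersion) and the total variance otherwise (the 1-vs-1
    pairwise case).  With few replicates the gene-wise excess-variance
    coefficient phi = 1/r0 is extremely noisy, so it is shrunk toward the
    transcriptome-wide median with ``prior_df`` pseudo-degrees of freedom,
    the usual moderated-dispersion construction for small-n RNA-seq.
    """
    na = xa.shape[1]
    x = np.concatenate([xa, xb], axis=1) / s[None, :]
    mean = x.mean(axis=1)
    if na >= 2 and x.shape[1] - na >= 2:
        va = x[:, :na].var(axis=1, ddof=1)
        vb = x[:, na:].var(axis=1, ddof=1)
        var = (va * (na - 1) + vb * (x.shape[1] - na - 1)) / (x.shape[1] - 2)
        df = x.shape[1] - 2
    else:
        var = x.var(axis=1, ddof=1) if x.shape[1] > 1 else mean
        df = max(x.shape[1] - 1, 1)
    mean = np.maximum(mean, 1e-8)
    phi = np.maximum(var - mean, 0.0) / (mean * mean)  # 1/r0, >= 0
    informative = mean > 1.0
    phi0 = float(np.median(phi[informative])) if informative.any() else float(np.median(phi))
    phi_shrunk = (df * phi + prior_df * phi0) / (df + prior_df)
    phi_shrunk = np.maximum(phi_shrunk, 1.0 / (50.0 * mean))  # caps r0 at 50 * mean
    r0 = 1.0 / phi_shrunk
    return np.clip(r0, 1e-2, 1e8)


def fit_eb(
    counts_a,
    counts_b,
    size_factors: Optional[Sequence[float]] = None,
    max_iter: int = 200,
    tol: float = 1e-6,
    p_init: float = 0.5,
) -> EBFit:
    """Fit the two-component EE/DE mixture by expectation-maximization.

    ``counts_a`` and ``counts_b`` are gene x sample matrices (DataFrames or
    arrays) for the two conditions with matched gene sets.  Size factors
    cover the concatenated samples (A then B); when omitted they default to
    column-sum ratios.  Each EM iteration maximizes the incomplete-data
    log-likelihood over (alpha, beta) by Nelder-Mead and updates the mixing
    proportion as the mean PPDE; the trace is non-decreasing by
    construction.  All-zero genes carry no evidence and are assigned
    PPDE = 0 outside the fit.
    """
    if isinstance(counts_a, pd.DataFrame):
        genes = counts_a.index
        if isinstance(counts_b, pd.DataFrame):
            if not counts_a.index.equals(counts_b.index):
                raise ValueError("condition matrices must share the gene index")
    else:
        genes = pd.RangeIndex(np.asarray(counts_a).shape[0])
    xa = _validate_counts(np.atleast_2d(np.asarray(counts_a, dtype=float)), "counts_a")
    xb = _validate_counts(np.atleast_2d(np.asarray(counts_b, dtype=float)), "counts_b")
    if xa.shape[0] != xb.shape[0]:
        raise ValueError("condition matrices must have matching gene sets")
    if xa.shape[1] < 1 or xb.shape[1] < 1:
        raise ValueError("each condition needs at least one sample")
    na, nb = xa.shape[1], xb.shape[1]

    if size_factors is None:
        totals = np.concatenate([xa, xb], axis=1).sum(axis=0).astype(float)
        totals = np.maximum(totals, 1.0)
        s = totals / np.exp(np.mean(np.log(totals)))
    else:
        s = np.asarray(size_factors, dtype=float)
        if s.shape != (na + nb,):
            raise ValueError("size_factors must cover A then B samples")
        if np.any(s <= 0):
            raise ValueError("size factors must be positive")

    X = np.concatenate([xa, xb], axis=1).astype(float)
    nonzero = X.sum(axis=1) > 0
    if not nonzero.all():
        logger.info("%d all-zero genes assigned PPDE = 0", int((~nonzero).sum()))

    r0 = _estimate_r0(xa, xb, s)
    R = r0[:, None] * s[None, :]
    Xa, Xb = X[:, :na], X[:, na:]
    Ra, Rb = R[:, :na], R[:, na:]

    # combinatorial terms do not depend on (alpha, beta): compute once
    comb_all = np.sum(gammaln(X + R) - gammaln(R) - gammaln(X + 1), axis=1)
    comb_a = np.sum(gammaln(Xa + Ra) - gammaln(Ra) - gammaln(Xa + 1), axis=1)
    comb_b = comb_all - comb_a

    fit_mask = nonzero
    sum_r, sum_x = R.sum(axis=1), X.sum(axis=1)
    sum_ra, sum_xa = Ra.sum(axis=1), Xa.sum(axis=1)
    sum_rb, sum_xb = Rb.sum(axis=1), Xb.sum(axis=1)

    def components(alpha: float, beta: float):
        lb0 = betaln(alpha, beta)
        lee = comb_all + betaln(alpha + sum_r, beta + sum_x) - lb0
        lde = (
            comb_all
            + betaln(alpha + sum_ra, beta + sum_xa)
            + betaln(alpha + sum_rb, beta + sum_xb)
            - 2.0 * lb0
        )
        return lee, lde

    def incomplete_ll(alpha: float, beta: float, p: float) -> float:
        lee, lde = components(alpha, beta)
        stacked = np.stack(
            [lee[fit_mask] + np.log1p(-p), lde[fit_mask] + np.log(p)]
        )
        return float(logsumexp(stacked, axis=0).sum())

    log_ab = np.array([0.0, 0.0])  # alpha = beta = 1
    p = float(np.clip(p_init, 1e-6, 1 - 1e-6))
    trace: list = []
    converged = False
    it = 0
    if not fit_mask.any():
        max_iter = 0  # nothing informative to fit: keep the initial prior
        converged = True
    for it in range(1, max_iter + 1):
        # M-step (alpha, beta): direct ascent of the incomplete-data loglik.
        # Nelder-Mead returns the best point evaluated, which includes the
        # starting point, so the trace cannot decrease here.
        def neg(v: np.ndarray) -> float:
            a = float(np.exp(np.clip(v[0], -_LOG_SHAPE_BOUND, _LOG_SHAPE_BOUND)))
            b = float(np.exp(np.clip(v[1], -_LOG_SHAPE_BOUND, _LOG_SHAPE_BOUND)))
            return -incomplete_ll(a, b, p)

        res = minimize(
            neg,
            log_ab,
            method="Nelder-Mead",
            options={"maxiter": 80, "xatol": 1e-3, "fatol": 1e-8},
        )
        if -res.fun >= -neg(log_ab):
            log_ab = np.clip(res.x, -_LOG_SHAPE_BOUND, _LOG_SHAPE_BOUND)
        alpha, beta = float(np.exp(log_ab[0])), float(np.exp(log_ab[1]))

        # E-step + exact M-step for p
        lee, lde = components(alpha, beta)
        log_num = lde[fit_mask] + np.log(p)
        log_den = np.logaddexp(lee[fit_mask] + np.log1p(-p), log_num)
        ppde_fit = np.exp(log_num - log_den)
        p = float(np.clip(ppde_fit.mean(), 1e-6, 1 - 1e-6))

        ll = incomplete_ll(alpha, beta, p)
        if trace and ll < trace[-1] - 1e-8 * (1.0 + abs(trace[-1])):
            logger.warning("EM log-likelihood decreased at iteration %d", it)
        if trace and abs(ll - trace[-1]) < tol * (1.0 + abs(ll)):
            trace.append(ll)
            converged = True
            break
        trace.append(ll)
    if not converged:
        logger.info("EM reached max_iter=%d without convergence", max_iter)

    alpha, beta = float(np.exp(log_ab[0])), float(np.exp(log_ab[1]))
    lee, lde = components(alpha, beta)
    log_num = lde + np.log(p)
    log_den = np.logaddexp(lee + np.log1p(-p), log_num)
    ppde = np.exp(log_num - log_den)
    ppde[~nonzero] = 0.0

    mean_a = (Xa / s[None, :na]).mean(axis=1)
    mean_b = (Xb / s[None, na:]).mean(axis=1)
    hyper = EBHyperparams(alpha=alpha, beta=beta, p_de=p, r0=r0)
    return EBFit(
        genes=genes,
        hyperparams=hyper,
        log_f_ee=lee,
        log_f_de=lde,
        ppde=pd.Series(ppde, index=genes, name="PPDE"),
        ppee=pd.Series(1.0 - ppde, index=genes, name="PPEE"),
        mean_a=pd.Series(mean_a, index=genes),
        mean_b=pd.Series(mean_b, index=genes),
        loglik_trace=trace,
        converged=converged,
        n_iter=it,
    )


def call_de(
    fit: EBFit, fdr: float = 0.05, min_fc: float = 1.5
) -> pd.DataFrame:
    """Call differential expression at PPDE >= 1 - fdr with a fold-change gate.

    The fold change is computed on pseudocounted normalized means,
    FC = (mean_A + 1) / (mean_B + 1), and a gene passes the gate when
    max(FC, 1/FC) > min_fc.  The returned table carries every gene with
    its posterior, fold change, direction and called flag; the expected
    false-discovery proportion of the called set (mean PPEE over calls) is
    bounded by ``fdr`` because each call individually satisfies
    PPEE <= fdr.
    """
    fc = (fit.mean_a + 1.0) / (fit.mean_b + 1.0)
    called = (fit.ppde >= 1.0 - fdr) & (np.maximum(fc, 1.0 / fc) > min_fc)
    direction = np.where(fc >= 1.0, "A", "B")
    return pd.DataFrame(
        {
            "PPDE": fit.ppde,
            "PPEE": fit.ppee,
            "FC": fc,
            "direction": direction,
            "called": called,
        },
        index=fit.genes,
    )


def call_ee(fit: EBFit, fdr: float = 0.05) -> pd.Index:
    """Genes called equally expressed: PPEE >= 1 - fdr."""
    return fit.genes[fit.ppee >= 1.0 - fdr]
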