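"""Empirical-Bayes moderated two-group differential expression.

Per gene, a pooled-variance two-group fit (subtype vs reference) gives the
log2 fold change and residual variance; variances are shrunk toward a
prior estimated by matching moments of log residual variances to
digamma/trigamma expressions, giving a moderated t with augmented degrees
of freedom; the B statistic is the posterior log-odds of differential
expression.  A gene is called over-expressed when log2FC >= +1 with
B >= 6, under-expressed when log2FC <= -1 with B >= 6, otherwise not
significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma

from .mi_network import ExpressionMatrix

_trigamma = lambda x: polygamma(1, x)
_tetragamma = lambda x: polygamma(2, x)

#: degrees of freedom treated as effectively infinite (full shrinkage)
_DF_INF = 1e12


@dataclass
class EBayesPrior:
    """Hyperparameters of the variance/fold-change prior.

    d0 : prior degrees of freedom of the inverse-chi-square variance prior
        (np.inf when all variances coincide: full shrinkage).
    s0_sq : prior residual variance (log2 units squared).
    v0 : prior variance of the log fold change, on the unscaled-variance
        scale, used by the B statistic.
    p_prior : prior probability that a gene is differentially expressed.
    """

    d0: float
    s0_sq: float
    v0: float
    p_prior: float = 0.01

    def __post_init__(self):
        if not self.d0 >= 0:
            raise ValueError("d0 must be non-negative (0 means no shrinkage)")
        if not self.s0_sq > 0:
            raise ValueError("s0_sq must be positive")
        if not 0 < self.p_prior < 1:
            raise ValueError("p_prior must lie in (0, 1)")


def fit_two_group(case: ExpressionMatrix, control: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene pooled-variance two-group fit on log2 values.

    Genes are matched by id (inner join of the two matrices' gene lists,
    in the case matrix's order).  Returns log_fc (case minus control),
    residual variance s2 with df = n1+n2-2, the ordinary t statistic, and
    the unscaled standard deviation sqrt(1/n1 + 1/n2).
    """
    if case.n_samples < 2 or control.n_samples < 2:
        raise ValueError("need at least 2 samples per group")
    common = [g for g in case.genes if g in set(control.genes)]
    if not common:
        raise ValueError("no shared genes between the two matrices")
    ci = {g: i for i, g in enumerate(case.genes)}
    ki = {g: i for i, g in enumerate(control.genes)}
    x = case.values[[ci[g] for g in common]]
    y = control.values[[ki[g] for g in common]]
    n1, n2 = x.shape[1], y.shape[1]
    log_fc = x.mean(axis=1) - y.mean(axis=1)
    ss = x.var(axis=1, ddof=1) * (n1 - 1) + y.var(axis=1, ddof=1) * (n2 - 1)
    df = n1 + n2 - 2
    s2 = ss / df
    su = np.sqrt(1 / n1 + 1 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(s2 > 0, log_fc / (np.sqrt(s2) * su), 0.0)
    return pd.DataFrame(
        {
            "gene": common,
            "log_fc": log_fc,
            "s2": s2,
            "df_residual": float(df),
            "t_ordinary": t,
            "stdev_unscaled": su,
            "zero_variance": s2 == 0,
        }
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1 / np.sqrt(y)
    x = 0.5 + 1 / y
    for _ in range(50):
        tri = _trigamma(x)
        dif = tri * (1 - tri / y) / _tetragamma(x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def estimate_prior(
    results: pd.DataFrame, p_prior: float = 0.01
) -> EBayesPrior:
    """Estimate (d0, s0_sq) by moment matching on log residual variances
    and v0 from the fold-change spread among the top-|t| genes.

    With s2 ~ s0^2 chi^2_df / df scaled by a chi^2_d0 prior, log s2 has
    mean log s0^2 + digamma(df/2) - log(df/2) shifted by the prior terms
    and excess variance trigamma(d0/2); inverting the trigamma gives d0.
    Identical variances give d0 = inf (full shrinkage).  v0 is a
    method-of-moments stand-in for the likelihood-based estimate used by
    limma, taken from genes in the top p_prior quantile of |moderated t|.
    """
    s2 = results["s2"].to_numpy(dtype=float)
    df = float(results["df_residual"].iloc[0])
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need at least 2 genes with positive variance")
    z = np.log(s2[ok])
    e = z - digamma(df / 2) + np.log(df / 2)
    excess = z.var(ddof=1) - _trigamma(df / 2)
    if excess <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(e.mean()))
    else:
        d0 = 2 * _trigamma_inverse(excess)
        s0_sq = float(np.exp(e.mean() + digamma(d0 / 2) - np.log(d0 / 2)))
    # provisional moderated t to rank genes for the v0 estimate
    d0_eff = min(d0, _DF_INF)
    s2_post = (d0_eff * s0_sq + df * s2) / (d0_eff + df)
    su = results["stdev_unscaled"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(s2_post > 0, results["log_fc"] / (np.sqrt(s2_post) * su), 0.0)
    ntop = max(1, int(np.ceil(p_prior * len(s2))))
    top = np.argsort(-np.abs(t_mod))[:ntop]
    # E[logfc^2] ~ (v_g + v0) * s2_post for truly DE genes
    v0_hat = np.mean(
        results["log_fc"].to_numpy()[top] ** 2 / s2_post[top] - su[top] ** 2
    )
    v0 = float(max(v0_hat, np.mean(su**2)))
    return EBayesPrior(d0=float(d0), s0_sq=s0_sq, v0=v0, p_prior=p_prior)


def moderate(results: pd.DataFrame, prior: EBayesPrior) -> pd.DataFrame:
    """Attach the posterior variance, moderated t, total df and B.

    s2_post = (d0 s0^2 + df s2) / (d0 + df); t_mod uses s2_post in place
    of s2; df_total = d0 + df.  B is the log posterior odds of DE:

        B = log(p/(1-p)) - log(r)/2
            + (1+df_total)/2 * log((t^2 + df_total) / (t^2/r + df_total))

    with r = (su^2 + v0)/su^2.  B is increasing in |t_mod| and collapses
    to log(p/(1-p)) (0 at p=1/2) as v0 -> 0.
    """
    out = results.copy()
    df = out["df_residual"].to_numpy(dtype=float)
    s2 = out["s2"].to_numpy(dtype=float)
    su = out["stdev_unscaled"].to_numpy(dtype=float)
    d0 = min(prior.d0, _DF_INF)
    s2_post = (d0 * prior.s0_sq + df * s2) / (d0 + df)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(
            s2_post > 0, out["log_fc"].to_numpy() / (np.sqrt(s2_post) * su), 0.0
        )
    df_total = d0 + df
    r = (su**2 + prior.v0) / su**2
    t2 = t_mod**2
    kernel = (1 + df_total) / 2 * np.log((t2 + df_total) / (t2 / r + df_total))
    b = np.log(prior.p_prior / (1 - prior.p_prior)) - np.log(r) / 2 + kernel
    out["s2_post"] = s2_post
    out["t_moderated"] = t_mod
    out["df_total"] = df_total
    out["B"] = b
    return out


def classify(
    results: pd.DataFrame, lfc_thresh: float = 1.0, b_thresh: float = 6.0
) -> pd.DataFrame:
    """Three-way call: over (log_fc >= +lfc and B >= b), under
    (log_fc <= -lfc and B >= b), else ns."""
    out = results.copy()
    lfc = out["log_fc"].to_numpy()
    b = out["B"].to_numpy()
    call = np.where(
        (lfc >= lfc_thresh) & (b >= b_thresh),
        "over",
        np.where((lfc <= -lfc_thresh) & (b >= b_thresh), "under", "ns"),
    )
    out["call"] = call
    return out


def run_de(
    case: ExpressionMatrix,
    control: ExpressionMatrix,
    lfc_thresh: float = 1.0,
    b_thresh: float = 6.0,
    p_prior: float = 0.01,
) -> pd.DataFrame:
    """Fit, moderate and classify in one call (case vs reference)."""
    fits = fit_two_group(case, control)
    prior = estimate_prior(fits, p_prior=p_prior)
    return classify(moderate(fits, prior), lfc_thresh, b_thresh)


def community_de_profile(
    community_sets: dict, calls_by_phenotype: dict
) -> pd.DataFrame:
    """Per-community, per-subtype composition of DE calls.

    ``community_sets`` maps network label -> CommunitySet;
    ``calls_by_phenotype`` maps subtype label -> classified DE table
    (that subtype vs the reference).  Genes absent from a DE table are
    counted as ns.  Counts always sum to the community size.
    """
    rows = []
    for net in sorted(community_sets):
        for comm in sorted(community_sets[net], key=lambda c: c.label):
            for pheno in sorted(calls_by_phenotype):
                table = calls_by_phenotype[pheno]
                call_of = dict(zip(table["gene"], table["call"]))
                counts = {"over": 0, "under": 0, "ns": 0}
                for g in comm.genes:
                    counts[call_of.get(g, "ns")] += 1
                rows.append(
                    (
                        net,
                        comm.label,
                        pheno,
                        len(comm.genes),
                        counts["over"],
                        counts["under"],
                        counts["ns"],
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "network",
            "community",
            "phenotype",
            "size",
            "n_over",
            "n_under",
            "n_ns",
        ],
    )
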