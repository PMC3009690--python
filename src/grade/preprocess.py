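"""Expression filtering and significance screening.

Inputs are assumed already background-corrected and normalized (e.g. RMA);
this module reproduces the downstream gene-selection steps: an intensity
filter on unlogged data ("expressed" = signal above a threshold in at least
one sample), optional probe-set to gene collapsing, and an empirical-Bayes
moderated-t screen of each condition against a baseline with
Benjamini-Hochberg control across all genes and contrasts.

The moderated t shrinks each gene's residual variance toward a pooled prior
estimated from the whole ensemble of genes by marginal moment matching
(closed-form method-of-moments on log sample variances), which stabilizes
inference when only a handful of arrays per condition is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .postprocess import bh_adjust

__all__ = [
    "FilterReport",
    "ModeratedTResult",
    "expression_filter",
    "collapse_probes",
    "moderated_t_screen",
]


@dataclass
class FilterReport:
    genes_in: int
    genes_kept: int
    rule: str
    threshold: float

    def __str__(self) -> str:
        return (f"expression filter [{self.rule}, threshold={self.threshold:g}]: "
                f"kept {self.genes_kept}/{self.genes_in} genes")


def expression_filter(
    X_unlogged: pd.DataFrame,
    threshold: float = 100.0,
) -> tuple[list[str], FilterReport]:
    """Keep genes whose unlogged signal exceeds *threshold* in >= 1 sample.

    The comparison is strict (a gene whose maximum equals the threshold is
    dropped).  Warns when the data look already log-transformed.
    """
    if len(X_unlogged) and np.nanmax(X_unlogged.to_numpy()) < 30:
        warnings.warn(
            "all intensities are below 30; input may already be log-scale "
            "while the filter expects unlogged data",
            stacklevel=2,
        )
    if len(X_unlogged):
        keep = X_unlogged.max(axis=1) > threshold
        kept = list(X_unlogged.index[keep])
    else:
        kept = []
    report = FilterReport(
        genes_in=len(X_unlogged),
        genes_kept=len(kept),
        rule="max-over-samples strictly above threshold",
        threshold=threshold,
    )
    return kept, report


def collapse_probes(
    X: pd.DataFrame,
    probe_to_gene: dict[str, str],
    strategy: str = "max_mean",
) -> pd.DataFrame:
    """Collapse probe-set rows to one row per gene.

    ``max_mean`` (default) keeps, for each gene, the probe set with the
    highest average intensity; ``mean`` averages all of a gene's probe sets.
    Probes without a gene mapping are dropped.
    """
    mapped = X.loc[[p for p in X.index if p in probe_to_gene]].copy()
    genes = pd.Series({p: probe_to_gene[p] for p in mapped.index})
    if strategy == "max_mean":
        best = (
            mapped.mean(axis=1)
            .groupby(genes)
            .idxmax()
        )
        out = mapped.loc[best.values]
        out.index = best.index
        return out
    if strategy == "mean":
        return mapped.groupby(genes).mean()
    raise ValueError(f"unknown collapsing strategy {strategy!r}")


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the inverse scale)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match the scaled inverse-chi-square prior (d0, s0^2).

    Matches mean and variance of ``log s^2`` against its sampling
    distribution given residual df; infinite d0 means complete pooling.
    Genes with zero sample variance are excluded from the fit.
    """
    s2 = s2[s2 > 0]
    if s2.size < 2:
        raise ValueError("need at least two genes with positive residual "
                         "variance to fit the variance prior")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    ebar = float(np.mean(e))
    n = e.size
    evar = float(np.mean((e - ebar) ** 2) * n / (n - 1)) - float(
        special.polygamma(1, df / 2.0)
    )
    if evar <= 0:
        # no excess spread in log s^2: complete pooling; the scale MLE is
        # the plain mean of the sample variances
        return np.inf, float(np.mean(s2))
    d0 = 2.0 * _trigamma_inverse(evar)
    s02 = float(np.exp(ebar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s02


@dataclass
class ModeratedTResult:
    table: pd.DataFrame  # gene, contrast, log_fc, t, p, p_adj
    significant_genes: list[str]
    prior_df: float
    prior_var: float


def moderated_t_screen(
    X: pd.DataFrame,
    conditions: list[str],
    baseline: str,
    alpha: float = 0.05,
) -> ModeratedTResult:
    """Empirical-Bayes moderated-t screen of each condition vs the baseline.

    Parameters
    ----------
    X
        Log-scale genes x samples matrix.
    conditions
        Condition label of each column; every condition needs >= 2
        replicates somewhere for the residual variance to be estimable.
    baseline
        The reference condition (e.g. the unstimulated time point).
    alpha
        BH-adjusted significance level, applied jointly across all genes
        and contrasts; a gene is reported significant if any of its
        contrasts passes.
    """
    if len(conditions) != X.shape[1]:
        raise ValueError("one condition label per column required")
    if baseline not in conditions:
        raise ValueError(f"baseline condition {baseline!r} not among labels")
    cond_arr = np.asarray(conditions)
    levels = list(dict.fromkeys(conditions))
    counts = {c: int(np.sum(cond_arr == c)) for c in levels}
    N, G = len(conditions), len(levels)
    df_resid = N - G
    if df_resid < 1:
        raise ValueError(
            "no residual degrees of freedom: need replicated conditions "
            "(at least one condition with >= 2 replicates)"
        )

    data = X.to_numpy(dtype=float)
    means = {c: data[:, cond_arr == c].mean(axis=1) for c in levels}
    rss = np.zeros(len(X))
    for c in levels:
        block = data[:, cond_arr == c]
        rss += ((block - means[c][:, None]) ** 2).sum(axis=1)
    s2 = rss / df_resid

    d0, s02 = _fit_variance_prior(s2, df_resid)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
    else:
        s2_post = (d0 * s02 + df_resid * s2) / (d0 + df_resid)
    # reference t distribution: residual + prior df, but never more df than
    # the whole ensemble of genes actually carries
    df_total = min(d0 + df_resid, len(X) * df_resid)

    rows = []
    for c in levels:
        if c == baseline:
            continue
        v = 1.0 / counts[c] + 1.0 / counts[baseline]
        log_fc = means[c] - means[baseline]
        t = log_fc / np.sqrt(s2_post * v)
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
        for g, fc_g, t_g, p_g in zip(X.index, log_fc, t, p):
            rows.append((g, c, fc_g, t_g, p_g))
    table = pd.DataFrame(
        rows, columns=["gene", "contrast", "log_fc", "t", "p"]
    )
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    sig = sorted(set(table.loc[table["p_adj"] < alpha, "gene"]))
    return ModeratedTResult(
        table=table,
        significant_genes=sig,
        prior_df=d0,
        prior_var=s02,
    )
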