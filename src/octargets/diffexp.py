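"""Two-group differential expression with empirical-Bayes moderated t.

Per gene, the cancer-control contrast is fit by least squares (group
means), residual variances are shrunk toward a pooled prior estimated by
moment matching on ``log s^2`` (the limma-style hierarchical model
``s^2 | sigma^2 ~ sigma^2 chi^2_df / df``, ``1/sigma^2 ~ chi^2_d0 /
(d0 s0^2)``), and the moderated t-statistic is referenced against a t
distribution with ``d0 + df`` degrees of freedom.  Genes pass the
selection gate when ``|logFC| >= log2(1.5)`` and the BH-adjusted p-value
is at most 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionDataset
from .errors import DesignError, InputFormatError

FC_THRESHOLD = 1.5
ADJP_THRESHOLD = 0.05

#: prior df beyond this are treated as infinite (complete shrinkage)
_D0_CAP = 1e6


@dataclass
class ContrastFit:
    """Per-gene summaries of the cancer-control contrast."""

    genes: list[str]
    logfc: np.ndarray
    s2: np.ndarray
    df: int
    n_cancer: int
    n_control: int
    zero_variance: np.ndarray = field(default=None)
    d0: float | None = None
    s0_sq: float | None = None
    s2_post: np.ndarray | None = None
    t_mod: np.ndarray | None = None
    p: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        cols = {"logFC": self.logfc, "s2": self.s2}
        if self.t_mod is not None:
            cols.update({"t": self.t_mod, "p": self.p})
        return pd.DataFrame(cols, index=self.genes)


def fit_group_contrast(ds: ExpressionDataset) -> ContrastFit:
    """Least-squares two-group fit: logFC = mean(cancer) - mean(control).

    ``s2`` is the pooled residual variance with ``df = n1 + n2 - 2``.
    """
    is_cancer = (ds.condition == "cancer").to_numpy()
    is_control = (ds.condition == "control").to_numpy()
    n1, n2 = int(is_cancer.sum()), int(is_control.sum())
    if n1 < 2 or n2 < 2:
        raise DesignError(f"need >= 2 samples per condition, got cancer={n1} control={n2}")
    X = ds.values.to_numpy(dtype=float)
    c, k = X[:, is_cancer], X[:, is_control]
    logfc = c.mean(axis=1) - k.mean(axis=1)
    df = n1 + n2 - 2
    s2 = ((c - c.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 += ((k - k.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 /= df
    return ContrastFit(genes=ds.genes, logfc=logfc, s2=s2, df=df,
                       n_cancer=n1, n_control=n2,
                       zero_variance=(s2 == 0.0))


def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y by Newton iteration (limma's trigammaInverse)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif / x) < tol:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-matching estimates of the prior df ``d0`` and scale ``s0^2``.

    Works on ``e = log(s^2)`` corrected for the chi-square log-moments;
    the prior df follows from inverting the trigamma relation
    ``var(e) = trigamma(df/2) + trigamma(d0/2)``.
    """
    s2 = np.asarray(s2, dtype=float)
    if s2.size < 10:
        raise DesignError("prior estimation needs at least 10 genes")
    if np.ptp(np.log(s2)) < 1e-12:
        # identical variances: infinite prior df, prior scale = the common
        # value, so moderation leaves the ordinary t untouched
        return np.inf, float(s2[0])
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if e_var <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
    else:
        d0 = 2.0 * _trigamma_inverse(float(e_var))
        if d0 > _D0_CAP:
            d0 = np.inf
            s0_sq = float(np.exp(e_mean))
        else:
            s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderate_variances(fit: ContrastFit, d0: float | None = None,
                       s0_sq: float | None = None) -> ContrastFit:
    """Shrink per-gene variances and fill moderated t and p-values.

    Hyperparameters are estimated once for the dataset unless supplied
    (forcing ``d0`` is useful for checking the ordinary-t limit).  Genes
    with zero sample variance are given one tenth of the smallest positive
    variance before moderation and flagged.
    """
    s2 = fit.s2.copy()
    zero = s2 == 0.0
    if zero.all():
        raise DesignError("all genes have zero residual variance")
    if zero.any():
        s2[zero] = s2[~zero].min() / 10.0

    if d0 is None or s0_sq is None:
        d0, s0_sq = estimate_prior(s2, fit.df)
    if not np.isfinite(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + fit.df * s2) / (d0 + fit.df)
        df_total = d0 + fit.df

    se = np.sqrt(s2_post * (1.0 / fit.n_cancer + 1.0 / fit.n_control))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, fit.logfc / se, 0.0)
    if np.isfinite(df_total):
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    else:
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    out = ContrastFit(genes=fit.genes, logfc=fit.logfc, s2=fit.s2, df=fit.df,
                      n_cancer=fit.n_cancer, n_control=fit.n_control,
                      zero_variance=zero)
    out.d0, out.s0_sq, out.s2_post, out.t_mod, out.p = d0, s0_sq, s2_post, t_mod, p
    return out


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p <= 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_de(fit: ContrastFit, fc_threshold: float = FC_THRESHOLD,
              adjp_threshold: float = ADJP_THRESHOLD) -> pd.DataFrame:
    """Apply the fold-change and FDR gate; returns the DE table.

    Kept genes satisfy ``|logFC| >= log2(fc_threshold)`` and
    ``adj_p <= adjp_threshold``; ``direction`` is the sign of logFC.
    Columns: gene (index), logFC, p, adj_p, direction.
    """
    if fit.p is None:
        raise InputFormatError("select_de needs a moderated fit (run moderate_variances)")
    adj_p = bh_adjust(fit.p)
    lfc_gate = np.abs(fit.logfc) >= np.log2(fc_threshold)
    keep = lfc_gate & (adj_p <= adjp_threshold)
    table = pd.DataFrame(
        {
            "logFC": fit.logfc[keep],
            "p": fit.p[keep],
            "adj_p": adj_p[keep],
            "direction": np.sign(fit.logfc[keep]).astype(int),
        },
        index=pd.Index(np.asarray(fit.genes)[keep], name="gene"),
    )
    return table.sort_values("adj_p", kind="mergesort")


def full_table(fit: ContrastFit) -> pd.DataFrame:
    """All genes with logFC, p, adj_p and sign (no gate applied)."""
    adj_p = bh_adjust(fit.p)
    return pd.DataFrame(
        {"logFC": fit.logfc, "p": fit.p, "adj_p": adj_p,
         "direction": np.sign(fit.logfc).astype(int)},
        index=pd.Index(fit.genes, name="gene"),
    )


def run_diffexp(ds: ExpressionDataset, fc_threshold: float = FC_THRESHOLD,
                adjp_threshold: float = ADJP_THRESHOLD) -> pd.DataFrame:
    """Fit, moderate and gate in one call."""
    return select_de(moderate_variances(fit_group_contrast(ds)),
                     fc_threshold=fc_threshold, adjp_threshold=adjp_threshold)
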