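"""Condition-specific graphical-Gaussian dependency networks.

For each condition, gene-gene partial correlations are estimated from a
correlation matrix shrunk toward the identity with the analytic
Ledoit-Wolf/Schafer-Strimmer intensity, edges are assigned p-values under
the null density of partial correlations ``f0(r) ~ (1 - r^2)^((kappa-3)/2)``
with ``kappa`` fitted by maximum likelihood, and BH q-values gate the
final network at q <= 0.05.  Degree statistics per gene feed the
``Diff = deg_cancer - deg_control`` topology filter downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, special

from .datatypes import ExpressionDataset
from .errors import SampleSizeError, SignificanceError
from .diffexp import bh_adjust

Q_THRESHOLD = 0.05


@dataclass
class PartialCorrelationMatrix:
    genes: list[str]
    pcor: np.ndarray  # symmetric, unit diagonal
    lam: float  # shrinkage intensity in [0, 1]
    n_samples: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pcor, index=self.genes, columns=self.genes)


def shrinkage_partial_correlation(values: pd.DataFrame,
                                  lam: float | None = None) -> PartialCorrelationMatrix:
    """Shrunk partial correlations for one condition's genes x samples block.

    The sample correlation matrix ``R`` is shrunk toward the identity,
    ``R* = (1 - lambda) R + lambda I``, with the analytic intensity
    ``lambda = sum Var(r_ij) / sum r_ij^2`` over off-diagonal entries
    (clipped to [0, 1]).  Partial correlations come from the standardized
    inverse: ``pcor_ij = -Omega_ij / sqrt(Omega_ii Omega_jj)`` with
    ``Omega = inv(R*)``.  Genes with zero variance get zero partial
    correlation against everything.
    """
    X = values.to_numpy(dtype=float).T  # samples x genes
    n, p = X.shape
    if n < 3:
        raise SampleSizeError(f"partial-correlation estimation needs >= 3 samples, got {n}")

    sd = X.std(axis=0, ddof=1)
    ok = sd > 0
    Z = np.zeros_like(X)
    Z[:, ok] = (X[:, ok] - X[:, ok].mean(axis=0)) / sd[ok]

    R = (Z.T @ Z) / (n - 1)
    # unbiased variance of each correlation entry (Schafer-Strimmer)
    sum_w2 = (Z**2).T @ (Z**2)
    sum_w = Z.T @ Z
    var_r = n / (n - 1.0) ** 3 * (sum_w2 - sum_w**2 / n)

    if lam is None:
        off = ~np.eye(p, dtype=bool)
        denom = (R[off] ** 2).sum()
        lam = 1.0 if denom == 0 else float(np.clip(var_r[off].sum() / denom, 0.0, 1.0))
    elif not 0.0 <= lam <= 1.0:
        raise ValueError("shrinkage intensity must lie in [0, 1]")

    R_star = (1.0 - lam) * R
    np.fill_diagonal(R_star, 1.0)
    try:
        omega = np.linalg.inv(R_star)
    except np.linalg.LinAlgError:
        omega = np.linalg.pinv(R_star)
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    pcor = (pcor + pcor.T) / 2.0
    # constant genes carry no dependency information
    if (~ok).any():
        pcor[~ok, :] = 0.0
        pcor[:, ~ok] = 0.0
        np.fill_diagonal(pcor, 1.0)
    return PartialCorrelationMatrix(list(values.index), pcor, lam, n)


def _fit_kappa(r: np.ndarray) -> float:
    """ML fit of the null degrees of freedom ``kappa``.

    The null density of a partial correlation with ``kappa`` effective
    degrees of freedom is ``(1 - r^2)^((kappa-3)/2) / B(1/2, (kappa-1)/2)``.
    """
    r2 = np.clip(r**2, 0.0, 1.0 - 1e-12)
    log1m = np.log1p(-r2)
    m = r.size

    def neg_ll(log_km1: float) -> float:
        kappa = 1.0 + np.exp(log_km1)
        return -(((kappa - 3.0) / 2.0) * log1m.sum()
                 - m * special.betaln(0.5, (kappa - 1.0) / 2.0))

    res = optimize.minimize_scalar(neg_ll, bounds=(np.log(0.5), np.log(1e8)),
                                   method="bounded", options={"xatol": 1e-8})
    if not res.success or not np.isfinite(res.fun):
        raise SignificanceError(
            f"kappa fit failed: success={res.success}, fun={res.fun!r}, x={res.x!r}"
        )
    return float(1.0 + np.exp(res.x))


def null_pvalue(r, kappa: float):
    """Two-sided tail of |r| under the kappa null: ``1 - I_{r^2}(1/2, (k-1)/2)``."""
    r2 = np.clip(np.asarray(r, dtype=float) ** 2, 0.0, 1.0)
    return 1.0 - special.betainc(0.5, (kappa - 1.0) / 2.0, r2)


def edge_significance(pcm: PartialCorrelationMatrix) -> pd.DataFrame:
    """Per-pair p and BH q-values for all gene pairs.

    Returns a DataFrame (gene_a, gene_b, pcor, p, q) with the pair in
    canonical lexicographic order; ``kappa`` is stored in ``.attrs``.
    """
    p = len(pcm.genes)
    iu = np.triu_indices(p, k=1)
    r = pcm.pcor[iu]
    kappa = _fit_kappa(r)
    pvals = np.clip(null_pvalue(r, kappa), np.finfo(float).tiny, 1.0)
    q = bh_adjust(pvals)

    a = np.asarray(pcm.genes)[iu[0]]
    b = np.asarray(pcm.genes)[iu[1]]
    swap = a > b
    a2 = np.where(swap, b, a)
    b2 = np.where(swap, a, b)
    edges = pd.DataFrame({"gene_a": a2, "gene_b": b2, "pcor": r, "p": pvals, "q": q})
    edges = edges.sort_values(["gene_a", "gene_b"], kind="mergesort").reset_index(drop=True)
    edges.attrs["kappa"] = kappa
    edges.attrs["n_samples"] = pcm.n_samples
    return edges


def build_network(edges: pd.DataFrame, q_threshold: float = Q_THRESHOLD) -> nx.Graph:
    """Undirected network of edges with ``q <= q_threshold`` (inclusive)."""
    g = nx.Graph()
    kept = edges[edges["q"] <= q_threshold]
    for row in kept.itertuples():
        g.add_edge(row.gene_a, row.gene_b, pcor=row.pcor, q=row.q)
    return g


def degree_diff(net_cancer: nx.Graph, net_control: nx.Graph,
                gene_universe) -> pd.DataFrame:
    """Per-gene degrees in both condition networks and their difference."""
    rows = []
    for g in gene_universe:
        dc = net_cancer.degree(g) if g in net_cancer else 0
        dk = net_control.degree(g) if g in net_control else 0
        rows.append((g, dc, dk, dc - dk))
    return pd.DataFrame(rows, columns=["gene", "deg_cancer", "deg_control", "diff"]
                        ).set_index("gene")


def percent_possible(n_genes: int, n_edges: int) -> float:
    """Edges as a percentage of all C(n_genes, 2) possible pairs."""
    total = n_genes * (n_genes - 1) / 2
    return 100.0 * n_edges / total


def condition_networks(ds: ExpressionDataset, genes=None,
                       q_threshold: float = Q_THRESHOLD):
    """Dependency networks for cancer and control over the given genes.

    Returns ``(networks, edges, degrees)`` where ``networks`` and
    ``edges`` are dicts keyed by condition and ``degrees`` is the combined
    degree table over the gene list.
    """
    genes = list(genes) if genes is not None else ds.genes
    nets, edge_tables = {}, {}
    for condition in ("cancer", "control"):
        sub = ds.subset_condition(condition)
        pcm = shrinkage_partial_correlation(sub.values.loc[genes])
        edges = edge_significance(pcm)
        edge_tables[condition] = edges
        nets[condition] = build_network(edges, q_threshold)
    degrees = degree_diff(nets["cancer"], nets["control"], genes)
    return nets, edge_tables, degrees
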