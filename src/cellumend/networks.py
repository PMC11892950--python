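"""Co-occurrence molecular ecological networks.

A network is built from a samples × taxa table by (i) keeping taxa
detected in at least ``min_prevalence`` samples, (ii) computing
Spearman correlations of log-transformed relative abundances (with a
pseudocount of half the smallest nonzero relative abundance), and
(iii) keeping |r| ≥ threshold as undirected edges.  The threshold can
be a fixed value or chosen by the random-matrix-theory criterion: the
smallest cutoff at which the nearest-neighbour spacing distribution of
the thresholded correlation matrix's eigenvalues is consistent with the
Poisson law (uncorrelated eigenvalues), tested by χ² goodness of fit
after empirical-CDF unfolding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import CommunityTable

__all__ = [
    "NetworkProps",
    "build_network",
    "rmt_threshold",
    "nnsd_poisson_pvalue",
    "sample_subnetwork",
    "topology_properties",
]


@dataclass(frozen=True)
class NetworkProps:
    n_nodes: int
    n_edges: int
    avgK: float
    avgCC: float
    GD: float
    n_modules: int
    modularity: float
    density: float


def _rel_abundance(table) -> pd.DataFrame:
    if isinstance(table, CommunityTable):
        df = table.counts
    else:
        df = pd.DataFrame(table)
    tot = df.sum(axis=1)
    if (tot == 0).any():
        raise ValueError("all-zero sample")
    return df.div(tot, axis=0)


def build_network(table, min_prevalence: int = 6, threshold=0.8,
                  rmt_scan=(0.3, 0.96, 0.02)) -> nx.Graph:
    """Spearman co-occurrence network over prevalence-filtered taxa.

    ``threshold`` is either a value in (0,1) or ``"rmt"``.  Edges carry
    ``weight`` = |r| and ``sign`` = sign of r.
    """
    rel = _rel_abundance(table)
    n_samples = rel.shape[0]
    if n_samples < 4:
        raise ValueError("need >= 4 samples")
    if min_prevalence > n_samples:
        raise ValueError("min_prevalence exceeds the number of samples")
    prev = (rel > 0).sum(axis=0)
    keep = prev[prev >= min_prevalence].index
    if len(keep) < 2:
        raise ValueError("fewer than 2 taxa survive the prevalence filter")
    sub = rel[keep]
    nz = sub.values[sub.values > 0]
    pseudo = nz.min() / 2.0
    logged = np.log(sub.to_numpy() + pseudo)
    rho = stats.spearmanr(logged).statistic
    rho = np.atleast_2d(rho)
    if rho.shape == (1, 1):  # two taxa: spearmanr returns a scalar
        r2 = stats.spearmanr(logged[:, 0], logged[:, 1]).statistic
        rho = np.array([[1.0, r2], [r2, 1.0]])
    np.fill_diagonal(rho, 1.0)
    sim = np.abs(rho)
    if threshold == "rmt":
        thr = rmt_threshold(sim, *rmt_scan)
    else:
        thr = float(threshold)
    g = nx.Graph(threshold=thr, min_prevalence=min_prevalence,
                 pseudocount=pseudo, transform="ln(rel_abundance + pseudo)")
    g.add_nodes_from(keep)
    taxa = list(keep)
    iu = np.triu_indices(len(taxa), k=1)
    for i, j in zip(*iu):
        if sim[i, j] >= thr:
            g.add_edge(taxa[i], taxa[j], weight=float(sim[i, j]),
                       sign=int(np.sign(rho[i, j])))
    return g


def _unfold(eigs: np.ndarray, degeneracy_tol: float = 1e-8) -> np.ndarray:
    """Nearest-neighbour spacings after empirical-CDF unfolding.

    Degenerate eigenvalues (within tolerance) are merged first; a
    cubic-spline fit to the cumulative distribution maps the spectrum
    to unit mean density.
    """
    e = np.sort(eigs)
    uniq = [e[0]]
    for v in e[1:]:
        if v - uniq[-1] > degeneracy_tol:
            uniq.append(v)
    e = np.asarray(uniq)
    n = len(e)
    if n < 3:
        return np.array([])
    cdf = np.arange(1, n + 1, dtype=float)
    # smooth unfolding: low-order polynomial fit of the cumulative count
    deg = min(5, n - 1)
    coef = np.polyfit(e, cdf, deg)
    unfolded = np.polyval(coef, e)
    s = np.diff(unfolded)
    s = s[s > 0]
    if len(s) == 0:
        return np.array([])
    return s / s.mean()


def nnsd_poisson_pvalue(sim: np.ndarray, threshold: float,
                        n_bins: int = 10, s_max: float = 3.0) -> float:
    """χ² goodness-of-fit p-value of the thresholded matrix's NNSD
    against the Poisson law P(s) = e^{−s}.

    Returns 1.0 when too few distinct eigenvalues remain to test
    (fully fragmented spectra are trivially Poisson-consistent).
    """
    a = np.where(sim >= threshold, sim, 0.0)
    np.fill_diagonal(a, 1.0)
    eigs = np.linalg.eigvalsh((a + a.T) / 2)
    s = _unfold(eigs)
    if len(s) < 20:
        return 1.0
    edges = np.linspace(0.0, s_max, n_bins + 1)
    obs, _ = np.histogram(np.clip(s, 0, None), bins=edges)
    tail = (s >= s_max).sum()
    probs = np.exp(-edges[:-1]) - np.exp(-edges[1:])
    counts = np.append(obs, tail).astype(float)
    probs = np.append(probs, np.exp(-s_max))
    expected = probs * len(s)
    # merge sparse bins so the χ² approximation holds
    merged_o, merged_e = [], []
    co = ce = 0.0
    for o, ex in zip(counts, expected):
        co += o
        ce += ex
        if ce >= 5:
            merged_o.append(co)
            merged_e.append(ce)
            co = ce = 0.0
    if ce > 0 and merged_e:
        merged_o[-1] += co
        merged_e[-1] += ce
    if len(merged_e) < 2:
        return 1.0
    merged_o = np.asarray(merged_o)
    merged_e = np.asarray(merged_e) * merged_o.sum() / np.sum(merged_e)
    chi2 = ((merged_o - merged_e) ** 2 / merged_e).sum()
    return float(stats.chi2.sf(chi2, df=len(merged_e) - 1))


def rmt_threshold(sim: np.ndarray, start: float = 0.3, stop: float = 0.96,
                  step: float = 0.02, alpha: float = 0.05) -> float:
    """Smallest scanned threshold whose NNSD is Poisson-consistent
    (χ² p > alpha)."""
    sim = np.asarray(sim, dtype=float)
    if not (0 < start < stop <= 1):
        raise ValueError("scan must lie within (0,1]")
    for thr in np.arange(start, stop + 1e-12, step):
        if nnsd_poisson_pvalue(sim, thr) > alpha:
            return float(round(thr, 10))
    raise ValueError("no scanned threshold passes the Poisson test; "
                     "use a fixed threshold")


def sample_subnetwork(net: nx.Graph, sample_abundances) -> nx.Graph:
    """Induced subgraph on the taxa present (abundance > 0) in a sample."""
    ab = pd.Series(sample_abundances)
    # taxa dropped by the prevalence filter are absent from the global
    # network and are simply ignored here
    present = [t for t in ab.index[ab > 0] if t in net.nodes]
    sub = net.subgraph(present).copy()
    sub.graph.update(net.graph)
    return sub


def topology_properties(net: nx.Graph) -> NetworkProps:
    """Topological summary: average degree 2E/N, density, mean local
    clustering, mean geodesic distance over the largest component, and
    greedy-modularity module count / modularity."""
    n = net.number_of_nodes()
    if n < 1:
        raise ValueError("network needs >= 1 node")
    e = net.number_of_edges()
    avgk = 2.0 * e / n
    density = nx.density(net) if n > 1 else 0.0
    avgcc = nx.average_clustering(net) if n > 0 else 0.0
    comps = list(nx.connected_components(net))
    largest = max(comps, key=len)
    if len(largest) > 1:
        gd = nx.average_shortest_path_length(net.subgraph(largest))
    else:
        gd = 0.0
    if e > 0:
        communities = nx.community.greedy_modularity_communities(net)
        mod = nx.community.modularity(net, communities)
        n_modules = len(communities)
    else:
        n_modules = n
        mod = 0.0
    return NetworkProps(n_nodes=n, n_edges=e, avgK=avgk, avgCC=avgcc,
                        GD=float(gd), n_modules=n_modules,
                        modularity=float(mod), density=float(density))
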