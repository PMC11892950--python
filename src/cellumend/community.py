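"""Community comparison and assembly statistics.

Implements the dissimilarity / ordination / dispersion toolchain used
to compare litterbag and soil communities, a taxonomic normalized
stochasticity ratio (tNST) defined as the proportion of (sample pair,
null replicate) comparisons in which the observed Bray–Curtis
dissimilarity exceeds that of richness-preserving randomized
communities, and matrix-correlation tests (Mantel, partial Mantel,
multiple regression on matrices) with add-one permutation p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .synthetic import CommunityTable

__all__ = [
    "DistanceMatrix",
    "NSTResult",
    "bray_curtis",
    "sorensen",
    "pcoa",
    "group_dispersion",
    "tnst",
    "mantel",
    "mrm",
    "variance_partition",
]


@dataclass
class DistanceMatrix:
    ids: list
    data: np.ndarray
    metric: str = "custom"

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if d.shape[0] != len(self.ids):
            raise ValueError("ids length must match matrix size")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if (np.diag(d) != 0).any():
            raise ValueError("diagonal must be zero")
        if (d < 0).any():
            raise ValueError("distances must be >= 0")
        self.data = d

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.data, checks=False)

    def subset(self, ids) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(ids=list(ids),
                              data=self.data[np.ix_(idx, idx)],
                              metric=self.metric)


def _abund_matrix(table) -> tuple[np.ndarray, list]:
    if isinstance(table, CommunityTable):
        x = table.counts.to_numpy(dtype=float)
        ids = table.samples
    elif isinstance(table, pd.DataFrame):
        x = table.to_numpy(dtype=float)
        ids = list(table.index)
    else:
        x = np.asarray(table, dtype=float)
        ids = list(range(x.shape[0]))
    if (x < 0).any():
        raise ValueError("abundances must be >= 0")
    if (x.sum(axis=1) == 0).any():
        raise ValueError("all-zero sample")
    return x, ids


def bray_curtis(table) -> DistanceMatrix:
    """d(x,y) = 1 − 2·Σmin(xᵢ,yᵢ) / (Σxᵢ + Σyᵢ)."""
    x, ids = _abund_matrix(table)
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(ids=ids, data=d, metric="bray_curtis")


def sorensen(table) -> DistanceMatrix:
    """Presence/absence Sørensen: d = 1 − 2a/(2a + b + c)."""
    x, ids = _abund_matrix(table)
    pa = (x > 0)
    d = squareform(pdist(pa, metric="dice"))
    return DistanceMatrix(ids=ids, data=d, metric="sorensen")


def pcoa(d: DistanceMatrix, k: int | None = None):
    """Classical scaling (principal coordinates) of a distance matrix.

    Returns (coordinates, eigenvalues): eigenvalues in decreasing order
    including negative ones; coordinates span the axes with positive
    eigenvalues (at most k).
    """
    n = d.n
    d2 = d.data ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    pos = vals > max(vals.max(), 0) * 1e-12
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    if k is not None:
        coords = coords[:, :k]
    return coords, vals


@dataclass
class DispersionResult:
    group_means: dict
    distances: pd.Series
    f_stat: float
    p_value: float
    n_permutations: int


def _dist_to_centroids(d: DistanceMatrix, labels: np.ndarray) -> np.ndarray:
    """Per-sample distance to its group centroid in the PCoA embedding,
    with the squared-distance correction real² − imag² for axes with
    negative eigenvalues (betadisper convention)."""
    n = d.n
    d2 = d.data ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh((b + b.T) / 2)
    pos = vals > 1e-10
    neg = vals < -1e-10
    xr = vecs[:, pos] * np.sqrt(vals[pos])
    xi = vecs[:, neg] * np.sqrt(-vals[neg])
    out = np.empty(n)
    for g in np.unique(labels):
        m = labels == g
        cr = xr[m].mean(axis=0)
        ci = xi[m].mean(axis=0) if xi.size else np.zeros(0)
        dr2 = ((xr[m] - cr) ** 2).sum(axis=1)
        di2 = ((xi[m] - ci) ** 2).sum(axis=1) if xi.size else 0.0
        out[m] = np.sqrt(np.maximum(dr2 - di2, 0.0))
    return out


def group_dispersion(d: DistanceMatrix, groups: dict, permutations: int = 999,
                     seed: int = 0) -> DispersionResult:
    """Multivariate homogeneity of group dispersions.

    ``groups`` maps group name -> sample ids.  Distances to group
    centroids are computed in PCoA space; groups are compared with a
    one-way F statistic whose p-value comes from permuting the
    distances among groups.
    """
    labels = np.empty(d.n, dtype=object)
    for g, samples in groups.items():
        if len(samples) < 2:
            raise ValueError(f"group {g!r} needs >= 2 samples")
        for s in samples:
            labels[d.ids.index(s)] = g
    if (labels == None).any():  # noqa: E711 - object array membership
        raise ValueError("groups must cover all samples in the matrix")
    z = _dist_to_centroids(d, labels)

    def fstat(zv):
        grand = zv.mean()
        ssb = ssw = 0.0
        k = 0
        for g in groups:
            m = labels == g
            k += 1
            ssb += m.sum() * (zv[m].mean() - grand) ** 2
            ssw += ((zv[m] - zv[m].mean()) ** 2).sum()
        df1, df2 = k - 1, len(zv) - k
        return (ssb / df1) / (ssw / df2) if ssw > 0 else np.inf

    f_obs = fstat(z)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(permutations):
        if fstat(rng.permutation(z)) >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + permutations)
    means = {g: float(z[labels == g].mean()) for g in groups}
    return DispersionResult(group_means=means,
                            distances=pd.Series(z, index=d.ids),
                            f_stat=float(f_obs), p_value=float(p),
                            n_permutations=permutations)


@dataclass
class NSTResult:
    group: str
    tnst: float
    n_pairs: int
    n_null: int
    method: str = "exceedance-proportion tNST"


def _randomize_sample(abund: np.ndarray, pool_prob: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Null community: keep the sample's richness and rank-abundance
    values, reassign them to taxa drawn from the group pool with
    probability proportional to occurrence frequency."""
    nz = np.flatnonzero(abund)
    richness = len(nz)
    pool = np.flatnonzero(pool_prob)
    k = min(richness, len(pool))
    chosen = rng.choice(pool, size=k, replace=False,
                        p=pool_prob[pool] / pool_prob[pool].sum())
    out = np.zeros_like(abund, dtype=float)
    vals = rng.permutation(abund[nz])[:k]
    out[chosen] = vals
    return out


def _bc_pair(x: np.ndarray, y: np.ndarray) -> float:
    s = x.sum() + y.sum()
    return 1.0 - 2.0 * np.minimum(x, y).sum() / s if s > 0 else 0.0


def tnst(table, group_samples=None, null_reps: int = 1000, seed: int = 0,
         group: str = "all") -> NSTResult:
    """Taxonomic normalized stochasticity ratio of one sample group.

    For every within-group sample pair and null replicate, both samples
    are replaced by randomized communities (richness preserved, taxa
    drawn with occurrence-frequency-proportional probability,
    abundances reassigned from each sample's rank-abundance profile);
    tNST is the proportion of comparisons where the observed
    Bray–Curtis dissimilarity exceeds the null one.
    """
    if null_reps < 1:
        raise ValueError("null_reps must be >= 1")
    if isinstance(table, CommunityTable):
        samples = group_samples if group_samples is not None else table.samples
        x = table.counts.loc[list(samples)].to_numpy(dtype=float)
    elif isinstance(table, pd.DataFrame):
        samples = group_samples if group_samples is not None else list(table.index)
        x = table.loc[list(samples)].to_numpy(dtype=float)
    else:
        x = np.asarray(table, dtype=float)
        samples = list(range(x.shape[0]))
    n = x.shape[0]
    if n < 2:
        raise ValueError("group needs >= 2 samples")
    occ = (x > 0).sum(axis=0).astype(float)
    pool_prob = occ / occ.sum()
    obs = squareform(pdist(x, metric="braycurtis"))
    rng = np.random.default_rng(seed)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    exceed = 0
    total = 0
    for _ in range(null_reps):
        nulls = [_randomize_sample(x[i], pool_prob, rng) for i in range(n)]
        for i, j in pairs:
            dn = _bc_pair(nulls[i], nulls[j])
            if obs[i, j] > dn:
                exceed += 1
            total += 1
    return NSTResult(group=group, tnst=exceed / total, n_pairs=len(pairs),
                     n_null=null_reps)


def _offdiag(d: np.ndarray) -> np.ndarray:
    return squareform(d, checks=False)


def _residualize(v: np.ndarray, on: np.ndarray) -> np.ndarray:
    x = np.column_stack([np.ones_like(on), on])
    beta, *_ = np.linalg.lstsq(x, v, rcond=None)
    return v - x @ beta


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    partial: bool = False


def mantel(d1: DistanceMatrix, d2: DistanceMatrix, permutations: int = 999,
           seed: int = 0, partial_on: DistanceMatrix | None = None) -> MantelResult:
    """(Partial) Mantel test.

    r is the Pearson correlation of the off-diagonal vectors (for the
    partial test, of both vectors' residuals after regressing on the
    third matrix).  p is one-sided (greater) with the add-one
    estimator; rows/columns of d1 are permuted jointly.
    """
    if d1.ids != d2.ids:
        raise ValueError("matrices must share sample ids (and order)")
    if permutations < 99:
        raise ValueError("use at least 99 permutations")
    n = d1.n
    v2 = _offdiag(d2.data)
    v3 = _offdiag(partial_on.data) if partial_on is not None else None

    def corr(m1: np.ndarray) -> float:
        v1 = _offdiag(m1)
        if v3 is not None:
            a = _residualize(v1, v3)
            b = _residualize(v2, v3)
        else:
            a, b = v1, v2
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])

    r_obs = corr(d1.data)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        if corr(d1.data[np.ix_(perm, perm)]) >= r_obs:
            exceed += 1
    p = (1 + exceed) / (1 + permutations)
    return MantelResult(r=r_obs, p_value=p, n_permutations=permutations,
                        partial=partial_on is not None)


@dataclass
class MrmResult:
    coefficients: np.ndarray     # intercept first
    p_values: np.ndarray         # permutation p per coefficient (no intercept p)
    r_squared: float
    p_model: float
    n_permutations: int
    predictor_names: list = field(default_factory=list)


def mrm(response: DistanceMatrix, predictors: list, permutations: int = 999,
        seed: int = 0, names=None) -> MrmResult:
    """Multiple regression on distance matrices.

    OLS of the response's off-diagonal vector on the predictors'; the
    significance of each coefficient (and of R²) comes from jointly
    permuting the response matrix's rows and columns.
    """
    if not predictors:
        raise ValueError("need at least one predictor matrix")
    for p_ in predictors:
        if p_.ids != response.ids:
            raise ValueError("all matrices must share sample ids")
    n = response.n
    xcols = [_offdiag(p_.data) for p_ in predictors]
    x = np.column_stack([np.ones(len(xcols[0]))] + xcols)

    def fit(m: np.ndarray):
        y = _offdiag(m)
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        sst = ((y - y.mean()) ** 2).sum()
        r2 = 1.0 - resid @ resid / sst if sst > 0 else 1.0
        return beta, r2

    beta_obs, r2_obs = fit(response.data)
    rng = np.random.default_rng(seed)
    exceed_b = np.zeros(len(predictors))
    exceed_r2 = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        beta_p, r2_p = fit(response.data[np.ix_(perm, perm)])
        exceed_b += np.abs(beta_p[1:]) >= np.abs(beta_obs[1:])
        if r2_p >= r2_obs:
            exceed_r2 += 1
    p_b = (1 + exceed_b) / (1 + permutations)
    p_model = (1 + exceed_r2) / (1 + permutations)
    return MrmResult(coefficients=beta_obs, p_values=p_b, r_squared=float(r2_obs),
                     p_model=float(p_model), n_permutations=permutations,
                     predictor_names=list(names or
                                          [f"x{i + 1}" for i in range(len(predictors))]))


def variance_partition(response: DistanceMatrix, abiotic: list,
                       biotic: list) -> dict:
    """Hierarchical partition of distance-matrix variance into abiotic,
    biotic and unexplained components (summing to 1): the abiotic share
    is the R² of the abiotic-only model, the biotic share is the R²
    increment from adding the biotic matrices."""
    y = _offdiag(response.data)

    def r2_of(cols):
        x = np.column_stack([np.ones(len(y))] + cols)
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        sst = ((y - y.mean()) ** 2).sum()
        return 1.0 - resid @ resid / sst if sst > 0 else 1.0

    cols_a = [_offdiag(m.data) for m in abiotic]
    cols_b = [_offdiag(m.data) for m in biotic]
    r2_a = r2_of(cols_a) if cols_a else 0.0
    r2_full = r2_of(cols_a + cols_b)
    return {"abiotic": float(r2_a), "biotic": float(r2_full - r2_a),
            "unexplained": float(1.0 - r2_full)}
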