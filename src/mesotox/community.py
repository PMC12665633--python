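"""Phytoplankton community analytics.

Shannon diversity with treatment-by-day linear-model contrasts, Bray-Curtis
dissimilarity, non-metric multidimensional scaling (NMDS, Kruskal stress-1),
one-way PERMANOVA with free permutation of labels, and a homogeneity-of-
dispersions test (distances to group centroids in principal-coordinates
space), used as a validity check so that a significant PERMANOVA can be read
as a location effect rather than a spread effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .mixedmodels import holm_bonferroni

__all__ = [
    "CommunityMatrix",
    "OrdinationResult",
    "PermanovaResult",
    "shannon_index",
    "diversity_lm_contrasts",
    "bray_curtis",
    "nmds",
    "permanova",
    "dispersion_homogeneity",
    "dominance_share",
    "chlorophyll_biomass_r2",
    "community_matrix_from_table",
]


@dataclass
class CommunityMatrix:
    """Tank x taxon count (or biomass) matrix for one sampling day."""
    counts: pd.DataFrame            # index tank_id, columns taxa
    day: int
    treatment: pd.Series            # per-tank treatment label

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative community matrix entries")
        self.treatment = self.treatment.loc[self.counts.index]


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame
    stress: float
    n_starts: int
    converged: bool
    seed: int


@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p: float
    n_permutations: int
    dispersion_p: float | None = None


def community_matrix_from_table(algae: pd.DataFrame, day: int,
                                treatment: pd.Series,
                                value: str = "count") -> CommunityMatrix:
    """Pivot the tidy algae table for one day into a tank x taxon matrix."""
    sub = algae[algae["day"] == day]
    mat = sub.pivot_table(index="tank_id", columns="taxon", values=value,
                          aggfunc="sum", fill_value=0.0)
    return CommunityMatrix(counts=mat, day=day, treatment=treatment.loc[mat.index])


def shannon_index(counts: np.ndarray, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i over taxa with p_i > 0.

    Natural log by default; pass ``base`` for other conventions.
    """
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("negative counts")
    total = c.sum()
    if total <= 0:
        raise ValueError("all-zero count vector")
    p = c[c > 0] / total
    H = float(-(p * np.log(p)).sum())
    return H / np.log(base) if base else H


def diversity_lm_contrasts(H: pd.Series, treatment: pd.Series, day: pd.Series,
                           control_label=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Least-squares fit of H ~ treatment x day, with treatment-vs-control
    contrasts within each day and Holm-adjusted p-values.

    Fits the saturated cell-means parameterization (equivalent to the full
    interaction model); contrasts are estimated cell-mean differences with
    pooled-residual standard errors.  Returns (cell-means table, contrasts).
    """
    df = pd.DataFrame({"H": H, "treatment": treatment, "day": day}).dropna()
    if control_label is None:
        control_label = sorted(df["treatment"].unique())[0]
    cells = df.groupby(["day", "treatment"])["H"].agg(["mean", "count"]).reset_index()
    fitted = df.merge(cells, on=["day", "treatment"])["mean"]
    resid = df["H"].to_numpy() - fitted.to_numpy()
    dfe = len(df) - len(cells)
    if dfe <= 0:
        raise ValueError("no residual degrees of freedom for contrasts")
    s2 = float((resid ** 2).sum() / dfe)

    rows = []
    for d in sorted(df["day"].unique()):
        sub = cells[cells["day"] == d].set_index("treatment")
        if control_label not in sub.index:
            continue
        m0, n0 = sub.loc[control_label, "mean"], sub.loc[control_label, "count"]
        for t in sub.index:
            if t == control_label:
                continue
            m1, n1 = sub.loc[t, "mean"], sub.loc[t, "count"]
            if n1 < 1 or n0 < 1:
                rows.append({"day": d, "treatment": t, "estimate": np.nan,
                             "se": np.nan, "t": np.nan, "p": np.nan,
                             "inestimable": True})
                continue
            est = m1 - m0
            se = np.sqrt(s2 * (1.0 / n1 + 1.0 / n0))
            tval = est / se
            p = 2 * stats.t.sf(abs(tval), dfe)
            rows.append({"day": d, "treatment": t, "estimate": est, "se": se,
                         "t": tval, "p": p, "inestimable": False})
    contrasts = pd.DataFrame(rows)
    ok = ~contrasts["inestimable"]
    adj = np.full(len(contrasts), np.nan)
    adj[ok.to_numpy()] = holm_bonferroni(contrasts.loc[ok, "p"].to_numpy())
    contrasts["p_holm"] = adj
    return cells, contrasts


def bray_curtis(counts: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Bray-Curtis dissimilarity d(a,b) = sum|a_i - b_i| / sum(a_i + b_i)."""
    if isinstance(counts, CommunityMatrix):
        counts = counts.counts
    mat = counts.to_numpy(float) if isinstance(counts, pd.DataFrame) else np.asarray(counts, float)
    if np.any(mat.sum(axis=1) <= 0):
        raise ValueError("Bray-Curtis undefined for zero-sum rows")
    D = squareform(pdist(mat, metric="braycurtis"))
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(D, index=counts.index, columns=counts.index)
    return pd.DataFrame(D)


def _pcoa(D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinates embedding: eigendecomposition of the Gower matrix.

    Returns (coordinates incl. axes for negative eigenvalues, eigenvalues).
    """
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    coords = vecs * np.sqrt(np.abs(vals))
    return coords, vals


def _stress1(D: np.ndarray, X: np.ndarray) -> float:
    """Kruskal stress-1 of configuration X against dissimilarities D, using
    isotonic (monotone) regression of configuration distances on ranks."""
    from sklearn.isotonic import IsotonicRegression
    iu = np.triu_indices(D.shape[0], 1)
    d = D[iu]
    dist = squareform(pdist(X))[iu]
    disp = IsotonicRegression().fit_transform(d, dist)
    denom = float((dist ** 2).sum())
    if denom == 0:
        return np.inf
    return float(np.sqrt(((dist - disp) ** 2).sum() / denom))


def nmds(dist: pd.DataFrame | np.ndarray, k: int = 2, n_starts: int = 50,
         seed: int = 0, max_iter: int = 500, eps: float = 1e-6) -> OrdinationResult:
    """Non-metric MDS minimizing Kruskal stress-1.

    Runs ``n_starts`` random initializations plus one metric-scaling (PCoA)
    initialization and keeps the lowest-stress configuration.  Deterministic
    under fixed seed.
    """
    index = dist.index if isinstance(dist, pd.DataFrame) else None
    D = np.asarray(dist, dtype=float)
    n = D.shape[0]
    if n < k + 2:
        raise ValueError("need at least k + 2 points")
    from sklearn.manifold import smacof

    best_X, best_stress = None, np.inf
    if n_starts > 0:
        X, _ = smacof(D, metric=False, n_components=k, n_init=n_starts,
                      max_iter=max_iter, eps=eps, random_state=seed,
                      normalized_stress=True)
        best_X, best_stress = X, _stress1(D, X)
    pco, _ = _pcoa(D)
    X, _ = smacof(D, metric=False, n_components=k, init=pco[:, :k], n_init=1,
                  max_iter=max_iter, eps=eps, random_state=seed,
                  normalized_stress=True)
    s = _stress1(D, X)
    if s < best_stress:
        best_X, best_stress = X, s
    coords = pd.DataFrame(best_X, index=index,
                          columns=[f"NMDS{i + 1}" for i in range(k)])
    return OrdinationResult(coordinates=coords, stress=best_stress,
                            n_starts=n_starts + 1,
                            converged=np.isfinite(best_stress), seed=seed)


def permanova(dist: pd.DataFrame | np.ndarray, groups, n_perm: int = 999,
              seed: int = 0, with_dispersion_test: bool = False) -> PermanovaResult:
    """One-way PERMANOVA on a dissimilarity matrix.

    Pseudo-F is computed from partitioned sums of squared dissimilarities
    (total SS = sum over pairs d^2 / n; within-group SS analogously per
    group); the p-value counts free random relabelings whose F meets or
    exceeds the observed one, with the observed statistic included in the
    reference set: p = (1 + #{F_perm >= F_obs}) / (n_perm + 1).
    """
    D2 = np.asarray(dist, dtype=float) ** 2
    labels = np.asarray(pd.Series(list(groups)).to_numpy())
    n = D2.shape[0]
    if len(labels) != n:
        raise ValueError("groups length must match the distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    if counts.min() < 2:
        raise ValueError("singleton group: PERMANOVA refused")
    a, N = len(uniq), n
    ss_total = D2[np.triu_indices(n, 1)].sum() / N

    def ss_within(lab: np.ndarray) -> float:
        out = 0.0
        for g in uniq:
            idx = np.flatnonzero(lab == g)
            sub = D2[np.ix_(idx, idx)]
            out += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
        return out

    def pseudo_f(lab: np.ndarray) -> float:
        ssw = ss_within(lab)
        return ((ss_total - ssw) / (a - 1)) / (ssw / (N - a))

    ssw_obs = ss_within(labels)
    f_obs = ((ss_total - ssw_obs) / (a - 1)) / (ssw_obs / (N - a))
    r2 = 1.0 - ssw_obs / ss_total

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if pseudo_f(rng.permutation(labels)) >= f_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    disp_p = None
    if with_dispersion_test:
        disp_p, _ = dispersion_homogeneity(np.sqrt(D2), labels, n_perm=n_perm,
                                           seed=seed + 1)
    return PermanovaResult(pseudo_f=float(f_obs), r2=float(r2), p=float(p),
                           n_permutations=n_perm, dispersion_p=disp_p)


def dispersion_homogeneity(dist: pd.DataFrame | np.ndarray, groups,
                           n_perm: int = 999, seed: int = 0
                           ) -> tuple[float, pd.Series]:
    """Homogeneity of multivariate group dispersions.

    Embeds the dissimilarities by principal coordinates, computes each point's
    distance to its group centroid with the imaginary-part correction for
    negative eigenvalues, and compares the one-way F statistic on those
    distances against group-label permutations.

    Returns (permutation p-value, per-group mean dispersion).
    """
    D = np.asarray(dist, dtype=float)
    labels = np.asarray(pd.Series(list(groups)).to_numpy())
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 groups with >= 2 members each")
    coords, vals = _pcoa(D)
    pos, neg = vals > 1e-10, vals < -1e-10
    z = np.empty(len(labels))
    for g in uniq:
        idx = labels == g
        c_pos = coords[idx][:, pos].mean(axis=0)
        c_neg = coords[idx][:, neg].mean(axis=0)
        d2 = (((coords[idx][:, pos] - c_pos) ** 2).sum(axis=1)
              - ((coords[idx][:, neg] - c_neg) ** 2).sum(axis=1))
        z[idx] = np.sqrt(np.clip(d2, 0.0, None))

    def f_stat(lab: np.ndarray) -> float:
        grand = z.mean()
        ss_b = sum((z[lab == g].mean() - grand) ** 2 * (lab == g).sum() for g in uniq)
        ss_w = sum(((z[lab == g] - z[lab == g].mean()) ** 2).sum() for g in uniq)
        a, N = len(uniq), len(z)
        if ss_w == 0:
            return np.inf if ss_b > 0 else 0.0
        return (ss_b / (a - 1)) / (ss_w / (N - a))

    f_obs = f_stat(labels)
    rng = np.random.default_rng(seed)
    count = sum(f_stat(rng.permutation(labels)) >= f_obs for _ in range(n_perm))
    p = (count + 1) / (n_perm + 1)
    disp = pd.Series({g: float(z[labels == g].mean()) for g in uniq},
                     name="mean_dispersion")
    return float(p), disp


def dominance_share(cm: CommunityMatrix, taxa: list[str],
                    value: str = "counts") -> pd.Series:
    """Fraction of the community contributed by ``taxa``, per treatment group."""
    mat = cm.counts
    unknown = [t for t in taxa if t not in mat.columns]
    if unknown:
        raise KeyError(f"unknown taxa: {unknown}")
    share_num = mat[taxa].sum(axis=1) if taxa else pd.Series(0.0, index=mat.index)
    tot = mat.sum(axis=1)
    per_treat = pd.DataFrame({"num": share_num, "tot": tot,
                              "treatment": cm.treatment}).groupby("treatment").sum()
    return per_treat["num"] / per_treat["tot"]


def chlorophyll_biomass_r2(chl: np.ndarray, biomass: np.ndarray) -> tuple[float, float]:
    """Least-squares correspondence of microscopy biomass on chlorophyll-a.

    Returns (R^2, p-value of the slope)."""
    res = stats.linregress(np.asarray(chl, float), np.asarray(biomass, float))
    return float(res.rvalue ** 2), float(res.pvalue)
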