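"""Compositional and inferential statistics.

Read counts are compositional: only relative abundances are informative, so
comparisons are made in centred log-ratio (CLR) space, where Euclidean
distance between samples equals the Aitchison distance between their
compositions.  This module provides

* the CLR transform (with a configurable pseudocount for zeros),
* SVD-based compositional PCA,
* Aitchison distances,
* a permutation PERMANOVA (Anderson's distance-based pseudo-F from the
  Gower-centred squared-distance matrix; see :func:`permanova` for the
  explicit formula) with Bonferroni adjustment for pairwise tests,
* PCA of standardised variables for group/flux covariability, and
* one-way ANOVA with Tukey-Kramer post hoc for richness comparisons.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform


# ---------------------------------------------------------------------------
# CLR and Aitchison distance

def clr_transform(table: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Centred log-ratio transform, row-wise.

    For row i and feature j: ``log((x_ij + d) / g_i)`` with ``g_i`` the
    geometric mean of ``x_i + d``.  Rows of the result sum to zero.  With
    zeros present the pseudocount must be positive; the same pseudocount
    must be shared by tables that are to be compared.
    """
    x = table.to_numpy(dtype=float) + float(pseudocount)
    if (x <= 0).any():
        raise ValueError("zero or negative entries with pseudocount "
                         f"{pseudocount}; CLR requires strictly positive values")
    logx = np.log(x)
    clr = logx - logx.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=table.index, columns=table.columns)


def aitchison_distance(clr: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distance between CLR rows (symmetric, zero diagonal)."""
    d = squareform(pdist(clr.to_numpy(dtype=float), metric="euclidean"))
    return pd.DataFrame(d, index=clr.index, columns=clr.index)


# ---------------------------------------------------------------------------
# PCA

@dataclasses.dataclass(frozen=True)
class PcaResult:
    """Scores (samples x components), loadings (features x components) and
    the fraction of variance carried by each component."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_explained: np.ndarray
    singular_values: np.ndarray


def pca_svd(matrix: pd.DataFrame) -> PcaResult:
    """Principal components analysis via singular value decomposition.

    The input is column-mean-centred and decomposed as ``X = U S V^T``;
    scores are ``U S``, loadings are the columns of ``V`` and the variance
    fractions are ``S^2 / sum(S^2)``.  With all components retained,
    ``scores @ loadings.T`` reconstructs the centred input exactly (to
    numerical precision).
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("PCA requires at least 2 samples and 2 features")
    x = matrix.to_numpy(dtype=float)
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    if not (s > 1e-12 * max(x.shape)).any():
        raise ValueError("matrix has rank 0 after centering")
    # Deterministic sign convention: the largest-magnitude loading of each
    # component is positive.
    v = vt.T
    for c in range(v.shape[1]):
        j = int(np.argmax(np.abs(v[:, c])))
        if v[j, c] < 0:
            v[:, c] = -v[:, c]
            u[:, c] = -u[:, c]
    comp = [f"PC{i + 1}" for i in range(len(s))]
    scores = pd.DataFrame(u * s, index=matrix.index, columns=comp)
    loadings = pd.DataFrame(v, index=matrix.columns, columns=comp)
    var = s ** 2 / np.sum(s ** 2)
    return PcaResult(scores=scores, loadings=loadings,
                     variance_explained=var, singular_values=s)


# ---------------------------------------------------------------------------
# PERMANOVA

@dataclasses.dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    group_labels: tuple[str, ...]
    adjusted_p: float | None = None
    n_samples: int = 0


def _validate_distance(dist: pd.DataFrame | np.ndarray) -> np.ndarray:
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-8):
        raise ValueError("distance matrix must have a zero diagonal")
    return d


def permanova(dist: pd.DataFrame | np.ndarray, labels,
              n_perm: int = 9999, seed: int = 0) -> PermanovaResult:
    """Permutational multivariate analysis of variance on a distance matrix.

    With total sum of squares ``SS_T = sum_{i<j} d_ij^2 / n`` and within-
    group ``SS_W = sum_g sum_{i<j in g} d_ij^2 / n_g``, the statistic is

        ``F = ((SS_T - SS_W) / (a - 1)) / (SS_W / (n - a))``

    for ``a`` groups of ``n`` samples.  Group labels are permuted uniformly;
    the p-value uses the add-one rule ``p = (1 + #{F_perm >= F_obs}) /
    (1 + n_perm)`` with ties counted as exceedances, so ``p >= 1/(n_perm+1)``
    and results are bit-reproducible under a fixed seed.
    """
    d = _validate_distance(dist)
    labels = np.asarray(pd.Series(labels), dtype=object)
    if len(labels) != d.shape[0]:
        raise ValueError("labels length does not match distance matrix")
    codes, uniques = pd.factorize(labels)
    a = len(uniques)
    if a < 2:
        raise ValueError("PERMANOVA requires at least 2 groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        small = [str(uniques[g]) for g in np.flatnonzero(sizes < 2)]
        raise ValueError(f"group(s) with fewer than 2 members: {small}")
    n = d.shape[0]
    d2 = d ** 2
    ss_total = d2.sum() / (2.0 * n)

    def _ss_within(code_rows: np.ndarray) -> np.ndarray:
        out = np.zeros(code_rows.shape[0])
        for g in range(a):
            m = (code_rows == g).astype(np.float64)
            out += np.einsum("ij,ij->i", m @ d2, m) / (2.0 * sizes[g])
        return out

    ss_within = float(_ss_within(codes[None, :])[0])
    f_obs = ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))

    rng = np.random.default_rng(seed)
    exceed = 0
    chunk = max(1, min(n_perm, int(2e7 // max(n, 1))))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perm_codes = rng.permuted(np.tile(codes, (m, 1)), axis=1)
        ssw = _ss_within(perm_codes)
        f_perm = ((ss_total - ssw) / (a - 1)) / (ssw / (n - a))
        exceed += int(np.sum(f_perm >= f_obs))
        done += m
    p = (1.0 + exceed) / (1.0 + n_perm)
    return PermanovaResult(pseudo_F=float(f_obs), p_value=float(p),
                           n_permutations=int(n_perm),
                           group_labels=tuple(str(u) for u in uniques),
                           n_samples=n)


def pairwise_permanova(dist: pd.DataFrame, labels, n_perm: int = 9999,
                       seed: int = 0) -> list[PermanovaResult]:
    """All pairwise group PERMANOVAs with Bonferroni-adjusted p-values.

    ``adjusted_p = min(1, p * m)`` where ``m`` is the number of pairwise
    tests actually performed.
    """
    labels = pd.Series(labels, index=dist.index)
    groups = sorted(labels.unique())
    pairs = list(itertools.combinations(groups, 2))
    m = len(pairs)
    if m < 1:
        raise ValueError("pairwise PERMANOVA requires at least 2 groups")
    results = []
    for k, (g1, g2) in enumerate(pairs):
        ids = labels.index[labels.isin([g1, g2])]
        sub = dist.loc[ids, ids]
        res = permanova(sub, labels.loc[ids], n_perm=n_perm, seed=seed + k)
        results.append(dataclasses.replace(
            res, adjusted_p=min(1.0, res.p_value * m)))
    return results


# ---------------------------------------------------------------------------
# Covariability PCA (standardised variables)

@dataclasses.dataclass(frozen=True)
class CovariabilityResult:
    pca: PcaResult
    #: squared Pearson correlation of each input variable with each score column
    r_squared: pd.DataFrame


def covariability_pca(variables: pd.DataFrame) -> CovariabilityResult:
    """PCA of mean-centred, standard-deviation-normalised variables.

    Used to examine covariability of pigment-group relative abundances with
    POC flux: pass a samples x variables frame (groups plus a flux column).
    Reports, for each variable, its squared correlation with each component
    score.  A zero-variance variable is an error naming the variable.
    """
    x = variables.astype(float)
    sd = x.std(axis=0, ddof=1)
    dead = sorted(sd.index[~(sd > 0)])
    if dead:
        raise ValueError(f"zero-variance variable(s): {dead}")
    z = (x - x.mean(axis=0)) / sd
    pca = pca_svd(z)
    scores = pca.scores.to_numpy()
    zz = z.to_numpy()
    r2 = np.zeros((z.shape[1], scores.shape[1]))
    for j in range(z.shape[1]):
        for c in range(scores.shape[1]):
            if np.std(scores[:, c]) < 1e-12:
                r2[j, c] = 0.0
            else:
                r2[j, c] = np.corrcoef(zz[:, j], scores[:, c])[0, 1] ** 2
    r2_df = pd.DataFrame(r2, index=variables.columns, columns=pca.scores.columns)
    return CovariabilityResult(pca=pca, r_squared=r2_df)


# ---------------------------------------------------------------------------
# One-way ANOVA with Tukey-Kramer post hoc

@dataclasses.dataclass(frozen=True)
class AnovaTukeyResult:
    f_statistic: float
    p_value: float
    group_labels: tuple[str, ...]
    #: one row per group pair: mean difference, adjusted p, 95% CI bounds
    tukey: pd.DataFrame


def anova_tukey(values, labels) -> AnovaTukeyResult:
    """One-way ANOVA plus Tukey-Kramer honest significant differences.

    The Tukey-Kramer procedure uses the studentized range distribution and
    handles unequal group sizes.  With all observations identical the ANOVA
    is degenerate and reported as F = 0, p = 1.
    """
    values = pd.Series(values, dtype=float)
    labels = pd.Series(labels, index=values.index)
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least 2 groups")
    arrays = [values[labels == g].to_numpy() for g in groups]
    if any(len(arr) < 2 for arr in arrays):
        raise ValueError("every group needs at least 2 members")
    pairs = list(itertools.combinations(range(len(groups)), 2))
    if np.ptp(values.to_numpy()) == 0:
        tukey = pd.DataFrame(
            [{"group_a": groups[i], "group_b": groups[j], "mean_diff": 0.0,
              "p_adj": 1.0, "ci_low": 0.0, "ci_high": 0.0} for i, j in pairs])
        return AnovaTukeyResult(0.0, 1.0, tuple(groups), tukey)
    f, p = sps.f_oneway(*arrays)
    hsd = sps.tukey_hsd(*arrays)
    ci = hsd.confidence_interval(0.95)
    rows = []
    for i, j in pairs:
        rows.append({"group_a": groups[i], "group_b": groups[j],
                     "mean_diff": float(np.mean(arrays[i]) - np.mean(arrays[j])),
                     "p_adj": float(hsd.pvalue[i, j]),
                     "ci_low": float(ci.low[i, j]),
                     "ci_high": float(ci.high[i, j])})
    return AnovaTukeyResult(float(f), float(p), tuple(groups),
                            pd.DataFrame(rows))
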