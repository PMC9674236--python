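"""Knockout-vs-wildtype differential statistics.

Pipeline order is fixed: replicate-completeness filter (quant_io) -> log2
transform -> per-sample left-shifted imputation -> pooled-variance Student's
t per peptide -> permutation-based q-values -> significance at q < 0.05 ->
z-scaling and hierarchical clustering of the significant set.

The permutation-FDR estimator: the same random relabeling of samples is
applied to all peptides per iteration and the null |t| values are pooled
across peptides.  For peptide i,

    q_raw(i) = [mean over permutations of #{null |t| >= |t_i|}]
               / #{observed |t| >= |t_i|}

clipped to [0, 1] and made monotone non-increasing in |t| by taking, for
each peptide, the minimum raw estimate over all thresholds at least as
lenient as its own.  Ties are counted inclusively (>=) on both sides.
Per-peptide permutation p-values are pooled-null tail fractions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as stats

from .quant_io import QuantTable

logger = logging.getLogger(__name__)

Q_CUTOFF = 0.05
N_PERM = 250


@dataclass(frozen=True)
class ImputationParams:
    """Left-shifted normal imputation, in units of each sample's observed
    log2 statistics: draws come from
    Normal(mean - downshift * sd, (width * sd)^2)."""

    downshift: float = 1.8
    width: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be > 0")


def log2_transform(values: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2; missing values stay missing, nonpositive values are
    a contract violation (zeros must have been encoded as missing)."""
    arr = values.to_numpy(dtype=float)
    if np.nanmin(arr, initial=np.inf) <= 0:
        raise ValueError("nonpositive abundance: zeros must be encoded as missing")
    return pd.DataFrame(np.log2(arr), index=values.index, columns=values.columns)


def impute_leftshift(log2_values: pd.DataFrame, params: ImputationParams | None = None) -> pd.DataFrame:
    """Impute missing cells from each sample's down-shifted normal."""
    params = params if params is not None else ImputationParams()
    rng = np.random.default_rng(params.seed)
    out = log2_values.copy()
    for col in out.columns:
        x = out[col]
        observed = x.dropna()
        if len(observed) < 2:
            raise ValueError(f"sample {col!r} has fewer than 2 observed values")
        mean, sd = float(observed.mean()), float(observed.std(ddof=1))
        n_missing = int(x.isna().sum())
        if n_missing:
            draws = rng.normal(mean - params.downshift * sd, params.width * sd, n_missing)
            out.loc[x.isna(), col] = draws
    return out


def student_t(group_a, group_b) -> tuple[float, float]:
    """Classical two-sample pooled-variance Student's t (A minus B).

    Returns (t, two-sided p) with df = nA + nB - 2.  Degenerate zero-
    variance input: equal means give (0, 1); unequal means give
    (signed inf, 0).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    t, p = _t_matrix(np.concatenate([a, b])[None, :],
                     np.arange(len(a) + len(b)) < len(a))
    return float(t[0]), float(p[0])


def _t_matrix(X: np.ndarray, mask_a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise pooled t and two-sided p for a peptides x samples matrix."""
    A, B = X[:, mask_a], X[:, ~mask_a]
    na, nb = A.shape[1], B.shape[1]
    diff = A.mean(axis=1) - B.mean(axis=1)
    sp2 = ((na - 1) * A.var(axis=1, ddof=1) + (nb - 1) * B.var(axis=1, ddof=1)) / (na + nb - 2)
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
        t = np.where(se == 0, np.where(diff == 0, 0.0, np.sign(diff) * np.inf), t)
    p = 2.0 * stats.t.sf(np.abs(t), df=na + nb - 2)
    p = np.where(np.isinf(t), 0.0, p)
    p = np.where((se == 0) & (diff == 0), 1.0, p)
    return t, p


def welch_t(group_a, group_b) -> tuple[float, float]:
    """Welch's unequal-variance alternative (configuration option)."""
    res = stats.ttest_ind(group_a, group_b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def _distinct_assignments(n: int, na: int):
    for idx in combinations(range(n), na):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        yield mask


def permutation_stats(X: np.ndarray, mask_a: np.ndarray, n_perm: int = N_PERM,
                      seed: int = 0) -> pd.DataFrame:
    """Permutation p- and q-values for all rows of a complete log2 matrix.

    Label assignments are drawn uniformly without replacement among the
    distinct ways of assigning group A (the observed assignment excluded);
    when fewer distinct assignments than ``n_perm`` exist, all of them are
    enumerated instead (with a warning).  Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n = X.shape[1]
    na = int(mask_a.sum())
    t_obs, _ = _t_matrix(X, mask_a)
    abs_obs = np.abs(t_obs)

    total = comb(n, na)
    if total - 1 <= n_perm:
        masks = list(_distinct_assignments(n, na))
        warnings.warn(
            f"only {total} distinct label assignments exist; enumerating all "
            f"instead of sampling {n_perm}", stacklevel=2)
    else:
        rng = np.random.default_rng(seed)
        chosen: set[tuple[int, ...]] = set()
        observed_key = tuple(np.flatnonzero(mask_a))
        while len(chosen) < n_perm:
            key = tuple(sorted(rng.choice(n, size=na, replace=False).tolist()))
            if key != observed_key:
                chosen.add(key)
        masks = []
        for key in sorted(chosen):
            m = np.zeros(n, dtype=bool)
            m[list(key)] = True
            masks.append(m)

    null = np.concatenate([np.abs(_t_matrix(X, m)[0]) for m in masks])
    null_sorted = np.sort(null)
    P, m_pep = len(masks), X.shape[0]
    # inclusive tail counts of the pooled null at each observed |t|
    tail = len(null_sorted) - np.searchsorted(null_sorted, abs_obs, side="left")
    p_perm = tail / (P * m_pep)

    obs_sorted = np.sort(abs_obs)
    n_discoveries = m_pep - np.searchsorted(obs_sorted, abs_obs, side="left")
    q_raw = np.clip((tail / P) / n_discoveries, 0.0, 1.0)
    order = np.argsort(abs_obs, kind="mergesort")
    q = np.empty_like(q_raw)
    q[order] = np.minimum.accumulate(q_raw[order])
    return pd.DataFrame({"t": t_obs, "abs_t": abs_obs, "p_perm": p_perm, "q": q})


def permutation_qvalues(X: np.ndarray, mask_a: np.ndarray, n_perm: int = N_PERM,
                        seed: int = 0) -> np.ndarray:
    return permutation_stats(X, mask_a, n_perm=n_perm, seed=seed)["q"].to_numpy()


def zscale(values: pd.DataFrame, ddof: int = 0) -> tuple[pd.DataFrame, np.ndarray]:
    """Row-wise z-score (population sd by default).  Constant rows become
    all zeros; the returned boolean array flags them."""
    arr = values.to_numpy(dtype=float)
    if arr.shape[1] < 2:
        raise ValueError("need at least 2 values per row to z-scale")
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=ddof, keepdims=True)
    constant = (sd == 0).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (arr - mean) / sd
    z[constant, :] = 0.0
    return pd.DataFrame(z, index=values.index, columns=values.columns), constant


def hcluster(scaled: pd.DataFrame, method: str = "average",
             metric: str = "euclidean") -> tuple[np.ndarray, np.ndarray]:
    """Agglomerative clustering of rows; returns (leaf order, linkage matrix)."""
    if len(scaled) < 2:
        raise ValueError("need at least 2 rows to cluster")
    Z = sch.linkage(scaled.to_numpy(dtype=float), method=method, metric=metric)
    return sch.leaves_list(Z), Z


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick string."""
    tree = sch.to_tree(Z)

    def rec(node, parent_dist) -> str:
        length = parent_dist - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        inner = ",".join(rec(c, node.dist) for c in (node.left, node.right))
        return f"({inner}):{length:.6g}"

    inner = ",".join(rec(c, tree.dist) for c in (tree.left, tree.right))
    return f"({inner});"


def differential_analysis(table: QuantTable, ko_genotype: str, wt_genotype: str = "WT",
                          n_perm: int = N_PERM, q_cutoff: float = Q_CUTOFF,
                          imputation: ImputationParams | None = None,
                          impute: bool = True, seed: int = 0) -> pd.DataFrame:
    """Full per-peptide differential analysis of one knockout contrast.

    Selects the samples of the two genotypes, log2-transforms, imputes
    missing values (unless ``impute=False``, the mode used for precursor-
    level comparisons on raw log2 values, where rows with missing values in
    either group are dropped), computes pooled-t statistics, permutation
    q-values, and significance calls.  log2FC is KO minus WT.
    """
    sel = table.samples["genotype"].isin([ko_genotype, wt_genotype])
    if not sel.any():
        raise ValueError(f"no samples for genotypes {ko_genotype!r}/{wt_genotype!r}")
    cols = table.samples.loc[sel, "sample_id"].tolist()
    mask_ko = (table.samples.loc[sel, "genotype"] == ko_genotype).to_numpy()
    log2 = log2_transform(table.values[cols])
    if impute:
        params = imputation if imputation is not None else ImputationParams(seed=seed)
        log2 = impute_leftshift(log2, params)
        peptides = table.peptides
    else:
        complete = log2.notna().all(axis=1)
        log2 = log2.loc[complete]
        peptides = table.peptides.loc[complete]
    X = log2.to_numpy(dtype=float)
    perm = permutation_stats(X, mask_ko, n_perm=n_perm, seed=seed)
    _, p_classic = _t_matrix(X, mask_ko)
    mean_ko = X[:, mask_ko].mean(axis=1)
    mean_wt = X[:, ~mask_ko].mean(axis=1)
    results = peptides.copy().reset_index(drop=True)
    results["mean_log2_ko"] = mean_ko
    results["mean_log2_wt"] = mean_wt
    results["log2fc"] = mean_ko - mean_wt
    results["t"] = perm["t"].to_numpy()
    results["p_value"] = p_classic
    results["p_perm"] = perm["p_perm"].to_numpy()
    results["q_value"] = perm["q"].to_numpy()
    results["significant"] = results["q_value"] < q_cutoff
    results["direction"] = np.where(results["log2fc"] > 0, "KO-enriched", "WT-enriched")
    return results


def enriched_sets(results: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split significant peptides into KO-enriched (log2FC > 0) and
    WT-enriched (log2FC < 0) sets."""
    sig = results[results["significant"]]
    return (sig[sig["log2fc"] > 0].copy(), sig[sig["log2fc"] < 0].copy())
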