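"""Quantitative statistics on the secretome intensity matrix.

The stage order mirrors a Perseus-style label-free workflow: keep proteins
detected in at least ``min_detected`` of the replicates of some cell type,
log2-transform LFQ intensities, impute missing values from a left-shifted
Gaussian (missing values in label-free MS are predominantly low-abundance,
so draws come from the lower tail of each sample's observed distribution),
then test for cell-type differences with a one-way ANOVA whose false
discovery rate is estimated from sample-label permutations.

The permutation FDR is the pooled-ratio (SAM/Tusher-style) estimator: for a
protein with observed statistic F, q(F) is the average number of permuted
statistics (pooled over all proteins) at or above F per randomization,
divided by the number of observed statistics at or above F, clipped to
[0, 1] and made monotone non-increasing in F.  The same label permutation
is applied to every protein within a randomization, preserving
protein-protein correlation under the null.  Permutations are uniform over
sample-label orderings (not stratified by cell type).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .msio import IntensityMatrix


@dataclass(frozen=True)
class DetectionFilterSpec:
    """Keep proteins with >= ``min_detected`` quantified replicates in at
    least one group (default: 2 of 3)."""

    min_detected: int = 2
    per_group_size: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.min_detected <= self.per_group_size:
            raise ValueError("need 0 < min_detected <= per_group_size")


@dataclass(frozen=True)
class ImputeSpec:
    """Left-shifted Gaussian imputation, per sample column.

    Missing entries are drawn from Normal(mu - downshift * sd,
    (width * sd)^2) where mu and sd are the mean and SD of the column's
    observed log2 intensities.  Defaults (width 0.3, downshift 1.8) are the
    standard Perseus convention.
    """

    width: float = 0.3
    downshift: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.downshift < 0:
            raise ValueError("downshift must be >= 0")


@dataclass
class AnovaResult:
    """Per-protein F statistics and permutation q-values.

    ``table`` has columns ``F``, ``q``, ``significant`` indexed by protein;
    ``significant`` is exactly ``q < q_threshold``.
    """

    table: pd.DataFrame
    n_permutations: int
    q_threshold: float
    seed: int
    metadata: dict = field(default_factory=dict)

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    @property
    def significant_proteins(self) -> pd.Index:
        return self.table.index[self.table["significant"]]


def filter_detected(m: IntensityMatrix, spec: DetectionFilterSpec | None = None) -> IntensityMatrix:
    """Keep proteins quantified in >= min_detected replicates of some group."""
    spec = spec or DetectionFilterSpec()
    groups = m.groups()
    for g, cols in groups.items():
        if len(cols) < spec.min_detected:
            raise ValueError(f"group '{g}' has {len(cols)} samples < min_detected")
    detected = m.lfq > 0
    keep = np.zeros(m.n_proteins, dtype=bool)
    for cols in groups.values():
        keep |= (detected[cols].sum(axis=1) >= spec.min_detected).to_numpy()
    return m.subset(m.protein_ids[keep])


def log2_transform(m: IntensityMatrix | pd.DataFrame) -> pd.DataFrame:
    """Log2 LFQ intensities with missing (0) entries as NaN; no imputation."""
    lfq = m.lfq if isinstance(m, IntensityMatrix) else m
    vals = lfq.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("negative intensity")
    out = np.full_like(vals, np.nan)
    pos = vals > 0
    out[pos] = np.log2(vals[pos])
    return pd.DataFrame(out, index=lfq.index, columns=lfq.columns)


def impute_left_gaussian(logm: pd.DataFrame, spec: ImputeSpec | None = None) -> pd.DataFrame:
    """Fill NaNs column-by-column from a down-shifted Gaussian.

    Observed values are never altered; the result is reproducible under a
    fixed ``spec.seed``.  Raises if any column has fewer than two observed
    values (mean and SD would be undefined).
    """
    spec = spec or ImputeSpec()
    rng = np.random.default_rng(spec.seed)
    vals = logm.to_numpy(dtype=float).copy()
    for j, col in enumerate(logm.columns):
        observed = vals[:, j][~np.isnan(vals[:, j])]
        if observed.size < 2:
            raise ValueError(f"column '{col}' has {observed.size} observed values (< 2)")
        mu, sd = observed.mean(), observed.std(ddof=1)
        missing = np.isnan(vals[:, j])
        vals[missing, j] = rng.normal(
            mu - spec.downshift * sd, spec.width * sd, size=int(missing.sum())
        )
    return pd.DataFrame(vals, index=logm.index, columns=logm.columns)


def anova_f_statistic(x: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Vectorized one-way ANOVA F over rows of ``x`` (rows = proteins).

    Rows with zero within- and between-group variance get NaN.
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    k, n = len(uniq), x.shape[1]
    if k < 2:
        raise ValueError("need >= 2 groups")
    grand = x.mean(axis=1)
    ssb = np.zeros(x.shape[0])
    ssw = np.zeros(x.shape[0])
    for g in uniq:
        cols = labels == g
        ng = int(cols.sum())
        if ng < 2:
            raise ValueError(f"group '{g}' has < 2 samples")
        mg = x[:, cols].mean(axis=1)
        ssb += ng * (mg - grand) ** 2
        ssw += ((x[:, cols] - mg[:, None]) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / (k - 1)) / (ssw / (n - k))
    f[~np.isfinite(f)] = np.nan
    return f


def _pooled_permutation_q(f_obs: np.ndarray, f_perm: np.ndarray) -> np.ndarray:
    """Pooled-ratio q-values, clipped to [0,1], monotone non-increasing in F.

    NaN statistics (constant rows) receive q = 1.
    """
    n_perm = f_perm.shape[0]
    valid = ~np.isnan(f_obs)
    q = np.ones_like(f_obs)
    if valid.any():
        obs = f_obs[valid]
        obs_sorted = np.sort(obs)
        pool = np.sort(f_perm[~np.isnan(f_perm)])
        n_obs_ge = obs.size - np.searchsorted(obs_sorted, obs, side="left")
        n_perm_ge = pool.size - np.searchsorted(pool, obs, side="left")
        raw = np.clip((n_perm_ge / n_perm) / n_obs_ge, 0.0, 1.0)
        # canonical q-value monotonization: q(F) = min of the raw FDR
        # estimate over all thresholds at or below F, so q is monotone
        # non-increasing in F; ties in F share identical raw q already,
        # order within ties follows input order
        order = np.argsort(-obs, kind="stable")  # descending F
        q_sorted = np.minimum.accumulate(raw[order][::-1])[::-1]
        q_valid = np.empty_like(raw)
        q_valid[order] = q_sorted
        q[valid] = q_valid
    return q


def permutation_fdr_anova(
    complete: pd.DataFrame,
    groups: pd.Series | np.ndarray | list,
    n_perm: int = 250,
    q_threshold: float = 0.01,
    seed: int = 0,
) -> AnovaResult:
    """One-way ANOVA across groups with permutation-based FDR.

    ``complete`` is the imputed proteins x samples log2 matrix; ``groups``
    gives the group label per sample column.  Defaults reproduce the
    reference analysis: 250 randomizations, significance at q < 0.01.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(pd.Series(groups).to_numpy())
    if labels.shape[0] != complete.shape[1]:
        raise ValueError("one group label per sample column required")
    x = complete.to_numpy(dtype=float)
    f_obs = anova_f_statistic(x, labels)
    rng = np.random.default_rng(seed)
    f_perm = np.empty((n_perm, x.shape[0]))
    for b in range(n_perm):
        f_perm[b] = anova_f_statistic(x, labels[rng.permutation(labels.shape[0])])
    q = _pooled_permutation_q(f_obs, f_perm)
    table = pd.DataFrame(
        {"F": f_obs, "q": q, "significant": q < q_threshold}, index=complete.index
    )
    return AnovaResult(
        table=table,
        n_permutations=n_perm,
        q_threshold=q_threshold,
        seed=seed,
        metadata={
            "estimator": "pooled-permutation ratio (SAM-style), monotonized",
            "permutation_scheme": "uniform unstratified; shared across proteins per randomization",
        },
    )


def pairwise_scatter(
    logm: pd.DataFrame,
    samples: pd.DataFrame,
    type_a: str,
    type_b: str,
) -> pd.DataFrame:
    """Per-protein (mean_a, mean_b) log2 intensities, without imputation.

    Missing values are excluded from each mean; a protein fully missing in
    a type gets NaN for that coordinate.
    """
    for t in (type_a, type_b):
        if t not in set(samples["group"]):
            raise ValueError(f"unknown cell type '{t}'")
    cols_a = samples.index[samples["group"] == type_a]
    cols_b = samples.index[samples["group"] == type_b]
    return pd.DataFrame(
        {type_a: logm[cols_a].mean(axis=1), type_b: logm[cols_b].mean(axis=1)},
        index=logm.index,
    )


def sample_pca_and_correlation(
    complete: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Project samples on the first two PCs and compute the sample-sample
    Pearson matrix, both on imputed log2 intensities.

    Returns (coordinates, correlation matrix, explained variance ratio).
    """
    from sklearn.decomposition import PCA

    if complete.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    x = complete.to_numpy(dtype=float).T  # samples x proteins
    x = x - x.mean(axis=0)  # center per protein
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(x)
    coords_df = pd.DataFrame(coords, index=complete.columns, columns=["PC1", "PC2"])
    corr = pd.DataFrame(
        np.corrcoef(complete.to_numpy(dtype=float), rowvar=False),
        index=complete.columns,
        columns=complete.columns,
    )
    return coords_df, corr, pca.explained_variance_ratio_
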