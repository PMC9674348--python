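"""Tissue-enrichment scoring against an expression atlas.

A gene's adipose-tissue enrichment score is the percentage of non-adipose
tissues that express it at a significantly lower level than the adipose
reference:

    score = 100 * n_enriched / (T - 2)

where T is the number of tissues in the atlas (two of them adipose) and a
comparison counts as enriched when the adipose-minus-tissue log2 fold
change exceeds 4 with a Benjamini-Hochberg adjusted p below 0.05.  The
per-comparison test is a two-sample t with empirical-Bayes variance
moderation: per-gene residual variances are shrunk toward a pooled prior
whose degrees of freedom and scale are estimated by method of moments on
the log residual variances (the standard limma-style squeeze), which keeps
small-replicate comparisons from being dominated by unstable variance
estimates.

The adipose reference is selectable: either white or brown adipose depot
alone, both pooled ("combined", the default — the worked Adipoq example
references eWAT and BAT combined), or "any" (a tissue counts if it is
significantly lower than any of the three references).

The module also computes relative tissue-expression profiles (per-gene
linear-scale tissue means divided by their sum) and embeds them with t-SNE
for visual grouping of tissue-restricted genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

MODES = ("combined", "white", "brown", "any")

DEFAULT_FC_THRESHOLD = 4.0
DEFAULT_FDR = 0.05


@dataclass
class TissueAtlas:
    """Genes x (tissue, replicate) log2 expression matrix.

    ``values`` carries a two-level column MultiIndex (tissue, replicate);
    ``adipose_tissues`` names the (white, brown) adipose tissue labels.
    """

    values: pd.DataFrame
    adipose_tissues: tuple[str, str]

    def __post_init__(self) -> None:
        if self.values.columns.nlevels != 2:
            raise ValueError("values needs (tissue, replicate) MultiIndex columns")
        self.values.columns = self.values.columns.set_names(["tissue", "replicate"])
        tissues = self.tissues
        if len(tissues) < 3:
            raise ValueError("atlas needs >= 3 tissues (two adipose + others)")
        for t in self.adipose_tissues:
            if t not in tissues:
                raise ValueError(f"adipose tissue '{t}' not in atlas")

    @property
    def tissues(self) -> list[str]:
        return list(self.values.columns.get_level_values("tissue").unique())

    @property
    def non_adipose_tissues(self) -> list[str]:
        return [t for t in self.tissues if t not in self.adipose_tissues]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def n_comparisons(self) -> int:
        return len(self.tissues) - 2

    def tissue_values(self, tissue: str) -> pd.DataFrame:
        return self.values.xs(tissue, axis=1, level="tissue")

    def reference_values(self, mode: str) -> pd.DataFrame:
        """Replicate values of the selected adipose reference."""
        white, brown = self.adipose_tissues
        if mode == "white":
            return self.tissue_values(white)
        if mode == "brown":
            return self.tissue_values(brown)
        if mode == "combined":
            return pd.concat(
                [self.tissue_values(white), self.tissue_values(brown)], axis=1
            )
        raise ValueError(f"mode must be one of {MODES}, got '{mode}'")


@dataclass
class EnrichmentResult:
    """Adipose enrichment of one gene: how many of the T-2 non-adipose
    tissues express it at a significantly lower level."""

    gene: str
    n_enriched: int
    n_comparisons: int
    mode: str = "combined"

    def __post_init__(self) -> None:
        if not 0 <= self.n_enriched <= self.n_comparisons:
            raise ValueError("need 0 <= n_enriched <= n_comparisons")

    @property
    def score_percent(self) -> float:
        return 100.0 * self.n_enriched / self.n_comparisons


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone, fast)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes shrinkage of per-gene residual variances.

    Models s2 as scaled-F distributed around a prior variance ``s0^2`` with
    prior degrees of freedom ``d0``, both estimated by method of moments on
    log s2 (matching the mean and variance of log s2 to the theoretical
    log-F moments via digamma/trigamma).  Returns posterior variances
    ``(d0*s0^2 + df*s2) / (d0 + df)``, d0 and s0^2.  With fewer than two
    finite variances, or when the observed spread is no larger than the
    chi-square sampling spread (d0 -> infinity), all posteriors collapse to
    the pooled value.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2[np.isfinite(s2) & (s2 > 0)]
    if pos.size < 2:
        pooled = float(pos.mean()) if pos.size else np.nan
        return np.full_like(s2, pooled), np.inf, pooled
    z = np.log(pos)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    emean = e.mean()
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_2 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        post = (d0 * s0_2 + df * s2) / (d0 + df)
    else:
        d0 = np.inf
        s0_2 = float(np.exp(emean))
        post = np.full_like(s2, s0_2)
    return post, d0, s0_2


def moderated_ttest(
    ref: np.ndarray,
    other: np.ndarray,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Two-sample moderated t per gene (rows).

    ``ref`` and ``other`` are genes x replicates arrays of log2 values.
    ``prior_df=None`` estimates the prior from the data; ``prior_df=0``
    recovers the ordinary equal-variance two-sample t.
    Returns log2FC (ref - other), t, raw p and the moderation parameters.
    """
    ref = np.atleast_2d(np.asarray(ref, dtype=float))
    other = np.atleast_2d(np.asarray(other, dtype=float))
    n1, n2 = ref.shape[1], other.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 replicates on each side")
    df = n1 + n2 - 2
    if df < 1:
        raise ValueError("zero residual degrees of freedom")
    m1, m2 = ref.mean(axis=1), other.mean(axis=1)
    ss = ((ref - m1[:, None]) ** 2).sum(axis=1) + ((other - m2[:, None]) ** 2).sum(axis=1)
    s2 = ss / df
    if prior_df is None:
        s2_post, d0, s0_2 = squeeze_variances(s2, df)
    elif prior_df == 0:
        s2_post, d0, s0_2 = s2, 0.0, np.nan
    else:
        _, _, s0_2 = squeeze_variances(s2, df)
        d0 = float(prior_df)
        s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
    lfc = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    total_df = df + d0
    if np.isinf(total_df):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), total_df)
    return pd.DataFrame(
        {"log2fc": lfc, "t": t, "p": p,
         "df_residual": df, "df_prior": d0, "s2_prior": s0_2}
    )


def pairwise_tissue_de(
    atlas: TissueAtlas,
    other_tissue: str,
    adipose_ref: str = "combined",
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    fdr: float = DEFAULT_FDR,
    prior_df: float | None = None,
    gene: str | None = None,
):
    """Moderated DE of the adipose reference against one other tissue.

    Significance requires log2FC (adipose minus tissue) > ``fc_threshold``
    AND BH-adjusted p < ``fdr``, with BH applied across genes within this
    tissue-pair comparison.  Returns the per-gene table, or the single
    tuple ``(log2fc, p, significant)`` when ``gene`` is given.
    """
    if other_tissue in atlas.adipose_tissues:
        raise ValueError(f"'{other_tissue}' is an adipose reference tissue")
    if other_tissue not in atlas.tissues:
        raise ValueError(f"unknown tissue '{other_tissue}'")
    ref = atlas.reference_values(adipose_ref).to_numpy()
    other = atlas.tissue_values(other_tissue).to_numpy()
    out = moderated_ttest(ref, other, prior_df=prior_df)
    out.index = atlas.genes
    out["p_adj"] = benjamini_hochberg(out["p"].to_numpy())
    out["significant"] = (out["log2fc"] > fc_threshold) & (out["p_adj"] < fdr)
    if gene is not None:
        row = out.loc[gene]
        return float(row["log2fc"]), float(row["p"]), bool(row["significant"])
    return out


def enrichment_scores(
    atlas: TissueAtlas,
    mode: str = "combined",
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    fdr: float = DEFAULT_FDR,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Adipose enrichment scores for every gene in the atlas.

    Runs the moderated pairwise DE against each of the T-2 non-adipose
    tissues with the selected adipose reference and counts, per gene, the
    tissues with significantly lower expression.  Mode "any" counts a
    tissue when it is significant against white, brown, or the combined
    reference.  Returns a DataFrame indexed by gene with columns
    ``n_enriched``, ``n_comparisons``, ``score_percent``, ``mode``.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got '{mode}'")
    refs = ("white", "brown", "combined") if mode == "any" else (mode,)
    n_enriched = np.zeros(len(atlas.genes), dtype=int)
    for tissue in atlas.non_adipose_tissues:
        sig = np.zeros(len(atlas.genes), dtype=bool)
        for ref in refs:
            de = pairwise_tissue_de(
                atlas, tissue, adipose_ref=ref,
                fc_threshold=fc_threshold, fdr=fdr, prior_df=prior_df,
            )
            sig |= de["significant"].to_numpy()
        n_enriched += sig
    n_comp = atlas.n_comparisons
    return pd.DataFrame(
        {
            "n_enriched": n_enriched,
            "n_comparisons": n_comp,
            "score_percent": 100.0 * n_enriched / n_comp,
            "mode": mode,
        },
        index=atlas.genes,
    )


def enrichment_score(
    atlas: TissueAtlas,
    gene: str,
    mode: str = "combined",
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    fdr: float = DEFAULT_FDR,
    prior_df: float | None = None,
) -> EnrichmentResult:
    """Enrichment score of a single gene (see :func:`enrichment_scores`)."""
    table = enrichment_scores(
        atlas, mode=mode, fc_threshold=fc_threshold, fdr=fdr, prior_df=prior_df
    )
    if gene not in table.index:
        raise KeyError(f"gene '{gene}' not in atlas")
    row = table.loc[gene]
    return EnrichmentResult(
        gene=gene, n_enriched=int(row["n_enriched"]),
        n_comparisons=int(row["n_comparisons"]), mode=mode,
    )


def relative_expression(atlas: TissueAtlas, linear: bool = True) -> pd.DataFrame:
    """Per-gene tissue-fraction profile and highest-expressing tissue.

    Tissue means are taken on the linear scale (2^log2 averaged per tissue;
    ``linear=False`` averages log2 values instead) and divided by the sum
    across tissues, so each gene's profile sums to 1.  Ties for the top
    tissue break by tissue-name order.
    """
    means = {}
    for t in atlas.tissues:
        v = atlas.tissue_values(t).to_numpy(dtype=float)
        means[t] = np.exp2(v).mean(axis=1) if linear else v.mean(axis=1)
    prof = pd.DataFrame(means, index=atlas.genes)
    totals = prof.sum(axis=1)
    if (totals <= 0).any():
        bad = prof.index[totals <= 0].tolist()
        raise ValueError(f"gene(s) with non-positive total expression: {bad[:5]}")
    frac = prof.div(totals, axis=0)
    frac = frac[sorted(frac.columns)]  # name order decides argmax ties
    frac["top_tissue"] = frac.idxmax(axis=1)
    return frac


def embed_tsne(
    profiles: pd.DataFrame,
    perplexity: float = 30.0,
    max_iter: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """2-D t-SNE embedding of relative-expression profiles.

    Reproducible under a fixed seed.  The perplexity is auto-reduced (with
    a warning) when fewer than 3 * perplexity profiles are supplied.
    """
    from sklearn.manifold import TSNE

    x = profiles.to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in profiles")
    n = x.shape[0]
    if n < 3 * perplexity:
        new = max(2.0, (n - 1) / 3.0)
        warnings.warn(
            f"perplexity {perplexity} too large for {n} profiles; using {new}",
            stacklevel=2,
        )
        perplexity = new
    ts = TSNE(
        n_components=2, perplexity=perplexity, max_iter=max_iter,
        random_state=seed, init="pca",
    )
    coords = ts.fit_transform(x)
    return pd.DataFrame(coords, index=profiles.index, columns=["tsne1", "tsne2"])


def write_atlas(atlas: TissueAtlas, path, sidecar_path) -> None:
    """CSV export: columns '<tissue>|<replicate>' plus a tissue sidecar."""
    flat = atlas.values.copy()
    flat.columns = [f"{t}|{r}" for t, r in flat.columns]
    flat.to_csv(path)
    pd.DataFrame(
        {"tissue": atlas.tissues,
         "is_adipose": [t in atlas.adipose_tissues for t in atlas.tissues]}
    ).to_csv(sidecar_path, index=False)


def read_atlas(path, sidecar_path) -> TissueAtlas:
    flat = pd.read_csv(path, index_col=0)
    cols = pd.MultiIndex.from_tuples(
        [(c.rsplit("|", 1)[0], int(c.rsplit("|", 1)[1])) for c in flat.columns],
        names=["tissue", "replicate"],
    )
    flat.columns = cols
    side = pd.read_csv(sidecar_path)
    adipose = tuple(side.loc[side["is_adipose"], "tissue"])
    if len(adipose) != 2:
        raise ValueError("sidecar must mark exactly two adipose tissues")
    return TissueAtlas(values=flat, adipose_tissues=adipose)  # type: ignore[arg-type]
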