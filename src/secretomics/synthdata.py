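"""Synthetic inputs with known ground truth for every pipeline stage.

Three kinds of input are emulated, mirroring the structure of a
conditioned-medium (CM) secretome experiment on three adipocyte types:

* a MaxQuant-style protein-groups matrix: log-normal LFQ intensities with
  replicate noise, a planted fraction of proteins carrying cell-type-specific
  secretion shifts, QC-flagged rows (reverse hits / contaminants), and
  intensity-dependent (missing-not-at-random) dropout — low-abundance values
  are preferentially missing, which is what motivates left-shifted Gaussian
  imputation downstream;
* a tissue expression atlas (genes x tissues x replicates, log2 scale) with
  a planted set of adipose-enriched genes elevated in the two designated
  adipose tissues;
* a secretion-predictor score table (signal peptide, transmembrane count,
  non-classical score, GPI specificity, localization, GO cell-component
  terms) with planted secretion routes.

A configurable number of "adipokine" genes is planted across all three
artifacts (secreted into CM, adipose-enriched in the atlas, present in the
serum detection set) so the end-to-end candidate funnel has an exact oracle.

Each artifact draws from its own RNG stream derived from ``config.seed`` by
a fixed offset, so generating one artifact never perturbs another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .atlas import TissueAtlas
from .msio import IntensityMatrix
from .secretion import EXTRACELLULAR_TERMS

_CELL_TYPES = ("Visc", "SubQ", "Brown")

# fixed per-artifact RNG stream offsets
_STREAM_CM = 11
_STREAM_ATLAS = 23
_STREAM_ANNOT = 37
_STREAM_SERUM = 41


@dataclass
class SynthConfig:
    """Parameters of the synthetic study.

    Defaults emulate the real experiment's conditions: 742 detected
    proteins of which ~18.6% are flagged, 3 cell types x 3 replicates,
    an 88-tissue atlas (hence 86 pairwise comparisons per gene), planted
    adipose enrichment of 6 log2 units, and secretion-route prevalences of
    roughly 68% classical / 10% non-classical / 70% with an extracellular
    annotation term.
    """

    n_proteins: int = 742
    n_cell_types: int = 3
    n_replicates: int = 3
    frac_differential: float = 0.6
    effect_log2: float = 3.0
    base_mu: float = 25.0
    base_sigma: float = 2.0
    rep_sigma: float = 0.4
    missing_beta0: float = 23.0
    missing_beta1: float = 1.0
    frac_flagged: float = 0.186
    # atlas
    n_tissues: int = 88
    n_atlas_genes: int = 300
    n_atlas_replicates: int = 3
    n_adipose_genes: int = 20
    atlas_effect_log2: float = 6.0
    atlas_base_mu: float = 6.0
    atlas_base_sigma: float = 1.0
    atlas_rep_sigma: float = 0.3
    # secretion annotation table
    frac_classical: float = 0.68
    frac_nonclassical: float = 0.10
    frac_gpi: float = 0.03
    frac_extracellular_cc: float = 0.70
    # planted end-to-end candidates and serum detection
    n_adipokines: int = 5
    serum_frac_cm: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_proteins", "n_cell_types", "n_replicates",
                     "n_atlas_genes", "n_atlas_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("frac_differential", "frac_flagged", "frac_classical",
                     "frac_nonclassical", "frac_gpi", "frac_extracellular_cc",
                     "serum_frac_cm"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("effect_log2", "base_mu", "base_sigma", "rep_sigma",
                     "missing_beta0", "missing_beta1", "atlas_effect_log2",
                     "atlas_base_mu", "atlas_base_sigma", "atlas_rep_sigma"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.n_tissues < 3:
            raise ValueError("n_tissues must be >= 3 (two adipose + at least one other)")
        if self.n_adipokines > min(self.n_proteins, self.n_adipose_genes):
            raise ValueError("n_adipokines cannot exceed n_proteins or n_adipose_genes")
        if self.n_adipose_genes > self.n_atlas_genes:
            raise ValueError("n_adipose_genes cannot exceed n_atlas_genes")

    def to_dict(self) -> dict:
        return asdict(self)


def _rng(config: SynthConfig, offset: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([offset, config.seed]))


def _cell_type_names(n: int) -> list[str]:
    names = list(_CELL_TYPES[:n])
    names += [f"Type{i + 1}" for i in range(len(names), n)]
    return names


def _protein_ids(n: int) -> list[str]:
    return [f"P{i + 1:05d}" for i in range(n)]


def _gene_symbols(n: int) -> list[str]:
    return [f"G{i + 1:05d}" for i in range(n)]


def missing_probability(log2_intensity: np.ndarray, beta0: float, beta1: float) -> np.ndarray:
    """Logistic MNAR dropout: P(missing) = expit(beta0 - beta1 * log2 x)."""
    from scipy.special import expit

    return expit(beta0 - beta1 * np.asarray(log2_intensity, dtype=float))


def simulate_cm_matrix(config: SynthConfig) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Simulate the conditioned-medium protein-groups matrix.

    Returns the matrix (LFQ + iBAQ layers, flags, sample metadata) and a
    truth table with one row per protein: gene symbol, whether it is truly
    differential (and which cell type is shifted), the true per-cell-type
    log2 means, the QC-flag status, and whether it is a planted adipokine.
    """
    rng = _rng(config, _STREAM_CM)
    n, k, r = config.n_proteins, config.n_cell_types, config.n_replicates
    proteins = _protein_ids(n)
    genes = _gene_symbols(n)
    cell_types = _cell_type_names(k)
    adipokine = np.zeros(n, dtype=bool)
    adipokine[: config.n_adipokines] = True

    base = rng.normal(config.base_mu, config.base_sigma, size=n)
    # planted adipokines sit high in the abundance distribution so their
    # detection in CM is not at the mercy of dropout
    base[adipokine] = config.base_mu + 2.0 * config.base_sigma

    n_diff = int(round(config.frac_differential * n))
    diff_idx = rng.choice(n, size=n_diff, replace=False)
    differential = np.zeros(n, dtype=bool)
    differential[diff_idx] = True
    shifted_group = np.full(n, "", dtype=object)
    true_means = np.tile(base[:, None], (1, k))
    which = rng.integers(0, k, size=n_diff)
    for i, g in zip(diff_idx, which):
        true_means[i, g] += config.effect_log2
        shifted_group[i] = cell_types[g]

    # flags on a random subset, sparing planted adipokines
    flaggable = np.flatnonzero(~adipokine)
    n_flag = int(round(config.frac_flagged * n))
    n_flag = min(n_flag, flaggable.size)
    flag_idx = rng.choice(flaggable, size=n_flag, replace=False)
    reverse = np.zeros(n, dtype=bool)
    contaminant = np.zeros(n, dtype=bool)
    only_site = np.zeros(n, dtype=bool)
    which_flag = rng.integers(0, 3, size=n_flag)
    reverse[flag_idx[which_flag == 0]] = True
    contaminant[flag_idx[which_flag == 1]] = True
    only_site[flag_idx[which_flag == 2]] = True

    sample_names = [f"{ct}_{j + 1}" for ct in cell_types for j in range(r)]
    log2 = np.empty((n, k * r))
    for g in range(k):
        log2[:, g * r:(g + 1) * r] = rng.normal(
            true_means[:, g][:, None], config.rep_sigma, size=(n, r)
        )
    p_miss = missing_probability(log2, config.missing_beta0, config.missing_beta1)
    missing = rng.random(size=log2.shape) < p_miss

    lfq = np.exp2(log2)
    lfq[missing] = 0.0
    # iBAQ = LFQ scaled per protein by a log-normal factor (iBAQ divides by
    # theoretical peptide count, a per-protein constant)
    ibaq_scale = rng.lognormal(mean=0.0, sigma=1.0, size=n)
    ibaq = lfq * ibaq_scale[:, None]

    samples = pd.DataFrame(
        {"group": [ct for ct in cell_types for _ in range(r)],
         "replicate": [j + 1 for _ in cell_types for j in range(r)]},
        index=sample_names,
    )
    idx = pd.Index(proteins, name="protein")
    matrix = IntensityMatrix(
        lfq=pd.DataFrame(lfq, index=idx, columns=sample_names),
        ibaq=pd.DataFrame(ibaq, index=idx, columns=sample_names),
        samples=samples,
        flags=pd.DataFrame(
            {"reverse": reverse, "contaminant": contaminant, "only_by_site": only_site},
            index=idx,
        ),
        gene_symbols=pd.Series(genes, index=idx, name="gene"),
    )
    truth = pd.DataFrame(
        {"gene": genes, "differential": differential, "shifted_group": shifted_group,
         "flagged": reverse | contaminant | only_site, "adipokine": adipokine},
        index=idx,
    )
    for g, ct in enumerate(cell_types):
        truth[f"mean_{ct}"] = true_means[:, g]
    return matrix, truth


def _atlas_gene_table(config: SynthConfig) -> pd.DataFrame:
    """Gene roster of the atlas: planted adipokines, a slice of other CM
    genes, and atlas-only genes; marks which genes are adipose-planted."""
    cm_genes = _gene_symbols(config.n_proteins)
    adipokines = cm_genes[: config.n_adipokines]
    n_rest = config.n_atlas_genes - config.n_adipokines
    n_shared = min(n_rest // 2, config.n_proteins - config.n_adipokines)
    shared = cm_genes[config.n_adipokines: config.n_adipokines + n_shared]
    atlas_only = [f"A{i + 1:05d}" for i in range(n_rest - n_shared)]
    genes = adipokines + shared + atlas_only
    planted = np.zeros(len(genes), dtype=bool)
    if config.atlas_effect_log2 != 0:  # zero effect = nothing planted
        planted[: config.n_adipokines] = True
        # remaining planted adipose genes come from the atlas-only pool so
        # that adipose enrichment alone never creates a spurious candidate
        extra = config.n_adipose_genes - config.n_adipokines
        if extra > len(atlas_only):
            raise ValueError("not enough atlas-only genes for n_adipose_genes")
        start = config.n_adipokines + len(shared)
        planted[start: start + extra] = True
    return pd.DataFrame({"gene": genes, "planted": planted,
                         "adipokine": [g in adipokines for g in genes]})


def simulate_atlas(config: SynthConfig) -> tuple[TissueAtlas, pd.DataFrame]:
    """Simulate the tissue expression atlas.

    Genes x tissues x replicates log2 values; planted genes are elevated by
    ``atlas_effect_log2`` in the two designated adipose tissues; all other
    genes are exchangeable across tissues.  Returns the atlas and a truth
    table listing planted genes.
    """
    if config.n_tissues < 3:
        raise ValueError("n_tissues must be >= 3")
    rng = _rng(config, _STREAM_ATLAS)
    roster = _atlas_gene_table(config)
    genes = roster["gene"].tolist()
    n_genes = len(genes)
    adipose = ("Adipose_white", "Adipose_brown")
    tissues = list(adipose) + [f"Tissue{i + 1:02d}" for i in range(config.n_tissues - 2)]
    r = config.n_atlas_replicates

    base = rng.normal(config.atlas_base_mu, config.atlas_base_sigma, size=n_genes)
    means = np.tile(base[:, None], (1, config.n_tissues))
    planted = roster["planted"].to_numpy()
    means[planted, 0] += config.atlas_effect_log2
    means[planted, 1] += config.atlas_effect_log2

    cols = pd.MultiIndex.from_tuples(
        [(t, j + 1) for t in tissues for j in range(r)], names=["tissue", "replicate"]
    )
    vals = rng.normal(
        np.repeat(means, r, axis=1), config.atlas_rep_sigma, size=(n_genes, len(cols))
    )
    values = pd.DataFrame(vals, index=pd.Index(genes, name="gene"), columns=cols)
    atlas = TissueAtlas(values=values, adipose_tissues=adipose)
    truth = roster.set_index("gene")
    return atlas, truth


def simulate_annotations(config: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the secretion-predictor score table for the CM proteins.

    Each protein is assigned a true route (classical / non-classical / GPI /
    none) with the configured prevalences and its predictor scores are drawn
    on the correct side of the rule thresholds.  Returns the annotation
    table (indexed by protein) and a truth table with the assigned route.
    """
    rng = _rng(config, _STREAM_ANNOT)
    n = config.n_proteins
    proteins = _protein_ids(n)
    u = rng.random(n)
    route = np.full(n, "none", dtype=object)
    c1 = config.frac_classical
    c2 = c1 + config.frac_nonclassical
    c3 = c2 + config.frac_gpi
    route[u < c1] = "classical"
    route[(u >= c1) & (u < c2)] = "nonclassical"
    route[(u >= c2) & (u < c3)] = "gpi"
    # planted adipokines are classically secreted
    route[: config.n_adipokines] = "classical"

    signal = rng.uniform(0.0, 0.5, size=n)
    signal[route == "classical"] = rng.uniform(0.55, 1.0, size=(route == "classical").sum())
    tm = rng.integers(0, 2, size=n)  # 0 or 1
    tm[route == "none"] = rng.integers(0, 5, size=(route == "none").sum())
    nonclassical = rng.uniform(0.0, 0.6, size=n)
    mask = route == "nonclassical"
    nonclassical[mask] = rng.uniform(0.65, 1.0, size=mask.sum())
    gpi = rng.uniform(0.0, 99.0, size=n)
    mask = route == "gpi"
    gpi[mask] = rng.uniform(99.1, 100.0, size=mask.sum())

    secreted = route != "none"
    loc = np.where(
        secreted & (rng.random(n) < 0.8), "Extracellular",
        rng.choice(["Cytoplasm", "Nucleus", "Mitochondrion"], size=n),
    )
    ec_terms = sorted(EXTRACELLULAR_TERMS)
    other_terms = [5886, 5739, 5783, 5794, 5829, 5634]
    cc = []
    has_ec = rng.random(n) < config.frac_extracellular_cc
    for i in range(n):
        terms = set(rng.choice(other_terms, size=rng.integers(0, 3), replace=False).tolist())
        if has_ec[i]:
            terms.add(int(ec_terms[rng.integers(0, len(ec_terms))]))
        cc.append(frozenset(terms))
    idx = pd.Index(proteins, name="protein")
    table = pd.DataFrame(
        {"signal_peptide_score": signal, "tm_count": tm,
         "nonclassical_score": nonclassical, "gpi_specificity": gpi,
         "localization": loc, "cc_terms": cc},
        index=idx,
    )
    truth = pd.DataFrame({"route": route, "has_extracellular_term": has_ec}, index=idx)
    return table, truth


def simulate_serum_set(config: SynthConfig) -> set[str]:
    """Genes detected in the (nascent) serum proteome: all planted
    adipokines, a fraction of the other CM genes, and a handful of
    atlas-only genes (circulating proteins of non-adipose origin)."""
    rng = _rng(config, _STREAM_SERUM)
    cm_genes = _gene_symbols(config.n_proteins)
    serum = set(cm_genes[: config.n_adipokines])
    others = cm_genes[config.n_adipokines:]
    n_pick = int(round(config.serum_frac_cm * len(others)))
    serum.update(rng.choice(others, size=n_pick, replace=False).tolist())
    roster = _atlas_gene_table(config)
    nonplanted_atlas_only = roster.loc[
        ~roster["planted"] & ~roster["gene"].isin(cm_genes), "gene"
    ].tolist()
    if nonplanted_atlas_only:
        n_extra = min(10, len(nonplanted_atlas_only))
        serum.update(rng.choice(nonplanted_atlas_only, size=n_extra, replace=False).tolist())
    return serum
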