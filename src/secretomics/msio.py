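"""Reading and writing MaxQuant-dialect protein-groups tables.

The central container is :class:`IntensityMatrix`: a proteins x samples
matrix with two intensity layers (LFQ for across-sample comparison, iBAQ
for across-protein abundance), per-sample metadata (cell type or tissue,
replicate index) and the three standard MaxQuant QC flags (reverse-database
hit, potential contaminant, only identified by site).

Parsing and filtering are deliberately separate: :func:`read_protein_groups`
returns every row of the file with its flags, and :func:`exclude_flagged`
drops flagged rows as a second, explicit step.  Intensity 0 encodes
"not quantified" throughout, matching the MaxQuant convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

FLAG_COLUMNS = {
    "reverse": "Reverse",
    "contaminant": "Potential contaminant",
    "only_by_site": "Only identified by site",
}

_FLAG_TOKEN = "+"


@dataclass
class IntensityMatrix:
    """Proteins x samples intensity matrix with LFQ and iBAQ layers.

    Attributes
    ----------
    lfq, ibaq : pandas.DataFrame
        Same shape and row/column order; non-negative; 0 encodes missing.
        Index = protein IDs, columns = sample names.
    samples : pandas.DataFrame
        Indexed by sample name with columns ``group`` (cell type or tissue)
        and ``replicate``.
    flags : pandas.DataFrame
        Boolean columns ``reverse``, ``contaminant``, ``only_by_site``
        indexed like ``lfq``.
    gene_symbols : pandas.Series
        Gene symbol per protein (may repeat across protein groups).
    """

    lfq: pd.DataFrame
    ibaq: pd.DataFrame
    samples: pd.DataFrame
    flags: pd.DataFrame
    gene_symbols: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.gene_symbols is None:
            self.gene_symbols = pd.Series(self.lfq.index, index=self.lfq.index)
        if self.lfq.shape != self.ibaq.shape:
            raise ValueError("lfq and ibaq layers must share shape")
        if not self.lfq.index.equals(self.ibaq.index):
            raise ValueError("lfq and ibaq layers must share row order")
        if self.lfq.index.has_duplicates:
            dupes = self.lfq.index[self.lfq.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate protein ids: {dupes}")
        if self.lfq.columns.has_duplicates:
            raise ValueError("duplicate sample names")
        if (self.lfq.to_numpy() < 0).any() or (self.ibaq.to_numpy() < 0).any():
            raise ValueError("intensities must be non-negative")

    @property
    def protein_ids(self) -> pd.Index:
        return self.lfq.index

    @property
    def n_proteins(self) -> int:
        return self.lfq.shape[0]

    @property
    def sample_names(self) -> list[str]:
        return list(self.lfq.columns)

    def groups(self) -> dict[str, list[str]]:
        """Sample names keyed by group label, in sample order."""
        out: dict[str, list[str]] = {}
        for name, row in self.samples.iterrows():
            out.setdefault(row["group"], []).append(name)
        return out

    def subset(self, protein_ids) -> "IntensityMatrix":
        """Row subset preserving the given order."""
        idx = pd.Index(protein_ids)
        return replace(
            self,
            lfq=self.lfq.loc[idx],
            ibaq=self.ibaq.loc[idx],
            flags=self.flags.loc[idx],
            gene_symbols=self.gene_symbols.loc[idx],
        )


def _normalize_sample_map(sample_map) -> pd.DataFrame:
    """Accept a DataFrame or a mapping sample -> (group, replicate)."""
    if isinstance(sample_map, pd.DataFrame):
        df = sample_map.copy()
        if not {"group", "replicate"}.issubset(df.columns):
            raise ValueError("sample_map needs 'group' and 'replicate' columns")
        return df[["group", "replicate"]]
    rows = {name: {"group": g, "replicate": r} for name, (g, r) in sample_map.items()}
    return pd.DataFrame.from_dict(rows, orient="index")


def read_protein_groups(path, sample_map) -> IntensityMatrix:
    """Parse a tab-separated protein-groups table.

    ``sample_map`` declares the samples (name -> (group, replicate) mapping
    or an equivalent DataFrame); each declared sample must have an
    ``LFQ intensity <name>`` and an ``iBAQ <name>`` column.  Flagged rows
    are parsed, not dropped.  Empty intensity cells decode to 0 (missing).
    """
    samples = _normalize_sample_map(sample_map)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "Protein IDs" not in df.columns:
        raise ValueError("missing 'Protein IDs' column")
    ids = pd.Index(df["Protein IDs"], name="protein")
    if ids.has_duplicates:
        dupes = ids[ids.duplicated()].unique().tolist()
        raise ValueError(f"duplicate protein ids in {path}: {dupes}")

    def intensity_layer(prefix: str) -> pd.DataFrame:
        cols = {}
        for name in samples.index:
            col = f"{prefix} {name}"
            if col not in df.columns:
                raise ValueError(f"missing intensity column '{col}'")
            vals = pd.to_numeric(df[col].replace("", "0"))
            cols[name] = vals.to_numpy(dtype=float)
        return pd.DataFrame(cols, index=ids)

    flags = pd.DataFrame(
        {key: (df[col] == _FLAG_TOKEN).to_numpy() if col in df.columns
         else np.zeros(len(df), dtype=bool)
         for key, col in FLAG_COLUMNS.items()},
        index=ids,
    )
    genes = pd.Series(
        df["Gene names"].to_numpy() if "Gene names" in df.columns else ids,
        index=ids, name="gene",
    )
    return IntensityMatrix(
        lfq=intensity_layer("LFQ intensity"),
        ibaq=intensity_layer("iBAQ"),
        samples=samples,
        flags=flags,
        gene_symbols=genes,
    )


def write_protein_groups(m: IntensityMatrix, path) -> None:
    """Write the MaxQuant-dialect TSV that :func:`read_protein_groups` reads."""
    out = pd.DataFrame({"Protein IDs": m.protein_ids, "Gene names": m.gene_symbols.to_numpy()})
    for key, col in FLAG_COLUMNS.items():
        out[col] = np.where(m.flags[key].to_numpy(), _FLAG_TOKEN, "")
    for name in m.sample_names:
        out[f"LFQ intensity {name}"] = m.lfq[name].to_numpy()
    for name in m.sample_names:
        out[f"iBAQ {name}"] = m.ibaq[name].to_numpy()
    out.to_csv(path, sep="\t", index=False)


def exclude_flagged(m: IntensityMatrix) -> IntensityMatrix:
    """Drop proteins flagged as reverse, contaminant or only-by-site.

    The union of the three flags is removed (the convention stated for the
    Perseus-style analysis); row order of the survivors is preserved.
    """
    keep = ~m.flags.any(axis=1)
    return m.subset(m.protein_ids[keep.to_numpy()])


def sum_ibaq(m: IntensityMatrix) -> pd.Series:
    """Per-sample total iBAQ intensity (sigma-iBAQ, a proxy for total
    protein moles detected); missing values contribute 0."""
    return m.ibaq.sum(axis=0)


def to_tidy(m: IntensityMatrix) -> pd.DataFrame:
    """Long-format export: one row per (protein, sample, layer)."""
    frames = []
    for layer, df in (("lfq", m.lfq), ("ibaq", m.ibaq)):
        t = df.stack().rename("intensity").reset_index()
        t.columns = ["protein", "sample", "intensity"]
        t.insert(2, "layer", layer)
        frames.append(t)
    tidy = pd.concat(frames, ignore_index=True)
    tidy["group"] = tidy["sample"].map(m.samples["group"])
    tidy["replicate"] = tidy["sample"].map(m.samples["replicate"])
    return tidy
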