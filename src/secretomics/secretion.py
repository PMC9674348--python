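"""Rule-based secretion-route classification and cell-component tallies.

Proteins are classified from pre-computed predictor scores (the predictors
themselves — signal-peptide, transmembrane-topology, non-classical-secretion
and GPI-anchor tools — are consumed as a score table, never run here):

* classical (ER/Golgi) secretion: signal-peptide score > 0.5 and at most
  one predicted transmembrane segment;
* non-classical secretion: non-classical score > 0.6 and signal-peptide
  score <= 0.5 (so classical and non-classical are mutually exclusive by
  construction);
* GPI-anchored: GPI specificity > 99%;
* predicted extracellular localization (case-insensitive label match).

All inequalities are strict exactly as stated above.  A missing predictor
value contributes False rather than an error, because real predictor tables
have dropouts; :func:`completeness_report` summarizes them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: GO cell-component term ids treated as "extracellular": extracellular
#: region (5576), extracellular space (5615), extracellular matrix (31012).
EXTRACELLULAR_TERMS = frozenset({5576, 5615, 31012})

#: Display categories for the cell-component tally.
DEFAULT_CC_CATEGORIES: dict[str, frozenset[int]] = {
    "Extracellular": EXTRACELLULAR_TERMS,
    "PM": frozenset({5886}),
    "Mito": frozenset({5739}),
    "ER": frozenset({5783}),
    "Golgi": frozenset({5794}),
    "Cytosol": frozenset({5829}),
    "Nucleus": frozenset({5634}),
}

SIGNAL_THRESHOLD = 0.5
NONCLASSICAL_THRESHOLD = 0.6
GPI_THRESHOLD = 99.0
MAX_TM_FOR_CLASSICAL = 1


@dataclass(frozen=True)
class SecretionAnnotation:
    """Predictor scores and annotations for one protein.

    ``None`` marks a predictor with no output for this protein.
    """

    signal_peptide_score: float | None = None
    tm_count: int | None = None
    nonclassical_score: float | None = None
    gpi_specificity: float | None = None
    localization: str | None = None
    cc_terms: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("signal_peptide_score", 0.0, 1.0),
            ("nonclassical_score", 0.0, 1.0),
            ("gpi_specificity", 0.0, 100.0),
        ):
            v = getattr(self, name)
            if v is not None and not (math.isnan(v) or lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.tm_count is not None and self.tm_count < 0:
            raise ValueError("tm_count must be non-negative")


@dataclass(frozen=True)
class SecretionVerdict:
    classical: bool
    nonclassical: bool
    gpi: bool
    extracellular_predicted: bool

    @property
    def any_criterion(self) -> bool:
        return self.classical or self.nonclassical or self.gpi or self.extracellular_predicted


def _present(v) -> bool:
    if v is None:
        return False
    if isinstance(v, float) and math.isnan(v):
        return False
    return True


def classify_secretion(a: SecretionAnnotation) -> SecretionVerdict:
    """Apply the four secretion rules to one protein's annotation."""
    sig_present = _present(a.signal_peptide_score)
    sig = a.signal_peptide_score if sig_present else None
    classical = (
        sig_present
        and sig > SIGNAL_THRESHOLD
        and _present(a.tm_count)
        and a.tm_count <= MAX_TM_FOR_CLASSICAL
    )
    # a protein with no signal-peptide prediction cannot be asserted to
    # satisfy "signal score <= 0.5", so it is not called non-classical
    nonclassical = (
        _present(a.nonclassical_score)
        and a.nonclassical_score > NONCLASSICAL_THRESHOLD
        and sig_present
        and sig <= SIGNAL_THRESHOLD
    )
    gpi = _present(a.gpi_specificity) and a.gpi_specificity > GPI_THRESHOLD
    extracellular = (
        _present(a.localization) and str(a.localization).lower() == "extracellular"
    )
    return SecretionVerdict(classical, nonclassical, gpi, extracellular)


def classify_table(annotations: pd.DataFrame) -> pd.DataFrame:
    """Vectorized :func:`classify_secretion` over an annotation table.

    Expects columns ``signal_peptide_score``, ``tm_count``,
    ``nonclassical_score``, ``gpi_specificity``, ``localization``
    (``cc_terms`` is carried by the table but not used here).  Returns a
    boolean DataFrame with the four criteria plus ``any_criterion``.
    """
    sig = pd.to_numeric(annotations["signal_peptide_score"], errors="coerce")
    nc = pd.to_numeric(annotations["nonclassical_score"], errors="coerce")
    gpi = pd.to_numeric(annotations["gpi_specificity"], errors="coerce")
    tm = pd.to_numeric(annotations["tm_count"], errors="coerce")
    for name, s, lo, hi in (
        ("signal_peptide_score", sig, 0.0, 1.0),
        ("nonclassical_score", nc, 0.0, 1.0),
        ("gpi_specificity", gpi, 0.0, 100.0),
    ):
        bad = s.dropna()
        bad = bad[(bad < lo) | (bad > hi)]
        if len(bad):
            raise ValueError(f"{name} outside [{lo}, {hi}] for {bad.index.tolist()[:5]}")
    loc = annotations["localization"].astype("string").str.lower()

    classical = (sig > SIGNAL_THRESHOLD) & (tm <= MAX_TM_FOR_CLASSICAL)
    nonclassical = (nc > NONCLASSICAL_THRESHOLD) & (sig <= SIGNAL_THRESHOLD)
    gpi_v = gpi > GPI_THRESHOLD
    extracellular = loc == "extracellular"
    out = pd.DataFrame(
        {
            "classical": classical.fillna(False),
            "nonclassical": nonclassical.fillna(False),
            "gpi": gpi_v.fillna(False),
            "extracellular_predicted": extracellular.fillna(False).astype(bool),
        },
        index=annotations.index,
    )
    out["any_criterion"] = out.any(axis=1)
    return out


def completeness_report(annotations: pd.DataFrame) -> pd.Series:
    """Fraction of proteins with a usable value per predictor field."""
    fields = ["signal_peptide_score", "tm_count", "nonclassical_score",
              "gpi_specificity", "localization"]
    return pd.Series(
        {f: float(annotations[f].notna().mean()) for f in fields}, name="completeness"
    )


def tally_cell_component(
    cc_terms: pd.Series,
    category_map: dict[str, frozenset[int]] | None = None,
) -> pd.DataFrame:
    """Count proteins per cell-component display category.

    ``cc_terms`` holds one set of integer GO term ids per protein.  A
    protein counts in every category for which it carries at least one
    term (categories overlap); term ids outside the map are skipped with
    a warning.  Returns counts and fractions of the total protein number.
    """
    if category_map is None:
        category_map = DEFAULT_CC_CATEGORIES
    known = set().union(*category_map.values()) if category_map else set()
    n = len(cc_terms)
    counts = {cat: 0 for cat in category_map}
    unknown: set[int] = set()
    for terms in cc_terms:
        terms = set(terms)
        unknown |= terms - known
        for cat, cat_terms in category_map.items():
            if terms & cat_terms:
                counts[cat] += 1
    if unknown:
        warnings.warn(f"skipping {len(unknown)} unmapped term ids", stacklevel=2)
    out = pd.DataFrame({"count": pd.Series(counts)})
    out["fraction"] = out["count"] / n if n else np.nan
    out.index.name = "category"
    return out


def parse_terms(joined: str) -> frozenset[int]:
    """Decode a semicolon-joined term-id string (the TSV dialect)."""
    if not joined or (isinstance(joined, float) and math.isnan(joined)):
        return frozenset()
    return frozenset(int(t) for t in str(joined).split(";") if t.strip())


def read_annotation_table(path) -> pd.DataFrame:
    """Read the TSV annotation dialect (protein id + five predictor fields
    + semicolon-joined cc term ids)."""
    df = pd.read_csv(path, sep="\t", index_col="protein")
    df["cc_terms"] = [parse_terms(v) for v in df.get("cc_terms", "")]
    return df


def write_annotation_table(annotations: pd.DataFrame, path) -> None:
    out = annotations.copy()
    out["cc_terms"] = [";".join(str(t) for t in sorted(terms)) for terms in out["cc_terms"]]
    out.to_csv(path, sep="\t")
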