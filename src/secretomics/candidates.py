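"""The candidate-adipokine funnel: intersect three lines of evidence.

A gene is nominated as a candidate adipokine when it is (1) detected in
adipocyte conditioned medium, (2) adipose-tissue enriched with a score
strictly above the threshold (default 80%), and (3) present in the serum
proteome.  Identifiers are gene symbols, joined case-insensitively.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

DEFAULT_SCORE_THRESHOLD = 80.0


def _normalize(genes: Iterable[str]) -> dict[str, str]:
    """Case-fold keys -> original symbol; error on collisions."""
    out: dict[str, str] = {}
    collisions = []
    for g in genes:
        key = str(g).casefold()
        if key in out and out[key] != g:
            collisions.append((out[key], g))
        out[key] = g
    if collisions:
        raise ValueError(f"gene symbols collide after case-normalization: {collisions}")
    return out


def build_candidates(
    cm_detected: Iterable[str],
    scores: Mapping[str, float] | pd.Series | pd.DataFrame,
    serum_detected: Iterable[str],
    threshold: float = DEFAULT_SCORE_THRESHOLD,
) -> pd.DataFrame:
    """Intersect CM detection, enrichment score and serum detection.

    ``scores`` maps gene -> enrichment score in percent (a DataFrame with a
    ``score_percent`` column is also accepted).  The report covers the
    union of all input genes, ordered alphabetically; a gene with no score
    fails the score criterion.  The threshold comparison is strict (>).
    """
    if isinstance(scores, pd.DataFrame):
        scores = scores["score_percent"]
    score_map = dict(pd.Series(scores).items())

    cm_norm = _normalize(cm_detected)
    serum_norm = _normalize(serum_detected)
    score_norm = _normalize(score_map)

    universe: dict[str, str] = {}
    for m in (cm_norm, score_norm, serum_norm):
        for key, orig in m.items():
            universe.setdefault(key, orig)

    rows = []
    for key in sorted(universe):
        gene = universe[key]
        in_cm = key in cm_norm
        score = float(score_map[score_norm[key]]) if key in score_norm else float("nan")
        score_pass = key in score_norm and score > threshold
        in_serum = key in serum_norm
        rows.append(
            {"gene": gene, "in_cm": in_cm, "enrichment_score": score,
             "score_pass": score_pass, "in_serum": in_serum,
             "candidate": in_cm and score_pass and in_serum}
        )
    return pd.DataFrame(rows).set_index("gene")


def candidate_genes(report: pd.DataFrame) -> list[str]:
    return report.index[report["candidate"]].tolist()


def summary(report: pd.DataFrame) -> dict:
    """Funnel counts for the run manifest / JSON export."""
    return {
        "n_cm": int(report["in_cm"].sum()),
        "n_score_pass": int(report["score_pass"].sum()),
        "n_serum": int(report["in_serum"].sum()),
        "n_cm_and_score": int((report["in_cm"] & report["score_pass"]).sum()),
        "n_candidates": int(report["candidate"].sum()),
        "candidates": candidate_genes(report),
    }
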