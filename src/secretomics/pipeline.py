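"""End-to-end orchestration: simulate -> parse -> filter -> impute ->
test -> cluster -> classify -> score -> intersect.

Stages hand files to each other on disk (auditable, independently
re-runnable) and a JSON manifest records seeds, parameters and per-stage
row counts.  A fixed configuration yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import atlas as atlas_mod
from . import candidates as cand_mod
from . import clusterprofile, msio, quantstats, secretion, synthdata

log = logging.getLogger("secretomics")


@dataclass
class RunConfig:
    """Everything a full synthetic run needs, with one master seed.

    Stage seeds are derived from ``seed`` by fixed offsets so stages stay
    decoupled; every stochastic stage is reproducible from this one value.
    """

    synth: synthdata.SynthConfig = field(default_factory=synthdata.SynthConfig)
    min_detected: int = 2
    impute_width: float = 0.3
    impute_downshift: float = 1.8
    n_permutations: int = 250
    q_threshold: float = 0.01
    cluster_k: int = 4
    atlas_mode: str = "combined"
    fc_threshold: float = 4.0
    atlas_fdr: float = 0.05
    candidate_threshold: float = 80.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.synth.seed != self.seed:
            self.synth = dataclasses.replace(self.synth, seed=self.seed)

    @property
    def impute_seed(self) -> int:
        return self.seed + 1

    @property
    def anova_seed(self) -> int:
        return self.seed + 2

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        synth = d.pop("synth", {})
        cfg = cls(**d)
        cfg.synth = synthdata.SynthConfig(**{**synth, "seed": cfg.seed})
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _param_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute every stage on synthetic inputs; return the run manifest.

    A stage failure halts the run with the failing stage named; outputs
    written so far are kept and the partial manifest is saved with a
    ``.partial`` suffix.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "secretomics",
        "config": config.to_dict(),
        "param_hash": _param_hash(config),
        "seeds": {"master": config.seed, "impute": config.impute_seed,
                  "anova": config.anova_seed},
        "counts": {},
        "stages": [],
    }
    counts = manifest["counts"]
    stage = "start"
    try:
        stage = "simulate"
        cm, cm_truth = synthdata.simulate_cm_matrix(config.synth)
        msio.write_protein_groups(cm, outdir / "protein_groups.tsv")
        cm_truth.to_csv(outdir / "cm_truth.csv")
        manifest["stages"].append(stage)

        stage = "parse"
        parsed = msio.read_protein_groups(outdir / "protein_groups.tsv", cm.samples)
        counts["parsed"] = parsed.n_proteins
        log.info("parsed %d proteins", parsed.n_proteins)
        manifest["stages"].append(stage)

        stage = "exclude_flagged"
        retained = msio.exclude_flagged(parsed)
        counts["excluded"] = parsed.n_proteins - retained.n_proteins
        counts["retained"] = retained.n_proteins
        log.info("excluded %d flagged rows, %d retained",
                 counts["excluded"], counts["retained"])
        manifest["stages"].append(stage)

        stage = "filter"
        spec = quantstats.DetectionFilterSpec(
            min_detected=config.min_detected,
            per_group_size=config.synth.n_replicates,
        )
        filtered = quantstats.filter_detected(retained, spec)
        counts["filtered"] = filtered.n_proteins
        log.info("%d proteins detected in >=%d replicates of some cell type",
                 filtered.n_proteins, config.min_detected)
        manifest["stages"].append(stage)

        stage = "impute"
        logm = quantstats.log2_transform(filtered)
        complete = quantstats.impute_left_gaussian(
            logm, quantstats.ImputeSpec(
                width=config.impute_width, downshift=config.impute_downshift,
                seed=config.impute_seed,
            ),
        )
        complete.to_csv(outdir / "imputed_log2_lfq.csv")
        manifest["stages"].append(stage)

        stage = "anova"
        anova = quantstats.permutation_fdr_anova(
            complete, filtered.samples["group"],
            n_perm=config.n_permutations, q_threshold=config.q_threshold,
            seed=config.anova_seed,
        )
        anova.table.to_csv(outdir / "anova.csv")
        counts["significant"] = anova.n_significant
        log.info("%d proteins significant at q<%g",
                 anova.n_significant, config.q_threshold)
        manifest["stages"].append(stage)

        stage = "cluster"
        sig = anova.significant_proteins
        if len(sig) >= config.cluster_k:
            z = clusterprofile.zscore_rows(complete.loc[sig])
            first_group = filtered.samples["group"].iloc[0]
            order_cols = list(
                filtered.samples.index[filtered.samples["group"] == first_group]
            )
            assignment = clusterprofile.hierarchical_cluster(
                z, k=config.cluster_k, order_by=order_cols
            )
            table = clusterprofile.cluster_table(filtered.subset(sig), assignment)
            table.to_csv(outdir / "clusters.csv")
            counts["clusters"] = {int(k): int(v) for k, v in assignment.sizes().items()}
        else:
            counts["clusters"] = {}
        manifest["stages"].append(stage)

        stage = "secretion"
        annot, annot_truth = synthdata.simulate_annotations(config.synth)
        secretion.write_annotation_table(annot, outdir / "secretion_annotations.tsv")
        annot_truth.to_csv(outdir / "secretion_truth.csv")
        detected_annot = annot.loc[retained.protein_ids]
        verdicts = secretion.classify_table(detected_annot)
        verdicts.to_csv(outdir / "secretion_verdicts.csv")
        tally = secretion.tally_cell_component(detected_annot["cc_terms"])
        tally.to_csv(outdir / "cc_tally.csv")
        counts["predicted_secreted"] = int(verdicts["any_criterion"].sum())
        manifest["stages"].append(stage)

        stage = "atlas_score"
        tissue_atlas, atlas_truth = synthdata.simulate_atlas(config.synth)
        atlas_mod.write_atlas(
            tissue_atlas, outdir / "atlas.csv", outdir / "atlas_tissues.csv"
        )
        atlas_truth.to_csv(outdir / "atlas_truth.csv")
        scores = atlas_mod.enrichment_scores(
            tissue_atlas, mode=config.atlas_mode,
            fc_threshold=config.fc_threshold, fdr=config.atlas_fdr,
        )
        scores.to_csv(outdir / "enrichment_scores.csv")
        counts["score_pass"] = int(
            (scores["score_percent"] > config.candidate_threshold).sum()
        )
        manifest["stages"].append(stage)

        stage = "candidates"
        serum = synthdata.simulate_serum_set(config.synth)
        cm_genes = filtered.gene_symbols.unique().tolist()
        report = cand_mod.build_candidates(
            cm_genes, scores, serum, threshold=config.candidate_threshold
        )
        report.to_csv(outdir / "candidates.csv")
        funnel = cand_mod.summary(report)
        counts["candidates"] = funnel["n_candidates"]
        manifest["funnel"] = funnel
        log.info("funnel: %d CM ^ %d score-pass ^ %d serum -> %d candidates",
                 funnel["n_cm"], funnel["n_score_pass"], funnel["n_serum"],
                 funnel["n_candidates"])
        manifest["stages"].append(stage)
    except Exception as exc:
        (outdir / "manifest.json.partial").write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        )
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
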