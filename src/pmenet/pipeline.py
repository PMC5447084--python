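"""End-to-end pipeline orchestration with a reproducible run manifest.

A run is described by a :class:`PipelineConfig` (typically loaded from a
YAML file): which stages to execute (simulate, preprocess, diversity,
pmen, conet), their parameters, and a single global seed from which every
stage derives its own independent substream. Each run writes a manifest
recording parameters, seeds, and the SHA-256 checksum of every output
file, so identical configs reproduce identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from pmenet import diversity as div
from pmenet import ensemble, pmen, preprocess, synthetic, tables

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "diversity", "pmen", "conet")


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


@dataclass
class PipelineConfig:
    output_dir: str = "pmenet_run"
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    seed: int = 0
    # inputs (ignored when the simulate stage is enabled, which generates them)
    counts_path: str | None = None
    geochip_path: str | None = None
    metadata_path: str | None = None
    annotation_path: str | None = None
    # stage parameters
    simulate: dict = field(default_factory=dict)
    rarefaction_depth: int | None = None
    min_occurrence: int = 4
    snr_threshold: float = 2.0
    pmen_threshold: float | None = None
    pmen_transform: str = "log_relative"
    group_by: str | None = "layer"
    n_perm: int = 100
    n_boot: int = 100
    min_support: int = 2
    min_coeff: float = 0.8
    alpha: float = 0.05
    fdr: bool = False

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be a non-negative integer")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        if "simulate" not in self.stages:
            for stage, attr in (("preprocess", "counts_path"), ("pmen", "counts_path")):
                if stage in self.stages and getattr(self, attr) is None:
                    raise ValueError(f"stage {stage!r} needs {attr} when not simulating")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and return the run manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": asdict(config), "stages": {}, "outputs": {}}

    def record(name: str, path: Path) -> None:
        manifest["outputs"][str(path.relative_to(out))] = _sha256(path)

    counts = geochip = None
    truth = None
    try:
        if "simulate" in config.stages:
            cfg = synthetic.SyntheticConfig(
                **{**config.simulate, "seed": _stage_seed(config.seed, "simulate")}
            )
            study = synthetic.generate_study(cfg)
            counts, geochip, truth = study["counts"], study["geochip"], study["truth"]
            tables.write_feature_table(counts, out / "counts.tsv")
            tables.write_feature_table(geochip, out / "geochip.tsv")
            study["metadata"].to_csv(out / "sample_metadata.tsv", sep="\t")
            truth.to_json(out / "truth.json")
            for f in ("counts.tsv", "geochip.tsv", "sample_metadata.tsv", "truth.json"):
                record("simulate", out / f)
            manifest["stages"]["simulate"] = {"n_samples": cfg.n_samples, "n_taxa": cfg.n_taxa}
        else:
            if config.counts_path:
                counts = tables.read_feature_table(
                    config.counts_path,
                    annotation_path=config.annotation_path,
                    metadata_path=config.metadata_path,
                )
            if config.geochip_path:
                geochip = tables.read_feature_table(
                    config.geochip_path, metadata_path=config.metadata_path
                )

        if "preprocess" in config.stages:
            if counts is None:
                raise StageError("preprocess: no count table available")
            if config.rarefaction_depth:
                counts = preprocess.rarefy(
                    counts, config.rarefaction_depth, seed=_stage_seed(config.seed, "rarefy")
                )
            counts = preprocess.prevalence_filter(counts, config.min_occurrence)
            if geochip is not None:
                geochip = preprocess.lnmr_normalize(geochip)
            tables.write_feature_table(counts, out / "counts.preprocessed.tsv")
            record("preprocess", out / "counts.preprocessed.tsv")
            if geochip is not None:
                tables.write_feature_table(geochip, out / "geochip.lnmr.tsv")
                record("preprocess", out / "geochip.lnmr.tsv")
            manifest["stages"]["preprocess"] = {
                "n_features": counts.n_features, "n_samples": counts.n_samples
            }

        if "diversity" in config.stages:
            if counts is None:
                raise StageError("diversity: no count table available")
            alpha_df = div.alpha_diversity(counts)
            alpha_df.to_csv(out / "alpha_diversity.tsv", sep="\t")
            record("diversity", out / "alpha_diversity.tsv")
            manifest["stages"]["diversity"] = {"n_samples": len(alpha_df)}

        if "pmen" in config.stages:
            if counts is None:
                raise StageError("pmen: no count table available")
            groups = {"all": counts.sample_ids}
            meta = counts.sample_metadata
            if config.group_by and meta is not None and config.group_by in meta.columns:
                groups = {
                    str(level): list(meta.index[meta[config.group_by] == level])
                    for level in sorted(meta[config.group_by].unique())
                }
            summaries = []
            for name, sample_ids in groups.items():
                sub = preprocess.prevalence_filter(
                    counts, config.min_occurrence, sample_ids=sample_ids
                )
                net = pmen.build_pmen(
                    sub,
                    threshold=config.pmen_threshold,
                    transform=config.pmen_transform,
                    seed=_stage_seed(config.seed, f"pmen:{name}"),
                )
                tables.export_network(net.graph, out / f"pmen.{name}.graphml")
                record("pmen", out / f"pmen.{name}.graphml")
                net.roles.to_csv(out / f"pmen.{name}.roles.tsv", sep="\t")
                record("pmen", out / f"pmen.{name}.roles.tsv")
                summaries.append({"group": name} | net.summary())
            pd.DataFrame(summaries).to_csv(out / "pmen.summary.tsv", sep="\t", index=False)
            record("pmen", out / "pmen.summary.tsv")
            manifest["stages"]["pmen"] = {"groups": list(groups)}

        if "conet" in config.stages:
            if counts is None or geochip is None:
                raise StageError("conet: needs both a count table and an array table")
            res = ensemble.ensemble_network(
                counts,
                geochip,
                n_perm=config.n_perm,
                n_boot=config.n_boot,
                min_support=config.min_support,
                min_coeff=config.min_coeff,
                alpha=config.alpha,
                fdr=config.fdr,
                seed=_stage_seed(config.seed, "conet"),
            )
            res.edges.to_csv(out / "conet.edges.tsv", sep="\t")
            record("conet", out / "conet.edges.tsv")
            tables.export_network(res.graph, out / "conet.graphml")
            record("conet", out / "conet.graphml")
            pd.DataFrame([res.summary]).to_csv(out / "conet.summary.tsv", sep="\t", index=False)
            record("conet", out / "conet.summary.tsv")
            manifest["stages"]["conet"] = res.summary
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - name the failing stage
        raise StageError(f"pipeline failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
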