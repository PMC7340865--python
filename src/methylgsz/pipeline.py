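"""End-to-end pipeline: preprocess -> EWAS -> gene scores -> GSZ -> regions.

One master seed deterministically derives per-stage seeds, so a fixed
configuration reproduces byte-identical stage outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dataset import DataError, MethylationDataset
from .ewas import EwasModel, ModelSpec
from .genescore import gene_proxy_scores, map_probes_to_genes
from .genesets import GeneSetCollection
from .gsz import GeneSetZTest, GszParams
from .preprocess import control_probe_pcs, filter_probes, read_blacklist
from .regions import region_analysis
from .synthdata import SynthConfig, generate_dataset, generate_genesets

logger = logging.getLogger(__name__)


def derive_seed(master: int, stage: str) -> int:
    """Stage seed derived deterministically from the master seed.

    Uses a CRC of the stage name (process-stable, unlike ``hash``).
    """
    import zlib

    ss = np.random.SeedSequence([master, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Declarative configuration of one pipeline run.

    Either point the input paths at files on disk or leave them None to run
    on freshly generated synthetic data (``synth``).
    """

    out_dir: str = "methylgsz_out"
    beta_path: str | None = None
    annotation_path: str | None = None
    sample_sheet_path: str | None = None
    control_path: str | None = None
    detection_p_path: str | None = None
    crossreactive_path: str | None = None
    snp_affected_path: str | None = None
    gmt_path: str | None = None
    models: tuple = ("model1",)
    gsz: GszParams = field(default_factory=GszParams)
    synth: SynthConfig | None = None
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "gsz" in raw:
            raw["gsz"] = GszParams(**raw["gsz"])
        if "synth" in raw and raw["synth"] is not None:
            raw["synth"] = SynthConfig(**raw["synth"])
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(**raw)


def _model_spec(name: str) -> ModelSpec:
    if name == "model1":
        return ModelSpec.model1()
    if name == "model2":
        return ModelSpec.model2()
    raise DataError(f"unknown model name {name!r}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns (and writes) the run manifest.

    Stage order: load-or-simulate, probe filtering, control-probe PCs,
    per-CpG EWAS (each requested model), gene proxy scores, gene set
    Z-score analysis, region analysis. Any stage failure raises with the
    stage name attached.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}
    stage = "load"
    try:
        control = None
        if config.beta_path is not None:
            ds = MethylationDataset.from_files(
                config.beta_path, config.annotation_path, config.sample_sheet_path)
            if config.control_path:
                control = pd.read_csv(config.control_path, sep="\t", index_col=0)
            gmt = (GeneSetCollection.read_gmt(config.gmt_path)
                   if config.gmt_path else None)
            if gmt is None:
                raise DataError("a GMT file is required when running on file inputs")
        else:
            synth = config.synth or SynthConfig()
            synth = synth.replace(seed=derive_seed(config.seed, "simulate"))
            ds, control, truth = generate_dataset(synth)
            gmt = generate_genesets(synth, ds.annotation)
            truth.write_tsv(out / "ground_truth.tsv")
            gmt.write_gmt(out / "gene_sets.gmt")
        manifest["stages"][stage] = {"n_probes": ds.n_probes, "n_samples": ds.n_samples}

        stage = "preprocess"
        detp = (pd.read_csv(config.detection_p_path, sep="\t", index_col=0)
                if config.detection_p_path else None)
        crossreactive = (read_blacklist(config.crossreactive_path)
                         if config.crossreactive_path else [])
        snp_affected = (read_blacklist(config.snp_affected_path)
                        if config.snp_affected_path else [])
        ds, report = filter_probes(ds, detp, crossreactive, snp_affected)
        pcs = control_probe_pcs(control) if control is not None else None
        manifest["stages"][stage] = {"filter_report": report.as_dict()}

        ewas_results = {}
        for model_name in config.models:
            stage = f"ewas_{model_name}"
            res = EwasModel(ds, _model_spec(model_name), pcs).fit()
            res.to_tsv(out / f"ewas_{model_name}.tsv")
            ewas_results[model_name] = res
            manifest["stages"][stage] = {
                "n_probes": len(res.table),
                "n_used": int(res.table["n_used"].iloc[0]),
                "n_fdr05": res.n_significant(),
                "genomic_lambda": round(res.genomic_lambda(), 4),
            }
        if "model1" in ewas_results and "model2" in ewas_results:
            h1 = set(ewas_results["model1"].table.query("q < 0.05").index)
            h2 = set(ewas_results["model2"].table.query("q < 0.05").index)
            manifest["stages"]["model_overlap"] = {
                "model1_hits": len(h1), "model2_hits": len(h2),
                "overlap": len(h1 & h2),
            }

        stage = "genescore"
        primary = ewas_results[config.models[0]]
        gene_map = map_probes_to_genes(ds.annotation)
        scores = gene_proxy_scores(primary.table, gene_map)
        scores.to_csv(out / "gene_scores.tsv", sep="\t")
        manifest["stages"][stage] = {"n_genes": len(scores)}

        stage = "gsz"
        params = GszParams(**{**config.gsz.__dict__,
                              "seed": derive_seed(config.seed, "gsz")})
        gsz_res = GeneSetZTest(scores, gmt, params).fit()
        gsz_res.to_tsv(out / "gsz_results.tsv")
        manifest["stages"][stage] = {
            "n_sets": len(gsz_res.table),
            "n_fdr05": gsz_res.n_significant(),
        }

        stage = "regions"
        reg = region_analysis(ds)
        reg.to_csv(out / "region_results.tsv", sep="\t")
        manifest["stages"][stage] = {
            "n_regions": len(reg),
            "n_nominal05": int((reg["p"] < 0.05).sum()),
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
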