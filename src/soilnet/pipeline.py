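"""End-to-end orchestration: config validation, stage execution, manifest.

The pipeline runs the stages in dependency order — synthetic data (or input
loading), plant metrics, OTU preparation, per-soil network inference, signed
clustering, coupling scores, null models, path models and the contribution
ledger — writing TSV/JSON outputs with a metadata header and recording every
file's checksum in a run manifest.  One global seed is expanded into
per-stage seeds through a counter-based scheme so each stage is reproducible
on its own.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import cluster_abundances, spinglass_cluster
from .coupling import coupling_scores, stability_coupling_test
from .errors import ConfigError
from .netinfer import stars_select, write_edge_list
from .nulls import null_modularity_test
from .otutable import OtuTable, write_otu_tsv
from .plants import mesocosm_metrics
from .prep import clr_transform, filter_otus, rarefy, specialisation_index
from .sem import build_and_run_sems, relative_contributions
from .synthetic import SyntheticConfig, generate_dataset

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "validate_config", "run_pipeline"]

_STAGE_DEFAULTS = {
    "filter": {"min_total_reads": 100, "min_samples": 5},
    "stars": {"n_lambda": 20, "beta_threshold": 0.05, "n_subsamples": 30,
              "subsample_fraction": 0.8},
    "cluster": {"n_restarts": 5},
    "nulls": {"R": 99, "enabled": True},
    "coupling": {"n_pairs": 9, "alpha": 0.05, "denominator": "clusters"},
    "sem": {"enabled": True, "alpha": 0.05},
}


@dataclasses.dataclass
class PipelineConfig:
    synthetic: SyntheticConfig | None
    stages: dict
    seed: int
    out_dir: Path

    def stage_seed(self, stage_index: int) -> int:
        return int(
            np.random.SeedSequence([self.seed, stage_index]).generate_state(1)[0]
            % (2**31)
        )


def validate_config(path) -> PipelineConfig:
    """Load and range-check a YAML pipeline config; unknown keys rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known_top = {"synthetic", "stages", "seed", "out_dir", "inputs"}
    unknown = set(raw) - known_top
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "synthetic" not in raw and "inputs" not in raw:
        raise ConfigError("config needs a 'synthetic' block or an 'inputs' block")
    synth = None
    if "synthetic" in raw:
        block = raw["synthetic"] or {}
        valid_fields = {f.name for f in dataclasses.fields(SyntheticConfig)}
        unknown = set(block) - valid_fields
        if unknown:
            raise ConfigError(f"unknown synthetic keys: {sorted(unknown)}")
        if "years" in block:
            block["years"] = tuple(block["years"])
        synth = SyntheticConfig(**block)
        synth.validate()
    stages = {k: dict(v) for k, v in _STAGE_DEFAULTS.items()}
    for stage, params in (raw.get("stages") or {}).items():
        if stage not in stages:
            raise ConfigError(f"unknown stage {stage!r}")
        unknown = set(params) - set(stages[stage])
        if unknown:
            raise ConfigError(f"unknown keys for stage {stage!r}: {sorted(unknown)}")
        stages[stage].update(params)
    alpha = stages["coupling"]["alpha"]
    if not 0 < alpha < 1:
        raise ConfigError(f"stages.coupling.alpha = {alpha} not in (0, 1)")
    seed = int(raw.get("seed", 0))
    out_dir = Path(raw.get("out_dir", "soilnet_out"))
    return PipelineConfig(synthetic=synth, stages=stages, seed=seed, out_dir=out_dir)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, params: dict, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# soilnet {__version__} seed={seed}\n")
        for k, v in params.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": []}
    t_start = time.time()

    def record(stage: str, files: list[Path], params: dict) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "params": {k: str(v) for k, v in params.items()},
                "outputs": {f.name: _checksum(f) for f in files},
                "elapsed_s": round(time.time() - t_start, 3),
            }
        )

    if config.synthetic is None:
        raise ConfigError("only synthetic-input pipelines are wired end-to-end")
    synth = dataclasses.replace(config.synthetic, seed=config.stage_seed(0))
    plant, chemistry, prok, fung, truth = generate_dataset(synth)
    plant_path = out / "plant_biomass.csv"
    chem_path = out / "soil_chemistry.csv"
    plant.to_csv(plant_path, index=False)
    chemistry.to_csv(chem_path, index=False)
    write_otu_tsv(prok, out / "otu_prokaryote.tsv")
    write_otu_tsv(fung, out / "otu_fungal.tsv")
    (out / "truth.json").write_text(json.dumps(truth.to_json_dict(), indent=1))
    record("simulate", [plant_path, chem_path, out / "otu_prokaryote.tsv",
                        out / "otu_fungal.tsv", out / "truth.json"],
           {"seed": synth.seed})

    metrics = mesocosm_metrics(plant, truth.axes)
    _write_tsv(metrics.set_index("mesocosm_id"), out / "plant_metrics.tsv", {},
               config.seed)
    record("plant-metrics", [out / "plant_metrics.tsv"], {})

    fcfg = config.stages["filter"]
    scfg = config.stages["stars"]
    ccfg = config.stages["cluster"]
    coup = config.stages["coupling"]
    abund = {}
    networks = {}
    partitions = {}
    for domain, table in (("prokaryote", prok), ("fungal", fung)):
        filtered = filter_otus(table, fcfg["min_total_reads"], fcfg["min_samples"])
        rarefied = rarefy(filtered, seed=config.stage_seed(1))
        si = specialisation_index(rarefied, k_habitats=2)
        _write_tsv(si.per_otu, out / f"si_{domain}.tsv",
                   {"k": si.k_habitats}, config.seed)
        clr = clr_transform(filtered)
        path, network = stars_select(
            clr,
            n_lambda=scfg["n_lambda"],
            beta_threshold=scfg["beta_threshold"],
            n_subsamples=scfg["n_subsamples"],
            subsample_fraction=scfg["subsample_fraction"],
            seed=config.stage_seed(2),
        )
        write_edge_list(network, out / f"network_{domain}.tsv")
        weights = filtered.relative().sum(axis=0)
        part = spinglass_cluster(
            network, n_restarts=ccfg["n_restarts"],
            seed=config.stage_seed(3), otu_weights=weights,
        )
        pd.Series(part.membership, name="cluster").rename_axis("otu_id").to_frame() \
            .to_csv(out / f"partition_{domain}.tsv", sep="\t")
        abund[domain] = cluster_abundances(part, filtered)
        networks[domain] = network
        partitions[domain] = part
        record(f"network-{domain}",
               [out / f"network_{domain}.tsv", out / f"partition_{domain}.tsv",
                out / f"si_{domain}.tsv"],
               {"selected_lambda": path.selected_lambda, "q": part.modularity})

    scores = coupling_scores(abund["prokaryote"], abund["fungal"],
                             n_pairs=coup["n_pairs"])
    _write_tsv(scores, out / "coupling_scores.tsv", {}, config.seed)
    m = metrics.set_index("mesocosm_id")
    test = stability_coupling_test(m["temporal_stability"], scores["beta"], m["soil"])
    (out / "stability_coupling.json").write_text(json.dumps({
        "slope": test.slope, "se": test.se, "wald_chi2": test.wald_chi2,
        "p": test.p, "n": test.n, "warning": test.warning}, indent=1))
    record("couple", [out / "coupling_scores.tsv", out / "stability_coupling.json"],
           {"n_pairs": coup["n_pairs"]})

    ncfg = config.stages["nulls"]
    if ncfg["enabled"]:
        reports = {}
        for domain in ("prokaryote", "fungal"):
            ens = null_modularity_test(
                networks[domain], R=ncfg["R"], seed=config.stage_seed(4),
                cluster_kwargs={"n_restarts": 2, "n_temps": 15},
            )
            reports[domain] = {"observed_q": ens.observed, "R": ens.R,
                               "p_lower": ens.p_lower, "p_upper": ens.p_upper}
        (out / "null_modularity.json").write_text(json.dumps(reports, indent=1))
        record("null", [out / "null_modularity.json"], {"R": ncfg["R"]})

    semcfg = config.stages["sem"]
    if semcfg["enabled"]:
        data = m.join(chemistry.set_index("mesocosm_id"))
        micro_vars = []
        sizes = {}
        for domain in ("prokaryote", "fungal"):
            a = abund[domain]
            for c in a.columns[: min(2, a.shape[1])]:
                name = f"{domain}_cluster{c}"
                data[name] = a[c]
                micro_vars.append(name)
                sizes[name] = float(a[c].mean())
        models = build_and_run_sems(data.reset_index(), micro_vars,
                                    compute_dsep=False)
        ledger = relative_contributions(models, sizes, alpha=semcfg["alpha"])
        _write_tsv(ledger.to_frame().set_index(["time", "component", "kind"]),
                   out / "contribution_ledger.tsv", {"alpha": semcfg["alpha"]},
                   config.seed)
        record("sem", [out / "contribution_ledger.tsv"],
               {"n_models": sum(len(v) for v in models.values())})

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest
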