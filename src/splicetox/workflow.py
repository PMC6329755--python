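"""Workflow orchestration: wire the modules into end-to-end runs.

Three workflows mirror the study's analysis arms:

* ``screen``    — counts (or a simulated screen) -> CPTM -> log ratios ->
  moderated t -> gene waterfall + hit calls;
* ``biomarker`` — expression panel + Emax -> ranked correlation table;
* ``synergy``   — dose matrix CSV (or simulated) -> Loewe surface ->
  excess grid + synergy score.

Runs are configured by a YAML mapping (unknown keys rejected) with a
single ``seed`` funnelling all randomness, and every run writes a
``manifest.json`` recording the package version, the effective
parameters, and sha256 checksums of the inputs, so outputs are
reproducible byte for byte given the same config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import biomarker_assoc, screen_analysis, synergy_loewe, synthetic_data

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_workflow"]

_KNOWN_KEYS = {
    "workflow",
    "inputs",
    "params",
    "outdir",
    "seed",
}
_WORKFLOWS = ("screen", "biomarker", "synergy")


@dataclass
class RunConfig:
    workflow: str
    outdir: str
    inputs: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.workflow not in _WORKFLOWS:
            raise ValueError(f"unknown workflow {self.workflow!r}; choose from {_WORKFLOWS}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "workflow" not in raw or "outdir" not in raw:
            raise ValueError("config requires 'workflow' and 'outdir'")
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(cfg: RunConfig, outdir: Path, outputs: list[str]) -> None:
    manifest = {
        "package_version": __version__,
        "workflow": cfg.workflow,
        "seed": cfg.seed,
        "params": cfg.params,
        "inputs": {
            key: {"path": str(p), "sha256": _sha256(Path(p))}
            for key, p in cfg.inputs.items()
            if isinstance(p, str) and Path(p).exists()
        },
        "outputs": sorted(outputs),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def _run_screen(cfg: RunConfig, outdir: Path) -> list[str]:
    params = dict(cfg.params)
    if "counts" in cfg.inputs:
        counts = pd.read_csv(cfg.inputs["counts"], sep="\t")
        pairing = [tuple(p) for p in params.pop("pairing")]
    else:
        sim_kwargs = dict(params.pop("simulate", {}))
        planted = [
            synthetic_data.PlantedEffect(**p) for p in sim_kwargs.pop("sensitizer_genes", [])
        ]
        sim_cfg = synthetic_data.SimScreenConfig(
            seed=cfg.seed, sensitizer_genes=planted, **sim_kwargs
        )
        counts, _, truth = synthetic_data.simulate_screen(sim_cfg)
        synthetic_data.write_truth(truth, outdir / "truth.json")
        pairing = [tuple(p) for p in truth["pairing"]]
        counts.to_csv(outdir / "counts.tsv", sep="\t", index=False)
    norm = screen_analysis.cptm_normalize(counts)
    ratios = screen_analysis.screen_log_ratios(norm, pairing)
    results = screen_analysis.moderated_t_test(ratios)
    genes = screen_analysis.gene_aggregate(results)
    hits = screen_analysis.call_gene_hits(
        results,
        alpha=float(params.pop("alpha", 0.05)),
        min_shrnas=int(params.pop("min_shrnas", 2)),
    )
    results.to_csv(outdir / "shrna_results.tsv", sep="\t", index=False)
    genes.to_csv(outdir / "gene_waterfall.tsv", sep="\t", index=False)
    hits.to_csv(outdir / "gene_hits.tsv", sep="\t", index=False)
    return ["shrna_results.tsv", "gene_waterfall.tsv", "gene_hits.tsv"]


def _run_biomarker(cfg: RunConfig, outdir: Path) -> list[str]:
    params = dict(cfg.params)
    if "expression" in cfg.inputs:
        panel = pd.read_csv(cfg.inputs["expression"], sep="\t", index_col=0)
        emax = pd.read_csv(cfg.inputs["emax"], sep="\t", index_col=0).iloc[:, 0]
    else:
        sim_cfg = synthetic_data.SimPanelConfig(seed=cfg.seed, **params.pop("simulate", {}))
        panel, emax, truth = synthetic_data.simulate_panel(sim_cfg)
        synthetic_data.write_truth(truth, outdir / "truth.json")
    ranked = biomarker_assoc.correlate_expression_emax(panel, emax)
    ranked.to_csv(outdir / "biomarker_rank.tsv", sep="\t", index=False)
    outputs = ["biomarker_rank.tsv"]
    for gene in params.pop("quartile_genes", []):
        grp = biomarker_assoc.quartile_group_compare(panel, emax, gene)
        pd.DataFrame(
            [
                {
                    "gene": grp.gene,
                    "n_high": len(grp.high_lines),
                    "n_low": len(grp.low_lines),
                    "mean_emax_high": grp.mean_emax_high,
                    "mean_emax_low": grp.mean_emax_low,
                    "t": grp.t,
                    "p": grp.p,
                }
            ]
        ).to_csv(outdir / f"quartiles_{gene}.tsv", sep="\t", index=False)
        outputs.append(f"quartiles_{gene}.tsv")
    return outputs


def _run_synergy(cfg: RunConfig, outdir: Path) -> list[str]:
    params = dict(cfg.params)
    if "matrix" in cfg.inputs:
        raw = pd.read_csv(cfg.inputs["matrix"], index_col=0)
        raw.columns = raw.columns.astype(float)
    else:
        sim_cfg = synthetic_data.SimMatrixConfig(seed=cfg.seed, **params.pop("simulate", {}))
        raw, truth = synthetic_data.simulate_matrix(sim_cfg)
        synthetic_data.write_truth(truth, outdir / "truth.json")
        raw.to_csv(outdir / "matrix.csv")
    matrix = synergy_loewe.build_inhibition_matrix(raw)
    surface = synergy_loewe.loewe_surface(matrix)
    result = synergy_loewe.synergy_score(
        surface, matrix, gate=params.pop("gate", "both")
    )
    pd.DataFrame(surface.i_loewe, index=matrix.dx, columns=matrix.dy).to_csv(
        outdir / "loewe_surface.csv"
    )
    pd.DataFrame(surface.excess, index=matrix.dx, columns=matrix.dy).to_csv(
        outdir / "loewe_excess.csv"
    )
    (outdir / "synergy.json").write_text(
        json.dumps({"score": result.score, "fx": result.fx, "fy": result.fy}, indent=1)
    )
    return ["loewe_surface.csv", "loewe_excess.csv", "synergy.json"]


def run_workflow(cfg: RunConfig) -> Path:
    """Execute one configured workflow; returns the output directory."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    runner = {"screen": _run_screen, "biomarker": _run_biomarker, "synergy": _run_synergy}[
        cfg.workflow
    ]
    outputs = runner(cfg, outdir)
    _write_manifest(cfg, outdir, outputs)
    logger.info("workflow %s complete: %s", cfg.workflow, outdir)
    return outdir
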