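"""End-to-end orchestration: config, stage artifacts, provenance.

Stages exchange files (OpenDX grids, CSV tables, PDB pseudo-atoms) rather
than only in-memory objects, mirroring how MSMD output arrives in practice
and making every stage resumable and inspectable. Each written table
carries the configuration hash in a leading comment line.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .density import (ProbeSpec, TrajectoryBundle, VoxelGrid, accumulate_occupancy,
                      build_grid, compute_gfe, grid_to_dx, normalize_occupancy)
from .extmap import MappingParams
from .features import PatchParams, assemble_features, hotspot_feature_row
from .hotspots import (DetectionParams, Hotspot, LabelParams, detect_hotspots,
                       hotspots_to_frame, hotspots_to_pdb, label_cryptic)
from .mlrank import FittedModel, ModelSpec, rank_hotspots, topn_report
from .structure import CrypticSiteDefinition, Structure
from .synth import SyntheticScenario, make_clash_pair, plant_probe_trajectory

log = logging.getLogger("cryptohot")

__all__ = ["RunConfig", "run_detect", "run_predict", "detect_from_scenario",
           "save_model_sidecar", "feature_hash", "write_table"]


@dataclass
class RunConfig:
    """One YAML-serialisable configuration for a full run."""

    seed: int = 0
    output_dir: str = "cryptohot_out"
    detection: DetectionParams = field(default_factory=DetectionParams)
    labeling: LabelParams = field(default_factory=LabelParams)
    patch: PatchParams = field(default_factory=PatchParams)
    mapping: MappingParams = field(default_factory=MappingParams)
    model: ModelSpec = field(default_factory=ModelSpec)
    scenario: SyntheticScenario | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("output_dir", None)   # hash the science, not the destination
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        scen = d.get("scenario")
        if scen:
            sites = scen.pop("planted_sites", None)
            if sites:
                from .synth import PlantedSite
                scen["planted_sites"] = [
                    PlantedSite(tuple(s["center"]), s.get("intensity", 18.0),
                                s.get("spread", 1.5)) for s in sites]
        return cls(
            seed=d.get("seed", 0),
            output_dir=d.get("output_dir", "cryptohot_out"),
            detection=DetectionParams(**d.get("detection", {})),
            labeling=LabelParams(**d.get("labeling", {})),
            patch=PatchParams(**d.get("patch", {})),
            mapping=MappingParams(**d.get("mapping", {})),
            model=ModelSpec(**d.get("model", {})),
            scenario=SyntheticScenario(**scen) if scen else None,
        )


def write_table(df: pd.DataFrame, path: str, config_hash: str = "") -> None:
    """CSV with a provenance comment line (readable with comment='#')."""
    with open(path, "w") as fh:
        fh.write(f"# cryptohot config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def feature_hash(columns) -> str:
    return hashlib.sha256(",".join(map(str, columns)).encode()).hexdigest()[:12]


def save_model_sidecar(model: FittedModel, path: str) -> None:
    """JSON metadata sidecar: algorithm, hyperparams, seed, feature hash."""
    meta = {
        "algorithm": model.spec.algorithm,
        "hyperparams": model.spec.hyperparams,
        "seed": model.spec.seed,
        "classification_threshold": model.spec.classification_threshold,
        "feature_columns": list(model.feature_names),
        "feature_hash": feature_hash(model.feature_names),
    }
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2)


def detect_from_scenario(scenario: SyntheticScenario,
                         params: DetectionParams = DetectionParams(),
                         label_params: LabelParams = LabelParams(),
                         label: bool = False
                         ) -> tuple[list[Hotspot], dict[str, VoxelGrid],
                                    Structure, CrypticSiteDefinition | None]:
    """Synthetic scenario → grids → merged hotspots (→ optional labels)."""
    from .structure import detect_clashes, superpose, transfer_ligand

    bundle = plant_probe_trajectory(scenario)
    reference = bundle.alignment_reference
    grid = build_grid(reference, padding=scenario.padding)
    grid = normalize_occupancy(accumulate_occupancy(bundle, grid))
    hotspots = detect_hotspots([grid], params)
    site = None
    if label:
        apo, holo, resname = make_clash_pair(scenario)
        fit = superpose(holo, apo)
        ligand = transfer_ligand(holo, resname, fit)
        site = detect_clashes(apo, ligand)
        hotspots = [label_cryptic(h, site, apo, label_params) for h in hotspots]
    return hotspots, {scenario.probe: grid}, reference, site


def run_detect(config: RunConfig,
               bundles: dict[str, TrajectoryBundle] | None = None,
               reference: Structure | None = None,
               site: CrypticSiteDefinition | None = None) -> pd.DataFrame:
    """Density → hotspots → (optional) labels, all artifacts written.

    ``bundles`` maps probe name to trajectory bundle; without them a
    synthetic scenario from the config is simulated. Returns the hotspot
    table; grids (OpenDX), the table (CSV) and voxel pseudo-atoms (PDB)
    land in the output directory together with a run log.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("run_detect start, config_hash=%s", chash)
        if bundles is None:
            if config.scenario is None:
                raise ValueError("run_detect needs bundles or a scenario")
            hotspots, grids, reference, site = detect_from_scenario(
                config.scenario, config.detection, config.labeling,
                label=True)
        else:
            if reference is None:
                raise ValueError("bundles given without an apo reference")
            grids = {}
            for name, bundle in sorted(bundles.items()):
                grid = build_grid(reference)
                grid = normalize_occupancy(accumulate_occupancy(bundle, grid))
                grids[name] = grid
            hotspots = detect_hotspots(list(grids.values()), config.detection)
            if site is not None:
                hotspots = [label_cryptic(h, site, reference, config.labeling)
                            for h in hotspots]
        for name, grid in grids.items():
            grid_to_dx(grid, str(out / f"occupancy_{name}.dx"))
        table = hotspots_to_frame(hotspots)
        write_table(table, str(out / "hotspots.csv"), chash)
        hotspots_to_pdb(hotspots, str(out / "hotspots.pdb"))
        config.to_yaml(str(out / "config.yaml"))
        log.info("run_detect wrote %d hotspots", len(hotspots))
        return table
    finally:
        log.removeHandler(handler)
        handler.close()


def run_predict(config: RunConfig, model: FittedModel,
                features: pd.DataFrame) -> tuple[pd.DataFrame, object]:
    """Score a feature table, rank per protein, and write report files."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    meta_cols = [c for c in ("hotspot_id", "protein_id", "label")
                 if c in features.columns]
    X = features.drop(columns=meta_cols)
    if feature_hash(X.columns) != feature_hash(model.feature_names):
        raise ValueError("feature columns do not match the model sidecar")
    probs = model.predict_proba(X)
    table = pd.DataFrame({
        "protein_id": features.get("protein_id", pd.Series(["P0"] * len(X))),
        "hotspot_id": features.get("hotspot_id",
                                   pd.Series([f"H{i}" for i in range(len(X))])),
        "probability": probs,
    })
    if "label" in features.columns:
        table["label"] = features["label"].to_numpy()
    ranked = rank_hotspots(table)
    write_table(ranked, str(out / "ranking.csv"), chash)
    report = None
    if "label" in ranked.columns and (ranked["label"] == "cryptic").any():
        report = topn_report(ranked)
        rep_df = pd.DataFrame({
            "N": list(report.hits),
            "n_proteins": report.n_proteins,
            "hits": list(report.hits.values()),
            "percent": list(report.percentages.values()),
        })
        write_table(rep_df, str(out / "topn.csv"), chash)
    return ranked, report


def extract_feature_table(hotspots: list[Hotspot], structure: Structure,
                          per_probe: dict[str, tuple],
                          params: PatchParams = PatchParams(),
                          protein_id: str = "") -> pd.DataFrame:
    """Feature rows for every hotspot of one protein (see features module)."""
    rows = [hotspot_feature_row(h, structure, per_probe, params,
                                protein_id=protein_id) for h in hotspots]
    return assemble_features(rows)
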