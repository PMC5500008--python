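"""End-to-end pipeline: simulate -> profile -> sharing -> aging.

A single YAML config drives all stages.  Every stage writes TSV outputs
into the output directory and records them, with SHA-256 checksums and the
seeds consumed, in ``manifest.json``; identical config and seed give
byte-identical outputs.  Stage seeds are derived deterministically from
the global seed and the stage name, so stages can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import aging as aging_mod
from . import cohort as cohort_mod
from . import insertions, sharing
from .model import RecombinationModel
from .repertoire import Repertoire, read_clonotype_table, write_clonotype_table

logger = logging.getLogger(__name__)

STAGES = ("simulate", "profile", "sharing", "aging")


@dataclass
class PipelineConfig:
    output_dir: str
    seed: int = 0
    stages: Sequence[str] = STAGES
    chain: str = "beta"
    cohort: dict = field(default_factory=dict)
    donors: list[dict] = field(default_factory=list)
    model_files: dict | None = None
    repertoire_files: dict = field(default_factory=dict)
    profile: dict = field(default_factory=lambda: {"bin_size": 3000, "mode": "posterior"})
    sharing: dict = field(default_factory=dict)
    aging: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(**d)

    def validate(self) -> None:
        for s in self.stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}")
        for label, p in (self.model_files or {}).items():
            if not Path(p).exists():
                raise FileNotFoundError(f"model file for {label!r} missing: {p}")
        for label, p in self.repertoire_files.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"repertoire file for {label!r} missing: {p}")
        if "table" in self.aging and not self.aging.get("series"):
            if not Path(self.aging["table"]).exists():
                raise FileNotFoundError(f"aging table missing: {self.aging['table']}")


def _stage_seed(seed: int, stage: str) -> int:
    return (seed * 100_003 + zlib.crc32(stage.encode())) % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_models(cfg: PipelineConfig) -> tuple[RecombinationModel, RecombinationModel]:
    if cfg.model_files:
        return (
            RecombinationModel.from_file(cfg.model_files["tdt_minus"]),
            RecombinationModel.from_file(cfg.model_files["tdt_plus"]),
        )
    return cohort_mod.default_models(cfg.chain)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the requested stages in dependency order; returns the manifest."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "stage_seeds": {s: _stage_seed(config.seed, s) for s in config.stages},
        "stages": list(config.stages),
        "outputs": {},
    }
    models = _load_models(config)
    repertoires: dict[str, tuple[Repertoire, Path]] = {}

    def record(path: Path) -> None:
        manifest["outputs"][path.name] = _sha256(path)

    def run_stage(name, fn):
        logger.info("stage %s (seed %d)", name, _stage_seed(config.seed, name))
        try:
            fn()
        except Exception as err:
            raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err

    if "simulate" in config.stages:
        def _simulate():
            cohort_cfg = cohort_mod.CohortConfig(
                seed=_stage_seed(config.seed, "simulate"), **config.cohort
            )
            specs = {
                d["donor_id"]: cohort_mod.DonorSpec(**{**d, "chain": d.get("chain", config.chain)})
                for d in config.donors
            }
            done: set[str] = set()
            for did, spec in specs.items():
                if did in done:
                    continue
                if spec.compartment == "cord":
                    reps = [
                        cohort_mod.simulate_cord_blood(
                            *models, cohort_cfg, donor_id=did, chain=spec.chain
                        )
                    ]
                    done.add(did)
                elif spec.twin_partner and spec.twin_partner in specs:
                    r1, r2 = cohort_mod.simulate_twin_pair(
                        spec, specs[spec.twin_partner], models, cohort_cfg
                    )
                    reps = [r1, r2]
                    done |= {did, spec.twin_partner}
                else:
                    reps = [cohort_mod.simulate_adult(spec, models, cohort_cfg)]
                    done.add(did)
                for rep in reps:
                    path = outdir / f"{rep.donor_id}_{rep.compartment}.tsv"
                    write_clonotype_table(rep, path)
                    record(path)
                    repertoires[rep.donor_id] = (rep, path)
            if config.aging.get("series"):
                s = config.aging["series"]
                table = cohort_mod.simulate_aging_series(
                    s["ages"],
                    tuple(s["true_params"]),
                    s.get("noise_sd", 0.002),
                    s.get("per_age_k", 2000),
                    rng_seed=_stage_seed(config.seed, "simulate"),
                )
                path = outdir / "aging_table.tsv"
                table.to_csv(path, sep="\t", index=False)
                record(path)
                config.aging.setdefault("table", str(path))

        run_stage("simulate", _simulate)

    for label, p in config.repertoire_files.items():
        rep = read_clonotype_table(p, donor_id=label, chain=config.chain)
        repertoires[label] = (rep, Path(p))

    if "profile" in config.stages:
        def _profile():
            for did, (rep, _) in repertoires.items():
                profs = insertions.profile_by_rank(
                    rep,
                    models[1],
                    bin_size=config.profile.get("bin_size", 3000),
                    classes=config.profile.get("classes"),
                    mode=config.profile.get("mode", "posterior"),
                )
                df = pd.DataFrame([dataclasses.asdict(p) for p in profs])
                path = outdir / f"{did}_profile.tsv"
                df.to_csv(path, sep="\t", index=False)
                record(path)

        run_stage("profile", _profile)

    if "sharing" in config.stages:
        def _sharing():
            pairs = config.sharing.get("pairs") or []
            frame = config.sharing.get("frame", "out_of_frame")
            rows = []
            donor_models: dict[str, RecombinationModel] = {}

            def donor_model(did: str) -> RecombinationModel:
                # per-individual model: insertion distribution re-fit by EM
                # on the donor's own frame-filtered sequences
                if did not in donor_models:
                    rep = repertoires[did][0]
                    seqs = [
                        c.cdr3_nt
                        for c in rep.clonotypes
                        if sharing._passes_frame(c.cdr3_nt, frame)
                    ]
                    donor_models[did] = insertions.fit_individual_model(
                        models[1], seqs, rng_seed=_stage_seed(config.seed, "sharing")
                    )
                return donor_models[did]

            for d1, d2 in pairs:
                rep1 = repertoires[d1][0]
                rep2 = repertoires[d2][0]
                if frame not in (None, "none"):
                    from .repertoire import frame_subset

                    rep1 = frame_subset(rep1, frame)
                    rep2 = frame_subset(rep2, frame)
                res = sharing.normalized_sharing(
                    rep1, rep2, config.sharing.get("key", "cdr3nt")
                )
                pred, pred_sd = sharing.predict_sharing_mc(
                    donor_model(d1),
                    donor_model(d2),
                    res.size1,
                    res.size2,
                    frame_filter=frame,
                    replicates=config.sharing.get("replicates", 5),
                    rng_seed=_stage_seed(config.seed, "sharing"),
                )
                rows.append(
                    {**dataclasses.asdict(res), "predicted": pred, "predicted_sd": pred_sd}
                )
            if rows:
                path = outdir / "sharing.tsv"
                pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
                record(path)

        run_stage("sharing", _sharing)

    if "aging" in config.stages:
        def _aging():
            table_path = config.aging.get("table")
            if not table_path:
                return
            df = pd.read_csv(table_path, sep="\t")
            obs = [
                aging_mod.AgingObservation(
                    str(r["donor"]), float(r["age"]), float(r["Z"]),
                    float(r["N"]) if "N" in df.columns and pd.notna(r["N"]) else None,
                    int(r.get("K", 2000)),
                )
                for _, r in df.iterrows()
            ]
            fit = aging_mod.fit_decay_models(obs)
            fit_df = pd.DataFrame(
                [{k: v for k, v in dataclasses.asdict(fit).items() if k != "residuals_z"}]
            )
            path = outdir / "aging_fit.tsv"
            fit_df.to_csv(path, sep="\t", index=False)
            record(path)
            grid = np.array(sorted({o.age for o in obs} | set(range(0, 91, 2))))
            curve = pd.DataFrame(
                {"age": grid, "Z_fit": fit.c + fit.a * np.exp(-fit.b * grid)}
            )
            if fit.b_naive is not None:
                confound = aging_mod.naive_confound_curve(fit)
                curve["Z_naive_confound"] = confound(curve["age"].to_numpy())
            path = outdir / "aging_curve.tsv"
            curve.to_csv(path, sep="\t", index=False)
            record(path)

        run_stage("aging", _aging)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
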