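"""One-command orchestration: simulate -> preprocess -> train -> denoise ->
evaluate -> quantify, with a JSON run manifest for provenance.

Stages communicate through files under the run directory, so any stage can be
re-run on its own as long as its inputs exist; a missing input raises an
error naming the stage that should have produced it.  The ``smoke`` profile
is the desk-scale configuration (32^3 phantoms, 2-level generator); the
``paper`` profile carries the full-scale defaults (128^3 grid, 4-level
generator, 400 epochs).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .metrics import evaluate_pairs
from .networks import GeneratorSpec
from .phantom import (CohortJitter, LabelMap, PhantomSpec, ScanMeta, make_cohort)
from .quantify import cohort_suvr_table, compare_cohort, smooth, suv_map, zai_map
from .training import (TrainConfig, load_checkpoint, save_checkpoint,
                       smoke_config, train)
from .volume_io import (PreprocRecord, Volume, invert_rescale, preprocess,
                        read_volume, write_volume)

STAGES = ("simulate", "preprocess", "train", "denoise", "evaluate", "quantify")


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, **info) -> None:
        self.stages[stage] = {"timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"), **info}

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(
            {"version": self.version, "config": self.config, "stages": self.stages},
            indent=2, default=str))


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a flat key/value mapping")
    return cfg


def default_config(profile: str = "smoke") -> dict:
    base = {
        "profile": profile, "seed": 0, "subjects": 10,
        "reference_region": "cerebellum", "thinning_fraction": 0.10,
        "attention_type": "ssab", "adversarial_form": "BCE",
        "discriminator_enabled": True, "fid_weight": 0.0,
        "lesion_probability": 0.0,
    }
    if profile == "smoke":
        base.update({"grid": 32, "voxel_mm": 5.0, "total_counts": 2_000_000,
                     "epochs": 30})
    else:
        base.update({"grid": 128, "voxel_mm": 2.0, "total_counts": 200_000_000,
                     "epochs": 400})
    return base


def _require(path: Path, stage: str, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{stage}' needs {path}, which stage '{producer}' produces; "
            f"run '{producer}' first")
    return path


class Pipeline:
    def __init__(self, out_dir: str | Path, config: dict | None = None):
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.config = {**default_config(), **(config or {})}
        self.manifest = RunManifest(self.config)

    # -- helpers -----------------------------------------------------------
    def _phantom_spec(self) -> PhantomSpec:
        c = self.config
        g = int(c["grid"])
        return PhantomSpec(
            grid_shape=(g, g, g), voxel_size_mm=(c["voxel_mm"],) * 3,
            total_counts_standard=int(c["total_counts"]),
            thinning_fraction=float(c["thinning_fraction"]), seed=int(c["seed"]),
        )

    def _train_config(self) -> TrainConfig:
        c = self.config
        if c.get("profile", "smoke") == "smoke":
            cfg = smoke_config(seed=int(c["seed"]), epochs=int(c["epochs"]),
                               attention_type=c["attention_type"])
        else:
            cfg = TrainConfig(seed=int(c["seed"]), epochs=int(c["epochs"]),
                              generator=GeneratorSpec(attention_type=c["attention_type"]))
        cfg.adversarial_form = c["adversarial_form"]
        cfg.discriminator_enabled = bool(c["discriminator_enabled"])
        cfg.weights.fid_weight = float(c["fid_weight"])
        if c.get("split"):
            cfg.split = tuple(float(f) for f in c["split"])
        return cfg

    def _load_cohort(self, stage: str):
        man = _require(self.out / "sim" / "manifest.csv", stage, "simulate")
        df = pd.read_csv(man)
        subjects = []
        for _, row in df.iterrows():
            low = read_volume(row["path_low"])
            std = read_volume(row["path_standard"])
            lab_vox = read_volume(row["path_labels"])
            from .phantom import REGION_LABELS, TISSUE_LABELS
            names = dict(TISSUE_LABELS)
            names.update(REGION_LABELS)
            labels = LabelMap(np.round(lab_vox.voxels).astype(np.int16), names,
                              lab_vox.spacing_mm)
            meta = ScanMeta(row["subject_id"], float(row["weight_kg"]),
                            float(row["dose_MBq"]), int(row["seed"]))
            subjects.append((low, std, labels, meta))
        return subjects

    # -- stages ------------------------------------------------------------
    def simulate(self) -> None:
        c = self.config
        jit = CohortJitter(lesion_probability=float(c.get("lesion_probability", 0.0)))
        _, manifest = make_cohort(int(c["subjects"]), self._phantom_spec(), jit,
                                  out_dir=self.out / "sim")
        self.manifest.record("simulate", subjects=len(manifest),
                             manifest=str(self.out / "sim" / "manifest.csv"))

    def preprocess(self) -> None:
        subjects = self._load_cohort("preprocess")
        pre_dir = self.out / "pre"
        pre_dir.mkdir(exist_ok=True)
        g = int(self.config["grid"])
        rows = []
        for low, std, labels, meta in subjects:
            out_row = {"subject_id": meta.subject_id}
            for arm, vol in (("low", low), ("standard", std)):
                pv, rec = preprocess(vol, (g, g, g))
                vol_path = pre_dir / f"{meta.subject_id}_{arm}.nii.gz"
                write_volume(pv, vol_path)
                mask_path = pre_dir / f"{meta.subject_id}_{arm}_mask.nii.gz"
                write_volume(Volume(rec.brain_mask.astype(np.float32), pv.spacing_mm),
                             mask_path)
                rec.to_json(pre_dir / f"{meta.subject_id}_{arm}.json", mask_path)
                out_row[f"path_{arm}"] = str(vol_path)
            rows.append(out_row)
        pd.DataFrame(rows).to_csv(pre_dir / "index.csv", index=False)
        self.manifest.record("preprocess", subjects=len(rows))

    def _load_preprocessed(self, stage: str) -> tuple[list, pd.DataFrame]:
        idx = _require(self.out / "pre" / "index.csv", stage, "preprocess")
        df = pd.read_csv(idx)
        pairs = [(read_volume(r["path_low"]).voxels, read_volume(r["path_standard"]).voxels)
                 for _, r in df.iterrows()]
        return pairs, df

    def train(self) -> None:
        pairs, _ = self._load_preprocessed("train")
        cfg = self._train_config()
        result = train(pairs, cfg)
        tdir = self.out / "train"
        tdir.mkdir(exist_ok=True)
        save_checkpoint(result, cfg, tdir / "checkpoint.pkl")
        result.history.to_csv(tdir / "history.csv", index=False)
        np.savez(tdir / "splits.npz", train=result.splits[0], val=result.splits[1],
                 test=result.splits[2])
        self.manifest.record("train", best_epoch=result.best_epoch,
                             best_val_ssim=result.best_val_ssim,
                             diverged=result.diverged)

    def denoise(self) -> None:
        pairs, df = self._load_preprocessed("denoise")
        ckpt = _require(self.out / "train" / "checkpoint.pkl", "denoise", "train")
        gen = load_checkpoint(ckpt)
        dn_dir = self.out / "dn"
        dn_dir.mkdir(exist_ok=True)
        rows = []
        for (ld, _sd), (_, row) in zip(pairs, df.iterrows()):
            dn = gen.denoise(ld)
            spacing = read_volume(row["path_low"]).spacing_mm
            path = dn_dir / f"{row['subject_id']}_dn.nii.gz"
            write_volume(Volume(dn, spacing), path)
            rows.append({"subject_id": row["subject_id"], "path_dn": str(path)})
        pd.DataFrame(rows).to_csv(dn_dir / "index.csv", index=False)
        self.manifest.record("denoise", subjects=len(rows))

    def evaluate(self) -> None:
        pairs, df = self._load_preprocessed("evaluate")
        dn_idx = _require(self.out / "dn" / "index.csv", "evaluate", "denoise")
        dn_df = pd.read_csv(dn_idx)
        subjects = self._load_cohort("evaluate")
        labels = [s[2] for s in subjects]
        dn_vols = [read_volume(r["path_dn"]).voxels for _, r in dn_df.iterrows()]
        sd_vols = [p[1] for p in pairs]
        report = evaluate_pairs(dn_vols, sd_vols, labels)
        edir = self.out / "eval"
        edir.mkdir(exist_ok=True)
        report.per_pair.to_csv(edir / "report.csv", index=False)
        report.summary.to_csv(edir / "summary.csv")
        self.manifest.record("evaluate", mean_ssim=float(report.per_pair["ssim"].mean()))

    def quantify(self) -> None:
        subjects = self._load_cohort("quantify")
        dn_idx = _require(self.out / "dn" / "index.csv", "quantify", "denoise")
        dn_df = pd.read_csv(dn_idx)
        ref = self.config["reference_region"]
        dn_suv, sd_suv, labels = [], [], []
        for (low, std, lab, meta), (_, row) in zip(subjects, dn_df.iterrows()):
            rec = PreprocRecord.from_json(self.out / "pre" / f"{meta.subject_id}_low.json")
            dn_vol = read_volume(row["path_dn"])
            dn_conc = invert_rescale(dn_vol, rec, mode="paper")
            dn_suv.append(smooth(suv_map(dn_conc, meta)))
            sd_suv.append(smooth(suv_map(std, meta)))
            labels.append(lab)
        dn_tab = cohort_suvr_table(dn_suv, labels, ref)
        sd_tab = cohort_suvr_table(sd_suv, labels, ref)
        stats = compare_cohort(dn_tab, sd_tab)
        qdir = self.out / "quant"
        qdir.mkdir(exist_ok=True)
        dn_tab.to_csv(qdir / "suvr_dn.csv", index=False)
        sd_tab.to_csv(qdir / "suvr_sd.csv", index=False)
        stats.to_csv(qdir / "report.csv", index=False)
        for vol, lab, (_, row) in zip(dn_suv, labels, dn_df.iterrows()):
            z = zai_map(vol, lab.brain_mask())
            write_volume(z, qdir / f"{row['subject_id']}_zai.nii.gz")
        self.manifest.record("quantify",
                             mean_pct_dev=float(stats["pct_dev_mean"].mean()))

    def run(self, stages: list[str] | None = None) -> RunManifest:
        stages = list(stages or STAGES)
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        for stage in STAGES:
            if stage in stages:
                getattr(self, stage)()
                self.manifest.save(self.out / "manifest.json")
        return self.manifest


def run_pipeline(config_path: str | Path, out_dir: str | Path | None = None,
                 stages: list[str] | None = None) -> RunManifest:
    cfg = load_config(config_path)
    out = Path(out_dir or cfg.get("out_dir", "smartpet_run"))
    return Pipeline(out, cfg).run(stages)
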