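"""End-to-end reproducible pipeline: simulate -> sample -> train -> explain -> evaluate.

Each stage reads files produced by its predecessor, records SHA-256
checksums of its inputs and outputs in a run manifest, and is skipped on
re-runs when its configuration and inputs are unchanged and its outputs
still verify.  Stage seeds are derived from the root seed and the stage
name, so stages are individually reproducible.

The training stage enforces the weak-supervision firewall structurally: it
loads only the image array and the label/subject manifest — the mask file
on disk is never opened during training.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field
from functools import partial
from pathlib import Path
from typing import Callable, Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import metrics as M
from . import models as mod
from . import phantom as ph
from . import patches as pa
from . import saliency as sal
from . import training as tr

__all__ = ["RunManifest", "load_config", "run_pipeline", "StageError", "DEFAULT_CONFIG"]

STAGES = ["phantom", "patches", "train", "explain", "evaluate"]

DEFAULT_CONFIG: Dict = {
    "seed": 0,
    "phantom": {
        "n_subjects": 6,
        "volume_shape": [24, 96, 96],
        "lesion_radius_range_vox": [3, 5],
    },
    "patches": {
        "patch_shape": [32, 32],
        "n_tumour": 6,
        "n_contralateral": 6,
        "offset_axial": 5,
        "offset_coronal": 20,
        "offset_sagittal": 20,
    },
    "model": {"arch": "wsunet", "depth": 2, "base_filters": 4},
    "training": {"max_epochs": 2, "batch_size": 8, "n_folds": 2,
                 "patience_epochs": 5},
    "explain": {
        "methods": ["wsunet_voxels", "gradcam", "integrated_gradients", "occlusion"],
        "gradcam_conv_layer": 3,
        "occlusion": {"window_width": 10, "stride": 8},
        "n_examples": 2,
    },
    "evaluate": {"n_bootstraps": 50, "threshold": 0.5},
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    config: Dict
    seed: int
    stages: Dict[str, Dict] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({"config": self.config, "seed": self.seed,
                           "stages": self.stages}, indent=2)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path) -> "RunManifest":
        d = json.loads(Path(path).read_text())
        return cls(d["config"], d["seed"], d["stages"])


def load_config(path_or_dict) -> Dict:
    """Merge a YAML/JSON config (file path or dict) over the defaults."""
    if isinstance(path_or_dict, (str, Path)):
        text = Path(path_or_dict).read_text()
        user = yaml.safe_load(text) or {}
    else:
        user = dict(path_or_dict or {})
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seed(root_seed: int, stage: str) -> int:
    ss = np.random.SeedSequence([int(root_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def _inputs_hash(stage_cfg, seed: int, input_files: List[Path]) -> str:
    payload = {
        "config": stage_cfg,
        "seed": seed,
        "inputs": {str(p): _sha256(p) for p in sorted(input_files)},
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def _outputs_ok(record: Dict) -> bool:
    return all(Path(p).exists() and _sha256(Path(p)) == c
               for p, c in record.get("outputs", {}).items())


def run_pipeline(config, out_dir=None, force: bool = False,
                 log: Callable[[str], None] = print) -> RunManifest:
    """Execute (or resume) the full pipeline under ``out_dir``.

    Stages whose configuration, seed and inputs are unchanged and whose
    outputs still match their recorded checksums are skipped; corrupting
    or deleting an output re-runs that stage and everything downstream.
    """
    cfg = load_config(config)
    out = Path(out_dir or cfg.get("out_dir", "wsunet_run"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))

    manifest_path = out / "manifest.json"
    previous = RunManifest.load(manifest_path).stages if manifest_path.exists() else {}
    manifest = RunManifest(cfg, seed)

    dirty = force
    for stage in STAGES:
        runner, stage_cfg, input_files = _STAGE_TABLE[stage](cfg, out)
        sseed = _stage_seed(seed, stage)
        try:
            ihash = _inputs_hash(stage_cfg, sseed, input_files)
            prev = previous.get(stage, {})
            if not dirty and prev.get("inputs_hash") == ihash and _outputs_ok(prev):
                manifest.stages[stage] = {**prev, "cached": True}
                log(f"[{stage}] cached")
            else:
                dirty = True
                outputs = runner(stage_cfg, sseed, out, log)
                manifest.stages[stage] = {
                    "inputs_hash": ihash,
                    "outputs": {str(p): _sha256(Path(p)) for p in outputs},
                    "cached": False,
                }
                log(f"[{stage}] done ({len(outputs)} artefacts)")
        except Exception as exc:  # noqa: BLE001 - tag and abort with partial manifest
            manifest.save(manifest_path)
            raise StageError(stage, exc) from exc
        manifest.save(manifest_path)
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _phantom_stage(cfg, out):
    def run(stage_cfg, sseed, out_dir, log):
        pcfg_kwargs = {k: v for k, v in stage_cfg.items() if k != "n_subjects"}
        for key in ("volume_shape", "lesion_count_range", "lesion_radius_range_vox"):
            if key in pcfg_kwargs:
                pcfg_kwargs[key] = tuple(pcfg_kwargs[key])
        pcfg = ph.PhantomConfig(seed=sseed, **pcfg_kwargs)
        vols = ph.generate_cohort(pcfg, int(stage_cfg["n_subjects"]))
        outputs = []
        for v in vols:
            outputs.extend(ph.write_volume(v, out_dir / "volumes"))
        return outputs

    return run, cfg["phantom"], []


def _patches_stage(cfg, out):
    vol_files = sorted((out / "volumes").glob("*.nii.gz")) if (out / "volumes").exists() else []

    def run(stage_cfg, sseed, out_dir, log):
        images = sorted((out_dir / "volumes").glob("*_image.nii.gz"))
        vols = [ph.read_volume(img, img.with_name(img.name.replace("_image", "_mask")))
                for img in images]
        kwargs = dict(stage_cfg)
        kwargs["patch_shape"] = tuple(kwargs.get("patch_shape", (128, 128)))
        scfg = pa.PatchSamplingConfig(seed=sseed, **kwargs)
        ds = pa.assemble_dataset(vols, scfg)
        pa.write_dataset(ds, out_dir / "dataset")
        return [out_dir / "dataset" / f for f in ("images.npy", "masks.npy", "manifest.csv")]

    return run, cfg["patches"], vol_files


def _build_arch(model_cfg: Dict, input_shape, seed: int) -> mod.ModelHandle:
    arch = model_cfg.get("arch", "wsunet")
    kwargs = {k: v for k, v in model_cfg.items() if k != "arch"}
    if arch == "wsunet":
        return mod.build_wsunet(mod.WSUnetConfig(input_shape=input_shape, **kwargs), seed=seed)
    if arch == "scnn":
        return mod.build_scnn(mod.SCNNConfig(input_shape=input_shape, **kwargs), seed=seed)
    raise ValueError(f"unknown arch {arch!r}")


def _maskless_dataset(dataset_dir: Path) -> pa.PatchDataset:
    """Load pixels + labels + subjects only — masks.npy is never opened."""
    x = np.load(dataset_dir / "images.npy")
    man = pd.read_csv(dataset_dir / "manifest.csv")
    patches = [
        pa.Patch(x[i, ..., 0], int(row["label"]), None, row["subject_id"],
                 (int(row["centre_axial"]), int(row["centre_coronal"]),
                  int(row["centre_sagittal"])), row["origin"])
        for i, row in man.iterrows()
    ]
    prov: Dict[str, tuple] = {}
    for p in patches:
        t, c = prov.get(p.subject_id, (0, 0))
        prov[p.subject_id] = (t + (p.origin == "tumour_centred"),
                              c + (p.origin == "contralateral"))
    cfg = pa.PatchSamplingConfig(patch_shape=x.shape[1:3])
    return pa.PatchDataset(patches, cfg, prov)


def _train_stage(cfg, out):
    ds_dir = out / "dataset"
    inputs = [ds_dir / "images.npy", ds_dir / "manifest.csv"]
    inputs = [p for p in inputs if p.exists()]
    stage_cfg = {"model": cfg["model"], "training": cfg["training"]}

    def run(stage_cfg, sseed, out_dir, log):
        ds = _maskless_dataset(out_dir / "dataset")
        tcfg = tr.TrainingConfig(seed=sseed, trace_voxel_metrics=False,
                                 **stage_cfg["training"])
        input_shape = ds.patches[0].pixels.shape + (1,)
        builder = partial(_build_arch, stage_cfg["model"], input_shape)
        model = tr.WeaklySupervisedImageModel(ds, builder, tcfg)
        res = model.fit(validation_fold=0)
        for rec in res.trace.records:
            log(f"[train] epoch {rec['epoch']}: val_loss={rec['val_loss']:.4f}")
        res.handle.save(out_dir / "model" / "model")
        res.trace.to_frame().to_csv(out_dir / "model" / "trace.csv", index=False)
        val_ids = pd.Series(res.val_dataset.subject_ids, name="subject_id")
        val_ids.to_csv(out_dir / "model" / "validation_subjects.csv", index=False)
        return [out_dir / "model" / f
                for f in ("model.npz", "model.json", "trace.csv",
                          "validation_subjects.csv")]

    return run, stage_cfg, inputs


def _load_val(out_dir: Path):
    ds = pa.read_dataset(out_dir / "dataset")
    val_ids = set(pd.read_csv(out_dir / "model" / "validation_subjects.csv")["subject_id"])
    return ds.subset(sorted(val_ids))


def _explain_stage(cfg, out):
    inputs = [p for p in (out / "model" / "model.npz", out / "dataset" / "images.npy")
              if p.exists()]

    def run(stage_cfg, sseed, out_dir, log):
        handle = mod.load_model(out_dir / "model" / "model")
        val = _load_val(out_dir)
        positives = [p for p in val.patches if p.label == 1]
        examples = positives[: int(stage_cfg.get("n_examples", 2))]
        occ = sal.OcclusionConfig(**stage_cfg.get("occlusion", {}))
        outputs = []
        for i, patch in enumerate(examples):
            for method in stage_cfg["methods"]:
                smap = _compute_map(handle, patch, method, stage_cfg, occ)
                if smap is None:
                    continue
                if smap.values.shape != patch.pixels.shape:
                    smap = sal.upsample_nearest(smap, patch.pixels.shape)
                base = out_dir / "explanations" / f"example{i}_{method}"
                sal.save_map(smap, base, patch=patch)
                outputs.extend([base.with_suffix(".npy"), base.with_suffix(".json"),
                                base.with_suffix(".png")])
        return outputs

    return run, cfg["explain"], inputs


def _compute_map(handle, patch, method, stage_cfg, occ):
    if method == "wsunet_voxels":
        return sal.wsunet_voxel_map(handle, patch) if handle.has_voxel_output else None
    if method == "gradcam":
        layer = handle.conv_layer_index(int(stage_cfg.get("gradcam_conv_layer", 3)))
        return sal.grad_cam(handle, layer, patch)
    if method == "integrated_gradients":
        return sal.integrated_gradients(handle, patch)
    if method == "occlusion":
        return sal.occlusion_sensitivity(handle, patch, occ)
    raise ValueError(f"unknown saliency method {method!r}")


def _evaluate_stage(cfg, out):
    inputs = [p for p in (out / "model" / "model.npz", out / "dataset" / "masks.npy")
              if p.exists()]

    def run(stage_cfg, sseed, out_dir, log):
        handle = mod.load_model(out_dir / "model" / "model")
        val = _load_val(out_dir)
        xv, yv, mv = val.arrays()
        boot = M.BootstrapConfig(n_bootstraps=int(stage_cfg.get("n_bootstraps", 500)),
                                 seed=sseed)
        frames = []
        image_scores = handle.predict_image(xv)
        rep_img = M.evaluate_images(image_scores, yv,
                                    threshold=stage_cfg.get("threshold", 0.5),
                                    bootstrap=boot)
        frames.append(rep_img.to_frame("validation", f"{handle.name} image"))
        if handle.has_voxel_output:
            vox = handle.predict_voxels(xv)
            rep_vox = M.evaluate_voxels(vox, mv, is_probability=True,
                                        threshold=stage_cfg.get("threshold", 0.5),
                                        bootstrap=boot)
            frames.append(rep_vox.to_frame("validation", "wsunet voxels"))
        table = pd.concat(frames, ignore_index=True)
        mdir = out_dir / "metrics"
        mdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(mdir / "metrics.csv", index=False)
        (mdir / "metrics.json").write_text(table.to_json(orient="records", indent=2))
        return [mdir / "metrics.csv", mdir / "metrics.json"]

    return run, cfg["evaluate"], inputs


_STAGE_TABLE = {
    "phantom": _phantom_stage,
    "patches": _patches_stage,
    "train": _train_stage,
    "explain": _explain_stage,
    "evaluate": _evaluate_stage,
}
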