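"""Stage orchestration: simulate → train → explain → extract → analyze.

Every stage is a plain function taking a :class:`RunConfig`; the CLI in
:mod:`nodulecam.cli` is a thin shell over these.  Stages communicate only
through files under ``config.outdir`` and each writes a ``<stage>_manifest
.json`` recording its outputs and the hash of the config that produced
them, so a run is reproducible and auditable from the output tree alone.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import classifier as _clf
from . import gradcam as _gc
from . import regions as _rg
from . import shape as _sh
from . import stats as _st
from . import synthetic as _syn


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------
@dataclass
class DatasetBlock:
    n_benign: int = 60
    n_malignant: int = 60
    image_shape: tuple[int, int] = (224, 224)
    master_seed: int = 0


@dataclass
class TrainBlock:
    variant: str = "tiny_hr"
    learning_rate: float = 3e-3
    epochs: int = 150
    batch_size: int = 8
    input_size: int = 112
    alpha: float = 0.25
    gamma: float = 2.0
    augment: bool = True
    tta: bool = True
    n_repeats: int = 3
    train_fraction: float = 0.7
    pretrained: str | None = None


@dataclass
class GradcamBlock:
    target: str = "predicted"  # or "benign" / "malignant"
    blend: float = 0.4
    save_raw: bool = False  # also write the raw CAM grid as CSV


@dataclass
class ExtractionBlock:
    h_lo: float = 20.0
    h_hi: float = 20.0
    s_min: float = 0.5
    v_min: float = 0.3
    min_area: int = 50
    largest_only: bool = True


@dataclass
class StatsBlock:
    test: str = "mann_whitney"
    alpha: float = 0.05
    bonferroni: bool = False


@dataclass
class RunConfig:
    outdir: str = "runs/scaled"
    dataset: DatasetBlock = field(default_factory=DatasetBlock)
    train: TrainBlock = field(default_factory=TrainBlock)
    gradcam: GradcamBlock = field(default_factory=GradcamBlock)
    extraction: ExtractionBlock = field(default_factory=ExtractionBlock)
    stats: StatsBlock = field(default_factory=StatsBlock)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        blocks = dict(
            dataset=DatasetBlock, train=TrainBlock, gradcam=GradcamBlock,
            extraction=ExtractionBlock, stats=StatsBlock,
        )
        kwargs = {"outdir": d.get("outdir", "runs/scaled")}
        for name, klass in blocks.items():
            sub = dict(d.get(name, {}))
            if name == "dataset" and "image_shape" in sub:
                sub["image_shape"] = tuple(sub["image_shape"])
            kwargs[name] = klass(**sub)
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def scaled_profile(outdir: str = "runs/scaled", master_seed: int = 0) -> RunConfig:
    """Desk-scale default: tiny backbone, 60+60 images, 3 repeats (minutes
    on one CPU)."""
    cfg = RunConfig(outdir=outdir)
    cfg.dataset.master_seed = master_seed
    return cfg


def paper_profile(outdir: str = "runs/paper", master_seed: int = 0) -> RunConfig:
    """Full-scale profile mirroring the clinical setting: resnet18 backbone,
    415/93 images, 10 random splits.  Hours on one CPU; not used by tests."""
    cfg = RunConfig(
        outdir=outdir,
        dataset=DatasetBlock(n_benign=415, n_malignant=93, master_seed=master_seed),
        train=TrainBlock(variant="resnet18", learning_rate=1e-4, epochs=30,
                         n_repeats=10),
    )
    return cfg


# --------------------------------------------------------------------------
# stage helpers
# --------------------------------------------------------------------------
def _stage_dir(config: RunConfig, stage: str) -> Path:
    d = Path(config.outdir) / stage
    d.mkdir(parents=True, exist_ok=True)
    return d


def _write_manifest(config: RunConfig, stage: str, outputs: list[str]) -> None:
    d = Path(config.outdir) / stage
    manifest = {"stage": stage, "config_hash": config.config_hash(),
                "outputs": sorted(outputs)}
    (d / f"{stage}_manifest.json").write_text(json.dumps(manifest, indent=2))


def _require(config: RunConfig, stage: str, path: Path) -> None:
    if not path.exists():
        raise FileNotFoundError(
            f"missing {path.name}: run the '{stage}' stage first (expected {path})"
        )


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------
def cmd_simulate(config: RunConfig):
    """Generate the synthetic dataset and write it to <outdir>/dataset."""
    ds = config.dataset
    images, manifest = _syn.generate_dataset(
        n_benign=ds.n_benign, n_malignant=ds.n_malignant,
        image_shape=ds.image_shape, master_seed=ds.master_seed,
    )
    outdir = _stage_dir(config, "dataset")
    _syn.write_dataset(images, manifest, outdir,
                       params={"master_seed": ds.master_seed})
    _write_manifest(config, "dataset", [r[0] for r in manifest.records] + ["manifest.csv"])
    return images, manifest


def cmd_train(config: RunConfig):
    """Repeated-split training/evaluation, then a final fit.

    The classification metrics come from ``n_repeats`` stratified 70/30
    splits (held-out evaluation).  The checkpoint used by the explain stage
    is a *final model* re-fit on the full dataset — the standard
    evaluate-by-resampling / deploy-the-full-fit protocol; saliency quality
    benefits directly from the extra training data."""
    ds_dir = Path(config.outdir) / "dataset"
    _require(config, "simulate", ds_dir / "manifest.csv")
    images, manifest = _syn.read_dataset(ds_dir / "manifest.csv")
    labels = [img.label for img in images]
    tb = config.train
    est = _clf.NoduleCNNClassifier(
        variant=tb.variant, learning_rate=tb.learning_rate, epochs=tb.epochs,
        batch_size=tb.batch_size, input_size=tb.input_size, alpha=tb.alpha,
        gamma=tb.gamma, augment=tb.augment, tta=tb.tta, pretrained=tb.pretrained,
        random_state=config.dataset.master_seed,
    )
    report = _clf.repeat_experiment(
        images, labels, n_repeats=tb.n_repeats, train_fraction=tb.train_fraction,
        master_seed=config.dataset.master_seed, estimator=est,
    )
    final = _clf.clone_estimator(est, random_state=config.dataset.master_seed)
    final.fit(images, labels)
    outdir = _stage_dir(config, "train")
    outputs = []
    rep_dict = report.to_dict()
    for row in rep_dict["per_repeat"]:
        curve = np.asarray(row.pop("roc_curve"))
        fname = f"roc_repeat{row['repeat']}.csv"
        pd.DataFrame(curve, columns=["threshold", "fpr", "tpr"]).to_csv(
            outdir / fname, index=False)
        outputs.append(fname)
    (outdir / "eval_report.json").write_text(json.dumps(rep_dict, indent=2))
    final.save(outdir / "checkpoint.npz")
    outputs += ["eval_report.json", "checkpoint.npz"]
    _write_manifest(config, "train", outputs)
    return report, final


def cmd_explain(config: RunConfig, checkpoint: str | None = None):
    """Grad-CAM heatmaps and overlays for every dataset image."""
    ds_dir = Path(config.outdir) / "dataset"
    _require(config, "simulate", ds_dir / "manifest.csv")
    ckpt = Path(checkpoint) if checkpoint else Path(config.outdir) / "train" / "checkpoint.npz"
    _require(config, "train", ckpt)
    images, manifest = _syn.read_dataset(ds_dir / "manifest.csv")
    est = _clf.NoduleCNNClassifier.load(ckpt)
    gb = config.gradcam
    target = None if gb.target == "predicted" else _clf.CLASS_ORDER.index(gb.target)
    outdir = _stage_dir(config, "explain")
    outputs = []
    for img, (path, _, _) in zip(images, manifest.records):
        x = _clf.preprocess(img, input_size=est.input_size,
                            normalize_mean=est.normalize_mean,
                            normalize_std=est.normalize_std)
        hm = _gc.explain(est.model_, x, target_class=target,
                         target_shape=img.pixels.shape,
                         original=img.pixels, blend=gb.blend)
        stem = Path(path).stem
        iio.imwrite(outdir / f"{stem}_heatmap.png",
                    np.round(hm.rendered * 255).astype(np.uint8))
        iio.imwrite(outdir / f"{stem}_overlay.png",
                    np.round(hm.overlay * 255).astype(np.uint8))
        outputs += [f"{stem}_heatmap.png", f"{stem}_overlay.png"]
        if gb.save_raw:
            np.savetxt(outdir / f"{stem}_raw.csv", hm.raw, delimiter=",")
            outputs.append(f"{stem}_raw.csv")
    _write_manifest(config, "explain", outputs)
    return outdir


def cmd_extract(config: RunConfig):
    """HSV red-capture + component extraction + shape features for every
    heatmap produced by the explain stage; writes features.csv."""
    ds_dir = Path(config.outdir) / "dataset"
    _require(config, "simulate", ds_dir / "manifest.csv")
    explain_dir = Path(config.outdir) / "explain"
    _require(config, "explain", explain_dir / "explain_manifest.json")
    images, manifest = _syn.read_dataset(ds_dir / "manifest.csv")
    xb = config.extraction
    thresholds = _rg.RedThresholds(h_lo=xb.h_lo, h_hi=xb.h_hi,
                                   s_min=xb.s_min, v_min=xb.v_min)
    outdir = _stage_dir(config, "regions")
    outputs = []
    kept_regions, kept_labels, kept_ids = [], [], []
    for img, (path, label, _) in zip(images, manifest.records):
        stem = Path(path).stem
        hm_path = explain_dir / f"{stem}_heatmap.png"
        _require(config, "explain", hm_path)
        rendered = iio.imread(hm_path).astype(float) / 255.0
        mask = _rg.capture_red(_rg.rgb_to_hsv(rendered), thresholds)
        regs = _rg.extract_regions(mask, min_area=xb.min_area,
                                   largest_only=xb.largest_only, source=stem)
        if not regs:
            warnings.warn(f"no red region captured for {stem}", stacklevel=2)
            kept_regions.append(None)
        else:
            region = regs[0]
            iio.imwrite(outdir / f"{stem}_region.png",
                        region.mask.astype(np.uint8) * 255)
            pd.DataFrame(region.contour, columns=["row", "col"]).to_csv(
                outdir / f"{stem}_contour.csv", index=False)
            over = _rg.overlay_contours(img.pixels, regs)
            iio.imwrite(outdir / f"{stem}_contour_overlay.png",
                        np.round(over * 255).astype(np.uint8))
            outputs += [f"{stem}_region.png", f"{stem}_contour.csv",
                        f"{stem}_contour_overlay.png"]
            kept_regions.append(region)
        kept_labels.append(label)
        kept_ids.append(stem)
    table = _sh.feature_table(kept_regions, kept_labels, image_ids=kept_ids)
    table.to_csv(outdir / "features.csv", index=False)
    sidecar = {"thresholds": asdict(thresholds), "min_area": xb.min_area,
               "largest_only": xb.largest_only,
               "config_hash": config.config_hash()}
    (outdir / "features_params.json").write_text(json.dumps(sidecar, indent=2))
    outputs += ["features.csv", "features_params.json"]
    _write_manifest(config, "regions", outputs)
    return table


def cmd_analyze(config: RunConfig) -> dict:
    """Group comparison of the three descriptors; JSON + text report and
    violin density grids."""
    feat_path = Path(config.outdir) / "regions" / "features.csv"
    _require(config, "extract", feat_path)
    table = pd.read_csv(feat_path)
    sb = config.stats
    report = _st.significance_report(table, test=sb.test, alpha=sb.alpha,
                                     bonferroni=sb.bonferroni)
    outdir = _stage_dir(config, "analysis")
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    (outdir / "report.txt").write_text(_st.render_report_text(report) + "\n")
    rows = []
    for feat, cmp_res in report["comparisons"].items():
        for group in ("benign", "malignant"):
            rows.append({
                "feature": feat, "group": group,
                "n": cmp_res[f"n_{group}"],
                "median": cmp_res[f"median_{group}"],
                "mean": cmp_res[f"mean_{group}"],
                "p_value": cmp_res["p_value"],
            })
    pd.DataFrame(rows).to_csv(outdir / "group_summaries.csv", index=False)
    outputs = ["report.json", "report.txt", "group_summaries.csv"]
    for feat, groups in report["violins"].items():
        for group, vio in groups.items():
            if vio is None:
                continue
            fname = f"violin_{feat}_{group}.csv"
            pd.DataFrame({"grid": vio["grid"], "density": vio["density"]}).to_csv(
                outdir / fname, index=False)
            outputs.append(fname)
    _write_manifest(config, "analysis", outputs)
    return report


def cmd_run_all(config: RunConfig) -> dict:
    """Full pipeline: simulate → train → explain → extract → analyze."""
    cmd_simulate(config)
    cmd_train(config)
    cmd_explain(config)
    cmd_extract(config)
    return cmd_analyze(config)
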