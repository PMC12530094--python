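"""End-to-end pipeline orchestration.

Runs the requested stages in acquisition order — simulate, reconstruct,
mmt, stats, train, compare — against a single output directory, with one
global seed fanned out deterministically to per-stage streams. Every run
writes a ``run_manifest.json`` echoing the fully resolved configuration;
existing artifacts are only overwritten with an explicit flag. Reports
(CSV/JSON) are byte-reproducible for identical config + seed; timing is
logged, never written into artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .dataset import build_model_input, center_crop, read_sample
from .mmt import compute_mmt, mmt_cohort_stats
from .reconstruction import canonical_table, as_printed_table, element_summary, normalize, reconstruct
from .stats import compute_fdh, compare_models, two_cohort_ttest
from .synthetic import SceneSpec, render_sample, write_dataset

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "STAGES"]

log = logging.getLogger("polamat")

STAGES = ("simulate", "reconstruct", "mmt", "stats", "train", "compare")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Fully resolved pipeline configuration; unknown keys are rejected."""

    stages: tuple
    out_dir: str
    seed: int = 0
    overwrite: bool = False
    # simulate
    n_per_class: int = 4
    image_size: int = 64
    noise: tuple = ("none",)
    quantization: str = "float"
    split_fraction: float = 0.8
    # reconstruct / preprocess
    crop: int | None = None
    table: str = "canonical"
    clip_elements: bool = False
    # mmt
    variant_A: str = "he2014_corrected"
    variant_G: str = "as_printed"
    # stats
    bins: int = 100
    alpha: float = 0.05
    # train
    arch: str = "cnn"
    widths: tuple = (8, 16, 32)
    model_size: int = 32
    train_overrides: dict = field(default_factory=dict)
    verbosity: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise PipelineError(f"unknown config keys: {unknown}")
        cfg = cls(**d)
        bad = sorted(set(cfg.stages) - set(STAGES))
        if bad:
            raise PipelineError(f"unknown stages: {bad}; valid stages are {STAGES}")
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["noise"] = list(self.noise)
        d["widths"] = list(self.widths)
        return d


def _ensure_writable(path: Path, overwrite: bool, what: str):
    if path.exists() and not overwrite:
        raise PipelineError(
            f"{what} already exists at {path}; pass overwrite=True (--overwrite) "
            "to replace existing artifacts"
        )


def _class_of(manifest: dict, sid: str) -> str:
    return {s["id"]: s["class"] for s in manifest["samples"]}[sid]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order; returns a result summary.

    Any stage failure raises :class:`PipelineError` naming the stage.
    """
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = {name: s for name, s in zip(STAGES, ss.spawn(len(STAGES)))}
    results: dict = {"version": __version__, "config": config.to_dict()}

    manifest_path = out / "run_manifest.json"
    _ensure_writable(manifest_path, config.overwrite, "run manifest")

    for stage in config.stages:
        t0 = time.perf_counter()
        try:
            _run_stage(stage, config, out, stage_seeds[stage], results)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        log.info("stage %s finished in %.2f s", stage, time.perf_counter() - t0)

    manifest_path.write_text(json.dumps(results, indent=2, default=str))
    return results


def _run_stage(stage, config: RunConfig, out: Path, seed_seq, results: dict):
    if stage == "simulate":
        _stage_simulate(config, out, seed_seq, results)
    elif stage == "reconstruct":
        _stage_reconstruct(config, out, results)
    elif stage == "mmt":
        _stage_mmt(config, out, results)
    elif stage == "stats":
        _stage_stats(config, out, results)
    elif stage == "train":
        _stage_train(config, out, seed_seq, results)
    elif stage == "compare":
        _stage_compare(config, out, results)


def _stage_simulate(config, out, seed_seq, results):
    ds_dir = out / "dataset"
    _ensure_writable(ds_dir / "manifest.json", config.overwrite, "simulated dataset")
    child = np.random.default_rng(seed_seq)
    bundles = []
    for label in ("normal", "cancer"):
        for k in range(config.n_per_class):
            seed = int(child.integers(0, 2**31 - 1))
            spec = SceneSpec(
                width=config.image_size,
                height=config.image_size,
                class_label=label,
                noise=tuple(config.noise),
                quantization=config.quantization,
                seed=seed,
            )
            bundles.append(render_sample(spec, sample_id=f"{label}_{k:04d}"))
    manifest = write_dataset(
        bundles, ds_dir, split_fraction=config.split_fraction,
        seed=int(child.integers(0, 2**31 - 1)),
    )
    results["simulate"] = {
        "n_samples": manifest["n_samples"],
        "n_images": manifest["n_images"],
        "dataset_dir": str(ds_dir),
    }


def _load_manifest(out: Path) -> dict:
    p = out / "dataset" / "manifest.json"
    if not p.exists():
        raise PipelineError(f"no dataset manifest at {p}; run the simulate stage first")
    return json.loads(p.read_text())


def _normalized_elements(config, out):
    import tifffile  # noqa: F401  (element maps written as float TIFF)

    manifest = _load_manifest(out)
    table = canonical_table() if config.table == "canonical" else as_printed_table()
    per_sample = {}
    for s in manifest["samples"]:
        stack = read_sample(out / "dataset" / s["id"])
        if config.crop:
            stack = center_crop(stack, config.crop)
        elems = normalize(reconstruct(stack, table), clip=config.clip_elements)
        per_sample[s["id"]] = elems
    return manifest, per_sample


def _stage_reconstruct(config, out, results):
    import tifffile

    el_dir = out / "elements"
    _ensure_writable(el_dir, config.overwrite, "element maps")
    manifest, per_sample = _normalized_elements(config, out)
    el_dir.mkdir(exist_ok=True)
    for sid, elems in per_sample.items():
        d = el_dir / sid
        d.mkdir(exist_ok=True)
        for r in range(1, 5):
            for c in range(1, 5):
                tifffile.imwrite(d / f"m{r}{c}.tiff",
                                 elems.element(r, c).astype(np.float32))
        _write_montage(elems, d / "montage.png")
    by_class = {}
    for sid, elems in per_sample.items():
        by_class.setdefault(_class_of(manifest, sid), []).append(elems)
    frames = []
    for label, group in sorted(by_class.items()):
        df = element_summary(group)
        df.insert(0, "class", label)
        frames.append(df)
    import pandas as pd

    pd.concat(frames).to_csv(el_dir / "element_summary.csv", index=False)
    results["reconstruct"] = {"n_samples": len(per_sample), "elements_dir": str(el_dir)}


def _write_montage(elems, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(4, 4, figsize=(8, 8))
    for r in range(4):
        for c in range(4):
            axes[r, c].imshow(elems.elements[r, c], cmap="RdBu_r", vmin=-1, vmax=1)
            axes[r, c].set_title(f"m{r + 1}{c + 1}", fontsize=8)
            axes[r, c].axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=72)
    plt.close(fig)


def _stage_mmt(config, out, results):
    import tifffile

    mmt_dir = out / "mmt"
    _ensure_writable(mmt_dir, config.overwrite, "MMT maps")
    manifest, per_sample = _normalized_elements(config, out)
    mmt_dir.mkdir(exist_ok=True)
    by_class = {}
    for sid, elems in per_sample.items():
        maps = compute_mmt(elems, variant_A=config.variant_A, variant_G=config.variant_G)
        d = mmt_dir / sid
        d.mkdir(exist_ok=True)
        for name in ("A", "b", "t", "G", "delta"):
            tifffile.imwrite(d / f"{name}.tiff", getattr(maps, name).astype(np.float32))
        by_class.setdefault(_class_of(manifest, sid), []).append(maps)
    entry = {"variant_A": config.variant_A, "variant_G": config.variant_G,
             "mmt_dir": str(mmt_dir)}
    if all(len(v) >= 2 for v in by_class.values()) and len(by_class) == 2:
        normal, cancer = by_class.get("normal", []), by_class.get("cancer", [])
        stats = mmt_cohort_stats(normal, cancer)
        import pandas as pd

        rows = [{"parameter": k, **v} for k, v in stats.items()]
        pd.DataFrame(rows).to_csv(mmt_dir / "cohort_stats.csv", index=False)
        entry["cohort_stats"] = stats
    results["mmt"] = entry


def _stage_stats(config, out, results):
    import pandas as pd

    st_dir = out / "stats"
    _ensure_writable(st_dir, config.overwrite, "statistics reports")
    manifest, per_sample = _normalized_elements(config, out)
    st_dir.mkdir(exist_ok=True)
    by_class = {}
    for sid, elems in per_sample.items():
        by_class.setdefault(_class_of(manifest, sid), []).append(elems)
    rows, fdh_rows = [], []
    for r in range(1, 5):
        for c in range(1, 5):
            if r == 1 and c == 1:
                continue
            name = f"m{r}{c}"
            cohorts = {
                lab: [(e.element(r, c), e.mask) for e in group]
                for lab, group in sorted(by_class.items())
            }
            fdh = compute_fdh(cohorts, bins=config.bins, element=name)
            for lab, peak in fdh.peak_locations().items():
                fdh_rows.append({"element": name, "class": lab, "peak": peak})
            if len(by_class) == 2:
                means = {
                    lab: [float(e.element(r, c)[e.mask].mean()) for e in group]
                    for lab, group in sorted(by_class.items())
                }
                (la, va), (lb, vb) = sorted(means.items())
                if min(len(va), len(vb)) >= 2:
                    res = two_cohort_ttest(va, vb, paired=False)
                    rows.append({"element": name, "cohort_a": la, "cohort_b": lb,
                                 "t": res.statistic, "p": res.pvalue, "stars": res.stars})
    pd.DataFrame(fdh_rows).to_csv(st_dir / "fdh_peaks.csv", index=False)
    if rows:
        pd.DataFrame(rows).to_csv(st_dir / "element_ttests.csv", index=False)
    results["stats"] = {"stats_dir": str(st_dir)}


def _stage_train(config, out, seed_seq, results):
    import pandas as pd

    from .classifier import TrainConfig, build_cnn, evaluate, train

    tr_dir = out / "training"
    _ensure_writable(tr_dir, config.overwrite, "training artifacts")
    manifest = _load_manifest(out)
    label_of = {s["id"]: s["class"] for s in manifest["samples"]}

    def _inputs(ids):
        xs, ys = [], []
        for sid in ids:
            stack = read_sample(out / "dataset" / sid)
            if config.crop:
                stack = center_crop(stack, config.crop)
            scale = 255.0 if config.quantization == "uint8" else 200.0
            mi = build_model_input(stack, size=config.model_size, count_scale=scale,
                                   class_label=label_of[sid])
            xs.append(mi)
            ys.append(1 if label_of[sid] == "cancer" else 0)
        return xs, np.array(ys)

    seed = int(np.random.default_rng(seed_seq).integers(0, 2**31 - 1))
    x_train, y_train = _inputs(manifest["train"])
    x_test, y_test = _inputs(manifest["test"])
    model = build_cnn(variant=config.arch, widths=tuple(config.widths), seed=seed)
    tc = TrainConfig(seed=seed, **config.train_overrides)
    history = train(model, x_train, y_train, x_test, y_test, tc)
    counts, metrics, preds = evaluate(model, x_test, y_test, threshold=tc.threshold)
    tr_dir.mkdir(exist_ok=True)
    pd.DataFrame({"sample_id": manifest["test"], "label": y_test, "pred": preds}).to_csv(
        tr_dir / "predictions.csv", index=False
    )
    (tr_dir / "metrics.json").write_text(json.dumps(
        {"confusion": dataclasses.asdict(counts), "metrics": metrics,
         "epochs_run": history["epochs_run"],
         "final_train_acc": history["train_acc"][-1]}, indent=2))
    (tr_dir / "model_manifest.json").write_text(json.dumps(model.manifest(), indent=2))
    results["train"] = {"metrics": metrics, "confusion": dataclasses.asdict(counts),
                        "epochs_run": history["epochs_run"]}


def _stage_compare(config, out, results):
    import pandas as pd

    pa = out / "training" / "predictions.csv"
    pb = out / "training_b" / "predictions.csv"
    if not (pa.exists() and pb.exists()):
        raise PipelineError(
            "compare stage needs predictions at training/predictions.csv and "
            "training_b/predictions.csv (train two models first)"
        )
    a = pd.read_csv(pa).sort_values("sample_id")
    b = pd.read_csv(pb).sort_values("sample_id")
    cmp_res = compare_models(a["pred"].to_numpy(), b["pred"].to_numpy(),
                             labels=a["label"].to_numpy(), alpha=config.alpha)
    payload = dataclasses.asdict(cmp_res)
    (out / "comparison.json").write_text(json.dumps(payload, indent=2))
    results["compare"] = payload
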