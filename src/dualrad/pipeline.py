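"""End-to-end pipeline: phantom -> split -> train -> segment -> radiomics ->
spectral reduction -> random-forest diagnosis.

A single flat config file (INI sections, ``key = value``) drives the run;
every stage writes its artifact into the run directory, and all randomness
derives from one global seed, so rerunning a config reproduces every CSV
byte-identically.
"""

from __future__ import annotations

import configparser
import dataclasses
import hashlib
import logging
import os
from dataclasses import dataclass, field
from typing import Dict

import numpy as np
import pandas as pd

from . import __version__
from . import autoencoder as ae
from . import classify as cl
from . import dataset_io as dio
from . import radiomics as rad
from . import spectral as sp
from .phantom import PhantomConfig, generate_cohort, write_cohort

log = logging.getLogger("dualrad")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage (and case, if any)."""


@dataclass(frozen=True)
class PipelineConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig.easy_segmentation)
    n_train: int = 40
    n_test: int = 20
    stratify: bool = True
    model_preset: str = "desk"
    train: ae.TrainConfig = field(default_factory=lambda: ae.TrainConfig(
        epochs=30, batch_size=8, lr_start=3e-3, lr_end=1e-4))
    masks: str = "predicted"          # or "ground_truth"
    n_gray_levels: int = 32
    n_components: int = 12
    k_neighbors: int = 10
    transductive: bool = False
    latent_keep: int = 4
    n_boot: int = 1000
    outdir: str = "runs/run"
    seed: int = 0

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("outdir", None)  # output location does not change the science
        return hashlib.sha1(repr(d).encode()).hexdigest()[:12]


def load_config(path: str) -> PipelineConfig:
    """Parse the flat INI config file into a PipelineConfig."""
    cp = configparser.ConfigParser()
    with open(path) as fh:
        cp.read_file(fh)
    g = cp["run"] if cp.has_section("run") else {}
    seed = int(g.get("seed", 0))
    ph = cp["phantom"] if cp.has_section("phantom") else {}
    if ph.get("preset", "") == "easy":
        phantom = PhantomConfig.easy_segmentation(
            n_benign=int(ph.get("n_benign", 30)),
            n_malignant=int(ph.get("n_malignant", 30)),
            seed=seed)
    else:
        phantom = PhantomConfig(
            image_size=int(ph.get("image_size", 64)),
            n_benign=int(ph.get("n_benign", 30)),
            n_malignant=int(ph.get("n_malignant", 30)),
            n_normal=int(ph.get("n_normal", 0)),
            speckle_scale=float(ph.get("speckle_scale", 0.4)),
            lesion_area_range=(float(ph.get("area_lo", 0.02)),
                               float(ph.get("area_hi", 0.20))),
            spiculation_amplitude=float(ph.get("spiculation_amplitude", 0.25)),
            seed=seed)
    sp_sec = cp["split"] if cp.has_section("split") else {}
    tr = cp["train"] if cp.has_section("train") else {}
    red = cp["reduce"] if cp.has_section("reduce") else {}
    clf = cp["classify"] if cp.has_section("classify") else {}
    total = phantom.n_benign + phantom.n_malignant + phantom.n_normal
    return PipelineConfig(
        phantom=phantom,
        n_train=int(sp_sec.get("n_train", (2 * total) // 3)),
        n_test=int(sp_sec.get("n_test", total - (2 * total) // 3)),
        stratify=str(sp_sec.get("stratify", "true")).lower() == "true",
        model_preset=cp.get("model", "preset", fallback="desk"),
        train=ae.TrainConfig(
            epochs=int(tr.get("epochs", 30)),
            batch_size=int(tr.get("batch_size", 8)),
            lr_start=float(tr.get("lr_start", 3e-3)),
            lr_end=float(tr.get("lr_end", 1e-4)),
            seed=seed),
        masks=cp.get("radiomics", "masks", fallback="predicted"),
        n_gray_levels=cp.getint("radiomics", "n_gray_levels", fallback=32),
        n_components=int(red.get("n_components", 12)),
        k_neighbors=int(red.get("k_neighbors", 10)),
        transductive=str(red.get("transductive", "false")).lower() == "true",
        latent_keep=cp.getint("model", "latent_keep", fallback=4),
        n_boot=int(clf.get("n_boot", 1000)),
        outdir=str(g.get("outdir", "runs/run")),
        seed=seed,
    )


def _write_csv(df: pd.DataFrame, path: str, cfg: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# dualrad {__version__} config_hash={cfg.config_hash()}\n")
        df.to_csv(fh, index=False)


def read_artifact_csv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def run_pipeline(cfg: PipelineConfig) -> Dict[str, object]:
    """Execute every stage; returns the in-memory artifacts and writes them
    under ``cfg.outdir``.  Any stage failure aborts with the stage name."""
    os.makedirs(cfg.outdir, exist_ok=True)
    handler = logging.FileHandler(os.path.join(cfg.outdir, "run.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run_stages(cfg)
    finally:
        log.removeHandler(handler)
        handler.close()


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **kw):
            log.info("stage %s: start", name)
            try:
                out = fn(*a, **kw)
            except Exception as e:
                log.error("stage %s: FAILED: %s", name, e)
                raise PipelineError(f"stage {name!r} failed: {e}") from e
            log.info("stage %s: done", name)
            return out
        return wrapped
    return deco


def _run_stages(cfg: PipelineConfig) -> Dict[str, object]:
    out = cfg.outdir
    datadir = os.path.join(out, "data")

    @_stage("phantom")
    def s_phantom():
        samples, manifest = generate_cohort(cfg.phantom)
        write_cohort(samples, manifest, datadir)
        _write_csv(manifest, os.path.join(out, "manifest.csv"), cfg)
        return samples, manifest

    samples, manifest = s_phantom()
    model_cfg = (ae.ModelConfig.desk() if cfg.model_preset == "desk"
                 else ae.ModelConfig.paper())

    @_stage("load")
    def s_load():
        return dio.load_dataset(datadir, target_size=model_cfg.input_size)

    samples = s_load()

    @_stage("split")
    def s_split():
        train, test = dio.split_dataset(samples, cfg.n_train, cfg.n_test,
                                        seed=cfg.seed, stratify=cfg.stratify)
        dio.write_split_csv(train, test, os.path.join(out, "split.csv"))
        return train, test

    train_set, test_set = s_split()

    @_stage("train")
    def s_train():
        model = ae.build_model(model_cfg, seed=cfg.seed)
        model, history = ae.train(model, train_set, val_samples=test_set,
                                  tcfg=cfg.train)
        ae.save_model(model, os.path.join(out, "model.npz"))
        _write_csv(history, os.path.join(out, "history.csv"), cfg)
        return model, history

    model, history = s_train()
    abnormal = [s for s in samples if s.label in ("benign", "malignant")]

    @_stage("segment")
    def s_segment():
        masks, latents, ids = [], [], []
        for s in abnormal:
            o = ae.predict(model, s.image)
            m = ae.binarize(o.prob_map)
            if cfg.masks == "predicted" and m.any():
                masks.append(m)
            else:
                if cfg.masks == "predicted":
                    log.warning("empty predicted mask for %s; using ground truth", s.id)
                masks.append(s.mask)
            latents.append(o.latent)
            ids.append(s.id)
        return ids, masks, np.vstack(latents)

    ids, seg_masks, latents = s_segment()

    @_stage("latent_filter")
    def s_latent():
        sel, reduced = ae.filter_latent(latents, k=cfg.latent_keep)
        df = pd.DataFrame(reduced, columns=[f"latent_{j}" for j in sel])
        df.insert(0, "id", ids)
        _write_csv(df, os.path.join(out, "latent.csv"), cfg)
        return sel, reduced

    latent_sel, X_deep = s_latent()

    @_stage("radiomics")
    def s_radiomics():
        feats = rad.extract_cohort_features(
            abnormal, cfg=rad.RadiomicsConfig(n_gray_levels=cfg.n_gray_levels),
            masks=seg_masks)
        _write_csv(feats, os.path.join(out, "features.csv"), cfg)
        return feats

    features = s_radiomics()
    feat_cols = [c for c in features.columns if c not in ("id", "label")]
    X_raw = features[feat_cols].to_numpy(float)
    y = (features["label"] == "malignant").to_numpy(int)

    @_stage("reduce")
    def s_reduce():
        emb = sp.embed_radiomics(X_raw, n_components=cfg.n_components,
                                 k_neighbors=cfg.k_neighbors)
        df = pd.DataFrame(emb.embedding,
                          columns=[f"spectral_{j+1}" for j in range(cfg.n_components)])
        df.insert(0, "id", features["id"].to_numpy())
        _write_csv(df, os.path.join(out, "embedded.csv"), cfg)
        return emb

    emb = s_reduce()

    @_stage("classify")
    def s_classify():
        if cfg.transductive:
            X_conv = emb.embedding
            ft = None
        else:
            X_conv = X_raw
            ft = make_inductive_reducer(cfg.n_components, cfg.k_neighbors)
        results = cl.grid_evaluate(X_conv, X_deep, y,
                                   conv_fold_transform=ft,
                                   n_boot=cfg.n_boot, boot_seed=cfg.seed)
        _write_csv(results, os.path.join(out, "results.csv"), cfg)
        return results

    results = s_classify()

    @_stage("wilcoxon")
    def s_wilcoxon():
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            wt = cl.per_feature_wilcoxon(X_raw, y)
        wt.insert(0, "feature", feat_cols)
        _write_csv(wt, os.path.join(out, "wilcoxon.csv"), cfg)
        return wt

    wilcoxon = s_wilcoxon()
    return {
        "samples": samples, "manifest": manifest, "history": history,
        "model": model, "latent_selected": latent_sel, "X_deep": X_deep,
        "features": features, "embedding": emb, "results": results,
        "wilcoxon": wilcoxon, "labels": y,
    }


def make_inductive_reducer(n_components: int = 12, k_neighbors: int = 10
                           ) -> cl.FoldTransform:
    """Per-fold transform: fit the eigenmap on the training rows only and
    place the left-out case by Nystrom extension (no leakage).

    Folds recur across hyperparameter settings, so fitted embeddings are
    memoized on the training-matrix content."""
    cache: Dict[bytes, sp.NystromEmbedder] = {}

    def ft(X_train: np.ndarray, X_test: np.ndarray):
        key = hashlib.sha1(np.ascontiguousarray(X_train).tobytes()).digest()
        emb = cache.get(key)
        if emb is None:
            emb = sp.NystromEmbedder(n_components=n_components,
                                     k_neighbors=min(k_neighbors, len(X_train) - 1))
            emb.fit(X_train)
            cache[key] = emb
        return emb.embedding_, emb.transform(X_test)
    return ft


# ---------------------------------------------------------------------------
# Desk-scale segmentation benchmark
# ---------------------------------------------------------------------------

def segmentation_benchmark(seed: int = 0, n_train: int = 60, n_holdout: int = 30,
                           epochs: int = 30) -> Dict[str, float]:
    """Train the desk-preset autoencoder on easy phantoms and report the mean
    hard Dice on the training set and on a freshly generated held-out set.

    This is the package's scaled-down analog of full-size segmentation
    training: 64x64 images, 8 base filters, 30 epochs, one CPU.
    """
    cfg = PhantomConfig.easy_segmentation(
        n_benign=n_train // 2, n_malignant=n_train - n_train // 2, seed=seed)
    train_samples, _ = generate_cohort(cfg)
    hold_cfg = cfg.replace(seed=seed + 10_000,
                           n_benign=n_holdout // 2,
                           n_malignant=n_holdout - n_holdout // 2)
    holdout, _ = generate_cohort(hold_cfg)
    model = ae.build_model(ae.ModelConfig.desk(), seed=seed)
    tcfg = ae.TrainConfig(epochs=epochs, batch_size=8,
                          lr_start=3e-3, lr_end=1e-4, seed=seed)
    model, history = ae.train(model, train_samples, tcfg=tcfg)
    return {
        "train_dice": ae.evaluate_dice(model, train_samples),
        "holdout_dice": ae.evaluate_dice(model, holdout),
        "final_soft_dice": float(history["train_dice"].iloc[-1]),
    }
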