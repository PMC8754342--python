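"""Config-driven orchestration of the full analysis pipeline.

Stages (simulate -> segment -> classify -> preprocess -> train -> encode ->
cluster -> interpret -> dynamics -> report) each read the previous stage's
artifacts from the output directory and write their own, recording every
output in a manifest with a hash of the parameters that produced it.
Reruns with an identical config and seed reproduce the CSV outputs.
"""

from __future__ import annotations

import hashlib
import json
import pickle
from pathlib import Path

import numpy as np
import pandas as pd

from . import (CellCrop, CellPhenotypeSpec, CropCanonicalizer, KNNLouvain,
               MarkovModel, SceneSpec, VAEEncoder, classify_viability,
               combine_latents, cut_crops, embed_umap, exaggerate_features,
               link_pairs, make_crop_dataset, morphometrics,
               population_dynamics, segment_frame, simulate_movie,
               train_labelfree, train_viability, transition_matrix, velocities,
               zscore_matrix)

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline", "STAGES"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "condition": "control",
    "simulate": {
        "frame_shape": [192, 192],
        "n_cells": 6,
        "n_frames": 6,
        "minutes_per_frame": 3.0,
        "um_per_px": 0.325,
        "step_sd": [1.5, 1.5],
        "exclusion_radius": 34.0,
        "transition_matrix": [[0.9, 0.1], [0.1, 0.9]],
        "phenotypes": [
            {"class_id": 0, "area_mean": 220, "area_sd": 20,
             "eccentricity_mean": 0.25, "eccentricity_sd": 0.05,
             "edge_contrast": 0.3, "granule_density": 0.0},
            {"class_id": 1, "area_mean": 420, "area_sd": 30,
             "eccentricity_mean": 0.75, "eccentricity_sd": 0.05,
             "edge_contrast": 0.12, "granule_density": 0.05},
        ],
    },
    "segment": {"labelfree_steps": 200, "patch_size": 32,
                "min_area": 40, "max_area": 4000, "crop_size": 63},
    "classify": {"enabled": True, "steps": 600, "threshold": 0.5,
                 "n_train_per_class": 40},
    "preprocess": {"size": 64},
    "train": {"latent_dim": 16, "hidden": 128, "gamma": 0.9, "a": 1.0,
              "steps": 400, "batch_size": 32, "lr": 1e-3},
    "encode": {"w": 0.5},
    "cluster": {"knn_k": 10, "resolution": 1.0, "merge_map": None,
                "umap_neighbors": 10, "min_dist": 0.1},
    "dynamics": {"d0": None, "d1": 12.0, "endpoint_fraction": 0.25},
}

STAGES = ["simulate", "segment", "classify", "preprocess", "train",
          "encode", "cluster", "interpret", "dynamics", "report"]

_DEAD_SPEC = dict(area_mean=120, area_sd=25, eccentricity_mean=0.5,
                  eccentricity_sd=0.15, edge_contrast=0.02,
                  granule_density=0.25, granule_darkness=0.35,
                  interior_level=-0.25)


def _deep_merge(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    cfg = DEFAULT_CONFIG
    if path is not None:
        import yaml

        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _deep_merge(cfg, user)
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    return cfg


def _hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True,
                                     default=str).encode()).hexdigest()[:12]


class _Run:
    """Output directory with a manifest and a plain-text run log."""

    def __init__(self, out_dir, config: dict):
        self.dir = Path(out_dir)
        self.dir.mkdir(parents=True, exist_ok=True)
        self.config = config
        self.manifest_path = self.dir / "manifest.json"
        self.manifest = json.loads(self.manifest_path.read_text()) \
            if self.manifest_path.exists() else {}

    def log(self, msg: str) -> None:
        with open(self.dir / "run.log", "a") as fh:
            fh.write(msg + "\n")

    def record(self, stage: str, outputs: list[str], **info) -> None:
        self.manifest[stage] = {
            "outputs": outputs,
            "config_hash": _hash({**self.config.get(stage, {}),
                                  "seed": self.config["seed"]}),
            **info,
        }
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2))
        self.log(f"[{stage}] outputs={outputs} info={info}")

    def need(self, stage: str, filename: str) -> Path:
        path = self.dir / filename
        if not path.exists():
            raise FileNotFoundError(
                f"stage requires '{path}' — run the '{stage}' stage first")
        return path


def _specs(cfg) -> list[CellPhenotypeSpec]:
    return [CellPhenotypeSpec(**p) for p in cfg["simulate"]["phenotypes"]]


def _load_crops(path) -> list[CellCrop]:
    data = np.load(path, allow_pickle=False)
    return [CellCrop(img, msk, (float(cy), float(cx)), frame=int(f),
                     condition=str(cond), crop_id=int(cid))
            for img, msk, cy, cx, f, cond, cid in zip(
                data["images"], data["masks"], data["cy"], data["cx"],
                data["frame"], data["condition"], data["crop_id"])]


def _save_crops(path, crops: list[CellCrop]) -> None:
    np.savez_compressed(
        path,
        images=np.stack([c.image for c in crops]),
        masks=np.stack([c.mask for c in crops]),
        cy=np.array([c.centroid[0] for c in crops]),
        cx=np.array([c.centroid[1] for c in crops]),
        frame=np.array([c.frame for c in crops]),
        condition=np.array([c.condition for c in crops]),
        crop_id=np.array([c.crop_id for c in crops]))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(run: _Run) -> None:
    cfg = run.config["simulate"]
    scene = SceneSpec(frame_shape=tuple(cfg["frame_shape"]),
                      n_cells=cfg["n_cells"],
                      um_per_px=cfg["um_per_px"],
                      minutes_per_frame=cfg["minutes_per_frame"],
                      step_sd=tuple(cfg["step_sd"]),
                      exclusion_radius=cfg["exclusion_radius"])
    model = MarkovModel(np.asarray(cfg["transition_matrix"], dtype=float))
    bf, fl, tracks = simulate_movie(scene, model, _specs(run.config),
                                    cfg["n_frames"], seed=run.config["seed"])
    from .synthetic import write_movie_tiff

    write_movie_tiff(run.dir / "movie_bf.tif", bf)
    write_movie_tiff(run.dir / "movie_fluor.tif", fl)
    tracks.to_csv(run.dir / "tracks.csv", index=False)
    run.record("simulate", ["movie_bf.tif", "movie_fluor.tif", "tracks.csv"],
               n_cells=cfg["n_cells"], n_frames=cfg["n_frames"])


def _read_stack(path) -> np.ndarray:
    import tifffile

    stack = tifffile.imread(path).astype(float)
    return stack / np.iinfo(np.uint16).max if stack.max() > 1.5 else stack


def stage_segment(run: _Run) -> None:
    cfg = run.config["segment"]
    bf = _read_stack(run.need("simulate", "movie_bf.tif"))
    fl = _read_stack(run.need("simulate", "movie_fluor.tif"))
    model = train_labelfree(list(zip(bf, fl)), steps=cfg["labelfree_steps"],
                            seed=run.config["seed"],
                            patch_size=cfg["patch_size"])
    rows, crops = [], []
    for t, frame in enumerate(bf):
        pred = model.predict(frame)
        dets = segment_frame(pred, min_area=cfg["min_area"],
                             max_area=cfg["max_area"])
        for d in dets:
            d.frame = t
        frame_crops = cut_crops(frame, dets, crop_size=cfg["crop_size"],
                                frame_index=t,
                                condition=run.config["condition"])
        for d, c in zip(dets, frame_crops):
            c.crop_id = len(crops)
            rows.append((t, c.crop_id, d.centroid[0], d.centroid[1], d.area,
                         d.touches_border))
            crops.append(c)
    det_df = pd.DataFrame(rows, columns=["frame", "cell_id", "y", "x", "area",
                                         "touches_border"])
    det_df.to_csv(run.dir / "detections.csv", index=False)
    _save_crops(run.dir / "crops.npz", crops)
    with open(run.dir / "labelfree_model.pkl", "wb") as fh:
        pickle.dump(model, fh)
    run.record("segment", ["detections.csv", "crops.npz",
                           "labelfree_model.pkl"], n_detections=len(det_df))


def stage_classify(run: _Run) -> None:
    cfg = run.config["classify"]
    crops = _load_crops(run.need("segment", "crops.npz"))
    if not cfg.get("enabled", True):
        kept = crops
        table = pd.DataFrame({"crop_id": [c.crop_id for c in crops],
                              "score": 1.0, "label": "Live"})
    else:
        size = crops[0].image.shape[0]
        live_specs = _specs(run.config)
        dead_spec = CellPhenotypeSpec(class_id=-1, **_DEAD_SPEC)
        n = cfg["n_train_per_class"]
        live, _ = make_crop_dataset(live_specs, max(1, n // len(live_specs)),
                                    seed=run.config["seed"], patch_size=size)
        dead, _ = make_crop_dataset([dead_spec], n,
                                    seed=run.config["seed"] + 1,
                                    patch_size=size)
        X = live + dead
        y = np.array([1] * len(live) + [0] * len(dead))
        clf = train_viability(X, y, steps=cfg["steps"],
                              seed=run.config["seed"])
        table = classify_viability(clf, crops, threshold=cfg["threshold"])
        keep_ids = set(table.loc[table["label"] == "Live", "crop_id"])
        kept = [c for c in crops if c.crop_id in keep_ids]
        if not kept:
            raise RuntimeError(
                "viability screening discarded every crop; increase "
                "classify.steps or lower classify.threshold")
    table.to_csv(run.dir / "viability.csv", index=False)
    _save_crops(run.dir / "crops_live.npz", kept)
    run.record("classify", ["viability.csv", "crops_live.npz"],
               n_in=len(crops), n_live=len(kept),
               n_discarded=len(crops) - len(kept))


def stage_preprocess(run: _Run) -> None:
    cfg = run.config["preprocess"]
    crops = _load_crops(run.need("classify", "crops_live.npz"))
    canon = CropCanonicalizer(size=cfg["size"])
    masks, textures = canon.transform(crops)
    np.savez_compressed(run.dir / "canonical.npz", masks=masks,
                        textures=textures,
                        crop_id=np.array([c.crop_id for c in crops]))
    pd.DataFrame(canon.poses_, columns=["crop_id", "rotation_deg", "flip_v",
                                        "flip_h", "scale", "degenerate"]) \
        .to_csv(run.dir / "poses.csv", index=False)
    run.record("preprocess", ["canonical.npz", "poses.csv"], n=len(crops))


def _twin_cfgs(run):
    t = run.config["train"]
    common = dict(latent_dim=t["latent_dim"], hidden=t["hidden"],
                  gamma=t["gamma"], a=t["a"], steps=t["steps"],
                  batch_size=t["batch_size"], lr=t["lr"])
    return (VAEEncoder(seed=run.config["seed"], **common),
            VAEEncoder(seed=run.config["seed"] + 1, **common))


def stage_train(run: _Run) -> None:
    data = np.load(run.need("preprocess", "canonical.npz"))
    shape_vae, texture_vae = _twin_cfgs(run)
    shape_vae.fit(data["masks"])
    texture_vae.fit(data["textures"])
    with open(run.dir / "vae_shape.pkl", "wb") as fh:
        pickle.dump(shape_vae, fh)
    with open(run.dir / "vae_texture.pkl", "wb") as fh:
        pickle.dump(texture_vae, fh)
    run.record("train", ["vae_shape.pkl", "vae_texture.pkl"],
               final_shape_loss=shape_vae.loss_history_[-1],
               final_texture_loss=texture_vae.loss_history_[-1])


def stage_encode(run: _Run) -> None:
    data = np.load(run.need("preprocess", "canonical.npz"))
    with open(run.need("train", "vae_shape.pkl"), "rb") as fh:
        shape_vae = pickle.load(fh)
    with open(run.need("train", "vae_texture.pkl"), "rb") as fh:
        texture_vae = pickle.load(fh)
    z_shape = shape_vae.transform(data["masks"])
    z_texture = texture_vae.transform(data["textures"])
    w = run.config["encode"]["w"]
    fused = combine_latents(z_shape, z_texture, w)
    for name, Z in [("latents_shape", z_shape), ("latents_texture", z_texture),
                    ("latents_fused", fused)]:
        df = pd.DataFrame(Z, columns=[f"z_{i}" for i in range(Z.shape[1])])
        df.insert(0, "crop_id", data["crop_id"])
        df.to_csv(run.dir / f"{name}.csv", index=False)
    run.record("encode", ["latents_shape.csv", "latents_texture.csv",
                          "latents_fused.csv"], w=w)


def stage_cluster(run: _Run) -> None:
    cfg = run.config["cluster"]
    fused = pd.read_csv(run.need("encode", "latents_fused.csv"))
    crops = _load_crops(run.need("classify", "crops_live.npz"))
    Z = fused.drop(columns="crop_id").to_numpy()
    merge_map = cfg.get("merge_map")
    if merge_map:
        merge_map = {int(k): int(v) for k, v in merge_map.items()}
    labels = KNNLouvain(knn_k=min(cfg["knn_k"], len(Z) - 1),
                        resolution=cfg["resolution"],
                        seed=run.config["seed"],
                        merge_map=merge_map).fit_predict(Z)
    coords = embed_umap(Z, n_neighbors=min(cfg["umap_neighbors"], len(Z) - 1),
                        min_dist=cfg["min_dist"], seed=run.config["seed"])
    um = run.config["simulate"]["um_per_px"]
    morph = [morphometrics(c.mask, c.image) if c.mask.any()
             else {"area": 0.0, "eccentricity": 0.0, "edge_strength": 0.0}
             for c in crops]
    table = pd.DataFrame({
        "crop_id": fused["crop_id"],
        "frame": [c.frame for c in crops],
        "condition": [c.condition for c in crops],
        "cluster": labels,
        "umap_x": coords[:, 0],
        "umap_y": coords[:, 1],
        "area_px2": [m["area"] for m in morph],
        "area_um2": [m["area"] * um**2 for m in morph],
        "eccentricity": [m["eccentricity"] for m in morph],
        "edge_strength": [m["edge_strength"] for m in morph],
    })
    table.to_csv(run.dir / "state_table.csv", index=False)
    run.record("cluster", ["state_table.csv"],
               n_clusters=int(labels.max()) + 1)


def stage_interpret(run: _Run) -> None:
    fused = pd.read_csv(run.need("encode", "latents_fused.csv"))
    table = pd.read_csv(run.need("cluster", "state_table.csv"))
    Z = fused.drop(columns="crop_id").to_numpy()
    zs, cluster_ids, row_order, col_order = zscore_matrix(
        Z, table["cluster"].to_numpy())
    pd.DataFrame(zs, index=[f"C{c}" for c in cluster_ids]) \
        .to_csv(run.dir / "zscores.csv")
    with open(run.need("train", "vae_shape.pkl"), "rb") as fh:
        shape_vae = pickle.load(fh)
    z_shape = pd.read_csv(run.dir / "latents_shape.csv") \
        .drop(columns="crop_id").to_numpy()
    mean_latent = z_shape.mean(axis=0)
    J = z_shape.shape[1]
    top = np.argsort(-np.abs(zs[:, :J]).max(axis=0))[:4]
    decoded, diff = exaggerate_features(shape_vae, mean_latent, top, 2.0)
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(9, 3))
    base = shape_vae.inverse_transform(mean_latent[None, :])[0]
    for ax, img, title in zip(axes, [base, decoded, diff],
                              ["mean decoding", "exaggerated", "difference"]):
        ax.imshow(img, cmap="gray")
        ax.set_title(title)
        ax.axis("off")
    fig.savefig(run.dir / "feature_decoding.png", dpi=100)
    plt.close(fig)
    fig, ax = plt.subplots(figsize=(5, 4))
    sc = ax.scatter(table["umap_x"], table["umap_y"], c=table["cluster"],
                    cmap="tab10", s=8)
    fig.colorbar(sc, label="cluster")
    fig.savefig(run.dir / "umap_clusters.png", dpi=100)
    plt.close(fig)
    run.record("interpret", ["zscores.csv", "feature_decoding.png",
                             "umap_clusters.png"])


def stage_dynamics(run: _Run) -> None:
    cfg = run.config["dynamics"]
    dets = pd.read_csv(run.need("segment", "detections.csv"))
    table = pd.read_csv(run.need("cluster", "state_table.csv"))
    labels = table.rename(columns={"crop_id": "cell_id"})[
        ["frame", "cell_id", "cluster"]]
    d0 = cfg["d0"] or suggest_d0_safe(dets)
    linkset = link_pairs(dets, d0=d0, d1=cfg["d1"])
    linkset.links.to_csv(run.dir / "links.csv", index=False)
    tm = transition_matrix(linkset, labels,
                           frame_interval_min=run.config["simulate"][
                               "minutes_per_frame"])
    pd.DataFrame(tm.P).to_csv(run.dir / "transition_matrix.csv", index=False)
    pd.DataFrame(tm.counts).to_csv(run.dir / "transition_counts.csv",
                                   index=False)
    per_link, summary = velocities(
        linkset, run.config["simulate"]["minutes_per_frame"],
        um_per_px=run.config["simulate"]["um_per_px"], labels=labels)
    per_link.to_csv(run.dir / "velocities.csv", index=False)
    fractions, test = population_dynamics(
        table, endpoint_fraction=cfg["endpoint_fraction"])
    fractions.to_csv(run.dir / "population_fractions.csv")
    if test is not None:
        (run.dir / "condition_test.json").write_text(json.dumps(test))
    run.record("dynamics", ["links.csv", "transition_matrix.csv",
                            "transition_counts.csv", "velocities.csv",
                            "population_fractions.csv"],
               n_links=len(linkset), d0=d0, d1=cfg["d1"])


def suggest_d0_safe(dets) -> float:
    from .dynamics import suggest_d0

    try:
        return suggest_d0(dets)
    except ValueError:
        return 10.0


def stage_report(run: _Run) -> None:
    summary = {stage: info for stage, info in run.manifest.items()}
    (run.dir / "report.json").write_text(json.dumps(summary, indent=2))
    run.record("report", ["report.json"])


_STAGE_FUNCS = {
    "simulate": stage_simulate, "segment": stage_segment,
    "classify": stage_classify, "preprocess": stage_preprocess,
    "train": stage_train, "encode": stage_encode, "cluster": stage_cluster,
    "interpret": stage_interpret, "dynamics": stage_dynamics,
    "report": stage_report,
}


def run_pipeline(config: dict, out_dir, stages=None) -> Path:
    """Run the requested stages (default: all) into ``out_dir``."""
    run = _Run(out_dir, config)
    run.log(f"seed={config['seed']}")
    for stage in (stages or STAGES):
        if stage not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {stage!r}")
        _STAGE_FUNCS[stage](run)
    return run.dir
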