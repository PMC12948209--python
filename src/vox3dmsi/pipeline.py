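"""End-to-end orchestration: reconstruct → segment → objects → stats.

A declarative :class:`RunConfig` (YAML on disk) drives the whole chain;
every intermediate is written to the output directory together with a
provenance record (config echo + hash, seeds, package version, per-stage
wall time), and runs are idempotent for fixed seeds.

Leaf→region assignment is scriptable: either an explicit leaf id → name
map, or marker-guided auto-assignment (per region a marker m/z whose
relative centroid intensity decides the leaf's name; leaves whose total
centroid intensity is near zero become background).
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import (FeatureAxis, SerialSectionDataset, read_dataset,
                 write_volume_nrrd)
from .objects import (classify_size, object_geometry, object_profiles,
                      pick_objects)
from .phantom import PhantomSpec, generate_phantom
from .reconstruct import (FeatureVolume, assemble_volume,
                          interslice_correlation, stack_dataset)
from .segment import assign_regions, bisecting_kmeans
from .stats import differential_test, volcano_table

__all__ = ["RunConfig", "run_pipeline", "qc_report",
           "infer_region_mapping", "segment_volume"]


class ConfigError(ValueError):
    """The run configuration fails validation."""


@dataclass
class RunConfig:
    """Declarative parameters of one pipeline run."""

    manifest: str | None = None
    landmark_mz: float = 200.0
    mz_values: tuple[float, ...] | None = None
    tolerance_ppm: float = 10.0
    pixel_size_um: float = 20.0
    thickness_um: float = 20.0
    # registration
    max_iters: int = 400
    metric: str = "ncc"
    reference: str = "chain"
    # segmentation
    n_leaves: int = 3
    seed: int = 0
    leaf_region_map: dict[int, str] | None = None
    region_markers: dict[str, float] | None = None
    # objects
    object_region: str = "fibroblast"
    connectivity: int = 26
    size_lower: int = 10
    size_upper: int = 100
    # stats
    group_a: str = "V2"
    group_b: str = "V3"
    alpha: float = 0.01
    lfc_threshold: float = 1.0
    test: str = "welch"
    # output
    outdir: str = "run_out"

    def validate(self) -> None:
        if self.manifest is not None and not os.path.exists(self.manifest):
            raise ConfigError(f"manifest not found: {self.manifest}")
        if self.leaf_region_map is None and self.region_markers is None:
            raise ConfigError(
                "either leaf_region_map or region_markers must be given")
        if self.leaf_region_map is not None:
            missing = sorted(set(range(self.n_leaves))
                             - {int(k) for k in self.leaf_region_map})
            if missing:
                raise ConfigError(
                    f"leaf_region_map misses leaf ids {missing}")
        if self.connectivity not in (6, 18, 26):
            raise ConfigError("connectivity must be 6, 18 or 26")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must be in (0, 1)")
        if self.size_lower >= self.size_upper:
            raise ConfigError("size_lower must be below size_upper")
        if self.max_iters < 1 or self.n_leaves < 1:
            raise ConfigError("max_iters and n_leaves must be positive")
        if self.test not in ("welch", "student"):
            raise ConfigError("test must be 'welch' or 'student'")
        if self.reference not in ("chain", "middle"):
            raise ConfigError("reference must be 'chain' or 'middle'")
        if self.metric not in ("ncc", "mi"):
            raise ConfigError("metric must be 'ncc' or 'mi'")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.leaf_region_map is not None:
            cfg.leaf_region_map = {int(k): v
                                   for k, v in cfg.leaf_region_map.items()}
        return cfg

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def sha256(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


# --------------------------------------------------------------------------
# segmentation over a volume
# --------------------------------------------------------------------------

def segment_volume(
    volume: FeatureVolume,
    n_leaves: int,
    seed: int = 0,
):
    """Cluster foreground voxels of a volume by bisecting k-means.

    Voxel spectra are RMS-normalized per voxel before clustering (the
    correlation-distance metric then sees shape only).  Returns
    ``(tree, member_index)`` where *member_index* are the (z, y, x)
    coordinate arrays of the clustered voxels.
    """
    member_index = np.nonzero(volume.masks)
    members = volume.data[member_index]
    rms = np.sqrt(np.mean(members ** 2, axis=1, keepdims=True))
    rms[rms == 0] = 1.0
    tree = bisecting_kmeans(members / rms, n_leaves, seed=seed)
    # keep raw-space centroids for marker-guided naming
    raw_centroids = [members[tree.leaf_labels == lid].mean(axis=0)
                     for lid in range(tree.n_leaves)]
    for lid, node in enumerate(tree.leaves):
        node.centroid = raw_centroids[lid]
    return tree, member_index


def infer_region_mapping(
    tree,
    axis: FeatureAxis,
    region_markers: dict[str, float],
    background_fraction: float = 0.1,
) -> dict[int, str]:
    """Name leaves from marker channels.

    A leaf whose total centroid intensity is below *background_fraction*
    of the strongest leaf's total becomes "background".  Every other
    leaf gets the region whose marker channel is the largest fraction of
    that leaf's centroid, relative to the across-leaf mean of that
    fraction (so a universally strong channel does not dominate).
    """
    cents = tree.leaf_centroids()
    totals = cents.sum(axis=1)
    idx = {r: axis.index_of(mz) for r, mz in region_markers.items()}
    frac = cents / np.maximum(totals[:, None], 1e-12)
    mapping: dict[int, str] = {}
    rel = {r: frac[:, i] / np.maximum(frac[:, i].mean(), 1e-12)
           for r, i in idx.items()}
    for lid in range(len(cents)):
        if totals[lid] < background_fraction * totals.max():
            mapping[lid] = "background"
            continue
        mapping[lid] = max(rel, key=lambda r: rel[r][lid])
    return mapping


# --------------------------------------------------------------------------
# run
# --------------------------------------------------------------------------

def run_pipeline(
    config: RunConfig,
    dataset: SerialSectionDataset | None = None,
) -> dict:
    """Execute all stages and write every intermediate plus provenance.

    A pre-built *dataset* bypasses manifest reading (used by the
    simulate→analyse flow and by tests); otherwise the manifest and
    feature list in *config* are read from disk.
    """
    config.validate()
    if dataset is None:
        if config.manifest is None or config.mz_values is None:
            raise ConfigError("manifest and mz_values required without "
                              "an in-memory dataset")
        axis = FeatureAxis(tuple(config.mz_values), config.tolerance_ppm)
        dataset = read_dataset(config.manifest, axis,
                               pixel_size_um=config.pixel_size_um,
                               thickness_um=config.thickness_um)
    os.makedirs(config.outdir, exist_ok=True)
    record: dict = {
        "config": asdict(config),
        "config_sha256": config.sha256(),
        "package_version": __version__,
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }

    def out(name: str) -> str:
        path = os.path.join(config.outdir, name)
        record["outputs"][name] = path
        return path

    def stage(name):
        record["stages"][name] = {"start": time.time()}
        return record["stages"][name]

    # ---- reconstruction -------------------------------------------------
    st = stage("reconstruct")
    before = interslice_correlation(assemble_volume(dataset),
                                    config.landmark_mz)
    volume = stack_dataset(dataset, config.landmark_mz,
                           max_iters=config.max_iters,
                           reference=config.reference,
                           metric=config.metric)
    after = interslice_correlation(volume, config.landmark_mz)
    st["wall_s"] = time.time() - st.pop("start")
    write_volume_nrrd(volume.channel(config.landmark_mz),
                      out("landmark_volume.nrrd"), dataset.voxel_um)
    pd.DataFrame(
        [{"z_index": i, "theta_deg": t.theta_deg, "tx_px": t.tx_px,
          "ty_px": t.ty_px} for i, t in enumerate(volume.transforms_applied)]
    ).to_csv(out("transforms.tsv"), sep="\t", index=False)
    qc = pd.DataFrame({
        "pair": [f"{i}-{j}" for i, j, _ in before["pairs"]],
        "r_before": [r for _, _, r in before["pairs"]],
        "r_after": [r for _, _, r in after["pairs"]],
    })
    qc.to_csv(out("qc_correlations.tsv"), sep="\t", index=False)
    record["qc"] = {
        "corr_before_mean": before["mean"], "corr_before_sd": before["sd"],
        "corr_after_mean": after["mean"], "corr_after_sd": after["sd"],
    }

    # ---- segmentation ---------------------------------------------------
    st = stage("segment")
    tree, member_index = segment_volume(volume, config.n_leaves, config.seed)
    if config.leaf_region_map is not None:
        mapping = {int(k): v for k, v in config.leaf_region_map.items()}
    else:
        mapping = infer_region_mapping(tree, dataset.feature_axis,
                                       config.region_markers)
    labels, region_ids = assign_regions(
        tree, mapping, geometry=volume.masks.shape,
        member_index=member_index)
    st["wall_s"] = time.time() - st.pop("start")
    write_volume_nrrd(labels.astype(np.int16), out("region_labels.nrrd"),
                      dataset.voxel_um)
    record["segmentation"] = {"leaf_region_map": {str(k): v for k, v
                                                  in mapping.items()},
                              "region_ids": region_ids}

    # ---- objects --------------------------------------------------------
    st = stage("objects")
    if config.object_region not in region_ids:
        raise ConfigError(
            f"object_region {config.object_region!r} is not among the "
            f"assigned regions {sorted(region_ids)}")
    target_mask = labels == region_ids[config.object_region]
    objects = pick_objects(target_mask, config.connectivity,
                           dataset.voxel_um)
    classify_size(objects, config.size_lower, config.size_upper)
    object_geometry(objects)
    profiles = object_profiles(objects, volume.data)
    st["wall_s"] = time.time() - st.pop("start")
    write_volume_nrrd(objects.labels.astype(np.int32),
                      out("object_labels.nrrd"), dataset.voxel_um)
    objects.table.to_csv(out("objects.tsv"), sep="\t", index=False)
    profiles.to_csv(out("object_profiles.tsv"), sep="\t", index=False)

    # ---- statistics -----------------------------------------------------
    st = stage("stats")
    ga = profiles[profiles["group"] == config.group_a]
    gb = profiles[profiles["group"] == config.group_b]
    volcano = None
    if len(ga) >= 2 and len(gb) >= 2:
        result = differential_test(
            ga, gb, mz=dataset.feature_axis.array,
            alpha=config.alpha, lfc_threshold=config.lfc_threshold,
            test=config.test)
        table, selected = volcano_table(result)
        table.to_csv(out("volcano.tsv"), sep="\t", index=False)
        selected.to_csv(out("volcano_selected.tsv"), sep="\t", index=False)
        volcano = table
        record["stats"] = {
            "n_a": int(len(ga)), "n_b": int(len(gb)),
            "n_significant": int(table["significant"].sum()),
        }
    else:
        record["stats"] = {"n_a": int(len(ga)), "n_b": int(len(gb)),
                           "skipped": "fewer than 2 objects in a group"}
    st["wall_s"] = time.time() - st.pop("start")

    with open(out("run_record.json"), "w") as fh:
        json.dump(record, fh, indent=2, default=str)
    record["_volume"] = volume
    record["_objects"] = objects
    record["_profiles"] = profiles
    record["_volcano"] = volcano
    return record


def qc_report(record: dict, path: str | None = None) -> pd.DataFrame:
    """Tabular QC report: correlations, transform magnitudes, sizes.

    One row per adjacent slice pair (correlation before/after) plus the
    transform magnitude per slice and the object size histogram appended
    as separate blocks when written to *path*.
    """
    outdir = record["outputs"].get("qc_correlations.tsv")
    qc = pd.read_csv(outdir, sep="\t")
    tf = pd.read_csv(record["outputs"]["transforms.tsv"], sep="\t")
    tf["translation_px"] = np.hypot(tf["tx_px"], tf["ty_px"])
    objects = pd.read_csv(record["outputs"]["objects.tsv"], sep="\t")
    hist = (objects["size_class"].value_counts().rename("n")
            .rename_axis("size_class").reset_index()
            if len(objects) else pd.DataFrame())
    if path is not None:
        with open(path, "w") as fh:
            fh.write("# inter-slice landmark correlation (before/after)\n")
            qc.to_csv(fh, sep="\t", index=False)
            fh.write("\n# per-slice transform magnitude\n")
            tf.to_csv(fh, sep="\t", index=False)
            fh.write("\n# object size histogram\n")
            hist.to_csv(fh, sep="\t", index=False)
    return qc


def simulate_to_disk(spec: PhantomSpec, outdir: str) -> dict:
    """Write a phantom as per-section imzML + manifest + truth files."""
    from .io import write_manifest, write_section_imzml

    dataset, truth = generate_phantom(spec)
    os.makedirs(outdir, exist_ok=True)
    rows = []
    for s in dataset.sections:
        name = f"section_{s.z_index:03d}.imzML"
        write_section_imzml(s, dataset.feature_axis,
                            os.path.join(outdir, name))
        rows.append({"sample_id": dataset.sample_id, "z_index": s.z_index,
                     "path": name})
    manifest = os.path.join(outdir, "manifest.tsv")
    write_manifest(manifest, rows)
    write_volume_nrrd(truth.region_volume.astype(np.int16),
                      os.path.join(outdir, "truth_regions.nrrd"),
                      truth.voxel_um)
    pd.DataFrame(
        [{"z_index": i, "theta_deg": t.theta_deg, "tx_px": t.tx_px,
          "ty_px": t.ty_px} for i, t in enumerate(truth.transforms)]
    ).to_csv(os.path.join(outdir, "truth_transforms.tsv"), sep="\t",
             index=False)
    pd.DataFrame(
        [{"feature_index": k, "mz": dataset.feature_axis.mz_values[k],
          "log2_fc": v} for k, v in sorted(truth.planted_effects.items())]
    ).to_csv(os.path.join(outdir, "truth_effects.tsv"), sep="\t",
             index=False)
    pd.DataFrame(truth.object_catalog).to_csv(
        os.path.join(outdir, "truth_objects.tsv"), sep="\t", index=False)
    return {"manifest": manifest, "dataset": dataset, "truth": truth}
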