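"""Self-contained validation experiments on synthetic phantoms.

Each routine generates its own inputs from a seed, runs one part of the
pipeline, and measures how well the known ground truth is recovered:
registration transform recovery, the before/after inter-slice
correlation gain, agreement of the object picker with an independent
flood-fill labeling, voxelated-sphere shape fidelity, calibration of
the testing layer (Benjamini-Hochberg step-up, Welch type-I error,
detection power), and the end-to-end biculture workflow.  The
acceptance script and the acceptance test suite both run these.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .objects import (classify_size, object_geometry, object_profiles,
                      pick_objects, voxelated_sphere)
from .phantom import (PhantomSpec, catalog_truth_objects, flood_fill_label,
                      generate_phantom)
from .pipeline import RunConfig, run_pipeline
from .reconstruct import assemble_volume, interslice_correlation, stack_dataset
from .stats import differential_test

__all__ = [
    "single_voxel_volume_um3",
    "registration_recovery",
    "qc_improvement",
    "picking_oracle_agreement",
    "sphere_fidelity",
    "bh_oracle_agreement",
    "welch_type_one_error",
    "detection_power",
    "end_to_end_biculture",
]


def single_voxel_volume_um3(voxel_um=(20.0, 20.0, 20.0)) -> float:
    """Volume reported for a single voxel at the standard raster."""
    objs = pick_objects(np.ones((1, 1, 1), bool), voxel_um=voxel_um)
    return float(object_geometry(objs, voxel_um)["volume_um3"].iloc[0])


def registration_recovery(
    n_phantoms: int = 20,
    seed: int = 0,
    tol_px: float = 0.5,
    tol_deg: float = 1.0,
) -> dict:
    """Fraction of slices whose composed transform matches the truth.

    Full-size biculture phantoms (600 µm spheroid, 30 sections,
    perturbations up to ±5 px / ±10°, default noise) are stacked on the
    landmark channel; each slice's applied transform composed with the
    truth perturbation is compared to the reference slice's frame.
    """
    ok = tot = 0
    per_phantom = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for i in range(n_phantoms):
            ds, truth = generate_phantom(PhantomSpec(seed=seed + i))
            vol = stack_dataset(ds, 200.0)
            ref_inv = truth.transforms[0].inverse()
            good = 0
            for applied, true_t in zip(vol.transforms_applied,
                                       truth.transforms):
                resid = applied.compose(true_t).compose(ref_inv)
                th, tr = resid.magnitude()
                good += (th <= tol_deg and tr <= tol_px)
            per_phantom.append(good / ds.n_sections)
            ok += good
            tot += ds.n_sections
    return {"fraction": ok / tot, "per_phantom": per_phantom, "n_slices": tot}


def _qc_spec(seed: int) -> PhantomSpec:
    # scaled-down phantom (300 µm spheroid, 14 sections) keeps 100
    # repeated stack-and-correlate runs tractable
    return PhantomSpec(spheroid_radius_um=150.0, n_clusters=3,
                       cluster_class_mix=(1, 2, 0),
                       cluster_radius_range_um=(18.0, 55.0),
                       margin_px=8, seed=seed)


def qc_improvement(n_runs: int = 100, seed: int = 0) -> dict:
    """How often registration raises the mean inter-slice correlation."""
    improved = 0
    befores, afters = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for i in range(n_runs):
            ds, _ = generate_phantom(_qc_spec(seed + i))
            before = interslice_correlation(assemble_volume(ds), 200.0)
            after = interslice_correlation(stack_dataset(ds, 200.0), 200.0)
            befores.append(before["mean"])
            afters.append(after["mean"])
            improved += after["mean"] > before["mean"]
    return {
        "improved_runs": improved,
        "n_runs": n_runs,
        "mean_before": float(np.mean(befores)),
        "mean_after": float(np.mean(afters)),
    }


def picking_oracle_agreement(n_masks: int = 100, seed: int = 0,
                             shape=(20, 20, 20), density: float = 0.2) -> dict:
    """Object count and membership agreement with the flood-fill oracle."""
    rng = np.random.default_rng(seed)
    agree = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for _ in range(n_masks):
            mask = rng.random(shape) < density
            conn = int(rng.choice([6, 18, 26]))
            objs = pick_objects(mask, conn)
            oracle = flood_fill_label(mask, conn)
            same = objs.n_objects == oracle.max()
            if same:
                for lab in range(1, oracle.max() + 1):
                    if len(np.unique(objs.labels[oracle == lab])) != 1:
                        same = False
                        break
                same = same and bool(np.array_equal(objs.labels > 0, mask))
            agree += same
    return {"agreeing_masks": agree, "n_masks": n_masks}


def sphere_fidelity(radii_vox=(5, 10, 15, 30), voxel_um: float = 20.0) -> dict:
    """Voxelated-sphere volume error and surface/volume convergence."""
    vol_errs, sa_v_errs = {}, {}
    for rv in radii_vox:
        r = rv * voxel_um
        objs = voxelated_sphere(r, (voxel_um,) * 3)
        vol = objs.table["volume_um3"].iloc[0]
        sa = objs.table["surface_area_um2"].iloc[0]
        analytic_v = 4.0 / 3.0 * np.pi * r ** 3
        vol_errs[rv] = abs(vol - analytic_v) / analytic_v
        sa_v_errs[rv] = abs(sa / vol - 3.0 / r) / (3.0 / r)
    monotone = list(sa_v_errs.values()) == sorted(sa_v_errs.values(),
                                                  reverse=True)
    return {"volume_rel_err": vol_errs, "sa_v_rel_err": sa_v_errs,
            "sa_v_monotone": monotone}


def bh_oracle_agreement(n_vectors: int = 1000, seed: int = 0) -> dict:
    """Benjamini-Hochberg vs the sorted cumulative-min construction."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_vectors):
        m = int(rng.integers(1, 80))
        p = rng.random(m)
        adj = multipletests(p, method="fdr_bh")[1]
        order = np.argsort(p, kind="stable")
        oracle = p[order] * m / np.arange(1, m + 1)
        oracle = np.minimum.accumulate(oracle[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(oracle, 1.0)
        agree += np.allclose(adj, out)
    return {"agreeing_vectors": agree, "n_vectors": n_vectors}


def welch_type_one_error(reps: int = 2000, n_per_group: int = 20,
                         alpha: float = 0.05, seed: int = 0) -> dict:
    """Rejection rate of the Welch test under a Gaussian null."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, (reps, n_per_group))
    b = rng.normal(0.0, 2.0, (reps, n_per_group))
    p = sps.ttest_ind(a, b, axis=1, equal_var=False).pvalue
    return {"rate": float((p < alpha).mean()), "reps": reps, "alpha": alpha}


def detection_power(reps: int = 200, lfc: float = 1.5, sigma: float = 0.15,
                    n_objects: int = 20, alpha: float = 0.01,
                    seed: int = 0) -> dict:
    """Power to flag a planted |log2 FC| among a null feature family."""
    rng = np.random.default_rng(seed)
    detected = 0
    mu = np.log(50.0)
    for _ in range(reps):
        a_eff = rng.lognormal(mu + lfc * np.log(2), sigma, (n_objects, 1))
        b_eff = rng.lognormal(mu, sigma, (n_objects, 1))
        null = rng.lognormal(mu, sigma, (2, n_objects, 99))
        res = differential_test(np.hstack([a_eff, null[0]]),
                                np.hstack([b_eff, null[1]]),
                                alpha=alpha, lfc_threshold=1.0)
        detected += bool(res.significant[0])
    return {"power": detected / reps, "reps": reps}


def end_to_end_biculture(seed: int = 0, outdir: str | None = None) -> dict:
    """Full workflow on the default biculture phantom.

    Measures (a) exact size-class recovery on the noise-free truth mask
    and (b) recovery of every planted differential feature by the
    registered, segmented, voxel-object volcano analysis.
    """
    import tempfile

    ds, truth = generate_phantom(PhantomSpec(seed=seed))

    # (a) size classes from the truth mask match the independent catalog
    objs = pick_objects(truth.region_volume == 2)
    classify_size(objs)
    got = sorted(zip(objs.table["voxel_count"], objs.table["size_class"]))
    expected = sorted((e["voxel_count"], e["size_class"])
                      for e in truth.object_catalog)
    classes_exact = got == expected

    # (b) registered pipeline at default noise
    cfg = RunConfig(
        landmark_mz=200.0, n_leaves=3, seed=seed,
        region_markers={"cancer": 210.0, "fibroblast": 250.0},
        object_region="fibroblast",
        outdir=outdir or tempfile.mkdtemp(prefix="vox3dmsi_e2e_"),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        record = run_pipeline(cfg, dataset=ds)
    volcano = record["_volcano"]
    planted_mz = {float(ds.feature_axis.mz_values[i])
                  for i in truth.planted_effects}
    selected = (set(volcano[volcano["significant"]]["mz"])
                if volcano is not None else set())
    return {
        "size_classes_exact": classes_exact,
        "planted_mz": sorted(planted_mz),
        "selected_mz": sorted(selected),
        "planted_recovered": planted_mz <= selected,
        "recovered_fraction": (len(planted_mz & selected) / len(planted_mz)
                               if planted_mz else float("nan")),
        "corr_before": record["qc"]["corr_before_mean"],
        "corr_after": record["qc"]["corr_after_mean"],
    }
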