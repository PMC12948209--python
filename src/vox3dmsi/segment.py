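"""Feature selection and spatial segmentation.

Feature lists are built two ways, mirroring the usual untargeted MSI
workflow: a sliding-window local-maximum filter on the dataset mean
spectrum with an absolute intensity threshold, then a ROC-based
discriminating-feature selection between two pixel groups.

Pixels/voxels are partitioned by bisecting k-means under correlation
distance (1 − centered cosine similarity): the leaf with the largest
within-cluster summed distance is repeatedly split in two until the
requested number of leaves is reached.  Leaves are then mapped to named
regions (background / cancer / fibroblast / shell / lumen ...) by an
explicit, scriptable leaf→region map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .io import FeatureAxis, SerialSectionDataset

__all__ = [
    "SegmentationTree",
    "threshold_feature_list",
    "roc_auc_scores",
    "roc_discriminating_features",
    "weak_denoise",
    "bisecting_kmeans",
    "assign_regions",
]


# --------------------------------------------------------------------------
# feature selection
# --------------------------------------------------------------------------

def mean_spectrum(dataset: SerialSectionDataset,
                  foreground_only: bool = True) -> np.ndarray:
    """Dataset mean intensity per feature-axis entry."""
    tot = np.zeros(len(dataset.feature_axis))
    n = 0
    for s in dataset.sections:
        if foreground_only:
            sel = s.intensities[s.foreground_mask]
        else:
            sel = s.intensities.reshape(-1, s.n_features)
        tot += sel.sum(axis=0)
        n += len(sel)
    if n == 0:
        raise ValueError("dataset has no pixels")
    return tot / n


def threshold_feature_list(
    dataset: SerialSectionDataset,
    intensity_threshold: float = 30000.0,
    window_da: float = 2.0,
) -> FeatureAxis:
    """Sliding-window feature selection on the dataset mean spectrum.

    A feature is retained when it is a local maximum of the mean spectrum
    within a centered window of width *window_da* and its mean intensity
    is at least *intensity_threshold*.
    """
    spec = mean_spectrum(dataset)
    mz = dataset.feature_axis.array
    half = window_da / 2.0
    keep = []
    for i in range(len(mz)):
        lo = np.searchsorted(mz, mz[i] - half, side="left")
        hi = np.searchsorted(mz, mz[i] + half, side="right")
        window = spec[lo:hi]
        if spec[i] >= intensity_threshold and spec[i] == window.max():
            # ties inside the window: keep only the lowest-m/z maximum
            if np.argmax(window) + lo == i:
                keep.append(i)
    if not keep:
        raise ValueError(
            f"no feature passes the {intensity_threshold} a.u. threshold; "
            "lower the threshold"
        )
    return FeatureAxis(tuple(mz[keep]), dataset.feature_axis.tolerance_ppm)


def roc_auc_scores(
    group_a: np.ndarray, group_b: np.ndarray
) -> np.ndarray:
    """Per-feature area under the ROC curve separating two pixel groups.

    Computed from midrank statistics (equivalent to the Mann-Whitney U /
    concordant-pair count with half credit for ties); a constant feature
    scores exactly 0.5.  Arrays are ``(n_pixels, n_features)``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = len(a), len(b)
    auc = np.empty(a.shape[1])
    for f in range(a.shape[1]):
        ranks = sps.rankdata(np.concatenate([a[:, f], b[:, f]]))
        auc[f] = (ranks[:na].sum() - na * (na + 1) / 2) / (na * nb)
    return auc


def roc_discriminating_features(
    dataset_or_matrix,
    labels: np.ndarray,
    axis: FeatureAxis | None = None,
    auc_threshold: float = 0.65,
    top_n: int | None = None,
) -> tuple[FeatureAxis, np.ndarray]:
    """Features that discriminate two pixel groups by ROC AUC.

    *labels* is boolean (True = group A) over the foreground pixels of
    the dataset (or the rows of a raw matrix).  The per-feature score is
    ``max(AUC, 1 − AUC)``; features scoring at least *auc_threshold* are
    retained, the best *top_n* of them if requested.

    Returns the selected axis and the scores on the full input axis.
    """
    if isinstance(dataset_or_matrix, SerialSectionDataset):
        mat = np.concatenate(
            [s.intensities[s.foreground_mask] for s in dataset_or_matrix.sections]
        )
        axis = dataset_or_matrix.feature_axis
    else:
        mat = np.asarray(dataset_or_matrix, dtype=float)
        if axis is None:
            raise ValueError("axis required for a raw matrix input")
    labels = np.asarray(labels, dtype=bool)
    if labels.sum() < 10 or (~labels).sum() < 10:
        raise ValueError("both groups need at least 10 pixels")
    auc = roc_auc_scores(mat[labels], mat[~labels])
    score = np.maximum(auc, 1.0 - auc)
    idx = np.nonzero(score >= auc_threshold)[0]
    if top_n is not None and len(idx) > top_n:
        idx = idx[np.argsort(score[idx])[::-1][:top_n]]
        idx = np.sort(idx)
    if len(idx) == 0:
        raise ValueError(
            f"no feature reaches AUC {auc_threshold}; lower the threshold")
    return FeatureAxis(tuple(axis.array[idx]), axis.tolerance_ppm), score


# --------------------------------------------------------------------------
# weak de-noising
# --------------------------------------------------------------------------

def weak_denoise(ion_image: np.ndarray,
                 foreground_mask: np.ndarray | None = None) -> np.ndarray:
    """3×3 median filter over foreground pixels.

    Background pixels (and out-of-frame positions at the edges) are
    excluded from each pixel's neighbourhood, so edges use a reduced
    neighbourhood and background stays untouched.
    """
    img = np.asarray(ion_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("ion image must be 2D")
    if foreground_mask is None:
        foreground_mask = np.ones(img.shape, dtype=bool)
    work = np.where(foreground_mask, img, np.nan)
    padded = np.pad(work, 1, constant_values=np.nan)
    stack = np.stack([
        padded[1 + dy: 1 + dy + img.shape[0], 1 + dx: 1 + dx + img.shape[1]]
        for dy in (-1, 0, 1) for dx in (-1, 0, 1)
    ])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
        med = np.nanmedian(stack, axis=0)
    out = img.copy()
    out[foreground_mask] = med[foreground_mask]
    return out


# --------------------------------------------------------------------------
# bisecting k-means with correlation distance
# --------------------------------------------------------------------------

@dataclass
class TreeNode:
    members: np.ndarray            # member row indices
    centroid: np.ndarray           # centroid intensity vector (raw space)
    inertia: float                 # summed correlation distance to centroid
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None


@dataclass
class SegmentationTree:
    """Binary split tree over pixels/voxels plus final leaf labels."""

    root: TreeNode
    leaf_labels: np.ndarray        # leaf id per member, 0..n_leaves-1
    leaves: list[TreeNode]
    zero_variance_members: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=int))

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def leaf_centroids(self) -> np.ndarray:
        return np.stack([lf.centroid for lf in self.leaves])


def _standardize_rows(mat: np.ndarray) -> np.ndarray:
    """Center each row and scale to unit norm (correlation geometry)."""
    c = mat - mat.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(c, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return c / norm


def _corr_dist(std_rows: np.ndarray, centroid: np.ndarray) -> np.ndarray:
    """Correlation distance of standardized rows to a raw centroid."""
    c = centroid - centroid.mean()
    n = np.linalg.norm(c)
    if n == 0:
        return np.ones(len(std_rows))
    return 1.0 - std_rows @ (c / n)


def _two_means(
    std_rows: np.ndarray, rng: np.random.Generator,
    n_init: int = 10, max_iter: int = 100,
) -> np.ndarray:
    """2-means under correlation distance on standardized rows.

    Lloyd iterations with the centroid re-standardized after every mean
    update; the best of *n_init* seeded restarts (lowest summed distance)
    wins.  Returns a boolean split assignment.
    """
    n = len(std_rows)
    best_assign, best_cost = None, np.inf
    for _ in range(n_init):
        picks = rng.choice(n, size=2, replace=False)
        cents = std_rows[picks].copy()
        assign = None
        for _ in range(max_iter):
            d = 1.0 - std_rows @ cents.T        # (n, 2) correlation dists
            new_assign = d[:, 1] < d[:, 0]
            if assign is not None and np.array_equal(new_assign, assign):
                break
            assign = new_assign
            for k, sel in enumerate((~assign, assign)):
                if sel.any():
                    m = std_rows[sel].mean(axis=0)
                    m = m - m.mean()
                    nn = np.linalg.norm(m)
                    cents[k] = m / nn if nn > 0 else std_rows[sel][0]
        d = 1.0 - std_rows @ cents.T
        cost = d[np.arange(n), assign.astype(int)].sum()
        if cost < best_cost and assign.any() and not assign.all():
            best_cost, best_assign = cost, assign
    if best_assign is None:   # all restarts degenerate: split off one row
        best_assign = np.zeros(n, dtype=bool)
        best_assign[0] = True
    return best_assign


def bisecting_kmeans(
    members: np.ndarray,
    n_leaves: int,
    seed: int = 0,
    n_init: int = 10,
) -> SegmentationTree:
    """Bisecting k-means under correlation distance.

    The leaf with the largest within-cluster summed correlation distance
    is split by 2-means (with *n_init* restarts) until *n_leaves* leaves
    exist.  Deterministic for a fixed seed.  Members with zero variance
    across features cannot carry correlation structure; they are held out
    and assigned to the nearest final leaf, and their indices reported on
    the tree.
    """
    mat = np.asarray(members, dtype=float)
    if mat.ndim != 2:
        raise ValueError("members must be (n_members, n_features)")
    if n_leaves < 1:
        raise ValueError("n_leaves must be >= 1")
    n = len(mat)
    var = mat.var(axis=1)
    zero_var = np.nonzero(var == 0)[0]
    active = np.nonzero(var > 0)[0]
    if len(np.unique(mat[active], axis=0)) < n_leaves:
        raise ValueError(
            f"only {len(np.unique(mat[active], axis=0))} distinct members "
            f"with variance; cannot form {n_leaves} leaves")
    rng = np.random.default_rng(seed)
    std = _standardize_rows(mat[active])

    def make_node(rows: np.ndarray) -> TreeNode:
        centroid = mat[active[rows]].mean(axis=0)
        inertia = float(_corr_dist(std[rows], centroid).sum())
        return TreeNode(members=active[rows], centroid=centroid,
                        inertia=inertia)

    # nodes track rows (indices into `active`) for splitting
    root_rows = np.arange(len(active))
    root = make_node(root_rows)
    leaves: list[tuple[TreeNode, np.ndarray]] = [(root, root_rows)]
    while len(leaves) < n_leaves:
        # split the leaf with the largest within-cluster inertia
        splittable = [i for i, (nd, rows) in enumerate(leaves)
                      if len(np.unique(std[rows], axis=0)) >= 2]
        if not splittable:
            raise ValueError("no leaf can be split further")
        i = max(splittable, key=lambda i: leaves[i][0].inertia)
        node, rows = leaves.pop(i)
        right_sel = _two_means(std[rows], rng, n_init=n_init)
        left_rows, right_rows = rows[~right_sel], rows[right_sel]
        node.left = make_node(left_rows)
        node.right = make_node(right_rows)
        leaves.append((node.left, left_rows))
        leaves.append((node.right, right_rows))

    leaf_nodes = [nd for nd, _ in leaves]
    labels = np.full(n, -1, dtype=int)
    for lid, (nd, rows) in enumerate(leaves):
        labels[active[rows]] = lid
    if len(zero_var):
        warnings.warn(
            f"{len(zero_var)} zero-variance member(s) assigned to nearest "
            "leaf", stacklevel=2)
        cents = np.stack([_standardize_rows(nd.centroid[None])[0]
                          for nd in leaf_nodes])
        # zero-variance rows standardize to 0 -> distance 1 to every leaf;
        # use plain Euclidean distance to raw centroids as the tie-break
        for i in zero_var:
            d = np.linalg.norm(
                np.stack([nd.centroid for nd in leaf_nodes]) - mat[i], axis=1)
            labels[i] = int(np.argmin(d))
    return SegmentationTree(root=root, leaf_labels=labels, leaves=leaf_nodes,
                            zero_variance_members=zero_var)


def assign_regions(
    tree: SegmentationTree,
    mapping: dict[int, str],
    geometry: tuple | None = None,
    member_index: tuple[np.ndarray, ...] | None = None,
    region_ids: dict[str, int] | None = None,
) -> tuple[np.ndarray, dict[str, int]]:
    """Map leaves to named regions and paint a label image/volume.

    *mapping* must cover every leaf id.  If *geometry* (output shape) and
    *member_index* (the coordinate arrays of each member) are given, a
    label array of that shape is painted (0 where no member lives);
    otherwise a flat per-member label vector is returned.  Region ids are
    assigned alphabetically unless *region_ids* is supplied; "background"
    always gets 0.

    Returns ``(labels, region_ids)``.
    """
    missing = sorted(set(range(tree.n_leaves)) - set(mapping))
    if missing:
        raise ValueError(f"leaf ids without a region mapping: {missing}")
    names = sorted(set(mapping.values()) - {"background"})
    if region_ids is None:
        region_ids = {"background": 0}
        region_ids.update({nm: i + 1 for i, nm in enumerate(names)})
    leaf_to_id = np.array([region_ids[mapping[l]]
                           for l in range(tree.n_leaves)])
    member_labels = leaf_to_id[tree.leaf_labels]
    if geometry is None:
        return member_labels, region_ids
    out = np.zeros(geometry, dtype=np.int16)
    out[member_index] = member_labels
    return out, region_ids
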