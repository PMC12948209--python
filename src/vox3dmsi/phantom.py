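"""Synthetic serial-section phantoms with known ground truth.

Two sample geometries are emulated:

``biculture_spheroid``
    A ~600 µm spheroid of cancer cells with embedded, non-overlapping
    fibroblast cluster spheres spanning the three voxel-count size
    classes (V1 < 10 vx, V2 10-100 vx, V3 > 100 vx).  A subset of
    features carries a planted log2 fold change between V2 and V3
    fibroblast objects, so the full object-level differential workflow
    has a known answer.

``cystic_organoid``
    A hollow shell with an off-center lumen; two lumen-exclusive
    low-mass features and several shell lipid features are planted
    (structural pattern only, no chemistry is simulated).

Per-voxel intensity is ``region_mean × LogNormal(0, sigma_mult) +
Normal(0, sigma_add)`` truncated at zero; background voxels get the
additive term only.  The landmark channel additionally carries a smooth
multiplicative texture field so that every slice has angular structure,
as real morphology-defining ion images do — without it a spherical
phantom would be rotationally symmetric and in-plane rotation would be
unidentifiable.  Each section is finally perturbed by an independent
random rigid transform (the ground truth records it).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import FeatureAxis, SectionImage, SerialSectionDataset
from .reconstruct import RigidTransform2D

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "MarkerSpec",
    "generate_phantom",
    "catalog_truth_objects",
    "flood_fill_label",
]

BACKGROUND, TISSUE_PRIMARY, TISSUE_SECONDARY = 0, 1, 2
# region 1 is cancer (spheroid) or shell (organoid); region 2 is the
# fibroblast clusters or the lumen.

REGION_NAMES = {
    "biculture_spheroid": {0: "background", 1: "cancer", 2: "fibroblast"},
    "cystic_organoid": {0: "background", 1: "shell", 2: "lumen"},
}


class PlacementError(RuntimeError):
    """Embedded clusters could not be placed without overlap."""


@dataclass
class MarkerSpec:
    """Per-feature mean intensities by region and planted effects.

    ``mean_primary`` / ``mean_secondary`` are length ``n_features`` mean
    intensities (a.u.) in region 1 and region 2.  ``group_lfc`` holds the
    planted log2 fold change applied multiplicatively to region-2 voxels
    of *group A* objects in the compared pair (V2 vs V3 for spheroids,
    lumen-object groups for organoids); zero means a null feature.
    """

    mean_primary: np.ndarray
    mean_secondary: np.ndarray
    group_lfc: np.ndarray
    mean_background: np.ndarray | None = None
    landmark_index: int = 0

    def __post_init__(self) -> None:
        self.mean_primary = np.asarray(self.mean_primary, dtype=float)
        self.mean_secondary = np.asarray(self.mean_secondary, dtype=float)
        self.group_lfc = np.asarray(self.group_lfc, dtype=float)
        n = len(self.mean_primary)
        if self.mean_background is None:
            self.mean_background = np.zeros(n)
        self.mean_background = np.asarray(self.mean_background, dtype=float)
        if not (len(self.mean_secondary) == len(self.group_lfc)
                == len(self.mean_background) == n):
            raise ValueError("marker arrays must share one length")

    @property
    def n_features(self) -> int:
        return len(self.mean_primary)


def default_marker_spec(mode: str, n_features: int = 30) -> MarkerSpec:
    """Default feature panel for a phantom mode.

    Channel 0 is the landmark (high across all tissue, with contrast
    between the two tissue regions).  Channels 1-4 mark region 1,
    channels 5-8 mark region 2, channels 9-11 carry planted group
    effects (+2, +2, -2 log2 units), the last two channels are a weak
    embedding-matrix signature seen off tissue, and the remainder are
    nulls.
    """
    if n_features < 14:
        raise ValueError("default marker spec needs at least 14 features")
    prim = np.full(n_features, 20.0)
    sec = np.full(n_features, 20.0)
    bg = np.zeros(n_features)
    lfc = np.zeros(n_features)
    prim[0], sec[0] = 100.0, 35.0          # landmark
    prim[1:5], sec[1:5] = 80.0, 5.0        # region-1 (cancer/shell) markers
    prim[5:9], sec[5:9] = 5.0, 80.0        # region-2 (fibro/lumen) markers
    prim[9:12], sec[9:12] = 10.0, 30.0     # group-effect carriers
    lfc[9:12] = (2.0, 2.0, -2.0)
    bg[-2:] = 8.0                          # embedding-matrix channels
    prim[-2:], sec[-2:] = 1.0, 1.0
    return MarkerSpec(prim, sec, lfc, mean_background=bg)


@dataclass
class PhantomSpec:
    """Study conditions for one synthetic sample.

    Defaults emulate the 20 µm raster / 20 µm thickness serial sectioning
    of a ≈600 µm biculture spheroid; perturbation bounds are ±5 px
    translation and ±10° rotation per section.
    """

    mode: str = "biculture_spheroid"
    spheroid_radius_um: float = 300.0
    pixel_size_um: float = 20.0
    thickness_um: float = 20.0
    n_clusters: int = 14
    cluster_radius_range_um: tuple[float, float] = (18.0, 85.0)
    cluster_radii_um: tuple[float, ...] | None = None
    cluster_class_mix: tuple[int, int, int] = (2, 6, 6)
    lumen_radius_fraction: float = 0.55
    lumen_offset_fraction: float = 0.15
    n_features: int = 30
    marker_spec: MarkerSpec | None = None
    sigma_mult: float = 0.15
    sigma_add: float = 2.0
    landmark_texture: float = 0.5
    texture_sigma: tuple[float, float, float] = (8.0, 2.5, 2.5)
    edge_width_px: float = 1.0
    perturb_translation_px: float = 5.0
    perturb_rotation_deg: float = 10.0
    margin_px: int = 10
    seed: int = 0
    sample_id: str = "phantom"

    def __post_init__(self) -> None:
        if self.mode not in REGION_NAMES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if min(self.spheroid_radius_um, self.pixel_size_um,
               self.thickness_um) <= 0:
            raise ValueError("geometry parameters must be positive")
        if self.sigma_mult < 0 or self.sigma_add < 0:
            raise ValueError("noise sigmas must be non-negative")
        if self.marker_spec is None:
            self.marker_spec = default_marker_spec(self.mode, self.n_features)
        if self.marker_spec.n_features != self.n_features:
            raise ValueError("marker_spec length disagrees with n_features")


@dataclass
class PhantomTruth:
    """Everything the generator knows that the pipeline must recover."""

    transforms: list[RigidTransform2D]
    region_volume: np.ndarray            # (z, y, x) labels, unperturbed
    object_catalog: list[dict]
    planted_effects: dict[int, float]    # feature index -> true log2 FC
    marker_spec: MarkerSpec
    region_names: dict[int, str]
    voxel_um: tuple[float, float, float]
    object_labels: np.ndarray | None = None  # (z, y, x) truth object ids


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------

def _voxel_centers(n: int, step: float) -> np.ndarray:
    """Coordinates of n voxel centers, centered on 0, spacing *step*."""
    return (np.arange(n) - (n - 1) / 2.0) * step


def _draw_cluster_radii(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.cluster_radii_um is not None:
        return np.asarray(spec.cluster_radii_um, dtype=float)
    lo, hi = spec.cluster_radius_range_um
    n1, n2, n3 = spec.cluster_class_mix
    if n1 + n2 + n3 != spec.n_clusters:
        raise ValueError("cluster_class_mix must sum to n_clusters")
    # stratified over the three size classes so each is represented:
    # sub-ranges chosen so the voxelized counts land in V1 / V2 / V3
    bands = [(max(lo, 18.0), min(hi, 25.0)),
             (max(lo, 30.0), min(hi, 55.0)),
             (max(lo, 62.0), min(hi, 85.0))]
    parts = []
    for n, (a, b) in zip((n1, n2, n3), bands):
        if n == 0:
            continue
        if a >= b:
            raise ValueError(
                f"cluster_radius_range_um {spec.cluster_radius_range_um} "
                f"cannot host the requested size-class band ({a}, {b})")
        parts.append(rng.uniform(a, b, n))
    return np.concatenate(parts)


def _place_clusters(
    spec: PhantomSpec, radii: np.ndarray, rng: np.random.Generator,
    max_retries: int = 500,
) -> list[tuple[np.ndarray, float]]:
    """Non-overlapping cluster spheres fully inside the spheroid."""
    placed: list[tuple[np.ndarray, float]] = []
    # two voxels of cancer between clusters so 26-connectivity cannot
    # merge neighbouring clusters across a single-voxel diagonal gap
    min_sep = 2.0 * spec.pixel_size_um
    for r in sorted(radii, reverse=True):
        limit = spec.spheroid_radius_um - r - spec.pixel_size_um
        if limit <= 0:
            raise PlacementError(
                f"cluster radius {r:.0f} µm does not fit inside the "
                f"{spec.spheroid_radius_um:.0f} µm spheroid"
            )
        for _ in range(max_retries):
            c = rng.uniform(-limit, limit, size=3)
            if np.linalg.norm(c) > limit:
                continue
            if all(np.linalg.norm(c - c2) > r + r2 + min_sep
                   for c2, r2 in placed):
                placed.append((c, r))
                break
        else:
            raise PlacementError(
                f"could not place {len(radii)} clusters of radii up to "
                f"{radii.max():.0f} µm without overlap; use fewer or "
                "smaller clusters"
            )
    return placed


@dataclass
class _Solids:
    """Analytic geometry of one phantom: everything needed to voxelize."""

    zc: np.ndarray
    yc: np.ndarray
    xc: np.ndarray
    spheroid_radius: float
    spheres: list[tuple[np.ndarray, float]]   # region-2 solids (center, r)

    def grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return np.meshgrid(self.zc, self.yc, self.xc, indexing="ij")


def _build_solids(spec: PhantomSpec, rng: np.random.Generator) -> _Solids:
    R = spec.spheroid_radius_um
    p, t = spec.pixel_size_um, spec.thickness_um
    n_z = max(2, 2 * int(np.floor(R / t)))
    half_extent = R + spec.margin_px * p
    n_xy = 2 * int(np.ceil(half_extent / p))
    zc = _voxel_centers(n_z, t)
    yc = _voxel_centers(n_xy, p)
    xc = _voxel_centers(n_xy, p)
    if spec.mode == "biculture_spheroid":
        spheres = None
        last_err: PlacementError | None = None
        for _ in range(10):  # fresh radii + positions per attempt
            radii = _draw_cluster_radii(spec, rng)
            try:
                spheres = [(c, r)
                           for c, r in _place_clusters(spec, radii, rng)]
                break
            except PlacementError as err:
                last_err = err
        if spheres is None:
            raise last_err
    else:
        r_lum = spec.lumen_radius_fraction * R
        off = spec.lumen_offset_fraction * R
        direction = rng.normal(size=3)
        c = off * direction / np.linalg.norm(direction)
        spheres = [(c, r_lum)]
    return _Solids(zc, yc, xc, R, spheres)


def _region_model(
    solids: _Solids,
) -> tuple[np.ndarray, np.ndarray]:
    """Voxelize the analytic solids: returns (region labels, object ids).

    A voxel belongs to a region if its center lies inside the analytic
    solid (inclusive boundary).  ``object ids`` label the individual
    region-2 solids (clusters or the lumen) as planted.
    """
    Z, Y, X = solids.grids()
    dist2 = Z ** 2 + Y ** 2 + X ** 2
    region = np.zeros(Z.shape, dtype=np.int16)
    objects = np.zeros_like(region)
    inside = dist2 <= solids.spheroid_radius ** 2
    region[inside] = TISSUE_PRIMARY
    for k, (c, r) in enumerate(solids.spheres, start=1):
        d2 = (Z - c[0]) ** 2 + (Y - c[1]) ** 2 + (X - c[2]) ** 2
        m = (d2 <= r ** 2) & inside
        region[m] = TISSUE_SECONDARY
        objects[m] = k
    return region, objects


# --------------------------------------------------------------------------
# intensities
# --------------------------------------------------------------------------

def _mean_volume(
    spec: PhantomSpec, solids: _Solids, region: np.ndarray,
    objects: np.ndarray, obj_groups: dict[int, str],
    rng: np.random.Generator,
) -> np.ndarray:
    """Noise-free per-voxel mean intensity, (z, y, x, feature).

    With ``edge_width_px > 0`` solid boundaries are rendered with a
    linear partial-volume ramp (coverage 1 → 0 across one raster width),
    emulating the spatial averaging of a MALDI laser pixel; interior
    voxels still equal their region mean exactly.  ``edge_width_px = 0``
    gives the binary voxel-center model.
    """
    ms = spec.marker_spec
    nf = ms.n_features
    w = spec.edge_width_px * spec.pixel_size_um
    Z, Y, X = solids.grids()

    def coverage(c, r):
        d = np.sqrt((Z - c[0]) ** 2 + (Y - c[1]) ** 2 + (X - c[2]) ** 2)
        if w == 0:
            return (d <= r).astype(float)
        return np.clip(0.5 - (d - r) / w, 0.0, 1.0)

    cov_tissue = coverage((0.0, 0.0, 0.0), solids.spheroid_radius)
    scale = 2.0 ** ms.group_lfc
    mean = np.zeros(region.shape + (nf,))
    cov_sec_total = np.zeros(region.shape)
    for oid, (c, r) in enumerate(solids.spheres, start=1):
        cov = np.minimum(coverage(c, r), cov_tissue)
        sec_mean = ms.mean_secondary * (scale if obj_groups.get(oid) == "A"
                                        else 1.0)
        mean += cov[..., None] * sec_mean
        cov_sec_total += cov
    cov_sec_total = np.minimum(cov_sec_total, 1.0)
    cov_prim = np.clip(cov_tissue - cov_sec_total, 0.0, 1.0)
    mean += cov_prim[..., None] * ms.mean_primary
    mean += (1.0 - np.maximum(cov_tissue, cov_sec_total))[..., None] \
        * ms.mean_background
    # landmark texture: smooth positive morphology field; long z
    # correlation because tissue texture persists across 20 µm sections
    if spec.landmark_texture > 0:
        field3d = ndimage.gaussian_filter(
            rng.standard_normal(region.shape), sigma=spec.texture_sigma)
        sd = field3d.std()
        if sd > 0:
            field3d = field3d / sd
        mean[..., ms.landmark_index] *= np.exp(
            spec.landmark_texture * field3d)
    return mean


def _default_group_assignment(
    objects: np.ndarray, mode: str
) -> dict[int, str]:
    """Which planted objects form compared group A vs B.

    Keys are the planted object ids of the ``objects`` volume.
    Spheroids: V2-sized objects are group A, V3 group B (V1 excluded).
    Organoids: the single lumen is group A (shell statistics are drawn
    from the shell region downstream); effect carriers are simply
    lumen-enriched.
    """
    counts = np.bincount(objects.ravel())
    groups: dict[int, str] = {}
    for oid in range(1, len(counts)):
        if counts[oid] == 0:
            continue
        if mode == "biculture_spheroid":
            cls = _size_class(int(counts[oid]))
            if cls == "V2":
                groups[oid] = "A"
            elif cls == "V3":
                groups[oid] = "B"
        else:
            groups[oid] = "A"
    return groups


# --------------------------------------------------------------------------
# flood-fill labeling (independent oracle for connected components)
# --------------------------------------------------------------------------

def _offsets(connectivity: int) -> list[tuple[int, int, int]]:
    offs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dz == dy == dx == 0:
                    continue
                order = abs(dz) + abs(dy) + abs(dx)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append((dz, dy, dx))
    return offs


def flood_fill_label(mask: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """Label connected components by explicit breadth-first flood fill.

    Deliberately simple (queue + neighbour offsets, no library calls) so
    it can serve as an independent oracle for component extraction.
    Labels are assigned in raster-scan order of each component's first
    voxel.
    """
    if connectivity not in (6, 18, 26):
        raise ValueError("connectivity must be 6, 18 or 26")
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=np.int32)
    offs = _offsets(connectivity)
    nz, ny, nx = mask.shape
    next_label = 0
    for z0 in range(nz):
        for y0 in range(ny):
            for x0 in range(nx):
                if not mask[z0, y0, x0] or labels[z0, y0, x0]:
                    continue
                next_label += 1
                q = deque([(z0, y0, x0)])
                labels[z0, y0, x0] = next_label
                while q:
                    z, y, x = q.popleft()
                    for dz, dy, dx in offs:
                        zz, yy, xx = z + dz, y + dy, x + dx
                        if (0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx
                                and mask[zz, yy, xx]
                                and not labels[zz, yy, xx]):
                            labels[zz, yy, xx] = next_label
                            q.append((zz, yy, xx))
    return labels


def _size_class(count: int, lower: int = 10, upper: int = 100) -> str:
    if count < lower:
        return "V1"
    if count <= upper:
        return "V2"
    return "V3"


def catalog_truth_objects(
    truth_or_region: "PhantomTruth | np.ndarray",
    thresholds: tuple[int, int] = (10, 100),
    connectivity: int = 26,
) -> list[dict]:
    """Connected components of the region-2 label by flood fill.

    Accepts a :class:`PhantomTruth` or a raw region volume.  Returns one
    entry per object: ``{"object_id", "voxel_count", "size_class"}``,
    ordered by decreasing voxel count (ties by first voxel).
    """
    region = (truth_or_region.region_volume
              if isinstance(truth_or_region, PhantomTruth)
              else np.asarray(truth_or_region))
    labels = flood_fill_label(region == TISSUE_SECONDARY, connectivity)
    lower, upper = thresholds
    counts = np.bincount(labels.ravel())
    entries = [
        {"object_id": int(i), "voxel_count": int(counts[i]),
         "size_class": _size_class(int(counts[i]), lower, upper)}
        for i in range(1, len(counts))
    ]
    entries.sort(key=lambda e: (-e["voxel_count"], e["object_id"]))
    return entries


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------

def generate_phantom(
    spec: PhantomSpec,
) -> tuple[SerialSectionDataset, PhantomTruth]:
    """Generate a serial-section dataset plus its ground truth.

    The 3D region model is voxelized (voxel-center rule), per-voxel
    intensities are drawn, the volume is sliced into sections, and each
    section is perturbed by an independent random rigid transform that is
    recorded in the truth.  Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    solids = _build_solids(spec, rng)
    region, objects = _region_model(solids)

    # truth object catalog by independent flood fill; the compared
    # groups are keyed on the planted object ids
    catalog = catalog_truth_objects(region)
    obj_groups = _default_group_assignment(objects, spec.mode)

    mean = _mean_volume(spec, solids, region, objects, obj_groups, rng)

    inten = mean.copy()
    if spec.sigma_mult > 0:
        inten *= rng.lognormal(0.0, spec.sigma_mult, size=inten.shape)
    if spec.sigma_add > 0:
        inten += rng.normal(0.0, spec.sigma_add, size=inten.shape)
    np.maximum(inten, 0.0, out=inten)

    ms = spec.marker_spec
    planted = {int(i): float(ms.group_lfc[i])
               for i in np.nonzero(ms.group_lfc)[0]}

    # feature axis: ascending synthetic m/z, well separated
    mz = tuple(200.0 + 10.0 * np.arange(spec.n_features))
    axis = FeatureAxis(mz, tolerance_ppm=10.0)

    sections = []
    transforms = []
    for z in range(region.shape[0]):
        if spec.perturb_translation_px > 0 or spec.perturb_rotation_deg > 0:
            theta = rng.uniform(-spec.perturb_rotation_deg,
                                spec.perturb_rotation_deg)
            tx = rng.uniform(-spec.perturb_translation_px,
                             spec.perturb_translation_px)
            ty = rng.uniform(-spec.perturb_translation_px,
                             spec.perturb_translation_px)
            t = RigidTransform2D(theta, tx, ty)
        else:
            t = RigidTransform2D()
        transforms.append(t)
        plane = inten[z]
        mask = region[z] > 0
        if not t.is_identity:
            plane = np.stack(
                [t.apply(plane[..., f]) for f in range(spec.n_features)],
                axis=-1)
            mask = t.apply(mask, order=0)
        sections.append(SectionImage(plane, mask, spec.pixel_size_um,
                                     spec.thickness_um, z))

    dataset = SerialSectionDataset(sections, axis, spec.sample_id)
    truth = PhantomTruth(
        transforms=transforms,
        region_volume=region,
        object_catalog=catalog,
        planted_effects=planted,
        marker_spec=ms,
        region_names=REGION_NAMES[spec.mode],
        voxel_um=(spec.thickness_um, spec.pixel_size_um, spec.pixel_size_um),
        object_labels=objects,
    )
    return dataset, truth
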