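"""Serial-section rigid registration and 3D volume assembly.

Each section is registered to its already-aligned predecessor on a single
morphology-defining "landmark" ion image (RMS-normalized), and the
recovered in-plane rigid transform is applied to every feature channel.
The registration backend is SimpleITK: normalized cross-correlation
metric, regular-step gradient descent, three-level multi-resolution
pyramid, linear resampling.

Transform convention
--------------------
:class:`RigidTransform2D` maps image content: rotation by ``theta_deg``
counterclockwise (in (x, y) axes) about the image center, followed by
translation ``(tx_px, ty_px)``.  Applying ``T`` to an image moves the
pixel at ``p`` to ``T(p)``.  Composition and inversion are closed and,
for transforms sharing a rotation center, independent of that center.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .io import FeatureAxis, SectionImage, SerialSectionDataset

__all__ = [
    "RigidTransform2D",
    "FeatureVolume",
    "rms_normalize",
    "extract_ion_image",
    "register_pair",
    "stack_dataset",
    "assemble_volume",
    "interslice_correlation",
]


@dataclass(frozen=True)
class RigidTransform2D:
    """In-plane rigid motion: rotate about the image center, then translate."""

    theta_deg: float = 0.0
    tx_px: float = 0.0
    ty_px: float = 0.0

    @property
    def is_identity(self) -> bool:
        return self.theta_deg == 0.0 and self.tx_px == 0.0 and self.ty_px == 0.0

    def _rot(self) -> np.ndarray:
        th = math.radians(self.theta_deg)
        c, s = math.cos(th), math.sin(th)
        return np.array([[c, -s], [s, c]])

    def compose(self, other: "RigidTransform2D") -> "RigidTransform2D":
        """``self ∘ other``: apply *other* first, then *self*.

        Exact for transforms about a common rotation center.
        """
        R = self._rot()
        t = R @ np.array([other.tx_px, other.ty_px]) + np.array(
            [self.tx_px, self.ty_px]
        )
        return RigidTransform2D(self.theta_deg + other.theta_deg,
                                float(t[0]), float(t[1]))

    def inverse(self) -> "RigidTransform2D":
        R = self._rot()
        t = -R.T @ np.array([self.tx_px, self.ty_px])
        return RigidTransform2D(-self.theta_deg, float(t[0]), float(t[1]))

    def magnitude(self) -> tuple[float, float]:
        """(|theta| wrapped to [0, 180] degrees, translation norm in px)."""
        wrapped = (self.theta_deg + 180.0) % 360.0 - 180.0
        return abs(wrapped), float(math.hypot(self.tx_px, self.ty_px))

    def apply(self, image: np.ndarray, order: int = 1) -> np.ndarray:
        """Resample *image* (2D ``(y, x)``) under this transform.

        ``order=1`` is linear interpolation (intensities), ``order=0``
        nearest neighbour (masks, labels).  Out-of-frame samples are 0.
        """
        image = np.asarray(image)
        h, w = image.shape
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        th = math.radians(self.theta_deg)
        c, s = math.cos(th), math.sin(th)
        # output(q) = input(T^-1 q); in (y, x) index order the inverse map
        # is  y_i = c*(y_o-cy-ty) - s*(x_o-cx-tx) + cy
        #     x_i = s*(y_o-cy-ty) + c*(x_o-cx-tx) + cx
        A = np.array([[c, -s], [s, c]])
        shift = np.array([cy + self.ty_px, cx + self.tx_px])
        b = np.array([cy, cx]) - A @ shift
        was_bool = image.dtype == bool
        out = ndimage.affine_transform(
            image.astype(np.float64), A, offset=b, order=order, cval=0.0,
            mode="constant",
        )
        if order == 1:
            np.maximum(out, 0.0, out=out)
        if was_bool:
            return out > 0.5
        if np.issubdtype(image.dtype, np.integer):
            return np.rint(out).astype(image.dtype)
        return out

    def apply_point(self, x: float, y: float, shape: tuple[int, int]) -> tuple[float, float]:
        """Map an (x, y) point under the transform for an image of *shape*."""
        h, w = shape
        c = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
        p = self._rot() @ (np.array([x, y]) - c) + c + np.array(
            [self.tx_px, self.ty_px]
        )
        return float(p[0]), float(p[1])


@dataclass
class FeatureVolume:
    """Registered multichannel stack: ``data`` is (z, y, x, feature)."""

    data: np.ndarray
    voxel_um: tuple[float, float, float]
    feature_axis: FeatureAxis
    masks: np.ndarray  # (z, y, x) bool foreground
    transforms_applied: list[RigidTransform2D] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError("data must be (z, y, x, feature)")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")
        self.masks = np.asarray(self.masks, dtype=bool)
        if self.masks.shape != self.data.shape[:3]:
            raise ValueError("masks shape must match (z, y, x)")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    def channel(self, mz: float, tol_ppm: float | None = None) -> np.ndarray:
        """The (z, y, x) sub-volume of one m/z feature."""
        return self.data[..., self.feature_axis.index_of(mz, tol_ppm)]


# --------------------------------------------------------------------------
# normalization and ion images
# --------------------------------------------------------------------------

def rms_normalize(section: SectionImage) -> SectionImage:
    """Divide each foreground pixel's spectrum by its root-mean-square.

    Foreground pixels with an all-zero spectrum are left unscaled and
    reported through a warning (QC log).  Background pixels are untouched.
    """
    out = section.copy()
    ys, xs = np.nonzero(out.foreground_mask)
    if len(ys) == 0:
        raise ValueError("section has no foreground pixels")
    vecs = out.intensities[ys, xs]
    rms = np.sqrt(np.mean(vecs ** 2, axis=1))
    zero = rms == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} foreground pixel(s) have all-zero spectra; "
            "left unscaled", stacklevel=2,
        )
        rms[zero] = 1.0
    out.intensities[ys, xs] = vecs / rms[:, None]
    return out


def extract_ion_image(
    section: SectionImage, axis: FeatureAxis, mz: float,
    tol_ppm: float | None = None,
) -> np.ndarray:
    """2D intensity grid of one feature; background pixels are 0."""
    img = section.intensities[..., axis.index_of(mz, tol_ppm)].copy()
    img[~section.foreground_mask] = 0.0
    return img


# --------------------------------------------------------------------------
# pairwise rigid registration
# --------------------------------------------------------------------------

def register_pair(
    fixed: np.ndarray,
    moving: np.ndarray,
    max_iters: int = 400,
    metric: str = "ncc",
    theta_starts_deg: tuple[float, ...] = (0.0, -6.0, 6.0, -12.0, 12.0),
) -> RigidTransform2D:
    """Rigid transform aligning *moving* onto *fixed*.

    Maximizes normalized cross-correlation (``metric="ncc"``; Mattes
    mutual information via ``"mi"``) with a 3-level multi-resolution
    regular-step gradient descent (at most *max_iters* iterations per
    level); linear resampling, out-of-frame treated as 0.  The rotation
    objective on near-round sections has shallow, multi-modal structure,
    so the descent is restarted from several initial angles and the best
    final metric value wins.  Returns the transform to
    :meth:`RigidTransform2D.apply` to *moving*.

    Degenerate (constant) inputs return the identity with a warning.
    """
    fixed = np.asarray(fixed, dtype=np.float64)
    moving = np.asarray(moving, dtype=np.float64)
    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving grids must have the same shape")
    if fixed.std() == 0 or moving.std() == 0:
        warnings.warn("constant image; returning identity transform",
                      stacklevel=2)
        return RigidTransform2D()
    if metric not in ("ncc", "mi"):
        raise ValueError("metric must be 'ncc' or 'mi'")

    f_img = sitk.GetImageFromArray(fixed)
    m_img = sitk.GetImageFromArray(moving)
    h, w = fixed.shape
    center = ((w - 1) / 2.0, (h - 1) / 2.0)

    candidates: list[tuple[float, sitk.Euler2DTransform, str]] = []
    # the leading None start locks the rotation (translation-only): on
    # rotationally degenerate content it ties the full searches and the
    # smallest-rotation tie-break then returns an exact zero rotation
    for theta0 in (None, *theta_starts_deg):
        init = sitk.Euler2DTransform()
        init.SetCenter(center)
        init.SetAngle(math.radians(theta0 or 0.0))

        reg = sitk.ImageRegistrationMethod()
        if metric == "ncc":
            reg.SetMetricAsCorrelation()
        else:
            reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=32)
        reg.SetInterpolator(sitk.sitkLinear)
        reg.SetOptimizerAsRegularStepGradientDescent(
            learningRate=1.0, minStep=1e-5,
            numberOfIterations=int(max_iters),
            relaxationFactor=0.5, gradientMagnitudeTolerance=1e-7,
        )
        reg.SetOptimizerScalesFromPhysicalShift()
        reg.SetShrinkFactorsPerLevel([4, 2, 1])
        # the final level keeps a slight blur: resampling a rotated image
        # smooths it, and on sharp-edged content that smoothing alone can
        # raise NCC; matching blur on both sides removes that false gain
        reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.5])
        reg.SetInitialTransform(init, inPlace=True)
        if theta0 is None:
            reg.SetOptimizerWeights([0.0, 1.0, 1.0])
        try:
            result = reg.Execute(f_img, m_img)
        except RuntimeError as exc:  # pragma: no cover - backend failure
            warnings.warn(f"registration start {theta0}° failed ({exc})",
                          stacklevel=2)
            continue
        candidates.append((reg.GetMetricValue(),   # ITK minimizes (−NCC)
                           sitk.Euler2DTransform(result),
                           reg.GetOptimizerStopConditionDescription()))
    if not candidates:  # pragma: no cover - all restarts failed
        warnings.warn("registration failed from every start; returning "
                      "identity", stacklevel=2)
        return RigidTransform2D()
    # Re-score every candidate on the *interior* of the fixed foreground
    # (rim eroded away): resampling a rotated image blurs it, and at the
    # sharp tissue/background rim that blur alone raises raw NCC, so the
    # optimizer's own metric values are not comparable across rotations.
    # The interior texture carries the genuine rotation signal.  On
    # near-round structure-poor sections the rotation is ill-determined
    # (flat metric); ties within a small margin break toward the
    # smallest rotation.
    fg = ndimage.binary_erosion(fixed > 0, iterations=2)
    margin = 3e-3
    if fg.sum() < 30:
        # no usable interior: the section is too small to determine a
        # rotation at all — any candidate ties, keep the smallest
        fg = np.ones(fixed.shape, dtype=bool)
        margin = math.inf

    def _score(img: np.ndarray) -> float:
        a = fixed[fg] - fixed[fg].mean()
        b = img[fg] - img[fg].mean()
        denom = math.sqrt(float(a @ a) * float(b @ b))
        return float(a @ b) / denom if denom > 0 else 0.0

    rescored = []
    for value, euler, stop in candidates:
        t = _euler_to_transform(euler)
        rescored.append((_score(t.apply(moving)), t, stop))
    best_score = max(r[0] for r in rescored)
    tied = [r for r in rescored if r[0] >= best_score - margin]
    best = min(tied, key=lambda r: r.__getitem__(1).magnitude()[0])
    if "Maximum" in best[2] and "iterations" in best[2].lower():
        warnings.warn(f"registration did not converge: {best[2]}",
                      stacklevel=2)
    return best[1]


def _euler_to_transform(euler: "sitk.Euler2DTransform") -> RigidTransform2D:
    """Convert an ITK Euler2D (fixed→moving map) to the content-moving
    transform in this package's convention (its inverse)."""
    phi = euler.GetAngle()
    ts = np.array(euler.GetTranslation())
    # ITK's y axis equals array rows, same orientation as ours
    c, s = math.cos(-phi), math.sin(-phi)
    Rinv = np.array([[c, -s], [s, c]])
    t = -Rinv @ ts
    return RigidTransform2D(math.degrees(-phi), float(t[0]), float(t[1]))


# --------------------------------------------------------------------------
# stacking
# --------------------------------------------------------------------------

def assemble_volume(dataset: SerialSectionDataset) -> FeatureVolume:
    """Stack sections into a volume without any registration."""
    data = np.stack([s.intensities for s in dataset.sections])
    masks = np.stack([s.foreground_mask for s in dataset.sections])
    return FeatureVolume(
        data, dataset.voxel_um, dataset.feature_axis, masks,
        [RigidTransform2D() for _ in dataset.sections],
    )


def stack_dataset(
    dataset: SerialSectionDataset,
    landmark_mz: float,
    max_iters: int = 400,
    reference: str = "chain",
    metric: str = "ncc",
) -> FeatureVolume:
    """Register all sections on the landmark ion image and stack them.

    Slice 0 is the reference.  Each slice ``i`` is registered to the
    already-transformed slice ``i-1`` on the RMS-normalized landmark
    image (``reference="chain"``); with ``reference="middle"`` all slices
    chain toward the middle slice instead, bounding drift.  The per-slice
    transform is applied to every feature channel (linear interpolation)
    and the mask (nearest).
    """
    if dataset.n_sections < 2:
        raise ValueError("stacking needs at least 2 sections")
    if reference not in ("chain", "middle"):
        raise ValueError("reference must be 'chain' or 'middle'")
    axis = dataset.feature_axis
    n = dataset.n_sections
    norm_landmarks = []
    for s in dataset.sections:
        if not s.foreground_mask.any():
            raise ValueError(f"section z={s.z_index} has empty foreground")
        norm_landmarks.append(extract_ion_image(rms_normalize(s), axis,
                                                landmark_mz))

    transforms: list[RigidTransform2D | None] = [None] * n
    aligned_landmark: list[np.ndarray | None] = [None] * n

    if reference == "chain":
        order = [(i, i - 1) for i in range(1, n)]
        ref_idx = 0
    else:
        ref_idx = n // 2
        order = [(i, i + 1) for i in range(ref_idx - 1, -1, -1)]
        order += [(i, i - 1) for i in range(ref_idx + 1, n)]
    transforms[ref_idx] = RigidTransform2D()
    aligned_landmark[ref_idx] = norm_landmarks[ref_idx]

    for i, ref in order:
        t = register_pair(aligned_landmark[ref], norm_landmarks[i],
                          max_iters=max_iters, metric=metric)
        transforms[i] = t
        aligned_landmark[i] = t.apply(norm_landmarks[i])

    data = np.empty(
        (n, *dataset.sections[0].foreground_mask.shape, len(axis)))
    masks = np.empty((n, *dataset.sections[0].foreground_mask.shape), dtype=bool)
    for i, s in enumerate(dataset.sections):
        t = transforms[i]
        if t.is_identity:
            data[i] = s.intensities
            masks[i] = s.foreground_mask
        else:
            for f in range(len(axis)):
                data[i, ..., f] = t.apply(s.intensities[..., f])
            masks[i] = t.apply(s.foreground_mask, order=0)
    return FeatureVolume(data, dataset.voxel_um, axis, masks,
                         [t for t in transforms])


# --------------------------------------------------------------------------
# inter-slice correlation QC
# --------------------------------------------------------------------------

def interslice_correlation(
    volume: FeatureVolume,
    mz: float,
    min_union_pixels: int = 10,
) -> dict:
    """Adjacent-slice correlation of the landmark channel.

    For each adjacent pair, the product-moment correlation of the landmark
    intensities over the union of the two foreground masks (a pixel
    missing on one side contributes that side's stored value, zero for
    background).  Pairs with fewer than *min_union_pixels* union pixels
    are skipped and reported.

    Returns ``{"pairs": [(i, j, r)...], "mean": float, "sd": float,
    "skipped": [(i, j)...]}``.
    """
    if volume.n_slices < 2:
        raise ValueError("need at least 2 slices")
    plane = volume.channel(mz)
    pairs, skipped = [], []
    for i in range(volume.n_slices - 1):
        union = volume.masks[i] | volume.masks[i + 1]
        if union.sum() < min_union_pixels:
            skipped.append((i, i + 1))
            continue
        a = plane[i][union]
        b = plane[i + 1][union]
        if a.std() == 0 or b.std() == 0:
            r = 0.0
        else:
            r = float(np.corrcoef(a, b)[0, 1])
        pairs.append((i, i + 1, r))
    rs = np.array([p[2] for p in pairs])
    return {
        "pairs": pairs,
        "mean": float(rs.mean()) if rs.size else float("nan"),
        "sd": float(rs.std(ddof=1)) if rs.size > 1 else 0.0,
        "skipped": skipped,
    }
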