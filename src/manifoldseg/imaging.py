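"""Image-side plumbing: multiparametric volumes, feature matrices, masks.

Converts co-registered MRI channels to the voxel-by-channel feature
matrix the manifold solvers consume, maps 1-D embeddings back onto the
image grid, computes the contrast-subtraction ground truth, thresholds
images into binary lesion masks, and block-downsamples to the study's
resolution ladder (256^2 / 128^2 / 64^2).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.measure import block_reduce

__all__ = [
    "CHANNELS",
    "T1POST",
    "MultiparametricVolume",
    "VoxelMap",
    "EmbeddedImage",
    "BinaryLesionMask",
    "stack_channels",
    "quantize_features",
    "select_informative_axis",
    "informative_projection",
    "embedding_to_image",
    "subtraction_image",
    "binarize",
    "resample_image",
    "resample_mask",
    "resample_volume",
    "save_volume",
    "load_volume",
    "save_mask",
    "load_mask",
    "save_png",
]

#: the four non-contrast input channels, in canonical order
CHANNELS = ("PD", "T2W", "FLAIR", "T1pre")
#: the post-contrast channel, reserved for ground truth
T1POST = "T1post"


@dataclass
class MultiparametricVolume:
    """Co-registered scalar channels on a shared 2-D grid.

    ``channels`` maps channel names (``PD``, ``T2W``, ``FLAIR``,
    ``T1pre`` and optionally ``T1post``) to images; ``brain_mask``
    restricts processing to intracranial voxels.
    """

    channels: dict[str, np.ndarray]
    voxel_size: tuple[float, ...] = (1.0, 1.0, 1.0)
    brain_mask: np.ndarray | None = None

    def __post_init__(self):
        if not self.channels:
            raise ValueError("volume needs at least one channel")
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels disagree on grid shape: {shapes}")
        for name, img in self.channels.items():
            if not np.all(np.isfinite(img)):
                raise ValueError(f"channel {name!r} has non-finite values")
        if self.brain_mask is not None and self.brain_mask.shape != self.shape:
            raise ValueError("brain mask shape differs from channels")

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.channels.values())).shape

    def mask_or_full(self) -> np.ndarray:
        if self.brain_mask is None:
            return np.ones(self.shape, dtype=bool)
        return self.brain_mask.astype(bool)


@dataclass
class VoxelMap:
    """Invertible map between image voxels and feature-matrix rows."""

    shape: tuple[int, ...]
    flat_indices: np.ndarray  # flat voxel index of each row

    @property
    def n_rows(self) -> int:
        return self.flat_indices.size


@dataclass
class EmbeddedImage:
    """Scalar embedded image; excluded voxels carry the background value."""

    values: np.ndarray
    excluded: np.ndarray  # bool image: outside mask or disconnected
    polarity_flipped: bool = False


@dataclass
class BinaryLesionMask:
    """Binary mask where 1 marks lesion pixels, with threshold provenance."""

    values: np.ndarray
    threshold: float | None = None
    method: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values).astype(bool)

    @property
    def n_positive(self) -> int:
        return int(self.values.sum())


def stack_channels(vol: MultiparametricVolume,
                   channel_order: tuple[str, ...] = CHANNELS,
                   normalize: str = "zscore") -> tuple[np.ndarray, VoxelMap]:
    """Flatten masked voxels into an (n_voxels, n_channels) matrix.

    The post-contrast channel is rejected by contract: it defines the
    ground truth and must never leak into the input features.
    ``normalize="zscore"`` standardizes each channel over the included
    voxels (constant channels become zeros with a warning).
    """
    if T1POST in channel_order:
        raise ValueError(f"{T1POST} is reserved for ground truth and cannot "
                         "be an input channel")
    missing = [c for c in channel_order if c not in vol.channels]
    if missing:
        raise ValueError(f"missing channels: {missing}")
    if normalize not in ("zscore", "none"):
        raise ValueError("normalize must be 'zscore' or 'none'")

    mask = vol.mask_or_full()
    if not mask.any():
        raise ValueError("brain mask is empty")
    flat_idx = np.flatnonzero(mask.ravel())

    cols = []
    for name in channel_order:
        v = vol.channels[name].ravel()[flat_idx].astype(np.float64)
        if normalize == "zscore":
            sd = v.std()
            if sd == 0:
                warnings.warn(f"channel {name!r} is constant over the mask; "
                              "z-scored to zeros")
                v = np.zeros_like(v)
            else:
                v = (v - v.mean()) / sd
        cols.append(v)
    X = np.column_stack(cols)
    return X, VoxelMap(shape=vol.shape, flat_indices=flat_idx)


def quantize_features(X: np.ndarray, max_codewords: int = 1500,
                      initial_step: float = 0.05,
                      growth: float = 1.6) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Collapse near-duplicate feature rows into a codebook.

    Voxel-level MRI features are heavily duplicated (piecewise-constant
    tissue intensities); exact duplicates also break k-NN graphs, whose
    neighbourhoods then collapse onto zero-distance clones.  Rows are
    binned on a uniform grid whose step grows geometrically until the
    number of occupied bins is at most ``max_codewords``; each codeword
    is the mean of its member rows.  In the discrete (noise-free) limit
    this is exact.

    Returns ``(codes, counts, inverse, step)`` with
    ``codes[inverse] ~= X`` row-wise and ``step == 0`` when the raw rows
    were already few enough.
    """
    X = np.asarray(X, dtype=np.float64)
    uniq, inverse, counts = np.unique(X, axis=0, return_inverse=True,
                                      return_counts=True)
    if uniq.shape[0] <= max_codewords:
        return uniq, counts, inverse, 0.0

    step = float(initial_step)
    for _ in range(64):
        keys = np.round(X / step).astype(np.int64)
        _, inverse, counts = np.unique(keys, axis=0, return_inverse=True,
                                       return_counts=True)
        m = counts.size
        if m <= max_codewords:
            codes = np.zeros((m, X.shape[1]))
            np.add.at(codes, inverse, X)
            codes /= counts[:, np.newaxis]
            return codes, counts, inverse, step
        step *= growth
    raise RuntimeError("quantization failed to reach the codeword budget")


def select_informative_axis(components: np.ndarray,
                            reference: np.ndarray,
                            percentile: float = 99.0) -> tuple[int, float]:
    """Pick the embedding component that best highlights reference-bright voxels.

    Eigen-embeddings order components by spectral softness, not by
    clinical relevance: with several weakly connected tissue clusters
    the leading component can encode e.g. CSF-versus-rest.  Scoring each
    component by the standardized contrast between voxels in the top
    ``percentile`` of the reference channel (FLAIR: lesions are
    hyperintense there) and the rest selects the axis along which
    lesion-like voxels are extreme.  Returns ``(index, sign)`` with sign
    chosen so the reference-bright voxels sit at the positive end.
    """
    comp = np.asarray(components, dtype=np.float64)
    if comp.ndim == 1:
        comp = comp[:, np.newaxis]
    ref = np.asarray(reference, dtype=np.float64).ravel()
    finite = np.all(np.isfinite(comp), axis=1) & np.isfinite(ref)
    if not finite.any():
        raise ValueError("no finite rows to score")
    cut = np.percentile(ref[finite], percentile)
    hi = finite & (ref >= cut)
    lo = finite & (ref < cut)
    if not hi.any() or not lo.any():
        return 0, 1.0
    best, best_score, best_sign = 0, -np.inf, 1.0
    for j in range(comp.shape[1]):
        y = comp[:, j]
        sd = y[finite].std()
        if sd == 0:
            continue
        score = (y[hi].mean() - y[lo].mean()) / sd
        if abs(score) > best_score:
            best, best_score = j, abs(score)
            best_sign = 1.0 if score >= 0 else -1.0
    return best, best_sign


def informative_projection(components: np.ndarray,
                           reference: np.ndarray,
                           percentile: float = 98.0
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Project a multi-component embedding onto its activity direction.

    Same anchoring idea as :func:`select_informative_axis`, but instead
    of picking one component it combines them: each component j gets
    weight ``sign(s_j) * s_j^2 / sd_j`` where ``s_j`` is its
    standardized contrast between reference-bright voxels (top
    ``percentile`` of the reference) and the rest.  The squared-contrast
    weighting means a single dominant component behaves like plain
    selection, while embeddings that split the lesion signal across
    several soft modes (typical of LLE on clustered data) are demixed.
    Returns ``(weights, projected_values)``; rows with non-finite
    components yield NaN.
    """
    comp = np.asarray(components, dtype=np.float64)
    if comp.ndim == 1:
        comp = comp[:, np.newaxis]
    ref = np.asarray(reference, dtype=np.float64).ravel()
    finite = np.all(np.isfinite(comp), axis=1) & np.isfinite(ref)
    if not finite.any():
        raise ValueError("no finite rows to score")
    cut = np.percentile(ref[finite], percentile)
    hi = finite & (ref >= cut)
    lo = finite & (ref < cut)
    if not hi.any() or not lo.any():
        w = np.zeros(comp.shape[1])
        w[0] = 1.0
        return w, comp @ w
    sd = comp[finite].std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    contrast = (comp[hi].mean(axis=0) - comp[lo].mean(axis=0)) / sd
    w = contrast * np.abs(contrast) / sd
    norm = np.linalg.norm(w)
    if norm == 0:
        w = np.zeros(comp.shape[1])
        w[0] = 1.0
    else:
        w = w / norm
    return w, comp @ w


def embedding_to_image(y: np.ndarray, vmap: VoxelMap,
                       polarity_reference: np.ndarray | None = None,
                       reference_percentile: float = 99.0) -> EmbeddedImage:
    """Place a d=1 embedding back onto the image grid.

    ``y`` holds one value per feature-matrix row; NaN rows (samples cut
    from a disconnected graph) and voxels outside the processing mask
    are set to the minimum of the finite values so they render as
    background.  If ``polarity_reference`` (typically the FLAIR channel
    restricted to the same rows) is given, the eigenvector sign is
    re-anchored so voxels bright on the reference are bright in the
    embedding — lesions are hyperintense on FLAIR, so a single-sided
    threshold then isolates them.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    if y.size != vmap.n_rows:
        raise ValueError(f"embedding has {y.size} rows, voxel map expects "
                         f"{vmap.n_rows}")
    finite = np.isfinite(y)
    if not finite.any():
        raise ValueError("embedding has no finite values")

    flipped = False
    if polarity_reference is not None:
        ref = np.asarray(polarity_reference, dtype=np.float64).ravel()
        if ref.size != y.size:
            raise ValueError("polarity reference must align with embedding rows")
        cut = np.percentile(ref[finite], reference_percentile)
        hi = finite & (ref >= cut)
        lo = finite & (ref < cut)
        if hi.any() and lo.any() and y[hi].mean() < y[lo].mean():
            y = -y
            flipped = True

    background = y[np.isfinite(y)].min()
    full = np.full(int(np.prod(vmap.shape)), background)
    vals = np.where(np.isfinite(y), y, background)
    full[vmap.flat_indices] = vals

    excluded = np.ones(int(np.prod(vmap.shape)), dtype=bool)
    excluded[vmap.flat_indices[np.isfinite(y)]] = False
    return EmbeddedImage(values=full.reshape(vmap.shape),
                         excluded=excluded.reshape(vmap.shape),
                         polarity_flipped=flipped)


def subtraction_image(vol: MultiparametricVolume) -> np.ndarray:
    """Ground-truth enhancement image: ``max(T1post - T1pre, 0)``.

    Gadolinium enhancement is an intensity increase; negative
    differences are registration or noise artifacts and are clipped.
    """
    for name in ("T1pre", T1POST):
        if name not in vol.channels:
            raise ValueError(f"subtraction image requires channel {name!r}")
    diff = vol.channels[T1POST].astype(np.float64) - vol.channels["T1pre"]
    return np.clip(diff, 0.0, None)


def binarize(img: np.ndarray | EmbeddedImage, method: str = "otsu",
             param: float | None = None,
             mask: np.ndarray | None = None) -> BinaryLesionMask:
    """Threshold an image into a binary lesion mask.

    Methods: ``otsu`` (two-class), ``multiotsu`` (three-class, keeps the
    top class), ``tail_multiotsu`` (three-class Otsu restricted to
    values above the in-mask median, keeps the top class), ``percentile``
    (``param`` = percentile) and ``absolute`` (``param`` = threshold).
    The threshold is computed over ``mask`` when given; outside voxels
    are always 0.

    ``tail_multiotsu`` exists for embedded images: lesion activity is
    one-sided (bright, once polarity is anchored to FLAIR), while the
    dark CSF end of the histogram carries large variance that would
    otherwise consume the Otsu class boundaries.  Dropping the lower
    half of the distribution leaves the bright-tail structure —
    tissue / lesion-bright / activity-bright — for the two thresholds.
    """
    if isinstance(img, EmbeddedImage):
        if mask is None:
            mask = ~img.excluded
        img = img.values
    img = np.asarray(img, dtype=np.float64)
    if not np.all(np.isfinite(img)):
        raise ValueError("image has non-finite values")
    sel = np.ones(img.shape, dtype=bool) if mask is None else mask.astype(bool)
    vals = img[sel]
    if method == "tail_multiotsu":
        vals = vals[vals >= np.median(vals)]

    if method in ("otsu", "multiotsu", "tail_multiotsu") and \
            np.unique(vals).size < (2 if method == "otsu" else 3):
        warnings.warn(f"image too flat for {method} thresholding; empty mask")
        return BinaryLesionMask(values=np.zeros(img.shape, dtype=bool),
                                threshold=None, method=method)
    if method == "otsu":
        thr = float(threshold_otsu(vals))
    elif method in ("multiotsu", "tail_multiotsu"):
        thr = float(threshold_multiotsu(vals, classes=3)[-1])
    elif method == "percentile":
        if param is None:
            raise ValueError("percentile method needs param")
        thr = float(np.percentile(vals, param))
    elif method == "absolute":
        if param is None:
            raise ValueError("absolute method needs param")
        thr = float(param)
    else:
        raise ValueError(f"unknown threshold method {method!r}")

    out = (img > thr) & sel
    return BinaryLesionMask(values=out, threshold=thr, method=method)


def _block_factor(shape, target):
    facs = []
    for s, t in zip(shape, target):
        if t > s:
            raise ValueError("upsampling is not supported")
        if s % t:
            raise ValueError(f"target {t} does not divide source {s}")
        facs.append(s // t)
    return tuple(facs)


def resample_image(img: np.ndarray, target: tuple[int, ...]) -> np.ndarray:
    """Anti-aliased block-mean downsampling to ``target`` shape."""
    f = _block_factor(img.shape, target)
    return block_reduce(img.astype(np.float64), f, np.mean)


def resample_mask(mask: np.ndarray, target: tuple[int, ...]) -> np.ndarray:
    """Downsample a binary mask by majority vote (>= 0.5 occupancy)."""
    f = _block_factor(mask.shape, target)
    return block_reduce(mask.astype(np.float64), f, np.mean) >= 0.5


def resample_volume(vol: MultiparametricVolume,
                    target: tuple[int, ...]) -> MultiparametricVolume:
    """Downsample every channel (block mean) and the mask (majority)."""
    channels = {n: resample_image(img, target) for n, img in vol.channels.items()}
    mask = None if vol.brain_mask is None else resample_mask(vol.brain_mask, target)
    scale = [s / t for s, t in zip(vol.shape, target)]
    voxel = tuple(v * s for v, s in zip(vol.voxel_size, scale + [1.0] * 3))[:len(vol.voxel_size)]
    return MultiparametricVolume(channels=channels, voxel_size=voxel,
                                 brain_mask=mask)


# ---------------------------------------------------------------------------
# NIfTI / manifest I/O


def _nifti_affine(voxel_size):
    aff = np.eye(4)
    for i, v in enumerate(tuple(voxel_size)[:3]):
        aff[i, i] = v
    return aff


def _to_3d(img: np.ndarray) -> np.ndarray:
    return img[..., np.newaxis] if img.ndim == 2 else img


def save_volume(vol: MultiparametricVolume, out_dir: str | Path,
                prefix: str = "") -> Path:
    """Write each channel (and mask) as NIfTI plus a YAML channel manifest.

    Returns the manifest path, which :func:`load_volume` consumes.
    """
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = _nifti_affine(vol.voxel_size)
    manifest: dict = {"channels": {}, "voxel_size": list(vol.voxel_size)}
    for name, img in vol.channels.items():
        fn = f"{prefix}{name}.nii.gz"
        nib.save(nib.Nifti1Image(_to_3d(img).astype(np.float32), aff), out_dir / fn)
        manifest["channels"][name] = fn
    if vol.brain_mask is not None:
        fn = f"{prefix}brain_mask.nii.gz"
        nib.save(nib.Nifti1Image(_to_3d(vol.brain_mask).astype(np.uint8), aff),
                 out_dir / fn)
        manifest["brain_mask"] = fn
    path = out_dir / f"{prefix}manifest.yaml"
    path.write_text(yaml.safe_dump(manifest))
    return path


def load_volume(manifest_path: str | Path) -> MultiparametricVolume:
    """Load a volume from a YAML channel manifest written by save_volume."""
    import nibabel as nib

    manifest_path = Path(manifest_path)
    manifest = yaml.safe_load(manifest_path.read_text())
    base = manifest_path.parent
    channels = {}
    for name, fn in manifest["channels"].items():
        data = np.asarray(nib.load(base / fn).dataobj, dtype=np.float64)
        channels[name] = np.squeeze(data)
    mask = None
    if manifest.get("brain_mask"):
        mask = np.squeeze(np.asarray(
            nib.load(base / manifest["brain_mask"]).dataobj)) > 0
    voxel = tuple(manifest.get("voxel_size", (1.0, 1.0, 1.0)))
    return MultiparametricVolume(channels=channels, voxel_size=voxel,
                                 brain_mask=mask)


def save_mask(mask: BinaryLesionMask | np.ndarray, path: str | Path,
              voxel_size=(1.0, 1.0, 1.0)) -> None:
    import nibabel as nib

    values = mask.values if isinstance(mask, BinaryLesionMask) else mask
    nib.save(nib.Nifti1Image(_to_3d(np.asarray(values)).astype(np.uint8),
                             _nifti_affine(voxel_size)), str(path))


def load_mask(path: str | Path) -> np.ndarray:
    import nibabel as nib

    return np.squeeze(np.asarray(nib.load(str(path)).dataobj)) > 0


def save_png(img: np.ndarray, path: str | Path, cmap: str = "gray") -> None:
    """Export a slice as PNG for quick visual reports."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.imsave(str(path), np.asarray(img, dtype=np.float64), cmap=cmap)
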