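"""Synthetic benchmarks: the Swiss-roll manifold and brain MRI phantoms.

The phantom emulates the statistical structure the lesion-segmentation
pipeline relies on, not MR acquisition physics: co-registered PD / T2W /
FLAIR / pre-contrast T1W channels with distinct tissue contrasts
(CSF, grey matter, white matter), hyperintense white-matter lesions, a
subset of "active" lesions that enhance on a held-out post-contrast T1W
channel, additive noise and an optional smooth bias field.

Crucially, active and inactive lesions differ on the four non-contrast
channels only through a *joint* signature: each lesion draws a nuisance
offset that moves FLAIR and T1pre in opposite directions, while activity
adds a common positive offset to both.  No single channel then separates
active from inactive pixels well, but the FLAIR+T1pre sum does — the
premise that activity information is carried jointly by the non-contrast
channels.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .imaging import CHANNELS, T1POST, MultiparametricVolume

__all__ = [
    "SwissRollSample",
    "PhantomSpec",
    "PhantomVolume",
    "make_swiss_roll",
    "make_phantom",
    "make_cohort",
    "lesion_separability",
    "DEFAULT_TISSUE_MEANS",
]


# ---------------------------------------------------------------------------
# Swiss roll


@dataclass
class SwissRollSample:
    """3-D Swiss-roll point cloud with its intrinsic 2-D coordinates."""

    points: np.ndarray      # (n, 3)
    intrinsic: np.ndarray   # (n, 2): (arc length along spiral, height)
    noise_sd: float
    seed: int


def _spiral_arclength(t: np.ndarray) -> np.ndarray:
    # arc length of r = t from 0: integral of sqrt(1 + u^2) du
    return 0.5 * (t * np.sqrt(1.0 + t ** 2) + np.arcsinh(t))


def make_swiss_roll(n: int, noise_sd: float = 0.0, seed: int = 0) -> SwissRollSample:
    """Sample the standard Swiss roll ``(t cos t, h, t sin t)``.

    ``t`` is uniform on [1.5*pi, 4.5*pi] and the height ``h`` uniform on
    [0, 21].  The intrinsic chart is (exact spiral arc length, height),
    so the unrolled pairwise distances are available in closed form.
    """
    if n < 50:
        raise ValueError("need n >= 50 points")
    rng = np.random.default_rng(seed)
    t = rng.uniform(1.5 * np.pi, 4.5 * np.pi, size=n)
    h = rng.uniform(0.0, 21.0, size=n)
    points = np.column_stack([t * np.cos(t), h, t * np.sin(t)])
    if noise_sd > 0:
        points = points + rng.normal(0.0, noise_sd, size=points.shape)
    intrinsic = np.column_stack([_spiral_arclength(t), h])
    return SwissRollSample(points=points, intrinsic=intrinsic,
                           noise_sd=float(noise_sd), seed=int(seed))


# ---------------------------------------------------------------------------
# Brain phantom

#: per-tissue mean intensities (arbitrary units) for each channel.
#: Ordering trends follow textbook contrasts: CSF bright on PD/T2 and
#: suppressed on FLAIR; lesions hyperintense on PD/T2/FLAIR and mildly
#: hypointense on T1.
DEFAULT_TISSUE_MEANS: dict[str, dict[str, float]] = {
    "CSF": {"PD": 66.0, "T2W": 62.0, "FLAIR": 30.0, "T1pre": 40.0},
    "GM": {"PD": 58.0, "T2W": 52.0, "FLAIR": 48.0, "T1pre": 50.0},
    "WM": {"PD": 50.0, "T2W": 45.0, "FLAIR": 42.0, "T1pre": 58.0},
    # lesion base signature: hyperintense on PD/T2/FLAIR and, unlike
    # chronic-lesion textbook contrast, also elevated on T1pre — chosen
    # (with the offsets below) by the one-off generator calibration so
    # that per-lesion nuisance variability stays orthogonal to the
    # lesion-versus-tissue axis in feature space
    "lesion": {"PD": 62.0, "T2W": 60.0, "FLAIR": 58.0, "T1pre": 70.0},
}

#: integer labels of the tissue map
LABELS = {"background": 0, "CSF": 1, "GM": 2, "WM": 3, "lesion": 4,
          "active_lesion": 5}


@dataclass
class PhantomSpec:
    """Parameters of one synthetic multiparametric brain slice.

    The activity signature and nuisance-jitter amplitudes were frozen
    by a one-off calibration of the generator so that (a) the best
    single-channel threshold stays a weak active-vs-inactive classifier
    while a two-channel linear rule is a strong one, and (b) the
    noise-free pipeline recovers the active mask nearly exactly.
    """

    shape: tuple[int, int] = (256, 256)
    tissue_means: dict = field(default_factory=lambda:
                               {k: dict(v) for k, v in DEFAULT_TISSUE_MEANS.items()})
    n_lesions: int = 10
    lesion_radius: tuple[float, float] = (5.0, 10.0)  # pixels at 256^2
    active_fraction: float = 0.5
    #: common positive offset added to FLAIR and T1pre of active lesions
    activity_offset: float = 14.0
    #: half-range of the per-lesion nuisance offset (+eta on FLAIR,
    #: -eta on T1pre, small compensating PD/T2W term), drawn
    #: Uniform(-a, a) for every lesion; overlaps the per-channel
    #: activity signature so no single channel separates the classes
    jitter_amplitude: float = 24.0
    #: enhancement added to T1post inside active lesions
    enhancement: float = 25.0
    #: Gaussian point-spread sigma (pixels at 256^2) emulating the
    #: partial-volume effect; boundary voxels form the continuous
    #: transitions between tissue clusters that make the data a manifold
    partial_volume_sigma: float = 0.7
    noise_sd: float = 2.0
    noise_model: str = "gaussian"  # or "rician"
    bias_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.enhancement <= 0:
            raise ValueError("enhancement must be > 0 (active lesions must "
                             "enhance on T1post)")
        if not 0.0 <= self.active_fraction <= 1.0:
            raise ValueError("active_fraction must lie in [0, 1]")
        if self.lesion_radius[0] > self.lesion_radius[1]:
            raise ValueError("lesion_radius must be (min, max)")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")


@dataclass
class PhantomVolume:
    """A MultiparametricVolume plus its generating ground truth."""

    volume: MultiparametricVolume
    lesion_mask: np.ndarray        # all lesions
    active_mask: np.ndarray        # enhancing subset
    labels: np.ndarray             # tissue label map (LABELS codes)
    spec: PhantomSpec


def _ellipse(shape, center, semi) -> np.ndarray:
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return (((rr - center[0]) / semi[0]) ** 2 +
            ((cc - center[1]) / semi[1]) ** 2) <= 1.0


def _tissue_geometry(shape) -> np.ndarray:
    """Concentric head geometry: CSF rim, GM ribbon, WM core, ventricles."""
    h, w = shape
    center = (h * 0.5, w * 0.5)
    labels = np.zeros(shape, dtype=np.uint8)
    outer = _ellipse(shape, center, (h * 0.42, w * 0.36))
    csf_in = _ellipse(shape, center, (h * 0.40, w * 0.34))
    gm_in = _ellipse(shape, center, (h * 0.34, w * 0.28))
    labels[outer] = LABELS["CSF"]
    labels[csf_in] = LABELS["GM"]
    labels[gm_in] = LABELS["WM"]
    for dc in (-0.06, 0.06):
        vent = _ellipse(shape, (h * 0.48, w * (0.5 + dc)),
                        (h * 0.10, w * 0.035))
        labels[vent] = LABELS["CSF"]
    return labels


def _place_lesions(labels: np.ndarray, spec: PhantomSpec,
                   rng: np.random.Generator):
    """Sample non-overlapping disks strictly inside white matter."""
    h, w = labels.shape
    scale = min(h, w) / 256.0
    wm = labels == LABELS["WM"]
    rr, cc = np.mgrid[0:h, 0:w]
    lesions = []
    occupied = np.zeros_like(wm)
    for i in range(spec.n_lesions):
        placed = False
        for _ in range(400):
            r = rng.uniform(*spec.lesion_radius) * scale
            r = max(r, 1.0)
            y = rng.uniform(r, h - r)
            x = rng.uniform(r, w - r)
            disk = (rr - y) ** 2 + (cc - x) ** 2 <= r ** 2
            # disk (with a 1px moat) must sit in WM and clear of others
            moat = (rr - y) ** 2 + (cc - x) ** 2 <= (r + 2.0 * scale) ** 2
            if disk.sum() < 4:
                continue
            if not np.all(wm[moat]) or np.any(occupied[moat]):
                continue
            lesions.append(disk)
            occupied |= disk
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place lesion {i + 1}/{spec.n_lesions}; "
                "reduce count or radius")
    return lesions


def _jitter_direction(tissue_means: dict) -> np.ndarray:
    """Per-lesion nuisance direction in channel space.

    The jitter models biological variability across lesions that is
    uninformative about activity.  It is built orthogonal to the
    activity direction (equal positive FLAIR and T1pre components) and
    to the lesion-vs-WM contrast vector, so lesion-to-lesion variation
    overlaps the per-channel activity signature without moving lesions
    along the axis that separates lesions from tissue: FLAIR gains
    +eta, T1pre -eta, and PD/T2W a compensating common component.
    """
    lam = np.array([tissue_means["lesion"][ch] - tissue_means["WM"][ch]
                    for ch in CHANNELS])
    d = {ch: j for j, ch in enumerate(CHANNELS)}
    u = np.zeros(len(CHANNELS))
    u[d["FLAIR"]], u[d["T1pre"]] = 1.0, -1.0
    pt = lam[d["PD"]] + lam[d["T2W"]]
    if abs(pt) > 1e-9:
        t = -(lam[d["FLAIR"]] - lam[d["T1pre"]]) / pt
        u[d["PD"]] = u[d["T2W"]] = t
    return u


def _smooth_bias(shape, amplitude, rng) -> np.ndarray:
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    u = (rr - h / 2) / h
    v = (cc - w / 2) / w
    coef = rng.uniform(-1.0, 1.0, size=5)
    f = coef[0] * u + coef[1] * v + coef[2] * u * v + coef[3] * u ** 2 + coef[4] * v ** 2
    f = f / max(np.abs(f).max(), 1e-12)
    return 1.0 + amplitude * f


def make_phantom(spec: PhantomSpec | None = None) -> PhantomVolume:
    """Generate one multiparametric brain slice with ground truth.

    Deterministic in ``spec`` (including its seed).  The returned volume
    carries the four input channels, the held-out T1post channel, and a
    brain mask; ``active_mask`` equals the support of the noise-free
    subtraction image by construction.
    """
    spec = PhantomSpec() if spec is None else spec
    rng = np.random.default_rng(spec.seed)
    labels = _tissue_geometry(spec.shape)
    lesions = _place_lesions(labels, spec, rng)

    n_active = int(round(spec.n_lesions * spec.active_fraction))
    order = rng.permutation(len(lesions))
    active_ids = set(order[:n_active].tolist())

    means = {name: np.zeros(spec.shape) for name in CHANNELS}
    for tissue in ("CSF", "GM", "WM"):
        sel = labels == LABELS[tissue]
        for ch in CHANNELS:
            means[ch][sel] = spec.tissue_means[tissue][ch]

    jitter_dir = _jitter_direction(spec.tissue_means)
    lesion_mask = np.zeros(spec.shape, dtype=bool)
    active_mask = np.zeros(spec.shape, dtype=bool)
    for i, disk in enumerate(lesions):
        eta = rng.uniform(-spec.jitter_amplitude, spec.jitter_amplitude)
        base = spec.tissue_means["lesion"]
        offsets = {ch: base[ch] + eta * jitter_dir[j]
                   for j, ch in enumerate(CHANNELS)}
        if i in active_ids:
            offsets["FLAIR"] += spec.activity_offset
            offsets["T1pre"] += spec.activity_offset
            active_mask |= disk
            labels[disk] = LABELS["active_lesion"]
        else:
            labels[disk] = LABELS["lesion"]
        lesion_mask |= disk
        for ch in CHANNELS:
            means[ch][disk] = offsets[ch]

    t1post = means["T1pre"].copy()
    t1post[active_mask] += spec.enhancement

    brain = labels > 0
    channels = {}
    all_means = dict(means)
    all_means[T1POST] = t1post
    if spec.partial_volume_sigma > 0:
        from scipy.ndimage import gaussian_filter
        sigma = spec.partial_volume_sigma * min(spec.shape) / 256.0
        # blur only inside the head: background stays at zero exactly
        for ch in all_means:
            all_means[ch] = np.where(brain, gaussian_filter(all_means[ch], sigma),
                                     all_means[ch])

    for ch, img in all_means.items():
        out = img.copy()
        if spec.bias_amplitude > 0:
            out = out * _smooth_bias(spec.shape, spec.bias_amplitude, rng)
        if spec.noise_sd > 0:
            if spec.noise_model == "gaussian":
                out = out + rng.normal(0.0, spec.noise_sd, size=spec.shape)
            else:  # rician: magnitude of a complex Gaussian around the mean
                re = out + rng.normal(0.0, spec.noise_sd, size=spec.shape)
                im = rng.normal(0.0, spec.noise_sd, size=spec.shape)
                out = np.sqrt(re ** 2 + im ** 2)
        channels[ch] = out

    vol = MultiparametricVolume(channels=channels, brain_mask=brain,
                                voxel_size=(0.94, 0.94, 1.5))
    return PhantomVolume(volume=vol, lesion_mask=lesion_mask,
                         active_mask=active_mask, labels=labels, spec=spec)


def make_cohort(spec: PhantomSpec | None = None, n_subjects: int = 40,
                seed: int = 0) -> list[PhantomVolume]:
    """A cohort of phantoms with jittered lesion counts and sizes.

    Per-subject seeds derive from the master seed, so the same master
    seed reproduces the identical cohort.
    """
    base = PhantomSpec() if spec is None else spec
    rng = np.random.default_rng(seed)
    cohort = []
    for _ in range(n_subjects):
        n_les = int(np.clip(base.n_lesions + rng.integers(-2, 3), 2, None))
        lo, hi = base.lesion_radius
        r_scale = rng.uniform(0.85, 1.15)
        sub = dataclasses.replace(
            base,
            n_lesions=n_les,
            lesion_radius=(lo * r_scale, hi * r_scale),
            seed=int(rng.integers(0, 2 ** 31 - 1)),
        )
        cohort.append(make_phantom(sub))
    return cohort


# ---------------------------------------------------------------------------
# Separability diagnostics


def _balanced_accuracy_1d(x: np.ndarray, y: np.ndarray) -> float:
    """Best balanced accuracy of a single threshold on x (either polarity)."""
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order].astype(np.float64)
    n1 = ys.sum()
    n0 = ys.size - n1
    if n1 == 0 or n0 == 0:
        return 1.0
    # cumulative class counts below each cut point
    c1 = np.concatenate([[0.0], np.cumsum(ys)])
    c0 = np.concatenate([[0.0], np.cumsum(1.0 - ys)])
    # predict 1 above the cut
    bacc_hi = 0.5 * ((n1 - c1) / n1 + c0 / n0)
    return float(np.maximum(bacc_hi, 1.0 - bacc_hi).max())


def lesion_separability(phantoms, channels: tuple[str, str] = ("FLAIR", "T1pre")
                        ) -> dict[str, float]:
    """How separable are active vs inactive lesion pixels, per channel?

    Pools lesion pixels over the given phantoms and reports the best
    single-channel threshold balanced accuracy for each input channel,
    and the balanced accuracy of a Fisher linear discriminant on the
    two channels named in ``channels``.
    """
    feats = {ch: [] for ch in CHANNELS}
    ys = []
    for ph in phantoms:
        sel = ph.lesion_mask
        inact = sel & ~ph.active_mask
        act = ph.active_mask
        for ch in CHANNELS:
            img = ph.volume.channels[ch]
            feats[ch].append(np.concatenate([img[inact], img[act]]))
        ys.append(np.concatenate([np.zeros(int(inact.sum())),
                                  np.ones(int(act.sum()))]))
    y = np.concatenate(ys)
    out: dict[str, float] = {}
    for ch in CHANNELS:
        out[f"single_{ch}"] = _balanced_accuracy_1d(np.concatenate(feats[ch]), y)
    out["best_single"] = max(out[f"single_{ch}"] for ch in CHANNELS)

    X2 = np.column_stack([np.concatenate(feats[channels[0]]),
                          np.concatenate(feats[channels[1]])])
    mu0 = X2[y == 0].mean(axis=0)
    mu1 = X2[y == 1].mean(axis=0)
    Xc = np.vstack([X2[y == 0] - mu0, X2[y == 1] - mu1])
    cov = (Xc.T @ Xc) / max(len(Xc) - 2, 1)
    wvec = np.linalg.solve(cov + 1e-9 * np.eye(2), mu1 - mu0)
    out["two_channel"] = _balanced_accuracy_1d(X2 @ wvec, y)
    return out
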