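"""Synthetic brightfield organoid z-stack time-series generator.

Emulates the three morphological trajectories that distinguish DILI severity
classes in brightfield organoid imaging:

* **vNo-DILI-Concern** — the organoid keeps growing into a translucent hollow
  sphere with a clear boundary (rendered as an annulus: bright lumen, dark rim).
* **vLess-DILI-Concern** — growth arrest; the sphere stays intact at roughly
  its initial diameter.
* **vMost-DILI-Concern** — progressive cell death; from the disintegration
  onset day (default Day 2) the sphere breaks into scattered irregular
  fragments.

Each sample is a T x Z grid of grayscale fields (T daily time points, Z focal
planes). Out-of-focus planes are emulated with a Gaussian blur whose width
grows linearly with the distance from each organoid's focal depth, so the
z-axis carries real information. All randomness derives from an explicit
integer seed; identical calls are bit-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError, LabelingError

__all__ = [
    "SimConfig",
    "OrganoidState",
    "OrganoidStack",
    "render_field",
    "generate_sample",
    "generate_dataset",
    "phenotype_features",
    "foreground_mask",
]

#: label vocabulary, in fixed class-index order
LABELS = ("vNo-DILI-Concern", "vLess-DILI-Concern", "vMost-DILI-Concern")

#: small compound vocabulary per class (drawn from the DILIrank-style panel)
_COMPOUNDS = {
    "vNo-DILI-Concern": ("Chlorpheniramine", "Digoxin", "Diphenhydramine", "Hydrocortisone", "Lidocaine", "Vinblastine"),
    "vLess-DILI-Concern": ("Pioglitazone", "Entacapone", "Cyclophosphamide", "Paclitaxel", "Dasatinib", "Simvastatin"),
    "vMost-DILI-Concern": ("Troglitazone", "Tolcapone", "Nefazodone", "Trovafloxacin", "Gefitinib", "Isoniazid"),
}

_BACKGROUND = 0.82  # brightfield background intensity


@dataclass(frozen=True)
class SimConfig:
    """Phenotype-dynamics, optics and noise parameters of the simulator.

    Pixel-valued defaults are expressed at the reference frame size of 224 px;
    use :meth:`scaled` to derive a consistent configuration at another
    resolution without touching the phenotype dynamics.
    """

    image_size: int = 224
    n_days: int = 4
    z_planes_range: tuple[int, int] = (12, 20)
    organoids_per_field: tuple[int, int] = (2, 6)
    init_radius_px: tuple[float, float] = (14.0, 24.0)
    #: per-class relative radius growth per day (class-index order)
    growth_rate_per_day: tuple[float, float, float] = (0.22, 0.0, 0.04)
    disintegration_onset_day: int = 2
    fragment_count_range: tuple[int, int] = (3, 6)
    #: Gaussian blur sigma (px) per unit z-offset from an organoid's focal depth
    defocus_sigma_per_plane: float = 1.0
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.image_size <= 0:
            raise ConfigurationError(f"image_size must be positive, got {self.image_size}")
        if self.n_days < 1:
            raise ConfigurationError("n_days must be >= 1")
        if self.init_radius_px[0] <= 0:
            raise ConfigurationError("init_radius_px must be positive")
        if self.z_planes_range[0] < 1 or self.z_planes_range[0] > self.z_planes_range[1]:
            raise ConfigurationError(f"bad z_planes_range {self.z_planes_range}")
        if self.growth_rate_per_day[0] <= self.growth_rate_per_day[1]:
            raise ConfigurationError("growth rate for the no-concern class must exceed the less-concern class")

    def scaled(self, image_size: int) -> "SimConfig":
        """Same phenotype dynamics at a different frame size (pixel quantities rescaled)."""
        s = image_size / self.image_size
        return dataclasses.replace(
            self,
            image_size=image_size,
            init_radius_px=(self.init_radius_px[0] * s, self.init_radius_px[1] * s),
            defocus_sigma_per_plane=self.defocus_sigma_per_plane * s,
        )


@dataclass
class OrganoidState:
    """Geometry of one organoid in one field at one day."""

    center: tuple[float, float]  # (row, col) px
    radius: float
    ring_thickness: float
    focal_depth: float  # in z-plane index units
    #: None while intact; list of (row, col, sigma) dark blobs once disintegrated
    fragments: list[tuple[float, float, float]] | None = None


@dataclass
class OrganoidStack:
    """One sample: a T x Z grid of brightfield frames plus metadata."""

    sample_id: str
    label: str
    compound: str
    platform: str
    images: np.ndarray  # (T, Z, H, W) float32 in [0, 1]
    z_positions: np.ndarray  # (Z,) ordered focal depths
    day_indices: np.ndarray  # 0..T-1

    @property
    def n_days(self) -> int:
        return self.images.shape[0]

    @property
    def n_planes(self) -> int:
        return self.images.shape[1]


def _ring_profile(size: int, state: OrganoidState, blur_sigma: float) -> np.ndarray:
    """Additive intensity deviation of one organoid, already defocus-blurred.

    Rendered into a local crop for speed, then pasted into a full frame.
    """
    if state.radius < 0:
        raise ConfigurationError(f"negative organoid radius {state.radius}")
    cy, cx = state.center
    if state.fragments is None:
        extent = state.radius + 3 * state.ring_thickness
    else:
        extent = max(
            np.hypot(fy - cy, fx - cx) + 4 * fs for fy, fx, fs in state.fragments
        )
    pad = int(np.ceil(extent + 4 * blur_sigma + 2))
    y0, y1 = int(np.floor(cy)) - pad, int(np.floor(cy)) + pad + 1
    x0, x1 = int(np.floor(cx)) - pad, int(np.floor(cx)) + pad + 1
    yy, xx = np.mgrid[y0:y1, x0:x1]
    delta = np.zeros(yy.shape)
    if state.fragments is None:
        d = np.hypot(yy - cy, xx - cx)
        # dark rim: Gaussian bump centred on the sphere boundary
        delta -= 0.50 * np.exp(-(((d - state.radius) / state.ring_thickness) ** 2))
        # translucent lumen: slight brightening inside the rim
        delta += 0.06 * (1.0 / (1.0 + np.exp((d - state.radius + state.ring_thickness) / 1.5)))
    else:
        for fy, fx, fs in state.fragments:
            df = np.hypot(yy - fy, xx - fx)
            delta -= 0.45 * np.exp(-((df / fs) ** 2))
    if blur_sigma > 1e-3:
        delta = gaussian_filter(delta, blur_sigma, mode="constant")
    # paste crop into the frame (clipping at borders)
    frame = np.zeros((size, size))
    fy0, fy1 = max(y0, 0), min(y1, size)
    fx0, fx1 = max(x0, 0), min(x1, size)
    if fy0 < fy1 and fx0 < fx1:
        frame[fy0:fy1, fx0:fx1] = delta[fy0 - y0 : fy1 - y0, fx0 - x0 : fx1 - x0]
    return frame


def render_field(
    day: int,
    z_offset: float,
    organoid_states: list[OrganoidState],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render one focal plane of one field at one day.

    Intact organoids appear as bright-lumen / dark-rim rings; disintegrated
    ones as scattered dark blobs. Each organoid is blurred with
    ``sigma = defocus_sigma_per_plane * |z_offset - focal_depth|``; additive
    Gaussian noise is applied and the result clipped to [0, 1].
    """
    if cfg.image_size <= 0:
        raise ConfigurationError("image_size must be positive")
    img = np.full((cfg.image_size, cfg.image_size), _BACKGROUND)
    for state in organoid_states:
        sigma = cfg.defocus_sigma_per_plane * abs(z_offset - state.focal_depth)
        img += _ring_profile(cfg.image_size, state, sigma)
    if cfg.noise_sd > 0:
        img += rng.normal(0.0, cfg.noise_sd, img.shape)
    return np.clip(img, 0.0, 1.0)


def _sample_geometry(label: str, cfg: SimConfig, rng: np.random.Generator):
    """Draw the per-sample latent state: Z, organoid placement and dynamics."""
    z_count = int(rng.integers(cfg.z_planes_range[0], cfg.z_planes_range[1] + 1))
    n_org = int(rng.integers(cfg.organoids_per_field[0], cfg.organoids_per_field[1] + 1))
    size = cfg.image_size
    r_max = cfg.init_radius_px[1]
    # keep intact spheres from merging even after three days of growth
    margin = 2.2 * r_max
    min_sep = 3.2 * r_max
    centers: list[tuple[float, float]] = []
    for _ in range(2000):
        if len(centers) == n_org:
            break
        cand = tuple(rng.uniform(margin, size - margin, size=2))
        if all(np.hypot(cand[0] - c[0], cand[1] - c[1]) >= min_sep for c in centers):
            centers.append(cand)
    n_org = len(centers)  # dense configs may place fewer
    radii = rng.uniform(cfg.init_radius_px[0], cfg.init_radius_px[1], size=n_org)
    focal = rng.uniform(0.0, z_count - 1.0, size=n_org)
    thickness = max(1.5, 0.01 * size)
    growth = cfg.growth_rate_per_day[LABELS.index(label)]
    onset = cfg.disintegration_onset_day

    organoids = []
    for i in range(n_org):
        frag = None
        if label == LABELS[2]:
            # fragment layout drawn once; applied from the onset day onward
            k = int(rng.integers(cfg.fragment_count_range[0], cfg.fragment_count_range[1] + 1))
            r_onset = radii[i] * (1.0 + growth) ** onset
            angles = np.arange(k) * 2 * np.pi / k + rng.uniform(-0.25, 0.25, size=k)
            dists = rng.uniform(0.55, 1.0, size=k) * r_onset
            sizes = rng.uniform(0.22, 0.33, size=k) * r_onset
            frag = [
                (
                    centers[i][0] + float(dists[j] * np.sin(angles[j])),
                    centers[i][1] + float(dists[j] * np.cos(angles[j])),
                    float(sizes[j]),
                )
                for j in range(k)
            ]
        organoids.append((centers[i], radii[i], focal[i], frag))
    return z_count, organoids, thickness, growth, onset


def _states_for_day(day, organoids, thickness, growth, onset, label) -> list[OrganoidState]:
    states = []
    disintegrated = label == LABELS[2] and day >= onset
    for center, r0, focal, frag in organoids:
        radius = r0 * (1.0 + growth) ** min(day, onset if label == LABELS[2] else day)
        states.append(
            OrganoidState(
                center=center,
                radius=radius,
                ring_thickness=thickness,
                focal_depth=focal,
                fragments=frag if disintegrated else None,
            )
        )
    return states


def generate_sample(label: str, cfg: SimConfig, seed: int, sample_id: str | None = None, platform: str = "HLO") -> OrganoidStack:
    """Generate one labeled T x Z brightfield stack. Same seed, same bits."""
    if label not in LABELS:
        raise LabelingError(f"unknown DILI label {label!r}; expected one of {LABELS}")
    rng = np.random.default_rng([seed, LABELS.index(label)])
    z_count, organoids, thickness, growth, onset = _sample_geometry(label, cfg, rng)
    compound = _COMPOUNDS[label][int(rng.integers(len(_COMPOUNDS[label])))]
    images = np.empty((cfg.n_days, z_count, cfg.image_size, cfg.image_size), dtype=np.float32)
    for day in range(cfg.n_days):
        states = _states_for_day(day, organoids, thickness, growth, onset, label)
        for z in range(z_count):
            images[day, z] = render_field(day, float(z), states, cfg, rng)
    return OrganoidStack(
        sample_id=sample_id or f"S{seed:06d}",
        label=label,
        compound=compound,
        platform=platform,
        images=images,
        z_positions=np.arange(z_count, dtype=float),
        day_indices=np.arange(cfg.n_days),
    )


def generate_dataset(n_per_class: int, cfg: SimConfig, seed: int, out_dir: str | Path):
    """Generate a balanced labeled dataset on disk and return its index.

    Writes one 16-bit grayscale TIFF per (sample, day, z) plus a CSV index
    with one row per image (header
    ``sample_id,label,compound,platform,day,z,path``). No timestamps are
    written, so repeated runs with the same arguments are byte-identical.
    """
    if n_per_class < 1:
        raise ConfigurationError("n_per_class must be >= 1")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    rows = []
    idx = 0
    for ci, label in enumerate(LABELS):
        for j in range(n_per_class):
            sid = f"S{idx:04d}"
            stack = generate_sample(label, cfg, seed=seed * 100_000 + idx, sample_id=sid)
            for day in range(stack.n_days):
                for z in range(stack.n_planes):
                    rel = f"{sid}_d{day}_z{z:02d}.tif"
                    arr = (stack.images[day, z] * 65535.0 + 0.5).astype(np.uint16)
                    tifffile.imwrite(out_dir / rel, arr)
                    rows.append((sid, label, stack.compound, stack.platform, day, z, rel))
            idx += 1
    df = pd.DataFrame(rows, columns=["sample_id", "label", "compound", "platform", "day", "z", "path"])
    df.to_csv(out_dir / "index.csv", index=False)
    from .data_io import DatasetIndex  # local import to avoid a cycle

    return DatasetIndex(df, base_dir=out_dir)


# ---------------------------------------------------------------------------
# simple morphology measurements (used by tests and the separability check)


def foreground_mask(image: np.ndarray, threshold: float = 0.15) -> np.ndarray:
    """Pixels deviating from the brightfield background by more than `threshold`."""
    return np.abs(np.asarray(image, dtype=float) - _BACKGROUND) > threshold


def count_components(mask: np.ndarray, min_size: int = 4) -> int:
    """8-connected foreground components, ignoring speckles below `min_size` px."""
    from scipy.ndimage import label as cc_label

    labeled, n = cc_label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return 0
    sizes = np.bincount(labeled.ravel())[1:]
    return int((sizes >= min_size).sum())


def phenotype_features(stack: OrganoidStack, threshold: float = 0.15) -> dict:
    """Hand-crafted per-sample features: foreground-area growth and fragmentation.

    Uses a per-pixel max-deviation projection across z so every organoid is
    measured near its own focal plane. Returns the day-T/day-0 foreground area
    ratio and the day-0 / final-day connected-component counts.
    """
    size = stack.images.shape[-1]
    min_size = max(4, int(round((0.018 * size) ** 2)))

    def day_measurements(day):
        dev = np.abs(stack.images[day].astype(float) - _BACKGROUND).max(axis=0)
        mask = dev > threshold
        n_comp = count_components(mask, min_size=min_size)
        return mask.sum(), n_comp

    area0, comp0 = day_measurements(0)
    area1, comp1 = day_measurements(stack.n_days - 1)
    return {
        "area_ratio": float(area1) / max(float(area0), 1.0),
        "components_day0": int(comp0),
        "components_final": int(comp1),
    }
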