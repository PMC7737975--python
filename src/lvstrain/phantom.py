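"""Synthetic deformable left-ventricular short-axis phantom.

The phantom stands in for a cine CMR study of one heart: a stack of
parallel short-axis slices through an ellipsoid-cap cavity whose
endocardial circumference shortens from end-diastole (ED, frame 0) to
end-systole (ES, last frame) following prescribed regional peak strains.
Every per-slice, per-frame cross-section is a circle of known radius, so
perimeters, areas, volumes, strains and the ejection fraction all have
closed forms that downstream measurement code can be checked against.

On top of the noise-free geometry the generator emulates the two error
sources a multi-reader, multi-software contouring study exhibits:

* reader noise — two components: a per-session radial offset (a reader's
  consistent tendency to trace tight or wide, constant across that
  session's slices and frames, SD ``reader_bias_sd``) and a smooth
  zero-mean angular perturbation per contour (human tracing errors are
  spatially correlated, so the field is built from a few low-order
  Fourier modes rather than per-point jitter, SD ``reader_noise_sd``);
* software bias — a per-package systematic offset of the contour length,
  by default proportional to contour size (the scale factor is
  calibrated so the offset averaged over all slices and frames equals
  the configured cm value), with a uniform additive radial offset
  (``bias_cm * 10 / 2π`` mm, identical for every contour) available as
  ``length_bias_mode="additive"``.  The proportional mode reproduces the
  agreement structure real contouring packages show — the difference
  between packages grows with the size of the contour being measured —
  and leaves size-normalised metrics (strain, ejection fraction)
  invariant, which is exactly why those metrics survive a change of
  software while the volumes do not.

Each (reader, repetition, software, slice, frame) contour draws its noise
from an independent, deterministically derived random stream, so a study
is reproducible bit-for-bit from one master seed and sessions are
insensitive to generation order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
from matplotlib.path import Path as _MplPath

from .errors import ConfigurationError, GenerationError

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "Session",
    "true_radius",
    "true_radius_grid",
    "phantom_truth",
    "render_contour",
    "rasterize_mask",
    "generate_study",
    "REGIONS",
]

#: Region labels ordered from the most basal slice block to the apical one.
REGIONS = ("base", "mid", "apex")


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, deformation, noise and study-design parameters.

    Defaults emulate the acquisition and study design the pipeline is
    meant to exercise: 9 short-axis slices of a dilated ventricle
    (8 mm thickness + 2 mm gap = 10 mm effective spacing, 1.6 mm in-plane
    pixels), 16 frames from just before ED to just after ES, seven
    readers tracing twice in each of two manual packages, plus one
    automated package run once with zero reader noise.

    Lengths are mm unless the name says otherwise; ``software_length_bias``
    and ``automated_length_bias`` are additive contour-length offsets in cm.
    """

    n_slices: int = 9
    n_frames: int = 16
    pixel_spacing: float = 1.6
    slice_spacing: float = 10.0
    grid_size: int = 128
    base_radius: float = 28.0
    cap_half_height: float = 100.0
    region_peak_strain: Mapping[str, float] = field(
        default_factory=lambda: {"base": -0.30, "mid": -0.20, "apex": -0.12}
    )
    reader_noise_sd: float = 0.5
    reader_noise_modes: int = 3
    reader_bias_sd: float = 0.6
    software_length_bias: Mapping[str, float] = field(
        default_factory=lambda: {"osirix": 0.0, "scanip": -1.9}
    )
    length_bias_mode: str = "proportional"
    automated_label: str = "cvi42"
    automated_length_bias: float = -0.6
    n_readers: int = 7
    n_repetitions: int = 2
    n_markers: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slices <= 0 or self.n_slices % 3 != 0:
            raise ConfigurationError(
                f"n_slices must be a positive multiple of 3, got {self.n_slices}"
            )
        if self.n_frames < 2:
            raise ConfigurationError(f"n_frames must be >= 2, got {self.n_frames}")
        if self.base_radius <= 0:
            raise ConfigurationError("base_radius must be positive")
        if self.pixel_spacing <= 0 or self.slice_spacing <= 0:
            raise ConfigurationError("pixel and slice spacings must be positive")
        if self.grid_size < 8:
            raise ConfigurationError("grid_size is too small")
        if self.n_markers < 3:
            raise ConfigurationError("n_markers must be >= 3")
        if self.reader_noise_sd < 0 or self.reader_noise_modes < 0 or self.reader_bias_sd < 0:
            raise ConfigurationError("reader noise parameters must be non-negative")
        if self.length_bias_mode not in ("proportional", "additive"):
            raise ConfigurationError(
                f"length_bias_mode must be 'proportional' or 'additive', got {self.length_bias_mode!r}"
            )
        if set(self.region_peak_strain) != set(REGIONS):
            raise ConfigurationError(
                f"region_peak_strain must have exactly the keys {set(REGIONS)}"
            )
        for region, eps in self.region_peak_strain.items():
            if not (-1.0 < eps <= 0.0):
                raise ConfigurationError(
                    f"peak strain for {region!r} must lie in (-1, 0], got {eps}"
                )
        if not self.software_length_bias:
            raise ConfigurationError("software_length_bias must name at least one package")
        if self.automated_label in self.software_length_bias:
            raise ConfigurationError(
                "automated_label must differ from the manual software labels"
            )
        if self.n_readers < 1 or self.n_repetitions < 1:
            raise ConfigurationError("n_readers and n_repetitions must be >= 1")
        half_extent = self.grid_size * self.pixel_spacing / 2.0
        if self.base_radius + 4.0 * (self.reader_noise_sd + self.reader_bias_sd) >= half_extent:
            raise ConfigurationError(
                "grid too small: base_radius + 4*(reader_noise_sd + reader_bias_sd) "
                f"must be below {half_extent:.1f} mm"
            )
        if self.slice_offsets[-1] >= self.cap_half_height:
            raise ConfigurationError(
                "the most apical slice lies beyond the ellipsoid cap "
                f"({self.slice_offsets[-1]:.1f} >= {self.cap_half_height:.1f} mm); "
                "increase cap_half_height or reduce n_slices/slice_spacing"
            )

    # -- geometry helpers ------------------------------------------------

    @property
    def slice_offsets(self) -> np.ndarray:
        """Long-axis offset of each slice midplane (mm), base to apex.

        Slice 0 is the most basal; offsets increase toward the apex in
        steps of ``slice_spacing`` starting half a spacing below the base.
        """
        return (np.arange(self.n_slices) + 0.5) * self.slice_spacing

    @property
    def center_mm(self) -> Tuple[float, float]:
        """In-plane coordinates of the cavity axis (grid center, mm)."""
        c = self.grid_size * self.pixel_spacing / 2.0
        return (c, c)

    def region_of_slice(self, slice_index: int) -> str:
        """Region label for a slice: equal thirds base / mid / apex."""
        block = self.n_slices // 3
        if not 0 <= slice_index < self.n_slices:
            raise IndexError(f"slice index {slice_index} out of range")
        return REGIONS[min(slice_index // block, 2)]

    def region_slices(self) -> Dict[str, List[int]]:
        block = self.n_slices // 3
        return {
            region: list(range(i * block, (i + 1) * block))
            for i, region in enumerate(REGIONS)
        }


@dataclass
class Session:
    """One contouring session: every slice × frame contour of one run.

    ``reader`` is a 1-based index for manual sessions and 0 for the
    automated run.  ``masks`` (if rendered) is a boolean array indexed
    ``(x, y, slice, frame)``.
    """

    session_id: str
    reader: int
    software: str
    repetition: int
    kind: str  # "manual" or "automated"
    n_slices: int
    n_frames: int
    contours: Dict[Tuple[int, int], np.ndarray]
    masks: Optional[np.ndarray] = None
    pixel_spacing: Optional[float] = None
    slice_spacing: Optional[float] = None
    duplicated: bool = False


@dataclass(frozen=True)
class PhantomTruth:
    """Analytic ground truth for one phantom configuration.

    Arrays are indexed ``(slice, frame)``.  ``metrics`` are the clinical
    quantities computed in closed form from the radii: regional /global
    peak circumferential strains (%), EDV/ESV (mL) and LVEF (%).
    """

    radius_mm: np.ndarray
    perimeter_cm: np.ndarray
    area_cm2: np.ndarray
    metrics: Dict[str, float]
    ed_frame: int
    es_frame: int


# ---------------------------------------------------------------------------
# noise-free geometry


def _resting_radius(config: PhantomConfig, slice_index: int) -> float:
    z = config.slice_offsets[slice_index]
    arg = 1.0 - (z / config.cap_half_height) ** 2
    return config.base_radius * np.sqrt(max(0.0, arg))


def temporal_profile(config: PhantomConfig, frame: int) -> float:
    """Raised-cosine contraction profile g(f): 0 at ED, 1 at the last frame."""
    return 0.5 * (1.0 - np.cos(np.pi * frame / (config.n_frames - 1)))


def true_radius(config: PhantomConfig, slice_index: int, frame: int) -> float:
    """Noise-free endocardial radius (mm) of one slice at one frame.

    ``r(s, f) = r0(s) * (1 + eps_region(s) * g(f))`` with ``r0`` the
    ellipsoid-cap resting radius and ``g`` the raised-cosine profile.
    """
    if not 0 <= slice_index < config.n_slices:
        raise IndexError(f"slice index {slice_index} out of range")
    if not 0 <= frame < config.n_frames:
        raise IndexError(f"frame index {frame} out of range")
    r0 = _resting_radius(config, slice_index)
    eps = config.region_peak_strain[config.region_of_slice(slice_index)]
    return r0 * (1.0 + eps * temporal_profile(config, frame))


def true_radius_grid(config: PhantomConfig) -> np.ndarray:
    """All noise-free radii as an ``(n_slices, n_frames)`` array (mm)."""
    r0 = np.array([_resting_radius(config, s) for s in range(config.n_slices)])
    eps = np.array(
        [config.region_peak_strain[config.region_of_slice(s)] for s in range(config.n_slices)]
    )
    g = np.array([temporal_profile(config, f) for f in range(config.n_frames)])
    return r0[:, None] * (1.0 + eps[:, None] * g[None, :])


def phantom_truth(config: PhantomConfig) -> PhantomTruth:
    """Closed-form per-slice table and clinical metrics of the phantom.

    Volumes follow the composite midpoint rule (area × effective slice
    spacing, summed over slices); strains are exact because a circle's
    perimeter is proportional to its radius.
    """
    radius = true_radius_grid(config)
    perimeter = 2.0 * np.pi * radius / 10.0  # cm
    area = np.pi * radius**2 / 100.0  # cm^2
    volumes = area.sum(axis=0) * (config.slice_spacing / 10.0)  # mL
    ed = int(np.argmax(volumes))
    es = int(np.argmin(volumes))
    strain = (perimeter - perimeter[:, [ed]]) / perimeter[:, [ed]]
    region_peaks = {}
    for region, slices in config.region_slices().items():
        curve = strain[slices].mean(axis=0)
        region_peaks[region] = 100.0 * curve.min()
    gcs = 100.0 * strain.mean(axis=0).min()
    edv, esv = float(volumes[ed]), float(volumes[es])
    metrics = {
        "ACS": region_peaks["apex"],
        "MCS": region_peaks["mid"],
        "BCS": region_peaks["base"],
        "GCS": gcs,
        "EDV": edv,
        "ESV": esv,
        "LVEF": 100.0 * (edv - esv) / edv,
    }
    return PhantomTruth(
        radius_mm=radius,
        perimeter_cm=perimeter,
        area_cm2=area,
        metrics=metrics,
        ed_frame=ed,
        es_frame=es,
    )


# ---------------------------------------------------------------------------
# stochastic contour rendering


def mean_true_radius(config: PhantomConfig) -> float:
    """Grand mean of the noise-free radius over all slices and frames (mm).

    Reference size for converting a configured length bias (cm) into the
    proportional radius scale factor.
    """
    return float(true_radius_grid(config).mean())


def _session_bias_mm(
    config: PhantomConfig, reader: int, repetition: int, software: str, bias_sd: float
) -> float:
    """Per-session radial offset: the reader's systematic tight/wide tendency."""
    if bias_sd == 0.0:
        return 0.0
    entropy = [
        int(config.seed),
        0xB1A5,
        int(reader),
        int(repetition),
        zlib.crc32(software.encode("utf-8")),
    ]
    rng = np.random.default_rng(np.random.SeedSequence(entropy))
    return float(rng.normal(0.0, bias_sd))


def _contour_rng(
    config: PhantomConfig,
    reader: int,
    repetition: int,
    software: str,
    slice_index: int,
    frame: int,
) -> np.random.Generator:
    """Independent random stream for one contour.

    The stream is keyed on the full identity of the contour, so sessions
    can be generated in any order (or individually) without changing the
    result.  Software labels enter through a CRC so renaming a package
    changes its streams but nothing else.
    """
    entropy = [
        int(config.seed),
        int(reader),
        int(repetition),
        zlib.crc32(software.encode("utf-8")),
        int(slice_index),
        int(frame),
    ]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _radial_noise(
    rng: np.random.Generator, theta: np.ndarray, sd: float, modes: int
) -> np.ndarray:
    """Smooth zero-mean angular perturbation with exact angular SD ``sd``.

    Built from ``modes`` random Fourier modes (k = 1..modes); the absence
    of a k = 0 term makes the perturbation integrate to zero around the
    contour, so it does not bias the perimeter to first order.
    """
    if sd == 0.0 or modes == 0:
        return np.zeros_like(theta)
    coeff = rng.standard_normal((2, modes))
    k = np.arange(1, modes + 1)
    variance = float((coeff**2).sum()) / 2.0
    if variance == 0.0:  # pragma: no cover - probability zero
        return np.zeros_like(theta)
    fld = coeff[0] @ np.cos(np.outer(k, theta)) + coeff[1] @ np.sin(np.outer(k, theta))
    return fld * (sd / np.sqrt(variance))


def render_contour(
    config: PhantomConfig,
    slice_index: int,
    frame: int,
    reader: int,
    repetition: int,
    software: str,
    *,
    noise_sd: Optional[float] = None,
    bias_sd: Optional[float] = None,
    length_bias_cm: Optional[float] = None,
    session_bias_mm: Optional[float] = None,
) -> np.ndarray:
    """Marker points (mm) of one traced contour, counter-clockwise.

    ``noise_sd``, ``bias_sd`` and ``length_bias_cm`` default to the
    configured reader noise and the bias registered for ``software``;
    pass zeros to render e.g. the noise-free automated run.
    ``session_bias_mm`` can pin the per-session reader offset explicitly
    (it is otherwise derived deterministically from the session identity,
    so repeated calls agree with full-session rendering).
    Returns an ``(n_markers, 2)`` array; closure is implied (the first
    point is not repeated).
    """
    if noise_sd is None:
        noise_sd = config.reader_noise_sd
    if bias_sd is None:
        bias_sd = config.reader_bias_sd
    if length_bias_cm is None:
        try:
            length_bias_cm = config.software_length_bias[software]
        except KeyError:
            if software == config.automated_label:
                length_bias_cm = config.automated_length_bias
            else:
                raise ConfigurationError(f"unknown software label {software!r}")
    if session_bias_mm is None:
        session_bias_mm = _session_bias_mm(config, reader, repetition, software, bias_sd)
    r = true_radius(config, slice_index, frame)
    if config.length_bias_mode == "proportional":
        r_biased = r * (1.0 + length_bias_cm * 10.0 / (2.0 * np.pi * mean_true_radius(config)))
    else:
        r_biased = r + length_bias_cm * 10.0 / (2.0 * np.pi)
    theta = 2.0 * np.pi * np.arange(config.n_markers) / config.n_markers
    rng = _contour_rng(config, reader, repetition, software, slice_index, frame)
    delta = _radial_noise(rng, theta, noise_sd, config.reader_noise_modes)
    radius = r_biased + session_bias_mm + delta
    if np.any(radius <= 0.0):
        raise GenerationError(
            f"non-positive contour radius at slice {slice_index}, frame {frame} "
            f"(software {software!r}, bias {length_bias_cm} cm)"
        )
    cx, cy = config.center_mm
    return np.column_stack((cx + radius * np.cos(theta), cy + radius * np.sin(theta)))


def _pixel_centers(grid_size: int, pixel_spacing: float) -> np.ndarray:
    c = (np.arange(grid_size) + 0.5) * pixel_spacing
    gx, gy = np.meshgrid(c, c, indexing="ij")
    return np.column_stack((gx.ravel(), gy.ravel()))


def rasterize_mask(contour: np.ndarray, config: PhantomConfig) -> np.ndarray:
    """Binarise one contour: pixels whose center lies inside the polygon.

    Mirrors a threshold-style package exporting binary images.  Returns a
    boolean ``(grid_size, grid_size)`` array indexed ``(x, y)``.
    """
    contour = np.asarray(contour, dtype=float)
    extent = config.grid_size * config.pixel_spacing
    if contour.min() <= 0.0 or contour.max() >= extent:
        raise GenerationError("contour escapes the pixel grid")
    path = _MplPath(contour, closed=False)
    centers = _pixel_centers(config.grid_size, config.pixel_spacing)
    inside = path.contains_points(centers)
    return inside.reshape(config.grid_size, config.grid_size)


# ---------------------------------------------------------------------------
# study generation


def _session_id(software: str, reader: int, repetition: int, kind: str) -> str:
    if kind == "automated":
        return f"{software}-auto"
    return f"{software}-r{reader:02d}-t{repetition}"


def render_session(
    config: PhantomConfig,
    reader: int,
    repetition: int,
    software: str,
    kind: str = "manual",
    *,
    render_masks: bool = True,
) -> Session:
    """Render every slice × frame contour (and optionally mask) of one run.

    Automated sessions are rendered without reader noise and without a
    session offset (an algorithm is assumed perfectly repeatable).
    """
    noise_sd = 0.0 if kind == "automated" else config.reader_noise_sd
    bias_sd = 0.0 if kind == "automated" else config.reader_bias_sd
    session_bias = _session_bias_mm(config, reader, repetition, software, bias_sd)
    contours: Dict[Tuple[int, int], np.ndarray] = {}
    for s in range(config.n_slices):
        for f in range(config.n_frames):
            contours[(s, f)] = render_contour(
                config, s, f, reader, repetition, software,
                noise_sd=noise_sd, bias_sd=bias_sd, session_bias_mm=session_bias,
            )
    masks = None
    if render_masks:
        masks = np.zeros(
            (config.grid_size, config.grid_size, config.n_slices, config.n_frames),
            dtype=bool,
        )
        for (s, f), pts in contours.items():
            masks[:, :, s, f] = rasterize_mask(pts, config)
    return Session(
        session_id=_session_id(software, reader, repetition, kind),
        reader=reader,
        software=software,
        repetition=repetition,
        kind=kind,
        n_slices=config.n_slices,
        n_frames=config.n_frames,
        contours=contours,
        masks=masks,
        pixel_spacing=config.pixel_spacing,
        slice_spacing=config.slice_spacing,
    )


def generate_study(
    config: PhantomConfig, *, render_masks: bool = True
) -> Tuple[List[Session], PhantomTruth]:
    """Simulate the full study.

    Yields ``n_readers × n_software × n_repetitions`` manual sessions with
    reader noise, plus exactly one automated session (zero reader noise,
    its own length bias), together with the analytic truth.
    """
    sessions: List[Session] = []
    for software in config.software_length_bias:
        for reader in range(1, config.n_readers + 1):
            for repetition in range(1, config.n_repetitions + 1):
                sessions.append(
                    render_session(
                        config, reader, repetition, software, "manual",
                        render_masks=render_masks,
                    )
                )
    sessions.append(
        render_session(
            config, 0, 1, config.automated_label, "automated",
            render_masks=render_masks,
        )
    )
    return sessions, phantom_truth(config)
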