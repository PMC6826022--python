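"""Ex vivo beating-heart video mechanics.

A paced, perfused adult zebrafish heart is filmed in two orthogonal planes
(a mirror provides the second view).  Each frame is segmented to a ventricle
silhouette; the short-axis area ``A_AL`` and long-axis length ``L_AL`` feed
the biplane area-length volume estimate

    V = (2/3) * A_AL * L_AL,

which is exact for an ellipsoidal chamber.  Per-cycle indices follow:
EF = (EDV-ESV)/EDV, FS = (L_d-L_s)/L_d, FAC = (EDA-ESA)/EDA.  Radial strain
is the fractional change of the mean center-to-boundary radius relative to
end-diastole; its time derivative gives contraction/relaxation velocities and
the closed velocity-strain loop, whose area serves as a contractility index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import find_peaks, savgol_filter
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.morphology import disk

from .exceptions import (
    CycleDetectionError,
    EmptyMaskError,
    InsufficientFramesError,
    InvalidParameterError,
    OpenLoopError,
    SegmentationError,
    StageError,
    ZeroDivisionInputError,
)

__all__ = [
    "BiplaneVideo",
    "FrameGeometry",
    "CardiacCycle",
    "StrainVelocitySeries",
    "HeartFunctionSummary",
    "SegmentationConfig",
    "AnalysisConfig",
    "segment_ventricle",
    "frame_geometry",
    "biplane_volume",
    "detect_cycles",
    "cycle_indices",
    "strain_velocity_series",
    "velocity_strain_loop",
    "summarize_heart",
]


@dataclass
class BiplaneVideo:
    """Two synchronized grayscale stacks of a beating ventricle.

    ``plane_long`` images the longitudinal (long-axis) plane, ``plane_short``
    the transverse (short-axis) plane.  Arrays are (frames, rows, cols).
    """

    plane_long: np.ndarray
    plane_short: np.ndarray
    pixel_size: float  # mm / pixel
    frame_rate: float  # frames / s

    def __post_init__(self) -> None:
        self.plane_long = np.asarray(self.plane_long)
        self.plane_short = np.asarray(self.plane_short)
        if self.plane_long.ndim != 3 or self.plane_short.ndim != 3:
            raise InvalidParameterError("image stacks must be (frames, rows, cols)")
        if self.plane_long.shape[0] != self.plane_short.shape[0]:
            raise InvalidParameterError("planes must have the same frame count")
        if self.pixel_size <= 0 or self.frame_rate <= 0:
            raise InvalidParameterError("pixel_size and frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.plane_long.shape[0]


@dataclass
class FrameGeometry:
    """Silhouette geometry of one frame: area, caliper length, ray radii."""

    area: float  # mm^2
    long_length: float  # mm, maximal caliper extent along the principal axis
    centroid: tuple[float, float]  # (row, col) pixels
    radii: np.ndarray  # mm, center-of-mass-to-boundary distances

    @property
    def mean_radius(self) -> float:
        return float(np.mean(self.radii))


@dataclass
class CardiacCycle:
    """One cardiac cycle with its volumetric and dimensional indices."""

    ed_frame: int
    es_frame: int
    edv: float  # mm^3
    esv: float  # mm^3
    ef: float
    fs: float
    fac: float
    end_frame: int | None = None  # frame index of the next end-diastole


@dataclass
class StrainVelocitySeries:
    """Radial strain and strain-rate over a stretch of frames."""

    time: np.ndarray  # s
    strain: np.ndarray  # dimensionless, 0 at the reference ED frame
    velocity: np.ndarray  # strain / s
    max_contraction_velocity: float  # most negative strain rate
    max_relaxation_velocity: float  # most positive strain rate


@dataclass
class HeartFunctionSummary:
    """Per-cycle table and cross-cycle means for one heart."""

    cycles: pd.DataFrame
    means: pd.Series
    n_cycles: int

    def summary(self) -> str:
        lines = ["Heart function summary (%d cycles averaged)" % self.n_cycles]
        units = {
            "edv": "mm^3", "esv": "mm^3", "ef": "", "fs": "", "fac": "",
            "max_contraction_velocity": "1/s", "max_relaxation_velocity": "1/s",
            "loop_area": "strain^2/s",
        }
        for name, val in self.means.items():
            lines.append(f"  {name:<26s} {val: .4f} {units.get(name, '')}")
        return "\n".join(lines)


@dataclass
class SegmentationConfig:
    """Thresholding / morphology knobs for silhouette extraction."""

    min_area_px: int = 50  # segmentation fails below this component size
    closing_radius: int = 2  # structuring-element radius for closing


@dataclass
class AnalysisConfig:
    """End-to-end analysis configuration for :func:`summarize_heart`."""

    pacing_rate: float = 2.0  # beats / s, the pacing frequency
    n_rays: int = 36
    smooth_window: int = 7  # odd; 1 disables smoothing
    smooth_polyorder: int = 2
    loop_closure_tol: float = 0.05  # strain units
    min_cycles: int = 3
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)


def segment_ventricle(frame: np.ndarray, config: SegmentationConfig | None = None) -> np.ndarray:
    """Extract the ventricle silhouette from one grayscale frame.

    Global (Otsu) threshold, morphological closing, hole filling, then the
    largest connected component.  Returns a boolean mask.

    Raises
    ------
    SegmentationError
        If the frame has no intensity contrast or no component reaches
        ``config.min_area_px``.
    """
    config = config or SegmentationConfig()
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise SegmentationError("empty frame")
    if np.ptp(frame) == 0:
        raise SegmentationError("frame has constant intensity; nothing to segment")
    thr = threshold_otsu(frame)
    fg = frame > thr
    if config.closing_radius > 0:
        fg = ndimage.binary_closing(fg, structure=disk(config.closing_radius))
    fg = ndimage.binary_fill_holes(fg)
    labels = sk_label(fg)
    if labels.max() == 0:
        raise SegmentationError("no foreground component found")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    best = int(np.argmax(sizes))
    if sizes[best] < config.min_area_px:
        raise SegmentationError(
            f"largest component ({sizes[best]} px) below minimum area "
            f"({config.min_area_px} px)"
        )
    return labels == best


def _principal_axis(coords: np.ndarray) -> np.ndarray:
    """Unit vector of the dominant principal axis of pixel coordinates."""
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / max(len(coords) - 1, 1)
    vals, vecs = np.linalg.eigh(cov)
    return vecs[:, np.argmax(vals)]


def frame_geometry(mask: np.ndarray, pixel_size: float, n_rays: int = 36) -> FrameGeometry:
    """Measure area, principal-axis caliper length and ray radii of a mask.

    ``area`` is foreground pixel count times ``pixel_size**2``.  ``long_length``
    is the pixel-extent span of the silhouette projected on its principal axis.
    ``radii`` are distances from the center of mass to the boundary along
    ``n_rays`` equally spaced directions (ray marching at quarter-pixel steps).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0 or not mask.any():
        raise EmptyMaskError("mask contains no foreground pixels")
    if pixel_size <= 0:
        raise InvalidParameterError("pixel_size must be positive")
    coords = np.argwhere(mask).astype(float)
    area = float(mask.sum()) * pixel_size**2
    axis = _principal_axis(coords)
    proj = coords @ axis
    long_length = (float(proj.max() - proj.min()) + 1.0) * pixel_size

    cy, cx = coords.mean(axis=0)
    angles = np.linspace(0.0, 2.0 * np.pi, n_rays, endpoint=False)
    step = 0.25
    nrows, ncols = mask.shape
    max_r = float(np.hypot(nrows, ncols))
    rr = np.arange(step, max_r + step, step)  # radial samples along each ray
    ys = np.rint(cy + rr[None, :] * np.sin(angles)[:, None]).astype(int)
    xs = np.rint(cx + rr[None, :] * np.cos(angles)[:, None]).astype(int)
    inside = (ys >= 0) & (ys < nrows) & (xs >= 0) & (xs < ncols)
    inside &= mask[np.clip(ys, 0, nrows - 1), np.clip(xs, 0, ncols - 1)]
    # first radial sample outside the mask bounds the radius along that ray
    first_out = np.argmin(inside, axis=1)
    first_out[inside.all(axis=1)] = len(rr)
    radii = first_out * step * pixel_size
    return FrameGeometry(area=area, long_length=long_length, centroid=(cy, cx), radii=radii)


def biplane_volume(area_short: float, length_long: float) -> float:
    """Biplane area-length chamber volume, V = (2/3) * A * L.

    Exact for an ellipsoid whose short-axis cross-section has area A and
    whose long axis has length L.
    """
    if area_short < 0 or length_long < 0:
        raise InvalidParameterError("area and length must be non-negative")
    return (2.0 / 3.0) * area_short * length_long


def detect_cycles(
    volume_trace: np.ndarray, frame_rate: float, pacing_rate: float
) -> list[CardiacCycle]:
    """Locate end-diastolic maxima / end-systolic minima of a volume trace.

    One ED/ES pair is expected per pacing period; extrema are found with a
    minimum separation of 0.7 pacing periods, and boundary frames may serve as
    ED.  Returned cycles carry frame indices only (volume indices are filled
    by :func:`cycle_indices`); each cycle spans ``ed_frame`` to ``end_frame``
    (the next ED).

    Raises
    ------
    CycleDetectionError
        If the trace is too short, shows no oscillation, or the detected
        cycle count deviates from pacing-implied expectation by more than 1.
    """
    v = np.asarray(volume_trace, dtype=float)
    if frame_rate <= 0 or pacing_rate <= 0:
        raise InvalidParameterError("rates must be positive")
    period_frames = frame_rate / pacing_rate
    if len(v) < 2 * period_frames:
        raise CycleDetectionError("trace shorter than two pacing periods")
    if np.ptp(v) == 0:
        raise CycleDetectionError("constant volume trace; no cycles")
    dist = max(int(round(0.7 * period_frames)), 1)
    pad = np.r_[-np.inf, v, -np.inf]
    ed, _ = find_peaks(pad, distance=dist)
    ed -= 1
    es, _ = find_peaks(-v, distance=dist)
    if len(ed) < 2 or len(es) == 0:
        raise CycleDetectionError("no oscillatory cycles found")

    cycles: list[CardiacCycle] = []
    for e0, e1 in zip(ed[:-1], ed[1:]):
        mids = es[(es > e0) & (es < e1)]
        if len(mids) == 0:
            continue
        es_frame = int(mids[np.argmin(v[mids])])
        cycles.append(
            CardiacCycle(
                ed_frame=int(e0), es_frame=es_frame, end_frame=int(e1),
                edv=float(v[e0]), esv=float(v[es_frame]),
                ef=np.nan, fs=np.nan, fac=np.nan,
            )
        )
    expected = int(np.floor(len(v) / frame_rate * pacing_rate))
    if abs(len(cycles) - expected) > 1:
        raise CycleDetectionError(
            f"found {len(cycles)} cycles, expected about {expected}"
        )
    return cycles


def cycle_indices(
    edv: float,
    esv: float,
    l_d: float,
    l_s: float,
    eda: float,
    esa: float,
    ed_frame: int = 0,
    es_frame: int = 1,
    end_frame: int | None = None,
) -> CardiacCycle:
    """Volumetric and dimensional indices of one cycle.

    EF = (EDV-ESV)/EDV, FS = (L_d-L_s)/L_d, FAC = (EDA-ESA)/EDA.
    """
    if min(edv, esv, l_d, l_s, eda, esa) < 0:
        raise InvalidParameterError("geometry inputs must be non-negative")
    if edv == 0 or l_d == 0 or eda == 0:
        raise ZeroDivisionInputError("EDV, L_d and EDA must be nonzero")
    return CardiacCycle(
        ed_frame=ed_frame,
        es_frame=es_frame,
        end_frame=end_frame,
        edv=edv,
        esv=esv,
        ef=(edv - esv) / edv,
        fs=(l_d - l_s) / l_d,
        fac=(eda - esa) / eda,
    )


def strain_velocity_series(
    radii_per_frame: np.ndarray,
    frame_rate: float,
    ed_frame: int | None = None,
    smooth_window: int = 7,
    smooth_polyorder: int = 2,
) -> StrainVelocitySeries:
    """Radial strain and its time derivative from per-frame ray radii.

    ``radii_per_frame`` is (frames, n_rays) or already the per-frame mean
    radius.  Strain is (r_mean(t) - r_ED) / r_ED with r_ED the mean radius at
    ``ed_frame`` (default: the frame of maximal mean radius).  The strain is
    smoothed with a moving-window polynomial (Savitzky-Golay) filter before
    differentiation; ``smooth_window=1`` disables smoothing.
    """
    radii = np.asarray(radii_per_frame, dtype=float)
    rbar = radii.mean(axis=1) if radii.ndim == 2 else radii
    n = len(rbar)
    if n < max(smooth_window, 5):
        raise InsufficientFramesError(f"need at least {max(smooth_window, 5)} frames, got {n}")
    if frame_rate <= 0:
        raise InvalidParameterError("frame_rate must be positive")
    if ed_frame is None:
        ed_frame = int(np.argmax(rbar))
    ref = rbar[ed_frame]
    if ref == 0:
        raise InvalidParameterError("reference ED radius is zero")
    strain = (rbar - ref) / ref
    if smooth_window > 1:
        win = min(smooth_window, n if n % 2 == 1 else n - 1)
        smoothed = savgol_filter(strain, win, min(smooth_polyorder, win - 1))
    else:
        smoothed = strain
    dt = 1.0 / frame_rate
    velocity = np.gradient(smoothed, dt)
    time = np.arange(n) * dt
    return StrainVelocitySeries(
        time=time,
        strain=smoothed,
        velocity=velocity,
        max_contraction_velocity=float(velocity.min()),
        max_relaxation_velocity=float(velocity.max()),
    )


def velocity_strain_loop(
    strain: np.ndarray, velocity: np.ndarray, closure_tol: float = 0.05
) -> float:
    """Absolute area of the closed (strain, velocity) polygon over one cycle.

    Vertices are taken frame-ordered; the shoelace formula closes the last
    vertex back to the first.  For harmonic strain of amplitude D at angular
    frequency w the loop is an ellipse of area pi*w*D^2.

    Raises
    ------
    OpenLoopError
        If first and last strain values differ by more than ``closure_tol``.
    """
    x = np.asarray(strain, dtype=float)
    y = np.asarray(velocity, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise InvalidParameterError("strain and velocity must be equal-length 1-D, n >= 3")
    if abs(x[-1] - x[0]) > closure_tol:
        raise OpenLoopError(
            f"loop endpoints differ in strain by {abs(x[-1] - x[0]):.4g} "
            f"(tolerance {closure_tol:.4g})"
        )
    area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    return float(abs(area2) / 2.0)


def summarize_heart(video: BiplaneVideo, config: AnalysisConfig | None = None) -> HeartFunctionSummary:
    """Run the full mechanics chain on a biplane video and average cycles.

    Per frame: segment both planes, measure short-axis area + radii and
    long-axis length, form the biplane volume.  Then detect cycles, compute
    EF/FS/FAC per cycle, the per-cycle strain/velocity series (ED-referenced)
    and velocity-strain loop area, and average over all detected cycles.
    Errors raised by a stage are re-raised as :class:`StageError` with the
    stage name attached.
    """
    config = config or AnalysisConfig()

    n = video.n_frames
    area_short = np.empty(n)
    length_long = np.empty(n)
    mean_radius = np.empty(n)
    eda_like = np.empty(n)
    try:
        for i in range(n):
            m_short = segment_ventricle(video.plane_short[i], config.segmentation)
            m_long = segment_ventricle(video.plane_long[i], config.segmentation)
            g_short = frame_geometry(m_short, video.pixel_size, config.n_rays)
            g_long = frame_geometry(m_long, video.pixel_size, config.n_rays)
            area_short[i] = g_short.area
            eda_like[i] = g_short.area
            length_long[i] = g_long.long_length
            mean_radius[i] = g_short.mean_radius
    except Exception as exc:  # noqa: BLE001 - stage identity attached
        raise StageError("segmentation/geometry", exc) from exc

    volume = (2.0 / 3.0) * area_short * length_long

    try:
        raw_cycles = detect_cycles(volume, video.frame_rate, config.pacing_rate)
    except Exception as exc:
        raise StageError("cycle-detection", exc) from exc
    if len(raw_cycles) < config.min_cycles:
        raise StageError(
            "cycle-detection",
            CycleDetectionError(
                f"only {len(raw_cycles)} cycles detected; {config.min_cycles} required"
            ),
        )

    rows = []
    try:
        for cyc in raw_cycles:
            ed, es, end = cyc.ed_frame, cyc.es_frame, cyc.end_frame
            idx = cycle_indices(
                edv=volume[ed], esv=volume[es],
                l_d=length_long[ed], l_s=length_long[es],
                eda=eda_like[ed], esa=eda_like[es],
                ed_frame=ed, es_frame=es, end_frame=end,
            )
            seg = mean_radius[ed : end + 1]
            sv = strain_velocity_series(
                seg, video.frame_rate, ed_frame=0,
                smooth_window=config.smooth_window,
                smooth_polyorder=config.smooth_polyorder,
            )
            loop = velocity_strain_loop(
                sv.strain[:-1], sv.velocity[:-1], config.loop_closure_tol
            )
            rows.append(
                {
                    "ed_frame": ed, "es_frame": es,
                    "edv": idx.edv, "esv": idx.esv,
                    "ef": idx.ef, "fs": idx.fs, "fac": idx.fac,
                    "max_contraction_velocity": sv.max_contraction_velocity,
                    "max_relaxation_velocity": sv.max_relaxation_velocity,
                    "loop_area": loop,
                }
            )
    except StageError:
        raise
    except Exception as exc:
        raise StageError("strain/loop", exc) from exc

    table = pd.DataFrame(rows)
    means = table.drop(columns=["ed_frame", "es_frame"]).mean()
    return HeartFunctionSummary(cycles=table, means=means, n_cycles=len(table))
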