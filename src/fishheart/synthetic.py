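"""Synthetic data generators with analytic ground truth.

Every input the phenotyping pipeline consumes can be generated here with
known ground truth, so each analysis stage is verifiable by parameter
recovery without any animal data.  The generators emulate the acquisition
protocols of the workflow:

* a 2 Hz-paced ex vivo ventricle filmed at 66 fps in two orthogonal planes
  (prolate ellipsoid chamber, raised-cosine volume waveform between EDV and
  ESV — for an ellipsoid the biplane area-length volume formula is exact, so
  the ground truth is analytic);
* myofibril force traces with mono-exponential activation, release-restretch
  force redevelopment, and biphasic (linear-then-exponential) relaxation;
* E/A diastolic inflow waveforms with valve-event annotations;
* stepwise swim-tunnel exhaustion records, two-group survival cohorts with
  administrative censoring, labelled images with exact positive-pixel and
  nucleus fractions, and Hill-form force-pCa tables.

All randomness flows from the explicit ``seed`` in each parameter set; a
generator is a pure function of its parameters, and noiseless outputs follow
their defining closed forms at every sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .doppler import DopplerWaveform
from .exceptions import InvalidParameterError, PackingError, RenderingError
from .myofibril import ForceTrace, ProtocolMarks
from .video import BiplaneVideo

__all__ = [
    "CardiacSimParams",
    "MyofibrilSimParams",
    "DopplerSimParams",
    "SwimProtocol",
    "CohortSimParams",
    "LabelImageSpec",
    "gen_beating_heart_video",
    "gen_myofibril_trace",
    "gen_doppler_waveform",
    "gen_swim_cohort",
    "gen_survival_cohort",
    "gen_labeled_image",
    "gen_force_pca",
]

_BG_LEVEL = 20.0
_FG_LEVEL = 220.0


@dataclass
class CardiacSimParams:
    """Beating-heart video simulation parameters (paced ex vivo protocol)."""

    edv: float = 4.0  # mm^3, end-diastolic volume
    esv: float = 2.0  # mm^3, end-systolic volume
    heart_rate: float = 2.0  # beats/s (pacing frequency)
    frame_rate: float = 66.0  # frames/s
    duration: float = 3.0  # s
    pixel_size: float = 0.02  # mm/pixel
    image_shape: tuple[int, int] = (192, 192)
    noise_sd: float = 0.0  # gray levels
    blur_sigma: float = 1.0  # pixels
    aspect_ratio: float = 1.5  # long semi-axis c over short semi-axis a
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.esv < self.edv:
            raise InvalidParameterError("require 0 < ESV < EDV")
        if self.heart_rate <= 0:
            raise InvalidParameterError("heart_rate must be positive")
        if self.frame_rate <= 2 * self.heart_rate:
            raise InvalidParameterError("frame_rate must exceed 2 * heart_rate")
        if self.duration * self.heart_rate < 3:
            raise InvalidParameterError("duration must cover at least 3 cycles")
        if self.pixel_size <= 0 or self.noise_sd < 0 or self.blur_sigma < 0:
            raise InvalidParameterError("pixel_size > 0 and noise/blur >= 0 required")
        if self.aspect_ratio < 1:
            raise InvalidParameterError("aspect_ratio must be >= 1 (prolate)")


@dataclass
class MyofibrilSimParams:
    """Myofibril force-trace simulation parameters."""

    f_max: float = 500.0  # nN, calcium-saturated plateau force
    f_passive: float = 50.0  # nN, relaxed (pCa 10) force
    k_act: float = 5.0  # 1/s, activation rate
    k_tr: float = 5.0  # 1/s, redevelopment rate after release-restretch
    t_lin: float = 0.05  # s, duration of the slow linear relaxation phase
    k_lin_slope: float = 1.5  # fraction of developed force per s
    k_rel: float = 10.0  # 1/s, fast exponential relaxation rate
    csa: float = 10.0  # um^2
    event_times: tuple[float, float, float, float] = (0.5, 2.5, 2.6, 4.5)
    duration: float = 6.0  # s
    sample_rate: float = 1000.0  # samples/s
    noise_sd: float = 0.0  # fraction of f_max
    seed: int = 0

    def validate(self) -> None:
        if min(self.k_act, self.k_tr, self.k_rel, self.k_lin_slope) <= 0:
            raise InvalidParameterError("all rates must be positive")
        if self.t_lin < 0:
            raise InvalidParameterError("t_lin must be non-negative")
        if not self.f_max > self.f_passive >= 0:
            raise InvalidParameterError("require f_max > f_passive >= 0")
        et = self.event_times
        if len(et) != 4 or np.any(np.diff(et) <= 0):
            raise InvalidParameterError("event_times must be 4 strictly increasing times")
        if et[0] <= 0 or et[3] >= self.duration:
            raise InvalidParameterError("events must fall strictly inside the trace")
        if self.k_lin_slope * self.t_lin >= 1.0:
            raise InvalidParameterError(
                "linear phase would consume the full developed force"
            )
        if self.sample_rate <= 0 or self.csa <= 0 or self.noise_sd < 0:
            raise InvalidParameterError("sample_rate, csa > 0 and noise_sd >= 0 required")


@dataclass
class DopplerSimParams:
    """Diastolic inflow (E/A) waveform simulation parameters."""

    e_peak: float = 18.0  # mm/s, early passive filling peak
    a_peak: float = 14.0  # mm/s, atrial-contraction peak
    ivct: float = 0.04  # s
    ivrt: float = 0.05  # s
    et: float = 0.18  # s
    period: float = 0.5  # s per cardiac cycle
    n_cycles: int = 6  # ~3 s recording
    sample_rate: float = 1000.0  # samples/s
    noise_sd: float = 0.0  # mm/s
    seed: int = 0

    def validate(self) -> None:
        if self.e_peak <= 0 or self.a_peak <= 0:
            raise InvalidParameterError("peak velocities must be positive")
        if min(self.ivct, self.ivrt) < 0 or self.et <= 0:
            raise InvalidParameterError("intervals must be non-negative, ET positive")
        if self.ivct + self.ivrt + self.et >= self.period:
            raise InvalidParameterError("IVCT + IVRT + ET must be less than the period")
        if self.n_cycles < 1 or self.sample_rate <= 0 or self.noise_sd < 0:
            raise InvalidParameterError("n_cycles >= 1, sample_rate > 0, noise_sd >= 0")


@dataclass
class SwimProtocol:
    """Stepwise swim-tunnel protocol: start speed, increment, stage length."""

    initial_speed: float = 9.0  # cm/s
    speed_increment: float = 8.66  # cm/s per stage
    stage_duration: float = 150.0  # s


@dataclass
class CohortSimParams:
    """Cohort simulation parameters (swim trials and survival)."""

    n_per_group: int = 30
    true_ucrit_mean: float | tuple[float, ...] = 35.0  # cm/s
    true_ucrit_sd: float = 5.0  # cm/s
    swim_protocol: SwimProtocol = field(default_factory=SwimProtocol)
    body_length_mean: float = 3.5  # cm
    body_length_sd: float = 0.3  # cm
    hazard_per_group: tuple[float, ...] = (0.005, 0.02)  # events / day
    censor_time: float = 180.0  # days
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise InvalidParameterError("n_per_group must be >= 1")
        if self.true_ucrit_sd < 0 or self.body_length_sd < 0:
            raise InvalidParameterError("standard deviations must be non-negative")
        p = self.swim_protocol
        if p.initial_speed <= 0 or p.speed_increment <= 0 or p.stage_duration <= 0:
            raise InvalidParameterError("protocol speeds and duration must be positive")
        if any(h < 0 for h in self.hazard_per_group):
            raise InvalidParameterError("hazards must be non-negative")
        if self.censor_time <= 0:
            raise InvalidParameterError("censor_time must be positive")


@dataclass
class LabelImageSpec:
    """Specification for synthetic labelled images."""

    shape: tuple[int, int] = (100, 100)
    target_fraction: float = 0.25  # area_fraction mode
    n_objects: int = 100  # nuclei mode: total nuclei N
    n_positive: int = 20  # nuclei mode: positive nuclei K
    object_radius: int = 3  # pixels, nucleus disk radius
    n_cells: int = 5  # cells mode
    cell_side: int = 20  # pixels, square cell side
    pixel_size: float = 1.0  # um/pixel
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.target_fraction <= 1.0:
            raise InvalidParameterError("target_fraction must be in [0, 1]")
        if self.n_objects < 0 or self.n_positive < 0 or self.n_cells < 0:
            raise InvalidParameterError("object counts must be non-negative")
        if self.n_positive > self.n_objects:
            raise InvalidParameterError("n_positive cannot exceed n_objects")
        if self.object_radius < 1 or self.cell_side < 1 or self.pixel_size <= 0:
            raise InvalidParameterError("object sizes and pixel_size must be positive")


# ---------------------------------------------------------------------------
# beating-heart video


def _render_ellipse(
    shape: tuple[int, int], semi_row: float, semi_col: float
) -> np.ndarray:
    """Centered filled ellipse mask with the given semi-axes in pixels."""
    nrows, ncols = shape
    cy, cx = (nrows - 1) / 2.0, (ncols - 1) / 2.0
    yy, xx = np.mgrid[0:nrows, 0:ncols]
    return ((yy - cy) / semi_row) ** 2 + ((xx - cx) / semi_col) ** 2 <= 1.0


def gen_beating_heart_video(
    params: CardiacSimParams,
) -> tuple[BiplaneVideo, dict]:
    """Render a paced ellipsoidal ventricle in two orthogonal planes.

    The chamber is a prolate ellipsoid with equal short-axis semi-axes
    a = b and long semi-axis c = aspect_ratio * a.  Its volume follows a
    raised-cosine cycle between ESV and EDV at the pacing rate, with
    end-diastole at t = 0.  The longitudinal plane shows an ellipse with
    semi-axes (a, c); the transverse plane a disk of radius a.  For this
    geometry the biplane formula V = (2/3) * (pi a^2) * (2c) is exact.

    Returns the video and a ground-truth record with per-frame true volume,
    short-axis area, long-axis length, ED/ES frame indices, EF and FS.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration * params.frame_rate))
    t = np.arange(n) / params.frame_rate

    vol = params.esv + (params.edv - params.esv) * (
        1.0 + np.cos(2.0 * np.pi * params.heart_rate * t)
    ) / 2.0
    # V = 4/3 pi a^2 c with c = ar * a  =>  a = (3V / (4 pi ar))^(1/3)
    a_mm = (3.0 * vol / (4.0 * np.pi * params.aspect_ratio)) ** (1.0 / 3.0)
    c_mm = params.aspect_ratio * a_mm

    a_px = a_mm / params.pixel_size
    c_px = c_mm / params.pixel_size
    margin = 2.0 + 3.0 * params.blur_sigma
    nrows, ncols = params.image_shape
    if c_px.max() + margin > ncols / 2.0 or a_px.max() + margin > nrows / 2.0:
        raise RenderingError(
            f"ellipse (a={a_px.max():.1f}, c={c_px.max():.1f} px) exceeds the "
            f"{params.image_shape} image bounds"
        )

    long_stack = np.empty((n, nrows, ncols), dtype=np.uint8)
    short_stack = np.empty((n, nrows, ncols), dtype=np.uint8)
    for i in range(n):
        for stack, (sr, sc) in (
            (long_stack, (a_px[i], c_px[i])),
            (short_stack, (a_px[i], a_px[i])),
        ):
            img = np.where(_render_ellipse(params.image_shape, sr, sc), _FG_LEVEL, _BG_LEVEL)
            if params.blur_sigma > 0:
                img = ndimage.gaussian_filter(img, params.blur_sigma)
            if params.noise_sd > 0:
                img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
            stack[i] = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    video = BiplaneVideo(
        plane_long=long_stack,
        plane_short=short_stack,
        pixel_size=params.pixel_size,
        frame_rate=params.frame_rate,
    )
    period_frames = params.frame_rate / params.heart_rate
    n_cycles = int(np.floor(params.duration * params.heart_rate))
    ed_frames = [int(round(k * period_frames)) for k in range(n_cycles + 1)]
    ed_frames = [f for f in ed_frames if f < n]
    es_frames = [int(round((k + 0.5) * period_frames)) for k in range(n_cycles)]
    es_frames = [f for f in es_frames if f < n]
    c_ed, c_es = c_mm.max(), c_mm.min()
    truth = {
        "time": t,
        "volume": vol,
        "area_short": np.pi * a_mm**2,
        "length_long": 2.0 * c_mm,
        "mean_radius": a_mm,
        "edv": params.edv,
        "esv": params.esv,
        "ef": (params.edv - params.esv) / params.edv,
        "fs": (c_ed - c_es) / c_ed,
        "ed_frames": ed_frames,
        "es_frames": es_frames,
        "heart_rate": params.heart_rate,
    }
    return video, truth


# ---------------------------------------------------------------------------
# myofibril force trace


def gen_myofibril_trace(params: MyofibrilSimParams) -> tuple[ForceTrace, dict]:
    """Simulate an activation / release-restretch / relaxation force trace.

    Closed form per phase (times relative to each phase onset):

    * baseline: F = f_passive;
    * activation: F = f_passive + (f_max - f_passive)(1 - exp(-k_act t));
    * release -> restretch: F = 0 (the fibre is slack);
    * redevelopment: F = f_max (1 - exp(-k_tr t));
    * relaxation: linear decline of slope k_lin_slope * (F_r - f_passive)
      for t_lin seconds, then exponential decay at k_rel towards f_passive,
      continuous at the breakpoint (F_r is the force at relaxation onset).

    Gaussian noise (sd = noise_sd * f_max) is added last.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration * params.sample_rate))
    t = np.arange(n) / params.sample_rate
    t_act, t_rel, t_str, t_rlx = params.event_times
    dev = params.f_max - params.f_passive

    f = np.full(n, params.f_passive)
    sel = (t >= t_act) & (t < t_rel)
    f[sel] = params.f_passive + dev * (1.0 - np.exp(-params.k_act * (t[sel] - t_act)))
    f[(t >= t_rel) & (t < t_str)] = 0.0
    sel = (t >= t_str) & (t < t_rlx)
    f[sel] = params.f_max * (1.0 - np.exp(-params.k_tr * (t[sel] - t_str)))

    f_r = params.f_max * (1.0 - np.exp(-params.k_tr * (t_rlx - t_str)))
    slope = params.k_lin_slope * (f_r - params.f_passive)
    f_break = f_r - slope * params.t_lin
    sel = (t >= t_rlx) & (t < t_rlx + params.t_lin)
    f[sel] = f_r - slope * (t[sel] - t_rlx)
    sel = t >= t_rlx + params.t_lin
    f[sel] = params.f_passive + (f_break - params.f_passive) * np.exp(
        -params.k_rel * (t[sel] - t_rlx - params.t_lin)
    )

    if params.noise_sd > 0:
        f = f + rng.normal(0.0, params.noise_sd * params.f_max, size=n)

    trace = ForceTrace(
        time=t,
        force=f,
        marks=ProtocolMarks(t_act, t_rel, t_str, t_rlx),
        csa=params.csa,
    )
    truth = {
        "k_act": params.k_act,
        "k_tr": params.k_tr,
        "t_lin": params.t_lin,
        "k_lin": params.k_lin_slope,
        "k_rel": params.k_rel,
        "f_max": params.f_max,
        "f_passive": params.f_passive,
        "f_relax_onset": f_r,
        "max_tension": (params.f_max - params.f_passive) / params.csa,
        "event_times": params.event_times,
    }
    return trace, truth


# ---------------------------------------------------------------------------
# Doppler inflow waveform


def gen_doppler_waveform(params: DopplerSimParams) -> tuple[DopplerWaveform, dict]:
    """Simulate a diastolic inflow waveform with E and A half-sine lobes.

    Each cycle starts at atrioventricular valve closure; IVCT, ET and IVRT
    occupy the first part of the cycle (inflow velocity 0), after which the
    diastolic filling window carries an E lobe then an A lobe.  Valve event
    times bounding the intervals are returned as annotations.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    total = params.n_cycles * params.period
    n = int(round(total * params.sample_rate))
    t = np.arange(n) / params.sample_rate
    v = np.zeros(n)

    systole = params.ivct + params.et + params.ivrt
    d = params.period - systole  # diastolic filling window
    e_start, e_width = 0.05 * d, 0.40 * d
    a_start, a_width = 0.55 * d, 0.35 * d
    rows = []
    for c in range(params.n_cycles):
        t0 = c * params.period
        av_open = t0 + systole
        for peak, start, width in (
            (params.e_peak, e_start, e_width),
            (params.a_peak, a_start, a_width),
        ):
            lo, hi = av_open + start, av_open + start + width
            sel = (t >= lo) & (t < hi)
            v[sel] += peak * np.sin(np.pi * (t[sel] - lo) / width)
        rows.append(
            {
                "cycle": c,
                "av_close": t0,
                "vb_open": t0 + params.ivct,
                "vb_close": t0 + params.ivct + params.et,
                "av_open": av_open,
            }
        )
    if params.noise_sd > 0:
        v = v + rng.normal(0.0, params.noise_sd, size=n)

    waveform = DopplerWaveform(time=t, velocity=v, events=pd.DataFrame(rows))
    truth = {
        "e_peak": params.e_peak,
        "a_peak": params.a_peak,
        "e_over_a": params.e_peak / params.a_peak,
        "ivct": params.ivct,
        "ivrt": params.ivrt,
        "et": params.et,
        "mpi": (params.ivct + params.ivrt) / params.et,
    }
    return waveform, truth


# ---------------------------------------------------------------------------
# swim-tunnel and survival cohorts


def gen_swim_cohort(params: CohortSimParams) -> tuple[pd.DataFrame, dict]:
    """Simulate swim-tunnel trials whose exhaustion times encode known Ucrit.

    Per-fish true Ucrit values are drawn Normal(mean, sd) per group (floored
    at the initial speed) and converted to exhaustion times so that the
    Brett-form computation recovers each true value exactly.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    p = params.swim_protocol
    means = (
        params.true_ucrit_mean
        if isinstance(params.true_ucrit_mean, (tuple, list))
        else (params.true_ucrit_mean,)
    )
    rows = []
    true_ucrit = []
    for gi, mu in enumerate(means):
        u = rng.normal(mu, params.true_ucrit_sd, size=params.n_per_group)
        u = np.maximum(u, p.initial_speed)
        bl = np.maximum(
            rng.normal(params.body_length_mean, params.body_length_sd, params.n_per_group),
            0.5,
        )
        m = np.floor((u - p.initial_speed) / p.speed_increment)
        frac = (u - p.initial_speed - m * p.speed_increment) / p.speed_increment
        exhaustion = (m + 1) * p.stage_duration + frac * p.stage_duration
        for i in range(params.n_per_group):
            rows.append(
                {
                    "id": f"g{gi}_f{i}",
                    "group": f"g{gi}",
                    "body_length": bl[i],
                    "initial_speed": p.initial_speed,
                    "speed_increment": p.speed_increment,
                    "stage_duration": p.stage_duration,
                    "exhaustion_time": exhaustion[i],
                }
            )
            true_ucrit.append(u[i])
    table = pd.DataFrame(rows)
    truth = {"true_ucrit": np.array(true_ucrit), "protocol": p}
    return table, truth


def gen_survival_cohort(params: CohortSimParams) -> tuple[pd.DataFrame, dict]:
    """Simulate exponential survival per group with administrative censoring.

    Event times are exponential with each group's hazard; times beyond
    ``censor_time`` are censored there.  Hazard 0 gives all-censored records.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    rows = []
    for gi, h in enumerate(params.hazard_per_group):
        if h > 0:
            times = rng.exponential(1.0 / h, size=params.n_per_group)
        else:
            times = np.full(params.n_per_group, np.inf)
        event = times <= params.censor_time
        obs = np.minimum(times, params.censor_time)
        for i in range(params.n_per_group):
            rows.append(
                {
                    "id": f"g{gi}_s{i}",
                    "group": f"g{gi}",
                    "time": obs[i],
                    "event": int(event[i]),
                }
            )
    table = pd.DataFrame(rows)
    truth = {"hazards": tuple(params.hazard_per_group), "censor_time": params.censor_time}
    return table, truth


# ---------------------------------------------------------------------------
# labelled images


def _place_disks(
    rng: np.random.Generator,
    shape: tuple[int, int],
    n: int,
    radius: int,
    max_tries: int = 20000,
) -> list[tuple[int, int]]:
    """Place n non-overlapping disk centers; PackingError when infeasible."""
    centers: list[tuple[int, int]] = []
    # two-pixel clearance so diagonal adjacency can never merge components
    min_d2 = (2 * radius + 3) ** 2
    tries = 0
    while len(centers) < n:
        if tries >= max_tries:
            raise PackingError(
                f"could not place {n} non-overlapping disks of radius {radius} "
                f"in a {shape} image"
            )
        y = int(rng.integers(radius, shape[0] - radius))
        x = int(rng.integers(radius, shape[1] - radius))
        tries += 1
        if all((y - cy) ** 2 + (x - cx) ** 2 >= min_d2 for cy, cx in centers):
            centers.append((y, x))
    return centers


def gen_labeled_image(mode: str, spec: LabelImageSpec) -> tuple[np.ndarray | tuple, dict]:
    """Generate labelled test images with exact ground truth.

    ``mode='area_fraction'``: binary image whose foreground count equals
    ``round(target_fraction * n_pixels)`` exactly.
    ``mode='nuclei'``: (total_channel, positive_channel) intensity images
    with N non-overlapping disk nuclei of which K are positive.
    ``mode='cells'``: integer-labelled mask of ``n_cells`` square cells with
    known per-cell pixel areas.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    if mode == "area_fraction":
        n_pix = spec.shape[0] * spec.shape[1]
        n_fg = int(round(spec.target_fraction * n_pix))
        img = np.zeros(n_pix, dtype=np.uint8)
        img[rng.choice(n_pix, size=n_fg, replace=False)] = 1
        img = img.reshape(spec.shape)
        return img, {"fraction": n_fg / n_pix, "n_foreground": n_fg}
    if mode == "nuclei":
        centers = _place_disks(rng, spec.shape, spec.n_objects, spec.object_radius)
        yy, xx = np.mgrid[0 : spec.shape[0], 0 : spec.shape[1]]
        total = np.full(spec.shape, 10.0)
        positive = np.full(spec.shape, 10.0)
        pos_idx = set(
            rng.choice(spec.n_objects, size=spec.n_positive, replace=False).tolist()
            if spec.n_positive
            else []
        )
        for i, (cy, cx) in enumerate(centers):
            disk_sel = (yy - cy) ** 2 + (xx - cx) ** 2 <= spec.object_radius**2
            total[disk_sel] = 200.0
            if i in pos_idx:
                positive[disk_sel] = 200.0
        frac = 100.0 * spec.n_positive / spec.n_objects if spec.n_objects else 0.0
        return (total, positive), {
            "n_total": spec.n_objects,
            "n_positive": spec.n_positive,
            "percent_positive": frac,
            "centers": centers,
        }
    if mode == "cells":
        side = spec.cell_side
        labels = np.zeros(spec.shape, dtype=np.int32)
        placed = 0
        tries = 0
        boxes: list[tuple[int, int]] = []
        while placed < spec.n_cells:
            if tries >= 20000:
                raise PackingError(
                    f"could not place {spec.n_cells} {side}x{side} cells in {spec.shape}"
                )
            y = int(rng.integers(0, spec.shape[0] - side + 1))
            x = int(rng.integers(0, spec.shape[1] - side + 1))
            tries += 1
            if all(abs(y - by) > side and abs(x - bx) > side for by, bx in boxes) or not boxes:
                if labels[y : y + side, x : x + side].any():
                    continue
                placed += 1
                boxes.append((y, x))
                labels[y : y + side, x : x + side] = placed
        areas = np.full(spec.n_cells, float(side * side) * spec.pixel_size**2)
        return labels, {"areas_um2": areas, "n_cells": spec.n_cells}
    raise InvalidParameterError(f"unknown labelled-image mode: {mode!r}")


# ---------------------------------------------------------------------------
# force-pCa table


def gen_force_pca(
    pca50: float,
    n_h: float,
    f_max: float,
    pca_values: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Hill-form force-pCa table: F = f_max / (1 + 10^(n_h (pCa - pCa50)))."""
    pca = np.asarray(pca_values, dtype=float)
    if pca.size == 0:
        raise InvalidParameterError("pca_values must be non-empty")
    if n_h <= 0 or f_max <= 0 or noise_sd < 0:
        raise InvalidParameterError("n_h, f_max must be positive; noise_sd >= 0")
    rng = np.random.default_rng(seed)
    tension = f_max / (1.0 + 10.0 ** (n_h * (pca - pca50)))
    if noise_sd > 0:
        tension = tension + rng.normal(0.0, noise_sd, size=pca.shape)
    table = pd.DataFrame({"pca": pca, "tension": tension})
    return table, {"pca50": pca50, "n_h": n_h, "f_max": f_max}
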