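"""Single-myofibril force-transient kinetics and force-pCa analysis.

A mounted cardiac myofibril is activated by a fast solution switch to high
calcium (pCa 10 -> 4.5), subjected to a rapid release-restretch maneuver, and
relaxed by switching back to pCa 10.  The trace yields:

* ``k_act`` — mono-exponential rate of calcium-induced force development,
* ``k_tr`` — rate of force redevelopment after the release-restretch,
* biphasic relaxation — a slow linear decline of duration ``t_lin`` and
  normalized slope ``k_lin`` followed by a fast exponential phase of rate
  ``k_rel``,
* maximal isometric tension — developed force over cross-sectional area
  (1 nN/um^2 == 1 mN/mm^2).

Calcium sensitivity is characterised by the Hill force-pCa relation
F(pCa) = F_max / (1 + 10^(n_H (pCa - pCa50))).  A fibre whose developed
tension runs down by more than 20% over a set of contractions is excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, least_squares

from .exceptions import (
    FitFailureError,
    InsufficientContractionsError,
    InsufficientPointsError,
    InsufficientRiseError,
    InvalidParameterError,
    MarkError,
    NonPositiveCSAError,
)

__all__ = [
    "ProtocolMarks",
    "ForceTrace",
    "PhaseWindows",
    "ExpFit",
    "BiphasicFit",
    "HillFit",
    "KineticsResult",
    "RundownQC",
    "segment_phases",
    "fit_exponential_rise",
    "fit_relaxation_biphasic",
    "compute_tension",
    "fit_hill",
    "qc_rundown",
    "analyze_trace",
]


@dataclass
class ProtocolMarks:
    """Protocol event times (s): activation onset, release, restretch,
    relaxation onset."""

    activation: float
    release: float
    restretch: float
    relaxation: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.activation, self.release, self.restretch, self.relaxation)


@dataclass
class ForceTrace:
    """Time-stamped myofibril force record with protocol marks."""

    time: np.ndarray  # s
    force: np.ndarray  # nN
    marks: ProtocolMarks
    csa: float | None = None  # um^2
    sarcomere_length: float = 2.3  # um
    temperature: float = 10.0  # degC

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.time.shape != self.force.shape or self.time.ndim != 1:
            raise InvalidParameterError("time and force must be equal-length 1-D")
        if len(self.time) > 1 and np.any(np.diff(self.time) <= 0):
            raise InvalidParameterError("time must be strictly increasing")


@dataclass
class PhaseWindows:
    """Half-open [start, stop) time windows for each protocol phase."""

    baseline: tuple[float, float]
    activation: tuple[float, float]
    redevelopment: tuple[float, float]
    relaxation: tuple[float, float]

    def slice_of(self, trace: ForceTrace, phase: str) -> tuple[np.ndarray, np.ndarray]:
        t0, t1 = getattr(self, phase)
        sel = (trace.time >= t0) & (trace.time < t1)
        return trace.time[sel], trace.force[sel]


@dataclass
class ExpFit:
    """Mono-exponential rise fit F(t) = F0 + (Finf - F0)(1 - exp(-k t))."""

    k: float  # 1/s
    f0: float
    f_inf: float
    sse: float
    n: int
    converged: bool = True


@dataclass
class BiphasicFit:
    """Piecewise linear-then-exponential relaxation fit."""

    t_lin: float  # s, duration of the linear phase
    k_lin: float  # 1/s, linear slope normalized by developed force
    k_rel: float  # 1/s, exponential phase rate
    f_break: float  # force at the breakpoint
    sse: float
    breakpoint_index: int
    converged: bool = True


@dataclass
class HillFit:
    """Force-pCa Hill fit: F = F_max / (1 + 10^(n_h (pCa - pCa50)))."""

    pca50: float
    n_h: float
    f_max: float
    sse: float

    def predict(self, pca: np.ndarray) -> np.ndarray:
        pca = np.asarray(pca, dtype=float)
        return self.f_max / (1.0 + 10.0 ** (self.n_h * (pca - self.pca50)))

    def summary(self) -> str:
        return (
            "Force-pCa Hill fit\n"
            f"  pCa50   {self.pca50:.4f}\n"
            f"  n_H     {self.n_h:.4f}\n"
            f"  F_max   {self.f_max:.4g}\n"
            f"  SSE     {self.sse:.3g}"
        )


@dataclass
class RundownQC:
    """Tension-rundown quality control over a set of contractions."""

    rundown: float  # (first - last) / first
    include: bool


@dataclass
class KineticsResult:
    """Fitted kinetic parameters of one myofibril force transient."""

    k_act: float  # 1/s
    k_tr: float  # 1/s
    t_lin: float  # s
    k_lin: float  # 1/s
    k_rel: float  # 1/s
    max_tension: float | None  # mN/mm^2, None when CSA was not provided
    baseline_force: float  # nN
    plateau_force: float  # nN
    diagnostics: dict = field(default_factory=dict)

    def summary(self) -> str:
        rows = [
            ("k_ACT", self.k_act, "1/s"),
            ("k_TR", self.k_tr, "1/s"),
            ("T_LIN", self.t_lin, "s"),
            ("k_LIN", self.k_lin, "1/s"),
            ("k_REL", self.k_rel, "1/s"),
        ]
        lines = ["Myofibril kinetics"]
        for name, val, unit in rows:
            lines.append(f"  {name:<6s} {val: .4g} {unit}")
        if self.max_tension is not None:
            lines.append(f"  max tension {self.max_tension:.4g} mN/mm^2")
        return "\n".join(lines)


def segment_phases(trace: ForceTrace) -> PhaseWindows:
    """Split a trace into baseline / activation / redevelopment / relaxation.

    The release-to-restretch interval is the mechanical maneuver itself and
    is excluded from fitting windows.
    """
    m = trace.marks
    for name in ("activation", "release", "restretch", "relaxation"):
        if getattr(m, name) is None:
            raise MarkError(f"missing protocol mark: {name}")
    t = m.as_tuple()
    if not (t[0] < t[1] < t[2] < t[3]):
        raise MarkError(f"marks out of order: {t}")
    if t[0] <= trace.time[0]:
        raise MarkError("activation mark precedes the trace start; no baseline")
    if t[3] >= trace.time[-1]:
        raise MarkError("relaxation mark at or beyond the trace end")
    return PhaseWindows(
        baseline=(float(trace.time[0]), t[0]),
        activation=(t[0], t[1]),
        redevelopment=(t[2], t[3]),
        relaxation=(t[3], float(trace.time[-1]) + np.finfo(float).eps),
    )


def _rise_model(t: np.ndarray, f0: float, f_inf: float, k: float) -> np.ndarray:
    return f0 + (f_inf - f0) * (1.0 - np.exp(-k * t))


def fit_exponential_rise(
    time: np.ndarray,
    force: np.ndarray,
    baseline: float,
    min_rise: float = 1e-6,
) -> ExpFit:
    """Least-squares mono-exponential rise fit; returns rate and plateau.

    The rate is initialised from the time to half-rise (ln 2 / t_half).
    Rates are invariant to force rescaling and to shifts of the time origin.

    Raises
    ------
    InsufficientRiseError
        If the window's dynamic range is below ``min_rise``.
    FitFailureError
        On non-convergence or a non-positive fitted rate.
    """
    t = np.asarray(time, dtype=float)
    f = np.asarray(force, dtype=float)
    if len(t) < 10:
        raise InsufficientPointsError(f"rise fit needs >= 10 samples, got {len(t)}")
    if float(np.ptp(f)) < min_rise:
        raise InsufficientRiseError(
            f"force range {np.ptp(f):.3g} below minimum rise {min_rise:.3g}"
        )
    tau = t - t[0]
    f_inf0 = float(np.mean(f[max(len(f) - max(len(f) // 10, 3), 1):]))
    f00 = baseline
    half = f00 + 0.5 * (f_inf0 - f00)
    above = np.nonzero(f >= half)[0]
    t_half = tau[above[0]] if len(above) and tau[above[0]] > 0 else tau[-1] / 4 or 1.0
    k0 = np.log(2.0) / t_half
    try:
        popt, _ = curve_fit(
            _rise_model, tau, f,
            p0=[f00, f_inf0, k0],
            bounds=([-np.inf, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(f"exponential rise fit failed: {exc}") from exc
    f0_fit, f_inf, k = map(float, popt)
    if k <= 0 or not np.isfinite(k):
        raise FitFailureError(f"non-physical rise rate {k}")
    sse = float(np.sum((f - _rise_model(tau, *popt)) ** 2))
    if tau[-1] < 2.0 / k:
        warnings.warn(
            f"rise window ({tau[-1]:.3g} s) spans less than 2/k ({2.0 / k:.3g} s); "
            "rate may be poorly constrained",
            stacklevel=2,
        )
    return ExpFit(k=k, f0=f0_fit, f_inf=f_inf, sse=sse, n=len(t))


def _fit_exp_decay_rate(
    tau: np.ndarray, f: np.ndarray, amplitude: float, baseline: float
) -> tuple[float, float]:
    """Fit k in F = baseline + amplitude * exp(-k tau); returns (k, sse)."""
    # initial rate from the half-decay crossing
    half = baseline + 0.5 * amplitude
    below = np.nonzero(f <= half)[0]
    t_half = tau[below[0]] if len(below) and tau[below[0]] > 0 else (tau[-1] / 4 or 1.0)
    k0 = np.log(2.0) / t_half

    def resid(logk: np.ndarray) -> np.ndarray:
        return baseline + amplitude * np.exp(-np.exp(logk[0]) * tau) - f

    sol = least_squares(resid, x0=[np.log(max(k0, 1e-9))], method="lm", max_nfev=2000)
    k = float(np.exp(sol.x[0]))
    sse = float(np.sum(sol.fun**2))
    return k, sse


def _piecewise_sse(
    tau: np.ndarray, f: np.ndarray, idx: int, baseline: float
) -> tuple[float, dict] | None:
    """Total SSE of a linear[0:idx] + exponential[idx:] split at sample idx."""
    if idx == 0:
        a, b = float(f[0]), 0.0
        sse_lin = 0.0
        f_break = float(f[0])
    else:
        b, a = np.polyfit(tau[: idx + 1], f[: idx + 1], 1)
        sse_lin = float(np.sum((a + b * tau[: idx + 1] - f[: idx + 1]) ** 2))
        f_break = float(a + b * tau[idx])
    amp = f_break - baseline
    if amp <= 0:
        return None
    te = tau[idx:] - tau[idx]
    try:
        k, sse_exp = _fit_exp_decay_rate(te, f[idx:], amp, baseline)
    except (ValueError, FloatingPointError):
        return None
    return sse_lin + sse_exp, {
        "slope": b, "intercept": a, "f_break": f_break, "k_rel": k, "idx": idx,
    }


def fit_relaxation_biphasic(
    time: np.ndarray,
    force: np.ndarray,
    plateau: float,
    baseline: float,
    min_exp_samples: int = 10,
    max_grid: int = 120,
) -> BiphasicFit:
    """Fit biphasic relaxation: linear decline for ``t_lin``, then exponential.

    The breakpoint is chosen by exhaustive search over candidate sample times
    (coarse grid of at most ``max_grid`` candidates, refined to single-sample
    resolution around the minimum) minimising the total SSE, with continuity
    enforced at the breakpoint.  ``k_lin`` is the linear slope magnitude
    normalized by the developed force (plateau - baseline), so it has units
    1/s and is comparable across fibres.

    Raises
    ------
    FitFailureError
        When no candidate admits a decaying exponential tail, the fitted rate
        is non-positive, or the best breakpoint sits at the end of the grid
        (the data show no exponential tail).
    """
    t = np.asarray(time, dtype=float)
    f = np.asarray(force, dtype=float)
    if len(t) < 20:
        raise InsufficientPointsError(f"relaxation fit needs >= 20 samples, got {len(t)}")
    # judge monotonicity on a smoothed trace and ignore sub-resolution
    # wiggles: only rises that are material against the developed force count
    win = max(5, len(f) // 20)
    kernel = np.ones(win) / win
    f_smooth = np.convolve(f, kernel, mode="valid")
    rise_floor = 1e-3 * abs(plateau - baseline)
    rising = np.mean(np.diff(f_smooth) > rise_floor)
    if rising > 0.2:
        warnings.warn(
            f"{rising:.0%} of relaxation samples rise; input may not be a relaxation",
            stacklevel=2,
        )
    developed = plateau - baseline
    if developed <= 0:
        raise InvalidParameterError("plateau must exceed baseline")
    tau = t - t[0]
    last = len(t) - min_exp_samples
    if last < 1:
        raise InsufficientPointsError("window too short for the exponential tail")

    candidates = np.unique(np.linspace(0, last, min(max_grid, last + 1)).astype(int))

    def best_over(idxs: np.ndarray) -> tuple[int, float, dict] | None:
        top: tuple[int, float, dict] | None = None
        for idx in idxs:
            out = _piecewise_sse(tau, f, int(idx), baseline)
            if out is None:
                continue
            sse, info = out
            if top is None or sse < top[1]:
                top = (int(idx), sse, info)
        return top

    top = best_over(candidates)
    if top is None:
        raise FitFailureError("no breakpoint admits a decaying exponential tail")
    # refine to single-sample resolution around the coarse optimum
    stride = max(1, int(np.ceil(last / max(len(candidates) - 1, 1))))
    lo, hi = max(0, top[0] - stride), min(last, top[0] + stride)
    refined = best_over(np.arange(lo, hi + 1))
    if refined is not None and refined[1] <= top[1]:
        top = refined
    idx, sse, info = top
    if idx >= last:
        raise FitFailureError(
            "best breakpoint at the window end; no exponential tail detected"
        )
    k_rel = info["k_rel"]
    if k_rel <= 0 or not np.isfinite(k_rel):
        raise FitFailureError(f"non-physical relaxation rate {k_rel}")
    slope = info["slope"] if idx > 0 else 0.0
    return BiphasicFit(
        t_lin=float(tau[idx]),
        k_lin=float(max(-slope, 0.0) / developed),
        k_rel=k_rel,
        f_break=info["f_break"],
        sse=float(sse),
        breakpoint_index=idx,
    )


def compute_tension(plateau: float, baseline: float, csa: float) -> float:
    """Developed tension in mN/mm^2: (plateau - baseline) / CSA.

    Forces in nN, CSA in um^2; 1 nN/um^2 equals 1 mN/mm^2, so no numeric
    conversion factor is needed.
    """
    if csa is None or csa <= 0:
        raise NonPositiveCSAError(f"cross-sectional area must be positive, got {csa}")
    return (plateau - baseline) / csa


def _hill(pca: np.ndarray, f_max: float, n_h: float, pca50: float) -> np.ndarray:
    return f_max / (1.0 + 10.0 ** (n_h * (pca - pca50)))


def fit_hill(table: pd.DataFrame | np.ndarray, tension: np.ndarray | None = None) -> HillFit:
    """Fit the Hill force-pCa relation to a (pCa, tension) table.

    Accepts a DataFrame with columns ``pca`` and ``tension`` or two arrays.
    Initialisation: pCa50 at the point closest to half-maximal force, n_H = 2.
    """
    if tension is None:
        pca = np.asarray(table["pca"], dtype=float)
        f = np.asarray(table["tension"], dtype=float)
    else:
        pca = np.asarray(table, dtype=float)
        f = np.asarray(tension, dtype=float)
    if len(np.unique(pca)) < 4:
        raise InsufficientPointsError(
            f"Hill fit needs >= 4 distinct pCa values, got {len(np.unique(pca))}"
        )
    f_max0 = float(f.max())
    pca50_0 = float(pca[np.argmin(np.abs(f - f_max0 / 2.0))])
    try:
        popt, _ = curve_fit(
            _hill, pca, f,
            p0=[f_max0, 2.0, pca50_0],
            bounds=([0.0, 1e-6, pca.min() - 2.0], [np.inf, 50.0, pca.max() + 2.0]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(f"Hill fit failed: {exc}") from exc
    f_max, n_h, pca50 = map(float, popt)
    sse = float(np.sum((f - _hill(pca, *popt)) ** 2))
    return HillFit(pca50=pca50, n_h=n_h, f_max=f_max, sse=sse)


def qc_rundown(tensions: np.ndarray) -> RundownQC:
    """Rundown QC: exclude a fibre losing more than 20% developed tension
    between the first and last contraction of a set."""
    t = np.asarray(tensions, dtype=float)
    if len(t) < 2:
        raise InsufficientContractionsError("need at least two contractions")
    if t[0] == 0:
        raise InvalidParameterError("first developed tension is zero")
    rundown = float((t[0] - t[-1]) / t[0])
    return RundownQC(rundown=rundown, include=rundown <= 0.20)


def analyze_trace(trace: ForceTrace) -> KineticsResult:
    """Full kinetic analysis of one activation/release-restretch/relaxation
    trace.

    Baseline force is the mean over the pre-activation window; ``k_act`` and
    the plateau come from the activation rise, ``k_tr`` from the
    post-restretch redevelopment, and the relaxation window yields the
    biphasic parameters.  Tension is reported only when the trace carries a
    cross-sectional area.
    """
    windows = segment_phases(trace)
    _, f_base = windows.slice_of(trace, "baseline")
    baseline = float(np.mean(f_base))

    t_act, f_act = windows.slice_of(trace, "activation")
    act = fit_exponential_rise(t_act, f_act, baseline)

    t_red, f_red = windows.slice_of(trace, "redevelopment")
    red = fit_exponential_rise(t_red, f_red, float(f_red[0]))

    t_rel, f_rel = windows.slice_of(trace, "relaxation")
    relax = fit_relaxation_biphasic(t_rel, f_rel, plateau=float(f_rel[0]), baseline=baseline)

    tension = compute_tension(act.f_inf, baseline, trace.csa) if trace.csa else None
    return KineticsResult(
        k_act=act.k, k_tr=red.k,
        t_lin=relax.t_lin, k_lin=relax.k_lin, k_rel=relax.k_rel,
        max_tension=tension,
        baseline_force=baseline, plateau_force=act.f_inf,
        diagnostics={
            "sse_activation": act.sse,
            "sse_redevelopment": red.sse,
            "sse_relaxation": relax.sse,
            "converged": act.converged and red.converged and relax.converged,
        },
    )
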