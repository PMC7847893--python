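"""Assay-level analyses: arousal threshold, curve comparison, PPI, habituation.

The *arousal threshold* of a dose-response experiment is the stimulus
strength producing half-maximal response probability.  Response curves —
response probability per stimulus intensity — are fitted with a
four-parameter logistic (4PL) in log10 intensity,

    p(x) = floor + (ceiling - floor) / (1 + 10**(slope * (log10(EC50) - x))),

and the threshold reported is the EC50, the intensity at
``(floor + ceiling) / 2``.  Two curves are compared with the extra
sum-of-squares F test between a shared fit (one 4PL for the pooled data)
and separate fits.

*Prepulse inhibition* (PPI) compares responses to a strong stimulus
preceded by a weak prepulse against an isolated control stimulus;
%PPI = 100 * (1 - p_PPI / p_control).  Fish (or individual trials) that
respond to the prepulse itself are excluded.  *Habituation* to a repeated
identical stimulus is summarized block-wise as
1 - p_last_block / p_first_block.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from .responses import ResponseEvent

__all__ = [
    "ResponseCurve",
    "DoseResponseFit",
    "FitError",
    "PpiTrial",
    "PpiResult",
    "build_response_curve",
    "fit_arousal_threshold",
    "compare_curves_f_test",
    "ppi_analysis",
    "habituation_analysis",
]


class FitError(RuntimeError):
    """Raised when a dose-response fit cannot produce a usable threshold."""


@dataclass
class ResponseCurve:
    """Response probability per stimulus intensity."""

    intensities: np.ndarray
    n_trials: np.ndarray
    n_responses: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.n_trials = np.asarray(self.n_trials, dtype=int)
        self.n_responses = np.asarray(self.n_responses, dtype=int)
        if not (len(self.intensities) == len(self.n_trials) == len(self.n_responses)):
            raise ValueError("curve arrays must have equal length")
        if np.any(self.intensities <= 0):
            raise ValueError("intensities must be positive (log-scale usable)")
        if np.any(self.n_responses > self.n_trials) or np.any(self.n_trials <= 0):
            raise ValueError("need 0 <= n_responses <= n_trials, n_trials > 0")

    @property
    def p(self) -> np.ndarray:
        return self.n_responses / self.n_trials

    def __len__(self) -> int:
        return len(self.intensities)


@dataclass
class DoseResponseFit:
    """A fitted 4PL dose-response model."""

    threshold: float           # EC50, in stimulus-intensity units
    hill_slope: float
    p_floor: float
    p_ceiling: float
    rss: float
    n_points: int
    threshold_in_range: bool
    success: bool = True
    message: str = ""

    @property
    def n_params(self) -> int:
        return 4

    def predict(self, intensities: np.ndarray) -> np.ndarray:
        x = np.log10(np.asarray(intensities, dtype=float))
        return _logistic4(x, math.log10(self.threshold), self.hill_slope,
                          self.p_floor, self.p_ceiling)


def _logistic4(x, log_ec50, slope, floor, ceiling):
    return floor + (ceiling - floor) / (1.0 + 10.0 ** (slope * (log_ec50 - x)))


def build_response_curve(
    trials: Iterable[tuple[float, "ResponseEvent | bool"]],
) -> ResponseCurve:
    """Group (intensity, outcome) trials into a response curve.

    ``outcome`` may be a :class:`ResponseEvent` or a plain bool.
    Intensities are sorted ascending in the result.
    """
    counts: dict[float, list[int]] = {}
    for intensity, outcome in trials:
        responded = outcome.responded if isinstance(outcome, ResponseEvent) \
            else bool(outcome)
        c = counts.setdefault(float(intensity), [0, 0])
        c[0] += 1
        c[1] += int(responded)
    if not counts:
        raise ValueError("no trials supplied")
    intens = np.array(sorted(counts))
    return ResponseCurve(
        intensities=intens,
        n_trials=np.array([counts[i][0] for i in intens]),
        n_responses=np.array([counts[i][1] for i in intens]),
    )


def _fit_4pl_points(
    x: np.ndarray,
    p: np.ndarray,
    n_starts: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Multi-start bounded least squares of the 4PL on (log10 intensity, p).

    Returns (params, rss) of the best converged start; params are
    (log_ec50, slope, floor, ceiling).
    """
    lo, hi = x.min(), x.max()
    span = max(hi - lo, 1e-6)
    bounds = ([lo - 2 * span, 0.05, 0.0, 0.0], [hi + 2 * span, 20.0, 1.0, 1.0])
    p_lo, p_hi = float(p.min()), float(p.max())
    base = (0.5 * (lo + hi), 2.0 / span, max(p_lo, 0.0), min(p_hi, 1.0))
    best: tuple[np.ndarray, float] | None = None
    for k in range(n_starts):
        if k == 0:
            start = np.array(base)
        else:
            start = np.array([
                rng.uniform(lo, hi),
                10.0 ** rng.uniform(math.log10(0.2 / span), math.log10(8.0 / span)),
                rng.uniform(0, max(p_lo, 0.05)),
                rng.uniform(min(p_hi, 0.95), 1.0),
            ])
        start = np.clip(start, bounds[0], bounds[1])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, _ = optimize.curve_fit(
                    _logistic4, x, p, p0=start, bounds=bounds, maxfev=5000
                )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((p - _logistic4(x, *popt)) ** 2))
        if best is None or rss < best[1] - 1e-12:
            best = (popt, rss)
    if best is None:
        raise FitError("4PL fit failed to converge from any start")
    return best


def fit_arousal_threshold(
    curve: ResponseCurve,
    n_starts: int = 5,
    seed: int | None = 0,
    min_dynamic_range: float = 0.1,
) -> DoseResponseFit:
    """Fit the 4PL and report the arousal threshold (EC50).

    Requires at least 4 intensity levels.  Degenerate data — a dynamic
    range (ceiling - floor) below ``min_dynamic_range``, as for a flat
    curve — yields a fit with ``success=False`` and a diagnostic message;
    the threshold of an unsuccessful fit is NaN, never a silent number.
    """
    if len(curve) < 4:
        raise ValueError("need >= 4 intensity levels for a 4PL fit")
    x = np.log10(curve.intensities)
    p = curve.p
    rng = np.random.default_rng(seed)
    try:
        (log_ec50, slope, floor, ceiling), rss = _fit_4pl_points(
            x, p, n_starts, rng
        )
    except FitError as e:
        return DoseResponseFit(
            threshold=float("nan"), hill_slope=float("nan"),
            p_floor=float("nan"), p_ceiling=float("nan"),
            rss=float("nan"), n_points=len(curve),
            threshold_in_range=False, success=False, message=str(e),
        )
    in_range = bool(x.min() <= log_ec50 <= x.max())
    if ceiling - floor < min_dynamic_range:
        return DoseResponseFit(
            threshold=float("nan"), hill_slope=slope, p_floor=floor,
            p_ceiling=ceiling, rss=rss, n_points=len(curve),
            threshold_in_range=False, success=False,
            message=(
                f"dynamic range {ceiling - floor:.3f} below "
                f"{min_dynamic_range}; threshold not identifiable"
            ),
        )
    return DoseResponseFit(
        threshold=float(10.0 ** log_ec50), hill_slope=float(slope),
        p_floor=float(floor), p_ceiling=float(ceiling), rss=float(rss),
        n_points=len(curve), threshold_in_range=in_range,
    )


def compare_curves_f_test(
    curve_a: ResponseCurve,
    curve_b: ResponseCurve,
    n_starts: int = 5,
    seed: int | None = 0,
) -> tuple[float, int, int, float]:
    """Extra sum-of-squares F test: one shared 4PL vs separate 4PLs.

    Returns ``(F, df_numerator, df_denominator, p)``.  The null model fits
    a single curve to the pooled points (4 parameters); the alternative
    fits each curve separately (8).  Identical inputs give F ~ 0, p ~ 1.
    """
    rng = np.random.default_rng(seed)
    xa, pa = np.log10(curve_a.intensities), curve_a.p
    xb, pb = np.log10(curve_b.intensities), curve_b.p
    x_pool = np.concatenate([xa, xb])
    p_pool = np.concatenate([pa, pb])
    _, rss_shared = _fit_4pl_points(x_pool, p_pool, n_starts, rng)
    _, rss_a = _fit_4pl_points(xa, pa, n_starts, rng)
    _, rss_b = _fit_4pl_points(xb, pb, n_starts, rng)
    rss_sep = rss_a + rss_b
    n = len(x_pool)
    df_num = 4
    df_den = n - 8
    if df_den <= 0:
        raise ValueError("too few points for separate fits (need > 8)")
    num = max(rss_shared - rss_sep, 0.0) / df_num
    den = rss_sep / df_den
    if den == 0:
        f_stat = 0.0 if num == 0 else float("inf")
    else:
        f_stat = num / den
    p_val = float(stats.f.sf(f_stat, df_num, df_den))
    return float(f_stat), df_num, df_den, p_val


# ---------------------------------------------------------------------------
# Prepulse inhibition
# ---------------------------------------------------------------------------

@dataclass
class PpiTrial:
    """One stimulus presentation in a PPI battery.

    ``kind`` is ``"ppi"`` (prepulse + strong stimulus) or ``"control"``
    (isolated strong stimulus).  ``prepulse_responded`` records whether
    the weak prepulse itself elicited a response (meaningful only on PPI
    trials).  ``magnitudes`` carries response-size metrics such as
    delta-pixel sum, distance, displacement and speed.
    """

    unit_id: str
    group: str
    kind: str
    responded: bool
    prepulse_responded: bool = False
    magnitudes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("ppi", "control"):
            raise ValueError("trial kind must be 'ppi' or 'control'")


@dataclass
class PpiResult:
    """Per-group PPI summary."""

    group: str
    n_ppi_trials: int
    n_control_trials: int
    p_ppi: float
    p_control: float
    ppi_percent: float
    magnitude_ppi: dict
    magnitude_control: dict
    n_excluded: int


def ppi_analysis(
    trials: Sequence[PpiTrial],
    exclude: str = "trial",
) -> dict[str, PpiResult]:
    """Per-group PPI and control response frequencies and magnitudes.

    Prepulse responders are excluded before any frequency is computed:
    ``exclude="trial"`` drops only the PPI trials whose own prepulse
    elicited a response (default; preserves power), while
    ``exclude="unit"`` drops every trial of any fish that responded to a
    prepulse at least once.  %PPI = 100 * (1 - p_PPI / p_control); NaN if
    the control rate is zero.  %PPI is invariant under trial reordering.
    """
    if exclude not in ("trial", "unit"):
        raise ValueError("exclude must be 'trial' or 'unit'")
    excluded_units: set[tuple[str, str]] = set()
    if exclude == "unit":
        excluded_units = {
            (t.group, t.unit_id) for t in trials
            if t.kind == "ppi" and t.prepulse_responded
        }

    groups: dict[str, dict] = {}
    for t in trials:
        g = groups.setdefault(t.group, {
            "ppi": [], "control": [], "excluded": 0,
        })
        if (t.group, t.unit_id) in excluded_units:
            g["excluded"] += 1
            continue
        if t.kind == "ppi" and t.prepulse_responded:
            g["excluded"] += 1
            continue
        g[t.kind].append(t)

    out: dict[str, PpiResult] = {}
    for group, g in sorted(groups.items()):
        p_ppi = _rate(g["ppi"])
        p_control = _rate(g["control"])
        if p_control and not math.isnan(p_control):
            ppi_pct = 100.0 * (1.0 - p_ppi / p_control)
        else:
            ppi_pct = float("nan")
        out[group] = PpiResult(
            group=group,
            n_ppi_trials=len(g["ppi"]),
            n_control_trials=len(g["control"]),
            p_ppi=p_ppi,
            p_control=p_control,
            ppi_percent=ppi_pct,
            magnitude_ppi=_mean_magnitudes(g["ppi"]),
            magnitude_control=_mean_magnitudes(g["control"]),
            n_excluded=g["excluded"],
        )
    return out


def _rate(trials: list[PpiTrial]) -> float:
    if not trials:
        return float("nan")
    return sum(t.responded for t in trials) / len(trials)


def _mean_magnitudes(trials: list[PpiTrial]) -> dict:
    """Mean of each magnitude metric over responding trials."""
    responders = [t for t in trials if t.responded and t.magnitudes]
    if not responders:
        return {}
    keys = set().union(*(t.magnitudes for t in responders))
    return {
        k: float(np.mean([t.magnitudes[k] for t in responders
                          if k in t.magnitudes]))
        for k in sorted(keys)
    }


# ---------------------------------------------------------------------------
# Habituation
# ---------------------------------------------------------------------------

def habituation_analysis(
    responded: Sequence[bool],
    block_size: int = 10,
) -> dict:
    """Block-wise response decline to a repeated identical stimulus.

    Splits the trial sequence into consecutive blocks of ``block_size``
    (the final block may be partial), reports per-block response
    probability and the habituation index ``1 - p_last / p_first``.  An
    all-zero first block makes the index undefined (NaN), never a
    division error.
    """
    if block_size <= 0:
        raise ValueError("block_size must be positive")
    flags = np.asarray([bool(r) for r in responded], dtype=float)
    if len(flags) == 0:
        raise ValueError("no trials supplied")
    n_blocks = int(math.ceil(len(flags) / block_size))
    block_p = np.array([
        flags[i * block_size:(i + 1) * block_size].mean()
        for i in range(n_blocks)
    ])
    p_first, p_last = block_p[0], block_p[-1]
    index = float("nan") if p_first == 0 else float(1.0 - p_last / p_first)
    return {
        "block_p": block_p,
        "n_blocks": n_blocks,
        "p_first_block": float(p_first),
        "p_last_block": float(p_last),
        "habituation_index": index,
    }
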