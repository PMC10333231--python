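"""Clearance kinetics of LOH-positive fractions under selection.

After editing, cells carrying megabase-scale rearrangements proliferate
more slowly than intact cells; the LOH-positive fraction therefore decays
over serial flow measurements.  The minimal formalization is discrete-
generation relative fitness: if LOH cells grow by a factor w per generation
relative to intact cells, the positive fraction after g generations is

    f(g) = f0 * w**g / (f0 * w**g + (1 - f0)),        g = t / generation_time

which is linear on the logit scale: logit f(g) = logit f0 + g ln w.  A flat
time course (persistent LOH) corresponds to w = 1; w < 1 produces the
clearance of rearranged clones seen in p53-proficient cells, while
p53-deficient cells behave as w ~ 1.  Assay background is added after
selection and subtracted before fitting.
"""

from __future__ import annotations

import math

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

__all__ = [
    "LohTimecourse",
    "ClearanceFit",
    "project_timecourse",
    "fit_clearance",
    "compare_genotypes",
]

DEFAULT_BACKGROUND = 0.005  # non-fluorescent background of the murine reporter assay


@dataclass
class LohTimecourse:
    """Day-indexed LOH-positive fractions for one genotype."""

    days: np.ndarray
    loh_fraction: np.ndarray
    genotype_label: str = ""
    background: float = 0.0
    n_events: float | None = None  # events per measurement, if known

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.loh_fraction = np.asarray(self.loh_fraction, dtype=float)
        if self.days.shape != self.loh_fraction.shape:
            raise ValueError("days and loh_fraction must have equal length")
        if ((self.loh_fraction < 0) | (self.loh_fraction > 1)).any():
            raise ValueError("fractions must be in [0, 1]")
        if (self.days < 0).any():
            raise ValueError("days must be non-negative")


@dataclass
class ClearanceFit:
    """Fitted selection parameters for one time course.

    ``w`` is per-generation relative fitness; ``f0`` the model's initial
    LOH fraction at t = 0 (an extrapolation: the earliest usable
    measurement is delayed by reporter clearance, so f0 is a model
    parameter, not an observation).  ``status`` is "fit", or "cleared" when
    too few points sit above background to fit (<= 1).
    """

    f0: float | None
    w: float | None
    generation_time: float
    residual: float | None
    n_points: int
    status: str = "fit"
    series: LohTimecourse | None = None
    warnings: list = field(default_factory=list)

    @property
    def persistent(self) -> bool | None:
        return None if self.w is None else abs(self.w - 1.0) < 0.05


def project_timecourse(
    f0: float,
    w: float,
    generation_time: float,
    days,
    background: float = 0.0,
    genotype_label: str = "",
) -> LohTimecourse:
    """Project the selection model forward.

    Generations are counted as g = t / generation_time; background is added
    after selection, so a fully cleared population reads at background.
    """
    if f0 < 0 or f0 >= 1:
        raise ValueError("f0 must be in [0, 1)")
    if w <= 0 or generation_time <= 0:
        raise ValueError("w and generation_time must be positive")
    days = np.asarray(days, dtype=float)
    g = days / generation_time
    num = f0 * np.power(w, g)
    frac = num / (num + (1.0 - f0))
    return LohTimecourse(
        days=days,
        loh_fraction=np.clip(frac + background, 0.0, 1.0),
        genotype_label=genotype_label,
        background=background,
    )


def fit_clearance(series: LohTimecourse, generation_time: float) -> ClearanceFit:
    """Fit relative fitness w and initial fraction f0 to a time course.

    Background is subtracted (clamped at zero) and the surviving points are
    regressed on generations on the logit scale: the slope is ln w and the
    intercept logit f0.  A point counts as above background only when it
    exceeds it by more than twice the binomial standard error of the
    background (when per-day event counts are known): measurements at the
    assay floor carry no slope information and would bias w toward 1.  When
    event counts are known the regression is also precision-weighted by the
    delta-method binomial variance of each logit; otherwise ordinary least
    squares.  With <= 1 usable point no fit is attempted and a qualitative
    "cleared" verdict is returned.
    """
    if generation_time <= 0:
        raise ValueError("generation_time must be positive")
    adj = series.loh_fraction - series.background
    floor = 0.0
    if series.n_events and np.isfinite(series.n_events) and series.background > 0:
        floor = 2.0 * math.sqrt(
            series.background * (1.0 - series.background) / series.n_events
        )
    above = adj > floor
    warnings = []
    if above.sum() <= 1:
        return ClearanceFit(
            f0=None,
            w=None,
            generation_time=generation_time,
            residual=None,
            n_points=int(above.sum()),
            status="cleared",
            series=series,
            warnings=["<= 1 point above background: LOH cleared, no fit"],
        )
    if above.sum() == 2:
        warnings.append("only 2 points above background: exact-fit, no residual df")
    days = series.days[above]
    p = np.clip(adj[above], 1e-12, 1.0 - 1e-12)
    g = days / generation_time
    y = logit(p)
    if series.n_events and np.isfinite(series.n_events):
        wts = series.n_events * p * (1.0 - p)
    else:
        wts = np.ones_like(p)
    X = np.column_stack([np.ones_like(g), g])
    sw = np.sqrt(wts)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    intercept, slope = beta
    resid = float(np.sum(wts * (y - X @ beta) ** 2))
    return ClearanceFit(
        f0=float(expit(intercept)),
        w=float(np.exp(slope)),
        generation_time=generation_time,
        residual=resid,
        n_points=int(above.sum()),
        status="fit",
        series=series,
        warnings=warnings,
    )


def compare_genotypes(
    fits: dict,
    n_boot: int = 200,
    seed: int = 0,
    n_events: float = 1e5,
) -> dict:
    """Order genotypes by fitted relative fitness with bootstrap intervals.

    ``fits`` maps genotype label to a :class:`ClearanceFit` carrying its
    series.  Uncertainty comes from a parametric bootstrap: each day's
    fraction is re-drawn binomially (with the series' event count, falling
    back to ``n_events``) and refitted.  A genotype whose 95% interval for
    w contains 1 is flagged persistent; cleared series (no fit) are ranked
    lowest.  When intervals overlap, no strict ordering is claimed between
    those genotypes.
    """
    rng = np.random.default_rng(seed)
    report = {}
    for label, fit in fits.items():
        entry = {"w": fit.w, "f0": fit.f0, "status": fit.status}
        if fit.status == "fit" and fit.series is not None:
            n = fit.series.n_events or n_events
            ws = []
            for _ in range(n_boot):
                drawn = rng.binomial(
                    int(n), fit.series.loh_fraction
                ) / float(int(n))
                boot = LohTimecourse(
                    days=fit.series.days,
                    loh_fraction=drawn,
                    background=fit.series.background,
                    n_events=n,
                )
                bf = fit_clearance(boot, fit.generation_time)
                if bf.w is not None:
                    ws.append(bf.w)
            if ws:
                lo, hi = np.percentile(ws, [2.5, 97.5])
                entry["w_ci"] = [float(lo), float(hi)]
                # persistent: interval reaches neutrality, or the point
                # estimate is within the practical-equivalence band around 1
                # (a CI at large n can exclude 1 for a biologically flat curve)
                entry["persistent"] = bool(
                    lo <= 1.0 <= hi or fit.w >= 1.0 or abs(fit.w - 1.0) < 0.05
                )
            else:
                entry["w_ci"] = None
                entry["persistent"] = False
        else:
            entry["w_ci"] = None
            entry["persistent"] = False
        report[label] = entry

    def sort_key(item):
        w = item[1]["w"]
        return -np.inf if w is None else w

    ordering = [label for label, _ in sorted(report.items(), key=sort_key)]
    # strict ordering only where bootstrap intervals do not overlap
    strict = []
    for a, b in zip(ordering[:-1], ordering[1:]):
        ci_a, ci_b = report[a].get("w_ci"), report[b].get("w_ci")
        if ci_a is None or ci_b is None:
            strict.append(report[a]["w"] is None and report[b]["w"] is not None)
        else:
            strict.append(ci_a[1] < ci_b[0])
    return {"genotypes": report, "ordering": ordering, "strictly_ordered": strict}
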