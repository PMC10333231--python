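"""Rare-event flow-cytometry quantification of LOH-positive fractions.

Gating is two-channel: an event is positive when its reporter intensity
exceeds a threshold set on a negative control and its control-channel
intensity stays below a second threshold, which removes autofluorescent
cells that light up in both channels.  Positive fractions near 1e-4 demand
an interval valid at the boundary, so the 95% interval is Wilson's score
interval.  Because the assay only sees LOH events that removed the
reporter-bearing homolog, the background-subtracted fraction is doubled to
estimate total LOH.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "FlowSample",
    "GateSpec",
    "LohFrequencyEstimate",
    "derive_gate",
    "estimate_loh_frequency",
    "limit_of_detection",
    "compare_frequencies",
]


@dataclass
class FlowSample:
    """Event-level two-channel intensity table."""

    events: pd.DataFrame  # columns: reporter_intensity, control_intensity
    label: str = "sample"

    def __post_init__(self) -> None:
        required = {"reporter_intensity", "control_intensity"}
        missing = required - set(self.events.columns)
        if missing:
            raise ValueError(f"flow sample missing columns: {sorted(missing)}")
        if (self.events[list(required)].to_numpy() <= 0).any():
            raise ValueError("flow intensities must be positive")

    @property
    def n_events(self) -> int:
        return len(self.events)


@dataclass(frozen=True)
class GateSpec:
    """Positivity rule: reporter > threshold AND control <= threshold."""

    reporter_threshold: float
    control_threshold: float

    def __post_init__(self) -> None:
        if not (
            np.isfinite(self.reporter_threshold)
            and np.isfinite(self.control_threshold)
            and self.reporter_threshold > 0
            and self.control_threshold > 0
        ):
            raise ValueError("gate thresholds must be finite and positive")

    def apply(self, sample: FlowSample) -> np.ndarray:
        """Boolean mask of gated-positive events."""
        rep = sample.events["reporter_intensity"].to_numpy()
        ctrl = sample.events["control_intensity"].to_numpy()
        return (rep > self.reporter_threshold) & (ctrl <= self.control_threshold)

    def positive_count(self, sample: FlowSample) -> int:
        return int(self.apply(sample).sum())

    def positive_fraction(self, sample: FlowSample) -> float:
        return self.positive_count(sample) / sample.n_events


@dataclass
class LohFrequencyEstimate:
    """Observed and corrected LOH-positive fraction with a 95% Wilson interval.

    ``corrected_total_loh`` is the homolog-corrected total LOH estimate:
    2 x max(observed - background, 0).
    """

    observed_fraction: float
    ci_low: float
    ci_high: float
    background_fraction: float
    corrected_total_loh: float
    n_events: int
    positives: int
    background_clamped: bool = False
    label: str = "sample"

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n_events": self.n_events,
            "positives": self.positives,
            "observed_fraction": self.observed_fraction,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "background_fraction": self.background_fraction,
            "corrected_total_loh": self.corrected_total_loh,
            "background_clamped": self.background_clamped,
        }


def derive_gate(
    negative_control: FlowSample,
    quantile: float = 0.9999,
    control_quantile: float = 0.9999,
) -> GateSpec:
    """Set gate thresholds from a negative control.

    The reporter threshold is the ``quantile`` of the control's reporter
    intensities.  The control-channel threshold is the ``control_quantile``
    of control-channel intensities among reporter-negative events — the
    restriction keeps autofluorescent events (bright in both channels) from
    dragging the threshold above their own cluster, which would defeat the
    exclusion gate.
    """
    if negative_control.n_events < 1000:
        raise ValueError(
            f"negative control has {negative_control.n_events} events; >= 1000 required"
        )
    rep = negative_control.events["reporter_intensity"].to_numpy()
    ctrl = negative_control.events["control_intensity"].to_numpy()
    reporter_threshold = float(np.quantile(rep, quantile))
    reporter_negative = rep <= reporter_threshold
    pool = ctrl[reporter_negative] if reporter_negative.any() else ctrl
    control_threshold = float(np.quantile(pool, control_quantile))
    return GateSpec(reporter_threshold, control_threshold)


def estimate_loh_frequency(
    sample: FlowSample,
    gate: GateSpec,
    background: float = 0.0,
) -> LohFrequencyEstimate:
    """Estimate the LOH-positive fraction of a sample under a gate.

    ``background`` is the gated fraction of a matched negative control; it
    is subtracted (clamped at zero, flagged) before the x2 homolog
    correction.
    """
    if sample.n_events == 0:
        raise ValueError("sample is empty")
    k = gate.positive_count(sample)
    n = sample.n_events
    observed = k / n
    ci_low, ci_high = proportion_confint(k, n, alpha=0.05, method="wilson")
    clamped = background > observed
    corrected = 2.0 * max(observed - background, 0.0)
    return LohFrequencyEstimate(
        observed_fraction=observed,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        background_fraction=background,
        corrected_total_loh=corrected,
        n_events=n,
        positives=k,
        background_clamped=clamped,
        label=sample.label,
    )


def limit_of_detection(negative_controls, gate: GateSpec) -> float:
    """Limit of detection: mean + 3 SD of gated fractions across controls.

    Frequencies at or below the LOD should be reported as not detected.
    """
    controls = list(negative_controls)
    if len(controls) < 2:
        raise ValueError("need at least 2 negative control samples")
    fractions = np.array([gate.positive_fraction(s) for s in controls])
    return float(fractions.mean() + 3.0 * fractions.std(ddof=1))


def compare_frequencies(groups: dict) -> dict:
    """Compare replicate positive fractions between groups.

    Two groups: two-sided Mann-Whitney U with midrank tie handling (no
    continuity correction, so identical groups give p = 1 exactly).  More
    than two: one-way ANOVA.  Fold changes of group means are reported for
    every ordered pair.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    cleaned = {label: np.asarray(vals, dtype=float) for label, vals in groups.items()}
    warnings = [
        f"group {label!r} has {len(v)} < 3 replicates"
        for label, v in cleaned.items()
        if len(v) < 3
    ]
    means = {label: float(v.mean()) for label, v in cleaned.items()}
    fold_changes = {
        f"{a}/{b}": means[a] / means[b]
        for a in means
        for b in means
        if a != b and means[b] > 0
    }
    labels = list(cleaned)
    if len(cleaned) == 2:
        a, b = (cleaned[label] for label in labels)
        stat, p = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        test = "mann-whitney"
    else:
        stat, p = stats.f_oneway(*cleaned.values())
        test = "anova"
        if np.isnan(stat):  # all groups identical and constant
            stat, p = 0.0, 1.0
    return {
        "test": test,
        "statistic": float(stat),
        "p_value": float(p),
        "group_means": means,
        "fold_changes": fold_changes,
        "warnings": warnings,
    }
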