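"""Mosaic copy-number and copy-neutral LOH calling from probe tracks.

The central quantity is the segment mean log2 ratio L of test over
reference hybridization intensity.  For a monoallelic event present in a
fraction f of cells of a diploid sample, the mean copy number is 2 - f
(loss) or 2 + f (gain), so

    loss:  L = log2((2 - f) / 2)   =>   f = 2 (1 - 2**L)
    gain:  L = log2((2 + f) / 2)   =>   f = 2 (2**L - 1)

Inverting L therefore reads the mosaic cell fraction straight off the
array: L = +0.3 -> f = 46%, L = -0.28 -> f = 35%, L = -0.33 -> f = 41%.
A segment with a run of homozygous B-allele frequencies but L ~ 0 is
copy-neutral LOH, invisible to copy number alone.

Clonal-event thresholds follow standard heterozygous-state calling:
deletion below L = -0.5, duplication above L = +0.3; between those and the
mosaic-detection floor the event is called mosaic and quantified by the
inversion above.
"""

from __future__ import annotations

import enum
import math
import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CnvBafTrack",
    "SegmentCall",
    "SegmentState",
    "Rearrangement",
    "CallThresholds",
    "segment_track",
    "mosaic_fraction_from_log2ratio",
    "classify_segment",
    "call_track",
    "decompose_loh",
    "distance_vs_frequency",
    "baf_loh_in_interval",
]

MAX_GAIN_L = math.log2(1.5)  # monoallelic gain in every cell: 3 copies


class SegmentState(str, enum.Enum):
    NORMAL = "NORMAL"
    HET_DELETION = "HET_DELETION"
    DUPLICATION = "DUPLICATION"
    MOSAIC_DELETION = "MOSAIC_DELETION"
    MOSAIC_DUPLICATION = "MOSAIC_DUPLICATION"


class Rearrangement(str, enum.Enum):
    NONE = "NONE"
    CL_LOH = "CL_LOH"
    CN_LOH = "CN_LOH"
    DUPLICATION = "DUPLICATION"


@dataclass
class CnvBafTrack:
    """Per-probe log2 ratio and BAF over one chromosome (positions in Mb)."""

    probes: pd.DataFrame  # columns: position, log2ratio, baf (NaN = uninformative)
    chrom_length: float

    def __post_init__(self) -> None:
        pos = self.probes["position"].to_numpy()
        if not np.all(np.diff(pos) > 0):
            raise ValueError("probe positions must be strictly increasing")
        if not np.all(np.isfinite(self.probes["log2ratio"].to_numpy())):
            raise ValueError("log2ratio values must be finite")

    @property
    def n_probes(self) -> int:
        return len(self.probes)


@dataclass
class SegmentCall:
    """One called segment: coordinates, mean level, state and rearrangement.

    ``mosaic_fraction`` is present only for MOSAIC_* states.  Probe indices
    are half-open; Mb coordinates 1-based-style inclusive of segment probes.
    """

    start_index: int
    end_index: int  # half-open in probe index
    start_mb: float
    end_mb: float
    mean_log2ratio: float
    n_probes: int
    state: SegmentState | None = None
    mosaic_fraction: float | None = None
    mosaic_clamped: bool = False
    baf_loh: bool | None = None
    rearrangement: Rearrangement = Rearrangement.NONE
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "start_mb": self.start_mb,
            "end_mb": self.end_mb,
            "mean_log2ratio": self.mean_log2ratio,
            "n_probes": self.n_probes,
            "state": self.state.value if self.state else None,
            "mosaic_fraction": self.mosaic_fraction,
            "baf_loh": self.baf_loh,
            "rearrangement": self.rearrangement.value,
            "warnings": list(self.warnings),
        }


@dataclass(frozen=True)
class CallThresholds:
    """Segment-classification thresholds (log2-ratio units).

    ``clonal_del`` / ``clonal_dup`` reproduce the standard heterozygous-state
    calling bounds (-0.5 / +0.3); ``mosaic_floor`` is the smallest |L|
    treated as a real copy-number shift rather than baseline wobble — 0.05
    keeps shallow mosaics (e.g. L = -0.08, f ~ 11%) callable.
    ``baf_split`` is the minimum mean |BAF - 0.5| of informative probes that
    flags allelic imbalance; ``baf_min_probes`` the minimum run length.
    """

    clonal_del: float = -0.5
    clonal_dup: float = 0.3
    mosaic_floor: float = 0.05
    baf_split: float = 0.15
    baf_min_probes: int = 20


def _segment_means(track: CnvBafTrack, boundaries: list[int]) -> list[SegmentCall]:
    pos = track.probes["position"].to_numpy()
    lr = track.probes["log2ratio"].to_numpy()
    calls = []
    for i, j in zip(boundaries[:-1], boundaries[1:]):
        calls.append(
            SegmentCall(
                start_index=i,
                end_index=j,
                start_mb=float(pos[i]),
                end_mb=float(pos[j - 1]),
                mean_log2ratio=float(lr[i:j].mean()),
                n_probes=j - i,
            )
        )
    return calls


def segment_track(
    track: CnvBafTrack,
    known_breakpoints=None,
    min_seg_probes: int = 10,
) -> list[SegmentCall]:
    """Partition a track into constant-level segments (means only).

    With ``known_breakpoints`` (Mb positions, e.g. the cut-site), the
    induced partition is returned directly.  Without, a single-changepoint
    two-means scan minimizes residual sum of squares over all admissible
    splits; the split is kept only if it lowers the BIC relative to the flat
    model, so a flat track yields one segment.
    """
    n = track.n_probes
    if n < min_seg_probes:
        raise ValueError(f"track has {n} probes; >= {min_seg_probes} required")
    pos = track.probes["position"].to_numpy()
    lr = track.probes["log2ratio"].to_numpy()

    if known_breakpoints is not None:
        bounds = [0]
        for bp in sorted(known_breakpoints):
            idx = int(np.searchsorted(pos, bp, side="right"))
            if 0 < idx < n and idx != bounds[-1]:
                bounds.append(idx)
        bounds.append(n)
        if len(bounds) - 1 > n // 1:
            raise ValueError("more segments than probes")
        return _segment_means(track, bounds)

    # O(n) scan via cumulative sums
    css = np.cumsum(lr)
    css2 = np.cumsum(lr**2)
    total = css[-1]
    total2 = css2[-1]
    rss_flat = total2 - total**2 / n

    best_k, best_rss = None, np.inf
    for k in range(min_seg_probes, n - min_seg_probes + 1):
        s1, s2 = css[k - 1], total - css[k - 1]
        q1, q2 = css2[k - 1], total2 - css2[k - 1]
        rss = (q1 - s1**2 / k) + (q2 - s2**2 / (n - k))
        if rss < best_rss:
            best_k, best_rss = k, rss

    if best_k is not None:
        rss0 = max(rss_flat, 0.0)
        rss1 = max(best_rss, 0.0)
        eps = 1e-12 * max(1.0, rss0)
        if rss1 < rss0 - eps:
            # one extra mean + one breakpoint = 2 extra parameters
            if rss1 <= eps or n * math.log(rss1 / rss0) + 2.0 * math.log(n) < 0:
                return _segment_means(track, [0, best_k, n])
    return _segment_means(track, [0, n])


def mosaic_fraction_from_log2ratio(L: float, direction: str) -> tuple[float, bool]:
    """Invert a segment mean log2 ratio to a mosaic cell fraction.

    ``direction`` is ``"loss"`` (f = 2(1 - 2**L), valid for -1 <= L < 0) or
    ``"gain"`` (f = 2(2**L - 1), valid for 0 < L <= log2(1.5)), assuming a
    diploid reference and a monoallelic event.  Returns ``(f, clamped)``
    where ``clamped`` flags numerical clipping into [0, 1].  L outside the
    monoallelic range is rejected: it implies multi-copy states whose cell
    fraction is not identifiable from L alone.
    """
    if direction not in ("loss", "gain"):
        raise ValueError("direction must be 'loss' or 'gain'")
    if L == 0:
        return 0.0, False
    if direction == "loss":
        if not (-1.0 <= L < 0.0):
            raise ValueError(
                f"L = {L} outside the monoallelic-loss range [-1, 0); levels below "
                "-1 imply homozygous/multi-copy loss, which the 2 - f model cannot "
                "attribute to a single cell fraction"
            )
        f = 2.0 * (1.0 - 2.0**L)
    else:
        if not (0.0 < L <= MAX_GAIN_L):
            raise ValueError(
                f"L = {L} outside the monoallelic-gain range (0, log2(1.5)]; higher "
                "levels imply >= 2 extra copies, which the 2 + f model cannot "
                "attribute to a single cell fraction"
            )
        f = 2.0 * (2.0**L - 1.0)
    clamped = f < 0.0 or f > 1.0
    return float(min(max(f, 0.0), 1.0)), clamped


def baf_loh_in_interval(
    track: CnvBafTrack,
    start_mb: float,
    end_mb: float,
    thresholds: CallThresholds = CallThresholds(),
) -> bool | None:
    """Allelic-imbalance flag for an interval from its informative BAF probes.

    True when at least ``baf_min_probes`` informative probes lie in the
    interval and their mean |BAF - 0.5| exceeds ``baf_split``; None when the
    interval has no informative probes at all.
    """
    probes = track.probes
    mask = (
        (probes["position"] >= start_mb)
        & (probes["position"] <= end_mb)
        & probes["baf"].notna()
    )
    if mask.sum() == 0:
        return None
    if mask.sum() < thresholds.baf_min_probes:
        return False
    split = float((probes.loc[mask, "baf"] - 0.5).abs().mean())
    return split > thresholds.baf_split


def classify_segment(
    seg: SegmentCall,
    baf_loh: bool | None,
    thresholds: CallThresholds = CallThresholds(),
) -> SegmentCall:
    """Assign state, rearrangement and mosaic fraction to a segment.

    Rules (L = segment mean, floor = mosaic-detection floor):
      |L| < floor, no BAF imbalance          -> NORMAL
      |L| < floor, BAF imbalance             -> NORMAL level, CN_LOH
      -0.5 <= L <= -floor                    -> MOSAIC_DELETION (CL_LOH if BAF imbalance)
      L < -0.5                               -> HET_DELETION (clonal; CL_LOH if BAF imbalance)
      floor <= L <= +0.3                     -> MOSAIC_DUPLICATION
      L > +0.3                               -> DUPLICATION (clonal)
    Without BAF information the call is copy-number-only: rearrangement
    stays NONE and a warning is recorded.
    """
    L = seg.mean_log2ratio
    floor = thresholds.mosaic_floor
    seg.baf_loh = baf_loh
    seg.warnings = list(seg.warnings)
    if baf_loh is None:
        seg.warnings.append("no informative BAF probes: copy-number-only call")
        baf_known = False
        baf_loh = False
    else:
        baf_known = True

    f = None
    clamped = False
    if abs(L) < floor:
        seg.state = SegmentState.NORMAL
        if baf_loh:
            seg.rearrangement = Rearrangement.CN_LOH
    elif L < thresholds.clonal_del:
        seg.state = SegmentState.HET_DELETION
        if baf_loh:
            seg.rearrangement = Rearrangement.CL_LOH
    elif L < 0:
        seg.state = SegmentState.MOSAIC_DELETION
        f, clamped = mosaic_fraction_from_log2ratio(max(L, -1.0), "loss")
        if baf_loh:
            seg.rearrangement = Rearrangement.CL_LOH
    elif L > thresholds.clonal_dup:
        seg.state = SegmentState.DUPLICATION
        seg.rearrangement = Rearrangement.DUPLICATION
    else:
        seg.state = SegmentState.MOSAIC_DUPLICATION
        f, clamped = mosaic_fraction_from_log2ratio(min(L, MAX_GAIN_L), "gain")
        seg.rearrangement = Rearrangement.DUPLICATION
    seg.mosaic_fraction = f
    seg.mosaic_clamped = clamped
    if not baf_known and seg.rearrangement in (Rearrangement.CL_LOH, Rearrangement.CN_LOH):
        seg.rearrangement = Rearrangement.NONE
    return seg


def call_track(
    track: CnvBafTrack,
    known_breakpoints=None,
    thresholds: CallThresholds = CallThresholds(),
    use_baf: bool = True,
) -> list[SegmentCall]:
    """Segment a track and classify every segment (the end-to-end caller)."""
    segments = segment_track(track, known_breakpoints=known_breakpoints)
    for seg in segments:
        baf = (
            baf_loh_in_interval(track, seg.start_mb, seg.end_mb, thresholds)
            if use_baf
            else None
        )
        classify_segment(seg, baf, thresholds)
    return segments


def decompose_loh(total_loh_fraction: float, f_del: float) -> tuple[float, float]:
    """Split a total LOH fraction into copy-loss and copy-neutral parts.

    In a sorted LOH-positive bulk every cell carries LOH (total = 1); the
    deletion mosaic fraction from the array is the copy-loss part and the
    remainder is copy-neutral.
    """
    if not (0.0 <= f_del <= 1.0 and 0.0 <= total_loh_fraction <= 1.0):
        raise ValueError("fractions must be in [0, 1]")
    if f_del > total_loh_fraction:
        raise ValueError(
            f"deletion fraction {f_del} exceeds total LOH fraction "
            f"{total_loh_fraction}: inconsistent inputs"
        )
    return f_del, total_loh_fraction - f_del


def distance_vs_frequency(points) -> dict:
    """Pearson correlation between cut-site distance and LOH frequency.

    ``points`` is a sequence of (distance_mb, loh_frequency).  An R² below
    0.5 is reported as no correlation.  Zero variance in either coordinate
    makes the coefficient undefined; R² is then reported as 0 with a flag.
    """
    pts = np.asarray(list(points), dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {
            "r": float("nan"),
            "r_squared": 0.0,
            "p_value": float("nan"),
            "n": len(pts),
            "correlated": False,
            "degenerate": True,
        }
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        r, p = stats.pearsonr(x, y)
    r2 = float(r**2)
    return {
        "r": float(r),
        "r_squared": r2,
        "p_value": float(p),
        "n": len(pts),
        "correlated": r2 >= 0.5,
        "degenerate": False,
    }
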