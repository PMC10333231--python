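"""Allele-specific qPCR SNP-loss calling and clone-level LOH verdicts.

A heterozygous SNP amplifies with both allele-specific primers, giving two
curves with similar cycle thresholds.  Loss of one allele leaves a single
informative curve, or two curves separated by a large delta-Ct when the
lost allele still amplifies weakly.  The calling rules:

  * curves with Ct >= 37 are excluded (treated as no amplification);
  * both curves excluded -> NO_CALL;
  * exactly one surviving curve -> LOSS;
  * two surviving curves with |delta Ct| > 6 -> LOSS;
  * otherwise -> HETEROZYGOUS.

A clone is called LOH-positive when at least two SNPs telomeric to the
cut-site are lost; one lost SNP alone is not sufficient evidence of a
megabase-scale event.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SnpCall",
    "CloneVerdict",
    "QpcrSnpResult",
    "CloneSnpPanel",
    "CohortComparison",
    "call_snp",
    "call_clone",
    "build_panels",
    "compare_cohorts",
    "call_clone_from_baf",
]

DEFAULT_INCLUSION_CT = 37.0
DEFAULT_DELTA_THRESHOLD = 6.0


class SnpCall(str, enum.Enum):
    HETEROZYGOUS = "HETEROZYGOUS"
    LOSS = "LOSS"
    NO_CALL = "NO_CALL"


class CloneVerdict(str, enum.Enum):
    LOH = "LOH"
    NO_LOH = "NO_LOH"
    UNEVALUABLE = "UNEVALUABLE"


@dataclass
class QpcrSnpResult:
    snp_id: str
    position: float
    ct_allele_a: float | None
    ct_allele_b: float | None
    call: SnpCall


@dataclass
class CloneSnpPanel:
    """Per-clone panel of telomeric SNP results plus the aggregated verdict."""

    clone_id: str
    snps: list[QpcrSnpResult]
    verdict: CloneVerdict = CloneVerdict.UNEVALUABLE

    @property
    def loh_verdict(self) -> bool:
        return self.verdict is CloneVerdict.LOH

    @property
    def n_losses(self) -> int:
        return sum(1 for s in self.snps if s.call is SnpCall.LOSS)

    @property
    def n_informative(self) -> int:
        return sum(1 for s in self.snps if s.call is not SnpCall.NO_CALL)


def _clean_ct(ct) -> float | None:
    """Normalize a raw Ct readout: None/NaN means no curve."""
    if ct is None:
        return None
    ct = float(ct)
    if math.isnan(ct):
        return None
    if ct < 0:
        raise ValueError(f"negative Ct value: {ct}")
    return ct


def call_snp(
    ct_a,
    ct_b,
    inclusion_ct: float = DEFAULT_INCLUSION_CT,
    delta_threshold: float = DEFAULT_DELTA_THRESHOLD,
) -> SnpCall:
    """Call one SNP from its pair of allele-specific Ct values.

    The inclusion filter (Ct < ``inclusion_ct``) is applied first; the
    single-curve and delta-Ct rules then act on the surviving curves.  A
    single surviving curve is a LOSS unconditionally.
    """
    a = _clean_ct(ct_a)
    b = _clean_ct(ct_b)
    a = a if (a is not None and a < inclusion_ct) else None
    b = b if (b is not None and b < inclusion_ct) else None
    if a is None and b is None:
        return SnpCall.NO_CALL
    if a is None or b is None:
        return SnpCall.LOSS
    if abs(a - b) > delta_threshold:
        return SnpCall.LOSS
    return SnpCall.HETEROZYGOUS


def call_clone(panel: CloneSnpPanel, min_losses: int = 2) -> CloneVerdict:
    """Aggregate SNP calls to a clone-level LOH verdict.

    LOH requires >= ``min_losses`` lost SNPs.  NO_CALL SNPs are excluded
    from the denominator; a clone whose informative SNPs cannot reach
    ``min_losses`` is UNEVALUABLE rather than negative.  The verdict is
    stored on the panel and returned.
    """
    if len(panel.snps) < min_losses:
        raise ValueError(
            f"clone {panel.clone_id}: only {len(panel.snps)} SNPs attempted, "
            f"need >= {min_losses}"
        )
    losses = panel.n_losses
    informative = panel.n_informative
    if losses >= min_losses:
        panel.verdict = CloneVerdict.LOH
    elif informative < min_losses:
        panel.verdict = CloneVerdict.UNEVALUABLE
    else:
        panel.verdict = CloneVerdict.NO_LOH
    return panel.verdict


def build_panels(
    curves: pd.DataFrame,
    inclusion_ct: float = DEFAULT_INCLUSION_CT,
    delta_threshold: float = DEFAULT_DELTA_THRESHOLD,
    min_losses: int = 2,
) -> list[CloneSnpPanel]:
    """Call every SNP and clone in a long-format curve table.

    ``curves`` needs columns ``clone_id``, ``snp_id``, ``position``,
    ``ct_a``, ``ct_b`` (NaN = no curve), one row per clone x SNP, as
    produced by the simulator or read from CSV.
    """
    panels = []
    for clone_id, grp in curves.groupby("clone_id", sort=True):
        grp = grp.sort_values("position")
        snps = [
            QpcrSnpResult(
                snp_id=str(row.snp_id),
                position=float(row.position),
                ct_allele_a=None if pd.isna(row.ct_a) else float(row.ct_a),
                ct_allele_b=None if pd.isna(row.ct_b) else float(row.ct_b),
                call=call_snp(row.ct_a, row.ct_b, inclusion_ct, delta_threshold),
            )
            for row in grp.itertuples()
        ]
        panel = CloneSnpPanel(clone_id=str(clone_id), snps=snps)
        call_clone(panel, min_losses=min_losses)
        panels.append(panel)
    return panels


@dataclass
class CohortComparison:
    """2x2 comparison of clone-level LOH rates between two cohorts."""

    loh_a: int
    total_a: int
    loh_b: int
    total_b: int
    rate_a: float
    rate_b: float
    chi_square: float
    p_value: float
    fisher_p: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "group_a": {"loh": self.loh_a, "total": self.total_a, "rate": self.rate_a},
            "group_b": {"loh": self.loh_b, "total": self.total_b, "rate": self.rate_b},
            "chi_square": self.chi_square,
            "p_value": self.p_value,
            "fisher_p": self.fisher_p,
            "degenerate": self.degenerate,
        }


def compare_cohorts(a: tuple[int, int], b: tuple[int, int], correction: bool = False) -> CohortComparison:
    """Compare LOH rates between cohorts given (loh_clones, total_clones).

    Pearson chi-square without continuity correction by default, with
    Fisher's exact p always co-reported because expected counts are small
    at the rare-event rates this assay produces.
    """
    loh_a, total_a = a
    loh_b, total_b = b
    if total_a < 1 or total_b < 1:
        raise ValueError("cohort totals must be >= 1")
    if not (0 <= loh_a <= total_a and 0 <= loh_b <= total_b):
        raise ValueError("LOH counts must lie in [0, total]")
    table = np.array([[loh_a, total_a - loh_a], [loh_b, total_b - loh_b]])
    degenerate = (table.sum(axis=0) == 0).any()
    if degenerate:
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
    _, fisher_p = stats.fisher_exact(table)
    return CohortComparison(
        loh_a=loh_a,
        total_a=total_a,
        loh_b=loh_b,
        total_b=total_b,
        rate_a=loh_a / total_a,
        rate_b=loh_b / total_b,
        chi_square=float(chi2),
        p_value=float(p),
        fisher_p=float(fisher_p),
        degenerate=bool(degenerate),
    )


def call_clone_from_baf(
    track,
    cut_site: float,
    hom_split: float = 0.4,
    min_losses: int = 2,
) -> CloneVerdict:
    """Clone LOH verdict from array BAF at parent-informative markers.

    Markers telomeric to ``cut_site`` (positions greater than the cut-site
    on this telomere-at-the-right chromosome) with non-missing BAF are
    assumed heterozygous in the parent line; a marker is counted lost when
    its BAF indicates homozygosity (|BAF - 0.5| > ``hom_split``).  The same
    >= ``min_losses`` rule as the qPCR path applies.
    """
    probes = track.probes
    telomeric = probes[(probes["position"] > cut_site) & probes["baf"].notna()]
    if len(telomeric) < min_losses:
        return CloneVerdict.UNEVALUABLE
    lost = int(((telomeric["baf"] - 0.5).abs() > hom_split).sum())
    return CloneVerdict.LOH if lost >= min_losses else CloneVerdict.NO_LOH
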