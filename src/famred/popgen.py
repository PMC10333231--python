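"""Synthetic edited-cell populations and their raw readouts.

This module is the ground-truth generator for the whole pipeline.  It
emulates a reporter system in which a megabase-scale loss of heterozygosity
(LOH) telomeric to a CRISPR cut-site flips a cell between fluorescent
states: a population of edited cells is drawn with a known outcome spectrum
(unedited / small InDel only / copy-loss LOH / copy-neutral LOH / CN-LOH
with interstitial duplication), and every downstream assay — two-channel
flow cytometry, aCGH log2-ratio and B-allele-frequency probe tracks,
allele-specific qPCR panels — is simulated from that truth.

Only LOH events that hit the homolog carrying the remaining functional
reporter allele are detectable; with unbiased targeting of the two homologs
this halves the observable fraction, which is why measured fluorescent-cell
percentages are doubled downstream to estimate total LOH.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Outcome",
    "OutcomeProfile",
    "EditedPopulation",
    "FlowChannelModel",
    "CtParams",
    "simulate_population",
    "simulate_flow_sample",
    "simulate_cnv_baf_track",
    "simulate_qpcr_panel",
    "sort_by_tracking",
    "detectable_loh_fraction",
]


class ConfigurationError(ValueError):
    """Raised when simulation parameters are internally inconsistent."""


class Outcome(str, enum.Enum):
    """Per-cell editing outcome at the cut-site."""

    UNEDITED = "UNEDITED"
    INDEL_ONLY = "INDEL_ONLY"
    CL_LOH = "CL_LOH"          # terminal deletion (copy loss)
    CN_LOH = "CN_LOH"          # copy-neutral LOH
    CN_LOH_DUP = "CN_LOH_DUP"  # CN-LOH plus interstitial duplication


LOH_OUTCOMES = (Outcome.CL_LOH, Outcome.CN_LOH, Outcome.CN_LOH_DUP)

_PROB_TOL = 1e-12


@dataclass(frozen=True)
class OutcomeProfile:
    """Outcome spectrum of an editing experiment.

    Parameters
    ----------
    p_unedited, p_indel_only, p_cl_loh, p_cn_loh, p_cn_loh_dup
        Probabilities of the five outcome classes; must sum to 1.
    division_modifier
        Multiplier applied to the LOH-class probabilities per completed
        division during the editing window (then renormalized).  Values > 1
        encode the observation that actively dividing cells acquire LOH more
        often; 1 disables the effect.
    fitness_loh
        Per-generation relative fitness of LOH-bearing cells (w <= 1 means
        rearranged clones are cleared over time).
    """

    p_unedited: float
    p_indel_only: float
    p_cl_loh: float = 0.0
    p_cn_loh: float = 0.0
    p_cn_loh_dup: float = 0.0
    division_modifier: float = 1.0
    fitness_loh: float = 1.0

    def __post_init__(self) -> None:
        probs = self.probabilities()
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"{name} = {p} is not a probability")
        total = sum(probs.values())
        if abs(total - 1.0) > _PROB_TOL:
            raise ConfigurationError(
                f"outcome probabilities sum to {total!r}, expected 1"
            )
        if self.fitness_loh <= 0:
            raise ConfigurationError("fitness_loh must be > 0")
        if self.division_modifier < 0:
            raise ConfigurationError("division_modifier must be >= 0")

    def probabilities(self) -> dict[str, float]:
        return {
            "p_unedited": self.p_unedited,
            "p_indel_only": self.p_indel_only,
            "p_cl_loh": self.p_cl_loh,
            "p_cn_loh": self.p_cn_loh,
            "p_cn_loh_dup": self.p_cn_loh_dup,
        }

    @property
    def p_loh_total(self) -> float:
        return self.p_cl_loh + self.p_cn_loh + self.p_cn_loh_dup

    @classmethod
    def from_loh_total(
        cls,
        p_loh_total: float,
        p_indel_only: float = 0.6,
        cl_share: float = 0.36,
        dup_share: float = 0.46,
        **kwargs,
    ) -> "OutcomeProfile":
        """Build a profile from a total LOH probability.

        ``cl_share`` is the fraction of LOH events that are copy-loss;
        ``dup_share`` the fraction of the copy-neutral remainder that also
        carries the interstitial duplication.  Defaults mirror the observed
        bulk composition of LOH-sorted cells (36% terminal deletion, 46%
        duplication).
        """
        p_cl = p_loh_total * cl_share
        p_cn_all = p_loh_total - p_cl
        p_dup = p_cn_all * dup_share
        return cls(
            p_unedited=1.0 - p_indel_only - p_loh_total,
            p_indel_only=p_indel_only,
            p_cl_loh=p_cl,
            p_cn_loh=p_cn_all - p_dup,
            p_cn_loh_dup=p_dup,
            **kwargs,
        )


@dataclass
class EditedPopulation:
    """Ground truth of a simulated editing experiment.

    ``cells`` is a table with one row per cell and columns ``cell_id``,
    ``outcome``, ``reporter_functional``, ``divisions``,
    ``tracking_intensity``.
    """

    cells: pd.DataFrame
    profile: OutcomeProfile
    seed: int
    homolog_targeting: float = 0.5

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def outcome_fractions(self) -> dict[str, float]:
        counts = self.cells["outcome"].value_counts()
        n = len(self.cells)
        return {o.value: counts.get(o.value, 0) / n for o in Outcome}

    def detectable_loh_fraction(self) -> float:
        """Fraction of cells whose LOH is visible to the reporter."""
        return float((~self.cells["reporter_functional"]).mean())

    def subset(self, index: np.ndarray) -> "EditedPopulation":
        return replace(self, cells=self.cells.loc[index].reset_index(drop=True))


def detectable_loh_fraction(profile: OutcomeProfile, homolog_targeting: float = 0.5) -> float:
    """Expected detectable-LOH fraction: homolog_targeting x total LOH probability.

    Only LOH events hitting the reporter-bearing homolog switch the cell's
    phenotype, hence the later x2 correction of observed percentages.
    """
    return homolog_targeting * profile.p_loh_total


def simulate_population(
    profile: OutcomeProfile,
    n: int,
    seed: int,
    homolog_targeting: float = 0.5,
    mean_divisions: float = 2.0,
    initial_intensity: float = 1e4,
    intensity_cv: float = 0.0,
) -> EditedPopulation:
    """Draw a population of ``n`` edited cells with known ground truth.

    Divisions completed during the editing window are Poisson with mean
    ``mean_divisions``; LOH-class probabilities are scaled by
    ``division_modifier ** divisions`` and renormalized, tying LOH risk to
    proliferative activity.  The cell-tracking dye intensity starts at
    ``initial_intensity`` and halves per division (times log-normal noise of
    coefficient of variation ``intensity_cv``).
    """
    if n < 1:
        raise ConfigurationError("population size must be >= 1")
    if not (0.0 <= homolog_targeting <= 1.0):
        raise ConfigurationError("homolog_targeting must be in [0, 1]")
    rng = np.random.default_rng(seed)

    divisions = rng.poisson(mean_divisions, size=n)
    base = np.array(
        [profile.p_unedited, profile.p_indel_only,
         profile.p_cl_loh, profile.p_cn_loh, profile.p_cn_loh_dup]
    )
    outcome_idx = np.empty(n, dtype=np.int64)
    u = rng.random(n)
    if profile.division_modifier == 1.0:
        cum = np.cumsum(base)
        outcome_idx = np.searchsorted(cum, u, side="right")
    else:
        # per-cell probabilities depend only on the division count, so draw
        # group-wise over the (small) Poisson support
        for d in np.unique(divisions):
            w = base.copy()
            w[2:] *= profile.division_modifier ** int(d)
            w /= w.sum()
            mask = divisions == d
            cum = np.cumsum(w)
            outcome_idx[mask] = np.searchsorted(cum, u[mask], side="right")
    outcome_idx = np.clip(outcome_idx, 0, 4)
    outcome_values = np.array([o.value for o in Outcome])
    outcomes = outcome_values[outcome_idx]

    is_loh = outcome_idx >= 2
    hits_reporter = rng.random(n) < homolog_targeting
    reporter_functional = ~(is_loh & hits_reporter)

    intensity = initial_intensity / np.exp2(divisions).astype(float)
    if intensity_cv > 0:
        sigma = math.sqrt(math.log1p(intensity_cv**2))
        intensity = intensity * rng.lognormal(-0.5 * sigma**2, sigma, size=n)

    cells = pd.DataFrame(
        {
            "cell_id": np.arange(n, dtype=np.int64),
            "outcome": outcomes,
            "reporter_functional": reporter_functional,
            "divisions": divisions,
            "tracking_intensity": intensity,
        }
    )
    return EditedPopulation(
        cells=cells, profile=profile, seed=seed, homolog_targeting=homolog_targeting
    )


# ---------------------------------------------------------------------------
# flow cytometry


@dataclass(frozen=True)
class FlowChannelModel:
    """Two-channel intensity model (log10 scale).

    The reporter channel separates switched (LOH-detectable) from
    non-switched cells; a second control channel is bright only for
    autofluorescent cells, which light up in both channels and must be
    excluded by the gate.  ``background_switch_rate`` is the assay noise
    floor: the probability that a truly non-LOH cell reads above the
    negative cluster (defaults to the 0.02% seen in untransfected /
    irrelevant-locus controls; a murine-reporter assay would use ~0.5%).
    Those noise events form an intermediate cluster (``mu_bg``,
    ``sigma_bg``) straddling the gate boundary rather than reaching the
    fully switched cluster.
    """

    mu_neg: float = 2.0
    sigma_neg: float = 0.3
    mu_pos: float = 4.5
    sigma_pos: float = 0.35
    mu_bg: float = 3.5
    sigma_bg: float = 0.5
    autofluorescence_rate: float = 0.0
    background_switch_rate: float = 0.0002

    def __post_init__(self) -> None:
        if self.mu_pos <= self.mu_neg:
            raise ConfigurationError("mu_pos must exceed mu_neg")
        for name in ("autofluorescence_rate", "background_switch_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1]")


def simulate_flow_sample(
    pop: EditedPopulation,
    model: FlowChannelModel,
    seed: int,
    label: str = "sample",
    post_clearance: bool = True,
):
    """Simulate one flow-cytometry event per cell.

    Switched cells (reporter not functional, assayed after the phenotype
    clearance delay) draw reporter intensity from the positive distribution;
    autofluorescent cells are bright in both channels; everything else is
    negative.  Returns a :class:`famred.flow.FlowSample`.
    """
    from .flow import FlowSample  # local import to avoid a cycle

    n = len(pop)
    if n == 0:
        raise ConfigurationError("population is empty")
    rng = np.random.default_rng(seed)

    switched = (~pop.cells["reporter_functional"].to_numpy()) & post_clearance
    background = (rng.random(n) < model.background_switch_rate) & ~switched
    autofl = rng.random(n) < model.autofluorescence_rate

    rep = rng.normal(model.mu_neg, model.sigma_neg, size=n)
    rep = np.where(background, rng.normal(model.mu_bg, model.sigma_bg, size=n), rep)
    rep = np.where(
        switched | autofl, rng.normal(model.mu_pos, model.sigma_pos, size=n), rep
    )
    ctrl = np.where(
        autofl,
        rng.normal(model.mu_pos, model.sigma_pos, size=n),
        rng.normal(model.mu_neg, model.sigma_neg, size=n),
    )
    events = pd.DataFrame(
        {
            "reporter_intensity": np.power(10.0, rep),
            "control_intensity": np.power(10.0, ctrl),
        }
    )
    return FlowSample(events=events, label=label)


# ---------------------------------------------------------------------------
# aCGH / BAF probe tracks

CHROM_LENGTH_MB = 135.0  # single synthetic chromosome, hChr10-like


def simulate_cnv_baf_track(
    f_del: float = 0.0,
    f_dup: float = 0.0,
    del_interval: tuple[float, float] | None = None,
    dup_interval: tuple[float, float] | None = None,
    probes: int = 500,
    noise_sd: float = 0.1,
    seed: int = 0,
    chrom_length: float = CHROM_LENGTH_MB,
    f_loh: float | None = None,
    loh_interval: tuple[float, float] | None = None,
    baf_sd: float = 0.03,
    het_probe_rate: float = 0.3,
    chrom: str = "chr10",
):
    """Simulate a per-probe log2-ratio + BAF track for a mosaic sample.

    A fraction ``f_del`` of cells carries a monoallelic deletion over
    ``del_interval`` and ``f_dup`` a monoallelic duplication over
    ``dup_interval`` (mean copy number ``2 - f_del`` / ``2 + f_dup``, i.e.
    log2 ratios ``log2((2 - f_del)/2)`` and ``log2((2 + f_dup)/2)``), plus
    i.i.d. Gaussian probe noise.  A fraction ``f_loh`` of cells is
    homozygous over ``loh_interval`` (defaults to the deletion interval /
    fraction): heterozygous probes there have their BAF shifted from 0.5 by
    ``f_loh / 2`` toward 0 or 1, mirrored at random per probe.
    Probes are evenly spaced over a single chromosome of ``chrom_length`` Mb.
    """
    from .cgh import CnvBafTrack  # local import to avoid a cycle

    if not (0.0 <= f_del <= 1.0 and 0.0 <= f_dup <= 1.0):
        raise ConfigurationError("f_del and f_dup must be in [0, 1]")
    if f_del > 0 and del_interval is None:
        raise ConfigurationError("f_del > 0 requires del_interval")
    if f_dup > 0 and dup_interval is None:
        raise ConfigurationError("f_dup > 0 requires dup_interval")
    for name, iv in (("del_interval", del_interval), ("dup_interval", dup_interval)):
        if iv is not None:
            lo, hi = iv
            if not (0.0 <= lo < hi <= chrom_length):
                raise ConfigurationError(f"{name} {iv} outside chromosome [0, {chrom_length}]")
    if del_interval is not None and dup_interval is not None:
        lo = max(del_interval[0], dup_interval[0])
        hi = min(del_interval[1], dup_interval[1])
        if lo < hi:
            raise ConfigurationError(
                "del_interval and dup_interval overlap; the duplication must be "
                "strictly centromeric to the terminal deletion"
            )
    if probes < 10:
        raise ConfigurationError("need at least 10 probes")

    rng = np.random.default_rng(seed)
    positions = np.linspace(chrom_length / probes, chrom_length, probes)

    log2ratio = np.zeros(probes)
    if del_interval is not None and f_del > 0:
        mask = (positions >= del_interval[0]) & (positions <= del_interval[1])
        log2ratio[mask] = math.log2((2.0 - f_del) / 2.0)
    if dup_interval is not None and f_dup > 0:
        mask = (positions >= dup_interval[0]) & (positions <= dup_interval[1])
        log2ratio[mask] = math.log2((2.0 + f_dup) / 2.0)
    if noise_sd > 0:
        log2ratio = log2ratio + rng.normal(0.0, noise_sd, size=probes)

    if f_loh is None:
        f_loh = f_del
    if loh_interval is None:
        loh_interval = del_interval

    baf = np.full(probes, np.nan)
    het = rng.random(probes) < het_probe_rate
    baf[het] = 0.5
    if loh_interval is not None and f_loh > 0:
        in_loh = het & (positions >= loh_interval[0]) & (positions <= loh_interval[1])
        sign = rng.choice([-1.0, 1.0], size=probes)
        baf[in_loh] = 0.5 + sign[in_loh] * (f_loh / 2.0)
    if baf_sd > 0:
        noisy = ~np.isnan(baf)
        baf[noisy] = np.clip(baf[noisy] + rng.normal(0.0, baf_sd, noisy.sum()), 0.0, 1.0)

    df = pd.DataFrame(
        {"chrom": chrom, "position": positions, "log2ratio": log2ratio, "baf": baf}
    )
    return CnvBafTrack(probes=df, chrom_length=chrom_length)


# ---------------------------------------------------------------------------
# allele-specific qPCR


@dataclass(frozen=True)
class CtParams:
    """Amplification parameters for simulated allele-specific qPCR.

    A retained heterozygous SNP yields two curves with a small Ct
    difference; a lost SNP yields either a single informative curve (the
    other allele drops out or crosses threshold past the inclusion cutoff)
    or two curves separated by a large delta-Ct.
    """

    mean_ct: float = 25.0
    between_clone_sd: float = 1.0
    het_delta_sd: float = 0.5
    loss_delta_low: float = 6.5
    loss_delta_high: float = 14.0
    dropout_rate: float = 0.5     # lost allele gives no curve at all
    failed_ct: float = 40.0       # "no amplification" placeholder, > inclusion cutoff


def simulate_qpcr_panel(
    clone_truths,
    ct_params: CtParams = CtParams(),
    seed: int = 0,
    snp_positions=None,
) -> pd.DataFrame:
    """Simulate paired allele-specific qPCR Ct values.

    ``clone_truths`` is a sequence (one entry per clone) of per-SNP loss
    booleans.  Returns a long-format table with columns ``clone_id``,
    ``snp_id``, ``position``, ``ct_a``, ``ct_b`` (NaN = no curve) and the
    ground-truth column ``lost``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for ci, truths in enumerate(clone_truths):
        truths = list(truths)
        if len(truths) < 1:
            raise ConfigurationError("each clone needs at least one SNP")
        if snp_positions is None:
            positions = [float(i + 1) for i in range(len(truths))]
        else:
            positions = list(snp_positions)
        base = rng.normal(ct_params.mean_ct, ct_params.between_clone_sd)
        for si, lost in enumerate(truths):
            ct_a = base + rng.normal(0.0, 0.3)
            if not lost:
                ct_b = ct_a + rng.normal(0.0, ct_params.het_delta_sd)
            elif rng.random() < ct_params.dropout_rate:
                ct_b = np.nan
            else:
                ct_b = ct_a + rng.uniform(
                    ct_params.loss_delta_low, ct_params.loss_delta_high
                )
            rows.append(
                {
                    "clone_id": f"clone_{ci:04d}",
                    "snp_id": f"snp_{si}",
                    "position": positions[si],
                    "ct_a": ct_a,
                    "ct_b": ct_b,
                    "lost": bool(lost),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cell-tracking sort


def sort_by_tracking(pop: EditedPopulation, decile: float = 0.1):
    """Split a population into tracking-high and tracking-low fractions.

    The dye halves per division, so the top fraction by intensity holds the
    least-divided cells and the bottom fraction the most-divided.  Ties are
    broken by ``cell_id`` for determinism.  Returns
    ``(high_fraction, low_fraction)``.
    """
    if not (0.0 < decile <= 0.5):
        raise ConfigurationError("decile must be in (0, 0.5]")
    n = len(pop)
    k = int(n * decile)
    if k < 1:
        raise ConfigurationError(
            f"population of {n} cells is too small for a {decile:.0%} fraction"
        )
    cells = pop.cells
    order = np.lexsort(
        (cells["cell_id"].to_numpy(), -cells["tracking_intensity"].to_numpy())
    )
    high = pop.subset(cells.index[order[:k]])
    low = pop.subset(cells.index[order[n - k:]])
    return high, low
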