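"""File formats, run configuration and end-to-end scenario orchestration.

All tables are plain text: flow events as CSV, probe tracks as TSV, called
segments in SEG-like format, qPCR curves as long-format CSV, kinetics as
tidy CSV, results as JSON, configuration as YAML or JSON.  Readers validate
schemas strictly and name the offending line on failure; every write/read
pair round-trips losslessly to float precision.

A :class:`RunConfig` makes the whole pipeline a pure function of one
document: every stochastic step derives its seed from the master seed and
its operation name, so two runs of the same config produce byte-identical
results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cgh, flow, kinetics, popgen, snp
from ._seeds import derive_seed

logger = logging.getLogger("famred")

__all__ = [
    "FormatError",
    "RunConfig",
    "read_events_csv",
    "write_events_csv",
    "read_track_tsv",
    "write_track_tsv",
    "write_seg",
    "read_qpcr_csv",
    "write_qpcr_csv",
    "read_timecourse_csv",
    "write_timecourse_csv",
    "write_results_json",
    "run_scenario",
    "scenario_wt_abraxas2",
]


class FormatError(ValueError):
    """Malformed input file; the message names the file and line."""


# ---------------------------------------------------------------------------
# table adapters


def _read_table(path, sep, columns, numeric, allow_na=()):
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in columns]
    if extra:
        logger.warning("%s: ignoring unknown columns %s", path, extra)
    for col in numeric:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna() if col in allow_na else parsed.isna()
        if bad.any():
            # +2: header line plus 1-based indexing
            line = int(bad.idxmax()) + 2
            raise FormatError(
                f"{path}: line {line}: invalid value {df[col].iloc[bad.idxmax()]!r} "
                f"in column {col!r}"
            )
        df[col] = parsed
    return df[list(columns)]


def read_events_csv(path, label=None) -> flow.FlowSample:
    df = _read_table(
        path, ",", ["reporter_intensity", "control_intensity"],
        ["reporter_intensity", "control_intensity"],
    )
    return flow.FlowSample(events=df, label=label or Path(path).stem)


def write_events_csv(sample: flow.FlowSample, path) -> None:
    sample.events.to_csv(path, index=False, float_format="%.17g")


def read_track_tsv(path, chrom_length=None) -> cgh.CnvBafTrack:
    df = _read_table(
        path, "\t", ["chrom", "position", "log2ratio", "baf"],
        ["position", "log2ratio", "baf"], allow_na=("baf",),
    )
    length = chrom_length if chrom_length is not None else float(df["position"].max())
    return cgh.CnvBafTrack(probes=df, chrom_length=length)


def write_track_tsv(track: cgh.CnvBafTrack, path) -> None:
    df = track.probes.copy()
    if "chrom" not in df.columns:
        df.insert(0, "chrom", "chr10")
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_seg(segments, path, sample: str = "sample", chrom: str = "chr10") -> None:
    """Write segment calls in SEG-like format (one row per segment)."""
    rows = [
        {
            "sample": sample,
            "chrom": chrom,
            "start": seg.start_mb,
            "end": seg.end_mb,
            "n_probes": seg.n_probes,
            "seg_mean": seg.mean_log2ratio,
        }
        for seg in segments
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_qpcr_csv(path) -> pd.DataFrame:
    """Read a long-format allele-specific qPCR table.

    Accepts either paired columns (clone_id, snp_id, position, ct_a, ct_b)
    or fully long rows (clone_id, snp_id, position, allele, ct) which are
    pivoted to pairs; empty ct = no curve.
    """
    path = Path(path)
    head = pd.read_csv(path, nrows=0)
    if "allele" in head.columns:
        df = _read_table(
            path, ",", ["clone_id", "snp_id", "position", "allele", "ct"],
            ["position", "ct"], allow_na=("ct",),
        )
        alleles = set(df["allele"].unique())
        if not alleles <= {"A", "B"}:
            raise FormatError(f"{path}: allele column must be 'A' or 'B', got {alleles}")
        wide = df.pivot(
            index=["clone_id", "snp_id", "position"], columns="allele", values="ct"
        ).reset_index()
        wide = wide.rename(columns={"A": "ct_a", "B": "ct_b"})
        for col in ("ct_a", "ct_b"):
            if col not in wide.columns:
                wide[col] = np.nan
        return wide[["clone_id", "snp_id", "position", "ct_a", "ct_b"]]
    return _read_table(
        path, ",", ["clone_id", "snp_id", "position", "ct_a", "ct_b"],
        ["position", "ct_a", "ct_b"], allow_na=("ct_a", "ct_b"),
    )


def write_qpcr_csv(curves: pd.DataFrame, path) -> None:
    cols = [c for c in ["clone_id", "snp_id", "position", "ct_a", "ct_b"] if c in curves]
    curves[cols].to_csv(path, index=False, float_format="%.17g")


def read_timecourse_csv(path) -> dict[str, kinetics.LohTimecourse]:
    """Read a tidy (day, genotype, fraction[, n_events, background]) table."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"day", "genotype", "fraction"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    out = {}
    for genotype, grp in df.groupby("genotype", sort=True):
        grp = grp.sort_values("day")
        n_events = float(grp["n_events"].iloc[0]) if "n_events" in grp else float("nan")
        background = float(grp["background"].iloc[0]) if "background" in grp else 0.0
        out[str(genotype)] = kinetics.LohTimecourse(
            days=grp["day"].to_numpy(float),
            loh_fraction=grp["fraction"].to_numpy(float),
            genotype_label=str(genotype),
            background=0.0 if np.isnan(background) else background,
            n_events=None if np.isnan(n_events) else n_events,
        )
    return out


def write_timecourse_csv(series_by_genotype: dict, path) -> None:
    rows = []
    for label, series in series_by_genotype.items():
        for day, frac in zip(series.days, series.loh_fraction):
            rows.append(
                {
                    "day": day,
                    "genotype": label,
                    "fraction": frac,
                    "n_events": series.n_events,
                    "background": series.background,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def _json_default(obj):
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_results_json(results: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


# ---------------------------------------------------------------------------
# configuration


def _asdict_no_none(obj) -> dict:
    return {k: v for k, v in dataclasses.asdict(obj).items()}


@dataclass
class RunConfig:
    """Complete, serializable description of one end-to-end run.

    Fractions everywhere (never percent); percent formatting happens only
    in the human-readable summary.
    """

    scenario: str = "scenario"
    master_seed: int = 0
    # population / flow
    p_loh_total: float = 0.0018
    p_indel_only: float = 0.6
    cl_share: float = 0.36
    dup_share: float = 0.46
    division_modifier: float = 1.0
    fitness_loh: float = 1.0
    homolog_targeting: float = 0.5
    mean_divisions: float = 2.0
    n_events: int = 1_000_000
    n_controls: int = 3
    gate_quantile: float = 0.9999
    flow_model: dict = field(default_factory=dict)
    # probe track
    track: dict = field(
        default_factory=lambda: {
            "f_del": 0.36,
            "f_dup": 0.46,
            "del_interval": [126.5, 135.0],
            "dup_interval": [54.5, 126.4],
            "f_loh": 1.0,
            "loh_interval": [126.5, 135.0],
            "probes": 2000,
            "noise_sd": 0.1,
        }
    )
    cut_site_mb: float = 126.5
    # qPCR cohorts
    qpcr: dict = field(
        default_factory=lambda: {
            "n_clones_high": 500,
            "n_clones_low": 82,
            "rate_high": 0.006,
            "rate_low": 0.061,
            "n_snps": 3,
        }
    )
    # kinetics
    kinetics: dict = field(
        default_factory=lambda: {
            "genotypes": {"WT": 0.4, "p21": 0.7, "p53": 1.0},
            "f0": 0.0385,
            "generation_time": 1.0,
            "days": [3, 7, 10, 14],
            "background": 0.005,
            "n_events": 100000,
        }
    )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise FormatError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def profile(self) -> popgen.OutcomeProfile:
        return popgen.OutcomeProfile.from_loh_total(
            self.p_loh_total,
            p_indel_only=self.p_indel_only,
            cl_share=self.cl_share,
            dup_share=self.dup_share,
            division_modifier=self.division_modifier,
            fitness_loh=self.fitness_loh,
        )

    def channel_model(self) -> popgen.FlowChannelModel:
        return popgen.FlowChannelModel(**self.flow_model)


def scenario_wt_abraxas2(master_seed: int = 0) -> RunConfig:
    """Bundled scenario: p53-proficient cells, cut 1 Mb from the reporter.

    True detectable LOH is 0.09% (total LOH 0.18% with unbiased homolog
    targeting), one million events, the regime in which LOH-sorted bulks
    show the 46%-duplication / 36%-terminal-deletion mosaic pair.
    """
    return RunConfig(scenario="wt_abraxas2", master_seed=master_seed)


# ---------------------------------------------------------------------------
# orchestration


def run_scenario(config: RunConfig, out_dir) -> dict:
    """Run simulate -> quantify -> characterize -> report end to end.

    Writes ground truth, intermediate tables, ``results.json`` and a
    human-readable ``summary.txt`` into ``out_dir``.  Outputs are staged in
    a temporary sibling directory and moved into place atomically on
    success, so a failed run leaves no partial output.  Returns the results
    dictionary.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()):
        raise FileExistsError(f"output directory {out_dir} exists and is not empty")
    out_dir.parent.mkdir(parents=True, exist_ok=True)
    staging = Path(tempfile.mkdtemp(prefix=".famred-", dir=out_dir.parent))
    try:
        results = _run_into(config, staging)
        if out_dir.exists():
            out_dir.rmdir()
        os.replace(staging, out_dir)
    except Exception:
        shutil.rmtree(staging, ignore_errors=True)
        raise
    return results


def _seed(config: RunConfig, name: str) -> int:
    s = derive_seed(config.master_seed, name)
    logger.debug("derived seed %d for operation %r", s, name)
    return s


def _run_into(config: RunConfig, out: Path) -> dict:
    model = config.channel_model()
    profile = config.profile()

    # --- simulate population and flow readout
    pop = popgen.simulate_population(
        profile,
        config.n_events,
        seed=_seed(config, "population"),
        homolog_targeting=config.homolog_targeting,
        mean_divisions=config.mean_divisions,
    )
    pop.cells.to_csv(out / "population_truth.csv", index=False, float_format="%.17g")
    sample = popgen.simulate_flow_sample(
        pop, model, seed=_seed(config, "flow_sample"), label=config.scenario
    )
    write_events_csv(sample, out / "flow_events.csv")

    unedited = popgen.OutcomeProfile(
        p_unedited=1.0, p_indel_only=0.0,
        division_modifier=profile.division_modifier, fitness_loh=profile.fitness_loh,
    )
    controls = []
    for i in range(max(config.n_controls, 2)):
        ctrl_pop = popgen.simulate_population(
            unedited, config.n_events, seed=_seed(config, f"control_population_{i}")
        )
        controls.append(
            popgen.simulate_flow_sample(
                ctrl_pop, model, seed=_seed(config, f"control_flow_{i}"), label=f"NT_{i}"
            )
        )
    gate = flow.derive_gate(controls[0], quantile=config.gate_quantile)
    background = gate.positive_fraction(controls[1])
    estimate = flow.estimate_loh_frequency(sample, gate, background=background)
    lod = flow.limit_of_detection(controls[1:], gate)
    detected = estimate.observed_fraction > lod

    # --- probe track, segmentation, mosaic inversion
    tr = dict(config.track)
    for key in ("del_interval", "dup_interval", "loh_interval"):
        if tr.get(key) is not None:
            tr[key] = tuple(tr[key])
    track = popgen.simulate_cnv_baf_track(seed=_seed(config, "cnv_track"), **tr)
    write_track_tsv(track, out / "probe_track.tsv")
    breakpoints = sorted(
        {
            b
            for key in ("del_interval", "dup_interval")
            if tr.get(key) is not None
            for b in tr[key]
            if 0 < b < track.chrom_length
        }
    )
    segments = cgh.call_track(track, known_breakpoints=breakpoints or None)
    write_seg(segments, out / "segments.seg", sample=config.scenario)
    del_segs = [
        s for s in segments
        if s.state in (cgh.SegmentState.MOSAIC_DELETION, cgh.SegmentState.HET_DELETION)
    ]
    f_del = del_segs[0].mosaic_fraction if del_segs and del_segs[0].mosaic_fraction else (
        1.0 if del_segs else 0.0
    )
    cl_fraction, cn_fraction = cgh.decompose_loh(1.0, min(f_del, 1.0))

    # --- qPCR cohort comparison
    q = config.qpcr
    rng = np.random.default_rng(_seed(config, "qpcr_truth"))
    truths_high = rng.random(q["n_clones_high"]) < q["rate_high"]
    truths_low = rng.random(q["n_clones_low"]) < q["rate_low"]
    cohorts = {}
    for name, truths in (("tracking_high", truths_high), ("tracking_low", truths_low)):
        curves = popgen.simulate_qpcr_panel(
            [[bool(t)] * q["n_snps"] for t in truths],
            seed=_seed(config, f"qpcr_{name}"),
        )
        write_qpcr_csv(curves, out / f"qpcr_{name}.csv")
        panels = snp.build_panels(curves)
        cohorts[name] = (
            sum(p.verdict is snp.CloneVerdict.LOH for p in panels),
            sum(p.verdict is not snp.CloneVerdict.UNEVALUABLE for p in panels),
        )
    comparison = snp.compare_cohorts(cohorts["tracking_high"], cohorts["tracking_low"])

    # --- kinetics
    k = config.kinetics
    series_by_genotype = {}
    fits = {}
    rng_k = np.random.default_rng(_seed(config, "kinetics_noise"))
    for label, w in k["genotypes"].items():
        clean = kinetics.project_timecourse(
            k["f0"], w, k["generation_time"], k["days"],
            background=k["background"], genotype_label=label,
        )
        n = int(k["n_events"])
        noisy = kinetics.LohTimecourse(
            days=clean.days,
            loh_fraction=rng_k.binomial(n, clean.loh_fraction) / n,
            genotype_label=label,
            background=k["background"],
            n_events=n,
        )
        series_by_genotype[label] = noisy
        fits[label] = kinetics.fit_clearance(noisy, k["generation_time"])
    write_timecourse_csv(series_by_genotype, out / "timecourse.csv")
    genotype_report = kinetics.compare_genotypes(
        fits, seed=_seed(config, "kinetics_bootstrap")
    )

    true_detectable = pop.detectable_loh_fraction()
    results = {
        "scenario": config.scenario,
        "master_seed": config.master_seed,
        "flow": {
            **estimate.to_dict(),
            "limit_of_detection": lod,
            "detected": bool(detected),
            "true_detectable_fraction": true_detectable,
            "true_total_loh_fraction": float(
                pop.cells["outcome"].isin([o.value for o in popgen.LOH_OUTCOMES]).mean()
            ),
        },
        "cgh": {
            "segments": [s.to_dict() for s in segments],
            "f_del": f_del,
            "cl_fraction": cl_fraction,
            "cn_fraction": cn_fraction,
        },
        "snp": {
            **comparison.to_dict(),
            "true_rate_high": q["rate_high"],
            "true_rate_low": q["rate_low"],
        },
        "kinetics": genotype_report,
    }
    write_results_json(results, out / "results.json")
    (out / "summary.txt").write_text(_summary_text(results))
    return results


def _summary_text(results: dict) -> str:
    fl = results["flow"]
    lines = [
        f"scenario: {results['scenario']} (seed {results['master_seed']})",
        "",
        "flow quantification",
        f"  observed fluorescent fraction: {fl['observed_fraction']:.4%}"
        f"  (95% CI {fl['ci_low']:.4%} - {fl['ci_high']:.4%})",
        f"  background: {fl['background_fraction']:.4%};"
        f"  LOD: {fl['limit_of_detection']:.4%};"
        f"  detected: {fl['detected']}",
        f"  corrected total LOH (x2, background-subtracted): {fl['corrected_total_loh']:.4%}",
        f"  simulation truth (detectable): {fl['true_detectable_fraction']:.4%}",
        "",
        "aCGH characterization of the LOH-sorted bulk",
    ]
    for seg in results["cgh"]["segments"]:
        f = seg["mosaic_fraction"]
        lines.append(
            f"  {seg['start_mb']:.1f}-{seg['end_mb']:.1f} Mb: L = {seg['mean_log2ratio']:+.3f}"
            f"  state = {seg['state']}"
            + (f"  mosaic fraction = {f:.1%}" if f is not None else "")
            + f"  rearrangement = {seg['rearrangement']}"
        )
    lines += [
        f"  LOH decomposition: copy-loss {results['cgh']['cl_fraction']:.1%},"
        f" copy-neutral {results['cgh']['cn_fraction']:.1%}",
        "",
        "clone cohorts (allele-specific qPCR)",
        f"  tracking-high: {results['snp']['group_a']['loh']}/{results['snp']['group_a']['total']}"
        f" = {results['snp']['group_a']['rate']:.2%}",
        f"  tracking-low:  {results['snp']['group_b']['loh']}/{results['snp']['group_b']['total']}"
        f" = {results['snp']['group_b']['rate']:.2%}",
        f"  chi-square = {results['snp']['chi_square']:.3f}"
        f"  p = {results['snp']['p_value']:.2e}  Fisher p = {results['snp']['fisher_p']:.2e}",
        "",
        "clearance kinetics (relative fitness w per genotype)",
    ]
    for label in results["kinetics"]["ordering"]:
        entry = results["kinetics"]["genotypes"][label]
        if entry["w"] is None:
            lines.append(f"  {label}: cleared (too few points above background)")
        else:
            ci = entry.get("w_ci")
            ci_text = f" (95% CI {ci[0]:.2f}-{ci[1]:.2f})" if ci else ""
            tag = "persistent" if entry["persistent"] else "clearing"
            lines.append(f"  {label}: w = {entry['w']:.3f}{ci_text}  -> {tag}")
    return "\n".join(lines) + "\n"
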