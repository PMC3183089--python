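"""End-to-end study orchestration.

Runs the full analysis in the order the study design dictates —
simulate (optional) → sample QC → probe filter → quantile normalization
→ MVP discovery (+ excess-count permutation, neighbor analysis) →
control-pair variance enrichment → independent replication → temporal
enrichment (pre, post, pre-vs-post paired, antibody-positive) — and
writes a machine-readable JSON summary plus a human-readable report.
Each stage's randomness comes from a named sub-stream of the single
top-level seed, so adding or re-running a stage never perturbs another
stage's draws, and every stage is a pure function of (inputs,
parameters, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .discovery import call_mvps, excess_count_permutation, neighbor_analysis, paired_differences
from .enrichment import bootstrap_enrichment, paired_pre_post
from .io_formats import (
    read_beta_matrix,
    read_probe_annotation,
    read_sample_sheet,
    write_beta_matrix,
    write_probe_annotation,
    write_results_table,
    write_sample_sheet,
)
from .preprocessing import probe_filter, quantile_normalize, sample_qc
from .synthetic import SimConfig, simulate_cohort
from .variability import control_pair_variance, replication_test, variance_enrichment_test

logger = logging.getLogger("twinmeth")

__all__ = ["PipelineConfig", "ConfigError", "StageError", "run_full_study"]


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class StageError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


@dataclass
class PipelineConfig:
    """Inputs (paths or a simulation config), stage parameters, seed, outdir."""

    outdir: str = "twinmeth_out"
    seed: int = 0
    simulate: SimConfig | None = None
    beta_matrix: str | None = None
    sample_sheet: str | None = None
    annotation: str | None = None
    alpha: float = 0.01
    n_perm: int = 1000
    n_boot: int = 10000
    ci_level: float = 0.95
    neighbor_window_bp: int = 2000
    max_missing_fraction: float = 0.05
    min_high_meth_fraction: float = 0.10
    enrichment_cohorts: tuple[str, ...] = ("pre_t1d", "post_t1d", "abpos_no_t1d")

    def __post_init__(self) -> None:
        if self.simulate is None and not (
            self.beta_matrix and self.sample_sheet and self.annotation
        ):
            raise ConfigError(
                "provide either a 'simulate' block or all three input paths"
            )
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must be in (0, 1)")
        if not (0 < self.ci_level < 1):
            raise ConfigError("ci_level must be in (0, 1)")
        if self.n_perm < 100 or self.n_boot < 100:
            raise ConfigError("n_perm and n_boot must be >= 100")
        if self.neighbor_window_bp < 0:
            raise ConfigError("neighbor_window_bp must be >= 0")
        for c in self.enrichment_cohorts:
            if c not in ("pre_t1d", "post_t1d", "abpos_no_t1d"):
                raise ConfigError(f"unknown enrichment cohort {c!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        if sim is not None:
            valid = {f.name for f in dataclasses.fields(SimConfig)}
            unknown = set(sim) - valid
            if unknown:
                raise ConfigError(f"unknown simulate keys: {sorted(unknown)}")
            if "effect_range" in sim:
                sim["effect_range"] = tuple(sim["effect_range"])
            if "neighbor_spacing_bp" in sim:
                sim["neighbor_spacing_bp"] = tuple(sim["neighbor_spacing_bp"])
            sim = SimConfig(**sim)
        inputs = raw.pop("inputs", {})
        params = raw.pop("params", {})
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = (set(raw) | set(inputs) | set(params)) - valid
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        if "enrichment_cohorts" in params:
            params["enrichment_cohorts"] = tuple(params["enrichment_cohorts"])
        return cls(simulate=sim, **inputs, **params, **raw)


def _stage_seeds(seed: int) -> dict[str, int]:
    names = ("simulate", "excess_count", "replication", "enrich_pre", "enrich_post",
             "pre_post", "enrich_abpos")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {
        n: int(np.random.default_rng(c).integers(2**31)) for n, c in zip(names, children)
    }


def run_full_study(config: PipelineConfig) -> dict:
    """Execute every stage and return the machine-readable summary dict.

    Also writes ``summary.json``, ``report.txt`` and per-stage TSVs to
    ``config.outdir``.  Deterministic given ``config.seed``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    summary: dict = {"version": __version__, "seed": config.seed}

    def stage(name, fn, *args, **kwargs):
        logger.info("stage %s", name)
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(f"stage {name!r} failed: {exc}") from exc

    # --- inputs -----------------------------------------------------------
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=seeds["simulate"])
        matrix, sheet, annotation, truth = stage("simulate", simulate_cohort, sim)
        write_beta_matrix(matrix, out / "betas_raw.tsv")
        write_sample_sheet(sheet, out / "sample_sheet.csv")
        write_probe_annotation(annotation, out / "annotation.tsv")
        write_results_table(truth.table, out / "truth.tsv", seed=config.seed)
        summary["simulate"] = {"n_true_mvps": len(truth.table), "seed": sim.seed}
    else:
        matrix = stage("read_inputs", read_beta_matrix, config.beta_matrix)
        sheet = stage("read_inputs", read_sample_sheet, config.sample_sheet)
        annotation = stage("read_inputs", read_probe_annotation, config.annotation)

    cohorts_present = set(sheet.table["cohort"])
    wanted = [c for c in config.enrichment_cohorts if c in cohorts_present]
    if wanted and "control_twins" not in cohorts_present:
        raise ConfigError(
            "enrichment cohorts present but no control_twins pairs to compare against"
        )

    # --- preprocessing ----------------------------------------------------
    qc = stage(
        "qc",
        sample_qc,
        matrix,
        max_missing_fraction=config.max_missing_fraction,
        min_high_meth_fraction=config.min_high_meth_fraction,
    )
    filtered, dropped = stage("probe_filter", probe_filter, matrix, annotation, qc.retained_samples)
    qc.probes = dropped
    write_results_table(qc.samples, out / "qc_samples.tsv", seed=config.seed)
    write_results_table(qc.probes, out / "qc_probes.tsv", seed=config.seed)
    normalized = stage("normalize", quantile_normalize, filtered)
    write_beta_matrix(normalized, out / "betas_normalized.tsv")
    counts = qc.counts()
    counts["probes_retained"] = int(len(normalized.probe_ids))
    counts["probes_input"] = int(len(matrix.probe_ids))
    summary["qc"] = counts
    logger.info(
        "QC: %d/%d samples retained, %d/%d probes retained",
        counts["samples_retained"], len(matrix.sample_ids),
        counts["probes_retained"], counts["probes_input"],
    )

    # --- discovery --------------------------------------------------------
    if "discovery_twins" not in cohorts_present:
        raise ConfigError("no discovery_twins cohort in the sample sheet")
    diffs = stage("discover", paired_differences, normalized, sheet, "discovery_twins")
    calls = stage("discover", call_mvps, diffs, alpha=config.alpha)
    write_results_table(calls.calls, out / "mvp_calls.tsv", seed=config.seed)
    excess = stage(
        "excess_count",
        excess_count_permutation,
        diffs,
        alpha=config.alpha,
        n_perm=config.n_perm,
        seed=seeds["excess_count"],
    )
    (out / "excess_count.txt").write_text(
        f"observed={excess.observed_count}\nempirical_p={excess.empirical_p}\n"
        f"n_perm={excess.n_perm}\n"
    )
    neighbors = stage("neighbors", neighbor_analysis, calls, diffs, annotation,
                      window_bp=config.neighbor_window_bp)
    write_results_table(neighbors.table, out / "neighbors.tsv", seed=config.seed)
    summary["discovery"] = {
        "n_mvps": len(calls.calls),
        "n_hyper": calls.n_hyper,
        "n_hypo": calls.n_hypo,
        "alpha": config.alpha,
        "n_probes_tested": calls.n_probes_tested,
        "excess_count_p": excess.empirical_p,
        "neighbor_p": neighbors.p_value,
    }
    logger.info("discovery: %d MVPs (%d hyper / %d hypo)",
                len(calls.calls), calls.n_hyper, calls.n_hypo)

    # --- variance control -------------------------------------------------
    if "control_twins" in cohorts_present:
        cdiffs = stage("variance", paired_differences, normalized, sheet, "control_twins")
        profile = stage("variance", control_pair_variance, cdiffs)
        write_results_table(profile.table, out / "control_variance.tsv", seed=config.seed)
        if len(calls.calls):
            summary["variance_enrichment_p"] = stage(
                "variance", variance_enrichment_test, profile, calls
            )

    # --- replication ------------------------------------------------------
    if "replication_twins" in cohorts_present and len(calls.calls):
        rdiffs = stage("replicate", paired_differences, normalized, sheet, "replication_twins")
        rep = stage("replicate", replication_test, rdiffs, calls,
                    n_boot=config.n_boot, seed=seeds["replication"])
        write_results_table(rep.groups, out / "replication_groups.tsv", seed=config.seed)
        summary["replication"] = {
            "p_value": rep.p_value,
            "groups": rep.groups.to_dict(orient="records"),
        }

    # --- temporal enrichment ---------------------------------------------
    if len(calls.calls):
        for cohort, key in (("pre_t1d", "enrich_pre"), ("post_t1d", "enrich_post"),
                            ("abpos_no_t1d", "enrich_abpos")):
            if cohort not in wanted:
                continue
            enr = stage(
                f"enrich_{cohort}",
                bootstrap_enrichment,
                normalized, sheet, cohort, calls,
                n_boot=config.n_boot, ci_level=config.ci_level, seed=seeds[key],
            )
            write_results_table(
                enr.per_probe_p.rename_axis("probe_id").reset_index(),
                out / f"enrichment_{cohort}.tsv", seed=config.seed,
            )
            summary[f"enrichment_{cohort}"] = enr.as_dict()
        if {"pre_t1d", "post_t1d"} <= cohorts_present:
            pp = stage("pre_post", paired_pre_post, normalized, sheet, calls,
                       n_boot=config.n_boot, ci_level=config.ci_level,
                       seed=seeds["pre_post"])
            summary["pre_post_paired"] = pp.as_dict()

    # --- reports ----------------------------------------------------------
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    (out / "report.txt").write_text(_render_report(summary))
    return summary


def _render_report(summary: dict) -> str:
    lines = [
        f"twinmeth {summary['version']} study report (seed {summary['seed']})",
        "",
    ]
    qc = summary.get("qc", {})
    lines.append(
        f"QC: {qc.get('samples_retained', '?')} samples retained "
        f"({qc.get('samples_discarded_missing', 0)} discarded for missingness, "
        f"{qc.get('samples_flagged_bimodality', 0)} flagged for bimodality); "
        f"{qc.get('probes_retained', '?')}/{qc.get('probes_input', '?')} probes retained."
    )
    d = summary.get("discovery", {})
    lines.append(
        f"Discovery: {d.get('n_mvps', 0)} MVPs at p<{d.get('alpha')} "
        f"({d.get('n_hyper', 0)} hyper / {d.get('n_hypo', 0)} hypo) of "
        f"{d.get('n_probes_tested', '?')} probes; excess-count permutation "
        f"P={d.get('excess_count_p'):.4g}; neighbor-CpG Welch P={d.get('neighbor_p'):.4g}."
    )
    if "variance_enrichment_p" in summary:
        lines.append(
            f"Control-pair variance enrichment (MVPs less variable): "
            f"P={summary['variance_enrichment_p']:.3g}."
        )
    if "replication" in summary:
        lines.append(
            f"Replication Welch P={summary['replication']['p_value']:.4g} "
            f"(hyper above hypo)."
        )
    for cohort in ("pre_t1d", "post_t1d", "abpos_no_t1d"):
        key = f"enrichment_{cohort}"
        if key in summary:
            e = summary[key]
            lines.append(
                f"Enrichment {cohort}: X={e['X']:.3f} "
                f"[{e['ci_low']:.3f}, {e['ci_high']:.3f}] "
                f"P={e['p_one_sided']:.4g}, directionality "
                f"{e['directionality_fraction']:.0%}."
            )
    if "pre_post_paired" in summary:
        e = summary["pre_post_paired"]
        lines.append(
            f"Pre vs post (paired): X={e['X']:.3f} "
            f"[{e['ci_low']:.3f}, {e['ci_high']:.3f}] P={e['p_one_sided']:.4g}."
        )
    return "\n".join(lines) + "\n"
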