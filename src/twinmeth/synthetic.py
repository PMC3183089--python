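"""Synthetic twin/singleton methylation cohorts with known ground truth.

The generator reproduces the statistical structure the downstream
analysis assumes, at the scale of the original study design: 15
disease-discordant MZ twin pairs for discovery, 9 unaffected control
pairs, 4 independent replication pairs, 7 singletons sampled before and
after diagnosis, and 4 autoantibody-positive disease-free singletons,
profiled on a promoter array of ~27K CpGs arranged roughly two per
promoter, 500–2,000 bp apart, with a small share of X/Y probes and
sporadic missing scores.

Value model (proportion scale):

    beta[p, s] = clip( mu[p] + shared[p, g(s)] + tech[p, s] + effect, 0, 1 )

* ``mu[p]`` — baseline methylation drawn per promoter from a bimodal
  mixture 0.7·Beta(5, 25) + 0.3·Beta(25, 5), shared by both probes of a
  promoter, so marginals show the expected low/high bimodality.
* ``shared`` — a biological deviation common to both co-twins of a pair
  (or to the pre and post samples of one subject).  For MZ twins,
  biology (genotype plus early environment) is modelled as fully
  pair-shared, with standard deviation noise_sd·sqrt(rho/(1−rho)), so
  the within-pair correlation of measured values is exactly
  ``pair_correlation`` and intra-pair differences contain only
  technical noise plus any disease effect.
* ``tech`` — per-array technical noise, s.d. ``noise_sd``.
* ``effect`` — for the ``n_true_mvps`` truth probes, an additive shift
  of the configured magnitude applied to affected co-twins and case
  singletons, positive for hypermethylated truth probes and negative
  for hypomethylated ones (hyper with probability ``hyper_fraction``,
  defaulting to the 58:74 split).

All randomness flows from a single seed through named sub-streams, so
identical configurations are bit-identical and adding a cohort never
perturbs another cohort's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import BetaMatrix, ProbeAnnotation, SampleSheet

__all__ = ["SimConfig", "SimTruth", "simulate_cohort", "simulate_intensities"]

_SUBSTREAMS = (
    "annotation",
    "baseline",
    "truth",
    "discovery_twins",
    "control_twins",
    "replication_twins",
    "pre_post",
    "abpos",
    "missing",
)


@dataclass(frozen=True)
class SimConfig:
    """Cohort-simulation parameters; defaults mirror the study design."""

    n_probes: int = 27458
    n_discovery_pairs: int = 15
    n_control_pairs: int = 9
    n_replication_pairs: int = 4
    n_pre_post_subjects: int = 7
    n_abpos_singletons: int = 4
    n_true_mvps: int = 132
    effect_range: tuple[float, float] = (0.0013, 0.066)
    hyper_fraction: float = 58 / 132
    pair_correlation: float = 0.8
    noise_sd: float = 0.02
    missing_rate: float = 0.005
    frac_sex_probes: float = 0.04
    neighbor_spacing_bp: tuple[int, int] = (500, 2000)
    effects_span_promoter: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.effect_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("effect_range must satisfy 0 <= low <= high <= 1")
        for name in (
            "n_probes",
            "n_discovery_pairs",
            "n_control_pairs",
            "n_replication_pairs",
            "n_pre_post_subjects",
            "n_abpos_singletons",
            "n_true_mvps",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if not (0.0 <= self.pair_correlation < 1.0):
            raise ValueError("pair_correlation must be in [0, 1)")
        if not (0.0 <= self.hyper_fraction <= 1.0):
            raise ValueError("hyper_fraction must be in [0, 1]")
        if not (0.0 <= self.frac_sex_probes < 1.0):
            raise ValueError("frac_sex_probes must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_true_mvps > self.n_probes:
            raise ValueError("n_true_mvps cannot exceed n_probes")

    @property
    def shared_sd(self) -> float:
        """Pair-shared biological s.d. implied by the correlation target."""
        rho = self.pair_correlation
        return self.noise_sd * np.sqrt(rho / (1.0 - rho))


@dataclass
class SimTruth:
    """Ground truth: which probes carry effects, in which direction."""

    table: pd.DataFrame  # probe_id, direction (hyper/hypo), effect
    cohort_effects: dict[str, bool] = field(
        default_factory=lambda: {
            "discovery_twins": True,
            "replication_twins": True,
            "pre_t1d": True,
            "post_t1d": True,
            "abpos_no_t1d": True,
        }
    )

    @property
    def mvp_probe_ids(self) -> list[str]:
        return list(self.table["probe_id"])


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    return {name: np.random.default_rng(s) for name, s in zip(_SUBSTREAMS, children)}


def _make_annotation(config: SimConfig, rng: np.random.Generator) -> ProbeAnnotation:
    """Promoter-paired probe layout; the last probes are placed on X/Y."""
    n = config.n_probes
    n_sex = int(round(config.frac_sex_probes * n))
    probe_ids = [f"cg{i:08d}" for i in range(n)]
    chroms: list[str] = []
    positions: list[int] = []
    genes: list[str] = []
    lo, hi = config.neighbor_spacing_bp
    autosomes = [f"chr{i}" for i in range(1, 23)]
    n_promoters = (n + 1) // 2
    spacing = rng.integers(lo, hi + 1, size=n_promoters)
    cursor = {}
    for prom in range(n_promoters):
        first = 2 * prom
        is_sex = first >= n - n_sex
        if is_sex:
            # ~90% X, remainder Y, mirroring the platform's X-heavy sex content
            chrom = "chrX" if (prom % 10) != 0 else "chrY"
        else:
            chrom = autosomes[prom % len(autosomes)]
        start = cursor.get(chrom, 1000) + 100_000
        cursor[chrom] = start
        for k, probe in enumerate(range(first, min(first + 2, n))):
            chroms.append(chrom)
            positions.append(start + k * int(spacing[prom]))
            genes.append(f"GENE{prom:05d}")
    return ProbeAnnotation(
        pd.DataFrame(
            {
                "probe_id": probe_ids,
                "chromosome": chroms,
                "position": positions,
                "gene_symbol": genes,
            }
        )
    )


def _draw_truth(
    config: SimConfig, annotation: ProbeAnnotation, rng: np.random.Generator
) -> tuple[SimTruth, np.ndarray]:
    """Pick truth probes (autosomal only) and per-probe signed effects."""
    n = config.n_probes
    effects = np.zeros(n)
    autosomal = ~annotation.table["chromosome"].isin(("chrX", "chrY")).to_numpy()
    candidates = np.flatnonzero(autosomal)
    if config.n_true_mvps > candidates.size:
        raise ValueError("not enough autosomal probes for the requested truth set")
    idx = np.sort(rng.choice(candidates, size=config.n_true_mvps, replace=False))
    magnitude = rng.uniform(config.effect_range[0], config.effect_range[1], size=idx.size)
    hyper = rng.random(idx.size) < config.hyper_fraction
    signed = np.where(hyper, magnitude, -magnitude)
    if config.effects_span_promoter:
        # the promoter mate of each truth probe carries the same shift
        for i, e in zip(idx, signed):
            mate = i + 1 if i % 2 == 0 else i - 1
            if 0 <= mate < n and autosomal[mate]:
                effects[mate] = e
    effects[idx] = signed
    probe_ids = annotation.table["probe_id"].to_numpy()
    truth = SimTruth(
        table=pd.DataFrame(
            {
                "probe_id": probe_ids[idx],
                "direction": np.where(hyper, "hyper", "hypo"),
                "effect": magnitude,
            }
        )
    )
    return truth, effects


def _twin_cohort_values(
    config: SimConfig,
    mu: np.ndarray,
    effects: np.ndarray,
    n_pairs: int,
    rng: np.random.Generator,
    with_effect: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """(affected, unaffected) value arrays, each (n_probes, n_pairs)."""
    P = mu.size
    shared = rng.normal(0.0, config.shared_sd, size=(P, n_pairs))
    base = mu[:, None] + shared
    affected = base + rng.normal(0.0, config.noise_sd, size=(P, n_pairs))
    unaffected = base + rng.normal(0.0, config.noise_sd, size=(P, n_pairs))
    if with_effect:
        affected = affected + effects[:, None]
    return np.clip(affected, 0.0, 1.0), np.clip(unaffected, 0.0, 1.0)


def simulate_cohort(
    config: SimConfig,
) -> tuple[BetaMatrix, SampleSheet, ProbeAnnotation, SimTruth]:
    """Generate one full synthetic study (betas, sheet, annotation, truth)."""
    rngs = _streams(config.seed)
    annotation = _make_annotation(config, rngs["annotation"])
    # baseline per promoter, shared by promoter mates
    n_prom = (config.n_probes + 1) // 2
    rng_b = rngs["baseline"]
    comp = rng_b.random(n_prom) < 0.7
    mu_prom = np.where(
        comp, rng_b.beta(5, 25, size=n_prom), rng_b.beta(25, 5, size=n_prom)
    )
    mu = np.repeat(mu_prom, 2)[: config.n_probes]
    truth, effects = _draw_truth(config, annotation, rngs["truth"])
    eff = truth.cohort_effects

    columns: dict[str, np.ndarray] = {}
    rows = []

    def add_pair_cohort(cohort: str, prefix: str, n_pairs: int) -> None:
        aff, unaff, = _twin_cohort_values(
            config, mu, effects, n_pairs, rngs[cohort], eff.get(cohort, False)
        )
        for i in range(n_pairs):
            pid = f"{prefix}{i + 1:02d}"
            a_id, u_id = f"{pid}A", f"{pid}U"
            columns[a_id] = aff[:, i]
            columns[u_id] = unaff[:, i]
            rows.append((a_id, f"{pid}S1", pid, "affected", cohort))
            rows.append((u_id, f"{pid}S2", pid, "unaffected", cohort))

    add_pair_cohort("discovery_twins", "D", config.n_discovery_pairs)
    add_pair_cohort("control_twins", "C", config.n_control_pairs)
    add_pair_cohort("replication_twins", "R", config.n_replication_pairs)

    # pre/post singletons: one subject latent shared across both time points
    P = config.n_probes
    rng_pp = rngs["pre_post"]
    n_pp = config.n_pre_post_subjects
    if n_pp:
        subj = rng_pp.normal(0.0, config.shared_sd, size=(P, n_pp))
        for when, cohort in (("PRE", "pre_t1d"), ("POST", "post_t1d")):
            vals = mu[:, None] + subj + rng_pp.normal(0.0, config.noise_sd, size=(P, n_pp))
            if eff.get(cohort, False):
                vals = vals + effects[:, None]
            vals = np.clip(vals, 0.0, 1.0)
            for i in range(n_pp):
                sid = f"S{i + 1:02d}{when}"
                columns[sid] = vals[:, i]
                rows.append((sid, f"PP{i + 1:02d}", "", "affected", cohort))

    rng_ab = rngs["abpos"]
    if config.n_abpos_singletons:
        n_ab = config.n_abpos_singletons
        vals = (
            mu[:, None]
            + rng_ab.normal(0.0, config.shared_sd, size=(P, n_ab))
            + rng_ab.normal(0.0, config.noise_sd, size=(P, n_ab))
        )
        if eff.get("abpos_no_t1d", False):
            vals = vals + effects[:, None]
        vals = np.clip(vals, 0.0, 1.0)
        for i in range(n_ab):
            sid = f"AB{i + 1:02d}"
            columns[sid] = vals[:, i]
            rows.append((sid, f"AB{i + 1:02d}S", "", "affected", "abpos_no_t1d"))

    if not columns:
        raise ValueError("configuration generates no samples")
    data = pd.DataFrame(columns, index=annotation.table["probe_id"])
    if config.missing_rate > 0:
        mask = rngs["missing"].random(data.shape) < config.missing_rate
        data = data.mask(mask)
    matrix = BetaMatrix(data)
    sheet = SampleSheet(
        pd.DataFrame(rows, columns=["sample_id", "subject_id", "pair_id", "status", "cohort"])
    )
    return matrix, sheet, annotation, truth


def simulate_intensities(beta_target: float, total_signal: float) -> "IntensityPair":
    """Invert the beta formula: (M, U) with M + U = total_signal.

    Solves M = beta_target * (total_signal + 100); infeasible targets
    (requiring M > total_signal, i.e. beta_target > total/(total+100))
    raise a ValueError.
    """
    from .preprocessing import BETA_OFFSET, IntensityPair

    if not (0.0 <= beta_target < 1.0):
        raise ValueError("beta_target must be in [0, 1)")
    if total_signal <= 0:
        raise ValueError("total_signal must be positive")
    m = beta_target * (total_signal + BETA_OFFSET)
    if m > total_signal:
        raise ValueError(
            f"beta_target {beta_target} infeasible at total_signal {total_signal}"
        )
    return IntensityPair(M=m, U=total_signal - m)


def null_config(**overrides) -> SimConfig:
    """A convenience configuration with no injected effects."""
    return replace(SimConfig(n_true_mvps=0), **overrides)
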