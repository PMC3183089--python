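"""Noise controls and independent confirmation of the MVP calls.

Three checks guard against the calls being artifacts of probe-level
noise, and confirm them in independent material:

* **Control-pair variance** — intra-pair differences in unaffected MZ
  pairs contain only technical plus metastable-CpG noise, so the
  per-probe variance of those differences profiles each probe's noise
  level.  If MVPs were merely the noisiest probes, their variance in
  control pairs would be elevated; the enrichment test asks the
  opposite — whether MVP probes sit at *lower* control-pair variance
  than the rest (one-sided Welch's t).
* **Replication** — in twin pairs unseen at discovery, each MVP's mean
  intra-pair difference should fall on the side of zero its discovery
  direction predicts; hyper- and hypo-MVP means are compared with a
  one-sided Welch's t-test, with percentile bootstrap CIs (resampling
  MVP probes, the plotted unit) on the group means.
* **Amplicon group test** — for targeted bisulfite amplicons, mean
  affected-vs-unaffected differences of hyper-indexed amplicons are
  compared against hypo-indexed ones, again one-sided Welch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .discovery import MVPCallSet, PairedDiffMatrix

__all__ = [
    "VarianceProfile",
    "AmpliconSummary",
    "ReplicationResult",
    "control_pair_variance",
    "variance_enrichment_test",
    "replication_test",
    "amplicon_groupwise_test",
    "read_amplicon_summaries",
]


@dataclass
class VarianceProfile:
    """Per-probe variance of intra-pair differences across control pairs."""

    table: pd.DataFrame  # probe_id, variance, rank (1..n by increasing variance)
    n_pairs: int

    def variances_for(self, probes) -> np.ndarray:
        return self.table.set_index("probe_id").loc[list(probes), "variance"].to_numpy()


def control_pair_variance(diffs: PairedDiffMatrix) -> VarianceProfile:
    """Sample variance (ddof=1) of each probe's control-pair differences.

    Ranks run from 1 (least variable) upward, ties broken by probe order.
    The profile is invariant to flipping any pair's arbitrary index
    assignment, since negating a column leaves variances unchanged.
    """
    d = diffs.data.to_numpy(dtype=float)
    if d.shape[1] < 2:
        raise ValueError("control variance needs at least 2 pairs")
    variance = d.var(axis=1, ddof=1)
    order = np.lexsort((np.arange(variance.size), variance))
    rank = np.empty(variance.size, dtype=int)
    rank[order] = np.arange(1, variance.size + 1)
    table = pd.DataFrame(
        {"probe_id": diffs.probe_ids, "variance": variance, "rank": rank}
    )
    return VarianceProfile(table=table, n_pairs=d.shape[1])


def variance_enrichment_test(profile: VarianceProfile, calls: MVPCallSet) -> float:
    """One-sided Welch's t: MVP-probe variances below non-MVP variances.

    With a single called probe Welch's t is undefined; the test then
    falls back to a one-sample formulation (non-MVP variances tested
    against the lone MVP variance, alternative greater) with a warning.
    """
    if calls.calls.empty:
        raise ValueError("empty call set")
    mvp_ids = set(calls.probe_ids)
    known = set(profile.table["probe_id"])
    missing = mvp_ids - known
    if missing:
        raise ValueError(f"profile lacks {len(missing)} called probe(s)")
    is_mvp = profile.table["probe_id"].isin(mvp_ids).to_numpy()
    v = profile.table["variance"].to_numpy()
    mvp_v, other_v = v[is_mvp], v[~is_mvp]
    if other_v.size < 2:
        raise ValueError("too few non-MVP probes for the enrichment test")
    if mvp_v.size == 1:
        warnings.warn(
            "single-probe call set: using one-sample fallback for the variance test"
        )
        return float(
            stats.ttest_1samp(other_v, mvp_v[0], alternative="greater").pvalue
        )
    return float(
        stats.ttest_ind(mvp_v, other_v, equal_var=False, alternative="less").pvalue
    )


@dataclass
class ReplicationResult:
    """Directional replication of the call set in independent twin pairs."""

    p_value: float  # one-sided Welch: hyper means > hypo means
    groups: pd.DataFrame  # direction, n, mean, ci50_low/high, ci95_low/high
    per_probe: pd.DataFrame  # probe_id, direction, mean_diff (replication pairs)
    n_boot: int
    seed: int | None
    excluded: list[str]


def _group_boot_ci(
    values: np.ndarray, n_boot: int, rng: np.random.Generator
) -> dict[str, float]:
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    q = np.percentile(means, [25, 75, 2.5, 97.5])
    return {
        "mean": float(values.mean()),
        "ci50_low": float(q[0]),
        "ci50_high": float(q[1]),
        "ci95_low": float(q[2]),
        "ci95_high": float(q[3]),
    }


def replication_test(
    diffs: PairedDiffMatrix,
    calls: MVPCallSet,
    n_boot: int = 10000,
    seed: int | None = None,
) -> ReplicationResult:
    """Test discovery MVPs in an independent twin cohort.

    Per MVP present in the replication matrix, the mean intra-pair
    difference across replication pairs is computed; hyper- vs hypo-MVP
    means are compared with a one-sided Welch's t-test, and percentile
    bootstrap CIs (50% and 95%) on the group means are obtained by
    resampling MVP probes with replacement.
    """
    if n_boot <= 0:
        raise ValueError("n_boot must be positive")
    if calls.calls.empty:
        raise ValueError("empty call set")
    present = [p for p in calls.probe_ids if p in diffs.data.index]
    excluded = [p for p in calls.probe_ids if p not in diffs.data.index]
    if not present:
        raise ValueError("no called probe is present in the replication matrix")
    if excluded:
        warnings.warn(
            f"{len(excluded)} called probe(s) absent from the replication matrix"
        )
    directions = calls.directions()
    means = diffs.data.loc[present].mean(axis=1)
    per_probe = pd.DataFrame(
        {
            "probe_id": present,
            "direction": directions.loc[present].to_numpy(),
            "mean_diff": means.to_numpy(),
        }
    )
    hyper = per_probe.loc[per_probe["direction"] == "hyper", "mean_diff"].to_numpy()
    hypo = per_probe.loc[per_probe["direction"] == "hypo", "mean_diff"].to_numpy()
    if hyper.size < 2 or hypo.size < 2:
        raise ValueError("need >= 2 replicated MVPs per direction")
    p = float(stats.ttest_ind(hyper, hypo, equal_var=False, alternative="greater").pvalue)
    rng = np.random.default_rng(seed)
    rows = []
    for direction, vals in (("hyper", hyper), ("hypo", hypo)):
        row = {"direction": direction, "n": vals.size}
        row.update(_group_boot_ci(vals, n_boot, rng))
        rows.append(row)
    return ReplicationResult(
        p_value=p,
        groups=pd.DataFrame(rows),
        per_probe=per_probe,
        n_boot=n_boot,
        seed=seed,
        excluded=excluded,
    )


@dataclass(frozen=True)
class AmpliconSummary:
    """Groupwise summary of one bisulfite amplicon."""

    amplicon_id: str
    direction: str  # inherited from the amplicon's index MVP
    mean_diff: float  # mean over amplicon CpGs of (affected − unaffected), over pairs

    def __post_init__(self) -> None:
        if self.direction not in ("hyper", "hypo"):
            raise ValueError("direction must be 'hyper' or 'hypo'")


def amplicon_groupwise_test(summaries) -> float:
    """One-sided Welch's t on amplicon mean differences, hyper vs hypo."""
    summaries = list(summaries)
    hyper = np.array([s.mean_diff for s in summaries if s.direction == "hyper"])
    hypo = np.array([s.mean_diff for s in summaries if s.direction == "hypo"])
    if hyper.size < 2 or hypo.size < 2:
        raise ValueError("need >= 2 amplicons per direction")
    se2 = hyper.var(ddof=1) / hyper.size + hypo.var(ddof=1) / hypo.size
    if se2 == 0.0:  # degenerate: both groups constant; t is 0/0
        delta = hyper.mean() - hypo.mean()
        return 0.5 if delta == 0 else (0.0 if delta > 0 else 1.0)
    return float(
        stats.ttest_ind(hyper, hypo, equal_var=False, alternative="greater").pvalue
    )


def read_amplicon_summaries(path) -> list[AmpliconSummary]:
    """TSV with columns amplicon_id, direction, mean_diff."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        AmpliconSummary(str(r.amplicon_id), str(r.direction), float(r.mean_diff))
        for r in df.itertuples()
    ]
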