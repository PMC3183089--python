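"""MVP discovery from discordant twin pairs.

A methylation variable position (MVP) is a CpG whose intra-pair
(affected − unaffected) beta differences are systematically non-zero
across discordant MZ pairs.  Discovery runs a two-sided Wilcoxon
signed-rank test per probe and calls every probe with p below the
calling threshold (0.01 by default); no multiple-testing correction is
applied — the call set records how many probes were tested so callers
may post-correct.  Direction (hyper/hypo) is the sign of the mean
intra-pair difference.

Whether the observed number of calls exceeds chance is assessed by a
within-pair label-flipping permutation: under exchangeability of the
affected/unaffected labels within a pair, negating each pair's
difference column with probability 1/2 regenerates the null.

The neighbor analysis asks whether the closest assayed CpG within 2 kb
of each MVP shifts in the same direction, comparing neighbors of hyper-
vs hypo-MVPs with a one-sided Welch's t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import BetaMatrix, ProbeAnnotation, SampleSheet
from .rankstats import (
    _prepare_signed_rank_rows,
    _signed_rank_p_from_w,
    signed_rank_p_matrix,
    signed_rank_test,
)

__all__ = [
    "PairedDiffMatrix",
    "MVPCall",
    "MVPCallSet",
    "paired_differences",
    "signed_rank_test",
    "call_mvps",
    "excess_count_permutation",
    "ExcessCountResult",
    "neighbor_analysis",
    "NeighborResult",
]


@dataclass
class PairedDiffMatrix:
    """Probe x pair grid of (affected − unaffected) beta differences."""

    data: pd.DataFrame  # index probe ids, columns pair ids
    cohort: str

    def __post_init__(self) -> None:
        vals = self.data.to_numpy(dtype=float)
        finite = vals[~np.isnan(vals)]
        if finite.size and (np.abs(finite) > 1.0 + 1e-12).any():
            raise ValueError("paired beta differences must lie in [-1, 1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index

    @property
    def pair_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def n_pairs(self) -> int:
        return self.data.shape[1]


def paired_differences(
    matrix: BetaMatrix, sheet: SampleSheet, cohort: str
) -> PairedDiffMatrix:
    """Per-probe (affected − unaffected) differences, one column per pair.

    For control twins the recorded arbitrary index assignment plays the
    affected role (index minus co-twin).
    """
    pairs = sheet.pairs(cohort)
    if pairs.empty:
        raise ValueError(f"no pairs in cohort {cohort!r}")
    available = set(matrix.sample_ids)
    for _, row in pairs.iterrows():
        missing = {row["affected"], row["unaffected"]} - available
        if missing:
            raise ValueError(
                f"pair {row['pair_id']!r} has member(s) missing from the "
                f"beta matrix: {sorted(missing)}"
            )
    aff = matrix.data.loc[:, pairs["affected"].tolist()].to_numpy(dtype=float)
    unaff = matrix.data.loc[:, pairs["unaffected"].tolist()].to_numpy(dtype=float)
    diffs = pd.DataFrame(
        aff - unaff, index=matrix.probe_ids, columns=pairs["pair_id"].tolist()
    )
    return PairedDiffMatrix(diffs, cohort=cohort)


@dataclass(frozen=True)
class MVPCall:
    probe_id: str
    p_value: float
    direction: str  # "hyper" iff mean_diff > 0
    mean_diff: float


@dataclass
class MVPCallSet:
    """Probes called at p < alpha, with direction and mean intra-pair diff."""

    calls: pd.DataFrame  # probe_id, p_value, direction, mean_diff
    alpha: float
    n_pairs: int
    n_probes_tested: int

    def __post_init__(self) -> None:
        if not self.calls.empty:
            if self.calls["probe_id"].duplicated().any():
                raise ValueError("duplicate probes in call set")
            if (self.calls["p_value"] >= self.alpha).any():
                raise ValueError("call set contains p >= alpha")
            hyper = self.calls["direction"] == "hyper"
            if not (hyper == (self.calls["mean_diff"] > 0)).all():
                raise ValueError("direction labels disagree with mean_diff sign")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.calls["probe_id"])

    def directions(self) -> pd.Series:
        return self.calls.set_index("probe_id")["direction"]

    @property
    def n_hyper(self) -> int:
        return int((self.calls["direction"] == "hyper").sum())

    @property
    def n_hypo(self) -> int:
        return int((self.calls["direction"] == "hypo").sum())


def call_mvps(diffs: PairedDiffMatrix, alpha: float = 0.01) -> MVPCallSet:
    """Two-sided signed-rank test per probe; keep probes with p < alpha."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    d = diffs.data.to_numpy(dtype=float)
    if np.isnan(d).any():
        raise ValueError(
            "paired differences contain missing values; run probe_filter first"
        )
    p, _degenerate = signed_rank_p_matrix(d, alternative="two-sided")
    mean_diff = d.mean(axis=1)
    called = p < alpha
    calls = pd.DataFrame(
        {
            "probe_id": diffs.probe_ids[called],
            "p_value": p[called],
            "direction": np.where(mean_diff[called] > 0, "hyper", "hypo"),
            "mean_diff": mean_diff[called],
        }
    ).reset_index(drop=True)
    return MVPCallSet(
        calls=calls,
        alpha=alpha,
        n_pairs=diffs.n_pairs,
        n_probes_tested=d.shape[0],
    )


@dataclass
class ExcessCountResult:
    observed_count: int
    empirical_p: float
    n_perm: int
    perm_counts: np.ndarray
    seed: int | None


def excess_count_permutation(
    diffs: PairedDiffMatrix,
    alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int | None = None,
) -> ExcessCountResult:
    """Null distribution of the MVP count by within-pair sign flipping.

    Each permutation independently negates every pair's difference column
    with probability 1/2 (equivalent to swapping the affected/unaffected
    labels inside pairs), recounts probes with p < alpha, and the
    empirical p-value is the add-one fraction of permutations reaching
    the observed count.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    d = diffs.data.to_numpy(dtype=float)
    if np.isnan(d).any():
        raise ValueError("paired differences contain missing values")
    rows = _prepare_signed_rank_rows(d)
    signs = np.sign(d)  # 0 at zero differences, which carry no rank weight
    w_obs = np.where(signs > 0, rows.ranks, 0.0).sum(axis=1)
    p_obs = _signed_rank_p_from_w(rows, w_obs, "two-sided")
    observed = int((p_obs < alpha).sum())
    rng = np.random.default_rng(seed)
    counts = np.empty(n_perm, dtype=int)
    chunk = max(1, int(2e7) // max(d.size, 1))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        flips = rng.choice([-1.0, 1.0], size=(b, d.shape[1]))
        flipped = signs[None, :, :] * flips[:, None, :]
        w = np.where(flipped > 0, rows.ranks[None, :, :], 0.0).sum(axis=2)
        for k in range(b):
            pk = _signed_rank_p_from_w(rows, w[k], "two-sided")
            counts[done + k] = int((pk < alpha).sum())
        done += b
    empirical_p = (1.0 + float((counts >= observed).sum())) / (n_perm + 1.0)
    return ExcessCountResult(observed, empirical_p, n_perm, counts, seed)


@dataclass
class NeighborResult:
    """Closest assayed CpG within the window, per MVP, plus the group test."""

    table: pd.DataFrame  # probe_id, direction, neighbor_id, distance, neighbor_mean_diff
    p_value: float  # one-sided Welch: hyper-MVP neighbors > hypo-MVP neighbors
    window_bp: int


def neighbor_analysis(
    calls: MVPCallSet,
    diffs: PairedDiffMatrix,
    annotation: ProbeAnnotation,
    window_bp: int = 2000,
) -> NeighborResult:
    """Directional behaviour of each MVP's closest neighbor CpG.

    For each called probe, the closest same-chromosome assayed probe at
    absolute distance <= ``window_bp`` is looked up (MVPs without such a
    neighbor are recorded with an empty neighbor field), its mean
    intra-pair difference taken, and the hyper-MVP neighbor group is
    compared against the hypo-MVP neighbor group with a one-sided
    Welch's t-test (alternative: hyper neighbors larger).
    """
    ann = annotation.table.set_index("probe_id")
    missing = set(diffs.probe_ids) - set(ann.index)
    if missing:
        raise ValueError(f"annotation lacks {len(missing)} assayed probe(s)")
    assayed = ann.loc[diffs.probe_ids]
    mean_diff = diffs.data.mean(axis=1)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in assayed.groupby("chromosome"):
        pos = grp["position"].to_numpy()
        order = np.argsort(pos, kind="stable")
        by_chrom[chrom] = (pos[order], grp.index.to_numpy()[order])
    records = []
    for _, call in calls.calls.iterrows():
        probe = call["probe_id"]
        if probe not in ann.index:
            continue
        chrom = ann.at[probe, "chromosome"]
        pos = int(ann.at[probe, "position"])
        neighbor_id, distance = "", np.nan
        if chrom in by_chrom:
            positions, ids = by_chrom[chrom]
            i = np.searchsorted(positions, pos)
            best = None
            for j in (i - 1, i, i + 1):
                if 0 <= j < positions.size and ids[j] != probe:
                    dist = abs(int(positions[j]) - pos)
                    if dist <= window_bp and (best is None or dist < best[1]):
                        best = (ids[j], dist)
            if best is not None:
                neighbor_id, distance = best
        records.append(
            {
                "probe_id": probe,
                "direction": call["direction"],
                "neighbor_id": neighbor_id,
                "distance": distance,
                "neighbor_mean_diff": mean_diff.get(neighbor_id, np.nan)
                if neighbor_id
                else np.nan,
            }
        )
    table = pd.DataFrame(
        records,
        columns=["probe_id", "direction", "neighbor_id", "distance", "neighbor_mean_diff"],
    )
    with_nb = table[table["neighbor_id"] != ""]
    hyper = with_nb.loc[with_nb["direction"] == "hyper", "neighbor_mean_diff"].to_numpy()
    hypo = with_nb.loc[with_nb["direction"] == "hypo", "neighbor_mean_diff"].to_numpy()
    if hyper.size >= 2 and hypo.size >= 2:
        p = float(
            stats.ttest_ind(hyper, hypo, equal_var=False, alternative="greater").pvalue
        )
    else:
        warnings.warn("too few MVP neighbors per direction for the group test")
        p = float("nan")
    return NeighborResult(table=table, p_value=p, window_bp=window_bp)
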