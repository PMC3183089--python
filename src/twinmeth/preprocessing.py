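"""Array preprocessing: beta computation, sample QC, probe filtering,
quantile normalization.

The beta value of a CpG is computed from the methylated (M) and
unmethylated (U) channel intensities as

    beta = max(M, 0) / (max(M, 0) + max(U, 0) + 100)

where the +100 offset stabilises low-intensity probes; negative raw
intensities are legal input and are clamped at zero.  The result lies in
[0, 1) — fully methylated probes approach but never reach 1.

Sample QC applies two rules with strict inequalities:

* an array with more than 5% missing beta values is discarded;
* an array whose beta distribution lacks the expected bimodality —
  strictly fewer than 10% of its non-missing betas at or above 0.75 —
  is flagged.  On the original platform such arrays were re-hybridised;
  software has no re-run to offer, so flagged arrays are excluded from
  analysis by default while the flag is preserved so a caller can
  substitute repeat data.

Probe filtering then keeps exactly the autosomal probes with a complete
set of scores across the retained arrays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import BetaMatrix, ProbeAnnotation, SEX_CHROMOSOMES, ValidationError

__all__ = [
    "IntensityPair",
    "QCReport",
    "compute_beta",
    "sample_qc",
    "probe_filter",
    "quantile_normalize",
    "MAX_MISSING_FRACTION",
    "MIN_HIGH_METH_FRACTION",
    "HIGH_METH_CUTOFF",
]

MAX_MISSING_FRACTION = 0.05
MIN_HIGH_METH_FRACTION = 0.10
HIGH_METH_CUTOFF = 0.75
BETA_OFFSET = 100.0


@dataclass(frozen=True)
class IntensityPair:
    """Raw two-channel signals; negative values are clamped at zero in use."""

    M: float
    U: float


def compute_beta(pair: IntensityPair) -> float:
    """Methylation proportion from an (M, U) intensity pair."""
    m, u = float(pair.M), float(pair.U)
    if not (math.isfinite(m) and math.isfinite(u)):
        raise ValueError("intensities must be finite")
    m = max(m, 0.0)
    u = max(u, 0.0)
    return m / (m + u + BETA_OFFSET)


@dataclass
class QCReport:
    """Per-sample verdicts plus (after probe filtering) per-probe drops."""

    samples: pd.DataFrame  # sample_id, missing_fraction, high_meth_fraction, verdict
    probes: pd.DataFrame  # probe_id, reason in {incomplete, sex_chromosome}

    @property
    def retained_samples(self) -> list[str]:
        ok = self.samples["verdict"] == "retained"
        return list(self.samples.loc[ok, "sample_id"])

    def counts(self) -> dict:
        return {
            "samples_retained": int((self.samples["verdict"] == "retained").sum()),
            "samples_discarded_missing": int(
                (self.samples["verdict"] == "discarded_missing").sum()
            ),
            "samples_flagged_bimodality": int(
                (self.samples["verdict"] == "flagged_bimodality").sum()
            ),
            "probes_dropped": int(len(self.probes)),
        }


def sample_qc(
    matrix: BetaMatrix,
    max_missing_fraction: float = MAX_MISSING_FRACTION,
    min_high_meth_fraction: float = MIN_HIGH_METH_FRACTION,
) -> QCReport:
    """Apply the per-array QC rules; probe drops are filled by probe_filter."""
    if matrix.data.empty:
        raise ValueError("cannot QC an empty beta matrix")
    vals = matrix.data.to_numpy(dtype=float)
    n_probes = vals.shape[0]
    missing = np.isnan(vals)
    missing_frac = missing.sum(axis=0) / n_probes
    n_obs = (~missing).sum(axis=0)
    high = np.nansum(vals >= HIGH_METH_CUTOFF, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        high_frac = np.where(n_obs > 0, high / np.maximum(n_obs, 1), 0.0)
    verdict = np.where(
        missing_frac > max_missing_fraction,
        "discarded_missing",
        np.where(high_frac < min_high_meth_fraction, "flagged_bimodality", "retained"),
    )
    samples = pd.DataFrame(
        {
            "sample_id": matrix.sample_ids,
            "missing_fraction": missing_frac,
            "high_meth_fraction": high_frac,
            "verdict": verdict,
        }
    )
    probes = pd.DataFrame(columns=["probe_id", "reason"])
    return QCReport(samples=samples, probes=probes)


def probe_filter(
    matrix: BetaMatrix,
    annotation: ProbeAnnotation,
    retained_samples,
) -> tuple[BetaMatrix, pd.DataFrame]:
    """Keep autosomal probes with complete data across the retained arrays.

    Returns the filtered matrix (restricted to ``retained_samples``) and a
    table of dropped probes with a single reason each (``sex_chromosome``
    takes precedence over ``incomplete``).  Surviving values are passed
    through untouched.
    """
    retained_samples = list(retained_samples)
    unknown = set(retained_samples) - set(matrix.sample_ids)
    if unknown:
        raise ValueError(f"retained samples not in matrix: {sorted(unknown)}")
    orphans = annotation.missing_probes(matrix)
    if orphans:
        raise ValidationError(
            f"{len(orphans)} probe(s) lack annotation (cannot establish "
            f"chromosome), e.g. {orphans[:5]}"
        )
    sub = matrix.data.loc[:, retained_samples]
    chrom = annotation.chromosomes_for(matrix.probe_ids)
    on_sex = chrom.isin(SEX_CHROMOSOMES).to_numpy()
    incomplete = sub.isna().any(axis=1).to_numpy()
    reason = np.where(on_sex, "sex_chromosome", np.where(incomplete, "incomplete", ""))
    dropped = pd.DataFrame(
        {"probe_id": matrix.probe_ids[reason != ""], "reason": reason[reason != ""]}
    ).reset_index(drop=True)
    kept = sub.loc[reason == ""]
    return BetaMatrix(kept.copy()), dropped


def quantile_normalize(matrix: BetaMatrix) -> BetaMatrix:
    """Force every sample onto the mean-of-order-statistics distribution.

    After normalization each sample's sorted values equal the across-sample
    mean of sorted values, and within-sample rank order is preserved.  Tied
    values within a sample receive the mean of the order-statistic means
    they jointly occupy (average-rank convention), which keeps the
    transform deterministic and idempotent.
    """
    df = matrix.data
    vals = df.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("quantile normalization requires a complete matrix; run probe_filter first")
    if vals.shape[0] == 0:
        return BetaMatrix(df.copy())
    target = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(col)
        assigned[order] = target
        # average within tied groups of the original values
        s = pd.Series(assigned)
        out[:, j] = s.groupby(col).transform("mean").to_numpy()
    return BetaMatrix(pd.DataFrame(out, index=df.index, columns=df.columns))
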