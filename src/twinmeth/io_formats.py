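"""On-disk formats and validated in-memory containers.

Three inputs drive the pipeline:

* **Beta matrix** — probes x samples TSV of methylation proportions in
  [0, 1]; empty cells (or a declared sentinel) mark missing scores, which
  are held as NaN in memory.  No imputation happens anywhere: missing
  values are only ever dropped.
* **Sample sheet** — CSV mapping each array to a subject, an optional
  twin pair, an affected/unaffected status and a cohort.  The sheet is
  the single source of grouping truth; column order in data files carries
  no meaning.
* **Probe annotation** — TSV of probe, chromosome, 1-based CpG position
  and gene symbol (BED-like layout but 1-based, matching array-manifest
  convention).  All genomic distances are absolute differences of CpG
  positions.

For control twin pairs (both co-twins healthy) the ``status`` column
records the arbitrary but fixed index-co-twin assignment: ``affected``
marks the index co-twin whose value enters intra-pair differences with a
positive sign.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__

__all__ = [
    "BetaMatrix",
    "SampleSheet",
    "ProbeAnnotation",
    "FormatError",
    "ValidationError",
    "COHORTS",
    "TWIN_COHORTS",
    "SINGLETON_COHORTS",
    "KARYOTYPE",
    "SEX_CHROMOSOMES",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_probe_annotation",
    "write_probe_annotation",
    "write_results_table",
]


class FormatError(ValueError):
    """Raised when a file cannot be parsed into a valid container."""


class ValidationError(ValueError):
    """Raised when parsed content violates a container invariant."""


TWIN_COHORTS = ("discovery_twins", "control_twins", "replication_twins")
SINGLETON_COHORTS = ("pre_t1d", "post_t1d", "abpos_no_t1d")
COHORTS = TWIN_COHORTS + SINGLETON_COHORTS
STATUSES = ("affected", "unaffected")

KARYOTYPE = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX", "chrY")
SEX_CHROMOSOMES = ("chrX", "chrY")


# ---------------------------------------------------------------------------
# BetaMatrix
# ---------------------------------------------------------------------------

@dataclass
class BetaMatrix:
    """Probe x sample grid of methylation proportions; NaN marks missing."""

    data: pd.DataFrame  # index = probe ids, columns = sample ids, float

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise ValidationError("duplicate probe ids in beta matrix")
        if df.columns.has_duplicates:
            raise ValidationError("duplicate sample ids in beta matrix")
        vals = df.to_numpy(dtype=float)
        bad = ~np.isnan(vals) & ((vals < 0.0) | (vals > 1.0))
        if bad.any():
            raise ValidationError(
                f"{int(bad.sum())} beta value(s) outside [0, 1]"
            )
        df = df.astype(float)
        df.index = df.index.rename("probe_id")
        df.columns = df.columns.rename(None)
        self.data = df

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def values_for(self, samples) -> np.ndarray:
        return self.data.loc[:, list(samples)].to_numpy(dtype=float)

    def subset(self, probes=None, samples=None) -> "BetaMatrix":
        df = self.data
        if probes is not None:
            df = df.loc[list(probes)]
        if samples is not None:
            df = df.loc[:, list(samples)]
        return BetaMatrix(df.copy())


def read_beta_matrix(path, missing_sentinels=("", "NA", "NaN")) -> BetaMatrix:
    """Read a probes x samples TSV; first column is the probe id."""
    df = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        dtype=str,
        keep_default_na=False,
        comment="#",
    )
    if df.index.has_duplicates:
        raise FormatError("duplicate probe ids in beta matrix file")
    if df.columns.has_duplicates:
        raise FormatError("duplicate sample ids in beta matrix file")
    out = pd.DataFrame(index=df.index.astype(str), columns=df.columns.astype(str), dtype=float)
    for col in df.columns:
        raw = df[col].str.strip()
        is_missing = raw.isin(missing_sentinels)
        numeric = pd.to_numeric(raw.where(~is_missing), errors="coerce")
        bad = ~is_missing & numeric.isna()
        if bad.any():
            offending = raw[bad].iloc[0]
            raise FormatError(
                f"non-numeric cell {offending!r} in sample {col!r}"
            )
        out[col] = numeric
    try:
        return BetaMatrix(out)
    except ValidationError as exc:
        raise FormatError(str(exc)) from exc


def write_beta_matrix(matrix: BetaMatrix, path) -> None:
    """Write the TSV form; missing values become empty cells."""
    matrix.data.to_csv(path, sep="\t", index_label="probe_id", na_rep="")


# ---------------------------------------------------------------------------
# SampleSheet
# ---------------------------------------------------------------------------

SHEET_COLUMNS = ["sample_id", "subject_id", "pair_id", "status", "cohort"]


@dataclass
class SampleSheet:
    """Sample -> subject / twin-pair / cohort / status mapping."""

    table: pd.DataFrame  # columns SHEET_COLUMNS; pair_id "" for singletons

    def __post_init__(self) -> None:
        t = self.table.copy()
        missing_cols = [c for c in SHEET_COLUMNS if c not in t.columns]
        if missing_cols:
            raise ValidationError(f"sample sheet missing columns {missing_cols}")
        t = t[SHEET_COLUMNS].astype(str)
        t["pair_id"] = t["pair_id"].replace({"nan": "", "<NA>": ""})
        if t["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample ids in sample sheet")
        bad_cohort = set(t["cohort"]) - set(COHORTS)
        if bad_cohort:
            raise ValidationError(f"unknown cohort label(s): {sorted(bad_cohort)}")
        bad_status = set(t["status"]) - set(STATUSES)
        if bad_status:
            raise ValidationError(f"unknown status label(s): {sorted(bad_status)}")
        for cohort in TWIN_COHORTS:
            sub = t[t["cohort"] == cohort]
            if (sub["pair_id"] == "").any():
                raise ValidationError(f"{cohort} sample without a pair_id")
            for pair_id, grp in sub.groupby("pair_id"):
                statuses = sorted(grp["status"])
                if statuses != ["affected", "unaffected"]:
                    raise ValidationError(
                        f"pair {pair_id!r} in {cohort} must have exactly one "
                        f"affected and one unaffected member, got {statuses}"
                    )
        self.table = t.reset_index(drop=True)

    def samples(self, cohort: str) -> list[str]:
        return list(self.table.loc[self.table["cohort"] == cohort, "sample_id"])

    def pairs(self, cohort: str) -> pd.DataFrame:
        """One row per pair: pair_id, affected sample, unaffected sample."""
        if cohort not in TWIN_COHORTS:
            raise ValueError(f"{cohort!r} is not a twin cohort")
        sub = self.table[self.table["cohort"] == cohort]
        rows = []
        for pair_id, grp in sub.groupby("pair_id", sort=True):
            by = grp.set_index("status")["sample_id"]
            rows.append(
                {
                    "pair_id": pair_id,
                    "affected": by["affected"],
                    "unaffected": by["unaffected"],
                }
            )
        return pd.DataFrame(rows, columns=["pair_id", "affected", "unaffected"])

    def pre_post_subjects(self) -> pd.DataFrame:
        """One row per subject with exactly one pre and one post sample."""
        pre = self.table[self.table["cohort"] == "pre_t1d"]
        post = self.table[self.table["cohort"] == "post_t1d"]
        merged = pre.merge(
            post, on="subject_id", suffixes=("_pre", "_post"), how="outer"
        )
        unpaired = merged["sample_id_pre"].isna() | merged["sample_id_post"].isna()
        if unpaired.any():
            subjects = sorted(merged.loc[unpaired, "subject_id"])
            raise ValidationError(f"subjects without both pre and post samples: {subjects}")
        counts = pre.groupby("subject_id").size()
        if (counts != 1).any() or (post.groupby("subject_id").size() != 1).any():
            raise ValidationError("each subject must have exactly one pre and one post sample")
        return merged[["subject_id", "sample_id_pre", "sample_id_post"]].rename(
            columns={"sample_id_pre": "pre", "sample_id_post": "post"}
        )


def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    try:
        return SampleSheet(df)
    except ValidationError:
        raise


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ProbeAnnotation
# ---------------------------------------------------------------------------

@dataclass
class ProbeAnnotation:
    """Probe genomic placement: chromosome, 1-based CpG position, gene."""

    table: pd.DataFrame  # columns probe_id, chromosome, position, gene_symbol
    karyotype: tuple = field(default=KARYOTYPE)

    def __post_init__(self) -> None:
        t = self.table.copy()
        required = ["probe_id", "chromosome", "position", "gene_symbol"]
        missing_cols = [c for c in required if c not in t.columns]
        if missing_cols:
            raise ValidationError(f"annotation missing columns {missing_cols}")
        t = t[required]
        if t["probe_id"].duplicated().any():
            raise ValidationError("duplicate probe ids in annotation")
        t["position"] = pd.to_numeric(t["position"], errors="raise").astype(int)
        if (t["position"] < 1).any():
            raise ValidationError("annotation positions must be >= 1 (1-based)")
        bad = set(t["chromosome"]) - set(self.karyotype)
        if bad:
            raise ValidationError(f"chromosome(s) outside karyotype: {sorted(bad)}")
        self.table = t.reset_index(drop=True)

    @property
    def probe_ids(self) -> pd.Index:
        return pd.Index(self.table["probe_id"])

    def chromosomes_for(self, probes) -> pd.Series:
        lookup = self.table.set_index("probe_id")["chromosome"]
        return lookup.reindex(list(probes))

    def missing_probes(self, matrix: BetaMatrix) -> list[str]:
        """Probes present in a beta matrix but absent from the annotation."""
        return sorted(set(matrix.probe_ids) - set(self.table["probe_id"]))


def read_probe_annotation(path) -> ProbeAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    return ProbeAnnotation(df)


def write_probe_annotation(annotation: ProbeAnnotation, path) -> None:
    annotation.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# results tables
# ---------------------------------------------------------------------------

def write_results_table(df: pd.DataFrame, path, seed=None, index: bool = False) -> None:
    """TSV with a comment line recording the pipeline version and seed."""
    buf = io.StringIO()
    buf.write(f"# twinmeth {__version__} seed={seed}\n")
    df.to_csv(buf, sep="\t", index=index)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
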