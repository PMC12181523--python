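"""Readers and writers for every external artifact of the pipeline.

Formats handled here:

* episode-level sleep logs — headered delimited table (comma by default,
  tab accepted) with one device-logged sleep episode per row;
* Olink-style long-format NPX tables (sample, panel, assay, protein, NPX
  on the log2 scale, QC flag), pivoted to a participants x assays matrix
  after QC exclusion;
* covariate tables (age, sex, BMI, steps, comorbidities, cystatin C);
* gene-set collections in the standard GMT dialect;
* association result tables (TSV).

All timestamps are naive wall-clock local time at minute resolution:
the cohort is single-site Japanese (no DST), and a minute is the device's
time quantum, so sub-minute inputs are rejected rather than rounded.
"""

from __future__ import annotations

import csv
import io as _stdio
import warnings
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PANELS",
    "SleepEpisode",
    "CovariateRow",
    "GeneSet",
    "NPXMatrix",
    "EpisodeLogError",
    "read_episode_log",
    "write_episode_log",
    "read_npx_long",
    "pivot_npx",
    "write_npx_long",
    "read_covariates",
    "write_covariates",
    "read_gmt",
    "write_gmt",
    "write_results_table",
    "read_results_table",
]

#: The four Olink Target 96 panels used by the study (92 assays each).
PANELS = ("CVD-II", "CVD-III", "Inflammation", "Metabolism")

#: Covariates entering every adjusted model, in canonical column order.
COVARIATE_COLUMNS = (
    "age",
    "sex",
    "bmi",
    "avg_steps",
    "metabolic_disease",
    "hypertension",
    "arrhythmia_hf",
    "cystatin_c",
)

EPISODE_COLUMNS = (
    "participant_id",
    "start",
    "end",
    "light_min",
    "deep_min",
    "rem_min",
    "awake_min",
)

NPX_COLUMNS = ("SampleID", "Panel", "Assay", "Protein", "NPX", "QC_Warning")

RESULT_COLUMNS = (
    "assay_id",
    "protein_id",
    "outcome",
    "beta",
    "se",
    "t_moderated",
    "p",
    "q",
    "direction",
)

#: Minimum episode span the wearable emits (it logs episodes of >= 1 h).
DEVICE_MIN_SPAN_MIN = 60


class EpisodeLogError(ValueError):
    """Malformed or invariant-violating episode-log content."""


@dataclass(frozen=True)
class SleepEpisode:
    """One continuous device-logged sleep period with per-stage minutes.

    Stage minutes (light/deep/REM/awake) must tile the wall-clock span
    exactly; total sleep time (TST) is the span minus awake minutes.
    """

    participant_id: str
    start: datetime
    end: datetime
    light_min: int
    deep_min: int
    rem_min: int
    awake_min: int

    def __post_init__(self) -> None:
        for name in ("light_min", "deep_min", "rem_min", "awake_min"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        for name in ("start", "end"):
            ts = getattr(self, name)
            if ts.second or ts.microsecond:
                raise ValueError(
                    f"{name}={ts.isoformat()} has sub-minute resolution; "
                    "episode timestamps are minute-quantized"
                )
        if self.end <= self.start:
            raise ValueError(
                f"episode end {self.end.isoformat()} not after start "
                f"{self.start.isoformat()}"
            )
        if self.stage_sum != self.span_min:
            raise ValueError(
                f"stage minutes sum to {self.stage_sum} but span is "
                f"{self.span_min} min for episode starting {self.start.isoformat()}"
            )

    @property
    def span_min(self) -> int:
        return int((self.end - self.start).total_seconds() // 60)

    @property
    def stage_sum(self) -> int:
        return self.light_min + self.deep_min + self.rem_min + self.awake_min

    @property
    def tst_min(self) -> int:
        """Total sleep time: asleep stages only, awake excluded."""
        return self.light_min + self.deep_min + self.rem_min


@dataclass(frozen=True)
class CovariateRow:
    """Complete-case covariates for one participant."""

    participant_id: str
    age: float
    sex: int  # 1 = female
    bmi: float
    avg_steps: float
    metabolic_disease: int
    hypertension: int
    arrhythmia_hf: int
    cystatin_c: float


@dataclass(frozen=True)
class GeneSet:
    """A named term with its member protein/gene identifiers."""

    term_id: str
    term_name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.term_id!r} is empty")


@dataclass
class NPXMatrix:
    """Participants x assays log2 NPX with per-assay panel/protein metadata.

    ``values`` is indexed by sample/participant id with one column per
    assay_id; cells are NaN where the measurement carried a QC warning.
    ``assays`` maps assay_id -> (panel, protein_id); two assays from
    different panels may share a protein_id.
    """

    values: pd.DataFrame
    assays: pd.DataFrame  # index assay_id; columns panel, protein_id

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.assays.index):
            raise ValueError("values columns and assay metadata out of sync")

    @property
    def participants(self) -> list[str]:
        return list(self.values.index)

    @property
    def assay_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def protein_ids(self) -> list[str]:
        """Distinct proteins measured (assays on two panels collapse)."""
        return sorted(set(self.assays["protein_id"]))

    def nonmissing_counts(self) -> pd.Series:
        return self.values.notna().sum(axis=0)

    def usable_assays(self, n_coef: int) -> list[str]:
        """Assays with at least ``n_coef + 3`` non-missing samples."""
        counts = self.nonmissing_counts()
        return list(counts.index[counts >= n_coef + 3])


# ---------------------------------------------------------------------------
# episode logs
# ---------------------------------------------------------------------------


def _sniff_delimiter(first_line: str) -> str:
    return "\t" if "\t" in first_line else ","


def _parse_minute_timestamp(text: str, line_no: int, path) -> datetime:
    try:
        ts = datetime.fromisoformat(text.strip())
    except ValueError as exc:
        raise EpisodeLogError(
            f"{path}, line {line_no}: malformed timestamp {text!r} ({exc})"
        ) from None
    if ts.second or ts.microsecond:
        raise EpisodeLogError(
            f"{path}, line {line_no}: timestamp {text!r} has sub-minute "
            "resolution; minute quantization is required"
        )
    if ts.tzinfo is not None:
        raise EpisodeLogError(
            f"{path}, line {line_no}: timestamp {text!r} carries a timezone; "
            "logs are naive local time"
        )
    return ts


def read_episode_log(
    path, *, min_span_min: int = DEVICE_MIN_SPAN_MIN
) -> list[SleepEpisode]:
    """Parse an episode log into validated :class:`SleepEpisode` records.

    Rows are returned sorted by (participant_id, start). Each record must
    satisfy the device invariants: stage minutes tile the span and the span
    is at least ``min_span_min`` minutes.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        first = fh.readline()
        if not first:
            raise EpisodeLogError(f"{path}: empty file, header row required")
        delim = _sniff_delimiter(first)
        header = [c.strip() for c in first.rstrip("\n").split(delim)]
        if header != list(EPISODE_COLUMNS):
            raise EpisodeLogError(
                f"{path}: header {header} does not match expected "
                f"{list(EPISODE_COLUMNS)}"
            )
        episodes: list[SleepEpisode] = []
        for line_no, row in enumerate(csv.reader(fh, delimiter=delim), start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(EPISODE_COLUMNS):
                raise EpisodeLogError(
                    f"{path}, line {line_no}: expected "
                    f"{len(EPISODE_COLUMNS)} fields, got {len(row)}"
                )
            pid = row[0].strip()
            start = _parse_minute_timestamp(row[1], line_no, path)
            end = _parse_minute_timestamp(row[2], line_no, path)
            try:
                stages = [int(c) for c in row[3:7]]
            except ValueError:
                raise EpisodeLogError(
                    f"{path}, line {line_no}: stage minutes must be integers, "
                    f"got {row[3:7]}"
                ) from None
            try:
                ep = SleepEpisode(pid, start, end, *stages)
            except ValueError as exc:
                raise EpisodeLogError(f"{path}, line {line_no}: {exc}") from None
            if ep.span_min < min_span_min:
                raise EpisodeLogError(
                    f"{path}, line {line_no}: episode span {ep.span_min} min "
                    f"below device minimum of {min_span_min} min"
                )
            episodes.append(ep)
    episodes.sort(key=lambda e: (e.participant_id, e.start))
    return episodes


def write_episode_log(episodes: Iterable[SleepEpisode], path, *, delimiter=",") -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(EPISODE_COLUMNS)
        for ep in episodes:
            w.writerow(
                [
                    ep.participant_id,
                    ep.start.isoformat(timespec="minutes"),
                    ep.end.isoformat(timespec="minutes"),
                    ep.light_min,
                    ep.deep_min,
                    ep.rem_min,
                    ep.awake_min,
                ]
            )


# ---------------------------------------------------------------------------
# NPX long tables
# ---------------------------------------------------------------------------


def read_npx_long(path) -> tuple[NPXMatrix, dict]:
    """Read a long-format NPX table, drop QC-warned measurements, pivot.

    Returns the pivoted :class:`NPXMatrix` (missing cells where
    measurements were excluded) and an exclusion report with per-assay
    dropped counts and the assays removed entirely because every
    measurement was flagged.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    return pivot_npx(df, source=str(path))


def pivot_npx(df: pd.DataFrame, *, source: str = "<records>") -> tuple[NPXMatrix, dict]:
    """QC-filter and pivot an in-memory long NPX table (see read_npx_long)."""
    path = source
    missing = [c for c in NPX_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing NPX columns {missing}")
    bad_panels = sorted(set(df["Panel"]) - set(PANELS))
    if bad_panels:
        raise ValueError(f"{path}: unknown panel labels {bad_panels}")
    dup = df.duplicated(subset=["SampleID", "Assay"])
    if dup.any():
        pairs = df.loc[dup, ["SampleID", "Assay"]].head(5).values.tolist()
        raise ValueError(f"{path}: duplicate (sample, assay) pairs, e.g. {pairs}")
    qc = df["QC_Warning"].astype(str).str.upper()
    bad_flags = sorted(set(qc) - {"PASS", "WARN"})
    if bad_flags:
        raise ValueError(f"{path}: QC_Warning values must be PASS/WARN, got {bad_flags}")
    flagged = qc == "WARN"

    meta = (
        df[["Assay", "Panel", "Protein"]]
        .drop_duplicates("Assay")
        .set_index("Assay")
        .rename(columns={"Panel": "panel", "Protein": "protein_id"})
    )
    conflicting = df.groupby("Assay")[["Panel", "Protein"]].nunique()
    if (conflicting > 1).any().any():
        bad = conflicting.index[(conflicting > 1).any(axis=1)].tolist()
        raise ValueError(f"{path}: inconsistent panel/protein metadata for {bad}")

    kept = df.loc[~flagged]
    dropped_per_assay = (
        df.loc[flagged].groupby("Assay").size().astype(int).to_dict()
    )
    wide = kept.pivot(index="SampleID", columns="Assay", values="NPX")
    # keep every sample that appears anywhere in the file
    wide = wide.reindex(index=sorted(df["SampleID"].unique()))
    all_dropped = [a for a in meta.index if a not in wide.columns or wide[a].isna().all()]
    wide = wide.reindex(columns=[a for a in meta.index if a not in all_dropped])
    meta = meta.loc[wide.columns]
    report = {
        "n_input_records": int(len(df)),
        "n_kept_records": int(len(kept)),
        "n_dropped_records": int(flagged.sum()),
        "dropped_per_assay": dropped_per_assay,
        "assays_removed": all_dropped,
    }
    return NPXMatrix(values=wide, assays=meta), report


def write_npx_long(records: pd.DataFrame, path) -> None:
    """Write a long-format NPX table (columns as in ``NPX_COLUMNS``)."""
    missing = [c for c in NPX_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records missing columns {missing}")
    records.loc[:, NPX_COLUMNS].to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------


def read_covariates(path) -> pd.DataFrame:
    """Read the covariate table; complete cases are required downstream."""
    df = pd.read_csv(path, sep=None, engine="python")
    cols = ["participant_id", *COVARIATE_COLUMNS]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing covariate columns {missing}")
    df = df[cols].set_index("participant_id")
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)].tolist()
        raise ValueError(f"{path}: missing covariate values for {bad}")
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate participant ids")
    for c in ("sex", "metabolic_disease", "hypertension", "arrhythmia_hf"):
        if not df[c].isin([0, 1]).all():
            raise ValueError(f"{path}: column {c} must be binary 0/1")
    return df


def write_covariates(cov: pd.DataFrame, path) -> None:
    # full repr precision so a read round-trips bit-identically
    cov.to_csv(path, index=True, index_label="participant_id")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT file: term, description, then tab-separated genes.

    Genes are uppercased and deduplicated within a line; empty lines are
    skipped with a warning; file order is preserved.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                warnings.warn(f"{path}, line {line_no}: empty line skipped")
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}, line {line_no}: GMT lines need >= 3 tab-separated "
                    f"fields (term, description, genes), got {len(fields)}"
                )
            genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            sets.append(GeneSet(term_id=fields[0], term_name=fields[1], genes=genes))
    return sets


def write_gmt(genesets: Sequence[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in genesets:
            fh.write("\t".join([gs.term_id, gs.term_name, *sorted(gs.genes)]) + "\n")


# ---------------------------------------------------------------------------
# association result tables
# ---------------------------------------------------------------------------


def write_results_table(results, path) -> None:
    """Write association results as TSV ordered by ascending p-value."""
    rows = [
        {
            "assay_id": r.assay_id,
            "protein_id": r.protein_id,
            "outcome": r.outcome,
            "beta": r.beta_sleep,
            "se": r.se,
            "t_moderated": r.t_mod,
            "p": r.p,
            "q": r.q,
            "direction": r.direction,
        }
        for r in results
    ]
    if not rows:
        raise ValueError("refusing to write an empty results table")
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    df = df.sort_values(["p", "assay_id"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_results_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing result columns {missing}")
    return df
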