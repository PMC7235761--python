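"""Data model and delimited-text I/O for RT-qPCR Cq matrices and sample annotation.

A Cq (quantification cycle) matrix holds one value per (miRNA, sample) cell;
lower Cq means higher abundance.  Missingness is explicit: a cell is either
detected with a finite Cq in (0, 50) cycles, or missing (never both).  By
qPCR convention, Cq values above a configurable limit of detection (default
37 cycles) are demoted to missing on load.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_MISSING_TOKENS = frozenset({"", "NA", "Undetermined"})
DEFAULT_LOD_CQ = 37.0


class Group(str, enum.Enum):
    """Patient group labels of the five-arm cohort."""

    BPH = "BPH"
    LPC = "LPC"
    APC = "APC"
    TRUSBX_BENIGN = "TRUSBX_BENIGN"
    TRUSBX_MALIGNANT = "TRUSBX_MALIGNANT"


class Dre(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNKNOWN = "unknown"


class Finding(str, enum.Enum):
    """Tri-state pathology finding (surgical margin, SVI, ECE, LNI)."""

    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNKNOWN = "unknown"


def grade_group_from_gleason(primary: int, secondary: int) -> int:
    """ISUP grade group implied by Gleason primary+secondary patterns."""
    total = primary + secondary
    if total <= 6:
        return 1
    if (primary, secondary) == (3, 4):
        return 2
    if (primary, secondary) == (4, 3):
        return 3
    if total == 8:
        return 4
    return 5  # 9-10


@dataclass
class ClinicalPathology:
    """Prostatectomy pathology fields feeding the CAPRA-S score."""

    psa_at_rp: float | None = None
    gleason_primary: int | None = None
    gleason_secondary: int | None = None
    t_stage: str | None = None  # "T1".."T4"
    gleason_grade_group: int | None = None
    sm: Finding = Finding.UNKNOWN
    svi: Finding = Finding.UNKNOWN
    ece: Finding = Finding.UNKNOWN
    lni: Finding = Finding.UNKNOWN

    def __post_init__(self) -> None:
        if self.t_stage is not None and self.t_stage not in {"T1", "T2", "T3", "T4"}:
            raise ValueError(f"invalid T stage {self.t_stage!r}")
        if self.gleason_grade_group is not None and not 1 <= self.gleason_grade_group <= 5:
            raise ValueError(f"grade group {self.gleason_grade_group} outside 1..5")
        if (
            self.gleason_primary is not None
            and self.gleason_secondary is not None
            and self.gleason_grade_group is not None
        ):
            implied = grade_group_from_gleason(self.gleason_primary, self.gleason_secondary)
            if implied != self.gleason_grade_group:
                raise ValueError(
                    f"grade group {self.gleason_grade_group} inconsistent with Gleason "
                    f"{self.gleason_primary}+{self.gleason_secondary} (implies {implied})"
                )


@dataclass
class SurvivalRecord:
    """Biochemical-recurrence follow-up (event = post-RP PSA >= 0.2 ng/mL)."""

    bcr_event: bool
    time_months: float

    def __post_init__(self) -> None:
        if not self.time_months > 0:
            raise ValueError("follow-up time must be > 0 months")


@dataclass
class SampleRecord:
    sample_id: str
    group: Group
    batch: str = "1"
    psa: float | None = None  # ng/mL, None = unknown
    dre: Dre = Dre.UNKNOWN
    age: float | None = None
    pathology: ClinicalPathology | None = None
    survival: SurvivalRecord | None = None

    def __post_init__(self) -> None:
        self.group = Group(self.group)
        self.dre = Dre(self.dre)
        if self.psa is not None and self.psa < 0:
            raise ValueError(f"negative PSA for {self.sample_id}")


@dataclass
class CqMatrix:
    """miRNA x sample matrix of Cq values; NaN cells are missing (undetected).

    ``values`` is a float DataFrame indexed by miRNA id with sample-id columns.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate miRNA ids: {dups}")
        if v.columns.duplicated().any():
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        arr = v.to_numpy(dtype=float)
        det = np.isfinite(arr)
        bad = det & ((arr <= 0) | (arr >= 50))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValueError(
                f"Cq out of (0, 50) at ({v.index[i]}, {v.columns[j]}): {arr[i, j]}"
            )

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def detected(self) -> pd.DataFrame:
        return self.values.notna()

    def detection_rates(self, sample_ids: list[str] | None = None) -> pd.Series:
        """Fraction of samples in which each miRNA is detected."""
        v = self.values if sample_ids is None else self.values[sample_ids]
        return v.notna().mean(axis=1)

    def subset_samples(self, sample_ids: list[str]) -> "CqMatrix":
        return CqMatrix(self.values[list(sample_ids)].copy())

    def write(self, path: str | Path, sep: str = "\t", missing_token: str = "NA") -> None:
        df = self.values.copy()
        df.index.name = "mirna_id"
        df.to_csv(path, sep=sep, na_rep=missing_token, float_format="%.10g")


@dataclass
class NormalizedMatrix:
    """miRNA x sample matrix of dCq values (reference-normalized, log2 scale).

    dCq = mean(reference Cqs) - target Cq, so higher dCq means more abundant.
    NaN cells are missing.
    """

    values: pd.DataFrame
    reference_pair: tuple[str, str] | None = None

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, sample_ids: list[str]) -> "NormalizedMatrix":
        return NormalizedMatrix(self.values[list(sample_ids)].copy(), self.reference_pair)

    def write(self, path: str | Path, sep: str = "\t", missing_token: str = "NA") -> None:
        df = self.values.copy()
        df.index.name = "mirna_id"
        df.to_csv(path, sep=sep, na_rep=missing_token, float_format="%.10g")


def _sniff_sep(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_cq_table(
    path: str | Path,
    missing_tokens: frozenset[str] | set[str] = DEFAULT_MISSING_TOKENS,
    lod_cq: float | None = DEFAULT_LOD_CQ,
) -> CqMatrix:
    """Read a delimited Cq table (first column miRNA id, header of sample ids).

    Cells matching ``missing_tokens`` become missing; any other non-numeric
    cell is an error reported with its (miRNA, sample) coordinates.  Detected
    Cq values above ``lod_cq`` are demoted to missing (pass None to disable).
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = _sniff_sep(header)
    # pandas mangles duplicate header fields; check them verbatim first
    fields = [f.strip() for f in header.rstrip("\n").split(sep)][1:]
    dup = sorted({f for f in fields if fields.count(f) > 1})
    if dup:
        raise ValueError(f"duplicate sample ids in header: {dup}")
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str).str.strip()
    raw.index.name = None
    raw.columns = raw.columns.astype(str).str.strip()

    def parse_cell(token: str, mirna: str, sample: str) -> float:
        token = token.strip()
        if token in missing_tokens:
            return math.nan
        try:
            return float(token)
        except ValueError:
            raise ValueError(
                f"non-numeric Cq at ({mirna}, {sample}): {token!r}"
            ) from None

    data = np.empty(raw.shape, dtype=float)
    for i, mirna in enumerate(raw.index):
        for j, sample in enumerate(raw.columns):
            data[i, j] = parse_cell(raw.iat[i, j], mirna, sample)
    if lod_cq is not None:
        data[data > lod_cq] = math.nan
    return CqMatrix(pd.DataFrame(data, index=raw.index, columns=raw.columns))


def read_normalized_table(path: str | Path) -> NormalizedMatrix:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = _sniff_sep(header)
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA"], keep_default_na=False)
    df.index.name = None
    return NormalizedMatrix(df.astype(float))


_SAMPLE_COLUMNS = {"sample_id", "group"}
_PATHOLOGY_COLUMNS = {
    "psa_at_rp",
    "gleason_primary",
    "gleason_secondary",
    "t_stage",
    "gleason_grade_group",
    "sm",
    "svi",
    "ece",
    "lni",
}


def _opt_float(token: str) -> float | None:
    token = token.strip()
    if token in DEFAULT_MISSING_TOKENS:
        return None
    return float(token)


def _opt_int(token: str) -> int | None:
    v = _opt_float(token)
    return None if v is None else int(v)


def _finding(token: str) -> Finding:
    token = token.strip().lower()
    if token in ("", "na", "unknown"):
        return Finding.UNKNOWN
    if token in ("positive", "pos", "1", "true"):
        return Finding.POSITIVE
    if token in ("negative", "neg", "0", "false"):
        return Finding.NEGATIVE
    raise ValueError(f"unrecognized finding token {token!r}")


def read_sample_table(path: str | Path) -> list[SampleRecord]:
    """Read sample annotation; unknown tokens map to explicit unknowns.

    Required columns: sample_id, group.  Recognized optional columns: batch,
    psa, dre, age, the pathology fields, and bcr_event/bcr_months.
    An unrecognized group label is an error, never silently dropped.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = _sniff_sep(header)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]
    missing_cols = _SAMPLE_COLUMNS - set(df.columns)
    if missing_cols:
        raise ValueError(f"annotation table lacks columns: {sorted(missing_cols)}")

    records: list[SampleRecord] = []
    for _, row in df.iterrows():
        sid = row["sample_id"].strip()
        glabel = row["group"].strip()
        try:
            group = Group(glabel)
        except ValueError:
            raise ValueError(f"unrecognized group label {glabel!r} for sample {sid!r}") from None

        dre = Dre.UNKNOWN
        if "dre" in df.columns:
            tok = row["dre"].strip().lower()
            if tok in ("positive", "negative"):
                dre = Dre(tok)
            elif tok not in ("", "na", "unknown"):
                raise ValueError(f"unrecognized DRE token {tok!r} for sample {sid!r}")

        pathology = None
        present = [c for c in _PATHOLOGY_COLUMNS if c in df.columns and row[c].strip() not in DEFAULT_MISSING_TOKENS]
        if present:
            pathology = ClinicalPathology(
                psa_at_rp=_opt_float(row.get("psa_at_rp", "")),
                gleason_primary=_opt_int(row.get("gleason_primary", "")),
                gleason_secondary=_opt_int(row.get("gleason_secondary", "")),
                t_stage=row.get("t_stage", "").strip() or None,
                gleason_grade_group=_opt_int(row.get("gleason_grade_group", "")),
                sm=_finding(row.get("sm", "")),
                svi=_finding(row.get("svi", "")),
                ece=_finding(row.get("ece", "")),
                lni=_finding(row.get("lni", "")),
            )

        survival = None
        if "bcr_event" in df.columns and row["bcr_event"].strip() not in DEFAULT_MISSING_TOKENS:
            survival = SurvivalRecord(
                bcr_event=row["bcr_event"].strip() in ("1", "true", "True"),
                time_months=float(row["bcr_months"]),
            )

        records.append(
            SampleRecord(
                sample_id=sid,
                group=group,
                batch=(row.get("batch", "") or "1").strip() or "1",
                psa=_opt_float(row.get("psa", "")),
                dre=dre,
                age=_opt_float(row.get("age", "")),
                pathology=pathology,
                survival=survival,
            )
        )
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({s for s in ids if ids.count(s) > 1})
        raise ValueError(f"duplicate sample ids in annotation: {dup}")
    return records


def write_sample_table(records: list[SampleRecord], path: str | Path, sep: str = "\t") -> None:
    rows = []
    for r in records:
        p = r.pathology
        s = r.survival
        rows.append(
            {
                "sample_id": r.sample_id,
                "group": r.group.value,
                "batch": r.batch,
                "psa": "" if r.psa is None else f"{r.psa:.10g}",
                "dre": r.dre.value if r.dre != Dre.UNKNOWN else "",
                "age": "" if r.age is None else f"{r.age:.10g}",
                "psa_at_rp": "" if p is None or p.psa_at_rp is None else f"{p.psa_at_rp:.10g}",
                "gleason_primary": "" if p is None or p.gleason_primary is None else p.gleason_primary,
                "gleason_secondary": "" if p is None or p.gleason_secondary is None else p.gleason_secondary,
                "t_stage": "" if p is None or p.t_stage is None else p.t_stage,
                "gleason_grade_group": "" if p is None or p.gleason_grade_group is None else p.gleason_grade_group,
                "sm": "" if p is None else p.sm.value,
                "svi": "" if p is None else p.svi.value,
                "ece": "" if p is None else p.ece.value,
                "lni": "" if p is None else p.lni.value,
                "bcr_event": "" if s is None else int(s.bcr_event),
                "bcr_months": "" if s is None else f"{s.time_months:.10g}",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


@dataclass
class ValidationReport:
    """Report-only cohort consistency check (never raises)."""

    samples_without_annotation: list[str] = field(default_factory=list)
    annotations_without_sample: list[str] = field(default_factory=list)
    detection_rates: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    group_counts: dict[str, int] = field(default_factory=dict)
    undetected_mirnas: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.samples_without_annotation and not self.annotations_without_sample


def validate_cohort(cq: CqMatrix, samples: list[SampleRecord]) -> ValidationReport:
    ann_ids = {r.sample_id for r in samples}
    mat_ids = set(cq.sample_ids)
    rates = cq.detection_rates()
    counts: dict[str, int] = {}
    for r in samples:
        counts[r.group.value] = counts.get(r.group.value, 0) + 1
    return ValidationReport(
        samples_without_annotation=sorted(mat_ids - ann_ids),
        annotations_without_sample=sorted(ann_ids - mat_ids),
        detection_rates=rates,
        group_counts=counts,
        undetected_mirnas=sorted(rates.index[rates == 0.0]),
    )
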