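"""Reading, deduplicating, and joining FAERS-style report tables.

FAERS quarterly extracts are dollar-sign-delimited ASCII tables.  Three of
them feed this analysis: DEMO (one row per report version, with patient
age, age unit, and gender), DRUG (one row per drug mention), and REAC (one
row per adverse-event preferred term).  Reports are identified by a
``primaryid``; a case may be re-submitted, producing several versions that
share a ``caseid``.

The analysis table ("Table A") is the inner join of the deduplicated
tables on the report identifier, carrying per-report taste/smell flags.
The demographic table ("Table B") restricts to antineoplastic-exposed
reports with a usable age in years and a known gender.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import SchemaError
from .vocab import SmqTermSet, TASTE_SMELL_SMQ, normalize_term

FAERS_DELIMITER = "$"

#: Logical field -> candidate source columns, per table kind.
_SCHEMAS: dict[str, dict[str, tuple[str, ...]]] = {
    "DEMO": {
        "primary_id": ("primaryid",),
        "case_id": ("caseid",),
        "case_version": ("caseversion",),
        "age_value": ("age",),
        "age_unit": ("age_cod",),
        "gender": ("sex", "gndr_cod"),
    },
    "DRUG": {
        "primary_id": ("primaryid",),
        "generic_name": ("drugname", "prod_ai", "generic_name"),
    },
    "REAC": {
        "primary_id": ("primaryid",),
        "pt_name": ("pt",),
    },
}

#: Optional fields that are carried through when present.
_OPTIONAL: dict[str, dict[str, tuple[str, ...]]] = {
    "DEMO": {},
    "DRUG": {},
    "REAC": {"pt_code": ("pt_cod", "pt_code")},
}

#: Recognised FAERS age-unit codes.
AGE_UNITS = {"YR", "DEC", "MON", "WK", "DY", "HR"}

_GENDER_MAP = {"M": "M", "F": "F", "MALE": "M", "FEMALE": "F", "UNK": "UNK", "NS": "UNK"}


def read_faers_table(path: str | Path, kind: str) -> pd.DataFrame:
    """Read one FAERS-dialect table into a typed, normalized DataFrame.

    Parameters
    ----------
    path:
        A ``$``-delimited text file with a header row.
    kind:
        ``"DEMO"``, ``"DRUG"``, or ``"REAC"``.

    Unparseable numeric fields become missing rather than raising; drug
    and PT names are normalized (case-folded, trimmed, whitespace
    collapsed).  A missing required column raises :class:`SchemaError`
    naming the column; an empty file yields an empty frame with a warning.
    """
    kind = kind.upper()
    if kind not in _SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}; expected DEMO, DRUG, or REAC")
    try:
        raw = pd.read_csv(path, sep=FAERS_DELIMITER, dtype=str, keep_default_na=False,
                          engine="python")
    except pd.errors.EmptyDataError:
        raw = pd.DataFrame()
    columns = {c.strip().lower(): c for c in raw.columns}

    out = pd.DataFrame()
    for logical, candidates in _SCHEMAS[kind].items():
        source = next((columns[c] for c in candidates if c in columns), None)
        if source is None:
            if raw.empty and not raw.columns.size:
                out[logical] = pd.Series(dtype=object)
                continue
            raise SchemaError(
                f"{kind} table {path} is missing required column "
                f"{'/'.join(candidates)!r} (for field {logical!r})"
            )
        out[logical] = raw[source]
    for logical, candidates in _OPTIONAL[kind].items():
        source = next((columns[c] for c in candidates if c in columns), None)
        if source is not None:
            out[logical] = raw[source]

    if out.empty:
        warnings.warn(f"{kind} table {path} contains no data rows", stacklevel=2)

    return _coerce_fields(out, kind)


def _coerce_fields(df: pd.DataFrame, kind: str) -> pd.DataFrame:
    df = df.copy()
    df["primary_id"] = df["primary_id"].astype(str).str.strip()
    if kind == "DEMO":
        df["case_id"] = df["case_id"].astype(str).str.strip()
        df["case_version"] = (
            pd.to_numeric(df["case_version"], errors="coerce").fillna(0).astype(int)
        )
        df["age_value"] = pd.to_numeric(df["age_value"], errors="coerce")
        unit = df["age_unit"].astype(str).str.strip().str.upper()
        df["age_unit"] = unit.where(unit.isin(AGE_UNITS))
        gender = df["gender"].astype(str).str.strip().str.upper()
        df["gender"] = gender.map(_GENDER_MAP)
    elif kind == "DRUG":
        df["generic_name"] = df["generic_name"].map(normalize_term)
        df = df[df["generic_name"] != ""]
    elif kind == "REAC":
        df["pt_name"] = df["pt_name"].map(normalize_term)
        df = df[df["pt_name"] != ""]
        if "pt_code" in df.columns:
            df["pt_code"] = pd.to_numeric(df["pt_code"], errors="coerce")
    return df.reset_index(drop=True)


def deduplicate(df: pd.DataFrame, kind: str) -> pd.DataFrame:
    """Remove duplicate content from one raw table.

    DEMO keeps exactly one row per ``case_id`` — the highest
    ``case_version``, ties broken by the lexicographically highest
    ``primary_id`` (later submissions supersede earlier ones).  DRUG and
    REAC collapse exact-duplicate rows.  Idempotent.
    """
    kind = kind.upper()
    if kind == "DEMO":
        ordered = df.sort_values(
            ["case_id", "case_version", "primary_id"], kind="mergesort"
        )
        return ordered.groupby("case_id", sort=False).tail(1).reset_index(drop=True)
    if kind in ("DRUG", "REAC"):
        return df.drop_duplicates().reset_index(drop=True)
    raise ValueError(f"unknown table kind {kind!r}")


@dataclass
class TableA:
    """The joined analysis table: reports present in DEMO, DRUG, and REAC.

    ``drugs`` and ``events`` hold the distinct (report, drug) and
    (report, PT) pairs; ``flags`` holds one row per report with
    ``has_taste`` / ``has_smell`` / ``has_tsd`` computed against the SMQ.
    """

    drugs: pd.DataFrame
    events: pd.DataFrame
    flags: pd.DataFrame
    smq: SmqTermSet = field(default=TASTE_SMELL_SMQ, repr=False)

    @property
    def report_ids(self) -> pd.Index:
        return self.flags.index

    @property
    def n_reports(self) -> int:
        return len(self.flags)

    def ids_with_drug(self, drugs: str | Iterable[str]) -> pd.Index:
        """Distinct report ids mentioning any of the given drugs."""
        if isinstance(drugs, str):
            drugs = [drugs]
        names = {normalize_term(d) for d in drugs}
        hit = self.drugs[self.drugs["generic_name"].isin(names)]
        return pd.Index(hit["primary_id"].unique())

    def ids_with_any_pt(self, pts: Iterable[str]) -> pd.Index:
        """Distinct report ids reporting any of the given PTs."""
        names = {normalize_term(p) for p in pts}
        hit = self.events[self.events["pt_name"].isin(names)]
        return pd.Index(hit["primary_id"].unique())

    def pt_report_counts(self) -> pd.Series:
        """Database-wide distinct-report count per PT (all drugs)."""
        return self.events.groupby("pt_name").size().sort_values(ascending=False)

    def drug_names(self) -> list[str]:
        return sorted(self.drugs["generic_name"].unique())

    def triples(self) -> pd.DataFrame:
        """The fully joined (primary_id, generic_name, pt_name) rows."""
        return self.drugs.merge(self.events, on="primary_id").drop_duplicates()

    def to_csv(self, path: str | Path) -> None:
        self.triples().sort_values(
            ["primary_id", "generic_name", "pt_name"]
        ).to_csv(path, index=False)


def build_table_a(
    demo: pd.DataFrame,
    drug: pd.DataFrame,
    reac: pd.DataFrame,
    smq: SmqTermSet = TASTE_SMELL_SMQ,
) -> TableA:
    """Inner-join the deduplicated tables on the report id.

    Only reports present in all three tables survive.  Per-report
    taste/smell flags use exact case-insensitive PT matching against the
    SMQ term set.
    """
    ids = (
        pd.Index(demo["primary_id"].unique())
        .intersection(pd.Index(drug["primary_id"].unique()))
        .intersection(pd.Index(reac["primary_id"].unique()))
    )
    drugs = (
        drug.loc[drug["primary_id"].isin(ids), ["primary_id", "generic_name"]]
        .assign(generic_name=lambda df: df["generic_name"].map(normalize_term))
        .drop_duplicates()
        .reset_index(drop=True)
    )
    events = (
        reac.loc[reac["primary_id"].isin(ids), ["primary_id", "pt_name"]]
        .assign(pt_name=lambda df: df["pt_name"].map(normalize_term))
        .drop_duplicates()
        .reset_index(drop=True)
    )

    flags = pd.DataFrame(index=ids.sort_values())
    flags.index.name = "primary_id"
    taste_ids = events.loc[events["pt_name"].isin(smq.taste_terms), "primary_id"]
    smell_ids = events.loc[events["pt_name"].isin(smq.smell_terms), "primary_id"]
    flags["has_taste"] = flags.index.isin(taste_ids)
    flags["has_smell"] = flags.index.isin(smell_ids)
    flags["has_tsd"] = flags["has_taste"] | flags["has_smell"]
    return TableA(drugs=drugs, events=events, flags=flags, smq=smq)


@dataclass(frozen=True)
class TsdReportCounts:
    """Partition of taste/smell-disorder reports among exposed reports.

    ``n_taste_only + n_smell_only + n_both == n_tsd_any``.
    """

    n_tsd_any: int
    n_taste_any: int
    n_taste_only: int
    n_smell_any: int
    n_smell_only: int
    n_both: int

    def __post_init__(self) -> None:
        if self.n_taste_only + self.n_smell_only + self.n_both != self.n_tsd_any:
            raise ValueError("taste-only + smell-only + both must equal total")
        if self.n_taste_any != self.n_taste_only + self.n_both:
            raise ValueError("taste-any must equal taste-only + both")
        if self.n_smell_any != self.n_smell_only + self.n_both:
            raise ValueError("smell-any must equal smell-only + both")

    def proportions(self) -> dict[str, float]:
        """Each count as a percentage of all taste-or-smell reports."""
        total = self.n_tsd_any
        if total == 0:
            return {k: float("nan") for k in
                    ("taste_any", "taste_only", "smell_any", "smell_only", "both")}
        return {
            "taste_any": 100.0 * self.n_taste_any / total,
            "taste_only": 100.0 * self.n_taste_only / total,
            "smell_any": 100.0 * self.n_smell_any / total,
            "smell_only": 100.0 * self.n_smell_only / total,
            "both": 100.0 * self.n_both / total,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n_tsd_any": self.n_tsd_any,
            "n_taste_any": self.n_taste_any,
            "n_taste_only": self.n_taste_only,
            "n_smell_any": self.n_smell_any,
            "n_smell_only": self.n_smell_only,
            "n_both": self.n_both,
            "proportions_pct": self.proportions(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def count_tsd_reports(table_a: TableA, exposure: Iterable[str]) -> TsdReportCounts:
    """Count taste/smell-disorder reports among reports exposed to any
    drug in ``exposure`` (e.g. all ATC L01 agents).

    A report counts as a case if it carries at least one SMQ PT; the
    taste-only / smell-only / both partition is over distinct reports.
    """
    exposure = set(exposure)
    if not exposure:
        raise ValueError("exposure drug set must be non-empty")
    exposed = table_a.ids_with_drug(exposure)
    f = table_a.flags.loc[table_a.flags.index.isin(exposed)]
    both = int((f["has_taste"] & f["has_smell"]).sum())
    taste_any = int(f["has_taste"].sum())
    smell_any = int(f["has_smell"].sum())
    return TsdReportCounts(
        n_tsd_any=int(f["has_tsd"].sum()),
        n_taste_any=taste_any,
        n_taste_only=taste_any - both,
        n_smell_any=smell_any,
        n_smell_only=smell_any - both,
        n_both=both,
    )


def build_table_b(
    demo: pd.DataFrame,
    drug: pd.DataFrame,
    reac: pd.DataFrame,
    l01_drugs: Iterable[str],
    smq: SmqTermSet = TASTE_SMELL_SMQ,
) -> pd.DataFrame:
    """Derive the demographic outcome table for antineoplastic-exposed reports.

    One row per report that (i) appears in all three tables, (ii) mentions
    at least one L01 drug, (iii) has age recorded in years (decade codes
    are multiplied by 10; other units are dropped, not converted) within
    [0, 120], and (iv) has a known male/female gender.  ``tsd`` flags any
    SMQ PT across the report's reactions.

    Columns: ``primary_id``, ``age_years``, ``gender``, ``tsd``.
    """
    l01 = {normalize_term(d) for d in l01_drugs}
    ids = (
        pd.Index(demo["primary_id"].unique())
        .intersection(pd.Index(drug["primary_id"].unique()))
        .intersection(pd.Index(reac["primary_id"].unique()))
    )
    exposed = pd.Index(
        drug.loc[drug["generic_name"].map(normalize_term).isin(l01), "primary_id"].unique()
    ).intersection(ids)

    d = demo.loc[demo["primary_id"].isin(exposed)].copy()
    age_years = pd.Series(np.nan, index=d.index)
    is_yr = d["age_unit"] == "YR"
    is_dec = d["age_unit"] == "DEC"
    age_years[is_yr] = d.loc[is_yr, "age_value"]
    age_years[is_dec] = d.loc[is_dec, "age_value"] * 10.0
    d["age_years"] = age_years

    keep = (
        d["age_years"].between(0.0, 120.0)
        & d["gender"].isin(["M", "F"])
    )
    d = d.loc[keep, ["primary_id", "age_years", "gender"]]
    d = d.drop_duplicates(subset="primary_id")

    tsd_ids = reac.loc[
        reac["pt_name"].map(normalize_term).isin(smq.all_terms), "primary_id"
    ].unique()
    d["tsd"] = d["primary_id"].isin(tsd_ids)
    return d.sort_values("primary_id").reset_index(drop=True)
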