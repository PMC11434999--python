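"""Shared fixtures: tiny hand-enumerable FAERS-dialect tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def write_faers_file(path: Path, header: list[str], rows: list[list]) -> Path:
    lines = ["$".join(header)] + ["$".join(str(v) for v in row) for row in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def demo_file(tmp_path):
    """Three DEMO rows: a months-coded age, a numeric age, a garbage age."""
    return write_faers_file(
        tmp_path / "DEMO.txt",
        ["primaryid", "caseid", "caseversion", "age", "age_cod", "sex"],
        [
            ["101", "10", "1", "18", "MON", "F"],
            ["201", "20", "1", "64", "YR", "M"],
            ["301", "30", "1", "abc", "YR", "F"],
        ],
    )


def demo_frame(rows):
    """Build an already-typed DEMO frame from
    (primary_id, case_id, case_version, age_value, age_unit, gender) tuples."""
    df = pd.DataFrame(
        rows,
        columns=["primary_id", "case_id", "case_version", "age_value", "age_unit", "gender"],
    )
    df["primary_id"] = df["primary_id"].astype(str)
    df["case_id"] = df["case_id"].astype(str)
    return df


def drug_frame(pairs):
    return pd.DataFrame(pairs, columns=["primary_id", "generic_name"]).astype(
        {"primary_id": str}
    )


def reac_frame(pairs):
    return pd.DataFrame(pairs, columns=["primary_id", "pt_name"]).astype(
        {"primary_id": str}
    )


@pytest.fixture
def ten_report_tables():
    """Ten reports with hand-enumerable taste/smell flags.

    Reports 1-10 all appear in DEMO, DRUG, REAC.  By construction:
    taste-only reports {1,2,3,4}, smell-only {5,6,7}, both {8,9},
    neither {10}.  Drug "alphanib" appears in reports 1-4 and 8;
    "betamab" in 5-7 and 9-10.
    """
    demo = demo_frame(
        [(str(i), str(i), 1, 50 + i, "YR", "F" if i % 2 else "M") for i in range(1, 11)]
    )
    drug = drug_frame(
        [(str(i), "alphanib") for i in (1, 2, 3, 4, 8)]
        + [(str(i), "betamab") for i in (5, 6, 7, 9, 10)]
    )
    reac = reac_frame(
        [(str(i), "dysgeusia") for i in (1, 2, 3, 4, 8, 9)]
        + [(str(i), "anosmia") for i in (5, 6, 7, 8, 9)]
        + [(str(i), "nausea") for i in (1, 5, 10)]
    )
    return demo, drug, reac
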