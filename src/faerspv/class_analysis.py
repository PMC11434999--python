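"""ATC-class-level risk analysis for antineoplastic agents.

Two views: the fraction of signal drugs within each L01 subclass, and a
class-level disproportionality where exposure means "the report mentions
at least one drug of the class".  A report exposed to several classes
counts in each class's table (tables are computed independently).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .disproportionality import (
    DEFAULT_CRITERIA,
    DisproportionalityResult,
    SignalCriteria,
    association,
    make_contingency,
)
from .errors import DegenerateDataError
from .faers_model import TableA
from .vocab import ATC_CLASSES, AtcClassMap, normalize_term


def class_signal_fraction(
    signals: Iterable[str], universe: AtcClassMap
) -> pd.DataFrame:
    """Per-class count and percentage of signal drugs among all mapped drugs.

    Returns one row per L01 subclass with ``n_signal``, ``n_total``, and
    ``percent`` (= 100 * n_signal / n_total, reported to 2 decimals;
    missing when the class maps no drugs).
    """
    signal_set = {normalize_term(s) for s in signals}
    unmapped = signal_set - universe.drugs
    if unmapped:
        raise ValueError(f"signal drugs not in the ATC map: {sorted(unmapped)}")
    rows = []
    for cls, label in ATC_CLASSES.items():
        members = universe.drugs_in_class(cls)
        n_total = len(members)
        n_signal = len(members & signal_set)
        percent = round(100.0 * n_signal / n_total, 2) if n_total else None
        rows.append(
            {"atc_class": cls, "label": label, "n_signal": n_signal,
             "n_total": n_total, "percent": percent}
        )
    return pd.DataFrame(rows).set_index("atc_class")


def class_association(
    table_a: TableA,
    atc_class: str,
    event_pts: Iterable[str],
    universe: AtcClassMap,
    criteria: SignalCriteria = DEFAULT_CRITERIA,
) -> DisproportionalityResult:
    """Disproportionality of one L01 subclass against the event PTs.

    Exposure is any report mentioning >= 1 drug of the class; the
    background is the whole of Table A, as in the per-drug screening.
    """
    members = universe.drugs_in_class(atc_class)
    present = members & set(table_a.drug_names())
    if not present:
        raise DegenerateDataError(
            f"class {atc_class} has no drugs present in Table A"
        )
    raw = make_contingency(table_a, present, event_pts)
    return association(raw, entity=atc_class, haldane=True, criteria=criteria)


def all_class_associations(
    table_a: TableA,
    event_pts: Iterable[str],
    universe: AtcClassMap,
    criteria: SignalCriteria = DEFAULT_CRITERIA,
) -> list[DisproportionalityResult]:
    """Association results for every class with >= 1 drug in Table A."""
    results = []
    for cls in ATC_CLASSES:
        try:
            results.append(
                class_association(table_a, cls, event_pts, universe, criteria)
            )
        except DegenerateDataError:
            continue
    return results


def write_class_tables(
    fraction: pd.DataFrame,
    associations: Sequence[DisproportionalityResult],
    fraction_path: str | Path,
    association_path: str | Path,
) -> None:
    fraction.to_csv(fraction_path)
    pd.DataFrame(
        {
            "atc_class": [r.entity for r in associations],
            "n_event": [r.n_event for r in associations],
            "ror": [r.ror for r in associations],
            "ci_low": [r.ci_low for r in associations],
            "ci_high": [r.ci_high for r in associations],
            "p": [r.p for r in associations],
        }
    ).to_csv(association_path, index=False)
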