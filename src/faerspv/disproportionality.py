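"""Reporting-odds-ratio disproportionality analysis on 2x2 report tables.

For a drug (or drug class, or patient stratum) and an event definition,
reports are cross-classified as

    =====================  ============  ===============
                           with event    without event
    ---------------------  ------------  ---------------
    exposed reports        a             b
    all other reports      c             d
    =====================  ============  ===============

and the reporting odds ratio is ROR = (a/b)/(c/d) = a*d / (b*c).  A
Haldane correction (+0.5 to every cell) keeps the ratio finite when a
cell is zero.  Significance is a two-sided Fisher exact test on the raw
integer counts; confidence intervals are Wald intervals on the log-odds
scale.  A drug is a signal when p < 0.05, ROR > 1, and the event was
reported at least 100 times with the drug.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractViolationError, DegenerateDataError
from .faers_model import TableA
from .vocab import normalize_term

#: Cap for -log10(p): p-values below 1e-308 underflow double precision.
NEG_LOG10_CAP = 308.0


@dataclass(frozen=True)
class ContingencyTable2x2:
    """The a/b/c/d counts with a Haldane-correction flag.

    Cells are non-negative; they are integers unless ``corrected``.
    """

    a: float
    b: float
    c: float
    d: float
    corrected: bool = False

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ValueError(f"negative cell in 2x2 table: {cells}")
        if not self.corrected and not all(float(x).is_integer() for x in cells):
            raise ValueError(f"uncorrected table must have integer cells: {cells}")

    @property
    def total(self) -> float:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    def transposed_exposure(self) -> "ContingencyTable2x2":
        """Swap the exposure rows: (a,b) <-> (c,d). Maps ROR to 1/ROR."""
        return ContingencyTable2x2(self.c, self.d, self.a, self.b, self.corrected)


def haldane_correct(t: ContingencyTable2x2) -> ContingencyTable2x2:
    """Add 0.5 to every cell. Refuses to correct twice."""
    if t.corrected:
        raise ContractViolationError("table is already Haldane-corrected")
    return ContingencyTable2x2(t.a + 0.5, t.b + 0.5, t.c + 0.5, t.d + 0.5, corrected=True)


def ror(t: ContingencyTable2x2) -> tuple[float, float]:
    """Return (ROR, lnROR) = (a*d/(b*c), its natural log)."""
    if t.b * t.c == 0:
        raise ZeroDivisionError(
            "b*c = 0: the odds ratio is undefined on this table; apply "
            "haldane_correct() first"
        )
    value = (t.a * t.d) / (t.b * t.c)
    return value, math.log(value) if value > 0 else -math.inf


def fisher_p(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p on the raw integer counts.

    Defined as the sum of hypergeometric probabilities of all tables (with
    the observed margins) no more probable than the observed one.  The
    Haldane correction is never applied here: the exact test is defined on
    integers.
    """
    if t.corrected:
        raise ContractViolationError(
            "Fisher's exact test requires raw integer counts, not a "
            "Haldane-corrected table"
        )
    table = [[int(t.a), int(t.b)], [int(t.c), int(t.d)]]
    p = float(stats.fisher_exact(table, alternative="two-sided").pvalue)
    return min(p, 1.0)


def neg_log10_p(p: float) -> float:
    """-log10(p), capped at 308 (p = 0 maps to the cap)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p == 0.0:
        return NEG_LOG10_CAP
    return min(-math.log10(p), NEG_LOG10_CAP)


def wald_ci(t: ContingencyTable2x2, level: float = 0.95) -> tuple[float, float]:
    """Wald confidence interval for the ROR on the log-odds scale:
    exp(lnROR +/- z * sqrt(1/a + 1/b + 1/c + 1/d))."""
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level {level} outside (0, 1)")
    if min(t.a, t.b, t.c, t.d) <= 0:
        raise ZeroDivisionError(
            "all cells must be positive for a Wald interval; apply "
            "haldane_correct() first"
        )
    _, ln = ror(t)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    z = stats.norm.ppf(0.5 + level / 2)
    return math.exp(ln - z * se), math.exp(ln + z * se)


@dataclass(frozen=True)
class SignalCriteria:
    """Thresholds defining a disproportionality signal."""

    max_p: float = 0.05
    min_ror: float = 1.0
    min_events: int = 100

    def is_signal(self, p: float, ror_value: float, n_event: int) -> bool:
        return p < self.max_p and ror_value > self.min_ror and n_event >= self.min_events


DEFAULT_CRITERIA = SignalCriteria()


@dataclass(frozen=True)
class DisproportionalityResult:
    """Per-entity association summary (drug, drug class, or stratum)."""

    entity: str
    n_event: int
    ror: float
    ln_ror: float
    p: float
    neg_log10_p: float
    ci_low: float
    ci_high: float
    signal: bool


def make_contingency(
    table_a: TableA, drugs: str | Iterable[str], event_pts: Iterable[str]
) -> ContingencyTable2x2:
    """Cross-classify all Table A reports by exposure to ``drugs`` and
    occurrence of any PT in ``event_pts``.

    The background ("all other reports") is the entire Table A, including
    reports of unrelated drugs.  An empty event set yields a = c = 0.
    """
    exposed = table_a.ids_with_drug(drugs)
    with_event = table_a.ids_with_any_pt(event_pts)
    a = len(exposed.intersection(with_event))
    b = len(exposed) - a
    c = len(with_event) - a
    d = table_a.n_reports - len(exposed) - c
    return ContingencyTable2x2(a, b, c, d, corrected=False)


def association(
    raw: ContingencyTable2x2,
    entity: str,
    haldane: bool = True,
    level: float = 0.95,
    criteria: SignalCriteria = DEFAULT_CRITERIA,
) -> DisproportionalityResult:
    """Full association summary from a raw (uncorrected) 2x2 table.

    The p-value always comes from the raw counts; the ROR and CI come from
    the Haldane-corrected table when ``haldane`` (the default for per-drug
    screening) and from the raw counts otherwise (used for the demographic
    strata, whose cells are large and zero-free).
    """
    if raw.corrected:
        raise ContractViolationError("association() expects a raw table")
    effective = haldane_correct(raw) if haldane else raw
    if not haldane and min(raw.a, raw.b, raw.c, raw.d) == 0:
        raise DegenerateDataError(
            f"{entity}: zero cell in uncorrected table; use haldane=True"
        )
    ror_value, ln = ror(effective)
    p = fisher_p(raw)
    low, high = wald_ci(effective, level)
    n_event = int(raw.a)
    return DisproportionalityResult(
        entity=entity,
        n_event=n_event,
        ror=ror_value,
        ln_ror=ln,
        p=p,
        neg_log10_p=neg_log10_p(p),
        ci_low=low,
        ci_high=high,
        signal=criteria.is_signal(p, ror_value, n_event),
    )


def screen_all_drugs(
    table_a: TableA,
    event_pts: Iterable[str],
    criteria: SignalCriteria = DEFAULT_CRITERIA,
    drugs: Iterable[str] | None = None,
) -> list[DisproportionalityResult]:
    """One association result per distinct drug in Table A.

    ROR and CI use Haldane-corrected counts; the Fisher p uses raw counts.
    Restrict to ``drugs`` to screen a subset (e.g. mapped antineoplastics).
    """
    event_ids = table_a.ids_with_any_pt(event_pts)
    n_total = table_a.n_reports
    n_event_total = len(event_ids)

    pairs = table_a.drugs
    flagged = pairs.assign(with_event=pairs["primary_id"].isin(event_ids))
    per_drug = flagged.groupby("generic_name")["with_event"].agg(["size", "sum"])

    if drugs is not None:
        wanted = [normalize_term(d) for d in drugs]
        per_drug = per_drug.loc[per_drug.index.intersection(wanted)]

    results = []
    for name, row in per_drug.sort_index().iterrows():
        n_exposed, a = int(row["size"]), int(row["sum"])
        raw = ContingencyTable2x2(
            a, n_exposed - a, n_event_total - a, n_total - n_exposed - (n_event_total - a)
        )
        results.append(association(raw, entity=name, haldane=True, criteria=criteria))
    return results


def signal_drugs(results: Sequence[DisproportionalityResult]) -> list[str]:
    return [r.entity for r in results if r.signal]


def results_to_frame(results: Sequence[DisproportionalityResult]) -> pd.DataFrame:
    """Tidy frame for volcano export: one row per entity."""
    return pd.DataFrame(
        {
            "entity": [r.entity for r in results],
            "n_event": [r.n_event for r in results],
            "ror": [r.ror for r in results],
            "ln_ror": [r.ln_ror for r in results],
            "p": [r.p for r in results],
            "neg_log10_p": [r.neg_log10_p for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "signal": [r.signal for r in results],
        }
    )


def write_volcano_csv(results: Sequence[DisproportionalityResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, index=False)


def volcano_plot(results: Sequence[DisproportionalityResult], path: str | Path) -> None:
    """Scatter of lnROR against -log10 p with signal drugs highlighted."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = results_to_frame(results)
    fig, ax = plt.subplots(figsize=(7, 5))
    bg = df[~df["signal"]]
    sig = df[df["signal"]]
    ax.scatter(bg["ln_ror"], bg["neg_log10_p"], s=12, c="grey", alpha=0.6, label="no signal")
    ax.scatter(sig["ln_ror"], sig["neg_log10_p"], s=18, c="crimson", label="signal")
    for _, row in sig.iterrows():
        ax.annotate(row["entity"], (row["ln_ror"], row["neg_log10_p"]), fontsize=6)
    ax.axhline(-math.log10(0.05), ls="--", lw=0.8, c="k")
    ax.axvline(0.0, ls="--", lw=0.8, c="k")
    ax.set_xlabel("lnROR")
    ax.set_ylabel(r"$-\log_{10} p$")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
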