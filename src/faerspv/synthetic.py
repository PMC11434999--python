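"""Synthetic spontaneous-report generator with known disproportionality.

Emulates the statistical structure of a FAERS extract: one DEMO row per
case version (with age, age-unit code, and gender), multiple drug
mentions and multiple preferred terms per report, superseded duplicate
case versions, and dirty age/gender fields.  Drug-event associations are
injected on the odds scale — for an exposed report the event odds are
multiplied by the target ROR — so the population reporting odds ratio of
a (drug, PT) pair equals the configured target exactly, which makes
parameter-recovery experiments well defined.  An optional age effect
multiplies the odds of every chemosensory PT for patients aged >= 70.

Every dataset carries a :class:`GroundTruthLedger` holding the realized
exposure and event indicators, so any downstream count can be checked
against the emitted files exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .disproportionality import ContingencyTable2x2
from .errors import ConfigError
from .faers_model import TsdReportCounts
from .vocab import SmqTermSet, TASTE_SMELL_SMQ, ATC_CLASSES, normalize_term

#: Drug mention given to reports that drew no drug (FAERS reports always
#: list at least one drug); not part of any analysis exposure set.
FALLBACK_DRUG = "unspecified comedication"

#: PT given to reports that drew no reaction (FAERS reports always list
#: at least one PT); a non-SMQ filler term.
FALLBACK_PT = "drug ineffective"

#: Baseline per-report probabilities of the 14 SMQ PTs, mirroring their
#: relative frequencies in a real FAERS snapshot (frequent taste terms,
#: rare instrumental/hallucination terms).
SMQ_BASELINE_RATES: dict[str, float] = {
    "dysgeusia": 0.015,
    "ageusia": 0.005,
    "taste disorder": 0.0024,
    "anosmia": 0.0021,
    "parosmia": 0.0015,
    "hypogeusia": 0.0006,
    "hyposmia": 0.0004,
    "hallucination, olfactory": 1e-4,
    "olfactory nerve disorder": 3e-5,
    "hypergeusia": 2e-5,
    "hallucination, gustatory": 2e-5,
    "gustometry abnormal": 1e-5,
    "olfactory test abnormal": 1e-5,
    "olfactory dysfunction": 5e-6,
}

#: Non-SMQ filler PTs keeping the "all other reports" background realistic.
FILLER_RATES: dict[str, float] = {
    FALLBACK_PT: 0.10,
    "nausea": 0.12,
    "fatigue": 0.10,
    "headache": 0.08,
    "diarrhoea": 0.07,
    "vomiting": 0.06,
    "rash": 0.05,
    "pyrexia": 0.05,
    "dizziness": 0.04,
    "arthralgia": 0.03,
}

#: The seven frequent chemosensory PTs retained by the report-count floor.
MAIN_PTS = [
    "dysgeusia", "ageusia", "taste disorder", "anosmia",
    "parosmia", "hypogeusia", "hyposmia",
]
MAIN_TASTE_PTS = ["dysgeusia", "ageusia", "taste disorder", "hypogeusia"]
MAIN_SMELL_PTS = ["anosmia", "parosmia", "hyposmia"]

#: Reference database size used to scale the PT report-count floor.
FULL_FAERS_REPORTS = 12_300_000


def scaled_pt_floor(n_reports: int, full_scale_floor: int = 3000) -> int:
    """The PT report-count floor rescaled from full-FAERS size to a
    synthetic database of ``n_reports`` (same per-report prevalence cut)."""
    return max(5, round(full_scale_floor * n_reports / FULL_FAERS_REPORTS))


@dataclass(frozen=True)
class DrugSpec:
    """One drug: generic name, ATC code (None for non-antineoplastics),
    and its marginal exposure probability per report."""

    name: str
    atc_code: str | None
    exposure_prob: float


@dataclass
class SyntheticConfig:
    """Generative parameters for one synthetic database.

    ``injected_signals`` maps drug name -> {PT name -> target ROR}; the
    tilt acts multiplicatively on the event odds of exposed reports.
    ``age_mixture`` is a tuple of (weight, mean, sd) normal components in
    years.  ``age_effect_ror`` multiplies the odds of every SMQ PT for
    patients aged >= 70.  A fixed seed makes the emitted files
    byte-identical across runs.
    """

    n_reports: int
    drugs: tuple[DrugSpec, ...]
    pt_marginals: dict[str, float]
    injected_signals: dict[str, dict[str, float]] = field(default_factory=dict)
    age_mixture: tuple[tuple[float, float, float], ...] = (
        (0.25, 40.0, 12.0),
        (0.55, 62.0, 10.0),
        (0.20, 76.0, 7.0),
    )
    age_effect_ror: float = 1.0
    gender_split: float = 0.55
    duplicate_fraction: float = 0.05
    invalid_age_fraction: float = 0.06
    decade_fraction: float = 0.02
    unknown_gender_fraction: float = 0.02
    smq: SmqTermSet = field(default=TASTE_SMELL_SMQ, repr=False)
    seed: int = 0

    def __post_init__(self) -> None:
        self.drugs = tuple(
            DrugSpec(normalize_term(d.name), d.atc_code, float(d.exposure_prob))
            for d in self.drugs
        )
        self.pt_marginals = {
            normalize_term(pt): float(p) for pt, p in self.pt_marginals.items()
        }
        if FALLBACK_PT not in self.pt_marginals:
            self.pt_marginals[FALLBACK_PT] = 0.05
        self.injected_signals = {
            normalize_term(d): {normalize_term(pt): float(r) for pt, r in m.items()}
            for d, m in self.injected_signals.items()
        }
        self.validate()

    def validate(self) -> None:
        if self.n_reports <= 0:
            raise ConfigError("n_reports must be positive")
        names = [d.name for d in self.drugs]
        if len(set(names)) != len(names):
            raise ConfigError("drug names must be unique")
        for d in self.drugs:
            if not 0.0 <= d.exposure_prob < 1.0:
                raise ConfigError(f"exposure probability of {d.name!r} outside [0, 1)")
        for pt, p in self.pt_marginals.items():
            if not 0.0 <= p < 1.0:
                raise ConfigError(f"baseline probability of PT {pt!r} outside [0, 1)")
        for frac_name in ("duplicate_fraction", "invalid_age_fraction",
                          "decade_fraction", "unknown_gender_fraction"):
            if not 0.0 <= getattr(self, frac_name) < 1.0:
                raise ConfigError(f"{frac_name} outside [0, 1)")
        if not 0.0 <= self.gender_split <= 1.0:
            raise ConfigError("gender_split outside [0, 1]")
        if self.age_effect_ror <= 0:
            raise ConfigError("age_effect_ror must be positive")
        weights = [w for w, _, _ in self.age_mixture]
        if abs(sum(weights) - 1.0) > 1e-9 or any(w < 0 for w in weights):
            raise ConfigError("age mixture weights must be non-negative and sum to 1")
        drug_set = set(names)
        for drug, per_pt in self.injected_signals.items():
            if drug not in drug_set:
                raise ConfigError(f"injected signal for unknown drug {drug!r}")
            for pt, r in per_pt.items():
                if pt not in self.pt_marginals:
                    raise ConfigError(f"injected signal on unknown PT {pt!r}")
                if r <= 0:
                    raise ConfigError(f"target ROR for ({drug!r}, {pt!r}) must be > 0")
        self._check_feasibility()

    def _check_feasibility(self) -> None:
        # The odds-scale tilt never reaches probability 1 exactly, but a
        # tilt that saturates the event for an exposed report would void
        # the target-recovery semantics; refuse it per (drug, PT).
        for drug, per_pt in self.injected_signals.items():
            for pt, target in per_pt.items():
                base = self.pt_marginals[pt]
                if base == 0.0:
                    continue
                lo = float(logit(base)) + np.log(target)
                if pt in self.smq.all_terms and self.age_effect_ror > 1.0:
                    lo += np.log(self.age_effect_ror)
                if expit(lo) >= 0.999:
                    raise ConfigError(
                        f"infeasible tilt for drug {drug!r} on PT {pt!r}: the "
                        f"event probability reaches {expit(lo):.4f}"
                    )

    @property
    def drug_names(self) -> list[str]:
        return [d.name for d in self.drugs]

    @property
    def l01_drug_names(self) -> list[str]:
        return [d.name for d in self.drugs if d.atc_code is not None]

    def atc_mapping(self) -> dict[str, str]:
        return {d.name: d.atc_code for d in self.drugs if d.atc_code is not None}


@dataclass
class GroundTruthLedger:
    """Realized per-report indicators behind a synthetic dataset.

    Counts derived here are exact bookkeeping over the final (highest
    case-version) reports — precisely what the file pipeline reproduces
    after deduplication and joining.
    """

    config: SyntheticConfig
    primary_ids: np.ndarray
    case_ids: np.ndarray
    exposure: np.ndarray  # (n_reports, n_drugs) bool
    occurrence: np.ndarray  # (n_reports, n_pts) bool
    fallback_drug: np.ndarray  # reports whose only drug is the fallback
    age_true: np.ndarray
    recorded_age_years: np.ndarray  # NaN where the DEMO field is unusable
    gender_true: np.ndarray
    gender_recorded: np.ndarray  # 'M'/'F'/'UNK'
    eligible: np.ndarray  # passes the Table B age/gender filters
    duplicated: np.ndarray  # cases re-emitted with a superseded version

    def __post_init__(self) -> None:
        self._drug_index = {d: i for i, d in enumerate(self.config.drug_names)}
        self._pt_index = {p: i for i, p in enumerate(self.config.pt_marginals)}

    @property
    def n_reports(self) -> int:
        return len(self.primary_ids)

    def _event_mask(self, event_pts: Iterable[str]) -> np.ndarray:
        cols = [self._pt_index[normalize_term(p)] for p in event_pts
                if normalize_term(p) in self._pt_index]
        if not cols:
            return np.zeros(self.n_reports, dtype=bool)
        return self.occurrence[:, cols].any(axis=1)

    def _exposure_mask(self, drugs: str | Iterable[str]) -> np.ndarray:
        if isinstance(drugs, str):
            drugs = [drugs]
        mask = np.zeros(self.n_reports, dtype=bool)
        for d in drugs:
            name = normalize_term(d)
            if name not in self._drug_index:
                raise KeyError(f"drug {name!r} is not in this ledger")
            mask |= self.exposure[:, self._drug_index[name]]
        return mask

    def contingency(
        self, drug: str | Iterable[str], event_pts: Iterable[str]
    ) -> ContingencyTable2x2:
        """Exact realized a/b/c/d for a drug (or drug set) and event PT set
        over all final-version reports (the Table A population)."""
        exp = self._exposure_mask(drug)
        ev = self._event_mask(event_pts)
        a = int((exp & ev).sum())
        b = int((exp & ~ev).sum())
        c = int((~exp & ev).sum())
        d = int((~exp & ~ev).sum())
        return ContingencyTable2x2(a, b, c, d, corrected=False)

    def tsd_counts(self, exposure_drugs: Iterable[str]) -> TsdReportCounts:
        """Ground-truth taste-only / smell-only / both partition among
        reports exposed to any of the given drugs."""
        exposed = self._exposure_mask(exposure_drugs)
        taste = self._event_mask(self.config.smq.taste_terms) & exposed
        smell = self._event_mask(self.config.smq.smell_terms) & exposed
        both = int((taste & smell).sum())
        return TsdReportCounts(
            n_tsd_any=int((taste | smell).sum()),
            n_taste_any=int(taste.sum()),
            n_taste_only=int(taste.sum()) - both,
            n_smell_any=int(smell.sum()),
            n_smell_only=int(smell.sum()) - both,
            n_both=both,
        )

    def table_b_truth(self) -> pd.DataFrame:
        """The expected Table B: eligible, antineoplastic-exposed reports."""
        mask = self.eligible & self._exposure_mask(self.config.l01_drug_names)
        tsd = self._event_mask(self.config.smq.all_terms)
        df = pd.DataFrame(
            {
                "primary_id": self.primary_ids[mask],
                "age_years": self.recorded_age_years[mask],
                "gender": self.gender_recorded[mask],
                "tsd": tsd[mask],
            }
        )
        return df.sort_values("primary_id").reset_index(drop=True)

    def age_contingency(
        self, cutoff: float = 70.0, event_pts: Iterable[str] | None = None
    ) -> ContingencyTable2x2:
        """Elderly-by-outcome 2x2 over the Table B population.

        The outcome defaults to the combined chemosensory event; a single
        PT can be passed to recover the per-PT age odds ratio, which the
        odds-scale injection makes exactly equal to the configured
        ``age_effect_ror`` (the combined event's odds ratio is only
        approximately the target, since the union of independently tilted
        events aggregates slightly super-multiplicatively)."""
        mask = self.eligible & self._exposure_mask(self.config.l01_drug_names)
        pts = self.config.smq.all_terms if event_pts is None else event_pts
        tsd = self._event_mask(pts)[mask]
        elderly = self.recorded_age_years[mask] >= cutoff
        return ContingencyTable2x2(
            int((elderly & tsd).sum()), int((elderly & ~tsd).sum()),
            int((~elderly & tsd).sum()), int((~elderly & ~tsd).sum()),
        )

    def summary(self) -> dict:
        smq_terms = sorted(self.config.smq.all_terms & set(self._pt_index))
        per_drug = {}
        for d in self.config.drug_names:
            t = self.contingency(d, smq_terms)
            per_drug[d] = {"a": t.a, "b": t.b, "c": t.c, "d": t.d}
        return {
            "n_reports": self.n_reports,
            "n_eligible": int(self.eligible.sum()),
            "n_duplicated_cases": int(self.duplicated.sum()),
            "combined_event_tables": per_drug,
        }


def ledger_contingency(
    ledger: GroundTruthLedger, drug: str, event_pts: Iterable[str]
) -> ContingencyTable2x2:
    """Module-level alias for :meth:`GroundTruthLedger.contingency`."""
    return ledger.contingency(drug, event_pts)


@dataclass
class SyntheticDataset:
    """A generated database: ground truth plus lazily rendered FAERS files."""

    config: SyntheticConfig
    ledger: GroundTruthLedger

    @cached_property
    def demo(self) -> pd.DataFrame:
        return _render_demo(self.ledger)

    @cached_property
    def drug(self) -> pd.DataFrame:
        return _render_mentions(
            self.ledger, self.ledger.exposure, self.config.drug_names,
            self.ledger.fallback_drug, FALLBACK_DRUG, "drugname",
        )

    @cached_property
    def reac(self) -> pd.DataFrame:
        no_extra = np.zeros(self.ledger.n_reports, dtype=bool)
        return _render_mentions(
            self.ledger, self.ledger.occurrence,
            list(self.config.pt_marginals), no_extra, FALLBACK_PT, "pt",
        )

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write DEMO/DRUG/REAC in the FAERS ``$`` dialect plus the ledger
        summary JSON; returns the paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "demo": out / "DEMO.txt",
            "drug": out / "DRUG.txt",
            "reac": out / "REAC.txt",
            "ledger": out / "ledger.json",
        }
        self.demo.to_csv(paths["demo"], sep="$", index=False)
        self.drug.to_csv(paths["drug"], sep="$", index=False)
        self.reac.to_csv(paths["reac"], sep="$", index=False)
        paths["ledger"].write_text(json.dumps(self.ledger.summary(), indent=2))
        return paths


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Draw one synthetic database from the configuration.

    Per report: age from the mixture, gender, an independent Bernoulli
    drug set, and a PT set whose per-PT odds are tilted by the exposed
    drugs' target RORs (and the age effect for SMQ terms).  A configured
    fraction of cases is re-emitted as a superseded earlier case version;
    a fraction of DEMO rows receives non-year age units, out-of-range
    ages, missing ages, or unknown gender.
    """
    cfg = config
    n = cfg.n_reports
    rng = np.random.default_rng(cfg.seed)

    weights = np.array([w for w, _, _ in cfg.age_mixture])
    means = np.array([m for _, m, _ in cfg.age_mixture])
    sds = np.array([s for _, _, s in cfg.age_mixture])
    comp = rng.choice(len(weights), size=n, p=weights)
    age_true = np.clip(np.rint(rng.normal(means[comp], sds[comp])), 0, 100).astype(int)
    elderly_true = age_true >= 70

    gender_true = np.where(rng.random(n) < cfg.gender_split, "F", "M")

    probs = np.array([d.exposure_prob for d in cfg.drugs])
    exposure = rng.random((n, len(cfg.drugs))) < probs[None, :]

    pt_names = list(cfg.pt_marginals)
    pt_index = {p: i for i, p in enumerate(pt_names)}
    occurrence = np.zeros((n, len(pt_names)), dtype=bool)
    log_age = np.log(cfg.age_effect_ror)
    for j, pt in enumerate(pt_names):
        base = cfg.pt_marginals[pt]
        draw = rng.random(n)
        if base == 0.0:
            continue
        lo = np.full(n, float(logit(base)))
        for drug, per_pt in cfg.injected_signals.items():
            target = per_pt.get(pt)
            if target is not None and target != 1.0:
                idx = cfg.drug_names.index(drug)
                lo = lo + np.log(target) * exposure[:, idx]
        if log_age != 0.0 and pt in cfg.smq.all_terms:
            lo = lo + log_age * elderly_true
        occurrence[:, j] = draw < expit(lo)

    # every report needs >= 1 reaction and >= 1 drug mention
    occurrence[~occurrence.any(axis=1), pt_index[FALLBACK_PT]] = True
    fallback_drug = ~exposure.any(axis=1)

    # dirty-field assignment (age units, out-of-range, missing, gender)
    r = rng.random(n)
    invalid = r < cfg.invalid_age_fraction
    decade = ~invalid & (r < cfg.invalid_age_fraction + cfg.decade_fraction)
    invalid_type = rng.integers(0, 3, size=n)
    overage = rng.integers(121, 400, size=n)
    unknown_gender = rng.random(n) < cfg.unknown_gender_fraction
    duplicated = rng.random(n) < cfg.duplicate_fraction

    recorded = age_true.astype(float)
    recorded[decade] = 10.0 * (age_true[decade] // 10)
    recorded[invalid] = np.nan
    gender_recorded = gender_true.copy()
    gender_recorded[unknown_gender] = "UNK"
    eligible = ~invalid & ~unknown_gender

    case_ids = np.char.add("1", np.char.zfill(np.arange(n).astype(str), 8))
    versions = np.where(duplicated, 2, 1)
    primary_ids = np.char.add(case_ids, versions.astype(str))

    ledger = GroundTruthLedger(
        config=cfg,
        primary_ids=primary_ids,
        case_ids=case_ids,
        exposure=exposure,
        occurrence=occurrence,
        fallback_drug=fallback_drug,
        age_true=age_true,
        recorded_age_years=recorded,
        gender_true=gender_true,
        gender_recorded=gender_recorded,
        eligible=eligible,
        duplicated=duplicated,
    )
    # stash rendering-only fields on the ledger (not part of its API)
    ledger._invalid = invalid
    ledger._decade = decade
    ledger._invalid_type = invalid_type
    ledger._overage = overage
    ledger._versions = versions
    return SyntheticDataset(config=cfg, ledger=ledger)


def _age_fields(ledger: GroundTruthLedger) -> tuple[np.ndarray, np.ndarray]:
    """DEMO age value/unit strings implementing the dirty-field scheme."""
    n = ledger.n_reports
    age = ledger.age_true
    value = age.astype(str).astype(object)
    unit = np.full(n, "YR", dtype=object)
    dec = ledger._decade
    value[dec] = (age[dec] // 10).astype(str)
    unit[dec] = "DEC"
    inv = ledger._invalid
    kind = ledger._invalid_type
    months = inv & (kind == 0)
    value[months] = (age[months] * 12).astype(str)
    unit[months] = "MON"
    out_of_range = inv & (kind == 1)
    value[out_of_range] = ledger._overage[out_of_range].astype(str)
    missing = inv & (kind == 2)
    value[missing] = ""
    return value, unit


def _render_demo(ledger: GroundTruthLedger) -> pd.DataFrame:
    value, unit = _age_fields(ledger)
    base = pd.DataFrame(
        {
            "primaryid": ledger.primary_ids,
            "caseid": ledger.case_ids,
            "caseversion": ledger._versions,
            "age": value,
            "age_cod": unit,
            "sex": ledger.gender_recorded,
        }
    )
    dup = ledger.duplicated
    superseded = base.loc[dup].copy()
    superseded["caseversion"] = 1
    superseded["primaryid"] = np.char.add(ledger.case_ids[dup], "1")
    full = pd.concat([base, superseded], ignore_index=True)
    return full.sort_values(["caseid", "caseversion"], kind="mergesort").reset_index(
        drop=True
    )


def _render_mentions(
    ledger: GroundTruthLedger,
    matrix: np.ndarray,
    names: Sequence[str],
    extra_mask: np.ndarray,
    extra_name: str,
    column: str,
) -> pd.DataFrame:
    """Explode a report-by-item indicator matrix into FAERS mention rows,
    adding fallback rows, superseded-version copies, and a sprinkling of
    exact duplicate rows (removed again by deduplication)."""
    ridx, cidx = np.nonzero(matrix)
    name_arr = np.asarray(names, dtype=object)
    rows = pd.DataFrame(
        {"primaryid": ledger.primary_ids[ridx], column: name_arr[cidx], "_r": ridx}
    )
    if extra_mask.any():
        extra = pd.DataFrame(
            {
                "primaryid": ledger.primary_ids[extra_mask],
                column: extra_name,
                "_r": np.flatnonzero(extra_mask),
            }
        )
        rows = pd.concat([rows, extra], ignore_index=True)
    dup_rows = rows.loc[ledger.duplicated[rows["_r"].to_numpy()]].copy()
    dup_rows["primaryid"] = np.char.add(
        ledger.case_ids[dup_rows["_r"].to_numpy()], "1"
    )
    rows = pd.concat([rows, dup_rows], ignore_index=True)
    exact_dups = rows.iloc[::37].copy()  # survive as literal duplicate lines
    rows = pd.concat([rows, exact_dups], ignore_index=True)
    return (
        rows.drop(columns="_r")
        .sort_values(["primaryid", column], kind="mergesort")
        .reset_index(drop=True)
    )


def _class_drugs(exposures: Sequence[float] = (0.01, 0.02, 0.03)) -> list[DrugSpec]:
    drugs = []
    for cls in ATC_CLASSES:
        for i, p in enumerate(exposures, start=1):
            drugs.append(DrugSpec(f"{cls.lower()}_agent_{i}", cls, p))
    return drugs


_BACKGROUND_DRUGS = (
    DrugSpec("comedication_a", None, 0.25),
    DrugSpec("comedication_b", None, 0.20),
    DrugSpec("comedication_c", None, 0.15),
    DrugSpec("analgesic_filler", None, 0.10),
    DrugSpec("antacid_filler", None, 0.05),
)


def default_config(seed: int = 0, n_reports: int = 200_000) -> SyntheticConfig:
    """The reference study conditions: 21 antineoplastic drugs (three per
    L01 subclass at exposure 1/2/3%), five background co-medications,
    FAERS-like PT marginals, and no injected association (a null
    database)."""
    return SyntheticConfig(
        n_reports=n_reports,
        drugs=tuple(_class_drugs()) + _BACKGROUND_DRUGS,
        pt_marginals={**SMQ_BASELINE_RATES, **FILLER_RATES},
        seed=seed,
    )


def coverage_config(seed: int = 0, n_reports: int = 200_000,
                    target_ror: float = 4.0) -> SyntheticConfig:
    """Reference conditions plus one planted (drug, PT) association:
    ``l01e_agent_2`` (exposure 2%) with dysgeusia odds multiplied by
    ``target_ror``.  Used for CI-coverage experiments."""
    cfg = default_config(seed=seed, n_reports=n_reports)
    cfg.injected_signals = {"l01e_agent_2": {"dysgeusia": float(target_ror)}}
    cfg.validate()
    return cfg


#: (drug, PT) pair planted by :func:`coverage_config`.
COVERAGE_PAIR = ("l01e_agent_2", "dysgeusia")


def archetype_config(
    seed: int = 0,
    n_reports: int = 200_000,
    n_per_archetype: int = 6,
    elevation: float = 2.0,
    exposure: float = 0.03,
) -> SyntheticConfig:
    """Three planted side-effect-profile archetypes for cluster recovery:
    drugs elevated on all seven frequent chemosensory PTs, drugs elevated
    on the taste PTs only, and baseline drugs, separated by ``elevation``
    lnROR units.  Drug names encode the archetype (prefix before '_')."""
    ror_value = float(np.exp(elevation))
    drugs = []
    signals: dict[str, dict[str, float]] = {}
    for i in range(1, n_per_archetype + 1):
        uniform, taste, base = f"uniform_{i}", f"tasteonly_{i}", f"baseline_{i}"
        drugs += [
            DrugSpec(uniform, "L01E", exposure),
            DrugSpec(taste, "L01X", exposure),
            DrugSpec(base, "L01B", exposure),
        ]
        signals[uniform] = {pt: ror_value for pt in MAIN_PTS}
        signals[taste] = {pt: ror_value for pt in MAIN_TASTE_PTS}
    return SyntheticConfig(
        n_reports=n_reports,
        drugs=tuple(drugs) + _BACKGROUND_DRUGS,
        pt_marginals={**SMQ_BASELINE_RATES, **FILLER_RATES},
        injected_signals=signals,
        seed=seed,
    )


def archetype_of(drug_name: str) -> str:
    """Planted archetype label encoded in an archetype-config drug name."""
    return normalize_term(drug_name).split("_", 1)[0]


def config_from_mapping(payload: Mapping) -> SyntheticConfig:
    """Build a configuration from a plain (YAML/JSON-loaded) mapping."""
    drugs = tuple(
        DrugSpec(d["name"], d.get("atc_code"), d["exposure_prob"])
        for d in payload["drugs"]
    )
    kwargs = {k: payload[k] for k in (
        "age_effect_ror", "gender_split", "duplicate_fraction",
        "invalid_age_fraction", "decade_fraction", "unknown_gender_fraction",
        "seed",
    ) if k in payload}
    if "age_mixture" in payload:
        kwargs["age_mixture"] = tuple(tuple(c) for c in payload["age_mixture"])
    return SyntheticConfig(
        n_reports=int(payload["n_reports"]),
        drugs=drugs,
        pt_marginals=dict(payload["pt_marginals"]),
        injected_signals={
            d: dict(m) for d, m in payload.get("injected_signals", {}).items()
        },
        **kwargs,
    )
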