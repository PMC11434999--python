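"""Controlled vocabularies: the chemosensory SMQ preferred terms and ATC classes.

Adverse events are coded at the MedDRA preferred-term (PT) level.  The
"taste and smell disorders" standardized MedDRA query (SMQ 20000046,
MedDRA v25.0) contributes 14 PTs after exclusion of congenital anosmia:
seven taste terms and seven smell terms.  Drugs are classified with the
WHO ATC taxonomy; antineoplastic agents are ATC group L01 with seven
subclasses L01A-L01X.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

from .errors import SchemaError


def normalize_term(term: str) -> str:
    """Case-fold, trim, and collapse internal whitespace.

    Used for both PT names and generic drug names; matching everywhere in
    the package is exact on the normalized string (no fuzzy matching).
    """
    return " ".join(str(term).strip().casefold().split())


#: Taste-related PTs of SMQ 20000046 with their MedDRA codes.
TASTE_PT_CODES: dict[str, int] = {
    "dysgeusia": 10013911,
    "ageusia": 10001480,
    "taste disorder": 10082490,
    "hypogeusia": 10020989,
    "hallucination, gustatory": 10019071,
    "hypergeusia": 10069147,
    "gustometry abnormal": 10064480,
}

#: Smell-related PTs of SMQ 20000046 with their MedDRA codes.
SMELL_PT_CODES: dict[str, int] = {
    "anosmia": 10002653,
    "parosmia": 10034018,
    "hyposmia": 10050515,
    "hallucination, olfactory": 10019072,
    "olfactory nerve disorder": 10056388,
    "olfactory test abnormal": 10062927,
    "olfactory dysfunction": 10086567,
}

PT_CODES: dict[str, int] = {**TASTE_PT_CODES, **SMELL_PT_CODES}

#: The congenital term explicitly excluded from the analysis SMQ.
EXCLUDED_PT = "congenital anosmia"


@dataclass(frozen=True)
class SmqTermSet:
    """A two-sided event vocabulary: taste PTs and smell PTs.

    Terms are stored normalized.  The two sides must be disjoint and the
    excluded congenital term may not appear.
    """

    taste_terms: frozenset[str]
    smell_terms: frozenset[str]

    def __post_init__(self) -> None:
        taste = frozenset(normalize_term(t) for t in self.taste_terms)
        smell = frozenset(normalize_term(t) for t in self.smell_terms)
        object.__setattr__(self, "taste_terms", taste)
        object.__setattr__(self, "smell_terms", smell)
        if taste & smell:
            raise ValueError(f"taste/smell term sets overlap: {sorted(taste & smell)}")
        if EXCLUDED_PT in taste | smell:
            raise ValueError(f"{EXCLUDED_PT!r} is excluded from the analysis SMQ")
        if not taste or not smell:
            raise ValueError("both taste and smell term sets must be non-empty")

    @property
    def all_terms(self) -> frozenset[str]:
        return self.taste_terms | self.smell_terms

    def side(self, pt_name: str) -> str | None:
        """Return 'taste', 'smell', or None for a PT name."""
        pt = normalize_term(pt_name)
        if pt in self.taste_terms:
            return "taste"
        if pt in self.smell_terms:
            return "smell"
        return None


#: The bundled 14-term taste-and-smell-disorders SMQ.
TASTE_SMELL_SMQ = SmqTermSet(
    taste_terms=frozenset(TASTE_PT_CODES),
    smell_terms=frozenset(SMELL_PT_CODES),
)


#: The seven antineoplastic ATC subclasses with their conventional labels.
ATC_CLASSES: dict[str, str] = {
    "L01A": "alkylating agents",
    "L01B": "antimetabolites",
    "L01C": "plant alkaloids and other natural products",
    "L01D": "cytotoxic antibiotics and related substances",
    "L01E": "protein kinase inhibitors",
    "L01F": "monoclonal antibodies and antibody drug conjugates",
    "L01X": "other antineoplastic agents",
}


@dataclass(frozen=True)
class AtcClassMap:
    """Mapping from normalized generic drug name to an ATC code.

    Codes must start with one of the seven L01 subclass prefixes; a drug
    therefore belongs to exactly one subclass (``code[:4]``).
    """

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        norm: dict[str, str] = {}
        for name, code in self.mapping.items():
            code = str(code).strip().upper()
            if code[:4] not in ATC_CLASSES:
                raise ValueError(f"ATC code {code!r} for {name!r} is not in L01A-L01X")
            norm[normalize_term(name)] = code
        object.__setattr__(self, "mapping", norm)

    @property
    def drugs(self) -> frozenset[str]:
        """All mapped (antineoplastic) drug names."""
        return frozenset(self.mapping)

    def atc_class(self, drug: str) -> str | None:
        code = self.mapping.get(normalize_term(drug))
        return code[:4] if code else None

    def drugs_in_class(self, atc_class: str) -> frozenset[str]:
        atc_class = atc_class.strip().upper()
        return frozenset(d for d, c in self.mapping.items() if c[:4] == atc_class)

    @classmethod
    def from_csv(cls, path: str | Path) -> "AtcClassMap":
        """Read a two-column CSV with header columns ``drug`` and ``atc_code``."""
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            fields = {f.strip().lower() for f in reader.fieldnames or []}
            for required in ("drug", "atc_code"):
                if required not in fields:
                    raise SchemaError(f"ATC map is missing required column {required!r}")
            mapping = {row["drug"]: row["atc_code"] for row in reader}
        return cls(mapping)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["drug", "atc_code"])
            for drug in sorted(self.mapping):
                writer.writerow([drug, self.mapping[drug]])


#: A small illustrative class-level map of well-known antineoplastic agents.
#: Real analyses should supply a complete curated drug -> ATC map.
EXAMPLE_ATC_MAP = AtcClassMap(
    {
        "cyclophosphamide": "L01A",
        "temozolomide": "L01A",
        "methotrexate": "L01B",
        "fluorouracil": "L01B",
        "capecitabine": "L01B",
        "paclitaxel": "L01C",
        "docetaxel": "L01C",
        "doxorubicin": "L01D",
        "epirubicin": "L01D",
        "imatinib": "L01E",
        "erlotinib": "L01E",
        "sunitinib": "L01E",
        "osimertinib": "L01E",
        "trastuzumab": "L01F",
        "pembrolizumab": "L01F",
        "daratumumab": "L01F",
        "tretinoin": "L01X",
        "vismodegib": "L01X",
        "olaparib": "L01X",
    }
)
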