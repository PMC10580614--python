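"""Mortality-record filtering and ICD-10 cause classification.

The analysis set is restricted to non-accidental deaths in adults
(age >= 18) inside the study window.  "Non-accidental" means every
ICD-10 chapter except most of the external-cause blocks V-Y; the
intentional self-harm and assault range (X60-Y09 by default) is kept
because acute air-pollution exposure is a plausible trigger for
self-harm and aggression.

Retained deaths are mapped onto mutually exclusive broad-category
(organ-system) and cause-specific outcome groups defined by inclusive
three-character ICD-10 code ranges in a YAML catalog.  Membership is
decided on the three-character root, so decimal sub-codes inherit their
root's class.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "OutcomeCatalog",
    "CauseClass",
    "load_default_catalog",
    "classify_cause",
    "filter_records",
]

_ICD_RE = re.compile(r"^[A-Z][0-9]{2}(\.[0-9A-Z]{1,2})?$")

#: Record-level exclusion reason codes used by :func:`filter_records`.
REASON_MALFORMED = "malformed"
REASON_WINDOW = "outside-study-window"
REASON_AGE = "under-18"
REASON_EXTERNAL = "external-cause"


def _root(code: str) -> str:
    return code.strip().upper()[:3]


def _in_ranges(root: str, ranges: Iterable[tuple[str, str]]) -> bool:
    # three-character roots are fixed-width, so lexicographic order is
    # identical to ICD order even across chapter letters
    return any(lo <= root <= hi for lo, hi in ranges)


@dataclass(frozen=True)
class CauseClass:
    """Classification of a single ICD-10 code."""

    status: str  # "retained" | "excluded"
    broad: str | None
    specific: str | None


@dataclass
class OutcomeCatalog:
    """Broad-category and cause-specific outcome definitions.

    Parameters
    ----------
    broad
        Mapping of broad-category name to a list of inclusive
        ``(lo, hi)`` three-character code ranges.
    specific
        Mapping of cause-specific name to ``{"broad": name,
        "ranges": [...]}``; specific categories must be pairwise
        disjoint and nest inside their stated broad category.
    retained_external, excluded_external
        Ranges inside the external-cause blocks V-Y that are kept in /
        dropped from the non-accidental analysis set.
    """

    broad: dict[str, list[tuple[str, str]]]
    specific: dict[str, dict]
    retained_external: list[tuple[str, str]] = field(default_factory=list)
    excluded_external: list[tuple[str, str]] = field(default_factory=list)
    name: str = "catalog"

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        roots = [f"{ch}{i:02d}" for ch in "ABCDEFGHIJKLMNOPQRSTUVWXYZ" for i in range(100)]
        owner: dict[str, str] = {}
        for name, spec in self.specific.items():
            for r in roots:
                if _in_ranges(r, spec["ranges"]):
                    if r in owner:
                        raise ValueError(
                            f"specific categories not mutually exclusive: {r} in "
                            f"{owner[r]!r} and {name!r}"
                        )
                    owner[r] = name
                    if spec.get("broad") and not _in_ranges(r, self.broad[spec["broad"]]):
                        raise ValueError(
                            f"{r} of specific {name!r} outside broad {spec['broad']!r}"
                        )

    @classmethod
    def from_yaml(cls, source) -> "OutcomeCatalog":
        """Load a catalog from a YAML path, file object or string."""
        if hasattr(source, "read"):
            raw = yaml.safe_load(source.read())
        else:
            text = str(source)
            if "\n" in text or ":" in text.splitlines()[0]:
                raw = yaml.safe_load(text)
            else:
                with open(text) as fh:
                    raw = yaml.safe_load(fh)
        tup = lambda pairs: [tuple(p) for p in pairs]
        return cls(
            broad={k: tup(v) for k, v in raw["broad"].items()},
            specific={
                k: {"broad": v.get("broad"), "ranges": tup(v["ranges"])}
                for k, v in raw["specific"].items()
            },
            retained_external=tup(raw.get("retained_external", [])),
            excluded_external=tup(raw.get("excluded_external", [])),
            name=raw.get("name", "catalog"),
        )

    def classify(self, icd10: str) -> CauseClass:
        return classify_cause(icd10, self)


def load_default_catalog() -> OutcomeCatalog:
    """The packaged outcome catalog (organ-system blocks and the
    cause-specific groups nested in them)."""
    text = resources.files("lagcrossover.data").joinpath("outcome_catalog.yaml").read_text()
    return OutcomeCatalog.from_yaml(text)


def is_valid_icd10(code) -> bool:
    return isinstance(code, str) and bool(_ICD_RE.match(code.strip().upper()))


def classify_cause(icd10: str, catalog: OutcomeCatalog | None = None) -> CauseClass:
    """Classify one ICD-10 code against the outcome catalog.

    External-cause roots (letters V-Y) are excluded unless they fall in
    a retained range; anything else is a retained non-accidental death.
    Retained codes outside every catalog category contribute only to the
    all-non-accidental total (``broad=None, specific=None``).
    """
    if catalog is None:
        catalog = load_default_catalog()
    root = _root(icd10)
    if root[0] in "VWXY" and not _in_ranges(root, catalog.retained_external):
        return CauseClass("excluded", None, None)
    broad = next((n for n, rg in catalog.broad.items() if _in_ranges(root, rg)), None)
    specific = next(
        (n for n, sp in catalog.specific.items() if _in_ranges(root, sp["ranges"])), None
    )
    return CauseClass("retained", broad, specific)


def filter_records(
    records: pd.DataFrame,
    study_start,
    study_end,
    catalog: OutcomeCatalog | None = None,
    min_age: int = 18,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict a mortality table to the analysis set.

    Keeps records with ``study_start <= death_date <= study_end``,
    ``age_years >= min_age`` and a retained (non-accidental) cause.
    Malformed dates or ICD codes exclude the record, never crash.

    Returns
    -------
    analysis : DataFrame
        Retained records with ``death_date`` coerced to datetime and
        added ``broad`` / ``specific`` outcome columns.
    exclusions : DataFrame
        One row per excluded record: original index and a reason code.
    """
    if catalog is None:
        catalog = load_default_catalog()
    df = records.copy()
    dates = pd.to_datetime(df["death_date"], errors="coerce")
    start, end = pd.Timestamp(study_start), pd.Timestamp(study_end)

    icd_ok = df["icd10"].map(is_valid_icd10)
    reason = pd.Series(pd.NA, index=df.index, dtype="object")
    reason[dates.isna() | ~icd_ok] = REASON_MALFORMED

    mask = reason.isna() & ((dates < start) | (dates > end))
    reason[mask] = REASON_WINDOW
    age = pd.to_numeric(df["age_years"], errors="coerce")
    reason[reason.isna() & ((age < min_age) | age.isna())] = REASON_AGE

    todo = reason.isna()
    roots = df.loc[todo, "icd10"].map(_root)
    classes = {r: classify_cause(r, catalog) for r in roots.unique()}
    external = roots.map(lambda r: classes[r].status == "excluded")
    reason[roots.index[external]] = REASON_EXTERNAL

    keep = reason.isna()
    analysis = df[keep].copy()
    analysis["death_date"] = dates[keep]
    kept_roots = roots[keep[roots.index]]
    analysis["broad"] = kept_roots.map(lambda r: classes[r].broad)
    analysis["specific"] = kept_roots.map(lambda r: classes[r].specific)

    exclusions = pd.DataFrame(
        {"record_index": df.index[~keep], "reason": reason[~keep].to_numpy()}
    )
    return analysis, exclusions
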