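"""Charlson comorbidity index (CCI) from ICD-10 diagnosis codes.

The mapping from ICD-10 codes to the 17 Charlson disease categories follows
the Quan coding with the original Charlson weights, shipped as an editable
CSV fixture so alternative weightings can be swapped in.  Matching is
prefix-based on the dot-stripped, upper-cased code; overlaps between
categories are resolved by the longest matching prefix.  Two hierarchy rules
apply: metastatic solid tumour supersedes any (localized) malignancy, and
moderate/severe liver disease supersedes mild liver disease (likewise
complicated supersedes uncomplicated diabetes).  A superseded category
contributes neither its flag nor its weight.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

#: Charlson categories marked as potentially smoking-related in the baseline
#: table of the surgical cohort analysis.
SMOKING_RELATED_CATEGORIES = frozenset(
    {
        "myocardial_infarction",
        "congestive_heart_failure",
        "peripheral_vascular_disease",
        "cerebrovascular_disease",
        "chronic_pulmonary_disease",
        "hemiplegia_paraplegia",
        "cancer",
        "metastatic_solid_tumour",
    }
)

_CODE_RE = re.compile(r"^[A-Z][0-9]{2}[0-9A-Z]*$")


@dataclass(frozen=True)
class CharlsonMap:
    """ICD-10 prefix table for the Charlson categories.

    Attributes
    ----------
    prefixes
        Mapping category -> tuple of upper-case dot-free ICD-10 prefixes.
    weights
        Mapping category -> integer Charlson weight (>= 1).
    supersedes
        Mapping winner-category -> loser-category; when the winner is
        flagged the loser is cleared.
    """

    prefixes: Mapping[str, tuple[str, ...]]
    weights: Mapping[str, int]
    supersedes: Mapping[str, str]
    # (prefix, category) pairs sorted by descending prefix length, for
    # longest-prefix resolution
    _lookup: tuple[tuple[str, str], ...] = field(default=(), repr=False)

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(self.prefixes)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CharlsonMap":
        prefixes: dict[str, list[str]] = {}
        weights: dict[str, int] = {}
        supersedes: dict[str, str] = {}
        for row in frame.itertuples(index=False):
            cat = str(row.category)
            prefixes.setdefault(cat, []).append(str(row.prefix).upper())
            weights[cat] = int(row.weight)
            sup = getattr(row, "supersedes", None)
            if isinstance(sup, str) and sup:
                supersedes[cat] = sup
        lookup = sorted(
            ((p, c) for c, ps in prefixes.items() for p in ps),
            key=lambda pc: -len(pc[0]),
        )
        return cls(
            prefixes={c: tuple(ps) for c, ps in prefixes.items()},
            weights=weights,
            supersedes=supersedes,
            _lookup=tuple(lookup),
        )

    @classmethod
    def from_csv(cls, path) -> "CharlsonMap":
        return cls.from_frame(pd.read_csv(path, keep_default_na=False))

    def match_code(self, code: str) -> str | None:
        """Map one normalized code to its category (longest prefix) or None."""
        for prefix, cat in self._lookup:
            if code.startswith(prefix):
                return cat
        return None


def load_default_map() -> CharlsonMap:
    """Load the shipped Quan ICD-10 / original-weight Charlson table."""
    with resources.files("smokesurg.data").joinpath(
        "charlson_quan_icd10.csv"
    ).open() as fh:
        return CharlsonMap.from_csv(fh)


_DEFAULT_MAP: CharlsonMap | None = None


def _default_map() -> CharlsonMap:
    global _DEFAULT_MAP
    if _DEFAULT_MAP is None:
        _DEFAULT_MAP = load_default_map()
    return _DEFAULT_MAP


def normalize_icd10(code: str) -> str:
    """Upper-case and strip the dot: ``"I21.0" -> "I210"``."""
    return code.strip().upper().replace(".", "")


@dataclass(frozen=True)
class CciResult:
    """Charlson flags plus the derived count, weighted score and count band."""

    flags: Mapping[str, bool]
    count: int
    score: int
    category_band: str  # one of "0","1","2","3","4",">=5"

    def present(self) -> frozenset[str]:
        return frozenset(c for c, f in self.flags.items() if f)


def count_band(count: int) -> str:
    return str(count) if count < 5 else ">=5"


def compute_cci(
    codes: Iterable[str], charlson_map: CharlsonMap | None = None
) -> CciResult:
    """Compute Charlson flags, comorbidity count and weighted score.

    Syntactically invalid codes are logged and skipped.  The empty code set
    yields an all-false result with score 0.
    """
    cmap = charlson_map if charlson_map is not None else _default_map()
    flags = dict.fromkeys(cmap.categories, False)
    for raw in set(codes):
        code = normalize_icd10(str(raw))
        if not _CODE_RE.match(code):
            logger.warning("skipping syntactically invalid ICD-10 code %r", raw)
            continue
        cat = cmap.match_code(code)
        if cat is not None:
            flags[cat] = True
    for winner, loser in cmap.supersedes.items():
        if flags.get(winner):
            flags[loser] = False
    count = sum(flags.values())
    score = sum(cmap.weights[c] for c, f in flags.items() if f)
    return CciResult(
        flags=flags, count=count, score=score, category_band=count_band(count)
    )


def smoking_related_flags(result: CciResult) -> frozenset[str]:
    """Subset of the present categories regarded as potentially smoking-related."""
    return result.present() & SMOKING_RELATED_CATEGORIES


def cci_table(
    diagnosis_events: pd.DataFrame,
    surgeries: pd.DataFrame,
    charlson_map: CharlsonMap | None = None,
    lookback_days: int | None = None,
) -> pd.DataFrame:
    """Per-surgery CCI summary from a diagnosis-event table.

    Only diagnosis events dated on or before the surgery date count
    (optionally restricted to ``lookback_days`` before surgery; default all
    history).  Returns a frame indexed like ``surgeries`` with columns
    ``cci_count``, ``cci_score``, ``cci_band``.
    """
    cmap = charlson_map if charlson_map is not None else _default_map()
    surg = surgeries[["surgery_id", "patient_id", "date"]].copy()
    surg["date"] = pd.to_datetime(surg["date"])
    ev = diagnosis_events.copy()
    ev["date"] = pd.to_datetime(ev["date"])
    merged = surg.merge(ev, on="patient_id", suffixes=("_surg", "_dx"))
    in_window = merged["date_dx"] <= merged["date_surg"]
    if lookback_days is not None:
        in_window &= merged["date_dx"] >= merged["date_surg"] - pd.Timedelta(
            days=lookback_days
        )
    merged = merged[in_window]
    grouped = merged.groupby("surgery_id")["icd10_code"].agg(list)

    rows = []
    for sid in surg["surgery_id"]:
        res = compute_cci(grouped.get(sid, []), cmap)
        rows.append((sid, res.count, res.score, res.category_band))
    return pd.DataFrame(
        rows, columns=["surgery_id", "cci_count", "cci_score", "cci_band"]
    )
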