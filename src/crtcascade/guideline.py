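"""Rule-based comparator: predict CRT response from guideline recommendation class.

Encodes the 2012 ACCF/AHA/HRS-style CRT recommendation classes as an ordered,
editable rule table (first matching row wins, a catch-all "none" row
terminates it).  A patient is predicted to respond iff their recommendation
class is I or IIa.  Sinus-rhythm and medical-therapy criteria are omitted:
they are not among the cohort's recorded variables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

RESPONDER_CLASSES = {"I", "IIa"}


@dataclass(frozen=True)
class RuleRow:
    """One recommendation row: all stated conditions must hold to match.

    ``lbbb`` of None means "either"; bounds of None are unconstrained.
    """

    label: str
    lvef_max: float | None = None
    lbbb: bool | None = None
    qrsd_min: float | None = None
    qrsd_max: float | None = None
    nyha: frozenset[str] = frozenset()

    def matches(self, lvef: float, lbbb: bool, qrsd: float, nyha: str) -> bool:
        if self.lvef_max is not None and lvef > self.lvef_max:
            return False
        if self.lbbb is not None and bool(lbbb) != self.lbbb:
            return False
        if self.qrsd_min is not None and qrsd < self.qrsd_min:
            return False
        if self.qrsd_max is not None and qrsd >= self.qrsd_max:
            return False
        if self.nyha and nyha not in self.nyha:
            return False
        return True


@dataclass
class RecommendationRule:
    """Ordered rule rows; total because the last row is unconditional."""

    rows: list[RuleRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        last = self.rows[-1]
        if any([last.lvef_max is not None, last.lbbb is not None,
                last.qrsd_min is not None, last.qrsd_max is not None, last.nyha]):
            raise ValueError("rule table must end with an unconditional default row")

    @classmethod
    def from_file(cls, path: str | Path) -> "RecommendationRule":
        raw = yaml.safe_load(Path(path).read_text())
        rows = [RuleRow(label=r["label"],
                        lvef_max=r.get("lvef_max"),
                        lbbb=r.get("lbbb"),
                        qrsd_min=r.get("qrsd_min"),
                        qrsd_max=r.get("qrsd_max"),
                        nyha=frozenset(r.get("nyha", [])))
                for r in raw["rules"]]
        return cls(rows=rows)


def default_rules() -> RecommendationRule:
    """Class I: LVEF<=35, LBBB, QRSd>=150 ms, NYHA II-IV.
    Class IIa: same but QRSd 120-149 ms, or non-LBBB with QRSd>=150 ms and
    NYHA III/IV.  Everything else: not recommended."""
    any_nyha = frozenset({"II", "III", "IV"})
    return RecommendationRule(rows=[
        RuleRow("I", lvef_max=35, lbbb=True, qrsd_min=150, nyha=any_nyha),
        RuleRow("IIa", lvef_max=35, lbbb=True, qrsd_min=120, qrsd_max=150,
                nyha=any_nyha),
        RuleRow("IIa", lvef_max=35, lbbb=False, qrsd_min=150,
                nyha=frozenset({"III", "IV"})),
        RuleRow("none"),
    ])


def classify_guideline(
    lvef: float,
    lbbb: bool,
    qrsd: float,
    nyha: str,
    rules: RecommendationRule | None = None,
) -> tuple[str, bool]:
    """Return (recommendation class, predicted responder) for one patient."""
    for name, val in (("lvef", lvef), ("qrsd", qrsd)):
        if val is None or (isinstance(val, float) and math.isnan(val)):
            raise ValueError(f"missing guideline field {name!r}")
    if lbbb is None or nyha is None:
        raise ValueError("missing guideline field lbbb/nyha")
    if not 0 < lvef < 100:
        raise ValueError(f"LVEF {lvef} out of (0, 100)")
    if qrsd <= 0:
        raise ValueError(f"QRSd {qrsd} must be positive")
    rules = rules or default_rules()
    for row in rules.rows:
        if row.matches(lvef, lbbb, qrsd, str(nyha)):
            return row.label, row.label in RESPONDER_CLASSES
    raise AssertionError("rule table is not total")  # unreachable by contract


def guideline_predict_cohort(
    df: pd.DataFrame,
    column_map: dict[str, str] | None = None,
    rules: RecommendationRule | None = None,
    nyha_levels: Sequence[str] = ("II", "III", "IV"),
) -> np.ndarray:
    """Per-patient responder predictions from the rule table.

    ``column_map`` maps the required fields {lvef, lbbb, qrsd, nyha} to the
    cohort's column names.  NYHA may be stored numerically (2/3/4); it is
    mapped onto ``nyha_levels``.
    """
    column_map = column_map or {k: k for k in ("lvef", "lbbb", "qrsd", "nyha")}
    missing = [v for v in column_map.values() if v not in df.columns]
    if missing:
        raise ValueError(f"guideline columns absent from cohort: {missing}")
    roman = {str(i + 2): lev for i, lev in enumerate(nyha_levels)}
    preds = np.zeros(len(df), dtype=int)
    for i, (_, row) in enumerate(df.iterrows()):
        nyha = row[column_map["nyha"]]
        nyha = roman.get(str(int(nyha)) if isinstance(nyha, (int, float)) else str(nyha),
                         str(nyha))
        _, responder = classify_guideline(
            lvef=float(row[column_map["lvef"]]),
            lbbb=bool(row[column_map["lbbb"]]),
            qrsd=float(row[column_map["qrsd"]]),
            nyha=nyha,
            rules=rules,
        )
        preds[i] = int(responder)
    return preds
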