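"""Ten-criterion active-compound (ADMET) screen.

A compound passes when all of the following hold, with inclusive bounds:
MW <= 500, Hdon <= 5, Hacc <= 10, AlogP <= 5, RBN <= 10 (Lipinski-style
rules) plus OB >= 30 %, DL >= 0.1, BBB >= 0.3, Caco-2 >= 0.4 and
TPSA <= 60 A^2 (database-style drugability criteria).

Missing values are handled by policy: ``strict`` raises, ``fail`` treats
the criterion as failed (the conservative default — an absent database
value cannot be assumed favourable), ``skip`` ignores the criterion.
Compounds flagged ``literature`` bypass the screen entirely; this mirrors
workflows that merge screened database compounds with literature-curated
ones lacking property records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .config import DEFAULT_ADMET_THRESHOLDS
from .errors import DataError

CRITERIA = tuple(DEFAULT_ADMET_THRESHOLDS)
_POLICIES = ("strict", "fail", "skip")


@dataclass(frozen=True)
class AdmetVerdict:
    compound_id: str
    passed: bool
    failed_criteria: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.passed != (len(self.failed_criteria) == 0):
            raise ValueError("passed flag inconsistent with failed_criteria")


def _is_missing(value) -> bool:
    if value is None:
        return True
    try:
        return math.isnan(float(value))
    except (TypeError, ValueError):
        return True


def screen_compound(props: dict, compound_id: str = "", policy: str = "fail",
                    thresholds: dict | None = None,
                    literature: bool = False) -> AdmetVerdict:
    """Apply the ten inclusive criteria to one property record."""
    if policy not in _POLICIES:
        raise DataError(f"unknown missing-value policy {policy!r}")
    thresholds = thresholds or DEFAULT_ADMET_THRESHOLDS
    if literature:
        return AdmetVerdict(compound_id, True, ())
    failed = []
    for name, (direction, bound) in thresholds.items():
        value = props.get(name)
        if _is_missing(value):
            if policy == "strict":
                raise DataError(f"compound {compound_id or '?'}: missing ADMET field {name}")
            if policy == "fail":
                failed.append(name)
            continue
        value = float(value)
        ok = value <= bound if direction == "le" else value >= bound
        if not ok:
            failed.append(name)
    return AdmetVerdict(compound_id, not failed, tuple(failed))


def screen_table(compounds: pd.DataFrame, policy: str = "fail",
                 thresholds: dict | None = None,
                 id_column: str = "compound_id") -> tuple[set[str], pd.DataFrame]:
    """Screen every row; returns (passing id set, verdict table).

    The verdict table has one row per input row, in input order, with
    columns ``compound_id``, ``passed`` and ``failed_criteria``
    (comma-joined). A boolean ``literature`` column in the input marks
    bypass compounds.
    """
    if compounds is None or len(compounds) == 0:
        raise DataError("screen_table: empty compound table")
    has_lit = "literature" in compounds.columns
    rows = []
    for _, row in compounds.iterrows():
        verdict = screen_compound(
            row.to_dict(), compound_id=str(row[id_column]), policy=policy,
            thresholds=thresholds,
            literature=bool(row["literature"]) if has_lit else False)
        rows.append({
            "compound_id": verdict.compound_id,
            "passed": verdict.passed,
            "failed_criteria": ",".join(verdict.failed_criteria),
        })
    verdicts = pd.DataFrame(rows)
    passing = set(verdicts.loc[verdicts["passed"], "compound_id"])
    return passing, verdicts
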