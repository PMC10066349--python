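"""Tabular I/O and schema validation for the pipeline's CSV contracts.

All files are UTF-8 CSV with a header row, '.' decimal and empty fields
for missing values; downstream analyses list-wise delete incomplete rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from altrudisc.config import HEXACO_TRAITS
from altrudisc.discounting import AMOUNTS, DISTANCES

__all__ = ["ValidationReport", "validate_choices", "validate_cohort", "validate_tables"]


@dataclass
class ValidationReport:
    """Per-file validation outcome; ``ok`` only if every file passed."""

    results: dict[str, list[str]] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return all(not errs for errs in self.results.values())

    def summary(self) -> str:
        lines = []
        for path, errs in self.results.items():
            status = "PASS" if not errs else f"FAIL ({errs[0]})"
            lines.append(f"{path}: {status}")
        return "\n".join(lines)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps({"ok": self.ok, "files": self.results}, indent=2)
        )


def validate_choices(df: pd.DataFrame) -> list[str]:
    """Choice-table invariants: 9-trial blocks on the exact amount ladder."""
    errors: list[str] = []
    required = {"participant_id", "distance", "amount_selfish", "choice"}
    missing = required - set(df.columns)
    if missing:
        return [f"missing columns {sorted(missing)}"]
    bad_dist = ~df["distance"].isin(DISTANCES)
    if bad_dist.any():
        row = int(np.where(bad_dist)[0][0])
        errors.append(f"row {row}: distance {df['distance'].iloc[row]} not in task grid")
    bad_amount = ~df["amount_selfish"].isin(AMOUNTS)
    if bad_amount.any():
        row = int(np.where(bad_amount)[0][0])
        errors.append(
            f"row {row}: amount {df['amount_selfish'].iloc[row]} not on the $155..$75 ladder"
        )
    bad_choice = ~df["choice"].isin((0, 1))
    if bad_choice.any():
        row = int(np.where(bad_choice)[0][0])
        errors.append(f"row {row}: choice must be 0/1")
    if not errors:
        sizes = df.groupby(["participant_id", "distance"]).size()
        wrong = sizes[sizes != 9]
        if len(wrong):
            pid, dist = wrong.index[0]
            errors.append(
                f"trial count: participant {pid!r} distance {dist} has "
                f"{wrong.iloc[0]} trials (9 required)"
            )
        dup = df.groupby(["participant_id", "distance"])["amount_selfish"].nunique()
        bad = dup[dup != 9]
        if len(bad):
            pid, dist = bad.index[0]
            errors.append(
                f"duplicate amounts: participant {pid!r} distance {dist}"
            )
    return errors


def validate_cohort(df: pd.DataFrame) -> list[str]:
    """Cohort-table invariants: ids unique, scales within range."""
    errors: list[str] = []
    if "participant_id" not in df.columns or "group" not in df.columns:
        return ["missing columns ['group', 'participant_id']"]
    if df["participant_id"].duplicated().any():
        row = int(np.where(df["participant_id"].duplicated())[0][0])
        errors.append(f"row {row}: duplicate participant_id")
    for trait in HEXACO_TRAITS:
        if trait not in df.columns:
            continue
        vals = pd.to_numeric(df[trait], errors="coerce")
        bad = vals.notna() & ((vals < 1) | (vals > 5))
        if bad.any():
            row = int(np.where(bad)[0][0])
            errors.append(
                f"row {row}: {trait} = {vals.iloc[row]} outside the 1-5 scale"
            )
    if "sex" in df.columns:
        bad = ~df["sex"].isin(("Male", "Female"))
        if bad.any():
            row = int(np.where(bad)[0][0])
            errors.append(f"row {row}: sex must be Male/Female")
    if "crt" in df.columns:
        vals = pd.to_numeric(df["crt"], errors="coerce")
        bad = vals.notna() & ~vals.isin((0, 1, 2, 3))
        if bad.any():
            row = int(np.where(bad)[0][0])
            errors.append(f"row {row}: crt outside 0..3")
    return errors


_VALIDATORS = {
    "choices": validate_choices,
    "cohort": validate_cohort,
}


def validate_tables(paths: dict[str, str | Path]) -> ValidationReport:
    """Validate named CSV files (keys: 'choices', 'cohort', ...).

    Unknown keys are checked only for readability.
    """
    report = ValidationReport()
    for kind, path in paths.items():
        path = Path(path)
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # unreadable file
            report.results[str(path)] = [f"I/O error: {exc}"]
            continue
        validator = _VALIDATORS.get(kind)
        report.results[str(path)] = validator(df) if validator else []
    return report
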