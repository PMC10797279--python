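"""Outcome code definitions for post-discharge depression/anxiety.

Depression is identified by ICD-10 diagnoses F31-F34, F39 and F06.3 or by
antidepressant use (ATC N06A); anxiety by ICD-10 F40-F43 and F06.4 or by
anxiolytic use (ATC N05B).  Matching is prefix-based, case-insensitive and
tolerant of the dot in ICD codes, so "f063" and "F06.3" are equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass

DEPRESSION_ICD_PREFIXES = ("F31", "F32", "F33", "F34", "F39", "F06.3")
ANXIETY_ICD_PREFIXES = ("F40", "F41", "F42", "F43", "F06.4")
ANTIDEPRESSANT_ATC_PREFIXES = ("N06A",)
ANXIOLYTIC_ATC_PREFIXES = ("N05B",)

# Concrete codes the synthetic generator plants as outcome events.
DEPRESSION_EVENT_ICD = ("F31.1", "F32.0", "F32.1", "F32.9", "F33.1", "F34.1", "F39", "F06.3")
ANXIETY_EVENT_ICD = ("F40.0", "F41.0", "F41.1", "F42.9", "F43.0", "F43.2", "F06.4")
ANTIDEPRESSANT_EVENT_ATC = ("N06AA09", "N06AB03", "N06AB06", "N06AX11")
ANXIOLYTIC_EVENT_ATC = ("N05BA01", "N05BA12", "N05BE01")

OUTCOME_EVENT_ICD = DEPRESSION_EVENT_ICD + ANXIETY_EVENT_ICD
OUTCOME_EVENT_ATC = ANTIDEPRESSANT_EVENT_ATC + ANXIOLYTIC_EVENT_ATC


def normalize_code(code: str) -> str:
    return code.upper().replace(".", "").strip()


def _match(code: str, prefixes: tuple[str, ...]) -> bool:
    c = normalize_code(code)
    return any(c.startswith(normalize_code(p)) for p in prefixes)


@dataclass(frozen=True)
class OutcomeCodeSets:
    """Prefix sets defining depression/anxiety outcome events."""

    depression_icd: tuple[str, ...] = DEPRESSION_ICD_PREFIXES
    anxiety_icd: tuple[str, ...] = ANXIETY_ICD_PREFIXES
    antidepressant_atc: tuple[str, ...] = ANTIDEPRESSANT_ATC_PREFIXES
    anxiolytic_atc: tuple[str, ...] = ANXIOLYTIC_ATC_PREFIXES

    def matches_diagnosis(self, code: str) -> bool:
        return _match(code, self.depression_icd) or _match(code, self.anxiety_icd)

    def matches_medication(self, code: str) -> bool:
        return _match(code, self.antidepressant_atc) or _match(code, self.anxiolytic_atc)

    def is_outcome(self, kind: str, code: str) -> bool:
        if kind == "diagnosis":
            return self.matches_diagnosis(code)
        if kind == "medication":
            return self.matches_medication(code)
        raise ValueError(f"unknown event kind: {kind!r}")
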