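"""Proficiency-test adjudication with censoring-aware verdicts.

Interlaboratory proficiency tests judge a calculated plasma concentration
against an organizer-defined acceptance range.  Because this screen is
designed for the upper-therapeutic-to-toxic range, PT target values often
lie below its LLOQ; a censored result then still demonstrates qualitative
detection.  The verdict semantics:

* numeric result — Passed iff accepted_low ≤ calculated ≤ accepted_high
  (inclusive), otherwise Failed;
* ``<LLOQ`` (detected, below the quantification range) — the censored
  result is consistent with the acceptance range whenever that range
  reaches below the LLOQ, so Passed_below_LLOQ when accepted_low < LLOQ,
  otherwise Failed (a quantifiable result was expected);
* ``nd`` (not detected) — Failed; annotated Failed_below_LLOQ when the
  target was below the LLOQ (detection was still expected).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .panel_io import PanelEntry, PTEntry

__all__ = ["PTVerdict", "ConcordanceReport", "adjudicate",
           "adjudicate_batch"]

VERDICTS = ("Passed", "Failed", "Passed_below_LLOQ", "Failed_below_LLOQ")


@dataclass(frozen=True)
class PTVerdict:
    """Deterministic verdict for one PT row."""

    verdict: str
    rationale: str

    def __post_init__(self):
        if self.verdict not in VERDICTS:
            raise ValueError(f"unknown verdict {self.verdict!r}")

    @property
    def passed(self) -> bool:
        return self.verdict.startswith("Passed")


@dataclass(frozen=True)
class ConcordanceReport:
    """Replay of a PT table against its reference comments."""

    verdicts: tuple[PTVerdict, ...]
    n_compared: int
    n_concordant: int
    discordant_rows: tuple[int, ...]          # pass/fail outcome flips
    annotation_only_rows: tuple[int, ...]     # <LLOQ annotation differs only

    @property
    def concordance_pct(self) -> float:
        if self.n_compared == 0:
            return 100.0
        return 100.0 * self.n_concordant / self.n_compared


def adjudicate(entry: PTEntry, lloq: float) -> PTVerdict:
    """Adjudicate one proficiency-test row against its acceptance range."""
    if lloq is None or lloq <= 0:
        raise ValueError(f"{entry.analyte_name}: LLOQ missing")
    lo, hi = entry.accepted_low, entry.accepted_high
    if entry.censored == "":
        c = entry.calculated
        if lo <= c <= hi:
            return PTVerdict("Passed",
                             f"{c:g} ng/mL within accepted {lo:g}-{hi:g}")
        side = "below" if c < lo else "above"
        return PTVerdict("Failed",
                         f"{c:g} ng/mL {side} accepted {lo:g}-{hi:g}")
    if entry.censored == "<LLOQ":
        if lo < lloq:
            return PTVerdict(
                "Passed_below_LLOQ",
                f"detected below LLOQ {lloq:g}; accepted range reaches "
                f"below the LLOQ, censored result consistent")
        return PTVerdict(
            "Failed",
            f"result censored below LLOQ {lloq:g} but accepted range "
            f"{lo:g}-{hi:g} lies entirely above it; quantifiable result "
            f"expected")
    # nd: detection expected in every case
    if entry.target < lloq:
        return PTVerdict(
            "Failed_below_LLOQ",
            f"not detected; target {entry.target:g} ng/mL below LLOQ "
            f"{lloq:g} but detection was expected")
    return PTVerdict(
        "Failed",
        f"not detected; target {entry.target:g} ng/mL within the "
        f"quantifiable range")


def _parse_reference_comment(comment: str) -> tuple[bool, bool]:
    """(passed, below_lloq_annotated) from a printed PT comment."""
    c = comment.strip().lower()
    passed = c.startswith("passed")
    below = "lloq" in c
    return passed, below


def adjudicate_batch(entries: Sequence[PTEntry],
                     panel: Sequence[PanelEntry],
                     lloq_overrides: Optional[dict[str, float]] = None,
                     ) -> ConcordanceReport:
    """Adjudicate a PT table and summarize concordance with its comments.

    The LLOQ for each row is resolved in precedence order: an explicit
    ``lloq_overrides`` entry, the LLOQ recorded with the PT row itself
    (PT reports state the LLOQ in force at measurement time, which can
    differ from the current panel), the censoring limit of a ``<X``
    token, then the panel.  An analyte resolvable nowhere raises.  When
    rows carry a
    reference comment, the report counts pass/fail concordance and lists
    discordant row indices (0-based) with their rationale retained in the
    verdicts.  Rows agreeing on the outcome but differing only in the
    "(< LLOQ)" annotation are listed separately and not counted
    discordant — the printed comments themselves annotate that case
    inconsistently.
    """
    lloq_by_name = {e.analyte_name: e.lloq for e in panel}
    verdicts: list[PTVerdict] = []
    discordant: list[int] = []
    annotation_only: list[int] = []
    n_compared = 0
    n_concordant = 0
    for i, entry in enumerate(entries):
        if lloq_overrides and entry.analyte_name in lloq_overrides:
            lloq = lloq_overrides[entry.analyte_name]
        elif entry.lloq is not None:
            lloq = entry.lloq
        elif entry.censor_limit is not None:
            lloq = entry.censor_limit
        elif entry.analyte_name in lloq_by_name:
            lloq = lloq_by_name[entry.analyte_name]
        else:
            raise KeyError(f"unknown analyte: {entry.analyte_name!r}")
        v = adjudicate(entry, lloq)
        verdicts.append(v)
        if entry.reference_comment:
            n_compared += 1
            ref_passed, ref_below = _parse_reference_comment(
                entry.reference_comment)
            if v.passed == ref_passed:
                n_concordant += 1
                if ("below_LLOQ" in v.verdict) != ref_below:
                    annotation_only.append(i)
            else:
                discordant.append(i)
    return ConcordanceReport(verdicts=tuple(verdicts),
                             n_compared=n_compared,
                             n_concordant=n_concordant,
                             discordant_rows=tuple(discordant),
                             annotation_only_rows=tuple(annotation_only))
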