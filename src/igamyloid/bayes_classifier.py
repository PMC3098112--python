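"""Positional naive Bayes classification of germline derivatives.

For a test sequence s with mutated-position set M, the amyloidogenic class
score is the product over unmasked, ungapped columns of p_AM(x) for x in M
and q_AM(x) = 1 - p_AM(x) otherwise; the non-amyloidogenic score uses
p_NAM/q_NAM.  The sequence is called AM when the AM product is strictly
greater.  Products are accumulated in log space: at realistic variable-domain
lengths (~110 columns) the raw products underflow double precision.

Evaluation follows the germline-stratified convention: per germline and per
class we report correct (C) over attempted (A), and the headline accuracy is
the unweighted mean +/- sd of per-germline C/A values (a pooled micro
accuracy is also available).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment_io import GAP, AlignmentError, GermlineAlignment, SequenceRecord
from .mutation_model import (
    MutationSet,
    PositionalProfile,
    estimate_profile,
    mutated_positions,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BayesResult:
    """Log class scores and the resulting label for one sequence."""

    record_id: str
    log_am: float
    log_nam: float
    germline_id: str

    @property
    def label(self) -> str:
        # Tie -> NAM: do not flag a sequence amyloidogenic without evidence.
        return "AM" if self.log_am > self.log_nam else "NAM"


def _scored_positions(
    record: SequenceRecord, aln: GermlineAlignment
) -> list[int]:
    """Unmasked columns where neither germline nor record has a gap."""
    return [
        pos
        for pos in aln.analysis_range
        if GAP not in (aln.germline_seq[pos - 1], record.sequence[pos - 1])
    ]


def bayes_score(
    ms: MutationSet,
    profile: PositionalProfile,
    positions: Sequence[int] | None = None,
) -> BayesResult:
    """Score a mutated-position set against a positional profile.

    ``positions`` restricts the product to the given columns (used to skip
    a test sequence's gap columns); by default all profile positions enter.
    """
    if ms.germline_id != profile.germline_id:
        raise AlignmentError(
            f"mutation set is for germline {ms.germline_id!r}, profile for "
            f"{profile.germline_id!r}"
        )
    pos_iter = profile.positions if positions is None else positions
    pos_set = set(profile.positions)
    mutated = ms.positions
    outside = mutated - pos_set
    if outside:
        raise AlignmentError(
            f"record {ms.record_id!r}: mutated positions {sorted(outside)} "
            "outside the profile's analysis range"
        )
    log_am = 0.0
    log_nam = 0.0
    for x in pos_iter:
        if x in mutated:
            log_am += math.log(profile.p_am[x])
            log_nam += math.log(profile.p_nam[x])
        else:
            log_am += math.log(1.0 - profile.p_am[x])
            log_nam += math.log(1.0 - profile.p_nam[x])
    return BayesResult(
        record_id=ms.record_id,
        log_am=log_am,
        log_nam=log_nam,
        germline_id=profile.germline_id,
    )


def classify(
    record: SequenceRecord,
    aln: GermlineAlignment,
    profile: PositionalProfile | None = None,
) -> BayesResult:
    """Classify one sequence against its germline's training profile.

    The profile is estimated from all labelled derivatives of ``aln``
    unless one is supplied (e.g. a leave-one-out profile).
    """
    from .mutation_model import call_mutations

    if profile is None:
        profile = estimate_profile(aln)
    ms = call_mutations(record, aln)
    return bayes_score(ms, profile, positions=_scored_positions(record, aln))


@dataclass
class EvaluationTable:
    """Per-germline correct/attempted tallies per class, Table-style.

    ``rows[germline][cls]`` is a ``(correct, attempted)`` pair.  The macro
    average is the unweighted mean of per-germline C/A over germlines with
    A > 0 for that class.
    """

    rows: dict[str, dict[str, tuple[int, int]]] = field(default_factory=dict)

    def add(self, germline_id: str, cls: str, correct: bool) -> None:
        row = self.rows.setdefault(germline_id, {})
        c, a = row.get(cls, (0, 0))
        row[cls] = (c + int(correct), a + 1)

    def merge(self, other: "EvaluationTable") -> "EvaluationTable":
        out = EvaluationTable()
        for table in (self, other):
            for germline, row in table.rows.items():
                for cls, (c, a) in row.items():
                    dest = out.rows.setdefault(germline, {})
                    pc, pa = dest.get(cls, (0, 0))
                    dest[cls] = (pc + c, pa + a)
        return out

    def per_germline_accuracy(self, cls: str) -> dict[str, float]:
        out = {}
        for germline, row in self.rows.items():
            c, a = row.get(cls, (0, 0))
            if a > 0:
                out[germline] = c / a
        return out

    def macro_accuracy(self, cls: str) -> tuple[float, float]:
        """Mean +/- sd (ddof=0) of per-germline accuracy for ``cls``."""
        accs = list(self.per_germline_accuracy(cls).values())
        if not accs:
            return (float("nan"), float("nan"))
        return (float(np.mean(accs)), float(np.std(accs)))

    def micro_accuracy(self, cls: str | None = None) -> float:
        c_tot = a_tot = 0
        for row in self.rows.values():
            for row_cls, (c, a) in row.items():
                if cls is None or row_cls == cls:
                    c_tot += c
                    a_tot += a
        return c_tot / a_tot if a_tot else float("nan")

    def to_frame(self) -> pd.DataFrame:
        records = []
        for germline in sorted(self.rows):
            row = self.rows[germline]
            rec: dict[str, object] = {"germline": germline}
            for cls in ("AM", "NAM"):
                c, a = row.get(cls, (0, 0))
                rec[f"{cls}_C"] = c
                rec[f"{cls}_A"] = a
            records.append(rec)
        return pd.DataFrame(
            records, columns=["germline", "AM_C", "AM_A", "NAM_C", "NAM_A"]
        )


def loo_cross_validate(aln: GermlineAlignment) -> EvaluationTable:
    """Leave-one-out cross-validation of the Bayes classifier.

    Each labelled derivative is classified with a profile re-estimated
    after removing it from its own class only.  Records whose class has a
    single member are skipped with a warning (no fold can be formed) and
    excluded from the attempted count.
    """
    table = EvaluationTable()
    for rec in aln.derivatives:
        if rec.label not in ("AM", "NAM"):
            continue
        if len(aln.members(rec.label)) < 2:
            logger.warning(
                "LOO: skipping %s (class %s has a single member for "
                "germline %s)",
                rec.id,
                rec.label,
                aln.germline_id,
            )
            continue
        profile = estimate_profile(
            aln, exclude_id=rec.id, exclude_from=rec.label
        )
        result = classify(rec, aln, profile=profile)
        table.add(aln.germline_id, rec.label, result.label == rec.label)
    return table


def holdout_evaluate(
    train: GermlineAlignment | Iterable[GermlineAlignment] | Mapping[str, GermlineAlignment],
    test: Iterable[SequenceRecord],
) -> EvaluationTable:
    """Train once per germline and classify an independent labelled set.

    Test records whose germline has no trained alignment are reported as
    unassigned (warning) and excluded from the attempted counts.
    """
    if isinstance(train, GermlineAlignment):
        alns = {train.germline_id: train}
    elif isinstance(train, Mapping):
        alns = dict(train)
    else:
        alns = {a.germline_id: a for a in train}
    profiles = {gid: estimate_profile(a) for gid, a in alns.items()}

    table = EvaluationTable()
    for rec in test:
        if rec.label not in ("AM", "NAM"):
            continue
        if rec.germline_id not in alns:
            logger.warning(
                "holdout: record %s has unknown germline %r; excluded",
                rec.id,
                rec.germline_id,
            )
            continue
        aln = alns[rec.germline_id]
        result = classify(rec, aln, profile=profiles[rec.germline_id])
        table.add(rec.germline_id, rec.label, result.label == rec.label)
    return table
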