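"""Ground-truth quality metrics for validating the perplexity surrogate.

On synthetic data with retained truth, correction quality is measured
directly against the error-free sequences: base accuracy (fraction of bases
matching truth after correction) and EC gain,

    gain = (errors_removed - errors_introduced) / errors_before,

the net fraction of original errors removed, penalized for errors the
corrector introduces.  Base accuracy stands in for the alignment rate a
reference-based evaluation would use; all reports state it as such.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .readset_io import ReadSet
from .synthetic_errors import SimulatedDataset, TruthRecord

__all__ = ["EvaluationError", "CorrectionReport", "score_correction", "pearson"]


class EvaluationError(ValueError):
    """Mismatched read sets or degenerate statistical input."""


@dataclass(frozen=True)
class CorrectionReport:
    """Positionwise accounting of a correction run against simulated truth."""

    base_accuracy: float
    errors_before: int
    errors_after: int
    errors_removed: int
    errors_introduced: int
    ec_gain: float


def _truth_map(truth) -> Mapping[str, str]:
    if isinstance(truth, SimulatedDataset):
        return {rid: rec.sequence for rid, rec in truth.truth.items()}
    if isinstance(truth, Mapping):
        first = next(iter(truth.values()), None)
        if isinstance(first, TruthRecord):
            return {rid: rec.sequence for rid, rec in truth.items()}
        return truth
    raise EvaluationError("truth must be a SimulatedDataset or a mapping")


def _bytes(s: str) -> np.ndarray:
    return np.frombuffer(s.encode(), dtype=np.uint8)


def score_correction(
    original: ReadSet, corrected: ReadSet, truth
) -> CorrectionReport:
    """Compare `corrected` against `original` positionwise, relative to truth.

    Requires equal read counts, matching identifiers and equal lengths per
    read triple (a substitution-only pipeline).  A position counts as
    *removed* if it was wrong before and right after correction, and
    *introduced* if right before and wrong after.
    """
    if len(original) != len(corrected):
        raise EvaluationError(
            f"read count mismatch: {len(original)} original vs {len(corrected)} corrected"
        )
    truth_seqs = _truth_map(truth)
    total = before = after = removed = introduced = 0
    for orig, corr in zip(original, corrected):
        if orig.identifier != corr.identifier:
            raise EvaluationError(
                f"identifier mismatch: {orig.identifier!r} vs {corr.identifier!r}"
            )
        if orig.identifier not in truth_seqs:
            raise EvaluationError(f"no truth record for {orig.identifier!r}")
        t = truth_seqs[orig.identifier]
        if not len(orig) == len(corr) == len(t):
            raise EvaluationError(
                f"length mismatch for {orig.identifier!r}: "
                f"{len(orig)}/{len(corr)}/{len(t)}"
            )
        o, c, tt = _bytes(orig.sequence), _bytes(corr.sequence), _bytes(t)
        wrong_before = o != tt
        wrong_after = c != tt
        before += int(wrong_before.sum())
        after += int(wrong_after.sum())
        removed += int((wrong_before & ~wrong_after).sum())
        introduced += int((~wrong_before & wrong_after).sum())
        total += len(t)
    base_accuracy = 1.0 - after / total
    ec_gain = (removed - introduced) / before if before else 0.0
    return CorrectionReport(
        base_accuracy=base_accuracy,
        errors_before=before,
        errors_after=after,
        errors_removed=removed,
        errors_introduced=introduced,
        ec_gain=ec_gain,
    )


def pearson(xs, ys) -> float:
    """Product-moment correlation of two equal-length series (n >= 3)."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.ndim != 1 or len(xs) < 3:
        raise EvaluationError("pearson needs two equal-length 1-D series, n >= 3")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise EvaluationError("pearson is undefined for a zero-variance series")
    return float(stats.pearsonr(xs, ys).statistic)
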