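"""Relative transcript quantification (2^−ΔΔCt), enzyme fold changes, and
transcript–protein concordance calls.

Target-gene Ct values are normalized against the actin reference
(ΔCt = Ct_target − Ct_actin, averaged over replicates within a group);
the untreated control is the calibrator (ΔΔCt = ΔCt_sample − ΔCt_control)
and relative abundance is 2^−ΔΔCt. Group differences are assessed with the
classical pooled-variance two-sample t-test.

Enzyme activities are expressed as fold change over control; a
not-detected treated activity (``"ND"`` sentinel) yields a flagged
zero-fold record rather than an error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QpcrRecord",
    "ConcordanceCall",
    "EnzymeFold",
    "UndefinedStatisticError",
    "ddct_fold_change",
    "delta_ct",
    "ttest_two_sample",
    "enzyme_fold_change",
    "concordance",
    "ND",
]

ND = "ND"  # not-detected sentinel in enzyme activity tables

CONCORDANT = "concordant"
DISCORDANT = "discordant"
UNCOUPLED = "uncoupled"


class UndefinedStatisticError(ValueError):
    """The t statistic is 0/0 (zero pooled variance, equal means)."""


@dataclass(frozen=True)
class QpcrRecord:
    """Per-replicate target/reference Ct values for one gene, one treatment."""

    gene: str
    treatment: str
    replicate: int
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for name, ct in (
            ("ct_target", self.ct_target),
            ("ct_reference", self.ct_reference),
        ):
            if not 0 < ct < 45:
                raise ValueError(f"{name}={ct} outside the plausible (0, 45)")


@dataclass(frozen=True)
class EnzymeFold:
    """Fold change of an enzyme activity over control."""

    fold: float
    not_detected: bool = False


@dataclass(frozen=True)
class ConcordanceCall:
    """Agreement between a transcript and a protein fold change."""

    gene: str
    stress: str
    transcript_fold: float
    protein_fold: float
    call: str


def delta_ct(records: list[QpcrRecord]) -> float:
    """Mean ΔCt = mean(Ct_target − Ct_reference) over replicates."""
    if not records:
        raise ValueError("empty record set")
    genes = {r.gene for r in records}
    if len(genes) > 1:
        raise ValueError(f"records mix genes: {sorted(genes)}")
    return float(np.mean([r.ct_target - r.ct_reference for r in records]))


def ddct_fold_change(
    sample: list[QpcrRecord], calibrator: list[QpcrRecord]
) -> float:
    """Relative abundance 2^−ΔΔCt of a sample versus its calibrator.

    ΔΔCt = ΔCt_sample − ΔCt_calibrator with per-group mean ΔCt. Both record
    sets must be for the same gene.
    """
    if not sample or not calibrator:
        raise ValueError("sample and calibrator must be nonempty")
    gs = {r.gene for r in sample} | {r.gene for r in calibrator}
    if len(gs) > 1:
        raise ValueError(f"sample/calibrator gene mismatch: {sorted(gs)}")
    ddct = delta_ct(sample) - delta_ct(calibrator)
    return float(2.0 ** (-ddct))


def ttest_two_sample(group_a, group_b) -> tuple[float, float]:
    """Classical pooled-variance two-sample t-test (two-sided).

    Raises :class:`UndefinedStatisticError` when both groups are constant
    with equal means (0/0 statistic).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        raise UndefinedStatisticError(
            "zero pooled variance with equal means: t undefined"
        )
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def enzyme_fold_change(
    treated_activity: float | str, control_activity: float
) -> EnzymeFold:
    """Enzyme activity fold change over control.

    A treated activity given as the ``"ND"`` sentinel (assay below
    detection) returns a flagged zero-fold record.
    """
    if control_activity <= 0:
        raise ValueError(
            f"control activity must be positive, got {control_activity}"
        )
    if isinstance(treated_activity, str):
        if treated_activity.strip().upper() == ND:
            return EnzymeFold(fold=0.0, not_detected=True)
        raise ValueError(f"unrecognized activity value {treated_activity!r}")
    if treated_activity < 0:
        raise ValueError("treated activity must be nonnegative")
    return EnzymeFold(fold=float(treated_activity) / float(control_activity))


def concordance(
    transcript_fold: float,
    protein_fold: float,
    neutral_band: tuple[float, float] = (1 / 1.5, 1.5),
    gene: str = "",
    stress: str = "",
) -> ConcordanceCall:
    """Compare transcript and protein responses to the same stress.

    Folds outside the neutral band on the same side agree (concordant);
    opposite sides disagree (discordant); exactly one inside the band means
    the two layers are uncoupled; both inside is agreement on no change.
    """
    lo, hi = neutral_band
    if not (transcript_fold > 0 and protein_fold > 0):
        raise ValueError("fold changes must be positive")
    if not 0 < lo < 1 < hi:
        raise ValueError("neutral band must bracket 1")

    def side(fold: float) -> int:
        if fold >= hi:
            return 1
        if fold <= lo:
            return -1
        return 0

    st, sp = side(transcript_fold), side(protein_fold)
    if st == sp:
        call = CONCORDANT
    elif st == 0 or sp == 0:
        call = UNCOUPLED
    else:
        call = DISCORDANT
    return ConcordanceCall(
        gene=gene,
        stress=stress,
        transcript_fold=float(transcript_fold),
        protein_fold=float(protein_fold),
        call=call,
    )


def qpcr_table_to_records(table: pd.DataFrame) -> dict[tuple[str, str], list[QpcrRecord]]:
    """Group a long-format Ct table into (gene, treatment) → records."""
    needed = {"gene", "treatment", "replicate", "ct_target", "ct_reference"}
    missing = needed - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    out: dict[tuple[str, str], list[QpcrRecord]] = {}
    for row in table.itertuples(index=False):
        rec = QpcrRecord(
            gene=str(row.gene),
            treatment=str(row.treatment),
            replicate=int(row.replicate),
            ct_target=float(row.ct_target),
            ct_reference=float(row.ct_reference),
        )
        out.setdefault((rec.gene, rec.treatment), []).append(rec)
    for key, recs in out.items():
        if len(recs) < 2:
            raise ValueError(f"fewer than 2 replicates for {key}")
    return out
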