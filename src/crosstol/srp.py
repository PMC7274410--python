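"""Stress-responsive protein (SRP) selection and expression clustering.

Works on long-format replicated 2-DE spot-density tables with the four
treatment conditions C (control), WS (water stress), HS (heat stress) and
WS+HS (combined). A spot is stress-responsive when a one-way ANOVA across
the four conditions gives p < alpha AND at least one stress shows a fold
change versus control of at least 1.5 (up) or at most 1/1.5 (down); both
thresholds are inclusive and configurable.

Selected spots are assigned to four expression classes from their
per-stress directions:

* I   — increased under at least one stress, decreased under none;
* II  — decreased under at least one stress, increased under none;
* III — unchanged under all three stresses;
* IV  — mixed, both increases and decreases present.

For display ordering, the spot × condition fold-change matrix can be
clustered agglomeratively with centroid linkage on Euclidean distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage

__all__ = [
    "CONDITIONS",
    "CONTROL",
    "STRESSES",
    "SPOT_COLUMNS",
    "SrpRecord",
    "UndefinedStatisticError",
    "validate_spot_table",
    "anova_oneway",
    "fold_change",
    "direction_of",
    "select_srp",
    "assign_cluster",
    "hierarchical_cluster",
    "ratio_matrix",
]

logger = logging.getLogger(__name__)

CONTROL = "C"
STRESSES = ("WS", "HS", "WS+HS")
CONDITIONS = (CONTROL,) + STRESSES
SPOT_COLUMNS = (
    "spot_id", "accession", "category",
    "cultivar", "condition", "replicate", "density",
)
UP, DOWN, UNCHANGED = "up", "down", "unchanged"


class UndefinedStatisticError(ValueError):
    """The test statistic is 0/0 (no variance anywhere)."""


@dataclass(frozen=True)
class SrpRecord:
    """One selected stress-responsive spot with its evidence."""

    spot_id: str
    cultivar: str
    fold_changes: dict[str, float]       # stress -> treatment/control ratio
    directions: dict[str, str]           # stress -> up/down/unchanged
    anova_p: float
    cluster: str                         # I, II, III or IV


def validate_spot_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format spot table's columns, conditions and densities."""
    missing = set(SPOT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"spot table missing columns: {sorted(missing)}")
    bad = set(table["condition"].unique()) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown conditions: {sorted(bad)}")
    if (table["density"] < 0).any() or table["density"].isna().any():
        raise ValueError("densities must be nonnegative and non-missing")
    counts = table.groupby(
        ["spot_id", "cultivar", "condition"], sort=False
    ).size()
    if (counts < 2).any():
        offender = counts[counts < 2].index[0]
        raise ValueError(f"fewer than 2 replicates for {offender}")
    return table


def anova_oneway(*groups) -> tuple[float, float]:
    """One-way ANOVA: F statistic and upper-tail p across ≥2 groups.

    Degrees of freedom are (k−1, N−k). When neither the between- nor the
    within-group sum of squares is positive the statistic is 0/0 and an
    :class:`UndefinedStatisticError` is raised.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs at least two values")
    pooled = np.concatenate(arrays)
    grand = pooled.mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ss_within == 0 and ss_between == 0:
        raise UndefinedStatisticError(
            "all observations identical: F statistic undefined"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def fold_change(treatment_mean: float, control_mean: float) -> float:
    """Ratio of treatment to control mean density."""
    if control_mean <= 0:
        raise ValueError(
            f"control mean must be positive, got {control_mean}"
        )
    return float(treatment_mean) / float(control_mean)


def direction_of(fc: float, fc_threshold: float = 1.5) -> str:
    """up / down / unchanged from a fold change (inclusive thresholds)."""
    if fc >= fc_threshold:
        return UP
    if fc <= 1.0 / fc_threshold:
        return DOWN
    return UNCHANGED


def assign_cluster(directions: dict[str, str]) -> str:
    """Map the per-stress direction triple to expression class I–IV."""
    missing = set(STRESSES) - set(directions)
    if missing:
        raise ValueError(f"directions missing for stresses: {sorted(missing)}")
    dirs = [directions[s] for s in STRESSES]
    has_up = UP in dirs
    has_down = DOWN in dirs
    if has_up and has_down:
        return "IV"
    if has_up:
        return "I"
    if has_down:
        return "II"
    return "III"


def select_srp(
    table: pd.DataFrame,
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
    fdr_correct: bool = False,
) -> list[SrpRecord]:
    """Select stress-responsive spots from a replicated spot table.

    For each (spot, cultivar): one-way ANOVA across the four conditions,
    fold change of each stress's mean density over the control mean, and
    per-stress direction at the inclusive ``fc_threshold``. A spot is
    selected when p < alpha and at least one stress is up or down; its
    expression class follows :func:`assign_cluster`. Spots without control
    replicates, or degenerate all-identical spots, are skipped with a log
    entry.

    Raw p-values are compared with ``alpha`` by default, matching the
    classical per-spot design; ``fdr_correct`` switches to
    Benjamini–Hochberg adjusted p-values across all scored spots.
    """
    validate_spot_table(table)
    candidates: list[tuple[SrpRecord, bool]] = []
    for (spot, cultivar), sub in table.groupby(
        ["spot_id", "cultivar"], sort=False
    ):
        by_cond = {
            cond: grp["density"].to_numpy()
            for cond, grp in sub.groupby("condition", sort=False)
        }
        if CONTROL not in by_cond:
            logger.warning(
                "spot %s (%s): no control replicates, skipped", spot, cultivar
            )
            continue
        groups = [by_cond[c] for c in CONDITIONS if c in by_cond]
        try:
            _, p = anova_oneway(*groups)
        except UndefinedStatisticError:
            logger.info(
                "spot %s (%s): all densities identical, not responsive",
                spot, cultivar,
            )
            continue
        control_mean = float(by_cond[CONTROL].mean())
        fcs, dirs = {}, {}
        for stress in STRESSES:
            if stress not in by_cond:
                logger.warning(
                    "spot %s (%s): missing %s replicates, skipped",
                    spot, cultivar, stress,
                )
                break
            fcs[stress] = fold_change(
                float(by_cond[stress].mean()), control_mean
            )
            dirs[stress] = direction_of(fcs[stress], fc_threshold)
        else:
            candidates.append(
                (
                    SrpRecord(
                        spot_id=str(spot),
                        cultivar=str(cultivar),
                        fold_changes=fcs,
                        directions=dirs,
                        anova_p=p,
                        cluster=assign_cluster(dirs),
                    ),
                    any(d != UNCHANGED for d in dirs.values()),
                )
            )
    pvals = np.array([rec.anova_p for rec, _ in candidates])
    if fdr_correct and len(pvals):
        pvals = stats.false_discovery_control(pvals, method="bh")
    return [
        rec
        for (rec, responsive), p_eff in zip(candidates, pvals)
        if responsive and p_eff < alpha
    ]


def ratio_matrix(
    table: pd.DataFrame, cultivar: str | None = None
) -> pd.DataFrame:
    """Spot × condition matrix of mean densities relative to control."""
    validate_spot_table(table)
    if cultivar is not None:
        table = table[table["cultivar"] == cultivar]
    means = (
        table.groupby(["spot_id", "condition"], sort=False)["density"]
        .mean()
        .unstack("condition")
        .reindex(columns=list(CONDITIONS))
    )
    return means.div(means[CONTROL], axis=0)


def hierarchical_cluster(
    matrix: np.ndarray | pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray]:
    """Centroid-linkage agglomeration of fold-change rows.

    Returns the scipy-format merge tree (linkage matrix) and the leaf order
    for heatmap display. Distances are Euclidean between cluster centroids;
    ties are broken by row index (first-found merge).
    """
    values = np.asarray(
        matrix.values if isinstance(matrix, pd.DataFrame) else matrix,
        dtype=float,
    )
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("need a 2-d matrix with at least two rows")
    if not np.all(np.isfinite(values)):
        raise ValueError("matrix entries must be finite")
    tree = linkage(values, method="centroid", metric="euclidean")
    return tree, leaves_list(tree)
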