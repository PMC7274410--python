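"""Readers and writers for the pipeline's plain-text formats.

Trajectories travel as long-format CSV/TSV with columns
``protein_id, condition_label, time_days, value``; candidate edges as TSV
and as SIF (``node<TAB>promotes|inhibits<TAB>node``) for network viewers.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .network import InteractionCandidate, NetworkSummary
from .srp import SrpRecord, STRESSES
from .ssystem import SSystemParams, Trajectory

__all__ = [
    "read_trajectories",
    "write_trajectories",
    "write_candidates_tsv",
    "read_candidates_tsv",
    "write_sif",
    "write_summary_tsv",
    "write_srp_tsv",
]

_TRAJ_COLUMNS = ["protein_id", "condition_label", "time_days", "value"]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","


def read_trajectories(path: str | Path) -> list[Trajectory]:
    """Load trajectories from a long-format CSV/TSV file."""
    path = Path(path)
    table = pd.read_csv(path, sep=_sep_for(path))
    missing = set(_TRAJ_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for (pid, label), sub in table.groupby(
        ["protein_id", "condition_label"], sort=False
    ):
        sub = sub.sort_values("time_days")
        out.append(
            Trajectory(
                protein_id=str(pid),
                times=sub["time_days"].to_numpy(float),
                values=sub["value"].to_numpy(float),
                condition_label=str(label),
            )
        )
    return out


def write_trajectories(trajectories: list[Trajectory], path: str | Path) -> None:
    path = Path(path)
    rows = [
        {
            "protein_id": t.protein_id,
            "condition_label": t.condition_label,
            "time_days": time,
            "value": value,
        }
        for t in trajectories
        for time, value in zip(t.times, t.values)
    ]
    pd.DataFrame(rows, columns=_TRAJ_COLUMNS).to_csv(
        path, sep=_sep_for(path), index=False, float_format="%.10g"
    )


def write_candidates_tsv(
    candidates: list[InteractionCandidate], path: str | Path
) -> None:
    rows = [
        {
            "regulator": c.regulator_id,
            "target": c.target_id,
            "alpha": c.params.alpha,
            "beta": c.params.beta,
            "g": c.params.g,
            "h": c.params.h,
            "r_squared": c.r_squared,
            "sign": c.sign,
        }
        for c in candidates
    ]
    pd.DataFrame(
        rows,
        columns=[
            "regulator", "target", "alpha", "beta", "g", "h",
            "r_squared", "sign",
        ],
    ).to_csv(Path(path), sep="\t", index=False, float_format="%.10g")


def read_candidates_tsv(path: str | Path) -> list[InteractionCandidate]:
    table = pd.read_csv(Path(path), sep="\t")
    return [
        InteractionCandidate(
            regulator_id=str(r.regulator),
            target_id=str(r.target),
            params=SSystemParams(
                alpha=float(r.alpha), beta=float(r.beta),
                g=float(r.g), h=float(r.h),
            ),
            r_squared=float(r.r_squared),
            sign=str(r.sign),
            converged=True,
        )
        for r in table.itertuples(index=False)
    ]


def write_sif(candidates: list[InteractionCandidate], path: str | Path) -> None:
    """SIF export: regulator <TAB> promotes|inhibits <TAB> target."""
    verb = {"promotive": "promotes", "inhibitive": "inhibits"}
    lines = [
        f"{c.regulator_id}\t{verb[c.sign]}\t{c.target_id}"
        for c in candidates
        if c.sign in verb
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_summary_tsv(summary: NetworkSummary, path: str | Path) -> None:
    rows = [
        {
            "category": cat,
            "promotive": pro,
            "inhibitive": inh,
        }
        for cat, (pro, inh) in sorted(summary.per_category_counts.items())
    ]
    rows.append(
        {
            "category": "TOTAL",
            "promotive": summary.n_promotive,
            "inhibitive": summary.n_inhibitive,
        }
    )
    pd.DataFrame(rows, columns=["category", "promotive", "inhibitive"]).to_csv(
        Path(path), sep="\t", index=False
    )


def write_srp_tsv(records: list[SrpRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        row = {"spot_id": rec.spot_id, "cultivar": rec.cultivar}
        for stress in STRESSES:
            row[f"fc_{stress}"] = rec.fold_changes[stress]
            row[f"dir_{stress}"] = rec.directions[stress]
        row["anova_p"] = rec.anova_p
        row["cluster"] = rec.cluster
        rows.append(row)
    columns = ["spot_id", "cultivar"]
    for stress in STRESSES:
        columns += [f"fc_{stress}", f"dir_{stress}"]
    columns += ["anova_p", "cluster"]
    pd.DataFrame(rows, columns=columns).to_csv(
        Path(path), sep="\t", index=False, float_format="%.10g"
    )
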