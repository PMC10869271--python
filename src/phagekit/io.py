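"""CSV/TSV readers and writers for the pipeline's tabular dialects.

All tables are plain comma- or tab-separated text (the delimiter is
sniffed from the extension or detected by pandas):

* kinetic table — one row per well per timepoint with columns
  ``well_id, strain_id, agent_id, moi, replicate, time_h, signal``
  (empty ``agent_id`` marks a bacteria-only control well);
* score table — one row per scored well (iAUC output);
* plaquing table — ``strain_id, agent_id, run, outcome[, titer]``;
* strain metadata — ``strain_id, phylogroup, mlst, resistance_flags``
  (semicolon-separated flags) plus optional ``mic_<drug>`` columns;
* agent metadata — ``agent_id, ancestor_id``;
* matrix CSV — strains as rows, agents as columns, each cell holding
  replicate outcome codes (P/L/N) or 0/1 calls separated by ``;``.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .host_range import (
    CODE_OUTCOMES,
    PanelStrain,
    PlaquingObservation,
    SusceptibilityMatrix,
)
from .kinetics import InhibitionScore, KineticSeries

__all__ = [
    "read_kinetic_table",
    "write_score_table",
    "read_score_table",
    "read_plaquing_table",
    "write_plaquing_table",
    "read_strain_table",
    "read_agent_table",
    "write_matrix_csv",
    "read_matrix_csv",
]

KINETIC_COLUMNS = [
    "well_id",
    "strain_id",
    "agent_id",
    "moi",
    "replicate",
    "time_h",
    "signal",
]


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def _require_columns(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")


def read_kinetic_table(path) -> list:
    """Read a long-format kinetic table into KineticSeries, one per well."""
    df = _read_table(path)
    _require_columns(df, KINETIC_COLUMNS, path)
    series = []
    for (well, strain, agent, moi, rep), grp in df.groupby(
        ["well_id", "strain_id", "agent_id", "moi", "replicate"], sort=True
    ):
        grp = grp.sort_values("time_h", key=lambda s: s.astype(float))
        series.append(
            KineticSeries(
                well_id=str(well),
                strain_id=str(strain),
                agent_id=str(agent) if str(agent) else None,
                moi=float(moi),
                replicate=int(rep),
                times=grp["time_h"].astype(float).to_numpy(),
                signal=grp["signal"].astype(float).to_numpy(),
            )
        )
    return series


def write_kinetic_table(series: Iterable[KineticSeries], path) -> None:
    rows = []
    for s in series:
        for t, y in zip(s.times, s.signal):
            rows.append(
                {
                    "well_id": s.well_id,
                    "strain_id": s.strain_id,
                    "agent_id": s.agent_id or "",
                    "moi": s.moi,
                    "replicate": s.replicate,
                    "time_h": t,
                    "signal": y,
                }
            )
    pd.DataFrame(rows, columns=KINETIC_COLUMNS).to_csv(path, index=False)


SCORE_COLUMNS = [
    "strain_id",
    "agent_id",
    "replicate",
    "auc_sample",
    "auc_control",
    "iauc",
    "susceptible",
]


def write_score_table(scores: Iterable[InhibitionScore], path) -> None:
    rows = [
        {
            "strain_id": s.strain_id,
            "agent_id": s.agent_id,
            "replicate": s.replicate,
            "auc_sample": s.auc_sample,
            "auc_control": s.auc_control,
            "iauc": s.iauc,
            "susceptible": int(s.susceptible),
        }
        for s in scores
    ]
    pd.DataFrame(rows, columns=SCORE_COLUMNS).to_csv(path, index=False)


def read_score_table(path) -> list:
    df = _read_table(path)
    _require_columns(df, SCORE_COLUMNS, path)
    return [
        InhibitionScore(
            strain_id=row["strain_id"],
            agent_id=row["agent_id"],
            replicate=int(row["replicate"]),
            auc_sample=float(row["auc_sample"]),
            auc_control=float(row["auc_control"]),
            iauc=float(row["iauc"]),
            susceptible=bool(int(row["susceptible"])),
        )
        for _, row in df.iterrows()
    ]


def read_plaquing_table(path) -> list:
    df = _read_table(path)
    _require_columns(df, ["strain_id", "agent_id", "run", "outcome"], path)
    obs = []
    for _, row in df.iterrows():
        titer = row.get("titer", "")
        obs.append(
            PlaquingObservation(
                strain_id=row["strain_id"],
                agent_id=row["agent_id"],
                run=int(row["run"]),
                outcome=row["outcome"],
                titer=float(titer) if titer else None,
            )
        )
    return obs


def write_plaquing_table(observations: Iterable[PlaquingObservation], path) -> None:
    rows = [
        {
            "strain_id": o.strain_id,
            "agent_id": o.agent_id,
            "run": o.run,
            "outcome": o.outcome,
            "titer": "" if o.titer is None else o.titer,
        }
        for o in observations
    ]
    pd.DataFrame(
        rows, columns=["strain_id", "agent_id", "run", "outcome", "titer"]
    ).to_csv(path, index=False)


def read_strain_table(path) -> list:
    """Read strain metadata; ``mic_<drug>`` columns populate the MIC table."""
    df = _read_table(path)
    _require_columns(df, ["strain_id"], path)
    mic_cols = [c for c in df.columns if c.startswith("mic_")]
    strains = []
    for _, row in df.iterrows():
        flags = frozenset(
            f for f in str(row.get("resistance_flags", "")).split(";") if f
        )
        mic_table: Optional[dict] = None
        mics = {
            c[len("mic_") :]: float(row[c]) for c in mic_cols if str(row[c]) != ""
        }
        if mics:
            mic_table = mics
        strains.append(
            PanelStrain(
                strain_id=row["strain_id"],
                phylogroup=str(row.get("phylogroup", "")),
                mlst=str(row.get("mlst", "")),
                resistance_flags=flags,
                mic_table=mic_table,
            )
        )
    return strains


def write_strain_table(strains: Iterable[PanelStrain], path) -> None:
    strains = list(strains)
    drugs = sorted({d for s in strains if s.mic_table for d in s.mic_table})
    columns = ["strain_id", "phylogroup", "mlst", "resistance_flags"] + [
        f"mic_{d}" for d in drugs
    ]
    rows = []
    for s in strains:
        row = {
            "strain_id": s.strain_id,
            "phylogroup": s.phylogroup,
            "mlst": s.mlst,
            "resistance_flags": ";".join(sorted(s.resistance_flags)),
        }
        for d in drugs:
            row[f"mic_{d}"] = (s.mic_table or {}).get(d, "")
        rows.append(row)
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def read_agent_table(path) -> dict:
    """Read agent metadata; returns {agent_id: ancestor_id}."""
    df = _read_table(path)
    _require_columns(df, ["agent_id", "ancestor_id"], path)
    return {
        row["agent_id"]: row["ancestor_id"] or row["agent_id"]
        for _, row in df.iterrows()
    }


def write_agent_table(ancestors: Mapping[str, str], path) -> None:
    pd.DataFrame(
        [{"agent_id": a, "ancestor_id": anc} for a, anc in sorted(ancestors.items())],
        columns=["agent_id", "ancestor_id"],
    ).to_csv(path, index=False)


def write_matrix_csv(matrix: SusceptibilityMatrix, path) -> None:
    """Write strains x agents cells as ``;``-joined per-replicate codes.

    Categorical matrices use P/L/N codes, boolean matrices 0/1; absent
    replicates are left blank within the cell.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["strain_id"] + list(matrix.agents))
        for i, strain in enumerate(matrix.strains):
            row = [strain.strain_id]
            for j in range(len(matrix.agents)):
                codes = []
                for r in range(matrix.n_replicates):
                    if not matrix.present[r, i, j]:
                        codes.append("")
                    elif matrix.outcomes is not None and matrix.outcomes[r, i, j]:
                        codes.append(matrix.outcomes[r, i, j])
                    else:
                        codes.append(str(int(matrix.calls[r, i, j])))
                row.append(";".join(codes))
            writer.writerow(row)


def read_matrix_csv(
    path,
    strains: Optional[list] = None,
    ancestors: Optional[Mapping[str, str]] = None,
) -> SusceptibilityMatrix:
    """Read a matrix CSV written by :func:`write_matrix_csv`."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.columns[0] != "strain_id":
        raise ValueError(f"{path}: first column must be strain_id")
    agents = list(df.columns[1:])
    strain_ids = df["strain_id"].tolist()
    n_r = 1
    cells = df[agents].to_numpy()
    for cell in cells.ravel():
        n_r = max(n_r, len(str(cell).split(";")))
    n_s, n_a = len(strain_ids), len(agents)
    calls = np.zeros((n_r, n_s, n_a), dtype=bool)
    present = np.zeros((n_r, n_s, n_a), dtype=bool)
    outcomes = np.full((n_r, n_s, n_a), "", dtype="<U1")
    has_outcomes = False
    for i in range(n_s):
        for j in range(n_a):
            codes = str(cells[i, j]).split(";")
            for r, code in enumerate(codes):
                code = code.strip()
                if not code:
                    continue
                present[r, i, j] = True
                if code in CODE_OUTCOMES:
                    has_outcomes = True
                    outcomes[r, i, j] = code
                    calls[r, i, j] = CODE_OUTCOMES[code] != "no_effect"
                elif code in ("0", "1"):
                    calls[r, i, j] = code == "1"
                else:
                    raise ValueError(f"{path}: unknown cell code {code!r}")
    if strains is not None:
        by_id = {s.strain_id: s for s in strains}
        strain_objs = [by_id.get(s, PanelStrain(strain_id=s)) for s in strain_ids]
    else:
        strain_objs = [PanelStrain(strain_id=s) for s in strain_ids]
    return SusceptibilityMatrix(
        strains=strain_objs,
        agents=agents,
        calls=calls,
        present=present,
        outcomes=outcomes if has_outcomes else None,
        ancestors=dict(ancestors) if ancestors else {},
    )
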