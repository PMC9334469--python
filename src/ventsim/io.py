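"""File I/O: per-breath logs, PEEP-trial tables, summaries and configs.

All outputs are plain text (CSV / JSON / YAML).  The per-breath CSV has
one row per breath with the realized mechanics and the quasi-steady blood
gas; the trials CSV has one row per pig, trial and descent step.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .controller import PeepFio2Table
from .pig import InjuryParams
from .protocol import ExperimentLog

__all__ = [
    "breaths_frame",
    "trials_frame",
    "write_experiment",
    "load_injury_params",
    "dump_injury_params",
    "pig_to_json",
    "pig_from_json",
    "default_config_path",
    "load_config",
]

BREATH_COLUMNS = [
    "time_s",
    "pip",
    "peep",
    "dp",
    "vt_ml",
    "rr",
    "fio2",
    "crs_dyn",
    "mp",
    "aeration",
    "consolidated_fraction",
    "pao2",
    "paco2",
    "ph",
    "spo2",
    "co",
]


def breaths_frame(log: ExperimentLog) -> pd.DataFrame:
    """Per-breath log as a DataFrame in the canonical column order."""
    df = pd.DataFrame([dataclasses.asdict(b) for b in log.breaths])
    return df[BREATH_COLUMNS] if not df.empty else pd.DataFrame(columns=BREATH_COLUMNS)


def trials_frame(logs: Sequence[ExperimentLog]) -> pd.DataFrame:
    """All PEEP-trial measurements: one row per pig, trial and step."""
    rows = []
    for log in logs:
        for k, trial in enumerate(log.trials, start=1):
            for s in trial.steps:
                rows.append(
                    {
                        "pig_id": log.pig_id,
                        "arm": log.arm,
                        "trial_index": k,
                        "peep": s.peep,
                        "pao2": s.pao2,
                        "paco2": s.paco2,
                        "crs": s.crs,
                        "co": s.co,
                        "do2": s.do2,
                        "pf": s.pf_ratio,
                        "terminated_reason": trial.terminated_reason,
                    }
                )
    return pd.DataFrame(rows)


def write_experiment(log: ExperimentLog, out_dir: str | Path) -> dict[str, Path]:
    """Write breaths.csv, trials.csv and summary.json for one pig's run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "breaths": out / "breaths.csv",
        "trials": out / "trials.csv",
        "summary": out / "summary.json",
    }
    breaths_frame(log).to_csv(paths["breaths"], index=False)
    trials_frame([log]).to_csv(paths["trials"], index=False)
    summary = {
        "arm": log.arm,
        "pig_id": log.pig_id,
        "lavage_cycles": log.lavage_cycles,
        "died_at_s": log.died_at_s,
        "snapshots": [
            {
                "label": s.label,
                "time_s": s.time_s,
                "pao2": s.bg.pao2,
                "paco2": s.bg.paco2,
                "ph": s.bg.ph,
                "pf_ratio": s.bg.pf_ratio,
                "crs": s.crs,
                "mp": s.mp,
                "co": s.co,
                "peep": s.peep,
                "dp": s.dp,
            }
            for s in log.snapshots
        ],
        "trials": [
            {
                "terminated_reason": t.terminated_reason,
                "n_steps": len(t.steps),
                "min_peep": min((s.peep for s in t.steps), default=None),
            }
            for t in log.trials
        ],
    }
    paths["summary"].write_text(json.dumps(summary, indent=2))
    return paths


def load_injury_params(path: str | Path) -> InjuryParams:
    """Injury/calibration parameters from a YAML mapping (missing keys
    keep their defaults)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    fields = {f.name for f in dataclasses.fields(InjuryParams)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown injury parameters: {sorted(unknown)}")
    if "lavage_het_mult" in data:
        data["lavage_het_mult"] = tuple(data["lavage_het_mult"])
    return InjuryParams(**data)


def dump_injury_params(params: InjuryParams, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(params), sort_keys=False))


def pig_to_json(pig, path: str | Path | None = None) -> str:
    """Serialize a pig's full parameter/unit state as JSON.

    The random generator itself is not serialized; the stored seed allows
    reconstruction of an equivalent fresh generator.
    """
    import numpy as np

    d = {}
    for f in dataclasses.fields(pig):
        if f.name == "rng":
            continue
        val = getattr(pig, f.name)
        if isinstance(val, np.ndarray):
            val = val.tolist()
        elif dataclasses.is_dataclass(val):
            val = dataclasses.asdict(val)
        d[f.name] = val
    text = json.dumps(d, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def pig_from_json(source: str | Path):
    """Rebuild a PigState from :func:`pig_to_json` output (file or string)."""
    import numpy as np

    from .pig import PigState

    p = Path(str(source))
    text = p.read_text() if p.exists() else str(source)
    d = json.loads(text)
    inj = d.pop("injury")
    if "lavage_het_mult" in inj:
        inj["lavage_het_mult"] = tuple(inj["lavage_het_mult"])
    d["injury"] = InjuryParams(**inj)
    for key in ("opening", "closing", "perfusion", "lavage_mult"):
        d[key] = np.asarray(d[key], dtype=float)
    d["state"] = np.asarray(d["state"], dtype=np.int8)
    d["rng"] = np.random.default_rng(d["rng_seed"])
    return PigState(**d)


def default_config_path() -> Path:
    """Path of the calibration defaults shipped inside the package."""
    return Path(__file__).parent / "data" / "defaults.yaml"


def load_config(path: str | Path | None = None) -> tuple[InjuryParams, PeepFio2Table]:
    """Injury parameters and controller table from a YAML config file.

    With no argument, loads the in-package defaults.  The file holds an
    ``injury`` mapping (InjuryParams fields) and a ``peep_fio2_table``
    list of [FiO2, PEEP] rows.
    """
    path = Path(path) if path is not None else default_config_path()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    injury = data.get("injury", {})
    if "lavage_het_mult" in injury:
        injury["lavage_het_mult"] = tuple(injury["lavage_het_mult"])
    params = InjuryParams(**injury)
    rows = tuple((float(r[0]), float(r[1])) for r in data["peep_fio2_table"])
    return params, PeepFio2Table(rows=rows)
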