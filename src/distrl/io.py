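"""Plain-text serialization of sessions, populations and reports.

A session saves as three text artifacts in one directory:

* ``trials.csv`` — the trial table (static or dynamic dialect);
* ``rates.csv`` — long-format per-trial epoch rates, one row per
  neuron x trial (columns: neuron_id, trial_index, choice_rate,
  feedback_rate);
* ``manifest.json`` — per-neuron metadata (subject, region, AP
  coordinate) and, for simulated populations, the generative ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .neurons import NeuronGroundTruth, NeuronRecord


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, set):
        return sorted(obj)
    return obj


def save_session(
    directory: str | Path,
    trials: pd.DataFrame,
    neurons: list[NeuronRecord],
    extra_manifest: dict | None = None,
) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    trials.to_csv(directory / "trials.csv", index=False)
    rate_rows = []
    for n in neurons:
        for t in range(n.n_trials):
            rate_rows.append(
                {
                    "neuron_id": n.neuron_id,
                    "trial_index": t,
                    "choice_rate": None if n.choice_rate is None else n.choice_rate[t],
                    "feedback_rate": n.feedback_rate[t],
                }
            )
    pd.DataFrame(rate_rows).to_csv(directory / "rates.csv", index=False)
    manifest = {
        "neurons": [
            {
                "neuron_id": n.neuron_id,
                "subject_id": n.subject_id,
                "region": n.region,
                "ap_mm": n.ap_mm,
                "sign_aligned": n.sign_aligned,
                "ground_truth": (
                    dataclasses.asdict(n.ground_truth) if n.ground_truth else None
                ),
            }
            for n in neurons
        ]
    }
    if extra_manifest:
        manifest.update(extra_manifest)
    (directory / "manifest.json").write_text(
        json.dumps(_jsonable(manifest), indent=2, sort_keys=True)
    )
    return directory


def load_session(directory: str | Path) -> tuple[pd.DataFrame, list[NeuronRecord]]:
    directory = Path(directory)
    trials = pd.read_csv(directory / "trials.csv")
    rates = pd.read_csv(directory / "rates.csv")
    manifest = json.loads((directory / "manifest.json").read_text())
    neurons = []
    for meta in manifest["neurons"]:
        sub = rates[rates["neuron_id"] == meta["neuron_id"]].sort_values("trial_index")
        choice = sub["choice_rate"].to_numpy()
        truth = meta.get("ground_truth")
        neurons.append(
            NeuronRecord(
                neuron_id=meta["neuron_id"],
                subject_id=meta["subject_id"],
                region=meta.get("region", "ACC"),
                ap_mm=meta.get("ap_mm", 0.0),
                choice_rate=None if np.all(pd.isna(choice)) else choice.astype(float),
                feedback_rate=sub["feedback_rate"].to_numpy(float),
                ground_truth=NeuronGroundTruth(**truth) if truth else None,
                sign_aligned=bool(meta.get("sign_aligned", False)),
            )
        )
    return trials, neurons


def write_report(directory: str | Path, report: dict, tables: dict[str, pd.DataFrame]) -> Path:
    """Write a JSON summary plus CSV tables for one analysis run."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "report.json").write_text(
        json.dumps(_jsonable(report), indent=2, sort_keys=True)
    )
    for name, df in tables.items():
        df.to_csv(directory / f"{name}.csv", index=False)
    return directory
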