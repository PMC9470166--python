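"""Pipeline orchestration: simulate → ingest → clean → featurize → train.

Each stage persists its output under the run directory and the whole run is
described by a :class:`RunManifest` (config hash, seeds, stage outputs,
timestamps) so any output file is reproducible from its manifest alone.
Stage failure leaves earlier stages' outputs intact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .classify import NetworkSpec, cross_validate_features
from .cleaning import clean_sessions
from .errors import SipstructError
from .features import compute_intake, feature_table
from .lickometer import read_sessions, write_events, write_sessions
from .synth import BehaviorParams, CohortConfig, generate_cohort

logger = logging.getLogger("sipstruct")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "simulate": {
        "n_per_class": {"water-ChR2": 8, "water-eGFP": 11, "alcohol-ChR2": 8, "alcohol-eGFP": 8},
        "weeks": 6,
        "sessions_per_week": 5,
        "params": {},  # overrides for BehaviorParams fields
    },
    "clean": {"threshold": 3.0, "grouping": "global"},
    "train": {
        "k": 6,
        "layer_widths": [2048, 512, 64, 4],
        "epochs": 100,
        "batch_size": 32,
        "learning_rate": 1.0e-3,
        "fold_safe": False,
    },
}


def config_hash(config: dict) -> str:
    """SHA-256 of the canonical (sorted-key) JSON form; field order invariant."""
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


@dataclass
class RunManifest:
    config: dict
    seed: int
    started_at: str = ""
    finished_at: str = ""
    package_version: str = __version__
    outputs: dict[str, str] = field(default_factory=dict)

    @property
    def hash(self) -> str:
        return config_hash(self.config)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["config_hash"] = self.hash
        return d

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def _merged_config(config: dict | None) -> dict:
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(merged.get(key), dict):
            merged[key].update(val)
        else:
            merged[key] = val
    return merged


def _cohort_from_config(cfg: dict, seed: int) -> tuple[CohortConfig, BehaviorParams]:
    sim = cfg["simulate"]
    n_per_class = {
        tuple(k.split("-")): int(v) for k, v in sim["n_per_class"].items()
    }
    cohort = CohortConfig(
        n_per_class=n_per_class,  # type: ignore[arg-type]
        weeks=int(sim["weeks"]),
        sessions_per_week=int(sim["sessions_per_week"]),
        seed=seed,
    )
    params = BehaviorParams(**sim.get("params", {}))
    return cohort, params


def run_pipeline(config: dict | None, outdir: str | Path) -> RunManifest:
    """Run simulate → clean → featurize → train end to end.

    Returns the manifest; all stage outputs (sessions, cleaning report,
    feature table, CV result, manifest) are written under ``outdir``.
    """
    cfg = _merged_config(config)
    seed = int(cfg["seed"])
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg, seed=seed, started_at=_now())

    logger.info("stage=simulate seed=%d", seed)
    cohort, params = _cohort_from_config(cfg, seed)
    sessions, truth = generate_cohort(cohort, params)
    raw_path = out / "sessions_raw.csv"
    write_sessions(sessions, raw_path)
    write_events(truth.events, out / "events.csv")
    manifest.outputs["sessions_raw"] = str(raw_path)
    manifest.outputs["events"] = str(out / "events.csv")

    logger.info("stage=clean threshold=%s", cfg["clean"]["threshold"])
    cleaned, report = clean_sessions(
        sessions,
        threshold=float(cfg["clean"]["threshold"]),
        grouping=cfg["clean"]["grouping"],
    )
    write_sessions(cleaned, out / "sessions.csv")
    (out / "cleaning_report.json").write_text(json.dumps(report.to_dict(), indent=2))
    manifest.outputs["sessions"] = str(out / "sessions.csv")
    manifest.outputs["cleaning_report"] = str(out / "cleaning_report.json")

    logger.info("stage=featurize n_sessions=%d", len(cleaned))
    table = feature_table(cleaned)
    table["dose_g_per_kg"] = [compute_intake(s).dose_g_per_kg for s in cleaned]
    table.to_csv(out / "features.csv", index=False)
    manifest.outputs["features"] = str(out / "features.csv")

    tr = cfg["train"]
    logger.info("stage=train k=%s widths=%s", tr["k"], tr["layer_widths"])
    spec = NetworkSpec(
        layer_widths=tuple(int(w) for w in tr["layer_widths"]),
        learning_rate=float(tr["learning_rate"]),
        epochs=int(tr["epochs"]),
        batch_size=int(tr["batch_size"]),
        seed=seed,
    )
    result = cross_validate_features(
        table, k=int(tr["k"]), spec=spec, fold_safe=bool(tr["fold_safe"])
    )
    (out / "cvresult.json").write_text(json.dumps(result.to_dict(), indent=2))
    _loss_curves_csv(result).to_csv(out / "loss_curves.csv", index=False)
    manifest.outputs["cvresult"] = str(out / "cvresult.json")
    manifest.outputs["loss_curves"] = str(out / "loss_curves.csv")

    manifest.finished_at = _now()
    manifest.write(out / "manifest.json")
    return manifest


def featurize_file(sessions_csv: str | Path, out_csv: str | Path) -> pd.DataFrame:
    sessions = read_sessions(sessions_csv)
    table = feature_table(sessions)
    table.to_csv(out_csv, index=False)
    return table


def _loss_curves_csv(result) -> pd.DataFrame:
    rows = []
    for fold, hist in enumerate(result.loss_curves, start=1):
        for epoch in range(len(hist["train_loss"])):
            rows.append(
                {
                    "fold": fold,
                    "epoch": epoch + 1,
                    "train_loss": hist["train_loss"][epoch],
                    "test_loss": hist.get("test_loss", [None] * (epoch + 1))[epoch],
                }
            )
    return pd.DataFrame(rows)


def _now() -> str:
    return time.strftime("%Y-%m-%dT%H:%M:%S")


class StageFailure(SipstructError):
    """A pipeline stage failed; message names the stage."""
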