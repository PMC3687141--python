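"""Run configuration, hierarchical seeding and file I/O.

A run is reproducible from a single master seed: per-subject (and any
other labelled) child seeds are derived deterministically from it, so
any subject's session can be regenerated in isolation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .field_fill import FieldSpec
from .geometry import SpiralSpec
from .observer import (
    AffinityParams,
    GroupingObserver,
    ObserverParams,
    OracleObserver,
    ParametricObserver,
    RandomObserver,
    default_params,
)
from .session import (
    build_experiment1_session,
    build_experiment2_session,
    build_experiment3_session,
    run_session,
)

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "derive_seeds",
    "make_observer",
    "run_experiment",
    "write_outputs",
    "read_records",
]

_SESSION_BUILDERS = {
    "1": build_experiment1_session,
    "2": build_experiment2_session,
    "3": build_experiment3_session,
}


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one simulated experiment run."""

    experiment: str
    master_seed: int
    subjects_younger: int = 1
    subjects_older: int = 1
    observer: str = "parametric"
    observer_params: dict | None = None
    design_variant: str = "full_crossing"
    render: bool = False
    output_dir: str = "runs"

    def __post_init__(self) -> None:
        if str(self.experiment) not in _SESSION_BUILDERS:
            raise ValueError(f"unknown experiment {self.experiment!r}")
        object.__setattr__(self, "experiment", str(self.experiment))
        if self.subjects_younger < 1 or self.subjects_older < 1:
            raise ValueError("subject counts must be >= 1")
        if self.observer not in ("parametric", "grouping", "oracle", "random"):
            raise ValueError(f"unknown observer {self.observer!r}")


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML/JSON config; unknown keys are rejected by name."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    if "experiment" not in raw or "master_seed" not in raw:
        raise ValueError("config requires 'experiment' and 'master_seed'")
    return RunConfig(**raw)


def save_config(config: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(asdict(config), sort_keys=False))
    return path


def derive_seeds(master_seed: int, labels: list[str]) -> dict[str, int]:
    """Deterministic, collision-checked child seed per label."""
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate seed label(s): {dupes}")
    seeds: dict[str, int] = {}
    for label in labels:
        digest = hashlib.sha256(label.encode()).digest()
        words = list(np.frombuffer(digest[:16], dtype=np.uint32))
        ss = np.random.SeedSequence([int(master_seed)] + [int(w) for w in words])
        seeds[label] = int(ss.generate_state(1, dtype=np.uint64)[0] >> 33)
    if len(set(seeds.values())) != len(seeds):
        raise RuntimeError("seed collision; change the master seed")
    return seeds


def make_observer(name: str, group: str, params: dict | None = None):
    if name == "parametric":
        base = default_params(group)
        if params:
            base = ObserverParams(**{**asdict_params(base), **params,
                                     "group": group})
        return ParametricObserver(base)
    if name == "grouping":
        return GroupingObserver(AffinityParams(**(params or {})))
    if name == "oracle":
        return OracleObserver()
    if name == "random":
        return RandomObserver()
    raise ValueError(f"unknown observer {name!r}")


def asdict_params(params: ObserverParams) -> dict:
    from dataclasses import asdict as _asdict
    return _asdict(params)


def run_experiment(config: RunConfig,
                   spiral_spec: SpiralSpec | None = None,
                   field_spec: FieldSpec | None = None
                   ) -> tuple[pd.DataFrame, dict]:
    """Simulate every subject of a configured experiment.

    Returns the concatenated trial records and a manifest with the
    config echo, the derived per-subject seeds and the cell counts.
    """
    subjects = ([("younger", f"y{i + 1:02d}") for i in range(config.subjects_younger)]
                + [("older", f"o{i + 1:02d}") for i in range(config.subjects_older)])
    seeds = derive_seeds(config.master_seed,
                         [f"exp{config.experiment}/{sid}" for _, sid in subjects])
    builder = _SESSION_BUILDERS[config.experiment]
    frames = []
    for group, sid in subjects:
        rng = np.random.default_rng(seeds[f"exp{config.experiment}/{sid}"])
        if config.experiment == "3":
            trials = builder(rng, design_variant=config.design_variant)
        else:
            trials = builder(rng)
        observer = make_observer(config.observer, group,
                                 config.observer_params)
        frames.append(run_session(trials, observer, rng, subject=sid,
                                  group=group, spiral_spec=spiral_spec,
                                  field_spec=field_spec))
    records = pd.concat(frames, ignore_index=True)
    counts = (records.groupby(["group", "spacing_lambda", "jitter_deg",
                               "duration_s", "background_mode", "rel_label"],
                              observed=True)
              .size().reset_index(name="n_trials"))
    manifest = {
        "config": asdict(config),
        "seeds": seeds,
        "n_subjects": len(subjects),
        "n_trials": int(len(records)),
        "cell_counts": counts.to_dict(orient="records"),
        "package": "spiralfield 0.1.0",
    }
    return records, manifest


def write_outputs(records: pd.DataFrame, manifest: dict,
                  out_dir: str | Path) -> dict[str, Path]:
    """Write records CSV + manifest JSON; re-reading reproduces records."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rec_path = out / "records.csv"
    man_path = out / "manifest.json"
    records.to_csv(rec_path, index=False)
    man_path.write_text(json.dumps(manifest, indent=2, default=str))
    return {"records": rec_path, "manifest": man_path}


def read_records(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
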