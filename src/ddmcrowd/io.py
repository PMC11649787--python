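"""File-format contracts: dataset CSVs, config files, result JSON.

A dataset on disk is two CSV files (comma-separated, UTF-8, header row,
floats at 17 significant digits so round trips are exact):

* ``items.csv`` — ``item_id, x1, x2, z``
* ``labels.csv`` — ``item_id, annotator_id, y, rt_seconds``

plus a ``provenance.json`` recording the generating config, seed and (for
synthetic data) the true annotator parameters.  Inference results are a
single versioned JSON document with per-annotator estimates, per-item
posteriors and the ELBO trace.  Configs may be YAML or JSON.
"""

from __future__ import annotations

import json
import subprocess
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ddm import AnnotatorDDM
from .inference import (
    DEFAULT_LIKELIHOOD_FORM,
    Schedule,
    VariationalState,
    estimate_supports,
)
from .simulate import CrowdDataset, ExperimentConfig, experiment_preset

__all__ = [
    "RunConfig",
    "SchemaError",
    "write_dataset",
    "read_dataset",
    "save_results",
    "load_results",
    "load_config",
]

_FLOAT_FMT = "%.17g"
RESULT_SCHEMA_VERSION = 1


class SchemaError(ValueError):
    """A file does not conform to its documented schema."""


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs, loadable from YAML/JSON.

    Defaults reproduce the reference procedure: learning rate 0.01, all
    parameters initialised at 0.5, beta = 30, stop at the later of 300
    iterations or an ELBO change below 0.1.
    """

    experiment: int | None = 1
    n_items: int = 200
    n_annotators: int = 10
    dt: float = 0.01
    seed: int = 0
    seeds: tuple[int, ...] | None = None
    method: str = "1"
    n_test: int = 10_000
    learning_rate: float = 0.01
    min_iters: int = 300
    elbo_tol: float = 0.1
    max_iters: int = 5000
    optimizer: str = "adam"
    beta: float = 30.0
    lam: float = 1.0
    likelihood_form: str = DEFAULT_LIKELIHOOD_FORM
    positive_branch: bool = False
    mu0_support: tuple[float, float] | None = None
    sigma0_support: tuple[float, float] | None = None
    mu1_support: tuple[float, float] | None = None
    sigma1_support: tuple[float, float] | None = None

    def experiment_config(self) -> ExperimentConfig:
        overrides = {
            name: tuple(v)
            for name in ("mu0_support", "sigma0_support", "mu1_support", "sigma1_support")
            if (v := getattr(self, name)) is not None
        }
        overrides.update(
            n_items=self.n_items, n_annotators=self.n_annotators, dt=self.dt
        )
        if self.experiment is not None:
            return experiment_preset(self.experiment, seed=self.seed, **overrides)
        return ExperimentConfig(seed=self.seed, **overrides)

    def schedule(self) -> Schedule:
        return Schedule(
            learning_rate=self.learning_rate,
            min_iters=self.min_iters,
            elbo_tol=self.elbo_tol,
            max_iters=self.max_iters,
            optimizer=self.optimizer,
        )

    def seed_list(self) -> list[int]:
        return list(self.seeds) if self.seeds is not None else [self.seed]


def load_config(path) -> RunConfig:
    """Read a RunConfig from a YAML or JSON file, rejecting unknown keys."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise SchemaError(f"{path}: unknown config keys {sorted(unknown)}")
    for key in ("seeds", "mu0_support", "sigma0_support", "mu1_support", "sigma1_support"):
        if data.get(key) is not None:
            data[key] = tuple(data[key])
    try:
        return RunConfig(**data)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def _git_hash() -> str | None:
    try:
        out = subprocess.run(
            ["git", "rev-parse", "HEAD"], capture_output=True, text=True, timeout=5
        )
        return out.stdout.strip() or None
    except Exception:
        return None


def write_dataset(
    ds: CrowdDataset,
    outdir,
    *,
    config: ExperimentConfig | None = None,
    annotators: list[AnnotatorDDM] | None = None,
    seed: int | None = None,
) -> None:
    """Write items.csv, labels.csv and provenance.json into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    items = pd.DataFrame(
        {"item_id": np.arange(ds.n_items), "x1": ds.x[:, 0], "x2": ds.x[:, 1], "z": ds.z}
    )
    items.to_csv(outdir / "items.csv", index=False, float_format=_FLOAT_FMT)
    i_idx, j_idx = np.meshgrid(
        np.arange(ds.n_items), np.arange(ds.n_annotators), indexing="ij"
    )
    labels = pd.DataFrame(
        {
            "item_id": i_idx.ravel(),
            "annotator_id": j_idx.ravel(),
            "y": ds.y.ravel(),
            "rt_seconds": ds.rt.ravel(),
        }
    )
    labels.to_csv(outdir / "labels.csv", index=False, float_format=_FLOAT_FMT)
    prov: dict = {"schema_version": 1, "kind": "ddmcrowd.dataset", "dt": ds.dt,
                  "git_hash": _git_hash()}
    if seed is not None:
        prov["seed"] = int(seed)
    if config is not None:
        d = asdict(config)
        d["grid"] = [list(map(float, iv)) for iv in config.grid]
        prov["config"] = d
    if annotators is not None:
        prov["true_annotators"] = [asdict(a) for a in annotators]
    (outdir / "provenance.json").write_text(json.dumps(prov, indent=2, sort_keys=True) + "\n")


def _require_columns(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {missing}")


def read_dataset(indir) -> tuple[CrowdDataset, dict]:
    """Read a dataset directory back; returns (dataset, provenance dict).

    Validation failures raise :class:`SchemaError` naming the offending file,
    row and column.
    """
    indir = Path(indir)
    items_path, labels_path = indir / "items.csv", indir / "labels.csv"
    for p in (items_path, labels_path):
        if not p.exists():
            raise SchemaError(f"missing dataset file {p}")
    items = pd.read_csv(items_path, float_precision="round_trip")
    labels = pd.read_csv(labels_path, float_precision="round_trip")
    _require_columns(items, ["item_id", "x1", "x2", "z"], "items.csv")
    _require_columns(labels, ["item_id", "annotator_id", "y", "rt_seconds"], "labels.csv")

    bad = ~items["z"].isin([0, 1])
    if bad.any():
        raise SchemaError(f"items.csv: row {int(bad.idxmax())}, column 'z' not in {{0,1}}")
    bad = ~labels["y"].isin([0, 1])
    if bad.any():
        raise SchemaError(f"labels.csv: row {int(bad.idxmax())}, column 'y' not in {{0,1}}")
    bad = ~(labels["rt_seconds"] > 0)
    if bad.any():
        raise SchemaError(
            f"labels.csv: row {int(bad.idxmax())}, column 'rt_seconds' must be positive"
        )

    items = items.sort_values("item_id").reset_index(drop=True)
    n = len(items)
    item_ids = items["item_id"].to_numpy()
    ann_ids = np.sort(labels["annotator_id"].unique())
    k = len(ann_ids)
    if len(labels) != n * k:
        raise SchemaError(
            f"labels.csv: expected {n * k} rows (items x annotators), got {len(labels)}"
        )
    pivot_y = labels.pivot(index="item_id", columns="annotator_id", values="y")
    pivot_rt = labels.pivot(index="item_id", columns="annotator_id", values="rt_seconds")
    if pivot_y.isna().any().any():
        raise SchemaError("labels.csv: incomplete item x annotator grid")
    pivot_y = pivot_y.loc[item_ids, ann_ids]
    pivot_rt = pivot_rt.loc[item_ids, ann_ids]

    prov = {}
    prov_path = indir / "provenance.json"
    if prov_path.exists():
        prov = json.loads(prov_path.read_text())
    ds = CrowdDataset(
        x=items[["x1", "x2"]].to_numpy(),
        z=items["z"].to_numpy(dtype=np.int64),
        y=pivot_y.to_numpy(dtype=np.int64),
        rt=pivot_rt.to_numpy(dtype=float),
        dt=float(prov.get("dt", 0.01)),
    )
    return ds, prov


def save_results(state: VariationalState, path, *, config: dict | None = None) -> None:
    """Serialise a fitted state (+ support estimates) to versioned JSON."""
    sup = estimate_supports(state)
    payload = {
        "schema_version": RESULT_SCHEMA_VERSION,
        "kind": "ddmcrowd.inference_result",
        "positive_branch": state.positive_branch,
        "annotators": [
            {
                "annotator_id": j,
                "mu0": float(state.mu0[j]),
                "sigma0": float(state.sigma0[j]),
                "mu1": float(state.mu1[j]),
                "sigma1": float(state.sigma1[j]),
                "sensitivity": float(state.sensitivities()[j]),
                "specificity": float(state.specificities()[j]),
            }
            for j in range(state.n_annotators)
        ],
        "items": [
            {"item_id": i, "q": float(state.q[i]), "f": float(state.f[i])}
            for i in range(state.n_items)
        ],
        "support_estimates": asdict(sup),
        "elbo_trace": [float(v) for v in state.elbo_trace],
    }
    if config is not None:
        payload["config"] = config
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def load_results(path) -> VariationalState:
    """Load a fitted state back from result JSON."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: invalid JSON ({exc})") from exc
    for key in ("annotators", "items", "elbo_trace"):
        if key not in payload:
            raise SchemaError(f"{path}: missing key {key!r}")
    ann = sorted(payload["annotators"], key=lambda a: a["annotator_id"])
    items = sorted(payload["items"], key=lambda d: d["item_id"])
    return VariationalState(
        q=np.array([d["q"] for d in items]),
        f=np.array([d["f"] for d in items]),
        mu0=np.array([a["mu0"] for a in ann]),
        sigma0=np.array([a["sigma0"] for a in ann]),
        mu1=np.array([a["mu1"] for a in ann]),
        sigma1=np.array([a["sigma1"] for a in ann]),
        elbo_trace=np.asarray(payload["elbo_trace"], dtype=float),
        positive_branch=bool(payload.get("positive_branch", False)),
    )
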