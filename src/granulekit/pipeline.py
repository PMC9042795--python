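"""Pipeline orchestrator: simulate -> segment -> measure -> summarize.

A YAML/dict config lists stages with per-stage parameter blocks under one
root seed. Validation is strict — unknown keys are rejected by name — and
every run writes a provenance record (config hash, seed, package
versions, stage timings) next to its outputs. Re-running an identical
config + seed reproduces all numeric outputs bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import scipy
import yaml

from . import __version__
from .image import ImageStack
from .io import write_image, write_json, write_records_csv
from .morphometrics import fit_size_distribution, partition_coefficient
from .segmentation import label_objects, measure_objects, threshold_image
from .synthetic import GranuleFieldParams, generate_granule_image

__all__ = ["ConfigError", "StageError", "validate_config", "run_pipeline"]


class ConfigError(ValueError):
    """Invalid pipeline configuration (unknown or missing keys)."""


class StageError(RuntimeError):
    """A stage failed; partial outputs are retained on disk."""


_TOP_KEYS = {"seed", "out_dir", "stages"}
_STAGE_KEYS = {
    "simulate_granules": {"params"},
    "segment": {"method", "value", "fraction", "channel"},
    "measure": {"channel"},
    "size_fit": set(),
    "partition": {"exclusion_halo_voxels", "channel"},
}


def validate_config(config: dict) -> dict:
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(config) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    if "stages" not in config or not config["stages"]:
        raise ConfigError("config must list at least one stage")
    for i, st in enumerate(config["stages"]):
        if "stage" not in st:
            raise ConfigError(f"stage #{i} missing 'stage' name")
        name = st["stage"]
        if name not in _STAGE_KEYS:
            raise ConfigError(f"unknown stage {name!r}")
        extra = set(st) - _STAGE_KEYS[name] - {"stage"}
        if extra:
            raise ConfigError(f"stage {name!r}: unknown key(s) {sorted(extra)}")
    return config


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(canon).hexdigest()[:16]


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Execute the configured stages in order.

    Returns a result bundle (per-stage outputs) and writes artifacts plus
    ``provenance.json`` under ``out_dir``. A stage failure raises
    :class:`StageError` naming the stage; earlier outputs stay on disk.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    validate_config(config)
    seed = int(config.get("seed", 0))
    out = Path(out_dir or config.get("out_dir", "."))
    out.mkdir(parents=True, exist_ok=True)

    ctx: dict = {"seed": seed}
    results: dict = {}
    timings: dict[str, float] = {}
    for st in config["stages"]:
        name = st["stage"]
        t0 = time.perf_counter()
        try:
            _STAGES[name](st, ctx, results, out)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        timings[name] = time.perf_counter() - t0

    provenance = {
        "config": config,
        "config_hash": _config_hash(config),
        "seed": seed,
        "versions": {
            "granulekit": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
        },
        "stage_timings_s": timings,
        "defaults_used": ctx.get("defaults_used", {}),
    }
    write_json(provenance, out / "provenance.json")
    return results


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------


def _stage_simulate(st: dict, ctx: dict, results: dict, out: Path) -> None:
    params = GranuleFieldParams(**{**st.get("params", {}), "seed": ctx["seed"]})
    stack, truth = generate_granule_image(params)
    ctx["stack"], ctx["truth"] = stack, truth
    write_image(stack, out / "image.tif")
    truth.save(out / "ground_truth.json")
    results["simulate_granules"] = {"n_granules": len(truth.granules)}


def _stage_segment(st: dict, ctx: dict, results: dict, out: Path) -> None:
    stack: ImageStack = ctx["stack"]
    mask = threshold_image(
        stack,
        channel=st.get("channel"),
        method=st.get("method", "intermodes"),
        value=st.get("value"),
        fraction=st.get("fraction"),
    )
    labels = label_objects(mask)
    ctx["mask"], ctx["labels"] = mask, labels
    ctx.setdefault("defaults_used", {})["connectivity"] = labels.connectivity
    results["segment"] = {"n_objects": labels.n_objects}


def _stage_measure(st: dict, ctx: dict, results: dict, out: Path) -> None:
    records = measure_objects(ctx["labels"], ctx["stack"], channel=st.get("channel"))
    ctx["records"] = records
    write_records_csv(records, out / "records.csv")
    results["measure"] = {"n_records": len(records)}


def _stage_size_fit(st: dict, ctx: dict, results: dict, out: Path) -> None:
    diam = np.array([r.equivalent_diameter_nm for r in ctx["records"]])
    fit = fit_size_distribution(diam)
    write_json(asdict(fit), out / "size_fit.json")
    results["size_fit"] = asdict(fit)


def _stage_partition(st: dict, ctx: dict, results: dict, out: Path) -> None:
    halo = int(st.get("exclusion_halo_voxels", 1))
    pc = partition_coefficient(
        ctx["stack"], st.get("channel"), ctx["mask"], exclusion_halo_voxels=halo
    )
    ctx.setdefault("defaults_used", {})["exclusion_halo_voxels"] = halo
    write_json(asdict(pc), out / "partition.json")
    results["partition"] = asdict(pc)


_STAGES = {
    "simulate_granules": _stage_simulate,
    "segment": _stage_segment,
    "measure": _stage_measure,
    "size_fit": _stage_size_fit,
    "partition": _stage_partition,
}
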