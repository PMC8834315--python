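"""End-to-end orchestration: run configured stages and emit a consolidated report.

A run is described by a single YAML or JSON config with a versioned
schema::

    schema: 1
    seed: 17
    out_dir: results/
    stages:
      - name: screen
        kind: triage
        reference_energy: -11.3        # input omitted -> packaged table
      - name: storage
        kind: lso
        manifest: fields.csv           # field_id,path[,mask_path]
        t_low: 10.0
        t_high: 120.0

Stage kinds: ``triage``, ``lso``, ``coloc``, ``blot``, ``stats``,
``simulate``. Stages run in listed order; a failing stage is recorded in
the report without aborting the others. Outputs are written atomically
(temp file + rename).
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from dataclasses import dataclass, field as dc_field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Callable

import pandas as pd

from . import __version__
from .errors import ConfigError, DegenerateFieldError
from . import blot as blotmod
from . import groupstats
from . import imaging
from . import synthetic
from . import triage as triagemod

__all__ = ["RunConfig", "StageResult", "RunReport", "run_pipeline", "write_report"]

logger = logging.getLogger("npcquant.pipeline")

SCHEMA_VERSION = 1
_STAGE_KINDS = ("triage", "lso", "coloc", "blot", "stats", "simulate")

# config keys per stage kind that name input files which must exist up front
_PATH_KEYS = {
    "triage": ("input",),
    "lso": ("manifest",),
    "coloc": ("ch1", "ch2", "mask"),
    "blot": ("lanes", "glyco"),
    "stats": ("input",),
    "simulate": (),
}


@dataclass
class RunConfig:
    stages: list[dict]
    out_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"
    base_dir: Path = dc_field(default_factory=Path)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        return cls.from_dict(raw, base_dir=path.parent)

    @classmethod
    def from_dict(cls, raw: dict, base_dir: str | Path = ".") -> "RunConfig":
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
        schema = raw.get("schema", SCHEMA_VERSION)
        if schema != SCHEMA_VERSION:
            raise ConfigError(f"unsupported config schema {schema!r}")
        stages = raw.get("stages")
        if not isinstance(stages, list) or not stages:
            raise ConfigError("config must list at least one stage")
        cfg = cls(
            stages=stages,
            out_dir=raw.get("out_dir", "results"),
            seed=int(raw.get("seed", 0)),
            log_level=str(raw.get("log_level", "INFO")),
            base_dir=Path(base_dir),
        )
        cfg.validate()
        return cfg

    def resolve(self, p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else self.base_dir / q

    def validate(self) -> None:
        """Full validation before any computation runs."""
        seen = set()
        for i, stage in enumerate(self.stages):
            if not isinstance(stage, dict):
                raise ConfigError(f"stage #{i} is not a mapping")
            kind = stage.get("kind")
            if kind not in _STAGE_KINDS:
                raise ConfigError(f"stage #{i}: unknown kind {kind!r}")
            name = stage.get("name", f"{kind}_{i}")
            if name in seen:
                raise ConfigError(f"duplicate stage name {name!r}")
            seen.add(name)
            for key in _PATH_KEYS[kind]:
                if key in stage and stage[key] is not None:
                    p = self.resolve(str(stage[key]))
                    if not p.exists():
                        raise ConfigError(f"stage {name!r}: missing file {p}")
            if kind == "lso":
                t_low = stage.get("t_low")
                t_high = stage.get("t_high")
                if t_low is None or t_high is None:
                    raise ConfigError(f"stage {name!r}: lso needs t_low and t_high")
                imaging.ThresholdPair(float(t_low), float(t_high))

    def echo(self) -> dict:
        return {
            "schema": SCHEMA_VERSION,
            "out_dir": self.out_dir,
            "seed": self.seed,
            "log_level": self.log_level,
            "stages": self.stages,
        }


@dataclass
class StageResult:
    name: str
    kind: str
    status: str  # ok | failed
    tables: dict[str, pd.DataFrame] = dc_field(default_factory=dict)
    summary: dict = dc_field(default_factory=dict)
    error: str | None = None


@dataclass
class RunReport:
    provenance: dict
    stages: list[StageResult] = dc_field(default_factory=list)

    def stage(self, name: str) -> StageResult:
        for s in self.stages:
            if s.name == name:
                return s
        raise KeyError(name)


# ---------------------------------------------------------------- stage handlers


def _stage_triage(cfg: RunConfig, stage: dict) -> StageResult:
    if stage.get("input"):
        records = triagemod.load_compound_table(cfg.resolve(stage["input"]))
    else:
        records = triagemod.load_reference_table()
    criterion = triagemod.HitCriterion(
        reference_energy=float(
            stage.get("reference_energy", triagemod.CHOLESTEROL_REFERENCE_ENERGY)
        )
    )
    table = triagemod.rank_compounds(records, criterion)
    hits = triagemod.select_hits(records, criterion)
    return StageResult(
        name=stage["name"],
        kind="triage",
        status="ok",
        tables={"ranking": table},
        summary={
            "n_compounds": len(records),
            "n_hits": len(hits),
            "hit_ids": [h.compound_id for h in hits],
            "reference_energy": criterion.reference_energy,
        },
    )


def _stage_lso(cfg: RunConfig, stage: dict) -> StageResult:
    thresholds = imaging.ThresholdPair(float(stage["t_low"]), float(stage["t_high"]))
    manifest = pd.read_csv(cfg.resolve(stage["manifest"]))
    measurements, skipped = [], []
    for _, row in manifest.iterrows():
        img = imaging.read_intensity_image(cfg.resolve(str(row["path"])))
        mask = None
        if "mask_path" in manifest.columns and isinstance(row.get("mask_path"), str):
            mask = imaging.read_intensity_image(cfg.resolve(row["mask_path"])) > 0
        try:
            measurements.append(
                imaging.lso_compartment_ratio(
                    img, thresholds, mask=mask, field_id=str(row["field_id"])
                )
            )
        except DegenerateFieldError:
            logger.warning("field %r degenerate, excluded", str(row["field_id"]))
            skipped.append(str(row["field_id"]))
    per_field = pd.DataFrame(
        [
            {
                "field_id": m.field_id,
                "ratio": m.ratio,
                "sum_high": m.sum_high,
                "n_low": m.n_low,
            }
            for m in measurements
        ]
    )
    summary = imaging.aggregate_fields(measurements)
    return StageResult(
        name=stage["name"],
        kind="lso",
        status="ok",
        tables={"per_field": per_field},
        summary={
            "mean_ratio": summary.mean,
            "sd_ratio": summary.sd,
            "n_fields": summary.n_fields,
            "t_low": thresholds.t_low,
            "t_high": thresholds.t_high,
            "skipped_fields": skipped,
        },
    )


def _stage_coloc(cfg: RunConfig, stage: dict) -> StageResult:
    ch1 = imaging.read_intensity_image(cfg.resolve(stage["ch1"]))
    ch2 = imaging.read_intensity_image(cfg.resolve(stage["ch2"]))
    summary: dict[str, Any] = {}
    whole = imaging.pearson_colocalization(ch1, ch2)
    summary["pearson_r"] = whole.r
    summary["n_pixels"] = whole.n_pixels
    if stage.get("mask"):
        mask = imaging.read_intensity_image(cfg.resolve(stage["mask"])) > 0
        masked = imaging.pearson_colocalization(ch1, ch2, mask=mask)
        summary["pearson_r_masked"] = masked.r
        summary["n_pixels_masked"] = masked.n_pixels
    return StageResult(
        name=stage["name"], kind="coloc", status="ok", summary=summary
    )


def _stage_blot(cfg: RunConfig, stage: dict) -> StageResult:
    lanes = blotmod.process_lane_table(pd.read_csv(cfg.resolve(stage["lanes"])))
    tables = {"levels": lanes}
    summary: dict[str, Any] = {}
    control = stage.get("control")
    if control:
        folds = blotmod.fold_changes_by_condition(lanes, str(control))
        tables["folds"] = folds
        summary["control_condition"] = str(control)
    if stage.get("glyco"):
        glyco = blotmod.process_glycoform_table(pd.read_csv(cfg.resolve(stage["glyco"])))
        tables["glycoforms"] = glyco
    return StageResult(
        name=stage["name"], kind="blot", status="ok", tables=tables, summary=summary
    )


def _stage_stats(cfg: RunConfig, stage: dict) -> StageResult:
    tidy = pd.read_csv(cfg.resolve(stage["input"]))
    control = str(stage["control"])
    groups = {
        str(g): tuple(float(x) for x in grp["value"])
        for g, grp in tidy.groupby("group", sort=False)
    }
    data = groupstats.GroupedMeasurements(groups=groups, control_label=control)
    result = groupstats.choose_and_run_test(data)
    table = pd.DataFrame(
        [
            {
                "group": g,
                "adjusted_p": result.p_values[g],
                "stars": result.stars[g],
                "normality_pass": result.normality_pass.get(g),
            }
            for g in result.p_values
        ]
    )
    return StageResult(
        name=stage["name"],
        kind="stats",
        status="ok",
        tables={"comparisons": table},
        summary={
            "test_used": result.test_used,
            "omnibus_p": result.omnibus_p,
            "control": control,
        },
    )


def _stage_simulate(cfg: RunConfig, stage: dict) -> StageResult:
    kind = stage.get("what") or stage.get("sim_kind") or stage.get("generator")
    if kind not in ("filipin", "coloc", "blot", "screen"):
        raise ConfigError(f"simulate stage needs generator in filipin/coloc/blot/screen, got {kind!r}")
    seed = int(stage.get("seed", cfg.seed))
    out_dir = Path(cfg.resolve(cfg.out_dir)) / stage["name"]
    out_dir.mkdir(parents=True, exist_ok=True)
    params = dict(stage.get("params", {}))
    summary: dict[str, Any] = {"generator": kind, "seed": seed}
    tables: dict[str, pd.DataFrame] = {}
    if kind == "filipin":
        import tifffile

        spec = synthetic.FilipinFieldSpec(seed=seed, **params)
        image, truth = synthetic.gen_filipin_field(spec)
        tif = out_dir / "field.tif"
        tifffile.imwrite(str(tif), image.astype("float32"))
        _atomic_json(out_dir / "field_truth.json", truth)
        summary.update(
            {"image": str(tif), "n_puncta_per_cell": truth["n_puncta_per_cell"]}
        )
    elif kind == "coloc":
        spec = synthetic.ColocSpec(seed=seed, **params)
        ch1, ch2 = synthetic.gen_coloc_pair(spec)
        tables["pixels"] = pd.DataFrame({"ch1": ch1, "ch2": ch2})
        summary["rho_true"] = spec.rho
    elif kind == "blot":
        spec = synthetic.BlotSpec(seed=seed, **params)
        lanes, glyco = synthetic.gen_blot_dataset(spec)
        tables["lanes"] = lanes
        tables["glycoforms"] = glyco
    else:  # screen
        spec = synthetic.ScreenSpec(seed=seed, **params)
        table, truth = synthetic.gen_screen_table(spec)
        tables["compounds"] = table
        summary["planted_hits"] = truth["n_hits"]
        _atomic_json(out_dir / "screen_truth.json", truth)
    for tname, tdf in tables.items():
        _atomic_csv(out_dir / f"{tname}.csv", tdf)
    summary["out_dir"] = str(out_dir)
    return StageResult(
        name=stage["name"], kind="simulate", status="ok", tables=tables, summary=summary
    )


_HANDLERS: dict[str, Callable[[RunConfig, dict], StageResult]] = {
    "triage": _stage_triage,
    "lso": _stage_lso,
    "coloc": _stage_coloc,
    "blot": _stage_blot,
    "stats": _stage_stats,
    "simulate": _stage_simulate,
}


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all configured stages; failures are isolated per stage."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    provenance = {
        "config": config.echo(),
        "package": "npcquant",
        "version": __version__,
        "seed": config.seed,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    report = RunReport(provenance=provenance)
    for i, stage in enumerate(config.stages):
        stage = {**stage, "name": stage.get("name", f"{stage['kind']}_{i}")}
        logger.info("[%s] running %s stage", stage["name"], stage["kind"])
        try:
            result = _HANDLERS[stage["kind"]](config, stage)
        except Exception as exc:  # isolate the failing stage
            logger.error("[%s] failed: %s", stage["name"], exc)
            result = StageResult(
                name=stage["name"], kind=stage["kind"], status="failed", error=str(exc)
            )
        report.stages.append(result)
    return report


# ------------------------------------------------------------------- reporting


def _atomic_write(path: Path, data: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _atomic_csv(path: Path, table: pd.DataFrame) -> None:
    _atomic_write(path, table.to_csv(index=False))


def _atomic_json(path: Path, obj: Any) -> None:
    _atomic_write(path, json.dumps(obj, indent=2, default=str) + "\n")


def report_to_dict(report: RunReport) -> dict:
    return {
        "provenance": report.provenance,
        "stages": [
            {
                "name": s.name,
                "kind": s.kind,
                "status": s.status,
                "error": s.error,
                "summary": s.summary,
                "tables": {k: v.to_dict(orient="records") for k, v in s.tables.items()},
            }
            for s in report.stages
        ],
    }


def write_report(
    report: RunReport, out_dir: str | Path, formats: tuple[str, ...] = ("csv", "json")
) -> list[Path]:
    """Write the consolidated report; returns the paths written.

    ``json`` -> one machine-readable ``report.json``; ``csv`` -> one CSV
    per stage table plus a ``stages.csv`` index. Writes are atomic.
    """
    out = Path(out_dir)
    written: list[Path] = []
    if "json" in formats:
        p = out / "report.json"
        _atomic_json(p, report_to_dict(report))
        written.append(p)
    if "csv" in formats:
        index_rows = []
        for s in report.stages:
            for tname, tdf in s.tables.items():
                p = out / f"{s.name}__{tname}.csv"
                _atomic_csv(p, tdf)
                written.append(p)
            index_rows.append(
                {"stage": s.name, "kind": s.kind, "status": s.status, "error": s.error}
            )
        p = out / "stages.csv"
        _atomic_csv(p, pd.DataFrame(index_rows))
        written.append(p)
    return written
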