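"""End-to-end runs: phantom → nnU-Net export → segment → evaluate → report.

A run is described by a JSON config (JSON, not YAML, to avoid dialect
ambiguity; the schema is versioned).  ``validate_config`` fills defaults and
rejects unknown keys with a suggestion; ``run`` executes the requested stages
in order, writes a machine-readable summary plus the normalized config and
tool version into the output directory (provenance), and is reproducible
artifact-for-artifact under a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import difflib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, volume_io
from .blocking import plan_blocks
from .metrics import MetricReport, evaluate_case, pairwise_ttests, summarize
from .phantom import PhantomSpec, generate_suite, write_suite
from .types import SemanticMask, TwoChannelVolume
from .watershed_seg import SegmentationParams, segment_biopsy

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1
STAGES = ("phantom", "export_nnunet", "segment", "evaluate", "report")

_IO_KEYS = {"out_dir", "input_dir", "predictions_dir", "reference_dir"}
_PHANTOM_KEYS = {"n_cases"} | {f.name for f in dataclasses.fields(PhantomSpec)} - {"seed"}
_SEGMENT_KEYS = {f.name for f in dataclasses.fields(SegmentationParams)} | {
    "block_shape", "overlap", "method_name"}
_EVALUATE_KEYS = {"level", "hausdorff_mode", "reference_method"}
_EXPORT_KEYS = {"dataset_id", "dataset_name"}
_TOP_KEYS = {"schema_version", "stages", "io", "seed", "log_level",
             "phantom", "export_nnunet", "segment", "evaluate", "report"}


class ConfigError(ValueError):
    """Invalid run configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Normalized pipeline configuration."""

    stages: list[str]
    io: dict
    seed: int = 42
    log_level: str = "INFO"
    phantom: dict = field(default_factory=dict)
    export_nnunet: dict = field(default_factory=dict)
    segment: dict = field(default_factory=dict)
    evaluate: dict = field(default_factory=dict)
    report: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        doc = dataclasses.asdict(self)
        doc["schema_version"] = SCHEMA_VERSION
        return doc


def _reject_unknown(given: dict, allowed: set, where: str) -> None:
    for key in given:
        if key not in allowed:
            hint = difflib.get_close_matches(key, allowed, n=1)
            msg = f"unknown key {key!r} in {where}"
            if hint:
                msg += f"; did you mean {hint[0]!r}?"
            raise ConfigError(msg)


def validate_config(source) -> RunConfig:
    """Validate and normalize a config (path, JSON string, or dict).

    Fills defaults, rejects unknown keys (with a closest-match suggestion),
    and checks that the requested stages form a valid dependency chain given
    the provided io paths.
    """
    if isinstance(source, dict):
        doc = dict(source)
    else:
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        doc = json.loads(text)
    if not isinstance(doc, dict):
        raise ConfigError("config must be a JSON object")
    _reject_unknown(doc, _TOP_KEYS, "config")
    if int(doc.get("schema_version", SCHEMA_VERSION)) != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema_version (expected {SCHEMA_VERSION})")

    stages = doc.get("stages")
    if not stages or not isinstance(stages, list):
        raise ConfigError("config must list at least one stage in 'stages'")
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ConfigError(f"unknown stage(s) {unknown}; valid: {list(STAGES)}")
    order = [STAGES.index(s) for s in stages]
    if order != sorted(order) or len(set(stages)) != len(stages):
        raise ConfigError(f"stages must be an ordered subset of {list(STAGES)}")

    io = dict(doc.get("io") or {})
    _reject_unknown(io, _IO_KEYS, "io")
    if "out_dir" not in io:
        raise ConfigError("io.out_dir is required")

    phantom = dict(doc.get("phantom") or {})
    _reject_unknown(phantom, _PHANTOM_KEYS, "phantom")
    export_nnunet = dict(doc.get("export_nnunet") or {})
    _reject_unknown(export_nnunet, _EXPORT_KEYS, "export_nnunet")
    segment = dict(doc.get("segment") or {})
    _reject_unknown(segment, _SEGMENT_KEYS, "segment")
    evaluate = dict(doc.get("evaluate") or {})
    _reject_unknown(evaluate, _EVALUATE_KEYS, "evaluate")
    report = dict(doc.get("report") or {})
    _reject_unknown(report, set(), "report")

    # eager validation of numeric parameter blocks (field-for-field mirrors)
    spec_kwargs = {k: v for k, v in phantom.items() if k != "n_cases"}
    PhantomSpec(**spec_kwargs)
    SegmentationParams(**{k: v for k, v in segment.items()
                          if k not in ("block_shape", "overlap", "method_name")})

    # dependency chain
    have = set()
    for s in stages:
        if s == "export_nnunet" and "phantom" not in have and "input_dir" not in io:
            raise ConfigError("stage 'export_nnunet' needs the phantom stage or io.input_dir")
        if s == "segment" and "phantom" not in have and "input_dir" not in io:
            raise ConfigError("stage 'segment' needs the phantom stage or io.input_dir")
        if s == "evaluate":
            if "segment" not in have and "predictions_dir" not in io:
                raise ConfigError("stage 'evaluate' needs the segment stage or "
                                  "io.predictions_dir")
            if "phantom" not in have and "reference_dir" not in io \
                    and "input_dir" not in io:
                raise ConfigError("stage 'evaluate' needs reference masks "
                                  "(phantom stage, io.reference_dir or io.input_dir)")
        if s == "report" and "evaluate" not in have:
            raise ConfigError("stage 'report' needs the evaluate stage")
        have.add(s)

    return RunConfig(stages=list(stages), io=io, seed=int(doc.get("seed", 42)),
                     log_level=str(doc.get("log_level", "INFO")),
                     phantom=phantom, export_nnunet=export_nnunet,
                     segment=segment, evaluate=evaluate, report=report)


# ---------------------------------------------------------------------------
# stage implementations

def _load_suite(input_dir) -> list[tuple[TwoChannelVolume, SemanticMask | None]]:
    input_dir = Path(input_dir)
    pairs = []
    for img in sorted(input_dir.glob("*_image.nii.gz")) + sorted(input_dir.glob("*_image.tiff")):
        name = img.name.split("_image")[0]
        vol = volume_io.read_volume(img)
        vol.name = name
        truth_path = None
        for ext in (".nii.gz", ".tiff"):
            cand = input_dir / f"{name}_truth{ext}"
            if cand.exists():
                truth_path = cand
                break
        truth = volume_io.read_mask(truth_path) if truth_path else None
        if truth is not None:
            truth.name = name
        pairs.append((vol, truth))
    if not pairs:
        raise FileNotFoundError(f"no '*_image.*' volumes found in {input_dir}")
    return pairs


def run(config: RunConfig | dict | str) -> dict:
    """Execute the configured stages in order and write a run summary.

    Returns the summary dict.  Raises :class:`StageError` (after recording
    the failure in the summary file) if any stage fails.
    """
    if not isinstance(config, RunConfig):
        config = validate_config(config)
    out_dir = Path(config.io["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    fh = logging.FileHandler(out_dir / "run.log")
    logging.getLogger().addHandler(fh)

    (out_dir / "normalized_config.json").write_text(json.dumps(config.to_dict(), indent=2))
    summary: dict = {"tool": "gland3d", "version": __version__,
                     "seed": config.seed, "stages": {}}

    cases = None          # list of (volume, truth) pairs
    predictions = None    # list of SemanticMask
    report_obj = None

    def _finish(stage, artifacts):
        summary["stages"][stage] = {"status": "ok", "artifacts": artifacts}
        logger.info("stage %s: ok", stage)

    try:
        for stage in config.stages:
            if stage == "phantom":
                n_cases = int(config.phantom.get("n_cases", 10))
                spec_kwargs = {k: v for k, v in config.phantom.items() if k != "n_cases"}
                spec = PhantomSpec(**spec_kwargs)
                suite, manifest = generate_suite(n_cases, spec, base_seed=config.seed)
                suite_dir = write_suite(suite, manifest, out_dir / "phantom")
                cases = [(c.volume, c.truth) for c in suite]
                _finish(stage, {"suite_dir": str(suite_dir), "n_cases": n_cases})
            elif stage == "export_nnunet":
                if cases is None:
                    cases = _load_suite(config.io["input_dir"])
                ds_dir = volume_io.export_nnunet_dataset(
                    [(v, t) for v, t in cases if t is not None],
                    out_dir / "nnunet",
                    dataset_id=int(config.export_nnunet.get("dataset_id", 1)),
                    dataset_name=str(config.export_nnunet.get("dataset_name",
                                                              "GlandPhantom")))
                _finish(stage, {"dataset_dir": str(ds_dir)})
            elif stage == "segment":
                if cases is None:
                    cases = _load_suite(config.io["input_dir"])
                seg_cfg = dict(config.segment)
                block_shape = seg_cfg.pop("block_shape", None)
                overlap = seg_cfg.pop("overlap", (0, 0, 0))
                seg_cfg.pop("method_name", None)
                params = SegmentationParams(**seg_cfg)
                pred_dir = out_dir / "predictions"
                pred_dir.mkdir(exist_ok=True)
                predictions = []
                for vol, _truth in cases:
                    layout = (plan_blocks(vol.shape, block_shape, overlap)
                              if block_shape else None)
                    mask = segment_biopsy(vol, params, layout)
                    volume_io.write_mask(mask, pred_dir / f"{vol.name}.nii.gz")
                    predictions.append(mask)
                _finish(stage, {"predictions_dir": str(pred_dir),
                                "n_cases": len(predictions)})
            elif stage == "evaluate":
                if cases is None:
                    src = config.io.get("reference_dir") or config.io.get("input_dir")
                    cases = _load_suite(src)
                if predictions is None:
                    names = [v.name for v, _ in cases]
                    predictions = volume_io.import_predictions(
                        config.io["predictions_dir"], names)
                method = str(config.segment.get("method_name", "watershed3d"))
                level = str(config.evaluate.get("level", "gland"))
                hmode = str(config.evaluate.get("hausdorff_mode", "boundary"))
                rows = []
                for (vol, truth), pred in zip(cases, predictions):
                    if truth is None:
                        raise ValueError(f"case {vol.name}: no reference mask")
                    df = evaluate_case(pred, truth, level=level, hausdorff_mode=hmode)
                    df["method"] = method
                    rows.append(df)
                import pandas as pd
                per_case = pd.concat(rows, ignore_index=True)
                eval_dir = out_dir / "evaluation"
                eval_dir.mkdir(exist_ok=True)
                per_case.to_csv(eval_dir / "per_case.csv", index=False)
                report_obj = MetricReport(per_case=per_case.rename(
                    columns={"comparison": "level"}))
                _finish(stage, {"per_case_csv": str(eval_dir / "per_case.csv"),
                                "n_rows": len(per_case)})
            elif stage == "report":
                rep_dir = out_dir / "report"
                methods = report_obj.per_case["method"].unique()
                if len(methods) > 1:
                    ref = str(config.evaluate.get("reference_method", methods[0]))
                    report_obj.pairwise = pairwise_ttests(report_obj.per_case, ref)
                agg = summarize(report_obj, rep_dir)
                summary["metrics"] = {
                    row["method"] + "/" + row["metric"]: {
                        "mean": row["mean"], "min": row["min"], "max": row["max"]}
                    for row in agg.to_dict("records")}
                _finish(stage, {"report_dir": str(rep_dir)})
    except Exception as err:
        stage = stage if "stage" in locals() else "?"
        summary["stages"][stage] = {"status": "failed", "error": str(err)}
        (out_dir / "run_summary.json").write_text(json.dumps(summary, indent=2))
        logging.getLogger().removeHandler(fh)
        raise StageError(stage, err) from err

    (out_dir / "run_summary.json").write_text(json.dumps(summary, indent=2))
    logging.getLogger().removeHandler(fh)
    return summary
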