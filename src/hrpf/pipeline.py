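"""End-to-end orchestration: calibrate -> rescore -> evaluate -> report.

A :class:`RunConfig` (YAML-serialisable) names the input files and carries
every tunable constant; :func:`run_rescoring_pipeline` produces a score
table, an ensemble report and a JSON run manifest recording parameters and
input checksums.  :func:`run_weight_scan` repeats the evaluation across
hrf_dynamics weights.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .errors import HrpfError, ValidationError
from .evaluation import EnsembleReport, PnearParams, p_near, rmsd_to_native, summarize_ensemble
from .exposure import ConeParams
from .hrpf_scoring import ScoreParams, ScoreRecord, rescore_ensemble
from .pf_calibration import CalibrationLine
from .structure_io import (SSESpec, extract_sse_residues, read_base_scores,
                           read_models, read_pf_table, write_score_table)

logger = logging.getLogger("hrpf")


@dataclass
class RunConfig:
    """Paths plus every scoring constant for one rescoring run."""

    models: str = ""
    native: str = ""
    pf: str = ""
    base_scores: str = ""
    out_dir: str = "hrpf_out"
    cone: ConeParams = field(default_factory=ConeParams)
    line: CalibrationLine = field(default_factory=CalibrationLine)
    steepness: float = 2.0
    delta: float = 3.5
    weight: float = 12.0
    pnear: PnearParams = field(default_factory=PnearParams)
    residue_filter: str = "WYFHL"
    top_n: int = 1000
    rmsd_threshold: float = 10.0
    sse: str = "auto"  # "auto" | "none" | comma-joined ranges "A:1-4,A:8-12"
    skip_missing: bool = False
    log_level: str = "INFO"
    seed: int = 0

    def score_params(self, weight: Optional[float] = None) -> ScoreParams:
        return ScoreParams(steepness=self.steepness, delta=self.delta,
                           weight=self.weight if weight is None else weight,
                           line=self.line, cone=self.cone)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cone" in d and isinstance(d["cone"], dict):
            d["cone"] = ConeParams(**d["cone"])
        if "line" in d and isinstance(d["line"], dict):
            d["line"] = CalibrationLine(**d["line"])
        if "pnear" in d and isinstance(d["pnear"], dict):
            d["pnear"] = PnearParams(**d["pnear"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    if path.is_dir():
        for p in sorted(path.iterdir()):
            if p.is_file():
                h.update(p.name.encode())
                h.update(p.read_bytes())
    else:
        h.update(path.read_bytes())
    return h.hexdigest()


def _resolve_sse(config: RunConfig) -> Optional[SSESpec]:
    if config.sse == "none":
        return None
    if config.sse == "auto":
        try:
            return extract_sse_residues(config.native)
        except (HrpfError, ValidationError):
            logger.warning("no SSE records in %s; RMSD_SSE omitted", config.native)
            return None
    from .structure_io import parse_sse_ranges
    return parse_sse_ranges(config.sse.split(","))


def run_rescoring_pipeline(config: RunConfig,
                           write_outputs: bool = True,
                           ) -> tuple[EnsembleReport, list[ScoreRecord]]:
    """Read inputs, rescore with hrf_dynamics, annotate RMSD, report.

    Outputs under ``config.out_dir``: ``scored.tsv`` (score table),
    ``report.json`` (ensemble metrics) and ``manifest.json`` (parameters and
    input checksums).  Output bytes depend only on inputs and config.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    written: list[Path] = []
    try:
        stage = "read inputs"
        native = read_models(config.native)[0]
        models = read_models(config.models)
        models.sort(key=lambda m: m.model_id)  # order-insensitive on disk layout
        pf = read_pf_table(config.pf, frozenset(config.residue_filter))
        base = read_base_scores(config.base_scores)
        sse = _resolve_sse(config)

        stage = "rescore"
        params = config.score_params()
        records = rescore_ensemble(models, pf, base, params,
                                   skip_missing=config.skip_missing)

        stage = "evaluate"
        models_by_id = {m.model_id: m for m in models}
        for r in records:
            if r.rmsd is None:
                r.rmsd = rmsd_to_native(models_by_id[r.model_id], native)
        report = summarize_ensemble(records, native, models_by_id, sse,
                                    top_n=config.top_n,
                                    threshold=config.rmsd_threshold,
                                    params=config.pnear)

        if write_outputs:
            stage = "write outputs"
            out_dir.mkdir(parents=True, exist_ok=True)
            score_path = out_dir / "scored.tsv"
            write_score_table(records, score_path)
            written.append(score_path)
            report_path = out_dir / "report.json"
            report_path.write_text(json.dumps(dataclasses.asdict(report),
                                              indent=2, sort_keys=True) + "\n")
            written.append(report_path)
            manifest = {
                "config": config.to_dict(),
                "inputs": {name: _sha256(Path(getattr(config, name)))
                           for name in ("models", "native", "pf", "base_scores")},
                "n_models": len(records),
            }
            manifest_path = out_dir / "manifest.json"
            manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
            written.append(manifest_path)
            logger.info("wrote %s", ", ".join(str(p) for p in written))
        return report, records
    except Exception:
        for p in written:  # do not leave partial outputs behind
            p.unlink(missing_ok=True)
        logger.error("pipeline failed during stage: %s", stage)
        raise


DEFAULT_WEIGHTS = tuple(float(w) for w in range(1, 21))


def run_weight_scan(config: RunConfig,
                    weights: Sequence[float] = DEFAULT_WEIGHTS,
                    ) -> dict[float, EnsembleReport]:
    """One ensemble report per hrf_dynamics weight (default 1..20).

    The hrf term is computed once; only the weighting and ranking change
    between weights.
    """
    weights = list(weights)
    if not weights:
        raise ValidationError("need at least one weight")
    base_cfg = dataclasses.replace(config, weight=weights[0])
    _, records = run_rescoring_pipeline(base_cfg, write_outputs=False)
    out: dict[float, EnsembleReport] = {}
    for w in weights:
        rw = [dataclasses.replace(r, total_score=w * r.hrf_score + r.base_score)
              for r in records]
        out[w] = summarize_ensemble(rw, top_n=config.top_n,
                                    threshold=config.rmsd_threshold,
                                    params=config.pnear)
    return out
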