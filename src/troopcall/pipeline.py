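"""End-to-end orchestration: simulate -> acoustics -> social -> movements -> stats.

Each stage is a pure function of its inputs, the configuration and the
seed; stage outputs are plain CSV (and WAV for audio), and a re-run of an
unchanged stage is a checksum-gated no-op.  The final report mirrors the
result structure of the field study: the call-type feature table, the
vocal/non-vocal movement tallies, the participant-count comparison, the
joining-order correlation, and the social-factor count model.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import acoustics, movement, social, stats, synthetic

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("troopcall")

_ALL_STAGES = ("simulate", "acoustics", "social", "movements", "stats")


class PipelineError(RuntimeError):
    """A stage failed or the run configuration is inconsistent."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one pipeline run.

    ``stages`` toggles each step; disabled stages must find their inputs
    already present in ``out_dir`` (the error names the stage to rerun).
    """

    out_dir: Path
    seed: int = 0
    stages: tuple[str, ...] = _ALL_STAGES
    preset: str | None = None
    troop: synthetic.TroopConfig | None = None
    call_jitter: float = 0.0
    ds_correction: str = "pij"
    family: str = "zip"
    report_format: str = "markdown"

    def __post_init__(self) -> None:
        object.__setattr__(self, "out_dir", Path(self.out_dir))
        unknown = [s for s in self.stages if s not in _ALL_STAGES]
        if unknown:
            raise PipelineError(f"unknown stages: {', '.join(unknown)}")
        if not self.stages:
            raise PipelineError("no stages enabled")
        if self.report_format not in ("markdown", "csv"):
            raise PipelineError(f"unknown report format: {self.report_format!r}")

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        run = raw.get("run", {})
        troop_raw = raw.get("troop", {})
        kwargs: dict = {
            "out_dir": Path(run.get("out_dir", "runs/troopcall")),
            "seed": int(run.get("seed", 0)),
            "stages": tuple(run.get("stages", _ALL_STAGES)),
            "preset": run.get("preset"),
            "call_jitter": float(run.get("call_jitter", 0.0)),
            "ds_correction": run.get("ds_correction", "pij"),
            "family": run.get("family", "zip"),
            "report_format": run.get("report_format", "markdown"),
        }
        kwargs.update(overrides)
        if troop_raw:
            kwargs["troop"] = synthetic.TroopConfig(seed=kwargs["seed"], **troop_raw)
        return cls(**kwargs)

    def troop_config(self) -> synthetic.TroopConfig:
        if self.troop is not None:
            return self.troop
        return synthetic.TroopConfig(seed=self.seed)


def _file_digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_signature(inputs: Sequence[Path], config_repr: str) -> str:
    h = hashlib.sha256(config_repr.encode())
    for path in sorted(inputs):
        h.update(str(path).encode())
        h.update(_file_digest(path).encode())
    return h.hexdigest()


class _StageState:
    """Persisted per-stage input signatures for checksum gating."""

    def __init__(self, out_dir: Path) -> None:
        self.path = out_dir / ".stage_state.json"
        self.state = {}
        if self.path.exists():
            self.state = json.loads(self.path.read_text())

    def unchanged(self, stage: str, signature: str, outputs: Sequence[Path]) -> bool:
        return self.state.get(stage) == signature and all(p.exists() for p in outputs)

    def record(self, stage: str, signature: str) -> None:
        self.state[stage] = signature
        self.path.write_text(json.dumps(self.state, indent=1, sort_keys=True))


def _require(out: Path, names: Sequence[str], needed_by: str, producer: str) -> list[Path]:
    paths = [out / n for n in names]
    missing = [p.name for p in paths if not p.exists()]
    if missing:
        raise PipelineError(
            f"stage '{needed_by}' is missing inputs {', '.join(missing)}; "
            f"rerun stage '{producer}'"
        )
    return paths


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order and write the report.

    Returns a dict of the report tables.  Raises ``PipelineError`` (and
    the CLI exits nonzero) on any stage failure.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    stderr_handler = logging.StreamHandler(sys.stderr)
    fmt = logging.Formatter("%(levelname)s %(name)s: %(message)s")
    for h in (handler, stderr_handler):
        h.setFormatter(fmt)
        logger.addHandler(h)
    logger.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        for h in (handler, stderr_handler):
            logger.removeHandler(h)
            h.close()


def _run(config: RunConfig, out: Path) -> dict:
    state = _StageState(out)
    logger.info("resolved config: %s", config)
    report: dict = {}

    if "simulate" in config.stages:
        troop = config.troop_config()
        sig = _stage_signature([], repr((troop, config.preset, config.call_jitter)))
        outputs = [out / n for n in ("roster.csv", "proximity.csv", "agonistic.csv", "movements.csv")]
        if state.unchanged("simulate", sig, outputs):
            logger.info("simulate: inputs unchanged, skipping")
        else:
            logger.info("simulate: seed=%d preset=%s", troop.seed, config.preset)
            synthetic.write_dataset(
                out, troop, preset=config.preset, call_jitter=config.call_jitter
            )
            state.record("simulate", sig)
            logger.info("simulate: wrote %s", ", ".join(p.name for p in outputs))

    if "acoustics" in config.stages:
        calls_dir = out / "calls"
        if not calls_dir.is_dir():
            raise PipelineError(
                "stage 'acoustics' is missing its calls/ directory; rerun stage 'simulate'"
            )
        wavs = sorted(calls_dir.glob("*.wav"))
        sig = _stage_signature(wavs, "acoustics")
        if state.unchanged("acoustics", sig, [out / "features.csv"]):
            logger.info("acoustics: inputs unchanged, skipping")
        else:
            rows = []
            for path in wavs:
                wave = acoustics.read_wav(path)
                feats = acoustics.extract_features(wave)
                name, dist = acoustics.classify_call(feats)
                rows.append(
                    {
                        "file": path.name,
                        "caller_id": "",
                        "duration_s": feats.duration,
                        "mean_f0": feats.mean_f0,
                        "min_f0": feats.min_f0,
                        "max_f0": feats.max_f0,
                        "mean_amp_db": feats.mean_amp,
                        "min_amp_db": feats.min_amp,
                        "max_amp_db": feats.max_amp,
                        "call_type": name,
                        "distance": dist,
                    }
                )
            pd.DataFrame(rows).to_csv(out / "features.csv", index=False)
            state.record("acoustics", sig)
            logger.info("acoustics: %d files -> features.csv", len(wavs))

    if "social" in config.stages:
        inputs = _require(out, ["proximity.csv", "agonistic.csv", "roster.csv"], "social", "simulate")
        sig = _stage_signature(inputs, config.ds_correction)
        outputs = [out / n for n in ("dai_matrix.csv", "centrality.csv", "dominance.csv")]
        if state.unchanged("social", sig, outputs):
            logger.info("social: inputs unchanged, skipping")
        else:
            roster = synthetic.roster_from_frame(pd.read_csv(out / "roster.csv", keep_default_na=False))
            prox = social.read_proximity_csv(out / "proximity.csv")
            bouts = social.read_agonistic_csv(out / "agonistic.csv")
            dai = social.compute_dai(prox, roster)
            centrality = social.eigenvector_centrality(dai)
            dominance = social.davids_score(bouts, roster, correction=config.ds_correction)
            social.write_social_outputs(out, dai, centrality, dominance)
            state.record("social", sig)
            logger.info(
                "social: %d proximity records, %d bouts -> DAI/centrality/dominance",
                len(prox),
                len(bouts),
            )

    if "movements" in config.stages:
        inputs = _require(out, ["movements.csv"], "movements", "simulate")
        sig = _stage_signature(inputs, "movements")
        outputs = [out / n for n in ("events_summary.csv", "order_index.csv", "vocal_rates.csv")]
        if state.unchanged("movements", sig, outputs):
            logger.info("movements: inputs unchanged, skipping")
        else:
            events = movement.read_movements_csv(out / "movements.csv")
            movement.write_movement_outputs(out, events)
            state.record("movements", sig)
            logger.info("movements: %d events", len(events))

    if "stats" in config.stages:
        inputs = _require(
            out,
            ["movements.csv", "roster.csv", "centrality.csv", "dominance.csv", "vocal_rates.csv"],
            "stats",
            "social/movements",
        )
        sig = _stage_signature(inputs, config.family)
        if state.unchanged("stats", sig, [out / "model_table.csv"]):
            logger.info("stats: inputs unchanged, skipping")
        else:
            _run_stats_stage(config, out)
            state.record("stats", sig)

    report = _build_report(config, out)
    return report


def _run_stats_stage(config: RunConfig, out: Path) -> None:
    roster = synthetic.roster_from_frame(pd.read_csv(out / "roster.csv", keep_default_na=False))
    events = movement.read_movements_csv(out / "movements.csv")
    centrality = pd.read_csv(out / "centrality.csv").set_index("id")["centrality"]
    dominance = pd.read_csv(out / "dominance.csv").set_index("id")["rank"]
    relatives = pd.Series({ind.id: ind.n_relatives for ind in roster})

    table = movement.observation_table(
        events, roster, centrality, rank=dominance, relatives=relatives
    )
    predictors = ["female", "centrality", "rank", "relatives", "order_index"]
    model = stats.VocalCountModel.from_dataframe(
        table, response="calls", predictors=predictors, family=config.family
    )
    results = model.fit()
    results.summary().to_csv(out / "model_table.csv", index=False)
    logger.info("stats: fitted %s model on %d observations", config.family, len(table))


def _build_report(config: RunConfig, out: Path) -> dict:
    report: dict = {}

    if (out / "features.csv").exists():
        feats = pd.read_csv(out / "features.csv")
        by_type = feats.groupby("call_type").agg(
            n=("file", "count"),
            duration=("duration_s", "mean"),
            mean_f0=("mean_f0", "mean"),
            min_f0=("min_f0", "mean"),
            max_f0=("max_f0", "mean"),
            mean_amp=("mean_amp_db", "mean"),
            min_amp=("min_amp_db", "mean"),
            max_amp=("max_amp_db", "mean"),
        )
        report["call_types"] = by_type.reset_index()

    events = None
    if (out / "movements.csv").exists():
        events = movement.read_movements_csv(out / "movements.csv")
        summary = movement.vocal_summary(events)
        report["tallies"] = pd.DataFrame([dataclasses.asdict(summary)])

        vocal_sizes = [e.n_participants for e in events if e.successful and e.vocal]
        silent_sizes = [e.n_participants for e in events if e.successful and not e.vocal]
        if vocal_sizes and silent_sizes:
            mw = stats.mann_whitney(vocal_sizes, silent_sizes)
            report["participants_test"] = pd.DataFrame(
                [
                    {
                        "mean_participants_vocal": np.mean(vocal_sizes),
                        "mean_participants_silent": np.mean(silent_sizes),
                        "U": mw.u,
                        "W": mw.w,
                        "p": mw.p_value,
                        "method": mw.method,
                    }
                ]
            )

        rates = movement.vocal_rates(events)
        if len(rates) >= 3:
            corr = stats.spearman(rates["mean_order_index"], rates["vocal_rate"])
            report["order_correlation"] = pd.DataFrame(
                [{"n": corr.n, "rho": corr.rho, "p": corr.p_value}]
            )

    if (out / "model_table.csv").exists():
        report["social_factors"] = pd.read_csv(out / "model_table.csv")

    _write_report(report, config, out)
    return report


def _write_report(report: dict, config: RunConfig, out: Path) -> None:
    titles = {
        "call_types": "Call types (feature means per assigned type)",
        "tallies": "Vocal communication during group movements",
        "participants_test": "Participants in vocal vs silent movements",
        "order_correlation": "Joining order vs vocal frequency",
        "social_factors": "Social factors and vocal frequency (count model)",
    }
    if config.report_format == "csv":
        for key, frame in report.items():
            frame.to_csv(out / f"report_{key}.csv", index=False)
        return
    lines = ["# troopcall run report", ""]
    for key, frame in report.items():
        lines.append(f"## {titles.get(key, key)}")
        lines.append("")
        lines.append(frame.to_markdown(index=False))
        lines.append("")
    (out / "report.md").write_text("\n".join(lines))
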