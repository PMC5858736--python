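"""End-to-end orchestration: simulate -> fd -> pairs -> acf -> anova -> predict.

Every stage writes a TSV whose header echoes the run configuration; a
manifest records each output file with its SHA-256 content hash so any
stage can be re-run and verified in isolation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import fractal, gaze_io, prediction, sequence_context, synthetic_study, variance_analysis
from .errors import DataError

DEFAULT_ANOVA_TERMS = ["F0", "P0", "F1", "P1", "D1"]


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "gazeseq_out"
    study: dict = field(default_factory=dict)
    fractal: dict = field(default_factory=dict)
    pairs: dict = field(default_factory=dict)       # max_lag
    acf: dict = field(default_factory=dict)         # max_lag
    anova: dict = field(default_factory=dict)       # terms, lag, alpha
    predict: dict = field(default_factory=dict)     # family, lags, hyperparams, reps

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config section(s): {sorted(unknown)}")
        return cls(**raw)

    def echo(self) -> str:
        payload = {
            "seed": self.seed,
            "study": self.study,
            "fractal": self.fractal,
            "pairs": self.pairs,
            "acf": self.acf,
            "anova": self.anova,
            "predict": self.predict,
        }
        return json.dumps(payload, sort_keys=True)


def attach_analysis_columns(
    readings_frame: pd.DataFrame, cases_frame: pd.DataFrame, fd_frame: pd.DataFrame
) -> pd.DataFrame:
    """Join readings with case density and per-reading FD."""
    merged = readings_frame.merge(
        cases_frame[["case_id", "density"]], on="case_id", how="left"
    ).merge(fd_frame[["reader_id", "case_id", "fd"]], on=["reader_id", "case_id"], how="left")
    if merged["density"].isna().any():
        raise DataError("density missing for one or more readings")
    if merged["fd"].isna().any():
        raise DataError("FD missing for one or more readings")
    return merged


def study_frame(readings, cases, geometry, grid_size: int = fractal.DEFAULT_GRID_SIZE) -> pd.DataFrame:
    """In-memory convenience: readings + density + FD for a simulated study."""
    frame = (geometry.total_width, geometry.height)
    fd_frame = fractal.fd_table(
        ((r.reader_id, r.case_id, r.scanpath) for r in readings),
        grid_size=grid_size,
        frame=frame,
    )
    return attach_analysis_columns(
        synthetic_study.readings_to_frame(readings),
        synthetic_study.cases_to_frame(cases),
        fd_frame,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage deterministically; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config": config.echo()}
    manifest: dict = {"seed": config.seed, "config": json.loads(config.echo()), "files": {}}

    def record(stage: str, path: Path, params: dict | None = None) -> None:
        manifest["files"][path.name] = {
            "stage": stage,
            "sha256": _sha256(path),
            "params": params or {},
        }

    # --- simulate ----------------------------------------------------------
    study_params = dict(config.study)
    geometry = gaze_io.DisplayGeometry(
        width=int(study_params.pop("display_width", 1280)),
        height=int(study_params.pop("display_height", 1024)),
    )
    readings, cases = synthetic_study.generate_study(
        seed=config.seed, geometry=geometry, **study_params
    )
    rate = float(study_params.get("rate", 60.0))
    cases_frame = synthetic_study.cases_to_frame(cases)
    readings_frame = synthetic_study.readings_to_frame(readings)
    gaze_table = gaze_io.gaze_table_from_streams(
        ((r.reader_id, r.case_id, r.scanpath) for r in readings), geometry, rate
    )
    gaze_io.write_cases(out / "cases.tsv", cases_frame, meta)
    gaze_io.write_readings(out / "readings.tsv", readings_frame, meta)
    gaze_io.write_gaze(out / "gaze.tsv", gaze_table)
    record("simulate", out / "cases.tsv", study_params)
    record("simulate", out / "readings.tsv", study_params)
    record("simulate", out / "gaze.tsv", study_params)

    # --- fd ----------------------------------------------------------------
    grid_size = int(config.fractal.get("grid_size", fractal.DEFAULT_GRID_SIZE))
    fd_frame = fractal.fd_table(
        ((r.reader_id, r.case_id, r.scanpath) for r in readings),
        grid_size=grid_size,
        frame=(geometry.total_width, geometry.height),
    )
    gaze_io.write_fd_table(out / "fd.tsv", fd_frame, meta)
    record("fd", out / "fd.tsv", {"grid_size": grid_size})

    analysis = attach_analysis_columns(readings_frame, cases_frame, fd_frame)

    # --- pairs -------------------------------------------------------------
    max_lag = int(config.pairs.get("max_lag", 5))
    for lag in range(max_lag + 1):
        parts = []
        for reader_id, sub in analysis.groupby("reader_id", sort=True):
            ds = sequence_context.build_lag_pairs(sub, lag)
            block = ds.frame.copy()
            block.insert(0, "reader_id", reader_id)
            parts.append(block)
        pairs_frame = pd.concat(parts, ignore_index=True)
        path = out / f"pairs_lag{lag}.tsv"
        with open(path, "w", encoding="utf-8") as fh:
            for key, value in meta.items():
                fh.write(f"# {key}: {value}\n")
            pairs_frame.to_csv(fh, sep="\t", index=False, float_format="%.6f")
        record("pairs", path, {"lag": lag})

    # --- acf ---------------------------------------------------------------
    acf_max_lag = int(config.acf.get("max_lag", 20))
    acf_rows = []
    for reader_id, sub in analysis.groupby("reader_id", sort=True):
        sub = sub.sort_values("order_index")
        for name, series in (
            ("decision", sequence_context.decision_series(sub["decision"])),
            ("fd", sub["fd"].to_numpy(dtype=float)),
        ):
            res = sequence_context.autocorrelation(series, acf_max_lag)
            for lag, r, sig in zip(res.lags, res.r, res.significant):
                acf_rows.append(
                    {
                        "reader_id": reader_id,
                        "series": name,
                        "lag": int(lag),
                        "r": float(r),
                        "band": res.band,
                        "significant": bool(sig),
                    }
                )
    acf_frame = pd.DataFrame(acf_rows)
    path = out / "acf.tsv"
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        acf_frame.to_csv(fh, sep="\t", index=False, float_format="%.6f")
    record("acf", path, {"max_lag": acf_max_lag})

    # --- anova -------------------------------------------------------------
    terms = list(config.anova.get("terms", DEFAULT_ANOVA_TERMS))
    anova_lag = int(config.anova.get("lag", 1))
    alpha = float(config.anova.get("alpha", 0.05))
    anova_rows = []
    for reader_id, sub in analysis.groupby("reader_id", sort=True):
        ds = sequence_context.build_lag_pairs(sub, anova_lag)
        table = variance_analysis.fixed_effects_anova(ds, terms, alpha=alpha)
        table.insert(0, "reader_id", reader_id)
        anova_rows.append(table)
    anova_frame = pd.concat(anova_rows, ignore_index=True).sort_values(
        ["reader_id", "p"], kind="stable"
    )
    path = out / "anova.tsv"
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        anova_frame.to_csv(fh, sep="\t", index=False, float_format="%.6g")
    record("anova", path, {"terms": terms, "lag": anova_lag, "alpha": alpha})

    # --- predict -----------------------------------------------------------
    pred_cfg = dict(config.predict)
    spec = prediction.ModelSpec(
        family=pred_cfg.get("family", "random-forest"),
        hyperparams=pred_cfg.get("hyperparams", {}),
        seed=config.seed,
    )
    lags = pred_cfg.get("lags", list(range(int(config.pairs.get("max_lag", 5)) + 1)))
    report, tier_report = prediction.sweep_lags(
        analysis,
        spec,
        lags=lags,
        baseline_reps=int(pred_cfg.get("reps", 1000)),
    )
    for name, frame in (("predict.tsv", report), ("predict_tiers.tsv", tier_report)):
        path = out / name
        with open(path, "w", encoding="utf-8") as fh:
            for key, value in meta.items():
                fh.write(f"# {key}: {value}\n")
            frame.to_csv(fh, sep="\t", index=False, float_format="%.6f")
        record("predict", path, {"family": spec.family, "lags": list(lags)})

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
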