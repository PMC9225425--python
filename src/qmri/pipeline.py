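"""End-to-end orchestration: simulate -> T2 maps -> DCE AUC -> measurement
table -> group statistics, with a reproducibility manifest.

Also hosts the cohort-level simulation studies (type-I error calibration and
effect-recovery) used to validate the statistics layer against the phantom's
known ground truth.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import dce, relaxometry, roistats
from ._version import __version__
from .groupstats import fit_mixed_model, hedges_g
from .phantom import (AcquisitionSpec, DesignSpec, Session, TissueSpec,
                      simulate_cohort)

__all__ = [
    "ConfigError",
    "StageError",
    "RunManifest",
    "load_config",
    "process_session",
    "run_cohort",
    "run_all",
    "type_one_error_rate",
    "recovery_study",
    "group_effect_size",
]


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    config: dict
    seed: int
    version: str
    started: str
    finished: str = ""
    file_hashes: Dict[str, str] = field(default_factory=dict)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def _parse_effects(d: Optional[Mapping[str, float]]) -> Dict[Tuple[str, str], float]:
    """YAML effect maps use 'roi@Day' keys; convert to (roi, day) tuples."""
    out: Dict[Tuple[str, str], float] = {}
    for key, mult in (d or {}).items():
        if "@" not in key:
            raise ConfigError(f"effect key {key!r} must look like 'roi@Day1'")
        roi, day = key.split("@", 1)
        out[(roi, day)] = float(mult)
    return out


def load_config(source) -> dict:
    """Load and validate the single-file YAML pipeline config.

    Required sections: ``design`` and ``acquisition``; optional: ``tissues``,
    ``exclusions``, ``analysis``, ``seed``.  Raises :class:`ConfigError`
    listing every missing required key.
    """
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text())
    else:
        raw = dict(source)
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    missing = [k for k in ("design", "acquisition") if k not in raw]
    if missing:
        raise ConfigError(f"config lacks required keys: {missing}")
    return raw


def _build_specs(cfg: dict, seed: Optional[int] = None):
    dcfg = dict(cfg.get("design", {}))
    dcfg["injury_effects"] = _parse_effects(dcfg.get("injury_effects"))
    dcfg["sex_effects"] = _parse_effects(dcfg.get("sex_effects"))
    if seed is not None:
        dcfg["seed"] = int(seed)
    elif "seed" in cfg:
        dcfg.setdefault("seed", int(cfg["seed"]))
    acfg = dict(cfg.get("acquisition", {}))
    for key in ("echo_times_ms", "voxel_size_um", "matrix"):
        if key in acfg:
            acfg[key] = tuple(acfg[key])
    try:
        design = DesignSpec(**dcfg)
        acq = AcquisitionSpec(**acfg)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    tissues = None
    if cfg.get("tissues"):
        tissues = [TissueSpec(**t) for t in cfg["tissues"]]
    rules = roistats.ExclusionConfig(**cfg.get("exclusions", {}))
    analysis = dict(metrics=("auc_norm", "t2_ms"), t2_method="nlls",
                    n_baseline_frames=2)
    analysis.update(cfg.get("analysis", {}))
    return design, acq, tissues, rules, analysis


# ---------------------------------------------------------------------------
# Per-session and cohort processing
# ---------------------------------------------------------------------------

def process_session(session: Session, rules: roistats.ExclusionConfig,
                    metrics: Sequence[str] = ("auc_norm", "t2_ms"),
                    t2_method: str = "nlls",
                    n_baseline_frames: int = 2) -> List[dict]:
    """Reduce one animal-visit's images to per-ROI measurement records."""
    records: List[dict] = []
    base = dict(animal_id=session.animal_id, sex=session.sex,
                injury=session.injury, regimen=session.regimen, day=session.day)

    auc_df = dce.roi_auc_stats(session.dce, session.labels,
                               n_baseline_frames=n_baseline_frames,
                               mad_k=rules.mad_k)
    muscle_auc = float(auc_df["muscle_auc_raw"].iloc[0])
    if "auc_norm" in metrics:
        for r in auc_df.itertuples():
            if r.roi == "muscle":
                continue
            records.append(dict(base, roi=r.roi, metric="auc_norm",
                                value=float(r.auc_norm),
                                muscle_auc_raw=muscle_auc,
                                n_voxels=int(r.n_voxels)))
    if "t2_ms" in metrics:
        if session.multi_echo is None:
            raise ValueError("session lacks a multi-echo stack for T2 analysis")
        t2map = relaxometry.fit_t2_map(session.multi_echo, session.labels,
                                       method=t2_method)
        t2df = relaxometry.roi_t2(t2map, session.labels, mad_k=rules.mad_k)
        for r in t2df.itertuples():
            if r.roi == "muscle":
                continue
            records.append(dict(base, roi=r.roi, metric="t2_ms",
                                value=float(r.mean) if not r.missing else np.nan,
                                muscle_auc_raw=muscle_auc,
                                n_voxels=int(r.n_voxels)))
    return records


def run_cohort(design: DesignSpec, acq: AcquisitionSpec,
               tissues: Optional[Sequence[TissueSpec]] = None,
               rules: Optional[roistats.ExclusionConfig] = None,
               metrics: Sequence[str] = ("auc_norm", "t2_ms"),
               t2_method: str = "nlls",
               n_baseline_frames: int = 2) -> pd.DataFrame:
    """Simulate a cohort and reduce it to the flagged measurement table."""
    rules = rules or roistats.ExclusionConfig()
    cohort = simulate_cohort(design, acq, tissues)
    records: List[dict] = []
    for session in cohort.iter_sessions(multi_echo="t2_ms" in metrics):
        records.extend(process_session(session, rules, metrics=metrics,
                                       t2_method=t2_method,
                                       n_baseline_frames=n_baseline_frames))
    table = roistats.assemble_table(records)
    return roistats.apply_exclusions(table, rules)


# ---------------------------------------------------------------------------
# Full pipeline with artifacts on disk
# ---------------------------------------------------------------------------

def run_all(config, out_dir, seed: Optional[int] = None) -> RunManifest:
    """Execute simulate -> fit-t2 -> dce-auc -> roi-stats -> group-stats.

    Writes NIfTI volumes, the measurement table, the statistics tables and a
    JSON manifest (config snapshot, seed, version, per-file SHA-256 hashes).
    Any stage failure aborts with :class:`StageError` naming the stage.
    """
    from . import io as qio

    cfg = load_config(config)
    design, acq, tissues, rules, analysis = _build_specs(cfg, seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg, seed=design.seed, version=__version__,
                           started=_dt.datetime.now().isoformat(timespec="seconds"))

    def _stage(name):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise StageError(name, exc) from exc
        return _Ctx()

    with _stage("simulate"):
        cohort = simulate_cohort(design, acq, tissues)
        qio.save_labels(cohort.labels, out / "labels.nii.gz", acq)
        cohort.truth.to_csv(out / "truth.csv", index=False)
        cohort.animals.to_csv(out / "animals.csv", index=False)
        img_dir = out / "images"
        img_dir.mkdir(exist_ok=True)
        for s in cohort.iter_sessions():
            stem = f"{s.animal_id}_{s.day}"
            qio.save_multi_echo(s.multi_echo, img_dir / f"{stem}_me.nii.gz", acq)
            qio.save_dce(s.dce, img_dir / f"{stem}_dce.nii.gz", acq)

    records: List[dict] = []
    t2_rows: List[pd.DataFrame] = []
    with _stage("fit-t2"):
        t2_dir = out / "t2maps"
        t2_dir.mkdir(exist_ok=True)
        for s in cohort.iter_sessions():
            stem = f"{s.animal_id}_{s.day}"
            stack = qio.load_multi_echo(img_dir / f"{stem}_me.nii.gz",
                                        acq.echo_times_ms)
            t2map = relaxometry.fit_t2_map(stack, cohort.labels,
                                           method=analysis["t2_method"])
            qio.save_volume(np.nan_to_num(t2map.t2_ms, nan=0.0),
                            t2_dir / f"{stem}_t2.nii.gz", acq.voxel_size_um)
            df = relaxometry.roi_t2(t2map, cohort.labels, mad_k=rules.mad_k)
            df.insert(0, "animal_id", s.animal_id)
            df.insert(1, "day", s.day)
            t2_rows.append(df)
        pd.concat(t2_rows).to_csv(out / "t2_roi.csv", index=False)

    with _stage("dce-auc"):
        auc_rows: List[pd.DataFrame] = []
        for s in cohort.iter_sessions(multi_echo=False):
            stem = f"{s.animal_id}_{s.day}"
            series = qio.load_dce(img_dir / f"{stem}_dce.nii.gz",
                                  acq.frame_duration_min, acq.injection_start_min)
            df = dce.roi_auc_stats(series, cohort.labels,
                                   n_baseline_frames=analysis["n_baseline_frames"],
                                   mad_k=rules.mad_k)
            df.insert(0, "animal_id", s.animal_id)
            df.insert(1, "day", s.day)
            auc_rows.append(df)
        pd.concat(auc_rows).to_csv(out / "auc_roi.csv", index=False)

    with _stage("roi-stats"):
        auc_all = pd.concat(auc_rows)
        t2_all = pd.concat(t2_rows)
        meta = cohort.animals
        for (aid, day), sub in auc_all.groupby(["animal_id", "day"]):
            muscle_auc = float(sub["muscle_auc_raw"].iloc[0])
            a = meta[meta.animal_id == aid].iloc[0]
            base = dict(animal_id=aid, sex=a.sex, injury=a.injury,
                        regimen=a.regimen, day=day)
            for r in sub.itertuples():
                if r.roi == "muscle":
                    continue
                records.append(dict(base, roi=r.roi, metric="auc_norm",
                                    value=float(r.auc_norm),
                                    muscle_auc_raw=muscle_auc,
                                    n_voxels=int(r.n_voxels)))
            t2sub = t2_all[(t2_all.animal_id == aid) & (t2_all.day == day)]
            for r in t2sub.itertuples():
                if r.roi == "muscle":
                    continue
                records.append(dict(base, roi=r.roi, metric="t2_ms",
                                    value=float(r.mean) if not r.missing else np.nan,
                                    muscle_auc_raw=muscle_auc,
                                    n_voxels=int(r.n_voxels)))
        table = roistats.assemble_table(records)
        table = roistats.apply_exclusions(table, rules)
        roistats.write_table(table, out / "measurements.csv")

    with _stage("group-stats"):
        clean = roistats.require_clean(table)
        reports = []
        stats_rows = []
        for metric in sorted(clean["metric"].unique()):
            sub = clean[(clean.metric == metric) & (clean.roi == "meninges")]
            res = fit_mixed_model(sub, response="value",
                                  between=("injury", "sex"), within=("day",))
            reports.append(f"== {metric} (meninges) ==\n" + res.summary())
            at = res.anova_table
            at.insert(0, "metric", metric)
            stats_rows.append(at)
        pd.concat(stats_rows).to_csv(out / "group_stats.csv", index=False)
        (out / "group_stats.txt").write_text("\n\n".join(reports) + "\n")

    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest.file_hashes[str(f.relative_to(out))] = _sha256(f)
    manifest.finished = _dt.datetime.now().isoformat(timespec="seconds")
    manifest.write(out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# Simulation studies against the phantom's ground truth
# ---------------------------------------------------------------------------

def _replace_seed(design: DesignSpec, seed: int) -> DesignSpec:
    from dataclasses import replace
    return replace(design, seed=int(seed))


def type_one_error_rate(design: DesignSpec, acq: AcquisitionSpec,
                        tissues: Optional[Sequence[TissueSpec]] = None,
                        n_cohorts: int = 200, roi: str = "meninges",
                        term: str = "injury x day", alpha: float = 0.05,
                        seed: int = 0) -> float:
    """Fraction of independently simulated *null* cohorts whose mixed-model
    omnibus test rejects ``term`` at ``alpha`` for the given ROI's
    muscle-normalized AUC.  ``design`` should carry empty effect maps."""
    rejections = 0
    for i in range(n_cohorts):
        d = _replace_seed(design, seed + i)
        table = run_cohort(d, acq, tissues, metrics=("auc_norm",))
        clean = roistats.require_clean(table)
        sub = clean[(clean.roi == roi) & (clean.metric == "auc_norm")]
        res = fit_mixed_model(sub, between=("injury", "sex"), within=("day",))
        at = res.anova_table
        p = float(at.loc[at.term == term, "p"].iloc[0])
        rejections += p < alpha
    return rejections / n_cohorts


def group_effect_size(table: pd.DataFrame, roi: str = "meninges",
                      day: str = "Day1", metric: str = "auc_norm") -> float:
    """Injured-vs-sham Hedges' g at one (roi, day), sexes pooled."""
    clean = roistats.require_clean(table)
    sub = clean[(clean.roi == roi) & (clean.metric == metric) & (clean.day == day)]
    x = sub.loc[sub.injury == "CHIMERA", "value"].to_numpy(dtype=float)
    y = sub.loc[sub.injury == "Sham", "value"].to_numpy(dtype=float)
    return hedges_g(x, y)


def recovery_study(design: DesignSpec, acq: AcquisitionSpec,
                   tissues: Optional[Sequence[TissueSpec]] = None,
                   n_seeds: int = 50, roi: str = "meninges", day: str = "Day1",
                   seed: int = 0) -> np.ndarray:
    """Run the full image pipeline on ``n_seeds`` independent cohorts and
    return the per-cohort injured-vs-sham Hedges' g at (roi, day)."""
    gs = []
    for i in range(n_seeds):
        d = _replace_seed(design, seed + i)
        table = run_cohort(d, acq, tissues, metrics=("auc_norm",))
        gs.append(group_effect_size(table, roi=roi, day=day))
    return np.asarray(gs)
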