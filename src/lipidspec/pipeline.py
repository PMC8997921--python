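"""End-to-end orchestration: simulate → preprocess → calibrate → select → diagnose.

A :class:`RunConfig` (YAML-serializable) fully determines a run.  One global
seed fans out to fixed per-stage seeds, so any stage can be re-run in
isolation and the whole run is bit-reproducible.  Every artifact is written
under the output directory, and a manifest records the config, its hash,
the seeds and the produced files.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chemometrics import cross_validate, pls_fit, select_components
from .containers import CompositionTable, SpectraSet
from .diagnostics import (DiagnosticsReport, cage_analysis, correlation_matrix,
                          covariance_inflation, explained_variance_curves)
from .preprocessing import (average_replicates, nir_chain, raman_chain,
                            reflectance_to_absorbance, trim)
from .reference import builtin_definitions, feature_table
from .selection import blocks_to_axis_ranges, bottom_up_select, region_retrain
from .synthetic import draw_compositions, synthesize_spectra, salmon_reference_spec

log = logging.getLogger("lipidspec")

FEATURES = ("EPA_DHA", "SFA", "MUFA", "PUFA", "iodine_value")

_STAGE_OFFSETS = {"simulate": 11, "spectra": 23, "preprocess": 37, "calibrate": 53,
                  "select": 71, "diagnose": 89}


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    h = hashlib.sha256(f"{seed}:{_STAGE_OFFSETS[stage]}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    modality: str = "raman"                      # raman | nir_reflectance
    n_samples: int = 300
    n_replicates: int = 3
    seed: int = 0
    targets: list[str] = field(default_factory=lambda: ["C18-1 (n-9)", "C20-5 (n-3)",
                                                        "C22-6 (n-3)"])
    absolute: bool = False                       # model absolute instead of proportional
    folds: int = 7
    a_max: int = 20
    rule: str = "min"                            # component-selection rule
    selection_method: str | None = None          # None | "bottom-up" | "regions"
    block_size: int = 100
    regions: list[tuple[float, float]] = field(default_factory=list)
    selection_tol: float = 0.0
    out_dir: str = "run"

    def config_hash(self) -> str:
        return hashlib.sha256(yaml.safe_dump(asdict(self), sort_keys=True).encode()
                              ).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["regions"] = [tuple(r) for r in raw.get("regions", [])]
        return cls(**raw)


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as e:  # noqa: BLE001 - reported with stage name
                raise StageError(f"stage '{name}' failed: {e}") from e
        return wrapped
    return deco


@_stage("simulate")
def simulate_stage(cfg: RunConfig) -> tuple[CompositionTable, SpectraSet]:
    spec = salmon_reference_spec(n_samples=cfg.n_samples, seed=stage_seed(cfg.seed, "simulate"))
    comps = draw_compositions(spec)
    spectra = synthesize_spectra(comps, modality=cfg.modality,
                                 n_replicates=cfg.n_replicates,
                                 seed=stage_seed(cfg.seed, "spectra"))
    return comps, spectra


@_stage("preprocess")
def preprocess_stage(cfg: RunConfig, spectra: SpectraSet) -> SpectraSet:
    if cfg.modality == "raman":
        processed, _ = raman_chain(spectra)
    else:
        processed = nir_chain(spectra)
    return processed


def _target_vector(name: str, comps: CompositionTable, features: pd.DataFrame,
                   absolute: bool) -> np.ndarray:
    y = features[name].to_numpy() if name in FEATURES else comps.column(name)
    return y * comps.fat.to_numpy() / 100.0 if absolute else y


@_stage("calibrate")
def calibrate_stage(cfg: RunConfig, X: np.ndarray, comps: CompositionTable,
                    features: pd.DataFrame) -> dict[str, dict]:
    out = {}
    a_cap = min(cfg.a_max, X.shape[1])
    for name in cfg.targets:
        y = _target_vector(name, comps, features, cfg.absolute)
        cv = cross_validate(X, y, a_cap, cfg.folds)
        a = select_components(cv, cfg.rule)
        model = pls_fit(X, y, cv.a_max)
        model.chosen_a = a
        out[name] = {"cv": cv, "model": model, "chosen_a": a,
                     "r2cv": float(cv.r2cv[a - 1]), "rmsecv": float(cv.rmsecv[a - 1])}
    return out


@_stage("select")
def select_stage(cfg: RunConfig, X: np.ndarray, axis: np.ndarray,
                 comps: CompositionTable, features: pd.DataFrame) -> dict[str, object]:
    out = {}
    for name in cfg.targets:
        y = _target_vector(name, comps, features, cfg.absolute)
        if cfg.selection_method == "bottom-up":
            res = bottom_up_select(X, y, block_size=cfg.block_size, k=cfg.folds,
                                   a_max=cfg.a_max, tol=cfg.selection_tol)
        else:
            res = region_retrain(X, y, axis, cfg.regions, cfg.a_max, cfg.folds)
        out[name] = res
    return out


@_stage("diagnose")
def diagnose_stage(cfg: RunConfig, X: np.ndarray, comps: CompositionTable,
                   calib: dict[str, dict], raw_block: np.ndarray | None = None
                   ) -> DiagnosticsReport:
    report = DiagnosticsReport()
    blocks = {"references": comps.values.to_numpy(), f"{cfg.modality}_processed": X}
    if raw_block is not None:
        # minimally processed spectra: the bulk water/protein/scatter variance
        # that SNV/EMSC remove is part of what the curves are meant to show
        blocks[cfg.modality] = raw_block
    report.explained_variance = explained_variance_curves(blocks)
    report.reference_correlation = correlation_matrix(comps)
    fa_targets = [t for t in cfg.targets if t not in FEATURES]
    if len(fa_targets) >= 2:
        preds = pd.DataFrame(
            {t: calib[t]["cv"].predictions[:, calib[t]["chosen_a"] - 1] for t in fa_targets},
            index=comps.values.index)
        refs = comps.values[fa_targets]
        report.predicted_correlation = correlation_matrix(preds)
        report.covariance_inflation_ratio = covariance_inflation(preds, refs)
        report.covariance_inflation_cov = covariance_inflation(preds, refs, use="covariance")
    if fa_targets:
        report.cage = cage_analysis(X, comps, a_max=min(cfg.a_max, X.shape[1]),
                                    k=cfg.folds, rule=cfg.rule, fa_names=fa_targets)
    return report


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages and write artifacts + manifest under ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    def save(name: str, writer) -> None:
        path = out / name
        writer(path)
        written.append(name)

    comps, spectra = simulate_stage(cfg)
    save("compositions.csv", comps.to_csv)
    save("spectra_raw.csv", spectra.to_csv)

    processed = preprocess_stage(cfg, spectra)
    save("spectra_processed.csv", processed.to_csv)
    save("preprocessing.yaml",
         lambda p: p.write_text(yaml.safe_dump({"chain": processed.provenance})))
    # align spectra rows with the composition table
    order = [processed.sample_ids.index(s) for s in comps.sample_ids]
    X = processed.intensities[order]

    features = feature_table(comps, builtin_definitions())
    save("features.csv", lambda p: features.to_csv(p))

    calib = calibrate_stage(cfg, X, comps, features)
    summary = pd.DataFrame({t: {"chosen_a": c["chosen_a"], "r2cv": c["r2cv"],
                                "rmsecv": c["rmsecv"]} for t, c in calib.items()}).T
    save("calibration_summary.csv", lambda p: summary.to_csv(p, index_label="target"))
    for t, c in calib.items():
        safe = t.replace(" ", "").replace("(", "").replace(")", "")
        curve = pd.DataFrame({"rmsecv": c["cv"].rmsecv, "r2cv": c["cv"].r2cv},
                             index=pd.RangeIndex(1, c["cv"].a_max + 1, name="components"))
        save(f"cv_{safe}.csv", lambda p, curve=curve: curve.to_csv(p))
        coefs = pd.DataFrame(c["model"].coefficients,
                             index=pd.Index(processed.axis, name="axis"))
        save(f"coefficients_{safe}.csv", lambda p, coefs=coefs: coefs.to_csv(p))

    if cfg.selection_method:
        sel = select_stage(cfg, X, processed.axis, comps, features)
        sel_out = {t: {"blocks_channels": [list(map(int, b)) for b in r.blocks],
                       "blocks_axis": blocks_to_axis_ranges(r.blocks, processed.axis),
                       "rmsecv_trace": [float(v) for v in r.trace],
                       "r2_trace": [float(v) for v in r.r2_trace],
                       "n_selected": int(r.n_selected),
                       "stopping_reason": r.stopping_reason}
                   for t, r in sel.items()}
        save("selection.yaml", lambda p: p.write_text(yaml.safe_dump(sel_out)))

    if cfg.modality == "raman":
        raw_avg = average_replicates(trim(spectra, 500.0, 1800.0))
    else:
        raw_avg = average_replicates(reflectance_to_absorbance(spectra))
    raw_block = raw_avg.intensities[[raw_avg.sample_ids.index(s)
                                     for s in comps.sample_ids]]
    report = diagnose_stage(cfg, X, comps, calib, raw_block)
    save("diagnostics.json", report.to_json)

    manifest = {
        "package": "lipidspec", "version": __version__,
        "seed": cfg.seed,
        "stage_seeds": {s: stage_seed(cfg.seed, s) for s in _STAGE_OFFSETS},
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "outputs": written,
    }
    save("manifest.yaml", lambda p: p.write_text(yaml.safe_dump(manifest, sort_keys=False)))
    return {"comps": comps, "processed": processed, "calibration": calib,
            "report": report, "manifest": manifest, "out_dir": str(out)}
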