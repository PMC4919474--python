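"""End-to-end orchestration: read -> normalize -> fit -> classify -> report.

A :class:`PipelineConfig` gathers every tunable (grid spec, classification
thresholds, expression/epistasis parameters); all thresholds are echoed
into every output header so a report is self-describing, and a config hash
is embedded for provenance.  For fixed inputs and config the pipeline is
byte-deterministic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field

import pandas as pd
import yaml

from .curve_class import (
    ClassThresholds,
    CurveClassResult,
    ScreenSummary,
    assign_curve_class,
    flag_cytotoxicity,
    summarize_screen,
    triage_quality,
)
from .hill import InsufficientDataError, f_test_vs_flat, fit_hill, mask_and_refit
from .sar import cluster_series, series_support
from .screen_model import (
    assemble_titrations,
    compute_plate_controls,
    read_plate_table,
)

log = logging.getLogger("ldscreen")

__all__ = ["PipelineConfig", "run_screen_pipeline", "write_reports"]


@dataclass
class PipelineConfig:
    """Validated pipeline settings.

    Concentrations are handled in molar internally and reported in nM.
    """

    grid_top: float = 46e-6
    grid_ratio: float = 5.0
    grid_points: int = 7
    thresholds: ClassThresholds = field(default_factory=ClassThresholds)
    mask_z_max: float = 3.0
    series_tanimoto: float = 0.7
    expression_percentile: float = 95.0
    rho_min: float = 0.95
    de_alpha: float = 0.001
    k_clusters: int = 5
    epistasis_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.thresholds, dict):
            self.thresholds = ClassThresholds(**self.thresholds)
        if self.grid_points < 2 or self.grid_top <= 0 or self.grid_ratio <= 1:
            raise ValueError("invalid titration grid specification")
        if not 0 < self.series_tanimoto <= 1:
            raise ValueError("series_tanimoto must lie in (0, 1]")
        if not 0 < self.de_alpha < 1 or not 0 < self.epistasis_alpha < 1:
            raise ValueError("alpha levels must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def run_screen_pipeline(
    config: PipelineConfig,
    plate_table_path=None,
    records=None,
    fingerprints=None,
) -> tuple[ScreenSummary, list[CurveClassResult]]:
    """Execute the full screen analysis on a plate table.

    Stages: read wells -> per-plate control normalization -> assemble
    titrations -> 4PL fit with single-outlier masking -> curve-class
    assignment -> cytotoxicity flag -> structural-series support ->
    quality triage -> summary.  Compounds whose titration cannot support a
    fit are classed from their raw points (class 3/4 path).
    """
    t0 = time.time()
    if records is None:
        if plate_table_path is None:
            raise ValueError("provide a plate table path or in-memory records")
        records = read_plate_table(plate_table_path)
    log.info("read %d well records", len(records))

    controls = compute_plate_controls(records)
    titrations = assemble_titrations(records, controls)
    log.info("assembled %d titrations from %d plates", len(titrations), len(controls))

    support = {}
    if fingerprints is not None:
        support = series_support(cluster_series(fingerprints, config.series_tanimoto))

    results = []
    for series in sorted(titrations, key=lambda s: s.compound_id):
        try:
            fit = fit_hill(series)
            series, fit = mask_and_refit(series, fit, z_max=config.mask_z_max)
        except InsufficientDataError:
            raise ValueError(
                f"compound {series.compound_id!r}: too few evaluable points to classify"
            )
        p_flat = f_test_vs_flat(series, fit)
        res = assign_curve_class(fit, series, config.thresholds, p_flat=p_flat)
        toxic = flag_cytotoxicity(series, config.thresholds, fit=fit)
        res = triage_quality(
            res, toxic, support.get(series.compound_id, False), config.thresholds
        )
        results.append(res)

    summary = summarize_screen(results)
    log.info(
        "classified %d compounds in %.1f s (HQ inhibitors: %d)",
        summary.n_compounds,
        time.time() - t0,
        summary.hq_inhibitors,
    )
    return summary, results


def results_frame(results) -> pd.DataFrame:
    rows = []
    for r in results:
        fit = r.fit
        rows.append(
            {
                "compound_id": r.compound_id,
                "curve_class": r.curve_class.value,
                "direction": r.direction.value,
                "efficacy": round(r.efficacy, 3),
                "quality": r.quality.value,
                "cytotoxic": r.cytotoxic,
                "ec50_nM": round(fit.ec50_nm, 4) if fit is not None and fit.converged else "",
                "slope": round(fit.slope, 4) if fit is not None and fit.converged else "",
                "r2": round(fit.r2, 4) if fit is not None and fit.r2 > -1e9 else "",
                "extrapolated": fit.extrapolated if fit is not None and fit.converged else "",
                "p_flat": f"{r.p_flat:.3e}",
            }
        )
    return pd.DataFrame(rows)


def write_reports(
    summary: ScreenSummary, results, out_dir, config: PipelineConfig | None = None
) -> dict:
    """Write curve_classes.csv and summary.json under ``out_dir``.

    summary.json carries the count tree plus the threshold block and
    config hash so every report states the cutoffs that produced it.
    Returns the parsed summary payload.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    results_frame(results).to_csv(os.path.join(out_dir, "curve_classes.csv"), index=False)
    payload = {
        "summary": summary.to_dict(),
        "thresholds": asdict(config.thresholds) if config else asdict(ClassThresholds()),
        "config_hash": config.config_hash if config else None,
    }
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return payload
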