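"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its arguments and a seed, and attaches
the ground truth it planted, so every analysis stage can be tested for
recovery without external data.  The emulated inputs:

* a multi-plate qHTS screen (raw LD / cell signals, solvent and
  positive-control wells, a 46 uM -> ~3 nM 1:5 titration per compound)
  with compounds drawn from the curve-class taxonomy and a configurable
  cytotoxic fraction;
* expression matrices with planted condition-specific gene clusters over a
  low-expression intergenic background whose 95th percentile is set
  exactly;
* replicate TAG group measurements with stated effect sizes;
* enzyme-assay count titrations with a known IC50.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enzyme import AssayTitration
from .expression import ExpressionMatrix
from .hill import HillFit, _response
from .screen_model import (
    Role,
    TitrationSeries,
    WellRecord,
    make_titration_concentrations,
    write_plate_table,
)
from .sar import Fingerprint

__all__ = [
    "STANDARD_GRID",
    "DEFAULT_CLASS_MIX",
    "simulate_titration",
    "simulate_screen",
    "simulate_fingerprints",
    "simulate_expression",
    "simulate_tag",
    "simulate_enzyme_assay",
]

# the screen's dilution design: 46 uM top, 1:5 steps, 7 points (~2.94 nM floor)
STANDARD_GRID = make_titration_concentrations(46e-6, 5.0, 7)

# screen-like composition: most library compounds inactive, single-point
# actives common, complete curves rare
DEFAULT_CLASS_MIX = {
    "1.1": 0.06,
    "1.2": 0.10,
    "2.1": 0.08,
    "2.2": 0.12,
    "3": 0.18,
    "4": 0.46,
}

# raw-signal anchors used when materializing plate wells
_CELL_BASE = 5000.0
_L_NEUTRAL = 2.0  # LD-per-cell at the solvent level
_L_POSITIVE = 0.4  # LD-per-cell at the positive-control level


def _hill_curve(grid, top, bottom, ec50, slope):
    return _response(np.log10(grid), top, bottom, math.log10(ec50), slope)


def simulate_titration(
    params: dict,
    grid: np.ndarray = STANDARD_GRID,
    noise_sd: float = 0.0,
    seed: int = 0,
    compound_id: str = "synthetic",
) -> TitrationSeries:
    """One titration from known Hill parameters plus iid Gaussian noise.

    ``params`` carries top, bottom, ec50 (molar) and slope.  Deterministic
    per seed; ``noise_sd`` is in percent-activity units.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    grid = np.asarray(grid, dtype=float)
    a = _hill_curve(grid, params["top"], params["bottom"], params["ec50"], params["slope"])
    a = a + rng.normal(0.0, noise_sd, size=len(grid)) if noise_sd > 0 else a
    return TitrationSeries(
        compound_id=compound_id,
        concentrations=grid,
        activity=a,
        cell_activity=np.zeros(len(grid)),
        mask=np.zeros(len(grid), dtype=bool),
    )


def _draw_compound(rng, cls: str, activator: bool):
    """Class-consistent generating parameters on the standard grid."""
    c_min, c_max = STANDARD_GRID[0], STANDARD_GRID[-1]
    if cls == "1.1":
        # complete sigmoid, both plateaus comfortably inside the range
        span = rng.uniform(95.0, 120.0)
        log_ec50 = rng.uniform(math.log10(c_min * 30.0), math.log10(c_max / 30.0))
        slope = rng.uniform(1.5, 3.0)
    elif cls == "1.2":
        # complete sigmoid at partial efficacy
        span = rng.uniform(40.0, 70.0)
        log_ec50 = rng.uniform(math.log10(c_min * 30.0), math.log10(c_max / 30.0))
        slope = rng.uniform(1.5, 3.0)
    elif cls == "2.1":
        # high-efficacy curve whose lower plateau stays clearly unreached
        span = rng.uniform(135.0, 165.0)
        log_ec50 = math.log10(c_max / 2.0)
        slope = 1.0
    elif cls == "2.2":
        # partial curve, midpoint at or beyond the top tested concentration
        span = rng.uniform(110.0, 140.0)
        log_ec50 = math.log10(c_max * rng.uniform(1.0, 1.5))
        slope = 1.0
    else:  # classes 3 and 4 are not governed by a sigmoid
        span = 0.0
        log_ec50 = math.log10(c_max)
        slope = 1.0
    sign = 1.0 if activator else -1.0
    return {"top": 0.0, "bottom": sign * span, "ec50": 10.0 ** log_ec50, "slope": slope}


def _true_activity(rng, cls: str, params: dict, grid) -> np.ndarray:
    if cls in ("1.1", "1.2", "2.1", "2.2"):
        return _hill_curve(grid, params["top"], params["bottom"], params["ec50"], params["slope"])
    if cls == "3":
        # erratic, concentration-independent wobble (alternating sign, so no
        # monotone curve can absorb it) plus one strong point at the extreme
        # concentration: real single-point actives look like this
        sign = math.copysign(1.0, params["bottom"]) if params["bottom"] else -1.0
        amp = rng.uniform(8.0, 15.0, size=len(grid))
        a = amp * np.where(np.arange(len(grid)) % 2 == 0, 1.0, -1.0)
        if rng.random() < 0.5:
            a = -a
        a[-1] = sign * rng.uniform(40.0, 70.0)
        return a
    return np.zeros(len(grid))


def simulate_screen(
    n: int,
    class_mix: dict | None = None,
    toxic_frac: float = 0.05,
    noise_sd: float = 0.0,
    seed: int = 0,
    grid: np.ndarray = STANDARD_GRID,
    activator_frac: float = 0.2,
    n_control_wells: int = 16,
    noise_mode: str = "relative",
    out_dir: str | None = None,
) -> tuple[list[WellRecord], pd.DataFrame]:
    """A full synthetic screen: raw plate wells plus the planted truth.

    One plate per grid concentration, each carrying every compound at that
    concentration plus ``n_control_wells`` solvent and positive-control
    wells.  Cytotoxic compounds get a correlated cell-signal collapse.
    Returns (well records, truth table); when ``out_dir`` is given the
    plate table and a truth.json sidecar are also written there.

    ``noise_mode='relative'`` (default) reads ``noise_sd`` as a percent of
    each compound's own response span (assay noise scales with signal;
    curveless compounds use the 0..-100 control window as their span), so
    ``noise_sd=10`` means 10%-of-span noise for every compound.
    ``'absolute'`` applies ``noise_sd`` percent-activity units uniformly.
    """
    class_mix = dict(DEFAULT_CLASS_MIX if class_mix is None else class_mix)
    total = sum(class_mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError("class_mix proportions must sum to 1")
    rng = np.random.default_rng(seed)
    grid = np.asarray(grid, dtype=float)
    classes = list(class_mix)
    probs = np.array([class_mix[c] for c in classes])

    if noise_mode not in ("relative", "absolute"):
        raise ValueError("noise_mode must be 'relative' or 'absolute'")
    truth_rows = []
    activities = np.zeros((n, len(grid)))
    cell_acts = np.zeros((n, len(grid)))
    noise_scale = np.zeros(n)
    n_series = max(1, n // 3)
    for i in range(n):
        cls = classes[int(rng.choice(len(classes), p=probs))]
        activator = cls not in ("4",) and rng.random() < activator_frac
        toxic = bool(rng.random() < toxic_frac)
        params = _draw_compound(rng, cls, activator)
        a = _true_activity(rng, cls, params, grid)
        cell = np.zeros(len(grid))
        if toxic:
            # cell loss follows its own sigmoid anchored at the compound's
            # midpoint (or mid-range for curveless classes)
            tox_ec50 = params["ec50"] if cls in ("1.1", "1.2", "2.1", "2.2") else float(
                np.sqrt(grid[0] * grid[-1])
            )
            cell = _hill_curve(grid, 0.0, -80.0, tox_ec50, 1.0)
        cid = f"CMPD{i:05d}"
        truth_rows.append(
            {
                "compound_id": cid,
                "curve_class": cls,
                "direction": "inactive"
                if cls == "4"
                else ("activator" if activator else "inhibitor"),
                "top": params["top"],
                "bottom": params["bottom"],
                "ec50": params["ec50"],
                "slope": params["slope"],
                "toxic": toxic,
                "series_id": f"S{int(rng.integers(n_series)):05d}",
            }
        )
        activities[i] = a
        cell_acts[i] = cell
        if noise_mode == "absolute":
            noise_scale[i] = 1.0
        else:
            # noise scales with the response span the compound actually
            # realizes in the tested window (assay noise tracks signal);
            # curveless compounds use the 0..-100 control window
            if cls in ("1.1", "1.2", "2.1", "2.2"):
                span = abs(a[-1] - a[0])
            elif cls == "3":
                span = abs(a[-1])
            else:
                span = 0.0
            noise_scale[i] = (span if span > 0 else 100.0) / 100.0

    if noise_sd > 0:
        per_compound_sd = noise_sd * noise_scale[:, None]
        activities = activities + rng.normal(0.0, 1.0, size=activities.shape) * per_compound_sd
        cell_acts = cell_acts + rng.normal(0.0, 1.0, size=cell_acts.shape) * per_compound_sd

    truth = pd.DataFrame(truth_rows).set_index("compound_id")
    records: list[WellRecord] = []
    for j, conc in enumerate(grid):
        plate = f"P{j + 1:02d}"
        for kind, level in (
            (Role.NEUTRAL_CONTROL, _L_NEUTRAL),
            (Role.POSITIVE_CONTROL, _L_POSITIVE),
        ):
            for w in range(n_control_wells):
                jitter = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                ld_per_cell_val = level + jitter * (_L_NEUTRAL - _L_POSITIVE) / 100.0
                records.append(
                    WellRecord(
                        plate_id=plate,
                        well_id=f"{kind.value[:3].upper()}{w:03d}",
                        compound_id="",
                        role=kind,
                        concentration=0.0,
                        ld_signal=max(0.0, ld_per_cell_val) * _CELL_BASE,
                        cell_signal=_CELL_BASE,
                    )
                )
        for i in range(n):
            a = activities[i, j]
            ca = cell_acts[i, j]
            lpc = _L_NEUTRAL + (a / 100.0) * (_L_NEUTRAL - _L_POSITIVE)
            cell_signal = _CELL_BASE * max(0.0, 1.0 + ca / 100.0)
            records.append(
                WellRecord(
                    plate_id=plate,
                    well_id=f"W{i:05d}",
                    compound_id=truth.index[i],
                    role=Role.SAMPLE,
                    concentration=float(conc),
                    ld_signal=max(0.0, lpc) * cell_signal,
                    cell_signal=cell_signal,
                )
            )

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        write_plate_table(records, os.path.join(out_dir, "plate_table.csv"))
        truth.reset_index().to_json(
            os.path.join(out_dir, "truth.json"), orient="records", indent=1
        )
    return records, truth


def simulate_fingerprints(truth: pd.DataFrame, n_bits: int = 128, seed: int = 0):
    """Fingerprints consistent with the truth table's structural series.

    Members of one series share a series-specific bit pattern with a few
    private bit flips (Tanimoto well above 0.7 within a series); distinct
    series get independent random patterns (Tanimoto near the random
    baseline, far below 0.7).
    """
    rng = np.random.default_rng(seed)
    base: dict[str, np.ndarray] = {}
    out = []
    for cid, row in truth.iterrows():
        sid = row["series_id"]
        if sid not in base:
            base[sid] = rng.random(n_bits) < 0.3
        bits = base[sid].copy()
        flips = rng.choice(n_bits, size=2, replace=False)
        bits[flips] = ~bits[flips]
        out.append(Fingerprint(id=cid, bits=tuple(bool(b) for b in bits)))
    return out


def simulate_expression(
    n_genes: int = 200,
    n_intergenic: int = 500,
    conditions=("control", "c1", "c2", "c3", "c4", "c5"),
    k_clusters: int = 5,
    effect: float = 2.0,
    noise_sd: float = 0.25,
    seed: int = 0,
    n_replicates: int = 3,
    intergenic_q95: float = 1.04,
    de_frac: float = 1.0,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Expression matrix with planted condition-specific gene clusters.

    Genic genes get a lognormal baseline (log2 FPKM ~ N(3, 1)); a fraction
    ``de_frac`` of them belong to one of ``k_clusters`` planted clusters,
    each upregulated by ``effect`` log2 units in its own non-control
    condition.  ``noise_sd`` is per-sample log2 noise.  Intergenic features
    form a low-expression background rescaled so its pooled 95th percentile
    equals ``intergenic_q95`` exactly.  Returns the matrix and a per-gene
    truth table (cluster, de_condition).
    """
    if k_clusters < 1:
        raise ValueError("k_clusters must be >= 1")
    conditions = list(conditions)
    if k_clusters > len(conditions) - 1:
        raise ValueError("need at least k_clusters non-control conditions")
    rng = np.random.default_rng(seed)
    samples = []
    for cond in conditions:
        for r in range(1, n_replicates + 1):
            samples.append({"sample": f"{cond}_r{r}", "condition": cond, "replicate": r})
    sheet = pd.DataFrame(samples)
    cols = sheet["sample"].tolist()
    cond_of = sheet.set_index("sample")["condition"]

    gene_ids = [f"gene{i:05d}" for i in range(n_genes)]
    n_de = int(round(de_frac * n_genes))
    cluster = np.full(n_genes, -1)
    cluster[:n_de] = np.arange(n_de) % k_clusters
    base = rng.normal(3.0, 1.0, size=n_genes)
    log2v = np.tile(base[:, None], (1, len(cols)))
    target_cond = {j: conditions[1 + j] for j in range(k_clusters)}
    for g in range(n_genes):
        if cluster[g] >= 0:
            hit = [c == target_cond[cluster[g]] for c in cond_of[cols]]
            log2v[g, np.array(hit)] += effect
    if noise_sd > 0:
        log2v = log2v + rng.normal(0.0, noise_sd, size=log2v.shape)
    genic = np.power(2.0, log2v)

    inter = np.abs(rng.normal(0.0, 0.4, size=(n_intergenic, len(cols))))
    q = np.percentile(inter, 95.0)
    if q > 0:
        inter = inter * (intergenic_q95 / q)
    inter_ids = [f"intergenic{i:05d}" for i in range(n_intergenic)]

    values = pd.DataFrame(
        np.vstack([genic, inter]), index=gene_ids + inter_ids, columns=cols
    )
    kind = pd.Series(
        ["genic"] * n_genes + ["intergenic"] * n_intergenic, index=values.index
    )
    matrix = ExpressionMatrix(values=values, feature_kind=kind, samples=sheet)
    truth = pd.DataFrame(
        {
            "cluster": cluster,
            "de_condition": [
                target_cond[c] if c >= 0 else "" for c in cluster
            ],
        },
        index=gene_ids,
    )
    return matrix, truth


def simulate_tag(groups_spec: dict, seed: int = 0) -> dict:
    """Replicate TAG values per group from (mean, sd, n) specs.

    Normal deviates truncated at zero (resampled), deterministic per seed.
    ``groups_spec`` maps group name -> (mean, sd, n) with mean > 0.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for name, (mean, sd, n) in groups_spec.items():
        if mean <= 0:
            raise ValueError(f"group {name!r} mean must be > 0")
        if sd == 0:
            out[name] = np.full(n, float(mean))
            continue
        vals = rng.normal(mean, sd, size=n)
        while np.any(vals <= 0):
            bad = vals <= 0
            vals[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        out[name] = vals
    return out


def simulate_enzyme_assay(
    ic50: float | None,
    grid: np.ndarray = STANDARD_GRID,
    noise: float = 0.0,
    seed: int = 0,
    enzyme: str = "DGAT1",
    background: float = 200.0,
    span: float = 4000.0,
    slope: float = 1.0,
    n_replicates: int = 3,
) -> AssayTitration:
    """Scintillation-count titration with a known IC50.

    Counts per well: background + span * (1 - inhibition(c)/100), with
    ``noise`` acting as a relative (CV) Gaussian perturbation on each
    count.  ``ic50=None`` simulates a non-inhibited enzyme (flat counts at
    the solvent level); ``enzyme='none'`` simulates the no-enzyme extract
    (counts at background).
    """
    rng = np.random.default_rng(seed)
    grid = np.asarray(grid, dtype=float)
    if enzyme == "none":
        level = np.zeros(len(grid))
    elif ic50 is None:
        level = np.full(len(grid), 1.0)
    else:
        if ic50 <= 0:
            raise ValueError("ic50 must be positive")
        inh = _hill_curve(grid, 0.0, 100.0, ic50, slope)
        level = 1.0 - inh / 100.0

    def noisy(mean, size):
        base = np.full(size, mean)
        if noise > 0:
            base = base * (1.0 + rng.normal(0.0, noise, size=size))
        return np.clip(base, 0.0, None)

    counts = np.vstack(
        [
            noisy(background + (span if enzyme != "none" else 0.0) * lv, n_replicates)
            for lv in level
        ]
    )
    dmso = noisy(background + (span if enzyme != "none" else 0.0), n_replicates)
    bg = noisy(background, n_replicates)
    return AssayTitration(
        enzyme=enzyme,
        concentrations=grid,
        counts=counts,
        dmso_counts=dmso,
        background_counts=bg,
    )
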