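"""Acyltransferase activity-assay reduction: percent inhibition and IC50.

The in vitro esterification assay measures radiolabeled TAG synthesis by
scintillation counting.  Extracts of a quadruple-mutant yeast strain that
cannot make neutral lipids define the background (no-enzyme) count level;
solvent-only (DMSO) reactions define the uninhibited level.  Percent
inhibition interpolates between the two, and the IC50 comes from the
shared four-parameter logistic machinery with the low-concentration
asymptote pinned near zero inhibition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hill import HillFit, fit_hill
from .screen_model import TitrationSeries

__all__ = ["AssayTitration", "percent_inhibition", "fit_ic50", "inhibition_verdict"]


@dataclass
class AssayTitration:
    """One enzyme's inhibitor titration in scintillation counts.

    ``counts`` is (n_concentrations, n_replicates) or 1-d; ``dmso_counts``
    and ``background_counts`` are replicate counts for the solvent-only and
    no-enzyme reference reactions.
    """

    enzyme: str  # "DGAT1" | "DGAT2" | "none"
    concentrations: np.ndarray  # molar, increasing
    counts: np.ndarray
    dmso_counts: np.ndarray
    background_counts: np.ndarray

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.counts = np.atleast_2d(np.asarray(self.counts, dtype=float))
        if self.counts.shape[0] != len(self.concentrations):
            self.counts = self.counts.T
        self.dmso_counts = np.asarray(self.dmso_counts, dtype=float)
        self.background_counts = np.asarray(self.background_counts, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        # a no-enzyme extract legitimately shows no signal over background
        if self.enzyme != "none" and self.dmso_counts.mean() <= self.background_counts.mean():
            raise ValueError(
                "solvent-reference counts do not exceed background: assay uninformative"
            )

    @classmethod
    def from_csv(cls, path, enzyme: str) -> "AssayTitration":
        """Read an assay CSV with columns enzyme, concentration_molar,
        counts, role in {sample, dmso, background}."""
        df = pd.read_csv(path)
        required = {"enzyme", "concentration_molar", "counts", "role"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"assay table missing column(s): {sorted(missing)}")
        df = df[df["enzyme"] == enzyme]
        samples = df[df["role"] == "sample"].sort_values("concentration_molar")
        conc = np.sort(samples["concentration_molar"].unique())
        counts = [
            samples.loc[samples["concentration_molar"] == c, "counts"].to_numpy()
            for c in conc
        ]
        width = min(len(c) for c in counts)
        return cls(
            enzyme=enzyme,
            concentrations=conc,
            counts=np.array([c[:width] for c in counts]),
            dmso_counts=df.loc[df["role"] == "dmso", "counts"].to_numpy(),
            background_counts=df.loc[df["role"] == "background", "counts"].to_numpy(),
        )


def percent_inhibition(counts, dmso_counts, background_counts) -> np.ndarray:
    """Percent inhibition per concentration from raw counts.

    ``100 * (1 - (c - bg) / (dmso - bg))`` with bg and dmso as means: 0 at
    the solvent level, 100 at background; noisy points may fall outside
    [0, 100].  Replicate count columns are averaged per concentration.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    bg = float(np.mean(background_counts))
    dmso = float(np.mean(dmso_counts))
    if dmso <= bg:
        raise ValueError("solvent-reference counts must exceed background")
    per_conc = counts.mean(axis=1) if counts.ndim == 2 else counts
    return 100.0 * (1.0 - (per_conc - bg) / (dmso - bg))


def fit_ic50(titration: AssayTitration, constrain_top: bool = True) -> HillFit:
    """Fit the inhibition titration with the 4PL; the midpoint is the IC50.

    By default the low-concentration asymptote (percent inhibition at zero
    inhibitor) is constrained to [-5, 5]; the high-concentration asymptote
    is free, so partial inhibitors are representable.
    """
    if len(titration.concentrations) < 4:
        raise ValueError("need >= 4 concentrations to fit an IC50")
    inh = percent_inhibition(
        titration.counts, titration.dmso_counts, titration.background_counts
    )
    series = TitrationSeries(
        compound_id=titration.enzyme,
        concentrations=titration.concentrations,
        activity=inh,
        cell_activity=np.zeros_like(inh),
        mask=np.zeros(len(inh), dtype=bool),
    )
    if constrain_top:
        logc = np.log10(titration.concentrations)
        lo = np.array([-5.0, -200.0, logc.min() - 2.0, -np.log(10.0)])
        hi = np.array([5.0, 200.0, logc.max() + 2.0, np.log(10.0)])
        return fit_hill(series, bounds=(lo, hi))
    return fit_hill(series)


def inhibition_verdict(fit: HillFit, min_efficacy: float = 10.0) -> str:
    """"inhibited" when a converged fit realizes a meaningful inhibition
    span within the tested range, else "no_inhibition" (flat titrations,
    e.g. an enzyme the compound does not touch)."""
    if not fit.converged:
        return "no_inhibition"
    realized = abs(
        (fit.bottom - fit.top)
        * (
            1.0 / (1.0 + (fit.ec50 / fit.conc_max) ** fit.slope)
            - 1.0 / (1.0 + (fit.ec50 / fit.conc_min) ** fit.slope)
        )
    )
    return "inhibited" if realized >= min_efficacy else "no_inhibition"
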