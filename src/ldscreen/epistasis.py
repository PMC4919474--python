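"""Whole-animal triglyceride statistics and the epistasis decision rule.

Fly TAG measurements per (genotype, treatment) group are compared by
classical one-way ANOVA followed by Bonferroni-corrected pairwise t tests.
The pharmacogenetic epistasis logic: if combining a drug with a lean
mutant lowers TAG significantly below *both* single perturbations, the two
act in separate pathways ("independent"); if the combination adds nothing
over either single perturbation, they act in the same pathway; anything in
between is inconclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Verdict",
    "TagDataset",
    "EpistasisCall",
    "anova_oneway",
    "bonferroni_posthoc",
    "epistasis_call",
]


class Verdict(str, Enum):
    INDEPENDENT = "independent"
    SAME_PATHWAY = "same_pathway"
    INCONCLUSIVE = "inconclusive"


@dataclass
class TagDataset:
    """Replicate TAG measurements (ug per animal pool) keyed by group.

    A group is a (genotype, treatment, cohort) combination, e.g.
    ("midway", "compound", "adult_male").  Each group needs >= 3 replicate
    pools for the ANOVA designs used here.
    """

    groups: dict  # key -> 1-d array of TAG values

    def __post_init__(self):
        clean = {}
        for k, v in self.groups.items():
            arr = np.asarray(v, dtype=float)
            if arr.ndim != 1 or len(arr) < 3:
                raise ValueError(f"group {k!r} needs >= 3 replicate values")
            if np.any(arr <= 0):
                raise ValueError(f"group {k!r} has non-positive TAG values")
            clean[k] = arr
        self.groups = clean

    @classmethod
    def from_csv(cls, path, cohort=None) -> "TagDataset":
        """Read a TAG table CSV with columns genotype, treatment, cohort,
        tag_ug (extra columns such as batch are ignored)."""
        df = pd.read_csv(path)
        required = {"genotype", "treatment", "cohort", "tag_ug"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"TAG table missing column(s): {sorted(missing)}")
        if cohort is not None:
            df = df[df["cohort"] == cohort]
        groups = {
            (g, t, c): sub["tag_ug"].to_numpy(dtype=float)
            for (g, t, c), sub in df.groupby(["genotype", "treatment", "cohort"])
        }
        return cls(groups=groups)


@dataclass
class EpistasisCall:
    verdict: Verdict
    p_combo_vs_drug: float
    p_combo_vs_mutant: float
    effect_sizes: dict  # group -> mean as percent of reference mean


def anova_oneway(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p-value.

    Degenerate inputs: no variance anywhere (all observations identical)
    gives p = 1; zero within-group variance with distinct means gives
    p -> 0 (F infinite).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    all_vals = np.concatenate(arrays)
    grand = all_vals.mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays)
    df_between = len(arrays) - 1
    df_within = len(all_vals) - len(arrays)
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, 1.0
        return math.inf, 0.0
    f = (ss_between / df_between) / (ss_within / df_within)
    return float(f), float(stats.f.sf(f, df_between, df_within))


def _pooled_within(groups: Mapping) -> tuple[float, int]:
    ss = sum(float(np.sum((np.asarray(v) - np.mean(v)) ** 2)) for v in groups.values())
    df = sum(len(v) for v in groups.values()) - len(groups)
    return ss / df if df > 0 else 0.0, df


def bonferroni_posthoc(
    groups: Mapping, comparisons: Sequence[tuple], welch: bool = False
) -> dict:
    """Bonferroni-adjusted pairwise t tests after a one-way ANOVA.

    By default each pair is tested with the pooled within-group mean square
    from *all* groups (classical post-hoc); ``welch=True`` switches to
    per-pair Welch t tests.  Adjusted p = min(1, m * p) for m comparisons.
    Returns {(a, b): adjusted_p}.
    """
    for a, b in comparisons:
        for g in (a, b):
            if g not in groups:
                raise ValueError(f"comparison references unknown group {g!r}")
    m = len(comparisons)
    out = {}
    ms_within, df_within = _pooled_within(groups)
    for a, b in comparisons:
        xa, xb = np.asarray(groups[a], float), np.asarray(groups[b], float)
        if welch:
            p = float(stats.ttest_ind(xa, xb, equal_var=False).pvalue)
        else:
            if ms_within == 0.0:
                p = 1.0 if xa.mean() == xb.mean() else 0.0
            else:
                se = math.sqrt(ms_within * (1 / len(xa) + 1 / len(xb)))
                t = (xa.mean() - xb.mean()) / se
                p = float(2.0 * stats.t.sf(abs(t), df_within))
        out[(a, b)] = min(1.0, m * p)
    return out


def epistasis_call(
    reference,
    drug_only,
    mutant_only,
    combo,
    alpha: float = 0.05,
    welch: bool = False,
) -> EpistasisCall:
    """Classify a 2x2 perturbation design as independent or same-pathway.

    All four groups (untreated reference, drug alone, mutant alone,
    drug+mutant combination) enter a pooled-variance Bonferroni post-hoc
    comparing the combination against each single perturbation.  Verdicts:

    * ``independent``  — combo mean below both singles, both adjusted p < alpha
      (the combination enhances either single effect: separate pathways);
    * ``same_pathway`` — neither comparison significant (no enhancement);
    * ``inconclusive`` — exactly one significant, or a significant
      difference with the combo not lower.
    """
    groups = {
        "reference": np.asarray(reference, float),
        "drug_only": np.asarray(drug_only, float),
        "mutant_only": np.asarray(mutant_only, float),
        "combo": np.asarray(combo, float),
    }
    for name, arr in groups.items():
        if len(arr) < 3:
            raise ValueError(f"group {name!r} needs >= 3 replicates")
    adj = bonferroni_posthoc(
        groups, [("combo", "drug_only"), ("combo", "mutant_only")], welch=welch
    )
    p_drug = adj[("combo", "drug_only")]
    p_mut = adj[("combo", "mutant_only")]
    combo_lower = (
        groups["combo"].mean() < groups["drug_only"].mean()
        and groups["combo"].mean() < groups["mutant_only"].mean()
    )
    sig_drug, sig_mut = p_drug < alpha, p_mut < alpha
    if sig_drug and sig_mut and combo_lower:
        verdict = Verdict.INDEPENDENT
    elif not sig_drug and not sig_mut:
        verdict = Verdict.SAME_PATHWAY
    else:
        verdict = Verdict.INCONCLUSIVE
    ref_mean = groups["reference"].mean()
    effects = {k: 100.0 * v.mean() / ref_mean for k, v in groups.items()}
    return EpistasisCall(
        verdict=verdict,
        p_combo_vs_drug=p_drug,
        p_combo_vs_mutant=p_mut,
        effect_sizes=effects,
    )
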