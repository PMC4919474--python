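"""Downstream RNA-Seq computations for compound-treatment signatures.

The stages, in the order a run applies them:

1. an expression cutoff set at a percentile (default 95th) of the pooled
   FPKM values over intergenic regions — genes never exceeding it are
   treated as unexpressed noise;
2. replicate QC by pairwise Spearman correlation of log(FPKM+1), dropping
   replicates that correlate poorly with the rest of their condition;
3. per-gene differential-expression calls between two conditions (Welch t
   on log2(FPKM+1) by default; the DE engine is pluggable so calls from an
   external tool can be injected);
4. Z-scored condition-mean signatures of the DE genes partitioned by
   k-means;
5. a paired Wilcoxon signed-rank comparison of DE burden between an active
   and an inactive derivative of the same chemotype;
6. hypergeometric gene-set enrichment with Benjamini-Hochberg correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "expression_cutoff",
    "replicate_qc",
    "de_test",
    "signature_clusters",
    "de_burden_compare",
    "set_enrichment",
]


@dataclass
class ExpressionMatrix:
    """FPKM-like values (features x samples) with feature and sample labels.

    ``feature_kind`` distinguishes genic features from the intergenic
    regions whose signal calibrates the expression cutoff; ``samples`` is a
    sheet with columns (sample, condition, replicate).
    """

    values: pd.DataFrame  # features x samples, nonnegative
    feature_kind: pd.Series  # 'genic' | 'intergenic', indexed like values
    samples: pd.DataFrame  # columns: sample, condition, replicate

    def __post_init__(self):
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be nonnegative")
        if not self.feature_kind.index.equals(self.values.index):
            raise ValueError("feature_kind index must match values index")
        bad = set(self.feature_kind.unique()) - {"genic", "intergenic"}
        if bad:
            raise ValueError(f"unknown feature kind(s): {sorted(bad)}")
        sheet = self.samples.set_index("sample")
        missing = [s for s in self.values.columns if s not in sheet.index]
        if missing:
            raise ValueError(f"sample(s) without condition label: {missing}")

    @property
    def genic(self) -> pd.DataFrame:
        return self.values.loc[self.feature_kind == "genic"]

    @property
    def intergenic(self) -> pd.DataFrame:
        return self.values.loc[self.feature_kind == "intergenic"]

    def condition_of(self) -> pd.Series:
        return self.samples.set_index("sample")["condition"].loc[self.values.columns]

    def subset_samples(self, keep) -> "ExpressionMatrix":
        keep = list(keep)
        return ExpressionMatrix(
            values=self.values[keep],
            feature_kind=self.feature_kind,
            samples=self.samples[self.samples["sample"].isin(keep)].reset_index(drop=True),
        )

    @classmethod
    def from_tsv(cls, matrix_path, sample_sheet_path) -> "ExpressionMatrix":
        """Read a features x samples TSV carrying a ``feature_kind`` column,
        plus a sample sheet TSV with (sample, condition, replicate)."""
        df = pd.read_csv(matrix_path, sep="\t", index_col=0)
        if "feature_kind" not in df.columns:
            raise ValueError("matrix TSV must carry a 'feature_kind' column")
        kind = df.pop("feature_kind")
        sheet = pd.read_csv(sample_sheet_path, sep="\t")
        return cls(values=df.astype(float), feature_kind=kind, samples=sheet)

    def to_tsv(self, matrix_path, sample_sheet_path) -> None:
        out = self.values.copy()
        out.insert(0, "feature_kind", self.feature_kind)
        out.to_csv(matrix_path, sep="\t")
        self.samples.to_csv(sample_sheet_path, sep="\t", index=False)


def expression_cutoff(matrix: ExpressionMatrix, percentile: float = 95.0) -> float:
    """Expression threshold: a percentile of the pooled intergenic signal.

    Uses linear interpolation on the pooled empirical distribution.  Genes
    whose maximum value stays below the returned threshold should be
    dropped as unexpressed before any downstream stage.
    """
    inter = matrix.intergenic.to_numpy().ravel()
    if inter.size == 0:
        raise ValueError("no intergenic features: expression cutoff undefined")
    if (matrix.feature_kind == "intergenic").sum() < 20:
        warnings.warn("fewer than 20 intergenic features; cutoff will be noisy")
    return float(np.percentile(inter, percentile))


def expressed_genes(matrix: ExpressionMatrix, threshold: float) -> pd.Index:
    """Genic features whose maximum FPKM reaches the threshold."""
    genic = matrix.genic
    return genic.index[genic.max(axis=1) >= threshold]


def replicate_qc(
    matrix: ExpressionMatrix, rho_min: float = 0.95, threshold: float | None = None
) -> tuple[list[str], pd.DataFrame]:
    """Drop replicates that correlate poorly within their condition.

    Pairwise Spearman correlations are computed on log(FPKM+1) over
    expressed genic features.  Iteratively, the replicate with the worst
    median within-condition rho below ``rho_min`` is removed, but a
    condition never drops below 2 replicates (its best 2 are kept, with a
    warning).  Returns the retained sample names and the full correlation
    matrix computed on the input.
    """
    cond = matrix.condition_of()
    for c, group in cond.groupby(cond):
        if len(group) < 2:
            raise ValueError(f"condition {c!r} has fewer than 2 replicates")
    if threshold is None:
        genes = matrix.genic.index
    else:
        genes = expressed_genes(matrix, threshold)
    logx = np.log1p(matrix.values.loc[genes])
    rho_full = logx.corr(method="spearman")

    retained = list(matrix.values.columns)
    while True:
        worst_sample, worst_rho = None, rho_min
        for c in cond.unique():
            members = [s for s in retained if cond[s] == c]
            if len(members) <= 2:
                continue
            for s in members:
                others = [m for m in members if m != s]
                med = float(rho_full.loc[s, others].median())
                if med < worst_rho:
                    worst_sample, worst_rho = s, med
        if worst_sample is None:
            break
        retained.remove(worst_sample)

    # conditions stuck at 2 members that still fail the gate: keep best 2
    for c in cond.unique():
        members = [s for s in retained if cond[s] == c]
        meds = {
            s: float(rho_full.loc[s, [m for m in members if m != s]].median())
            for s in members
        }
        if any(m < rho_min for m in meds.values()):
            warnings.warn(
                f"condition {c!r}: replicates remain below rho {rho_min}; "
                "keeping the best 2 available"
            )
    return retained, rho_full


def de_test(
    matrix: ExpressionMatrix,
    cond_a: str,
    cond_b: str,
    alpha: float = 0.001,
    genes=None,
) -> pd.DataFrame:
    """Per-gene differential expression between two conditions.

    Welch's two-sample t on log2(FPKM+1); log2FC is the difference of
    condition means on that scale (A minus B).  Genes with zero variance
    and equal means in both groups get p = 1.  Returns a frame with
    columns (log2fc, p_value, significant).
    """
    cond = matrix.condition_of()
    a_cols = [s for s in matrix.values.columns if cond[s] == cond_a]
    b_cols = [s for s in matrix.values.columns if cond[s] == cond_b]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("both conditions need >= 2 retained replicates")
    sub = matrix.genic if genes is None else matrix.values.loc[genes]
    la = np.log2(sub[a_cols].to_numpy() + 1.0)
    lb = np.log2(sub[b_cols].to_numpy() + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    log2fc = la.mean(axis=1) - lb.mean(axis=1)
    degenerate = ~np.isfinite(p)
    p = np.where(degenerate & (log2fc == 0), 1.0, p)
    p = np.where(degenerate & (log2fc != 0), 0.0, p)
    out = pd.DataFrame(
        {"log2fc": log2fc, "p_value": p, "significant": p < alpha}, index=sub.index
    )
    return out


def signature_clusters(
    matrix: ExpressionMatrix, de_genes, k: int = 5, seed: int = 0
) -> pd.Series:
    """k-means partition of Z-scored condition-mean expression signatures.

    Each DE gene's profile is its mean FPKM per condition, standardized to
    mean 0 / sd 1 across conditions (a Z score), so clusters group genes by
    profile shape rather than expression level.  k-means runs 50 restarts
    from k-means++ seeds under a fixed RNG; labels are canonicalized by
    decreasing cluster size (label 0 = largest).  Genes with zero profile
    variance are excluded with a warning.
    """
    de_genes = list(de_genes)
    if not de_genes:
        raise ValueError("no DE genes to cluster")
    if k > len(de_genes):
        raise ValueError("k exceeds the number of DE genes")
    cond = matrix.condition_of()
    means = matrix.values.loc[de_genes].T.groupby(cond).mean().T
    means = means[sorted(means.columns)]
    mu = means.mean(axis=1)
    sd = means.std(axis=1, ddof=0)
    usable = sd > 0
    if not usable.all():
        warnings.warn(
            f"{int((~usable).sum())} gene(s) with zero variance across conditions "
            "excluded from signature clustering"
        )
    z = means.loc[usable].sub(mu[usable], axis=0).div(sd[usable], axis=0)
    km = KMeans(n_clusters=k, n_init=50, init="k-means++", random_state=seed)
    labels = km.fit_predict(z.to_numpy())
    # canonical labels: 0 = largest cluster; ties broken by old label
    sizes = pd.Series(labels).value_counts()
    order = sorted(sizes.index, key=lambda l: (-sizes[l], l))
    remap = {old: new for new, old in enumerate(order)}
    return pd.Series([remap[l] for l in labels], index=z.index, name="cluster")


def de_burden_compare(abs_log2fc_active, abs_log2fc_inactive) -> float:
    """Two-sided Wilcoxon signed-rank p for paired per-gene |log2FC| vectors.

    Tests whether an active derivative perturbs the transcriptome more
    than its inactive structural sibling, gene by gene.  All-zero
    differences give p = 1.
    """
    a = np.asarray(abs_log2fc_active, dtype=float)
    b = np.asarray(abs_log2fc_inactive, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    diff = a - b
    if np.all(diff == 0):
        return 1.0
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
    return float(res.pvalue)


def set_enrichment(de_genes, universe, gene_sets: dict) -> pd.DataFrame:
    """Hypergeometric over-representation of DE genes in each gene set.

    For a universe of N genes with n DE among them, a set covering K
    universe genes and overlapping the DE list in k is scored with the
    upper-tail hypergeometric p = P(X >= k); Benjamini-Hochberg q-values
    are computed across sets.  Returns a frame indexed by set name with
    columns (k, K, n, N, fold_enrichment, p_value, q_value).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    de = set(de_genes)
    if not de <= universe:
        raise ValueError("de_genes must be a subset of the universe")
    n, N = len(de), len(universe)
    rows = []
    for name, members in gene_sets.items():
        inset = set(members) & universe
        K = len(inset)
        k = len(inset & de)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        fold = (k / n) / (K / N) if (K and n) else float("nan")
        rows.append({"set": name, "k": k, "K": K, "n": n, "N": N,
                     "fold_enrichment": fold, "p_value": p})
    df = pd.DataFrame(rows).set_index("set")
    if len(df):
        df["q_value"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    else:
        df["q_value"] = []
    return df
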