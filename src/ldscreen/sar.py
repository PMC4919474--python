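"""Structural-series support and cross-species activity concordance.

Hit triage asks whether several structurally similar compounds are active
(a singleton active is more likely an artifact).  Similarity is Tanimoto
on user-supplied fingerprint bitvectors; series are single-linkage
components of the similarity graph, because the triage question is only
"are there >= 2 similar actives", not "is this a tight cluster".

The concordance summary asks, per chemotype, what fraction of derivatives
kept their lipid-storage activity across every cell line they were
analyzed in (fly plus mammalian lines).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "Fingerprint",
    "ACTIVITY_CALLS",
    "ACTIVE_CALLS",
    "tanimoto",
    "cluster_series",
    "series_support",
    "cross_species_concordance",
]

# closed vocabulary for per-cell-line activity calls
ACTIVITY_CALLS = ("no_change", "reduced", "absent", "not_analyzed")
ACTIVE_CALLS = frozenset({"reduced", "absent"})


@dataclass(frozen=True)
class Fingerprint:
    """A fixed-length binary structural fingerprint.

    Fingerprints arrive as bitvectors of any origin; the core never parses
    chemical structures (use :func:`fingerprint_from_smiles` when RDKit is
    installed).
    """

    id: str
    bits: tuple

    def __post_init__(self):
        if len(self.bits) == 0:
            raise ValueError("fingerprint must have positive length")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.bits, dtype=bool)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Jaccard similarity of two equal-length bitvectors.

    The all-zero/all-zero pair is defined as similarity 1 (identical,
    if featureless, structures).
    """
    va, vb = a.array, b.array
    if len(va) != len(vb):
        raise ValueError(f"fingerprint length mismatch: {len(va)} vs {len(vb)}")
    union = int(np.sum(va | vb))
    if union == 0:
        return 1.0
    return float(np.sum(va & vb)) / union


def cluster_series(fingerprints, threshold: float = 0.7) -> dict[str, str]:
    """Single-linkage structural series at a Tanimoto threshold.

    Returns compound id -> series label, where a series label is the
    lexicographically smallest member id (deterministic, order-invariant).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    fps = sorted(fingerprints, key=lambda f: f.id)
    n = len(fps)
    if n == 0:
        return {}
    rows, cols = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if tanimoto(fps[i], fps[j]) >= threshold:
                rows.append(i)
                cols.append(j)
    graph = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    _, labels = connected_components(graph, directed=False)
    series: dict[int, list[str]] = {}
    for fp, lab in zip(fps, labels):
        series.setdefault(int(lab), []).append(fp.id)
    out = {}
    for members in series.values():
        leader = min(members)
        for m in members:
            out[m] = leader
    return out


def series_support(series_labels: dict[str, str]) -> dict[str, bool]:
    """Per compound: does its structural series have >= 2 members?"""
    sizes = pd.Series(series_labels).value_counts()
    return {cid: bool(sizes[lab] >= 2) for cid, lab in series_labels.items()}


def cross_species_concordance(
    calls: pd.DataFrame, chemotypes: dict[str, str] | pd.Series
) -> pd.DataFrame:
    """Per-chemotype fraction of derivatives active in *all* analyzed lines.

    ``calls`` is derivatives x cell lines with entries from the closed
    vocabulary (``no_change`` / ``reduced`` / ``absent`` / ``not_analyzed``).
    A derivative counts as concordant-active when every analyzed entry is
    ``reduced`` or ``absent``; ``not_analyzed`` entries are excluded from
    the requirement, and derivatives with no analyzed line at all are
    excluded from the denominator.  Returns a frame indexed by chemotype
    with columns (numerator, denominator, fraction); an empty group yields
    fraction NaN.
    """
    bad = set(np.unique(calls.to_numpy().astype(str))) - set(ACTIVITY_CALLS)
    if bad:
        raise ValueError(f"unknown activity call(s): {sorted(bad)}")
    chemo = pd.Series(chemotypes)
    missing = [d for d in calls.index if d not in chemo.index]
    if missing:
        raise ValueError(f"derivative(s) without chemotype: {missing}")
    rows = []
    for ct in sorted(chemo.unique()):
        members = [d for d in calls.index if chemo[d] == ct]
        num = den = 0
        for d in members:
            entries = calls.loc[d]
            analyzed = entries[entries != "not_analyzed"]
            if len(analyzed) == 0:
                continue
            den += 1
            if all(e in ACTIVE_CALLS for e in analyzed):
                num += 1
        rows.append(
            {
                "chemotype": ct,
                "numerator": num,
                "denominator": den,
                "fraction": num / den if den else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("chemotype")


def fingerprint_from_smiles(compound_id: str, smiles: str, n_bits: int = 1024) -> Fingerprint:
    """Optional adapter: Morgan fingerprint from a SMILES string.

    Requires RDKit; the core API never calls this.
    """
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES for {compound_id!r}: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    return Fingerprint(id=compound_id, bits=tuple(bool(fp.GetBit(i)) for i in range(n_bits)))
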