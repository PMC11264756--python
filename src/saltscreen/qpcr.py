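"""Relative gene expression by the 2^-ΔΔCt method.

For each (sample, gene) with a reference gene measured under the same
conditions (here EF1), replicate Ct values are averaged per condition,
then

    ΔCt  = Ct_target − Ct_reference        (per condition)
    ΔΔCt = ΔCt_treated − ΔCt_control
    fold = 2^(−ΔΔCt)

Fold changes are relative to the control condition (low salinity); the
amplification efficiency is fixed at 2, with no efficiency correction.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = ["ddct", "cluster_order"]

REQUIRED = ("sample", "condition", "gene", "Ct")
CONDITIONS = ("control", "treated")


class MissingReferenceError(ValueError):
    pass


def ddct(ct: pd.DataFrame, reference_gene: str = "EF1") -> pd.DataFrame:
    """Fold-change matrix (samples x genes) from a long Ct table.

    ``ct`` needs columns ``sample, condition, gene, Ct`` with conditions
    ``control`` and ``treated``; replicates are averaged before the Δ
    computations.  Genes missing one condition for a sample are skipped
    with a warning; a missing reference Ct raises.
    """
    for col in REQUIRED:
        if col not in ct.columns:
            raise ValueError(f"Ct table missing column {col!r}")
    bad = set(ct["condition"]) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown conditions {sorted(bad)}; expected {CONDITIONS}")
    if not np.all(np.isfinite(ct["Ct"])) or (ct["Ct"] <= 0).any():
        raise ValueError("Ct values must be finite and > 0")

    mean_ct = ct.groupby(["sample", "condition", "gene"], sort=False)["Ct"].mean()
    folds: dict[str, dict[str, float]] = {}
    for sample in ct["sample"].unique():
        folds[sample] = {}
        ref = {}
        for cond in CONDITIONS:
            try:
                ref[cond] = mean_ct.loc[(sample, cond, reference_gene)]
            except KeyError:
                raise MissingReferenceError(
                    f"no reference ({reference_gene}) Ct for sample {sample!r}, condition {cond!r}"
                ) from None
        genes = ct.loc[ct["sample"] == sample, "gene"].unique()
        for gene in genes:
            if gene == reference_gene:
                continue
            try:
                dct = {
                    cond: mean_ct.loc[(sample, cond, gene)] - ref[cond] for cond in CONDITIONS
                }
            except KeyError:
                warnings.warn(
                    f"gene {gene!r} missing a condition for sample {sample!r}; skipped",
                    stacklevel=2,
                )
                continue
            ddct_val = dct["treated"] - dct["control"]
            folds[sample][gene] = 2.0 ** (-ddct_val)
    out = pd.DataFrame(folds).T
    out.index.name = "sample"
    out.columns.name = "gene"
    return out


def cluster_order(matrix: pd.DataFrame, log2: bool = True) -> list[str]:
    """Row order from hierarchical clustering (Euclidean, average linkage).

    Mirrors the heatmap presentation of expression matrices: clustering
    on log2 fold changes groups co-regulated samples.
    """
    data = np.log2(matrix.to_numpy()) if log2 else matrix.to_numpy()
    if len(matrix) < 3:
        return list(matrix.index)
    link = hierarchy.linkage(pdist(data), method="average")
    order = hierarchy.leaves_list(hierarchy.optimal_leaf_ordering(link, pdist(data)))
    return [matrix.index[i] for i in order]
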