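"""Relative salinity performance, reduction factors and the SPI.

Varieties are phenotyped on two platforms irrigated at low (4 dS/m) and
medium (8 dS/m) salinity across three growth stages (leaf 3, boot,
flowering).  For each variety x stage x parameter cell the *relative
value* is the ratio of medium- to low-platform means; values below 1
quantify the salinity-induced depression.  The *reduction factor* (RF)
of a parameter is its relative value at leaf 3 divided by its relative
value at flowering — RF > 1 means the depression deepened as the crop
developed.

The parameter with the largest consistent, statistically significant RF
(in practice the absorption-based performance index PIabs) becomes the
salt-performance marker, and its mean RF rounded to an integer becomes
the weight n in the salt performance index

    SPI = log10(A) + n * log10(B)

where A and B are the marker's relative values at leaf 3 and at
flowering.  Tolerant varieties hold B near 1 and score near 0; sensitive
varieties collapse at flowering and score strongly negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .groupstats import GroupSample, one_way_anova

__all__ = [
    "PARAMETERS",
    "STAGES",
    "relative_values",
    "reduction_factors",
    "select_marker",
    "spi",
    "spi_correlations",
    "SPIResult",
]

PARAMETERS = ("NPQ", "ETR", "FvFm", "A", "PIabs")
STAGES = ("leaf3", "boot", "flowering")
PLATFORMS = ("low", "medium")


class UndefinedRatioError(ValueError):
    pass


class MarkerSelectionError(ValueError):
    pass


@dataclass(frozen=True)
class SPIResult:
    variety: str
    A_rel: float
    B_rel: float
    n: int
    SPI: float


def _check_panel(panel: pd.DataFrame) -> None:
    required = {"variety", "stage", "platform", "replicate"}
    missing = required - set(panel.columns)
    if missing:
        raise ValueError(f"panel missing columns: {sorted(missing)}")


def relative_values(panel: pd.DataFrame, parameters: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Medium/low ratios of platform means per (variety, stage, parameter).

    Parameters
    ----------
    panel : DataFrame
        Long replicate-level table with columns ``variety, stage,
        platform, replicate`` plus one column per measured parameter and
        optionally ``dry_matter``.

    Returns a tidy frame ``variety, stage, parameter, relative_value``
    with ``dm_gain`` (medium/low dry-matter ratio, stage-independent)
    merged in where dry matter is present.
    """
    _check_panel(panel)
    parameters = parameters or tuple(p for p in PARAMETERS if p in panel.columns)
    means = panel.groupby(["variety", "stage", "platform"], sort=False)[list(parameters)].mean()
    rows = []
    for (variety, stage) in means.index.droplevel("platform").unique():
        try:
            low = means.loc[(variety, stage, "low")]
            med = means.loc[(variety, stage, "medium")]
        except KeyError as exc:
            raise ValueError(f"cell ({variety}, {stage}) missing a platform") from exc
        for p in parameters:
            if low[p] == 0:
                raise UndefinedRatioError(
                    f"low-platform mean is 0 for ({variety}, {stage}, {p}): ratio undefined"
                )
            rows.append(
                {"variety": variety, "stage": stage, "parameter": p, "relative_value": med[p] / low[p]}
            )
    rel = pd.DataFrame(rows)
    if "dry_matter" in panel.columns and panel["dry_matter"].notna().any():
        dm = (
            panel.dropna(subset=["dry_matter"])
            .groupby(["variety", "platform"])["dry_matter"]
            .mean()
            .unstack("platform")
        )
        gain = (dm["medium"] / dm["low"]).rename("dm_gain")
        rel = rel.merge(gain, left_on="variety", right_index=True, how="left")
    return rel


def _stage_contrast_pvalues(
    panel: pd.DataFrame,
    parameters: tuple[str, ...],
    early: str = "leaf3",
    late: str = "flowering",
    min_replicates: int = 3,
) -> pd.DataFrame:
    """Per-variety leaf3-vs-flowering contrast on replicate-level relative values.

    Replicate-level relative value: each medium-platform replicate divided
    by the low-platform cell mean.  The two stage groups are then compared
    with the one-way ANOVA (k = 2, equivalent to a pooled t test).
    """
    rows = []
    low_means = (
        panel[panel["platform"] == "low"]
        .groupby(["variety", "stage"])[list(parameters)]
        .mean()
    )
    med = panel[panel["platform"] == "medium"]
    for variety, grp in med.groupby("variety"):
        for p in parameters:
            groups = []
            for stage in (early, late):
                sub = grp[grp["stage"] == stage]
                if len(sub) < min_replicates:
                    groups = []
                    break
                denom = low_means.loc[(variety, stage), p]
                groups.append(GroupSample(stage, sub[p].to_numpy() / denom))
            if not groups:
                pval = np.nan
            else:
                try:
                    pval = one_way_anova(groups).p
                except ValueError:
                    pval = np.nan
            rows.append({"variety": variety, "parameter": p, "p_contrast": pval})
    return pd.DataFrame(rows)


def reduction_factors(
    rel: pd.DataFrame,
    panel: pd.DataFrame | None = None,
    alpha: float = 0.01,
    early: str = "leaf3",
    late: str = "flowering",
) -> pd.DataFrame:
    """Reduction factor RF = relative value at leaf 3 / at flowering.

    When the replicate-level ``panel`` is supplied, each (variety,
    parameter) RF carries a ``significant`` flag from the stage contrast
    at the given alpha; otherwise the flag is NaN.
    """
    wide = rel.pivot_table(index=["variety", "parameter"], columns="stage", values="relative_value")
    for stage in (early, late):
        if stage not in wide.columns:
            raise ValueError(f"relative values missing stage {stage!r}")
    if (wide[late] == 0).any():
        bad = wide.index[wide[late] == 0].tolist()
        raise UndefinedRatioError(f"flowering relative value is 0 for {bad}: RF undefined")
    out = (wide[early] / wide[late]).rename("RF").reset_index()
    if panel is not None:
        params = tuple(out["parameter"].unique())
        pv = _stage_contrast_pvalues(panel, params, early, late)
        out = out.merge(pv, on=["variety", "parameter"], how="left")
        out["significant"] = out["p_contrast"] <= alpha
    else:
        out["p_contrast"] = np.nan
        out["significant"] = np.nan
    return out


def select_marker(
    rfs: pd.DataFrame,
    consistency_fraction: float = 1.0,
) -> tuple[str, int]:
    """Choose the marker parameter and the SPI weight n.

    Eligible parameters show a significant decline (RF > 1) in at least
    ``consistency_fraction`` of varieties.  Among eligible parameters the
    one with the largest mean RF wins; ties break first on the fraction
    of significant varieties, then lexicographically.  n is the mean RF
    of the chosen parameter rounded to the nearest integer, floored at 1.
    """
    if rfs["parameter"].nunique() < 2 or rfs["variety"].nunique() < 2:
        raise ValueError("need >= 2 parameters and >= 2 varieties")
    stats_rows = []
    for p, grp in rfs.groupby("parameter"):
        declining = (grp["RF"] > 1) & grp["significant"].fillna(False).astype(bool)
        frac = declining.mean()
        stats_rows.append({"parameter": p, "mean_RF": grp["RF"].mean(), "frac_significant": frac})
    table = pd.DataFrame(stats_rows)
    eligible = table[table["frac_significant"] >= consistency_fraction]
    if eligible.empty:
        raise MarkerSelectionError(
            "no parameter declines significantly and consistently across varieties; "
            "lower consistency_fraction or set the marker manually"
        )
    eligible = eligible.sort_values(
        by=["mean_RF", "frac_significant", "parameter"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    best = eligible.iloc[0]
    n = max(1, int(round(best["mean_RF"])))
    return str(best["parameter"]), n


def spi(
    rel: pd.DataFrame,
    marker: str,
    n: int,
    early: str = "leaf3",
    late: str = "flowering",
    log_base: float = 10.0,
) -> pd.DataFrame:
    """Salt performance index per variety: SPI = log(A) + n*log(B).

    A and B are the marker's relative values at the early and late
    stage.  Returns ``variety, A_rel, B_rel, n, SPI`` (``dm_gain``
    carried through when present in ``rel``).
    """
    sub = rel[rel["parameter"] == marker]
    if sub.empty:
        raise ValueError(f"no relative values for marker {marker!r}")
    wide = sub.pivot_table(index="variety", columns="stage", values="relative_value")
    if (wide[[early, late]] <= 0).any().any():
        raise ValueError("non-positive relative value: SPI log undefined")
    log = lambda x: np.log(x) / math.log(log_base)
    out = pd.DataFrame(
        {
            "variety": wide.index,
            "A_rel": wide[early].to_numpy(),
            "B_rel": wide[late].to_numpy(),
            "n": n,
            "SPI": log(wide[early].to_numpy()) + n * log(wide[late].to_numpy()),
        }
    )
    if "dm_gain" in rel.columns:
        gain = rel.drop_duplicates("variety").set_index("variety")["dm_gain"]
        out = out.merge(gain, left_on="variety", right_index=True, how="left")
    return out.reset_index(drop=True)


def spi_correlations(spis: pd.DataFrame, rel: pd.DataFrame | None = None) -> dict:
    """Pearson correlations of SPI with the marker's late relative value and dry-matter gain.

    Returns a report dict with r, R^2 and the two-sided p value for each
    available pairing, plus the scatter table for plotting.
    """
    if len(spis) < 3:
        raise ValueError("need >= 3 varieties for correlation")
    report: dict = {"pairs": {}, "scatter": spis.copy()}

    def corr(x: np.ndarray, y: np.ndarray) -> dict:
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValueError("zero variance: correlation undefined")
        r, p = sps.pearsonr(x, y)
        return {"r": float(r), "r2": float(r) ** 2, "p": float(p)}

    report["pairs"]["SPI_vs_marker_rel"] = corr(
        spis["SPI"].to_numpy(), spis["B_rel"].to_numpy()
    )
    if "dm_gain" in spis.columns and spis["dm_gain"].notna().all():
        report["pairs"]["SPI_vs_dm_gain"] = corr(
            spis["SPI"].to_numpy(), spis["dm_gain"].to_numpy()
        )
    return report
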