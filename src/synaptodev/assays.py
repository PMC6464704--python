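"""Viability, densitometry and palmitoylation (APEGS) read-outs, plus the
thin group-comparison statistics stage.

All quantities here are simple ratios of measured signals:

* cell viability per well as a percentage of the vehicle-treated control
  mean on the same plate;
* immunoblot band density normalized to the β-actin loading control within
  lane, and the within-animal GluN2A/GluN2B ratio;
* the APEGS palmitoylation ratio — summed PEG-shifted band density over the
  non-palmitoylated band (the band matched to the −HA control), divided by
  β-actin from the same lane;
* two-group t-tests, one-way and two-way ANOVA with Tukey post-hoc
  comparisons, with per-group mean ± s.e.m. (sd/√n over independent
  experiments; technical repetitions should be averaged first).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DegenerateInputError, InferenceError, ParameterError

__all__ = [
    "LaneDensitometry",
    "normalize_viability",
    "average_technical_replicates",
    "band_normalize",
    "subunit_ratio",
    "apegs_ratio",
    "compare_groups",
]


@dataclass
class LaneDensitometry:
    """Densitometry of one APEGS lane."""

    shifted_bands: list  # densities of PEG-shifted (palmitoylated) bands
    nonpalm_band: float  # band matched to the −HA control
    actin: float
    minus_ha_reference: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if any(b < 0 for b in self.shifted_bands) or self.nonpalm_band < 0:
            raise ParameterError("band densities must be >= 0")
        if self.actin <= 0:
            raise ParameterError("actin: loading control density must be > 0")


def normalize_viability(plate: pd.DataFrame, vehicle: str = "vehicle") -> dict:
    """Express each well as a percentage of the vehicle-control mean.

    ``plate`` needs columns ``condition`` and ``fluorescence``.  Returns the
    per-well table (with a ``viability_pct`` column) and a per-condition
    summary (mean, s.e.m., n).  By construction the vehicle condition's mean
    is exactly 100%.
    """
    if "condition" not in plate.columns or "fluorescence" not in plate.columns:
        raise ParameterError("plate: needs 'condition' and 'fluorescence' columns")
    veh = plate.loc[plate["condition"] == vehicle, "fluorescence"]
    if veh.empty:
        raise ParameterError(f"vehicle condition '{vehicle}' not present")
    veh_mean = float(veh.mean())
    if veh_mean <= 0:
        raise ParameterError("vehicle mean fluorescence must be > 0")

    wells = plate.copy()
    wells["viability_pct"] = 100.0 * wells["fluorescence"] / veh_mean
    summary = (
        wells.groupby("condition")["viability_pct"]
        .agg(mean="mean", sem=lambda x: x.sem(ddof=1) if len(x) > 1 else float("nan"), n="size")
        .reset_index()
    )
    return {"per_well": wells, "summary": summary, "vehicle_mean": veh_mean}


def average_technical_replicates(
    df: pd.DataFrame, value: str = "value", by: list[str] | None = None
) -> pd.DataFrame:
    """Average technical repetitions so inference runs on independent experiments."""
    by = by or ["condition", "experiment"]
    return df.groupby(by, as_index=False)[value].mean()


def band_normalize(band: float, actin: float) -> float:
    """Band density over the β-actin loading control of the same lane."""
    if actin <= 0:
        raise ParameterError("actin: must be > 0")
    if band < 0:
        raise ParameterError("band: must be >= 0")
    return band / actin


def subunit_ratio(glun2a_density: float, glun2b_density: float, actin: float = 1.0) -> float:
    """Within-lane GluN2A/GluN2B band-density ratio.

    Both bands share the lane's actin control, which cancels in the ratio;
    it is accepted anyway so call sites document the normalization.
    """
    if glun2b_density <= 0:
        raise ParameterError("glun2b_density: must be > 0")
    return band_normalize(glun2a_density, actin) / band_normalize(glun2b_density, actin)


def apegs_ratio(lane: LaneDensitometry) -> dict:
    """Palmitoylation ratio from one APEGS lane.

    palm = sum of PEG-shifted band densities; ratio = (palm / nonpalm) / actin.
    """
    palm = float(sum(lane.shifted_bands))
    if lane.nonpalm_band <= 0:
        raise DegenerateInputError("non-palmitoylated band density is 0; ratio undefined")
    ratio = (palm / lane.nonpalm_band) / lane.actin
    return {"palm": palm, "nonpalm": float(lane.nonpalm_band), "ratio": float(ratio)}


def _group_summary(df: pd.DataFrame, value: str, group: str) -> pd.DataFrame:
    return (
        df.groupby(group)[value]
        .agg(mean="mean", sem=lambda x: x.sem(ddof=1) if len(x) > 1 else float("nan"), n="size")
        .reset_index()
    )


def compare_groups(
    data: pd.DataFrame,
    test: str = "t",
    value: str = "value",
    group: str = "condition",
    factor2: str | None = None,
    paired: bool = False,
    welch: bool = False,
    alpha: float = 0.05,
) -> dict:
    """Group comparison used throughout the figure-level statistics.

    ``test``:

    * ``"t"`` — two-group Student's t-test (``welch=True`` for unequal
      variances, ``paired=True`` for within-cell designs);
    * ``"anova_tukey"`` — one-way ANOVA followed by Tukey's HSD across all
      group pairs;
    * ``"two_way_anova_tukey"`` — two-factor ANOVA (``group`` x ``factor2``,
      with interaction) followed by Tukey's HSD on the factor-combination
      cells.

    Returns the test statistic, degrees of freedom, p-value, a pairwise
    table for Tukey variants, and a per-group mean ± s.e.m. summary.
    """
    from statsmodels.formula.api import ols
    from statsmodels.stats.anova import anova_lm
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    groups = list(data[group].unique())
    if len(groups) < 2:
        raise InferenceError("need at least 2 groups")
    counts = data.groupby(group)[value].size()
    if (counts < 2).any():
        raise InferenceError("need at least 2 replicates per group for inference")

    result: dict = {"test": test, "summary": _group_summary(data, value, group)}

    if test == "t":
        if len(groups) != 2:
            raise InferenceError("t-test requires exactly 2 groups")
        a = data.loc[data[group] == groups[0], value].to_numpy()
        b = data.loc[data[group] == groups[1], value].to_numpy()
        if paired:
            if len(a) != len(b):
                raise InferenceError("paired t-test requires equal group sizes")
            res = sps.ttest_rel(a, b)
            dof = len(a) - 1
        else:
            res = sps.ttest_ind(a, b, equal_var=not welch)
            dof = float(res.df) if hasattr(res, "df") else len(a) + len(b) - 2
        result.update(statistic=float(res.statistic), p=float(res.pvalue), df=dof)
    elif test == "anova_tukey":
        arrays = [data.loc[data[group] == g, value].to_numpy() for g in groups]
        f = sps.f_oneway(*arrays)
        tuk = pairwise_tukeyhsd(data[value].to_numpy(), data[group].to_numpy(), alpha=alpha)
        result.update(
            statistic=float(f.statistic),
            p=float(f.pvalue),
            df=(len(groups) - 1, len(data) - len(groups)),
            pairwise=pd.DataFrame(
                tuk.summary().data[1:], columns=tuk.summary().data[0]
            ),
        )
    elif test == "two_way_anova_tukey":
        if factor2 is None or factor2 not in data.columns:
            raise InferenceError("two-way ANOVA requires factor2")
        d = data.rename(columns={value: "_y", group: "_a", factor2: "_b"})
        model = ols("_y ~ C(_a) * C(_b)", data=d).fit()
        table = anova_lm(model, typ=2)
        cells = (d["_a"].astype(str) + ":" + d["_b"].astype(str)).to_numpy()
        tuk = pairwise_tukeyhsd(d["_y"].to_numpy(), cells, alpha=alpha)
        result.update(
            anova_table=table,
            statistic=float(table.loc["C(_a)", "F"]),
            p=float(table.loc["C(_a)", "PR(>F)"]),
            df=(float(table.loc["C(_a)", "df"]), float(table.loc["Residual", "df"])),
            pairwise=pd.DataFrame(tuk.summary().data[1:], columns=tuk.summary().data[0]),
        )
    else:
        raise InferenceError(f"unknown test '{test}'")
    return result
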