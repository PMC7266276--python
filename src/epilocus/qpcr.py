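"""qPCR quantification: ChIP percent-input and relative expression.

ChIP signals are expressed as a percentage of the total chromatin input used
in each immunoprecipitation:

    percent_input = 100 * dilution_factor * E^(Cq_input - Cq_IP)

with amplification efficiency E = 2 per cycle unless configured otherwise.
Expression is quantified by the double-delta-Cq method, normalised to a
reference gene (GAPDH) and reported as a percent of a calibrator sample:

    relative = 100 * 2^-((Cq_t - Cq_r) - (Cq_t,cal - Cq_r,cal))

Group statistics follow the two-group / multi-group convention: a two-tailed
Student's t-test for two groups, one-way ANOVA with Tukey HSD for more, with
star annotations at P < 0.05 (*), < 0.01 (**) and < 0.001 (***).  IgG
background is reported alongside the specific antibodies, never subtracted.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

AMPLICONS = tuple("abcdefghi")
ANTIBODIES = ("H3Ac", "H3K4Me3", "H3K27Me3", "H3K9Me3", "H3", "IgG")


def percent_input(cq_ip: float, cq_input: float, dilution_factor: float = 1.0,
                  efficiency: float = 2.0) -> float:
    """Percent of input chromatin recovered in the IP for one amplicon."""
    if dilution_factor <= 0:
        raise ValueError("dilution_factor must be positive")
    if not (math.isfinite(cq_ip) and math.isfinite(cq_input)):
        raise ValueError("Cq values must be finite")
    return 100.0 * dilution_factor * efficiency ** (cq_input - cq_ip)


def relative_expression(cq_t: float, cq_r: float, calibrator_cq_t: float,
                        calibrator_cq_r: float) -> float:
    """Expression as percent of the calibrator by the double-delta-Cq method."""
    for v in (cq_t, cq_r, calibrator_cq_t, calibrator_cq_r):
        if not math.isfinite(v):
            raise ValueError("Cq values must be finite")
    ddcq = (cq_t - cq_r) - (calibrator_cq_t - calibrator_cq_r)
    return 100.0 * 2.0 ** (-ddcq)


def quantify_chip(cq_table: pd.DataFrame, efficiency: float = 2.0) -> pd.DataFrame:
    """Apply :func:`percent_input` to a replicate-level Cq table.

    Expects columns amplicon, antibody, replicate, Cq_IP, Cq_input and
    optionally input_dilution_factor (default 1).
    """
    df = cq_table.copy()
    dil = df.get("input_dilution_factor", pd.Series(1.0, index=df.index))
    df["percent_input"] = [
        percent_input(ip, inp, d, efficiency)
        for ip, inp, d in zip(df["Cq_IP"], df["Cq_input"], dil)
    ]
    return df


def quantify_expression(cq_table: pd.DataFrame, calibrator: str) -> pd.DataFrame:
    """Per-replicate relative expression as percent of the calibrator sample.

    Replicates pair by index within sample; the calibrator Cqs are the mean
    over its replicates, so the calibrator's own mean relative expression is
    100 by construction.
    """
    cal = cq_table[cq_table["sample"] == calibrator]
    if cal.empty:
        raise ValueError(f"calibrator {calibrator!r} not in table")
    cal_t, cal_r = cal["Cq_target"].mean(), cal["Cq_reference"].mean()
    df = cq_table.copy()
    df["relative_expression_percent"] = [
        relative_expression(t, r, cal_t, cal_r)
        for t, r in zip(df["Cq_target"], df["Cq_reference"])
    ]
    return df


def stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def group_stats(values_by_condition: dict[str, np.ndarray], paired: bool = False):
    """Compare replicate values across conditions.

    Two groups: two-tailed Student's t-test (paired if requested).  More than
    two: one-way ANOVA followed by Tukey HSD.  Returns a dict with keys
    ``test``, ``p_value`` (overall), ``stars`` and, for >2 groups,
    ``tukey`` (the pairwise result frame).
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_condition.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 replicates")
    if len(groups) == 2:
        a, b = groups.values()
        if paired:
            t, p = stats.ttest_rel(a, b)
        else:
            t, p = stats.ttest_ind(a, b)
        return {"test": "t-test", "statistic": float(t), "p_value": float(p),
                "stars": stars(p)}
    f, p = stats.f_oneway(*groups.values())
    labels = np.concatenate([[name] * len(v) for name, v in groups.items()])
    data = np.concatenate(list(groups.values()))
    tk = pairwise_tukeyhsd(data, labels)
    tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    return {"test": "anova+tukey", "statistic": float(f), "p_value": float(p),
            "stars": stars(p), "tukey": tukey}
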