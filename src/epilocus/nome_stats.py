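"""Summary statistics over NOMe-seq call matrices.

Per-position frequencies and pooled region means for either channel,
Kruskal–Wallis comparison of conditions at each position, detection of
nucleosome-scale accessibility footprints, and a profile-plot export
(per-clone lollipop rows plus group means, the layout used by
methylation-profile plotting tools).

The region mean is the pooled ratio 100 x (methylated calls / informative
calls) over all sites and clones — not a mean of per-clone means — so
partial clones contribute exactly the sites they cover.  Frequencies are
raw: no correction for incomplete bisulfite conversion is applied, which
leaves an upward bias of about (1-p)(1-c_bis) at true methylation p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from epilocus.nome import CloneCallMatrix

LOW_COVERAGE_MIN = 3


@dataclass(frozen=True)
class RegionSummary:
    region: str
    channel: str
    frequencies: pd.Series        # per-position fraction methylated
    region_mean_percent: float
    n_clones: int
    n_informative_calls: int


@dataclass(frozen=True)
class FootprintCall:
    """A consensus protected interval (TSS-relative, half-open)."""

    start: int
    end: int
    clone_support: float

    @property
    def span(self) -> int:
        return self.end - self.start


def region_mean(matrix: CloneCallMatrix, channel: str) -> RegionSummary:
    """Pooled percent methylated (or accessible) over all informative calls."""
    grid = matrix.channel(channel)
    values = grid.to_numpy(dtype=float)
    informative = np.isfinite(values)
    n_inf = int(informative.sum())
    if n_inf == 0:
        raise ValueError("zero informative calls")
    pct = 100.0 * values[informative].sum() / n_inf
    freqs = grid.mean(axis=0, skipna=True)
    return RegionSummary(
        region=matrix.site_map.ref.name,
        channel=channel,
        frequencies=freqs,
        region_mean_percent=float(pct),
        n_clones=len(grid),
        n_informative_calls=n_inf,
    )


def per_position_frequency(matrix: CloneCallMatrix, channel: str) -> pd.DataFrame:
    """Per-site methylated fraction among informative clones.

    Sites with fewer than 3 informative clones are flagged low-coverage (and
    should be dropped from plots); all-missing sites get NaN frequency.
    """
    grid = matrix.channel(channel)
    n_informative = grid.notna().sum(axis=0)
    freq = grid.mean(axis=0, skipna=True)
    return pd.DataFrame(
        {
            "offset": grid.columns,
            "frequency": freq.to_numpy(),
            "n_informative": n_informative.to_numpy(),
            "low_coverage": (n_informative < LOW_COVERAGE_MIN).to_numpy(),
        }
    ).set_index("offset")


def compare_conditions(
    matrices_by_group: dict[str, CloneCallMatrix],
    channel: str = "endogenous",
    alpha: float = 0.05,
    correction: str | None = None,
) -> pd.DataFrame:
    """Per-position Kruskal–Wallis test across condition groups.

    Clone-level binary calls are the replicates at each position (midranks
    with tie correction, scipy's default).  Positions informative in fewer
    than two groups get NaN.  No multiple-testing correction is applied by
    default; pass ``correction="fdr_bh"`` for Benjamini–Hochberg.
    """
    if len(matrices_by_group) < 2:
        raise ValueError("need at least two groups")
    grids = {g: m.channel(channel) for g, m in matrices_by_group.items()}
    for g, grid in grids.items():
        if len(grid) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 passing clones")
    offsets = next(iter(grids.values())).columns
    pvals = []
    for off in offsets:
        samples = []
        for grid in grids.values():
            if off in grid.columns:
                vals = grid[off].dropna().to_numpy()
                if len(vals):
                    samples.append(vals)
        if len(samples) < 2:
            pvals.append(np.nan)
            continue
        pooled = np.concatenate(samples)
        if np.all(pooled == pooled[0]):
            pvals.append(1.0)  # no variation anywhere: no evidence of difference
            continue
        _, p = stats.kruskal(*samples)
        pvals.append(p)
    out = pd.DataFrame({"offset": offsets, "p_value": pvals}).set_index("offset")
    if correction is not None:
        mask = out["p_value"].notna()
        adj = np.full(len(out), np.nan)
        adj[mask.to_numpy()] = multipletests(out.loc[mask, "p_value"], method=correction)[1]
        out["p_adjusted"] = adj
        out["significant"] = out["p_adjusted"] < alpha
    else:
        out["significant"] = out["p_value"] < alpha
    out.loc[out["p_value"].isna(), "significant"] = False
    return out


def _clone_runs(values: np.ndarray, offsets: np.ndarray, min_span_bp: int):
    """Maximal runs of consecutive protected (0) GCH calls with span >= min_span."""
    runs = []
    start = None
    for i, v in enumerate(values):
        if v == 0.0:
            if start is None:
                start = i
        else:
            if start is not None:
                runs.append((start, i - 1))
                start = None
    if start is not None:
        runs.append((start, len(values) - 1))
    return [
        (offsets[a], offsets[b] + 1)
        for a, b in runs
        if offsets[b] + 1 - offsets[a] >= min_span_bp
    ]


def call_footprints(
    matrix: CloneCallMatrix,
    min_span_bp: int = 140,
    min_clone_fraction: float = 0.5,
) -> list[FootprintCall]:
    """Consensus nucleosome-scale protected intervals on the accessibility channel.

    Per clone, maximal runs of consecutive protected GpCs spanning at least
    ``min_span_bp`` (default 140 bp, just under a nucleosome core) are
    collected; GCH sites covered by such runs in at least
    ``min_clone_fraction`` of passing clones are merged into consensus
    intervals, which must themselves reach ``min_span_bp``.
    """
    grid = matrix.channel("accessibility")
    offsets = np.asarray(grid.columns, dtype=int)
    if len(offsets) == 0:
        raise ValueError("no GpC sites in matrix")
    coverage = np.zeros(len(offsets))
    n_clones = len(grid)
    for _, row in grid.iterrows():
        for start, end in _clone_runs(row.to_numpy(dtype=float), offsets, min_span_bp):
            coverage[(offsets >= start) & (offsets < end)] += 1
    frac = coverage / max(n_clones, 1)
    covered = frac >= min_clone_fraction
    calls = []
    i = 0
    while i < len(offsets):
        if covered[i]:
            j = i
            while j + 1 < len(offsets) and covered[j + 1]:
                j += 1
            start, end = int(offsets[i]), int(offsets[j]) + 1
            if end - start >= min_span_bp:
                calls.append(FootprintCall(start, end, float(frac[i : j + 1].mean())))
            i = j + 1
        else:
            i += 1
    return calls


def export_profile(matrix: CloneCallMatrix, channel: str, path) -> pd.DataFrame:
    """Write profile-plot data: one lollipop row per passing clone plus a
    group-mean row, columns at the individual site positions.  Re-reading the
    file reproduces the per-position frequencies exactly."""
    grid = matrix.channel(channel)
    out = grid.copy()
    out.loc["__mean__"] = grid.mean(axis=0, skipna=True)
    out.to_csv(path, sep="\t", na_rep="NA", index_label="clone")
    return out


def read_profile(path) -> tuple[pd.DataFrame, pd.Series]:
    """Read an exported profile back into (clone rows, mean row)."""
    df = pd.read_csv(path, sep="\t", index_col="clone")
    df.columns = df.columns.astype(int)
    mean = df.loc["__mean__"]
    return df.drop(index="__mean__"), mean
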