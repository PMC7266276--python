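"""3D-FISH spot pairing, cis/trans discrimination and proximity classification.

Each nucleus carries up to two chromosome-5 homologs, each hybridised with a
red probe (the gene locus) and a green probe (the 5p subtelomere).  The
pipeline computes 3D Euclidean distances between probe centroids, matches red
and green spots within a nucleus by mutual nearest neighbours (mutual pairs
are the cis pairs, i.e. both probes on the same homolog; leftover cross
pairings are trans), and classifies cis pairs into proximity classes with
cell-line-specific distance thresholds:

* adjacent  — distance strictly below ``adjacent_max_nm``,
* separated — distance strictly above ``separated_min_nm``,
* intermediate — everything in between (boundary values included here).

Thresholds follow nuclear size: 300/665 nm for NB4-LR1 and 340/730 nm for
the smaller-telomere NB4-LR1^SFD subline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

RED = "hTERT_red"
GREEN = "subtel_green"

ADJACENT = "adjacent"
INTERMEDIATE = "intermediate"
SEPARATED = "separated"
CLASSES = (ADJACENT, INTERMEDIATE, SEPARATED)

SPOT_COLUMNS = ["nucleus_id", "channel", "x_um", "y_um", "z_um", "homolog_id"]


@dataclass(frozen=True)
class Thresholds:
    """Proximity-class distance cut-offs (nm) for one cell line."""

    cell_line: str
    adjacent_max_nm: float
    separated_min_nm: float

    def __post_init__(self) -> None:
        if not self.adjacent_max_nm < self.separated_min_nm:
            raise ValueError("adjacent_max_nm must be below separated_min_nm")


THRESHOLDS: dict[str, Thresholds] = {
    "NB4-LR1": Thresholds("NB4-LR1", 300.0, 665.0),
    "NB4-LR1-SFD": Thresholds("NB4-LR1-SFD", 340.0, 730.0),
}


def distance_3d(spot_a, spot_b) -> float:
    """Euclidean distance in nm between two spots given in µm coordinates."""
    a = np.asarray([spot_a["x_um"], spot_a["y_um"], spot_a["z_um"]], dtype=float)
    b = np.asarray([spot_b["x_um"], spot_b["y_um"], spot_b["z_um"]], dtype=float)
    return float(np.linalg.norm(a - b) * 1000.0)


def classify_pair(distance_nm: float, thresholds: Thresholds) -> str:
    """Assign a proximity class; both inequalities are strict, so boundary
    distances fall in the intermediate class."""
    if distance_nm < thresholds.adjacent_max_nm:
        return ADJACENT
    if distance_nm > thresholds.separated_min_nm:
        return SEPARATED
    return INTERMEDIATE


def pair_spots(spots: pd.DataFrame, thresholds: Thresholds | None = None) -> pd.DataFrame:
    """Match red and green spots per nucleus and label cis/trans pairs.

    Mutual-nearest-neighbour matching within each nucleus: a red and a green
    spot form a cis pair when each is the other's nearest opposite-channel
    spot.  All remaining red x green combinations are recorded as trans.
    Nuclei with more than two spots in either channel (aneuploidy or
    segmentation artifacts) are excluded with a logged warning.

    Returns a pair-level table with columns nucleus_id, red_index,
    green_index, cis, distance_nm and, when ``thresholds`` is given,
    proximity_class (cis pairs only; trans pairs get NA).
    """
    rows = []
    n_excluded = 0
    for nucleus_id, nuc in spots.groupby("nucleus_id", sort=True):
        reds = nuc[nuc["channel"] == RED]
        greens = nuc[nuc["channel"] == GREEN]
        if len(reds) > 2 or len(greens) > 2:
            n_excluded += 1
            continue
        if len(reds) == 0 or len(greens) == 0:
            continue
        dmat = np.array(
            [[distance_3d(r, g) for _, g in greens.iterrows()] for _, r in reds.iterrows()]
        )
        nearest_green = dmat.argmin(axis=1)
        nearest_red = dmat.argmin(axis=0)
        for i in range(len(reds)):
            for j in range(len(greens)):
                cis = nearest_green[i] == j and nearest_red[j] == i
                rows.append(
                    {
                        "nucleus_id": nucleus_id,
                        "red_index": reds.index[i],
                        "green_index": greens.index[j],
                        "cis": cis,
                        "distance_nm": dmat[i, j],
                    }
                )
    if n_excluded:
        logger.warning("excluded %d nuclei with >2 spots in a channel", n_excluded)
    pairs = pd.DataFrame(rows, columns=["nucleus_id", "red_index", "green_index", "cis", "distance_nm"])
    if thresholds is not None:
        pairs["proximity_class"] = [
            classify_pair(d, thresholds) if cis else pd.NA
            for d, cis in zip(pairs["distance_nm"], pairs["cis"])
        ]
    return pairs


def cis_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    return pairs[pairs["cis"]].reset_index(drop=True)


def class_percentages(pairs: pd.DataFrame, thresholds: Thresholds) -> pd.Series:
    """Percent of cis pairs in each proximity class (sums to 100 exactly)."""
    cis = cis_pairs(pairs)
    if len(cis) == 0:
        raise ValueError("no cis pairs to classify")
    labels = cis["distance_nm"].map(lambda d: classify_pair(d, thresholds))
    counts = labels.value_counts().reindex(CLASSES, fill_value=0)
    return 100.0 * counts / counts.sum()


def summarize_condition(
    pairs_by_condition: dict[str, pd.DataFrame],
    thresholds_by_condition: dict[str, Thresholds] | Thresholds,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Proximity-class proportions per condition plus pairwise Mann-Whitney tests.

    Proportions are computed over cis pairs only.  For every pair of
    conditions a two-sided Mann-Whitney U test compares the raw cis-pair
    distance distributions.  Returns (proportions table, tests table).
    """
    rows, tests = [], []
    names = list(pairs_by_condition)
    for name in names:
        thr = (
            thresholds_by_condition[name]
            if isinstance(thresholds_by_condition, dict)
            else thresholds_by_condition
        )
        cis = cis_pairs(pairs_by_condition[name])
        if len(cis) == 0:
            raise ValueError(f"condition {name!r} has zero cis pairs")
        pct = class_percentages(pairs_by_condition[name], thr)
        rows.append({"condition": name, "n_cis_pairs": len(cis), **pct.to_dict()})
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            da = cis_pairs(pairs_by_condition[a])["distance_nm"]
            db = cis_pairs(pairs_by_condition[b])["distance_nm"]
            stat, p = stats.mannwhitneyu(da, db, alternative="two-sided")
            tests.append({"condition_a": a, "condition_b": b, "U": stat, "p_value": p,
                          "significant": p < 0.05})
    return pd.DataFrame(rows), pd.DataFrame(tests)
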