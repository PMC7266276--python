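"""Packaged condition profiles for the synthetic generators.

A :class:`ConditionProfile` describes one NOMe-seq condition (a cell line and
treatment): per-site endogenous CpG methylation probabilities, nucleosome
footprints blocking GpC accessibility, the M.CviPI labelling efficiency
(default 0.95) and the bisulfite conversion rate (default 0.99).

Packaged profiles are calibrated so that the *raw* pooled estimate produced
by the pipeline — which inherits a small upward bias of (1-p)(1-c_bis) from
incomplete conversion — reproduces the study-scale region means:

==========================  ========  =====================
profile                     region    pooled raw percent
==========================  ========  =====================
LR1_untreated               I         23.7
SFD_untreated               I         14.7
LR1_ATRA                    I          9.4
SFD_ATRA_ATO                I          2.2
LR1_untreated_regionII      II        89.1
SFD_untreated_regionII      II        33.5
==========================  ========  =====================

Region-I profiles carry the dual-domain promoter structure (a hypomethylated
proximal zone near the TSS, a more methylated distal zone upstream of -200 bp)
via a distal:proximal probability ratio; region II is uniform.

FISH profiles give the adjacent/intermediate/separated mixture per condition
(adjacent ~37% untreated NB4-LR1 rising to ~55% after ATRA; ~43% in
NB4-LR1-SFD, unchanged by ATRA), with class distance supports that respect
the cell line's classification thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from epilocus.contexts import SiteMap
from epilocus.fish3d import THRESHOLDS, Thresholds

MIN_FOOTPRINT_BP = 120  # nucleosome-scale; smaller intervals need an explicit override

DOMAIN_BOUNDARY = {"region_I": -200, "region_II": None}


@dataclass(frozen=True)
class ConditionProfile:
    """Generator parameters for one NOMe-seq condition.

    ``cpg_meth_prob`` may be a scalar probability, a ``{tss_offset: prob}``
    mapping, or None, in which case per-site probabilities are derived from
    ``pooled_target_percent`` (see :meth:`site_meth_probs`).
    """

    label: str
    region: str = "region_I"
    cpg_meth_prob: float | dict[int, float] | None = None
    pooled_target_percent: float | None = None
    distal_ratio: float = 4.0
    footprint_model: tuple[tuple[int, int, float], ...] = ()
    open_gpc_prob: float = 0.8
    e_gpc: float = 0.95
    c_bis: float = 0.99
    n_clones: int | None = None  # None: drawn uniformly in 10..20 at generation
    allow_short_footprints: bool = False

    def __post_init__(self) -> None:
        for p in (self.open_gpc_prob, self.e_gpc, self.c_bis):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if isinstance(self.cpg_meth_prob, float) and not 0.0 <= self.cpg_meth_prob <= 1.0:
            raise ValueError("cpg_meth_prob must lie in [0, 1]")
        for start, end, occ in self.footprint_model:
            if not 0.0 <= occ <= 1.0:
                raise ValueError("footprint occupancy must lie in [0, 1]")
            if end - start < MIN_FOOTPRINT_BP and not self.allow_short_footprints:
                raise ValueError(
                    f"footprint [{start}, {end}) shorter than {MIN_FOOTPRINT_BP} bp; "
                    "set allow_short_footprints=True to override"
                )

    def with_(self, **kwargs) -> "ConditionProfile":
        return replace(self, **kwargs)

    def site_meth_probs(self, site_map: SiteMap) -> np.ndarray:
        """Endogenous methylation probability for every HCG site (by site order).

        When calibrated from ``pooled_target_percent`` t, the site mean is
        solved so the raw pooled estimate equals t:
        mean(p) = (t/100 - (1 - c_bis)) / c_bis, split across the proximal and
        distal domains with p_distal = distal_ratio * p_proximal where the
        region has a domain boundary.
        """
        offsets = site_map.offsets(site_map.hcg)
        if isinstance(self.cpg_meth_prob, dict):
            return np.array([self.cpg_meth_prob[int(o)] for o in offsets], dtype=float)
        if self.cpg_meth_prob is not None:
            return np.full(len(offsets), float(self.cpg_meth_prob))
        if self.pooled_target_percent is None:
            raise ValueError("profile defines neither cpg_meth_prob nor pooled_target_percent")
        p_mean = (self.pooled_target_percent / 100.0 - (1.0 - self.c_bis)) / self.c_bis
        if not 0.0 <= p_mean <= 1.0:
            raise ValueError("pooled target unreachable at this conversion rate")
        boundary = DOMAIN_BOUNDARY.get(self.region)
        if boundary is None or self.distal_ratio == 1.0:
            return np.full(len(offsets), p_mean)
        distal = offsets < boundary
        n, n_dist = len(offsets), int(distal.sum())
        n_prox = n - n_dist
        if n_dist == 0 or n_prox == 0:
            return np.full(n, p_mean)
        p_prox = p_mean * n / (n_prox + self.distal_ratio * n_dist)
        p_dist = self.distal_ratio * p_prox
        if p_dist > 1.0:  # saturate the distal domain, keep the pooled mean exact
            p_dist = 1.0
            p_prox = (n * p_mean - n_dist) / n_prox
        probs = np.where(distal, p_dist, p_prox)
        return probs


@dataclass(frozen=True)
class FishProfile:
    """Mixture of proximity classes and distance supports for one condition."""

    label: str
    cell_line: str
    p_adjacent: float
    p_intermediate: float
    p_separated: float
    class_distance_params: dict[str, tuple[float, float]] | None = None  # nm, uniform (lo, hi)
    n_nuclei: int | None = None  # None: drawn uniformly in 150..200
    trans_rate: float = 0.1
    nucleus_radius_um: float = 3.0
    z_step_um: float = 0.37

    def __post_init__(self) -> None:
        weights = (self.p_adjacent, self.p_intermediate, self.p_separated)
        if any(w < 0 for w in weights) or abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("class weights must be non-negative and sum to 1")
        if not 0.0 <= self.trans_rate <= 1.0:
            raise ValueError("trans_rate must lie in [0, 1]")
        for lo, hi in self.distance_params().values():
            if lo < 0 or hi <= lo:
                raise ValueError("degenerate distance parameters")

    @property
    def thresholds(self) -> Thresholds:
        return THRESHOLDS[self.cell_line]

    def distance_params(self) -> dict[str, tuple[float, float]]:
        """Per-class uniform distance supports; defaults keep a 10 nm margin
        inside the cell line's thresholds so class identity survives rounding."""
        if self.class_distance_params is not None:
            return self.class_distance_params
        thr = self.thresholds
        return {
            "adjacent": (60.0, thr.adjacent_max_nm - 10.0),
            "intermediate": (thr.adjacent_max_nm + 10.0, thr.separated_min_nm - 10.0),
            "separated": (thr.separated_min_nm + 10.0, 1400.0),
        }

    def with_(self, **kwargs) -> "FishProfile":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PatientProfile:
    """One patient/donor group of the RRBS-style beta matrix."""

    group: str
    n_samples: int
    proximal_beta: tuple[float, float]  # (mean, sd)
    distal_beta: tuple[float, float]
    missing_rate: float = 0.1

    def __post_init__(self) -> None:
        for mean, sd in (self.proximal_beta, self.distal_beta):
            if not 0.0 <= mean <= 1.0 or sd <= 0:
                raise ValueError("beta mean must lie in [0,1] with positive sd")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")


_CORE_FOOTPRINT = ((-200, 1, 0.35),)  # TSS-proximal nucleosome, partly occupied

NOME_PROFILES: dict[str, ConditionProfile] = {
    "LR1_untreated": ConditionProfile(
        "LR1_untreated", "region_I", pooled_target_percent=23.7,
        footprint_model=_CORE_FOOTPRINT, open_gpc_prob=0.75,
    ),
    "SFD_untreated": ConditionProfile(
        "SFD_untreated", "region_I", pooled_target_percent=14.7,
        footprint_model=((-200, 1, 0.40),), open_gpc_prob=0.75,
    ),
    "LR1_ATRA": ConditionProfile(
        "LR1_ATRA", "region_I", pooled_target_percent=9.4,
        footprint_model=((-200, 1, 0.90),), open_gpc_prob=0.60,
    ),
    "SFD_ATRA": ConditionProfile(
        # ATRA alone changes neither methylation nor accessibility in SFD cells
        "SFD_ATRA", "region_I", pooled_target_percent=14.7,
        footprint_model=((-200, 1, 0.40),), open_gpc_prob=0.75,
    ),
    "SFD_ATO": ConditionProfile(
        # distal-only hypomethylation, accessibility unchanged (no printed mean)
        "SFD_ATO", "region_I", pooled_target_percent=8.0, distal_ratio=1.5,
        footprint_model=((-200, 1, 0.40),), open_gpc_prob=0.75,
    ),
    "SFD_ATRA_ATO": ConditionProfile(
        "SFD_ATRA_ATO", "region_I", pooled_target_percent=2.2,
        footprint_model=((-200, 1, 0.85),), open_gpc_prob=0.55,
    ),
    "LR1_untreated_regionII": ConditionProfile(
        "LR1_untreated_regionII", "region_II", pooled_target_percent=89.1,
        distal_ratio=1.0, footprint_model=((-5300, -5100, 0.4),), open_gpc_prob=0.7,
    ),
    "SFD_untreated_regionII": ConditionProfile(
        "SFD_untreated_regionII", "region_II", pooled_target_percent=33.5,
        distal_ratio=1.0, footprint_model=((-5300, -5100, 0.4),), open_gpc_prob=0.7,
    ),
}

FISH_PROFILES: dict[str, FishProfile] = {
    # untreated NB4-LR1: adjacent ~37%, separated ~63%
    "LR1_untreated_fish": FishProfile("LR1_untreated_fish", "NB4-LR1", 0.37, 0.0, 0.63),
    # 7 days ATRA: adjacent rises to ~55%, separated falls to ~45%
    "LR1_ATRA_fish": FishProfile("LR1_ATRA_fish", "NB4-LR1", 0.55, 0.0, 0.45),
    # NB4-LR1-SFD: adjacent ~43%, unchanged by ATRA
    "SFD_untreated_fish": FishProfile("SFD_untreated_fish", "NB4-LR1-SFD", 0.43, 0.12, 0.45),
    "SFD_ATRA_fish": FishProfile("SFD_ATRA_fish", "NB4-LR1-SFD", 0.43, 0.12, 0.45),
}

PATIENT_PROFILES: tuple[PatientProfile, ...] = (
    PatientProfile("diagnosis", 18, proximal_beta=(0.05, 0.05), distal_beta=(0.60, 0.05)),
    PatientProfile("remission", 8, proximal_beta=(0.05, 0.05), distal_beta=(0.20, 0.05)),
    PatientProfile("healthy_CD34", 8, proximal_beta=(0.05, 0.05), distal_beta=(0.20, 0.05)),
    PatientProfile("healthy_promyelocyte", 8, proximal_beta=(0.05, 0.05), distal_beta=(0.25, 0.05)),
)
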