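"""End-to-end convenience workflows over the packaged condition profiles.

Each function generates synthetic data from a packaged profile, runs the full
estimation pipeline on it, and returns the headline estimate — the study-scale
quantities: region methylation means, enzyme-efficiency and conversion-rate QC,
and FISH proximity-class proportions.
"""

from __future__ import annotations

import pandas as pd

from epilocus import fish3d, nome_stats
from epilocus.contexts import classify_contexts
from epilocus.nome import build_matrix
from epilocus.profiles import FISH_PROFILES, NOME_PROFILES, ConditionProfile
from epilocus.regions import make_reference
from epilocus.simulate import fully_open_control, simulate_clones, simulate_fish

REFERENCE_SEED = 7  # packaged fixture sequences


def nome_region_mean(
    profile: str | ConditionProfile,
    n_clones: int,
    seed: int,
    channel: str = "endogenous",
    treated: bool = True,
    qc_threshold: float = 0.95,
) -> float:
    """Simulate clones from a profile and return the pooled percent for a channel."""
    prof = NOME_PROFILES[profile] if isinstance(profile, str) else profile
    ref = make_reference(prof.region, REFERENCE_SEED)
    sim = simulate_clones(ref, prof, treated=treated, seed=seed, n_clones=n_clones)
    matrix = build_matrix(sim.records, classify_contexts(ref), treated=treated,
                          qc_threshold=qc_threshold)
    return nome_stats.region_mean(matrix, channel).region_mean_percent


def enzyme_efficiency_estimate(n_clones: int, seed: int) -> float:
    """Accessibility-channel percent on a fully open control region: the
    M.CviPI labelling-efficiency estimate."""
    prof = fully_open_control(NOME_PROFILES["LR1_untreated"])
    return nome_region_mean(prof, n_clones, seed, channel="accessibility")


def conversion_rate_estimate(n_clones: int, seed: int) -> float:
    """Mean per-clone bisulfite conversion rate (percent) on untreated clones."""
    prof = NOME_PROFILES["LR1_untreated"]
    ref = make_reference(prof.region, REFERENCE_SEED)
    sim = simulate_clones(ref, prof, treated=False, seed=seed, n_clones=n_clones)
    matrix = build_matrix(sim.records, classify_contexts(ref), treated=False)
    return 100.0 * float(matrix.qc["conversion_rate"].mean())


def fish_condition_summary(profile: str, n_nuclei: int, seed: int) -> pd.Series:
    """Simulate nuclei, pair spots and return proximity-class percentages."""
    prof = FISH_PROFILES[profile]
    spots = simulate_fish(prof, seed=seed, n_nuclei=n_nuclei)
    pairs = fish3d.pair_spots(spots)
    return fish3d.class_percentages(pairs, prof.thresholds)


def fish_adjacent_percent(profile: str, n_nuclei: int, seed: int) -> float:
    return float(fish_condition_summary(profile, n_nuclei, seed)["adjacent"])
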