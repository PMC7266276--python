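"""Synthetic generators for every input of the pipeline.

All generators are pure functions of (profile, seed): the same arguments give
byte-identical output.  Each dataset carries ground-truth labels (per-site
methylation and accessibility states, homolog identity, group membership, the
simulated percent-input or expression truth) so downstream estimators can be
scored against what the generator actually did.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from epilocus import fish3d
from epilocus.contexts import classify_contexts
from epilocus.methclust import BetaMatrix
from epilocus.profiles import ConditionProfile, FishProfile, PatientProfile
from epilocus.regions import ReferenceRegion


# ---------------------------------------------------------------------------
# NOMe-seq bisulfite clones
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CloneSimulation:
    """Bisulfite-converted clone sequences plus the generator truth.

    ``endog_truth`` (clones x HCG sites) and ``access_truth`` / ``enzyme_truth``
    (clones x GCH sites) are 0/1 DataFrames indexed by clone id with
    TSS-offset columns.  Truth is recorded before bisulfite chemistry, so it
    is the quantity the caller should compare noiseless pipeline calls to.
    """

    ref: ReferenceRegion
    profile: ConditionProfile
    treated: bool
    records: tuple[SeqRecord, ...]
    endog_truth: pd.DataFrame
    access_truth: pd.DataFrame
    enzyme_truth: pd.DataFrame


def simulate_clones(
    ref: ReferenceRegion,
    profile: ConditionProfile,
    treated: bool,
    seed: int,
    n_clones: int | None = None,
) -> CloneSimulation:
    """Simulate bisulfite-converted top-strand amplicon clones.

    Per clone: (1) endogenous methylation is drawn per HCG site from the
    profile's site probabilities (GCG sites receive the same endogenous
    behaviour but are ambiguous downstream); (2) if ``treated``, nucleosome
    footprints occupy each clone with their occupancy probability and block
    GpC accessibility, open GCH sites are accessible with ``open_gpc_prob``
    and accessible sites are labelled by M.CviPI with efficiency ``e_gpc``;
    (3) bisulfite chemistry converts every unmethylated cytosine to T with
    probability ``c_bis`` while methylated cytosines stay C.
    """
    if profile.region != ref.name:
        raise ValueError(f"profile targets {profile.region!r} but reference is {ref.name!r}")
    sm = classify_contexts(ref)
    rng = np.random.default_rng(seed)
    if n_clones is None:
        n_clones = profile.n_clones if profile.n_clones is not None else int(rng.integers(10, 21))

    hcg = np.array(sm.hcg, dtype=int)
    gch = np.array(sm.gch, dtype=int)
    gcg = np.array(sm.gcg, dtype=int)
    hcg_probs = profile.site_meth_probs(sm)
    gcg_prob = float(hcg_probs.mean()) if len(hcg_probs) else 0.0

    # footprint intervals in sequence indices (half-open), validated in-region
    fp_idx = []
    for start, end, occ in profile.footprint_model:
        if start < ref.tss_start or end > ref.tss_end:
            raise ValueError(f"footprint [{start}, {end}) outside {ref.name} "
                             f"[{ref.tss_start}, {ref.tss_end})")
        fp_idx.append((ref.index_of(start), ref.index_of(end), occ))

    endog = rng.random((n_clones, len(hcg))) < hcg_probs  # (clones, HCG)
    gcg_meth = rng.random((n_clones, len(gcg))) < gcg_prob

    protected = np.zeros((n_clones, len(gch)), dtype=bool)
    for i0, i1, occ in fp_idx:
        occupied = rng.random(n_clones) < occ
        in_fp = (gch >= i0) & (gch < i1)
        protected |= occupied[:, None] & in_fp[None, :]
    accessible = ~protected & (rng.random((n_clones, len(gch))) < profile.open_gpc_prob)
    enzyme = accessible & (rng.random((n_clones, len(gch))) < profile.e_gpc)
    if not treated:
        accessible = np.zeros_like(accessible)
        enzyme = np.zeros_like(enzyme)

    seq_arr = np.frombuffer(ref.sequence.encode(), dtype="S1")
    c_positions = np.flatnonzero(seq_arr == b"C")
    meth = np.zeros((n_clones, len(seq_arr)), dtype=bool)
    if len(hcg):
        meth[:, hcg] = endog
    if len(gcg):
        meth[:, gcg] = gcg_meth
    if treated and len(gch):
        meth[:, gch] = enzyme

    converts = rng.random((n_clones, len(c_positions))) < profile.c_bis
    records = []
    treated_tag = "yes" if treated else "no"
    for k in range(n_clones):
        clone = seq_arr.copy()
        to_t = c_positions[converts[k] & ~meth[k, c_positions]]
        clone[to_t] = b"T"
        name = f"clone{k:03d}|{profile.label}|treated={treated_tag}"
        records.append(SeqRecord(Seq(clone.tobytes().decode()), id=name, description=""))

    clone_ids = [r.id.split("|")[0] for r in records]
    return CloneSimulation(
        ref=ref,
        profile=profile,
        treated=treated,
        records=tuple(records),
        endog_truth=pd.DataFrame(endog.astype(int), index=clone_ids, columns=sm.offsets(hcg)),
        access_truth=pd.DataFrame(accessible.astype(int), index=clone_ids, columns=sm.offsets(gch)),
        enzyme_truth=pd.DataFrame(enzyme.astype(int), index=clone_ids, columns=sm.offsets(gch)),
    )


def fully_open_control(profile: ConditionProfile) -> ConditionProfile:
    """A copy of ``profile`` with no footprints and every GpC accessible —
    the control used to estimate the M.CviPI labelling efficiency."""
    return profile.with_(footprint_model=(), open_gpc_prob=1.0)


# ---------------------------------------------------------------------------
# 3D-FISH spot tables
# ---------------------------------------------------------------------------

def simulate_fish(profile: FishProfile, seed: int, n_nuclei: int | None = None) -> pd.DataFrame:
    """Simulate a nucleus-by-nucleus 3D spot table.

    Each nucleus holds two chromosome-5 homologs placed at well-separated
    territory centres inside a spherical nucleus; each homolog carries one
    red (gene locus) and one green (subtelomere) spot whose separation is
    drawn from the proximity-class mixture (classes allocated to homologs by
    stratified exact-count assignment, so the mixture weights are encoded
    exactly and only detection dropout and pairing perturb the recovered
    proportions).  z coordinates are quantised to
    the optical-section spacing (0.37 µm) without distorting the pair
    distance, by drawing the z displacement on the section grid first.  With
    probability ``trans_rate`` only one homolog of a nucleus is detected
    (territory out of the imaged stack), so cross-homolog (trans) pairings
    arise only in fully detected nuclei.  The ``homolog_id`` and
    ``true_class`` columns are generator truth for validating recovery.
    """
    rng = np.random.default_rng(seed)
    if n_nuclei is None:
        n_nuclei = profile.n_nuclei if profile.n_nuclei is not None else int(rng.integers(150, 201))
    params = profile.distance_params()
    weights = np.array([profile.p_adjacent, profile.p_intermediate, profile.p_separated])
    zs = profile.z_step_um
    R = profile.nucleus_radius_um

    # stratified class assignment: the mixture weights are the condition being
    # encoded, so homolog classes hit them exactly (largest-remainder rounding)
    # and only detection dropout and pairing add noise to the recovered
    # proportions.  Classes are shuffled across homolog slots.
    total = 2 * n_nuclei
    counts = np.floor(weights * total).astype(int)
    remainder = weights * total - counts
    for i in np.argsort(-remainder)[: total - counts.sum()]:
        counts[i] += 1
    class_slots = np.repeat(np.array(fish3d.CLASSES), counts)
    rng.shuffle(class_slots)

    def territory_centres():
        while True:
            pts = rng.uniform(-R, R, size=(2, 3))
            # distinct chromosome territories: keep centres far enough apart
            # that a probe pair never reaches across to the other homolog
            if all(np.linalg.norm(p) <= R for p in pts) and np.linalg.norm(pts[0] - pts[1]) >= 2.5:
                return pts

    rows = []
    for n in range(n_nuclei):
        centres = territory_centres()
        detected = [0, 1]
        if rng.random() < profile.trans_rate:
            detected = [int(rng.integers(2))]
        for h in detected:
            cls = str(class_slots[2 * n + h])
            lo, hi = params[cls]
            d_um = rng.uniform(lo, hi) / 1000.0
            kmax = int(d_um / zs)
            dz = zs * rng.integers(-kmax, kmax + 1)
            r_xy = np.sqrt(max(d_um**2 - dz**2, 0.0))
            theta = rng.uniform(0, 2 * np.pi)
            cx, cy, cz = centres[h]
            cz = zs * round(cz / zs)  # red spot sits on the section grid
            red = (cx, cy, cz)
            green = (cx + r_xy * np.cos(theta), cy + r_xy * np.sin(theta), cz + dz)
            for channel, (x, y, z) in ((fish3d.RED, red), (fish3d.GREEN, green)):
                rows.append(
                    {"nucleus_id": f"nuc{n:04d}", "channel": channel,
                     "x_um": x, "y_um": y, "z_um": z, "homolog_id": h, "true_class": cls}
                )
    return pd.DataFrame(rows, columns=fish3d.SPOT_COLUMNS + ["true_class"])


# ---------------------------------------------------------------------------
# Patient-style beta matrix
# ---------------------------------------------------------------------------

def _beta_draw(rng, mean, sd, size):
    nu = mean * (1 - mean) / sd**2 - 1
    if nu <= 0:
        raise ValueError("beta dispersion too large for the given mean")
    return rng.beta(mean * nu, (1 - mean) * nu, size=size)


def simulate_patient_matrix(
    profiles: tuple[PatientProfile, ...],
    n_cpg_proximal: int = 30,
    n_cpg_distal: int = 30,
    seed: int = 0,
) -> BetaMatrix:
    """Simulate a samples x CpG beta-value matrix with dual-domain structure.

    Columns are named by TSS offset (proximal CpGs tile -199..+150, distal
    CpGs tile -600..-201); each group's values are Beta-distributed around
    its per-domain mean, and cells are masked missing at ``missing_rate``.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two groups")
    if n_cpg_proximal + n_cpg_distal == 0:
        raise ValueError("need at least one CpG column")
    rng = np.random.default_rng(seed)
    prox_off = np.linspace(-199, 150, n_cpg_proximal).astype(int) if n_cpg_proximal else np.array([], int)
    dist_off = np.linspace(-600, -201, n_cpg_distal).astype(int) if n_cpg_distal else np.array([], int)
    columns = [f"pos_{o}" for o in np.concatenate([dist_off, prox_off])]
    domains = pd.Series(
        ["distal"] * n_cpg_distal + ["proximal"] * n_cpg_proximal, index=columns
    )
    blocks, groups, names = [], [], []
    for prof in profiles:
        vals = np.empty((prof.n_samples, len(columns)))
        vals[:, :n_cpg_distal] = _beta_draw(rng, *prof.distal_beta, (prof.n_samples, n_cpg_distal))
        vals[:, n_cpg_distal:] = _beta_draw(rng, *prof.proximal_beta, (prof.n_samples, n_cpg_proximal))
        if prof.missing_rate > 0:
            vals[rng.random(vals.shape) < prof.missing_rate] = np.nan
        blocks.append(vals)
        groups += [prof.group] * prof.n_samples
        names += [f"{prof.group}_{i:02d}" for i in range(prof.n_samples)]
    values = pd.DataFrame(np.vstack(blocks), index=names, columns=columns)
    return BetaMatrix(values=values, sample_groups=pd.Series(groups, index=names), domains=domains)


# ---------------------------------------------------------------------------
# qPCR Cq tables
# ---------------------------------------------------------------------------

def simulate_chip_qpcr(
    truth_percent_input: dict[tuple[str, str], float],
    dilution_factor: float = 1.0,
    efficiency: float = 2.0,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
    cq_input_base: float = 28.0,
) -> pd.DataFrame:
    """Generate ChIP-qPCR Cq values whose percent-input inverts to the truth.

    ``truth_percent_input`` maps (amplicon, antibody) to the percent-of-input
    signal to encode.  Cq noise (sd in cycles) is added independently to the
    IP and input wells; at ``noise_sd=0`` the percent-input formula recovers
    the truth exactly.
    """
    if not 1.0 < efficiency <= 2.0:
        raise ValueError("efficiency must lie in (1, 2]")
    rng = np.random.default_rng(seed)
    rows = []
    for (amplicon, antibody), pct in truth_percent_input.items():
        if pct <= 0:
            raise ValueError("truth percent_input must be positive")
        delta = np.log(pct / (100.0 * dilution_factor)) / np.log(efficiency)
        for rep in range(n_replicates):
            cq_in = cq_input_base + rng.normal(0, noise_sd) if noise_sd else cq_input_base
            cq_ip = cq_input_base - delta + (rng.normal(0, noise_sd) if noise_sd else 0.0)
            rows.append({"amplicon": amplicon, "antibody": antibody, "replicate": rep,
                         "Cq_IP": cq_ip, "Cq_input": cq_in,
                         "input_dilution_factor": dilution_factor,
                         "truth_percent_input": pct})
    return pd.DataFrame(rows)


def simulate_expression_qpcr(
    truth_relative_percent: dict[str, float],
    calibrator: str,
    efficiency: float = 2.0,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
    cq_reference_base: float = 20.0,
    calibrator_delta: float = 5.0,
) -> pd.DataFrame:
    """Generate qRT-PCR Cq values (target + reference gene) encoding relative
    expression as a percent of the calibrator sample."""
    if not 1.0 < efficiency <= 2.0:
        raise ValueError("efficiency must lie in (1, 2]")
    if calibrator not in truth_relative_percent:
        raise ValueError("calibrator sample must appear in the truth dict")
    rng = np.random.default_rng(seed)
    rows = []
    for sample, pct in truth_relative_percent.items():
        if pct <= 0:
            raise ValueError("truth relative expression must be positive")
        delta = calibrator_delta - np.log(pct / 100.0) / np.log(efficiency)
        for rep in range(n_replicates):
            cq_ref = cq_reference_base + (rng.normal(0, noise_sd) if noise_sd else 0.0)
            cq_t = cq_ref + delta + (rng.normal(0, noise_sd) if noise_sd else 0.0)
            rows.append({"sample": sample, "replicate": rep, "Cq_target": cq_t,
                         "Cq_reference": cq_ref, "truth_relative_percent": pct})
    return pd.DataFrame(rows)
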