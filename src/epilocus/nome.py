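"""Single-molecule NOMe-seq calling from bisulfite clone sequences.

Turns bisulfite-converted amplicon clones plus their reference into per-clone,
per-site calls in two channels:

* endogenous — HCG sites: C read as C means methylated, T means unmethylated;
* accessibility — GCH sites of M.CviPI-treated clones: C means the GpC was
  accessible to the enzyme, T means protected (nucleosome-bound);

GCG sites are ambiguous (both signals overlap) and never enter a channel.
GCH sites of untreated control clones feed a control channel used only to
confirm endogenous CpG levels.  Cytosines in neither context (other_C) are
unmethylated in vivo, so the fraction read as T is the per-clone bisulfite
conversion rate; clones below the QC threshold (default 0.95) are retained
but excluded from downstream statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align

from epilocus.contexts import GCG, GCH, HCG, OTHER_C, SiteMap
from epilocus.regions import ReferenceRegion

logger = logging.getLogger(__name__)

METHYLATED = "methylated"
UNMETHYLATED = "unmethylated"
AMBIGUOUS = "ambiguous"
MISSING = "missing"

DEFAULT_QC_THRESHOLD = 0.95
MAX_MISMATCH_FRACTION = 0.05
MAX_LENGTH_DEVIATION = 0.10


@dataclass(frozen=True)
class AlignedClone:
    """Per-reference-position clone bases ('N' where unobserved)."""

    clone_id: str
    bases: np.ndarray          # dtype '<U1', length == len(ref)
    n_mismatches: int
    n_aligned: int
    failed: bool
    reason: str | None = None


def _bisulfite_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    aligner.match_score = 1
    aligner.mismatch_score = -1
    return aligner


def align_clone(ref: ReferenceRegion, clone_seq: str, clone_id: str = "clone") -> AlignedClone:
    """Bisulfite-aware positional mapping of a clone onto the reference.

    A reference C read as T in the clone is not a mismatch (bisulfite
    conversion); any other disagreement is.  Equal-length clones are mapped
    positionally; length mismatches within ±10% fall back to a gapped global
    alignment.  Clones with more than 5% true mismatches over aligned
    positions are marked failed (reported, not fatal).
    """
    clone_seq = clone_seq.upper()
    n = len(ref)
    if abs(len(clone_seq) - n) > MAX_LENGTH_DEVIATION * n:
        return AlignedClone(clone_id, np.full(n, "N"), 0, 0, True, "length deviation > 10%")
    bases = np.full(n, "N", dtype="<U1")
    if len(clone_seq) == n:
        bases[:] = list(clone_seq)
    else:
        aln = _bisulfite_aligner().align(ref.sequence, clone_seq)[0]
        for (rs, re), (qs, qe) in zip(*aln.aligned):
            bases[rs:re] = list(clone_seq[qs:qe])
    ref_arr = np.array(list(ref.sequence))
    observed = bases != "N"
    agree = bases == ref_arr
    bis_ok = (ref_arr == "C") & (bases == "T")
    mismatch = observed & ~agree & ~bis_ok
    n_mm, n_obs = int(mismatch.sum()), int(observed.sum())
    if n_obs == 0 or n_mm > MAX_MISMATCH_FRACTION * n_obs:
        logger.warning("clone %s rejected: %d/%d non-bisulfite mismatches", clone_id, n_mm, n_obs)
        return AlignedClone(clone_id, bases, n_mm, n_obs, True, "mismatch fraction > 5%")
    return AlignedClone(clone_id, bases, n_mm, n_obs, False)


def call_sites(site_map: SiteMap, aligned: AlignedClone, treated: bool) -> pd.DataFrame:
    """Per-site calls for one clone.

    Returns a tidy frame with columns offset, context, channel, state.
    Channels: HCG -> endogenous; GCH -> accessibility (treated) or control
    (untreated); other_C -> qc; GCG sites are always state=ambiguous and
    belong to no analysis channel.  Unobserved bases propagate as missing.
    """
    rows = []
    gch_channel = "accessibility" if treated else "control"
    for idx in site_map.all_c:
        ctx = site_map.context[idx]
        base = aligned.bases[idx]
        offset = site_map.ref.tss_start + idx
        if ctx == GCG:
            rows.append((offset, ctx, "none", AMBIGUOUS))
            continue
        channel = {HCG: "endogenous", GCH: gch_channel, OTHER_C: "qc"}[ctx]
        if base == "C":
            state = METHYLATED
        elif base == "T":
            state = UNMETHYLATED
        else:
            state = MISSING
        rows.append((offset, ctx, channel, state))
    return pd.DataFrame(rows, columns=["offset", "context", "channel", "state"])


def clone_qc(calls: pd.DataFrame, threshold: float = DEFAULT_QC_THRESHOLD) -> tuple[float, bool]:
    """Per-clone bisulfite conversion rate and QC verdict.

    conversion_rate = other_C sites read as T / other_C sites observed;
    the threshold is inclusive (rate >= threshold passes).  With no
    observable other_C site the rate is undefined (NaN) and QC fails.
    """
    qc = calls[calls["channel"] == "qc"]
    observed = qc["state"].isin([METHYLATED, UNMETHYLATED])
    n_obs = int(observed.sum())
    if n_obs == 0:
        logger.warning("no observable other_C sites; conversion rate undefined, QC failed")
        return float("nan"), False
    n_converted = int((qc["state"] == UNMETHYLATED).sum())
    rate = n_converted / n_obs
    return rate, rate >= threshold


def _state_to_float(state: str) -> float:
    return {METHYLATED: 1.0, UNMETHYLATED: 0.0}.get(state, np.nan)


@dataclass
class CloneCallMatrix:
    """Per-clone x per-site call grids for one amplicon.

    ``endogenous`` covers HCG sites for all clones; ``accessibility`` covers
    GCH sites (the control channel of untreated clones is stored under the
    same grid with ``treated=False``).  Values are 1 (methylated/accessible),
    0 (unmethylated/protected) or NaN (missing).  ``qc`` has one row per
    clone: conversion_rate, qc_pass, aligned, n_mismatches.  Failing clones
    are retained in the grids but excluded by the ``*_passing`` accessors.
    """

    site_map: SiteMap
    treated: bool
    endogenous: pd.DataFrame
    accessibility: pd.DataFrame
    qc: pd.DataFrame
    qc_threshold: float = DEFAULT_QC_THRESHOLD
    channel_of_gch: str = field(init=False)

    def __post_init__(self) -> None:
        self.channel_of_gch = "accessibility" if self.treated else "control"

    @property
    def passing_clones(self) -> pd.Index:
        return self.qc.index[self.qc["qc_pass"]]

    @property
    def endogenous_passing(self) -> pd.DataFrame:
        return self.endogenous.loc[self.passing_clones]

    @property
    def accessibility_passing(self) -> pd.DataFrame:
        return self.accessibility.loc[self.passing_clones]

    def channel(self, name: str, passing_only: bool = True) -> pd.DataFrame:
        if name == "endogenous":
            return self.endogenous_passing if passing_only else self.endogenous
        if name in ("accessibility", "control"):
            if name != self.channel_of_gch:
                raise ValueError(
                    f"matrix holds the {self.channel_of_gch!r} GCH channel, not {name!r}"
                )
            return self.accessibility_passing if passing_only else self.accessibility
        raise ValueError(f"unknown channel {name!r}")

    def to_tsv(self, calls_path, qc_path=None) -> None:
        wide = pd.concat(
            {
                "endogenous": self.endogenous,
                self.channel_of_gch: self.accessibility,
            },
            axis=1,
        )
        wide.columns = [f"{off}:{chan}" for chan, off in wide.columns]
        wide.to_csv(calls_path, sep="\t", na_rep="NA", index_label="clone")
        if qc_path is not None:
            self.qc.to_csv(qc_path, sep="\t", na_rep="NA", index_label="clone")


def build_matrix(
    clones,
    site_map: SiteMap,
    treated: bool,
    qc_threshold: float = DEFAULT_QC_THRESHOLD,
) -> CloneCallMatrix:
    """Align, call and QC a set of clones into a rectangular call matrix.

    ``clones`` is an iterable of Bio.SeqRecord or (id, sequence) pairs.
    Clones failing alignment or conversion QC stay in the matrix with
    ``qc_pass=False`` but are excluded from the passing accessors; if every
    clone fails, an error lists the per-clone conversion rates.
    """
    ref = site_map.ref
    endo_offsets = list(site_map.offsets(site_map.hcg))
    gch_offsets = list(site_map.offsets(site_map.gch))
    endo_rows, gch_rows, qc_rows, ids = [], [], [], []
    for clone in clones:
        if hasattr(clone, "seq"):
            cid, seq = clone.id.split("|")[0], str(clone.seq)
        else:
            cid, seq = clone
        aligned = align_clone(ref, seq, cid)
        ids.append(cid)
        if aligned.failed:
            endo_rows.append([np.nan] * len(endo_offsets))
            gch_rows.append([np.nan] * len(gch_offsets))
            qc_rows.append({"conversion_rate": np.nan, "qc_pass": False,
                            "aligned": False, "n_mismatches": aligned.n_mismatches})
            continue
        calls = call_sites(site_map, aligned, treated)
        rate, qc_pass = clone_qc(calls, qc_threshold)
        by_offset = calls.set_index("offset")["state"]
        endo_rows.append([_state_to_float(by_offset[o]) for o in endo_offsets])
        gch_rows.append([_state_to_float(by_offset[o]) for o in gch_offsets])
        qc_rows.append({"conversion_rate": rate, "qc_pass": qc_pass,
                        "aligned": True, "n_mismatches": aligned.n_mismatches})
    qc = pd.DataFrame(qc_rows, index=pd.Index(ids, name="clone"))
    if not qc["qc_pass"].any():
        rates = ", ".join(f"{i}={r:.3f}" for i, r in qc["conversion_rate"].items())
        raise ValueError(f"all clones failed QC (conversion rates: {rates})")
    return CloneCallMatrix(
        site_map=site_map,
        treated=treated,
        endogenous=pd.DataFrame(endo_rows, index=qc.index, columns=endo_offsets),
        accessibility=pd.DataFrame(gch_rows, index=qc.index, columns=gch_offsets),
        qc=qc,
        qc_threshold=qc_threshold,
    )
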