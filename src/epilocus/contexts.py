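"""Trinucleotide context classification of reference cytosines.

NOMe-seq reads two signals off one bisulfite-converted molecule, separated by
the local context of each cytosine (H = A/C/T):

* ``HCG`` — a CpG not preceded by G: carries endogenous CpG methylation;
* ``GCH`` — a GpC not followed by G: carries M.CviPI accessibility signal;
* ``GCG`` — both a GpC and a CpG: the two signals are confounded, so these
  sites are flagged ambiguous and excluded from both channels;
* ``other_C`` — all remaining cytosines: unmethylated in vivo, so their
  conversion to T measures per-clone bisulfite conversion efficiency.

The partition is mutually exclusive and exhaustive over reference cytosines;
terminal cytosines with an undefined neighbour fall into ``other_C``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from epilocus.regions import ReferenceRegion

HCG = "HCG"
GCH = "GCH"
GCG = "GCG"
OTHER_C = "other_C"


@dataclass(frozen=True)
class SiteMap:
    """Context assignment for every cytosine of a reference region.

    Site lists hold 0-based sequence indices; ``offsets`` maps an index to its
    TSS-relative position.
    """

    ref: ReferenceRegion
    hcg: tuple[int, ...]
    gch: tuple[int, ...]
    gcg: tuple[int, ...]
    other_c: tuple[int, ...]
    context: dict[int, str] = field(repr=False)

    def offsets(self, indices) -> np.ndarray:
        return np.asarray(indices, dtype=int) + self.ref.tss_start

    @property
    def all_c(self) -> tuple[int, ...]:
        return tuple(sorted(self.context))


def classify_contexts(ref: ReferenceRegion) -> SiteMap:
    """Assign every cytosine of ``ref`` exactly one trinucleotide context."""
    seq = ref.sequence
    if len(seq) < 3:
        raise ValueError("reference must be at least 3 bp")
    if set(seq) - set("ACGT"):
        raise ValueError("reference contains non-ACGT characters")
    hcg, gch, gcg, other = [], [], [], []
    for i, base in enumerate(seq):
        if base != "C":
            continue
        if i == 0 or i == len(seq) - 1:
            other.append(i)
            continue
        prev_g = seq[i - 1] == "G"
        next_g = seq[i + 1] == "G"
        if prev_g and next_g:
            gcg.append(i)
        elif next_g:
            hcg.append(i)
        elif prev_g:
            gch.append(i)
        else:
            other.append(i)
    context = {i: HCG for i in hcg}
    context.update({i: GCH for i in gch})
    context.update({i: GCG for i in gcg})
    context.update({i: OTHER_C for i in other})
    return SiteMap(
        ref=ref,
        hcg=tuple(hcg),
        gch=tuple(gch),
        gcg=tuple(gcg),
        other_c=tuple(other),
        context=context,
    )
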