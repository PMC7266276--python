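"""Reference amplicon regions with TSS-relative coordinates.

Two promoter regions are modelled: ``region_I`` spans -650..+150 bp relative
to the transcription start site (800 bp, the core promoter with its dual
proximal/distal methylation domains) and ``region_II`` spans -5500..-4900 bp
(600 bp, a putative upstream enhancer).  Packaged sequences are synthetic,
with CpG-island-like dinucleotide densities, so no genome download is needed;
coordinates are 0-based half-open internally, and a site's TSS offset is
``tss_start + index``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

REGION_COORDS = {
    "region_I": (-650, 150),
    "region_II": (-5500, -4900),
}

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ReferenceRegion:
    """An amplicon reference sequence anchored to TSS-relative coordinates."""

    name: str
    tss_start: int
    tss_end: int
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != self.tss_end - self.tss_start:
            raise ValueError(
                f"sequence length {len(self.sequence)} != span "
                f"{self.tss_end - self.tss_start}"
            )
        if set(self.sequence) - set("ACGT"):
            raise ValueError("sequence must contain only A/C/G/T")

    def __len__(self) -> int:
        return len(self.sequence)

    def offset_of(self, index: int) -> int:
        """TSS-relative offset of a 0-based sequence index."""
        return self.tss_start + index

    def index_of(self, offset: int) -> int:
        """0-based sequence index of a TSS-relative offset."""
        return offset - self.tss_start


def make_reference(name: str, seed: int, gc_content: float = 0.6) -> ReferenceRegion:
    """Generate a deterministic synthetic reference for ``region_I`` or ``region_II``.

    The sequence is drawn i.i.d. with GC-rich composition (CpG-island-like) and
    regenerated from successive substreams until it is informative in both
    NOMe channels (>= 10 HCG and >= 20 GCH sites), so the result is still a
    pure function of (name, seed, gc_content).
    """
    from epilocus.contexts import classify_contexts

    if name not in REGION_COORDS:
        raise ValueError(f"unknown region name {name!r}; expected one of {sorted(REGION_COORDS)}")
    start, end = REGION_COORDS[name]
    length = end - start
    p = np.array([(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2])
    for attempt in range(100):
        name_key = sorted(REGION_COORDS).index(name)
        rng = np.random.default_rng([seed, name_key, attempt])
        seq = "".join(_BASES[rng.choice(4, size=length, p=p)])
        ref = ReferenceRegion(name, start, end, seq)
        sm = classify_contexts(ref)
        if len(sm.hcg) >= 10 and len(sm.gch) >= 20:
            return ref
    raise RuntimeError("could not generate an informative reference")  # pragma: no cover
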