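"""Plain-text serialisation of the pipeline's inputs and outputs.

FASTA for reference and clone sequences (via Biopython), TSV for spot
tables, beta matrices and region definitions.  Clone headers follow
``cloneNN|condition|treated={yes,no}``; beta matrices use ``NA`` for
unavailable cells.
"""

from __future__ import annotations

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from epilocus.fish3d import SPOT_COLUMNS
from epilocus.methclust import BetaMatrix
from epilocus.regions import ReferenceRegion


def write_fasta(records, path) -> None:
    SeqIO.write(records, path, "fasta")


def read_fasta(path) -> list[SeqRecord]:
    return list(SeqIO.parse(path, "fasta"))


def write_reference(ref: ReferenceRegion, fasta_path, regions_path=None) -> None:
    """Reference FASTA plus an optional BED-like region table
    (name, tss_start, tss_end)."""
    write_fasta([SeqRecord(Seq(ref.sequence), id=ref.name, description="")], fasta_path)
    if regions_path is not None:
        pd.DataFrame(
            [{"name": ref.name, "tss_start": ref.tss_start, "tss_end": ref.tss_end}]
        ).to_csv(regions_path, sep="\t", index=False)


def read_reference(fasta_path, regions_path) -> ReferenceRegion:
    rec = read_fasta(fasta_path)[0]
    regions = pd.read_csv(regions_path, sep="\t").set_index("name")
    row = regions.loc[rec.id]
    return ReferenceRegion(rec.id, int(row["tss_start"]), int(row["tss_end"]), str(rec.seq))


def write_spots(spots: pd.DataFrame, path, include_truth: bool = True) -> None:
    cols = [c for c in spots.columns if include_truth or c in SPOT_COLUMNS]
    spots[cols].to_csv(path, sep="\t", index=False)


def read_spots(path) -> pd.DataFrame:
    """Read a spot table; the homolog_id / true_class truth columns are optional."""
    return pd.read_csv(path, sep="\t")


def write_beta_matrix(matrix: BetaMatrix, values_path, annot_path) -> None:
    matrix.values.to_csv(values_path, sep="\t", na_rep="NA", index_label="sample")
    annot = pd.DataFrame({"sample": matrix.sample_groups.index,
                          "group": matrix.sample_groups.to_numpy()})
    annot.to_csv(annot_path, sep="\t", index=False)


def read_beta_matrix(values_path, annot_path, domain_boundary: int = -200) -> BetaMatrix:
    """Read a beta matrix; CpG domains are re-derived from the TSS offsets in
    the column names (``pos_<offset>``) against ``domain_boundary``."""
    values = pd.read_csv(values_path, sep="\t", index_col="sample")
    values.index.name = None  # in-memory convention: unnamed sample index
    annot = pd.read_csv(annot_path, sep="\t").set_index("sample")["group"]
    offsets = [int(c.split("_", 1)[1]) for c in values.columns]
    domains = pd.Series(
        ["distal" if o < domain_boundary else "proximal" for o in offsets],
        index=values.columns,
    )
    return BetaMatrix(values=values, sample_groups=annot.loc[values.index], domains=domains)
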