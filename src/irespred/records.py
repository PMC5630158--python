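"""Library I/O: sequence records, activity thresholding and origin groups.

An assayed library is a table of RNA sequences with a measured IRES
(internal ribosome entry site) activity.  Sequences are anchored at the
reporter start AUG: ``aug_offset`` is the index of the position immediately
5' of the AUG, so by default the 3' end of the stored sequence abuts the
start codon.  A sequence is *active* when its activity exceeds the
detection floor derived from empty-vector measurements (an input here, as
the floor is assay-specific).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

#: The seven origin groups: three locations within human transcripts and
#: four viral classes (Baltimore classification).
GROUPS = (
    "human_5utr",
    "human_3utr",
    "human_cds",
    "ssrna_plus",
    "ssrna_minus",
    "dsrna",
    "retro",
)

#: Pseudo-group denoting the union of all seven groups.
ALL_GROUP = "all"

_RNA_ALPHABET = frozenset("ACGU")


@dataclass(frozen=True)
class SequenceRecord:
    """One assayed RNA sequence with its measured activity.

    ``active`` is derived: activity strictly above the detection
    threshold.  ``aug_offset`` locates the reporter start AUG; position
    ``i`` of ``rna`` sits at AUG-relative coordinate ``i - aug_offset``
    (negative = upstream).
    """

    id: str
    rna: str
    group: str
    activity: float
    active: bool
    aug_offset: int

    def __post_init__(self) -> None:
        if not self.rna:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.rna) - _RNA_ALPHABET
        if bad:
            raise ValueError(f"{self.id}: non-ACGU characters {sorted(bad)}")
        if self.group not in GROUPS:
            raise ValueError(f"{self.id}: unknown group {self.group!r}")
        if not (1 <= self.aug_offset <= len(self.rna)):
            raise ValueError(
                f"{self.id}: aug_offset {self.aug_offset} outside [1, {len(self.rna)}]"
            )


def transliterate(seq: str) -> str:
    """Uppercase and convert DNA T to RNA U."""
    return seq.upper().replace("T", "U")


def make_record(
    id: str,
    seq: str,
    group: str,
    activity: float,
    threshold: float,
    aug_offset: int | None = None,
) -> SequenceRecord:
    """Build a validated record, transliterating DNA input."""
    rna = transliterate(str(seq))
    if aug_offset is None:
        aug_offset = len(rna)
    return SequenceRecord(
        id=str(id),
        rna=rna,
        group=group,
        activity=float(activity),
        active=float(activity) > threshold,
        aug_offset=int(aug_offset),
    )


def load_library(
    table_path: str | Path,
    fasta_path: str | Path | None = None,
    threshold: float = 0.0,
) -> list[SequenceRecord]:
    """Load a library from a TSV table (plus optional companion FASTA).

    The table needs columns ``id``, ``group`` and ``activity``; sequences
    come either from a ``sequence`` column or from the FASTA keyed by id.
    An optional ``aug_offset`` column overrides the default anchor (the
    3' end).  Records with out-of-alphabet sequences are rejected with a
    logged reason; a missing FASTA cross-reference or an unknown group
    label is a hard error.
    """
    table = pd.read_csv(table_path, sep="\t", dtype={"id": str})
    required = {"id", "group", "activity"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"library table lacks columns {sorted(missing)}")

    seqs: dict[str, str] | None = None
    if fasta_path is not None:
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    elif "sequence" not in table.columns:
        raise ValueError("no sequence column and no FASTA given")

    records: list[SequenceRecord] = []
    for row in table.itertuples(index=False):
        if seqs is not None:
            if row.id not in seqs:
                raise KeyError(f"sequence id {row.id!r} absent from FASTA")
            raw = seqs[row.id]
        else:
            raw = row.sequence
        if row.group not in GROUPS:
            raise ValueError(f"{row.id}: unknown group {row.group!r}")
        aug = getattr(row, "aug_offset", None)
        try:
            rec = make_record(
                row.id, raw, row.group, row.activity, threshold,
                aug_offset=None if aug is None or pd.isna(aug) else int(aug),
            )
        except ValueError as exc:
            logger.warning("rejected record: %s", exc)
            continue
        records.append(rec)
    return records


def write_library(
    records: list[SequenceRecord],
    table_path: str | Path,
    fasta_path: str | Path | None = None,
) -> None:
    """Write records back to TSV (+ optional FASTA), round-trip safe."""
    table = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "group": [r.group for r in records],
            "activity": [repr(r.activity) for r in records],
            "aug_offset": [r.aug_offset for r in records],
        }
    )
    if fasta_path is None:
        table["sequence"] = [r.rna for r in records]
    table.to_csv(table_path, sep="\t", index=False)
    if fasta_path is not None:
        bio = [
            _BioSeqRecord(Seq(r.rna), id=r.id, description="") for r in records
        ]
        SeqIO.write(bio, str(fasta_path), "fasta")


def partition_by_group(
    records: list[SequenceRecord],
) -> dict[str, list[SequenceRecord]]:
    """Split records into the seven origin groups (plus ``all``)."""
    parts: dict[str, list[SequenceRecord]] = {g: [] for g in GROUPS}
    for rec in records:
        parts[rec.group].append(rec)
    parts[ALL_GROUP] = list(records)
    return parts


def active_fraction(records: list[SequenceRecord]) -> float:
    """Fraction of records above the detection floor."""
    if not records:
        return 0.0
    return sum(r.active for r in records) / len(records)
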