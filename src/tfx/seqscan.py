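"""Charge scan of three-finger toxin sequences.

Counts positively charged residues (Lys/Arg by default; His excluded) in the
alignment region corresponding to the toxin's membrane-active site, and
summarises per toxin class the fraction of sequences with at least a
threshold number of basic residues there.  UniProt-wide tallies depend on the
database snapshot, so sequences are always user-supplied FASTA - nothing is
fetched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
DEFAULT_BASIC = frozenset("KR")
TOXIN_CLASSES = ("long_chain", "short_chain", "non_conventional", "other")


@dataclass
class ToxinRecord:
    id: str
    toxin_class: str
    sequence: str
    aligned: str | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not set(self.sequence) <= AA_ALPHABET:
            bad = sorted(set(self.sequence) - AA_ALPHABET)
            raise ValueError(f"{self.id}: non-amino-acid letters {bad}")
        if self.aligned is not None:
            self.aligned = self.aligned.upper()
            if self.aligned.replace("-", "").replace(".", "") != self.sequence:
                raise ValueError(f"{self.id}: aligned sequence does not de-gap to sequence")
        if self.toxin_class not in TOXIN_CLASSES:
            self.toxin_class = "other"


@dataclass
class RegionMask:
    """Positions (0-based) defining the membrane-active-site region.

    Positions index the alignment when records carry aligned sequences, and
    the plain sequence otherwise.
    """

    columns: tuple

    def __post_init__(self) -> None:
        self.columns = tuple(int(c) for c in self.columns)
        if any(c < 0 for c in self.columns):
            raise ValueError("mask columns must be >= 0")


def read_toxin_fasta(path, class_field: int = 1, delimiter: str = "|") -> list[ToxinRecord]:
    """Read (optionally aligned) FASTA; class parsed from the header.

    Header convention: ``>identifier|toxin_class``; records without a class
    token fall into ``other``.  Gapped sequences are stored as alignments.
    """
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split(delimiter)
        cls = parts[class_field] if len(parts) > class_field else "other"
        seq = str(rec.seq).upper()
        if "-" in seq or "." in seq:
            records.append(ToxinRecord(parts[0], cls,
                                       seq.replace("-", "").replace(".", ""), aligned=seq))
        else:
            records.append(ToxinRecord(parts[0], cls, seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def count_basic_in_region(rec: ToxinRecord, mask: RegionMask,
                          basic_set: frozenset = DEFAULT_BASIC) -> int:
    """Number of basic residues at the masked positions."""
    text = rec.aligned if rec.aligned is not None else rec.sequence
    if mask.columns and max(mask.columns) >= len(text):
        raise ValueError(f"{rec.id}: mask column {max(mask.columns)} out of range "
                         f"(length {len(text)})")
    return sum(1 for c in mask.columns if text[c] in basic_set)


def classify_toxin_set(records: list[ToxinRecord], mask: RegionMask,
                       threshold: int = 3,
                       basic_set: frozenset = DEFAULT_BASIC) -> pd.DataFrame:
    """Per-class counts of sequences with >= threshold basic residues in region.

    The displayed fraction is rounded to a whole percent.
    """
    if not records:
        raise ValueError("empty record set")
    rows = {}
    for rec in records:
        cls = rec.toxin_class
        n = count_basic_in_region(rec, mask, basic_set)
        entry = rows.setdefault(cls, {"toxin_class": cls, "n_total": 0, "n_positive": 0})
        entry["n_total"] += 1
        entry["n_positive"] += int(n >= threshold)
    out = pd.DataFrame(sorted(rows.values(), key=lambda r: r["toxin_class"]))
    out["fraction_pct"] = (100.0 * out["n_positive"] / out["n_total"]).round().astype(int)
    return out
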