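"""Readers and writers for the external representations used by the pipeline.

FASTA (mature miRNA libraries and 3'UTR references), HGVS-like ``c.*`` SNV
strings, delimited genotype/phenotype/Ct tables, and TSV/JSON result output.
Sequence records are normalised to uppercase with T<->U converted to the
requested alphabet; 3'UTR coordinates are 1-based with position 1 the first
base 3' of the stop codon (``c.*1``).
"""

from __future__ import annotations

import dataclasses
import io
import json
import math
import re
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FormatError",
    "ReferenceMismatchError",
    "MirnaRecord",
    "UtrRecord",
    "UtrVariant",
    "GenotypeRow",
    "PhenotypeRow",
    "CtTableRow",
    "read_fasta",
    "write_fasta",
    "parse_variant",
    "read_table",
    "write_sites_tsv",
    "write_json",
]

RNA_ALPHABET = set("ACGUN")
DNA_ALPHABET = set("ACGTN")
GROUPS = ("case", "control_longlived", "control_healthy")


class FormatError(ValueError):
    """Raised for malformed input files or strings."""


class ReferenceMismatchError(ValueError):
    """Raised when a variant's stated reference base disagrees with the sequence."""


@dataclasses.dataclass(frozen=True)
class MirnaRecord:
    """A mature miRNA: id (e.g. ``hsa-miR-92b-5p``) and 5'->3' RNA sequence."""

    mirna_id: str
    sequence: str

    @property
    def species_prefix(self) -> str:
        return self.mirna_id[:3]

    def __post_init__(self) -> None:
        if len(self.sequence) < 8:
            raise FormatError(
                f"miRNA {self.mirna_id!r}: sequence shorter than 8 nt "
                f"({len(self.sequence)})"
            )
        _check_alphabet(self.sequence, RNA_ALPHABET, self.mirna_id)


@dataclasses.dataclass(frozen=True)
class UtrRecord:
    """A 3'UTR reference sequence (DNA, sense strand, c.* coordinates)."""

    utr_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"UTR {self.utr_id!r}: empty sequence")
        _check_alphabet(self.sequence, DNA_ALPHABET, self.utr_id)

    def base(self, position: int) -> str:
        """Base at 1-based c.* position."""
        if not 1 <= position <= len(self.sequence):
            raise IndexError(
                f"position c.*{position} outside UTR {self.utr_id!r} "
                f"(length {len(self.sequence)})"
            )
        return self.sequence[position - 1]


@dataclasses.dataclass(frozen=True)
class UtrVariant:
    """A single-nucleotide substitution in c.* coordinates (e.g. c.*28T>C)."""

    utr_id: str
    position: int
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise FormatError(f"variant position must be >= 1, got {self.position}")
        for name, base in (("ref", self.ref_base), ("alt", self.alt_base)):
            if base not in "ACGT":
                raise FormatError(f"{name} base must be one of A/C/G/T, got {base!r}")
        if self.ref_base == self.alt_base:
            raise FormatError("ref and alt bases are identical")

    @property
    def hgvs(self) -> str:
        return f"c.*{self.position}{self.ref_base}>{self.alt_base}"

    def swapped(self) -> "UtrVariant":
        """The reverting substitution (alt>ref)."""
        return UtrVariant(self.utr_id, self.position, self.alt_base, self.ref_base)


def _normalize_genotype(text: str) -> tuple[str, str]:
    alleles = re.split(r"[/|]", text.strip().upper())
    if len(alleles) != 2 or any(a not in ("T", "C") for a in alleles):
        raise FormatError(f"unknown genotype string {text!r} (expected e.g. T/T, T/C)")
    return tuple(sorted(alleles))  # type: ignore[return-value]


@dataclasses.dataclass(frozen=True)
class GenotypeRow:
    """One subject's group assignment and biallelic genotype.

    The genotype is an unordered allele pair: ``C/T`` and ``T/C`` are the
    same class. Alleles are T (wild type) and C (variant).
    """

    subject_id: str
    group: str
    alleles: tuple[str, str]

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise FormatError(
                f"subject {self.subject_id!r}: unknown group {self.group!r} "
                f"(expected one of {GROUPS})"
            )
        object.__setattr__(self, "alleles", tuple(sorted(self.alleles)))
        if any(a not in ("T", "C") for a in self.alleles) or len(self.alleles) != 2:
            raise FormatError(
                f"subject {self.subject_id!r}: invalid alleles {self.alleles}"
            )

    @property
    def genotype(self) -> str:
        # render major allele first: T/T, T/C, C/C
        order = {"T": 0, "C": 1}
        a, b = sorted(self.alleles, key=order.get)
        return f"{a}/{b}"

    @property
    def minor_allele_count(self) -> int:
        return sum(1 for a in self.alleles if a == "C")

    @property
    def is_carrier(self) -> bool:
        return self.minor_allele_count >= 1


@dataclasses.dataclass(frozen=True)
class PhenotypeRow:
    """Per-subject ECG intervals in milliseconds; any field may be missing (None)."""

    subject_id: str
    pr_ms: float | None = None
    rr_ms: float | None = None
    qrs_ms: float | None = None
    qt_ms: float | None = None

    def __post_init__(self) -> None:
        for name in ("pr_ms", "rr_ms", "qrs_ms", "qt_ms"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v <= 0):
                raise FormatError(
                    f"subject {self.subject_id!r}: {name} must be finite and > 0, got {v}"
                )


CT_ROLES = ("target", "spike_in", "housekeeping")


@dataclasses.dataclass(frozen=True)
class CtTableRow:
    """Raw qPCR cycle thresholds: one sample/assay with 1-3 replicate Cts."""

    sample_id: str
    assay_id: str
    ct_values: tuple[float, ...]
    role: str

    def __post_init__(self) -> None:
        if self.role not in CT_ROLES:
            raise FormatError(f"unknown Ct role {self.role!r} (expected {CT_ROLES})")
        if not 1 <= len(self.ct_values) <= 3:
            raise FormatError(
                f"sample {self.sample_id!r}/{self.assay_id!r}: expected 1-3 replicate "
                f"Cts, got {len(self.ct_values)}"
            )
        for ct in self.ct_values:
            if not (0 < ct <= 45):
                raise FormatError(
                    f"sample {self.sample_id!r}/{self.assay_id!r}: Ct {ct} outside (0, 45]"
                )


def _check_alphabet(seq: str, alphabet: set[str], record_id: str) -> None:
    for i, ch in enumerate(seq, start=1):
        if ch not in alphabet:
            raise FormatError(
                f"record {record_id!r}: invalid character {ch!r} at position {i}"
            )


def read_fasta(path, alphabet: str):
    """Read a FASTA file into MirnaRecords (``alphabet='rna'``) or UtrRecords (``'dna'``).

    Sequences are uppercased; T->U for RNA, U->T for DNA. The record id is the
    first whitespace-delimited header token. File order is preserved.
    """
    if alphabet not in ("rna", "dna"):
        raise ValueError(f"alphabet must be 'rna' or 'dna', got {alphabet!r}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    out = []
    for rec in records:
        seq = str(rec.seq).upper()
        seq = seq.replace("T", "U") if alphabet == "rna" else seq.replace("U", "T")
        if alphabet == "rna":
            out.append(MirnaRecord(mirna_id=rec.id, sequence=seq))
        else:
            out.append(UtrRecord(utr_id=rec.id, sequence=seq))
    return out


def write_fasta(records: Iterable[MirnaRecord | UtrRecord], path) -> None:
    seqrecs = []
    for r in records:
        rid = r.mirna_id if isinstance(r, MirnaRecord) else r.utr_id
        seqrecs.append(SeqRecord(Seq(r.sequence), id=rid, description=""))
    SeqIO.write(seqrecs, str(path), "fasta")


_VARIANT_RE = re.compile(r"^c\.\*(\d+)([ACGTacgt])>([ACGTacgt])$")


def parse_variant(text: str, utr: UtrRecord) -> UtrVariant:
    """Parse an HGVS-like 3'UTR SNV string (``c.*28T>C``), validated against the UTR.

    Only single-nucleotide substitutions in c.* coordinates are supported;
    raises :class:`ReferenceMismatchError` if the stated reference base differs
    from the sequence.
    """
    m = _VARIANT_RE.match(text.strip())
    if m is None:
        raise FormatError(
            f"cannot parse variant {text!r}: expected c.*<pos><ref>><alt>, e.g. c.*28T>C"
        )
    pos = int(m.group(1))
    ref, alt = m.group(2).upper(), m.group(3).upper()
    if pos > len(utr.sequence):
        raise FormatError(
            f"variant position c.*{pos} beyond UTR {utr.utr_id!r} "
            f"(length {len(utr.sequence)})"
        )
    found = utr.base(pos)
    if found != ref:
        raise ReferenceMismatchError(
            f"{text}: expected reference base {ref} at c.*{pos} of "
            f"{utr.utr_id!r} but sequence has {found}"
        )
    return UtrVariant(utr_id=utr.utr_id, position=pos, ref_base=ref, alt_base=alt)


def _read_delimited(path) -> pd.DataFrame:
    # autodetect TSV vs CSV from the header line
    text = Path(path).read_text()
    if not text.strip():
        raise FormatError(f"{path}: empty table")
    header = text.splitlines()[0]
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(io.StringIO(text), sep=sep, dtype={"subject_id": str, "sample_id": str})


def read_table(path, schema: str) -> list:
    """Read a genotype, phenotype or Ct table (TSV/CSV with header row).

    Missing phenotype cells are preserved as missing, never coerced to zero.
    """
    df = _read_delimited(path)
    if schema == "genotype":
        _require_columns(df, ("subject_id", "group", "genotype"), path)
        return [
            GenotypeRow(str(r.subject_id), str(r.group), _normalize_genotype(str(r.genotype)))
            for r in df.itertuples()
        ]
    if schema == "phenotype":
        _require_columns(df, ("subject_id",), path)
        rows = []
        for r in df.itertuples():
            kwargs = {}
            for col in ("pr_ms", "rr_ms", "qrs_ms", "qt_ms"):
                v = getattr(r, col, None)
                kwargs[col] = None if v is None or pd.isna(v) else float(v)
            rows.append(PhenotypeRow(str(r.subject_id), **kwargs))
        return rows
    if schema == "ct":
        _require_columns(df, ("sample_id", "assay_id", "role"), path)
        rows = []
        for r in df.itertuples():
            cts = []
            for col in ("ct1", "ct2", "ct3"):
                v = getattr(r, col, None)
                if v is None or pd.isna(v):
                    continue
                try:
                    cts.append(float(v))
                except (TypeError, ValueError):
                    raise FormatError(
                        f"{path}: non-numeric Ct {v!r} for sample {r.sample_id!r}"
                    ) from None
            rows.append(CtTableRow(str(r.sample_id), str(r.assay_id), tuple(cts), str(r.role)))
        return rows
    raise ValueError(f"unknown table schema {schema!r}")


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


SITE_TSV_COLUMNS = (
    "mirna_id",
    "utr_id",
    "start",
    "end",
    "site_type",
    "match_len",
    "allele",
    "overlaps_variant",
    "status",
)


def write_sites_tsv(rows: Iterable[dict], path) -> None:
    """Write seed-site rows (dicts keyed by SITE_TSV_COLUMNS) as UTF-8 TSV, LF endings."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(SITE_TSV_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in SITE_TSV_COLUMNS) + "\n")


def write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
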