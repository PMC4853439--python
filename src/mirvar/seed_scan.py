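"""Allele-aware exhaustive scan for miRNA seed-match sites in a 3'UTR.

A site is nucleated by a 6mer seed match: a UTR window that is the perfect
Watson-Crick reverse complement (U == T) of miRNA nucleotides 2-7. Because the
miRNA binds the mRNA antiparallel, miRNA nt 8 faces the UTR base immediately
5' of that window and miRNA nt 1 faces the base immediately 3' of it. The
canonical stronger classes are upgrades of the 6mer:

* 7mer-m8 — the 5'-flanking UTR base also pairs miRNA nt 8;
* 7mer-A1 — the 3'-flanking UTR base is an A (the adenine convention;
  a pairing-based rule is available via ``a1_rule='pair'``);
* 8mer    — both conditions hold.

Each site is reported once with the single highest class it attains, plus
``match_len``: the length of the maximal contiguous perfectly paired run
through the seed duplex, extending 5'-ward on the UTR against miRNA nt 8, 9,
... until the first mismatch, plus the nt-1 position when it Watson-Crick
pairs. G:U wobbles are not counted as pairs unless ``allow_wobble`` is set.

``diff_sites`` scans both alleles of a single-nucleotide variant and reports
the sites gained and lost, identifying a site by (mirna_id, start, site_type).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Literal

from .io_formats import MirnaRecord, ReferenceMismatchError, UtrRecord, UtrVariant

__all__ = [
    "SeedSite",
    "SiteDelta",
    "extract_seed",
    "apply_variant",
    "scan_sites",
    "diff_sites",
]

SITE_TYPES = ("6mer", "7mer-A1", "7mer-m8", "8mer")

# DNA-vs-RNA Watson-Crick complement: UTR base (DNA) pairing a miRNA base (RNA)
_PAIRS = {("A", "U"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("T", "G"), ("G", "U")}  # UTR T : miRNA G and UTR G : miRNA U

_RC_RNA_TO_DNA = {"A": "T", "C": "G", "G": "C", "U": "A"}


@dataclasses.dataclass(frozen=True)
class SeedSite:
    """A classified seed-match site on one allele of a UTR.

    ``start``/``end`` are 1-based inclusive c.* coordinates of the full site
    footprint (6, 7 or 8 bases according to ``site_type``).
    """

    mirna_id: str
    utr_id: str
    start: int
    end: int
    site_type: str
    match_len: int
    allele: str  # "ref" | "alt"

    @property
    def key(self) -> tuple[str, int, str]:
        """Site identity across alleles: (mirna_id, start, site_type)."""
        return (self.mirna_id, self.start, self.site_type)

    def overlaps(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclasses.dataclass(frozen=True)
class SiteDelta:
    """Sites gained (alt-only) and lost (ref-only) by a variant."""

    variant: UtrVariant
    gained: tuple[SeedSite, ...]
    lost: tuple[SeedSite, ...]


def extract_seed(mirna: MirnaRecord) -> str:
    """The 6-base seed: miRNA nucleotides 2-7, 1-based from the 5' end."""
    if len(mirna.sequence) < 8:
        raise ValueError(
            f"miRNA {mirna.mirna_id!r} is {len(mirna.sequence)} nt; need >= 8"
        )
    return mirna.sequence[1:7]


def seed_match_window(mirna: MirnaRecord) -> str:
    """The DNA UTR window complementary to the seed (reverse complement, U->T)."""
    seed = extract_seed(mirna)
    return "".join(_RC_RNA_TO_DNA[b] for b in reversed(seed))


def apply_variant(utr: UtrRecord, v: UtrVariant) -> UtrRecord:
    """Return the alternate-allele UTR (same length, one substitution)."""
    found = utr.base(v.position)  # raises IndexError when out of range
    if found != v.ref_base:
        raise ReferenceMismatchError(
            f"{v.hgvs}: expected {v.ref_base} at c.*{v.position} of "
            f"{utr.utr_id!r} but sequence has {found}"
        )
    seq = utr.sequence
    return UtrRecord(utr.utr_id, seq[: v.position - 1] + v.alt_base + seq[v.position :])


def _pairs(utr_base: str, mirna_base: str, allow_wobble: bool) -> bool:
    if (utr_base, mirna_base) in _PAIRS:
        return True
    return allow_wobble and (utr_base, mirna_base) in _WOBBLE


def _classify(
    utr_seq: str,
    window_start0: int,  # 0-based index of the 6mer window start
    mirna_seq: str,
    a1_rule: str,
    allow_wobble: bool,
) -> tuple[str, int, int, int]:
    """Classify one seed match; returns (site_type, start, end, match_len), 1-based."""
    n = len(utr_seq)
    w0, w5 = window_start0, window_start0 + 5

    # miRNA nt 8 faces utr_seq[w0 - 1]; nt 1 faces utr_seq[w5 + 1]
    m8 = (
        w0 - 1 >= 0
        and len(mirna_seq) >= 8
        and _pairs(utr_seq[w0 - 1], mirna_seq[7], allow_wobble)
    )
    if w5 + 1 < n:
        a1_base = utr_seq[w5 + 1]
        a1_paired = _pairs(a1_base, mirna_seq[0], allow_wobble)
        a1 = a1_base == "A" if a1_rule == "adenine" else a1_paired
    else:
        a1 = False
        a1_paired = False

    if m8 and a1:
        site_type, start0, end0 = "8mer", w0 - 1, w5 + 1
    elif m8:
        site_type, start0, end0 = "7mer-m8", w0 - 1, w5
    elif a1:
        site_type, start0, end0 = "7mer-A1", w0, w5 + 1
    else:
        site_type, start0, end0 = "6mer", w0, w5

    # maximal contiguous paired run through the seed: extend 5'-ward on the UTR
    # against miRNA nt 8, 9, ... until mismatch or either sequence ends
    match_len = 6
    i, j = w0 - 1, 7
    while i >= 0 and j < len(mirna_seq) and _pairs(utr_seq[i], mirna_seq[j], allow_wobble):
        match_len += 1
        i -= 1
        j += 1
    if w5 + 1 < n and a1_paired:
        match_len += 1

    return site_type, start0 + 1, end0 + 1, match_len


def scan_sites(
    utr: UtrRecord,
    mirnas: Iterable[MirnaRecord],
    allele: Literal["ref", "alt"] = "ref",
    *,
    a1_rule: str = "adenine",
    allow_wobble: bool = False,
) -> list[SeedSite]:
    """Exhaustively scan a UTR for seed matches against a miRNA library.

    Every 6-base UTR window that perfectly reverse-complements some miRNA's
    seed (nt 2-7) yields exactly one site, classified at the highest class it
    attains. Windows containing N never match. Overlapping sites and multiple
    miRNAs matching the same window are all reported. Output is ordered by
    (start, mirna_id) and is deterministic.
    """
    mirnas = list(mirnas)
    if not mirnas:
        raise ValueError("empty miRNA library")
    if a1_rule not in ("adenine", "pair"):
        raise ValueError(f"a1_rule must be 'adenine' or 'pair', got {a1_rule!r}")
    seq = utr.sequence
    if len(seq) < 6:
        raise ValueError(f"UTR {utr.utr_id!r} shorter than 6 nt")

    # index the library by seed-complementary DNA window
    by_window: dict[str, list[MirnaRecord]] = {}
    for m in mirnas:
        by_window.setdefault(seed_match_window(m), []).append(m)

    sites: list[SeedSite] = []
    for w0 in range(len(seq) - 5):
        window = seq[w0 : w0 + 6]
        if "N" in window:
            continue
        for m in by_window.get(window, ()):
            site_type, start, end, match_len = _classify(
                seq, w0, m.sequence, a1_rule, allow_wobble
            )
            sites.append(
                SeedSite(
                    mirna_id=m.mirna_id,
                    utr_id=utr.utr_id,
                    start=start,
                    end=end,
                    site_type=site_type,
                    match_len=match_len,
                    allele=allele,
                )
            )
    sites.sort(key=lambda s: (s.start, s.mirna_id))
    return sites


def diff_sites(
    utr: UtrRecord,
    mirnas: Iterable[MirnaRecord],
    v: UtrVariant,
    report: str = "overlapping_only",
    *,
    a1_rule: str = "adenine",
    allow_wobble: bool = False,
) -> SiteDelta:
    """Sites gained and lost when the variant's alternate allele is applied.

    A site present for the alt allele and absent for ref (under the identity
    key mirna_id/start/site_type) is gained; the symmetric set is lost. With
    ``report='overlapping_only'`` (default) only sites whose footprint covers
    the variant position are kept; ``report='all'`` keeps every changed site.
    """
    if report not in ("overlapping_only", "all"):
        raise ValueError(f"report must be 'overlapping_only' or 'all', got {report!r}")
    mirnas = list(mirnas)
    alt_utr = apply_variant(utr, v)
    ref_sites = scan_sites(utr, mirnas, "ref", a1_rule=a1_rule, allow_wobble=allow_wobble)
    alt_sites = scan_sites(alt_utr, mirnas, "alt", a1_rule=a1_rule, allow_wobble=allow_wobble)
    ref_keys = {s.key for s in ref_sites}
    alt_keys = {s.key for s in alt_sites}
    gained = [s for s in alt_sites if s.key not in ref_keys]
    lost = [s for s in ref_sites if s.key not in alt_keys]
    if report == "overlapping_only":
        gained = [s for s in gained if s.overlaps(v.position)]
        lost = [s for s in lost if s.overlaps(v.position)]
    return SiteDelta(variant=v, gained=tuple(gained), lost=tuple(lost))


def sites_to_rows(delta: SiteDelta) -> list[dict]:
    """Flatten a SiteDelta for TSV output (gained then lost, scan order)."""
    rows = []
    for status, sites in (("gained", delta.gained), ("lost", delta.lost)):
        for s in sites:
            rows.append(
                {
                    "mirna_id": s.mirna_id,
                    "utr_id": s.utr_id,
                    "start": s.start,
                    "end": s.end,
                    "site_type": s.site_type,
                    "match_len": s.match_len,
                    "allele": s.allele,
                    "overlaps_variant": s.overlaps(delta.variant.position),
                    "status": status,
                }
            )
    return rows
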