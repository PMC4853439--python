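"""Independent brute-force oracles used to cross-check the implementation.

These re-derive expected results by enumeration or direct definition and
deliberately share no code with the package modules they check.
"""

from math import comb

_DNA_TO_RNA_PAIR = {"A": "U", "T": "A", "G": "C", "C": "G"}
_RNA_COMPLEMENT_DNA = {"A": "T", "C": "G", "G": "C", "U": "A"}


def naive_scan(utr_seq: str, mirnas: list[tuple[str, str]]) -> list[dict]:
    """Window-by-window enumeration of seed matches with naive classification.

    ``mirnas`` is a list of (id, RNA sequence). Returns dicts with 1-based
    footprint start/end, site_type and match_len, sorted by (start, id).
    """
    out = []
    n = len(utr_seq)
    for mid, mseq in mirnas:
        seed = mseq[1:7]
        target = "".join(_RNA_COMPLEMENT_DNA[b] for b in seed)[::-1]
        for w0 in range(n - 5):
            window = utr_seq[w0 : w0 + 6]
            if "N" in window or window != target:
                continue
            m8 = (
                w0 >= 1
                and len(mseq) >= 8
                and _DNA_TO_RNA_PAIR.get(utr_seq[w0 - 1]) == mseq[7]
            )
            a1 = w0 + 6 < n and utr_seq[w0 + 6] == "A"
            if m8 and a1:
                stype, s0, e0 = "8mer", w0 - 1, w0 + 6
            elif m8:
                stype, s0, e0 = "7mer-m8", w0 - 1, w0 + 5
            elif a1:
                stype, s0, e0 = "7mer-A1", w0, w0 + 6
            else:
                stype, s0, e0 = "6mer", w0, w0 + 5
            mlen = 6
            i, j = w0 - 1, 7
            while i >= 0 and j < len(mseq) and _DNA_TO_RNA_PAIR.get(utr_seq[i]) == mseq[j]:
                mlen += 1
                i -= 1
                j += 1
            if w0 + 6 < n and _DNA_TO_RNA_PAIR.get(utr_seq[w0 + 6]) == mseq[0]:
                mlen += 1
            out.append(
                {
                    "mirna_id": mid,
                    "start": s0 + 1,
                    "end": e0 + 1,
                    "site_type": stype,
                    "match_len": mlen,
                }
            )
    out.sort(key=lambda d: (d["start"], d["mirna_id"]))
    return out


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration over one margin."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    pmf = {k: comb(r1, k) * comb(r2, c1 - k) / denom for k in range(lo, hi + 1)}
    observed = pmf[a]
    # tables at most as probable as the observed one (small tolerance for
    # float round-off in the probability comparison)
    return min(1.0, sum(p for p in pmf.values() if p <= observed * (1 + 1e-9)))


def pearson_chi2(a: int, b: int, c: int, d: int) -> float:
    """Closed-form Pearson chi-squared for a 2x2 table, no correction."""
    n = a + b + c + d
    obs = [a, b, c, d]
    exp = [
        (a + b) * (a + c) / n,
        (a + b) * (b + d) / n,
        (c + d) * (a + c) / n,
        (c + d) * (b + d) / n,
    ]
    return sum((o - e) ** 2 / e for o, e in zip(obs, exp))
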