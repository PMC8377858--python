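"""Independent brute-force oracles used by the test suite.

Everything here is written from first principles against the documented
conventions (coordinates, filters, energy model) without importing the
corresponding production code paths, so a bug in the implementation
cannot cancel out in the tests.
"""

from __future__ import annotations

import numpy as np

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rc(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(seq))


# ---------------------------------------------------------------------------
# RNA folding: exhaustive Boltzmann enumeration

RNA_PAIRS = {
    ("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")
}


def enumerate_structures(seq: str, i: int = 0, j: int | None = None):
    """Yield every non-crossing set of pairs with hairpin loops >= 3."""
    if j is None:
        j = len(seq) - 1
    if i > j:
        yield []
        return
    for rest in enumerate_structures(seq, i + 1, j):
        yield rest
    for k in range(i + 4, j + 1):
        if (seq[i], seq[k]) in RNA_PAIRS:
            for inside in enumerate_structures(seq, i + 1, k - 1):
                for outside in enumerate_structures(seq, k + 1, j):
                    yield [(i, k)] + inside + outside


def oracle_bpp(seq: str, pair_weight: float = np.e) -> np.ndarray:
    """Exact P(i,j) (1-based, symmetric) by summing over all structures."""
    n = len(seq)
    z = 0.0
    acc = np.zeros((n + 1, n + 1))
    for pairs in enumerate_structures(seq):
        wt = pair_weight ** len(pairs)
        z += wt
        for a, b in pairs:
            acc[a + 1, b + 1] += wt
    P = acc / z
    return P + P.T


# ---------------------------------------------------------------------------
# design enumeration: direct scans in oriented coordinates


def _core(ref: str, alt: str) -> tuple[int, str, str]:
    p = 0
    while p < min(len(ref), len(alt)) and ref[p] == alt[p]:
        p += 1
    r, a = ref[p:], alt[p:]
    while r and a and r[-1] == a[-1]:
        r, a = r[:-1], a[:-1]
    return p, r, a


def oriented_views(seq: str, edit_offset: int, ref: str, alt: str):
    """(strand, oriented unedited, oriented edited, core start) per strand.

    The minimal edit is left-aligned on each strand's own alleles (the
    documented convention)."""
    edited = seq[:edit_offset] + alt + seq[edit_offset + len(ref) :]
    off, cref, calt = _core(ref, alt)
    yield "+", seq, edited, edit_offset + off, len(cref), len(calt)
    L = len(seq)
    off_m = L - (edit_offset + len(ref))
    pm, crefm, caltm = _core(rc(ref), rc(alt))
    yield "-", rc(seq), rc(edited), off_m + pm, len(crefm), len(caltm)


def oracle_spacers(seq, edit_offset, ref, alt, max_target_pos):
    """Every 20+NGG site (both strands) with 1 <= target_pos <= max."""
    found = []
    for strand, T, _E, ce, _lr, _la in oriented_views(
        seq, edit_offset, ref, alt
    ):
        for p in range(len(T) - 22):
            if T[p + 21 : p + 23] == "GG":
                tp = ce - (p + 17) + 1
                if 1 <= tp <= max_target_pos:
                    found.append((strand, T[p : p + 20], tp))
    return sorted(found)


def oracle_extensions(
    seq, edit_offset, ref, alt, strand, nick, pbs_range, rtt_range, min_flank
):
    """(pbs_len, rtt_len, pbs_seq, rtt_seq) tuples passing all filters."""
    for s, T, E, ce, _lr, la in oriented_views(seq, edit_offset, ref, alt):
        if s != strand:
            continue
        tp = ce - nick + 1
        out = []
        for pbs in pbs_range:
            if nick - pbs < 0:
                continue
            for rtt in rtt_range:
                if nick + rtt > len(E):
                    continue
                if rtt - (tp - 1) - la < min_flank:
                    continue
                out.append(
                    (pbs, rtt, rc(T[nick - pbs : nick]), rc(E[nick : nick + rtt]))
                )
        return sorted(out)
    raise ValueError(strand)


def oracle_ngrnas(seq, edit_offset, ref, alt, strand, nick, pos_range):
    """(spacer, ngrna_pos, is_pe3b) per the documented scanning rules."""
    for s, T, E, _ce, _lr, _la in oriented_views(seq, edit_offset, ref, alt):
        if s != strand:
            continue
        res = {}
        u0 = rc(T)
        for source, edited in ((rc(T), False), (rc(E), True)):
            L = len(source)
            for q in range(L - 22):
                if source[q + 21 : q + 23] != "GG":
                    continue
                sp = source[q : q + 20]
                if edited and sp in u0:
                    continue
                pos = (L - (q + 17)) - nick
                if pos_range[0] <= pos <= pos_range[1]:
                    res.setdefault((sp, pos), edited)
        return sorted((sp, pos, e) for (sp, pos), e in res.items())
    raise ValueError(strand)


# ---------------------------------------------------------------------------
# alignment op counts: exhaustive path enumeration


def oracle_edit_ops(ref: str, alt: str):
    """Optimal-global-alignment op counts; ties resolved toward
    substitutions, then fewest gap columns (match +1, mismatch -1, gap
    open -2, extend -1, affine)."""
    _p, cref, calt = _core(ref, alt)
    if len(cref) == len(calt):
        return sum(a != b for a, b in zip(cref, calt)), 0, 0
    if not cref:
        return 0, len(calt), 0
    if not calt:
        return 0, 0, len(cref)

    best_score = -np.inf
    results = []

    def walk(i, j, score, nsub, nins, ndel, last):
        nonlocal best_score, results
        if i == len(cref) and j == len(calt):
            if score > best_score:
                best_score, results = score, [(nsub, nins, ndel)]
            elif score == best_score:
                results.append((nsub, nins, ndel))
            return
        if i < len(cref) and j < len(calt):
            same = cref[i] == calt[j]
            walk(
                i + 1, j + 1, score + (1 if same else -1),
                nsub + (0 if same else 1), nins, ndel, "m",
            )
        if j < len(calt):  # gap in ref = insertion
            walk(i, j + 1, score - (1 if last == "i" else 2),
                 nsub, nins + 1, ndel, "i")
        if i < len(cref):  # gap in alt = deletion
            walk(i + 1, j, score - (1 if last == "d" else 2),
                 nsub, nins, ndel + 1, "d")

    walk(0, 0, 0.0, 0, 0, 0, "")
    return min(results, key=lambda t: (-t[0], t[1] + t[2]))


# ---------------------------------------------------------------------------
# PAM disruption: literal recheck on the edited sequence


def oracle_pam_disruption(seq, edit_offset, ref, alt, strand, proto_start):
    for s, _T, E, _ce, _lr, _la in oriented_views(
        seq, edit_offset, ref, alt
    ):
        if s != strand:
            continue
        pam = E[proto_start + 20 : proto_start + 23]
        return 0 if len(pam) == 3 and pam[1:] == "GG" else 1
    raise ValueError(strand)
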