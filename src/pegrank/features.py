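"""The 23-feature vector scored for every pegRNA/ngRNA design.

Five feature groups feed the efficiency model:

1. Cas9 activity — one score for the pegRNA protospacer (pluggable
   scorer; see :class:`TableScorer` and :class:`SurrogateScorer`).
2. Oligo — length and GC fraction of the PBS and RTT.
3. Target mutation — PAM disruption (``is_dPAM``), PE3b status, and the
   substitution/insertion/deletion counts of the edit.
4. Position — ``target_pos`` (nick → first edited base), ``ngrna_pos``
   (pegRNA nick → ngRNA nick, signed), ``target_end_flank`` (downstream
   homology after the edit on the RTT).
5. RNA folding — disruption scores D(1)..D(10) of the 3' extension
   against the scaffold.

The PE2 model uses the 21 features that do not involve an ngRNA; the PE3
model uses all 23.  In the full vector, PE2 (no-ngRNA) designs carry the
sentinels ``ngrna_pos = 0`` and ``is_PE3b = 0``.
"""

from __future__ import annotations

import hashlib
from typing import Mapping

import numpy as np

from .enumeration import PegDesign, SpacerCandidate, orient
from .folding import PegLayout, compute_bpp, disruption_scores
from .variants import TargetWindow, minimal_edit

N_FOLD_FEATURES = 10

FEATURE_NAMES: tuple[str, ...] = (
    "cas9_score",
    "pbs_len",
    "rtt_len",
    "pbs_gc",
    "rtt_gc",
    "is_dPAM",
    "is_PE3b",
    "n_sub",
    "n_ins",
    "n_del",
    "target_pos",
    "ngrna_pos",
    "target_end_flank",
) + tuple(f"fold_d{i}" for i in range(1, N_FOLD_FEATURES + 1))

assert len(FEATURE_NAMES) == 23

#: ngRNA-dependent features, excluded from the PE2 model
PE3_ONLY_FEATURES = ("ngrna_pos", "is_PE3b")

PE2_FEATURE_NAMES: tuple[str, ...] = tuple(
    n for n in FEATURE_NAMES if n not in PE3_ONLY_FEATURES
)


def schema_hash(names=FEATURE_NAMES) -> str:
    """Stable digest of the ordered feature schema."""
    return hashlib.sha256(",".join(names).encode()).hexdigest()[:16]


def gc_content(seq: str) -> float:
    """(#G + #C) / length, as a fraction."""
    if not seq:
        raise ValueError("empty sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)


def edit_op_counts(ref: str, alt: str) -> tuple[int, int, int]:
    """(n_sub, n_ins, n_del) between the ref and alt alleles.

    Equal-length alleles are compared position-wise; anchored pure indels
    are counted directly; complex alleles are resolved by optimal global
    alignment (match +1, mismatch −1, gap open −2, gap extend −1), with
    ties among co-optimal alignments broken toward substitutions.
    """
    if ref == alt:
        raise ValueError("ref == alt is not an edit")
    _, cref, calt = minimal_edit(ref, alt)
    if len(cref) == len(calt):
        return sum(a != b for a, b in zip(cref, calt)), 0, 0
    if not cref:
        return 0, len(calt), 0
    if not calt:
        return 0, 0, len(cref)
    from Bio import Align

    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=-1,
        open_gap_score=-2,
        extend_gap_score=-1,
    )
    best = None
    for idx, aln in enumerate(aligner.align(cref, calt)):
        if idx >= 256:  # co-optimal alignments of short alleles
            break
        a, b = str(aln[0]), str(aln[1])
        n_sub = sum(
            x != "-" and y != "-" and x != y for x, y in zip(a, b)
        )
        n_ins = a.count("-")
        n_del = b.count("-")
        cand = (-n_sub, n_ins + n_del, (n_sub, n_ins, n_del))
        if best is None or cand < best:
            best = cand
    return best[2]


def pam_disruption(spacer: SpacerCandidate, window: TargetWindow) -> int:
    """1 iff the edit breaks the spacer's NGG PAM (the N never counts)."""
    ov = orient(window, spacer.strand)
    p = spacer.proto_start
    edited_pam = ov.edited[p + 20 : p + 23]
    return 0 if len(edited_pam) == 3 and edited_pam[1:] == "GG" else 1


def position_features(design: PegDesign) -> tuple[int, int, int]:
    """(target_pos, ngrna_pos, target_end_flank); ngrna_pos is 0 for PE2."""
    ext = design.extension
    if ext.target_end_flank < 0:
        raise ValueError("RTT does not cover the edit")
    ngrna_pos = design.ngrna.ngrna_pos if design.ngrna is not None else 0
    return design.spacer.target_pos, ngrna_pos, ext.target_end_flank


# ---------------------------------------------------------------------------
# Cas9 activity scorers


class TableScorer:
    """Looks the protospacer up in a user-supplied spacer→score table.

    This is the fidelity path: feed it per-spacer scores from any external
    activity predictor (two-column whitespace-delimited text, or a dict).
    """

    def __init__(self, table: Mapping[str, float] | str):
        if isinstance(table, str):
            scores: dict[str, float] = {}
            with open(table) as fh:
                for line in fh:
                    line = line.strip()
                    if not line or line.startswith("#"):
                        continue
                    spacer, value = line.split()[:2]
                    scores[spacer.upper()] = float(value)
            self.table = scores
        else:
            self.table = {k.upper(): float(v) for k, v in table.items()}

    def __call__(self, context30: str) -> float:
        if len(context30) != 30:
            raise ValueError("context must be 30 nt")
        spacer = context30[4:24]
        if spacer not in self.table:
            raise KeyError(f"no activity score for spacer {spacer!r}")
        return self.table[spacer]


def _surrogate_weights() -> np.ndarray:
    """Deterministic 30×4 position-nucleotide weight matrix.

    Pseudo-random base weights (fixed generator seed 11, N(0, 0.35))
    overlaid with documented heuristics: a bonus for G at protospacer
    position 20 (context column 23) and a preference against T in the
    PAM-proximal seed (context columns 16–23).
    """
    rng = np.random.default_rng(11)
    W = rng.normal(0.0, 0.35, size=(30, 4))
    W[23, 2] += 1.0  # G immediately 5' of the PAM
    W[16:24, 3] -= 0.4  # T disfavored in the seed
    return W


class SurrogateScorer:
    """Self-contained deterministic activity heuristic in [0, 1].

    score = logistic( Σ_p W[p, base_p]  −  3·(GC − 0.55)²·20
                      − 1.5 · #TTTT occurrences in the protospacer )

    where W is the fixed matrix from :func:`_surrogate_weights`, GC is the
    protospacer GC fraction, and poly-T tracts are penalized (Pol III
    terminator-like runs make poor guides).  Unknown bases (N) weigh 0.
    """

    _BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

    def __init__(self):
        self.weights = _surrogate_weights()

    def __call__(self, context30: str) -> float:
        if len(context30) != 30:
            raise ValueError("context must be 30 nt")
        context30 = context30.upper()
        raw = 0.0
        for p, base in enumerate(context30):
            idx = self._BASE_INDEX.get(base)
            if idx is not None:
                raw += self.weights[p, idx]
        proto = context30[4:24]
        gc = gc_content(proto)
        raw -= 3.0 * (gc - 0.55) ** 2 * 20
        raw -= 1.5 * sum(
            1 for i in range(len(proto) - 3) if proto[i : i + 4] == "TTTT"
        )
        return float(1.0 / (1.0 + np.exp(-raw / 4.0)))


def cas9_activity(context30: str, scorer) -> float:
    """Score a 30-nt context (4 up + protospacer + PAM + 3 down)."""
    if len(context30) != 30:
        raise ValueError(f"context must be 30 nt, got {len(context30)}")
    return float(scorer(context30))


# ---------------------------------------------------------------------------
# assembly


def assemble_features(
    design: PegDesign,
    window: TargetWindow,
    scorer,
    fold_engine: str = "nearest_neighbor",
) -> dict[str, float]:
    """The canonical 23-feature mapping for one design (ordered)."""
    ext = design.extension
    v = window.variant
    n_sub, n_ins, n_del = edit_op_counts(v.ref, v.alt)
    target_pos, ngrna_pos, end_flank = position_features(design)
    layout = PegLayout(
        spacer_len=len(design.spacer.spacer_seq),
        scaffold_len=len(design.scaffold),
        ext_len=len(ext.ext_seq),
    )
    bpp = compute_bpp(design.pegrna_full, engine=fold_engine)
    profile = disruption_scores(bpp, layout, k=N_FOLD_FEATURES)
    feats: dict[str, float] = {
        "cas9_score": cas9_activity(design.spacer.context30, scorer),
        "pbs_len": float(ext.pbs_len),
        "rtt_len": float(ext.rtt_len),
        "pbs_gc": gc_content(ext.pbs_seq),
        "rtt_gc": gc_content(ext.rtt_seq),
        "is_dPAM": float(pam_disruption(design.spacer, window)),
        "is_PE3b": float(
            design.ngrna.is_pe3b if design.ngrna is not None else 0
        ),
        "n_sub": float(n_sub),
        "n_ins": float(n_ins),
        "n_del": float(n_del),
        "target_pos": float(target_pos),
        "ngrna_pos": float(ngrna_pos),
        "target_end_flank": float(end_flank),
    }
    for i in range(N_FOLD_FEATURES):
        feats[f"fold_d{i + 1}"] = float(profile.D[i])
    assert tuple(feats) == FEATURE_NAMES
    if not all(np.isfinite(list(feats.values()))):
        raise ValueError("non-finite feature value")
    return feats


def feature_vector(feats: Mapping[str, float]) -> np.ndarray:
    """Dict → array in canonical order."""
    return np.array([feats[n] for n in FEATURE_NAMES], dtype=float)
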