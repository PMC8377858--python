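import numpy as np
import pytest

from pegrank import (
    DesignConfig,
    FEATURE_NAMES,
    PE2_FEATURE_NAMES,
    SurrogateScorer,
    TableScorer,
    assemble_designs,
    assemble_features,
    cas9_activity,
    edit_op_counts,
    find_spacers,
    gc_content,
    pam_disruption,
    position_features,
    schema_hash,
)

import oracles
from conftest import make_window


def test_schema():
    assert len(FEATURE_NAMES) == 23
    assert len(PE2_FEATURE_NAMES) == 21
    assert "ngrna_pos" not in PE2_FEATURE_NAMES
    assert "is_PE3b" not in PE2_FEATURE_NAMES
    assert schema_hash(FEATURE_NAMES) != schema_hash(PE2_FEATURE_NAMES)
    assert schema_hash(FEATURE_NAMES) == schema_hash(FEATURE_NAMES)


@pytest.mark.parametrize(
    "seq,expected", [("GGCC", 1.0), ("ATAT", 0.0), ("GATC", 0.5)]
)
def test_gc_content(seq, expected):
    assert gc_content(seq) == expected


def test_gc_content_empty_errors():
    with pytest.raises(ValueError):
        gc_content("")


@pytest.mark.parametrize(
    "ref,alt,expected",
    [
        ("T", "G", (1, 0, 0)),
        ("A", "ATT", (0, 2, 0)),
        ("ATT", "A", (0, 0, 2)),
        ("ACGT", "AGT", (0, 0, 1)),
        ("AC", "GT", (2, 0, 0)),
        ("ACGTACG", "ATG", (0, 0, 4)),
    ],
)
def test_edit_op_counts_examples(ref, alt, expected):
    assert edit_op_counts(ref, alt) == expected
    assert oracles.oracle_edit_ops(ref, alt) == expected


def test_edit_op_counts_random_vs_alignment_oracle():
    rng = np.random.default_rng(12)
    for _ in range(60):
        lr, la = int(rng.integers(1, 7)), int(rng.integers(1, 7))
        ref = "".join("ACGT"[b] for b in rng.integers(0, 4, lr))
        alt = "".join("ACGT"[b] for b in rng.integers(0, 4, la))
        if ref == alt:
            continue
        assert edit_op_counts(ref, alt) == oracles.oracle_edit_ops(ref, alt)


def plant(seq, pos, motif):
    return seq[:pos] + motif + seq[pos + len(motif) :]


def test_pam_disruption_examples():
    base = plant("A" * 100, 26, "GG")  # protospacer 5, PAM 25..27, nick 22
    # SNV at PAM position 2 (offset 26, a G) -> disrupted
    w = make_window(base, 27, "G", "T", flank=200)
    (sp,) = find_spacers(w, 25)
    assert sp.target_pos == 5 and pam_disruption(sp, w) == 1
    # SNV at PAM position 1 (the N, offset 25) -> not disrupted
    w2 = make_window(base, 26, "A", "T", flank=200)
    (sp2,) = find_spacers(w2, 25)
    assert sp2.target_pos == 4 and pam_disruption(sp2, w2) == 0


def test_pam_disruption_exhaustive_single_nt_edits():
    # every single-nt substitution at every placement of a 100-nt locus
    rng = np.random.default_rng(7)
    seq = "".join("ACGT"[b] for b in rng.integers(0, 4, 100))
    for pos0 in range(100):
        ref = seq[pos0]
        for alt in "ACGT":
            if alt == ref:
                continue
            w = make_window(seq, pos0 + 1, ref, alt, flank=200)
            for sp in find_spacers(w, 25):
                assert pam_disruption(sp, w) == oracles.oracle_pam_disruption(
                    seq, pos0, ref, alt, sp.strand, sp.proto_start
                )


def test_pam_disruption_deletion_spanning_pam():
    base = plant("A" * 100, 26, "GG")
    # delete the two PAM Gs (anchored deletion A+GG -> A)
    w = make_window(base, 26, "AGG", "A", flank=200)
    spacers = [s for s in find_spacers(w, 25) if s.proto_start == 5]
    assert spacers and pam_disruption(spacers[0], w) == 1


def test_position_features_conventions():
    # HEK3-style +1 SNV with rtt 13 -> flank 12; +5 with rtt 20 -> 15
    base = plant("A" * 100, 26, "GG")
    for tp, rtt, flank in [(1, 13, 12), (5, 20, 15)]:
        if tp == 5:  # position +5 is the first PAM G itself
            seq, ref, alt = base, "G", "T"
        else:
            seq, ref, alt = plant(base, 22 + tp - 1, "T"), "T", "G"
        w = make_window(seq, 22 + tp, ref, alt, flank=200)
        sp = [s for s in find_spacers(w, 25) if s.proto_start == 5][0]
        assert sp.target_pos == tp
        from pegrank import enumerate_extensions

        (ext,) = enumerate_extensions(sp, w, [13], [rtt], 0)
        assert ext.target_end_flank == flank


def test_position_features_insertion():
    # +1 insertion of 3 nt with rtt 13 -> 10 nt of downstream homology
    base = plant("A" * 100, 26, "GG")
    seq = plant(base, 21, "T")
    w = make_window(seq, 22, "T", "TCGC", flank=200)
    sp = [s for s in find_spacers(w, 25) if s.proto_start == 5][0]
    assert sp.target_pos == 1
    from pegrank import enumerate_extensions

    (ext,) = enumerate_extensions(sp, w, [13], [13], 0)
    assert ext.target_end_flank == 10
    designs = [
        d for d in assemble_designs(w, DesignConfig()) if d.ngrna is None
    ]
    tp, ng, fl = position_features(designs[0])
    assert ng == 0  # PE2 sentinel


def test_table_scorer_lookup_and_missing(tmp_path):
    ctx = "AAAA" + "C" * 20 + "AGG" + "TTT"
    scorer = TableScorer({"C" * 20: 0.73})
    assert cas9_activity(ctx, scorer) == 0.73
    with pytest.raises(KeyError, match="A" * 20):
        scorer("AAAA" + "A" * 20 + "AGGTTT")
    p = tmp_path / "scores.txt"
    p.write_text(f"{'C' * 20}\t0.25\n")
    assert TableScorer(str(p))(ctx) == 0.25
    with pytest.raises(ValueError):
        scorer("TOOSHORT")


def test_surrogate_scorer_deterministic_bounded():
    scorer = SurrogateScorer()
    rng = np.random.default_rng(5)
    ctxs = [
        "".join("ACGT"[b] for b in rng.integers(0, 4, 30)) for _ in range(50)
    ]
    scores = [scorer(c) for c in ctxs]
    assert scores == [scorer(c) for c in ctxs]
    assert all(0 <= s <= 1 for s in scores)


def test_surrogate_poly_t_penalized():
    scorer = SurrogateScorer()
    rng = np.random.default_rng(6)
    ctxs = [
        "".join("ACGT"[b] for b in rng.integers(0, 4, 30)) for _ in range(101)
    ]
    median = np.median([scorer(c) for c in ctxs])
    poly_t = "AAAA" + "T" * 20 + "AGG" + "AAA"
    assert scorer(poly_t) < median


@pytest.fixture(scope="module")
def scored_window():
    rng = np.random.default_rng(20)
    while True:
        seq = "".join("ACGT"[b] for b in rng.integers(0, 4, 120))
        ce = 60
        ref = seq[ce]
        alt = {"A": "T", "T": "G", "G": "T", "C": "A"}[ref]
        w = make_window(seq, ce + 1, ref, alt, flank=200)
        designs = assemble_designs(w, DesignConfig())
        if designs:
            return w, designs


def test_assemble_features_canonical(scored_window):
    w, designs = scored_window
    scorer = SurrogateScorer()
    feats = assemble_features(designs[0], w, scorer, fold_engine="simple")
    assert tuple(feats) == FEATURE_NAMES
    vals = np.array(list(feats.values()))
    assert np.isfinite(vals).all()
    pe2 = [d for d in designs if d.ngrna is None]
    if pe2:
        f2 = assemble_features(pe2[0], w, scorer, fold_engine="simple")
        assert f2["ngrna_pos"] == 0 and f2["is_PE3b"] == 0


def test_pbs_length_only_difference(scored_window):
    w, designs = scored_window
    scorer = SurrogateScorer()
    by_key = {}
    for d in designs:
        key = (
            d.spacer.spacer_seq,
            d.extension.rtt_len,
            d.ngrna.spacer_seq if d.ngrna else ".",
        )
        by_key.setdefault(key, []).append(d)
    pair = next(v for v in by_key.values() if len(v) >= 2)
    a, b = pair[0], pair[1]
    fa = assemble_features(a, w, scorer, fold_engine="simple")
    fb = assemble_features(b, w, scorer, fold_engine="simple")
    diff = {k for k in fa if fa[k] != fb[k]}
    allowed = {"pbs_len", "pbs_gc"} | {
        f"fold_d{i}" for i in range(1, 11)
    }
    assert diff and diff <= allowed


def test_fold_features_depend_only_on_pegrna(scored_window):
    # permuting window context outside the design footprint cannot change
    # the folding features (they are a function of the pegRNA sequence)
    w, designs = scored_window
    d = designs[0]
    scorer = SurrogateScorer()
    f = assemble_features(d, w, scorer, fold_engine="simple")
    from pegrank.folding import PegLayout, compute_bpp, disruption_scores

    bpp = compute_bpp(d.pegrna_full, engine="simple")
    prof = disruption_scores(
        bpp,
        PegLayout(20, len(d.scaffold), len(d.extension.ext_seq)),
    )
    for i in range(10):
        assert f[f"fold_d{i + 1}"] == prof.D[i]
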