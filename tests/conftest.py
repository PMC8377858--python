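import warnings

import numpy as np
import pytest

from pegrank import (
    GenomicVariant,
    SimConfig,
    TargetWindow,
    extract_window,
    make_toy_locus,
    simulate_training_table,
    train_test_split_train,
)

warnings.filterwarnings("ignore", message="feature .* is degenerate")


@pytest.fixture(scope="session")
def toy_locus():
    return make_toy_locus(seed=1)


@pytest.fixture(scope="session")
def toy_windows(toy_locus):
    return {
        v.id: extract_window(v, toy_locus.reference, flank=200)
        for v in toy_locus.variants
    }


def make_window(seq, pos1, ref, alt, name="w", flank=200):
    """Window helper for hand-built sequences (1-based pos)."""
    var = GenomicVariant(id=name, chrom=name, pos=pos1, ref=ref, alt=alt)
    return TargetWindow(
        variant=var, seq=seq, window_start=1, edit_offset=pos1 - 1,
        flank=flank,
    )


def random_edit_window(rng, length=80, kind="snv", name="rw"):
    """A random window with an SNV/ins/del edit near the middle."""
    seq = "".join("ACGT"[b] for b in rng.integers(0, 4, length))
    ce = length // 2
    anchor = seq[ce]
    if kind == "snv":
        ref, alt = anchor, rng.choice([b for b in "ACGT" if b != anchor])
    elif kind == "ins":
        k = int(rng.integers(1, 4))
        ref = anchor
        alt = anchor + "".join("ACGT"[b] for b in rng.integers(0, 4, k))
    else:
        k = int(rng.integers(1, 4))
        ref, alt = seq[ce : ce + 1 + k], anchor
    return make_window(seq, ce + 1, ref, str(alt), name=name, flank=200)


@pytest.fixture(scope="session")
def sim_table_small():
    """Shared small simulated PE3 screen (~6 loci)."""
    return simulate_training_table(
        SimConfig(seed=2, n_variants=6, designs_per_variant=30)
    )


@pytest.fixture(scope="session")
def sim_table_small_pe2():
    return simulate_training_table(
        SimConfig(seed=3, n_variants=6, designs_per_variant=30, system="PE2")
    )


def _quick_model(table, system, seed=0):
    rng = np.random.default_rng(seed)
    labels = np.where(rng.random(len(table)) < 0.8, "train", "test")
    return train_test_split_train(table, labels, system=system, seed=seed)


@pytest.fixture(scope="session")
def model_pe3(sim_table_small):
    return _quick_model(sim_table_small, "PE3")


@pytest.fixture(scope="session")
def model_pe2(sim_table_small_pe2):
    return _quick_model(sim_table_small_pe2, "PE2")
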