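"""Synthetic fixtures: engineered toy loci and simulated training tables.

Nothing here touches the network.  :func:`make_toy_locus` builds small
deterministic contigs with hand-placed PAM sites exercising every design
situation (single spacer, multiple spacers on both strands, no spacer at
all, a PE3b-capable opposite-strand site, and a PAM-disrupting edit).
:func:`simulate_training_table` emulates an efficiency screen: realistic
design windows, real enumerated designs and real extracted features, with
efficiency generated as a documented monotone function of a handful of
features plus Gaussian noise — so that model-recovery tests have a known
ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enumeration import DesignConfig, assemble_designs
from .features import FEATURE_NAMES, PE2_FEATURE_NAMES, SurrogateScorer, assemble_features
from .variants import GenomicVariant, TargetWindow, write_variants_vcf

_BASES = "ACGT"


def _pamfree(rng: np.random.Generator, k: int) -> str:
    """Random DNA with no GG and no CC dinucleotide (PAM-free both strands)."""
    out = []
    prev = ""
    for _ in range(k):
        while True:
            b = _BASES[rng.integers(4)]
            if not (prev == b and b in "GC"):
                break
        out.append(b)
        prev = b
    return "".join(out)


def _plant(seq: list[str], pos: int, motif: str) -> None:
    seq[pos : pos + len(motif)] = list(motif)


@dataclass(frozen=True)
class ToyLocus:
    reference: dict[str, str]
    variants: list[GenomicVariant]

    def write(self, ref_path, vcf_path) -> None:
        with open(ref_path, "w") as fh:
            for name, seq in self.reference.items():
                fh.write(f">{name}\n{seq}\n")
        write_variants_vcf(self.variants, vcf_path)


def make_toy_locus(seed: int = 1, contig_len: int = 240) -> ToyLocus:
    """Deterministic engineered contigs.

    ``single``  one + strand protospacer, edit at target_pos 10;
    ``multi``   two + strand sites and one − strand site;
    ``none``    PAM-free contig (design must fail);
    ``pe3b``    the ``single`` layout plus an opposite-strand protospacer
                overlapping the edit (PE3b ngRNA possible);
    ``dpam``    edit hits the first PAM G (is_dPAM = 1, target_pos 5).
    """
    rng = np.random.default_rng(seed)
    ce = contig_len // 2  # 0-based edit offset in every contig
    ref: dict[str, str] = {}
    variants: list[GenomicVariant] = []

    def add(name: str, planted: list[tuple[int, str]], ref_base=None, alt=None):
        seq = list(_pamfree(rng, contig_len))
        for pos, motif in planted:
            _plant(seq, pos, motif)
        if ref_base is not None:
            _plant(seq, ce, ref_base)
        s = "".join(seq)
        ref[name] = s
        rb = s[ce] if ref_base is None else ref_base
        if alt is None:
            alt = {"A": "T", "T": "G", "G": "T", "C": "A"}[rb]
        variants.append(
            GenomicVariant(id=name, chrom=name, pos=ce + 1, ref=rb, alt=alt)
        )

    # one + strand PAM; protospacer at ce-26, PAM TGG at ce-6 -> nick at
    # ce-9, so the edit sits at target_pos 10
    add("single", [(ce - 6, "TGG"), (ce - 3, "A")])

    # two + strand sites (target_pos 14 and 20) and one - strand site
    # (CC on the + strand makes an NGG PAM on the - strand)
    add(
        "multi",
        [(ce - 10, "TGGA"), (ce - 16, "TGGA"), (ce + 5, "ACCA")],
    )

    # PAM-free contig: no design possible
    add("none", [])

    # single layout plus a - strand protospacer covering the edit:
    # CC at [ce-13, ce-11) puts a - strand 20+NGG site over the edit
    add("pe3b", [(ce - 6, "TGG"), (ce - 3, "A"), (ce - 14, "ACCA")])

    # edit destroys the PAM: protospacer at ce-21, PAM TGG at ce-1 covers
    # [ce-1, ce+2), so the edit (target_pos 5) hits the first PAM G
    add("dpam", [(ce - 1, "TGG"), (ce + 2, "A")], ref_base="G", alt="T")

    return ToyLocus(reference=ref, variants=variants)


# ---------------------------------------------------------------------------
# simulated efficiency screens


#: per-feature additive effects (percentage points per SD) of the
#: simulated efficiency function; the six leading entries carry signal,
#: the mutation-type counts are deliberately weak
DEFAULT_EFFECTS: dict[str, float] = {
    "cas9_score": 12.0,
    "fold_d1": -8.0,
    "pbs_gc": 7.0,
    "is_dPAM": 6.0,
    "target_pos": -6.0,
    "target_end_flank": 4.0,
    "n_sub": -0.5,
    "n_ins": -0.5,
    "n_del": -0.5,
}


@dataclass(frozen=True)
class SimConfig:
    """Conditions of one simulated screen."""

    seed: int = 1
    n_variants: int = 50
    designs_per_variant: int = 40
    flank: int = 200
    window_len: int = 421  # contig length; edit at the center
    edit_mix: tuple[float, float, float] = (0.6, 0.2, 0.2)  # SNV, ins, del
    max_indel: int = 3
    effects: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    mu: float = 40.0
    sigma: float = 5.0
    system: str = "PE3"
    fold_engine: str = "nearest_neighbor"

    def __post_init__(self):
        if abs(sum(self.edit_mix) - 1.0) > 1e-9:
            raise ValueError("edit_mix proportions must sum to 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def _random_variant(
    rng: np.random.Generator, config: SimConfig, idx: int
) -> tuple[GenomicVariant, str]:
    seq = "".join(_BASES[b] for b in rng.integers(0, 4, config.window_len))
    ce = config.window_len // 2
    kind = rng.choice(3, p=config.edit_mix)
    anchor = seq[ce]
    if kind == 0:  # SNV
        ref, alt = anchor, rng.choice([b for b in _BASES if b != anchor])
    elif kind == 1:  # insertion (anchored)
        k = int(rng.integers(1, config.max_indel + 1))
        ref = anchor
        alt = anchor + "".join(_BASES[b] for b in rng.integers(0, 4, k))
    else:  # deletion (anchored)
        k = int(rng.integers(1, config.max_indel + 1))
        ref, alt = seq[ce : ce + 1 + k], anchor
    name = f"sim{idx}"
    var = GenomicVariant(id=name, chrom=name, pos=ce + 1, ref=ref, alt=str(alt))
    return var, seq


def simulate_training_table(config: SimConfig = SimConfig()) -> pd.DataFrame:
    """Enumerate real designs on random loci and attach simulated
    efficiencies.

    efficiency = clip( mu + Σ_f effect_f · z(feature_f) + N(0, sigma²),
                       0, 100 )

    with z the per-feature standardization over the emitted table.  The
    group id is the target-mutation key (position + target allele), the
    unit the grouped CV splits on.
    """
    rng = np.random.default_rng(config.seed)
    scorer = SurrogateScorer()
    design_cfg = DesignConfig(flank=config.flank)
    want_pe3 = config.system.upper() == "PE3"
    rows = []
    made = 0
    attempts = 0
    while made < config.n_variants:
        attempts += 1
        if attempts > 20 * config.n_variants:
            raise RuntimeError("could not generate enough designable loci")
        var, seq = _random_variant(rng, config, attempts)
        window = TargetWindow(
            variant=var,
            seq=seq,
            window_start=1,
            edit_offset=var.pos - 1,
            flank=config.flank,
        )
        designs = [
            d
            for d in assemble_designs(window, design_cfg)
            if (d.ngrna is not None) == want_pe3
        ]
        if not designs:
            continue
        made += 1
        take = min(config.designs_per_variant, len(designs))
        for i in rng.choice(len(designs), size=take, replace=False):
            d = designs[int(i)]
            feats = assemble_features(
                d, window, scorer, fold_engine=config.fold_engine
            )
            feats["group_id"] = var.key
            rows.append(feats)
    df = pd.DataFrame(rows)

    signal = np.zeros(len(df))
    for name, effect in config.effects.items():
        col = df[name].to_numpy(dtype=float)
        sd = col.std()
        if sd == 0:
            if effect != 0:
                warnings.warn(
                    f"feature {name!r} is degenerate in the simulated "
                    "table; its effect is dropped",
                    stacklevel=2,
                )
            continue
        signal += effect * (col - col.mean()) / sd
    noise = rng.normal(0.0, config.sigma, len(df))
    df["efficiency"] = np.clip(config.mu + signal + noise, 0.0, 100.0)
    names = FEATURE_NAMES if want_pe3 else PE2_FEATURE_NAMES
    return df[["group_id", *names, "efficiency"]]
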