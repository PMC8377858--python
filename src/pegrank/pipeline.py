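"""End-to-end orchestration: initiate → expand → rank → report.

For every variant the pipeline extracts the design window, enumerates all
spacer × extension × (ngRNA ∪ {none}) combinations, extracts features,
scores PE3 designs (those with an ngRNA) with the PE3 model and PE2
designs with the PE2 model, and emits a ranked wide table (one row per
design).  Variants with no possible design land in a skip table with a
reason.  Ties in predicted efficiency break deterministically: shorter
RTT, then PBS length closest to 13, then ngRNA nick closest to +60, then
lexicographic extension sequence.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .enumeration import DesignConfig, PegDesign, assemble_designs
from .features import FEATURE_NAMES, assemble_features
from .model import EfficiencyModel, predict
from .variants import (
    GenomicVariant,
    TargetWindow,
    _is_fasta,
    extract_window,
    load_reference,
    read_fasta_dialect,
    read_variants,
)

logger = logging.getLogger("pegrank")

TABLE_COLUMNS = [
    "variant_id",
    "strand",
    "spacer_seq",
    "pam",
    "pbs_seq",
    "rtt_seq",
    "ext_seq",
    "pegrna_full",
    "ngrna_seq",
    "ngrna_pos",
    "is_PE3b",
    "is_dPAM",
    "target_pos",
    "pbs_len",
    "rtt_len",
    "target_end_flank",
    "predicted_efficiency",
    "rank",
]

#: tie-break stand-in for the ngRNA distance term on PE2 designs
_PE2_NG_TIE = 60


def rank(
    designs: Sequence[PegDesign], scores: Sequence[float]
) -> list[int]:
    """Indices ordered by descending score with deterministic tie-breaks."""
    scores = [float(s) for s in scores]
    if not all(np.isfinite(scores)):
        raise ValueError("non-finite prediction")

    def key(i: int):
        d = designs[i]
        ng = abs(d.ngrna.ngrna_pos - 60) if d.ngrna else _PE2_NG_TIE
        return (
            -scores[i],
            d.extension.rtt_len,
            abs(d.extension.pbs_len - 13),
            ng,
            d.extension.ext_seq,
        )

    return sorted(range(len(designs)), key=key)


def _design_row(
    design: PegDesign, feats: Mapping[str, float], score: float
) -> dict:
    ng = design.ngrna
    return {
        "variant_id": design.variant_id,
        "strand": design.spacer.strand,
        "spacer_seq": design.spacer.spacer_seq,
        "pam": design.spacer.pam_seq,
        "pbs_seq": design.extension.pbs_seq,
        "rtt_seq": design.extension.rtt_seq,
        "ext_seq": design.extension.ext_seq,
        "pegrna_full": design.pegrna_full,
        "ngrna_seq": ng.spacer_seq if ng else ".",
        "ngrna_pos": int(ng.ngrna_pos) if ng else 0,
        "is_PE3b": int(feats["is_PE3b"]),
        "is_dPAM": int(feats["is_dPAM"]),
        "target_pos": int(feats["target_pos"]),
        "pbs_len": int(feats["pbs_len"]),
        "rtt_len": int(feats["rtt_len"]),
        "target_end_flank": int(feats["target_end_flank"]),
        "predicted_efficiency": round(float(score), 4),
    }


def design_variant(
    window: TargetWindow,
    model_pe2: EfficiencyModel,
    model_pe3: EfficiencyModel,
    scorer,
    config: DesignConfig = DesignConfig(),
    fold_engine: str = "nearest_neighbor",
    top_n: Optional[int] = None,
) -> pd.DataFrame:
    """Score and rank every design for one window (empty frame if none)."""
    designs = assemble_designs(window, config)
    if not designs:
        return pd.DataFrame(columns=TABLE_COLUMNS)
    feats = [
        assemble_features(d, window, scorer, fold_engine=fold_engine)
        for d in designs
    ]
    fdf = pd.DataFrame(feats)
    scores = np.empty(len(designs))
    pe3_mask = np.array([d.ngrna is not None for d in designs])
    if pe3_mask.any():
        scores[pe3_mask] = predict(model_pe3, fdf[pe3_mask])
    if (~pe3_mask).any():
        scores[~pe3_mask] = predict(model_pe2, fdf[~pe3_mask])
    order = rank(designs, scores)
    if top_n is None:
        top_n = config.top_n
    rows = []
    for r, i in enumerate(order[:top_n], start=1):
        row = _design_row(designs[i], feats[i], scores[i])
        row["rank"] = r
        rows.append(row)
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def run_design(
    variants: Sequence[GenomicVariant],
    reference: Mapping[str, object],
    model_pe2: EfficiencyModel,
    model_pe3: EfficiencyModel,
    scorer,
    config: DesignConfig = DesignConfig(),
    fold_engine: str = "nearest_neighbor",
    top_n: Optional[int] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Design and rank all variants.

    Returns (ranked design table, skip table).  Per-variant failures are
    recorded in the skip table with a reason; the run continues.
    """
    tables, skips = [], []
    for var in variants:
        try:
            window = extract_window(var, reference, flank=config.flank)
            table = design_variant(
                window,
                model_pe2,
                model_pe3,
                scorer,
                config,
                fold_engine,
                top_n,
            )
        except (ValueError, KeyError) as exc:
            logger.warning("variant %s skipped: %s", var.id, exc)
            skips.append({"variant_id": var.id, "reason": str(exc)})
            continue
        if table.empty:
            skips.append(
                {"variant_id": var.id, "reason": "no design found"}
            )
            continue
        best = table["predicted_efficiency"].iloc[0]
        logger.info("variant %s: best predicted efficiency %.2f%%", var.id, best)
        tables.append(table)
    designs = (
        pd.concat(tables, ignore_index=True)
        if tables
        else pd.DataFrame(columns=TABLE_COLUMNS)
    )
    skipdf = pd.DataFrame(skips, columns=["variant_id", "reason"])
    return designs, skipdf


def batch_mode(
    variants: Sequence[GenomicVariant],
    reference: Mapping[str, object],
    model_pe2: EfficiencyModel,
    model_pe3: EfficiencyModel,
    scorer,
    config: DesignConfig = DesignConfig(),
    fold_engine: str = "nearest_neighbor",
    efficiency_threshold: float = 40.0,
) -> tuple[dict, pd.DataFrame, pd.DataFrame]:
    """Streaming batch design with aggregate designability counts."""
    table, skipdf = run_design(
        variants, reference, model_pe2, model_pe3, scorer, config, fold_engine
    )
    designed_ids = set(table["variant_id"]) if len(table) else set()
    summary = {
        "n_variants": len(variants),
        "n_designed": len(designed_ids),
        "n_skipped": len(skipdf),
        "n_designs": int(len(table)),
        "n_pam_disrupting": int((table["is_dPAM"] == 1).sum()),
        "n_pe3b": int((table["is_PE3b"] == 1).sum()),
        "n_above_threshold": int(
            (table["predicted_efficiency"] >= efficiency_threshold).sum()
        ),
    }
    return summary, table, skipdf


def write_design_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_design_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"ngrna_seq": str})
    return df[TABLE_COLUMNS] if len(df) else df


def write_design_table_long(df: pd.DataFrame, path) -> None:
    """Optional long format: one row per design component (sgRNA, PBS,
    RTT, ngRNA), mirroring component-wise layouts."""
    rows = []
    for _, r in df.iterrows():
        key = (r["variant_id"], r["rank"])
        rows.append((*key, "sgRNA", r["spacer_seq"], r["predicted_efficiency"]))
        rows.append((*key, "PBS", r["pbs_seq"], r["predicted_efficiency"]))
        rows.append((*key, "RTT", r["rtt_seq"], r["predicted_efficiency"]))
        if r["ngrna_seq"] != ".":
            rows.append(
                (*key, "ngRNA", r["ngrna_seq"], r["predicted_efficiency"])
            )
    long_df = pd.DataFrame(
        rows,
        columns=["variant_id", "rank", "component", "seq", "predicted_efficiency"],
    )
    long_df.to_csv(path, sep="\t", index=False)


def load_inputs(
    input_path, reference_path=None, flank: int = 200
) -> tuple[list[GenomicVariant], Mapping[str, object]]:
    """Resolve CLI inputs: VCF+reference, or self-contained edit FASTA."""
    if _is_fasta(input_path):
        return read_fasta_dialect(input_path)
    if reference_path is None:
        raise ValueError("VCF input requires --reference")
    reference = load_reference(reference_path)
    return read_variants(input_path, reference), reference
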