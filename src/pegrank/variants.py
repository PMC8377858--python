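"""Variant input, reference windows, and edits in sequence space.

A desired edit is a :class:`GenomicVariant` (VCF-style: 1-based position,
ref allele observed on the reference, alt allele to install).  Design work
happens inside a :class:`TargetWindow`, the reference sequence within
``flank`` nt (default 200) of the edit.  Coordinates are 0-based half-open
internally; 1-based only at the VCF/FASTA boundary.

Two input dialects are supported:

* VCF 4.x plus a reference FASTA (multi-allelic records are expanded, one
  variant per alt allele);
* a self-contained FASTA whose record header encodes the edit as
  ``>id|pos=<1-based>|ref=<allele>|alt=<allele>`` — the record sequence is
  its own reference.
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass
from typing import Mapping

from Bio import SeqIO

logger = logging.getLogger("pegrank")

DNA_ALPHABET = frozenset("ACGT")

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N allowed)."""
    return seq.translate(_COMP)[::-1]


def _check_dna(seq: str, what: str) -> str:
    seq = seq.upper()
    if not seq or not set(seq) <= DNA_ALPHABET:
        raise ValueError(f"{what} must be nonempty A/C/G/T, got {seq!r}")
    return seq


@dataclass(frozen=True)
class GenomicVariant:
    """One desired edit: ``ref`` → ``alt`` at 1-based ``pos`` on ``chrom``.

    Pure insertions/deletions are VCF-normalized with one anchor base
    (e.g. ref="A", alt="ATT"); :func:`minimal_edit` strips the anchor for
    edit-length accounting.
    """

    id: str
    chrom: str
    pos: int  # 1-based position of the first ref base
    ref: str
    alt: str

    def __post_init__(self):
        object.__setattr__(self, "ref", _check_dna(self.ref, "ref"))
        object.__setattr__(self, "alt", _check_dna(self.alt, "alt"))
        if self.ref == self.alt:
            raise ValueError(f"variant {self.id}: ref == alt ({self.ref})")
        if self.pos < 1:
            raise ValueError(f"variant {self.id}: pos must be >= 1")

    @property
    def key(self) -> str:
        """Target-mutation key (position + target allele); the CV group id."""
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


def minimal_edit(ref: str, alt: str) -> tuple[int, str, str]:
    """Strip common prefix then common suffix of (ref, alt).

    Returns ``(offset, core_ref, core_alt)`` where ``offset`` is the number
    of leading bases shared (the anchor for VCF-style indels).  For a pure
    insertion ``core_ref`` is empty; for a pure deletion ``core_alt`` is.
    """
    p = 0
    while p < len(ref) and p < len(alt) and ref[p] == alt[p]:
        p += 1
    s = 0
    while (
        s < len(ref) - p and s < len(alt) - p and ref[-1 - s] == alt[-1 - s]
    ):
        s += 1
    return p, ref[p : len(ref) - s], alt[p : len(alt) - s]


@dataclass(frozen=True)
class TargetWindow:
    """Reference sequence around one variant.

    ``window_start`` is the 1-based reference coordinate of ``seq[0]``;
    ``edit_offset`` is the 0-based offset of the variant's first ref base
    within ``seq``.
    """

    variant: GenomicVariant
    seq: str
    window_start: int
    edit_offset: int
    flank: int = 200

    def __post_init__(self):
        v = self.variant
        got = self.seq[self.edit_offset : self.edit_offset + len(v.ref)]
        if got != v.ref:
            raise ValueError(
                f"variant {v.id}: window does not contain ref allele "
                f"({got!r} != {v.ref!r} at offset {self.edit_offset})"
            )
        if not set(self.seq) <= DNA_ALPHABET:
            raise ValueError(
                f"variant {v.id}: non-ACGT base inside design window"
            )

    @property
    def core(self) -> tuple[int, str, str]:
        """(0-based window offset, core_ref, core_alt) of the minimal edit."""
        off, cref, calt = minimal_edit(self.variant.ref, self.variant.alt)
        return self.edit_offset + off, cref, calt


def apply_edit(window: TargetWindow) -> str:
    """Window sequence with ref replaced by alt at the edit site."""
    v = window.variant
    e = window.edit_offset
    return window.seq[:e] + v.alt + window.seq[e + len(v.ref) :]


def extract_window(
    variant: GenomicVariant,
    reference: Mapping[str, object],
    flank: int = 200,
) -> TargetWindow:
    """Cut the ±``flank`` nt design window around a variant.

    ``reference`` is any mapping of contig name to a sliceable sequence
    (a ``pyfaidx.Fasta`` or a plain ``dict`` of strings).  The window is
    truncated at contig ends.  Requires ``flank >= 30`` (the smallest
    window that can hold a spacer+PAM on either side of the edit).
    """
    if flank < 30:
        raise ValueError("flank must be >= 30")
    if variant.chrom not in reference:
        raise KeyError(f"unknown contig {variant.chrom!r}")
    contig = reference[variant.chrom]
    contig_len = len(contig)
    start0 = max(0, variant.pos - 1 - flank)  # 0-based inclusive
    end0 = min(contig_len, variant.pos - 1 + len(variant.ref) + flank)
    seq = str(contig[start0:end0]).upper()
    edit_offset = variant.pos - 1 - start0
    got = seq[edit_offset : edit_offset + len(variant.ref)]
    if got != variant.ref:
        raise ValueError(
            f"variant {variant.id}: ref allele mismatch at "
            f"{variant.chrom}:{variant.pos} (reference has {got!r}, "
            f"variant says {variant.ref!r})"
        )
    if len(seq) < len(variant.ref) + 2 * 30:
        raise ValueError(
            f"variant {variant.id}: window too small "
            f"({len(seq)} nt) — no room for a spacer+PAM"
        )
    return TargetWindow(
        variant=variant,
        seq=seq,
        window_start=start0 + 1,
        edit_offset=edit_offset,
        flank=flank,
    )


def load_reference(path: str | os.PathLike) -> Mapping[str, object]:
    """Open a reference FASTA (indexed lazily via pyfaidx)."""
    from pyfaidx import Fasta

    return Fasta(str(path), sequence_always_upper=True)


# ---------------------------------------------------------------------------
# Readers / writers


def _parse_fasta_dialect(path) -> list[tuple[GenomicVariant, str]]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.description.split("|")
        kv = {}
        for f in fields[1:]:
            if "=" in f:
                k, _, v = f.partition("=")
                kv[k.strip()] = v.strip()
        missing = {"pos", "ref", "alt"} - set(kv)
        if missing:
            raise ValueError(
                f"FASTA record {rec.id!r}: header lacks {sorted(missing)} "
                "(expected >id|pos=<1-based>|ref=<seq>|alt=<seq>)"
            )
        name = fields[0].split()[0].lstrip(">")
        var = GenomicVariant(
            id=name,
            chrom=name,
            pos=int(kv["pos"]),
            ref=kv["ref"],
            alt=kv["alt"],
        )
        seq = str(rec.seq).upper()
        got = seq[var.pos - 1 : var.pos - 1 + len(var.ref)]
        if got != var.ref:
            raise ValueError(
                f"FASTA record {rec.id!r}: sequence has {got!r} at pos "
                f"{var.pos}, header says ref={var.ref!r}"
            )
        out.append((var, seq))
    return out


def _is_fasta(path) -> bool:
    name = str(path).lower()
    if name.endswith((".fa", ".fasta", ".fna")):
        return True
    if name.endswith((".vcf", ".vcf.gz", ".bcf")):
        return False
    with open(path) as fh:
        first = fh.readline()
    return first.startswith(">")


def read_variants(
    path: str | os.PathLike,
    reference: Mapping[str, object] | None = None,
) -> list[GenomicVariant]:
    """Read variants from a VCF (needs ``reference``) or edit-dialect FASTA.

    Multi-allelic VCF records are expanded to one variant per alt allele.
    Every ref allele is verified against the reference; a mismatch is a
    hard error naming the record.
    """
    if _is_fasta(path):
        variants = [v for v, _ in _parse_fasta_dialect(path)]
    else:
        if reference is None:
            raise ValueError("VCF input requires a reference FASTA")
        from cyvcf2 import VCF

        variants = []
        for rec in VCF(str(path)):
            rid = rec.ID or f"{rec.CHROM}_{rec.POS}"
            for alt in rec.ALT:
                var = GenomicVariant(
                    id=rid, chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alt=alt
                )
                if var.chrom not in reference:
                    raise KeyError(
                        f"variant {var.id}: unknown contig {var.chrom!r}"
                    )
                contig = reference[var.chrom]
                got = str(contig[var.pos - 1 : var.pos - 1 + len(var.ref)])
                got = got.upper()
                if got != var.ref:
                    raise ValueError(
                        f"variant {var.id}: REF {var.ref!r} does not match "
                        f"reference {got!r} at {var.chrom}:{var.pos}"
                    )
                variants.append(var)
    if not variants:
        warnings.warn(f"no variants parsed from {path}", stacklevel=2)
    return variants


def read_fasta_dialect(
    path: str | os.PathLike,
) -> tuple[list[GenomicVariant], dict[str, str]]:
    """Edit-dialect FASTA → (variants, {record id: sequence})."""
    pairs = _parse_fasta_dialect(path)
    return [v for v, _ in pairs], {v.chrom: s for v, s in pairs}


def write_variants_vcf(variants, path) -> None:
    """Minimal VCF 4.2 writer (CHROM POS ID REF ALT only)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\t.\t.\n"
            )


def write_variants_fasta(variants, reference, path, flank: int = 200) -> None:
    """Write variants in the edit-dialect FASTA (window-sized records)."""
    with open(path, "w") as fh:
        for v in variants:
            w = extract_window(v, reference, flank=flank)
            fh.write(
                f">{v.id}|pos={w.edit_offset + 1}|ref={v.ref}|alt={v.alt}\n"
            )
            fh.write(w.seq + "\n")
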