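"""Enumeration of pegRNA/ngRNA design candidates for one target window.

The search covers both strands.  All arithmetic is done in *oriented*
coordinates: for a minus-strand spacer the window (and the edited window)
is reverse-complemented so that the PAM strand always reads 5'→3' left to
right.  On that axis:

* a protospacer occupies ``[p, p+20)`` with its NGG PAM at ``[p+20, p+23)``;
* the SpCas9 nick falls between protospacer positions 17 and 18, i.e. at
  inter-base coordinate ``n = p + 17`` (3 nt 5' of the PAM);
* ``target_pos`` is the 1-based distance from the nick to the first edited
  base (the HEK3 "+1" convention: an edit immediately 3' of the nick has
  ``target_pos == 1``);
* the PBS is the reverse complement of the ``pbs_len`` PAM-strand bases 5'
  of the nick, and the RTT is the reverse complement of the first
  ``rtt_len`` bases of the *edited* PAM strand 3' of the nick.

ngRNAs (PE3/PE3b) are 20+NGG sites on the opposite strand; ``ngrna_pos``
is the signed distance from the pegRNA nick to the ngRNA nick measured
along the PAM strand (positive = 3' of the pegRNA nick).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

from .variants import TargetWindow, apply_edit, minimal_edit, revcomp

logger = logging.getLogger("pegrank")

SPACER_LEN = 20
PAM_LEN = 3
NICK_FROM_PROTO = 17  # nick between protospacer positions 17 and 18

#: 76-nt SpCas9 sgRNA scaffold (DNA alphabet).  With a 20-nt spacer,
#: full-pegRNA position 81 is scaffold position 61 (a G able to pair with a
#: C at the first RTT position).
DEFAULT_SCAFFOLD = (
    "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGTTATCAACTTGAAAAAGTGG"
    "CACCGAGTCGGTGC"
)
assert len(DEFAULT_SCAFFOLD) == 76 and DEFAULT_SCAFFOLD[60] == "G"


@dataclass(frozen=True)
class DesignConfig:
    """Enumeration parameter set (all ranges inclusive)."""

    pbs_min: int = 8
    pbs_max: int = 17
    rtt_min: int = 10
    rtt_max: int = 30
    ngrna_min: int = -150
    ngrna_max: int = 150
    min_end_flank: int = 5
    flank: int = 200
    scaffold: str = DEFAULT_SCAFFOLD
    pam: str = "NGG"
    top_n: int = 3

    @property
    def max_target_pos(self) -> int:
        # farthest edit the longest RTT can cover while keeping the
        # minimum downstream homology
        return self.rtt_max - self.min_end_flank

    @classmethod
    def from_file(cls, path) -> "DesignConfig":
        """Read a key=value config file (unknown keys rejected)."""
        kwargs = {}
        fields_ = cls.__dataclass_fields__
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, val = line.partition("=")
                key = key.strip()
                if key not in fields_:
                    raise ValueError(f"unknown config key {key!r}")
                typ = fields_[key].type
                kwargs[key] = (
                    val.strip() if typ == "str" else int(val.strip())
                )
        return cls(**kwargs)


@dataclass(frozen=True)
class OrientedWindow:
    """A target window viewed from one strand's PAM-strand axis."""

    strand: str  # '+' or '-'
    seq: str  # unedited, oriented 5'->3'
    edited: str  # edited, oriented 5'->3'
    core_start: int  # first edited base (inter-base point for insertions)
    core_ref_len: int  # edited-allele length on the old strand
    core_alt_len: int  # edited-allele length on the new strand


def orient(window: TargetWindow, strand: str) -> OrientedWindow:
    """View the window with ``strand`` as the PAM strand.

    The minimal edit is re-normalized (left-aligned) on the oriented
    alleles, so the "first edited base" is always read 5'→3' on the PAM
    strand; repeat-ambiguous indels thereby place symmetrically under
    reverse complement.
    """
    v = window.variant
    seq, edited = window.seq, apply_edit(window)
    if strand == "+":
        off, ref_o, alt_o = window.edit_offset, v.ref, v.alt
        T, E = seq, edited
    elif strand == "-":
        off = len(seq) - (window.edit_offset + len(v.ref))
        ref_o, alt_o = revcomp(v.ref), revcomp(v.alt)
        T, E = revcomp(seq), revcomp(edited)
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    p, cref, calt = minimal_edit(ref_o, alt_o)
    return OrientedWindow(strand, T, E, off + p, len(cref), len(calt))


@dataclass(frozen=True)
class SpacerCandidate:
    strand: str
    proto_start: int  # oriented offset of protospacer 5' end
    spacer_seq: str  # 20 nt
    pam_seq: str  # 3 nt, N-G-G on the unedited window
    nick_offset: int  # oriented inter-base coordinate of the nick
    target_pos: int  # 1-based nick -> first edited base distance
    context30: str  # 4 nt up + protospacer + PAM + 3 nt down ('N'-padded)


def find_spacers(
    window: TargetWindow, max_target_pos: int
) -> list[SpacerCandidate]:
    """All 20-nt+NGG protospacers on either strand whose nick is 5' of the
    edit with ``1 <= target_pos <= max_target_pos``."""
    out = []
    for strand in "+-":
        ov = orient(window, strand)
        T = ov.seq
        L = len(T)
        for p in range(L - SPACER_LEN - PAM_LEN + 1):
            if T[p + 21 : p + 23] != "GG":
                continue
            n = p + NICK_FROM_PROTO
            tpos = ov.core_start - n + 1
            if not (1 <= tpos <= max_target_pos):
                continue
            lo, hi = p - 4, p + SPACER_LEN + PAM_LEN + 3
            ctx = (
                "N" * max(0, -lo)
                + T[max(0, lo) : min(L, hi)]
                + "N" * max(0, hi - L)
            )
            out.append(
                SpacerCandidate(
                    strand=strand,
                    proto_start=p,
                    spacer_seq=T[p : p + SPACER_LEN],
                    pam_seq=T[p + SPACER_LEN : p + SPACER_LEN + PAM_LEN],
                    nick_offset=n,
                    target_pos=tpos,
                    context30=ctx,
                )
            )
    return out


@dataclass(frozen=True)
class Extension:
    """One 3' extension: RTT followed by PBS, read 5'→3'."""

    pbs_len: int
    rtt_len: int
    pbs_seq: str
    rtt_seq: str
    target_end_flank: int
    first_rtt_c: bool  # flagged, never filtered: the model learns the cost

    @property
    def ext_seq(self) -> str:
        return self.rtt_seq + self.pbs_seq


def enumerate_extensions(
    spacer: SpacerCandidate,
    window: TargetWindow,
    pbs_range: Iterable[int],
    rtt_range: Iterable[int],
    min_end_flank: int = 5,
) -> list[Extension]:
    """Cartesian product of PBS × RTT lengths, keeping RTTs that cover the
    whole edit with at least ``min_end_flank`` nt of downstream homology."""
    ov = orient(window, spacer.strand)
    n = spacer.nick_offset
    out = []
    for pbs_len in pbs_range:
        if n - pbs_len < 0:
            logger.debug("pbs_len %d runs off the window; skipped", pbs_len)
            continue
        pbs_seq = revcomp(ov.seq[n - pbs_len : n])
        for rtt_len in rtt_range:
            if n + rtt_len > len(ov.edited):
                logger.debug(
                    "rtt_len %d runs off the window; skipped", rtt_len
                )
                continue
            flank = rtt_len - (spacer.target_pos - 1) - ov.core_alt_len
            if flank < min_end_flank:
                continue
            rtt_seq = revcomp(ov.edited[n : n + rtt_len])
            out.append(
                Extension(
                    pbs_len=pbs_len,
                    rtt_len=rtt_len,
                    pbs_seq=pbs_seq,
                    rtt_seq=rtt_seq,
                    target_end_flank=flank,
                    first_rtt_c=rtt_seq[0] == "C",
                )
            )
    return out


@dataclass(frozen=True)
class NgRNACandidate:
    spacer_seq: str  # 20 nt on the non-edited strand
    pam_seq: str
    nick_offset: int  # cut coordinate on the pegRNA PAM-strand axis
    ngrna_pos: int  # signed nick-to-nick distance (+ = 3' of pegRNA nick)
    is_pe3b: bool  # spacer matches edited but not unedited sequence


def find_ngrnas(
    spacer: SpacerCandidate,
    window: TargetWindow,
    ngrna_pos_range: tuple[int, int] = (-150, 150),
) -> list[NgRNACandidate]:
    """All opposite-strand 20+NGG sites within the ngRNA distance range.

    Sites are scanned on both the unedited and the edited opposite strand.
    A site whose spacer occurs in the unedited sequence is an ordinary PE3
    ngRNA (distance measured pre-edit); a site that only exists after the
    edit is installed is a PE3b ngRNA (seed mismatch against unedited DNA;
    distance measured on the edited sequence).
    """
    ov = orient(window, spacer.strand)
    n = spacer.nick_offset
    lo, hi = ngrna_pos_range
    out = []
    seen = set()

    def scan(pam_strand_seq: str, edited: bool):
        U = revcomp(pam_strand_seq)
        L = len(U)
        unedited_opp = revcomp(ov.seq)
        for q in range(L - SPACER_LEN - PAM_LEN + 1):
            if U[q + 21 : q + 23] != "GG":
                continue
            sp = U[q : q + SPACER_LEN]
            in_unedited = sp in unedited_opp
            if edited and in_unedited:
                continue  # same molecular site as an unedited-derived hit
            if not edited and not in_unedited:
                raise AssertionError("unedited scan yielded foreign spacer")
            cut_own_axis = q + NICK_FROM_PROTO
            pos = (L - cut_own_axis) - n
            if not (lo <= pos <= hi):
                continue
            key = (sp, pos)
            if key in seen:
                continue
            seen.add(key)
            out.append(
                NgRNACandidate(
                    spacer_seq=sp,
                    pam_seq=U[q + SPACER_LEN : q + SPACER_LEN + PAM_LEN],
                    nick_offset=L - cut_own_axis,
                    ngrna_pos=pos,
                    is_pe3b=edited,
                )
            )

    scan(ov.seq, edited=False)
    scan(ov.edited, edited=True)
    out.sort(key=lambda g: (g.ngrna_pos, g.spacer_seq))
    return out


@dataclass(frozen=True)
class PegDesign:
    """One complete design: spacer + extension (+ optional ngRNA)."""

    variant_id: str
    spacer: SpacerCandidate
    extension: Extension
    ngrna: Optional[NgRNACandidate] = None
    scaffold: str = DEFAULT_SCAFFOLD

    @property
    def pegrna_full(self) -> str:
        """Full pegRNA 5'→3' in the RNA alphabet: spacer+scaffold+ext."""
        dna = self.spacer.spacer_seq + self.scaffold + self.extension.ext_seq
        return dna.replace("T", "U")

    @property
    def is_pe3(self) -> bool:
        return self.ngrna is not None


def reconstruct_edited_span(design: PegDesign, window: TargetWindow) -> bool:
    """Edit-installation round trip.

    Primes the PBS at the nick it anneals to on the unedited PAM strand,
    reverse-transcribes the RTT into a 3' flap, and checks that nick-prefix
    plus flap reproduces ``apply_edit(window)`` over the covered interval.
    """
    ov = orient(window, design.spacer.strand)
    ext = design.extension
    n = design.spacer.nick_offset
    if revcomp(ext.pbs_seq) != ov.seq[n - ext.pbs_len : n]:
        return False
    flap = revcomp(ext.rtt_seq)
    covered = n + ext.rtt_len
    return ov.seq[:n] + flap == ov.edited[:covered]


def assemble_designs(
    window: TargetWindow, config: DesignConfig = DesignConfig()
) -> list[PegDesign]:
    """All spacer × extension × (ngRNA ∪ {no-ngRNA}) combinations.

    The PE2 design (no ngRNA) is always emitted alongside the PE3 designs
    for every spacer/extension pair.  Returns an empty list when the
    variant is undesignable (no reachable PAM, or no RTT can cover the
    edit)."""
    designs: list[PegDesign] = []
    spacers = find_spacers(window, config.max_target_pos)
    for sp in spacers:
        exts = enumerate_extensions(
            sp,
            window,
            range(config.pbs_min, config.pbs_max + 1),
            range(config.rtt_min, config.rtt_max + 1),
            config.min_end_flank,
        )
        ngrnas: list[Optional[NgRNACandidate]] = [None]
        ngrnas += find_ngrnas(sp, window, (config.ngrna_min, config.ngrna_max))
        for ext in exts:
            for ng in ngrnas:
                designs.append(
                    PegDesign(
                        variant_id=window.variant.id,
                        spacer=sp,
                        extension=ext,
                        ngrna=ng,
                        scaffold=config.scaffold,
                    )
                )
    logger.info(
        "variant %s: %d spacers, %d designs",
        window.variant.id,
        len(spacers),
        len(designs),
    )
    return designs
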