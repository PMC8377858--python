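"""pegRNA secondary structure: base-pair probabilities and disruption scores.

A pegRNA's 3' extension can base-pair with the sgRNA scaffold and disrupt
the fold Cas9 requires (the classic case: a C at the first RTT position
pairing with the scaffold G at full-pegRNA position 81).  The per-position
RNA-folding disruption score

    D(i) = max_j P(ext_i, scaffold_j)

is the maximal equilibrium pairing probability between extension position
``i`` (counted 5'→3' from the scaffold end, continuing into the PBS when
the RTT is shorter than ``i``) and any scaffold position.

Three engines compute the base-pair probability matrix P:

* ``simple`` — an exact McCaskill partition function over a minimal energy
  model (every Watson-Crick or GU pair contributes energy −1, kT = 1, no
  stacking, hairpin loops ≥ 3).  Small enough to verify against exhaustive
  structure enumeration.
* ``nearest_neighbor`` (alias ``vienna``) — the ViennaRNA Turner-model
  partition function via the Python bindings.
* ``external`` — shells out to ``RNAplfold`` with a full-length window and
  parses the dot plot (the probabilities then coincide with a global fold).
"""

from __future__ import annotations

import math
import os
import subprocess
import tempfile
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

RNA_ALPHABET = frozenset("ACGU")

#: Boltzmann weight of one pair in the simple engine (energy −1, kT 1).
PAIR_WEIGHT = math.e

#: minimum hairpin loop size: i and j can pair only if j − i ≥ 4
MIN_LOOP = 3

_CAN_PAIR = frozenset(
    [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
)


def can_pair(a: str, b: str) -> bool:
    """Watson-Crick or GU wobble."""
    return (a, b) in _CAN_PAIR


@dataclass(frozen=True)
class BasePairProbMatrix:
    """P(i, j) over a full RNA sequence, 1-based symmetric."""

    seq: str
    P: np.ndarray  # (n+1, n+1); row/col 0 unused

    def prob(self, i: int, j: int) -> float:
        return float(self.P[i, j])

    def __len__(self) -> int:
        return len(self.seq)

    def dump(self, path, cutoff: float = 1e-6) -> None:
        """Plain-text dump: one ``i j P(i,j)`` line per pair above cutoff."""
        n = len(self.seq)
        with open(path, "w") as fh:
            fh.write(f"# seq {self.seq}\n")
            for i in range(1, n + 1):
                for j in range(i + 1, n + 1):
                    if self.P[i, j] >= cutoff:
                        fh.write(f"{i}\t{j}\t{self.P[i, j]:.10g}\n")


def _check_rna(seq: str, max_len: int) -> str:
    seq = seq.upper().replace("T", "U")
    if len(seq) < 8:
        raise ValueError("sequence too short to fold (< 8 nt)")
    if len(seq) > max_len:
        raise ValueError(f"sequence longer than the {max_len}-nt cap")
    if not set(seq) <= RNA_ALPHABET:
        raise ValueError(f"invalid RNA alphabet in {seq!r}")
    return seq


# ---------------------------------------------------------------------------
# simple engine: exact partition function over the −1-per-pair model


def _simple_bpp(seq: str, pair_weight: float = PAIR_WEIGHT) -> np.ndarray:
    n = len(seq)
    s = " " + seq  # 1-based
    w = pair_weight
    pairable = np.zeros((n + 2, n + 2))
    for i in range(1, n + 1):
        for j in range(i + MIN_LOOP + 1, n + 1):
            if can_pair(s[i], s[j]):
                pairable[i, j] = 1.0

    # inside: Z[i, j] = partition function on [i, j]; empty interval = 1
    Z = np.ones((n + 2, n + 2))
    Zb = np.zeros((n + 2, n + 2))  # i pairs j
    for span in range(1, n):
        for i in range(1, n - span + 1):
            j = i + span
            if pairable[i, j]:
                Zb[i, j] = w * Z[i + 1, j - 1]
            # j unpaired, or paired to some k in [i, j-4]
            acc = Z[i, j - 1]
            ks = np.arange(i, j - MIN_LOOP)
            if ks.size:
                acc += float(
                    np.dot(Z[i, ks - 1] * pairable[ks, j], w * Z[ks + 1, j - 1])
                )
            Z[i, j] = acc
    Ztot = Z[1, n]

    # outside: Q[a, b] = weight of all conformations of the complement of
    # [a, b] compatible with (a, b) pairing.  Immediate enclosing pairs are
    # pushed down as outer-product contributions, largest spans first.
    P = np.zeros((n + 1, n + 1))
    T = np.zeros((n + 2, n + 2))
    for span in range(n - 1, MIN_LOOP, -1):
        for a in range(1, n - span + 1):
            b = a + span
            if not pairable[a, b]:
                continue
            q = Z[1, a - 1] * Z[b + 1, n] + T[a, b]
            P[a, b] = Zb[a, b] * q / Ztot
            if a + 1 <= b - 1:
                inner = np.arange(a + 1, b)
                r = Z[a + 1, inner - 1]  # Z(a+1 .. a'-1)
                c = Z[inner + 1, b - 1]  # Z(b'+1 .. b-1)
                T[a + 1 : b, a + 1 : b] += w * q * np.outer(r, c)
    P = P + P.T
    out = np.zeros((n + 1, n + 1))
    out[1:, 1:] = P[1:, 1:]
    return out


# ---------------------------------------------------------------------------
# ViennaRNA engines


def _vienna_bpp(seq: str) -> np.ndarray:
    try:
        import RNA
    except ImportError as exc:  # pragma: no cover
        raise RuntimeError(
            "the nearest_neighbor engine needs the ViennaRNA python "
            "bindings; use engine='simple' or engine='external'"
        ) from exc
    fc = RNA.fold_compound(seq)
    fc.pf()
    raw = fc.bpp()  # (n+1) x (n+1) upper triangle, 1-based
    n = len(seq)
    P = np.zeros((n + 1, n + 1))
    for i in range(1, n + 1):
        row = raw[i]
        for j in range(i + 1, n + 1):
            p = row[j]
            if p > 0:
                P[i, j] = P[j, i] = p
    return P


def _rnaplfold_bpp(seq: str) -> np.ndarray:
    n = len(seq)
    with tempfile.TemporaryDirectory() as tmp:
        proc = subprocess.run(
            ["RNAplfold", "-W", str(n), "-c", "1e-6"],
            input=f">pegrna\n{seq}\n",
            text=True,
            capture_output=True,
            cwd=tmp,
        )
        if proc.returncode != 0:  # pragma: no cover
            raise RuntimeError(f"RNAplfold failed: {proc.stderr}")
        ps = os.path.join(tmp, "pegrna_dp.ps")
        P = np.zeros((n + 1, n + 1))
        with open(ps) as fh:
            for line in fh:
                if line.rstrip().endswith("ubox"):
                    parts = line.split()
                    if len(parts) == 4:
                        i, j, v = int(parts[0]), int(parts[1]), float(parts[2])
                        P[i, j] = P[j, i] = v * v  # dot plot stores sqrt(P)
    return P


_ENGINES = {
    "simple": _simple_bpp,
    "vienna": _vienna_bpp,
    "nearest_neighbor": _vienna_bpp,
    "external": _rnaplfold_bpp,
}


@lru_cache(maxsize=4096)
def _compute_bpp_cached(seq: str, engine: str) -> BasePairProbMatrix:
    return BasePairProbMatrix(seq=seq, P=_ENGINES[engine](seq))


def compute_bpp(
    seq: str, engine: str = "nearest_neighbor", max_len: int = 500
) -> BasePairProbMatrix:
    """Base-pair probability matrix of an RNA (T silently mapped to U)."""
    if engine not in _ENGINES:
        raise ValueError(
            f"unknown engine {engine!r}; choose from {sorted(_ENGINES)}"
        )
    return _compute_bpp_cached(_check_rna(seq, max_len), engine)


# ---------------------------------------------------------------------------
# disruption scores


@dataclass(frozen=True)
class PegLayout:
    """1-based index ranges of the pegRNA parts within the full sequence."""

    spacer_len: int
    scaffold_len: int
    ext_len: int

    @property
    def scaffold_range(self) -> tuple[int, int]:
        return self.spacer_len + 1, self.spacer_len + self.scaffold_len

    @property
    def ext_start(self) -> int:
        return self.spacer_len + self.scaffold_len + 1


@dataclass(frozen=True)
class DisruptionProfile:
    D: np.ndarray  # D[i-1] = score of extension position i
    layout: PegLayout


def disruption_scores(
    bpp: BasePairProbMatrix, layout: PegLayout, k: int = 10
) -> DisruptionProfile:
    """D(i) = max over scaffold positions j of P(extension_i, j), i = 1..k.

    Extension position ``i`` counts 5'→3' along RTT+PBS; positions beyond
    the extension length score 0.
    """
    n = len(bpp.seq)
    total = layout.spacer_len + layout.scaffold_len + layout.ext_len
    if total != n:
        raise ValueError(
            f"layout ({total} nt) inconsistent with matrix ({n} nt)"
        )
    if layout.ext_len < 1:
        raise ValueError("extension must be at least 1 nt")
    lo, hi = layout.scaffold_range
    D = np.zeros(k)
    for i in range(1, k + 1):
        if i <= layout.ext_len:
            row = layout.ext_start + i - 1
            D[i - 1] = float(bpp.P[row, lo : hi + 1].max())
    return DisruptionProfile(D=D, layout=layout)


def position_correlation_profile(
    d_matrix,
    efficiencies,
    positions: int = 16,
    n_permutations: int = 1000,
    seed: int = 0,
):
    """Spearman correlation of D(i) with efficiency, per extension position.

    ``d_matrix`` is (n_obs, >= positions); needs at least 20 observations.
    Each position gets a permutation p-value (efficiencies shuffled).
    Constant D(i) columns are reported as NaN.
    Returns a DataFrame (position, rho, p_perm, n).
    """
    import pandas as pd
    from scipy.stats import spearmanr

    d_matrix = np.asarray(d_matrix, dtype=float)
    y = np.asarray(efficiencies, dtype=float)
    if len(y) < 20:
        raise ValueError("need at least 20 observations")
    if d_matrix.shape[1] < positions:
        raise ValueError("d_matrix has fewer columns than requested positions")
    rng = np.random.default_rng(seed)
    perms = [rng.permutation(y) for _ in range(n_permutations)]
    rows = []
    for i in range(positions):
        col = d_matrix[:, i]
        if np.ptp(col) == 0:
            rows.append((i + 1, float("nan"), float("nan"), len(y)))
            continue
        rho = spearmanr(col, y).statistic
        null = np.array([spearmanr(col, p).statistic for p in perms])
        pval = (1 + np.sum(np.abs(null) >= abs(rho))) / (1 + n_permutations)
        rows.append((i + 1, float(rho), float(pval), len(y)))
    return pd.DataFrame(rows, columns=["position", "rho", "p_perm", "n"])
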