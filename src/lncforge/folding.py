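"""Minimum-free-energy folding by nested base-pairing dynamic programming.

The folder minimizes the sum of base-pair energies over all pseudoknot-free
(nested) pairings with a minimum hairpin loop size.  The default energy
model assigns GC = -3, AU = -2 and GU = -1 kcal/mol per pair, with no
stacking or loop terms: the pipeline needs a consistent, comparable MFE for
native-versus-mutated comparisons, not thermodynamic fidelity, and the pure
pair-energy model is exactly verifiable against exhaustive enumeration of
structures.  DNA input is accepted; T is treated as U for pairing.

The optimum is computed with the interval recurrence

    E[i][j] = min( E[i+1][j],
                   min_{k} e(i,k) + E[i+1][k-1] + E[k+1][j] )

over partners ``k`` with ``k - i > min_loop`` and an allowed pair (i,k).
Traceback ties are broken deterministically: pairing beats leaving ``i``
unpaired, and the smallest admissible partner wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .intervals import ValidationError

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}


def _default_pair_energies() -> dict:
    return {("G", "C"): -3.0, ("A", "U"): -2.0, ("G", "U"): -1.0}


@dataclass(frozen=True)
class EnergyModel:
    """Pair energies in kcal/mol (symmetric; unlisted pairs are forbidden)."""

    pair_energies: dict = field(default_factory=_default_pair_energies)
    min_loop: int = 3

    def matrix(self) -> np.ndarray:
        """4x4 pair-energy matrix indexed by A,C,G,U; +inf = forbidden."""
        mat = np.full((4, 4), np.inf)
        for (a, b), e in self.pair_energies.items():
            ia, ib = _BASE_INDEX[a], _BASE_INDEX[b]
            mat[ia, ib] = e
            mat[ib, ia] = e
        return mat


DEFAULT_MODEL = EnergyModel()


@dataclass
class FoldResult:
    """An optimal nested pairing and its energy."""

    mfe: float
    pairing: tuple  # ((i, j), ...) with i < j, 0-based
    sequence_length: int

    def dot_bracket(self) -> str:
        chars = ["."] * self.sequence_length
        for i, j in self.pairing:
            chars[i] = "("
            chars[j] = ")"
        return "".join(chars)


def encode_sequence(sequence: str) -> np.ndarray:
    seq = sequence.upper()
    try:
        return np.array([_BASE_INDEX[b] for b in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValidationError(f"invalid base {exc.args[0]!r} in fold input") from None


@njit(cache=False)
def _fold_table(codes, pair_mat, min_loop):  # pragma: no cover - numba kernel
    n = codes.shape[0]
    E = np.zeros((n, n))
    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span
            best = E[i + 1, j] if i + 1 <= j else 0.0
            for k in range(i + min_loop + 1, j + 1):
                e = pair_mat[codes[i], codes[k]]
                if e < np.inf:
                    total = e
                    if k - 1 >= i + 1:
                        total += E[i + 1, k - 1]
                    if k + 1 <= j:
                        total += E[k + 1, j]
                    if total < best:
                        best = total
            E[i, j] = best
    return E


def _traceback(E, codes, pair_mat, min_loop) -> list:
    n = codes.shape[0]
    pairs = []
    stack = [(0, n - 1)]
    tol = 1e-9
    while stack:
        i, j = stack.pop()
        if i >= j:
            continue
        target = E[i, j]
        chosen = None
        for k in range(i + min_loop + 1, j + 1):
            e = pair_mat[codes[i], codes[k]]
            if not np.isfinite(e):
                continue
            total = e
            if k - 1 >= i + 1:
                total += E[i + 1, k - 1]
            if k + 1 <= j:
                total += E[k + 1, j]
            if abs(total - target) <= tol:
                chosen = k
                break
        if chosen is not None:
            pairs.append((i, chosen))
            stack.append((i + 1, chosen - 1))
            stack.append((chosen + 1, j))
        else:
            stack.append((i + 1, j))
    return sorted(pairs)


def fold_mfe(sequence: str, model: EnergyModel = DEFAULT_MODEL) -> FoldResult:
    """Fold a sequence; returns the MFE (<= 0) and one optimal nested pairing."""
    if len(sequence) == 0:
        raise ValidationError("cannot fold an empty sequence")
    codes = encode_sequence(sequence)
    n = codes.shape[0]
    if n <= model.min_loop + 1:
        return FoldResult(mfe=0.0, pairing=(), sequence_length=n)
    pair_mat = model.matrix()
    E = _fold_table(codes, pair_mat, model.min_loop)
    pairs = _traceback(E, codes, pair_mat, model.min_loop)
    mfe = float(E[0, n - 1])
    return FoldResult(mfe=mfe, pairing=tuple(pairs), sequence_length=n)


def pairing_energy(sequence: str, pairing, model: EnergyModel = DEFAULT_MODEL) -> float:
    """Energy of an explicit pairing (used to check traceback consistency)."""
    codes = encode_sequence(sequence)
    mat = model.matrix()
    total = 0.0
    for i, j in pairing:
        e = mat[codes[i], codes[j]]
        if not np.isfinite(e):
            raise ValidationError(f"forbidden pair at ({i}, {j})")
        total += e
    return total
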