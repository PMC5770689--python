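"""Minimum-free-energy folding of short RNAs under a simple pair-energy model.

The folder predicts a pseudoknot-free secondary structure by Nussinov-style
dynamic programming over a base-pair energy table (GC, AU and GU wobble
pairs), with a minimum hairpin-loop size. It is intended as a fast,
fully-specified proxy for 5'-UTR structural stability: absolute energies are
in model units, so only comparisons *within* one run (e.g. regulated versus
non-regulated UTR distributions) are meaningful. The backend is pluggable —
any callable mapping a sequence to a ``FoldResult`` can stand in for
:func:`mfe_fold` downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .utr import normalize_rna

__all__ = ["EnergyModel", "FoldResult", "mfe_fold", "brute_force_mfe"]

_TIE_TOL = 1e-9


@dataclass(frozen=True)
class EnergyModel:
    """Symmetric base-pair energies (model units, negative = stabilizing).

    Parameters
    ----------
    pair_energies:
        Map from two-letter pair (alphabetically sorted, e.g. ``"GU"``) to
        energy. Defaults: GC -3.0, AU -2.0, GU -1.0.
    min_hairpin:
        Minimum number of unpaired bases enclosed by any pair (default 3).
    max_len:
        Sequences longer than this are refused rather than truncated.
    """

    pair_energies: dict[str, float] = field(
        default_factory=lambda: {"CG": -3.0, "AU": -2.0, "GU": -1.0}
    )
    min_hairpin: int = 3
    max_len: int = 5000

    def __post_init__(self) -> None:
        if self.min_hairpin < 0:
            raise ValueError("min_hairpin must be >= 0")
        for pair, e in self.pair_energies.items():
            if not e < 0:
                raise ValueError(f"pair energy for {pair!r} must be negative")

    def energy(self, a: str, b: str) -> float:
        """Energy of pairing bases ``a`` and ``b``; +inf if unpairable."""
        return self.pair_energies.get("".join(sorted((a, b))), np.inf)


DEFAULT_MODEL = EnergyModel()


@dataclass(frozen=True)
class FoldResult:
    delta_g: float
    structure: str

    def pairs(self) -> list[tuple[int, int]]:
        """Base pairs as 0-based (i, j) tuples recovered from dot-bracket."""
        stack: list[int] = []
        out = []
        for i, c in enumerate(self.structure):
            if c == "(":
                stack.append(i)
            elif c == ")":
                out.append((stack.pop(), i))
        return sorted(out)


def _pair_matrix(seq: str, model: EnergyModel) -> np.ndarray:
    n = len(seq)
    P = np.full((n, n), np.inf)
    for i in range(n):
        for j in range(i + model.min_hairpin + 1, n):
            P[i, j] = model.energy(seq[i], seq[j])
    return P


def mfe_fold(seq: str, model: EnergyModel = DEFAULT_MODEL) -> FoldResult:
    """Fold ``seq`` to its minimum pair-energy structure.

    Dynamic programming over intervals (O(n^3) time, O(n^2) memory) with a
    deterministic traceback: when energies tie, leaving the interval's 3'
    base unpaired is preferred, then pairing it with the 5'-most admissible
    partner. ``N`` bases never pair. A sequence with no admissible pair
    returns ``delta_g=0`` and an all-dot structure.
    """
    s = normalize_rna(seq)
    n = len(s)
    if n > model.max_len:
        raise ValueError(f"sequence length {n} exceeds cap {model.max_len}")
    if n == 0:
        return FoldResult(0.0, "")
    mh = model.min_hairpin
    P = _pair_matrix(s, model)
    # E[a, b+1] = MFE of s[a..b] inclusive; empty/short intervals are 0.
    E = np.zeros((n + 1, n + 1))
    for span in range(mh + 1, n):
        i = np.arange(0, n - span)
        j = i + span
        best = E[i, j].copy()  # j unpaired
        for d in range(0, span - mh):
            k = i + d
            cand = E[i, k] + E[k + 1, j] + P[k, j]
            np.minimum(best, cand, out=best)
        E[i, j + 1] = best

    # traceback
    struct = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        a, b = stack.pop()
        if b - a <= mh:
            continue
        e = E[a, b + 1]
        if e >= -_TIE_TOL:
            continue
        if abs(e - E[a, b]) <= _TIE_TOL:
            stack.append((a, b - 1))
            continue
        for k in range(a, b - mh):
            if np.isfinite(P[k, b]) and abs(E[a, k] + E[k + 1, b] + P[k, b] - e) <= _TIE_TOL:
                struct[k], struct[b] = "(", ")"
                stack.append((a, k - 1))
                stack.append((k + 1, b - 1))
                break
        else:  # pragma: no cover - would indicate a DP/traceback mismatch
            raise AssertionError("traceback failed to reproduce DP energy")
    return FoldResult(float(E[0, n]), "".join(struct))


def brute_force_mfe(
    seq: str, model: EnergyModel = DEFAULT_MODEL, max_len: int = 22
) -> FoldResult:
    """Exhaustive-enumeration oracle for :func:`mfe_fold`.

    Recursively enumerates every pseudoknot-free pairing that respects the
    hairpin constraint (no memoization, leftmost-base decomposition — a
    different recursion than the production DP) and returns the minimum
    total energy. Guarded to short sequences.
    """
    s = normalize_rna(seq)
    n = len(s)
    if n > max_len:
        raise ValueError(f"brute force limited to length {max_len}, got {n}")
    mh = model.min_hairpin

    def rec(a: int, b: int) -> tuple[float, list[tuple[int, int]]]:
        if b - a <= mh:
            return 0.0, []
        # leftmost base unpaired
        best_e, best_p = rec(a + 1, b)
        # or paired with every admissible partner
        for k in range(a + mh + 1, b + 1):
            e_pair = model.energy(s[a], s[k])
            if not np.isfinite(e_pair):
                continue
            e1, p1 = rec(a + 1, k - 1)
            e2, p2 = rec(k + 1, b)
            e = e_pair + e1 + e2
            if e < best_e - _TIE_TOL:
                best_e, best_p = e, [(a, k), *p1, *p2]
        return best_e, best_p

    e, pairs = rec(0, n - 1)
    struct = ["."] * n
    for i, j in pairs:
        struct[i], struct[j] = "(", ")"
    return FoldResult(float(e), "".join(struct))
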