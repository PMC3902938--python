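"""Secondary-structure pseudo-energy via a maximum base-pairing DP.

This is a deterministic proxy for thermodynamic folding: a Nussinov-style
dynamic program over Watson-Crick plus G:U wobble pairs (minimum hairpin
loop of 3 unpaired bases) that additionally rewards helix stacking.  The
score of a structure is ``pair_bonus`` per base pair plus ``stack_bonus``
per stacked pair (a pair (i, j) whose enclosing pair (i-1, j+1) is also
formed); the reported pseudo-energy is minus the optimal score, so lower
means more structured.  Values are in arbitrary units, not kcal/mol.
"""

from __future__ import annotations

import numpy as np

NEG = -1_000_000.0

# A=0 C=1 G=2 U=3, N=4 (unpairable)
_ENCODE = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}

_CAN_PAIR = np.zeros((5, 5), dtype=np.bool_)
for _a, _b in ((0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)):  # AU, CG, GU
    _CAN_PAIR[_a, _b] = True


def _pairing_dp_py(code: np.ndarray, pair_bonus: float, stack_bonus: float) -> float:
    n = code.shape[0]
    V = np.full((n, n), NEG)
    W = np.zeros((n, n))
    for span in range(4, n):
        for i in range(n - span):
            j = i + span
            if _CAN_PAIR[code[i], code[j]]:
                best_in = W[i + 1, j - 1]
                if V[i + 1, j - 1] > NEG / 2:
                    stacked = V[i + 1, j - 1] + stack_bonus
                    if stacked > best_in:
                        best_in = stacked
                V[i, j] = pair_bonus + best_in
            best = W[i + 1, j]
            for k in range(i + 4, j + 1):
                if V[i, k] > NEG / 2:
                    cand = V[i, k] + (W[k + 1, j] if k + 1 <= j else 0.0)
                    if cand > best:
                        best = cand
            W[i, j] = best
    return W[0, n - 1] if n > 1 else 0.0


try:  # numba gives ~100x on long windows; plain python remains the fallback
    from numba import njit

    _pairing_dp = njit(cache=True)(_pairing_dp_py)
except Exception:  # pragma: no cover - numba present in supported envs
    _pairing_dp = _pairing_dp_py


def pairing_pseudo_energy(
    seq: str,
    pair_bonus: float = 1.0,
    stack_bonus: float = 1.0,
    max_window: int | None = None,
) -> float:
    """Pseudo-energy of ``seq`` (RNA string); 0.0 for sequences < 8 nt.

    ``max_window`` folds only the first ``max_window`` nt (the DP is
    cubic in length); None folds the whole sequence.
    """
    if len(seq) < 8:
        return 0.0
    if max_window is not None and len(seq) > max_window:
        seq = seq[:max_window]
    code = np.array([_ENCODE.get(b, 4) for b in seq], dtype=np.int8)
    score = float(_pairing_dp(code, float(pair_bonus), float(stack_bonus)))
    return -score
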