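"""RNA secondary-structure prediction for hairpin evaluation.

The bundled backend is a Zuker-style minimum-free-energy dynamic program
with simplified Turner-style nearest-neighbour parameters: stacking
energies for Watson-Crick and G:U pairs, tabulated hairpin/bulge/interior
loop penalties with logarithmic extrapolation, a linear multiloop model,
and no pseudoknots.  Interior loops are bounded at MAXLOOP unpaired
nucleotides, the standard restriction.  Energies are in kcal/mol at 37C.

Absolute energies are backend-dependent; the pipeline therefore treats the
free-energy threshold as configurable and the testable contract between
backends is pass/fail agreement at the threshold, not numeric equality.
An external ViennaRNA backend is available behind the same contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .seqs import normalize, to_rna

INF = 1e9
MAXLOOP = 12
_ENC = {"A": 0, "C": 1, "G": 2, "T": 3}

# pair type indices: CG GC GT TG AT TA
_PIDX = -np.ones((4, 4), dtype=np.int64)
for _k, (_a, _b) in enumerate([(1, 2), (2, 1), (2, 3), (3, 2), (0, 3), (3, 0)]):
    _PIDX[_a, _b] = _k

# stacking free energies, outer pair (rows) over inner pair (cols)
_STACK = np.array(
    [
        # CG     GC     GU     UG     AU     UA
        [-3.3, -2.4, -2.1, -1.4, -2.1, -2.1],  # CG
        [-3.4, -3.3, -2.5, -1.5, -2.2, -2.4],  # GC
        [-2.5, -2.1, -1.4, 0.3, -1.4, -1.3],  # GU
        [-2.1, -1.4, -0.6, -0.5, -1.0, -0.6],  # UG
        [-2.4, -2.2, -1.4, -1.0, -1.1, -0.9],  # AU
        [-2.1, -2.1, -1.3, -0.8, -1.3, -0.6],  # UA
    ]
)

_HAIRPIN = np.array([INF, INF, INF, 5.4, 5.6, 5.7, 5.4, 6.0, 5.5, 6.4])
_BULGE = np.array([INF, 3.8, 2.8, 3.2, 3.6, 4.0, 4.4])
_INTERNAL = np.array([INF, INF, 1.0, 1.8, 2.0, 2.2, 2.5])
_LOG_EXTRAP = 1.08  # 1.75 * RT at 37C
_ASYM = 0.6
_ASYM_CAP = 3.0
_MA, _MB, _MC = 3.4, 0.4, 0.1


@njit(cache=True)
def _hairpin_e(n):
    if n < 3:
        return INF
    if n <= 9:
        return _HAIRPIN[n]
    return _HAIRPIN[9] + _LOG_EXTRAP * math.log(n / 9.0)


@njit(cache=True)
def _bulge_e(n):
    if n <= 6:
        return _BULGE[n]
    return _BULGE[6] + _LOG_EXTRAP * math.log(n / 6.0)


@njit(cache=True)
def _internal_e(n1, n2):
    n = n1 + n2
    if n <= 6:
        e = _INTERNAL[n]
    else:
        e = _INTERNAL[6] + _LOG_EXTRAP * math.log(n / 6.0)
    asym = _ASYM * abs(n1 - n2)
    if asym > _ASYM_CAP:
        asym = _ASYM_CAP
    return e + asym


@njit(cache=True)
def _loop_e(lu, ru, p1, p2):
    """Energy of the interior loop/stack closed by pair types p1 (outer)
    and p2 (inner) with lu/ru unpaired nucleotides on each side."""
    if lu == 0 and ru == 0:
        return _STACK[p1, p2]
    if lu == 0 or ru == 0:
        sz = lu + ru
        e = _bulge_e(sz)
        if sz == 1:
            e += _STACK[p1, p2]
        return e
    return _internal_e(lu, ru)


@njit(cache=True)
def _fill(s):
    n = s.shape[0]
    V = np.full((n, n), INF)
    WM = np.full((n, n), INF)
    for span in range(1, n):
        for i in range(n - span):
            j = i + span
            p1 = _PIDX[s[i], s[j]]
            if p1 >= 0 and span >= 4:
                best = _hairpin_e(j - i - 1)
                pmax = i + MAXLOOP + 1
                if pmax > j - 4:
                    pmax = j - 4
                for p in range(i + 1, pmax + 1):
                    lu = p - i - 1
                    qmin = j - 1 - (MAXLOOP - lu)
                    if qmin < p + 4:
                        qmin = p + 4
                    for q in range(qmin, j):
                        p2 = _PIDX[s[p], s[q]]
                        if p2 < 0 or V[p, q] >= INF / 2:
                            continue
                        e = V[p, q] + _loop_e(lu, j - q - 1, p1, p2)
                        if e < best:
                            best = e
                for k in range(i + 2, j - 2):
                    if WM[i + 1, k] < INF / 2 and WM[k + 1, j - 1] < INF / 2:
                        e = WM[i + 1, k] + WM[k + 1, j - 1] + _MA + _MB
                        if e < best:
                            best = e
                V[i, j] = best
            # multiloop partial: at least one branch inside [i, j]
            wm = INF
            if V[i, j] < INF / 2:
                wm = V[i, j] + _MB
            if WM[i + 1, j] + _MC < wm:
                wm = WM[i + 1, j] + _MC
            if WM[i, j - 1] + _MC < wm:
                wm = WM[i, j - 1] + _MC
            for k in range(i + 1, j):
                if WM[i, k] < INF / 2 and WM[k + 1, j] < INF / 2:
                    e = WM[i, k] + WM[k + 1, j]
                    if e < wm:
                        wm = e
            WM[i, j] = wm
    W = np.zeros(n + 1)
    for j in range(n):
        best = W[j]
        for i in range(0, j - 3):
            if V[i, j] < INF / 2 and W[i] + V[i, j] < best:
                best = W[i] + V[i, j]
        W[j + 1] = best
    return V, WM, W


_EPS = 1e-6


def _traceback(s: np.ndarray, V: np.ndarray, WM: np.ndarray, W: np.ndarray) -> list[int]:
    n = s.shape[0]
    pairs = [-1] * n
    tasks: list[tuple[str, int, int]] = []
    j = n - 1
    while j >= 0:
        if abs(W[j + 1] - W[j]) < _EPS:
            j -= 1
            continue
        for i in range(0, j - 3):
            if V[i, j] < INF / 2 and abs(W[i] + V[i, j] - W[j + 1]) < _EPS:
                tasks.append(("V", i, j))
                j = i - 1
                break
        else:  # pragma: no cover - numerical safety
            j -= 1
    while tasks:
        kind, i, j = tasks.pop()
        if kind == "V":
            pairs[i], pairs[j] = j, i
            p1 = _PIDX[s[i], s[j]]
            if abs(V[i, j] - _hairpin_e(j - i - 1)) < _EPS:
                continue
            found = False
            pmax = min(i + MAXLOOP + 1, j - 4)
            for p in range(i + 1, pmax + 1):
                lu = p - i - 1
                qmin = max(p + 4, j - 1 - (MAXLOOP - lu))
                for q in range(qmin, j):
                    p2 = _PIDX[s[p], s[q]]
                    if p2 < 0 or V[p, q] >= INF / 2:
                        continue
                    if abs(V[p, q] + _loop_e(lu, j - q - 1, p1, p2) - V[i, j]) < _EPS:
                        tasks.append(("V", p, q))
                        found = True
                        break
                if found:
                    break
            if found:
                continue
            for k in range(i + 2, j - 2):
                if (
                    WM[i + 1, k] < INF / 2
                    and WM[k + 1, j - 1] < INF / 2
                    and abs(WM[i + 1, k] + WM[k + 1, j - 1] + _MA + _MB - V[i, j]) < _EPS
                ):
                    tasks.append(("M", i + 1, k))
                    tasks.append(("M", k + 1, j - 1))
                    break
        else:  # WM
            while True:
                if V[i, j] < INF / 2 and abs(V[i, j] + _MB - WM[i, j]) < _EPS:
                    tasks.append(("V", i, j))
                    break
                if i + 1 <= j and abs(WM[i + 1, j] + _MC - WM[i, j]) < _EPS:
                    i += 1
                    continue
                if j - 1 >= i and abs(WM[i, j - 1] + _MC - WM[i, j]) < _EPS:
                    j -= 1
                    continue
                done = False
                for k in range(i + 1, j):
                    if (
                        WM[i, k] < INF / 2
                        and WM[k + 1, j] < INF / 2
                        and abs(WM[i, k] + WM[k + 1, j] - WM[i, j]) < _EPS
                    ):
                        tasks.append(("M", i, k))
                        tasks.append(("M", k + 1, j))
                        done = True
                        break
                if done:
                    break
                break  # pragma: no cover - numerical safety
    return pairs


@dataclass(frozen=True)
class FoldResult:
    """A minimum-free-energy structure in dot-bracket form with its energy."""

    structure: str
    delta_g: float

    def pairs(self) -> list[int]:
        """Partner index per position (-1 if unpaired)."""
        pairs = [-1] * len(self.structure)
        stack: list[int] = []
        for i, c in enumerate(self.structure):
            if c == "(":
                stack.append(i)
            elif c == ")":
                j = stack.pop()
                pairs[i], pairs[j] = j, i
        if stack:
            raise ValueError("unbalanced dot-bracket structure")
        return pairs


def _encode(sequence: str) -> np.ndarray:
    seq = normalize(sequence)
    try:
        return np.array([_ENC[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-ACGT character in sequence: {exc}") from exc


def fold_builtin(sequence: str) -> FoldResult:
    """Bundled nearest-neighbour MFE fold."""
    s = _encode(sequence)
    if s.shape[0] < 5:
        return FoldResult("." * s.shape[0], 0.0)
    V, WM, W = _fill(s)
    dg = float(W[s.shape[0]])
    pairs = _traceback(s, V, WM, W)
    struct = "".join(
        "(" if p > i else (")" if 0 <= p < i else ".") for i, p in enumerate(pairs)
    )
    return FoldResult(struct, min(dg, 0.0))


def fold_vienna(sequence: str) -> FoldResult:
    """External ViennaRNA backend (same contract)."""
    import RNA

    _encode(sequence)  # same input validation
    struct, mfe = RNA.fold(to_rna(normalize(sequence)))
    return FoldResult(struct, float(mfe))


_BACKENDS = {"builtin": fold_builtin, "vienna": fold_vienna}


def fold(sequence: str, backend="builtin") -> FoldResult:
    """Predict one MFE structure.  ``backend`` is a name or a callable
    implementing the same (sequence) -> FoldResult contract."""
    if callable(backend):
        return backend(sequence)
    return _BACKENDS[backend](sequence)
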