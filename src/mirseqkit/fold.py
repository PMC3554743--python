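"""RNA secondary-structure prediction for hairpin (pre-miRNA) scoring.

Implements minimum-free-energy folding of short RNAs under a
nearest-neighbour model: stacking energies for the six canonical and
wobble base pairs, hairpin-loop closure penalties by loop size, and
bulge/internal-loop penalties.  Multibranch and exterior loops carry no
penalty, pseudoknots are excluded, and interior loops above a size cap
are disallowed outright — the cap is part of the model, so any
loop-decomposition rescoring of a structure reproduces the DP energy
exactly.

Energies are handled internally in integer tenths of kcal/mol to keep
dynamic-programming comparisons exact; public values are kcal/mol floats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import yaml

MIN_HAIRPIN = 3  # minimum unpaired bases closed by a hairpin pair

_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}

_INF = 10**9


class EnergyModel:
    """Nearest-neighbour energy tables, loaded from the bundled YAML.

    All lookups return integer tenths of kcal/mol; interior loops larger
    than ``max_interior`` unpaired bases return ``None`` (disallowed).
    """

    def __init__(self, params: dict):
        def deci(x: float) -> int:
            return round(x * 10)

        self.stack = {
            (x, y): deci(e)
            for x, row in params["stack"].items()
            for y, e in row.items()
        }
        self._hairpin = {int(k): deci(v) for k, v in params["hairpin"].items()}
        self._hairpin_c = float(params["hairpin_extrapolation"])
        self._bulge = {int(k): deci(v) for k, v in params["bulge"].items()}
        self._bulge_c = float(params["bulge_extrapolation"])
        self._internal = {int(k): deci(v) for k, v in params["internal"].items()}
        self._internal_c = float(params["internal_extrapolation"])
        self.max_interior = int(params["max_interior"])

    @classmethod
    def default(cls) -> "EnergyModel":
        return _default_model()

    def pairable(self, a: str, b: str) -> bool:
        return (a, b) in _PAIRS

    def stack_energy(self, outer: str, inner: str) -> int:
        """Stack of inner pair directly on outer pair, e.g. ('CG', 'GC')."""
        return self.stack[(outer, inner)]

    def hairpin_penalty(self, loop: int) -> int:
        if loop < MIN_HAIRPIN:
            return _INF
        if loop in self._hairpin:
            return self._hairpin[loop]
        base = max(self._hairpin)
        return self._hairpin[base] + round(10 * self._hairpin_c * math.log(loop / base))

    def interior_penalty(self, left: int, right: int) -> int | None:
        """Penalty for a bulge/internal loop with the given unpaired counts.

        Returns None when the loop exceeds the model's size cap.
        """
        total = left + right
        if total < 1 or total > self.max_interior:
            return None
        if left == 0 or right == 0:
            table, c = self._bulge, self._bulge_c
        else:
            table, c = self._internal, self._internal_c
        if total in table:
            return table[total]
        base = max(table)
        return table[base] + round(10 * c * math.log(total / base))


@lru_cache(maxsize=1)
def _default_model() -> EnergyModel:
    text = resources.files("mirseqkit.data").joinpath("energy_params.yaml").read_text()
    return EnergyModel(yaml.safe_load(text))


@dataclass(frozen=True)
class FoldResult:
    """A folded sequence: dot-bracket structure and its MFE in kcal/mol."""

    sequence: str
    structure: str
    mfe: float

    def pairs(self) -> list[tuple[int, int]]:
        return pairs_from_structure(self.structure)


def _as_rna(sequence: str) -> str:
    return sequence.upper().replace("T", "U")


def pairs_from_structure(structure: str) -> list[tuple[int, int]]:
    """Parse dot-bracket notation into a sorted list of (i, j) pairs."""
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for idx, ch in enumerate(structure):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced structure")
            pairs.append((stack.pop(), idx))
        elif ch != ".":
            raise ValueError(f"invalid structure character {ch!r}")
    if stack:
        raise ValueError("unbalanced structure")
    return sorted(pairs)


def structure_energy(
    sequence: str, structure: str, model: EnergyModel | None = None
) -> float:
    """Score an explicit structure by loop decomposition (kcal/mol).

    Used as the independent rescoring route for DP results and by
    enumeration oracles.  Raises ValueError for crossing pairs,
    non-pairable bases or hairpin loops below the minimum; returns
    ``math.inf`` for interior loops above the model's size cap.
    """
    model = model or EnergyModel.default()
    seq = _as_rna(sequence)
    if len(structure) != len(seq):
        raise ValueError("structure length does not match sequence")
    pairs = pairs_from_structure(structure)
    partner = {}
    for i, j in pairs:
        partner[i] = j
        partner[j] = i
        if not model.pairable(seq[i], seq[j]):
            raise ValueError(f"non-pairable bases at {i},{j}")
    total = 0
    for i, j in pairs:
        # collect pairs directly enclosed by (i, j)
        children = []
        k = i + 1
        while k < j:
            if k in partner:
                l = partner[k]
                if l < k or l >= j:
                    raise ValueError("crossing (pseudoknotted) pairs")
                children.append((k, l))
                k = l + 1
            else:
                k += 1
        if not children:
            loop = j - i - 1
            if loop < MIN_HAIRPIN:
                raise ValueError("hairpin loop below minimum size")
            total += model.hairpin_penalty(loop)
        elif len(children) == 1:
            k, l = children[0]
            left, right = k - i - 1, j - l - 1
            if left == 0 and right == 0:
                total += model.stack_energy(seq[i] + seq[j], seq[k] + seq[l])
            else:
                pen = model.interior_penalty(left, right)
                if pen is None:
                    return math.inf
                total += pen
        # multibranch loops contribute 0
    return total / 10.0


def fold_rna(
    sequence: str, model: EnergyModel | None = None, max_len: int = 200
) -> FoldResult:
    """Fold an RNA (or DNA) sequence to its minimum-free-energy structure.

    Zuker-style interval dynamic programming over the nearest-neighbour
    model; ties are broken toward fewer pairs.  The empty structure has
    energy 0, so the MFE is never positive.
    """
    model = model or EnergyModel.default()
    seq = _as_rna(sequence)
    n = len(seq)
    if n == 0 or n > max_len:
        raise ValueError(f"sequence length must be in [1, {max_len}], got {n}")
    if any(c not in "ACGU" for c in seq):
        raise ValueError("sequence must contain only A/C/G/T/U")

    pairable = model.pairable
    interior = model.interior_penalty
    hairpin = model.hairpin_penalty
    stack_e = model.stack

    V = [[_INF] * n for _ in range(n)]
    WM = [[_INF] * n for _ in range(n)]
    max_int = model.max_interior

    for span in range(MIN_HAIRPIN + 1, n):
        for i in range(0, n - span):
            j = i + span
            si, sj = seq[i], seq[j]
            if pairable(si, sj):
                best = hairpin(j - i - 1)
                # stacks, bulges and internal loops onto an inner pair
                for left in range(0, max_int + 1):
                    k = i + 1 + left
                    if k + MIN_HAIRPIN + 1 > j - 1:
                        break
                    row_v = V[k]
                    for right in range(0, max_int + 1 - left):
                        l = j - 1 - right
                        if l <= k + MIN_HAIRPIN:
                            break
                        v = row_v[l]
                        if v >= _INF:
                            continue
                        if left == 0 and right == 0:
                            e = stack_e[(si + sj, seq[k] + seq[l])] + v
                        else:
                            pen = interior(left, right)
                            if pen is None:
                                continue
                            e = pen + v
                        if e < best:
                            best = e
                # multibranch: two or more branches, loop energy 0
                row_wm = WM[i + 1]
                for m in range(i + 1, j - 1):
                    a = row_wm[m]
                    if a >= _INF:
                        continue
                    b = WM[m + 1][j - 1]
                    if b < _INF and a + b < best:
                        best = a + b
                V[i][j] = best
            # WM: at least one pair inside [i, j]
            best_wm = V[i][j]
            if WM[i + 1][j] < best_wm:
                best_wm = WM[i + 1][j]
            if WM[i][j - 1] < best_wm:
                best_wm = WM[i][j - 1]
            row_wm_i = WM[i]
            for m in range(i + 1, j):
                a = row_wm_i[m - 1]
                if a >= _INF:
                    continue
                b = WM[m][j]
                if b < _INF and a + b < best_wm:
                    best_wm = a + b
            WM[i][j] = best_wm

    # exterior loop
    W = [0] * (n + 1)  # W[j+1] = best energy of prefix [0, j]
    for j in range(n):
        best = W[j]  # j unpaired: prefer on ties (fewer pairs)
        for k in range(0, j):
            v = V[k][j]
            if v < _INF and W[k] + v < best:
                best = W[k] + v
        W[j + 1] = best

    structure = ["."] * n
    _traceback(seq, V, WM, W, structure, model)
    return FoldResult(sequence=sequence, structure="".join(structure), mfe=W[n] / 10.0)


def _traceback(seq, V, WM, W, structure, model):
    n = len(seq)
    stack_e = model.stack
    tasks: list[tuple[str, int, int]] = [("W", 0, n - 1)]
    while tasks:
        kind, i, j = tasks.pop()
        if j < i:
            continue
        if kind == "W":
            # W over prefix [0, j]; i is always 0 here
            jj = j
            while jj >= 0:
                if W[jj + 1] == W[jj]:
                    jj -= 1
                    continue
                found = False
                for k in range(0, jj + 1):
                    if V[k][jj] < _INF and W[k] + V[k][jj] == W[jj + 1]:
                        tasks.append(("V", k, jj))
                        jj = k - 1
                        found = True
                        break
                if not found:  # pragma: no cover - defensive
                    break
        elif kind == "V":
            structure[i] = "("
            structure[j] = ")"
            e = V[i][j]
            si, sj = seq[i], seq[j]
            if e == model.hairpin_penalty(j - i - 1):
                continue
            done = False
            for left in range(0, model.max_interior + 1):
                k = i + 1 + left
                if k + MIN_HAIRPIN + 1 > j - 1 or done:
                    break
                for right in range(0, model.max_interior + 1 - left):
                    l = j - 1 - right
                    if l <= k + MIN_HAIRPIN:
                        break
                    v = V[k][l]
                    if v >= _INF:
                        continue
                    if left == 0 and right == 0:
                        cand = stack_e[(si + sj, seq[k] + seq[l])] + v
                    else:
                        pen = model.interior_penalty(left, right)
                        if pen is None:
                            continue
                        cand = pen + v
                    if cand == e:
                        tasks.append(("V", k, l))
                        done = True
                        break
            if done:
                continue
            for m in range(i + 1, j - 1):
                a, b = WM[i + 1][m], WM[m + 1][j - 1]
                if a < _INF and b < _INF and a + b == e:
                    tasks.append(("M", i + 1, m))
                    tasks.append(("M", m + 1, j - 1))
                    break
        else:  # WM
            e = WM[i][j]
            if e >= _INF:
                continue
            if WM[i + 1][j] == e:
                tasks.append(("M", i + 1, j))
            elif WM[i][j - 1] == e:
                tasks.append(("M", i, j - 1))
            elif V[i][j] == e:
                tasks.append(("V", i, j))
            else:
                for m in range(i + 1, j):
                    a, b = WM[i][m - 1], WM[m][j]
                    if a < _INF and b < _INF and a + b == e:
                        tasks.append(("M", i, m - 1))
                        tasks.append(("M", m, j))
                        break
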