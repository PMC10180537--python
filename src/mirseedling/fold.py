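"""Minimum-free-energy RNA secondary structure prediction.

A reduced nearest-neighbor model — Turner-style stacking energies plus
loop-size penalties (hairpin, bulge, internal with an asymmetry term) and
an affine multiloop cost, at 37 degC, with no dangling ends or coaxial
stacking — evaluated by a Zuker-type dynamic program with traceback.
Pseudoknots are excluded and hairpin loops hold at least 3 unpaired bases.

All energies are handled internally as integers in units of 0.01 kcal/mol,
so the DP minimum, structure re-scoring, and exhaustive enumeration agree
exactly with no floating-point slack.

Also provides the precursor statistics used for miRNA hairpin filtering:
GC%, AMFE (|MFE|/length x 100) and MFEI (AMFE / GC%), plus the geometric
features of a mature miRNA placed on a hairpin (arm, paired bases, bulges,
terminal loop, inferred star span).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
import numpy as np
from numba import njit

from .seqio import to_rna

__all__ = [
    "EnergyModel",
    "SecondaryStructure",
    "HairpinFeatures",
    "default_model",
    "gc_content",
    "amfe",
    "mfei",
    "fold_mfe",
    "energy_of_structure",
    "parse_dot_bracket",
    "hairpin_features",
]

INF = 10 ** 8
MAXLOOP = 30          # max unpaired bases in a bulge/internal loop (DP cap)
MIN_HAIRPIN = 3

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
_PAIR_NAMES = ["", "AU", "UA", "GC", "CG", "GU", "UG"]
_PAIR_INDEX = {name: i for i, name in enumerate(_PAIR_NAMES) if name}
_FLIP = [0, 2, 1, 4, 3, 6, 5]  # AU<->UA, GC<->CG, GU<->UG

# pair-type lookup by nucleotide codes (A,C,G,U)
_PTYPE = np.zeros((4, 4), dtype=np.int64)
_PTYPE[0, 3] = _PAIR_INDEX["AU"]
_PTYPE[3, 0] = _PAIR_INDEX["UA"]
_PTYPE[2, 1] = _PAIR_INDEX["GC"]
_PTYPE[1, 2] = _PAIR_INDEX["CG"]
_PTYPE[2, 3] = _PAIR_INDEX["GU"]
_PTYPE[3, 2] = _PAIR_INDEX["UG"]


def encode(sequence: str) -> np.ndarray:
    seq = sequence.upper()
    try:
        return np.array([_CODE[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"invalid nucleotide {exc} in sequence") from None


@dataclass(frozen=True)
class EnergyModel:
    """Immutable parameter set for the reduced nearest-neighbor model.

    ``stack[p][q]`` is the energy (0.01 kcal/mol integers) of pair type
    ``p = (i, j)`` stacked on interior pair ``q = (i+1, j-1)``; loop
    penalty tables are extrapolated beyond their tabulated sizes with a
    Jacobson-Stockmayer ``c * ln(n/n_max)`` term.
    """

    stack: np.ndarray            # (7, 7) int
    hairpin_tab: np.ndarray      # by loop size, int
    bulge_tab: np.ndarray
    internal_tab: np.ndarray
    asym_per_base: int
    asym_max: int
    ml_close: int
    ml_branch: int
    ml_unpaired: int
    js_coef: float

    def _extrapolate(self, tab: np.ndarray, size: int, min_size: int) -> int:
        if size < min_size:
            return INF
        last = len(tab) - 1
        if size <= last:
            return int(tab[size])
        return int(round(tab[last] + 100 * self.js_coef * math.log(size / last)))

    def hairpin(self, size: int) -> int:
        return self._extrapolate(self.hairpin_tab, size, MIN_HAIRPIN)

    def bulge(self, size: int) -> int:
        return self._extrapolate(self.bulge_tab, size, 1)

    def internal(self, size: int) -> int:
        return self._extrapolate(self.internal_tab, size, 2)

    def loop_arrays(self, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Loop penalties pre-tabulated up to size ``n`` for the DP kernel."""
        hp = np.array([self.hairpin(s) for s in range(n + 1)], dtype=np.int64)
        bu = np.array([self.bulge(s) for s in range(n + 1)], dtype=np.int64)
        it = np.array([self.internal(s) for s in range(n + 1)], dtype=np.int64)
        return hp, bu, it

    def internal_loop_energy(self, u1: int, u2: int) -> int:
        """Bulge or internal-loop penalty for u1/u2 unpaired on each side."""
        if u1 == 0 and u2 == 0:
            raise ValueError("0x0 interior loop is a stack, not a loop")
        if u1 == 0 or u2 == 0:
            return self.bulge(u1 + u2)
        asym = min(abs(u1 - u2) * self.asym_per_base, self.asym_max)
        return self.internal(u1 + u2) + asym


def _load_params() -> dict:
    text = (
        resources.files("mirseedling.data")
        .joinpath("energy_params.tsv")
        .read_text()
    )
    rows = []
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith("kind\t"):
            continue
        kind, k1, k2, dg = line.split("\t")
        rows.append((kind, k1, k2, float(dg)))
    return {"rows": rows}


def _build_default_model() -> EnergyModel:
    rows = _load_params()["rows"]
    stack = np.zeros((7, 7), dtype=np.int64)
    stack[:] = INF
    hairpin: dict[int, int] = {}
    bulge: dict[int, int] = {}
    internal: dict[int, int] = {}
    coefs: dict[str, float] = {}
    for kind, k1, k2, dg in rows:
        e = int(round(dg * 100))
        if kind == "stack":
            p, q = _PAIR_INDEX[k1], _PAIR_INDEX[k2]
            stack[p, q] = e
            stack[_FLIP[q], _FLIP[p]] = e  # helix-direction symmetry
        elif kind == "hairpin":
            hairpin[int(k1)] = e
        elif kind == "bulge":
            bulge[int(k1)] = e
        elif kind == "internal":
            internal[int(k1)] = e
        elif kind == "coef":
            coefs[k1] = dg

    def tab(d: dict[int, int]) -> np.ndarray:
        top = max(d)
        out = np.full(top + 1, INF, dtype=np.int64)
        for k, v in d.items():
            out[k] = v
        return out

    return EnergyModel(
        stack=stack,
        hairpin_tab=tab(hairpin),
        bulge_tab=tab(bulge),
        internal_tab=tab(internal),
        asym_per_base=int(round(coefs["asym_per_base"] * 100)),
        asym_max=int(round(coefs["asym_max"] * 100)),
        ml_close=int(round(coefs["multiloop_close"] * 100)),
        ml_branch=int(round(coefs["multiloop_branch"] * 100)),
        ml_unpaired=int(round(coefs["multiloop_unpaired"] * 100)),
        js_coef=coefs["jacobson_stockmayer"],
    )


_DEFAULT_MODEL: EnergyModel | None = None


def default_model() -> EnergyModel:
    """The packaged parameter set (loaded once per process)."""
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        _DEFAULT_MODEL = _build_default_model()
    return _DEFAULT_MODEL


# ---------------------------------------------------------------------------
# Precursor statistics
# ---------------------------------------------------------------------------

def gc_content(sequence: str) -> float:
    """GC percentage: 100 x (#G + #C) / length."""
    if not sequence:
        raise ValueError("empty sequence")
    s = sequence.upper()
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


def amfe(mfe: float, length: int) -> float:
    """Adjusted MFE: |MFE| / length x 100 (kcal/mol per 100 nt)."""
    if length <= 0:
        raise ValueError("length must be positive")
    return abs(mfe) / length * 100.0


def mfei(mfe: float, length: int, gc: float) -> float:
    """Minimal folding free energy index: AMFE / GC%, reported as a
    positive magnitude (catalogues print MFEI as positive even though MFE
    is negative)."""
    if gc <= 0:
        raise ValueError("MFEI undefined for GC content 0")
    return amfe(mfe, length) / gc


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

def parse_dot_bracket(dot_bracket: str) -> dict[int, int]:
    """Pair map from a Vienna dot-bracket string (errors on imbalance)."""
    stack: list[int] = []
    pairs: dict[int, int] = {}
    for i, c in enumerate(dot_bracket):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            pairs[j] = i
            pairs[i] = j
        elif c != ".":
            raise ValueError(f"invalid structure character {c!r}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return pairs


@dataclass(frozen=True)
class SecondaryStructure:
    """A folded sequence: dot-bracket, MFE (kcal/mol) and the pair map."""

    sequence: str                      # RNA alphabet
    dot_bracket: str
    mfe: float
    pair_map: dict[int, int] = field(repr=False)

    def partner(self, i: int) -> int | None:
        return self.pair_map.get(i)

    @property
    def n_pairs(self) -> int:
        return len(self.pair_map) // 2


def energy_of_structure(
    sequence: str, dot_bracket: str, model: EnergyModel | None = None
) -> float:
    """Score a dot-bracket by loop decomposition (kcal/mol).

    This is the model definition itself: the fold DP must reproduce it
    exactly on its own output, and exhaustive enumeration uses it to score
    every candidate structure.
    """
    return _energy_int(sequence, parse_dot_bracket(dot_bracket), model) / 100.0


def _energy_int(
    sequence: str, pairs: dict[int, int], model: EnergyModel | None = None
) -> int:
    model = model or default_model()
    codes = encode(sequence)
    n = len(codes)
    opening = sorted(i for i, j in pairs.items() if i < j)
    total = 0
    for i in opening:
        j = pairs[i]
        pt = _PTYPE[codes[i], codes[j]]
        if pt == 0:
            raise ValueError(f"disallowed pair {sequence[i]}{sequence[j]} at ({i},{j})")
        # walk the loop closed by (i, j): direct children + unpaired count
        children: list[tuple[int, int]] = []
        unpaired = 0
        k = i + 1
        while k < j:
            if k in pairs:
                children.append((k, pairs[k]))
                k = pairs[k] + 1
            else:
                unpaired += 1
                k += 1
        if not children:
            if unpaired < MIN_HAIRPIN:
                raise ValueError(f"hairpin loop of size {unpaired} at ({i},{j})")
            total += model.hairpin(unpaired)
        elif len(children) == 1:
            k, l = children[0]
            qt = _PTYPE[codes[k], codes[l]]
            u1, u2 = k - i - 1, j - l - 1
            if u1 == 0 and u2 == 0:
                total += int(model.stack[pt, qt])
            else:
                total += model.internal_loop_energy(u1, u2)
        else:
            total += (
                model.ml_close
                + model.ml_branch * (len(children) + 1)
                + model.ml_unpaired * unpaired
            )
    return total


# ---------------------------------------------------------------------------
# Zuker DP (numba kernel) + traceback
# ---------------------------------------------------------------------------

@njit(cache=True)
def _fill(codes, ptype, stack, hp, bu, it, asym_per, asym_max,
          ml_a, ml_b, ml_c, inf):  # pragma: no cover - exercised via fold_mfe
    n = len(codes)
    V = np.full((n, n), inf, dtype=np.int64)
    WM = np.full((n, n), inf, dtype=np.int64)
    for d in range(1, n):
        for i in range(0, n - d):
            j = i + d
            pt = ptype[codes[i], codes[j]]
            if pt > 0 and j - i - 1 >= 3:
                best = hp[j - i - 1]
                # stack / bulge / internal loop to interior pair (k, l)
                for k in range(i + 1, j - 4 + 1):
                    u1 = k - i - 1
                    if u1 > 30:
                        break
                    for l in range(j - 1, k + 3, -1):
                        u2 = j - l - 1
                        if u1 + u2 > 30:
                            break
                        qt = ptype[codes[k], codes[l]]
                        if qt == 0 or V[k, l] >= inf:
                            continue
                        if u1 == 0 and u2 == 0:
                            e = stack[pt, qt] + V[k, l]
                        elif u1 == 0 or u2 == 0:
                            e = bu[u1 + u2] + V[k, l]
                        else:
                            a = abs(u1 - u2) * asym_per
                            if a > asym_max:
                                a = asym_max
                            e = it[u1 + u2] + a + V[k, l]
                        if e < best:
                            best = e
                # multiloop: two WM segments inside
                for m in range(i + 2, j - 2):
                    if WM[i + 1, m] < inf and WM[m + 1, j - 1] < inf:
                        e = ml_a + ml_b + WM[i + 1, m] + WM[m + 1, j - 1]
                        if e < best:
                            best = e
                V[i, j] = best
            # WM
            best = inf
            if V[i, j] < inf:
                best = V[i, j] + ml_b
            if i + 1 <= j and WM[i + 1, j] < inf and WM[i + 1, j] + ml_c < best:
                best = WM[i + 1, j] + ml_c
            if j - 1 >= i and WM[i, j - 1] < inf and WM[i, j - 1] + ml_c < best:
                best = WM[i, j - 1] + ml_c
            for m in range(i, j):
                if WM[i, m] < inf and WM[m + 1, j] < inf:
                    e = WM[i, m] + WM[m + 1, j]
                    if e < best:
                        best = e
            WM[i, j] = best
    W = np.zeros(n + 1, dtype=np.int64)
    for j in range(1, n + 1):
        best = W[j - 1]
        for i in range(0, j):
            if V[i, j - 1] < inf:
                e = W[i] + V[i, j - 1]
                if e < best:
                    best = e
        W[j] = best
    return V, WM, W


def fold_mfe(sequence: str, model: EnergyModel | None = None) -> SecondaryStructure:
    """Fold a sequence to its minimum-energy non-crossing structure.

    Deterministic: at energy ties the traceback prefers leaving positions
    unpaired, then the lexicographically earliest branch, so repeated runs
    (and runs across platforms) give the same dot-bracket.
    """
    model = model or default_model()
    seq = sequence.upper()
    n = len(seq)
    if n < 10:
        raise ValueError(f"sequence too short to fold ({n} < 10 nt)")
    if n > 2000:
        raise ValueError("sequence longer than 2000 nt not supported")
    codes = encode(seq)
    hp, bu, it = model.loop_arrays(max(n, MAXLOOP + 2))
    V, WM, W = _fill(
        codes, _PTYPE, model.stack, hp, bu, it,
        model.asym_per_base, model.asym_max,
        model.ml_close, model.ml_branch, model.ml_unpaired, INF,
    )
    pairs: dict[int, int] = {}
    _traceback(codes, model, V, WM, W, n, pairs)
    db = ["."] * n
    for i, j in pairs.items():
        if i < j:
            db[i], db[j] = "(", ")"
    mfe_int = int(W[n])
    structure = SecondaryStructure(
        sequence=to_rna(seq),
        dot_bracket="".join(db),
        mfe=mfe_int / 100.0,
        pair_map=pairs,
    )
    return structure


def _traceback(codes, model, V, WM, W, n, pairs: dict[int, int]) -> None:
    stack_tasks: list[tuple[str, int, int]] = [("W", 0, n)]
    ptype = _PTYPE
    st = model.stack
    while stack_tasks:
        kind, i, j = stack_tasks.pop()
        if kind == "W":
            # W over prefix [0, j); peel from the right
            while j > 0:
                if W[j] == W[j - 1]:
                    j -= 1
                    continue
                found = False
                for a in range(0, j):
                    if V[a, j - 1] < INF and W[a] + V[a, j - 1] == W[j]:
                        stack_tasks.append(("V", a, j - 1))
                        j = a
                        found = True
                        break
                if not found:  # numerical impossibility guard
                    raise AssertionError("W traceback failed")
        elif kind == "V":
            pairs[i] = j
            pairs[j] = i
            e = V[i, j]
            pt = ptype[codes[i], codes[j]]
            if e == model.hairpin(j - i - 1):
                continue
            done = False
            for k in range(i + 1, j - 3):
                u1 = k - i - 1
                if u1 > MAXLOOP:
                    break
                for l in range(j - 1, k + 3, -1):
                    u2 = j - l - 1
                    if u1 + u2 > MAXLOOP:
                        break
                    qt = ptype[codes[k], codes[l]]
                    if qt == 0 or V[k, l] >= INF:
                        continue
                    if u1 == 0 and u2 == 0:
                        cand = int(st[pt, qt]) + V[k, l]
                    elif u1 == 0 or u2 == 0:
                        cand = model.bulge(u1 + u2) + V[k, l]
                    else:
                        cand = model.internal_loop_energy(u1, u2) + V[k, l]
                    if cand == e:
                        stack_tasks.append(("V", k, l))
                        done = True
                        break
                if done:
                    break
            if done:
                continue
            for m in range(i + 2, j - 2):
                if WM[i + 1, m] < INF and WM[m + 1, j - 1] < INF and (
                    model.ml_close + model.ml_branch
                    + WM[i + 1, m] + WM[m + 1, j - 1] == e
                ):
                    stack_tasks.append(("WM", i + 1, m))
                    stack_tasks.append(("WM", m + 1, j - 1))
                    done = True
                    break
            if not done:
                raise AssertionError(f"V traceback failed at ({i},{j})")
        else:  # WM segment
            e = WM[i, j]
            if i + 1 <= j and WM[i + 1, j] < INF and WM[i + 1, j] + model.ml_unpaired == e:
                stack_tasks.append(("WM", i + 1, j))
                continue
            if j - 1 >= i and WM[i, j - 1] < INF and WM[i, j - 1] + model.ml_unpaired == e:
                stack_tasks.append(("WM", i, j - 1))
                continue
            if V[i, j] < INF and V[i, j] + model.ml_branch == e:
                stack_tasks.append(("V", i, j))
                continue
            done = False
            for m in range(i, j):
                if WM[i, m] < INF and WM[m + 1, j] < INF and WM[i, m] + WM[m + 1, j] == e:
                    stack_tasks.append(("WM", i, m))
                    stack_tasks.append(("WM", m + 1, j))
                    done = True
                    break
            if not done:
                raise AssertionError(f"WM traceback failed at ({i},{j})")


# ---------------------------------------------------------------------------
# Hairpin geometry of a placed mature miRNA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HairpinFeatures:
    """Geometry of a mature miRNA within a folded precursor."""

    arm: str                     # "5p" | "3p" | "loop-spanning"
    paired_mature_bases: int
    mature_mismatches: int       # mature bases unpaired in the duplex
    largest_asymmetric_bulge: int
    terminal_loop_size: int
    star_span: tuple[int, int]   # half-open, on precursor coordinates


def hairpin_features(
    structure: SecondaryStructure, mature_span: tuple[int, int]
) -> HairpinFeatures:
    """Describe where a mature span sits on a folded hairpin.

    The star span is inferred as the pairing partner region of the mature,
    extended by the canonical 2-nt 3' offset of the processed duplex.
    """
    s, e = mature_span
    n = len(structure.sequence)
    if not (0 <= s < e <= n):
        raise ValueError(f"mature span {mature_span} outside sequence of length {n}")
    partner = structure.pair_map
    paired = [p for p in range(s, e) if p in partner]
    if not paired:
        return HairpinFeatures("loop-spanning", 0, e - s, 0, 0, (0, 0))
    partners = [partner[p] for p in paired]
    if all(q >= e for q in partners):
        arm = "5p"
    elif all(q < s for q in partners):
        arm = "3p"
    else:
        arm = "loop-spanning"
    mismatches = (e - s) - len(paired)
    largest_bulge = 0
    for a, b in zip(paired, paired[1:]):
        gap_m = b - a - 1
        gap_s = abs(partner[a] - partner[b]) - 1
        largest_bulge = max(largest_bulge, abs(gap_m - gap_s))
    # terminal loop: innermost pair (no pairs inside) nearest the mature helix
    loops = []
    for i, j in partner.items():
        if i < j and not any(k in partner for k in range(i + 1, j)):
            loops.append((i, j))
    terminal = 0
    if loops:
        if arm == "5p":
            cands = [lo for lo in loops if lo[0] >= max(paired)]
        elif arm == "3p":
            cands = [lo for lo in loops if lo[1] <= min(paired)]
        else:
            cands = loops
        if not cands:
            cands = loops
        i, j = min(cands, key=lambda lo: abs(lo[0] - (s + e) // 2))
        terminal = j - i - 1
    lo = partner[max(paired)]
    hi = partner[min(paired)] + 1 + 2  # 2-nt 3' overhang of the star
    star = (max(0, min(lo, hi)), min(n, max(lo, hi)))
    return HairpinFeatures(
        arm=arm,
        paired_mature_bases=len(paired),
        mature_mismatches=mismatches,
        largest_asymmetric_bulge=largest_bulge,
        terminal_loop_size=terminal,
        star_span=star,
    )
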