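"""Intermolecular RNA:RNA hybrid minimum free energy by dynamic programming.

The hybridization model follows the classical nearest-neighbor picture used
by duplex-prediction tools: a hybrid is a set of base pairs between a miRNA
(5'->3') and a target site (5'->3'), antiparallel, with no intramolecular
pairs and no pseudoknots (pair indices strictly monotone on both strands).
Its free energy is

    dG = init + sum(stack terms for adjacent pairs)
              + sum(open + extend * n_unpaired  for each interior loop/bulge)

where ``init`` is the helix initiation penalty and loops are charged one
affine penalty on the *total* unpaired count of both strands (asymmetric
internal loops thus pay per unpaired nucleotide). Allowed pairs are the
Watson-Crick pairs plus G:U wobbles; stack energies come from an editable
TSV table (Turner-style values for Watson-Crick doublets).

The empty structure is not admissible: the reported MFE is the optimum over
hybrids with at least one pair, so a lone pair scores exactly ``init`` (a
positive number). With ``require_seed=True`` only structures pairing every
miRNA seed position 2-8 (1-based) are admissible.

The dynamic program is O(n*s) in the two lengths via running prefix minima
over the affine loop terms; a brute-force enumeration of all hybrids serves
as its oracle in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

from .errors import ConfigurationError, InputError

ALLOWED_PAIRS = frozenset({("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"),
                           ("G", "U"), ("U", "G")})
WATSON_CRICK = frozenset({("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")})

_INF = math.inf

# 0-based miRNA indices that must be paired under the seed constraint
SEED_INDICES = range(1, 8)


@dataclass(frozen=True)
class EnergyModel:
    """Nearest-neighbor duplex parameters (kcal/mol).

    ``stacks`` maps keys ``"XY/WZ"`` (both strands written 5'->3'; pairs
    X:Z and Y:W) to stacking free energies.
    """

    stacks: dict
    init: float
    loop_open: float
    loop_extend: float

    def __post_init__(self):
        if self.loop_open < 0 or self.loop_extend < 0:
            raise ConfigurationError("loop penalties must be >= 0")
        for key, value in self.stacks.items():
            x, y = key[0], key[1]
            w, z = key[3], key[4]
            if (x, z) not in ALLOWED_PAIRS or (y, w) not in ALLOWED_PAIRS:
                raise ConfigurationError(f"stack key {key!r} does not stack two allowed pairs")
            if (x, z) in WATSON_CRICK and (y, w) in WATSON_CRICK and value > 0:
                raise ConfigurationError(f"Watson-Crick stack {key!r} must be <= 0")

    def stack(self, key: str) -> float:
        try:
            return self.stacks[key]
        except KeyError:
            raise ConfigurationError(f"energy model is missing stack doublet {key!r}") from None


def load_energy_model(path: str | Path) -> EnergyModel:
    """Load a TSV with rows ``kind<TAB>key<TAB>value`` (kinds: init,
    loop_open, loop_extend, stack)."""
    stacks: dict[str, float] = {}
    scalars: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("kind\t"):
            continue
        kind, key, value = line.split("\t")
        if kind == "stack":
            stacks[key] = float(value)
        else:
            scalars[kind] = float(value)
    for name in ("init", "loop_open", "loop_extend"):
        if name not in scalars:
            raise ConfigurationError(f"energy model file lacks scalar {name!r}")
    return EnergyModel(stacks=stacks, init=scalars["init"],
                       loop_open=scalars["loop_open"],
                       loop_extend=scalars["loop_extend"])


@lru_cache(maxsize=1)
def default_energy_model() -> EnergyModel:
    """The packaged stack table (``mirarray/data/energy_model.tsv``)."""
    with resources.as_file(resources.files("mirarray").joinpath("data/energy_model.tsv")) as p:
        return load_energy_model(p)


@dataclass(frozen=True)
class DuplexResult:
    """One optimal hybrid: pairs as ``(mirna_index, site_index)`` 0-based in
    the original 5'->3' orientations of both sequences."""

    mirna_name: str
    site: str
    mfe: float
    pairs: tuple
    diagram: str

    @property
    def paired_mirna_positions_1based(self) -> tuple:
        return tuple(i + 1 for i, _ in self.pairs)


def _to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def score_structure(mirna: str, site: str, pairs, model: EnergyModel) -> float:
    """Re-sum the energy of a pair set under the model (oracle-friendly).

    ``pairs`` are ``(i, j)`` in original orientations; they must be strictly
    increasing in i and strictly decreasing in j (antiparallel, no knots).
    """
    m, t = _to_rna(mirna), _to_rna(site)
    pairs = sorted(pairs)
    if not pairs:
        raise InputError("empty structure has no defined hybrid energy")
    for i, j in pairs:
        if (m[i], t[j]) not in ALLOWED_PAIRS:
            raise InputError(f"pair ({i},{j}) = {m[i]}:{t[j]} is not an allowed pair")
    energy = model.init
    for (i0, j0), (i1, j1) in zip(pairs, pairs[1:]):
        if i1 <= i0 or j1 >= j0:
            raise InputError("pairs must be strictly monotone (antiparallel, no pseudoknots)")
        gap = (i1 - i0 - 1) + (j0 - j1 - 1)
        if gap == 0:
            energy += model.stack(f"{m[i0]}{m[i1]}/{t[j1]}{t[j0]}")
        else:
            energy += model.loop_open + model.loop_extend * gap
    return energy


def _render_diagram(mirna: str, site: str, pairs) -> str:
    """Three-line ASCII hybrid diagram: target 5'->3' over miRNA 3'->5'."""
    m, t = _to_rna(mirna), _to_rna(site)
    by_j = sorted(pairs, key=lambda p: p[1])  # ascending target index
    t_line, bars, m_line = [], [], []

    def emit(t_frag: str, m_frag: str):
        width = max(len(t_frag), len(m_frag))
        t_line.append(t_frag.ljust(width))
        m_line.append(m_frag.ljust(width))
        bars.append(" " * width)

    prev_j, prev_i = -1, len(m)  # miRNA runs 3'->5' left to right
    for i, j in by_j:
        t_gap = t[prev_j + 1:j]
        m_gap = m[i + 1:prev_i][::-1]
        if t_gap or m_gap:
            emit(t_gap, m_gap)
        t_line.append(t[j])
        m_line.append(m[i])
        bars.append("|")
        prev_j, prev_i = j, i
    emit(t[prev_j + 1:], m[:prev_i][::-1])
    return (f"target 5' {''.join(t_line)} 3'\n"
            f"          {''.join(bars)}\n"
            f"miRNA  3' {''.join(m_line)} 5'")


def duplex_mfe(mirna_name: str, mirna: str, site: str,
               model: EnergyModel | None = None,
               require_seed: bool = False) -> DuplexResult:
    """Minimum free energy hybrid between a miRNA and a target site window.

    Both sequences are given 5'->3' (T is read as U). The DP considers every
    antiparallel, knot-free set of intermolecular pairs with at least one
    pair. With ``require_seed``, only structures pairing all miRNA positions
    2-8 are admissible; if none exists the result has ``mfe = inf`` and an
    empty pair set.
    """
    if model is None:
        model = default_energy_model()
    m = _to_rna(mirna)
    t = _to_rna(site)
    if not t or not m:
        raise InputError("empty sequence")
    if require_seed:
        if len(t) < 7:
            raise InputError(f"site window shorter than 7 nt ({len(t)}) cannot pair a full seed")
        if len(m) < 8:
            raise InputError("seed constraint needs a miRNA of length >= 8")
    n, s = len(m), len(t)
    u = t[::-1]  # u[j] pairs are antiparallel-aligned with m
    init, opn, ext = model.init, model.loop_open, model.loop_extend

    pairable = [[(m[i], u[j]) in ALLOWED_PAIRS for j in range(s)] for i in range(n)]
    # stack energy keyed on-the-fly: f"{m[i-1]}{m[i]}/{u[j]}{u[j-1]}"
    M = [[_INF] * s for _ in range(n)]
    kind = [[""] * s for _ in range(n)]
    if require_seed:
        R = [[_INF] * s for _ in range(n)]    # row prefix min of M[i][j0]-ext*j0
        P7 = [[_INF] * s for _ in range(n)]   # 2D prefix min of M-ext*(i+j), rows >= 7
    else:
        P = [[_INF] * s for _ in range(n)]    # 2D prefix min of M[i][j]-ext*(i+j)

    for i in range(n):
        for j in range(s):
            if pairable[i][j]:
                best, how = _INF, ""
                if not require_seed or i <= 1:
                    best, how = init, "I"
                if i > 0 and j > 0 and M[i - 1][j - 1] < _INF:
                    cand = M[i - 1][j - 1] + model.stack(f"{m[i-1]}{m[i]}/{u[j]}{u[j-1]}")
                    if cand < best:
                        best, how = cand, "S"
                loop = _INF
                if not require_seed:
                    c1 = P[i - 2][j - 1] if (i >= 2 and j >= 1) else _INF
                    c2 = P[i - 1][j - 2] if (i >= 1 and j >= 2) else _INF
                    pm = min(c1, c2)
                    if pm < _INF:
                        loop = pm + opn + ext * ((i - 1) + (j - 1))
                elif 1 <= i <= 8:
                    # within/entering the seed block: only target-side bulges
                    if j >= 2 and R[i - 1][j - 2] < _INF:
                        loop = R[i - 1][j - 2] + opn + ext * (j - 1)
                elif i >= 9:
                    c1 = P7[i - 2][j - 1] if (i - 2 >= 7 and j >= 1) else _INF
                    c2 = P7[i - 1][j - 2] if j >= 2 else _INF
                    pm = min(c1, c2)
                    if pm < _INF:
                        loop = pm + opn + ext * ((i - 1) + (j - 1))
                if loop < best:
                    best, how = loop, "L"
                M[i][j] = best
                kind[i][j] = how
            # prefix structures
            if require_seed:
                rv = M[i][j] - ext * j if M[i][j] < _INF else _INF
                R[i][j] = min(rv, R[i][j - 1]) if j > 0 else rv
                if i >= 7:
                    wv = M[i][j] - ext * (i + j) if M[i][j] < _INF else _INF
                    above = P7[i - 1][j] if i - 1 >= 7 else _INF
                    left = P7[i][j - 1] if j > 0 else _INF
                    P7[i][j] = min(wv, above, left)
            else:
                wv = M[i][j] - ext * (i + j) if M[i][j] < _INF else _INF
                above = P[i - 1][j] if i > 0 else _INF
                left = P[i][j - 1] if j > 0 else _INF
                P[i][j] = min(wv, above, left)

    i_min = 7 if require_seed else 0
    best_val, best_cell = _INF, None
    for i in range(i_min, n):
        for j in range(s):
            if M[i][j] < best_val:
                best_val, best_cell = M[i][j], (i, j)
    if best_cell is None:
        return DuplexResult(mirna_name, t, _INF, (), "(no admissible hybrid)")

    # traceback; loop predecessors are re-found by direct argmin over the
    # admissible source set (the DP stores only the decision kind)
    pairs_rev = []
    i, j = best_cell
    while True:
        pairs_rev.append((i, j))
        how = kind[i][j]
        if how == "I":
            break
        if how == "S":
            i, j = i - 1, j - 1
            continue
        lo = 0
        if require_seed:
            lo = max(0, i - 1) if i <= 8 else 7
        src, src_val = None, _INF
        for i0 in range(lo, i):
            row = M[i0]
            if require_seed and 1 <= i <= 8 and i0 != i - 1:
                continue
            for j0 in range(0, j):
                if i0 == i - 1 and j0 == j - 1:
                    continue
                if row[j0] < _INF:
                    cand = row[j0] + opn + ext * ((i - 1 - i0) + (j - 1 - j0))
                    if cand < src_val:
                        src_val, src = cand, (i0, j0)
        i, j = src
    pairs = tuple(sorted((i, s - 1 - j) for i, j in pairs_rev))
    mfe = score_structure(m, t, pairs, model)
    assert abs(mfe - best_val) < 1e-6
    diagram = _render_diagram(m, t, pairs)
    return DuplexResult(mirna_name, t, mfe, pairs, diagram)
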