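"""Independent brute-force oracles used to validate the package's algorithms.

Each oracle re-derives the expected answer from the bare definition
(exhaustive enumeration, position-by-position search, literal step-up
formula) without sharing code with the implementation under test.
"""

from __future__ import annotations

import numpy as np

STOPS = {"TAA", "TAG", "TGA"}
ALLOWED = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}


def brute_force_orfs(seq: str, min_len_codons: int):
    """Every-ATG codon walk: (start, end, frame, complete) tuples, sorted."""
    out = []
    n = len(seq)
    for s in range(n - 2):
        if seq[s:s + 3] != "ATG":
            continue
        pos = s + 3
        end, complete = None, False
        while pos + 3 <= n:
            if seq[pos:pos + 3] in STOPS:
                end, complete = pos + 3, True
                break
            pos += 3
        if end is None:
            end = pos
        if (end - s) // 3 < min_len_codons:
            continue
        if "N" in seq[s:end]:
            continue
        out.append((s, end, s % 3, complete))
    return sorted(out)


def naive_seed_search(utr_seq: str, pattern: str):
    """All (possibly overlapping) occurrence positions by direct comparison."""
    k = len(pattern)
    return [i for i in range(len(utr_seq) - k + 1) if utr_seq[i:i + k] == pattern]


def enumerate_duplex_mfe(mirna: str, site: str, model, require_seed: bool = False) -> float:
    """Exhaustive enumeration of every intermolecular hybrid (>=1 pair).

    Pairs are chosen with miRNA index and reversed-site index both strictly
    increasing (antiparallel, no pseudoknots); energy = initiation + stacks
    for adjacent pairs + affine penalty per interior loop. Returns inf when
    no admissible structure exists.
    """
    m = mirna.upper().replace("T", "U")
    u = site.upper().replace("T", "U")[::-1]
    n, s = len(m), len(u)
    cells = [(i, j) for i in range(n) for j in range(s) if (m[i], u[j]) in ALLOWED]
    seed_mask_full = sum(1 << i for i in range(1, 8) if i < n)
    best = [np.inf]

    def admissible(mask: int) -> bool:
        return not require_seed or mask & seed_mask_full == seed_mask_full

    def extend(i0: int, j0: int, energy: float, mask: int) -> None:
        if admissible(mask):
            best[0] = min(best[0], energy)
        for (i, j) in cells:
            if i <= i0 or j <= j0:
                continue
            if i == i0 + 1 and j == j0 + 1:
                cost = model.stack(f"{m[i0]}{m[i]}/{u[j]}{u[j0]}")
            else:
                gap = (i - i0 - 1) + (j - j0 - 1)
                cost = model.loop_open + model.loop_extend * gap
            extend(i, j, energy + cost, mask | (1 << i))

    for (i, j) in cells:
        extend(i, j, model.init, 1 << i)
    return best[0]


def bh_step_up(p):
    """Literal BH definition: adjusted_i = min over j >= rank(i) of m*p_(j)/j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    sorted_p = p[order]
    for rank_i in range(m):
        candidates = [m * sorted_p[j] / (j + 1) for j in range(rank_i, m)]
        adjusted[order[rank_i]] = min(1.0, min(candidates))
    return adjusted


def venn_membership_cells(sets_by_group: dict):
    """Tabulate each element of the union into its exact membership cell."""
    cells: dict[frozenset, set] = {}
    union = set().union(*sets_by_group.values())
    for x in union:
        key = frozenset(g for g, s in sets_by_group.items() if x in s)
        cells.setdefault(key, set()).add(x)
    return cells
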