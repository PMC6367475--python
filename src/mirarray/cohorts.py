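"""Cohort comparison bookkeeping and Venn partitioning.

Reproduces the comparison structure of a four-cohort, two-tissue design:
all six cohort pairs within each tissue plus the fat-body-vs-cuticle
contrast within each cohort (16 comparisons), the exclusion of miRNAs
shared between the two infected cohorts (R+ and S+), and the disjoint
seven-cell Venn partition of up-/down-regulated miRNAs relative to the
uninfected susceptible (S-) reference cohort.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import pandas as pd

from .config import COHORTS, TISSUES
from .errors import InputError
from .expression import DesignTable, call_de

logger = logging.getLogger(__name__)

VENN_GROUPS = ("S+", "R+", "R-")  # each contrasted against S-
DIRECTIONS = ("up", "down")

# cohort pairs in the conventional reporting order
COHORT_PAIRS = (("R-", "S-"), ("R-", "S+"), ("R+", "S-"),
                ("R+", "S+"), ("S+", "S-"), ("R+", "R-"))


@dataclass(frozen=True)
class ComparisonSpec:
    """One contrast: two (cohort, tissue) cells and the significance gate."""

    label: str
    group_a: tuple[str, str]
    group_b: tuple[str, str]
    alpha: float = 0.01

    def __post_init__(self):
        if self.group_a == self.group_b:
            raise InputError("comparison groups must differ")


def all_comparisons(alpha: float = 0.01) -> list[ComparisonSpec]:
    """Every cohort pair within each tissue plus tissue contrasts per cohort."""
    specs = []
    for tissue in TISSUES:
        for a, b in COHORT_PAIRS:
            specs.append(ComparisonSpec(f"{a} vs {b} / {tissue}",
                                        (a, tissue), (b, tissue), alpha))
    for cohort in COHORTS:
        specs.append(ComparisonSpec(f"{cohort} / fat_body vs cuticle",
                                    (cohort, "fat_body"), (cohort, "cuticle"), alpha))
    return specs


def run_all_comparisons(normalized: pd.DataFrame, design: DesignTable,
                        probe_to_mirna: pd.Series, alpha: float = 0.01,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """DE for all 16 comparisons.

    Returns ``(counts, results)``: the per-comparison DE counts and the
    concatenated per-miRNA results. Comparisons whose cohorts are absent
    from the design are listed with a missing count and a logged warning.
    """
    counts_rows = []
    frames = []
    present = design.cohorts
    for spec in all_comparisons(alpha):
        if spec.group_a[0] not in present or spec.group_b[0] not in present:
            logger.warning("comparison %s skipped: cohort missing from design", spec.label)
            counts_rows.append({"comparison": spec.label, "n_de": pd.NA})
            continue
        frame = call_de(normalized, design, probe_to_mirna,
                        spec.group_a, spec.group_b, alpha=spec.alpha, label=spec.label)
        frames.append(frame)
        counts_rows.append({"comparison": spec.label,
                            "n_de": int(frame["significant"].sum())})
    counts = pd.DataFrame(counts_rows)
    results = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return counts, results


def de_name_sets(results: pd.DataFrame, tissue: str) -> dict:
    """Up/down DE miRNA name sets vs S- for each test cohort in one tissue.

    A miRNA is upregulated in X vs S- iff significant and log2_fc > 0
    (strictly); no fold-change floor is applied.
    """
    sets: dict[tuple[str, str], set] = {}
    for cohort in VENN_GROUPS:
        label = f"{cohort} vs S- / {tissue}"
        sub = results[results["comparison"] == label]
        sig = sub[sub["significant"]]
        sets[(cohort, "up")] = set(sig.loc[sig["log2_fc"] > 0, "mirna_name"])
        sets[(cohort, "down")] = set(sig.loc[sig["log2_fc"] < 0, "mirna_name"])
    return sets


def exclude_shared_duplicates(de_rplus: set, de_splus: set) -> tuple[set, set, set]:
    """Drop miRNAs present in both infected cohorts (R+ and S+) from both sets.

    Returns ``(rplus_only, splus_only, shared)``.
    """
    shared = de_rplus & de_splus
    return de_rplus - shared, de_splus - shared, shared


def venn_partition(sets_by_group: dict) -> dict:
    """Disjoint 7-cell partition of three name sets (per direction).

    ``sets_by_group`` maps each of S+, R+, R- to a name set; keys of the
    result are frozensets over the group names ("specifically" regulated
    miRNAs sit in singleton cells). Cells are pairwise disjoint and their
    union is the union of the inputs.
    """
    missing = set(VENN_GROUPS) - set(sets_by_group)
    if missing:
        raise InputError(f"venn partition needs sets for {sorted(missing)}")
    cells = {frozenset(combo): set()
             for r in (1, 2, 3)
             for combo in itertools.combinations(VENN_GROUPS, r)}
    universe = set().union(*sets_by_group.values())
    for name in universe:
        membership = frozenset(g for g in VENN_GROUPS if name in sets_by_group[g])
        cells[membership].add(name)
    return cells


def venn_partition_by_tissue(results: pd.DataFrame, apply_exclusion: bool = True) -> dict:
    """Per-tissue, per-direction Venn partitions of DE-vs-S- sets.

    Follows the reporting order of the underlying study: the R+/S+ shared
    duplicates are removed (per tissue and direction) before partitioning.
    Returns ``{(tissue, direction): {cell_key: name_set}}``.
    """
    out = {}
    for tissue in TISSUES:
        sets = de_name_sets(results, tissue)
        for direction in DIRECTIONS:
            by_group = {g: set(sets[(g, direction)]) for g in VENN_GROUPS}
            if apply_exclusion:
                rp, sp, _shared = exclude_shared_duplicates(by_group["R+"], by_group["S+"])
                by_group["R+"], by_group["S+"] = rp, sp
            out[(tissue, direction)] = venn_partition(by_group)
    return out


def membership_agreement(truth_sets: dict, recovered_sets: dict) -> tuple[int, int]:
    """Agreement between two Venn inputs as (agreeing, total) membership
    indicators.

    A membership is one element-of-set indicator (miRNA x group); the
    partition cells are derived from exactly these indicators. Counted over
    the union of both partitions' members, three indicators per miRNA.
    """
    union = set().union(*truth_sets.values()) | set().union(*recovered_sets.values())
    agree = total = 0
    for name in union:
        for g in VENN_GROUPS:
            total += 1
            agree += (name in truth_sets[g]) == (name in recovered_sets[g])
    return agree, total


def venn_cells_frame(partitions: dict) -> pd.DataFrame:
    """Flatten venn partitions to a TSV-friendly frame."""
    rows = []
    for (tissue, direction), cells in partitions.items():
        for key in sorted(cells, key=lambda k: (len(k), sorted(k))):
            members = sorted(cells[key])
            rows.append({"tissue": tissue, "direction": direction,
                         "cell": "&".join(sorted(key)), "size": len(members),
                         "members": ",".join(members)})
    return pd.DataFrame(rows)
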