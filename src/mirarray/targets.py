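"""miRNA target prediction: seed scan plus hybridization-energy confirmation.

Candidate sites are exact Watson-Crick seed complements in putative 3'UTRs;
each candidate is confirmed by computing the minimum free energy of the
miRNA:site hybrid (seed pairing enforced) over a window of the seed match
plus flanking UTR context, and retained when the MFE is at or below a
configurable threshold. An optional transcript -> biological-process
annotation table turns the target list into per-process counts.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Optional

import pandas as pd

from .duplex import EnergyModel, DuplexResult, default_energy_model, duplex_mfe
from .orfs import UtrRecord
from .seeds import SeedMatch, SeedPattern, derive_seed, scan_seed_matches

logger = logging.getLogger(__name__)

DEFAULT_MFE_THRESHOLD = -20.0  # kcal/mol
DEFAULT_FLANK = 30             # nt of UTR context each side of the seed match


def _dna_to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def site_window(utr: UtrRecord, match_pos: int, flank: int = DEFAULT_FLANK) -> tuple[int, str]:
    """UTR window around a seed match (truncated at the UTR bounds), as RNA."""
    lo = max(0, match_pos - flank)
    hi = min(len(utr.sequence), match_pos + 7 + flank)
    return lo, _dna_to_rna(utr.sequence[lo:hi])


def predict_targets(mirnas: Iterable[tuple[str, str]], utrs: Iterable[UtrRecord],
                    model: Optional[EnergyModel] = None,
                    mfe_threshold: float = DEFAULT_MFE_THRESHOLD,
                    flank: int = DEFAULT_FLANK, seed_mode: str = "standard",
                    ) -> tuple[pd.DataFrame, list[DuplexResult]]:
    """Scan UTRs for seed matches and keep those whose hybrid MFE passes.

    Returns a table with one row per retained (miRNA, contig, site) and the
    matching DuplexResult list (for diagram output). ``mfe_threshold = inf``
    retains every seed match.
    """
    if model is None:
        model = default_energy_model()
    mirnas = list(mirnas)
    utrs = list(utrs)
    mirna_seq = dict(mirnas)
    patterns: list[SeedPattern] = [derive_seed(n, s, mode=seed_mode) for n, s in mirnas]
    matches: list[SeedMatch] = scan_seed_matches(utrs, patterns)
    utr_by_contig = {u.contig_id: u for u in utrs}
    rows = []
    duplexes: list[DuplexResult] = []
    for match in matches:
        utr = utr_by_contig[match.contig_id]
        _lo, window = site_window(utr, match.utr_pos, flank)
        result = duplex_mfe(match.mirna_name, mirna_seq[match.mirna_name], window,
                            model=model, require_seed=True)
        if result.mfe <= mfe_threshold:
            rows.append({
                "mirna_name": match.mirna_name,
                "contig_id": match.contig_id,
                "utr_pos": match.utr_pos,
                "contig_pos": match.contig_pos,
                "mfe_kcal_mol": result.mfe if math.isfinite(result.mfe) else float("nan"),
                "n_pairs": len(result.pairs),
            })
            duplexes.append(result)
    table = pd.DataFrame(rows, columns=["mirna_name", "contig_id", "utr_pos",
                                        "contig_pos", "mfe_kcal_mol", "n_pairs"])
    return table, duplexes


def summarize_by_process(targets: pd.DataFrame,
                         annotation: Optional[pd.DataFrame]) -> pd.DataFrame:
    """Distinct target contigs per biological process per miRNA.

    ``annotation`` has columns ``contig_id`` and ``process``; contigs
    without a usable annotation row are tallied as "unannotated". Malformed
    rows are skipped (a warning reports how many).
    """
    proc_map: dict[str, str] = {}
    skipped = 0
    if annotation is not None:
        for row in annotation.itertuples(index=False):
            contig = getattr(row, "contig_id", None)
            process = getattr(row, "process", None)
            if (not isinstance(contig, str) or not contig
                    or not isinstance(process, str) or not process):
                skipped += 1
                continue
            proc_map[contig] = process
    if skipped:
        logger.warning("summarize_by_process: skipped %d malformed annotation rows", skipped)
    if targets.empty:
        return pd.DataFrame(columns=["mirna_name", "process", "n_targets"])
    tab = targets[["mirna_name", "contig_id"]].drop_duplicates().copy()
    tab["process"] = tab["contig_id"].map(lambda c: proc_map.get(c, "unannotated"))
    out = (tab.groupby(["mirna_name", "process"])["contig_id"]
           .nunique().reset_index(name="n_targets")
           .sort_values(["mirna_name", "process"]).reset_index(drop=True))
    return out
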