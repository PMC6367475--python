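"""Synthetic transcriptome, miRNA set, design table and microarray generator.

Every downstream stage of the pipeline is exercised against data produced
here, with the planted ground truth recorded in a machine-readable
:class:`TruthTable`:

* contigs are built as ``5' pad + ORF (ATG..stop, no internal in-frame
  stop) + 3' tail``; with probability ``site_plant_prob`` the tail carries a
  target site for one designated miRNA (either the bare 7-mer seed
  complement or, by default, the reverse complement of the whole miRNA so
  the site also survives hybridization-energy confirmation);
* pads and tails are kept free of spurious start codons, and walks through
  planted sites are terminated early, so the 3'-most-complete-ORF reference
  rule recovers the planted ORF -- and hence the planted UTR -- exactly;
* microarray foreground signal is, on the log2 scale, a per-miRNA baseline
  plus planted cohort-by-tissue effects, a smooth intensity-dependent bias
  (per-sample coefficients spread evenly over [-1, 1] times a one-period
  sine of the baseline), and i.i.d. Gaussian replicate noise; intensities
  are emitted on the linear scale with an additive background channel, one
  probe triplicate per miRNA.

A single RNG stream seeded by ``rng_seed`` drives all draws; the draw order
(miRNAs, then contigs in order, then microarray baselines, DE assignment,
background, noise) is fixed so outputs are byte-stable for a given config.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimConfig, COHORTS, TISSUES
from .errors import ConfigurationError, IntegrityError
from .orfs import Contig, find_orfs, select_reference_orf, STOP_CODONS
from .seeds import derive_seed, rna_reverse_complement_dna

DNA = np.array(list("ACGT"))
RNA = "ACGU"
_NON_STOP_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                    if a + b + c not in STOP_CODONS]
_STOPS = sorted(STOP_CODONS)
TEST_COHORTS = ("S+", "R+", "R-")  # contrasted against the S- reference cohort


@dataclass
class TruthTable:
    """Planted ground truth: ORF coordinates, seed-site positions and DE effects.

    Coordinates are 0-based half-open; ``planted_sites`` records the offset
    of the exact seed-match 7-mer within the contig's 3'UTR (tail).
    """

    planted_orfs: list = field(default_factory=list)    # (contig, start, end, frame)
    planted_sites: list = field(default_factory=list)   # (contig, mirna, utr_offset)
    planted_de: list = field(default_factory=list)      # (mirna, comparison, direction, log2_fc)

    def orfs_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.planted_orfs, columns=["contig_id", "start", "end", "frame"])

    def sites_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.planted_sites, columns=["contig_id", "mirna_name", "utr_offset"])

    def de_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.planted_de,
                            columns=["mirna_name", "comparison", "direction", "log2_fc"])


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(DNA[rng.integers(0, 4, size=n)])


def make_mirna_set(config: SimConfig) -> list[tuple[str, str]]:
    """``n_mirnas`` mature miRNA records (RNA alphabet, unique names)."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    return _draw_mirnas(config, rng)


def _draw_mirnas(config: SimConfig, rng: np.random.Generator) -> list[tuple[str, str]]:
    lo, hi = config.mirna_len
    records = []
    width = max(4, len(str(config.n_mirnas)))
    for i in range(config.n_mirnas):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(RNA[b] for b in rng.integers(0, 4, size=length))
        records.append((f"syn-mir-{i + 1:0{width}d}", seq))
    return records


def _scrub_contig(seq: list, orf_start: int, orf_end: int, site_span, patterns,
                  min_orf_codons: int) -> None:
    """Mutate ``seq`` in place until no spurious reference-ORF candidate or
    (optionally) background seed occurrence survives.

    Spurious ATGs lose their G (G->C never creates a stop codon or a new
    ATG); ATGs whose G falls in a protected span (the planted stop codon or
    site) keep it, and if their reading frame would yield a complete ORF of
    ``min_orf_codons`` or more, a TAA is placed just past the protected
    region (insertion positions are reserved so fixes for different frames
    cannot undo each other). Background seed hits are broken at their
    middle base.
    """
    n = len(seq)
    site_lo, site_hi = site_span if site_span else (0, 0)
    reserved: set[int] = set()  # positions holding inserted TAA stops

    def in_site(p: int) -> bool:
        return site_span is not None and site_lo <= p < site_hi

    def first_stop_codons(pos: int):
        """Codon count to the first in-frame stop after ``pos``; None if none."""
        walk = pos + 3
        while walk + 3 <= n:
            if "".join(seq[walk:walk + 3]) in STOP_CODONS:
                return (walk + 3 - pos) // 3
            walk += 3
        return None

    for _ in range(100):
        changed = False
        s = "".join(seq)
        if patterns:
            # keep the UTR (tail) free of chance seed matches
            for pat in patterns:
                pos = s.find(pat, orf_end)
                while pos != -1:
                    if site_span is None or not (pos < site_hi and pos + len(pat) > site_lo):
                        for off in (3, 4, 2, 5, 1, 6, 0):
                            mut = pos + off
                            if mut < n and mut not in reserved:
                                seq[mut] = "C" if seq[mut] != "C" else "A"
                                changed = True
                                s = "".join(seq)
                                break
                    pos = s.find(pat, pos + 1)
        pos = s.find("ATG")
        while pos != -1:
            if pos != orf_start:
                g = pos + 2
                if in_site(g) or orf_end - 3 <= g < orf_end:
                    # protected G: terminate this frame early if it would
                    # otherwise out-compete the planted ORF
                    codons = first_stop_codons(pos)
                    if codons is not None and codons >= min_orf_codons:
                        protected_end = site_hi if in_site(g) else orf_end
                        q = pos + 3 * ((protected_end - pos + 2) // 3)
                        while (q + 3 <= n
                               and ((site_span is not None and q < site_hi and q + 3 > site_lo)
                                    or any(r in reserved for r in range(q, q + 3)))):
                            q += 3
                        if q + 3 <= n:
                            seq[q:q + 3] = list("TAA")
                            reserved.update(range(q, q + 3))
                            changed = True
                            s = "".join(seq)
                else:
                    seq[g] = "C"
                    changed = True
                    s = "".join(seq)
            pos = s.find("ATG", pos + 1)
        if not changed:
            return
    raise IntegrityError("contig scrubbing did not converge")


def make_transcriptome(config: SimConfig, mirnas: list[tuple[str, str]],
                       rng: np.random.Generator | None = None,
                       ) -> tuple[list[tuple[str, str]], TruthTable]:
    """Contigs with planted ORFs and (optionally) planted miRNA seed sites."""
    config.validate()
    if not mirnas:
        raise ConfigurationError("miRNA set is empty")
    if config.orf_len[0] < config.min_orf_codons:
        raise ConfigurationError(
            f"orf_len minimum {config.orf_len[0]} is below min_orf_codons "
            f"{config.min_orf_codons}; planted ORFs would not be recoverable"
        )
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
        _draw_mirnas(config, rng)  # keep the documented draw order
    patterns = ([derive_seed(name, seq).match_dna for name, seq in mirnas]
                if config.scrub_background_seeds else None)
    truth = TruthTable()
    contigs: list[tuple[str, str]] = []
    width = max(4, len(str(config.n_contigs)))
    for ci in range(config.n_contigs):
        cid = f"contig{ci + 1:0{width}d}"
        length = int(rng.integers(config.contig_len[0], config.contig_len[1] + 1))
        codons = int(rng.integers(config.orf_len[0], config.orf_len[1] + 1))
        orf_nt = 3 * codons
        pad5 = int(rng.integers(0, length - orf_nt - 30 + 1))
        tail_len = length - pad5 - orf_nt
        pad = _random_bases(rng, pad5)
        interior = "".join(_NON_STOP_CODONS[k]
                           for k in rng.integers(0, len(_NON_STOP_CODONS), size=codons - 2))
        stop = _STOPS[rng.integers(0, 3)]
        tail = list(_random_bases(rng, tail_len))
        site_span = None
        plant = rng.random() < config.site_plant_prob
        if plant:
            mi = int(rng.integers(0, len(mirnas)))
            name, mseq = mirnas[mi]
            site_dna = (rna_reverse_complement_dna(mseq) if config.site_context == "full"
                        else derive_seed(name, mseq).match_dna)
            if tail_len < len(site_dna):
                raise ConfigurationError("tail too short to plant a site; enlarge contig_len")
            off = int(rng.integers(0, tail_len - len(site_dna) + 1))
            tail[off:off + len(site_dna)] = list(site_dna)
            orf_end = pad5 + orf_nt
            site_span = (orf_end + off, orf_end + off + len(site_dna))
            seed_off = off + (len(mseq) - 8 if config.site_context == "full" else 0)
            truth.planted_sites.append((cid, name, seed_off))
        seq = list(pad + "ATG" + interior + stop) + tail
        orf_start, orf_end = pad5, pad5 + orf_nt
        _scrub_contig(seq, orf_start, orf_end, site_span, patterns, config.min_orf_codons)
        contig_seq = "".join(seq)
        truth.planted_orfs.append((cid, orf_start, orf_end, orf_start % 3))
        ref = select_reference_orf(find_orfs(Contig(cid, contig_seq), config.min_orf_codons))
        if ref is None or (ref.start, ref.end) != (orf_start, orf_end):
            raise IntegrityError(f"{cid}: planted ORF not recovered as reference ORF")
        contigs.append((cid, contig_seq))
    # planted seed matches must be literally present
    seqs = dict(contigs)
    mir_seq = dict(mirnas)
    orf_ends = {c: e for c, _s, e, _f in truth.planted_orfs}
    for cid, name, seed_off in truth.planted_sites:
        pat = derive_seed(name, mir_seq[name]).match_dna
        start = orf_ends[cid] + seed_off
        if seqs[cid][start: start + 7] != pat:
            raise IntegrityError(f"{cid}: planted site corrupted during scrubbing")
    return contigs, truth


def make_design(config: SimConfig) -> pd.DataFrame:
    """4 cohorts x 2 tissues x ``replicates`` samples with unique ids."""
    config.validate()
    rows = [
        {"sample_id": f"{cohort}_{tissue}_r{rep}", "cohort": cohort,
         "tissue": tissue, "replicate": rep}
        for cohort in COHORTS for tissue in TISSUES
        for rep in range(1, config.replicates + 1)
    ]
    return pd.DataFrame(rows)


def _bias_curve(baseline_log2: np.ndarray) -> np.ndarray:
    """Smooth intensity-dependent bias shape: a ramp over the baseline range,
    scaled to [-1, 1] (the classic linear-in-log-intensity channel bias)."""
    lo, hi = 8.0, 13.0
    return 2.0 * (baseline_log2 - 0.5 * (lo + hi)) / (hi - lo)


def make_microarray(config: SimConfig, mirnas: list[tuple[str, str]],
                    design: pd.DataFrame, truth: TruthTable | None = None,
                    rng: np.random.Generator | None = None,
                    planted_de: list | None = None):
    """Linear-scale probe intensities (triplicate probes per miRNA) plus truth.

    ``planted_de`` may pre-specify ``(mirna_name, comparison, direction,
    log2_fc)`` rows; by default ``n_de_per_comparison`` miRNAs are drawn per
    cohort-vs-S- contrast in each tissue. Returns an
    :class:`~mirarray.expression.IntensityMatrix`.
    """
    from .expression import IntensityMatrix  # local import to avoid a cycle

    config.validate()
    if truth is None:
        truth = TruthTable()
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    names = [n for n, _ in mirnas]
    name_to_idx = {n: i for i, n in enumerate(names)}
    n_mir = len(names)
    samples = list(design["sample_id"])
    n_samp = len(samples)

    baselines = rng.uniform(8.0, 13.0, size=n_mir)

    if planted_de is None:
        planted_de = []
        k = min(config.n_de_per_comparison, n_mir)
        for tissue in TISSUES:
            for cohort in TEST_COHORTS:
                picks = rng.choice(n_mir, size=k, replace=False)
                dirs = rng.choice([1.0, -1.0], size=k)
                label = f"{cohort} vs S- / {tissue}"
                for idx, d in zip(picks, dirs):
                    planted_de.append((names[idx], label,
                                       "up" if d > 0 else "down", d * config.log2_fc))
    effects = np.zeros((n_mir, n_samp))
    cohort_of = dict(zip(design["sample_id"], design["cohort"]))
    tissue_of = dict(zip(design["sample_id"], design["tissue"]))
    for mirna_name, label, _direction, lfc in planted_de:
        if mirna_name not in name_to_idx:
            raise ConfigurationError(f"planted_de names unknown miRNA {mirna_name!r}")
        cohort = label.split(" vs ")[0]
        tissue = label.split(" / ")[1]
        for k_s, s in enumerate(samples):
            if cohort_of[s] == cohort and tissue_of[s] == tissue:
                effects[name_to_idx[mirna_name], k_s] += lfc
    truth.planted_de.extend(planted_de)

    bias_coef = np.linspace(-1.0, 1.0, n_samp) if n_samp > 1 else np.zeros(1)
    probe_ids, probe_mirnas, probe_rep = [], [], []
    for n in names:
        for k_p in (1, 2, 3):
            probe_ids.append(f"{n}|p{k_p}")
            probe_mirnas.append(n)
            probe_rep.append(k_p)
    n_probes = len(probe_ids)
    mir_idx = np.repeat(np.arange(n_mir), 3)

    if config.background_mean > 0:
        background = rng.normal(config.background_mean, 0.1 * config.background_mean,
                                size=(n_probes, n_samp)).clip(min=0.0)
    else:
        background = np.zeros((n_probes, n_samp))
    noise = (rng.normal(0.0, config.noise_sd, size=(n_probes, n_samp))
             if config.noise_sd > 0 else np.zeros((n_probes, n_samp)))

    base = baselines[mir_idx][:, None]
    log2_signal = (base + effects[mir_idx, :]
                   + config.bias_amplitude * bias_coef[None, :] * _bias_curve(base)
                   + noise)
    foreground = np.power(2.0, log2_signal) + background

    fg = pd.DataFrame(foreground, index=probe_ids, columns=samples)
    bg = pd.DataFrame(background, index=probe_ids, columns=samples)
    probe_map = pd.Series(probe_mirnas, index=probe_ids, name="mirna_name")
    matrix = IntensityMatrix(foreground=fg, background=bg, probe_to_mirna=probe_map,
                             replicate_probe=pd.Series(probe_rep, index=probe_ids))
    return matrix, truth


def simulate_all(config: SimConfig):
    """Run all four generators on one RNG stream in the documented order."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    mirnas = _draw_mirnas(config, rng)
    contigs, truth = make_transcriptome(config, mirnas, rng=rng)
    design = make_design(config)
    matrix, truth = make_microarray(config, mirnas, design, truth, rng=rng)
    return mirnas, contigs, design, matrix, truth
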