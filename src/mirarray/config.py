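"""Configuration dataclasses for the simulator and the pipeline."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from .errors import ConfigurationError

COHORTS = ("R+", "R-", "S+", "S-")
TISSUES = ("cuticle", "fat_body")


@dataclass
class SimConfig:
    """Study conditions for the synthetic-data generator.

    Defaults emulate the profiled system at desk scale: four cohorts
    (resistant/susceptible x infected/uninfected) sampled in two tissues
    with three replicates, miRNAs of 18-24 nt printed in probe triplicate,
    contigs carrying a single coding ORF followed by a 3' tail that may
    contain a planted miRNA seed site.
    """

    rng_seed: int = 0
    n_contigs: int = 400
    contig_len: tuple[int, int] = (600, 1200)     # nt, inclusive range
    orf_len: tuple[int, int] = (40, 150)          # codons incl. start & stop
    n_mirnas: int = 300
    mirna_len: tuple[int, int] = (18, 24)         # nt, inclusive range
    site_plant_prob: float = 0.30
    n_de_per_comparison: int = 20
    log2_fc: float = 2.0
    noise_sd: float = 0.25                        # log2-scale replicate noise
    bias_amplitude: float = 0.8                   # log2 units of smooth MA bias
    background_mean: float = 60.0                 # linear fluorescence units
    replicates: int = 3
    site_context: str = "full"                    # "full" | "seed"
    scrub_background_seeds: bool = False
    min_orf_codons: int = 30                      # reference-ORF threshold the fixture honors

    def validate(self) -> None:
        for name in ("n_contigs", "n_mirnas", "n_de_per_comparison", "replicates"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.replicates < 2:
            raise ConfigurationError("replicates must be >= 2 for paired testing")
        if not 0.0 <= self.site_plant_prob <= 1.0:
            raise ConfigurationError("site_plant_prob must be in [0, 1]")
        for name in ("contig_len", "orf_len", "mirna_len"):
            lo, hi = getattr(self, name)
            if lo > hi or lo <= 0:
                raise ConfigurationError(f"{name} range ({lo}, {hi}) is empty or nonpositive")
        if self.mirna_len[0] < 8:
            raise ConfigurationError("mirna_len minimum must be >= 8 (seed positions 2-8)")
        if self.noise_sd < 0 or self.bias_amplitude < 0 or self.background_mean < 0:
            raise ConfigurationError("noise_sd, bias_amplitude, background_mean must be >= 0")
        if self.site_context not in ("full", "seed"):
            raise ConfigurationError("site_context must be 'full' or 'seed'")
        # contig must hold the largest ORF plus a usable tail
        if 3 * self.orf_len[1] + 30 > self.contig_len[0]:
            raise ConfigurationError(
                f"orf_len up to {self.orf_len[1]} codons does not fit in contigs of "
                f"{self.contig_len[0]} nt with a 3' tail"
            )


@dataclass
class PipelineConfig:
    """One structured configuration for the whole pipeline."""

    seed: int = 0
    out_dir: str = "mirarray_out"
    sim: SimConfig = field(default_factory=SimConfig)
    span: float = 0.3                 # LOWESS span (fraction of probes)
    alpha_mirna: float = 0.01         # miRNA DE significance gate
    alpha_other: float = 0.05         # all other tests
    seed_mode: str = "standard"       # seed interpretation flag
    energy_model_path: Optional[str] = None
    mfe_threshold: float = -20.0      # kcal/mol
    site_flank: int = 30              # nt of UTR context each side of a seed match
    min_orf_codons: int = 30
    min_utr_len: int = 7
    annotation_path: Optional[str] = None

    def validate(self) -> None:
        for name in ("alpha_mirna", "alpha_other"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ConfigurationError(f"{name} must be in (0, 1)")
        if not 0.0 < self.span <= 1.0:
            raise ConfigurationError("span must be in (0, 1]")
        self.sim.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", {})
        for key in ("contig_len", "orf_len", "mirna_len"):
            if key in sim_raw:
                sim_raw[key] = tuple(sim_raw[key])
        cfg = cls(**{k: v for k, v in raw.items()}, sim=SimConfig(**sim_raw)) \
            if sim_raw is not None else cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self) -> str:
        d = asdict(self)
        for key in ("contig_len", "orf_len", "mirna_len"):
            d["sim"][key] = list(d["sim"][key])
        return yaml.safe_dump(d, sort_keys=True)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (output location excluded)."""
        d = yaml.safe_load(self.to_yaml())
        d.pop("out_dir", None)
        return hashlib.sha256(yaml.safe_dump(d, sort_keys=True).encode()).hexdigest()[:12]
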