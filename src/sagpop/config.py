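"""Pipeline configuration: per-stage parameter blocks, YAML loading with
strict key checking, and per-stage RNG substreams derived from one root
seed (re-running one stage never shifts another stage's randomness).
"""
from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field, fields

import numpy as np
import yaml

logger = logging.getLogger(__name__)


@dataclass
class SimulateBlock:
    n_species: int = 3
    pop_size: int = 100
    genome_length: int = 50_000
    mut_rate: float = 2.5e-5
    recomb_rate: float = 1e-2
    tract_mean: float = 5000.0
    generations: int = 1000
    sample_n: int = 16
    breadth_mean: float = 0.7
    breadth_sd: float = 0.1
    block_mean: int = 5000
    min_contig: int = 500
    contam_prob: float = 0.0
    species_divergence: float = 0.12


@dataclass
class AniBlock:
    frag_len: int = 1000
    kmer: int = 16
    min_frag_frac: float = 0.2
    band: int = 32
    species_threshold: float = 95.0
    mge_threshold: float = 99.0


@dataclass
class SnpBlock:
    max_contamination: float = 0.05
    min_called_cells: int = 10
    min_called_frac: float = 0.5
    min_minor_count: int = 2


@dataclass
class LdBlock:
    min_cells: int = 5
    bin_min: float = 10.0
    bin_max: float = 50_000.0
    n_bins: int = 20
    ld50_threshold: float = 0.5
    min_maf: float = 0.25
    min_pairs_per_bin: int = 10
    n_boot: int = 200
    write_pairs: bool = False


@dataclass
class PopstructBlock:
    min_shared: int = 20
    k_max: int = 10
    n_perm: int = 999
    distance: str = "cophenetic"  # or "snp"


@dataclass
class GenefamBlock:
    identity: float = 0.8
    coverage: float = 0.8
    min_genomes: int = 2
    sag_only_rule: bool = True
    rarefaction_mode: str = "closed_form"
    n_perm: int = 1000
    gene_length: int = 900


@dataclass
class MgeBlock:
    min_len: int = 10_000
    n_perm: int = 999
    circular_min_overlap: int = 50
    circular_max_mismatch: int = 0
    tnf_z_cutoff: float = 2.0


@dataclass
class CrisprBlock:
    repeat_len_min: int = 19
    repeat_len_max: int = 48
    spacer_len_min: int = 17
    spacer_len_max: int = 50
    min_repeats: int = 3
    max_repeat_mismatch: int = 1
    max_mismatch: int = 1
    exclusion_margin: int = 500


@dataclass
class PrimerBlock:
    # 926wF / 1392R (Tremblay et al. 2015) supplied as configuration
    fw: str = "AAACTYAAAKGAATTGRCGG"
    rv: str = "ACGGGCGGTGTGTRC"
    amplicon_min: int = 300
    amplicon_max: int = 600
    max_total_mm: int = 1
    max_3prime_mm: int = 0
    intron_excess: int = 150
    fail_floor: int = 5
    fail_frac_threshold: float = 0.8


_BLOCKS = {
    "simulate": SimulateBlock,
    "ani": AniBlock,
    "snp": SnpBlock,
    "ld": LdBlock,
    "popstruct": PopstructBlock,
    "genefam": GenefamBlock,
    "mge": MgeBlock,
    "crispr": CrisprBlock,
    "primers": PrimerBlock,
}


@dataclass
class PipelineConfig:
    rng_seed: int = 0
    simulate: SimulateBlock = field(default_factory=SimulateBlock)
    ani: AniBlock = field(default_factory=AniBlock)
    snp: SnpBlock = field(default_factory=SnpBlock)
    ld: LdBlock = field(default_factory=LdBlock)
    popstruct: PopstructBlock = field(default_factory=PopstructBlock)
    genefam: GenefamBlock = field(default_factory=GenefamBlock)
    mge: MgeBlock = field(default_factory=MgeBlock)
    crispr: CrisprBlock = field(default_factory=CrisprBlock)
    primers: PrimerBlock = field(default_factory=PrimerBlock)

    def rng(self, stage: str) -> np.random.Generator:
        """Independent substream keyed by (root seed, stage name)."""
        digest = hashlib.sha256(stage.encode()).digest()
        key = int.from_bytes(digest[:4], "big")
        return np.random.default_rng([int(self.rng_seed), key])

    def log_stage(self, stage: str) -> None:
        block = getattr(self, stage, None)
        if block is not None:
            logger.info("stage %s parameters: %s", stage, dataclasses.asdict(block))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str) -> PipelineConfig:
    """Load YAML config; any unknown key (top-level or within a stage
    block) is an error naming that key."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    cfg = PipelineConfig()
    for key, val in raw.items():
        if key == "rng_seed":
            cfg.rng_seed = int(val)
        elif key in _BLOCKS:
            block = getattr(cfg, key)
            valid = {f.name for f in fields(block)}
            for subkey, subval in (val or {}).items():
                if subkey not in valid:
                    raise ValueError(f"unknown config key {key}.{subkey!r}")
                setattr(block, subkey, type(getattr(block, subkey))(subval))
        else:
            raise ValueError(f"unknown config key {key!r}")
    return cfg
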