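"""Run configuration: one YAML document drives every stage.

Unknown keys are rejected and validation errors are reported in a batch,
so a typo in a parameter name cannot silently fall back to a default.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError


class Paths(BaseModel):
    model_config = ConfigDict(extra="forbid")

    reference_fasta: Optional[str] = None
    length_table: Optional[str] = None
    abundance: Optional[str] = None
    design: Optional[str] = None
    alignments_dir: Optional[str] = None   # per-sample TSV/SAM files
    readmaps_dir: Optional[str] = None


class SimulationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_genes: int = 200
    n_replicates: int = 3
    depth: int = 100_000
    n_stalls: int = 4
    stall_amplitude: float = 20.0
    readthrough_min: float = 0.1
    readthrough_max: float = 0.5
    stall_codon_min: int = 16
    stall_codon_max: int = 60
    uorf_rate: float = 0.1
    paralog_rate: float = 0.02
    polyA_neg_rate: float = 0.02
    dispersion: float = 0.05
    assays: List[str] = Field(default_factory=lambda: ["ribo", "mrna"])


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    paths: Paths = Field(default_factory=Paths)
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)

    psite_offset: int = 14
    min_len: int = 26
    max_len: int = 34
    max_sites: int = 5
    min_tpm: float = 1.0
    isoform_mode: str = "best"
    min_fraction: float = 0.1
    bin_size: int = 300
    z_min: float = 2.0
    fdr_max: float = 0.1
    default_codon: int = 50
    cod_z_min: float = 3.0
    omit_first: List[int] = Field(default_factory=lambda: [0, 50, 100, 150])
    min_reads: int = 64
    min_cds_len: int = 600
    metagene_start_window: List[int] = Field(default_factory=lambda: [-50, 300])
    metagene_stop_window: List[int] = Field(default_factory=lambda: [-300, 50])

    seed: int = 1
    outdir: str = "ribostall_out"


class ConfigError(ValueError):
    """Raised with every validation problem listed, not just the first."""


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as e:
        lines = [f"  {'.'.join(str(x) for x in err['loc'])}: {err['msg']}"
                 for err in e.errors()]
        raise ConfigError("invalid configuration:\n" + "\n".join(lines)) from None
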