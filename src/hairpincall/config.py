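"""Pipeline configuration: tunable thresholds, organism presets, file parsing.

The config file dialect is flat ``key = value`` lines with ``#`` comments.
Precedence (lowest to highest): organism preset defaults, config file,
explicit overrides (e.g. from ``--set key=value`` on the command line).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping


class ConfigError(ValueError):
    """Raised for unknown keys or invariant violations."""


@dataclass
class Config:
    """All tunable thresholds of the precursor-identification pipeline.

    Units: lengths in nt, energies in kcal/mol (per nt where noted),
    fractions in [0, 1].
    """

    # stage 1 -- candidate cluster definition
    cluster_min_reads: int = 10      # min summed read multiplicity per contig
    cluster_gap_size: int = 10       # merge contigs separated by < this many nt
    cluster_flank_size: int = 200    # flank F added on both sides of a contig
    cluster_max_length: int = 2000   # contigs longer than this are discarded

    # stage 2a -- secondary structure constraints
    min_mfe_per_nt: float = -0.2     # pass iff MFE/nt <= this (kcal/mol/nt)
    max_hairpin_count: int = 4       # pass iff N_term < this
    min_double_strand_length: int = 18  # pass iff L_ds,max >= this

    # stage 2b -- shuffle significance
    permutation_count: int = 100
    max_pvalue: float = 0.05

    # stage 3 -- mature/star duplex verification
    min_coverage: float = 0.10       # mature stack share of precursor reads (strict >)
    min_duplex_length: int = 20      # min_duplex_length <= L < max_duplex_length
    max_duplex_length: int = 25
    min_paired_fraction: float = 0.67
    allow_three_mismatches: bool = True
    allow_two_terminal_mismatches: bool = True

    # execution
    worker_count: int = 1
    window_step: int = 5             # fold-window grid granularity, nt
    uniqueness_tolerance: float = 0.01  # kcal/mol/nt band for the uniqueness flag
    seed: int = 42

    # extras behind explicit switches
    fold_backend: str = "vienna"     # "vienna" (thermodynamic) or "maxpair" (fallback)
    dinucleotide_shuffle: bool = False
    bh_correction: bool = False
    edge_tolerance: int = 0          # nt; merge near-identical read stacks
    primary_only: bool = False       # drop secondary/supplementary alignments

    def validate(self) -> None:
        def bound(cond: bool, msg: str) -> None:
            if not cond:
                raise ConfigError(msg)

        bound(self.cluster_min_reads >= 1, "cluster_min_reads >= 1 violated")
        bound(self.cluster_gap_size >= 0, "cluster_gap_size >= 0 violated")
        bound(self.cluster_flank_size >= 0, "cluster_flank_size >= 0 violated")
        bound(self.cluster_max_length > 0, "cluster_max_length > 0 violated")
        bound(self.min_duplex_length < self.max_duplex_length,
              "min_duplex_length < max_duplex_length violated")
        bound(0.0 <= self.max_pvalue <= 1.0, "0 <= max_pvalue <= 1 violated")
        bound(0.0 < self.min_coverage <= 1.0, "0 < min_coverage <= 1 violated")
        bound(0.0 <= self.min_paired_fraction <= 1.0,
              "0 <= min_paired_fraction <= 1 violated")
        bound(self.permutation_count >= 1, "permutation_count >= 1 violated")
        bound(self.worker_count >= 1, "worker_count >= 1 violated")
        bound(self.window_step >= 1, "window_step >= 1 violated")
        bound(self.uniqueness_tolerance >= 0.0,
              "uniqueness_tolerance >= 0 violated")
        bound(self.max_hairpin_count >= 1, "max_hairpin_count >= 1 violated")
        bound(self.edge_tolerance >= 0, "edge_tolerance >= 0 violated")
        bound(self.fold_backend in ("vienna", "maxpair"),
              "fold_backend must be 'vienna' or 'maxpair'")


# Organism presets. The contrast follows known precursor-population
# differences: algal precursors carry longer double-stranded segments and
# lower per-nucleotide minimum free energies than plant precursors.
PRESETS: dict[str, dict[str, Any]] = {
    "plants": {"min_mfe_per_nt": -0.2, "min_double_strand_length": 18},
    "algae": {"min_mfe_per_nt": -0.4, "min_double_strand_length": 24},
}

_FIELDS = {f.name: f.type for f in dataclasses.fields(Config)}
_BOOL_TRUE = {"1", "true", "yes", "on"}
_BOOL_FALSE = {"0", "false", "no", "off"}


def _coerce(key: str, value: Any) -> Any:
    target = _FIELDS[key]
    if isinstance(value, str):
        value = value.strip()
        if target == "bool" or target is bool:
            low = value.lower()
            if low in _BOOL_TRUE:
                return True
            if low in _BOOL_FALSE:
                return False
            raise ConfigError(f"cannot parse boolean for '{key}': {value!r}")
        if target == "int" or target is int:
            return int(value)
        if target == "float" or target is float:
            return float(value)
        return value
    return value


def parse_config_file(path: str | Path) -> dict[str, str]:
    """Parse a flat ``key = value`` file with ``#`` comments."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        out[key] = value
    return out


def load_config(path: str | Path | None = None,
                overrides: Mapping[str, Any] | None = None,
                preset: str = "plants") -> Config:
    """Build a validated :class:`Config`.

    Precedence: preset defaults, then the config file, then ``overrides``.
    Unknown keys are a hard error naming the key.
    """
    if preset not in PRESETS:
        raise ConfigError(f"unknown preset '{preset}' (choose from {sorted(PRESETS)})")
    values: dict[str, Any] = dict(PRESETS[preset])
    layers: list[Mapping[str, Any]] = []
    if path is not None:
        layers.append(parse_config_file(path))
    if overrides:
        layers.append(overrides)
    for layer in layers:
        for key, value in layer.items():
            if key not in _FIELDS:
                raise ConfigError(f"unknown configuration key '{key}'")
            values[key] = _coerce(key, value)
    cfg = Config(**values)
    cfg.validate()
    return cfg


def dump_config(cfg: Config) -> str:
    """Serialize a Config back to the flat file dialect (round-trippable)."""
    lines = [f"{f.name} = {getattr(cfg, f.name)}" for f in dataclasses.fields(Config)]
    return "\n".join(lines) + "\n"
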