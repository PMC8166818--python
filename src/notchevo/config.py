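"""Run-wide configuration.

Every tunable of the pipeline lives in :class:`RunConfig` so that a run is
fully described by (inputs, config, seed).  The on-disk representation is a
flat ``key: value`` text file; unknown keys are an error so that typos are
caught instead of silently ignored.
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path

from .errors import ValidationError


@dataclasses.dataclass
class RunConfig:
    """Pipeline parameters with their scientifically meaningful defaults.

    Parameters
    ----------
    e_value_threshold:
        Domain hits with E-value above this are discarded before
        classification (HMMER-style screen at E <= 1e-5).
    several_min_count:
        Operational floor for "several" repeats in family definitions
        (EGF and ANK counts in the Notch receptor signature).
    window_lo, window_hi:
        Premature-stop window, in amino acids downstream of the conserved
        anchor residue of the reference paralog (inclusive bounds).
    complementarity_threshold, similarity_threshold:
        Rank-correlation cutoffs for calling a pair of developmental
        expression profiles complementary (score <= -0.5) or similar
        (score >= 0.5).
    gap_fraction_trim:
        Alignment columns with a gap fraction above this are removed
        before distance computation.
    bootstrap_reps:
        Number of column-resampling replicates for branch support.
    rng_seed:
        Seed for every stochastic step of a run.
    anchor_residue:
        Amino acid used as the truncation-window anchor (arginine for the
        Delta1/Delta2 comparison; configurable for other families).
    low_expression_floor:
        Genes whose median raw expression is below this are flagged as
        low-expressed in reports (no further claim is attached).
    """

    e_value_threshold: float = 1e-5
    several_min_count: int = 2
    window_lo: int = 1
    window_hi: int = 10
    complementarity_threshold: float = -0.5
    similarity_threshold: float = 0.5
    gap_fraction_trim: float = 0.5
    bootstrap_reps: int = 1000
    rng_seed: int = 0
    anchor_residue: str = "R"
    low_expression_floor: float = 1.0

    def __post_init__(self) -> None:
        if self.e_value_threshold <= 0:
            raise ValidationError("e_value_threshold must be positive")
        if self.several_min_count < 1:
            raise ValidationError("several_min_count must be >= 1")
        if self.window_lo > self.window_hi:
            raise ValidationError("window_lo must be <= window_hi")
        if not -1.0 <= self.complementarity_threshold <= 0.0:
            raise ValidationError("complementarity_threshold must be in [-1, 0]")
        if not 0.0 <= self.similarity_threshold <= 1.0:
            raise ValidationError("similarity_threshold must be in [0, 1]")
        if not 0.0 <= self.gap_fraction_trim <= 1.0:
            raise ValidationError("gap_fraction_trim must be in [0, 1]")
        if self.bootstrap_reps < 1:
            raise ValidationError("bootstrap_reps must be >= 1")
        if len(self.anchor_residue) != 1 or not self.anchor_residue.isalpha():
            raise ValidationError("anchor_residue must be a single letter")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Read a flat ``key: value`` config file; unknown keys are errors."""
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise ValidationError(f"{path}:{lineno}: expected 'key: value'")
            key, _, value = line.partition(":")
            key, value = key.strip(), value.strip()
            if key not in fields:
                raise ValidationError(f"{path}:{lineno}: unknown config key {key!r}")
            typ = fields[key].type
            try:
                if typ in ("int", int):
                    kwargs[key] = int(value)
                elif typ in ("float", float):
                    kwargs[key] = float(value)
                else:
                    kwargs[key] = value
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: bad value for {key}: {exc}")
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        lines = [
            f"{f.name}: {getattr(self, f.name)}" for f in dataclasses.fields(self)
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    def config_hash(self) -> str:
        """Short stable digest of all parameter values (stamped on outputs)."""
        payload = ";".join(
            f"{f.name}={getattr(self, f.name)!r}" for f in dataclasses.fields(self)
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
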