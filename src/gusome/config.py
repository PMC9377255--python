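"""Pipeline configuration: defaults, TOML loading, validation."""
from __future__ import annotations

import dataclasses
import logging
import sys
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .align import AlignParams


@dataclass
class ClassThresholds:
    """Loop-length thresholds for structural-class assignment.

    Lengths are measured as the span of the candidate segment projected
    onto a representative's loop window (residues, including the window
    flanks).  ``fmn_identity_cutoff`` and ``fmn_min_coverage`` govern the
    FMN C-terminal-segment test that runs before the loop rule.
    """

    loop_long: int = 16  # >= -> L1 / L2
    loop_mini: int = 7  # >= -> mL1 / mL2 (below loop_long)
    fmn_identity_cutoff: float = 0.30
    fmn_min_coverage: float = 0.75


@dataclass
class PipelineConfig:
    """All tunables of the discovery/quantification pipeline."""

    identity_threshold: float = 0.25  # strict > for the screen
    cluster_threshold: float = 0.90  # >= for redundancy clustering
    alignment: AlignParams = field(default_factory=AlignParams)
    class_thresholds: ClassThresholds = field(default_factory=ClassThresholds)
    taxonomy_floor: float = 0.40
    residue_check_mode: str = "best_rep"  # or "any_rep"
    shannon_base: float = 2.0
    n_permutations: int = 999
    wald_reference: str = "normal"  # or "t"
    length_unit: str = "aa"  # gene length unit in the bias regression
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.identity_threshold < self.cluster_threshold <= 1):
            raise ValueError(
                "need 0 < identity_threshold < cluster_threshold <= 1, got "
                f"{self.identity_threshold} / {self.cluster_threshold}"
            )
        if self.residue_check_mode not in ("best_rep", "any_rep"):
            raise ValueError(f"bad residue_check_mode {self.residue_check_mode!r}")
        if self.wald_reference not in ("normal", "t"):
            raise ValueError(f"bad wald_reference {self.wald_reference!r}")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from a TOML file with one section per stage."""
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        kwargs: dict = {}
        screen = data.get("screen", {})
        for key in ("identity_threshold", "cluster_threshold", "residue_check_mode",
                    "taxonomy_floor"):
            if key in screen:
                kwargs[key] = screen[key]
        if "alignment" in data:
            kwargs["alignment"] = AlignParams(**data["alignment"])
        if "classes" in data:
            kwargs["class_thresholds"] = ClassThresholds(**data["classes"])
        stats = data.get("stats", {})
        for key in ("shannon_base", "n_permutations", "wald_reference"):
            if key in stats:
                kwargs[key] = stats[key]
        if "abundance" in data and "length_unit" in data["abundance"]:
            kwargs["length_unit"] = data["abundance"]["length_unit"]
        if "seed" in data:
            kwargs["seed"] = data["seed"]
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def get_logger(name: str = "gusome", verbose: bool = False) -> logging.Logger:
    """Timestamped stage/level logging to standard error."""
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)
    return logger
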