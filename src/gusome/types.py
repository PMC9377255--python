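"""Domain types shared across the pipeline.

Coordinate convention: all residue positions are 1-based and intervals are
closed, matching the convention written into every TSV output header.
"""
from __future__ import annotations

from dataclasses import dataclass, field

#: Structural classes of gut microbial beta-glucuronidases, in the fixed
#: order used for deterministic tie-breaking.
GUS_CLASSES = ("L1", "mL1", "L2", "mL2", "mL1_2", "NL", "FMN", "NC")

#: Canonical amino-acid alphabet plus the ambiguity letter X.
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class ProteinRecord:
    """One protein-catalog entry (a translated metagenomic gene)."""

    id: str
    seq: str
    samples: frozenset[str] = frozenset()
    description: str = ""

    @property
    def length(self) -> int:
        return len(self.seq)

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = set(self.seq) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r} contains non-amino-acid letters: "
                f"{''.join(sorted(bad))}"
            )


@dataclass(frozen=True)
class RepresentativeGus:
    """A reference GUS enzyme with annotated catalytic and loop architecture.

    ``catalytic_positions`` are exactly seven (position, residue) pairs,
    1-based on this representative's own sequence.  ``loop1_window`` and
    ``loop2_window`` are closed 1-based intervals marking the active-site
    loop regions used for structural-class assignment.  ``fmn_segment`` is
    the closed interval of the C-terminal FMN-binding domain (FMN-class
    representatives only, else None).
    """

    id: str
    seq: str
    gus_class: str
    catalytic_positions: tuple[tuple[int, str], ...]
    loop1_window: tuple[int, int]
    loop2_window: tuple[int, int]
    fmn_segment: tuple[int, int] | None = None
    taxonomy: str = ""

    @property
    def length(self) -> int:
        return len(self.seq)

    def __post_init__(self) -> None:
        if self.gus_class not in GUS_CLASSES:
            raise ValueError(f"unknown GUS class {self.gus_class!r}")
        if len(self.catalytic_positions) != 7:
            raise ValueError(
                f"representative {self.id!r} must annotate exactly 7 "
                f"catalytic positions, got {len(self.catalytic_positions)}"
            )
        for pos, letter in self.catalytic_positions:
            if not (1 <= pos <= len(self.seq)):
                raise ValueError(
                    f"catalytic position {pos} outside {self.id!r} "
                    f"(length {len(self.seq)})"
                )
            if self.seq[pos - 1] != letter:
                raise ValueError(
                    f"representative {self.id!r} residue at {pos} is "
                    f"{self.seq[pos - 1]}, annotation says {letter}"
                )


@dataclass(frozen=True)
class SampleMeta:
    """Cohort metadata for one fecal sample."""

    sample_id: str
    group: str  # "MMF_recipient" | "healthy"
    covariates: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.group not in ("MMF_recipient", "healthy"):
            raise ValueError(f"unknown group label {self.group!r}")


@dataclass
class GusCall:
    """Screening verdict for one catalog candidate."""

    candidate_id: str
    best_rep: str
    best_identity: float
    residue_matches: tuple[bool, ...]
    accepted: bool
    reject_reason: str  # "below_identity" | "missing_residue" | "none"

    def __post_init__(self) -> None:
        if self.reject_reason not in ("below_identity", "missing_residue", "none"):
            raise ValueError(f"bad reject_reason {self.reject_reason!r}")
        if self.accepted and self.reject_reason != "none":
            raise ValueError("accepted call cannot carry a reject reason")


@dataclass
class GusCluster:
    """One non-redundant GUSome entry after 90% redundancy filtering."""

    cluster_id: str
    representative_id: str
    member_ids: tuple[str, ...]
    gus_class: str = "NC"
    class_flag: str = ""  # "", "by_nearest", "ambiguous"
    taxonomy: str = "unassigned"
    taxonomy_identity: float = 0.0


@dataclass
class RateEstimate:
    """Reactivation rate for one sample (or specific activity for an enzyme)."""

    id: str
    replicate_rates: tuple[float, ...]
    mean_rate: float
    sem: float
    log2_rate: float | None
    r_squared: float
    flagged_rising: bool = False


@dataclass
class AssociationResult:
    """Wald slope test of reactivation rate against one predictor."""

    predictor: str
    slope: float
    slope_se: float
    statistic: float
    p_value: float
    n: int
    reference: str = "normal"  # "normal" | "t"
    exact_fit: bool = False
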