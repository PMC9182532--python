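"""Mapping limited-proteolysis peptide reads onto a parent protein.

After an amyloid fibril is digested with a non-specific protease
(subtilisin), the surviving peptides delineate the hydrogen-bonded
cross-beta core: residues inside the structured scaffold are protected,
residues in flexible flanks are degraded. This module takes the
identified-peptide list from LC-MS, maps each read back onto the parent
construct by exact substring matching, computes a per-residue prevalence
profile (the fraction of reads covering each position), and extracts the
contiguous protected core around the RHIM tetrad.

Coordinates are 1-based and inclusive throughout, expressed in
full-length-protein numbering via the construct offset, so residue names
like S654 or the VQLG tetrad at 663-666 read directly off the profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    AmbiguousReadError,
    EmptyProfileError,
    UnmappedReadError,
    ValidationError,
)

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ProteinSequence:
    """A protein construct: residues plus full-length numbering offset.

    ``offset`` is the 1-based full-length position of the first residue,
    so a 112-residue construct with offset 601 spans positions 601-712.
    """

    residues: str
    offset: int = 1

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValidationError("protein sequence must be non-empty")
        bad = set(self.residues.upper()) - AMINO_ACIDS
        if bad:
            raise ValidationError(f"non-amino-acid residues: {sorted(bad)}")
        if self.offset < 1:
            raise ValidationError("offset must be >= 1")
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def span(self) -> tuple[int, int]:
        """Inclusive full-length interval covered by the construct."""
        return (self.offset, self.offset + len(self.residues) - 1)


@dataclass(frozen=True)
class PeptideRead:
    """One identified peptide with its spectral support.

    ``modifications`` holds ``(position_in_peptide, name)`` pairs with
    1-based positions; in practice only methionine oxidation occurs, as
    an electrospray artefact, so modifications are stripped before any
    sequence matching.
    """

    sequence: str
    count: int = 1
    modifications: tuple[tuple[int, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError("peptide sequence must be non-empty")
        if self.count < 1:
            raise ValidationError("read count must be >= 1")
        for pos, _name in self.modifications:
            if not 1 <= pos <= len(self.sequence):
                raise ValidationError(
                    f"modification position {pos} outside peptide of length "
                    f"{len(self.sequence)}"
                )


@dataclass
class ProtectionProfile:
    """Per-residue read prevalence plus the delineated protected core."""

    positions: np.ndarray  # full-length positions covered by the construct
    residues: str
    prevalence: np.ndarray  # per-position fraction of mapped reads, in [0, 1]
    tetrad_interval: tuple[int, int]
    tetrad_prevalence: float
    n_reads_mapped: int
    n_reads_unmapped: int = 0
    n_reads_ambiguous: int = 0
    core_interval: tuple[int, int] | None = None

    def prevalence_at(self, position: int) -> float:
        """Prevalence at one full-length residue position."""
        lo = int(self.positions[0])
        if not lo <= position <= int(self.positions[-1]):
            raise ValidationError(f"position {position} outside construct span")
        return float(self.prevalence[position - lo])


def map_read(read: PeptideRead, protein: ProteinSequence) -> tuple[int, int]:
    """Locate a read as an exact substring; return its full-length interval.

    Raises :class:`UnmappedReadError` if the read does not occur and
    :class:`AmbiguousReadError` if it occurs more than once — ambiguous
    reads cannot be assigned a unique interval and are excluded from
    profiles rather than fractionally counted.
    """
    seq = read.sequence.upper()
    first = protein.residues.find(seq)
    if first < 0:
        raise UnmappedReadError(f"read {seq!r} not found in parent protein")
    if protein.residues.find(seq, first + 1) >= 0:
        raise AmbiguousReadError(f"read {seq!r} matches at multiple positions")
    start = protein.offset + first
    return (start, start + len(seq) - 1)


def build_profile(
    reads: list[PeptideRead],
    protein: ProteinSequence,
    tetrad: tuple[int, int],
    weight_by_count: bool = True,
) -> ProtectionProfile:
    """Compute per-residue prevalence of reads over the construct.

    Prevalence at position p is the (count-weighted) fraction of mapped
    reads whose interval covers p; ``tetrad_prevalence`` is the fraction
    of mapped reads containing the complete tetrad. With
    ``weight_by_count=False`` every distinct peptide contributes once,
    mirroring a unique-peptide rather than spectral-count analysis.

    Unmapped and ambiguous reads are excluded and tallied in the profile.
    """
    t_lo, t_hi = tetrad
    lo, hi = protein.span
    if not (lo <= t_lo <= t_hi <= hi):
        raise ValidationError(f"tetrad {tetrad} outside construct span {protein.span}")

    coverage = np.zeros(len(protein), dtype=float)
    total = 0.0
    tetrad_weight = 0.0
    n_unmapped = 0
    n_ambiguous = 0
    n_mapped = 0
    for read in reads:
        try:
            start, end = map_read(read, protein)
        except UnmappedReadError:
            n_unmapped += 1
            continue
        except AmbiguousReadError:
            n_ambiguous += 1
            continue
        w = float(read.count) if weight_by_count else 1.0
        n_mapped += 1
        total += w
        coverage[start - lo : end - lo + 1] += w
        if start <= t_lo and end >= t_hi:
            tetrad_weight += w

    if n_mapped == 0:
        raise EmptyProfileError("no read could be mapped onto the parent protein")

    return ProtectionProfile(
        positions=np.arange(lo, hi + 1),
        residues=protein.residues,
        prevalence=coverage / total,
        tetrad_interval=(t_lo, t_hi),
        tetrad_prevalence=tetrad_weight / total,
        n_reads_mapped=n_mapped,
        n_reads_unmapped=n_unmapped,
        n_reads_ambiguous=n_ambiguous,
    )


def delineate_core(
    profile: ProtectionProfile, threshold: float = 0.7
) -> tuple[int, int] | None:
    """Extract the protected core: the maximal contiguous run of positions
    with prevalence >= threshold that contains the tetrad.

    Returns ``None`` when no such run reaches the threshold. The result
    is also stored on ``profile.core_interval``.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValidationError("threshold must lie in (0, 1]")
    lo = int(profile.positions[0])
    t_lo, t_hi = profile.tetrad_interval
    above = profile.prevalence >= threshold

    i_lo, i_hi = t_lo - lo, t_hi - lo
    if not above[i_lo : i_hi + 1].all():
        profile.core_interval = None
        return None
    start = i_lo
    while start > 0 and above[start - 1]:
        start -= 1
    end = i_hi
    while end < len(above) - 1 and above[end + 1]:
        end += 1
    profile.core_interval = (lo + start, lo + end)
    return profile.core_interval
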