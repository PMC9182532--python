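"""Synthetic data with known ground truth for every downstream stage.

Two generators live here. The trace generator emulates a dual-channel
confocal coincidence spectroscopy (CCS) acquisition: a femtolitre
confocal volume watched for minutes at 1-ms binning, with a Poisson
photon background from monomeric protein in solution and transient
bursts whenever a bright diffusing assembly transits the volume. A
heteromeric (dual-labelled) assembly writes a burst into both spectral
channels at the same instant; homomeric assemblies light up one channel
only. The digest generator emulates the identified-peptide list from a
limited-proteolysis LC-MS experiment on an amyloid fibril, where reads
preferentially cover the protease-protected core.

Both generators are deterministic given their seed, so every simulated
record carries exact ground truth (burst apexes and species, or the
protected interval) against which detection and mapping are scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .coremap import PeptideRead, ProteinSequence
from .exceptions import ConfigurationError, ValidationError

# Default mixture parameters: a bright assembly against a dim monomeric
# baseline, dwelling ~2 ms in the confocal volume. The acquisition the
# generator emulates does not publish event rates or brightnesses, so
# these are free, realistic choices (see docs/methods.md).
DEFAULT_BRIGHTNESS = 100.0  # photons/ms at burst apex
DEFAULT_TRANSIT_MS = 2.0
DEFAULT_BACKGROUND = 2.0  # photons/ms per channel


@dataclass(frozen=True)
class SpeciesModel:
    """One diffusing fluorescent species.

    ``arrival_rate`` is the expected number of transits per second
    (homogeneous Poisson process); the brightnesses are the mean photon
    rates contributed at the burst apex in each channel; ``transit_ms``
    is the mean dwell time in the confocal volume and sets the burst
    width. A heteromeric species has both brightnesses positive, a
    homomeric species exactly one.
    """

    name: str
    arrival_rate: float
    brightness_green: float
    brightness_red: float
    transit_ms: float

    def __post_init__(self) -> None:
        if self.arrival_rate < 0:
            raise ValidationError("arrival_rate must be >= 0")
        if self.brightness_green < 0 or self.brightness_red < 0:
            raise ValidationError("brightness must be >= 0")
        if self.transit_ms <= 0:
            raise ValidationError("transit_ms must be > 0")

    @property
    def is_dual(self) -> bool:
        return self.brightness_green > 0 and self.brightness_red > 0


@dataclass(frozen=True)
class TraceConfig:
    """Acquisition parameters: a 3-minute record at 1-ms binning by default."""

    duration_s: float = 180.0
    bin_ms: float = 1.0
    background_green: float = DEFAULT_BACKGROUND
    background_red: float = DEFAULT_BACKGROUND
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.bin_ms <= 0:
            raise ConfigurationError("duration_s and bin_ms must be > 0")
        if self.background_green < 0 or self.background_red < 0:
            raise ValidationError("backgrounds must be >= 0")
        n = self.duration_s * 1000.0 / self.bin_ms
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                f"duration {self.duration_s} s does not divide into whole "
                f"{self.bin_ms} ms bins"
            )

    @property
    def n_bins(self) -> int:
        return round(self.duration_s * 1000.0 / self.bin_ms)


@dataclass(frozen=True)
class GroundTruthBurst:
    """One placed burst: which species caused it and where its apex sits."""

    species: str
    apex_bin: int
    is_dual: bool


@dataclass
class TimeTrace:
    """Two aligned per-bin photon-count series plus the bin width.

    ``ground_truth`` is populated for simulated traces and lists every
    placed burst; it is ``None`` for traces read from disk.
    """

    bin_ms: float
    green: np.ndarray
    red: np.ndarray
    ground_truth: list[GroundTruthBurst] | None = None

    def __post_init__(self) -> None:
        self.green = np.asarray(self.green, dtype=np.int64)
        self.red = np.asarray(self.red, dtype=np.int64)
        if self.green.shape != self.red.shape or self.green.ndim != 1:
            raise ValidationError("green and red must be 1-D and equal length")
        if (self.green < 0).any() or (self.red < 0).any():
            raise ValidationError("photon counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.green.size

    def dual_fraction(self, channel: str = "green") -> float:
        """Ground-truth fraction of channel-visible bursts that are dual."""
        if self.ground_truth is None:
            raise ValidationError("trace carries no ground truth")
        visible = [
            b
            for b in self.ground_truth
            if b.is_dual or b.species.startswith(channel)
        ]
        if not visible:
            return float("nan")
        return sum(b.is_dual for b in visible) / len(visible)


def _envelope(species: SpeciesModel, bin_ms: float) -> tuple[np.ndarray, np.ndarray]:
    """Truncated Gaussian burst envelope sampled at bin centres.

    The standard deviation is transit_ms/4 and the envelope is truncated
    at +/- 3 sd, so a burst never bleeds more than ~0.75 transit times
    from its apex. Returns (bin offsets, unit-apex weights).
    """
    sd_bins = species.transit_ms / 4.0 / bin_ms
    extent = int(math.floor(3.0 * sd_bins))
    offsets = np.arange(-extent, extent + 1)
    weights = np.exp(-0.5 * (offsets / sd_bins) ** 2)
    return offsets, weights


def simulate_trace(
    species: list[SpeciesModel], config: TraceConfig
) -> TimeTrace:
    """Generate one dual-channel photon time trace.

    Per-bin counts are independent Poisson draws in each channel around a
    deterministic intensity: the channel background plus the sum of burst
    envelopes. Burst arrivals follow a homogeneous Poisson process per
    species; apex positions are uniform over the bins whose truncated
    envelope fits inside the record, so no burst crosses a boundary and
    the ground-truth count is exact. A dual species shares one apex
    between the channels but the photon noise in the two detectors is
    independent.
    """
    if not species and config.background_green == 0 and config.background_red == 0:
        raise ValidationError("need at least one species or a nonzero background")
    names = [s.name for s in species]
    if len(set(names)) != len(names):
        raise ValidationError("species names must be unique")

    rng = np.random.default_rng(config.seed)
    n_bins = config.n_bins
    lam_green = np.full(n_bins, config.background_green * config.bin_ms)
    lam_red = np.full(n_bins, config.background_red * config.bin_ms)

    truth: list[GroundTruthBurst] = []
    for sp in species:
        n_bursts = rng.poisson(sp.arrival_rate * config.duration_s)
        if n_bursts == 0:
            continue
        offsets, weights = _envelope(sp, config.bin_ms)
        extent = offsets[-1]
        if 2 * extent + 1 > n_bins:
            raise ConfigurationError(
                f"burst envelope of {sp.name} is wider than the record"
            )
        apexes = rng.integers(extent, n_bins - extent, size=n_bursts)
        idx = (apexes[:, None] + offsets[None, :]).ravel()
        if sp.brightness_green > 0:
            contrib = sp.brightness_green * config.bin_ms * weights
            np.add.at(lam_green, idx, np.broadcast_to(contrib, (n_bursts, contrib.size)).ravel())
        if sp.brightness_red > 0:
            contrib = sp.brightness_red * config.bin_ms * weights
            np.add.at(lam_red, idx, np.broadcast_to(contrib, (n_bursts, contrib.size)).ravel())
        truth.extend(
            GroundTruthBurst(sp.name, int(a), sp.is_dual) for a in apexes
        )

    truth.sort(key=lambda b: (b.apex_bin, b.species))
    green = rng.poisson(lam_green)
    red = rng.poisson(lam_red)
    return TimeTrace(bin_ms=config.bin_ms, green=green, red=red, ground_truth=truth)


def simulate_mixture(
    hetero_fraction: float,
    n_events_target: float,
    config: TraceConfig,
    brightness: float = DEFAULT_BRIGHTNESS,
    transit_ms: float = DEFAULT_TRANSIT_MS,
) -> TimeTrace:
    """Emulate a two-protein co-incubation with a known hetero fraction.

    Builds three species — green-only, red-only and dual-labelled — with
    arrival rates split so that the dual species carries
    ``hetero_fraction`` of the green-visible events (and, symmetrically,
    of the red-visible events), and the expected total burst count over
    the record is ``n_events_target``. The realised dual fraction of any
    one trace is recovered from its ground truth via
    :meth:`TimeTrace.dual_fraction`.
    """
    if not 0.0 <= hetero_fraction <= 1.0:
        raise ValidationError("hetero_fraction must lie in [0, 1]")
    if n_events_target < 0:
        raise ValidationError("n_events_target must be >= 0")

    # Green-visible events V = green_only + dual with dual = h * V, and the
    # mixture is colour-symmetric, so total = V * (2 - h).
    visible = n_events_target / (2.0 - hetero_fraction)
    n_dual = hetero_fraction * visible
    n_single = (1.0 - hetero_fraction) * visible
    per_second = 1.0 / config.duration_s

    species = [
        SpeciesModel("green_only", n_single * per_second, brightness, 0.0, transit_ms),
        SpeciesModel("red_only", n_single * per_second, 0.0, brightness, transit_ms),
        SpeciesModel("dual", n_dual * per_second, brightness, brightness, transit_ms),
    ]
    return simulate_trace(species, config)


@dataclass(frozen=True)
class DigestConfig:
    """Parameters of a synthetic limited-proteolysis digest.

    ``core_start``/``core_end`` delimit the protected interval in
    full-length numbering; ``core_prevalence`` is the fraction of reads
    that fully cover it; outside the core the probability that a read
    extends k residues past the boundary falls off geometrically as
    (1 - decay_per_residue)^k. When ``anchor`` is set (e.g. the RHIM
    tetrad) every emitted read contains that interval: reads that do not
    cover the whole core are then shorter protected fragments within it.
    ``met_oxidation_rate`` is the per-methionine chance of an oxidation
    annotation, mimicking the electrospray artefact.
    """

    protein: ProteinSequence
    core_start: int
    core_end: int
    core_prevalence: float = 0.7
    n_reads: int = 200
    length_range: tuple[int, int] = (10, 90)
    decay_per_residue: float = 0.2
    anchor: tuple[int, int] | None = None
    met_oxidation_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.protein.span
        if not (lo <= self.core_start <= self.core_end <= hi):
            raise ConfigurationError("core interval outside the protein span")
        if not 0.0 <= self.core_prevalence <= 1.0:
            raise ConfigurationError("core_prevalence must lie in [0, 1]")
        if self.n_reads <= 0:
            raise ConfigurationError("n_reads must be > 0")
        min_len, max_len = self.length_range
        if not 1 <= min_len <= max_len:
            raise ConfigurationError("length_range must satisfy 1 <= min <= max")
        core_len = self.core_end - self.core_start + 1
        if self.core_prevalence > 0 and core_len > max_len:
            raise ConfigurationError(
                f"core of {core_len} residues cannot fit in max peptide "
                f"length {max_len}"
            )
        if not 0.0 <= self.decay_per_residue <= 1.0:
            raise ConfigurationError("decay_per_residue must lie in [0, 1]")
        if not 0.0 <= self.met_oxidation_rate <= 1.0:
            raise ConfigurationError("met_oxidation_rate must lie in [0, 1]")
        if self.anchor is not None:
            a_lo, a_hi = self.anchor
            if not (self.core_start <= a_lo <= a_hi <= self.core_end):
                raise ConfigurationError("anchor must lie within the core")
            if a_hi - a_lo + 1 < min_len <= 0:
                raise ConfigurationError("anchor shorter than minimum length")


def _truncated_geometric(rng: np.random.Generator, survival: float, max_k: int) -> int:
    """Draw k in [0, max_k] with P(k) proportional to survival**k.

    survival = 1 reduces to a uniform draw over the allowed extents.
    """
    if max_k <= 0:
        return 0
    ks = np.arange(max_k + 1)
    if survival == 0.0:
        return 0
    w = survival**ks
    return int(rng.choice(ks, p=w / w.sum()))


def simulate_digest(config: DigestConfig) -> list[PeptideRead]:
    """Emit synthetic peptide reads from a protease-protection experiment.

    Each read is an exact substring of the parent. A fraction
    ``core_prevalence`` of reads (rounded to a whole count, so the target
    is hit exactly up to rounding) fully covers the core and extends past
    its boundaries with geometrically decaying probability; the remaining
    reads are shorter fragments — inside the core when an anchor is set,
    anywhere that does not cover the full core otherwise. Methionines are
    oxidation-annotated at ``met_oxidation_rate``. Deterministic under
    the seed.
    """
    rng = np.random.default_rng(config.seed)
    prot = config.protein
    p_lo, p_hi = prot.span
    min_len, max_len = config.length_range
    c_lo, c_hi = config.core_start, config.core_end
    survival = 1.0 - config.decay_per_residue

    n_core = round(config.core_prevalence * config.n_reads)
    intervals: list[tuple[int, int]] = []

    for _ in range(n_core):
        room = max_len - (c_hi - c_lo + 1)
        ext_l = _truncated_geometric(rng, survival, min(room, c_lo - p_lo))
        ext_r = _truncated_geometric(
            rng, survival, min(room - ext_l, p_hi - c_hi)
        )
        intervals.append((c_lo - ext_l, c_hi + ext_r))

    for _ in range(config.n_reads - n_core):
        intervals.append(_draw_partial_read(rng, config))

    reads = []
    for start, end in intervals:
        seq = prot.residues[start - p_lo : end - p_lo + 1]
        mods = tuple(
            (i + 1, "Oxidation (M)")
            for i, aa in enumerate(seq)
            if aa == "M" and rng.random() < config.met_oxidation_rate
        )
        reads.append(PeptideRead(sequence=seq, count=1, modifications=mods))
    return reads


def _draw_partial_read(
    rng: np.random.Generator, config: DigestConfig
) -> tuple[int, int]:
    """One read interval that does not fully cover the core."""
    p_lo, p_hi = config.protein.span
    min_len, max_len = config.length_range
    c_lo, c_hi = config.core_start, config.core_end
    for _ in range(10_000):
        if config.anchor is not None:
            a_lo, a_hi = config.anchor
            # A protected fragment inside the core containing the anchor.
            start = int(rng.integers(c_lo, a_lo + 1))
            end = int(rng.integers(a_hi, c_hi + 1))
        else:
            length = int(rng.integers(min_len, max_len + 1))
            start = int(rng.integers(p_lo, p_hi - length + 2))
            end = start + length - 1
        covers_core = start <= c_lo and end >= c_hi
        if min_len <= end - start + 1 <= max_len and not covers_core:
            return (start, end)
    raise ConfigurationError(
        "could not place a non-core-covering read; length_range and core "
        "geometry leave no room"
    )


# ---------------------------------------------------------------------------
# Synthetic reference construct
# ---------------------------------------------------------------------------

_FLANK_N = "PLIIHHAQM"  # nine residues N-terminal of the tetrad
_TETRAD = "VQLG"


def synthetic_trif_like_protein() -> ProteinSequence:
    """A synthetic 112-residue TRIF-like RHIM construct, offset 601.

    The real construct sequence is not bundled with the package, so
    fixtures use this deterministic synthetic stand-in: it places the
    documented PLIIHHAQM flank at positions 654-662 and the RHIM core
    tetrad VQLG at 663-666; all other residues are an arbitrary but fixed
    draw over the 20 amino acids. Suitable for exercising the mapping and
    simulation machinery, not for biological inference.
    """
    rng = np.random.default_rng(20220526)
    alphabet = np.array(sorted("ACDEFGHIKLNPQRSTWY"))  # avoid extra M/V runs
    seq = rng.choice(alphabet, size=112)
    start = 654 - 601  # 0-based index of the flank
    motif = _FLANK_N + _TETRAD
    seq[start : start + len(motif)] = list(motif)
    return ProteinSequence(residues="".join(seq), offset=601)


TETRAD_INTERVAL = (663, 666)
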