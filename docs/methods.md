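# Methods

## The measurement being modelled

In confocal coincidence spectroscopy (CCS) two lasers excite a ~1 fL
confocal volume and fluorescence is collected in two spectral channels
(here called *green*, e.g. a YPet fusion, and *red*, e.g. an mCherry
fusion), binned at 1 ms for records of minutes. Monomeric labelled
protein in solution contributes a steady Poisson background; a bright
assembly of many fluorophores transiting the volume produces a
millisecond-scale burst well above that background. A heteromeric
assembly carrying both labels bursts in both channels simultaneously.
The directional interaction measure is

    colourQ = (# Colour-A peaks aligned with a Colour-B peak) / (# Colour-A peaks)

with **redQ** the fraction of green peaks aligned with red peaks and
**greenQ** the converse. The photon counting histogram (PCH) — detected
peak intensities binned in photons/ms — is used descriptively as a proxy
for the assembly size distribution.

The companion proteomics analysis maps limited-proteolysis LC-MS peptide
reads onto the parent construct: residues inside the hydrogen-bonded
amyloid core survive a non-specific protease, so per-residue read
prevalence delineates the protected core around the RHIM tetrad
(VQLG, positions 663–666 of the TRIF construct numbering used here).

## Trace simulation

Each diffusing species is a homogeneous Poisson arrival process with
rate `arrival_rate` (events/s). A burst is a Gaussian envelope with apex
amplitude `brightness` (photons/ms), standard deviation `transit_ms/4`,
truncated at ±3 sd. The envelope shape is a modelling choice — smooth,
two parameters, mimicking diffusive transit through an approximately
Gaussian detection profile; the analysis stages never assume it. Apex
positions are drawn uniformly over the bins whose truncated envelope
fits inside the record, which is equivalent to redrawing
boundary-crossing bursts and keeps the ground-truth burst count exact.
Per-bin counts are independent Poisson draws in each channel around
background + summed envelopes; a dual-labelled species shares one apex
between channels but the two detectors' shot noise is independent.

`simulate_mixture` builds a colour-symmetric three-species mixture
(green-only, red-only, dual) in which the dual species carries a chosen
fraction *h* of the green-visible events; with total expected events
*T*, the green-visible count is *V = T/(2−h)*.

Defaults, chosen once as realistic for a single-molecule confocal setup
and not calibrated to any particular instrument:

| parameter | default | why |
|---|---|---|
| `duration_s` | 180 s | three-minute records |
| `bin_ms` | 1 ms | millisecond binning |
| background | 2 photons/ms/channel | dim monomeric baseline |
| `brightness` | 100 photons/ms | bright multi-fluorophore assembly, ≫ background |
| `transit_ms` | 2 ms | few-ms dwell of a large complex |

What the generator does **not** model: excitation/detection optics (PSF,
focal-volume geometry), triplet blinking, FRET, detector crosstalk,
afterpulsing or dead time. Passing tests therefore demonstrate that the
analysis recovers coincidence fractions under ideal Poisson photon
statistics with well-separated bursts — not that it is robust to
instrument artefacts real traces may carry.

## Burst detection

Baseline = median of the per-bin counts; noise scale
σ = max(1.4826·MAD, √max(baseline, 1)). The median/MAD pair is immune to
the burst-heavy upper tail; the Poisson floor matters because on integer
counts the MAD is quantised (at a baseline of 3 the scaled MAD is 1.48,
below the true shot noise √3). A peak is a maximal run of bins strictly
above baseline + k·σ (default k = 5), optionally merging runs separated
by ≤ `merge_gap_bins` (default 0) and discarding runs narrower than
`min_width_bins` (default 1). The apex is the first maximum of the run
(tie-break: earliest bin); `max_intensity` is the apex count in
photons/ms; `integrated_photons` subtracts the baseline over the span
and is floored at 0 (gap bins admitted by merging can dip below

baseline).

## Alignment, colourQ and the chance diagnostic

Two peaks are aligned when their spans, each dilated by
`tolerance_bins` (default 0), intersect — bursts are extended objects,
so span overlap rather than apex distance is the primitive; an
apex-distance criterion is recovered by feeding width-1 spans. One A
peak overlapping several B peaks counts once: the statistic counts
peaks, not pairs. Multi-trace experiments aggregate by pooling peak
counts across traces before taking the ratio, so information-rich traces
weigh more than sparse ones. colourQ is *undefined* (an error, not 0)
when the A channel has no peaks.

The chance-coincidence diagnostic is the probability that an A peak of
mean width w_A touches at least one of n_B independently placed B peaks
of mean width w_B:

    P_chance = 1 − exp(−n_B · (w_A + w_B − 1 + 2·tol) / n_bins).

Both widths enter because two intervals intersect when their *sum* of
half-widths exceeds their separation; dropping w_A (the point-peak
approximation) underestimates the empirical chance alignment of
independent channels by roughly (w_A+w_B−1)/w_B. The rate is reported
next to colourQ and never subtracted from it, so users can judge how
much of a small Q is chance.

Known bias: chance crossings of the background (expected ≈ n_bins ×
Poisson tail at the threshold, about 8 single-bin peaks per 180 s trace
at the defaults) enter the redQ denominator as unaligned green peaks.
This depresses recovered redQ by ~0.02–0.03 when the true dual fraction
is high, which is inside the ±0.05 recovery tolerance the tests
enforce; raising `k_sigma` or `min_width_bins` trades this against
recall.

## Photon counting histograms

`build_pch` histograms `Peak.max_intensity` (photons/ms) in half-open
bins of width 100 photons/ms by default; baseline-subtracted integrated
photons are available behind a flag. With an explicit intensity ceiling
the final bin absorbs overflow so counts are always conserved.
Histogram comparison reports the shift in count-weighted mean bin centre
and the change in tail mass above a stated intensity — the two
qualitative comparisons the assay supports. No super-Poissonian PCH
model is fitted; the histogram is descriptive.

## Digest simulation and core mapping

Coordinates are 1-based inclusive, in full-length numbering via the
construct offset (the bundled synthetic construct spans 601–712). A
digest emits `n_reads` exact substrings of the parent: a fraction
`core_prevalence` (rounded to a whole read count) covers the whole
protected interval and extends past each boundary with probability
decaying geometrically per residue — extent k drawn ∝ (1−d)^k with
d = `decay_per_residue` (default 0.2), truncated by the construct ends
and the maximum peptide length. The geometric form was chosen over a
linear decay because it stays a valid probability for any extent; at
d = 0 it degenerates to a uniform draw over allowed extents. The default
d = 0.2 places the first flanking residue's expected prevalence
(≈ 0.7·(1−d)) more than three binomial standard errors below the 0.7
delineation threshold at the default 200 reads, so core recovery is
exact rather than borderline. When an `anchor` interval is set (the
tetrad, in all fixtures) every read contains it and non-core-covering
reads are confined to the core — the most-protected fragments — which
keeps flank prevalence strictly below the core share. Methionines are
oxidation-annotated independently at `met_oxidation_rate` (default 0.2),
mimicking the electrospray artefact; modifications are stripped before
matching.

Mapping is exact substring search; a read matching nowhere or at more
than one position is excluded (and tallied) rather than guessed or
fractionally assigned. Prevalence at a position is the count-weighted
fraction of mapped reads covering it; unique-peptide weighting is
available behind a flag because the spectral-count convention is not
universal. The protected core is the maximal contiguous run of positions
with prevalence ≥ threshold (default 0.7) containing the tetrad; if the
tetrad itself fails the threshold there is no core.

The bundled 112-residue construct is **synthetic**: the analysis needs a
concrete parent sequence, so `synthetic_trif_like_protein()` fixes an
arbitrary seeded sequence carrying the documented PLIIHHAQM flank
(654–662) and VQLG tetrad (663–666). It exercises the machinery; it
supports no biological inference.

## Problem sizes and numerical choices

Tests and the acceptance script run simulations sized for tight
statistical bounds at desk scale: 3-minute traces with ~320
green-visible events for recovery checks (50 replicates per dual
fraction), 1-minute traces for the 200-replicate independence null, 200
reads per digest across 20 seeds for core recovery. Determinism: every
generator consumes a single `numpy` Generator stream seeded from its
config, so identical configs give bit-identical outputs; file writers
emit no timestamps, making seeded pipeline runs byte-reproducible.

## Limitations

- The coincidence statistic is occupancy-sensitive: at high event rates
  chance overlap inflates Q; the chance diagnostic quantifies but does
  not remove this.
- No brightness-ratio stoichiometry, FCCS amplitudes or diffusion-time
  analysis — peaks are counted and sized, not modelled.
- The digest generator draws read placements independently; it does not
  model protease site preference, peptide ionisation efficiency or
  missed-cleavage structure in real LC-MS data.
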