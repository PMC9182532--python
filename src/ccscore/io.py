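"""Plain-text readers and writers for every interchange format.

All stage outputs are inspectable tabular text: traces and ground truth
as tab-separated tables, peaks / pairs / digests / histograms as CSV,
protection profiles as TSV, proteins as FASTA. Modifications travel in a
compact dialect, ``pos:name`` terms joined by ``;`` (e.g.
``"5:Oxidation (M);12:Oxidation (M)"``), with 1-based positions in the
peptide.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .bursts import Peak
from .coincidence import CoincidenceResult
from .coremap import PeptideRead, ProteinSequence, ProtectionProfile
from .exceptions import ValidationError
from .pch import PCHistogram
from .simulate import GroundTruthBurst, TimeTrace


# ---------------------------------------------------------------------------
# Traces
# ---------------------------------------------------------------------------

def write_trace(trace: TimeTrace, path: str | Path) -> None:
    """Tab-separated table: bin_index, green_counts, red_counts."""
    df = pd.DataFrame(
        {
            "bin_index": np.arange(trace.n_bins),
            "green_counts": trace.green,
            "red_counts": trace.red,
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# bin_ms={trace.bin_ms}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_trace(path: str | Path) -> TimeTrace:
    bin_ms = 1.0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# bin_ms="):
            bin_ms = float(first.split("=", 1)[1])
        else:
            fh.seek(0)
        df = pd.read_csv(fh, sep="\t")
    required = {"bin_index", "green_counts", "red_counts"}
    if df.empty or not required.issubset(df.columns):
        raise ValidationError(
            f"{path}: expected non-empty columns {sorted(required)}"
        )
    return TimeTrace(
        bin_ms=bin_ms,
        green=df["green_counts"].to_numpy(),
        red=df["red_counts"].to_numpy(),
    )


def write_ground_truth(trace: TimeTrace, path: str | Path) -> None:
    """Sidecar table of placed bursts: apex_bin, species, is_dual."""
    if trace.ground_truth is None:
        raise ValidationError("trace carries no ground truth to write")
    pd.DataFrame(
        {
            "apex_bin": [b.apex_bin for b in trace.ground_truth],
            "species": [b.species for b in trace.ground_truth],
            "is_dual": [int(b.is_dual) for b in trace.ground_truth],
        }
    ).to_csv(path, sep="\t", index=False)


def read_ground_truth(path: str | Path) -> list[GroundTruthBurst]:
    df = pd.read_csv(path, sep="\t")
    return [
        GroundTruthBurst(str(r.species), int(r.apex_bin), bool(r.is_dual))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Peaks, pairs, coincidence reports, PCH
# ---------------------------------------------------------------------------

PEAK_COLUMNS = [
    "channel",
    "start_bin",
    "end_bin",
    "apex_bin",
    "max_intensity",
    "integrated_photons",
]


def write_peaks(peaks: list[Peak], path: str | Path) -> None:
    pd.DataFrame(
        [[getattr(p, c) for c in PEAK_COLUMNS] for p in peaks],
        columns=PEAK_COLUMNS,
    ).to_csv(path, index=False)


def read_peaks(path: str | Path) -> list[Peak]:
    df = pd.read_csv(path)
    return [
        Peak(
            channel=str(r.channel),
            start_bin=int(r.start_bin),
            end_bin=int(r.end_bin),
            apex_bin=int(r.apex_bin),
            max_intensity=float(r.max_intensity),
            integrated_photons=float(r.integrated_photons),
        )
        for r in df.itertuples()
    ]


def write_ccs_report(result: CoincidenceResult, path: str | Path) -> None:
    """Flat key/value report of a coincidence analysis."""
    lines = [
        f"n_green\t{result.n_green}",
        f"n_red\t{result.n_red}",
        f"n_green_aligned\t{result.n_green_aligned}",
        f"n_red_aligned\t{result.n_red_aligned}",
        f"redQ\t{'undefined' if result.redq is None else f'{result.redq:.6f}'}",
        f"greenQ\t{'undefined' if result.greenq is None else f'{result.greenq:.6f}'}",
        f"chance_rate\t{result.chance_rate:.6f}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_pairs(result: CoincidenceResult, path: str | Path) -> None:
    pd.DataFrame(
        result.pairs, columns=["green_peak_index", "red_peak_index"]
    ).to_csv(path, index=False)


def write_pch(hist: PCHistogram, path: str | Path) -> None:
    pd.DataFrame(
        {
            "bin_low": hist.bin_edges[:-1],
            "bin_high": hist.bin_edges[1:],
            "count": hist.counts,
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Proteins, digests, profiles
# ---------------------------------------------------------------------------

def write_protein(protein: ProteinSequence, path: str | Path, name: str = "construct") -> None:
    """Single-record FASTA; the id carries the span as name/start-end."""
    lo, hi = protein.span
    record = SeqRecord(Seq(protein.residues), id=f"{name}/{lo}-{hi}", description="")
    SeqIO.write([record], str(path), "fasta")


def read_protein(path: str | Path, offset: int | None = None) -> ProteinSequence:
    """Read a single-record FASTA.

    The numbering offset is taken from a ``name/start-end`` suffix on the
    record id when present (the usual domain-fragment convention), unless
    overridden explicitly.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValidationError(f"{path}: expected exactly one FASTA record")
    record = records[0]
    if offset is None:
        offset = 1
        if "/" in record.id:
            span = record.id.rsplit("/", 1)[1]
            if "-" in span:
                try:
                    offset = int(span.split("-")[0])
                except ValueError:
                    offset = 1
    return ProteinSequence(residues=str(record.seq), offset=offset)


def format_modifications(mods: tuple[tuple[int, str], ...]) -> str:
    return ";".join(f"{pos}:{name}" for pos, name in mods)


def parse_modifications(text: str) -> tuple[tuple[int, str], ...]:
    if not text or not text.strip():
        return ()
    out = []
    for term in text.split(";"):
        pos, _, name = term.partition(":")
        out.append((int(pos), name))
    return tuple(out)


def write_reads(reads: list[PeptideRead], path: str | Path) -> None:
    """CSV of peptide reads: peptide, count, modifications.

    Identical (sequence, modifications) reads are aggregated by count, so
    the file is a compact spectral-count table.
    """
    agg: dict[tuple[str, tuple], int] = {}
    for r in reads:
        key = (r.sequence, r.modifications)
        agg[key] = agg.get(key, 0) + r.count
    pd.DataFrame(
        [
            {"peptide": seq, "count": n, "modifications": format_modifications(mods)}
            for (seq, mods), n in sorted(agg.items())
        ]
    ).to_csv(path, index=False)


def read_reads(path: str | Path) -> list[PeptideRead]:
    df = pd.read_csv(path, keep_default_na=False)
    if "peptide" not in df.columns:
        raise ValidationError(f"{path}: missing 'peptide' column")
    counts = df["count"] if "count" in df.columns else [1] * len(df)
    mods = df["modifications"] if "modifications" in df.columns else [""] * len(df)
    return [
        PeptideRead(
            sequence=str(seq),
            count=int(n) if str(n).strip() else 1,
            modifications=parse_modifications(str(m)),
        )
        for seq, n, m in zip(df["peptide"], counts, mods)
    ]


def write_profile(profile: ProtectionProfile, path: str | Path) -> None:
    """TSV per-residue profile: position, residue, prevalence."""
    pd.DataFrame(
        {
            "position": profile.positions,
            "residue": list(profile.residues),
            "prevalence": np.round(profile.prevalence, 6),
        }
    ).to_csv(path, sep="\t", index=False)


def write_profile_report(profile: ProtectionProfile, path: str | Path) -> None:
    core = profile.core_interval
    lines = [
        f"n_reads_mapped\t{profile.n_reads_mapped}",
        f"n_reads_unmapped\t{profile.n_reads_unmapped}",
        f"n_reads_ambiguous\t{profile.n_reads_ambiguous}",
        f"tetrad_interval\t{profile.tetrad_interval[0]}-{profile.tetrad_interval[1]}",
        f"tetrad_prevalence\t{profile.tetrad_prevalence:.6f}",
        f"core_interval\t{'none' if core is None else f'{core[0]}-{core[1]}'}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------

def write_manifest(params: dict, path: str | Path) -> None:
    """JSON run manifest: every parameter and seed needed to reproduce."""
    Path(path).write_text(json.dumps(params, indent=2, sort_keys=True) + "\n")
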