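#!/usr/bin/env python
"""Protease-protection mapping of the synthetic RHIM construct.

Simulates a limited-proteolysis digest of the 112-residue TRIF-like
construct (70% of reads fully covering the protected interval 654-709,
flank coverage decaying geometrically, the VQLG tetrad in every read),
maps the reads back onto the construct, and delineates the protected
core at the 0.7 prevalence threshold. Writes the per-residue profile,
the digest read table and a summary report under results/.
"""

from __future__ import annotations

import argparse
from pathlib import Path

from ccscore import (
    DigestConfig,
    TETRAD_INTERVAL,
    build_profile,
    delineate_core,
    io,
    simulate_digest,
    synthetic_trif_like_protein,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--threshold", type=float, default=0.7)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    protein = synthetic_trif_like_protein()
    config = DigestConfig(
        protein=protein, core_start=654, core_end=709, core_prevalence=0.7,
        anchor=TETRAD_INTERVAL, seed=args.seed * 1000 + 53,
    )
    reads = simulate_digest(config)
    profile = build_profile(reads, protein, TETRAD_INTERVAL)
    core = delineate_core(profile, args.threshold)

    io.write_protein(protein, args.outdir / "synthetic_construct.fasta",
                     name="synthetic_trif_like")
    io.write_reads(reads, args.outdir / "digest_reads.csv")
    io.write_profile(profile, args.outdir / "protection_profile.tsv")
    io.write_profile_report(profile, args.outdir / "coremap_report.txt")

    print(f"mapped {profile.n_reads_mapped} reads "
          f"({profile.n_reads_unmapped} unmapped, "
          f"{profile.n_reads_ambiguous} ambiguous)")
    print(f"tetrad {TETRAD_INTERVAL[0]}-{TETRAD_INTERVAL[1]} prevalence: "
          f"{profile.tetrad_prevalence:.3f}")
    print("protected core:",
          "none" if core is None else f"{core[0]}-{core[1]}")


if __name__ == "__main__":
    main()
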