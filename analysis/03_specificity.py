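#!/usr/bin/env python
"""Cleavage-specificity evidence from the enriched peptide sets.

For the carboxypeptidase scenarios (CPE, CPB1) builds deduplicated
C-terminus logos of the KO- and WT-enriched sets and the substrate
repertoires; for DPP4 builds N-terminus logos and detects the
substrate/product peptide pairs that differ by one X-P/A dipeptide.
Also builds the wild-type proglucagon N-terminus logo.  Writes
position-frequency-matrix TSVs (and PNG renderings) under
results/specificity/ and prints the headline residue fractions.
"""

import argparse
from pathlib import Path

import pandas as pd

from enteropep import bundled_registry
from enteropep.differential import enriched_sets
from enteropep.quant_io import map_peptides, read_quant_table
from enteropep.specificity import (
    build_logo,
    dedupe_contexts,
    extract_contexts,
    find_dipeptide_pairs,
    render_logo,
    residue_fraction,
    substrate_repertoire,
    write_logo_tsv,
)
from enteropep.synthetic_data import Genotype, simulate_peptidome

SCENARIOS = {"CPE": "C", "CPB1": "C", "DPP4": "N"}


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--diffdir", type=Path, default=Path("results/differential"))
    parser.add_argument("--simdir", type=Path, default=Path("results/sim"))
    parser.add_argument("--outdir", type=Path, default=Path("results/specificity"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)
    registry = bundled_registry()

    for scenario, terminus in SCENARIOS.items():
        results = pd.read_csv(args.diffdir / f"{scenario}_results.tsv", sep="\t").fillna(
            {"modifications": ""})
        ko, wt = enriched_sets(results)
        for name, peptide_set in (("ko_enriched", ko), ("wt_enriched", wt)):
            unique = peptide_set[peptide_set["map_status"] == "unique"]
            if unique.empty:
                continue
            contexts, _ = extract_contexts(unique, registry, terminus)
            logo = build_logo(dedupe_contexts(contexts))
            stem = args.outdir / f"{scenario}_{name}_{terminus}term"
            write_logo_tsv(logo, f"{stem}.tsv")
            render_logo(logo, f"{stem}.png", title=f"{scenario} {name}")
            substrate_repertoire(unique).rename("n_peptides").to_csv(
                args.outdir / f"{scenario}_{name}_repertoire.tsv",
                sep="\t", index_label="accession")
            pos, res = (-1, "KR") if terminus == "C" else (+2, "PA")
            print(f"{scenario} {name}: {logo.n_contexts} unique contexts, "
                  f"{res} fraction at {pos:+d} = "
                  f"{residue_fraction(contexts, pos, res):.2f}")
        if scenario == "DPP4":
            table = read_quant_table(args.simdir / "DPP4_quant.tsv")
            mapped, _ = map_peptides(table, registry)
            pairs = find_dipeptide_pairs(mapped)
            pairs.to_csv(args.outdir / "DPP4_dipeptide_pairs.tsv", sep="\t", index=False)
            print(f"DPP4: {len(pairs)} substrate/product dipeptide pairs")

    # wild-type proglucagon N termini (endoprotease specificity)
    pgc = bundled_registry(include_synthetic=False)
    species = simulate_peptidome(pgc, Genotype("WT", frozenset(), ("c",)))
    peptides = pd.DataFrame({"accession": [s.accession for s in species],
                             "start": [s.start for s in species],
                             "end": [s.end for s in species]})
    contexts, _ = extract_contexts(peptides, pgc, "N")
    unique = dedupe_contexts(contexts)
    logo = build_logo(unique)
    write_logo_tsv(logo, args.outdir / "proglucagon_WT_Nterm.tsv")
    render_logo(logo, args.outdir / "proglucagon_WT_Nterm.png",
                title="proglucagon WT N termini")
    kr1 = logo.frequencies.loc[-1, "K"] + logo.frequencies.loc[-1, "R"]
    kr2 = logo.frequencies.loc[-2, "K"] + logo.frequencies.loc[-2, "R"]
    print(f"proglucagon WT: {len(unique)} unique N termini, "
          f"K/R frequency P1 = {kr1:.2f}, P2 = {kr2:.2f}")


if __name__ == "__main__":
    main()
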