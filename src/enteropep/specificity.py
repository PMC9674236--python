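"""Cleavage-specificity evidence from enriched peptide sets.

Positions are labeled with signed integers: -1..-4 walk upstream from the
cleavage boundary (Schechter-Berger P1..P4) and +1..+4 downstream
(P1'..P4').  For a peptide's N terminus the boundary sits before its first
residue, so +1 is the first peptide residue and -1/-2 the residues the
endoprotease recognized; for the C terminus the boundary sits after the
last residue, so -1 is the final peptide residue (where carboxypeptidase
substrates retain K/R) and +1 the first residue beyond it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as stats

from .precursors import GAP, PrecursorRegistry, TerminusContext, window
from .quant_io import QuantTable

RESIDUES = sorted("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class LogoMatrix:
    """Position-wise residue counts/frequencies over a set of contexts."""

    counts: pd.DataFrame       # positions x residues
    frequencies: pd.DataFrame  # rows sum to 1 over non-gap observations
    information: pd.Series     # bits per position, log2(20) background
    n_contexts: int

    @property
    def positions(self) -> list[int]:
        return list(self.counts.index)


def extract_contexts(peptides: pd.DataFrame, registry: PrecursorRegistry,
                     terminus: str, flank: int = 4):
    """Terminus windows for uniquely mapped peptides.

    ``peptides`` needs accession/start/end columns (and, if present,
    map_status == 'unique' rows are used).  Returns (contexts, n_skipped).
    """
    if terminus not in {"N", "C"}:
        raise ValueError("terminus must be 'N' or 'C'")
    rows = peptides
    if "map_status" in peptides.columns:
        rows = peptides[peptides["map_status"] == "unique"]
    skipped = len(peptides) - len(rows)
    contexts = []
    for _, row in rows.iterrows():
        rec = registry[row["accession"]]
        boundary = int(row["start"]) - 1 if terminus == "N" else int(row["end"])
        contexts.append(window(rec, boundary, flank=flank, terminus=terminus))
    return contexts, skipped


def dedupe_contexts(contexts: list[TerminusContext]) -> list[TerminusContext]:
    """Collapse contexts with identical window strings (order-preserving)."""
    seen: set[str] = set()
    unique = []
    for ctx in contexts:
        if ctx.key not in seen:
            seen.add(ctx.key)
            unique.append(ctx)
    return unique


def build_logo(contexts: list[TerminusContext]) -> LogoMatrix:
    """Count residues per signed position and derive frequencies and
    information content (bits against a uniform 20-residue background)."""
    if not contexts:
        raise ValueError("no contexts")
    flank = contexts[0].flank
    positions = [*range(-flank, 0), *range(1, flank + 1)]
    counts = pd.DataFrame(0, index=positions, columns=RESIDUES, dtype=int)
    for ctx in contexts:
        for pos in positions:
            res = ctx.at(pos)
            if res != GAP:
                counts.loc[pos, res] += 1
    totals = counts.sum(axis=1)
    freqs = counts.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = freqs * np.log2(freqs.where(freqs > 0, 1.0))
    information = np.log2(20) + plogp.sum(axis=1)
    information[totals == 0] = 0.0
    return LogoMatrix(counts=counts, frequencies=freqs,
                      information=information, n_contexts=len(contexts))


def residue_fraction(contexts: list[TerminusContext], position: int,
                     residues) -> float:
    """Fraction of contexts carrying one of ``residues`` at ``position``."""
    if not contexts:
        raise ValueError("no contexts")
    residues = set(residues)
    hits = sum(ctx.at(position) in residues for ctx in contexts)
    return hits / len(contexts)


def residue_enrichment(contexts_a: list[TerminusContext],
                       contexts_b: list[TerminusContext],
                       position: int, residues) -> tuple[float, float, float, float]:
    """Compare residue occupancy at one position between two context sets.

    Returns (fraction_a, fraction_b, odds ratio, two-sided Fisher exact p).
    """
    if not contexts_a or not contexts_b:
        raise ValueError("both context sets must be non-empty")
    residues = set(residues)
    ka = sum(ctx.at(position) in residues for ctx in contexts_a)
    kb = sum(ctx.at(position) in residues for ctx in contexts_b)
    na, nb = len(contexts_a), len(contexts_b)
    odds, p = stats.fisher_exact([[ka, na - ka], [kb, nb - kb]])
    return ka / na, kb / nb, float(odds), float(p)


def find_dipeptide_pairs(table: QuantTable, residues_at_2=("P", "A")) -> pd.DataFrame:
    """Peptide pairs differing exactly by an N-terminal X-P/A dipeptide.

    A pair (long, short) qualifies when short equals long minus its first
    two residues, residue 2 of long is in ``residues_at_2``, both map to the
    same precursor when mapping information is present, and the two carry
    identical modifications (the N-terminal state aside, which the trim
    itself changes).  Matching is exact string identity, so there are no
    false positives by construction.
    """
    residues_at_2 = set(residues_at_2)
    peptides = table.peptides
    by_key: dict[tuple[str, str], list[int]] = {}
    for i, (seq, mods) in enumerate(zip(peptides["sequence"], peptides["modifications"])):
        by_key.setdefault((seq, str(mods)), []).append(i)
    rows = []
    has_map = "accession" in peptides.columns
    for i, (seq, mods) in enumerate(zip(peptides["sequence"], peptides["modifications"])):
        if len(seq) < 3 or seq[1] not in residues_at_2:
            continue
        for j in by_key.get((seq[2:], str(mods)), []):
            if has_map:
                acc_i, acc_j = peptides["accession"].iat[i], peptides["accession"].iat[j]
                if acc_i and acc_j and acc_i != acc_j:
                    continue
            rows.append({
                "long_sequence": seq, "short_sequence": seq[2:],
                "dipeptide": seq[:2], "modifications": str(mods),
                "accession": peptides["accession"].iat[i] if has_map else "",
                "long_row": i, "short_row": j,
            })
    return pd.DataFrame(rows, columns=["long_sequence", "short_sequence", "dipeptide",
                                       "modifications", "accession", "long_row", "short_row"])


def pair_zscaled_matrix(table: QuantTable, pairs: pd.DataFrame) -> pd.DataFrame:
    """Row-z-scaled log2 abundances of all pair members (Fig-style heatmap
    input); missing values are left out of the scaling."""
    from .differential import zscale  # local import to avoid a cycle

    idx = pd.unique(pd.concat([pairs["long_row"], pairs["short_row"]]))
    values = table.values.iloc[idx]
    log2 = np.log2(values.where(values > 0))
    arr = log2.to_numpy(dtype=float)
    mean = np.nanmean(arr, axis=1, keepdims=True)
    sd = np.nanstd(arr, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (arr - mean) / sd
    out = pd.DataFrame(z, columns=values.columns)
    out.insert(0, "sequence", table.peptides["sequence"].iloc[idx].to_numpy())
    return out


def substrate_repertoire(peptides: pd.DataFrame) -> pd.Series:
    """Number of (enriched) peptides per precursor accession."""
    if "accession" not in peptides.columns:
        raise ValueError("peptides are not mapped")
    mapped = peptides[peptides["accession"].astype(str) != ""]
    return mapped["accession"].value_counts().sort_index()


def write_logo_tsv(logo: LogoMatrix, path) -> None:
    out = logo.frequencies.copy()
    out.index.name = "position"
    out.to_csv(path, sep="\t")


def render_logo(logo: LogoMatrix, path, title: str = "") -> None:
    """Minimal stacked-letter logo rendering (information-scaled)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.0 + 0.6 * len(logo.positions), 2.4))
    for x, pos in enumerate(logo.positions):
        heights = (logo.frequencies.loc[pos] * logo.information[pos]).sort_values()
        bottom = 0.0
        for res, h in heights.items():
            if h <= 0:
                continue
            ax.text(x, bottom + h / 2, res, ha="center", va="center",
                    fontsize=6 + 14 * min(h / np.log2(20), 1.0),
                    color="red" if res in "KR" else ("blue" if res in "PA" else "black"))
            bottom += h
    ax.set_xticks(range(len(logo.positions)))
    ax.set_xticklabels([f"{p:+d}" for p in logo.positions])
    ax.set_ylim(0, np.log2(20))
    ax.set_ylabel("bits")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
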