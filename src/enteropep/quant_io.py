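"""Peptide quantification tables: IO, normalization, filtering, mapping.

A :class:`QuantTable` is the pipeline's central container: a rectangular
peptides × samples abundance matrix plus two metadata frames.  Missing
values are NaN in memory and empty cells on disk.  The on-disk dialect is a
pair of TSVs: the main table (``sequence``, ``modifications``, optional
mapping columns, then one column per sample) and a ``<stem>.samples.tsv``
sidecar with the sample metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .precursors import PrecursorRegistry

SAMPLE_COLUMNS = ["sample_id", "clone_id", "genotype", "bmp", "replicate"]
PEPTIDE_COLUMNS = ["sequence", "modifications"]
MAPPING_COLUMNS = ["accession", "start", "end", "map_status"]


class QuantTableError(ValueError):
    pass


@dataclass
class QuantTable:
    peptides: pd.DataFrame  # sequence, modifications, optionally mapping columns
    samples: pd.DataFrame   # SAMPLE_COLUMNS
    values: pd.DataFrame    # one column per sample_id, row-aligned with peptides

    def __post_init__(self) -> None:
        self.peptides = self.peptides.reset_index(drop=True)
        self.values = self.values.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise QuantTableError(f"sample metadata lacks required columns {missing}")
        if list(self.values.columns) != list(self.samples["sample_id"]):
            raise QuantTableError("value columns do not match sample metadata order")
        if len(self.values) != len(self.peptides):
            raise QuantTableError("peptide metadata and value matrix disagree in length")
        if self.samples.duplicated(["clone_id", "bmp", "replicate"]).any():
            raise QuantTableError("(clone_id, bmp, replicate) must be unique")
        arr = self.values.to_numpy(dtype=float)
        if np.nanmin(arr, initial=np.inf) < 0:
            raise QuantTableError("negative abundance values")

    @property
    def n_peptides(self) -> int:
        return len(self.peptides)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def copy(self) -> "QuantTable":
        return QuantTable(self.peptides.copy(), self.samples.copy(), self.values.copy())

    def subset(self, row_mask) -> "QuantTable":
        return QuantTable(self.peptides.loc[row_mask].copy(), self.samples.copy(),
                          self.values.loc[row_mask].copy())

    def mapped(self) -> "QuantTable":
        """Rows with an unambiguous precursor assignment."""
        if "map_status" not in self.peptides.columns:
            raise QuantTableError("peptides are not mapped; run map_peptides first")
        return self.subset(self.peptides["map_status"] == "unique")


def write_quant_table(table: QuantTable, path: str | Path) -> None:
    path = Path(path)
    main = pd.concat([table.peptides, table.values], axis=1)
    main.to_csv(path, sep="\t", index=False, na_rep="")
    table.samples.to_csv(path.with_suffix(".samples.tsv"), sep="\t", index=False)


def read_quant_table(path: str | Path, samples_path: str | Path | None = None) -> QuantTable:
    path = Path(path)
    samples_path = Path(samples_path) if samples_path else path.with_suffix(".samples.tsv")
    if not samples_path.exists():
        raise QuantTableError(
            f"missing sample metadata sidecar {samples_path}; "
            f"required columns: {SAMPLE_COLUMNS}"
        )
    samples = pd.read_csv(samples_path, sep="\t", dtype={"sample_id": str, "clone_id": str})
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise QuantTableError(f"sample metadata lacks required columns {missing}")
    main = pd.read_csv(path, sep="\t")
    meta_cols = [c for c in PEPTIDE_COLUMNS + MAPPING_COLUMNS if c in main.columns]
    for c in PEPTIDE_COLUMNS:
        if c not in main.columns:
            raise QuantTableError(f"quant table lacks required column {c!r}")
    sample_ids = list(samples["sample_id"])
    absent = [s for s in sample_ids if s not in main.columns]
    if absent:
        raise QuantTableError(f"quant table lacks columns for samples {absent}")
    peptides = main[meta_cols].copy()
    peptides["modifications"] = peptides["modifications"].fillna("")
    values = main[sample_ids].astype(float)
    return QuantTable(peptides=peptides, samples=samples, values=values)


def normalize_total(table: QuantTable) -> QuantTable:
    """Total-intensity normalization across all files.

    Every sample is rescaled so its total (over non-missing values) equals
    the grand median of the pre-normalization totals; missing stays missing.
    """
    totals = table.values.sum(axis=0, skipna=True)
    empty = totals[table.values.notna().sum(axis=0) == 0]
    if len(empty):
        raise QuantTableError(f"sample(s) with no observed values: {list(empty.index)}")
    target = float(np.median(totals.to_numpy()))
    scaled = table.values * (target / totals)
    return replace(table, values=scaled,
                   peptides=table.peptides.copy(), samples=table.samples.copy())


def filter_replicate_complete(table: QuantTable,
                              grouping: tuple[str, ...] = ("clone_id", "bmp")) -> QuantTable:
    """Keep peptides observed in *every* replicate of at least one group.

    Default grouping is clone × BMP state, i.e. one organoid-clone
    condition; a peptide sporadically seen across clones but never complete
    within one is dropped.
    """
    observed = table.values.notna().to_numpy()
    keep = np.zeros(table.n_peptides, dtype=bool)
    for _, grp in table.samples.groupby(list(grouping), sort=False):
        cols = grp.index.to_numpy()
        keep |= observed[:, cols].all(axis=1)
    return table.subset(keep)


def map_peptides(table: QuantTable, registry: PrecursorRegistry):
    """Locate every peptide in the precursor registry by exact substring.

    A single hit fills ``accession/start/end`` and marks the row
    ``unique``; zero hits mark it ``unmapped``; several hits ``ambiguous``
    (all locations recorded in ``locations``).  Amidated peptides must
    additionally be followed by a glycine in the precursor (the amide-donor
    rule); amidated peptides with hits but no glycine-valid location are
    marked ``amidation_invalid`` and excluded downstream.

    Returns ``(mapped_table, report)``.
    """
    peptides = table.peptides.copy()
    statuses, accs, starts, ends, locs = [], [], [], [], []
    for seq, mods in zip(peptides["sequence"], peptides["modifications"]):
        hits = registry.locate(seq)
        amidated = "amidated_C_term" in str(mods)
        if amidated:
            valid = [(a, s, e) for a, s, e in hits
                     if e < len(registry[a]) and registry[a].sequence[e] == "G"]
            if hits and not valid:
                statuses.append("amidation_invalid")
                accs.append(""); starts.append(0); ends.append(0); locs.append("")
                continue
            hits = valid
        if len(hits) == 1:
            a, s, e = hits[0]
            statuses.append("unique"); accs.append(a); starts.append(s); ends.append(e)
            locs.append(f"{a}:{s}-{e}")
        elif not hits:
            statuses.append("unmapped")
            accs.append(""); starts.append(0); ends.append(0); locs.append("")
        else:
            statuses.append("ambiguous")
            accs.append(""); starts.append(0); ends.append(0)
            locs.append(";".join(f"{a}:{s}-{e}" for a, s, e in hits))
    peptides["accession"] = accs
    peptides["start"] = starts
    peptides["end"] = ends
    peptides["map_status"] = statuses
    peptides["locations"] = locs
    report = dict(pd.Series(statuses).value_counts())
    report = {k: int(v) for k, v in report.items()}
    return replace(table, peptides=peptides, samples=table.samples.copy(),
                   values=table.values.copy()), report


def aggregate_precursor(table: QuantTable) -> pd.DataFrame:
    """Precursor-level abundance: per sample, the sum of mapped peptide
    abundances; all peptides missing in a sample gives NaN (n.d.)."""
    mapped = table.mapped()
    frame = pd.concat([mapped.peptides[["accession"]], mapped.values], axis=1)
    return frame.groupby("accession").sum(min_count=1)


def match_bioactive(table: QuantTable, registry: PrecursorRegistry) -> pd.Series:
    """Label observations that exactly match an annotated bioactive feature.

    Exact coordinate equality and matching amidation state are required;
    amidated forms get an 'a' suffix on the feature name.  Returns a Series
    aligned to the table's rows ('' where no feature matches).
    """
    if "map_status" not in table.peptides.columns:
        raise QuantTableError("peptides are not mapped; run map_peptides first")
    labels = []
    for _, row in table.peptides.iterrows():
        label = ""
        if row["map_status"] == "unique":
            amidated = "amidated_C_term" in str(row["modifications"])
            for feat in registry[row["accession"]].features:
                if (feat.kind != "signal" and feat.start == row["start"]
                        and feat.end == row["end"] and feat.amidated == amidated):
                    label = feat.name + ("a" if amidated else "")
                    break
        labels.append(label)
    return pd.Series(labels, index=table.peptides.index, name="bioactive")
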