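"""In-silico prohormone processing and knockout peptidome simulation.

The generator composes four enzymatic mechanisms into ground-truthed peptide
quantification tables mirroring the knockout-organoid study design:

* **endoprotease** (PCSK1/PCSK2 family): cleaves immediately C-terminal to a
  dibasic pair (KK, KR, RK, RR), so every released fragment ends with the
  pair that licensed its cleavage;
* **carboxypeptidase** (CPE or CPB1): removes exposed C-terminal basic
  residues one at a time until a non-basic terminus remains;
* **amidation**: a C-terminal glycine exposed by carboxypeptidase trimming is
  converted into a C-terminal amide on the preceding residue;
* **DPP4**: removes the N-terminal dipeptide when residue 2 is proline or
  alanine (optionally iteratively).

PCSK1 and PCSK2 are not given distinct site preferences; endoproteolysis is
abolished only when both are disabled (they are redundant in this model).
Each precursor is handled by exactly one carboxypeptidase so that a single
knockout produces accumulating species; CPB1 covers the SST/NPW/PPY
stand-ins, CPE everything else.

Measurement emulation: per-species log2 base levels, clone and technical
Gaussian noise, a knockout log2 shift that moves substrate species between a
"present" and a "depleted" state, and left-censored missingness (the lowest
fraction of linear intensities is set missing, as in label-free LC-MS data
where low-abundance ions drop below the detection limit).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .precursors import ALPHABET, PrecursorRecord, PrecursorRegistry

BASIC = frozenset("KR")
DPP4_SECOND = frozenset("PA")
_DIBASIC_RE = re.compile("(?=[KR][KR])")

#: Accessions handled by CPB1 in the bundled fixture set; all other
#: precursors are CPE substrates.
CPB1_SUBSTRATES = frozenset({"SYNP001", "SYNP002", "SYNP003"})

ENZYMES = ("PCSK1", "PCSK2", "CPE", "CPB1", "DPP4", "amidation")


@dataclass(frozen=True)
class EnzymeRule:
    """One enzyme's mechanism and per-event firing probability."""

    enzyme_name: str
    mechanism: str  # endo_dibasic | carboxy_basic | amino_dipeptide | c_terminal_amidation
    efficiency: float = 1.0
    substrates: frozenset[str] | None = None  # None = all precursors
    iterative: bool = False  # DPP4 only: keep removing eligible dipeptides

    def __post_init__(self) -> None:
        if not (0.0 <= self.efficiency <= 1.0):
            raise ValueError(f"efficiency must be in [0, 1], got {self.efficiency}")


def default_rules() -> dict[str, EnzymeRule]:
    """Fixture enzyme set: redundant endoproteases, partitioned
    carboxypeptidases, single-pass DPP4, full-efficiency amidation."""
    return {
        "PCSK_endo": EnzymeRule("PCSK_endo", "endo_dibasic", 1.0),
        "CPE": EnzymeRule("CPE", "carboxy_basic", 1.0, substrates=None),
        "CPB1": EnzymeRule("CPB1", "carboxy_basic", 1.0, substrates=CPB1_SUBSTRATES),
        "DPP4": EnzymeRule("DPP4", "amino_dipeptide", 1.0),
        "amidation": EnzymeRule("amidation", "c_terminal_amidation", 1.0),
    }


@dataclass(frozen=True)
class Genotype:
    """An organoid line genotype: which enzymes are disabled, and the clone
    identifiers measured for it (the parental 'bulk' culture counts as a
    clone id)."""

    name: str
    disabled: frozenset[str] = frozenset()
    clones: tuple[str, ...] = ()

    def endo_active(self) -> bool:
        # PCSK1/PCSK2 are redundant: both must be lost to abolish cleavage.
        if "PCSK_endo" in self.disabled:
            return False
        return not {"PCSK1", "PCSK2"} <= self.disabled


def knockout_design(ko_enzyme: str, replicates: int = 3, seed: int = 1) -> "SimDesign":
    """The study's comparison design: bulk + clonal wild type versus two
    knockout clones, three technical replicates each."""
    wt = Genotype("WT", frozenset(), ("bulk", "wt1"))
    disabled = frozenset({"PCSK1", "PCSK2"}) if ko_enzyme == "PCSK_endo" else frozenset({ko_enzyme})
    ko = Genotype(f"{ko_enzyme}_KO", disabled, ("ko1", "ko2"))
    return SimDesign(genotypes=(wt, ko), replicates_per_clone=replicates, seed=seed)


@dataclass(frozen=True)
class SimDesign:
    genotypes: tuple[Genotype, ...]
    replicates_per_clone: int = 3
    bmp_states: tuple[str, ...] = ("minus",)
    seed: int = 1

    def __post_init__(self) -> None:
        if self.replicates_per_clone < 1:
            raise ValueError("replicates_per_clone must be >= 1")
        names = [g.name for g in self.genotypes]
        if "WT" not in names:
            raise ValueError("design must include a wild-type genotype named 'WT'")
        if any(s not in {"minus", "plus"} for s in self.bmp_states):
            raise ValueError("bmp_states must be a subset of {'minus', 'plus'}")

    @property
    def wild_type(self) -> Genotype:
        return next(g for g in self.genotypes if g.name == "WT")


@dataclass(frozen=True)
class NoiseModel:
    """Log-normal abundance noise and left-censored missingness.

    All spreads are on the log2 scale.  ``ko_log2_shift`` is the distance
    between a species' "present" and "depleted" states: a knockout-
    accumulating species sits ``shift`` below its base level in wild-type
    samples (a trace-level intermediate), and a mature product sits
    ``shift`` below base in knockout samples.
    """

    log2_sd_biological: float = 0.25
    log2_sd_technical: float = 0.5
    ko_log2_shift: float = 4.0
    censor_quantile: float = 0.1
    base_log2_mean: float = 20.5
    base_log2_sd: float = 1.0

    def __post_init__(self) -> None:
        if min(self.log2_sd_biological, self.log2_sd_technical, self.ko_log2_shift) < 0:
            raise ValueError("noise parameters must be nonnegative")
        if not (0.0 <= self.censor_quantile < 1.0):
            raise ValueError("censor_quantile must be in [0, 1)")


@dataclass(frozen=True)
class Species:
    """A ground-truth peptide species located on its precursor."""

    accession: str
    start: int  # 1-based inclusive
    end: int
    sequence: str
    amidated: bool = False

    @property
    def modifications(self) -> str:
        return "amidated_C_term" if self.amidated else ""


# ---------------------------------------------------------------------------
# mechanisms


def dibasic_boundaries(sequence: str) -> list[int]:
    """Between-residue boundaries immediately C-terminal to a dibasic pair.

    Boundary ``b`` means cleavage between residues ``b`` and ``b+1``
    (0-based between-residue index relative to ``sequence``).
    """
    return [m.start() + 2 for m in _DIBASIC_RE.finditer(sequence)]


def digest_endo(sequence: str, efficiency: float = 1.0,
                rng: np.random.Generator | None = None) -> list[tuple[str, int, int]]:
    """Endoprotease digestion after dibasic pairs.

    Each eligible boundary fires independently with probability
    ``efficiency``.  Returns ``(fragment, start0, end0)`` triples where
    ``start0``/``end0`` are 0-based half-open offsets into ``sequence``; the
    fragments concatenate to the input.
    """
    if not sequence:
        raise ValueError("empty sequence")
    sites = [b for b in dibasic_boundaries(sequence) if b < len(sequence)]
    if efficiency >= 1.0:
        fired = sites
    elif efficiency <= 0.0:
        fired = []
    else:
        if rng is None:
            rng = np.random.default_rng(0)
        fired = [b for b in sites if rng.random() < efficiency]
    cuts = [0, *fired, len(sequence)]
    return [(sequence[a:b], a, b) for a, b in zip(cuts, cuts[1:])]


def trim_carboxy(peptide: str, enzyme_active: bool = True) -> list[str]:
    """Carboxypeptidase trimming chain.

    Active: strip C-terminal K/R one residue at a time, emitting every
    intermediate, until the C terminus is non-basic (or the peptide is
    exhausted).  Inactive: the peptide is returned unchanged — the species
    that accumulates in the knockout.
    """
    if not peptide:
        raise ValueError("empty peptide")
    if not enzyme_active or peptide[-1] not in BASIC:
        return [peptide]
    chain = []
    p = peptide
    while p and p[-1] in BASIC:
        p = p[:-1]
        if p:
            chain.append(p)
    return chain if chain else [peptide]


def trim_amino_dpp4(peptide: str, enzyme_active: bool = True,
                    iterative: bool = False) -> list[str]:
    """DPP4 N-terminal dipeptide removal (residue 2 must be P or A)."""
    if len(peptide) < 3:
        raise ValueError("peptide must be at least 3 residues")
    if not enzyme_active or peptide[1] not in DPP4_SECOND:
        return [peptide]
    species = []
    p = peptide
    while len(p) >= 3 and p[1] in DPP4_SECOND:
        p = p[2:]
        species.append(p)
        if not iterative:
            break
    return species if species else [peptide]


def amidate(fragment: str) -> str | None:
    """Convert a glycine-ending fragment into its amidated species.

    Returns the sequence with the glycine removed (the new C terminus is
    amidated), or None when the fragment does not end in glycine or the
    product would be empty.
    """
    if not fragment.endswith("G") or len(fragment) < 2:
        return None
    return fragment[:-1]


# ---------------------------------------------------------------------------
# genotype-level simulation


def _carboxy_enzyme_for(accession: str, rules: dict[str, EnzymeRule]) -> EnzymeRule | None:
    specific = None
    fallback = None
    for rule in rules.values():
        if rule.mechanism != "carboxy_basic":
            continue
        if rule.substrates is not None and accession in rule.substrates:
            specific = rule
        elif rule.substrates is None:
            fallback = rule
    return specific or fallback


def simulate_peptidome(registry: PrecursorRegistry, genotype: Genotype,
                       rules: dict[str, EnzymeRule] | None = None,
                       seed: int = 0) -> list[Species]:
    """Simulate the steady-state peptidome of one genotype.

    Deterministic given ``seed``; with all efficiencies at 1 it is fully
    deterministic and each precursor fragment contributes exactly one final
    species (trimming and amidation run to completion, so transient
    intermediates do not persist).
    """
    rules = rules if rules is not None else default_rules()
    rng = np.random.default_rng(seed)
    out: list[Species] = []
    for rec in sorted(registry, key=lambda r: r.accession):
        sig = rec.signal_end()
        chain = rec.sequence[sig:]
        if not chain:
            continue
        endo = rules.get("PCSK_endo")
        eff = endo.efficiency if (endo and genotype.endo_active()) else 0.0
        for frag, a0, b0 in digest_endo(chain, eff, rng):
            start = sig + a0 + 1
            end = sig + b0
            seq = frag
            # carboxypeptidase trimming
            carboxy = _carboxy_enzyme_for(rec.accession, rules)
            active = carboxy is not None and carboxy.enzyme_name not in genotype.disabled
            if active:
                while len(seq) > 1 and seq[-1] in BASIC and rng.random() < carboxy.efficiency:
                    seq = seq[:-1]
                    end -= 1
            # amidation of an exposed C-terminal glycine
            amidated = False
            amid = rules.get("amidation")
            if (amid and "amidation" not in genotype.disabled and seq.endswith("G")
                    and len(seq) > 1 and rng.random() < amid.efficiency):
                seq = seq[:-1]
                end -= 1
                amidated = True
            # DPP4 N-terminal dipeptidase
            dpp4 = rules.get("DPP4")
            if dpp4 and "DPP4" not in genotype.disabled:
                while len(seq) >= 3 and seq[1] in DPP4_SECOND and rng.random() < dpp4.efficiency:
                    seq = seq[2:]
                    start += 2
                    if not dpp4.iterative:
                        break
            if seq:
                out.append(Species(rec.accession, start, end, seq, amidated))
    return out


def _deterministic_rules(rules: dict[str, EnzymeRule]) -> dict[str, EnzymeRule]:
    return {k: replace(r, efficiency=1.0) for k, r in rules.items()}


def label_species(registry: PrecursorRegistry, design: SimDesign,
                  rules: dict[str, EnzymeRule] | None = None) -> pd.DataFrame:
    """Ground-truth table for every species appearing in any genotype.

    Truth is defined at efficiency 1 (deterministic processing): a species
    present only in the wild type is ``mature``, present only in a knockout
    is ``KO-accumulating`` (annotated with that genotype's disabled
    enzymes), present in both is ``constitutive``.
    """
    rules = _deterministic_rules(rules if rules is not None else default_rules())
    sets = {g.name: set(simulate_peptidome(registry, g, rules)) for g in design.genotypes}
    wt = sets["WT"]
    rows = []
    seen: dict[tuple[str, str], dict] = {}
    for g in design.genotypes:
        for sp in sets[g.name]:
            key = (sp.sequence, sp.modifications)
            if key not in seen:
                seen[key] = {
                    "sequence": sp.sequence,
                    "modifications": sp.modifications,
                    "accession": sp.accession,
                    "start": sp.start,
                    "end": sp.end,
                    "genotypes": set(),
                }
            seen[key]["genotypes"].add(g.name)
    ko_names = [g.name for g in design.genotypes if g.name != "WT"]
    for key, info in seen.items():
        in_wt = "WT" in info["genotypes"]
        in_ko = [n for n in ko_names if n in info["genotypes"]]
        if in_wt and len(in_ko) == len(ko_names):
            label, enzyme = "constitutive", ""
        elif in_wt:
            label, enzyme = "mature", ""
        else:
            label = "KO-accumulating"
            enzyme = ";".join(sorted(
                e for n in in_ko
                for e in next(g for g in design.genotypes if g.name == n).disabled))
        rows.append({**{k: info[k] for k in
                        ("sequence", "modifications", "accession", "start", "end")},
                     "present_in": ",".join(sorted(info["genotypes"])),
                     "label": label, "enzyme": enzyme})
    truth = pd.DataFrame(rows).sort_values(
        ["accession", "start", "end", "modifications"], kind="mergesort"
    ).reset_index(drop=True)
    return truth


def _background_peptides(n: int, registry: PrecursorRegistry,
                         rng: np.random.Generator) -> list[str]:
    """Random constitutive peptides that map to no precursor (the
    non-hormone background of a real search database)."""
    letters = np.array(sorted(ALPHABET))
    seqs: list[str] = []
    corpus = [rec.sequence for rec in registry]
    attempts = 0
    while len(seqs) < n and attempts < 50 * n:
        attempts += 1
        length = int(rng.integers(9, 19))
        s = "".join(letters[rng.integers(0, len(letters), size=length)])
        if any(s in c for c in corpus) or s in seqs:
            continue
        seqs.append(s)
    if len(seqs) < n:
        raise RuntimeError("could not generate enough background peptides")
    return seqs


def generate_quant_table(design: SimDesign,
                         registry: PrecursorRegistry | None = None,
                         rules: dict[str, EnzymeRule] | None = None,
                         noise: NoiseModel | None = None,
                         n_background: int = 30):
    """Simulate a peptide quantification table plus its truth table.

    Returns ``(table, truth)`` where ``table`` is a
    :class:`enteropep.quant_io.QuantTable` and ``truth`` a DataFrame with one
    row per peptide carrying the ground-truth label.  Reproducible given
    ``design.seed``.
    """
    from .quant_io import QuantTable  # local import to avoid a cycle

    if registry is None:
        from .precursors import bundled_registry
        registry = bundled_registry()
    noise = noise if noise is not None else NoiseModel()
    rng = np.random.default_rng(design.seed)

    truth = label_species(registry, design, rules)
    bg = _background_peptides(n_background, registry, rng)
    bg_truth = pd.DataFrame({
        "sequence": bg, "modifications": "", "accession": "", "start": 0, "end": 0,
        "present_in": ",".join(sorted(g.name for g in design.genotypes)),
        "label": "constitutive", "enzyme": "",
    })
    truth = pd.concat([truth, bg_truth], ignore_index=True)

    samples = []
    for g in design.genotypes:
        for clone in g.clones:
            for bmp in design.bmp_states:
                for rep in range(1, design.replicates_per_clone + 1):
                    samples.append({
                        "sample_id": f"{clone}_{bmp}_r{rep}",
                        "clone_id": clone, "genotype": g.name,
                        "bmp": bmp, "replicate": rep,
                    })
    sample_df = pd.DataFrame(samples)

    m, n = len(truth), len(sample_df)
    base = rng.normal(noise.base_log2_mean, noise.base_log2_sd, size=m)
    clone_ids = sorted({s["clone_id"] for s in samples})
    clone_eff = {c: rng.normal(0.0, noise.log2_sd_biological, size=m) for c in clone_ids}
    present_sets = [set(p.split(",")) for p in truth["present_in"]]

    log2 = np.empty((m, n))
    for j, s in enumerate(samples):
        shift = np.where([s["genotype"] in ps for ps in present_sets],
                         0.0, -noise.ko_log2_shift)
        tech = rng.normal(0.0, noise.log2_sd_technical, size=m)
        log2[:, j] = base + clone_eff[s["clone_id"]] + shift + tech

    linear = np.exp2(log2)
    if noise.censor_quantile > 0:
        threshold = np.quantile(linear, noise.censor_quantile)
        linear = np.where(linear < threshold, np.nan, linear)

    values = pd.DataFrame(linear, columns=sample_df["sample_id"].tolist())
    peptides = truth[["sequence", "modifications"]].copy()
    table = QuantTable(peptides=peptides, samples=sample_df, values=values)
    return table, truth
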