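"""End-to-end orchestration: simulate -> ingest -> filter/normalize ->
differential -> specificity -> report bundle.

Everything is deterministic given the config seed: one global seed fans out
to per-stage seeds via a CRC32 of ``"<seed>:<stage>"`` (documented here so
stages can be re-run in isolation with the same stream).
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import differential as diff
from . import ms1_targeted as ms1
from . import quant_io, specificity
from .precursors import PrecursorRegistry, bundled_registry, load_feature_table, load_precursor_fasta
from .synthetic_data import NoiseModel, SimDesign, default_rules, generate_quant_table, knockout_design

logger = logging.getLogger(__name__)

KNOWN_SCENARIOS = ("CPE", "CPB1", "DPP4", "PCSK_endo")


def derive_seed(seed: int, stage: str) -> int:
    return zlib.crc32(f"{seed}:{stage}".encode()) % (2**31)


@dataclass
class SimulationConfig:
    scenario: str = "CPE"          # which enzyme the KO clones lack
    replicates: int = 3
    n_background: int = 30
    noise: NoiseModel = field(default_factory=NoiseModel)


@dataclass
class AnalysisConfig:
    n_perm: int = 250
    q_cutoff: float = 0.05
    imputation_downshift: float = 1.8
    imputation_width: float = 0.3
    normalization: str = "total"   # "total" | "none"
    linkage: str = "average"
    impute: bool = True


@dataclass
class MS1Config:
    idotp_threshold: float = 0.88
    rt_window: tuple[float, float] = (89.0, 91.0)
    simulate_envelopes: bool = True
    envelopes_path: str = ""
    targets_path: str = ""


@dataclass
class PipelineConfig:
    source: str = "simulate"       # "simulate" or a quant TSV path
    fasta_path: str = ""           # empty = bundled fixture registry
    features_path: str = ""
    outdir: str = "results/run"
    seed: int = 1
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    ms1: MS1Config = field(default_factory=MS1Config)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = PipelineConfig()
    for key in ("source", "fasta_path", "features_path", "outdir", "seed"):
        if key in raw:
            setattr(cfg, key, raw[key])
    if "simulation" in raw:
        sim = raw["simulation"]
        noise = NoiseModel(**sim.pop("noise", {}))
        cfg.simulation = SimulationConfig(noise=noise, **sim)
    if "analysis" in raw:
        cfg.analysis = AnalysisConfig(**raw["analysis"])
    if "ms1" in raw:
        m = dict(raw["ms1"])
        if "rt_window" in m:
            m["rt_window"] = tuple(m["rt_window"])
        cfg.ms1 = MS1Config(**m)
    return cfg


def validate_config(config: PipelineConfig) -> list[str]:
    """Every violation names the offending field and constraint."""
    v = []
    if not (0.0 < config.analysis.q_cutoff < 1.0):
        v.append(f"analysis.q_cutoff must be in (0, 1), got {config.analysis.q_cutoff}")
    if config.analysis.n_perm < 1:
        v.append(f"analysis.n_perm must be >= 1, got {config.analysis.n_perm}")
    if config.analysis.normalization not in {"total", "none"}:
        v.append(f"analysis.normalization must be 'total' or 'none', got {config.analysis.normalization!r}")
    if config.source != "simulate":
        if not Path(config.source).exists():
            v.append(f"source quant table {config.source!r} does not exist")
        if not config.fasta_path:
            v.append("fasta_path is required when source is not 'simulate'")
    if config.source == "simulate" and config.simulation.scenario not in KNOWN_SCENARIOS:
        v.append(f"simulation.scenario must be one of {KNOWN_SCENARIOS}, got {config.simulation.scenario!r}")
    if not (0.0 < config.ms1.idotp_threshold <= 1.0):
        v.append(f"ms1.idotp_threshold must be in (0, 1], got {config.ms1.idotp_threshold}")
    if config.simulation.replicates < 1:
        v.append(f"simulation.replicates must be >= 1, got {config.simulation.replicates}")
    return v


def _load_registry(config: PipelineConfig) -> PrecursorRegistry:
    if config.fasta_path:
        registry = load_precursor_fasta(config.fasta_path)
        if config.features_path:
            load_feature_table(config.features_path, registry)
        return registry
    return bundled_registry()


def _simulate_ms1(config: PipelineConfig, table: quant_io.QuantTable, outdir: Path) -> pd.DataFrame:
    """Desk-scale MS1 verification demo on the glucagon target.

    Observed envelopes are the theoretical envelope scaled by a per-sample
    abundance with multiplicative noise in alternating samples; the others
    get an incoherent envelope and an off-window retention time, so they
    come out n.d. with abundance zero.
    """
    glucagon = "HSQGTFTSDYSKYLDSRRAQDFVQWLMNT"
    target = ms1.TargetIon(glucagon, frozenset(), charge=4)
    theo = ms1.theoretical_envelope(ms1.elemental_composition(target))
    rng = np.random.default_rng(derive_seed(config.seed, "ms1"))
    rows = []
    for k, sample in enumerate(table.samples["sample_id"]):
        present = k % 2 == 1  # alternate detected / n.d. samples in the demo
        T = float(2 ** rng.normal(18.0, 0.5))
        if present:
            obs = theo.intensities * T * (1 + rng.normal(0, 0.02, ms1.N_ISOTOPES))
            rt = float(rng.uniform(*config.ms1.rt_window))
        else:
            obs = rng.uniform(0, 1, ms1.N_ISOTOPES) * T  # no coherent envelope
            rt = float(rng.uniform(60.0, 80.0))
        rows.append({"sequence": glucagon, "sample": sample,
                     **{f"m{i}": max(v, 0.0) for i, v in enumerate(obs)}, "rt": rt})
    envelopes = pd.DataFrame(rows)
    envelopes.to_csv(outdir / "ms1_envelopes.tsv", sep="\t", index=False)
    results = ms1.run_ms1([target], envelopes, config.ms1.idotp_threshold, config.ms1.rt_window)
    results.to_csv(outdir / "ms1_results.tsv", sep="\t", index=False)
    return results


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write the report bundle into ``outdir``.

    Returns the manifest (also written as ``run_manifest.json``), which
    records seeds, stage row counts, and headline specificity fractions.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    registry = _load_registry(config)
    manifest: dict = {"seed": config.seed, "stages": {}, "config": _config_dict(config)}

    # --- ingest -----------------------------------------------------------
    if config.source == "simulate":
        design = knockout_design(config.simulation.scenario,
                                 replicates=config.simulation.replicates,
                                 seed=derive_seed(config.seed, "simulate"))
        table, truth = generate_quant_table(
            design, registry, default_rules(), config.simulation.noise,
            n_background=config.simulation.n_background)
        quant_io.write_quant_table(table, outdir / "simulated_quant.tsv")
        truth.to_csv(outdir / "simulated_truth.tsv", sep="\t", index=False)
        ko_genotype = f"{config.simulation.scenario}_KO"
    else:
        table = quant_io.read_quant_table(config.source)
        truth = None
        kos = [g for g in table.samples["genotype"].unique() if g != "WT"]
        if len(kos) != 1:
            raise ValueError(f"expected exactly one knockout genotype, found {kos}")
        ko_genotype = kos[0]
    manifest["stages"]["input"] = {"peptides": table.n_peptides, "samples": table.n_samples}

    # --- normalize / filter / map ----------------------------------------
    if config.analysis.normalization == "total":
        table = quant_io.normalize_total(table)
    filtered = quant_io.filter_replicate_complete(table)
    manifest["stages"]["replicate_filter"] = {
        "kept": filtered.n_peptides,
        "dropped": table.n_peptides - filtered.n_peptides,
    }
    mapped, map_report = quant_io.map_peptides(filtered, registry)
    manifest["stages"]["mapping"] = map_report

    # --- differential -----------------------------------------------------
    results = diff.differential_analysis(
        mapped, ko_genotype,
        n_perm=config.analysis.n_perm, q_cutoff=config.analysis.q_cutoff,
        imputation=diff.ImputationParams(config.analysis.imputation_downshift,
                                         config.analysis.imputation_width,
                                         seed=derive_seed(config.seed, "impute")),
        impute=config.analysis.impute, seed=derive_seed(config.seed, "permutation"))
    results.to_csv(outdir / "differential_results.tsv", sep="\t", index=False)
    ko_set, wt_set = diff.enriched_sets(results)
    manifest["stages"]["differential"] = {
        "tested": len(results), "ko_enriched": len(ko_set), "wt_enriched": len(wt_set),
    }

    # --- specificity ------------------------------------------------------
    terminus = "N" if ko_genotype.startswith("DPP4") else "C"
    spec_summary = {}
    for name, peptide_set in (("ko_enriched", ko_set), ("wt_enriched", wt_set)):
        unique = peptide_set[peptide_set.get("map_status", "") == "unique"]
        if unique.empty:
            continue
        contexts, _ = specificity.extract_contexts(unique, registry, terminus)
        deduped = specificity.dedupe_contexts(contexts)
        logo = specificity.build_logo(deduped)
        specificity.write_logo_tsv(logo, outdir / f"logo_{name}_{terminus}term.tsv")
        spec_summary[name] = {
            "n_contexts": len(contexts), "n_unique": len(deduped),
            "frac_KR_minus1": specificity.residue_fraction(contexts, -1, "KR"),
            "frac_KR_plus1": specificity.residue_fraction(contexts, +1, "KR"),
            "frac_PA_plus2": specificity.residue_fraction(contexts, +2, "PA"),
        }
        repertoire = specificity.substrate_repertoire(unique)
        repertoire.rename("n_peptides").to_csv(
            outdir / f"repertoire_{name}.tsv", sep="\t", index_label="accession")
    manifest["stages"]["specificity"] = spec_summary

    pairs = specificity.find_dipeptide_pairs(mapped)
    pairs.to_csv(outdir / "dipeptide_pairs.tsv", sep="\t", index=False)
    if not pairs.empty:
        specificity.pair_zscaled_matrix(mapped, pairs).to_csv(
            outdir / "dipeptide_pairs_zscaled.tsv", sep="\t", index=False)
    manifest["stages"]["dipeptide_pairs"] = {"n_pairs": len(pairs)}

    # --- clustering of the significant set --------------------------------
    sig = results[results["significant"]]
    if len(sig) >= 2:
        log2 = diff.log2_transform(mapped.values)
        log2 = diff.impute_leftshift(log2, diff.ImputationParams(
            config.analysis.imputation_downshift, config.analysis.imputation_width,
            seed=derive_seed(config.seed, "impute")))
        scaled, _ = diff.zscale(log2.iloc[sig.index])
        order, Z = diff.hcluster(scaled, method=config.analysis.linkage)
        clustered = scaled.iloc[order]
        clustered.insert(0, "sequence", mapped.peptides["sequence"].iloc[sig.index].iloc[order].to_numpy())
        clustered.to_csv(outdir / "significant_zscaled_clustered.tsv", sep="\t", index=False)
        labels = mapped.peptides["sequence"].iloc[sig.index].tolist()
        (outdir / "significant_dendrogram.nwk").write_text(
            diff.linkage_to_newick(Z, labels) + "\n")

    # --- MS1 --------------------------------------------------------------
    if config.ms1.envelopes_path and config.ms1.targets_path:
        targets = ms1.read_targets_tsv(config.ms1.targets_path)
        envelopes = pd.read_csv(config.ms1.envelopes_path, sep="\t")
        ms1_results = ms1.run_ms1(targets, envelopes, config.ms1.idotp_threshold,
                                  config.ms1.rt_window)
        ms1_results.to_csv(outdir / "ms1_results.tsv", sep="\t", index=False)
    elif config.ms1.simulate_envelopes:
        ms1_results = _simulate_ms1(config, table, outdir)
    else:
        ms1_results = pd.DataFrame()
    manifest["stages"]["ms1"] = {
        "n_ions": len(ms1_results),
        "n_detected": int(ms1_results["detected"].sum()) if len(ms1_results) else 0,
    }

    manifest["config_crc32"] = zlib.crc32(
        json.dumps(manifest["config"], sort_keys=True).encode())
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["ms1"]["rt_window"] = list(d["ms1"]["rt_window"])
    return d
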