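"""End-to-end orchestration: consensus -> alignments -> events -> variants
-> statistics -> clustering, with table and JSON report emission."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .alignment import AlignParams, build_gdna_consensus, global_align
from .effects import classify_effect
from .rdd_caller import call_events, merge_deletion_runs, summarize_sites
from .stats_cluster import (gene_tissue_counts, rdd_rate, site_counts_by_tissue,
                            spectrum_by_tissue, substitution_spectrum,
                            syn_nonsyn_counts, three_prime_context_bias,
                            tissue_dendrogram)
from .synthetic_data import SimConfig, read_dataset, simulate_dataset, write_dataset

logger = logging.getLogger("rddkit")


@dataclass
class PipelineConfig:
    """Exactly one of ``simulate`` or ``data_dir`` must be supplied."""

    simulate: SimConfig | None = None
    data_dir: str | None = None
    align: AlignParams = field(default_factory=AlignParams)
    stop_gain_convention: str = "stop_position"   # or "length"
    signal_peptide_end: dict = field(default_factory=dict)  # gene_id -> residue
    cluster_features: str = "sites"               # or "spectrum"
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self):
        if (self.simulate is None) == (self.data_dir is None):
            raise ValueError("supply exactly one of simulate config or data_dir")
        if self.cluster_features not in ("sites", "spectrum"):
            raise ValueError("cluster_features must be 'sites' or 'spectrum'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulate" in raw and raw["simulate"] is not None:
            raw["simulate"] = SimConfig.from_dict(raw["simulate"])
        if "align" in raw and raw["align"] is not None:
            raw["align"] = AlignParams(**raw["align"])
        return cls(**raw)

    def resolved(self) -> dict:
        out = {"stop_gain_convention": self.stop_gain_convention,
               "cluster_features": self.cluster_features,
               "signal_peptide_end": dict(self.signal_peptide_end),
               "data_dir": self.data_dir, "out_dir": self.out_dir,
               "seed": self.seed,
               "align": {"match": self.align.match,
                         "mismatch": self.align.mismatch,
                         "gap_open": self.align.gap_open,
                         "gap_extend": self.align.gap_extend}}
        if self.simulate is not None:
            out["simulate"] = self.simulate.to_dict()
        return out


@dataclass
class PipelineResults:
    genes: list                  # (GeneModel, TranscriptRef)
    clones: list
    consensus: dict              # gene_id -> ConsensusResult
    events: list                 # merged RDDEvents, all genes
    variants: list               # (clone_id, gene_id, tissue, [rna names], ProteinVariant)
    matrix: "pd.DataFrame"
    spectrum: object
    site_summaries: dict         # gene_id -> list of SiteSummary
    rates: dict                  # gene_id -> (per_clone, per_kb_per_clone)
    context_bias: dict           # gene_id -> (proportion, p, n) or None
    syn_nonsyn: tuple
    dendrogram: object           # Dendrogram or None
    manifest: object             # TruthManifest or None


def call_clone(ref, consensus, clone, params: AlignParams):
    """Align one cDNA clone to the consensus and call merged events."""
    pair = global_align(consensus.consensus, clone.seq, params)
    events = call_events(consensus, pair, clone)
    return merge_deletion_runs(events)


def run_pipeline(config: PipelineConfig) -> PipelineResults:
    """Run every stage and return in-memory results (no files written).

    Use :func:`export_tables` to write the report bundle.
    """
    if config.simulate is not None:
        ds = simulate_dataset(config.simulate)
        genes, clones, manifest = ds.genes, ds.clones, ds.manifest
    else:
        genes, clones, manifest = read_dataset(config.data_dir)
    refs = {ref.gene_id: ref for _, ref in genes}
    logger.info("pipeline: %d genes, %d clones", len(genes), len(clones))

    consensus = {}
    for gene_id, ref in refs.items():
        gdna = [c.seq for c in clones if c.gene_id == gene_id and c.source == "gDNA"]
        if gdna:
            consensus[gene_id] = build_gdna_consensus(ref.cdna, gdna, config.align)
        else:
            from .alignment import ConsensusResult
            logger.warning("%s: no gDNA clones; using the reference as consensus",
                           gene_id)
            consensus[gene_id] = ConsensusResult(ref.cdna, [])

    all_events = []
    variants = []
    n_cdna = 0
    for clone in clones:
        if clone.source != "cDNA":
            continue
        n_cdna += 1
        ref = refs[clone.gene_id]
        events = call_clone(ref, consensus[clone.gene_id], clone, config.align)
        all_events.extend(events)
        variant = classify_effect(
            ref, clone.seq, clone_id=clone.clone_id,
            convention=config.stop_gain_convention,
            signal_peptide_end=config.signal_peptide_end.get(clone.gene_id, 0))
        variants.append((clone.clone_id, clone.gene_id, clone.tissue,
                         [e.rna_name for e in events], variant))
    logger.info("pipeline: %d cDNA clones aligned and classified, %d events",
                n_cdna, len(all_events))

    gene_ids = list(refs)
    tissue_names = sorted({c.tissue for c in clones if c.source == "cDNA"})
    matrix = gene_tissue_counts(all_events, genes=gene_ids, tissues=tissue_names)
    spectrum = substitution_spectrum(all_events)
    for gene_id in gene_ids:
        per_gene = [e for e in all_events if e.gene_id == gene_id]
        logger.info("  %s: %d events (%s)", gene_id, len(per_gene),
                    ", ".join(f"{t}={sum(1 for e in per_gene if e.tissue == t)}"
                              for t in tissue_names))

    site_summaries = {g: summarize_sites([e for e in all_events if e.gene_id == g])
                      for g in gene_ids}
    rates = {}
    context = {}
    syn = nonsyn = 0
    for gene_id, ref in refs.items():
        per_gene = [e for e in all_events if e.gene_id == gene_id]
        n_clones = sum(1 for c in clones
                       if c.gene_id == gene_id and c.source == "cDNA")
        if n_clones:
            rates[gene_id] = rdd_rate(per_gene, n_clones, ref)
        try:
            context[gene_id] = three_prime_context_bias(per_gene, ref)
        except ValueError:
            context[gene_id] = None
        s, ns = syn_nonsyn_counts(per_gene, ref)
        syn, nonsyn = syn + s, nonsyn + ns

    dendro = None
    features = (site_counts_by_tissue(all_events)
                if config.cluster_features == "sites"
                else spectrum_by_tissue(all_events))
    try:
        dendro = tissue_dendrogram(features)
    except ValueError as exc:
        logger.warning("clustering skipped: %s", exc)

    return PipelineResults(genes=genes, clones=clones, consensus=consensus,
                           events=all_events, variants=variants, matrix=matrix,
                           spectrum=spectrum, site_summaries=site_summaries,
                           rates=rates, context_bias=context,
                           syn_nonsyn=(syn, nonsyn), dendrogram=dendro,
                           manifest=manifest)


# ---------------------------------------------------------------------------
# report emission
# ---------------------------------------------------------------------------

def events_frame(events) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.clone_id, e.gene_id, e.tissue, e.individual, e.kind, e.pos,
          e.ref_allele, e.alt_allele, e.rna_name) for e in events],
        columns=["clone_id", "gene_id", "tissue", "individual", "kind", "pos",
                 "ref", "alt", "rna_name"])


def variants_frame(variants) -> pd.DataFrame:
    rows = []
    for clone_id, gene_id, tissue, rna_names, v in variants:
        rows.append((clone_id, gene_id, tissue, ";".join(rna_names),
                     v.protein_name, v.category, v.reported_len_aa, v.mass_kda,
                     v.aborted, v.signal_peptide))
    return pd.DataFrame(rows, columns=[
        "clone_id", "gene_id", "tissue", "rna_variants", "protein_variant",
        "category", "amino_acids", "mw_kda", "aborted", "signal_peptide"])


def sites_frame(site_summaries) -> pd.DataFrame:
    rows = []
    for gene_id, summaries in site_summaries.items():
        for s in summaries:
            for tissue in s.tissues:
                subs = ";".join(f"{n}^{alt}" for alt, n in
                                sorted(s.substitutions.get(tissue, {}).items()))
                rows.append((gene_id, s.pos, tissue, subs,
                             s.deletions.get(tissue, 0),
                             s.insertions.get(tissue, 0)))
    return pd.DataFrame(rows, columns=["gene_id", "pos", "tissue",
                                       "substitutions", "deletions", "insertions"])


def export_tables(results: PipelineResults, out_dir,
                  config: PipelineConfig | None = None) -> dict:
    """Write the report bundle; returns {name: path}."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    table1 = results.matrix.with_totals()
    table1.index.name = "gene"
    table1.to_csv(out / "table1.tsv", sep="\t")
    paths["table1"] = out / "table1.tsv"

    variants_frame(results.variants).to_csv(out / "table2.tsv", sep="\t",
                                            index=False)
    paths["table2"] = out / "table2.tsv"

    results.spectrum.to_frame().to_csv(out / "spectrum.tsv", sep="\t", index=False)
    paths["spectrum"] = out / "spectrum.tsv"

    sites_frame(results.site_summaries).to_csv(out / "sites.tsv", sep="\t",
                                               index=False)
    paths["sites"] = out / "sites.tsv"

    events_frame(results.events).to_csv(out / "events.tsv", sep="\t", index=False)
    paths["events"] = out / "events.tsv"

    with open(out / "dendrogram.nwk", "w") as fh:
        fh.write((results.dendrogram.newick + "\n")
                 if results.dendrogram is not None else "")
    paths["dendrogram"] = out / "dendrogram.nwk"

    summary = {
        "n_genes": len(results.genes),
        "n_clones": len(results.clones),
        "n_events": len(results.events),
        "gene_totals": {g: int(t) for g, t in results.matrix.gene_totals.items()},
        "tissue_totals": {t: int(v) for t, v in results.matrix.tissue_totals.items()},
        "grand_total": results.matrix.grand_total,
        "spectrum": results.spectrum.counts,
        "fraction_a_to_g": results.spectrum.fraction_a_to_g,
        "syn": results.syn_nonsyn[0],
        "nonsyn": results.syn_nonsyn[1],
        "rates": {g: {"per_clone": r[0], "per_kb_per_clone": r[1]}
                  for g, r in results.rates.items()},
        "context_bias": {g: (None if c is None else
                             {"proportion_3prime_A": c[0], "p_value": c[1],
                              "n": c[2], "note": "single planned test; "
                              "no multiple-testing correction"})
                         for g, c in results.context_bias.items()},
        "dendrogram_heights": (results.dendrogram.heights
                               if results.dendrogram else []),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    paths["summary"] = out / "summary.json"

    if config is not None:
        with open(out / "config.resolved.yaml", "w") as fh:
            yaml.safe_dump(config.resolved(), fh, sort_keys=True)
        paths["config"] = out / "config.resolved.yaml"
    return paths


def run_and_export(config: PipelineConfig) -> PipelineResults:
    results = run_pipeline(config)
    if config.out_dir:
        export_tables(results, config.out_dir, config)
        if config.simulate is not None:
            write_dataset(results.genes, results.clones, results.manifest,
                          Path(config.out_dir) / "dataset", config.simulate)
    return results
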