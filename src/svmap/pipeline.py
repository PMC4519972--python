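"""End-to-end pipeline: simulate -> call SVs -> design markers -> genotype ->
map -> anchor, with every stage's output written as a machine-readable file
and a final plain-text report.

The stages communicate only through their documented on-disk formats, so any
stage can be re-run standalone from the previous stage's files (the CLI
exposes each one).  All randomness flows from the single seed in the
simulation config.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as svio
from .anchor import (anchor_scaffolds, detect_conflicts, gene_content,
                     genome_stats, recombination_scan)
from .genotypes import filter_population
from .linkage import GeneticMap, LinkageGroup, build_map, summarize_map_table
from .markers import attrition_table, design_markers, markers_to_frame
from .simulate import (SimConfig, GenomePair, simulate_annotation,
                       simulate_meiosis, simulate_parental_genomes,
                       simulate_read_pairs)
from .svcall import call_svs, fit_insert_model, summarize_calls

__all__ = ["ConfigError", "DataError", "RunConfig", "load_config",
           "true_marker_map", "run_all"]


class ConfigError(ValueError):
    """Invalid or unknown configuration."""


class DataError(ValueError):
    """A pipeline stage received unusable data."""


_SECTION_DEFAULTS: dict[str, dict] = {
    "svcall": {"k": 3.0, "min_support": 6, "max_cluster_gap": 150},
    "markers": {"min_len": 200, "max_len": 800, "flank": 300, "tip": 20,
                "abs_min": 20, "rel_min": 0.05},
    "map": {"lod_threshold": 3.0, "max_rf": None},
    "anchor": {"hot_factor": 3.0, "cold_factor": 1 / 3},
    "annotation": {"n_genes": 200},
}


@dataclasses.dataclass
class RunConfig:
    """Union of all stage parameter blocks; unknown keys are rejected."""
    simulate: SimConfig
    svcall: dict
    markers: dict
    map: dict
    anchor: dict
    annotation: dict

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw or {})
        known = {"simulate", *_SECTION_DEFAULTS}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config sections: {sorted(unknown)}")
        sim_raw = dict(raw.get("simulate") or {})
        sim_fields = {f.name for f in dataclasses.fields(SimConfig)}
        bad = set(sim_raw) - sim_fields
        if bad:
            raise ConfigError(f"unknown simulate keys: {sorted(bad)}")
        if "sv_length_ranges" in sim_raw:
            sim_raw["sv_length_ranges"] = {
                k: tuple(v) for k, v in sim_raw["sv_length_ranges"].items()}
        if "complex_replacement_range" in sim_raw:
            sim_raw["complex_replacement_range"] = tuple(
                sim_raw["complex_replacement_range"])
        try:
            sim = SimConfig(**sim_raw)
            sim.validate()
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc
        sections = {}
        for name, defaults in _SECTION_DEFAULTS.items():
            block = dict(defaults)
            extra = dict(raw.get(name) or {})
            bad = set(extra) - set(defaults)
            if bad:
                raise ConfigError(f"unknown {name} keys: {sorted(bad)}")
            block.update(extra)
            sections[name] = block
        return cls(simulate=sim, **sections)

    def to_dict(self) -> dict:
        return {"simulate": self.simulate.to_dict(), "svcall": self.svcall,
                "markers": self.markers, "map": self.map,
                "anchor": self.anchor, "annotation": self.annotation}


def load_config(path) -> RunConfig:
    """Load and validate the single structured (YAML) run configuration."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    return RunConfig.from_dict(raw)


def true_marker_map(marker_table: pd.DataFrame, scaffolds: pd.DataFrame,
                    cm_per_mb: float) -> GeneticMap:
    """Place effective markers on the simulation's true genetic map.

    A marker's true cM position is its chromosome-level midpoint coordinate
    scaled by the genome-average recombination rate; each chromosome is one
    group with positions rebased to start at 0.
    """
    info = scaffolds.set_index("scaffold")
    eff = marker_table[marker_table["status"] == "effective"].copy()
    if not len(eff):
        return GeneticMap(groups=[])
    eff["chromosome"] = eff["scaffold"].map(info["chromosome"])
    mid = (eff["start"] + eff["end"]) // 2
    eff["chrom_bp"] = eff["scaffold"].map(info["chrom_offset"]) + mid
    eff["cm"] = eff["chrom_bp"] * cm_per_mb / 1e6
    groups = []
    for chrom, sub in eff.groupby("chromosome", sort=True):
        sub = sub.sort_values(["chrom_bp", "marker"])
        pos = sub["cm"].to_numpy(float)
        groups.append(LinkageGroup(f"chr{int(chrom)}", list(sub["marker"]),
                                   pos - pos[0]))
    return GeneticMap(groups=groups)


def _fmt_table(df: pd.DataFrame) -> str:
    return df.to_string(index=False)


def run_all(config: RunConfig, outdir) -> dict:
    """Run every stage, writing artifacts under ``outdir``.

    Returns a dict of the in-memory stage results.  Any stage failure is
    re-raised as :class:`DataError` tagged with the stage name.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"config": config}
    report: list[str] = []
    report.append("svmap run report")
    report.append("================")
    report.append(f"seed: {config.simulate.seed}")
    report.append("parameters:")
    report.append(json.dumps(config.to_dict(), indent=2, default=str))

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except (ConfigError,):
                raise
            except Exception as exc:
                raise DataError(f"stage '{name}' failed: {exc}") from exc
        return deco

    # 1. parental genomes -----------------------------------------------------
    @stage("simulate-genomes")
    def genomes() -> GenomePair:
        g = simulate_parental_genomes(config.simulate)
        svio.write_fasta(g.reference, out / "reference.fasta")
        svio.write_fasta(g.donor, out / "donor.fasta")
        svio.write_variants_tsv(g.variants, out / "true_variants.tsv")
        g.scaffolds.to_csv(out / "scaffolds.tsv", sep="\t", index=False)
        return g

    results["genomes"] = genomes
    report.append(f"\nscaffolds: {len(genomes.scaffolds)}, "
                  f"genome {genomes.scaffolds['length'].sum():,} bp, "
                  f"planted SVs: {len(genomes.variants)}, "
                  f"SNPs: {len(genomes.snps)}")

    # 2. read pairs -----------------------------------------------------------
    @stage("simulate-reads")
    def pairs() -> pd.DataFrame:
        p = simulate_read_pairs(genomes)
        svio.write_pairs_tsv(p, out / "pairs.tsv")
        return p

    results["pairs"] = pairs
    report.append(f"read pairs: {len(pairs):,} "
                  f"({config.simulate.coverage}x, "
                  f"insert {config.simulate.insert_mean:.0f} bp)")

    # 3. SV calling -----------------------------------------------------------
    @stage("call-sv")
    def calls():
        model = fit_insert_model(pairs, k=config.svcall["k"])
        cs = call_svs(pairs, model, min_support=config.svcall["min_support"],
                      max_cluster_gap=config.svcall["max_cluster_gap"])
        cs.to_frame().to_csv(out / "sv_calls.tsv", sep="\t", index=False)
        summarize_calls(cs).to_csv(out / "sv_summary.tsv", sep="\t", index=False)
        results["insert_model"] = model
        return cs

    results["calls"] = calls
    report.append(f"\nfitted insert model: mean {results['insert_model'].mean:.1f}, "
                  f"sd {results['insert_model'].sd:.1f}, "
                  f"k {results['insert_model'].k}")
    report.append("\nSV locus summary (per class):")
    report.append(_fmt_table(summarize_calls(calls)))
    report.append(f"scaffolds carrying >=1 SV locus: {calls.n_scaffolds}")

    # 4. marker design --------------------------------------------------------
    @stage("design-markers")
    def markers():
        ms = design_markers(calls, genomes.reference, genomes.donor,
                            min_len=config.markers["min_len"],
                            max_len=config.markers["max_len"],
                            flank=config.markers["flank"],
                            tip=config.markers["tip"],
                            abs_min=config.markers["abs_min"],
                            rel_min=config.markers["rel_min"])
        markers_to_frame(ms).to_csv(out / "markers.tsv", sep="\t", index=False)
        svio.write_flank_fasta(ms, genomes.reference, out / "marker_regions.fasta")
        return ms

    results["markers"] = markers
    marker_df = markers_to_frame(markers)
    n_effective = int((marker_df["status"] == "effective").sum())
    report.append("\nmarker attrition:")
    report.append(_fmt_table(attrition_table(markers)))

    if n_effective == 0:
        report.append("\nno effective markers; mapping stages skipped")
        (out / "report.txt").write_text("\n".join(report) + "\n")
        results["n_effective"] = 0
        return results
    results["n_effective"] = n_effective

    # 5. progeny genotypes ----------------------------------------------------
    @stage("simulate-progeny")
    def genotyped():
        tm = true_marker_map(marker_df, genomes.scaffolds,
                             config.simulate.cm_per_mb)
        gm, truth = simulate_meiosis(
            tm, config.simulate.n_progeny,
            heterokaryon_rate=config.simulate.heterokaryon_rate,
            missing_rate=config.simulate.missing_rate,
            seed=config.simulate.seed + 2)
        gm.to_tsv(out / "genotypes.tsv")
        truth.to_csv(out / "strain_truth.tsv", sep="\t", index=False)
        return tm, gm, truth

    true_map, genos, strain_truth = genotyped
    results["true_map"] = true_map
    results["genotypes"] = genos
    report.append(f"\nprogeny genotyped: {len(genos.strains)} strains x "
                  f"{len(genos.markers)} effective markers")

    # 6. homokaryon filter ----------------------------------------------------
    @stage("genotype-filter")
    def filtered():
        fm, info = filter_population(genos)
        fm.to_tsv(out / "genotypes_homokaryons.tsv")
        fm.to_mapmaker_raw(out / "genotypes.raw")
        return fm, info

    homo, filt_info = filtered
    results["population"] = homo
    report.append(f"homokaryon filter: {filt_info['n_homokaryons']} homokaryons "
                  f"kept, {filt_info['n_heterokaryons']} heterokaryons and "
                  f"{filt_info['n_undetermined']} undetermined excluded, "
                  f"{filt_info['n_coerced_h']} residual 'h' calls coerced to '-'")

    # 7. linkage map ----------------------------------------------------------
    @stage("map")
    def gmap():
        m = build_map(homo, lod_threshold=config.map["lod_threshold"],
                      max_rf=config.map["max_rf"])
        m.to_frame().to_csv(out / "map.tsv", sep="\t", index=False)
        return m

    results["map"] = gmap
    map_summary = gmap.summary()

    # 8. anchoring + statistics ----------------------------------------------
    @stage("anchor")
    def anchored():
        coords = marker_df[marker_df["status"] == "effective"].copy()
        coords["bp"] = (coords["start"] + coords["end"]) // 2
        coords = coords[["marker", "scaffold", "bp"]]
        mapped = set(gmap.to_frame()["marker"])
        coords = coords[coords["marker"].isin(mapped)]
        anchors, per_group = anchor_scaffolds(gmap, coords,
                                              genomes.scaffold_lengths())
        svio.write_anchors_tsv(anchors, out / "anchors.tsv")
        svio.write_agp(anchors, out / "superscaffolds.agp")
        conflicts = detect_conflicts(gmap, coords)
        conflicts.to_csv(out / "conflicts.tsv", sep="\t", index=False)
        scan = recombination_scan(gmap, coords,
                                  hot_factor=config.anchor["hot_factor"],
                                  cold_factor=config.anchor["cold_factor"])
        scan.to_csv(out / "recombination_scan.tsv", sep="\t", index=False)
        return coords, anchors, per_group, conflicts, scan

    coords, anchors, per_group, conflicts, scan = anchored
    results["anchors"] = anchors
    genome_size = int(genomes.scaffolds["length"].sum())
    stats = genome_stats(gmap, anchors, genome_size, len(genomes.scaffolds))
    results["stats"] = stats
    stats_df = pd.DataFrame([dataclasses.asdict(stats)])
    stats_df.to_csv(out / "genome_stats.tsv", sep="\t", index=False)

    # 9. gene content ---------------------------------------------------------
    @stage("gene-content")
    def genes():
        ann = simulate_annotation(genomes.scaffolds,
                                  n_genes=config.annotation["n_genes"],
                                  seed=config.simulate.seed + 3)
        svio.write_gff3_genes(ann, out / "genes.gff3")
        n_on, frac, per_scaffold = gene_content(
            anchors, ann, known_scaffolds=set(genomes.reference))
        return ann, n_on, frac

    annotation, genes_on, gene_frac = genes
    results["gene_content"] = (genes_on, gene_frac)

    # 10. report --------------------------------------------------------------
    summary = map_summary.merge(per_group, on="group", how="left")
    totals = summarize_map_table(summary)
    report.append("\nlinkage map (per group):")
    report.append(_fmt_table(summary))
    report.append(f"linkage groups: {len(gmap.groups)}; "
                  f"unlinked markers: {len(gmap.unlinked)}"
                  + (f" ({', '.join(gmap.unlinked)})" if gmap.unlinked else ""))
    report.append(f"total map length: {totals['total_cm']} cM over "
                  f"{totals['n_markers']} markers "
                  f"(mean spacing {totals['mean_spacing_cm']} cM)")
    report.append(f"\nanchoring: {stats.anchored_scaffolds} scaffolds "
                  f"({stats.anchored_kb:,.0f} kb, {stats.coverage_pct}% of the "
                  f"{genome_size / 1e6:.1f} Mb genome) on "
                  f"{len({a.group for a in anchors})} groups; "
                  f"1 cM ~= {stats.kb_per_cm} kb")
    report.append(f"scaffold count after super-scaffolding: "
                  f"{stats.original_scaffolds} -> {stats.reduced_scaffolds}")
    report.append(f"interleaving conflicts: {len(conflicts)}")
    n_hot = int((scan['label'] == 'hot').sum()) if len(scan) else 0
    n_cold = int((scan['label'] == 'cold').sum()) if len(scan) else 0
    report.append(f"recombination scan: {len(scan)} intervals, "
                  f"{n_hot} hot, {n_cold} cold")
    report.append(f"genes on anchored scaffolds: {genes_on} of "
                  f"{len(annotation)} ({100 * gene_frac:.1f}%)")
    (out / "report.txt").write_text("\n".join(report) + "\n")
    return results
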