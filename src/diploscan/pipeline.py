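"""End-to-end orchestration: simulate -> align -> call -> classify -> report.

A single RunConfig carries every numeric threshold used downstream, the
stage toggles and the seed; a run writes its outputs plus a manifest with
SHA-256 checksums, so reruns with an identical config are byte-identical
and every reported number is traceable to the thresholds that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .alignment import anchor_align, read_paf, write_paf
from .ase import (
    ase_fraction,
    ase_gene_set,
    cluster_ase_profiles,
    expression_matrix,
    select_informative_snps,
    sv_ase_enrichment,
    te_expression_association,
    test_ase,
    upstream_te_groups,
)
from .effects import classify_effects, find_pav_genes, impact_summary
from .models import DependencyError
from .simulate import (
    SimParams,
    generate_reference,
    plant_variants,
    simulate_allele_counts,
    write_fixture,
)
from .te import (
    classify_te_zygosity,
    compare_age_by_zygosity,
    density_to_bedgraph,
    detect_tsd_for_variant,
    ltr_insertion_age,
    merged_reference_intervals,
    window_density,
)
from .variants import extract_variants, feature_context, variant_density

ALL_STAGES = ("simulate", "align", "callvars", "te", "effects", "ase")


@dataclass
class RunConfig:
    out_dir: str = "diploscan_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # inputs (used when the simulate stage is disabled)
    phase0_fasta: str | None = None
    phase1_fasta: str | None = None
    paf: str | None = None
    genes_gff3: str | None = None
    tes_gff3: str | None = None
    counts_tsv: str | None = None
    # simulation parameters (passed through to SimParams; seed is shared)
    sim: dict = field(default_factory=dict)
    # thresholds
    sv_min_len: int = 40
    indel_snp_distance: int = 50
    upstream_window: int = 1000
    overlap_frac_deletion: float = 0.5
    overlap_frac_te: float = 0.8
    tsd_max: int = 20
    fdr: float = 0.05
    min_reads: int = 10
    window_density_bp: int = 100_000
    mu: float = 1.3e-8
    cluster_k: int = 4
    anchor_k: int = 21

    def validate(self) -> None:
        for name in ("sv_min_len", "indel_snp_distance", "upstream_window",
                     "tsd_max", "min_reads", "window_density_bp", "cluster_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if "simulate" not in self.stages and not (
            self.phase0_fasta and self.phase1_fasta
        ):
            raise ValueError("either enable the simulate stage or give input paths")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["stages"] = list(self.stages)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest."""
    config.validate()
    out = dio.ensure_dir(config.out_dir)
    rng = np.random.default_rng(config.seed)
    counters: dict[str, object] = {}
    written: list[Path] = []

    def save(name: str, writer) -> Path:
        path = out / name
        writer(path)
        written.append(path)
        return path

    genes = tes = None
    p0 = p1 = None
    counts = None
    truth = None

    if "simulate" in config.stages:
        params = SimParams(**{**config.sim, "seed": config.seed})
        reference = generate_reference(params, rng)
        pair, truth = plant_variants(reference, params, rng)
        counts = simulate_allele_counts(truth, params, rng)
        fix = write_fixture(out / "fixture", reference, pair, truth, counts)
        written.extend(fix.values())
        genes, tes = reference.genes, reference.tes
        p0, p1 = pair.phase0, pair.phase1
        counters["simulate"] = {
            "chromosomes": len(p0),
            "genes": len(genes),
            "te_copies": len(tes),
            "planted_variants": len(truth.planted_variants),
            "het_te": truth.het_te_count(),
        }
    else:
        p0 = dio.read_fasta(config.phase0_fasta)
        p1 = dio.read_fasta(config.phase1_fasta)
        genes = dio.read_genes_gff3(config.genes_gff3) if config.genes_gff3 else []
        tes = dio.read_tes_gff3(config.tes_gff3) if config.tes_gff3 else []
        counts = (dio.read_counts_tsv(config.counts_tsv)
                  if config.counts_tsv else None)

    blocks = None
    if "align" in config.stages:
        if config.paf:
            blocks = read_paf(config.paf)
        else:
            blocks = []
            for chrom in sorted(p0):
                if chrom not in p1:
                    raise DependencyError(f"chromosome {chrom} missing from phase-1")
                blocks.extend(
                    anchor_align(p0[chrom], p1[chrom], k=config.anchor_k,
                                 ref_name=chrom, query_name=chrom)
                )
            save("alignment.paf",
                 lambda path: write_paf(blocks, path,
                                        {c: len(s) for c, s in p0.items()}))
        counters["align"] = {"blocks": len(blocks)}

    variants = None
    if "callvars" in config.stages:
        if blocks is None:
            raise DependencyError("callvars requires the align stage (or a PAF)")
        te_mask = {}
        for t in tes or []:
            te_mask.setdefault(t.chrom, []).append((t.start, t.end))
        variants = extract_variants(blocks, p0, p1, sv_min=config.sv_min_len,
                                    te_mask=te_mask)
        save("variants.vcf", lambda path: dio.write_vcf(variants, p0, path))
        aligned = merged_reference_intervals(blocks)
        span = sum(e - s for ivs in aligned.values() for s, e in ivs)
        density = variant_density(variants, span)
        save("variant_density.tsv", lambda path: pd.DataFrame(
            [{"var_class": c, "count": density.counts[c],
              "bp_per_variant": density.bp_per_variant.get(c)}
             for c in sorted(density.counts)]
        ).to_csv(path, sep="\t", index=False))
        if genes:
            ctx = feature_context(variants, genes, flank=config.upstream_window)
            save("feature_context.tsv",
                 lambda path: ctx.to_csv(path, sep="\t", index=False))
        chrom_lengths = {c: len(s) for c, s in p0.items()}
        sv_feats = [(v.chrom, v.pos, max(v.end, v.pos + 1))
                    for v in variants if v.var_class == "SV"]
        track = density_to_bedgraph(
            window_density(sv_feats, chrom_lengths, config.window_density_bp),
            chrom_lengths, config.window_density_bp)
        save("sv_density.bedgraph", lambda path: dio.write_bedgraph(track, path))
        counters["callvars"] = {
            "span_bp": span,
            **{f"n_{c.lower()}": n for c, n in sorted(density.counts.items())},
            "bp_per_variant": density.bp_per_variant,
        }

    zygosity = None
    if "te" in config.stages:
        if variants is None or blocks is None:
            raise DependencyError("te stage requires callvars")
        deletions = [v for v in variants
                     if v.var_class == "SV" and v.is_deletion()]
        zygosity = classify_te_zygosity(
            tes or [], deletions, blocks,
            min_frac_of_deletion=config.overlap_frac_deletion,
            min_frac_of_te=config.overlap_frac_te)
        save("te_zygosity.tsv", lambda path: pd.DataFrame(
            [dataclasses.asdict(z) for z in zygosity]
        ).to_csv(path, sep="\t", index=False))

        tsd_rows = []
        for v in variants:
            if v.var_class == "SV" and v.is_insertion() and v.alt_allele:
                res = detect_tsd_for_variant(v, p0, max_len=config.tsd_max)
                tsd_rows.append(dataclasses.asdict(res))
        save("tsd.tsv", lambda path: pd.DataFrame(tsd_rows)
             .to_csv(path, sep="\t", index=False))

        label_by_te = {z.te_id: z.label for z in zygosity}
        ages = []
        for t in tes or []:
            if t.order == "LTR" and t.intact and t.ltr5 and t.ltr3:
                seq = p0[t.chrom]
                est = ltr_insertion_age(seq[t.ltr5[0]:t.ltr5[1]],
                                        seq[t.ltr3[0]:t.ltr3[1]],
                                        mu=config.mu, te_id=t.id)
                ages.append({"te_id": t.id, "divergence": est.divergence,
                             "age_years": est.age_years,
                             "label": label_by_te.get(t.id, "")})
        ages_df = pd.DataFrame(ages)
        save("ltr_ages.tsv",
             lambda path: ages_df.to_csv(path, sep="\t", index=False))
        te_counter = {
            "labels": pd.Series([z.label for z in zygosity]).value_counts().to_dict(),
            "tsd_found": sum(1 for r in tsd_rows if r["found"]),
            "tsd_modal_length": (
                int(pd.Series([r["tsd_length"] for r in tsd_rows if r["found"]])
                    .mode().iloc[0]) if any(r["found"] for r in tsd_rows) else None
            ),
        }
        if not ages_df.empty:
            het = ages_df.loc[ages_df.label == "heterozygous", "age_years"].tolist()
            hom = ages_df.loc[ages_df.label == "homozygous", "age_years"].tolist()
            if het and hom:
                mh, mo, pv = compare_age_by_zygosity(het, hom)
                te_counter["age_mean_het"] = mh
                te_counter["age_mean_hom"] = mo
                te_counter["age_wilcoxon_p"] = pv
        counters["te"] = te_counter

    if "effects" in config.stages:
        if variants is None:
            raise DependencyError("effects stage requires callvars")
        if not genes:
            raise DependencyError("effects stage requires gene models")
        small = [v for v in variants if v.var_class in ("SNP", "INDEL")]
        calls = classify_effects(small, genes, p0, flank=config.upstream_window)
        save("effects.tsv", lambda path: pd.DataFrame(
            [dataclasses.asdict(c) for c in calls]
        ).to_csv(path, sep="\t", index=False))
        summary, n_high = impact_summary(calls)
        save("impact_summary.tsv",
             lambda path: summary.to_csv(path, sep="\t", index=False))
        pav = find_pav_genes(genes, [v for v in variants
                                     if v.var_class == "SV" and v.is_deletion()])
        save("pav_genes.txt",
             lambda path: Path(path).write_text("".join(g + "\n" for g in pav)))
        counters["effects"] = {"calls": len(calls), "genes_with_high": n_high,
                               "pav_genes": len(pav)}

    if "ase" in config.stages:
        if counts is None:
            raise DependencyError("ase stage requires an allele-count table")
        results = test_ase(counts, fdr=config.fdr)
        save("ase_results.tsv",
             lambda path: results.to_csv(path, sep="\t", index=False))
        tested = set(results.loc[results.testable, "gene"])
        ase_set = ase_gene_set(results)
        ase_counter = {
            "genes_tested": len(tested),
            "genes_ase": len(ase_set),
            "ase_percent": ase_fraction(len(ase_set), len(tested)) if tested else None,
        }
        if variants is not None and genes:
            informative = select_informative_snps(
                [v for v in variants if v.var_class == "SNP"],
                [v for v in variants if v.var_class == "INDEL"],
                genes, min_indel_distance=config.indel_snp_distance)
            ase_counter["informative_snps"] = len(informative)
            het_svs = [v for v in variants if v.var_class == "SV"]
            enr = sv_ase_enrichment(ase_set, tested, het_svs, genes,
                                    window_bp=config.upstream_window)
            save("sv_ase_enrichment.json", lambda path: Path(path).write_text(
                json.dumps(dataclasses.asdict(enr), indent=1, sort_keys=True)))
            ase_counter["sv_enrichment_p"] = enr.p_value
        if zygosity is not None and genes:
            groups = upstream_te_groups(genes, tes or [],
                                        {z.te_id: z.label for z in zygosity},
                                        window_bp=config.upstream_window)
            assoc = te_expression_association(expression_matrix(counts), groups)
            save("te_expression_association.tsv",
                 lambda path: assoc.to_csv(path, sep="\t", index=False))
        try:
            clusters = cluster_ase_profiles(results, counts,
                                            min_reads=config.min_reads,
                                            k=config.cluster_k)
            save("ase_clusters.tsv",
                 lambda path: clusters.to_csv(path, sep="\t", index=False))
            ase_counter["clustered_genes"] = len(clusters)
        except ValueError as exc:
            ase_counter["clustered_genes"] = 0
            ase_counter["cluster_note"] = str(exc)
        counters["ase"] = ase_counter

    manifest = {
        "config": {**dataclasses.asdict(config), "stages": list(config.stages)},
        "counters": counters,
        "files": {str(p.relative_to(out)): _sha256(p) for p in sorted(written)},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=float)
    return manifest
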