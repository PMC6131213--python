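"""End-to-end orchestration: run every analysis stage on one input set
(by default a freshly simulated genome) and write the summary bundle.

The bundle mirrors the summary tables of a genome-landscape study: assembly
statistics, telomere calls, centromeric repeat arrays, centromere calls and
size summary, tandem arrays and an old-vs-new assembly comparison, synteny
blocks with a depth profile, and expression gene sets. Outputs are plain
TSV/JSON and byte-stable under a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import assembly, centromere, expression, repeats, simulate, synteny, tandem
from .core import Interval

log = logging.getLogger("chromoscape")

_KNOWN_KEYS = {
    "seed", "n_chromosomes", "chrom_length", "telomere_motif", "telomere_copies",
    "centromere_monomer_length", "monomer_divergence", "ltr_field_density",
    "n_genes_per_chrom", "min_copies", "min_identity", "ltr_threshold",
    "depression_threshold", "e_value_max", "max_gene_distance", "min_anchors",
    "max_rank_gap", "n_tissues", "specific_fraction", "library_size", "bin_size",
    "collapse_fraction", "collapse_keep", "inversion_count", "substitution_rate",
}

_FLOAT_KEYS = {
    "monomer_divergence", "ltr_field_density", "min_identity", "ltr_threshold",
    "depression_threshold", "e_value_max", "specific_fraction", "collapse_fraction",
    "substitution_rate",
}


@dataclass
class RunConfig:
    """Effective parameters of a report run; unknown config keys are rejected."""

    seed: int = 0
    bin_size: int = 25_000
    min_copies: int = 5
    min_identity: float = 70.0
    ltr_threshold: float = 0.85
    depression_threshold: float = 0.6
    e_value_max: float = 1e-5
    max_gene_distance: int = 10
    min_anchors: int = 5
    max_rank_gap: int = 25
    n_tissues: int = 10
    specific_fraction: float = 0.1
    library_size: int = 20_000_000
    collapse_fraction: float = 0.5
    collapse_keep: int = 4
    inversion_count: int = 2
    substitution_rate: float = 0.1
    sim_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, raw: dict[str, str]) -> "RunConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict = {}
        sim: dict = {}
        sim_fields = {"n_chromosomes", "chrom_length", "telomere_motif", "telomere_copies",
                      "centromere_monomer_length", "monomer_divergence", "ltr_field_density",
                      "n_genes_per_chrom"}
        for key, value in raw.items():
            if key == "telomere_motif":
                sim[key] = value
                continue
            parsed = float(value) if key in _FLOAT_KEYS else int(float(value))
            if key in sim_fields:
                sim[key] = parsed
            else:
                kwargs[key] = parsed
        cfg = cls(**kwargs)
        cfg.sim_overrides = sim
        return cfg


def _iv(iv: Interval) -> list[int]:
    return [iv.start, iv.end]


def run_report(config: RunConfig, out_dir: str | Path, include_hic: bool = True) -> dict:
    """Simulate the preset genome and run all seven analysis sections."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("effective config: %s", asdict(config))
    sim_cfg = simulate.raspberry_like_config(seed=config.seed, **config.sim_overrides)
    genome, ann, truth = simulate.generate_genome(sim_cfg)

    report: dict = {}

    # 1. assembly summary
    summ = assembly.assembly_summary(genome)
    report["assembly"] = {
        "total_size": summ.total_size,
        "n_sequences": summ.n_sequences,
        "n50": summ.nX_values[50],
        "gap_count": summ.gap_count,
        "gap_bases": summ.gap_bases,
    }

    # 2. telomeres
    telomeres = assembly.detect_telomeres(genome, motif=sim_cfg.telomere_motif)
    report["telomeres"] = {
        "n_tracks": len(telomeres),
        "calls": [
            {"chrom": t.chrom, "end": t.end_label, "interval": _iv(t.interval), "copies": t.copy_number}
            for t in telomeres
        ],
    }

    # 3. centromeric repeat arrays (monomer rediscovered from sequence)
    monomer = _discover_monomer(genome, sim_cfg)
    arrays = repeats.scan_repeat_arrays(
        genome, monomer, min_copies=config.min_copies, min_identity=config.min_identity
    )
    report["repeat_arrays"] = {
        "monomer_length": len(monomer),
        "arrays": [
            {"chrom": a.chrom, "interval": _iv(a.interval), "copies": a.copy_number,
             "mean_identity": round(a.mean_identity, 2)}
            for a in arrays
        ],
    }

    # 4. centromere calls
    ltr_tracks = {
        chrom: repeats.windowed_density(
            [iv for c, iv in ann.ltr_intervals if c == chrom], L, chrom=chrom
        )
        for chrom, L in genome.lengths.items()
    }
    depression: dict[str, object] = {}
    if include_hic:
        contacts = simulate.generate_contact_matrix(
            truth, bin_size=config.bin_size, noise_dispersion=0.1, seed=config.seed + 1
        )
        depression = {c: centromere.contact_depression_track(m) for c, m in contacts.items()}
    else:
        log.warning("Hi-C input missing: centromere calls made without hic_depression evidence")
    calls = [
        centromere.call_centromere(
            chrom,
            arrays,
            ltr_tracks[chrom],
            depression.get(chrom),
            config.bin_size if include_hic else None,
            ltr_threshold=config.ltr_threshold,
            depression_threshold=config.depression_threshold,
            chrom_length=genome.lengths[chrom],
        )
        for chrom in genome.names
    ]
    report["centromeres"] = {
        "calls": [
            {"chrom": c.chrom, "status": c.status,
             "interval": _iv(c.interval) if c.interval else None,
             "evidence": sorted(c.evidence)}
            for c in calls
        ],
        "summary": centromere.centromere_summary(calls),
    }

    # 5. tandem arrays, new vs degraded-old comparison
    seqs = tandem.extract_gene_sequences(genome, ann)
    hits_new = tandem.all_vs_all_hits(ann.genes, seqs, same_chrom_only=True,
                                      e_value_max=config.e_value_max)
    arrays_new = tandem.call_tandem_arrays(ann, hits_new, config.e_value_max, config.max_gene_distance)
    old_genome, old_ann, old_truth = simulate.degrade_assembly(
        genome, ann, truth,
        collapse_fraction=config.collapse_fraction,
        collapse_keep=config.collapse_keep,
        inversion_count=0,
        seed=config.seed + 2,
    )
    old_seqs = tandem.extract_gene_sequences(old_genome, old_ann)
    hits_old = tandem.all_vs_all_hits(old_ann.genes, old_seqs, same_chrom_only=True,
                                      e_value_max=config.e_value_max)
    arrays_old = tandem.call_tandem_arrays(old_ann, hits_old, config.e_value_max, config.max_gene_distance)
    gene_map = {g.id: g.id for g in old_ann.genes}  # degraded assembly keeps gene ids
    comparison = tandem.compare_assemblies(arrays_old, arrays_new, gene_map)
    report["tandem"] = {
        "n_arrays": len(arrays_new),
        "sizes": sorted((a.size for a in arrays_new), reverse=True),
        "n_arrays_old": len(arrays_old),
        "comparison": {
            "matched": comparison.matched,
            "novel_new_arrays": comparison.novel_new_arrays,
            "shared_genes": comparison.shared_genes,
            "old_only_genes": comparison.old_only_genes,
            "new_only_genes": comparison.new_only_genes,
        },
        "collapsed_truth": old_truth.collapsed_arrays,
    }

    # 6. synteny against a simulated diverged relative
    ort_genome, ort_ann, ort_truth = simulate.generate_ortholog_genome(
        genome, ann, truth,
        substitution_rate=config.substitution_rate,
        inversion_count=config.inversion_count,
        seed=config.seed + 3,
    )
    ort_seqs = tandem.extract_gene_sequences(ort_genome, ort_ann)
    cross = tandem.cross_genome_hits(ann.genes, seqs, ort_ann.genes, ort_seqs,
                                     e_value_max=config.e_value_max)
    anchors = synteny.anchor_pairs(ann, ort_ann, cross, config.e_value_max, top_k=1)
    blocks = synteny.chain_blocks(anchors, ann, ort_ann, config.min_anchors, config.max_rank_gap)
    depth = synteny.syntenic_depth(blocks)
    hits_ort = tandem.all_vs_all_hits(ort_ann.genes, ort_seqs, same_chrom_only=True,
                                      e_value_max=config.e_value_max)
    arrays_ort = tandem.call_tandem_arrays(ort_ann, hits_ort, config.e_value_max, config.max_gene_distance)
    classification = synteny.classify_syntenic_arrays(arrays_new, arrays_ort, blocks)
    dot = synteny.dotplot_table(blocks, ann, ort_ann)
    report["synteny"] = {
        "n_anchors": len(anchors),
        "n_blocks": len(blocks),
        "n_inverted_blocks": sum(1 for b in blocks if b.orientation == "inverted"),
        "fraction_1to1": depth.fraction_1to1,
        "fraction_1to1_bases": depth.fraction_1to1_bases,
        "arrays_conserved": classification.n_conserved,
        "arrays_unique": classification.n_unique,
    }

    # 7. expression atlas
    counts, lengths = simulate.generate_expression_counts(
        ann,
        n_tissues=config.n_tissues,
        specific_fraction=config.specific_fraction,
        library_size=config.library_size,
        seed=config.seed + 4,
        truth=truth,
    )
    mat = expression.fpkm(counts, lengths, pd.Series(config.library_size, index=counts.columns))
    detectable = expression.detectable_genes(mat)
    specific = expression.tissue_specific_genes(mat)
    report["expression"] = {
        "n_genes": int(mat.shape[0]),
        "n_detectable": len(detectable),
        "n_tissue_specific": len(specific),
        "planted_specific": len(truth.specific_genes),
    }

    _write_bundle(out, report, telomeres, arrays, calls, arrays_new, comparison, blocks, dot, mat)
    return report


def _discover_monomer(genome, sim_cfg) -> str:
    """Rediscover the satellite monomer from the middle of each chromosome;
    keep the consensus with the strongest period support."""
    best: tuple[int, str] | None = None
    for chrom, seq in genome.sequences.items():
        mid = seq[int(len(seq) * 0.35) : int(len(seq) * 0.65)]
        found = repeats.find_tandem_monomer(mid, min_period=100, max_period=1_000)
        for consensus, _period, support in found[:1]:
            if best is None or support > best[0]:
                best = (support, consensus)
    if best is None:
        raise RuntimeError("no tandem periodicity found in any chromosome")
    return best[1]


def _write_bundle(out, report, telomeres, arrays, calls, arrays_new, comparison, blocks, dot, fpkm_mat):
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    pd.DataFrame(
        [{"chrom": t.chrom, "end": t.end_label, "start": t.interval.start,
          "end_pos": t.interval.end, "copies": t.copy_number} for t in telomeres]
    ).to_csv(out / "telomeres.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"chrom": a.chrom, "start": a.interval.start, "end": a.interval.end,
          "monomer_length": a.monomer_length, "copies": a.copy_number,
          "mean_identity": round(a.mean_identity, 2)} for a in arrays]
    ).to_csv(out / "repeat_arrays.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"chrom": c.chrom, "status": c.status,
          "start": c.interval.start if c.interval else "",
          "end": c.interval.end if c.interval else "",
          "evidence": ",".join(sorted(c.evidence))} for c in calls]
    ).to_csv(out / "centromeres.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"chrom": a.chrom, "size": a.size, "members": ",".join(a.members)} for a in arrays_new]
    ).to_csv(out / "tandem_arrays.tsv", sep="\t", index=False)
    pd.DataFrame(comparison.matched).to_csv(out / "tandem_comparison.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"chrom_a": b.chrom_a, "start_a": b.span_a.start, "end_a": b.span_a.end,
          "chrom_b": b.chrom_b, "start_b": b.span_b.start, "end_b": b.span_b.end,
          "orientation": b.orientation, "n_anchors": len(b.anchors)} for b in blocks]
    ).to_csv(out / "synteny_blocks.tsv", sep="\t", index=False)
    dot.to_csv(out / "dotplot.tsv", sep="\t", index=False)
    fpkm_mat.round(4).to_csv(out / "fpkm.tsv", sep="\t")
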