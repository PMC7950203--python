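"""End-to-end orchestration: simulate -> digest -> quantify -> compare ->
mine-ncr -> ncr-tree -> report, with a reproducible output manifest.

Also hosts the validation routine that recomputes the published summary
arithmetic (replicon percentages, host-specific totals, iTRAQ classification
counts, symbiotic percent reductions) from the reference tables shipped with
the package.
"""

from __future__ import annotations

import hashlib
import io as _stdio
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from rhizoquant import digestion, host_specificity, ncr_mining, phylo, quantify
from rhizoquant.io import (
    AnalysisConfig,
    PSMTable,
    format_percent,
    logger,
    write_fasta,
    write_proteome,
    write_psm_table,
    write_report,
)
from rhizoquant.synthetic_data import GeneratorSpec, generate_itraq, generate_ncr_corpus, generate_proteome, generate_psm_tables, preset


@dataclass(frozen=True)
class PipelineRun:
    config: AnalysisConfig
    stages: tuple[str, ...]
    manifest: dict[str, str]  # relative file path -> sha256


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def simulate_inputs(spec: GeneratorSpec, out_dir: Path) -> list[Path]:
    """Materialise one synthetic study (both hosts' inputs plus truth tables)."""
    out_dir.mkdir(parents=True, exist_ok=True)
    proteome, proteome_truth = generate_proteome(spec)
    table_a, table_b, psm_truth = generate_psm_tables(proteome, spec)
    ratios, itraq_truth = generate_itraq(proteome, spec)
    corpus = generate_ncr_corpus(spec)

    write_proteome(proteome, out_dir / "proteome.fasta")
    write_psm_table(table_a, out_dir / "psm_pea.tsv")
    write_psm_table(table_b, out_dir / "psm_lentil.tsv")
    pd.DataFrame(
        {"protein_id": list(ratios), "itraq_pl_ratio": list(ratios.values())}
    ).to_csv(out_dir / "itraq.tsv", sep="\t", index=False, lineterminator="\n")
    write_fasta(corpus.reference_alignment, out_dir / "ncr_reference_alignment.fasta")
    write_fasta(corpus.precursors, out_dir / "ncr_precursors.fasta")
    corpus.cleavage_table.to_csv(
        out_dir / "ncr_cleavage.tsv", sep="\t", index=False, lineterminator="\n"
    )
    write_fasta(corpus.contigs, out_dir / "contigs.fasta")
    (out_dir / "denovo_peptides.txt").write_text(
        "\n".join(corpus.denovo_peptides) + "\n"
    )
    truth_dir = out_dir / "truth"
    write_report(
        {
            "truth_proteome": proteome_truth,
            "truth_psm": psm_truth,
            "truth_itraq": itraq_truth,
            "truth_ncr": corpus.truth,
        },
        truth_dir,
    )
    return sorted(p for p in out_dir.rglob("*") if p.is_file())


def run_pipeline(
    config: AnalysisConfig, input_dir: Path, out_dir: Path
) -> PipelineRun:
    """Run every analysis stage over a directory of pipeline inputs.

    Expects the file layout written by :func:`simulate_inputs`. Writes all
    stage outputs under ``out_dir`` and returns the manifest of checksums.
    """
    from rhizoquant.io import read_fasta_sequences, read_proteome, read_psm_table

    input_dir, out_dir = Path(input_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []

    logger.info("stage io: reading inputs from %s", input_dir)
    proteome = read_proteome(input_dir / "proteome.fasta")
    table_a = read_psm_table(input_dir / "psm_pea.tsv", "pea")
    table_b = read_psm_table(input_dir / "psm_lentil.tsv", "lentil")
    itraq_df = pd.read_csv(input_dir / "itraq.tsv", sep="\t")
    stages.append("io")

    logger.info("stage digest: %d proteins", len(proteome))
    opts = digestion.DigestOptions(
        max_missed_cleavages=config.max_missed_cleavages,
        apply_proline_rule=config.apply_proline_rule,
        min_length=config.min_peptide_length,
    )
    denominators = digestion.digest_proteome(proteome, opts)
    stages.append("digest")

    logger.info("stage quantify")
    quant_a = quantify.aggregate_replicates(table_a, denominators)
    quant_b = quantify.aggregate_replicates(table_b, denominators)
    summary_a = quantify.replicon_summary((r.id for r in quant_a), proteome)
    summary_b = quantify.replicon_summary((r.id for r in quant_b), proteome)
    stages.append("quantify")

    logger.info("stage compare")
    calls_a, calls_b = host_specificity.call_host_specific(
        table_a, table_b, config.min_accumulated_spectra
    )
    itraq_records = host_specificity.classify_itraq_table(
        dict(zip(itraq_df["protein_id"], itraq_df["itraq_pl_ratio"])),
        config.itraq_threshold,
    )
    reconciled = host_specificity.reconcile_calls(calls_a + calls_b, itraq_records)
    stages.append("compare")

    logger.info("stage mine-ncr")
    reference = read_fasta_sequences(input_dir / "ncr_reference_alignment.fasta")
    tags = ncr_mining.build_tag_set(reference, config.min_tag_conservation)
    peptides = [
        line.strip()
        for line in (input_dir / "denovo_peptides.txt").read_text().splitlines()
        if line.strip()
    ]
    tag_hits = ncr_mining.tag_search(peptides, tags)
    contigs = read_fasta_sequences(input_dir / "contigs.fasta")
    orfs = ncr_mining.translate_contigs(contigs, config.min_orf_length)
    candidates = ncr_mining.match_candidates(
        tag_hits, orfs, config.min_identity, config.min_coverage
    )
    cleavage = pd.read_csv(input_dir / "ncr_cleavage.tsv", sep="\t")
    cleavage_by_id = dict(zip(cleavage["ncr_id"], cleavage["cleavage_position"]))
    precursors = read_fasta_sequences(input_dir / "ncr_precursors.fasta")
    ncr_peptides = [
        ncr_mining.NCRPeptide(name, seq, int(cleavage_by_id[name]))
        for name, seq in precursors
        if name in cleavage_by_id
    ]
    distribution = ncr_mining.charge_distribution(ncr_peptides) if ncr_peptides else {}
    write_fasta(
        [(p.id, p.mature) for p in ncr_peptides], out_dir / "ncr_mature.fasta"
    )
    stages.append("mine-ncr")

    logger.info("stage ncr-tree")
    newick = ""
    matures = [(p.id, p.mature) for p in ncr_peptides]
    same_length = len({len(m) for _, m in matures}) == 1
    if len(matures) >= 3 and same_length:
        tree = phylo.neighbor_joining(phylo.p_distance(matures))
        newick = phylo.write_newick(tree)
    elif len(matures) >= 3:
        # unaligned mature peptides: pad to equal length so the p-distance
        # stage has a defined input; a real run would supply an alignment
        width = max(len(m) for _, m in matures)
        padded = [(n, m.ljust(width, "-")) for n, m in matures]
        tree = phylo.neighbor_joining(phylo.p_distance(padded))
        newick = phylo.write_newick(tree)
    (out_dir / "ncr_tree.nwk").write_text(newick + "\n")
    stages.append("ncr-tree")

    logger.info("stage report")
    tables = {
        "replicon_summary_pea": summary_a.to_frame(),
        "replicon_summary_lentil": summary_b.to_frame(),
        "quant_pea": quantify.quant_frame(quant_a),
        "quant_lentil": quantify.quant_frame(quant_b),
        "host_specific": pd.DataFrame(
            [
                {"protein_id": c.id, "host": c.host, "accumulated_psm": c.accumulated_psm_in_host}
                for c in calls_a + calls_b
            ],
            columns=["protein_id", "host", "accumulated_psm"],
        ),
        "itraq_classified": pd.DataFrame(
            [{"protein_id": r.id, "ratio": r.ratio, "label": r.label} for r in itraq_records],
            columns=["protein_id", "ratio", "label"],
        ),
        "reconciled": reconciled,
        "ncr_candidates": pd.DataFrame(
            [
                {
                    "peptide": c.peptide,
                    "contig_id": c.contig_id,
                    "frame": c.frame,
                    "identity": round(c.identity, 1),
                    "coverage": round(c.coverage, 1),
                }
                for c in candidates
            ],
            columns=["peptide", "contig_id", "frame", "identity", "coverage"],
        ),
        "ncr_charge_classes": pd.DataFrame(
            [
                {"ncr_id": p.id, "pi": round(p.pi, 2), "charge_class": p.charge_class}
                for p in ncr_peptides
            ],
            columns=["ncr_id", "pi", "charge_class"],
        ),
        "ncr_charge_distribution": pd.DataFrame(
            [{"charge_class": k, "percent": v} for k, v in distribution.items()],
            columns=["charge_class", "percent"],
        ),
    }
    write_report(tables, out_dir)
    stages.append("report")

    manifest = {
        str(p.relative_to(out_dir)): _checksum(p)
        for p in sorted(out_dir.rglob("*"))
        if p.is_file()
    }
    return PipelineRun(config=config, stages=tuple(stages), manifest=manifest)


# ---------------------------------------------------------------------------
# validation against the shipped reference tables


def _read_packaged_tsv(name: str) -> pd.DataFrame:
    with resources.files("rhizoquant.data").joinpath(name).open() as fh:
        return pd.read_csv(_stdio.StringIO(fh.read()), sep="\t", comment="#")


def load_reference_replicon_table() -> pd.DataFrame:
    return _read_packaged_tsv("reference_replicon_table.tsv")


def load_reference_itraq_table() -> pd.DataFrame:
    return _read_packaged_tsv("reference_itraq_table.tsv")


def load_reference_plant_assay_table() -> pd.DataFrame:
    return _read_packaged_tsv("reference_plant_assay_table.tsv")


def validate_reference_arithmetic(itraq_threshold: float = 2.0) -> pd.DataFrame:
    """Recompute the published summary arithmetic from the shipped tables.

    Returns a check report with one row per check (name, expected, computed,
    pass). Covers: replicon percentages recomputed from printed counts,
    host-specific per-replicon sums, iTRAQ classification counts at the
    inclusive threshold, and the wild-type-versus-mutant percent reductions.
    """
    rows = []
    rep = load_reference_replicon_table()
    body = rep[rep["replicon"] != "Total"]
    genome_denominator = int(rep.loc[rep["replicon"] == "Total", "genome_count"].iloc[0])
    for column, denom in (
        ("genome", genome_denominator),
        ("vegetative", int(body["vegetative_count"].sum())),
        ("pea", int(body["pea_count"].sum())),
        ("lentil", int(body["lentil_count"].sum())),
    ):
        counts = dict(zip(body["replicon"], body[f"{column}_count"].astype(int)))
        summary = quantify.RepliconSummary.from_counts(counts, denom)
        for replicon in counts:
            expected = f'{rep.loc[rep["replicon"] == replicon, f"{column}_pct"].iloc[0]:.1f}'
            computed = summary.formatted_percentages[replicon]
            rows.append(
                {
                    "check": f"{column}:{replicon}",
                    "expected": expected,
                    "computed": computed,
                    "pass": computed == expected,
                }
            )
    for host, expected_total in (("pea", 28), ("lentil", 25)):
        total = int(body[f"{host}_host_specific"].sum())
        rows.append(
            {
                "check": f"host_specific_total:{host}",
                "expected": str(expected_total),
                "computed": str(total),
                "pass": total == expected_total,
            }
        )
    itraq = load_reference_itraq_table()
    labels = [
        host_specificity.classify_itraq(r, itraq_threshold)
        for r in itraq["itraq_pl_ratio"]
    ]
    for label, expected_count in (("pea_over", 28), ("lentil_over", 8)):
        count = labels.count(label)
        rows.append(
            {
                "check": f"itraq_count:{label}",
                "expected": str(expected_count),
                "computed": str(count),
                "pass": count == expected_count,
            }
        )
    assay = load_reference_plant_assay_table().set_index("strain")
    for measure, expected_pct in (("pea_n_fixed", 28), ("pea_shoot_dry_weight", 28)):
        reduction = quantify.percent_reduction(
            float(assay.loc["UPM791", measure]), float(assay.loc["UPM1418", measure])
        )
        rows.append(
            {
                "check": f"percent_reduction:{measure}",
                "expected": str(expected_pct),
                "computed": str(reduction),
                "pass": reduction == expected_pct,
            }
        )
    return pd.DataFrame(rows, columns=["check", "expected", "computed", "pass"])
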