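"""End-to-end orchestration: QC -> trim -> concatenate -> stats -> tree ->
composite -> saturation -> concordance -> jackknife.

Every run is deterministic given the inputs and the seed, and writes a
machine-readable manifest listing each output file with a SHA-256 digest, so
re-running over existing outputs with an identical configuration changes
nothing.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import dendropy

from . import composite as composite_mod
from . import concordance as concordance_mod
from . import qc as qc_mod
from . import saturation as saturation_mod
from . import seqio
from . import sensitivity as sensitivity_mod
from . import supermatrix as supermatrix_mod
from . import treekit
from .errors import PhylomosaicError
from .supermatrix import Alignment

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Settings for one full analysis run."""

    marker_fastas: list[Path]
    out_dir: Path
    taxonomy_path: Optional[Path] = None
    reference_tree_path: Optional[Path] = None
    gene_tree_paths: dict[str, Path] = field(default_factory=dict)
    gap_threshold: float = 0.5
    qc_threshold: float = qc_mod.DEFAULT_NEAR_IDENTICAL_THRESHOLD
    build_composite: bool = True
    scf_quartets: int = 100
    seed: int = 0

    def validate(self) -> None:
        paths = list(self.marker_fastas) + list(self.gene_tree_paths.values())
        if self.taxonomy_path:
            paths.append(self.taxonomy_path)
        if self.reference_tree_path:
            paths.append(self.reference_tree_path)
        missing = [str(p) for p in paths if not Path(p).exists()]
        if missing:
            raise PhylomosaicError(f"input paths do not exist: {missing}")
        if not self.marker_fastas:
            raise PhylomosaicError("no marker FASTAs given")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str, t0: float) -> float:
    t1 = time.monotonic()
    logger.info("stage %-12s %.2fs", name, t1 - t0)
    return t1


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written to
    ``<out_dir>/manifest.json``)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    t0 = time.monotonic()

    markers = [seqio.read_fasta(p) for p in config.marker_fastas]
    taxonomy = (
        seqio.read_taxonomy(config.taxonomy_path) if config.taxonomy_path else None
    )
    gene_trees: dict[str, dendropy.Tree] = {
        m: seqio.read_newick_file(p) for m, p in config.gene_tree_paths.items()
    }
    t0 = _stage("read", t0)

    # QC screens (report-only)
    flags = []
    if taxonomy is not None:
        for aln in markers:
            flags.extend(
                qc_mod.flag_near_identical_cross_group(
                    aln, taxonomy, config.qc_threshold
                )
            )
        for name, gt in gene_trees.items():
            flags.extend(qc_mod.flag_misplaced_taxa(gt, taxonomy, marker=name))
    qc_path = out / "qc_flags.tsv"
    qc_mod.write_flags_tsv(flags, qc_path)
    outputs.append(qc_path)
    t0 = _stage("qc", t0)

    # gap-threshold trimming
    trimmed = []
    for aln in markers:
        t_aln, kept = supermatrix_mod.gap_threshold_trim(aln, config.gap_threshold)
        if t_aln.length == 0:
            logger.warning("marker %s trimmed to zero columns; excluded", aln.marker)
            continue
        trimmed.append(t_aln)
    t0 = _stage("trim", t0)

    matrix = supermatrix_mod.concatenate(trimmed)
    sm_path = out / "supermatrix.fasta"
    seqio.write_fasta(matrix, sm_path)
    part_path = out / "partitions.txt"
    seqio.write_partition_file(matrix, part_path)
    outputs += [sm_path, part_path]
    t0 = _stage("concat", t0)

    # reference tree: provided, or JC-NJ on the supermatrix
    if config.reference_tree_path:
        reference = seqio.read_newick_file(config.reference_tree_path)
    else:
        reference = sensitivity_mod.default_engine(matrix)
    ref_path = out / "reference_tree.nwk"
    seqio.write_newick_file(reference, ref_path)
    outputs.append(ref_path)
    t0 = _stage("tree", t0)

    # per-marker gene trees: provided, or JC-NJ per marker
    for aln in trimmed:
        if aln.marker not in gene_trees:
            try:
                gene_trees[aln.marker] = treekit.nj_from_alignment(aln)
            except PhylomosaicError as exc:
                logger.warning("no gene tree for %s: %s", aln.marker, exc)
    gt_dir = out / "gene_trees"
    gt_dir.mkdir(exist_ok=True)
    for name, gt in sorted(gene_trees.items()):
        p = gt_dir / f"{name}.nwk"
        seqio.write_newick_file(gt, p)
        outputs.append(p)
    t0 = _stage("gene_trees", t0)

    # per-marker statistics: occupancy, informative sites, saturation
    n_total = len(matrix.taxa)
    stats_rows: list[seqio.MarkerStats] = []
    sat_pairs = [
        (aln, gene_trees[aln.marker]) for aln in trimmed if aln.marker in gene_trees
    ]
    sat_rows = {r.marker: r for r in saturation_mod.saturation_report(sat_pairs)}
    for aln in trimmed:
        row = sat_rows.get(aln.marker, seqio.MarkerStats(marker=aln.marker))
        row.n_sequences = len(aln.taxa)
        row.n_taxa_total = n_total
        row.n_sites = aln.length
        _, row.informative_pct = supermatrix_mod.count_informative_sites(aln)
        stats_rows.append(row)
    t0 = _stage("stats", t0)

    # concordance bookkeeping
    node_rows = []
    marker_rows = {}
    for aln in trimmed:
        gt = gene_trees.get(aln.marker)
        if gt is None:
            continue
        gene_taxa = treekit.leaf_labels(gt) & set(matrix.taxa)
        if len(gene_taxa) < 2:
            continue
        mc = concordance_mod.marker_concordance(
            treekit.prune_to_taxa(gt, gene_taxa), reference, marker=aln.marker
        )
        marker_rows[aln.marker] = mc
    gcf = concordance_mod.node_concordance_factors(
        reference, [gene_trees[a.marker] for a in trimmed if a.marker in gene_trees]
    )
    scf = concordance_mod.site_concordance_factors(
        reference, matrix, n_quartets=config.scf_quartets, seed=config.seed
    )
    scf_by_bip = {nc.bipartition: nc for nc in scf}
    node_path = out / "node_concordance.tsv"
    with open(node_path, "w") as fh:
        fh.write("bipartition_side\tgcf\tn_gene_trees\tscf\tn_quartets\n")
        for nc in gcf:
            sc = scf_by_bip.get(nc.bipartition)
            fh.write(
                "\t".join(
                    [
                        ",".join(sorted(nc.bipartition.side)),
                        "NA" if nc.gcf is None else f"{nc.gcf:.1f}",
                        str(nc.n_decisive),
                        "NA" if sc is None or sc.scf is None else f"{sc.scf:.1f}",
                        "0" if sc is None else str(sc.n_quartets),
                    ]
                )
                + "\n"
            )
    outputs.append(node_path)
    for row in stats_rows:
        mc = marker_rows.get(row.marker)
        if mc is not None:
            row.n_concordant = mc.n_concordant
            row.n_nodes_total = mc.n_total
            row.n_missing = mc.n_missing
            row.concordance_pct = mc.percentage
    report_path = out / "report.tsv"
    seqio.write_report_tsv(stats_rows, report_path)
    outputs.append(report_path)
    t0 = _stage("concordance", t0)

    # composite matrix
    if config.build_composite and taxonomy is not None:
        comp_matrix, specs = composite_mod.build_composite_matrix(
            trimmed, taxonomy, reference, gene_trees
        )
        comp_path = out / "composite.fasta"
        seqio.write_fasta(comp_matrix, comp_path)
        comp_part = out / "composite_partitions.txt"
        seqio.write_partition_file(comp_matrix, comp_part)
        prov_path = out / "composite_provenance.tsv"
        composite_mod.write_provenance_tsv(specs, prov_path)
        outputs += [comp_path, comp_part, prov_path]
        logger.info(
            "missing fraction: original %.3f -> composite %.3f",
            supermatrix_mod.missing_fraction(matrix),
            supermatrix_mod.missing_fraction(comp_matrix),
        )
        t0 = _stage("composite", t0)

    # single-marker jackknife
    if len(matrix.partitions) >= 2:
        jack = sensitivity_mod.jackknife_topology_scan(matrix)
        jack_path = out / "jackknife.tsv"
        sensitivity_mod.write_jackknife_tsv(jack, jack_path)
        outputs.append(jack_path)
        t0 = _stage("jackknife", t0)

    manifest = {
        "config": {
            "marker_fastas": [str(p) for p in config.marker_fastas],
            "taxonomy": str(config.taxonomy_path) if config.taxonomy_path else None,
            "reference_tree": (
                str(config.reference_tree_path) if config.reference_tree_path else None
            ),
            "gap_threshold": config.gap_threshold,
            "qc_threshold": config.qc_threshold,
            "scf_quartets": config.scf_quartets,
            "seed": config.seed,
        },
        "outputs": {str(p.relative_to(out)): _digest(p) for p in outputs},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
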