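"""End-to-end pipeline: phase -> trees -> haploweb -> congruence -> report.

The pipeline consumes a mixed-read table for the biparental nuclear
marker, a pre-aligned haplotype FASTA for that marker, and a
per-individual aligned FASTA for the clonally inherited mitochondrial
marker.  It phases every individual, builds bootstrapped neighbor-
joining haplotype trees for both markers, delimits allele pools
(fields for recombination) on the nuclear side and distance clades on
the mitochondrial side, counts cross-pool heterozygotes, and tests
congruence of the two partitions.  All stages are deterministic given
the configured seeds; every threshold and seed must be explicit in the
configuration so a run is a reproducible record.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field

from . import io as hio
from . import webs
from .phasing import phase_dataset
from .phylo import (
    Alignment,
    bootstrap_nj,
    cluster_by_distance,
    collapse_haplotypes,
    k2p_distance,
    nj_tree,
    root_with_outgroup,
)

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, msg: str):
        super().__init__(f"[{stage}] {msg}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Explicit inputs, thresholds and seeds of one pipeline run."""

    reads_tsv: str
    nuclear_fasta: str
    mito_fasta: str
    out_dir: str
    samples_tsv: str | None = None
    outgroup: tuple[str, ...] = ()
    bootstrap_replicates: int = 100
    seed: int = 0
    height_threshold: float = 0.65
    distance_threshold: str | float = "auto"
    marker: str = "nuclear"

    def validate(self) -> None:
        for name in ("reads_tsv", "nuclear_fasta", "mito_fasta"):
            path = getattr(self, name)
            if not os.path.exists(path):
                raise PipelineError("config", f"{name} does not exist: {path}")
        if self.samples_tsv is not None and not os.path.exists(self.samples_tsv):
            raise PipelineError("config", f"samples_tsv does not exist: {self.samples_tsv}")
        if self.bootstrap_replicates < 1:
            raise PipelineError("config", "bootstrap_replicates must be >= 1")
        if not 0.5 < self.height_threshold <= 1.0:
            raise PipelineError("config", "height_threshold must lie in (0.5, 1.0]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = hio.read_yaml(path)
        if "outgroup" in data and isinstance(data["outgroup"], list):
            data["outgroup"] = tuple(data["outgroup"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["outgroup"] = list(self.outgroup)
        return d


@dataclass
class RunReport:
    """Per-stage accounting of one pipeline run."""

    n_individuals: int
    route_counts: dict[str, int]
    n_haplotypes: int
    n_pools: int
    n_weak_pools: int
    n_mito_haplotypes: int
    n_mito_clusters: int
    n_heterozygotes: int
    cross_pool_heterozygotes: int
    cross_pool_individuals: list[str]
    rand_index: float
    partitions_identical: bool
    conflicts: list[str]
    version: str = __version__
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if sum(self.route_counts.values()) != self.n_individuals:
            raise ValueError("route counts must sum to the individual count")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunReport":
        return cls(**d)


def export_report(report: RunReport, path, format: str) -> None:
    """Serialize a run report as JSON or TSV (identical content)."""
    d = report.to_dict()
    if format == "json":
        hio.write_json(path, d)
    elif format == "tsv":
        flat: list[tuple[str, str]] = []

        def walk(prefix: str, value) -> None:
            if isinstance(value, dict):
                for k in sorted(value):
                    walk(f"{prefix}.{k}" if prefix else str(k), value[k])
            elif isinstance(value, (list, tuple)):
                flat.append((prefix, ",".join(str(v) for v in value)))
            else:
                flat.append((prefix, str(value)))

        walk("", d)
        with open(path, "w") as fh:
            fh.write("key\tvalue\n")
            for k, v in flat:
                fh.write(f"{k}\t{v}\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc

        return wrapper

    return deco


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full analysis chain and write all artifacts.

    Stages: read inputs -> phase nuclear reads -> map phased sequences
    to catalogue haplotypes -> nuclear haplotype tree (collapse, K2P,
    NJ + bootstrap) -> mitochondrial tree and distance clades ->
    haploweb + FFR delimitation -> cross-pool heterozygote count +
    partition congruence -> artifacts and run report.  A stage failure
    aborts with the stage name and the offending records.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)

    reads = _stage("read-inputs")(hio.read_reads_tsv)(config.reads_tsv, marker=config.marker)
    nuc_records = _stage("read-inputs")(hio.read_fasta)(config.nuclear_fasta, role="aligned")
    mito_records = _stage("read-inputs")(hio.read_fasta)(config.mito_fasta, role="aligned")
    if not reads:
        raise PipelineError("read-inputs", "no reads for marker " + config.marker)

    # --- phase the nuclear marker
    phased = _stage("phasing")(phase_dataset)(
        reads, marker=config.marker, height_threshold=config.height_threshold
    )
    route_counts: dict[str, int] = {}
    for g in phased:
        route_counts[g.route] = route_counts.get(g.route, 0) + 1
    logger.info("phasing routes: %s", route_counts)

    # --- map phased sequences onto the aligned haplotype catalogue
    degap = {sid: seq.replace("-", "") for sid, seq in nuc_records}
    seq_to_id: dict[str, str] = {}
    for sid in sorted(degap):
        seq_to_id.setdefault(degap[sid], sid)
    unmatched = sorted(
        {
            g.individual_id
            for g in phased
            if g.haplotypes is not None
            and any(h not in seq_to_id for h in g.haplotypes)
        }
    )
    if unmatched:
        raise PipelineError(
            "haplotype-mapping",
            f"phased sequences not present in {config.nuclear_fasta}: "
            f"individuals {unmatched}",
        )
    phased_ids = [
        dataclasses.replace(
            g,
            haplotypes=None
            if g.haplotypes is None
            else tuple(sorted(seq_to_id[h] for h in g.haplotypes)),
        )
        for g in phased
    ]

    # --- nuclear haplotype tree (only haplotypes actually observed)
    observed = sorted({h for g in phased_ids if g.haplotypes for h in g.haplotypes})
    nuc_aln = Alignment.from_pairs(
        [(sid, seq) for sid, seq in nuc_records if sid in observed]
    )
    nuc_aln, nuc_members = collapse_haplotypes(nuc_aln)
    nuc_tree = _stage("nuclear-tree")(bootstrap_nj)(
        nuc_aln, config.bootstrap_replicates, seed=config.seed
    )
    nuc_dm = k2p_distance(nuc_aln, "pairwise")

    # --- mitochondrial tree and distance clades
    mito_aln = Alignment.from_pairs(mito_records)
    mito_haps, mito_members = collapse_haplotypes(mito_aln)
    mito_dm = _stage("mito-tree")(k2p_distance)(mito_haps, "pairwise")
    if len(mito_haps) >= 3:
        mito_tree = _stage("mito-tree")(bootstrap_nj)(
            mito_haps, config.bootstrap_replicates, seed=config.seed + 1
        )
        if config.outgroup:
            present = set(config.outgroup) & set(mito_haps.ids)
            if present:
                mito_tree = _stage("mito-tree")(root_with_outgroup)(
                    mito_tree, sorted(present)
                )
    else:
        mito_tree = None
    clusters = _stage("mito-clades")(cluster_by_distance)(
        mito_dm, config.distance_threshold
    )
    mito_partition_ind: dict[str, str] = {}
    for idx, comp in enumerate(clusters, start=1):
        for rep in comp:
            for ind in mito_members[rep]:
                mito_partition_ind[ind] = f"clade_{idx}"

    # --- haploweb and FFR delimitation
    hw = _stage("haploweb")(webs.build_haploweb)(phased_ids)
    ffr = _stage("haploweb")(webs.delimit_ffrs)(hw)

    # --- congruence: cross-pool heterozygotes against mito clades
    # each nuclear haplotype inherits the mitochondrial clade of the
    # majority of its carriers (ties broken by clade label); mixed-carrier
    # haplotypes are logged -- they are themselves evidence of pool mixing
    carrier_clades: dict[str, dict[str, int]] = {}
    for g in phased_ids:
        if g.haplotypes is None:
            continue
        clade = mito_partition_ind.get(g.individual_id)
        if clade is None:
            raise PipelineError(
                "congruence",
                f"individual {g.individual_id} missing from the mitochondrial "
                "alignment",
            )
        for h in g.haplotypes:
            counts = carrier_clades.setdefault(h, {})
            counts[clade] = counts.get(clade, 0) + 1
    hap_to_mito: dict[str, str] = {}
    for h, counts in carrier_clades.items():
        if len(counts) > 1:
            logger.warning(
                "haplotype %s carried by individuals of different "
                "mitochondrial clades: %s", h, counts,
            )
        hap_to_mito[h] = min(counts, key=lambda c: (-counts[c], c))
    n_cross, cross_ids = _stage("congruence")(webs.count_cross_pool_heterozygotes)(
        phased_ids, hap_to_mito
    )
    resolved_inds = {g.individual_id for g in phased_ids if g.haplotypes is not None}
    congruence = _stage("congruence")(webs.compare_partitions)(
        {i: ffr.individuals[i] for i in sorted(resolved_inds)},
        {i: mito_partition_ind[i] for i in sorted(resolved_inds)},
    )

    # --- artifacts
    out = config.out_dir
    hio.write_phased_fasta(os.path.join(out, "phased.fasta"), phased)
    hio.write_phase_report(os.path.join(out, "phase_report.tsv"), phased_ids)
    hio.write_newick(os.path.join(out, "nuclear_tree.nwk"), nuc_tree)
    nuc_dm.to_dataframe().to_csv(os.path.join(out, "nuclear_distances.tsv"), sep="\t")
    mito_dm.to_dataframe().to_csv(os.path.join(out, "mito_distances.tsv"), sep="\t")
    if mito_tree is not None:
        hio.write_newick(os.path.join(out, "mito_tree.nwk"), mito_tree)
    hio.write_partition_tsv(
        os.path.join(out, "pools_haplotypes.tsv"), ffr.haplotype_block(), "haplotype"
    )
    hio.write_partition_tsv(
        os.path.join(out, "pools_individuals.tsv"), ffr.individuals, "individual"
    )
    hio.write_partition_tsv(
        os.path.join(out, "mito_clusters.tsv"), mito_partition_ind, "individual"
    )
    layout = webs.render_haploweb(nuc_tree, hw, ffr)
    webs.write_layout_json(layout, os.path.join(out, "haploweb.json"))
    webs.write_svg(layout, os.path.join(out, "haploweb.svg"))

    het_ids = hw.heterozygous_individuals
    report = RunReport(
        n_individuals=len(phased),
        route_counts=route_counts,
        n_haplotypes=len(nuc_aln),
        n_pools=ffr.n_pools,
        n_weak_pools=len(ffr.weak),
        n_mito_haplotypes=len(mito_haps),
        n_mito_clusters=len(clusters),
        n_heterozygotes=len(het_ids),
        cross_pool_heterozygotes=n_cross,
        cross_pool_individuals=cross_ids,
        rand_index=congruence.rand_index,
        partitions_identical=congruence.identical,
        conflicts=congruence.conflicts,
        config=config.to_dict(),
    )
    export_report(report, os.path.join(out, "report.json"), "json")
    export_report(report, os.path.join(out, "report.tsv"), "tsv")
    return report
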