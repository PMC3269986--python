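"""Haplowebs and species delimitation by mutual allelic exclusivity.

A haploweb is a haplotype tree (or network) augmented with connections
between haplotypes found co-occurring in heterozygous individuals.
Alleles linked through shared carriers form a *field for recombination*
(FFR): a pool of alleles that demonstrably segregate within one
reproductively coherent group.  Under the mutual-allelic-exclusivity
criterion each pool delimits a candidate species — no individual may
carry alleles from two different pools, which holds structurally for
the pools produced here (they are connected components of the
individual-allele incidence graph).

Congruence between the nuclear FFR partition and an independent
partition (here, distance-based clades of a clonally inherited
mitochondrial marker) is the test that rejects hybridization: a hybrid
individual would carry alleles from two pools and merge them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import networkx as nx

from .phasing import PhasedGenotype

logger = logging.getLogger(__name__)


class HaplowebError(ValueError):
    pass


@dataclass
class Haploweb:
    """Co-occurrence graph plus individual-haplotype incidence.

    ``graph`` has one node per distinct haplotype and one edge per
    heterozygous co-occurrence, weighted by the number of heterozygous
    individuals carrying both endpoints.  ``incidence`` maps each
    resolved individual to its (unordered) haplotype pair.
    """

    graph: nx.Graph
    incidence: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        for a, b, w in self.graph.edges(data="weight"):
            if w is None or w < 1:
                raise HaplowebError(f"edge {a}-{b} has weight {w}, must be >= 1")
        carried = set()
        for pair in self.incidence.values():
            carried.update(pair)
        for a, b in self.graph.edges():
            if a not in carried or b not in carried:
                raise HaplowebError(f"edge {a}-{b} has an endpoint with no carrier")

    @property
    def haplotypes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def heterozygous_individuals(self) -> list[str]:
        return sorted(i for i, (a, b) in self.incidence.items() if a != b)


@dataclass
class FFRPartition:
    """Fields for recombination: disjoint allele pools and the induced
    assignment of individuals to candidate species.

    ``weak`` flags singleton pools (one allele, homozygous carriers
    only), for which the exclusivity criterion is vacuous.
    """

    pools: dict[str, set[str]]
    individuals: dict[str, str]
    weak: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for label, pool in self.pools.items():
            if seen & pool:
                raise HaplowebError("pools must be disjoint")
            seen |= pool
        for ind, label in self.individuals.items():
            if label not in self.pools:
                raise HaplowebError(f"individual {ind} assigned to unknown pool {label}")

    @property
    def n_pools(self) -> int:
        return len(self.pools)

    def haplotype_block(self) -> dict[str, str]:
        """Flat haplotype -> pool-label map."""
        return {h: lbl for lbl, pool in self.pools.items() for h in pool}


@dataclass
class CongruenceReport:
    """Agreement between two partitions of the same individuals."""

    identical: bool
    rand_index: float
    conflicts: list[str]
    cross_pool_heterozygotes: int = 0

    def __post_init__(self) -> None:
        if self.identical and (self.rand_index != 1.0 or self.conflicts):
            raise HaplowebError("identical partitions must have Rand 1 and no conflicts")


# ---------------------------------------------------------------------------
# construction and delimitation


def build_haploweb(phased: list[PhasedGenotype]) -> Haploweb:
    """Build the haploweb from a phased genotype table.

    One node per distinct haplotype (the caller supplies collapsed
    haplotype identifiers or raw sequences — either works, identity is
    string equality); one edge per heterozygous co-occurrence, with
    weights accumulating across individuals.  Unresolved genotypes are
    excluded with a logged count.
    """
    resolved = [g for g in phased if g.haplotypes is not None]
    skipped = len(phased) - len(resolved)
    if skipped:
        logger.info("haploweb: excluding %d unresolved individual(s)", skipped)
    if not resolved:
        raise HaplowebError("no resolved genotypes to build a haploweb from")
    g = nx.Graph()
    incidence: dict[str, tuple[str, str]] = {}
    for geno in resolved:
        a, b = sorted(geno.haplotypes)
        incidence[geno.individual_id] = (a, b)
        g.add_node(a)
        g.add_node(b)
        if a != b:
            if g.has_edge(a, b):
                g[a][b]["weight"] += 1
            else:
                g.add_edge(a, b, weight=1)
    return Haploweb(g, incidence)


def delimit_ffrs(hw: Haploweb) -> FFRPartition:
    """Delimit allele pools as components of the incidence graph.

    The bipartite individual-haplotype graph is used, so two haplotypes
    joined only through a shared carrier (e.g. a homozygote for one and
    a heterozygote carrying both) are pooled together.  Each individual
    lands in the component holding its alleles; by construction no
    individual spans two pools.
    """
    bip = nx.Graph()
    for h in hw.graph.nodes:
        bip.add_node(("hap", h))
    for ind, (a, b) in hw.incidence.items():
        bip.add_node(("ind", ind))
        bip.add_edge(("ind", ind), ("hap", a))
        bip.add_edge(("ind", ind), ("hap", b))
    comps = []
    for comp in nx.connected_components(bip):
        haps = {x for kind, x in comp if kind == "hap"}
        inds = {x for kind, x in comp if kind == "ind"}
        comps.append((haps, inds))
    comps.sort(key=lambda c: (-len(c[0]), min(c[0])))
    pools: dict[str, set[str]] = {}
    individuals: dict[str, str] = {}
    weak: set[str] = set()
    for idx, (haps, inds) in enumerate(comps, start=1):
        label = f"pool_{idx}"
        pools[label] = haps
        for ind in inds:
            individuals[ind] = label
        if len(haps) == 1:
            weak.add(label)
    if weak:
        logger.info(
            "%d singleton pool(s) flagged weak evidence: %s", len(weak), sorted(weak)
        )
    return FFRPartition(pools, individuals, weak)


def count_cross_pool_heterozygotes(
    phased: list[PhasedGenotype], partition: dict[str, str]
) -> tuple[int, list[str]]:
    """Heterozygotes whose two alleles fall in different partition blocks.

    ``partition`` maps haplotype -> block label and must cover every
    haplotype carried by a resolved genotype.  Against the FFR pools the
    count is structurally zero; against the mitochondrial clades it is
    the hybridization test the delimitation rests on.
    """
    hits = []
    for g in phased:
        if g.haplotypes is None:
            continue
        a, b = g.haplotypes
        for h in (a, b):
            if h not in partition:
                raise HaplowebError(f"haplotype {h!r} absent from partition")
        if a != b and partition[a] != partition[b]:
            hits.append(g.individual_id)
    return len(hits), sorted(hits)


# ---------------------------------------------------------------------------
# partition comparison


def _pair_same(assign: dict[str, str], a: str, b: str) -> bool:
    return assign[a] == assign[b]


def compare_partitions(
    p1: dict[str, str], p2: dict[str, str], universe=None
) -> CongruenceReport:
    """Congruence of two partitions over the same universe of elements.

    ``p1`` and ``p2`` map element -> block label.  The Rand index is the
    fraction of element pairs on which the partitions agree (together in
    both, or separate in both); conflicts list the elements whose
    co-membership differs between the partitions.
    """
    if universe is None:
        universe = set(p1)
    universe = set(universe)
    if set(p1) != universe or set(p2) != universe:
        diff = sorted((set(p1) ^ universe) | (set(p2) ^ universe))
        raise HaplowebError(f"partitions cover different universes: {diff}")
    elements = sorted(universe)
    if len(elements) < 2:
        rand = 1.0
    else:
        from sklearn.metrics import rand_score

        l1 = [p1[e] for e in elements]
        l2 = [p2[e] for e in elements]
        rand = float(rand_score(l1, l2))
    blocks1 = {frozenset(e for e in elements if p1[e] == lbl) for lbl in set(p1.values())}
    blocks2 = {frozenset(e for e in elements if p2[e] == lbl) for lbl in set(p2.values())}
    identical = blocks1 == blocks2
    conflicts = []
    for e in elements:
        co1 = {x for x in elements if _pair_same(p1, e, x)}
        co2 = {x for x in elements if _pair_same(p2, e, x)}
        if co1 != co2:
            conflicts.append(e)
    if identical:
        rand = 1.0
        conflicts = []
    return CongruenceReport(identical, rand, conflicts)


# ---------------------------------------------------------------------------
# rendering


#: qualitative palette for pool colouring (cycled when pools exceed it)
_PALETTE = (
    "#1b9e77", "#d95f02", "#7570b3", "#e7298a",
    "#66a61e", "#e6ab02", "#a6761d", "#666666",
)

#: curve stroke width per unit of edge weight, in SVG pixels
_WIDTH_PER_WEIGHT = 1.5


def render_haploweb(tree, hw: Haploweb, partition: FFRPartition | None = None) -> dict:
    """Layout specification for a tree-plus-curves haploweb drawing.

    Tips are placed in ladderized order; co-occurrence curves connect
    tip positions with stroke width proportional to edge weight; pools
    are colour-coded.  Haploweb nodes missing from the tree are placed
    in an ``unplaced`` margin with a warning.  Returns a JSON-ready
    dict; see :func:`write_svg` for the SVG rendering.
    """
    from .phylo import ladderized_tip_order

    if partition is None:
        partition = delimit_ffrs(hw)
    tip_order = ladderized_tip_order(tree)
    tips_in_tree = set(tip_order)
    unplaced = sorted(set(hw.graph.nodes) - tips_in_tree)
    if unplaced:
        logger.warning("haploweb nodes missing from tree, drawn unplaced: %s", unplaced)
    order = tip_order + unplaced
    index = {h: i for i, h in enumerate(order)}
    block = partition.haplotype_block()
    pool_labels = sorted(partition.pools)
    colors = {lbl: _PALETTE[i % len(_PALETTE)] for i, lbl in enumerate(pool_labels)}
    curves = []
    for a, b, w in sorted(hw.graph.edges(data="weight")):
        curves.append(
            {
                "a": a,
                "b": b,
                "weight": int(w),
                "thickness": _WIDTH_PER_WEIGHT * int(w),
                "same_pool": block.get(a) == block.get(b),
            }
        )
    return {
        "tips": [
            {
                "id": h,
                "y": index[h],
                "pool": block.get(h),
                "color": colors.get(block.get(h), "#000000"),
                "placed": h in tips_in_tree,
            }
            for h in order
        ],
        "curves": curves,
        "pools": {lbl: sorted(pool) for lbl, pool in partition.pools.items()},
        "colors": colors,
        "unplaced": unplaced,
    }


def write_layout_json(layout: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(layout, fh, indent=2, sort_keys=True)


def write_svg(layout: dict, path, row_height: int = 18, width: int = 640) -> None:
    """Deterministic SVG of a haploweb layout: tip labels + weight-scaled
    connection curves, pool-coloured."""
    tips = layout["tips"]
    height = row_height * (len(tips) + 2)
    x_label = width * 0.45
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
        f'height="{height}" font-family="monospace" font-size="12">'
    ]
    ys = {}
    for tip in tips:
        y = row_height * (tip["y"] + 1)
        ys[tip["id"]] = y
        style = "" if tip["placed"] else " font-style=\"italic\""
        parts.append(
            f'<text x="{x_label:.1f}" y="{y}" fill="{tip["color"]}"{style}>'
            f'{tip["id"]}</text>'
        )
    x0 = x_label + 90
    for curve in layout["curves"]:
        ya, yb = ys[curve["a"]], ys[curve["b"]]
        xc = x0 + 12 + 6 * abs(ya - yb) / row_height
        parts.append(
            f'<path d="M {x0:.1f} {ya} Q {xc:.1f} {(ya + yb) / 2:.1f} {x0:.1f} {yb}" '
            f'fill="none" stroke="#555555" stroke-width="{curve["thickness"]:.1f}"/>'
        )
    parts.append("</svg>")
    with open(path, "w") as fh:
        fh.write("\n".join(parts) + "\n")
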