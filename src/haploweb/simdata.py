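"""Synthetic multi-species diploid datasets for offline benchmarking.

The generator emulates the statistical structure the delimitation
analysis assumes: ``n_species`` reproductively isolated species, each
with a private pool of nuclear alleles derived from a species ancestor
(which in turn derives from a common root), diploid individuals carrying
one or two alleles of their own species, indel-bearing alleles that
produce length-variant heterozygote read pairs, and species-concordant
mitochondrial haplotypes.  Optional hybrid individuals draw their two
alleles from two different species and inherit the mitochondrial
haplotype of a randomly chosen parent species.

Substitutions are independent per site under equal base frequencies
(Jukes-Cantor-like) — the simplest model that yields recoverable clade
structure.  Each allele carries at most one deletion (1-5 bp, uniform
interior placement), which keeps the forward/reverse deconvolution
model exact (a single offset).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .reads import BASES, MixedRead, superpose

logger = logging.getLogger(__name__)

#: deletion lengths are drawn uniformly from this range (inclusive)
DELETION_RANGE = (1, 5)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic dataset generator.

    Divergences are expected substitutions per site; the between-species
    divergence must exceed the within-species one so that species clades
    are recoverable.  ``amplification_bias``, when set, attaches
    per-position peak heights to the simulated reads (the relative
    height of the first allele's peak), enabling the peak-height phasing
    route.
    """

    n_species: int = 3
    alleles_per_species: int | tuple[int, ...] = 5
    seq_length: int = 500
    subs_divergence_within: float = 0.01
    subs_divergence_between: float = 0.2
    indel_prob: float = 0.3
    n_individuals_per_species: int | tuple[int, ...] = 15
    het_fraction: float = 0.8
    hybrid_fraction: float = 0.0
    amplification_bias: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("indel_prob", "het_fraction", "hybrid_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name}={v} outside [0, 1]")
        for name in ("subs_divergence_within", "subs_divergence_between"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name}={v} outside [0, 1]")
        if self.n_species < 1:
            raise SimulationError("n_species must be >= 1")
        alleles = self.alleles_per_species
        if isinstance(alleles, int):
            alleles = (alleles,)
        if any(a < 1 for a in alleles):
            raise SimulationError("alleles_per_species must be >= 1")
        if self.seq_length <= 0:
            raise SimulationError("seq_length must be positive")
        if self.n_species > 1:
            if self.subs_divergence_between <= self.subs_divergence_within:
                raise SimulationError(
                    "subs_divergence_between must exceed subs_divergence_within"
                )
            if self.seq_length * self.subs_divergence_between < 1:
                raise SimulationError(
                    "seq_length too small: expected between-species differences "
                    "fall below one site"
                )
        if self.amplification_bias is not None and not 0.0 < self.amplification_bias < 1.0:
            raise SimulationError("amplification_bias must lie in (0, 1)")

    @property
    def species_labels(self) -> tuple[str, ...]:
        return tuple(f"sp{i + 1}" for i in range(self.n_species))

    def individuals_for(self, species_index: int) -> int:
        n = self.n_individuals_per_species
        if isinstance(n, int):
            return n
        return int(n[species_index])

    def alleles_for(self, species_index: int) -> int:
        a = self.alleles_per_species
        if isinstance(a, int):
            return a
        return int(a[species_index])


@dataclass(frozen=True)
class HaplotypeRecord:
    """One simulated allele: ungapped sequence plus its gapped form in
    root coordinates (so the catalogue is born aligned)."""

    id: str
    species: str
    seq: str
    aligned: str


@dataclass(frozen=True)
class Individual:
    id: str
    species: str
    allele_ids: tuple[str, str]
    mito_id: str
    is_hybrid: bool = False


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    catalogue: dict[str, HaplotypeRecord]
    mito: dict[str, HaplotypeRecord]
    individuals: list[Individual]
    reads: dict[str, dict[str, MixedRead]]

    def __post_init__(self) -> None:
        for ind in self.individuals:
            for a in ind.allele_ids:
                if a not in self.catalogue:
                    raise SimulationError(f"{ind.id}: unknown allele {a}")
            if ind.mito_id not in self.mito:
                raise SimulationError(f"{ind.id}: unknown mito haplotype {ind.mito_id}")
            if not ind.is_hybrid:
                species = {self.catalogue[a].species for a in ind.allele_ids}
                if species != {ind.species}:
                    raise SimulationError(f"{ind.id}: non-hybrid with foreign allele")
                if self.mito[ind.mito_id].species != ind.species:
                    raise SimulationError(f"{ind.id}: mito species mismatch")

    def truth_partition(self) -> dict[str, str]:
        """Individual -> species label (hybrids carry their mito parent)."""
        return {ind.id: ind.species for ind in self.individuals}

    def observed_allele_truth(self) -> dict[str, str]:
        """Observed allele id -> species label."""
        seen: dict[str, str] = {}
        for ind in self.individuals:
            for a in ind.allele_ids:
                seen[a] = self.catalogue[a].species
        return seen

    def hybrids(self) -> list[str]:
        return sorted(ind.id for ind in self.individuals if ind.is_hybrid)

    def sequence_to_allele(self) -> dict[str, str]:
        """Ungapped sequence -> allele id (smallest id wins on identical
        sequences, matching haplotype collapsing downstream)."""
        out: dict[str, str] = {}
        for hid in sorted(self.catalogue):
            seq = self.catalogue[hid].seq
            out.setdefault(seq, hid)
        return out


# ---------------------------------------------------------------------------
# sequence-level simulation


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Independent per-site substitution with equal base frequencies."""
    if rate == 0:
        return seq
    arr = np.array(list(seq), dtype="<U1")
    hits = rng.random(len(arr)) < rate
    for i in np.nonzero(hits)[0]:
        choices = [b for b in BASES if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def _maybe_delete(rng: np.random.Generator, seq: str, prob: float) -> tuple[str, str]:
    """Apply at most one interior deletion; returns (ungapped, aligned)."""
    if rng.random() >= prob or len(seq) < DELETION_RANGE[1] + 2:
        return seq, seq
    lo, hi = DELETION_RANGE
    length = int(rng.integers(lo, hi + 1))
    start = int(rng.integers(1, len(seq) - length))  # interior: never at an end
    aligned = seq[:start] + "-" * length + seq[start + length:]
    return seq[:start] + seq[start + length:], aligned


def simulate_alleles(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> dict[str, HaplotypeRecord]:
    """Simulate the nuclear allele catalogue.

    One ancestral sequence per species is mutated from a common root at
    the between-species divergence; ``alleles_per_species`` variants are
    then mutated from each ancestor at the within-species divergence and
    optionally receive one deletion.  Deterministic given the config
    seed.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[0])
    root = _random_seq(rng, config.seq_length)
    catalogue: dict[str, HaplotypeRecord] = {}
    for s_idx, species in enumerate(config.species_labels):
        ancestor = _mutate(rng, root, config.subs_divergence_between)
        for a_idx in range(config.alleles_for(s_idx)):
            seq = _mutate(rng, ancestor, config.subs_divergence_within)
            seq, aligned = _maybe_delete(rng, seq, config.indel_prob)
            hid = f"{species}_h{a_idx + 1:02d}"
            catalogue[hid] = HaplotypeRecord(hid, species, seq, aligned)
    return catalogue


#: number of mitochondrial variants segregating within each species
MITO_VARIANTS = 3


def simulate_mito(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> dict[str, HaplotypeRecord]:
    """Species-private mitochondrial haplotypes (no indels): one ancestor
    per species plus small within-species variation, mirroring clonally
    inherited clades."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[1])
    root = _random_seq(rng, config.seq_length)
    mito: dict[str, HaplotypeRecord] = {}
    for species in config.species_labels:
        ancestor = _mutate(rng, root, config.subs_divergence_between)
        for v in range(MITO_VARIANTS):
            seq = _mutate(rng, ancestor, config.subs_divergence_within)
            mid = f"{species}_m{v + 1}"
            mito[mid] = HaplotypeRecord(mid, species, seq, seq)
    return mito


def simulate_individuals(
    catalogue: dict[str, HaplotypeRecord],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    mito: dict[str, HaplotypeRecord] | None = None,
) -> list[Individual]:
    """Assign species, allele pairs and mitochondrial haplotypes.

    Each individual is heterozygous with probability ``het_fraction``
    (two distinct alleles of its species, else one allele twice) and a
    hybrid with probability ``hybrid_fraction`` (one allele from each of
    two species, mitochondrion from a random parent).
    """
    if not catalogue:
        raise SimulationError("empty allele catalogue")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[2])
    if mito is None:
        mito = simulate_mito(config)
    pools: dict[str, list[str]] = {}
    for hid in sorted(catalogue):
        pools.setdefault(catalogue[hid].species, []).append(hid)
    mito_pools: dict[str, list[str]] = {}
    for mid in sorted(mito):
        mito_pools.setdefault(mito[mid].species, []).append(mid)

    min_alleles = min(config.alleles_for(i) for i in range(config.n_species))
    if config.het_fraction > 0 and min_alleles == 1:
        warnings.warn(
            "het_fraction > 0 with a single allele per species: individuals "
            "forced homozygous",
            stacklevel=2,
        )

    def draw(pool: list[str]) -> str:
        return pool[rng.integers(0, len(pool))]

    individuals: list[Individual] = []
    for s_idx, species in enumerate(config.species_labels):
        pool = pools.get(species, [])
        if not pool:
            raise SimulationError(f"species {species} has no alleles")
        for i in range(config.individuals_for(s_idx)):
            ind_id = f"{species}_i{i + 1:03d}"
            is_hybrid = (
                config.n_species > 1 and rng.random() < config.hybrid_fraction
            )
            if is_hybrid:
                others = [s for s in config.species_labels if s != species]
                other = others[rng.integers(0, len(others))]
                a, b = draw(pool), draw(pools[other])
                parent = species if rng.random() < 0.5 else other
                m = draw(mito_pools[parent])
                individuals.append(
                    Individual(ind_id, parent, tuple(sorted((a, b))), m, True)
                )
                continue
            het = len(pool) > 1 and rng.random() < config.het_fraction
            if het:
                a = draw(pool)
                b = a
                while b == a:
                    b = draw(pool)
                pair = tuple(sorted((a, b)))
            else:
                a = draw(pool)
                pair = (a, a)
            m = draw(mito_pools[species])
            individuals.append(Individual(ind_id, species, pair, m, False))
    return individuals


def simulate_reads(
    dataset_catalogue: dict[str, HaplotypeRecord],
    individuals: list[Individual],
    config: SimulationConfig,
) -> dict[str, dict[str, MixedRead]]:
    """Forward/reverse superposed read pair for every individual."""
    reads: dict[str, dict[str, MixedRead]] = {}
    for ind in individuals:
        a, b = ind.allele_ids
        fwd, rev = superpose(
            dataset_catalogue[a].seq,
            dataset_catalogue[b].seq,
            bias=config.amplification_bias,
        )
        reads[ind.id] = {"forward": fwd, "reverse": rev}
    return reads


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """End-to-end dataset generation, deterministic given ``config.seed``."""
    streams = np.random.SeedSequence(config.seed).spawn(4)
    catalogue = simulate_alleles(config, np.random.default_rng(streams[0]))
    mito = simulate_mito(config, np.random.default_rng(streams[1]))
    individuals = simulate_individuals(
        catalogue, config, np.random.default_rng(streams[2]), mito
    )
    reads = simulate_reads(catalogue, individuals, config)
    return SimulatedDataset(config, catalogue, mito, individuals, reads)


# ---------------------------------------------------------------------------
# on-disk round trip (FASTA + TSV; see io module for format details)


def write_dataset(dataset: SimulatedDataset, directory) -> dict[str, str]:
    """Write the dataset as FASTA/TSV files; returns the path map.

    Files: nuclear haplotypes (ungapped and aligned FASTA), per-species
    mitochondrial haplotypes plus a per-individual aligned mitochondrial
    FASTA (pipeline input), the individual table, the mixed-read table
    and the truth labels.  Everything round-trips losslessly through
    :func:`read_dataset`.
    """
    import os

    from . import io as hio

    os.makedirs(directory, exist_ok=True)
    paths = {
        "haplotypes": os.path.join(directory, "haplotypes.fasta"),
        "haplotypes_aligned": os.path.join(directory, "haplotypes_aligned.fasta"),
        "mito_haplotypes": os.path.join(directory, "mito_haplotypes.fasta"),
        "mito_by_individual": os.path.join(directory, "mito_by_individual.fasta"),
        "individuals": os.path.join(directory, "individuals.tsv"),
        "reads": os.path.join(directory, "reads.tsv"),
        "truth": os.path.join(directory, "truth.tsv"),
        "config": os.path.join(directory, "config.yaml"),
    }
    cat = dataset.catalogue
    hio.write_fasta(paths["haplotypes"], [(h, cat[h].seq) for h in sorted(cat)])
    hio.write_fasta(
        paths["haplotypes_aligned"], [(h, cat[h].aligned) for h in sorted(cat)]
    )
    hio.write_fasta(
        paths["mito_haplotypes"],
        [(m, dataset.mito[m].seq) for m in sorted(dataset.mito)],
    )
    hio.write_fasta(
        paths["mito_by_individual"],
        [(ind.id, dataset.mito[ind.mito_id].seq) for ind in dataset.individuals],
    )
    hio.write_individuals_tsv(paths["individuals"], dataset.individuals)
    hio.write_reads_tsv(paths["reads"], dataset.reads)
    truth_rows = [
        ("allele", hid, cat[hid].species) for hid in sorted(cat)
    ] + [
        ("individual", ind.id, ind.species) for ind in dataset.individuals
    ]
    hio.write_truth_tsv(paths["truth"], truth_rows)
    hio.write_yaml(paths["config"], _config_to_dict(dataset.config))
    return paths


def _config_to_dict(config: SimulationConfig) -> dict:
    d = {
        k: getattr(config, k)
        for k in (
            "n_species",
            "alleles_per_species",
            "seq_length",
            "subs_divergence_within",
            "subs_divergence_between",
            "indel_prob",
            "n_individuals_per_species",
            "het_fraction",
            "hybrid_fraction",
            "amplification_bias",
            "seed",
        )
    }
    for key in ("n_individuals_per_species", "alleles_per_species"):
        if isinstance(d[key], tuple):
            d[key] = list(d[key])
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    for key in ("n_individuals_per_species", "alleles_per_species"):
        if isinstance(d.get(key), list):
            d[key] = tuple(d[key])
    return SimulationConfig(**d)


def read_dataset(directory) -> SimulatedDataset:
    """Reconstruct a dataset written by :func:`write_dataset`."""
    import os

    from . import io as hio

    config = config_from_dict(hio.read_yaml(os.path.join(directory, "config.yaml")))
    seqs = dict(hio.read_fasta(os.path.join(directory, "haplotypes.fasta"), role="haplotypes"))
    aligned = dict(
        hio.read_fasta(os.path.join(directory, "haplotypes_aligned.fasta"), role="aligned")
    )
    mito_seqs = dict(
        hio.read_fasta(os.path.join(directory, "mito_haplotypes.fasta"), role="haplotypes")
    )
    truth = hio.read_truth_tsv(os.path.join(directory, "truth.tsv"))
    allele_species = {i: s for kind, i, s in truth if kind == "allele"}
    catalogue = {
        hid: HaplotypeRecord(hid, allele_species[hid], seqs[hid], aligned[hid])
        for hid in seqs
    }
    mito = {
        mid: HaplotypeRecord(mid, mid.split("_")[0], mito_seqs[mid], mito_seqs[mid])
        for mid in mito_seqs
    }
    individuals = hio.read_individuals_tsv(os.path.join(directory, "individuals.tsv"))
    reads = hio.read_reads_tsv(os.path.join(directory, "reads.tsv"))
    return SimulatedDataset(config, catalogue, mito, individuals, reads)
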