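"""Readers and writers for the pipeline's on-disk formats.

FASTA for sequences (via Biopython), newick for trees (via dendropy),
TSV for tables, YAML for configuration, JSON for reports and drawings.
FASTA validation is role-dependent: aligned haplotype input must be
plain ``A/C/G/T/-/N``, whereas degenerate *reads* may contain two-base
IUPAC codes (three/four-base codes are rejected everywhere — a diploid
superposition cannot produce them).
"""

from __future__ import annotations

import json
import logging
import re
import warnings

import yaml
from Bio import SeqIO

from .phasing import PhasedGenotype
from .reads import CODE_TO_SET, MixedRead
from .simdata import Individual

logger = logging.getLogger(__name__)

_PLAIN = set("ACGT")
_ALIGNED = set("ACGT-N")
_READ = set(CODE_TO_SET)


class IOFormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, role: str = "aligned") -> list[tuple[str, str]]:
    """Parse a FASTA file into ordered (id, sequence) pairs.

    ``role`` selects validation: ``"aligned"`` allows gaps and N,
    ``"haplotypes"`` plain ACGT only, ``"reads"`` additionally allows
    two-base IUPAC codes.  Mixed case is normalised to upper and U is
    mapped to T with a warning; duplicate ids and other alphabet
    violations are errors.
    """
    allowed = {"aligned": _ALIGNED, "haplotypes": _PLAIN, "reads": _READ}.get(role)
    if allowed is None:
        raise IOFormatError(f"unknown FASTA role {role!r}")
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise IOFormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if "U" in seq:
            warnings.warn(f"{path}: {rec.id}: U mapped to T", stacklevel=2)
            seq = seq.replace("U", "T")
        bad = set(seq) - allowed
        if bad:
            raise IOFormatError(
                f"{path}: {rec.id}: characters {sorted(bad)} not allowed for "
                f"role {role!r}"
            )
        if not seq:
            raise IOFormatError(f"{path}: {rec.id}: empty sequence")
        records.append((rec.id, seq))
    if not records:
        raise IOFormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(path, records, width: int = 70) -> None:
    with open(path, "w") as fh:
        for sid, seq in records:
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# mixed-read TSV

_READS_HEADER = ["individual", "marker", "orientation", "sequence", "heights"]


def _heights_field(read: MixedRead) -> str:
    if read.heights is None:
        return ""
    parts = []
    for i in read.double_peaks():
        parts.append(f"{i}:{read.bases[i][0]}:{read.heights[i]:.4f}")
    return ";".join(parts)


def _parse_heights(iupac: str, spec: str) -> MixedRead:
    read = MixedRead.from_iupac(iupac)
    if not spec:
        return read
    cells = list(read.bases)
    heights = [1.0] * len(cells)
    for chunk in spec.split(";"):
        m = re.fullmatch(r"(\d+):([ACGT]):(0?\.\d+|1(?:\.0+)?)", chunk)
        if not m:
            raise IOFormatError(f"bad height entry {chunk!r}")
        i, primary, h = int(m.group(1)), m.group(2), float(m.group(3))
        if i >= len(cells) or len(cells[i]) != 2 or primary not in cells[i]:
            raise IOFormatError(f"height entry {chunk!r} does not match read")
        other = cells[i][0] if cells[i][1] == primary else cells[i][1]
        cells[i] = (primary, other)
        heights[i] = h
    return MixedRead(tuple(cells), heights=tuple(heights))


def write_reads_tsv(path, reads: dict[str, dict[str, MixedRead]], marker: str = "nuclear") -> None:
    """One row per read: individual, marker, orientation, IUPAC string
    and optional double-peak heights (``pos:taller_base:height;...``)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_READS_HEADER) + "\n")
        for ind in sorted(reads):
            for orientation in ("forward", "reverse"):
                read = reads[ind].get(orientation)
                if read is None:
                    continue
                fh.write(
                    "\t".join(
                        [ind, marker, orientation, read.iupac, _heights_field(read)]
                    )
                    + "\n"
                )


def read_reads_tsv(path, marker: str | None = None) -> dict[str, dict[str, MixedRead]]:
    reads: dict[str, dict[str, MixedRead]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _READS_HEADER:
            raise IOFormatError(f"{path}: unexpected header {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(_READS_HEADER):
                raise IOFormatError(f"{path}:{lineno}: expected {len(_READS_HEADER)} fields")
            ind, mk, orientation, iupac, heights = fields
            if marker is not None and mk != marker:
                continue
            if orientation not in ("forward", "reverse"):
                raise IOFormatError(f"{path}:{lineno}: bad orientation {orientation!r}")
            try:
                read = _parse_heights(iupac, heights)
            except ValueError as exc:
                raise IOFormatError(f"{path}:{lineno}: {exc}") from exc
            read = MixedRead(read.bases, heights=read.heights, orientation=orientation)
            reads.setdefault(ind, {})[orientation] = read
    return reads


# ---------------------------------------------------------------------------
# individual / truth / sample tables

_IND_HEADER = ["individual", "species", "allele_a", "allele_b", "mito", "is_hybrid"]


def write_individuals_tsv(path, individuals: list[Individual]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_IND_HEADER) + "\n")
        for ind in individuals:
            fh.write(
                "\t".join(
                    [
                        ind.id,
                        ind.species,
                        ind.allele_ids[0],
                        ind.allele_ids[1],
                        ind.mito_id,
                        "1" if ind.is_hybrid else "0",
                    ]
                )
                + "\n"
            )


def read_individuals_tsv(path) -> list[Individual]:
    out: list[Individual] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _IND_HEADER:
            raise IOFormatError(f"{path}: unexpected header {header}")
        for line in fh:
            if not line.strip():
                continue
            iid, species, a, b, mito, hybrid = line.rstrip("\n").split("\t")
            out.append(Individual(iid, species, (a, b), mito, hybrid == "1"))
    return out


def write_truth_tsv(path, rows) -> None:
    with open(path, "w") as fh:
        fh.write("kind\tid\tspecies\n")
        for kind, rid, species in rows:
            fh.write(f"{kind}\t{rid}\t{species}\n")


def read_truth_tsv(path) -> list[tuple[str, str, str]]:
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["kind", "id", "species"]:
            raise IOFormatError(f"{path}: unexpected header {header}")
        for line in fh:
            if line.strip():
                rows.append(tuple(line.rstrip("\n").split("\t")))
    return rows


def bundled_samples_path() -> str:
    """Path of the packaged study sample table (id, location, depth)."""
    import importlib.resources

    return str(importlib.resources.files("haploweb").joinpath("data/samples.tsv"))


def read_samples_tsv(path):
    """Sample table (individual id, coordinates/location, depth) as a
    pandas DataFrame."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample" not in df.columns:
        raise IOFormatError(f"{path}: missing 'sample' column")
    if df["sample"].duplicated().any():
        dupes = df["sample"][df["sample"].duplicated()].tolist()
        raise IOFormatError(f"{path}: duplicate sample ids {dupes}")
    return df


# ---------------------------------------------------------------------------
# phased output


def write_phased_fasta(path, phased: list[PhasedGenotype]) -> None:
    """Two entries per heterozygote (``_a``/``_b`` suffixes), one per
    homozygote; unresolved individuals are omitted."""
    records = []
    for g in phased:
        if g.haplotypes is None:
            continue
        a, b = g.haplotypes
        if a == b:
            records.append((g.individual_id, a))
        else:
            records.append((f"{g.individual_id}_a", a))
            records.append((f"{g.individual_id}_b", b))
    write_fasta(path, records)


_PHASE_HEADER = ["individual", "marker", "route", "ambiguous", "haplotype_a", "haplotype_b", "note"]


def write_phase_report(path, phased: list[PhasedGenotype], id_map: dict[str, str] | None = None) -> None:
    """Phase report TSV with route tags; ``id_map`` optionally renames
    haplotype sequences to catalogue identifiers."""
    with open(path, "w") as fh:
        fh.write("\t".join(_PHASE_HEADER) + "\n")
        for g in phased:
            if g.haplotypes is None:
                a = b = ""
            else:
                a, b = g.haplotypes
                if id_map is not None:
                    a, b = id_map.get(a, a), id_map.get(b, b)
            fh.write(
                "\t".join(
                    [g.individual_id, g.marker, g.route,
                     "1" if g.ambiguous else "0", a, b, g.note]
                )
                + "\n"
            )


def read_phase_report(path) -> list[PhasedGenotype]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _PHASE_HEADER:
            raise IOFormatError(f"{path}: unexpected header {header}")
        for line in fh:
            if not line.strip():
                continue
            ind, marker, route, amb, a, b, note = line.rstrip("\n").split("\t")
            haps = None if route == "unresolved" else (a, b)
            out.append(PhasedGenotype(ind, marker, haps, route, amb == "1", note))
    return out


# ---------------------------------------------------------------------------
# partitions, YAML, JSON


def write_partition_tsv(path, partition: dict[str, str], kind: str = "member") -> None:
    with open(path, "w") as fh:
        fh.write(f"{kind}\tblock\n")
        for member in sorted(partition):
            fh.write(f"{member}\t{partition[member]}\n")


def read_partition_tsv(path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            if line.strip():
                member, block = line.rstrip("\n").split("\t")
                out[member] = block
    return out


def write_yaml(path, data: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_json(path, data: dict) -> None:
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2, sort_keys=True)


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# trees


def write_newick(path, tree) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )


def read_newick(path):
    import dendropy

    return dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)


# ---------------------------------------------------------------------------
# GenBank validation helper


def load_genbank_genotypes(path, sample_pattern: str = r"\b(0\d[A-Za-z]+\d+)\b"):
    """Reconstruct per-individual genotypes from a pre-downloaded GenBank
    flat file of deposited haplotype sequences.

    Sequence definitions are scanned with ``sample_pattern`` for the
    sample identifier they came from; individuals with one matching
    sequence are treated as homozygotes and individuals with two as
    heterozygotes.  Returns (genotypes, sequences) where genotypes maps
    individual -> tuple of sequence ids and sequences maps id -> string.
    Network fetching is out of scope — the flat file must already be on
    disk.
    """
    pattern = re.compile(sample_pattern)
    by_individual: dict[str, list[str]] = {}
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "genbank"):
        m = pattern.search(rec.description or "")
        if not m:
            logger.warning("no sample id found in %r; record skipped", rec.description)
            continue
        ind = m.group(1)
        sequences[rec.id] = str(rec.seq).upper()
        by_individual.setdefault(ind, []).append(rec.id)
    genotypes: dict[str, tuple[str, ...]] = {}
    for ind, recs in sorted(by_individual.items()):
        if len(recs) > 2:
            logger.warning("%s has %d sequences; excluded (>2 alleles)", ind, len(recs))
            continue
        genotypes[ind] = tuple(sorted(recs))
    return genotypes, sequences
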