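"""Resolving heterozygote haplotypes from degenerate Sanger reads.

Four routes are attempted in order of decreasing directness, mirroring
standard practice for nuclear markers sequenced directly from diploids:

1. *homozygote* — clean reads, the single sequence is the genotype;
2. *single-peak* — exactly one double peak: the two resolutions are the
   two haplotypes, no inference needed;
3. *deconvolution* — length-variant heterozygotes: the forward read is
   start-aligned and the reverse read end-aligned, so the two reads form
   two coupled constraint systems that usually pin down both alleles
   exactly (constraint propagation to fixpoint; ambiguity is reported,
   never guessed);
4. *peak-height* — clear-cut peak-size differences assign the taller
   base at every double peak to one allele;
5. *clark* — Clark's parsimony method: haplotypes known from
   unambiguous individuals are subtracted from the remaining genotypes
   iteratively until a fixpoint.

Genotypes that no route reaches are tagged ``unresolved``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

from .reads import BASES, MixedRead, ReadError, superpose

logger = logging.getLogger(__name__)

ROUTES = ("homozygote", "single-peak", "deconvolution", "peak-height", "clark", "unresolved")


class PhasingError(ValueError):
    """Phasing route applied outside its precondition."""


class AmbiguityError(PhasingError):
    """The constraint system admits more than one solution."""

    def __init__(self, msg: str, unresolved: list[int] | None = None):
        super().__init__(msg)
        self.unresolved = unresolved or []


class InconsistencyError(PhasingError):
    """Observed reads contradict the superposition model."""


@dataclass(frozen=True)
class PhasedGenotype:
    """An individual's resolved haplotype pair for one marker.

    ``haplotypes`` holds the two sequences (equal for homozygotes) or
    ``None`` when unresolved; ``route`` records how the resolution was
    obtained.
    """

    individual_id: str
    marker: str
    haplotypes: tuple[str, str] | None
    route: str
    ambiguous: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if self.route not in ROUTES:
            raise ValueError(f"unknown route {self.route!r}")
        if self.route == "unresolved":
            if self.haplotypes is not None:
                raise ValueError("unresolved genotypes carry no haplotype pair")
        else:
            if self.haplotypes is None:
                raise ValueError(f"route {self.route!r} requires a haplotype pair")
            same = self.haplotypes[0] == self.haplotypes[1]
            if same != (self.route == "homozygote"):
                raise ValueError("route=homozygote iff the two sequences are identical")

    @property
    def is_heterozygous(self) -> bool:
        return self.haplotypes is not None and self.haplotypes[0] != self.haplotypes[1]


@dataclass(frozen=True)
class UnphasedGenotype:
    """Equal-length genotype as a list of unordered per-site base pairs."""

    individual_id: str
    sites: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("genotype must have at least one site")
        for i, (a, b) in enumerate(self.sites):
            if a not in BASES or b not in BASES:
                raise ValueError(f"site {i}: invalid bases {(a, b)!r}")
            if (a, b) != tuple(sorted((a, b))):
                raise ValueError(f"site {i}: pair must be sorted")

    @classmethod
    def from_read(cls, read: MixedRead, individual_id: str) -> "UnphasedGenotype":
        sites = []
        for cell in read.bases:
            if len(cell) == 1:
                sites.append((cell[0], cell[0]))
            else:
                sites.append(tuple(sorted(cell)))
        return cls(individual_id, tuple(sites))

    def het_sites(self) -> list[int]:
        return [i for i, (a, b) in enumerate(self.sites) if a != b]


# ---------------------------------------------------------------------------
# direct routes


def find_double_peaks(read: MixedRead) -> list[int]:
    """Sorted indices of double-peak positions (empty for clean reads)."""
    return read.double_peaks()


def resolve_single_double_peak(read: MixedRead) -> tuple[str, str]:
    """Enumerate the two haplotypes of a single-double-peak read.

    Returns the pair in lexicographic order.  Errors when the read has
    zero or more than one double peak (other routes apply there).
    """
    doubles = read.double_peaks()
    if len(doubles) != 1:
        raise PhasingError(
            f"single-double-peak route needs exactly 1 double peak, found "
            f"{len(doubles)}; use homozygote/deconvolution/Clark routes"
        )
    i = doubles[0]
    a, b = sorted(read.bases[i])
    template = [cell[0] for cell in read.bases]
    h1 = template.copy()
    h1[i] = a
    h2 = template.copy()
    h2[i] = b
    return tuple(sorted(("".join(h1), "".join(h2))))


def phase_by_peak_height(
    read: MixedRead, consistency_threshold: float = 0.65
) -> tuple[str, str] | None:
    """Split a read into (taller-base haplotype, shorter-base haplotype).

    Accepted only if the taller peak's relative height reaches
    ``consistency_threshold`` at *every* double peak; otherwise returns
    ``None`` (route declined — not an error, just unsuitable).
    """
    doubles = read.double_peaks()
    if read.heights is None:
        raise PhasingError("peak-height route requires per-position heights")
    for i in doubles:
        if read.heights[i] < consistency_threshold:
            return None
    tall, short = [], []
    for i, cell in enumerate(read.bases):
        tall.append(cell[0])
        short.append(cell[1] if len(cell) == 2 else cell[0])
    return "".join(tall), "".join(short)


# ---------------------------------------------------------------------------
# length-variant deconvolution

_UNRESOLVED = None


def _propagate(
    fwd: tuple[frozenset[str], ...], rev: tuple[frozenset[str], ...], k: int
) -> tuple[list[str | None], list[str | None], bool]:
    """Constraint propagation for the two-read superposition model.

    Model: ``|s1| = |s2| + k``; forward position ``i`` shows
    ``{s1[i]} | {s2[i]}`` (start-aligned), reverse position ``i`` shows
    ``{s1[i]} | {s2[i-k]}`` (end-aligned, forward coordinates).  Every
    observed set is *exactly* the union, so a double peak is an
    exclusive-or constraint between its two cell variables.

    Returns (s1, s2, consistent); unknown positions stay ``None``.
    """
    L = len(fwd)
    n2 = L - k
    s1: list[str | None] = [None] * L
    s2: list[str | None] = [None] * n2

    def assign(arr: list[str | None], i: int, b: str) -> bool:
        """True if anything changed; raises on conflict."""
        if arr[i] is None:
            arr[i] = b
            return True
        if arr[i] != b:
            raise InconsistencyError(f"conflicting assignment at position {i}")
        return False

    try:
        # structural singletons: regions covered by only one allele
        for i in range(L):
            f, r = fwd[i], rev[i]
            if i >= n2 and len(f) != 1:
                raise InconsistencyError(f"forward tail position {i} must be single-peak")
            if i < k and len(r) != 1:
                raise InconsistencyError(f"reverse head position {i} must be single-peak")
        changed = True
        while changed:
            changed = False
            for i in range(L):
                f = fwd[i]
                if len(f) == 1:
                    (b,) = f
                    changed |= assign(s1, i, b)
                    if i < n2:
                        changed |= assign(s2, i, b)
                else:  # xor: {s1[i], s2[i]} == f
                    if s1[i] is not None:
                        if s1[i] not in f:
                            raise InconsistencyError(f"forward position {i}")
                        changed |= assign(s2, i, next(iter(f - {s1[i]})))
                    elif i < n2 and s2[i] is not None:
                        if s2[i] not in f:
                            raise InconsistencyError(f"forward position {i}")
                        changed |= assign(s1, i, next(iter(f - {s2[i]})))
                r = rev[i]
                if len(r) == 1:
                    (b,) = r
                    changed |= assign(s1, i, b)
                    if i >= k:
                        changed |= assign(s2, i - k, b)
                else:  # xor: {s1[i], s2[i-k]} == r
                    if s1[i] is not None:
                        if s1[i] not in r:
                            raise InconsistencyError(f"reverse position {i}")
                        changed |= assign(s2, i - k, next(iter(r - {s1[i]})))
                    elif s2[i - k] is not None:
                        if s2[i - k] not in r:
                            raise InconsistencyError(f"reverse position {i}")
                        changed |= assign(s1, i, next(iter(r - {s2[i - k]})))
        # final verification of fully fixed cells
        for i in range(L):
            if s1[i] is not None:
                expect_f = {s1[i]} | ({s2[i]} if i < n2 and s2[i] is not None else set())
                if len(fwd[i]) == 1 and expect_f != set(fwd[i]):
                    raise InconsistencyError(f"forward position {i}")
    except InconsistencyError:
        return s1, s2, False
    return s1, s2, True


def estimate_offset(
    forward: MixedRead, reverse: MixedRead, k_max: int | None = None
) -> int:
    """Length difference between the two alleles of a length-variant pair.

    Tries every offset ``k`` in ``1..k_max`` under the two-read
    superposition model and returns the one maximising joint consistency
    (number of positions fixed without contradiction), ties broken
    toward smaller ``k``.  Errors when no offset is consistent — the
    reads are then not a length-variant pattern.
    """
    if len(forward) != len(reverse):
        raise PhasingError("forward and reverse reads must have equal length")
    L = len(forward)
    if k_max is None:
        k_max = min(L - 1, 20)
    fwd, rev = forward.sets, reverse.sets
    best_k, best_score = None, -1
    for k in range(1, k_max + 1):
        s1, s2, ok = _propagate(fwd, rev, k)
        if not ok:
            continue
        score = sum(x is not None for x in s1) + sum(x is not None for x in s2)
        if score == 2 * L - k:
            # complete consistent solve; no larger k can score higher
            return k
        if score > best_score:
            best_k, best_score = k, score
    if best_k is None:
        raise PhasingError(
            "no offset k >= 1 is consistent with the superposition model; "
            "reads are not a length-variant heterozygote pattern"
        )
    return best_k


def deconvolve_length_variant(
    forward: MixedRead, reverse: MixedRead, k: int
) -> tuple[str, str]:
    """Exactly recover both alleles of a length-variant heterozygote.

    Solves the coupled start-/end-aligned constraint systems by
    propagation to fixpoint.  The unique solution is returned (longer
    sequence first); if positions remain undetermined an
    :class:`AmbiguityError` lists them, and contradictions raise
    :class:`InconsistencyError`.
    """
    if k < 1:
        raise PhasingError("offset k must be >= 1")
    if len(forward) != len(reverse):
        raise PhasingError("forward and reverse reads must have equal length")
    if k >= len(forward):
        raise PhasingError("offset k must be smaller than the read length")
    fwd, rev = forward.sets, reverse.sets
    s1, s2, ok = _propagate(fwd, rev, k)
    if not ok:
        raise InconsistencyError(
            "reads contradict the length-variant superposition model at offset "
            f"k={k}"
        )
    unresolved = [i for i, b in enumerate(s1) if b is None] + [
        i for i, b in enumerate(s2) if b is None
    ]
    if unresolved:
        raise AmbiguityError(
            f"deconvolution ambiguous at offset k={k}; unresolved positions "
            f"{sorted(set(unresolved))}",
            unresolved=sorted(set(unresolved)),
        )
    return "".join(s1), "".join(s2)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# Clark's parsimony method


def _compatible(hap: str, g: UnphasedGenotype) -> bool:
    return len(hap) == len(g.sites) and all(
        hap[i] in pair for i, pair in enumerate(g.sites)
    )


def _complement(hap: str, g: UnphasedGenotype) -> str:
    out = []
    for i, (a, b) in enumerate(g.sites):
        out.append(b if hap[i] == a else a)
    return "".join(out)


def clark_phase(
    unresolved: list[UnphasedGenotype],
    seed_haplotypes: list[str],
) -> tuple[list[PhasedGenotype], list[UnphasedGenotype]]:
    """Clark's iterative parsimony phasing, conservative resolutions first.

    Starting from the seed haplotype set (homozygotes and individuals
    already resolved by direct routes), genotypes are resolved by
    subtracting a site-wise compatible known haplotype and adding its
    complement to the known set, iterating to fixpoint.  Resolutions
    are applied in three tiers so that novel haplotypes are only ever
    invented when nothing safer remains:

    1. genotypes for which some compatible known haplotype has an
       already-known complement (no new haplotype created);
    2. genotypes with exactly one compatible known haplotype (the
       subtraction is forced);
    3. the lexicographically smallest remaining genotype with any
       compatible haplotype, preferring the most frequent candidate and
       then the lexicographically smallest.

    Genotypes with zero or one heterozygous site are resolved up front
    (their phasing is unconditional).  Genotypes sharing no haplotype
    with the growing known set are returned unresolved — never guessed.
    """
    lengths = {len(g.sites) for g in unresolved}
    if len(lengths) > 1:
        raise PhasingError("all genotypes must share one aligned length")
    # seeds of a different length (e.g. indel-bearing alleles resolved by
    # deconvolution) can never be site-wise compatible; drop them up front
    if unresolved:
        (length,) = lengths
        seed_haplotypes = [h for h in seed_haplotypes if len(h) == length]

    known: dict[str, int] = {}

    def add(hap: str, times: int = 1) -> None:
        known[hap] = known.get(hap, 0) + times

    for h in seed_haplotypes:
        add(h)

    phased: dict[str, PhasedGenotype] = {}

    def resolve(g: UnphasedGenotype, hap: str) -> None:
        comp = _complement(hap, g)
        pair = tuple(sorted((hap, comp)))
        phased[g.individual_id] = PhasedGenotype(g.individual_id, "", pair, "clark")
        add(hap)
        add(comp)

    pending: list[UnphasedGenotype] = []
    for g in sorted(unresolved, key=lambda g: g.individual_id):
        het = g.het_sites()
        if not het:
            hap = "".join(a for a, _ in g.sites)
            phased[g.individual_id] = PhasedGenotype(
                g.individual_id, "", (hap, hap), "homozygote"
            )
            add(hap, 2)
        elif len(het) == 1:
            i = het[0]
            h1 = [a for a, _ in g.sites]
            h2 = h1.copy()
            h1[i], h2[i] = g.sites[i]
            pair = tuple(sorted(("".join(h1), "".join(h2))))
            phased[g.individual_id] = PhasedGenotype(g.individual_id, "", pair, "clark")
            add(pair[0])
            add(pair[1])
        else:
            pending.append(g)

    while pending:
        progress = False
        # tier 1: resolutions that create no new haplotype
        for g in list(pending):
            candidates = [h for h in known if _compatible(h, g)]
            closed = [h for h in candidates if _complement(h, g) in known]
            if closed:
                resolve(g, min(closed, key=lambda h: (-known[h], h)))
                pending.remove(g)
                progress = True
        if progress:
            continue
        # tier 2: forced subtractions (a single compatible candidate)
        for g in list(pending):
            candidates = [h for h in known if _compatible(h, g)]
            if len(candidates) == 1:
                resolve(g, candidates[0])
                pending.remove(g)
                progress = True
                break  # re-enter tier 1 with the new haplotype
        if progress:
            continue
        # tier 3: guess once, most frequent candidate first, then retry
        for g in pending:  # already in lexicographic id order
            candidates = [h for h in known if _compatible(h, g)]
            if candidates:
                resolve(g, min(candidates, key=lambda h: (-known[h], h)))
                pending.remove(g)
                progress = True
                break
        if not progress:
            break

    out = [
        phased[g.individual_id]
        for g in sorted(unresolved, key=lambda g: g.individual_id)
        if g.individual_id in phased
    ]
    return out, pending


# ---------------------------------------------------------------------------
# whole-dataset driver


def phase_dataset(
    reads: dict[str, dict[str, MixedRead]],
    marker: str = "nuclear",
    height_threshold: float = 0.65,
) -> list[PhasedGenotype]:
    """Phase every individual of a dataset, one route tag each.

    ``reads`` maps individual id to ``{"forward": MixedRead}`` with an
    optional ``"reverse"`` read (forward coordinates).  Routes are tried
    in order: homozygote, single double peak, length-variant
    deconvolution (when forward and reverse disagree in double-peak
    placement), peak height (when heights are present and clear-cut),
    and finally Clark's method seeded with everything already resolved.
    """
    results: dict[str, PhasedGenotype] = {}
    clark_queue: list[UnphasedGenotype] = []

    for ind in sorted(reads):
        entry = reads[ind]
        f = entry["forward"]
        r = entry.get("reverse")
        try:
            df = f.double_peaks()
            dr = r.double_peaks() if r is not None else df
            if not df and not dr:
                results[ind] = PhasedGenotype(
                    ind, marker, (f.iupac, f.iupac), "homozygote"
                )
                continue
            if r is not None and (f.sets != r.sets):
                # frame-shifted double peaks: length-variant heterozygote
                k = estimate_offset(f, r)
                pair = deconvolve_length_variant(f, r, k)
                results[ind] = PhasedGenotype(
                    ind, marker, tuple(sorted(pair)), "deconvolution"
                )
                continue
            if len(df) == 1:
                pair = resolve_single_double_peak(f)
                results[ind] = PhasedGenotype(ind, marker, pair, "single-peak")
                continue
            if f.heights is not None:
                pair = phase_by_peak_height(f, height_threshold)
                if pair is not None:
                    results[ind] = PhasedGenotype(
                        ind, marker, tuple(sorted(pair)), "peak-height"
                    )
                    continue
            clark_queue.append(UnphasedGenotype.from_read(f, ind))
        except PhasingError as exc:
            logger.warning("individual %s: %s; tagged unresolved", ind, exc)
            results[ind] = PhasedGenotype(
                ind, marker, None, "unresolved", ambiguous=True, note=str(exc)
            )

    seeds: list[str] = []
    for g in results.values():
        if g.haplotypes is not None:
            seeds.extend(g.haplotypes)

    by_length: dict[int, list[UnphasedGenotype]] = {}
    for g in clark_queue:
        by_length.setdefault(len(g.sites), []).append(g)
    for group in by_length.values():
        phased, leftover = clark_phase(group, seeds)
        for g in phased:
            results[g.individual_id] = replace(g, marker=marker)
        for g in leftover:
            logger.warning(
                "individual %s: Clark fixpoint unreachable; tagged unresolved",
                g.individual_id,
            )
            results[g.individual_id] = PhasedGenotype(
                g.individual_id, marker, None, "unresolved",
                note="no compatible known haplotype",
            )

    return [results[ind] for ind in sorted(results)]
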