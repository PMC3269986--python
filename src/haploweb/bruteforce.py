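"""Exhaustive reference implementations for validation.

These brute-force searches are deliberately naive and independent of
the production algorithms: they enumerate complete solution spaces and
are therefore only usable on small instances.  They exist so that the
constraint-propagation deconvolver and Clark's parsimony phaser can be
checked against ground truth, and are exercised by the test-suite and
the acceptance script, not by the pipeline.
"""

from __future__ import annotations

import itertools

from .phasing import UnphasedGenotype
from .reads import MixedRead


def enumerate_phasings(genotype: UnphasedGenotype) -> list[tuple[str, str]]:
    """All unordered haplotype pairs consistent with one genotype."""
    het = genotype.het_sites()
    base = [a for a, _ in genotype.sites]
    if not het:
        hap = "".join(base)
        return [(hap, hap)]
    out = set()
    for bits in itertools.product((0, 1), repeat=len(het)):
        h1, h2 = base.copy(), base.copy()
        for bit, i in zip(bits, het):
            a, b = genotype.sites[i]
            h1[i], h2[i] = (a, b) if bit == 0 else (b, a)
        out.add(tuple(sorted(("".join(h1), "".join(h2)))))
    return sorted(out)


def minimum_haplotype_search(
    genotypes: list[UnphasedGenotype], cap: int = 1_000_000
) -> tuple[int, list[tuple[tuple[str, str], ...]]]:
    """Exhaustive minimum-haplotype-set phasing.

    Enumerates every joint phase assignment and returns the minimal
    number of distinct haplotypes together with *all* assignments
    attaining it (one tuple of unordered pairs per input genotype, in
    input order).  Raises when the joint space exceeds ``cap``.
    """
    options = [enumerate_phasings(g) for g in genotypes]
    total = 1
    for opt in options:
        total *= len(opt)
    if total > cap:
        raise ValueError(f"search space {total} exceeds cap {cap}")
    best_size: int | None = None
    best: list[tuple[tuple[str, str], ...]] = []
    for combo in itertools.product(*options):
        haps: set[str] = set()
        for pair in combo:
            haps.update(pair)
        if best_size is None or len(haps) < best_size:
            best_size, best = len(haps), [combo]
        elif len(haps) == best_size:
            best.append(combo)
    assert best_size is not None
    return best_size, best


def enumerate_deconvolutions(
    forward: MixedRead, reverse: MixedRead, k: int
) -> list[tuple[str, str]]:
    """All (s1, s2) pairs satisfying the two-read superposition model.

    Enumerates every base assignment at the forward read's double peaks
    (each double peak is an exclusive-or between ``s1[i]`` and
    ``s2[i]``) and keeps assignments whose induced pair also reproduces
    the reverse read exactly.  Feasible for reads up to roughly a dozen
    double peaks.
    """
    fwd, rev = forward.sets, reverse.sets
    L = len(fwd)
    n2 = L - k
    if n2 < 1:
        return []
    doubles = [i for i in range(L) if len(fwd[i]) == 2]
    if any(i >= n2 for i in doubles):
        return []  # forward tail is covered by s1 alone and must be clean
    solutions = []
    for bits in itertools.product((0, 1), repeat=len(doubles)):
        s1 = [next(iter(c)) if len(c) == 1 else None for c in fwd]
        s2 = s1[:n2]
        ok = True
        for bit, i in zip(bits, doubles):
            a, b = sorted(fwd[i])
            s1[i], s2[i] = (a, b) if bit == 0 else (b, a)
        for i in range(L):
            expect = {s1[i]}
            if i >= k:
                expect.add(s2[i - k])
            if expect != rev[i]:
                ok = False
                break
        if ok:
            solutions.append(("".join(s1), "".join(s2)))
    return sorted(set(solutions))
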