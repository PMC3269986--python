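"""Degenerate base calls and the two-allele superposition model.

A direct Sanger read of a diploid PCR product is the position-wise
superposition of the individual's two alleles: wherever the alleles
disagree, the chromatogram shows two peaks at one position, written as a
two-base IUPAC ambiguity code (R, Y, S, W, K, M).  When the two alleles
differ in length the forward and reverse reads are frame-shifted against
each other — the forward read is start-aligned, the reverse read
end-aligned — which is the signal the length-variant deconvolution route
exploits.

Coordinates are 0-based, half-open throughout.  Reverse reads are always
represented in forward orientation (already reverse-complemented), so
that position ``i`` of either read refers to the same output column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data.IUPACData import ambiguous_dna_values

BASES = ("A", "C", "G", "T")

#: two-base IUPAC ambiguity codes only; three/four-base codes (B, D, H, V, N)
#: are rejected on input because a diploid superposition cannot produce them.
CODE_TO_SET: dict[str, frozenset[str]] = {
    code: frozenset(vals)
    for code, vals in ambiguous_dna_values.items()
    if len(vals) <= 2 and set(vals) <= set(BASES)
}
SET_TO_CODE: dict[frozenset[str], str] = {s: c for c, s in CODE_TO_SET.items()}


class ReadError(ValueError):
    """Malformed degenerate read."""


@dataclass(frozen=True)
class MixedRead:
    """A degenerate read: 1-2 candidate bases per position.

    Parameters
    ----------
    bases:
        One tuple per position holding one or two distinct bases.  When
        ``heights`` are present the first base of a double is the taller
        peak.
    heights:
        Optional per-position relative height of the first-listed base,
        in (0.5, 1.0]; 1.0 at single-peak positions.
    orientation:
        ``"forward"`` or ``"reverse"`` (reverse reads are stored in
        forward coordinates).
    """

    bases: tuple[tuple[str, ...], ...]
    heights: tuple[float, ...] | None = None
    orientation: str = "forward"

    def __post_init__(self) -> None:
        if not self.bases:
            raise ReadError("empty read")
        if self.orientation not in ("forward", "reverse"):
            raise ReadError(f"bad orientation {self.orientation!r}")
        for i, cell in enumerate(self.bases):
            if not 1 <= len(cell) <= 2 or len(set(cell)) != len(cell):
                raise ReadError(f"position {i}: base set must hold 1-2 distinct bases")
            for b in cell:
                if b not in BASES:
                    raise ReadError(f"position {i}: invalid base {b!r}")
        if self.heights is not None:
            if len(self.heights) != len(self.bases):
                raise ReadError("heights length does not match read length")
            for i, h in enumerate(self.heights):
                if not 0.5 < h <= 1.0:
                    raise ReadError(f"position {i}: height {h} outside (0.5, 1.0]")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def sets(self) -> tuple[frozenset[str], ...]:
        return tuple(frozenset(cell) for cell in self.bases)

    @property
    def iupac(self) -> str:
        return "".join(SET_TO_CODE[frozenset(cell)] for cell in self.bases)

    @property
    def is_single_peak(self) -> bool:
        return all(len(cell) == 1 for cell in self.bases)

    def double_peaks(self) -> list[int]:
        return [i for i, cell in enumerate(self.bases) if len(cell) == 2]

    @classmethod
    def from_iupac(
        cls,
        s: str,
        heights: tuple[float, ...] | None = None,
        orientation: str = "forward",
    ) -> "MixedRead":
        s = s.upper().replace("U", "T")
        cells = []
        for i, ch in enumerate(s):
            if ch not in CODE_TO_SET:
                raise ReadError(
                    f"position {i}: {ch!r} is not a plain base or two-base IUPAC code"
                )
            cells.append(tuple(sorted(CODE_TO_SET[ch])))
        return cls(tuple(cells), heights=heights, orientation=orientation)


def _check_haplotype(seq: str, name: str) -> None:
    if not seq:
        raise ReadError(f"{name}: empty sequence")
    bad = set(seq) - set(BASES)
    if bad:
        raise ReadError(f"{name}: non-ACGT characters {sorted(bad)}")


def _cell(b1: str | None, b2: str | None, bias: float | None) -> tuple[tuple[str, ...], float]:
    """Union of the two allele contributions at one output position.

    ``bias`` is the relative peak height of allele 1's base; the taller
    base is listed first.  Returns (cell, height-of-first-base).
    """
    if b1 is None and b2 is None:  # pragma: no cover - never constructed
        raise ReadError("position with no contributing allele")
    if b1 is None:
        return (b2,), 1.0
    if b2 is None or b1 == b2:
        return (b1,), 1.0
    if bias is None:
        pair = tuple(sorted((b1, b2)))
        return pair, 1.0  # height unused when bias absent
    if bias >= 0.5:
        return (b1, b2), bias
    return (b2, b1), 1.0 - bias


def superpose(
    hap1: str, hap2: str, bias: float | None = None
) -> tuple[MixedRead, MixedRead]:
    """Simulate the forward/reverse read pair of a diploid individual.

    The forward read is the start-aligned position-wise union of the two
    alleles; the reverse read is the end-aligned union, reported in
    forward orientation.  For equal-length alleles the two reads carry
    identical base content; for length-variant heterozygotes their
    double-peak placements are frame-shifted by the length difference.

    ``bias`` (optional, in (0, 1)) is the relative amplification of
    ``hap1``; when given, per-position peak heights are attached.
    """
    _check_haplotype(hap1, "hap1")
    _check_haplotype(hap2, "hap2")
    if bias is not None and not 0.0 < bias < 1.0:
        raise ReadError(f"bias {bias} outside (0, 1)")
    L1, L2, L = len(hap1), len(hap2), max(len(hap1), len(hap2))

    def build(off1: int, off2: int, orientation: str) -> MixedRead:
        cells, heights = [], []
        for i in range(L):
            b1 = hap1[i - off1] if off1 <= i < off1 + L1 else None
            b2 = hap2[i - off2] if off2 <= i < off2 + L2 else None
            cell, h = _cell(b1, b2, bias)
            cells.append(cell)
            heights.append(h)
        return MixedRead(
            tuple(cells),
            heights=tuple(heights) if bias is not None else None,
            orientation=orientation,
        )

    forward = build(0, 0, "forward")
    reverse = build(L - L1, L - L2, "reverse")
    return forward, reverse
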