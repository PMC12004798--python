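"""Genome build: the ordered coordinate frame for all interval arithmetic.

Coordinates are 1-based inclusive throughout the package (Ensembl
convention); BED export converts to 0-based half-open at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class GenomeError(ValueError):
    """Raised for invalid genome configurations."""


@dataclass(frozen=True)
class GenomeBuild:
    """Ordered set of chromosomes with lengths in base pairs.

    Parameters
    ----------
    chromosomes
        Sequence of ``(name, length)`` pairs. Order is significant and is
        preserved in every output the package writes.
    """

    chromosomes: tuple[tuple[str, int], ...]
    _lengths: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        chroms = tuple((str(n), int(l)) for n, l in self.chromosomes)
        object.__setattr__(self, "chromosomes", chroms)
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise GenomeError("chromosome names must be unique")
        for name, length in chroms:
            if length <= 0:
                raise GenomeError(f"chromosome {name!r} has non-positive length {length}")
        object.__setattr__(self, "_lengths", dict(chroms))

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    def length(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]
        except KeyError:
            raise GenomeError(f"unknown chromosome {chrom!r}") from None

    @property
    def total_length(self) -> int:
        """Total genome length in bp (the denominator of coverage percentages)."""
        return sum(l for _, l in self.chromosomes)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths
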