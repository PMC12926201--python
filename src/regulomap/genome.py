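"""Genome model: an ordered set of named chromosomes with lengths.

Coordinates throughout the package are 0-based, half-open (BED convention).
"""
from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Genome:
    """Ordered chromosome names and lengths in base pairs."""

    lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def names(self) -> list[str]:
        return list(self.lengths)

    @property
    def size(self) -> int:
        """Total genome size in bp."""
        return sum(self.lengths.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def length(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    @classmethod
    def from_chrom_sizes(cls, path) -> "Genome":
        """Read a UCSC-style chrom.sizes file (name<TAB>length)."""
        lengths: dict[str, int] = {}
        with open(path) as fh:
            for i, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) < 2:
                    raise ValueError(f"{path}:{i}: expected 'name length', got {line!r}")
                lengths[parts[0]] = int(parts[1])
        return cls(lengths)

    def to_chrom_sizes(self, path) -> None:
        with open(path, "w") as fh:
            for name, length in self.lengths.items():
                fh.write(f"{name}\t{length}\n")
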