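"""Sample-to-population assignment.

A population map defines the contrast groups of every downstream analysis
(diversity per group, pairwise FST, the sweep scan's target/reference split).
It is a plain two-column TSV on disk: ``sample<TAB>population``.
"""

from __future__ import annotations

from pathlib import Path


class PopulationMap:
    """Ordered mapping of sample id -> population label."""

    def __init__(self, assignments: dict[str, str]):
        if not assignments:
            raise ValueError("population map is empty")
        self._map = dict(assignments)

    @property
    def samples(self) -> list[str]:
        return list(self._map)

    @property
    def populations(self) -> list[str]:
        """Distinct population labels in first-seen order."""
        seen: dict[str, None] = {}
        for pop in self._map.values():
            seen.setdefault(pop)
        return list(seen)

    def population_of(self, sample: str) -> str:
        return self._map[sample]

    def samples_in(self, population: str) -> list[str]:
        out = [s for s, p in self._map.items() if p == population]
        if not out:
            raise KeyError(f"population {population!r} has zero samples")
        return out

    def indices_in(self, population: str, sample_order: list[str]) -> list[int]:
        """Column indices of a population's samples within ``sample_order``."""
        members = set(self.samples_in(population))
        return [i for i, s in enumerate(sample_order) if s in members]

    def __contains__(self, sample: str) -> bool:
        return sample in self._map

    def __len__(self) -> int:
        return len(self._map)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PopulationMap) and self._map == other._map

    @classmethod
    def read_tsv(cls, path: str | Path) -> "PopulationMap":
        assignments: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ValueError(f"malformed population map line: {line!r}")
            assignments[fields[0]] = fields[1]
        return cls(assignments)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sample, pop in self._map.items():
                fh.write(f"{sample}\t{pop}\n")
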