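"""GENEPOP genotype file reading/writing and the in-memory genotype table.

GENEPOP is the interchange format of classical microsatellite analysis:
a title line, one locus name per line (or one comma-separated line),
then population blocks opened by a line reading ``pop`` (case-insensitive),
with one individual per line as ``name , 0102 0304 ...``.  Alleles are
2- or 3-digit positive codes; 00/000 marks a missing allele.

A genotype with one missing allele is treated as entirely missing at that
locus: dialects differ on half-calls and dropping the whole genotype is
the conservative reading for every statistic downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeTable", "read_genepop", "write_genepop", "GenepopError"]

MISSING = 0


class GenepopError(ValueError):
    """Malformed GENEPOP input (message carries the offending line number)."""


@dataclass
class GenotypeTable:
    """Diploid multilocus genotypes with population labels.

    ``calls`` has shape (n_individuals, n_loci, 2) with positive integer
    allele codes; 0 codes a missing allele.  Genotypes are unordered: any
    half-missing call is canonicalised to fully missing on construction.
    """

    ids: list[str]
    populations: list[str]
    loci: list[str]
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int32)
        n, L = len(self.ids), len(self.loci)
        if self.calls.shape != (n, L, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} != ({n}, {L}, 2)"
            )
        if len(self.populations) != n:
            raise ValueError("one population label required per individual")
        if (self.calls < 0).any():
            raise ValueError("allele codes must be non-negative")
        half = (self.calls == MISSING).any(axis=2)
        self.calls[half] = MISSING

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def pop_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p, None)
        return list(seen)

    def pop_mask(self, pop: str) -> np.ndarray:
        return np.asarray([p == pop for p in self.populations])

    def subset(self, pops: list[str]) -> "GenotypeTable":
        keep = np.asarray([p in set(pops) for p in self.populations])
        return GenotypeTable(
            [i for i, k in zip(self.ids, keep) if k],
            [p for p, k in zip(self.populations, keep) if k],
            list(self.loci),
            self.calls[keep].copy(),
        )

    def genotyped_mask(self, locus: int) -> np.ndarray:
        """Individuals with a complete genotype at locus index ``locus``."""
        return (self.calls[:, locus, :] != MISSING).all(axis=1)

    def allele_counts(self, locus: int, pop: str | None = None) -> dict[int, int]:
        mask = self.genotyped_mask(locus)
        if pop is not None:
            mask &= self.pop_mask(pop)
        alleles = self.calls[mask, locus, :].ravel()
        vals, counts = np.unique(alleles, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def genotype_counts(self, locus: int, pop: str | None = None) -> np.ndarray:
        """k x k upper-triangular genotype count matrix at one locus.

        Allele codes are mapped to 0..k-1 in ascending code order; entry
        (i, j), i <= j, counts individuals carrying the unordered pair.
        """
        mask = self.genotyped_mask(locus)
        if pop is not None:
            mask &= self.pop_mask(pop)
        pairs = np.sort(self.calls[mask, locus, :], axis=1)
        codes = np.unique(pairs.ravel())
        lookup = {c: i for i, c in enumerate(codes.tolist())}
        k = len(codes)
        counts = np.zeros((k, k), dtype=np.int64)
        for a, b in pairs:
            counts[lookup[a], lookup[b]] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        data = {"id": self.ids, "population": self.populations}
        for li, locus in enumerate(self.loci):
            data[locus] = [f"{a:03d}/{b:03d}" for a, b in self.calls[:, li, :]]
        return pd.DataFrame(data)


def _parse_locus_names(lines: list[str]) -> tuple[list[str], int]:
    """Locus names may be one per line or comma-separated on one line."""
    loci: list[str] = []
    for idx, raw in enumerate(lines):
        if raw.strip().lower() == "pop":
            return loci, idx
        if "," in raw and not loci:
            loci = [t.strip() for t in raw.split(",") if t.strip()]
            # comma form must be immediately followed by the first Pop line
            nxt = idx + 1
            if nxt < len(lines) and lines[nxt].strip().lower() == "pop":
                return loci, nxt
            # otherwise keep reading one-per-line names
            continue
        loci.append(raw.strip())
    raise GenepopError("no 'Pop' line found")


def _parse_genotype(token: str, lineno: int) -> tuple[int, int]:
    if len(token) == 4:
        w = 2
    elif len(token) == 6:
        w = 3
    else:
        raise GenepopError(
            f"line {lineno}: genotype '{token}' is not 4 or 6 digits wide"
        )
    try:
        a, b = int(token[:w]), int(token[w:])
    except ValueError as exc:
        raise GenepopError(f"line {lineno}: non-numeric genotype '{token}'") from exc
    return a, b


def read_genepop(path, pop_labels: list[str] | None = None) -> GenotypeTable:
    """Parse a GENEPOP file into a :class:`GenotypeTable`.

    Population labels default to the name of the *last* individual in each
    block (the GENEPOP convention); pass ``pop_labels`` to override, or they
    fall back to ``Pop1..PopK`` when the final names are empty.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise GenepopError("file too short to be GENEPOP")
    body = lines[1:]
    loci, pop_at = _parse_locus_names(body)
    if not loci:
        raise GenepopError("no locus names before first 'Pop'")

    ids: list[str] = []
    pops_idx: list[int] = []
    calls: list[list[tuple[int, int]]] = []
    block_last_name: list[str] = []
    block = -1
    block_size = 0
    for off, raw in enumerate(body[pop_at:]):
        lineno = off + pop_at + 2  # 1-based, counting the title line
        line = raw.strip()
        if not line:
            continue
        if line.lower() == "pop":
            if block >= 0 and block_size == 0:
                raise GenepopError(f"line {lineno}: empty population block")
            block += 1
            block_size = 0
            block_last_name.append("")
            continue
        if "," not in line:
            raise GenepopError(f"line {lineno}: expected 'name , genotypes'")
        name, _, rest = line.partition(",")
        tokens = rest.split()
        if len(tokens) != len(loci):
            raise GenepopError(
                f"line {lineno}: {len(tokens)} genotypes for {len(loci)} loci"
            )
        row = [_parse_genotype(t, lineno) for t in tokens]
        ids.append(name.strip() or f"ind{len(ids) + 1}")
        pops_idx.append(block)
        calls.append(row)
        block_last_name[block] = name.strip()
        block_size += 1
    if block < 0:
        raise GenepopError("no population blocks found")
    if block_size == 0:
        raise GenepopError("last population block is empty")

    n_pops = block + 1
    if pop_labels is not None:
        if len(pop_labels) != n_pops:
            raise GenepopError(
                f"{len(pop_labels)} labels supplied for {n_pops} populations"
            )
        labels = list(pop_labels)
    else:
        labels = [
            block_last_name[b] if block_last_name[b] else f"Pop{b + 1}"
            for b in range(n_pops)
        ]
        if len(set(labels)) != n_pops:
            labels = [f"Pop{b + 1}" for b in range(n_pops)]
    populations = [labels[b] for b in pops_idx]
    return GenotypeTable(ids, populations, loci, np.asarray(calls))


def write_genepop(gt: GenotypeTable, path, title: str = "qstfst export",
                  digits: int = 3) -> None:
    fmt = f"{{:0{digits}d}}"
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in gt.loci:
            fh.write(locus + "\n")
        for pop in gt.pop_names:
            fh.write("Pop\n")
            mask = gt.pop_mask(pop)
            for i in np.flatnonzero(mask):
                genos = " ".join(
                    fmt.format(a) + fmt.format(b) for a, b in gt.calls[i]
                )
                fh.write(f"{pop} ,  {genos}\n")
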