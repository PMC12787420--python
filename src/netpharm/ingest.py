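"""Reading and curating the tabular inputs of a multi-herb formulation study.

The upstream data model is a herb--compound table (one row per bioactive
constituent, identified by PubChem CID), a compound-to-gene target map
obtained from literature co-occurrence mining, and a flat disease gene
list.  Curation is deliberately minimal and deterministic: exact
``(herb, CID)`` de-duplication, exclusion of compounds without any mapped
gene target, and symbol normalisation by upper-casing and whitespace
trimming.  No alias resolution is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

logger = logging.getLogger(__name__)

COMPOUND_COLUMNS = ("compound", "pubchem_cid", "herb")
TARGET_COLUMNS = ("compound", "gene")


@dataclass(frozen=True)
class CompoundRecord:
    """One herb--compound row: a named constituent with its PubChem CID."""

    compound_name: str
    pubchem_cid: int
    herb: str

    def __post_init__(self) -> None:
        if not self.compound_name:
            raise ValueError("compound_name must be non-empty")
        if self.pubchem_cid <= 0:
            raise ValueError(f"pubchem_cid must be positive, got {self.pubchem_cid}")


@dataclass
class TargetMapping:
    """Compound name -> set of (uppercase) gene symbols."""

    entries: dict[str, set[str]] = field(default_factory=dict)

    def __contains__(self, compound: str) -> bool:
        return compound in self.entries

    def __getitem__(self, compound: str) -> set[str]:
        return self.entries[compound]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class GeneSet:
    """A labelled set of normalised (uppercase, trimmed) gene symbols."""

    label: str
    genes: set[str] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


def normalize_symbol(symbol: str) -> str:
    return symbol.strip().upper()


def _data_lines(path: str | Path):
    """Yield (1-based line number, line) skipping blanks and '#' comments."""
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def _read_header(lines, required: tuple[str, ...], path) -> dict[str, int]:
    try:
        _, header = next(lines)
    except StopIteration:
        raise ValueError(f"{path}: empty file, expected header {required}")
    cols = [c.strip().lower() for c in header.split("\t")]
    index = {c: i for i, c in enumerate(cols)}
    for col in required:
        if col not in index:
            raise ValueError(f"{path}: missing required column '{col}' (found {cols})")
    return index


def read_compound_table(path: str | Path) -> list[CompoundRecord]:
    """Read a herb--compound TSV and drop exact ``(herb, CID)`` duplicates.

    The same CID may legitimately appear under different herbs (shared
    constituents such as glycyrrhizin), so de-duplication is scoped to the
    (herb, CID) pair.  File order is preserved.

    Raises
    ------
    ValueError
        If a required column is missing, or a CID is not a positive
        integer (the error names the offending line).
    """
    lines = _data_lines(path)
    index = _read_header(lines, COMPOUND_COLUMNS, path)
    records: list[CompoundRecord] = []
    seen: set[tuple[str, int]] = set()
    for lineno, line in lines:
        fields = line.split("\t")
        if len(fields) <= max(index[c] for c in COMPOUND_COLUMNS):
            raise ValueError(f"{path}:{lineno}: expected {len(index)} fields, got {len(fields)}")
        name = fields[index["compound"]].strip()
        herb = fields[index["herb"]].strip()
        raw_cid = fields[index["pubchem_cid"]].strip()
        try:
            cid = int(raw_cid)
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-integer PubChem CID {raw_cid!r}") from None
        key = (herb, cid)
        if key in seen:
            continue
        seen.add(key)
        records.append(CompoundRecord(compound_name=name, pubchem_cid=cid, herb=herb))
    return records


def write_compound_table(records: Iterable[CompoundRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(COMPOUND_COLUMNS) + "\n")
        for rec in records:
            fh.write(f"{rec.compound_name}\t{rec.pubchem_cid}\t{rec.herb}\n")


def read_target_map(path: str | Path) -> TargetMapping:
    """Read a compound->gene TSV into a :class:`TargetMapping`.

    Gene symbols are upper-cased and trimmed; duplicate (compound, gene)
    rows collapse.  Rows with an empty gene field are skipped with a
    logged warning rather than aborting the load.
    """
    lines = _data_lines(path)
    try:
        index = _read_header(lines, TARGET_COLUMNS, path)
    except ValueError as err:
        if "empty file" in str(err):
            return TargetMapping()
        raise
    mapping: dict[str, set[str]] = {}
    for lineno, line in lines:
        fields = line.split("\t")
        if len(fields) < 2:
            logger.warning("%s:%d: row has no gene field, skipped", path, lineno)
            continue
        compound = fields[index["compound"]].strip()
        gene = normalize_symbol(fields[index["gene"]])
        if not gene:
            logger.warning("%s:%d: empty gene symbol for %r, skipped", path, lineno, compound)
            continue
        mapping.setdefault(compound, set()).add(gene)
    return TargetMapping(entries=mapping)


def write_target_map(mapping: TargetMapping, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(TARGET_COLUMNS) + "\n")
        for compound in sorted(mapping.entries):
            for gene in sorted(mapping.entries[compound]):
                fh.write(f"{compound}\t{gene}\n")


def read_gene_list(path: str | Path, label: str = "genes") -> GeneSet:
    """Read a one-symbol-per-line gene list (blank and '#' lines ignored)."""
    genes: set[str] = set()
    for _, line in _data_lines(path):
        symbol = normalize_symbol(line)
        if symbol:
            genes.add(symbol)
    return GeneSet(label=label, genes=genes)


def write_gene_list(genes: Iterable[str] | GeneSet, path: str | Path) -> None:
    if isinstance(genes, GeneSet):
        genes = genes.genes
    with open(path, "w", encoding="utf-8") as fh:
        for gene in sorted(genes):
            fh.write(gene + "\n")


def drop_targetless(records: list[CompoundRecord], mapping: TargetMapping) -> list[CompoundRecord]:
    """Keep only compounds with at least one mapped gene target.

    Mirrors the curation step that excludes constituents lacking
    literature-based target annotations.  Original order is preserved.
    """
    return [rec for rec in records if rec.compound_name in mapping]


def union_targets(mapping: TargetMapping, records: list[CompoundRecord]) -> GeneSet:
    """Union of the target sets of the (curated) compound records."""
    genes: set[str] = set()
    for rec in records:
        genes |= mapping.entries.get(rec.compound_name, set())
    return GeneSet(label="predicted_targets", genes=genes)


def per_herb_counts(records: list[CompoundRecord]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for rec in records:
        counts[rec.herb] = counts.get(rec.herb, 0) + 1
    return counts


def reference_compound_path() -> Path:
    """Path of the packaged Mecasin herb--compound table (192 constituents)."""
    return Path(resources.files("netpharm") / "fixtures" / "mecasin_compounds.tsv")


def load_reference_compounds() -> list[CompoundRecord]:
    """The packaged nine-herb Mecasin constituent table as curated records."""
    return read_compound_table(reference_compound_path())
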