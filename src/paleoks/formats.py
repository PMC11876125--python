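"""Readers and writers for every on-disk artifact the pipeline touches.

All tables are UTF-8 tab-separated text with Unix newlines and ``NA`` for
missing values.  The collinearity dialect is one gene pair per line with
columns ``block_id``, ``species``, ``gene_a``, ``gene_b``; ``#`` starts a
comment line.  Parsers validate the type invariants and raise
:class:`FormatError` naming the offending line where possible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO


class FormatError(ValueError):
    """Raised when an input file violates the format contract."""


# ---------------------------------------------------------------------------
# domain types


@dataclass
class CollinearBlock:
    """A syntenic block: ordered paralog gene pairs within one species.

    The block is the unit over which the median Ks is taken downstream.
    """

    block_id: str
    species: str
    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.pairs:
            raise FormatError(
                f"block {self.block_id!r} of {self.species!r} has no pairs"
            )
        for a, b in self.pairs:
            if a == b:
                raise FormatError(
                    f"block {self.block_id!r}: self-pair {a!r}"
                )

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class SpeciesMeta:
    """Per-species metadata: polyploidy rounds and reference status.

    ``rounds`` counts polyploidy events affecting the lineage (the shared
    core-eudicot triplication counts as one).  ``group`` is derived:
    one round -> ``P1R``, two or more -> ``P2R``.
    """

    species: str
    rounds: int
    is_reference: bool = False

    def __post_init__(self) -> None:
        if self.rounds < 1:
            raise FormatError(
                f"{self.species!r}: rounds must be >= 1, got {self.rounds}"
            )

    @property
    def group(self) -> str:
        return "P1R" if self.rounds == 1 else "P2R"


KS_COLUMNS = ["species", "block_id", "gene_a", "gene_b", "ks", "ka"]


# ---------------------------------------------------------------------------
# collinearity


def read_collinearity(path: str | Path) -> list[CollinearBlock]:
    """Parse a collinearity file into blocks, preserving pair order.

    Blank lines and ``#`` comments are skipped.  Duplicate
    (species, block_id, pair) rows are rejected.
    """
    path = Path(path)
    order: list[tuple[str, str]] = []  # (species, block_id) first-seen order
    pairs: dict[tuple[str, str], list[tuple[str, str]]] = {}
    seen_rows: set[tuple[str, str, str, str]] = set()
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise FormatError(
                    f"{path}:{lineno}: expected 4 tab-separated fields, "
                    f"got {len(fields)}"
                )
            block_id, species, gene_a, gene_b = (f.strip() for f in fields)
            if not all((block_id, species, gene_a, gene_b)):
                raise FormatError(f"{path}:{lineno}: empty field")
            if gene_a == gene_b:
                raise FormatError(
                    f"{path}:{lineno}: gene paired with itself ({gene_a!r})"
                )
            row = (species, block_id, gene_a, gene_b)
            if row in seen_rows:
                raise FormatError(f"{path}:{lineno}: duplicate pair {row}")
            seen_rows.add(row)
            key = (species, block_id)
            if key not in pairs:
                pairs[key] = []
                order.append(key)
            pairs[key].append((gene_a, gene_b))
    return [
        CollinearBlock(block_id=bid, species=sp, pairs=pairs[(sp, bid)])
        for sp, bid in order
    ]


def write_collinearity(blocks: Iterable[CollinearBlock], path: str | Path) -> None:
    """Write blocks in the one-pair-per-line dialect (round-trips with
    :func:`read_collinearity`)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("# block_id\tspecies\tgene_a\tgene_b\n")
        for block in blocks:
            for a, b in block.pairs:
                fh.write(f"{block.block_id}\t{block.species}\t{a}\t{b}\n")


# ---------------------------------------------------------------------------
# Ks tables


def read_ks_table(path: str | Path) -> pd.DataFrame:
    """Read a Ks table TSV with columns species, block_id, gene_a, gene_b,
    ks, ka (``NA`` for missing ka).  Negative ks is rejected, as are
    duplicate (species, gene_a, gene_b) rows."""
    path = Path(path)
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        na_values=["NA"],
        keep_default_na=False,
        dtype={
            "species": str,
            "block_id": str,
            "gene_a": str,
            "gene_b": str,
            "ks": float,
            "ka": float,
        },
    )
    missing = [c for c in KS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df = df[KS_COLUMNS]
    validate_ks_table(df, source=str(path))
    return df.reset_index(drop=True)


def validate_ks_table(df: pd.DataFrame, source: str = "ks table") -> None:
    if (df["ks"].dropna() < 0).any():
        raise FormatError(f"{source}: negative ks value")
    if (df["ka"].dropna() < 0).any():
        raise FormatError(f"{source}: negative ka value")
    dup = df.duplicated(subset=["species", "gene_a", "gene_b"])
    if dup.any():
        first = df[dup].iloc[0]
        raise FormatError(
            f"{source}: duplicate pair "
            f"({first['species']}, {first['gene_a']}, {first['gene_b']})"
        )


def write_ks_table(df: pd.DataFrame, path: str | Path,
                   header_comment: str | None = None) -> None:
    """Write a Ks table TSV; missing ka is encoded as ``NA``."""
    path = Path(path)
    validate_ks_table(df, source="ks table (write)")
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df[KS_COLUMNS].to_csv(fh, sep="\t", index=False, na_rep="NA",
                              float_format="%.6g", lineterminator="\n")


# ---------------------------------------------------------------------------
# FASTA / annotation / species metadata


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an id -> upper-cased sequence map; duplicate ids are
    an error."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise FormatError(f"{path}: duplicate FASTA id {record.id!r}")
        sequences[record.id] = str(record.seq).upper()
    return sequences


def write_fasta(sequences: dict[str, str], path: str | Path,
                width: int = 60) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_annotation(path: str | Path) -> dict[str, list[str]]:
    """Read a gene<TAB>category annotation table.

    A gene may appear on several lines; its categories accumulate in file
    order (duplicates within a gene are kept once).  Genes with no category
    are dropped with a warning.
    """
    path = Path(path)
    annot: dict[str, list[str]] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected gene<TAB>category"
                )
            gene, category = fields[0].strip(), fields[1].strip()
            if not gene:
                raise FormatError(f"{path}:{lineno}: empty gene id")
            if not category:
                warnings.warn(
                    f"{path}:{lineno}: gene {gene!r} has empty category; "
                    "line dropped"
                )
                continue
            cats = annot.setdefault(gene, [])
            if category not in cats:
                cats.append(category)
    return annot


def write_annotation(annot: dict[str, list[str]], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("# gene\tcategory\n")
        for gene, cats in annot.items():
            for cat in cats:
                fh.write(f"{gene}\t{cat}\n")


def read_species_meta(path: str | Path) -> list[SpeciesMeta]:
    """Read the species metadata TSV (species, rounds, is_reference).

    Exactly one species may carry the reference flag; the derived P1R/P2R
    group is recomputed from ``rounds``, never read.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"species": str, "rounds": int})
    for col in ("species", "rounds", "is_reference"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    metas = [
        SpeciesMeta(
            species=row.species,
            rounds=int(row.rounds),
            is_reference=_parse_bool(row.is_reference, path),
        )
        for row in df.itertuples()
    ]
    names = [m.species for m in metas]
    if len(set(names)) != len(names):
        raise FormatError(f"{path}: duplicate species name")
    n_ref = sum(m.is_reference for m in metas)
    if n_ref != 1:
        raise FormatError(
            f"{path}: exactly one reference species required, found {n_ref}"
        )
    return metas


def write_species_meta(metas: Iterable[SpeciesMeta], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("species\trounds\tis_reference\n")
        for m in metas:
            fh.write(f"{m.species}\t{m.rounds}\t{str(m.is_reference).lower()}\n")


def _parse_bool(value: object, path: Path) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in {"true", "1", "yes"}:
        return True
    if text in {"false", "0", "no"}:
        return False
    raise FormatError(f"{path}: cannot parse boolean {value!r}")
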