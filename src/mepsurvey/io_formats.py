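"""Readers, writers and genetic-code tables for the survey's external formats.

Genome assemblies arrive as nucleotide FASTA (one file per genome, one or
more contigs); protein families arrive as aligned amino-acid FASTA; the
pipeline's tabular outputs (gene presence/absence matrices, census tables)
are plain tab-separated text so they diff cleanly between runs.

Genetic codes: almost all bacteria use the standard code (table 1); the
Mollicutes genera *Spiroplasma*, *Mycoplasma*, *Mycoplasmoides*,
*Malacoplasma* and *Ureaplasma* read TGA as tryptophan and are translated
with table 4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable

from .errors import ConfigError, FormatError

# ---------------------------------------------------------------------------
# Genetic codes

#: Genera translated with codon table 4 (TGA = Trp); lowercase for matching.
TABLE4_GENERA = frozenset(
    {"spiroplasma", "mycoplasma", "mycoplasmoides", "malacoplasma", "ureaplasma"}
)


def _make_codon_table(table_id: int) -> tuple[dict, frozenset]:
    t = CodonTable.unambiguous_dna_by_id[table_id]
    return dict(t.forward_table), frozenset(t.stop_codons)


#: table id -> (codon -> amino acid, stop codon set)
CODON_TABLES: dict[int, tuple[dict, frozenset]] = {
    1: _make_codon_table(1),
    4: _make_codon_table(4),
}

#: table id -> amino acid -> tuple of synonymous codons
SYNONYMOUS_CODONS: dict[int, dict[str, tuple[str, ...]]] = {}
for _tid, (_fwd, _stops) in CODON_TABLES.items():
    _by_aa: dict[str, list[str]] = {}
    for _codon, _aa in sorted(_fwd.items()):
        _by_aa.setdefault(_aa, []).append(_codon)
    SYNONYMOUS_CODONS[_tid] = {aa: tuple(c) for aa, c in _by_aa.items()}


def assign_genetic_code(genus: str, override: Optional[int] = None) -> int:
    """Return the NCBI translation-table id for a genus.

    Table 4 for the five Mollicutes genera (case-insensitive exact match),
    table 1 otherwise. An explicit ``override`` wins when given.
    """
    if override is not None:
        if override not in (1, 4):
            raise ConfigError(f"genetic-code override must be 1 or 4, got {override!r}")
        return override
    if not genus:
        raise ConfigError("genus must be a nonempty string")
    return 4 if genus.strip().lower() in TABLE4_GENERA else 1


def genus_of(species_name: str) -> str:
    """First whitespace-delimited token of a binomial species name."""
    parts = species_name.split()
    return parts[0] if parts else ""


# ---------------------------------------------------------------------------
# Domain types

_NT_OK = frozenset("ACGTN")
# IUPAC ambiguity codes other than N collapse to N
_NT_AMBIG = frozenset("RYSWKMBDHV")


def _normalize_nt(seq: str, source: str) -> str:
    s = seq.upper().replace("U", "T")
    if set(s) <= _NT_OK:
        return s
    bad = set(s) - _NT_OK
    if bad <= _NT_AMBIG:
        warnings.warn(
            f"{source}: IUPAC ambiguity codes {sorted(bad)} collapsed to N",
            stacklevel=3,
        )
        return s.translate(str.maketrans({c: "N" for c in _NT_AMBIG}))
    raise FormatError(f"{source}: non-nucleotide characters {sorted(bad - _NT_AMBIG)}")


@dataclass
class GenomeRecord:
    """One genome: its contigs, taxonomy labels and translation table."""

    genome_id: str
    contigs: list[tuple[str, str]]
    species_name: str = ""
    genus: str = ""
    genetic_code: int = 1

    def __post_init__(self) -> None:
        if self.genetic_code not in (1, 4):
            raise ConfigError(
                f"{self.genome_id}: genetic_code must be 1 or 4, got {self.genetic_code}"
            )
        if not self.genus and self.species_name:
            self.genus = genus_of(self.species_name)

    @property
    def genome_size(self) -> int:
        """Total assembly length in bp (sum of contig lengths)."""
        return sum(len(s) for _, s in self.contigs)


@dataclass
class FamilyAlignment:
    """A protein-family multiple sequence alignment ('-' is the gap char)."""

    family_id: str
    aligned_sequences: list[tuple[str, str]]
    columns: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.aligned_sequences:
            raise FormatError(f"{self.family_id}: empty alignment")
        lengths = {len(s) for _, s in self.aligned_sequences}
        if len(lengths) != 1:
            raise FormatError(
                f"{self.family_id}: ragged alignment (row lengths {sorted(lengths)})"
            )
        self.columns = lengths.pop()


@dataclass
class TrainingSet:
    """Curated positives (family members) and negatives for calibration."""

    family_id: str
    positives: list[tuple[str, str]]
    negatives: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.positives:
            raise ConfigError(f"{self.family_id}: positives must be nonempty")
        pos_ids = {i for i, _ in self.positives}
        neg_ids = {i for i, _ in self.negatives}
        if pos_ids & neg_ids:
            raise ConfigError(
                f"{self.family_id}: positive and negative ids overlap: "
                f"{sorted(pos_ids & neg_ids)[:5]}"
            )


# ---------------------------------------------------------------------------
# FASTA

def read_genome_fasta(
    path,
    genome_id: Optional[str] = None,
    genetic_code: int = 1,
    species_name: str = "",
    genus: str = "",
) -> GenomeRecord:
    """Read a (multi-)contig nucleotide FASTA into a :class:`GenomeRecord`.

    Sequences are uppercased, U is mapped to T, and IUPAC ambiguity codes
    other than N are collapsed to N with a warning. All records in the file
    are treated as contigs of one genome.
    """
    path = Path(path)
    contigs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        contigs.append((rec.id, _normalize_nt(str(rec.seq), f"{path.name}:{rec.id}")))
    if not contigs:
        raise FormatError(f"{path}: no FASTA records")
    return GenomeRecord(
        genome_id=genome_id or path.stem,
        contigs=contigs,
        species_name=species_name,
        genus=genus,
        genetic_code=genetic_code,
    )


def write_fasta(records: Sequence[tuple[str, str]], path, width: int = 70) -> None:
    """Write (id, sequence) pairs as FASTA with fixed line width."""
    with open(path, "w", newline="\n") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_protein_fasta(path) -> list[tuple[str, str]]:
    """Read an amino-acid FASTA as (id, uppercase sequence) pairs."""
    out = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not out:
        raise FormatError(f"{path}: no FASTA records")
    return out


def read_alignment(path, family_id: Optional[str] = None) -> FamilyAlignment:
    """Read an aligned amino-acid FASTA; all rows must be equal length."""
    path = Path(path)
    seqs = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not seqs:
        raise FormatError(f"{path}: no FASTA records")
    return FamilyAlignment(family_id=family_id or path.stem, aligned_sequences=seqs)


# ---------------------------------------------------------------------------
# Presence/absence matrix TSV (tab-separated, UTF-8, Unix newlines)

def write_presence_matrix(matrix, path) -> None:
    """Write a :class:`~mepsurvey.ortholog_caller.GenePresenceMatrix` as TSV.

    Header row is ``genome_id`` followed by one column per gene role;
    cells are 0/1.
    """
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(["genome_id", *matrix.roles]) + "\n")
        for gi, gid in enumerate(matrix.genome_ids):
            cells = [str(int(v)) for v in matrix.present[gi]]
            fh.write("\t".join([gid, *cells]) + "\n")


def read_presence_matrix(path, roles: Optional[Sequence[str]] = None):
    """Read a presence/absence TSV back into a GenePresenceMatrix.

    ``roles``: the set of known gene-role names used to validate columns;
    defaults to the pipeline's curated 16-role list.
    """
    import numpy as np

    from .ortholog_caller import ALL_ROLES, GenePresenceMatrix

    known = set(ALL_ROLES if roles is None else roles)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    if not lines:
        raise FormatError(f"{path}: empty matrix file")
    header = lines[0].split("\t")
    if header[0] != "genome_id":
        raise FormatError(f"{path}: first column must be 'genome_id'")
    cols = header[1:]
    unknown = [c for c in cols if c not in known]
    if unknown:
        raise ConfigError(f"{path}: unknown gene-role columns {unknown}")
    genome_ids, rows = [], []
    for ln in lines[1:]:
        parts = ln.split("\t")
        if len(parts) != len(cols) + 1:
            raise FormatError(f"{path}: row has {len(parts)} fields, expected {len(cols) + 1}")
        genome_ids.append(parts[0])
        rows.append([bool(int(v)) for v in parts[1:]])
    present = np.array(rows, dtype=bool).reshape(len(genome_ids), len(cols))
    return GenePresenceMatrix(genome_ids=genome_ids, roles=list(cols), present=present)
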