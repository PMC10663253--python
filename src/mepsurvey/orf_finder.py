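"""Six-frame open-reading-frame extraction and translation.

Scans both strands of every contig in all three frames and reports each
ORF of at least ``min_length`` nucleotides (start codon through stop codon
inclusive) together with its peptide translation. Conventions:

* Start codons: ATG only by default (extensible via ``start_codons``).
* Nested starts: only the 5'-most qualifying start per (frame, stop codon)
  is reported, so each stop yields at most one ORF per frame.
* ORFs running off a contig end without a stop are reported if long enough
  and flagged with ``has_stop=False`` (draft-assembly tolerance).
* Coordinates are 0-based half-open on the forward strand of the contig.
* Codons containing N translate to X and never act as stop or start codons.
* Under table 4 (Mollicutes) TGA encodes tryptophan, not stop.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigError
from .io_formats import CODON_TABLES, GenomeRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(codons: str, table: int = 1) -> str:
    """Translate a nucleotide string, stopping at the first stop codon.

    The input length must be divisible by 3. Codons containing N are
    translated as X and do not terminate translation.
    """
    if table not in CODON_TABLES:
        raise ConfigError(f"unsupported translation table {table}")
    if len(codons) % 3 != 0:
        raise ValueError(f"sequence length {len(codons)} not divisible by 3")
    fwd, stops = CODON_TABLES[table]
    out = []
    for i in range(0, len(codons), 3):
        codon = codons[i : i + 3]
        if "N" in codon:
            out.append("X")
        elif codon in stops:
            break
        else:
            out.append(fwd[codon])
    return "".join(out)


@dataclass
class ORF:
    """One open reading frame, in forward-strand coordinates."""

    orf_id: str
    genome_id: str
    contig_id: str
    start: int  # 0-based inclusive, forward strand
    end: int    # exclusive
    strand: str  # '+' or '-'
    frame: int  # 0/1/2 on the scanned strand
    nt_length: int  # includes the stop codon when present
    peptide: str  # translation, stop symbol excluded
    has_stop: bool = True


def _scan_frames(seq: str, table: int, min_length: int, start_codons: frozenset):
    """Yield (start, end, frame, has_stop) in local coordinates of ``seq``."""
    _, stops = CODON_TABLES[table]
    n = len(seq)
    for frame in range(3):
        pending = None
        p = frame
        while p + 3 <= n:
            codon = seq[p : p + 3]
            if "N" not in codon and codon in stops:
                if pending is not None and p + 3 - pending >= min_length:
                    yield pending, p + 3, frame, True
                pending = None
            elif pending is None and codon in start_codons:
                pending = p
            p += 3
        if pending is not None and p - pending >= min_length:
            # ran off the contig end without a stop; p is the end of the
            # last complete codon in this frame
            yield pending, p, frame, False


def find_orfs(
    genome: GenomeRecord,
    min_length: int = 150,
    start_codons=("ATG",),
) -> list[ORF]:
    """All ORFs of the genome, both strands, all frames.

    Deterministic order: contigs in genome order; per contig strand '+'
    then '-'; within a strand ascending forward-strand start.
    """
    if min_length < 3:
        raise ConfigError(f"min_length must be >= 3, got {min_length}")
    starts = frozenset(start_codons)
    table = genome.genetic_code
    orfs: list[ORF] = []
    for contig_id, seq in genome.contigs:
        n = len(seq)
        for strand in "+-":
            local = seq if strand == "+" else reverse_complement(seq)
            found = []
            for s, e, frame, has_stop in _scan_frames(local, table, min_length, starts):
                if strand == "+":
                    fs, fe = s, e
                else:
                    fs, fe = n - e, n - s
                pep_region = local[s : e - 3] if has_stop else local[s:e]
                found.append(
                    ORF(
                        orf_id=f"{genome.genome_id}|{contig_id}|{fs}|{fe}|{strand}",
                        genome_id=genome.genome_id,
                        contig_id=contig_id,
                        start=fs,
                        end=fe,
                        strand=strand,
                        frame=frame,
                        nt_length=e - s,
                        peptide=translate(pep_region, table),
                        has_stop=has_stop,
                    )
                )
            found.sort(key=lambda o: o.start)
            orfs.extend(found)
    return orfs


def write_orf_fasta(orfs: list[ORF], path) -> None:
    """Write ORF peptides as amino-acid FASTA (header = orf_id)."""
    from .io_formats import write_fasta

    write_fasta([(o.orf_id, o.peptide) for o in orfs], path)
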