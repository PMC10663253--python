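"""Six-frame ORF extraction under the standard and Mollicutes genetic codes.

Builds a small two-gene contig and shows how the translation table changes
which reading frames survive: under table 4, TGA encodes tryptophan instead
of stop, so TGA-containing frames stay open.
"""

from mepsurvey import GenomeRecord, find_orfs

# gene 1: 50 lysines; gene 2 contains an internal TGA codon
gene1 = "ATG" + "AAA" * 50 + "TAA"
gene2 = "ATG" + "AAA" * 24 + "TGA" + "AAA" * 26 + "TAA"
contig = "TAGTAA" + gene1 + "TAACTA" + gene2 + "TAGTAG"

for table in (1, 4):
    genome = GenomeRecord("demo", [("c1", contig)], genetic_code=table)
    orfs = find_orfs(genome, min_length=150)
    print(f"translation table {table}: {len(orfs)} ORF(s) of >= 150 nt")
    for o in orfs:
        print(
            f"  {o.start:4d}-{o.end:<4d} {o.strand} frame {o.frame} "
            f"{o.nt_length:3d} nt  peptide {o.peptide[:12]}... ({len(o.peptide)} aa)"
        )

# Under table 1 the TGA inside gene 2 terminates translation early, so only
# gene 1 reaches the 150 nt threshold; under table 4 the same codon reads
# as Trp (W) and gene 2 is reported as a single long ORF.
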