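"""Synthetic genomes, protein families and training sets with planted truth.

Every pipeline input can be generated here with controlled statistical
structure, so the whole survey is testable without any external database:

* ``make_family`` draws an ancestor peptide from the background and evolves
  family members by i.i.d. per-site substitution at a controlled divergence
  (no indels by default, so the columnwise alignment is trivially correct).
  Negatives are shuffled members plus length-matched background peptides.
* ``make_genome`` reverse-translates one member peptide per present gene
  role (uniform choice among synonymous codons under the genome's
  translation table), wraps it in a start and stop codon, and embeds it on
  a random strand between stop-rich intergenic spacers, recording planted
  coordinates as ground truth. Decoy genes encoding unrelated random
  peptides are planted the same way.
* ``make_cohort`` expands a class-level genotype composition (e.g. "23
  candidates missing only Dxs") into per-genome genotypes and emits
  genomes, families, taxonomy and the truth tables.

Spacers are concatenations of the codon tokens TAA/TAG/CTA/TTA — stop
codons on the forward strand and reverse complements of stops — with rare
random phase-shift nucleotides, so every reading frame on both strands hits
a stop within a few codons and spurious ORFs cannot reach the 150 nt
reporting threshold inside intergenic sequence. All randomness flows from a
single integer seed: the same seed reproduces byte-identical FASTA output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError
from .io_formats import (
    CODON_TABLES,
    SYNONYMOUS_CODONS,
    FamilyAlignment,
    GenomeRecord,
    TrainingSet,
    assign_genetic_code,
)
from .orf_finder import reverse_complement, translate
from .ortholog_caller import ALL_ROLES
from .phmm import AMINO_ACIDS

_SPACER_TOKENS = ("TAA", "TAG", "CTA", "TTA")


# ---------------------------------------------------------------------------
# Families

@dataclass
class FamilySpec:
    family_id: str
    ancestor_length: int = 300  # aa; >= 50 so planted genes exceed 150 nt
    n_members: int = 30
    divergence: float = 0.1  # per-site substitution probability
    indel_rate: float = 0.0  # per-site deletion probability (gapped families)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ancestor_length < 50:
            raise ConfigError("ancestor_length must be >= 50")
        if not 0.0 <= self.divergence <= 0.5:
            raise ConfigError("divergence must be in [0, 0.5]")


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


def _mutate(rng: np.random.Generator, peptide: str, divergence: float) -> str:
    out = []
    for a in peptide:
        if rng.random() < divergence:
            # substitute with one of the 19 other residues, uniformly
            j = rng.integers(0, 19)
            b = AMINO_ACIDS[j if AMINO_ACIDS[j] != a else 19]
            out.append(b)
        else:
            out.append(a)
    return "".join(out)


def make_family(spec: FamilySpec) -> tuple[FamilyAlignment, TrainingSet]:
    """A synthetic protein family: trivial alignment plus training sets."""
    rng = np.random.default_rng(spec.seed)
    ancestor = _random_peptide(rng, spec.ancestor_length)
    aligned, positives = [], []
    for i in range(spec.n_members):
        member = _mutate(rng, ancestor, spec.divergence)
        if spec.indel_rate > 0:
            gapped = "".join(
                "-" if rng.random() < spec.indel_rate else a for a in member
            )
        else:
            gapped = member
        aligned.append((f"{spec.family_id}_pos{i}", gapped))
        positives.append((f"{spec.family_id}_pos{i}", gapped.replace("-", "")))
    negatives = []
    for i, (_, seq) in enumerate(positives):
        shuffled = "".join(rng.permutation(list(seq)))
        negatives.append((f"{spec.family_id}_shuf{i}", shuffled))
        negatives.append(
            (f"{spec.family_id}_rand{i}", _random_peptide(rng, len(seq)))
        )
    alignment = FamilyAlignment(
        family_id=spec.family_id, aligned_sequences=aligned
    )
    training = TrainingSet(
        family_id=spec.family_id, positives=positives, negatives=negatives
    )
    return alignment, training


# ---------------------------------------------------------------------------
# Genomes

@dataclass
class PlantedGene:
    genome_id: str
    role: Optional[str]  # None for decoys
    contig_id: str
    start: int
    end: int
    strand: str
    peptide: str  # translation of the planted ORF (leading M included)


def _spacer(rng: np.random.Generator, mean_length: int, gc: float) -> str:
    n_tokens = max(4, int(rng.poisson(max(mean_length, 12) / 3)))
    parts = []
    for _ in range(n_tokens):
        parts.append(_SPACER_TOKENS[rng.integers(0, len(_SPACER_TOKENS))])
        if rng.random() < 0.1:  # rare phase-shift nucleotide
            parts.append("GC"[rng.integers(0, 2)] if rng.random() < gc
                         else "AT"[rng.integers(0, 2)])
    return "".join(parts)


def _reverse_translate(
    rng: np.random.Generator, peptide: str, table: int
) -> tuple[str, str]:
    """Build a gene cassette (ATG ... stop) for a peptide; returns
    (nucleotide cassette, translated peptide of the cassette)."""
    syn = SYNONYMOUS_CODONS[table]
    _, stops = CODON_TABLES[table]
    if peptide[0] != "M":
        peptide = "M" + peptide
    codons = []
    for aa in peptide:
        options = syn[aa]
        codons.append(options[rng.integers(0, len(options))])
    stops_sorted = sorted(stops)
    codons.append(stops_sorted[rng.integers(0, len(stops_sorted))])
    cassette = "".join(codons)
    assert translate(cassette, table) == peptide, "planted gene is not a clean ORF"
    return cassette, peptide


def make_genome(
    genome_id: str,
    genotype: dict[str, bool],
    families: dict[str, list[str]],
    genetic_code: int = 1,
    seed: int = 0,
    intergenic_length_mean: int = 60,
    genome_gc: float = 0.5,
    n_decoys: int = 2,
    species_name: str = "",
    genus: str = "",
) -> tuple[GenomeRecord, list[PlantedGene]]:
    """One synthetic genome with planted family members and decoy genes.

    ``families`` maps role -> member peptides; one member is chosen at
    random for each role marked present. Returns the genome and the planted
    truth table (forward-strand half-open coordinates, stop codon included).
    """
    rng = np.random.default_rng(seed)
    present_roles = [r for r in ALL_ROLES if genotype.get(r, False)]
    extra = [r for r in genotype if genotype[r] and r not in ALL_ROLES]
    if extra:
        present_roles += sorted(extra)
    for role in present_roles:
        if role not in families:
            raise ConfigError(f"{genome_id}: role {role} present but has no family")

    inserts: list[tuple[Optional[str], str]] = []  # (role or None, peptide)
    for role in present_roles:
        members = families[role]
        inserts.append((role, members[rng.integers(0, len(members))]))
    for _ in range(n_decoys):
        inserts.append((None, _random_peptide(rng, int(rng.integers(55, 90)))))

    parts = [_spacer(rng, intergenic_length_mean, genome_gc)]
    offset = len(parts[0])
    planted: list[PlantedGene] = []
    for role, pep in inserts:
        cassette, full_pep = _reverse_translate(rng, pep, genetic_code)
        strand = "+-"[rng.integers(0, 2)]
        seq = cassette if strand == "+" else reverse_complement(cassette)
        planted.append(
            PlantedGene(
                genome_id=genome_id,
                role=role,
                contig_id="c1",
                start=offset,
                end=offset + len(seq),
                strand=strand,
                peptide=full_pep,
            )
        )
        parts.append(seq)
        offset += len(seq)
        spacer = _spacer(rng, intergenic_length_mean, genome_gc)
        parts.append(spacer)
        offset += len(spacer)
    contig = "".join(parts)
    genome = GenomeRecord(
        genome_id=genome_id,
        contigs=[("c1", contig)],
        species_name=species_name,
        genus=genus,
        genetic_code=genetic_code,
    )
    return genome, planted


# ---------------------------------------------------------------------------
# Cohorts

@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort.

    ``genotype_plan`` is either a class-level composition
    (``{"MEP_only": 341, "MVA_only": 54, ...}``) expanded into per-genome
    genotypes, or an explicit list of per-genome role->bool maps.
    """

    genotype_plan: dict | list
    divergence: float = 0.1
    intergenic_length_mean: int = 60
    genome_gc: float = 0.5
    seed: int = 0
    n_members: int = 30
    ancestor_length: int = 300
    n_decoys: int = 2
    #: fraction of candidate genomes carrying both shunt genes / only the
    #: methylsulfurase (exercises the MTA-shunt flags end to end)
    shunt_both_fraction: float = 0.10
    shunt_methyl_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.divergence <= 0.5:
            raise ConfigError("divergence must be in [0, 0.5]")


@dataclass
class SyntheticCohort:
    spec: CohortSpec
    genomes: list[GenomeRecord]
    families: dict[str, tuple[FamilyAlignment, TrainingSet]]
    truth_presence: dict[str, dict[str, bool]]  # genome_id -> role -> bool
    expected_class: dict[str, str]
    planted: list[PlantedGene]
    taxonomy: dict[str, str]  # genome_id -> genus

    @property
    def genome_sizes(self) -> dict[str, int]:
        return {g.genome_id: g.genome_size for g in self.genomes}


_MVA_SLOT_ROLES = {
    "HMGS": ("HMGS",),
    "HMGR": ("HMGRI", "HMGRII"),
    "MVK": ("MVK",),
    "DPMD": ("DPMD",),
}
_MVA_SLOT_ORDER = ("HMGS", "HMGR", "MVK", "DPMD")


def _pick(rng: np.random.Generator, options: Sequence[str]) -> str:
    return options[rng.integers(0, len(options))]


def _complete_mep(rng: np.random.Generator) -> dict[str, bool]:
    roles = {"Dxs": True, "IspE": True, "IspG": True, "IspH": True}
    roles[_pick(rng, ("DxrI", "DxrII"))] = True
    if rng.random() < 0.25:  # bifunctional fusion satisfies both slots
        roles["IspDF"] = True
    else:
        roles["IspD"] = True
        roles["IspF"] = True
    return roles


def _mva_genes(rng: np.random.Generator, n_slots: int) -> dict[str, bool]:
    slots = list(_MVA_SLOT_ORDER)
    rng.shuffle(slots)
    out: dict[str, bool] = {}
    for slot in slots[:n_slots]:
        out[_pick(rng, _MVA_SLOT_ROLES[slot])] = True
    return out


def _genotype_for_class(cls: str, rng: np.random.Generator,
                        spec: CohortSpec) -> dict[str, bool]:
    g: dict[str, bool] = {}
    if cls == "MEP_only":
        g.update(_complete_mep(rng))
    elif cls == "both":
        g.update(_complete_mep(rng))
        g.update(_mva_genes(rng, int(rng.integers(2, 5))))
    elif cls == "MVA_only":
        g.update(_mva_genes(rng, int(rng.integers(2, 5))))
        # an incomplete scattering of MEP genes (never all 7 slots)
        for role in ("Dxs", "IspE", "IspG"):
            if rng.random() < 0.3:
                g[role] = True
    elif cls == "neither":
        if rng.random() < 0.3:  # at most one stray MVA gene
            g.update(_mva_genes(rng, 1))
    elif cls == "candidate":
        g.update(_complete_mep(rng))
        g["Dxs"] = False  # missing Dxs only: the dominant candidate pattern
        if rng.random() < 0.3:
            g.update(_mva_genes(rng, 1))
        u = rng.random()
        if u < spec.shunt_both_fraction:
            g["MTRu1P_isomerase"] = True
            g["MTXu5P_methylsulfurase"] = True
        elif u < spec.shunt_both_fraction + spec.shunt_methyl_fraction:
            g["MTXu5P_methylsulfurase"] = True
    else:
        raise ConfigError(f"unknown genotype class {cls!r}")
    return g


def make_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Families plus genomes for a full synthetic survey, deterministic in
    ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    fam_seeds = rng.integers(0, 2**31 - 1, size=len(ALL_ROLES))
    families = {}
    member_peps: dict[str, list[str]] = {}
    for role, fseed in zip(ALL_ROLES, fam_seeds):
        aln, training = make_family(
            FamilySpec(
                family_id=role,
                ancestor_length=spec.ancestor_length,
                n_members=spec.n_members,
                divergence=spec.divergence,
                seed=int(fseed),
            )
        )
        families[role] = (aln, training)
        member_peps[role] = [s for _, s in training.positives]

    if isinstance(spec.genotype_plan, dict):
        plan: list[tuple[str, dict[str, bool]]] = []
        for cls in ("MEP_only", "MVA_only", "both", "neither", "candidate"):
            for _ in range(spec.genotype_plan.get(cls, 0)):
                plan.append((cls, _genotype_for_class(cls, rng, spec)))
    else:
        from .classifier import classify

        plan = []
        for genotype in spec.genotype_plan:
            cls = classify("tmp", genotype).genotype_class
            plan.append((cls, dict(genotype)))

    genomes, planted_all = [], []
    truth_presence: dict[str, dict[str, bool]] = {}
    expected_class: dict[str, str] = {}
    taxonomy: dict[str, str] = {}
    genome_seeds = rng.integers(0, 2**31 - 1, size=len(plan))
    n_myco = 0
    for i, ((cls, genotype), gseed) in enumerate(zip(plan, genome_seeds)):
        gid = f"G{i:04d}"
        if cls == "neither" and n_myco % 2 == 0:
            genus = "Mycoplasma"
            n_myco += 1
        elif cls == "neither":
            genus = f"Genus{i // 5:03d}"
            n_myco += 1
        else:
            genus = f"Genus{i // 5:03d}"
        code = assign_genetic_code(genus)
        genome, planted = make_genome(
            genome_id=gid,
            genotype=genotype,
            families=member_peps,
            genetic_code=code,
            seed=int(gseed),
            intergenic_length_mean=spec.intergenic_length_mean,
            genome_gc=spec.genome_gc,
            n_decoys=spec.n_decoys,
            species_name=f"{genus} species{i}",
            genus=genus,
        )
        genomes.append(genome)
        planted_all.extend(planted)
        truth_presence[gid] = {r: bool(genotype.get(r, False)) for r in ALL_ROLES}
        expected_class[gid] = cls
        taxonomy[gid] = genus
    return SyntheticCohort(
        spec=spec,
        genomes=genomes,
        families=families,
        truth_presence=truth_presence,
        expected_class=expected_class,
        planted=planted_all,
        taxonomy=taxonomy,
    )


def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Emit genomes/*.fna, families/*.faa (+ aligned), truth.tsv and
    taxonomy.tsv under ``out_dir``."""
    from pathlib import Path

    from .io_formats import write_fasta

    out = Path(out_dir)
    (out / "genomes").mkdir(parents=True, exist_ok=True)
    (out / "families").mkdir(parents=True, exist_ok=True)
    for g in cohort.genomes:
        write_fasta(g.contigs, out / "genomes" / f"{g.genome_id}.fna")
    for role, (aln, training) in cohort.families.items():
        write_fasta(aln.aligned_sequences, out / "families" / f"{role}.aln.faa")
        write_fasta(training.positives, out / "families" / f"{role}.pos.faa")
        write_fasta(training.negatives, out / "families" / f"{role}.neg.faa")
    with open(out / "truth.tsv", "w", newline="\n") as fh:
        fh.write("genome_id\trole\tcontig_id\tstart\tend\tstrand\n")
        for p in cohort.planted:
            fh.write(
                f"{p.genome_id}\t{p.role or 'decoy'}\t{p.contig_id}\t"
                f"{p.start}\t{p.end}\t{p.strand}\n"
            )
    with open(out / "taxonomy.tsv", "w", newline="\n") as fh:
        fh.write("genome_id\tgenus\n")
        for gid, genus in cohort.taxonomy.items():
            fh.write(f"{gid}\t{genus}\n")
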