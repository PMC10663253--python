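"""Scan genomes' ORFs against family profiles and call gene presence/absence.

For each (genome, family) pair, every ORF peptide is scored against the
family profile. Under an adaptive threshold the gene is called present iff
the best bit score is >= the family threshold; under an e-value threshold
(DxrII, IspD, IspF in the MEP survey) iff the smallest e-value is below
the cutoff, with the e-value's database size bound to the number of ORFs
scanned in that genome. The best-scoring ORF is recorded as evidence, and
a KofamScan-style detail table of every above-threshold hit can be written.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError
from .io_formats import GenomeRecord
from .orf_finder import ORF, find_orfs
from .calibration import FamilyThreshold
from .phmm import ProfileHMM, encode_peptide

#: Curated gene-role list of the survey: the seven MEP steps (with the
#: alternative enzymes DxrII and the IspDF fusion), the four MVA genes
#: (with the two HMGR isoforms), and the two MTA-isoprenoid-shunt enzymes.
ALL_ROLES = (
    "Dxs", "DxrI", "DxrII", "IspD", "IspDF", "IspE", "IspF", "IspG", "IspH",
    "HMGS", "HMGRI", "HMGRII", "MVK", "DPMD",
    "MTRu1P_isomerase", "MTXu5P_methylsulfurase",
)

#: Roles called by e-value cutoff rather than adaptive bit-score threshold.
EVALUE_ROLES = frozenset({"DxrII", "IspD", "IspF"})


@dataclass
class Evidence:
    orf_id: str
    bit_score: float
    evalue: float


@dataclass
class GenePresenceMatrix:
    """Genomes x gene-roles boolean matrix with per-call evidence."""

    genome_ids: list[str]
    roles: list[str]
    present: np.ndarray  # (G, R) bool
    evidence: dict[tuple[str, str], Evidence] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.present = np.asarray(self.present, dtype=bool).reshape(
            len(self.genome_ids), len(self.roles)
        )

    def row(self, genome_id: str) -> dict[str, bool]:
        gi = self.genome_ids.index(genome_id)
        return {r: bool(self.present[gi, ri]) for ri, r in enumerate(self.roles)}

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.present.astype(int), index=self.genome_ids, columns=self.roles
        )


def _threshold_map(
    models: Sequence[ProfileHMM], thresholds: Sequence[FamilyThreshold]
) -> dict[str, FamilyThreshold]:
    tmap = {t.family_id: t for t in thresholds}
    missing = [m.family_id for m in models if m.family_id not in tmap]
    if missing:
        raise ConfigError(f"no threshold entry for families {missing}")
    return tmap


def call_genome(
    orfs: Sequence[ORF],
    models: Sequence[ProfileHMM],
    thresholds: Sequence[FamilyThreshold],
) -> tuple[dict[str, bool], dict[str, Evidence], list[tuple]]:
    """One genome's presence row.

    Returns ``(present, evidence, detail_rows)`` where detail rows are
    ``('*', genome_id, orf_id, family_id, threshold, bit_score, evalue)``
    for every above-threshold hit (mirroring a detail-TSV scan output).
    """
    tmap = _threshold_map(models, thresholds)
    encoded = [(o, encode_peptide(o.peptide)) for o in orfs]
    n_orfs = len(orfs)
    present: dict[str, bool] = {}
    evidence: dict[str, Evidence] = {}
    detail: list[tuple] = []
    for model in models:
        fam = model.family_id
        rule = tmap[fam]
        hits = []
        for o, xi in encoded:
            bit = model.bit_score_encoded(xi)
            ev = model.evalue(bit, database_size=n_orfs)
            hits.append((o, bit, ev))
        if rule.mode == "adaptive":
            above = [h for h in hits if h[1] >= rule.threshold_bits]
            thr_repr = f"{rule.threshold_bits:.4f}"
        else:
            if model.evalue_params is None:
                raise ConfigError(
                    f"{fam}: e-value threshold requires a calibrated model"
                )
            above = [h for h in hits if h[2] < rule.evalue_cutoff]
            thr_repr = f"E<{rule.evalue_cutoff:g}"
        present[fam] = bool(above)
        if hits:
            best = max(hits, key=lambda h: h[1])
            if present[fam]:
                evidence[fam] = Evidence(best[0].orf_id, best[1], best[2])
        for o, bit, ev in sorted(above, key=lambda h: (-h[1], h[0].orf_id)):
            gid = o.genome_id
            detail.append(("*", gid, o.orf_id, fam, thr_repr, bit, ev))
    return present, evidence, detail


def scan_cohort(
    genomes: Sequence[GenomeRecord],
    models: Sequence[ProfileHMM],
    thresholds: Sequence[FamilyThreshold],
    min_orf_length: int = 150,
    detail_path=None,
) -> GenePresenceMatrix:
    """Scan every genome; one matrix row per genome, one column per family.

    Row order follows the input cohort; column order follows ``models``.
    When ``detail_path`` is given, a deterministic TSV of all
    above-threshold hits is written.
    """
    ids = [g.genome_id for g in genomes]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ConfigError(f"duplicate genome_ids in cohort: {dupes}")
    if not genomes:
        raise ConfigError("empty cohort")
    roles = [m.family_id for m in models]
    present = np.zeros((len(genomes), len(models)), dtype=bool)
    evidence: dict[tuple[str, str], Evidence] = {}
    detail_rows: list[tuple] = []
    for gi, genome in enumerate(genomes):
        orfs = find_orfs(genome, min_length=min_orf_length)
        row, ev, detail = call_genome(orfs, models, thresholds)
        for ri, fam in enumerate(roles):
            present[gi, ri] = row[fam]
            if fam in ev:
                evidence[(genome.genome_id, fam)] = ev[fam]
        detail_rows.extend(detail)
    if detail_path is not None:
        with open(detail_path, "w", newline="\n") as fh:
            fh.write("flag\tgenome_id\torf_id\tfamily_id\tthreshold\tbit_score\tevalue\n")
            for flag, gid, oid, fam, thr, bit, ev in detail_rows:
                fh.write(f"{flag}\t{gid}\t{oid}\t{fam}\t{thr}\t{bit:.6f}\t{ev:.6e}\n")
    return GenePresenceMatrix(
        genome_ids=ids, roles=roles, present=present, evidence=evidence
    )
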