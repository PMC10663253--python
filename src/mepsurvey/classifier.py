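"""Per-genome pathway status and terpenoid-biosynthesis genotype class.

The MEP (methylerythritol phosphate) pathway is scored over seven role
slots — Dxs, Dxr, IspD, IspE, IspF, IspG, IspH — where the Dxr slot is
satisfied by either of the non-homologous enzymes DxrI/DxrII, and the
bifunctional IspDF fusion satisfies both the IspD and IspF slots. The MVA
(mevalonate) pathway is scored over four slots (HMGS, HMGR with two
isoforms counted once, MVK, DPMD) and is called present when at least two
slots are satisfied.

Genotype classes partition every possible presence row:

========================  ==========================================
class                     rule
========================  ==========================================
MEP_only                  MEP complete, MVA absent
both                      MEP complete, MVA present
MVA_only                  MEP not complete, MVA present
neither                   zero MEP slots satisfied, MVA absent
candidate                 1-6 MEP slots satisfied, MVA absent
========================  ==========================================

"candidate" genomes (incomplete MEP, at most one MVA gene) are the
candidates for a non-canonical MEP route. Carriage of the MTA-isoprenoid
shunt (MTRu-1P isomerase + MTXu-5P methylsulfurase), a natural bypass of
Dxs, is flagged separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional

import yaml

from .errors import ConfigError

logger = logging.getLogger(__name__)

#: Pathway definitions as data so other pathways can be surveyed.
DEFAULT_PATHWAYS: dict = {
    "mep_slots": {
        "Dxs": ["Dxs"],
        "Dxr": ["DxrI", "DxrII"],
        "IspD": ["IspD", "IspDF"],
        "IspE": ["IspE"],
        "IspF": ["IspF", "IspDF"],
        "IspG": ["IspG"],
        "IspH": ["IspH"],
    },
    "mva_slots": {
        "HMGS": ["HMGS"],
        "HMGR": ["HMGRI", "HMGRII"],
        "MVK": ["MVK"],
        "DPMD": ["DPMD"],
    },
    "mva_min_slots": 2,
    "shunt": {
        "isomerase": "MTRu1P_isomerase",
        "methylsulfurase": "MTXu5P_methylsulfurase",
    },
}

GENOTYPE_CLASSES = ("MEP_only", "MVA_only", "both", "neither", "candidate")


def load_pathway_config(path) -> dict:
    """Load a pathway-definition config (YAML with the DEFAULT_PATHWAYS keys)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    missing = {"mep_slots", "mva_slots", "mva_min_slots", "shunt"} - set(cfg)
    if missing:
        raise ConfigError(f"{path}: pathway config missing keys {sorted(missing)}")
    return cfg


@dataclass
class PathwayStatus:
    """A genome's pathway completeness calls and genotype class."""

    genome_id: str
    mep_status: str  # complete | incomplete | absent
    missing_mep_roles: frozenset
    mva_gene_count: int
    mva_status: str  # present | absent
    genotype_class: str
    shunt_flags: str  # none | methylsulfurase_only | both_shunt


def _slot_satisfied(row: Mapping[str, bool], members: list[str]) -> bool:
    return any(row.get(m, False) for m in members)


def mep_completeness(
    row: Mapping[str, bool], config: Optional[dict] = None
) -> tuple[str, frozenset]:
    """MEP pathway status of a presence row: which of the 7 slots are missing."""
    cfg = config or DEFAULT_PATHWAYS
    missing = frozenset(
        slot for slot, members in cfg["mep_slots"].items()
        if not _slot_satisfied(row, members)
    )
    n_slots = len(cfg["mep_slots"])
    if not missing:
        status = "complete"
    elif len(missing) == n_slots:
        status = "absent"
    else:
        status = "incomplete"
    return status, missing


def mva_status(
    row: Mapping[str, bool], config: Optional[dict] = None
) -> tuple[int, str]:
    """Number of satisfied MVA slots (isoforms count once) and pathway call."""
    cfg = config or DEFAULT_PATHWAYS
    count = sum(
        1 for members in cfg["mva_slots"].values() if _slot_satisfied(row, members)
    )
    return count, ("present" if count >= cfg["mva_min_slots"] else "absent")


def genotype_class(mep: str, mva: str) -> str:
    """Genotype class from the (mep_status, mva_status) rule table."""
    if mva == "present":
        return "both" if mep == "complete" else "MVA_only"
    if mep == "complete":
        return "MEP_only"
    if mep == "absent":
        return "neither"
    return "candidate"


def shunt_flags(row: Mapping[str, bool], config: Optional[dict] = None) -> str:
    """MTA-isoprenoid-shunt carriage flag for a presence row."""
    cfg = config or DEFAULT_PATHWAYS
    iso = row.get(cfg["shunt"]["isomerase"], False)
    methyl = row.get(cfg["shunt"]["methylsulfurase"], False)
    if iso and methyl:
        return "both_shunt"
    if methyl:
        return "methylsulfurase_only"
    if iso:
        logger.warning("isomerase without methylsulfurase: flagged as 'none'")
    return "none"


def classify(
    genome_id: str, row: Mapping[str, bool], config: Optional[dict] = None
) -> PathwayStatus:
    """Full per-genome pathway status from a gene-role presence row."""
    mep, missing = mep_completeness(row, config)
    count, mva = mva_status(row, config)
    return PathwayStatus(
        genome_id=genome_id,
        mep_status=mep,
        missing_mep_roles=missing,
        mva_gene_count=count,
        mva_status=mva,
        genotype_class=genotype_class(mep, mva),
        shunt_flags=shunt_flags(row, config),
    )


def classify_matrix(matrix, config: Optional[dict] = None) -> list[PathwayStatus]:
    """Classify every genome of a :class:`GenePresenceMatrix`."""
    out = []
    for gi, gid in enumerate(matrix.genome_ids):
        row = {r: bool(matrix.present[gi, ri]) for ri, r in enumerate(matrix.roles)}
        out.append(classify(gid, row, config))
    return out


def write_status_table(statuses, path) -> None:
    """Deterministic TSV of per-genome statuses."""
    with open(path, "w", newline="\n") as fh:
        fh.write(
            "genome_id\tmep_status\tmissing_mep_roles\tmva_gene_count\t"
            "mva_status\tgenotype_class\tshunt_flags\n"
        )
        for s in statuses:
            missing = ",".join(sorted(s.missing_mep_roles))
            fh.write(
                f"{s.genome_id}\t{s.mep_status}\t{missing}\t{s.mva_gene_count}\t"
                f"{s.mva_status}\t{s.genotype_class}\t{s.shunt_flags}\n"
            )
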