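"""Cohort-level aggregation of per-genome pathway statuses.

Produces the survey's headline tables: genotype-class counts and
percentages, the breakdown of candidate (non-canonical-MEP) genomes by the
exact set of missing MEP slots, MTA-shunt carriage among the Dxs-only
candidates, per-genus pathway composition with bifurcation detection, and
the median genome size of pathway-less ("neither") genomes.

Percent rendering follows the survey's reporting convention: shares below
10% are rounded (half up) to one decimal, shares of 10% or more to the
nearest integer. Raw fractions are carried alongside so no precision is
lost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from statistics import median
from typing import Mapping, Optional, Sequence

import pandas as pd

from .classifier import GENOTYPE_CLASSES, PathwayStatus
from .errors import ConfigError


def render_percent(count: int, total: int) -> float:
    """100*count/total rendered per the reporting convention (see module doc)."""
    if total <= 0:
        raise ConfigError("render_percent needs a positive denominator")
    p = Decimal(count) * 100 / Decimal(total)
    if p < 10:
        return float(p.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    return float(p.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def render_percent_int(count: int, total: int) -> int:
    """Integer-rounded (half up) percentage."""
    if total <= 0:
        raise ConfigError("render_percent_int needs a positive denominator")
    p = Decimal(count) * 100 / Decimal(total)
    return int(p.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def _check_unique(statuses: Sequence[PathwayStatus]) -> None:
    ids = [s.genome_id for s in statuses]
    if len(set(ids)) != len(ids):
        raise ConfigError("duplicate genome_ids in status list")


def class_census(
    statuses: Sequence[PathwayStatus],
) -> dict[str, dict[str, float]]:
    """Counts, rendered percents and raw fractions per genotype class."""
    if not statuses:
        raise ConfigError("class_census needs a nonempty status list")
    _check_unique(statuses)
    total = len(statuses)
    out = {}
    for cls in GENOTYPE_CLASSES:
        n = sum(1 for s in statuses if s.genotype_class == cls)
        out[cls] = {
            "count": n,
            "percent": render_percent(n, total),
            "fraction": n / total,
        }
    return out


#: candidate missing-set buckets, in reporting order
CANDIDATE_PATTERNS = ("Dxs_only", "IspG_only", "IspH_only", "other")

_PATTERN_SETS = {
    "Dxs_only": frozenset({"Dxs"}),
    "IspG_only": frozenset({"IspG"}),
    "IspH_only": frozenset({"IspH"}),
}


def candidate_breakdown(
    statuses: Sequence[PathwayStatus],
) -> dict[str, dict[str, float]]:
    """Bucket candidate genomes by their exact missing-MEP-slot set."""
    cands = [s for s in statuses if s.genotype_class == "candidate"]
    denom = len(cands)
    counts = dict.fromkeys(CANDIDATE_PATTERNS, 0)
    for s in cands:
        for name, pattern in _PATTERN_SETS.items():
            if s.missing_mep_roles == pattern:
                counts[name] += 1
                break
        else:
            counts["other"] += 1
    return {
        name: {
            "count": n,
            "percent": render_percent_int(n, denom) if denom else 0,
            "fraction": n / denom if denom else 0.0,
        }
        for name, n in counts.items()
    }


def shunt_census(statuses: Sequence[PathwayStatus]) -> dict[str, float]:
    """MTA-shunt carriage among candidates missing exactly {Dxs}.

    The denominator is the number of Dxs-only candidates.
    """
    dxs_only = [
        s for s in statuses
        if s.genotype_class == "candidate" and s.missing_mep_roles == frozenset({"Dxs"})
    ]
    denom = len(dxs_only)
    n_methyl = sum(1 for s in dxs_only if s.shunt_flags == "methylsulfurase_only")
    n_both = sum(1 for s in dxs_only if s.shunt_flags == "both_shunt")
    return {
        "denominator": denom,
        "methylsulfurase_only_count": n_methyl,
        "methylsulfurase_only_percent": render_percent_int(n_methyl, denom) if denom else 0,
        "both_shunt_count": n_both,
        "both_shunt_percent": render_percent_int(n_both, denom) if denom else 0,
    }


def genus_census(
    statuses: Sequence[PathwayStatus], taxonomy: Mapping[str, str]
) -> pd.DataFrame:
    """Per-genus pathway composition and bifurcation calls.

    ``taxonomy`` maps genome_id -> genus. A genus is bifurcated when it has
    at least two species, at least one on the MEP side (MEP_only, or the
    'both' class, whose MEP pathway is complete by definition) and at least
    one MVA_only species.
    """
    missing = [s.genome_id for s in statuses if s.genome_id not in taxonomy]
    if missing:
        raise ConfigError(f"genomes without genus in taxonomy: {missing[:5]}")
    rows = []
    by_genus: dict[str, list[PathwayStatus]] = {}
    for s in statuses:
        by_genus.setdefault(taxonomy[s.genome_id], []).append(s)
    for genus in sorted(by_genus):
        members = by_genus[genus]
        n = len(members)
        n_mep = sum(1 for s in members if s.genotype_class == "MEP_only")
        n_mva = sum(1 for s in members if s.genotype_class == "MVA_only")
        n_both = sum(1 for s in members if s.genotype_class == "both")
        n_other = n - n_mep - n_mva - n_both
        rows.append(
            {
                "genus": genus,
                "n_species": n,
                "n_MEP_only": n_mep,
                "n_MVA_only": n_mva,
                "n_both": n_both,
                "n_other": n_other,
                "pct_MEP_only": render_percent(n_mep, n),
                "pct_MVA_only": render_percent(n_mva, n),
                "bifurcated": bool(n >= 2 and (n_mep + n_both) >= 1 and n_mva >= 1),
            }
        )
    return pd.DataFrame(rows)


def neither_genome_stats(
    statuses: Sequence[PathwayStatus], genome_sizes: Mapping[str, int]
) -> float:
    """Median genome size (bp) of 'neither'-class genomes.

    Even-count medians are the mean of the central pair.
    """
    sizes = [
        genome_sizes[s.genome_id]
        for s in statuses
        if s.genotype_class == "neither"
    ]
    if not sizes:
        raise ConfigError("no genomes in the 'neither' class")
    return float(median(sizes))


@dataclass
class CensusReport:
    """Full cohort report: every headline table in one object."""

    total_genomes: int
    class_counts: dict
    candidate_patterns: dict
    shunt: dict
    genus_table: Optional[pd.DataFrame] = None
    neither_median_genome_size: Optional[float] = None
    _statuses: list = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        d = {
            "total_genomes": self.total_genomes,
            "class_counts": self.class_counts,
            "candidate_patterns": self.candidate_patterns,
            "shunt": self.shunt,
            "neither_median_genome_size": self.neither_median_genome_size,
        }
        if self.genus_table is not None:
            d["genus_table"] = self.genus_table.to_dict(orient="records")
        return d


def full_census(
    statuses: Sequence[PathwayStatus],
    taxonomy: Optional[Mapping[str, str]] = None,
    genome_sizes: Optional[Mapping[str, int]] = None,
) -> CensusReport:
    """Aggregate statuses into a :class:`CensusReport`."""
    classes = class_census(statuses)
    report = CensusReport(
        total_genomes=len(statuses),
        class_counts=classes,
        candidate_patterns=candidate_breakdown(statuses),
        shunt=shunt_census(statuses),
        _statuses=list(statuses),
    )
    if taxonomy is not None:
        report.genus_table = genus_census(statuses, taxonomy)
    if genome_sizes is not None and classes["neither"]["count"] > 0:
        report.neither_median_genome_size = neither_genome_stats(
            statuses, genome_sizes
        )
    return report


def write_report(report: CensusReport, out_dir) -> None:
    """Write class_census.tsv, candidate_breakdown.tsv, genus_table.tsv and
    report.json under ``out_dir`` (deterministic, diffable)."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "class_census.tsv", "w", newline="\n") as fh:
        fh.write("class\tcount\tpercent\tfraction\n")
        for cls, d in report.class_counts.items():
            fh.write(f"{cls}\t{d['count']}\t{d['percent']}\t{d['fraction']!r}\n")
    with open(out / "candidate_breakdown.tsv", "w", newline="\n") as fh:
        fh.write("pattern\tcount\tpercent\tfraction\n")
        for name, d in report.candidate_patterns.items():
            fh.write(f"{name}\t{d['count']}\t{d['percent']}\t{d['fraction']!r}\n")
    if report.genus_table is not None:
        report.genus_table.to_csv(out / "genus_table.tsv", sep="\t", index=False)
    with open(out / "report.json", "w", newline="\n") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
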