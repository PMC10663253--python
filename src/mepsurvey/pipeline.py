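"""End-to-end glue: calibrate families, scan a cohort, classify, census.

This is the programmatic equivalent of running the survey stages in
sequence: build one profile per family from its full alignment, derive its
ortholog-call rule (three-fold adaptive bit-score threshold, or Gumbel
e-value cutoff for the e-value-mode roles), find and scan every genome's
ORFs, classify the presence rows into genotype classes, and aggregate the
cohort census.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .calibration import (
    DEFAULT_EVALUE_CUTOFF,
    FamilyThreshold,
    adaptive_threshold,
)
from .census import CensusReport, full_census
from .classifier import PathwayStatus, classify_matrix
from .ortholog_caller import EVALUE_ROLES, GenePresenceMatrix, scan_cohort
from .phmm import ProfileHMM, build_profile, calibrate_evalue
from .synthetic_data import SyntheticCohort


def calibrate_families(
    families: dict,
    seed: int = 0,
    pseudocount: float = 0.1,
    n_random: int = 200,
    evalue_roles: frozenset = EVALUE_ROLES,
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
) -> tuple[list[ProfileHMM], list[FamilyThreshold]]:
    """Build one profile per family and its ortholog-call rule.

    ``families`` maps family_id -> (FamilyAlignment, TrainingSet). Every
    profile gets a Gumbel e-value calibration (used by the e-value-mode
    roles and reported in scan detail output); adaptive roles additionally
    get the rotating F-maximization bit-score threshold.
    """
    rng = np.random.default_rng(seed)
    child = rng.integers(0, 2**31 - 1, size=2 * len(families))
    models, thresholds = [], []
    for i, fam in enumerate(sorted(families)):
        aln, training = families[fam]
        model = build_profile(aln, pseudocount=pseudocount)
        calibrate_evalue(
            model, n_random=n_random, seed=int(child[2 * i]), database_size=1.0
        )
        models.append(model)
        if fam in evalue_roles:
            thresholds.append(FamilyThreshold.evalue_mode(fam, evalue_cutoff))
        else:
            thresholds.append(
                adaptive_threshold(
                    training, pseudocount=pseudocount, seed=int(child[2 * i + 1])
                )
            )
    return models, thresholds


@dataclass
class SurveyResult:
    models: list[ProfileHMM]
    thresholds: list[FamilyThreshold]
    matrix: GenePresenceMatrix
    statuses: list[PathwayStatus]
    report: CensusReport


def run_survey(
    cohort: SyntheticCohort,
    seed: int = 0,
    min_orf_length: int = 150,
    detail_path=None,
) -> SurveyResult:
    """Run the full pipeline on a synthetic cohort."""
    models, thresholds = calibrate_families(cohort.families, seed=seed)
    matrix = scan_cohort(
        cohort.genomes,
        models,
        thresholds,
        min_orf_length=min_orf_length,
        detail_path=detail_path,
    )
    statuses = classify_matrix(matrix)
    report = full_census(
        statuses, taxonomy=cohort.taxonomy, genome_sizes=cohort.genome_sizes
    )
    return SurveyResult(
        models=models,
        thresholds=thresholds,
        matrix=matrix,
        statuses=statuses,
        report=report,
    )


def evaluate_calls(
    matrix: GenePresenceMatrix, truth_presence: dict
) -> tuple[float, float]:
    """Planted-gene recall and false-presence rate of a scan vs truth.

    Recall = called present among truly planted; false-presence rate =
    called present among truly absent (both over all genome x role cells).
    """
    tp = fn = fp = tn = 0
    for gi, gid in enumerate(matrix.genome_ids):
        truth_row = truth_presence[gid]
        for ri, role in enumerate(matrix.roles):
            called = bool(matrix.present[gi, ri])
            true = bool(truth_row.get(role, False))
            if true and called:
                tp += 1
            elif true:
                fn += 1
            elif called:
                fp += 1
            else:
                tn += 1
    recall = tp / (tp + fn) if tp + fn else 1.0
    fpr = fp / (fp + tn) if fp + tn else 0.0
    return recall, fpr
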