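"""Adaptive per-family bit-score thresholds by rotating F-measure maximization.

The curated positive set of a family is split at random into three groups.
In each of three rotations, two groups build the profile, and the held-out
group plus all negatives are scored against it; the bit-score cutoff that
maximizes the F measure (harmonic mean of precision and recall) on that
fold is recorded. The family's final threshold is the mean of the three
fold thresholds, and the reported F measure is the mean of the fold F
values. A score >= threshold calls an ortholog.

Families without enough curated members for cross-validation (or without a
usable adaptive threshold, like DxrII/IspD/IspF in the MEP survey) use an
e-value cutoff instead (default 1e-10).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import CalibrationError
from .io_formats import FamilyAlignment, TrainingSet
from .phmm import ProfileHMM, build_profile

DEFAULT_EVALUE_CUTOFF = 1e-10


def f_measure(tp: int, fp: int, fn: int) -> float:
    """Harmonic mean of precision and recall; 0 when there are no true positives."""
    if tp + fp + fn < 1:
        raise ValueError("f_measure needs tp + fp + fn >= 1")
    if tp == 0:
        return 0.0
    p = tp / (tp + fp)
    r = tp / (tp + fn)
    return 2.0 * p * r / (p + r)


def best_threshold(
    pos_scores: Sequence[float], neg_scores: Sequence[float]
) -> tuple[float, float, float, float]:
    """Exhaustive threshold scan maximizing F.

    Candidate thresholds are the midpoints between adjacent distinct values
    of the pooled scores, plus one candidate below the minimum and one above
    the maximum (offset by the pooled score range, so the scan commutes with
    affine rescaling). A score >= threshold is classified positive. Ties in
    F are broken toward the higher threshold. Returns
    ``(threshold, precision, recall, F)``.
    """
    pos = np.sort(np.asarray(pos_scores, dtype=float))
    neg = np.sort(np.asarray(neg_scores, dtype=float))
    if pos.size == 0:
        raise CalibrationError("best_threshold needs at least one positive score")
    pooled = np.unique(np.concatenate([pos, neg]))
    span = pooled[-1] - pooled[0]
    if span == 0.0:
        span = 1.0
    cands = np.concatenate(
        [[pooled[0] - span], (pooled[:-1] + pooled[1:]) / 2.0, [pooled[-1] + span]]
    )
    best = None
    for t in cands:
        tp = int(pos.size - np.searchsorted(pos, t, side="left"))
        fp = int(neg.size - np.searchsorted(neg, t, side="left"))
        fn = int(pos.size - tp)
        F = f_measure(tp, fp, fn)
        if best is None or F > best[3] or (F == best[3] and t > best[0]):
            if tp > 0:
                p = tp / (tp + fp)
                r = tp / (tp + fn)
            else:
                p = r = 0.0
            best = (float(t), p, r, F)
    return best


@dataclass
class FamilyThreshold:
    """Per-family ortholog-call rule."""

    family_id: str
    mode: str  # 'adaptive' or 'evalue'
    threshold_bits: Optional[float] = None
    evalue_cutoff: Optional[float] = None
    f_measure: Optional[float] = None
    #: per rotation: (threshold, precision, recall, F)
    per_fold: list[tuple[float, float, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mode not in ("adaptive", "evalue"):
            raise CalibrationError(f"unknown threshold mode {self.mode!r}")
        if self.mode == "adaptive" and self.threshold_bits is None:
            raise CalibrationError(f"{self.family_id}: adaptive mode needs threshold_bits")
        if self.mode == "evalue" and self.evalue_cutoff is None:
            raise CalibrationError(f"{self.family_id}: evalue mode needs evalue_cutoff")

    @classmethod
    def evalue_mode(cls, family_id: str,
                    cutoff: float = DEFAULT_EVALUE_CUTOFF) -> "FamilyThreshold":
        return cls(family_id=family_id, mode="evalue", evalue_cutoff=cutoff)


def _three_way_split(n: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Seeded shuffle split into 3 groups with sizes differing by at most 1."""
    order = rng.permutation(n)
    sizes = [n // 3 + (1 if r < n % 3 else 0) for r in range(3)]
    groups, at = [], 0
    for s in sizes:
        groups.append(order[at : at + s])
        at += s
    return groups


def adaptive_threshold(
    training: TrainingSet,
    pseudocount: float = 0.1,
    background: Optional[np.ndarray] = None,
    seed: int = 0,
) -> FamilyThreshold:
    """Three-fold rotating F-maximization threshold for one family.

    The positive sequences must be equal length (they are treated as a
    trivial columnwise alignment when building each fold's profile); build
    an explicit :class:`FamilyAlignment` first if the family has indels.
    """
    n_pos = len(training.positives)
    if n_pos < 3:
        raise CalibrationError(
            f"{training.family_id}: {n_pos} positives < 3; cannot rotate folds — "
            "use an e-value threshold (FamilyThreshold.evalue_mode) instead"
        )
    lengths = {len(s) for _, s in training.positives}
    if len(lengths) != 1:
        raise CalibrationError(
            f"{training.family_id}: positives of unequal length "
            f"{sorted(lengths)}; provide an aligned family instead"
        )
    rng = np.random.default_rng(seed)
    groups = _three_way_split(n_pos, rng)
    neg_seqs = [s for _, s in training.negatives]
    folds = []
    for r in range(3):
        held = groups[r]
        train_idx = np.concatenate([groups[i] for i in range(3) if i != r])
        aln = FamilyAlignment(
            family_id=training.family_id,
            aligned_sequences=[training.positives[i] for i in train_idx],
        )
        model = build_profile(aln, background=background, pseudocount=pseudocount)
        pos_scores = [model.bit_score(training.positives[i][1]) for i in held]
        neg_scores = [model.bit_score(s) for s in neg_seqs]
        folds.append(best_threshold(pos_scores, neg_scores))
    return FamilyThreshold(
        family_id=training.family_id,
        mode="adaptive",
        threshold_bits=float(np.mean([f[0] for f in folds])),
        f_measure=float(np.mean([f[3] for f in folds])),
        per_fold=folds,
    )


# ---------------------------------------------------------------------------
# Threshold table TSV

def write_thresholds(thresholds: Sequence[FamilyThreshold], path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("family_id\tmode\tthreshold_bits\tevalue_cutoff\tf_measure\tfolds\n")
        for t in thresholds:
            folds = ";".join(
                f"{thr!r},{p!r},{r!r},{f!r}" for thr, p, r, f in t.per_fold
            )
            fh.write(
                "\t".join(
                    [
                        t.family_id,
                        t.mode,
                        "" if t.threshold_bits is None else repr(t.threshold_bits),
                        "" if t.evalue_cutoff is None else repr(t.evalue_cutoff),
                        "" if t.f_measure is None else repr(t.f_measure),
                        folds,
                    ]
                )
                + "\n"
            )


def read_thresholds(path) -> list[FamilyThreshold]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("family_id\t"):
            raise CalibrationError(f"{path}: not a thresholds TSV")
        for ln in fh:
            fid, mode, tb, ec, fm, folds = ln.rstrip("\n").split("\t")
            per_fold = []
            if folds:
                for item in folds.split(";"):
                    per_fold.append(tuple(float(v) for v in item.split(",")))
            out.append(
                FamilyThreshold(
                    family_id=fid,
                    mode=mode,
                    threshold_bits=float(tb) if tb else None,
                    evalue_cutoff=float(ec) if ec else None,
                    f_measure=float(fm) if fm else None,
                    per_fold=per_fold,
                )
            )
    return out
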