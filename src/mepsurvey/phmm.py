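"""Profile hidden Markov models for protein families.

A profile is built from a family multiple alignment: alignment columns with
at most 50% gaps become match states; emissions are pseudocount-smoothed
residue counts; transitions (M->M/I/D, I->M/I, D->M/D, plus begin->M/D) are
estimated from the observed column-to-column paths with the same
pseudocount scheme. Insert states emit the background distribution.

Scoring is best-path (Viterbi) in bits: log2 of the joint probability of
the best state path against the background model. The alignment is global
in the model and local in the sequence — flanking residues on either side
of the matched substring are emitted at background rates with no
transition cost, so they contribute zero bits. This is deliberately
simpler than HMMER's forward/glocal statistic: absolute scores will not
match HMMER's, but every threshold in this package is calibrated on the
same statistic, so presence/absence calls are internally consistent.

E-values come from a Gumbel (EVD) null fitted by maximum likelihood to the
scores of random background-sampled peptides:
``E(s) = database_size * (1 - exp(-exp(-lambda * (s - mu))))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import gumbel_r

from .errors import CalibrationError, ModelError
from .io_formats import FamilyAlignment

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_X_INDEX = 20  # unknown residue: emitted at background rate (log-odds 0)

#: uniform background distribution over the 20 amino acids
UNIFORM_BACKGROUND = np.full(20, 1.0 / 20.0)

_NEG = -1.0e300
_GAP_CHARS = frozenset("-.")


def encode_peptide(peptide: str) -> np.ndarray:
    """Map a peptide to integer indices; unknown letters become X."""
    return np.array([_AA_INDEX.get(a, _X_INDEX) for a in peptide], dtype=np.int64)


@dataclass
class Hit:
    """One peptide scored against one family profile."""

    orf_id: str
    family_id: str
    bit_score: float
    evalue: float


@dataclass
class ProfileHMM:
    family_id: str
    match_emissions: np.ndarray  # (M, 20), rows sum to 1
    insert_emissions: np.ndarray  # (20,) == background
    background: np.ndarray  # (20,)
    # transition probabilities; index k is the source position
    # (k=0 is begin; M/I/D at k transition toward position k+1)
    t_mm: np.ndarray  # (M,) M_k -> M_{k+1}; k=0 is B -> M_1
    t_mi: np.ndarray  # (M,) M_k -> I_k; 0 at k=0
    t_md: np.ndarray  # (M,) M_k -> D_{k+1}; k=0 is B -> D_1
    t_im: np.ndarray  # (M,) I_k -> M_{k+1}; undefined at k=0
    t_ii: np.ndarray  # (M,) I_k -> I_k
    t_dm: np.ndarray  # (M,) D_k -> M_{k+1}; undefined at k=0
    t_dd: np.ndarray  # (M,) D_k -> D_{k+1}
    #: (mu, lambda, database_size) of the fitted Gumbel null, or None
    evalue_params: Optional[tuple[float, float, float]] = None
    _cost_cache: Optional[tuple] = field(default=None, repr=False, compare=False)

    @property
    def n_match_states(self) -> int:
        return self.match_emissions.shape[0]

    # -- scoring ---------------------------------------------------------

    def _costs(self):
        """Log2 emission odds and transition costs, cached."""
        if self._cost_cache is None:
            M = self.n_match_states
            lo = np.zeros((M, 21))
            with np.errstate(divide="ignore"):
                lo[:, :20] = np.log2(self.match_emissions) - np.log2(self.background)
                def lg(p):
                    out = np.full_like(p, _NEG)
                    nz = p > 0
                    out[nz] = np.log2(p[nz])
                    return out
                self._cost_cache = (
                    lo,
                    lg(self.t_mm), lg(self.t_mi), lg(self.t_md),
                    lg(self.t_im), lg(self.t_ii),
                    lg(self.t_dm), lg(self.t_dd),
                )
        return self._cost_cache

    def bit_score_encoded(self, xi: np.ndarray) -> float:
        lo, amm, ami, amd, aim, aii, adm, add = self._costs()
        return float(_viterbi(xi, lo, amm, ami, amd, aim, aii, adm, add))

    def bit_score(self, peptide: str) -> float:
        """Best-path bit score of a peptide (empty peptide = all-delete path)."""
        return self.bit_score_encoded(encode_peptide(peptide))

    def evalue(self, bit_score: float, database_size: Optional[float] = None) -> float:
        """E-value of a bit score under the fitted Gumbel null."""
        if self.evalue_params is None:
            return math.inf
        mu, lam, db = self.evalue_params
        if database_size is not None:
            db = database_size
        return float(db * gumbel_r.sf(bit_score, loc=mu, scale=1.0 / lam))

    def score(self, peptide: str, orf_id: str = "") -> Hit:
        s = self.bit_score(peptide)
        return Hit(orf_id=orf_id, family_id=self.family_id, bit_score=s,
                   evalue=self.evalue(s))


# ---------------------------------------------------------------------------
# Viterbi kernel (numba-jitted when available; same function as pure Python)

def _viterbi_impl(xi, lo, amm, ami, amd, aim, aii, adm, add):
    M = lo.shape[0]
    L = xi.shape[0]
    NEG = -1.0e300
    m_prev = np.full(M + 1, NEG)
    i_prev = np.full(M + 1, NEG)
    d_prev = np.full(M + 1, NEG)
    # j = 0: only the all-delete chain B -> D_1 -> ... -> D_M is reachable
    d_prev[1] = amd[0]
    for k in range(2, M + 1):
        d_prev[k] = d_prev[k - 1] + add[k - 1]
    best = d_prev[M] if d_prev[M] > m_prev[M] else m_prev[M]
    m_cur = np.full(M + 1, NEG)
    i_cur = np.full(M + 1, NEG)
    d_cur = np.full(M + 1, NEG)
    for j in range(1, L + 1):
        x = xi[j - 1]
        # begin state is free at every sequence position (local in
        # sequence): entering M_1 consumes this residue
        m_cur[1] = lo[0, x] + amm[0]
        for k in range(2, M + 1):
            cand = m_prev[k - 1] + amm[k - 1]
            c2 = i_prev[k - 1] + aim[k - 1]
            if c2 > cand:
                cand = c2
            c3 = d_prev[k - 1] + adm[k - 1]
            if c3 > cand:
                cand = c3
            m_cur[k] = lo[k - 1, x] + cand
        for k in range(1, M):  # insert emits background: log-odds 0
            ci = m_prev[k] + ami[k]
            c2 = i_prev[k] + aii[k]
            if c2 > ci:
                ci = c2
            i_cur[k] = ci
        d_cur[1] = amd[0]
        for k in range(2, M + 1):
            cd = m_cur[k - 1] + amd[k - 1]
            c2 = d_cur[k - 1] + add[k - 1]
            if c2 > cd:
                cd = c2
            d_cur[k] = cd
        if m_cur[M] > best:
            best = m_cur[M]
        if d_cur[M] > best:
            best = d_cur[M]
        m_prev, m_cur = m_cur, m_prev
        i_prev, i_cur = i_cur, i_prev
        d_prev, d_cur = d_cur, d_prev
    return best


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _viterbi = njit(cache=True)(_viterbi_impl)
except Exception:  # pragma: no cover
    _viterbi = _viterbi_impl


# ---------------------------------------------------------------------------
# Model construction

def build_profile(
    alignment: FamilyAlignment,
    background: Optional[np.ndarray] = None,
    pseudocount: float = 0.1,
) -> ProfileHMM:
    """Estimate a profile HMM from a family alignment.

    Match states are the columns with <= 50% gaps. Emissions are
    ``(count + a) / (total + 20 a)`` with pseudocount ``a``; transitions use
    the same additive smoothing within each source-state group.
    """
    if pseudocount <= 0:
        raise ModelError("pseudocount must be > 0")
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    seqs = [s for _, s in alignment.aligned_sequences]
    n_seqs = len(seqs)
    ncol = alignment.columns

    is_gap = np.array(
        [[c in _GAP_CHARS for c in s] for s in seqs], dtype=bool
    ).reshape(n_seqs, ncol)
    gap_frac = is_gap.mean(axis=0) if ncol else np.zeros(0)
    match_cols = [c for c in range(ncol) if gap_frac[c] <= 0.5]
    M = len(match_cols)
    if M == 0:
        raise ModelError(f"{alignment.family_id}: no column has <= 50% gaps")

    emis = np.zeros((M, 20))
    for mi, c in enumerate(match_cols):
        for s in seqs:
            a = s[c]
            if a in _AA_INDEX:
                emis[mi, _AA_INDEX[a]] += 1.0
    totals = emis.sum(axis=1, keepdims=True)
    emis = (emis + pseudocount) / (totals + 20.0 * pseudocount)

    # transition counts; index k = source position (0 = begin)
    n_mm = np.zeros(M)
    n_mi = np.zeros(M)
    n_md = np.zeros(M)
    n_im = np.zeros(M)
    n_ii = np.zeros(M)
    n_dm = np.zeros(M)
    n_dd = np.zeros(M)
    match_set = set(match_cols)
    for si, s in enumerate(seqs):
        states = ["D" if is_gap[si, c] else "M" for c in match_cols]
        # residues in non-match columns strictly between match cols k-1, k
        inserts = np.zeros(M, dtype=int)
        for k in range(1, M):
            lo_c, hi_c = match_cols[k - 1], match_cols[k]
            cnt = 0
            for c in range(lo_c + 1, hi_c):
                if c not in match_set and not is_gap[si, c]:
                    cnt += 1
            inserts[k] = cnt
        # begin -> first state
        if states[0] == "M":
            n_mm[0] += 1
        else:
            n_md[0] += 1
        for k in range(1, M):
            prev_state, next_state = states[k - 1], states[k]
            c = inserts[k]
            if prev_state == "M" and c > 0 and next_state == "M":
                n_mi[k] += 1
                n_ii[k] += c - 1
                n_im[k] += 1
            elif prev_state == "M":
                # inserts adjacent to a delete have no legal path (no I<->D
                # transitions); they are dropped from the counts
                if next_state == "M":
                    n_mm[k] += 1
                else:
                    n_md[k] += 1
            else:  # prev D
                if next_state == "M":
                    n_dm[k] += 1
                else:
                    n_dd[k] += 1

    a = pseudocount
    t_mm = np.zeros(M)
    t_mi = np.zeros(M)
    t_md = np.zeros(M)
    t_im = np.zeros(M)
    t_ii = np.zeros(M)
    t_dm = np.zeros(M)
    t_dd = np.zeros(M)
    # begin group: {B->M1, B->D1}
    tot = n_mm[0] + n_md[0] + 2 * a
    t_mm[0] = (n_mm[0] + a) / tot
    t_md[0] = (n_md[0] + a) / tot
    for k in range(1, M):
        tot = n_mm[k] + n_mi[k] + n_md[k] + 3 * a
        t_mm[k] = (n_mm[k] + a) / tot
        t_mi[k] = (n_mi[k] + a) / tot
        t_md[k] = (n_md[k] + a) / tot
        tot = n_im[k] + n_ii[k] + 2 * a
        t_im[k] = (n_im[k] + a) / tot
        t_ii[k] = (n_ii[k] + a) / tot
        tot = n_dm[k] + n_dd[k] + 2 * a
        t_dm[k] = (n_dm[k] + a) / tot
        t_dd[k] = (n_dd[k] + a) / tot

    return ProfileHMM(
        family_id=alignment.family_id,
        match_emissions=emis,
        insert_emissions=bg.copy(),
        background=bg,
        t_mm=t_mm, t_mi=t_mi, t_md=t_md,
        t_im=t_im, t_ii=t_ii,
        t_dm=t_dm, t_dd=t_dd,
    )


# ---------------------------------------------------------------------------
# E-value calibration

def sample_background_peptide(rng: np.random.Generator, length: int,
                              background: Optional[np.ndarray] = None) -> str:
    bg = UNIFORM_BACKGROUND if background is None else background
    idx = rng.choice(20, size=length, p=bg)
    return "".join(AMINO_ACIDS[i] for i in idx)


def calibrate_evalue(
    model: ProfileHMM,
    n_random: int = 200,
    length: Optional[int] = None,
    seed: int = 0,
    database_size: float = 1.0,
) -> ProfileHMM:
    """Fit a Gumbel null to scores of random background peptides.

    ``length`` defaults to the number of match states. The fitted (mu,
    lambda) and ``database_size`` are stored on the model; the database
    size can be overridden per scan (e.g. the number of ORFs searched).
    """
    if n_random < 100:
        raise CalibrationError(f"n_random must be >= 100, got {n_random}")
    L = length if length is not None else model.n_match_states
    rng = np.random.default_rng(seed)
    scores = np.array(
        [model.bit_score(sample_background_peptide(rng, L, model.background))
         for _ in range(n_random)]
    )
    if np.ptp(scores) < 1e-12:
        raise CalibrationError(
            f"{model.family_id}: degenerate null-score distribution"
        )
    loc, scale = gumbel_r.fit(scores)
    model.evalue_params = (float(loc), float(1.0 / scale), float(database_size))
    return model


# ---------------------------------------------------------------------------
# Plain-text serialization

def write_profile(model: ProfileHMM, path) -> None:
    """Serialize a profile to a documented plain-text format."""
    with open(path, "w", newline="\n") as fh:
        fh.write(f"MEPSURVEY-PHMM 1\nfamily_id\t{model.family_id}\n")
        fh.write(f"M\t{model.n_match_states}\n")
        if model.evalue_params is None:
            fh.write("evalue_params\tnone\n")
        else:
            mu, lam, db = model.evalue_params
            fh.write(f"evalue_params\t{float(mu)!r}\t{float(lam)!r}\t{float(db)!r}\n")
        fh.write("background\t" + "\t".join(repr(float(v)) for v in model.background) + "\n")
        for name, arr in [("t_mm", model.t_mm), ("t_mi", model.t_mi),
                          ("t_md", model.t_md), ("t_im", model.t_im),
                          ("t_ii", model.t_ii), ("t_dm", model.t_dm),
                          ("t_dd", model.t_dd)]:
            fh.write(name + "\t" + "\t".join(repr(float(v)) for v in arr) + "\n")
        for row in model.match_emissions:
            fh.write("match\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_profile(path) -> ProfileHMM:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or not lines[0].startswith("MEPSURVEY-PHMM"):
        raise ModelError(f"{path}: not a mepsurvey profile file")
    fields: dict[str, list[str]] = {}
    match_rows = []
    for ln in lines[1:]:
        parts = ln.split("\t")
        if parts[0] == "match":
            match_rows.append([float(v) for v in parts[1:]])
        elif parts[0]:
            fields[parts[0]] = parts[1:]
    ev = None
    if fields["evalue_params"][0] != "none":
        ev = tuple(float(v) for v in fields["evalue_params"][:3])
    bg = np.array([float(v) for v in fields["background"]])
    kw = {name: np.array([float(v) for v in fields[name]])
          for name in ("t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_dm", "t_dd")}
    return ProfileHMM(
        family_id=fields["family_id"][0],
        match_emissions=np.array(match_rows),
        insert_emissions=bg.copy(),
        background=bg,
        evalue_params=ev,
        **kw,
    )
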