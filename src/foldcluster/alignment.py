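"""Scoring and alignment kernel.

Residue pairs are scored by a weighted sum of a 3Di substitution matrix and
an amino-acid substitution matrix (BLOSUM62):

    s(i, j) = w_3di * M3di[q3di_i, t3di_j] + w_aa * Maa[qaa_i, taa_j]

On top of this column score the module provides ungapped diagonal rescoring
(1-D local alignment), a local Gotoh alignment with affine gaps, Gumbel
E-value calibration on shuffled decoys, the superposition-free alignment
LDDT, least-squares rigid superposition and the TM-score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit
from scipy import stats

from .records import ALPHABET, NEUTRAL, StructureRecord, StructureSet

__all__ = [
    "ScoringParams",
    "GumbelParams",
    "Alignment",
    "Superposition",
    "default_3di_matrix",
    "blosum62_matrix",
    "read_substitution_matrix",
    "column_score",
    "ungapped_diagonal_score",
    "gapped_align",
    "calibrate_evalue",
    "evalue",
    "alignment_lddt",
    "superpose",
    "tm_score",
]

N_LETTERS = len(ALPHABET)
_LETTER_INDEX = {c: i for i, c in enumerate(ALPHABET)}
_LETTER_INDEX[NEUTRAL] = N_LETTERS  # neutral symbol: extra row/column of zeros


def default_3di_matrix(match: int = 6, mismatch: int = -4) -> np.ndarray:
    """Default 3Di substitution matrix (half-bit log-odds, uniform model).

    Under a structural alphabet whose states mutate by uniform resampling,
    the log-odds matrix has one match and one mismatch value; the defaults
    are scaled to match the magnitude of published 3Di matrices.  Use
    :func:`read_substitution_matrix` to load an externally published table.
    """
    m = np.full((N_LETTERS, N_LETTERS), mismatch, dtype=np.int64)
    np.fill_diagonal(m, match)
    return m


def blosum62_matrix() -> np.ndarray:
    """BLOSUM62 restricted to the 20 canonical letters, as a dense array."""
    from Bio.Align import substitution_matrices

    b = substitution_matrices.load("BLOSUM62")
    m = np.zeros((N_LETTERS, N_LETTERS), dtype=np.int64)
    for i, a in enumerate(ALPHABET):
        for j, c in enumerate(ALPHABET):
            m[i, j] = int(b[a][c])
    return m


def read_substitution_matrix(path) -> np.ndarray:
    """Read a whitespace-separated 20x20 substitution matrix file.

    Accepts the usual matrix dialect: comment lines starting with ``#``, a
    header row of letters, one labelled row per letter.  Letters outside the
    canonical 20 (e.g. a wildcard column) are ignored.
    """
    header: list[str] = []
    rows: dict[str, dict[str, int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if not header:
                header = parts
                continue
            label, values = parts[0], parts[1:]
            rows[label] = {h: int(round(float(v)))
                           for h, v in zip(header, values)}
    m = np.zeros((N_LETTERS, N_LETTERS), dtype=np.int64)
    for i, a in enumerate(ALPHABET):
        for j, c in enumerate(ALPHABET):
            m[i, j] = rows[a][c]
    return m


@dataclass
class ScoringParams:
    """Weights and penalties for combined 3Di + AA scoring."""

    tdi_matrix: np.ndarray = field(default_factory=default_3di_matrix)
    aa_matrix: np.ndarray = field(default_factory=blosum62_matrix)
    w_tdi: float = 2.1
    w_aa: float = 1.4
    gap_open: float = 10.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        for name, m in (("tdi_matrix", self.tdi_matrix),
                        ("aa_matrix", self.aa_matrix)):
            m = np.asarray(m)
            if m.shape != (N_LETTERS, N_LETTERS):
                raise ValueError(f"{name} must be {N_LETTERS}x{N_LETTERS}")
            if not np.array_equal(m, m.T):
                raise ValueError(f"{name} must be symmetric")
        if self.w_tdi < 0 or self.w_aa < 0:
            raise ValueError("weights must be non-negative")
        if self.w_tdi == 0 and self.w_aa == 0:
            raise ValueError("at least one of w_tdi, w_aa must be positive")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        # padded matrices with a zero row/column for the neutral symbol
        self._tdi = np.zeros((N_LETTERS + 1, N_LETTERS + 1))
        self._tdi[:N_LETTERS, :N_LETTERS] = self.tdi_matrix
        self._aa = np.zeros((N_LETTERS + 1, N_LETTERS + 1))
        self._aa[:N_LETTERS, :N_LETTERS] = self.aa_matrix

    @classmethod
    def aa_only(cls, **kw) -> "ScoringParams":
        """AA-only scoring (sequence pre-clustering mode)."""
        return cls(w_tdi=0.0, w_aa=1.0, **kw)


def encode(seq: str) -> np.ndarray:
    """Map a sequence to integer letter indices (neutral symbol -> 20)."""
    try:
        return np.fromiter((_LETTER_INDEX[c] for c in seq), dtype=np.int64,
                           count=len(seq))
    except KeyError as exc:
        raise ValueError(f"invalid letter {exc.args[0]!r}") from None


def column_score(a_tdi: str, b_tdi: str, a_aa: str, b_aa: str,
                 params: ScoringParams) -> float:
    """Score one aligned column: w_3di*M3di[a,b] + w_aa*Maa[a,b]."""
    it, jt = _LETTER_INDEX.get(a_tdi), _LETTER_INDEX.get(b_tdi)
    ia, ja = _LETTER_INDEX.get(a_aa), _LETTER_INDEX.get(b_aa)
    if None in (it, jt, ia, ja):
        raise ValueError("invalid letter in column_score")
    return float(params.w_tdi * params._tdi[it, jt]
                 + params.w_aa * params._aa[ia, ja])


def _score_profile(q: StructureRecord, t: StructureRecord,
                   params: ScoringParams) -> np.ndarray:
    """Dense column-score matrix S[i, j] for all residue pairs."""
    qt, tt = encode(q.tdi_seq), encode(t.tdi_seq)
    qa, ta = encode(q.aa_seq), encode(t.aa_seq)
    return (params.w_tdi * params._tdi[np.ix_(qt, tt)]
            + params.w_aa * params._aa[np.ix_(qa, ta)])


def ungapped_diagonal_score(q: StructureRecord, t: StructureRecord,
                            diagonal: int, params: ScoringParams
                            ) -> tuple[float, int, int]:
    """Best contiguous segment score along one diagonal (qpos - tpos).

    1-D local alignment (Kadane with floor 0) under the column score.
    Returns ``(score, qstart, qend)`` with a 0-based half-open query span;
    an empty-overlap diagonal yields ``(0.0, 0, 0)``.
    """
    qlen, tlen = len(q), len(t)
    qstart = max(0, diagonal)
    tstart = qstart - diagonal
    n = min(qlen - qstart, tlen - tstart)
    if n <= 0:
        return 0.0, 0, 0
    qt, tt = encode(q.tdi_seq), encode(t.tdi_seq)
    qa, ta = encode(q.aa_seq), encode(t.aa_seq)
    qi = np.arange(qstart, qstart + n)
    ti = np.arange(tstart, tstart + n)
    s = (params.w_tdi * params._tdi[qt[qi], tt[ti]]
         + params.w_aa * params._aa[qa[qi], ta[ti]])
    best = run = 0.0
    best_start = best_end = run_start = 0
    for i, v in enumerate(s):
        if run <= 0:
            run = 0.0
            run_start = i
        run += v
        if run > best:
            best = run
            best_start, best_end = run_start, i + 1
    if best <= 0:
        return 0.0, 0, 0
    return float(best), qstart + best_start, qstart + best_end


@njit(cache=True)
def _gotoh_kernel(S, gap_open, gap_extend):  # pragma: no cover - jitted
    n, m = S.shape
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), -1e30)  # gap in query (horizontal)
    F = np.full((n + 1, m + 1), -1e30)  # gap in target (vertical)
    # pointers: 0 stop, 1 diagonal, 2 vertical (gap-in-target), 3 horizontal
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)
    ee = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 1: E came from E
    ff = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 1: F came from F
    best = 0.0
    bi = bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e_open = H[i, j - 1] - gap_open
            e_ext = E[i, j - 1] - gap_extend
            if e_ext > e_open:
                E[i, j] = e_ext
                ee[i, j] = 1
            else:
                E[i, j] = e_open
            f_open = H[i - 1, j] - gap_open
            f_ext = F[i - 1, j] - gap_extend
            if f_ext > f_open:
                F[i, j] = f_ext
                ff[i, j] = 1
            else:
                F[i, j] = f_open
            diag = H[i - 1, j - 1] + S[i - 1, j - 1]
            # tie-break: diagonal, then gap-in-target (F), then gap-in-query
            h = 0.0
            p = 0
            if diag >= h and diag >= F[i, j] and diag >= E[i, j]:
                h, p = diag, 1
            elif F[i, j] >= h and F[i, j] >= E[i, j]:
                h, p = F[i, j], 2
            elif E[i, j] >= h:
                h, p = E[i, j], 3
            H[i, j] = h
            ptr[i, j] = p
            if h > best:
                best = h
                bi, bj = i, j
    return best, bi, bj, ptr, ee, ff


@dataclass
class Alignment:
    """A local pairwise alignment with derived statistics."""

    query_id: str
    target_id: str
    columns: list[tuple[int, int]]  # aligned (qpos, tpos), strictly increasing
    score: float
    qlen: int
    tlen: int
    n_columns_total: int = 0        # traceback length including gap columns
    n_identical: int = 0            # AA matches over aligned columns
    evalue: Optional[float] = None
    lddt: Optional[float] = None
    alntmscore: Optional[float] = None

    @property
    def qcov(self) -> float:
        if not self.columns:
            return 0.0
        qs, qe = self.columns[0][0], self.columns[-1][0] + 1
        return (qe - qs) / self.qlen

    @property
    def tcov(self) -> float:
        if not self.columns:
            return 0.0
        ts, te = self.columns[0][1], self.columns[-1][1] + 1
        return (te - ts) / self.tlen

    @property
    def seq_identity(self) -> float:
        """Matches divided by alignment length (gap columns included)."""
        if self.n_columns_total == 0:
            return 0.0
        return self.n_identical / self.n_columns_total


def gapped_align(q: StructureRecord, t: StructureRecord,
                 params: ScoringParams) -> Alignment:
    """Optimal local alignment with affine gaps (Gotoh).

    Traceback is deterministic: at score ties the diagonal move is
    preferred, then the gap-in-target move, then gap-in-query.
    """
    if len(q) == 0 or len(t) == 0:
        raise ValueError("sequences must be non-empty")
    S = _score_profile(q, t, params)
    best, bi, bj, ptr, ee, ff = _gotoh_kernel(
        S, float(params.gap_open), float(params.gap_extend))
    columns: list[tuple[int, int]] = []
    n_total = 0
    n_ident = 0
    if best > 0:
        i, j = bi, bj
        state = 0  # 0: in H, 2: in F chain, 3: in E chain
        while i > 0 and j > 0:
            p = ptr[i, j] if state == 0 else state
            if state == 0 and p == 0:
                break
            if p == 1:
                columns.append((i - 1, j - 1))
                if q.aa_seq[i - 1] == t.aa_seq[j - 1]:
                    n_ident += 1
                n_total += 1
                i, j = i - 1, j - 1
                state = 0
            elif p == 2:  # vertical: consumes query residue, gap in target
                n_total += 1
                state = 2 if ff[i, j] else 0
                i -= 1
            else:  # horizontal: consumes target residue, gap in query
                n_total += 1
                state = 3 if ee[i, j] else 0
                j -= 1
        columns.reverse()
    return Alignment(
        query_id=q.id,
        target_id=t.id,
        columns=columns,
        score=float(best),
        qlen=len(q),
        tlen=len(t),
        n_columns_total=n_total,
        n_identical=n_ident,
    )


@dataclass
class GumbelParams:
    """Extreme-value (Gumbel) parameters of the null score distribution."""

    lambda_: float
    K: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lambda_) and self.lambda_ > 0):
            raise ValueError("lambda must be finite and positive")
        if not (np.isfinite(self.K) and self.K > 0):
            raise ValueError("K must be finite and positive")


def calibrate_evalue(decoy_set: StructureSet, n_pairs: int, seed: int,
                     params: ScoringParams) -> GumbelParams:
    """Fit Gumbel null parameters from alignments of shuffled decoy pairs.

    Random record pairs are drawn, each sequence is shuffled (AA and 3Di
    with the same permutation, preserving the pairing of the two strings),
    and the local alignment score is collected.  A Gumbel distribution is
    fitted by maximum likelihood (moment-based start); ``lambda = 1/scale``
    and ``K = exp(lambda * loc) / (mean_m * mean_n)``.
    """
    if n_pairs < 100:
        raise ValueError("n_pairs must be >= 100 for a stable calibration")
    rng = np.random.default_rng(seed)
    recs = list(decoy_set)
    if len(recs) < 2:
        raise ValueError("decoy set must contain at least two records")
    scores = np.empty(n_pairs)
    mn = []
    for p in range(n_pairs):
        a, b = rng.choice(len(recs), size=2, replace=False)
        qa, qb = recs[a], recs[b]
        pa = rng.permutation(len(qa))
        pb = rng.permutation(len(qb))
        sq = StructureRecord(
            id="d1",
            aa_seq="".join(qa.aa_seq[i] for i in pa),
            tdi_seq="".join(qa.tdi_seq[i] for i in pa),
        )
        st = StructureRecord(
            id="d2",
            aa_seq="".join(qb.aa_seq[i] for i in pb),
            tdi_seq="".join(qb.tdi_seq[i] for i in pb),
        )
        scores[p] = gapped_align(sq, st, params).score
        mn.append(len(sq) * len(st))
    return fit_gumbel(scores, float(np.mean(mn)))


def fit_gumbel(scores: np.ndarray, mean_mn: float) -> GumbelParams:
    """Fit Gumbel params to max-score draws (moments init, ML refine)."""
    scores = np.asarray(scores, dtype=float)
    if np.ptp(scores) == 0:
        raise ValueError("degenerate decoy scores: all equal")
    scale0 = np.std(scores) * np.sqrt(6) / np.pi
    loc0 = np.mean(scores) - np.euler_gamma * scale0
    loc, scale = stats.gumbel_r.fit(scores, loc=loc0, scale=scale0)
    lam = 1.0 / scale
    K = float(np.exp(lam * loc) / mean_mn)
    return GumbelParams(lambda_=lam, K=K)


def evalue(score: float, qlen: int, tlen: int, gumbel: GumbelParams,
           db_size: int = 1) -> float:
    """Karlin-Altschul style E-value: K * m * n * db_size * exp(-lambda*s)."""
    return float(gumbel.K * qlen * tlen * db_size
                 * np.exp(-gumbel.lambda_ * score))


# ---------------------------------------------------------------------------
# structural metrics

LDDT_THRESHOLDS = (0.5, 1.0, 2.0, 4.0)
LDDT_RADIUS = 15.0


def alignment_lddt(alignment: Alignment, qcoords: np.ndarray,
                   tcoords: np.ndarray) -> float:
    """C-alpha alignment LDDT of the target mapped onto query distances.

    For every pair of aligned columns whose query-side C-alpha distance is
    below 15 A (sequence separation >= 1), the fraction whose distance
    difference falls under each of the thresholds {0.5, 1, 2, 4} A is
    averaged over the four thresholds.
    """
    if qcoords is None or tcoords is None:
        raise ValueError("both structures need coordinates for LDDT")
    cols = alignment.columns
    if len(cols) < 2:
        raise ValueError("LDDT undefined for fewer than 2 aligned columns")
    qi = np.array([c[0] for c in cols])
    ti = np.array([c[1] for c in cols])
    qc = np.asarray(qcoords, dtype=float)[qi]
    tc = np.asarray(tcoords, dtype=float)[ti]
    dq = np.linalg.norm(qc[:, None, :] - qc[None, :, :], axis=-1)
    dt = np.linalg.norm(tc[:, None, :] - tc[None, :, :], axis=-1)
    iu, ju = np.triu_indices(len(cols), k=1)
    mask = dq[iu, ju] < LDDT_RADIUS
    if not np.any(mask):
        raise ValueError("no residue pairs within the LDDT inclusion radius")
    diff = np.abs(dq[iu, ju][mask] - dt[iu, ju][mask])
    fractions = [np.mean(diff < thr) for thr in LDDT_THRESHOLDS]
    return float(np.mean(fractions))


@dataclass
class Superposition:
    """Least-squares rigid-body superposition result."""

    rotation: np.ndarray  # 3x3 proper rotation
    translation: np.ndarray  # 3-vector
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def superpose(A: np.ndarray, B: np.ndarray) -> Superposition:
    """Superpose B onto A: find R, t minimizing ||A - (B R^T + t)||.

    Kabsch/SVD with reflection correction.  Requires N >= 3; collinear
    point sets are still handled but trigger a warning.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("A and B must both be N x 3")
    n = A.shape[0]
    if n < 3:
        raise ValueError("superposition requires at least 3 points")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    Ac, Bc = A - ca, B - cb
    H = Bc.T @ Ac
    U, s, Vt = np.linalg.svd(H)
    if s[1] < 1e-9 * max(s[0], 1.0):
        warnings.warn("nearly collinear point set: superposition ill-conditioned")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - cb @ R.T
    diff = A - (B @ R.T + t)
    rmsd = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
    return Superposition(rotation=R, translation=t, rmsd=rmsd)


def tm_d0(l_norm: int) -> float:
    """TM-score distance scale d0, floored at 0.5 A."""
    if l_norm > 15:
        d0 = 1.24 * (l_norm - 15) ** (1.0 / 3.0) - 1.8
    else:
        d0 = 0.5
    return max(d0, 0.5)


def tm_score(alignment: Alignment, qcoords: np.ndarray, tcoords: np.ndarray,
             normalize: str = "query") -> float:
    """TM-score of an alignment, maximized by iterative superposition.

    Starting from a superposition on all aligned columns, the column subset
    is refined by keeping columns with superposed distance below d0-scaled
    cutoffs (d0 * c for c in {8,...,3}), re-superposing until the subset is
    stable; the best score over all visited superpositions is returned.
    """
    cols = alignment.columns
    if len(cols) < 3:
        raise ValueError("TM-score requires at least 3 aligned columns")
    if normalize == "query":
        l_norm = alignment.qlen
    elif normalize == "target":
        l_norm = alignment.tlen
    else:
        raise ValueError("normalize must be 'query' or 'target'")
    d0 = tm_d0(l_norm)
    qi = np.array([c[0] for c in cols])
    ti = np.array([c[1] for c in cols])
    qc = np.asarray(qcoords, dtype=float)[qi]
    tc = np.asarray(tcoords, dtype=float)[ti]

    def score_from(sub: np.ndarray) -> tuple[float, np.ndarray]:
        sp = superpose(qc[sub], tc[sub])
        d = np.linalg.norm(qc - sp.apply(tc), axis=1)
        return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_norm), d

    all_idx = np.arange(len(cols))
    best, d = score_from(all_idx)
    for cut in (8.0, 7.0, 6.0, 5.0, 4.0, 3.0):
        thr = d0 * cut  # inclusion radius shrinks with the cut schedule
        sub = all_idx[d < thr] if np.sum(d < thr) >= 3 else all_idx
        prev: Optional[np.ndarray] = None
        for _ in range(20):
            if prev is not None and np.array_equal(sub, prev):
                break
            prev = sub
            s, dd = score_from(sub)
            best = max(best, s)
            nxt = all_idx[dd < thr]
            if len(nxt) < 3:
                break
            sub = nxt
    return best
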