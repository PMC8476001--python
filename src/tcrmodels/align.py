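"""Fixed-width multiple alignment of variable-length CDR3s.

Pipeline (default width 19):

1. per-length position weight matrices (PWMs);
2. progressive profile-profile alignment from the shortest to the longest
   length, inserting one gap column into the shorter profile per step
   (Needleman-Wunsch on profile columns, expected BLOSUM62 column score,
   affine gap penalties);
3. a profile HMM estimated from the resulting seed alignment, with match
   states assigned to the columns of lowest gap fraction;
4. Viterbi alignment of every sequence to the HMM. Residues routed through
   insert states are dropped from the emitted fixed-width string and the
   sequence is flagged as truncated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .alphabet import AA_INDEX, AMINO_ACIDS, GAP, N_AA

logger = logging.getLogger(__name__)

DEFAULT_N_MATCH = 19
DEFAULT_L_MIN = 5
DEFAULT_L_MAX = 23
DEFAULT_GAP_OPEN = 8.0
DEFAULT_GAP_EXTEND = 1.0


def _blosum62() -> np.ndarray:
    mat = substitution_matrices.load("BLOSUM62")
    out = np.zeros((N_AA, N_AA))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            out[i, j] = mat[a][b]
    return out


_B62 = _blosum62()


@dataclass
class PositionWeightMatrix:
    """Residue frequencies per column for one CDR3 length."""

    columns: np.ndarray  # (length, 20), rows sum to 1
    length: int
    support: int

    def __post_init__(self) -> None:
        if self.columns.shape != (self.length, N_AA):
            raise ValueError("PWM shape mismatch")


@dataclass
class SeedAlignment:
    """Gapped rows of width l_max plus the per-length gap patterns."""

    rows: list[str]
    width: int
    column_maps: dict[int, list[int]] = field(default_factory=dict)


@dataclass
class ProfileHMM:
    n_match: int
    match_emissions: np.ndarray  # (n_match, 20)
    insert_emissions: np.ndarray  # (n_match + 1, 20)
    # transitions[k, from, to]; from/to in {M, I, D}; k = 0..n_match
    transitions: np.ndarray

    M, I, D = 0, 1, 2


@dataclass
class AlignedCDR3:
    aligned: str
    source: str
    truncated: bool = False
    score: float = 0.0


def build_length_profiles(
    seqs: list[str],
    l_min: int = DEFAULT_L_MIN,
    l_max: int = DEFAULT_L_MAX,
    pseudocount: float = 0.0,
) -> dict[int, PositionWeightMatrix]:
    """Maximum-likelihood PWM per CDR3 length in [l_min, l_max]."""
    if not seqs:
        raise ValueError("no sequences")
    by_length: dict[int, list[str]] = {}
    for s in seqs:
        if l_min <= len(s) <= l_max:
            by_length.setdefault(len(s), []).append(s)
    if not by_length:
        raise ValueError(f"no sequences with length in [{l_min}, {l_max}]")
    profiles: dict[int, PositionWeightMatrix] = {}
    for l, group in sorted(by_length.items()):
        counts = np.full((l, N_AA), pseudocount, dtype=float)
        for s in group:
            for i, c in enumerate(s):
                counts[i, AA_INDEX[c]] += 1.0
        profiles[l] = PositionWeightMatrix(
            counts / counts.sum(axis=1, keepdims=True), length=l, support=len(group)
        )
    return profiles


def _column_score(p: np.ndarray, gap_p: float, q: np.ndarray) -> float:
    # expected BLOSUM62 under the product of the two residue distributions,
    # discounted by the gap mass of the (possibly gappy) seed column
    return float((1.0 - gap_p) * p @ _B62 @ q)


def _align_seed_to_profile(
    seed_cols: np.ndarray,
    seed_gap: np.ndarray,
    pwm: np.ndarray,
    gap_open: float,
    gap_extend: float,
) -> list[int]:
    """Positions (in the longer profile) receiving gap columns in the seed.

    Global alignment in which the seed (width w) is threaded through the
    longer profile (width l > w); gaps are only inserted into the seed, so
    exactly l - w gap columns result.
    """
    w = seed_cols.shape[0]
    l = pwm.shape[0]
    NEG = -np.inf
    score = np.full((w + 1, l + 1), NEG)
    in_gap = np.full((w + 1, l + 1), False)
    ptr = np.zeros((w + 1, l + 1), dtype=np.int8)  # 1 diag, 2 gap-in-seed
    score[0, 0] = 0.0
    for j in range(1, l + 1):
        score[0, j] = -(gap_open + gap_extend * (j - 1))
        ptr[0, j] = 2
        in_gap[0, j] = True
    for i in range(1, w + 1):
        for j in range(i, l + 1):  # seed column i needs >= i profile columns
            diag = score[i - 1, j - 1] + _column_score(
                seed_cols[i - 1], seed_gap[i - 1], pwm[j - 1]
            )
            if score[i, j - 1] > NEG:
                gap_cost = gap_extend if in_gap[i, j - 1] else gap_open
                gap = score[i, j - 1] - gap_cost
            else:
                gap = NEG
            if diag >= gap:
                score[i, j], ptr[i, j], in_gap[i, j] = diag, 1, False
            else:
                score[i, j], ptr[i, j], in_gap[i, j] = gap, 2, True
    # backtrace
    gaps: list[int] = []
    i, j = w, l
    while i > 0 or j > 0:
        if ptr[i, j] == 1:
            i, j = i - 1, j - 1
        else:
            gaps.append(j - 1)
            j -= 1
    return sorted(gaps)


def progressive_profile_align(
    profiles: dict[int, PositionWeightMatrix],
    seqs: list[str] | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    bridge: bool = False,
) -> SeedAlignment:
    """Progressively align per-length profiles from l_min to l_max.

    Lengths must form a contiguous range unless ``bridge`` is set, in which
    case a step across a missing length inserts several gap columns at once.
    Returns the seed alignment of width l_max together with a column map per
    length; when ``seqs`` is given, every sequence is threaded through its
    length's gap pattern to produce the alignment rows.
    """
    lengths = sorted(profiles)
    if not lengths:
        raise ValueError("no profiles")
    if not bridge and lengths != list(range(lengths[0], lengths[-1] + 1)):
        raise ValueError(
            f"profile lengths {lengths} are not contiguous; pool sequences or "
            "bridge the missing lengths before aligning"
        )
    l0 = lengths[0]
    # seed profile over residues + explicit gap mass, support-weighted
    seed_cols = profiles[l0].columns.copy()
    seed_gap = np.zeros(l0)
    seed_support = float(profiles[l0].support)
    column_maps: dict[int, list[int]] = {l0: list(range(l0))}

    for l in lengths[1:]:
        pwm = profiles[l]
        gap_positions = _align_seed_to_profile(
            seed_cols, seed_gap, pwm.columns, gap_open, gap_extend
        )
        # insert gap columns into the seed at the reported positions
        assert seed_cols.shape[0] + len(gap_positions) == l
        new_cols = np.zeros((l, N_AA))
        new_gap = np.zeros(l)
        gapset = set(gap_positions)
        src = 0
        old_to_new: list[int] = []
        for j in range(l):
            if j in gapset:
                new_gap[j] = 1.0
                new_cols[j] = seed_cols.mean(axis=0)  # placeholder residue mix
            else:
                new_cols[j] = seed_cols[src]
                new_gap[j] = seed_gap[src]
                old_to_new.append(j)
                src += 1
        for ln, cmap in column_maps.items():
            column_maps[ln] = [old_to_new[c] for c in cmap]
        column_maps[l] = list(range(l))
        # merge with the new length's PWM, weighting by support
        tot = seed_support + pwm.support
        merged = (seed_support * ((1 - new_gap)[:, None] * new_cols) +
                  pwm.support * pwm.columns)
        norm = merged.sum(axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        seed_cols = merged / norm
        seed_gap = seed_support * new_gap / tot
        seed_support = tot

    width = lengths[-1]
    rows: list[str] = []
    if seqs is not None:
        for s in seqs:
            cmap = column_maps.get(len(s))
            if cmap is None:
                continue
            row = [GAP] * width
            for c, col in zip(s, cmap):
                row[col] = c
            rows.append("".join(row))
    return SeedAlignment(rows=rows, width=width, column_maps=column_maps)


def build_hmm_profile(
    seed: SeedAlignment, n_match: int = DEFAULT_N_MATCH, pseudocount: float = 1.0
) -> ProfileHMM:
    """Estimate a profile HMM from a seed alignment.

    Match states are the ``n_match`` columns with the lowest gap fraction
    (ties broken leftmost); emissions and transitions get Laplace
    pseudocounts.
    """
    if n_match > seed.width:
        raise ValueError(f"n_match {n_match} exceeds seed width {seed.width}")
    if not seed.rows:
        raise ValueError("seed alignment has no rows")
    rows = seed.rows
    width = seed.width
    gap_frac = np.array(
        [sum(r[j] == GAP for r in rows) / len(rows) for j in range(width)]
    )
    order = sorted(range(width), key=lambda j: (gap_frac[j], j))
    match_cols = sorted(order[:n_match])
    is_match = np.zeros(width, dtype=bool)
    is_match[match_cols] = True

    m = n_match
    M, I, D = ProfileHMM.M, ProfileHMM.I, ProfileHMM.D
    match_counts = np.full((m, N_AA), pseudocount)
    insert_counts = np.full((m + 1, N_AA), pseudocount)
    trans_counts = np.full((m + 1, 3, 3), pseudocount)
    # delete states do not exist at the flanks of the architecture:
    # from k=0 nothing can come *from* D, and no transition enters D past m
    trans_counts[0, D, :] = 0.0
    trans_counts[m, :, D] = 0.0

    col_to_match = {c: k for k, c in enumerate(match_cols)}
    for r in rows:
        state, k = M, 0  # begin state = (M, 0)
        for j in range(width):
            c = r[j]
            if is_match[j]:
                kk = col_to_match[j]
                if c == GAP:
                    trans_counts[k, state, D] += 1.0
                    state = D
                else:
                    match_counts[kk, AA_INDEX[c]] += 1.0
                    trans_counts[k, state, M] += 1.0
                    state = M
                k = kk + 1
            else:
                if c != GAP:
                    insert_counts[k, AA_INDEX[c]] += 1.0
                    trans_counts[k, state, I] += 1.0
                    state = I
        trans_counts[m, state, M] += 1.0  # exit to end

    transitions = np.zeros_like(trans_counts)
    for k in range(m + 1):
        for s in (M, I, D):
            tot = trans_counts[k, s].sum()
            if tot > 0:
                transitions[k, s] = trans_counts[k, s] / tot
    return ProfileHMM(
        n_match=m,
        match_emissions=match_counts / match_counts.sum(axis=1, keepdims=True),
        insert_emissions=insert_counts / insert_counts.sum(axis=1, keepdims=True),
        transitions=transitions,
    )


def align_to_profile(seq: str, hmm: ProfileHMM) -> AlignedCDR3:
    """Viterbi alignment of one CDR3 to the profile HMM.

    Ties are broken toward match states. The emitted string has exactly
    ``n_match`` symbols; insert-state residues are dropped and flagged.
    """
    if not seq:
        raise ValueError("empty sequence")
    m = hmm.n_match
    L = len(seq)
    M, I, D = ProfileHMM.M, ProfileHMM.I, ProfileHMM.D
    with np.errstate(divide="ignore"):
        lt = np.log(hmm.transitions)
        le_m = np.log(hmm.match_emissions)
        le_i = np.log(hmm.insert_emissions)
    x = np.array([AA_INDEX[c] for c in seq])

    NEG = -np.inf
    vm = np.full((m + 1, L + 1), NEG)
    vi = np.full((m + 1, L + 1), NEG)
    vd = np.full((m + 1, L + 1), NEG)
    bm = np.zeros((m + 1, L + 1), dtype=np.int8)
    bi = np.zeros((m + 1, L + 1), dtype=np.int8)
    bd = np.zeros((m + 1, L + 1), dtype=np.int8)
    vm[0, 0] = 0.0  # begin

    def best(cands):
        # cands: list of (score, state_tag); prefer M on ties, then I, then D
        s, tag = cands[0]
        for sc, tg in cands[1:]:
            if sc > s:
                s, tag = sc, tg
        return s, tag

    for k in range(0, m + 1):
        for j in range(0, L + 1):
            if k > 0 and j > 0:
                s, tag = best(
                    [
                        (vm[k - 1, j - 1] + lt[k - 1, M, M], M),
                        (vi[k - 1, j - 1] + lt[k - 1, I, M], I),
                        (vd[k - 1, j - 1] + lt[k - 1, D, M], D),
                    ]
                )
                vm[k, j] = s + le_m[k - 1, x[j - 1]]
                bm[k, j] = tag
            if j > 0 and not (k == 0 and j == 0):
                s, tag = best(
                    [
                        (vm[k, j - 1] + lt[k, M, I], M),
                        (vi[k, j - 1] + lt[k, I, I], I),
                        (vd[k, j - 1] + lt[k, D, I], D),
                    ]
                )
                vi[k, j] = s + le_i[k, x[j - 1]]
                bi[k, j] = tag
            if k > 0:
                s, tag = best(
                    [
                        (vm[k - 1, j] + lt[k - 1, M, D], M),
                        (vi[k - 1, j] + lt[k - 1, I, D], I),
                        (vd[k - 1, j] + lt[k - 1, D, D], D),
                    ]
                )
                vd[k, j] = s
                bd[k, j] = tag

    ends = [
        (vm[m, L] + lt[m, M, M], M),
        (vi[m, L] + lt[m, I, M], I),
        (vd[m, L] + lt[m, D, M], D),
    ]
    total, state = best(ends)

    # backtrace
    k, j = m, L
    out = [GAP] * m
    used_insert = False
    while k > 0 or j > 0:
        if state == M:
            out[k - 1] = seq[j - 1]
            prev = bm[k, j]
            k, j = k - 1, j - 1
        elif state == I:
            used_insert = True
            prev = bi[k, j]
            j -= 1
        else:  # D
            prev = bd[k, j]
            k -= 1
        state = prev
        if k == 0 and j == 0:
            break
    return AlignedCDR3(
        aligned="".join(out), source=seq, truncated=used_insert, score=float(total)
    )


def align_all(
    seqs: list[str],
    n_match: int = DEFAULT_N_MATCH,
    l_min: int = DEFAULT_L_MIN,
    l_max: int = DEFAULT_L_MAX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    pseudocount: float = 1.0,
) -> list[AlignedCDR3]:
    """Run the full alignment pipeline; deterministic in the inputs."""
    if not seqs:
        raise ValueError("no sequences")
    profiles = build_length_profiles(seqs, l_min=l_min, l_max=l_max)
    in_range = sorted((s for s in set(seqs) if l_min <= len(s) <= l_max))
    seed = progressive_profile_align(
        profiles, seqs=in_range, gap_open=gap_open, gap_extend=gap_extend,
        bridge=True,
    )
    hmm = build_hmm_profile(seed, n_match=n_match, pseudocount=pseudocount)
    cache: dict[str, AlignedCDR3] = {}
    out = []
    for s in seqs:
        if s not in cache:
            cache[s] = align_to_profile(s, hmm)
        a = cache[s]
        out.append(AlignedCDR3(a.aligned, a.source, a.truncated, a.score))
    return out


def save_hmm(hmm: ProfileHMM, path) -> None:
    np.savez(
        path,
        match_emissions=hmm.match_emissions,
        insert_emissions=hmm.insert_emissions,
        transitions=hmm.transitions,
        n_match=np.array(hmm.n_match),
    )


def load_hmm(path) -> ProfileHMM:
    with np.load(path, allow_pickle=False) as data:
        return ProfileHMM(
            n_match=int(data["n_match"]),
            match_emissions=data["match_emissions"],
            insert_emissions=data["insert_emissions"],
            transitions=data["transitions"],
        )


def write_msa_fasta(aligned: list[AlignedCDR3], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for i, a in enumerate(aligned):
            fh.write(f">{i} src={a.source} truncated={int(a.truncated)}\n{a.aligned}\n")
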