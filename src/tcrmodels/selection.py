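"""Independent-site selection model over Left+Right CDR3 features.

The model reweights a pluggable background distribution P_bg:

    P(sigma) = Q(sigma) P_bg(sigma),
    Q(sigma) = (1/Z) prod_i q^L(d_left(i), sigma_i) * q^R(d_right(i), sigma_i),

with one positive selection factor per (side, distance-from-anchor, residue)
up to a reference length (default 19); out-of-range distances contribute
factor 1. q-factors are learned by weighted maximum likelihood with an L2
penalty on the log-factors; the model expectation of the gradient and the
normalization Z are estimated on fresh background samples each epoch
(importance reweighting by the unnormalized Q).
"""

from __future__ import annotations

import json
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

from .alphabet import AA_INDEX, AMINO_ACIDS, N_AA, validate_cdr3
from .encoding import DEFAULT_REF_LENGTH, left_right_encode


class UnsupportedSequenceError(ValueError):
    """Sequence has zero probability under the background model."""


class BackgroundModel(ABC):
    """Interface for background CDR3 distributions (P_gen / P_post / P_0 stand-ins).

    External generation-probability providers can be adapted by implementing
    this interface.
    """

    @abstractmethod
    def log_prob(self, cdr3: str) -> float:
        """Normalized log probability; raises UnsupportedSequenceError at zero mass."""

    @abstractmethod
    def sample(self, n: int, seed: int | np.random.Generator = 0) -> list[str]:
        """Draw n CDR3s."""


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


class EmpiricalBackground(BackgroundModel):
    """Categorical distribution over the unique sequences of a sample."""

    def __init__(self, sequences: list[str], weights=None):
        if not sequences:
            raise ValueError("insufficient fit data")
        counts: dict[str, float] = {}
        if weights is None:
            weights = np.ones(len(sequences))
        for s, w in zip(sequences, weights):
            counts[s] = counts.get(s, 0.0) + float(w)
        self.sequences = list(counts)
        p = np.array([counts[s] for s in self.sequences])
        self.probs = p / p.sum()
        self._index = {s: i for i, s in enumerate(self.sequences)}

    def log_prob(self, cdr3: str) -> float:
        i = self._index.get(cdr3)
        if i is None:
            raise UnsupportedSequenceError(f"{cdr3!r} unseen in empirical background")
        return float(np.log(self.probs[i]))

    def sample(self, n: int, seed=0) -> list[str]:
        rng = _as_rng(seed)
        idx = rng.choice(len(self.sequences), size=n, p=self.probs)
        return [self.sequences[i] for i in idx]


class PositionwiseBackground(BackgroundModel):
    """Anchored independent-site model: P(sigma) = P(l) * first * interior * last.

    The first and last residues have their own distributions (capturing the
    C and F/V anchors); interior residues are independent with per-left-
    position distributions shared across lengths. Exactly normalized.
    """

    def __init__(self, sequences: list[str], pseudocount: float = 0.5, max_len: int = 30,
                 anchor_pseudocount: float = 0.0):
        if not sequences:
            raise ValueError("insufficient fit data")
        self.max_len = max_len
        len_counts = np.zeros(max_len + 1)
        # anchors are fit without smoothing so hard constraints in the data
        # (first residue C, last F/V) stay hard in the model
        first = np.full(N_AA, anchor_pseudocount)
        last = np.full(N_AA, anchor_pseudocount)
        interior = np.full((max_len, N_AA), pseudocount)
        for s in sequences:
            validate_cdr3(s)
            l = len(s)
            if l < 2 or l > max_len:
                continue
            len_counts[l] += 1
            first[AA_INDEX[s[0]]] += 1
            last[AA_INDEX[s[-1]]] += 1
            for i in range(1, l - 1):
                interior[i, AA_INDEX[s[i]]] += 1
        if len_counts.sum() == 0:
            raise ValueError("insufficient fit data (no sequence of length 2..max_len)")
        self.length_probs = len_counts / len_counts.sum()
        self.first = first / first.sum()
        self.last = last / last.sum()
        self.interior = interior / interior.sum(axis=1, keepdims=True)

    def log_prob(self, cdr3: str) -> float:
        validate_cdr3(cdr3)
        l = len(cdr3)
        if l > self.max_len or l < 2 or self.length_probs[l] == 0:
            raise UnsupportedSequenceError(f"length {l} unsupported by background")
        if self.first[AA_INDEX[cdr3[0]]] == 0 or self.last[AA_INDEX[cdr3[-1]]] == 0:
            raise UnsupportedSequenceError(f"anchor residues of {cdr3!r} have zero mass")
        lp = np.log(self.length_probs[l])
        lp += np.log(self.first[AA_INDEX[cdr3[0]]])
        lp += np.log(self.last[AA_INDEX[cdr3[-1]]])
        for i in range(1, l - 1):
            lp += np.log(self.interior[i, AA_INDEX[cdr3[i]]])
        return float(lp)

    def sample(self, n: int, seed=0) -> list[str]:
        rng = _as_rng(seed)
        lengths = rng.choice(self.max_len + 1, size=n, p=self.length_probs)
        max_l = int(lengths.max())
        firsts = rng.choice(N_AA, size=n, p=self.first)
        lasts = rng.choice(N_AA, size=n, p=self.last)
        mids = np.stack(
            [rng.choice(N_AA, size=n, p=self.interior[i]) for i in range(1, max_l - 1)],
            axis=1,
        ) if max_l > 2 else np.zeros((n, 0), dtype=int)
        out = []
        for k, l in enumerate(lengths):
            mid = "".join(AMINO_ACIDS[a] for a in mids[k, : l - 2])
            out.append(AMINO_ACIDS[firsts[k]] + mid + AMINO_ACIDS[lasts[k]])
        return out


class Markov1Background(BackgroundModel):
    """Order-1 Markov chain per position with an anchored first residue."""

    def __init__(self, sequences: list[str], pseudocount: float = 0.5, max_len: int = 30,
                 anchor_pseudocount: float = 0.0):
        if not sequences:
            raise ValueError("insufficient fit data")
        self.max_len = max_len
        len_counts = np.zeros(max_len + 1)
        first = np.full(N_AA, anchor_pseudocount)
        trans = np.full((N_AA, N_AA), pseudocount)
        for s in sequences:
            validate_cdr3(s)
            l = len(s)
            if l < 2 or l > max_len:
                continue
            len_counts[l] += 1
            first[AA_INDEX[s[0]]] += 1
            for a, b in zip(s, s[1:]):
                trans[AA_INDEX[a], AA_INDEX[b]] += 1
        if len_counts.sum() == 0:
            raise ValueError("insufficient fit data")
        self.length_probs = len_counts / len_counts.sum()
        self.first = first / first.sum()
        self.trans = trans / trans.sum(axis=1, keepdims=True)

    def log_prob(self, cdr3: str) -> float:
        validate_cdr3(cdr3)
        l = len(cdr3)
        if l > self.max_len or l < 2 or self.length_probs[l] == 0:
            raise UnsupportedSequenceError(f"length {l} unsupported by background")
        if self.first[AA_INDEX[cdr3[0]]] == 0:
            raise UnsupportedSequenceError(f"first residue of {cdr3!r} has zero mass")
        lp = np.log(self.length_probs[l]) + np.log(self.first[AA_INDEX[cdr3[0]]])
        for a, b in zip(cdr3, cdr3[1:]):
            lp += np.log(self.trans[AA_INDEX[a], AA_INDEX[b]])
        return float(lp)

    def sample(self, n: int, seed=0) -> list[str]:
        rng = _as_rng(seed)
        lengths = rng.choice(self.max_len + 1, size=n, p=self.length_probs)
        max_l = int(lengths.max())
        cum = np.cumsum(self.trans, axis=1)
        states = np.empty((n, max_l), dtype=int)
        states[:, 0] = rng.choice(N_AA, size=n, p=self.first)
        for t in range(1, max_l):
            u = rng.random(n)
            states[:, t] = (cum[states[:, t - 1]] < u[:, None]).sum(axis=1)
        return [
            "".join(AMINO_ACIDS[a] for a in states[k, :l]) for k, l in enumerate(lengths)
        ]


def builtin_background(kind: str, fit_data: list[str], seed: int = 0, **kwargs) -> BackgroundModel:
    """Fit one of the built-in background models to a list of CDR3s."""
    kinds = {
        "empirical_day0": EmpiricalBackground,
        "positionwise_independent": PositionwiseBackground,
        "markov1": Markov1Background,
    }
    if kind not in kinds:
        raise ValueError(f"unknown background kind {kind!r}; choose from {sorted(kinds)}")
    return kinds[kind](fit_data, **kwargs)


@dataclass
class SelectionModel:
    """Left+Right q-factors on top of a background distribution."""

    log_qL: np.ndarray  # (ref_length, 20)
    log_qR: np.ndarray  # (ref_length, 20)
    log_z: float
    background: BackgroundModel | None = None
    ref_length: int = DEFAULT_REF_LENGTH

    @classmethod
    def neutral(cls, background: BackgroundModel | None = None,
                ref_length: int = DEFAULT_REF_LENGTH) -> "SelectionModel":
        return cls(
            np.zeros((ref_length, N_AA)), np.zeros((ref_length, N_AA)),
            log_z=0.0, background=background, ref_length=ref_length,
        )

    @property
    def theta(self) -> np.ndarray:
        """Flat log-factor vector in Left+Right feature order."""
        return np.concatenate([self.log_qL.ravel(), self.log_qR.ravel()])

    def q_factor(self, position_from_left: int, length: int, residue: str) -> float:
        """Combined L x R selection factor of one residue at one position."""
        if not (0 <= position_from_left < length):
            raise ValueError("position outside sequence")
        a = AA_INDEX.get(residue)
        if a is None:
            raise ValueError(f"invalid residue {residue!r}")
        lq = 0.0
        if position_from_left < self.ref_length:
            lq += self.log_qL[position_from_left, a]
        d_right = length - 1 - position_from_left
        if d_right < self.ref_length:
            lq += self.log_qR[d_right, a]
        return float(np.exp(lq))

    def log_q_tilde(self, cdr3: str) -> float:
        """Unnormalized log selection weight: features dot log-factors."""
        enc = left_right_encode(cdr3, self.ref_length)
        return float(enc.vector @ self.theta)

    def log_prob(self, cdr3: str) -> float:
        if self.background is None:
            raise ValueError("selection model has no background attached")
        bg = self.background.log_prob(cdr3)  # raises on unsupported sequences
        return self.log_q_tilde(cdr3) - self.log_z + bg

    def sample(self, n: int, seed=0, n_proposals: int | None = None) -> list[str]:
        """Sample from Q * P_bg by importance resampling of background draws."""
        rng = _as_rng(seed)
        if n_proposals is None:
            n_proposals = max(20 * n, 2000)
        props = self.background.sample(n_proposals, rng)
        logq = np.array([self.log_q_tilde(s) for s in props])
        p = np.exp(logq - logsumexp(logq))
        idx = rng.choice(n_proposals, size=n, p=p)
        return [props[i] for i in idx]


def _feature_matrix(seqs: list[str], ref_length: int) -> np.ndarray:
    return np.stack(
        [left_right_encode(s, ref_length).vector for s in seqs]
    ).astype(float)


def estimate_log_z(theta: np.ndarray, bg_features: np.ndarray) -> float:
    """Monte-Carlo log Z = log E_bg[exp(features dot theta)]."""
    logq = bg_features @ theta
    return float(logsumexp(logq) - np.log(len(logq)))


@dataclass
class SoniaTrainingLog:
    epochs: list[int] = field(default_factory=list)
    objective: list[float] = field(default_factory=list)


def train_sonia(
    sequences: list[str],
    background: BackgroundModel,
    weights: np.ndarray | None = None,
    l2: float = 0.01,
    n_background_samples: int = 20000,
    epochs: int = 150,
    learning_rate: float = 0.5,
    ref_length: int = DEFAULT_REF_LENGTH,
    seed: int = 0,
    resample_every: int = 10,
) -> tuple[SelectionModel, SoniaTrainingLog]:
    """Weighted maximum-likelihood fit of the selection factors.

    The concave objective <log Q>_data - log Z - l2 ||log q||^2 is climbed by
    plain gradient ascent; the model expectation and Z use background samples
    importance-weighted by the unnormalized Q, redrawn every
    ``resample_every`` epochs. Deterministic given ``seed``.
    """
    if not sequences:
        raise ValueError("no training sequences")
    rng = np.random.default_rng(seed)
    if weights is None:
        weights = np.ones(len(sequences))
    weights = np.asarray(weights, dtype=float)
    w = weights / weights.sum()

    X = _feature_matrix(sequences, ref_length)
    data_mean = w @ X
    dim = X.shape[1]
    theta = np.zeros(dim)
    log = SoniaTrainingLog()
    bg_feats: np.ndarray | None = None

    for epoch in range(epochs):
        if bg_feats is None or epoch % resample_every == 0:
            bg_seqs = background.sample(n_background_samples, rng)
            bg_feats = _feature_matrix(bg_seqs, ref_length)
        logq = bg_feats @ theta
        log_z = float(logsumexp(logq) - np.log(len(logq)))
        u = np.exp(logq - logsumexp(logq))
        model_mean = u @ bg_feats
        grad = data_mean - model_mean - 2.0 * l2 * theta
        theta += learning_rate * grad
        log.epochs.append(epoch)
        log.objective.append(float(data_mean @ theta - log_z - l2 * theta @ theta))

    n_aa = N_AA
    final_log_z = estimate_log_z(theta, bg_feats)
    model = SelectionModel(
        log_qL=theta[: ref_length * n_aa].reshape(ref_length, n_aa),
        log_qR=theta[ref_length * n_aa:].reshape(ref_length, n_aa),
        log_z=final_log_z,
        background=background,
        ref_length=ref_length,
    )
    return model, log


def save_selection_model(model: SelectionModel, path: str | Path) -> None:
    meta = {"format_version": 1, "ref_length": model.ref_length, "log_z": model.log_z}
    np.savez(path, log_qL=model.log_qL, log_qR=model.log_qR, meta=np.array(json.dumps(meta)))


def load_selection_model(path: str | Path, background: BackgroundModel | None = None) -> SelectionModel:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        return SelectionModel(
            log_qL=data["log_qL"],
            log_qR=data["log_qR"],
            log_z=meta["log_z"],
            background=background,
            ref_length=meta["ref_length"],
        )
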