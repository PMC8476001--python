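"""Clonal expansion calling, response/specificity scores and evaluation.

Fold change uses a 1/2 pseudo-count on both timepoints. Expansion combines a
fold-change threshold with a one-sided Fisher's exact test corrected by
Storey q-values. Response scores are log-ratios of a post-stimulation model
to a background model; specificity scores are differences of response scores
across antigens. Scores are computed in natural log and converted to log10
only for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .align import ProfileHMM, align_to_profile
from .encoding import encode_indices
from .io import ClonotypeTable, ClonotypeRecord
from . import rbm as rbm_mod

LOG10 = np.log(10.0)


def fold_change(n21: int, n0: int) -> float:
    """(n21 + 1/2) / (n0 + 1/2)."""
    if n21 < 0 or n0 < 0:
        raise ValueError("counts must be non-negative")
    return (n21 + 0.5) / (n0 + 0.5)


def storey_qvalues(pvalues: np.ndarray, lambdas: np.ndarray | None = None) -> np.ndarray:
    """Storey q-values with pi0 estimated on a lambda grid (0.05..0.95)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    m = p.size
    pi0_grid = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    pi0 = float(np.clip(pi0_grid.mean(), 1.0 / m, 1.0))
    order = np.argsort(p)
    q = np.empty(m)
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q[order] = np.minimum.accumulate(ranked[::-1])[::-1]
    return np.clip(q, 0.0, 1.0)


@dataclass
class ExpansionCall:
    cdr3: str
    n0: int
    n21: int
    fold_change: float
    p_value: float
    q_value: float
    expanded: bool


def call_expanded(
    day0: ClonotypeTable,
    day21: ClonotypeTable,
    fc_threshold: float = 2.0,
    q_threshold: float = 0.05,
) -> list[ExpansionCall]:
    """Expansion calls for every clone seen at either timepoint.

    Each clone gets a one-sided Fisher's exact test on the 2x2 table of
    (clone reads, all other reads) at day 0 vs day 21; q-values follow
    Storey's procedure across all tested clones. A clone is expanded when
    FC > fc_threshold and q < q_threshold. Clones absent at a timepoint
    count 0 there.
    """
    c0 = day0.counts_by_cdr3()
    c21 = day21.counts_by_cdr3()
    if not c0 and not c21:
        raise ValueError("both tables are empty")
    tot0 = sum(c0.values())
    tot21 = sum(c21.values())
    cdr3s = sorted(set(c0) | set(c21))
    pvals = np.empty(len(cdr3s))
    fcs = np.empty(len(cdr3s))
    for i, s in enumerate(cdr3s):
        n0, n21 = c0.get(s, 0), c21.get(s, 0)
        fcs[i] = fold_change(n21, n0)
        table = [[n21, tot21 - n21], [n0, tot0 - n0]]
        pvals[i] = stats.fisher_exact(table, alternative="greater")[1]
    qvals = storey_qvalues(pvals)
    return [
        ExpansionCall(
            cdr3=s,
            n0=c0.get(s, 0),
            n21=c21.get(s, 0),
            fold_change=float(fcs[i]),
            p_value=float(pvals[i]),
            q_value=float(qvals[i]),
            expanded=bool(fcs[i] > fc_threshold and qvals[i] < q_threshold),
        )
        for i, s in enumerate(cdr3s)
    ]


class RBMScorer:
    """Log-probability scorer wrapping an RBM and its alignment profile.

    Alignments are cached per sequence. When ``unnormalized`` is true the
    cached log Z is not required; scores are then defined up to a constant,
    which cancels in specificity scores and leaves AUROC unchanged.
    """

    def __init__(self, model: rbm_mod.RBMModel, hmm: ProfileHMM, unnormalized: bool = False):
        self.model = model
        self.hmm = hmm
        self.unnormalized = unnormalized
        self._cache: dict[str, float] = {}

    def log_prob(self, cdr3: str) -> float:
        val = self._cache.get(cdr3)
        if val is None:
            aligned = align_to_profile(cdr3, self.hmm).aligned
            raw = float(rbm_mod.log_score(self.model, encode_indices(aligned))[0])
            if not self.unnormalized:
                if self.model.log_z is None:
                    raise ValueError("model log_z unset; estimate it or use unnormalized=True")
                raw -= self.model.log_z
            self._cache[cdr3] = val = raw
        return val


def response_score(model21, background, seqs: list[str]) -> np.ndarray:
    """S_resp = log P21(sigma) - log P_bg(sigma) (natural log).

    Both arguments expose ``log_prob(cdr3)``; unsupported-sequence errors
    from the background propagate to the caller.
    """
    return np.array([model21.log_prob(s) - background.log_prob(s) for s in seqs])


def specificity_score(
    resp_scores_by_antigen: dict[str, np.ndarray], focal: str
) -> np.ndarray:
    """S_spec^p = S_resp^p - max_{p' != p} S_resp^{p'} (elementwise)."""
    if focal not in resp_scores_by_antigen:
        raise ValueError(f"unknown focal antigen {focal!r}")
    others = [np.asarray(v, dtype=float) for k, v in resp_scores_by_antigen.items() if k != focal]
    if not others:
        raise ValueError("specificity needs at least two antigens")
    lengths = {len(v) for v in resp_scores_by_antigen.values()}
    if len(lengths) != 1:
        raise ValueError("score vectors must align over the same clone list")
    return np.asarray(resp_scores_by_antigen[focal], dtype=float) - np.max(others, axis=0)


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Exact rank-statistic AUROC with midrank tie handling."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both label classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class EvaluationReport:
    auroc: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    correlation_curve: list[tuple[int, float, float]] = field(default_factory=list)
    pairwise_auroc: pd.DataFrame | None = None


def specificity_auroc(s_spec: np.ndarray, labels: np.ndarray) -> EvaluationReport:
    """ROC curve and AUROC of a specificity score against binary labels."""
    from sklearn.metrics import roc_curve

    a = auroc(s_spec, labels)
    fpr, tpr, _ = roc_curve(np.asarray(labels, dtype=int), np.asarray(s_spec, dtype=float))
    return EvaluationReport(auroc=a, roc_fpr=fpr, roc_tpr=tpr)


def pairwise_auroc_matrix(
    resp_scores_by_antigen: dict[str, np.ndarray],
    fold_changes_by_antigen: dict[str, np.ndarray],
) -> pd.DataFrame:
    """AUROC of S_resp^a - S_resp^b against FC^a > FC^b, for every antigen pair."""
    antigens = sorted(resp_scores_by_antigen)
    out = pd.DataFrame(np.nan, index=antigens, columns=antigens)
    for a in antigens:
        for b in antigens:
            if a == b:
                continue
            diff = np.asarray(resp_scores_by_antigen[a]) - np.asarray(resp_scores_by_antigen[b])
            labels = np.asarray(fold_changes_by_antigen[a]) > np.asarray(fold_changes_by_antigen[b])
            ties = np.asarray(fold_changes_by_antigen[a]) == np.asarray(fold_changes_by_antigen[b])
            keep = ~ties
            if labels[keep].any() and not labels[keep].all():
                out.loc[a, b] = auroc(diff[keep], labels[keep])
    return out


def correlation_vs_abundance_filter(
    scores: np.ndarray,
    counts: np.ndarray,
    targets: np.ndarray,
    retain_ns: list[int],
    cdr3s: list[str] | None = None,
) -> list[tuple[int, float, float]]:
    """Correlation of score with target over the N most-abundant clones.

    Count ties are broken by lexicographic CDR3 order (score-independent)
    for determinism. Returns (retained_n, pearson_r, spearman_r) per N in
    decreasing retained_n order; requests above the number of clones are
    truncated.
    """
    scores = np.asarray(scores, dtype=float)
    counts = np.asarray(counts, dtype=float)
    targets = np.asarray(targets, dtype=float)
    n = scores.size
    if cdr3s is None:
        cdr3s = [""] * n
    order = sorted(range(n), key=lambda i: (-counts[i], cdr3s[i]))
    curve = []
    for retain in sorted({min(r, n) for r in retain_ns}, reverse=True):
        idx = order[:retain]
        if retain < 2:
            curve.append((retain, float("nan"), float("nan")))
            continue
        pear = stats.pearsonr(scores[idx], targets[idx])[0]
        spear = stats.spearmanr(scores[idx], targets[idx])[0]
        curve.append((retain, float(pear), float(spear)))
    return curve


def split_reads_train_test(
    table: ClonotypeTable, fraction: float = 0.8, seed: int | np.random.Generator = 0
) -> tuple[ClonotypeTable, ClonotypeTable]:
    """Assign each read independently to the train split with prob ``fraction``."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    train_recs, test_recs = [], []
    for r in table.records:
        k = int(rng.binomial(r.count, fraction))
        if k > 0:
            train_recs.append(ClonotypeRecord(r.cdr3, k, r.v_gene, r.j_gene, r.productive))
        if r.count - k > 0:
            test_recs.append(ClonotypeRecord(r.cdr3, r.count - k, r.v_gene, r.j_gene, r.productive))
    meta = dict(sample_id=table.sample_id, timepoint=table.timepoint, antigen=table.antigen)
    return ClonotypeTable(train_recs, **meta), ClonotypeTable(test_recs, **meta)


def kfold_unique_clones(
    clones: list[str], k: int = 5, seed: int | np.random.Generator = 0
) -> list[list[str]]:
    """Disjoint covering folds of unique CDR3s (sizes differ by at most 1)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    unique = sorted(set(clones))
    if len(unique) < k:
        raise ValueError(f"need at least {k} unique clones, got {len(unique)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(len(unique))
    folds: list[list[str]] = [[] for _ in range(k)]
    for pos, idx in enumerate(perm):
        folds[pos % k].append(unique[idx])
    return folds


@dataclass
class CloneScore:
    cdr3: str
    n0: int
    n21: int
    fold_change: float
    s_resp: dict[str, float]
    s_spec: dict[str, float] = field(default_factory=dict)
    expanded: bool = False
    specific_label: str | None = None


def write_score_report(clone_scores: list[CloneScore], path) -> None:
    """ScoreReport TSV; response/specificity scores displayed in log base 10."""
    antigens = sorted({a for cs in clone_scores for a in cs.s_resp})
    rows = []
    for cs in clone_scores:
        row = {
            "cdr3": cs.cdr3,
            "n0": cs.n0,
            "n21": cs.n21,
            "fold_change": cs.fold_change,
            "expanded": cs.expanded,
            "specific_label": cs.specific_label or "",
        }
        for a in antigens:
            if a in cs.s_resp:
                row[f"s_resp_log10[{a}]"] = cs.s_resp[a] / LOG10
            if a in cs.s_spec:
                row[f"s_spec_log10[{a}]"] = cs.s_spec[a] / LOG10
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, encoding="utf-8")
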