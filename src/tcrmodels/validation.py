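"""End-to-end validation protocols on synthetic repertoires.

Two repertoire-level controls:

* the replicate null — split the reads of one repertoire into two technical
  replicates, train a model on each, and score specificity between them;
  the samples are statistically indistinguishable, so the expected AUROC is
  0.5;
* the planted-specificity pipeline — two antigens with disjoint responder
  motifs; a model trained per antigen should discriminate the two responder
  sets (high AUROC).

Specificity scores here are differences of unnormalized model log-scores:
the two partition functions enter as a constant shift, which cannot change
a rank statistic such as the AUROC.
"""

from __future__ import annotations

import numpy as np

from . import align as align_mod
from . import rbm as rbm_mod
from .encoding import encode_indices
from .io import ClonotypeTable
from .scoring import auroc, fold_change, split_reads_train_test
from .simulate import (
    AntigenSpec,
    SimulationConfig,
    generate_repertoire,
    make_replicates,
    simulate_counts,
    simulate_experiment,
)


def _build_hmm(clones: list[str]) -> align_mod.ProfileHMM:
    profiles = align_mod.build_length_profiles(clones)
    seed_aln = align_mod.progressive_profile_align(
        profiles, seqs=sorted(set(clones)), bridge=True
    )
    return align_mod.build_hmm_profile(seed_aln)


def _aligned_matrix(clones: list[str], hmm) -> dict[str, np.ndarray]:
    return {s: encode_indices(align_mod.align_to_profile(s, hmm).aligned) for s in set(clones)}


def _train_on_table(
    table: ClonotypeTable,
    aligned: dict[str, np.ndarray],
    n_hidden: int,
    epochs: int,
    seed: int,
    **kwargs,
) -> rbm_mod.RBMModel:
    seqs = [r.cdr3 for r in table.records if r.cdr3 in aligned]
    V = np.stack([aligned[s] for s in seqs])
    w = np.array([r.count for r in table.records if r.cdr3 in aligned], dtype=float)
    model, _ = rbm_mod.train_rbm(
        V, w, n_hidden=n_hidden, epochs=epochs, seed=seed, **kwargs
    )
    return model


def replicate_null_auroc(
    seed: int,
    n_clones: int = 2000,
    depth: int = 100_000,
    n_hidden: int = 10,
    epochs: int = 20,
    train_fraction: float = 0.8,
    **train_kwargs,
) -> float:
    """Specificity AUROC between two replicate splits of one repertoire.

    Simulates a repertoire with no antigen effect, splits its reads
    binomially into two technical replicates, trains one RBM per replicate
    on the count-weighted training split (80% of reads, as in the standard
    read-split validation), scores clones by the difference of model
    log-scores, and labels them by which replicate's held-out test reads
    show the higher fold change. The two samples are statistically
    indistinguishable, so the expected value is 0.5; evaluating labels on
    held-out reads keeps the models' fit to their own training-count noise
    out of the comparison.
    """
    rng = np.random.default_rng(seed)
    cfg = SimulationConfig(n_clones=n_clones, depth=depth, seed=int(rng.integers(2**31)))
    clones, freqs = generate_repertoire(cfg)
    table, _ = simulate_counts(clones, freqs, np.ones(n_clones), depth, rng)
    rep_a, rep_b = make_replicates(table, rng)
    train_a, test_a = split_reads_train_test(rep_a, train_fraction, rng)
    train_b, test_b = split_reads_train_test(rep_b, train_fraction, rng)

    hmm = _build_hmm(clones)
    aligned = _aligned_matrix(clones, hmm)
    model_a = _train_on_table(train_a, aligned, n_hidden, epochs,
                              int(rng.integers(2**31)), **train_kwargs)
    model_b = _train_on_table(train_b, aligned, n_hidden, epochs,
                              int(rng.integers(2**31)), **train_kwargs)

    ca, cb = test_a.counts_by_cdr3(), test_b.counts_by_cdr3()
    seqs = [s for s in sorted(set(ca) | set(cb)) if ca.get(s, 0) != cb.get(s, 0)]
    V = np.stack([aligned[s] for s in seqs])
    s_spec = rbm_mod.log_score(model_a, V) - rbm_mod.log_score(model_b, V)
    labels = np.array([ca.get(s, 0) > cb.get(s, 0) for s in seqs])
    return auroc(s_spec, labels)


def planted_specificity_auroc(
    seed: int,
    n_clones: int = 2000,
    depth: int = 100_000,
    n_hidden: int = 10,
    epochs: int = 60,
    responder_fraction: float = 0.1,
    fold_meanlog: float = float(np.log(30.0)),
    min_fc: float = 2.0,
    **train_kwargs,
) -> float:
    """Two-antigen specificity AUROC with disjoint planted motifs.

    Trains one RBM per antigen's day-21 sample; the specificity score for
    antigen A is the difference of the two models' log-scores (the shared
    day-0 background cancels). Clones responding to either antigen (empirical
    max fold change > ``min_fc``) are labeled by which antigen expanded them
    more; strong planting should give AUROC well above 0.5.
    """
    rng = np.random.default_rng(seed)
    cfg = SimulationConfig(
        n_clones=n_clones,
        depth=depth,
        seed=int(rng.integers(2**31)),
        antigens=[
            AntigenSpec("A", {3: "V", 4: "V", 5: "V"},
                        responder_fraction=responder_fraction,
                        fold_meanlog=fold_meanlog),
            AntigenSpec("B", {6: "W", 7: "S", 8: "A"},
                        responder_fraction=responder_fraction,
                        fold_meanlog=fold_meanlog),
        ],
    )
    exp = simulate_experiment(cfg)
    hmm = _build_hmm(exp.clones)
    aligned = _aligned_matrix(exp.clones, hmm)
    models = {
        name: _train_on_table(t21, aligned, n_hidden, epochs,
                              int(rng.integers(2**31)), **train_kwargs)
        for name, t21 in exp.day21_by_antigen.items()
    }
    c0 = exp.day0.counts_by_cdr3()
    counts = {name: t.counts_by_cdr3() for name, t in exp.day21_by_antigen.items()}
    rows = []
    for s in sorted(set(counts["A"]) | set(counts["B"])):
        fc = {name: fold_change(counts[name].get(s, 0), c0.get(s, 0)) for name in counts}
        if max(fc.values()) <= min_fc or fc["A"] == fc["B"]:
            continue
        rows.append((s, fc["A"] > fc["B"]))
    seqs = [s for s, _ in rows]
    labels = np.array([lab for _, lab in rows])
    V = np.stack([aligned[s] for s in seqs])
    s_spec = rbm_mod.log_score(models["A"], V) - rbm_mod.log_score(models["B"], V)
    return auroc(s_spec, labels)


def motif_recovery_overlap(
    seed: int,
    motif: dict[int, str] | None = None,
    n_clones: int = 1500,
    responder_fraction: float = 0.25,
    n_hidden: int = 10,
    epochs: int = 150,
    learning_rate: float = 0.02,
    top_k: int = 3,
) -> int:
    """Best overlap between any hidden unit's top weights and a planted motif.

    Trains an RBM on a day-21 count-weighted sample whose responders share
    ``motif`` and returns the maximum, over hidden units, of how many of the
    unit's ``top_k`` strongest residue weights (by |w|, gap state excluded)
    fall on the planted (position, residue) pairs.
    """
    from .alphabet import AA_INDEX

    if motif is None:
        motif = {3: "V", 4: "V", 5: "V"}
    rng = np.random.default_rng(seed)
    cfg = SimulationConfig(
        n_clones=n_clones,
        depth=100_000,
        seed=int(rng.integers(2**31)),
        antigens=[AntigenSpec("A", motif, responder_fraction=responder_fraction)],
    )
    exp = simulate_experiment(cfg)
    hmm = _build_hmm(exp.clones)
    aligned = _aligned_matrix(exp.clones, hmm)
    model = _train_on_table(
        exp.day21_by_antigen["A"], aligned, n_hidden, epochs,
        int(rng.integers(2**31)), learning_rate=learning_rate,
    )
    # planted (position, residue) pairs in alignment coordinates: motif
    # positions are left-anchored and sit left of the gap region, so the
    # alignment keeps them at their left positions
    wanted = {(pos, AA_INDEX[res]) for pos, res in motif.items()}
    best = 0
    n_aa = len(AA_INDEX)
    for mu in range(model.n_hidden):
        w = np.abs(model.W[:, mu, :n_aa])  # gap state excluded
        flat = np.argsort(-w.ravel())[:top_k]
        pairs = {(int(i // n_aa), int(i % n_aa)) for i in flat}
        best = max(best, len(pairs & wanted))
    return best
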