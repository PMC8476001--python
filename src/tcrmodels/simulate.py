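"""Synthetic repertoire experiments with planted motifs and planted expansion.

Generates a baseline repertoire of anchored CDR3s (start 'C', end 'F'/'V',
lengths in a configurable law over [5, 23]) with heavy-tailed baseline clone
frequencies, plants per-antigen responder motifs, expands responders by
clone-specific log-normal fold factors, and samples read counts at two
timepoints, plus binomial technical replicates for null controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .alphabet import AMINO_ACIDS, N_AA
from .io import ClonotypeRecord, ClonotypeTable

DEFAULT_LENGTH_RANGE = (5, 23)


def default_length_probs(l_min: int = 5, l_max: int = 23, mode: int = 14, width: float = 2.2) -> dict[int, float]:
    """A unimodal discrete length law peaked near the typical CDR3 length."""
    lengths = np.arange(l_min, l_max + 1)
    w = np.exp(-0.5 * ((lengths - mode) / width) ** 2)
    w /= w.sum()
    return dict(zip(lengths.tolist(), w.tolist()))


@dataclass
class AntigenSpec:
    name: str
    motif: dict[int, str]  # left-anchored position -> residue
    responder_fraction: float = 0.05
    fold_meanlog: float = float(np.log(10.0))
    fold_sdlog: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.responder_fraction < 1.0:
            raise ValueError("responder_fraction must be in [0, 1)")
        for pos, res in self.motif.items():
            if res not in AMINO_ACIDS:
                raise ValueError(f"motif residue {res!r} not canonical")
            if pos < 0:
                raise ValueError("motif positions must be non-negative")


@dataclass
class SimulationConfig:
    n_clones: int = 2000
    length_probs: dict[int, float] = field(default_factory=default_length_probs)
    residue_model: str = "positionwise"  # or "markov1"
    antigens: list[AntigenSpec] = field(default_factory=list)
    depth: int = 100_000
    power_law_exponent: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.length_probs.values())
        if not np.isclose(total, 1.0):
            raise ValueError("length probabilities must sum to 1")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if any(l < 3 for l in self.length_probs):
            raise ValueError("lengths below 3 cannot carry both anchors")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        antigens = [
            AntigenSpec(
                name=a["name"],
                motif={int(k): v for k, v in a["motif"].items()},
                responder_fraction=a.get("responder_fraction", 0.05),
                fold_meanlog=a.get("fold_meanlog", float(np.log(10.0))),
                fold_sdlog=a.get("fold_sdlog", 0.5),
            )
            for a in raw.get("antigens", [])
        ]
        kwargs = {k: v for k, v in raw.items() if k not in {"antigens", "length_probs"}}
        if "length_probs" in raw:
            kwargs["length_probs"] = {int(k): float(v) for k, v in raw["length_probs"].items()}
        return cls(antigens=antigens, **kwargs)


# interior residue usage, loosely mimicking CDR3 composition (G/S/A-rich)
_INTERIOR_WEIGHTS = {
    "A": 5, "C": 1, "D": 3, "E": 4, "F": 3, "G": 8, "H": 2, "I": 3, "K": 2,
    "L": 6, "M": 1, "N": 3, "P": 3, "Q": 4, "R": 5, "S": 9, "T": 6, "V": 4,
    "W": 1, "Y": 5,
}


def _interior_probs() -> np.ndarray:
    w = np.array([_INTERIOR_WEIGHTS[a] for a in AMINO_ACIDS], dtype=float)
    return w / w.sum()


def generate_repertoire(config: SimulationConfig, seed: int | None = None) -> tuple[list[str], np.ndarray]:
    """Unique anchored CDR3s plus power-law baseline frequencies.

    Frequencies follow the rank-frequency law f_k ~ k^(-1/(a-1)) implied by a
    clone-size distribution with power-law exponent ``a`` (default 2).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lengths = sorted(config.length_probs)
    lprobs = np.array([config.length_probs[l] for l in lengths])
    interior = _interior_probs()
    markov = config.residue_model == "markov1"
    if markov:
        # blend of interior composition with a same-residue bonus
        trans = 0.85 * np.tile(interior, (N_AA, 1)) + 0.15 * np.eye(N_AA)
        trans /= trans.sum(axis=1, keepdims=True)

    max_space = sum(
        2 * N_AA ** max(l - 2, 0)
        for l in lengths
        if config.length_probs[l] > 0
    )
    if config.n_clones > max_space:
        raise ValueError("n_clones too large for the sequence space")

    clones: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(clones) < config.n_clones:
        attempts += 1
        if attempts > 100 * config.n_clones:
            raise ValueError("cannot generate enough unique clones; enlarge the space")
        l = int(rng.choice(lengths, p=lprobs))
        mid = []
        prev = None
        for _ in range(l - 2):
            if markov and prev is not None:
                a = int(rng.choice(N_AA, p=trans[prev]))
            else:
                a = int(rng.choice(N_AA, p=interior))
            mid.append(AMINO_ACIDS[a])
            prev = a
        s = "C" + "".join(mid) + ("F" if rng.random() < 0.8 else "V")
        if s not in seen:
            seen.add(s)
            clones.append(s)

    ranks = rng.permutation(config.n_clones) + 1
    exponent = 1.0 / (config.power_law_exponent - 1.0)
    freqs = ranks.astype(float) ** (-exponent)
    freqs /= freqs.sum()
    return clones, freqs


def plant_responders(
    clones: list[str],
    antigens: list[AntigenSpec],
    seed: int | np.random.Generator = 0,
    disjoint: bool = True,
) -> tuple[list[str], dict[str, np.ndarray]]:
    """Rewrite a fraction of clones to carry each antigen's motif.

    Returns the modified clone list and a boolean responder mask per antigen.
    Responder sets are disjoint across antigens when ``disjoint`` (the
    default); overlapping motif positions across antigens then remain legal.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not disjoint and len(antigens) > 1:
        positions: set[int] = set()
        for a in antigens:
            overlap = positions & set(a.motif)
            if overlap:
                raise ValueError(
                    f"motif positions {sorted(overlap)} conflict across antigens; "
                    "enable disjoint responder sets"
                )
            positions |= set(a.motif)
    clones = list(clones)
    n = len(clones)
    taken = np.zeros(n, dtype=bool)
    labels: dict[str, np.ndarray] = {}
    for spec in antigens:
        n_resp = int(round(spec.responder_fraction * n))
        eligible = np.flatnonzero(
            (~taken if disjoint else np.ones(n, dtype=bool))
            & np.array([len(c) > max(spec.motif, default=0) + 1 for c in clones])
        )
        chosen = rng.choice(eligible, size=min(n_resp, eligible.size), replace=False)
        mask = np.zeros(n, dtype=bool)
        for i in chosen:
            s = list(clones[i])
            for pos, res in spec.motif.items():
                if 0 < pos < len(s) - 1:  # keep anchors intact
                    s[pos] = res
            clones[i] = "".join(s)
            mask[i] = True
            taken[i] = True
        labels[spec.name] = mask
    return clones, labels


def draw_fold_factors(
    n_clones: int,
    responder_mask: np.ndarray,
    spec: AntigenSpec,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Clone-specific fold factors: log-normal for responders, 1 otherwise."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    factors = np.ones(n_clones)
    k = int(responder_mask.sum())
    factors[responder_mask] = rng.lognormal(spec.fold_meanlog, spec.fold_sdlog, size=k)
    return factors


def simulate_counts(
    clones: list[str],
    baseline_freqs: np.ndarray,
    fold_factors: np.ndarray,
    depth: int,
    seed: int | np.random.Generator = 0,
    sample_id: str = "sim",
    antigen: str | None = None,
) -> tuple[ClonotypeTable, ClonotypeTable]:
    """Multinomial read counts at day 0 and day 21.

    Day-21 clone frequencies are the baseline frequencies scaled by the fold
    factors and renormalized. Total reads per table equal ``depth`` exactly.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    baseline_freqs = np.asarray(baseline_freqs, dtype=float)
    f21 = baseline_freqs * np.asarray(fold_factors, dtype=float)
    f21 /= f21.sum()
    n0 = rng.multinomial(depth, baseline_freqs)
    n21 = rng.multinomial(depth, f21)

    def table(counts: np.ndarray, timepoint: str) -> ClonotypeTable:
        recs = [
            ClonotypeRecord(cdr3=c, count=int(k))
            for c, k in zip(clones, counts)
            if k > 0
        ]
        return ClonotypeTable(recs, sample_id=sample_id, timepoint=timepoint, antigen=antigen)

    return table(n0, "day0"), table(n21, "day21")


def make_replicates(
    table: ClonotypeTable, seed: int | np.random.Generator = 0
) -> tuple[ClonotypeTable, ClonotypeTable]:
    """Split each clone's reads binomially (p = 0.5) into two technical
    replicates; the two halves are statistically indistinguishable."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rec_a, rec_b = [], []
    for r in table.records:
        k = int(rng.binomial(r.count, 0.5))
        if k > 0:
            rec_a.append(ClonotypeRecord(r.cdr3, k, r.v_gene, r.j_gene, r.productive))
        if r.count - k > 0:
            rec_b.append(ClonotypeRecord(r.cdr3, r.count - k, r.v_gene, r.j_gene, r.productive))
    meta = dict(sample_id=table.sample_id, timepoint=table.timepoint, antigen=table.antigen)
    return ClonotypeTable(rec_a, **meta), ClonotypeTable(rec_b, **meta)


@dataclass
class SimulatedExperiment:
    clones: list[str]
    baseline_freqs: np.ndarray
    day0: ClonotypeTable
    day21_by_antigen: dict[str, ClonotypeTable]
    responder_labels: dict[str, np.ndarray]
    fold_factors: dict[str, np.ndarray]


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """End-to-end simulation: repertoire, motifs, expansion, read sampling."""
    rng = np.random.default_rng(config.seed)
    clones, freqs = generate_repertoire(config, seed=rng)
    clones, labels = plant_responders(clones, config.antigens, seed=rng)
    day0 = None
    day21: dict[str, ClonotypeTable] = {}
    factors: dict[str, np.ndarray] = {}
    if not config.antigens:
        d0, _ = simulate_counts(clones, freqs, np.ones(len(clones)), config.depth, rng)
        day0 = d0
    for spec in config.antigens:
        f = draw_fold_factors(len(clones), labels[spec.name], spec, rng)
        d0, d21 = simulate_counts(
            clones, freqs, f, config.depth, rng, antigen=spec.name
        )
        if day0 is None:
            day0 = d0  # one shared pre-stimulation sample
        day21[spec.name] = d21
        factors[spec.name] = f
    return SimulatedExperiment(
        clones=clones,
        baseline_freqs=freqs,
        day0=day0,
        day21_by_antigen=day21,
        responder_labels=labels,
        fold_factors=factors,
    )
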