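"""Clonotype table I/O: reading TSV dialects, productive filtering,
CDR3 collapsing and count-weighted datasets.

A clonotype is defined by its CDR3 amino-acid sequence alone; V/J calls are
kept on collapsed records for provenance but never used by the models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .alphabet import AA_INDEX, N_AA, is_valid_cdr3

logger = logging.getLogger(__name__)

#: canonical column names per supported TSV dialect
DIALECTS: dict[str, dict[str, str | None]] = {
    "simple_tsv": {
        "cdr3": "cdr3",
        "count": "count",
        "v_gene": None,
        "j_gene": None,
        "productive": None,
    },
    "adaptive": {
        "cdr3": "aminoAcid",
        "count": "count (templates/reads)",
        "v_gene": "vGeneName",
        "j_gene": "jGeneName",
        "productive": "sequenceStatus",
    },
    "airr": {
        "cdr3": "junction_aa",
        "count": "duplicate_count",
        "v_gene": "v_call",
        "j_gene": "j_call",
        "productive": "productive",
    },
}

#: substrings marking a gene call as a pseudogene (configurable)
DEFAULT_PSEUDOGENE_MARKERS: tuple[str, ...] = ("OR",)


class FormatError(ValueError):
    """Raised when an input table does not conform to its declared dialect."""


@dataclass(frozen=True)
class ClonotypeRecord:
    cdr3: str
    count: int
    v_gene: str | None = None
    j_gene: str | None = None
    productive: bool = True

    def __post_init__(self) -> None:
        if len(self.cdr3) < 1:
            raise ValueError("empty CDR3")
        if self.count < 0:
            raise ValueError(f"negative count for {self.cdr3}")


@dataclass
class ClonotypeTable:
    """One (sample, timepoint) clonotype table."""

    records: list[ClonotypeRecord] = field(default_factory=list)
    sample_id: str = ""
    timepoint: str = ""
    antigen: str | None = None

    @property
    def total_reads(self) -> int:
        return sum(r.count for r in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def counts_by_cdr3(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            out[r.cdr3] = out.get(r.cdr3, 0) + r.count
        return out


@dataclass
class CountWeightedDataset:
    """Sequences with positive multiplicities; the model training unit.

    Weighting is mathematically equivalent to replicating each sequence
    ``weight`` times in every likelihood used downstream.
    """

    sequences: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.sequences) != len(self.weights):
            raise ValueError("sequences and weights length mismatch")
        if len(self.weights) and not np.all(self.weights > 0):
            raise ValueError("all weights must be positive")

    def __len__(self) -> int:
        return len(self.sequences)

    def replicate(self) -> list[str]:
        """Explicit replication (test oracle; weights must be integral)."""
        out: list[str] = []
        for s, w in zip(self.sequences, self.weights):
            out.extend([s] * int(round(w)))
        return out

    def site_frequencies(self) -> np.ndarray:
        """Weighted single-site residue frequencies (requires equal lengths)."""
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError("site frequencies need equal-length sequences")
        L = lengths.pop()
        freq = np.zeros((L, N_AA + 1))
        for s, w in zip(self.sequences, self.weights):
            for i, c in enumerate(s):
                freq[i, AA_INDEX.get(c, N_AA)] += w
        return freq / self.weights.sum()


class EmptyDatasetError(ValueError):
    """Raised when a filtering step leaves nothing to train on."""


def _parse_productive(value) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    return s in {"true", "t", "1", "in", "productive", "yes"}


def read_clonotype_table(
    path: str | Path,
    dialect: str = "simple_tsv",
    sample_id: str = "",
    timepoint: str = "",
    antigen: str | None = None,
) -> ClonotypeTable:
    """Read a clonotype TSV in one of the supported dialects."""
    if dialect not in DIALECTS:
        raise FormatError(f"unknown dialect {dialect!r}; choose from {sorted(DIALECTS)}")
    colmap = DIALECTS[dialect]
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for canonical in ("cdr3", "count"):
        col = colmap[canonical]
        if col not in df.columns:
            raise FormatError(
                f"dialect {dialect!r} requires column {col!r}, "
                f"found {list(df.columns)}"
            )
    records: list[ClonotypeRecord] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        row_d = dict(zip(df.columns, row))
        raw_count = row_d[colmap["count"]]
        try:
            count = int(raw_count)
        except (TypeError, ValueError):
            raise FormatError(
                f"non-integer count {raw_count!r} at row {idx} of {path}"
            ) from None
        v = row_d.get(colmap["v_gene"]) if colmap["v_gene"] else None
        j = row_d.get(colmap["j_gene"]) if colmap["j_gene"] else None
        prod = (
            _parse_productive(row_d[colmap["productive"]])
            if colmap["productive"] and colmap["productive"] in df.columns
            else True
        )
        records.append(
            ClonotypeRecord(
                cdr3=row_d[colmap["cdr3"]],
                count=count,
                v_gene=v or None,
                j_gene=j or None,
                productive=prod,
            )
        )
    return ClonotypeTable(records, sample_id=sample_id, timepoint=timepoint, antigen=antigen)


def read_fasta(path: str | Path, **table_kwargs) -> ClonotypeTable:
    """Read CDR3s from FASTA; every sequence gets count 1."""
    records = [
        ClonotypeRecord(cdr3=str(rec.seq), count=1)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    return ClonotypeTable(records, **table_kwargs)


def write_clonotype_table(table: ClonotypeTable, path: str | Path) -> None:
    """Write the canonical simple_tsv dialect (UTF-8, tab-separated)."""
    df = pd.DataFrame(
        {
            "cdr3": [r.cdr3 for r in table.records],
            "count": [r.count for r in table.records],
            "v_gene": [r.v_gene or "" for r in table.records],
            "j_gene": [r.j_gene or "" for r in table.records],
            "productive": [r.productive for r in table.records],
        }
    )
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")


def _is_pseudogene(gene: str | None, markers: Sequence[str]) -> bool:
    if not gene:
        return False
    return any(m in gene for m in markers)


def filter_productive(
    table: ClonotypeTable,
    pseudogene_markers: Sequence[str] = DEFAULT_PSEUDOGENE_MARKERS,
) -> ClonotypeTable:
    """Keep productive records with conserved anchors and non-pseudogene calls.

    A record passes when it is flagged productive, its CDR3 starts with the
    conserved Cysteine, ends with Phenylalanine or Valine, uses only canonical
    residues, and neither gene call matches a pseudogene marker.
    """
    kept: list[ClonotypeRecord] = []
    removed = {"nonproductive": 0, "anchors": 0, "alphabet": 0, "pseudogene": 0}
    for r in table.records:
        if not r.productive:
            removed["nonproductive"] += 1
            continue
        if not is_valid_cdr3(r.cdr3):
            removed["alphabet"] += 1
            continue
        if not (r.cdr3[0] == "C" and r.cdr3[-1] in "FV"):
            removed["anchors"] += 1
            continue
        if _is_pseudogene(r.v_gene, pseudogene_markers) or _is_pseudogene(
            r.j_gene, pseudogene_markers
        ):
            removed["pseudogene"] += 1
            continue
        kept.append(r)
    if any(removed.values()):
        logger.info("filter_productive removed %s", removed)
    return ClonotypeTable(
        kept, sample_id=table.sample_id, timepoint=table.timepoint, antigen=table.antigen
    )


def collapse_by_cdr3(table: ClonotypeTable) -> tuple[ClonotypeTable, float]:
    """Collapse records sharing a CDR3; counts are summed.

    The collapsed record carries the V/J of the highest-count contributing
    row (ties broken to the lexicographically smallest V gene) for provenance
    only. Also returns the fraction of reads whose CDR3 had more than one
    distinct V-J combination (a diagnostic the models never see).
    """
    groups: dict[str, list[ClonotypeRecord]] = {}
    order: list[str] = []
    for r in table.records:
        if r.cdr3 not in groups:
            groups[r.cdr3] = []
            order.append(r.cdr3)
        groups[r.cdr3].append(r)

    collapsed: list[ClonotypeRecord] = []
    multi_vj_reads = 0
    total = 0
    for cdr3 in order:
        rows = groups[cdr3]
        count = sum(r.count for r in rows)
        total += count
        vj = {(r.v_gene, r.j_gene) for r in rows}
        if len(vj) > 1:
            multi_vj_reads += count
        best = min(rows, key=lambda r: (-r.count, r.v_gene or "", r.j_gene or ""))
        collapsed.append(
            ClonotypeRecord(
                cdr3=cdr3,
                count=count,
                v_gene=best.v_gene,
                j_gene=best.j_gene,
                productive=all(r.productive for r in rows),
            )
        )
    fraction = multi_vj_reads / total if total else 0.0
    out = ClonotypeTable(
        collapsed,
        sample_id=table.sample_id,
        timepoint=table.timepoint,
        antigen=table.antigen,
    )
    return out, fraction


def to_count_weighted(table: ClonotypeTable, min_count: int = 1) -> CountWeightedDataset:
    """Turn a collapsed table into a count-weighted training dataset."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    seqs = [r.cdr3 for r in table.records if r.count >= min_count]
    weights = [r.count for r in table.records if r.count >= min_count]
    if not seqs:
        raise EmptyDatasetError(
            f"no clonotype with count >= {min_count}; models cannot train on an empty dataset"
        )
    return CountWeightedDataset(seqs, np.asarray(weights, dtype=float))
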