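"""From amplicon reads to a guide count matrix, with sequencing QC.

Reads from the sgRNA amplicon carry a constant vector anchor immediately
ahead of the 20-nt variable protospacer; quantification extracts the bases
following the first exact anchor occurrence and tallies exact matches
against the library. Exact matching is deliberate — it is a pure function
of the read multiset and round-trips the synthetic generator — and a
1-mismatch rescue is available but off by default.

QC per sample covers mapping rates, zero-count guide fraction, mean reads
per guide, and the Gini index of the count distribution (a rise in Gini
between inlet and an outlet flags positive selection: a few knockouts
dominating the sorted subset).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .stats import gini_index
from .synthetic import ANCHOR

__all__ = [
    "CoverageParams",
    "extract_protospacer",
    "count_guides",
    "sample_qc",
    "coverage",
    "read_manifest",
    "write_counts",
    "read_counts",
]


@dataclass(frozen=True)
class CoverageParams:
    """Inputs of the cells-per-guide coverage arithmetic."""

    n_cells: float
    infection_efficiency: float
    n_guides: int

    def __post_init__(self) -> None:
        if self.n_guides < 1:
            raise ValueError("n_guides must be >= 1")
        if not (0.0 <= self.infection_efficiency <= 1.0):
            raise ValueError("infection efficiency must lie in [0, 1]")


def coverage(params: CoverageParams) -> float:
    """Expected cells per guide: n_cells * efficiency / n_guides.

    E.g. transducing 60e6 cells at 40% efficiency over a 76,441-guide
    library maintains ~315 cells per knockout.
    """
    return params.n_cells * params.infection_efficiency / params.n_guides


def extract_protospacer(
    read: str,
    anchor: str = ANCHOR,
    length: int = 20,
    policy: str = "anchored",
) -> str | None:
    """Extract the protospacer from one read; None signals a miss.

    ``anchored``: the ``length`` bases after the first exact anchor
    occurrence; ``positional``: the first ``length`` bases of the read.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if policy == "anchored":
        pos = read.find(anchor)
        if pos < 0:
            return None
        start = pos + len(anchor)
    elif policy == "positional":
        start = 0
    else:
        raise ValueError(f"unknown policy {policy!r}")
    end = start + length
    if end > len(read):
        return None
    return read[start:end]


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _match_map(library: pd.DataFrame, mismatch_rescue: bool) -> dict[str, str]:
    protos = library["protospacer"].tolist()
    guides = library["guide_id"].tolist()
    if len(set(protos)) != len(protos):
        dupes = library["protospacer"][library["protospacer"].duplicated()].unique()
        raise ValueError(f"duplicate protospacers in library (ambiguous): {dupes[:5]}")
    table = dict(zip(protos, guides))
    if mismatch_rescue:
        # map every 1-mismatch neighbour that is unambiguous
        neighbours: dict[str, str | None] = {}
        for p, g in zip(protos, guides):
            for i in range(len(p)):
                for b in "ACGT":
                    if b == p[i]:
                        continue
                    q = p[:i] + b + p[i + 1:]
                    neighbours[q] = None if q in neighbours else g
        for q, g in neighbours.items():
            if g is not None and q not in table:
                table[q] = g
    return table


def count_guides(
    fastq_by_sample: Mapping[str, Sequence[str | Path] | str | Path],
    library: pd.DataFrame,
    anchor: str = ANCHOR,
    policy: str = "anchored",
    mismatch_rescue: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count exact protospacer matches per guide and sample.

    ``fastq_by_sample`` maps sample name to one or more FASTQ paths
    (gzipped ok). Returns (counts, stats): ``counts`` is guide x sample
    with rows for every library guide; ``stats`` reports per sample the
    total, mapped, unextracted (no anchor / too short) and unmapped
    (extracted but not in the library) read tallies and the mapping rate.
    Order-invariant and deterministic.
    """
    length = int(library["protospacer"].str.len().iloc[0])
    table = _match_map(library, mismatch_rescue)
    guide_index = pd.Index(library["guide_id"], name="guide_id")
    counts = pd.DataFrame(0, index=guide_index, columns=list(fastq_by_sample), dtype=np.int64)
    stat_rows = []
    for sample, paths in fastq_by_sample.items():
        if isinstance(paths, (str, Path)):
            paths = [paths]
        tally: dict[str, int] = {}
        total = unextracted = unmapped = 0
        for path in paths:
            with _open_text(Path(path)) as fh:
                for _title, seq, _qual in FastqGeneralIterator(fh):
                    total += 1
                    proto = extract_protospacer(seq, anchor, length, policy)
                    if proto is None:
                        unextracted += 1
                        continue
                    guide = table.get(proto)
                    if guide is None:
                        unmapped += 1
                        continue
                    tally[guide] = tally.get(guide, 0) + 1
        if tally:
            col = pd.Series(tally, dtype=np.int64)
            counts.loc[col.index, sample] = col
        mapped = total - unextracted - unmapped
        stat_rows.append(
            {
                "sample": sample,
                "total_reads": total,
                "mapped_reads": mapped,
                "unextracted_reads": unextracted,
                "unmapped_reads": unmapped,
                "mapping_rate": mapped / total if total else 0.0,
            }
        )
    return counts, pd.DataFrame(stat_rows).set_index("sample")


def sample_qc(
    counts: pd.DataFrame, mapping_stats: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-sample QC: totals, zero-guide fraction, mean reads/guide, Gini.

    All-zero samples get a NaN Gini and a flag instead of an error. When
    ``mapping_stats`` (from :func:`count_guides`) is given, its totals and
    mapping rate are merged in.
    """
    if counts.shape[0] < 1:
        raise ValueError("count matrix has no guides")
    rows = []
    for sample in counts.columns:
        col = counts[sample].to_numpy()
        total = int(col.sum())
        row = {
            "sample": sample,
            "total_counts": total,
            "zero_guide_fraction": float((col == 0).mean()),
            "mean_reads_per_guide": total / col.size,
            "gini": gini_index(col) if total > 0 else float("nan"),
            "flag": "" if total > 0 else "all-zero",
        }
        rows.append(row)
    qc = pd.DataFrame(rows).set_index("sample")
    if mapping_stats is not None:
        qc = qc.join(mapping_stats, how="left")
    return qc


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a sample manifest CSV: sample,role,replicate[,path].

    ``role`` is ``inlet`` or ``outlet1``..``outlet5``; replicate an integer.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in ("sample", "role", "replicate") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing manifest columns {missing}")
    valid = {"inlet"} | {f"outlet{i}" for i in range(1, 6)}
    bad = ~df["role"].isin(valid)
    if bad.any():
        raise ValueError(f"{path}: unknown roles {df['role'][bad].unique()[:5]}")
    if df["sample"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample names")
    return df


def write_counts(counts: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    counts.to_csv(path, sep="\t")
    return path


def read_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative counts")
    return df.astype(np.int64)
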