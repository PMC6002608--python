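"""Spacer extraction and exact-match counting of sgRNA reads.

The amplified sgRNA cassette has a fixed structure: a vector-derived
upstream flank, the 20-nt spacer, then the constant sgRNA scaffold. A read
is assigned to a guide when the spacer between the flanks matches a library
spacer exactly; there is no mismatch tolerance by default, mirroring the
exact-match counting used for the original screen.
"""

from __future__ import annotations

import dataclasses
import gzip
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .library_index import LibraryIndex

__all__ = [
    "POPULATIONS",
    "CassetteSpec",
    "CountMatrix",
    "CountingReport",
    "CountingError",
    "extract_spacer",
    "count_reads",
]

POPULATIONS = ("PhagoLate", "PhagoNeg", "Initial")

_ACGT = frozenset("ACGT")


class CountingError(ValueError):
    """Raised on malformed inputs to the counting stage."""


@dataclasses.dataclass(frozen=True)
class CassetteSpec:
    """Read structure of the amplified sgRNA cassette.

    Defaults mirror the lentiCRISPRv2 context: the tail of the U6 promoter
    (ending in the BsmBI cloning overhang ``CACCG``) upstream and the start
    of the constant sgRNA scaffold downstream. The true amplicon flanks of
    any given screen depend on its PCR design, so both are configurable.
    """

    upstream: str = "TTGTGGAAAGGACGAAACACCG"
    downstream: str = "GTTTTAGAGCTAGAAATAGCAAG"
    spacer_length: int = 20

    def __post_init__(self) -> None:
        for name, flank in (("upstream", self.upstream), ("downstream", self.downstream)):
            if not flank or set(flank) - _ACGT:
                raise CountingError(f"{name} flank must be non-empty and ACGT-only")
        if self.spacer_length < 1:
            raise CountingError("spacer_length must be positive")

    def read_for(self, spacer: str) -> str:
        """The error-free read emitted for a guide with this spacer."""
        return self.upstream + spacer + self.downstream

    def to_json(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_json(cls, obj: Mapping) -> "CassetteSpec":
        return cls(**obj)


@dataclasses.dataclass
class CountMatrix:
    """Integer sgRNA x sample count matrix with per-sample metadata.

    ``counts`` is a DataFrame indexed by sgrna_id with one column per
    sample; ``sample_meta`` is indexed by sample_id with columns
    ``replicate`` (int) and ``population`` (PhagoLate / PhagoNeg / Initial).
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            raise CountingError("duplicate sgrna_ids in count matrix")
        if not self.counts.columns.is_unique:
            raise CountingError("duplicate sample_ids in count matrix")
        if list(self.counts.columns) != list(self.sample_meta.index):
            raise CountingError("sample_meta index must match count matrix columns")
        bad = set(self.sample_meta["population"]) - set(POPULATIONS)
        if bad:
            raise CountingError(f"unknown population(s): {sorted(bad)}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise CountingError("counts must be integers")
            self.counts = self.counts.round().astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise CountingError("counts must be non-negative")

    @property
    def sgrna_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in(self, population: str) -> list[str]:
        return list(self.sample_meta.index[self.sample_meta["population"] == population])

    def to_tsv(self, counts_path: str | Path, samples_path: str | Path | None = None) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="sgrna_id")
        if samples_path is not None:
            self.sample_meta.to_csv(samples_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(
        cls, counts_path: str | Path, samples_path: str | Path | None = None
    ) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col="sgrna_id")
        if samples_path is not None:
            meta = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
        else:
            meta = sample_meta_from_ids(counts.columns)
        return cls(counts=counts.astype(np.int64), sample_meta=meta)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, CountMatrix)
            and self.counts.equals(other.counts)
            and self.sample_meta.equals(other.sample_meta)
        )


def sample_meta_from_ids(sample_ids: Sequence[str]) -> pd.DataFrame:
    """Derive (replicate, population) metadata from 'rep{i}_{population}' ids."""
    rows = []
    for sid in sample_ids:
        try:
            rep, pop = sid.split("_", 1)
            if not rep.startswith("rep") or pop not in POPULATIONS:
                raise ValueError
            rows.append((sid, int(rep[3:]), pop))
        except ValueError:
            raise CountingError(
                f"unknown sample id {sid!r}: expected 'rep<i>_<population>' with "
                f"population in {POPULATIONS}, or provide an explicit sample sheet"
            ) from None
    return pd.DataFrame(rows, columns=["sample_id", "replicate", "population"]).set_index(
        "sample_id"
    )


@dataclasses.dataclass
class CountingReport:
    """Read-assignment bookkeeping for one counting run."""

    total_reads: int
    assigned_reads: int
    unassigned_reads: int
    per_sample: pd.DataFrame  # columns: total, assigned, unassigned, assignment_rate

    def __post_init__(self) -> None:
        assert self.assigned_reads + self.unassigned_reads == self.total_reads

    def to_json(self) -> dict:
        return {
            "total_reads": int(self.total_reads),
            "assigned_reads": int(self.assigned_reads),
            "unassigned_reads": int(self.unassigned_reads),
            "per_sample": {
                sid: {k: (float(v) if k == "assignment_rate" else int(v)) for k, v in row.items()}
                for sid, row in self.per_sample.to_dict("index").items()
            },
        }


def extract_spacer(read_sequence: str, cassette: CassetteSpec) -> str | None:
    """Extract the spacer from a read, or None if the cassette is not found.

    Scans for exact occurrences of the upstream flank anywhere in the read
    and returns the following ``spacer_length`` bases, provided they are
    ACGT-only and followed by at least the first 4 bases of the downstream
    flank (fewer only if the flank itself is shorter). Failure is a None
    return, never an error.
    """
    up, down, length = cassette.upstream, cassette.downstream, cassette.spacer_length
    need = min(4, len(down))
    tail_ref = down[:need]
    start = read_sequence.find(up)
    while start != -1:
        s = start + len(up)
        spacer = read_sequence[s : s + length]
        tail = read_sequence[s + length : s + length + need]
        if len(spacer) == length and tail == tail_ref and not spacer.strip("ACGT"):
            return spacer
        start = read_sequence.find(up, start + 1)
    return None


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, encoding="ascii")


def count_reads(
    sample_fastqs: Mapping[str, str | Path | Sequence[str | Path]],
    index: LibraryIndex,
    cassette: CassetteSpec | None = None,
    sample_meta: pd.DataFrame | None = None,
    reverse_complement: bool = False,
) -> tuple[CountMatrix, CountingReport]:
    """Count exact spacer matches per sample from FASTQ files.

    Parameters
    ----------
    sample_fastqs
        Mapping sample_id -> FASTQ path (or list of paths). Sample ids must
        follow 'rep{i}_{population}' unless ``sample_meta`` is given.
    reverse_complement
        Also try the reverse complement of each read (off by default: the
        cassette orientation is fixed by the amplification design).

    Each read contributes at most one count to exactly one guide; guides
    with no reads appear with count zero. Malformed FASTQ records raise
    :class:`CountingError` naming the record number.
    """
    if cassette is None:
        cassette = CassetteSpec()
    if sample_meta is None:
        sample_meta = sample_meta_from_ids(list(sample_fastqs))
    else:
        missing = set(sample_fastqs) - set(sample_meta.index)
        if missing:
            raise CountingError(f"unknown sample id(s) {sorted(missing)}: not in sample sheet")
        sample_meta = sample_meta.loc[list(sample_fastqs)]

    sgrna_ids = index.sgrna_ids
    row_of = {sid: i for i, sid in enumerate(sgrna_ids)}
    spacer_row = {sp: row_of[sid] for sp, sid in index.lookup.items()}
    counts = np.zeros((len(sgrna_ids), len(sample_fastqs)), dtype=np.int64)
    per_sample_rows = []

    comp = str.maketrans("ACGTN", "TGCAN")
    for j, (sample_id, paths) in enumerate(sample_fastqs.items()):
        if isinstance(paths, (str, Path)):
            paths = [paths]
        total = assigned = 0
        for path in paths:
            with _open_maybe_gzip(path) as fh:
                it = FastqGeneralIterator(fh)
                while True:
                    try:
                        rec = next(it, None)
                    except ValueError as exc:
                        raise CountingError(
                            f"{path}: malformed FASTQ record {total + 1}: {exc}"
                        ) from exc
                    if rec is None:
                        break
                    total += 1
                    seq = rec[1]
                    spacer = extract_spacer(seq, cassette)
                    if spacer is None and reverse_complement:
                        spacer = extract_spacer(seq.translate(comp)[::-1], cassette)
                    if spacer is not None:
                        row = spacer_row.get(spacer)
                        if row is not None:
                            counts[row, j] += 1
                            assigned += 1
        per_sample_rows.append(
            (sample_id, total, assigned, total - assigned, assigned / total if total else 0.0)
        )

    per_sample = pd.DataFrame(
        per_sample_rows,
        columns=["sample_id", "total", "assigned", "unassigned", "assignment_rate"],
    ).set_index("sample_id")
    report = CountingReport(
        total_reads=int(per_sample["total"].sum()),
        assigned_reads=int(per_sample["assigned"].sum()),
        unassigned_reads=int(per_sample["unassigned"].sum()),
        per_sample=per_sample,
    )
    matrix = CountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(sgrna_ids, name="sgrna_id"),
                            columns=list(sample_fastqs)),
        sample_meta=sample_meta,
    )
    return matrix, report
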