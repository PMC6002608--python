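"""sgRNA library index: the catalog of guides a pooled screen is counted against.

The index models a lentiviral knockout library focused on the SLC
(solute carrier) gene family: every SLC gene is covered by a fixed number
of guides, flanked by two control sets — guides against genes known to be
essential in haploid leukemia lines (positive depletion controls) and
non-targeting guides that match nothing in the genome (negative controls).
Reads are assigned to guides by exact spacer match, so the index enforces
spacer uniqueness at construction.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence
from pathlib import Path

import numpy as np

__all__ = [
    "SgRNARecord",
    "LibraryIndex",
    "LibraryIndexError",
    "CATEGORIES",
    "NONTARGETING_GENE",
    "build_index",
    "default_library",
    "read_index_tsv",
    "write_index_tsv",
    "write_spacer_fasta",
]

CATEGORIES = ("SLC", "EssentialControl", "NonTargeting")
#: sentinel gene symbol carried by non-targeting guides
NONTARGETING_GENE = "NonTargeting"

_ACGT = frozenset("ACGT")


class LibraryIndexError(ValueError):
    """Raised when an index or one of its records violates an invariant."""


@dataclasses.dataclass(frozen=True)
class SgRNARecord:
    """One guide: unique id, target gene symbol, spacer sequence, category."""

    sgrna_id: str
    gene: str
    spacer: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise LibraryIndexError(
                f"unknown category {self.category!r} for {self.sgrna_id!r}; "
                f"expected one of {CATEGORIES}"
            )
        if not self.spacer or set(self.spacer) - _ACGT:
            raise LibraryIndexError(
                f"spacer of {self.sgrna_id!r} must be non-empty and ACGT-only, "
                f"got {self.spacer!r}"
            )
        if (self.category == "NonTargeting") != (self.gene == NONTARGETING_GENE):
            raise LibraryIndexError(
                f"{self.sgrna_id!r}: NonTargeting category and the sentinel gene "
                f"{NONTARGETING_GENE!r} must be used together "
                f"(got gene={self.gene!r}, category={self.category!r})"
            )


class LibraryIndex:
    """Immutable collection of :class:`SgRNARecord` with an exact spacer lookup.

    Invariants enforced at construction: unique sgRNA ids, unique spacers,
    one common spacer length.
    """

    def __init__(self, records: Sequence[SgRNARecord]):
        records = list(records)
        if not records:
            raise LibraryIndexError("empty library: an index needs at least one record")
        lengths = {len(r.spacer) for r in records}
        if len(lengths) != 1:
            raise LibraryIndexError(f"mixed spacer lengths in index: {sorted(lengths)}")
        self.spacer_length: int = lengths.pop()

        seen_ids: dict[str, str] = {}
        lookup: dict[str, str] = {}
        dup_ids, dup_spacers = [], []
        for r in records:
            if r.sgrna_id in seen_ids:
                dup_ids.append(r.sgrna_id)
            seen_ids[r.sgrna_id] = r.spacer
            if r.spacer in lookup:
                dup_spacers.append((r.spacer, lookup[r.spacer], r.sgrna_id))
            lookup[r.spacer] = r.sgrna_id
        if dup_ids:
            raise LibraryIndexError(f"duplicate sgrna_id(s): {sorted(set(dup_ids))}")
        if dup_spacers:
            offenders = "; ".join(
                f"{sp!r} shared by {a!r} and {b!r}" for sp, a, b in dup_spacers[:5]
            )
            raise LibraryIndexError(f"duplicate spacer(s): {offenders}")

        self.records: list[SgRNARecord] = records
        self.lookup: dict[str, str] = lookup
        self._by_id = {r.sgrna_id: r for r in records}

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, LibraryIndex) and self.records == other.records

    def __iter__(self):
        return iter(self.records)

    def record(self, sgrna_id: str) -> SgRNARecord:
        return self._by_id[sgrna_id]

    @property
    def sgrna_ids(self) -> list[str]:
        return [r.sgrna_id for r in self.records]

    def genes(self, category: str | None = None) -> list[str]:
        """Distinct gene symbols, optionally restricted to one category.

        Non-targeting guides carry a sentinel, not a gene, and are excluded
        unless the NonTargeting category is requested explicitly.
        """
        out: list[str] = []
        seen = set()
        for r in self.records:
            if category is None and r.category == "NonTargeting":
                continue
            if category is not None and r.category != category:
                continue
            if r.gene not in seen:
                seen.add(r.gene)
                out.append(r.gene)
        return out

    def sgrnas_for_gene(self, gene: str) -> list[SgRNARecord]:
        return [r for r in self.records if r.gene == gene]

    def composition(self) -> dict[str, dict[str, int]]:
        """Per-category summary: number of guides and of distinct genes."""
        out: dict[str, dict[str, int]] = {}
        for cat in CATEGORIES:
            recs = [r for r in self.records if r.category == cat]
            genes = {r.gene for r in recs} if cat != "NonTargeting" else set()
            out[cat] = {"n_sgrnas": len(recs), "n_genes": len(genes)}
        return out


def build_index(records: Iterable[SgRNARecord]) -> LibraryIndex:
    """Validate records and build a :class:`LibraryIndex`."""
    return LibraryIndex(list(records))


def _random_unique_spacers(n: int, length: int, rng: np.random.Generator) -> list[str]:
    bases = np.array(list("ACGT"))
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        batch = rng.integers(0, 4, size=(n - len(out), length))
        for row in batch:
            sp = "".join(bases[row])
            if sp not in seen:
                seen.add(sp)
                out.append(sp)
    return out


def default_library(seed: int = 0, spacer_length: int = 20) -> LibraryIndex:
    """The default screen design: 391 SLC genes x 6 guides, 20 essential
    genes x 6 guides, and 120 non-targeting guides (2,586 records total).

    Gene symbols and spacer sequences are synthetic (the real library's
    spacers are not public); composition is fixed, spacers are drawn
    uniquely at random and are deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    n_slc_genes, n_ess_genes, n_per_gene, n_nt = 391, 20, 6, 120
    total = n_slc_genes * n_per_gene + n_ess_genes * n_per_gene + n_nt
    spacers = iter(_random_unique_spacers(total, spacer_length, rng))

    records: list[SgRNARecord] = []
    for g in range(1, n_slc_genes + 1):
        gene = f"SLC{g:03d}"
        for k in range(1, n_per_gene + 1):
            records.append(SgRNARecord(f"{gene}_sg{k}", gene, next(spacers), "SLC"))
    for g in range(1, n_ess_genes + 1):
        gene = f"ESS{g:02d}"
        for k in range(1, n_per_gene + 1):
            records.append(
                SgRNARecord(f"{gene}_sg{k}", gene, next(spacers), "EssentialControl")
            )
    for k in range(1, n_nt + 1):
        records.append(
            SgRNARecord(f"NT_{k:03d}", NONTARGETING_GENE, next(spacers), "NonTargeting")
        )
    return LibraryIndex(records)


_TSV_COLUMNS = ("sgrna_id", "gene", "spacer", "category")


def write_index_tsv(index: LibraryIndex, path: str | Path) -> None:
    """Write the index as a four-column TSV (header + one row per guide)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for r in index.records:
            fh.write(f"{r.sgrna_id}\t{r.gene}\t{r.spacer}\t{r.category}\n")


def read_index_tsv(path: str | Path) -> LibraryIndex:
    """Read an index TSV written by :func:`write_index_tsv`.

    Lines starting with '#' are comments. Parse errors report the
    offending 1-based line number.
    """
    records: list[SgRNARecord] = []
    header: list[str] | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                missing = [c for c in _TSV_COLUMNS if c not in header]
                if missing:
                    raise LibraryIndexError(
                        f"{path}: missing column(s) {missing} in header (line {lineno})"
                    )
                continue
            row = dict(zip(header, fields))
            try:
                records.append(
                    SgRNARecord(
                        row["sgrna_id"], row["gene"], row["spacer"], row["category"]
                    )
                )
            except (KeyError, LibraryIndexError) as exc:
                raise LibraryIndexError(f"{path}: line {lineno}: {exc}") from exc
    if not records:
        raise LibraryIndexError(f"{path}: empty library (no data rows)")
    return LibraryIndex(records)


def write_spacer_fasta(index: LibraryIndex, path: str | Path) -> None:
    """Export spacers as FASTA, one record per guide, id line = sgrna_id."""
    with open(path, "w", encoding="utf-8") as fh:
        for r in index.records:
            fh.write(f">{r.sgrna_id}\n{r.spacer}\n")
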