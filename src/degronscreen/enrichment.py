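"""Exclusive-hit GO-slim ranking and whole-term recovery percentages.

Hits (strains with a severe growth defect) are partitioned by the media in
which they appear; the hits exclusive to one medium rank that medium's GO
slim terms by how many exclusive hits each term annotates.  For reporting,
the *whole* hit list of the medium is then used to compute what percentage
of a term's genome-wide annotations was recovered as hits — regardless of
whether those genes are present in the library.  No enrichment p-value is
attached by default: the procedure reports counts and recovery percentages.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "AnnotationTable",
    "TermRecovery",
    "TermRank",
    "rank_exclusive_terms",
    "term_recovery",
    "shared_hits_recovery",
]


class AnnotationTable:
    """Gene -> GO-slim term annotations with derived maps.

    Duplicated (gene, term) pairs are dropped on construction.  The loader
    accepts both a minimal two-column TSV (gene_id, term_id) and a GAF-like
    dialect (tab-separated, ``!`` comment lines, gene identifier in column 2,
    GO term in column 5; evidence codes ignored), since GO slim files
    circulate in both shapes.
    """

    def __init__(self, pairs: pd.DataFrame) -> None:
        df = pairs.iloc[:, :2].copy()
        df.columns = ["gene_id", "term_id"]
        df = df.astype(str).drop_duplicates(ignore_index=True)
        self.pairs = df
        self.term_to_genes: dict[str, set] = {
            t: set(g) for t, g in df.groupby("term_id")["gene_id"]
        }
        self.gene_to_terms: dict[str, set] = {
            g: set(t) for g, t in df.groupby("gene_id")["term_id"]
        }

    def term_size(self, term_id: str) -> int:
        if term_id not in self.term_to_genes:
            raise KeyError(f"unknown GO slim term: {term_id}")
        return len(self.term_to_genes[term_id])

    @property
    def terms(self) -> list[str]:
        return sorted(self.term_to_genes)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AnnotationTable":
        path = Path(path)
        rows: list[tuple[str, str]] = []
        gaf = False
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("!"):
                    gaf = gaf or line.startswith("!")
                    continue
                fields = line.split("\t")
                if len(fields) >= 5 and (gaf or fields[4].startswith("GO:")):
                    rows.append((fields[1], fields[4]))  # GAF: DB object id, GO id
                elif len(fields) >= 2:
                    rows.append((fields[0], fields[1]))
                else:
                    raise ValueError(f"{path}: unparseable annotation line: {line!r}")
        if rows and rows[0] == ("gene_id", "term_id"):
            rows = rows[1:]
        if not rows:
            raise ValueError(f"{path}: no annotations found")
        return cls(pd.DataFrame(rows, columns=["gene_id", "term_id"]))

    def to_tsv(self, path: str | Path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False)


@dataclass
class TermRecovery:
    """Recovery of one GO-slim term by a hit list.

    ``recovery_pct`` is 100 * all_hits_count / term_size rounded to one
    decimal, computed over the term's genome-wide annotation regardless of
    library presence; library/responsive counts are carried as metadata.
    """

    term_id: str
    all_hits_count: int
    term_size: int
    recovery_pct: float
    exclusive_count: int | None = None
    exclusive_total: int | None = None
    in_library: int | None = None
    responsive_in_library: int | None = None


@dataclass(frozen=True)
class TermRank:
    term_id: str
    exclusive_count: int
    exclusive_total: int
    term_size: int


def rank_exclusive_terms(
    exclusive_hits: set | Sequence[str],
    annotation: AnnotationTable,
    k: int = 3,
) -> list[TermRank]:
    """Top-k GO-slim terms among the hits exclusive to one medium.

    Terms are ordered by how many exclusive hits they annotate (descending);
    ties break toward the term with the larger exclusive recovery
    (exclusive_count / term_size) and then lexically by term id.  The
    reported pair (exclusive_count, exclusive_total) matches the "[22/73]"
    convention: 22 of the 73 exclusive hits annotated to the term.
    """
    hits = set(exclusive_hits)
    if not hits:
        return []
    counts = {
        term: len(genes & hits)
        for term, genes in annotation.term_to_genes.items()
        if genes & hits
    }
    ordered = sorted(
        counts,
        key=lambda t: (-counts[t], -counts[t] / annotation.term_size(t), t),
    )
    return [
        TermRank(t, counts[t], len(hits), annotation.term_size(t)) for t in ordered[:k]
    ]


def term_recovery(
    term_id: str,
    all_hits: set | Sequence[str],
    annotation: AnnotationTable,
    library_genes: set | None = None,
    responsive_genes: set | None = None,
    exclusive_hits: set | None = None,
) -> TermRecovery:
    """Whole-term recovery percentage for one term against a full hit list."""
    genes = annotation.term_to_genes.get(term_id)
    if genes is None:
        raise KeyError(f"unknown GO slim term: {term_id}")
    hits = set(all_hits)
    count = len(genes & hits)
    size = len(genes)
    return TermRecovery(
        term_id=term_id,
        all_hits_count=count,
        term_size=size,
        recovery_pct=round(100.0 * count / size, 1),
        exclusive_count=len(genes & exclusive_hits) if exclusive_hits is not None else None,
        exclusive_total=len(exclusive_hits) if exclusive_hits is not None else None,
        in_library=len(genes & library_genes) if library_genes is not None else None,
        responsive_in_library=(
            len(genes & responsive_genes) if responsive_genes is not None else None
        ),
    )


def shared_hits_recovery(
    intersection_hits: set | Sequence[str], annotation: AnnotationTable
) -> list[TermRecovery]:
    """Recovery records for every term touched by the all-media hit set."""
    hits = set(intersection_hits)
    out = [
        term_recovery(term, hits, annotation)
        for term, genes in sorted(annotation.term_to_genes.items())
        if genes & hits
    ]
    return out
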