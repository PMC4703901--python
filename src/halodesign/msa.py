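"""Alignment parsing and per-position variability profiles.

Candidate positions for surface acidification are the query positions that
are most variable across homologs: variability tolerated by evolution is
taken as variability the fold will tolerate. Two metrics are offered —
Shannon entropy in bits (default) and the count of distinct residues — both
mapped from alignment columns onto the query's own numbering.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .tables import AMINO_ACIDS

GAP_CHARS = "-."
VALID_CHARS = set(AMINO_ACIDS) | set(GAP_CHARS) | {"X"}


class AlignmentError(ValueError):
    pass


@dataclass
class Alignment:
    """Gapped homolog alignment; all rows equal length, gaps normalised to '-'."""

    records: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("alignment has no records")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged alignment: row lengths {sorted(lengths)}")
        for ident, seq in self.records:
            bad = set(seq.upper()) - VALID_CHARS
            if bad:
                raise AlignmentError(
                    f"unknown residue codes {sorted(bad)} in record {ident!r}"
                )

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def n_rows(self) -> int:
        return len(self.records)

    def row(self, identifier: str) -> str:
        for ident, seq in self.records:
            if ident == identifier:
                return seq
        raise KeyError(f"record {identifier!r} not in alignment")

    def column(self, index: int) -> str:
        return "".join(seq[index] for _, seq in self.records)


@dataclass
class MsaProfile:
    """Variability scores on query numbering.

    ``table`` columns: position (query numbering), residue (query letter),
    entropy_bits, distinct_count, coverage (non-gap row fraction of the
    column), low_coverage flag. Low-coverage positions carry NaN scores.
    """

    query_id: str
    metric: str
    min_coverage: float
    table: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def ranked_positions(self) -> list[int]:
        """Positions ordered most-variable-first; low-coverage ones excluded."""
        scored = self.table[~self.table["low_coverage"]]
        scored = scored.sort_values(
            [self.metric, "position"], ascending=[False, True]
        )
        return scored["position"].tolist()


def _normalize(seq: str) -> str:
    return seq.upper().replace(".", "-")


def parse_alignment(path, format: str = "fasta") -> Alignment:
    """Read a FASTA or Clustal alignment via Bio.AlignIO."""
    from Bio import AlignIO

    if format not in ("fasta", "clustal"):
        raise ValueError(f"unsupported alignment format {format!r}")
    try:
        aln = AlignIO.read(str(path), format)
    except ValueError as exc:
        raise AlignmentError(f"cannot parse {path} as {format}: {exc}") from exc
    return Alignment(records=[(rec.id, _normalize(str(rec.seq))) for rec in aln])


def write_alignment(alignment: Alignment, path, format: str = "fasta") -> None:
    from Bio import AlignIO
    from Bio.Align import MultipleSeqAlignment
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    msa = MultipleSeqAlignment(
        [SeqRecord(Seq(seq), id=ident, description="") for ident, seq in alignment.records]
    )
    AlignIO.write(msa, str(path), format)


def map_columns_to_query(
    alignment: Alignment, query_id: str, start_number: int = 1
) -> dict[int, int]:
    """Map 0-based column index -> query residue number for non-gap query columns."""
    query = alignment.row(query_id)
    mapping: dict[int, int] = {}
    number = start_number
    for col, char in enumerate(query):
        if char not in GAP_CHARS:
            mapping[col] = number
            number += 1
    return mapping


def column_entropy(column: str, gap_policy: str = "exclude") -> float:
    """Shannon entropy of a column in bits; NaN for an empty effective column.

    gap_policy 'exclude' drops gaps before counting; 'as_21st' keeps '-' as
    its own symbol (entropy may then reach log2(21)).
    """
    if gap_policy not in ("exclude", "as_21st"):
        raise ValueError(f"unknown gap_policy {gap_policy!r}")
    symbols = _normalize(column)
    if gap_policy == "exclude":
        symbols = symbols.replace("-", "")
    if not symbols:
        return math.nan
    counts = Counter(symbols)
    n = len(symbols)
    return -sum((c / n) * math.log2(c / n) for c in counts.values()) + 0.0


def column_distinct_count(column: str, gap_policy: str = "exclude") -> float:
    symbols = _normalize(column)
    if gap_policy == "exclude":
        symbols = symbols.replace("-", "")
    if not symbols:
        return math.nan
    return float(len(set(symbols)))


def variability_profile(
    alignment: Alignment,
    query_id: str,
    metric: str = "entropy",
    min_coverage: float = 0.5,
    gap_policy: str = "exclude",
    start_number: int = 1,
) -> MsaProfile:
    """Per-query-position variability, with low-coverage columns flagged unscored."""
    if metric not in ("entropy", "distinct_count"):
        raise ValueError(f"unknown metric {metric!r}")
    mapping = map_columns_to_query(alignment, query_id, start_number)
    query = alignment.row(query_id)
    rows = []
    for col, position in mapping.items():
        column = alignment.column(col)
        coverage = 1.0 - sum(c in GAP_CHARS for c in column) / len(column)
        low = coverage < min_coverage
        rows.append(
            {
                "position": position,
                "residue": query[col],
                "entropy": math.nan if low else column_entropy(column, gap_policy),
                "distinct_count": math.nan
                if low
                else column_distinct_count(column, gap_policy),
                "coverage": coverage,
                "low_coverage": low,
            }
        )
    metric_col = "entropy" if metric == "entropy" else "distinct_count"
    table = pd.DataFrame(
        rows,
        columns=["position", "residue", "entropy", "distinct_count", "coverage", "low_coverage"],
    )
    return MsaProfile(
        query_id=query_id, metric=metric_col, min_coverage=min_coverage, table=table
    )
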