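"""microRNA target-set construction by multi-database agreement.

A predicted (microRNA, gene) pair is retained only when at least
``min_db`` of the supplied prediction tables contain it, the microRNA
belongs to the prognostic signature and the gene belongs to the
differentially expressed mRNA pool.  Identifiers are normalised by
lowercasing and stripping a species prefix ("hsa-") before comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .data import ValidationError

__all__ = ["TargetTable", "normalize_mirna_id", "intersect_targets"]


def normalize_mirna_id(mirna_id: str) -> str:
    s = str(mirna_id).strip().lower()
    if s.startswith("hsa-"):
        s = s[4:]
    return s


@dataclass(frozen=True)
class TargetTable:
    """One prediction database: a named set of (mirna, gene) pairs.

    Pairs are normalised and de-duplicated at construction.
    """

    db_name: str
    pairs: frozenset

    @classmethod
    def from_pairs(cls, db_name: str, pairs) -> "TargetTable":
        norm = frozenset((normalize_mirna_id(m), str(g)) for m, g in pairs)
        return cls(db_name=db_name, pairs=norm)

    @classmethod
    def from_dataframe(cls, db_name: str, df: pd.DataFrame,
                       mirna_col: str = "mirna", gene_col: str = "gene") -> "TargetTable":
        return cls.from_pairs(db_name, zip(df[mirna_col], df[gene_col]))

    @classmethod
    def read_tsv(cls, path, db_name: str | None = None) -> "TargetTable":
        df = pd.read_csv(path, sep="\t")
        name = db_name if db_name is not None else str(path)
        return cls.from_dataframe(name, df)

    def to_dataframe(self) -> pd.DataFrame:
        rows = sorted(self.pairs)
        return pd.DataFrame(rows, columns=["mirna", "gene"])

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self.pairs)


def intersect_targets(signature, de_mrnas, tables, min_db: int = 2) -> pd.DataFrame:
    """Targets supported by >= ``min_db`` databases, restricted to the
    signature microRNAs and the DE mRNA pool.

    Returns a DataFrame with columns ``mirna, gene, n_db`` sorted by
    (mirna, gene); invariant to table order and duplicate rows.
    """
    tables = list(tables)
    if len(tables) < min_db:
        raise ValidationError(
            f"need at least min_db={min_db} tables, got {len(tables)}"
        )
    sig = {normalize_mirna_id(m) for m in signature}
    genes = {str(g) for g in de_mrnas}
    if not sig or not genes:
        raise ValidationError("signature and DE mRNA pool must be non-empty")
    counts: dict[tuple[str, str], int] = {}
    for table in tables:
        for pair in table.pairs:
            counts[pair] = counts.get(pair, 0) + 1
    rows = [
        (m, g, c)
        for (m, g), c in counts.items()
        if c >= min_db and m in sig and g in genes
    ]
    rows.sort()
    return pd.DataFrame(rows, columns=["mirna", "gene", "n_db"])
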