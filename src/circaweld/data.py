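"""Core data containers and plain-text I/O.

Expression data travel as an :class:`ExpressionMatrix` — a genes × samples
table with per-sample time/platform metadata and an explicit scale tag — and
gene sets as a :class:`GeneSetCollection` with GMT semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Recognised scale tags and whether they are log2 scales.
SCALES = {
    "counts": False,
    "log2-cpm": True,
    "log2-intensity": True,
    "log2-intensity-matched": True,
    "linear": False,
    "linear-normalized": False,
}


@dataclass
class ExpressionMatrix:
    """Gene × sample abundance table with sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, one column per sample id.
    sample_time_h
        Hours since synchronization per sample, aligned with the columns.
    platform
        Platform label per sample (e.g. ``"microarray"``, ``"rnaseq"``).
    scale
        One of ``counts``, ``log2-cpm``, ``log2-intensity``,
        ``log2-intensity-matched``, ``linear``, ``linear-normalized``.
    """

    values: pd.DataFrame
    sample_time_h: pd.Series
    platform: pd.Series
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale tag {self.scale!r}")
        self.values = pd.DataFrame(self.values)
        if not self.values.index.is_unique:
            raise ValueError("gene ids must be unique")
        if not self.values.columns.is_unique:
            raise ValueError("sample ids must be unique")
        if self.values.isna().any().any():
            raise ValueError("missing values are not allowed")
        self.sample_time_h = pd.Series(self.sample_time_h, dtype=float).reindex(
            self.values.columns
        )
        if self.sample_time_h.isna().any():
            raise ValueError("every sample needs a time annotation")
        if (self.sample_time_h < 0).any():
            raise ValueError("sample times must be >= 0 h")
        if np.isscalar(self.platform) or isinstance(self.platform, str):
            self.platform = pd.Series(self.platform, index=self.values.columns)
        else:
            self.platform = pd.Series(self.platform).reindex(self.values.columns)
        if self.platform.isna().any():
            raise ValueError("every sample needs a platform label")
        if self.scale == "counts":
            arr = self.values.to_numpy()
            if (arr < 0).any():
                raise ValueError("counts must be non-negative")
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integer-valued")

    # -- convenience -------------------------------------------------------

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def is_log_scale(self) -> bool:
        return SCALES[self.scale]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        """Restrict to the given genes, preserving their order in the index."""
        keep = self.values.index.intersection(pd.Index(genes))
        keep = self.values.index[self.values.index.isin(keep)]
        return ExpressionMatrix(
            self.values.loc[keep], self.sample_time_h, self.platform, self.scale
        )

    def to_linear(self) -> "ExpressionMatrix":
        """Undo a log2 scale (2**x); linear scales pass through unchanged."""
        if not self.is_log_scale:
            return self
        return ExpressionMatrix(
            np.exp2(self.values), self.sample_time_h, self.platform, "linear"
        )

    def with_values(self, values: pd.DataFrame, scale: str) -> "ExpressionMatrix":
        return ExpressionMatrix(values, self.sample_time_h, self.platform, scale)

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, matrix_path, samples_path=None) -> None:
        """Write the matrix (first column gene_id) and optionally a sample sheet."""
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(matrix_path, sep="\t")
        if samples_path is not None:
            self.sample_sheet().to_csv(samples_path, sep="\t", index=False)

    def sample_sheet(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "time_h": self.sample_time_h.to_numpy(),
                "platform": self.platform.to_numpy(),
            }
        )

    @classmethod
    def from_tsv(cls, matrix_path, samples_path, scale: str) -> "ExpressionMatrix":
        """Read a gene × sample TSV plus a sample sheet (sample_id, time_h, platform)."""
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        sheet = pd.read_csv(samples_path, sep="\t").set_index("sample_id")
        sheet = sheet.reindex(values.columns)
        return cls(values, sheet["time_h"], sheet["platform"], scale)


@dataclass
class GeneSetCollection:
    """Named gene sets with GMT semantics.

    ``sets`` maps a unique set name to an ordered list of unique member gene
    ids; ``descriptions`` is the GMT description column; ``truth_labels`` is
    only populated for synthetic collections (``"clustered"`` / ``"null"``).
    """

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    truth_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(set(members)) != len(members):
                raise ValueError(f"duplicate members in set {name!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for name, members in self.sets.items():
                desc = self.descriptions.get(name, "")
                fh.write("\t".join([name, desc, *members]) + "\n")

    @classmethod
    def from_gmt(cls, path) -> "GeneSetCollection":
        sets: dict[str, list[str]] = {}
        descriptions: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            name, desc, *members = fields
            if name in sets:
                raise ValueError(f"duplicate set name {name!r}")
            # drop accidental duplicates while keeping order
            sets[name] = list(dict.fromkeys(m for m in members if m))
            descriptions[name] = desc
        return cls(sets, descriptions)


def read_gene_list(path) -> list[str]:
    """Read a one-gene-id-per-line text file (blank lines ignored)."""
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
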