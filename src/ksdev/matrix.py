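"""Genes-by-samples expression container with sample metadata.

Expression values are stored on the log2 scale throughout the package;
operations that must happen on linear intensities (mixing, subtraction)
exponentiate internally and re-log on the way out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd


@dataclass
class ExpressionMatrix:
    """A genes × samples abundance table plus per-sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, one column per sample, log2 scale.
    samples
        DataFrame indexed by sample id with metadata columns such as
        ``stage``, ``region``, ``genotype``, ``replicate``. Must cover
        exactly the columns of ``values``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.samples is None:
            self.samples = pd.DataFrame(index=self.values.columns)
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples metadata missing for: {sorted(missing)}")
        self.samples = self.samples.loc[list(self.values.columns)]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def select_samples(self, **criteria: object) -> list[str]:
        """Sample ids whose metadata match every keyword criterion."""
        mask = pd.Series(True, index=self.samples.index)
        for key, want in criteria.items():
            if key not in self.samples.columns:
                raise KeyError(f"no metadata column {key!r}")
            mask &= self.samples[key] == want
        return list(self.samples.index[mask])

    def subset(self, sample_ids: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[sample_ids].copy(), self.samples.loc[sample_ids].copy())

    def write_tsv(self, values_path: str | Path, samples_path: str | Path | None = None) -> None:
        self.values.to_csv(values_path, sep="\t", index_label="gene_id")
        if samples_path is not None:
            self.samples.to_csv(samples_path, sep="\t", index_label="sample_id")

    @classmethod
    def read_tsv(
        cls, values_path: str | Path, samples_path: str | Path | None = None
    ) -> "ExpressionMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col="gene_id")
        samples = None
        if samples_path is not None:
            samples = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
        return cls(values, samples)
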