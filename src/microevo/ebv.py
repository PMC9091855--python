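"""Posterior breeding-value container shared by the genomic and pedigree models."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class EbvPosterior:
    """Individuals x posterior-samples matrix of (G)EBVs, with cohort metadata.

    ``values[i, s]`` is individual i's breeding value (kg) in posterior
    sample s.  ``provenance`` records whether the samples came from the
    genomic (SNP-effect) or pedigree (animal-model) chain.
    """

    ids: np.ndarray
    birth_year: np.ndarray
    values: np.ndarray
    provenance: str = "genomic"
    is_training: np.ndarray | None = None

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=str)
        self.birth_year = np.asarray(self.birth_year, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape[0] != len(self.ids) or len(self.birth_year) != len(self.ids):
            raise ValueError("EbvPosterior dimensions inconsistent")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite breeding values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def posterior_mean(self) -> pd.Series:
        return pd.Series(self.values.mean(axis=1), index=self.ids, name="ebv_mean")

    def select(self, mask) -> "EbvPosterior":
        mask = np.asarray(mask)
        return EbvPosterior(
            ids=self.ids[mask],
            birth_year=self.birth_year[mask],
            values=self.values[mask],
            provenance=self.provenance,
            is_training=None if self.is_training is None else self.is_training[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[f"s{k}" for k in range(self.n_samples)])
        df.insert(0, "birth_year", self.birth_year)
        df.insert(0, "id", self.ids)
        if self.is_training is not None:
            df.insert(2, "is_training", self.is_training.astype(int))
        return df

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#provenance={self.provenance}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "EbvPosterior":
        provenance = "genomic"
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#provenance="):
                provenance = first.strip().split("=", 1)[1]
                df = pd.read_csv(fh, sep="\t")
            else:
                fh.seek(0)
                df = pd.read_csv(fh, sep="\t")
        sample_cols = [c for c in df.columns if c.startswith("s") and c[1:].isdigit()]
        is_training = None
        if "is_training" in df.columns:
            is_training = df["is_training"].to_numpy().astype(bool)
        return cls(
            ids=df["id"].to_numpy(dtype=str),
            birth_year=df["birth_year"].to_numpy(),
            values=df[sample_cols].to_numpy(),
            provenance=provenance,
            is_training=is_training,
        )
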