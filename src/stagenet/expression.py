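"""Expression matrices with sample stage labels.

The pipeline's substrate is a feature-by-sample real matrix (miRNA or gene
expression on a log-like scale) together with a map from sample id to
pathological stage (I--IV).  Missing values are permitted before
preprocessing and forbidden afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

STAGES = ("I", "II", "III", "IV")

__all__ = ["ExpressionMatrix", "STAGES", "read_expression_tsv", "read_stage_tsv"]


@dataclass
class ExpressionMatrix:
    """A feature x sample expression matrix plus a sample->stage map.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by feature id, columns by sample id.  ``NaN`` marks a
        missing measurement.
    stage : dict
        Maps sample id to a stage label.  Samples absent from the map are
        treated as stage-unknown and dropped by :func:`stagenet.preprocess.
        filter_samples`.
    """

    values: pd.DataFrame
    stage: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("feature ids must be unique")
        if not self.values.columns.is_unique:
            raise ValueError("sample ids must be unique")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        samples = [s for s in samples if s in self.values.columns]
        return ExpressionMatrix(self.values.loc[:, samples].copy(), dict(self.stage))

    def samples_of_stage(self, stage: str) -> list[str]:
        return [s for s in self.sample_ids if self.stage.get(s) == stage]

    def to_tsv(self, path: str | Path) -> None:
        """Write the matrix as TSV: first column ``feature``, then samples."""
        out = self.values.copy()
        out.index.name = "feature"
        out.to_csv(path, sep="\t", float_format="%.10g", na_rep="NA")

    def stage_to_tsv(self, path: str | Path) -> None:
        rows = [(s, self.stage.get(s, "unknown")) for s in self.sample_ids]
        pd.DataFrame(rows, columns=["sample", "stage"]).to_csv(path, sep="\t", index=False)


def read_expression_tsv(path: str | Path, stage: Mapping[str, str] | None = None) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df.astype(np.float64), dict(stage or {}))


def read_stage_tsv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["sample"], df["stage"]))
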