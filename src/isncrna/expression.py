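"""Expression containers: microarray matrices and RNA-Seq proxies."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

STATE_RAW = "raw"
STATE_QUANTILE = "log2_quantile"
STATE_GRSN = "log2_grsn"


@dataclass
class ExpressionMatrix:
    """Probes x samples intensity table with a normalization state.

    ``data`` is indexed by probe id with one column per array; on the
    ``raw`` state values are linear-scale intensities (> 0), after
    normalization they are log2.
    """

    data: pd.DataFrame
    normalization_state: str = STATE_RAW

    def __post_init__(self) -> None:
        if self.normalization_state not in (STATE_RAW, STATE_QUANTILE, STATE_GRSN):
            raise ValueError(f"unknown state {self.normalization_state!r}")
        if self.normalization_state == STATE_RAW and (self.data.to_numpy() <= 0).any():
            raise ValueError("raw intensities must be strictly positive")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.data.to_csv(path, sep="\t", index_label="probe_id")

    @classmethod
    def from_tsv(cls, path: Union[str, Path], normalization_state: str = STATE_RAW):
        df = pd.read_csv(path, sep="\t", index_col="probe_id")
        return cls(df, normalization_state)


@dataclass
class SeqExpression:
    """Per-sample RNA-Seq expression proxy per probe (e.g. transfrag mean
    coverage); non-negative, used for the direction-consistency check."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.data.to_numpy() < 0).any():
            raise ValueError("sequencing expression proxies must be non-negative")

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.data.to_csv(path, sep="\t", index_label="probe_id")

    @classmethod
    def from_tsv(cls, path: Union[str, Path]):
        return cls(pd.read_csv(path, sep="\t", index_col="probe_id"))
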