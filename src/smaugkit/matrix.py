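"""Gene x sample intensity matrices with sample metadata.

Sample identity is carried in the column names:

* polysome samples: ``{genotype}_pool{1-4}_rep{k}`` (genotype ``wt``/``mut``)
* RIP samples: ``{role}_rep{k}`` with role ``smaug_ip`` / ``mock_ip`` / ``input``

Spike-in control rows are ordinary rows whose ids are listed in
``spikein_ids`` (serialized as a boolean ``spikein`` column in TSV).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

_POLYSOME_RE = re.compile(r"^(?P<genotype>\w+?)_pool(?P<pool>[1-4])_rep(?P<rep>\d+)$")
_RIP_RE = re.compile(r"^(?P<role>smaug_ip|mock_ip|input)_rep(?P<rep>\d+)$")


@dataclass
class ExpressionMatrix:
    values: pd.DataFrame                  # genes x samples, nonnegative
    spikein_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("missing values in expression matrix")
        missing = set(self.spikein_ids) - set(self.values.index)
        if missing:
            raise ValueError(f"spikein ids not in matrix: {sorted(missing)}")

    # -- metadata -------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def assay_ids(self) -> list[str]:
        """Gene ids excluding spike-in control rows."""
        spike = set(self.spikein_ids)
        return [g for g in self.values.index if g not in spike]

    def sample_meta(self) -> pd.DataFrame:
        rows = []
        for col in self.values.columns:
            m = _POLYSOME_RE.match(col)
            if m:
                rows.append({"sample": col, "genotype": m["genotype"],
                             "pool": int(m["pool"]), "replicate": int(m["rep"]),
                             "role": None})
                continue
            m = _RIP_RE.match(col)
            if m:
                rows.append({"sample": col, "genotype": None, "pool": None,
                             "replicate": int(m["rep"]), "role": m["role"]})
                continue
            rows.append({"sample": col, "genotype": None, "pool": None,
                         "replicate": None, "role": None})
        return pd.DataFrame(rows).set_index("sample")

    def columns_where(self, **conditions) -> list[str]:
        meta = self.sample_meta()
        mask = pd.Series(True, index=meta.index)
        for key, val in conditions.items():
            mask &= meta[key] == val
        return list(meta.index[mask])

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        return ExpressionMatrix(values, list(self.spikein_ids))

    # -- I/O ------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "spikein", [g in set(self.spikein_ids) for g in out.index])
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", float_format="%.6f")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        spike = list(df.index[df["spikein"].astype(bool)])
        return cls(df.drop(columns=["spikein"]), spike)
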