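"""Feature-by-sample count matrices with a sample -> condition map."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The four hormone-treatment conditions, in display order.
CONDITIONS = ("nt", "gluc", "cort", "dual")


@dataclass
class CountMatrix:
    """Nonnegative integer counts (features x samples) plus metadata.

    ``conditions`` maps every sample (column) to one condition label.
    ``lengths`` (bp per feature) is only needed for RPKM.
    """

    counts: pd.DataFrame
    conditions: dict[str, str] = field(default_factory=dict)
    lengths: pd.Series | None = None
    #: genome-wide per-sample totals (e.g. track tag totals) for
    #: total-count normalization; defaults to column sums when absent
    sample_totals: pd.Series | None = None

    def __post_init__(self):
        vals = self.counts.to_numpy()
        if np.any(vals < 0):
            raise ValueError("counts must be nonnegative")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integral")
        missing = [s for s in self.counts.columns if s not in self.conditions]
        if missing:
            raise ValueError(f"samples without a condition: {missing}")
        if self.lengths is not None:
            self.lengths = self.lengths.reindex(self.counts.index)
            if self.lengths.isna().any() or (self.lengths <= 0).any():
                raise ValueError("feature lengths must be positive and complete")

    @property
    def features(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.conditions[s] == condition]

    def condition_means(self, values: pd.DataFrame | None = None) -> pd.DataFrame:
        """Mean across replicates per condition (of counts, or of ``values``)."""
        values = self.counts if values is None else values
        cols = {}
        for cond in dict.fromkeys(self.conditions.values()):
            cols[cond] = values[self.samples_for(cond)].mean(axis=1)
        return pd.DataFrame(cols)

    def to_tsv(self, counts_path, conditions_path=None) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="feature")
        if conditions_path is not None:
            pd.Series(self.conditions, name="condition").rename_axis(
                "sample"
            ).to_csv(conditions_path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path, conditions) -> "CountMatrix":
        """Load counts TSV; ``conditions`` is a mapping or a 2-column TSV path."""
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        if not isinstance(conditions, dict):
            conditions = (
                pd.read_csv(conditions, sep="\t", index_col=0)["condition"]
                .to_dict()
            )
        return cls(counts, conditions)
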