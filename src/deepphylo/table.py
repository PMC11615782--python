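"""The OTU-by-sample abundance table.

Convention used throughout the package: OTUs are rows, samples are columns
(an m x n matrix). This matches how amplicon feature tables are usually
written to disk, and is the single most common source of user error, so
every consumer validates shape against the label vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AbundanceTable"]


@dataclass
class AbundanceTable:
    """Nonnegative m x n matrix: rows = OTUs, columns = samples."""

    values: np.ndarray
    otu_labels: list[str]
    sample_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("abundance table must be 2-D")
        m, n = self.values.shape
        if m != len(self.otu_labels):
            raise ValueError(f"{len(self.otu_labels)} OTU labels for {m} rows")
        if n != len(self.sample_labels):
            raise ValueError(f"{len(self.sample_labels)} sample labels for {n} columns")
        if len(set(self.otu_labels)) != m:
            raise ValueError("duplicate OTU labels")
        if len(set(self.sample_labels)) != n:
            raise ValueError("duplicate sample labels")
        if np.any(np.isnan(self.values)):
            bad = np.argwhere(np.isnan(self.values))[0]
            raise ValueError(
                f"NaN at OTU {self.otu_labels[bad[0]]!r}, sample {self.sample_labels[bad[1]]!r}"
            )
        if np.any(self.values < 0):
            bad = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative entry at OTU {self.otu_labels[bad[0]]!r}, "
                f"sample {self.sample_labels[bad[1]]!r}"
            )
        empty = np.where(self.values.sum(axis=0) == 0)[0]
        if empty.size:
            names = [self.sample_labels[j] for j in empty[:5]]
            raise ValueError(f"samples with all-zero counts: {names}")

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    def relative_abundances(self) -> np.ndarray:
        """Columns normalized to sum to one."""
        return self.values / self.values.sum(axis=0, keepdims=True)

    def reorder_otus(self, labels: list[str]) -> "AbundanceTable":
        """Return a copy with rows reordered to ``labels`` (must be a permutation)."""
        if set(labels) != set(self.otu_labels):
            missing = sorted(set(labels) - set(self.otu_labels))[:5]
            extra = sorted(set(self.otu_labels) - set(labels))[:5]
            raise ValueError(f"OTU label mismatch; missing={missing}, extra={extra}")
        index = {lab: i for i, lab in enumerate(self.otu_labels)}
        rows = [index[lab] for lab in labels]
        return AbundanceTable(self.values[rows], list(labels), list(self.sample_labels))
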