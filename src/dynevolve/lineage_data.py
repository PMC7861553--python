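"""Barcode count tables: container, TSV round-trip, and frequency transforms.

A lineage-tracking dataset is an integer matrix of amplicon read counts,
lineages x timepoints, together with the generation number of each sampled
timepoint and the environment code of each inter-timepoint interval.
Optional per-lineage metadata carry spiked-in neutral flags and the
experiment of origin of each barcode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LineageTrackingDataset",
    "DatasetValidationError",
    "read_counts",
    "write_counts",
    "to_frequencies",
]


class DatasetValidationError(ValueError):
    """Raised when a count table violates the dataset invariants."""


@dataclass
class LineageTrackingDataset:
    """Integer barcode counts over sampled timepoints.

    Attributes
    ----------
    counts
        ``(n_lineages, n_timepoints)`` non-negative integer matrix.
    generations
        Strictly increasing generation number of each timepoint.
    env_labels
        Environment code of each interval between consecutive timepoints
        (length ``n_timepoints - 1``).
    barcode_ids
        Unique lineage identifiers.
    neutral_flags
        Optional booleans marking known-neutral (spiked-in) lineages.
    origin_labels
        Optional experiment-of-origin label per lineage.
    """

    counts: np.ndarray
    generations: np.ndarray
    env_labels: list[str]
    barcode_ids: list[str] = field(default=None)
    neutral_flags: np.ndarray | None = None
    origin_labels: list[str] | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.generations = np.asarray(self.generations)
        if self.barcode_ids is None:
            self.barcode_ids = [f"bc{i}" for i in range(self.counts.shape[0])]
        self.validate()

    def validate(self) -> None:
        c = self.counts
        if c.ndim != 2:
            raise DatasetValidationError("counts must be a 2-D matrix")
        if np.any(c < 0):
            i, j = np.argwhere(c < 0)[0]
            raise DatasetValidationError(
                f"negative count at lineage {self.barcode_ids[i]!r} "
                f"(row {i}), timepoint column {j}"
            )
        if len(self.generations) != c.shape[1]:
            raise DatasetValidationError("generations length != n_timepoints")
        if np.any(np.diff(self.generations) <= 0):
            raise DatasetValidationError("generations must be strictly increasing")
        if len(self.env_labels) != c.shape[1] - 1:
            raise DatasetValidationError(
                "env_labels must have one entry per interval "
                f"({c.shape[1] - 1}), got {len(self.env_labels)}"
            )
        if len(self.barcode_ids) != c.shape[0]:
            raise DatasetValidationError("barcode_ids length != n_lineages")
        if len(set(self.barcode_ids)) != len(self.barcode_ids):
            seen, dup = set(), None
            for b in self.barcode_ids:
                if b in seen:
                    dup = b
                    break
                seen.add(b)
            raise DatasetValidationError(f"duplicated barcode id {dup!r}")
        if self.neutral_flags is not None:
            self.neutral_flags = np.asarray(self.neutral_flags, dtype=bool)
            if len(self.neutral_flags) != c.shape[0]:
                raise DatasetValidationError("neutral_flags length != n_lineages")
        if self.origin_labels is not None and len(self.origin_labels) != c.shape[0]:
            raise DatasetValidationError("origin_labels length != n_lineages")

    @property
    def n_lineages(self) -> int:
        return self.counts.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.counts.shape[1]

    @property
    def interval_generations(self) -> np.ndarray:
        """Generation span of each inter-timepoint interval."""
        return np.diff(self.generations)

    def subset(self, row_mask) -> "LineageTrackingDataset":
        """New dataset restricted to the selected lineages."""
        idx = np.asarray(row_mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return LineageTrackingDataset(
            counts=self.counts[idx],
            generations=self.generations.copy(),
            env_labels=list(self.env_labels),
            barcode_ids=[self.barcode_ids[i] for i in idx],
            neutral_flags=None if self.neutral_flags is None else self.neutral_flags[idx],
            origin_labels=None
            if self.origin_labels is None
            else [self.origin_labels[i] for i in idx],
        )


def to_frequencies(dataset: LineageTrackingDataset, pseudocount: float = 0.0) -> np.ndarray:
    """Per-timepoint lineage frequencies, ``(c + p) / sum(c + p)``.

    With ``pseudocount=0`` this is plain column normalization (used for
    diversity statistics); ``pseudocount=0.5`` keeps log-frequencies finite
    for slope-based fitness estimation.
    """
    c = dataset.counts.astype(float)
    col_tot = c.sum(axis=0)
    if np.any(col_tot == 0):
        j = int(np.argmax(col_tot == 0))
        raise DatasetValidationError(
            f"all-zero counts at timepoint column {j} "
            f"(generation {dataset.generations[j]})"
        )
    c = c + pseudocount
    return c / c.sum(axis=0, keepdims=True)


def write_counts(dataset: LineageTrackingDataset, path) -> None:
    """Write a dataset as a TSV count table.

    Interval environment labels go in a ``# env_labels:`` comment line;
    columns are ``barcode``, optional ``neutral``/``origin`` metadata, and
    one integer column per timepoint headed by its generation number.
    """
    df = pd.DataFrame({"barcode": dataset.barcode_ids})
    if dataset.neutral_flags is not None:
        df["neutral"] = dataset.neutral_flags.astype(int)
    if dataset.origin_labels is not None:
        df["origin"] = dataset.origin_labels
    for j, g in enumerate(dataset.generations):
        df[str(int(g))] = dataset.counts[:, j].astype(np.int64)
    with open(path, "w") as fh:
        fh.write("# env_labels: " + ",".join(dataset.env_labels) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_counts(path) -> LineageTrackingDataset:
    """Read a TSV count table written by :func:`write_counts`.

    Malformed tables (negative counts, non-monotone generation header,
    duplicated barcodes) raise :class:`DatasetValidationError` naming the
    offending row or column.
    """
    env_labels: list[str] = []
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            if line.lstrip("#").strip().startswith("env_labels:"):
                payload = line.split("env_labels:", 1)[1].strip()
                env_labels = [s for s in payload.split(",") if s]
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    meta_cols = [c for c in df.columns if not c.lstrip("-").isdigit()]
    gen_cols = [c for c in df.columns if c.lstrip("-").isdigit()]
    if "barcode" not in meta_cols:
        raise DatasetValidationError("count table lacks a 'barcode' column")
    generations = np.array([int(c) for c in gen_cols])
    counts = df[gen_cols].to_numpy()
    if not np.issubdtype(counts.dtype, np.number):
        raise DatasetValidationError("non-numeric count entries")
    counts = counts.astype(np.int64)
    if not env_labels:
        env_labels = ["?"] * (len(gen_cols) - 1)
    return LineageTrackingDataset(
        counts=counts,
        generations=generations,
        env_labels=env_labels,
        barcode_ids=df["barcode"].astype(str).tolist(),
        neutral_flags=df["neutral"].to_numpy().astype(bool) if "neutral" in df else None,
        origin_labels=df["origin"].astype(str).tolist() if "origin" in df else None,
    )
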