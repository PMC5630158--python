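"""Global and positional k-mer features anchored at the start AUG.

Sequences are described by exact overlapping occurrence counts of every
RNA k-mer of length 1..k_max, recorded over the whole sequence (global
features) and inside 20-nt windows advanced 5'-ward from the AUG in 10-nt
steps (positional features).  Windows are labelled by AUG-relative
half-open intervals, e.g. ``[-20, 0)`` is the 20 nt immediately upstream
of the start codon, so sequences of different lengths share labels.  A
*presence* representation caps every count at 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .records import SequenceRecord

_BASES = "ACGU"

COUNT = "count"
PRESENCE = "presence"
GLOBAL = "global"
WINDOW = "window"


@dataclass(frozen=True)
class FeaturizationConfig:
    k_max: int = 4
    window_len: int = 20
    step: int = 10
    representation: str = COUNT
    include_global: bool = True
    include_positional: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.k_max <= 5:
            raise ValueError("k_max must be in 1..5")
        if self.step > self.window_len:
            raise ValueError("step must not exceed window_len")
        if self.window_len < self.k_max:
            raise ValueError("window_len must be >= k_max")
        if self.representation not in (COUNT, PRESENCE):
            raise ValueError(f"unknown representation {self.representation!r}")


@dataclass(frozen=True)
class FeatureDescriptor:
    """Identity of one feature column.

    ``window`` is an AUG-relative half-open interval ``(start, end)``
    for positional features and ``None`` for global ones.
    """

    kmer: str
    scope: str
    representation: str
    window: tuple[int, int] | None = None

    def label(self) -> str:
        if self.scope == GLOBAL:
            return f"{self.kmer}|global"
        return f"{self.kmer}|[{self.window[0]},{self.window[1]})"


@dataclass
class FeatureMatrix:
    """Samples x features matrix of non-negative integer k-mer values."""

    sample_ids: list[str]
    descriptors: list[FeatureDescriptor]
    values: np.ndarray

    def __post_init__(self) -> None:
        n, m = self.values.shape
        if n != len(self.sample_ids) or m != len(self.descriptors):
            raise ValueError("matrix shape disagrees with ids/descriptors")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_columns(self, cols: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            self.sample_ids,
            [self.descriptors[j] for j in cols],
            self.values[:, cols],
        )


def enumerate_kmers(k_max: int) -> list[str]:
    """All RNA k-mers of length 1..k_max, lexicographic within length."""
    if not 1 <= k_max <= 5:
        raise ValueError("k_max must be in 1..5")
    out: list[str] = []
    for k in range(1, k_max + 1):
        level = [""]
        for _ in range(k):
            level = [p + b for p in level for b in _BASES]
        out.extend(level)
    return out


def count_global(rna: str, kmer: str) -> int:
    """Overlapping occurrence count of ``kmer`` in ``rna``."""
    k = len(kmer)
    return sum(1 for i in range(len(rna) - k + 1) if rna[i : i + k] == kmer)


def windows_for(
    rna_length: int, aug_offset: int, cfg: FeaturizationConfig
) -> list[tuple[int, int]]:
    """AUG-relative windows fully contained in the sequence.

    Windows are ``[-w*step - window_len, -w*step)`` for w = 0, 1, ...
    while the window still fits 5' of the anchor; partial 5' windows are
    dropped.  Returned most-upstream first.
    """
    if rna_length < cfg.window_len:
        warnings.warn("sequence shorter than one window; no positional features")
        return []
    wins: list[tuple[int, int]] = []
    w = 0
    while cfg.window_len + w * cfg.step <= aug_offset:
        wins.append((-cfg.window_len - w * cfg.step, -w * cfg.step))
        w += 1
    wins.reverse()
    return wins


def count_windowed(
    rna: str, kmer: str, window: tuple[int, int], aug_offset: int | None = None
) -> int:
    """Occurrences whose full extent lies inside the AUG-relative window."""
    if aug_offset is None:
        aug_offset = len(rna)
    k = len(kmer)
    lo = max(window[0] + aug_offset, 0)
    hi = min(window[1] + aug_offset, len(rna))
    return sum(1 for i in range(lo, hi - k + 1) if rna[i : i + k] == kmer)


def _window_count_for(aug_offset: int, cfg: FeaturizationConfig) -> int:
    if aug_offset < cfg.window_len:
        return 0
    return (aug_offset - cfg.window_len) // cfg.step + 1


def build_matrix(
    records: list[SequenceRecord], cfg: FeaturizationConfig
) -> FeatureMatrix:
    """Featurize a library.

    Columns are the global features (if enabled) followed by positional
    features ordered by window (most upstream first) then k-mer.  Windows
    are the union over records; a record lacking a window contributes 0
    there.
    """
    kmers = enumerate_kmers(cfg.k_max)
    kindex = {km: j for j, km in enumerate(kmers)}
    n_kmers = len(kmers)

    max_w = max((_window_count_for(r.aug_offset, cfg) for r in records), default=0)
    windows = [
        (-cfg.window_len - w * cfg.step, -w * cfg.step) for w in range(max_w)
    ]
    windows.reverse()
    win_block = {win: i for i, win in enumerate(windows)}

    descriptors: list[FeatureDescriptor] = []
    if cfg.include_global:
        descriptors += [
            FeatureDescriptor(km, GLOBAL, cfg.representation) for km in kmers
        ]
    if cfg.include_positional:
        for win in windows:
            descriptors += [
                FeatureDescriptor(km, WINDOW, cfg.representation, win)
                for km in kmers
            ]

    g_off = 0 if cfg.include_global else None
    p_off = (n_kmers if cfg.include_global else 0) if cfg.include_positional else None

    values = np.zeros((len(records), len(descriptors)), dtype=np.int32)
    wl, st = cfg.window_len, cfg.step
    for i, rec in enumerate(records):
        rna, aug = rec.rna, rec.aug_offset
        L = len(rna)
        n_w = _window_count_for(aug, cfg)
        row = values[i]
        for pos in range(L):
            for k in range(1, cfg.k_max + 1):
                if pos + k > L:
                    break
                j = kindex[rna[pos : pos + k]]
                if g_off is not None:
                    row[g_off + j] += 1
                if p_off is None or n_w == 0:
                    continue
                # occurrence spans AUG-relative [p, p+k); window w holds it
                # iff -wl - w*st <= p and p + k <= -w*st
                p = pos - aug
                w_lo = max(0, -((p + wl) // st))
                w_hi = min(n_w - 1, (-(p + k)) // st)
                for w in range(w_lo, w_hi + 1):
                    win = (-wl - w * st, -w * st)
                    row[p_off + win_block[win] * n_kmers + j] += 1
    if cfg.representation == PRESENCE:
        np.minimum(values, 1, out=values)
    return FeatureMatrix([r.id for r in records], descriptors, values)


def apply_presence(matrix: FeatureMatrix) -> FeatureMatrix:
    """Cap counts at 1 (idempotent)."""
    descs = [
        FeatureDescriptor(d.kmer, d.scope, PRESENCE, d.window)
        for d in matrix.descriptors
    ]
    return FeatureMatrix(matrix.sample_ids, descs, np.minimum(matrix.values, 1))


def descriptor_table(descriptors: list[FeatureDescriptor]) -> pd.DataFrame:
    """Long-format descriptor sidecar (kmer, scope, window bounds, representation)."""
    return pd.DataFrame(
        {
            "kmer": [d.kmer for d in descriptors],
            "scope": [d.scope for d in descriptors],
            "window_start": [d.window[0] if d.window else pd.NA for d in descriptors],
            "window_end": [d.window[1] if d.window else pd.NA for d in descriptors],
            "representation": [d.representation for d in descriptors],
        }
    )


def write_matrix(matrix: FeatureMatrix, prefix: str | Path) -> None:
    """Serialize as sparse triplets plus a descriptor sidecar (TSV)."""
    prefix = Path(prefix)
    rows, cols = np.nonzero(matrix.values)
    trip = pd.DataFrame(
        {"row": rows, "col": cols, "value": matrix.values[rows, cols]}
    )
    trip.to_csv(prefix.with_suffix(".triplets.tsv"), sep="\t", index=False)
    sidecar = descriptor_table(matrix.descriptors)
    sidecar.insert(0, "col", np.arange(len(matrix.descriptors)))
    sidecar.to_csv(prefix.with_suffix(".features.tsv"), sep="\t", index=False)
    pd.DataFrame({"row": np.arange(matrix.n_samples), "id": matrix.sample_ids}).to_csv(
        prefix.with_suffix(".samples.tsv"), sep="\t", index=False
    )


def read_matrix(prefix: str | Path) -> FeatureMatrix:
    prefix = Path(prefix)
    trip = pd.read_csv(prefix.with_suffix(".triplets.tsv"), sep="\t")
    feats = pd.read_csv(prefix.with_suffix(".features.tsv"), sep="\t")
    samples = pd.read_csv(prefix.with_suffix(".samples.tsv"), sep="\t", dtype={"id": str})
    descriptors = [
        FeatureDescriptor(
            row.kmer,
            row.scope,
            row.representation,
            None
            if pd.isna(row.window_start)
            else (int(row.window_start), int(row.window_end)),
        )
        for row in feats.itertuples(index=False)
    ]
    values = np.zeros((len(samples), len(descriptors)), dtype=np.int32)
    values[trip["row"].to_numpy(), trip["col"].to_numpy()] = trip["value"].to_numpy()
    return FeatureMatrix(samples["id"].tolist(), descriptors, values)
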