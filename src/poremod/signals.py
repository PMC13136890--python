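"""Per-read, per-position current signal features and their preprocessing.

A signal matrix holds one record per (read, reference position): dwell time,
event current mean, and event current standard deviation, as emitted by
signal-to-reference aligners.  Before the energy-distance stage the dwell
channel is log-transformed and every channel is robustly scaled per position
— (x − median) / (1.4826 · MAD) — with the median and MAD pooled over the
modified and control samples jointly, so that genuine between-sample shifts
survive scaling.  The per-position feature vectors used downstream are
9-dimensional: (log-dwell, mean, sd) at the center position and its two
immediate neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, FormatError, ValidationError

CHANNELS = ("dwell", "mean", "sd")
SIGNAL_COLUMNS = ["read_id", "position", "dwell", "mean", "sd"]

#: consistency constant making MAD estimate the SD under normality
MAD_SCALE = 1.4826


class SignalMatrix:
    """Per-read, per-position signal records for one sample.

    At most one record per (read_id, position).  ``preprocessed`` marks a
    matrix whose dwell channel is log-scaled and whose channels are robustly
    scaled; raw-domain invariants (dwell > 0, sd ≥ 0) apply only before
    preprocessing.
    """

    def __init__(self, df: pd.DataFrame, ref_length: int, label: str = "",
                 preprocessed: bool = False):
        missing = [c for c in SIGNAL_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"signal matrix missing columns {missing}")
        df = df[SIGNAL_COLUMNS].copy()
        dup = df.duplicated(subset=["read_id", "position"])
        if dup.any():
            pairs = df.loc[dup, ["read_id", "position"]].head(5).to_numpy().tolist()
            raise ValidationError(f"duplicate (read_id, position) records: {pairs}")
        if not preprocessed:
            bad_dwell = df.index[df["dwell"] <= 0].tolist()
            if bad_dwell:
                raise ValidationError(
                    f"non-positive dwell in rows {bad_dwell[:10]} (0-based data rows)"
                )
            if (df["sd"] < 0).any():
                raise ValidationError("negative current SD values")
        if len(df) and df["position"].max() > ref_length:
            raise ValidationError("record position exceeds reference length")
        self.df = df.reset_index(drop=True)
        self.ref_length = int(ref_length)
        self.label = label
        self.preprocessed = preprocessed

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_reads(self) -> int:
        return self.df["read_id"].nunique()

    def coverage_fractions(self) -> pd.Series:
        """Covered-position count / reference length, per read."""
        return self.df.groupby("read_id")["position"].nunique() / self.ref_length

    def equals(self, other: "SignalMatrix") -> bool:
        a = self.df.sort_values(["read_id", "position"]).reset_index(drop=True)
        b = other.df.sort_values(["read_id", "position"]).reset_index(drop=True)
        return self.ref_length == other.ref_length and a.equals(b)

    def to_dense(self) -> dict[str, np.ndarray]:
        """Dense (n_reads, ref_length) arrays per channel, NaN where absent."""
        reads = self.df["read_id"].unique()
        ridx = pd.Series(np.arange(len(reads)), index=reads)
        i = ridx[self.df["read_id"]].to_numpy()
        j = self.df["position"].to_numpy() - 1
        dense = {}
        for ch in CHANNELS:
            arr = np.full((len(reads), self.ref_length), np.nan)
            arr[i, j] = self.df[ch].to_numpy()
            dense[ch] = arr
        return dense

    # --- I/O --------------------------------------------------------------

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def read_signal_tsv(path, ref_length: int | None = None, label: str = "") -> SignalMatrix:
    """Read the signal TSV dialect (read_id, position, dwell, mean, sd).

    Malformed rows are rejected with their (1-based) data line numbers.
    ``ref_length`` defaults to the maximum observed position.
    """
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot parse signal TSV {path}: {exc}") from exc
    missing = [c for c in SIGNAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    for col in ("position", "dwell", "mean", "sd"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna()] + 1
        if len(bad):
            raise FormatError(f"{path}: non-numeric {col!r} in data rows {bad.tolist()[:10]}")
        df[col] = coerced
    bad_dwell = (df.index[df["dwell"] <= 0] + 1).tolist()
    if bad_dwell:
        raise ValidationError(f"{path}: non-positive dwell in data rows {bad_dwell[:10]}")
    df["position"] = df["position"].astype(int)
    df["read_id"] = df["read_id"].astype(str)
    if ref_length is None:
        ref_length = int(df["position"].max()) if len(df) else 0
    return SignalMatrix(df, ref_length=ref_length, label=label)


def coverage_filter(sm: SignalMatrix, min_frac: float = 0.9) -> SignalMatrix:
    """Retain reads whose covered fraction of the reference is ≥ min_frac."""
    if not 0 < min_frac <= 1:
        raise ConfigurationError(f"min_frac must be in (0, 1], got {min_frac}")
    frac = sm.coverage_fractions()
    keep = frac.index[frac >= min_frac]
    df = sm.df[sm.df["read_id"].isin(keep)]
    return SignalMatrix(df, ref_length=sm.ref_length, label=sm.label,
                        preprocessed=sm.preprocessed)


def robust_scale(values: np.ndarray) -> tuple[np.ndarray, bool]:
    """Center by the median and scale by 1.4826·MAD.

    Returns (scaled values, degenerate flag); when MAD is 0 the values are
    only centered and the flag is True.
    """
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    if mad == 0:
        return values - med, True
    return (values - med) / (MAD_SCALE * mad), False


def preprocess(
    modified: SignalMatrix, control: SignalMatrix
) -> tuple[SignalMatrix, SignalMatrix, list[tuple[int, str]]]:
    """Log-transform dwell and robustly scale every channel per position.

    Median and MAD are pooled over both samples at each position.  Returns
    the two scaled matrices plus a list of (position, channel) pairs where
    the MAD was 0 and the fallback (centering only) was taken.
    """
    if len(modified) == 0 or len(control) == 0:
        raise ValidationError("preprocess requires two non-empty signal matrices")
    if modified.preprocessed or control.preprocessed:
        raise ValidationError("signal matrices are already preprocessed")

    dfs = [modified.df.copy(), control.df.copy()]
    for df in dfs:
        df["dwell"] = np.log(df["dwell"].to_numpy())

    pooled = pd.concat(dfs, keys=("modified", "control"))
    warnings: list[tuple[int, str]] = []
    for ch in CHANNELS:
        grouped = pooled.groupby("position")[ch]
        med = grouped.transform("median")
        mad = (pooled[ch] - med).abs().groupby(pooled["position"]).transform("median")
        scale = MAD_SCALE * mad
        degenerate = scale == 0
        scaled = np.where(degenerate, pooled[ch] - med, (pooled[ch] - med) / scale.replace(0, 1))
        pooled[ch] = scaled
        for pos in sorted(pooled.loc[degenerate, "position"].unique()):
            warnings.append((int(pos), ch))

    out = []
    for key, src in zip(("modified", "control"), (modified, control)):
        df = pooled.loc[key].reset_index(drop=True)
        out.append(SignalMatrix(df, ref_length=src.ref_length, label=src.label,
                                preprocessed=True))
    return out[0], out[1], warnings


@dataclass
class SampleFeatures:
    """Windowed 9-dimensional feature vectors for one sample at one center.

    Feature order: (log-dwell, mean, sd) at center−1, then center, then
    center+1.  One row per read covering all three positions.
    """

    center: int
    vectors: np.ndarray  # shape (n_reads, 9)
    feature_names: tuple = field(
        default=tuple(
            f"{ch}@{off:+d}" for off in (-1, 0, 1) for ch in CHANNELS
        ),
        repr=False,
    )

    @property
    def n(self) -> int:
        return self.vectors.shape[0]


def window_features(sm: SignalMatrix, center: int,
                    dense: dict[str, np.ndarray] | None = None) -> SampleFeatures | None:
    """Collect 9-vectors at ``center`` from reads covering center−1..center+1.

    Returns None (undefined-window marker) at reference edges.  ``dense`` may
    carry a precomputed ``sm.to_dense()`` to amortize repeated windowing.
    """
    if center < 2 or center > sm.ref_length - 1:
        return None
    if dense is None:
        dense = sm.to_dense()
    cols = []
    for off in (-1, 0, 1):
        j = center - 1 + off  # 0-based column
        for ch in CHANNELS:
            cols.append(dense[ch][:, j])
    mat = np.column_stack(cols)
    mat = mat[~np.isnan(mat).any(axis=1)]
    return SampleFeatures(center=center, vectors=mat)
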