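"""Two-sample energy distance profiles along a reference.

The energy distance between feature sets X = {x_1..x_n} and Y = {y_1..y_m}
is the V-statistic

    E(X, Y) = 2/(nm) ΣᵢΣⱼ ‖xᵢ − yⱼ‖  −  1/n² ΣᵢΣⱼ ‖xᵢ − xⱼ‖
                                      −  1/m² ΣᵢΣⱼ ‖yᵢ − yⱼ‖,

with ‖·‖ the Euclidean norm.  It is symmetric, zero on identical multisets,
and nonnegative in expectation under equal distributions; it is used here as
a raw per-position score, not as a test statistic with a p-value.  Sliding
3-nt windows of (log-dwell, current mean, current SD) give 9-dimensional
vectors per read; the profile holds one energy distance per valid center
position.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .exceptions import FormatError, ValidationError
from .signals import SampleFeatures, SignalMatrix, window_features

PROFILE_COLUMNS = ["position", "energy_distance", "n", "m", "defined"]


def energy_distance(x, y) -> float:
    """Two-sample energy statistic between row-wise vector sets.

    Accepts arrays of shape (n, d) / (m, d) (1-D inputs are treated as
    single-feature vectors) or SampleFeatures.
    """
    if isinstance(x, SampleFeatures):
        x = x.vectors
    if isinstance(y, SampleFeatures):
        y = y.vectors
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if y.ndim == 1:
        y = y[:, None]
    if x.ndim != 2 or y.ndim != 2:
        raise ValidationError("energy_distance expects 2-D vector sets")
    if x.shape[0] == 0 or y.shape[0] == 0:
        raise ValidationError("energy_distance requires non-empty samples")
    if x.shape[1] != y.shape[1]:
        raise ValidationError("samples must share dimensionality")
    n, m = x.shape[0], y.shape[0]
    cross = cdist(x, y).sum()
    within_x = cdist(x, x).sum()
    within_y = cdist(y, y).sum()
    return 2.0 * cross / (n * m) - within_x / n**2 - within_y / m**2


class EnergyProfile:
    """Per-position energy distances with the vector counts that produced them."""

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"energy profile missing columns {missing}")
        self.df = df[PROFILE_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def values(self) -> pd.Series:
        """Energy distance indexed by position; NaN at undefined positions."""
        s = pd.Series(
            np.where(self.df["defined"], self.df["energy_distance"], np.nan),
            index=self.df["position"],
            name="energy_distance",
        )
        return s

    def defined_values(self) -> pd.Series:
        v = self.values()
        return v[~v.isna()]

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "EnergyProfile":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls(df)


def profile(
    modified: SignalMatrix,
    control: SignalMatrix,
    min_vectors: int = 10,
    max_vectors: int = 1000,
    subsample_seed: int = 0,
) -> EnergyProfile:
    """Energy distance per sliding 3-nt window center along the reference.

    Both matrices should have been preprocessed (log-dwell, robust scaling).
    Windows at the reference edges or with fewer than ``min_vectors`` vectors
    in either sample are undefined.  Windows larger than ``max_vectors`` are
    subsampled uniformly without replacement, seeded per position so the
    profile is reproducible.
    """
    if min_vectors < 1:
        raise ValidationError(f"min_vectors must be ≥ 1, got {min_vectors}")
    if max_vectors < min_vectors:
        raise ValidationError("max_vectors must be ≥ min_vectors")
    length = max(modified.ref_length, control.ref_length)
    pos_mod = set(modified.df["position"].unique())
    pos_ctl = set(control.df["position"].unique())
    if not pos_mod & pos_ctl:
        raise ValidationError("signal matrices cover disjoint position ranges")

    dense_mod = modified.to_dense()
    dense_ctl = control.to_dense()

    records = []
    for center in range(1, length + 1):
        fx = window_features(modified, center, dense=dense_mod)
        fy = window_features(control, center, dense=dense_ctl)
        if fx is None or fy is None or fx.n < min_vectors or fy.n < min_vectors:
            n = 0 if fx is None else fx.n
            m = 0 if fy is None else fy.n
            records.append((center, np.nan, n, m, False))
            continue
        xv, yv = fx.vectors, fy.vectors
        rng = np.random.default_rng([subsample_seed, center])
        if xv.shape[0] > max_vectors:
            xv = xv[rng.choice(xv.shape[0], size=max_vectors, replace=False)]
        if yv.shape[0] > max_vectors:
            yv = yv[rng.choice(yv.shape[0], size=max_vectors, replace=False)]
        e = energy_distance(xv, yv)
        records.append((center, e, xv.shape[0], yv.shape[0], True))

    df = pd.DataFrame(records, columns=PROFILE_COLUMNS)
    return EnergyProfile(df)
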