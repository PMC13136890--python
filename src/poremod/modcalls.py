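"""Modification-call pileups and the canonical-call denominator.

Modification-aware basecallers report, per position, how many reads were
called modified (``n_mod``), how many were called the canonical base but
unmodified (``n_canonical``), and how many were something else — miscalled,
deleted, or filtered (``n_other``).  The quantification convention is

    percent_modified = 100 · n_mod / (n_mod + n_canonical),

i.e. only reads basecalled as the relevant canonical base enter the ratio;
a site whose reads are often miscalled can therefore report a high modified
percentage from a small denominator.  ``n_other`` never affects the ratio.

The interchange format is a minimal bedMethyl-like tab-separated dialect
(0-based half-open length-1 intervals):

    chrom  start  end  mod_code  score  strand  n_mod  n_canonical  n_other  percent

where score is the valid coverage n_mod + n_canonical and strand is "+"
for single-stranded RNA references.  Percent is emitted for readability and
recomputed from the counts on input.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

MODPILEUP_COLUMNS = ["position", "mod_code", "n_mod", "n_canonical", "n_other"]


class ModPileup:
    """Per-(position, mod code) modification-call counts for one sample."""

    def __init__(self, df: pd.DataFrame, chrom: str = "ref", label: str = ""):
        missing = [c for c in MODPILEUP_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"mod pileup missing columns {missing}")
        df = df[MODPILEUP_COLUMNS].copy()
        counts = df[["n_mod", "n_canonical", "n_other"]].to_numpy()
        if (counts < 0).any():
            raise ValidationError("negative counts in modification pileup")
        if df.duplicated(subset=["position", "mod_code"]).any():
            raise ValidationError("duplicate (position, mod_code) rows")
        self.df = df.sort_values(["position", "mod_code"]).reset_index(drop=True)
        self.chrom = chrom
        self.label = label

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ModPileup)
            and self.chrom == other.chrom
            and self.df.equals(other.df)
        )

    def percent_modified(self) -> pd.Series:
        """100·n_mod/(n_mod+n_canonical) indexed by position; NaN when the
        valid coverage is zero."""
        valid = (self.df["n_mod"] + self.df["n_canonical"]).to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self.df["n_mod"].to_numpy() / valid
        pct[valid == 0] = np.nan
        return pd.Series(pct, index=self.df["position"], name="percent_modified")


def read_bedmethyl(path, label: str = "") -> ModPileup:
    """Parse the bedMethyl-like dialect; positions converted to 1-based."""
    rows = []
    chrom = "ref"
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise FormatError(f"{path}:{lineno}: expected 10 tab-separated columns")
            chrom, start, end, code = fields[0], int(fields[1]), int(fields[2]), fields[3]
            strand = fields[5]
            if end - start != 1:
                raise FormatError(
                    f"{path}:{lineno}: interval length must be 1, got {end - start}"
                )
            if strand not in ("+", "-", "."):
                raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            n_mod, n_canonical, n_other = int(fields[6]), int(fields[7]), int(fields[8])
            if min(n_mod, n_canonical, n_other) < 0:
                raise ValidationError(f"{path}:{lineno}: negative counts")
            rows.append((start + 1, code, n_mod, n_canonical, n_other))
    df = pd.DataFrame(rows, columns=MODPILEUP_COLUMNS)
    return ModPileup(df, chrom=chrom, label=label)


def write_bedmethyl(mp: ModPileup, path) -> None:
    with open(path, "w") as fh:
        for r in mp.df.itertuples(index=False):
            position, code, n_mod, n_canonical, n_other = r
            valid = n_mod + n_canonical
            pct = 100.0 * n_mod / valid if valid else 0.0
            fh.write(
                f"{mp.chrom}\t{position - 1}\t{position}\t{code}\t{valid}\t+"
                f"\t{n_mod}\t{n_canonical}\t{n_other}\t{pct:.2f}\n"
            )


def mod_fraction(mp: ModPileup, positions=None) -> pd.DataFrame:
    """Per-position modified percent, optionally restricted to a position set."""
    pct = mp.percent_modified()
    df = pd.DataFrame(
        {
            "position": mp.df["position"].to_numpy(),
            "mod_code": mp.df["mod_code"].to_numpy(),
            "percent_modified": pct.to_numpy(),
            "defined": ~np.isnan(pct.to_numpy()),
        }
    )
    if positions is not None:
        wanted = set(int(p) for p in positions)
        df = df[df["position"].isin(wanted)].reset_index(drop=True)
    return df


def cumulative_curve(mp: ModPileup) -> pd.DataFrame:
    """Running sum of percent_modified over ascending positions.

    Undefined positions contribute 0, so the curve is always non-decreasing;
    a flat curve is the signature of an unmodified control.
    """
    frac = mod_fraction(mp)
    per_pos = frac.groupby("position")["percent_modified"].sum(min_count=1)
    per_pos = per_pos.fillna(0.0).sort_index()
    return pd.DataFrame(
        {
            "position": per_pos.index.to_numpy(),
            "cumulative_percent": per_pos.cumsum().to_numpy(),
        }
    )
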