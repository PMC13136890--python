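"""Per-position basecall pileups and the total-variation error statistic.

Direct-RNA nanopore reads carry characteristic basecalling errors at and
around chemically modified nucleotides.  The primary screening statistic is
the *total variation percentage* at a reference position:

    TV = 100 * (mismatches + deletion calls + insertion calls)
             / (A + C + G + U calls + deletion calls + insertion calls)

Positions with a zero denominator (coverage gaps) are *undefined*, carried
as NaN, and excluded from every downstream summary — they are never
reported as 0%.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

RNA_BASES = ("A", "C", "G", "U")

#: column order of the pileup CSV dialect
PILEUP_COLUMNS = ["position", "ref_base", "A", "C", "G", "U", "del", "ins"]

_BASE_INDEX = {b: i for i, b in enumerate(RNA_BASES)}


def normalize_base(base: str) -> str:
    """Map a base symbol to the RNA alphabet (T -> U, lowercase folded)."""
    b = base.upper()
    return "U" if b == "T" else b


@dataclass(frozen=True)
class PileupRow:
    """Counts of base calls, deletions and insertions at one position."""

    position: int
    ref_base: str
    a: int = 0
    c: int = 0
    g: int = 0
    u: int = 0
    del_calls: int = 0
    ins_calls: int = 0

    def __post_init__(self) -> None:
        if self.ref_base not in RNA_BASES:
            raise ValidationError(
                f"ref_base {self.ref_base!r} at position {self.position} "
                f"not in RNA alphabet {RNA_BASES}"
            )
        for name in ("a", "c", "g", "u", "del_calls", "ins_calls"):
            if getattr(self, name) < 0:
                raise ValidationError(f"negative count {name} at position {self.position}")

    @property
    def depth(self) -> int:
        """Aligned depth: base calls plus deletion calls (insertions excluded)."""
        return self.a + self.c + self.g + self.u + self.del_calls

    @property
    def base_counts(self) -> dict:
        return {"A": self.a, "C": self.c, "G": self.g, "U": self.u}


@dataclass(frozen=True)
class ErrorBreakdown:
    """Per-type error fractions sharing the total-variation denominator.

    ``mismatch_*`` are percentages of calls to each non-reference base; the
    reference base's own slot is 0 by construction.  Components sum to
    ``total_variation_pct``.
    """

    position: int
    mismatch_A: float
    mismatch_C: float
    mismatch_G: float
    mismatch_U: float
    deletion_pct: float
    insertion_pct: float
    total_variation_pct: float


def total_variation(row: PileupRow) -> float:
    """Total variation percentage for one pileup row; NaN when undefined."""
    denom = row.a + row.c + row.g + row.u + row.del_calls + row.ins_calls
    if denom == 0:
        return float("nan")
    mismatches = row.depth - row.del_calls - row.base_counts[row.ref_base]
    return 100.0 * (mismatches + row.del_calls + row.ins_calls) / denom


def breakdown(row: PileupRow) -> ErrorBreakdown:
    """Split a row's total variation into per-type components."""
    denom = row.a + row.c + row.g + row.u + row.del_calls + row.ins_calls
    if denom == 0:
        nan = float("nan")
        return ErrorBreakdown(row.position, nan, nan, nan, nan, nan, nan, nan)
    mm = {
        b: (0.0 if b == row.ref_base else 100.0 * n / denom)
        for b, n in row.base_counts.items()
    }
    del_pct = 100.0 * row.del_calls / denom
    ins_pct = 100.0 * row.ins_calls / denom
    total = sum(mm.values()) + del_pct + ins_pct
    return ErrorBreakdown(
        row.position, mm["A"], mm["C"], mm["G"], mm["U"], del_pct, ins_pct, total
    )


class PileupTable:
    """Ordered per-position pileup counts over a contiguous reference interval.

    Thin wrapper around a DataFrame with columns ``position, ref_base, A, C,
    G, U, del, ins``; positions are 1-based and strictly increasing.
    """

    def __init__(self, df: pd.DataFrame, label: str = ""):
        missing = [c for c in PILEUP_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"pileup table missing columns {missing}")
        df = df[PILEUP_COLUMNS].copy()
        df["ref_base"] = df["ref_base"].map(normalize_base)
        bad = ~df["ref_base"].isin(RNA_BASES)
        if bad.any():
            raise ValidationError(
                f"ref_base outside RNA alphabet at positions "
                f"{df.loc[bad, 'position'].tolist()[:5]}"
            )
        counts = df[["A", "C", "G", "U", "del", "ins"]]
        if (counts.to_numpy() < 0).any():
            raise ValidationError("negative counts in pileup table")
        pos = df["position"].to_numpy()
        if len(pos) and not (np.diff(pos) > 0).all():
            raise ValidationError("positions must be strictly increasing without duplicates")
        self.df = df.reset_index(drop=True)
        self.label = label

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PileupTable) and self.df.equals(other.df)

    @property
    def positions(self) -> np.ndarray:
        return self.df["position"].to_numpy()

    def row(self, position: int) -> PileupRow:
        rec = self.df.loc[self.df["position"] == position]
        if rec.empty:
            raise KeyError(f"position {position} not in pileup table")
        r = rec.iloc[0]
        return PileupRow(
            int(r["position"]), r["ref_base"],
            int(r["A"]), int(r["C"]), int(r["G"]), int(r["U"]),
            int(r["del"]), int(r["ins"]),
        )

    def rows(self) -> Iterator[PileupRow]:
        # itertuples mangles the "del" column name, so go by position
        for r in self.df.itertuples(index=False):
            yield PileupRow(int(r[0]), r[1], int(r[2]), int(r[3]),
                            int(r[4]), int(r[5]), int(r[6]), int(r[7]))

    # --- vectorized statistics -------------------------------------------

    def depth(self) -> pd.Series:
        d = self.df[["A", "C", "G", "U", "del"]].sum(axis=1)
        d.index = self.df["position"]
        return d

    def total_variation(self) -> pd.Series:
        """Per-position total variation percentage, indexed by position.

        Undefined (zero-denominator) positions are NaN.
        """
        counts = self.df[["A", "C", "G", "U"]].to_numpy(dtype=float)
        dels = self.df["del"].to_numpy(dtype=float)
        ins = self.df["ins"].to_numpy(dtype=float)
        ref_idx = self.df["ref_base"].map(_BASE_INDEX).to_numpy()
        ref_count = counts[np.arange(len(counts)), ref_idx]
        denom = counts.sum(axis=1) + dels + ins
        mismatches = counts.sum(axis=1) - ref_count
        with np.errstate(invalid="ignore", divide="ignore"):
            tv = 100.0 * (mismatches + dels + ins) / denom
        tv[denom == 0] = np.nan
        return pd.Series(tv, index=self.df["position"], name="total_variation_pct")

    def breakdown_table(self) -> pd.DataFrame:
        """Per-type error percentages plus the total, one row per position."""
        counts = self.df[["A", "C", "G", "U"]].to_numpy(dtype=float)
        dels = self.df["del"].to_numpy(dtype=float)
        ins = self.df["ins"].to_numpy(dtype=float)
        ref_idx = self.df["ref_base"].map(_BASE_INDEX).to_numpy()
        denom = counts.sum(axis=1) + dels + ins
        with np.errstate(invalid="ignore", divide="ignore"):
            mm = 100.0 * counts / denom[:, None]
            del_pct = 100.0 * dels / denom
            ins_pct = 100.0 * ins / denom
        mm[np.arange(len(mm)), ref_idx] = 0.0
        undef = denom == 0
        mm[undef] = np.nan
        del_pct[undef] = np.nan
        ins_pct[undef] = np.nan
        out = pd.DataFrame(
            {
                "position": self.df["position"],
                "ref_base": self.df["ref_base"],
                "mismatch_A": mm[:, 0],
                "mismatch_C": mm[:, 1],
                "mismatch_G": mm[:, 2],
                "mismatch_U": mm[:, 3],
                "deletion_pct": del_pct,
                "insertion_pct": ins_pct,
            }
        )
        out["total_variation_pct"] = out[
            ["mismatch_A", "mismatch_C", "mismatch_G", "mismatch_U",
             "deletion_pct", "insertion_pct"]
        ].sum(axis=1, skipna=False)
        return out

    # --- I/O --------------------------------------------------------------

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, label: str = "") -> "PileupTable":
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # noqa: BLE001 - rewrap for the caller
            raise FormatError(f"cannot parse pileup CSV {path}: {exc}") from exc
        return cls(df, label=label or Path(str(path)).stem)


def error_delta(modified: PileupTable, control: PileupTable) -> pd.DataFrame:
    """Per-position total-variation difference, modified minus control.

    Positions undefined in either table are undefined (NaN) in the delta.
    Raises ValidationError when the position ranges do not overlap.
    """
    tv_mod = modified.total_variation()
    tv_ctl = control.total_variation()
    shared = tv_mod.index.intersection(tv_ctl.index)
    if shared.empty:
        raise ValidationError("pileup tables cover disjoint position ranges")
    delta = tv_mod.loc[shared] - tv_ctl.loc[shared]
    return pd.DataFrame(
        {
            "position": shared.to_numpy(),
            "tv_modified_pct": tv_mod.loc[shared].to_numpy(),
            "tv_control_pct": tv_ctl.loc[shared].to_numpy(),
            "delta_pct": delta.to_numpy(),
            "defined": ~np.isnan(delta.to_numpy()),
        }
    )


def pileup_from_alignments(
    alignment_path,
    reference: Mapping[str, str] | str,
    min_mapq: int = 20,
    label: str = "",
) -> PileupTable:
    """Build a PileupTable from a coordinate-sorted alignment file.

    Secondary, supplementary and unmapped records are excluded, as are reads
    below ``min_mapq`` (default Q20).  Insertions are counted as one event at
    the reference position they follow (left-anchored), at most once per read
    per position; deletions contribute one deletion call per deleted
    reference position.

    ``reference`` is either a FASTA path or a mapping of name -> sequence.
    BAM/CRAM input must be indexed; plain SAM is read sequentially.
    """
    import pysam

    from .io import read_fasta

    if isinstance(reference, (str, Path)):
        reference = read_fasta(reference)
    refs = {name: "".join(normalize_base(b) for b in seq)
            for name, seq in reference.items()}

    af = pysam.AlignmentFile(str(alignment_path))
    try:
        if (af.is_bam or af.is_cram) and not af.has_index():
            raise OSError(f"alignment file {alignment_path} has no index")
        for name in af.references:
            if name in refs and af.get_reference_length(name) != len(refs[name]):
                raise ValidationError(
                    f"reference {name!r} length mismatch between alignment header "
                    f"({af.get_reference_length(name)}) and FASTA ({len(refs[name])})"
                )
        if len(refs) != 1:
            raise ValidationError("exactly one reference sequence is expected")
        (ref_name, ref_seq), = refs.items()
        length = len(ref_seq)
        base_counts = np.zeros((length, 4), dtype=np.int64)
        del_counts = np.zeros(length, dtype=np.int64)
        ins_counts = np.zeros(length, dtype=np.int64)

        iterator = (
            af.fetch(ref_name) if af.has_index() else af.fetch(until_eof=True)
        )
        for read in iterator:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < min_mapq:
                continue
            if read.reference_name != ref_name:
                raise ValidationError(
                    f"read {read.query_name} aligned to unknown reference "
                    f"{read.reference_name!r}"
                )
            qseq = read.query_sequence or ""
            rpos = read.reference_start  # 0-based
            qpos = 0
            seen_ins: set[int] = set()
            for op, ln in read.cigartuples or ():
                if op in (0, 7, 8):  # M, =, X
                    for k in range(ln):
                        b = normalize_base(qseq[qpos + k])
                        if b in _BASE_INDEX:
                            base_counts[rpos + k, _BASE_INDEX[b]] += 1
                    rpos += ln
                    qpos += ln
                elif op == 1:  # I — anchored to the preceding reference position
                    anchor = rpos - 1
                    if anchor >= 0 and anchor not in seen_ins:
                        ins_counts[anchor] += 1
                        seen_ins.add(anchor)
                    qpos += ln
                elif op == 2:  # D
                    del_counts[rpos:rpos + ln] += 1
                    rpos += ln
                elif op == 3:  # N
                    rpos += ln
                elif op == 4:  # S
                    qpos += ln
                # H/P consume neither
    finally:
        af.close()

    df = pd.DataFrame(
        {
            "position": np.arange(1, length + 1),
            "ref_base": list(ref_seq),
            "A": base_counts[:, 0],
            "C": base_counts[:, 1],
            "G": base_counts[:, 2],
            "U": base_counts[:, 3],
            "del": del_counts,
            "ins": ins_counts,
        }
    )
    return PileupTable(df, label=label or ref_name)
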