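"""Seeded generator of paired canonical/modified nanopore-style datasets.

The generator emulates the phenomenology that the downstream analyses
assume, without synthesizing raw current waveforms:

* deletion-dominant basecall-error elevation at modified positions, decaying
  linearly to a low (<5% total) background over ``neighbor_halfwidth`` nt;
* an additive current-mean shift and multiplicative current-SD inflation at
  modified positions;
* a dwell-time slowdown applied ``dwell_offset`` positions downstream (in
  reference coordinates) of each modified site — direct RNA is sequenced
  3'→5', so the motor protein meets a modification ~10 nt before the pore's
  sensing region reads that site;
* 5'-end coverage decay: reads are 3'-anchored and a configurable fraction
  is truncated before reaching the 5' end (geometric truncation depth);
* modification-call pileups with sub-stoichiometric call rates, derived only
  from correctly basecalled reads.

Everything is driven by one integer seed; identical configurations produce
byte-identical fixture files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError
from .io import read_bed, write_bed, write_fasta
from .pileup import RNA_BASES, PileupTable
from .modcalls import ModPileup
from .signals import SignalMatrix

#: declared vocabulary of modification codes
MOD_CODE_VOCABULARY = frozenset(
    {"2OMe", "2OMePS", "PS", "LNA", "2MOE", "2F",
     "m1Y", "5moU", "m5C", "5iodoC", "mod"}
)

#: default site layout: three clusters of three alternating sites
DEFAULT_MODIFIED_POSITIONS = (33, 35, 37, 70, 72, 74, 107, 109, 111)
DEFAULT_MOD_CODES = {
    33: "2OMePS", 35: "2OMePS", 37: "2OMePS",
    70: "2OMe", 72: "2OMe", 74: "2OMe",
    107: "PS", 109: "PS", 111: "PS",
}

_ALT_BASES = {
    b: tuple(x for x in RNA_BASES if x != b) for b in RNA_BASES
}
_BASE_IDX = {b: i for i, b in enumerate(RNA_BASES)}


@dataclass(frozen=True)
class ErrorRates:
    """Per-position basecall outcome rates; the remainder is a correct call."""

    mismatch: float
    deletion: float
    insertion: float

    def validate(self, name: str) -> None:
        for f in ("mismatch", "deletion", "insertion"):
            v = getattr(self, f)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name}.{f} must be in [0, 1], got {v}")
        if self.mismatch + self.deletion > 1:
            raise ConfigurationError(
                f"{name}: mismatch + deletion must be ≤ 1 "
                f"(remainder is the correct-call probability)"
            )


@dataclass(frozen=True)
class GroundTruth:
    """1-based modified reference positions with modification codes."""

    positions: tuple
    codes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", tuple(sorted(int(p) for p in self.positions)))
        for p in self.positions:
            code = self.codes.get(p, "mod")
            if code not in MOD_CODE_VOCABULARY:
                raise ConfigurationError(
                    f"mod code {code!r} at position {p} not in vocabulary"
                )

    def code(self, position: int) -> str:
        return self.codes.get(position, "mod")

    def to_bed(self, path, chrom: str = "ref") -> None:
        write_bed([(chrom, p, self.code(p)) for p in self.positions], path)

    @classmethod
    def from_bed(cls, path) -> "GroundTruth":
        entries = read_bed(path)
        return cls(
            positions=tuple(p for _, p, _ in entries),
            codes={p: name for _, p, name in entries},
        )


@dataclass
class SimConfig:
    """Study conditions for one paired canonical/modified simulation.

    Defaults emulate a 120-nt synthetic construct with nine modified sites
    in three clusters, deletion-dominant error elevation at sites (total
    variation >20% against a <5% background), a 3-SD current-mean shift,
    1.5× current-SD inflation, and a twofold dwell slowdown offset 10 nt
    from each site.
    """

    seed: int
    ref_length: int = 120
    ref_sequence: str | None = None
    n_reads_control: int = 500
    n_reads_modified: int = 500
    modified_positions: tuple = DEFAULT_MODIFIED_POSITIONS
    mod_codes: dict | None = None
    baseline_error: ErrorRates = field(
        default_factory=lambda: ErrorRates(mismatch=0.02, deletion=0.01, insertion=0.005)
    )
    modified_error: ErrorRates = field(
        default_factory=lambda: ErrorRates(mismatch=0.05, deletion=0.15, insertion=0.02)
    )
    neighbor_halfwidth: int = 3
    signal_base_levels: dict = field(
        default_factory=lambda: {"A": -0.5, "C": 0.5, "G": 1.0, "U": -1.0}
    )
    noise_sd: float = 0.25
    dwell_logmean: float = 2.0
    dwell_logsd: float = 0.5
    mod_mean_shift: float = 0.75
    mod_sd_inflation: float = 1.5
    dwell_offset: int = 10
    dwell_shift_logmean: float = math.log(2.0)
    five_prime_dropout: float = 0.3
    five_prime_dropout_depth: float = 15.0
    mod_call_rate: float = 0.8
    false_mod_rate: float = 0.01

    def __post_init__(self) -> None:
        self.modified_positions = tuple(int(p) for p in self.modified_positions)
        self.validate()

    def validate(self) -> None:
        if self.ref_length < 3:
            raise ConfigurationError(f"ref_length must be ≥ 3, got {self.ref_length}")
        if self.ref_sequence is not None:
            seq = self.ref_sequence.upper().replace("T", "U")
            if len(seq) != self.ref_length:
                raise ConfigurationError(
                    f"ref_sequence length {len(seq)} != ref_length {self.ref_length}"
                )
            if not set(seq) <= set(RNA_BASES):
                raise ConfigurationError("ref_sequence must be over {A,C,G,U}")
            self.ref_sequence = seq
        for f in ("n_reads_control", "n_reads_modified"):
            if getattr(self, f) < 1:
                raise ConfigurationError(f"{f} must be ≥ 1")
        for p in self.modified_positions:
            if not 1 <= p <= self.ref_length:
                raise ConfigurationError(
                    f"modified_positions: {p} outside [1, {self.ref_length}]"
                )
        if len(set(self.modified_positions)) != len(self.modified_positions):
            raise ConfigurationError("modified_positions contains duplicates")
        self.baseline_error.validate("baseline_error")
        self.modified_error.validate("modified_error")
        if self.neighbor_halfwidth < 0:
            raise ConfigurationError("neighbor_halfwidth must be ≥ 0")
        if set(self.signal_base_levels) != set(RNA_BASES):
            raise ConfigurationError("signal_base_levels must map exactly A,C,G,U")
        for f in ("noise_sd", "dwell_logsd"):
            if getattr(self, f) <= 0:
                raise ConfigurationError(f"{f} must be > 0")
        if self.mod_sd_inflation <= 0:
            raise ConfigurationError("mod_sd_inflation must be > 0")
        if self.dwell_offset < 0:
            raise ConfigurationError("dwell_offset must be ≥ 0")
        for f in ("five_prime_dropout", "mod_call_rate", "false_mod_rate"):
            v = getattr(self, f)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{f} must be in [0, 1], got {v}")
        if self.five_prime_dropout_depth <= 0:
            raise ConfigurationError("five_prime_dropout_depth must be > 0")
        codes = self.mod_codes or {}
        for p, code in codes.items():
            if code not in MOD_CODE_VOCABULARY:
                raise ConfigurationError(f"mod_codes[{p}] = {code!r} not in vocabulary")

    @classmethod
    def null(cls, seed: int, **overrides) -> "SimConfig":
        """A configuration with every modification effect disabled.

        The modified sample is then drawn from the same distribution as the
        control (label-exchangeable), which calibrates the null behavior of
        the downstream statistics.
        """
        base = cls(seed=seed, **overrides)
        return replace(
            base,
            modified_error=base.baseline_error,
            mod_mean_shift=0.0,
            mod_sd_inflation=1.0,
            dwell_shift_logmean=0.0,
        )

    # --- YAML round-trip --------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["modified_positions"] = list(self.modified_positions)
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("baseline_error", "modified_error"):
            if isinstance(d.get(key), dict):
                d[key] = ErrorRates(**d[key])
        if d.get("modified_positions") is not None:
            d["modified_positions"] = tuple(d["modified_positions"])
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigurationError(f"unknown SimConfig fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class SimBundle:
    """One complete paired simulation: reference, tables, truth, config."""

    reference: str
    ref_name: str
    pileup_control: PileupTable
    pileup_modified: PileupTable
    signal_control: SignalMatrix
    signal_modified: SignalMatrix
    modcalls_control: ModPileup
    modcalls_modified: ModPileup
    truth: GroundTruth
    config: SimConfig


def _elevation_weights(cfg: SimConfig) -> np.ndarray:
    """Linear decay of error elevation around each modified site.

    Weight 1 at the site, falling to 0 just beyond ``neighbor_halfwidth``;
    overlapping clusters take the maximum.
    """
    w = np.zeros(cfg.ref_length)
    h = cfg.neighbor_halfwidth
    for p in cfg.modified_positions:
        for d in range(-h, h + 1):
            q = p + d
            if 1 <= q <= cfg.ref_length:
                w[q - 1] = max(w[q - 1], 1.0 - abs(d) / (h + 1))
    return w


def _simulate_sample(
    cfg: SimConfig,
    rng: np.random.Generator,
    ref: str,
    n_reads: int,
    modified: bool,
    label: str,
) -> tuple[PileupTable, SignalMatrix, ModPileup]:
    L = cfg.ref_length
    positions = np.arange(1, L + 1)
    ref_idx = np.array([_BASE_IDX[b] for b in ref])

    w = _elevation_weights(cfg) if modified else np.zeros(L)
    b, m = cfg.baseline_error, cfg.modified_error
    p_del = b.deletion + w * (m.deletion - b.deletion)
    p_mis = b.mismatch + w * (m.mismatch - b.mismatch)
    p_ins = b.insertion + w * (m.insertion - b.insertion)

    site = np.zeros(L, dtype=bool)
    offset_site = np.zeros(L, dtype=bool)
    if modified:
        for p in cfg.modified_positions:
            site[p - 1] = True
            offset_site[min(p + cfg.dwell_offset, L) - 1] = True

    # 3'-anchored coverage: a dropout fraction of reads starts downstream of 1
    drop = rng.random(n_reads) < cfg.five_prime_dropout
    trunc = rng.geometric(1.0 / cfg.five_prime_dropout_depth, size=n_reads)
    start = np.ones(n_reads, dtype=int)
    start[drop] = np.minimum(1 + trunc[drop], L)
    covered = positions[None, :] >= start[:, None]

    # basecall outcome per covered position
    u = rng.random((n_reads, L))
    deleted = covered & (u < p_del)
    mismatched = covered & ~deleted & (u < p_del + p_mis)
    correct = covered & ~deleted & ~mismatched
    alt_choice = rng.integers(0, 3, size=(n_reads, L))
    inserted = covered & (rng.random((n_reads, L)) < p_ins)

    # signal draws (drawn for every cell; masked afterwards)
    base_level = np.array([cfg.signal_base_levels[b_] for b_ in RNA_BASES])[ref_idx]
    mean_loc = base_level + np.where(site, cfg.mod_mean_shift, 0.0)
    current_mean = mean_loc[None, :] + rng.normal(0.0, cfg.noise_sd, (n_reads, L))
    sd_scale = np.where(site, cfg.mod_sd_inflation, 1.0)
    current_sd = cfg.noise_sd * np.abs(rng.normal(1.0, 0.3, (n_reads, L))) * sd_scale[None, :]
    dwell_loc = cfg.dwell_logmean + np.where(offset_site, cfg.dwell_shift_logmean, 0.0)
    dwell = np.exp(rng.normal(dwell_loc[None, :], cfg.dwell_logsd, (n_reads, L)))
    mod_call_u = rng.random((n_reads, L))

    # --- pileup counts ----------------------------------------------------
    call_idx = np.where(correct, ref_idx[None, :], -1)
    alt_table = np.array(
        [[_BASE_IDX[x] for x in _ALT_BASES[b_]] for b_ in RNA_BASES]
    )  # (4 ref bases, 3 alternatives)
    alt_idx = alt_table[ref_idx[None, :], alt_choice]
    call_idx = np.where(mismatched, alt_idx, call_idx)
    base_counts = np.zeros((L, 4), dtype=np.int64)
    for k in range(4):
        base_counts[:, k] = (call_idx == k).sum(axis=0)
    pile_df = pd.DataFrame(
        {
            "position": positions,
            "ref_base": list(ref),
            "A": base_counts[:, 0],
            "C": base_counts[:, 1],
            "G": base_counts[:, 2],
            "U": base_counts[:, 3],
            "del": deleted.sum(axis=0),
            "ins": inserted.sum(axis=0),
        }
    )
    pileup = PileupTable(pile_df, label=label)

    # --- signal matrix (records only for non-deleted covered positions) ---
    present = covered & ~deleted
    i, j = np.nonzero(present)
    sig_df = pd.DataFrame(
        {
            "read_id": pd.Series(i).map(lambda k: f"{label}_read_{k:05d}"),
            "position": j + 1,
            "dwell": dwell[i, j],
            "mean": current_mean[i, j],
            "sd": current_sd[i, j],
        }
    )
    signal = SignalMatrix(sig_df, ref_length=L, label=label)

    # --- modification calls (from correctly basecalled reads only) --------
    call_rate = np.where(site, cfg.mod_call_rate, cfg.false_mod_rate)
    called_mod = correct & (mod_call_u < call_rate[None, :])
    n_correct = correct.sum(axis=0)
    n_mod = called_mod.sum(axis=0)
    depth = covered.sum(axis=0)
    codes = cfg.mod_codes or DEFAULT_MOD_CODES
    code_per_pos = [
        (codes.get(p, "mod") if (modified and p in cfg.modified_positions) else "mod")
        for p in positions
    ]
    mc_df = pd.DataFrame(
        {
            "position": positions,
            "mod_code": code_per_pos,
            "n_mod": n_mod,
            "n_canonical": n_correct - n_mod,
            "n_other": depth - n_correct,
        }
    )
    mc_df = mc_df[depth > 0].reset_index(drop=True)
    modcalls = ModPileup(mc_df, chrom="ref", label=label)

    return pileup, signal, modcalls


def simulate_dataset(cfg: SimConfig) -> SimBundle:
    """Generate paired control/modified datasets under one seed.

    The control sample has every modification effect disabled; the modified
    sample applies error elevation, signal shifts and the offset dwell
    perturbation at the configured sites.  The same configuration always
    yields identical output.
    """
    cfg.validate()
    root = np.random.SeedSequence(cfg.seed)
    ss_seq, ss_ctl, ss_mod = root.spawn(3)

    if cfg.ref_sequence is not None:
        ref = cfg.ref_sequence
    else:
        ref = "".join(
            np.random.default_rng(ss_seq).choice(list(RNA_BASES), size=cfg.ref_length)
        )

    codes = cfg.mod_codes if cfg.mod_codes is not None else {
        p: DEFAULT_MOD_CODES.get(p, "mod") for p in cfg.modified_positions
    }
    truth = GroundTruth(positions=cfg.modified_positions, codes=codes)

    pc, sc, mc = _simulate_sample(
        cfg, np.random.default_rng(ss_ctl), ref, cfg.n_reads_control,
        modified=False, label="control",
    )
    pm, sm, mm = _simulate_sample(
        cfg, np.random.default_rng(ss_mod), ref, cfg.n_reads_modified,
        modified=True, label="modified",
    )
    return SimBundle(
        reference=ref,
        ref_name="synthetic_ref",
        pileup_control=pc,
        pileup_modified=pm,
        signal_control=sc,
        signal_modified=sm,
        modcalls_control=mc,
        modcalls_modified=mm,
        truth=truth,
        config=cfg,
    )


def write_fixture(bundle: SimBundle, out_dir) -> dict[str, Path]:
    """Write a bundle as plain-text fixture files; returns name -> path.

    The files round-trip losslessly through the package's readers.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": out / "reference.fasta",
        "pileup_control": out / "pileup_control.csv",
        "pileup_modified": out / "pileup_modified.csv",
        "signal_control": out / "signal_control.tsv",
        "signal_modified": out / "signal_modified.tsv",
        "modcalls_control": out / "modcalls_control.bedmethyl",
        "modcalls_modified": out / "modcalls_modified.bedmethyl",
        "truth": out / "truth.bed",
        "config": out / "config.yaml",
    }
    from .modcalls import write_bedmethyl

    write_fasta({bundle.ref_name: bundle.reference}, paths["reference"])
    bundle.pileup_control.to_csv(paths["pileup_control"])
    bundle.pileup_modified.to_csv(paths["pileup_modified"])
    bundle.signal_control.to_tsv(paths["signal_control"])
    bundle.signal_modified.to_tsv(paths["signal_modified"])
    write_bedmethyl(bundle.modcalls_control, paths["modcalls_control"])
    write_bedmethyl(bundle.modcalls_modified, paths["modcalls_modified"])
    bundle.truth.to_bed(paths["truth"], chrom=bundle.ref_name)
    bundle.config.to_yaml(paths["config"])
    return paths
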