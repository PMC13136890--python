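"""End-to-end orchestration of the analysis stages.

``run_all`` executes whatever stages the provided inputs permit: basecall
pileup error analysis, signal preprocessing plus the energy-distance
profile, site-level detection metrics against a truth BED, and
modification-call summarization.  Missing optional inputs skip their stage
with a logged notice; every output lands inside the configured output
directory, and a manifest records the package version, parameters, and
SHA-256 digests of the inputs so a re-run can be verified byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .energy import profile as energy_profile
from .evaluate import ScoredPositions, summarize
from .exceptions import ConfigurationError
from .modcalls import cumulative_curve, mod_fraction, read_bedmethyl
from .pileup import PileupTable, error_delta
from .signals import coverage_filter, preprocess, read_signal_tsv
from .simulate import GroundTruth

log = logging.getLogger("poremod")

_INPUT_FIELDS = (
    "reference", "pileup_control", "pileup_modified",
    "signal_control", "signal_modified",
    "bedmethyl_control", "bedmethyl_modified", "truth_bed",
)


@dataclass
class RunConfig:
    """Paths and parameters for one pipeline run; all paths optional except out_dir."""

    out_dir: str
    reference: str | None = None
    pileup_control: str | None = None
    pileup_modified: str | None = None
    signal_control: str | None = None
    signal_modified: str | None = None
    bedmethyl_control: str | None = None
    bedmethyl_modified: str | None = None
    truth_bed: str | None = None
    min_mapq: int = 20
    coverage_min_frac: float = 0.9
    min_vectors: int = 10
    max_vectors: int = 1000
    subsample_seed: int = 0
    tv_threshold_pct: float = 20.0
    proximity_window: int = 7
    ref_length: int | None = None
    make_plots: bool = True

    def validate(self) -> None:
        if not 0 < self.coverage_min_frac <= 1:
            raise ConfigurationError("coverage_min_frac must be in (0, 1]")
        if self.min_vectors < 1 or self.max_vectors < self.min_vectors:
            raise ConfigurationError("need 1 ≤ min_vectors ≤ max_vectors")
        if self.proximity_window < 0:
            raise ConfigurationError("proximity_window must be ≥ 0")
        for name in _INPUT_FIELDS:
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"{name}: no such file {p}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown RunConfig fields: {sorted(unknown)}")
        return cls(**d)


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_all(cfg: RunConfig) -> dict:
    """Run every stage the inputs permit; returns the manifest dict."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    outputs: dict[str, str] = {}
    metrics: dict[str, dict] = {}
    truth = GroundTruth.from_bed(cfg.truth_bed) if cfg.truth_bed else None

    def emit(name: str, path: Path) -> None:
        outputs[name] = str(path.relative_to(out))

    # --- basecall error stage --------------------------------------------
    tv_scores = None
    have_pileups = cfg.pileup_control and cfg.pileup_modified
    if have_pileups:
        ctl = PileupTable.read_csv(cfg.pileup_control, label="control")
        mod = PileupTable.read_csv(cfg.pileup_modified, label="modified")
        for table, name in ((ctl, "control"), (mod, "modified")):
            bt = table.breakdown_table()
            bt.insert(2, "depth", table.depth().to_numpy())
            path = out / f"errors_{name}.csv"
            bt.to_csv(path, index=False)
            emit(f"errors_{name}", path)
        delta = error_delta(mod, ctl)
        path = out / "error_delta.csv"
        delta.to_csv(path, index=False)
        emit("error_delta", path)
        tv_scores = mod.total_variation()
        log.info("error stage: %d positions, %d defined deltas",
                 len(delta), int(delta["defined"].sum()))
    else:
        log.info("error stage skipped: pileup CSVs not provided")

    # --- signal / energy stage -------------------------------------------
    eprofile = None
    have_signal = cfg.signal_control and cfg.signal_modified
    if have_signal:
        sc = read_signal_tsv(cfg.signal_control, ref_length=cfg.ref_length,
                             label="control")
        sm = read_signal_tsv(cfg.signal_modified, ref_length=cfg.ref_length,
                             label="modified")
        ref_length = max(sc.ref_length, sm.ref_length)
        sc.ref_length = sm.ref_length = ref_length
        n_before = (sc.n_reads, sm.n_reads)
        sc = coverage_filter(sc, cfg.coverage_min_frac)
        sm = coverage_filter(sm, cfg.coverage_min_frac)
        log.info(
            "coverage filter ≥%.0f%%: control %d→%d reads, modified %d→%d reads",
            100 * cfg.coverage_min_frac, n_before[0], sc.n_reads,
            n_before[1], sm.n_reads,
        )
        sm_p, sc_p, warnings = preprocess(sm, sc)
        if warnings:
            log.warning("robust scaling fell back to centering at %d "
                        "(position, channel) pairs", len(warnings))
        eprofile = energy_profile(
            sm_p, sc_p,
            min_vectors=cfg.min_vectors,
            max_vectors=cfg.max_vectors,
            subsample_seed=cfg.subsample_seed,
        )
        path = out / "energy_profile.csv"
        eprofile.to_csv(path)
        emit("energy_profile", path)
        log.info("energy stage: %d/%d positions defined",
                 int(eprofile.df["defined"].sum()), len(eprofile))
    else:
        log.info("signal stage skipped: signal TSVs not provided")

    # --- detection evaluation --------------------------------------------
    if truth is not None:
        if tv_scores is not None:
            sp = ScoredPositions.from_scores(tv_scores, truth.positions)
            metrics["total_variation"] = summarize(
                sp, threshold=cfg.tv_threshold_pct,
                proximity_window=cfg.proximity_window,
            )
        if eprofile is not None:
            sp = ScoredPositions.from_scores(eprofile.values(), truth.positions)
            metrics["energy_distance"] = summarize(sp)
        if metrics:
            path = out / "metrics.json"
            path.write_text(json.dumps(metrics, indent=2, sort_keys=True))
            emit("metrics", path)
    elif cfg.truth_bed is None:
        log.info("evaluation skipped: no truth BED provided")

    # --- modification-call summary ---------------------------------------
    for name, src in (("control", cfg.bedmethyl_control),
                      ("modified", cfg.bedmethyl_modified)):
        if not src:
            continue
        mp = read_bedmethyl(src, label=name)
        frac = mod_fraction(mp, positions=truth.positions if truth else None)
        path = out / f"mod_fraction_{name}.csv"
        frac.to_csv(path, index=False)
        emit(f"mod_fraction_{name}", path)
        curve = cumulative_curve(mp)
        path = out / f"cumulative_{name}.csv"
        curve.to_csv(path, index=False)
        emit(f"cumulative_{name}", path)

    # --- plots ------------------------------------------------------------
    if cfg.make_plots:
        from . import plots

        truth_pos = truth.positions if truth else ()
        if have_pileups:
            plots.plot_depth(ctl.depth(), mod.depth(), out / "depth.png", truth_pos)
            plots.plot_tv_delta(delta, out / "tv_delta.png", truth_pos)
            emit("depth_plot", out / "depth.png")
            emit("tv_delta_plot", out / "tv_delta.png")
        if eprofile is not None:
            plots.plot_energy_profile(eprofile, out / "energy.png", truth_pos)
            emit("energy_plot", out / "energy.png")
            for ch in ("dwell", "mean", "sd"):
                p = out / f"signal_{ch}.png"
                plots.plot_signal_bands(sm_p, sc_p, ch, p, truth_pos)
                emit(f"signal_{ch}_plot", p)

    manifest = {
        "poremod_version": __version__,
        "config": asdict(cfg),
        "inputs": {
            name: {"path": getattr(cfg, name), "sha256": _sha256(getattr(cfg, name))}
            for name in _INPUT_FIELDS if getattr(cfg, name)
        },
        "outputs": outputs,
        "metrics": metrics,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
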